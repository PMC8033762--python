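"""AP and CaT morphology biomarkers from sampled traces.

Extracts, per spontaneous cycle and averaged over the last transients:

* APA (mV) — AP amplitude, peak minus maximum diastolic potential (MDP);
* APD30/40/70/80/90 (ms) — duration from the upstroke (time of maximum
  dV/dt within the cycle) to x% repolarization between the peak and the
  cycle's MDP, with linear interpolation at the threshold crossing;
* AP_Tri — triangulation ratio (APD40-APD30)/(APD80-APD70);
* rate (bpm), dV/dt_max (V/s);
* CTD90 (ms) — CaT duration at 90% decay toward the per-transient
  pre-upstroke diastolic Ca2+ level, averaged over the last ``n_last``
  transients (default 8);
* diastolic and systolic cytosolic Ca2+ (nM).

Quiescent traces are a valid input: cycle detection returns an empty set
and biomarkers are reported missing with a reason rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .core import Trace

__all__ = [
    "Cycle",
    "CycleSet",
    "BiomarkerSet",
    "detect_cycles",
    "compute_biomarkers",
]

#: Repolarization levels reported as APD_x.
APD_LEVELS = (30, 40, 70, 80, 90)


@dataclass(frozen=True)
class Cycle:
    """One detected cycle: upstroke → peak → repolarization → next minimum."""

    i_start: int      # index of the pre-upstroke minimum
    i_peak: int
    i_end: int        # index of the post-peak minimum (next cycle's start)
    t_up: float       # time of max dV/dt (parabolic-refined), s
    t_peak: float
    v_peak: float
    baseline: float   # pre-upstroke diastolic level (min before upstroke)
    mdp: float        # post-peak minimum value
    t_mdp: float


@dataclass
class CycleSet:
    """Time-ordered, non-overlapping cycles for one signal (vm or cai)."""

    signal: str
    cycles: list[Cycle] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cycles)

    def __iter__(self):
        return iter(self.cycles)

    @property
    def peak_times(self) -> np.ndarray:
        return np.array([c.t_peak for c in self.cycles])

    @property
    def lengths(self) -> np.ndarray:
        """Cycle lengths (s): consecutive peak-to-peak intervals."""
        return np.diff(self.peak_times)


@dataclass
class BiomarkerSet:
    """Morphology features; unavailable entries are None with a reason."""

    apa: float | None = None          # mV
    mdp: float | None = None          # mV
    apd30: float | None = None        # ms
    apd40: float | None = None
    apd70: float | None = None
    apd80: float | None = None
    apd90: float | None = None
    ap_tri: float | None = None       # dimensionless
    rate_bpm: float | None = None
    dvdt_max: float | None = None     # V/s
    ctd90: float | None = None        # ms
    diastolic_cai: float | None = None  # nM
    systolic_cai: float | None = None   # nM
    missing: dict = field(default_factory=dict)

    def apd(self, level: int) -> float | None:
        return getattr(self, f"apd{level}")

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "missing"}
        d["missing"] = dict(self.missing)
        return d


def _refine_argmax(t: np.ndarray, y: np.ndarray, j: int) -> float:
    """Parabolic refinement of a discrete argmax (sub-sample accuracy)."""
    if j <= 0 or j >= len(y) - 1:
        return float(t[j])
    denom = y[j - 1] - 2.0 * y[j] + y[j + 1]
    if denom >= 0:
        return float(t[j])
    delta = 0.5 * (y[j - 1] - y[j + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(t[j] + delta * (t[1] - t[0]))


def detect_cycles(
    trace: Trace,
    signal: str = "vm",
    min_height: float | None = None,
    prominence: float | None = None,
    min_distance_s: float = 0.1,
    smooth_s: float = 0.011,
) -> CycleSet:
    """Peak-based cycle detection on the vm or cai channel.

    Defaults: for vm, minimum peak height 0 mV (sub-threshold residual
    activity between -40 and 0 mV does not count as an AP) and prominence
    20 mV; for cai, no absolute height and prominence 25% of the signal
    range.  Peaks and minima are located on a lightly smoothed copy (a
    quadratic local fit preserves smooth extrema exactly) while values are
    read from the raw samples.  Flat or quiescent traces yield an empty
    set.
    """
    if signal not in ("vm", "cai"):
        raise ValueError("signal must be 'vm' or 'cai'")
    y = trace.vm if signal == "vm" else trace.cai
    t = trace.t
    if len(y) < 3:
        return CycleSet(signal=signal)
    w = max(5, int(round(smooth_s / trace.dt)) | 1)
    ys = savgol_filter(y, w, polyorder=2) if w < len(y) else y
    if signal == "vm":
        height = 0.0 if min_height is None else min_height
        prom = 20.0 if prominence is None else prominence
    else:
        height = min_height
        rng = float(np.ptp(ys))
        prom = (0.25 * rng if rng > 0 else None) if prominence is None else prominence
    distance = max(1, int(round(min_distance_s / trace.dt)))
    peaks, _ = find_peaks(ys, height=height, prominence=prom, distance=distance)
    if len(peaks) == 0:
        return CycleSet(signal=signal)
    # refine to the raw-sample maximum: the smoother can shift a peak that
    # sits on a slope kink by a few samples
    k = w // 2
    peaks = np.array(
        [p - min(p, k) + int(np.argmax(y[max(p - k, 0):p + k + 1]))
         for p in peaks]
    )
    peaks = peaks[np.concatenate(([True], np.diff(peaks) > 0))]

    dydt = np.gradient(y, t)
    cycles: list[Cycle] = []
    bounds = [0, *[
        int(peaks[i] + np.argmin(ys[peaks[i]:peaks[i + 1]]))
        for i in range(len(peaks) - 1)
    ], len(y) - 1]
    for i, p in enumerate(peaks):
        i_start, i_end = bounds[i], bounds[i + 1]
        if p - i_start < 2 or i_end - p < 1:
            continue
        seg = slice(i_start, p + 1)
        j = i_start + int(np.argmax(dydt[seg]))
        t_up = _refine_argmax(t, dydt, j)
        i_mdp = p + int(np.argmin(ys[p:i_end + 1]))
        i_base = i_start + int(
            np.argmin(ys[i_start:max(i_start + 1, j + 1)])
        )
        # locate extrema on the smoothed copy, read values from the raw
        # samples (the smoother undershoots at slope kinks)
        cycles.append(
            Cycle(
                i_start=i_start,
                i_peak=int(p),
                i_end=i_end,
                t_up=t_up,
                t_peak=float(t[p]),
                v_peak=float(y[p]),
                baseline=float(y[i_base]),
                mdp=float(y[i_mdp]),
                t_mdp=float(t[i_mdp]),
            )
        )
    return CycleSet(signal=signal, cycles=cycles)


def _cross_time(
    t: np.ndarray, y: np.ndarray, i_from: int, i_to: int, thr: float
) -> float | None:
    """First downward crossing of ``thr`` in [i_from, i_to], interpolated."""
    seg = y[i_from:i_to + 1]
    below = np.nonzero(seg <= thr)[0]
    if len(below) == 0:
        return None
    j = i_from + int(below[0])
    if j == i_from or y[j] == thr:
        return float(t[j])
    t0, t1 = t[j - 1], t[j]
    y0, y1 = y[j - 1], y[j]
    return float(t0 + (t1 - t0) * (y0 - thr) / (y0 - y1))


def _transient_duration(
    t: np.ndarray, y: np.ndarray, cycle: Cycle, decay_frac: float,
    baseline: float | None = None,
) -> float | None:
    """Duration (ms) from upstroke to ``decay_frac`` recovery toward baseline."""
    base = cycle.baseline if baseline is None else baseline
    thr = cycle.v_peak - decay_frac * (cycle.v_peak - base)
    t_cross = _cross_time(t, y, cycle.i_peak, cycle.i_end, thr)
    if t_cross is None:
        return None
    return 1000.0 * (t_cross - cycle.t_up)


def compute_biomarkers(
    trace: Trace,
    n_last: int = 8,
    cycles_vm: CycleSet | None = None,
    cycles_cai: CycleSet | None = None,
    ctd_baseline: str = "per-transient",
) -> BiomarkerSet:
    """Biomarkers from the last complete cycles of a trace.

    AP features average over the last (up to) ``n_last`` complete vm cycles;
    CTD90 averages over exactly the last ``n_last`` complete CaT transients
    and is reported missing (with a reason) when fewer exist.

    ``ctd_baseline`` selects the Ca2+ decay reference: ``"per-transient"``
    (each transient's pre-upstroke diastolic level; the default) or
    ``"global"`` (the trace-wide minimum) for drifting baselines.
    """
    if ctd_baseline not in ("per-transient", "global"):
        raise ValueError("ctd_baseline must be 'per-transient' or 'global'")
    bm = BiomarkerSet()
    cyc_v = cycles_vm if cycles_vm is not None else detect_cycles(trace, "vm")
    cyc_c = cycles_cai if cycles_cai is not None else detect_cycles(trace, "cai")
    t = trace.t

    if len(cyc_v) == 0:
        bm.missing["ap"] = "no spontaneous activity"
    else:
        use = cyc_v.cycles[-n_last:]
        apas, mdps, dvdts = [], [], []
        apds: dict[int, list[float]] = {x: [] for x in APD_LEVELS}
        dvdt = np.gradient(trace.vm, t)
        for c in use:
            apas.append(c.v_peak - c.mdp)
            mdps.append(c.mdp)
            dvdts.append(float(np.max(dvdt[c.i_start:c.i_peak + 1])) / 1000.0)
            for x in APD_LEVELS:
                thr = c.v_peak - (x / 100.0) * (c.v_peak - c.mdp)
                t_cross = _cross_time(t, trace.vm, c.i_peak, c.i_end, thr)
                if t_cross is not None:
                    apds[x].append(1000.0 * (t_cross - c.t_up))
        bm.apa = float(np.mean(apas))
        bm.mdp = float(np.mean(mdps))
        bm.dvdt_max = float(np.mean(dvdts))
        for x in APD_LEVELS:
            if apds[x]:
                setattr(bm, f"apd{x}", float(np.mean(apds[x])))
        if None not in (bm.apd30, bm.apd40, bm.apd70, bm.apd80):
            denom = bm.apd80 - bm.apd70
            if denom > 0:
                bm.ap_tri = (bm.apd40 - bm.apd30) / denom
        lengths = np.diff([c.t_peak for c in use])
        if len(lengths) > 0:
            bm.rate_bpm = 60.0 / float(np.mean(lengths))

    if len(cyc_c) == 0:
        bm.missing["cat"] = "no spontaneous activity"
    else:
        use_c = cyc_c.cycles[-n_last:]
        bm.diastolic_cai = float(np.mean([c.baseline for c in use_c]))
        bm.systolic_cai = float(np.mean([c.v_peak for c in use_c]))
        global_base = float(np.min(trace.cai))
        base = None if ctd_baseline == "per-transient" else global_base
        all_durs = [
            _transient_duration(t, trace.cai, c, 0.90, baseline=base)
            for c in cyc_c.cycles
        ]
        # a transient cut off by the end of the recording never reaches 90%
        # recovery; it is not a complete CaT
        while all_durs and all_durs[-1] is None \
                and cyc_c.cycles[len(all_durs) - 1].i_end >= len(t) - 1:
            all_durs.pop()
        if len(all_durs) < n_last:
            bm.missing["ctd90"] = (
                f"only {len(all_durs)} complete CaT transients, need {n_last}"
            )
        else:
            durs = all_durs[-n_last:]
            if all(d is not None for d in durs):
                bm.ctd90 = float(np.mean(durs))
            else:
                n_bad = sum(d is None for d in durs)
                bm.missing["ctd90"] = (
                    "CaT decay did not reach 90% recovery in "
                    f"{n_bad} of the last {n_last} transients"
                )
    return bm
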