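"""Rule-based rhythm classification of AP/CaT traces.

Operationalizes the visually-assessed event vocabulary used in hSC-CM drug
screening into explicit, configurable rules over a trace and its detected
cycles.  Labels:

* ``EAD`` — early afterdepolarization: transient reversal of the membrane
  repolarization (phase 2/3) or of the CaT decay;
* ``DAD`` — delayed afterdepolarization: transient depolarization (or
  cytosolic Ca2+ increment) during diastole;
* ``RF``  — repolarization failure: stable (max upstroke velocity below
  0.2 V/s) membrane potential above -40 mV throughout the last 15 s;
* ``IRR`` — irregular rhythm: consecutive cycle-length change above 150%
  (on APs or CaTs);
* ``VT``  — tachycardia-like rhythm: spontaneous rate above 2 Hz;
* ``Q``   — quiescence: mean vm over the last 15 s below -40 mV, or all
  residual peaks below -40 mV;
* ``RESAC`` — residual activity: sub-threshold peaks between -40 and 0 mV
  that never develop into APs;
* ``NORMAL`` — none of the above.

Q and RESAC mark cessation of automaticity and are not pro-arrhythmic;
they are mutually exclusive, and NORMAL excludes everything else.

The EAD/DAD amplitude/slope/duration thresholds have no canonical printed
values (such events are usually judged by eye); the defaults here are
calibrated on the synthetic waveform suite and are all configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_coeffs, savgol_filter

from .biomarkers import Cycle, CycleSet, detect_cycles
from .core import Trace

__all__ = [
    "PROARRHYTHMIC_LABELS",
    "RhythmConfig",
    "RhythmAssessment",
    "classify_rhythm",
    "detect_ead",
    "detect_dad",
]

PROARRHYTHMIC_LABELS = frozenset({"EAD", "DAD", "RF", "IRR", "VT"})
ALL_LABELS = frozenset({"NORMAL", "EAD", "DAD", "RF", "IRR", "VT", "Q", "RESAC"})


@dataclass(frozen=True)
class RhythmConfig:
    """Thresholds for the classification rules (units in comments)."""

    window_s: float = 15.0        # cessation/RF assessment window, s
    vm_threshold: float = -40.0   # mV; Q/RESAC/RF boundary potential
    ap_peak_min: float = 0.0      # mV; peaks below this are not APs
    rf_dvdt_max: float = 0.2      # V/s; "stable" = max upstroke velocity below
    irr_ratio: float = 1.5        # consecutive cycle-length change above 150%
    vt_rate_hz: float = 2.0       # tachycardia-like above 2 Hz
    ead_min_amp: float = 2.0      # mV net re-depolarization
    ead_min_duration: float = 0.010  # s
    ead_slope: float = 10.0       # mV/s during the aberrant rise
    ead_cai_rel: float = 0.05     # CaT-decay reversal, fraction of amplitude
    dad_min_amp: float = 2.0      # mV above the local diastolic baseline
    dad_cai_rel: float = 0.10     # diastolic Ca2+ bump, fraction of baseline
    residual_prominence: float = 2.0  # mV; peaks counted as residual activity
    smooth_light_s: float = 0.011     # s; smoothing for AP-peak detection
    smooth_bump_s: float = 0.035      # s; smoothing for EAD/DAD/residual bumps
    smooth_heavy_s: float = 0.051     # s; smoothing for dV/dt estimates


@dataclass
class RhythmAssessment:
    """Label set plus the per-label evidence that triggered each rule."""

    labels: frozenset[str]
    evidence: dict = field(default_factory=dict)
    config: RhythmConfig = field(default_factory=RhythmConfig)

    def __post_init__(self):
        labels = frozenset(self.labels)
        unknown = labels - ALL_LABELS
        if unknown:
            raise ValueError(f"unknown labels {sorted(unknown)}")
        if "NORMAL" in labels and len(labels) > 1:
            raise ValueError("NORMAL is exclusive of all other labels")
        if {"Q", "RESAC"} <= labels:
            raise ValueError("Q and RESAC are mutually exclusive")
        self.labels = labels

    @property
    def proarrhythmic(self) -> bool:
        """True iff any pro-arrhythmic label fired (cessation alone is not)."""
        return bool(self.labels & PROARRHYTHMIC_LABELS)

    @property
    def cessation(self) -> bool:
        return bool(self.labels & {"Q", "RESAC"})

    def composite(self) -> str:
        """Report-style rendering, with the conventional short forms for
        co-occurring repolarization abnormalities (EDR, ER)."""
        ev = self.labels - {"Q", "RESAC"}
        parts = []
        if {"EAD", "DAD", "RF"} <= ev:
            parts.append("EDR")
            ev = ev - {"EAD", "DAD", "RF"}
        elif {"EAD", "RF"} <= ev:
            parts.append("ER")
            ev = ev - {"EAD", "RF"}
        parts.extend(sorted(ev))
        parts.extend(sorted(self.labels & {"Q", "RESAC"}))
        return "+".join(parts)


def _smooth(y: np.ndarray, dt: float, span_s: float, deriv: int = 0) -> np.ndarray:
    w = max(5, int(round(span_s / dt)) | 1)  # odd, at least 5
    if w >= len(y):
        w = (len(y) - 1) | 1
        if w < 5:
            out = y.astype(float)
            return np.gradient(out, dt) if deriv else out
    out = savgol_filter(y, w, polyorder=3 if deriv else 2, deriv=deriv,
                        delta=dt if deriv else 1.0)
    return out


def _smooth_with_floor(
    y: np.ndarray, dt: float, span_s: float
) -> tuple[np.ndarray, float]:
    """Smoothed signal plus the noise level surviving the smoother.

    The residual's robust sigma (MAD) estimates the raw noise; multiplied by
    the smoother's white-noise gain it bounds spurious bump prominence, so
    detection thresholds can be floored above it.
    """
    ys = _smooth(y, dt, span_s)
    w = max(5, min(int(round(span_s / dt)) | 1, (len(y) - 1) | 1))
    resid = y - ys
    sigma_raw = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    gain = float(np.sqrt(np.sum(savgol_coeffs(w, 2) ** 2))) if w > 2 else 1.0
    return ys, sigma_raw * gain


def detect_ead(
    trace: Trace,
    cycles: CycleSet | None = None,
    cfg: RhythmConfig | None = None,
    signal: str = "vm",
) -> list[dict]:
    """Transient reversals of repolarization (vm) or CaT decay (cai).

    Within each cycle's post-peak, pre-minimum segment, a bump counts as an
    event if its prominence on the lightly smoothed signal reaches the
    amplitude threshold, it lasts at least the minimum duration, its rising
    limb exceeds the slope threshold, and it sits above the diastolic band.
    """
    cfg = cfg or RhythmConfig()
    y = trace.vm if signal == "vm" else trace.cai
    cyc = cycles if cycles is not None else detect_cycles(trace, signal)
    if len(cyc) == 0:
        return []
    ys, floor = _smooth_with_floor(y, trace.dt, cfg.smooth_bump_s)
    events: list[dict] = []
    for k, c in enumerate(cyc):
        i0, i1 = c.i_peak, c.i_end
        if i1 - i0 < 5:
            continue
        seg = ys[i0:i1 + 1]
        if signal == "vm":
            min_amp = cfg.ead_min_amp
            band = c.mdp + 0.1 * (c.v_peak - c.mdp)
            min_slope = cfg.ead_slope
        else:
            amp = c.v_peak - c.baseline
            min_amp = cfg.ead_cai_rel * amp
            band = c.baseline + 0.1 * amp
            min_slope = 0.0
        min_amp = max(min_amp, 10.0 * floor)
        if signal == "vm":
            new_ap = cfg.ap_peak_min
        else:
            new_ap = c.baseline + 0.9 * (c.v_peak - c.baseline)
        peaks, props = find_peaks(seg, prominence=min_amp)
        for p, lb in zip(peaks, props["left_bases"]):
            if seg[p] <= band:
                continue
            if seg[p] >= new_ap:
                continue  # reaches the AP/CaT range: a new beat, not an EAD
            dur = (p - lb) * trace.dt
            if dur < cfg.ead_min_duration:
                continue
            rise = np.diff(seg[lb:p + 1]) / trace.dt
            if min_slope > 0 and (len(rise) == 0 or np.max(rise) < min_slope):
                continue
            events.append(
                {
                    "cycle": k,
                    "signal": signal,
                    "time": float(trace.t[i0 + p]),
                    "amplitude": float(seg[p] - seg[lb]),
                }
            )
    return events


def detect_dad(
    trace: Trace,
    cycles_vm: CycleSet | None = None,
    cycles_cai: CycleSet | None = None,
    cfg: RhythmConfig | None = None,
) -> list[dict]:
    """Transient diastolic depolarizations (vm) or Ca2+ increments (cai).

    Searches the intervals between one cycle's post-peak minimum and the
    next cycle's upstroke.  A vm excursion must exceed ``dad_min_amp`` above
    the local MDP baseline without reaching the AP-peak threshold; a cai
    excursion must exceed ``dad_cai_rel`` of the diastolic level.
    """
    cfg = cfg or RhythmConfig()
    events: list[dict] = []
    for signal in ("vm", "cai"):
        y = trace.vm if signal == "vm" else trace.cai
        cyc = (cycles_vm if signal == "vm" else cycles_cai)
        if cyc is None:
            cyc = detect_cycles(trace, signal)
        if len(cyc) < 2:
            continue
        ys, floor = _smooth_with_floor(y, trace.dt, cfg.smooth_bump_s)
        for k in range(len(cyc) - 1):
            c0, c1 = cyc.cycles[k], cyc.cycles[k + 1]
            # diastole starts where the signal first re-enters the band
            # just above the baseline (a hump may precede the minimum)
            band = c0.mdp + 0.1 * (c0.v_peak - c0.mdp)
            rel = np.nonzero(ys[c0.i_peak:c0.i_end + 1] < band)[0]
            if len(rel) == 0:
                continue
            i0 = c0.i_peak + int(rel[0])
            i1 = c1.i_start + int(
                np.argmax(np.gradient(ys[c1.i_start:c1.i_peak + 1], trace.dt))
            )
            if i1 - i0 < 5:
                continue
            seg = ys[i0:i1 + 1]
            if signal == "vm":
                min_amp = cfg.dad_min_amp
            else:
                min_amp = cfg.dad_cai_rel * max(c0.mdp, 1e-9)
            min_amp = max(min_amp, 10.0 * floor)
            peaks, props = find_peaks(seg, prominence=min_amp)
            for p, prom in zip(peaks, props["prominences"]):
                if signal == "vm" and seg[p] >= cfg.ap_peak_min:
                    continue  # reached AP threshold: a new AP, not a DAD
                events.append(
                    {
                        "cycle": k,
                        "signal": signal,
                        "time": float(trace.t[i0 + p]),
                        "amplitude": float(prom),
                    }
                )
    return events


def _cessation_labels(
    trace: Trace, cfg: RhythmConfig
) -> tuple[str, dict] | None:
    """Q / RESAC / RF assessment on the last ``window_s`` seconds.

    Returns (label, evidence) or None when spontaneous APs are present.
    """
    t_end = trace.t[-1]
    win = trace.window(t_end - cfg.window_s, t_end)
    vs = _smooth(win.vm, win.dt, cfg.smooth_light_s)
    ap_peaks, _ = find_peaks(vs, height=cfg.ap_peak_min, prominence=20.0)
    if len(ap_peaks) > 0:
        return None
    vb = _smooth(win.vm, win.dt, cfg.smooth_bump_s)
    res_peaks, _ = find_peaks(vb, prominence=cfg.residual_prominence)
    res_vals = vb[res_peaks]
    mean_vm = float(np.mean(win.vm))
    thr = cfg.vm_threshold
    if len(res_peaks) and np.all(res_vals < cfg.ap_peak_min) and np.max(res_vals) > thr:
        ev = {
            "n_peaks": int(len(res_peaks)),
            "peak_range_mV": [float(np.min(res_vals)), float(np.max(res_vals))],
        }
        return "RESAC", ev
    if mean_vm < thr or (len(res_peaks) and np.all(res_vals < thr)):
        return "Q", {"mean_vm_mV": mean_vm}
    dvdt = _smooth(win.vm, win.dt, cfg.smooth_heavy_s, deriv=1) / 1000.0  # V/s
    if np.all(win.vm > thr) and float(np.max(dvdt)) < cfg.rf_dvdt_max:
        return "RF", {
            "mean_vm_mV": mean_vm,
            "max_upstroke_V_per_s": float(np.max(dvdt)),
        }
    # No rule matched cleanly (e.g. slow drift across -40 mV): call it
    # failed repolarization if vm stays depolarized on average, else Q.
    if mean_vm > thr:
        return "RF", {"mean_vm_mV": mean_vm, "note": "drifting, rule fallback"}
    return "Q", {"mean_vm_mV": mean_vm, "note": "drifting, rule fallback"}


def classify_rhythm(
    trace: Trace,
    cycles_vm: CycleSet | None = None,
    cycles_cai: CycleSet | None = None,
    cfg: RhythmConfig | None = None,
) -> RhythmAssessment:
    """Classify a trace's rhythm into the label vocabulary above.

    Cessation (Q/RESAC) and repolarization failure are judged on the last
    ``window_s`` seconds; irregularity, tachycardia and afterdepolarizations
    on all complete cycles of the trace.  The trace must cover at least the
    assessment window.
    """
    cfg = cfg or RhythmConfig()
    if trace.duration < cfg.window_s:
        raise ValueError(
            f"trace covers {trace.duration:.3g} s but classification "
            f"requires at least the {cfg.window_s:.3g} s assessment window"
        )
    cyc_v = cycles_vm if cycles_vm is not None else detect_cycles(trace, "vm")
    cyc_c = cycles_cai if cycles_cai is not None else detect_cycles(trace, "cai")

    labels: set[str] = set()
    evidence: dict = {}

    cess = _cessation_labels(trace, cfg)
    if cess is not None:
        label, ev = cess
        labels.add(label)
        evidence[label] = ev

    # Irregular rhythm: any consecutive cycle pair, on APs or CaTs.
    irr_ev = []
    for cyc in (cyc_v, cyc_c):
        cl = cyc.lengths
        for k in range(len(cl) - 1):
            lo = min(cl[k], cl[k + 1])
            if lo > 0 and abs(cl[k + 1] - cl[k]) / lo > cfg.irr_ratio:
                irr_ev.append(
                    {
                        "signal": cyc.signal,
                        "time": float(cyc.peak_times[k + 1]),
                        "lengths_s": [float(cl[k]), float(cl[k + 1])],
                    }
                )
    if irr_ev:
        labels.add("IRR")
        evidence["IRR"] = irr_ev

    if cess is None and len(cyc_v) >= 2:
        rate_hz = 1.0 / float(np.mean(cyc_v.lengths))
        if rate_hz > cfg.vt_rate_hz:
            labels.add("VT")
            evidence["VT"] = {"rate_hz": rate_hz}

    ead_ev = detect_ead(trace, cyc_v, cfg, signal="vm") + detect_ead(
        trace, cyc_c, cfg, signal="cai"
    )
    if ead_ev:
        labels.add("EAD")
        evidence["EAD"] = ead_ev
    dad_ev = detect_dad(trace, cyc_v, cyc_c, cfg)
    if dad_ev:
        labels.add("DAD")
        evidence["DAD"] = dad_ev

    if not labels:
        labels = {"NORMAL"}
    return RhythmAssessment(frozenset(labels), evidence, cfg)
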