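"""Synthetic AP/CaT waveform trains with closed-form ground truth.

Templates are piecewise analytic, not ODE-derived, so every biomarker has
an exact value independent of any solver: a raised-cosine upstroke (maximum
dV/dt exactly at its midpoint), a piecewise-linear repolarization whose
knots ARE the APD30/40/70/80/90 crossing times, and an exponential
diastole.  The CaT is built the same way with its 90%-decay knot at CTD90.
Cycle onsets snap to the sampling grid so sampled extrema coincide with the
analytic ones.

Abnormalities are injected by program — each (kind, onset, magnitude) entry
perturbs the template in a way that satisfies the corresponding
classification rule by construction — and Gaussian noise is added last.
Output is deterministic given the seed.

Default morphology (rate 35 bpm, APD90 390 ms, CTD90 550 ms, MDP -75 mV,
APA 102 mV) is chosen near published baseline values for spontaneously
beating hSC-CM models, so synthetic traces resemble real recordings; these
are generator defaults, not assertions about any model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biomarkers import BiomarkerSet
from .core import Trace
from .rhythm import RhythmAssessment

__all__ = [
    "Abnormality",
    "SynthConfig",
    "generate_trace",
    "generate_label_suite",
    "generate_invitro_table",
]

ABNORMALITY_KINDS = frozenset({"EAD", "DAD", "RF", "IRR", "VT", "Q", "RESAC"})


@dataclass(frozen=True)
class Abnormality:
    """One program entry: a labeled deviation from the normal template.

    ``magnitude`` semantics by kind: EAD/DAD bump height (mV); RF plateau
    potential (mV); IRR cycle-length multiplier for one cycle; VT overriding
    rate (bpm); RESAC residual peak potential (mV); Q ignores it.
    """

    kind: str
    onset_s: float = 0.0
    magnitude: float | None = None

    def __post_init__(self):
        if self.kind not in ABNORMALITY_KINDS:
            raise ValueError(f"unknown abnormality kind {self.kind!r}")


_DEFAULT_MAGNITUDE = {
    "EAD": 15.0, "DAD": 5.0, "RF": -20.0, "IRR": 2.8, "VT": 150.0,
    "RESAC": -20.0, "Q": 0.0,
}


@dataclass(frozen=True)
class SynthConfig:
    """Waveform-train parameters; the seed fully determines the output."""

    rate_bpm: float = 35.0
    duration_s: float = 30.0
    dt: float = 1e-3
    # AP template (mV, ms)
    apa: float = 102.0
    mdp: float = -75.0
    apd30: float = 210.0
    apd40: float = 252.0
    apd70: float = 330.0
    apd80: float = 345.0
    apd90: float = 390.0
    upstroke_ms: float = 10.0
    tau_dia_ms: float = 30.0
    # CaT template (nM, ms)
    cat_amp: float = 159.0
    dia_cai: float = 18.0
    ctd90: float = 550.0
    cat_upstroke_ms: float = 40.0
    cat_delay_ms: float = 10.0
    tau_cat_ms: float = 60.0
    # noise
    sigma_vm: float = 0.0
    sigma_cai: float = 0.0
    program: tuple[Abnormality, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.rate_bpm <= 0 or self.apa <= 0 or self.apd90 <= 0:
            raise ValueError("rate, APA and APD90 must be positive")
        knots = (self.apd30, self.apd40, self.apd70, self.apd80, self.apd90)
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise ValueError("APD knots must increase strictly")
        if self.apd90 >= 1000.0 * 60.0 / self.rate_bpm:
            raise ValueError("APD90 must be shorter than the cycle length")
        kinds = [a.kind for a in self.program]
        if "Q" in kinds and "VT" in kinds:
            raise ValueError("Q and VT programs conflict")
        if "Q" in kinds and "RESAC" in kinds:
            raise ValueError("Q and RESAC programs conflict")


def _ap_cycle(
    tt: np.ndarray, cfg: SynthConfig, peak: float, tscale: float
) -> np.ndarray:
    """Analytic AP template on local time tt (s from cycle onset)."""
    d_up = cfg.upstroke_ms / 1000.0 * tscale
    apa = peak - cfg.mdp
    knots_t = np.array(
        [cfg.apd30, cfg.apd40, cfg.apd70, cfg.apd80, cfg.apd90]
    ) / 1000.0 * tscale + d_up / 2.0
    knots_v = peak - np.array([0.30, 0.40, 0.70, 0.80, 0.90]) * apa
    t90 = knots_t[-1]
    v90 = knots_v[-1]
    tau = cfg.tau_dia_ms / 1000.0

    v = np.full_like(tt, cfg.mdp)
    m_up = tt < d_up
    v[m_up] = cfg.mdp + apa * 0.5 * (1.0 - np.cos(np.pi * tt[m_up] / d_up))
    m_rep = (tt >= d_up) & (tt <= t90)
    v[m_rep] = np.interp(tt[m_rep], np.concatenate(([d_up], knots_t)),
                         np.concatenate(([peak], knots_v)))
    m_dia = tt > t90
    v[m_dia] = cfg.mdp + (v90 - cfg.mdp) * np.exp(-(tt[m_dia] - t90) / tau)
    return v


def _cat_cycle(tt: np.ndarray, cfg: SynthConfig, amp: float, tscale: float) -> np.ndarray:
    """Analytic CaT template on local time tt (s from cycle onset)."""
    delay = cfg.cat_delay_ms / 1000.0 * tscale
    d_up = cfg.cat_upstroke_ms / 1000.0 * tscale
    peak = cfg.dia_cai + amp
    t90 = delay + d_up / 2.0 + cfg.ctd90 / 1000.0 * tscale
    c90 = cfg.dia_cai + 0.10 * amp
    tau = cfg.tau_cat_ms / 1000.0

    c = np.full_like(tt, cfg.dia_cai)
    s = tt - delay
    m_up = (s >= 0) & (s < d_up)
    c[m_up] = cfg.dia_cai + amp * 0.5 * (1.0 - np.cos(np.pi * s[m_up] / d_up))
    m_dec = (s >= d_up) & (tt <= t90)
    c[m_dec] = np.interp(tt[m_dec], [delay + d_up, t90], [peak, c90])
    m_tail = tt > t90
    c[m_tail] = cfg.dia_cai + (c90 - cfg.dia_cai) * np.exp(-(tt[m_tail] - t90) / tau)
    return c


def generate_trace(
    cfg: SynthConfig,
) -> tuple[Trace, RhythmAssessment, BiomarkerSet]:
    """Build a waveform train plus its ground-truth labels and biomarkers.

    The returned BiomarkerSet holds the template's analytic values; for
    programs that destroy the normal morphology (RF, Q, RESAC, EAD...)
    the biomarkers describe the unperturbed cycles only.
    """
    rng = np.random.default_rng(cfg.seed)
    by_kind = {a.kind: a for a in cfg.program}
    mag = {
        a.kind: (a.magnitude if a.magnitude is not None
                 else _DEFAULT_MAGNITUDE[a.kind])
        for a in cfg.program
    }

    rate = mag["VT"] if "VT" in by_kind else cfg.rate_bpm
    cl_base = 60.0 / cfg.rate_bpm
    cl = 60.0 / rate
    tscale = min(1.0, cl / cl_base)  # compress templates for fast rhythms

    peak = cfg.mdp + cfg.apa
    cat_amp = cfg.cat_amp
    if "RESAC" in by_kind:
        peak = mag["RESAC"]          # residual peaks, not developing APs
        cat_amp = 0.2 * cfg.cat_amp

    n = int(round(cfg.duration_s / cfg.dt)) + 1
    t = np.arange(n) * cfg.dt
    vm = np.full(n, cfg.mdp)
    cai = np.full(n, cfg.dia_cai)

    # Cycle onsets on the sampling grid (keeps sampled extrema analytic).
    onsets: list[float] = []
    t0 = 0.2  # lead-in diastole
    irr = by_kind.get("IRR")
    irr_done = False
    while t0 < cfg.duration_s:
        if "Q" in by_kind and t0 >= by_kind["Q"].onset_s:
            break
        t0g = round(t0 / cfg.dt) * cfg.dt
        onsets.append(t0g)
        step = cl
        if irr is not None and not irr_done and t0 >= irr.onset_s:
            step = cl * mag["IRR"]
            irr_done = True
        t0 = t0g + step
        if "RF" in by_kind and onsets and onsets[-1] >= by_kind["RF"].onset_s:
            break

    n_ead = n_dad = 0
    rf_from: float | None = None
    for k, on in enumerate(onsets):
        sl = t >= on
        tt = t[sl] - on
        v_cyc = _ap_cycle(tt, cfg, peak, tscale)
        c_cyc = _cat_cycle(tt, cfg, cat_amp, tscale)

        is_last_rf = "RF" in by_kind and k == len(onsets) - 1
        if is_last_rf:
            v_rf = mag["RF"]
            hit = v_cyc <= v_rf
            v_cyc = np.where(hit, v_rf, v_cyc)
            # the CaT also fails to return to baseline, from its decay on
            decay_on = tt > (cfg.cat_delay_ms + cfg.cat_upstroke_ms) / 1000.0
            c_cyc = np.where(decay_on,
                             np.maximum(c_cyc, cfg.dia_cai + 0.3 * cat_amp),
                             c_cyc)
            rf_from = on
        vm[sl] = v_cyc
        cai[sl] = c_cyc

        if "EAD" in by_kind and on >= by_kind["EAD"].onset_s and not is_last_rf:
            # bump at 60% repolarization (between the 40% and 70% knots)
            t60 = (cfg.apd40 + (60 - 40) / (70 - 40) * (cfg.apd70 - cfg.apd40)
                   ) / 1000.0 * tscale
            tc = on + cfg.upstroke_ms / 2000.0 * tscale + t60
            vm += mag["EAD"] * np.exp(-0.5 * ((t - tc) / 0.012) ** 2)
            n_ead += 1
        if "DAD" in by_kind and on >= by_kind["DAD"].onset_s and not is_last_rf:
            t_end_ap = cfg.upstroke_ms / 2000.0 + cfg.apd90 / 1000.0
            tc = on + (t_end_ap + 0.5 * (cl - t_end_ap)) * tscale
            if tc < cfg.duration_s - 0.1:
                vm += mag["DAD"] * np.exp(-0.5 * ((t - tc) / 0.030) ** 2)
                cai += 0.15 * cfg.dia_cai * np.exp(-0.5 * ((t - tc) / 0.030) ** 2)
                n_dad += 1

    if cfg.sigma_vm > 0:
        vm = vm + rng.normal(0.0, cfg.sigma_vm, n)
    if cfg.sigma_cai > 0:
        cai = cai + rng.normal(0.0, cfg.sigma_cai, n)

    trace = Trace(
        t=t, vm=vm, cai=cai, dt=cfg.dt,
        metadata={"model": "synthetic", "seed": cfg.seed,
                  "program": [a.kind for a in cfg.program]},
    )

    # Ground truth
    truth_labels = set(by_kind) or {"NORMAL"}
    evidence: dict = {}
    if "EAD" in by_kind:
        evidence["EAD"] = {"n_events": n_ead}
    if "DAD" in by_kind:
        evidence["DAD"] = {"n_events": n_dad}
    if rf_from is not None:
        evidence["RF"] = {"from_s": rf_from}
    truth = RhythmAssessment(frozenset(truth_labels), evidence)

    bm = BiomarkerSet(
        apa=peak - cfg.mdp,
        mdp=cfg.mdp,
        apd30=cfg.apd30 * tscale,
        apd40=cfg.apd40 * tscale,
        apd70=cfg.apd70 * tscale,
        apd80=cfg.apd80 * tscale,
        apd90=cfg.apd90 * tscale,
        ap_tri=(cfg.apd40 - cfg.apd30) / (cfg.apd80 - cfg.apd70),
        rate_bpm=rate,
        dvdt_max=(peak - cfg.mdp) * math.pi
        / (2.0 * cfg.upstroke_ms * tscale),  # mV/ms == V/s
        ctd90=cfg.ctd90 * tscale,
        diastolic_cai=cfg.dia_cai,
        systolic_cai=cfg.dia_cai + cat_amp,
    )
    return trace, truth, bm


def generate_label_suite(
    seed: int = 0,
    sigma_vm: float = 0.0,
    sigma_cai: float = 0.0,
    duration_s: float = 30.0,
) -> dict[str, tuple[Trace, RhythmAssessment, BiomarkerSet]]:
    """One trace per rhythm label, with ground truth — the classifier
    calibration/validation suite."""
    programs: dict[str, tuple[Abnormality, ...]] = {
        "NORMAL": (),
        "EAD": (Abnormality("EAD", 0.0),),
        "DAD": (Abnormality("DAD", 0.0),),
        "RF": (Abnormality("RF", duration_s / 3.0),),
        "IRR": (Abnormality("IRR", duration_s / 3.0),),
        "VT": (Abnormality("VT", 0.0),),
        "Q": (Abnormality("Q", duration_s / 4.0),),
        "RESAC": (Abnormality("RESAC", 0.0),),
    }
    suite = {}
    for i, (label, program) in enumerate(programs.items()):
        cfg = SynthConfig(
            duration_s=duration_s, sigma_vm=sigma_vm, sigma_cai=sigma_cai,
            program=program, seed=seed + i,
        )
        suite[label] = generate_trace(cfg)
    return suite


def generate_invitro_table(
    n_drugs: int = 3,
    n_conc: int = 3,
    emax_pct: float = 60.0,
    ec50_uM: float = 1.0,
    hill: float = 1.0,
    sigma_pct: float = 0.0,
    event_rate: float = 0.0,
    cessation_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulated in vitro summary table: per drug x concentration rows.

    ΔCTD90% follows a monotone Hill dose-effect (per-drug Emax spread around
    ``emax_pct``) with additive Gaussian noise truncated so monotonicity in
    concentration is preserved; event/cessation labels occur at the given
    Bernoulli rates at the highest concentrations.  Schema matches the real
    in vitro loader: drug, characterization, conc_uM, dCTD90_pct, events,
    cessation.
    """
    if n_drugs < 1 or n_conc < 1:
        raise ValueError("need at least one drug and one concentration")
    rng = np.random.default_rng(seed)
    rows = []
    concs = ec50_uM * np.logspace(-1, 1, n_conc) if n_conc > 1 else [ec50_uM]
    for d in range(n_drugs):
        drug = f"drug{d + 1:02d}"
        emax = emax_pct * (1.0 + 0.25 * rng.standard_normal()) if emax_pct else 0.0
        prev = -np.inf
        for j, c in enumerate(concs):
            eff = emax * c**hill / (c**hill + ec50_uM**hill)
            if sigma_pct > 0:
                eff = eff + rng.normal(0.0, sigma_pct)
            eff = max(eff, prev)  # keep the configured monotone dose-effect
            prev = eff
            top = j == n_conc - 1
            events = "EAD" if (top and rng.random() < event_rate) else "X"
            cess = "Q" if (top and rng.random() < cessation_rate) else ""
            rows.append(
                {
                    "drug": drug,
                    "characterization": "I",
                    "conc_uM": float(c),
                    "dCTD90_pct": float(eff),
                    "events": events,
                    "cessation": cess,
                }
            )
    return pd.DataFrame(rows)
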