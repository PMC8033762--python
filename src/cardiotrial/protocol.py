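"""Experiment drivers: concentration-response drug trials and pairwise
simultaneous-block sensitivity maps.

The drug-trial protocol mirrors common in-silico screening practice for
spontaneously beating cells: free-run the model to its steady state
(default 800 s pre-run, cached per model x base scaling), then for each
drug concentration run a fixed post-drug window (default 200 s) from that
steady state, compute CTD90 on the last eight spontaneous CaTs, and assess
pro-arrhythmic events.  The control arm runs the same post-window with no
drug so that ΔCTD90% compares like for like (and an identity drug gives
exactly 0).

The sensitivity map blocks two currents simultaneously at
(0, 20, 40, 60, 80, 100)% each — 36 tests per current pair — and assigns
each cell one of four categories: spontaneous APs, cessation (quiescence /
residual activity), transient irregular rhythm turning into cessation, or
arrhythmic events (annotated with the event types).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomarkers import compute_biomarkers, detect_cycles
from .core import (
    CellModelPlugin,
    ChannelScaling,
    IntegrationFailure,
    Trace,
    run_to_steady_state,
    simulate,
)
from .drugs import DrugSpec, apply_drug
from .rhythm import RhythmAssessment, RhythmConfig, classify_rhythm

__all__ = [
    "TrialConfig",
    "TrialResult",
    "SensitivityMap",
    "SteadyStateCache",
    "run_drug_trial",
    "run_sensitivity_map",
    "run_batch",
    "load_batch_config",
    "BLOCK_LEVELS",
]

log = logging.getLogger(__name__)

#: Block percentages of the standard sensitivity grid.
BLOCK_LEVELS = (0, 20, 40, 60, 80, 100)


@dataclass(frozen=True)
class TrialConfig:
    """Protocol durations and analysis settings (seconds)."""

    t_pre: float = 800.0        # free run to steady state
    t_run: float = 200.0        # post-drug assessment run
    t_sens: float = 500.0       # sensitivity-map run
    t_sens_slow: float = 200.0  # shorter map run for slow ("heavy") models
    output_dt: float = 1e-3
    n_last: int = 8             # CaTs entering CTD90
    rhythm: RhythmConfig = field(default_factory=RhythmConfig)

    def sens_duration(self, model: CellModelPlugin) -> float:
        return self.t_sens_slow if model.slow else self.t_sens


class SteadyStateCache:
    """Memoizes run_to_steady_state per (model, base scaling, t_pre)."""

    def __init__(self):
        self._cache: dict = {}

    def get(
        self,
        model: CellModelPlugin,
        scaling: ChannelScaling | None,
        cfg: TrialConfig,
    ) -> np.ndarray:
        key = (
            model.name,
            tuple(sorted((scaling or ChannelScaling()).effective().items())),
            cfg.t_pre,
            cfg.output_dt,
        )
        if key not in self._cache:
            state, diag = run_to_steady_state(
                model, scaling, t_pre=cfg.t_pre, output_dt=cfg.output_dt
            )
            if diag["cycle_length_rel_change"] is not None:
                log.info(
                    "%s steady state at %g s: cycle-length rel change %.2e",
                    model.name, cfg.t_pre, diag["cycle_length_rel_change"],
                )
            self._cache[key] = state
        return self._cache[key]


_default_cache = SteadyStateCache()


@dataclass
class TrialResult:
    """One (model, drug, characterization, concentration) outcome."""

    model: str
    drug: str
    characterization: str
    conc_uM: float
    baseline_ctd90: float | None
    drug_ctd90: float | None
    delta_ctd90_pct: float | None
    assessment: RhythmAssessment | None
    missing_reason: str = ""

    @property
    def cessation(self) -> bool:
        return self.assessment is not None and self.assessment.cessation

    def as_record(self) -> dict:
        return {
            "model": self.model,
            "drug": self.drug,
            "characterization": self.characterization,
            "conc_uM": self.conc_uM,
            "baseline_ctd90_ms": self.baseline_ctd90,
            "drug_ctd90_ms": self.drug_ctd90,
            "dCTD90_pct": self.delta_ctd90_pct,
            "labels": (
                "+".join(sorted(self.assessment.labels))
                if self.assessment else ""
            ),
            "composite": (
                self.assessment.composite() if self.assessment else ""
            ),
            "proarrhythmic": (
                self.assessment.proarrhythmic if self.assessment else None
            ),
            "cessation": self.cessation,
            "missing_reason": self.missing_reason,
        }


def _assess_run(
    model: CellModelPlugin,
    scaling: ChannelScaling,
    state0: np.ndarray,
    cfg: TrialConfig,
    duration: float,
) -> tuple[Trace, RhythmAssessment, float | None, str]:
    """Run one post-steady-state window; return trace, labels, CTD90."""
    trace, _ = simulate(
        model, duration, scaling, initial_state=state0, output_dt=cfg.output_dt
    )
    cyc_v = detect_cycles(trace, "vm")
    cyc_c = detect_cycles(trace, "cai")
    assessment = classify_rhythm(trace, cyc_v, cyc_c, cfg.rhythm)
    bm = compute_biomarkers(
        trace, n_last=cfg.n_last, cycles_vm=cyc_v, cycles_cai=cyc_c
    )
    reason = bm.missing.get("ctd90", "") or bm.missing.get("cat", "")
    return trace, assessment, bm.ctd90, reason


def run_drug_trial(
    model: CellModelPlugin,
    spec: DrugSpec,
    concentrations: list[float],
    cfg: TrialConfig | None = None,
    base_scaling: ChannelScaling | None = None,
    cache: SteadyStateCache | None = None,
) -> list[TrialResult]:
    """Concentration-response trial of one drug characterization.

    A cached steady state feeds one control run (no drug) and one run per
    concentration, all over the same ``t_run`` window so ΔCTD90% is a
    like-for-like comparison.  Integration failures are recorded per
    concentration, not fatal to the batch.
    """
    cfg = cfg or TrialConfig()
    cache = cache or _default_cache
    base = base_scaling or ChannelScaling()
    state0 = cache.get(model, base, cfg)

    _, _, baseline_ctd90, base_reason = _assess_run(
        model, base, state0, cfg, cfg.t_run
    )
    if baseline_ctd90 is None:
        log.warning(
            "%s control run has no measurable CTD90: %s", model.name, base_reason
        )

    results = []
    for conc in concentrations:
        scaling = apply_drug(base, spec, conc, model=model)
        try:
            _, assessment, ctd90, reason = _assess_run(
                model, scaling, state0, cfg, cfg.t_run
            )
        except IntegrationFailure as err:
            results.append(
                TrialResult(
                    model.name, spec.name, spec.characterization, conc,
                    baseline_ctd90, None, None, None,
                    missing_reason=f"integration failure: {err}",
                )
            )
            continue
        delta = None
        if ctd90 is not None and baseline_ctd90:
            delta = 100.0 * (ctd90 - baseline_ctd90) / baseline_ctd90
        results.append(
            TrialResult(
                model.name, spec.name, spec.characterization, conc,
                baseline_ctd90, ctd90, delta, assessment,
                missing_reason=reason if ctd90 is None else "",
            )
        )
    return results


# ---------------------------------------------------------------------------
# Sensitivity maps

CATEGORY_COLORS = {
    "SPONTANEOUS": "#3b6fd4",               # blue
    "CESSATION": "#5fd3e8",                 # cyan
    "TRANSIENT_IRR_TO_CESSATION": "#4fb860",  # green
    "ARRHYTHMIC": "#f2d94e",                # yellow
    "ERROR": "#b0b0b0",
}


@dataclass
class SensitivityMap:
    """6x6 (by default) grid of rhythm categories under simultaneous block.

    ``cells[(pa, pb)]`` maps block percentages of channels A and B to a dict
    with ``category``, ``labels`` and (for arrhythmic cells) ``detail``.
    """

    model: str
    pair: tuple[str, str]
    levels: tuple[int, ...]
    cells: dict[tuple[int, int], dict] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cells)

    def category(self, pa: int, pb: int) -> str:
        return self.cells[(pa, pb)]["category"]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "block_" + self.pair[0] + "_pct": pa,
                "block_" + self.pair[1] + "_pct": pb,
                "category": cell["category"],
                "labels": "+".join(sorted(cell["labels"])),
                "detail": cell.get("detail", ""),
            }
            for (pa, pb), cell in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """Render the grid with the conventional four-color code."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        n = len(self.levels)
        for i, pa in enumerate(self.levels):
            for j, pb in enumerate(self.levels):
                cell = self.cells.get((pa, pb), {"category": "ERROR"})
                color = CATEGORY_COLORS.get(cell["category"], "#ffffff")
                ax.add_patch(plt.Rectangle((j, n - 1 - i), 1, 1,
                                           facecolor=color, edgecolor="k"))
                detail = cell.get("detail", "")
                if detail:
                    ax.text(j + 0.5, n - 0.5 - i, detail, ha="center",
                            va="center", fontsize=7)
        ax.set_xlim(0, n)
        ax.set_ylim(0, n)
        ax.set_xticks(np.arange(n) + 0.5, [str(v) for v in self.levels])
        ax.set_yticks(np.arange(n) + 0.5,
                      [str(v) for v in reversed(self.levels)])
        ax.set_xlabel(f"{self.pair[1]} block (%)")
        ax.set_ylabel(f"{self.pair[0]} block (%)")
        ax.set_title(self.model)
        return ax


def _categorize(assessment: RhythmAssessment) -> tuple[str, str]:
    labels = assessment.labels
    if labels == {"NORMAL"}:
        return "SPONTANEOUS", ""
    cessation = bool(labels & {"Q", "RESAC"})
    events = labels & (PROARR := {"EAD", "DAD", "RF", "IRR", "VT"})
    if cessation and events == {"IRR"}:
        # irregular rhythm that died out by run end
        return "TRANSIENT_IRR_TO_CESSATION", ""
    if cessation and not events:
        return "CESSATION", ""
    return "ARRHYTHMIC", assessment.composite()


def run_sensitivity_map(
    model: CellModelPlugin,
    pair: tuple[str, str] = ("I_Kr", "I_CaL"),
    levels: tuple[int, ...] = BLOCK_LEVELS,
    cfg: TrialConfig | None = None,
    cache: SteadyStateCache | None = None,
) -> SensitivityMap:
    """Simultaneous block of two currents on a full percentage grid.

    All runs start from the cached no-drug steady state.  A cell whose
    labels mix persistent events with cessation is ARRHYTHMIC; only a pure
    "irregular then quiescent/residual" trajectory is categorized as
    transient.  Per-cell integration failures are recorded, not raised.
    """
    cfg = cfg or TrialConfig()
    cache = cache or _default_cache
    missing = [c for c in pair if c not in model.scalable_currents]
    if missing:
        raise ValueError(
            f"model {model.name} cannot scale {missing}; "
            f"scalable: {sorted(model.scalable_currents)}"
        )
    state0 = cache.get(model, None, cfg)
    duration = cfg.sens_duration(model)

    smap = SensitivityMap(model=model.name, pair=pair, levels=tuple(levels))
    for pa in levels:
        for pb in levels:
            scaling = ChannelScaling(
                {pair[0]: 1.0 - pa / 100.0, pair[1]: 1.0 - pb / 100.0}
            )
            try:
                _, assessment, _, _ = _assess_run(
                    model, scaling, state0, cfg, duration
                )
            except IntegrationFailure as err:
                smap.cells[(pa, pb)] = {
                    "category": "ERROR", "labels": frozenset(),
                    "detail": str(err),
                }
                continue
            category, detail = _categorize(assessment)
            smap.cells[(pa, pb)] = {
                "category": category,
                "labels": assessment.labels,
                "detail": detail,
            }
    return smap


# ---------------------------------------------------------------------------
# Batch configuration

def load_batch_config(path) -> dict:
    """Read a models x drugs x concentrations batch description from YAML.

    Schema::

        models: [fixture, ...]
        drug_table: characterizations.csv   # optional; default: shipped examples
        drugs:
          - name: dofetilide
            characterization: I             # optional, default "I"
            concentrations: [0.001, 0.01, 0.1]
        t_pre: 800        # optional protocol overrides
        t_run: 200
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("models", "drugs"):
        if key not in cfg:
            raise ValueError(f"batch config missing {key!r}")
    return cfg


def run_batch(
    config: dict,
    cache: SteadyStateCache | None = None,
) -> dict[str, list[TrialResult]]:
    """Run every (model, drug, concentration) combination of a batch config.

    Returns model name → TrialResult list, ready for the comparison report.
    """
    from .core import registry
    from .drugs import example_drug_table, load_drug_table

    cache = cache or _default_cache
    cfg = TrialConfig(
        **{
            k: config[k]
            for k in ("t_pre", "t_run", "t_sens", "n_last", "output_dt")
            if k in config
        }
    )
    table = (
        load_drug_table(config["drug_table"])
        if config.get("drug_table")
        else example_drug_table()
    )
    by_key = {(s.name, s.characterization): s for s in table}

    out: dict[str, list[TrialResult]] = {}
    for model_name in config["models"]:
        model = registry.create(model_name)
        results: list[TrialResult] = []
        for entry in config["drugs"]:
            if isinstance(entry, str):
                entry = {"name": entry}
            key = (entry["name"], str(entry.get("characterization", "I")))
            if key not in by_key:
                raise KeyError(
                    f"no characterization {key[1]!r} of {key[0]!r} in the "
                    f"drug table; available: {sorted(by_key)}"
                )
            concs = [float(c) for c in entry.get("concentrations", [])]
            results.extend(
                run_drug_trial(model, by_key[key], concs, cfg, cache=cache)
            )
        out[model_name] = results
    return out
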