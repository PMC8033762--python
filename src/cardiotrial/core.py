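"""ODE engine and cell-model plugin contract.

A cell model is a set of coupled ODEs describing the membrane potential,
gating/recovery variables and intracellular Ca2+ of a spontaneously beating
cardiomyocyte.  Models plug in through :class:`CellModelPlugin`; the engine
(:func:`simulate`) integrates them with an adaptive stiff solver, with every
named ionic current individually scalable through a :class:`ChannelScaling`
(the interface used by the pore-block drug model).

No stimulus current is ever injected: all activity is automaticity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "CANONICAL_CURRENTS",
    "CellModelPlugin",
    "ChannelScaling",
    "IntegrationFailure",
    "Trace",
    "UnknownCurrentError",
    "simulate",
    "run_to_steady_state",
    "ModelRegistry",
    "registry",
]

#: Vocabulary of scalable currents and fluxes across supported models.
CANONICAL_CURRENTS = frozenset(
    {
        "I_Na", "I_NaL", "I_CaL", "I_CaT", "I_Kr", "I_Ks", "I_K1", "I_to",
        "I_f", "I_NCX", "I_NaK", "I_pCa", "I_bNa", "I_bCa",
        "J_RyR", "J_SERCA", "J_leak", "J_IP3",
    }
)

#: Modeling-paradigm tags a plugin may attach to each current.
FORMULATION_TAGS = frozenset({"HH", "HH-R", "HH-GHK", "Markov", "TT"})


class UnknownCurrentError(ValueError):
    """A scaling names a current the model cannot scale."""

    def __init__(self, unknown: Iterable[str], scalable: Iterable[str]):
        self.unknown = sorted(unknown)
        self.scalable = sorted(scalable)
        super().__init__(
            f"unknown current(s) {self.unknown}; "
            f"this model can scale {self.scalable}"
        )


class IntegrationFailure(RuntimeError):
    """The stiff solver collapsed its step size before reaching t_end."""

    def __init__(self, message: str, last_time: float):
        self.last_time = last_time
        super().__init__(f"{message} (last valid time {last_time:.6g} s)")


class ChannelScaling(Mapping[str, float]):
    """Per-current multiplicative conductance factors in [0, 1].

    Missing entries mean 1 (no block); 0 is a full block.  Composition of
    two scalings is the element-wise product.
    """

    __slots__ = ("_factors",)

    def __init__(self, factors: Mapping[str, float] | None = None):
        factors = dict(factors or {})
        for name, f in factors.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(
                    f"scaling factor for {name} must be in [0, 1], got {f}"
                )
        self._factors = factors

    def __getitem__(self, key: str) -> float:
        return self._factors[key]

    def __iter__(self):
        return iter(self._factors)

    def __len__(self) -> int:
        return len(self._factors)

    def __repr__(self) -> str:
        return f"ChannelScaling({self._factors!r})"

    def __eq__(self, other) -> bool:
        if isinstance(other, ChannelScaling):
            other = other._factors
        if isinstance(other, Mapping):
            return self.effective() == ChannelScaling(dict(other)).effective()
        return NotImplemented

    def __hash__(self):
        return hash(tuple(sorted(self.effective().items())))

    def factor(self, current: str) -> float:
        """Factor for one current (1.0 when unset)."""
        return self._factors.get(current, 1.0)

    def effective(self) -> dict[str, float]:
        """Factors with redundant 1.0 entries dropped."""
        return {k: v for k, v in self._factors.items() if v != 1.0}

    def compose(self, other: "ChannelScaling | Mapping[str, float]") -> "ChannelScaling":
        """Element-wise product of two scalings."""
        other = other if isinstance(other, ChannelScaling) else ChannelScaling(other)
        keys = set(self._factors) | set(other._factors)
        return ChannelScaling({k: self.factor(k) * other.factor(k) for k in keys})

    def restrict(self, currents: Iterable[str]) -> "ChannelScaling":
        """Drop factors for currents outside ``currents``."""
        allowed = set(currents)
        return ChannelScaling(
            {k: v for k, v in self._factors.items() if k in allowed}
        )


@dataclass
class Trace:
    """Uniformly sampled membrane-potential / cytosolic-Ca2+ time series.

    Units: ``t`` seconds, ``vm`` mV, ``cai`` nM.
    """

    t: np.ndarray
    vm: np.ndarray
    cai: np.ndarray
    dt: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.vm = np.asarray(self.vm, dtype=float)
        self.cai = np.asarray(self.cai, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (len(self.t) == len(self.vm) == len(self.cai)):
            raise ValueError("t, vm and cai must have the same length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def window(self, t_start: float, t_end: float | None = None) -> "Trace":
        """Sub-trace on [t_start, t_end] (inclusive)."""
        if t_end is None:
            t_end = self.t[-1]
        mask = (self.t >= t_start - 1e-12) & (self.t <= t_end + 1e-12)
        return Trace(self.t[mask], self.vm[mask], self.cai[mask], self.dt,
                     dict(self.metadata))


@dataclass
class CellModelPlugin:
    """Contract a spontaneously active cell model must satisfy.

    ``rhs(t, y, factors)`` returns dy/dt given the per-current factor dict
    (every scalable current present as a key); it must be deterministic.
    ``currents(t, y, factors)``, when provided, returns a record of the
    individual current values for inspection/plotting.

    ``vm_index`` / ``cai_index`` locate membrane potential (mV) and
    cytosolic Ca2+ (nM) in the state vector.
    """

    name: str
    state_names: tuple[str, ...]
    scalable_currents: frozenset[str]
    formulation_tags: dict[str, str]
    rhs: Callable[[float, np.ndarray, Mapping[str, float]], np.ndarray]
    default_initial_state: np.ndarray
    vm_index: int
    cai_index: int
    currents: Callable[[float, np.ndarray, Mapping[str, float]], dict] | None = None
    atol: np.ndarray | float = 1e-8
    slow: bool = False  # heavy models may request reduced protocol durations

    def __post_init__(self):
        unknown = self.scalable_currents - CANONICAL_CURRENTS
        if unknown:
            raise ValueError(f"non-canonical current names: {sorted(unknown)}")
        bad_tags = {
            c: t for c, t in self.formulation_tags.items()
            if t not in FORMULATION_TAGS
        }
        if bad_tags:
            raise ValueError(f"unknown formulation tags: {bad_tags}")
        self.default_initial_state = np.asarray(
            self.default_initial_state, dtype=float
        )
        if len(self.default_initial_state) != len(self.state_names):
            raise ValueError("initial state length must match state_names")

    def full_factors(self, scaling: ChannelScaling | None) -> dict[str, float]:
        """Factor dict with an entry for every scalable current.

        Raises :class:`UnknownCurrentError` if the scaling names a current
        this model cannot scale.
        """
        factors = {c: 1.0 for c in self.scalable_currents}
        if scaling is not None:
            unknown = set(scaling.effective()) - self.scalable_currents
            if unknown:
                raise UnknownCurrentError(unknown, self.scalable_currents)
            for c in scaling:
                if c in factors:
                    factors[c] = scaling.factor(c)
        return factors


def simulate(
    model: CellModelPlugin,
    duration: float,
    scaling: ChannelScaling | None = None,
    initial_state: np.ndarray | None = None,
    output_dt: float = 1e-3,
    rtol: float = 1e-7,
) -> tuple[Trace, np.ndarray]:
    """Integrate a cell model and return (Trace, final state).

    Adaptive stiff integration (LSODA) with dense output sampled on a
    uniform grid of spacing ``output_dt``.  Deterministic: identical inputs
    give bit-identical traces.  No external pacing is applied.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if output_dt <= 0:
        raise ValueError("output_dt must be positive")
    y0 = (
        model.default_initial_state
        if initial_state is None
        else np.asarray(initial_state, dtype=float)
    )
    if len(y0) != len(model.state_names):
        raise ValueError(
            f"initial state has {len(y0)} entries, "
            f"model has {len(model.state_names)} states"
        )

    factors = model.full_factors(scaling)
    rhs = model.rhs

    def fun(t, y):
        return rhs(t, y, factors)

    n = int(round(duration / output_dt))
    t_eval = np.arange(n + 1) * output_dt
    t_eval[-1] = min(t_eval[-1], duration)
    sol = solve_ivp(
        fun,
        (0.0, duration),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=model.atol,
        dense_output=False,
    )
    if not sol.success:
        last_t = float(sol.t[-1]) if len(sol.t) else 0.0
        raise IntegrationFailure(sol.message, last_t)

    trace = Trace(
        t=sol.t,
        vm=sol.y[model.vm_index],
        cai=sol.y[model.cai_index],
        dt=output_dt,
        metadata={
            "model": model.name,
            "scaling": (scaling.effective() if scaling is not None else {}),
            "duration_s": duration,
            "rtol": rtol,
        },
    )
    return trace, sol.y[:, -1].copy()


def run_to_steady_state(
    model: CellModelPlugin,
    scaling: ChannelScaling | None = None,
    t_pre: float = 800.0,
    output_dt: float = 1e-3,
) -> tuple[np.ndarray, dict]:
    """Free-run a model from its default initial state for ``t_pre`` seconds.

    Returns the final state plus a convergence diagnostic comparing the last
    two complete cycles: relative change of cycle length and of per-transient
    CTD90.  The diagnostic is reported, not asserted — whether ``t_pre``
    suffices is for the caller to judge.
    """
    if t_pre <= 0:
        raise ValueError("t_pre must be positive")
    trace, state = simulate(model, t_pre, scaling, output_dt=output_dt)

    diag: dict = {"cycle_length_rel_change": None, "ctd90_rel_change": None,
                  "n_cycles_seen": 0}
    # Local import: biomarkers depends on core for the Trace type.
    from .biomarkers import detect_cycles, _transient_duration

    tail = trace.window(max(0.0, t_pre - 60.0))
    cyc_vm = detect_cycles(tail, signal="vm")
    diag["n_cycles_seen"] = len(cyc_vm)
    if len(cyc_vm) >= 3:
        lengths = np.diff([c.t_peak for c in cyc_vm.cycles])
        if len(lengths) >= 2 and lengths[-2] > 0:
            diag["cycle_length_rel_change"] = float(
                abs(lengths[-1] - lengths[-2]) / lengths[-2]
            )
    cyc_cai = detect_cycles(tail, signal="cai")
    if len(cyc_cai) >= 2:
        d = [_transient_duration(tail.t, tail.cai, c, 0.90)
             for c in cyc_cai.cycles[-2:]]
        if d[0] is not None and d[1] is not None and d[0] > 0:
            diag["ctd90_rel_change"] = float(abs(d[1] - d[0]) / d[0])
    return state, diag


class ModelRegistry:
    """Name → plugin registry; models are discovered by name in configs."""

    def __init__(self):
        self._models: dict[str, Callable[[], CellModelPlugin]] = {}

    def register(self, name: str, factory: Callable[[], CellModelPlugin]) -> None:
        self._models[name] = factory

    def create(self, name: str, **kwargs) -> CellModelPlugin:
        try:
            factory = self._models[name]
        except KeyError:
            raise KeyError(
                f"unknown model {name!r}; registered: {sorted(self._models)}"
            ) from None
        return factory(**kwargs)

    def names(self) -> list[str]:
        return sorted(self._models)


#: Global default registry; the fixture oscillator self-registers on import.
registry = ModelRegistry()
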