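"""Fixture oscillator: a fully specified, self-contained beating cell.

A two-current relaxation oscillator of the FitzHugh-Nagumo class — cubic
fast variable, linear recovery variable — expressed directly in membrane
millivolts, plus a phenomenological cytosolic-Ca2+ follower (first-order
relaxation toward a sigmoid function of vm).  It exercises every pipeline
stage (automaticity, graded current block, cessation, biomarkers) without
any external model code, and every quantity about it (fixed points, period)
can be obtained independently by root-solving or high-accuracy integration.

The two scalable "currents" are named after the roles they play:

* ``I_CaL`` — the regenerative depolarizing current (cubic term + its own
  drive).  Scaling it to 0 removes all inward drive and the cell relaxes to
  a sub-threshold resting point (quiescence).
* ``I_Kr`` — the repolarizing recovery current.  Reducing its factor
  prolongs the action potential monotonically.

A non-scalable background leak anchors the resting potential.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .core import CellModelPlugin, registry

__all__ = ["FixtureParams", "fixture_oscillator", "resting_point"]


@dataclass(frozen=True)
class FixtureParams:
    """Versioned fixture parameters (dimensionless core + unit mapping)."""

    eps: float = 0.08      # recovery-variable time-scale ratio
    beta: float = 0.7      # recovery offset
    gamma: float = 0.8     # recovery self-limiting slope
    g_leak: float = 0.5    # background leak conductance (dimensionless)
    u_leak: float = -1.5   # leak reversal, dimensionless v-units
    drive: float = 1.25    # intrinsic drive carried by the depolarizing current
    k_rate: float = 16.8   # global rate constant, 1/s (sets the beating rate)
    v_scale: float = 40.4  # mV per dimensionless v-unit
    v_offset: float = -17.8  # mV at u = 0
    # Ca2+ follower
    cai_dia: float = 20.0    # nM, diastolic target
    cai_amp: float = 220.0   # nM, sigmoid amplitude
    v_half: float = -30.0    # mV, half-activation of the Ca2+ target
    k_ca: float = 5.0        # mV, sigmoid slope
    tau_ca: float = 0.12     # s, follower relaxation time


def _make_rhs(p: FixtureParams):
    a, b = p.v_scale, p.v_offset

    def rhs(t, y, factors):
        vm, w, c = y
        u = (vm - b) / a
        i_dep = factors["I_CaL"] * (u - u * u * u / 3.0 + p.drive)
        i_rep = factors["I_Kr"] * w
        i_leak = p.g_leak * (p.u_leak - u)
        du = p.k_rate * (i_dep - i_rep + i_leak)
        dw = p.k_rate * p.eps * (u + p.beta - p.gamma * w)
        c_inf = p.cai_dia + p.cai_amp / (1.0 + np.exp(-(vm - p.v_half) / p.k_ca))
        dc = (c_inf - c) / p.tau_ca
        return np.array([a * du, dw, dc])

    def currents(t, y, factors):
        vm, w, c = y
        u = (vm - b) / a
        return {
            "I_CaL": factors["I_CaL"] * (u - u * u * u / 3.0 + p.drive),
            "I_Kr": factors["I_Kr"] * w,
            "I_leak": p.g_leak * (p.u_leak - u),
        }

    return rhs, currents


def resting_point(
    p: FixtureParams | None = None,
    dep_factor: float = 0.0,
    rep_factor: float = 1.0,
) -> np.ndarray:
    """Algebraic fixed point of the fixture under the given current factors.

    Root-solves the (u, w) nullcline intersection independently of any time
    integration; the Ca2+ follower sits at its target.  Used as the oracle
    for cessation behavior.
    """
    p = p or FixtureParams()

    def f(u):
        w = (u + p.beta) / p.gamma
        return (
            dep_factor * (u - u**3 / 3.0 + p.drive)
            - rep_factor * w
            + p.g_leak * (p.u_leak - u)
        )

    u_star = brentq(f, -6.0, 6.0, xtol=1e-14, rtol=1e-15)
    w_star = (u_star + p.beta) / p.gamma
    vm = p.v_scale * u_star + p.v_offset
    c = p.cai_dia + p.cai_amp / (1.0 + np.exp(-(vm - p.v_half) / p.k_ca))
    return np.array([vm, w_star, c])


def fixture_oscillator(
    params: FixtureParams | None = None,
    oscillating: bool = True,
) -> CellModelPlugin:
    """Build the fixture plugin.

    ``oscillating=False`` returns a variant with the intrinsic drive removed,
    whose only attractor is a sub-threshold resting point — used to test
    steady-state convergence against the algebraic fixed point.
    """
    p = params or FixtureParams()
    if not oscillating:
        p = replace(p, drive=0.0)
    rhs, currents = _make_rhs(p)
    name = "fixture" if oscillating else "fixture-quiescent"
    # Start slightly off the resting point so the oscillating variant
    # self-starts; the state is (vm mV, recovery, cai nM).
    y0 = np.array([-70.0, 0.0, p.cai_dia])
    return CellModelPlugin(
        name=name,
        state_names=("vm", "w", "cai"),
        scalable_currents=frozenset({"I_CaL", "I_Kr"}),
        formulation_tags={"I_CaL": "HH", "I_Kr": "HH"},
        rhs=rhs,
        currents=currents,
        default_initial_state=y0,
        vm_index=0,
        cai_index=2,
        atol=np.array([1e-6, 1e-9, 1e-4]),
    )


registry.register("fixture", lambda **kw: fixture_oscillator(**kw))
registry.register(
    "fixture-quiescent",
    lambda **kw: fixture_oscillator(oscillating=False, **kw),
)
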