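"""Pore-block drug model: Hill dose-response acting on ionic conductances.

A drug is characterized per affected channel by a half-maximal blocking
concentration IC50 (µM) and a Hill coefficient n_H.  At concentration [D]
(µM), the current carried by channel i is reduced to

    I_i = I_i' / (1 + ([D]/IC50)^n_H)

i.e. a multiplicative conductance factor 1 - b with blocked fraction
b = 1 - 1/(1 + ([D]/IC50)^n_H).  Several alternative characterizations of
the same compound (different channel panels or (IC50, n_H) pairs, labeled
"I", "II", "III") may coexist.

Characterization tables load from CSV/JSON with columns/keys
``drug, characterization, channel, ic50_uM, hill`` and validate against the
seven-channel vocabulary commonly used for conductance-block screening.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import CellModelPlugin, ChannelScaling

__all__ = [
    "SEVEN_CHANNELS",
    "DrugEffect",
    "DrugSpec",
    "block_fraction",
    "fit_two_point_hill",
    "apply_drug",
    "load_drug_table",
    "save_drug_table",
    "example_drug_table",
]

log = logging.getLogger(__name__)

#: Channel panel a drug characterization may act on.
SEVEN_CHANNELS = frozenset(
    {"I_Na", "I_Kr", "I_CaL", "I_NaL", "I_Ks", "I_to", "I_K1"}
)


@dataclass(frozen=True)
class DrugEffect:
    """One channel's Hill dose-response: (channel, IC50 µM, Hill coefficient)."""

    channel: str
    ic50: float  # µM
    n_h: float   # dimensionless, > 0

    def __post_init__(self):
        if self.channel not in SEVEN_CHANNELS:
            raise ValueError(
                f"channel {self.channel!r} not in {sorted(SEVEN_CHANNELS)}"
            )
        if not self.ic50 > 0:
            raise ValueError("ic50 must be positive")
        if not self.n_h > 0:
            raise ValueError("Hill coefficient must be positive")


@dataclass(frozen=True)
class DrugSpec:
    """Named drug characterization: a set of per-channel Hill effects."""

    name: str
    characterization: str = "I"
    effects: tuple[DrugEffect, ...] = field(default_factory=tuple)
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "effects", tuple(self.effects))
        channels = [e.channel for e in self.effects]
        if len(channels) != len(set(channels)):
            raise ValueError(
                f"{self.name} {self.characterization}: "
                "at most one effect per channel per characterization"
            )

    @property
    def channels(self) -> set[str]:
        return {e.channel for e in self.effects}


def block_fraction(conc: float, effect: DrugEffect) -> float:
    """Blocked fraction in [0, 1) at concentration ``conc`` (µM).

    b = 1 - 1/(1 + (conc/IC50)^n_H); the conductance factor is 1 - b.
    Exactly 0.5 at conc == IC50 for any Hill coefficient.
    """
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    if conc == 0.0:
        return 0.0
    r = (conc / effect.ic50) ** effect.n_h
    return r / (1.0 + r)


def fit_two_point_hill(
    c1: float, b1: float, c2: float, b2: float, channel: str = "I_Kr"
) -> DrugEffect:
    """Hill curve through two (concentration, blocked-fraction) anchors.

    Closed form via the log-odds of block, r_k = b_k/(1-b_k):

        n_H  = ln(r2/r1) / ln(c2/c1)
        IC50 = c1 / r1^(1/n_H)

    The fitted curve passes through both anchors exactly (machine
    precision).  Useful to reconstruct (IC50, n_H) pairs from printed block
    percentages.
    """
    if not (0.0 < b1 < 1.0 and 0.0 < b2 < 1.0):
        raise ValueError("block fractions must lie strictly in (0, 1)")
    if c1 <= 0 or c2 <= 0 or c1 == c2:
        raise ValueError("concentrations must be positive and distinct")
    if b1 == b2 or (b2 - b1) * (c2 - c1) < 0:
        raise ValueError(
            "degenerate fit: block must increase strictly with concentration"
        )
    r1 = b1 / (1.0 - b1)
    r2 = b2 / (1.0 - b2)
    n_h = math.log(r2 / r1) / math.log(c2 / c1)
    ic50 = c1 / r1 ** (1.0 / n_h)
    return DrugEffect(channel=channel, ic50=ic50, n_h=n_h)


def apply_drug(
    base: ChannelScaling,
    spec: DrugSpec,
    conc: float,
    model: CellModelPlugin | None = None,
) -> ChannelScaling:
    """Compose a drug's block at ``conc`` µM onto an existing scaling.

    Each affected channel's factor is multiplied by (1 - block_fraction);
    untouched channels pass through.  When ``model`` is given, effects on
    channels the model does not include are skipped with a warning rather
    than raising — a shared characterization can then be applied across
    models with different current inventories.
    """
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    factors = dict(base)
    for effect in spec.effects:
        if model is not None and effect.channel not in model.scalable_currents:
            log.warning(
                "%s %s: channel %s absent from model %s; effect ignored",
                spec.name, spec.characterization, effect.channel, model.name,
            )
            continue
        b = block_fraction(conc, effect)
        factors[effect.channel] = factors.get(effect.channel, 1.0) * (1.0 - b)
    return ChannelScaling(factors)


# ---------------------------------------------------------------------------
# Characterization-table I/O

_COLUMNS = ["drug", "characterization", "channel", "ic50_uM", "hill"]


def _specs_from_frame(df: pd.DataFrame) -> list[DrugSpec]:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"drug table missing columns {missing}")
    specs = []
    for (drug, charac), grp in df.groupby(
        ["drug", "characterization"], sort=True
    ):
        effects = tuple(
            DrugEffect(row.channel, float(row.ic50_uM), float(row.hill))
            for row in grp.itertuples()
        )
        prov = ""
        if "provenance" in grp.columns:
            prov = "; ".join(sorted(set(grp["provenance"].fillna("")))).strip("; ")
        specs.append(
            DrugSpec(str(drug), str(charac), effects, provenance=prov)
        )
    return specs


def load_drug_table(path: str | Path) -> list[DrugSpec]:
    """Load drug characterizations from CSV or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    return _specs_from_frame(df)


def save_drug_table(specs: list[DrugSpec], path: str | Path) -> None:
    """Write drug characterizations to CSV or JSON (lossless round trip)."""
    rows = [
        {
            "drug": s.name,
            "characterization": s.characterization,
            "channel": e.channel,
            "ic50_uM": e.ic50,
            "hill": e.n_h,
            "provenance": s.provenance,
        }
        for s in specs
        for e in s.effects
    ]
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        pd.DataFrame(rows, columns=_COLUMNS + ["provenance"]).to_csv(
            path, index=False
        )


def example_drug_table() -> list[DrugSpec]:
    """Example characterizations shipped with the package.

    These are reconstructions: (IC50, n_H) pairs fitted through published
    per-concentration block percentages, not measured values — see each
    entry's provenance note.
    """
    path = Path(__file__).parent / "data" / "example_drugs.csv"
    return load_drug_table(path)
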