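"""In vitro / in silico comparison report.

Joins simulated trial results against an in vitro summary table on
(drug, characterization, concentration) and reports, per row, the percent
CTD90 change on both sides plus qualitative agreement flags:

* sign concordance — both sides prolong, or both shorten;
* event concordance — both sides show an arrhythmic event, or both show
  cessation of spontaneous activity, or neither shows anything.

Missing measurements (the spontaneous activity stopped, or an event
prevented measuring CTD90) are carried as code strings (Q, RESAC, RF, IRR,
EAD, DAD, VT, OTH; X marks "no in vitro arrhythmic events") so both sides
render side by side.  Summary statistics are recomputed row-wise, never
cached.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .protocol import TrialResult

__all__ = ["build_comparison", "INVITRO_COLUMNS"]

INVITRO_COLUMNS = ["drug", "characterization", "conc_uM", "dCTD90_pct",
                   "events", "cessation"]


def _match_conc(a: float, b: float, rtol: float) -> bool:
    return math.isclose(a, b, rel_tol=rtol, abs_tol=0.0)


def build_comparison(
    trials: dict[str, list[TrialResult]],
    invitro: pd.DataFrame,
    conc_rtol: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Comparison rows plus summary statistics.

    ``trials`` maps model name → TrialResult list; ``invitro`` follows
    :data:`INVITRO_COLUMNS`.  Returns (rows, summary) where summary holds,
    per model, the sign-concordance fraction and the fraction of
    sign-concordant rows where the simulated |ΔCTD90| is smaller than the
    measured one, plus an appendix of unmatched keys (never dropped
    silently).
    """
    missing = [c for c in INVITRO_COLUMNS if c not in invitro.columns]
    if missing:
        raise ValueError(f"in vitro table missing columns {missing}")

    models = sorted(trials)
    rows = []
    matched_keys = set()
    for _, vit in invitro.iterrows():
        key = (str(vit["drug"]), str(vit["characterization"]),
               float(vit["conc_uM"]))
        row: dict = {
            "drug": key[0],
            "characterization": key[1],
            "conc_uM": key[2],
            "invitro_dCTD90_pct": (
                float(vit["dCTD90_pct"])
                if pd.notna(vit["dCTD90_pct"]) else None
            ),
            "invitro_events": str(vit.get("events", "") or "X"),
            "invitro_cessation": str(vit.get("cessation", "") or ""),
        }
        for model in models:
            hit = next(
                (
                    r for r in trials[model]
                    if r.drug == key[0]
                    and r.characterization == key[1]
                    and _match_conc(r.conc_uM, key[2], conc_rtol)
                ),
                None,
            )
            if hit is None:
                row[f"{model}_dCTD90_pct"] = None
                row[f"{model}_code"] = "missing"
                row[f"{model}_sign_concordant"] = None
                row[f"{model}_event_concordant"] = None
                continue
            matched_keys.add((model, key))
            code = hit.assessment.composite() if hit.assessment else ""
            row[f"{model}_dCTD90_pct"] = hit.delta_ctd90_pct
            row[f"{model}_code"] = code or "NORMAL"
            sign = None
            if (
                hit.delta_ctd90_pct is not None
                and row["invitro_dCTD90_pct"] is not None
            ):
                sign = (
                    np.sign(hit.delta_ctd90_pct)
                    == np.sign(row["invitro_dCTD90_pct"])
                )
            row[f"{model}_sign_concordant"] = sign
            vit_event = row["invitro_events"] not in ("", "X")
            vit_cess = row["invitro_cessation"] != ""
            sil_event = bool(hit.assessment and hit.assessment.proarrhythmic)
            sil_cess = hit.cessation
            row[f"{model}_event_concordant"] = (
                vit_event == sil_event and vit_cess == sil_cess
            )
        rows.append(row)

    frame = pd.DataFrame(rows)
    summary: dict = {"per_model": {}, "unmatched": []}
    for model in models:
        sc = frame[f"{model}_sign_concordant"].dropna()
        frac_sign = float(sc.mean()) if len(sc) else None
        both = frame.dropna(
            subset=[f"{model}_dCTD90_pct", "invitro_dCTD90_pct"]
        )
        smaller = None
        if len(both):
            smaller = float(
                (
                    both[f"{model}_dCTD90_pct"].abs()
                    < both["invitro_dCTD90_pct"].abs()
                ).mean()
            )
        ec = frame[f"{model}_event_concordant"].dropna()
        summary["per_model"][model] = {
            "n_rows": int(len(frame)),
            "n_compared": int(len(both)),
            "sign_concordance": frac_sign,
            "frac_insilico_smaller": smaller,
            "event_concordance": float(ec.mean()) if len(ec) else None,
        }
        for r in trials[model]:
            key = (r.drug, r.characterization, float(r.conc_uM))
            if (model, key) not in matched_keys:
                summary["unmatched"].append({"model": model, "key": key})
    return frame, summary
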