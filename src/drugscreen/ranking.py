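"""Delta-AUC combination ranking.

For every drug and cell line the screen yields two fitted dose-response
AUCs: one from the single-agent arm and one from the arm co-dosed with a
fixed sensitizing concentration of the compound of interest.  The *delta*
is AUC(single) - AUC(sensitized); positive deltas mean the sensitizer
increased the drug's effect.  Deltas are mean-centred z-scored within each
cell line (across all drugs), and drugs are ranked by their median z across
cell lines — the drug with the largest median z is the best combination
partner.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._exceptions import SchemaError

__all__ = ["compute_deltas", "zscore_deltas", "rank_drugs"]

logger = logging.getLogger(__name__)


def compute_deltas(curves: pd.DataFrame) -> pd.DataFrame:
    """Pair per-arm AUCs into delta records.

    ``curves`` needs columns cell_line, compound, arm ("single" /
    "sensitized") and auc.  (cell_line, compound) pairs missing either arm
    are skipped with a log message.
    """
    for col in ("cell_line", "compound", "arm", "auc"):
        if col not in curves.columns:
            raise SchemaError(f"curve table missing column {col!r}")

    wide = curves.pivot_table(
        index=["cell_line", "compound"], columns="arm", values="auc", aggfunc="first"
    )
    for arm in ("single", "sensitized"):
        if arm not in wide.columns:
            wide[arm] = np.nan
    incomplete = wide["single"].isna() | wide["sensitized"].isna()
    if incomplete.any():
        for cell_line, compound in wide.index[incomplete]:
            logger.warning(
                "skipping %s / %s: missing one arm's AUC", cell_line, compound
            )
        wide = wide.loc[~incomplete]

    out = wide.reset_index().rename(
        columns={"single": "auc_single", "sensitized": "auc_sensitized",
                 "compound": "drug"}
    )
    out["delta"] = out["auc_single"] - out["auc_sensitized"]
    return out[["cell_line", "drug", "auc_single", "auc_sensitized", "delta"]]


def zscore_deltas(deltas: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Mean-centred z-scoring of deltas within each cell line.

    ``ddof=1`` (sample standard deviation) is the default; pass ``ddof=0``
    for the population convention.  Degenerate lines (all deltas equal) get
    z = 0 with ``degenerate=True``; single-drug lines get undefined z with
    a warning.
    """
    out = deltas.copy()
    out["z"] = np.nan
    out["degenerate"] = False
    for cell_line, grp in out.groupby("cell_line", sort=False):
        vals = grp["delta"].to_numpy(dtype=float)
        if len(vals) < 2:
            logger.warning("cell line %s has a single drug: z undefined", cell_line)
            continue
        sd = float(np.std(vals, ddof=ddof))
        # identical deltas can leave a float-epsilon sd; treat as degenerate
        if sd <= 1e-12 * max(1.0, float(np.max(np.abs(vals)))):
            out.loc[grp.index, "z"] = 0.0
            out.loc[grp.index, "degenerate"] = True
        else:
            out.loc[grp.index, "z"] = (vals - vals.mean()) / sd
    return out


def rank_drugs(zscored: pd.DataFrame) -> pd.DataFrame:
    """Rank drugs by median z across cell lines (rank 1 = best partner).

    The median ignores cell lines where z is undefined; ties in median z are
    broken lexicographically by drug label.  Drugs with z available in at
    most half of the cell lines are flagged ``low_confidence``.
    """
    n_lines = zscored["cell_line"].nunique()
    rows = []
    for drug, grp in zscored.groupby("drug", sort=True):
        z = grp["z"].dropna()
        rows.append({
            "drug": drug,
            "median_z": float(np.median(z)) if len(z) else np.nan,
            "n_lines": int(len(z)),
            "low_confidence": bool(len(z) * 2 < n_lines),
        })
    ranking = pd.DataFrame(rows)
    ranking = ranking.sort_values(
        ["median_z", "drug"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    ranking["rank"] = np.arange(1, len(ranking) + 1)

    zwide = zscored.pivot_table(index="drug", columns="cell_line", values="z",
                                aggfunc="first")
    zwide.columns = [f"z_{c}" for c in zwide.columns]
    ranking = ranking.merge(zwide, left_on="drug", right_index=True, how="left")
    return ranking
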