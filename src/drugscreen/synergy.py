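"""Loewe-additivity combination-index analysis of checkerboard grids.

A checkerboard varies two drugs over nine-point 1:3 dilution series plus a
true 0-µM dose each (10 x 10 cells, triplicate).  Triplicates are averaged,
single-agent reference curves are fitted from the grid's own zero-dose
margins, and each interior cell's combination index is

    CI = a / A + b / B

where a, b are the combined doses and A, B the single-agent doses predicted
(by inverting the margin curves) to produce the same effect.  CI = 1 is
additive, CI < 1 synergy, CI > 1 antagonism.  Cells whose effect lies at or
beyond the fitted floor/ceiling of either margin curve have no positive
finite inversion; their CI is undefined and is emitted as an explicit null
(a white tile on the log2 CI map), never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import GridError, SchemaError
from .doseresponse import DoseResponseCurve, dose_for_effect, fit_ll4

__all__ = ["GridSurface", "average_grid", "fit_margins", "loewe_ci", "render_ci_map"]

CI_COLUMNS = ("dose_a_uM", "dose_b_uM", "effect", "A_pred_uM", "B_pred_uM",
              "ci", "log2_ci", "defined")


@dataclass(frozen=True)
class GridSurface:
    """Replicate-averaged relative-CTG viability over a dose grid.

    ``viability[i, j]`` is the mean viability at (doses_a[i], doses_b[j]);
    doses are ascending and include exactly one 0 per axis.
    """

    drug_a: str
    drug_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    viability: np.ndarray
    n_replicates: int

    def __post_init__(self) -> None:
        if (self.doses_a == 0).sum() != 1 or (self.doses_b == 0).sum() != 1:
            raise GridError("each dose axis must include exactly one 0 µM point")
        if not np.all(np.isfinite(self.viability)):
            raise GridError("grid viability contains non-finite values")


def average_grid(records: pd.DataFrame) -> GridSurface:
    """Normalize (if needed) and triplicate-average a long grid table.

    Expects columns drug_a, drug_b, dose_a_uM, dose_b_uM, replicate and
    either ``relative_ctg`` or ``raw_intensity``; raw intensities are
    normalized against the mean of the (0, 0) vehicle wells.  A missing
    (dose_a, dose_b) cell raises ``GridError`` listing the gaps.
    """
    for col in ("drug_a", "drug_b", "dose_a_uM", "dose_b_uM"):
        if col not in records.columns:
            raise SchemaError(f"grid table missing column {col!r}")
    if "relative_ctg" in records.columns:
        values = records["relative_ctg"].astype(float)
    elif "raw_intensity" in records.columns:
        zero = records[(records["dose_a_uM"] == 0) & (records["dose_b_uM"] == 0)]
        if zero.empty:
            raise GridError("no (0, 0) vehicle wells to normalize against")
        vmean = float(zero["raw_intensity"].mean())
        if not vmean > 0:
            raise GridError("vehicle mean intensity is not positive")
        values = records["raw_intensity"].astype(float) / vmean
    else:
        raise SchemaError("grid table needs a relative_ctg or raw_intensity column")

    table = records.assign(_v=values)
    doses_a = np.sort(table["dose_a_uM"].unique())
    doses_b = np.sort(table["dose_b_uM"].unique())
    mean = table.groupby(["dose_a_uM", "dose_b_uM"])["_v"].mean()

    missing = [
        (a, b) for a in doses_a for b in doses_b if (a, b) not in mean.index
    ]
    if missing:
        raise GridError(f"incomplete grid; missing cells: {missing[:10]}")

    viability = np.empty((doses_a.size, doses_b.size))
    for i, a in enumerate(doses_a):
        for j, b in enumerate(doses_b):
            viability[i, j] = mean.loc[(a, b)]

    n_rep = int(table.groupby(["dose_a_uM", "dose_b_uM"]).size().min())
    return GridSurface(
        drug_a=str(table["drug_a"].iloc[0]), drug_b=str(table["drug_b"].iloc[0]),
        doses_a=doses_a, doses_b=doses_b, viability=viability, n_replicates=n_rep,
    )


def fit_margins(surface: GridSurface) -> tuple[DoseResponseCurve, DoseResponseCurve]:
    """Fit single-agent LL.4 curves from the zero-dose margins.

    Drug A's curve comes from the b = 0 column, drug B's from the a = 0 row;
    the (0, 0) vehicle cell is included as the zero-dose ceiling anchor.  A
    non-converged margin aborts the CI map with a diagnostic.
    """
    j0 = int(np.flatnonzero(surface.doses_b == 0)[0])
    i0 = int(np.flatnonzero(surface.doses_a == 0)[0])
    curve_a = fit_ll4(surface.doses_a, surface.viability[:, j0])
    curve_b = fit_ll4(surface.doses_b, surface.viability[i0, :])
    for name, curve in ((surface.drug_a, curve_a), (surface.drug_b, curve_b)):
        if not curve.converged:
            raise GridError(
                f"margin fit for {name} did not converge "
                f"(rss={curve.rss:.3g}, flat or ill-conditioned margin); "
                "CI map aborted"
            )
    return curve_a, curve_b


def loewe_ci(
    surface: GridSurface,
    curve_a: DoseResponseCurve,
    curve_b: DoseResponseCurve,
    clip_tol: float = 1e-4,
) -> pd.DataFrame:
    """Combination index for every interior (a > 0, b > 0) cell.

    For each cell the mean effect E is inverted through both margin curves;
    CI = a/A + b/B.  If E lies at or outside the response range of either
    curve the inversion has no positive finite solution and the cell is
    undefined (``ci`` and ``log2_ci`` are NaN, ``defined`` is False).
    ``clip_tol`` widens the undefined band to effects within that fraction
    of the response range of the floor/ceiling, so a cell measured exactly
    at a margin's asymptote never yields a spuriously extreme inversion.
    """

    def invertible(curve: DoseResponseCurve, effect: float) -> bool:
        span = curve.d - curve.c
        return (curve.c + clip_tol * span) < effect < (curve.d - clip_tol * span)

    rows = []
    for i, a in enumerate(surface.doses_a):
        if a == 0:
            continue
        for j, b in enumerate(surface.doses_b):
            if b == 0:
                continue
            effect = float(surface.viability[i, j])
            defined = invertible(curve_a, effect) and invertible(curve_b, effect)
            A = dose_for_effect(curve_a, effect) if defined else float("nan")
            B = dose_for_effect(curve_b, effect) if defined else float("nan")
            defined = defined and np.isfinite(A) and np.isfinite(B) and A > 0 and B > 0
            ci = a / A + b / B if defined else np.nan
            rows.append({
                "dose_a_uM": float(a), "dose_b_uM": float(b), "effect": effect,
                "A_pred_uM": float(A), "B_pred_uM": float(B),
                "ci": float(ci), "log2_ci": float(np.log2(ci)) if defined else np.nan,
                "defined": bool(defined),
            })
    return pd.DataFrame(rows, columns=list(CI_COLUMNS))


def render_ci_map(results: pd.DataFrame, plot_path: str | None = None,
                  rescale: bool = False) -> pd.DataFrame:
    """Pivot CI results into a log2(CI) matrix; optionally write a heatmap.

    Undefined cells stay NaN and render as white tiles.  ``rescale``
    symmetrizes the colour gradient per grid for display only; the stored
    CI values are never altered.
    """
    matrix = results.pivot(index="dose_a_uM", columns="dose_b_uM", values="log2_ci")
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        cmap = plt.get_cmap("RdBu").copy()
        cmap.set_bad("white")
        data = np.ma.masked_invalid(matrix.to_numpy())
        vmax = float(np.nanmax(np.abs(matrix.to_numpy()))) if rescale else 2.0
        vmax = vmax if np.isfinite(vmax) and vmax > 0 else 1.0
        im = ax.imshow(data, origin="lower", cmap=cmap, vmin=-vmax, vmax=vmax,
                       aspect="auto")
        ax.set_xticks(range(len(matrix.columns)))
        ax.set_xticklabels([f"{v:g}" for v in matrix.columns], rotation=90)
        ax.set_yticks(range(len(matrix.index)))
        ax.set_yticklabels([f"{v:g}" for v in matrix.index])
        ax.set_xlabel("dose B (µM)")
        ax.set_ylabel("dose A (µM)")
        fig.colorbar(im, ax=ax, label="log2(CI)")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return matrix
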