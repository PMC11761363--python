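"""End-to-end conveniences chaining the screening stages.

These helpers wire the module surfaces together exactly as the CLI does:
plate table -> normalization -> per-(line, drug, arm) 4PL fits -> EC/AUC
metrics -> delta-AUC ranking, and grid table -> averaging -> margin fits ->
Loewe CI map.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .doseresponse import compute_auc, effective_concentration, fit_ll4
from .plate import normalize_plate
from .ranking import compute_deltas, rank_drugs, zscore_deltas
from .synergy import average_grid, fit_margins, loewe_ci
from .synthetic import SimulationConfig, simulate_grid, simulate_screen

__all__ = ["fit_screen", "screen_to_ranking", "grid_to_ci"]


def fit_screen(
    normalized: pd.DataFrame,
    dose_range: tuple[float, float] | None = None,
    ec_p: float = 30.0,
    ec_mode: str = "relative",
) -> pd.DataFrame:
    """Fit one pooled-triplicate LL.4 curve per (cell_line, compound, arm).

    Returns a curve table with parameters, convergence, EC-p and the
    normalized AUC over ``dose_range`` (default: the observed dose range of
    each series).  Vehicle records are ignored; zero doses never enter fits.
    """
    treated = normalized[normalized["role"] == "treated"]
    rows = []
    for (cell_line, compound, arm), grp in treated.groupby(
        ["cell_line", "compound", "arm"], sort=True
    ):
        doses = grp["dose_uM"].to_numpy(dtype=float)
        viab = grp["relative_ctg"].to_numpy(dtype=float)
        keep = doses > 0
        curve = fit_ll4(doses[keep], viab[keep])
        rng_ = dose_range or (float(doses[keep].min()), float(doses[keep].max()))
        rows.append({
            "cell_line": cell_line, "compound": compound, "arm": arm,
            "b": curve.b, "c": curve.c, "d": curve.d, "e": curve.e,
            "rss": curve.rss, "n_obs": curve.n_obs, "converged": curve.converged,
            f"ec{ec_p:g}_uM": effective_concentration(curve, ec_p, ec_mode)
            if curve.converged else np.nan,
            "auc": compute_auc(curve, rng_),
        })
    return pd.DataFrame(rows)


def screen_to_ranking(
    config: SimulationConfig, ddof: int = 1
) -> tuple[pd.DataFrame, dict]:
    """Simulate a two-arm screen and run it through to the drug ranking."""
    table, truth = simulate_screen(config)
    normalized = normalize_plate(table)
    curves = fit_screen(normalized)
    deltas = compute_deltas(curves)
    ranking = rank_drugs(zscore_deltas(deltas, ddof=ddof))
    return ranking, truth


def grid_to_ci(
    config: SimulationConfig, drug_a: str, drug_b: str
) -> tuple[pd.DataFrame, dict]:
    """Simulate a checkerboard and compute its Loewe CI table."""
    table, truth = simulate_grid(config, drug_a, drug_b)
    surface = average_grid(table)
    curve_a, curve_b = fit_margins(surface)
    return loewe_ci(surface, curve_a, curve_b), truth
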