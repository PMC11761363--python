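"""Xenograft tumour volumes and log-linear growth-rate comparison.

Caliper measurements (two perpendicular diameters L and W in centimetres)
convert to a modified-ellipsoid volume in cubic millimetres:

    V = (4/3) * pi * (L/2) * (W/2) * ((L+W)/4) * 10^3

which reduces to the sphere volume when L = W.  Under an exponential growth
assumption each animal's series is summarized by ordinary least squares of
log2(volume) on time,

    log2 V = beta0 + beta1 * t + eps,

so beta1 is the growth rate in log2 mm^3 per day (1.0 = daily doubling).
Arms are compared with a Kruskal–Wallis omnibus test on the per-animal
slopes plus pairwise Welch t-tests, Bonferroni-corrected by the number of
pairwise tests performed.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import InsufficientDataError

__all__ = [
    "GrowthFit",
    "tumour_volume",
    "fit_growth_rate",
    "fit_growth_rates",
    "compare_growth_rates",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GrowthFit:
    """Per-animal log-linear growth fit: log2 V = beta0 + beta1 * t."""

    animal: str
    arm: str
    beta0: float
    beta1: float
    r2: float
    n: int


def tumour_volume(L, W):
    """Modified-ellipsoid tumour volume in mm^3 from diameters in cm."""
    L = np.asarray(L, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(L <= 0) or np.any(W <= 0):
        raise InsufficientDataError("tumour diameters must be positive")
    vol = (4.0 / 3.0) * math.pi * (L / 2.0) * (W / 2.0) * ((L + W) / 4.0) * 1e3
    return vol if vol.ndim else float(vol)


def fit_growth_rate(days, volumes, animal: str = "", arm: str = "") -> GrowthFit:
    """OLS fit of log2(volume) on day for one animal's series."""
    t = np.asarray(days, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if np.unique(t).size < 2:
        raise InsufficientDataError(
            f"animal {animal or '?'}: need >= 2 distinct timepoints"
        )
    if np.any(v <= 0):
        raise InsufficientDataError(
            f"animal {animal or '?'}: volumes must be positive for a log fit"
        )
    res = stats.linregress(t, np.log2(v))
    return GrowthFit(
        animal=animal, arm=arm, beta0=float(res.intercept),
        beta1=float(res.slope), r2=float(res.rvalue**2), n=int(t.size),
    )


def fit_growth_rates(calipers: pd.DataFrame) -> pd.DataFrame:
    """Per-animal growth fits from a caliper table.

    Expects columns animal, arm, day, L_cm, W_cm (or a precomputed
    ``volume_mm3``).  Returns one row per animal with beta0, beta1, r2, n.
    """
    table = calipers.copy()
    if "volume_mm3" not in table.columns:
        table["volume_mm3"] = tumour_volume(table["L_cm"], table["W_cm"])
    rows = []
    for (animal, arm), grp in table.groupby(["animal", "arm"], sort=True):
        fit = fit_growth_rate(grp["day"], grp["volume_mm3"], animal=animal, arm=arm)
        rows.append(fit.__dict__)
    return pd.DataFrame(rows)


def compare_growth_rates(
    fits: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    alternative: str | dict = "two-sided",
) -> dict:
    """Kruskal–Wallis omnibus plus pairwise Welch t-tests on beta1 by arm.

    ``pairs`` defaults to all arm pairs; ``alternative`` is a single
    sidedness or a {(arm1, arm2): sidedness} map.  Pairwise p-values are
    Bonferroni-adjusted by the number of tests performed.  Arms with fewer
    than two animals are excluded with a warning.
    """
    groups: dict[str, np.ndarray] = {}
    excluded = []
    for arm, grp in fits.groupby("arm", sort=True):
        slopes = grp["beta1"].to_numpy(dtype=float)
        if slopes.size < 2:
            logger.warning("arm %s has %d animal(s); excluded", arm, slopes.size)
            excluded.append(arm)
            continue
        groups[arm] = slopes
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 arms with >= 2 animals each")

    kw_stat, kw_p = stats.kruskal(*groups.values())
    report: dict = {
        "kruskal": {"statistic": float(kw_stat), "p": float(kw_p),
                    "df": len(groups) - 1},
        "excluded_arms": excluded,
        "pairwise": [],
    }

    if pairs is None:
        pairs = list(itertools.combinations(sorted(groups), 2))
    pairs = [p for p in pairs if p[0] in groups and p[1] in groups]
    m = len(pairs)
    for arm1, arm2 in pairs:
        alt = alternative.get((arm1, arm2), "two-sided") \
            if isinstance(alternative, dict) else alternative
        res = stats.ttest_ind(groups[arm1], groups[arm2], equal_var=False,
                              alternative=alt)
        report["pairwise"].append({
            "arm1": arm1, "arm2": arm2, "alternative": alt,
            "t": float(res.statistic), "df": float(res.df),
            "p": float(res.pvalue),
            "p_adjusted": float(min(1.0, m * res.pvalue)),
        })
    report["n_pairwise_tests"] = m
    return report
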