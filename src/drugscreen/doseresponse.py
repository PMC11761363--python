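"""Four-parameter log-logistic (4PL / LL.4) dose-response modelling.

The model for viability y at dose x > 0 is

    f(x) = c + (d - c) / (1 + (x / e)**b)

with floor ``c``, ceiling ``d`` (the zero-dose response), slope ``b`` and
midpoint ``e`` (the EC50 on the dose axis).  For a cytotoxic compound the
curve is decreasing (b > 0): f(0+) -> d and f(inf) -> c.

Sensitivity metrics derived from a fitted curve:

* EC-p — the concentration producing a p% effect, either *relative* to the
  fitted response range (solve f(x) = d - (p/100)(d - c)) or *absolute* on
  the viability scale (solve f(x) = 1 - p/100).
* AUC — the mean of the fitted curve over a log10-dose window, i.e. the
  trapezoidal integral on a uniform log10-dose grid divided by the window
  width.  An inert compound scores 1, a fully lethal one approaches 0, so
  lower AUC means greater sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import leastsq

from ._exceptions import FitError, InsufficientDataError

__all__ = [
    "DoseResponseCurve",
    "ll4",
    "fit_ll4",
    "predict",
    "effective_concentration",
    "dose_for_effect",
    "compute_auc",
]


@dataclass(frozen=True)
class DoseResponseCurve:
    """Fitted LL.4 parameters plus fit diagnostics.

    ``converged`` is False for degenerate (flat) data, where ``c == d`` is
    set to the mean response and the slope/midpoint are placeholders.
    """

    b: float
    c: float
    d: float
    e: float
    rss: float
    n_obs: int
    converged: bool

    def __post_init__(self) -> None:
        if not (self.e > 0):
            raise FitError(f"LL.4 midpoint e must be positive, got {self.e}")


def ll4(x, b, c, d, e):
    """Evaluate the LL.4 model; dose 0 returns the zero-dose limit ``d``."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        val = c + (d - c) / (1.0 + (x / e) ** b)
    val = np.where(x == 0, d, val)
    return val if val.ndim else float(val)


def predict(curve: DoseResponseCurve, dose) -> float | np.ndarray:
    """Predicted viability at ``dose`` (µM); vectorized over arrays."""
    return ll4(dose, curve.b, curve.c, curve.d, curve.e)


def _make_objective(x, y):
    """Residual and Jacobian closures in (b, c, d, log e).

    Doses are fixed across iterations, so their logs are precomputed; the
    exponent is clipped so extreme slopes never overflow.  Zero doses are
    ceiling anchors (model value d) with Jacobian rows (0, 0, 1, 0).
    """
    pos = x > 0
    logx = np.log(x[pos])
    n = x.size
    all_pos = bool(pos.all())

    def resid(theta):
        b, c, d, loge = theta
        z = np.clip(b * (loge - logx), -700.0, 700.0)
        f_pos = c + (d - c) / (1.0 + np.exp(-z))
        if all_pos:
            return f_pos - y
        f = np.full(n, d)
        f[pos] = f_pos
        return f - y

    def jac(theta):
        b, c, d, loge = theta
        z = np.clip(b * (loge - logx), -700.0, 700.0)
        r = np.exp(-z)  # (x/e)^b
        denom = 1.0 + r
        w = (r / denom) / denom  # two divisions: denom**2 can overflow
        Jp = np.empty((logx.size, 4))
        Jp[:, 0] = -(d - c) * w * (logx - loge)
        Jp[:, 1] = 1.0 - 1.0 / denom
        Jp[:, 2] = 1.0 / denom
        Jp[:, 3] = (d - c) * b * w
        if all_pos:
            return Jp
        J = np.empty((n, 4))
        J[~pos] = (0.0, 0.0, 1.0, 0.0)
        J[pos] = Jp
        return J

    return resid, jac


_SLOPE_STARTS = (1.0, 2.0, 0.5, -1.0)


def fit_ll4(doses, viabilities, zero_anchor: bool = True) -> DoseResponseCurve:
    """Least-squares LL.4 fit on all replicate points.

    Parameters
    ----------
    doses, viabilities
        Paired observations; replicates appear as repeated doses.  Doses of
        exactly 0 are treated as zero-dose anchors (model value ``d``) when
        ``zero_anchor`` is True and dropped otherwise.
    zero_anchor
        Whether 0-µM observations pin the ceiling via the zero-dose limit.

    Notes
    -----
    The midpoint is optimized on the log scale so e > 0 is structural; the
    floor, ceiling and slope are unbounded.  Several slope starting values
    are tried and the solution with the smallest residual sum of squares
    wins, ties broken in favour of the smaller ``|b|``.  Flat data (zero
    response range) short-circuits to c = d = mean with ``converged=False``.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(viabilities, dtype=float)
    if x.shape != y.shape:
        raise FitError("doses and viabilities must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise FitError("non-finite dose or viability values")
    if np.any(x < 0):
        raise FitError("negative doses are not valid concentrations")
    if not zero_anchor:
        keep = x > 0
        x, y = x[keep], y[keep]

    pos = np.unique(x[x > 0])
    if pos.size < 4:
        raise InsufficientDataError(
            f"LL.4 needs >= 4 distinct positive doses, got {pos.size}"
        )

    geo_mid = float(np.exp(np.mean(np.log(pos))))
    if float(np.ptp(y)) < 1e-12:
        mean_y = float(np.mean(y))
        return DoseResponseCurve(
            b=1.0, c=mean_y, d=mean_y, e=geo_mid, rss=0.0,
            n_obs=x.size, converged=False,
        )

    # heuristic: ceiling from the lowest dose (or the 0-µM anchor), floor from the highest
    d0 = float(np.mean(y[x == 0])) if np.any(x == 0) else float(np.mean(y[x == pos[0]]))
    c0 = float(np.mean(y[x == pos[-1]]))

    resid, jac = _make_objective(x, y)
    best = None
    for b0 in _SLOPE_STARTS:
        theta0 = np.array([b0, c0, d0, np.log(geo_mid)])
        try:
            theta, _, _, _, ier = leastsq(
                resid, theta0, Dfun=jac, full_output=True
            )
        except Exception:
            continue
        if not np.all(np.isfinite(theta)):
            continue
        rss = float(np.sum(resid(theta) ** 2))
        cand = (rss, abs(float(theta[0])), theta, ier in (1, 2, 3, 4))
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        raise FitError("LL.4 optimization failed for every starting point")

    rss, _, theta, ok = best
    b, c, d, loge = theta
    # the LL.4 surface is invariant under (b, c, d) -> (-b, d, c) for x > 0;
    # canonicalize to d >= c so the ceiling is always the zero-dose response.
    # A 0-µM anchor already pins d, so the swap is only safe without one.
    if c > d and not np.any(x == 0):
        b, c, d = -b, d, c
    return DoseResponseCurve(
        b=float(b), c=float(c), d=float(d), e=float(np.exp(loge)),
        rss=rss, n_obs=int(x.size), converged=bool(ok),
    )


def dose_for_effect(curve: DoseResponseCurve, effect: float) -> float:
    """Invert the fitted curve at a viability level.

    Returns the dose x with f(x) = effect, or ``nan`` when the effect lies
    outside the open response range (min(c, d), max(c, d)) — there is then
    no positive finite dose producing it.
    """
    if curve.b == 0:
        raise FitError("cannot invert a curve with zero slope")
    lo, hi = sorted((curve.c, curve.d))
    if not (lo < effect < hi):
        return float("nan")
    ratio = (curve.d - curve.c) / (effect - curve.c) - 1.0
    if ratio <= 0:
        return float("nan")
    return float(curve.e * ratio ** (1.0 / curve.b))


def effective_concentration(
    curve: DoseResponseCurve, p: float, mode: str = "relative"
) -> float:
    """EC-p of a fitted curve in µM, or ``nan`` when unattainable.

    ``relative`` targets p% of the fitted response range (EC50 at p=50 is
    the midpoint ``e`` by construction); ``absolute`` targets the viability
    level 1 - p/100 on the normalized scale.
    """
    if not 0 < p < 100:
        raise FitError(f"p must be in (0, 100), got {p}")
    if mode == "relative":
        target = curve.d - (p / 100.0) * (curve.d - curve.c)
    elif mode == "absolute":
        target = 1.0 - p / 100.0
    else:
        raise FitError(f"unknown EC mode {mode!r}")
    return dose_for_effect(curve, target)


def compute_auc(
    curve: DoseResponseCurve, dose_range: tuple[float, float], n_grid: int = 201
) -> float:
    """Normalized area under the fitted curve over a log10-dose window.

    Trapezoidal integral of predicted viability on a uniform ``n_grid``-point
    log10-dose grid, divided by the log10 window width.  A constant curve at
    viability v scores exactly v for any window.
    """
    lo, hi = float(dose_range[0]), float(dose_range[1])
    if not (0 < lo < hi):
        raise FitError(f"dose range must satisfy 0 < min < max, got {dose_range}")
    grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    y = predict(curve, grid)
    logx = np.log10(grid)
    return float(np.trapezoid(y, logx) / (logx[-1] - logx[0]))
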