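"""Regression-family suite for protection-gradient curves.

FRAC_PROT along a gradient is regressed on class midpoints with six classical
families, and the winner is chosen by Akaike's information criterion:

==============  =========================================  ========
family          form                                       n_params
==============  =========================================  ========
poly1           a + b·x                                    2
poly2           a + b·x + c·x²                             3
exponential     a·exp(b·x)                                 2
one_phase       y0 + (plateau − y0)·(1 − exp(−k·x)), k>0   3
semilog         a + b·ln x  (requires x > 0)               2
piecewise       continuous two-segment linear, break ψ     4
==============  =========================================  ========

AIC uses the Gaussian form n·ln(RSS/n) + 2(k+1), the +1 counting the error
variance; the same formula applies to every family so only RSS and the
parameter count matter. Goodness of fit is reported as a pseudo-R², the
squared Pearson correlation of observed and predicted values.

Nonlinear families are fitted by least squares with multiple seeded starts;
the piecewise breakpoint is found by a grid search over interior midpoints
followed by bounded local refinement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy import optimize

from .errors import DegenerateDataError, ProtgradError

logger = logging.getLogger(__name__)

FAMILY_ORDER = ("poly1", "poly2", "exponential", "one_phase", "semilog", "piecewise")
N_PARAMS = {"poly1": 2, "poly2": 3, "exponential": 2, "one_phase": 3,
            "semilog": 2, "piecewise": 4}

MIN_POINTS = 8          # the modeling floor: re-bin histograms below this
N_RANDOM_STARTS = 5     # per nonlinear family, in addition to the heuristic start
AIC_TIE_TOL = 1e-6
_RSS_FLOOR = 1e-300


@dataclass
class ModelFit:
    family: str
    coefficients: dict[str, float] = dataclass_field(default_factory=dict)
    n_params: int = 0
    rss: float = math.inf
    aic: float = math.inf
    pseudo_r2: float = 0.0
    predictions: np.ndarray | None = None
    ok: bool = True
    message: str = ""

    @classmethod
    def failed(cls, family: str, message: str) -> "ModelFit":
        return cls(family=family, n_params=N_PARAMS[family], ok=False, message=message)


def aic(fit: ModelFit, n_points: int) -> float:
    """Gaussian AIC = n·ln(RSS/n) + 2(k+1); −inf sentinel for an exact fit."""
    k = fit.n_params
    if n_points <= k + 2:
        raise DegenerateDataError(
            f"AIC undefined: n={n_points} points for k={k} parameters"
        )
    if fit.rss <= _RSS_FLOOR:
        return -math.inf
    return n_points * math.log(fit.rss / n_points) + 2.0 * (k + 1)


def pseudo_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Squared Pearson correlation of observed and predicted values."""
    if np.std(y) == 0 or np.std(yhat) == 0:
        return 0.0
    r = float(np.corrcoef(y, yhat)[0, 1])
    if not np.isfinite(r):
        return 0.0
    return r * r


def _finalize(family, x, y, coefficients, predict):
    yhat = predict(x)
    rss = float(np.sum((y - yhat) ** 2))
    # snap float-noise residuals of an exact fit to zero so that exact fits
    # from different families tie at the -inf AIC sentinel
    scale = float(np.max(np.abs(y))) or 1.0
    if rss <= len(x) * (16 * np.finfo(float).eps * scale) ** 2:
        rss = 0.0
    fit = ModelFit(
        family=family,
        coefficients=coefficients,
        n_params=N_PARAMS[family],
        rss=rss,
        pseudo_r2=pseudo_r2(y, yhat),
        predictions=yhat,
    )
    fit.aic = aic(fit, len(x))
    return fit


# --- family fitters ---------------------------------------------------------

def _fit_poly(x, y, degree):
    coef = np.polyfit(x, y, degree)           # highest power first
    names = {1: ("b", "a"), 2: ("c", "b", "a")}[degree]
    coefficients = dict(zip(names, map(float, coef)))
    return coefficients, lambda t: np.polyval(coef, t)


def _profiled_1d_fit(x, y, basis, starts):
    """Minimize RSS over one nonlinear rate parameter u, solving the
    amplitude coefficients by linear least squares at each u (the models are
    linear conditional on the rate). Brent refinement from each seeded start;
    returns (u, beta, rss) of the best start or None."""

    def rss_at(u):
        A = basis(u)
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        return float(resid @ resid), beta

    best = None
    for u0 in starts:
        try:
            res = optimize.minimize_scalar(
                lambda u: rss_at(u)[0], bracket=(u0 - 1.0, u0, u0 + 1.0),
                method="brent", options={"maxiter": 200},
            )
        except (RuntimeError, ValueError):
            continue
        u = float(res.x)
        rss, beta = rss_at(u)
        if math.isfinite(rss) and (best is None or rss < best[2]):
            best = (u, beta, rss)
    return best


def _fit_exponential(x, y, seed):
    """y = a·exp(b·x); linear in a for fixed b, so search over b only."""
    rng = np.random.default_rng(seed)
    xspan = float(np.ptp(x)) or 1.0

    def basis(b):
        with np.errstate(over="ignore"):
            return np.exp(np.clip(b * x, -700, 700))[:, None]

    starts = []
    if (y > 0).all():                       # log-linear heuristic start
        starts.append(float(np.polyfit(x, np.log(y), 1)[0]))
    starts += list(rng.normal(0.0, 2.0 / xspan, N_RANDOM_STARTS))
    best = _profiled_1d_fit(x, y, basis, starts)
    if best is None:
        return None
    b, beta, _ = best
    a = float(beta[0])
    return {"a": a, "b": float(b)}, (
        lambda t: a * np.exp(np.clip(b * np.asarray(t, float), -700, 700))
    )


def _fit_one_phase(x, y, seed):
    """y = y0 + (plateau − y0)(1 − e^{−kx}), k > 0: linear in (y0, plateau)
    for fixed k, so search over u = ln k (keeping k positive)."""
    rng = np.random.default_rng(seed)
    xspan = float(np.ptp(x)) or 1.0

    def basis(u):
        decay = np.exp(-np.clip(math.exp(min(u, 20.0)) * x, 0, 700))
        return np.column_stack([decay, 1.0 - decay])

    starts = [math.log(1.0 / xspan)]        # rate ~ 1 / gradient span
    starts += list(math.log(1.0 / xspan) + rng.normal(0.0, 2.0, N_RANDOM_STARTS))
    best = _profiled_1d_fit(x, y, basis, starts)
    if best is None:
        return None
    u, beta, _ = best
    k = math.exp(min(u, 20.0))
    y0, plateau = float(beta[0]), float(beta[1])
    return ({"y0": y0, "plateau": plateau, "k": k},
            lambda t: y0 + (plateau - y0) * (1.0 - np.exp(-k * np.asarray(t, float))))


def _fit_semilog(x, y):
    if (x <= 0).any():
        return None                             # family undefined on this gradient
    b, a = np.polyfit(np.log(x), y, 1)
    return ({"a": float(a), "b": float(b)},
            lambda t: a + b * np.log(t))


def _piecewise_design(x, psi):
    return np.column_stack([np.ones_like(x), x, np.maximum(x - psi, 0.0)])


def _piecewise_rss(x, y, psi):
    beta, *_ = np.linalg.lstsq(_piecewise_design(x, psi), y, rcond=None)
    resid = y - _piecewise_design(x, psi) @ beta
    return float(resid @ resid), beta


def _fit_piecewise(x, y):
    xs = np.sort(np.unique(x))
    if xs.size < 4:
        return None
    # candidate breakpoints: midpoints between consecutive distinct x, keeping
    # at least two points on each side of the break
    candidates = 0.5 * (xs[1:-2] + xs[2:-1])
    if candidates.size == 0:
        return None
    rss_values = [_piecewise_rss(x, y, psi)[0] for psi in candidates]
    best_i = int(np.argmin(rss_values))
    lo = candidates[max(best_i - 1, 0)]
    hi = candidates[min(best_i + 1, len(candidates) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda p: _piecewise_rss(x, y, p)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        psi = float(res.x)
        if _piecewise_rss(x, y, psi)[0] > rss_values[best_i]:
            psi = float(candidates[best_i])
    else:
        psi = float(candidates[best_i])
    rss, beta = _piecewise_rss(x, y, psi)
    a, b1, delta = map(float, beta)
    coefficients = {"a": a, "slope1": b1, "slope2": b1 + delta, "breakpoint": psi}
    return coefficients, lambda t: _piecewise_design(np.asarray(t, float), psi) @ beta


# --- public operations ------------------------------------------------------

def fit_family(x, y, family: str, seed: int = 0) -> ModelFit:
    """Least-squares fit of one family; returns a failed ModelFit when the
    family does not converge or is undefined on this gradient."""
    if family not in FAMILY_ORDER:
        raise ProtgradError(f"unknown family {family!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ProtgradError("x and y must be 1-D vectors of equal length")
    if len(x) < MIN_POINTS:
        raise DegenerateDataError(
            f"{len(x)} points < modeling floor of {MIN_POINTS}; re-bin the histogram"
        )
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DegenerateDataError("non-finite values in regression input")

    try:
        if family == "poly1":
            result = _fit_poly(x, y, 1)
        elif family == "poly2":
            result = _fit_poly(x, y, 2)
        elif family == "exponential":
            result = _fit_exponential(x, y, seed)
        elif family == "one_phase":
            result = _fit_one_phase(x, y, seed)
        elif family == "semilog":
            result = _fit_semilog(x, y)
        else:
            result = _fit_piecewise(x, y)
    except np.linalg.LinAlgError as exc:
        return ModelFit.failed(family, f"linear algebra failure: {exc}")
    if result is None:
        return ModelFit.failed(family, "no convergent fit" if family != "semilog"
                               else "semilog requires all x > 0")
    coefficients, predict = result
    return _finalize(family, x, y, coefficients, predict)


def fit_all(x, y, families=FAMILY_ORDER, seed: int = 0) -> list[ModelFit]:
    """Fit every requested family (failures included, marked not ok)."""
    return [fit_family(x, y, fam, seed=seed) for fam in families]


def select_model(fits: list[ModelFit]) -> ModelFit:
    """Minimum-AIC fit; near-ties (ΔAIC < 1e-6) go to fewer parameters, then
    to the fixed family order."""
    ok = [f for f in fits if f.ok]
    if not ok:
        raise DegenerateDataError("all regression families failed")
    best_aic = min(f.aic for f in ok)
    def near(f):
        if math.isinf(best_aic):
            return math.isinf(f.aic)
        return f.aic - best_aic < AIC_TIE_TOL
    tied = [f for f in ok if near(f)]
    tied.sort(key=lambda f: (f.n_params, FAMILY_ORDER.index(f.family)))
    return tied[0]
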