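"""Psychometric fits for the two-interval speed-discrimination task.

Responses ("test faster") as a function of the log test/reference speed
ratio are fitted with a logistic by binomial maximum likelihood, optionally
with a symmetric lapse rate:

    P(test faster | x) = lam/2 + (1 - lam) / (1 + exp(-slope * (x - alpha)))

The point of subjective equality (PSE) is the speed ratio at which the
fitted curve crosses 0.5; with a symmetric lapse this equals ``alpha``.
Sign convention: a *positive* PSE means the test had to move physically
faster to appear equal, i.e. the test stimulus was perceived as slower.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

LAPSE_MAX = 0.06


def make_trial_table(relative_speeds, n_test_faster, n_trials,
                     condition: str = "single") -> pd.DataFrame:
    df = pd.DataFrame({
        "condition": condition,
        "relative_speed": np.asarray(relative_speeds, dtype=float),
        "n_test_faster": np.asarray(n_test_faster, dtype=int),
        "n_trials": np.asarray(n_trials, dtype=int),
    })
    if ((df.n_test_faster < 0) | (df.n_test_faster > df.n_trials)).any():
        raise ValueError("n_test_faster must lie in [0, n_trials]")
    return df


@dataclass
class PsychFit:
    alpha: float          # midpoint, log speed-ratio units
    slope: float
    lapse: float
    loglik: float
    pse: float
    converged: bool
    flat: bool = False    # no information in the data
    boundary: bool = False  # slope at its bound (near-complete separation)


def _predicted(x, alpha, slope, lapse):
    return lapse / 2.0 + (1.0 - lapse) * expit(slope * (x - alpha))


def _nll(params, x, k, n, fix_lapse):
    alpha, log_slope = params[:2]
    lapse = fix_lapse if fix_lapse is not None else params[2]
    p = np.clip(_predicted(x, alpha, np.exp(log_slope), lapse), 1e-12, 1 - 1e-12)
    return -np.sum(k * np.log(p) + (n - k) * np.log(1 - p))


_SLOPE_BOUNDS = (np.log(1e-2), np.log(1e4))


def fit_psychometric(table: pd.DataFrame, fix_lapse: float | None = None,
                     lapse_max: float = LAPSE_MAX) -> PsychFit:
    """Binomial maximum-likelihood logistic fit for one condition.

    Multi-start L-BFGS-B over a grid of midpoint/slope initialisations;
    deterministic given the data. Lapse is bounded to [0, lapse_max]
    (fixed if ``fix_lapse`` is given). Flat data (all responses at
    chance-equivalent rates) are flagged; near-complete separation yields
    a boundary fit with a warning.
    """
    x = table["relative_speed"].to_numpy(dtype=float)
    k = table["n_test_faster"].to_numpy(dtype=float)
    n = table["n_trials"].to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct speed levels")

    span = x.max() - x.min()
    bounds = [(x.min() - 2 * span, x.max() + 2 * span), _SLOPE_BOUNDS]
    if fix_lapse is None:
        bounds.append((0.0, lapse_max))

    best = None
    for a0 in np.quantile(x, [0.25, 0.5, 0.75]):
        for s0 in (1.0 / max(span, 1e-6), 10.0 / max(span, 1e-6)):
            p0 = [a0, np.log(s0)] + ([] if fix_lapse is not None else [0.01])
            res = optimize.minimize(_nll, p0, args=(x, k, n, fix_lapse),
                                    method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res

    alpha, log_slope = best.x[:2]
    lapse = fix_lapse if fix_lapse is not None else float(best.x[2])
    slope = float(np.exp(log_slope))
    fit = PsychFit(alpha=float(alpha), slope=slope, lapse=lapse,
                   loglik=-float(best.fun), pse=np.nan, converged=bool(best.success))

    props = k / n
    if np.ptp(props) == 0 or slope <= np.exp(_SLOPE_BOUNDS[0]) * 1.01:
        fit.flat = True
        fit.pse = float(np.median(x))  # flagged: PSE carries no information
        warnings.warn("flat psychometric data; PSE set to the data midpoint and flagged")
        return fit
    # separation: the fitted curve completes its 0.001->0.999 transition
    # within a single gap between adjacent levels (slope is unidentified)
    gap = np.min(np.diff(np.sort(np.unique(x))))
    if slope * gap > 2.0 * np.log(999.0):
        fit.boundary = True
        warnings.warn("complete separation: slope unidentified; boundary fit reported")
    fit.pse = pse(fit)
    return fit


def pse(fit: PsychFit) -> float:
    """Log speed ratio at which the fitted curve crosses P = 0.5."""
    if fit.flat:
        raise ValueError("PSE undefined for a flat fit")
    # with a symmetric lapse, P(alpha) = 0.5 exactly
    lo, hi = fit.alpha - 1e3 / fit.slope, fit.alpha + 1e3 / fit.slope
    f = lambda x: _predicted(x, fit.alpha, fit.slope, fit.lapse) - 0.5
    if f(lo) * f(hi) > 0:
        raise ValueError("fitted curve does not cross 0.5")
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def simulate_observer(true_pse: float, slope: float, lapse: float,
                      speed_levels, n_per_level: int, seed,
                      condition: str = "single") -> pd.DataFrame:
    """Binomial trial counts drawn from the generative psychometric curve."""
    rng = np.random.default_rng(seed)
    x = np.asarray(speed_levels, dtype=float)
    p = _predicted(x, true_pse, slope, lapse)
    k = rng.binomial(n_per_level, p)
    return make_trial_table(x, k, np.full(len(x), n_per_level), condition)


def default_speed_levels(half_range: float = 0.12, n_levels: int = 7) -> np.ndarray:
    """Seven log speed-ratio levels symmetric about equality."""
    return np.linspace(-half_range, half_range, n_levels)
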