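"""Maximum-likelihood psychometric fits and the fit-adequacy screen.

Two functions are fit per subject × condition, both by binomial maximum
likelihood from per-level counts:

* a cumulative Gaussian ``p(x) = Φ((x − μ)/σ)`` to the rightward-choice
  counts — μ is the decisional PSE;
* a raised Gaussian ``q(x) = floor + amplitude·exp(−(x − μ_c)²/(2σ_c²))`` to
  the low-confidence counts — μ_c, the peak-uncertainty point, is a second,
  decision-free PSE estimate.

Both optimizations start from a fixed coarse parameter grid and run a
deterministic bounded local search from the best starts, so fits are exactly
reproducible; ties are broken toward the smallest ``|μ|``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import chi2

__all__ = [
    "PsychometricFit",
    "ConfidenceFit",
    "tabulate",
    "fit_decision",
    "fit_confidence",
    "adequacy",
]

# parameter bounds, in coherence % where applicable
MU_BOUNDS = (-60.0, 60.0)
SIGMA_BOUNDS = (0.5, 60.0)
AMPLITUDE_BOUNDS = (0.01, 1.0)
FLOOR_BOUNDS = (0.0, 0.5)
STIMULUS_RANGE = 60.0  # full span of the coherence axis used by the screen

_EPS = 1e-10


@dataclass(frozen=True)
class PsychometricFit:
    """Cumulative-Gaussian decision fit; ``mu`` is the PSE (50% point)."""

    mu: float
    sigma: float
    loglik: float
    converged: bool
    n_levels: int

    def predict(self, x):
        return ndtr((np.asarray(x, float) - self.mu) / self.sigma)


@dataclass(frozen=True)
class ConfidenceFit:
    """Raised-Gaussian confidence fit; ``mu_c`` is the peak-uncertainty PSE."""

    mu_c: float
    sigma_c: float
    amplitude: float
    floor: float
    loglik: float
    converged: bool
    n_levels: int

    def predict(self, x):
        x = np.asarray(x, float)
        return self.floor + self.amplitude * np.exp(
            -((x - self.mu_c) ** 2) / (2.0 * self.sigma_c**2)
        )


def tabulate(table: pd.DataFrame, condition=None) -> pd.DataFrame:
    """Collapse a trial table to per-level counts.

    Parameters
    ----------
    table : trial table (one row per trial).
    condition : optional label, list of labels, or boolean predicate applied
        row-wise to select trials before counting.

    Returns
    -------
    DataFrame with columns ``coherence, n_trials, n_right, n_low_confidence``,
    one row per distinct coherence, sorted ascending.
    """
    sub = table
    if condition is not None:
        if callable(condition):
            sub = table[table.apply(condition, axis=1)]
        elif isinstance(condition, (list, tuple, set)):
            sub = table[table["condition"].isin(list(condition))]
        else:
            sub = table[table["condition"] == condition]
    if len(sub) == 0:
        raise ValueError("no trials left after filtering")
    g = sub.groupby("coherence", sort=True)
    counts = pd.DataFrame(
        {
            "n_trials": g.size(),
            "n_right": g["choice"].apply(lambda s: int((s == "right").sum())),
            "n_low_confidence": g["confidence"].apply(lambda s: int((s == "low").sum())),
        }
    ).reset_index()
    return counts


def _as_count_arrays(counts: pd.DataFrame, response_col: str):
    x = np.asarray(counts["coherence"], dtype=float)
    n = np.asarray(counts["n_trials"], dtype=float)
    k = np.asarray(counts[response_col], dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("counts must satisfy 0 <= k <= n")
    return x, n, k


def _binom_nll(p, n, k):
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return -np.sum(k * np.log(p) + (n - k) * np.log(1.0 - p))


def fit_decision(counts: pd.DataFrame) -> PsychometricFit:
    """Fit the cumulative-Gaussian decision function by binomial MLE.

    Requires at least 4 distinct levels spanning both signs of coherence.
    ``converged`` is False when the responses never cross 50% (all-left or
    all-right profiles leave the midpoint unidentified).
    """
    x, n, k = _as_count_arrays(counts, "n_right")
    if len(x) < 4 or x.min() >= 0 or x.max() <= 0:
        raise ValueError("need >= 4 distinct coherence levels spanning both signs")

    def nll_grad(theta):
        mu, sigma = theta
        z = (x - mu) / sigma
        p = np.clip(ndtr(z), _EPS, 1.0 - _EPS)
        f = -np.sum(k * np.log(p) + (n - k) * np.log(1.0 - p))
        # d(nll)/dp times dp/d(mu, sigma); phi is the standard normal pdf
        dldp = -(k / p - (n - k) / (1.0 - p))
        phi = np.exp(-0.5 * z**2) / np.sqrt(2.0 * np.pi)
        g_mu = np.sum(dldp * (-phi / sigma))
        g_sigma = np.sum(dldp * (-z * phi / sigma))
        return f, np.array([g_mu, g_sigma])

    # fixed multi-start grid; vectorized scan picks the best starts
    mu_grid = np.linspace(-40.0, 40.0, 17)
    sig_grid = np.geomspace(1.0, 40.0, 8)
    mm, ss = np.meshgrid(mu_grid, sig_grid, indexing="ij")
    p_grid = ndtr((x[None, None, :] - mm[..., None]) / ss[..., None])
    p_grid = np.clip(p_grid, _EPS, 1 - _EPS)
    nll_grid = -np.sum(k * np.log(p_grid) + (n - k) * np.log(1 - p_grid), axis=-1)
    order = np.argsort(nll_grid, axis=None)[:3]
    best = None
    for idx in order:
        i, j = np.unravel_index(idx, nll_grid.shape)
        res = minimize(
            nll_grad,
            x0=[mm[i, j], ss[i, j]],
            method="L-BFGS-B",
            jac=True,
            bounds=[MU_BOUNDS, SIGMA_BOUNDS],
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-9 or (
            abs(res.fun - best.fun) <= 1e-9 and abs(res.x[0]) < abs(best.x[0])
        ):
            best = res
    phat = np.where(n > 0, k / n, 0.5)
    crosses = (phat.min() < 0.5) and (phat.max() > 0.5)
    return PsychometricFit(
        mu=float(best.x[0]),
        sigma=float(best.x[1]),
        loglik=float(-best.fun),
        converged=bool(best.success and crosses),
        n_levels=len(x),
    )


def fit_confidence(counts: pd.DataFrame) -> ConfidenceFit:
    """Fit the raised-Gaussian confidence function by binomial MLE.

    Requires >= 5 distinct levels and some variation in the low-confidence
    counts.  A flat profile (fitted amplitude at/below 0.05) is reported as
    non-converged: there is no detectable uncertainty peak to locate.
    """
    x, n, k = _as_count_arrays(counts, "n_low_confidence")
    if len(x) < 5:
        raise ValueError("need >= 5 distinct coherence levels")
    phat = np.where(n > 0, k / n, 0.0)
    if np.allclose(phat, phat[0]):
        return ConfidenceFit(
            mu_c=0.0, sigma_c=SIGMA_BOUNDS[0], amplitude=AMPLITUDE_BOUNDS[0],
            floor=float(np.clip(phat[0], *FLOOR_BOUNDS)), loglik=float("-inf"),
            converged=False, n_levels=len(x),
        )

    def nll(theta):
        mu_c, sigma_c, amp, floor = theta
        q = floor + amp * np.exp(-((x - mu_c) ** 2) / (2.0 * sigma_c**2))
        return _binom_nll(q, n, k)

    def nll_grad(theta):
        mu_c, sigma_c, amp, floor = theta
        bell = np.exp(-((x - mu_c) ** 2) / (2.0 * sigma_c**2))
        q = np.clip(floor + amp * bell, _EPS, 1.0 - _EPS)
        f = -np.sum(k * np.log(q) + (n - k) * np.log(1.0 - q))
        dldq = -(k / q - (n - k) / (1.0 - q))
        d_mu = np.sum(dldq * amp * bell * (x - mu_c) / sigma_c**2)
        d_sigma = np.sum(dldq * amp * bell * (x - mu_c) ** 2 / sigma_c**3)
        d_amp = np.sum(dldq * bell)
        d_floor = np.sum(dldq)
        return f, np.array([d_mu, d_sigma, d_amp, d_floor])

    floor0 = float(np.clip(phat.min(), *FLOOR_BOUNDS))
    amp0 = float(np.clip(phat.max() - phat.min(), 0.05, 1.0 - floor0))
    mu_grid = np.linspace(-30.0, 30.0, 13)
    sig_grid = np.geomspace(1.5, 30.0, 6)
    starts = sorted(
        ((nll((m, s, amp0, floor0)), abs(m), m, s) for m in mu_grid for s in sig_grid)
    )[:3]
    constraint = {"type": "ineq", "fun": lambda th: 1.0 - th[2] - th[3]}
    bounds = [MU_BOUNDS, SIGMA_BOUNDS, AMPLITUDE_BOUNDS, FLOOR_BOUNDS]
    best = None
    for _, _, m, s in starts:
        res = minimize(
            nll_grad,
            x0=[m, s, amp0, floor0],
            method="SLSQP",
            jac=True,
            bounds=bounds,
            constraints=[constraint],
            options={"ftol": 1e-12, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-9 or (
            abs(res.fun - best.fun) <= 1e-9 and abs(res.x[0]) < abs(best.x[0])
        ):
            best = res
    mu_c, sigma_c, amp, floor = (float(v) for v in best.x)
    # project back onto floor + amplitude <= 1 (SLSQP honors it only to ftol)
    amp = min(amp, 1.0 - floor)
    loglik = float(-nll((mu_c, sigma_c, amp, floor)))
    # "no detectable peak": the raised Gaussian must beat a flat constant-rate
    # model by more than its 3 extra parameters can explain by chance
    # (chi-square screen at the 5% level); otherwise the located peak is a
    # likelihood degeneracy fit to sampling noise, not an uncertainty peak
    p_flat = np.clip(k.sum() / n.sum(), _EPS, 1 - _EPS)
    ll_flat = float(np.sum(k * np.log(p_flat) + (n - k) * np.log(1 - p_flat)))
    peak_detected = 2.0 * (loglik - ll_flat) > chi2.ppf(0.95, df=3)
    return ConfidenceFit(
        mu_c=mu_c,
        sigma_c=sigma_c,
        amplitude=amp,
        floor=floor,
        loglik=loglik,
        converged=bool(amp > 0.05 and peak_detected and np.isfinite(loglik)),
        n_levels=len(x),
    )


def adequacy(dec: PsychometricFit, conf: ConfidenceFit, design) -> tuple[bool, str]:
    """Screen a subject's fits the way unfittable participants are excluded.

    Returns ``(adequate, reason)``; ``reason`` names the first failing
    criterion, or is ``"ok"``.
    """
    max_level = max(abs(c) for c in design.coherence_levels)
    if not dec.converged:
        return False, "decision fit did not converge"
    if not conf.converged:
        return False, "confidence fit did not converge"
    if abs(dec.mu) > max_level:
        return False, "PSE outside stimulus range"
    if abs(conf.mu_c) > max_level:
        return False, "peak uncertainty outside stimulus range"
    if dec.sigma > STIMULUS_RANGE:
        return False, "decision slope too shallow"
    if conf.sigma_c > STIMULUS_RANGE:
        return False, "confidence width exceeds stimulus range"
    if conf.amplitude < 0.05:
        return False, "no detectable uncertainty peak"
    return True, "ok"
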