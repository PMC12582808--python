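"""Univariable two-sample MR estimators.

All estimators operate on a :class:`~medmr.sumstats.HarmonizedSet` holding
per-SNP exposure effects ``bx`` (se ``sx``), outcome effects ``by`` (se
``sy``) on a shared effect-allele convention.  The per-SNP Wald ratio
``by/bx`` estimates the causal effect under the instrumental-variable
assumptions; the estimators differ in how they combine ratios when some
instruments may be invalid:

* inverse-variance weighted (IVW): weighted regression of ``by`` on ``bx``
  through the origin with weights ``1/sy^2`` — efficient when every
  instrument is valid.  The multiplicative random-effects variant inflates
  the fixed-effect standard error by ``max(1, sqrt(Q/(n-1)))`` where Q is
  Cochran's Q at the estimate.
* MR-Egger: the same regression with an unconstrained intercept after
  orienting all exposure effects non-negative; the intercept absorbs
  directional pleiotropy (valid under InSIDE), the slope is the adjusted
  effect.  Inference uses a t distribution with ``n - 2`` df and residual
  variance floored at 1.
* weighted median: the weight-0.5 quantile of the ordered Wald ratios —
  consistent when instruments carrying a majority of the weight are valid.
* simple/weighted mode: the kernel-density mode of the ratios — consistent
  when the largest cluster of instruments is valid (ZEMPA).

Bootstrap-based standard errors (median, modes) take an explicit seed; there
is no hidden global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sumstats import HarmonizedSet

METHODS = frozenset(
    {
        "ivw_fixed",
        "ivw_random",
        "egger_slope",
        "weighted_median",
        "simple_mode",
        "weighted_mode",
        "wald_ratio",
    }
)

_MIN_NSNP = {
    "ivw_fixed": 2,
    "ivw_random": 2,
    "egger_slope": 3,
    "weighted_median": 3,
    "simple_mode": 3,
    "weighted_mode": 3,
    "wald_ratio": 1,
}


def _two_sided_normal_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


@dataclass
class MREstimate:
    """A causal-effect estimate on the log-odds scale."""

    method: str
    beta: float
    se: float
    pval: float
    nsnp: int

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.se <= 0:
            raise ValueError("se must be positive")
        if self.nsnp < _MIN_NSNP[self.method]:
            raise ValueError(f"{self.method} requires >= {_MIN_NSNP[self.method]} SNPs")

    def odds_ratio(self, level: float = 0.95) -> "OddsRatioView":
        return to_odds_ratio(self, level)


@dataclass
class OddsRatioView:
    """Exponentiated effect with a symmetric-in-log-space confidence interval."""

    or_point: float
    ci_low: float
    ci_high: float
    level: float = 0.95


@dataclass
class EggerFit:
    """MR-Egger slope plus the pleiotropy intercept and its test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float
    nsnp: int


def wald_ratio(beta_exp: float, beta_out: float, se_out: float) -> MREstimate:
    """Single-SNP causal estimate by/bx with first-order se se_out/|bx|."""
    if beta_exp == 0:
        raise ValueError("undefined ratio: exposure effect is zero")
    if se_out <= 0:
        raise ValueError("se_out must be positive")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return MREstimate("wald_ratio", float(beta), float(se), _two_sided_normal_p(beta / se), 1)


def ivw(h: HarmonizedSet, effects: str = "random") -> MREstimate:
    """Inverse-variance weighted estimate (fixed or multiplicative random effects)."""
    if effects not in ("fixed", "random"):
        raise ValueError("effects must be 'fixed' or 'random'")
    n = h.nsnp
    if n < 2:
        raise ValueError("IVW requires at least 2 SNPs")
    bx, by, sy = h.beta_exp, h.beta_out, h.se_out
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    if sxx == 0:
        raise ValueError("no instrument signal: all exposure effects are zero")
    beta = float(np.sum(w * bx * by)) / sxx
    se = 1.0 / np.sqrt(sxx)
    method = "ivw_fixed"
    if effects == "random":
        q = float(np.sum(w * (by - beta * bx) ** 2))
        se *= max(1.0, np.sqrt(q / (n - 1)))
        method = "ivw_random"
    return MREstimate(method, beta, float(se), _two_sided_normal_p(beta / se), n)


def mr_egger(h: HarmonizedSet) -> EggerFit:
    """Weighted regression with intercept after orienting exposure effects >= 0."""
    n = h.nsnp
    if n < 3:
        raise ValueError("MR-Egger requires at least 3 SNPs")
    sign = np.where(h.beta_exp < 0, -1.0, 1.0)
    x = h.beta_exp * sign
    y = h.beta_out * sign
    w = 1.0 / h.se_out**2
    if np.ptp(x) <= 1e-14 * max(1.0, np.abs(x).max()):
        raise ValueError("collinear design: exposure effects identical after orientation")
    X = np.column_stack([np.ones(n), x])
    xtwx = X.T @ (X * w[:, None])
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / (n - 2)
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    se = np.sqrt(np.diag(cov))
    p = [float(min(1.0, 2.0 * stats.t.sf(abs(c / s), n - 2))) for c, s in zip(coef, se)]
    return EggerFit(
        slope=MREstimate("egger_slope", float(coef[1]), float(se[1]), p[1], n),
        intercept=float(coef[0]),
        intercept_se=float(se[0]),
        intercept_p=p[0],
        nsnp=n,
    )


def _ratios_and_weights(h: HarmonizedSet, weighted: bool = True):
    r = h.beta_out / h.beta_exp
    if weighted:
        # inverse variance of the first-order Wald ratio, var ~ sy^2 / bx^2
        w = h.beta_exp**2 / h.se_out**2
    else:
        w = np.ones_like(r)
    return r, w


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, p, r))


def _bootstrap_se(h: HarmonizedSet, statistic, n_boot: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    n = h.nsnp
    bxs = h.beta_exp + rng.standard_normal((n_boot, n)) * h.se_exp
    bys = h.beta_out + rng.standard_normal((n_boot, n)) * h.se_out
    ests = np.empty(n_boot)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(n_boot):
            ests[i] = statistic(bxs[i], bys[i])
    ests = ests[np.isfinite(ests)]
    se = float(np.std(ests, ddof=1))
    return max(se, np.finfo(float).tiny)


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, *, seed: int) -> MREstimate:
    """Weighted-median estimator; se from a seeded parametric bootstrap."""
    if h.nsnp < 3:
        raise ValueError("weighted median requires at least 3 SNPs")
    r, w = _ratios_and_weights(h, weighted=True)
    beta = _weighted_median(r, w)

    def stat(bx, by):
        mask = bx != 0
        if mask.sum() < 3:
            return np.nan
        return _weighted_median(by[mask] / bx[mask], bx[mask] ** 2 / h.se_out[mask] ** 2)

    se = _bootstrap_se(h, stat, n_boot, seed)
    return MREstimate("weighted_median", beta, se, _two_sided_normal_p(beta / se), h.nsnp)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    w = weights / np.sum(weights)
    s = 1.4826 * float(np.median(np.abs(ratios - np.median(ratios))))
    if s == 0:
        # degenerate bandwidth: discrete weighted mode (ties -> smallest value)
        vals, inv = np.unique(ratios, return_inverse=True)
        mass = np.bincount(inv, weights=w)
        return float(vals[np.argmax(mass)])
    n = len(ratios)
    h_bw = phi * 1.06 * s * n ** (-0.2)
    m = float(np.mean(ratios))
    lo = min(m - 4 * s, ratios.min())
    hi = max(m + 4 * s, ratios.max())
    grid = np.linspace(lo, hi, 512)
    dens = np.sum(w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h_bw) ** 2), axis=1)
    return float(grid[np.argmax(dens)])


def mode_estimate(
    h: HarmonizedSet,
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    *,
    seed: int,
) -> MREstimate:
    """Kernel-density mode of the Wald ratios (simple or inverse-variance weighted)."""
    if h.nsnp < 3:
        raise ValueError("mode estimators require at least 3 SNPs")
    if phi <= 0:
        raise ValueError("phi must be positive")
    r, w = _ratios_and_weights(h, weighted=weighted)
    beta = _mode_point(r, w, phi)

    def stat(bx, by):
        mask = bx != 0
        if mask.sum() < 3:
            return np.nan
        wb = bx[mask] ** 2 / h.se_out[mask] ** 2 if weighted else np.ones(mask.sum())
        return _mode_point(by[mask] / bx[mask], wb, phi)

    se = _bootstrap_se(h, stat, n_boot, seed)
    method = "weighted_mode" if weighted else "simple_mode"
    return MREstimate(method, beta, se, _two_sided_normal_p(beta / se), h.nsnp)


def to_odds_ratio(
    e: MREstimate, level: float = 0.95, critical_value: float | None = None
) -> OddsRatioView:
    """Exponentiate a log-odds effect into an OR with its Wald confidence interval.

    At the default 95% level the conventional fixed multiplier 1.96 is used,
    matching the reporting convention of the standard MR toolchain; other
    levels use the exact standard-normal quantile.  Pass ``critical_value``
    to override either.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0,1)")
    if critical_value is not None:
        z = critical_value
    elif abs(level - 0.95) < 1e-12:
        z = 1.96
    else:
        z = stats.norm.ppf(0.5 * (1 + level))
    return OddsRatioView(
        or_point=float(np.exp(e.beta)),
        ci_low=float(np.exp(e.beta - z * e.se)),
        ci_high=float(np.exp(e.beta + z * e.se)),
        level=level,
    )
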