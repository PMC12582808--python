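"""Sensitivity and directionality diagnostics for two-sample MR.

Heterogeneity across instruments is measured by Cochran's Q at a candidate
causal estimate, with I-squared summarising the excess over its degrees of
freedom.  Directional horizontal pleiotropy is tested by the MR-Egger
intercept.  Leave-one-out re-estimates the causal effect dropping each
instrument in turn.  The Steiger test compares the variance in exposure vs
outcome explained by the instruments to confirm the causal orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import MREstimate, ivw, mr_egger
from .sumstats import HarmonizedSet


@dataclass
class HeterogeneityResult:
    q: float
    df: int
    pval: float
    i2: float  # percentage in [0, 100]


@dataclass
class PleiotropyResult:
    intercept: float
    se: float
    pval: float


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    pval: float


@dataclass
class LeaveOneOutTable:
    rows: list[tuple[str, MREstimate]]
    full: MREstimate


def i_squared(q: float, df: int, convention: str = "standard") -> float:
    """Proportion of variation attributable to heterogeneity, as a percentage.

    ``"standard"``: max(0, (Q - df)/Q) * 100.  ``"paper"``: an alternative
    convention, df/Q * 100 when Q exceeds df and 0 otherwise, provided to
    reproduce published tables that use it; not the default.
    """
    if q < 0:
        raise ValueError("Q must be non-negative")
    if convention == "standard":
        return 0.0 if q <= df or q == 0 else float(100.0 * (q - df) / q)
    if convention == "paper":
        return 0.0 if q <= df else float(100.0 * df / q)
    raise ValueError(f"unknown I2 convention {convention!r}")


def cochran_q(
    h: HarmonizedSet, at_estimate: float | None = None, i2_convention: str = "standard"
) -> HeterogeneityResult:
    """Cochran's Q of the per-SNP Wald ratios around ``at_estimate``.

    Weights are the inverse first-order variances of the ratios,
    ``bx^2 / se_out^2``.  Defaults to evaluating at the fixed-effects IVW
    estimate, where Q is minimal.
    """
    if h.nsnp < 2:
        raise ValueError("Cochran's Q requires at least 2 SNPs")
    if at_estimate is None:
        at_estimate = ivw(h, effects="fixed").beta
    w = h.beta_exp**2 / h.se_out**2
    ratios = h.beta_out / h.beta_exp
    q = float(np.sum(w * (ratios - at_estimate) ** 2))
    df = h.nsnp - 1
    return HeterogeneityResult(
        q=q,
        df=df,
        pval=float(stats.chi2.sf(q, df)),
        i2=i_squared(q, df, i2_convention),
    )


def egger_intercept_test(h: HarmonizedSet) -> PleiotropyResult:
    """MR-Egger intercept with its t-test (n-2 df): nonzero indicates pleiotropy."""
    fit = mr_egger(h)
    return PleiotropyResult(intercept=fit.intercept, se=fit.intercept_se, pval=fit.intercept_p)


def leave_one_out(h: HarmonizedSet, effects: str = "random") -> LeaveOneOutTable:
    """Random-effects IVW re-estimated with each instrument excluded in turn."""
    if h.nsnp < 3:
        raise ValueError("leave-one-out requires at least 3 SNPs")
    full = ivw(h, effects=effects)
    rows = []
    idx = np.arange(h.nsnp)
    for i in range(h.nsnp):
        rows.append((h.snp_ids[i], ivw(h.subset(idx[idx != i]), effects=effects)))
    return LeaveOneOutTable(rows=rows, full=full)


def _r2_from_z(beta: np.ndarray, se: np.ndarray, n: int) -> float:
    z2 = (beta / se) ** 2
    return float(np.sum(z2 / (z2 + n - 2)))


def steiger(
    h: HarmonizedSet, n_exp: int | None = None, n_out: int | None = None
) -> SteigerResult:
    """Directionality test: instruments should explain more exposure than outcome variance.

    Per-SNP variance explained is recovered from the Wald z statistic,
    r2 = z^2 / (z^2 + n - 2), and summed over instruments for each trait.
    The p-value compares the implied correlations sqrt(r2) by a two-sample
    Fisher-z test at the two GWAS sample sizes.
    """
    n_exp = n_exp if n_exp is not None else h.n_exp
    n_out = n_out if n_out is not None else h.n_out
    if n_exp is None or n_out is None:
        raise ValueError("sample size required for Steiger on both exposure and outcome")
    if n_exp < 10 or n_out < 10:
        raise ValueError("Steiger requires sample sizes >= 10")
    r2_exp = min(_r2_from_z(h.beta_exp, h.se_exp, n_exp), 1.0 - 1e-12)
    r2_out = min(_r2_from_z(h.beta_out, h.se_out, n_out), 1.0 - 1e-12)
    z_e = np.arctanh(np.sqrt(r2_exp))
    z_o = np.arctanh(np.sqrt(r2_out))
    denom = np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z = (z_e - z_o) / denom
    return SteigerResult(
        r2_exposure=r2_exp,
        r2_outcome=r2_out,
        correct_direction=bool(r2_exp > r2_out),
        pval=float(min(1.0, 2.0 * stats.norm.sf(abs(z)))),
    )
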