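"""Two-step MR mediation decomposition (product of coefficients).

For an exposure E, mediator M and outcome O the decomposition combines
three summary effects:

* ``beta`` — total effect E -> O from univariable MR;
* ``alpha`` — effect E -> M from univariable MR;
* ``beta2`` — direct effect M -> O conditional on E, from MVMR.

The indirect (mediated) effect is ``alpha * beta2``, the direct effect is
``beta1 = beta - alpha * beta2``, and the proportion mediated is
``(alpha * beta2 / beta) * 100`` percent.  The indirect-effect standard
error uses the delta method, sqrt(alpha^2 se2^2 + beta2^2 se_alpha^2); the
proportion's interval propagates the ratio the same way (treating numerator
and denominator as independent, appropriate for two-sample summary data)
and is reported untruncated — with inconsistent signs it may legitimately
exceed 100% or be negative.  A seeded parametric bootstrap is available as
an alternative interval method.

Mediation is only interpreted (gated) when both the total effect and the
exposure -> mediator effect are individually significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import MREstimate

logger = logging.getLogger(__name__)


@dataclass
class MediationResult:
    """Total/direct/indirect decomposition with delta-method intervals."""

    total_beta: float
    total_se: float
    alpha: float
    alpha_se: float
    beta2: float
    beta2_se: float
    indirect: float
    indirect_se: float
    direct: float
    direct_se: float
    proportion_pct: float | None
    proportion_se: float | None
    ci: dict[str, tuple[float, float] | None]
    significant_gate: bool
    sign_consistent: bool | None
    level: float = 0.95
    exposure: str = ""
    mediator: str = ""
    outcome: str = ""
    warnings: list[str] = field(default_factory=list)


@dataclass
class MediationCandidate:
    """One (exposure, mediator) pair with its upstream estimates."""

    exposure: str
    mediator: str
    outcome: str
    total: MREstimate
    exp_to_med: MREstimate
    med_to_out: tuple[float, float]  # (beta2, se2) from MVMR


def two_step_mediation(
    total: MREstimate,
    exp_to_med: MREstimate,
    med_to_out: tuple[float, float],
    level: float = 0.95,
    gate_level: float = 0.05,
    ci_method: str = "delta",
    n_boot: int = 1000,
    seed: int | None = None,
    exposure: str = "",
    mediator: str = "",
    outcome: str = "",
) -> MediationResult:
    """Decompose the total effect into direct and mediated components."""
    beta2, se2 = med_to_out
    if total.se <= 0 or exp_to_med.se <= 0 or se2 <= 0:
        raise ValueError("all three standard errors must be positive")
    alpha, se_a = exp_to_med.beta, exp_to_med.se
    b, se_b = total.beta, total.se

    indirect = alpha * beta2
    se_ind = float(np.sqrt(alpha**2 * se2**2 + beta2**2 * se_a**2))
    direct = b - indirect
    se_dir = float(np.sqrt(se_b**2 + se_ind**2))

    warnings: list[str] = []
    if b == 0:
        proportion = prop_se = None
        warnings.append("total effect is zero: proportion mediated undefined")
        logger.warning("total effect is zero: proportion mediated undefined")
    else:
        proportion = 100.0 * indirect / b
        prop_se = 100.0 * float(
            np.sqrt(se_ind**2 / b**2 + indirect**2 * se_b**2 / b**4)
        )
        if not 0 <= proportion <= 100:
            warnings.append(
                f"proportion mediated {proportion:.2f}% outside [0,100] "
                "(inconsistent effect signs); reported untruncated"
            )

    z = stats.norm.ppf(0.5 * (1 + level))
    ci: dict[str, tuple[float, float] | None] = {
        "total": (b - z * se_b, b + z * se_b),
        "alpha": (alpha - z * se_a, alpha + z * se_a),
        "beta2": (beta2 - z * se2, beta2 + z * se2),
        "indirect": (indirect - z * se_ind, indirect + z * se_ind),
        "direct": (direct - z * se_dir, direct + z * se_dir),
        "proportion": None
        if proportion is None
        else (proportion - z * prop_se, proportion + z * prop_se),
    }
    if ci_method == "bootstrap":
        if seed is None:
            raise ValueError("bootstrap interval requires a seed")
        rng = np.random.default_rng(seed)
        a_s = rng.normal(alpha, se_a, n_boot)
        b2_s = rng.normal(beta2, se2, n_boot)
        t_s = rng.normal(b, se_b, n_boot)
        ind_s = a_s * b2_s
        qs = [0.5 * (1 - level), 0.5 * (1 + level)]
        ci["indirect"] = tuple(np.quantile(ind_s, qs))
        ci["direct"] = tuple(np.quantile(t_s - ind_s, qs))
        if proportion is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                p_s = 100.0 * ind_s / t_s
            ci["proportion"] = tuple(np.quantile(p_s[np.isfinite(p_s)], qs))
    elif ci_method != "delta":
        raise ValueError("ci_method must be 'delta' or 'bootstrap'")

    sign_consistent = None
    if indirect != 0 and direct != 0:
        sign_consistent = bool(np.sign(indirect) == np.sign(direct))

    res = MediationResult(
        total_beta=b,
        total_se=se_b,
        alpha=alpha,
        alpha_se=se_a,
        beta2=beta2,
        beta2_se=se2,
        indirect=indirect,
        indirect_se=se_ind,
        direct=direct,
        direct_se=se_dir,
        proportion_pct=proportion,
        proportion_se=prop_se,
        ci=ci,
        significant_gate=bool(total.pval < gate_level and exp_to_med.pval < gate_level),
        sign_consistent=sign_consistent,
        level=level,
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        warnings=warnings,
    )
    # decomposition identity holds by construction; assert defensively
    tol = 4 * np.finfo(float).eps * max(1.0, abs(res.total_beta))
    assert abs(res.direct + res.indirect - res.total_beta) <= tol
    return res


def gate_models(
    candidates: list[MediationCandidate],
    gate_level: float = 0.05,
    **kwargs,
) -> tuple[list[MediationResult], list[tuple[str, str]]]:
    """Decompose only candidates with significant E->O and E->M effects.

    Returns the passing :class:`MediationResult` list plus
    ``(exposure, failed criterion)`` entries for the rest.
    """
    passed: list[MediationResult] = []
    excluded: list[tuple[str, str]] = []
    for c in candidates:
        if c.total.pval >= gate_level:
            excluded.append((c.exposure, "exposure->outcome not significant"))
            continue
        if c.exp_to_med.pval >= gate_level:
            excluded.append((c.exposure, "exposure->mediator not significant"))
            continue
        passed.append(
            two_step_mediation(
                c.total,
                c.exp_to_med,
                c.med_to_out,
                gate_level=gate_level,
                exposure=c.exposure,
                mediator=c.mediator,
                outcome=c.outcome,
                **kwargs,
            )
        )
    return passed, excluded
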