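"""Model/Results objects tying the estimators and diagnostics together.

`MRModel` wraps a harmonized exposure/outcome set and exposes the
univariable estimators through ``fit``; `MVMRModel` does the same for the
multivariable design.  Both return results objects carrying the estimate,
its uncertainty and a ``summary()`` table, in the spirit of statsmodels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import estimators as est
from . import sensitivity as sens
from .mvmr import MVMRInput, MVMRResult, mvmr_ivw
from .sumstats import HarmonizedSet, SumStatRecord, harmonize

#: the study's five supplementary-analysis estimators, keyed by fit() method name
FIVE_METHODS = ("ivw_random", "egger", "weighted_median", "simple_mode", "weighted_mode")


class MRModel:
    """Univariable two-sample MR model on a harmonized SNP set.

    Parameters
    ----------
    data : HarmonizedSet
        Per-SNP exposure/outcome effects on a shared allele convention.
    exposure, outcome : str
        Trait labels used in summaries.
    """

    def __init__(self, data: HarmonizedSet, exposure: str = "exposure", outcome: str = "outcome"):
        self.data = data
        self.exposure = exposure
        self.outcome = outcome

    @classmethod
    def from_records(
        cls,
        exposure_records: list[SumStatRecord],
        outcome_records: list[SumStatRecord],
        palindromic_eaf_window: float = 0.08,
        exposure: str = "exposure",
        outcome: str = "outcome",
    ) -> "MRModel":
        h = harmonize(exposure_records, outcome_records, palindromic_eaf_window)
        return cls(h, exposure=exposure, outcome=outcome)

    def fit(
        self,
        method: str = "ivw_random",
        n_boot: int = 1000,
        seed: int | None = None,
        phi: float = 1.0,
    ) -> "MRResults":
        """Fit one estimator; bootstrap-based methods require a seed."""
        h = self.data
        egger_fit = None
        if method == "ivw_random":
            e = est.ivw(h, effects="random")
        elif method == "ivw_fixed":
            e = est.ivw(h, effects="fixed")
        elif method in ("egger", "egger_slope"):
            egger_fit = est.mr_egger(h)
            e = egger_fit.slope
        elif method == "weighted_median":
            e = est.weighted_median(h, n_boot=n_boot, seed=self._need_seed(seed))
        elif method == "simple_mode":
            e = est.mode_estimate(h, weighted=False, phi=phi, n_boot=n_boot, seed=self._need_seed(seed))
        elif method == "weighted_mode":
            e = est.mode_estimate(h, weighted=True, phi=phi, n_boot=n_boot, seed=self._need_seed(seed))
        else:
            raise ValueError(f"unknown method {method!r}")
        return MRResults(self, e, egger=egger_fit)

    @staticmethod
    def _need_seed(seed):
        if seed is None:
            raise ValueError("this method's bootstrap se requires an explicit seed")
        return seed

    def fit_all(self, n_boot: int = 1000, seed: int = 0, phi: float = 1.0) -> dict[str, "MRResults"]:
        """Fit the five standard estimators (IVW random, Egger, median, modes)."""
        out = {}
        for i, m in enumerate(FIVE_METHODS):
            out[m] = self.fit(m, n_boot=n_boot, seed=seed + i, phi=phi)
        return out

    # -- diagnostics ---------------------------------------------------------
    def heterogeneity(self, at_estimate: float | None = None, i2_convention: str = "standard"):
        return sens.cochran_q(self.data, at_estimate=at_estimate, i2_convention=i2_convention)

    def pleiotropy_test(self):
        return sens.egger_intercept_test(self.data)

    def leave_one_out(self, effects: str = "random"):
        return sens.leave_one_out(self.data, effects=effects)

    def steiger(self, n_exp: int | None = None, n_out: int | None = None):
        return sens.steiger(self.data, n_exp=n_exp, n_out=n_out)


class MRResults:
    """A fitted causal-effect estimate with OR view and summary table."""

    def __init__(self, model: MRModel, estimate: est.MREstimate, egger: est.EggerFit | None = None):
        self.model = model
        self.estimate = estimate
        self.egger = egger

    @property
    def beta(self) -> float:
        return self.estimate.beta

    params = beta

    @property
    def bse(self) -> float:
        return self.estimate.se

    @property
    def pvalue(self) -> float:
        return self.estimate.pval

    @property
    def nsnp(self) -> int:
        return self.estimate.nsnp

    @property
    def method(self) -> str:
        return self.estimate.method

    def conf_int(self, level: float = 0.95) -> tuple[float, float]:
        orv = est.to_odds_ratio(self.estimate, level)
        return float(np.log(orv.ci_low)), float(np.log(orv.ci_high))

    def odds_ratio(self, level: float = 0.95) -> est.OddsRatioView:
        return est.to_odds_ratio(self.estimate, level)

    def to_frame(self) -> pd.DataFrame:
        orv = self.odds_ratio()
        return pd.DataFrame(
            [
                {
                    "exposure": self.model.exposure,
                    "outcome": self.model.outcome,
                    "method": self.method,
                    "nsnp": self.nsnp,
                    "beta": self.beta,
                    "se": self.bse,
                    "pval": self.pvalue,
                    "or": orv.or_point,
                    "or_ci_low": orv.ci_low,
                    "or_ci_high": orv.ci_high,
                }
            ]
        )

    def summary(self) -> str:
        lines = [
            f"MR estimate: {self.model.exposure} -> {self.model.outcome}",
            self.to_frame().to_string(index=False, float_format=lambda v: f"{v:.6f}"),
        ]
        if self.egger is not None:
            lines.append(
                f"Egger intercept: {self.egger.intercept:.6f} "
                f"(se {self.egger.intercept_se:.6f}, p {self.egger.intercept_p:.6f})"
            )
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<MRResults {self.method} beta={self.beta:.4f} se={self.bse:.4f} "
            f"p={self.pvalue:.3g} nsnp={self.nsnp}>"
        )


class MVMRModel:
    """Multivariable MR model over a joint instrument set."""

    def __init__(self, data: MVMRInput, outcome: str = "outcome"):
        self.data = data
        self.outcome = outcome

    @classmethod
    def from_exposures(cls, exposures, outcome_records, outcome: str = "outcome", **kw):
        from .mvmr import build_mvmr_input

        return cls(build_mvmr_input(exposures, outcome_records, **kw), outcome=outcome)

    def fit(self) -> "MVMRResults":
        return MVMRResults(self, mvmr_ivw(self.data))

    @property
    def exposure_labels(self):
        return self.data.exposure_labels


class MVMRResults:
    """Per-exposure direct effects from the multivariable fit."""

    def __init__(self, model: MVMRModel, result: MVMRResult):
        self.model = model
        self.result = result

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.result.beta, index=self.result.exposure_labels)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.result.se, index=self.result.exposure_labels)

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(self.result.pval, index=self.result.exposure_labels)

    @property
    def nsnp(self) -> int:
        return self.result.nsnp

    def effect(self, label: str) -> tuple[float, float]:
        """(beta, se) for one exposure, e.g. to feed the mediation step."""
        i = self.result.exposure_labels.index(label)
        return float(self.result.beta[i]), float(self.result.se[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.result.exposure_labels,
                "outcome": self.model.outcome,
                "beta": self.result.beta,
                "se": self.result.se,
                "pval": self.result.pval,
                "nsnp": self.result.nsnp,
            }
        )

    def summary(self) -> str:
        return (
            f"MVMR-IVW ({self.nsnp} SNPs) -> {self.model.outcome}\n"
            + self.to_frame().to_string(index=False, float_format=lambda v: f"{v:.6f}")
        )
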