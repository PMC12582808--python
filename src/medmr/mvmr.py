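"""Multivariable MR: joint direct effects of several exposures on one outcome.

The design matrix stacks each exposure's per-SNP effects over the union of
the exposures' instruments, restricted to SNPs available in every exposure
and the outcome, all harmonized pairwise to the first exposure's
effect-allele convention.  The estimator is weighted multivariable
regression of the outcome effects on the matrix columns without intercept
(weights 1/se_out^2), with multiplicative residual inflation floored at 1 —
the multi-exposure generalisation of random-effects IVW.  With a single
exposure it reduces exactly to univariable IVW.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sumstats import SumStatRecord, harmonize


@dataclass
class MVMRInput:
    """Aligned per-SNP effects for several exposures and one outcome."""

    snp_ids: list[str]
    beta_exp_matrix: np.ndarray  # nsnp x n_exposures
    se_exp_matrix: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    exposure_labels: list[str]
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        def _as_matrix(a):
            a = np.asarray(a, dtype=float)
            return a[:, None] if a.ndim == 1 else a

        self.beta_exp_matrix = _as_matrix(self.beta_exp_matrix)
        self.se_exp_matrix = _as_matrix(self.se_exp_matrix)
        n, k = self.beta_exp_matrix.shape
        if len(self.snp_ids) != n or len(self.exposure_labels) != k:
            raise ValueError("MVMR input dimensions inconsistent")
        if self.se_exp_matrix.shape != (n, k):
            raise ValueError("se matrix shape mismatch")
        if len(self.beta_out) != n or len(self.se_out) != n:
            raise ValueError("outcome vectors must match nsnp")

    @property
    def nsnp(self) -> int:
        return self.beta_exp_matrix.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.beta_exp_matrix.shape[1]


@dataclass
class MVMRResult:
    """Per-exposure direct effects conditional on the other exposures."""

    exposure_labels: list[str]
    beta: np.ndarray
    se: np.ndarray
    pval: np.ndarray
    nsnp: int

    def rows(self):
        return list(zip(self.exposure_labels, self.beta, self.se, self.pval))


def _normalize_exposure_arg(exposures):
    norm = []
    for item in exposures:
        if len(item) == 2:
            label, selected = item
            full = selected
        elif len(item) == 3:
            label, selected, full = item
        else:
            raise ValueError("each exposure must be (label, selected[, full_records])")
        norm.append((label, list(selected), list(full)))
    return norm


def build_mvmr_input(
    exposures: list[tuple],
    outcome: list[SumStatRecord],
    palindromic_eaf_window: float = 0.08,
) -> MVMRInput:
    """Assemble the MVMR design from per-exposure instruments and summary stats.

    ``exposures`` is a list of ``(label, selected_records, full_records)``
    tuples (``full_records`` optional, defaulting to the selected set): the
    instrument list is the union of the selected sets, restricted to SNPs
    present in every exposure's full summary statistics and in the outcome,
    harmonized pairwise against the first exposure's convention.
    """
    exps = _normalize_exposure_arg(exposures)
    if len(exps) < 2:
        raise ValueError("MVMR requires at least 2 exposures")
    for label, selected, _ in exps:
        if not selected:
            raise ValueError(f"exposure {label!r} has no selected instruments")

    union: list[str] = []
    seen: set[str] = set()
    for _, selected, _ in exps:
        for r in selected:
            if r.snp_id not in seen:
                seen.add(r.snp_id)
                union.append(r.snp_id)

    dropped: list[tuple[str, str]] = []
    ref_label, _, ref_full = exps[0]
    ref_by_id = {}
    for r in ref_full:
        ref_by_id.setdefault(r.snp_id, r)
    kept = [s for s in union if s in ref_by_id]
    dropped += [(s, f"{ref_label}:missing") for s in union if s not in ref_by_id]
    ref_records = [ref_by_id[s] for s in kept]

    # harmonize every other table (exposures 2..k and the outcome) to exposure 1
    aligned: list[dict[str, tuple[float, float]]] = []
    tables = [(label, full) for label, _, full in exps[1:]] + [("outcome", list(outcome))]
    for label, table in tables:
        hs = harmonize(ref_records, table, palindromic_eaf_window)
        aligned.append(
            {s: (b, se) for s, b, se in zip(hs.snp_ids, hs.beta_out, hs.se_out)}
        )
        lost = set(r.snp_id for r in ref_records) - set(hs.snp_ids)
        reasons = dict(hs.dropped)
        dropped += [(s, f"{label}:{reasons.get(s, 'dropped')}") for s in sorted(lost)]

    final = [s for s in kept if all(s in a for a in aligned)]
    k = len(exps)
    n = len(final)
    if n <= k:
        raise ValueError(
            f"underdetermined MVMR design: {n} SNPs for {k} exposures (drops: {len(dropped)})"
        )
    beta = np.empty((n, k))
    se = np.empty((n, k))
    ref_map = {s: (ref_by_id[s].beta, ref_by_id[s].se) for s in final}
    for i, s in enumerate(final):
        beta[i, 0], se[i, 0] = ref_map[s]
        for j in range(1, k):
            beta[i, j], se[i, j] = aligned[j - 1][s]
    beta_out = np.array([aligned[-1][s][0] for s in final])
    se_out = np.array([aligned[-1][s][1] for s in final])
    return MVMRInput(
        snp_ids=final,
        beta_exp_matrix=beta,
        se_exp_matrix=se,
        beta_out=beta_out,
        se_out=se_out,
        exposure_labels=[label for label, _, _ in exps],
        dropped=dropped,
    )


def mvmr_ivw(inp: MVMRInput) -> MVMRResult:
    """Weighted multivariable regression of outcome effects on the exposure matrix.

    No intercept; weights 1/se_out^2; per-exposure standard errors from the
    weighted normal-equations covariance with multiplicative residual
    inflation floored at 1; two-sided normal p-values.
    """
    X = inp.beta_exp_matrix
    y = inp.beta_out
    n, k = X.shape
    if n <= k:
        raise ValueError("underdetermined MVMR design")
    w = 1.0 / inp.se_out**2
    xtwx = X.T @ (X * w[:, None])
    if np.linalg.matrix_rank(xtwx) < k or np.linalg.cond(xtwx) > 1e12:
        raise ValueError("collinear exposures: MVMR design matrix is rank deficient")
    beta = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ beta
    sigma2 = float(np.sum(w * resid**2)) / (n - k)
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    se = np.sqrt(np.diag(cov))
    pval = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(beta / se)))
    return MVMRResult(
        exposure_labels=list(inp.exposure_labels),
        beta=beta,
        se=se,
        pval=pval,
        nsnp=n,
    )
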