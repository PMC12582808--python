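"""Synthetic linked GWAS summary statistics with known causal ground truth.

The generator emulates the statistical structure a summary-level mediation
MR analysis assumes: three GWAS tables (exposure, mediator, outcome) over a
shared SNP panel, connected by a causal chain

    exposure --alpha--> mediator --beta2--> outcome,
    exposure --beta1--> outcome (direct),

so the implied total exposure -> outcome effect is beta1 + alpha * beta2.

Per SNP j, the true per-allele exposure effect is gamma_j ~ N(0, gamma_sd^2)
and the mediator carries an additional independent genetic component
delta_j ~ N(0, med_gamma_sd^2) (without which the mediator column would be a
multiple of the exposure column and MVMR would be unidentifiable):

    beta_exp,j = gamma_j
    beta_med,j = alpha * gamma_j + delta_j
    beta_out,j = beta1 * gamma_j + beta2 * beta_med,j + s_j * p_j

where p_j is a pleiotropic effect on the outcome for the invalid fraction
(zero / N(0, sd) balanced / N(mean, sd) directional) and s_j = sign(gamma_j)
orients pleiotropy to the exposure-increasing allele, the scale on which
MR-Egger's intercept is defined.  Balanced mode keeps InSIDE intact.

Standard errors follow the GWAS scaling 1/sqrt(2 n maf (1-maf)) for each
trait's (effective) sample size; observed betas add N(0, se^2) noise and
p-values are two-sided Wald.  Everything is reproducible from the seed.

Default sample sizes mirror the study the package is designed around:
a 16S microbiome GWAS of 18,340 individuals for the exposure, and FinnGen
binary traits for mediator and outcome, entered as effective sample sizes
(4 / (1/ncase + 1/nctrl); the constipation GWAS of 44,590 cases / 409,143
controls gives ~160,845).  Default instrument spread (gamma_sd = 0.04)
makes the p < 1e-5 screen select roughly 8-12 SNPs per trait with
F statistics around 19-30, the regime reported for real microbiome taxa.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .instruments import LDMatrix
from .sumstats import SumStatRecord, write_sumstats

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationConfig:
    """Ground truth and sampling design for one synthetic dataset."""

    n_snps: int = 60
    n_exp: int = 18340
    n_med: int = 16700
    n_out: int = 160845
    true_alpha: float = 0.4
    true_beta2: float = 0.3
    true_beta1: float = 0.08
    gamma_sd: float = 0.04
    med_gamma_sd: float = 0.04
    pleiotropy: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    prop_invalid: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    palindromic_frac: float = 0.2
    ld_blocks: tuple[int, float] | None = None  # (block size, within-block r2)
    seed: int = 0

    @property
    def total_effect(self) -> float:
        return self.true_beta1 + self.true_alpha * self.true_beta2

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError("degenerate maf_range: need 0 < low < high <= 0.5")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError("pleiotropy must be none, balanced or directional")
        if not 0 <= self.prop_invalid <= 1:
            raise ValueError("prop_invalid must lie in [0,1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["ld_blocks"] = None if self.ld_blocks is None else list(self.ld_blocks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d.pop("total_effect", None)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if d.get("ld_blocks") is not None:
            d["ld_blocks"] = tuple(d["ld_blocks"])
        return cls(**d)

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class SyntheticDataset:
    """Three linked summary-stat tables plus the ground truth that made them."""

    exposure: list[SumStatRecord]
    mediator: list[SumStatRecord]
    outcome: list[SumStatRecord]
    ld: LDMatrix | None
    truth: dict = field(default_factory=dict)


def _se_scaling(n: int, maf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _records(ids, chrom, pos, ea, oa, eaf, beta, se, n) -> list[SumStatRecord]:
    pval = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(beta / se)))
    pval = np.maximum(pval, np.finfo(float).tiny)
    return [
        SumStatRecord(
            snp_id=ids[j], effect_allele=ea[j], other_allele=oa[j],
            beta=float(beta[j]), se=float(se[j]), pval=float(pval[j]),
            eaf=float(eaf[j]), n=int(n), chrom=str(chrom[j]), pos=int(pos[j]),
        )
        for j in range(len(ids))
    ]


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Draw one synthetic exposure/mediator/outcome dataset from the config."""
    c = config
    rng = np.random.default_rng(c.seed)
    m = c.n_snps
    ids = [f"rs{1000000 + j}" for j in range(m)]

    # genomic placement: far apart (> any clumping window) unless LD blocks
    # are requested, in which case SNPs within a block sit adjacently
    if c.ld_blocks is None:
        chrom = np.array([str(1 + (j % 22)) for j in range(m)])
        pos = np.array([1_000_000 + 20_000_000 * (j // 22) for j in range(m)])
    else:
        bsize, br2 = c.ld_blocks
        block = np.arange(m) // bsize
        chrom = np.array([str(1 + (b % 22)) for b in block])
        within = np.arange(m) % bsize
        pos = 1_000_000 + 50_000_000 * (block // 22) + 100_000 * within

    maf = rng.uniform(c.maf_range[0], c.maf_range[1], m)
    pal = rng.random(m) < c.palindromic_frac
    pair_idx = rng.integers(0, 8, m)
    pal_idx = rng.integers(0, 4, m)
    ea = np.where(pal, [ _PALINDROMIC_PAIRS[i][0] for i in pal_idx],
                  [_NONPALINDROMIC_PAIRS[i][0] for i in pair_idx])
    oa = np.where(pal, [ _PALINDROMIC_PAIRS[i][1] for i in pal_idx],
                  [_NONPALINDROMIC_PAIRS[i][1] for i in pair_idx])

    gamma = rng.normal(0.0, c.gamma_sd, m)
    delta = rng.normal(0.0, c.med_gamma_sd, m)
    pleio = np.zeros(m)
    if c.pleiotropy != "none" and c.prop_invalid > 0:
        invalid = rng.random(m) < c.prop_invalid
        mean = c.pleiotropy_mean if c.pleiotropy == "directional" else 0.0
        draw = rng.normal(mean, c.pleiotropy_sd, m)
        # orient pleiotropy to the exposure-increasing allele so a directional
        # mean survives MR-Egger's beta_exp >= 0 orientation
        pleio = np.where(invalid, np.where(gamma < 0, -draw, draw), 0.0)

    true_exp = gamma
    true_med = c.true_alpha * gamma + delta
    true_out = c.true_beta1 * gamma + c.true_beta2 * true_med + pleio

    tables = {}
    for name, truth, n in (
        ("exposure", true_exp, c.n_exp),
        ("mediator", true_med, c.n_med),
        ("outcome", true_out, c.n_out),
    ):
        se = _se_scaling(n, maf)
        beta = truth + rng.normal(0.0, 1.0, m) * se
        tables[name] = _records(ids, chrom, pos, ea, oa, maf, beta, se, n)

    ld = None
    if c.ld_blocks is not None:
        bsize, br2 = c.ld_blocks
        block = np.arange(m) // bsize
        r2 = np.where(block[:, None] == block[None, :], br2, 0.0)
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(snp_ids=ids, r2=r2)

    truth = c.to_dict()
    truth["total_effect"] = c.total_effect
    return SyntheticDataset(
        exposure=tables["exposure"],
        mediator=tables["mediator"],
        outcome=tables["outcome"],
        ld=ld,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the three GWAS TSVs, optional LD TSV and a truth YAML; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, recs in (("exposure", ds.exposure), ("mediator", ds.mediator), ("outcome", ds.outcome)):
        p = out_dir / f"{name}.tsv"
        write_sumstats(recs, p)
        paths[name] = p
    if ds.ld is not None:
        p = out_dir / "ld.tsv"
        ds.ld.write_tsv(p)
        paths["ld"] = p
    p = out_dir / "truth.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(ds.truth, fh, sort_keys=True)
    paths["truth"] = p
    return paths


# ----------------------------------------------------------------------------
# Named study conditions (documented in docs/methods.md)
# ----------------------------------------------------------------------------

def study_scale_config(**kw) -> SimulationConfig:
    """Default study-scale conditions: F ~ 20 instruments, mediation chain truth."""
    return SimulationConfig(**kw)


def null_config(**kw) -> SimulationConfig:
    """All causal effects zero; instruments still predict the exposure."""
    base = dict(true_alpha=0.0, true_beta2=0.0, true_beta1=0.0)
    base.update(kw)
    return SimulationConfig(**base)


def balanced_pleiotropy_null_config(**kw) -> SimulationConfig:
    """Zero-mean pleiotropy on every instrument (InSIDE holds): Egger null."""
    base = dict(
        true_alpha=0.0, true_beta2=0.0, true_beta1=0.0,
        pleiotropy="balanced", prop_invalid=1.0, pleiotropy_sd=0.01,
        gamma_sd=0.15, med_gamma_sd=0.15,
    )
    base.update(kw)
    return SimulationConfig(**base)


def strong_chain_config(**kw) -> SimulationConfig:
    """Mediation chain with strong instruments (estimator-property regime)."""
    base = dict(gamma_sd=0.15, med_gamma_sd=0.15)
    base.update(kw)
    return SimulationConfig(**base)


def paper_scale_effect_config(**kw) -> SimulationConfig:
    """Small total effect (~0.03) at study-scale instrument strength.

    Reproduces the qualitative variance-explained pattern of the real
    screen: exposure r2 of order 1e-2 against an outcome r2 orders of
    magnitude smaller.  The mediator -> outcome path is kept weak so the
    outcome's per-SNP signal stays below its sampling noise; note the
    z-based r2 has a chi-square noise floor of about nsnp/n_outcome.
    """
    base = dict(true_alpha=0.2, true_beta2=0.05, true_beta1=0.02)
    base.update(kw)
    return SimulationConfig(**base)
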