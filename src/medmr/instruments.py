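"""Instrumental-variable selection for two-sample MR.

Candidate instruments are chosen from the exposure GWAS by a p-value
threshold (strict ``<``, default 1e-5), pruned for linkage disequilibrium by
greedy clumping (r-squared < 0.001 within a 10,000 kb window by default), and
screened for strength by the per-SNP F statistic, F = (beta/se)^2, with
F < 10 conventionally flagging weak instruments.

The clumping step normally runs against a population LD reference.  Here an
LD matrix may be supplied explicitly (square TSV, unit diagonal); when it is
absent, any pair of candidates on the same chromosome within the window is
treated as linked and only the most significant survives (distance-only
pruning — deliberately conservative, and loudly not equivalent to
reference-panel clumping).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import SumStatRecord


@dataclass
class LDMatrix:
    """Pairwise r-squared between SNPs; symmetric with unit diagonal."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise ValueError("LD matrix dimensions do not match snp_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("LD matrix diagonal must be exactly 1")
        if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
            raise ValueError("LD r-squared values must lie in [0,1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise ValueError(f"SNP {exc.args[0]!r} missing from LD matrix") from None

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(snp_ids=list(df.columns), r2=df.to_numpy(dtype=float))

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(path, sep="\t")


@dataclass
class InstrumentSet:
    """Selected instruments with per-SNP F statistics and an audit log."""

    records: list[SumStatRecord]
    f_stats: np.ndarray
    selection_log: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.f_stats = np.asarray(self.f_stats, dtype=float)
        if len(self.f_stats) != len(self.records):
            raise ValueError("f_stats must align 1:1 with records")

    @property
    def nsnp(self) -> int:
        return len(self.records)

    def f_summary(self) -> tuple[float, float, float]:
        return summarize_f(self)

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.selection_log, columns=["snp", "action", "reason"])

    def write_log(self, path: str | Path) -> None:
        self.log_frame().to_csv(path, sep="\t", index=False)


def select_by_pvalue(
    records: list[SumStatRecord],
    threshold: float = 1e-5,
    log: list | None = None,
) -> list[SumStatRecord]:
    """Keep records with pval strictly below ``threshold``, in original order."""
    if not 0 < threshold <= 1:
        raise ValueError("p-value threshold must be in (0,1]")
    kept = []
    for r in records:
        if r.pval < threshold:
            kept.append(r)
        elif log is not None:
            log.append((r.snp_id, "excluded", f"pval {r.pval:.3g} >= {threshold:.3g}"))
    return kept


def _within_window(a: SumStatRecord, b: SumStatRecord, window_bp: float) -> bool:
    if a.chrom is None or b.chrom is None or a.pos is None or b.pos is None:
        return True  # position unknown: treat as potentially linked
    return a.chrom == b.chrom and abs(a.pos - b.pos) <= window_bp


def ld_clump(
    records: list[SumStatRecord],
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
    log: list | None = None,
) -> list[SumStatRecord]:
    """Greedy LD clumping: accept SNPs in ascending p-value order.

    A candidate is accepted iff, against every already-accepted SNP, being on
    the same chromosome within the window implies r-squared below the
    threshold.  Without an LD matrix any same-chromosome pair within the
    window counts as linked.  Ties in p-value break on lexicographic snp id,
    making the output independent of input row order.
    """
    if not 0 <= r2_threshold <= 1:
        raise ValueError("r2_threshold must be in [0,1]")
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    if ld is None:
        for r in records:
            if r.chrom is None or r.pos is None:
                raise ValueError(
                    f"distance-only clumping requires chrom/pos on every record ({r.snp_id})"
                )
    window_bp = window_kb * 1000.0
    ordered = sorted(records, key=lambda r: (r.pval, r.snp_id))
    accepted: list[SumStatRecord] = []
    for cand in ordered:
        clash = None
        for kept in accepted:
            if not _within_window(cand, kept, window_bp):
                continue
            if ld is None or ld.lookup(cand.snp_id, kept.snp_id) >= r2_threshold:
                clash = kept
                break
        if clash is None:
            accepted.append(cand)
        elif log is not None:
            log.append((cand.snp_id, "excluded", f"linked to {clash.snp_id}"))
    return accepted


def f_statistic(record: SumStatRecord, method: str = "ratio") -> float:
    """Per-SNP instrument-strength F statistic.

    ``"ratio"`` (default): F = (beta/se)^2, the squared Wald z.  ``"r2"``:
    F = r2 (n-2) / (1 - r2) with r2 = 2 maf (1-maf) beta^2, the variance
    explained under a standardized-trait approximation; requires eaf and n.
    """
    if record.se <= 0:
        raise ValueError("se must be positive")
    if method == "ratio":
        return float((record.beta / record.se) ** 2)
    if method == "r2":
        if record.eaf is None or record.n is None:
            raise ValueError("r2-based F requires eaf and n")
        maf = min(record.eaf, 1 - record.eaf)
        r2 = 2 * maf * (1 - maf) * record.beta**2
        if r2 >= 1:
            raise ValueError("implied r2 >= 1; beta not on a standardized scale")
        return float(r2 * (record.n - 2) / (1 - r2))
    raise ValueError(f"unknown F-statistic method {method!r}")


def filter_weak(instruments: InstrumentSet, f_min: float = 10.0) -> InstrumentSet:
    """Retain instruments with F >= ``f_min`` (the boundary value is kept)."""
    if f_min < 0:
        raise ValueError("f_min must be non-negative")
    keep = instruments.f_stats >= f_min
    log = list(instruments.selection_log)
    for r, f, k in zip(instruments.records, instruments.f_stats, keep):
        if not k:
            log.append((r.snp_id, "excluded", f"weak instrument F={f:.3f} < {f_min:g}"))
    if not keep.any():
        raise ValueError("no instruments survive strength filter")
    return InstrumentSet(
        records=[r for r, k in zip(instruments.records, keep) if k],
        f_stats=instruments.f_stats[keep],
        selection_log=log,
    )


def summarize_f(instruments: InstrumentSet) -> tuple[float, float, float]:
    """(median, min, max) of the per-SNP F statistics."""
    if instruments.nsnp < 1:
        raise ValueError("at least one instrument required")
    f = instruments.f_stats
    return float(np.median(f)), float(f.min()), float(f.max())


def select_instruments(
    records: list[SumStatRecord],
    p_threshold: float = 1e-5,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
    f_min: float = 10.0,
    f_method: str = "ratio",
) -> InstrumentSet:
    """Full selection pipeline: p-threshold, LD clump, weak-instrument filter."""
    log: list[tuple[str, str, str]] = []
    sig = select_by_pvalue(records, p_threshold, log=log)
    clumped = ld_clump(sig, ld=ld, r2_threshold=r2_threshold, window_kb=window_kb, log=log)
    if not clumped:
        raise ValueError("no instruments remain after p-value selection and clumping")
    inst = InstrumentSet(
        records=clumped,
        f_stats=np.array([f_statistic(r, method=f_method) for r in clumped]),
        selection_log=log,
    )
    return filter_weak(inst, f_min=f_min)
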