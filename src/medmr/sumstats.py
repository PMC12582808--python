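"""GWAS summary-statistic records, file I/O and allele harmonization.

Two-sample Mendelian randomization works entirely from per-SNP association
summaries: for every variant, an effect allele, the other allele, the
per-allele effect (log odds ratio for binary traits), its standard error,
p-value and, optionally, the effect-allele frequency and sample size.

Before any estimator can combine an exposure GWAS with an outcome GWAS, the
two tables must be expressed on a common effect-allele convention.
:func:`harmonize` implements the standard rules: align the outcome to the
exposure's effect allele (flipping the sign of the outcome beta and
complementing its frequency when the labels are swapped), resolve strand
flips via base complement, and drop palindromic (A/T, C/G) variants whose
orientation cannot be established from allele frequency.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column names, as written by :func:`write_sumstats`
DEFAULT_COLUMN_MAP = {
    "snp": "snp",
    "chr": "chrom",
    "pos": "pos",
    "ea": "effect_allele",
    "oa": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

REQUIRED_KEYS = ("snp", "ea", "oa", "beta", "se", "pval")

#: reasons a SNP can be dropped during harmonization
DROP_REASONS = ("allele_mismatch", "palindromic_ambiguous", "missing_in_outcome", "duplicate")


class SumStatError(ValueError):
    """Fatal problem with a summary-statistics file or harmonization run."""


@dataclass
class SumStatRecord:
    """One SNP's association summary for one trait."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None
    chrom: str | None = None
    pos: int | None = None

    def problems(self) -> list[str]:
        """Return invariant violations as human-readable strings (empty if valid)."""
        out = []
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            out.append("invalid allele")
        elif self.effect_allele == self.other_allele:
            out.append("effect and other allele identical")
        if not np.isfinite(self.beta):
            out.append("non-finite beta")
        if not (np.isfinite(self.se) and self.se > 0):
            out.append("nonpositive se")
        if not (np.isfinite(self.pval) and 0 < self.pval <= 1):
            out.append("pval outside (0,1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            out.append("eaf outside (0,1)")
        if self.pos is not None and self.pos < 0:
            out.append("negative position")
        if self.n is not None and self.n <= 0:
            out.append("nonpositive n")
        return out

    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand cannot be read off the labels."""
        return COMPLEMENT.get(self.effect_allele) == self.other_allele


@dataclass
class HarmonizedSet:
    """Per-SNP aligned exposure/outcome effects sharing the exposure's effect allele."""

    snp_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    eaf: np.ndarray | None = None
    n_exp: int | None = None
    n_out: int | None = None
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def nsnp(self) -> int:
        return len(self.snp_ids)

    def subset(self, indices) -> "HarmonizedSet":
        idx = np.asarray(indices)
        return HarmonizedSet(
            snp_ids=[self.snp_ids[i] for i in idx],
            beta_exp=self.beta_exp[idx],
            se_exp=self.se_exp[idx],
            beta_out=self.beta_out[idx],
            se_out=self.se_out[idx],
            eaf=None if self.eaf is None else self.eaf[idx],
            n_exp=self.n_exp,
            n_out=self.n_out,
            dropped=[],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "snp": self.snp_ids,
                "beta_exp": self.beta_exp,
                "se_exp": self.se_exp,
                "beta_out": self.beta_out,
                "se_out": self.se_out,
            }
        )
        if self.eaf is not None:
            df["eaf"] = self.eaf
        return df

    def write(self, path: str | Path) -> None:
        """Write the harmonized table as TSV with a ``.droplog.tsv`` sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        log = pd.DataFrame(self.dropped, columns=["snp", "reason"])
        log.to_csv(path.with_suffix(path.suffix + ".droplog.tsv"), sep="\t", index=False)


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_sumstats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    trait_label: str = "",
    max_bad_fraction: float = 0.10,
) -> list[SumStatRecord]:
    """Read and validate a GWAS summary-statistics table (TSV or CSV).

    Parameters
    ----------
    path : file path
        Delimited text with a header row; tab or comma, auto-detected.
    column_map : dict
        Maps the logical keys ``snp, chr, pos, ea, oa, eaf, beta, se, pval, n``
        to the file's column names.  Defaults to the canonical names used by
        :func:`write_sumstats`.
    trait_label : str
        Used only to make log messages attributable.
    max_bad_fraction : float
        Abort if more than this fraction of data rows fails validation.

    Rows violating the per-record invariants are reported (with row numbers)
    as warnings and excluded; alleles are uppercased on read.
    """
    path = Path(path)
    if not path.exists():
        raise SumStatError(f"summary-statistics file not found: {path}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise SumStatError(f"{path}: no data rows")
    for key in REQUIRED_KEYS:
        if cmap[key] not in df.columns:
            raise SumStatError(f"{path}: mapped column {cmap[key]!r} (for {key!r}) not present")
    have = {k: cmap[k] for k in cmap if cmap[k] in df.columns}

    records: list[SumStatRecord] = []
    errors: list[tuple[int, str]] = []

    def _float(row, key):
        raw = row.get(have[key]) if key in have else None
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
            return None
        return float(raw)

    for i, row in enumerate(df.to_dict("records"), start=2):  # 1-based incl. header
        try:
            rec = SumStatRecord(
                snp_id=str(row[have["snp"]]).strip(),
                effect_allele=str(row[have["ea"]]).strip().upper(),
                other_allele=str(row[have["oa"]]).strip().upper(),
                beta=_float(row, "beta"),
                se=_float(row, "se"),
                pval=_float(row, "pval"),
                eaf=_float(row, "eaf") if "eaf" in have else None,
                n=(int(v) if (v := _float(row, "n")) is not None else None) if "n" in have else None,
                chrom=str(row[have["chr"]]).strip() if "chr" in have and not pd.isna(row[have["chr"]]) else None,
                pos=(int(v) if (v := _float(row, "pos")) is not None else None) if "pos" in have else None,
            )
        except (TypeError, ValueError):
            errors.append((i, "unparseable numeric field"))
            continue
        if rec.beta is None or rec.se is None or rec.pval is None:
            errors.append((i, "missing required numeric field"))
            continue
        probs = rec.problems()
        if probs:
            errors.append((i, "; ".join(probs)))
            continue
        records.append(rec)

    total = len(df)
    if errors and len(errors) > max_bad_fraction * total:
        detail = "; ".join(f"row {r}: {msg}" for r, msg in errors[:5])
        raise SumStatError(
            f"{path} ({trait_label}): {len(errors)}/{total} rows failed validation ({detail} ...)"
        )
    for r, msg in errors:
        logger.warning("%s (%s) row %d rejected: %s", path.name, trait_label, r, msg)
    dup = [s for s, c in Counter(r.snp_id for r in records).items() if c > 1]
    if dup:
        logger.warning("%s (%s): duplicate snp ids flagged: %s", path.name, trait_label, dup[:10])
    return records


def write_sumstats(records: list[SumStatRecord], path: str | Path) -> None:
    """Write records as a canonical tab-separated table (lossless round trip)."""
    pd.DataFrame(
        {
            "snp": [r.snp_id for r in records],
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "eaf": [r.eaf for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "pval": [r.pval for r in records],
            "n": [r.n for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def _orientation(exp: SumStatRecord, out: SumStatRecord) -> str | None:
    """How the outcome record's alleles relate to the exposure's.

    Returns ``"same"``, ``"flip"`` (labels swapped, so the outcome beta refers
    to the exposure's other allele) or ``None`` when the alleles cannot be
    reconciled even after strand complement.
    """
    ea, oa = exp.effect_allele, exp.other_allele
    pair = (out.effect_allele, out.other_allele)
    if pair == (ea, oa):
        return "same"
    if pair == (oa, ea):
        return "flip"
    comp = (COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele])
    if comp == (ea, oa):
        return "same"
    if comp == (oa, ea):
        return "flip"
    return None


def harmonize(
    exposure: list[SumStatRecord],
    outcome: list[SumStatRecord],
    palindromic_eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect-allele convention.

    Join key is the SNP id.  Swapped allele labels flip the outcome beta sign
    and complement its frequency; strand flips (A<->T, C<->G on both alleles)
    are complemented before alignment.  Palindromic variants are retained only
    when both effect-allele frequencies are available, both lie outside
    ``[0.5 - w, 0.5 + w]``, and they agree on the minor allele after label
    alignment; otherwise they are dropped as ``palindromic_ambiguous``
    (conservative: frequency missing on either side also drops).
    """
    if not exposure or not outcome:
        raise SumStatError("harmonize requires non-empty exposure and outcome record lists")
    w = palindromic_eaf_window
    out_by_id: dict[str, SumStatRecord] = {}
    for rec in outcome:
        out_by_id.setdefault(rec.snp_id, rec)

    ids, bx, sx, by, so, eafs = [], [], [], [], [], []
    dropped: list[tuple[str, str]] = []
    seen: set[str] = set()
    for e in exposure:
        if e.snp_id in seen:
            dropped.append((e.snp_id, "duplicate"))
            continue
        seen.add(e.snp_id)
        o = out_by_id.get(e.snp_id)
        if o is None:
            dropped.append((e.snp_id, "missing_in_outcome"))
            continue
        orient = _orientation(e, o)
        if orient is None:
            dropped.append((e.snp_id, "allele_mismatch"))
            continue
        if e.is_palindromic():
            if e.eaf is None or o.eaf is None:
                dropped.append((e.snp_id, "palindromic_ambiguous"))
                continue
            eaf_out = 1.0 - o.eaf if orient == "flip" else o.eaf
            inside = abs(e.eaf - 0.5) <= w or abs(eaf_out - 0.5) <= w
            agree = (e.eaf - 0.5) * (eaf_out - 0.5) > 0
            if inside or not agree:
                dropped.append((e.snp_id, "palindromic_ambiguous"))
                continue
        ids.append(e.snp_id)
        bx.append(e.beta)
        sx.append(e.se)
        by.append(-o.beta if orient == "flip" else o.beta)
        so.append(o.se)
        eafs.append(np.nan if e.eaf is None else e.eaf)
    if not ids:
        counts = Counter(reason for _, reason in dropped)
        raise SumStatError(f"no SNPs survive harmonization (drops: {dict(counts)})")

    def _median_n(recs, kept):
        ns = [r.n for r in recs if r.snp_id in kept and r.n is not None]
        return int(np.median(ns)) if ns else None

    kept = set(ids)
    eaf_arr = np.array(eafs, dtype=float)
    return HarmonizedSet(
        snp_ids=ids,
        beta_exp=np.array(bx, dtype=float),
        se_exp=np.array(sx, dtype=float),
        beta_out=np.array(by, dtype=float),
        se_out=np.array(so, dtype=float),
        eaf=None if np.all(np.isnan(eaf_arr)) else eaf_arr,
        n_exp=_median_n(exposure, kept),
        n_out=_median_n(outcome, kept),
        dropped=dropped,
    )
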