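"""Reading, validating and harmonizing summary-statistic tables."""

import numpy as np
import pytest

from medmr.sumstats import (
    SumStatError,
    SumStatRecord,
    harmonize,
    read_sumstats,
    write_sumstats,
)

from conftest import make_record


def _write_tsv(path, rows, header="snp\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn"):
    path.write_text("\n".join([header] + rows) + "\n")


class TestReadSumstats:
    def test_wellformed_tsv_roundtrip(self, tmp_path):
        recs = [make_record(snp_id=f"rs{i}", beta=0.1 * (i + 1)) for i in range(3)]
        p = tmp_path / "x.tsv"
        write_sumstats(recs, p)
        back = read_sumstats(p)
        assert back == recs

    def test_invalid_rows_rejected_with_reason(self, tmp_path, caplog):
        rows = [f"rs{i}\t1\t{1000 + i}\tA\tG\t0.3\t0.1\t0.01\t1e-6\t5000" for i in range(10)]
        rows.append("rsbad\t1\t2000\tA\tG\t0.3\t0.1\t0\t1e-6\t5000")  # se = 0
        p = tmp_path / "x.tsv"
        _write_tsv(p, rows)
        with caplog.at_level("WARNING"):
            recs = read_sumstats(p)
        assert len(recs) == 10
        assert any("nonpositive se" in m for m in caplog.messages)

    def test_aborts_when_too_many_rows_fail(self, tmp_path):
        rows = [
            "rs1\t1\t1000\tA\tG\t0.3\t0.1\t0.01\t1e-6\t5000",
            "rs2\t1\t2000\tA\tG\t0.3\tnot_a_number\t0.01\t1e-6\t5000",
            "rs3\t1\t3000\tA\tG\t0.3\t0.1\t-1\t1e-6\t5000",
        ]
        p = tmp_path / "x.tsv"
        _write_tsv(p, rows)
        with pytest.raises(SumStatError, match="failed validation"):
            read_sumstats(p)

    def test_csv_with_custom_column_map_matches_tsv(self, tmp_path):
        # same records, comma-delimited, renamed and reordered columns
        p = tmp_path / "x.csv"
        p.write_text(
            "P,SE,BETA,A2,A1,RSID,FREQ\n"
            "1e-6,0.01,0.1,G,A,rs1,0.3\n"
            "1e-7,0.02,-0.2,T,C,rs2,0.45\n"
        )
        recs = read_sumstats(
            p,
            column_map={"snp": "RSID", "ea": "A1", "oa": "A2", "eaf": "FREQ",
                        "beta": "BETA", "se": "SE", "pval": "P"},
        )
        expect = [
            SumStatRecord("rs1", "A", "G", 0.1, 0.01, 1e-6, eaf=0.3),
            SumStatRecord("rs2", "C", "T", -0.2, 0.02, 1e-7, eaf=0.45),
        ]
        assert recs == expect

    def test_missing_mapped_column_is_fatal(self, tmp_path):
        p = tmp_path / "x.tsv"
        _write_tsv(p, ["rs1\t1\t1\tA\tG\t0.3\t0.1\t0.01\t1e-6\t10"])
        with pytest.raises(SumStatError, match="not present"):
            read_sumstats(p, column_map={"beta": "nope"})

    def test_empty_file_is_fatal(self, tmp_path):
        p = tmp_path / "x.tsv"
        _write_tsv(p, [])
        with pytest.raises(SumStatError, match="no data rows"):
            read_sumstats(p)

    def test_alleles_uppercased(self, tmp_path):
        p = tmp_path / "x.tsv"
        _write_tsv(p, ["rs1\t1\t1\ta\tg\t0.3\t0.1\t0.01\t1e-6\t10"])
        (rec,) = read_sumstats(p)
        assert (rec.effect_allele, rec.other_allele) == ("A", "G")


class TestHarmonize:
    def test_matching_alleles_retained_unchanged(self):
        e = [make_record(ea="A", oa="G", beta=0.1)]
        o = [make_record(ea="A", oa="G", beta=0.2, se=0.05)]
        h = harmonize(e, o)
        assert h.snp_ids == ["rs1"]
        assert h.beta_out[0] == pytest.approx(0.2)

    def test_swapped_alleles_flip_outcome_sign(self):
        e = [make_record(ea="A", oa="G", beta=0.1)]
        o = [make_record(ea="G", oa="A", beta=0.2, se=0.05, eaf=0.7)]
        h = harmonize(e, o)
        assert h.beta_out[0] == pytest.approx(-0.2)

    def test_strand_flip_resolved_by_complement(self):
        e = [make_record(ea="A", oa="G", beta=0.1)]
        o = [make_record(ea="T", oa="C", beta=0.2, se=0.05)]  # other strand, same order
        h = harmonize(e, o)
        assert h.beta_out[0] == pytest.approx(0.2)

    def test_palindromic_at_half_frequency_always_ambiguous(self):
        e = [make_record(ea="A", oa="T", beta=0.1, eaf=0.5)]
        o = [make_record(ea="A", oa="T", beta=0.2, se=0.05, eaf=0.3)]
        for w in (0.001, 0.08, 0.2):
            with pytest.raises(SumStatError):
                harmonize(e, o, palindromic_eaf_window=w)

    def test_mixed_six_snp_fixture(self):
        # hand-enumerated: aligned / swapped / strand-flipped retained;
        # near-0.5 palindromic, allele mismatch and absent SNP dropped
        e = [
            make_record("s1", "A", "G", beta=0.10, eaf=0.3),
            make_record("s2", "C", "T", beta=0.20, eaf=0.4),
            make_record("s3", "A", "G", beta=0.30, eaf=0.2),
            make_record("s4", "A", "T", beta=0.40, eaf=0.48),
            make_record("s5", "A", "G", beta=0.50, eaf=0.3),
            make_record("s6", "A", "G", beta=0.60, eaf=0.3),
        ]
        o = [
            make_record("s1", "A", "G", beta=1.0, se=0.1, eaf=0.3),
            make_record("s2", "T", "C", beta=2.0, se=0.1, eaf=0.6),
            make_record("s3", "T", "C", beta=3.0, se=0.1, eaf=0.8),
            make_record("s4", "A", "T", beta=4.0, se=0.1, eaf=0.48),
            make_record("s5", "A", "C", beta=5.0, se=0.1, eaf=0.3),
        ]
        h = harmonize(e, o, palindromic_eaf_window=0.08)
        assert h.snp_ids == ["s1", "s2", "s3"]
        assert h.beta_out == pytest.approx([1.0, -2.0, 3.0])
        assert dict(h.dropped) == {
            "s4": "palindromic_ambiguous",
            "s5": "allele_mismatch",
            "s6": "missing_in_outcome",
        }

    def test_palindromic_oriented_by_agreeing_minor_allele(self):
        e = [make_record("s1", "A", "T", beta=0.1, eaf=0.2)]
        o = [make_record("s1", "A", "T", beta=0.3, se=0.1, eaf=0.25)]
        h = harmonize(e, o)
        assert h.beta_out[0] == pytest.approx(0.3)
        # disagreeing minor allele is dropped, not flipped (conservative)
        o_bad = [make_record("s1", "A", "T", beta=0.3, se=0.1, eaf=0.75)]
        with pytest.raises(SumStatError):
            harmonize(e, o_bad)

    def test_duplicate_exposure_ids_dropped(self):
        e = [make_record("s1", beta=0.1), make_record("s1", beta=0.2),
             make_record("s2", beta=0.3)]
        o = [make_record("s1", beta=1.0, se=0.1), make_record("s2", beta=2.0, se=0.1)]
        h = harmonize(e, o)
        assert h.snp_ids == ["s1", "s2"]
        assert ("s1", "duplicate") in h.dropped

    def test_every_exposure_snp_accounted_for(self):
        rng = np.random.default_rng(11)
        e = [make_record(f"s{i}", beta=rng.normal()) for i in range(20)]
        o = [make_record(f"s{i}", beta=rng.normal(), se=0.1) for i in range(5, 25)]
        h = harmonize(e, o)
        assert h.nsnp + len(h.dropped) == len(e)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        e = [make_record(f"s{i}", ea="A", oa="G", beta=rng.normal(), eaf=0.3)
             for i in range(6)]
        o = [make_record(f"s{i}", ea="G", oa="A", beta=rng.normal(), se=0.1, eaf=0.7)
             for i in range(6)]
        h1 = harmonize(e, o)
        # re-express the harmonized outcome as records on the exposure convention
        o2 = [
            make_record(s, ea="A", oa="G", beta=b, se=se, eaf=0.3)
            for s, b, se in zip(h1.snp_ids, h1.beta_out, h1.se_out)
        ]
        h2 = harmonize(e, o2)
        assert h2.snp_ids == h1.snp_ids
        assert h2.beta_out == pytest.approx(h1.beta_out)

    def test_sign_equivariance_under_outcome_label_flip(self):
        rng = np.random.default_rng(7)
        pairs = [("A", "G"), ("C", "T"), ("G", "T"), ("A", "C")]
        e, o, o_flipped = [], [], []
        for i in range(12):
            ea, oa = pairs[i % 4]
            b = rng.normal()
            e.append(make_record(f"s{i}", ea=ea, oa=oa, beta=rng.normal(), eaf=0.3))
            o.append(make_record(f"s{i}", ea=ea, oa=oa, beta=b, se=0.1, eaf=0.4))
            o_flipped.append(make_record(f"s{i}", ea=oa, oa=ea, beta=-b, se=0.1, eaf=0.6))
        h1 = harmonize(e, o)
        h2 = harmonize(e, o_flipped)
        assert h1.beta_out == pytest.approx(h2.beta_out)

    def test_zero_survivors_fatal_with_drop_counts(self):
        e = [make_record("s1")]
        o = [make_record("s2", se=0.1)]
        with pytest.raises(SumStatError, match="missing_in_outcome"):
            harmonize(e, o)

    def test_harmonized_write_with_droplog(self, tmp_path):
        e = [make_record("s1"), make_record("s2")]
        o = [make_record("s1", beta=0.5, se=0.1)]
        h = harmonize(e, o)
        out = tmp_path / "h.tsv"
        h.write(out)
        assert out.exists()
        assert "missing_in_outcome" in out.with_suffix(".tsv.droplog.tsv").read_text()
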