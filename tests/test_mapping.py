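import numpy as np
import pandas as pd
import pytest

from sexlink import (FormatError, SdrInterval, chromosome_counts,
                     filter_and_assign, loci_in_region, read_blast_tab,
                     sdr_interval, write_karyotype_bed)
from sexlink.mapping import read_karyotype_bed, region_percent


def _hit(query="L1", subject="chr9", ident=99.0, length=69, sstart=1000,
         send=1068, evalue=1e-30, bits=130.0):
    return "\t".join(map(str, [query, subject, ident, length, 1, 0, 1, 69,
                               sstart, send, evalue, bits]))


def _hits_df(lines, tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text("\n".join(lines) + "\n" if lines else "")
    return read_blast_tab(p)


class TestReadBlastTab:
    def test_canonical_line(self, tmp_path):
        hits = _hits_df([_hit()], tmp_path)
        assert len(hits) == 1
        assert hits.loc[0, "subject_id"] == "chr9"
        assert hits.loc[0, "strand"] == "+"

    def test_minus_strand_normalized(self, tmp_path):
        hits = _hits_df([_hit(sstart=500, send=400)], tmp_path)
        assert hits.loc[0, "strand"] == "-"
        assert (hits.loc[0, "s_lo"], hits.loc[0, "s_hi"]) == (400, 500)

    def test_empty_file(self, tmp_path):
        assert len(_hits_df([], tmp_path)) == 0

    def test_malformed_line_numbered(self, tmp_path):
        with pytest.raises(FormatError, match="line 2"):
            _hits_df([_hit(), "only\tthree\tcols"], tmp_path)


class TestFilterAndAssign:
    def test_strict_thresholds(self, tmp_path):
        hits = _hits_df([
            _hit(query="keep", ident=96.0, length=70),
            _hit(query="low_ident", ident=94.9, length=200),
            _hit(query="short", ident=99.0, length=65),
        ], tmp_path)
        asn = filter_and_assign(hits)
        assert list(asn.placed.index) == ["keep"]
        assert sorted(asn.unplaced) == ["low_ident", "short"]

    def test_best_bitscore_wins(self, tmp_path):
        hits = _hits_df([
            _hit(subject="chrA", bits=120.0),
            _hit(subject="chrB", bits=110.0),
        ], tmp_path)
        asn = filter_and_assign(hits)
        assert asn.placed.loc["L1", "chromosome"] == "chrA"

    def test_tie_break_cascade(self, tmp_path):
        hits = _hits_df([
            _hit(subject="chrA", bits=120.0, evalue=1e-20),
            _hit(subject="chrB", bits=120.0, evalue=1e-30),
        ], tmp_path)
        asn = filter_and_assign(hits)
        assert asn.placed.loc["L1", "chromosome"] == "chrB"
        # equal e-values too → longer alignment, then subject id
        hits = _hits_df([
            _hit(subject="chrB", bits=120.0, length=69),
            _hit(subject="chrA", bits=120.0, length=69),
        ], tmp_path)
        assert filter_and_assign(hits).placed.loc["L1", "chromosome"] == "chrA"

    def test_position_is_midpoint(self, tmp_path):
        hits = _hits_df([_hit(sstart=100, send=168)], tmp_path)
        asn = filter_and_assign(hits)
        assert asn.placed.loc["L1", "position"] == 134


class TestChromosomeCounts:
    def test_reconstructs_planted_design(self, tmp_path):
        # 71 specific on chr9, 1 on chr7, 1 on chr19 — the study layout
        lines = [_hit(query=f"S{i}", subject="chr9") for i in range(71)]
        lines += [_hit(query="S71", subject="chr7"),
                  _hit(query="S72", subject="chr19")]
        asn = filter_and_assign(_hits_df(lines, tmp_path))
        tiers = pd.Series("specific", index=[f"S{i}" for i in range(73)])
        counts = chromosome_counts(asn, tiers)
        table = counts.set_index("chromosome")["n_loci"]
        assert table["chr9"] == 71
        assert table["chr7"] == 1 and table["chr19"] == 1

    def test_unplaced_row(self, tmp_path):
        asn = filter_and_assign(_hits_df([_hit(query="A")], tmp_path))
        tiers = pd.Series({"A": "specific", "B": "linked_90"})
        counts = chromosome_counts(asn, tiers).set_index("chromosome")
        assert counts.loc["unplaced", "n_loci"] == 1

    def test_empty(self, tmp_path):
        asn = filter_and_assign(_hits_df([], tmp_path))
        assert len(chromosome_counts(asn, pd.Series(dtype=object))) == 0

    def test_off_chromosome_percentage(self):
        # 128 of 1033 male-linked loci lie off the candidate chromosome
        assert region_percent(128, 1033) == 12.391


class TestSdrInterval:
    def test_study_coordinates_span(self, tmp_path):
        hits = _hits_df([
            _hit(query="A", sstart=26285178 - 34, send=26285178 + 34),
            _hit(query="B", sstart=31930103 - 34, send=31930103 + 34),
        ], tmp_path)
        iv = sdr_interval(filter_and_assign(hits), "chr9")
        assert (iv.start, iv.end) == (26285178, 31930103)
        assert iv.span_bp == 5_644_926
        assert iv.span_mb == "5.6 Mb"

    def test_single_locus_span_one(self, tmp_path):
        iv = sdr_interval(filter_and_assign(_hits_df([_hit()], tmp_path)), "chr9")
        assert iv.span_bp == 1

    def test_min_max_arithmetic(self, tmp_path):
        lines = [_hit(query=q, sstart=p - 34, send=p + 34)
                 for q, p in [("A", 100), ("B", 250), ("C", 400)]]
        iv = sdr_interval(filter_and_assign(_hits_df(lines, tmp_path)), "chr9")
        assert (iv.start, iv.end, iv.span_bp) == (100, 400, 301)

    def test_order_and_duplicate_invariance(self, tmp_path):
        lines = [_hit(query=q, sstart=p - 34, send=p + 34)
                 for q, p in [("A", 400), ("B", 100), ("C", 400)]]
        iv = sdr_interval(filter_and_assign(_hits_df(lines, tmp_path)), "chr9")
        assert (iv.start, iv.end) == (100, 400)

    def test_no_loci_is_error(self, tmp_path):
        asn = filter_and_assign(_hits_df([], tmp_path))
        with pytest.raises(ValueError):
            sdr_interval(asn, "chr9")


class TestLociInRegion:
    def test_region_occupancy_percent(self):
        # 461 of the 905 chromosome-9 linked loci fall inside the region
        assert region_percent(461, 905) == 50.939

    def test_count_and_fraction(self, tmp_path):
        lines = [_hit(query=f"L{i}", sstart=p - 34, send=p + 34)
                 for i, p in enumerate([100, 200, 300, 5000])]
        asn = filter_and_assign(_hits_df(lines, tmp_path))
        iv = SdrInterval("chr9", 50, 350, n_loci=3)
        count, frac = loci_in_region(asn, iv)
        assert count == 3
        assert frac == pytest.approx(0.75)

    def test_whole_chromosome_fraction_one(self, tmp_path):
        asn = filter_and_assign(_hits_df([_hit()], tmp_path))
        iv = SdrInterval("chr9", 1, 10**9, n_loci=1)
        assert loci_in_region(asn, iv) == (1, 1.0)

    def test_empty_overlap(self, tmp_path):
        asn = filter_and_assign(_hits_df([_hit(sstart=966, send=1034)], tmp_path))
        assert loci_in_region(asn, SdrInterval("chr9", 1, 10, n_loci=0))[0] == 0


class TestBed:
    def test_zero_based_conversion_and_roundtrip(self, tmp_path):
        hits = _hits_df([_hit(sstart=26285178 - 34, send=26285178 + 34)],
                        tmp_path)
        asn = filter_and_assign(hits)
        bed = tmp_path / "k.bed"
        write_karyotype_bed(asn, bed)
        line = bed.read_text().strip().split("\t")
        assert (line[0], line[1], line[2]) == ("chr9", "26285177", "26285178")
        back = read_karyotype_bed(bed)
        assert back.loc["L1", "position"] == 26285178

    def test_unplaced_omitted(self, tmp_path):
        hits = _hits_df([_hit(query="good"), _hit(query="bad", ident=50.0)],
                        tmp_path)
        asn = filter_and_assign(hits)
        bed = tmp_path / "k.bed"
        write_karyotype_bed(asn, bed)
        assert len(bed.read_text().strip().splitlines()) == 1
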