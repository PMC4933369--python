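"""Coordinate model, interval algebra and file IO."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bmpchip.core import (
    GeneRecord,
    GenomicInterval,
    IntervalCollection,
    Peak,
    intersect_u,
    merge,
    normalize_chrom,
    read_bed,
    read_gene_table,
    read_supplementary_xlsx,
    subtract_u,
    write_bed,
    write_gene_table,
)

from .conftest import brute_force_overlapping, make_coll, random_coll


class TestDomainTypes:
    def test_interval_invariants(self):
        iv = GenomicInterval("chr2L", 100, 200)
        assert len(iv) == 100
        with pytest.raises(ValueError):
            GenomicInterval("chr2L", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr2L", -1, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 100)

    def test_half_open_overlap(self):
        a = GenomicInterval("chr2L", 100, 200)
        assert a.overlaps(GenomicInterval("chr2L", 199, 300))
        assert not a.overlaps(GenomicInterval("chr2L", 200, 300))
        assert not a.overlaps(GenomicInterval("chr3R", 150, 160))

    def test_peak_summit_must_lie_inside(self):
        iv = GenomicInterval("chr1", 100, 200)
        assert Peak(iv, 100).summit == 100
        with pytest.raises(ValueError):
            Peak(iv, 200)
        # midpoint fallback when no summit recorded
        assert Peak.from_interval(iv).summit == 150

    def test_gene_record_de_consistency(self):
        GeneRecord("g1", "chr2L", 5000, "+", "up", 0.001)
        with pytest.raises(ValueError):
            GeneRecord("g1", "chr2L", 5000, "+", "maybe")
        with pytest.raises(ValueError):
            GeneRecord("g1", "chr2L", 5000, "+", "up", 0.5)

    def test_collection_sorted(self, rng):
        coll = random_coll(rng, 50)
        keys = [(r.chrom, r.start, r.end) for r in coll.intervals()]
        assert keys == sorted(keys)


class TestBedIO:
    def test_parse_simple_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2L\t100\t200\n")
        coll = read_bed(p)
        assert coll.intervals() == [GenomicInterval("chr2L", 100, 200)]

    def test_inverted_coordinates_error_names_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2L\t100\t200\nchr2L\t200\t100\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(p)

    def test_too_few_columns_error(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2L\t100\n")
        with pytest.raises(ValueError, match="3 tab-separated"):
            read_bed(p)

    def test_random_records_round_trip(self, tmp_path, rng):
        coll = random_coll(rng, 100)
        out = tmp_path / "rt.bed"
        write_bed(coll, out)
        assert read_bed(out) == coll
        # byte-stable: a second write is identical
        out2 = tmp_path / "rt2.bed"
        write_bed(read_bed(out), out2)
        assert out.read_bytes() == out2.read_bytes()

    def test_summit_column_round_trip(self, tmp_path):
        peaks = IntervalCollection(
            [
                Peak(GenomicInterval("chr1", 100, 400, name="p1"), 250),
                Peak(GenomicInterval("chr2", 50, 90, name="p2"), 51),
            ]
        )
        out = tmp_path / "p.bed"
        write_bed(peaks, out)
        back = read_bed(out, summit_col=4)
        assert [r.summit for r in back.records] == [250, 51]


class TestGeneTable:
    def test_round_trip_preserves_de_counts(self, tmp_path, rng):
        statuses = ["up", "down", "not_de"]
        genes = [
            GeneRecord(
                f"g{i}", "chr2L", int(rng.integers(0, 10_000)),
                "+" if rng.random() < 0.5 else "-",
                statuses[rng.integers(3)],
            )
            for i in range(100)
        ]
        p = tmp_path / "genes.tsv"
        write_gene_table(genes, p)
        back = read_gene_table(p)
        assert len(back) == 100
        for s in statuses:
            assert sum(g.de_status == s for g in back) == sum(
                g.de_status == s for g in genes
            )

    def test_unknown_de_status_rejected(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text(
            "gene_id\tchrom\ttss\tstrand\tde_status\tadj_p\n"
            "g1\tchr2L\t5000\t+\tmaybe\t\n"
        )
        with pytest.raises(ValueError, match="maybe"):
            read_gene_table(p)

    def test_missing_column_listed(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("gene_id\tchrom\ttss\n" "g1\tchr2L\t5000\n")
        with pytest.raises(ValueError, match="strand"):
            read_gene_table(p)


class TestSupplementaryXlsx:
    @pytest.fixture
    def workbook(self, tmp_path):
        import pandas as pd

        path = tmp_path / "supp.xlsx"
        peaks = pd.DataFrame(
            {
                "Chromosome": ["chr2L"] * 3 + ["chr3R"] * 2,
                "Start": [101, 501, 901, 11, 51],
                "End": [200, 600, 1000, 40, 90],
                "Name": ["p1", "p2", "p3", "p4", "w"],
                "Summit": [150, 550, 950, 25, 70],
                "Zld overlap": [1, 0, 1, 0, 1],
            }
        )
        genes = pd.DataFrame(
            {
                "Gene": ["gA", "gB", "w", "tkv"],
                "Chromosome": ["chr2L"] * 4,
                "TSS": [1000, 2000, 3000, 4000],
                "Strand": ["+", "-", "+", "+"],
                "Direction": ["up", "down", "up", "down"],
            }
        )
        with pd.ExcelWriter(path) as xl:
            peaks.to_excel(xl, sheet_name="Brk 2-2.5h", index=False)
            genes.to_excel(xl, sheet_name="diff genes", index=False)
        return path

    def test_peak_sheet(self, workbook):
        coll = read_supplementary_xlsx(workbook, "Brk 2-2.5h", "peaks")
        assert len(coll) == 5
        rec = coll.records[0]
        # 1-based inclusive converted to 0-based half-open
        assert (rec.start, rec.end, rec.summit) == (100, 200, 149)
        assert ("Zld overlap", True) in rec.attrs

    def test_exclusion_list(self, workbook):
        coll = read_supplementary_xlsx(
            workbook, "Brk 2-2.5h", "peaks", exclude=("w", "tkv")
        )
        assert len(coll) == 4
        genes = read_supplementary_xlsx(
            workbook, "diff genes", "genes", exclude=("w", "tkv")
        )
        assert [g.gene_id for g in genes] == ["gA", "gB"]
        assert [g.de_status for g in genes] == ["up", "down"]

    def test_unknown_sheet_lists_available(self, workbook):
        with pytest.raises(ValueError, match="diff genes"):
            read_supplementary_xlsx(workbook, "nope", "peaks")


class TestIntervalAlgebra:
    def test_one_base_shared(self):
        a = make_coll([(100, 200)], chrom="chr2L")
        b = make_coll([(199, 300)], chrom="chr2L")
        assert len(intersect_u(a, b)) == 1

    def test_bookended_do_not_share(self):
        a = make_coll([(100, 200)], chrom="chr2L")
        b = make_coll([(200, 300)], chrom="chr2L")
        assert len(intersect_u(a, b)) == 0

    def test_intersect_matches_brute_force(self, rng):
        for _ in range(20):
            a = random_coll(rng, 200)
            b = random_coll(rng, 200)
            fast = intersect_u(a, b).records
            slow = brute_force_overlapping(a, b)
            assert fast == slow
            # complement partitions a
            assert len(fast) + len(subtract_u(a, b)) == len(a)

    def test_merge_examples(self):
        assert merge(make_coll([(100, 200), (150, 250)])) == make_coll(
            [(100, 250)]
        )
        disjoint = make_coll([(100, 200), (300, 400)])
        assert merge(disjoint) == disjoint
        # book-ended records join (distance 0)
        assert merge(make_coll([(100, 200), (200, 300)])) == make_coll(
            [(100, 300)]
        )

    def test_merge_per_base_oracle(self, rng):
        for _ in range(10):
            coll = random_coll(rng, 100, span=5_000, max_len=200)
            merged = merge(coll)
            assert merge(merged) == merged  # idempotent
            # disjoint, non-book-ended output
            for x, y in zip(merged.intervals(), merged.intervals()[1:]):
                assert x.chrom != y.chrom or x.end < y.start
            covered = {
                (iv.chrom, p)
                for iv in coll.intervals()
                for p in range(iv.start, iv.end)
            }
            merged_bases = sum(len(iv) for iv in merged.intervals())
            assert merged_bases == len(covered)

    @given(
        st.lists(
            st.tuples(st.integers(0, 1000), st.integers(1, 100)),
            min_size=0,
            max_size=30,
        )
    )
    def test_intersect_subset_property(self, spans):
        a = make_coll([(s, s + w) for s, w in spans])
        b = make_coll([(s + 7, s + w + 7) for s, w in spans[::2]])
        sub = intersect_u(a, b)
        assert len(sub) <= len(a)
        a_keys = [(r.chrom, r.start, r.end) for r in a.intervals()]
        assert all(
            (r.chrom, r.start, r.end) in a_keys for r in sub.intervals()
        )


def test_normalize_chrom_styles():
    assert normalize_chrom("2L", "chr") == "chr2L"
    assert normalize_chrom("chr2L", "plain") == "2L"
    assert normalize_chrom("chr2L", None) == "chr2L"
    with pytest.raises(ValueError):
        normalize_chrom("2L", "banana")
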