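"""Interval algebra, variant I/O, and overlap primitives."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from finder.genome_io import (
    BedParseError,
    FeatureTrack,
    GeneModel,
    GenomicInterval,
    SchemaError,
    SummitTrack,
    Transcript,
    VariantSet,
    annotate_variants,
    complement_track,
    coverage_fraction,
    dedup_by_id,
    intersect_tracks,
    intersect_variants,
    jaccard,
    merge_track,
    nearest_signed_distance,
    read_bed,
    read_summits,
    read_variants,
    write_bed,
    write_summits,
)
from conftest import make_track, make_variants, random_track


def brute_force_overlap(vs, track):
    """O(n·m) all-pairs oracle for point-in-interval membership."""
    out = np.zeros(len(vs), dtype=bool)
    ivs = list(track.df[["chrom", "start", "end"]].itertuples(index=False))
    for i, row in enumerate(vs.df.itertuples(index=False)):
        p0 = row.pos - 1
        out[i] = any(c == row.chrom and s <= p0 < e for c, s, e in ivs)
    return out


class TestBedIO:
    def test_read_sorts_intervals(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\nchr1\t50\t80\n")
        t = read_bed(p)
        assert t.df[["start", "end"]].values.tolist() == [[50, 80], [100, 200]]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert len(read_bed(p)) == 0

    @pytest.mark.parametrize(
        "line", ["chr1\t200\t100", "chr1\t100\t100", "chr1\tx\t200", "chr1\t100"]
    )
    def test_malformed_line_names_lineno(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t2\n" + line + "\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p)

    def test_extra_columns_preserved_but_ignored(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t10\t20\tpeak1\t500\n")
        t = read_bed(p)
        assert t.df["col4"].iloc[0] == "peak1"
        assert merge_track(t).total_bp() == 10

    def test_round_trip_two_chroms(self, tmp_path):
        t = make_track("t", [("chr2", 5, 9), ("chr1", 100, 200), ("chr1", 0, 10)])
        p = tmp_path / "rt.bed"
        write_bed(t, p)
        assert read_bed(p) == t
        # grouped by chrom, ascending starts
        lines = p.read_text().splitlines()
        assert lines[0].startswith("chr1\t0") and lines[2].startswith("chr2")

    def test_write_empty(self, tmp_path):
        p = tmp_path / "empty.bed"
        write_bed(make_track("t", []), p)
        assert p.read_text() == ""


class TestVariantIO:
    def test_tsv_and_dedup(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("id\tchrom\tpos\nrs1\tchr1\t150\nrs1\tchr1\t150\n")
        vs = dedup_by_id(read_variants(p))
        assert len(vs) == 1

    def test_gwas_catalog_pvalue_filter(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(
            "id\tchrom\tpos\tpvalue\nrs1\tchr1\t10\t1e-4\nrs2\tchr1\t20\t1e-6\n"
            "rs3\tchr1\t30\t1e-5\n"
        )
        strict = read_variants(p, dialect="gwas_catalog")
        assert list(strict.ids) == ["rs2"]
        inclusive = read_variants(p, dialect="gwas_catalog", inclusive_threshold=True)
        assert list(inclusive.ids) == ["rs2", "rs3"]

    def test_vcf_field_mapping(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text("##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\nchr2\t300\trs9\tA\tG\n")
        vs = read_variants(p, dialect="vcf")
        row = vs.df.iloc[0]
        assert (row["id"], row["chrom"], row["pos"]) == ("rs9", "chr2", 300)

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tchrom\nrs1\tchr1\n")
        with pytest.raises(SchemaError):
            read_variants(p)

    def test_conflicting_duplicate_warns_keeps_first(self):
        vs = make_variants([("rs1", "chr1", 10), ("rs1", "chr1", 99)])
        with pytest.warns(UserWarning, match="conflicting"):
            out = dedup_by_id(vs)
        assert out.df["pos"].iloc[0] == 10

    def test_dedup_identity_and_empty(self):
        vs = make_variants([("rs1", "chr1", 1), ("rs2", "chr1", 2)])
        assert len(dedup_by_id(vs)) == 2
        assert len(dedup_by_id(make_variants([]))) == 0


class TestMerge:
    def test_one_bp_overlap_merges(self):
        t = merge_track(make_track("t", [("chr1", 0, 10), ("chr1", 9, 20)]))
        assert t.df[["start", "end"]].values.tolist() == [[0, 20]]

    def test_book_ended_not_merged(self):
        t = merge_track(make_track("t", [("chr1", 0, 10), ("chr1", 10, 20)]))
        assert len(t) == 2

    def test_single_interval_identity(self):
        t = merge_track(make_track("t", [("chr1", 5, 8)]))
        assert t.df[["start", "end"]].values.tolist() == [[5, 8]]

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 50)), min_size=0, max_size=40
        )
    )
    def test_merge_properties(self, raw):
        t = make_track("t", [("chr1", s, s + l) for s, l in raw])
        m = merge_track(t)
        # idempotent, count non-increasing, covered bp preserved
        assert merge_track(m) == m
        assert len(m) <= len(t)
        covered = np.zeros(600, dtype=bool)
        for s, l in raw:
            covered[s : s + l] = True
        assert m.total_bp() == covered.sum()
        # output disjoint with no 1-bp overlaps
        d = m.df
        assert (d["start"].values[1:] >= d["end"].values[:-1]).all()


class TestCoverage:
    def test_half_genome(self):
        t = make_track("t", [("chr1", 0, 500)])
        assert coverage_fraction(t, {"chr1": 1000}) == 0.5

    def test_empty(self):
        assert coverage_fraction(make_track("t", []), {"chr1": 1000}) == 0.0

    def test_internal_merge(self):
        t = make_track("t", [("chr1", 0, 400), ("chr1", 200, 600)])
        assert coverage_fraction(t, {"chr1": 1000}) == 0.6

    def test_unknown_chrom_raises(self):
        with pytest.raises(ValueError, match="chrX"):
            coverage_fraction(make_track("t", [("chrX", 0, 10)]), {"chr1": 100})

    def test_union_subadditive(self):
        rng = np.random.default_rng(3)
        sizes = {"chr1": 1000, "chr2": 1000}
        for _ in range(20):
            a, b = random_track(rng), random_track(rng)
            u = FeatureTrack("u", pd.concat([a.df, b.df], ignore_index=True))
            assert (
                coverage_fraction(u, sizes)
                <= coverage_fraction(a, sizes) + coverage_fraction(b, sizes) + 1e-12
            )


class TestIntersectVariants:
    def test_half_open_boundaries(self):
        vs = make_variants([("rs1", "chr1", 100)])
        assert intersect_variants(vs, make_track("t", [("chr1", 99, 100)]))[0]
        assert not intersect_variants(vs, make_track("t", [("chr1", 100, 200)]))[0]

    def test_interior_and_empty_track(self):
        vs = make_variants([("rs1", "chr1", 150)])
        assert intersect_variants(vs, make_track("t", [("chr1", 100, 200)]))[0]
        assert not intersect_variants(vs, make_track("t", []))[0]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            track = random_track(rng)
            n = rng.integers(0, 100)
            vs = make_variants(
                [
                    (f"rs{i}", rng.choice(["chr1", "chr2"]), int(rng.integers(1, 1100)))
                    for i in range(n)
                ]
            )
            np.testing.assert_array_equal(
                intersect_variants(vs, track), brute_force_overlap(vs, track)
            )


class TestJaccard:
    def test_identity_disjoint_closed_form(self):
        a = make_track("a", [("chr1", 0, 100)])
        b = make_track("b", [("chr1", 50, 150)])
        assert jaccard(a, a) == 1.0
        assert jaccard(a, make_track("b", [("chr2", 0, 10)])) == 0.0
        assert jaccard(a, b) == pytest.approx(50 / 150)
        assert jaccard(make_track("a", []), make_track("b", [])) == 0.0

    def test_symmetry_and_bound(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a, b = random_track(rng, "a"), random_track(rng, "b")
            ja, jb = jaccard(a, b), jaccard(b, a)
            assert ja == jb
            inter = intersect_tracks(a, b).total_bp()
            assert inter <= min(merge_track(a).total_bp(), merge_track(b).total_bp())


class TestNearestDistance:
    def test_inside_is_zero(self):
        t = make_track("t", [("chr1", 100, 200)])
        d = nearest_signed_distance(make_variants([("rs1", "chr1", 150)]), t)
        assert d[0] == 0

    def test_downstream_positive(self):
        t = make_track("t", [("chr1", 100, 200)])
        d = nearest_signed_distance(make_variants([("rs1", "chr1", 90)]), t)
        assert d[0] == 10

    def test_upstream_negative(self):
        # pos 211 leaves 10 bases (200..209) strictly between the interval
        # and the point, mirroring the downstream case at pos 90
        t = make_track("t", [("chr1", 100, 200)])
        d = nearest_signed_distance(make_variants([("rs1", "chr1", 211)]), t)
        assert d[0] == -10

    def test_gap_symmetry(self):
        # [49,69) is the mirror image of [130,150) around the point base 99:
        # equal-magnitude gaps with opposite signs
        pt = make_variants([("rs1", "chr1", 100)])
        dr = nearest_signed_distance(pt, make_track("t", [("chr1", 130, 150)]))
        dl = nearest_signed_distance(pt, make_track("t", [("chr1", 49, 69)]))
        assert dr[0] == 30
        assert dl[0] == -30

    def test_containment_wins(self):
        t = make_track("t", [("chr1", 100, 200), ("chr1", 240, 260)])
        d = nearest_signed_distance(make_variants([("rs1", "chr1", 250)]), t)
        assert d[0] == 0

    def test_missing_chrom_nan(self):
        t = make_track("t", [("chr1", 0, 10)])
        d = nearest_signed_distance(make_variants([("rs1", "chr9", 5)]), t)
        assert np.isnan(d[0])


class TestBedtoolsOracle:
    """Cross-checks against the bedtools suite on random inputs."""

    def _write(self, path, track):
        write_bed(track, path)

    def test_merge_matches_bedtools(self, tmp_path):
        rng = np.random.default_rng(21)
        for k in range(5):
            t = random_track(rng, n_max=80)
            p = tmp_path / f"m{k}.bed"
            self._write(p, t)
            # -d -1 requires >= 1 shared bp, matching our merge semantics
            out = subprocess.run(
                ["bedtools", "merge", "-d", "-1", "-i", str(p)],
                capture_output=True, text=True, check=True,
            ).stdout
            ours = merge_track(t)
            theirs = [
                (f[0], int(f[1]), int(f[2]))
                for f in (line.split("\t") for line in out.splitlines())
            ]
            assert list(ours.df[["chrom", "start", "end"]].itertuples(index=False, name=None)) == theirs

    def test_jaccard_matches_bedtools(self, tmp_path):
        rng = np.random.default_rng(22)
        for k in range(5):
            a = merge_track(random_track(rng, "a", n_max=60))
            b = merge_track(random_track(rng, "b", n_max=60))
            if len(a) == 0 or len(b) == 0:
                continue
            pa, pb = tmp_path / f"a{k}.bed", tmp_path / f"b{k}.bed"
            self._write(pa, a)
            self._write(pb, b)
            out = subprocess.run(
                ["bedtools", "jaccard", "-a", str(pa), "-b", str(pb)],
                capture_output=True, text=True, check=True,
            ).stdout.splitlines()[1].split("\t")
            # compare against the exact bp counts (the printed ratio is rounded)
            assert jaccard(a, b) == pytest.approx(int(out[0]) / int(out[1]), abs=1e-12)


class TestSummits:
    def test_round_trip(self, tmp_path):
        st_ = SummitTrack(
            pd.DataFrame(
                {
                    "chrom": ["chr1"],
                    "start": [100],
                    "end": [300],
                    "summit": [201],
                    "core_start": [180],
                    "core_end": [220],
                }
            )
        )
        p = tmp_path / "s.bed"
        write_summits(st_, p)
        back = read_summits(p)
        pd.testing.assert_frame_equal(back.df, st_.df)

    def test_summit_outside_parent_rejected(self):
        with pytest.raises(ValueError, match="summit"):
            SummitTrack(
                pd.DataFrame(
                    {
                        "chrom": ["chr1"], "start": [100], "end": [200],
                        "summit": [300], "core_start": [100], "core_end": [101],
                    }
                )
            )


class TestAnnotate:
    @pytest.fixture()
    def model(self):
        # one + strand coding transcript, one - strand transcript whose
        # intron covers the first transcript's exon2
        tx1 = Transcript(
            name="tx1", chrom="chr1", strand="+", tx_start=10_000, tx_end=20_000,
            cds_start=11_000, cds_end=19_000,
            exon_starts=(10_000, 15_000), exon_ends=(12_000, 20_000),
        )
        tx2 = Transcript(
            name="tx2", chrom="chr1", strand="-", tx_start=14_000, tx_end=30_000,
            cds_start=22_000, cds_end=29_000,
            exon_starts=(14_000, 22_000), exon_ends=(14_500, 30_000),
        )
        return GeneModel([tx1, tx2])

    def test_promoter_window(self, model):
        vs = make_variants([("rs1", "chr1", 9_501)])  # 500 bp upstream of tx1 TSS
        assert annotate_variants(vs, model).iloc[0] == "promoter-TSS"

    def test_intergenic(self, model):
        vs = make_variants([("rs1", "chr1", 500_000)])
        assert annotate_variants(vs, model).iloc[0] == "intergenic"

    def test_exon_beats_intron_across_transcripts(self, model):
        # pos 16_001 (0-based 16_000): CDS exon of tx1, intron of tx2
        vs = make_variants([("rs1", "chr1", 16_001)])
        assert annotate_variants(vs, model).iloc[0] == "exon"

    def test_utr_categories_strand_aware(self, model):
        five = make_variants([("rs1", "chr1", 10_501)])  # before cds_start, + strand
        three = make_variants([("rs2", "chr1", 19_501)])  # after cds_end, + strand
        assert annotate_variants(five, model).iloc[0] == "5'UTR"
        assert annotate_variants(three, model).iloc[0] == "3'UTR"

    def test_intron(self, model):
        vs = make_variants([("rs1", "chr1", 13_001)])
        assert annotate_variants(vs, model).iloc[0] == "intron"


class TestComplement:
    def test_partition(self):
        rng = np.random.default_rng(9)
        # random_track intervals can end at 1000 + 59, so allow headroom
        sizes = {"chr1": 1100, "chr2": 1100}
        for _ in range(10):
            t = random_track(rng)
            c = complement_track(t, sizes)
            assert merge_track(t).total_bp() + c.total_bp() == 2200
            assert intersect_tracks(t, c).total_bp() == 0


def test_genomic_interval_invariants():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 5)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 5, 5)
    assert len(GenomicInterval("chr1", 2, 7)) == 5
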