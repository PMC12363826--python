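"""Overlap statistics: readers, sweep queries vs brute force, synth truth."""

import json

import numpy as np
import pytest

from svload.trapstats import (
    GenerationError,
    IntervalVariant,
    PointVariant,
    SynthSpec,
    compute_overlap_report,
    feature_overlap_counts,
    nucleotides_by_svtype,
    per_chromosome_sv_counts,
    read_feature_intervals,
    read_interval_variants,
    read_point_variants,
    synth_variant_pair,
    trapped_fraction,
)

SNP_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chrI,length=1000000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""

SV_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chrI,length=1000000>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">
##INFO=<ID=END,Number=1,Type=Integer,Description="e">
##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="l">
##ALT=<ID=DEL,Description="d">
##ALT=<ID=INS,Description="i">
##ALT=<ID=INV,Description="v">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestPointReader:
    def test_empty_body(self, tmp_path):
        assert read_point_variants(_write(tmp_path, "e.vcf", SNP_HEADER)) == []

    def test_quality_and_depth_filters(self, tmp_path):
        body = (
            "chrI\t100\ts1\tA\tT\t10\tPASS\tDP=30\n"
            "chrI\t200\ts2\tA\tT\t25\tPASS\tDP=30\n"
            "chrI\t300\ts3\tA\tT\t30\tPASS\tDP=30\n"
            "chrI\t400\ts4\tA\tT\t30\tPASS\tDP=5\n"
            "chrI\t500\ts5\tA\tT\t30\tPASS\t.\n"
        )
        pts = read_point_variants(_write(tmp_path, "q.vcf", SNP_HEADER + body))
        # QUAL 10 fails minQUAL=20; DP 5 fails minDP=10; missing DP skipped
        assert [p.pos for p in pts] == [200, 300]

    def test_multiallelic_counted_once(self, tmp_path):
        body = "chrI\t700\tma\tA\tT,G\t50\tPASS\tDP=40\n"
        pts = read_point_variants(_write(tmp_path, "m.vcf", SNP_HEADER + body))
        assert len(pts) == 1 and pts[0].pos == 700

    def test_non_snp_records_ignored(self, tmp_path):
        body = "chrI\t800\tindel\tAT\tA\t50\tPASS\tDP=40\n"
        assert read_point_variants(_write(tmp_path, "i.vcf", SNP_HEADER + body)) == []


class TestIntervalReader:
    def test_span_rules(self, tmp_path):
        body = (
            "chrI\t100\tdel1\tN\t<DEL>\t60\tPASS\tSVTYPE=DEL;END=199\n"
            "chrI\t500\tins1\tN\t<INS>\t60\tPASS\tSVTYPE=INS;SVLEN=300\n"
            "chrI\t10\tinv1\tN\t<INV>\t60\tPASS\tSVTYPE=INV;SVLEN=-90\n"
            "chrI\t900\tbnd1\tN\t<TRA>\t60\tPASS\tSVTYPE=TRA\n"
            "chrI\t950\tbad\tN\t<DEL>\t60\tPASS\tSVTYPE=DEL\n"
        )
        ivs = read_interval_variants(_write(tmp_path, "s.vcf", SV_HEADER + body))
        by_id = {iv.id: iv for iv in ivs}
        assert (by_id["del1"].start, by_id["del1"].end, by_id["del1"].length) == (100, 199, 100)
        assert (by_id["ins1"].start, by_id["ins1"].end, by_id["ins1"].length) == (500, 500, 300)
        assert (by_id["inv1"].start, by_id["inv1"].end) == (10, 99)  # |SVLEN| fallback
        assert (by_id["bnd1"].start, by_id["bnd1"].end, by_id["bnd1"].length) == (900, 900, 1)
        assert "bad" not in by_id  # spanning record without END or SVLEN skipped


class TestFeatureReader:
    def test_bed_normalized_to_one_based_inclusive(self, tmp_path):
        p = _write(tmp_path, "f.bed", "chrI\t9\t20\tx\nchrI\t29\t40\ty\n")
        assert read_feature_intervals(p) == [("chrI", 10, 20), ("chrI", 30, 40)]

    def test_gff3_exons_filtered(self, tmp_path):
        text = (
            "##gff-version 3\n"
            "chrI\tsrc\texon\t10\t20\t.\t+\t.\tID=e1\n"
            "chrI\tsrc\tgene\t5\t50\t.\t+\t.\tID=g1\n"
        )
        p = _write(tmp_path, "f.gff3", text)
        assert read_feature_intervals(p, feature="exon") == [("chrI", 10, 20)]


def _brute_trapped(points, intervals):
    return sum(
        1
        for p in points
        if any(iv.chrom == p.chrom and iv.start <= p.pos <= iv.end for iv in intervals)
    )


class TestTrappedFraction:
    def test_toy_one_third(self):
        pts = [PointVariant("chrI", p) for p in (5, 15, 25)]
        ivs = [IntervalVariant("chrI", 10, 20, "DEL", 11)]
        rep = trapped_fraction(pts, ivs)
        assert rep.trapped_points == 1 and rep.trapped_fraction == pytest.approx(1 / 3)

    def test_no_intervals_flagged_zero(self):
        rep = trapped_fraction([PointVariant("chrI", 5)], [])
        assert rep.trapped_fraction == 0.0 and rep.trapped_fraction_defined

    def test_no_points_flagged_undefined(self):
        rep = trapped_fraction([], [IntervalVariant("chrI", 1, 5, "DEL", 5)])
        assert rep.trapped_fraction == 0.0 and not rep.trapped_fraction_defined

    def test_boundaries_inclusive(self):
        ivs = [IntervalVariant("chrI", 10, 20, "INV", 11)]
        for pos, inside in ((9, 0), (10, 1), (20, 1), (21, 0)):
            assert trapped_fraction([PointVariant("chrI", pos)], ivs).trapped_points == inside

    def test_point_in_overlapping_intervals_counted_once(self):
        ivs = [
            IntervalVariant("chrI", 10, 30, "DEL", 21),
            IntervalVariant("chrI", 5, 25, "DUP", 21),
        ]
        rep = trapped_fraction([PointVariant("chrI", 15)], ivs)
        assert rep.trapped_points == 1

    def test_svtype_filter(self):
        ivs = [IntervalVariant("chrI", 10, 10, "INS", 500)]
        pts = [PointVariant("chrI", 10)]
        assert trapped_fraction(pts, ivs).trapped_points == 1
        assert trapped_fraction(pts, ivs, svtypes=("DEL", "DUP", "INV")).trapped_points == 0

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_bruteforce_on_random_fixtures(self, seed):
        """Sorted-sweep containment equals the all-pairs oracle."""
        rng = np.random.default_rng(seed)
        chroms = ["chrI", "chrII", "chrX"][: 1 + seed % 3]
        pts = [
            PointVariant(chroms[rng.integers(len(chroms))], int(rng.integers(1, 5000)))
            for _ in range(int(rng.integers(1, 120)))
        ]
        ivs = []
        for _ in range(int(rng.integers(0, 40))):
            start = int(rng.integers(1, 4800))
            end = start + int(rng.integers(0, 400))
            ivs.append(
                IntervalVariant(
                    chroms[rng.integers(len(chroms))], start, end, "DEL", end - start + 1
                )
            )
        rep = trapped_fraction(pts, ivs)
        assert rep.trapped_points == _brute_trapped(pts, ivs)
        assert rep.trapped_points <= rep.total_points


class TestFeatureOverlap:
    def test_toy_cases(self):
        feats = [("chrI", 10, 20)]
        pts = [PointVariant("chrI", 15)]
        assert feature_overlap_counts(pts, [], feats) == (1, 0)
        ivs = [IntervalVariant("chrI", 5, 9, "DEL", 5)]
        assert feature_overlap_counts([], ivs, feats) == (0, 0)  # adjacency, no overlap
        ivs = [IntervalVariant("chrI", 5, 10, "DEL", 6)]
        assert feature_overlap_counts([], ivs, feats) == (0, 1)  # 1-nt overlap counts

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(1000 + seed)
        pts = [PointVariant("c", int(rng.integers(1, 2000))) for _ in range(60)]
        ivs = [
            IntervalVariant("c", s, s + int(rng.integers(0, 100)), "INV", 1)
            for s in rng.integers(1, 1900, size=15).tolist()
        ]
        ivs = [IntervalVariant(i.chrom, i.start, i.end, i.svtype, i.end - i.start + 1) for i in ivs]
        feats = [
            ("c", int(s), int(s) + int(rng.integers(0, 150)))
            for s in rng.integers(1, 1900, size=10)
        ]
        ep, ei = feature_overlap_counts(pts, ivs, feats)
        assert ep == sum(
            1 for p in pts if any(c == p.chrom and s <= p.pos <= e for c, s, e in feats)
        )
        assert ei == sum(
            1
            for iv in ivs
            if any(c == iv.chrom and s <= iv.end and e >= iv.start for c, s, e in feats)
        )


class TestTallies:
    def test_nucleotides_by_type(self):
        ivs = [
            IntervalVariant("chrI", 1, 100, "DEL", 100),
            IntervalVariant("chrI", 500, 549, "DEL", 50),
            IntervalVariant("chrI", 700, 700, "INS", 300),
        ]
        totals = nucleotides_by_svtype(ivs)
        assert totals == {"DEL": 150, "INS": 300}
        assert nucleotides_by_svtype([]) == {}

    def test_merged_union_variant(self):
        ivs = [
            IntervalVariant("chrI", 1, 100, "DEL", 100),
            IntervalVariant("chrI", 50, 149, "DEL", 100),
        ]
        assert nucleotides_by_svtype(ivs)["DEL"] == 200
        assert nucleotides_by_svtype(ivs, merge_overlaps=True)["DEL"] == 149

    def test_per_chromosome_table(self):
        ivs = [IntervalVariant("chrIV", 1, 10, "DEL", 10) for _ in range(3)]
        ivs.append(IntervalVariant("chrX", 5, 50, "INV", 46))
        table = per_chromosome_sv_counts(ivs)
        assert table.loc["chrIV", "DEL"] == 3
        assert table.loc["chrX", "INV"] == 1
        assert table.values.sum() == len(ivs)
        assert per_chromosome_sv_counts([]).empty


class TestSynth:
    def test_truth_recovered_through_readers(self, tmp_path):
        spec = SynthSpec(
            chromosomes={"chrI": 200_000, "chrII": 100_000},
            n_points=80, n_intervals=12, target_trapped_fraction=0.4,
            n_features=8, seed=9,
        )
        truth = synth_variant_pair(spec, tmp_path / "p.vcf", tmp_path / "s.vcf",
                                   tmp_path / "t.json")
        pts = read_point_variants(tmp_path / "p.vcf")
        ivs = read_interval_variants(tmp_path / "s.vcf")
        feats = read_feature_intervals(truth["features_bed"])
        rep = compute_overlap_report(pts, ivs, feats)
        assert rep.total_points == truth["total_points"] == 80
        assert rep.trapped_points == truth["trapped_points"] == 32
        assert rep.exonic_points == truth["exonic_points"]
        assert rep.exonic_intervals == truth["exonic_intervals"]
        assert rep.nt_by_type == truth["nt_by_type"]
        assert rep.per_chrom_by_type == truth["per_chrom_by_type"]
        saved = json.loads((tmp_path / "t.json").read_text())
        assert saved["trapped_points"] == 32

    def test_target_zero_places_nothing_inside(self, tmp_path):
        spec = SynthSpec(chromosomes={"chrI": 50_000}, n_points=60, n_intervals=10,
                         target_trapped_fraction=0.0, seed=3)
        synth_variant_pair(spec, tmp_path / "p.vcf", tmp_path / "s.vcf")
        pts = read_point_variants(tmp_path / "p.vcf")
        ivs = read_interval_variants(tmp_path / "s.vcf")
        assert _brute_trapped(pts, ivs) == 0

    def test_byte_identical_reruns(self, tmp_path):
        spec = SynthSpec(chromosomes={"chrI": 80_000}, n_points=40, n_intervals=8, seed=5)
        synth_variant_pair(spec, tmp_path / "a.vcf", tmp_path / "b.vcf")
        synth_variant_pair(spec, tmp_path / "a2.vcf", tmp_path / "b2.vcf")
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "a2.vcf").read_bytes()
        assert (tmp_path / "b.vcf").read_bytes() == (tmp_path / "b2.vcf").read_bytes()

    def test_infeasible_outside_placement(self, tmp_path):
        # intervals blanket the chromosome: no room for outside points
        spec = SynthSpec(chromosomes={"chrI": 100}, n_points=10, n_intervals=30,
                         target_trapped_fraction=0.5, min_sv_len=100, max_sv_len=100,
                         svtype_mix={"DEL": 1.0}, seed=1)
        with pytest.raises(GenerationError):
            synth_variant_pair(spec, tmp_path / "p.vcf", tmp_path / "s.vcf")

    def test_invalid_spec_rejected(self):
        with pytest.raises(GenerationError):
            SynthSpec(chromosomes={}, n_points=5)
        with pytest.raises(GenerationError):
            SynthSpec(chromosomes={"c": 100}, target_trapped_fraction=1.5)
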