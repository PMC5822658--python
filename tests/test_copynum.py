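"""Mask-and-append reference construction, read mapping, depth counting and
the coverage-ratio copy-number estimator."""

from __future__ import annotations

import numpy as np
import pytest

from teratornscan import simulate as sim
from teratornscan.copynum import (
    CoverageProfile,
    GeneInterval,
    Placement,
    build_masked_reference,
    estimate_copy_number,
    map_reads,
    per_base_depth,
    read_depth_table,
    write_depth_table,
)
from teratornscan.genome import GenomeAssembly, Read

from conftest import random_genome
from oracles import exhaustive_substring_placements, per_base_recount


class TestMaskedReference:
    def test_construction(self):
        genome = random_genome(10_000, 1)
        ref = build_masked_reference(genome, [("contig_1", 2000, 3000)], "ACGT" * 100)
        assert len(ref["contig_1"]) == 10_000
        assert ref["contig_1"][2000:3000] == "N" * 1000
        assert ref["Teratorn_element"] == "ACGT" * 100

    def test_no_intervals_degenerate(self):
        genome = random_genome(5_000, 2)
        ref = build_masked_reference(genome, [], "ACGTACGTACGT")
        assert ref["contig_1"] == genome["contig_1"]
        assert len(ref) == 2

    def test_bad_interval_raises(self):
        genome = random_genome(5_000, 3)
        with pytest.raises(ValueError):
            build_masked_reference(genome, [("contig_1", 4000, 6000)], "ACGT")
        with pytest.raises(KeyError):
            build_masked_reference(genome, [("zz", 0, 10)], "ACGT")


class TestMapReads:
    def test_error_free_read_placed_exactly(self):
        genome = random_genome(20_000, 4)
        read = Read("r1", genome["contig_1"][500:600], "I" * 100)
        (p,) = map_reads([read], genome)
        assert (p.contig_id, p.start, p.strand, p.mismatches) == ("contig_1", 500, "+", 0)

    def test_read_spanning_masked_region_unplaced(self):
        genome = random_genome(20_000, 5)
        read = Read("r1", genome["contig_1"][500:600], "I" * 100)
        masked = build_masked_reference(genome, [("contig_1", 550, 560)], "ACGT" * 50)
        del masked.contigs["Teratorn_element"]
        assert map_reads([read], GenomeAssembly(masked.contigs), max_mismatches=4) == []

    def test_reverse_strand_read(self):
        from teratornscan._seq import revcomp

        genome = random_genome(20_000, 6)
        read = Read("r1", revcomp(genome["contig_1"][700:800]), "I" * 100)
        (p,) = map_reads([read], genome)
        assert (p.start, p.strand) == (700, "-")

    def test_matches_exhaustive_oracle(self):
        genome = random_genome(30_000, 7)
        reads = sim.simulate_reads(genome, 2.0, 60, 0.0, seed=8)[:1500]
        placements = map_reads(reads, genome, seed_kmer=21, max_mismatches=0)
        placed = {p.read_id: (p.contig_id, p.start, p.strand) for p in placements}
        for r in reads:
            oracle = exhaustive_substring_placements(r.sequence, dict(genome.items()))
            if len(oracle) == 1:
                assert placed[r.read_id] == oracle[0]
            elif len(oracle) > 1:
                assert placed[r.read_id] in oracle

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            map_reads([], GenomeAssembly({}))


class TestDepth:
    def test_single_read_unit_depth(self):
        genome = random_genome(1000, 9)
        placements = [Placement("r", "contig_1", 10, "+", 0)]
        profile = per_base_depth(
            placements, [GeneInterval("contig_1", 0, 300, "g", "host")], genome, 100
        )
        d = profile.depths[0]
        assert d[:10].sum() == 0 and (d[10:110] == 1).all() and d[110:].sum() == 0

    def test_depth_mass_conservation(self):
        genome = random_genome(5000, 10)
        rng = np.random.default_rng(11)
        placements = [
            Placement(f"r{i}", "contig_1", int(s), "+", 0)
            for i, s in enumerate(rng.integers(0, 4900, size=200))
        ]
        profile = per_base_depth(
            placements, [GeneInterval("contig_1", 0, 5000, "g", "host")], genome, 100
        )
        assert profile.depths[0].sum() == 200 * 100

    def test_matches_brute_force_recount(self):
        genome = random_genome(4000, 12)
        rng = np.random.default_rng(13)
        placements = [
            Placement(f"r{i}", "contig_1", int(s), "+", 0)
            for i, s in enumerate(rng.integers(0, 3900, size=1000))
        ]
        intervals = [
            GeneInterval("contig_1", 100, 600, "g1", "host"),
            GeneInterval("contig_1", 2000, 2400, "g2", "viral"),
        ]
        profile = per_base_depth(placements, intervals, genome, 100)
        oracle = per_base_recount(
            [(p.contig_id, p.start) for p in placements],
            100,
            [(iv.contig_id, iv.start, iv.end) for iv in intervals],
        )
        for got, exp in zip(profile.depths, oracle):
            assert got.tolist() == exp


class TestDepthTable:
    def test_round_trip(self, tmp_path):
        genome = random_genome(2000, 14)
        placements = [Placement("r", "contig_1", 50, "+", 0)]
        intervals = [GeneInterval("contig_1", 0, 300, "g", "host")]
        profile = per_base_depth(placements, intervals, genome, 100)
        path = tmp_path / "depth.tsv"
        write_depth_table(profile, path)
        again = read_depth_table(path, intervals)
        assert again.depths[0].tolist() == profile.depths[0].tolist()

    def test_one_based_convention(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("c\t1\t7\nc\t2\t8\nc\t3\t9\n")
        profile = read_depth_table(path, [GeneInterval("c", 0, 3, "g", "host")])
        assert profile.depths[0].tolist() == [7, 8, 9]

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("c\t1\t7\nc\tx\t8\n")
        with pytest.raises(ValueError, match="line 2"):
            read_depth_table(path, [])


class TestEstimator:
    @staticmethod
    def make_profile(viral_depth, host_depth, n_viral=3, n_host=5, length=200):
        intervals, depths = [], []
        for i in range(n_viral):
            intervals.append(GeneInterval("e", i * length, (i + 1) * length, f"v{i}", "viral"))
            depths.append(np.full(length, viral_depth, dtype=np.int64))
        for i in range(n_host):
            intervals.append(GeneInterval("c", i * length, (i + 1) * length, f"h{i}", "host"))
            depths.append(np.full(length, host_depth, dtype=np.int64))
        return CoverageProfile(intervals, depths)

    def test_ratio_arithmetic(self):
        est = estimate_copy_number(self.make_profile(300, 30), n_bootstrap=0)
        assert est.copy_number == pytest.approx(10.0)

    def test_zero_viral_depth(self):
        est = estimate_copy_number(self.make_profile(0, 30), n_bootstrap=0)
        assert est.copy_number == 0.0

    def test_zero_host_depth_raises(self):
        with pytest.raises(ZeroDivisionError):
            estimate_copy_number(self.make_profile(300, 0), n_bootstrap=0)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(20)
        intervals, depths = [], []
        for i in range(4):
            intervals.append(GeneInterval("e", 0, 200, f"v{i}", "viral"))
            depths.append(rng.poisson(300, size=200))
        for i in range(6):
            intervals.append(GeneInterval("c", 0, 200, f"h{i}", "host"))
            depths.append(rng.poisson(30, size=200))
        est = estimate_copy_number(CoverageProfile(intervals, depths), n_bootstrap=500, seed=1)
        lo, hi = est.bootstrap_ci
        assert lo <= est.copy_number <= hi


def copy_number_run(seed: int, n_copies_per_subtype: int = 5):
    """Full simulate->mask->map->depth->estimate round trip at small scale."""
    catalog = [("pol", 220), ("hel", 200), ("mcp", 220), ("ORF54", 150)]
    template = sim.build_viral_element(catalog, "absent", tir_length=13, seed=seed)
    host, host_truth = sim.simulate_host_genome(
        1, 60_000, 0.45, 8, seed=seed + 1, gene_length=1200
    )
    genome, truth = sim.insert_element_copies(
        host,
        template,
        [(n_copies_per_subtype, 0.17, 0.02), (n_copies_per_subtype, 0.17, 0.02)],
        seed=seed + 2,
        host_truth=host_truth,
        min_separation=1000,
    )
    reads = sim.simulate_reads(genome, 30.0, 100, 0.002, seed=seed + 3)
    # one appended reference per subtype: the first planted copy of each
    reps = {}
    for ins in truth.insertions:
        name = f"element_{ins.subtype_label}"
        if name not in reps:
            reps[name] = genome[ins.contig_id][ins.start : ins.end]
    masked = build_masked_reference(
        genome,
        [(i.contig_id, i.start, i.end) for i in truth.insertions],
        reps,
    )
    intervals = [
        GeneInterval(name, iv.start, iv.end, f"{name}:{iv.gene_id}", "viral")
        for name in reps
        for iv in truth.element_cds_intervals
    ] + [
        GeneInterval(iv.contig_id, iv.start, iv.end, iv.gene_id, "host")
        for iv in truth.host_cds_intervals
    ]
    placements = map_reads(reads, masked, seed_kmer=21, max_mismatches=8, seed=seed + 4)
    profile = per_base_depth(placements, intervals, masked, 100)
    return profile, truth


class TestRecovery:
    def test_ten_copies_recovered(self):
        from teratornscan.copynum import estimate_copy_number_total

        profile, truth = copy_number_run(seed=100)
        per_subtype, total = estimate_copy_number_total(profile, n_bootstrap=0)
        assert len(per_subtype) == 2
        assert total.copy_number == pytest.approx(10.0, rel=0.15)
        for est in per_subtype.values():
            assert est.copy_number == pytest.approx(5.0, rel=0.3)

    def test_single_copy_host_control(self):
        profile, _ = copy_number_run(seed=200)
        # relabel one host gene as 'viral': its depth ratio is ~1
        intervals = []
        flipped = False
        for iv in profile.intervals:
            if iv.gene_class == "host" and not flipped:
                intervals.append(GeneInterval(iv.contig_id, iv.start, iv.end, iv.gene_id, "viral"))
                flipped = True
            elif iv.gene_class == "viral":
                intervals.append(GeneInterval(iv.contig_id, iv.start, iv.end, iv.gene_id, "skip"))
            else:
                intervals.append(iv)
        control = CoverageProfile(intervals, profile.depths)
        est = estimate_copy_number(control, n_bootstrap=0)
        assert est.copy_number == pytest.approx(1.0, rel=0.15)

    def test_unmasked_reference_underestimates(self):
        # why mask-and-append matters: with copies left in the reference,
        # reads distribute across them and the appended element starves
        catalog = [("pol", 220), ("hel", 200)]
        template = sim.build_viral_element(catalog, "absent", tir_length=13, seed=7)
        host, host_truth = sim.simulate_host_genome(1, 50_000, 0.45, 6, seed=8, gene_length=1200)
        genome, truth = sim.insert_element_copies(
            host, template, [(6, 0.0, 0.0)], seed=9, host_truth=host_truth,
            min_separation=1000,
        )
        reads = sim.simulate_reads(genome, 30.0, 100, 0.0, seed=10)
        intervals = [
            GeneInterval(iv.contig_id, iv.start, iv.end, iv.gene_id, "viral")
            for iv in truth.element_cds_intervals
        ] + [
            GeneInterval(iv.contig_id, iv.start, iv.end, iv.gene_id, "host")
            for iv in truth.host_cds_intervals
        ]
        masked = build_masked_reference(
            genome, [(i.contig_id, i.start, i.end) for i in truth.insertions],
            template.sequence,
        )
        unmasked = build_masked_reference(genome, [], template.sequence)
        est_masked = estimate_copy_number(
            per_base_depth(map_reads(reads, masked, seed=1), intervals, masked, 100),
            n_bootstrap=0,
        )
        est_unmasked = estimate_copy_number(
            per_base_depth(map_reads(reads, unmasked, seed=1), intervals, unmasked, 100),
            n_bootstrap=0,
        )
        assert est_masked.copy_number == pytest.approx(6.0, rel=0.2)
        assert est_unmasked.copy_number < 0.5 * est_masked.copy_number
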