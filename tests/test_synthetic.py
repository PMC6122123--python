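"""The generators reproduce the stated meiotic model and are seed-deterministic."""

import numpy as np
import pandas as pd
import pytest

from recinv import (
    ChromosomeSpec,
    CrossConfig,
    TruthInversion,
    detect_crossovers,
    fd_window,
    simulate_cross,
    simulate_popgen_sites,
    simulate_split_read_candidates,
    simulate_trio_alignments,
)


class TestSimulateCross:
    def test_obligate_model_mean_crossovers(self):
        """21 chromosomes, one obligate chiasma each, recombinant chromatid
        inherited half the time -> 10.5 expected crossovers per offspring."""
        genome = [ChromosomeSpec(f"c{i}", 2_000_000) for i in range(21)]
        ds = simulate_cross(CrossConfig(n_offspring=1000, seed=5), genome)
        mean = len(ds.truth_crossovers) / 1000
        se = np.sqrt(21 * 0.25 / 1000)
        assert abs(mean - 10.5) < 3 * se

    def test_female_meiosis_achiasmatic(self, noisy_cross):
        assert noisy_cross.truth_maternal_crossovers.empty
        # detector confirms: constant maternal haplotypes yield no crossovers
        assert detect_crossovers(noisy_cross, which="maternal") == []

    def test_seed_determinism(self, small_genome):
        cfg = CrossConfig(n_offspring=50, genotype_error_rate=0.01, missing_rate=0.05, seed=3)
        a = simulate_cross(cfg, small_genome)
        b = simulate_cross(cfg, small_genome)
        assert a.truth_crossovers.equals(b.truth_crossovers)
        for chrom in a.genotypes:
            assert np.array_equal(a.markers[chrom], b.markers[chrom])
            assert np.array_equal(a.genotypes[chrom], b.genotypes[chrom])
            assert np.array_equal(a.maternal_genotypes[chrom], b.maternal_genotypes[chrom])

    def test_full_suppression_blocks_crossovers_in_hybrids(self, hybrid_cross, inversion):
        xo = hybrid_cross.truth_crossovers
        inside = xo[
            (xo.chrom == inversion.chrom)
            & (xo.pos_bp >= inversion.start_bp)
            & (xo.pos_bp < inversion.end_bp)
        ]
        assert len(inside) == 0

    def test_suppression_not_applied_to_homozygous_parents(self, small_genome, inversion):
        """A within-species father carries the inversion homozygously: no suppression."""
        ds = simulate_cross(
            CrossConfig(design="within_species_F1", species="cydno", n_offspring=300, seed=13),
            small_genome,
            [inversion],
        )
        xo = ds.truth_crossovers
        inside = xo[
            (xo.chrom == inversion.chrom)
            & (xo.pos_bp >= inversion.start_bp)
            & (xo.pos_bp < inversion.end_bp)
        ]
        assert len(inside) > 0

    def test_suppression_monotone(self, small_genome):
        """Increasing suppression decreases crossovers inside the interval."""
        counts = []
        for s in (0.0, 0.5, 1.0):
            inv = TruthInversion("chr1", 2_000_000, 8_000_000, "cydno", suppression=s)
            ds = simulate_cross(
                CrossConfig(design="hybrid_backcross", n_offspring=400, seed=21),
                small_genome,
                [inv],
            )
            xo = ds.truth_crossovers
            counts.append(
                len(
                    xo[
                        (xo.chrom == "chr1")
                        & (xo.pos_bp >= 2_000_000)
                        & (xo.pos_bp < 8_000_000)
                    ]
                )
            )
        assert counts[0] > counts[1] > counts[2] == 0

    def test_truth_crossovers_match_phase_switches(self, clean_cross):
        """Conservation: without noise, detected switches (min_support=1) equal
        truth crossovers falling within the marker span."""
        detected = detect_crossovers(clean_cross, min_support=1)
        n_in_span = 0
        for r in clean_cross.truth_crossovers.itertuples():
            pos = clean_cross.markers[r.chrom]
            n_in_span += pos[0] < r.pos_bp <= pos[-1]
        assert len(detected) == n_in_span

    def test_invalid_inputs_rejected(self, small_genome):
        with pytest.raises(ValueError):
            CrossConfig(n_offspring=0)
        with pytest.raises(ValueError):
            simulate_cross(
                CrossConfig(n_offspring=5),
                small_genome,
                [TruthInversion("chr1", 0, 99_000_000, "cydno")],
            )
        with pytest.raises(ValueError):
            TruthInversion("chr1", 5, 5, "cydno")


class TestSplitReadCandidates:
    def test_truth_yields_both_sexes(self, small_genome, inversion):
        cands = simulate_split_read_candidates([inversion], 0, small_genome, seed=1)
        assert len(cands) == 2
        assert {c.sex for c in cands} == {"female", "male"}
        assert all(c.species == "cydno" and c.support_tier == "default" for c in cands)
        assert all(
            (c.start_bp, c.end_bp) == (inversion.start_bp, inversion.end_bp) for c in cands
        )

    def test_false_positive_count(self, small_genome):
        cands = simulate_split_read_candidates([], 49, small_genome, seed=2)
        assert len(cands) == 49
        lengths = {c.chrom for c in cands}
        assert lengths <= {"chr1", "chr2", "chr3"}

    def test_determinism(self, small_genome, inversion):
        a = simulate_split_read_candidates([inversion], 20, small_genome, seed=7)
        b = simulate_split_read_candidates([inversion], 20, small_genome, seed=7)
        assert a == b


class TestTrioAlignments:
    def test_collinear_without_inversions(self, small_genome):
        alns = simulate_trio_alignments([], small_genome, seed=3)
        assert alns and all(a.orientation == "forward" for a in alns)

    def test_carrier_reversed_inside_noncarrier_spans(self, small_genome, inversion):
        alns = simulate_trio_alignments(
            [inversion], small_genome, scaffold_n50_bp=500_000, seed=3
        )
        carrier = [a for a in alns if a.species == "cydno" and a.chrom == "chr1"]
        rev = [a for a in carrier if a.orientation == "reverse"]
        assert rev and all(
            a.ref_start_bp >= inversion.start_bp and a.ref_end_bp <= inversion.end_bp
            for a in rev
        )
        # non-carrier collinear, with alignments spanning each breakpoint
        other = [a for a in alns if a.species == "melpomene" and a.chrom == "chr1"]
        assert all(a.orientation == "forward" for a in other)
        for bp in (inversion.start_bp, inversion.end_bp):
            assert any(a.ref_start_bp < bp < a.ref_end_bp for a in other)

    def test_determinism(self, small_genome, inversion):
        a = simulate_trio_alignments([inversion], small_genome, seed=9)
        b = simulate_trio_alignments([inversion], small_genome, seed=9)
        assert a == b


class TestPopgenSites:
    def test_no_introgression_gives_null_fd(self):
        freqs = simulate_popgen_sites(40_000, gamma=0.0, seed=4)
        d, fd = fd_window(freqs)
        if np.isfinite(fd):
            assert abs(fd) < 0.02
        else:  # D < 0 by Monte-Carlo chance: the symmetric check
            assert abs(d) < 0.02

    def test_p2_equal_p3_forces_fd_one(self):
        freqs = simulate_popgen_sites(5_000, gamma=0.0, seed=5)
        freqs = freqs.assign(p2=freqs["p3"])
        d, fd = fd_window(freqs)
        assert d >= 0
        assert fd == pytest.approx(1.0, abs=1e-12)

    def test_determinism_and_bounds(self):
        a = simulate_popgen_sites(1_000, gamma=0.3, seed=6)
        b = simulate_popgen_sites(1_000, gamma=0.3, seed=6)
        pd.testing.assert_frame_equal(a, b)
        for col in ("p1", "p2", "p3", "pO"):
            assert a[col].between(0, 1).all()

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            simulate_popgen_sites(10, gamma=1.5)
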