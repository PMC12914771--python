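"""Synthetic sort-seq generator: landscapes, libraries, gates, reads, curves."""

import math

import numpy as np
import pytest
from scipy import stats

from timpdesign import PRESORT, Stringency, count_reads, enrichment_ratios
from timpdesign.synthetic import (
    DEFAULT_MUTATION_MIX,
    SortSimulationConfig,
    emit_reads,
    make_landscape,
    make_reference_scheme,
    sample_library,
    simulate_inhibition_data,
    simulate_sort_counts,
    true_log2_er,
)


class TestReferenceScheme:
    def test_planted_wt_letters(self, scheme):
        assert scheme.wt_signature == "SINSVHT"
        assert len(scheme.wt_sequence) == 127

    def test_deterministic(self):
        assert make_reference_scheme().wt_sequence == make_reference_scheme().wt_sequence


class TestLandscape:
    def test_wt_energy_zero(self, scheme):
        ls = make_landscape(scheme, seed=1)
        assert ls.energy(scheme.wt_signature) == 0.0

    def test_seed_reproducible(self, scheme):
        a = make_landscape(scheme, seed=5)
        b = make_landscape(scheme, seed=5)
        assert np.array_equal(a.energies, b.energies)

    def test_additivity_without_epistasis(self, scheme):
        ls = make_landscape(scheme, seed=2)
        wt = scheme.wt_signature
        single1 = "R" + wt[1:]
        single2 = wt[:3] + "W" + wt[4:]
        double = "R" + wt[1:3] + "W" + wt[4:]
        assert ls.energy(double) == pytest.approx(
            ls.energy(single1) + ls.energy(single2), abs=1e-12
        )

    def test_epistasis_breaks_additivity_but_not_wt(self, scheme):
        ls = make_landscape(scheme, seed=3, epistasis_pairs=21)
        assert ls.energy(scheme.wt_signature) == 0.0
        assert len(ls.epistasis) == 21


class TestLibrarySampling:
    def test_mutation_histogram_matches_mix(self, scheme):
        n = 100_000
        config = SortSimulationConfig(n_variants=n, seed=4)
        library = sample_library(scheme, config)
        counts = {k: 0 for k in DEFAULT_MUTATION_MIX}
        for sig, abundance in library.items():
            k = scheme.num_mutations(sig)
            if k in counts and sig != scheme.wt_signature:
                counts[k] += abundance
        for k, p in DEFAULT_MUTATION_MIX.items():
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[k] / n - p) < 3 * se + 1 / n

    def test_all_singles_config(self, scheme):
        config = SortSimulationConfig(n_variants=500, mutation_mix={1: 1.0}, seed=5)
        library = sample_library(scheme, config)
        for sig in library:
            if sig != scheme.wt_signature:
                assert scheme.num_mutations(sig) == 1

    def test_wt_always_present_and_seed_reproducible(self, scheme):
        config = SortSimulationConfig(n_variants=200, seed=6)
        a = sample_library(scheme, config)
        assert scheme.wt_signature in a
        assert a == sample_library(scheme, config)


class TestSortSimulation:
    def test_gate_totals_match_configured_reads(self, scheme):
        config = SortSimulationConfig(n_variants=300, reads_per_gate=50_000, seed=7)
        library = sample_library(scheme, config)
        landscape = make_landscape(scheme, seed=7)
        tables = simulate_sort_counts(library, landscape, config)
        for stringency in (Stringency.PRESORT, Stringency.LOW, Stringency.HIGH):
            assert tables[stringency].total_reads == 50_000

    def test_step_gate_partitions_by_energy(self, scheme):
        config = SortSimulationConfig(
            n_variants=200, reads_per_gate=20_000, gate_tau=0.0, seed=8
        )
        library = sample_library(scheme, config)
        landscape = make_landscape(scheme, seed=8)
        tables = simulate_sort_counts(library, landscape, config)
        high_energies = [
            landscape.energy(sig) for sig in tables[Stringency.HIGH].counts
        ]
        low_energies = [landscape.energy(sig) for sig in tables[Stringency.LOW].counts]
        assert all(e > config.gate_mu for e in high_energies)
        assert all(e <= config.gate_mu for e in low_energies)

    def test_deep_read_log2_er_tracks_energy(self, scheme):
        # In the deep-read limit the measured high-gate log2 ER rank-orders
        # variants by their true energy.
        config = SortSimulationConfig(
            n_variants=400, reads_per_gate=10_000_000, gate_tau=0.5, seed=9
        )
        library = sample_library(scheme, config)
        landscape = make_landscape(scheme, seed=9)
        tables = simulate_sort_counts(library, landscape, config)
        records, _ = enrichment_ratios(
            tables[Stringency.PRESORT], tables[Stringency.HIGH], scheme
        )
        energies = [landscape.energy(r.signature) for r in records]
        rho = stats.spearmanr([r.log2_er for r in records], energies).statistic
        assert rho >= 0.9

    def test_swapping_gates_negates_log2_er(self, scheme):
        config = SortSimulationConfig(n_variants=100, reads_per_gate=500_000, seed=10)
        library = sample_library(scheme, config)
        landscape = make_landscape(scheme, seed=10)
        tables = simulate_sort_counts(library, landscape, config)
        fwd, _ = enrichment_ratios(
            tables[Stringency.PRESORT], tables[Stringency.HIGH], scheme
        )
        rev, _ = enrichment_ratios(
            tables[Stringency.HIGH], tables[Stringency.PRESORT], scheme
        )
        rev_map = {r.signature: r.log2_er for r in rev}
        for r in fwd:
            assert rev_map[r.signature] == pytest.approx(-r.log2_er, abs=1e-12)

    def test_true_log2_er_zero_at_wt(self, scheme):
        config = SortSimulationConfig(seed=11)
        landscape = make_landscape(scheme, seed=11)
        truth = true_log2_er([scheme.wt_signature], landscape, config)
        assert truth[0] == 0.0


class TestEmitReads:
    def small_table(self, scheme, seed):
        config = SortSimulationConfig(n_variants=50, seed=seed)
        library = sample_library(scheme, config)
        return {sig: min(ab, 5) for sig, ab in library.items()}, config

    def test_clean_reads_roundtrip(self, scheme):
        table, config = self.small_table(scheme, 12)
        reads = [seq for _, seq in emit_reads(table, scheme, config)]
        recovered = count_reads(reads, PRESORT, scheme)
        assert recovered.counts == table
        assert recovered.rejection_stats == {}

    def test_corruption_rates_observed(self, scheme):
        config = SortSimulationConfig(
            n_variants=2000, off_target_mutation_rate=0.1, truncation_rate=0.05, seed=13
        )
        library = sample_library(scheme, config)
        reads = [seq for _, seq in emit_reads(library, scheme, config)]
        n = len(reads)
        recovered = count_reads(reads, PRESORT, scheme)
        rejected = sum(recovered.rejection_stats.values())
        # Truncation (5%) always rejects; off-target (10%) rejects unless truncated first.
        expected = 0.05 + 0.10 * 0.95
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(rejected / n - expected) < 3 * se
        assert recovered.rejection_stats.get("TOO_SHORT", 0) > 0
        assert recovered.rejection_stats.get("OFF_TARGET_MUTATION", 0) > 0

    def test_truncated_reads_never_counted(self, scheme):
        config = SortSimulationConfig(n_variants=100, truncation_rate=1.0, seed=14)
        library = sample_library(scheme, config)
        reads = [seq for _, seq in emit_reads(library, scheme, config)]
        recovered = count_reads(reads, PRESORT, scheme)
        assert recovered.counts == {}

    def test_headers_carry_truth_signature(self, scheme):
        table, config = self.small_table(scheme, 15)
        for header, seq in emit_reads(table, scheme, config):
            sig = header.split("|")[1].removeprefix("sig=")
            assert sig in table


class TestInhibitionSimulation:
    def test_noiseless_matches_forward_model(self):
        from timpdesign import morrison_relative_velocity, ki_to_kiapp

        ki, e, s, km = 2.0, 0.325, 7.5, 4.75
        grid = [0.0, 1.0, 4.0, 16.0]
        (curve,) = simulate_inhibition_data(ki, e, s, km, grid)
        kiapp = ki_to_kiapp(ki, s, km)
        expected = morrison_relative_velocity(e, np.array(grid), kiapp)
        assert np.array_equal(curve.relative_velocity, expected)

    def test_replicates_differ_iff_noisy(self):
        grid = [0.0, 1.0, 4.0, 16.0]
        quiet = simulate_inhibition_data(2.0, 0.325, 7.5, 4.75, grid, replicates=2)
        noisy = simulate_inhibition_data(
            2.0, 0.325, 7.5, 4.75, grid, noise_sd=0.05, replicates=2, seed=1
        )
        assert np.array_equal(quiet[0].relative_velocity, quiet[1].relative_velocity)
        assert not np.array_equal(noisy[0].relative_velocity, noisy[1].relative_velocity)
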