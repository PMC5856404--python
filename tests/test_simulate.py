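"""Synthetic-data generators: dilution arithmetic, molecule conservation,
count structure, artifact mode, full-process controls and droplets."""

import numpy as np
import pytest

from amplicall import (
    ArtifactConfig,
    BackgroundModel,
    TruthVariant,
    dilute_truth,
    make_toy_panel,
    sample_molecules,
    simulate_counts,
    simulate_droplets,
    simulate_full_process_control,
    split_replicates,
)
from amplicall.simulate import MoleculePool, SimulationError


def _snv(panel, site_index, stock_af, expected_af=None):
    chrom, pos = panel.positions()[site_index]
    ref = panel.ref_base(chrom, pos)
    alt = "A" if ref != "A" else "C"
    return TruthVariant(
        chrom, pos, ref, alt, "SNV", stock_af,
        stock_af if expected_af is None else expected_af,
    )


class TestDilution:
    def test_tier_arithmetic(self):
        v = TruthVariant("chr1", 5, "G", "T", "SNV", 0.013, 0.013)
        assert dilute_truth([v], 0.5)[0].expected_af == pytest.approx(0.0065)
        assert dilute_truth([v], 1.0)[0].expected_af == pytest.approx(0.013)
        assert dilute_truth([v], 1 / 16)[0].expected_af == pytest.approx(0.0008125)

    def test_order_preserved_and_bad_factor_rejected(self):
        vs = [TruthVariant("chr1", p, "G", "T", "SNV", 0.01, 0.01) for p in (9, 3, 7)]
        assert [v.pos for v in dilute_truth(vs, 0.25)] == [9, 3, 7]
        for factor in (0.0, -0.1, 1.5):
            with pytest.raises(SimulationError):
                dilute_truth(vs, factor)


class TestMoleculeSampling:
    def test_degenerate_allele_fractions(self, toy_panel):
        v0 = _snv(toy_panel, 0, 0.5, expected_af=0.0)
        v1 = _snv(toy_panel, 1, 1.0, expected_af=1.0)
        pool = sample_molecules([v0, v1], 5000, seed=1)
        assert pool.mutant_copies[v0] == 0
        assert pool.mutant_copies[v1] == 5000

    def test_binomial_mean_recovered_over_seeds(self, toy_panel):
        v = _snv(toy_panel, 2, 0.0025)
        draws = np.array(
            [sample_molecules([v], 8000, seed=s).mutant_copies[v] for s in range(10_000)]
        )
        expected = 8000 * 0.0025  # 20 copies
        se = np.sqrt(expected * (1 - 0.0025) / len(draws))
        assert abs(draws.mean() - expected) < 3 * se

    def test_bit_reproducible(self, toy_panel):
        v = _snv(toy_panel, 3, 0.01)
        a = sample_molecules([v], 8000, seed=99)
        b = sample_molecules([v], 8000, seed=99)
        assert a.mutant_copies == b.mutant_copies


class TestReplicateSplit:
    def test_conservation(self, toy_panel):
        v = _snv(toy_panel, 0, 0.01)
        pool = MoleculePool(total_ac=8000, mutant_copies={v: 20}, seed=0)
        reps = split_replicates(pool, 8, seed=1)
        assert sum(r.total_ac for r in reps) == 8000
        assert sum(r.mutant_copies[v] for r in reps) == 20

    def test_zero_copies_split_to_zero(self, toy_panel):
        v = _snv(toy_panel, 0, 0.01)
        pool = MoleculePool(total_ac=100, mutant_copies={v: 0}, seed=0)
        assert all(r.mutant_copies[v] == 0 for r in split_replicates(pool, 4, seed=2))

    def test_equal_expected_share(self, toy_panel):
        v = _snv(toy_panel, 0, 0.01)
        pool = MoleculePool(total_ac=160, mutant_copies={v: 16}, seed=0)
        n_trials = 2000
        shares = np.array(
            [split_replicates(pool, 8, seed=s)[0].mutant_copies[v] for s in range(n_trials)]
        )
        expected = 16 / 8
        se = np.sqrt(16 * (1 / 8) * (7 / 8) / n_trials)
        assert abs(shares.mean() - expected) < 3 * se

    def test_fewer_than_two_replicates_rejected(self, toy_panel):
        pool = MoleculePool(total_ac=10, mutant_copies={}, seed=0)
        with pytest.raises(SimulationError):
            split_replicates(pool, 1, seed=0)


class TestCountSimulation:
    def test_zero_background_zero_mutants_is_pure_reference(self, toy_panel):
        bg = BackgroundModel.uniform(toy_panel, rate=0.0, rho=0.0)
        pool = MoleculePool(total_ac=1000, mutant_copies={}, seed=0)
        reps = split_replicates(pool, 2, seed=1)
        tensor = simulate_counts(reps, toy_panel, bg, seed=2)
        df = tensor.df
        for b in "ACGT":
            nonref = df[df["ref"] != b]
            assert (nonref[b] == 0).all()

    def test_high_depth_alt_fraction_converges_to_molecule_fraction(self, toy_panel):
        bg = BackgroundModel.uniform(toy_panel, rate=0.0, rho=0.0)
        v = _snv(toy_panel, 5, 0.04)
        pool = MoleculePool(total_ac=10_000, mutant_copies={v: 400}, seed=0)
        reps = split_replicates(pool, 2, seed=1)
        tensor = simulate_counts(reps, toy_panel, bg, reads_per_molecule=100.0, seed=2)
        rows = tensor.df[tensor.df["pos"] == v.pos]
        frac = rows[v.alt].sum() / rows[list("ACGT")].sum().sum()
        assert frac == pytest.approx(0.04, rel=0.05)

    def test_oxidative_mode_scales_only_gt_ca_errors(self, toy_panel):
        bg = BackgroundModel.uniform(toy_panel, rate=2e-4, rho=0.0)
        pool = MoleculePool(total_ac=4000, mutant_copies={}, seed=0)
        reps = split_replicates(pool, 8, seed=1)
        plain = simulate_counts(reps, toy_panel, bg, seed=5)
        damaged = simulate_counts(
            reps, toy_panel, bg,
            artifact=ArtifactConfig(oxidative_mode=True, gt_multiplier=10.0),
            seed=5,
        )

        def rates(tensor, ref, alt):
            rows = tensor.df[tensor.df["ref"] == ref]
            return rows[alt].sum() / rows[list("ACGT")].sum().sum()

        for ref, alt in (("G", "T"), ("C", "A")):
            ratio = rates(damaged, ref, alt) / rates(plain, ref, alt)
            assert 6.0 < ratio < 14.0  # ~10x with sampling noise
        for ref, alt in (("A", "G"), ("T", "C")):
            ratio = rates(damaged, ref, alt) / rates(plain, ref, alt)
            assert 0.6 < ratio < 1.4

    def test_same_seed_same_tensor(self, toy_panel):
        bg = BackgroundModel.uniform(toy_panel, rate=1e-4, rho=1e-3)
        pool = MoleculePool(total_ac=1000, mutant_copies={}, seed=0)
        reps = split_replicates(pool, 2, seed=1)
        a = simulate_counts(reps, toy_panel, bg, seed=3)
        b = simulate_counts(reps, toy_panel, bg, seed=3)
        assert a.df.equals(b.df)


class TestFullProcessControl:
    def test_zero_efficiency_recovers_nothing(self):
        fpc = simulate_full_process_control(0.05, 10_000, 5_000, 0.0, seed=1)
        assert fpc.recovered_spike_copies == 0
        assert fpc.expected_measured_af == 0.0

    def test_equal_copies_full_efficiency_halves_af(self):
        fpc = simulate_full_process_control(0.05, 8_000, 8_000, 1.0, seed=1)
        assert fpc.expected_measured_af == pytest.approx(0.025)

    def test_half_recovery_dilutes_below_nominal_tier(self):
        for seed in range(20):
            fpc = simulate_full_process_control(0.05, 10_000, 6_000, 0.5, seed=seed)
            assert fpc.expected_measured_af < 0.05
            assert fpc.expected_measured_af <= 0.05  # never exceeds the spike AF


class TestDroplets:
    def test_all_rates_zero_all_negative(self):
        d = simulate_droplets(0.0, 0.0, 20_000, seed=1)
        assert d.negative == d.n_droplets == 20_000

    def test_poisson_occupancy_fraction(self):
        d = simulate_droplets(0.0, 1.0, 20_000, seed=2)
        frac = d.wt_positive / d.n_droplets
        expect = 1 - np.exp(-1)
        se = np.sqrt(expect * (1 - expect) / 20_000)
        assert abs(frac - expect) < 3 * se

    def test_false_positive_rate_mean(self):
        counts = [
            simulate_droplets(0.0, 0.0, 20_000, fpr_lambda=1e-4, seed=s).mut_positive
            for s in range(300)
        ]
        expect = 20_000 * (1 - np.exp(-1e-4))  # ~2
        se = np.sqrt(expect / len(counts))
        assert abs(np.mean(counts) - expect) < 3 * se

    def test_classes_sum_to_droplets(self):
        d = simulate_droplets(0.3, 1.2, 15_000, fpr_lambda=1e-4, seed=3)
        assert d.mut_single_pos + d.wt_single_pos + d.double_pos + d.negative == 15_000
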