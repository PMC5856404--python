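"""Threshold calibration, variant calling end to end, contamination
checks and copy-number inference."""

import numpy as np
import pandas as pd
import pytest

from amplicall import (
    AlleleCountTensor,
    BackgroundModel,
    ReplicateCallingModel,
    TruthVariant,
    calibrate_threshold,
    call_variants,
    check_contamination,
    infer_cnv,
    make_toy_panel,
    sample_molecules,
    simulate_counts,
    simulate_wildtype_sample,
    split_replicates,
)
from amplicall.calling import CallingError, Thresholds


def _mk_thresholds(snv=30.0, indel=30.0):
    return Thresholds(snv=snv, indel=indel, specificity_budget=3e-6, n_sim=0, null_max_lr=0.0)


def _variant_tensor(panel, bg, site_index, af, input_ac, seed, vclass="SNV"):
    chrom, pos = panel.positions()[site_index]
    ref = panel.ref_base(chrom, pos)
    if vclass == "SNV":
        alt = "A" if ref != "A" else "C"
        v = TruthVariant(chrom, pos, ref, alt, "SNV", af, af)
    else:
        deleted = "".join(panel.ref_base(chrom, pos + i) for i in range(15))
        v = TruthVariant(chrom, pos, deleted, deleted[0], "deletion", af, af)
    pool = sample_molecules([v], input_ac, seed=seed)
    reps = split_replicates(pool, 8, seed=seed + 1)
    tensor = simulate_counts(reps, panel, bg, seed=seed + 2, sample="S")
    return tensor, v, pool


class TestCalibration:
    def test_zero_noise_background_produces_no_false_calls(self, toy_panel):
        silent = BackgroundModel.uniform(toy_panel, rate=0.0, rho=0.0)
        thr = calibrate_threshold(silent, toy_panel, n_sim=20, seed=0)
        wt = simulate_wildtype_sample(toy_panel, silent, seed=1)
        calls = call_variants(wt, silent, thr, toy_panel)
        assert [c for c in calls if c.status == "called"] == []

    def test_loosening_budget_never_raises_threshold(self, toy_panel, flat_background):
        tight = calibrate_threshold(
            flat_background, toy_panel, specificity_budget=3e-6, n_sim=30, seed=5
        )
        loose = calibrate_threshold(
            flat_background, toy_panel, specificity_budget=3e-5, n_sim=30, seed=5
        )
        assert loose.snv <= tight.snv

    def test_unreachable_budget_reports_diagnostics(self, toy_panel, flat_background):
        from amplicall.calling import CalibrationError

        with pytest.raises(CalibrationError) as err:
            calibrate_threshold(
                flat_background, toy_panel, n_sim=30, seed=5, max_threshold=0.5
            )
        assert err.value.diagnostic_positions


class TestCallVariants:
    def test_wildtype_sample_yields_no_calls(self, study_fixture):
        wt = simulate_wildtype_sample(
            study_fixture.panel, study_fixture.true_background, seed=77, sample="WT"
        )
        calls = call_variants(
            wt, study_fixture.fitted_background, study_fixture.thresholds,
            study_fixture.panel,
        )
        assert [c for c in calls if c.status == "called"] == []

    def test_low_input_high_af_variant_called_with_accurate_af(self, study_fixture):
        # 2.5% AF at 2,000 amplifiable copies: the fully-sensitive regime
        tensor, v, _ = _variant_tensor(
            study_fixture.panel, study_fixture.true_background,
            site_index=123, af=0.025, input_ac=2000, seed=11,
        )
        calls = call_variants(
            tensor, study_fixture.fitted_background, study_fixture.thresholds,
            study_fixture.panel,
        )
        hits = [
            c for c in calls
            if c.status == "called" and c.pos == v.pos and c.alt == v.alt
        ]
        assert len(hits) == 1
        assert 0.015 <= hits[0].af_mle <= 0.035

    def test_ultralow_indel_callable_when_molecules_survive(self, study_fixture):
        # a 15-base deletion at 0.02% AF with 12,450 input copies and a
        # clean indel background: callable in the favorable draws where a
        # handful of mutant molecules survive sampling (a best-case
        # demonstration, not a sensitivity guarantee at this AF)
        panel = study_fixture.panel
        for seed in range(60):
            tensor, v, pool = _variant_tensor(
                panel, study_fixture.true_background,
                site_index=40, af=0.0002, input_ac=12_450, seed=100 + seed,
                vclass="deletion",
            )
            if pool.mutant_copies[v] >= 4:
                break
        assert pool.mutant_copies[v] >= 4
        calls = call_variants(
            tensor, study_fixture.fitted_background, study_fixture.thresholds,
            panel,
        )
        indels = [c for c in calls if c.variant_class == "deletion" and c.status == "called"]
        assert len(indels) == 1
        assert indels[0].ref[1:] == v.ref and indels[0].alt == indels[0].ref[0]

    def test_model_results_facade_reports_calls(self, study_fixture):
        tensor, v, _ = _variant_tensor(
            study_fixture.panel, study_fixture.true_background,
            site_index=321, af=0.05, input_ac=8000, seed=31,
        )
        results = ReplicateCallingModel(
            tensor, study_fixture.fitted_background, study_fixture.panel
        ).fit(study_fixture.thresholds)
        assert len(results.called) == 1
        assert str(v.pos + 1) in results.summary()
        frame = results.frame()
        assert {"af_mle", "pooled_af", "lr", "status"} <= set(frame.columns)

    def test_low_confidence_background_requires_acknowledgement(self, toy_panel):
        bg = BackgroundModel.uniform(toy_panel, rate=1e-4, rho=0.0)
        bg.snv["low_confidence"] = True
        tensor, v, _ = _variant_tensor(toy_panel, bg, 5, 0.05, 8000, seed=3)
        thr = _mk_thresholds()
        flagged = call_variants(tensor, bg, thr, toy_panel)
        assert all(c.status == "low_confidence_region" for c in flagged)
        acknowledged = call_variants(
            tensor, bg, thr, toy_panel, allow_low_confidence=True
        )
        assert any(c.status == "called" for c in acknowledged)

    def test_failing_depth_qc_rejected(self, toy_panel, flat_background):
        tensor, *_ = _variant_tensor(toy_panel, flat_background, 5, 0.05, 8000, seed=3)
        with pytest.raises(CallingError, match="QC"):
            call_variants(
                tensor, flat_background, _mk_thresholds(), toy_panel,
                min_mean_depth=1e9,
            )

    def test_background_panel_mismatch_rejected(self, toy_panel, flat_background):
        other = make_toy_panel(n_amplicons=2, insert_len=60, seed=77)
        bg_other = BackgroundModel.uniform(other, rate=1e-4)
        tensor, *_ = _variant_tensor(toy_panel, flat_background, 5, 0.05, 8000, seed=3)
        from amplicall.background import BackgroundError

        with pytest.raises((BackgroundError, CallingError)):
            call_variants(tensor, bg_other, _mk_thresholds(), toy_panel)


class TestContamination:
    def test_clean_genotype_profile(self):
        afs = [0.00, 0.49, 1.00, 0.51, 0.0, 1.0, 0.5, 0.02, 0.98, 0.5]
        assert check_contamination(afs, [1000] * 10).status == "clean"

    def test_consistent_intermediate_shift_is_contamination(self):
        # a 6% mixture pushes homozygous-reference SNPs to ~0.06
        afs = [0.06] * 5 + [0.5, 1.0, 0.0, 0.5, 1.0]
        assert check_contamination(afs, [1000] * 10).status == "contaminated"

    def test_fingerprint_mismatch_is_possible_swap(self):
        prior = [0.5, 0.5, 0.5, 0.5, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0]
        current = [1.0, 0.0, 1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0]
        rep = check_contamination(current, [1000] * 10, prior_genotypes=prior)
        assert rep.status == "possible_swap"

    def test_insufficient_coverage_is_indeterminate(self):
        assert check_contamination([0.5] * 10, [100] * 10).status == "indeterminate"
        assert check_contamination([0.5] * 5, [1000] * 5).status == "indeterminate"


class TestCnv:
    @pytest.fixture()
    def baseline(self, toy_panel, rng):
        """Amplicon-specific depths, identical across baseline samples
        (the degenerate case where normalization is exact)."""
        amps = [a.amplicon_id for a in toy_panel]
        profile = rng.poisson(2000, size=len(amps)).astype(float)
        return pd.DataFrame(
            np.tile(profile, (6, 1)), columns=amps, index=[f"B{i}" for i in range(6)]
        )

    @pytest.fixture()
    def noisy_baseline(self, toy_panel, rng):
        amps = [a.amplicon_id for a in toy_panel]
        return pd.DataFrame(
            rng.poisson(2000, size=(6, len(amps))).astype(float),
            columns=amps,
            index=[f"B{i}" for i in range(6)],
        )

    def test_baseline_sample_recovers_two_copies(self, toy_panel, baseline):
        test = baseline.iloc[[0]].rename(index={"B0": "T"})
        calls = infer_cnv(test, baseline, toy_panel)["T"]
        assert all(c.copy_number == pytest.approx(2.0) for c in calls)
        assert all(c.status == "normal" for c in calls)

    def test_doubled_gene_reports_four_copies(self, toy_panel, baseline):
        test = baseline.iloc[[0]].rename(index={"B0": "T"})
        gene_amps = sorted(toy_panel.genes["GENE01"])
        test[gene_amps] = test[gene_amps] * 2
        calls = {c.gene: c for c in infer_cnv(test, baseline, toy_panel)["T"]}
        assert calls["GENE01"].copy_number == pytest.approx(4.0, abs=0.1)
        assert calls["GENE01"].status == "amplified"
        for gene, call in calls.items():
            if gene != "GENE01":
                assert call.copy_number == pytest.approx(2.0, abs=0.1)

    def test_noisy_cohort_stays_near_two_copies(self, toy_panel, noisy_baseline, rng):
        amps = [a.amplicon_id for a in toy_panel]
        test = pd.DataFrame(
            rng.poisson(2000, size=(1, len(amps))).astype(float), columns=amps, index=["T"]
        )
        calls = infer_cnv(test, noisy_baseline, toy_panel)["T"]
        assert all(c.copy_number == pytest.approx(2.0, abs=0.3) for c in calls)

    def test_library_size_effect_cancels(self, toy_panel, baseline):
        test = (baseline.iloc[[0]] * 3).rename(index={"B0": "T"})
        calls = infer_cnv(test, baseline, toy_panel)["T"]
        assert all(c.copy_number == pytest.approx(2.0) for c in calls)

    def test_single_amplicon_gene_flagged(self, baseline, toy_panel, rng):
        from amplicall.panel import PanelDesign

        amps = list(toy_panel.amplicons)
        relabeled = [
            type(a)(**{**a.__dict__, "gene": f"G{i}"}) if i == 0 else a
            for i, a in enumerate(amps)
        ]
        panel = PanelDesign(relabeled)
        test = baseline.iloc[[0]].rename(index={"B0": "T"})
        calls = {c.gene: c for c in infer_cnv(test, baseline, panel)["T"]}
        assert calls["G0"].low_confidence

    def test_small_baseline_rejected(self, toy_panel, baseline):
        with pytest.raises(CallingError, match=">= 5"):
            infer_cnv(baseline.iloc[[0]], baseline.iloc[:4], toy_panel)
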