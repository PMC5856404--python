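"""Background-model fitting: degenerate inputs, parameter recovery,
monotonicity, artifact elevation and leave-one-out indel nulls."""

import numpy as np
import pandas as pd
import pytest

from amplicall import (
    AlleleCountTensor,
    BackgroundModel,
    batch_indel_background,
    make_toy_panel,
    simulate_wildtype_sample,
)
from amplicall.background import PSEUDO_DEN, PSEUDO_NUM, BackgroundError
from amplicall.counts import BASES


def _clean_tensor(panel, samples, depth=2000, n_replicates=2):
    """Controls with zero alt reads everywhere at fixed depth."""
    rows = []
    for s in samples:
        for r in range(n_replicates):
            for chrom, pos in panel.positions():
                ref = panel.ref_base(chrom, pos)
                row = {
                    "sample": s, "replicate": r + 1, "amplicon_id": "x",
                    "chrom": chrom, "pos": pos, "ref": ref,
                    "A": 0, "C": 0, "G": 0, "T": 0,
                }
                row[ref] = depth
                rows.append(row)
    return AlleleCountTensor(pd.DataFrame(rows))


@pytest.fixture(scope="module")
def small_panel():
    return make_toy_panel(n_amplicons=2, insert_len=50, seed=3)


class TestFit:
    def test_zero_alt_controls_hit_pseudocount_floor(self, small_panel):
        tensor = _clean_tensor(small_panel, [f"C{i}" for i in range(4)], depth=1000)
        model = BackgroundModel.fit(tensor, small_panel)
        pooled_depth = 2000  # 2 replicates x 1000
        floor = PSEUDO_NUM / (pooled_depth + PSEUDO_DEN)
        assert np.allclose(model.snv["mean_rate"], floor)
        assert (model.snv["rho"] == 0).all()

    def test_constant_error_rate_recovered_within_20_percent(self, small_panel):
        truth = BackgroundModel.uniform(small_panel, rate=1e-3, rho=0.0)
        tensors = [
            simulate_wildtype_sample(
                small_panel, truth, input_ac=10_000, n_replicates=2,
                reads_per_molecule=1.0, seed=50 + i, sample=f"C{i}",
            )
            for i in range(20)
        ]
        model = BackgroundModel.fit(AlleleCountTensor.concat(tensors), small_panel)
        assert model.snv["mean_rate"].mean() == pytest.approx(1e-3, rel=0.2)

    def test_betabinomial_parameters_recovered(self, small_panel):
        # known (mean, rho): the pooled moment estimator should recover both
        truth = BackgroundModel.uniform(small_panel, rate=5e-4, rho=2e-3)
        estimates = []
        for rep in range(10):
            tensors = [
                simulate_wildtype_sample(
                    small_panel, truth, input_ac=8000, n_replicates=8,
                    seed=1000 * rep + i, sample=f"C{i}",
                )
                for i in range(20)
            ]
            model = BackgroundModel.fit(AlleleCountTensor.concat(tensors), small_panel)
            estimates.append((model.snv["mean_rate"].mean(), model.snv["rho"].iloc[0]))
        means, rhos = np.array(estimates).T
        assert means.mean() == pytest.approx(5e-4, rel=0.1)
        assert rhos.mean() == pytest.approx(2e-3, rel=0.35)

    def test_fewer_than_three_controls_rejected(self, small_panel):
        tensor = _clean_tensor(small_panel, ["C0", "C1"])
        with pytest.raises(BackgroundError, match=">= 3"):
            BackgroundModel.fit(tensor, small_panel)

    def test_low_depth_sites_flagged_low_confidence(self, small_panel):
        tensor = _clean_tensor(small_panel, [f"C{i}" for i in range(4)], depth=10)
        model = BackgroundModel.fit(tensor, small_panel, min_depth=100)
        assert model.snv["low_confidence"].all()

    def test_adding_noisier_control_never_decreases_mean(self, small_panel):
        base = _clean_tensor(small_panel, [f"C{i}" for i in range(4)], depth=1000)
        model_before = BackgroundModel.fit(base, small_panel)
        noisy = _clean_tensor(small_panel, ["C9"], depth=1000)
        alt_cols = noisy.df["ref"].map(lambda r: next(b for b in BASES if b != r))
        for i, alt in enumerate(alt_cols):
            # 0.5% errors in the extra control, at constant total depth
            noisy.df.loc[i, alt] = 5
            noisy.df.loc[i, noisy.df.loc[i, "ref"]] -= 5
        model_after = BackgroundModel.fit(
            AlleleCountTensor.concat([base, noisy]), small_panel
        )
        assert (
            model_after.snv["mean_rate"] >= model_before.snv["mean_rate"] - 1e-12
        ).all()

    def test_round_trip_tsv(self, small_panel, tmp_path):
        model = BackgroundModel.uniform(small_panel, rate=1e-4, rho=1e-3)
        model.to_tsv(tmp_path / "bg.tsv")
        back = BackgroundModel.from_tsv(tmp_path / "bg.tsv")
        pd.testing.assert_frame_equal(model.snv, back.snv)


class TestArtifactMode:
    def test_artifact_controls_elevate_only_gt_entries(self, small_panel):
        truth = BackgroundModel.uniform(small_panel, rate=2e-4, rho=0.0)
        damaged = truth.with_artifact(10.0)
        fits = {}
        for label, gen in (("plain", truth), ("oxo", damaged)):
            tensors = [
                simulate_wildtype_sample(
                    small_panel, gen, input_ac=8000, n_replicates=4,
                    seed=300 + i, sample=f"C{i}",
                )
                for i in range(12)
            ]
            fits[label] = BackgroundModel.fit(
                AlleleCountTensor.concat(tensors), small_panel
            ).snv
        merged = fits["plain"].merge(
            fits["oxo"], on=["chrom", "pos", "ref", "alt"], suffixes=("_p", "_o")
        )
        gt = merged[((merged.ref == "G") & (merged.alt == "T"))
                    | ((merged.ref == "C") & (merged.alt == "A"))]
        other = merged[~merged.index.isin(gt.index)]
        assert gt["mean_rate_o"].mean() > 5 * gt["mean_rate_p"].mean()
        assert other["mean_rate_o"].mean() == pytest.approx(
            other["mean_rate_p"].mean(), rel=0.25
        )


class TestIndelBatchBackground:
    def _batch(self, panel, indel_counts: dict[str, int], depth=5000):
        chrom, pos = panel.positions()[10]
        ref = panel.ref_base(chrom, pos)
        rows = []
        for s, c in indel_counts.items():
            row = {
                "sample": s, "replicate": 1, "amplicon_id": "x",
                "chrom": chrom, "pos": pos, "ref": ref,
                "A": 0, "C": 0, "G": 0, "T": 0, "del:15": c,
            }
            row[ref] = depth - c
            rows.append(row)
        return AlleleCountTensor(pd.DataFrame(rows)), chrom, pos

    def test_clean_batch_gives_floor_rate(self, small_panel):
        tensor, chrom, pos = self._batch(
            small_panel, {f"S{i}": 0 for i in range(5)}
        )
        table = batch_indel_background(tensor, chrom, pos, "del:15")
        assert np.allclose(table["mean_rate"], PSEUDO_NUM / (5000 + PSEUDO_DEN))

    def test_true_indel_excluded_from_own_background(self, small_panel):
        counts = {"S0": 250, "S1": 0, "S2": 0, "S3": 0, "S4": 0}  # S0 has 5% AF
        tensor, chrom, pos = self._batch(small_panel, counts)
        table = batch_indel_background(tensor, chrom, pos, "del:15")
        floor = PSEUDO_NUM / (5000 + PSEUDO_DEN)
        assert table.loc["S0", "mean_rate"] == pytest.approx(floor, rel=1e-6)
        # the others see S0's signal in their background
        assert table.loc["S1", "mean_rate"] > 100 * floor

    def test_uniform_artifact_rate_recovered_for_everyone(self, small_panel):
        counts = {f"S{i}": 5 for i in range(6)}  # 5/5000 = 1e-3 everywhere
        tensor, chrom, pos = self._batch(small_panel, counts)
        table = batch_indel_background(tensor, chrom, pos, "del:15")
        assert np.allclose(table["mean_rate"], (5 + PSEUDO_NUM) / (5000 + PSEUDO_DEN))

    def test_small_batch_instructs_fallback(self, small_panel):
        tensor, chrom, pos = self._batch(small_panel, {f"S{i}": 0 for i in range(3)})
        with pytest.raises(BackgroundError, match="control cohort"):
            batch_indel_background(tensor, chrom, pos, "del:15")
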