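"""End-to-end simulation studies: dilution-series detection grids,
allele-fraction recovery, and wild-type specificity runs.

These reproduce the *structure* of an analytical validation: a truth
background generates the data, an independently fitted background and
calibrated thresholds score it, and detection rates / estimation errors
are tabulated per dilution tier and DNA input.

Default study conditions: a 1 kb toy panel; background error rates
log-normal around 1e-4 per substitution with beta-binomial intra-class
correlation 1e-3 (a few-fold the binomial variance at typical depths);
30 control samples; 8 replicate libraries per sample; 2 sequenced reads
per amplifiable molecule; input tiers of 2,000 / 8,000 / 16,000
amplifiable copies; dilution tiers from 1-1.3% down to 0.06-0.08% AF.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .background import BackgroundModel, simulate_alt_counts
from .calling import Thresholds, calibrate_threshold, call_variants
from .counts import AlleleCountTensor
from .likelihood import integrate_replicates_batch
from .panel import PanelDesign
from .simulate import make_toy_panel, simulate_wildtype_sample

#: dilution tiers as allele-fraction ranges (fractions, not %)
AF_TIERS: list[tuple[float, float]] = [
    (0.0006, 0.0008),
    (0.0013, 0.0016),
    (0.0025, 0.0033),
    (0.0050, 0.0065),
    (0.0100, 0.0130),
]

#: DNA input tiers in amplifiable copies
INPUT_TIERS: list[int] = [2000, 8000, 16000]

READS_PER_MOLECULE = 2.0
N_REPLICATES = 8
N_CONTROLS = 30


@dataclasses.dataclass
class StudyFixture:
    """A calibrated assay: panel, generative truth, fitted null, thresholds."""

    panel: PanelDesign
    true_background: BackgroundModel
    fitted_background: BackgroundModel
    thresholds: Thresholds
    seed: int


def build_study_fixture(
    seed: int = 0,
    n_amplicons: int = 10,
    insert_len: int = 100,
    n_controls: int = N_CONTROLS,
    control_input_ac: int = 8000,
    calibration_sims: int = 200,
    specificity_budget: float = 3e-6,
) -> StudyFixture:
    """Simulate a control cohort, fit the background, calibrate thresholds."""
    rng = np.random.default_rng(seed)
    panel = make_toy_panel(
        n_amplicons=n_amplicons, insert_len=insert_len, n_genes=5, seed=seed
    )
    true_bg = BackgroundModel.random(panel, rng)
    tensors = [
        simulate_wildtype_sample(
            panel, true_bg, input_ac=control_input_ac,
            n_replicates=N_REPLICATES, reads_per_molecule=READS_PER_MOLECULE,
            seed=int(rng.integers(2**31)), sample=f"CTRL{i:02d}",
        )
        for i in range(n_controls)
    ]
    cohort = AlleleCountTensor.concat(tensors)
    fitted = BackgroundModel.fit(cohort, panel)
    mean_depth = READS_PER_MOLECULE * control_input_ac / N_REPLICATES
    thresholds = calibrate_threshold(
        fitted, panel,
        specificity_budget=specificity_budget,
        n_sim=calibration_sims,
        mean_depth=mean_depth,
        n_replicates=N_REPLICATES,
        seed=int(rng.integers(2**31)),
    )
    return StudyFixture(panel, true_bg, fitted, thresholds, seed)


def _site_params(fixture: StudyFixture, n_variants: int, rng: np.random.Generator):
    """Pick variant sites/alts cycling over the panel; return aligned
    generative and fitted background parameters."""
    bg_true = fixture.true_background.snv
    bg_fit = fixture.fitted_background.snv
    rows = rng.choice(len(bg_true), size=n_variants, replace=n_variants > len(bg_true))
    true_mean = bg_true["mean_rate"].to_numpy()[rows]
    true_rho = bg_true["rho"].to_numpy()[rows]
    fit_mean = bg_fit["mean_rate"].to_numpy()[rows]
    fit_rho = bg_fit["rho"].to_numpy()[rows]
    return true_mean, true_rho, fit_mean, fit_rho


def _simulate_variant_counts(
    af: np.ndarray,
    input_ac: int,
    true_mean: np.ndarray,
    true_rho: np.ndarray,
    rng: np.random.Generator,
    n_replicates: int = N_REPLICATES,
    reads_per_molecule: float = READS_PER_MOLECULE,
    fixed_depth: float | None = None,
    molecule_sampling: bool = True,
):
    """Per-variant replicate alt/depth arrays with the full molecule
    bottleneck (or without, for pure estimator studies)."""
    V = len(af)
    R = n_replicates
    rep_tot = rng.multinomial(input_ac, np.full(R, 1.0 / R), size=V)
    if molecule_sampling:
        copies = rng.binomial(input_ac, af)
        mut = np.zeros((V, R), dtype=np.int64)
        for v in range(V):
            mut[v] = rng.multivariate_hypergeometric(rep_tot[v], copies[v])
        mol_frac = mut / np.maximum(rep_tot, 1)
    else:
        mol_frac = np.broadcast_to(af[:, None], (V, R))
    if fixed_depth is not None:
        depth = np.full((V, R), int(fixed_depth), dtype=np.int64)
    else:
        depth = rng.poisson(reads_per_molecule * rep_tot)
    mut_reads = rng.binomial(depth, np.clip(mol_frac, 0.0, 1.0))
    err = simulate_alt_counts(depth, true_mean[:, None], true_rho[:, None], rng)
    alt = np.minimum(mut_reads + err, depth)
    return alt, depth


def detection_rate_grid(
    fixture: StudyFixture,
    n_variants: int = 200,
    af_tiers: list[tuple[float, float]] = AF_TIERS,
    input_tiers: list[int] = INPUT_TIERS,
    seed: int = 1,
) -> pd.DataFrame:
    """Detection rate per (AF tier x DNA input) cell.

    Each cell simulates ``n_variants`` independent variants with the full
    stochastic chain (molecule sampling into the input, multinomial
    replicate split, Poisson depths, binomial mutant reads plus
    beta-binomial background errors) and scores them against the fitted
    background at the calibrated threshold.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for lo, hi in af_tiers:
        for input_ac in input_tiers:
            true_mean, true_rho, fit_mean, fit_rho = _site_params(
                fixture, n_variants, rng
            )
            af = rng.uniform(lo, hi, size=n_variants)
            alt, depth = _simulate_variant_counts(
                af, input_ac, true_mean, true_rho, rng
            )
            af_hat, lr = integrate_replicates_batch(alt, depth, fit_mean, fit_rho)
            detected = (lr >= fixture.thresholds.snv) & (af_hat > 0)
            rows.append(
                {
                    "af_lo_percent": 100 * lo,
                    "af_hi_percent": 100 * hi,
                    "input_ac": input_ac,
                    "n": n_variants,
                    "detected": int(detected.sum()),
                    "detection_rate_percent": 100.0 * detected.mean(),
                }
            )
    return pd.DataFrame(rows)


def af_recovery_study(
    fixture: StudyFixture,
    afs: tuple[float, ...] = (0.001, 0.005, 0.01, 0.05),
    depth: int = 5000,
    n_sims: int = 200,
    seed: int = 2,
) -> pd.DataFrame:
    """Estimator accuracy: median relative error of the joint AF MLE.

    Counts are simulated directly at the stated allele fraction and
    fixed per-replicate depth (no molecule bottleneck — this measures
    the estimator, not assay sensitivity).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for af in afs:
        true_mean, true_rho, fit_mean, fit_rho = _site_params(fixture, n_sims, rng)
        af_arr = np.full(n_sims, af)
        alt, dep = _simulate_variant_counts(
            af_arr, 8 * depth, true_mean, true_rho, rng,
            fixed_depth=depth, molecule_sampling=False,
        )
        af_hat, _ = integrate_replicates_batch(alt, dep, fit_mean, fit_rho)
        rel_err = np.abs(af_hat - af) / af
        rows.append(
            {
                "af_true": af,
                "n": n_sims,
                "median_af_mle": float(np.median(af_hat)),
                "median_relative_error": float(np.median(rel_err)),
            }
        )
    return pd.DataFrame(rows)


def wildtype_false_call_study(
    fixture: StudyFixture,
    n_samples: int = 200,
    input_ac: int = 8000,
    seed: int = 3,
) -> dict:
    """Fresh wild-type samples through the full tensor/caller pipeline;
    returns false-call counts and the per-base rate."""
    rng = np.random.default_rng(seed)
    fp = 0
    for _ in range(n_samples):
        wt = simulate_wildtype_sample(
            fixture.panel, fixture.true_background, input_ac=input_ac,
            n_replicates=N_REPLICATES, reads_per_molecule=READS_PER_MOLECULE,
            seed=int(rng.integers(2**31)), sample="WT",
        )
        calls = call_variants(
            wt, fixture.fitted_background, fixture.thresholds, fixture.panel
        )
        fp += sum(1 for c in calls if c.status == "called")
    bases = fixture.panel.footprint_bases * n_samples
    return {
        "false_calls": fp,
        "n_samples": n_samples,
        "screened_bases": bases,
        "per_base_rate": fp / bases,
    }
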