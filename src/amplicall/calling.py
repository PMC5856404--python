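"""Replicate-aware variant calling, threshold calibration, contamination
checks and depth-based copy-number inference.

Calling logic: every panel position x substitution (and every observed
indel allele) is scored with the joint across-replicate likelihood ratio
against the fitted background null; a site is called when its LR clears
a threshold calibrated so that simulated wild-type samples stay within a
per-base false-call budget.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .background import BackgroundEntry, BackgroundModel, simulate_alt_counts
from .counts import AlleleCountTensor
from .likelihood import (
    integrate_replicates_batch,
    per_replicate_lr,
)
from .panel import PanelDesign
from .variants import CnvCall, ReplicateSupport, VariantCall
from .vcfio import calls_to_frame

# safety margin applied on top of the empirically calibrated threshold so
# the specificity budget holds on samples outside the calibration set
_MARGIN_SCALE = 1.25
_MARGIN_SHIFT = 2.0


class CallingError(ValueError):
    pass


class CalibrationError(RuntimeError):
    def __init__(self, message: str, diagnostic_positions=None):
        super().__init__(message)
        self.diagnostic_positions = diagnostic_positions or []


@dataclasses.dataclass
class Thresholds:
    """Calibrated LR thresholds per variant class, with provenance."""

    snv: float
    indel: float
    specificity_budget: float
    n_sim: int
    null_max_lr: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Thresholds":
        return cls(**json.loads(Path(path).read_text()))


def calibrate_threshold(
    background: BackgroundModel,
    panel: PanelDesign,
    specificity_budget: float = 3e-6,
    n_sim: int = 200,
    mean_depth: float = 2000.0,
    n_replicates: int = 8,
    seed: int = 0,
    max_threshold: float | None = None,
) -> Thresholds:
    """Choose the smallest LR threshold meeting a false-call budget.

    ``n_sim`` wild-type samples are simulated from the background model
    (Poisson depths around ``mean_depth`` per replicate); the threshold
    is the smallest value at which the empirical per-base false-call
    count stays within ``specificity_budget * footprint * n_sim``, then a
    finite-simulation safety margin is applied. The indel threshold is
    calibrated separately against the indel null (the pseudocount floor
    rate, one allele per position), which is far cleaner than the
    substitution background.
    """
    if specificity_budget <= 0:
        raise CalibrationError("specificity_budget must be positive")
    rng = np.random.default_rng(seed)
    bg = background.snv
    n_entries = len(bg)
    n_sites = panel.footprint_bases
    mean = bg["mean_rate"].to_numpy()
    rho = bg["rho"].to_numpy()

    per_base_max = np.empty((n_sim, n_sites))
    for s in range(n_sim):
        depth = rng.poisson(mean_depth, size=(n_entries, n_replicates))
        alt = simulate_alt_counts(depth, mean[:, None], rho[:, None], rng)
        _, lr = integrate_replicates_batch(alt, depth, mean, rho)
        # three substitution rows per base, contiguous after the sort in
        # BackgroundModel; a base is false-called if any of them fires
        per_base_max[s] = lr.reshape(n_sites, 3).max(axis=1)

    flat = np.sort(per_base_max.ravel())[::-1]
    allowed = int(np.floor(specificity_budget * n_sites * n_sim))
    t0 = flat[allowed] + 1e-9 if allowed < flat.size else 0.0
    threshold = _MARGIN_SCALE * t0 + _MARGIN_SHIFT

    # indel null: floor rate, binomial, one candidate allele per position
    floor = np.full(n_sites, background.default_floor)
    zeros = np.zeros(n_sites)
    indel_max = np.empty((n_sim, n_sites))
    for s in range(n_sim):
        depth = rng.poisson(mean_depth, size=(n_sites, n_replicates))
        alt = simulate_alt_counts(depth, floor[:, None], zeros[:, None], rng)
        _, lr = integrate_replicates_batch(alt, depth, floor, zeros)
        indel_max[s] = lr
    iflat = np.sort(indel_max.ravel())[::-1]
    it0 = iflat[allowed] + 1e-9 if allowed < iflat.size else 0.0
    indel_threshold = _MARGIN_SCALE * it0 + _MARGIN_SHIFT

    if max_threshold is not None and threshold > max_threshold:
        worst = np.argsort(per_base_max.max(axis=0))[::-1][:10]
        positions = [panel.positions()[i] for i in worst]
        raise CalibrationError(
            f"budget {specificity_budget} unreachable below threshold "
            f"{max_threshold}; noisiest positions: {positions}",
            diagnostic_positions=positions,
        )
    return Thresholds(
        snv=float(threshold),
        indel=float(indel_threshold),
        specificity_budget=float(specificity_budget),
        n_sim=int(n_sim),
        null_max_lr=float(flat[0]) if flat.size else 0.0,
    )


def _indel_allele_to_vcf(
    panel: PanelDesign, chrom: str, pos: int, allele: str
) -> tuple[int, str, str, str]:
    """Convert an internal indel allele key to anchored VCF representation."""
    kind, payload = allele.split(":", 1)
    anchor_pos = pos - 1
    if not panel.covers(chrom, anchor_pos):
        raise CallingError(
            f"indel at {chrom}:{pos} has no anchor base inside the panel footprint"
        )
    anchor = panel.ref_base(chrom, anchor_pos)
    if kind == "del":
        length = int(payload)
        deleted = "".join(
            panel.ref_base(chrom, p) if panel.covers(chrom, p) else "N"
            for p in range(pos, pos + length)
        )
        return anchor_pos, anchor + deleted, anchor, "deletion"
    if kind == "ins":
        return anchor_pos, anchor, anchor + payload, "insertion"
    raise CallingError(f"unknown indel allele key {allele!r}")


def call_variants(
    sample_counts: AlleleCountTensor,
    background: BackgroundModel,
    thresholds: Thresholds | Mapping[str, float],
    panel: PanelDesign,
    sample: str | None = None,
    min_mean_depth: float = 100.0,
    indel_background: pd.DataFrame | None = None,
    allow_low_confidence: bool = False,
    include_not_called: bool = False,
) -> list[VariantCall]:
    """Score every panel position x substitution plus observed indels.

    ``indel_background`` is an optional per-sample leave-one-out batch
    table (see :func:`amplicall.background.batch_indel_background`);
    absent entries use the background model's floor rate.
    """
    if sample is None:
        samples = sample_counts.samples
        if len(samples) != 1:
            raise CallingError("multiple samples present; pass sample=")
        sample = samples[0]
    thr_snv = thresholds["snv"] if isinstance(thresholds, Mapping) else thresholds.snv
    thr_indel = (
        thresholds["indel"] if isinstance(thresholds, Mapping) else thresholds.indel
    )
    sites, depth, allele_counts = sample_counts.site_matrix(sample)
    if depth.sum(axis=1).mean() < min_mean_depth:
        raise CallingError(
            f"sample {sample!r} fails QC: mean depth "
            f"{depth.sum(axis=1).mean():.1f} < {min_mean_depth}"
        )
    for _, row in sites.iterrows():
        if not panel.covers(row.chrom, row.pos):
            raise CallingError(
                f"sample position {row.chrom}:{row.pos} not in panel footprint"
            )
    bg = background.arrays_for_sites(sites)  # 3 rows per site, aligned
    n_sites = len(sites)
    reps = sorted(sample_counts.df[sample_counts.df["sample"] == sample]["replicate"].unique())

    # --- substitutions ---------------------------------------------------
    alt_mat = np.empty((len(bg), depth.shape[1]), dtype=float)
    depth_mat = np.repeat(depth, 3, axis=0).astype(float)
    site_of_row = np.repeat(np.arange(n_sites), 3)
    for j, r in enumerate(bg.itertuples(index=False)):
        alt_mat[j] = allele_counts[r.alt][site_of_row[j]]
    mean = bg["mean_rate"].to_numpy()
    rho = bg["rho"].to_numpy()
    min_thr = max(min(thr_snv, thr_indel) / 2.0, 2.0)
    af, lr = integrate_replicates_batch(alt_mat, depth_mat, mean, rho, exact_min_lr=min_thr)

    calls: list[VariantCall] = []
    for j in range(len(bg)):
        fired = lr[j] >= thr_snv and af[j] > 0
        if not fired and not include_not_called:
            continue
        r = bg.iloc[j]
        if fired and bool(r.low_confidence) and not allow_low_confidence:
            status = "low_confidence_region"
        elif fired:
            status = "called"
        else:
            status = "not_called"
        entry = BackgroundEntry(float(r.mean_rate), float(r.rho))
        rep_lr = per_replicate_lr(alt_mat[j], depth_mat[j], entry, float(af[j]))
        support = [
            ReplicateSupport(replicate=reps[k], alt=int(alt_mat[j, k]),
                             depth=int(depth_mat[j, k]), lr=rep_lr[k])
            for k in range(depth.shape[1])
        ]
        pooled = float(alt_mat[j].sum() / max(depth_mat[j].sum(), 1.0))
        calls.append(
            VariantCall(
                chrom=r.chrom,
                pos=int(r.pos),
                ref=r.ref,
                alt=r.alt,
                variant_class="SNV",
                af_mle=float(af[j]),
                pooled_af=pooled,
                lr=float(lr[j]),
                status=status,
                replicates=support,
            )
        )

    # --- indel alleles ----------------------------------------------------
    floor = background.default_floor
    for col in sample_counts.indel_columns:
        counts = allele_counts[col]
        for i in np.flatnonzero(counts.sum(axis=1) > 0):
            row = sites.iloc[i]
            if indel_background is not None and sample in indel_background.index:
                mean_i = float(indel_background.loc[sample, "mean_rate"])
                rho_i = float(indel_background.loc[sample, "rho"])
            else:
                mean_i, rho_i = floor, 0.0
            alt_i = counts[i].astype(float)[None, :]
            depth_i = (depth[i] + counts[i]).astype(float)[None, :]
            af_i, lr_i = integrate_replicates_batch(
                alt_i, depth_i, np.array([mean_i]), np.array([rho_i]),
                exact_min_lr=min_thr,
            )
            fired = lr_i[0] >= thr_indel and af_i[0] > 0
            if not fired and not include_not_called:
                continue
            anchor_pos, ref_al, alt_al, vclass = _indel_allele_to_vcf(
                panel, row.chrom, int(row.pos), col
            )
            entry = BackgroundEntry(mean_i, rho_i)
            rep_lr = per_replicate_lr(alt_i[0], depth_i[0], entry, float(af_i[0]))
            support = [
                ReplicateSupport(replicate=reps[k], alt=int(alt_i[0, k]),
                                 depth=int(depth_i[0, k]), lr=rep_lr[k])
                for k in range(depth.shape[1])
            ]
            calls.append(
                VariantCall(
                    chrom=row.chrom,
                    pos=anchor_pos,
                    ref=ref_al,
                    alt=alt_al,
                    variant_class=vclass,
                    af_mle=float(af_i[0]),
                    pooled_af=float(alt_i.sum() / max(depth_i.sum(), 1.0)),
                    lr=float(lr_i[0]),
                    status="called" if fired else "not_called",
                    replicates=support,
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    return calls


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------


class ReplicateCallingModel:
    """Statistical model for one sample's replicate allele counts.

    Ties the count tensor to a background null and a panel;
    :meth:`fit` runs the joint maximum-likelihood integration at every
    locus and returns a :class:`CallingResults`.
    """

    def __init__(
        self,
        counts: AlleleCountTensor,
        background: BackgroundModel,
        panel: PanelDesign,
        sample: str | None = None,
    ) -> None:
        self.counts = counts
        self.background = background
        self.panel = panel
        self.sample = sample or counts.samples[0]

    def fit(
        self,
        thresholds: Thresholds,
        **kwargs,
    ) -> "CallingResults":
        calls = call_variants(
            self.counts,
            self.background,
            thresholds,
            self.panel,
            sample=self.sample,
            **kwargs,
        )
        return CallingResults(self, thresholds, calls)


class CallingResults:
    """Fitted calls plus reporting helpers."""

    def __init__(
        self,
        model: ReplicateCallingModel,
        thresholds: Thresholds,
        calls: list[VariantCall],
    ) -> None:
        self.model = model
        self.thresholds = thresholds
        self.calls = calls

    @property
    def called(self) -> list[VariantCall]:
        return [c for c in self.calls if c.status == "called"]

    def frame(self) -> pd.DataFrame:
        return calls_to_frame(self.calls)

    def summary(self) -> str:
        lines = [
            f"Replicate calling results: sample {self.model.sample!r}",
            f"  panel footprint: {self.model.panel.footprint_bases} bases, "
            f"{len(self.model.panel)} amplicons",
            f"  LR threshold (SNV/indel): {self.thresholds.snv:.2f} / "
            f"{self.thresholds.indel:.2f} "
            f"(budget {self.thresholds.specificity_budget:g} per base)",
            f"  calls: {len(self.called)}",
        ]
        for c in self.called:
            lines.append(
                f"    {c.chrom}:{c.pos + 1} {c.ref}>{c.alt} "
                f"[{c.variant_class}] AF={c.af_mle:.4%} "
                f"(pooled {c.pooled_af:.4%}) LR={c.lr:.1f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# SNP contamination / swap check
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ContaminationReport:
    status: str  # clean | contaminated | possible_swap | indeterminate
    n_informative: int
    deviating: list[int]
    genotypes: list[float]  # nearest of 0 / 0.5 / 1 per informative locus


def check_contamination(
    snp_af: np.ndarray,
    snp_depth: np.ndarray,
    prior_genotypes: np.ndarray | None = None,
    min_loci: int = 10,
    min_depth: int = 500,
    het_tol: float = 0.05,
    hom_tol: float = 0.02,
    min_deviating: int = 3,
) -> ContaminationReport:
    """Genotype-consistency check at common SNP loci.

    Germline SNP allele fractions must sit near 0, 0.5 or 1; a consistent
    shift of several loci toward intermediate fractions indicates cross-
    sample contamination, and a genotype fingerprint that contradicts a
    previous sample from the same patient indicates a possible swap.
    """
    snp_af = np.asarray(snp_af, dtype=float)
    snp_depth = np.asarray(snp_depth)
    usable = snp_depth >= min_depth
    if usable.sum() < min_loci:
        return ContaminationReport("indeterminate", int(usable.sum()), [], [])
    af = snp_af[usable]
    idx = np.flatnonzero(usable)
    hom_ref = af <= hom_tol
    hom_alt = af >= 1.0 - hom_tol
    het = np.abs(af - 0.5) <= het_tol
    deviating = ~(hom_ref | hom_alt | het)
    genotypes = np.where(hom_ref, 0.0, np.where(het, 0.5, np.where(hom_alt, 1.0, np.nan)))
    report_geno = [float(g) for g in genotypes]
    dev_idx = [int(i) for i in idx[deviating]]
    if deviating.sum() >= min_deviating:
        return ContaminationReport("contaminated", len(af), dev_idx, report_geno)
    if prior_genotypes is not None:
        prior = np.asarray(prior_genotypes, dtype=float)[usable]
        comparable = ~np.isnan(genotypes) & ~np.isnan(prior)
        mismatches = comparable & (genotypes != prior)
        if mismatches.sum() >= min_deviating:
            return ContaminationReport("possible_swap", len(af), dev_idx, report_geno)
    if deviating.any():
        return ContaminationReport("indeterminate", len(af), dev_idx, report_geno)
    return ContaminationReport("clean", len(af), [], report_geno)


# ---------------------------------------------------------------------------
# CNV from normalized depth
# ---------------------------------------------------------------------------


def _lower_median(values: np.ndarray) -> float:
    v = np.sort(np.asarray(values, dtype=float))
    return float(v[(len(v) - 1) // 2])


def infer_cnv(
    depths: pd.DataFrame,
    baseline: pd.DataFrame,
    panel: PanelDesign,
    amplified_cn: float = 3.0,
) -> dict[str, list[CnvCall]]:
    """Gene copy number from median-of-ratios normalized read depth.

    ``depths`` and ``baseline`` are samples x amplicons matrices. Each
    amplicon's reference depth is its median across the baseline cohort
    after per-sample size normalization; a test sample's size factor is
    the median of its depth ratios over all amplicons (robust to a
    single amplified gene); gene copy number is 2 x the lower-median
    normalized ratio over the gene's amplicons.
    """
    if len(baseline) < 5:
        raise CallingError(f"CNV baseline needs >= 5 samples, got {len(baseline)}")
    amplicons = [a.amplicon_id for a in panel]
    missing = [a for a in amplicons if a not in depths.columns or a not in baseline.columns]
    if missing:
        raise CallingError(f"depth matrices missing amplicons: {missing[:5]}")
    base = baseline[amplicons].to_numpy(dtype=float)
    base_factors = np.median(base / np.median(base, axis=0, keepdims=True), axis=1)
    ref_profile = np.median(base / base_factors[:, None], axis=0)
    if (ref_profile <= 0).any():
        raise CallingError("baseline contains amplicons with zero reference depth")
    out: dict[str, list[CnvCall]] = {}
    for sample, row in depths[amplicons].iterrows():
        d = row.to_numpy(dtype=float)
        ratios = d / ref_profile
        factor = float(np.median(ratios))
        if factor <= 0:
            raise CallingError(f"sample {sample!r} has non-positive median depth ratio")
        norm = ratios / factor
        calls = []
        for gene, amp_ids in sorted(panel.genes.items()):
            cols = [amplicons.index(a) for a in sorted(amp_ids)]
            gene_ratios = norm[cols]
            cn = 2.0 * _lower_median(gene_ratios)
            calls.append(
                CnvCall(
                    gene=gene,
                    copy_number=cn,
                    amplicon_ratios={amplicons[c]: float(norm[c]) for c in cols},
                    status="amplified" if cn >= amplified_cn else "normal",
                    low_confidence=len(cols) < 2,
                )
            )
        out[sample] = calls
    return out
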