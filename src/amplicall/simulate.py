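"""Synthetic data generation: reference-standard dilutions, molecule
pools, replicate splits, allele-count tensors, full-process plasma
controls, droplet reactions and optional FASTQ.

The generators emulate the study design of an amplicon ctDNA assay
validation: cell-line reference standards carrying known mutations are
sheared, diluted into wild-type DNA at fixed input tiers (2,000 /
8,000 / 16,000 amplifiable copies), split across replicate analyses,
amplified and sequenced. Every generator is bit-reproducible given its
seed. An oxidative-damage mode multiplies G>T / C>A error rates only,
mimicking 8-oxoguanine lesions introduced by acoustic shearing.
"""

from __future__ import annotations

import dataclasses
import gzip
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .background import BackgroundModel, simulate_alt_counts
from .counts import BASES, AlleleCountTensor
from .dpcr import DEFAULT_PARTITION_VOLUME_NL, DropletCounts
from .panel import Amplicon, PanelDesign, TruthVariant

INPUT_TIERS_AC = {"low": 2000, "medium": 8000, "high": 16000}

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# panels
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def make_toy_panel(
    n_amplicons: int = 10,
    insert_len: int = 100,
    primer_len: int = 16,
    gap: int = 50,
    chrom: str = "chr1",
    n_genes: int = 2,
    seed: int = 0,
) -> PanelDesign:
    """A small non-overlapping panel with random sequences (footprint =
    n_amplicons * insert_len)."""
    rng = np.random.default_rng(seed)
    amplicons = []
    start = 1000
    for i in range(n_amplicons):
        amplicons.append(
            Amplicon(
                amplicon_id=f"AMP{i + 1:03d}",
                chrom=chrom,
                insert_start=start,
                insert_end=start + insert_len,
                fwd_primer=_random_dna(rng, primer_len),
                rev_primer=_random_dna(rng, primer_len),
                insert_seq=_random_dna(rng, insert_len),
                gene=f"GENE{(i % n_genes) + 1:02d}",
            )
        )
        start += insert_len + gap
    return PanelDesign(amplicons)


def make_reference_panel(seed: int = 0) -> PanelDesign:
    """A panel-scale fixture: 35 genes, 110 amplicons, 10,610 interrogated
    bases, amplicon lengths within the short-fragment design bounds."""
    rng = np.random.default_rng(seed)
    primer_len = 16
    insert_lens = [96] * 60 + [97] * 50  # 60*96 + 50*97 = 10,610
    amplicons = []
    start = 10_000
    for i, ins_len in enumerate(insert_lens):
        amplicons.append(
            Amplicon(
                amplicon_id=f"REF{i + 1:03d}",
                chrom="chr1",
                insert_start=start,
                insert_end=start + ins_len,
                fwd_primer=_random_dna(rng, primer_len),
                rev_primer=_random_dna(rng, primer_len),
                insert_seq=_random_dna(rng, ins_len),
                gene=f"GENE{(i % 35) + 1:02d}",
            )
        )
        start += ins_len + 40
    return PanelDesign(amplicons)


# ---------------------------------------------------------------------------
# truth sets, molecule pools, replicate splits
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MoleculePool:
    """Amplifiable copies present in one sample, per variant."""

    total_ac: int
    mutant_copies: dict[TruthVariant, int]
    seed: int

    def __post_init__(self) -> None:
        for v, m in self.mutant_copies.items():
            if not 0 <= m <= self.total_ac:
                raise SimulationError(
                    f"mutant copies {m} outside [0, {self.total_ac}] for {v.chrom}:{v.pos}"
                )


@dataclasses.dataclass
class ReplicateMolecules:
    """One replicate's share of a molecule pool."""

    total_ac: int
    mutant_copies: dict[TruthVariant, int]


@dataclasses.dataclass(frozen=True)
class ArtifactConfig:
    """Oxidative-damage artifact switch for sheared-standard material."""

    oxidative_mode: bool = False
    gt_multiplier: float = 10.0

    def __post_init__(self) -> None:
        if self.gt_multiplier < 1:
            raise SimulationError("gt_multiplier must be >= 1")


def dilute_truth(
    stock: Sequence[TruthVariant], dilution_factor: float
) -> list[TruthVariant]:
    """Dilute a reference standard into wild-type DNA: every variant's
    expected AF scales by the dilution factor; order preserved."""
    if not 0 < dilution_factor <= 1:
        raise SimulationError(
            f"dilution factor must be in (0, 1], got {dilution_factor}"
        )
    return [
        dataclasses.replace(v, expected_af=v.stock_af * dilution_factor)
        for v in stock
    ]


def sample_molecules(
    truth: Sequence[TruthVariant], input_ac: int, seed: int
) -> MoleculePool:
    """Stochastic sampling of mutant molecules into a fixed DNA input:
    mutant copies ~ Binomial(input_ac, expected_af), independently."""
    if input_ac <= 0:
        raise SimulationError("input_ac must be positive")
    rng = np.random.default_rng(seed)
    mutants = {
        v: int(rng.binomial(input_ac, v.expected_af)) for v in truth
    }
    return MoleculePool(total_ac=input_ac, mutant_copies=mutants, seed=seed)


def split_replicates(
    pool: MoleculePool, n_replicates: int, seed: int
) -> list[ReplicateMolecules]:
    """Multinomial split of the pool into equal-probability replicates;
    totals and per-variant copies are conserved exactly."""
    if n_replicates < 2:
        raise SimulationError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    probs = np.full(n_replicates, 1.0 / n_replicates)
    totals = rng.multinomial(pool.total_ac, probs)
    per_variant: dict[TruthVariant, np.ndarray] = {}
    for v, m in pool.mutant_copies.items():
        # conditionally on the totals, mutant molecules land in replicates
        # like draws without replacement from the replicate bins
        per_variant[v] = rng.multivariate_hypergeometric(totals, m)
    return [
        ReplicateMolecules(
            total_ac=int(totals[r]),
            mutant_copies={v: int(arr[r]) for v, arr in per_variant.items()},
        )
        for r in range(n_replicates)
    ]


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------


def _variant_allele_column(v: TruthVariant) -> str:
    if v.variant_class == "SNV":
        return v.alt
    if v.variant_class == "deletion":
        return f"del:{len(v.ref)}"
    return f"ins:{v.alt}"


def simulate_counts(
    replicates: Sequence[ReplicateMolecules],
    panel: PanelDesign,
    background: BackgroundModel,
    reads_per_molecule: float = 2.0,
    artifact: ArtifactConfig | None = None,
    seed: int = 0,
    sample: str = "S1",
) -> AlleleCountTensor:
    """Simulate the per-replicate allele-count tensor for one sample.

    Per position and replicate, depth ~ Poisson(reads_per_molecule x
    replicate molecules); mutant reads ~ Binomial(depth, molecule
    fraction); substitution errors are drawn from the background model's
    beta-binomial (with G>T / C>A rates multiplied in oxidative mode);
    the reference count absorbs the remainder. Indel variants are keyed
    at their left-normalized locus as ``del:<len>`` / ``ins:<seq>``.
    """
    rng = np.random.default_rng(seed)
    bg = background
    if artifact is not None and artifact.oxidative_mode:
        bg = background.with_artifact(artifact.gt_multiplier)
    entries = bg.snv  # sorted (chrom, pos, alt); 3 rows per position
    sites = entries[["chrom", "pos", "ref"]].drop_duplicates().reset_index(drop=True)
    n_sites = len(sites)
    site_key = {(r.chrom, r.pos): i for i, r in enumerate(sites.itertuples(index=False))}
    mean = entries["mean_rate"].to_numpy().reshape(n_sites, 3)
    rho = entries["rho"].to_numpy().reshape(n_sites, 3)
    alt_base = entries["alt"].to_numpy().reshape(n_sites, 3)

    frames = []
    indel_cols: set[str] = set()
    amp_of_site = {}
    for amp in panel:
        for p in range(amp.insert_start, amp.insert_end):
            amp_of_site.setdefault((amp.chrom, p), amp.amplicon_id)

    for rep_idx, rep in enumerate(replicates):
        if rep.total_ac <= 0:
            raise SimulationError("replicate has no molecules")
        depth = rng.poisson(reads_per_molecule * rep.total_ac, size=n_sites)
        err = simulate_alt_counts(depth[:, None], mean, rho, rng)
        base_counts = {b: np.zeros(n_sites, dtype=np.int64) for b in BASES}
        extra: dict[str, np.ndarray] = {}
        # true mutant reads
        mutant_at_site = np.zeros(n_sites, dtype=np.int64)
        for v, m in rep.mutant_copies.items():
            if m == 0:
                continue
            i = site_key.get((v.chrom, v.pos))
            if i is None:
                raise SimulationError(
                    f"truth variant {v.chrom}:{v.pos} outside the background/panel sites"
                )
            mut_reads = rng.binomial(depth[i], min(m / rep.total_ac, 1.0))
            col = _variant_allele_column(v)
            if col in BASES:
                base_counts[col][i] += mut_reads
            else:
                extra.setdefault(col, np.zeros(n_sites, dtype=np.int64))[i] += mut_reads
                indel_cols.add(col)
            mutant_at_site[i] += mut_reads
        # errors onto their alt bases
        err_total = np.zeros(n_sites, dtype=np.int64)
        for j in range(3):
            for b in BASES:
                mask = alt_base[:, j] == b
                base_counts[b][mask] += err[mask, j]
            err_total += err[:, j]
        # reference absorbs the remainder
        ref_reads = np.maximum(depth - mutant_at_site - err_total, 0)
        for b in BASES:
            mask = sites["ref"].to_numpy() == b
            base_counts[b][mask] += ref_reads[mask]
        df = pd.DataFrame(
            {
                "sample": sample,
                "replicate": rep_idx + 1,
                "amplicon_id": [
                    amp_of_site.get((r.chrom, r.pos), "NA")
                    for r in sites.itertuples(index=False)
                ],
                "chrom": sites["chrom"],
                "pos": sites["pos"],
                "ref": sites["ref"],
                **base_counts,
                **extra,
            }
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    for col in indel_cols:
        out[col] = out[col].fillna(0).astype(np.int64)
    return AlleleCountTensor(out)


def simulate_wildtype_sample(
    panel: PanelDesign,
    background: BackgroundModel,
    input_ac: int = 8000,
    n_replicates: int = 8,
    reads_per_molecule: float = 2.0,
    seed: int = 0,
    sample: str = "WT",
) -> AlleleCountTensor:
    """Convenience: a sample with no mutant molecules, errors only."""
    pool = MoleculePool(total_ac=input_ac, mutant_copies={}, seed=seed)
    reps = split_replicates(pool, n_replicates, seed)
    return simulate_counts(
        reps, panel, background, reads_per_molecule, seed=seed + 1, sample=sample
    )


# ---------------------------------------------------------------------------
# full-process plasma controls
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FullProcessControl:
    """A spiked-plasma control after extraction."""

    pool: MoleculePool
    recovered_spike_copies: int
    expected_measured_af: float


def simulate_full_process_control(
    spike_af: float,
    spike_copies: int,
    plasma_background_ac: int,
    extraction_efficiency: float,
    seed: int = 0,
    variant: TruthVariant | None = None,
) -> FullProcessControl:
    """Mutant reference standard spiked into plasma before extraction.

    Recovered spike copies ~ Binomial(spike_copies, efficiency); the
    plasma's own wild-type DNA dilutes the spike, so the expected
    measured AF is spike_af x recovered / (recovered + plasma), always
    <= the nominal spike AF.
    """
    if not 0.0 <= extraction_efficiency <= 1.0:
        raise SimulationError("extraction efficiency must be in [0, 1]")
    if not 0.0 <= spike_af <= 1.0:
        raise SimulationError("spike_af must be in [0, 1]")
    rng = np.random.default_rng(seed)
    recovered = int(rng.binomial(spike_copies, extraction_efficiency))
    total = recovered + plasma_background_ac
    expected_af = spike_af * recovered / total if total > 0 else 0.0
    if variant is None:
        variant = TruthVariant(
            chrom="chr1", pos=0, ref="A", alt="T", variant_class="SNV",
            stock_af=spike_af, expected_af=expected_af,
        )
    else:
        variant = dataclasses.replace(variant, expected_af=expected_af)
    mutant = int(rng.binomial(recovered, spike_af)) if recovered > 0 else 0
    mutant = min(mutant, total)
    pool = MoleculePool(total_ac=max(total, 1), mutant_copies={variant: mutant}, seed=seed)
    return FullProcessControl(
        pool=pool,
        recovered_spike_copies=recovered,
        expected_measured_af=float(expected_af),
    )


# ---------------------------------------------------------------------------
# droplets
# ---------------------------------------------------------------------------


def simulate_droplets(
    mut_lambda: float,
    wt_lambda: float,
    n_droplets: int,
    fpr_lambda: float = 0.0,
    seed: int = 0,
    reaction_id: str = "R1",
    partition_volume_nl: float = DEFAULT_PARTITION_VOLUME_NL,
) -> DropletCounts:
    """Simulate one dPCR reaction.

    Channel occupancies are independent Poissons; false positives add to
    the mutant channel at ``fpr_lambda`` per droplet. Droplets are
    classified into mutant-single / wild-type-single / double / negative.
    """
    if min(mut_lambda, wt_lambda, fpr_lambda) < 0:
        raise SimulationError("rates must be non-negative")
    if n_droplets <= 0:
        raise SimulationError("n_droplets must be positive")
    rng = np.random.default_rng(seed)
    p_mut = 1.0 - np.exp(-(mut_lambda + fpr_lambda))
    p_wt = 1.0 - np.exp(-wt_lambda)
    probs = [
        p_mut * (1 - p_wt),
        p_wt * (1 - p_mut),
        p_mut * p_wt,
        (1 - p_mut) * (1 - p_wt),
    ]
    mut_s, wt_s, dbl, neg = rng.multinomial(n_droplets, probs)
    return DropletCounts(
        reaction_id=reaction_id,
        n_droplets=n_droplets,
        mut_single_pos=int(mut_s),
        wt_single_pos=int(wt_s),
        double_pos=int(dbl),
        negative=int(neg),
        partition_volume_nl=partition_volume_nl,
    )


# ---------------------------------------------------------------------------
# FASTQ emission
# ---------------------------------------------------------------------------


def _apply_variant(amp: Amplicon, v: TruthVariant) -> str:
    off = v.pos - amp.insert_start
    ins = amp.insert_seq
    if v.variant_class == "SNV":
        return ins[:off] + v.alt + ins[off + 1 :]
    if v.variant_class == "deletion":
        return ins[:off] + ins[off + len(v.ref) :]
    return ins[:off] + v.alt + ins[off:]


def emit_fastq(
    replicate: ReplicateMolecules,
    panel: PanelDesign,
    r1_path: str | Path,
    r2_path: str | Path,
    reads_per_molecule: float = 2.0,
    read_length: int = 150,
    base_quality: int = 37,
    seed: int = 0,
    prefix: str = "sim",
) -> int:
    """Write paired gzipped FASTQ for one replicate; returns pairs written.

    Each template is a known amplicon with primers attached; every
    molecule yields exactly ``round(reads_per_molecule)`` read pairs, so
    on error-free data the pileup allele fraction equals the molecule
    fraction exactly. Mutant molecules yield reads carrying the variant
    allele. Reads are clipped to ``read_length``; R2 is the reverse
    complement strand.
    """
    multiplicity = max(int(round(reads_per_molecule)), 1)
    qual = chr(base_quality + 33)
    n_pairs = 0
    with gzip.open(r1_path, "wt") as f1, gzip.open(r2_path, "wt") as f2:
        for amp in panel:
            variants_here = {
                v: m
                for v, m in replicate.mutant_copies.items()
                if v.chrom == amp.chrom and amp.insert_start <= v.pos < amp.insert_end
            }
            n_mut = {v: multiplicity * m for v, m in variants_here.items()}
            n_reads = multiplicity * replicate.total_ac
            alleles = [(None, n_reads - sum(n_mut.values()))] + list(n_mut.items())
            for v, count in alleles:
                if count <= 0:
                    continue
                insert = amp.insert_seq if v is None else _apply_variant(amp, v)
                template = amp.fwd_primer + insert + revcomp(amp.rev_primer)
                r1 = template[:read_length]
                r2 = revcomp(template)[:read_length]
                for _ in range(count):
                    n_pairs += 1
                    name = f"{prefix}:{amp.amplicon_id}:{n_pairs}"
                    f1.write(f"@{name}/1\n{r1}\n+\n{qual * len(r1)}\n")
                    f2.write(f"@{name}/2\n{r2}\n+\n{qual * len(r2)}\n")
    return n_pairs
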