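"""Paired-end read merging, primer-anchored amplicon assignment and
quality-gated pileup.

Because every template is a known amplicon, alignment reduces to
anchored primer matching: merge the pair into a synthetic read on the
top strand, find the unique amplicon whose primers match both ends,
clip the primers and pile the insert up against the amplicon reference.
Discordant bases at the merge step are demoted to Phred 2, and only
bases at or above Phred 30 enter the analytics.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from pathlib import Path

from Bio import Align, SeqIO

from .counts import BASES, AlleleCountTensor
from .panel import PanelDesign, left_normalize_indel
from .simulate import revcomp

DISCORDANT_PHRED = 2
DEFAULT_MIN_PHRED = 30


class PileupError(ValueError):
    pass


@dataclasses.dataclass
class MergedRead:
    """A merged synthetic read on the reference top strand."""

    sequence: str
    qualities: list[int]
    amplicon_id: str | None = None
    discordant_positions: set[int] = dataclasses.field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities must have equal length")
        for p in self.discordant_positions:
            if self.qualities[p] != DISCORDANT_PHRED:
                raise ValueError(
                    f"discordant position {p} must carry Phred {DISCORDANT_PHRED}"
                )


def merge_pair(
    r1: tuple[str, list[int]],
    r2: tuple[str, list[int]],
    min_overlap: int = 10,
    min_identity: float = 0.8,
) -> MergedRead | None:
    """Merge a read pair by the best ungapped overlap.

    R2 is reverse-complemented onto the top strand first. The overlap
    with the most matching bases wins (it must reach ``min_identity``);
    a tie between two overlap lengths, or no qualifying overlap, returns
    ``None`` (the pair is dropped and counted in QC). Concordant overlap
    bases keep the higher quality; discordant bases take the
    higher-quality base demoted to Phred 2.
    """
    seq1, qual1 = r1
    seq2, qual2 = r2
    if not seq1 or not seq2:
        raise ValueError("reads must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seq2rc = revcomp(seq2)
    qual2r = list(reversed(qual2))
    best_o, best_matches, tie = None, -1, False
    for o in range(min_overlap, min(len(seq1), len(seq2)) + 1):
        a = seq1[len(seq1) - o :]
        b = seq2rc[:o]
        matches = sum(x == y for x, y in zip(a, b))
        if matches < min_identity * o:
            continue
        if matches > best_matches:
            best_o, best_matches, tie = o, matches, False
        elif matches == best_matches:
            tie = True
    if best_o is None or tie:
        return None
    o = best_o
    left_n = len(seq1) - o
    seq = list(seq1[:left_n])
    quals = list(qual1[:left_n])
    discordant: set[int] = set()
    for i in range(o):
        b1, b2 = seq1[left_n + i], seq2rc[i]
        q1, q2 = qual1[left_n + i], qual2r[i]
        if b1 == b2:
            seq.append(b1)
            quals.append(max(q1, q2))
        else:
            seq.append(b1 if q1 >= q2 else b2)
            quals.append(DISCORDANT_PHRED)
            discordant.add(left_n + i)
    seq.extend(seq2rc[o:])
    quals.extend(qual2r[o:])
    return MergedRead(
        sequence="".join(seq), qualities=quals, discordant_positions=discordant
    )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def assign_amplicon(
    merged: MergedRead, panel: PanelDesign, max_mismatch: int = 2
) -> MergedRead | None:
    """Assign by primer anchoring and clip the primers.

    The unique amplicon whose forward primer matches the 5' end and
    whose reverse primer (as it appears on the top strand) matches the
    3' end, each within ``max_mismatch``, wins; zero or multiple
    qualifying amplicons leave the read unassigned.
    """
    hits = []
    for amp in panel:
        flen, rlen = len(amp.fwd_primer), len(amp.rev_primer)
        if len(merged.sequence) < flen + rlen + 1:
            continue
        if _hamming(merged.sequence[:flen], amp.fwd_primer) > max_mismatch:
            continue
        if _hamming(merged.sequence[-rlen:], revcomp(amp.rev_primer)) > max_mismatch:
            continue
        hits.append(amp)
    if len(hits) != 1:
        return None
    amp = hits[0]
    flen, rlen = len(amp.fwd_primer), len(amp.rev_primer)
    end = len(merged.sequence) - rlen
    return MergedRead(
        sequence=merged.sequence[flen:end],
        qualities=merged.qualities[flen:end],
        amplicon_id=amp.amplicon_id,
        discordant_positions={
            p - flen for p in merged.discordant_positions if flen <= p < end
        },
    )


# affine gap penalties keep multi-base indels contiguous, as a genomic
# aligner would; unit-cost edit distance tends to fragment long deletions
_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=2,
    mismatch_score=-3,
    open_gap_score=-6,
    extend_gap_score=-1,
)


def _walk_alignment(read: MergedRead, ref: str, start: int, min_phred: int):
    """Yield (pos, allele_key, passes_quality) events from a global
    alignment of the clipped read insert against the amplicon insert."""
    if read.sequence == ref:
        for i, base in enumerate(ref):
            yield start + i, base, read.qualities[i] >= min_phred
        return
    aln = _ALIGNER.align(read.sequence, ref)[0]
    q_blocks, t_blocks = aln.aligned
    prev_q = prev_t = 0
    events = list(zip(q_blocks, t_blocks)) + [
        ((len(read.sequence), len(read.sequence)), (len(ref), len(ref)))
    ]
    for (qs, qe), (ts, te) in events:
        if ts > prev_t:  # deletion in the read
            length = ts - prev_t
            off, _ = left_normalize_indel(ref, prev_t, deleted=ref[prev_t:ts])
            anchor_q = read.qualities[prev_q - 1] if prev_q > 0 else min_phred
            yield start + off, f"del:{length}", anchor_q >= min_phred
        if qs > prev_q:  # insertion in the read
            inserted = read.sequence[prev_q:qs]
            off, seq = left_normalize_indel(ref, ts, inserted=inserted)
            min_q = min(read.qualities[prev_q:qs])
            yield start + off, f"ins:{seq}", min_q >= min_phred
        for i in range(qe - qs):
            base = read.sequence[qs + i]
            ok = read.qualities[qs + i] >= min_phred
            yield start + ts + i, base, ok
        prev_q, prev_t = qe, te


def pileup_counts(
    assigned: list[MergedRead],
    panel: PanelDesign,
    min_phred: int = DEFAULT_MIN_PHRED,
    sample: str = "S1",
    replicate: int | str = 1,
) -> AlleleCountTensor:
    """Pile clipped reads up into an allele-count tensor slice.

    Bases below ``min_phred`` contribute nothing at their position (so
    Phred-2 merge-discordant bases never count). Indel alleles are keyed
    by their left-normalized representation.
    """
    import pandas as pd

    tallies: dict[tuple[str, int], dict[str, int]] = {}
    refs: dict[tuple[str, int], str] = {}
    amp_ids: dict[tuple[str, int], str] = {}
    for read in assigned:
        if read.amplicon_id is None:
            raise PileupError("pileup requires assigned reads")
        amp = panel.get(read.amplicon_id)
        if len(read.sequence) > amp.insert_length + 50:
            raise PileupError(
                f"read of length {len(read.sequence)} extends far beyond the "
                f"{amp.insert_length} bp insert of {amp.amplicon_id}; clipping bug?"
            )
        for pos, allele, ok in _walk_alignment(
            read, amp.insert_seq, amp.insert_start, min_phred
        ):
            if not ok:
                continue
            key = (amp.chrom, pos)
            tallies.setdefault(key, {}).setdefault(allele, 0)
            tallies[key][allele] += 1
    for amp in panel:
        for off in range(amp.insert_length):
            key = (amp.chrom, amp.insert_start + off)
            refs[key] = amp.insert_seq[off]
            amp_ids.setdefault(key, amp.amplicon_id)
            tallies.setdefault(key, {})
    rows = []
    indel_cols = sorted(
        {a for t in tallies.values() for a in t if a.startswith(("ins:", "del:"))}
    )
    for (chrom, pos), t in sorted(tallies.items()):
        row = {
            "sample": sample,
            "replicate": replicate,
            "amplicon_id": amp_ids[(chrom, pos)],
            "chrom": chrom,
            "pos": pos,
            "ref": refs[(chrom, pos)],
        }
        for b in BASES:
            row[b] = t.get(b, 0)
        for c in indel_cols:
            row[c] = t.get(c, 0)
        rows.append(row)
    return AlleleCountTensor(pd.DataFrame(rows))


@dataclasses.dataclass
class ReadProcessingQC:
    pairs_in: int = 0
    merged: int = 0
    assigned: int = 0
    discordant_bases: int = 0
    merged_bases: int = 0

    @property
    def discordant_fraction(self) -> float:
        return self.discordant_bases / self.merged_bases if self.merged_bases else 0.0

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["discordant_fraction"] = self.discordant_fraction
        Path(path).write_text(json.dumps(d, indent=2))


def process_fastq_pair(
    r1_path: str | Path,
    r2_path: str | Path,
    panel: PanelDesign,
    min_overlap: int = 10,
    max_mismatch: int = 2,
    min_phred: int = DEFAULT_MIN_PHRED,
    sample: str = "S1",
    replicate: int | str = 1,
) -> tuple[AlleleCountTensor, ReadProcessingQC]:
    """FASTQ pair -> merged -> assigned -> allele-count tensor, with QC."""

    def _open(p):
        p = str(p)
        return gzip.open(p, "rt") if p.endswith(".gz") else open(p)

    qc = ReadProcessingQC()
    assigned_reads: list[MergedRead] = []
    with _open(r1_path) as f1, _open(r2_path) as f2:
        for rec1, rec2 in zip(SeqIO.parse(f1, "fastq"), SeqIO.parse(f2, "fastq")):
            qc.pairs_in += 1
            merged = merge_pair(
                (str(rec1.seq), rec1.letter_annotations["phred_quality"]),
                (str(rec2.seq), rec2.letter_annotations["phred_quality"]),
                min_overlap=min_overlap,
            )
            if merged is None:
                continue
            qc.merged += 1
            qc.merged_bases += len(merged.sequence)
            qc.discordant_bases += len(merged.discordant_positions)
            clipped = assign_amplicon(merged, panel, max_mismatch=max_mismatch)
            if clipped is None:
                continue
            qc.assigned += 1
            assigned_reads.append(clipped)
    tensor = pileup_counts(
        assigned_reads, panel, min_phred=min_phred, sample=sample, replicate=replicate
    )
    return tensor, qc
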