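"""Amplicon panel data model and tabular I/O.

The panel is the static description of the assay: a set of short PCR
amplicons (72-154 bp including primers by default), each with a forward
primer, a reverse primer (stored as synthesized, i.e. the reverse
complement of the reference top strand at its 3' site) and the insert
sequence between them. All genomic coordinates are 0-based half-open
internally; 1-based coordinates appear only in VCF output.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import pandas as pd

_DNA = set("ACGT")

PANEL_COLUMNS = [
    "amplicon_id",
    "chrom",
    "insert_start",
    "insert_end",
    "fwd_primer",
    "rev_primer",
    "insert_seq",
    "gene",
]

TRUTH_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "stock_af",
    "expected_af",
]

VARIANT_CLASSES = ("SNV", "insertion", "deletion")


class PanelError(ValueError):
    """Malformed panel, amplicon or truth-set input."""


def _check_dna(seq: str, what: str) -> None:
    if not seq or set(seq) - _DNA:
        raise PanelError(f"{what} must be a non-empty A/C/G/T string, got {seq!r}")


@dataclasses.dataclass(frozen=True)
class Amplicon:
    """One amplicon: primers plus the interrogated insert between them."""

    amplicon_id: str
    chrom: str
    insert_start: int
    insert_end: int
    fwd_primer: str
    rev_primer: str
    insert_seq: str
    gene: str = ""

    def __post_init__(self) -> None:
        if self.insert_end <= self.insert_start:
            raise PanelError(
                f"{self.amplicon_id}: insert_end must exceed insert_start "
                f"({self.insert_start}..{self.insert_end})"
            )
        _check_dna(self.fwd_primer, f"{self.amplicon_id} fwd_primer")
        _check_dna(self.rev_primer, f"{self.amplicon_id} rev_primer")
        _check_dna(self.insert_seq, f"{self.amplicon_id} insert_seq")
        if len(self.insert_seq) != self.insert_end - self.insert_start:
            raise PanelError(
                f"{self.amplicon_id}: insert_seq length {len(self.insert_seq)} "
                f"!= interval length {self.insert_end - self.insert_start}"
            )

    @property
    def length(self) -> int:
        """Full amplicon length, primers included."""
        return len(self.fwd_primer) + len(self.insert_seq) + len(self.rev_primer)

    @property
    def insert_length(self) -> int:
        return self.insert_end - self.insert_start


class PanelDesign:
    """A validated collection of amplicons with gene bookkeeping.

    Parameters
    ----------
    amplicons
        Amplicon records. Overlapping inserts are allowed (tiled exons);
        duplicate ids are not.
    length_bounds
        (min, max) allowed full amplicon length; ``None`` disables the
        check. The default reflects a short-amplicon cfDNA design.
    """

    def __init__(
        self,
        amplicons: Iterable[Amplicon],
        length_bounds: tuple[int, int] | None = (72, 154),
    ) -> None:
        self.amplicons: list[Amplicon] = list(amplicons)
        if not self.amplicons:
            raise PanelError("panel contains no amplicons")
        seen: set[str] = set()
        for amp in self.amplicons:
            if amp.amplicon_id in seen:
                raise PanelError(f"duplicate amplicon_id {amp.amplicon_id!r}")
            seen.add(amp.amplicon_id)
            if length_bounds is not None:
                lo, hi = length_bounds
                if not lo <= amp.length <= hi:
                    raise PanelError(
                        f"{amp.amplicon_id}: amplicon length {amp.length} "
                        f"outside [{lo}, {hi}]"
                    )
        self.genes: dict[str, set[str]] = {}
        for amp in self.amplicons:
            self.genes.setdefault(amp.gene, set()).add(amp.amplicon_id)
        self._ref: dict[tuple[str, int], str] = {}
        for amp in self.amplicons:
            for off, base in enumerate(amp.insert_seq):
                key = (amp.chrom, amp.insert_start + off)
                prev = self._ref.setdefault(key, base)
                if prev != base:
                    raise PanelError(
                        f"inconsistent reference base at {key}: {prev} vs {base} "
                        f"(amplicon {amp.amplicon_id})"
                    )
        self.footprint_bases = len(self._ref)

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self):
        return iter(self.amplicons)

    def get(self, amplicon_id: str) -> Amplicon:
        for amp in self.amplicons:
            if amp.amplicon_id == amplicon_id:
                return amp
        raise KeyError(amplicon_id)

    def positions(self) -> list[tuple[str, int]]:
        """All interrogated (chrom, pos), sorted."""
        return sorted(self._ref)

    def ref_base(self, chrom: str, pos: int) -> str:
        return self._ref[(chrom, pos)]

    def covers(self, chrom: str, pos: int) -> bool:
        return (chrom, pos) in self._ref


@dataclasses.dataclass(frozen=True)
class TruthVariant:
    """A known variant in a reference standard, before and after dilution."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    stock_af: float
    expected_af: float

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise PanelError(f"unknown variant_class {self.variant_class!r}")
        if self.ref == self.alt:
            raise PanelError(f"ref == alt at {self.chrom}:{self.pos}")
        if not 0.0 <= self.expected_af <= self.stock_af <= 1.0:
            raise PanelError(
                f"need 0 <= expected_af <= stock_af <= 1 at {self.chrom}:{self.pos}, "
                f"got stock={self.stock_af} expected={self.expected_af}"
            )


def load_panel(
    path: str | Path, length_bounds: tuple[int, int] | None = (72, 154)
) -> PanelDesign:
    """Read a panel TSV (one amplicon per row) into a validated PanelDesign."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns and c != "gene"]
    if missing:
        raise PanelError(f"panel file {path} missing columns: {missing}")
    if "gene" not in df.columns:
        df["gene"] = ""
    amplicons = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            amplicons.append(
                Amplicon(
                    amplicon_id=row.amplicon_id,
                    chrom=row.chrom,
                    insert_start=int(row.insert_start),
                    insert_end=int(row.insert_end),
                    fwd_primer=row.fwd_primer,
                    rev_primer=row.rev_primer,
                    insert_seq=row.insert_seq,
                    gene=row.gene or "",
                )
            )
        except (PanelError, TypeError, ValueError) as exc:
            raise PanelError(f"{path} line {i}: {exc}") from exc
    return PanelDesign(amplicons, length_bounds=length_bounds)


def write_panel(panel: PanelDesign, path: str | Path) -> None:
    rows = [
        {
            "amplicon_id": a.amplicon_id,
            "chrom": a.chrom,
            "insert_start": a.insert_start,
            "insert_end": a.insert_end,
            "fwd_primer": a.fwd_primer,
            "rev_primer": a.rev_primer,
            "insert_seq": a.insert_seq,
            "gene": a.gene,
        }
        for a in panel
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def load_truth(path: str | Path) -> list[TruthVariant]:
    """Read a truth-set TSV of known variants."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"truth file {path} missing columns: {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                TruthVariant(
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    variant_class=row.variant_class,
                    stock_af=float(row.stock_af),
                    expected_af=float(row.expected_af),
                )
            )
        except (PanelError, ValueError) as exc:
            raise PanelError(f"{path} line {i}: {exc}") from exc
    return out


def write_truth(truth: Iterable[TruthVariant], path: str | Path) -> None:
    rows = [dataclasses.asdict(t) for t in truth]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def left_normalize_indel(
    ref_seq: str, offset: int, inserted: str = "", deleted: str = ""
) -> tuple[int, str]:
    """Left-align an indel within a reference sequence.

    ``offset`` is the 0-based position within ``ref_seq`` where the event
    starts (first deleted base, or the base before which the insertion
    occurs). Exactly one of ``inserted``/``deleted`` must be non-empty.
    Returns the normalized (offset, allele_seq). The allele can be shifted
    left one base at a time while the base preceding the event equals the
    last base of the indel sequence (the classic VCF normalization rule).
    """
    if bool(inserted) == bool(deleted):
        raise ValueError("exactly one of inserted/deleted must be non-empty")
    seq = inserted or deleted
    pos = offset
    while pos > 0 and ref_seq[pos - 1] == seq[-1]:
        seq = ref_seq[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq
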