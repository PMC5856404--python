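"""Call record types shared by the caller and the writers."""

from __future__ import annotations

import dataclasses

CALL_STATUSES = ("called", "not_called", "low_confidence_region")


@dataclasses.dataclass
class ReplicateSupport:
    """Evidence from one replicate at one locus."""

    replicate: str | int
    alt: int
    depth: int
    lr: float = 0.0


@dataclasses.dataclass
class VariantCall:
    """A candidate variant with joint maximum-likelihood evidence.

    ``pos`` is 0-based; for indels it is the VCF anchor-base position and
    ``ref``/``alt`` are the anchored, left-normalized allele strings.
    ``af_mle`` is the joint across-replicate MLE of the allele fraction;
    ``pooled_af`` is the simple pooled count ratio, reported alongside.
    ``lr`` is the likelihood-ratio statistic 2*(l(af_mle) - l(0)).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    af_mle: float
    pooled_af: float
    lr: float
    status: str
    replicates: list[ReplicateSupport] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status not in CALL_STATUSES:
            raise ValueError(f"bad status {self.status!r}")
        if not 0.0 <= self.af_mle <= 1.0:
            raise ValueError(f"af_mle out of [0,1]: {self.af_mle}")

    @property
    def depth(self) -> int:
        return sum(r.depth for r in self.replicates)

    @property
    def alt_count(self) -> int:
        return sum(r.alt for r in self.replicates)


@dataclasses.dataclass
class CnvCall:
    """Gene-level copy-number estimate from normalized read depth."""

    gene: str
    copy_number: float
    amplicon_ratios: dict[str, float]
    status: str  # "normal" | "amplified"
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.copy_number <= 0:
            raise ValueError("copy_number must be positive")
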