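"""VCF 4.2 and flat-TSV emission of variant calls.

Internally everything is 0-based half-open; POS in the VCF is 1-based.
Indels are written left-normalized with an anchor base, VCF style.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .panel import PanelDesign
from .variants import ReplicateSupport, VariantCall

_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Joint maximum-likelihood allele fraction">',
    '##INFO=<ID=PAF,Number=1,Type=Float,Description="Pooled across-replicate count fraction">',
    '##INFO=<ID=LR,Number=1,Type=Float,Description="Likelihood ratio statistic vs background null">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth across replicates">',
    '##INFO=<ID=VC,Number=1,Type=String,Description="Variant class (SNV/insertion/deletion)">',
    '##INFO=<ID=STATUS,Number=1,Type=String,Description="Call status">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype (placeholder 0/1 for somatic calls)">',
    '##FORMAT=<ID=RAD,Number=.,Type=Integer,Description="Per-replicate alt read counts">',
    '##FORMAT=<ID=RDP,Number=.,Type=Integer,Description="Per-replicate depths">',
]


class VcfError(ValueError):
    pass


def _contig_lines(panel: PanelDesign) -> list[str]:
    ends: dict[str, int] = {}
    for amp in panel:
        ends[amp.chrom] = max(ends.get(amp.chrom, 0), amp.insert_end)
    return [
        f"##contig=<ID={chrom},length={end + 1000}>" for chrom, end in sorted(ends.items())
    ]


def _check_in_footprint(call: VariantCall, panel: PanelDesign) -> None:
    # For indels the anchor may sit one base left of the event; the event
    # itself must touch the panel footprint.
    candidates = [call.pos, call.pos + 1]
    if not any(panel.covers(call.chrom, p) for p in candidates):
        raise VcfError(
            f"call at {call.chrom}:{call.pos} ({call.ref}>{call.alt}) is outside "
            "the panel footprint"
        )


def write_calls_vcf(
    calls: list[VariantCall],
    panel: PanelDesign,
    path: str | Path,
    sample_name: str = "SAMPLE",
) -> None:
    """Write calls as a VCF 4.2 text file (header-only when no calls)."""
    for call in calls:
        _check_in_footprint(call, panel)
    lines = list(_HEADER_LINES) + _contig_lines(panel)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_name
    )
    for call in sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt)):
        info = (
            f"AF={call.af_mle:.6g};PAF={call.pooled_af:.6g};LR={call.lr:.6g};"
            f"DP={call.depth};VC={call.variant_class};STATUS={call.status}"
        )
        rad = ",".join(str(r.alt) for r in call.replicates) or "."
        rdp = ",".join(str(r.depth) for r in call.replicates) or "."
        lines.append(
            "\t".join(
                [
                    call.chrom,
                    str(call.pos + 1),  # 1-based POS
                    ".",
                    call.ref,
                    call.alt,
                    ".",
                    "PASS" if call.status == "called" else call.status,
                    info,
                    "GT:RAD:RDP",
                    f"0/1:{rad}:{rdp}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_calls_vcf(path: str | Path) -> list[VariantCall]:
    """Read back a VCF written by :func:`write_calls_vcf` (round-trip aid)."""
    calls: list[VariantCall] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        fields = line.split("\t")
        chrom, pos, _, ref, alt, _, _, info = fields[:8]
        kv = dict(item.split("=", 1) for item in info.split(";"))
        reps: list[ReplicateSupport] = []
        if len(fields) >= 10:
            fmt = dict(zip(fields[8].split(":"), fields[9].split(":")))
            if fmt.get("RAD", ".") != ".":
                alts = [int(x) for x in fmt["RAD"].split(",")]
                dps = [int(x) for x in fmt["RDP"].split(",")]
                reps = [
                    ReplicateSupport(replicate=i, alt=a, depth=d)
                    for i, (a, d) in enumerate(zip(alts, dps))
                ]
        calls.append(
            VariantCall(
                chrom=chrom,
                pos=int(pos) - 1,
                ref=ref,
                alt=alt,
                variant_class=kv["VC"],
                af_mle=float(kv["AF"]),
                pooled_af=float(kv["PAF"]),
                lr=float(kv["LR"]),
                status=kv["STATUS"],
                replicates=reps,
            )
        )
    return calls


def calls_to_frame(calls: list[VariantCall]) -> pd.DataFrame:
    """Flat TSV-ready report of calls."""
    rows = []
    for c in calls:
        rows.append(
            {
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "variant_class": c.variant_class,
                "af_mle": c.af_mle,
                "pooled_af": c.pooled_af,
                "lr": c.lr,
                "status": c.status,
                "alt_count": c.alt_count,
                "depth": c.depth,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "variant_class",
            "af_mle",
            "pooled_af",
            "lr",
            "status",
            "alt_count",
            "depth",
        ],
    )
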