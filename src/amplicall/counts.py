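"""The allele-count tensor: per (sample, replicate, position) allele counts.

This is the caller's substrate. Each row of the underlying DataFrame holds
the base counts (A/C/G/T) plus any indel allele counts (``ins:<seq>`` /
``del:<len>`` columns) observed at one panel position in one replicate of
one sample.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
FIXED_COLUMNS = ["sample", "replicate", "amplicon_id", "chrom", "pos", "ref"]


class CountsError(ValueError):
    pass


class AlleleCountTensor:
    """Thin wrapper over a long-format allele-count DataFrame.

    Rows are unique on (sample, replicate, chrom, pos). Indel allele
    columns are created lazily as ``ins:<seq>`` / ``del:<len>``; absent
    indel columns mean zero counts.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in FIXED_COLUMNS + list(BASES) if c not in df.columns]
        if missing:
            raise CountsError(f"count table missing columns: {missing}")
        self.df = df.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    @property
    def indel_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith(("ins:", "del:"))]

    def base_depth(self) -> pd.Series:
        """Depth from base calls only (A+C+G+T), per row."""
        return self.df[list(BASES)].sum(axis=1)

    def total_depth(self) -> pd.Series:
        """Base depth plus indel-supporting reads, per row."""
        cols = list(BASES) + self.indel_columns
        return self.df[cols].sum(axis=1)

    def for_sample(self, sample: str) -> "AlleleCountTensor":
        sub = self.df[self.df["sample"] == sample]
        if sub.empty:
            raise CountsError(f"no rows for sample {sample!r}")
        return AlleleCountTensor(sub.copy())

    def select_samples(self, samples: Iterable[str]) -> "AlleleCountTensor":
        sub = self.df[self.df["sample"].isin(list(samples))]
        return AlleleCountTensor(sub.copy())

    # -- array extraction for the caller ---------------------------------
    def site_matrix(self, sample: str) -> tuple[pd.DataFrame, np.ndarray, dict[str, np.ndarray]]:
        """Pivot one sample into replicate-major arrays.

        Returns ``(sites, depth, allele_counts)`` where ``sites`` is a
        DataFrame of unique (chrom, pos, ref, amplicon_id) rows, ``depth``
        is an (n_sites, n_replicates) base-depth array, and
        ``allele_counts`` maps each allele column (bases and indels) to an
        (n_sites, n_replicates) count array. Replicates missing a site get
        zero depth.
        """
        sub = self.df[self.df["sample"] == sample]
        if sub.empty:
            raise CountsError(f"no rows for sample {sample!r}")
        reps = sorted(sub["replicate"].unique())
        sites = (
            sub[["chrom", "pos", "ref", "amplicon_id"]]
            .drop_duplicates(subset=["chrom", "pos"])
            .sort_values(["chrom", "pos"])
            .reset_index(drop=True)
        )
        key = sites["chrom"].astype(str) + ":" + sites["pos"].astype(str)
        index = pd.Index(key, name="site")
        alleles = list(BASES) + self.indel_columns
        out: dict[str, np.ndarray] = {}
        for col in alleles:
            piv = sub.pivot_table(
                index=sub["chrom"].astype(str) + ":" + sub["pos"].astype(str),
                columns="replicate",
                values=col,
                aggfunc="sum",
                fill_value=0,
            ).reindex(index=index, columns=reps, fill_value=0)
            out[col] = piv.to_numpy(dtype=np.int64)
        depth = sum(out[b] for b in BASES)
        return sites, depth, out

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        cols = FIXED_COLUMNS + list(BASES) + sorted(self.indel_columns)
        self.df[cols].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlleleCountTensor":
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str, "ref": str})
        return cls(df)

    @classmethod
    def concat(cls, tensors: Iterable["AlleleCountTensor"]) -> "AlleleCountTensor":
        frames = [t.df for t in tensors]
        df = pd.concat(frames, ignore_index=True).fillna(0)
        for col in df.columns:
            if col.startswith(("ins:", "del:")) or col in BASES:
                df[col] = df[col].astype(np.int64)
        return cls(df)
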