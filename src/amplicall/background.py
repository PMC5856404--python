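"""Position- and substitution-specific background error models.

Amplicon sequencing shows reproducible, position-dependent error rates
that are overdispersed relative to binomial sampling (PCR errors
propagate clonally; oxidative damage inflates specific substitutions).
The null model here is a beta-binomial per (position, alt allele),
fitted by method of moments over the error fractions observed in a
cohort of control samples. Indel backgrounds are estimated from the
samples of the same batch, leaving the tested sample out so a true
indel cannot mask itself.
"""

from __future__ import annotations

from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .counts import BASES, AlleleCountTensor
from .panel import PanelDesign

PSEUDO_NUM = 0.5  # added to alt counts
PSEUDO_DEN = 1.0  # added to depths
MAX_RHO = 0.99


class BackgroundError(ValueError):
    pass


class BackgroundEntry(NamedTuple):
    """Null parameters for one (position, alt allele)."""

    mean_rate: float
    rho: float  # beta-binomial intra-class correlation; 0 => binomial
    n_controls: int = 0
    low_confidence: bool = False


def _moment_fit(frac: np.ndarray, inv_depth: np.ndarray, usable: np.ndarray):
    """Method-of-moments beta-binomial fit over control error fractions.

    ``frac``/``inv_depth``/``usable`` are (n_sites, n_obs) arrays. The
    observed variance of the fractions is decomposed into the binomial
    sampling part (mean(1/d) * m(1-m)) and the between-library part; the
    remainder determines the intra-class correlation rho, clamped to
    [0, MAX_RHO]. Returns (mean, rho, n_used, rho_num, rho_den) per site;
    the last two allow pooling rho across sites.
    """
    n_used = usable.sum(axis=1)
    w = usable.astype(float)
    denom = np.maximum(n_used, 1)
    m = (frac * w).sum(axis=1) / denom
    resid = (frac - m[:, None]) * w
    var = (resid**2).sum(axis=1) / np.maximum(n_used - 1, 1)
    mean_inv_d = (inv_depth * w).sum(axis=1) / denom
    mv = m * (1.0 - m)
    rho_num = var - mv * mean_inv_d
    rho_den = mv * (1.0 - mean_inv_d)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = rho_num / rho_den
    rho = np.where((n_used >= 2) & (mv > 0), rho, 0.0)
    rho = np.clip(np.nan_to_num(rho, nan=0.0), 0.0, MAX_RHO)
    valid = (n_used >= 2) & (mv > 0)
    return m, rho, n_used.astype(int), np.where(valid, rho_num, 0.0), np.where(valid, rho_den, 0.0)


class BackgroundModel:
    """Fitted (or specified) per-site substitution error distributions.

    The same object serves two roles: the null for variant calling, and
    the generative error model for simulation. ``snv`` is a DataFrame with
    columns chrom, pos, ref, alt, mean_rate, rho, n_controls,
    low_confidence — one row for every panel position x 3 substitutions.
    """

    def __init__(self, snv: pd.DataFrame, default_floor: float = 1e-6) -> None:
        required = {"chrom", "pos", "ref", "alt", "mean_rate", "rho", "n_controls", "low_confidence"}
        missing = required - set(snv.columns)
        if missing:
            raise BackgroundError(f"background frame missing columns: {sorted(missing)}")
        if (snv["mean_rate"] < 0).any() or (snv["mean_rate"] >= 1).any():
            raise BackgroundError("mean_rate must lie in [0, 1)")
        if (snv["rho"] < 0).any():
            raise BackgroundError("rho must be >= 0")
        self.snv = snv.sort_values(["chrom", "pos", "alt"]).reset_index(drop=True)
        self.default_floor = float(default_floor)
        self._index = {
            (r.chrom, r.pos, r.alt): i for i, r in enumerate(self.snv.itertuples(index=False))
        }

    # -- constructors ----------------------------------------------------
    @classmethod
    def uniform(
        cls, panel: PanelDesign, rate: float = 1e-4, rho: float = 0.0
    ) -> "BackgroundModel":
        """A flat generative background: every substitution at ``rate``."""
        rows = []
        for chrom, pos in panel.positions():
            ref = panel.ref_base(chrom, pos)
            for alt in BASES:
                if alt == ref:
                    continue
                rows.append((chrom, pos, ref, alt, rate, rho, 0, False))
        return cls(_frame(rows))

    @classmethod
    def random(
        cls,
        panel: PanelDesign,
        rng: np.random.Generator,
        median_rate: float = 1e-4,
        log10_sd: float = 0.35,
        rho: float = 1e-3,
    ) -> "BackgroundModel":
        """A heterogeneous background: per-site rates log-normal around
        ``median_rate`` with a shared overdispersion, emulating the
        position-to-position spread of amplicon error rates."""
        rows = []
        for chrom, pos in panel.positions():
            ref = panel.ref_base(chrom, pos)
            for alt in BASES:
                if alt == ref:
                    continue
                rate = float(median_rate * 10 ** rng.normal(0.0, log10_sd))
                rows.append((chrom, pos, ref, alt, min(rate, 0.01), rho, 0, False))
        return cls(_frame(rows))

    @classmethod
    def fit(
        cls,
        control_counts: AlleleCountTensor,
        panel: PanelDesign,
        min_depth: int = 100,
        rho_mode: str = "pooled",
    ) -> "BackgroundModel":
        """Fit per-(position, substitution) beta-binomial nulls from controls.

        The mean error rate per site is the average over controls of each
        control's pooled-across-replicates fraction, pseudocounted
        ``(alt + 0.5) / (depth + 1)`` per control; controls below
        ``min_depth`` at a site are skipped there. The intra-class
        correlation rho is estimated from raw per-replicate library
        fractions (the granularity at which the calling likelihood
        applies the overdispersion; the pseudocount would masquerade as
        binomial variance) and is, by default, pooled across the whole
        panel (``rho_mode="pooled"``) because per-site second moments
        are far too noisy at realistic control-cohort sizes;
        ``rho_mode="per_site"`` keeps the raw per-site estimates.
        Sites with fewer than 3 usable controls are flagged
        low-confidence.
        """
        if rho_mode not in ("pooled", "per_site"):
            raise BackgroundError(f"unknown rho_mode {rho_mode!r}")
        controls = control_counts.samples
        if len(controls) < 3:
            raise BackgroundError(f"need >= 3 control samples, got {len(controls)}")
        df = control_counts.df
        pivots = {
            b: df.pivot_table(
                index=["chrom", "pos"],
                columns=["sample", "replicate"],
                values=b,
                fill_value=0,
            )
            for b in BASES
        }
        site_index = pivots["A"].index
        col_samples = np.array([c[0] for c in pivots["A"].columns])
        unique_samples = np.unique(col_samples)
        sample_mat = (col_samples[None, :] == unique_samples[:, None]).astype(float)
        arr = {b: pivots[b].to_numpy(dtype=float) for b in BASES}
        depth = sum(arr[b] for b in BASES)  # per library (S, L)
        pooled_depth = depth @ sample_mat.T  # per control (S, n_samples)
        usable_ctrl = pooled_depth >= min_depth
        n_samples_used = usable_ctrl.sum(axis=1).astype(int)
        lib_usable = depth >= 1
        inv_depth = np.where(depth > 0, 1.0 / np.maximum(depth, 1.0), 0.0)
        mean_depth = (
            float(pooled_depth[pooled_depth > 0].mean()) if (pooled_depth > 0).any() else 0.0
        )
        floor = PSEUDO_NUM / (mean_depth + PSEUDO_DEN) if mean_depth > 0 else PSEUDO_NUM
        fits = {}
        ref_of_site = np.array(
            [panel.ref_base(c, p) if panel.covers(c, p) else "N" for c, p in site_index]
        )
        rho_num_total = rho_den_total = 0.0
        w_ctrl = usable_ctrl.astype(float)
        for b in BASES:
            # mean: pseudocounted per-control pooled fractions
            pooled_alt = arr[b] @ sample_mat.T
            frac_ctrl = (pooled_alt + PSEUDO_NUM) / (pooled_depth + PSEUDO_DEN)
            m_pseudo = (frac_ctrl * w_ctrl).sum(axis=1) / np.maximum(n_samples_used, 1)
            m_pseudo = np.where(n_samples_used > 0, m_pseudo, floor)
            # overdispersion: raw per-library fractions
            frac_raw = arr[b] / np.maximum(depth, 1.0)
            _, rho_b, _, num_b, den_b = _moment_fit(frac_raw, inv_depth, lib_usable)
            fits[b] = (m_pseudo, rho_b)
            is_alt = ref_of_site != b
            rho_num_total += float(num_b[is_alt].sum())
            rho_den_total += float(den_b[is_alt].sum())
        rho_pooled = 0.0
        if rho_den_total > 0:
            rho_pooled = float(np.clip(rho_num_total / rho_den_total, 0.0, MAX_RHO))
        site_lookup = {key: i for i, key in enumerate(site_index)}
        rows = []
        for chrom, pos in panel.positions():
            ref = panel.ref_base(chrom, pos)
            i = site_lookup.get((chrom, pos))
            for alt in BASES:
                if alt == ref:
                    continue
                if i is None:
                    rows.append((chrom, pos, ref, alt, floor, 0.0, 0, True))
                    continue
                m, rho = fits[alt]
                n_s = int(n_samples_used[i])
                rho_i = rho_pooled if rho_mode == "pooled" else float(rho[i])
                rows.append(
                    (chrom, pos, ref, alt, float(m[i]), rho_i, n_s, n_s < 3)
                )
        return cls(_frame(rows), default_floor=floor)

    # -- lookups ---------------------------------------------------------
    def entry(self, chrom: str, pos: int, alt: str) -> BackgroundEntry:
        i = self._index.get((chrom, pos, alt))
        if i is None:
            raise KeyError((chrom, pos, alt))
        r = self.snv.iloc[i]
        return BackgroundEntry(
            float(r.mean_rate), float(r.rho), int(r.n_controls), bool(r.low_confidence)
        )

    def arrays_for_sites(self, sites: pd.DataFrame) -> pd.DataFrame:
        """Background rows aligned to (chrom, pos) site order, 3 alts per
        site, in BASES order excluding the ref base."""
        merged = sites[["chrom", "pos", "ref"]].merge(
            self.snv, on=["chrom", "pos"], how="left", suffixes=("", "_bg")
        )
        if merged["mean_rate"].isna().any():
            bad = merged[merged["mean_rate"].isna()][["chrom", "pos"]].drop_duplicates()
            raise BackgroundError(
                f"sample positions absent from background model: {bad.values.tolist()[:5]}"
            )
        return merged

    def with_artifact(self, gt_multiplier: float) -> "BackgroundModel":
        """Oxidative-damage mode: multiply G>T and C>A error rates.

        8-oxoguanine lesions from acoustic shearing read out as G>T on the
        damaged strand and C>A on the opposite strand; all other
        substitution rates are untouched.
        """
        if gt_multiplier < 1:
            raise BackgroundError("gt_multiplier must be >= 1")
        snv = self.snv.copy()
        mask = ((snv["ref"] == "G") & (snv["alt"] == "T")) | (
            (snv["ref"] == "C") & (snv["alt"] == "A")
        )
        snv.loc[mask, "mean_rate"] = np.minimum(
            snv.loc[mask, "mean_rate"] * gt_multiplier, 0.5
        )
        return BackgroundModel(snv, default_floor=self.default_floor)

    # -- serialization ---------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.snv.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BackgroundModel":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
        return cls(df)


def _frame(rows: list[tuple]) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "mean_rate", "rho", "n_controls", "low_confidence"],
    )


def simulate_alt_counts(
    depth: np.ndarray,
    mean_rate: np.ndarray,
    rho: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw beta-binomial error counts; rho == 0 falls back to binomial.

    All arrays broadcast together; ``mean_rate``/``rho`` are typically
    (n_sites, 1) against a (n_sites, n_replicates) depth.
    """
    depth, mean_rate, rho = np.broadcast_arrays(
        np.asarray(depth), np.asarray(mean_rate, dtype=float), np.asarray(rho, dtype=float)
    )
    p = np.array(mean_rate, dtype=float)
    od = rho > 0
    if od.any():
        s = (1.0 - rho[od]) / rho[od]
        a = np.maximum(mean_rate[od] * s, 1e-12)
        b = np.maximum((1.0 - mean_rate[od]) * s, 1e-12)
        p[od] = rng.beta(a, b)
    return rng.binomial(depth, np.clip(p, 0.0, 1.0))


def batch_indel_background(
    batch_counts: AlleleCountTensor,
    chrom: str,
    pos: int,
    allele: str,
    min_depth: int = 100,
) -> pd.DataFrame:
    """Leave-one-out indel background from the samples of one batch.

    For each sample in the batch, the null rate for ``allele`` (an
    ``ins:<seq>`` / ``del:<len>`` column key) at the locus is fitted from
    the *other* samples' pooled fractions, so a genuine indel in the
    tested sample cannot inflate its own null. Returns a DataFrame
    indexed by tested sample with mean_rate, rho, n_controls.
    """
    samples = batch_counts.samples
    if len(samples) < 4:
        raise BackgroundError(
            f"indel batch background needs >= 4 samples (got {len(samples)}); "
            "fall back to the control cohort"
        )
    df = batch_counts.df
    rows_here = df[(df["chrom"] == chrom) & (df["pos"] == pos)]
    per_sample = rows_here.groupby("sample")[list(BASES)].sum().sum(axis=1)
    if allele in rows_here.columns:
        alt = rows_here.groupby("sample")[allele].sum()
    else:
        alt = pd.Series(0, index=per_sample.index)
    depth = per_sample.reindex(samples, fill_value=0).to_numpy(dtype=float)
    alt = alt.reindex(samples, fill_value=0).to_numpy(dtype=float)
    # indel-supporting reads also contribute to the denominator
    depth = depth + alt
    frac = (alt + PSEUDO_NUM) / (depth + PSEUDO_DEN)
    usable = depth >= min_depth
    inv_depth = np.where(depth > 0, 1.0 / np.maximum(depth, 1.0), 0.0)
    out = []
    for i, tested in enumerate(samples):
        keep = np.ones(len(samples), dtype=bool)
        keep[i] = False
        m, rho, n_used = _moment_fit(
            frac[None, keep], inv_depth[None, keep], usable[None, keep]
        )[:3]
        out.append((tested, float(m[0]), float(rho[0]), int(n_used[0])))
    return pd.DataFrame(out, columns=["sample", "mean_rate", "rho", "n_controls"]).set_index(
        "sample"
    )
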