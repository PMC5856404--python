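"""Droplet digital PCR quantification and limit-of-detection statistics.

A reaction partitions the template into ~0.85 nL droplets; the count of
mutant-positive droplets follows a binomial whose per-droplet rate mixes
Poisson occupancy of true mutant copies with a false-positive rate per
droplet (lambda). The limit of detection combines two binomials: the
critical level is the 95th percentile of the false-positive binomial
(alpha = 0.05), and the LOD is the smallest mutant load whose detection
binomial leaves at most 5% probability (beta = 0.05) at or below that
critical level.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PARTITION_VOLUME_NL = 0.85


class DpcrError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class DropletCounts:
    """Classified droplet counts for one reaction."""

    reaction_id: str
    n_droplets: int
    mut_single_pos: int
    wt_single_pos: int
    double_pos: int
    negative: int
    partition_volume_nl: float = DEFAULT_PARTITION_VOLUME_NL

    def __post_init__(self) -> None:
        parts = (self.mut_single_pos, self.wt_single_pos, self.double_pos, self.negative)
        if any(p < 0 for p in parts):
            raise DpcrError("droplet class counts must be non-negative")
        if sum(parts) != self.n_droplets:
            raise DpcrError(
                f"droplet classes sum to {sum(parts)}, expected n_droplets={self.n_droplets}"
            )

    @property
    def mut_positive(self) -> int:
        return self.mut_single_pos + self.double_pos

    @property
    def wt_positive(self) -> int:
        return self.wt_single_pos + self.double_pos


@dataclasses.dataclass(frozen=True)
class LODResult:
    """Dual-binomial limit-of-detection summary for one assay."""

    fpr_lambda: float
    n_droplets: float
    critical_level: int
    p_det: float
    lod_copies: float
    lod_af_percent: float
    alpha: float = 0.05
    beta: float = 0.05

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def poisson_concentration(
    k_positive: int,
    n_droplets: int,
    partition_volume_nl: float = DEFAULT_PARTITION_VOLUME_NL,
) -> tuple[float, float]:
    """Copies/uL and per-droplet lambda from a positive-droplet count.

    Occupancy is Poisson, so ``lambda = -ln(1 - k/n)``; the concentration
    divides by the droplet volume (0.85 nL = 8.5e-4 uL by default).
    """
    if not 0 <= k_positive < n_droplets:
        raise DpcrError(
            f"need 0 <= k < n (saturated reaction has undefined lambda); "
            f"got k={k_positive}, n={n_droplets}"
        )
    lam = -np.log1p(-k_positive / n_droplets)
    conc = lam / (partition_volume_nl * 1e-3)
    return float(conc), float(lam)


def estimate_fpr(reactions: Sequence[DropletCounts]) -> float:
    """Pooled false-positive rate per droplet from wild-type-only controls."""
    if not reactions:
        raise DpcrError("need at least one control reaction")
    total_pos = sum(r.mut_positive for r in reactions)
    total_droplets = sum(r.n_droplets for r in reactions)
    if total_droplets == 0:
        raise DpcrError("zero accepted droplets across control reactions")
    return total_pos / total_droplets


def _binomial_upper_quantile(n: int, p: float, q: float) -> int:
    """Smallest k with CDF(k) >= q (ties upward)."""
    if p <= 0:
        return 0
    return int(stats.binom.ppf(q, n, p))


def compute_lod(
    fpr_lambda: float,
    n_droplets: int,
    wt_lambda: float,
    alpha: float = 0.05,
    beta: float = 0.05,
    tol: float = 1e-9,
) -> LODResult:
    """Dual-binomial LOD in mutant copies/reaction and as AF%.

    critical_level: 95th percentile of Binomial(n, fpr_lambda) — the
    largest positive count plausibly produced by false positives alone.
    p_det: smallest per-droplet positive probability whose binomial
    leaves at most ``beta`` probability at or below the critical level,
    solved by bisection on the exact CDF. LOD in copies is
    ``n * -ln(1 - p_det)`` (inverting Poisson occupancy) and as AF%
    relative to total target copies ``n * wt_lambda + lod_copies``.
    """
    if fpr_lambda < 0 or wt_lambda < 0:
        raise DpcrError("rates must be non-negative")
    if fpr_lambda >= 1:
        raise DpcrError("fpr_lambda >= 1 is unphysical")
    if n_droplets < 1:
        raise DpcrError("n_droplets must be >= 1")
    n = int(n_droplets)
    lc = _binomial_upper_quantile(n, fpr_lambda, 1.0 - alpha)

    def fn_prob(p: float) -> float:
        # probability of beta-type failure: count <= critical level
        return stats.binom.cdf(lc, n, p)

    lo, hi = 0.0, 1.0
    while hi - lo > tol * max(hi, 1e-12):
        mid = 0.5 * (lo + hi)
        if fn_prob(mid) <= beta:
            hi = mid
        else:
            lo = mid
    p_det = hi
    lod_copies = n * -np.log1p(-p_det)
    total = n * wt_lambda + lod_copies
    lod_af = 100.0 * lod_copies / total if total > 0 else 100.0
    return LODResult(
        fpr_lambda=float(fpr_lambda),
        n_droplets=float(n),
        critical_level=int(lc),
        p_det=float(p_det),
        lod_copies=float(lod_copies),
        lod_af_percent=float(lod_af),
        alpha=alpha,
        beta=beta,
    )


def load_droplet_csv(path: str | Path) -> list[DropletCounts]:
    df = pd.read_csv(path)
    required = ["reaction_id", "n_droplets", "mut_single_pos", "wt_single_pos", "double_pos", "negative"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DpcrError(f"droplet CSV missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            DropletCounts(
                reaction_id=str(row.reaction_id),
                n_droplets=int(row.n_droplets),
                mut_single_pos=int(row.mut_single_pos),
                wt_single_pos=int(row.wt_single_pos),
                double_pos=int(row.double_pos),
                negative=int(row.negative),
                partition_volume_nl=float(getattr(row, "partition_volume_nl", DEFAULT_PARTITION_VOLUME_NL)),
            )
        )
    return out


def write_droplet_csv(reactions: Iterable[DropletCounts], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in reactions]).to_csv(path, index=False)
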