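"""Replicate likelihoods and joint allele-fraction estimation.

The observation model for one replicate at one site is a (beta-)binomial
on the alt read count with success rate ``mu = af + (1 - af) * e`` where
``e`` is the background error rate and ``af`` the shared true allele
fraction; the beta-binomial intra-class correlation ``rho`` comes from
the background fit. ``af = 0`` reduces exactly to the null. The joint
MLE maximizes the summed log-likelihood over replicates at a shared
``af``; the decision statistic is the likelihood ratio
``lr = 2 * (l(af_mle) - l(0))``.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, xlog1py, xlogy

__all__ = [
    "betabinom_logpmf",
    "replicate_loglik",
    "integrate_replicates",
    "integrate_replicates_batch",
    "NoCoverageError",
]

_RHO_EPS = 1e-9


class NoCoverageError(ValueError):
    """All replicates had zero depth at the locus."""


def betabinom_logpmf(k, n, mu, rho):
    """Vectorized beta-binomial log-pmf parameterized by mean and
    intra-class correlation; ``rho`` below ~1e-9 uses the binomial limit."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu, dtype=float)
    rho = np.asarray(rho, dtype=float)
    k, n, mu, rho = np.broadcast_arrays(k, n, mu, rho)
    out = np.empty(k.shape, dtype=float)
    comb = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    binom_branch = (rho < _RHO_EPS) | (mu <= 0.0) | (mu >= 1.0)
    if binom_branch.any():
        m = np.clip(mu[binom_branch], 0.0, 1.0)
        out[binom_branch] = (
            comb[binom_branch]
            + xlogy(k[binom_branch], m)
            + xlog1py(n[binom_branch] - k[binom_branch], -m)
        )
    bb = ~binom_branch
    if bb.any():
        s = (1.0 - rho[bb]) / rho[bb]
        a = mu[bb] * s
        b = (1.0 - mu[bb]) * s
        out[bb] = (
            comb[bb]
            + gammaln(k[bb] + a)
            + gammaln(n[bb] - k[bb] + b)
            - gammaln(n[bb] + a + b)
            + gammaln(a + b)
            - gammaln(a)
            - gammaln(b)
        )
    return out if out.shape else float(out)


def _mixture_rate(af, mean_rate):
    return af + (1.0 - af) * mean_rate


def _effective_params(af, mean_rate, rho):
    """Mixture rate and signal-attenuated overdispersion.

    Overdispersion belongs to the *error* process: mutant reads sample a
    fixed molecule fraction (binomial), while background errors carry
    the beta-binomial intra-class correlation. Modelling the total count
    as beta-binomial with the full rho would skew the low-AF likelihood
    and bias the MLE upward, so rho is scaled by the error component's
    share of the mixture variance: rho_eff = rho * e(1-e) / (mu(1-mu))
    with e = (1-af) * mean_rate. At af = 0 this is exactly the null.
    """
    af = np.asarray(af, dtype=float)
    e = (1.0 - af) * mean_rate
    mu = af + e
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(mu > 0, (e * (1.0 - e)) / np.maximum(mu * (1.0 - mu), 1e-300), 1.0)
    rho_eff = rho * np.clip(scale, 0.0, 1.0)
    return mu, rho_eff


def replicate_loglik(alt: int, depth: int, entry, af: float) -> float:
    """Log-likelihood of one replicate's alt count at allele fraction ``af``.

    ``entry`` is anything with ``mean_rate`` and ``rho`` attributes (a
    BackgroundEntry) or a (mean_rate, rho) pair.
    """
    if not 0 <= alt <= depth:
        raise ValueError(f"need 0 <= alt <= depth, got alt={alt} depth={depth}")
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"af out of [0,1]: {af}")
    mean_rate, rho = _entry_params(entry)
    mu, rho_eff = _effective_params(af, mean_rate, rho)
    return float(betabinom_logpmf(alt, depth, mu, rho_eff))


def _entry_params(entry) -> tuple[float, float]:
    if hasattr(entry, "mean_rate"):
        return float(entry.mean_rate), float(entry.rho)
    mean_rate, rho = entry[0], entry[1]
    return float(mean_rate), float(rho)


class IntegrationResult(NamedTuple):
    af_mle: float
    lr: float
    pooled_af: float
    n_replicates: int


def integrate_replicates(
    replicates: Sequence[tuple[int, int]], entry
) -> IntegrationResult:
    """Joint MLE of a shared allele fraction across replicates.

    ``replicates`` is a sequence of (alt, depth); zero-depth replicates
    are excluded rather than failing the locus. Raises
    :class:`NoCoverageError` if nothing remains.
    """
    mean_rate, rho = _entry_params(entry)
    pairs = [(a, d) for a, d in replicates if d > 0]
    if not pairs:
        raise NoCoverageError("all replicates have zero depth")
    if len(pairs) < 1:
        raise ValueError("need at least one covered replicate")
    alt = np.array([a for a, _ in pairs], dtype=float)
    depth = np.array([d for _, d in pairs], dtype=float)
    pooled = float(alt.sum() / depth.sum())
    if alt.sum() == 0:
        return IntegrationResult(0.0, 0.0, pooled, len(pairs))

    def nll(af: float) -> float:
        mu, rho_eff = _effective_params(af, mean_rate, rho)
        return -float(betabinom_logpmf(alt, depth, mu, rho_eff).sum())

    ll0 = -nll(0.0)
    # closed form for the binomial case: the pooled fraction is sufficient
    af_closed = min(max((pooled - mean_rate) / (1.0 - mean_rate), 0.0), 1.0)
    if rho < _RHO_EPS:
        best_af = af_closed
    else:
        grid = np.unique(
            np.clip(
                np.concatenate(
                    [np.geomspace(1e-7, 1.0, 120), [af_closed, pooled]]
                ),
                0.0,
                1.0,
            )
        )
        vals = [nll(a) for a in grid]
        i = int(np.argmin(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(nll, bounds=(lo, hi), method="bounded")
        best_af = float(res.x) if res.fun <= vals[i] else float(grid[i])
    ll_best = -nll(best_af)
    if ll0 >= ll_best:  # MLE at the null boundary
        best_af, ll_best = 0.0, ll0
    lr = max(2.0 * (ll_best - ll0), 0.0)
    return IntegrationResult(float(best_af), float(lr), pooled, len(pairs))


# ---------------------------------------------------------------------------
# batch path: many sites at once (calibration, whole-sample calling)
# ---------------------------------------------------------------------------


def _site_loglik(alt, depth, af, mean_rate, rho):
    """Summed replicate log-likelihood per site.

    alt/depth: (S, R); af/mean_rate/rho: (S,). Zero-depth replicates
    contribute log 1 = 0 by construction (k = n = 0).
    """
    mu, rho_eff = _effective_params(af, mean_rate, rho)
    return betabinom_logpmf(alt, depth, mu[:, None], rho_eff[:, None]).sum(axis=1)


def integrate_replicates_batch(
    alt: np.ndarray,
    depth: np.ndarray,
    mean_rate: np.ndarray,
    rho: np.ndarray,
    exact_min_lr: float = 8.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized joint MLE and LR for many sites.

    For ``rho == 0`` the pooled count is sufficient and the MLE and LR
    have closed forms. Overdispersed sites use a zoomed multiplicative
    grid around the closed-form start, but only where a cheap pooled
    binomial LRT screen (``exact_min_lr``) or a pooled alt count >= 5
    indicates the site could matter; far-sub-threshold sites keep a
    single-evaluation LR at the closed-form AF, which is accurate to
    within the curvature of an already negligible statistic.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    mean_rate = np.asarray(mean_rate, dtype=float)
    rho = np.asarray(rho, dtype=float)
    S = alt.shape[0]
    K = alt.sum(axis=1)
    N = np.maximum(depth.sum(axis=1), 1.0)
    pooled = K / N
    af_closed = np.clip((pooled - mean_rate) / (1.0 - mean_rate), 0.0, 1.0)
    mu_hat = np.where(af_closed > 0, pooled, mean_rate)
    lr_bin = 2.0 * (
        xlogy(K, mu_hat) + xlog1py(N - K, -mu_hat)
        - xlogy(K, mean_rate) - xlog1py(N - K, -mean_rate)
    )
    lr_bin = np.maximum(np.nan_to_num(lr_bin, nan=0.0), 0.0)

    af_out = af_closed.copy()
    lr_out = lr_bin.copy()
    zero = K == 0
    af_out[zero] = 0.0
    lr_out[zero] = 0.0

    od = (rho >= _RHO_EPS) & ~zero
    if od.any():
        idx = np.flatnonzero(od)
        a_od, d_od = alt[idx], depth[idx]
        m_od, r_od = mean_rate[idx], rho[idx]
        ll0 = _site_loglik(a_od, d_od, np.zeros(len(idx)), m_od, r_od)
        ll_closed = _site_loglik(a_od, d_od, af_closed[idx], m_od, r_od)
        lr_closed = np.maximum(2.0 * (ll_closed - ll0), 0.0)
        af_out[idx] = af_closed[idx]
        lr_out[idx] = lr_closed
        cand = np.flatnonzero((lr_bin[idx] >= exact_min_lr) | (K[idx] >= 5))
        if cand.size:
            ci = idx[cand]
            af_c, ll_c = _zoom_grid_mle(
                alt[ci], depth[ci], mean_rate[ci], rho[ci],
                np.maximum(af_closed[ci], 1e-8),
                np.maximum(pooled[ci], 1e-8),
            )
            better = ll_c > ll_closed[cand]
            af_best = np.where(better, af_c, af_closed[ci])
            ll_best = np.maximum(ll_c, ll_closed[cand])
            lr_c = np.maximum(2.0 * (ll_best - ll0[cand]), 0.0)
            af_out[ci] = np.where(lr_c > 0, af_best, 0.0)
            lr_out[ci] = lr_c
    return af_out, lr_out


def _zoom_grid_mle(alt, depth, mean_rate, rho, af_start, pooled):
    """Vectorized multiplicative grid search with zoom refinement.

    The opening grid spans pooled/300 .. pooled*4 (the MLE can sit far
    above the naive background-subtracted start when the pooled rate
    barely exceeds the null mean), with the closed-form start included.
    """
    best_af = np.clip(af_start, 0.0, 1.0)
    best_ll = _site_loglik(alt, depth, best_af, mean_rate, rho)
    for f in np.geomspace(1.0 / 300.0, 4.0, 25):
        af = np.clip(pooled * f, 0.0, 1.0)
        ll = _site_loglik(alt, depth, af, mean_rate, rho)
        upd = ll > best_ll
        best_af = np.where(upd, af, best_af)
        best_ll = np.where(upd, ll, best_ll)
    center = best_af.copy()
    for n_pts, spn in ((9, 1.6), (9, 1.15), (9, 1.03), (9, 1.006)):
        for f in np.geomspace(1.0 / spn, spn, n_pts):
            af = np.clip(center * f, 0.0, 1.0)
            ll = _site_loglik(alt, depth, af, mean_rate, rho)
            upd = ll > best_ll
            best_af = np.where(upd, af, best_af)
            best_ll = np.where(upd, ll, best_ll)
        center = best_af.copy()
    return best_af, best_ll


def per_replicate_lr(alt, depth, entry, af: float) -> list[float]:
    """Per-replicate LR contributions at the joint MLE, for reporting."""
    mean_rate, rho = _entry_params(entry)
    out = []
    for a, d in zip(alt, depth):
        if d == 0:
            out.append(0.0)
            continue
        mu, rho_eff = _effective_params(af, mean_rate, rho)
        l1 = betabinom_logpmf(a, d, mu, rho_eff)
        l0 = betabinom_logpmf(a, d, mean_rate, rho)
        out.append(float(2.0 * (l1 - l0)))
    return out
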