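"""Compositionality-robust correlation estimation (SparCC-style).

Sequencing counts are compositional: each sample's counts are closed to its
sequencing depth, so Pearson correlations of proportions are distorted
(spuriously negative, and dominated by abundant taxa). The estimator here
works on log-ratio variances, which are invariant to the closure:

    t_ij = Var_s[ log(f_si / f_sj) ]
         = w_i^2 + w_j^2 - 2 rho_ij w_i w_j

where w_i^2 is the (unobserved) basis variance of OTU i on the log scale.
Under approximate sparsity of the correlation matrix the basis variances
solve the linear system

    (diag(d) + A) w^2 = (t * A) row sums,      A = pair-inclusion indicator

and rho_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j). Strongly correlated pairs
violate the sparsity approximation, so the strongest remaining pair above an
exclusion threshold is iteratively removed from the system and the basis
variances re-solved (a Sherman-Morrison rank-one downdate of the system
inverse, batched over estimation passes).

The full estimator repeats this over ``n_iter`` independent Dirichlet
posterior draws of the underlying fractions (add-one prior, the standard
zero-replacement) and reports the elementwise median. p-values come from a
permutation null that shuffles each OTU independently across samples
(applied to the posterior fractions, so each value keeps its own
depth-dependent sampling noise), destroying association while preserving
every OTU's marginal distribution; null replicates use the same
median-of-iterations estimator as the observed matrix, which keeps observed
and null statistics exchangeable and the p-values calibrated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("otunet")

_OMEGA_EPS = 1e-6  # floor for basis variances (log-scale variance units)


@dataclass
class LogRatioVariance:
    """t_ij = Var[log(f_i/f_j)] plus the per-OTU basis-variance estimates."""

    t: np.ndarray
    omega2: np.ndarray | None = None


@dataclass
class CorrelationResult:
    """Point estimates and bootstrap p-values for one OTU table."""

    rho: pd.DataFrame
    pvals: pd.DataFrame
    n_iterations: int
    n_bootstraps: int
    seed: int | None

    def __post_init__(self) -> None:
        r = self.rho.to_numpy()
        if not np.allclose(r, r.T):
            raise ValueError("rho must be symmetric")
        if self.pvals is not None:
            p = self.pvals.to_numpy()
            if not np.allclose(p, p.T):
                raise ValueError("pvals must be symmetric")


def _t_stack(fractions: np.ndarray) -> np.ndarray:
    """Batched log-ratio variances: (B, n, D) fractions -> (B, D, D) t."""
    logf = np.log(fractions)
    x = logf - logf.mean(axis=1, keepdims=True)
    c = np.einsum("bni,bnj->bij", x, x) / (fractions.shape[1] - 1)
    v = np.einsum("bii->bi", c)
    t = v[:, :, None] + v[:, None, :] - 2.0 * c
    t = 0.5 * (t + t.transpose(0, 2, 1))
    t[t < 0] = 0.0  # numerical dust from the covariance identity
    idx = np.arange(t.shape[1])
    t[:, idx, idx] = 0.0
    return t


def log_ratio_variance(fractions: np.ndarray) -> LogRatioVariance:
    """Variance over samples of log(f_i) - log(f_j) for every OTU pair.

    ``fractions``: samples x OTUs, strictly positive (pseudocount applied
    upstream). Uses the identity t_ij = v_i + v_j - 2 c_ij with v, c the
    sample variances/covariances of the log fractions (ddof=1).
    """
    f = np.asarray(fractions, dtype=float)
    if f.ndim != 2:
        raise ValueError("fractions must be 2-D (samples x OTUs)")
    if (f <= 0).any():
        raise ValueError("fractions must be strictly positive; apply a pseudocount")
    return LogRatioVariance(t=_t_stack(f[None])[0])


def _rho_batch(t: np.ndarray, omega2: np.ndarray) -> np.ndarray:
    w = np.sqrt(omega2)
    rho = (omega2[:, :, None] + omega2[:, None, :] - t) / (
        2.0 * w[:, :, None] * w[:, None, :]
    )
    rho = np.clip(rho, -1.0, 1.0)
    idx = np.arange(t.shape[1])
    rho[:, idx, idx] = 1.0
    return 0.5 * (rho + rho.transpose(0, 2, 1))


def _batched_basis_correlations(
    t: np.ndarray,
    exclusion_threshold: float = 0.1,
    max_exclusions: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the basis-variance system with iterative pair exclusion.

    ``t``: (B, D, D) log-ratio variance stack. Returns (rho, omega2) with
    shapes (B, D, D) and (B, D). Each batch element runs its own exclusion
    sequence; exclusion stops per element when the strongest remaining
    correlation falls below the threshold, a node would drop below two
    included partners, or ``max_exclusions`` pairs have been removed.
    """
    B, D, _ = t.shape
    if D < 4:
        raise ValueError(
            f"need at least 4 OTUs for the basis-variance system (got {D}); "
            "fall back to naive Pearson for smaller problems"
        )
    if max_exclusions is None:
        max_exclusions = (D * (D - 1) // 2) // 10
    eye = np.eye(D)
    include = np.broadcast_to(1.0 - eye, (B, D, D)).copy()
    deg = include.sum(-1)
    M = include.copy()
    M[:, np.arange(D), np.arange(D)] = deg
    Minv = np.linalg.inv(M)
    rhs = (t * include).sum(-1)
    omega2 = np.clip(np.einsum("bij,bj->bi", Minv, rhs), _OMEGA_EPS, None)
    rho = _rho_batch(t, omega2)
    active = np.ones(B, dtype=bool)
    n_clipped = 0
    for _ in range(int(max_exclusions)):
        if not active.any():
            break
        b_idx = np.flatnonzero(active)
        masked = (np.abs(rho[b_idx]) * include[b_idx]).reshape(len(b_idx), -1)
        flat = masked.argmax(1)
        vals = masked[np.arange(len(b_idx)), flat]
        i_arr, j_arr = np.divmod(flat, D)
        stop = (vals <= exclusion_threshold) | (deg[b_idx, i_arr] <= 2) | (
            deg[b_idx, j_arr] <= 2
        )
        active[b_idx[stop]] = False
        keep = ~stop
        if not keep.any():
            continue
        b2, i2, j2 = b_idx[keep], i_arr[keep], j_arr[keep]
        u = Minv[b2, :, i2] + Minv[b2, :, j2]  # M^-1 (e_i + e_j)
        k = np.arange(len(b2))
        denom = 1.0 - (u[k, i2] + u[k, j2])
        good = denom > 1e-10
        if not good.all():
            active[b2[~good]] = False
            b2, i2, j2, u, denom, k = (
                b2[good], i2[good], j2[good], u[good], denom[good], np.arange(good.sum()),
            )
            if len(b2) == 0:
                continue
        # exclude pair (i, j): M -> M - (e_i+e_j)(e_i+e_j)^T, Sherman-Morrison
        Minv[b2] += u[:, :, None] * u[:, None, :] / denom[:, None, None]
        include[b2, i2, j2] = 0.0
        include[b2, j2, i2] = 0.0
        deg[b2, i2] -= 1.0
        deg[b2, j2] -= 1.0
        tij = t[b2, i2, j2]
        rhs[b2, i2] -= tij
        rhs[b2, j2] -= tij
        om = np.einsum("bij,bj->bi", Minv[b2], rhs[b2])
        n_clipped += int((om < _OMEGA_EPS).sum())
        omega2[b2] = np.clip(om, _OMEGA_EPS, None)
        rho[b2] = _rho_batch(t[b2], omega2[b2])
    if n_clipped:
        logger.debug("clipped %d non-positive basis variances to %.0e", n_clipped, _OMEGA_EPS)
    return rho, omega2


def estimate_basis_correlations(
    lrv: LogRatioVariance,
    exclusion_threshold: float = 0.1,
    max_exclusions: int | None = None,
) -> np.ndarray:
    """Basis correlations from one log-ratio variance matrix.

    Solves for basis variances under the sparsity approximation, computes
    rho, then repeatedly drops the most strongly correlated remaining pair
    with |rho| > ``exclusion_threshold`` from the linear system and re-solves
    (up to ``max_exclusions`` pairs, default 10% of all pairs). Returns the
    final clipped correlation matrix; basis variances are stored on ``lrv``.
    """
    rho, omega2 = _batched_basis_correlations(
        lrv.t[None], exclusion_threshold, max_exclusions
    )
    lrv.omega2 = omega2[0]
    return rho[0]


def _counts_matrix(counts) -> tuple[np.ndarray, list]:
    """Accept an OtuTable or an OTU x sample DataFrame; return samples x OTUs."""
    if hasattr(counts, "counts"):  # OtuTable
        df = counts.counts
    else:
        df = counts
    return df.to_numpy(dtype=float).T, list(df.index)


def _estimate_from_counts(
    x: np.ndarray, rng, n_iter, exclusion_threshold, max_exclusions,
    column_perms: np.ndarray | None = None,
) -> np.ndarray:
    """Median over ``n_iter`` Dirichlet posterior draws (add-one prior).

    ``column_perms`` (n_samples x n_otus row-index array), if given, permutes
    each OTU's posterior fractions across samples after every draw — the
    permutation null. Permuting fractions rather than raw counts keeps each
    value's depth-dependent sampling noise attached to it, so the null
    preserves every OTU's marginal log-abundance distribution exactly while
    destroying association (log-ratio variances are invariant to the row
    closure, so the permuted matrix needs no renormalization).
    """
    g = rng.standard_gamma(x + 1.0, size=(n_iter,) + x.shape)
    f = g / g.sum(axis=2, keepdims=True)
    if column_perms is not None:
        cols = np.arange(x.shape[1])[None, :]
        f = f[:, column_perms, cols]
    rho, _ = _batched_basis_correlations(_t_stack(f), exclusion_threshold, max_exclusions)
    med = np.median(rho, axis=0)
    med = 0.5 * (med + med.T)
    np.fill_diagonal(med, 1.0)
    return med


def sparcc_estimate(
    counts,
    n_iter: int = 20,
    seed: int | None = None,
    exclusion_threshold: float = 0.1,
    max_exclusions: int | None = None,
) -> pd.DataFrame:
    """Median-of-``n_iter`` SparCC correlation estimate.

    Each iteration draws fractions from the add-one Dirichlet posterior of
    every sample, computes log-ratio variances, and runs the basis-variance
    estimator; the elementwise median over iterations is returned (symmetric,
    unit diagonal). Deterministic given ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    x, otu_ids = _counts_matrix(counts)
    rng = np.random.default_rng(seed)
    rho = _estimate_from_counts(x, rng, n_iter, exclusion_threshold, max_exclusions)
    return pd.DataFrame(rho, index=otu_ids, columns=otu_ids)


def bootstrap_pvalues(
    counts,
    observed_rho: pd.DataFrame,
    n_boot: int = 100,
    seed: int | None = None,
    n_iter_boot: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclusions: int | None = None,
) -> pd.DataFrame:
    """Two-sided permutation p-values for every correlation.

    Each of ``n_boot`` null replicates draws one independent permutation per
    OTU and applies it to that OTU's posterior fractions across samples
    (no association, same marginal distributions), then re-estimates the
    correlation matrix with the same ``n_iter_boot``-pass median estimator
    used for the observed data.
    p_ij = (1 + #{|rho_null| >= |rho_obs|}) / (n_boot + 1), so p is never 0
    (add-one correction). Diagonal set to 0 by convention.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    x, otu_ids = _counts_matrix(counts)
    if list(observed_rho.index) != otu_ids:
        raise ValueError("observed_rho index does not match the count table")
    rng = np.random.default_rng(seed)
    obs = np.abs(observed_rho.to_numpy())
    exceed = np.zeros_like(obs)
    n_samples = x.shape[0]
    for _ in range(n_boot):
        perms = np.argsort(rng.random((n_samples, x.shape[1])), axis=0)
        rho_null = _estimate_from_counts(
            x, rng, n_iter_boot, exclusion_threshold, max_exclusions,
            column_perms=perms,
        )
        exceed += np.abs(rho_null) >= obs
    pvals = (1.0 + exceed) / (n_boot + 1.0)
    pvals = 0.5 * (pvals + pvals.T)
    np.fill_diagonal(pvals, 0.0)
    return pd.DataFrame(pvals, index=otu_ids, columns=otu_ids)


def sparcc(
    counts,
    n_iter: int = 20,
    n_boot: int = 100,
    seed: int | None = None,
    n_iter_boot: int | None = None,
    exclusion_threshold: float = 0.1,
    max_exclusions: int | None = None,
) -> CorrelationResult:
    """Full stage: median-of-iterations estimate plus bootstrap p-values.

    ``n_iter_boot`` defaults to ``n_iter`` so null replicates use the same
    estimator as the observed matrix; set it lower to trade calibration for
    speed.
    """
    if n_iter_boot is None:
        n_iter_boot = n_iter
    rng = np.random.default_rng(seed)
    est_seed = int(rng.integers(2**31))
    boot_seed = int(rng.integers(2**31))
    rho = sparcc_estimate(
        counts, n_iter=n_iter, seed=est_seed,
        exclusion_threshold=exclusion_threshold, max_exclusions=max_exclusions,
    )
    pvals = bootstrap_pvalues(
        counts, rho, n_boot=n_boot, seed=boot_seed, n_iter_boot=n_iter_boot,
        exclusion_threshold=exclusion_threshold, max_exclusions=max_exclusions,
    )
    return CorrelationResult(
        rho=rho, pvals=pvals, n_iterations=n_iter, n_bootstraps=n_boot, seed=seed
    )


def pearson_on_proportions(counts) -> pd.DataFrame:
    """Naive Pearson correlation of per-sample proportions.

    Not part of the pipeline: the baseline the compositionality-robust
    estimator is compared against in the robustness harness.
    """
    x, otu_ids = _counts_matrix(counts)
    props = (x + 1.0) / (x + 1.0).sum(axis=1, keepdims=True)
    r = np.corrcoef(props, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=otu_ids, columns=otu_ids)


def pearson_pvalues_by_permutation(
    counts, observed_r: pd.DataFrame, n_boot: int = 100, seed: int | None = None
) -> pd.DataFrame:
    """Permutation p-values for the naive Pearson baseline (same null)."""
    x, otu_ids = _counts_matrix(counts)
    rng = np.random.default_rng(seed)
    obs = np.abs(observed_r.to_numpy())
    exceed = np.zeros_like(obs)
    for _ in range(n_boot):
        perm = rng.permuted(x, axis=0)
        r_null = pearson_on_proportions(pd.DataFrame(perm.T, index=otu_ids)).to_numpy()
        exceed += np.abs(r_null) >= obs
    pvals = (1.0 + exceed) / (n_boot + 1.0)
    np.fill_diagonal(pvals, 0.0)
    return pd.DataFrame(0.5 * (pvals + pvals.T), index=otu_ids, columns=otu_ids)


# -- I/O -------------------------------------------------------------------


def write_correlation_result(result: CorrelationResult, rho_path, pvals_path, sidecar_path) -> None:
    result.rho.to_csv(rho_path, sep="\t")
    result.pvals.to_csv(pvals_path, sep="\t")
    with open(sidecar_path, "w") as fh:
        json.dump(
            {
                "n_iterations": result.n_iterations,
                "n_bootstraps": result.n_bootstraps,
                "seed": result.seed,
            },
            fh,
            indent=1,
        )
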