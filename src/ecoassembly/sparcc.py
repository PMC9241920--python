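"""SparCC: correlation inference for compositional count data.

Sequencing counts only carry relative information, so naive correlations
between proportions are biased (closure forces spurious negative
covariance).  SparCC works from log-ratio variances

    t_ij = Var[ log(x_i / x_j) ] = w_i + w_j - 2 * rho_ij * sqrt(w_i w_j)

where w_i is the (unobservable) basis log-abundance variance.  Assuming
the correlations are sparse, the row sums of t yield a linear system for
the basis variances; correlations follow as

    r_ij = (w_i + w_j - t_ij) / (2 * sqrt(w_i * w_j)),   clipped to [-1, 1].

Pairs whose estimated |r| exceeds a threshold violate the sparsity
assumption and are iteratively excluded from the system, which is then
re-solved.  Count uncertainty is propagated by re-drawing the underlying
fractions from a Dirichlet posterior (unit prior) per estimation
iteration and taking the element-wise median correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .otu import OtuTable

__all__ = ["sparcc_correlations", "sparcc_bootstrap_p"]

_MIN_VARIANCE = 1e-10


def _sample_fractions(counts: np.ndarray, rng: np.random.Generator, method: str) -> np.ndarray:
    """Component fractions from counts: Dirichlet posterior with a unit
    prior ("dirichlet", the default) or a fixed +1 pseudocount."""
    if method == "dirichlet":
        gam = rng.standard_gamma(counts + 1.0)
        return gam / gam.sum(axis=1, keepdims=True)
    if method == "pseudocount":
        f = counts + 1.0
        return f / f.sum(axis=1, keepdims=True)
    raise ValueError(f"unknown zero-handling method {method!r}")


def _variation_matrix(fractions: np.ndarray) -> np.ndarray:
    """t_ij = Var(log(x_i/x_j)) over samples, via the log covariance."""
    logf = np.log(fractions)
    cov = np.cov(logf, rowvar=False)
    var = np.diag(cov)
    return var[:, None] + var[None, :] - 2.0 * cov


def _basis_correlations(
    t_mat: np.ndarray,
    n_exclusion_iters: int,
    exclusion_threshold: float,
) -> np.ndarray:
    """Solve the sparse-basis approximation for one variation matrix,
    iteratively excluding the strongest above-threshold pair."""
    d = t_mat.shape[0]
    if d < 4:
        raise ValueError("SparCC needs at least 4 taxa")
    m_mat = np.ones((d, d)) + np.diag(np.full(d, d - 2.0))
    t_vec = t_mat.sum(axis=1)
    excluded_mask = np.zeros((d, d), dtype=bool)
    # a component may lose at most d-3 pairs, or the system degenerates
    exclusion_count = np.zeros(d, dtype=int)
    corr = None
    for _ in range(n_exclusion_iters + 1):
        omega = np.linalg.solve(m_mat, t_vec)
        omega = np.maximum(omega, _MIN_VARIANCE)
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        corr = np.clip((omega[:, None] + omega[None, :] - t_mat) / denom, -1.0, 1.0)
        np.fill_diagonal(corr, 1.0)
        strength = np.abs(corr)
        np.fill_diagonal(strength, 0.0)
        strength[excluded_mask] = 0.0
        saturated = exclusion_count >= d - 3
        strength[saturated, :] = 0.0
        strength[:, saturated] = 0.0
        i, j = np.unravel_index(int(np.argmax(strength)), strength.shape)
        if strength[i, j] <= exclusion_threshold:
            break
        # drop pair (i,j) from the linear system
        excluded_mask[i, j] = excluded_mask[j, i] = True
        exclusion_count[i] += 1
        exclusion_count[j] += 1
        m_mat[i, i] -= 1.0
        m_mat[j, j] -= 1.0
        m_mat[i, j] -= 1.0
        m_mat[j, i] -= 1.0
        t_vec[i] -= t_mat[i, j]
        t_vec[j] -= t_mat[i, j]
    return corr


def _sparcc_once(
    counts: np.ndarray,
    rng: np.random.Generator,
    n_estimation_iters: int,
    n_exclusion_iters: int,
    exclusion_threshold: float,
    zero_handling: str,
) -> np.ndarray:
    estimates = np.empty((n_estimation_iters, counts.shape[1], counts.shape[1]))
    for it in range(n_estimation_iters):
        fractions = _sample_fractions(counts.astype(float), rng, zero_handling)
        t_mat = _variation_matrix(fractions)
        estimates[it] = _basis_correlations(t_mat, n_exclusion_iters, exclusion_threshold)
    out = np.median(estimates, axis=0)
    np.fill_diagonal(out, 1.0)
    return np.clip(out, -1.0, 1.0)


def sparcc_correlations(
    table: OtuTable,
    n_estimation_iters: int = 20,
    n_exclusion_iters: int = 10,
    exclusion_threshold: float = 0.1,
    seed: int = 0,
    zero_handling: str = "dirichlet",
) -> pd.DataFrame:
    """SparCC correlation matrix (taxa x taxa, symmetric, unit diagonal).

    Defaults mirror the reference algorithm: 20 estimation iterations,
    10 exclusion iterations, exclusion threshold 0.1.
    """
    rng = np.random.default_rng(seed)
    corr = _sparcc_once(
        table.counts,
        rng,
        n_estimation_iters,
        n_exclusion_iters,
        exclusion_threshold,
        zero_handling,
    )
    return pd.DataFrame(corr, index=table.taxon_ids, columns=table.taxon_ids)


def sparcc_bootstrap_p(
    table: OtuTable,
    n_boot: int = 100,
    seed: int = 0,
    n_estimation_iters: int = 20,
    n_exclusion_iters: int = 10,
    exclusion_threshold: float = 0.1,
    zero_handling: str = "dirichlet",
) -> pd.DataFrame:
    """SparCC estimates with permutation-bootstrap two-sided p-values.

    Each bootstrap permutes every taxon's counts across samples
    independently (destroying all true correlation while keeping marginal
    distributions) and recomputes SparCC; p = (1 + #{|r_boot| >= |r_obs|})
    / (n_boot + 1).  Returns a long table of unordered taxon pairs with
    columns id_a, id_b, estimate, p_value.
    """
    if n_boot < 20:
        raise ValueError("need at least 20 bootstrap permutations")
    master = np.random.SeedSequence(seed)
    obs_rng = np.random.default_rng(master.spawn(1)[0])
    counts = table.counts
    obs = _sparcc_once(
        counts, obs_rng, n_estimation_iters, n_exclusion_iters,
        exclusion_threshold, zero_handling,
    )
    exceed = np.zeros_like(obs)
    for ss in master.spawn(n_boot):
        rng = np.random.default_rng(ss)
        perm = np.empty_like(counts)
        for col in range(counts.shape[1]):
            perm[:, col] = rng.permutation(counts[:, col])
        boot = _sparcc_once(
            perm, rng, n_estimation_iters, n_exclusion_iters,
            exclusion_threshold, zero_handling,
        )
        exceed += (np.abs(boot) >= np.abs(obs)).astype(float)
    pvals = (exceed + 1.0) / (n_boot + 1.0)
    taxa = table.taxon_ids
    records = []
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            records.append((taxa[i], taxa[j], float(obs[i, j]), float(pvals[i, j])))
    return pd.DataFrame(records, columns=["id_a", "id_b", "estimate", "p_value"])
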