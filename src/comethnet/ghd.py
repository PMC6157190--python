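"""Generalized Hamming distance (GHD) test for differential module topology.

Each module's pre- and post-treatment correlation submatrices are
binarized at a |correlation| threshold, edges are weighted by one-step
topological overlap of the binary graph, and the GHD — the mean squared
difference of mean-centered edge weights — is compared against a node-label
permutation null.  The permutation distribution is approximately normal for
scale-free modules, so a Z score and two-sided normal p-value are reported;
rejecting the independence null means the module pair shares structure
(no topological change).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from comethnet.network import ModuleAssignment, _tom_offdiag

__all__ = [
    "binarize_network",
    "binary_tom_weights",
    "ghd_statistic",
    "ghd_null_moments",
    "ghd_test",
    "bonferroni_threshold",
    "z_to_p",
    "GHDNullMoments",
    "DegenerateNullError",
]


class DegenerateNullError(ValueError):
    """Permutation null has zero variance (e.g. both graphs empty/complete)."""


@dataclass
class GHDNullMoments:
    mu_pi: float
    sigma2_pi: float
    n_perm: int


def binarize_network(
    cor: pd.DataFrame, tau: float = 0.2, inclusive: bool = True
) -> pd.DataFrame:
    """(0,1)-adjacency with an edge where |cor| >= tau (or > tau); zero diagonal."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    a = np.abs(cor.to_numpy(dtype=float))
    adj = (a >= tau) if inclusive else (a > tau)
    adj = adj.astype(float)
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=cor.index, columns=cor.columns)


def binary_tom_weights(net: pd.DataFrame) -> np.ndarray:
    """One-step topological overlap edge weights of a binary network.

    ``w_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` for
    ``i != j`` and 0 on the diagonal; isolated non-adjacent pairs get 0.
    """
    a = net.to_numpy(dtype=float) if isinstance(net, pd.DataFrame) else np.asarray(net, dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("binary network is not symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    return _tom_offdiag(a)


def _centered_offdiag(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    mean = (W.sum() - np.trace(W)) / (n * (n - 1))
    C = W - mean
    np.fill_diagonal(C, 0.0)
    return C


def ghd_statistic(W_A: np.ndarray, W_B: np.ndarray) -> float:
    """Mean squared difference of mean-centered off-diagonal weights.

    ``GHD = (1 / (n (n-1))) * sum_{i != j} (wbar_A_ij - wbar_B_ij)^2`` where
    each matrix is centered by its own off-diagonal mean.
    """
    W_A = np.asarray(W_A, dtype=float)
    W_B = np.asarray(W_B, dtype=float)
    if W_A.shape != W_B.shape:
        raise ValueError("weight matrices have different shapes")
    n = W_A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes")
    diff = _centered_offdiag(W_A) - _centered_offdiag(W_B)
    return float((diff**2).sum() / (n * (n - 1)))


def ghd_null_moments(
    W_A: np.ndarray, W_B: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> GHDNullMoments:
    """Monte-Carlo moments of GHD under node-label permutation of network A.

    Relabeling a graph relabels its topological-overlap weights, so each
    draw permutes the rows and columns of ``W_A`` jointly.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    W_A = np.asarray(W_A, dtype=float)
    W_B = np.asarray(W_B, dtype=float)
    n = W_A.shape[0]
    rng = np.random.default_rng(seed)
    stats = np.empty(n_perm)
    for b in range(n_perm):
        p = rng.permutation(n)
        stats[b] = ghd_statistic(W_A[np.ix_(p, p)], W_B)
    mu = float(stats.mean())
    var = float(stats.var(ddof=1))
    # zero variance up to float noise from summation order
    if var <= (1e-9 * max(mu, 1e-12)) ** 2:
        raise DegenerateNullError("GHD permutation null has zero variance")
    return GHDNullMoments(mu_pi=mu, sigma2_pi=var, n_perm=n_perm)


def z_to_p(z: float) -> float:
    """Two-sided standard-normal p-value."""
    return float(2.0 * norm.sf(abs(z)))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def ghd_test(
    pre_cor: pd.DataFrame,
    post_cor: pd.DataFrame,
    modules: ModuleAssignment,
    tau: float = 0.2,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-module GHD test of pre vs post topology.

    Returns a table indexed by module with the observed GHD, permutation
    null moments, Z score, two-sided p and ``preserved`` — True when the
    independence null is rejected at the Bonferroni level ``alpha / m``
    (small p means the two module networks share structure, i.e. no
    topological change).  Degenerate nulls are flagged and yield missing
    Z / p with ``preserved = False``.
    """
    if not pre_cor.index.equals(post_cor.index):
        raise ValueError("pre and post networks have different probe sets")
    rng = np.random.default_rng(seed)
    tested = []
    for m in range(1, modules.n_modules + 1):
        probes = [p for p in modules.module_probes(m) if p in pre_cor.index]
        if len(probes) < 3:
            warnings.warn(f"module {m} has fewer than 3 probes after restriction; skipped")
            continue
        tested.append((m, probes))
    n_tests = len(tested)
    threshold = bonferroni_threshold(alpha, n_tests) if n_tests else np.nan

    rows = []
    for m, probes in tested:
        sub_pre = pre_cor.loc[probes, probes]
        sub_post = post_cor.loc[probes, probes]
        W_A = binary_tom_weights(binarize_network(sub_pre, tau))
        W_B = binary_tom_weights(binarize_network(sub_post, tau))
        observed = ghd_statistic(W_A, W_B)
        mod_seed = int(rng.integers(2**63))
        try:
            moments = ghd_null_moments(W_A, W_B, n_perm=n_perm, seed=mod_seed)
            z = (observed - moments.mu_pi) / np.sqrt(moments.sigma2_pi)
            p = z_to_p(z)
            degenerate = False
        except DegenerateNullError:
            warnings.warn(f"module {m}: degenerate GHD permutation null")
            moments = GHDNullMoments(observed, 0.0, n_perm)
            z, p, degenerate = np.nan, np.nan, True
        rows.append(
            {
                "module": m,
                "size": len(probes),
                "ghd": observed,
                "mu_null": moments.mu_pi,
                "sigma2_null": moments.sigma2_pi,
                "z": z,
                "p_value": p,
                "preserved": bool(p < threshold) if np.isfinite(p) else False,
                "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "module", "size", "ghd", "mu_null", "sigma2_null", "z",
            "p_value", "preserved", "degenerate",
        ],
    ).set_index("module")
    out.attrs["bonferroni_threshold"] = threshold
    return out
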