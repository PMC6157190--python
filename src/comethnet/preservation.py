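"""Permutation-based module preservation between two networks.

For each reference module, density statistics (mean within-module
correlation and adjacency in the test network) and connectivity statistics
(correlation of intramodular connectivity vectors and of the vectorized
within-module correlation entries between reference and test) are compared
against a null in which the module is replaced by random probe sets of the
same size drawn from the test network.  Per-statistic permutation Z scores
aggregate into Z_density, Z_connectivity and Z_summary; medianRank ranks
modules on the observed statistics alone.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from comethnet.network import ModuleAssignment

__all__ = [
    "observed_stats",
    "module_preservation",
    "preservation_category",
    "DENSITY_STATS",
    "CONNECTIVITY_STATS",
]

DENSITY_STATS = ("mean_cor", "mean_adj")
CONNECTIVITY_STATS = ("cor_kIM", "cor_cor")
_ALL_STATS = DENSITY_STATS + CONNECTIVITY_STATS


def _offdiag_mean(M: np.ndarray) -> float:
    n = M.shape[0]
    return float((M.sum() - np.trace(M)) / (n * (n - 1)))


def _safe_cor(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _module_stats(
    ref_cor: np.ndarray,
    ref_adj: np.ndarray,
    test_cor: np.ndarray,
    test_adj: np.ndarray,
    ref_idx: np.ndarray,
    test_idx: np.ndarray,
) -> dict[str, float]:
    """The four preservation statistics for one (ref module, test set) pair."""
    rc = ref_cor[np.ix_(ref_idx, ref_idx)]
    ra = ref_adj[np.ix_(ref_idx, ref_idx)]
    tc = test_cor[np.ix_(test_idx, test_idx)]
    ta = test_adj[np.ix_(test_idx, test_idx)]
    iu = np.triu_indices(len(ref_idx), k=1)
    kim_ref = ra.sum(axis=0)
    kim_test = ta.sum(axis=0)
    return {
        "mean_cor": _offdiag_mean(tc),
        "mean_adj": _offdiag_mean(ta),
        "cor_kIM": _safe_cor(kim_ref, kim_test),
        "cor_cor": _safe_cor(rc[iu], tc[iu]),
    }


def _check_alignment(ref_cor, test_cor, modules: ModuleAssignment) -> None:
    if not ref_cor.index.equals(test_cor.index):
        raise ValueError("reference and test networks have different probe sets")
    if not ref_cor.index.equals(modules.probe_ids):
        raise ValueError("module assignment does not match network probes")


def observed_stats(
    ref_cor: pd.DataFrame,
    ref_adj: pd.DataFrame,
    test_cor: pd.DataFrame,
    test_adj: pd.DataFrame,
    modules: ModuleAssignment,
) -> pd.DataFrame:
    """Observed preservation statistics per module (index = module label)."""
    _check_alignment(ref_cor, test_cor, modules)
    rc, ra = ref_cor.to_numpy(), ref_adj.to_numpy()
    tc, ta = test_cor.to_numpy(), test_adj.to_numpy()
    labels = modules.labels.to_numpy()
    rows = {}
    for m in range(1, modules.n_modules + 1):
        idx = np.flatnonzero(labels == m)
        if len(idx) < 3:
            raise ValueError(f"module {m} has fewer than 3 probes")
        rows[m] = _module_stats(rc, ra, tc, ta, idx, idx)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "module"
    return out


def preservation_category(z_summary: float) -> str:
    if z_summary > 10:
        return "strong"
    if z_summary >= 2:
        return "weak"
    return "none"


def median_rank(observed: pd.DataFrame) -> pd.Series:
    """Median over statistics of each module's rank (1 = highest observed)."""
    ranks = observed[list(_ALL_STATS)].rank(ascending=False, method="average")
    return ranks.median(axis=1).rename("median_rank")


def module_preservation(
    ref_cor: pd.DataFrame,
    ref_adj: pd.DataFrame,
    test_cor: pd.DataFrame,
    test_adj: pd.DataFrame,
    modules: ModuleAssignment,
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation Z_summary / medianRank preservation table.

    Null draws assign each module a random probe set of its own size from
    all network probes; ``Z = (observed - mean_null) / sd_null`` per
    statistic.  ``Z_density`` / ``Z_connectivity`` are medians over the
    density / connectivity statistic Zs and ``Z_summary`` their mean.
    ``median_rank`` depends on the observed statistics only.
    """
    if n_perm < 50:
        raise ValueError("n_perm must be >= 50")
    _check_alignment(ref_cor, test_cor, modules)
    obs = observed_stats(ref_cor, ref_adj, test_cor, test_adj, modules)
    rc, ra = ref_cor.to_numpy(), ref_adj.to_numpy()
    tc, ta = test_cor.to_numpy(), test_adj.to_numpy()
    labels = modules.labels.to_numpy()
    n_probes = len(labels)
    rng = np.random.default_rng(seed)

    module_idx = {m: np.flatnonzero(labels == m) for m in obs.index}
    null: dict[int, list[dict[str, float]]] = {m: [] for m in obs.index}
    for _ in range(n_perm):
        for m in obs.index:
            size = len(module_idx[m])
            perm_idx = rng.choice(n_probes, size=size, replace=False)
            null[m].append(_module_stats(rc, ra, tc, ta, module_idx[m], perm_idx))

    rows = []
    for m in obs.index:
        nt = pd.DataFrame(null[m])
        z = {}
        for stat in _ALL_STATS:
            mu, sd = nt[stat].mean(), nt[stat].std(ddof=1)
            if sd == 0:
                warnings.warn(f"degenerate null (sd=0) for {stat} in module {m}")
                z[stat] = np.inf if obs.loc[m, stat] > mu else (-np.inf if obs.loc[m, stat] < mu else 0.0)
            else:
                z[stat] = (obs.loc[m, stat] - mu) / sd
        z_density = float(np.median([z[s] for s in DENSITY_STATS]))
        z_connectivity = float(np.median([z[s] for s in CONNECTIVITY_STATS]))
        z_summary = (z_density + z_connectivity) / 2.0
        rows.append(
            {
                "module": m,
                "size": len(module_idx[m]),
                **{f"Z_{s}": z[s] for s in _ALL_STATS},
                "Z_density": z_density,
                "Z_connectivity": z_connectivity,
                "Z_summary": z_summary,
                "category": preservation_category(z_summary),
            }
        )
    out = pd.DataFrame(rows).set_index("module")
    out["median_rank"] = median_rank(obs)
    return out
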