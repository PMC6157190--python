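"""Weighted correlation network construction and module detection.

Pipeline: pairwise Pearson correlation on residuals -> soft-threshold power
chosen by the approximate scale-free topology criterion -> unsigned
adjacency ``a_ij = |cor_ij|**beta`` -> topological overlap matrix (TOM) ->
average-linkage hierarchical clustering of ``1 - TOM`` with a height-based
branch decomposition enforcing a minimum module size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

__all__ = [
    "ModuleAssignment",
    "SoftPowerChoice",
    "pairwise_correlation",
    "scale_free_fit",
    "soft_threshold_scan",
    "pick_soft_power",
    "adjacency_from_correlation",
    "topological_overlap",
    "detect_modules",
    "MODULE_COLORS",
]

# Color aliases assigned to modules in descending size order; 0 = unassigned.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]
UNASSIGNED_COLOR = "grey"


class ModuleAssignment:
    """Probe -> module label map; label 0 means unassigned.

    Labels are contiguous integers from 1, ordered by descending module
    size, each aliased to a color.  Construction renumbers arbitrary
    non-zero labels into that canonical order.
    """

    def __init__(self, labels: pd.Series):
        labels = labels.astype(int)
        sizes = labels[labels != 0].value_counts()
        # stable renumber: by descending size, ties by first appearance
        order = sorted(sizes.index, key=lambda m: (-sizes[m], list(labels).index(m)))
        remap = {old: new for new, old in enumerate(order, start=1)}
        remap[0] = 0
        self.labels = labels.map(remap).rename("module")

    @property
    def probe_ids(self) -> pd.Index:
        return self.labels.index

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0

    def sizes(self) -> pd.Series:
        s = self.labels[self.labels != 0].value_counts().sort_index()
        s.name = "size"
        return s

    def module_probes(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]

    def color(self, module: int) -> str:
        if module == 0:
            return UNASSIGNED_COLOR
        return MODULE_COLORS[(module - 1) % len(MODULE_COLORS)]

    def colors(self) -> pd.Series:
        return self.labels.map(self.color).rename("color")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"probe_id": self.labels.index, "module": self.labels.to_numpy(),
             "color": self.colors().to_numpy()}
        )

    def __eq__(self, other) -> bool:  # same partition, same probe order
        return isinstance(other, ModuleAssignment) and self.labels.equals(other.labels)

    def __repr__(self) -> str:
        return f"ModuleAssignment({self.n_modules} modules, {len(self.labels)} probes)"


def pairwise_correlation(residuals: pd.DataFrame, min_overlap: int = 3) -> pd.DataFrame:
    """Probe x probe Pearson correlation on pairwise-complete samples.

    Pairs with fewer than ``min_overlap`` overlapping samples, and pairs
    where either probe has zero variance within the overlap, get
    correlation 0 (a warning reports the count).  Diagonal is 1.
    """
    values = residuals.to_numpy(dtype=float)
    if not np.isnan(values).any():
        with np.errstate(invalid="ignore", divide="ignore"):
            cor = np.corrcoef(values)
        n_bad = int(np.isnan(cor).sum())
        if n_bad:
            warnings.warn(f"{n_bad} zero-variance correlation entries set to 0")
            cor = np.nan_to_num(cor, nan=0.0)
    else:
        cor = residuals.T.corr(min_periods=min_overlap).to_numpy()
        n_bad = int(np.isnan(cor).sum())
        if n_bad:
            warnings.warn(
                f"{n_bad} correlation entries with <{min_overlap} overlapping "
                "samples or zero variance set to 0"
            )
            cor = np.nan_to_num(cor, nan=0.0)
    np.fill_diagonal(cor, 1.0)
    cor = np.clip((cor + cor.T) / 2.0, -1.0, 1.0)
    return pd.DataFrame(cor, index=residuals.index, columns=residuals.index)


def scale_free_fit(connectivities: np.ndarray, n_bins: int = 10) -> float:
    """Signed R² of the log-log degree-distribution fit.

    Connectivities are binned into ``n_bins`` equal-width bins; the log10
    relative frequency is regressed on the log10 mean connectivity of each
    non-empty bin.  The returned index is R² with the sign flipped so that
    a negative slope (scale-free-like decay) gives a positive value.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    k = np.asarray(connectivities, dtype=float)
    k = k[k > 0]
    if k.size == 0:
        raise ValueError("no positive connectivities")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges[-1] += 1e-12
    which = np.digitize(k, edges) - 1
    mean_k = np.array([k[which == b].mean() if (which == b).any() else np.nan for b in range(n_bins)])
    freq = np.array([(which == b).mean() for b in range(n_bins)])
    ok = (freq > 0) & np.isfinite(mean_k) & (mean_k > 0)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 non-empty connectivity bins")
    fit = linregress(np.log10(mean_k[ok]), np.log10(freq[ok]))
    return float(fit.rvalue**2 * (-np.sign(fit.slope) if fit.slope != 0 else 0.0))


def soft_threshold_scan(
    cor: pd.DataFrame, powers=tuple(range(1, 21)), n_bins: int = 10
) -> pd.DataFrame:
    """Scale-free fit R² and mean connectivity for each candidate power."""
    abs_cor = np.abs(cor.to_numpy(dtype=float))
    np.fill_diagonal(abs_cor, 0.0)
    rows = []
    for beta in powers:
        k = (abs_cor**beta).sum(axis=0)
        try:
            r2 = scale_free_fit(k, n_bins=n_bins)
        except ValueError:
            r2 = np.nan
        rows.append({"power": beta, "scale_free_r2": r2, "mean_connectivity": float(k.mean())})
    return pd.DataFrame(rows)


@dataclass
class SoftPowerChoice:
    power: int
    scan: pd.DataFrame
    below_threshold: bool  # True when no power reached the R² threshold


def pick_soft_power(
    cor: pd.DataFrame,
    powers=tuple(range(1, 21)),
    r2_threshold: float = 0.9,
    n_bins: int = 10,
) -> SoftPowerChoice:
    """Smallest power whose scale-free R² exceeds the threshold.

    Falls back to the argmax R² (flagged) when no candidate reaches it.
    """
    powers = list(powers)
    if not powers:
        raise ValueError("powers must be non-empty")
    scan = soft_threshold_scan(cor, powers=powers, n_bins=n_bins)
    above = scan[scan["scale_free_r2"] > r2_threshold]
    if len(above):
        return SoftPowerChoice(int(above["power"].iloc[0]), scan, False)
    if scan["scale_free_r2"].notna().any():
        best = int(scan.loc[scan["scale_free_r2"].idxmax(), "power"])
    else:
        best = powers[0]
    warnings.warn(
        f"no power reached scale-free R² > {r2_threshold}; "
        f"using argmax R² power={best}"
    )
    return SoftPowerChoice(best, scan, True)


def adjacency_from_correlation(cor: pd.DataFrame, power: float) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency ``|cor|**power`` with zero diagonal."""
    adj = np.abs(cor.to_numpy(dtype=float)) ** power
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=cor.index, columns=cor.columns)


def _tom_offdiag(adj: np.ndarray) -> np.ndarray:
    """Topological overlap for i != j; diagonal of result left at 0.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``.
    """
    a = adj.astype(float)
    shared = a @ a
    k = a.sum(axis=0)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 0.0)
    return tom


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """TOM of a symmetric [0,1] adjacency with zero diagonal; TOM_ii = 1."""
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency matrix is not symmetric")
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    tom = _tom_offdiag(a)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def _cluster_tree(tom: pd.DataFrame) -> np.ndarray:
    """Average-linkage tree on dissimilarity 1 - TOM."""
    d = 1.0 - tom.to_numpy(dtype=float)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return linkage(squareform(d, checks=False), method="average")


def _core_cut_height(Z: np.ndarray, min_module_size: int) -> float | None:
    """Lowest merge height maximizing the count of >=min-size branches.

    Walks the merge sequence once with a union-find-style size table; the
    dendrogram is only well defined between distinct heights, so counts are
    taken where the next merge is strictly higher.  Returns None when no
    branch ever reaches ``min_module_size`` (then everything is unassigned).
    """
    n = Z.shape[0] + 1
    sizes = np.ones(2 * n - 1, dtype=int)
    heights = Z[:, 2]
    n_big = 0
    best_count, best_height = 0, None
    for i in range(n - 1):
        a, b = int(Z[i, 0]), int(Z[i, 1])
        merged = sizes[a] + sizes[b]
        sizes[n + i] = merged
        n_big += int(merged >= min_module_size)
        n_big -= int(sizes[a] >= min_module_size) + int(sizes[b] >= min_module_size)
        if (i == n - 2 or heights[i + 1] > heights[i]) and n_big > best_count:
            best_count, best_height = n_big, heights[i]
    return best_height


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float | None = None,
    extend_rel: float = 0.5,
) -> ModuleAssignment:
    """Height-based branch decomposition of the 1 - TOM dendrogram.

    Stage 1 (branch cores): the average-linkage tree is cut at the lowest
    height maximizing the number of branches with at least
    ``min_module_size`` probes (or at ``cut_height`` when given); each such
    branch is a module core, smaller branches are unassigned.  Stage 2
    (extension): each unassigned probe joins the core with the highest mean
    topological overlap, provided that overlap reaches ``extend_rel`` times
    the core's median within-core TOM; otherwise it stays at label 0.
    Labels are ordered by descending module size.  The assignment carries
    the linkage matrix as ``linkage_`` for dendrogram plotting.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    n = len(tom)
    if n < min_module_size:
        raise ValueError("fewer probes than min_module_size")
    Z = _cluster_tree(tom)
    if cut_height is None:
        cut_height = _core_cut_height(Z, min_module_size)
    labels = np.zeros(n, dtype=int)
    if cut_height is not None:
        raw = fcluster(Z, t=float(cut_height), criterion="distance")
        counts = pd.Series(raw).value_counts()
        next_label = 1
        for cl in counts.index:
            if counts[cl] >= min_module_size:
                labels[raw == cl] = next_label
                next_label += 1

    if labels.max() > 0 and (labels == 0).any():
        T = tom.to_numpy(dtype=float)
        cores = [np.flatnonzero(labels == m) for m in range(1, labels.max() + 1)]
        thresholds = []
        for core in cores:
            iu = np.triu_indices(len(core), k=1)
            thresholds.append(extend_rel * float(np.median(T[np.ix_(core, core)][iu])))
        for p in np.flatnonzero(labels == 0):
            overlap = [T[p, core].mean() for core in cores]
            m = int(np.argmax(overlap))
            if overlap[m] >= thresholds[m]:
                labels[p] = m + 1

    assignment = ModuleAssignment(pd.Series(labels, index=tom.index))
    assignment.linkage_ = Z
    assignment.cut_height_ = None if cut_height is None else float(cut_height)
    return assignment
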