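"""Hypergeometric gene-set over-representation for changed modules."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "read_gmt",
    "map_probes_to_genes",
    "hypergeom_enrichment",
    "bh_fdr",
]


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file: one set per line, ``name <tab> description <tab> genes...``."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def map_probes_to_genes(probes, annotation: pd.DataFrame) -> set[str]:
    """Deduplicated gene symbols for a probe list; unannotated probes dropped."""
    ann = annotation.set_index("probe_id")["gene"]
    probes = list(probes)
    mapped = ann.reindex(probes).dropna()
    n_lost = len(probes) - len(mapped)
    if n_lost:
        warnings.warn(f"{n_lost} probes without gene annotation dropped")
    return set(mapped)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def hypergeom_enrichment(
    module_genes: set[str],
    background_genes: set[str],
    sets: dict[str, set[str]],
) -> pd.DataFrame:
    """Over-representation of each gene set among the module's genes.

    With ``N = |background|``, ``K = |set ∩ background|``, ``n = |module|``
    and ``k`` the overlap, reports ``p = P(X >= k)`` for
    ``X ~ Hypergeometric(N, K, n)`` plus BH FDR, sorted by p-value.  Sets
    with no background genes are dropped.
    """
    if not background_genes:
        raise ValueError("background gene set is empty")
    if not module_genes <= background_genes:
        raise ValueError("module genes must be a subset of the background")
    N, n = len(background_genes), len(module_genes)
    rows = []
    for name, genes in sets.items():
        in_bg = genes & background_genes
        K = len(in_bg)
        if K == 0:
            continue
        k = len(in_bg & module_genes)
        p = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        rows.append({"pathway": name, "n_de": k, "set_size": K, "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["pathway", "n_de", "set_size", "p_value"])
    if len(out):
        out["fdr"] = bh_fdr(out["p_value"].to_numpy())
        out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    else:
        out["fdr"] = []
    return out
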