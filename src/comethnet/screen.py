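"""Phenotype-association probe screen and residual-matrix QC filters."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import t as t_dist

from comethnet.residualize import KinshipEigen, build_design, compute_pcs, fit_lmm

__all__ = [
    "tg_association_screen",
    "variance_filter",
    "missingness_filter",
    "detect_outlier_samples",
]


def tg_association_screen(
    betas: pd.DataFrame,
    logtg: pd.Series,
    sample_sheet: pd.DataFrame,
    K: pd.DataFrame,
    alpha_screen: float = 0.05,
    n_pcs: int = 0,
    probe_as_outcome: bool = False,
) -> pd.DataFrame:
    """Nominal phenotype-association screen with a kinship random effect.

    Default direction: the phenotype is the outcome and each probe enters
    the fixed effects next to the covariates (flip with
    ``probe_as_outcome``).  The probe coefficient's Wald p-value uses a t
    reference with ``n - p`` degrees of freedom, so with an identity
    kinship it reduces exactly to the ordinary regression t-test.

    Returns a table (probe_id, coefficient, standard_error, p_value,
    retained) with ``retained = p_value < alpha_screen``; constant probes
    get p 1 and are dropped.
    """
    sheet = sample_sheet.set_index("sample_id") if "sample_id" in sample_sheet else sample_sheet
    samples = [s for s in betas.columns if s in sheet.index and s in K.index]
    logtg = logtg.reindex(samples) if isinstance(logtg, pd.Series) else pd.Series(
        np.asarray(logtg, dtype=float), index=betas.columns
    ).reindex(samples)
    ok = logtg.notna()
    samples = [s for s, keep in zip(samples, ok) if keep]
    if len(samples) < 10:
        raise ValueError("fewer than 10 samples with non-missing phenotype")
    pcs = None
    if n_pcs > 0:
        complete = betas[samples].dropna(axis=0)
        k_eff = min(n_pcs, len(complete), len(samples))
        pcs = compute_pcs(complete.T, k_eff) if k_eff > 0 else None
    Xbase = build_design(sheet.loc[samples].reset_index(), pcs).to_numpy(dtype=float)
    yv = logtg.loc[samples].to_numpy(dtype=float)
    eigen = KinshipEigen(K.loc[samples, samples].to_numpy())

    rows = []
    for probe_id, row in betas[samples].iterrows():
        probe = row.to_numpy(dtype=float)
        if np.nanstd(probe) == 0 or np.isnan(probe).all():
            rows.append((probe_id, np.nan, np.nan, 1.0, False))
            continue
        if probe_as_outcome:
            y, X = probe, np.column_stack([Xbase, yv])
        else:
            y, X = yv.copy(), np.column_stack([Xbase, probe])
        y = y.copy()
        y[np.isnan(X).any(axis=1)] = np.nan  # pairwise-complete on the probe too
        X = np.nan_to_num(X)
        fit = fit_lmm(y, X, eigen)
        mask = fit.mask
        n, p = int(mask.sum()), X.shape[1]
        d, U = eigen.subset(mask)
        lam = fit.h2 * d + (1.0 - fit.h2)
        Xt = U.T @ X[mask]
        XtWX = Xt.T @ (Xt / lam[:, None])
        cov = np.linalg.inv(XtWX) * (fit.sigma_g2 + fit.sigma_e2)
        coef = float(fit.beta_hat[-1])
        se = float(np.sqrt(cov[-1, -1]))
        tval = coef / se if se > 0 else np.inf
        pval = float(2.0 * t_dist.sf(abs(tval), df=n - p))
        rows.append((probe_id, coef, se, pval, pval < alpha_screen))
    return pd.DataFrame(
        rows, columns=["probe_id", "coefficient", "standard_error", "p_value", "retained"]
    )


def variance_filter(residuals: pd.DataFrame, rel_tol: float = 1e-10) -> pd.DataFrame:
    """Drop probes with variance below ``rel_tol * max(abs(residuals))``."""
    if residuals.empty:
        raise ValueError("empty residual matrix")
    threshold = rel_tol * float(np.nanmax(np.abs(residuals.to_numpy(dtype=float))))
    variances = residuals.var(axis=1, ddof=1, skipna=True)
    keep = variances >= threshold
    return residuals.loc[keep]


def missingness_filter(residuals: pd.DataFrame) -> pd.DataFrame:
    """Drop samples with more than half of their residuals missing (strict)."""
    frac = residuals.isna().mean(axis=0)
    return residuals.loc[:, frac <= 0.5]


def detect_outlier_samples(
    residuals: pd.DataFrame, cut_height: float | str = "auto"
) -> list[str]:
    """Samples outside the largest cluster of an average-linkage tree.

    Samples are clustered on Euclidean distance between residual profiles
    (probes with any missing value are ignored) and the tree is cut at
    ``cut_height``; ``"auto"`` uses the 99th percentile of merge heights.
    """
    if residuals.shape[1] < 3:
        raise ValueError("need at least 3 samples for outlier detection")
    complete = residuals.dropna(axis=0)
    if complete.empty:
        raise ValueError("no probes without missing values for outlier distances")
    Z = linkage(pdist(complete.T.to_numpy(dtype=float)), method="average")
    if cut_height == "auto":
        cut_height = float(np.quantile(Z[:, 2], 0.99))
    cut_height = float(cut_height)
    if cut_height <= 0:
        raise ValueError("cut_height must be positive")
    labels = fcluster(Z, t=cut_height, criterion="distance")
    counts = pd.Series(labels).value_counts()
    keep = counts.idxmax()
    return [s for s, lab in zip(residuals.columns, labels) if lab != keep]
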