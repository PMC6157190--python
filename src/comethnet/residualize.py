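"""Kinship-aware linear mixed model residualization of methylation values.

Model per probe: ``y = X b + g + e`` with ``g ~ N(0, sigma_g2 * K)`` and
``e ~ N(0, sigma_e2 * I)``.  REML estimation works in the eigenbasis of the
kinship matrix (one decomposition per cohort), reducing the fit to a 1-D
optimization over the heritability ratio ``h = sigma_g2 / (sigma_g2 +
sigma_e2)``.  Residuals are conditional by default (fixed effects and BLUP
subtracted) so family structure does not inflate network edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LMMFit",
    "KinshipEigen",
    "fit_lmm",
    "lmm_residuals",
    "compute_pcs",
    "residualize_matrix",
    "build_design",
]

_H_EPS = 1e-8


@dataclass
class LMMFit:
    """REML fit of a single-kinship-component linear mixed model."""

    beta_hat: np.ndarray
    sigma_g2: float
    sigma_e2: float
    loglik: float
    blup: np.ndarray  # aligned to the samples passed in; NaN where y missing
    h2: float
    mask: np.ndarray  # samples used in the fit


class KinshipEigen:
    """Cached eigendecomposition of a kinship matrix (and of sample subsets)."""

    def __init__(self, K: np.ndarray):
        K = np.asarray(K, dtype=float)
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kinship matrix is not symmetric")
        self.K = (K + K.T) / 2.0
        self._cache: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}

    def subset(self, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        key = np.packbits(mask).tobytes()
        if key not in self._cache:
            Ksub = self.K[np.ix_(mask, mask)]
            d, U = np.linalg.eigh(Ksub)
            if d.min() < -1e-8:
                raise ValueError(f"kinship matrix not PSD (min eigenvalue {d.min():.3g})")
            self._cache[key] = (np.maximum(d, 0.0), U)
        return self._cache[key]


def _reml_loglik(h: float, yt: np.ndarray, Xt: np.ndarray, d: np.ndarray):
    """Profiled REML log-likelihood at heritability ratio ``h``.

    Returns (loglik, beta_hat, sigma_total2, weights).
    """
    n, p = Xt.shape
    lam = h * d + (1.0 - h)
    w = 1.0 / lam
    Xw = Xt * w[:, None]
    XtWX = Xt.T @ Xw
    XtWy = Xw.T @ yt
    beta = np.linalg.solve(XtWX, XtWy)
    r = yt - Xt @ beta
    rss = float(r @ (w * r))
    sigma2 = max(rss / (n - p), 1e-300)
    sign, logdet_xx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf, beta, sigma2, w
    ll = -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * sigma2) + 1.0)
        + np.log(lam).sum()
        + logdet_xx
    )
    return float(ll), beta, sigma2, w


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray | KinshipEigen,
    n_grid: int = 41,
) -> LMMFit:
    """REML fit of ``y = X b + g + e`` with ``cov(g) = sigma_g2 K``.

    Samples with missing ``y`` are dropped pairwise.  The 1-D REML
    objective over ``h = sigma_g2/(sigma_g2+sigma_e2)`` is maximized by a
    coarse grid followed by bounded Brent refinement, so the optimum is
    never worse than the grid.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) != X.shape[0]:
        raise ValueError("y and X have different numbers of samples")
    eigen = K if isinstance(K, KinshipEigen) else KinshipEigen(np.asarray(K))
    mask = ~np.isnan(y)
    if np.isnan(X[mask]).any():
        raise ValueError("missing values in design matrix for retained samples")
    yo, Xo = y[mask], X[mask]
    n, p = Xo.shape
    if n <= p:
        raise ValueError("not enough non-missing samples to fit the model")
    if np.linalg.matrix_rank(Xo) < p:
        raise ValueError("design matrix is rank deficient")
    d, U = eigen.subset(mask)
    yt = U.T @ yo
    Xt = U.T @ Xo

    grid = np.linspace(0.0, 1.0 - _H_EPS, n_grid)
    lls = np.array([_reml_loglik(h, yt, Xt, d)[0] for h in grid])
    # first grid point within tolerance of the max: when the likelihood is
    # flat in h (e.g. K = I) prefer h = 0 so the model collapses to OLS
    i = int(np.flatnonzero(lls >= lls.max() - 1e-7)[0])
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda h: -_reml_loglik(h, yt, Xt, d)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    h_opt, ll_opt = float(res.x), float(-res.fun)
    if ll_opt <= lls[i] + 1e-9:  # keep the grid point unless Brent truly improved
        h_opt, ll_opt = float(grid[i]), float(lls[i])

    ll, beta, sigma2, w = _reml_loglik(h_opt, yt, Xt, d)
    sigma_g2 = h_opt * sigma2
    sigma_e2 = max((1.0 - h_opt) * sigma2, 1e-300)
    resid_t = yt - Xt @ beta
    blup_o = U @ (h_opt * d * w * resid_t)
    blup = np.full(len(y), np.nan)
    blup[mask] = blup_o
    return LMMFit(
        beta_hat=beta,
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        loglik=ll,
        blup=blup,
        h2=h_opt,
        mask=mask,
    )


def lmm_residuals(
    fit: LMMFit, y: np.ndarray, X: np.ndarray, conditional: bool = True
) -> np.ndarray:
    """Residuals ``y - X b_hat`` minus the BLUP when ``conditional``.

    Missing ``y`` entries give missing residuals.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != len(y) or X.shape[1] != len(fit.beta_hat) or len(y) != len(fit.blup):
        raise ValueError("dimension mismatch between fit and data")
    r = y - X @ fit.beta_hat
    if conditional:
        r = r - fit.blup
    r[~fit.mask] = np.nan
    return r


def compute_pcs(values: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k principal component scores of a sample x feature table.

    Columns are standardized (constant columns dropped); scores come from
    the SVD of the standardized matrix.  Sign is fixed so each component's
    largest-magnitude feature loading is positive.
    """
    M = values.to_numpy(dtype=float)
    sd = M.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all features are constant; PCs undefined")
    Z = (M[:, keep] - M[:, keep].mean(axis=0)) / sd[keep]
    if k > min(Z.shape):
        raise ValueError(f"k={k} exceeds min(n_samples, n_features)={min(Z.shape)}")
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for j in range(k):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            scores[:, j] *= -1.0
    return pd.DataFrame(
        scores, index=values.index, columns=[f"PC{i + 1}" for i in range(k)]
    )


def build_design(
    sample_sheet: pd.DataFrame, pcs: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Fixed-effect design: intercept, age, sex, center dummies, smoking, PCs."""
    sheet = sample_sheet.set_index("sample_id") if "sample_id" in sample_sheet else sample_sheet
    X = pd.DataFrame(index=sheet.index)
    X["intercept"] = 1.0
    X["age"] = sheet["age"].astype(float)
    X["sex"] = sheet["sex"].astype(float)
    center = pd.get_dummies(sheet["center"], prefix="center", drop_first=True)
    for c in center.columns:
        X[c] = center[c].astype(float)
    X["smoking"] = sheet["smoking"].astype(float)
    if pcs is not None:
        for c in pcs.columns:
            X[c] = pcs.loc[X.index, c].astype(float)
    return X


def residualize_matrix(
    betas: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    K: pd.DataFrame,
    n_pcs: int = 10,
    conditional: bool = True,
    pcs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-probe LMM residuals of a probe x sample beta matrix.

    The design is [intercept, age, sex, center dummies, smoking, PC1..PCk]
    with PCs computed from the standardized beta matrix itself unless
    supplied.  Residuals are centered to mean 0 per probe.  Missing beta
    values propagate as missing residuals.
    """
    sheet = sample_sheet.set_index("sample_id") if "sample_id" in sample_sheet else sample_sheet
    samples = [s for s in betas.columns if s in sheet.index and s in K.index]
    if len(samples) < 10:
        raise ValueError("fewer than 10 samples after aligning betas, sheet and kinship")
    betas = betas[samples]
    if n_pcs > 0 and pcs is None and len(betas) > 0:
        complete = betas.dropna(axis=0)
        k_eff = min(n_pcs, len(complete), len(samples))
        pcs = compute_pcs(complete.T, k_eff) if k_eff > 0 else None
    X = build_design(sheet.loc[samples].reset_index(), pcs if n_pcs > 0 else None)
    Xv = X.to_numpy(dtype=float)
    eigen = KinshipEigen(K.loc[samples, samples].to_numpy())

    out = np.full(betas.shape, np.nan)
    for i, (_, row) in enumerate(betas.iterrows()):
        yv = row.to_numpy(dtype=float)
        if np.isnan(yv).all() or np.nanstd(yv) == 0:
            out[i] = np.where(np.isnan(yv), np.nan, 0.0)
            continue
        fit = fit_lmm(yv, Xv, eigen)
        out[i] = lmm_residuals(fit, yv, Xv, conditional=conditional)
    res = pd.DataFrame(out, index=betas.index, columns=samples)
    return res.sub(res.mean(axis=1, skipna=True), axis=0)
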