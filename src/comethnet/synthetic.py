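"""Synthetic family-structured methylation studies with planted modules.

Generates pre- and post-treatment beta matrices from a latent-Gaussian
factor model: probes within a planted module load on a shared latent
factor, a kinship random effect induces family correlation, fixed covariate
effects are added, and latent values are squashed into (0, 1) with the
inverse logit.  Post-treatment data keep the module loadings for preserved
modules and redraw them (as random directions in a high-dimensional factor
space) for rewired modules, so rewired modules keep their marginal variance
but lose any pre/post edge correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from comethnet.network import ModuleAssignment

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "build_kinship",
    "simulate_study",
    "write_study",
    "nuclear_family_pedigree",
]


# ---------------------------------------------------------------------------
# Kinship


def nuclear_family_pedigree(n_families: int, family_size: int) -> pd.DataFrame:
    """Pedigree of ``n_families`` nuclear families.

    Each family has two founders; remaining members are their full-sib
    children.  A ``family_size`` of 1 yields singletons.  Returns a table
    with columns ``id``, ``father``, ``mother`` ("0" marks a founder) and
    ``family``.
    """
    rows = []
    for f in range(n_families):
        fam = f"F{f:03d}"
        ids = [f"{fam}_I{k}" for k in range(family_size)]
        for k, iid in enumerate(ids):
            if family_size >= 3 and k >= 2:
                rows.append((iid, ids[0], ids[1], fam))
            else:
                rows.append((iid, "0", "0", fam))
    return pd.DataFrame(rows, columns=["id", "father", "mother", "family"])


def build_kinship(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Expected-relatedness (2·kinship) matrix from a pedigree.

    Uses the tabular method on a topological ordering of the pedigree:
    ``A[i, i] = 1 + A[father, mother] / 2`` and
    ``A[i, j] = (A[j, father] + A[j, mother]) / 2`` for ``j`` ordered before
    ``i``.  Founders have both parents equal to ``"0"`` (or NaN).  Diagonal
    is 1 for non-inbred individuals.

    Raises
    ------
    ValueError
        If a parent id does not appear in the ``id`` column, or the
        pedigree contains a cycle.
    """
    ped = pedigree.copy()
    ped["father"] = ped["father"].fillna("0").astype(str)
    ped["mother"] = ped["mother"].fillna("0").astype(str)
    ids = ped["id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids in pedigree")
    parents = {r.id: (r.father, r.mother) for r in ped.itertuples(index=False)}
    known = set(ids)
    for iid, (fa, mo) in parents.items():
        for p in (fa, mo):
            if p != "0" and p not in known:
                raise ValueError(f"unknown parent id {p!r} for individual {iid!r}")

    # Kahn-style topological sort; leftovers indicate a cycle.
    order: list[str] = []
    placed: set[str] = set()
    remaining = list(ids)
    while remaining:
        progress = [i for i in remaining if all(p == "0" or p in placed for p in parents[i])]
        if not progress:
            raise ValueError("pedigree contains a cycle")
        order.extend(progress)
        placed.update(progress)
        remaining = [i for i in remaining if i not in placed]

    pos = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, iid in enumerate(order):
        fa, mo = parents[iid]
        fi = pos.get(fa, -1) if fa != "0" else -1
        mi = pos.get(mo, -1) if mo != "0" else -1
        A[i, i] = 1.0 + (0.5 * A[fi, mi] if fi >= 0 and mi >= 0 else 0.0)
        for j in range(i):
            a = 0.0
            if fi >= 0:
                a += 0.5 * A[j, fi]
            if mi >= 0:
                a += 0.5 * A[j, mi]
            A[i, j] = A[j, i] = a
    out = pd.DataFrame(A, index=order, columns=order)
    return out.loc[ids, ids]


# ---------------------------------------------------------------------------
# Simulation


@dataclass
class SimulationConfig:
    """Parameters of a synthetic pre/post methylation study."""

    n_families: int = 50
    family_size: int = 4
    n_probes: int = 400
    module_sizes: tuple[int, ...] = (60, 50, 45, 40, 35, 30)
    module_correlation: float = 0.7
    rewired_modules: frozenset[int] = frozenset()
    heritability: float = 0.3
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.3, "sex": 0.3, "center": 0.2, "smoking": 0.2}
    )
    phenotype_module: int = 1
    phenotype_effect: float = 1.0
    noise_sd: float = 1.0
    dropout_keep: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        self.rewired_modules = frozenset(int(m) for m in self.rewired_modules)
        if sum(self.module_sizes) > self.n_probes:
            raise ValueError("sum(module_sizes) exceeds n_probes")
        n_mod = len(self.module_sizes)
        if not self.rewired_modules <= set(range(1, n_mod + 1)):
            raise ValueError("rewired_modules must be a subset of module indices 1..n_modules")
        if not 0.0 <= self.module_correlation < 1.0:
            raise ValueError("module_correlation must be in [0, 1)")
        if not 0.0 <= self.heritability < 1.0:
            raise ValueError("heritability must be in [0, 1)")
        if n_mod and not 1 <= self.phenotype_module <= n_mod:
            raise ValueError("phenotype_module out of range")


@dataclass
class SimulatedStudy:
    """Outputs of :func:`simulate_study`."""

    pre_betas: pd.DataFrame  # probes x samples
    post_betas: pd.DataFrame
    sample_sheet: pd.DataFrame
    kinship: pd.DataFrame
    probe_annotation: pd.DataFrame
    planted_modules: ModuleAssignment
    rewired_flags: dict[int, bool]
    config: SimulationConfig


def _module_loadings(rng: np.random.Generator, sizes: tuple[int, ...], rho: float):
    """Per-probe loading magnitudes a_j = sqrt(rho) * U(0.5, 1).

    The spread makes within-module correlations heterogeneous, so binarized
    module graphs have hub structure rather than being complete.
    """
    return [np.sqrt(rho) * rng.uniform(0.5, 1.0, s) for s in sizes]


def _structural_component(
    rng: np.random.Generator,
    n_samples: int,
    n_probes: int,
    sizes: tuple[int, ...],
    loadings: list[np.ndarray],
    rewired: frozenset[int],
    noise_sd: float,
) -> np.ndarray:
    """Probe x sample latent matrix with planted module correlation.

    Preserved module m: probe j gets ``a_j * f_m + sqrt(1 - a_j^2) * e``
    with a single factor per module.  Rewired module m: probe j loads on a
    fresh random unit direction in a module-sized factor space, which keeps
    marginal variance but makes pairwise correlations ~0 and unrelated to
    the pre-treatment pattern.
    """
    x = np.empty((n_probes, n_samples))
    start = 0
    for m, (size, a) in enumerate(zip(sizes, loadings), start=1):
        sl = slice(start, start + size)
        if m in rewired:
            q = size
            directions = rng.standard_normal((size, q))
            directions /= np.linalg.norm(directions, axis=1, keepdims=True)
            factors = rng.standard_normal((q, n_samples))
            shared = (a[:, None] * directions) @ factors
        else:
            f = rng.standard_normal(n_samples)
            shared = a[:, None] * f[None, :]
        eps = rng.standard_normal((size, n_samples))
        x[sl] = shared + np.sqrt(1.0 - a**2)[:, None] * noise_sd * eps
        start += size
    x[start:] = noise_sd * rng.standard_normal((n_probes - start, n_samples))
    return x


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a reproducible pre/post methylation study.

    Latent probe values combine the module factor component (weight
    ``sqrt(1 - h2)``), a kinship random effect (weight ``sqrt(h2)`` with
    ``h2 = heritability``) and fixed covariate effects, then pass through
    the inverse logit to give betas in (0, 1).  Post-treatment samples are
    a random subset (fraction ``dropout_keep``) of pre-treatment samples.
    """
    rng = np.random.default_rng(config.seed)
    ped = nuclear_family_pedigree(config.n_families, config.family_size)
    kinship = build_kinship(ped.drop(columns="family"))
    sample_ids = kinship.index.to_numpy()
    n = len(sample_ids)
    K = kinship.to_numpy()
    L = np.linalg.cholesky(K + 1e-10 * np.eye(n))

    probe_ids = np.array([f"cg{j:06d}" for j in range(config.n_probes)])
    sizes = config.module_sizes

    # Covariates
    age = rng.uniform(20.0, 70.0, n)
    sex = rng.integers(0, 2, n)
    center = rng.integers(0, 2, n)
    smoking = (rng.random(n) < 0.25).astype(int)
    age_z = (age - age.mean()) / age.std()
    cov = config.covariate_effects
    covar_shift = (
        cov.get("age", 0.0) * age_z
        + cov.get("sex", 0.0) * (sex - 0.5)
        + cov.get("center", 0.0) * (center - 0.5)
        + cov.get("smoking", 0.0) * (smoking - 0.25)
    )

    h2 = config.heritability
    mu = rng.normal(0.0, 1.0, config.n_probes)
    pre_loadings = _module_loadings(rng, sizes, config.module_correlation)

    pos = {s: i for i, s in enumerate(sample_ids)}

    def latent(rng_t: np.random.Generator, ids: np.ndarray, rewired: frozenset[int]) -> np.ndarray:
        idx = np.array([pos[s] for s in ids])
        struct = _structural_component(
            rng_t, len(ids), config.n_probes, sizes, pre_loadings, rewired, config.noise_sd
        )
        g = (L @ rng_t.standard_normal((n, config.n_probes))).T  # probe x sample, cov K
        x = np.sqrt(1.0 - h2) * struct + np.sqrt(h2) * g[:, idx]
        return mu[:, None] + x + covar_shift[idx][None, :]

    # Pre-treatment: all samples, no rewiring.
    rng_pre = np.random.default_rng(rng.integers(2**63))
    x_pre = latent(rng_pre, sample_ids, frozenset())
    pre_betas = pd.DataFrame(expit(x_pre), index=probe_ids, columns=sample_ids)

    # Phenotype from the pre-treatment latent values of the phenotype module.
    if sizes:
        start = sum(sizes[: config.phenotype_module - 1])
        mod_latent = x_pre[start : start + sizes[config.phenotype_module - 1]].mean(axis=0)
        mod_latent = (mod_latent - mod_latent.mean()) / mod_latent.std()
    else:
        mod_latent = np.zeros(n)
    tg_noise = np.sqrt(1 - h2) * rng.standard_normal(n) + np.sqrt(h2) * (L @ rng.standard_normal(n))
    logtg = (
        config.phenotype_effect * mod_latent
        + 0.3 * covar_shift
        + tg_noise
    )

    # Post-treatment: dropout, redraw stochastic components, rewire chosen modules.
    n_post = max(3, int(round(config.dropout_keep * n)))
    post_ids = np.sort(rng.choice(sample_ids, size=n_post, replace=False))
    rng_post = np.random.default_rng(rng.integers(2**63))
    x_post = latent(rng_post, post_ids, config.rewired_modules)
    post_betas = pd.DataFrame(expit(x_post), index=probe_ids, columns=post_ids)

    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "family_id": ped["family"].to_numpy(),
            "age": age,
            "sex": sex,
            "center": center,
            "smoking": smoking,
            "logTG": logtg,
        }
    )

    labels = np.zeros(config.n_probes, dtype=int)
    start = 0
    for m, size in enumerate(sizes, start=1):
        labels[start : start + size] = m
        start += size
    planted = ModuleAssignment(pd.Series(labels, index=probe_ids, name="module"))

    genes = np.array([f"GENE{j // 2:05d}" for j in range(config.n_probes)])
    annotation = pd.DataFrame({"probe_id": probe_ids, "gene": genes})

    rewired_flags = {m: (m in config.rewired_modules) for m in range(1, len(sizes) + 1)}
    return SimulatedStudy(
        pre_betas=pre_betas,
        post_betas=post_betas,
        sample_sheet=sheet,
        kinship=kinship,
        probe_annotation=annotation,
        planted_modules=planted,
        rewired_flags=rewired_flags,
        config=config,
    )


def write_study(study: SimulatedStudy, out_dir: str | Path) -> None:
    """Write all study tables as TSV under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.pre_betas.to_csv(out / "pre_betas.tsv", sep="\t", index_label="probe_id")
    study.post_betas.to_csv(out / "post_betas.tsv", sep="\t", index_label="probe_id")
    study.sample_sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    study.kinship.to_csv(out / "kinship.tsv", sep="\t", index_label="sample_id")
    study.probe_annotation.to_csv(out / "probe_annotation.tsv", sep="\t", index=False)
    truth = study.planted_modules.to_frame()
    truth["rewired"] = [
        study.rewired_flags.get(m, False) for m in truth["module"]
    ]
    truth.to_csv(out / "planted_modules.tsv", sep="\t", index=False)
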