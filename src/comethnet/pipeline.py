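"""End-to-end orchestration: residualize -> screen/QC -> pre-treatment
network modules -> preservation + GHD verdicts -> enrichment of changed
modules, with per-stage TSV outputs, figures, a run log and a summary."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from comethnet import __version__, io
from comethnet.enrichment import hypergeom_enrichment, map_probes_to_genes, read_gmt
from comethnet.ghd import ghd_test
from comethnet.network import (
    ModuleAssignment,
    adjacency_from_correlation,
    detect_modules,
    pairwise_correlation,
    pick_soft_power,
    topological_overlap,
)
from comethnet.plots import plot_dendrogram, plot_module_network
from comethnet.preservation import module_preservation
from comethnet.residualize import residualize_matrix
from comethnet.screen import (
    detect_outlier_samples,
    missingness_filter,
    tg_association_screen,
    variance_filter,
)

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]

log = logging.getLogger("comethnet")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and stage parameters of a full run; round-trips through YAML."""

    pre_betas: str = ""
    post_betas: str = ""
    sample_sheet: str = ""
    kinship: str = ""
    annotation: str = ""
    gmt: str = ""
    out_dir: str = "run"
    alpha_screen: float = 0.05
    screen_n_pcs: int = 10
    n_pcs: int = 10
    cut_height: str | float = "auto"
    min_module_size: int = 30
    power: str | int = "auto"
    powers: list[int] = field(default_factory=lambda: list(range(1, 21)))
    r2_threshold: float = 0.9
    tau: float = 0.2
    alpha: float = 0.05
    n_perm_preservation: int = 200
    n_perm_ghd: int = 1000
    seed: int = 1
    make_plots: bool = True

    def validate(self) -> None:
        if not 0 < self.alpha_screen < 1 or not 0 < self.alpha < 1:
            raise ValueError("alpha values must be in (0, 1)")
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.n_pcs < 0 or self.screen_n_pcs < 0:
            raise ValueError("PC counts must be non-negative")
        if self.n_perm_preservation < 50 or self.n_perm_ghd < 100:
            raise ValueError("permutation counts too small")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _stage_seeds(seed: int) -> dict[str, int]:
    """One global seed deterministically spawns per-stage seeds."""
    ss = np.random.SeedSequence(seed)
    names = ["preservation", "ghd"]
    return {n: int(s.generate_state(1)[0]) for n, s in zip(names, ss.spawn(len(names)))}


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the output directory.

    Writes per-stage TSVs, optional figures, ``run_log.txt`` and
    ``summary.json`` (module sizes, both methods' verdicts, concordance).
    Any stage failure raises :class:`StageError`; outputs of completed
    stages are kept.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run_log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    seeds = _stage_seeds(config.seed)
    log.info("comethnet %s", __version__)
    log.info("parameters: %s", json.dumps(asdict(config)))
    log.info("stage seeds: %s", seeds)
    config.to_file(out / "config.yaml")

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                log.info("stage %s: start", name)
                result = fn(*args, **kwargs)
                log.info("stage %s: done", name)
                return result
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                log.error("stage %s: FAILED (%s)", name, exc)
                raise StageError(name, exc) from exc

        return wrap

    try:
        pre_betas = io.read_matrix(config.pre_betas)
        post_betas = io.read_matrix(config.post_betas)
        sheet = io.read_sample_sheet(config.sample_sheet)
        kinship = io.read_kinship(config.kinship)

        # --- screen on pre-treatment betas against the phenotype
        logtg = sheet.set_index("sample_id")["logTG"]
        screen = stage("screen")(
            tg_association_screen,
            pre_betas, logtg, sheet, kinship,
            alpha_screen=config.alpha_screen, n_pcs=config.screen_n_pcs,
        )
        screen.to_csv(out / "screen.tsv", sep="\t", index=False)
        retained = screen.loc[screen["retained"], "probe_id"]
        log.info("screen: retained %d of %d probes", len(retained), len(screen))
        pre_betas = pre_betas.loc[retained]
        post_betas = post_betas.loc[[p for p in retained if p in post_betas.index]]

        # --- residualize both cohorts
        pre_res = stage("residualize_pre")(
            residualize_matrix, pre_betas, sheet, kinship, n_pcs=config.n_pcs
        )
        post_res = stage("residualize_post")(
            residualize_matrix, post_betas, sheet, kinship, n_pcs=config.n_pcs
        )

        # --- QC filters, harmonized across cohorts
        def qc(res):
            res = variance_filter(missingness_filter(res))
            outliers = detect_outlier_samples(res, config.cut_height)
            return res.drop(columns=outliers), outliers

        (pre_res, out_pre), (post_res, out_post) = stage("qc")(
            lambda: (qc(pre_res), qc(post_res))
        )
        common = pre_res.index.intersection(post_res.index)
        pre_res, post_res = pre_res.loc[common], post_res.loc[common]
        log.info(
            "qc: %d common probes; outliers pre=%s post=%s", len(common), out_pre, out_post
        )
        io.write_matrix(pre_res, out / "pre_residuals.tsv", "probe_id")
        io.write_matrix(post_res, out / "post_residuals.tsv", "probe_id")

        # --- pre-treatment network and modules
        def build_network():
            pre_cor = pairwise_correlation(pre_res)
            if config.power == "auto":
                choice = pick_soft_power(
                    pre_cor, powers=config.powers, r2_threshold=config.r2_threshold
                )
                choice.scan.to_csv(out / "soft_threshold_scan.tsv", sep="\t", index=False)
                power = choice.power
            else:
                power = int(config.power)
            pre_adj = adjacency_from_correlation(pre_cor, power)
            tom = topological_overlap(pre_adj)
            modules = detect_modules(tom, min_module_size=config.min_module_size)
            return pre_cor, pre_adj, power, modules

        pre_cor, pre_adj, power, modules = stage("network")(build_network)
        modules.to_frame().to_csv(out / "modules.tsv", sep="\t", index=False)
        log.info("network: power=%d modules=%s", power, dict(modules.sizes()))

        post_cor = pairwise_correlation(post_res)
        post_adj = adjacency_from_correlation(post_cor, power)

        # --- preservation and GHD
        preservation = stage("preservation")(
            module_preservation,
            pre_cor, pre_adj, post_cor, post_adj, modules,
            n_perm=config.n_perm_preservation, seed=seeds["preservation"],
        )
        preservation.to_csv(out / "preservation.tsv", sep="\t")
        ghd = stage("ghd")(
            ghd_test,
            pre_cor, post_cor, modules,
            tau=config.tau, alpha=config.alpha,
            n_perm=config.n_perm_ghd, seed=seeds["ghd"],
        )
        ghd.to_csv(out / "ghd.tsv", sep="\t")

        # --- verdicts: a module is "changed" when GHD fails to reject
        verdicts = pd.DataFrame(
            {
                "size": modules.sizes(),
                "color": [modules.color(m) for m in modules.sizes().index],
                "Z_summary": preservation["Z_summary"],
                "median_rank": preservation["median_rank"],
                "preservation_preserved": preservation["Z_summary"] >= 2,
                "ghd_p": ghd["p_value"],
                "ghd_preserved": ghd["preserved"],
            }
        )
        verdicts["changed"] = ~verdicts["ghd_preserved"]
        verdicts.to_csv(out / "verdicts.tsv", sep="\t")
        concordant = (verdicts["preservation_preserved"] == verdicts["ghd_preserved"]).sum()

        # --- enrichment of changed modules
        enrichment_results = {}
        if config.annotation and config.gmt:
            annotation = io.read_annotation(config.annotation)
            gene_sets = read_gmt(config.gmt)
            background = map_probes_to_genes(screen.loc[screen["retained"], "probe_id"], annotation)
            for m in verdicts.index[verdicts["changed"]]:
                genes = map_probes_to_genes(modules.module_probes(m), annotation) & background
                table = stage(f"enrichment_m{m}")(
                    hypergeom_enrichment, genes, background, gene_sets
                )
                table.to_csv(out / f"enrichment_module{m}.tsv", sep="\t", index=False)
                enrichment_results[int(m)] = str(out / f"enrichment_module{m}.tsv")

        # --- figures
        if config.make_plots:
            def figures():
                post_tom = topological_overlap(post_adj)
                post_modules = detect_modules(
                    post_tom, min_module_size=config.min_module_size
                )
                plot_dendrogram(
                    modules.linkage_,
                    {"pre": modules.colors(), "post": post_modules.colors()},
                    out / "dendrogram.png",
                )
                for m in verdicts.index:
                    plot_module_network(
                        pre_cor, post_cor, modules, m, tau=config.tau,
                        out_path=out / f"network_module{m}.png",
                    )

            stage("figures")(figures)

        summary = {
            "version": __version__,
            "seed": config.seed,
            "stage_seeds": seeds,
            "power": int(power),
            "n_probes_screened": int(len(retained)),
            "n_probes_network": int(len(common)),
            "module_sizes": {int(m): int(s) for m, s in modules.sizes().items()},
            "verdicts": json.loads(verdicts.to_json(orient="index")),
            "concordance": {"agree": int(concordant), "total": int(len(verdicts))},
            "enrichment_outputs": enrichment_results,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        log.info("pipeline complete: %s", out)
        return out
    finally:
        log.removeHandler(handler)
        handler.close()
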