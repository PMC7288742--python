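"""End-to-end orchestration: validate → metrics → null models → GLM report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, community, io as gio, models, phylo
from .datasets import GypsumDataset, NullModelConfig, validate_dataset
from .simulate import ScenarioConfig, generate_dataset

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "S", "invSimpson", "GR", "CMG", "GD",
    "SES_GR", "SES_GD", "PSV", "PSR", "MPD", "NRI",
]


@dataclass
class RunConfig:
    """Inputs, replication and model options for one full analysis run.

    Exactly one of (the four input paths) or ``scenario`` must be given.
    """

    community: str | Path | None = None
    traits: str | Path | None = None
    tree: str | Path | None = None
    environment: str | Path | None = None
    scenario: ScenarioConfig | None = None
    null_config: NullModelConfig = field(default_factory=NullModelConfig)
    center_predictors: bool = False
    cover_units: str = "percent"  # or "fraction"
    outdir: str | Path = "."

    def __post_init__(self) -> None:
        paths = [self.community, self.traits, self.tree, self.environment]
        have_paths = all(p is not None for p in paths)
        if have_paths == (self.scenario is not None):
            raise ValueError(
                "provide either all four input paths or a scenario, not both"
            )


def load_dataset(cfg: RunConfig) -> GypsumDataset:
    if cfg.scenario is not None:
        dataset, _ = generate_dataset(cfg.scenario)
        return dataset
    cm = gio.read_community_matrix(cfg.community)
    tt = gio.read_trait_table(cfg.traits)
    ph = gio.read_newick(cfg.tree)
    env = gio.read_environment_table(cfg.environment)
    if cfg.cover_units == "fraction":
        env.table["cover"] = env.table["cover"] * 100.0
    return validate_dataset(cm, tt, ph, env)


def compute_plot_metrics(
    dataset: GypsumDataset, null_cfg: NullModelConfig
) -> pd.DataFrame:
    """Per-plot metrics table: S, invSimpson, GR, CMG, GD, SES_GR, SES_GD,
    PSV, PSR, MPD, NRI (one row per plot, fixed column order)."""
    seeds = np.random.SeedSequence(null_cfg.seed).spawn(3)
    trait_metrics = community.plot_trait_metrics(dataset.community, dataset.traits)
    ses_gr = community.ses_metric(
        dataset.community, dataset.traits, "GR", null_cfg,
        rng=np.random.default_rng(seeds[0]),
    )
    ses_gd = community.ses_metric(
        dataset.community, dataset.traits, "GD", null_cfg,
        rng=np.random.default_rng(seeds[1]),
    )
    phylo_metrics = phylo.plot_phylo_metrics(dataset.community, dataset.phylogeny)
    nri_result = phylo.nri(
        dataset.community, dataset.phylogeny, null_cfg,
        rng=np.random.default_rng(seeds[2]),
    )
    out = trait_metrics.copy()
    out["SES_GR"] = ses_gr["ses"]
    out["SES_GD"] = ses_gd["ses"]
    out = out.join(phylo_metrics)
    out["NRI"] = nri_result["nri"]
    return out[METRIC_COLUMNS]


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run the whole pipeline and write metrics, model report and audit log.

    Returns a dict with the metrics frame, model report frame, collinearity
    check and output paths. Outputs are written atomically (temp file then
    rename) so a failed run leaves no partial files.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "validate"
    try:
        dataset = load_dataset(cfg)
        logger.info("dataset: %s", dataset.coverage)

        stage = "metrics"
        metrics = compute_plot_metrics(dataset, cfg.null_config)

        stage = "models"
        collinearity = models.collinearity_check(dataset.environment)
        report = models.model_report(
            metrics, dataset.environment, center=cfg.center_predictors
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    metrics_path = outdir / "metrics.csv"
    report_path = outdir / "model_report.csv"
    audit_path = outdir / "audit.yaml"
    gio.atomic_write(lambda p: gio.write_metrics(metrics, p), metrics_path)
    gio.atomic_write(lambda p: gio.write_model_report(report, p), report_path)

    na_counts = {c: int(metrics[c].isna().sum()) for c in METRIC_COLUMNS}
    audit = {
        "gypsodiv_version": __version__,
        "coverage": dataset.coverage,
        "seed": cfg.null_config.seed,
        "n_rand_trait": cfg.null_config.n_rand_trait,
        "n_rand_phylo": cfg.null_config.n_rand_phylo,
        "swap_iterations": cfg.null_config.swap_iterations,
        "center_predictors": cfg.center_predictors,
        "na_counts": na_counts,
        "collinearity": {k: (None if isinstance(v, float) and np.isnan(v) else v)
                         for k, v in collinearity.items()},
    }
    gio.atomic_write(lambda p: gio.write_config(audit, p), audit_path)

    return {
        "metrics": metrics,
        "report": report,
        "collinearity": collinearity,
        "paths": {"metrics": metrics_path, "report": report_path,
                  "audit": audit_path},
    }
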