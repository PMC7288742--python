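"""Synthetic gypsum-community datasets with known, recorded ground truth.

The generator emulates the structure of a gypsum-outcrop vegetation survey:
a regional pool of perennial species scored on the gypsophily index
(GI 2–5, with a fixed number of strict gypsophytes at GI 5), an ultrametric
pool phylogeny on which GI may carry phylogenetic signal, an aridity
gradient of plots (Tmax, MAP, total cover drawn over the survey's observed
ranges) and plot communities assembled by environmental filtering:

* occurrence weights are logistic in GI with an intensity that grows from
  zero at the coolest plots to ``beta_cmg_T`` at the hottest, so gypsum
  specialists come to dominate hot plots (CMG rises with T) while cool
  plots admit the full GI range (GR falls with T);
* a per-plot richness budget declines log-linearly in standardized T and P
  (``beta_div_T``, ``beta_div_P``), so taxonomic diversity falls toward
  both hot and wet ends;
* abundances of occurring species are log-normal and renormalised so each
  plot's total equals its total cover.

All seeded effects are recorded in :class:`GroundTruth` so pipeline
recovery tests can compare fitted signs against what was generated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import io as gio
from .datasets import (
    CommunityMatrix,
    EnvironmentTable,
    GypsumDataset,
    Phylogeny,
    TraitTable,
    ValidationError,
    validate_dataset,
)


@dataclass
class ScenarioConfig:
    """Study-scale defaults: 89 plots, 111-species pool, 16 gypsophytes,
    Tmax 30.8–34.5 °C, MAP 195–565 mm, cover 11–52.2 %."""

    n_plots: int = 89
    n_species_pool: int = 111
    n_gypsophytes: int = 16
    t_range: tuple[float, float] = (30.8, 34.5)
    p_range: tuple[float, float] = (195.0, 565.0)
    cover_range: tuple[float, float] = (11.0, 52.2)
    beta_cmg_T: float = 4.0
    beta_div_T: float = 0.4
    beta_div_P: float = 0.4
    phylo_signal: float = 1.0
    baseline_richness: float = 20.0
    abundance_sigma: float = 0.8
    env_correlation: float = 0.0
    include_gi1: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gypsophytes > self.n_species_pool:
            raise ValidationError("n_gypsophytes cannot exceed the pool size")
        for lo, hi in (self.t_range, self.p_range, self.cover_range):
            if not lo <= hi:
                raise ValidationError("ranges must be ordered (low, high)")
        if min(self.n_plots, self.n_species_pool) < 1:
            raise ValidationError("counts must be positive")
        if self.phylo_signal < 0:
            raise ValidationError("phylo_signal must be >= 0")


@dataclass
class GroundTruth:
    """Seeded effects behind one synthetic dataset."""

    betas: dict
    expected_signs: dict
    filter_intensity: list = field(default_factory=list)
    n_resampled_plots: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "betas": self.betas,
                    "expected_signs": self.expected_signs,
                    "filter_intensity": self.filter_intensity,
                    "n_resampled_plots": self.n_resampled_plots,
                },
                fh,
                indent=2,
            )


def _species_labels(n: int) -> list[str]:
    return [f"sp{i + 1:03d}" for i in range(n)]


def _plot_labels(n: int) -> list[str]:
    return [f"plot{i + 1:03d}" for i in range(n)]


def generate_pool(cfg: ScenarioConfig, rng: np.random.Generator | None = None) -> TraitTable:
    """Species pool with integer GI: ``n_gypsophytes`` at GI 5, the rest
    spread evenly over the gypsovag classes (2–4, or 1–4 with
    ``include_gi1``)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    labels = _species_labels(cfg.n_species_pool)
    classes = [1.0, 2.0, 3.0, 4.0] if cfg.include_gi1 else [2.0, 3.0, 4.0]
    n_rest = cfg.n_species_pool - cfg.n_gypsophytes
    gi = np.full(cfg.n_species_pool, 5.0)
    rest = np.array(classes * (n_rest // len(classes) + 1))[:n_rest]
    gi[cfg.n_gypsophytes:] = np.sort(rest)
    rng.shuffle(gi)
    return TraitTable(pd.Series(gi, index=labels))


class _Node:
    __slots__ = ("children", "edge_length", "label", "value")

    def __init__(self, label=None):
        self.children = []
        self.edge_length = 0.0
        self.label = label
        self.value = 0.0


def _random_coalescent(labels: list[str], rng: np.random.Generator) -> _Node:
    """Ultrametric random tree: merge random pairs at exponential waiting
    times (rate = number of open lineages), then rescale depth to 100."""
    lineages = [( _Node(lab), 0.0) for lab in labels]
    height = 0.0
    while len(lineages) > 1:
        height += rng.exponential(1.0 / len(lineages))
        i, j = rng.choice(len(lineages), size=2, replace=False)
        (a, ha), (b, hb) = lineages[i], lineages[j]
        a.edge_length = height - ha
        b.edge_length = height - hb
        parent = _Node()
        parent.children = [a, b]
        lineages = [lineages[k] for k in range(len(lineages)) if k not in (i, j)]
        lineages.append((parent, height))
    root, root_height = lineages[0]
    scale = 100.0 / root_height
    _scale_edges(root, scale)
    return root


def _scale_edges(node: _Node, scale: float) -> None:
    for child in node.children:
        child.edge_length *= scale
        _scale_edges(child, scale)


def _newick(node: _Node) -> str:
    if not node.children:
        return f"{node.label}:{node.edge_length:.17g}"
    inner = ",".join(_newick(c) for c in node.children)
    if node.edge_length > 0:
        return f"({inner}):{node.edge_length:.17g}"
    return f"({inner})"


def _brownian_tips(root: _Node, rng: np.random.Generator) -> dict[str, float]:
    """Brownian-motion tip values (unit rate per branch-length unit)."""
    values = {}
    stack = [(root, 0.0)]
    while stack:
        node, value = stack.pop()
        if not node.children:
            values[node.label] = value
            continue
        for child in node.children:
            step = rng.normal(0.0, np.sqrt(max(child.edge_length, 0.0)))
            stack.append((child, value + step))
    return values


def generate_tree(
    pool: TraitTable, cfg: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[Phylogeny, TraitTable]:
    """Random ultrametric pool phylogeny; with ``phylo_signal > 0`` the GI
    values are re-assigned along a Brownian latent trait so that related
    species share GI classes (keeping the class counts fixed).

    Returns the tree and the (possibly re-assigned) trait table.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    labels = list(pool.species_ids)
    root = _random_coalescent(labels, rng)
    newick = "(" + ",".join(_newick(c) for c in root.children) + ");"
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
    phylogeny = Phylogeny(tree)

    traits = pool
    if cfg.phylo_signal > 0:
        bm = _brownian_tips(root, rng)
        bm_values = np.array([bm[lab] for lab in labels])
        sd = bm_values.std()
        bm_z = (bm_values - bm_values.mean()) / (sd if sd > 0 else 1.0)
        latent = cfg.phylo_signal * bm_z + rng.normal(size=len(labels))
        # keep the exact GI class counts: assign sorted GI to latent ranks
        order = np.argsort(latent)
        sorted_gi = np.sort(pool.gi.to_numpy())
        gi_new = np.empty(len(labels))
        gi_new[order] = sorted_gi
        traits = TraitTable(pd.Series(gi_new, index=labels))
    return phylogeny, traits


def generate_environment(
    cfg: ScenarioConfig, rng: np.random.Generator | None = None
) -> EnvironmentTable:
    """Uniform Tmax, MAP and cover over the configured ranges; an optional
    Gaussian copula induces a mild T–P correlation (``env_correlation``)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_plots
    if cfg.env_correlation != 0.0:
        rho = float(np.clip(cfg.env_correlation, -0.99, 0.99))
        cov = np.array([[1.0, rho], [rho, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        from scipy.stats import norm

        u_t, u_p = norm.cdf(z[:, 0]), norm.cdf(z[:, 1])
    else:
        u_t, u_p = rng.uniform(size=n), rng.uniform(size=n)
    t = cfg.t_range[0] + u_t * (cfg.t_range[1] - cfg.t_range[0])
    p = cfg.p_range[0] + u_p * (cfg.p_range[1] - cfg.p_range[0])
    cover = rng.uniform(cfg.cover_range[0], cfg.cover_range[1], size=n)
    table = pd.DataFrame(
        {"Tmax": t, "MAP": p, "cover": cover}, index=_plot_labels(n)
    )
    return EnvironmentTable(table)


def _unit_scale(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def generate_communities(
    pool: TraitTable,
    tree: Phylogeny,
    env: EnvironmentTable,
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CommunityMatrix, GroundTruth]:
    """Assemble plot communities by GI-based environmental filtering.

    Occurrence weight of species s in plot k: logistic in
    ``beta_cmg_T × x_T(k) × (GI_s − 3.5)`` where x_T is Tmax min–max scaled
    to [0, 1] — no filtering at the coolest plots, full-strength specialist
    filtering at the hottest. Plot richness: round of
    ``baseline_richness × exp(−beta_div_T z_T − beta_div_P z_P)`` with z the
    midpoint-scaled gradient position in [−1, 1], clipped to [3, pool size].
    Abundances are log-normal and renormalised so each plot sums to its
    total cover.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    labels = list(pool.species_ids)
    gi = pool.gi.to_numpy()
    n_plots = len(env.plot_ids)

    t = env.table["Tmax"].to_numpy()
    p = env.table["MAP"].to_numpy()
    x_t = _unit_scale(t, *cfg.t_range)
    z_t = 2.0 * x_t - 1.0
    z_p = 2.0 * _unit_scale(p, *cfg.p_range) - 1.0

    budget = cfg.baseline_richness * np.exp(
        -cfg.beta_div_T * z_t - cfg.beta_div_P * z_p
    )
    richness = np.clip(np.round(budget), 3, len(labels)).astype(int)

    abundance = np.zeros((n_plots, len(labels)))
    intensity = cfg.beta_cmg_T * x_t
    n_resampled = 0
    for k in range(n_plots):
        logit = intensity[k] * (gi - 3.5)
        w = 1.0 / (1.0 + np.exp(-logit))
        w = w / w.sum()
        chosen = rng.choice(len(labels), size=richness[k], replace=False, p=w)
        raw = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=richness[k])
        while raw.sum() <= 0:  # cannot occur with lognormal draws; guard only
            n_resampled += 1
            raw = rng.lognormal(0.0, cfg.abundance_sigma, size=richness[k])
        cover_k = env.table["cover"].iloc[k]
        abundance[k, chosen] = raw / raw.sum() * cover_k

    cm = CommunityMatrix(
        pd.DataFrame(abundance, index=env.plot_ids, columns=labels)
    )
    truth = GroundTruth(
        betas={
            "beta_cmg_T": cfg.beta_cmg_T,
            "beta_div_T": cfg.beta_div_T,
            "beta_div_P": cfg.beta_div_P,
            "phylo_signal": cfg.phylo_signal,
        },
        expected_signs={
            "CMG~T": "+",
            "GR~T": "-",
            "diversity~T": "-",
            "diversity~P": "-",
            "richness~T": "-",
            "richness~P": "-",
        },
        filter_intensity=intensity.tolist(),
        n_resampled_plots=n_resampled,
    )
    return cm, truth


def generate_dataset(cfg: ScenarioConfig) -> tuple[GypsumDataset, GroundTruth]:
    """Full scenario: pool → tree (with trait signal) → environment →
    communities, all streams seeded from ``cfg.seed``."""
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    pool = generate_pool(cfg, np.random.default_rng(seeds[0]))
    tree, traits = generate_tree(pool, cfg, np.random.default_rng(seeds[1]))
    env = generate_environment(cfg, np.random.default_rng(seeds[2]))
    cm, truth = generate_communities(
        traits, tree, env, cfg, np.random.default_rng(seeds[3])
    )
    dataset = validate_dataset(cm, traits, tree, env)
    return dataset, truth


def write_scenario(cfg: ScenarioConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the four input files plus a ground-truth sidecar to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset, truth = generate_dataset(cfg)
    paths = {
        "community": outdir / "community.csv",
        "traits": outdir / "traits.csv",
        "tree": outdir / "tree.nwk",
        "environment": outdir / "environment.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    gio.write_community_matrix(dataset.community, paths["community"])
    gio.write_trait_table(dataset.traits, paths["traits"])
    gio.write_newick(dataset.phylogeny, paths["tree"])
    gio.write_environment_table(dataset.environment, paths["environment"])
    truth.to_json(paths["ground_truth"])
    return paths
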