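"""Per-plot taxonomic and soil-affinity (gypsophily) metrics.

Given relative abundances p_i and gypsophily indices GI_i of the species
present in a plot, the module computes:

* richness S and the inverse Simpson index 1 / Σ p_i²,
* GR = max(GI) − min(GI), the gypsophily analogue of functional richness,
* CMG = Σ GI_i p_i, the community-weighted mean gypsophily,
* GD = Σ_{i,j} (GI_i − GI_j)² p_i p_j, Rao quadratic entropy on the GI axis,

and standardized effect sizes of GR and GD against a null model that
permutes the species→GI assignment across the full regional pool while
holding the community matrix fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import CommunityMatrix, NullModelConfig, TraitTable, ValidationError

_NORM_TOL = 1e-12


@dataclass
class AbundanceVector:
    """Species present in one plot with relative abundances and GI values."""

    species: list[str]
    p: np.ndarray
    gi: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.gi = np.asarray(self.gi, dtype=float)
        if self.p.size == 0:
            raise ValidationError("empty abundance vector")
        if (self.p <= 0).any():
            raise ValidationError("abundance vector retains non-positive p_i")
        total = self.p.sum()
        if abs(total - 1.0) > 1e-9:
            self.p = self.p / total
        if abs(self.p.sum() - 1.0) > _NORM_TOL:
            raise ValidationError("relative abundances do not sum to 1")

    @classmethod
    def from_plot(
        cls, cm: CommunityMatrix, tt: TraitTable, plot_id: str
    ) -> "AbundanceVector":
        """Extract one plot, dropping zero-abundance species before anything else."""
        row = cm.abundance.loc[plot_id]
        present = row[row > 0]
        species = list(present.index)
        return cls(species, present.to_numpy(), tt.gi.loc[species].to_numpy())


def richness(v: AbundanceVector) -> int:
    """Number of species with positive abundance."""
    return int(v.p.size)


def inverse_simpson(v: AbundanceVector) -> float:
    """Effective species number 1 / Σ p_i²; equals S under perfect evenness."""
    return float(1.0 / np.sum(v.p**2))


def gypsophily_range(v: AbundanceVector) -> float:
    """GR = max(GI) − min(GI) over species present; abundance-independent."""
    return float(v.gi.max() - v.gi.min())


def community_mean_gypsophily(v: AbundanceVector) -> float:
    """CMG = Σ GI_i p_i, the abundance-weighted mean gypsophily."""
    return float(np.dot(v.gi, v.p))


def gypsophily_diversity(v: AbundanceVector) -> float:
    """Rao quadratic entropy GD = Σ_{i,j} (GI_i − GI_j)² p_i p_j.

    The double sum runs over all ordered pairs (the diagonal contributes
    zero); it collapses to 2 × the abundance-weighted variance of GI, which
    is the form computed here.
    """
    cmg = np.dot(v.gi, v.p)
    return float(2.0 * np.dot(v.p, (v.gi - cmg) ** 2))


def _null_gr_gd(
    presence: np.ndarray,
    weights: np.ndarray,
    gi_draws: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """GR and GD for every plot under every GI assignment, vectorised.

    presence: (plots, species) bool; weights: (plots, species) row-normalised
    relative abundances (zeros where absent); gi_draws: (draws, species).
    Returns (gr, gd), each (plots, draws).
    """
    masked = np.where(presence[:, None, :], gi_draws[None, :, :], np.nan)
    gr = np.nanmax(masked, axis=2) - np.nanmin(masked, axis=2)
    cmg = weights @ gi_draws.T
    second = weights @ (gi_draws**2).T
    gd = 2.0 * (second - cmg**2)
    # round-off can push tiny variances negative
    np.clip(gd, 0.0, None, out=gd)
    return gr, gd


def ses_metric(
    cm: CommunityMatrix,
    tt: TraitTable,
    metric: str,
    cfg: NullModelConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Standardized effect size of GR or GD per plot under trait shuffling.

    Each of ``cfg.n_rand_trait`` randomizations permutes the species→GI
    assignment across the full regional pool and recomputes the metric for
    every plot. SES = (observed − null mean) / null sd; plots where the null
    has zero spread get NA.

    Returns a DataFrame indexed by plot with columns observed, null_mean,
    null_sd, ses, n_rand.
    """
    if metric not in {"GR", "GD"}:
        raise ValueError(f"metric must be 'GR' or 'GD', got {metric!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    gi = tt.gi.loc[cm.species_ids].to_numpy()
    abundance = cm.abundance.to_numpy()
    presence = abundance > 0
    weights = abundance / abundance.sum(axis=1, keepdims=True)

    obs_gr, obs_gd = _null_gr_gd(presence, weights, gi[None, :])
    observed = (obs_gr if metric == "GR" else obs_gd)[:, 0]

    n_plots = presence.shape[0]
    sums = np.zeros(n_plots)
    sq_sums = np.zeros(n_plots)
    batch = 200
    done = 0
    while done < cfg.n_rand_trait:
        k = min(batch, cfg.n_rand_trait - done)
        draws = rng.permuted(np.tile(gi, (k, 1)), axis=1)
        gr, gd = _null_gr_gd(presence, weights, draws)
        values = gr if metric == "GR" else gd
        sums += values.sum(axis=1)
        sq_sums += (values**2).sum(axis=1)
        done += k

    n = float(cfg.n_rand_trait)
    null_mean = sums / n
    var = sq_sums / n - null_mean**2
    null_sd = np.sqrt(np.clip(var, 0.0, None) * (n / max(n - 1, 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        ses = np.where(null_sd > 0, (observed - null_mean) / null_sd, np.nan)

    return pd.DataFrame(
        {
            "observed": observed,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "ses": ses,
            "n_rand": int(n),
        },
        index=pd.Index(cm.plot_ids, name="plot_id"),
    )


def plot_trait_metrics(cm: CommunityMatrix, tt: TraitTable) -> pd.DataFrame:
    """S, invSimpson, GR, CMG and GD for every plot."""
    records = {}
    for plot_id in cm.plot_ids:
        v = AbundanceVector.from_plot(cm, tt, plot_id)
        records[plot_id] = {
            "S": richness(v),
            "invSimpson": inverse_simpson(v),
            "GR": gypsophily_range(v),
            "CMG": community_mean_gypsophily(v),
            "GD": gypsophily_diversity(v),
        }
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "plot_id"
    return df
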