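"""Phylogenetic structure of plot assemblages: PSV, PSR, MPD and NRI.

PSV (phylogenetic species variability) is one minus the mean off-diagonal
element of the phylogenetic correlation matrix restricted to the species in
a plot: 1 on a star phylogeny (all species unrelated), approaching 0 as
species become more related. PSR is PSV × richness. MPD is the mean
patristic distance over all unordered pairs of species present
(presence-based). NRI is −1 × the standardized effect size of MPD against
null assemblages generated by the independent-swap algorithm, which
preserves plot richness and species occupancy exactly; positive NRI means
phylogenetic clustering.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datasets import CommunityMatrix, NullModelConfig, Phylogeny, ValidationError

logger = logging.getLogger(__name__)


def pairwise_distances(ph: Phylogeny) -> pd.DataFrame:
    """Patristic distance matrix: d(a, b) = branch length along the path a→b."""
    if not ph.tree.is_rooted:
        raise ValidationError("phylogeny must be rooted")
    pdm = ph.tree.phylogenetic_distance_matrix()
    taxa = list(ph.tree.taxon_namespace)
    labels = [t.label for t in taxa]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return pd.DataFrame(d, index=labels, columns=labels)


def phylo_correlation(ph: Phylogeny) -> pd.DataFrame:
    """Phylogenetic correlation matrix C from shared root-to-tip branch length.

    V_ab is the branch length shared by the root-to-tip paths of a and b
    (their MRCA's depth); C_ab = V_ab / sqrt(V_aa V_bb), which also handles
    non-ultrametric trees. Diagonal is exactly 1.
    """
    if not ph.tree.is_rooted:
        raise ValidationError("phylogeny must be rooted")
    d = pairwise_distances(ph)
    labels = list(d.index)
    tree = ph.tree
    depth = {}
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    for leaf in tree.leaf_node_iter():
        depth[leaf.taxon.label] = leaf.root_distance
    root_dist = np.array([depth[lab] for lab in labels])
    if (root_dist <= 0).any():
        bad = [lab for lab, rd in zip(labels, root_dist) if rd <= 0]
        raise ValidationError(f"tips with zero root-to-tip distance: {bad}")
    # V_ab = (depth_a + depth_b - d_ab) / 2
    shared = (root_dist[:, None] + root_dist[None, :] - d.to_numpy()) / 2.0
    c = shared / np.sqrt(np.outer(root_dist, root_dist))
    np.fill_diagonal(c, 1.0)
    np.clip(c, 0.0, 1.0, out=c)
    return pd.DataFrame(c, index=labels, columns=labels)


def psv(corr: pd.DataFrame, species: list[str]) -> float:
    """PSV = 1 − mean off-diagonal phylogenetic correlation; NA for singletons."""
    missing = sorted(set(species) - set(corr.index))
    if missing:
        raise ValidationError(f"species missing from correlation matrix: {missing}")
    n = len(species)
    if n < 2:
        return float("nan")
    sub = corr.loc[species, species].to_numpy()
    off_mean = (sub.sum() - n) / (n * (n - 1))
    return float(1.0 - off_mean)


def psr(psv_value: float, s: int) -> float:
    """PSR = PSV × S: richness discounted by relatedness (NA propagates)."""
    if np.isnan(psv_value):
        return float("nan")
    return float(psv_value * s)


def mpd(species: list[str], dist: pd.DataFrame) -> float:
    """Mean patristic distance over all unordered pairs of present species."""
    missing = sorted(set(species) - set(dist.index))
    if missing:
        raise ValidationError(f"species missing from distance matrix: {missing}")
    n = len(species)
    if n < 2:
        return float("nan")
    sub = dist.loc[species, species].to_numpy()
    return float(sub.sum() / (n * (n - 1)))


def _mpd_profile(presence: np.ndarray, d: np.ndarray) -> np.ndarray:
    """MPD for every row of a boolean presence matrix; NaN where S < 2."""
    p = presence.astype(float)
    totals = np.einsum("ps,st,pt->p", p, d, p)
    s = p.sum(axis=1)
    denom = s * (s - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, totals / denom, np.nan)
    return out


def independent_swap(
    matrix: np.ndarray,
    iterations: int | str = "auto",
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Randomise a binary occupancy matrix by 2×2 checkerboard swaps.

    Repeatedly samples a pair of rows and a pair of columns; whenever the
    2×2 submatrix is a checkerboard ([[1,0],[0,1]] or [[0,1],[1,0]]) its
    diagonal is flipped. Row sums (plot richness) and column sums (species
    occupancy) are preserved exactly. ``iterations='auto'`` attempts 10× the
    number of occupied cells.
    """
    m = np.asarray(matrix)
    if not np.isin(m, (0, 1)).all():
        raise ValidationError("independent swap requires a binary matrix")
    n_rows, n_cols = m.shape
    if n_rows < 2 or n_cols < 2:
        raise ValidationError("need at least 2 plots and 2 species to swap")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if iterations == "auto":
        iterations = 10 * int(m.sum())
    # plain Python lists: the trial loop is orders of magnitude faster than
    # scalar indexing into an ndarray
    out = m.astype(int).tolist()
    rows = rng.integers(0, n_rows, size=(iterations, 2)).tolist()
    cols = rng.integers(0, n_cols, size=(iterations, 2)).tolist()
    accepted = 0
    for (r1, r2), (c1, c2) in zip(rows, cols):
        if r1 == r2 or c1 == c2:
            continue
        row1 = out[r1]
        row2 = out[r2]
        a = row1[c1]
        b = row1[c2]
        if a != b and row2[c1] == b and row2[c2] == a:
            row1[c1] = b
            row1[c2] = a
            row2[c1] = a
            row2[c2] = b
            accepted += 1
    if accepted == 0:
        logger.warning(
            "independent swap found no checkerboard in %d attempts; "
            "matrix returned unchanged",
            iterations,
        )
    return np.asarray(out, dtype=matrix.dtype)


def nri(
    cm: CommunityMatrix,
    ph: Phylogeny,
    cfg: NullModelConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """NRI per plot against ``cfg.n_rand_phylo`` independent-swap assemblages.

    NRI = −(MPD_obs − mean MPD_null) / sd MPD_null. Each null assemblage is
    an independent randomisation restarting from the observed
    presence/absence matrix. Singleton plots and degenerate nulls (sd = 0)
    yield NA.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    dist = pairwise_distances(ph)
    species = cm.species_ids
    d = dist.loc[species, species].to_numpy()
    presence = cm.presence().to_numpy()

    obs = _mpd_profile(presence, d)
    base = presence.astype(np.int8)
    n_rand = cfg.n_rand_phylo
    nulls = np.empty((n_rand, presence.shape[0]))
    for k in range(n_rand):
        shuffled = independent_swap(base, cfg.swap_iterations, rng)
        nulls[k] = _mpd_profile(shuffled.astype(bool), d)

    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1) if n_rand > 1 else np.zeros(obs.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(
            null_sd > 0, -(obs - null_mean) / null_sd, np.nan
        )
    return pd.DataFrame(
        {
            "mpd_obs": obs,
            "mpd_null_mean": null_mean,
            "mpd_null_sd": null_sd,
            "nri": values,
        },
        index=pd.Index(cm.plot_ids, name="plot_id"),
    )


def plot_phylo_metrics(cm: CommunityMatrix, ph: Phylogeny) -> pd.DataFrame:
    """PSV, PSR and MPD for every plot (NRI is computed separately)."""
    dist = pairwise_distances(ph)
    corr = phylo_correlation(ph)
    presence = cm.presence()
    records = {}
    for plot_id in cm.plot_ids:
        row = presence.loc[plot_id]
        present = list(row.index[row])
        p = psv(corr, present)
        records[plot_id] = {
            "PSV": p,
            "PSR": psr(p, len(present)),
            "MPD": mpd(present, dist),
        }
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "plot_id"
    return df
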