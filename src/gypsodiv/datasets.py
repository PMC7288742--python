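"""Core domain containers for gypsum-community analyses.

The pipeline links four artifacts: a plot×species abundance (cover) matrix,
a species→gypsophily-index (GI) trait table, a rooted phylogeny with branch
lengths over the species pool, and a per-plot environment table (mean maximum
temperature of the hottest month, mean annual precipitation, total plant
cover). Each container wraps a pandas object and knows how to validate
itself; :class:`GypsumDataset` cross-links them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

GI_MIN = 1.0
GI_MAX = 5.0


class DataFormatError(ValueError):
    """Malformed input artifact (duplicate keys, missing columns, bad Newick)."""


class ValidationError(ValueError):
    """Well-formed input whose values or cross-links violate an invariant."""


def _check_unique(values, what: str) -> None:
    counts = pd.Index(values).value_counts()
    dupes = counts[counts > 1].index.tolist()
    if dupes:
        raise DataFormatError(f"duplicate {what}: {dupes}")


@dataclass
class CommunityMatrix:
    """Plot×species nonnegative abundance table (cover units, raw or relative).

    Rows are plots, columns are species. Relative abundances are always
    recomputed per plot (row-normalised), so raw transect intercept lengths,
    percentages or proportions are all acceptable inputs.
    """

    abundance: pd.DataFrame

    def __post_init__(self) -> None:
        self.abundance = self.abundance.astype(float)
        self.validate()

    @property
    def plot_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.abundance.columns)

    def validate(self) -> None:
        _check_unique(self.abundance.index, "plot ids")
        _check_unique(self.abundance.columns, "species ids")
        values = self.abundance.to_numpy()
        if not np.all(np.isfinite(values)):
            raise ValidationError("community matrix contains non-finite values")
        if (values < 0).any():
            rows, cols = np.nonzero(values < 0)
            r, c = rows[0], cols[0]
            raise ValidationError(
                "negative abundance at plot "
                f"{self.abundance.index[r]!r}, species "
                f"{self.abundance.columns[c]!r}: {values[r, c]}"
            )
        empty = self.abundance.index[values.sum(axis=1) <= 0].tolist()
        if empty:
            raise ValidationError(f"plots with no positive abundance: {empty}")

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised abundances p_i (each row sums to 1)."""
        totals = self.abundance.sum(axis=1)
        return self.abundance.div(totals, axis=0)

    def presence(self) -> pd.DataFrame:
        """Boolean occupancy matrix (abundance strictly positive)."""
        return self.abundance > 0


@dataclass
class TraitTable:
    """Species → gypsophily index GI, an ordinal soil-affinity score.

    GI runs from 1 (avoids gypsum) to 5 (strict gypsophyte). Real values in
    [1, 5] are accepted so that interpolated indices also work.
    """

    gi: pd.Series

    def __post_init__(self) -> None:
        self.gi = self.gi.astype(float)
        self.gi.name = "GI"
        self.validate()

    @property
    def species_ids(self) -> list[str]:
        return list(self.gi.index)

    def validate(self) -> None:
        _check_unique(self.gi.index, "species ids in trait table")
        bad = self.gi[(self.gi < GI_MIN) | (self.gi > GI_MAX) | ~np.isfinite(self.gi)]
        if len(bad):
            raise ValidationError(
                f"GI values outside [{GI_MIN:g}, {GI_MAX:g}]: {dict(bad)}"
            )


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths (divergence-time units) over the pool."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        self.validate()

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def validate(self) -> None:
        labels = self.tip_labels
        _check_unique(labels, "tip labels")
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                raise DataFormatError(
                    "tree has edges without branch lengths; patristic "
                    "distances are undefined"
                )
            if node.edge.length < 0:
                raise ValidationError("negative branch length in tree")


@dataclass
class EnvironmentTable:
    """Per-plot predictors: Tmax (°C), MAP (mm) and total plant cover (%)."""

    table: pd.DataFrame

    REQUIRED = ("Tmax", "MAP", "cover")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DataFormatError(f"environment table missing columns: {missing}")
        self.table = self.table[list(self.REQUIRED)].astype(float)
        self.validate()

    @property
    def plot_ids(self) -> list[str]:
        return list(self.table.index)

    def validate(self) -> None:
        _check_unique(self.table.index, "plot ids in environment table")
        if not np.all(np.isfinite(self.table.to_numpy())):
            raise ValidationError("environment table contains non-finite values")
        cover = self.table["cover"]
        if ((cover < 0) | (cover > 100)).any():
            raise ValidationError("cover must lie in [0, 100] percent")


@dataclass
class NullModelConfig:
    """Replication settings for the permutation null models.

    ``n_rand_trait`` trait-pool shuffles back the SES of GR and GD
    (default 10 000); ``n_rand_phylo`` independent-swap assemblages back NRI
    (default 999). ``swap_iterations='auto'`` attempts 10× the number of
    occupied cells per randomisation.
    """

    n_rand_trait: int = 10_000
    n_rand_phylo: int = 999
    swap_iterations: int | str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rand_trait < 1 or self.n_rand_phylo < 1:
            raise ValidationError("randomization counts must be >= 1")
        if self.swap_iterations != "auto" and int(self.swap_iterations) < 1:
            raise ValidationError("swap_iterations must be >= 1 or 'auto'")


@dataclass
class GypsumDataset:
    """Validated, cross-linked bundle of the four input artifacts."""

    community: CommunityMatrix
    traits: TraitTable
    phylogeny: Phylogeny
    environment: EnvironmentTable
    coverage: dict = field(default_factory=dict)


def validate_dataset(
    community: CommunityMatrix,
    traits: TraitTable,
    phylogeny: Phylogeny,
    environment: EnvironmentTable,
) -> GypsumDataset:
    """Cross-link the four artifacts and fail loudly on any mismatch.

    Every community species must carry a GI and appear as a tree tip, and
    every plot must have an environment row. Returns the linked dataset with
    a small coverage report (plot, species and gypsophyte counts).
    """
    species = set(community.species_ids)
    missing_gi = sorted(species - set(traits.species_ids))
    if missing_gi:
        raise ValidationError(f"species without GI in trait table: {missing_gi}")
    missing_tip = sorted(species - set(phylogeny.tip_labels))
    if missing_tip:
        raise ValidationError(f"species missing from phylogeny: {missing_tip}")
    plots = set(community.plot_ids)
    missing_env = sorted(plots - set(environment.plot_ids))
    if missing_env:
        raise ValidationError(f"plots without environment data: {missing_env}")

    gi = traits.gi.loc[community.species_ids]
    coverage = {
        "n_plots": len(community.plot_ids),
        "n_species": len(community.species_ids),
        "n_gypsophytes": int((gi == GI_MAX).sum()),
    }
    return GypsumDataset(community, traits, phylogeny, environment, coverage)
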