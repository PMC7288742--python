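"""Phylogenetic structure: distances, PSV/PSR, MPD and the swap null model."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gypsodiv import (
    CommunityMatrix,
    NullModelConfig,
    ValidationError,
    independent_swap,
    mpd,
    nri,
    pairwise_distances,
    phylo_correlation,
    psr,
    psv,
)
from conftest import make_tree, star_tree


class TestPairwiseDistances:
    def test_two_tip_star(self):
        d = pairwise_distances(star_tree(2))
        assert d.loc["t0", "t1"] == pytest.approx(2.0)

    def test_hand_computed_path_sums(self):
        d = pairwise_distances(make_tree("((A:1,B:1):1,C:2);"))
        assert d.loc["A", "B"] == pytest.approx(2.0)
        assert d.loc["A", "C"] == pytest.approx(4.0)
        assert d.loc["B", "C"] == pytest.approx(4.0)
        assert np.allclose(d.to_numpy(), d.to_numpy().T)
        assert np.all(np.diag(d.to_numpy()) == 0)

    def test_zero_length_cherry(self):
        d = pairwise_distances(make_tree("((A:0,B:0):1,C:2);"))
        assert d.loc["A", "B"] == 0.0


class TestPhyloCorrelation:
    def test_star_has_zero_off_diagonal(self):
        c = phylo_correlation(star_tree(4))
        arr = c.to_numpy()
        assert np.allclose(np.diag(arr), 1.0)
        assert np.allclose(arr - np.diag(np.diag(arr)), 0.0)

    def test_half_shared_depth_gives_half_correlation(self):
        c = phylo_correlation(make_tree("((A:1,B:1):1,C:2);"))
        assert c.loc["A", "B"] == pytest.approx(0.5)
        assert c.loc["A", "C"] == pytest.approx(0.0)

    def test_zero_length_split_gives_unit_correlation(self):
        c = phylo_correlation(make_tree("((A:0,B:0):1,C:2);"))
        assert c.loc["A", "B"] == pytest.approx(1.0)

    def test_zero_depth_tip_rejected(self):
        with pytest.raises(ValidationError, match="zero root-to-tip"):
            phylo_correlation(make_tree("(A:0,B:1);"))


class TestPsvPsr:
    def test_star_subset_gives_one(self):
        c = phylo_correlation(star_tree(10))
        assert psv(c, [f"t{i}" for i in range(10)]) == pytest.approx(1.0)

    def test_uniform_half_correlation_gives_half(self):
        labels = ["a", "b", "c"]
        c = pd.DataFrame(0.5, index=labels, columns=labels)
        np.fill_diagonal(c.to_numpy(), 1.0)
        c = pd.DataFrame(np.where(np.eye(3), 1.0, 0.5), index=labels, columns=labels)
        assert psv(c, labels) == pytest.approx(0.5)

    def test_singleton_plot_is_na(self):
        c = phylo_correlation(star_tree(3))
        assert np.isnan(psv(c, ["t0"]))

    @pytest.mark.parametrize("p, s, expected", [(1.0, 10, 10.0), (0.5, 4, 2.0)])
    def test_psr_scales_psv_by_richness(self, p, s, expected):
        assert psr(p, s) == expected

    def test_psr_propagates_na(self):
        assert np.isnan(psr(float("nan"), 5))

    def test_psv_decreases_as_shared_basal_branch_lengthens(self):
        values = []
        for shared in (0.0, 0.5, 1.0, 1.5):
            nwk = f"((A:{2-shared:g},B:{2-shared:g}):{shared:g},C:2);" \
                if shared > 0 else "(A:2,B:2,C:2);"
            c = phylo_correlation(make_tree(nwk))
            values.append(psv(c, ["A", "B", "C"]))
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_matches_external_reference_values(self):
        # frozen from an independent community-phylogenetics implementation
        # run on this exact tree and plots
        tree = make_tree("((A:1,B:1):1,(C:2,(D:1,E:1):1):0.5);")
        c = phylo_correlation(tree)
        d = pairwise_distances(tree)
        assert psv(c, ["A", "B", "D"]) == pytest.approx(0.8333333, abs=1e-6)
        assert psv(c, ["B", "C", "E"]) == pytest.approx(0.9333333, abs=1e-6)
        assert mpd(["A", "B", "D"], d) == pytest.approx(3.666667, abs=1e-5)
        assert mpd(["A", "C", "D", "E"], d) == pytest.approx(3.916667, abs=1e-5)


class TestMpd:
    def test_pair_equals_distance(self):
        d = pairwise_distances(make_tree("((A:1,B:1):1,C:2);"))
        assert mpd(["A", "C"], d) == pytest.approx(4.0)

    def test_equidistant_triple(self):
        d = pairwise_distances(star_tree(3))
        assert mpd(["t0", "t1", "t2"], d) == pytest.approx(2.0)

    def test_singleton_is_na(self):
        d = pairwise_distances(star_tree(3))
        assert np.isnan(mpd(["t0"], d))

    def test_matches_brute_force_pair_enumeration(self, rng):
        n = 15
        tips = ",".join(f"s{i}:{rng.uniform(0.5, 3):.6f}" for i in range(n))
        # random caterpillar-ish tree via pairs of nested cherries
        tree = make_tree(f"({tips});")
        d = pairwise_distances(tree)
        for _ in range(20):
            k = rng.integers(2, n + 1)
            subset = [f"s{i}" for i in rng.choice(n, size=k, replace=False)]
            brute = np.mean([
                d.loc[a, b] for a, b in itertools.combinations(subset, 2)
            ])
            assert mpd(subset, d) == pytest.approx(brute, abs=1e-12)


class TestIndependentSwap:
    def test_single_checkerboard_flips(self):
        m = np.array([[1, 0], [0, 1]])
        out = independent_swap(m, iterations=50, rng=3)
        assert out.tolist() in ([[0, 1], [1, 0]], [[1, 0], [0, 1]])
        # with 50 attempts on a 2x2 a swap is found almost surely
        assert out.tolist() == [[0, 1], [1, 0]]

    def test_all_ones_unchanged(self):
        m = np.ones((3, 3), dtype=int)
        out = independent_swap(m, iterations=100, rng=0)
        assert (out == 1).all()

    def test_preserves_margins_for_random_matrices(self, rng):
        for _ in range(20):
            m = (rng.random((10, 20)) < 0.3).astype(int)
            out = independent_swap(m, iterations=1000, rng=rng)
            assert (out.sum(axis=0) == m.sum(axis=0)).all()
            assert (out.sum(axis=1) == m.sum(axis=1)).all()
            assert set(np.unique(out)) <= {0, 1}

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError, match="binary"):
            independent_swap(np.array([[2, 0], [0, 1]]))


def _community(presence: np.ndarray, species: list[str]) -> CommunityMatrix:
    df = pd.DataFrame(
        presence.astype(float),
        index=[f"p{i}" for i in range(presence.shape[0])],
        columns=species,
    )
    return CommunityMatrix(df)


class TestNri:
    def test_saturated_matrix_gives_na(self):
        ph = star_tree(4)
        cm = _community(np.ones((3, 4), dtype=int), [f"t{i}" for i in range(4)])
        out = nri(cm, ph, NullModelConfig(n_rand_phylo=20, seed=0))
        assert out["nri"].isna().all()

    def test_clustered_plot_scores_higher_than_scattered(self):
        # two clades of four; one plot holds a tight clade, the other spans both
        ph = make_tree(
            "(((A:1,B:1):1,(C:1,D:1):1):2,((E:1,F:1):1,(G:1,H:1):1):2);"
        )
        species = list("ABCDEFGH")
        presence = np.zeros((8, 8), dtype=int)
        presence[0, :4] = 1                      # tight clade
        presence[1, [0, 2, 4, 6]] = 1            # scattered across clades
        rng = np.random.default_rng(5)
        for k in range(2, 8):                    # background plots
            presence[k, rng.choice(8, 4, replace=False)] = 1
        cm = _community(presence, species)
        out = nri(cm, ph, NullModelConfig(n_rand_phylo=199, seed=2))
        assert out["nri"].iloc[0] > out["nri"].iloc[1]

    def test_deterministic_given_seed(self):
        ph = star_tree(6)
        rng = np.random.default_rng(1)
        presence = (rng.random((5, 6)) < 0.5).astype(int)
        presence[presence.sum(axis=1) < 2] = 1
        cm = _community(presence, [f"t{i}" for i in range(6)])
        cfg = NullModelConfig(n_rand_phylo=30, seed=9)
        a = nri(cm, ph, cfg)
        b = nri(cm, ph, cfg)
        pd.testing.assert_frame_equal(a, b)


def test_nri_self_null_calibration(rng):
    """NRI of communities generated by the swap null itself is centered:
    mean near 0 and sd near 1 across plots."""
    from gypsodiv.simulate import ScenarioConfig, generate_pool, generate_tree

    n_plots, n_species = 210, 40
    cfg = ScenarioConfig(n_species_pool=n_species, n_gypsophytes=6, seed=3)
    pool = generate_pool(cfg, rng)
    ph, _ = generate_tree(pool, cfg, rng)
    base = (rng.random((n_plots, n_species)) < 0.25).astype(int)
    base[base.sum(axis=1) < 2] = 1
    observed = independent_swap(base, rng=rng)
    cm = _community(observed, list(pool.species_ids))
    out = nri(cm, ph, NullModelConfig(n_rand_phylo=99, seed=17))
    values = out["nri"].dropna()
    assert len(values) >= 200
    assert -0.2 < values.mean() < 0.2
    assert 0.8 < values.std() < 1.2
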