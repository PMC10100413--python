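"""Trait-space chain: fuzzy coding, Gower dissimilarity (vs a
brute-force loop), PCoA round trips, and the three FD metrics against
analytic / exhaustive oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from planklag.functional_diversity import (
    FuzzyTraitMatrix,
    embed_trait_space,
    fd_series,
    fdis,
    feve,
    fric,
    fuzzy_code,
    gower_dissimilarity,
)
from planklag.synthetic_data import GUILD_TRAITS, TraitBlock, generate_trait_table
from tests.conftest import make_panel


def brute_force_gower(traits: FuzzyTraitMatrix) -> np.ndarray:
    """Per-pair loop implementation, independent of the vectorized one."""
    n = len(traits.data)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = den = 0.0
            for block in traits.blocks:
                if block.kind == "numeric":
                    xi = traits.data[block.name].iloc[i]
                    xj = traits.data[block.name].iloc[j]
                    if np.isnan(xi) or np.isnan(xj):
                        continue
                    col = traits.data[block.name]
                    rng_ = col.max() - col.min()
                    d = abs(xi - xj) / rng_ if rng_ > 0 else 0.0
                else:
                    ai = traits.data[block.columns].iloc[i].to_numpy()
                    aj = traits.data[block.columns].iloc[j].to_numpy()
                    if np.isnan(ai).any() or np.isnan(aj).any():
                        continue
                    d = 0.5 * np.abs(ai - aj).sum()
                num += block.weight * d
                den += block.weight
            D[i, j] = num / den
    return D


def exhaustive_mst_weight_sets(points: np.ndarray):
    """All spanning trees of the complete graph on <= 6 points; yields
    edge lists.  Used as an exhaustive oracle for the MST in FEve."""
    n = len(points)
    edges = list(itertools.combinations(range(n), 2))
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        ok = True
        for a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            yield subset


TWO_BLOCKS = (
    TraitBlock("size", "fuzzy", ("s", "m", "l")),
    TraitBlock("carbon", "numeric"),
)


class TestFuzzyCode:
    def test_genus_of_two_species_split_affinities(self):
        rec = pd.DataFrame(
            {
                "taxon": ["g1", "g1"],
                "cell_length_um": ["<=10", ">10-25"],
            }
        )
        blocks = (GUILD_TRAITS["phyto"][0],)
        out = fuzzy_code(rec, blocks)
        row = out.data.loc["g1"]
        assert np.allclose(row.to_numpy(), [0.5, 0.5, 0.0, 0.0])

    def test_single_species_taxon_is_one_hot(self):
        rec = pd.DataFrame({"taxon": ["a"], "mobility": ["flagellated"]})
        blocks = (TraitBlock("mobility", "categorical", ("none", "flagellated", "rapheated")),)
        out = fuzzy_code(rec, blocks)
        assert np.allclose(out.data.loc["a"].to_numpy(), [0.0, 1.0, 0.0])

    def test_genus_of_four_species_three_colonial(self):
        rec = pd.DataFrame(
            {
                "taxon": ["g"] * 4,
                "colonial": ["colonial", "colonial", "colonial", "not_colonial"],
            }
        )
        blocks = (TraitBlock("colonial", "categorical", ("colonial", "not_colonial")),)
        out = fuzzy_code(rec, blocks)
        assert np.allclose(out.data.loc["g"].to_numpy(), [0.75, 0.25])

    def test_numeric_traits_averaged(self):
        rec = pd.DataFrame({"taxon": ["g", "g"], "carbon": [1.0, 3.0]})
        out = fuzzy_code(rec, (TraitBlock("carbon", "numeric"),))
        assert out.data.loc["g", "carbon"] == 2.0

    def test_taxon_without_data_listed_not_silently_dropped(self):
        rec = pd.DataFrame(
            {"taxon": ["a", "b"], "carbon": [1.0, np.nan]}
        )
        out = fuzzy_code(rec, (TraitBlock("carbon", "numeric"),))
        assert out.excluded == ["b"]
        assert out.taxa == ["a"]


class TestGower:
    def test_identical_rows_give_zero(self):
        df = pd.DataFrame(
            {"size.s": [1.0, 1.0], "size.m": [0.0, 0.0], "size.l": [0.0, 0.0],
             "carbon": [2.0, 2.0]},
            index=["a", "b"],
        )
        D = gower_dissimilarity(FuzzyTraitMatrix(df, TWO_BLOCKS))
        assert D.loc["a", "b"] == 0.0

    def test_disjoint_one_hot_categories_give_one(self):
        blocks = (
            TraitBlock("size", "fuzzy", ("s", "l")),
            TraitBlock("shape", "fuzzy", ("round", "long")),
        )
        df = pd.DataFrame(
            {"size.s": [1.0, 0.0], "size.l": [0.0, 1.0],
             "shape.round": [1.0, 0.0], "shape.long": [0.0, 1.0]},
            index=["a", "b"],
        )
        D = gower_dissimilarity(FuzzyTraitMatrix(df, blocks))
        assert D.loc["a", "b"] == pytest.approx(1.0)

    def test_hand_computed_mixed_pair(self):
        # numeric at range endpoints (d=1) + identical categorical (d=0),
        # equal weights -> (1 + 0)/2 = 0.5
        blocks = (
            TraitBlock("carbon", "numeric"),
            TraitBlock("colonial", "categorical", ("yes", "no")),
        )
        df = pd.DataFrame(
            {"carbon": [0.0, 10.0], "colonial.yes": [1.0, 1.0], "colonial.no": [0.0, 0.0]},
            index=["a", "b"],
        )
        D = gower_dissimilarity(FuzzyTraitMatrix(df, blocks))
        assert D.loc["a", "b"] == pytest.approx(0.5)

    def test_matches_brute_force_loop_on_random_tables(self):
        for seed in range(3):
            table = generate_trait_table(8, "phyto", seed=seed)
            m = FuzzyTraitMatrix.from_table(table, GUILD_TRAITS["phyto"])
            D = gower_dissimilarity(m).to_numpy()
            assert np.allclose(D, brute_force_gower(m), atol=1e-12)
            assert np.allclose(D, D.T, atol=1e-12)
            assert np.allclose(np.diag(D), 0.0)
            assert (D >= 0).all() and (D <= 1 + 1e-12).all()


class TestTraitSpace:
    def test_three_equidistant_taxa_form_equilateral_triangle(self):
        D = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        space = embed_trait_space(D, max_dim=10)
        assert space.m == 2
        pts = space.coordinates.to_numpy()
        dists = [np.linalg.norm(pts[i] - pts[j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
        assert np.allclose(dists, 1.0, atol=1e-8)

    def test_euclidean_input_round_trips(self, rng):
        pts = rng.normal(size=(12, 4))
        from scipy.spatial.distance import pdist, squareform

        D = pd.DataFrame(squareform(pdist(pts)))
        space = embed_trait_space(D, max_dim=10)
        rec = squareform(pdist(space.coordinates.to_numpy()))
        assert np.allclose(rec, D.to_numpy(), atol=1e-8)
        assert space.cailliez_constant == 0.0

    def test_rank_bound_for_five_taxa(self):
        D = pd.DataFrame(1.0 - np.eye(5))
        space = embed_trait_space(D, max_dim=10)
        assert space.m <= 4

    def test_fewer_than_three_taxa_rejected(self):
        D = pd.DataFrame(1.0 - np.eye(2))
        with pytest.raises(ValueError, match="3"):
            embed_trait_space(D)

    def test_agrees_with_skbio_pcoa_on_euclidean_input(self, rng):
        skbio = pytest.importorskip("skbio")
        from scipy.spatial.distance import pdist, squareform

        pts = rng.normal(size=(9, 3))
        D = squareform(pdist(pts))
        ours = embed_trait_space(pd.DataFrame(D), max_dim=3).coordinates.to_numpy()
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(D), number_of_dimensions=3
        ).samples.to_numpy()
        # axes agree up to sign
        for k in range(3):
            assert np.allclose(np.abs(ours[:, k]), np.abs(theirs[:, k]), atol=1e-6)


def square_space():
    """A 2-D trait space whose global hull is the unit square."""
    from planklag.functional_diversity import TraitSpace

    coords = pd.DataFrame(
        {"pcoa_1": [0.0, 1.0, 0.0, 1.0], "pcoa_2": [0.0, 0.0, 1.0, 1.0]},
        index=["a", "b", "c", "d"],
    )
    return TraitSpace(coords, eigenvalues=np.array([1.0, 1.0]))


class TestFRic:
    def test_all_taxa_give_one(self):
        assert fric(square_space(), ["a", "b", "c", "d"]) == pytest.approx(1.0)

    def test_triangle_in_unit_square_is_half(self):
        # shoelace oracle: area of (0,0),(1,0),(0,1) = 0.5
        assert fric(square_space(), ["a", "b", "c"]) == pytest.approx(0.5, abs=1e-10)

    def test_hull_volume_monotone_under_taxon_addition(self):
        space = square_space()
        m_eff = 2
        from planklag.functional_diversity import _hull_volume

        v3 = _hull_volume(space.points(["a", "b", "c"], m_eff))
        v4 = _hull_volume(space.points(["a", "b", "c", "d"], m_eff))
        assert v4 >= v3

    def test_too_few_taxa_is_missing(self):
        assert np.isnan(fric(square_space(), ["a"]))

    def test_collinear_present_set_falls_back_to_interval(self):
        # S=2 -> m_eff=1: the metric degrades to a length ratio
        v = fric(square_space(), ["a", "b"])
        assert v == pytest.approx(1.0)  # span of x-extent over global x-extent


class TestFDis:
    def test_two_taxa_equal_weights_half_distance(self):
        space = square_space()
        assert fdis(space, {"a": 1.0, "b": 1.0}) == pytest.approx(0.5)

    def test_all_weight_on_one_taxon_zero(self):
        assert fdis(square_space(), {"a": 5.0, "b": 0.0}) == pytest.approx(0.0)

    def test_invariant_to_weight_scaling(self):
        space = square_space()
        w = {"a": 1.0, "b": 2.0, "c": 3.0}
        w10 = {k: 10 * v for k, v in w.items()}
        assert fdis(space, w) == pytest.approx(fdis(space, w10))

    def test_invariant_to_rotation_and_translation(self, rng):
        from planklag.functional_diversity import TraitSpace

        pts = rng.normal(size=(5, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pts @ R.T + np.array([3.0, -2.0])
        idx = list("abcde")
        s1 = TraitSpace(pd.DataFrame(pts, index=idx), np.ones(2))
        s2 = TraitSpace(pd.DataFrame(moved, index=idx), np.ones(2))
        w = dict(zip(idx, [1.0, 2.0, 0.5, 1.5, 3.0]))
        assert fdis(s1, w) == pytest.approx(fdis(s2, w), abs=1e-10)


class TestFEve:
    def test_equally_spaced_equal_abundance_is_one(self):
        from planklag.functional_diversity import TraitSpace

        pts = np.column_stack([np.arange(5.0), np.zeros(5)])
        space = TraitSpace(pd.DataFrame(pts, index=list("abcde")), np.ones(2))
        assert feve(space, dict.fromkeys("abcde", 1.0)) == pytest.approx(1.0)

    def test_extreme_unevenness_approaches_zero(self):
        from planklag.functional_diversity import TraitSpace

        pts = np.column_stack([np.array([0.0, 1e-6, 2e-6, 1000.0]), np.zeros(4)])
        space = TraitSpace(pd.DataFrame(pts, index=list("abcd")), np.ones(2))
        v = feve(space, dict.fromkeys("abcd", 1.0))
        assert 0.0 <= v < 0.05

    def test_fewer_than_three_taxa_missing(self):
        assert np.isnan(feve(square_space(), {"a": 1.0, "b": 1.0}))

    def test_value_in_unit_interval_and_mst_matches_exhaustive(self, rng):
        from planklag.functional_diversity import TraitSpace
        from scipy.sparse.csgraph import minimum_spanning_tree
        from scipy.spatial.distance import pdist, squareform

        for _ in range(5):
            pts = rng.normal(size=(6, 2))
            idx = list("abcdef")
            space = TraitSpace(pd.DataFrame(pts, index=idx), np.ones(2))
            w = dict(zip(idx, rng.uniform(0.5, 2.0, 6)))
            v = feve(space, w)
            assert 0.0 <= v <= 1.0
            # exhaustive spanning-tree oracle: scipy's MST weight is minimal
            D = squareform(pdist(pts))
            scipy_weight = minimum_spanning_tree(D).sum()
            best = min(
                sum(D[a, b] for a, b in tree)
                for tree in exhaustive_mst_weight_sets(pts)
            )
            assert scipy_weight == pytest.approx(best, abs=1e-10)

    def test_invariant_to_uniform_abundance_scaling(self, rng):
        from planklag.functional_diversity import TraitSpace

        pts = rng.normal(size=(5, 3))
        idx = list("abcde")
        space = TraitSpace(pd.DataFrame(pts, index=idx), np.ones(3))
        w = dict(zip(idx, rng.uniform(0.5, 2.0, 5)))
        w4 = {k: 4.0 * v for k, v in w.items()}
        assert feve(space, w) == pytest.approx(feve(space, w4), abs=1e-12)


class TestFDSeries:
    def setup_method(self):
        self.table = generate_trait_table(6, "phyto", seed=5)
        m = FuzzyTraitMatrix.from_table(self.table, GUILD_TRAITS["phyto"])
        self.space = embed_trait_space(gower_dissimilarity(m), max_dim=4)

    def test_all_present_equal_density_fric_is_one(self):
        panel = make_panel(np.ones((4, 6)), ["phyto"] * 6)
        panel.data.columns = self.space.taxa
        panel.guilds = dict.fromkeys(self.space.taxa, "phyto")
        out = fd_series(panel, self.space, "phyto")
        assert np.allclose(out.fric.to_numpy(), 1.0)

    def test_single_taxon_month(self):
        vals = np.ones((3, 6))
        vals[1, 1:] = 0.0  # month 1: only one taxon present
        panel = make_panel(vals, ["phyto"] * 6)
        panel.data.columns = self.space.taxa
        panel.guilds = dict.fromkeys(self.space.taxa, "phyto")
        out = fd_series(panel, self.space, "phyto")
        assert out.fdis.to_numpy()[1] == 0.0
        assert np.isnan(out.fric.to_numpy()[1])
        assert np.isnan(out.feve.to_numpy()[1])

    def test_constant_panel_gives_constant_series(self, rng):
        row = rng.uniform(1, 5, size=6)
        panel = make_panel(np.tile(row, (5, 1)), ["phyto"] * 6)
        panel.data.columns = self.space.taxa
        panel.guilds = dict.fromkeys(self.space.taxa, "phyto")
        out = fd_series(panel, self.space, "phyto")
        for series in out.as_dict().values():
            vals = series.to_numpy()
            assert np.allclose(vals, vals[0], equal_nan=True)
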