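import numpy as np
import pandas as pd
import pytest

from phyloarch.architecture import (Branch, IndividualArchitecture,
                                    RawTraitMeasurements,
                                    branching_index_table, derive_traits,
                                    exploration_index, integrative_index,
                                    photosynthetic_index, segregate_classes)
from oracles import pc1_scores_2col


def make_ind(trunk_len=100.0, trunk_la=(50.0, 50.0), branches=(), n_branches=None):
    return IndividualArchitecture("sp", trunk_len, trunk_la, tuple(branches),
                                  n_branches)


class TestRawIndexes:
    def test_monocaulous_limits(self):
        ind = make_ind()
        assert photosynthetic_index(ind) == 0.0
        assert exploration_index(ind) == 0.0

    def test_photosynthetic_ratio(self):
        ind = make_ind(trunk_la=(100.0,),
                       branches=[Branch(50.0, (200.0,)), Branch(50.0, (200.0,))])
        assert photosynthetic_index(ind) == pytest.approx(400 / 500)

    def test_all_leaves_on_branches(self):
        ind = make_ind(trunk_la=(0.0,), branches=[Branch(10.0, (5.0,))])
        assert photosynthetic_index(ind) == pytest.approx(1.0)

    def test_exploration_ratio(self):
        ind = make_ind(trunk_len=100.0,
                       branches=[Branch(150.0, (1.0,)), Branch(150.0, (1.0,))])
        assert exploration_index(ind) == pytest.approx(300 / 400)

    def test_zero_trunk_warns_and_returns_one(self):
        ind = make_ind(trunk_len=0.0, branches=[Branch(10.0, (1.0,))])
        with pytest.warns(UserWarning):
            assert exploration_index(ind) == pytest.approx(1.0)

    def test_zero_total_leaf_area_errors(self):
        ind = make_ind(trunk_la=(0.0,))
        with pytest.raises(ValueError, match="undefined"):
            photosynthetic_index(ind)

    def test_representative_branch_extrapolation(self):
        # 2 measured of a 10-branch census: totals scale by 5
        ind = make_ind(trunk_len=100.0, trunk_la=(100.0,),
                       branches=[Branch(10.0, (10.0,)), Branch(30.0, (30.0,))],
                       n_branches=10)
        assert ind.branch_leaf_area == pytest.approx(200.0)
        assert exploration_index(ind) == pytest.approx(200 / 300)

    def test_unit_free_invariance(self):
        a = make_ind(trunk_len=100.0, trunk_la=(40.0,),
                     branches=[Branch(60.0, (60.0,))])
        b = make_ind(trunk_len=700.0, trunk_la=(280.0,),
                     branches=[Branch(420.0, (420.0,))])
        assert photosynthetic_index(a) == pytest.approx(photosynthetic_index(b))
        assert exploration_index(a) == pytest.approx(exploration_index(b))

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_ind(branches=[], n_branches=3)
        with pytest.raises(ValueError):
            make_ind(trunk_len=-1.0)


class TestIntegrativeIndex:
    def test_collinear_columns_pc1_explains_all(self):
        df = pd.DataFrame({"photo": [0.1, 0.3, 0.6, 0.9],
                           "explo": [0.2, 0.6, 1.2, 1.8]})
        res = integrative_index(df)
        assert res.explained == pytest.approx(1.0)
        z = (df.photo - df.photo.mean()) / df.photo.std(ddof=1)
        assert np.corrcoef(res.scores, z)[0, 1] == pytest.approx(1.0)

    def test_matches_eigen_oracle(self, rng):
        base = rng.uniform(0, 1, 6)
        df = pd.DataFrame({"photo": base + rng.normal(0, 0.1, 6),
                           "explo": base + rng.normal(0, 0.1, 6)},
                          index=[f"s{i}" for i in range(6)])
        res = integrative_index(df)
        scores, expl = pc1_scores_2col(df.to_numpy())
        np.testing.assert_allclose(res.scores.to_numpy(), scores, atol=1e-10)
        assert res.explained == pytest.approx(expl)

    def test_positive_loadings_monotone(self, rng):
        base = rng.uniform(0, 1, 8)
        df = pd.DataFrame({"photo": base + rng.normal(0, 0.05, 8),
                           "explo": base + rng.normal(0, 0.05, 8)})
        res = integrative_index(df)
        assert np.all(res.loadings > 0)
        # raising photo of one species raises its score
        df2 = df.copy()
        df2.loc[0, "photo"] += 0.2
        res2 = integrative_index(df2)
        assert res2.project(df2.iloc[[0]]).iloc[0] > res.project(df.iloc[[0]]).iloc[0]

    def test_constant_column_degenerate(self):
        df = pd.DataFrame({"photo": [0.5] * 4, "explo": [0.1, 0.2, 0.3, 0.4]})
        with pytest.raises(ValueError, match="degenerate"):
            integrative_index(df)

    def test_too_few_species(self):
        df = pd.DataFrame({"photo": [0.1, 0.9], "explo": [0.1, 0.9]})
        with pytest.raises(ValueError):
            integrative_index(df)


class TestSegregation:
    def _clusters(self, rng, centers, n_sp=5, n_ind=5, sd=0.03):
        scores = {}
        truth = {}
        i = 0
        for cl, c in enumerate(centers, start=1):
            for _ in range(n_sp):
                i += 1
                scores[f"s{i:02d}"] = c + rng.normal(0, sd, n_ind)
                truth[f"s{i:02d}"] = cl
        return scores, truth

    def test_three_separated_clusters_recovered(self, rng):
        scores, truth = self._clusters(rng, [0.05, 0.45, 0.85])
        seg = segregate_classes(scores, alpha=0.1, k=3)
        assert seg.classes == truth

    def test_null_single_distribution_warns(self, rng):
        scores = {f"s{i}": rng.normal(0.5, 0.001, 5) for i in range(6)}
        with pytest.warns(UserWarning):
            seg = segregate_classes(scores, alpha=0.1, k=3)
        assert seg.warning is not None

    def test_identical_species_share_letter_and_class(self, rng):
        base = rng.normal(0.2, 0.02, 5)
        scores = {"a": base.copy(), "b": base.copy(),
                  "c": base + 0.6, "d": base + 0.61, "e": base + 1.2}
        seg = segregate_classes(scores, alpha=0.1, k=3)
        assert seg.letters["a"] == seg.letters["b"]
        assert seg.classes["a"] == seg.classes["b"]

    def test_rank_invariance_under_monotone_transform(self, rng):
        scores, _ = self._clusters(rng, [0.05, 0.45, 0.85], n_sp=3)
        seg1 = segregate_classes(scores)
        seg2 = segregate_classes({s: np.exp(4 * v) for s, v in scores.items()})
        assert seg1.classes == seg2.classes

    def test_k_below_two_rejected(self, rng):
        scores, _ = self._clusters(rng, [0.1, 0.9], n_sp=3)
        with pytest.raises(ValueError):
            segregate_classes(scores, k=1)


class TestDeriveTraits:
    def test_geometric_mean_internode(self):
        t = derive_traits(RawTraitMeasurements(min_internode_diameter=0.4,
                                               max_internode_diameter=0.9))
        assert t["internode_d"] == pytest.approx(0.6)

    def test_fruit_volume(self):
        t = derive_traits(RawTraitMeasurements(fruit_length=3.0, fruit_width=2.0))
        assert t["fruit_vol"] == pytest.approx(12.0)

    def test_section_proportions_close(self):
        t = derive_traits(RawTraitMeasurements(pith_area=2.0, wood_area=5.0,
                                               cortex_area=3.0,
                                               whole_section_area=10.0))
        assert (t["pct_pith"], t["pct_wood"], t["pct_cortex"]) == (0.2, 0.5, 0.3)
        assert t["pct_pith"] + t["pct_wood"] + t["pct_cortex"] == pytest.approx(1.0)

    def test_zero_denominator_is_per_trait_nan(self):
        t = derive_traits(RawTraitMeasurements(plant_height=100.0,
                                               basal_diameter=0.0,
                                               fruit_length=3.0, fruit_width=2.0))
        assert np.isnan(t["sr"])
        assert t["fruit_vol"] == pytest.approx(12.0)

    def test_ratio_traits(self):
        t = derive_traits(RawTraitMeasurements(
            plant_height=300.0, basal_diameter=3.0, wood_dry_mass=5.0,
            wood_fresh_volume=10.0, stem_dry_mass=6.0, stem_fresh_volume=12.0,
            wood_area_pom=2.0, leaf_area_above_pom=400.0, leaf_fresh_area=50.0,
            leaf_dry_mass=2.5, mean_trunk_leaf_area=100.0, n_trunk_leaves=10,
            branch_mean_leaf_area=20.0, branch_mean_leaf_number=4.0,
            n_branches=5))
        assert t["sr"] == pytest.approx(100.0)
        assert t["swd"] == pytest.approx(0.5)
        assert t["ssd"] == pytest.approx(0.5)
        assert t["hv"] == pytest.approx(0.005)
        assert t["sla"] == pytest.approx(20.0)
        assert t["total_la"] == pytest.approx(20 * 5 + 100 * 10)
        assert t["nb_leaf"] == pytest.approx(10 + 4 * 5)

    def test_section_closure_violation_rejected(self):
        with pytest.raises(ValueError):
            RawTraitMeasurements(pith_area=5.0, wood_area=5.0, cortex_area=5.0,
                                 whole_section_area=10.0)


def test_branching_index_table_shape():
    inds = [make_ind(), make_ind(branches=[Branch(50.0, (25.0,))])]
    df = branching_index_table(inds)
    assert list(df.columns) == ["species", "photo", "explo"]
    assert len(df) == 2
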