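"""Mantel tests and permutation-significance feature importance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from manuresub.drivers import (
    correlation_table,
    driver_report,
    feature_distance,
    mantel_test,
    permutation_importance,
    significance_stars,
)


def _random_distance(rng, n, dim=2):
    return squareform(pdist(rng.normal(size=(n, dim))))


class TestMantel:
    def test_identity_matrices_give_r_one_and_min_p(self, rng):
        d = _random_distance(rng, 8)
        res = mantel_test(d, d, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 200)

    def test_monte_carlo_matches_exhaustive_enumeration_4x4(self, rng):
        """All 24 simultaneous row/column permutations of a 4x4 matrix can
        be enumerated; the Monte-Carlo p must agree within binomial error."""
        d1 = _random_distance(rng, 4)
        d2 = _random_distance(rng, 4)
        iu = np.triu_indices(4, 1)
        r_obs = stats.pearsonr(d1[iu], d2[iu])[0]
        exact = np.mean([
            stats.pearsonr(d1[iu], d2[np.ix_(p, p)][iu])[0] >= r_obs
            for p in map(list, itertools.permutations(range(4)))
        ])
        res = mantel_test(d1, d2, n_perm=4999, seed=1)
        se = np.sqrt(exact * (1 - exact) / 4999)
        assert abs(res.p - exact) < 4 * se + 1e-3

    def test_spearman_invariant_under_monotone_rescaling(self, rng):
        d1 = _random_distance(rng, 7)
        d2 = _random_distance(rng, 7)
        a = mantel_test(d1, d2, method="spearman", n_perm=99, seed=5)
        b = mantel_test(d1, d2**2, method="spearman", n_perm=99, seed=5)
        assert a.r == pytest.approx(b.r)
        assert a.p == b.p

    def test_seeded_reproducibility_and_never_zero_p(self, rng):
        d1 = _random_distance(rng, 6)
        d2 = _random_distance(rng, 6)
        a = mantel_test(d1, d2, n_perm=99, seed=3)
        b = mantel_test(d1, d2, n_perm=99, seed=3)
        assert a.p == b.p and a.p >= 1 / 100

    def test_input_validation(self):
        asym = np.array([[0, 1.0], [2.0, 0]])
        sym = np.array([[0, 1.0], [1.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            mantel_test(asym, sym)
        with pytest.raises(ValueError, match="dimension"):
            mantel_test(np.zeros((3, 3)), np.zeros((4, 4)))


class TestPermutationImportance:
    def test_perfect_predictor_ranks_first_and_significant(self, rng):
        hits = 0
        for seed in range(20):
            X = pd.DataFrame(
                rng.normal(size=(24, 5)), columns=list("ABCDE")
            )
            y = X["A"].to_numpy().copy()
            res = permutation_importance(X, y, n_trees=60, n_null=39, seed=seed)
            top = res.ranked()
            hits += top.index[0] == "A" and top.loc["A", "p"] <= 0.05
        assert hits >= 19

    def test_constant_feature_never_important(self, rng):
        X = pd.DataFrame(rng.normal(size=(24, 4)), columns=list("ABCD"))
        X["D"] = 1.0
        y = X["A"] + rng.normal(scale=0.2, size=24)
        ps, imps = [], []
        for seed in range(30):
            res = permutation_importance(X, y, n_trees=40, n_null=19, seed=seed)
            ps.append(res.table.loc["D", "p"])
            imps.append(res.table.loc["D", "importance"])
        assert all(p > 0.05 for p in ps)
        assert np.mean(imps) == pytest.approx(0.0, abs=1e-6)

    def test_reproducible_for_fixed_seed(self, rng):
        X = pd.DataFrame(rng.normal(size=(16, 4)), columns=list("ABCD"))
        y = X["B"] + rng.normal(scale=0.3, size=16)
        a = permutation_importance(X, y, n_trees=30, n_null=9, seed=7)
        b = permutation_importance(X, y, n_trees=30, n_null=9, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_degenerate_inputs_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("ABC"))
        with pytest.raises(ValueError, match="no variance"):
            permutation_importance(X, np.ones(10), n_trees=10, n_null=1, seed=0)
        with pytest.raises(ValueError, match="8 samples"):
            permutation_importance(X.head(5), np.arange(5.0), n_trees=10,
                                   n_null=1, seed=0)


class TestHelpers:
    def test_significance_stars(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.06) == ""

    def test_correlation_table_flags_known_association(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("ABC"))
        y = 3 * X["A"] + rng.normal(scale=0.1, size=30)
        table = correlation_table(X, y)
        assert table.loc["A", "stars"] == "***"
        assert abs(table.loc["A", "r"]) > 0.9

    def test_feature_distance_properties(self, rng):
        block = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("xyz"))
        d = feature_distance(block).to_numpy()
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0.0)
        # scale invariance through z-scoring
        d2 = feature_distance(block * 100.0).to_numpy()
        assert np.allclose(d, d2)


class TestDriverReport:
    def test_known_drivers_recovered_on_generated_trial(self):
        """Yield rebuilt from soil water and phosphatase must surface as
        top-ranked, starred drivers."""
        from manuresub.synthetic import generate_trial, null_config

        # a trial with no treatment structure, so features vary
        # independently and the injected signal is identifiable
        ds = generate_trial(null_config(seed=11), include_community=False)
        wide = ds.to_wide()
        rng = np.random.default_rng(0)
        # overwrite plot-level yield with a known function of topsoil SW and ALP
        top = wide.xs("0-20", level="depth")
        sw = (top["SW"] - top["SW"].mean()) / top["SW"].std()
        alp = (top["ALP"] - top["ALP"].mean()) / top["ALP"].std()
        synthetic_yield = 10 + 2 * sw + 2 * alp + rng.normal(scale=0.3, size=len(sw))
        records = ds.records.copy()
        mask = records["variable"] == "yield"
        keyed = records.loc[mask, ["treatment", "replicate"]].apply(tuple, axis=1)
        records.loc[mask, "value"] = keyed.map(dict(zip(sw.index, synthetic_yield))).to_numpy()
        from manuresub.synthetic import TrialDataset
        ds2 = TrialDataset(records=records)

        from manuresub.soil_quality import sqi_pipeline
        from manuresub.stoichiometry import panel_from_dataset

        report = driver_report(
            ds2, panel_from_dataset(ds2), sqi_pipeline(ds2),
            depths=["0-20"], n_perm=199, n_null=49, n_trees=500, seed=1,
        )
        tables = report["0-20"]["yield"]
        top3 = tables["importance"].index[:3]
        assert "SW" in top3 and "ALP" in top3
        assert tables["correlations"].loc["SW", "stars"] != ""
        assert {"physicochemical", "enzymes", "stoichiometry"} >= set(
            tables["mantel"].index
        )

    def test_single_depth_input_restricts_report(self, small_dataset):
        from manuresub.soil_quality import sqi_pipeline
        from manuresub.stoichiometry import panel_from_dataset

        report = driver_report(
            small_dataset, panel_from_dataset(small_dataset),
            sqi_pipeline(small_dataset), depths=["20-40"],
            n_perm=99, n_null=9, n_trees=30, seed=2,
        )
        assert list(report) == ["20-40"]
        assert {"yield", "SQI"} == set(report["20-40"])
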