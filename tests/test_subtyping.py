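"""Consensus NMF subtyping: feature filtering, the non-negative split,
rank selection on planted clusters, representative features, Jaccard
concordance and the signed-FDR CDF."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from igpkit.simulate import simulate_cohort
from igpkit.subtyping import (
    extract_representative_features,
    filter_variable_features,
    jaccard_index,
    label_permutation_test,
    nmf_consensus,
    nonnegative_split,
    select_rank,
    signed_fdr,
    signed_fdr_cdf,
)


def _matrix(rows, index=None):
    rows = np.asarray(rows, dtype=float)
    return pd.DataFrame(
        rows,
        index=index or [f"f{i}" for i in range(rows.shape[0])],
        columns=[f"s{i}" for i in range(rows.shape[1])],
    )


class TestVariableFilter:
    def test_drops_least_variable_quartile(self, rng):
        base = rng.standard_normal((4, 50))
        m = _matrix(base * np.array([1.0, 2.0, 3.0, 4.0])[:, None])
        out = filter_variable_features(m)
        assert "f0" not in out.index and len(out) == 3

    def test_constant_feature_always_dropped(self, rng):
        m = _matrix(np.vstack([np.zeros(30), rng.standard_normal((5, 30))]))
        out = filter_variable_features(m)
        assert "f0" not in out.index

    def test_survivors_are_z_scored(self, rng):
        m = _matrix(rng.standard_normal((10, 40)) * rng.uniform(0.5, 3, (10, 1)))
        out = filter_variable_features(m)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_absolute_mode(self, rng):
        m = _matrix(np.vstack([0.1 * rng.standard_normal(200), rng.standard_normal(200)]))
        out = filter_variable_features(m, mode="absolute", sd_threshold=0.25)
        assert list(out.index) == ["f1"]


class TestNonnegativeSplit:
    def test_quoted_example(self):
        m = _matrix([[1.0, -2.0, 0.0]])
        out = nonnegative_split(m)
        np.testing.assert_array_equal(out.loc["f0+"], [1.0, 0.0, 0.0])
        np.testing.assert_array_equal(out.loc["f0-"], [0.0, 2.0, 0.0])

    def test_all_positive_gives_zero_negative_half(self, rng):
        m = _matrix(rng.uniform(0.1, 5, (6, 8)))
        out = nonnegative_split(m)
        assert (out.iloc[6:] == 0).all().all()

    def test_exactly_invertible(self, rng):
        m = _matrix(rng.standard_normal((10, 12)))
        out = nonnegative_split(m)
        recon = out.iloc[:10].to_numpy() - out.iloc[10:].to_numpy()
        np.testing.assert_array_equal(recon, m.to_numpy())
        assert (out.to_numpy() >= 0).all()


def _blocks(k=3, per=8, n_feat=60, shift=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_feat, k * per)) * 0.2
    for c in range(k):
        X[c * (n_feat // k) : (c + 1) * (n_feat // k), c * per : (c + 1) * per] += shift
    return _matrix(np.abs(X))


class TestConsensusNMF:
    def test_ideal_blocks_perfect_consensus(self):
        m = _blocks()
        model = nmf_consensus(m, 3, n_runs=5, seed=1)
        assert model.cophenetic == pytest.approx(1.0)
        assert model.dispersion == pytest.approx(1.0)
        c = model.consensus.to_numpy()
        np.testing.assert_allclose(c, c.T)
        np.testing.assert_allclose(np.diag(c), 1.0)

    def test_rank_one_rejected(self):
        with pytest.raises(ValueError, match="k must be >= 2"):
            nmf_consensus(_blocks(), 1)

    def test_negative_input_rejected(self):
        m = _matrix([[-1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match="non-negative"):
            nmf_consensus(m, 2)

    def test_deterministic_under_seed(self):
        m = _blocks()
        m1 = nmf_consensus(m, 3, n_runs=4, seed=9)
        m2 = nmf_consensus(m, 3, n_runs=4, seed=9)
        pd.testing.assert_series_equal(m1.labels, m2.labels)
        pd.testing.assert_frame_equal(m1.basis, m2.basis)

    def test_labels_are_coefficient_argmax(self):
        m = _blocks()
        model = nmf_consensus(m, 3, n_runs=3, seed=2)
        expected = model.coefficients.to_numpy().argmax(axis=0) + 1
        np.testing.assert_array_equal(model.labels.to_numpy(), expected)


class TestRankSelection:
    @pytest.mark.parametrize("k", [2, 3])
    def test_recovers_planted_k_and_labels(self, k):
        cohort = simulate_cohort(
            n_tumor=45, n_nat=10, k_clusters=k, n_features=400, seed=20 + k,
            missing_rate=0.0,
        )
        tumors = [c for c in cohort.glycoforms.columns if c.startswith("T")]
        filtered = filter_variable_features(cohort.glycoforms[tumors])
        nn = nonnegative_split(filtered)
        model, survey = select_rank(nn, k_range=range(2, 6), n_runs=6, final_runs=12, seed=0)
        assert model.rank == k
        ari = adjusted_rand_score(cohort.truth.clusters[tumors], model.labels[tumors])
        assert ari >= 0.9
        assert survey.loc[k, "product"] == survey["product"].max()


class TestRepresentativeFeatures:
    def _model(self, basis_rows):
        m = _blocks()
        model = nmf_consensus(m, 3, n_runs=2, seed=0)
        model.basis = pd.DataFrame(
            np.asarray(basis_rows, dtype=float),
            index=[f"f{i}" for i in range(len(basis_rows))],
            columns=[1, 2, 3],
        )
        return model

    def test_dominant_row_assigned(self):
        model = self._model([[0.9, 0.05, 0.05]])
        assert extract_representative_features(model)[1] == ["f0"]

    def test_uniform_row_unassigned(self):
        model = self._model([[1.0, 1.0, 1.0]])
        reps = extract_representative_features(model)
        assert all(not v for v in reps.values())

    def test_boundary_inclusive(self):
        model = self._model([[0.8, 0.2, 0.0]])
        assert extract_representative_features(model)[1] == ["f0"]


class TestJaccard:
    def test_examples(self):
        assert jaccard_index({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)
        assert jaccard_index({"a"}, {"a"}) == 1.0
        assert jaccard_index({"a"}, {"b"}) == 0.0
        assert jaccard_index(set(), set()) == 0.0


class TestPermutationTest:
    def _labels(self, values):
        return pd.Series(values, index=[f"s{i}" for i in range(len(values))])

    def test_identical_labelings_extreme_p(self):
        l1 = self._labels([1, 1, 1, 2, 2, 2, 3, 3, 3] * 3)
        res = label_permutation_test(l1, l1, n_perm=99, seed=0)
        diag = res[res["class_1"] == res["class_2"]]
        np.testing.assert_allclose(diag["p_value"].to_numpy(), 1 / 100)

    def test_deterministic_under_seed(self, rng):
        l1 = self._labels(rng.integers(1, 3, 30))
        l2 = self._labels(rng.integers(1, 4, 30))
        r1 = label_permutation_test(l1, l2, n_perm=50, seed=3)
        r2 = label_permutation_test(l1, l2, n_perm=50, seed=3)
        pd.testing.assert_frame_equal(r1, r2)

    def test_null_p_values_not_anticonservative(self):
        """Under independent random labelings the permutation p-values
        are (super-)uniform: P(p <= t) <= t + sampling slack."""
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(60):
            l1 = self._labels(rng.integers(1, 3, 40))
            l2 = self._labels(rng.integers(1, 3, 40))
            res = label_permutation_test(l1, l2, n_perm=99, seed=int(rng.integers(1 << 30)))
            ps.append(res["p_value"].iloc[0])
        ps = np.array(ps)
        for t in (0.05, 0.1, 0.25, 0.5):
            assert (ps <= t).mean() <= t + 0.12


class TestSignedFdr:
    def test_formula(self):
        np.testing.assert_allclose(signed_fdr([2.0, -1.0], [0.01, 0.1]), [2.0, -1.0])

    def test_cdf_properties(self, rng):
        de = pd.DataFrame(
            {
                "log2fc": rng.standard_normal(100),
                "fdr": rng.uniform(0.001, 1, 100),
            },
            index=[f"f{i}" for i in range(100)],
        )
        types = pd.Series(
            rng.choice(["HM", "F+S", "Other"], 100), index=de.index
        )
        cdfs = signed_fdr_cdf(de, types)
        assert set(cdfs) == {"HM", "F+S", "Other"}
        for df in cdfs.values():
            assert (np.diff(df["value"]) >= 0).all()
            assert (np.diff(df["cdf"]) >= 0).all()
            assert 0 < df["cdf"].iloc[0] <= 1
            assert df["cdf"].iloc[-1] == pytest.approx(1.0)
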