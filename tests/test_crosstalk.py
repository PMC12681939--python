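"""Glyco-phospho crosstalk: overlap counts, fold-change concordance,
paired-condition correlation rewiring and enzyme-glycan patterns."""

import numpy as np
import pandas as pd
import pytest

from igpkit.crosstalk import (
    enzyme_glycan_patterns,
    fold_change_concordance,
    hub_counts,
    modified_protein_overlap,
    paired_condition_correlations,
    rewired_pairs,
)
from igpkit.simulate import simulate_cohort


class TestOverlap:
    def test_disjoint(self):
        out = modified_protein_overlap({"a"}, {"b"}, {"c"})
        assert out["all_three"] == 0
        assert out["glyco_only"] == out["phospho_only"] == out["global_only"] == 1

    def test_identical(self):
        out = modified_protein_overlap({"a", "b"}, {"a", "b"}, {"a", "b"})
        assert out["all_three"] == 2
        assert sum(v for k, v in out.items() if k != "all_three") == 0

    def test_example(self):
        out = modified_protein_overlap({"a", "b"}, {"b", "c"}, {"b"})
        assert out["all_three"] == 1
        assert out["glyco_only"] == 1 and out["phospho_only"] == 1


def _de(values, index):
    return pd.DataFrame({"log2fc": values}, index=index)


class TestConcordance:
    def test_identical_vectors_perfect_fit(self):
        idx = [f"f{i}" for i in range(10)]
        vals = np.linspace(-2, 2, 10)
        genes = pd.Series([f"G{i}" for i in range(10)], index=idx)
        pairs, fit = fold_change_concordance(_de(vals, idx), _de(vals, idx), genes, genes)
        assert len(pairs) == 10
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        idx = [f"f{i}" for i in range(5)]
        genes = pd.Series([f"G{i}" for i in range(5)], index=idx)
        _, fit = fold_change_concordance(
            _de(np.arange(5.0), idx), _de(np.ones(5), idx), genes, genes
        )
        assert fit is None

    def test_matches_closed_form_least_squares(self, rng):
        idx = [f"f{i}" for i in range(50)]
        x = rng.standard_normal(50)
        y = 0.4 * x + rng.standard_normal(50) * 0.5
        genes = pd.Series([f"G{i}" for i in range(50)], index=idx)
        _, fit = fold_change_concordance(_de(x, idx), _de(y, idx), genes, genes)
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(y.mean() - slope * x.mean(), abs=1e-9)

    def test_planted_correlation_recovered(self, rng):
        n = 500
        x = rng.standard_normal(n)
        y = 0.3 * x + np.sqrt(1 - 0.09) * rng.standard_normal(n)
        idx = [f"f{i}" for i in range(n)]
        genes = pd.Series([f"G{i}" for i in range(n)], index=idx)
        _, fit = fold_change_concordance(_de(x, idx), _de(y, idx), genes, genes)
        assert fit.r == pytest.approx(0.3, abs=0.1)


class TestPairedCorrelations:
    def test_planted_decoupling_recovered(self):
        cohort = simulate_cohort(
            n_tumor=44, n_nat=44, n_features=80, n_phospho=80,
            n_crosstalk_pairs=20, corr_nat=0.9, corr_tumor=0.0,
            missing_rate=0.0, seed=3,
        )
        tumors = [c for c in cohort.glycoforms.columns if c.startswith("T")]
        nats = [c for c in cohort.glycoforms.columns if c.startswith("N")]
        pairs = paired_condition_correlations(
            cohort.glycoforms, cohort.phosphosites, tumors, nats
        )
        assert pairs["corr_tumor"].between(-1, 1).all()
        assert pairs["corr_nat"].between(-1, 1).all()
        truth = cohort.truth.crosstalk_pairs
        merged = truth.merge(pairs, on=["glycoform", "phosphosite"], suffixes=("_true", ""))
        assert len(merged) == len(truth)
        assert np.abs(merged["corr_nat"] - 0.9).max() <= 0.15
        assert np.abs(merged["corr_tumor"]).max() <= 0.5

    def test_constant_feature_omitted(self):
        g = pd.DataFrame(
            np.vstack([np.ones(20), np.random.default_rng(0).standard_normal(20)]),
            index=["const", "varying"],
            columns=[f"T{i}" for i in range(10)] + [f"N{i}" for i in range(10)],
        )
        p = pd.DataFrame(
            np.random.default_rng(1).standard_normal((1, 20)),
            index=["PP_S1"], columns=g.columns,
        )
        pairs = paired_condition_correlations(
            g, p, [f"T{i}" for i in range(10)], [f"N{i}" for i in range(10)], min_pairs=5
        )
        assert "const" not in set(pairs["glycoform"])


class TestRewiredPairs:
    def _pairs(self, rows):
        df = pd.DataFrame(rows, columns=["glycoform", "phosphosite", "corr_nat", "corr_tumor"])
        df["delta"] = df["corr_nat"] - df["corr_tumor"]
        return df

    def test_selection_rules(self):
        pairs = self._pairs(
            [
                ("g1", "p1", 0.8, 0.1),    # selected: floor and delta pass
                ("g2", "p2", 0.2, -0.3),   # rejected: NAT below floor
                ("g3", "p3", 0.9, 0.7),    # rejected: delta 0.2
            ]
        )
        out = rewired_pairs(pairs, delta_threshold=0.3)
        assert list(out["glycoform"]) == ["g1"]
        assert out["delta"].iloc[0] == pytest.approx(0.7)

    def test_sorted_by_delta_descending(self):
        pairs = self._pairs(
            [("g1", "p1", 0.8, 0.2), ("g2", "p2", 0.9, -0.1), ("g3", "p3", 0.7, 0.1)]
        )
        out = rewired_pairs(pairs)
        assert (out["delta"].diff().dropna() <= 0).all()


class TestHubCounts:
    def test_counts_and_conservation(self):
        sel = pd.DataFrame(
            {
                "glycoform": [
                    "P1_GX_10_N2H5F0S0G0",
                    "P2_GX_11_N2H5F0S0G0",
                    "P3_GY_12_N2H6F0S0G0",
                ],
                "phosphosite": ["PA_S1", "PA_S2", "PB_S3"],
            }
        )
        glyco, phospho = hub_counts(sel)
        assert glyco["GX"] == 2 and glyco["GY"] == 1
        assert phospho["PA"] == 2 and phospho["PB"] == 1
        assert glyco.sum() == phospho.sum() == len(sel)

    def test_empty_selection(self):
        glyco, phospho = hub_counts(pd.DataFrame(columns=["glycoform", "phosphosite"]))
        assert glyco.empty and phospho.empty


class TestEnzymePatterns:
    def test_planted_opposite_programs_recovered(self, rng):
        n_samples = 60
        cols = [f"T{i}" for i in range(n_samples)]
        driver = rng.standard_normal(n_samples)
        comps = ["N2H5F0S0G0", "N2H6F0S0G0", "N2H7F0S0G0",
                 "N4H5F1S2G0", "N4H6F1S2G0", "N5H6F1S3G0"]
        rows, index = [], []
        for i, comp in enumerate(comps):
            sign = 1.0 if i < 3 else -1.0
            for rep in range(3):
                rows.append(sign * driver + 0.2 * rng.standard_normal(n_samples))
                index.append(f"P{i}{rep}_G{i}{rep}_{10 + rep}_{comp}")
        glyco = pd.DataFrame(rows, index=index, columns=cols)
        enzymes = pd.DataFrame(
            np.vstack(
                [sign * driver + 0.1 * rng.standard_normal(n_samples) for sign in (1, 1, -1, -1)]
            ),
            index=["MGAT1", "MGAT5", "FUT8", "ST6GAL1"],
            columns=cols,
        )
        corr, labels = enzyme_glycan_patterns(glyco, enzymes, k=2)
        assert len(corr) == len(comps)  # one row per composition
        assert set(labels.unique()) == {"GC.1", "GC.2"}
        first = {labels[c] for c in comps[:3]}
        second = {labels[c] for c in comps[3:]}
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_correlations_bounded(self, rng):
        cols = [f"T{i}" for i in range(20)]
        glyco = pd.DataFrame(
            rng.standard_normal((4, 20)),
            index=[f"P{i}_G{i}_5_N2H{5 + i}F0S0G0" for i in range(4)],
            columns=cols,
        )
        enzymes = pd.DataFrame(rng.standard_normal((3, 20)), index=list("abc"), columns=cols)
        corr, _ = enzyme_glycan_patterns(glyco, enzymes)
        vals = corr.to_numpy(dtype=float)
        assert np.nanmax(np.abs(vals)) <= 1 + 1e-12
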