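"""Dichotomization rules, feature encoding, coevolution site statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from apogee import (
    DichotomizationRule,
    coevolution_site_stats,
    dichotomize_categorical,
    dichotomize_numeric,
    encode_features,
    significance_call,
)
from apogee.exceptions import UnmappedCategoryError, ValidationError
from apogee.features import (
    ColumnImputer,
    FeatureMatrix,
    decode_dichotomized,
    default_rules,
    load_rules,
)

CADD = DichotomizationRule("cadd_phred", "numeric_threshold", threshold=12.0)
COVEC = DichotomizationRule("covec_wmv", "numeric_threshold", threshold=0.0)


class TestNumericDichotomization:
    @pytest.mark.parametrize("x,rule,expected", [
        (12.4, CADD, "harmful"),           # exceeds the published cutoff of 12
        (12.0, CADD, "neutral"),           # boundary does not exceed
        (11.9, CADD, "neutral"),
        (None, CADD, None),
        (float("nan"), CADD, None),
        (float("inf"), CADD, None),        # non-finite treated as missing
        (0.5, COVEC, "harmful"),           # positive consensus score
        (0.0, COVEC, "neutral"),           # zero is not positive
        (-1.0, COVEC, "neutral"),
        (0.4312, DichotomizationRule("mtoolbox_ds", "numeric_threshold", threshold=0.4311),
         "harmful"),
    ])
    def test_strict_threshold(self, x, rule, expected):
        assert dichotomize_numeric(x, rule) == expected

    def test_less_direction(self):
        rule = DichotomizationRule("provean", "numeric_threshold",
                                   threshold=-2.5, direction="less")
        assert dichotomize_numeric(-3.0, rule) == "harmful"
        assert dichotomize_numeric(-2.5, rule) == "neutral"


class TestCategoricalDichotomization:
    def rules(self):
        return {r.name: r for r in default_rules()}

    def test_mutation_assessor_categories(self):
        r = self.rules()["mutation_assessor"]
        assert dichotomize_categorical("medium", r) == "harmful"
        assert dichotomize_categorical("high", r) == "harmful"
        assert dichotomize_categorical("low", r) == "neutral"
        assert dichotomize_categorical("neutral", r) == "neutral"

    def test_polyphen2_two_variants(self):
        rules = self.rules()
        assert dichotomize_categorical("possibly damaging", rules["polyphen2"]) == "neutral"
        assert dichotomize_categorical("possibly damaging", rules["polyphen2_b"]) == "harmful"
        for name in ("polyphen2", "polyphen2_b"):
            assert dichotomize_categorical("probably damaging", rules[name]) == "harmful"
            assert dichotomize_categorical("benign", rules[name]) == "neutral"

    def test_sift_tolerated(self):
        assert dichotomize_categorical("tolerated", self.rules()["sift"]) == "neutral"

    def test_missing_and_unknown(self):
        r = self.rules()["sift"]
        assert dichotomize_categorical(None, r) is None
        assert dichotomize_categorical(float("nan"), r) is None
        with pytest.raises(UnmappedCategoryError, match="sift.*bogus"):
            dichotomize_categorical("bogus", r)


class TestSignificanceCall:
    @pytest.mark.parametrize("p,fdr,expected", [
        (0.01, 0.1, "harmful"),
        (0.01, 0.5, "neutral"),   # FDR fails
        (0.05, 0.1, "neutral"),   # strict inequality on p
        (0.01, 0.2, "neutral"),   # strict inequality on FDR
        (None, 0.1, None),
        (0.01, None, None),
    ])
    def test_joint_rule(self, p, fdr, expected):
        assert significance_call(p, fdr) == expected

    def test_out_of_range_raises(self):
        with pytest.raises(ValidationError):
            significance_call(1.5, 0.1)
        with pytest.raises(ValidationError):
            significance_call(0.01, -0.2)


class TestEncodeFeatures:
    def test_mixed_table_encoding(self):
        raw = pd.DataFrame({
            "cadd_phred": [15.0, 8.0],
            "sift": ["deleterious", "tolerated"],
        })
        rules = [r for r in default_rules() if r.name == "sift"]
        fm = encode_features(raw, rules)
        assert fm.columns == ["cadd_phred", "sift"]
        assert fm.kinds == ["raw_numeric", "dichotomized"]
        np.testing.assert_array_equal(fm.values, [[15.0, 1.0], [8.0, 0.0]])

    def test_all_missing_column_dropped_with_log(self):
        raw = pd.DataFrame({"good": [1.0, 2.0], "empty": [np.nan, np.nan]})
        fm = encode_features(raw)
        assert fm.columns == ["good"]
        assert any("empty" in line for line in fm.provenance)

    def test_dichotomized_round_trip(self):
        calls = ["medium", "low", None, "high", "neutral"]
        rule = {r.name: r for r in default_rules()}["mutation_assessor"]
        raw = pd.DataFrame({"mutation_assessor": calls, "x": np.arange(5.0)})
        fm = encode_features(raw, [rule])
        col = fm.values[:, fm.columns.index("mutation_assessor")]
        decoded = decode_dichotomized(col)
        expected = [dichotomize_categorical(c, rule) for c in calls]
        assert decoded == expected

    def test_significance_pair_consumed(self):
        raw = pd.DataFrame({"vest_pvalue": [0.01, 0.5], "vest_fdr": [0.1, 0.1],
                            "x": [1.0, 2.0]})
        fm = encode_features(raw, default_rules())
        assert "vest" in fm.columns
        v = fm.values[:, fm.columns.index("vest")]
        np.testing.assert_array_equal(v, [1.0, 0.0])

    def test_column_permutation_commutes(self, rng):
        raw = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        perm = ["d", "a", "e", "c", "b"]
        fm1 = encode_features(raw)
        fm2 = encode_features(raw[perm])
        idx = [fm1.columns.index(c) for c in perm]
        np.testing.assert_array_equal(fm1.values[:, idx], fm2.values)

    def test_masked_cells_are_nan(self, rng):
        vals = rng.normal(size=(4, 2))
        mask = np.zeros((4, 2), bool)
        mask[1, 0] = True
        fm = FeatureMatrix(vals, mask, ["a", "b"], ["raw_numeric"] * 2)
        assert np.isnan(fm.values[1, 0])


class TestColumnImputer:
    def test_mean_for_numeric_zero_for_dichotomized(self):
        vals = np.array([[1.0, 1.0], [3.0, np.nan], [np.nan, 0.0]])
        fm = FeatureMatrix(vals, np.isnan(vals), ["num", "dich"],
                           ["raw_numeric", "dichotomized"])
        imp = ColumnImputer().fit(fm)
        out = imp.transform(fm.values)
        assert out[2, 0] == pytest.approx(2.0)   # column mean
        assert out[1, 1] == 0.0                  # neutral fill
        assert not np.isnan(out).any()

    def test_fit_restricted_to_training_rows(self):
        vals = np.array([[0.0], [0.0], [100.0], [np.nan]])
        fm = FeatureMatrix(vals, np.isnan(vals), ["x"], ["raw_numeric"])
        imp = ColumnImputer().fit(fm, rows=[0, 1])
        assert imp.transform(fm.values)[3, 0] == 0.0


class TestCoevolutionSiteStats:
    def test_hand_enumerated_three_site_example(self):
        m = np.array([[0.0, 7.0, 2.0],
                      [7.0, 0.0, 6.6],
                      [2.0, 6.6, 0.0]])
        out = coevolution_site_stats(m, z_cut=6.5)
        np.testing.assert_allclose(out.coevolving_frequency, [0.5, 1.0, 0.5])
        np.testing.assert_allclose(out.mean_z, [7.0, 6.8, 6.6])

    def test_all_below_cut(self):
        m = np.full((4, 4), 1.0)
        np.fill_diagonal(m, 0.0)
        out = coevolution_site_stats(m)
        assert (out.coevolving_frequency == 0).all()
        assert out.mean_z.isna().all()

    def test_boundary_excluded(self):
        m = np.array([[0.0, 6.5], [6.5, 0.0]])
        out = coevolution_site_stats(m)
        assert (out.coevolving_frequency == 0).all()

    def test_asymmetry_rejected(self):
        m = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValidationError, match="symmetric"):
            coevolution_site_stats(m)

    def test_single_hot_pair_touches_exactly_two_sites(self, rng):
        for _ in range(5):
            L = int(rng.integers(3, 9))
            m = np.minimum(rng.normal(0, 2, (L, L)), 6.0)
            m = (m + m.T) / 2
            i, j = rng.choice(L, 2, replace=False)
            m[i, j] = m[j, i] = 9.0
            np.fill_diagonal(m, 0.0)
            out = coevolution_site_stats(m)
            assert (out.coevolving_frequency > 0).sum() == 2
            defined = out.mean_z.dropna()
            assert (defined > 6.5).all()

    @given(st.integers(2, 8), st.integers(0, 1000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_frequency_bounds_and_mean_above_cut(self, L, seed):
        r = np.random.default_rng(seed)
        m = r.normal(0, 4, (L, L))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        out = coevolution_site_stats(m)
        assert ((out.coevolving_frequency >= 0) & (out.coevolving_frequency <= 1)).all()
        assert (out.mean_z.dropna() > 6.5).all()


def test_load_rules_yaml_and_json(tmp_path):
    ypath = tmp_path / "rules.yaml"
    ypath.write_text("- name: foo\n  kind: numeric_threshold\n  threshold: 1.5\n")
    (rule,) = load_rules(ypath)
    assert rule.threshold == 1.5
    jpath = tmp_path / "rules.json"
    jpath.write_text('[{"name": "bar", "kind": "numeric_threshold", "threshold": 2.0}]')
    (rule,) = load_rules(jpath)
    assert rule.name == "bar"
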