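"""Growth quantification, statistics, classification, multilinear model."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from singlechan.gatingsim import GrowthModel, default_panel
from singlechan.growthcorr import (
    classify_vs_wt,
    decorrelation_curve,
    fold_change,
    fold_change_summary,
    multilinear_r2,
    pearson_r,
    ttest_vs_wt,
)


def growth_table(rows):
    return pd.DataFrame(rows, columns=["genotype", "replicate", "time_h", "od600"])


def r2_oracle(y, x_cols):
    """Independent normal-equations R^2 for y on [1, x_cols...]."""
    x = np.column_stack([np.ones_like(y)] + list(x_cols))
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))


class TestFoldChange:
    def test_simple_fold(self):
        t = growth_table([("WT", 1, 0.0, 0.1), ("WT", 1, 24.0, 0.8)])
        mean, sd, n = fold_change(t, "WT", 24.0)
        assert mean == pytest.approx(8.0)
        assert n == 1

    def test_no_growth_gives_unity(self):
        t = growth_table([("WT", 1, 0.0, 0.1), ("WT", 1, 24.0, 0.1)])
        assert fold_change(t, "WT", 24.0)[0] == pytest.approx(1.0)

    def test_replicate_statistics_hand_formula(self):
        rows = []
        for rep, fold in enumerate([8.0, 9.0, 10.0], start=1):
            rows += [("WT", rep, 0.0, 0.1), ("WT", rep, 48.0, 0.1 * fold)]
        mean, sd, n = fold_change(growth_table(rows), "WT", 48.0)
        assert mean == pytest.approx(9.0)
        assert sd == pytest.approx(1.0)
        assert n == 3

    def test_missing_time_zero_names_replicate(self):
        t = growth_table([("WT", 1, 0.0, 0.1), ("WT", 1, 24.0, 0.5),
                          ("WT", 2, 24.0, 0.6)])
        with pytest.raises(ValueError, match="replicate 2"):
            fold_change(t, "WT", 24.0)

    def test_summary_covers_genotypes_and_times(self):
        rows = []
        for g, fold in (("WT", 5.0), ("M", 2.0)):
            for rep in (1, 2):
                rows += [(g, rep, 0.0, 0.1), (g, rep, 24.0, 0.05 * fold),
                         (g, rep, 48.0, 0.1 * fold)]
        folds = fold_change_summary(growth_table(rows))
        assert folds.at("WT", 48.0) == pytest.approx(5.0)
        assert folds.at("M", 24.0) == pytest.approx(1.0)


class TestTTest:
    def test_identical_groups(self):
        p, flag = ttest_vs_wt([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
        assert p == pytest.approx(1.0)
        assert flag is False

    def test_matches_closed_form_oracle(self):
        a = np.array([1.0, 1.1, 0.9])
        b = np.array([5.0, 5.1, 4.9])
        p, flag = ttest_vs_wt(a, b)
        # independent oracle: pooled-variance t and Student-t tail probability
        n1, n2 = a.size, b.size
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
        p_oracle = special.betainc(df / 2, 0.5, df / (df + t * t))
        assert p == pytest.approx(p_oracle, rel=1e-8)
        assert flag is True

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            ttest_vs_wt([1.0], [1.0, 2.0])

    def test_welch_differs_under_unequal_variance(self):
        a = [1.0, 1.2, 0.8, 1.1]
        b = [5.0, 9.0, 1.0, 6.0]
        p_student, _ = ttest_vs_wt(a, b, welch=False)
        p_welch, _ = ttest_vs_wt(a, b, welch=True)
        assert p_student != p_welch

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 2**20))
    def test_symmetry_under_group_swap(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(1.0, 0.3, 4)
        b = rng.normal(2.0, 0.5, 5)
        assert ttest_vs_wt(a, b)[0] == pytest.approx(ttest_vs_wt(b, a)[0])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # x=(1,2,3), y=(1,2,2): r = 1/sqrt(4/3) = sqrt(3)/2
        assert pearson_r([1, 2, 3], [1, 2, 2]) == pytest.approx(
            math.sqrt(3) / 2, rel=1e-9
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        b=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        a=st.floats(-5, 5),
        seed=st.integers(0, 2**20),
    )
    def test_affine_relation_gives_sign_of_slope(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 10)
        assert pearson_r(x, a + b * x) == pytest.approx(np.sign(b), abs=1e-9)


class TestClassification:
    def test_concordant_and_discordant(self):
        features = {"WT": 1.0, "up": 2.0, "down": 2.0}
        growth = {"WT": 4.0, "up": 8.0, "down": 2.0}
        outcomes, counts = classify_vs_wt(features, growth, "WT")
        calls = {o.genotype: o.call for o in outcomes}
        assert calls == {"up": "concordant", "down": "discordant"}
        assert counts == {"concordant": 1, "discordant": 1, "tie-excluded": 0}

    def test_tie_excluded_with_warning(self):
        features = {"WT": 1.0, "same": 1.0}
        growth = {"WT": 4.0, "same": 8.0}
        with pytest.warns(UserWarning, match="tie"):
            outcomes, counts = classify_vs_wt(features, growth, "WT")
        assert outcomes[0].call == "tie-excluded"
        assert counts["tie-excluded"] == 1

    def test_currents_compared_as_absolute_values(self):
        # more-negative current = larger inward current = above WT
        features = {"WT": -1.0, "big": -2.0}
        growth = {"WT": 4.0, "big": 8.0}
        outcomes, _ = classify_vs_wt(features, growth, "WT", feature="i_meas")
        assert outcomes[0].feature_relation == "above_wt"
        assert outcomes[0].call == "concordant"

    def test_missing_wt_rejected(self):
        with pytest.raises(ValueError, match="WT"):
            classify_vs_wt({"a": 1.0}, {"a": 1.0}, "WT")

    def test_invariant_under_monotone_feature_transform(self):
        rng = np.random.default_rng(0)
        features = {f"g{k}": float(v) for k, v in enumerate(rng.uniform(0.1, 5, 12))}
        features["WT"] = 1.3
        growth = {g: float(rng.uniform(1, 9)) for g in features}
        base, _ = classify_vs_wt(features, growth, "WT", feature="po")
        for transform in (np.sqrt, np.log, lambda v: 3 * v + 2, lambda v: v**3):
            warped = {g: float(transform(v)) for g, v in features.items()}
            out, _ = classify_vs_wt(warped, growth, "WT", feature="po")
            assert [o.call for o in out] == [o.call for o in base]

    def test_panel_fully_concordant_without_hidden_variance(self):
        # expression 1 and zero noise: growth is monotone in |activity|
        panel = default_panel()
        gm = GrowthModel(noise_sd=0.0)
        features, growth = {}, {}
        for entry in panel:
            label = entry.model.genotype_label
            act = entry.model.truth_activity(-140.0)
            features[label] = act
            growth[label] = gm.od_at(gm.rate_for(act), 48.0) / gm.od0
        outcomes, counts = classify_vs_wt(features, growth, "WT",
                                          feature="activity_meas")
        assert counts["discordant"] == 0
        assert counts["concordant"] == len(outcomes) - counts["tie-excluded"]


class TestMultilinear:
    def test_exact_linear_relation_gives_r2_one(self):
        rng = np.random.default_rng(2)
        i = rng.uniform(0, 10, 12)
        po = rng.uniform(0, 0.5, 12)
        growth = 2.0 + 0.5 * i - po
        fit = multilinear_r2(growth, i, po)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(2.0, abs=1e-8)
        assert fit.beta_i == pytest.approx(0.5, abs=1e-8)
        assert fit.beta_po == pytest.approx(-1.0, abs=1e-8)
        assert fit.beta_product == pytest.approx(0.0, abs=1e-8)

    def test_constant_growth_gives_r2_zero(self):
        rng = np.random.default_rng(3)
        fit = multilinear_r2(np.full(8, 3.3), rng.uniform(0, 1, 8),
                             rng.uniform(0, 1, 8))
        assert fit.r2 == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        i = rng.uniform(0, 5, 10)
        po = rng.uniform(0, 0.5, 10)
        growth = 1.0 + 0.3 * i + 2.0 * po + rng.normal(0, 0.5, 10)
        fit = multilinear_r2(growth, i, po)
        assert fit.r2 == pytest.approx(r2_oracle(growth, [i, po, i * po]), abs=1e-8)

    def test_nested_model_monotonicity(self):
        rng = np.random.default_rng(5)
        i = rng.uniform(0, 5, 15)
        po = rng.uniform(0, 0.5, 15)
        growth = 1.0 + 0.3 * i + rng.normal(0, 1.0, 15)
        full = multilinear_r2(growth, i, po).r2
        for sub in ([i], [po], [i, po], [i * po]):
            assert full >= r2_oracle(growth, sub) - 1e-12

    def test_collinear_regressor_named(self):
        rng = np.random.default_rng(6)
        i = rng.uniform(0, 5, 10)
        with pytest.raises(ValueError, match="collinear"):
            multilinear_r2(rng.uniform(0, 1, 10), i, 2.0 * i)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n >= 5"):
            multilinear_r2([1, 2, 3], [1, 2, 3], [1, 2, 3])


class TestDecorrelation:
    def test_hidden_expression_variance_destroys_correlation(self):
        panel = default_panel()
        acts = {e.model.genotype_label: e.model.truth_activity(-140.0)
                for e in panel}
        med = decorrelation_curve(acts, GrowthModel(), [0.0, 1.0, 4.0],
                                  n_seeds=20, seed=11)
        assert med[0] > med[1] > med[2]
        assert med[0] > 0.9
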