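"""Logit pipeline, mixed models, contrasts and percent-of-control."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from patchdose.simulate import ExperimentDesign, simulate_experiment
from patchdose.stats import (
    back_transformed_means,
    fit_mixed_model,
    h2s_contrasts,
    inverse_logit,
    linear_contrasts,
    logit,
    percent_of_control,
    star_code,
    transform_table,
)


class TestLogit:
    def test_symmetry_point(self):
        assert logit(0.5) == 0.0

    def test_reference_value(self):
        assert logit(0.0887) == pytest.approx(-2.330, abs=1e-3)

    @pytest.mark.parametrize("p", [0.01, 0.5, 0.99])
    def test_roundtrip(self, p):
        assert inverse_logit(logit(p)) == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.1])
    def test_domain_error_no_clamping(self, p):
        with pytest.raises(ValueError):
            logit(p)


class TestTransformTable:
    def test_log_dwell_and_flags(self):
        tab = pd.DataFrame(
            {
                "patch_id": ["a", "b", "c"],
                "po": [0.1, 1.0, 0.2],
                "dwell_ms": [1.0, 2.0, 3.0],
            }
        )
        with pytest.warns(UserWarning, match="untransformable"):
            out = transform_table(tab)
        assert out.loc[0, "log_dwell"] == 0.0
        assert out["untransformable"].tolist() == [False, True, False]
        assert len(out) == 3  # flagged, never dropped
        assert math.isnan(out.loc[1, "logit_po"])

    def test_back_transformed_means_convention(self):
        des = ExperimentDesign(conditions=("ATP1",), n_patches=30)
        tab = simulate_experiment(des, seed=8)
        bt = back_transformed_means(tab, response="logit-po")
        tt = transform_table(tab)
        for _, row in bt.iterrows():
            grp = tt[(tt.condition == row.condition) & (tt.phase == row.phase)]
            assert row["mean"] == pytest.approx(
                inverse_logit(grp["logit_po"].mean()), rel=1e-12
            )
            assert row["lo"] <= row["mean"] <= row["hi"]


class TestMixedModel:
    def test_contrast_equals_paired_t(self):
        des = ExperimentDesign(conditions=("ATP1",), n_patches=12)
        tab = simulate_experiment(des, seed=5)
        fit = fit_mixed_model(tab, response="logit-po", fixed=("phase",))
        res = linear_contrasts(fit, h2s_contrasts(fit), adjust="none")[0]
        tt = transform_table(tab)
        piv = tt.pivot_table(index="patch_id", columns="phase", values="logit_po")
        d = piv["H2S"] - piv["control"]
        t_paired = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert res.statistic == pytest.approx(t_paired, abs=1e-6)
        assert res.estimate == pytest.approx(d.mean(), abs=1e-6)

    def test_zero_patch_variance_reduces_to_ols(self):
        # identical patches: random-intercept SD collapses to the boundary
        des = ExperimentDesign(
            conditions=("ATP1",), n_patches=10, patch_sd=0.0, residual_sd=0.3
        )
        tab = simulate_experiment(des, seed=21)
        fit = fit_mixed_model(tab, response="logit-po", fixed=("phase",))
        assert fit.random_intercept_sd < 0.15
        tt = transform_table(tab)
        means = tt.groupby("phase")["logit_po"].mean()
        ols_effect = means["H2S"] - means["control"]
        res = linear_contrasts(fit, h2s_contrasts(fit), adjust="none")[0]
        assert res.estimate == pytest.approx(ols_effect, abs=1e-6)

    def test_singular_design_names_term(self):
        des = ExperimentDesign(conditions=("ATP1",), n_patches=6)
        tab = simulate_experiment(des, seed=3)
        tab["condition"] = tab["phase"]  # condition aliases phase -> singular
        with pytest.raises(ValueError, match="singular"):
            fit_mixed_model(tab, response="logit-po")

    def test_needs_two_patches(self):
        des = ExperimentDesign(conditions=("ATP1",), n_patches=1)
        tab = simulate_experiment(des, seed=3)
        with pytest.raises(ValueError):
            fit_mixed_model(tab, response="logit-po", fixed=("phase",))

    def test_logit_reduces_heteroscedasticity(self):
        # variance ratio across condition x phase groups shrinks after logit
        # for designs spanning Po ~0.015-0.4 in >=90% of replicates
        wins = 0
        reps = 20
        for r in range(reps):
            des = ExperimentDesign(
                conditions=("ATP0", "ATP1", "OA"), n_patches=8
            )
            tab = simulate_experiment(des, seed=40_000 + r)
            tt = transform_table(tab)
            g = tt.groupby(["condition", "phase"])
            before = g["po"].var()
            after = g["logit_po"].var()
            wins += (after.max() / after.min()) <= (before.max() / before.min())
        assert wins >= 0.9 * reps


@pytest.fixture(scope="module")
def fitted():
    des = ExperimentDesign(conditions=("ATP0", "ATP1", "OA"), n_patches=8)
    tab = simulate_experiment(des, seed=17)
    return fit_mixed_model(tab)


class TestContrasts:
    def test_family_of_one_unadjusted(self, fitted):
        cons = h2s_contrasts(fitted)
        label = next(iter(cons))
        single = linear_contrasts(fitted, {label: cons[label]}, adjust="max-t")[0]
        assert single.p_adjusted == pytest.approx(single.p_unadjusted, rel=1e-9)

    def test_duplicated_contrasts_identical(self, fitted):
        cons = h2s_contrasts(fitted)
        label = next(iter(cons))
        dup = {"a": cons[label], "b": cons[label]}
        ra, rb = linear_contrasts(fitted, dup, adjust="max-t", seed=0)
        assert ra.statistic == rb.statistic
        assert ra.p_adjusted == rb.p_adjusted

    def test_adjustment_never_more_significant(self, fitted):
        cons = h2s_contrasts(fitted)
        for method in ("max-t", "holm"):
            for r in linear_contrasts(fitted, cons, adjust=method, seed=0):
                assert r.p_adjusted >= r.p_unadjusted - 1e-12
                assert 0.0 <= r.p_adjusted <= 1.0

    def test_zero_contrast_rejected(self, fitted):
        with pytest.raises(ValueError):
            linear_contrasts(fitted, {"null": np.zeros(len(fitted.exog_names))})

    def test_holm_deterministic_fallback(self, fitted):
        cons = h2s_contrasts(fitted)
        a = linear_contrasts(fitted, cons, adjust="holm")
        b = linear_contrasts(fitted, cons, adjust="holm")
        assert [r.p_adjusted for r in a] == [r.p_adjusted for r in b]


class TestStarCode:
    @pytest.mark.parametrize(
        "p, stars",
        [
            (0.5, ""),
            (0.06, ""),
            (0.05, ""),       # boundary: less-significant category
            (0.03, "*"),
            (0.01, "**"),
            (0.005, "**"),
            (0.001, "***"),
            (0.0005, "***"),
        ],
    )
    def test_coding(self, p, stars):
        assert star_code(p) == stars

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            star_code(1.5)


class TestPercentOfControl:
    def test_identity_is_100_percent(self):
        tab = pd.DataFrame(
            {
                "patch_id": ["a", "a", "b", "b"],
                "condition": ["ATP1"] * 4,
                "phase": ["control", "H2S"] * 2,
                "po": [0.1, 0.1, 0.2, 0.2],
            }
        )
        out = percent_of_control(tab)
        assert out.loc[0, "mean_percent"] == pytest.approx(100.0)
        assert out.loc[0, "sem_percent"] == pytest.approx(0.0)

    def test_hand_computed_ratios(self):
        tab = pd.DataFrame(
            {
                "patch_id": ["a", "a", "b", "b"],
                "condition": ["ATP1"] * 4,
                "phase": ["control", "H2S"] * 2,
                "po": [0.1, 0.15, 0.1, 0.25],  # ratios 1.5 and 2.5
            }
        )
        out = percent_of_control(tab)
        assert out.loc[0, "mean_percent"] == pytest.approx(200.0)
        assert out.loc[0, "sem_percent"] == pytest.approx(50.0)

    def test_scale_invariance(self):
        des = ExperimentDesign(conditions=("ATP1",), n_patches=8)
        tab = simulate_experiment(des, seed=9)
        a = percent_of_control(tab)
        tab2 = tab.copy()
        tab2["po"] = tab2["po"] * 0.37
        b = percent_of_control(tab2)
        assert a["mean_percent"].iloc[0] == pytest.approx(b["mean_percent"].iloc[0])

    def test_unpaired_patch_excluded_with_warning(self):
        tab = pd.DataFrame(
            {
                "patch_id": ["a", "a", "b"],
                "condition": ["ATP1"] * 3,
                "phase": ["control", "H2S", "control"],
                "po": [0.1, 0.2, 0.3],
            }
        )
        with pytest.warns(UserWarning, match="unpaired"):
            out = percent_of_control(tab)
        assert out.loc[0, "n_patches"] == 1

    def test_mean_ratio_exceeds_ratio_of_means_under_negative_correlation(self):
        # Jensen-gap: when low-Po patches show large folds, the per-patch
        # ratio convention exceeds the ratio of group means
        rng = np.random.default_rng(4)
        rows = []
        for i in range(200):
            control = rng.uniform(0.02, 0.3)
            fold = 1.0 + 0.5 / control * 0.1  # negatively correlated fold
            rows.append(("p%d" % i, "control", control))
            rows.append(("p%d" % i, "H2S", control * fold))
        tab = pd.DataFrame(rows, columns=["patch_id", "phase", "po"])
        tab["condition"] = "ATP1"
        out = percent_of_control(tab)
        piv = tab.pivot_table(index="patch_id", columns="phase", values="po")
        ratio_of_means = 100.0 * piv["H2S"].mean() / piv["control"].mean()
        assert out.loc[0, "mean_percent"] > ratio_of_means
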