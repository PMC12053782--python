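"""Study-level models, contrasts, BH correction, and the AIC screen."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dreamwake as dw
from dreamwake.review_stats import (
    auxiliary_covariate_model,
    covariate_tests,
    stack_observations,
)
from dreamwake.study_corpus import StudyTable


def bh_step_up_oracle(p):
    """Literal step-up definition: adj_(k) = min_{j>=k} m*p_(j)/j, clipped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = m * p[order] / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def ols_normal_equations(X, y):
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestComposition:
    def test_proportions_sum_to_one(self, table1):
        for factor in ("method", "question", "setting"):
            comp = dw.composition_stats(table1, factor)
            assert sum(comp.proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_level_table(self):
        frame = pd.DataFrame({"study_id": ["A", "B"], "question": ["mind", "mind"]})
        comp = dw.composition_stats(StudyTable(frame=frame), "question")
        assert comp.proportions == {"mind": 1.0}

    def test_unknown_factor(self, table1):
        with pytest.raises(ValueError):
            dw.composition_stats(table1, "weather")

    def test_all_missing_errors(self):
        frame = pd.DataFrame({"study_id": ["A"], "question": ["missing"]})
        with pytest.raises(ValueError, match="missing"):
            dw.composition_stats(StudyTable(frame=frame), "question")


class TestCondenseNrem:
    def test_single_substage_stacks_as_nrem(self):
        assert dw.condense_nrem({"N2": 0.5, "REM": 0.8}) == [("NREM", 0.5), ("REM", 0.8)]

    def test_equal_weight_mean(self):
        out = dw.condense_nrem({"N1": 1.0, "N2": 0.0}, how="mean")
        assert out == {"NREM": 0.5}

    def test_multiple_nrem_observations_retained_when_stacked(self):
        stacked = dw.condense_nrem({"NREM": 0.6, "N2": 0.5})
        assert sorted(v for g, v in stacked if g == "NREM") == [0.5, 0.6]

    def test_stacked_and_mean_runs_agree_in_contrast_sign(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(30):
            rates = {"N2": 0.5 + 0.02 * rng.normal(), "N3": 0.5 + 0.02 * rng.normal(),
                     "REM": 0.8 + 0.02 * rng.normal()}
            rows.append({"study_id": f"S{i}",
                         **{f"rate_{s}_with_recall": v for s, v in rates.items()}})
        table = StudyTable(frame=pd.DataFrame(rows))
        signs = {}
        for condense in ("stack", "mean"):
            obs = stack_observations(table, "with_recall", condense=condense)
            fit = dw.fit_linear_model(obs, ["stage"])
            (c,) = [r for r in dw.emm_contrasts(fit, "stage") if r.label == "NREM - REM"]
            signs[condense] = math.copysign(1, c.estimate)
        assert signs["stack"] == signs["mean"] == -1

    def test_empty_stage_set(self):
        with pytest.raises(ValueError):
            dw.condense_nrem({})


class TestFitLinearModel:
    def test_noiseless_interpolation(self):
        rows = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        rows["y"] = 0.5 + 0.2 * rows["x"]
        fit = dw.fit_linear_model(rows, ["x"])
        assert fit.coefficients["Intercept"] == pytest.approx(0.5, abs=1e-12)
        assert fit.coefficients["x"] == pytest.approx(0.2, abs=1e-12)

    def test_intercept_only_is_mean(self):
        rows = pd.DataFrame({"y": [0.1, 0.4, 0.7]})
        fit = dw.fit_linear_model(rows, [])
        assert fit.coefficients["Intercept"] == pytest.approx(0.4)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        X = rng.normal(size=(n, 3))
        y = rng.normal(size=n)
        rows = pd.DataFrame(X, columns=["x1", "x2", "x3"])
        rows["y"] = y
        fit = dw.fit_linear_model(rows, ["x1", "x2", "x3"])
        beta = ols_normal_equations(np.column_stack([np.ones(n), X]), y)
        assert np.allclose(fit.coefficients.to_numpy(), beta, atol=1e-10)

    def test_rank_deficient_design_errors(self):
        rows = pd.DataFrame({"x1": [1.0, 2.0, 3.0, 4.0]})
        rows["x2"] = 2 * rows["x1"]
        rows["y"] = rows["x1"]
        with pytest.raises(ValueError, match="aliased|rank"):
            dw.fit_linear_model(rows, ["x1", "x2"])

    def test_aic_of_nested_models_tracks_likelihood_ratio(self):
        rng = np.random.default_rng(3)
        rows = pd.DataFrame({"x": rng.normal(size=50), "z": rng.normal(size=50)})
        rows["y"] = 0.3 * rows["x"] + rng.normal(scale=0.5, size=50)
        small = dw.fit_linear_model(rows, ["x"])
        big = dw.fit_linear_model(rows, ["x", "z"])
        lr = 2 * (big.result.llf - small.result.llf)
        assert big.aic - small.aic == pytest.approx(2 - lr, abs=1e-8)


class TestEmmContrasts:
    def test_balanced_design_equals_group_mean_difference(self):
        rows = pd.DataFrame(
            {"g": ["A"] * 4 + ["B"] * 4, "y": [0.3, 0.31, 0.29, 0.3, 0.7, 0.71, 0.69, 0.7]}
        )
        fit = dw.fit_linear_model(rows, ["g"])
        (c,) = dw.emm_contrasts(fit, "g")
        assert c.label == "A - B"
        assert c.estimate == pytest.approx(
            rows[rows.g == "A"].y.mean() - rows[rows.g == "B"].y.mean(), abs=1e-12
        )

    def test_unbalanced_two_factor_design_averages_levels_equally(self):
        # EMMs weight each level of the other factor equally, so the
        # contrast equals the mean of the within-level differences
        rows = pd.DataFrame(
            {
                "g": ["A", "A", "A", "B", "A", "B", "B", "B", "B"],
                "h": ["u", "u", "u", "u", "v", "v", "v", "v", "v"],
                "y": [0.2, 0.22, 0.21, 0.5, 0.4, 0.72, 0.7, 0.71, 0.69],
            }
        )
        fit = dw.fit_linear_model(rows, ["g", "h"])
        (c,) = dw.emm_contrasts(fit, "g")
        assert c.label == "A - B"
        # additive model: estimate is the g coefficient regardless of h mix
        assert c.estimate == pytest.approx(-fit.coefficients["C(g)[T.B]"], abs=1e-10)

    def test_d_times_residual_sd_is_estimate(self):
        rng = np.random.default_rng(9)
        rows = pd.DataFrame({"g": list("ABAB") * 5, "y": rng.random(20)})
        fit = dw.fit_linear_model(rows, ["g"])
        for c in dw.emm_contrasts(fit, "g"):
            assert c.d * fit.residual_sd == pytest.approx(c.estimate, abs=1e-12)

    def test_absent_factor(self):
        rows = pd.DataFrame({"g": list("AB") * 3, "y": np.linspace(0, 1, 6)})
        fit = dw.fit_linear_model(rows, ["g"])
        with pytest.raises(ValueError):
            dw.emm_contrasts(fit, "h")


class TestBhAdjust:
    def test_closed_form_triple(self):
        assert np.allclose(dw.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_test_unchanged(self):
        assert dw.bh_adjust([0.04]) == pytest.approx([0.04])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    @settings(max_examples=200, deadline=None)
    def test_equals_brute_force_step_up(self, p):
        assert np.allclose(dw.bh_adjust(p), bh_step_up_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=10), st.randoms())
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance_and_monotonicity(self, p, rand):
        adj = dw.bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        perm = list(range(len(p)))
        rand.shuffle(perm)
        adj_perm = dw.bh_adjust([p[i] for i in perm])
        assert np.allclose(adj_perm, adj[perm], atol=1e-12)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            dw.bh_adjust([0.5, 1.2])


class TestEffectSizeCategory:
    @pytest.mark.parametrize(
        "d, expected",
        [
            (0.594, "medium"),
            (0.16, "negligible"),
            (-0.8, "large"),
            (0.2, "small"),
            (0.5, "medium"),
            (-0.19, "negligible"),
            (1.43, "large"),
        ],
    )
    def test_thresholds(self, d, expected):
        assert dw.effect_size_category(d) == expected

    def test_non_finite(self):
        with pytest.raises(ValueError):
            dw.effect_size_category(float("nan"))


def welch_oracle(a, b):
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    t = (np.mean(a) - np.mean(b)) / math.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    return t, df


class TestN2N3:
    def _table(self, n2, n3):
        rows = []
        for i, v in enumerate(n2):
            rows.append({"study_id": f"A{i}", "rate_N2_with_recall": v})
        for i, v in enumerate(n3):
            rows.append({"study_id": f"B{i}", "rate_N3_with_recall": v})
        return StudyTable(frame=pd.DataFrame(rows))

    def test_identical_samples_give_t_zero_p_one(self):
        table = self._table([0.4, 0.5, 0.6], [0.4, 0.5, 0.6])
        res = dw.n2_n3_test(table, "with_recall")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_welch_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random(6), rng.random(9)
        res = dw.n2_n3_test(self._table(a, b), "with_recall")
        t, df = welch_oracle(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            dw.n2_n3_test(self._table([0.5], [0.4, 0.6]), "with_recall")


class TestStepwiseAic:
    def _rows(self, interaction, seed=21, n=40):
        rng = np.random.default_rng(seed)
        stage = rng.choice(["NREM", "REM"], size=n)
        method = rng.choice(["alarm", "name"], size=n)
        y = (
            0.5
            + 0.2 * (stage == "REM")
            + 0.05 * (method == "name")
            + interaction * ((stage == "REM") & (method == "name"))
            + rng.normal(scale=0.05, size=n)
        )
        return pd.DataFrame({"stage": stage, "method": method, "y": y})

    def test_pure_noise_candidates_leave_base_model(self):
        rows = self._rows(interaction=0.0, seed=2)
        base = dw.fit_linear_model(rows, ["stage", "method"])
        out = dw.stepwise_aic_interactions(base, ["stage:method"])
        assert out.terms == base.terms

    def test_true_interaction_is_selected(self):
        rows = self._rows(interaction=0.3, seed=2)
        base = dw.fit_linear_model(rows, ["stage", "method"])
        out = dw.stepwise_aic_interactions(base, ["stage:method"])
        assert "stage:method" in out.terms

    def test_greedy_matches_exhaustive_search_small(self):
        rng = np.random.default_rng(99)
        rows = self._rows(interaction=0.3, seed=8)
        rows["question"] = rng.choice(["mind", "dream"], size=len(rows))
        base = dw.fit_linear_model(rows, ["stage", "method", "question"])
        candidates = ["stage:method", "stage:question"]
        out = dw.stepwise_aic_interactions(base, candidates)
        best_aic = math.inf
        for mask in range(4):
            subset = [c for i, c in enumerate(candidates) if mask & (1 << i)]
            fit = dw.fit_linear_model(rows, list(base.terms) + subset)
            best_aic = min(best_aic, fit.aic)
        assert out.aic == pytest.approx(best_aic, abs=1e-9)

    def test_main_effects_always_retained(self):
        rows = self._rows(interaction=0.3)
        base = dw.fit_linear_model(rows, ["stage", "method"])
        out = dw.stepwise_aic_interactions(base, ["stage:method"])
        assert set(base.terms) <= set(out.terms)

    def test_candidate_without_main_effect_rejected(self):
        rows = self._rows(interaction=0.0)
        base = dw.fit_linear_model(rows, ["stage"])
        with pytest.raises(ValueError, match="method"):
            dw.stepwise_aic_interactions(base, ["stage:method"])


class TestAuxiliaryCovariate:
    def test_constant_covariate_errors(self):
        frame = pd.DataFrame(
            {
                "study_id": [f"S{i}" for i in range(6)],
                "year": [2010] * 6,
                "rate_NREM_with_recall": np.linspace(0.4, 0.7, 6),
            }
        )
        with pytest.raises(ValueError, match="constant"):
            auxiliary_covariate_model(StudyTable(frame=frame), "year", "with_recall")

    def test_null_slope_gives_uniform_p(self):
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            frame = pd.DataFrame(
                {
                    "study_id": [f"S{i}" for i in range(20)],
                    "year": np.arange(2000, 2020),
                    "rate_NREM_with_recall": np.clip(
                        0.6 + rng.normal(scale=0.1, size=20), 0, 1
                    ),
                }
            )
            res = auxiliary_covariate_model(StudyTable(frame=frame), "year", "with_recall")
            ps.append(res.p_raw)
        # under the null the p-values should look uniform, not clustered small
        assert 0.25 < np.mean(ps) < 0.75
        assert min(ps) > 1e-4

    def test_gentle_effect_recovery(self):
        rng = np.random.default_rng(14)
        gentle = rng.choice(["yes", "no"], size=30)
        frame = pd.DataFrame(
            {
                "study_id": [f"S{i}" for i in range(30)],
                "gentle": gentle,
                "rate_NREM_with_recall": np.clip(
                    0.55 + 0.07 * (gentle == "yes") + rng.normal(scale=0.01, size=30),
                    0,
                    1,
                ),
            }
        )
        res = auxiliary_covariate_model(StudyTable(frame=frame), "gentle", "with_recall")
        diff = res.estimate if res.label == "yes - no" else -res.estimate
        assert diff == pytest.approx(0.07, abs=0.01)


def test_review_model_family_is_bh_corrected():
    table, _ = dw.generate_study_table({("method", "name"): 0.10}, 0.05, 40, seed=2)
    fit, family = dw.review_model(table, "with_recall")
    p_raw = [r.p_raw for r in family]
    p_cor = [r.p_cor for r in family]
    assert np.allclose(p_cor, dw.bh_adjust(p_raw))
    assert all(c >= r - 1e-15 for r, c in zip(p_raw, p_cor))


def test_covariate_d_uses_t_conversion():
    rng = np.random.default_rng(4)
    rows = pd.DataFrame({"x": rng.normal(size=30)})
    rows["y"] = 0.1 * rows["x"] + rng.normal(scale=0.2, size=30)
    fit = dw.fit_linear_model(rows, ["x"])
    (res,) = covariate_tests(fit)
    assert res.d == pytest.approx(2 * res.statistic / math.sqrt(fit.residual_df))
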