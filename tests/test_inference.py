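"""Contrasts, condition screen, cascade models, dropout ANOVA and power."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import jointgaze as jg
from jointgaze.inference import (ModelSpec, anova_power, build_design,
                                 cascade_lm, condition_screen, dropout_anova,
                                 fit_mixed, marginal_contrasts,
                                 marginal_means)


def feature_frame(seed=0, n_p=60, rates=(0.25, 0.10), sd_p=0.0):
    """Per-trial table with two groups at fixed response rates."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_p):
        group = "A" if i < n_p // 2 else "B"
        p = rates[0] if group == "A" else rates[1]
        u = rng.normal(0, sd_p)
        for tr in range(16):
            eta = np.log(p / (1 - p)) + u
            rows.append({"participant": f"p{i}", "group": group,
                         "timepoint": "BL", "trial": tr + 1,
                         "rja": float(rng.random() < expit(eta))})
    return pd.DataFrame(rows)


class TestDesign:
    def test_factor_and_interaction_columns(self):
        data = pd.DataFrame({"group": ["A", "B", "A", "B"],
                             "timepoint": ["BL", "BL", "FU", "FU"],
                             "age": [1.0, 2.0, 3.0, 4.0]})
        X, names = build_design(data, factors=("group", "timepoint"),
                                interactions=(("group", "timepoint"),),
                                covariates=("age",))
        assert names == ["Intercept", "group[B]", "timepoint[FU]",
                         "group[B]:timepoint[FU]", "age"]
        np.testing.assert_array_equal(X[:, 1], [0, 1, 0, 1])
        np.testing.assert_array_equal(X[:, 3], [0, 0, 0, 1])


@pytest.fixture(scope="module")
def fitted():
    data = feature_frame()
    spec = ModelSpec(outcome="rja", factors=("group",),
                     interactions=(), random=("participant", "trial"))
    return data, spec, fit_mixed(data, spec)


class TestContrasts:
    def test_cell_means_match_empirical_rates(self, fitted):
        data, spec, res = fitted
        cells = [{"group": "A"}, {"group": "B"}]
        means = marginal_means(res, data, cells)
        emp = data.groupby("group")["rja"].mean()
        # zero simulated heterogeneity: cell means are the empirical rates
        assert means["mean"].iloc[0] == pytest.approx(emp["A"], abs=1e-3)
        assert means["mean"].iloc[1] == pytest.approx(emp["B"], abs=1e-3)

    def test_odds_ratio_equals_link_scale_difference(self, fitted):
        data, spec, res = fitted
        pairs = [({"group": "A"}, {"group": "B"})]
        out = marginal_contrasts(res, data, pairs, boot_k=30, seed=1)
        emp = data.groupby("group")["rja"].mean()
        odds = lambda p: p / (1 - p)
        assert out[0].estimate == pytest.approx(
            odds(emp["A"]) / odds(emp["B"]), rel=1e-2)
        assert out[0].ci_low < out[0].estimate < out[0].ci_high

    def test_identical_cells_give_unit_or(self, fitted):
        data, spec, res = fitted
        pairs = [({"group": "A"}, {"group": "A"})]
        out = marginal_contrasts(res, data, pairs, boot_k=5, seed=0)
        assert out[0].estimate == pytest.approx(1.0)

    def test_reference_level_invariance(self, fitted):
        data, spec, res = fitted
        flipped = data.copy()
        flipped["group"] = pd.Categorical(flipped["group"],
                                          categories=["B", "A"])
        res2 = fit_mixed(flipped, spec)
        pairs = [({"group": "A"}, {"group": "B"})]
        a = marginal_contrasts(res, data, pairs, boot_k=5, seed=0)
        b = marginal_contrasts(res2, flipped, pairs, boot_k=5, seed=0)
        assert a[0].estimate == pytest.approx(b[0].estimate, rel=1e-3)

    def test_empty_cell_rejected(self, fitted):
        data, spec, res = fitted
        with pytest.raises(ValueError, match="cell"):
            marginal_contrasts(res, data, [({"group": "A"}, {"group": "Z"})],
                               boot_k=2)


class TestConditionScreen:
    def test_multi_level_factors_reported_single_level_skipped(self):
        data = feature_frame(seed=3)
        rng = np.random.default_rng(0)
        data["stimulus"] = rng.choice(["rabbit", "truck"], len(data))
        data["target_side"] = "left"  # degenerate factor
        spec = ModelSpec(outcome="rja", factors=("group",), interactions=())
        out = condition_screen(data, spec,
                               condition_cols=("stimulus", "target_side"))
        assert out["factor"].tolist() == ["stimulus"]
        assert out["p"].iloc[0] > 0.001  # no effect was simulated


class TestCascade:
    def test_perfect_negative_slope(self):
        table = pd.DataFrame({"d_out": -1.0 * np.arange(10.0),
                              "d_pred": np.arange(10.0)})
        res = cascade_lm(table, "d_out", "d_pred")
        assert res.beta == pytest.approx(-1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_null_association(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({"d_out": rng.normal(size=200),
                              "d_pred": rng.normal(size=200)})
        res = cascade_lm(table, "d_out", "d_pred")
        assert abs(res.beta) < 0.2
        assert res.ci_low < res.beta < res.ci_high

    def test_covariate_adjusted_variant_runs(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=100)
        pred = rng.normal(size=100)
        table = pd.DataFrame({"d_pred": pred, "baseline": base,
                              "d_out": -1.2 * pred + 0.5 * base
                              + rng.normal(0, 1.0, 100)})
        res = cascade_lm(table, "d_out", "d_pred", covariates=("baseline",))
        assert res.ci_low < -0.4  # strongly negative slope detected

    def test_too_few_cases_rejected(self):
        table = pd.DataFrame({"d_out": [1.0, 2.0], "d_pred": [0.0, 1.0]})
        with pytest.raises(ValueError, match="complete cases"):
            cascade_lm(table, "d_out", "d_pred")

    def test_recovery_with_noise(self):
        rng = np.random.default_rng(3)
        pred = rng.normal(size=100)
        out = -1.2 * pred + rng.normal(0, 1.5, 100)
        table = pd.DataFrame({"d_out": out, "d_pred": pred})
        res = cascade_lm(table, "d_out", "d_pred")
        true_std_beta = -1.2 * pred.std() / out.std()
        assert res.ci_low < true_std_beta < res.ci_high


class TestDropoutAnova:
    def _toy(self):
        # balanced 2x2 with 2 observations per cell
        return pd.DataFrame({
            "group": ["A", "A", "A", "A", "B", "B", "B", "B"],
            "retained": [0, 0, 1, 1, 0, 0, 1, 1],
            "y": [1.0, 2.0, 3.0, 4.0, 2.0, 3.0, 6.0, 7.0],
        })

    def test_matches_hand_computed_sums_of_squares(self):
        # cell means: A0=1.5 A1=3.5 B0=2.5 B1=6.5; grand mean 3.5
        # SS_group = 8 * (0.5)^2 * ... computed directly below
        table = self._toy()
        out = dropout_anova(table, "y")
        y = table["y"].to_numpy()
        a = table["group"].to_numpy()
        b = np.asarray(table["retained"])
        mean = y.mean()
        ss_a = sum(4 * (y[a == g].mean() - mean) ** 2 for g in ("A", "B"))
        ss_b = sum(4 * (y[b == r].mean() - mean) ** 2 for r in (0, 1))
        cell = {(g, r): y[(a == g) & (b == r)].mean()
                for g in ("A", "B") for r in (0, 1)}
        ss_cells = sum(2 * (m - mean) ** 2 for m in cell.values())
        ss_ab = ss_cells - ss_a - ss_b
        ss_resid = sum((y[(a == g) & (b == r)] - cell[(g, r)]) ** 2
                       for g in ("A", "B") for r in (0, 1)).sum()
        assert out.loc["group", "ss"] == pytest.approx(ss_a)
        assert out.loc["retained", "ss"] == pytest.approx(ss_b)
        assert out.loc["group:retained", "ss"] == pytest.approx(ss_ab)
        assert out.loc["Residual", "ss"] == pytest.approx(ss_resid)
        f_a = (ss_a / 1) / (ss_resid / 4)
        assert out.loc["group", "F"] == pytest.approx(f_a)

    def test_constant_outcome_all_f_zero(self):
        table = self._toy()
        table["y"] = 5.0
        out = dropout_anova(table, "y")
        assert (out["F"].dropna() == 0.0).all()

    def test_group_effect_detected_at_large_n(self):
        rng = np.random.default_rng(4)
        n = 400
        group = rng.integers(0, 2, n)
        table = pd.DataFrame({
            "group": np.where(group == 1, "B", "A"),
            "retained": rng.integers(0, 2, n),
            "y": 1.0 * group + rng.normal(0, 1, n)})
        out = dropout_anova(table, "y")
        assert out.loc["group", "p"] < 1e-6

    def test_empty_cell_named(self):
        table = self._toy()[lambda d: ~((d.group == "B") & (d.retained == 1))]
        with pytest.raises(ValueError, match="B"):
            dropout_anova(table, "y")


class TestAnovaPower:
    def test_null_effect_gives_alpha(self):
        assert anova_power(0.0, 60, 1, alpha=0.05,
                           method="ncf") == pytest.approx(0.05, abs=1e-9)
        assert anova_power(0.0, 60, 1, alpha=0.05,
                           method="chi2") == pytest.approx(0.05, abs=1e-9)

    def test_published_value_reproduced(self):
        assert anova_power(0.12, 60, 1) == pytest.approx(0.82, abs=0.01)

    def test_exact_f_variant_close(self):
        assert anova_power(0.12, 60, 1, method="ncf") == pytest.approx(
            0.80, abs=0.01)

    def test_monotone_in_sample_size(self):
        values = [anova_power(0.12, n, 1) for n in (30, 60, 120, 600)]
        assert all(a < b for a, b in zip(values, values[1:]))
        assert values[-1] > 0.999

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            anova_power(1.2, 60, 1)
        with pytest.raises(ValueError):
            anova_power(0.1, 4, 1)
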