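"""Contingency, rank/effect-size, mixed-model, and post hoc machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy.stats import chi2_contingency

from ramplab.exceptions import DegenerateDataError, ValidationError
from ramplab.stats import (
    ContingencyTable2x2,
    ModelSpec,
    chi_square_2x2,
    fit_model,
    model_spec,
    posthoc_marginal_means,
    signed_rank_and_d,
)


class TestChiSquare:
    def test_reference_area_counts(self):
        """10/47 vs 28/58 modulated neurons: statistic 8.20, P ~ 0.004."""
        stat, df, p = chi_square_2x2(np.array([[10, 37], [28, 30]]))
        assert stat == pytest.approx(8.20, abs=0.01)
        assert df == 1 and p == pytest.approx(0.004, abs=5e-4)

    def test_identical_proportions_zero(self):
        stat, _, p = chi_square_2x2(np.array([[5, 5], [5, 5]]))
        assert stat == 0.0 and p == 1.0

    def test_direct_formula_value(self):
        stat, _, _ = chi_square_2x2(np.array([[1, 9], [9, 1]]))
        assert stat == pytest.approx(12.8)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateDataError):
            chi_square_2x2(np.array([[0, 0], [5, 5]]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(hst.lists(hst.integers(1, 40), min_size=4, max_size=4))
    def test_closed_form_and_permutation_invariance(self, cells):
        a, b, c, d = cells
        t = np.array([[a, b], [c, d]], float)
        stat, _, p = chi_square_2x2(t)
        n = t.sum()
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(closed, rel=1e-12)
        assert chi_square_2x2(t[::-1])[0] == pytest.approx(stat)
        assert chi_square_2x2(t[:, ::-1])[0] == pytest.approx(stat)
        # independent oracle: scipy without continuity correction
        ref = chi2_contingency(t, correction=False)
        assert stat == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_table_validation(self):
        with pytest.raises(ValidationError):
            ContingencyTable2x2(np.array([[1, 2, 3], [4, 5, 6]]))


class TestSignedRank:
    def test_all_zero_differences_degenerate(self):
        x = np.arange(10.0)
        with pytest.raises(DegenerateDataError):
            signed_rank_and_d(x, x)

    def test_constant_difference_d_capped(self):
        x = np.arange(10.0)
        res = signed_rank_and_d(x + 1.0, x)
        assert res.d_capped and np.isinf(res.cohens_d) and res.cohens_d > 0
        assert res.p_value < 0.01

    def test_power_and_effect_size_on_unit_shift(self):
        """n=30 pairs with Normal(1,1) differences: near-certain rejection
        and d concentrated around 1."""
        rng = np.random.default_rng(1)
        rejections, ds = 0, []
        n_sims = 400
        for _ in range(n_sims):
            d = rng.normal(1.0, 1.0, 30)
            x = rng.normal(5.0, 2.0, 30)
            res = signed_rank_and_d(x + d, x)
            rejections += res.p_value < 0.05
            ds.append(res.cohens_d)
        assert rejections / n_sims > 0.99
        assert np.mean(ds) == pytest.approx(1.0, abs=0.15)

    def test_length_guard(self):
        with pytest.raises(ValidationError):
            signed_rank_and_d([1, 2], [2, 3])


class TestFitModel:
    def test_gaussian_without_random_effects_is_ols(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.normal(size=80), "g": list("ab") * 40})
        df["y"] = 1.5 + 2.0 * df["x"] + rng.normal(size=80)
        fit = fit_model(ModelSpec("y", ["x"]), df)
        X = np.column_stack([np.ones(80), df["x"]])
        beta = np.linalg.lstsq(X, df["y"], rcond=None)[0]
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)
        assert fit.kind == "ols"

    def test_mixed_model_recovers_context_shift(self):
        """-0.5 s context effect with animal random intercepts comes back
        within +/-0.15 s on a 7-animal cohort."""
        rng = np.random.default_rng(3)
        rows = []
        for a in range(7):
            intercept = rng.normal(0, 0.3)
            for ctx in ("one_interval", "two_interval"):
                shift = -0.5 if ctx == "two_interval" else 0.0
                for v in 9.6 + shift + intercept + rng.normal(0, 1.0, 200):
                    rows.append({"animal_id": f"a{a}", "context": ctx, "response_time": v})
        fit = fit_model(model_spec("response_context"), pd.DataFrame(rows))
        est = fit.params["C(context)[T.two_interval]"]
        assert est == pytest.approx(-0.5, abs=0.15)
        assert fit.kind == "mixedlm" and fit.random_effect_variance > 0
        assert fit.term_tests.loc[0, "p"] < 1e-6
        assert "mixedlm" in fit.summary()

    def test_null_type_one_rate_calibrated(self):
        """No true effect: the context term rejects at about alpha."""
        rng = np.random.default_rng(4)
        rejections, n_sims = 0, 200
        for _ in range(n_sims):
            rows = []
            for a in range(7):
                intercept = rng.normal(0, 0.3)
                for ctx in ("one", "two"):
                    for v in 9.6 + intercept + rng.normal(0, 1.0, 15):
                        rows.append({"animal_id": f"a{a}", "context": ctx, "y": v})
            fit = fit_model(ModelSpec("y", ["C(context)"], ["animal_id"]), pd.DataFrame(rows))
            rejections += fit.term_tests.loc[0, "p"] < 0.05
        assert 0.02 <= rejections / n_sims <= 0.10

    def test_poisson_time_sign_matches_ramp_direction(self):
        """Poisson rate models recover the sign of planted ramps."""
        from ramplab.ramping import binned_rates
        from ramplab.synth import GeneratorConfig, generate_trials, generate_unit, substream

        config = GeneratorConfig(n_trials_per_interval=40)
        trials, _ = generate_trials(config, 0, substream(55, "t"))
        rng = substream(55, "u")
        matches, n = 0, 30
        for i in range(n):
            cls = "ramp_up" if i % 2 == 0 else "ramp_down"
            unit, truth = generate_unit(config, cls, "MFC", trials, rng, unit_id=f"u{i}")
            centers, rates = binned_rates(unit, trials)
            df = pd.DataFrame({"count": rates * 40 * 0.1, "time": centers,
                               "exposure": 40 * 0.1})
            fit = fit_model(ModelSpec("count", ["time"], family="poisson",
                                      offset="exposure"), df)
            matches += np.sign(fit.params["time"]) == np.sign(truth.slope["FI12"])
        assert matches / n > 0.95

    def test_spec_validation(self):
        with pytest.raises(ValidationError):
            fit_model(ModelSpec("y", ["y"]), pd.DataFrame({"y": [1.0, 2.0]}))
        with pytest.raises(ValidationError):
            fit_model(ModelSpec("y", ["x"], ["g"]),
                      pd.DataFrame({"y": [1.0, 2.0], "x": [0.0, 1.0], "g": ["a", "a"]}))


class TestPosthoc:
    def test_two_level_factor_equals_unadjusted(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"g": ["a"] * 40 + ["b"] * 40, "y": rng.normal(size=80)})
        df.loc[df["g"] == "b", "y"] += 0.7
        fit = fit_model(ModelSpec("y", ["C(g)"]), df)
        ph = posthoc_marginal_means(fit, "g")
        t_p = float(fit.result.pvalues["C(g)[T.b]"])
        assert ph["p_adj"].iloc[0] == pytest.approx(t_p, rel=1e-3)
        assert ph["estimate"].iloc[0] == pytest.approx(-0.7, abs=0.4)

    def test_three_equal_groups_rarely_significant(self):
        rng = np.random.default_rng(6)
        min_ps = []
        for _ in range(100):
            df = pd.DataFrame({"g": list("abc") * 20, "y": rng.normal(size=60)})
            fit = fit_model(ModelSpec("y", ["C(g)"]), df)
            min_ps.append(posthoc_marginal_means(fit, "g")["p_adj"].min())
        assert np.median(min_ps) > 0.3
        assert np.mean(np.array(min_ps) < 0.05) < 0.12

    def test_single_area_context_drop_localized(self):
        """A context effect planted only in MFC: the MFC contrast is
        significant and the DMS contrast is not, in most simulations."""
        rng = np.random.default_rng(7)
        good_mfc = good_dms = 0
        n_sims = 60
        for _ in range(n_sims):
            rows = []
            for a in range(7):
                intercept = rng.normal(0, 0.2)
                for area in ("MFC", "DMS"):
                    for ctx in ("one", "two"):
                        eff = -0.8 if (area == "MFC" and ctx == "two") else 0.0
                        for v in 2.0 + intercept + eff + rng.normal(0, 0.5, 8):
                            rows.append({"animal_id": f"a{a}",
                                         "cell": f"{area}_{ctx}", "abs_score": v})
            fit = fit_model(ModelSpec("abs_score", ["C(cell)"], ["animal_id"]),
                            pd.DataFrame(rows))
            ph = posthoc_marginal_means(fit, "cell").set_index("contrast")
            good_mfc += ph.loc["MFC_one - MFC_two", "p_adj"] < 0.05
            good_dms += ph.loc["DMS_one - DMS_two", "p_adj"] >= 0.05
        assert good_mfc / n_sims > 0.9
        assert good_dms / n_sims > 0.9

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"g": ["a"] * 10, "y": np.arange(10.0)})
        fit = fit_model(ModelSpec("y", ["1"]), df)
        with pytest.raises(ValidationError):
            posthoc_marginal_means(fit, "g")
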