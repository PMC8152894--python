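"""PETH construction, ensemble PCA, slope fits, and modulation screens."""

import numpy as np
import pytest

from ramplab.exceptions import DegenerateDataError, InsufficientDataError
from ramplab.model import PethMatrix, TrialRecord, UnitRecord
from ramplab.ramping import (
    classify_ramping,
    compute_peth,
    ensemble_pca,
    fit_ramp_slope,
    ramp_strength,
    screen_interval_modulation,
    stack_peths,
    zscore_rows,
)
from ramplab.synth import GeneratorConfig, generate_trials, generate_unit, substream


def _one_trial():
    return TrialRecord(0, "FI12", 100.0, 12.0, np.array([12.5]), 12.5, 8.0)


class TestPeth:
    def test_no_spikes_gives_zero_row(self):
        unit = UnitRecord("u", "MFC", np.array([]))
        peth = compute_peth(unit, [_one_trial()])
        assert peth.values.shape == (1, 120)
        assert not peth.values.any()

    def test_single_spike_peak_value_is_kernel_height(self):
        """One spike at a bin center: rate there is 1/(bw*sqrt(2pi)) Hz."""
        unit = UnitRecord("u", "MFC", np.array([106.05]))  # 6.05 s after cue
        peth = compute_peth(unit, [_one_trial()], bandwidth=0.5)
        i = np.argmin(np.abs(peth.bin_centers - 6.05))
        assert peth.values[0, i] == pytest.approx(1.0 / (0.5 * np.sqrt(2 * np.pi)), rel=1e-9)
        # kernel mass integrates to ~1 over the interval
        assert peth.values[0].sum() * 0.1 == pytest.approx(1.0, abs=1e-3)

    def test_homogeneous_unit_flat_peth(self):
        config = GeneratorConfig(n_trials_per_interval=200, baseline_rate=5.0)
        trials, _ = generate_trials(config, 0, substream(8, "t"))
        unit, _ = generate_unit(config, "untuned", "MFC", trials, substream(8, "u"))
        peth = compute_peth(unit, trials)
        interior = peth.values[0, 20:-20]
        assert np.all(np.abs(interior - 5.0) < 0.5)

    def test_requires_trials_and_single_type(self):
        unit = UnitRecord("u", "MFC", np.array([1.0]))
        with pytest.raises(ValueError):
            compute_peth(unit, [])


class TestZscore:
    def test_rows_standardized(self):
        rng = np.random.default_rng(0)
        peth = PethMatrix(["a", "b"], np.arange(10) * 0.1 + 0.05, rng.uniform(1, 5, (2, 10)))
        z = zscore_rows(peth)
        np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.values.std(axis=1), 1.0, atol=1e-9)

    def test_constant_row_dropped_with_warning(self):
        vals = np.vstack([np.full(10, 3.0), np.arange(10.0)])
        peth = PethMatrix(["flat", "ramp"], np.arange(10) * 0.1, vals)
        with pytest.warns(UserWarning, match="flat"):
            z = zscore_rows(peth)
        assert z.unit_ids == ["ramp"]

    def test_linear_ramp_stays_affine(self):
        t = np.arange(20) * 0.1
        peth = PethMatrix(["r"], t, (2.0 + 3.0 * t)[None, :])
        z = zscore_rows(peth)
        assert abs(np.corrcoef(z.values[0], t)[0, 1]) == pytest.approx(1.0)


class TestEnsemblePca:
    def _zramp(self, n_bins=40):
        t = np.arange(n_bins) * 0.1
        r = (t - t.mean()) / t.std()
        return t, r

    def test_rank_one_up_down_ensemble(self):
        """Half the units ramp up, half down: PC1 is the ramp and explains
        all variance; |scores| are identical across units."""
        t, r = self._zramp()
        X = np.vstack([r] * 5 + [-r] * 5)
        peth = PethMatrix([f"u{i}" for i in range(10)], t, X, normalization="zscore")
        pca = ensemble_pca(peth)
        assert pca.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-12)
        assert abs(np.corrcoef(pca.components[0], r)[0, 1]) == pytest.approx(1.0)
        strengths = [ramp_strength(pca, u) for u in peth.unit_ids]
        np.testing.assert_allclose(strengths, strengths[0])

    def test_components_orthonormal_scores_uncorrelated(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 30))
        peth = PethMatrix([f"u{i}" for i in range(12)], np.arange(30) * 0.1, X)
        pca = ensemble_pca(peth)
        gram = pca.components @ pca.components.T
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
        cov = np.cov(pca.scores, rowvar=False)
        np.testing.assert_allclose(cov - np.diag(np.diag(cov)), 0.0, atol=1e-8)
        assert pca.explained_variance_fraction.sum() == pytest.approx(1.0, abs=1e-8)
        diffs = np.diff(pca.explained_variance_fraction)
        assert np.all(diffs <= 1e-12)

    def test_matches_bruteforce_eigendecomposition(self):
        """3-unit, 4-bin toy agrees with an explicit covariance eigensolve."""
        X = np.array([[1.0, 2.0, 0.5, -1.0], [0.2, -0.3, 1.5, 2.2], [-1.1, 0.4, 0.9, 0.0]])
        peth = PethMatrix(["a", "b", "c"], np.arange(4) * 0.1, X)
        pca = ensemble_pca(peth)
        Xc = X - X.mean(axis=0, keepdims=True)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (X.shape[0] - 1))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        k = pca.components.shape[0]
        for j in range(min(k, 2)):  # rank 2 after centering 3 rows
            v = evecs[:, j]
            s = np.sign(v @ pca.components[j]) or 1.0
            np.testing.assert_allclose(pca.components[j], s * v, atol=1e-8)
            np.testing.assert_allclose(pca.scores[:, j], s * (Xc @ v), atol=1e-8)
        frac = evals[:k] / evals.sum()
        np.testing.assert_allclose(pca.explained_variance_fraction, frac, atol=1e-8)

    def test_reconstruction_from_scores(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 15))
        peth = PethMatrix([f"u{i}" for i in range(8)], np.arange(15) * 0.1, X)
        pca = ensemble_pca(peth)
        recon = pca.scores @ pca.components + X.mean(axis=0, keepdims=True)
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_ramp_strength_invariant_to_unit_order(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(9, 25))
        ids = [f"u{i}" for i in range(9)]
        pca1 = ensemble_pca(PethMatrix(ids, np.arange(25) * 0.1, X))
        perm = rng.permutation(9)
        pca2 = ensemble_pca(PethMatrix([ids[i] for i in perm], np.arange(25) * 0.1, X[perm]))
        for uid in ids:
            assert ramp_strength(pca1, uid) == pytest.approx(ramp_strength(pca2, uid), abs=1e-8)

    def test_too_few_units_rejected(self):
        peth = PethMatrix(["a"], np.arange(4) * 0.1, np.arange(4.0)[None, :])
        with pytest.raises(InsufficientDataError):
            ensemble_pca(peth)


def test_ramping_units_have_larger_pc1_scores():
    """Ground-truth ramping units dominate |PC1| relative to untuned units."""
    config = GeneratorConfig(n_trials_per_interval=100)
    trials, _ = generate_trials(config, 0, substream(12, "t"))
    rng = substream(12, "u")
    rows, kinds = [], []
    for i in range(40):
        kind = "ramp_up" if i < 10 else "ramp_down" if i < 20 else "untuned"
        unit, _ = generate_unit(config, kind, "MFC", trials, rng, unit_id=f"u{i}")
        rows.append(compute_peth(unit, trials))
        kinds.append(kind)
    pca = ensemble_pca(zscore_rows(stack_peths(rows)))
    strength = np.array([ramp_strength(pca, f"u{i}") for i in range(40)])
    ramping = np.array([k != "untuned" for k in kinds])
    assert strength[ramping].mean() > 2.0 * strength[~ramping].mean()


class TestSlopeFit:
    def test_recovers_planted_slope(self):
        """lambda(t) = 2 + 1*t Hz over FI12: slope back within 0.1 Hz/s."""
        config = GeneratorConfig(baseline_rate=2.0, ramp_slope_fi12=1.0,
                                 n_trials_per_interval=200)
        trials, _ = generate_trials(config, 0, substream(21, "t"))
        unit, _ = generate_unit(config, "ramp_up", "MFC", trials, substream(21, "u"))
        fit = fit_ramp_slope(unit, trials)
        assert fit.slope == pytest.approx(1.0, abs=0.1)
        assert fit.abs_slope == abs(fit.slope)
        assert fit.p_value < 1e-6

    def test_poisson_method_agrees(self):
        config = GeneratorConfig(baseline_rate=2.0, ramp_slope_fi12=1.0,
                                 n_trials_per_interval=100)
        trials, _ = generate_trials(config, 0, substream(22, "t"))
        unit, _ = generate_unit(config, "ramp_up", "MFC", trials, substream(22, "u"))
        ols = fit_ramp_slope(unit, trials, method="ols")
        pois = fit_ramp_slope(unit, trials, method="poisson")
        assert pois.slope == pytest.approx(ols.slope, abs=0.1)

    def test_null_false_positive_rate_near_alpha(self):
        """Homogeneous units: the slope test rejects at about its alpha."""
        config = GeneratorConfig(n_trials_per_interval=15)
        trials, _ = generate_trials(config, 0, substream(23, "t"))
        rng = substream(23, "u")
        rejections = 0
        n = 300
        for i in range(n):
            unit, _ = generate_unit(config, "untuned", "MFC", trials, rng, unit_id=f"n{i}")
            rejections += classify_ramping(fit_ramp_slope(unit, trials))
        assert 0.013 < rejections / n < 0.094  # 0.05 +/- ~3 binomial SEs

    def test_guards(self):
        unit = UnitRecord("u", "MFC", np.array([]))
        with pytest.raises(InsufficientDataError):
            fit_ramp_slope(unit, [_one_trial()] * 5)
        with pytest.raises(DegenerateDataError):
            fit_ramp_slope(unit, [_one_trial()] * 12)

    def test_classify_ramping_threshold(self):
        from ramplab.ramping import SlopeFit

        assert classify_ramping(SlopeFit(1.0, 0.0, 0.01))
        assert not classify_ramping(SlopeFit(1.0, 0.0, 0.5))


class TestIntervalModulation:
    def _trials(self, seed, n):
        config = GeneratorConfig(n_trials_per_interval=n)
        trials, _ = generate_trials(config, 1, substream(seed, "t"))
        fi3 = [t for t in trials if t.interval_type == "FI3"]
        fi12 = [t for t in trials if t.interval_type == "FI12"]
        return config, trials, fi3, fi12

    def test_strong_modulation_detected(self):
        config, trials, fi3, fi12 = self._trials(31, 50)
        config.interval_mod_rate = 5.0
        unit, _ = generate_unit(config, "interval_modulated", "DMS", trials,
                                substream(31, "u"), modulated_interval="FI12")
        res = screen_interval_modulation(unit, fi3, fi12)
        assert res.modulated and res.interval_effect_p < 1e-6
        assert res.rate_fi12 > res.rate_fi3

    def test_null_false_positive_rate_near_alpha(self):
        config, trials, fi3, fi12 = self._trials(32, 25)
        rng = substream(32, "u")
        rejections = 0
        n = 300
        for i in range(n):
            unit, _ = generate_unit(config, "untuned", "DMS", trials, rng, unit_id=f"m{i}")
            rejections += screen_interval_modulation(unit, fi3, fi12).modulated
        assert 0.013 < rejections / n < 0.094

    def test_insufficient_trials_returns_none(self):
        config, trials, fi3, fi12 = self._trials(33, 12)
        unit, _ = generate_unit(config, "untuned", "DMS", trials, substream(33, "u"))
        assert screen_interval_modulation(unit, fi3[:4], fi12) is None

    def test_area_asymmetry_direction_recovered(self):
        """More modulated units planted in DMS than MFC -> recovered counts
        preserve the direction of the asymmetry."""
        from ramplab.synth import generate_session

        config = GeneratorConfig(
            n_units_per_area=20, n_trials_per_interval=30,
            ramping_fraction=0.0, response_locked_fraction=0.0,
            interval_mod_fraction_by_area={"MFC": 0.2, "DMS": 0.5},
        )
        session, _ = generate_session(config, "rat", 1, seed=34)
        fi3, fi12 = session.trials_of("FI3"), session.trials_of("FI12")
        counts = {"MFC": 0, "DMS": 0}
        for u in session.units:
            res = screen_interval_modulation(u, fi3, fi12)
            counts[u.area] += bool(res and res.modulated)
        assert counts["DMS"] > counts["MFC"]
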