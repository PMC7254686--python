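"""Per-gait OLS calibration, prediction intervals and residual diagnostics."""

import numpy as np
import pytest

from trackway import (
    GaitGeneratorSpec,
    TrackwayRecord,
    fit_gait_model,
    generate,
    load_models,
    predict_with_interval,
    residual_normality,
    save_models,
)
from trackway.calibration import DegenerateDesignError, InsufficientDataError

from conftest import make_linear_records


def normal_equation_fit(x, y):
    """Independent OLS oracle: solve X'X b = X'y directly."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[1], beta[0]  # slope, intercept


class TestFit:
    def test_noiseless_line_recovered_exactly(self):
        recs = make_linear_records(3.20, -0.23, np.linspace(0.225, 0.322, 10))
        m = fit_gait_model(recs, "walking")
        assert m.slope == pytest.approx(3.20, abs=1e-10)
        assert m.intercept == pytest.approx(-0.23, abs=1e-10)
        assert m.r2 == pytest.approx(1.0, abs=1e-10)
        assert m.residual_sd == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_normal_equation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        x = rng.uniform(0.2, 0.7, n)
        y = 3.0 * x + 0.1 + rng.normal(0, 0.2, n)
        recs = make_linear_records(0, 0, x, noise=y)  # u = y directly
        m = fit_gait_model(recs, "walking")
        slope, intercept = normal_equation_fit(x, y)
        assert m.slope == pytest.approx(slope, rel=1e-8)
        assert m.intercept == pytest.approx(intercept, rel=1e-8)

    def test_df_and_f_identity(self, training_records):
        m = fit_gait_model(training_records, "walking")
        assert m.n == 48
        assert m.df == (1, 46)
        # simple-regression identity F = r2 / (1 - r2) * (n - 2)
        assert m.f_stat == pytest.approx(m.r2 / (1 - m.r2) * (m.n - 2), rel=1e-8)
        assert 0.0 <= m.r2 <= 1.0

    def test_insufficient_data(self):
        recs = make_linear_records(3.2, -0.23, [0.25, 0.30])
        with pytest.raises(InsufficientDataError):
            fit_gait_model(recs, "walking")

    def test_records_without_speed_are_excluded(self):
        recs = make_linear_records(3.2, -0.23, np.linspace(0.23, 0.32, 5))
        recs.append(TrackwayRecord(id="nospeed", l_stride=0.3, gait="walking"))
        m = fit_gait_model(recs, "walking")
        assert m.n == 5

    def test_zero_stride_variance_is_degenerate(self):
        recs = [
            TrackwayRecord(id=f"r{i}", l_stride=0.3, gait="walking", u_measured=v)
            for i, v in enumerate([0.5, 0.6, 0.7])
        ]
        with pytest.raises(DegenerateDesignError):
            fit_gait_model(recs, "walking")

    def test_parameter_recovery_within_monte_carlo_error(self):
        """Mean fitted slope over seeded replicates sits within 2 MC SE of truth."""
        spec = GaitGeneratorSpec(
            gait="walking", slope=3.20, intercept=-0.23,
            residual_sd=0.092, l_range=(0.225, 0.322), n=48,
        )
        reps = 200
        seeds = np.random.SeedSequence(7).generate_state(reps)
        slopes = [
            fit_gait_model(generate([spec], int(s)), "walking").slope
            for s in seeds
        ]
        mc_se = np.std(slopes, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(slopes) - 3.20) < 2 * mc_se


class TestPredictionInterval:
    @pytest.fixture
    def model(self, training_records):
        return fit_gait_model(training_records, "walking")

    def test_point_is_line_value(self, model):
        point, lo, hi = predict_with_interval(model, 0.27)
        assert point == pytest.approx(model.slope * 0.27 + model.intercept)
        assert lo < point < hi

    def test_width_grows_away_from_training_mean(self, model):
        def width(l):
            _, lo, hi = predict_with_interval(model, l)
            return hi - lo

        near = width(model.l_mean)
        assert width(model.l_mean + 0.1) > near
        assert width(model.l_mean - 0.1) > near

    def test_zero_noise_collapses_interval(self):
        recs = make_linear_records(3.2, -0.23, np.linspace(0.23, 0.32, 6))
        m = fit_gait_model(recs, "walking")
        point, lo, hi = predict_with_interval(m, 0.28)
        assert lo == point == hi

    def test_level_must_be_a_probability(self, model):
        with pytest.raises(ValueError):
            predict_with_interval(model, 0.3, level=1.0)

    def test_empirical_coverage_near_nominal(self):
        """~95% of new observations fall inside the 95% interval
        (unconditional coverage over replicated fits)."""
        spec = GaitGeneratorSpec(
            gait="walking", slope=3.20, intercept=-0.23,
            residual_sd=0.092, l_range=(0.225, 0.322), n=48,
        )
        rng = np.random.default_rng(11)
        hits = trials = 0
        for rep in range(100):
            m = fit_gait_model(generate([spec], int(rng.integers(2**31))), "walking")
            l_new = rng.uniform(*spec.l_range, size=10)
            u_new = spec.slope * l_new + spec.intercept + rng.normal(
                0, spec.residual_sd, 10
            )
            for l, u in zip(l_new, u_new):
                _, lo, hi = predict_with_interval(m, l, 0.95)
                hits += lo <= u <= hi
                trials += 1
        assert abs(hits / trials - 0.95) < 0.02


class TestResidualNormality:
    def test_gaussian_residuals_rarely_rejected(self):
        spec = GaitGeneratorSpec(
            gait="walking", slope=3.20, intercept=-0.23,
            residual_sd=0.092, l_range=(0.225, 0.322), n=48,
        )
        seeds = np.random.SeedSequence(3).generate_state(200)
        accepted = 0
        for s in seeds:
            recs = generate([spec], int(s))
            m = fit_gait_model(recs, "walking")
            _, p = residual_normality(m, recs)
            accepted += p > 0.05
        assert accepted / len(seeds) >= 0.90

    def test_heavy_tailed_residuals_mostly_rejected(self):
        rng = np.random.default_rng(5)
        rejected = 0
        reps = 100
        for _ in range(reps):
            x = rng.uniform(0.225, 0.322, 48)
            # Cauchy-tailed noise, clipped only far enough to keep speeds
            # physical (positive); the tails stay grossly non-Gaussian
            noise = np.clip(rng.standard_t(df=1, size=48), -80, 80) * 0.05
            recs = make_linear_records(3.2, 5.0, x, noise=noise)
            m = fit_gait_model(recs, "walking")
            _, p = residual_normality(m, recs)
            rejected += p < 0.05
        assert rejected / reps > 0.5

    def test_constant_residuals_are_degenerate(self):
        recs = make_linear_records(3.2, -0.23, np.linspace(0.23, 0.32, 6))
        m = fit_gait_model(recs, "walking")
        with pytest.raises(DegenerateDesignError):
            residual_normality(m, recs)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, training_records):
        models = [
            fit_gait_model(training_records, g)
            for g in ("walking", "grounded_running", "aerial_running")
        ]
        path = tmp_path / "models.txt"
        save_models(models, path)
        back = load_models(path)
        assert len(back) == 3
        for a, b in zip(models, back):
            assert a == b
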