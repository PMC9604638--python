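import numpy as np
import pandas as pd
import pytest

from pefrisk.qr import (
    DEFAULT_TAU_GRID,
    SlidingQRModel,
    WindowSpec,
    band_table,
    band_table_marginals,
    detect_crossings,
    err_tau,
    err_tau_by_quantile,
    fit_qr,
    grid_search_windows,
    pinball_loss,
    predict_quantile,
    sliding_window_run,
)


def _empty_design(n):
    return np.empty((n, 0))


class TestFitQr:
    def test_intercept_only_median(self):
        beta = fit_qr(_empty_design(3), [1.0, 2.0, 3.0], 0.5)
        assert beta[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("tau", [0.1, 0.5, 0.9])
    def test_noiseless_exact_fit(self, tau):
        x = np.linspace(-3, 3, 40)
        beta = fit_qr(x[:, None], 2 * x, tau)
        assert beta == pytest.approx([0.0, 2.0], abs=1e-8)

    @pytest.mark.parametrize("tau", [0.1, 0.5, 0.9])
    def test_flat_optimum_matches_grid_oracle(self, tau):
        """The LP's achieved pinball loss equals a brute-force constant grid."""
        y = np.arange(1.0, 11.0)
        beta = fit_qr(_empty_design(10), y, tau)
        loss = pinball_loss(y, np.full(10, beta[0]), tau)
        grid = np.linspace(0.0, 11.0, 2201)
        oracle = min(pinball_loss(y, np.full(10, c), tau) for c in grid)
        assert loss <= oracle + 1e-9

    def test_parameter_recovery(self, rng):
        x = rng.normal(0, 1, 5000)
        y = 1 + 2 * x + rng.normal(0, 1, 5000)
        beta = fit_qr(x[:, None], y, 0.5)
        assert beta == pytest.approx([1.0, 2.0], abs=0.1)

    def test_matches_independent_qr_solver(self, rng):
        """Cross-check the LP against statsmodels' IRLS quantile fit."""
        import statsmodels.api as sm

        X = rng.normal(0, 1, (200, 3))
        y = 0.5 + X @ [1.0, -2.0, 0.3] + rng.standard_t(5, 200)
        for tau in (0.25, 0.5, 0.75):
            ours = fit_qr(X, y, tau)
            theirs = sm.QuantReg(y, sm.add_constant(X)).fit(q=tau).params
            X1 = np.column_stack([np.ones(200), X])
            assert pinball_loss(y, X1 @ ours, tau) <= pinball_loss(y, X1 @ theirs, tau) + 1e-9
            assert ours == pytest.approx(np.asarray(theirs), abs=5e-3)

    def test_tau_domain_error(self):
        with pytest.raises(ValueError):
            fit_qr(_empty_design(5), np.ones(5), 1.5)

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])  # col 0 duplicates intercept
        with pytest.raises(ValueError, match="collinear"):
            fit_qr(X, np.arange(20.0), 0.5)

    def test_training_calibration_bound(self, rng):
        """Share of negative residuals lies within tau +/- (p+1)/n."""
        n, p = 300, 4
        X = rng.normal(0, 1, (n, p))
        y = X @ rng.normal(0, 1, p) + rng.normal(0, 1, n)
        for tau in (0.2, 0.5, 0.8):
            beta = fit_qr(X, y, tau)
            resid = y - np.column_stack([np.ones(n), X]) @ beta
            frac = np.mean(resid < 0)
            assert tau - (p + 1) / n <= frac <= tau + (p + 1) / n

    def test_beats_empirical_quantile_baseline(self, rng):
        n = 120
        X = rng.normal(0, 1, (n, 2))
        y = 1 + X @ [2.0, -1.0] + rng.normal(0, 1, n)
        X1 = np.column_stack([np.ones(n), X])
        for tau in DEFAULT_TAU_GRID:
            beta = fit_qr(X, y, tau)
            base = np.quantile(y, tau)
            assert pinball_loss(y, X1 @ beta, tau) <= pinball_loss(y, np.full(n, base), tau) + 1e-9


class TestPredictQuantile:
    def _model(self, coefs):
        names = [f"x{i}" for i in range(len(next(iter(coefs.values()))) - 1)]
        return SlidingQRModel(coefficients={t: np.asarray(b, float) for t, b in coefs.items()},
                              feature_names=names)

    def test_intercept_only(self):
        m = self._model({0.5: [7.0]})
        assert predict_quantile(m, _empty_design(3), 0.5) == pytest.approx([7.0] * 3)

    def test_manual_dot_product(self):
        m = self._model({0.2: [1.0, 2.0, -0.5, 3.0]})
        x = np.array([[4.0, 2.0, 1.0]])
        assert predict_quantile(m, x, 0.2)[0] == pytest.approx(1 + 8 - 1 + 3)

    def test_off_grid_tau_lists_available(self):
        m = self._model({0.5: [7.0]})
        with pytest.raises(KeyError, match="0.5"):
            predict_quantile(m, _empty_design(1), 0.9)

    def test_crossing_detected_and_flagged(self):
        m = self._model({0.5: [10.0], 0.9: [5.0]})
        assert detect_crossings(m, _empty_design(1)) == [(0.5, 0.9)]


class TestSlidingWindow:
    @staticmethod
    def _series(n, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n)
        return pd.DataFrame({"x": x, "am_pefr": 1 + 2 * x + rng.normal(0, 1, n)})

    def test_window_arithmetic(self):
        models, preds = sliding_window_run(
            self._series(60), WindowSpec.from_window(45, 7), (0.5,), feature_cols=["x"]
        )
        assert len(models) == 3
        assert len(preds) == 60 - 45
        assert preds.groupby("iteration").size().tolist() == [7, 7, 1]

    def test_unit_slide(self):
        _, preds = sliding_window_run(
            self._series(52), WindowSpec.from_window(45, 1), (0.5,), feature_cols=["x"]
        )
        assert len(preds) == 7
        assert (preds.groupby("iteration").size() == 1).all()

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_run(
                self._series(45), WindowSpec.from_window(45, 7), (0.5,), feature_cols=["x"]
            )

    def test_each_day_predicted_once_out_of_window(self):
        s = self._series(80)
        _, preds = sliding_window_run(s, WindowSpec.from_window(45, 7), (0.5,), feature_cols=["x"])
        assert preds.index.is_unique
        assert preds.index.min() == 45  # first W days never predicted

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            WindowSpec(window=45, train_size=30, valid_size=10, m=7)
        with pytest.raises(ValueError):
            WindowSpec(window=45, train_size=30, valid_size=15, m=0)


class TestErrTau:
    @pytest.mark.parametrize(
        "n,n_under,tau,expected",
        [(100, 20, 0.2, 0.0), (10, 0, 0.2, 0.2), (7, 2, 0.2, abs(2 / 7 - 0.2))],
    )
    def test_examples(self, n, n_under, tau, expected):
        pred = np.zeros(n)
        obs = np.where(np.arange(n) < n_under, -1.0, 1.0)  # ties impossible
        assert err_tau(pred, obs, tau) == pytest.approx(expected)

    def test_tie_counts_as_not_under(self):
        assert err_tau([5.0], [5.0], 0.2) == pytest.approx(0.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            err_tau([], [], 0.5)

    def test_bound_property(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 50))
            tau = float(rng.uniform(0.01, 0.99))
            e = err_tau(rng.normal(0, 1, n), rng.normal(0, 1, n), tau)
            assert 0 <= e <= max(tau, 1 - tau) + 1e-12


# published 10-band x 4-window calibration benchmark (T_use = 7); the
# band x column cells of a reference quantile-calibration table
REFERENCE_CELLS = pd.DataFrame(
    {
        30: [0.092, 0.057, 0.019, 0.030, 0.030, 0.033, 0.046, 0.111, 0.143, 0.173],
        35: [0.103, 0.112, 0.053, 0.015, 0.009, 0.050, 0.101, 0.105, 0.157, 0.169],
        45: [0.118, 0.068, 0.021, 0.016, 0.025, 0.048, 0.071, 0.100, 0.152, 0.145],
        50: [0.037, 0.042, 0.032, 0.012, 0.045, 0.078, 0.055, 0.056, 0.113, 0.153],
    },
    index=[
        "0.01-0.10", "0.11-0.20", "0.21-0.30", "0.31-0.40", "0.41-0.50",
        "0.51-0.60", "0.61-0.70", "0.71-0.80", "0.81-0.90", "0.91-0.99",
    ],
)


class TestBandTable:
    def test_marginals_reproduce_reference_table(self):
        out = band_table_marginals(REFERENCE_CELLS)
        assert out.loc["average", 30] == pytest.approx(0.0734, abs=5e-5)
        assert out.loc["0.31-0.40", "Average"] == pytest.approx(0.018, abs=5e-4)
        assert out.loc["0.91-0.99", "Average"] == pytest.approx(0.160, abs=5e-4)
        # grand average: printed-cell rounding admits +/-0.0005 slack
        assert out.loc["average", "Average"] == pytest.approx(0.0747, abs=5e-4)
        band_avgs = out.loc[REFERENCE_CELLS.index, "Average"]
        assert band_avgs.min() == pytest.approx(0.018, abs=5e-4)
        assert band_avgs.max() == pytest.approx(0.160, abs=5e-4)

    def test_band_table_collapses_tau_grid(self):
        err = pd.DataFrame({45: np.linspace(0.01, 0.2, len(DEFAULT_TAU_GRID))},
                           index=DEFAULT_TAU_GRID)
        bt = band_table(err)
        assert len(bt) == 10
        assert bt[45].is_monotonic_increasing

    def test_grid_search_single_pair(self):
        rng = np.random.default_rng(3)
        series = []
        for _ in range(2):
            x = rng.normal(0, 1, 70)
            series.append(pd.DataFrame({"x": x, "am_pefr": 1 + 2 * x + rng.normal(0, 1, 70)}))
        long, best, tables = grid_search_windows(
            series, [45], [7], (0.3, 0.5, 0.7), feature_cols=["x"]
        )
        assert best == (45, 7)
        assert list(tables[7].columns) == [45]

    def test_grid_search_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            grid_search_windows([], [45], [7], (0.5,), feature_cols=["x"])
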