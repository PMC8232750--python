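"""Transfer-entropy estimator: zero laws, oracle agreement, lag scanning."""

import numpy as np
import pytest

from teflow.te import TEConfig, TEResult, gaussian_te_oracle, ksg_te, lag_scan_te, nats_to_bits

from conftest import simulate_var, standard_var

# exact closed form for the reference VAR with coupling 0.5, derived
# symbolically from the stationary moments (sxx=4/3, sxy=4/9, syy=56/27):
# TE = ln(sqrt(2310)/42)
REFERENCE_VAR_TE = 0.1348317834745513


class TestZeroLaws:
    def test_independent_series_near_zero(self):
        r = np.random.default_rng(0)
        res = ksg_te(r.standard_normal(4096), r.standard_normal(4096), TEConfig(delay=1))
        assert abs(res.value) <= 0.02

    def test_synchronized_copy_is_zero(self):
        # a fully synchronized pair transfers no information beyond the
        # target's own past
        x = np.random.default_rng(1).standard_normal(4096)
        res = ksg_te(x, x.copy(), TEConfig(delay=1))
        assert abs(res.value) <= 0.02

    def test_zero_law_mean_over_pairs(self):
        vals = []
        for i in range(100):
            r = np.random.default_rng(1000 + i)
            vals.append(
                ksg_te(r.standard_normal(1024), r.standard_normal(1024),
                       TEConfig(delay=1)).value
            )
        assert abs(np.mean(vals)) <= 0.005


class TestGaussianOracle:
    def test_matches_symbolic_closed_form(self):
        A, S = standard_var(0.5)
        assert gaussian_te_oracle(A, S, delay=1) == pytest.approx(REFERENCE_VAR_TE, abs=1e-12)

    def test_matches_regression_plugin_on_long_simulation(self):
        # brute-force route: residual variances of the two conditional
        # regressions on a long simulated realization
        A, _ = standard_var(0.5)
        d = simulate_var(A, 200_000, seed=3)
        yf, yp, xp = d[1, 1:], d[1, :-1], d[0, :-1]

        def resvar(cols):
            X = np.column_stack([np.ones(yf.size)] + cols)
            beta = np.linalg.lstsq(X, yf, rcond=None)[0]
            return np.var(yf - X @ beta)

        plugin = 0.5 * np.log(resvar([yp]) / resvar([yp, xp]))
        assert plugin == pytest.approx(REFERENCE_VAR_TE, abs=0.005)

    def test_zero_coupling_gives_exactly_zero(self):
        A, S = standard_var(0.0)
        assert gaussian_te_oracle(A, S, delay=1) == pytest.approx(0.0, abs=1e-14)

    def test_symmetric_bidirectional_coupling(self):
        A = np.array([[0.4, 0.3], [0.3, 0.4]])
        S = np.eye(2)
        fwd = gaussian_te_oracle(A, S, delay=1, source=0, target=1)
        rev = gaussian_te_oracle(A, S, delay=1, source=1, target=0)
        assert fwd == pytest.approx(rev, rel=1e-12)
        assert fwd > 0

    def test_nonstationary_coefficients_rejected(self):
        with pytest.raises(ValueError, match="stationary"):
            gaussian_te_oracle(np.array([[1.01, 0.0], [0.5, 0.5]]), np.eye(2))


class TestKSGAgainstOracle:
    def test_within_15_percent_at_moderate_coupling(self):
        A, S = standard_var(0.5)
        oracle = gaussian_te_oracle(A, S, delay=1)
        d = simulate_var(A, 20_000, seed=7)
        est = ksg_te(d[0], d[1], TEConfig(delay=1)).value
        assert est == pytest.approx(oracle, rel=0.15)

    def test_monotone_and_correlated_across_strengths(self):
        oracle_vals, est_vals = [], []
        for c in (0.1, 0.3, 0.5):
            A, S = standard_var(c)
            oracle_vals.append(gaussian_te_oracle(A, S, delay=1))
            ests = [
                ksg_te(*simulate_var(A, 4096, seed=50 + s), TEConfig(delay=1)).value
                for s in range(3)
            ]
            est_vals.append(np.mean(ests))
        assert est_vals[0] < est_vals[1] < est_vals[2]
        assert np.corrcoef(oracle_vals, est_vals)[0, 1] > 0.99

    def test_asymmetry_of_unidirectional_coupling(self):
        # driver->response must dominate the reverse direction
        A, _ = standard_var(0.5)
        wins = 0
        for s in range(20):
            d = simulate_var(A, 1500, seed=300 + s)
            fwd = ksg_te(d[0], d[1], TEConfig(delay=1)).value
            rev = ksg_te(d[1], d[0], TEConfig(delay=1)).value
            wins += fwd > rev
        assert wins >= 19


class TestLagScan:
    def test_recovers_true_coupling_delay(self, coupled_recording):
        res = lag_scan_te(coupled_recording.channel("A"),
                          coupled_recording.channel("B"), TEConfig(), 0, 15)
        assert res.delay_used == 5

    def test_single_candidate_equals_plain_estimate(self):
        r = np.random.default_rng(2)
        x, y = r.standard_normal(600), r.standard_normal(600)
        scan = lag_scan_te(x, y, TEConfig(), 3, 3)
        plain = ksg_te(x, y, TEConfig(delay=3))
        assert scan.value == plain.value
        assert scan.delay_used == 3

    def test_independent_series_stay_in_noise_band(self):
        r = np.random.default_rng(3)
        res = lag_scan_te(r.standard_normal(2048), r.standard_normal(2048),
                          TEConfig(), 0, 10)
        # maximum over 11 lags of a zero-TE pair: small positive excursion
        assert res.value < 0.05
        assert 0 <= res.delay_used <= 10

    def test_invalid_lag_order_rejected(self):
        r = np.random.default_rng(4)
        with pytest.raises(ValueError):
            lag_scan_te(r.standard_normal(500), r.standard_normal(500),
                        TEConfig(), 5, 2)


class TestValidation:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            ksg_te(np.zeros(200), np.zeros(300))

    def test_short_series_error_names_minimum(self):
        r = np.random.default_rng(5)
        with pytest.raises(ValueError, match="need >= "):
            ksg_te(r.standard_normal(50), r.standard_normal(50))

    def test_constant_series_rejected(self):
        r = np.random.default_rng(6)
        with pytest.raises(ValueError, match="constant"):
            ksg_te(np.full(500, 3.0), r.standard_normal(500))

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            TEConfig(k_neighbors=0)
        with pytest.raises(ValueError):
            TEConfig(delay=-1)
        with pytest.raises(ValueError):
            TEResult(value=np.nan, delay_used=0, n_vectors=10)


class TestNumericalContracts:
    def test_jitter_invariance(self):
        A, _ = standard_var(0.5)
        d = simulate_var(A, 4000, seed=9)
        v1 = ksg_te(d[0], d[1], TEConfig(delay=1, noise_jitter_sd=1e-8)).value
        v2 = ksg_te(d[0], d[1], TEConfig(delay=1, noise_jitter_sd=2e-8)).value
        assert v2 == pytest.approx(v1, rel=0.01)

    def test_deterministic_repeat_calls(self):
        A, _ = standard_var(0.3)
        d = simulate_var(A, 2000, seed=10)
        assert ksg_te(d[0], d[1], TEConfig(delay=1)).value == ksg_te(
            d[0], d[1], TEConfig(delay=1)).value

    def test_nats_to_bits(self):
        assert nats_to_bits(np.log(2.0)) == pytest.approx(1.0)
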