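"""Time-domain grounding: sine+jitter signals, Pearson FC, analytic signal, PLV."""

import numpy as np
import pytest

from fcbasis.core import TWO_PI
from fcbasis.fitting import FitConfig, fit
from fcbasis.signals import (
    TimeSeriesMatrix,
    analytic_signal,
    generate_sine_signals,
    pearson_fc,
    plv,
)

OMEGA = 1.0
DT = TWO_PI / 100  # 100 samples per period


def _corr(ts, a, b):
    return pearson_fc(ts).values[a, b]


class TestGenerateSineSignals:
    def test_identical_phase_unit_jitter_correlates_perfectly(self):
        ts = generate_sine_signals([0.3, 0.3], [1, 1], OMEGA, 2000, DT, seed=0)
        assert _corr(ts, 0, 1) == pytest.approx(1.0, abs=1e-9)

    def test_quadrature_phases_uncorrelated(self):
        ts = generate_sine_signals([0.0, np.pi / 2], [1, 1], OMEGA, 2000, DT, seed=0)
        assert _corr(ts, 0, 1) == pytest.approx(0.0, abs=1e-9)

    def test_antiphase_anticorrelated(self):
        ts = generate_sine_signals([0.0, np.pi], [1, 1], OMEGA, 2000, DT, seed=0)
        assert _corr(ts, 0, 1) == pytest.approx(-1.0, abs=1e-9)

    def test_jitter_mixture_matches_closed_form(self):
        """corr ~= j_c j_d cos(dtheta); Monte-Carlo across seeds vs 0.5."""
        vals = [
            _corr(generate_sine_signals([0.7, 0.7], [0.5, 1.0], OMEGA, 20000, DT, seed=s), 0, 1)
            for s in range(12)
        ]
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.5) < 3 * max(se, 1e-4)

    def test_jitter_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="jitters"):
            generate_sine_signals([0, 0], [0.5, 1.2], OMEGA, 2000, DT)

    def test_too_short_span_rejected(self):
        with pytest.raises(ValueError, match="periods"):
            generate_sine_signals([0, 0], [1, 1], OMEGA, 50, DT)

    def test_seeded_determinism(self):
        a = generate_sine_signals([0, 1], [0.5, 0.5], OMEGA, 500, DT, seed=4)
        b = generate_sine_signals([0, 1], [0.5, 0.5], OMEGA, 500, DT, seed=4)
        assert np.array_equal(a.values, b.values)


class TestPearsonFC:
    def test_sign_flip_gives_minus_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        ts = TimeSeriesMatrix(np.stack([x, -x]), dt=1.0)
        assert pearson_fc(ts).values[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_covariance_ratio_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((3, 50))
        got = pearson_fc(TimeSeriesMatrix(x, dt=1.0)).values
        for c in range(3):
            for d in range(3):
                xc, xd = x[c] - x[c].mean(), x[d] - x[d].mean()
                want = np.sum(xc * xd) / np.sqrt(np.sum(xc**2) * np.sum(xd**2))
                assert got[c, d] == pytest.approx(want, abs=1e-12)

    def test_zero_variance_row_named(self):
        x = np.vstack([np.ones(50), np.arange(50.0)])
        with pytest.raises(ValueError, match="region 0"):
            pearson_fc(TimeSeriesMatrix(x, dt=1.0))


class TestAnalyticSignal:
    def test_cosine_maps_to_sine(self):
        t = np.arange(1000) * DT
        ts = TimeSeriesMatrix(np.cos(OMEGA * t)[None, :], dt=DT)
        xa = analytic_signal(ts)
        assert np.max(np.abs(xa.imag[0] - np.sin(OMEGA * t))) < 1e-6

    def test_real_part_is_input(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((2, 256))
        xa = analytic_signal(TimeSeriesMatrix(x, dt=1.0))
        assert np.allclose(xa.real, x, atol=1e-10)

    def test_unit_sinusoid_has_unit_envelope_in_interior(self):
        t = np.arange(2000) * DT
        ts = TimeSeriesMatrix(np.sin(OMEGA * t)[None, :], dt=DT)
        env = np.abs(analytic_signal(ts))[0]
        interior = env[100:-100]
        assert np.max(np.abs(interior - 1.0)) < 1e-3


class TestPLV:
    def test_identical_rows_lock_perfectly(self):
        t = np.arange(1000) * DT
        x = np.sin(OMEGA * t)
        p = plv(TimeSeriesMatrix(np.stack([x, x]), dt=DT))
        assert p[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_constant_offset_locks(self):
        t = np.arange(2000) * DT
        x = np.stack([np.sin(OMEGA * t), np.sin(OMEGA * t + 1.1)])
        p = plv(TimeSeriesMatrix(x, dt=DT))
        assert p[0, 1] == pytest.approx(1.0, abs=1e-3)

    def test_amplitude_invariance_and_bounds(self):
        ts = generate_sine_signals([0, 1, 2], [0.8, 0.6, 0.9], OMEGA, 1000, DT, seed=3)
        p1 = plv(ts)
        scaled = ts.values.copy()
        scaled[1] *= 7.5
        p2 = plv(TimeSeriesMatrix(scaled, dt=ts.dt))
        assert np.allclose(p1, p2, atol=1e-12)
        assert np.all((p1 >= 0) & (p1 <= 1))

    def test_independent_narrowband_signals_match_simulation_oracle(self):
        """PLV of independent random-phase signals vs a direct MC oracle."""
        def one(seed):
            rng = np.random.default_rng(seed)
            t = np.arange(1000) * DT
            x = np.stack([
                np.sin(OMEGA * t + rng.uniform(0, TWO_PI))
                + 0.5 * rng.standard_normal(1000),
                np.sin(1.13 * OMEGA * t + rng.uniform(0, TWO_PI))
                + 0.5 * rng.standard_normal(1000),
            ])
            return plv(TimeSeriesMatrix(x, dt=DT))[0, 1]

        obs = np.array([one(s) for s in range(24)])
        oracle = np.array([one(1000 + s) for s in range(200)])
        se = oracle.std(ddof=1) / np.sqrt(len(obs))
        assert abs(obs.mean() - oracle.mean()) < 3 * se


class TestModelConsistency:
    def test_fc_converges_to_cosine_of_phase_difference(self):
        """The core identity: unit-jitter sine FC -> cos(dtheta) at large T."""
        rng = np.random.default_rng(8)
        phases = rng.uniform(0, TWO_PI, 10)
        ts = generate_sine_signals(phases, np.ones(10), OMEGA, 10000, DT, seed=1)
        fc = pearson_fc(ts).values
        want = np.cos(phases[:, None] - phases[None, :])
        off = ~np.eye(10, dtype=bool)
        assert np.max(np.abs(fc - want)[off]) < 0.02

    def test_full_pipeline_closure(self):
        """FC simulated from known (theta, j) is recovered by the fitting module."""
        rng = np.random.default_rng(9)
        phases = rng.uniform(0, TWO_PI, 12)
        jitters = rng.uniform(0.6, 1.0, 12)
        ts = generate_sine_signals(phases, jitters, OMEGA, 10000, DT, seed=2)
        fc = pearson_fc(ts)
        dec = fit(fc, FitConfig(seed=3))
        assert dec.final_loss < 0.05
        got = np.cos(dec.basis.phases[0][:, None] - dec.basis.phases[0][None, :])
        want = np.cos(phases[:, None] - phases[None, :])
        off = ~np.eye(12, dtype=bool)
        assert np.max(np.abs(got - want)[off]) < 0.05

    def test_timeseries_validation(self):
        with pytest.raises(ValueError, match="at least 4"):
            TimeSeriesMatrix(np.zeros((2, 3)), dt=1.0)
        with pytest.raises(ValueError, match="dt"):
            TimeSeriesMatrix(np.zeros((2, 10)), dt=0.0)
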