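import numpy as np
import pytest
from scipy.signal import butter, sosfiltfilt

from castates.fitting import ScoreConfig, score
from castates.preprocess import (
    CalciumTrace,
    CalibrationError,
    calibrate,
    extract_features,
    noise_floor,
    smooth,
)


class TestCalibrate:
    def test_fmin_maps_to_zero(self):
        assert calibrate(np.array([100.0]), kd=0.345, fmin=100, fmax=900)[0] == 0.0

    def test_midpoint_maps_to_kd(self):
        mid = np.array([(100.0 + 900.0) / 2])
        assert calibrate(mid, kd=0.345, fmin=100, fmax=900)[0] == pytest.approx(0.345)

    def test_near_fmax_diverges(self):
        # F = Fmax - eps evaluates to Kd*(Fmax-eps-Fmin)/eps
        kd, fmin, fmax, eps = 0.345, 100.0, 900.0, 1e-3
        got = calibrate(np.array([fmax - eps]), kd, fmin, fmax)[0]
        assert got == pytest.approx(kd * (fmax - eps - fmin) / eps, rel=1e-9)

    def test_f_at_fmax_errors_without_clamp(self):
        with pytest.raises(CalibrationError):
            calibrate(np.array([900.0]), 0.345, 100, 900)

    def test_clamp_mode(self):
        got = calibrate(np.array([950.0]), 0.345, 100, 900, clamp=True)
        assert np.isfinite(got[0]) and got[0] > 0

    def test_strictly_increasing_on_open_interval(self):
        f = np.linspace(101, 899, 200)
        ca = calibrate(f, 0.345, 100, 900)
        assert np.all(np.diff(ca) > 0)

    def test_requires_fmin_below_fmax(self):
        with pytest.raises(ValueError):
            calibrate(np.array([1.0]), 0.345, 5.0, 5.0)


class TestSmooth:
    def test_constant_passes(self):
        tr = CalciumTrace(values=np.full(64, 3.7), dt=2.0)
        out = smooth(tr, cutoff=0.05)
        assert np.allclose(out.values, 3.7, atol=1e-9)

    def test_same_grid(self):
        tr = CalciumTrace(values=np.random.default_rng(0).random(50), dt=2.0)
        out = smooth(tr)
        assert len(out) == len(tr) and out.dt == tr.dt

    def test_supra_cutoff_sinusoid_attenuated(self):
        # 0.2 Hz sine vs 0.05 Hz cutoff: analytic |H|^2 = 1.24e-4,
        # far beyond the required 90% attenuation
        t = np.arange(200) * 2.0
        tr = CalciumTrace(values=2.0 + np.sin(2 * np.pi * 0.2 * t), dt=2.0)
        out = smooth(tr, cutoff=0.05).values - 2.0
        assert np.abs(out[20:-20]).max() < 0.1

    def test_zero_phase_on_passband_sinusoid(self):
        # well below cutoff the signal passes with no shift
        t = np.arange(400) * 2.0
        x = np.sin(2 * np.pi * 0.005 * t)
        tr = CalciumTrace(values=x + 2.0, dt=2.0)
        out = smooth(tr, cutoff=0.05).values - 2.0
        lag = np.argmax(np.correlate(out[50:-50], x[50:-50], "full"))
        assert lag == len(x[50:-50]) - 1  # zero-lag peak

    def test_reflective_padding_preserves_sharp_onset(self):
        # truncated calcium traces start with basal then a sharp rise;
        # mirror padding keeps that edge, unpadded filtering damps it
        rise = np.ones(100)
        rise[0] = 0.0
        tr = CalciumTrace(values=rise, dt=2.0)
        padded = smooth(tr, cutoff=0.05).values
        sos = butter(2, 0.05 / 0.25, btype="low", output="sos")
        unpadded = sosfiltfilt(sos, rise, padtype=None)
        assert padded[0] == 0.0                 # basal point kept verbatim
        assert padded[1] > 0.8                  # rise survives
        assert abs(unpadded[0] - 0.0) > 0.3     # edge artifact without padding

    def test_idempotent_within_one_percent(self):
        rng = np.random.default_rng(1)
        x = 1.0 + 0.01 * np.cumsum(rng.normal(size=150))
        once = smooth(CalciumTrace(values=x, dt=2.0), cutoff=0.05)
        twice = smooth(once, cutoff=0.05)
        rel = (np.sqrt(np.mean((twice.values - once.values) ** 2))
               / np.sqrt(np.mean(once.values ** 2)))
        assert rel < 0.01

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            smooth(CalciumTrace(values=np.ones(4), dt=2.0))


class TestNoiseFloor:
    def _score(self, a, b):
        return score(a, b, ScoreConfig(deriv_weight=1.0))

    def test_identical_gives_zero(self):
        tr = CalciumTrace(values=np.linspace(0, 1, 50), dt=2.0)
        assert noise_floor(tr, tr, self._score) == 0.0

    def test_monotone_in_noise_sd(self):
        rng = np.random.default_rng(2)
        base = np.linspace(0.05, 0.8, 120)
        floors = []
        for sigma in (0.01, 0.1, 1.0):
            raw = CalciumTrace(values=base + rng.normal(0, sigma, 120), dt=2.0)
            proc = CalciumTrace(values=base, dt=2.0)
            floors.append(noise_floor(raw, proc, self._score))
        assert floors[0] < floors[1] < floors[2]

    def test_population_floors_positive(self, short_protocol, regimes):
        from castates.pipeline import preprocess_cell
        from castates.synthetic import (NoiseSpec, render_traces,
                                        sample_population)
        rng = np.random.default_rng(3)
        thetas, labels = sample_population(regimes, 8, rng)
        traces, _ = render_traces(
            thetas, short_protocol,
            NoiseSpec(sigma_meas=0.02, hf_amp=0.02, seed=4),
            regimes=regimes, labels=labels)
        floors = [preprocess_cell(t, 0.1, ScoreConfig())[1] for t in traces]
        assert all(f > 0 for f in floors)

    def test_grid_mismatch(self):
        a = CalciumTrace(values=np.ones(10), dt=2.0)
        b = CalciumTrace(values=np.ones(11), dt=2.0)
        with pytest.raises(ValueError):
            noise_floor(a, b, self._score)


class TestFeatures:
    def test_triangle_pulse_geometry(self):
        # rise 0 -> 1 over 10 s, fall back to 0 over 20 s, dt = 1 s
        up = np.linspace(0, 1, 11)
        down = np.linspace(1, 0, 21)[1:]
        tr = CalciumTrace(values=np.concatenate([up, down, np.zeros(30)]),
                          dt=1.0)
        f = extract_features(tr, tail_fraction=0.1)
        assert f.t50u == pytest.approx(5.0)
        assert f.tm == pytest.approx(10.0)
        assert f.t50d == pytest.approx(10.0)
        assert f.fm == pytest.approx(1.0)
        assert f.f0 == pytest.approx(0.0)
        assert f.responder and not f.plateau

    def test_constant_trace_flagged(self):
        f = extract_features(CalciumTrace(values=np.full(50, 0.3), dt=1.0))
        assert not f.responder
        assert np.isnan(f.t50u) and np.isnan(f.tm)

    def test_plateau_flagged(self):
        x = np.concatenate([[0.0], np.ones(49)])
        f = extract_features(CalciumTrace(values=x, dt=1.0))
        assert f.plateau
        assert f.t50d == pytest.approx(49.0 - f.tm)

    def test_fm_at_least_f0(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.random(30)
            f = extract_features(CalciumTrace(values=x, dt=1.0))
            assert f.fm >= f.f0

    def test_invariant_to_filtered_noise(self, short_protocol):
        # features of a simulated reference trace survive noise + smoothing
        from castates.model import simulate
        ca = simulate(np.zeros(17), short_protocol, 0.05)
        post = ca[short_protocol.stim_index():]
        clean = CalciumTrace(values=post, dt=short_protocol.dt_out)
        f_clean = extract_features(smooth(clean, cutoff=0.05))
        rng = np.random.default_rng(5)
        t = np.arange(len(post)) * short_protocol.dt_out
        noisy = post + 0.01 * rng.normal(size=len(post)) \
            + 0.01 * np.sin(2 * np.pi * 0.2 * t)
        f_noisy = extract_features(
            smooth(CalciumTrace(values=noisy, dt=short_protocol.dt_out),
                   cutoff=0.05))
        dt = short_protocol.dt_out
        assert abs(f_noisy.tm - f_clean.tm) <= dt
        assert abs(f_noisy.t50u - f_clean.t50u) <= dt
        assert abs(f_noisy.t50d - f_clean.t50d) <= dt
        assert f_noisy.fm == pytest.approx(f_clean.fm, rel=0.05)


class TestCalibrationProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(min_value=101.0, max_value=899.0),
                    min_size=2, max_size=50),
           st.floats(min_value=0.01, max_value=10.0))
    @settings(max_examples=50, deadline=None)
    def test_calibration_inverts(self, fs, kd):
        # Ca -> F -> Ca round trip is the identity on (Fmin, Fmax)
        fmin, fmax = 100.0, 900.0
        f = np.array(fs)
        ca = calibrate(f, kd, fmin, fmax)
        f_back = (fmin * kd + fmax * ca) / (kd + ca)
        np.testing.assert_allclose(f_back, f, rtol=1e-9)

    @given(st.floats(min_value=100.0001, max_value=899.0),
           st.floats(min_value=0.5, max_value=10.0))
    @settings(max_examples=50, deadline=None)
    def test_calibration_monotone_step(self, f, delta):
        fmin, fmax = 100.0, 900.0
        lo, hi = calibrate(np.array([f, min(f + delta, 899.5)]),
                           0.345, fmin, fmax)
        assert hi >= lo
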