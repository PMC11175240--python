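"""Gait indexes against brute-force oracles and analytic limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs
from hypothesis.extra import numpy as hnp

import oracles
from gaitbalance import indexes, simdata
from gaitbalance.indexes import (
    DegenerateInputError, EmbeddingParams, HarmonicSpectrum, ami_delay,
    average_mutual_information, cv_step_length, extract_all, fnn_dimension,
    fnn_fraction, harmonic_ratio, recurrence_quantify, stride_harmonics,
)


def _tone_signal(freq_mult: float, n_strides: int = 10, fs: float = 100.0):
    """Noise-free cosine at a multiple of a 1 Hz stride frequency."""
    t = np.arange(int(n_strides * fs) + 1) / fs
    x = np.cos(2 * np.pi * freq_mult * t)
    events = np.arange(0, n_strides + 1) * int(fs)
    return simdata.TrunkSignal(t=t, acc_AP=x, acc_ML=x.copy(), acc_V=x.copy(),
                               stride_events=events, fs=fs)


class TestStrideHarmonics:
    @pytest.mark.parametrize("mult,peak", [(1, 0), (2, 1)])
    def test_single_tone_peaks_at_its_harmonic(self, mult, peak):
        spectra = stride_harmonics(_tone_signal(mult), "AP", filter_mode=None)
        for s in spectra:
            assert s.amplitudes[peak] == pytest.approx(1.0, abs=1e-6)
            rest = np.delete(s.amplitudes, peak)
            assert np.all(rest < 1e-6)

    def test_matches_brute_force_projection(self):
        rng = np.random.default_rng(0)
        sig = simdata.simulate_trunk_signal(simdata.SignalParams(seed=1, n_strides=6))
        spectra = stride_harmonics(sig, "AP", filter_mode=None)
        x = sig.acc_AP
        for s in spectra:
            a, b = sig.stride_events[s.stride_index], sig.stride_events[s.stride_index + 1]
            seg = indexes._resample_stride(x[a: b + 1], 100)
            brute = oracles.brute_fourier_amplitudes(seg, 20)
            np.testing.assert_allclose(s.amplitudes, brute, rtol=1e-8, atol=1e-10)

    def test_parseval_energy_identity(self):
        """Total harmonic energy equals the AC time-domain energy of each
        resampled stride (relative error < 1e-6)."""
        sig = simdata.simulate_trunk_signal(
            simdata.SignalParams(seed=2, n_strides=5, noise_sd=0.0))
        x = sig.acc_AP
        for k in range(sig.n_strides):
            a, b = sig.stride_events[k], sig.stride_events[k + 1]
            seg = indexes._resample_stride(x[a: b + 1], 100)
            X = np.fft.rfft(seg)
            # all non-DC bins, not just the first 20 harmonics
            amps = 2.0 * np.abs(X[1:]) / 100
            amps[-1] /= 2 ** 0.5 if len(seg) % 2 == 0 else 1.0
            spectral = np.sum(amps**2) / 2.0
            temporal = np.mean((seg - seg.mean()) ** 2)
            assert spectral == pytest.approx(temporal, rel=1e-6)

    def test_no_strides_errors(self):
        sig = _tone_signal(1, n_strides=3)
        short = simdata.TrunkSignal(t=sig.t[:30], acc_AP=sig.acc_AP[:30],
                                    acc_ML=sig.acc_ML[:30], acc_V=sig.acc_V[:30],
                                    stride_events=np.array([0, 29]), fs=100.0)
        with pytest.raises(DegenerateInputError):
            stride_harmonics(short, "AP")


class TestHarmonicRatio:
    def _spectrum(self, a1=0.0, a2=0.0, axis="AP"):
        amps = np.zeros(20)
        amps[0], amps[1] = a1, a2
        return HarmonicSpectrum(amps, axis=axis, stride_index=0)

    def test_hand_computed_ratios(self):
        assert harmonic_ratio([self._spectrum(0.1, 1.0)]) == pytest.approx(10.0)
        assert harmonic_ratio([self._spectrum(0.1, 1.0, "ML")]) == pytest.approx(0.1)
        assert harmonic_ratio([self._spectrum(a1=1.0, a2=0.0)]) == 0.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(hnp.arrays(np.float64, 20,
                      elements=hs.floats(min_value=0.01, max_value=10.0)))
    def test_ap_and_ml_conventions_are_inverse(self, amps):
        ap = harmonic_ratio([HarmonicSpectrum(amps, "AP", 0)])
        ml = harmonic_ratio([HarmonicSpectrum(amps, "ML", 0)])
        assert ap * ml == pytest.approx(1.0)

    def test_all_denominators_zero_errors(self):
        # AP denominator is the odd-harmonic sum, zero here
        with pytest.raises(DegenerateInputError):
            harmonic_ratio([self._spectrum(a1=0.0, a2=1.0, axis="AP")])


class TestCvStepLength:
    def test_hand_cases(self):
        assert cv_step_length([0.6, 0.6, 0.6, 0.6]) == 0.0
        assert cv_step_length([1, 1, 1, 3]) == pytest.approx(66.6667, abs=0.01)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(hnp.arrays(np.float64, 30,
                      elements=hs.floats(min_value=0.1, max_value=2.0)),
           hs.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, steps, scale):
        assert cv_step_length(scale * steps) == pytest.approx(
            cv_step_length(steps), rel=1e-9)

    def test_errors(self):
        with pytest.raises(DegenerateInputError):
            cv_step_length([0.5])
        with pytest.raises(DegenerateInputError):
            cv_step_length([-1.0, 1.0])


class TestAmi:
    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        x = np.cumsum(rng.standard_normal(500))
        lags = [0, 3, 7, 12, 18]
        mine = average_mutual_information(x, lags)
        for lag, val in zip(lags, mine):
            assert val == pytest.approx(oracles.brute_ami(x, lag), abs=1e-10)

    def test_lag_zero_is_maximal(self):
        rng = np.random.default_rng(5)
        x = np.sin(np.arange(600) * 0.21) + 0.1 * rng.standard_normal(600)
        vals = average_mutual_information(x, list(range(0, 19)))
        assert np.all(vals[1:] <= vals[0] + 1e-12)

    def test_pipeline_signals_give_delay_in_range(self):
        for label in ("pwCA", "HS"):
            sig, _ = simdata.subject_signal(label, seed=0, n_strides=25)
            series = indexes.time_normalize(sig, "AP")
            tau = ami_delay(series)
            assert 7 <= tau <= 18

    def test_constant_series_errors(self):
        with pytest.raises(DegenerateInputError):
            ami_delay(np.ones(500))


class TestFnn:
    def test_sinusoid_embeds_in_the_plane(self):
        t = np.arange(3000)
        x = np.sin(2 * np.pi * t / 400)
        assert fnn_dimension(x, tau=100) == 2

    def test_lorenz_needs_three_dimensions(self):
        lor = simdata._lorenz_series(5000, 0.01, np.random.default_rng(0))
        assert fnn_dimension(lor, tau=11) == 3

    def test_fraction_non_increasing_in_m(self):
        lor = simdata._lorenz_series(4000, 0.01, np.random.default_rng(1))
        fracs = [fnn_fraction(lor, m, 11) for m in range(2, 7)]
        assert all(b <= a + 1e-9 for a, b in zip(fracs, fracs[1:]))


class TestRqa:
    def test_constant_series_fully_recurrent(self):
        _, rec, det = recurrence_quantify(np.ones(60), EmbeddingParams(m=2, tau=1),
                                          literal=True)
        assert rec == 100.0
        assert det > 99.5  # the two corner cells are single-point lines

    def test_iid_points_tiny_radius_no_recurrence(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(120)
        _, rec, det = recurrence_quantify(x, EmbeddingParams(m=3, tau=2),
                                          radius=1e-9)
        assert rec == 0.0
        assert det == 0.0

    def test_matches_brute_force_oracle_on_random_instances(self):
        """Exact agreement with an O(N^2) + line-scan oracle, 100 instances."""
        rng = np.random.default_rng(3)
        for trial in range(100):
            n = int(rng.integers(40, 160))
            m = int(rng.integers(2, 4))
            tau = int(rng.integers(1, 4))
            kind = trial % 3
            if kind == 0:
                x = np.sin(2 * np.pi * np.arange(n) / rng.integers(10, 30))
            elif kind == 1:
                x = rng.standard_normal(n)
            else:
                x = np.cumsum(rng.standard_normal(n))
            params = EmbeddingParams(m=m, tau=tau, theiler=int(rng.integers(0, 4)))
            literal = bool(rng.integers(0, 2))
            rp, rec, det = recurrence_quantify(x, params, recurrence_rate=0.05,
                                               literal=literal)
            orec, odet = oracles.brute_rqa(x, m, tau, rp.radius,
                                           params.theiler_window,
                                           literal=literal)
            assert rec == pytest.approx(orec, abs=1e-9)
            assert det == pytest.approx(odet, abs=1e-9)

    def test_periodic_signal_highly_deterministic(self):
        x = np.sin(2 * np.pi * np.arange(300) / 25)
        _, rec, det = recurrence_quantify(x, EmbeddingParams(m=3, tau=5))
        assert det > 90.0
        assert rec == pytest.approx(2.5, abs=1.0)

    def test_explicit_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            recurrence_quantify(np.sin(np.arange(100.0)), radius=-1.0)


class TestSlle:
    def test_periodic_signal_is_locally_stable(self):
        p = simdata.SignalParams(noise_sd=0.0, stride_time_cv=0.0,
                                 instability_gain=0.0, n_strides=22, seed=3)
        sig = simdata.simulate_trunk_signal(p)
        assert abs(indexes.slle_rosenstein(sig, "AP")) < 0.02

    def test_monotone_in_instability_gain(self):
        """Mean sLLE strictly increases along the chaos-gain sweep (10 seeds)."""
        means = []
        for gain in (0.0, 0.25, 0.5):
            vals = []
            for seed in range(10):
                sig = simdata.simulate_trunk_signal(simdata.SignalParams(
                    instability_gain=gain, n_strides=20, seed=seed))
                vals.append(indexes.slle_rosenstein(sig, "AP"))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_lorenz_matches_benettin_oracle(self):
        lor = simdata._lorenz_series(8000, 0.01, np.random.default_rng(0))
        lam = indexes.lyapunov_rosenstein(lor, m=3, tau=11, theiler=150,
                                          fit_steps=(100, 300), dt=0.01)
        ref = oracles.benettin_lle()
        assert abs(lam - ref) / ref < 0.15

    def test_too_few_strides_errors(self):
        sig = simdata.simulate_trunk_signal(simdata.SignalParams(n_strides=5, seed=0))
        with pytest.raises(DegenerateInputError):
            indexes.slle_rosenstein(sig, "AP")


class TestExtractAll:
    CFG = indexes.ExtractConfig(compute_rqa=False, compute_slle=False)

    def test_deterministic(self):
        sig, steps = simdata.subject_signal("HS", seed=0, n_strides=20)
        a = extract_all(sig, steps, self.CFG)
        b = extract_all(sig, steps, self.CFG)
        assert a.as_dict() == b.as_dict()

    def test_class_presets_order_correctly(self):
        """Healthy presets produce higher HR_AP and lower step-length CV."""
        hr = {lab: [] for lab in ("pwCA", "HS")}
        cv = {lab: [] for lab in ("pwCA", "HS")}
        for lab in ("pwCA", "HS"):
            for seed in range(30):
                sig, steps = simdata.subject_signal(lab, seed=seed, n_strides=12)
                ix = extract_all(sig, steps, self.CFG)
                hr[lab].append(ix.HR_AP)
                cv[lab].append(ix.CV_steplength)
        assert np.mean(hr["HS"]) > np.mean(hr["pwCA"])
        assert np.mean(cv["pwCA"]) > np.mean(cv["HS"])

    def test_full_extraction_populates_all_indexes(self):
        sig, steps = simdata.subject_signal("HS", seed=1, n_strides=20)
        ix = extract_all(sig, steps)
        assert ix.missing == ()
        assert all(v is not None for v in ix.as_dict().values())
        assert 0 <= ix.RQArec <= 100 and 0 <= ix.RQAdet <= 100

    def test_missing_stride_events_error(self):
        sig, steps = simdata.subject_signal("HS", seed=1, n_strides=5)
        empty = simdata.TrunkSignal(t=sig.t, acc_AP=sig.acc_AP, acc_ML=sig.acc_ML,
                                    acc_V=sig.acc_V, stride_events=np.array([0]),
                                    fs=sig.fs)
        with pytest.raises(DegenerateInputError):
            extract_all(empty, steps, self.CFG)
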