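"""Signal conditioning: filter frequency response, resampling accuracy,
and scaler semantics."""

import numpy as np
import pytest

from swimlap.activities import ImuRecording
from swimlap.preprocess import (
    ChannelScaler,
    apply_scaler,
    butterworth_lowpass,
    fit_scaler,
    preprocess,
    resample_to,
)


def _rec(samples, rate=280.0, **kw):
    return ImuRecording(samples, sample_rate=rate, **kw)


def _sine_rec(freq, rate=280.0, dur=20.0):
    t = np.arange(int(dur * rate)) / rate
    x = np.sin(2 * np.pi * freq * t)
    return _rec(np.tile(x[:, None], (1, 6)), rate=rate), x


def _steady_amplitude(y):
    """Peak amplitude of the middle half of a signal (edge effects excluded)."""
    n = y.size
    return np.abs(y[n // 4 : 3 * n // 4]).max()


class TestButterworth:
    def test_unit_dc_gain(self):
        rec = _rec(np.ones((1000, 6)))
        out = butterworth_lowpass(rec)
        assert np.allclose(out.samples, 1.0, atol=1e-9)

    @pytest.mark.parametrize("freq,expected,atol", [
        # zero-phase application squares the single-pass magnitude response
        # |H(f)|^2 = 1 / (1 + (f/fc)^(2*order)); at the 10 Hz cutoff: 0.5
        (10.0, 0.50, 0.02),
        (100.0, 1.0 / (1.0 + (100.0 / 10.0) ** 4), 0.01),
    ])
    def test_frequency_response_matches_analog_prototype(self, freq, expected, atol):
        rec, _ = _sine_rec(freq)
        out = butterworth_lowpass(rec, cutoff_hz=10.0, order=2)
        ratio = _steady_amplitude(out.samples[:, 0])
        assert ratio == pytest.approx(expected, abs=atol)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        rec = _rec(np.zeros((100, 6)) + 1.0)
        with pytest.raises(ValueError, match="Nyquist"):
            butterworth_lowpass(rec, cutoff_hz=140.0)


class TestResample:
    def test_duration_arithmetic(self):
        rec = _rec(np.random.default_rng(0).normal(size=(2800, 6)))
        out = resample_to(rec, 50.0)
        assert out.n_frames == 500
        assert out.sample_rate == 50.0

    def test_constant_preserved(self):
        rec = _rec(np.full((560, 6), 3.25))
        out = resample_to(rec, 50.0)
        assert np.allclose(out.samples, 3.25)

    def test_sinusoid_against_analytic_oracle(self):
        rec, _ = _sine_rec(1.0, dur=10.0)
        out = resample_to(rec, 50.0)
        expected = np.sin(2 * np.pi * 1.0 * np.arange(out.n_frames) / 50.0)
        assert np.abs(out.samples[:, 0] - expected).max() < 1e-3

    def test_upsampling_rejected(self):
        rec = _rec(np.zeros((100, 6)) + 1.0, rate=50.0)
        with pytest.raises(ValueError, match="upsampling"):
            resample_to(rec, 280.0)


class TestScaler:
    def test_two_value_channel(self):
        rec = _rec(np.array([[1.0] * 6, [3.0] * 6]), rate=50.0)
        scaler = fit_scaler([rec])
        assert np.allclose(scaler.means, 2.0)
        assert np.allclose(scaler.sds, np.sqrt(2.0))  # ddof=1

    def test_idempotence_on_standardised_data(self, rng):
        rec = _rec(rng.normal(2.0, 3.0, size=(500, 6)), rate=50.0)
        z = apply_scaler(rec, fit_scaler([rec]))
        refit = fit_scaler([z])
        assert np.allclose(refit.means, 0.0, atol=1e-9)
        assert np.allclose(refit.sds, 1.0, atol=1e-9)

    def test_pooled_fit_equals_concatenation_oracle(self, rng):
        a = _rec(rng.normal(size=(300, 6)), rate=50.0)
        b = _rec(rng.normal(1.0, 2.0, size=(200, 6)), rate=50.0)
        pooled = fit_scaler([a, b])
        concat = _rec(np.vstack([a.samples, b.samples]), rate=50.0)
        oracle = fit_scaler([concat])
        assert np.allclose(pooled.means, oracle.means)
        assert np.allclose(pooled.sds, oracle.sds)

    def test_apply_examples(self):
        scaler = ChannelScaler(np.full(6, 5.0), np.full(6, 2.0))
        rec = _rec(np.full((10, 6), 7.0), rate=50.0)
        out = apply_scaler(rec, scaler)
        assert np.allclose(out.samples, 1.0)
        assert out.preprocessed
        ident = ChannelScaler(np.zeros(6), np.ones(6))
        assert np.allclose(apply_scaler(rec, ident).samples, rec.samples)

    def test_apply_then_invert_recovers_input(self, rng):
        rec = _rec(rng.normal(size=(100, 6)), rate=50.0)
        scaler = fit_scaler([rec])
        z = apply_scaler(rec, scaler)
        back = z.samples * scaler.sds + scaler.means
        assert np.abs(back - rec.samples).max() < 1e-12

    def test_zero_variance_channel_rejected(self):
        x = np.random.default_rng(0).normal(size=(50, 6))
        x[:, 2] = 4.0
        with pytest.raises(ValueError, match="az"):
            fit_scaler([_rec(x, rate=50.0)])

    def test_channel_count_mismatch_rejected(self):
        scaler = ChannelScaler(np.zeros(4), np.ones(4))
        with pytest.raises(ValueError, match="mismatch"):
            apply_scaler(_rec(np.ones((5, 6))), scaler)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            ChannelScaler(np.zeros(6), np.zeros(6))


class TestPipeline:
    def test_linearity_before_standardisation(self, rng):
        x = rng.normal(size=(1400, 6))
        a = 3.7
        out1 = resample_to(butterworth_lowpass(_rec(x)), 50.0)
        out2 = resample_to(butterworth_lowpass(_rec(a * x)), 50.0)
        assert np.allclose(out2.samples, a * out1.samples, atol=1e-9)

    def test_end_to_end_order_and_rate(self, rng):
        rec = _rec(rng.normal(size=(2800, 6)))
        scaler_src = resample_to(butterworth_lowpass(rec), 50.0)
        scaler = fit_scaler([scaler_src])
        out = preprocess(rec, scaler)
        assert out.sample_rate == 50.0
        assert out.preprocessed
        # standardisation happened last: statistics on the output are ~(0, 1)
        assert np.allclose(out.samples.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(out.samples.std(axis=0, ddof=1), 1.0, atol=1e-9)
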