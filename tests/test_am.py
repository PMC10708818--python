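"""Filter design, zero-phase filtering, Hilbert envelopes, the validity
mask, and the two-stage AM decomposition."""

import numpy as np
import pytest
from scipy import signal as sps

from amdyn import (BandSpec, CANONICAL_BANK, am_decompose, design_band_filter,
                   hilbert_envelope, valid_am_pairs, zero_phase_filter)
from amdyn.filters import frequency_response

from conftest import make_epoch

FS = 256.0


class TestFilterDesign:
    @pytest.mark.parametrize("band, f_pass, f_stop", [
        (BandSpec("alpha", 8, 12), 10.0, 4.0),
        (BandSpec("delta", 1, 4), 2.5, None),
        (BandSpec("theta", 4, 8), 6.0, 12.0),
    ])
    def test_single_pass_response(self, band, f_pass, f_stop):
        taps = design_band_filter(band, FS)
        assert frequency_response(taps, [f_pass], FS)[0] >= 0.99
        if f_stop is not None:
            assert frequency_response(taps, [f_stop], FS)[0] <= 0.01

    def test_band_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            design_band_filter(BandSpec("bad", 100, 130), FS)

    def test_taps_symmetric_odd(self):
        taps = design_band_filter(BandSpec("beta", 12, 30), FS)
        assert len(taps) % 2 == 1
        np.testing.assert_allclose(taps, taps[::-1])


class TestZeroPhaseFilter:
    def test_zero_group_delay_on_passband_tone(self):
        taps = design_band_filter(BandSpec("alpha", 8, 12), FS)
        t = np.arange(int(8 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t)
        y = zero_phase_filter(x, taps)
        xc = np.correlate(x, y, mode="full")
        lag = np.argmax(xc) - (len(x) - 1)
        assert lag == 0
        r = np.corrcoef(x[256:-256], y[256:-256])[0, 1]
        assert r > 0.99

    def test_stopband_tone_suppressed(self):
        taps = design_band_filter(BandSpec("alpha", 8, 12), FS)
        t = np.arange(int(8 * FS)) / FS
        x = np.sin(2 * np.pi * 2 * t)
        y = zero_phase_filter(x, taps)
        interior = slice(int(FS), -int(FS))
        assert np.sqrt(np.mean(y[interior] ** 2)) < 0.01 * np.sqrt(
            np.mean(x[interior] ** 2))

    def test_zero_in_zero_out(self):
        taps = design_band_filter(BandSpec("alpha", 8, 12), FS)
        np.testing.assert_array_equal(
            zero_phase_filter(np.zeros(2000), taps), 0)

    def test_too_short_input(self):
        taps = design_band_filter(BandSpec("alpha", 8, 12), FS)
        with pytest.raises(ValueError, match="short"):
            zero_phase_filter(np.zeros(3 * len(taps)), taps)

    def test_matches_filtfilt_oracle(self):
        """Forward-backward convolution on an even-mirror-padded signal
        is exactly scipy's filtfilt with matching padding."""
        rng = np.random.default_rng(7)
        taps = design_band_filter(BandSpec("alpha", 8, 12), FS)
        for _ in range(5):
            x = rng.standard_normal(3 * len(taps) + 123)
            mine = zero_phase_filter(x, taps)
            oracle = sps.filtfilt(taps, [1.0], x, padtype="even",
                                  padlen=min(len(taps), len(x) - 1))
            rel = np.max(np.abs(mine - oracle)) / np.std(oracle)
            assert rel < 1e-8


class TestHilbertEnvelope:
    def test_constant_amplitude_tone(self):
        t = np.arange(int(8 * FS)) / FS
        A = 2.3
        env = hilbert_envelope(A * np.sin(2 * np.pi * 10 * t))
        interior = env[int(FS):-int(FS)]
        assert np.all(np.abs(interior - A) < 0.01 * A)

    def test_zero_signal(self):
        np.testing.assert_array_equal(hilbert_envelope(np.zeros(100)), 0)

    def test_recovers_am_envelope(self):
        t = np.arange(int(8 * FS)) / FS
        true_env = 1 + 0.5 * np.sin(2 * np.pi * 2 * t)
        env = hilbert_envelope(true_env * np.sin(2 * np.pi * 10 * t))
        interior = slice(int(FS), -int(FS))
        err = np.sqrt(np.mean((env[interior] - true_env[interior]) ** 2))
        assert err < 0.03 * np.sqrt(np.mean(true_env[interior] ** 2))

    def test_nonnegative(self):
        rng = np.random.default_rng(0)
        assert (hilbert_envelope(rng.standard_normal(1000)) >= 0).all()


class TestValidityMask:
    def test_canonical_bank_14_of_25(self):
        pairs = valid_am_pairs(CANONICAL_BANK)
        assert len(pairs) == 25
        valid = sorted(p.name for p in pairs if p.valid)
        assert len(valid) == 14
        assert valid == sorted([
            "delta_mdelta",
            "theta_mdelta", "theta_mtheta",
            "alpha_mdelta", "alpha_mtheta",
            "beta_mdelta", "beta_mtheta", "beta_malpha", "beta_mbeta",
            "gamma_mdelta", "gamma_mtheta", "gamma_malpha", "gamma_mbeta",
            "gamma_mgamma",
        ])

    def test_slow_carrier_fast_modulant_invalid(self):
        pairs = {p.name: p for p in valid_am_pairs(CANONICAL_BANK)}
        assert not pairs["delta_mgamma"].valid
        assert not pairs["delta_mtheta"].valid
        assert not pairs["alpha_mbeta"].valid

    def test_single_band_bank(self):
        pairs = valid_am_pairs((BandSpec("delta", 1, 4),))
        assert len(pairs) == 1 and pairs[0].valid  # f_lo 1 <= bandwidth 3

    def test_unordered_bank_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            valid_am_pairs((BandSpec("alpha", 8, 12), BandSpec("delta", 1, 4)))

    def test_gamma_mgamma_needs_override(self):
        pairs = {p.name: p for p in
                 valid_am_pairs(CANONICAL_BANK, overrides=frozenset())}
        assert not pairs["gamma_mgamma"].valid
        assert sum(p.valid for p in pairs.values()) == 13


class TestAMDecompose:
    def test_analytic_am_construction(self, am_epoch, fs):
        """10 Hz carrier with 2 Hz depth-0.5 AM: the alpha-mdelta series
        carries the 2 Hz envelope component; other alpha modulants are
        near-silent."""
        ams = am_decompose(am_epoch)
        interior = slice(int(2 * fs), -int(2 * fs))
        rms = {n: np.sqrt(np.mean(ams.series["C3"][n][interior] ** 2))
               for n in ams.pair_names}
        expected = 0.5 / np.sqrt(2)  # RMS of the 0.5 sin(2 pi 2 t) term
        assert abs(rms["alpha_mdelta"] - expected) < 0.1 * expected
        assert rms["alpha_mtheta"] < 0.2 * rms["alpha_mdelta"]

    def test_envelope_energy_concentrated_in_carrier_band(self, fs):
        t = np.arange(int(16 * fs)) / fs
        ep = make_epoch(np.sin(2 * np.pi * 10 * t), fs, channels=["C3"])
        ams = am_decompose(ep)
        means = {b: env.mean() for b, env in ams.envelopes["C3"].items()}
        for other in ("delta", "theta", "beta", "gamma"):
            assert means["alpha"] > 10 * means[other]

    def test_envelopes_nonnegative(self, am_epoch):
        ams = am_decompose(am_epoch)
        for env in ams.envelopes["C3"].values():
            assert (env >= 0).all()

    def test_zero_epoch(self, fs):
        ep = make_epoch(np.zeros(int(16 * fs)), fs)
        ams = am_decompose(ep)
        for s in ams.series["ch0"].values():
            np.testing.assert_array_equal(s, 0)

    def test_white_noise_all_14_series_alive(self, rng, fs):
        ep = make_epoch(rng.standard_normal(int(16 * fs)), fs)
        ams = am_decompose(ep)
        assert len(ams.series["ch0"]) == 14
        for s in ams.series["ch0"].values():
            assert np.isfinite(s).all() and np.any(s != 0)
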