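import numpy as np
import pandas as pd
import pytest
import scipy.signal

from qeeg.core import DISJOINT_BANDS
from qeeg.preprocess import EpochSet
from qeeg.spectral import (
    PSDSet, aggregate, band_power_absolute, band_power_linear,
    band_power_relative, band_power_table, export_topomap, multitaper_psd,
    multitaper_psd_array, spectral_ratios, total_power_linear,
)

FS = 512.0


def _epochs_from_channel_signal(montage, signal, fs=FS, n_epochs=None):
    n_samp = int(fs * 5)
    n_epochs = n_epochs or signal.size // n_samp
    data = signal[: n_epochs * n_samp].reshape(n_epochs, 1, n_samp)
    data = np.repeat(data, montage.n_channels, axis=1)
    return EpochSet(data=data, fs=fs, montage=montage)


def _flat_psd(montage, level=1.0, fmin=0.5, fmax=45.0, df=0.2):
    freqs = np.arange(np.ceil(fmin / df), np.floor(fmax / df) + 1) * df
    psd = np.full((montage.n_channels, freqs.size), level)
    return PSDSet(freqs=freqs, psd=psd, fs=FS, n_epochs_averaged=1,
                  montage=montage)


class TestMultitaperPSD:
    def test_white_noise_level_matches_welch_oracle(self, montage):
        rng = np.random.default_rng(0)
        sig = rng.standard_normal(int(FS * 180))
        eps = _epochs_from_channel_signal(montage, sig)
        psd = multitaper_psd(eps, 0.5, 45.0)
        # unit-variance white noise: flat density 1/(fs/2) = 1/256 uV^2/Hz
        assert np.abs(psd.psd.mean() - 1 / 256) < 0.1 / 256
        from qeeg.core import BandScheme

        scheme = BandScheme()
        f_w, p_w = scipy.signal.welch(sig, fs=FS, nperseg=2560)
        for band in DISJOINT_BANDS:
            mask = scheme.mask(psd.freqs, band)
            mt = psd.psd[0, mask].sum() * psd.df
            wmask = scheme.mask(f_w, band)
            welch = p_w[wmask].sum() * (f_w[1] - f_w[0])
            assert mt == pytest.approx(welch, rel=0.15)

    def test_sine_parseval(self, montage):
        rng = np.random.default_rng(1)
        t = np.arange(int(FS * 180)) / FS
        sig = np.sqrt(2) * np.sin(2 * np.pi * 10.0 * t) \
            + 1e-3 * rng.standard_normal(t.size)
        eps = _epochs_from_channel_signal(montage, sig)
        psd = multitaper_psd(eps, 0.5, 45.0)
        mask = (psd.freqs >= 9.0) & (psd.freqs <= 11.0)
        power = psd.psd[0, mask].sum() * psd.df
        assert power == pytest.approx(1.0, rel=0.05)

    def test_psd_nonnegative(self, montage):
        rng = np.random.default_rng(2)
        eps = _epochs_from_channel_signal(
            montage, rng.standard_normal(int(FS * 30)))
        psd = multitaper_psd(eps)
        assert (psd.psd >= 0).all()

    def test_matches_mne_implementation(self, montage, scheme):
        """Cross-check against MNE's multitaper estimator.

        MNE weights eigenspectra by their concentration eigenvalues while
        this package averages them unweighted; with NW=4 all retained
        eigenvalues are near 1, so band-integrated powers must agree
        closely.
        """
        from mne.time_frequency import psd_array_multitaper

        rng = np.random.default_rng(3)
        data = rng.standard_normal((4, 3, 1280))
        ours, freqs = multitaper_psd_array(data, 256.0, 0.5, 45.0, nw=4.0)
        theirs, f_mne = psd_array_multitaper(
            data, 256.0, fmin=0.5, fmax=45.0, bandwidth=2 * 4.0 / 5.0,
            adaptive=False, low_bias=True, normalization="full",
            verbose="error")
        assert np.allclose(freqs, f_mne)
        df = freqs[1] - freqs[0]
        for band in DISJOINT_BANDS:
            mask = scheme.mask(freqs, band)
            assert np.allclose((ours[..., mask]).sum(-1) * df,
                               (theirs[..., mask]).sum(-1) * df, rtol=0.05)

    def test_requires_kept_epochs(self, montage):
        eps = _epochs_from_channel_signal(montage, np.zeros(int(FS * 10)))
        eps.status[:] = "dropped_manual"
        with pytest.raises(ValueError):
            multitaper_psd(eps)


class TestBandPowers:
    def test_decibel_identities(self, montage, scheme):
        psd = _flat_psd(montage, level=1.0)
        # flat 1 uV^2/Hz over theta's 4 Hz -> 10*log10(4) ~ 6.02 dB
        assert band_power_absolute(psd, "theta", scheme)[0] == pytest.approx(
            10 * np.log10(4.0), abs=0.15)
        p = band_power_linear(psd, "theta", scheme)
        assert 10 * np.log10(1000.0) == pytest.approx(30.0)
        assert 10 * np.log10(1.0) == 0.0
        # dB of the integral itself round-trips
        assert band_power_absolute(psd, "theta", scheme)[0] \
            == pytest.approx(10 * np.log10(p[0]))

    def test_relative_powers_sum_to_100(self, montage, scheme):
        rng = np.random.default_rng(5)
        psd = _flat_psd(montage)
        psd.psd[:] = rng.uniform(0.1, 10.0, size=psd.psd.shape)
        total = sum(band_power_relative(psd, b, scheme)
                    for b in DISJOINT_BANDS)
        assert np.allclose(total, 100.0, atol=1e-6)

    def test_flat_psd_relative_theta(self, montage, scheme):
        psd = _flat_psd(montage)
        rel = band_power_relative(psd, "theta", scheme)
        assert rel[0] == pytest.approx(100 * 4.0 / 44.5, abs=0.3)

    def test_pure_tone_dominates_relative_power(self, montage, scheme):
        t = np.arange(int(FS * 60)) / FS
        rng = np.random.default_rng(6)
        sig = np.sin(2 * np.pi * 6.0 * t) \
            + 1e-3 * rng.standard_normal(t.size)  # noise floor -60 dB
        eps = _epochs_from_channel_signal(montage, sig)
        psd = multitaper_psd(eps)
        assert band_power_relative(psd, "theta", scheme)[0] > 99.0

    def test_low_plus_high_alpha_equals_alpha(self, montage, scheme):
        rng = np.random.default_rng(7)
        psd = _flat_psd(montage)
        psd.psd[:] = rng.uniform(0.1, 10.0, size=psd.psd.shape)
        la = band_power_relative(psd, "low_alpha", scheme)
        ha = band_power_relative(psd, "high_alpha", scheme)
        assert np.allclose(la + ha, band_power_relative(psd, "alpha", scheme))


class TestSpectralRatios:
    def test_flat_psd_ratios(self, montage):
        ratios = spectral_ratios(_flat_psd(montage))
        assert ratios["alpha_theta_ratio"].iloc[0] == pytest.approx(5 / 4,
                                                                    abs=0.02)
        assert ratios["spr"].iloc[0] == pytest.approx((5 + 17) / (3.5 + 4),
                                                      abs=0.05)

    def test_ratio_equals_relative_power_quotient(self, montage, scheme):
        rng = np.random.default_rng(8)
        psd = _flat_psd(montage)
        psd.psd[:] = rng.uniform(0.1, 10.0, size=psd.psd.shape)
        ratios = spectral_ratios(psd, scheme)
        rel_a = band_power_relative(psd, "alpha", scheme)
        rel_t = band_power_relative(psd, "theta", scheme)
        assert np.allclose(ratios["alpha_theta_ratio"], rel_a / rel_t)

    def test_band_additivity_is_exact(self, montage, scheme):
        rng = np.random.default_rng(9)
        psd = _flat_psd(montage)
        psd.psd[:] = rng.uniform(0.1, 10.0, size=psd.psd.shape)
        parts = sum(band_power_linear(psd, b, scheme) for b in DISJOINT_BANDS)
        assert np.allclose(parts, total_power_linear(psd, scheme), rtol=1e-12)

    def test_frequency_shift_flips_alpha_theta(self, montage, scheme):
        """Moving an oscillation from 6 to 10 Hz flips the ratio direction."""
        t = np.arange(int(FS * 30)) / FS
        rng = np.random.default_rng(10)
        noise = 0.05 * rng.standard_normal(t.size)
        ratios = {}
        for f in (6.0, 10.0):
            sig = np.sin(2 * np.pi * f * t) + noise
            psd = multitaper_psd(_epochs_from_channel_signal(montage, sig))
            ratios[f] = spectral_ratios(psd,
                                        scheme)["alpha_theta_ratio"].iloc[0]
            # 10 Hz sits on the low/high alpha edge, so check the full band
            rel = band_power_relative(
                psd, "theta" if f == 6.0 else "alpha", scheme)
            assert rel[0] > 50.0
        assert ratios[6.0] < 1.0 < ratios[10.0]


class TestAggregate:
    def test_constant_field(self, montage):
        values = np.full(19, 3.25)
        for scope in ("global", "occipital", ("temporal", "left")):
            assert aggregate(values, montage, scope) == pytest.approx(3.25)

    def test_singleton_region(self, montage):
        values = np.arange(19.0)
        expected = values[montage.index_of("O1")]
        assert aggregate(values, montage, ("occipital", "left")) == expected

    def test_global_is_mean_of_19(self, montage):
        rng = np.random.default_rng(11)
        values = rng.standard_normal(19)
        assert aggregate(values, montage, "global") == pytest.approx(
            values.mean())


class TestTopomapExport:
    def test_round_trip(self, montage, tmp_path):
        rng = np.random.default_rng(12)
        values = pd.Series(rng.standard_normal(19),
                           index=list(montage.channel_names))
        path = tmp_path / "map.csv"
        export_topomap(values, montage, path)
        back = pd.read_csv(path)
        assert len(back) == 19
        assert np.allclose(back["value"], values.to_numpy())
        for _, row in back.iterrows():
            assert np.allclose((row.x, row.y), montage.positions[row.channel])

    def test_missing_channel_rejected(self, montage, tmp_path):
        values = pd.Series(np.zeros(18),
                           index=list(montage.channel_names[:-1]))
        with pytest.raises(ValueError):
            export_topomap(values, montage, tmp_path / "map.csv")

    def test_render_png(self, montage, tmp_path):
        values = pd.Series(np.linspace(0, 1, 19),
                           index=list(montage.channel_names))
        png = tmp_path / "map.png"
        export_topomap(values, montage, tmp_path / "map.csv",
                       render=png)
        assert png.stat().st_size > 0


def test_band_power_table_schema(montage, scheme):
    rng = np.random.default_rng(13)
    eps = _epochs_from_channel_signal(
        montage, rng.standard_normal(int(FS * 30)))
    psd = multitaper_psd(eps)
    table = band_power_table(psd, scheme)
    assert list(table.index) == list(montage.channel_names)
    for band in scheme.bands:
        assert f"abs_{band}" in table.columns
        assert f"rel_{band}" in table.columns
    assert {"alpha_theta_ratio", "spr"} <= set(table.columns)
    rel_cols = [f"rel_{b}" for b in DISJOINT_BANDS]
    assert np.allclose(table[rel_cols].sum(axis=1), 100.0, atol=1e-6)
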