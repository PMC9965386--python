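"""Multitaper PSD estimation and band-power / ratio biomarkers.

Per subject, the PSD of every kept 5-s epoch is estimated with DPSS
(Slepian) multitapers and averaged over epochs, giving one spectrum per
channel on a 0.5-45 Hz grid.  From it:

* absolute band power: PSD integrated over the band, in dB re 1 uV^2;
* relative band power: the band integral as a percentage of the broadband
  (0.5-45 Hz) integral — the five disjoint bands sum to 100%;
* alpha/theta ratio: P_alpha / P_theta on linear power;
* SPR (spectral power ratio): (P_alpha + P_beta) / (P_delta + P_theta),
  a global slowing index.

Both ratios are identical whether computed from absolute or relative power
(the broadband normaliser cancels).  Channel-level values are aggregated by
arithmetic mean over the whole scalp ("global") or over (lateralised)
region channel sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.signal.windows import dpss

from .core import BandScheme, Montage1020, region_channels
from .preprocess import EpochSet

#: Default time-halfbandwidth product per epoch (NW); 2*NW-1 = 7 tapers.
DEFAULT_NW = 4.0


@dataclass
class PSDSet:
    """Per-channel power spectral density (uV^2/Hz) averaged over epochs."""

    freqs: np.ndarray
    psd: np.ndarray  # channels x frequencies
    fs: float
    n_epochs_averaged: int
    montage: Montage1020

    def __post_init__(self):
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.psd < 0):
            raise ValueError("PSD must be non-negative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@lru_cache(maxsize=8)
def _dpss_tapers(n_times: int, nw: float) -> np.ndarray:
    """Unit-energy DPSS tapers; tapers with concentration <= 0.9 dropped."""
    tapers, ratios = dpss(n_times, nw, Kmax=int(2 * nw - 1),
                          return_ratios=True, sym=False)
    keep = ratios > 0.9
    if not keep.any():
        keep[0] = True
    return tapers[keep]


def multitaper_psd_array(
    data: np.ndarray, fs: float, fmin: float, fmax: float,
    nw: float = DEFAULT_NW,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided DPSS multitaper PSD of (..., n_times) arrays, uV^2/Hz.

    Eigenspectra of 2*nw - 1 unit-energy Slepian tapers are averaged
    unweighted; one-sided density scaling 2/fs (no doubling at DC/Nyquist).
    Returns (psd restricted to [fmin, fmax], frequency grid).
    """
    data = np.asarray(data, dtype=np.float64)
    n_times = data.shape[-1]
    tapers = _dpss_tapers(n_times, nw)
    data = data - data.mean(axis=-1, keepdims=True)
    # eigenspectra are computed in single precision: the taper-averaged
    # estimator's statistical error dwarfs float32 roundoff
    tapered = (data[..., None, :] * tapers).astype(np.float32)
    flat = np.fft.rfft(tapered.reshape(-1, n_times), axis=-1)
    spectra = flat.reshape(tapered.shape[:-1] + (flat.shape[-1],))
    psd = (spectra.real ** 2 + spectra.imag ** 2).mean(axis=-2) \
        .astype(np.float64) * (2.0 / fs)
    freqs = np.fft.rfftfreq(n_times, 1.0 / fs)
    psd[..., 0] /= 2.0
    if n_times % 2 == 0:
        psd[..., -1] /= 2.0
    sel = (freqs >= fmin) & (freqs <= fmax)
    return psd[..., sel], freqs[sel]


def multitaper_psd(
    epochs: EpochSet,
    fmin: float = 0.5,
    fmax: float = 45.0,
    nw: float = DEFAULT_NW,
) -> PSDSet:
    """DPSS multitaper PSD of the kept epochs, averaged across epochs.

    ``nw`` is the time-halfbandwidth product per epoch (half-bandwidth
    nw / epoch_length Hz); 2*nw - 1 tapers are averaged unweighted.
    The density is normalised so that sum(psd) * df over the grid
    approximates the in-band signal variance.
    """
    X = epochs.kept_data
    if X.shape[0] == 0:
        raise ValueError("no kept epochs to estimate a PSD from")
    psd, freqs = multitaper_psd_array(X, epochs.fs, fmin, fmax, nw)
    return PSDSet(freqs=freqs, psd=psd.mean(axis=0), fs=epochs.fs,
                  n_epochs_averaged=X.shape[0], montage=epochs.montage)


# ---------------------------------------------------------------------------
# Band powers
# ---------------------------------------------------------------------------

def band_power_linear(psd: PSDSet, band: str, scheme: BandScheme) -> np.ndarray:
    """Rectangle-rule band integral per channel, in uV^2."""
    mask = scheme.mask(psd.freqs, band)
    if not mask.any():
        raise ValueError(f"band {band!r} contains no frequency bins")
    return psd.psd[:, mask].sum(axis=1) * psd.df


def total_power_linear(psd: PSDSet, scheme: BandScheme) -> np.ndarray:
    """Broadband integral over the scheme's full range, per channel."""
    lo, hi = scheme.fmin, scheme.fmax
    mask = (psd.freqs >= lo) & ((psd.freqs < hi) | np.isclose(psd.freqs, hi))
    return psd.psd[:, mask].sum(axis=1) * psd.df


def band_power_absolute(psd: PSDSet, band: str,
                        scheme: BandScheme | None = None) -> np.ndarray:
    """Absolute band power per channel in dB re 1 uV^2."""
    scheme = scheme or BandScheme()
    p = band_power_linear(psd, band, scheme)
    if np.any(p <= 0):
        raise ValueError(f"non-positive power in band {band!r}")
    return 10.0 * np.log10(p)


def band_power_relative(psd: PSDSet, band: str,
                        scheme: BandScheme | None = None) -> np.ndarray:
    """Relative band power per channel, percent of broadband power."""
    scheme = scheme or BandScheme()
    total = total_power_linear(psd, scheme)
    if np.any(total <= 0):
        raise ValueError("zero broadband power")
    return 100.0 * band_power_linear(psd, band, scheme) / total


def spectral_ratios(psd: PSDSet,
                    scheme: BandScheme | None = None) -> pd.DataFrame:
    """Per-channel alpha/theta ratio and SPR, computed on linear power."""
    scheme = scheme or BandScheme()
    p = {b: band_power_linear(psd, b, scheme)
         for b in ("delta", "theta", "alpha", "beta")}
    if np.any(p["theta"] <= 0) or np.any(p["delta"] + p["theta"] <= 0):
        raise ValueError("zero denominator in spectral ratio")
    return pd.DataFrame(
        {
            "alpha_theta_ratio": p["alpha"] / p["theta"],
            "spr": (p["alpha"] + p["beta"]) / (p["delta"] + p["theta"]),
        },
        index=list(psd.montage.channel_names),
    )


def band_power_table(psd: PSDSet,
                     scheme: BandScheme | None = None) -> pd.DataFrame:
    """Per-channel table of absolute (dB) and relative (%) band powers.

    Columns: ``abs_<band>`` and ``rel_<band>`` for every band of the scheme,
    plus ``alpha_theta_ratio`` and ``spr``.
    """
    scheme = scheme or BandScheme()
    cols = {}
    for band in scheme.bands:
        cols[f"abs_{band}"] = band_power_absolute(psd, band, scheme)
        cols[f"rel_{band}"] = band_power_relative(psd, band, scheme)
    table = pd.DataFrame(cols, index=list(psd.montage.channel_names))
    return table.join(spectral_ratios(psd, scheme))


# ---------------------------------------------------------------------------
# Aggregation and map export
# ---------------------------------------------------------------------------

def aggregate(
    values, montage: Montage1020,
    scheme: str | tuple[str, str] = "global",
) -> float:
    """Arithmetic mean of a per-channel metric over a channel set.

    ``scheme`` is ``"global"`` (all 19 channels), a region name, or a
    ``(region, laterality)`` pair.
    """
    values = pd.Series(np.asarray(values, dtype=float),
                       index=list(montage.channel_names)) \
        if not isinstance(values, pd.Series) else values
    if scheme == "global":
        chans = montage.channel_names
    elif isinstance(scheme, str):
        chans = region_channels(scheme, "both", montage)
    else:
        chans = region_channels(scheme[0], scheme[1], montage)
    if len(chans) == 0:
        raise ValueError(f"empty channel set for scheme {scheme!r}")
    return float(values.loc[list(chans)].mean())


def export_topomap(values, montage: Montage1020, path,
                   render: str | None = None) -> pd.DataFrame:
    """Write a value-per-electrode map (channel, x, y, value) as CSV.

    ``render`` optionally names a PNG to draw a basic scatter map into.
    """
    values = pd.Series(values, index=list(montage.channel_names)) \
        if not isinstance(values, pd.Series) else values
    missing = set(montage.channel_names) - set(values.index)
    if missing:
        raise ValueError(f"missing channels: {sorted(missing)}")
    rows = [
        {"channel": ch, "x": montage.positions[ch][0],
         "y": montage.positions[ch][1], "value": float(values[ch])}
        for ch in montage.channel_names
    ]
    table = pd.DataFrame(rows)
    table.to_csv(path, index=False, float_format="%.10g")
    if render is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        circ = plt.Circle((0, 0), 1.05, fill=False, color="k")
        ax.add_patch(circ)
        sc = ax.scatter(table.x, table.y, c=table.value, s=300, cmap="RdBu_r")
        for _, r in table.iterrows():
            ax.annotate(r.channel, (r.x, r.y), ha="center", va="center",
                        fontsize=6)
        fig.colorbar(sc, ax=ax)
        ax.set_xlim(-1.2, 1.2); ax.set_ylim(-1.2, 1.2)
        ax.set_aspect("equal"); ax.axis("off")
        fig.savefig(render, dpi=120)
        plt.close(fig)
    return table
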