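"""Phase Lag Index (PLI) connectivity per frequency band.

The PLI between two channels is the absolute time-average of the sign of
their wrapped instantaneous phase difference.  It ranges over [0, 1] and is
insensitive to zero-lag coupling, so a common source mixed into two
channels by volume conduction does not inflate it — the property that makes
it attractive for scalp EEG.

Phases come from band-pass filtered (zero-phase FIR) epochs via the
analytic signal; 0.25 s at each epoch edge is excluded to suppress filter
transients.  The sign of the phase difference is averaged over the retained
samples of all epochs and the absolute value taken at the end (the
estimator of Stam et al.; sign(0) contributes nothing).  A per-epoch
variant is available but carries a positive small-sample bias.
"""

from __future__ import annotations

from dataclasses import dataclass

from functools import lru_cache

import numpy as np
import scipy.signal
from mne.filter import create_filter

from .core import BandScheme, Montage1020, region_channels
from .preprocess import _apply_fir

#: Bands for which PLI is reported (delta omitted by convention here).
PLI_BANDS = ("theta", "alpha", "beta", "gamma")

#: Seconds trimmed from each epoch edge before averaging signs.
EDGE_TRIM_S = 0.25


@dataclass
class PhaseSet:
    """Instantaneous phase per epoch/channel for one band."""

    band: str
    phases: np.ndarray  # epochs x channels x samples, radians
    fs: float
    montage: Montage1020
    edge_trim_s: float = EDGE_TRIM_S

    @property
    def valid_slice(self) -> slice:
        n = int(round(self.edge_trim_s * self.fs))
        return slice(n, self.phases.shape[2] - n)


@dataclass
class PLIMatrix:
    """Symmetric channels x channels phase-lag-index matrix for one band."""

    band: str
    matrix: np.ndarray
    n_epochs: int
    montage: Montage1020

    def __post_init__(self):
        m = self.matrix
        if not np.allclose(m, m.T):
            raise ValueError("PLI matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("PLI diagonal must be zero")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("PLI values must lie in [0, 1]")


@lru_cache(maxsize=32)
def _bandpass_kernel(fs: float, lo: float, hi: float) -> np.ndarray:
    """Zero-phase FIR band-pass, transition width 25% of each band edge."""
    return create_filter(
        None, fs, l_freq=lo, h_freq=hi,
        l_trans_bandwidth=0.25 * lo, h_trans_bandwidth=0.25 * hi,
        fir_window="hamming", phase="zero", verbose="error",
    )


def band_phase(epochs, band: str, scheme: BandScheme | None = None,
               edge_trim_s: float = EDGE_TRIM_S) -> PhaseSet:
    """Band-limited instantaneous phase of the kept epochs.

    Zero-phase FIR band-pass (transition width 25% of each band edge), then
    the analytic-signal phase.  The first/last ``edge_trim_s`` seconds of
    every epoch are flagged for exclusion from PLI averaging.
    """
    scheme = scheme or BandScheme()
    lo, hi = scheme.edges(band)
    if hi > epochs.fs / 2:
        raise ValueError(f"band {band!r} upper edge {hi} Hz above Nyquist")
    X = epochs.kept_data
    n_ep, n_ch, n_t = X.shape
    flat = _apply_fir(X.reshape(n_ep * n_ch, n_t),
                      _bandpass_kernel(epochs.fs, lo, hi),
                      cache_key=("bp", epochs.fs, lo, hi))
    phases = np.angle(scipy.signal.hilbert(flat, axis=1))
    return PhaseSet(band=band, phases=phases.reshape(n_ep, n_ch, n_t),
                    fs=epochs.fs, montage=epochs.montage,
                    edge_trim_s=edge_trim_s)


def pli_matrix(phases: PhaseSet, pooled: bool = True) -> PLIMatrix:
    """PLI = |mean sign(dphi)| over retained samples of all epochs.

    With ``pooled=True`` (default) the signed means are pooled across
    epochs before taking the absolute value, so the no-coupling floor
    shrinks with the number of epochs.  ``pooled=False`` instead averages
    per-epoch |mean sign| values; that variant carries a positive bias of
    roughly sqrt(2/(pi * n_independent_samples)) per epoch, which for
    narrowband signals on 5-s epochs does not vanish with more data.
    """
    ph = phases.phases[:, :, phases.valid_slice]
    n_ep, n_ch, _ = ph.shape
    if n_ep < 1:
        raise ValueError("need at least one epoch of phases")
    acc = np.zeros((n_ch, n_ch))
    for e in range(n_ep):
        dphi = ph[e][:, None, :] - ph[e][None, :, :]
        # sign of the wrapped difference equals sign(sin(dphi))
        signed = np.sign(np.sin(dphi)).mean(axis=2)
        acc += np.abs(signed) if not pooled else signed
    m = np.abs(acc) / n_ep if pooled else acc / n_ep
    np.fill_diagonal(m, 0.0)
    m = (m + m.T) / 2  # exact symmetry against roundoff
    return PLIMatrix(band=phases.band, matrix=m, n_epochs=n_ep,
                     montage=phases.montage)


def aggregate_pli(
    pli: PLIMatrix,
    scheme="global",
) -> float:
    """Mean PLI over all unordered channel pairs or a region pair.

    ``scheme`` is ``"global"`` (all C*(C-1)/2 pairs) or a pair of
    ``(region, laterality)`` tuples, e.g. ``(("occipital", "left"),
    ("temporal", "left"))``; region-pair means use all cross pairs between
    the two (distinct) lateralised channel sets.
    """
    m = pli.matrix
    mont = pli.montage
    if scheme == "global":
        iu = np.triu_indices(m.shape[0], k=1)
        return float(m[iu].mean())
    (reg_a, lat_a), (reg_b, lat_b) = scheme
    chans_a = region_channels(reg_a, lat_a, mont)
    chans_b = region_channels(reg_b, lat_b, mont)
    pairs = [
        (mont.index_of(a), mont.index_of(b))
        for a in chans_a for b in chans_b if a != b
    ]
    if not pairs:
        raise ValueError(f"empty channel-pair set for scheme {scheme!r}")
    return float(np.mean([m[i, j] for i, j in pairs]))


#: The lateralised region pairs highlighted in the group results
#: (parietal-left/frontal-right, occipital-left/frontal-right,
#: occipital-left/temporal-left, parietal-left/temporal-left).
NAMED_REGION_PAIRS = {
    "PL-FR": (("parietal", "left"), ("frontal", "right")),
    "OL-FR": (("occipital", "left"), ("frontal", "right")),
    "OL-TL": (("occipital", "left"), ("temporal", "left")),
    "PL-TL": (("parietal", "left"), ("temporal", "left")),
}


def all_region_pairs(montage: Montage1020) -> dict[str, tuple]:
    """Every unordered pair of distinct lateralised regions with a label."""
    initial = {"frontal": "F", "central": "C", "temporal": "T",
               "parietal": "P", "occipital": "O"}
    sets = [(f"{initial[r]}{l[0].upper()}", (r, l))
            for r in montage.regions for l in ("left", "right")]
    out = {}
    for i, (name_a, a) in enumerate(sets):
        for name_b, b in sets[i + 1:]:
            out[f"{name_a}-{name_b}"] = (a, b)
    return out
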