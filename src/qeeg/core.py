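"""Montage, scalp-region, and frequency-band definitions shared by all stages.

The analysis operates on 19-channel resting-state EEG recorded under the
10-20 International System.  Channels are grouped into five scalp regions
(frontal, central, temporal, parietal, occipital); results are additionally
reported for the left/right half of each region, using the 10-20 convention
that odd-numbered electrodes lie over the left hemisphere, even-numbered
over the right, and z-suffixed electrodes on the midline.

Frequency bands are half-open intervals ``[low, high)`` so that shared edges
(4, 8, 13, 30 Hz) belong to exactly one band; the topmost band (gamma) is
closed at its upper edge so the five disjoint bands tile [0.5, 45] Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

#: The 19 electrodes of the reduced 10-20 montage, in recording order.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz",
    "C3", "C4", "Cz", "T3", "T4", "T5", "T6",
    "P3", "P4", "Pz", "O1", "O2",
)

#: Scalp-region membership.
REGIONS = {
    "frontal": ("Fp1", "Fp2", "F3", "F4", "Fz"),
    "central": ("C3", "C4", "Cz"),
    "temporal": ("F7", "F8", "T3", "T4", "T5", "T6"),
    "parietal": ("P3", "P4", "Pz"),
    "occipital": ("O1", "O2"),
}

# 2D electrode positions: standard unit-circle projection of the 10-20
# layout (x toward the right ear, y toward the nasion, head rim at r=1).
# Used only for value-per-electrode map export.
_OUTER = {  # (radius, angle from +y axis, clockwise toward +x, degrees)
    "Fp1": -18, "Fp2": 18, "F7": -54, "F8": 54, "T3": -90, "T4": 90,
    "T5": -126, "T6": 126, "O1": -162, "O2": 162,
}
_INNER = {
    "Fz": (0.5, 0), "Cz": (0.0, 0), "Pz": (0.5, 180),
    "F3": (0.55, -39), "F4": (0.55, 39), "C3": (0.5, -90), "C4": (0.5, 90),
    "P3": (0.55, -141), "P4": (0.55, 141),
}


def _positions() -> dict[str, tuple[float, float]]:
    pos = {}
    for ch, ang in _OUTER.items():
        a = np.deg2rad(ang)
        pos[ch] = (float(np.sin(a)), float(np.cos(a)))
    for ch, (r, ang) in _INNER.items():
        a = np.deg2rad(ang)
        pos[ch] = (float(r * np.sin(a)), float(r * np.cos(a)))
    return pos


@dataclass(frozen=True)
class Montage1020:
    """The 19-channel 10-20 montage with region and laterality assignments."""

    channel_names: tuple[str, ...]
    positions: dict[str, tuple[float, float]]
    regions: dict[str, tuple[str, ...]]

    def region_of(self, channel: str) -> str:
        for region, chans in self.regions.items():
            if channel in chans:
                return region
        raise KeyError(f"unknown channel {channel!r}")

    def laterality_of(self, channel: str) -> str:
        """left/right/midline from the 10-20 label convention."""
        if channel not in self.channel_names:
            raise KeyError(f"unknown channel {channel!r}")
        if channel.endswith("z"):
            return "midline"
        return "left" if int(channel[-1]) % 2 == 1 else "right"

    def index_of(self, channel: str) -> int:
        return self.channel_names.index(channel)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


def build_standard_montage() -> Montage1020:
    """Return the canonical 19-channel 10-20 montage used throughout."""
    return Montage1020(
        channel_names=CHANNELS_1020,
        positions=_positions(),
        regions=dict(REGIONS),
    )


def region_channels(
    region: str, laterality: str = "both", montage: Montage1020 | None = None
) -> tuple[str, ...]:
    """Electrodes of a scalp region restricted to one hemisphere.

    Midline (z) channels are included only when ``laterality='both'``.
    """
    montage = montage or build_standard_montage()
    if region not in montage.regions:
        raise KeyError(f"unknown region {region!r}; expected one of "
                       f"{sorted(montage.regions)}")
    if laterality not in ("left", "right", "both"):
        raise ValueError(f"laterality must be left/right/both, got {laterality!r}")
    chans = montage.regions[region]
    if laterality == "both":
        return tuple(chans)
    return tuple(c for c in chans if montage.laterality_of(c) == laterality)


# ---------------------------------------------------------------------------
# Frequency bands
# ---------------------------------------------------------------------------

#: Canonical bands in Hz.  ``low_alpha``/``high_alpha`` are sub-bands of
#: alpha and are excluded from the disjoint broadband partition.
DEFAULT_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "low_alpha": (8.0, 10.0),
    "high_alpha": (10.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: The five disjoint bands that tile the broadband [0.5, 45] Hz interval.
DISJOINT_BANDS = ("delta", "theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class BandScheme:
    """Named frequency bands; half-open ``[low, high)``, topmost band closed."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    @property
    def fmin(self) -> float:
        return min(lo for lo, _ in self.bands.values())

    @property
    def fmax(self) -> float:
        return max(hi for _, hi in self.bands.values())

    def edges(self, band: str) -> tuple[float, float]:
        return self.bands[band]

    def mask(self, freqs: np.ndarray, band: str) -> np.ndarray:
        """Boolean mask of frequency bins belonging to *band*.

        Bins on a shared edge count toward the higher band; the global upper
        edge (45 Hz by default) is included so the disjoint bands partition
        the grid.
        """
        lo, hi = self.bands[band]
        freqs = np.asarray(freqs)
        m = (freqs >= lo) & (freqs < hi)
        if hi >= self.fmax:  # close the top band
            m |= np.isclose(freqs, hi)
        return m

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: list(v) for k, v in self.bands.items()}, fh)

    @classmethod
    def from_yaml(cls, path) -> "BandScheme":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(bands={k: (float(v[0]), float(v[1])) for k, v in raw.items()})


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

GROUP_LABELS = ("PD-CogN", "PD-MCI", "PD-D")


@dataclass
class Annotation:
    """A technician/event annotation: label with onset and duration in s."""

    label: str
    onset: float
    duration: float

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class EEGRecording:
    """Continuous multichannel EEG in microvolts.

    ``samples`` is channels x time; ``fs`` the sampling frequency in Hz
    (512 Hz for the routine clinical recordings this package targets).
    """

    samples: np.ndarray
    fs: float
    montage: Montage1020
    annotations: list[Annotation] = field(default_factory=list)
    subject_id: str = ""
    group: str | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if self.samples.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"channel count {self.samples.shape[0]} does not match montage "
                f"({self.montage.n_channels})"
            )
        for ann in self.annotations:
            if ann.onset < 0 or ann.end > self.duration + 1e-9:
                raise ValueError(
                    f"annotation {ann.label!r} [{ann.onset}, {ann.end}] s lies "
                    f"outside the recording (duration {self.duration:.3f} s)"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, samples: np.ndarray) -> "EEGRecording":
        return EEGRecording(
            samples=samples, fs=self.fs, montage=self.montage,
            annotations=list(self.annotations), subject_id=self.subject_id,
            group=self.group,
        )

    def crop(self, tmin: float, tmax: float) -> "EEGRecording":
        """Restrict to [tmin, tmax] s; annotations are shifted and clipped."""
        i0 = int(round(tmin * self.fs))
        i1 = min(int(round(tmax * self.fs)), self.n_samples)
        if i1 <= i0:
            raise ValueError("empty crop window")
        anns = []
        for ann in self.annotations:
            onset = max(ann.onset, tmin)
            end = min(ann.end, tmax)
            if end > onset:
                anns.append(Annotation(ann.label, onset - tmin, end - onset))
        out = EEGRecording(
            samples=self.samples[:, i0:i1].copy(), fs=self.fs,
            montage=self.montage, annotations=anns,
            subject_id=self.subject_id, group=self.group,
        )
        return out
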