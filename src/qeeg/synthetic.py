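"""Synthetic resting-state EEG cohorts with known ground truth.

Each subject's signal is built per channel as

* an aperiodic 1/f^chi Gaussian background (chi is the PSD exponent),
* narrowband oscillatory components per frequency band — band-filtered
  Gaussian noise carriers scaled to a target RMS amplitude, so spectra have
  realistic width and phase statistics (pure tones would make the phase
  lag index degenerate),
* optional inter-regional coupling: for a coupling edge (A, B, band,
  strength kappa) a shared band-limited source is mixed into both regions'
  channels with weight kappa (and sqrt(1-kappa^2) of independent carrier),
  delayed by 1/8 cycle at the band centre in region B so that a
  zero-lag-insensitive connectivity measure registers it,
* transient artifacts at Poisson times: frontally weighted blink templates
  (0.3 s, 300-600 uV) and broadband movement bursts (1-2 s, 500-1000 uV),
  with a ground-truth annotation list.

The ``paper-like`` preset emulates a three-group Parkinson's cohort
(PD-CogN / PD-MCI / PD-D, default sizes 43/30/25): relative theta power is
elevated by ~1.1 percentage points and the alpha/theta ratio reduced by
~0.12 in PD-D versus PD-CogN (with PD-MCI halfway on the log scale), while
a global amplitude elevation carries the absolute theta power up by
~3.2 dB.  The oscillation/scale factors that achieve this are solved
analytically from the baseline band shares at preset-construction time.
Everything is deterministic given the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    Annotation, BandScheme, DISJOINT_BANDS, EEGRecording, GROUP_LABELS,
    Montage1020, build_standard_montage, region_channels,
)

# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Coupling:
    """A phase-coupled edge between two lateralised regions in one band."""

    region_a: str
    lat_a: str
    region_b: str
    lat_b: str
    band: str
    kappa: float

    def __post_init__(self):
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("coupling strength kappa must lie in [0, 1]")


@dataclass
class SubjectProfile:
    """Generative parameters of one subject's EEG."""

    group: str
    band_amp: dict[str, float]  # uV RMS per oscillatory band component
    background_rms: float = 4.0  # uV RMS of the aperiodic background
    chi: float = 1.2  # PSD exponent of the 1/f^chi background
    region_scale: dict[str, dict[str, float]] = field(default_factory=dict)
    couplings: list[Coupling] = field(default_factory=list)
    blink_rate: float = 0.0  # events / minute
    movement_rate: float = 0.0  # events / minute
    age: float = 65.0
    duration_years: float = 8.0

    def __post_init__(self):
        if any(a < 0 for a in self.band_amp.values()):
            raise ValueError("band amplitudes must be non-negative")
        if not 0.5 <= self.chi <= 2.0:
            raise ValueError("background exponent chi must lie in [0.5, 2]")
        if self.blink_rate < 0 or self.movement_rate < 0:
            raise ValueError("artifact rates must be non-negative")


@dataclass
class GroupModel:
    """Population distribution a group's subject profiles are drawn from."""

    label: str
    band_amp: dict[str, float]  # group-mean component amplitudes, uV RMS
    background_rms: float = 4.0
    chi: float = 1.2
    global_sigma_log: float = 0.30  # between-subject log-amplitude SD (all bands)
    band_sigma_log: float = 0.03  # extra per-band log-amplitude jitter
    couplings: list[Coupling] = field(default_factory=list)
    blink_rate: float = 2.0
    movement_rate: float = 0.5
    age_mean: float = 65.0
    age_sd: float = 10.0
    duration_mean: float = 9.0
    duration_sd: float = 6.0
    #: multiplicative theta-amplitude slope per year of age
    age_theta_slope: float = 0.002
    #: multiplicative alpha-amplitude decline per year of disease duration
    #: (applied in the PD-MCI group)
    duration_alpha_slope: float = 0.0


def draw_profile(model: GroupModel, rng: np.random.Generator) -> SubjectProfile:
    """Draw one subject's profile from the group distribution."""
    g = float(np.exp(rng.normal(0.0, model.global_sigma_log)))
    age = float(rng.normal(model.age_mean, model.age_sd))
    dur = float(max(0.5, rng.normal(model.duration_mean, model.duration_sd)))
    amps = {}
    for band, a in model.band_amp.items():
        jitter = np.exp(rng.normal(0.0, model.band_sigma_log))
        amps[band] = a * g * jitter
    amps["theta"] *= np.exp(model.age_theta_slope * (age - model.age_mean))
    if model.duration_alpha_slope:
        amps["alpha"] *= np.exp(
            -model.duration_alpha_slope * (dur - model.duration_mean))
    return SubjectProfile(
        group=model.label, band_amp=amps,
        background_rms=model.background_rms * g, chi=model.chi,
        couplings=list(model.couplings), blink_rate=model.blink_rate,
        movement_rate=model.movement_rate, age=age, duration_years=dur,
    )


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _soft_band_mask(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Raised-cosine band mask with ramps inside 15% of the bandwidth."""
    t = 0.15 * (hi - lo)
    m = np.zeros_like(freqs)
    core = (freqs >= lo + t) & (freqs <= hi - t)
    m[core] = 1.0
    up = (freqs >= lo) & (freqs < lo + t)
    m[up] = 0.5 * (1 - np.cos(np.pi * (freqs[up] - lo) / t))
    dn = (freqs > hi - t) & (freqs <= hi)
    m[dn] = 0.5 * (1 - np.cos(np.pi * (hi - freqs[dn]) / t))
    return m


def _unit_rms(x: np.ndarray) -> np.ndarray:
    s = x.std(axis=-1, keepdims=True)
    s[s == 0] = 1.0
    return x / s


def _complex_noise(rng: np.random.Generator, shape) -> np.ndarray:
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


def _rms_normalised(profile: np.ndarray, n: int) -> np.ndarray:
    """Scale a spectral magnitude profile to unit time-domain RMS.

    For x = irfft(Z * profile) with Z iid standard complex Gaussian, the
    per-sample variance is (2/n^2) * sum(profile^2); the profile is scaled
    so that this equals 1 (the realised RMS then fluctuates naturally with
    the spectral degrees of freedom, as real EEG band power does).
    """
    e = float(np.sum(profile ** 2))
    if e == 0:
        return profile
    return profile * (n / np.sqrt(2.0 * e))

#: RMS of the additive white sensor noise, uV.
SENSOR_NOISE_RMS = 0.5


def generate_subject(
    profile: SubjectProfile,
    duration_s: float,
    fs: float,
    seed: int,
    montage: Montage1020 | None = None,
    scheme: BandScheme | None = None,
) -> EEGRecording:
    """Synthesise one artifact-free recording from a subject profile.

    All independent Gaussian components (background, sensor noise, the
    independent share of each channel's band carriers) are assembled as a
    single complex spectrum per channel; coupled shared sources are added
    per edge with their 1/8-cycle lag applied as a spectral phase ramp.
    One inverse FFT per subject then yields the signal.
    """
    montage = montage or build_standard_montage()
    scheme = scheme or BandScheme()
    if fs <= 2 * scheme.fmax:
        raise ValueError(
            f"fs={fs} must exceed twice the highest band edge {scheme.fmax}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    n_ch = montage.n_channels
    freqs = np.fft.rfftfreq(n, 1.0 / fs)

    # aperiodic 1/f^chi background (amplitude spectrum ~ f^(-chi/2),
    # flattened below 0.5 Hz, no DC) plus white sensor noise
    bg = np.zeros_like(freqs)
    nz = freqs > 0
    bg[nz] = np.maximum(freqs[nz], 0.5) ** (-profile.chi / 2.0)
    bg = _rms_normalised(bg, n) * profile.background_rms
    white = np.zeros_like(freqs)
    white[nz] = 1.0
    white = _rms_normalised(white, n) * SENSOR_NOISE_RMS

    # per-band spectral profiles, restricted to their support bins
    band_profiles: dict[str, np.ndarray] = {}
    band_support: dict[str, slice] = {}
    ch_amp: dict[str, np.ndarray] = {}
    for band, amp in profile.band_amp.items():
        if amp <= 0:
            continue
        lo, hi = scheme.edges(band)
        prof = _rms_normalised(_soft_band_mask(freqs, lo, hi), n)
        nz = np.nonzero(prof)[0]
        sl = slice(int(nz[0]), int(nz[-1]) + 1)
        band_profiles[band] = prof[sl]
        band_support[band] = sl
        rscale = profile.region_scale.get(band, {})
        ch_amp[band] = np.array([
            amp * rscale.get(montage.region_of(c), 1.0)
            for c in montage.channel_names
        ])

    # per-channel mixing weights: sequential coupling mixtures leave each
    # channel's band carrier with residual independent weight prod(q_e) and
    # one shared-source weight per edge it participates in
    indep_frac = {b: np.ones(n_ch) for b in band_profiles}
    shared: list[tuple[str, np.ndarray]] = []  # (band, per-channel weights)
    for edge in profile.couplings:
        if edge.band not in band_profiles or edge.kappa == 0:
            continue
        lo, hi = scheme.edges(edge.band)
        f_c = 0.5 * (lo + hi)
        lag_s = max(1, int(round(fs / (8.0 * f_c)))) / fs
        idx_a = [montage.index_of(c) for c in
                 region_channels(edge.region_a, edge.lat_a, montage)]
        idx_b = [montage.index_of(c) for c in
                 region_channels(edge.region_b, edge.lat_b, montage)]
        w = np.zeros(n_ch, dtype=complex)
        # each new source enters at weight kappa * sqrt(residual); the
        # residual fractions keep every channel's total variance at 1
        res = indep_frac[edge.band]
        w[idx_a] = edge.kappa * np.sqrt(res[idx_a])
        ramp = np.exp(-2j * np.pi * freqs[band_support[edge.band]] * lag_s)
        w_b = edge.kappa * np.sqrt(res[idx_b])
        q2 = 1.0 - edge.kappa ** 2
        res[idx_a] *= q2
        res[idx_b] *= q2
        wb = np.zeros(n_ch, dtype=complex)
        wb[idx_b] = w_b
        shared.append((edge.band,
                       w[:, None] + wb[:, None] * ramp[None, :]))

    # independent part: one complex-Gaussian draw scaled by the root of the
    # summed component variances (sum of independent Gaussians)
    var = np.broadcast_to(bg ** 2 + white ** 2,
                          (n_ch, freqs.size)).copy()
    for band, prof in band_profiles.items():
        sl = band_support[band]
        var[:, sl] += (ch_amp[band][:, None]
                       * np.sqrt(indep_frac[band])[:, None]
                       * prof[None, :]) ** 2
    spectrum = _complex_noise(rng, (n_ch, freqs.size)) * np.sqrt(var)

    for band, weights in shared:
        src = _complex_noise(rng, band_profiles[band].size) \
            * band_profiles[band]
        spectrum[:, band_support[band]] += \
            weights * (ch_amp[band][:, None] * src[None, :])

    x = np.fft.irfft(spectrum, n=n, axis=1)
    return EEGRecording(samples=x, fs=fs, montage=montage,
                        subject_id="", group=profile.group)


def inject_artifacts(
    rec: EEGRecording, profile: SubjectProfile, seed: int
) -> tuple[EEGRecording, list[Annotation]]:
    """Add blink and movement transients at Poisson times.

    Returns a new recording plus the ground-truth annotation list (also
    attached to the recording's annotations).
    """
    rng = np.random.default_rng(seed)
    mont = rec.montage
    x = rec.samples.copy()
    fs, dur = rec.fs, rec.duration
    truth: list[Annotation] = []

    frontal_w = np.full(mont.n_channels, 0.05)
    for ch in ("F3", "F4", "F7", "F8", "Fz"):
        frontal_w[mont.index_of(ch)] = 0.4
    for ch in ("Fp1", "Fp2"):
        frontal_w[mont.index_of(ch)] = 1.0

    n_blinks = rng.poisson(profile.blink_rate * dur / 60.0)
    for _ in range(n_blinks):
        length = 0.3
        onset = rng.uniform(0, dur - length)
        amp = rng.uniform(300.0, 600.0)
        i0 = int(round(onset * fs))
        nt = int(round(length * fs))
        t = np.linspace(0, np.pi, nt)
        template = np.sin(t) ** 2 * amp
        x[:, i0:i0 + nt] += frontal_w[:, None] * template[None, :]
        truth.append(Annotation("blink", onset, length))

    n_moves = rng.poisson(profile.movement_rate * dur / 60.0)
    for _ in range(n_moves):
        length = rng.uniform(1.0, 2.0)
        amp = rng.uniform(500.0, 1000.0)
        onset = rng.uniform(0, dur - length)
        i0 = int(round(onset * fs))
        nt = int(round(length * fs))
        env = np.hanning(nt)
        burst = rng.standard_normal((mont.n_channels, nt))
        burst = _unit_rms(burst) * (amp / 3.0) * env[None, :]
        burst *= rng.uniform(0.5, 1.0, size=(mont.n_channels, 1))
        x[:, i0:i0 + nt] += burst
        truth.append(Annotation("movement", onset, length))

    out = EEGRecording(samples=x, fs=fs, montage=mont,
                       annotations=list(rec.annotations) + list(truth),
                       subject_id=rec.subject_id, group=rec.group)
    return out, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Default group sizes of the emulated cohort.
DEFAULT_SIZES = {"PD-CogN": 43, "PD-MCI": 30, "PD-D": 25}


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort."""

    groups: dict[str, GroupModel]
    sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SIZES))
    duration_s: float = 180.0
    fs: float = 512.0
    seed: int = 0
    with_artifacts: bool = True

    def __post_init__(self):
        if any(n < 1 for n in self.sizes.values()):
            raise ValueError("group sizes must be >= 1")


class Cohort:
    """A realised cohort: metadata + truth tables, recordings on demand.

    Recordings are regenerated deterministically from per-subject seeds, so
    a 98-subject cohort never needs to be held in memory at once.
    """

    def __init__(self, spec: CohortSpec, montage: Montage1020 | None = None):
        self.spec = spec
        self.montage = montage or build_standard_montage()
        self.profiles: list[SubjectProfile] = []
        meta_rows, truth_rows = [], []
        idx = 0
        for label, n in spec.sizes.items():
            model = spec.groups[label]
            for _ in range(n):
                sid = f"sub-{idx:03d}"
                rng = np.random.default_rng(
                    np.random.SeedSequence([spec.seed, idx, 0]))
                prof = draw_profile(model, rng)
                self.profiles.append(prof)
                meta_rows.append({
                    "subject_id": sid, "group": label, "age": prof.age,
                    "duration_years": prof.duration_years,
                })
                row = {"subject_id": sid, "group": label}
                row.update({f"amp_{b}": a for b, a in prof.band_amp.items()})
                row["background_rms"] = prof.background_rms
                for e in prof.couplings:
                    row[f"kappa_{e.band}_{e.region_a[0]}{e.lat_a[0]}-"
                        f"{e.region_b[0]}{e.lat_b[0]}"] = e.kappa
                truth_rows.append(row)
                idx += 1
        self.metadata = pd.DataFrame(meta_rows)
        self.truth = pd.DataFrame(truth_rows)

    @property
    def n_subjects(self) -> int:
        return len(self.profiles)

    def recording(self, i: int) -> EEGRecording:
        """Deterministically (re)generate subject *i*'s recording."""
        spec = self.spec
        prof = self.profiles[i]
        rec = generate_subject(
            prof, spec.duration_s, spec.fs,
            seed=np.random.SeedSequence([spec.seed, i, 1]),
            montage=self.montage,
        )
        rec.subject_id = self.metadata.subject_id.iloc[i]
        if spec.with_artifacts:
            rec, _ = inject_artifacts(
                rec, prof, seed=np.random.SeedSequence([spec.seed, i, 2]))
        return rec

    def iter_recordings(self):
        for i in range(self.n_subjects):
            yield self.recording(i)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Realise subject profiles (seeded) for a cohort specification."""
    return Cohort(spec)


# ---------------------------------------------------------------------------
# The paper-like preset
# ---------------------------------------------------------------------------

#: Baseline (cognitively normal) oscillation amplitudes, uV RMS.
BASELINE_AMPS = {"delta": 2.5, "theta": 6.0, "alpha": 6.8, "beta": 7.0,
                 "gamma": 2.0}
BASELINE_BG_RMS = 4.0
BASELINE_CHI = 1.2

#: Preset effect targets for PD-D vs PD-CogN (mirroring the direction and
#: magnitude of the emulated cohort's group differences).
REL_THETA_SHIFT_PCT = 1.1  # percentage points of global relative theta
ALPHA_THETA_SHIFT = -0.12  # absolute change of the alpha/theta ratio
ABS_THETA_SHIFT_DB = 3.17  # dB change of global absolute theta power

#: Theta-band coupling strengths on the four highlighted region pairs.
COUPLED_PAIRS = (("parietal", "left", "frontal", "right"),
                 ("occipital", "left", "frontal", "right"),
                 ("occipital", "left", "temporal", "left"),
                 ("parietal", "left", "temporal", "left"))
KAPPA_BY_GROUP = {"PD-CogN": 0.15, "PD-MCI": 0.25, "PD-D": 0.45}

#: Age / disease-duration distributions of the emulated cohort.
AGE_DIST = {"PD-CogN": (61.79, 12.49), "PD-MCI": (68.27, 6.20),
            "PD-D": (71.36, 5.34)}
DURATION_DIST = {"PD-CogN": (8.65, 6.80), "PD-MCI": (8.40, 6.17),
                 "PD-D": (13.88, 4.55)}


def _background_band_power(chi: float, total_power: float,
                           scheme: BandScheme) -> dict[str, float]:
    """Analytic share of 1/f^chi background power per disjoint band."""
    def integral(a, b):
        if abs(chi - 1.0) < 1e-12:
            return np.log(b / a)
        e = 1.0 - chi
        return (b ** e - a ** e) / e

    tot = integral(scheme.fmin, scheme.fmax)
    return {
        b: total_power * integral(*scheme.edges(b)) / tot
        for b in DISJOINT_BANDS
    }


def _expected_band_powers(amps: dict[str, float], bg_rms: float,
                          chi: float, scheme: BandScheme) -> dict[str, float]:
    bg = _background_band_power(chi, bg_rms ** 2, scheme)
    return {b: amps.get(b, 0.0) ** 2 + bg[b] for b in DISJOINT_BANDS}


def _solve_dementia_factors(scheme: BandScheme) -> dict[str, float]:
    """Measured-power factors for the PD-D group, solved from the targets.

    Theta and alpha oscillation factors produce the relative-theta and
    alpha/theta shifts; a global amplitude scale then lifts absolute theta
    by the target dB without touching any relative quantity.
    """
    p = _expected_band_powers(BASELINE_AMPS, BASELINE_BG_RMS, BASELINE_CHI,
                              scheme)
    total = sum(p.values())
    s_theta, s_alpha = p["theta"] / total, p["alpha"] / total
    at0 = p["alpha"] / p["theta"]
    t = (at0 + ALPHA_THETA_SHIFT) / at0  # alpha/theta power-ratio factor
    target_share = s_theta + REL_THETA_SHIFT_PCT / 100.0

    from scipy.optimize import brentq

    def gap(f_theta):
        f_alpha = t * f_theta
        T = 1 + s_theta * (f_theta - 1) + s_alpha * (f_alpha - 1)
        return s_theta * f_theta / T - target_share

    f_theta = brentq(gap, 1.0, 3.0)
    f_alpha = t * f_theta
    g2 = 10.0 ** (ABS_THETA_SHIFT_DB / 10.0) / f_theta  # global power scale
    return {"theta": f_theta, "alpha": f_alpha, "global": g2}


def _scaled_amps(power_factors: dict[str, float],
                 scheme: BandScheme) -> tuple[dict[str, float], float]:
    """Convert measured-power factors into oscillation amplitudes + bg."""
    bg = _background_band_power(BASELINE_CHI, BASELINE_BG_RMS ** 2, scheme)
    g = np.sqrt(power_factors.get("global", 1.0))
    amps = {}
    for band, a in BASELINE_AMPS.items():
        f = power_factors.get(band, 1.0)
        p_osc = f * (a ** 2 + bg[band]) - bg[band]
        amps[band] = g * np.sqrt(max(p_osc, 0.0))
    return amps, g * BASELINE_BG_RMS


def paper_like_spec(
    sizes: dict[str, int] | None = None,
    duration_s: float = 180.0,
    fs: float = 512.0,
    seed: int = 0,
    effect: float = 1.0,
    with_artifacts: bool = True,
) -> CohortSpec:
    """The default three-group cohort preset.

    ``effect`` scales the group differences on the log scale: 1 is the
    calibrated preset, 0 a null cohort in which all three groups share the
    PD-CogN generative model (labels only).
    """
    scheme = BandScheme()
    factors_d = _solve_dementia_factors(scheme)
    groups = {}
    for label in GROUP_LABELS:
        # PD-MCI sits halfway between PD-CogN and PD-D on the log scale
        step = {"PD-CogN": 0.0, "PD-MCI": 0.5, "PD-D": 1.0}[label] * effect
        pf = {k: v ** step for k, v in factors_d.items()}
        amps, bg_rms = _scaled_amps(pf, scheme)
        kappa0 = KAPPA_BY_GROUP["PD-CogN"]
        kappa = kappa0 + (KAPPA_BY_GROUP[label] - kappa0) * effect
        groups[label] = GroupModel(
            label=label, band_amp=amps, background_rms=bg_rms,
            chi=BASELINE_CHI,
            couplings=[Coupling(*pair, "theta", kappa)
                       for pair in COUPLED_PAIRS],
            age_mean=AGE_DIST[label][0], age_sd=AGE_DIST[label][1],
            duration_mean=DURATION_DIST[label][0],
            duration_sd=DURATION_DIST[label][1],
            duration_alpha_slope=0.004 if label == "PD-MCI" else 0.0,
        )
    return CohortSpec(groups=groups, sizes=dict(sizes or DEFAULT_SIZES),
                      duration_s=duration_s, fs=fs, seed=seed,
                      with_artifacts=with_artifacts)
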