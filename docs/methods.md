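# Methods

This package reimplements, as a tested pipeline, a quantitative-EEG (QEEG)
analysis of cognitive decline in Parkinson's disease: 19-channel
eyes-closed resting-state EEG is reduced to spectral band powers, two
slowing indices, and phase-lag-index (PLI) connectivity, and the three
cognitive groups (PD with normal cognition, PD-CogN; mild cognitive
impairment, PD-MCI; dementia, PD-D) are compared with an assumption-gated
statistical procedure.  Because no patient data are distributed, the
pipeline ships with a synthetic cohort generator whose ground truth makes
every stage testable.

## Preprocessing

The chain is fixed in this order: crop to the eyes-closed resting segment
(default the first 180 s), 50 Hz zero-phase FIR band-stop (Hamming window,
2 Hz stop width; >= 40 dB attenuation at the line frequency, < 1 dB beyond
±2 Hz), 0.1 Hz zero-phase Hamming FIR high-pass, segmentation into
contiguous non-overlapping 5-s epochs from t = 0, per-epoch linear
detrending plus mean (baseline) subtraction, removal of epochs overlapping
technician artifact annotations (labels `movement`, `blink`, `speak`,
`bad` by default), data-driven epoch rejection (below), optional manual
exclusion lists, and common-average re-referencing.  Filters are applied
by FFT convolution of reflect-padded signals with linear-phase kernels, so
they introduce no group delay; a recording shorter than a kernel's group
delay is refused.

**Epoch rejection.** The global variant of the cross-validated
peak-to-peak threshold method: for each candidate threshold τ (default 40
values log-spaced over 50–1000 µV) and each of 5 cross-validation folds,
epochs whose largest channel-wise peak-to-peak amplitude exceeds τ are
excluded from the training split, and the validation error is the RMSE
between the mean of the retained training epochs and the point-wise median
of the validation epochs.  The τ minimising the mean cross-validated error
wins; ties break toward the larger τ.  Epochs are removed, never repaired
by interpolation, because only removal affects the downstream statistics
here.  The fold assignment is seeded and recorded.

## Spectral analysis

Per subject, the PSD of each kept epoch is estimated with DPSS (Slepian)
multitapers — time-halfbandwidth product NW = 4 per 5-s epoch
(half-bandwidth 0.8 Hz), 2·NW − 1 = 7 tapers, eigenvalue-unweighted mean,
tapers with spectral concentration ≤ 0.9 dropped — and averaged over
epochs, giving one spectrum per channel on a 0.5–45 Hz grid (0.2 Hz
spacing for 5-s epochs).  Eigenspectra and filter convolutions are
computed in single precision — the taper-averaged estimator's statistical
error and the filters' ~50 dB stopbands sit orders of magnitude above the
float32 noise floor — while all band integrals, ratios and statistics run
in double precision.  This estimator is cross-checked in the tests
against MNE's multitaper (which weights tapers by their eigenvalues;
band-integrated powers agree within a few percent) and against a Welch
periodogram oracle (within 15% on stationary signals).

Bands are half-open intervals [low, high): delta 0.5–4, theta 4–8, alpha
8–13 (low 8–10, high 10–13), beta 13–30, gamma 30–45 Hz, with gamma closed
at 45 Hz so the five disjoint bands tile [0.5, 45] and every frequency bin
is counted exactly once.  From the rectangle-rule band integrals P_band
(µV²):

* absolute power: 10·log10(P_band / 1 µV²) — the dB reference is fixed at
  1 µV² and declared here because printed dB levels are meaningless
  without one;
* relative power: 100·P_band / P_[0.5,45]; the five disjoint bands sum to
  100 by construction (the low/high alpha sub-bands are excluded from the
  denominator);
* alpha/theta ratio P_alpha/P_theta and spectral power ratio
  SPR = (P_alpha + P_beta)/(P_delta + P_theta), computed on linear power;
  both are identical whether absolute or relative powers are used.

Channel values are aggregated by arithmetic mean: globally (19 channels),
per scalp region (frontal Fp1,Fp2,F3,F4,Fz; central C3,C4,Cz; temporal
F7,F8,T3,T4,T5,T6; parietal P3,P4,Pz; occipital O1,O2), and per
lateralised region using the 10–20 convention (odd = left, even = right,
z = midline; midline channels appear only in non-lateralised sets).  The
lateral split is a convention of this package — the region results it
feeds are flagged as such in the run log.  A value-per-electrode map
(channel, 2-D unit-circle position, value) can be exported as CSV with an
optional rendered PNG.

## Connectivity

PLI between two channels is |mean sign(Δφ)| where Δφ is the wrapped
instantaneous phase difference; sign(0) contributes nothing, so zero-lag
(volume-conducted) coupling is invisible to it.  Phases come from
zero-phase FIR band-pass filtering (transition width 25% of each band
edge) of the average-referenced epochs, followed by the analytic signal;
0.25 s per epoch edge is discarded against filter transients.  The sign is
averaged over the retained samples of **all** epochs before the absolute
value is taken.  The per-epoch-then-average variant is available
(`pli_matrix(..., pooled=False)`) but carries a positive bias of order
sqrt(2/(π·n_eff)) per epoch — about 0.15 for theta-band signals on 5-s
epochs — which does not shrink with more epochs; the pooled default decays
toward zero under the null, which the validity checks require.

PLI is reported for theta, alpha, beta, and gamma.  Aggregates: global
(mean over all 171 unordered channel pairs) and region pairs (mean over
all cross pairs between two distinct lateralised region sets, e.g. OL–TL
= {O1} × {F7, T3, T5}); intra-regional pairs never enter region-pair
means.

## Group statistics

For each metric, the omnibus test over the three groups is chosen by a
fixed decision tree at α = 0.05: Shapiro–Wilk normality per group and a
chi-square goodness-of-fit test of the group sizes against equal counts;
if any group is non-normal or the sizes are significantly unequal,
Kruskal–Wallis (tie-corrected) with effect size
ε² = H/((n²−1)/(n+1)) and pairwise Wilcoxon rank-sum post-hocs; otherwise
Levene's test (mean-centred) decides between one-way ANOVA (pairwise
pooled-variance t) and Welch's ANOVA (pairwise Welch t), both with
η² = SS_between/SS_total (approximate under the Welch branch).  All
pairwise p-values receive Holm's step-down adjustment; every
assumption-check p-value is recorded so the branch taken is auditable.
Families are corrected within a metric only — many metrics are reported
side by side without a global correction, mirroring per-metric reporting
practice (a global-FDR switch would be a one-liner on the output table and
is deliberately not the default).

Numerical choices worth noting: the Kruskal–Wallis p-value is exact
(full enumeration of the permutation distribution) for pooled n ≤ 12,
chi-square (df = k−1) otherwise; rank-sum tests are exact for small
tie-free samples and use the tie/continuity-corrected normal approximation
otherwise; with exactly equal group variances and sizes Welch's F equals
the classic F divided by 1 + 1/(3(n−1)) — they agree only asymptotically.
Correlations follow the scale rule: Pearson for two interval variables,
Spearman when either is ordinal.

## Synthetic cohorts

Each channel of a synthetic subject is the sum of (i) a 1/f^χ Gaussian
background (χ = 1.2, PSD exponent; amplitude spectrum flattened below
0.5 Hz), (ii) per-band narrowband components — Gaussian noise shaped by a
raised-cosine band mask — scaled to target RMS amplitudes, (iii) shared
band-limited sources for coupled region pairs, mixed with weight κ (and
sqrt(1−κ²) of independent carrier) and delayed by 1/8 cycle at the band
centre in the second region so the PLI registers the coupling, and (iv)
0.5 µV white sensor noise.  All independent components are assembled as a
single complex spectrum per channel and inverted with one FFT, which keeps
a 98-subject cohort cheap enough to replicate hundreds of times.
Components are normalised to their target RMS in expectation, so band
power fluctuates with the spectral degrees of freedom as real EEG does.

Artifacts are injected at Poisson times: blink templates (0.3 s, 300–600
µV, weighted 1.0 on Fp1/Fp2, 0.4 on other frontal channels, 0.05
elsewhere) and broadband movement bursts (1–2 s, 500–1000 µV, all
channels).  The ground-truth event list doubles as the technician
annotation stream.

**The paper-like preset.** Baseline (PD-CogN) component amplitudes are
delta/theta/alpha/beta/gamma = 2.5/6.0/6.8/7.0/2.0 µV RMS over a 4 µV RMS
background, giving an alpha-dominant spectrum with alpha/theta ≈ 1.25 and
SPR ≈ 1.9.  The PD-D group differs by three factors solved analytically
from the targets *relative theta +1.1 percentage points*, *alpha/theta
−0.12*, and *absolute theta +3.17 dB*: a theta and an alpha oscillation
factor produce the two relative shifts, and a global amplitude scale then
lifts absolute theta (and with it all absolute powers) by the remaining
dB without touching any relative quantity.  PD-MCI sits halfway on the
log scale.  Theta-band coupling on four region pairs (PL–FR, OL–FR,
OL–TL, PL–TL) rises with severity (κ = 0.15/0.25/0.45).  Between-subject
dispersion is log-normal: a global amplitude scale with σ = 0.30
(absolute-power SD ≈ 2.6 dB) plus per-band jitter with σ = 0.03
(alpha/theta SD ≈ 0.11) — the same order as the emulated cohort's
dispersion, on its slightly cleaner side.  Ages and disease durations are
drawn from the cohort's group means/SDs; theta amplitude rises 0.2% per
year of age in all groups and alpha falls 0.4% per year of disease
duration in PD-MCI, so the correlation analyses recover the expected
directions.  `effect=0` collapses all three groups onto the PD-CogN model
(a null cohort).

What the generator does **not** emulate: biophysical forward modelling
and realistic cross-channel correlation structure of the background,
non-stationarity (drowsiness, vigilance drift), line-noise harmonics,
electrode drift and impedance artifacts, and any true spatial topography
beyond region-level amplitude scaling.  Passing the recovery tests
therefore shows that the pipeline measures what the generative model
encodes at realistic amplitudes, sample sizes and artifact rates — not
that it would reproduce a clinical study.

## Problem sizes in the validation suite

The test suite and `scripts/acceptance.py` validate at sizes chosen for
a desk-scale run: recovery cohorts use the full 43/30/25 group structure
with 60-s recordings at 128 Hz (the 0.5–45 Hz analysis range needs only
a 90 Hz rate; 128 Hz is a standard clinical decimation), 100 replicate
cohorts per arm in the tests and 30 in the acceptance script; null
calibration uses 1000 (tests) / 500 (script) replicates; the
artifact-rejection operating point is measured over 20 (tests) / 10
(script) seeded 180-s recordings.  EDF export writes 16-bit samples over
a ±1000 µV physical range in 1-s records with an EDF+ annotation stream;
truth tables carry the unrounded generator targets.

## Known limitations

* The global rejection threshold cannot repair a single bad channel; a
  channel-level variant (with interpolation) is out of scope.
* Welch-branch η² is the classical (not partial, not ω²) effect size and
  is only approximate under heteroscedasticity.
* Absolute dB levels depend on the 1 µV² reference and on the average
  reference (which removes the common-mode part of coupled sources), so
  they are comparable within this pipeline, not across packages.
* Region-pair PLI inherits the parity-based lateral split; other
  conventions would move electrode F7/F8 (here temporal, per the region
  definition used) and the midline handling.
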