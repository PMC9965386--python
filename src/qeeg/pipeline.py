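"""End-to-end orchestration: ingest -> preprocess -> spectral -> PLI -> stats.

One configuration object drives the whole chain and the run is fully
deterministic given its seed.  Outputs are tidy tables:

* ``biomarkers`` — one row per subject x scope x metric (absolute dB and
  relative % band powers, alpha/theta ratio, SPR, per-band PLI),
* ``comparisons`` — one row per metric x scope with the chosen omnibus
  test, its statistic/p/effect size, the assumption-check p-values that
  drove the choice, and Holm-adjusted pairwise p-values,
* ``correlations`` — per-group correlations of global biomarkers with age
  and disease duration,
* ``epoch_status`` — per-subject epoch bookkeeping (kept/drop cause),

plus a JSON run log recording the configuration fingerprint and every
subject exclusion.  Subjects with fewer kept epochs than
``min_kept_epochs`` are excluded from statistics (and logged).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BandScheme, EEGRecording, build_standard_montage
from .connectivity import (
    NAMED_REGION_PAIRS, PLI_BANDS, aggregate_pli, band_phase, pli_matrix,
)
from .preprocess import PreprocessSettings, preprocess_recording
from .spectral import band_power_linear, multitaper_psd, total_power_linear
from .stats import GroupSample, correlate, select_and_run_omnibus


@dataclass
class PipelineConfig:
    """Parameters of a full pipeline run."""

    seed: int = 0
    crop: tuple[float, float] | None = (0.0, 180.0)
    notch_hz: float | None = 50.0
    highpass_hz: float | None = 0.1
    epoch_length_s: float = 5.0
    artifact_labels: tuple[str, ...] = ("movement", "blink", "speak", "bad")
    n_folds: int = 5
    bands: dict[str, tuple[float, float]] | None = None  # None -> defaults
    nw: float = 4.0
    pli_bands: tuple[str, ...] = PLI_BANDS  # empty tuple disables PLI
    pli_edge_trim_s: float = 0.25
    scopes: tuple[str, ...] = ("global", "regions", "lateral")
    alpha: float = 0.05
    min_kept_epochs: int = 10
    input_dir: str | None = None
    output_dir: str | None = None

    def band_scheme(self) -> BandScheme:
        return BandScheme() if self.bands is None else BandScheme(
            bands={k: tuple(v) for k, v in self.bands.items()})

    def preprocess_settings(self) -> PreprocessSettings:
        return PreprocessSettings(
            crop=self.crop, notch_hz=self.notch_hz,
            highpass_hz=self.highpass_hz, epoch_length_s=self.epoch_length_s,
            artifact_labels=tuple(self.artifact_labels),
            n_folds=self.n_folds, seed=self.seed,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(asdict(self))), fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, value in raw.items():
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)


@dataclass
class PipelineResult:
    biomarkers: pd.DataFrame
    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    epoch_status: pd.DataFrame
    log: dict = field(default_factory=dict)


def _scope_indices(config: PipelineConfig, montage) -> list[tuple[str, np.ndarray]]:
    """Scope label -> channel index array, per the configured scope set."""
    from .core import region_channels

    def idx(chans):
        return np.array([montage.index_of(c) for c in chans], dtype=int)

    scopes: list[tuple[str, np.ndarray]] = []
    if "global" in config.scopes:
        scopes.append(("global", np.arange(montage.n_channels)))
    if "regions" in config.scopes:
        scopes += [(r, idx(montage.regions[r])) for r in montage.regions]
    if "lateral" in config.scopes:
        for r in montage.regions:
            for lat in ("left", "right"):
                chans = region_channels(r, lat, montage)
                if chans:
                    scopes.append((f"{r}_{lat}", idx(chans)))
    return scopes


def process_subject(
    rec: EEGRecording, config: PipelineConfig
) -> tuple[list[dict], dict]:
    """Biomarker rows and a log entry for one recording."""
    scheme = config.band_scheme()
    epochs, model = preprocess_recording(rec, config.preprocess_settings())
    entry = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "drop_counts": epochs.drop_counts(),
        "rejection_threshold_uv":
            None if model is None else model.threshold,
        "included": epochs.n_kept >= config.min_kept_epochs,
        "status": list(map(str, epochs.status)),
    }
    if not entry["included"]:
        return [], entry

    psd = multitaper_psd(epochs, fmin=scheme.fmin, fmax=scheme.fmax,
                         nw=config.nw)
    linear = {b: band_power_linear(psd, b, scheme) for b in scheme.bands}
    total = total_power_linear(psd, scheme)
    metrics: dict[str, np.ndarray] = {}
    for band, p in linear.items():
        metrics[f"abs_{band}"] = 10.0 * np.log10(p)
        metrics[f"rel_{band}"] = 100.0 * p / total
    metrics["alpha_theta_ratio"] = linear["alpha"] / linear["theta"]
    metrics["spr"] = ((linear["alpha"] + linear["beta"])
                      / (linear["delta"] + linear["theta"]))
    rows = []
    for scope_name, chan_idx in _scope_indices(config, rec.montage):
        for metric, values in metrics.items():
            rows.append({
                "subject_id": rec.subject_id, "group": rec.group,
                "scope": scope_name, "metric": metric,
                "value": float(values[chan_idx].mean()),
            })
    for band in config.pli_bands:
        phases = band_phase(epochs, band, scheme,
                            edge_trim_s=config.pli_edge_trim_s)
        pli = pli_matrix(phases)
        rows.append({
            "subject_id": rec.subject_id, "group": rec.group,
            "scope": "global", "metric": f"pli_{band}",
            "value": aggregate_pli(pli, "global"),
        })
        for pair_name, pair in NAMED_REGION_PAIRS.items():
            rows.append({
                "subject_id": rec.subject_id, "group": rec.group,
                "scope": pair_name, "metric": f"pli_{band}",
                "value": aggregate_pli(pli, pair),
            })
    return rows, entry


def compare_groups(biomarkers: pd.DataFrame,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Run the adaptive omnibus + post-hoc machinery per metric x scope."""
    out = []
    for (metric, scope), chunk in biomarkers.groupby(["metric", "scope"]):
        groups = {g: sub["value"].to_numpy()
                  for g, sub in chunk.groupby("group")}
        if len(groups) < 2 or any(len(v) < 3 for v in groups.values()):
            continue
        try:
            res = select_and_run_omnibus(
                GroupSample(metric=metric, groups=groups), alpha=alpha)
        except ValueError:
            continue
        row = {
            "metric": metric, "scope": scope, "test": res.test,
            "statistic": res.statistic, "p_value": res.p_value,
            "effect_size": res.effect_size,
            "effect_size_label": res.effect_size_label,
        }
        for name, mean in chunk.groupby("group")["value"].mean().items():
            row[f"mean_{name}"] = mean
        for name, sd in chunk.groupby("group")["value"].std(ddof=1).items():
            row[f"sd_{name}"] = sd
        for key, val in res.assumptions.items():
            row[f"assump_{key}"] = val
        for _, pw in res.pairwise.iterrows():
            tag = f"{pw.group_a}_vs_{pw.group_b}"
            row[f"p_raw_{tag}"] = pw.p_raw
            row[f"p_holm_{tag}"] = pw.p_holm
        out.append(row)
    return pd.DataFrame(out)


#: (biomarker metric, covariate) pairs correlated within each group.
CORRELATION_PAIRS = (
    ("abs_theta", "age"), ("abs_low_alpha", "age"),
    ("alpha_theta_ratio", "duration_years"), ("spr", "duration_years"),
)


def correlate_with_covariates(biomarkers: pd.DataFrame,
                              metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-group Pearson correlations of global biomarkers with covariates."""
    rows = []
    glob = biomarkers[biomarkers.scope == "global"]
    merged = glob.merge(metadata, on="subject_id", suffixes=("", "_meta"))
    for (metric, covar) in CORRELATION_PAIRS:
        sub = merged[merged.metric == metric]
        if covar not in sub.columns or sub.empty:
            continue
        for group, chunk in sub.groupby("group"):
            if len(chunk) < 3 or np.ptp(chunk[covar].to_numpy()) == 0:
                continue
            res = correlate(chunk[covar], chunk["value"],
                            scales="interval-interval",
                            names=(covar, metric))
            rows.append({
                "group": group, "metric": metric, "covariate": covar,
                "method": res.method, "r": res.r, "p_value": res.p_value,
                "n": res.n,
            })
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    recordings=None,
    metadata: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full chain over an iterable of recordings (or an EDF dir).

    ``recordings`` may be any iterable of :class:`EEGRecording` (e.g. a
    synthetic :class:`~qeeg.synthetic.Cohort`'s ``iter_recordings()``); if
    omitted, ``config.input_dir`` must point at a directory of EDF files
    with a ``metadata.csv`` (columns ``subject_id``, ``group``, optionally
    ``age``/``duration_years``; ``subject_id`` matches the EDF stem).
    """
    montage = build_standard_montage()
    if recordings is None:
        if config.input_dir is None:
            raise ValueError("need recordings or config.input_dir")
        from .io import read_recording

        indir = Path(config.input_dir)
        metadata = pd.read_csv(indir / "metadata.csv")
        recordings = (
            read_recording(indir / f"{row.subject_id}.edf", montage,
                           subject_id=row.subject_id, group=row.group)
            for row in metadata.itertuples()
        )

    bio_rows, log_entries, status_rows = [], [], []
    for rec in recordings:
        rows, entry = process_subject(rec, config)
        bio_rows += rows
        log_entries.append(entry)
        for i, st in enumerate(entry.pop("status")):
            status_rows.append({"subject_id": entry["subject_id"],
                                "epoch_index": i, "status": st})

    biomarkers = pd.DataFrame(bio_rows)
    comparisons = compare_groups(biomarkers, alpha=config.alpha) \
        if not biomarkers.empty else pd.DataFrame()
    correlations = (
        correlate_with_covariates(biomarkers, metadata)
        if metadata is not None and not biomarkers.empty else pd.DataFrame()
    )
    log = {
        "config": asdict(config),
        "n_subjects": len(log_entries),
        "n_included": sum(e["included"] for e in log_entries),
        "excluded": [e["subject_id"] for e in log_entries
                     if not e["included"]],
        "subjects": log_entries,
    }
    result = PipelineResult(
        biomarkers=biomarkers, comparisons=comparisons,
        correlations=correlations, epoch_status=pd.DataFrame(status_rows),
        log=log,
    )
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.biomarkers.to_csv(outdir / "biomarkers.csv", index=False,
                                 float_format="%.10g")
        result.comparisons.to_csv(outdir / "group_comparison.csv",
                                  index=False, float_format="%.10g")
        result.correlations.to_csv(outdir / "correlations.csv", index=False,
                                   float_format="%.10g")
        result.epoch_status.to_csv(outdir / "epoch_status.csv", index=False)
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, default=str)
    return result
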