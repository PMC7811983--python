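"""End-to-end study pipeline: simulate → preprocess → features → associate →
segment, with a single serialisable configuration and persisted intermediates.

Every numeric constant of the analysis (filter edges, epoch/tract lengths,
band edges via the spectral module, rejection thresholds, Bonferroni family
size, perfusion thresholds) lives in :class:`RunConfig`; a run writes its
configuration verbatim into the output directory, and re-running with an
identical configuration reproduces the feature and report tables
byte-identically.  Patients that fail a stage are excluded with a logged
reason, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imaging, io, spectral, stats, synthetic
from .preprocess import (
    DEFAULT_AMP_THRESH_UV,
    DEFAULT_BANDPASS,
    DEFAULT_FILTER_ORDER,
    DEFAULT_FLAT_SD_THRESH_UV,
    InsufficientCleanDataError,
    bandpass_filter,
    select_clean_segment,
)

logger = logging.getLogger("strokeqeeg")

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class PreprocessConfig:
    bandpass_low: float = DEFAULT_BANDPASS[0]
    bandpass_high: float = DEFAULT_BANDPASS[1]
    filter_order: int = DEFAULT_FILTER_ORDER
    amp_thresh: float = DEFAULT_AMP_THRESH_UV
    flat_sd_thresh: float = DEFAULT_FLAT_SD_THRESH_UV
    target_seconds: float = 120.0


@dataclass(frozen=True)
class SpectralConfig:
    tract_s: float = spectral.DEFAULT_TRACT_S
    window: str = "hann"
    average_method: str = "mean_of_ratios"


@dataclass(frozen=True)
class ImagingConfig:
    enabled: bool = True
    grow_window_low: float = imaging.DEFAULT_GROW_WINDOW[0]
    grow_window_high: float = imaging.DEFAULT_GROW_WINDOW[1]
    mtt_ratio: float = imaging.MTT_RATIO_THRESHOLD
    cbv_core: float = imaging.CBV_CORE_THRESHOLD
    midline_axis: int = 0


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one pipeline run (serialisable to YAML)."""

    output_dir: str = "run_output"
    eeg_dir: str | None = None
    outcome_table: str | None = None
    imaging_dir: str | None = None
    simulate: bool = True
    seed: int = 0
    log_level: str = "INFO"
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    stats: stats.StatsConfig = field(default_factory=stats.StatsConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        nested = {
            "cohort": synthetic.CohortConfig,
            "preprocess": PreprocessConfig,
            "spectral": SpectralConfig,
            "stats": stats.StatsConfig,
            "imaging": ImagingConfig,
        }
        kwargs: dict = {}
        for key, sub_cls in nested.items():
            if key in data:
                kwargs[key] = sub_cls(**data.pop(key))
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass(frozen=True)
class Exclusion:
    patient_id: str
    stage: str
    reason: str


@dataclass(frozen=True)
class StudyReport:
    """Everything one run produces, with file-level persistence paths."""

    features: pd.DataFrame
    report: stats.CorrelationReport
    descriptives: pd.DataFrame
    exclusions: tuple[Exclusion, ...]
    segmentation: pd.DataFrame | None
    ctp: pd.DataFrame | None
    output_dir: Path
    config_hash: str


def cohort_descriptives(outcomes: dict[str, stats.PatientOutcomes]) -> pd.DataFrame:
    """Median and (min–max) range for each numeric outcome, cohort-wide."""
    if not outcomes:
        raise ValueError("need at least one patient")
    df = io.outcomes_frame(outcomes)
    rows = []
    for col in df.columns:
        vals = df[col].astype(float)
        rows.append(
            {
                "outcome": col,
                "median": float(vals.median()),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "n": int(vals.notna().sum()),
            }
        )
    return pd.DataFrame(rows).set_index("outcome")


def simulate_inputs(config: RunConfig, input_dir: Path) -> None:
    """Generate the synthetic cohort and persist it in study formats."""
    eeg_dir = input_dir / "eeg"
    img_dir = input_dir / "imaging"
    eeg_dir.mkdir(parents=True, exist_ok=True)
    img_dir.mkdir(parents=True, exist_ok=True)
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    patients = synthetic.generate_cohort(cohort_cfg)
    outcomes: dict[str, stats.PatientOutcomes] = {}
    truth_rows = []
    for p in patients:
        io.write_edf(p.recording, eeg_dir / f"{p.patient_id}.edf")
        io.write_nifti(
            p.volume_image.voxels, p.volume_image.spacing,
            img_dir / f"{p.patient_id}_nect.nii.gz",
        )
        io.write_nifti(
            p.perfusion.mtt, p.perfusion.spacing, img_dir / f"{p.patient_id}_mtt.nii.gz"
        )
        io.write_nifti(
            p.perfusion.cbv, p.perfusion.spacing, img_dir / f"{p.patient_id}_cbv.nii.gz"
        )
        outcomes[p.patient_id] = p.outcomes
        truth_rows.append(
            {
                "id": p.patient_id,
                "true_severity": p.true_severity,
                "true_volume_ml": p.true_volume_ml,
                "contaminated_epochs": ";".join(map(str, p.contaminated_epochs)),
            }
        )
    io.write_outcomes(outcomes, input_dir / "outcomes.csv")
    pd.DataFrame(truth_rows).to_csv(
        input_dir / "ground_truth.csv", index=False, float_format=_FLOAT_FMT
    )
    logger.info("simulated %d patients into %s", len(patients), input_dir)


def _extract_patient_features(
    rec, config: RunConfig
) -> tuple[spectral.ScalpFeatures, spectral.QEEGFeatures, object]:
    pp = config.preprocess
    filtered = bandpass_filter(
        rec, low=pp.bandpass_low, high=pp.bandpass_high, order=pp.filter_order
    )
    seg = select_clean_segment(
        filtered,
        target_s=pp.target_seconds,
        amp_thresh=pp.amp_thresh,
        flat_sd_thresh=pp.flat_sd_thresh,
    )
    feats = spectral.extract_features(
        seg, tract_s=config.spectral.tract_s, window=config.spectral.window
    )
    scalp = spectral.scalp_average(feats, method=config.spectral.average_method)
    return scalp, feats, seg


def run_pipeline(config: RunConfig) -> StudyReport:
    """Execute every stage in order and persist all intermediates.

    Deterministic given the configuration (including seeds): rerunning with
    an identical config produces byte-identical tables.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    (out / "config.yaml").write_text(config.to_yaml())

    if config.simulate:
        input_dir = out / "input"
        simulate_inputs(config, input_dir)
        eeg_dir = input_dir / "eeg"
        outcome_table = input_dir / "outcomes.csv"
        imaging_dir = input_dir / "imaging"
    else:
        if not (config.eeg_dir and config.outcome_table):
            raise ValueError("eeg_dir and outcome_table required when simulate=False")
        eeg_dir = Path(config.eeg_dir)
        outcome_table = Path(config.outcome_table)
        imaging_dir = Path(config.imaging_dir) if config.imaging_dir else None

    edf_files = sorted(eeg_dir.glob("*.edf"))
    if not edf_files:
        raise FileNotFoundError(f"no EDF files found in {eeg_dir}")
    outcomes = io.read_outcomes(outcome_table)

    exclusions: list[Exclusion] = []
    feature_rows: list[dict] = []
    channel_rows: list[dict] = []
    segment_rows: list[dict] = []
    for edf_path in edf_files:
        pid = edf_path.stem
        try:
            rec = io.read_edf(edf_path)
            scalp, per_channel, seg = _extract_patient_features(rec, config)
        except InsufficientCleanDataError as err:
            logger.warning("excluding %s at preprocess: %s", pid, err)
            exclusions.append(Exclusion(pid, "preprocess", str(err)))
            continue
        except Exception as err:  # propagate with stage context
            raise RuntimeError(f"patient {pid}, stage features: {err}") from err
        feature_rows.append({"id": pid, **scalp.as_dict()})
        segment_rows.append(
            {
                "id": pid,
                "epoch_indices": ";".join(map(str, seg.epoch_indices)),
                "n_rejected": sum(1 for v in seg.rejection_log if not v.passed),
            }
        )
        for c, label in enumerate(per_channel.channel_labels):
            channel_rows.append(
                {
                    "id": pid,
                    "channel": label,
                    "rel_delta": per_channel.rel_delta[c],
                    "rel_theta": per_channel.rel_theta[c],
                    "rel_alpha": per_channel.rel_alpha[c],
                    "rel_beta": per_channel.rel_beta[c],
                    "dar": per_channel.dar[c],
                    "dtabr": per_channel.dtabr[c],
                }
            )

    if not feature_rows:
        raise RuntimeError("no patient yielded a clean 120 s segment")
    features = pd.DataFrame(feature_rows).set_index("id").sort_index()
    features.to_csv(out / "features.csv", float_format=_FLOAT_FMT)
    pd.DataFrame(channel_rows).to_csv(
        out / "features_per_channel.csv", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(segment_rows).to_csv(out / "clean_segments.csv", index=False)
    pd.DataFrame(
        [dataclasses.asdict(e) for e in exclusions],
        columns=["patient_id", "stage", "reason"],
    ).to_csv(out / "exclusions.csv", index=False)

    included = {pid: o for pid, o in outcomes.items() if pid in features.index}
    missing_outcomes = sorted(set(features.index) - set(included))
    if missing_outcomes:
        raise ValueError(f"no outcome rows for patients: {missing_outcomes}")
    outcome_df = io.outcomes_frame(included)
    report = stats.run_association_study(features, outcome_df, config.stats)
    report.correlation_table().to_csv(out / "correlations.csv", float_format=_FLOAT_FMT)
    report.logistic_table().to_csv(out / "logistic.csv", float_format=_FLOAT_FMT)

    descriptives = cohort_descriptives(included)
    descriptives.to_csv(out / "descriptives.csv", float_format=_FLOAT_FMT)

    segmentation = ctp = None
    if config.imaging.enabled and imaging_dir is not None and Path(imaging_dir).is_dir():
        segmentation, ctp = _imaging_stage(Path(imaging_dir), out, config)

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_patients_in": len(edf_files),
        "n_patients_analysed": int(len(features)),
        "versions": _versions(),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))

    return StudyReport(
        features=features,
        report=report,
        descriptives=descriptives,
        exclusions=tuple(exclusions),
        segmentation=segmentation,
        ctp=ctp,
        output_dir=out,
        config_hash=config.config_hash(),
    )


def _imaging_stage(
    imaging_dir: Path, out: Path, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    cfg = config.imaging
    window = (cfg.grow_window_low, cfg.grow_window_high)
    seg_rows, ctp_rows = [], []
    for nect in sorted(imaging_dir.glob("*_nect.nii*")):
        pid = nect.name.split("_nect")[0]
        vol = io.read_labeled_volume(nect)
        seed_point = np.unravel_index(int(np.argmax(vol.voxels)), vol.voxels.shape)
        try:
            mask = imaging.region_grow(vol, seed_point, window)
            volume_ml = imaging.mask_volume_ml(mask, vol.spacing)
        except imaging.SeedOutsideWindowError:
            # brightest voxel below the lesion window → no lesion present
            volume_ml = 0.0
        seg_rows.append({"id": pid, "segmented_volume_ml": volume_ml})
        mtt_path = imaging_dir / nect.name.replace("_nect", "_mtt")
        cbv_path = imaging_dir / nect.name.replace("_nect", "_cbv")
        if mtt_path.exists() and cbv_path.exists():
            maps = io.read_perfusion_maps(mtt_path, cbv_path, cfg.midline_axis)
            res = imaging.classify_core_penumbra(maps, cfg.mtt_ratio, cfg.cbv_core)
            ctp_rows.append(
                {
                    "id": pid,
                    "core_ml": res.core_ml,
                    "penumbra_ml": res.penumbra_ml,
                    "total_hypoperfused_ml": res.total_hypoperfused_ml,
                    "mismatch": res.mismatch,
                }
            )
    segmentation = pd.DataFrame(seg_rows)
    ctp = pd.DataFrame(ctp_rows)
    segmentation.to_csv(out / "segmentation.csv", index=False, float_format=_FLOAT_FMT)
    ctp.to_csv(out / "ctp.csv", index=False, float_format=_FLOAT_FMT)
    return segmentation, ctp


def _versions() -> dict[str, str]:
    import importlib.metadata as md

    out = {}
    for pkg in ("strokeqeeg", "numpy", "scipy", "pandas", "statsmodels", "mne", "nibabel"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            out[pkg] = "unknown"
    return out
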