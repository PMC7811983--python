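"""Synthetic stroke cohort with known ground truth.

No patient data accompanies the study design this package implements, so
every downstream stage is exercised on simulated patients: 19-channel scalp
EEG whose spectrum shifts from alpha-dominant toward delta-dominant with a
scalar severity, clinical outcomes (NIHSS, mRS, final infarct volume)
monotonically coupled to the same severity, a follow-up volume containing a
compact lesion of exactly known voxel volume, and paired MTT/CBV perfusion
maps honouring the core/penumbra thresholds.

Signal model per channel: 1/f^gamma background noise plus four band-limited
Gaussian-noise oscillators (delta, theta, alpha, beta).  Oscillator
amplitudes interpolate linearly between a healthy alpha-dominant gain vector
and a stroke delta-dominant one, so every spectral biomarker is a monotone
function of severity by construction.  Everything is a pure function of its
arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .imaging import LabeledVolume, PerfusionMaps
from .preprocess import EPOCH_SECONDS, MONTAGE_10_20, EEGRecording
from .stats import PatientOutcomes

# --- spectral model constants ----------------------------------------------

#: RMS amplitude (µV) of a unit-gain band oscillator.
OSCILLATOR_RMS_UV = 5.0
#: RMS amplitude (µV) of the broadband 1/f^gamma background.
BACKGROUND_RMS_UV = 5.0
#: Pass bands (Hz) of the four oscillators.
OSCILLATOR_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}
#: Healthy gain vector: alpha-dominant spectrum.
HEALTHY_GAINS = {"delta": 0.7, "theta": 0.8, "alpha": 2.0, "beta": 0.7}
#: Stroke gain vector: delta-dominant (cortical slowing).
STROKE_GAINS = {"delta": 2.2, "theta": 1.2, "alpha": 0.6, "beta": 0.4}
DEFAULT_BACKGROUND_EXPONENT = 1.0

# --- outcome model constants -----------------------------------------------

#: Logistic mean curve for admission NIHSS: steepness and midpoint chosen so
#: a uniform-severity cohort has median admission NIHSS ≈ 10 of 42.
NIHSS_STEEPNESS = 6.0
NIHSS_MIDPOINT = 0.7
NIHSS_MAX = 42.0
#: Recovery factors applied to the admission mean curve at 7 days / 12 months.
RECOVERY_7D = 0.4
RECOVERY_12M = 0.25
#: 12-month NIHSS cut points mapping to mRS 1..6.
MRS_NIHSS_CUTS = (1, 2, 4, 6, 8, 10)
#: Volume model: volume_scale · severity^k · lognormal noise.
DEFAULT_VOLUME_EXPONENT = 4.5
DEFAULT_VOLUME_NOISE_SD = 0.4

# --- imaging model constants -----------------------------------------------

LESION_INTENSITY = 80.0
BACKGROUND_INTENSITY = 40.0
IMAGE_NOISE_SD = 2.0
BASELINE_MTT = 4.0
BASELINE_CBV = 4.0
LESION_MTT_FACTOR = 1.8   # MTT elevation inside the lesion (>1.45)
CORE_CBV = 1.0            # CBV inside the necrotic core (<2.0)
PENUMBRA_CBV = 3.0        # CBV in the non-core lesion (≥2.0)


@dataclass(frozen=True)
class SeverityProfile:
    """Spectral consequence of a scalar stroke severity in [0, 1]."""

    severity: float
    alpha_gain: float
    delta_gain: float
    theta_gain: float
    beta_gain: float
    background_exponent: float = DEFAULT_BACKGROUND_EXPONENT

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"severity must be in [0, 1], got {self.severity}")

    @classmethod
    def from_severity(
        cls, severity: float, background_exponent: float = DEFAULT_BACKGROUND_EXPONENT
    ) -> "SeverityProfile":
        """Linear interpolation between the healthy and stroke gain vectors."""
        if not 0.0 <= severity <= 1.0:
            raise ValueError(f"severity must be in [0, 1], got {severity}")
        g = {
            b: (1.0 - severity) * HEALTHY_GAINS[b] + severity * STROKE_GAINS[b]
            for b in OSCILLATOR_BANDS
        }
        return cls(
            severity=severity,
            delta_gain=g["delta"],
            theta_gain=g["theta"],
            alpha_gain=g["alpha"],
            beta_gain=g["beta"],
            background_exponent=background_exponent,
        )

    @property
    def gains(self) -> dict[str, float]:
        return {
            "delta": self.delta_gain,
            "theta": self.theta_gain,
            "alpha": self.alpha_gain,
            "beta": self.beta_gain,
        }


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated cohort."""

    n_patients: int = 20
    duration_s: float = 300.0
    fs: float = 128.0
    n_channels: int = 19
    outcome_noise_sd: float = 1.0
    volume_scale: float = 116.0
    volume_exponent: float = DEFAULT_VOLUME_EXPONENT
    artifact_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.fs <= 60.0:
            raise ValueError("fs must exceed twice the beta band (60 Hz)")
        expected_bad = self.artifact_rate * self.duration_s / EPOCH_SECONDS
        if self.duration_s < 120.0 + EPOCH_SECONDS * expected_bad:
            raise ValueError(
                "duration_s too short to leave a clean 120 s segment with "
                f"high probability at artifact_rate={self.artifact_rate}"
            )


@dataclass(frozen=True)
class SyntheticPatient:
    patient_id: str
    recording: EEGRecording
    outcomes: PatientOutcomes
    true_severity: float
    true_volume_ml: float
    volume_image: LabeledVolume
    perfusion: PerfusionMaps
    contaminated_epochs: tuple[int, ...] = field(default=())


# ---------------------------------------------------------------------------
# EEG generation


def _pink_noise(n: int, fs: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    return x / x.std()


def _band_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` (4th-order Butterworth)."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def generate_eeg(
    profile: SeverityProfile,
    duration_s: float,
    fs: float = 128.0,
    n_channels: int = 19,
    seed: int = 0,
) -> EEGRecording:
    """Multichannel EEG whose spectral content follows the severity profile.

    Each channel is an independent realisation of the same spectral model:
    1/f^gamma background plus the four band-limited oscillators scaled by the
    profile's gains.  Channels carry 10-20 labels.  Bit-identical for
    identical arguments.
    """
    if duration_s < EPOCH_SECONDS:
        raise ValueError(f"duration_s must be at least {EPOCH_SECONDS:g} s")
    if fs < 64.0:
        raise ValueError("fs must be at least 64 Hz")
    if not 1 <= n_channels <= len(MONTAGE_10_20):
        raise ValueError(f"n_channels must be in 1..{len(MONTAGE_10_20)}")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    gains = profile.gains
    channels = np.empty((n_channels, n))
    for c in range(n_channels):
        x = BACKGROUND_RMS_UV * _pink_noise(n, fs, profile.background_exponent, rng)
        for band_name, edges in OSCILLATOR_BANDS.items():
            x = x + (
                OSCILLATOR_RMS_UV
                * gains[band_name]
                * _band_noise(n, fs, edges, rng)
            )
        channels[c] = x
    return EEGRecording(
        samples=channels,
        fs=fs,
        channel_labels=MONTAGE_10_20[:n_channels],
    )


def inject_artifacts(
    rec: EEGRecording, artifact_rate: float, seed: int = 0
) -> tuple[EEGRecording, tuple[int, ...]]:
    """Contaminate a random subset of 10 s epochs; returns the new recording
    and the sorted indices of contaminated epochs.

    Each contaminated epoch receives either a high-amplitude biphasic
    transient (10× the channel's SD, at least 150 µV — above the default
    100 µV rejection threshold) or a full-epoch flatline on one channel
    (driving that channel's epoch SD to zero).  ``artifact_rate=0`` returns
    the input unchanged.
    """
    if not 0.0 <= artifact_rate < 1.0:
        raise ValueError(f"artifact_rate must be in [0, 1), got {artifact_rate}")
    if artifact_rate == 0.0:
        return rec, ()
    rng = np.random.default_rng(seed)
    samples_per_epoch = int(round(EPOCH_SECONDS * rec.fs))
    n_epochs = rec.n_samples // samples_per_epoch
    hit = np.nonzero(rng.random(n_epochs) < artifact_rate)[0]
    samples = rec.samples.copy()
    for e in hit:
        ch = int(rng.integers(rec.n_channels))
        start = e * samples_per_epoch
        segment = samples[ch, start : start + samples_per_epoch]
        if rng.random() < 0.5:  # transient
            amp = max(10.0 * segment.std(), 150.0)
            width = int(round(0.2 * rec.fs))
            pos = int(rng.integers(samples_per_epoch - 2 * width))
            segment[pos : pos + width] += amp
            segment[pos + width : pos + 2 * width] -= amp
        else:  # flatline for the whole epoch (≥ 2 s by a wide margin)
            segment[:] = segment.mean()
    out = EEGRecording(
        samples=samples,
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        start_time=rec.start_time,
        onset_to_eeg_min=rec.onset_to_eeg_min,
    )
    return out, tuple(int(e) for e in hit)


# ---------------------------------------------------------------------------
# Outcomes


def _nihss_mean(severity: float) -> float:
    """Logistic-shaped severity→NIHSS mean curve, pinned to 0 at severity 0
    and to the full 42-point scale at severity 1."""
    def sig(s: float) -> float:
        return 1.0 / (1.0 + np.exp(-NIHSS_STEEPNESS * (s - NIHSS_MIDPOINT)))

    return NIHSS_MAX * (sig(severity) - sig(0.0)) / (sig(1.0) - sig(0.0))


def _mrs_from_nihss(nihss_12m: int) -> int:
    return int(sum(nihss_12m >= cut for cut in MRS_NIHSS_CUTS))


def generate_outcomes(
    severity: float,
    noise_sd: float,
    volume_scale: float,
    seed: int = 0,
    volume_exponent: float = DEFAULT_VOLUME_EXPONENT,
    volume_noise_sd: float = DEFAULT_VOLUME_NOISE_SD,
) -> PatientOutcomes:
    """Clinical outcomes monotonically coupled to severity.

    NIHSS at each time point is a logistic-shaped monotone function of
    severity plus truncated Gaussian noise, integer-rounded and clipped to
    0–42; 12-month mRS is a monotone step function of the 12-month NIHSS;
    final infarct volume is ``volume_scale · severity^k`` with lognormal
    noise.  With ``noise_sd=0`` and severity 0 every score is 0.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must be in [0, 1], got {severity}")
    rng = np.random.default_rng(seed)
    base = _nihss_mean(severity)

    def score(mean: float) -> int:
        noisy = mean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        return int(np.clip(round(noisy), 0, NIHSS_MAX))

    nihss_admission = score(base)
    nihss_7d = score(RECOVERY_7D * base)
    nihss_12m = score(RECOVERY_12M * base)
    mrs_12m = _mrs_from_nihss(nihss_12m)
    mrs_premorbid = int(rng.choice([0, 1, 2, 3], p=[0.6, 0.2, 0.1, 0.1]))
    if severity == 0.0:
        volume = 0.0
    else:
        noise = (
            float(np.exp(rng.normal(0.0, volume_noise_sd)))
            if noise_sd > 0
            else 1.0
        )
        volume = volume_scale * severity**volume_exponent * noise
    return PatientOutcomes(
        nihss_admission=nihss_admission,
        nihss_7d=nihss_7d,
        nihss_12m=nihss_12m,
        mrs_premorbid=0 if noise_sd == 0 else mrs_premorbid,
        mrs_12m=mrs_12m,
        final_volume_ml=volume,
    )


# ---------------------------------------------------------------------------
# Lesion volume and perfusion maps


def generate_lesion_volume(
    true_volume_ml: float,
    grid_shape: tuple[int, int, int] = (84, 84, 84),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    seed: int = 0,
    midline_axis: int = 0,
) -> LabeledVolume:
    """Follow-up scan with an approximately ellipsoidal lesion of known volume.

    The lesion is the set of the N voxel centres closest to a random centre
    under a random mildly anisotropic ellipsoidal metric, where N matches
    the requested volume; its exact voxel count × voxel volume is the ground
    truth, recorded in the returned ``mask``.  Lesion intensity is distinct
    from background, with additive noise small enough that neither tissue
    strays into the other's region-growing window.  The lesion is confined
    to one side of the midline axis so perfusion maps can use the mirrored
    contralateral side as the healthy reference.
    """
    if true_volume_ml < 0:
        raise ValueError("true_volume_ml must be ≥ 0")
    rng = np.random.default_rng(seed)
    spacing = tuple(float(s) for s in spacing)
    shape = tuple(int(d) for d in grid_shape)
    voxel_ml = float(np.prod(spacing)) / 1000.0
    n_target = int(round(true_volume_ml / voxel_ml))
    voxels = BACKGROUND_INTENSITY + rng.normal(0.0, IMAGE_NOISE_SD, size=shape)
    mask = np.zeros(shape, dtype=bool)
    if n_target == 0:
        return LabeledVolume(voxels=voxels, spacing=spacing, mask=mask)

    ratios = rng.uniform(0.8, 1.2, size=3)
    # nominal ellipsoid radius (mm) for the requested volume, with a safety
    # margin covering anisotropy and voxelisation
    r_mm = (3.0 * true_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    a_max = 1.1 * r_mm * float(ratios.max())
    extents = np.array([d * s for d, s in zip(shape, spacing)])
    mid = extents[midline_axis]
    if a_max >= mid / 4.0 or np.any(a_max >= extents / 2.5):
        raise ValueError(
            f"{true_volume_ml} ml lesion (radius ≈ {r_mm:.0f} mm) does not "
            f"fit on one side of the midline in a {shape} grid at spacing "
            f"{spacing}"
        )
    centre = np.empty(3)
    for ax in range(3):
        if ax == midline_axis:
            lo, hi = mid / 2.0 + a_max, mid - a_max
        else:
            lo, hi = a_max, extents[ax] - a_max
        centre[ax] = rng.uniform(lo, hi)

    # evaluate the ellipsoidal metric only inside a bounding box
    los, his, axes_mm = [], [], []
    for ax in range(3):
        half = int(np.ceil(1.4 * a_max / spacing[ax])) + 2
        c_vox = int(centre[ax] / spacing[ax])
        lo = max(0, c_vox - half)
        hi = min(shape[ax], c_vox + half + 1)
        los.append(lo)
        his.append(hi)
        axes_mm.append((np.arange(lo, hi) + 0.5) * spacing[ax])
    gx, gy, gz = np.meshgrid(*axes_mm, indexing="ij")
    q = (
        ((gx - centre[0]) / ratios[0]) ** 2
        + ((gy - centre[1]) / ratios[1]) ** 2
        + ((gz - centre[2]) / ratios[2]) ** 2
    )
    flat = np.argsort(q, axis=None, kind="stable")[:n_target]
    box_mask = np.zeros(q.shape, dtype=bool)
    box_mask.flat[flat] = True
    mask[los[0] : his[0], los[1] : his[1], los[2] : his[2]] = box_mask
    voxels[mask] = LESION_INTENSITY + rng.normal(0.0, IMAGE_NOISE_SD, size=n_target)
    return LabeledVolume(voxels=voxels, spacing=spacing, mask=mask)


def generate_perfusion_maps(
    lesion: LabeledVolume, core_fraction: float, seed: int = 0, midline_axis: int = 0
) -> PerfusionMaps:
    """MTT/CBV maps consistent with the core/penumbra thresholds.

    MTT inside the lesion is elevated to 180% of the mirrored contralateral
    baseline (above the 145% hypoperfusion threshold); CBV drops below
    2.0 mL/100 g on the innermost ``core_fraction`` of lesion voxels (by
    distance from the lesion centroid) and stays at 3.0 elsewhere in the
    lesion.  Outside the lesion both maps are mirror-symmetric, so the
    contralateral ratio is exactly 1.
    """
    if not 0.0 <= core_fraction <= 1.0:
        raise ValueError(f"core_fraction must be in [0, 1], got {core_fraction}")
    if lesion.mask is None:
        raise ValueError("lesion volume carries no mask")
    rng = np.random.default_rng(seed)
    shape = lesion.voxels.shape
    noise = rng.normal(0.0, 0.15, size=shape)
    sym = (noise + np.flip(noise, axis=midline_axis)) / 2.0
    mtt = BASELINE_MTT + sym
    cbv = np.full(shape, BASELINE_CBV) + sym
    mask = lesion.mask
    n_lesion = int(mask.sum())
    if n_lesion:
        mirrored = np.flip(mtt, axis=midline_axis)
        mtt = mtt.copy()
        mtt[mask] = LESION_MTT_FACTOR * mirrored[mask]
        coords = np.argwhere(mask).astype(float) * np.array(lesion.spacing)
        centroid = coords.mean(axis=0)
        dist = np.linalg.norm(coords - centroid, axis=1)
        n_core = int(round(core_fraction * n_lesion))
        inner = np.argsort(dist, kind="stable")[:n_core]
        lesion_idx = np.argwhere(mask)
        cbv[mask] = PENUMBRA_CBV
        ci = lesion_idx[inner]
        cbv[ci[:, 0], ci[:, 1], ci[:, 2]] = CORE_CBV
    return PerfusionMaps(mtt=mtt, cbv=cbv, spacing=lesion.spacing, midline_axis=midline_axis)


# ---------------------------------------------------------------------------
# Whole-cohort assembly


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Seeded cohort: independent patients with severities uniform on [0, 1].

    Per-patient randomness is derived from ``config.seed`` through a
    ``SeedSequence`` spawn, so the cohort is reproducible as a whole and any
    patient is independent of cohort size-neutral ordering.
    """
    root = np.random.SeedSequence(config.seed)
    severity_rng = np.random.default_rng(root.spawn(1)[0])
    severities = severity_rng.uniform(0.0, 1.0, size=config.n_patients)
    patients: list[SyntheticPatient] = []
    for i, severity in enumerate(severities):
        sub = np.random.SeedSequence(entropy=config.seed, spawn_key=(i + 1,))
        seeds = [int(s) for s in sub.generate_state(5) % (2**31)]
        profile = SeverityProfile.from_severity(float(severity))
        rec = generate_eeg(
            profile,
            duration_s=config.duration_s,
            fs=config.fs,
            n_channels=config.n_channels,
            seed=seeds[0],
        )
        rec, contaminated = inject_artifacts(rec, config.artifact_rate, seed=seeds[1])
        outcomes = generate_outcomes(
            float(severity),
            noise_sd=config.outcome_noise_sd,
            volume_scale=config.volume_scale,
            seed=seeds[2],
            volume_exponent=config.volume_exponent,
        )
        volume_image = generate_lesion_volume(
            outcomes.final_volume_ml, seed=seeds[3]
        )
        true_volume = (
            float(volume_image.mask.sum()) * volume_image.voxel_volume_mm3 / 1000.0
        )
        perfusion = generate_perfusion_maps(
            volume_image, core_fraction=float(severity_rng.uniform(0.0, 1.0)),
            seed=seeds[4],
        )
        patients.append(
            SyntheticPatient(
                patient_id=f"P{i + 1:03d}",
                recording=rec,
                outcomes=outcomes,
                true_severity=float(severity),
                true_volume_ml=true_volume,
                volume_image=volume_image,
                perfusion=perfusion,
                contaminated_epochs=contaminated,
            )
        )
    return patients
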