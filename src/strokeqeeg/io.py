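"""File formats: EDF for EEG, delimited tables for outcomes, NIfTI for volumes.

Reading EDF goes through MNE (:func:`mne.io.read_raw_edf`).  Writing uses a
minimal EDF encoder implemented here: the format is a fixed-layout ASCII
header plus 16-bit little-endian sample records, one second per record.
Round-tripping through MNE's reader is covered by the test suite; the
16-bit quantisation error is bounded by (physical range)/65535 per sample,
far below any feature tolerance.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .imaging import LabeledVolume, PerfusionMaps
from .preprocess import EEGRecording
from .stats import PatientOutcomes

OUTCOME_COLUMNS = (
    "id",
    "nihss_admission",
    "nihss_7d",
    "nihss_12m",
    "mrs_premorbid",
    "mrs_12m",
    "volume_ml",
)

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as EDF (one-second data records, 16-bit samples).

    Requires an integer sampling rate and a whole number of seconds of data
    (trailing partial seconds are truncated with a strict check against
    silent data loss of more than one second).
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF export requires an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per record (1 s records)
    n_records = rec.n_samples // spr
    if n_records == 0:
        raise ValueError("recording shorter than one EDF record (1 s)")
    if rec.n_samples - n_records * spr >= spr:
        raise ValueError("internal truncation error")

    data = rec.samples[:, : n_records * spr]
    phys_min = np.floor(data.min(axis=1))
    phys_max = np.ceil(data.max(axis=1))
    flat = phys_max <= phys_min
    phys_max[flat] = phys_min[flat] + 1.0

    ns = rec.n_channels
    buf = _io.BytesIO()
    start = rec.start_time
    date = start.strftime("%d.%m.%y") if start else "01.01.00"
    time = start.strftime("%H.%M.%S") if start else "00.00.00"
    buf.write(_ascii("0", 8))
    buf.write(_ascii("X X X X", 80))
    buf.write(_ascii("Startdate X X X X", 80))
    buf.write(_ascii(date, 8))
    buf.write(_ascii(time, 8))
    buf.write(_ascii(256 * (ns + 1), 8))
    buf.write(_ascii("", 44))
    buf.write(_ascii(n_records, 8))
    buf.write(_ascii(1, 8))
    buf.write(_ascii(ns, 4))
    for label in rec.channel_labels:
        buf.write(_ascii(f"EEG {label}", 16))
    for _ in range(ns):
        buf.write(_ascii("AgAgCl electrode", 80))
    for _ in range(ns):
        buf.write(_ascii("uV", 8))
    for v in phys_min:
        buf.write(_ascii(f"{v:.8g}"[:8], 8))
    for v in phys_max:
        buf.write(_ascii(f"{v:.8g}"[:8], 8))
    for _ in range(ns):
        buf.write(_ascii(_DIG_MIN, 8))
    for _ in range(ns):
        buf.write(_ascii(_DIG_MAX, 8))
    for _ in range(ns):
        buf.write(_ascii("", 80))
    for _ in range(ns):
        buf.write(_ascii(spr, 8))
    for _ in range(ns):
        buf.write(_ascii("", 32))

    scale = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    offset = phys_min - _DIG_MIN * scale
    digital = np.round((data - offset[:, None]) / scale[:, None])
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")
    # records: for each second, each channel's block in sequence
    reshaped = digital.reshape(ns, n_records, spr).transpose(1, 0, 2)
    buf.write(reshaped.tobytes())
    path.write_bytes(buf.getvalue())
    return path


def read_edf(path: str | Path) -> EEGRecording:
    """Load an EDF/EDF+ file into an :class:`EEGRecording` (µV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = tuple(name.removeprefix("EEG ").strip() for name in raw.ch_names)
    return EEGRecording(
        samples=raw.get_data() * 1e6,  # MNE stores volts
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
    )


# ---------------------------------------------------------------------------
# Outcome tables


def write_outcomes(outcomes: dict[str, PatientOutcomes], path: str | Path) -> Path:
    """One row per patient: id, NIHSS ×3, mRS ×2, final volume (ml)."""
    path = Path(path)
    rows = [
        {
            "id": pid,
            "nihss_admission": o.nihss_admission,
            "nihss_7d": o.nihss_7d,
            "nihss_12m": o.nihss_12m,
            "mrs_premorbid": o.mrs_premorbid,
            "mrs_12m": o.mrs_12m,
            "volume_ml": o.final_volume_ml,
        }
        for pid, o in sorted(outcomes.items())
    ]
    pd.DataFrame(rows, columns=list(OUTCOME_COLUMNS)).to_csv(
        path, index=False, float_format="%.6f"
    )
    return path


def read_outcomes(path: str | Path) -> dict[str, PatientOutcomes]:
    df = pd.read_csv(path)
    missing = set(OUTCOME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"outcome table missing columns: {sorted(missing)}")
    return {
        str(row["id"]): PatientOutcomes(
            nihss_admission=int(row["nihss_admission"]),
            nihss_7d=int(row["nihss_7d"]),
            nihss_12m=int(row["nihss_12m"]),
            mrs_premorbid=int(row["mrs_premorbid"]),
            mrs_12m=int(row["mrs_12m"]),
            final_volume_ml=float(row["volume_ml"]),
        )
        for _, row in df.iterrows()
    }


def outcomes_frame(outcomes: dict[str, PatientOutcomes]) -> pd.DataFrame:
    """Outcome table as a DataFrame indexed by patient id (analysis layout)."""
    return pd.DataFrame(
        {
            pid: {
                "nihss_admission": o.nihss_admission,
                "nihss_7d": o.nihss_7d,
                "nihss_12m": o.nihss_12m,
                "mrs_premorbid": o.mrs_premorbid,
                "mrs_12m": o.mrs_12m,
                "final_volume_ml": o.final_volume_ml,
            }
            for pid, o in sorted(outcomes.items())
        }
    ).T.rename_axis("id")


# ---------------------------------------------------------------------------
# NIfTI volumes


def write_nifti(
    array: np.ndarray, spacing: tuple[float, float, float], path: str | Path
) -> Path:
    path = Path(path)
    affine = np.diag([*spacing, 1.0])
    dtype = np.uint8 if array.dtype == bool else np.float32
    img = nib.Nifti1Image(np.asarray(array, dtype=dtype), affine)
    nib.save(img, str(path))
    return path


def read_labeled_volume(path: str | Path, mask_path: str | Path | None = None) -> LabeledVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).get_fdata() > 0.5)
    return LabeledVolume(
        voxels=np.asarray(img.get_fdata(), dtype=float), spacing=spacing, mask=mask
    )


def read_perfusion_maps(
    mtt_path: str | Path, cbv_path: str | Path, midline_axis: int = 0
) -> PerfusionMaps:
    mtt_img = nib.load(str(mtt_path))
    cbv_img = nib.load(str(cbv_path))
    spacing = tuple(float(z) for z in mtt_img.header.get_zooms()[:3])
    return PerfusionMaps(
        mtt=np.asarray(mtt_img.get_fdata(), dtype=float),
        cbv=np.asarray(cbv_img.get_fdata(), dtype=float),
        spacing=spacing,
        midline_axis=midline_axis,
    )
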