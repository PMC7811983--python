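"""Morphological outcome procedures on volumetric images.

Two operations mirror the clinical workflow: (1) seed-based region growing
on a follow-up non-enhanced CT to delineate the final infarct and measure
its volume in ml; (2) CT-perfusion core/penumbra classification — a voxel is
hypoperfused when its MTT exceeds 145% of the mirrored contralateral value,
and hypoperfused tissue splits into necrotic core (CBV < 2.0 mL/100 g) and
salvageable penumbra (CBV ≥ 2.0; the boundary value is assigned to
penumbra, conservative toward salvageable tissue).

The contralateral reference is a voxel-wise mirror across the stated midline
axis; no registration is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: MTT elevation defining hypoperfusion, relative to the mirrored side.
MTT_RATIO_THRESHOLD = 1.45
#: CBV (mL/100 g) below which hypoperfused tissue is necrotic core.
CBV_CORE_THRESHOLD = 2.0

#: Default region-growing intensity window for the synthetic follow-up scans.
DEFAULT_GROW_WINDOW = (70.0, 90.0)

_NEIGHBOR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.intp,
)


class SeedOutsideWindowError(ValueError):
    """The growth seed's intensity falls outside the homogeneity window."""


@dataclass(frozen=True)
class LabeledVolume:
    """3-D intensity grid with physical voxel spacing (mm per axis)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels, dtype=float)
        if voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        object.__setattr__(self, "voxels", voxels)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != voxels.shape:
                raise ValueError("mask shape must match voxels")
            object.__setattr__(self, "mask", mask)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class PerfusionMaps:
    """Paired CT-perfusion maps: MTT (relative time units) and CBV (mL/100 g)."""

    mtt: np.ndarray
    cbv: np.ndarray
    spacing: tuple[float, float, float]
    midline_axis: int = 0

    def __post_init__(self) -> None:
        mtt = np.asarray(self.mtt, dtype=float)
        cbv = np.asarray(self.cbv, dtype=float)
        if mtt.shape != cbv.shape or mtt.ndim != 3:
            raise ValueError("mtt and cbv must be 3-D arrays of equal shape")
        if np.any(mtt < 0) or np.any(cbv < 0):
            raise ValueError("perfusion maps must be non-negative")
        if not 0 <= self.midline_axis < 3:
            raise ValueError(f"midline_axis must be 0, 1 or 2, got {self.midline_axis}")
        object.__setattr__(self, "mtt", mtt)
        object.__setattr__(self, "cbv", cbv)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))


@dataclass(frozen=True)
class CorePenumbraResult:
    core_mask: np.ndarray
    penumbra_mask: np.ndarray
    core_ml: float
    penumbra_ml: float
    total_hypoperfused_ml: float
    mismatch: float  # penumbra / total hypoperfused; NaN when nothing is hypoperfused


def region_grow(
    vol: LabeledVolume,
    seed_point: tuple[int, int, int],
    intensity_window: tuple[float, float] = DEFAULT_GROW_WINDOW,
) -> np.ndarray:
    """Seed-based region growing with a fixed intensity window.

    Breadth-first growth from ``seed_point`` over 6-connected neighbours
    whose intensity lies within ``[low, high]``; terminates when the frontier
    is empty.  Deterministic: the result is the 6-connected component of the
    in-window voxel set that contains the seed.
    """
    low, high = intensity_window
    if low > high:
        raise ValueError(f"invalid window [{low}, {high}]")
    seed = tuple(int(i) for i in seed_point)
    shape = vol.voxels.shape
    if len(seed) != 3 or any(not 0 <= s < d for s, d in zip(seed, shape)):
        raise ValueError(f"seed {seed} outside grid of shape {shape}")
    seed_val = vol.voxels[seed]
    if not low <= seed_val <= high:
        raise SeedOutsideWindowError(
            f"seed intensity {seed_val:.2f} outside window [{low}, {high}]"
        )
    in_window = (vol.voxels >= low) & (vol.voxels <= high)
    mask = np.zeros(shape, dtype=bool)
    mask[seed] = True
    frontier = np.array([seed], dtype=np.intp)
    dims = np.array(shape, dtype=np.intp)
    while frontier.size:
        cand = frontier[:, None, :] + _NEIGHBOR_OFFSETS[None, :, :]
        cand = cand.reshape(-1, 3)
        ok = np.all((cand >= 0) & (cand < dims), axis=1)
        cand = cand[ok]
        idx = (cand[:, 0], cand[:, 1], cand[:, 2])
        grow = in_window[idx] & ~mask[idx]
        cand = cand[grow]
        if cand.size:
            # deduplicate voxels reached from several frontier cells
            flat = np.ravel_multi_index((cand[:, 0], cand[:, 1], cand[:, 2]), shape)
            _, uniq = np.unique(flat, return_index=True)
            cand = cand[uniq]
            mask[cand[:, 0], cand[:, 1], cand[:, 2]] = True
        frontier = cand
    return mask


def mask_volume_ml(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Volume of a binary mask in ml: voxel count × voxel volume (mm³) / 1000."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise ValueError("mask must be boolean")
    return float(mask.sum()) * float(np.prod(spacing)) / 1000.0


def classify_core_penumbra(
    maps: PerfusionMaps,
    mtt_ratio: float = MTT_RATIO_THRESHOLD,
    cbv_core: float = CBV_CORE_THRESHOLD,
) -> CorePenumbraResult:
    """Threshold the perfusion maps into necrotic core and salvageable penumbra.

    Hypoperfused tissue: MTT > ``mtt_ratio`` × the mirrored contralateral MTT.
    Core: hypoperfused with CBV < ``cbv_core``; penumbra: the rest of the
    hypoperfused region (CBV ≥ ``cbv_core``).  Mismatch is the penumbra
    fraction of total hypoperfused volume (NaN when nothing is hypoperfused).
    """
    if not np.any(maps.mtt > 0):
        raise ValueError("degenerate MTT map (all zero); classification undefined")
    mirrored = np.flip(maps.mtt, axis=maps.midline_axis)
    hypoperfused = maps.mtt > mtt_ratio * mirrored
    core = hypoperfused & (maps.cbv < cbv_core)
    penumbra = hypoperfused & ~core
    core_ml = mask_volume_ml(core, maps.spacing)
    penumbra_ml = mask_volume_ml(penumbra, maps.spacing)
    total = core_ml + penumbra_ml
    mismatch = penumbra_ml / total if total > 0 else float("nan")
    return CorePenumbraResult(
        core_mask=core,
        penumbra_mask=penumbra,
        core_ml=core_ml,
        penumbra_ml=penumbra_ml,
        total_hypoperfused_ml=total,
        mismatch=mismatch,
    )
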