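"""Per-organelle morphometry: volume, LAC, bead calibration, shape, FA.

Volume is voxel counting times the voxel volume.  Density is the mean (and
population SD) of reconstructed LAC under the organelle mask, reported both
raw (µm⁻¹) and as a dimensionless bead-normalized value: dividing by the
mean LAC measured inside the gold fiducials cancels any global gain a
tomogram picked up from background variation or reconstruction artefacts,
making densities comparable across tomograms.

Shape is summarized by the eigenvalues λ₁ ≥ λ₂ ≥ λ₃ of the second central
moment tensor of the mask voxel coordinates (the equivalent-ellipsoid
convention of 3D region properties) and condensed into the fractional
anisotropy

    FA = 100 · √(3/2) · √Σ(λᵢ − λ̄)² / √Σλᵢ² ,   λ̄ = (λ₁+λ₂+λ₃)/3,

which is 0 for an isotropic body, 100 for a fully one-dimensional one, and
invariant to scale and eigenvalue order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .recon import ReconVolume
from .segment import LabelVolume

__all__ = [
    "BeadCalibration",
    "ShapeEigenvalues",
    "organelle_volume",
    "organelle_lac",
    "calibrate_beads",
    "shape_eigenvalues",
    "fractional_anisotropy",
    "area_2d",
    "quantify_cell",
]


@dataclass(frozen=True)
class BeadCalibration:
    """Multiplicative LAC calibration derived from gold fiducial beads."""

    measured_bead_lac_mean: float  # µm⁻¹
    nominal_bead_lac: float  # µm⁻¹
    scale: float  # nominal / measured
    n_beads_used: int

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("calibration scale must be positive")
        if self.n_beads_used < 1:
            raise ValueError("at least one bead required")

    def normalize(self, lac: float | np.ndarray) -> float | np.ndarray:
        """Dimensionless bead-normalized LAC: measured / measured-bead-mean."""
        return lac * self.scale / self.nominal_bead_lac


@dataclass(frozen=True)
class ShapeEigenvalues:
    """Sorted second-moment eigenvalues (nm²) with a degeneracy flag."""

    l1: float
    l2: float
    l3: float
    degenerate: bool = False

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.l1, self.l2, self.l3)


def organelle_volume(mask_voxel_count: int, voxel_size: float) -> float:
    """Volume in nm³ = voxel count × voxel volume, exact."""
    if mask_voxel_count < 1:
        raise ValueError("mask_voxel_count must be >= 1")
    return float(mask_voxel_count) * float(voxel_size) ** 3


def organelle_lac(recon: ReconVolume, mask: np.ndarray) -> tuple[float, float]:
    """Mean and population SD of reconstructed LAC under a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(recon.lac, dtype=np.float64)[mask]
    return float(vals.mean()), float(vals.std(ddof=0))


def calibrate_beads(
    recon: ReconVolume,
    beads: LabelVolume,
    nominal_bead_lac: float = 8.0,
    erosion_iterations: int = 1,
) -> BeadCalibration:
    """Estimate a per-tomogram LAC gain from the gold fiducial beads.

    Bead masks are eroded (default one voxel) to drop the partial-volume
    shell before averaging; beads whose core erodes away fall back to the
    full mask.  ``scale`` is nominal/measured, so applying it to the bead
    LAC returns the nominal value by construction, and any global
    multiplicative gain of the tomogram cancels in normalized values.
    """
    bead_ids = beads.bead_ids or tuple(
        int(v) for v in np.unique(beads.labels) if v > 0
    )
    if not bead_ids:
        raise ValueError("no bead labels to calibrate on")
    lac = np.asarray(recon.lac, dtype=np.float64)
    core_vals = []
    for b in bead_ids:
        m = np.asarray(beads.labels) == b
        if erosion_iterations > 0:
            core = ndimage.binary_erosion(m, iterations=erosion_iterations)
            m = core if core.any() else m
        core_vals.append(lac[m])
    measured = float(np.concatenate(core_vals).mean())
    if measured <= 0:
        raise ValueError("measured bead LAC is non-positive; cannot calibrate")
    return BeadCalibration(
        measured_bead_lac_mean=measured,
        nominal_bead_lac=float(nominal_bead_lac),
        scale=float(nominal_bead_lac) / measured,
        n_beads_used=len(bead_ids),
    )


def shape_eigenvalues(mask: np.ndarray, voxel_size: float) -> ShapeEigenvalues:
    """Eigenvalues of the second central moment tensor of mask coordinates.

    Coordinates are voxel centers scaled by ``voxel_size`` (nm), so the
    eigenvalues carry nm²; FA is unaffected by that choice (scale
    invariance).  Rotation-invariant up to rasterization error.  Masks with
    fewer than 4 voxels or without full 3D rank are returned with zero
    eigenvalues where degenerate and flagged, not raised.
    """
    coords = np.argwhere(np.asarray(mask, dtype=bool)).astype(np.float64)
    if coords.shape[0] == 0:
        raise ValueError("empty mask")
    coords *= float(voxel_size)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / coords.shape[0]
    vals = np.linalg.eigvalsh(cov)[::-1]
    vals = np.clip(vals, 0.0, None)
    degenerate = coords.shape[0] < 4 or vals[2] <= 1e-12 * max(vals[0], 1.0)
    return ShapeEigenvalues(float(vals[0]), float(vals[1]), float(vals[2]), bool(degenerate))


def fractional_anisotropy(l1: float, l2: float, l3: float) -> float:
    """Fractional anisotropy (percent) of three shape-tensor eigenvalues.

    FA = 100·√(3/2)·√[(λ₁−λ̄)² + (λ₂−λ̄)² + (λ₃−λ̄)²] / √(λ₁²+λ₂²+λ₃²).

    Ranges over [0, 100]: 0 when all eigenvalues are equal (no preferential
    direction), 100 when all variance lies on a single axis.  Symmetric
    under permutation and invariant under positive rescaling of the triple.
    """
    lam = np.asarray([l1, l2, l3], dtype=np.float64)
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be nonnegative")
    denom = float(np.sum(lam**2))
    if denom == 0.0:
        raise ValueError("all-zero eigenvalues have undefined anisotropy")
    mean = lam.mean()
    fa = np.sqrt(1.5 * float(np.sum((lam - mean) ** 2)) / denom)
    return float(100.0 * min(fa, 1.0))


def area_2d(mask_slice: np.ndarray, pixel_size: float) -> float:
    """2D area in nm² = pixel count × pixel area (micrograph-style measure)."""
    mask_slice = np.asarray(mask_slice, dtype=bool)
    n = int(mask_slice.sum())
    if n == 0:
        raise ValueError("empty 2D mask")
    return float(n) * float(pixel_size) ** 2


def quantify_cell(
    recon: ReconVolume,
    labels: LabelVolume,
    calibration: BeadCalibration | None = None,
    cell_id: str = "",
    group: str = "",
    exclude_labels: tuple[int, ...] = (),
) -> pd.DataFrame:
    """One morphometry record per organelle in a labelled tomogram.

    Bead labels and any explicitly excluded labels (e.g. a ground-truth
    nucleus) never enter the organelle table.  Columns: organelle_id,
    voxel_count, volume_nm3, lac_mean, lac_sd, lac_normalized, l1/l2/l3
    (nm²), fa_percent, degenerate, cell_id, group.  Sorted by organelle_id;
    deterministic.
    """
    lab = np.asarray(labels.labels)
    skip = set(labels.bead_ids) | set(exclude_labels) | {0}
    rows = []
    for organelle_id in sorted(int(v) for v in np.unique(lab) if int(v) not in skip):
        mask = lab == organelle_id
        try:
            count = int(mask.sum())
            volume = organelle_volume(count, labels.voxel_size)
            lac_mean, lac_sd = organelle_lac(recon, mask)
            eig = shape_eigenvalues(mask, labels.voxel_size)
            fa = (
                fractional_anisotropy(*eig.as_tuple())
                if not (eig.l1 == eig.l2 == eig.l3 == 0.0)
                else float("nan")
            )
        except ValueError as exc:
            raise ValueError(f"organelle {organelle_id}: {exc}") from exc
        rows.append(
            {
                "organelle_id": organelle_id,
                "voxel_count": count,
                "volume_nm3": volume,
                "lac_mean": lac_mean,
                "lac_sd": lac_sd,
                "lac_normalized": (
                    float(calibration.normalize(lac_mean)) if calibration else float("nan")
                ),
                "l1": eig.l1,
                "l2": eig.l2,
                "l3": eig.l3,
                "fa_percent": fa,
                "degenerate": eig.degenerate,
                "cell_id": cell_id,
                "group": group,
            }
        )
    if not rows:
        warnings.warn("no organelles to quantify", stacklevel=2)
    return pd.DataFrame(
        rows,
        columns=[
            "organelle_id", "voxel_count", "volume_nm3", "lac_mean", "lac_sd",
            "lac_normalized", "l1", "l2", "l3", "fa_percent", "degenerate",
            "cell_id", "group",
        ],
    )
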