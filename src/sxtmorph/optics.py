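"""Beer-Lambert optics: forward projection, noise, flat-field, absorbance.

The forward model is a parallel beam with a single tilt axis (``y``).  At
tilt angle θ the volume is rotated by −θ in the (z, x) plane and the LAC is
integrated along ``z``; transmission is then ``T = exp(−∫µ dt)`` with the
path element in µm so that LAC stays in µm⁻¹.  A 140° range sampled every
1° (the default geometry) yields 141 projections and the classic
missing-wedge artefact downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .phantom import Phantom

__all__ = [
    "TiltSeries",
    "AbsorbanceSeries",
    "default_tilt_angles",
    "project",
    "add_noise",
    "apply_flatfield",
    "to_absorbance",
]


@dataclass
class TiltSeries:
    """Stack of 2D transmission frames T(y, x) in (0, 1] with an angle list."""

    images: np.ndarray  # (n_angles, ny, nx)
    angles: np.ndarray  # degrees, strictly increasing
    pixel_size: float  # nm
    flatfield: np.ndarray | None = None  # I0(y, x); None once normalized

    def __post_init__(self) -> None:
        # float dtype is preserved (float64 stays float64 for precision work)
        self.images = np.asarray(self.images)
        if not np.issubdtype(self.images.dtype, np.floating):
            self.images = self.images.astype(np.float32)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n_angles, ny, nx) stack")
        if len(self.angles) != self.images.shape[0]:
            raise ValueError(
                f"{self.images.shape[0]} frames but {len(self.angles)} angles"
            )
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")


@dataclass
class AbsorbanceSeries:
    """Stack of absorbance frames µt = −ln T (≥ 0 up to noise)."""

    images: np.ndarray
    angles: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if not np.issubdtype(self.images.dtype, np.floating):
            self.images = self.images.astype(np.float32)
        self.angles = np.asarray(self.angles, dtype=float)
        if len(self.angles) != self.images.shape[0]:
            raise ValueError(
                f"{self.images.shape[0]} frames but {len(self.angles)} angles"
            )
        if not np.all(np.isfinite(self.images)):
            raise ValueError("absorbance contains non-finite values")


def default_tilt_angles(angular_range: float = 140.0, step: float = 1.0) -> np.ndarray:
    """Symmetric single-axis tilt scheme: ±range/2 sampled every ``step`` degrees.

    The default (140°, 1°) gives 141 angles from −70° to +70° inclusive.
    """
    half = angular_range / 2.0
    n = int(round(angular_range / step)) + 1
    return np.linspace(-half, half, n)


def _rotate_zx(volume: np.ndarray, angle_deg: float, order: int) -> np.ndarray:
    if angle_deg == 0.0:
        return volume
    return ndimage.rotate(
        volume, angle_deg, axes=(0, 2), reshape=False, order=order,
        mode="constant", cval=0.0, prefilter=False,
    )


def project(
    phantom: Phantom,
    angles: np.ndarray | None = None,
    order: int = 1,
    flatfield: np.ndarray | None = None,
) -> TiltSeries:
    """Forward-project a phantom into a transmission tilt series.

    Each frame is exp(−line integral of µ) along the beam at that tilt; the
    line integral is computed by rotating the volume (spline order
    ``order``, linear by default) and summing along ``z`` scaled by the
    voxel size in µm.  If ``flatfield`` (incident intensity I0) is given the
    frames are multiplied by it, emulating raw detector images.
    """
    if angles is None:
        angles = default_tilt_angles()
    angles = np.asarray(angles, dtype=float)
    if np.any((angles <= -90.0) | (angles >= 90.0)):
        raise ValueError("tilt angles must lie in (-90, 90) degrees (single-axis parallel beam)")
    lac = np.asarray(phantom.lac_volume, dtype=np.float32)
    if not np.all(np.isfinite(lac)):
        raise ValueError("phantom LAC must be finite")
    dt_um = phantom.voxel_size * 1e-3
    frames = np.empty((len(angles),) + lac.shape[1:], dtype=np.float32)
    for i, a in enumerate(angles):
        path = _rotate_zx(lac, float(a), order).sum(axis=0) * dt_um
        frames[i] = np.exp(-path)
    if flatfield is not None:
        frames = frames * np.asarray(flatfield, dtype=np.float32)[None]
    return TiltSeries(
        images=frames, angles=angles, pixel_size=phantom.voxel_size,
        flatfield=None if flatfield is None else np.asarray(flatfield, np.float32),
    )


def apply_flatfield(tilt: TiltSeries) -> TiltSeries:
    """Normalize raw frames by the flat-field image: T = I / I0.

    Removes any multiplicative incident-intensity pattern exactly in the
    noiseless case.  A no-op when no flat field is attached.
    """
    if tilt.flatfield is None:
        return tilt
    ff = tilt.flatfield
    if np.any(ff <= 0):
        raise ValueError("flat-field must be strictly positive")
    return TiltSeries(
        images=tilt.images / ff[None],
        angles=tilt.angles,
        pixel_size=tilt.pixel_size,
        flatfield=None,
    )


def add_noise(tilt: TiltSeries, photons_per_pixel: float, seed: int) -> TiltSeries:
    """Poisson photon noise at a given incident dose.

    Counts are drawn as Poisson(photons·T) per pixel and renormalized by the
    dose; zero-count pixels are clamped to half a count so the downstream
    logarithm stays finite.  Deterministic for a fixed seed.
    """
    if photons_per_pixel <= 0:
        raise ValueError("photons_per_pixel must be > 0")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(photons_per_pixel * np.asarray(tilt.images, dtype=float))
    counts = np.maximum(counts, 0.5)
    return replace(tilt, images=(counts / photons_per_pixel).astype(np.float32))


def to_absorbance(tilt: TiltSeries) -> AbsorbanceSeries:
    """Convert transmission to absorbance, A = −ln T.

    Noisy pixels with T slightly above 1 yield small negative absorbances;
    they are kept (not clipped) so reconstruction noise stays zero-mean.
    """
    tilt = apply_flatfield(tilt)
    t = np.asarray(tilt.images, dtype=np.float64)
    bad = t <= 0
    if bad.any():
        frames = np.unique(np.nonzero(bad)[0])
        raise ValueError(
            f"non-positive transmission in frame(s) {frames.tolist()} "
            f"({int(bad.sum())} pixels); apply a count floor before conversion"
        )
    return AbsorbanceSeries(
        images=(-np.log(t)).astype(tilt.images.dtype),
        angles=tilt.angles,
        pixel_size=tilt.pixel_size,
    )
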