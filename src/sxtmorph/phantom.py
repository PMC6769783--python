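"""Digital-cell phantoms for cryo-SXT morphometry.

A phantom is a cubic voxel grid holding the ground-truth linear absorption
coefficient (LAC, µm⁻¹) of a simplified cell: a spherical cytoplasm region,
one nucleus, a set of ellipsoidal mitochondria with controlled semi-axis
ratios and matrix LAC, and high-absorbing gold fiducial beads.  Two shape
regimes are supported out of the box: elongated, dense-matrix organelles
("S-like", mimicking a drug-sensitive line with a condensed matrix and
network-forming mitochondria) and near-spherical, lucent-matrix organelles
("R-like", mimicking a resistant line with fragmented, orthodox
mitochondria).

Coordinate convention: 0-based voxel indices, axis order ``(z, y, x)``,
voxel centers at integer coordinates.  The tilt axis used downstream is
``y``; the beam at zero tilt runs along ``z``.

The phantom stores µ = µ_m·ρ (mass absorption coefficient times density)
directly per voxel; the two factors are never modelled separately because
only their product is observable in a transmission measurement.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PhantomConfig", "Phantom", "make_cell_phantom", "make_population"]

LABEL_BACKGROUND = 0
LABEL_NUCLEUS = 1
FIRST_ORGANELLE_LABEL = 2


class PlacementError(RuntimeError):
    """Raised when organelles cannot be placed without overlap."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters fully specifying one digital cell.

    LAC values are in µm⁻¹; lengths in nm unless suffixed ``_vox``.
    ``axis_ratio`` gives the relative semi-axes (a : b : c) of the
    ellipsoidal mitochondria; organelle size is parameterised by the
    equivalent-sphere radius ``mito_radius_vox`` so that the analytic volume
    4/3·π·a·b·c is independent of the ratio — populations generated with the
    same radius distribution are volume-matched by construction.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 11.8
    n_mitochondria: int = 5
    axis_ratio: tuple[float, float, float] = (1.2, 1.0, 1.0)
    axis_ratio_jitter: float = 0.08
    mito_radius_vox: float = 4.0
    mito_radius_jitter: float = 0.10
    mito_lac: float = 0.35
    cytoplasm_lac: float = 0.20
    nucleus_lac: float = 0.25
    nucleus_radius_frac: float = 0.18
    cell_radius_frac: float = 0.46
    n_beads: int = 2
    bead_diameter: float = 200.0
    bead_lac: float = 8.0
    placement_margin_vox: float = 3.0
    beads_on_film: bool = True
    film_clearance_rows: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 32 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 ints all >= 32, got {self.grid_shape}")
        for name in ("mito_lac", "cytoplasm_lac", "nucleus_lac", "bead_lac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_beads > 0 and self.bead_diameter / self.voxel_size < 3:
            raise ValueError(
                "bead_diameter / voxel_size must be >= 3 so beads span multiple "
                f"voxels (got {self.bead_diameter / self.voxel_size:.2f})"
            )
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if min(self.axis_ratio) <= 0:
            raise ValueError("axis_ratio components must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["axis_ratio"] = list(self.axis_ratio)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        d["grid_shape"] = tuple(int(v) for v in d["grid_shape"])
        d["axis_ratio"] = tuple(float(v) for v in d["axis_ratio"])
        return cls(**d)


@dataclass
class Phantom:
    """Ground-truth LAC volume, label volume and per-organelle truth table.

    Labels: 0 background/cytoplasm, 1 nucleus, 2..K mitochondria, K+1.. beads.
    ``truth_table`` columns: label, kind, cz/cy/cx (voxels), semi-axis lengths
    a >= b >= c (nm), lac (µm⁻¹), volume_nm3 (analytic 4/3·π·a·b·c for
    ellipsoids, sphere formula for beads), voxel_count (rasterized).
    """

    lac_volume: np.ndarray
    label_volume: np.ndarray
    voxel_size: float
    truth_table: pd.DataFrame
    config: PhantomConfig | None = None

    @property
    def mito_labels(self) -> list[int]:
        t = self.truth_table
        return [int(v) for v in t.loc[t["kind"] == "mitochondrion", "label"]]

    @property
    def bead_labels(self) -> list[int]:
        t = self.truth_table
        return [int(v) for v in t.loc[t["kind"] == "bead", "label"]]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _ellipsoid_mask(
    grid_shape: tuple[int, int, int],
    center: np.ndarray,
    semi_axes_vox: np.ndarray,
    rotation: np.ndarray,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Voxel indices inside a rotated ellipsoid, restricted to a bounding box.

    Returns (flat mask over the box, box slices) or None if the bounding box
    leaves the grid.
    """
    r_max = float(np.max(semi_axes_vox))
    lo = np.floor(center - r_max - 1).astype(int)
    hi = np.ceil(center + r_max + 2).astype(int)
    if np.any(lo < 0) or np.any(hi > np.asarray(grid_shape)):
        return None
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    zz, yy, xx = np.meshgrid(
        *(np.arange(s.start, s.stop) for s in box), indexing="ij"
    )
    pts = np.stack([zz, yy, xx], axis=-1).astype(float) - center
    local = pts @ rotation  # rotation columns = ellipsoid axes in grid frame
    u = local / semi_axes_vox
    inside = np.einsum("...i,...i->...", u, u) <= 1.0
    return inside, box


def make_cell_phantom(config: PhantomConfig) -> Phantom:
    """Generate one digital cell.

    Deterministic for a fixed config (including its seed).  Organelles and
    beads are placed by rejection sampling inside the spherical cytoplasm
    region, never overlapping the nucleus, each other, or the beads; a
    crowded grid raises :class:`PlacementError` naming the offending count.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(int(n) for n in config.grid_shape)
    lac = np.zeros(shape, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.int32)

    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    cell_radius = config.cell_radius_frac * min(shape)
    zz, yy, xx = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    r2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    cell_mask = r2 <= cell_radius**2
    lac[cell_mask] = config.cytoplasm_lac

    rows: list[dict] = []

    # Fiducials sit on the support film: a thin slab at the low-y cap of the
    # cell.  Because the single tilt axis is y, each y-slice reconstructs
    # independently, so confining beads (and their streak artefacts) to rows
    # no organelle occupies keeps organelle morphometry artefact-clean while
    # the beads stay available for LAC calibration.
    bead_r_vox = 0.5 * config.bead_diameter / config.voxel_size
    if config.beads_on_film and config.n_beads > 0:
        film_y_lo = center[1] - (cell_radius - bead_r_vox - 1.5)
        film_y_hi = max(center[1] - 0.55 * cell_radius,
                        film_y_lo + bead_r_vox + 2.0)
        mito_y_min = film_y_hi + config.film_clearance_rows
    else:
        film_y_lo = film_y_hi = None
        mito_y_min = None

    # Nucleus: sphere offset from the cell center along a random direction
    # (kept in the upper hemisphere, clear of the fiducial film slab).
    # A zero nucleus_radius_frac skips the nucleus entirely (bare fixtures).
    nuc_radius = config.nucleus_radius_frac * min(shape)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    if film_y_hi is not None:
        direction[1] = abs(direction[1]) + 0.2
        direction /= np.linalg.norm(direction)
    nuc_center = center + direction * (cell_radius - nuc_radius) * 0.45
    if nuc_radius > 0:
        nuc_mask = (
            (zz - nuc_center[0]) ** 2
            + (yy - nuc_center[1]) ** 2
            + (xx - nuc_center[2]) ** 2
        ) <= nuc_radius**2
        nuc_mask &= cell_mask
        lac[nuc_mask] = config.nucleus_lac
        labels[nuc_mask] = LABEL_NUCLEUS
        nr_nm = nuc_radius * config.voxel_size
        rows.append(
            {
                "label": LABEL_NUCLEUS,
                "kind": "nucleus",
                "cz": nuc_center[0],
                "cy": nuc_center[1],
                "cx": nuc_center[2],
                "a_nm": nr_nm,
                "b_nm": nr_nm,
                "c_nm": nr_nm,
                "lac": config.nucleus_lac,
                "volume_nm3": 4.0 / 3.0 * np.pi * nr_nm**3,
                "voxel_count": int(nuc_mask.sum()),
            }
        )

    ratio = np.asarray(config.axis_ratio, dtype=float)
    next_label = FIRST_ORGANELLE_LABEL

    def place_one(semi_axes_vox, value, label, kind, max_tries=2000,
                  y_range=None, y_min=None):
        nonlocal lac, labels
        r_min = float(np.min(semi_axes_vox))
        for _ in range(max_tries):
            # centers sampled so at least the minor axis clears the membrane;
            # the rasterized mask is then checked voxel-by-voxel, which lets
            # elongated organelles pack tangentially near the cell boundary
            cand = center + rng.uniform(-1, 1, size=3) * (cell_radius - r_min - 1.0)
            if y_range is not None:
                # beads: y drawn directly inside the film band
                cand[1] = rng.uniform(y_range[0], y_range[1])
            if np.linalg.norm(cand - center) > cell_radius - r_min - 1.0:
                continue
            rot = _random_rotation(rng)
            hit = _ellipsoid_mask(shape, cand, np.asarray(semi_axes_vox, float), rot)
            if hit is None:
                continue
            inside, box = hit
            if not inside.any():
                continue
            if not cell_mask[box][inside].all():
                continue
            if y_min is not None and box[1].start < y_min:
                if np.nonzero(inside)[1].min() + box[1].start < y_min:
                    continue
            # overlap is tested on a margin-enlarged ellipsoid so organelles
            # keep a clearance (membranes, downstream separability); the true
            # shape is what gets painted
            margin = config.placement_margin_vox
            if margin > 0:
                pad_hit = _ellipsoid_mask(
                    shape, cand, np.asarray(semi_axes_vox, float) + margin, rot
                )
                if pad_hit is None:
                    continue
                pad_inside, pad_box = pad_hit
                if np.any(labels[pad_box][pad_inside] != LABEL_BACKGROUND):
                    continue
            elif np.any(labels[box][inside] != LABEL_BACKGROUND):
                continue
            lac[box][inside] = value
            labels[box][inside] = label
            sa_nm = np.sort(np.asarray(semi_axes_vox, float))[::-1] * config.voxel_size
            rows.append(
                {
                    "label": label,
                    "kind": kind,
                    "cz": cand[0],
                    "cy": cand[1],
                    "cx": cand[2],
                    "a_nm": sa_nm[0],
                    "b_nm": sa_nm[1],
                    "c_nm": sa_nm[2],
                    "lac": value,
                    "volume_nm3": 4.0 / 3.0 * np.pi * np.prod(sa_nm),
                    "voxel_count": int(inside.sum()),
                }
            )
            return
        raise PlacementError(
            f"could not place {kind} #{label} after {max_tries} tries "
            f"({config.n_mitochondria} mitochondria + {config.n_beads} beads "
            f"on grid {shape}); reduce counts or organelle size"
        )

    # Beads first (they calibrate everything downstream; placement must succeed).
    bead_y_range = (
        (film_y_lo, film_y_hi - bead_r_vox) if film_y_hi is not None else None
    )
    for _ in range(config.n_beads):
        place_one(np.full(3, bead_r_vox), config.bead_lac, next_label, "bead",
                  y_range=bead_y_range)
        next_label += 1

    for _ in range(config.n_mitochondria):
        radius = config.mito_radius_vox * float(
            np.exp(rng.normal(0.0, config.mito_radius_jitter))
        )
        jitter = np.exp(rng.normal(0.0, config.axis_ratio_jitter, size=3))
        axes = ratio * jitter
        # normalise so the equivalent-sphere radius equals `radius`
        semi = radius * axes / np.prod(axes) ** (1.0 / 3.0)
        place_one(np.sort(semi)[::-1], config.mito_lac, next_label, "mitochondrion",
                  y_min=mito_y_min)
        next_label += 1

    columns = [
        "label", "kind", "cz", "cy", "cx", "a_nm", "b_nm", "c_nm",
        "lac", "volume_nm3", "voxel_count",
    ]
    truth = pd.DataFrame(rows, columns=columns).sort_values("label").reset_index(drop=True)
    # relabel so mitochondria come before beads, as documented (2..K mito, K+1.. beads)
    mito = truth[truth["kind"] == "mitochondrion"]
    beads = truth[truth["kind"] == "bead"]
    mapping = {LABEL_NUCLEUS: LABEL_NUCLEUS}
    nxt = FIRST_ORGANELLE_LABEL
    for old in list(mito["label"]) + list(beads["label"]):
        mapping[int(old)] = nxt
        nxt += 1
    relabeled = np.zeros_like(labels)
    for old, new in mapping.items():
        relabeled[labels == old] = new
    truth["label"] = truth["label"].map(lambda v: mapping.get(int(v), int(v)))
    truth = truth.sort_values("label").reset_index(drop=True)

    return Phantom(
        lac_volume=lac,
        label_volume=relabeled,
        voxel_size=config.voxel_size,
        truth_table=truth,
        config=config,
    )


def make_population(
    config_s: PhantomConfig,
    config_r: PhantomConfig,
    n_cells: int,
    master_seed: int = 0,
    n_mitochondria_range: tuple[int, int] = (15, 20),
) -> list[tuple[Phantom, Phantom]]:
    """Generate ``n_cells`` matched pairs of S-like and R-like cells.

    Per-cell seeds and mitochondrion counts (uniform over the inclusive
    ``n_mitochondria_range``) are drawn from named substreams of
    ``master_seed``, so the population is reproducible from one integer and
    the two arm configs alone.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    lo, hi = n_mitochondria_range
    pairs = []
    for i in range(n_cells):
        pair = []
        for arm, cfg in (("S", config_s), ("R", config_r)):
            ss = np.random.SeedSequence(master_seed, spawn_key=(i, 0 if arm == "S" else 1))
            arm_rng = np.random.default_rng(ss)
            n_mito = int(arm_rng.integers(lo, hi + 1))
            # bounded deterministic reseeding: a crowded placement draw is
            # retried with the next seed from the same substream, so the
            # population is still a pure function of master_seed
            for attempt in range(5):
                cell_seed = int(arm_rng.integers(0, 2**31 - 1))
                cell_cfg = dataclasses.replace(cfg, n_mitochondria=n_mito, seed=cell_seed)
                try:
                    pair.append(make_cell_phantom(cell_cfg))
                    break
                except PlacementError:
                    if attempt == 4:
                        raise
        pairs.append(tuple(pair))
    return pairs
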