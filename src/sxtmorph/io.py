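"""File formats: MRC volumes, TIFF tilt stacks with JSON sidecars, CSV tables.

MRC (the de facto volume format of cryo tomography) is read and written
directly as MRC2014 — mode 2 float32 for LAC volumes and mode 1 int16 for
label volumes — with the voxel size carried in the cell dimensions.  Only
the small header subset the pipeline needs is implemented; extended headers
are skipped on read and never written.

Tilt series travel as multi-page TIFF plus an explicit JSON sidecar for the
angle list and pixel size (tilt-angle extended MRC headers are
dialect-prone; the angle list is never inferred).  CSV tables are written
with 9 significant digits so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .optics import AbsorbanceSeries, TiltSeries

__all__ = [
    "write_mrc",
    "read_mrc",
    "write_tilt_series",
    "read_tilt_series",
    "write_table",
    "read_table",
    "config_hash",
    "save_json",
    "load_json",
]

_MRC_HEADER_BYTES = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def write_mrc(path: str | Path, volume: np.ndarray, voxel_size: float) -> None:
    """Write a 3D array as MRC2014; float data → mode 2, integer → mode 1.

    ``voxel_size`` is in nm and is stored in the cell dimensions (Å).
    Axis order of the array is (z, y, x), i.e. x is the fastest axis on
    disk, the MRC default.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("MRC writer expects a 3D volume")
    if np.issubdtype(volume.dtype, np.floating):
        data, mode = volume.astype("<f4"), 2
    else:
        if volume.min() < -32768 or volume.max() > 32767:
            raise ValueError("integer volume exceeds int16 range of MRC mode 1")
        data, mode = volume.astype("<i2"), 1
    nz, ny, nx = volume.shape
    cell_a = (nx * voxel_size * 10.0, ny * voxel_size * 10.0, nz * voxel_size * 10.0)
    dmin, dmax = float(data.min()), float(data.max())
    dmean = float(np.asarray(data, dtype=np.float64).mean())
    rms = float(np.asarray(data, dtype=np.float64).std())
    header = bytearray(_MRC_HEADER_BYTES)
    struct.pack_into("<3i", header, 0, nx, ny, nz)  # NX NY NZ
    struct.pack_into("<i", header, 12, mode)  # MODE
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # NXSTART..
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # MX MY MZ
    struct.pack_into("<3f", header, 40, *cell_a)  # CELLA (Å)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # MAPC MAPR MAPS
    struct.pack_into("<3f", header, 76, dmin, dmax, dmean)
    struct.pack_into("<i", header, 88, 1)  # ISPG: volume
    struct.pack_into("<i", header, 92, 0)  # NSYMBT
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, rms)
    struct.pack_into("<i", header, 220, 1)  # NLABL
    label = b"sxtmorph"
    header[224 : 224 + len(label)] = label
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes(order="C"))


def read_mrc(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an MRC volume; returns (array in (z, y, x) order, voxel size nm)."""
    raw = Path(path).read_bytes()
    if len(raw) < _MRC_HEADER_BYTES:
        raise ValueError(f"{path}: truncated MRC header")
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    (mode,) = struct.unpack_from("<i", raw, 12)
    mx = struct.unpack_from("<3i", raw, 28)[0]
    cell_x = struct.unpack_from("<3f", raw, 40)[0]
    (nsymbt,) = struct.unpack_from("<i", raw, 92)
    if raw[208:212] not in (b"MAP ", b"MAP\x00"):
        raise ValueError(f"{path}: missing MAP stamp; not an MRC2014 file")
    if mode not in _MODE_DTYPES:
        raise ValueError(f"{path}: unsupported MRC mode {mode}")
    dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
    count = nx * ny * nz
    offset = _MRC_HEADER_BYTES + int(nsymbt)
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=offset)
    voxel_size = (cell_x / (mx if mx else nx)) / 10.0  # Å → nm
    return data.reshape(nz, ny, nx).copy(), float(voxel_size)


def write_tilt_series(
    path: str | Path,
    series: TiltSeries | AbsorbanceSeries,
    meta: dict | None = None,
) -> None:
    """Write frames as multi-page TIFF and angles/pixel size as a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(series.images, dtype=np.float32),
                     photometric="minisblack")
    sidecar = {
        "angles_deg": [float(a) for a in series.angles],
        "pixel_size_nm": float(series.pixel_size),
        "flavor": "absorbance" if isinstance(series, AbsorbanceSeries) else "transmission",
    }
    if meta:
        sidecar.update(meta)
    save_json(path.with_suffix(".json"), sidecar)


def read_tilt_series(path: str | Path) -> TiltSeries | AbsorbanceSeries:
    """Read a TIFF stack with its JSON sidecar back into a series object."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"{sidecar_path}: angle sidecar is required (angles are never inferred)"
        )
    meta = load_json(sidecar_path)
    images = tifffile.imread(path)
    cls = AbsorbanceSeries if meta.get("flavor") == "absorbance" else TiltSeries
    return cls(
        images=images,
        angles=np.asarray(meta["angles_deg"], dtype=float),
        pixel_size=float(meta["pixel_size_nm"]),
    )


def write_table(path: str | Path, table: pd.DataFrame, meta: dict | None = None) -> None:
    """CSV with fixed 9-significant-digit floats; optional '#' metadata header."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if meta:
            fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
        table.to_csv(fh, index=False, float_format="%.9g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def config_hash(config: object) -> str:
    """Short stable hash of a config (dataclass or plain dict) for provenance."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    else:
        payload = config
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def save_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
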