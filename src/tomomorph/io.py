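"""Labeled-volume container and MRC2014 volume I/O.

Volumes follow the tomography convention: arrays are indexed ``(z, y, x)``
with ``z`` the beam/thickness axis, and the (isotropic) voxel size is carried
in Ångström.  The MRC reader/writer implements the small subset of the
MRC2014 standard needed here: modes 0/1/2/6, C-ordered data with ``x``
fastest, and the cell dimensions used to record the voxel size.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabelVolume", "read_mrc", "write_mrc", "read_label_volume", "write_label_volume"]

_HEADER_WORDS = 256
_MODE_DTYPES = {
    0: np.dtype(np.int8),
    1: np.dtype(np.int16),
    2: np.dtype(np.float32),
    6: np.dtype(np.uint16),
}
_MACHST_LE = bytes((0x44, 0x41, 0x00, 0x00))


@dataclass
class LabelVolume:
    """Integer-labeled voxel grid: 0 is background, k > 0 the k-th object.

    Parameters
    ----------
    voxels:
        3-D integer array, axis order ``(z, y, x)``.
    voxel_size:
        Edge length of one voxel in Å (isotropic; anisotropic data is
        rejected upstream rather than silently mishandled).
    """

    voxels: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"label volume must be 3-D, got shape {self.voxels.shape}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError(f"label volume must be integer-typed, got {self.voxels.dtype}")
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("labels must be nonnegative")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def voxel_size_nm(self) -> float:
        return self.voxel_size / 10.0

    def labels(self) -> np.ndarray:
        """Sorted array of the distinct nonzero labels present."""
        u = np.unique(self.voxels)
        return u[u > 0]


def _pick_mode(data: np.ndarray) -> int:
    if np.issubdtype(data.dtype, np.floating):
        return 2
    lo = int(data.min()) if data.size else 0
    hi = int(data.max()) if data.size else 0
    if -128 <= lo and hi <= 127:
        return 0
    if -32768 <= lo and hi <= 32767:
        return 1
    if 0 <= lo and hi <= 65535:
        return 6
    return 2  # labels too large for any integer mode: store as float


def write_mrc(path: str | os.PathLike, data: np.ndarray, voxel_size: float) -> None:
    """Write a 3-D array as an MRC2014 file; ``voxel_size`` in Å."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("MRC writer expects a 3-D array")
    if not voxel_size > 0:
        raise ValueError("voxel_size must be positive")
    mode = _pick_mode(data)
    out = np.ascontiguousarray(data.astype(_MODE_DTYPES[mode], copy=False))
    nz, ny, nx = out.shape

    hdr_i = np.zeros(_HEADER_WORDS, dtype="<i4")
    hdr_f = hdr_i.view("<f4")
    hdr_i[0:3] = (nx, ny, nz)
    hdr_i[3] = mode
    hdr_i[7:10] = (nx, ny, nz)  # sampling grid mx, my, mz
    hdr_f[10:13] = (nx * voxel_size, ny * voxel_size, nz * voxel_size)
    hdr_f[13:16] = 90.0
    hdr_i[16:19] = (1, 2, 3)  # column=x, row=y, section=z
    stats = out.astype(np.float64)
    hdr_f[19] = float(stats.min()) if out.size else 0.0
    hdr_f[20] = float(stats.max()) if out.size else 0.0
    hdr_f[21] = float(stats.mean()) if out.size else 0.0
    hdr_i[22] = 1  # ispg: 3-D volume
    hdr_f[54] = float(stats.std()) if out.size else 0.0
    raw = bytearray(hdr_i.tobytes())
    raw[52 * 4 : 52 * 4 + 4] = b"MAP "
    raw[53 * 4 : 53 * 4 + 4] = _MACHST_LE

    with open(path, "wb") as fh:
        fh.write(bytes(raw))
        fh.write(out.tobytes(order="C"))


def read_mrc(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    """Read an MRC file, returning ``(array (z, y, x), voxel_size Å)``."""
    with open(path, "rb") as fh:
        raw = fh.read(_HEADER_WORDS * 4)
        if len(raw) < _HEADER_WORDS * 4:
            raise ValueError(f"{path}: truncated MRC header")
        hdr_i = np.frombuffer(raw, dtype="<i4")
        hdr_f = hdr_i.view("<f4")
        nx, ny, nz = (int(v) for v in hdr_i[0:3])
        mode = int(hdr_i[3])
        if mode not in _MODE_DTYPES:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        nsymbt = int(hdr_i[23])
        fh.seek(nsymbt, os.SEEK_CUR)
        dtype = _MODE_DTYPES[mode]
        count = nx * ny * nz
        data = np.frombuffer(fh.read(count * dtype.itemsize), dtype=dtype, count=count)
    mx = int(hdr_i[7]) or nx
    voxel_size = float(hdr_f[10]) / mx if mx else 1.0
    return data.reshape(nz, ny, nx).copy(), voxel_size


def write_label_volume(path: str | os.PathLike, volume: LabelVolume) -> None:
    write_mrc(path, volume.voxels, volume.voxel_size)


def read_label_volume(path: str | os.PathLike) -> LabelVolume:
    data, voxel_size = read_mrc(path)
    if np.issubdtype(data.dtype, np.floating):
        data = np.rint(data).astype(np.int32)
    return LabelVolume(voxels=data, voxel_size=voxel_size)
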