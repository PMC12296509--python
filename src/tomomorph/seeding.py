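"""Filament-axis particle seeding for sub-volume averaging.

Resampled backbone points become a particle table: coordinates in pixels at
the extraction pixel size, plus ZYZ Euler-angle priors (rot, tilt, psi) that
point the reference z-axis along the filament tangent.  The rot angle, which
spins about the filament axis, is unconstrained and set to 0.  Tables are
written as classic single-block STAR files (loop over coordinate and angle
columns) for downstream sub-volume extraction.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Sequence, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "ExtractionSpec",
    "ParticleRow",
    "tangent_to_priors",
    "priors_to_axis",
    "euler_zyz_matrix",
    "build_particle_table",
    "particles_to_dataframe",
    "write_star",
    "read_star",
]

STAR_COLUMNS = (
    "rlnCoordinateX",
    "rlnCoordinateY",
    "rlnCoordinateZ",
    "rlnAngleRot",
    "rlnAngleTilt",
    "rlnAnglePsi",
    "rlnTomoName",
)


@dataclass
class ExtractionSpec:
    """Sub-volume extraction geometry.

    Defaults reproduce the acquisition arithmetic: 1.98 Å/pixel unbinned,
    4x downsampling (effective pixel 7.92 Å), box of 84 pixels.
    """

    unbinned_pixel_size: float = 1.98
    downsample_factor: int = 4
    box_size: int = 84

    def __post_init__(self) -> None:
        if not self.unbinned_pixel_size > 0:
            raise ValueError("unbinned_pixel_size must be positive")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be a positive integer")
        if self.box_size < 1:
            raise ValueError("box_size must be a positive integer")

    @property
    def effective_pixel_size(self) -> float:
        """Pixel size of the extracted sub-volumes, in Å."""
        return self.unbinned_pixel_size * self.downsample_factor


@dataclass
class ParticleRow:
    """One seeded particle: pixel coordinates plus Euler-angle priors."""

    coordinate_x: float
    coordinate_y: float
    coordinate_z: float
    angle_rot: float
    angle_tilt: float
    angle_psi: float
    tomogram_id: str = "tomo"
    in_bounds: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle_tilt <= 180.0:
            raise ValueError(f"tilt must be in [0, 180], got {self.angle_tilt}")
        for name in ("angle_rot", "angle_psi"):
            v = getattr(self, name)
            if not -180.0 < v <= 180.0:
                raise ValueError(f"{name} must be in (-180, 180], got {v}")


def _rot_z(angle_deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(angle_deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def euler_zyz_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """ZYZ rotation ``R = Rz(psi) @ Ry(tilt) @ Rz(rot)``.

    ``R @ [0, 0, 1]`` is the direction the priors encode: tilt is the polar
    angle from z, psi the azimuth, rot a free spin about the axis itself.
    """
    return _rot_z(psi) @ _rot_y(tilt) @ _rot_z(rot)


def priors_to_axis(rot: float, tilt: float, psi: float) -> np.ndarray:
    """Unit filament-axis direction encoded by (rot, tilt, psi)."""
    return euler_zyz_matrix(rot, tilt, psi) @ np.array([0.0, 0.0, 1.0])


def tangent_to_priors(tangent: np.ndarray, atol: float = 1e-6) -> tuple[float, float, float]:
    """Euler priors (rot, tilt, psi), degrees, aligning the z-axis to a unit tangent.

    tilt = arccos(t_z); psi = atan2(t_y, t_x) in (-180, 180]; rot = 0 (the
    spin about the filament axis is unconstrained).  Round trip:
    ``priors_to_axis(*tangent_to_priors(t))`` reproduces ``t``.
    """
    t = np.asarray(tangent, dtype=float)
    if t.shape != (3,):
        raise ValueError("tangent must be a 3-vector")
    norm = float(np.linalg.norm(t))
    if abs(norm - 1.0) > atol:
        raise ValueError(f"tangent must be unit-norm, got |t| = {norm}")
    tilt = math.degrees(math.acos(float(np.clip(t[2], -1.0, 1.0))))
    psi = math.degrees(math.atan2(t[1], t[0]))
    if psi <= -180.0:
        psi += 360.0
    return 0.0, tilt, psi


def build_particle_table(
    points: np.ndarray,
    tangents: np.ndarray,
    spec: ExtractionSpec,
    tomogram_id: str = "tomo",
    volume_shape_px: tuple[int, int, int] | None = None,
) -> list[ParticleRow]:
    """Convert resampled backbone points (Å, columns x/y/z) into particle rows.

    Coordinates are divided by the effective pixel size; row order follows
    the input.  When ``volume_shape_px`` = (nx, ny, nz) at the extraction
    sampling is given, rows whose centered box would exceed the volume are
    flagged ``in_bounds=False`` rather than dropped (extraction tools differ
    in how they pad, so the decision is left to the consumer).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tangents = np.atleast_2d(np.asarray(tangents, dtype=float))
    if points.shape != tangents.shape or (points.size and points.shape[1] != 3):
        raise ValueError("points and tangents must be matching (n, 3) arrays")
    px = spec.effective_pixel_size
    half = spec.box_size / 2.0
    rows: list[ParticleRow] = []
    for p, t in zip(points, tangents):
        rot, tilt, psi = tangent_to_priors(t)
        coord = p / px
        in_bounds = True
        if volume_shape_px is not None:
            in_bounds = all(
                coord[i] - half >= 0 and coord[i] + half <= volume_shape_px[i] for i in range(3)
            )
        rows.append(
            ParticleRow(
                coordinate_x=float(coord[0]),
                coordinate_y=float(coord[1]),
                coordinate_z=float(coord[2]),
                angle_rot=rot,
                angle_tilt=tilt,
                angle_psi=psi,
                tomogram_id=tomogram_id,
                in_bounds=in_bounds,
            )
        )
    return rows


def particles_to_dataframe(rows: Sequence[ParticleRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rlnCoordinateX": r.coordinate_x,
                "rlnCoordinateY": r.coordinate_y,
                "rlnCoordinateZ": r.coordinate_z,
                "rlnAngleRot": r.angle_rot,
                "rlnAngleTilt": r.angle_tilt,
                "rlnAnglePsi": r.angle_psi,
                "rlnTomoName": r.tomogram_id,
            }
            for r in rows
        ],
        columns=list(STAR_COLUMNS),
    )


def write_star(rows: Sequence[ParticleRow], destination: str | os.PathLike | TextIO) -> None:
    """Write particles as a classic single-block STAR file.

    One ``data_particles`` block with a loop over coordinate/angle/tomogram
    columns, whitespace-delimited; an empty row list still yields a valid
    header with zero data lines.
    """
    if hasattr(destination, "write"):
        stream: TextIO = destination  # type: ignore[assignment]
        close = False
    else:
        try:
            stream = open(destination, "w")
        except OSError as exc:
            raise OSError(f"cannot write STAR file {destination}: {exc}") from exc
        close = True
    try:
        stream.write("data_particles\n\nloop_\n")
        for i, col in enumerate(STAR_COLUMNS, start=1):
            stream.write(f"_{col} #{i}\n")
        for r in rows:
            stream.write(
                f"{r.coordinate_x:.6f} {r.coordinate_y:.6f} {r.coordinate_z:.6f} "
                f"{r.angle_rot:.6f} {r.angle_tilt:.6f} {r.angle_psi:.6f} {r.tomogram_id}\n"
            )
    finally:
        if close:
            stream.close()


def read_star(source: str | os.PathLike | TextIO) -> pd.DataFrame:
    """Parse a single-block STAR loop back into a DataFrame (round-trip reader)."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()  # type: ignore[union-attr]
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    columns: list[str] = []
    data: list[list[str]] = []
    in_loop = False
    for line in lines:
        s = line.strip()
        if not s or s.startswith("data_"):
            continue
        if s == "loop_":
            in_loop = True
            columns = []
            data = []
            continue
        if in_loop and s.startswith("_"):
            columns.append(s.split()[0].lstrip("_"))
            continue
        if in_loop:
            fields = s.split()
            if len(fields) != len(columns):
                raise ValueError(
                    f"STAR data line has {len(fields)} fields, expected {len(columns)}: {s!r}"
                )
            data.append(fields)
    if not columns:
        raise ValueError("no loop_ block found in STAR input")
    table = pd.DataFrame(data, columns=columns)
    for col in table.columns:
        if col != "rlnTomoName":
            table[col] = table[col].astype(float)
    return table
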