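"""Per-frame geometric order parameters: distances and dihedral angles.

Distances use the orthorhombic minimum-image convention.  Dihedrals follow
the IUPAC sign convention and are reported in (-180, 180] degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, SelectionError, UndefinedGeometryError
from .traj_io import AtomSelection, Trajectory


@dataclass
class OPSeries:
    """A named per-frame scalar series (one value per trajectory frame)."""

    name: str
    values: np.ndarray
    units: str  # "angstrom" or "degrees"
    times: np.ndarray
    chain: str = ""
    atom_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise ParameterError("values and times must have equal length")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(len(self.values)),
            "time_ns": self.times,
            "chain": self.chain,
            "op_name": self.name,
            "value": self.values,
        })


def min_image_distance(
    p: Sequence[float], q: Sequence[float], box: Sequence[float]
) -> float:
    """Euclidean distance between p and q under the orthorhombic minimum image."""
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ParameterError(f"box lengths must be positive, got {box}")
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    d -= box * np.round(d / box)
    return float(np.sqrt(np.dot(d, d)))


def min_image_displacements(dx: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Vectorized minimum-image correction of raw displacement components."""
    return dx - box * np.round(dx / box)


def dihedral(
    p1: Sequence[float],
    p2: Sequence[float],
    p3: Sequence[float],
    p4: Sequence[float],
) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    Computed with the atan2 formulation, which is numerically stable near 0
    and 180 degrees.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b1) == 0 or np.linalg.norm(b2) == 0 or np.linalg.norm(b3) == 0:
        raise UndefinedGeometryError("consecutive dihedral points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise UndefinedGeometryError(
            "dihedral undefined: three consecutive points are collinear")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def op_series(
    trajectory: Trajectory,
    selections: Sequence[AtomSelection],
    kind: Literal["distance", "dihedral"],
    name: str = "",
    chain: str = "",
) -> OPSeries:
    """Evaluate a distance (2 selections) or dihedral (4 selections) per frame.

    Every selection must resolve to exactly one atom; distances are taken
    under the minimum image of each frame's box.
    """
    expected = 2 if kind == "distance" else 4
    if kind not in ("distance", "dihedral"):
        raise ParameterError(f"unknown op kind {kind!r}")
    if len(selections) != expected:
        raise SelectionError(
            f"{kind} op needs {expected} selections, got {len(selections)}")
    try:
        idx = [s.the_one() for s in selections]
    except SelectionError as exc:
        raise SelectionError(f"op {name or kind!r}: {exc}") from exc

    values = np.empty(trajectory.n_frames)
    for fi, frame in enumerate(trajectory.frames):
        pts = [frame.coordinates[i] for i in idx]
        if kind == "distance":
            values[fi] = min_image_distance(pts[0], pts[1], frame.box)
        else:
            values[fi] = dihedral(*pts)
    units = "angstrom" if kind == "distance" else "degrees"
    return OPSeries(name=name or kind, values=values, units=units,
                    times=trajectory.times, chain=chain,
                    atom_indices=tuple(idx))


def write_op_csv(series_list: Sequence[OPSeries], path: str | Path) -> None:
    """Tidy CSV export: frame, time_ns, chain, op_name, value."""
    df = pd.concat([s.to_frame() for s in series_list], ignore_index=True)
    df.to_csv(path, index=False)


def read_op_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
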