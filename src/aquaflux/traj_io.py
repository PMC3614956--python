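"""Structure/trajectory I/O and the internal coordinate model.

The on-disk formats are plain PDB (ATOM/HETATM/MODEL/CRYST1 records, one
frame per MODEL) and CHARMM/NAMD-style single-precision DCD.  Internally a
:class:`Trajectory` is an ordered list of :class:`Frame` objects sharing one
:class:`Topology`; the topology's atom order is the canonical frame order.

Only orthorhombic boxes are supported; triclinic cells are rejected so that
minimum-image arithmetic downstream stays exact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    ParameterError,
    ParseError,
    StructureError,
)

logger = logging.getLogger(__name__)

#: Element -> van der Waals radius (Å).  Bondi-like set; configurable per call.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}

#: Radius used for elements absent from :data:`VDW_RADII` (a warning is logged).
DEFAULT_VDW_RADIUS = 1.70

#: Box used when a PDB carries no CRYST1 record: effectively non-periodic.
_FALLBACK_BOX = (999.999, 999.999, 999.999)

#: Default synthesized time per frame (ns) for formats without timestamps.
DEFAULT_FRAME_STRIDE_NS = 0.1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    serial: int
    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    element: str
    vdw_radius: float


@dataclass
class Topology:
    """Ordered atom table; the atom order defines the coordinate order."""

    atoms: list[Atom]

    def __post_init__(self) -> None:
        keys = {(a.chain_id, a.residue_number, a.atom_name) for a in self.atoms}
        if len(keys) != len(self.atoms):
            raise StructureError(
                "duplicate (chain, residue_number, atom_name) in topology"
            )
        for a in self.atoms:
            if a.vdw_radius <= 0:
                raise StructureError(f"non-positive vdW radius for atom {a}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def atom_names(self) -> np.ndarray:
        return np.array([a.atom_name for a in self.atoms])

    @property
    def residue_names(self) -> np.ndarray:
        return np.array([a.residue_name for a in self.atoms])

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.array([a.residue_number for a in self.atoms])

    @property
    def chain_ids(self) -> np.ndarray:
        return np.array([a.chain_id for a in self.atoms])

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)


@dataclass
class Frame:
    """One snapshot: Å coordinates, orthorhombic box lengths (Å), time (ns)."""

    coordinates: np.ndarray  # (n_atoms, 3)
    box: tuple[float, float, float]
    time: float

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructureError("frame coordinates must have shape (n_atoms, 3)")
        if any(b <= 0 for b in self.box):
            raise StructureError(f"box lengths must be positive, got {self.box}")


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for i, f in enumerate(self.frames):
            if f.coordinates.shape[0] != n:
                raise StructureError(
                    f"frame {i} has {f.coordinates.shape[0]} atoms, topology has {n}"
                )
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise StructureError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    @property
    def coords(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_atoms, 3)."""
        return np.stack([f.coordinates for f in self.frames])

    @property
    def boxes(self) -> np.ndarray:
        return np.array([f.box for f in self.frames], dtype=float)


@dataclass(frozen=True)
class AtomSelection:
    """Sorted unique atom positions referring into a topology."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(self.indices)
        if list(idx) != sorted(set(idx)):
            raise StructureError("selection indices must be unique and sorted")
        if idx and idx[0] < 0:
            raise StructureError("selection indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def the_one(self) -> int:
        """Return the single index; raise if the selection is not a singleton."""
        from .errors import SelectionError

        if len(self.indices) != 1:
            raise SelectionError(
                f"expected exactly one atom, selection has {len(self.indices)}"
            )
        return self.indices[0]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def vdw_radius_for(element: str, table: dict[str, float] | None = None) -> float:
    table = VDW_RADII if table is None else table
    el = element.strip().upper()
    if el in table:
        return table[el]
    logger.warning("element %r not in vdW table; using default %.2f Å",
                   element, DEFAULT_VDW_RADIUS)
    return DEFAULT_VDW_RADIUS


def infer_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name (first alphabetic character)."""
    for ch in atom_name.strip():
        if ch.isalpha():
            return ch.upper()
    return ""


def _check_orthorhombic(angles: Sequence[float]) -> None:
    if not np.allclose(angles, 90.0, atol=1e-3):
        raise StructureError(
            f"only orthorhombic boxes are supported; got angles {tuple(angles)}"
        )


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(
    path: str | Path,
    frame_stride_ns: float = DEFAULT_FRAME_STRIDE_NS,
    vdw_table: dict[str, float] | None = None,
) -> tuple[Topology, Trajectory]:
    """Read a (possibly multi-MODEL) PDB file.

    One :class:`Frame` per MODEL record; a file without MODEL records yields a
    single frame.  Elements come from columns 77-78 when present, else are
    inferred from the atom name.  Frame times are synthesized from
    ``frame_stride_ns`` because PDB carries no timestamps.
    """
    path = Path(path)
    atoms: list[Atom] = []
    model_coords: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] | None = None
    box: tuple[float, float, float] | None = None
    in_model = False
    first_model_done = False

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                try:
                    a, b, c = (float(line[6:15]), float(line[15:24]),
                               float(line[24:33]))
                    ang = (float(line[33:40]), float(line[40:47]),
                           float(line[47:54]))
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: malformed CRYST1 record") from exc
                _check_orthorhombic(ang)
                box = (a, b, c)
            elif rec == "MODEL":
                in_model = True
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    model_coords.append(current)
                    first_model_done = True
                current = None
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = []
                    in_model = False
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    resname = line[17:21].strip()
                    chain = line[21].strip()
                    resnum = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except (ValueError, IndexError) as exc:
                    raise ParseError(
                        f"{path}:{lineno}: malformed fixed-width "
                        f"ATOM/HETATM record: {line.rstrip()!r}") from exc
                element = line[76:78].strip() if len(line) >= 78 else ""
                if not element:
                    element = infer_element(name)
                if not first_model_done:
                    atoms.append(Atom(
                        serial=serial, atom_name=name, residue_name=resname,
                        residue_number=resnum, chain_id=chain, element=element,
                        vdw_radius=vdw_radius_for(element, vdw_table),
                    ))
                current.append((x, y, z))

    if current is not None and current:
        model_coords.append(current)
    if not atoms:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records found")
    n = len(atoms)
    for i, mc in enumerate(model_coords):
        if len(mc) != n:
            raise StructureError(
                f"{path}: MODEL {i + 1} has {len(mc)} atoms, expected {n}")

    topology = Topology(atoms)
    use_box = box if box is not None else _FALLBACK_BOX
    frames = [
        Frame(np.array(mc, dtype=float), use_box, i * frame_stride_ns)
        for i, mc in enumerate(model_coords)
    ]
    return topology, Trajectory(topology, frames)


def _format_atom_name(name: str, element: str) -> str:
    # 4-char field: 1-letter elements start in column 14 unless the name is
    # already 4 characters long.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(topology: Topology, trajectory: Trajectory, path: str | Path) -> None:
    """Write a standard-conformant PDB; multi-frame trajectories use MODEL blocks."""
    if trajectory.n_frames == 0:
        raise EmptyInputError("refusing to write a 0-frame PDB")
    if trajectory.topology.n_atoms != topology.n_atoms:
        raise StructureError("topology does not match trajectory")
    path = Path(path)
    multi = trajectory.n_frames > 1
    with open(path, "w") as fh:
        bx, by, bz = trajectory.frames[0].box
        fh.write(f"CRYST1{bx:9.3f}{by:9.3f}{bz:9.3f}"
                 f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
        for fi, frame in enumerate(trajectory.frames):
            if multi:
                fh.write(f"MODEL     {fi + 1:4d}\n")
            for a, xyz in zip(topology.atoms, frame.coordinates):
                fh.write(
                    "ATOM  {serial:5d} {name:4s}{alt:1s}{res:<4s}{chain:1s}"
                    "{resnum:4d}{icode:1s}   "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
                    "{el:>2s}\n".format(
                        serial=a.serial % 100000,
                        name=_format_atom_name(a.atom_name, a.element),
                        alt=" ", res=a.residue_name, chain=a.chain_id or "A",
                        resnum=a.residue_number % 10000, icode=" ",
                        x=xyz[0], y=xyz[1], z=xyz[2], occ=1.0, b=0.0,
                        el=a.element[:2],
                    )
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# DCD (via MDAnalysis; CHARMM/NAMD dialect, single precision)
# ---------------------------------------------------------------------------

def read_dcd(
    path: str | Path,
    topology: Topology,
    box: tuple[float, float, float] | None = None,
    frame_stride_ns: float = DEFAULT_FRAME_STRIDE_NS,
) -> Trajectory:
    """Read a CHARMM/NAMD DCD.

    The unit cell stored in the file is used when present; otherwise ``box``
    must be given.  Times are synthesized at ``frame_stride_ns`` per frame
    (the DCD time header is not trusted across writers).
    """
    from MDAnalysis.coordinates.DCD import DCDReader

    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reader = DCDReader(str(path))
    except (OSError, EOFError, ValueError, IOError) as exc:
        raise ParseError(f"{path}: cannot open DCD: {exc}") from exc

    if reader.n_frames == 0:
        reader.close()
        raise EmptyInputError(f"{path}: DCD contains no frames")
    if reader.n_atoms != topology.n_atoms:
        reader.close()
        raise StructureError(
            f"{path}: DCD has {reader.n_atoms} atoms, "
            f"topology has {topology.n_atoms}")

    frames: list[Frame] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, ts in enumerate(reader):
                dims = ts.dimensions
                if dims is not None and dims[0] > 0:
                    _check_orthorhombic(dims[3:6])
                    fbox = (float(dims[0]), float(dims[1]), float(dims[2]))
                elif box is not None:
                    fbox = tuple(box)
                else:
                    raise StructureError(
                        f"{path}: DCD has no unit cell; a box must be configured")
                frames.append(Frame(ts.positions.astype(float), fbox,
                                    i * frame_stride_ns))
    except EOFError as exc:
        raise ParseError(
            f"{path}: truncated DCD; last complete frame was "
            f"{len(frames) - 1}") from exc
    finally:
        reader.close()

    if not frames:
        raise EmptyInputError(f"{path}: DCD contains no frames")
    return Trajectory(topology, frames)


def write_dcd(trajectory: Trajectory, path: str | Path) -> None:
    """Write a CHARMM/NAMD single-precision DCD with unit cell."""
    from MDAnalysis.coordinates.DCD import DCDWriter
    import MDAnalysis as mda

    if trajectory.n_frames == 0:
        raise EmptyInputError("refusing to write a 0-frame DCD")
    n = trajectory.topology.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with DCDWriter(str(path), n_atoms=n) as w:
            for frame in trajectory.frames:
                u.atoms.positions = frame.coordinates.astype(np.float32)
                u.dimensions = [*frame.box, 90.0, 90.0, 90.0]
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

#: PDB-dialect atom-name equivalences (v2 vs v3 names), applied per residue.
_NAME_EQUIV = {
    ("ILE", "CD"): {"CD", "CD1"},
    ("ILE", "CD1"): {"CD", "CD1"},
}


def select(
    topology: Topology,
    residue_name: str | None = None,
    residue_number: int | None = None,
    atom_name: str | None = None,
    chain: str | None = None,
) -> AtomSelection:
    """Select atoms matching every given criterion.  Empty result is valid.

    Isoleucine's delta carbon is matched under both its "CD" and "CD1"
    dialect names regardless of which one the query or the file uses.
    """
    indices = []
    for i, a in enumerate(topology.atoms):
        if residue_name is not None and a.residue_name != residue_name:
            continue
        if residue_number is not None and a.residue_number != residue_number:
            continue
        if chain is not None and a.chain_id != chain:
            continue
        if atom_name is not None:
            accepted = _NAME_EQUIV.get((a.residue_name, atom_name), {atom_name})
            if a.atom_name not in accepted:
                continue
        indices.append(i)
    return AtomSelection(tuple(indices))
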