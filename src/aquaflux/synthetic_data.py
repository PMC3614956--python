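"""Synthetic trajectories, order-parameter series, and toy pore geometries
with known ground truth.

Every generator takes one integer seed and is bitwise-reproducible.  The
single-file generator carries its own hop-resolved permeation event list, a
recommended :class:`~aquaflux.permeation.ChannelSpec`, and the analytic
permeability expectations, so every downstream estimator can be validated
without any MD input.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np

from .errors import ParameterError
from .order_params import OPSeries, dihedral, min_image_distance
from .permeation import (
    AVOGADRO,
    NS_PER_S,
    ChannelSpec,
    water_specific_volume,
)
from .traj_io import Atom, Frame, Topology, Trajectory

_BOX_XY = 20.0  # Å lateral box for single-file systems


# ---------------------------------------------------------------------------
# single-file water trajectories
# ---------------------------------------------------------------------------

@dataclass
class TruthEvent:
    water_id: int     # topology atom index of the water oxygen
    direction: int    # +1 exits the top, -1 exits the bottom
    time_ns: float


@dataclass
class SingleFileTruth:
    """Ground truth accompanying a generated single-file trajectory."""

    n_waters: int
    L: float                       # analysis channel length (Å)
    mode: str                      # "ctrw" | "brownian"
    D_n_true: float                # 1/ns (equals k in CTRW mode)
    hop_rate: float                # 1/ns per direction (0 in Brownian mode)
    expected_pf: float             # cm^3/s
    expected_pd: float             # cm^3/s (nan in Brownian mode)
    seed: int
    channel: ChannelSpec
    events: list[TruthEvent] = field(default_factory=list)

    @property
    def n_events_pos(self) -> int:
        return sum(1 for e in self.events if e.direction > 0)

    @property
    def n_events_neg(self) -> int:
        return sum(1 for e in self.events if e.direction < 0)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_waters": self.n_waters, "L": self.L, "mode": self.mode,
            "D_n_true": self.D_n_true, "hop_rate": self.hop_rate,
            "expected_pf": self.expected_pf, "expected_pd": self.expected_pd,
            "seed": self.seed,
            "channel": {"z_lo": self.channel.z_lo, "z_hi": self.channel.z_hi,
                        "buffer": self.channel.buffer,
                        "radial_cutoff": self.channel.radial_cutoff},
            "events": [{"water_id": e.water_id, "direction": e.direction,
                        "time_ns": e.time_ns} for e in self.events],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _water_topology(n: int) -> Topology:
    atoms = [Atom(serial=i + 1, atom_name="O", residue_name="HOH",
                  residue_number=i + 1, chain_id="W", element="O",
                  vdw_radius=1.52) for i in range(n)]
    return Topology(atoms)


def gen_single_file(
    n_waters: int,
    L: float,
    mode: Literal["ctrw", "brownian"],
    duration_ns: float,
    dt_ns: float,
    seed: int,
    k: float | None = None,
    D_n_true: float | None = None,
) -> tuple[Trajectory, SingleFileTruth]:
    """Single-file water column through a z-aligned channel, plus reservoirs.

    All waters sit on a ring lattice spanning the periodic box (spacing
    ``a = L/(n_waters+1)``) so that reservoir waters feed the channel mouths
    and region/occupancy logic sees real entries and exits.

    CTRW mode: the whole file hops by +-a as a Poisson process of rate ``k``
    per direction; a water leaving one end re-enters at the other through the
    periodic reservoirs.  Completed transits are logged hop-by-hop into the
    truth record.  The collective coordinate then diffuses with D_n = k and
    the one-directional transit rate is k/(n_waters+1), giving
    p_f/p_d = n_waters + 1 exactly.

    Brownian mode: the file makes collective Gaussian steps calibrated so
    the collective coordinate has Var(dn) = 2 * D_n_true * dt per step.

    The recommended analysis channel bounds returned in the truth are offset
    a quarter lattice spacing from the water sites so no site ever sits
    exactly on a region boundary; the analysis channel length is
    ``n_waters * a``.
    """
    if n_waters < 1:
        raise ParameterError("n_waters must be >= 1")
    if duration_ns < 100 * dt_ns:
        raise ParameterError("duration must be at least 100 steps")
    if mode == "ctrw":
        if k is None or k < 0:
            raise ParameterError("CTRW mode needs a hop rate k >= 0")
    elif mode == "brownian":
        if D_n_true is None or D_n_true < 0:
            raise ParameterError("Brownian mode needs D_n_true >= 0")
    else:
        raise ParameterError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    N = n_waters
    a = L / (N + 1)
    slab_sites = max(N, 3)                 # ~2x occupancy of reservoir waters
    R = N + 1 + 2 * slab_sites             # total lattice sites == waters
    Lz = R * a
    z_sites = (np.arange(R) + 0.5) * a

    # analysis channel: quarter-spacing offset keeps sites off the boundaries
    z_lo = (slab_sites + 0.25) * a
    z_hi = z_lo + N * a
    channel = ChannelSpec(z_lo=z_lo, z_hi=z_hi, buffer=0.0,
                          radial_cutoff=5.0)

    n_frames = int(round(duration_ns / dt_ns)) + 1
    times = np.arange(n_frames) * dt_ns

    events: list[TruthEvent] = []
    if mode == "ctrw":
        shift = _simulate_ctrw(rng, k, times, R, slab_sites, N, events)
        z = (z_sites[None, :] + shift[:, None] * a) % Lz
        D_true = float(k)
        q0_true = k / (N + 1)
        expected_pd = water_specific_volume() * q0_true * NS_PER_S
    else:
        steps = rng.normal(0.0, a * math.sqrt(2.0 * D_n_true * dt_ns),
                           size=n_frames - 1)
        w = np.concatenate([[0.0], np.cumsum(steps)])
        z = (z_sites[None, :] + w[:, None]) % Lz
        D_true = float(D_n_true)
        expected_pd = float("nan")
    expected_pf = water_specific_volume() * D_true * NS_PER_S

    topology = _water_topology(R)
    box = (_BOX_XY, _BOX_XY, Lz)
    xy = _BOX_XY / 2.0
    frames = []
    for fi in range(n_frames):
        coords = np.column_stack([
            np.full(R, xy), np.full(R, xy), z[fi]])
        frames.append(Frame(coords, box, float(times[fi])))
    trajectory = Trajectory(topology, frames)

    truth = SingleFileTruth(
        n_waters=N, L=channel.length, mode=mode, D_n_true=D_true,
        hop_rate=float(k) if mode == "ctrw" else 0.0,
        expected_pf=expected_pf, expected_pd=expected_pd, seed=seed,
        channel=channel, events=events,
    )
    return trajectory, truth


def _simulate_ctrw(rng, k, times, R, slab_sites, N, events):
    """Hop-resolved CTRW of the whole file; returns the net shift sampled at
    the frame times and appends completed transits to ``events``.

    Site regions: [0, slab) below, [slab, slab+N) inside, the rest above.
    A transit is logged when a water enters the opposite bulk having passed
    inside since it last sat in a bulk region -- the same bookkeeping the
    analysis does, but at exact hop resolution.
    """
    duration = float(times[-1])
    shift_at = np.zeros(len(times), dtype=np.int64)
    if k == 0:
        return shift_at

    # exact Poisson event times at total rate 2k
    t = 0.0
    hop_times = []
    while True:
        t += rng.exponential(1.0 / (2.0 * k))
        if t > duration:
            break
        hop_times.append(t)
    signs = rng.choice([1, -1], size=len(hop_times))

    last_bulk = np.full(R, -1, dtype=np.int8)   # 0 below, 2 above, -1 none
    passed_inside = np.zeros(R, dtype=bool)
    sites = np.arange(R)

    def region_of(site):
        if site < slab_sites:
            return 0
        if site < slab_sites + N:
            return 1
        return 2

    for w in range(R):
        r = region_of(w)
        if r != 1:
            last_bulk[w] = 0 if r == 0 else 2

    S = 0
    fi = 1
    for ht, sg in zip(hop_times, signs):
        while fi < len(times) and times[fi] < ht:
            shift_at[fi] = S
            fi += 1
        S += int(sg)
        cur = (sites + S) % R
        for w in range(R):
            r = region_of(cur[w])
            if r == 1:
                if last_bulk[w] != -1:
                    passed_inside[w] = True
            else:
                bulk = 0 if r == 0 else 2
                if last_bulk[w] != -1 and bulk != last_bulk[w] and passed_inside[w]:
                    events.append(TruthEvent(
                        water_id=w, direction=+1 if bulk == 2 else -1,
                        time_ns=float(ht)))
                last_bulk[w] = bulk
                passed_inside[w] = False
    while fi < len(times):
        shift_at[fi] = S
        fi += 1
    return shift_at


# ---------------------------------------------------------------------------
# telegraph order-parameter series
# ---------------------------------------------------------------------------

@dataclass
class TelegraphTruth:
    state_means: tuple[float, ...]
    state_sds: tuple[float, ...]
    switch_rate: float             # 1/ns
    true_labels: np.ndarray        # per-frame state index
    seed: int


def gen_telegraph_op(
    state_means: Sequence[float],
    state_sds: Sequence[float],
    switch_rate: float,
    duration_ns: float,
    dt_ns: float,
    seed: int,
    name: str = "telegraph",
) -> tuple[OPSeries, TelegraphTruth]:
    """Telegraph switching between Gaussian emission regimes.

    Dwell times are exponential with the given rate; transitions go to an
    adjacent state (states are ordered by mean), so a middle state acts as
    the intermediate band.  ``switch_rate=0`` stays in the initial state.
    """
    if len(state_means) != len(state_sds) or len(state_means) < 1:
        raise ParameterError("need matching non-empty means and sds")
    if any(s <= 0 for s in state_sds):
        raise ParameterError("state sds must be positive")
    if switch_rate < 0:
        raise ParameterError("switch_rate must be >= 0")

    order = np.argsort(state_means)
    means = np.asarray(state_means, dtype=float)[order]
    sds = np.asarray(state_sds, dtype=float)[order]
    n_states = len(means)

    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_ns / dt_ns)) + 1
    labels = np.empty(n_frames, dtype=int)

    state = 0
    t_next = (rng.exponential(1.0 / switch_rate)
              if switch_rate > 0 else float("inf"))
    for i in range(n_frames):
        t = i * dt_ns
        while t >= t_next:
            if n_states > 1:
                if state == 0:
                    state = 1
                elif state == n_states - 1:
                    state = n_states - 2
                else:
                    state += rng.choice([-1, 1])
            t_next += rng.exponential(1.0 / switch_rate)
        labels[i] = state

    values = rng.normal(means[labels], sds[labels])
    series = OPSeries(name=name, values=values, units="angstrom",
                      times=np.arange(n_frames) * dt_ns)
    truth = TelegraphTruth(tuple(means), tuple(sds), switch_rate,
                           labels, seed)
    return series, truth


# keep the two-state name as an alias: the common case in tests and docs
gen_two_state_op = gen_telegraph_op


# ---------------------------------------------------------------------------
# toy pore geometries
# ---------------------------------------------------------------------------

def _pseudo_atoms(positions: np.ndarray, vdw: float) -> Topology:
    atoms = [Atom(serial=i + 1, atom_name="C", residue_name="PSE",
                  residue_number=i + 1, chain_id="P", element="C",
                  vdw_radius=vdw) for i in range(len(positions))]
    return Topology(atoms)


def gen_toy_pore(
    kind: Literal["cylinder", "hourglass", "ring"],
    **params,
) -> tuple[Topology, Frame, Callable[[float], float]]:
    """Pseudo-atom pore with an analytic maximal-sphere radius.

    ring:      ring_radius, n_atoms=64, vdw=1.5, z0=0
    cylinder:  radius, length, n_per_ring=64, ring_spacing=0.5, vdw=1.5
    hourglass: waist, curvature, length, n_per_ring=64, ring_spacing=0.5, vdw=1.5

    Pseudo-atom centers sit at (pore radius + vdw) from the z axis; rings are
    azimuthally staggered so the discretization error of the maximal-sphere
    radius stays below 0.05 Å.
    """
    vdw = float(params.get("vdw", 1.5))
    n_ring = int(params.get("n_per_ring", params.get("n_atoms", 64)))
    if vdw <= 0 or n_ring < 8:
        raise ParameterError("need vdw > 0 and at least 8 atoms per ring")

    if kind == "ring":
        rr = float(params["ring_radius"])
        z0 = float(params.get("z0", 0.0))
        if rr <= vdw:
            raise ParameterError("ring radius must exceed the vdw radius")
        theta = 2 * np.pi * np.arange(n_ring) / n_ring
        pos = np.column_stack([rr * np.cos(theta), rr * np.sin(theta),
                               np.full(n_ring, z0)])

        def analytic(z: float) -> float:
            return math.sqrt(rr ** 2 + (z - z0) ** 2) - vdw

    elif kind in ("cylinder", "hourglass"):
        length = float(params["length"])
        spacing = float(params.get("ring_spacing", 0.5))
        zs = np.arange(-length / 2, length / 2 + spacing / 2, spacing)
        if kind == "cylinder":
            radius = float(params["radius"])

            def surface(z: float) -> float:
                return radius
        else:
            waist = float(params["waist"])
            curv = float(params.get("curvature", 0.02))
            if waist <= 0 or curv < 0:
                raise ParameterError("waist must be > 0 and curvature >= 0")

            def surface(z: float) -> float:
                return waist + curv * z * z

        rows = []
        for i, z in enumerate(zs):
            rc = surface(z) + vdw
            theta = (2 * np.pi * np.arange(n_ring) / n_ring
                     + (np.pi / n_ring) * (i % 2))
            rows.append(np.column_stack([
                rc * np.cos(theta), rc * np.sin(theta),
                np.full(n_ring, z)]))
        pos = np.vstack(rows)

        def analytic(z: float, _zs=zs, _surface=surface, _vdw=vdw) -> float:
            # exact minimal distance to the placed ring centers (on-axis)
            zz = np.asarray(_zs)
            rc = np.array([_surface(t) for t in zz]) + _vdw
            return float(np.min(np.sqrt(rc ** 2 + (z - zz) ** 2)) - _vdw)

    else:
        raise ParameterError(f"unknown toy pore kind {kind!r}")

    topology = _pseudo_atoms(pos, vdw)
    extent = float(np.abs(pos).max()) * 2 + 50.0
    frame = Frame(pos + 0.0, (extent, extent, extent), 0.0)
    return topology, frame, analytic


# ---------------------------------------------------------------------------
# minimal gating fixture (the four key residues)
# ---------------------------------------------------------------------------

def _place_by_internal(a, b, c, bond, angle_deg, torsion_deg):
    """Position a fourth atom from bond length, angle at c, and torsion a-b-c-d."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(ang),
                        bond * math.sin(ang) * math.cos(tor),
                        bond * math.sin(ang) * math.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def gen_gating_fixture(
    d1: float,
    d2: float,
    chi_his173: float = 180.0,
    chi_his67: float = 180.0,
) -> tuple[Topology, Frame]:
    """Minimal PDB-writable system with His67, Ile165, His173 and Ser183
    placed so that D1 (His173:NE2 - Ser183:O), D2 (His67:CB - Ile165:CD) and
    the two sidechain dihedrals (CA-CG-CD2-NE2 and CG-CB-CA-C) take the
    requested values exactly."""
    if d1 < 0 or d2 < 0:
        raise ParameterError("requested distances must be >= 0")

    # His173 fragment around the origin
    ca173 = np.array([0.0, 0.0, 0.0])
    cg173 = np.array([1.50, 0.0, 0.0])
    cd2 = cg173 + 1.40 * np.array([math.cos(math.radians(54.0)),
                                   math.sin(math.radians(54.0)), 0.0])
    ne2 = _place_by_internal(ca173, cg173, cd2, 1.35, 109.0, chi_his173)
    o183 = ne2 + np.array([0.0, 0.0, d1])

    # His67 fragment well separated in x
    c67 = np.array([50.0, 0.0, 0.0])
    ca67 = np.array([51.52, 0.0, 0.0])
    cb67 = ca67 + 1.53 * np.array([math.cos(math.radians(66.0)),
                                   math.sin(math.radians(66.0)), 0.0])
    # torsion CG-CB-CA-C equals torsion C-CA-CB-CG by reversal symmetry
    cg67 = _place_by_internal(c67, ca67, cb67, 1.53, 114.0, chi_his67)
    cd165 = cb67 + np.array([0.0, 0.0, d2])

    spec = [
        ("CB", "HIS", 67, "C", cb67), ("CA", "HIS", 67, "C", ca67),
        ("C", "HIS", 67, "C", c67), ("CG", "HIS", 67, "C", cg67),
        ("CD", "ILE", 165, "C", cd165),
        ("CA", "HIS", 173, "C", ca173), ("CG", "HIS", 173, "C", cg173),
        ("CD2", "HIS", 173, "C", cd2), ("NE2", "HIS", 173, "N", ne2),
        ("O", "SER", 183, "O", o183),
    ]
    atoms = []
    coords = []
    for i, (name, res, num, el, xyz) in enumerate(spec):
        atoms.append(Atom(serial=i + 1, atom_name=name, residue_name=res,
                          residue_number=num, chain_id="A", element=el,
                          vdw_radius={"C": 1.70, "N": 1.55, "O": 1.52}[el]))
        coords.append(xyz)
    topology = Topology(atoms)
    frame = Frame(np.array(coords), (200.0, 200.0, 200.0), 0.0)
    return topology, frame
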