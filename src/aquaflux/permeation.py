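"""Water transit detection and diffusive single-channel permeability.

A transit (permeation event) is a water whose region history goes
bulk-below -> inside -> bulk-above (direction +1) or the reverse (-1)
without touching the opposite bulk in between.  Mouth recrossings count
zero.  The one-directional rate q0 averages the + and - event counts, and
p_d = v_w * q0 converts it to a diffusive permeability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import EmptyInputError, ParameterError
from .order_params import min_image_displacements
from .traj_io import AtomSelection, Trajectory

AVOGADRO = 6.02214e23  # 1/mol
NS_PER_S = 1e9
#: Permeabilities are reported in units of 1e-14 cm^3/s.
REPORT_UNIT = 1e-14

DEFAULT_WATER_RESNAMES = ("HOH", "TIP3", "WAT", "SOL")

# region codes
BELOW, INSIDE, ABOVE, OUTSIDE = 0, 1, 2, 3
REGION_NAMES = {BELOW: "below", INSIDE: "inside", ABOVE: "above",
                OUTSIDE: "outside"}


@dataclass
class ChannelSpec:
    """Geometry of the channel region used for counting and the collective
    coordinate.

    z_lo/z_hi bound the channel along z (Å); ``buffer`` is the extra distance
    beyond a mouth a water must reach before it counts as bulk; waters
    further than ``radial_cutoff`` from the channel axis are "outside".
    The axis is the per-frame (x, y) centroid of ``center_selection`` when
    given, else the box center.
    """

    z_lo: float
    z_hi: float
    buffer: float = 2.0
    radial_cutoff: float = 6.0
    center_selection: AtomSelection | None = None
    water_resnames: tuple[str, ...] = DEFAULT_WATER_RESNAMES

    def __post_init__(self) -> None:
        if self.z_hi <= self.z_lo:
            raise ParameterError("z_hi must exceed z_lo")
        if self.buffer < 0:
            raise ParameterError("buffer must be >= 0")
        if self.radial_cutoff <= 0:
            raise ParameterError("radial_cutoff must be > 0")

    @property
    def length(self) -> float:
        """Channel length L (Å)."""
        return self.z_hi - self.z_lo


@dataclass
class PermeationEvent:
    water_id: int      # atom index of the water oxygen in the topology
    direction: int     # +1: below->above, -1: above->below
    entry_frame: int   # first in-channel frame of the completed transit
    exit_frame: int    # frame at which the destination bulk is reached

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ParameterError("direction must be +1 or -1")
        if self.exit_frame <= self.entry_frame:
            raise ParameterError("exit_frame must exceed entry_frame")


@dataclass
class RegionSeries:
    """Per-water region labels plus the unwrapped z used to produce them."""

    water_indices: np.ndarray      # (n_waters,) topology atom indices
    regions: np.ndarray            # (n_waters, n_frames) int8 region codes
    z_unwrapped: np.ndarray        # (n_waters, n_frames) Å
    times: np.ndarray              # (n_frames,) ns
    channel: ChannelSpec

    @property
    def n_waters(self) -> int:
        return len(self.water_indices)

    @property
    def n_frames(self) -> int:
        return self.regions.shape[1]

    def slice_frames(self, start: int, end: int) -> "RegionSeries":
        return RegionSeries(self.water_indices, self.regions[:, start:end],
                            self.z_unwrapped[:, start:end],
                            self.times[start:end], self.channel)


def find_water_oxygens(trajectory: Trajectory,
                       water_resnames: Sequence[str]) -> np.ndarray:
    """Topology indices of water oxygen atoms (element O in a water residue)."""
    top = trajectory.topology
    idx = [i for i, a in enumerate(top.atoms)
           if a.residue_name in water_resnames and a.element == "O"]
    return np.array(idx, dtype=int)


def unwrap_z(z: np.ndarray, boxes_z: np.ndarray) -> np.ndarray:
    """Continuity-unwrap per-water z across frames.

    ``z`` has shape (n_waters, n_frames).  A jump larger than half the box is
    treated as a periodic wrap, so wrapped waters cannot fake transits.
    """
    dz = np.diff(z, axis=1)
    dz = min_image_displacements(dz, boxes_z[1:])
    out = np.empty_like(z)
    out[:, 0] = z[:, 0]
    out[:, 1:] = z[:, [0]] + np.cumsum(dz, axis=1)
    return out


def track_regions(trajectory: Trajectory, channel: ChannelSpec) -> RegionSeries:
    """Label every water at every frame as below/inside/above/outside.

    z is unwrapped per water for displacement continuity, then folded back
    into the primary box for region labeling (regions are defined in box
    coordinates).
    """
    widx = find_water_oxygens(trajectory, channel.water_resnames)
    if len(widx) == 0:
        raise EmptyInputError(
            f"no water oxygens found (residue names {channel.water_resnames})")

    coords = trajectory.coords            # (F, N, 3)
    boxes = trajectory.boxes              # (F, 3)
    wxyz = coords[:, widx, :]             # (F, W, 3)
    z_raw = wxyz[:, :, 2].T               # (W, F)
    zu = unwrap_z(z_raw, boxes[:, 2])
    z_fold = zu - np.floor(zu / boxes[:, 2]) * boxes[:, 2]

    # channel axis per frame
    if channel.center_selection is not None and len(channel.center_selection):
        sel = list(channel.center_selection.indices)
        axis_xy = coords[:, sel, :2].mean(axis=1)      # (F, 2)
    else:
        axis_xy = boxes[:, :2] / 2.0
    dxy = wxyz[:, :, :2] - axis_xy[:, None, :]
    dxy = min_image_displacements(dxy, boxes[:, None, :2])
    radial = np.sqrt((dxy ** 2).sum(axis=2)).T         # (W, F)

    lo, hi, d = channel.z_lo, channel.z_hi, channel.buffer
    regions = np.full(z_fold.shape, OUTSIDE, dtype=np.int8)
    regions[z_fold < lo - d] = BELOW
    regions[z_fold > hi + d] = ABOVE
    inside = (z_fold >= lo) & (z_fold <= hi) & (radial <= channel.radial_cutoff)
    regions[inside] = INSIDE
    return RegionSeries(widx, regions, zu, trajectory.times, channel)


def count_events(region_series: RegionSeries) -> list[PermeationEvent]:
    """Scan region histories for completed transits.

    A water must leave one bulk, pass through the inside region, and reach
    the opposite bulk; touching its origin bulk in between resets the
    attempt, and buffer/outside excursions are ignored.
    """
    events: list[PermeationEvent] = []
    for w, wid in enumerate(region_series.water_indices):
        regs = region_series.regions[w]
        last_bulk = -1          # BELOW/ABOVE, or -1 before first bulk contact
        first_inside = -1       # first inside frame since leaving last_bulk
        for f, r in enumerate(regs):
            if r == INSIDE:
                if last_bulk != -1 and first_inside == -1:
                    first_inside = f
            elif r == BELOW or r == ABOVE:
                if last_bulk != -1 and r != last_bulk and first_inside != -1:
                    events.append(PermeationEvent(
                        water_id=int(wid),
                        direction=+1 if r == ABOVE else -1,
                        entry_frame=first_inside,
                        exit_frame=f,
                    ))
                last_bulk = r
                first_inside = -1
    events.sort(key=lambda e: (e.exit_frame, e.water_id))
    return events


@dataclass
class RateEstimate:
    q0: float              # one-directional permeation rate (1/ns)
    slope: float           # linear-fit slope of the cumulative curve (1/ns)
    n_pos: int
    n_neg: int
    t0: float
    t1: float


def cumulative_curve(events: Sequence[PermeationEvent],
                     times: np.ndarray) -> np.ndarray:
    """Cumulative permeation count vs frame time, averaged over directions."""
    times = np.asarray(times, dtype=float)
    pos = np.zeros(len(times))
    neg = np.zeros(len(times))
    for e in events:
        if e.exit_frame < len(times):
            if e.direction > 0:
                pos[e.exit_frame:] += 1
            else:
                neg[e.exit_frame:] += 1
    return (pos + neg) / 2.0


def permeation_rate(events: Sequence[PermeationEvent], times: np.ndarray,
                    t0: float | None = None,
                    t1: float | None = None) -> RateEstimate:
    """One-directional rate q0 over [t0, t1]: the mean of the + and - event
    counts divided by the window length; also the OLS slope of the
    direction-averaged cumulative curve over the same window."""
    times = np.asarray(times, dtype=float)
    if len(times) == 0:
        raise ParameterError("empty time base")
    if t0 is None:
        t0 = float(times[0])
    if t1 is None:
        t1 = float(times[-1])
    if t1 <= t0:
        raise ParameterError(f"empty rate window: [{t0}, {t1}]")

    in_win = [e for e in events
              if t0 <= times[min(e.exit_frame, len(times) - 1)] <= t1]
    n_pos = sum(1 for e in in_win if e.direction > 0)
    n_neg = sum(1 for e in in_win if e.direction < 0)
    q0 = 0.5 * (n_pos + n_neg) / (t1 - t0)

    curve = cumulative_curve(events, times)
    mask = (times >= t0) & (times <= t1)
    if mask.sum() >= 2:
        slope = float(np.polyfit(times[mask], curve[mask], 1)[0])
    else:
        slope = float("nan")
    return RateEstimate(q0=q0, slope=slope, n_pos=n_pos, n_neg=n_neg,
                        t0=t0, t1=t1)


def water_specific_volume(molar_volume_cm3: float = 18.0) -> float:
    """Specific volume of one water molecule (cm^3) from the molar volume."""
    if molar_volume_cm3 <= 0:
        raise ParameterError("molar volume must be positive")
    return molar_volume_cm3 / AVOGADRO


def diffusive_permeability(q0_per_ns: float, v_w_cm3: float) -> float:
    """p_d = v_w * q0, in cm^3/s (q0 given in 1/ns)."""
    if q0_per_ns < 0:
        raise ParameterError("q0 must be >= 0")
    return v_w_cm3 * q0_per_ns * NS_PER_S
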