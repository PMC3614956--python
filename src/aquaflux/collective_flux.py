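"""Collective water coordinate, windowed-MSD diffusion estimate, osmotic
permeability, channel occupancy, and per-state permeability tables.

The dimensionless collective coordinate n(t) accumulates, per trajectory
step, the sum of the unwrapped z-displacements of all waters inside the
channel divided by the channel length; one complete single-water transit
advances n by exactly 1, which ties the p_f and p_d scales together.
Membership in a step is evaluated at the earlier frame of the step.

D_n is the half-slope of an ordinary least-squares fit (free intercept) of
the mean square displacement of n, computed in non-overlapping windows
(default 2 ns) over lags up to half the window; p_f = v_w * D_n.

For ideal single-file transport the hopping model predicts
p_f / p_d = N + 1 with N the mean channel occupancy; ``ctrw_check``
reports the measured ratio, that prediction, and their deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError, StructureError
from .gating_states import Segment
from .permeation import (
    INSIDE,
    NS_PER_S,
    REPORT_UNIT,
    ChannelSpec,
    RegionSeries,
    count_events,
    diffusive_permeability,
    permeation_rate,
    track_regions,
    water_specific_volume,
)
from .traj_io import Trajectory

DEFAULT_WINDOW_NS = 2.0
DEFAULT_MAX_LAG_FRACTION = 0.5


@dataclass
class CollectiveSeries:
    n: np.ndarray            # (n_frames,) cumulative collective coordinate
    occupancy: np.ndarray    # (n_frames,) waters inside channel
    times: np.ndarray        # ns
    L: float                 # channel length (Å)
    window_ns: float = DEFAULT_WINDOW_NS

    def __post_init__(self) -> None:
        if len(self.n) and self.n[0] != 0.0:
            raise StructureError("collective coordinate must start at 0")


def collective_coordinate(
    trajectory: Trajectory,
    channel: ChannelSpec,
    region_series: RegionSeries | None = None,
    window_ns: float = DEFAULT_WINDOW_NS,
) -> CollectiveSeries:
    """Build n(t) and the per-frame channel occupancy N(t).

    Per step, dn = sum_i dz_i / L over waters labeled inside at the step's
    earlier frame (z unwrapped); n is the cumulative sum with n(0) = 0.
    """
    if channel.length <= 0:
        raise ParameterError("channel length must be positive")
    rs = region_series if region_series is not None else track_regions(
        trajectory, channel)
    inside = rs.regions == INSIDE                    # (W, F)
    dz = np.diff(rs.z_unwrapped, axis=1)             # (W, F-1)
    dn = (dz * inside[:, :-1]).sum(axis=0) / channel.length
    n = np.concatenate([[0.0], np.cumsum(dn)])
    occ = inside.sum(axis=0).astype(float)
    return CollectiveSeries(n=n, occupancy=occ, times=rs.times,
                            L=channel.length, window_ns=window_ns)


@dataclass
class MSDResult:
    lags_ns: np.ndarray          # (n_lags,)
    msd: np.ndarray              # (n_windows, n_lags)
    d_per_window: np.ndarray     # (n_windows,) slope/2 per window (1/ns)
    D_n: float                   # mean over windows (1/ns)
    D_n_se: float                # SE over windows (nan if single window)
    window_ns: float
    superdiffusive: bool         # curvature diagnostic on the pooled MSD

    @property
    def n_windows(self) -> int:
        return len(self.d_per_window)


def msd_of_n(
    series: CollectiveSeries,
    window_ns: float | None = None,
    max_lag_fraction: float = DEFAULT_MAX_LAG_FRACTION,
) -> MSDResult:
    """Windowed MSD of n(t) and the per-window diffusion coefficient.

    The trajectory is cut into non-overlapping windows of ``window_ns``;
    within each window MSD(tau) is averaged over all time origins for lags
    tau up to ``max_lag_fraction`` of the window, and D = slope/2 from an
    OLS fit with free intercept.
    """
    if window_ns is None:
        window_ns = series.window_ns
    if window_ns <= 0:
        raise ParameterError("window_ns must be positive")
    if not 0 < max_lag_fraction <= 1:
        raise ParameterError("max_lag_fraction must be in (0, 1]")
    t = series.times
    if len(t) < 2:
        raise InsufficientDataError("need at least 2 frames")
    dt = float(t[1] - t[0])
    wlen = int(round(window_ns / dt))
    if wlen < 3:
        raise InsufficientDataError(
            f"window of {window_ns} ns is under 3 frames at dt={dt} ns")
    n_windows = len(series.n) // wlen
    if n_windows < 1:
        raise InsufficientDataError(
            f"trajectory ({len(series.n)} frames) shorter than one "
            f"{window_ns} ns window ({wlen} frames)")

    max_lag = max(2, int(wlen * max_lag_fraction))
    lags = np.arange(1, max_lag + 1)
    msd = np.empty((n_windows, len(lags)))
    d = np.empty(n_windows)
    for w in range(n_windows):
        seg = series.n[w * wlen:(w + 1) * wlen]
        for j, lag in enumerate(lags):
            diffs = seg[lag:] - seg[:-lag]
            msd[w, j] = np.mean(diffs ** 2)
        slope, _ = np.polyfit(lags * dt, msd[w], 1)
        d[w] = slope / 2.0

    pooled = msd.mean(axis=0)
    # curvature diagnostic: quadratic term dominating the linear one flags
    # ballistic/deterministic drift rather than diffusion
    c2, c1, _ = np.polyfit(lags * dt, pooled, 2)
    superdiff = abs(c2) * (lags[-1] * dt) > abs(c1)

    D_n = float(np.mean(d))
    D_se = float(np.std(d, ddof=1) / np.sqrt(n_windows)) if n_windows > 1 else float("nan")
    return MSDResult(lags_ns=lags * dt, msd=msd, d_per_window=d, D_n=D_n,
                     D_n_se=D_se, window_ns=window_ns,
                     superdiffusive=bool(superdiff))


def osmotic_permeability(D_n_per_ns: float, v_w_cm3: float,
                         D_n_se: float = float("nan")) -> tuple[float, float]:
    """p_f = v_w * D_n in cm^3/s, with the SE of D_n propagated linearly."""
    if D_n_per_ns < 0:
        raise ParameterError("D_n must be >= 0")
    pf = v_w_cm3 * D_n_per_ns * NS_PER_S
    pf_se = v_w_cm3 * D_n_se * NS_PER_S if np.isfinite(D_n_se) else float("nan")
    return pf, pf_se


def occupancy(
    trajectory: Trajectory,
    channel: ChannelSpec,
    block_ns: float = DEFAULT_WINDOW_NS,
) -> tuple[np.ndarray, float, float]:
    """Per-frame inside-water count N(t) and its mean with a blocked SE."""
    cs = collective_coordinate(trajectory, channel, window_ns=block_ns)
    n_bar, se = occupancy_stats(cs, block_ns=block_ns)
    return cs.occupancy, n_bar, se


def occupancy_stats(series: CollectiveSeries,
                    block_ns: float | None = None) -> tuple[float, float]:
    """Mean channel occupancy and its blocked standard error.

    Blocks of ``block_ns`` (default: the MSD window length) decorrelate the
    per-frame counts before the SE is taken.
    """
    occ = series.occupancy
    if len(occ) == 0:
        raise InsufficientDataError("empty occupancy series")
    if block_ns is None:
        block_ns = series.window_ns
    t = series.times
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    blen = max(1, int(round(block_ns / dt)))
    nblocks = len(occ) // blen
    if nblocks >= 2:
        blocks = occ[:nblocks * blen].reshape(nblocks, blen).mean(axis=1)
        se = float(np.std(blocks, ddof=1) / np.sqrt(nblocks))
    else:
        se = float(np.std(occ, ddof=1) / np.sqrt(len(occ))) if len(occ) > 1 else 0.0
    return float(np.mean(occ)), se


@dataclass
class CTRWCheck:
    ratio: float | None        # p_f/p_d, None when p_d == 0 (undefined, not inf)
    predicted: float           # N_bar + 1
    deviation: float | None    # ratio - predicted

    def ratio_2dp(self) -> str:
        """Report rendering of the ratio; undefined prints as an en dash."""
        return "–" if self.ratio is None else f"{self.ratio:.2f}"


def ctrw_check(p_f: float, p_d: float, n_bar: float) -> CTRWCheck:
    """Compare the measured p_f/p_d ratio with the single-file hopping-model
    prediction N + 1.  p_f and p_d must share units; with p_d = 0 the ratio
    is flagged undefined rather than infinite."""
    predicted = n_bar + 1.0
    if p_d <= 0:
        return CTRWCheck(ratio=None, predicted=predicted, deviation=None)
    ratio = p_f / p_d
    return CTRWCheck(ratio=ratio, predicted=predicted,
                     deviation=ratio - predicted)


@dataclass
class PermeabilityEstimate:
    """One Table-style column: permeabilities conditioned on a joint state."""

    state_label: str
    p_f: float | None          # 1e-14 cm^3/s; None when under 2 MSD windows
    p_f_se: float | None
    p_d: float                 # 1e-14 cm^3/s
    q0: float                  # 1/ns
    D_n: float | None          # 1/ns
    D_n_se: float | None
    N_bar: float
    N_se: float
    n_windows: int
    n_events_pos: int
    n_events_neg: int
    t_start_ns: float
    t_end_ns: float

    @property
    def check(self) -> CTRWCheck:
        pf = self.p_f if self.p_f is not None else float("nan")
        return ctrw_check(pf, self.p_d, self.N_bar)


def estimate_on_frames(
    trajectory: Trajectory,
    channel: ChannelSpec,
    state_label: str = "",
    region_series: RegionSeries | None = None,
    start: int = 0,
    end: int | None = None,
    window_ns: float = DEFAULT_WINDOW_NS,
    molar_volume_cm3: float = 18.0,
    max_lag_fraction: float = DEFAULT_MAX_LAG_FRACTION,
) -> PermeabilityEstimate:
    """Compute q0, p_d, D_n, p_f and N_bar on the frame range [start, end)."""
    rs = region_series if region_series is not None else track_regions(
        trajectory, channel)
    if end is None:
        end = rs.n_frames
    if not (0 <= start < end <= rs.n_frames):
        raise StructureError(
            f"frame range [{start}, {end}) outside trajectory of "
            f"{rs.n_frames} frames")
    sub = rs.slice_frames(start, end)
    v_w = water_specific_volume(molar_volume_cm3)

    events = count_events(sub)
    rate = permeation_rate(events, sub.times)
    p_d = diffusive_permeability(rate.q0, v_w)

    cs = CollectiveSeries(
        n=np.concatenate([[0.0], np.cumsum(_dn_steps(sub, channel))]),
        occupancy=(sub.regions == INSIDE).sum(axis=0).astype(float),
        times=sub.times, L=channel.length, window_ns=window_ns)
    n_bar, n_se = occupancy_stats(cs)

    p_f = p_f_se = D_n = D_se = None
    n_windows = 0
    try:
        msd = msd_of_n(cs, window_ns=window_ns,
                       max_lag_fraction=max_lag_fraction)
        n_windows = msd.n_windows
        if n_windows >= 2:
            D_n, D_se = msd.D_n, msd.D_n_se
            pf_cm3, pf_se_cm3 = osmotic_permeability(max(D_n, 0.0), v_w, D_se)
            p_f, p_f_se = pf_cm3 / REPORT_UNIT, pf_se_cm3 / REPORT_UNIT
    except InsufficientDataError:
        pass

    return PermeabilityEstimate(
        state_label=state_label,
        p_f=p_f, p_f_se=p_f_se,
        p_d=p_d / REPORT_UNIT,
        q0=rate.q0, D_n=D_n, D_n_se=D_se,
        N_bar=n_bar, N_se=n_se, n_windows=n_windows,
        n_events_pos=rate.n_pos, n_events_neg=rate.n_neg,
        t_start_ns=float(sub.times[0]), t_end_ns=float(sub.times[-1]),
    )


def _dn_steps(rs: RegionSeries, channel: ChannelSpec) -> np.ndarray:
    inside = rs.regions == INSIDE
    dz = np.diff(rs.z_unwrapped, axis=1)
    return (dz * inside[:, :-1]).sum(axis=0) / channel.length


def per_state_estimates(
    trajectory: Trajectory,
    channel: ChannelSpec,
    segments: Sequence[Segment],
    window_ns: float = DEFAULT_WINDOW_NS,
    molar_volume_cm3: float = 18.0,
    region_series: RegionSeries | None = None,
) -> list[PermeabilityEstimate]:
    """Independent permeability estimates on each segment's frames.

    Segments sharing a state label stay separate rows; aggregation into a
    per-state table happens at report time.
    """
    rs = region_series if region_series is not None else track_regions(
        trajectory, channel)
    out = []
    for seg in segments:
        out.append(estimate_on_frames(
            trajectory, channel, state_label=seg.state, region_series=rs,
            start=seg.start, end=seg.end, window_ns=window_ns,
            molar_volume_cm3=molar_volume_cm3))
    return out


def estimates_to_frame(estimates: Sequence[PermeabilityEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        chk = e.check if e.p_f is not None else ctrw_check(
            float("nan"), e.p_d, e.N_bar)
        rows.append({
            "state": e.state_label,
            "p_f_1e-14cm3_s": e.p_f, "p_f_se": e.p_f_se,
            "p_d_1e-14cm3_s": e.p_d,
            "ratio": chk.ratio if e.p_f is not None else None,
            "predicted_ratio": chk.predicted,
            "N_bar": e.N_bar, "N_se": e.N_se,
            "q0_per_ns": e.q0, "D_n_per_ns": e.D_n,
            "n_windows": e.n_windows,
            "n_events_pos": e.n_events_pos, "n_events_neg": e.n_events_neg,
            "t_start_ns": e.t_start_ns, "t_end_ns": e.t_end_ns,
        })
    return pd.DataFrame(rows)
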