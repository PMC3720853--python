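"""Dry-mass conversion, trajectory assembly, normalisation and rate fits.

The dry mass of a detection is

    m = k * A_pixel * sum(OPD over the cell's support)          [pg]

with OPD background-referenced in micrometres, A_pixel in um^2 and
k = 5.56 pg/um^3 the inverse specific refractive increment.  Trajectories
collect per-frame mass, projected area and mean OPD along a track;
mass-accumulation rates are ordinary-least-squares slopes of mass versus
time over a window, with merged frames (where two cells share a detection)
excluded from single-cell fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import OpticsConfig
from .segment import Detection
from .track import CellTrack

ROLE_TARGET = "target"
ROLE_CTL = "ctl"
ROLE_UNKNOWN = "unknown"


def cell_mass(detection: Detection, optics: OpticsConfig) -> float:
    """Dry mass (pg) of one detection from its background-referenced OPD sum."""
    if detection.sum_opd_um < 0:
        raise ValueError(
            "negative integrated OPD: background referencing failed for "
            f"detection {detection.label} in frame {detection.frame}"
        )
    return optics.k_pg_per_um3 * optics.pixel_area_um2 * detection.sum_opd_um


@dataclass
class MassTrajectory:
    track_id: int
    role: str
    time_min: np.ndarray
    mass_pg: np.ndarray
    area_um2: np.ndarray
    mean_opd_um: np.ndarray
    merged: np.ndarray  # bool
    x_um: np.ndarray
    y_um: np.ndarray
    end_reason: str = "stack-end"
    normalized: np.ndarray | None = None
    norm_ref_time_min: float | None = None
    merge_partners: dict[int, int] = field(default_factory=dict)
    frames: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.time_min)

    @property
    def span_min(self) -> tuple[float, float]:
        return float(self.time_min[0]), float(self.time_min[-1])

    def mass_at(self, t_min: float, use_merged: bool = False) -> float:
        """Mass at an arbitrary time, linearly interpolated between samples."""
        sel = np.ones(len(self), dtype=bool) if use_merged else ~self.merged
        if sel.sum() < 1:
            raise ValueError("no usable samples")
        t, m = self.time_min[sel], self.mass_pg[sel]
        if not (t[0] <= t_min <= t[-1]):
            raise ValueError(f"time {t_min} outside trajectory span [{t[0]}, {t[-1]}]")
        return float(np.interp(t_min, t, m))


def build_trajectories(
    tracks: list[CellTrack],
    optics: OpticsConfig,
    role_mass_threshold_pg: float = 400.0,
) -> list[MassTrajectory]:
    """Convert tracks into mass trajectories; assign coarse roles by mass.

    T cells and target cells differ several-fold in dry mass, so the first
    unmerged mass below/above ``role_mass_threshold_pg`` labels the track
    ctl/target.
    """
    out = []
    dt_roles = {True: ROLE_TARGET, False: ROLE_CTL}
    for tr in tracks:
        if not tr.entries:
            continue
        times, masses, areas, means, merged, xs, ys, frames = [], [], [], [], [], [], [], []
        for e in tr.entries:
            times.append(e.frame * optics.frame_interval_min)
            masses.append(cell_mass(e.detection, optics))
            areas.append(e.detection.area_um2)
            means.append(e.detection.mean_opd_um)
            merged.append(e.merged)
            xs.append(e.detection.x_um)
            ys.append(e.detection.y_um)
            frames.append(e.frame)
        merged_arr = np.array(merged, dtype=bool)
        mass_arr = np.array(masses)
        role = ROLE_UNKNOWN
        unmerged_idx = np.flatnonzero(~merged_arr)
        if unmerged_idx.size:
            role = dt_roles[bool(mass_arr[unmerged_idx[0]] >= role_mass_threshold_pg)]
        out.append(
            MassTrajectory(
                track_id=tr.track_id,
                role=role,
                time_min=np.array(times),
                mass_pg=mass_arr,
                area_um2=np.array(areas),
                mean_opd_um=np.array(means),
                merged=merged_arr,
                x_um=np.array(xs),
                y_um=np.array(ys),
                end_reason=tr.end_reason,
                merge_partners=dict(tr.merge_partners),
                frames=np.array(frames),
            )
        )
    return out


def normalize(traj: MassTrajectory, ref_time_min: float) -> MassTrajectory:
    """Divide the mass series by the (interpolated) mass at ``ref_time_min``.

    The normalised series is exactly 1 at the reference time.  Raises if the
    reference lies outside the trajectory span or the reference mass is 0.
    """
    m_ref = traj.mass_at(ref_time_min)
    if m_ref == 0:
        raise ValueError("reference mass is zero")
    traj.normalized = traj.mass_pg / m_ref
    traj.norm_ref_time_min = float(ref_time_min)
    return traj


@dataclass
class RateTriplet:
    """Mass-accumulation rates before / during / after an event window."""

    r_pre: float  # pg/h, NaN when undefined
    r_during: float
    r_post: float
    n_pre: int
    n_during: int
    n_post: int
    resid_sd_pre: float
    resid_sd_during: float
    resid_sd_post: float
    t0_min: float
    during_window_min: float

    @property
    def during_pre_ratio(self) -> float:
        if not (math.isfinite(self.r_pre) and math.isfinite(self.r_during)) or self.r_pre == 0:
            return float("nan")
        return self.r_during / self.r_pre


def fit_rate(
    traj: MassTrajectory,
    t_lo: float = -math.inf,
    t_hi: float = math.inf,
    include_lo: bool = True,
    include_hi: bool = False,
) -> tuple[float, int, float]:
    """OLS slope of mass vs time (pg/h) over a time window.

    Merged samples are excluded.  Returns (slope, n, residual SD); the slope
    is NaN when fewer than 3 usable samples fall in the window.
    """
    lo_ok = traj.time_min >= t_lo if include_lo else traj.time_min > t_lo
    hi_ok = traj.time_min <= t_hi if include_hi else traj.time_min < t_hi
    sel = lo_ok & hi_ok & ~traj.merged
    n = int(sel.sum())
    if n < 3:
        return float("nan"), n, float("nan")
    t_h = traj.time_min[sel] / 60.0
    m = traj.mass_pg[sel]
    tc = t_h - t_h.mean()
    denom = float(tc @ tc)
    if denom == 0:
        return float("nan"), n, float("nan")
    slope = float(tc @ (m - m.mean())) / denom
    resid = m - m.mean() - slope * tc
    sd = float(np.sqrt(resid @ resid / max(n - 2, 1)))
    return slope, n, sd


def rate_triplet(
    traj: MassTrajectory,
    t0_min: float,
    during_window_min: float = 100.0,
    pre_end_min: float | None = None,
) -> RateTriplet:
    """Rates over pre = [start, t0), during = [t0, t0+W], post = (t0+W, end].

    Window membership is half-open as written; a sample at exactly t0+W
    belongs to the during window.  ``pre_end_min`` optionally ends the pre
    window earlier than t0 (e.g. at the onset of CTL-target contact, where
    overlapping footprints bias single-cell mass assignment).
    """
    pre_hi = t0_min if pre_end_min is None else min(pre_end_min, t0_min)
    r_pre, n_pre, sd_pre = fit_rate(traj, -math.inf, pre_hi, include_hi=False)
    r_dur, n_dur, sd_dur = fit_rate(
        traj, t0_min, t0_min + during_window_min, include_lo=True, include_hi=True
    )
    r_post, n_post, sd_post = fit_rate(
        traj, t0_min + during_window_min, math.inf, include_lo=False, include_hi=True
    )
    return RateTriplet(
        r_pre=r_pre,
        r_during=r_dur,
        r_post=r_post,
        n_pre=n_pre,
        n_during=n_dur,
        n_post=n_post,
        resid_sd_pre=sd_pre,
        resid_sd_during=sd_dur,
        resid_sd_post=sd_post,
        t0_min=float(t0_min),
        during_window_min=float(during_window_min),
    )


def endpoint_mass(traj: MassTrajectory, t0_min: float | None = None, window_min: float = 240.0) -> float:
    """Mass at the last unmerged sample (within ``window_min`` after ``t0_min``
    when an event time is given) -- the 'endpoint mass' used for population
    comparisons."""
    sel = ~traj.merged
    if t0_min is not None:
        sel = sel & (traj.time_min <= t0_min + window_min)
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        return float("nan")
    return float(traj.mass_pg[idx[-1]])


def endpoint_area(traj: MassTrajectory, t0_min: float | None = None, window_min: float = 240.0) -> float:
    sel = ~traj.merged
    if t0_min is not None:
        sel = sel & (traj.time_min <= t0_min + window_min)
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        return float("nan")
    return float(traj.area_um2[idx[-1]])
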