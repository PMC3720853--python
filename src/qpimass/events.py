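"""Cytotoxic-event detection, classification and population statistics.

A T-cell-mediated killing event is recognised from label-free morphology and
mass kinetics alone:

1. *contact* -- the target and a CTL touch (segmentation supports within one
   pixel, or sharing a single merged detection) for a sustained interval;
2. *ball-up* -- the target abruptly rounds up: projected area drops >= 30%
   against its trailing 5-frame median while mean OPD (mass density) rises
   >= 30%; the earliest such frame defines the event time t = 0;
3. *death* -- the target's mass falls by at least 20% of its t0 value within
   4 h.  An event is confirmed only when a >= 30 min contact interval
   precedes or overlaps t0, mirroring the requirement that cytotoxicity be
   attributable to a specific CTL.
4. *activation* -- the attacking CTL's mass-accumulation rate is fit before,
   during the first 100 min of, and after the event; a during/pre ratio
   >= 2 flags the CTL as activated (the ratio itself is always reported).

Population contrasts (activated vs unresponsive CTL mass and area) use
Welch's two-sided t-test with unequal variances and sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .config import EventParams, OpticsConfig
from .massprof import (
    MassTrajectory,
    RateTriplet,
    endpoint_area,
    endpoint_mass,
    rate_triplet,
)
from .segment import FrameSegmentation


@dataclass
class ContactInterval:
    target_track_id: int
    ctl_track_id: int
    start_frame: int
    end_frame: int
    duration_min: float
    min_boundary_distance_um: float

    def overlaps_or_precedes(self, t0_min: float, frame_interval_min: float, slack_min: float = 30.0) -> bool:
        start = self.start_frame * frame_interval_min
        end = self.end_frame * frame_interval_min
        return start <= t0_min and end >= t0_min - slack_min


@dataclass
class CytotoxicityEvent:
    target_track_id: int
    ctl_track_id: int | None
    t0_min: float
    mass_loss_fraction: float
    loss_duration_h: float
    contact_duration_min: float
    contact_start_min: float = float("nan")
    ctl_rates: RateTriplet | None = None
    ctl_endpoint_mass_pg: float = float("nan")
    ctl_mass_fold_vs_unresponsive: float = float("nan")
    death_confirmed: bool = True
    ctl_activated: bool = False

    def to_dict(self) -> dict:
        d = {
            "target_track_id": self.target_track_id,
            "ctl_track_id": self.ctl_track_id,
            "t0_min": self.t0_min,
            "mass_loss_fraction": self.mass_loss_fraction,
            "loss_duration_h": self.loss_duration_h,
            "contact_duration_min": self.contact_duration_min,
            "ctl_endpoint_mass_pg": self.ctl_endpoint_mass_pg,
            "ctl_mass_fold_vs_unresponsive": self.ctl_mass_fold_vs_unresponsive,
            "death_confirmed": self.death_confirmed,
            "ctl_activated": self.ctl_activated,
        }
        if self.ctl_rates is not None:
            d["ctl_rates"] = {
                "r_pre_pg_per_h": self.ctl_rates.r_pre,
                "r_during_pg_per_h": self.ctl_rates.r_during,
                "r_post_pg_per_h": self.ctl_rates.r_post,
                "during_pre_ratio": self.ctl_rates.during_pre_ratio,
            }
        return d


# ----------------------------------------------------------------------
# contact detection
# ----------------------------------------------------------------------


def _support_pixels(seg: FrameSegmentation, label: int) -> np.ndarray:
    rr, cc = np.nonzero(seg.label_map == label)
    return np.column_stack([rr, cc])


def contact_intervals(
    trajectories: list[MassTrajectory],
    frame_segs: list[FrameSegmentation],
    optics: OpticsConfig,
    params: EventParams | None = None,
) -> list[ContactInterval]:
    """Maximal contact runs between every coexisting pair of tracks.

    Contact at a frame means the two tracks share a merged detection or their
    segmentation supports come within ``contact_distance_px`` of touching.
    Runs tolerate gaps of ``contact_gap_frames``.
    """
    params = params or EventParams()
    by_id = {t.track_id: t for t in trajectories}
    # frame -> track -> (detection label, merged partner or None)
    presence: dict[int, dict[int, tuple[int, bool]]] = {}
    labels: dict[tuple[int, int], int] = {}
    for traj in trajectories:
        for i, f in enumerate(traj.frames):
            presence.setdefault(int(f), {})[traj.track_id] = (i, bool(traj.merged[i]))
    contact_frames: dict[tuple[int, int], list[tuple[int, float]]] = {}
    px = optics.pixel_um
    max_gap_px = params.contact_distance_px + 1.0  # centre-to-centre for adjacency
    for frame, seg in enumerate(frame_segs):
        tracks_here = presence.get(frame, {})
        ids = sorted(tracks_here)
        # cache support pixels lazily per label
        pix_cache: dict[int, np.ndarray] = {}
        for a_pos in range(len(ids)):
            for b_pos in range(a_pos + 1, len(ids)):
                ta, tb = ids[a_pos], ids[b_pos]
                ia, ma = tracks_here[ta]
                ib, mb = tracks_here[tb]
                tra, trb = by_id[ta], by_id[tb]
                # shared detection (merge) counts as contact at distance 0
                if ma and tra.merge_partners.get(frame) == tb or mb and trb.merge_partners.get(frame) == ta:
                    contact_frames.setdefault((ta, tb), []).append((frame, 0.0))
                    continue
                dx = tra.x_um[ia] - trb.x_um[ib]
                dy = tra.y_um[ia] - trb.y_um[ib]
                centroid_d = math.hypot(dx, dy)
                ra = math.sqrt(tra.area_um2[ia] / math.pi)
                rb = math.sqrt(trb.area_um2[ib] / math.pi)
                if centroid_d > ra + rb + 15.0:
                    continue
                la = int(seg.mass_label_map[int(round(tra.y_um[ia] / px)), int(round(tra.x_um[ia] / px))])
                lb = int(seg.mass_label_map[int(round(trb.y_um[ib] / px)), int(round(trb.x_um[ib] / px))])
                if la == 0 or lb == 0 or la == lb:
                    continue
                for lab in (la, lb):
                    if lab not in pix_cache:
                        pix_cache[lab] = _support_pixels(seg, lab)
                if not len(pix_cache[la]) or not len(pix_cache[lb]):
                    continue
                d_px = float(cdist(pix_cache[la], pix_cache[lb]).min())
                if d_px <= max_gap_px:
                    contact_frames.setdefault((ta, tb), []).append((frame, (d_px - 1.0) * px))
    out: list[ContactInterval] = []
    dt = optics.frame_interval_min
    for (ta, tb), frames_d in contact_frames.items():
        frames_d.sort()
        run: list[tuple[int, float]] = []

        def flush(run: list[tuple[int, float]]) -> None:
            if not run:
                return
            start, end = run[0][0], run[-1][0]
            tgt, ctl = (ta, tb) if by_id[ta].role == "target" else (tb, ta)
            out.append(
                ContactInterval(
                    target_track_id=tgt,
                    ctl_track_id=ctl,
                    start_frame=start,
                    end_frame=end,
                    duration_min=(end - start) * dt,
                    min_boundary_distance_um=min(d for _, d in run),
                )
            )

        for f, d in frames_d:
            if run and f - run[-1][0] > params.contact_gap_frames + 1:
                flush(run)
                run = []
            run.append((f, d))
        flush(run)
    return out


# ----------------------------------------------------------------------
# event classification
# ----------------------------------------------------------------------


def detect_ballup(traj: MassTrajectory, params: EventParams | None = None) -> float | None:
    """Earliest time (min) at which the cell 'balls up': projected area drops
    by >= ``ballup_area_drop`` against the trailing-median baseline while the
    mean OPD rises by >= ``ballup_opd_rise`` within two frames.  None if the
    morphology never changes that way."""
    params = params or EventParams()
    n = len(traj)
    if n < params.ballup_trailing_frames:
        return None
    k = params.ballup_trailing_frames
    for i in range(k, n):
        base_area = float(np.median(traj.area_um2[i - k : i]))
        base_opd = float(np.median(traj.mean_opd_um[i - k : i]))
        if base_area <= 0 or base_opd <= 0:
            continue
        area_drop = traj.area_um2[i] <= (1.0 - params.ballup_area_drop) * base_area
        if not area_drop:
            continue
        lo, hi = max(i - 2, 0), min(i + 3, n)
        opd_rise = np.any(traj.mean_opd_um[lo:hi] >= (1.0 + params.ballup_opd_rise) * base_opd)
        if opd_rise:
            return float(traj.time_min[i])
    return None


def classify_death(
    traj: MassTrajectory,
    contacts: list[ContactInterval],
    optics: OpticsConfig,
    params: EventParams | None = None,
    t0_min: float | None = None,
) -> CytotoxicityEvent | None:
    """Confirm a killing event on a target trajectory.

    Requires a qualifying contact interval (>= ``min_contact_min``) that
    precedes or overlaps the ball-up time, and a mass decrease of at least
    ``min_loss_fraction`` of the t0 mass within ``loss_window_min``.
    """
    params = params or EventParams()
    if t0_min is None:
        t0_min = detect_ballup(traj, params)
    if t0_min is None:
        return None
    span_lo, span_hi = traj.span_min
    if span_hi < t0_min + 60.0:
        return None  # needs >= 1 h of post-event coverage
    qualifying = [
        c
        for c in contacts
        if c.target_track_id == traj.track_id
        and c.duration_min >= params.min_contact_min
        and c.overlaps_or_precedes(t0_min, optics.frame_interval_min)
    ]
    if not qualifying:
        return None
    try:
        m0 = traj.mass_at(t0_min)
    except ValueError:
        return None
    if m0 <= 0:
        return None
    sel = (~traj.merged) & (traj.time_min >= t0_min) & (traj.time_min <= t0_min + params.loss_window_min)
    if not sel.any():
        return None
    masses = traj.mass_pg[sel]
    times = traj.time_min[sel]
    loss = (m0 - masses) / m0
    i_max = int(np.argmax(loss))
    max_loss = float(loss[i_max])
    if max_loss < params.min_loss_fraction:
        return None
    contact = max(qualifying, key=lambda c: c.duration_min)
    return CytotoxicityEvent(
        target_track_id=traj.track_id,
        ctl_track_id=contact.ctl_track_id,
        t0_min=float(t0_min),
        mass_loss_fraction=max_loss,
        loss_duration_h=float(times[i_max] - t0_min) / 60.0,
        contact_duration_min=contact.duration_min,
        contact_start_min=contact.start_frame * optics.frame_interval_min,
    )


def classify_activation(
    ctl_traj: MassTrajectory,
    event: CytotoxicityEvent,
    unresponsive_mean_mass_pg: float | None = None,
    params: EventParams | None = None,
) -> CytotoxicityEvent:
    """Attach CTL rate kinetics and activation metrics to an event.

    The activation flag requires a during/pre rate ratio of at least
    ``activation_rate_ratio``; the ratio and the endpoint-mass fold-change
    are reported regardless of the flag.
    """
    params = params or EventParams()
    span_lo, span_hi = ctl_traj.span_min
    if span_lo > event.t0_min - 30.0 or span_hi < event.t0_min + 30.0:
        event.ctl_rates = None  # insufficient coverage; metrics undefined
        return event
    # the pre-event baseline ends where persistent contact begins: once the
    # footprints overlap, single-cell mass assignment is biased
    pre_end = event.contact_start_min - 7.0 if math.isfinite(event.contact_start_min) else None
    rates = rate_triplet(ctl_traj, event.t0_min, params.during_window_min, pre_end_min=pre_end)
    event.ctl_rates = rates
    event.ctl_endpoint_mass_pg = endpoint_mass(ctl_traj, event.t0_min)
    if unresponsive_mean_mass_pg and unresponsive_mean_mass_pg > 0:
        event.ctl_mass_fold_vs_unresponsive = event.ctl_endpoint_mass_pg / unresponsive_mean_mass_pg
    ratio = rates.during_pre_ratio
    event.ctl_activated = bool(math.isfinite(ratio) and ratio >= params.activation_rate_ratio)
    return event


def find_events(
    trajectories: list[MassTrajectory],
    contacts: list[ContactInterval],
    optics: OpticsConfig,
    params: EventParams | None = None,
) -> list[CytotoxicityEvent]:
    """Scan all target-role trajectories for confirmed killing events and
    classify the attacking CTLs."""
    params = params or EventParams()
    by_id = {t.track_id: t for t in trajectories}
    events: list[CytotoxicityEvent] = []
    for traj in trajectories:
        if traj.role != "target":
            continue
        ev = classify_death(traj, contacts, optics, params)
        if ev is None:
            continue
        events.append(ev)
    event_ctls = {ev.ctl_track_id for ev in events}
    unresp_masses = [
        endpoint_mass(t)
        for t in trajectories
        if t.role == "ctl" and t.track_id not in event_ctls and math.isfinite(endpoint_mass(t))
    ]
    unresp_mean = float(np.mean(unresp_masses)) if unresp_masses else None
    for ev in events:
        ctl = by_id.get(ev.ctl_track_id)
        if ctl is not None:
            classify_activation(ctl, ev, unresp_mean, params)
    return events


# ----------------------------------------------------------------------
# population statistics
# ----------------------------------------------------------------------


def welch_t(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float, float]:
    """Two-tailed Welch's t-test with unequal variances and sample sizes.

    Returns (t, Welch-Satterthwaite df, two-sided p).  When both samples
    have zero variance and equal means, p = 1 by convention.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0:
        if diff == 0:
            return 0.0, float(na + nb - 2), 1.0
        return math.copysign(math.inf, diff), float(na + nb - 2), 0.0
    t = diff / math.sqrt(se2)
    denom = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    df = se2 * se2 / denom if denom > 0 else float(na + nb - 2)
    if not math.isfinite(df):  # numerical underflow of tiny variances
        df = float(na + nb - 2)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


def significance_stars(p: float) -> str:
    if p < 1e-3:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def population_summary(
    trajectories: list[MassTrajectory],
    events: list[CytotoxicityEvent],
    params: EventParams | None = None,
) -> pd.DataFrame:
    """Per-group endpoint mass/area statistics with Welch tests.

    Groups: ``activated`` CTLs (attributed to a confirmed event) and
    ``unresponsive`` CTLs (no confirmed event); fold-changes are relative to
    the unresponsive group.  For near-spherical T cells an area fold-change
    implies a volume fold-change of (area fold)^1.5, which is also reported.
    """
    params = params or EventParams()
    event_by_ctl = {ev.ctl_track_id: ev for ev in events if ev.ctl_track_id is not None}
    groups: dict[str, dict[str, list[float]]] = {
        "activated": {"mass": [], "area": []},
        "unresponsive": {"mass": [], "area": []},
    }
    for traj in trajectories:
        if traj.role != "ctl":
            continue
        ev = event_by_ctl.get(traj.track_id)
        if ev is not None:
            m = endpoint_mass(traj, ev.t0_min)
            a = endpoint_area(traj, ev.t0_min)
            grp = "activated"
        else:
            m = endpoint_mass(traj)
            a = endpoint_area(traj)
            grp = "unresponsive"
        if math.isfinite(m):
            groups[grp]["mass"].append(m)
        if math.isfinite(a):
            groups[grp]["area"].append(a)
    ref_mass = np.asarray(groups["unresponsive"]["mass"])
    ref_area = np.asarray(groups["unresponsive"]["area"])
    rows = []
    for name, vals in groups.items():
        mass = np.asarray(vals["mass"])
        area = np.asarray(vals["area"])
        if mass.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 cells")
        fold_mass = float(mass.mean() / ref_mass.mean()) if ref_mass.size else float("nan")
        fold_area = float(area.mean() / ref_area.mean()) if ref_area.size else float("nan")
        if name != "unresponsive" and ref_mass.size >= 2:
            t_m, df_m, p_m = welch_t(mass, ref_mass)
            t_a, df_a, p_a = welch_t(area, ref_area)
        else:
            t_m = df_m = t_a = df_a = float("nan")
            p_m = p_a = float("nan")
        rows.append(
            {
                "group": name,
                "n": int(mass.size),
                "mass_mean_pg": float(mass.mean()),
                "mass_sd_pg": float(mass.std(ddof=1)),
                "area_mean_um2": float(area.mean()),
                "area_sd_um2": float(area.std(ddof=1)),
                "mass_fold_vs_unresponsive": fold_mass,
                "area_fold_vs_unresponsive": fold_area,
                "implied_volume_fold": fold_area**1.5 if math.isfinite(fold_area) else float("nan"),
                "welch_t_mass": t_m,
                "welch_df_mass": df_m,
                "p_mass": p_m,
                "stars_mass": significance_stars(p_m) if math.isfinite(p_m) else "",
                "welch_t_area": t_a,
                "welch_df_area": df_a,
                "p_area": p_a,
                "stars_area": significance_stars(p_a) if math.isfinite(p_a) else "",
            }
        )
    return pd.DataFrame(rows)
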