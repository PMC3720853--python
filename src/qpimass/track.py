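"""Frame-to-frame linking of detections into cell tracks.

Linking is squared-displacement-minimising assignment in the Crocker-Grier
tradition: between consecutive frames, the one-to-one partial assignment
minimising

    sum of squared centroid displacements
    + max_disp^2 per unmatched detection

over all assignments whose links stay within ``max_disp_um`` is found with
the Hungarian algorithm.  Gaps of up to ``gap_max`` frames are closed with a
gap-inflated search radius.  Overlapping cells (a CTL pressed against its
target) appear as a single detection; the displaced track "rides" the shared
detection, keeping its identity, and both tracks carry a merged flag for
those frames so combined mass is attributed to the pair rather than split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import OpticsConfig, TrackParams
from .segment import Detection, FrameSegmentation

END_STACK = "stack-end"
END_LEFT_FIELD = "left-field"
END_WASHED_AWAY = "washed-away"
END_MERGED = "merged"


@dataclass
class TrackEntry:
    frame: int
    detection: Detection
    merged: bool = False


@dataclass
class CellTrack:
    track_id: int
    entries: list[TrackEntry] = field(default_factory=list)
    gap_frames: list[int] = field(default_factory=list)
    end_reason: str = END_STACK
    merge_partners: dict[int, int] = field(default_factory=dict)  # frame -> partner track id

    @property
    def frames(self) -> list[int]:
        return [e.frame for e in self.entries]

    @property
    def last_separate_centroid(self) -> tuple[float, float]:
        for e in reversed(self.entries):
            if not e.merged:
                return e.detection.centroid_um
        return self.entries[-1].detection.centroid_um

    def merge_intervals(self) -> list[tuple[int, int]]:
        """Maximal runs of merged frames."""
        runs: list[tuple[int, int]] = []
        start = prev = None
        for e in self.entries:
            if e.merged:
                if start is None:
                    start = e.frame
                prev = e.frame
            elif start is not None:
                runs.append((start, prev))
                start = prev = None
        if start is not None:
            runs.append((start, prev))
        return runs


def link_frames(
    dets_t: list[Detection],
    dets_t1: list[Detection],
    max_disp_um: float,
) -> list[tuple[int, int]]:
    """Optimal partial assignment between two detection lists.

    Returns index pairs (i in ``dets_t``, j in ``dets_t1``).  The objective
    is the total squared displacement plus a penalty of ``max_disp_um**2``
    for every detection (in either frame) left unmatched; links longer than
    ``max_disp_um`` are forbidden.
    """
    if max_disp_um <= 0:
        raise ValueError("max_disp_um must be positive")
    n, m = len(dets_t), len(dets_t1)
    if n == 0 or m == 0:
        return []
    big = 1e9 * max_disp_um * max_disp_um
    pen = max_disp_um * max_disp_um
    size = n + m
    cost = np.zeros((size, size))
    cost[:n, m:] = pen  # detection in t unmatched
    cost[n:, :m] = pen  # detection in t+1 unmatched
    for i, a in enumerate(dets_t):
        for j, b in enumerate(dets_t1):
            d2 = (a.x_um - b.x_um) ** 2 + (a.y_um - b.y_um) ** 2
            # tiny lexicographic tie-break keeps the output deterministic
            cost[i, j] = (d2 + 1e-9 * pen * (i * (m + 1) + j) / (size * size)) if d2 <= pen else big
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if i < n and j < m and cost[i, j] < big]


def _end_reason(track: CellTrack, optics: OpticsConfig, border_um: float) -> str:
    if track.entries and track.entries[-1].merged:
        return END_MERGED
    x, y = track.last_separate_centroid
    h_um = optics.image_shape[0] * optics.pixel_um
    w_um = optics.image_shape[1] * optics.pixel_um
    dist_border = min(x, y, w_um - x, h_um - y)
    return END_LEFT_FIELD if dist_border <= border_um else END_WASHED_AWAY


def build_tracks(
    frame_segs: list[FrameSegmentation],
    optics: OpticsConfig,
    params: TrackParams | None = None,
) -> list[CellTrack]:
    """Chain per-frame detections into tracks with gap and merge handling."""
    params = params or TrackParams()
    tracks: list[CellTrack] = []
    active: list[CellTrack] = []
    gaps: dict[int, int] = {}  # track_id -> consecutive missed frames
    next_id = 1
    px = optics.pixel_um
    for frame, seg in enumerate(frame_segs):
        dets = seg.detections
        # assignment between active tracks (at last separate position) and detections
        pairs: list[tuple[int, int]] = []
        if active and dets:
            pseudo = [
                Detection(
                    frame=frame - 1,
                    label=-1,
                    centroid_um=tr.last_separate_centroid,
                    n_pixels=1,
                    n_mass_pixels=1,
                    area_um2=1.0,
                    mean_opd_um=0.0,
                    sum_opd_um=0.0,
                )
                for tr in active
            ]
            # inflate the search radius for gapped tracks
            radius = params.max_disp_um * math.sqrt(1 + max(gaps.values(), default=0))
            pairs = link_frames(pseudo, dets, radius)
            # enforce per-track radius (stricter for tracks without gaps)
            pairs = [
                (i, j)
                for i, j in pairs
                if (pseudo[i].x_um - dets[j].x_um) ** 2 + (pseudo[i].y_um - dets[j].y_um) ** 2
                <= (params.max_disp_um * math.sqrt(1 + gaps[active[i].track_id])) ** 2
            ]
        matched_tracks = {i for i, _ in pairs}
        matched_dets = {j for _, j in pairs}
        det_claims: dict[int, list[CellTrack]] = {j: [active[i]] for i, j in pairs}
        for i, j in pairs:
            tr = active[i]
            tr.entries.append(TrackEntry(frame=frame, detection=dets[j]))
            gaps[tr.track_id] = 0
        survivors: list[CellTrack] = [active[i] for i in matched_tracks]
        for i, tr in enumerate(active):
            if i in matched_tracks:
                continue
            # rider attachment: predicted position inside an assigned detection
            x, y = tr.last_separate_centroid
            col, row = int(round(x / px)), int(round(y / px))
            label = 0
            if 0 <= row < seg.mass_label_map.shape[0] and 0 <= col < seg.mass_label_map.shape[1]:
                label = int(seg.mass_label_map[row, col])
            host_j = None
            if label > 0:
                cand = label - 1  # labels are compacted to detection order
                if 0 <= cand < len(dets) and dets[cand].label == label:
                    host_j = cand
            if host_j is not None and host_j in matched_dets:
                tr.entries.append(TrackEntry(frame=frame, detection=dets[host_j], merged=True))
                det_claims.setdefault(host_j, []).append(tr)
                gaps[tr.track_id] = 0
                survivors.append(tr)
            else:
                gaps[tr.track_id] += 1
                if gaps[tr.track_id] > params.gap_max:
                    tr.end_reason = _end_reason(tr, optics, params.washed_away_border_um)
                    del gaps[tr.track_id]
                else:
                    tr.gap_frames.append(frame)
                    survivors.append(tr)
        # flag hosts whose detection is shared, record partners
        for j, claimants in det_claims.items():
            if len(claimants) > 1:
                ids = [t.track_id for t in claimants]
                for t in claimants:
                    t.entries[-1].merged = True
                    partner = next(i for i in ids if i != t.track_id)
                    t.merge_partners[frame] = partner
        for j, det in enumerate(dets):
            if j not in det_claims:
                tr = CellTrack(track_id=next_id, entries=[TrackEntry(frame=frame, detection=det)])
                next_id += 1
                tracks.append(tr)
                survivors.append(tr)
                gaps[tr.track_id] = 0
        active = survivors
    for tr in tracks:
        if tr.track_id in gaps:
            tr.end_reason = END_STACK
    return tracks


def annotate_merges(tracks: list[CellTrack]) -> list[CellTrack]:
    """Cross-check merge bookkeeping: flag every entry whose detection is
    shared between two tracks in the same frame and record the partner."""
    by_frame: dict[tuple[int, int], list[CellTrack]] = {}
    for tr in tracks:
        for e in tr.entries:
            by_frame.setdefault((e.frame, id(e.detection)), []).append(tr)
    for (frame, _), claimants in by_frame.items():
        if len(claimants) > 1:
            ids = [t.track_id for t in claimants]
            for t in claimants:
                for e in t.entries:
                    if e.frame == frame:
                        e.merged = True
                t.merge_partners[frame] = next(i for i in ids if i != t.track_id)
    return tracks
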