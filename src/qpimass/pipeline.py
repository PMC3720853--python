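"""End-to-end orchestration: phantom stacks through events and statistics.

Stage order follows the measurement chain: unwrap -> wrap-error correction
-> segmentation -> tracking -> mass trajectories -> events.  Everything is
deterministic for a given (config, seed): the phantom renderer, the GA
refinement and every downstream stage derive their randomness from the run
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import __version__ as _pkg_version
from . import events as _events
from . import io as _io
from . import massprof as _massprof
from . import phantom as _phantom
from . import segment as _segment
from . import track as _track
from . import unwrap as _unwrap
from . import wrapfix as _wrapfix
from .config import RunConfig

log = logging.getLogger("qpimass")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

_FIELD_ID_STRIDE = 10000


@dataclass
class FieldResult:
    field_index: int
    optics: object
    frame_segs: list
    tracks: list
    trajectories: list
    corrected: np.ndarray | None = None
    unwrapped: np.ndarray | None = None


@dataclass
class ScenarioResult:
    name: str
    seed: int
    config: RunConfig
    fields: list[FieldResult]
    trajectories: list
    contacts: list
    events: list
    summary: pd.DataFrame | None


def train_default_model(config: RunConfig, n_images: int = 200, refine: bool = True):
    """Train the wrap-boundary classifier on phantom sub-images.

    Roughly 200 sub-images, each containing one cell tall enough to wrap,
    with labels from the ground-truth wrap-count map; LDA first, then GA
    refinement of the score/flood thresholds.
    """
    t0 = time.time()
    train = _wrapfix.make_training_set(
        n_images=n_images, seed=config.seed, optics=config.optics, noise=config.noise
    )
    model = _wrapfix.train_lda(train, seed=config.seed)
    if refine:
        model = _wrapfix.ga_refine(model, train, config.ga, seed=config.seed)
    log.info("wrapfix model trained in %.1f s", time.time() - t0)
    return model


def process_stack(
    stack: _phantom.PhaseStack,
    config: RunConfig,
    model=None,
    field_index: int = 0,
    keep_images: bool = False,
) -> FieldResult:
    """Run unwrap -> correct -> segment -> track on one phase stack."""
    optics = stack.optics
    lam = optics.wavelength_um
    frame_segs = []
    unwrapped_stack = [] if keep_images else None
    corrected_stack = [] if keep_images else None
    t0 = time.time()
    for f in range(stack.wrapped.shape[0]):
        uw = _unwrap.min_discontinuity_unwrap(stack.wrapped[f], lam)
        # single-wavelength region errors require OPD above lambda; restrict
        # the (feature + watershed) detector to a padded crop around such
        # pixels -- flat frames and flat areas only need the median filter
        high = (uw - np.median(uw)) > 0.7 * lam
        corrected = ndimage.median_filter(uw, size=3, mode="reflect")
        if model is not None and high.any():
            rr, cc = np.nonzero(high)
            pad = 24
            r0, r1 = max(int(rr.min()) - pad, 0), min(int(rr.max()) + pad + 1, uw.shape[0])
            c0, c1 = max(int(cc.min()) - pad, 0), min(int(cc.max()) + pad + 1, uw.shape[1])
            crop = (slice(r0, r1), slice(c0, c1))
            feats = _wrapfix.extract_features(stack.wrapped[f][crop], stack.intensity[f][crop], lam)
            corrected[crop] = _wrapfix.correct_regions(uw[crop], model, feats)
        # fix the unwrapping gauge: the global offset is an integer number of
        # wavelengths; zero the background (image median) before segmentation
        corrected = corrected - np.median(corrected)
        seg = _segment.segment_frame(corrected, optics, config.segment, frame=f)
        frame_segs.append(seg)
        if keep_images:
            unwrapped_stack.append(uw)
            corrected_stack.append(corrected)
    tracks = _track.build_tracks(frame_segs, optics, config.track)
    _track.annotate_merges(tracks)
    trajectories = _massprof.build_trajectories(
        tracks, optics, role_mass_threshold_pg=config.events.role_mass_threshold_pg
    )
    log.info(
        "field %d: %d frames, %d tracks in %.1f s",
        field_index,
        stack.wrapped.shape[0],
        len(tracks),
        time.time() - t0,
    )
    return FieldResult(
        field_index=field_index,
        optics=optics,
        frame_segs=frame_segs,
        tracks=tracks,
        trajectories=trajectories,
        unwrapped=np.stack(unwrapped_stack) if keep_images else None,
        corrected=np.stack(corrected_stack) if keep_images else None,
    )


def _offset_ids(result: FieldResult, offset: int) -> tuple[list, list, list]:
    """Re-id a field's trajectories/contacts/events into a global namespace."""
    for traj in result.trajectories:
        traj.track_id += offset
        traj.merge_partners = {f: p + offset for f, p in traj.merge_partners.items()}
    return result.trajectories


def run_scenario(
    name: str,
    seed: int,
    config: RunConfig | None = None,
    model=None,
    train_model: bool = True,
    keep_segs: bool = False,
) -> ScenarioResult:
    """Simulate a named phantom scenario and push it through the pipeline."""
    config = config or RunConfig()
    config.seed = seed
    config.scenario = name
    scenes = _phantom.build_scenario(name, seed, config.optics)
    if model is None and train_model:
        model = train_default_model(config)
    fields = []
    all_trajs: list = []
    all_contacts: list = []
    for i, scene in enumerate(scenes):
        stack, _ = _phantom.render_stack(scene, config.noise, seed=seed + i)
        res = process_stack(stack, config, model=model, field_index=i)
        contacts = _events.contact_intervals(res.trajectories, res.frame_segs, res.optics, config.events)
        offset = _FIELD_ID_STRIDE * (i + 1)
        _offset_ids(res, offset)
        for c in contacts:
            c.target_track_id += offset
            c.ctl_track_id += offset
        if not keep_segs:
            res.frame_segs = []  # label maps are only needed for contacts
        fields.append(res)
        all_trajs.extend(res.trajectories)
        all_contacts.extend(contacts)
    evts = _events.find_events(all_trajs, all_contacts, config.optics, config.events)
    summary = None
    n_act = len({e.ctl_track_id for e in evts})
    n_ctl = sum(1 for t in all_trajs if t.role == "ctl")
    if n_act >= 2 and n_ctl - n_act >= 2:
        summary = _events.population_summary(all_trajs, evts, config.events)
    return ScenarioResult(
        name=name,
        seed=seed,
        config=config,
        fields=fields,
        trajectories=all_trajs,
        contacts=all_contacts,
        events=evts,
        summary=summary,
    )


# ----------------------------------------------------------------------
# validation harness
# ----------------------------------------------------------------------


def match_trajectories_to_truth(
    trajectories: list,
    truth_table: pd.DataFrame,
    optics,
    max_dist_um: float = 10.0,
) -> pd.DataFrame:
    """Per (track, frame) match to the nearest ground-truth cell.

    Returns a table with measured and true mass per matched unmerged
    trajectory sample, used for mass-fidelity and purity metrics.
    """
    rows = []
    by_frame = {f: g for f, g in truth_table.groupby("frame")}
    for traj in trajectories:
        for i, f in enumerate(traj.frames):
            g = by_frame.get(int(f))
            if g is None:
                continue
            d2 = (g["x_um"].to_numpy() - traj.x_um[i]) ** 2 + (g["y_um"].to_numpy() - traj.y_um[i]) ** 2
            j = int(np.argmin(d2))
            if d2[j] > max_dist_um**2:
                continue
            rows.append(
                {
                    "track_id": traj.track_id,
                    "frame": int(f),
                    "merged": bool(traj.merged[i]),
                    "cell_id": int(g["cell_id"].iloc[j]),
                    "mass_meas_pg": float(traj.mass_pg[i]),
                    "mass_true_pg": float(g["mass_pg"].iloc[j]),
                    "role_true": g["role"].iloc[j],
                    "state": g["state"].iloc[j],
                }
            )
    return pd.DataFrame(rows)


def evaluate(result: ScenarioResult, scenes: list[_phantom.Scene] | None = None) -> dict:
    """Validation metrics of a phantom run against its own ground truth."""
    if scenes is None:
        scenes = _phantom.build_scenario(result.name, result.seed, result.config.optics)
    all_matches = []
    for i, (fr, scene) in enumerate(zip(result.fields, scenes)):
        offset = _FIELD_ID_STRIDE * (i + 1)
        trajs = [t for t in result.trajectories if offset <= t.track_id < offset + _FIELD_ID_STRIDE]
        m = match_trajectories_to_truth(trajs, scene.truth, scene.optics)
        if len(m):
            m["cell_id"] += offset
            m["field"] = i
            all_matches.append(m)
    if not all_matches:
        raise ValueError("no trajectory/ground-truth matches; id mismatch?")
    matches = pd.concat(all_matches, ignore_index=True)
    unmerged = matches[~matches.merged]
    rel_err = np.abs(unmerged.mass_meas_pg - unmerged.mass_true_pg) / unmerged.mass_true_pg
    # track purity: fraction of samples agreeing with each track's majority cell
    purity_num = purity_den = 0
    for tid, g in matches[~matches.merged].groupby("track_id"):
        counts = g["cell_id"].value_counts()
        purity_num += int(counts.iloc[0])
        purity_den += int(counts.sum())
    # event sensitivity: scripted killed cells with a confirmed event at a matching time
    killed = pd.concat(
        [
            scene.truth[scene.truth.role == _phantom.ROLE_TARGET_KILLED].assign(
                cell_id=lambda d: d.cell_id + _FIELD_ID_STRIDE * (i + 1)
            )
            for i, scene in enumerate(scenes)
        ],
        ignore_index=True,
    )
    killed_ids = sorted(killed.cell_id.unique())
    true_t0 = {
        cid: float(g.loc[g.state != "pre", "time_min"].min()) for cid, g in killed.groupby("cell_id")
        if (g.state != "pre").any()
    }
    track_to_cell = {
        tid: int(g["cell_id"].value_counts().index[0]) for tid, g in matches.groupby("track_id")
    }
    detected = {}
    false_events = 0
    for ev in result.events:
        cid = track_to_cell.get(ev.target_track_id)
        if cid in true_t0 and abs(ev.t0_min - true_t0[cid]) <= 15.0:
            detected[cid] = ev
        else:
            false_events += 1
    sensitivity = len(detected) / len(killed_ids) if killed_ids else float("nan")
    out = {
        "n_cell_frames": int(len(unmerged)),
        "mass_rel_err_median": float(rel_err.median()) if len(unmerged) else float("nan"),
        "mass_rel_err_frac_below_2pct": float((rel_err < 0.02).mean()) if len(unmerged) else float("nan"),
        "track_purity": purity_num / purity_den if purity_den else float("nan"),
        "n_true_death_events": len(killed_ids),
        "n_detected_death_events": len(detected),
        "event_sensitivity": sensitivity,
        "n_false_events": int(false_events),
    }
    if result.summary is not None:
        act = result.summary[result.summary.group == "activated"].iloc[0]
        out["mass_fold_activated"] = float(act.mass_fold_vs_unresponsive)
        out["area_fold_activated"] = float(act.area_fold_vs_unresponsive)
    return out


def inject_mass_bias(result: ScenarioResult, bias: float) -> ScenarioResult:
    """Scale every measured mass by (1 + bias); used to verify the
    validation harness detects calibration errors."""
    for traj in result.trajectories:
        traj.mass_pg = traj.mass_pg * (1.0 + bias)
    return result


# ----------------------------------------------------------------------
# file-based runs
# ----------------------------------------------------------------------


def _manifest(config: RunConfig, extra: dict | None = None) -> dict:
    cfg = config.to_dict()
    blob = json.dumps(cfg, sort_keys=True).encode()
    man = {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "version": _pkg_version,
    }
    if extra:
        man.update(extra)
    return man


def simulate_to_dir(name: str, seed: int, out_dir: str | Path, config: RunConfig | None = None) -> list[Path]:
    """Render a named scenario to disk: per-field wrapped/intensity stacks,
    wrap-count and label maps (TIFF) plus the ground-truth table (CSV)."""
    config = config or RunConfig()
    config.seed = seed
    config.scenario = name
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scenes = _phantom.build_scenario(name, seed, config.optics)
    paths = []
    for i, scene in enumerate(scenes):
        stack, truth = _phantom.render_stack(scene, config.noise, seed=seed + i)
        fdir = out_dir / f"field{i:02d}"
        fdir.mkdir(exist_ok=True)
        _io.write_stack(fdir / "wrapped.tif", stack.wrapped, scene.optics, kind="wrapped_opd_um")
        _io.write_stack(fdir / "intensity.tif", stack.intensity, scene.optics, kind="intensity")
        _io.write_int_stack(fdir / "wrap_count.tif", truth.wrap_count)
        _io.write_int_stack(fdir / "labels.tif", truth.label_map)
        _io.write_truth_csv(fdir / "truth.csv", truth.table)
        paths.append(fdir)
    _io.write_json(out_dir / "manifest.json", _manifest(config, {"n_fields": len(scenes), "stage": "simulate"}))
    return paths


def tracks_table(trajectories: list) -> pd.DataFrame:
    rows = []
    for traj in trajectories:
        for i in range(len(traj)):
            rows.append(
                {
                    "track_id": traj.track_id,
                    "frame": int(traj.frames[i]),
                    "time_min": float(traj.time_min[i]),
                    "x_um": float(traj.x_um[i]),
                    "y_um": float(traj.y_um[i]),
                    "area_um2": float(traj.area_um2[i]),
                    "mass_pg": float(traj.mass_pg[i]),
                    "merged_with": traj.merge_partners.get(int(traj.frames[i]), -1),
                    "role": traj.role,
                    "end_reason": traj.end_reason,
                }
            )
    return pd.DataFrame(rows)


def run_to_dir(
    name: str, seed: int, out_dir: str | Path, config: RunConfig | None = None
) -> ScenarioResult:
    """Full pipeline on a simulated scenario with all artifacts on disk."""
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = run_scenario(name, seed, config)
    tracks_table(result.trajectories).to_csv(out_dir / "tracks.csv", index=False)
    _io.write_json(out_dir / "events.json", [e.to_dict() for e in result.events])
    if result.summary is not None:
        result.summary.to_csv(out_dir / "summary.csv", index=False)
    _io.write_json(out_dir / "manifest.json", _manifest(config, {"stage": "run", "scenario": name}))
    return result
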