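"""Tracking: optimal assignment, gap closure, merge bookkeeping."""

import itertools

import numpy as np
import pytest

from qpimass import phantom, track
from qpimass.config import NoiseConfig, OpticsConfig, TrackParams
from qpimass.segment import Detection, FrameSegmentation
from qpimass.pipeline import process_stack
from qpimass.config import RunConfig


def det(x, y, frame=0, label=1):
    return Detection(
        frame=frame,
        label=label,
        centroid_um=(x, y),
        n_pixels=50,
        n_mass_pixels=50,
        area_um2=20.0,
        mean_opd_um=0.2,
        sum_opd_um=10.0,
    )


def brute_force_cost(dets_t, dets_t1, max_disp):
    """Exhaustive minimum of the linking objective over all partial assignments."""
    n, m = len(dets_t), len(dets_t1)
    pen = max_disp * max_disp
    best = np.inf
    for k in range(min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                cost = 0.0
                ok = True
                for i, j in zip(rows, cols):
                    d2 = (dets_t[i].x_um - dets_t1[j].x_um) ** 2 + (
                        dets_t[i].y_um - dets_t1[j].y_um
                    ) ** 2
                    if d2 > pen:
                        ok = False
                        break
                    cost += d2
                if not ok:
                    continue
                cost += pen * (n - k) + pen * (m - k)
                best = min(best, cost)
    return best


def assignment_cost(pairs, dets_t, dets_t1, max_disp):
    pen = max_disp * max_disp
    cost = sum(
        (dets_t[i].x_um - dets_t1[j].x_um) ** 2 + (dets_t[i].y_um - dets_t1[j].y_um) ** 2
        for i, j in pairs
    )
    cost += pen * (len(dets_t) - len(pairs)) + pen * (len(dets_t1) - len(pairs))
    return cost


class TestLinkFrames:
    def test_single_pair_within_range_is_linked(self):
        assert track.link_frames([det(0, 0)], [det(1, 0)], 15.0) == [(0, 0)]

    def test_identity_pairing_beats_swap(self):
        # positions 0,10 -> 1,9: identity cost 1+1=2, swap cost 81+81=162
        a = [det(0, 0), det(10, 0)]
        b = [det(1, 0), det(9, 0)]
        assert sorted(track.link_frames(a, b, 15.0)) == [(0, 0), (1, 1)]

    def test_long_links_forbidden(self):
        assert track.link_frames([det(0, 0)], [det(50, 0)], 15.0) == []

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_brute_force_on_random_sets(self, trial):
        rng = np.random.default_rng(trial)
        n, m = rng.integers(1, 4), rng.integers(1, 4)
        a = [det(*rng.uniform(0, 40, 2)) for _ in range(n)]
        b = [det(*rng.uniform(0, 40, 2)) for _ in range(m)]
        pairs = track.link_frames(a, b, 15.0)
        got = assignment_cost(pairs, a, b, 15.0)
        want = brute_force_cost(a, b, 15.0)
        assert got == pytest.approx(want, rel=1e-9)

    def test_six_detections_against_exhaustive_oracle(self):
        rng = np.random.default_rng(99)
        a = [det(*rng.uniform(0, 30, 2)) for _ in range(3)]
        b = [det(*rng.uniform(0, 30, 2)) for _ in range(3)]
        pairs = track.link_frames(a, b, 20.0)
        assert assignment_cost(pairs, a, b, 20.0) == pytest.approx(
            brute_force_cost(a, b, 20.0), rel=1e-9
        )

    def test_invalid_max_disp(self):
        with pytest.raises(ValueError):
            track.link_frames([det(0, 0)], [det(1, 1)], 0.0)


def _segs_from_positions(frames, optics, missing=()):
    """Minimal FrameSegmentation list from per-frame position lists."""
    h, w = optics.image_shape
    out = []
    for f, positions in enumerate(frames):
        dets, lab = [], np.zeros((h, w), np.int32)
        for k, (x, y) in enumerate(positions):
            if (f, k) in missing:
                continue
            label = len(dets) + 1
            d = det(x, y, frame=f, label=label)
            row, col = int(y / optics.pixel_um), int(x / optics.pixel_um)
            lab[max(row - 2, 0) : row + 3, max(col - 2, 0) : col + 3] = label
            dets.append(d)
        out.append(
            FrameSegmentation(
                detections=dets,
                label_map=lab,
                mass_label_map=lab,
                background_median=0.0,
                background_sigma=0.001,
                otsu_threshold=0.1,
            )
        )
    return out


class TestBuildTracks:
    def test_single_cell_spans_all_frames(self, optics):
        segs = _segs_from_positions([[(50.0, 50.0)]] * 6, optics)
        tracks = track.build_tracks(segs, optics)
        assert len(tracks) == 1
        assert tracks[0].frames == list(range(6))
        assert tracks[0].end_reason == track.END_STACK

    def test_one_frame_gap_is_closed(self, optics):
        segs = _segs_from_positions([[(50.0, 50.0)]] * 6, optics, missing={(3, 0)})
        tracks = track.build_tracks(segs, optics, TrackParams(gap_max=2))
        assert len(tracks) == 1
        assert tracks[0].frames == [0, 1, 2, 4, 5]
        assert tracks[0].gap_frames == [3]

    def test_track_ends_after_gap_max_exceeded(self, optics):
        frames = [[(100.0, 80.0)]] * 3 + [[]] * 4 + [[(100.0, 80.0)]]
        segs = _segs_from_positions(frames, optics)
        tracks = track.build_tracks(segs, optics, TrackParams(gap_max=2))
        assert len(tracks) == 2
        assert tracks[0].end_reason == track.END_WASHED_AWAY

    def test_track_leaving_field_edge(self, optics):
        xs = [5.0, 4.0, 3.0]
        frames = [[(x, 50.0)] for x in xs] + [[]] * 4
        segs = _segs_from_positions(frames, optics)
        tracks = track.build_tracks(segs, optics, TrackParams(gap_max=2))
        assert tracks[0].end_reason == track.END_LEFT_FIELD


@pytest.fixture(scope="module")
def merge_result(optics):
    """Two cells scripted to collide mid-stack and separate again."""
    from dataclasses import replace

    o = replace(optics, image_shape=(128, 128))
    cells = [
        phantom.CellSpec(1, phantom.ROLE_TARGET_HEALTHY, 600.0, 10.0, [(0.0, 28.0, 38.0)]),
        phantom.CellSpec(
            2,
            phantom.ROLE_TARGET_HEALTHY,
            600.0,
            10.0,
            [
                (0.0, 58.0, 38.0),
                (14.0, 58.0, 38.0),
                (24.5, 42.0, 38.0),
                (38.5, 42.0, 38.0),
                (49.0, 58.0, 38.0),
                (70.0, 58.0, 38.0),
            ],
        ),
    ]
    scene = phantom.build_scene(phantom.SceneConfig(optics=o, n_frames=21, cells=cells))
    stack, truth = phantom.render_stack(scene, NoiseConfig(), seed=4)
    cfg = RunConfig()
    res = process_stack(stack, cfg, model=None)
    return scene, truth, res


class TestMerges:
    def test_both_tracks_flagged_merged_during_contact(self, merge_result):
        scene, truth, res = merge_result
        tracks = [t for t in res.trajectories if len(t) >= 15]
        assert len(tracks) == 2
        merged_a = set(np.asarray(tracks[0].frames)[tracks[0].merged])
        merged_b = set(np.asarray(tracks[1].frames)[tracks[1].merged])
        assert merged_a and merged_a == merged_b
        # partners reference each other
        for f in merged_a:
            assert tracks[0].merge_partners[f] == tracks[1].track_id
            assert tracks[1].merge_partners[f] == tracks[0].track_id

    def test_combined_mass_is_conserved_across_merge(self, merge_result):
        scene, truth, res = merge_result
        tracks = [t for t in res.trajectories if len(t) >= 15]
        a, b = tracks
        shared = sorted(set(np.asarray(a.frames)[a.merged]))
        f = shared[len(shared) // 2]
        ia = list(a.frames).index(f)
        combined = a.mass_pg[ia]
        # last separate masses before the merge
        pre_a = a.mass_pg[~a.merged][np.asarray(a.frames)[~a.merged] < shared[0]][-1]
        pre_b = b.mass_pg[~b.merged][np.asarray(b.frames)[~b.merged] < shared[0]][-1]
        assert combined == pytest.approx(pre_a + pre_b, rel=0.05)

    def test_no_overlap_no_merge_flags(self, optics):
        segs = _segs_from_positions([[(30.0, 30.0), (100.0, 100.0)]] * 5, optics)
        tracks = track.build_tracks(segs, optics)
        assert all(not e.merged for t in tracks for e in t.entries)
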