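"""Event logic: contacts, ball-up, death/activation classification, Welch."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from qpimass import events, massprof
from qpimass.config import EventParams, OpticsConfig


def traj(times, masses, areas=None, opds=None, role="target", track_id=1, merged=None):
    n = len(times)
    return massprof.MassTrajectory(
        track_id=track_id,
        role=role,
        time_min=np.asarray(times, float),
        mass_pg=np.asarray(masses, float),
        area_um2=np.asarray(areas if areas is not None else np.full(n, 400.0), float),
        mean_opd_um=np.asarray(opds if opds is not None else np.full(n, 0.25), float),
        merged=np.zeros(n, bool) if merged is None else np.asarray(merged, bool),
        x_um=np.zeros(n),
        y_um=np.zeros(n),
        frames=np.arange(n),
    )


def contact(tgt=1, ctl=2, start=0, end=20, dt=3.5):
    return events.ContactInterval(
        target_track_id=tgt,
        ctl_track_id=ctl,
        start_frame=start,
        end_frame=end,
        duration_min=(end - start) * dt,
        min_boundary_distance_um=0.0,
    )


class TestWelch:
    def test_identical_samples(self):
        t, df, p = events.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == 1.0

    def test_hand_computed_example(self):
        # a=(1,2,3), b=(2,4,6): t = -2/sqrt(1/3+4/3) = -1.549, df = 2.94
        t, df, p = events.welch_t([1, 2, 3], [2, 4, 6])
        assert t == pytest.approx(-1.549, abs=1e-3)
        assert df == pytest.approx(2.94, abs=0.01)

    def test_swapping_samples_negates_t_keeps_p(self):
        t1, _, p1 = events.welch_t([1, 2, 3], [2, 4, 6])
        t2, _, p2 = events.welch_t([2, 4, 6], [1, 2, 3])
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_zero_variance_equal_means_p_one(self):
        t, _, p = events.welch_t([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            events.welch_t([1.0], [1.0, 2.0])

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.lists(st.floats(-100, 100), min_size=3, max_size=20),
        b=st.lists(st.floats(-100, 100), min_size=3, max_size=20),
    )
    def test_agrees_with_scipy_reference(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        if a.var(ddof=1) < 1e-12 or b.var(ddof=1) < 1e-12:
            return
        t, df, p = events.welch_t(a, b)
        ref = sstats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-6)
        assert p == pytest.approx(ref.pvalue, abs=1e-6)


class TestDetectBallup:
    def test_constant_morphology_gives_none(self):
        t = traj(np.arange(0, 100, 3.5), np.full(29, 800.0))
        assert events.detect_ballup(t) is None

    def test_area_drop_with_density_rise_detected(self):
        n = 30
        times = np.arange(n) * 3.5
        areas = np.full(n, 700.0)
        opds = np.full(n, 0.25)
        areas[18:] = 250.0  # -64%
        opds[18:] = 0.60  # +140%
        t = traj(times, np.full(n, 800.0), areas, opds)
        assert events.detect_ballup(t) == pytest.approx(times[18])

    def test_area_drop_without_density_rise_ignored(self):
        # a cell sliding off the field edge loses area but not density
        n = 30
        areas = np.full(n, 700.0)
        areas[18:] = 250.0
        t = traj(np.arange(n) * 3.5, np.full(n, 800.0), areas)
        assert events.detect_ballup(t) is None

    def test_too_short_trajectory(self):
        t = traj([0, 3.5, 7.0], [1, 1, 1])
        assert events.detect_ballup(t) is None


def killed_traj(t0_idx=30, loss=0.4, n=90, m0=800.0, track_id=1):
    times = np.arange(n) * 3.5
    masses = np.full(n, m0)
    areas = np.full(n, 700.0)
    opds = np.full(n, 0.25)
    t0 = times[t0_idx]
    for i in range(t0_idx, n):
        frac = min((times[i] - t0) / 120.0, 1.0)
        masses[i] = m0 * (1 - loss * frac)
        areas[i] = 250.0
        opds[i] = 0.60
    return traj(times, masses, areas, opds, track_id=track_id)


class TestClassifyDeath:
    optics = OpticsConfig()

    def test_forty_percent_loss_after_contact_confirmed(self):
        t = killed_traj(loss=0.40)
        ev = events.classify_death(t, [contact(start=10, end=32)], self.optics)
        assert ev is not None
        assert ev.mass_loss_fraction == pytest.approx(0.40, abs=0.02)
        assert ev.ctl_track_id == 2

    def test_small_dip_with_recovery_rejected(self):
        n = 90
        times = np.arange(n) * 3.5
        masses = np.full(n, 800.0)
        areas = np.full(n, 700.0)
        opds = np.full(n, 0.25)
        masses[30:40] = 720.0  # 10% dip, below the 20% floor
        areas[30:] = 250.0
        opds[30:] = 0.60
        t = traj(times, masses, areas, opds)
        ev = events.classify_death(t, [contact(start=10, end=32)], self.optics)
        assert ev is None

    def test_loss_without_contact_not_attributed(self):
        t = killed_traj(loss=0.40)
        assert events.classify_death(t, [], self.optics) is None

    def test_short_contact_rejected(self):
        t = killed_traj(loss=0.40)
        short = contact(start=28, end=32)  # 14 min < 30 min requirement
        assert events.classify_death(t, [short], self.optics) is None

    @pytest.mark.parametrize("loss_pair", [(0.25, 0.30), (0.30, 0.50), (0.45, 0.60)])
    def test_monotone_in_scripted_loss_fraction(self, loss_pair):
        lo, hi = loss_pair
        cts = [contact(start=10, end=32)]
        ev_lo = events.classify_death(killed_traj(loss=lo), cts, self.optics)
        ev_hi = events.classify_death(killed_traj(loss=hi), cts, self.optics)
        assert ev_lo is not None and ev_hi is not None
        assert ev_hi.mass_loss_fraction >= ev_lo.mass_loss_fraction


class TestClassifyActivation:
    optics = OpticsConfig()

    def _event(self, t0=105.0):
        return events.CytotoxicityEvent(
            target_track_id=1,
            ctl_track_id=2,
            t0_min=t0,
            mass_loss_fraction=0.4,
            loss_duration_h=2.0,
            contact_duration_min=45.0,
        )

    def test_fourfold_rate_step_flagged_activated(self):
        times = np.arange(0, 300, 3.5)
        t0 = 105.0
        masses = np.where(times <= t0, 60 + 5 * times / 60, 60 + 5 * t0 / 60 + 20 * (times - t0) / 60)
        ctl = traj(times, masses, role="ctl", track_id=2)
        ev = events.classify_activation(ctl, self._event(t0))
        assert ev.ctl_activated
        assert ev.ctl_rates.during_pre_ratio == pytest.approx(4.0, abs=0.3)

    def test_flat_ctl_not_activated(self):
        times = np.arange(0, 300, 3.5)
        masses = 60 + 5 * times / 60
        ctl = traj(times, masses, role="ctl", track_id=2)
        ev = events.classify_activation(ctl, self._event())
        assert not ev.ctl_activated
        assert ev.ctl_rates.during_pre_ratio == pytest.approx(1.0, abs=0.2)

    def test_insufficient_coverage_leaves_metrics_undefined(self):
        times = np.arange(150, 300, 3.5)  # starts after t0
        ctl = traj(times, np.full(len(times), 80.0), role="ctl", track_id=2)
        ev = events.classify_activation(ctl, self._event(105.0))
        assert ev.ctl_rates is None


class TestPopulationSummary:
    def _population(self, act_mass, act_area, n_act=6, n_un=12):
        trajs, evts = [], []
        times = np.arange(0, 200, 3.5)
        rng = np.random.default_rng(0)
        tid = 1
        for _ in range(n_act):
            m = act_mass * rng.normal(1, 0.02)
            trajs.append(
                traj(times, np.full(len(times), m), np.full(len(times), act_area), role="ctl", track_id=tid)
            )
            evts.append(
                events.CytotoxicityEvent(
                    target_track_id=1000 + tid,
                    ctl_track_id=tid,
                    t0_min=100.0,
                    mass_loss_fraction=0.4,
                    loss_duration_h=1.0,
                    contact_duration_min=45.0,
                )
            )
            tid += 1
        for _ in range(n_un):
            m = 65 * rng.normal(1, 0.02)
            trajs.append(
                traj(times, np.full(len(times), m), np.full(len(times), 60.0), role="ctl", track_id=tid)
            )
            tid += 1
        return trajs, evts

    def test_identical_groups_fold_one_p_near_one(self):
        trajs, evts = self._population(act_mass=65.0, act_area=60.0)
        df = events.population_summary(trajs, evts)
        act = df[df.group == "activated"].iloc[0]
        assert act.mass_fold_vs_unresponsive == pytest.approx(1.0, abs=0.05)
        assert act.p_mass > 0.05

    def test_headline_folds_and_volume_arithmetic(self):
        trajs, evts = self._population(act_mass=182.0, act_area=84.0)
        df = events.population_summary(trajs, evts)
        act = df[df.group == "activated"].iloc[0]
        assert act.mass_fold_vs_unresponsive == pytest.approx(2.8, abs=0.1)
        assert act.area_fold_vs_unresponsive == pytest.approx(1.4, abs=0.05)
        # spherical-cell consistency: area fold 1.4 -> volume fold 1.4^1.5 = 1.66
        assert act.implied_volume_fold == pytest.approx(act.area_fold_vs_unresponsive**1.5)
        assert act.implied_volume_fold == pytest.approx(1.66, abs=0.1)
        assert act.stars_mass in {"*", "**", "***"}

    def test_small_group_rejected(self):
        trajs, evts = self._population(act_mass=182.0, act_area=84.0, n_act=1)
        with pytest.raises(ValueError):
            events.population_summary(trajs, evts)


def test_significance_stars_thresholds():
    assert events.significance_stars(0.2) == ""
    assert events.significance_stars(0.04) == "*"
    assert events.significance_stars(0.005) == "**"
    assert events.significance_stars(1e-4) == "***"
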