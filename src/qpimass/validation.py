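"""Headline parameter-recovery analyses on phantom scenarios.

Each function simulates a named scenario, runs the full pipeline on the
rendered wrapped-phase stacks and measures one population quantity the
generator encodes: healthy growth, killing mass loss, CTL rate step-up,
activated/unresponsive mass and area contrasts, and measurement
repeatability.  They exist so that validation runs and the test suite share
one implementation.
"""

from __future__ import annotations

import numpy as np

from . import massprof as _massprof
from .config import RunConfig
from .pipeline import ScenarioResult, run_scenario, train_default_model


def healthy_mass_gain_percent(
    seed: int, model=None, config: RunConfig | None = None, result: ScenarioResult | None = None
) -> tuple[float, int]:
    """Mean percent mass gain at 4 h of healthy target cells.

    Runs the healthy-default scenario (300 simulated target cells), builds
    normalised trajectories (reference = first sample) and interpolates each
    at t = 240 min.  Returns (100 * (mean normalised mass - 1), n cells).
    """
    result = result or run_scenario("healthy-default", seed, config, model=model)
    vals = []
    for traj in result.trajectories:
        if traj.role != "target" or len(traj) < 10:
            continue
        sel = ~traj.merged
        if sel.sum() < 10:
            continue
        t = traj.time_min[sel]
        if t[0] > 5.0 or t[-1] < 240.0:
            continue
        _massprof.normalize(traj, float(t[0]))
        vals.append(float(np.interp(240.0, t, traj.normalized[sel])))
    return 100.0 * (float(np.mean(vals)) - 1.0), len(vals)


def min_confirmed_loss_percent(
    seed: int, model=None, config: RunConfig | None = None, result: ScenarioResult | None = None
) -> tuple[float, int]:
    """Smallest percent mass loss among confirmed killing events
    (death-default scenario: 20 scripted kills spanning the 20-60% regime)."""
    result = result or run_scenario("death-default", seed, config, model=model)
    losses = [100.0 * ev.mass_loss_fraction for ev in result.events if ev.death_confirmed]
    if not losses:
        raise RuntimeError("no confirmed death events")
    return float(min(losses)), len(losses)


def mean_rate_ratio(
    seed: int, model=None, config: RunConfig | None = None, result: ScenarioResult | None = None
) -> tuple[float, int]:
    """Mean CTL during/pre mass-accumulation-rate ratio over detected events
    (activation-default scenario, 10 CTL-target pairs)."""
    result = result or run_scenario("activation-default", seed, config, model=model)
    ratios = [
        ev.ctl_rates.during_pre_ratio
        for ev in result.events
        if ev.ctl_rates is not None and np.isfinite(ev.ctl_rates.during_pre_ratio)
    ]
    if not ratios:
        raise RuntimeError("no events with rate triplets")
    return float(np.mean(ratios)), len(ratios)


def run_mixed_population(seed: int, model=None, config: RunConfig | None = None) -> ScenarioResult:
    return run_scenario("mixed-population-default", seed, config, model=model)


def activated_mass_fold(result: ScenarioResult) -> tuple[float, int]:
    """Activated / unresponsive mean endpoint-mass ratio from the population
    summary of a mixed-population run."""
    if result.summary is None:
        raise RuntimeError("population summary unavailable (too few events?)")
    act = result.summary[result.summary.group == "activated"].iloc[0]
    return float(act.mass_fold_vs_unresponsive), int(act.n)


def activated_area_fold(result: ScenarioResult) -> tuple[float, int]:
    """Activated / unresponsive mean adaptive-threshold area ratio."""
    if result.summary is None:
        raise RuntimeError("population summary unavailable (too few events?)")
    act = result.summary[result.summary.group == "activated"].iloc[0]
    return float(act.area_fold_vs_unresponsive), int(act.n)


def static_mass_cv_percent(
    seed: int, model=None, config: RunConfig | None = None, result: ScenarioResult | None = None
) -> tuple[float, int]:
    """Coefficient of variation (%) of repeated mass measurements of one
    motionless, non-growing cell over 50 frames at default noise."""
    result = result or run_scenario("static-cell", seed, config, model=model)
    traj = max(result.trajectories, key=len)
    masses = traj.mass_pg[~traj.merged]
    return 100.0 * float(masses.std() / masses.mean()), int(masses.size)


def shared_model(seed: int, config: RunConfig | None = None):
    """One trained wrap-correction model reused across scenario runs."""
    config = config or RunConfig()
    config.seed = seed
    return train_default_model(config)
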