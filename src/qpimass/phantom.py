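"""Synthetic phase-image phantoms with per-cell ground truth.

Cells are rendered as radially symmetric optical-path-difference (OPD) caps

    OPD(r) = h * (1 - (r/R)^2)^q,        r <= R,

whose continuous spatial integral is h * pi * R^2 / (q + 1).  The peak height
``h`` is chosen so that k * integral equals the cell's prescribed dry mass,
which makes every rendered frame a quantitative oracle for the downstream
pipeline: mass, area, position, wrap counts and cell identity are all known
exactly.

Kinetic repertoire (per cell role):

* ``target_healthy`` -- multiplicative growth, default +15% of initial mass
  per 4 h.
* ``target_killed`` -- healthy growth until the scripted death time ``t0``,
  then an abrupt "ball-up" (footprint radius contracts to 0.6 R with peak
  height rescaled to conserve mass) followed by an exponential-to-linear mass
  loss reaching a prescribed fraction f in [0.2, 0.6] of the t0 mass over
  1-4 h.
* ``ctl_activated`` -- piecewise-linear mass accumulation: rate r_pre before
  t0, 4 x r_pre during the first 100 min after t0, 2 x r_pre afterwards.
* ``ctl_unresponsive`` -- slow healthy-like growth.

The rendered OPD field is the sum of all cell caps plus zero-mean Gaussian
noise, wrapped into [0, lambda) exactly as a single-wavelength interferometer
would measure it; the integer number of wavelengths removed per pixel is kept
as ground truth.  A matched "average intensity" image is produced as a
monotone decreasing transform of the clean OPD plus its own noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import NoiseConfig, OpticsConfig

ROLE_TARGET_HEALTHY = "target_healthy"
ROLE_TARGET_KILLED = "target_killed"
ROLE_CTL_ACTIVATED = "ctl_activated"
ROLE_CTL_UNRESPONSIVE = "ctl_unresponsive"
ROLES = (
    ROLE_TARGET_HEALTHY,
    ROLE_TARGET_KILLED,
    ROLE_CTL_ACTIVATED,
    ROLE_CTL_UNRESPONSIVE,
)

STATE_PRE = "pre"
STATE_BALLUP = "ballup"
STATE_DYING = "dying"
STATE_DEAD = "dead"

_LABEL_MIN_OPD_UM = 0.005  # cap contribution below this does not claim a pixel


@dataclass
class CellSpec:
    """Scripted ground-truth behaviour of a single phantom cell."""

    cell_id: int
    role: str
    initial_mass_pg: float
    radius_um: float
    waypoints: list[tuple[float, float, float]]  # (t_min, x_um, y_um)
    profile_q: float = 1.0
    growth_per_4h: float = 0.15
    # death kinetics (target_killed)
    t0_min: float | None = None
    loss_fraction: float | None = None
    loss_duration_min: float | None = None
    ballup_shrink: float = 0.6
    # activation kinetics (ctl_activated)
    r_pre_pg_per_h: float | None = None
    during_multiplier: float = 4.0
    post_multiplier: float = 2.0
    during_window_min: float = 100.0
    radius_end_um: float | None = None
    radius_end_t_min: float | None = None
    partner_id: int | None = None

    def validate(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown cell role {self.role!r}")
        if self.initial_mass_pg <= 0:
            raise ValueError("initial_mass_pg must be positive")
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")
        if self.profile_q <= 0:
            raise ValueError("profile_q must be positive")
        if not self.waypoints:
            raise ValueError("waypoints must be non-empty")
        if self.role == ROLE_TARGET_KILLED:
            if self.t0_min is None or self.loss_fraction is None or self.loss_duration_min is None:
                raise ValueError("target_killed requires t0_min, loss_fraction, loss_duration_min")
            if not (0.2 <= self.loss_fraction <= 0.6):
                raise ValueError("loss_fraction must lie in [0.2, 0.6]")
            if not (60.0 <= self.loss_duration_min <= 240.0):
                raise ValueError("loss_duration_min must lie in [60, 240] min")
            if not (0 < self.ballup_shrink < 1):
                raise ValueError("ballup_shrink must lie in (0, 1)")
        if self.role == ROLE_CTL_ACTIVATED:
            if self.t0_min is None or self.r_pre_pg_per_h is None:
                raise ValueError("ctl_activated requires t0_min and r_pre_pg_per_h")
            if self.during_multiplier <= 1.0:
                raise ValueError("during_multiplier must exceed the pre-event rate multiplier (1)")
            if self.during_window_min <= 0:
                raise ValueError("during_window_min must be positive")

    # ------------------------------------------------------------------
    # scripted kinetics
    # ------------------------------------------------------------------

    def _growth_factor(self, t_min: float) -> float:
        return (1.0 + self.growth_per_4h) ** (t_min / 240.0)

    def mass_at(self, t_min: float) -> float:
        """True dry mass (pg) at time ``t_min`` from the start of the stack."""
        if self.role in (ROLE_TARGET_HEALTHY, ROLE_CTL_UNRESPONSIVE):
            return self.initial_mass_pg * self._growth_factor(t_min)
        if self.role == ROLE_TARGET_KILLED:
            t0 = float(self.t0_min)
            if t_min < t0:
                return self.initial_mass_pg * self._growth_factor(t_min)
            m0 = self.initial_mass_pg * self._growth_factor(t0)
            tau = min(max((t_min - t0) / float(self.loss_duration_min), 0.0), 1.0)
            # exponential-to-linear decay profile, reaches f exactly at tau=1
            a = 3.0
            s = (1.0 - math.exp(-a * tau)) / (1.0 - math.exp(-a))
            return m0 * (1.0 - float(self.loss_fraction) * s)
        if self.role == ROLE_CTL_ACTIVATED:
            t0 = float(self.t0_min)
            r = float(self.r_pre_pg_per_h)
            w = self.during_window_min
            if t_min <= t0:
                return self.initial_mass_pg + r * t_min / 60.0
            m_t0 = self.initial_mass_pg + r * t0 / 60.0
            if t_min <= t0 + w:
                return m_t0 + self.during_multiplier * r * (t_min - t0) / 60.0
            m_w = m_t0 + self.during_multiplier * r * w / 60.0
            return m_w + self.post_multiplier * r * (t_min - t0 - w) / 60.0
        raise AssertionError(self.role)

    def radius_at(self, t_min: float) -> float:
        if self.role == ROLE_TARGET_KILLED and t_min >= float(self.t0_min):
            return self.radius_um * self.ballup_shrink
        if self.role == ROLE_CTL_ACTIVATED and self.radius_end_um is not None:
            t0 = float(self.t0_min)
            t_end = float(self.radius_end_t_min if self.radius_end_t_min is not None else t0)
            if t_min <= t0 or t_end <= t0:
                return self.radius_um
            frac = min((t_min - t0) / (t_end - t0), 1.0)
            return self.radius_um + frac * (self.radius_end_um - self.radius_um)
        return self.radius_um

    def state_at(self, t_min: float, frame_interval_min: float) -> str:
        if self.role != ROLE_TARGET_KILLED:
            return STATE_PRE
        t0 = float(self.t0_min)
        if t_min < t0:
            return STATE_PRE
        if t_min < t0 + frame_interval_min:
            return STATE_BALLUP
        if t_min < t0 + float(self.loss_duration_min):
            return STATE_DYING
        return STATE_DEAD

    def position_at(self, t_min: float) -> tuple[float, float]:
        wp = self.waypoints
        ts = [w[0] for w in wp]
        x = float(np.interp(t_min, ts, [w[1] for w in wp]))
        y = float(np.interp(t_min, ts, [w[2] for w in wp]))
        return x, y


def cap_height_um(mass_pg: float, radius_um: float, q: float, k_pg_per_um3: float) -> float:
    """Peak OPD of a power-cap whose continuous integral encodes ``mass_pg``."""
    return mass_pg * (q + 1.0) / (k_pg_per_um3 * math.pi * radius_um * radius_um)


@dataclass
class SceneConfig:
    optics: OpticsConfig
    n_frames: int
    cells: list[CellSpec]

    def duration_min(self) -> float:
        return (self.n_frames - 1) * self.optics.frame_interval_min


@dataclass
class Scene:
    """Deterministic ground-truth trajectories for one imaging field."""

    optics: OpticsConfig
    cells: list[CellSpec]
    n_frames: int
    truth: pd.DataFrame  # one row per (frame, cell)

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.optics.frame_interval_min


def build_scene(config: SceneConfig, seed: int = 0) -> Scene:
    """Evaluate scripted kinetics into a per-frame, per-cell truth table.

    ``seed`` is accepted for interface symmetry with the renderer; the scene
    itself is fully scripted and does not consume randomness.
    """
    if config.n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    ids = [c.cell_id for c in config.cells]
    if len(set(ids)) != len(ids):
        raise ValueError("cell ids must be unique")
    for c in config.cells:
        c.validate()
    # initial-overlap rejection: centres closer than the sum of radii
    for i, a in enumerate(config.cells):
        ax, ay = a.position_at(0.0)
        for b in config.cells[i + 1 :]:
            bx, by = b.position_at(0.0)
            if math.hypot(ax - bx, ay - by) < a.radius_um + b.radius_um:
                raise ValueError(
                    f"cells {a.cell_id} and {b.cell_id} overlap at t=0 "
                    "(separation below the sum of radii)"
                )
    dt = config.optics.frame_interval_min
    rows = []
    for frame in range(config.n_frames):
        t = frame * dt
        for c in config.cells:
            r = c.radius_at(t)
            x, y = c.position_at(t)
            rows.append(
                (
                    frame,
                    t,
                    c.cell_id,
                    c.role,
                    c.mass_at(t),
                    math.pi * r * r,
                    r,
                    x,
                    y,
                    c.state_at(t, dt),
                    c.partner_id if c.partner_id is not None else -1,
                )
            )
    truth = pd.DataFrame(
        rows,
        columns=[
            "frame",
            "time_min",
            "cell_id",
            "role",
            "mass_pg",
            "area_um2",
            "radius_um",
            "x_um",
            "y_um",
            "state",
            "partner_id",
        ],
    )
    return Scene(optics=config.optics, cells=list(config.cells), n_frames=config.n_frames, truth=truth)


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------


@dataclass
class FrameTruth:
    frame: int
    wrap_count: np.ndarray  # int16, wavelengths removed per pixel
    label_map: np.ndarray  # int32, 0 = background
    clean_opd: np.ndarray  # float64, noise-free unwrapped OPD, um
    table: pd.DataFrame  # per-cell truth rows for this frame


@dataclass
class StackTruth:
    wrap_count: np.ndarray  # (T, H, W) int16
    label_map: np.ndarray  # (T, H, W) int32
    clean_opd: np.ndarray  # (T, H, W) float64
    table: pd.DataFrame


@dataclass
class PhaseStack:
    """Time-ordered wrapped OPD images plus matched intensity images."""

    wrapped: np.ndarray  # (T, H, W) float64, each value in [0, lambda)
    intensity: np.ndarray  # (T, H, W) float64
    optics: OpticsConfig


def _compose_clean_frame(
    scene: Scene, frame_index: int, optics: OpticsConfig
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    h_px, w_px = optics.image_shape
    opd = np.zeros((h_px, w_px), dtype=np.float64)
    best = np.zeros((h_px, w_px), dtype=np.float64)
    labels = np.zeros((h_px, w_px), dtype=np.int32)
    sub = scene.truth[scene.truth["frame"] == frame_index]
    px = optics.pixel_um
    for row in sub.itertuples(index=False):
        r_um = row.radius_um
        if row.mass_pg <= 0:
            continue
        spec = next(c for c in scene.cells if c.cell_id == row.cell_id)
        h_cap = cap_height_um(row.mass_pg, r_um, spec.profile_q, optics.k_pg_per_um3)
        c0 = max(int(math.floor((row.x_um - r_um) / px)), 0)
        c1 = min(int(math.ceil((row.x_um + r_um) / px)) + 1, w_px)
        r0 = max(int(math.floor((row.y_um - r_um) / px)), 0)
        r1 = min(int(math.ceil((row.y_um + r_um) / px)) + 1, h_px)
        if c0 >= c1 or r0 >= r1:
            continue
        yy = (np.arange(r0, r1) * px - row.y_um)[:, None]
        xx = (np.arange(c0, c1) * px - row.x_um)[None, :]
        u2 = (yy * yy + xx * xx) / (r_um * r_um)
        cap = h_cap * np.clip(1.0 - u2, 0.0, None) ** spec.profile_q
        opd[r0:r1, c0:c1] += cap
        claim = cap > np.maximum(best[r0:r1, c0:c1], _LABEL_MIN_OPD_UM)
        labels[r0:r1, c0:c1][claim] = row.cell_id
        np.maximum(best[r0:r1, c0:c1], cap, out=best[r0:r1, c0:c1])
    if np.any(opd < 0):
        raise ValueError("composed scene has negative OPD; phantom is unphysical")
    return opd, labels, sub.reset_index(drop=True)


def render_frame(
    scene: Scene,
    frame_index: int,
    optics: OpticsConfig | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, FrameTruth]:
    """Render one frame into (wrapped OPD image, intensity image, truth).

    The wrapped image satisfies ``wrapped + lambda * wrap_count == clean + n``
    exactly, where ``n`` is the additive OPD noise realisation (zero when the
    noise amplitude is zero).
    """
    optics = optics or scene.optics
    noise = noise or NoiseConfig()
    if not (0 <= frame_index < scene.n_frames):
        raise IndexError(f"frame_index {frame_index} outside scene duration")
    clean, labels, table = _compose_clean_frame(scene, frame_index, optics)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(frame_index)]))
    lam = optics.wavelength_um
    noisy = clean
    if noise.sigma_opd_um > 0:
        noisy = clean + rng.normal(0.0, noise.sigma_opd_um, clean.shape)
    wrap_count = np.floor(noisy / lam).astype(np.int16)
    wrapped = noisy - lam * wrap_count
    intensity = np.exp(-clean / noise.intensity_decay_um)
    if noise.sigma_intensity > 0:
        intensity = intensity + rng.normal(0.0, noise.sigma_intensity, clean.shape)
    truth = FrameTruth(
        frame=frame_index,
        wrap_count=wrap_count,
        label_map=labels,
        clean_opd=clean,
        table=table,
    )
    return wrapped, intensity, truth


def render_stack(
    scene: Scene, noise: NoiseConfig | None = None, seed: int = 0
) -> tuple[PhaseStack, StackTruth]:
    """Render the whole scene; bit-for-bit reproducible for a given seed."""
    noise = noise or NoiseConfig()
    h_px, w_px = scene.optics.image_shape
    t = scene.n_frames
    wrapped = np.empty((t, h_px, w_px), dtype=np.float64)
    intensity = np.empty((t, h_px, w_px), dtype=np.float64)
    wrap_count = np.empty((t, h_px, w_px), dtype=np.int16)
    labels = np.empty((t, h_px, w_px), dtype=np.int32)
    clean = np.empty((t, h_px, w_px), dtype=np.float64)
    for i in range(t):
        try:
            w, inten, ft = render_frame(scene, i, scene.optics, noise, seed)
        except ValueError as exc:
            raise ValueError(f"frame {i}: {exc}") from exc
        wrapped[i] = w
        intensity[i] = inten
        wrap_count[i] = ft.wrap_count
        labels[i] = ft.label_map
        clean[i] = ft.clean_opd
    truth = StackTruth(wrap_count=wrap_count, label_map=labels, clean_opd=clean, table=scene.truth)
    return PhaseStack(wrapped=wrapped, intensity=intensity, optics=scene.optics), truth


# ----------------------------------------------------------------------
# scenario library
# ----------------------------------------------------------------------

#: Default per-role geometry (um) and mass (pg).  Target radius is large
#: enough that the balled-up cap (0.6 R, mass-conserving) stays below the
#: per-pixel Nyquist bound of lambda/2 at the default pixel pitch.
DEFAULTS = {
    "target_mass_pg": 840.0,
    "target_radius_um": 15.5,
    "ctl_mass_pg": 65.0,
    "ctl_unresponsive_mass_pg": 60.0,
    "ctl_radius_um": 4.4,
    "activated_endpoint_mass_pg": 240.0,
    "activated_mass_fold": 2.8,
    "activated_area_fold": 1.4,
}


def _place_sites(
    rng: np.random.Generator,
    radii: Sequence[float],
    field_um: tuple[float, float],
    max_attempts: int = 40000,
) -> list[tuple[float, float]]:
    """Dart-throwing placement of disjoint circular sites inside the field."""
    placed: list[tuple[float, float, float]] = []
    out: list[tuple[float, float]] = []
    fy, fx = field_um
    failed = False
    for r in radii:
        ok = False
        for _ in range(max_attempts):
            x = rng.uniform(r + 2.0, fx - r - 2.0)
            y = rng.uniform(r + 2.0, fy - r - 2.0)
            if all((x - px) ** 2 + (y - py) ** 2 >= (r + pr) ** 2 for px, py, pr in placed):
                placed.append((x, y, r))
                out.append((x, y))
                ok = True
                break
        if not ok:
            failed = True
            break
    if not failed:
        return out
    # dense fields: fall back to a jittered grid, largest sites first
    order = np.argsort(radii)[::-1]
    r_max = max(radii)
    spacing = 2.0 * r_max + 2.0
    nx = int((fx - 2.0 * (r_max + 2.0)) // spacing) + 1
    ny = int((fy - 2.0 * (r_max + 2.0)) // spacing) + 1
    if nx * ny < len(radii):
        raise RuntimeError("could not place phantom sites without overlap; field too crowded")
    xs = r_max + 2.0 + spacing * np.arange(nx) + (fx - 2.0 * (r_max + 2.0) - spacing * (nx - 1)) / 2.0
    ys = r_max + 2.0 + spacing * np.arange(ny) + (fy - 2.0 * (r_max + 2.0) - spacing * (ny - 1)) / 2.0
    nodes = [(x, y) for y in ys for x in xs]
    rng.shuffle(nodes)
    out2: list[tuple[float, float] | None] = [None] * len(radii)
    for k, idx in enumerate(order):
        x, y = nodes[k]
        jitter = max((spacing - 2.0 * radii[idx]) / 2.0 - 1.0, 0.0)
        out2[idx] = (
            float(x + rng.uniform(-jitter, jitter)),
            float(y + rng.uniform(-jitter, jitter)),
        )
    return out2


def _drift_waypoints(
    rng: np.random.Generator,
    x: float,
    y: float,
    duration_min: float,
    speed_um_per_min: float,
    field_um: tuple[float, float],
    margin_um: float,
    step_min: float = 40.0,
) -> list[tuple[float, float, float]]:
    wps = [(0.0, x, y)]
    t = 0.0
    fy, fx = field_um
    while t < duration_min:
        t = min(t + step_min, duration_min)
        ang = rng.uniform(0, 2 * math.pi)
        step = speed_um_per_min * step_min
        x = float(np.clip(x + step * math.cos(ang), margin_um, fx - margin_um))
        y = float(np.clip(y + step * math.sin(ang), margin_um, fy - margin_um))
        wps.append((t, x, y))
    return wps


def _field_um(optics: OpticsConfig) -> tuple[float, float]:
    return (optics.image_shape[0] * optics.pixel_um, optics.image_shape[1] * optics.pixel_um)


def _make_pair(
    rng: np.random.Generator,
    next_id: int,
    site: tuple[float, float],
    duration_min: float,
    t0_min: float,
    target_kw: dict,
    ctl_kw: dict,
) -> tuple[CellSpec, CellSpec]:
    """A killed target plus its attacking CTL, scripted through contact,
    ball-up at ``t0`` and the post-event window."""
    tx, ty = site
    r_t = target_kw.pop("radius_um")
    r_c = ctl_kw.pop("radius_um")
    ang = rng.uniform(0, 2 * math.pi)
    d_start = r_t + r_c + 8.0
    d_contact = 0.68 * (r_t + r_c)
    sx, sy = tx + d_start * math.cos(ang), ty + d_start * math.sin(ang)
    cx, cy = tx + d_contact * math.cos(ang), ty + d_contact * math.sin(ang)
    t_contact = t0_min - 45.0
    if t_contact < 15.0:
        raise ValueError("t0 too early for a >=30 min contact interval")
    target = CellSpec(
        cell_id=next_id,
        role=ROLE_TARGET_KILLED,
        radius_um=r_t,
        waypoints=[(0.0, tx, ty)],
        t0_min=t0_min,
        partner_id=next_id + 1,
        **target_kw,
    )
    # after the target balls up it detaches and condenses; the CTL holds a
    # small stand-off distance for the rest of the recording
    d_post = d_contact + 4.0
    px2, py2 = tx + d_post * math.cos(ang), ty + d_post * math.sin(ang)
    # activated T cells swell as they accumulate mass; growing the footprint
    # keeps the cap's edge slope within the sampling limit of the imaging
    ctl_kw.setdefault("radius_end_um", r_c * 1.25)
    ctl_kw.setdefault("radius_end_t_min", duration_min)
    ctl = CellSpec(
        cell_id=next_id + 1,
        role=ROLE_CTL_ACTIVATED,
        radius_um=r_c,
        waypoints=[
            (0.0, sx, sy),
            (t_contact - 12.0, sx, sy),
            (t_contact, cx, cy),
            (t0_min, cx, cy),
            (min(t0_min + 4.0, duration_min), px2, py2),
            (duration_min, px2, py2),
        ],
        t0_min=t0_min,
        partner_id=next_id,
        **ctl_kw,
    )
    return target, ctl


def _scenario_healthy(seed: int, optics: OpticsConfig) -> list[SceneConfig]:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    n_cells, per_field, n_frames = 300, 8, 70
    field = _field_um(optics)
    configs = []
    cid = 1
    remaining = n_cells
    while remaining > 0:
        n = min(per_field, remaining)
        sites = _place_sites(rng, [DEFAULTS["target_radius_um"] + 3.0] * n, field)
        cells = []
        for x, y in sites:
            cells.append(
                CellSpec(
                    cell_id=cid,
                    role=ROLE_TARGET_HEALTHY,
                    initial_mass_pg=float(rng.normal(DEFAULTS["target_mass_pg"], 60.0)),
                    radius_um=float(rng.normal(DEFAULTS["target_radius_um"], 0.7)),
                    growth_per_4h=float(rng.normal(0.15, 0.03)),
                    waypoints=_drift_waypoints(
                        rng, x, y, (n_frames - 1) * optics.frame_interval_min, 0.05, field, 20.0
                    ),
                )
            )
            cid += 1
        configs.append(SceneConfig(optics=optics, n_frames=n_frames, cells=cells))
        remaining -= n
    return configs


def _scenario_death(seed: int, optics: OpticsConfig) -> list[SceneConfig]:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 102]))
    optics = replace(optics, image_shape=(320, 320))
    field = _field_um(optics)
    n_fields, pairs_per_field, n_frames = 5, 4, 108
    duration = (n_frames - 1) * optics.frame_interval_min
    configs = []
    cid = 1
    for _ in range(n_fields):
        r_t = DEFAULTS["target_radius_um"]
        r_c = DEFAULTS["ctl_radius_um"]
        site_r = (r_t + r_c + 8.0) + r_c + 2.0
        sites = _place_sites(rng, [site_r] * pairs_per_field, field)
        cells = []
        for site in sites:
            t0 = float(rng.uniform(60.0, 120.0))
            target, ctl = _make_pair(
                rng,
                cid,
                site,
                duration,
                t0,
                target_kw=dict(
                    initial_mass_pg=float(rng.normal(DEFAULTS["target_mass_pg"], 60.0)),
                    radius_um=float(rng.normal(r_t, 0.7)),
                    loss_fraction=float(rng.uniform(0.2, 0.6)),
                    loss_duration_min=float(rng.uniform(60.0, 240.0)),
                ),
                ctl_kw=dict(
                    initial_mass_pg=float(rng.normal(DEFAULTS["ctl_mass_pg"], 6.0)),
                    radius_um=float(rng.normal(r_c, 0.25)),
                    r_pre_pg_per_h=float(rng.normal(6.0, 1.0)),
                ),
            )
            cells.extend([target, ctl])
            cid += 2
        configs.append(SceneConfig(optics=optics, n_frames=n_frames, cells=cells))
    return configs


def _scenario_activation(seed: int, optics: OpticsConfig) -> list[SceneConfig]:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 103]))
    optics = replace(optics, image_shape=(320, 320))
    field = _field_um(optics)
    field_pairs, n_frames = (4, 3, 3), 82
    duration = (n_frames - 1) * optics.frame_interval_min
    configs = []
    cid = 1
    for pairs_per_field in field_pairs:
        r_t = DEFAULTS["target_radius_um"]
        r_c = DEFAULTS["ctl_radius_um"]
        site_r = (r_t + r_c + 8.0) + r_c + 2.0
        sites = _place_sites(rng, [site_r] * pairs_per_field, field)
        cells = []
        for site in sites:
            t0 = float(rng.uniform(95.0, 115.0))
            target, ctl = _make_pair(
                rng,
                cid,
                site,
                duration,
                t0,
                target_kw=dict(
                    initial_mass_pg=float(rng.normal(DEFAULTS["target_mass_pg"], 60.0)),
                    radius_um=float(rng.normal(r_t, 0.7)),
                    loss_fraction=float(rng.uniform(0.35, 0.55)),
                    loss_duration_min=float(rng.uniform(90.0, 180.0)),
                ),
                ctl_kw=dict(
                    initial_mass_pg=float(rng.normal(DEFAULTS["ctl_mass_pg"], 4.0)),
                    radius_um=float(rng.normal(r_c, 0.2)),
                    r_pre_pg_per_h=float(rng.normal(6.0, 0.5)),
                ),
            )
            cells.extend([target, ctl])
            cid += 2
        configs.append(SceneConfig(optics=optics, n_frames=n_frames, cells=cells))
    return configs


def _scenario_mixed(seed: int, optics: OpticsConfig) -> list[SceneConfig]:
    """Mixed population: killed-target/activated-CTL pairs among unresponsive
    CTLs.  Generator defaults encode the headline population contrasts:
    activated endpoint mass = 2.8 x the expected unresponsive endpoint mean,
    activated endpoint footprint area = 1.4 x the unresponsive mean."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104]))
    n_frames = 94
    duration = (n_frames - 1) * optics.frame_interval_min
    r_c = DEFAULTS["ctl_radius_um"]
    r_t = DEFAULTS["target_radius_um"]
    m_u = DEFAULTS["ctl_unresponsive_mass_pg"]
    unresp_end_mean = m_u * (1.15) ** (duration / 240.0)
    act_end_mean = DEFAULTS["activated_mass_fold"] * unresp_end_mean
    act_radius_end = r_c * math.sqrt(DEFAULTS["activated_area_fold"])

    def unresponsive(cid: int, x: float, y: float, field: tuple[float, float]) -> CellSpec:
        return CellSpec(
            cell_id=cid,
            role=ROLE_CTL_UNRESPONSIVE,
            initial_mass_pg=float(rng.normal(m_u, 8.0)),
            radius_um=float(rng.normal(r_c, 0.25)),
            growth_per_4h=float(rng.normal(0.15, 0.03)),
            waypoints=_drift_waypoints(rng, x, y, duration, 0.12, field, 10.0),
        )

    configs = []
    cid = 1
    # event fields: pairs + bystander unresponsive CTLs
    ev_optics = replace(optics, image_shape=(320, 320))
    ev_field = _field_um(ev_optics)
    for _ in range(8):
        site_r = (r_t + r_c + 8.0) + r_c + 2.0
        radii = [site_r] * 3 + [r_c + 3.0] * 8
        sites = _place_sites(rng, radii, ev_field)
        cells = []
        for site in sites[:3]:
            t0 = float(rng.uniform(95.0, 115.0))
            m_start = float(rng.normal(65.0, 6.0))
            m_end = float(act_end_mean * rng.lognormal(0.0, 0.09))
            # back-compute the pre-event rate so the scripted endpoint mass
            # hits the prescribed activated-population mean
            hours = t0 / 60.0 + 4.0 * (100.0 / 60.0) + 2.0 * (duration - t0 - 100.0) / 60.0
            r_pre = max((m_end - m_start) / hours, 1.0)
            target, ctl = _make_pair(
                rng,
                cid,
                site,
                duration,
                t0,
                target_kw=dict(
                    initial_mass_pg=float(rng.normal(DEFAULTS["target_mass_pg"], 60.0)),
                    radius_um=float(rng.normal(r_t, 0.7)),
                    loss_fraction=float(rng.uniform(0.3, 0.5)),
                    loss_duration_min=float(rng.uniform(90.0, 180.0)),
                ),
                ctl_kw=dict(
                    initial_mass_pg=m_start,
                    radius_um=float(rng.normal(r_c, 0.2)),
                    r_pre_pg_per_h=r_pre,
                    radius_end_um=float(act_radius_end * rng.normal(1.0, 0.05)),
                    radius_end_t_min=duration,
                ),
            )
            cells.extend([target, ctl])
            cid += 2
        for x, y in sites[3:]:
            cells.append(unresponsive(cid, x, y, ev_field))
            cid += 1
        configs.append(SceneConfig(optics=ev_optics, n_frames=n_frames, cells=cells))
    # CTL-only fields: unresponsive bystanders
    field = _field_um(optics)
    for _ in range(2):
        sites = _place_sites(rng, [r_c + 3.0] * 10, field)
        cells = []
        for x, y in sites:
            cells.append(unresponsive(cid, x, y, field))
            cid += 1
        configs.append(SceneConfig(optics=optics, n_frames=n_frames, cells=cells))
    return configs


def _scenario_static(seed: int, optics: OpticsConfig) -> list[SceneConfig]:
    """One motionless, non-growing activated-class (240 pg) cell, 50 frames;
    used for measurement-repeatability (CV) checks."""
    optics = replace(optics, image_shape=(96, 96))
    field = _field_um(optics)
    cell = CellSpec(
        cell_id=1,
        role=ROLE_TARGET_HEALTHY,
        initial_mass_pg=DEFAULTS["activated_endpoint_mass_pg"],
        radius_um=6.0,
        growth_per_4h=0.0,
        waypoints=[(0.0, field[1] / 2.0, field[0] / 2.0)],
    )
    return [SceneConfig(optics=optics, n_frames=50, cells=[cell])]


def _scenario_fidelity(seed: int, optics: OpticsConfig) -> list[SceneConfig]:
    """20-cell benchmark field (1 event pair, 2 healthy targets, 16
    unresponsive CTLs) on the default 256 x 256 grid, 60 frames."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 106]))
    n_frames = 60
    duration = (n_frames - 1) * optics.frame_interval_min
    field = _field_um(optics)
    r_t = DEFAULTS["target_radius_um"]
    r_c = DEFAULTS["ctl_radius_um"]
    site_r = (r_t + r_c + 8.0) + r_c + 2.0
    radii = [site_r] + [r_t + 3.0] * 2 + [r_c + 3.0] * 16
    sites = _place_sites(rng, radii, field)
    cells = []
    cid = 1
    t0 = float(rng.uniform(70.0, 90.0))
    target, ctl = _make_pair(
        rng,
        cid,
        sites[0],
        duration,
        t0,
        target_kw=dict(
            initial_mass_pg=float(rng.normal(DEFAULTS["target_mass_pg"], 60.0)),
            radius_um=float(rng.normal(r_t, 0.7)),
            loss_fraction=float(rng.uniform(0.35, 0.55)),
            loss_duration_min=float(rng.uniform(90.0, 180.0)),
        ),
        ctl_kw=dict(
            initial_mass_pg=float(rng.normal(DEFAULTS["ctl_mass_pg"], 5.0)),
            radius_um=float(rng.normal(r_c, 0.2)),
            r_pre_pg_per_h=float(rng.normal(6.0, 0.5)),
        ),
    )
    cells.extend([target, ctl])
    cid += 2
    for x, y in sites[1:3]:
        cells.append(
            CellSpec(
                cell_id=cid,
                role=ROLE_TARGET_HEALTHY,
                initial_mass_pg=float(rng.normal(DEFAULTS["target_mass_pg"], 60.0)),
                radius_um=float(rng.normal(r_t, 0.7)),
                growth_per_4h=float(rng.normal(0.15, 0.03)),
                waypoints=_drift_waypoints(rng, x, y, duration, 0.05, field, 20.0),
            )
        )
        cid += 1
    for x, y in sites[3:]:
        cells.append(
            CellSpec(
                cell_id=cid,
                role=ROLE_CTL_UNRESPONSIVE,
                initial_mass_pg=float(rng.normal(DEFAULTS["ctl_unresponsive_mass_pg"], 8.0)),
                radius_um=float(rng.normal(r_c, 0.25)),
                growth_per_4h=float(rng.normal(0.15, 0.03)),
                waypoints=_drift_waypoints(rng, x, y, duration, 0.12, field, 10.0),
            )
        )
        cid += 1
    return [SceneConfig(optics=optics, n_frames=n_frames, cells=cells)]


SCENARIOS: dict[str, Callable[[int, OpticsConfig], list[SceneConfig]]] = {
    "healthy-default": _scenario_healthy,
    "death-default": _scenario_death,
    "activation-default": _scenario_activation,
    "mixed-population-default": _scenario_mixed,
    "static-cell": _scenario_static,
    "mass-fidelity-default": _scenario_fidelity,
}


def build_scenario(name: str, seed: int, optics: OpticsConfig | None = None) -> list[Scene]:
    """Instantiate a named scenario into a list of per-field scenes."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}")
    optics = optics or OpticsConfig()
    return [build_scene(cfg, seed) for cfg in SCENARIOS[name](seed, optics)]
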