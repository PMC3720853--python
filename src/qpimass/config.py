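"""Shared configuration objects for the dry-mass imaging pipeline.

All optical-path-difference (OPD) values in this package are stored in
micrometres, not radians.  With OPD in length units, the dry-mass relation

    m = k * sum(OPD) * A_pixel

is dimensionally direct: k in pg/um^3 (the inverse specific refractive
increment, d(rho)/d(n)), pixel area in um^2, OPD in um, mass in pg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

#: Illumination wavelength of the interferometer's fiber-coupled LED, um.
DEFAULT_WAVELENGTH_UM = 0.530

#: Mass conversion factor (inverse specific refractive increment), pg/um^3.
DEFAULT_K_PG_PER_UM3 = 5.56

#: Effective pixel pitch at the sample plane, um/pixel.
DEFAULT_PIXEL_UM = 0.6

#: Time between frames, minutes (imaging cadence of 3-4 min).
DEFAULT_FRAME_INTERVAL_MIN = 3.5


@dataclass(frozen=True)
class OpticsConfig:
    """Optical and acquisition geometry of a phase-imaging run."""

    wavelength_um: float = DEFAULT_WAVELENGTH_UM
    k_pg_per_um3: float = DEFAULT_K_PG_PER_UM3
    pixel_um: float = DEFAULT_PIXEL_UM
    image_shape: tuple[int, int] = (256, 256)
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")
        if self.k_pg_per_um3 <= 0:
            raise ValueError("k_pg_per_um3 must be positive")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        if len(self.image_shape) != 2 or min(self.image_shape) < 2:
            raise ValueError("image_shape must be 2-D with both sides >= 2")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_um * self.pixel_um

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "OpticsConfig":
        d = dict(d)
        if "image_shape" in d:
            d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)


@dataclass(frozen=True)
class NoiseConfig:
    """Additive measurement-noise model for rendered phantoms.

    ``sigma_opd_um`` is the per-pixel Gaussian noise on the OPD field,
    applied *before* phase wrapping.  ``sigma_intensity`` applies to the
    synthetic average-intensity image.
    """

    sigma_opd_um: float = 0.004
    sigma_intensity: float = 0.01
    intensity_decay_um: float = 0.8  # e-folding OPD of the intensity transform

    def __post_init__(self) -> None:
        if self.sigma_opd_um < 0 or self.sigma_intensity < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.intensity_decay_um <= 0:
            raise ValueError("intensity_decay_um must be positive")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class SegmentParams:
    """Detection / area-measurement parameters."""

    lowpass_sigma_px: float = 2.0
    min_area_px: int = 30
    support_dilation_px: float = 10.0
    adaptive_window_px: int = 201
    adaptive_offset_um: float = 0.015
    merge_suspect_area_um2: float = 1500.0

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class TrackParams:
    max_disp_um: float = 15.0
    gap_max: int = 2
    washed_away_border_um: float = 10.0

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class EventParams:
    contact_distance_px: float = 1.0
    contact_gap_frames: int = 1
    min_contact_min: float = 30.0
    ballup_area_drop: float = 0.30
    ballup_opd_rise: float = 0.30
    ballup_trailing_frames: int = 5
    min_loss_fraction: float = 0.20
    loss_window_min: float = 240.0
    activation_rate_ratio: float = 2.0
    during_window_min: float = 100.0
    role_mass_threshold_pg: float = 400.0

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class GAConfig:
    """Real-coded genetic-algorithm settings for threshold refinement."""

    population: int = 32
    generations: int = 50
    tournament: int = 3
    mutation_sigma_frac: float = 0.10
    elitism: int = 2
    n_fitness_images: int = 12

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class RunConfig:
    """Full pipeline configuration (one imaging field)."""

    optics: OpticsConfig = field(default_factory=OpticsConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    segment: SegmentParams = field(default_factory=SegmentParams)
    track: TrackParams = field(default_factory=TrackParams)
    events: EventParams = field(default_factory=EventParams)
    ga: GAConfig = field(default_factory=GAConfig)
    seed: int = 0
    scenario: str | None = None

    def to_dict(self) -> dict[str, Any]:
        return {
            "optics": self.optics.to_dict(),
            "noise": self.noise.to_dict(),
            "segment": self.segment.to_dict(),
            "track": self.track.to_dict(),
            "events": self.events.to_dict(),
            "ga": self.ga.to_dict(),
            "seed": self.seed,
            "scenario": self.scenario,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        return cls(
            optics=OpticsConfig.from_dict(d.get("optics", {})),
            noise=NoiseConfig(**d.get("noise", {})),
            segment=SegmentParams(**d.get("segment", {})),
            track=TrackParams(**d.get("track", {})),
            events=EventParams(**d.get("events", {})),
            ga=GAConfig(**d.get("ga", {})),
            seed=int(d.get("seed", 0)),
            scenario=d.get("scenario"),
        )
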