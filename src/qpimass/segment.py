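"""Per-frame cell detection and area measurement.

Detection follows the standard recipe for quantitative phase images:
Gaussian low-pass, global Otsu threshold, 8-connected component labelling
with a minimum-size filter.  Two different pixel supports are then used:

* the *mass support* -- the Otsu component grown by a label-constrained
  dilation (``support_dilation_px``).  The Otsu level sits at an appreciable
  fraction of a cell's peak OPD, so integrating over the raw component would
  systematically miss the low-OPD skirt of the cell; the dilated support
  captures it while ``skimage.segmentation.expand_labels`` keeps touching
  cells from claiming each other's pixels.  Dry mass is integrated over this
  support only.
* the *area support* -- a local adaptive threshold (mean over a
  ``adaptive_window_px``-sided square minus an offset, floored at the
  background noise level) evaluated inside the mass support.  This is the
  projected 2-D area reported for each detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.segmentation import expand_labels

from .config import OpticsConfig, SegmentParams


@dataclass
class Detection:
    """One segmented object in one frame."""

    frame: int
    label: int
    centroid_um: tuple[float, float]  # (x, y)
    n_pixels: int  # Otsu component support
    n_mass_pixels: int  # dilated mass support
    area_um2: float  # adaptive-threshold area
    mean_opd_um: float  # over the Otsu component
    sum_opd_um: float  # background-referenced, over the mass support
    mass_pg: float = float("nan")
    merge_suspect: bool = False

    @property
    def x_um(self) -> float:
        return self.centroid_um[0]

    @property
    def y_um(self) -> float:
        return self.centroid_um[1]


@dataclass
class FrameSegmentation:
    detections: list[Detection]
    label_map: np.ndarray  # Otsu components, int32
    mass_label_map: np.ndarray  # dilated supports, int32
    background_median: float
    background_sigma: float
    otsu_threshold: float


def lowpass(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian low-pass with reflecting boundary; sigma 0 is the identity."""
    if sigma_px < 0:
        raise ValueError("sigma_px must be non-negative")
    if sigma_px == 0:
        return np.asarray(image, dtype=np.float64).copy()
    return ndimage.gaussian_filter(np.asarray(image, dtype=np.float64), sigma_px, mode="reflect")


def otsu_threshold(image: np.ndarray) -> float:
    """Otsu's between-class-variance-maximising threshold (256-bin histogram)."""
    image = np.asarray(image)
    if np.ptp(image) == 0:
        raise ValueError("constant image has no Otsu threshold")
    return float(threshold_otsu(image, nbins=256))


def label_cells(
    binary_mask: np.ndarray,
    opd_image: np.ndarray,
    optics: OpticsConfig,
    min_area_px: int = 30,
    frame: int = 0,
    merge_suspect_area_um2: float = float("inf"),
) -> tuple[list[Detection], np.ndarray]:
    """8-connected components of a binary mask as detections.

    Components smaller than ``min_area_px`` are discarded.  Centroids are
    intensity-weighted by OPD.  Area and mass fields are placeholders to be
    filled by :func:`segment_frame`.
    """
    lab = sk_label(binary_mask, connectivity=2).astype(np.int32)
    px = optics.pixel_um
    dets: list[Detection] = []
    keep = np.zeros(lab.max() + 1, dtype=bool)
    for rid in range(1, lab.max() + 1):
        mask = lab == rid
        n = int(mask.sum())
        if n < min_area_px:
            lab[mask] = 0
            continue
        keep[rid] = True
        weights = np.clip(opd_image[mask], 1e-12, None)
        rr, cc = np.nonzero(mask)
        cx = float((cc * weights).sum() / weights.sum()) * px
        cy = float((rr * weights).sum() / weights.sum()) * px
        area = n * optics.pixel_area_um2
        dets.append(
            Detection(
                frame=frame,
                label=int(rid),
                centroid_um=(cx, cy),
                n_pixels=n,
                n_mass_pixels=n,
                area_um2=area,
                mean_opd_um=float(opd_image[mask].mean()),
                sum_opd_um=float(opd_image[mask].sum()),
                merge_suspect=area > merge_suspect_area_um2,
            )
        )
    # compact labels so they are 1..n in detection order
    remap = np.zeros(lab.max() + 1, dtype=np.int32)
    for new_id, det in enumerate(dets, start=1):
        remap[det.label] = new_id
        det.label = new_id
    lab = remap[lab]
    return dets, lab


def adaptive_area(
    phase_image: np.ndarray,
    support_mask: np.ndarray,
    optics: OpticsConfig,
    window_px: int = 201,
    offset_um: float = 0.015,
    noise_floor_um: float = 0.0,
) -> float:
    """Projected 2-D area from a local adaptive threshold.

    A pixel belongs to the cell when its OPD exceeds the local mean over a
    ``window_px``-sided square minus ``offset_um`` (never below
    ``noise_floor_um``), intersected with the given support mask.
    """
    if not support_mask.any():
        raise ValueError("empty detection support")
    phase_image = np.asarray(phase_image, dtype=np.float64)
    if window_px > min(phase_image.shape):
        warnings.warn("adaptive window larger than image; using the global mean", stacklevel=2)
        local_mean = np.full_like(phase_image, phase_image.mean())
    else:
        size = window_px if window_px % 2 == 1 else window_px + 1
        local_mean = ndimage.uniform_filter(phase_image, size=size, mode="reflect")
    thr = np.maximum(local_mean - offset_um, noise_floor_um)
    in_cell = (phase_image > thr) & support_mask
    return float(in_cell.sum()) * optics.pixel_area_um2


def segment_frame(
    opd_image: np.ndarray,
    optics: OpticsConfig,
    params: SegmentParams | None = None,
    frame: int = 0,
) -> FrameSegmentation:
    """Full per-frame detection pass on a corrected, unwrapped OPD image.

    The image is zero-referenced internally: the median of non-component
    pixels is subtracted before OPD sums are taken, so detections carry
    background-referenced ``sum_opd_um`` ready for mass conversion.
    """
    params = params or SegmentParams()
    opd_image = np.asarray(opd_image, dtype=np.float64)
    smoothed = lowpass(opd_image, params.lowpass_sigma_px)
    # a very bright outlier (a balled-up dying cell) would otherwise drag the
    # global Otsu level above dim cells; clip the histogram at a robust
    # ceiling so the threshold keeps separating background from cells
    med = float(np.median(smoothed))
    sig = float(1.4826 * np.median(np.abs(smoothed - med))) or 1e-6
    ceiling = max(med + 20.0 * sig, float(np.percentile(smoothed, 99.0)))
    try:
        thr = otsu_threshold(np.minimum(smoothed, ceiling))
    except ValueError:
        return FrameSegmentation([], np.zeros(opd_image.shape, np.int32), np.zeros(opd_image.shape, np.int32), 0.0, 0.0, float("nan"))
    mask = smoothed > thr
    dets, lab = label_cells(
        mask,
        opd_image,
        optics,
        min_area_px=params.min_area_px,
        frame=frame,
        merge_suspect_area_um2=params.merge_suspect_area_um2,
    )
    mass_lab = expand_labels(lab, distance=params.support_dilation_px)
    # background statistics from pixels outside every dilated support: the
    # Otsu components alone would leave low-OPD cell skirts in the
    # "background" and bias the reference level upward
    background = mass_lab == 0
    if not background.any():
        background = lab == 0
    bg_median = float(np.median(opd_image[background])) if background.any() else 0.0
    bg_sigma = (
        float(1.4826 * np.median(np.abs(opd_image[background] - bg_median))) if background.any() else 0.0
    )
    referenced = opd_image - bg_median
    noise_floor = 3.0 * bg_sigma
    for det in dets:
        mass_mask = mass_lab == det.label
        det.n_mass_pixels = int(mass_mask.sum())
        det.sum_opd_um = float(referenced[mass_mask].sum())
        det.mean_opd_um = float(referenced[lab == det.label].mean())
        det.area_um2 = adaptive_area(
            referenced,
            mass_mask,
            optics,
            window_px=params.adaptive_window_px,
            offset_um=params.adaptive_offset_um,
            noise_floor_um=noise_floor,
        )
    return FrameSegmentation(
        detections=dets,
        label_map=lab,
        mass_label_map=mass_lab,
        background_median=bg_median,
        background_sigma=bg_sigma,
        otsu_threshold=thr,
    )
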