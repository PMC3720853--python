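"""Supervised correction of residual single-wavelength wrap errors.

Even a good unwrapper can leave whole regions of a cell offset by one
wavelength when the fringe boundary is corrupted.  This module implements
the supervised repair stage: per-pixel image statistics are fed to a Fisher
linear discriminant trained to recognise pixels on the boundary of
phase-wrapped regions; a genetic algorithm refines the discriminant's score
threshold and the watershed flood threshold; watershed regions delimited by
the detected boundaries are shifted by exactly one wavelength -- with the
sign and pixel-exact extent chosen to minimise the residual boundary
discontinuity against a locally re-unwrapped smooth reference -- and the
frame is finished with a 3x3 median filter.

Training data comes from phantom ground truth: wrap-count boundary pixels
(dilated by one pixel) stand in for the manually corrected sub-images a
microscopist would curate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .config import GAConfig, NoiseConfig, OpticsConfig
from . import phantom as _phantom
from . import unwrap as _unwrap

N_FEATURES = 16
FEATURE_MENU_VERSION = "qpimass-16ch-v1"

#: Channel names, fixed for reproducibility.  Beyond the raw wrapped image
#: and the intensity image, the menu is a set of edge/texture statistics
#: computed on the wrapped phase (and two on the intensity image).
FEATURE_NAMES = (
    "wrapped_phase",
    "intensity",
    "grad_mag_sobel",
    "diff_x",
    "diff_y",
    "laplacian",
    "scharr_mag",
    "grad_mag_smoothed",
    "local_std_3",
    "local_std_7",
    "morph_gradient_3",
    "dist_to_half_lambda",
    "local_range_3",
    "smoothed_phase",
    "smoothed_intensity",
    "intensity_grad_mag",
)


def _local_std(img: np.ndarray, size: int) -> np.ndarray:
    m = ndimage.uniform_filter(img, size=size, mode="reflect")
    m2 = ndimage.uniform_filter(img * img, size=size, mode="reflect")
    return np.sqrt(np.clip(m2 - m * m, 0.0, None))


def extract_features(
    wrapped: np.ndarray,
    intensity: np.ndarray,
    wavelength_um: float,
) -> np.ndarray:
    """Per-pixel feature stack, shape (16, H, W).  Deterministic."""
    if wrapped.shape != intensity.shape:
        raise ValueError("wrapped and intensity images must share a shape")
    w = np.asarray(wrapped, dtype=np.float64)
    it = np.asarray(intensity, dtype=np.float64)
    if not (np.all(np.isfinite(w)) and np.all(np.isfinite(it))):
        raise ValueError("non-finite pixels in input images")
    sx = ndimage.sobel(w, axis=1, mode="reflect")
    sy = ndimage.sobel(w, axis=0, mode="reflect")
    smooth1 = ndimage.gaussian_filter(w, 1.0, mode="reflect")
    ssx = ndimage.sobel(smooth1, axis=1, mode="reflect")
    ssy = ndimage.sobel(smooth1, axis=0, mode="reflect")
    isx = ndimage.sobel(it, axis=1, mode="reflect")
    isy = ndimage.sobel(it, axis=0, mode="reflect")
    dx = np.zeros_like(w)
    dx[:, 1:] = np.diff(w, axis=1)
    dy = np.zeros_like(w)
    dy[1:, :] = np.diff(w, axis=0)
    scharr_x = ndimage.correlate(w, np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]]) / 32.0, mode="reflect")
    scharr_y = ndimage.correlate(w, np.array([[3, 10, 3], [0, 0, 0], [-3, -10, -3]]) / 32.0, mode="reflect")
    feats = np.stack(
        [
            w,
            it,
            np.hypot(sx, sy),
            dx,
            dy,
            ndimage.laplace(w, mode="reflect"),
            np.hypot(scharr_x, scharr_y),
            np.hypot(ssx, ssy),
            _local_std(w, 3),
            _local_std(w, 7),
            ndimage.grey_dilation(w, size=3) - ndimage.grey_erosion(w, size=3),
            np.abs(w - wavelength_um / 2.0),
            ndimage.maximum_filter(w, size=3) - ndimage.minimum_filter(w, size=3),
            smooth1,
            ndimage.gaussian_filter(it, 1.0, mode="reflect"),
            np.hypot(isx, isy),
        ]
    )
    assert feats.shape[0] == N_FEATURES
    return feats


@dataclass
class BoundaryModel:
    """Fisher-discriminant wrap-boundary classifier plus region thresholds."""

    weights: np.ndarray  # (16,)
    bias: float
    score_threshold: float
    flood_threshold: float
    feature_mean: np.ndarray  # (16,)
    feature_std: np.ndarray  # (16,)
    wavelength_um: float
    trained_on: str = ""
    feature_menu: str = FEATURE_MENU_VERSION

    def score_map(self, features: np.ndarray) -> np.ndarray:
        z = (features - self.feature_mean[:, None, None]) / self.feature_std[:, None, None]
        return np.tensordot(self.weights, z, axes=(0, 0)) + self.bias

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "bias": self.bias,
                "score_threshold": self.score_threshold,
                "flood_threshold": self.flood_threshold,
                "feature_mean": self.feature_mean.tolist(),
                "feature_std": self.feature_std.tolist(),
                "wavelength_um": self.wavelength_um,
                "trained_on": self.trained_on,
                "feature_menu": self.feature_menu,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "BoundaryModel":
        d = json.loads(text)
        return cls(
            weights=np.asarray(d["weights"], dtype=np.float64),
            bias=float(d["bias"]),
            score_threshold=float(d["score_threshold"]),
            flood_threshold=float(d["flood_threshold"]),
            feature_mean=np.asarray(d["feature_mean"], dtype=np.float64),
            feature_std=np.asarray(d["feature_std"], dtype=np.float64),
            wavelength_um=float(d["wavelength_um"]),
            trained_on=d.get("trained_on", ""),
            feature_menu=d.get("feature_menu", FEATURE_MENU_VERSION),
        )


@dataclass
class TrainingImage:
    """One training sub-image with ground-truth wrap labels."""

    wrapped: np.ndarray
    intensity: np.ndarray
    unwrapped: np.ndarray  # field presented to the corrector (may carry an injected error)
    clean: np.ndarray  # true unwrapped field
    boundary_labels: np.ndarray  # bool: wrap-region boundary pixels (dilated 1)
    region_labels: np.ndarray  # bool: pixels whose wrap count is wrong in `unwrapped`


@dataclass
class TrainingSet:
    images: list[TrainingImage]
    wavelength_um: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.images:
            n_pos = sum(int(im.boundary_labels.sum()) for im in self.images)
            n_neg = sum(int((~im.boundary_labels).sum()) for im in self.images)
            if n_pos == 0 or n_neg == 0:
                raise ValueError("training set must contain both classes")


def make_training_set(
    n_images: int = 200,
    seed: int = 0,
    optics: OpticsConfig | None = None,
    noise: NoiseConfig | None = None,
    size_px: int = 48,
    inject_fraction: float = 0.5,
) -> TrainingSet:
    """Phantom-derived training sub-images.

    Each sub-image holds a single cell tall enough to wrap (peak OPD above
    lambda).  Boundary labels are the edges of the ground-truth wrap-count
    map, dilated by one pixel.  In ``inject_fraction`` of the images the
    wrapped region of the unwrapped field is deliberately shifted by -lambda,
    emulating an unwrapper failure; those pixels form the region labels used
    to score the full correction pass.
    """
    from dataclasses import replace as _replace

    optics = optics or OpticsConfig()
    optics = _replace(optics, image_shape=(size_px, size_px))
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7001]))
    lam = optics.wavelength_um
    images: list[TrainingImage] = []
    field_um = size_px * optics.pixel_um
    for idx in range(n_images):
        mass = float(rng.uniform(220.0, 420.0))
        # radius window: peak above lambda but per-pixel steps well below lambda/2
        r_lo = (0.66 * mass) ** (1.0 / 3.0)
        r_hi = math.sqrt(2.0 * mass / (optics.k_pg_per_um3 * math.pi * lam)) - 0.3
        radius = float(rng.uniform(r_lo, max(r_hi, r_lo + 0.2)))
        x = field_um / 2 + float(rng.uniform(-3, 3))
        y = field_um / 2 + float(rng.uniform(-3, 3))
        cell = _phantom.CellSpec(
            cell_id=1,
            role=_phantom.ROLE_TARGET_HEALTHY,
            initial_mass_pg=mass,
            radius_um=radius,
            growth_per_4h=0.0,
            waypoints=[(0.0, x, y)],
        )
        scene = _phantom.build_scene(_phantom.SceneConfig(optics=optics, n_frames=1, cells=[cell]))
        wrapped, intensity, ft = _phantom.render_frame(scene, 0, optics, noise, seed=int(rng.integers(2**31)))
        noisy_unwrapped = wrapped + lam * ft.wrap_count
        wrap_region = ft.wrap_count >= 1
        boundary = wrap_region ^ ndimage.binary_erosion(wrap_region)
        boundary = ndimage.binary_dilation(boundary, iterations=1)
        unwrapped = noisy_unwrapped.copy()
        region = np.zeros_like(wrap_region)
        if rng.uniform() < inject_fraction and wrap_region.any():
            unwrapped[wrap_region] -= lam
            region = wrap_region.copy()
        images.append(
            TrainingImage(
                wrapped=wrapped,
                intensity=intensity,
                unwrapped=unwrapped,
                clean=ft.clean_opd,
                boundary_labels=boundary,
                region_labels=region,
            )
        )
    return TrainingSet(images=images, wavelength_um=lam, provenance=f"phantom(seed={seed}, n={n_images})")


def train_lda(train: TrainingSet, max_pixels_per_class: int = 40000, seed: int = 0) -> BoundaryModel:
    """Closed-form Fisher discriminant for wrap-boundary pixels.

    w is proportional to pooled-covariance^-1 (mu1 - mu0); the initial score
    threshold sits at the midpoint of the projected class means.  A ridge of
    1e-6 * trace/16 is added if the pooled covariance is singular.
    """
    xs, ys = [], []
    for im in train.images:
        f = extract_features(im.wrapped, im.intensity, train.wavelength_um)
        xs.append(f.reshape(N_FEATURES, -1).T)
        ys.append(im.boundary_labels.ravel())
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.shape[0] < N_FEATURES + 1:
        raise ValueError("need at least 17 training samples")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7002]))
    sel = []
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        if idx.size == 0:
            raise ValueError("training set must contain both classes")
        if idx.size > max_pixels_per_class:
            idx = rng.choice(idx, size=max_pixels_per_class, replace=False)
        sel.append(idx)
    idx = np.concatenate(sel)
    x, y = x[idx], y[idx]
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0] = 1.0
    z = (x - mean) / std
    mu0 = z[~y].mean(axis=0)
    mu1 = z[y].mean(axis=0)
    if np.allclose(mu0, mu1):
        raise ValueError("degenerate training set: class means coincide")
    n0, n1 = int((~y).sum()), int(y.sum())
    z0 = z[~y] - mu0
    z1 = z[y] - mu1
    sw = (z0.T @ z0 + z1.T @ z1) / (n0 + n1 - 2)
    ridge = 1e-6 * np.trace(sw) / N_FEATURES
    try:
        w = np.linalg.solve(sw, mu1 - mu0)
    except np.linalg.LinAlgError:
        w = np.linalg.solve(sw + ridge * np.eye(N_FEATURES), mu1 - mu0)
    if not np.all(np.isfinite(w)) or np.allclose(w, 0):
        w = np.linalg.solve(sw + ridge * np.eye(N_FEATURES), mu1 - mu0)
    thr = 0.5 * float(w @ mu0 + w @ mu1)
    scores_pos = z[y] @ w
    flood = float(np.quantile(scores_pos, 0.25))
    return BoundaryModel(
        weights=w,
        bias=0.0,
        score_threshold=thr,
        flood_threshold=flood,
        feature_mean=mean,
        feature_std=std,
        wavelength_um=train.wavelength_um,
        trained_on=train.provenance,
    )


# ----------------------------------------------------------------------
# region correction
# ----------------------------------------------------------------------


def _detect_regions(
    score: np.ndarray, score_threshold: float, flood_threshold: float
) -> list[tuple[tuple[slice, slice], np.ndarray]]:
    """Watershed basins fully enclosed by high-score boundary ridges.

    Returns (bounding-box slices, mask-within-box) pairs.  The watershed is
    run on a padded bounding box around the boundary pixels; basins touching
    the box edge are treated like image-border basins and skipped, which is
    exact for fully enclosed regions.
    """
    boundary = score >= score_threshold
    if not boundary.any() or boundary.all():
        return []
    rr, cc = np.nonzero(boundary)
    pad = 4
    r0, r1 = max(int(rr.min()) - pad, 0), min(int(rr.max()) + pad + 1, score.shape[0])
    c0, c1 = max(int(cc.min()) - pad, 0), min(int(cc.max()) + pad + 1, score.shape[1])
    box = (slice(r0, r1), slice(c0, c1))
    s = score[box]
    b = boundary[box]
    # candidate regions are areas fully enclosed by the boundary band
    filled = ndimage.binary_fill_holes(b)
    comps, n_comp = ndimage.label(filled)
    border = np.zeros_like(b)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_ids = set(np.unique(comps[border]).tolist())
    regions = []
    objects = ndimage.find_objects(comps)
    for rid in range(1, n_comp + 1):
        if rid in border_ids:
            continue
        sl = objects[rid - 1]
        if sl is None:
            continue
        # work inside the component's own padded bounding box
        p = 3
        rsl = (
            slice(max(sl[0].start - p, 0), min(sl[0].stop + p, b.shape[0])),
            slice(max(sl[1].start - p, 0), min(sl[1].stop + p, b.shape[1])),
        )
        comp = comps[rsl] == rid
        if comp.sum() < 9:
            continue  # speckle, smaller than any resolvable wrap region
        interior = comp & ~b[rsl]
        if not interior.any():
            # small regions can be swallowed whole by the boundary band; the
            # pixel-level refinement in the shift step recovers the extent
            interior = ndimage.binary_erosion(comp)
            if not interior.any():
                interior = comp
        # one marker for the (possibly fragmented) interior, one for the
        # outside; the watershed splits the boundary band along its score
        # crest, which traces the wrap fringe
        markers = np.zeros(comp.shape, dtype=np.int32)
        markers[~comp] = 1
        markers[interior] = 2
        ws = watershed(s[rsl], markers=markers)
        mask = ws == 2
        ring = ndimage.binary_dilation(mask) ^ mask
        if ring.any() and float(s[rsl][ring].mean()) >= flood_threshold:
            full = np.zeros(b.shape, dtype=bool)
            full[rsl] = mask
            regions.append((box, full))
    return regions


def _region_views(field: np.ndarray, box: tuple[slice, slice], mask: np.ndarray):
    """Crop a 1-px-padded view of ``field`` around ``box`` with the region
    mask embedded at the right offset."""
    r0, r1 = box[0].start, box[0].stop
    c0, c1 = box[1].start, box[1].stop
    R0, R1 = max(r0 - 1, 0), min(r1 + 1, field.shape[0])
    C0, C1 = max(c0 - 1, 0), min(c1 + 1, field.shape[1])
    fv = field[R0:R1, C0:C1]
    mv = np.zeros(fv.shape, dtype=bool)
    mv[r0 - R0 : r0 - R0 + mask.shape[0], c0 - C0 : c0 - C0 + mask.shape[1]] = mask
    return fv, mv


def _boundary_steps(field: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Signed outward steps (outside - inside) across the region boundary."""
    steps = []
    for axis in (0, 1):
        d = np.diff(field, axis=axis)
        a = mask.take(range(0, mask.shape[axis] - 1), axis=axis)
        b = mask.take(range(1, mask.shape[axis]), axis=axis)
        crossing = a ^ b
        sign = np.where(a, 1.0, -1.0)  # orient as outside minus inside
        steps.append((sign * d)[crossing])
    return np.concatenate(steps) if steps else np.empty(0)


def _best_shift(
    field: np.ndarray, box: tuple[slice, slice], mask: np.ndarray, lam: float
) -> tuple[float, np.ndarray]:
    """Shift in {-lam, +lam} (or 0 for none) with a pixel-refined region mask.

    The watershed crest locates the candidate region only to within a pixel
    or two, so the decision is made against a local smooth reference: the
    box is re-wrapped and unwrapped, gauge-anchored on the pixels well away
    from the candidate region, and each pixel's integer wavelength offset is
    read off.  The majority offset over the candidate region gives the sign
    (0 means the region is already consistent and is left untouched); the
    refined mask is exactly the pixels sharing that offset, so the boundary
    discontinuity after the shift is minimal by construction.
    """
    # work on the region's own padded bounding box: the enclosing detection
    # box may span several cells and re-unwrapping it would be wasteful
    full_shape = mask.shape
    rr, cc = np.nonzero(mask)
    pad = 6
    r0 = max(int(rr.min()) - pad, 0)
    r1 = min(int(rr.max()) + pad + 1, full_shape[0])
    c0 = max(int(cc.min()) - pad, 0)
    c1 = min(int(cc.max()) + pad + 1, full_shape[1])
    inner = (slice(r0, r1), slice(c0, c1))
    sub_box = (
        slice(box[0].start + r0, box[0].start + r1),
        slice(box[1].start + c0, box[1].start + c1),
    )
    sub_mask = mask[inner]
    sub = field[sub_box]
    ref = _unwrap.min_discontinuity_unwrap(_unwrap.wrap(sub, lam), lam)
    near = ndimage.binary_dilation(sub_mask, iterations=3)
    outside = ~near
    if not outside.any():
        return 0.0, mask
    gauge = np.rint(np.median((sub - ref)[outside]) / lam)
    ref = ref + lam * gauge
    kmap = np.rint((sub - ref) / lam).astype(int)
    votes = kmap[sub_mask]
    vals, counts = np.unique(votes, return_counts=True)
    c = int(vals[np.argmax(counts)])
    frac = counts.max() / votes.size
    if c == 0 or frac < 0.6:
        return 0.0, mask
    c = max(min(c, 1), -1)  # single-wavelength corrections per pass
    refined_sub = (kmap == c) & near
    if not refined_sub.any():
        return 0.0, mask
    refined = np.zeros(full_shape, dtype=bool)
    refined[inner] = refined_sub
    return -c * lam, refined


def _boundary_discontinuity(unwrapped: np.ndarray, mask: np.ndarray, shift: float) -> float:
    """Summed |difference| across the region boundary after shifting by `shift`."""
    total = 0.0
    for axis in (0, 1):
        d = np.diff(unwrapped, axis=axis)
        a = mask.take(range(0, mask.shape[axis] - 1), axis=axis)  # earlier pixel inside?
        b = mask.take(range(1, mask.shape[axis]), axis=axis)  # later pixel inside?
        crossing = a ^ b
        # shifting the region by `shift` changes the step by shift * (b - a)
        d_shifted = d + shift * (b.astype(np.float64) - a.astype(np.float64))
        total += float(np.abs(d_shifted[crossing]).sum())
    return total


def correct_regions(
    unwrapped: np.ndarray,
    model: BoundaryModel,
    features: np.ndarray,
    n_iter: int = 1,
    median_size: int = 3,
) -> np.ndarray:
    """Shift detected mis-wrapped regions by one wavelength and median filter.

    Every pre-median output pixel differs from the input by exactly 0 or
    +-lambda.  The shift sign minimises the region's summed absolute boundary
    discontinuity; regions where no shift improves on the identity are left
    untouched.
    """
    if model.weights is None or not np.any(model.weights):
        raise ValueError("untrained model")
    lam = model.wavelength_um
    out = np.asarray(unwrapped, dtype=np.float64).copy()
    for _ in range(max(n_iter, 1)):
        score = model.score_map(features)
        shifted_any = False
        for box, mask in _detect_regions(score, model.score_threshold, model.flood_threshold):
            shift, refined = _best_shift(out, box, mask, lam)
            if shift != 0.0:
                out[box][refined] += shift
                shifted_any = True
        if not shifted_any:
            break
    if median_size and median_size > 1:
        out = ndimage.median_filter(out, size=median_size, mode="reflect")
    return out


def corrected_mask(unwrapped_in: np.ndarray, model: BoundaryModel, features: np.ndarray) -> np.ndarray:
    """Pixels the correction pass would shift (pre-median), as a bool mask."""
    pre = correct_regions(unwrapped_in, model, features, median_size=0)
    return np.abs(pre - unwrapped_in) > model.wavelength_um / 2


# ----------------------------------------------------------------------
# genetic refinement
# ----------------------------------------------------------------------


def _fitness(
    model: BoundaryModel,
    images: list[TrainingImage],
    score_maps: list[np.ndarray],
) -> float:
    """Pixel F1 of the corrected-region mask against the region labels."""
    tp = fp = fn = 0
    lam = model.wavelength_um
    for im, score in zip(images, score_maps):
        out = im.unwrapped.copy()
        for box, mask in _detect_regions(score, model.score_threshold, model.flood_threshold):
            shift, refined = _best_shift(out, box, mask, lam)
            if shift != 0.0:
                out[box][refined] += shift
        pred = np.abs(out - im.unwrapped) > lam / 2
        truth = im.region_labels
        tp += int((pred & truth).sum())
        fp += int((pred & ~truth).sum())
        fn += int((~pred & truth).sum())
    if tp == 0:
        return 0.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


def ga_fitness(model: BoundaryModel, train: TrainingSet, n_images: int | None = None) -> float:
    """Convenience wrapper: fitness of a model on (a prefix of) a training set."""
    images = train.images[: n_images or len(train.images)]
    maps = [model.score_map(extract_features(im.wrapped, im.intensity, train.wavelength_um)) for im in images]
    return _fitness(model, images, maps)


def ga_refine(
    model: BoundaryModel,
    train: TrainingSet,
    ga: GAConfig | None = None,
    seed: int = 0,
) -> BoundaryModel:
    """Real-coded GA over (score_threshold, flood_threshold).

    Tournament selection, Gaussian mutation (sigma = 10% of each parameter's
    search range), elitism.  The incumbent model is injected into the initial
    population, so the returned fitness is never below the input's.
    Deterministic for a given seed.
    """
    if not train.images:
        raise ValueError("empty training set")
    ga = ga or GAConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7003]))
    images = train.images[: ga.n_fitness_images]
    base = BoundaryModel(**{**model.__dict__})
    score_maps = [
        base.score_map(extract_features(im.wrapped, im.intensity, train.wavelength_um)) for im in images
    ]
    all_scores = np.concatenate([s.ravel() for s in score_maps])
    lo, hi = np.quantile(all_scores, [0.5, 0.9999])
    span = max(hi - lo, 1e-6)
    lo_b, hi_b = lo - 0.1 * span, hi + 0.5 * span

    def clamp(v: float) -> float:
        return float(min(max(v, lo_b), hi_b))

    def evaluate(genome: tuple[float, float]) -> float:
        m = BoundaryModel(**{**base.__dict__})
        m.score_threshold, m.flood_threshold = genome
        return _fitness(m, images, score_maps)

    pop = [(clamp(model.score_threshold), clamp(model.flood_threshold))]
    while len(pop) < ga.population:
        pop.append((float(rng.uniform(lo_b, hi_b)), float(rng.uniform(lo_b, hi_b))))
    fits = [evaluate(g) for g in pop]
    sigma = ga.mutation_sigma_frac * (hi_b - lo_b)
    for _ in range(ga.generations):
        order = np.argsort(fits)[::-1]
        new_pop = [pop[i] for i in order[: ga.elitism]]
        new_fits = [fits[i] for i in order[: ga.elitism]]
        while len(new_pop) < ga.population:
            # tournament selection of two parents, blend crossover, mutation
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, len(pop), size=ga.tournament)
                parents.append(pop[max(contenders, key=lambda i: fits[i])])
            alpha = rng.uniform()
            child = tuple(
                clamp(alpha * a + (1 - alpha) * b + rng.normal(0.0, sigma))
                for a, b in zip(parents[0], parents[1])
            )
            new_pop.append(child)
            new_fits.append(evaluate(child))
        pop, fits = new_pop, new_fits
    best_i = int(np.argmax(fits))
    incumbent = evaluate((clamp(model.score_threshold), clamp(model.flood_threshold)))
    refined = BoundaryModel(**{**base.__dict__})
    if fits[best_i] >= incumbent:
        refined.score_threshold, refined.flood_threshold = pop[best_i]
    else:  # pragma: no cover - elitism makes this unreachable
        refined.score_threshold, refined.flood_threshold = model.score_threshold, model.flood_threshold
    return refined
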