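"""Two-dimensional minimum-discontinuity phase unwrapping.

A single-wavelength interferometer measures optical path difference (OPD)
modulo the illumination wavelength lambda.  Unwrapping restores the
continuous field by adding an integer number of wavelengths per pixel.  The
estimator used here minimises the total residual discontinuity: it finds the
L1-minimal set of integer corrections to the wrapped pixel-difference field
that makes it curl-free, then integrates.  This is the same objective that
minimum-discontinuity (Flynn-style) unwrappers optimise with tree moves; the
solution returned here is a *global* optimum of the L1 relaxation, obtained
by detecting phase residues and routing them through a min-cost-flow linear
program (the constraint matrix is totally unimodular, so the LP optimum is
integral).  Residue-free fields -- the common case for well-sampled images --
take a vectorised fast path that integrates wrapped differences directly.

Conventions
-----------
* OPD is in micrometres; the wrapping period is ``wavelength_um``.
* The output is congruent to the input modulo lambda at every pixel,
  *exactly*: the result is computed as ``input + lambda * K`` with an
  integer correction map ``K``.
* The solution is anchored so the correction at pixel (0, 0) is zero, which
  makes the operator equivariant under global shifts by whole wavelengths.
  Zero-referencing against the image background is a separate, explicit step
  (:func:`zero_background`) used by the pipeline before mass integration.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, sparse

from .config import DEFAULT_WAVELENGTH_UM

__all__ = [
    "itoh_unwrap_1d",
    "min_discontinuity_unwrap",
    "unwrap_stack",
    "wrap",
    "wrapped_difference",
    "count_discontinuities",
    "zero_background",
]


def wrap(values: np.ndarray, wavelength_um: float = DEFAULT_WAVELENGTH_UM) -> np.ndarray:
    """Map values into the principal interval [0, lambda)."""
    return values - wavelength_um * np.floor(values / wavelength_um)


def wrapped_difference(d: np.ndarray, wavelength_um: float) -> np.ndarray:
    """Map differences into (-lambda/2, lambda/2]."""
    return d - wavelength_um * np.ceil(d / wavelength_um - 0.5)


def itoh_unwrap_1d(row: np.ndarray, wavelength_um: float = DEFAULT_WAVELENGTH_UM) -> np.ndarray:
    """Classical 1-D cumulative unwrapping (test oracle).

    Each step's wrapped difference, mapped into (-lambda/2, lambda/2], is
    integrated from the first sample.  Exact whenever the true step size
    stays below lambda/2.
    """
    row = np.asarray(row, dtype=np.float64)
    if row.ndim != 1:
        raise ValueError("itoh_unwrap_1d expects a 1-D sequence")
    if not np.all(np.isfinite(row)):
        raise ValueError("non-finite values")
    if row.size < 2:
        return row.copy()
    steps = wrapped_difference(np.diff(row), wavelength_um)
    out = np.empty_like(row)
    out[0] = row[0]
    out[1:] = row[0] + np.cumsum(steps)
    # snap to exact congruence with the input
    k = np.rint((out - row) / wavelength_um)
    return row + wavelength_um * k


def count_discontinuities(field: np.ndarray, wavelength_um: float) -> int:
    """Number of 4-connected pixel pairs whose difference exceeds lambda/2."""
    f = np.asarray(field, dtype=np.float64)
    n = int(np.count_nonzero(np.abs(np.diff(f, axis=0)) > wavelength_um / 2))
    n += int(np.count_nonzero(np.abs(np.diff(f, axis=1)) > wavelength_um / 2))
    return n


def _residues(dx: np.ndarray, dy: np.ndarray, lam: float) -> np.ndarray:
    """Integer curl of the wrapped difference field around each 2x2 loop.

    ``dx`` has shape (H, W-1) (differences along columns), ``dy`` has shape
    (H-1, W) (differences along rows).
    """
    curl = dx[:-1, :] + dy[:, 1:] - dx[1:, :] - dy[:, :-1]
    return np.rint(curl / lam).astype(np.int64)


def _solve_residues_lp(res: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """L1-minimal integer edge corrections cancelling the given residues.

    Returns (kx, ky) integer maps matching the shapes of the wrapped
    difference fields.  Solved as a min-cost-flow LP: each primal edge
    carries an unknown correction (split into positive and negative parts,
    cost 1 each); each interior 2x2 loop imposes a curl constraint.  Flow may
    terminate on the image boundary, whose loops are unconstrained.
    """
    hh, ww = res.shape  # (H-1, W-1) loops
    h, w = hh + 1, ww + 1
    n_kx = h * (w - 1)
    n_ky = (h - 1) * w

    def kx_idx(i: int | np.ndarray, j: int | np.ndarray):
        return i * (w - 1) + j

    def ky_idx(i: int | np.ndarray, j: int | np.ndarray):
        return n_kx + i * w + j

    rows, cols, vals = [], [], []
    ii, jj = np.nonzero(np.ones_like(res))
    loop = np.arange(res.size)
    # curl of corrections around loop (i, j):
    #   + kx[i, j] + ky[i, j+1] - kx[i+1, j] - ky[i, j] = -res[i, j]
    for idx, sign in (
        (kx_idx(ii, jj), 1.0),
        (ky_idx(ii, jj + 1), 1.0),
        (kx_idx(ii + 1, jj), -1.0),
        (ky_idx(ii, jj), -1.0),
    ):
        rows.append(loop)
        cols.append(idx)
        vals.append(np.full(res.size, sign))
    n_var = n_kx + n_ky
    a_eq = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(res.size, n_var),
    ).tocsc()
    # split variables into positive/negative parts, both with unit cost
    a_full = sparse.hstack([a_eq, -a_eq], format="csc")
    c = np.ones(2 * n_var)
    b = -res.ravel().astype(np.float64)
    result = optimize.linprog(c, A_eq=a_full, b_eq=b, bounds=(0, None), method="highs")
    if not result.success:  # pragma: no cover - LP on a feasible flow problem
        raise RuntimeError(f"residue flow LP failed: {result.message}")
    k = np.rint(result.x[:n_var] - result.x[n_var:]).astype(np.int64)
    kx = k[:n_kx].reshape(h, w - 1)
    ky = k[n_kx:].reshape(h - 1, w)
    return kx, ky


def _integrate(psi: np.ndarray, dx: np.ndarray, dy: np.ndarray, lam: float) -> np.ndarray:
    """Integrate a curl-free difference field, anchored at pixel (0, 0)."""
    out = np.empty_like(psi)
    out[0, 0] = psi[0, 0]
    out[1:, 0] = psi[0, 0] + np.cumsum(dy[:, 0])
    out[:, 1:] = out[:, :1] + np.cumsum(dx, axis=1)
    k = np.rint((out - psi) / lam)
    return psi + lam * k


def min_discontinuity_unwrap(
    wrapped: np.ndarray, wavelength_um: float = DEFAULT_WAVELENGTH_UM
) -> np.ndarray:
    """Unwrap a 2-D wrapped OPD image by minimum total discontinuity.

    The output differs from the input by an integer multiple of lambda at
    every pixel (exactly), with the correction at pixel (0, 0) fixed to zero.
    """
    psi = np.asarray(wrapped, dtype=np.float64)
    if psi.ndim != 2 or min(psi.shape) < 2:
        raise ValueError("expected a 2-D image of at least 2x2 pixels")
    if not np.all(np.isfinite(psi)):
        raise ValueError("non-finite pixels")
    lam = float(wavelength_um)
    dx = wrapped_difference(np.diff(psi, axis=1), lam)
    dy = wrapped_difference(np.diff(psi, axis=0), lam)
    res = _residues(dx, dy, lam)
    if np.any(res):
        kx, ky = _solve_residues_lp(res)
        dx = dx + lam * kx
        dy = dy + lam * ky
    return _integrate(psi, dx, dy, lam)


# kept as an alias: the minimum-discontinuity objective is the one named
# after Flynn in the phase-unwrapping literature
flynn_unwrap = min_discontinuity_unwrap


def unwrap_stack(stack: np.ndarray, wavelength_um: float = DEFAULT_WAVELENGTH_UM) -> np.ndarray:
    """Unwrap every frame of a (T, H, W) stack independently."""
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("expected a (T, H, W) stack")
    return np.stack([min_discontinuity_unwrap(f, wavelength_um) for f in stack])


def zero_background(field: np.ndarray, background_mask: np.ndarray) -> np.ndarray:
    """Shift a field so the median of the background pixels is zero."""
    if not np.any(background_mask):
        raise ValueError("background mask is empty")
    return field - np.median(field[background_mask])
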