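"""Shared periodic-grid primitives: deposition, interpolation, segment weighting.

Grids tile the orthorhombic box exactly: an axis of length L sampled with
``n`` voxels has spacing L/n and voxel centers at origin + (i + 1/2) * spacing,
0-based indexing, periodic wrap everywhere.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError


def grid_shape_for(box: np.ndarray, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Voxel counts and the exact per-axis spacing that tiles the box.

    The requested spacing is rounded to the nearest divisor of each box
    length so voxels tile exactly (required for volume conservation).
    """
    box = np.asarray(box, dtype=float)
    if spacing <= 0:
        raise InvalidParameterError("grid spacing must be > 0")
    if np.any(spacing > box):
        raise InvalidParameterError("grid spacing larger than the box")
    shape = np.maximum(1, np.round(box / spacing).astype(int))
    return shape, box / shape


def cic_deposit(
    points: np.ndarray,
    values: np.ndarray,
    shape: np.ndarray,
    spacing: np.ndarray,
    origin: np.ndarray | None = None,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Cloud-in-cell (trilinear) deposition of per-point values onto a periodic grid.

    ``values`` has shape (n,) or (n, c); the result has shape ``(*shape,)`` or
    ``(*shape, c)``. Weights sum to 1 per point, so sums over the grid conserve
    the deposited quantity exactly.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = np.asarray(values, dtype=float)
    scalar = values.ndim == 1
    vals = values[:, None] if scalar else values
    shape = np.asarray(shape, dtype=int)
    nc = vals.shape[1]
    if out is None:
        out = np.zeros((*shape, nc))
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)

    u = (points - origin) / spacing - 0.5
    i0 = np.floor(u).astype(int)
    frac = u - i0
    flat = out.reshape(-1, nc)
    for corner in range(8):
        bits = np.array([(corner >> a) & 1 for a in range(3)])
        idx = np.mod(i0 + bits, shape)
        w = np.prod(np.where(bits, frac, 1.0 - frac), axis=1)
        lin = (idx[:, 0] * shape[1] + idx[:, 1]) * shape[2] + idx[:, 2]
        np.add.at(flat, lin, w[:, None] * vals)
    return out


def trilinear_interpolate(
    field: np.ndarray,
    points: np.ndarray,
    spacing: np.ndarray,
    origin: np.ndarray | None = None,
    gradient: bool = False,
):
    """Trilinear interpolation of a periodic voxel-center field at arbitrary points.

    ``field`` has shape (nx, ny, nz) or (nx, ny, nz, c). Returns the
    interpolated values (n,) / (n, c); with ``gradient=True`` also returns the
    analytic gradient of the trilinear interpolant, shape (n, 3) / (n, c, 3).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    scalar = field.ndim == 3
    f = field[..., None] if scalar else field
    shape = np.asarray(f.shape[:3])
    nc = f.shape[3]
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)

    u = (points - origin) / spacing - 0.5
    i0 = np.floor(u).astype(int)
    frac = u - i0

    vals = np.zeros((len(points), nc))
    grads = np.zeros((len(points), nc, 3)) if gradient else None
    for corner in range(8):
        bits = np.array([(corner >> a) & 1 for a in range(3)])
        idx = np.mod(i0 + bits, shape)
        fv = f[idx[:, 0], idx[:, 1], idx[:, 2]]
        w_ax = np.where(bits, frac, 1.0 - frac)  # (n, 3)
        w = np.prod(w_ax, axis=1)
        vals += w[:, None] * fv
        if gradient:
            sign = np.where(bits, 1.0, -1.0)
            for a in range(3):
                others = [b for b in range(3) if b != a]
                wg = sign[a] / spacing[a] * w_ax[:, others[0]] * w_ax[:, others[1]]
                grads[:, :, a] += wg[:, None] * fv
    if scalar:
        vals = vals[:, 0]
        if gradient:
            grads = grads[:, 0, :]
    return (vals, grads) if gradient else vals


def segment_voxel_weights(
    start: np.ndarray,
    direction: np.ndarray,
    shape: np.ndarray,
    spacing: np.ndarray,
) -> list[tuple[tuple[int, int, int], float]]:
    """Split the segment start -> start + direction across voxel boundaries.

    Returns ``(voxel index, length fraction)`` pairs; fractions sum to 1
    exactly (up to float rounding), which underwrites the stress-conservation
    invariant. Voxel indices are wrapped periodically, so the segment may
    legitimately leave the primary box (minimum-image partner positions do).
    """
    start = np.asarray(start, dtype=float)
    direction = np.asarray(direction, dtype=float)
    shape = np.asarray(shape, dtype=int)
    ts = [0.0, 1.0]
    for a in range(3):
        if direction[a] == 0.0:
            continue
        k0 = start[a] / spacing[a]
        k1 = (start[a] + direction[a]) / spacing[a]
        lo, hi = sorted((k0, k1))
        for k in range(int(np.floor(lo)) + 1, int(np.ceil(hi))):
            t = (k * spacing[a] - start[a]) / direction[a]
            if 0.0 < t < 1.0:
                ts.append(t)
    ts = sorted(set(ts))
    pieces = []
    for t0, t1 in zip(ts[:-1], ts[1:]):
        mid = start + 0.5 * (t0 + t1) * direction
        idx = tuple(int(np.floor(mid[a] / spacing[a])) % shape[a] for a in range(3))
        pieces.append((idx, t1 - t0))
    return pieces
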