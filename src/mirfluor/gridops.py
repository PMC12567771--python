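"""Grid resampling primitives shared by the forward models and preprocessing.

All routines use the same spatial convention: a field of shape ``(ny, nx)``
with pixel pitch ``p`` (µm) covers an extent of ``ny*p`` by ``nx*p`` µm, with
pixel (i, j) centred at ``(i*p, j*p)`` relative to the scan origin.  Raster
combs likewise place sample j at ``origin + j*step``, so a 20 µm comb is an
exact 4x decimation of a 5 µm comb over the same field.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "area_downsample",
    "spot_average",
    "raster_sample",
    "raster_positions",
    "resample_labels_nearest",
]


def area_downsample(field: np.ndarray, pitch_in: float, pitch_out: float) -> np.ndarray:
    """Exact area-weighted box average onto a coarser square-pixel grid.

    Works for non-integer pitch ratios: the cumulative-sum (integral) image of
    a piecewise-constant field is exactly piecewise bilinear, so sampling it
    with bilinear interpolation at fractional box corners yields the exact
    integral over each output pixel footprint.
    """
    field = np.asarray(field, dtype=float)
    if pitch_out < pitch_in:
        raise ValueError("area_downsample only coarsens; use resize for upscaling")
    r = pitch_out / pitch_in
    ny, nx = field.shape
    n_out_y = int(np.floor(ny / r))
    n_out_x = int(np.floor(nx / r))
    if min(n_out_y, n_out_x) < 1:
        raise ValueError("output pitch larger than the field extent")
    integral = np.zeros((ny + 1, nx + 1))
    integral[1:, 1:] = np.cumsum(np.cumsum(field, axis=0), axis=1)
    ey = np.arange(n_out_y + 1) * r
    ex = np.arange(n_out_x + 1) * r
    gy, gx = np.meshgrid(ey, ex, indexing="ij")
    corners = ndimage.map_coordinates(
        integral, [gy.ravel(), gx.ravel()], order=1, mode="nearest"
    ).reshape(gy.shape)
    box = corners[1:, 1:] - corners[:-1, 1:] - corners[1:, :-1] + corners[:-1, :-1]
    return box / (r * r)


def spot_average(field: np.ndarray, pitch: float, sigma_um: float, mode: str = "nearest") -> np.ndarray:
    """Gaussian-weighted local average with standard deviation ``sigma_um``."""
    field = np.asarray(field, dtype=float)
    if sigma_um <= 0:
        return field.copy()
    return ndimage.gaussian_filter(field, sigma=sigma_um / pitch, mode=mode)


def raster_positions(n: int, pitch: float, step: float, origin: float = 0.0) -> np.ndarray:
    """Sample positions (in input pixel-index units) of a raster comb."""
    extent = n * pitch
    m = int(np.floor((extent - origin) / step))
    if m < 1:
        raise ValueError("raster step larger than the field extent")
    return (origin + np.arange(m) * step) / pitch


def raster_sample(
    field: np.ndarray, pitch: float, step: float, origin: float = 0.0
) -> np.ndarray:
    """Sample a field on a square raster comb (bilinear sub-pixel sampling)."""
    field = np.asarray(field, dtype=float)
    ys = raster_positions(field.shape[0], pitch, step, origin)
    xs = raster_positions(field.shape[1], pitch, step, origin)
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    return ndimage.map_coordinates(
        field, [gy.ravel(), gx.ravel()], order=1, mode="nearest"
    ).reshape(gy.shape)


def resample_labels_nearest(labels: np.ndarray, pitch_in: float, pitch_out: float) -> np.ndarray:
    """Nearest-neighbour resampling of an integer label image (never interpolates)."""
    labels = np.asarray(labels)
    shape_out = tuple(
        max(1, int(round(n * pitch_in / pitch_out))) for n in labels.shape
    )
    coords = []
    for n_out, n_in in zip(shape_out, labels.shape):
        c = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
        coords.append(np.clip(np.rint(c).astype(int), 0, n_in - 1))
    return labels[np.ix_(coords[0], coords[1])]
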