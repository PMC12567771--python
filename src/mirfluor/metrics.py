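"""Quantitative evaluation: contingency tables, adjusted Rand index,
Davies-Bouldin index, cross-resolution segmentation comparison and
line-grating contrast/resolution analysis.

The ARI is computed from the pair-counting contingency formula

    ARI = (Σ_ij C(n_ij,2) − E) / (½[Σ_i C(a_i,2) + Σ_j C(b_j,2)] − E),
    E   = Σ_i C(a_i,2) · Σ_j C(b_j,2) / C(n,2),

which is chance-corrected and invariant to label permutations — the reason it
is preferred over Dice or NMI for comparing segmentations that were resampled
and cropped across resolutions.

Grating analysis measures the modulation of a scanned binary bar target as
twice the Fourier-coefficient magnitude at the grating frequency divided by
the profile mean (phase-insensitive), normalized by the 4/π square-wave
fundamental factor so an ideal system scores 1.  Frequencies at or above the
raster comb's Nyquist limit are reported as contrast 0 with an aliasing flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gridops import raster_sample, resample_labels_nearest, spot_average
from .mir import RasterGrid, SpotProfile
from .phantom import GratingSpec, generate_grating_field
from .segment import SegmentationMap

#: 18-step frequency ladder (lp/mm) spanning the resolution target's
#: 1.25-250 lines/mm range.
DEFAULT_LADDER = (
    1.25, 2.5, 5.0, 10.0, 12.5, 16.0, 20.0, 25.0, 31.5,
    40.0, 50.0, 63.0, 80.0, 100.0, 125.0, 160.0, 200.0, 250.0,
)

__all__ = [
    "DEFAULT_LADDER",
    "ContingencyTable",
    "ContrastCurve",
    "SegmentationComparison",
    "contingency_table",
    "adjusted_rand_index",
    "davies_bouldin",
    "compare_segmentations",
    "contrast_curve",
    "resolution_limit",
]


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray  # (r, c) non-negative integers
    row_marginals: np.ndarray
    col_marginals: np.ndarray
    n: int


@dataclass(frozen=True)
class ContrastCurve:
    """Modulation contrast versus spatial frequency; ``aliased`` flags
    frequencies at or beyond the sampling Nyquist limit."""

    frequencies: tuple[float, ...]
    contrasts: tuple[float, ...]
    aliased: tuple[bool, ...]

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies)
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")


@dataclass(frozen=True)
class SegmentationComparison:
    ari: float
    pitch_a: float
    pitch_b: float
    shift: tuple[float, float]
    crop_shape: tuple[int, int]


def contingency_table(a: np.ndarray, b: np.ndarray) -> ContingencyTable:
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError("label fields must share a shape")
    _, a_inv = np.unique(a, return_inverse=True)
    _, b_inv = np.unique(b, return_inverse=True)
    counts = np.zeros((a_inv.max() + 1, b_inv.max() + 1), dtype=np.int64)
    np.add.at(counts, (a_inv, b_inv), 1)
    return ContingencyTable(
        counts=counts,
        row_marginals=counts.sum(axis=1),
        col_marginals=counts.sum(axis=0),
        n=int(counts.sum()),
    )


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x * (x - 1.0) / 2.0


def adjusted_rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected pair-counting agreement of two labelings, in [−1, 1]."""
    t = contingency_table(a, b)
    if t.n < 2:
        raise ValueError("need at least two items")
    sum_ij = _comb2(t.counts).sum()
    sum_a = _comb2(t.row_marginals).sum()
    sum_b = _comb2(t.col_marginals).sum()
    expected = sum_a * sum_b / _comb2(np.array(t.n))
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial: identical by convention
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def davies_bouldin(points: np.ndarray, labels: np.ndarray) -> float:
    """DBI = (1/k) Σ_i max_{j≠i} (S_i + S_j) / M_ij with S the mean Euclidean
    distance to the centroid and M the centroid separation.  Lower is better;
    invariant to global translation, rotation and scaling."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels).ravel()
    if points.ndim == 1:
        points = points[:, None]
    ids = np.unique(labels)
    k = len(ids)
    if k < 2:
        raise ValueError("need at least two clusters")
    centroids = np.stack([points[labels == i].mean(axis=0) for i in ids])
    spreads = np.array(
        [np.linalg.norm(points[labels == i] - centroids[j], axis=1).mean()
         for j, i in enumerate(ids)]
    )
    sep = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    if np.any(sep[~np.eye(k, dtype=bool)] == 0):
        raise ValueError("coincident centroids: DBI undefined")
    ratio = (spreads[:, None] + spreads[None, :]) / np.where(sep == 0, np.inf, sep)
    np.fill_diagonal(ratio, -np.inf)
    return float(ratio.max(axis=1).mean())


def compare_segmentations(
    seg_a: SegmentationMap, seg_b: SegmentationMap, register: bool = True
) -> SegmentationComparison:
    """ARI between segmentations at possibly mismatched resolutions.

    The coarser map is resampled to the finer pitch with nearest-neighbour
    interpolation (labels are never interpolated), translation-registered,
    cropped to the common field of view and compared with the ARI.

    Registration needs comparable label values, so the second map is first
    harmonized to the first (maximum-overlap assignment) on the unshifted
    crop; phase correlation then runs on the harmonized label images.  The
    ARI itself is permutation-invariant, so harmonization only affects the
    registration, never the score.
    """
    a, pa = seg_a.labels, seg_a.pitch
    b, pb = seg_b.labels, seg_b.pitch
    fine = min(pa, pb)
    if pa > fine:
        a = resample_labels_nearest(a, pa, fine)
    if pb > fine:
        b = resample_labels_nearest(b, pb, fine)
    dy = dx = 0
    if register:
        from .preprocess import Image2D, register_translation
        from .segment import SegmentationMap as _Seg, harmonize_labels

        ny, nx = min(a.shape[0], b.shape[0]), min(a.shape[1], b.shape[1])
        fa = a[:ny, :nx].astype(float)
        fb = harmonize_labels(
            _Seg(a[:ny, :nx], fine), _Seg(b[:ny, :nx], fine)
        ).labels.astype(float)
        if fa.std() > 0 and fb.std() > 0:
            sh = register_translation(Image2D(fb, fine, "b"), Image2D(fa, fine, "a"))
            dy, dx = int(round(sh.dy)), int(round(sh.dx))
            if max(abs(dy), abs(dx)) > min(ny, nx) // 4:  # implausible offset
                dy = dx = 0
    # positive (dy, dx): b's content sits shifted by that amount relative to a
    ay0, by0 = max(dy, 0), max(-dy, 0)
    ax0, bx0 = max(dx, 0), max(-dx, 0)
    ny = min(a.shape[0] - ay0, b.shape[0] - by0)
    nx = min(a.shape[1] - ax0, b.shape[1] - bx0)
    if ny < 1 or nx < 1:
        raise ValueError("empty intersection")
    a_c = a[ay0 : ay0 + ny, ax0 : ax0 + nx]
    b_c = b[by0 : by0 + ny, bx0 : bx0 + nx]
    return SegmentationComparison(
        ari=adjusted_rand_index(a_c, b_c),
        pitch_a=pa,
        pitch_b=pb,
        shift=(float(dy), float(dx)),
        crop_shape=(ny, nx),
    )


def _grating_modulation(
    frequency: float,
    spot: SpotProfile,
    grid: RasterGrid,
    field_pitch: float,
) -> float:
    """Scan one noiseless binary grating and fit the fundamental.

    The profile is projected onto [1, cos(2πfx), sin(2πfx)] by least squares
    (a phase-insensitive discrete Fourier coefficient at the exact grating
    frequency, robust to sampling not being commensurate with the period).
    """
    period = 1000.0 / frequency
    n_periods = max(8, int(np.ceil(240.0 / period)))
    extent_x = n_periods * period
    extent_y = max(16 * field_pitch, 4 * grid.step)
    spec = GratingSpec(frequency=frequency, duty=0.5, extent=(extent_y, extent_x))
    target = generate_grating_field(spec, field_pitch)
    blurred = spot_average(target, field_pitch, spot.sigma, mode="wrap")
    profile = raster_sample(blurred, field_pitch, grid.step).mean(axis=0)
    x_um = np.arange(profile.size) * grid.step
    design = np.column_stack(
        [
            np.ones_like(x_um),
            np.cos(2 * np.pi * x_um / period),
            np.sin(2 * np.pi * x_um / period),
        ]
    )
    coef, *_ = np.linalg.lstsq(design, profile, rcond=None)
    mean = coef[0]
    amplitude = float(np.hypot(coef[1], coef[2]))
    if mean <= 0:
        return 0.0
    # |c_f| = amplitude/2; modulation = 2|c_f|/mean, normalized by the 4/π
    # square-wave fundamental so an ideal system reports 1
    return float(np.clip((np.pi / 4.0) * amplitude / mean, 0.0, 1.0))


def contrast_curve(
    spot: SpotProfile,
    grid: RasterGrid,
    ladder: tuple[float, ...] = DEFAULT_LADDER,
    field_pitch: float = 1.0,
) -> ContrastCurve:
    """Modulation contrast of noiseless scanned gratings over a frequency
    ladder.  Frequencies at or above the raster Nyquist (1000/(2·step) lp/mm)
    are unrecoverable and reported as 0 with the aliasing flag set."""
    if any(f <= 0 or f > 250.0 for f in ladder):
        raise ValueError("ladder frequencies must lie in (0, 250] lp/mm")
    nyquist = 1000.0 / (2.0 * grid.step)
    contrasts, aliased = [], []
    for f in ladder:
        if f >= nyquist:
            contrasts.append(0.0)
            aliased.append(True)
        else:
            contrasts.append(_grating_modulation(f, spot, grid, field_pitch))
            aliased.append(False)
    return ContrastCurve(
        frequencies=tuple(ladder),
        contrasts=tuple(contrasts),
        aliased=tuple(aliased),
    )


def resolution_limit(curve: ContrastCurve, threshold: float = 0.2) -> float:
    """Highest ladder frequency with modulation contrast ≥ threshold (0 if none)."""
    best = 0.0
    for f, c, al in zip(curve.frequencies, curve.contrasts, curve.aliased):
        if not al and c >= threshold:
            best = max(best, f)
    return best
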