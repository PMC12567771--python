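"""Raw-data chain: count normalization, absorbance conversion against the
gold reference, dual-reference scattering correction, bicubic upscaling to the
fusion grid, translation registration and datacube assembly.

The scattering correction exploits the two reference lasers: since the
forward model's baseline is linear in wavenumber, the per-pixel linear
interpolation between the 2792 cm⁻¹ and 3704 cm⁻¹ absorbances reproduces the
baseline at the target wavenumbers exactly in the noiseless limit, so the
corrected target layers are pure chemical absorbance.  Under noise the
corrected layers may contain small negatives; they are retained (clipping
would bias cluster means).

Before clustering, every layer of an assembled cube is z-scored so that
mixed-unit modalities (MIR absorbance vs AF counts) contribute comparably to
the Euclidean K-means metric.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import resize as _sk_resize

from .mir import FULL_SCALE, BandSet

EPS_FLOOR = 1.0 / FULL_SCALE  # one count

__all__ = [
    "Image2D",
    "DataCube",
    "RegistrationShift",
    "normalize_counts",
    "to_absorbance",
    "scatter_correct",
    "resize_bicubic",
    "register_translation",
    "assemble_cube",
]


@dataclass(frozen=True)
class Image2D:
    values: np.ndarray
    pitch: float
    channel: str
    source: str = ""  # provenance tag: "mir" | "af" | "ftir" | ...

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise ValueError("pitch must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")


@dataclass
class DataCube:
    """Ordered stack of co-registered layers on one common grid."""

    layers: list[Image2D]
    pitch: float

    def __post_init__(self) -> None:
        shapes = {l.values.shape for l in self.layers}
        if len(shapes) > 1:
            raise ValueError("cube layers must share one shape")
        names = [l.channel for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")

    @property
    def names(self) -> list[str]:
        return [l.channel for l in self.layers]

    def get(self, channel: str) -> Image2D:
        for l in self.layers:
            if l.channel == channel:
                return l
        raise KeyError(channel)

    def stack(self) -> np.ndarray:
        """(n_pixels, n_layers) feature matrix for clustering."""
        return np.stack([l.values.ravel() for l in self.layers], axis=1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers[0].values.shape


@dataclass(frozen=True)
class RegistrationShift:
    dy: float
    dx: float
    score: float


def normalize_counts(image: np.ndarray, channel: str = "", pitch: float = 1.0) -> Image2D:
    """Map detector counts [0, 65535] linearly onto [0, 1]."""
    image = np.asarray(image, dtype=float)
    if np.any(image < 0) or np.any(image > FULL_SCALE):
        raise ValueError("counts outside [0, 65535]")
    return Image2D(values=image / FULL_SCALE, pitch=pitch, channel=channel)


def to_absorbance(image: Image2D, i_ref: float) -> Image2D:
    """Decadic absorbance against the normalized gold-reference level:
    A = −log10(max(value, ε_floor) / i_ref)."""
    if i_ref <= 0:
        raise ValueError("i_ref must be > 0")
    a = -np.log10(np.maximum(image.values, EPS_FLOOR) / i_ref)
    return replace(image, values=a)


def scatter_correct(cube: DataCube, bands: BandSet) -> DataCube:
    """Remove the scattering baseline from the target layers.

    Per target laser t: A_corr(t) = A(t) − B̂(ν_t), with B̂ the per-pixel linear
    interpolation in wavenumber between the two reference-laser absorbances.
    Exact whenever the true baseline is linear in wavenumber and noise-free.
    """
    refs = [b for b in bands if b.role == "reference"]
    targets = [b for b in bands if b.role == "target"]
    if len(refs) != 2:
        raise ValueError("need exactly two reference layers")
    lo, hi = sorted(refs, key=lambda b: b.wavenumber)
    try:
        a_lo = cube.get(lo.id).values
        a_hi = cube.get(hi.id).values
    except KeyError as e:
        raise ValueError(f"missing reference layer {e}") from e
    corrected: list[Image2D] = []
    for t in targets:
        if t.id not in cube.names:
            continue
        layer = cube.get(t.id)
        w = (t.wavenumber - lo.wavenumber) / (hi.wavenumber - lo.wavenumber)
        baseline = (1.0 - w) * a_lo + w * a_hi
        corrected.append(replace(layer, values=layer.values - baseline))
    if not corrected:
        raise ValueError("no target layers present in the cube")
    return DataCube(layers=corrected, pitch=cube.pitch)


def resize_bicubic(image: Image2D, target_pitch: float) -> Image2D:
    """Cubic interpolation onto a new pitch; output size rounds toward
    coverage (ceil), preserving the global mean within ~1% for smooth fields."""
    if target_pitch <= 0:
        raise ValueError("target_pitch must be > 0")
    if target_pitch == image.pitch:
        return image
    factor = image.pitch / target_pitch
    shape_out = tuple(int(np.ceil(n * factor)) for n in image.values.shape)
    out = _sk_resize(
        image.values, shape_out, order=3, mode="edge",
        anti_aliasing=factor < 1.0, preserve_range=True,
    )
    return replace(image, values=out, pitch=target_pitch)


def register_translation(moving: Image2D, fixed: Image2D) -> RegistrationShift:
    """Translation offset of ``moving`` relative to ``fixed`` via phase
    correlation with sub-pixel peak refinement (0.05 px grid).

    The returned (dy, dx) satisfies moving ≈ fixed shifted by (dy, dx), so a
    circularly shifted copy reports the shift that was applied to it.
    """
    if moving.pitch != fixed.pitch:
        raise ValueError("images must share a pixel pitch")
    if float(np.std(moving.values)) == 0.0 or float(np.std(fixed.values)) == 0.0:
        raise ValueError("degenerate (constant) image: registration undefined")
    shift, error, _ = phase_cross_correlation(
        fixed.values, moving.values, upsample_factor=20, normalization=None
    )
    # skimage returns the shift that maps moving onto fixed; our convention is
    # the displacement of moving's content relative to fixed.
    dy, dx = (-float(shift[0]), -float(shift[1]))
    return RegistrationShift(dy=dy, dx=dx, score=1.0 - float(error))


def _apply_shift(values: np.ndarray, shift: RegistrationShift) -> np.ndarray:
    # shifts below the 0.1 px refinement precision are indistinguishable from zero
    if abs(shift.dy) <= 0.1 and abs(shift.dx) <= 0.1:
        return values
    return ndimage.shift(values, (shift.dy, shift.dx), order=1, mode="nearest")


def _gradient_magnitude(values: np.ndarray) -> np.ndarray:
    gy, gx = np.gradient(values)
    return np.hypot(gy, gx)


def _zscore(values: np.ndarray) -> np.ndarray:
    mu = values.mean()
    sd = values.std()
    if sd == 0:
        raise ValueError("constant layer cannot be z-scored")
    return (values - mu) / sd


def assemble_cube(
    layers: Sequence[Image2D],
    target_pitch: float = 4.0,
    register: bool = True,
    zscore: bool = True,
) -> DataCube:
    """Fuse layers onto one grid: resize to ``target_pitch``, register every
    layer to the reference (the first AF layer if any, else the first layer),
    crop to the common overlap and z-score per layer."""
    if not layers:
        raise ValueError("no layers to assemble")
    resized = [resize_bicubic(l, target_pitch) for l in layers]
    ref_idx = next((i for i, l in enumerate(resized) if l.source == "af"), 0)
    ref = resized[ref_idx]
    if register and len(resized) > 1:
        # cross-modality layers can have opposite contrast, so alignment uses
        # gradient magnitudes (edges co-locate across modalities regardless of
        # the sign of the contrast)
        aligned: list[Image2D] = []
        max_shift = 0.1 * min(ref.values.shape)
        for i, l in enumerate(resized):
            if i == ref_idx:
                aligned.append(l)
                continue
            ny = min(l.values.shape[0], ref.values.shape[0])
            nx = min(l.values.shape[1], ref.values.shape[1])
            try:
                sh = register_translation(
                    replace(l, values=_gradient_magnitude(l.values[:ny, :nx])),
                    replace(ref, values=_gradient_magnitude(ref.values[:ny, :nx])),
                )
            except ValueError:
                sh = RegistrationShift(0.0, 0.0, 0.0)
            if max(abs(sh.dy), abs(sh.dx)) > max_shift:  # implausible: keep unshifted
                sh = RegistrationShift(0.0, 0.0, 0.0)
            undo = RegistrationShift(-sh.dy, -sh.dx, sh.score)
            aligned.append(replace(l, values=_apply_shift(l.values, undo)))
        resized = aligned
    ny = min(l.values.shape[0] for l in resized)
    nx = min(l.values.shape[1] for l in resized)
    if ny < 2 or nx < 2:
        raise ValueError("empty overlap after registration")
    cropped = [replace(l, values=l.values[:ny, :nx]) for l in resized]
    if zscore:
        cropped = [replace(l, values=_zscore(l.values)) for l in cropped]
    return DataCube(layers=list(cropped), pitch=target_pitch)
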