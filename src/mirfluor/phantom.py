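"""Synthetic brain-tissue phantoms and line-grating resolution targets.

The phantom is the stated world of every downstream experiment: a 2-D label
map on a fine ground-truth grid (default 2 µm pitch) with one class per pixel
(background, ventricle, gray matter, white matter, fine structure), plus
per-species chemical concentration fields (lipid, protein, water), per-
fluorophore concentration fields (collagen/elastin, flavin, lipopigment) and a
smooth scattering baseline.  Class compositions emulate the contrasts expected
of brain compartments: white matter is lipid-rich (compact myelin) with strong
flavin and collagen/elastin autofluorescence, gray matter is protein-rich with
stronger lipopigment (lipofuscin-like) autofluorescence, the ventricle is a
dilute, water-rich compartment, and fine structure is an extremely protein-rich
reticular network of 5-20 µm elements embedded in gray matter.

Absolute concentrations are arbitrary units chosen for class separability, not
biological calibration; no published quantitative reference exists for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

SPECIES = ("lipid", "protein", "water")
FLUOROPHORES = ("collagen_elastin", "flavin", "lipopigment")

CLASS_NAMES = ("background", "ventricle", "gray_matter", "white_matter", "fine_structure")
BACKGROUND, VENTRICLE, GRAY_MATTER, WHITE_MATTER, FINE_STRUCTURE = range(5)

__all__ = [
    "SPECIES",
    "FLUOROPHORES",
    "CLASS_NAMES",
    "TissueClassSpec",
    "PhantomConfig",
    "Phantom",
    "GratingSpec",
    "default_class_table",
    "generate_brain_phantom",
    "generate_grating_field",
]


@dataclass(frozen=True)
class TissueClassSpec:
    """Compositional prior of one tissue class.

    ``chem_mean``/``fluor_mean`` are per-species mean concentrations in
    arbitrary units; ``chem_cv``/``fluor_cv`` the coefficient of variation of
    the within-class log-normal texture; ``scatter_mean`` the unitless
    baseline level of the scattering field inside the class.
    """

    class_id: int
    name: str
    chem_mean: Mapping[str, float]
    chem_cv: Mapping[str, float]
    fluor_mean: Mapping[str, float]
    fluor_cv: Mapping[str, float]
    scatter_mean: float

    def __post_init__(self) -> None:
        for m in (self.chem_mean, self.fluor_mean):
            for k, v in m.items():
                if v < 0:
                    raise ValueError(f"negative concentration for {k!r}")
        for m in (self.chem_cv, self.fluor_cv):
            for k, v in m.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"cv for {k!r} outside [0, 1]")
        if self.scatter_mean < 0:
            raise ValueError("scatter_mean must be >= 0")

    def mean_vector(self) -> np.ndarray:
        """Class mean in the joint (chem ∪ fluor) feature space."""
        return np.array(
            [self.chem_mean.get(s, 0.0) for s in SPECIES]
            + [self.fluor_mean.get(f, 0.0) for f in FLUOROPHORES]
        )

    def sd_vector(self) -> np.ndarray:
        return np.array(
            [self.chem_cv.get(s, 0.0) * self.chem_mean.get(s, 0.0) for s in SPECIES]
            + [self.fluor_cv.get(f, 0.0) * self.fluor_mean.get(f, 0.0) for f in FLUOROPHORES]
        )


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and sampling of the ground-truth grid.

    grid_pitch : µm per ground-truth pixel.  Must not exceed half the minimum
        structure width so the truth itself is never aliased.
    section_thickness : tissue section thickness l (µm) entering Beer-Lambert.
    """

    grid_pitch: float = 2.0
    width: int = 512
    height: int = 512
    seed: int = 0
    min_structure_width: float = 5.0
    max_structure_width: float = 100.0
    section_thickness: float = 10.0

    def __post_init__(self) -> None:
        if self.grid_pitch <= 0 or self.width < 8 or self.height < 8:
            raise ValueError("invalid phantom grid")
        if self.grid_pitch > self.min_structure_width / 2:
            raise ValueError(
                "grid too coarse for requested min_structure_width "
                f"(pitch {self.grid_pitch} > {self.min_structure_width / 2})"
            )
        if self.min_structure_width > self.max_structure_width:
            raise ValueError("min_structure_width > max_structure_width")


@dataclass
class Phantom:
    """Ground-truth label map plus concentration and scattering fields."""

    labels: np.ndarray
    chem: dict[str, np.ndarray]
    fluor: dict[str, np.ndarray]
    scatter: np.ndarray
    pitch: float
    classes: tuple[TissueClassSpec, ...]
    config: PhantomConfig

    @property
    def thickness(self) -> float:
        return self.config.section_thickness


@dataclass(frozen=True)
class GratingSpec:
    """Binary bar target: ``frequency`` line pairs per mm, ``duty`` bright fraction."""

    frequency: float
    duty: float = 0.5
    extent: tuple[float, float] | None = None  # (height µm, width µm)
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if not 0.0 <= self.duty <= 1.0:
            raise ValueError("duty must lie in [0, 1]")

    @property
    def period_um(self) -> float:
        return 1000.0 / self.frequency


def default_class_table() -> list[TissueClassSpec]:
    """Five-class compositional table with the field's expected contrasts.

    Orderings encoded here (and asserted by tests): white matter is the most
    lipid-rich class and carries the strongest flavin and collagen/elastin
    autofluorescence; gray matter is more protein-rich than white matter and
    dominates lipopigment autofluorescence; the background (bare gold
    substrate) is chemically and fluorescently empty.
    """
    cv = {s: 0.1 for s in SPECIES}
    fcv = {f: 0.1 for f in FLUOROPHORES}
    return [
        TissueClassSpec(
            BACKGROUND,
            "background",
            {s: 0.0 for s in SPECIES},
            cv,
            {f: 0.0 for f in FLUOROPHORES},
            fcv,
            scatter_mean=0.02,
        ),
        TissueClassSpec(
            VENTRICLE,
            "ventricle",
            {"lipid": 0.05, "protein": 0.25, "water": 0.6},
            cv,
            {"collagen_elastin": 0.05, "flavin": 0.05, "lipopigment": 0.1},
            fcv,
            scatter_mean=0.12,
        ),
        TissueClassSpec(
            GRAY_MATTER,
            "gray_matter",
            {"lipid": 0.45, "protein": 1.0, "water": 0.1},
            cv,
            {"collagen_elastin": 0.25, "flavin": 0.35, "lipopigment": 0.9},
            fcv,
            scatter_mean=0.18,
        ),
        TissueClassSpec(
            WHITE_MATTER,
            "white_matter",
            {"lipid": 1.2, "protein": 0.55, "water": 0.1},
            cv,
            {"collagen_elastin": 0.6, "flavin": 0.9, "lipopigment": 0.35},
            fcv,
            scatter_mean=0.22,
        ),
        TissueClassSpec(
            FINE_STRUCTURE,
            "fine_structure",
            {"lipid": 0.35, "protein": 1.5, "water": 0.1},
            cv,
            {"collagen_elastin": 0.9, "flavin": 0.5, "lipopigment": 0.7},
            fcv,
            scatter_mean=0.18,
        ),
    ]


def _label_map(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the geometric layout: tissue ellipse, ventricles, curved white-matter
    bands with widths spanning min..max structure width, and a reticular
    fine-structure network inside gray matter."""
    h, w, p = config.height, config.width, config.grid_pitch
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    a = 0.44 * w  # semi-axes in pixels
    b = 0.40 * h

    u = (xx - cx) / a
    v = (yy - cy) / b
    theta = np.arctan2(v, u)
    # gently wobbled tissue outline so boundaries are curved, not conic
    wob_phase = rng.uniform(0, 2 * np.pi, size=3)
    outline = 1.0 + 0.035 * np.sin(2 * theta + wob_phase[0]) + 0.02 * np.sin(
        3 * theta + wob_phase[1]
    )
    rho = np.sqrt(u * u + v * v)
    tissue = rho < outline

    labels = np.full((h, w), BACKGROUND, dtype=np.int16)
    labels[tissue] = GRAY_MATTER

    # curved white-matter bands: wobbled elliptical annuli, widths log-spaced
    # from the minimum to the maximum structure width
    r_eff = np.sqrt(a * b) * p  # effective tissue radius in µm
    # cap band widths on small fields so white matter stays a minority class
    widths = np.minimum(
        np.geomspace(config.min_structure_width, config.max_structure_width, 4),
        0.22 * r_eff,
    )
    radii = (0.22, 0.38, 0.55, 0.72)
    for k, (w_um, rk) in enumerate(zip(widths, radii)):
        band_wobble = 1.0 + 0.05 * np.sin(3 * theta + wob_phase[2] + 1.7 * k)
        half = 0.5 * w_um / r_eff
        band = np.abs(rho - rk * band_wobble) < half
        labels[band & tissue] = WHITE_MATTER

    # reticular fine structure: thin ridges along the zero level-set of a
    # smooth Gaussian random field, restricted to gray matter
    sigma_px = 12.0 / p
    g = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma_px)
    g /= g.std()
    grad_scale = np.hypot(*np.gradient(g))
    ridge_half_um = 4.0  # target ridge width ~8 µm (within the 5-20 µm range)
    tau = ridge_half_um / p * np.maximum(grad_scale, 1e-6)
    fine = (np.abs(g) < tau) & (labels == GRAY_MATTER)
    labels[fine] = FINE_STRUCTURE

    # ventricles last: two tilted ellipses near the midline override everything
    for sx, tilt in ((-1.0, 0.35), (1.0, -0.35)):
        vx = cx + sx * 0.13 * w
        vy = cy - 0.05 * h
        du = (xx - vx) * np.cos(tilt) - (yy - vy) * np.sin(tilt)
        dv = (xx - vx) * np.sin(tilt) + (yy - vy) * np.cos(tilt)
        vent = (du / (0.045 * w)) ** 2 + (dv / (0.14 * h)) ** 2 < 1.0
        labels[vent & tissue] = VENTRICLE
    return labels


def _textured_field(
    labels: np.ndarray,
    means: np.ndarray,
    cvs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Class mean × log-normal texture with per-class cv, clipped to mean·(1±5cv)."""
    mean_map = means[labels]
    cv_map = cvs[labels]
    z = rng.standard_normal(labels.shape)
    sigma = np.sqrt(np.log1p(cv_map**2))
    texture = np.exp(sigma * z - 0.5 * sigma**2)  # unit mean for every cv
    out = mean_map * texture
    lo = mean_map * (1.0 - 5.0 * cv_map)
    hi = mean_map * (1.0 + 5.0 * cv_map)
    return np.clip(out, np.maximum(lo, 0.0), hi)


def generate_brain_phantom(
    config: PhantomConfig, classes: Sequence[TissueClassSpec] | None = None
) -> Phantom:
    """Generate a seeded coronal-section-like phantom.

    The same seed and config always yield a bit-identical phantom.  With all
    cv set to zero the concentration fields are exactly piecewise constant at
    the class means.
    """
    if classes is None:
        classes = default_class_table()
    classes = tuple(sorted(classes, key=lambda c: c.class_id))
    ids = [c.class_id for c in classes]
    if len(set(ids)) != len(ids):
        raise ValueError("class_ids must be unique")
    if ids != list(range(len(ids))):
        raise ValueError("class_ids must be consecutive from 0")

    rng = np.random.default_rng(config.seed)
    labels = _label_map(config, rng)

    chem: dict[str, np.ndarray] = {}
    for s in SPECIES:
        means = np.array([c.chem_mean.get(s, 0.0) for c in classes])
        cvs = np.array([c.chem_cv.get(s, 0.0) for c in classes])
        chem[s] = _textured_field(labels, means, cvs, rng)
    fluor: dict[str, np.ndarray] = {}
    for f in FLUOROPHORES:
        means = np.array([c.fluor_mean.get(f, 0.0) for c in classes])
        cvs = np.array([c.fluor_cv.get(f, 0.0) for c in classes])
        fluor[f] = _textured_field(labels, means, cvs, rng)

    # smooth, strictly positive scattering baseline (correlation length ~50 µm):
    # a slowly varying log-normal texture modulating softly blended class levels
    p = config.grid_pitch
    smooth_sigma = 21.0 / p  # Gaussian kernel with ~50 µm FWHM
    noise = ndimage.gaussian_filter(rng.standard_normal(labels.shape), smooth_sigma)
    noise /= max(noise.std(), 1e-12)
    level = np.array([c.scatter_mean for c in classes])[labels]
    level = ndimage.gaussian_filter(level, 10.0 / p)
    scatter = np.maximum(level * np.exp(0.25 * noise - 0.03125), 0.005)

    return Phantom(
        labels=labels,
        chem=chem,
        fluor=fluor,
        scatter=scatter,
        pitch=p,
        classes=classes,
        config=config,
    )


def generate_grating_field(spec: GratingSpec, pitch: float) -> np.ndarray:
    """Binary reflectance bar pattern in [0, 1] on a grid of the given pitch.

    Bars run perpendicular to the x axis for orientation 0; the extent must
    contain at least 8 full periods.  Pixels straddling a bar edge take the
    exact area fraction (8×8 subpixel sampling), so the realized duty cycle —
    and with it the square-wave fundamental — is unbiased even when the
    period is not an integer number of pixels.
    """
    period = spec.period_um
    if pitch > period / 4:
        raise ValueError(
            f"grid pitch {pitch} µm undersamples the {period:.2f} µm period"
        )
    if spec.extent is None:
        length = 8 * period
        extent = (min(length, 64 * pitch), length)
    else:
        extent = spec.extent
    ny = max(1, int(round(extent[0] / pitch)))
    nx = int(round(extent[1] / pitch))
    if nx * pitch < 8 * period - 1e-9:
        raise ValueError("extent must contain at least 8 full periods")
    ang = np.deg2rad(spec.orientation)
    sub = 8
    offsets = (np.arange(sub) + 0.5) / sub - 0.5  # pixel-footprint subsamples
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    field = np.zeros((ny, nx))
    for oy in offsets:
        for ox in offsets:
            coord = ((xx + ox) * np.cos(ang) + (yy + oy) * np.sin(ang)) * pitch
            phase = np.mod(coord / period, 1.0)
            field += phase < spec.duty
    return field / (sub * sub)
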