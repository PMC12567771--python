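"""Forward model of the four-laser flying-spot MIR scanner and an FTIR-like
dense-band reference modality.

Physics
-------
Per band, chemical absorbance follows the additive multi-species Beer-Lambert
law A(x, y) = Σ_s ε_s(ν)·c_s(x, y)·l.  A slowly varying scattering baseline
B(x, y, ν) = scatter(x, y)·(b0 + b1·ν), linear in wavenumber, is added to every
band; the reference lasers (3704 and 2792 cm⁻¹) have negligible tissue
absorptivity and therefore carry the baseline alone, which is what makes the
downstream two-reference linear interpolation exact in the noiseless limit.

The flying-spot scanner averages the effective attenuation over a Gaussian
spot (σ = 1/e² diameter / 4), samples on a square raster comb and transduces
to detector counts against the bare-gold reference level:

    counts = clip(i_ref · 10^(−⟨A_eff⟩_spot) + η, 0, 65535)

with additive zero-mean detector noise η.  Counts are kept as floats so that
the noiseless inverse (preprocess.to_absorbance) is exact; quantization only
happens when images are written to 16-bit TIFF.

The FTIR-like modality shares the physics but replaces the Gaussian spot with
exact square-pixel box averaging and an ideal background subtraction, so its
output is absorbance directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .gridops import area_downsample, raster_sample, spot_average
from .phantom import Phantom

FULL_SCALE = 65535.0

#: Scattering baseline coefficients: B = scatter · (B0 + B1·wavenumber).
B0 = 0.2
B1 = 1.0e-4

__all__ = [
    "LaserLine",
    "SpotProfile",
    "RasterGrid",
    "BandSet",
    "MIRScanSet",
    "default_mir_bands",
    "default_ftir_bands",
    "absorbance_field",
    "signal_with_scatter",
    "flying_spot_scan",
    "simulate_mir",
    "simulate_ftir",
]


@dataclass(frozen=True)
class LaserLine:
    """One narrowband source (or FTIR band): wavenumber, role and per-species
    molar absorptivities (arbitrary units per concentration·µm)."""

    id: str
    wavenumber: float
    role: str  # "target" | "reference"
    epsilon: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.wavenumber <= 0:
            raise ValueError("wavenumber must be > 0")
        if self.role not in ("target", "reference"):
            raise ValueError("role must be 'target' or 'reference'")


@dataclass(frozen=True)
class SpotProfile:
    """Gaussian beam spot; ``diameter_1e2`` is the 1/e² intensity diameter."""

    diameter_1e2: float = 22.0
    shape: str = "gaussian"

    @property
    def sigma(self) -> float:
        # 1/e² diameter of a Gaussian beam = 4σ
        return self.diameter_1e2 / 4.0


@dataclass(frozen=True)
class RasterGrid:
    """Square raster comb: 20 µm native, 5 µm when super-sampling."""

    step: float = 20.0
    origin: float = 0.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("raster step must be > 0")


@dataclass(frozen=True)
class BandSet:
    bands: tuple[LaserLine, ...]

    def __post_init__(self) -> None:
        wns = [b.wavenumber for b in self.bands]
        if len(set(wns)) != len(wns):
            raise ValueError("wavenumbers must be unique")

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    def get(self, band_id: str) -> LaserLine:
        for b in self.bands:
            if b.id == band_id:
                return b
        raise KeyError(band_id)


@dataclass
class MIRScanSet:
    """Per-band 2-D images with acquisition metadata.

    ``kind`` is "counts" for the laser scanner (images in [0, 65535], gold
    reference level ``i_ref``) and "absorbance" for the FTIR-like modality.
    """

    images: dict[str, np.ndarray]
    pitch: float
    i_ref: float | None
    bands: BandSet
    spot: SpotProfile | None
    grid: RasterGrid | None
    seed: int | None
    kind: str = "counts"


def default_mir_bands() -> BandSet:
    """The four-laser set.

    2928 cm⁻¹ sits on the CH₂ stretch and is lipid-dominant; 3352 cm⁻¹ sits in
    the NH stretch region (3200-3570 cm⁻¹) and is protein-dominant, with a
    water OH contribution enabling hydration correction.  3704 and 2792 cm⁻¹
    bracket the targets outside the chemical bands and act as pure scattering
    references.
    """
    return BandSet(
        (
            LaserLine("L1", 3704.0, "reference", {}),
            LaserLine("L2", 3352.0, "target", {"protein": 0.05, "lipid": 0.008, "water": 0.05}),
            LaserLine("L3", 2928.0, "target", {"lipid": 0.06, "protein": 0.01, "water": 0.004}),
            LaserLine("L4", 2792.0, "reference", {}),
        )
    )


def default_ftir_bands() -> BandSet:
    """Ten-band set: the four scanner lines plus six diagnostically relevant
    FTIR bands (OH, CH, amide I/II/III, C-O)."""
    extra = (
        LaserLine("B3450", 3450.0, "target", {"water": 0.08, "protein": 0.02}),
        LaserLine("B2878", 2878.0, "target", {"lipid": 0.045, "protein": 0.012}),
        LaserLine("B1655", 1655.0, "target", {"protein": 0.08, "lipid": 0.005, "water": 0.01}),
        LaserLine("B1550", 1550.0, "target", {"protein": 0.06, "lipid": 0.004}),
        LaserLine("B1320", 1320.0, "target", {"protein": 0.03, "lipid": 0.008}),
        LaserLine("B1159", 1159.0, "target", {"lipid": 0.02, "protein": 0.01}),
    )
    return BandSet(tuple(default_mir_bands()) + extra)


def absorbance_field(phantom: Phantom, line: LaserLine, thickness: float | None = None) -> np.ndarray:
    """Chemical absorbance A = Σ_s ε_s·c_s·l on the phantom grid."""
    l = phantom.thickness if thickness is None else thickness
    a = np.zeros_like(phantom.scatter)
    for species, eps in line.epsilon.items():
        if species not in phantom.chem:
            raise KeyError(f"phantom has no species {species!r}")
        c = phantom.chem[species]
        if np.any(c < 0):
            raise ValueError("negative concentration input")
        a += eps * c * l
    return a


def signal_with_scatter(
    a: np.ndarray, scatter: np.ndarray, line: LaserLine, b0: float = B0, b1: float = B1
) -> np.ndarray:
    """Effective attenuation A_eff = A + scatter·(b0 + b1·ν)."""
    if a.shape != scatter.shape:
        raise ValueError("absorbance and scatter shapes differ")
    return a + scatter * (b0 + b1 * line.wavenumber)


def flying_spot_scan(
    field: np.ndarray,
    pitch: float,
    spot: SpotProfile,
    grid: RasterGrid,
    noise_sd: float = 0.0,
    i_ref: float = 58000.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Scan an attenuation field: Gaussian spot average, raster sampling,
    decadic transduction against the gold reference, additive detector noise,
    clipping to the 16-bit count range."""
    if i_ref <= 0:
        raise ValueError("i_ref must be > 0")
    if pitch > grid.step:
        raise ValueError("field pitch must not exceed the raster step")
    averaged = spot_average(field, pitch, spot.sigma)
    sampled = raster_sample(averaged, pitch, grid.step, grid.origin)
    counts = i_ref * np.power(10.0, -sampled)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        counts = counts + rng.normal(0.0, noise_sd, size=counts.shape)
    return np.clip(counts, 0.0, FULL_SCALE)


def simulate_mir(
    phantom: Phantom,
    bands: BandSet | None = None,
    spot: SpotProfile | None = None,
    grid: RasterGrid | None = None,
    noise_sd: float = 50.0,
    i_ref: float = 58000.0,
    seed: int = 0,
) -> MIRScanSet:
    """Simulate the laser scanner: one count image per band, fully seeded."""
    bands = bands if bands is not None else default_mir_bands()
    spot = spot if spot is not None else SpotProfile()
    grid = grid if grid is not None else RasterGrid()
    rng = np.random.default_rng(seed)
    images: dict[str, np.ndarray] = {}
    for line in bands:
        a = absorbance_field(phantom, line)
        a_eff = signal_with_scatter(a, phantom.scatter, line)
        images[line.id] = flying_spot_scan(
            a_eff, phantom.pitch, spot, grid, noise_sd=noise_sd, i_ref=i_ref, rng=rng
        )
    return MIRScanSet(
        images=images, pitch=grid.step, i_ref=i_ref, bands=bands,
        spot=spot, grid=grid, seed=seed, kind="counts",
    )


def simulate_ftir(
    phantom: Phantom,
    bands: BandSet | None = None,
    pixel_pitch: float = 6.25,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> MIRScanSet:
    """FTIR-like modality: box-averaged absorbance images at the given pixel
    pitch (6.25 or 25 µm in the emulated instrument), ideal background
    subtraction, additive absorbance noise."""
    bands = bands if bands is not None else default_ftir_bands()
    if pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be > 0")
    rng = np.random.default_rng(seed)
    images: dict[str, np.ndarray] = {}
    for line in bands:
        a = absorbance_field(phantom, line)
        a_eff = signal_with_scatter(a, phantom.scatter, line)
        img = area_downsample(a_eff, phantom.pitch, pixel_pitch)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        images[line.id] = img
    return MIRScanSet(
        images=images, pitch=pixel_pitch, i_ref=None, bands=bands,
        spot=None, grid=None, seed=seed, kind="absorbance",
    )
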