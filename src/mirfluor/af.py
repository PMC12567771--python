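"""Forward model of the autofluorescence camera path.

Each channel couples one or two excitation LEDs to an emission band-pass
filter.  Excitation and emission spectra of the endogenous fluorophores are
modeled as Gaussians around their published peak positions (the literature
gives peaks and ranges, not curves), so the LED-fluorophore and
filter-emission couplings have closed forms: for two Gaussians with centers
c1, c2 and widths s1, s2 the normalized overlap is exp(−(c1−c2)²/(2(s1²+s2²))),
equal to 1 when the centers coincide.  The per-channel expected
photoelectron rate is linear in every fluorophore concentration, summed over
*all* fluorophores — spectral crosstalk between the overlapping emission bands
is deliberately retained, which is why the instrument reports only relative
count images, never absolute concentrations.

The camera model follows the spec sheet of a cooled CCD: optical blur of
3 µm FWHM, resampling to the 4 µm sample-plane pitch, Poisson shot noise on
signal + dark charge, Gaussian read noise, conversion gain in e⁻/ADU, and
clipping to the 16-bit range.  AF counts are integers (rounded ADU).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gridops import area_downsample, spot_average
from .phantom import FLUOROPHORES, Phantom

FULL_SCALE = 65535
_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))

__all__ = [
    "FluorophoreSpec",
    "IlluminationSpec",
    "EmissionFilterSpec",
    "CameraSpec",
    "AFChannel",
    "AFChannelPlan",
    "AFImageSet",
    "default_fluorophores",
    "default_channel_plan",
    "overlap_coefficient",
    "channel_flux",
    "camera_image",
    "simulate_af",
]


@dataclass(frozen=True)
class FluorophoreSpec:
    """Gaussian excitation/emission model of an endogenous fluorophore.

    ``exc_peaks`` is a list of (center nm, sigma nm); ``em_peak``/``em_width``
    the emission Gaussian center and sigma; ``quantum_yield`` a relative yield.
    """

    name: str
    exc_peaks: tuple[tuple[float, float], ...]
    em_peak: float
    em_width: float
    quantum_yield: float = 1.0

    def __post_init__(self) -> None:
        if any(w <= 0 for _, w in self.exc_peaks) or self.em_width <= 0:
            raise ValueError("spectral widths must be > 0")
        if self.quantum_yield <= 0:
            raise ValueError("quantum yield must be > 0")


@dataclass(frozen=True)
class IlluminationSpec:
    """One LED ring: center wavelength, Gaussian bandwidth (sigma), relative
    irradiance in expected photoelectrons per second per unit concentration
    at unit coupling."""

    led_nm: float
    bandwidth: float = 8.0
    power: float = 800.0

    def __post_init__(self) -> None:
        if self.power <= 0 or self.bandwidth <= 0:
            raise ValueError("power and bandwidth must be > 0")


@dataclass(frozen=True)
class EmissionFilterSpec:
    center: float
    fwhm: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")

    @property
    def sigma(self) -> float:
        return self.fwhm / _FWHM


@dataclass(frozen=True)
class CameraSpec:
    """Cooled-CCD characteristics mapped to the sample plane.

    The 6 µm sensor pixels and zoom optics are absorbed into a fixed 4 µm
    effective sample-plane pitch (the fusion grid); optical resolution is a
    Gaussian PSF of 3 µm FWHM.
    """

    pixel_pitch_sample: float = 4.0
    gain: float = 0.6  # e-/ADU
    read_noise: float = 9.0  # e- rms
    dark_current: float = 0.25  # e-/s
    full_well_adu: int = FULL_SCALE
    psf_fwhm: float = 3.0  # µm

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.read_noise < 0 or self.dark_current <= 0:
            raise ValueError("gain, read_noise, dark_current must be positive")


@dataclass(frozen=True)
class AFChannel:
    name: str
    leds: tuple[IlluminationSpec, ...]
    emission_filter: EmissionFilterSpec
    exposure: float

    def __post_init__(self) -> None:
        if not 5.0 <= self.exposure <= 50.0:
            raise ValueError("exposure must lie in [5, 50] s")


@dataclass(frozen=True)
class AFChannelPlan:
    channels: tuple[AFChannel, ...]


@dataclass
class AFImageSet:
    images: dict[str, np.ndarray]
    pitch: float
    plan: AFChannelPlan
    seed: int


def default_fluorophores() -> tuple[FluorophoreSpec, ...]:
    """Collagen/elastin (exc 320-360, em 400-440), flavins (exc 360 & 450,
    em 500-600) and lipopigments (exc 400-500, em 480-700), as Gaussians."""
    return (
        FluorophoreSpec("collagen_elastin", ((340.0, 18.0),), 420.0, 20.0, 1.0),
        FluorophoreSpec("flavin", ((360.0, 15.0), (450.0, 15.0)), 530.0, 30.0, 0.55),
        FluorophoreSpec("lipopigment", ((450.0, 45.0),), 590.0, 55.0, 0.7),
    )


LED_355 = IlluminationSpec(355.0)
LED_395 = IlluminationSpec(395.0)
LED_435 = IlluminationSpec(435.0)
LED_440 = IlluminationSpec(440.0)
FILT_400 = EmissionFilterSpec(400.0, 10.0)
FILT_440 = EmissionFilterSpec(440.0, 10.0)
FILT_550 = EmissionFilterSpec(550.0, 40.0)


def default_channel_plan() -> AFChannelPlan:
    """The four designed channels: collagen/elastin via 355→400 and 355→440,
    lipopigments via 440→550, flavins via 355+440→550."""
    return AFChannelPlan(
        (
            AFChannel("collagen_400", (LED_355,), FILT_400, exposure=20.0),
            AFChannel("collagen_440", (LED_355,), FILT_440, exposure=20.0),
            AFChannel("lipopigment_550", (LED_440,), FILT_550, exposure=10.0),
            AFChannel("flavin_550", (LED_355, LED_440), FILT_550, exposure=10.0),
        )
    )


def _gauss_overlap(c1: float, s1: float, c2: float, s2: float) -> float:
    return float(np.exp(-((c1 - c2) ** 2) / (2.0 * (s1 * s1 + s2 * s2))))


def overlap_coefficient(
    fluor: FluorophoreSpec, led: IlluminationSpec, filt: EmissionFilterSpec
) -> float:
    """Unitless coupling k = yield · (excitation overlap) · (emission overlap).

    Each overlap integral is normalized to 1 at coincident centers; with a
    single excitation peak and unit yield, k ≤ 1.
    """
    exc = sum(
        _gauss_overlap(center, width, led.led_nm, led.bandwidth)
        for center, width in fluor.exc_peaks
    )
    em = _gauss_overlap(fluor.em_peak, fluor.em_width, filt.center, filt.sigma)
    return fluor.quantum_yield * exc * em


def channel_flux(
    phantom: Phantom,
    channel: AFChannel,
    fluorophores: Sequence[FluorophoreSpec] | None = None,
) -> np.ndarray:
    """Expected photoelectron rate field (e⁻/s) on the phantom grid.

    Sums over every fluorophore and every LED of the channel; off-target
    fluorophores contribute through their (small) spectral crosstalk.
    """
    if fluorophores is None:
        fluorophores = default_fluorophores()
    rate = np.zeros_like(phantom.scatter)
    for f in fluorophores:
        if f.name not in phantom.fluor:
            raise KeyError(f"phantom has no fluorophore {f.name!r}")
        c = phantom.fluor[f.name]
        for led in channel.leds:
            k = overlap_coefficient(f, led, channel.emission_filter)
            rate += k * c * led.power
    return rate


def camera_image(
    rate: np.ndarray,
    pitch_in: float,
    cam: CameraSpec,
    exposure: float,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Integrate a photoelectron-rate field into a count image.

    Optical PSF blur, box resampling to the camera's sample-plane pitch, then
    ADU = clip(round((Poisson(rate·t + dark·t) + Normal(0, read_noise)) / gain),
    0, full_well).
    """
    if exposure <= 0:
        raise ValueError("exposure must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    blurred = spot_average(rate, pitch_in, cam.psf_fwhm / _FWHM)
    if cam.pixel_pitch_sample > pitch_in:
        resampled = area_downsample(blurred, pitch_in, cam.pixel_pitch_sample)
    else:
        resampled = blurred
    electrons_mean = np.maximum(resampled, 0.0) * exposure + cam.dark_current * exposure
    electrons = rng.poisson(electrons_mean).astype(float)
    electrons += rng.normal(0.0, cam.read_noise, size=electrons.shape)
    adu = np.rint(electrons / cam.gain)
    return np.clip(adu, 0, cam.full_well_adu)


def simulate_af(
    phantom: Phantom,
    plan: AFChannelPlan | None = None,
    cam: CameraSpec | None = None,
    seed: int = 0,
) -> AFImageSet:
    """One count image per channel at the camera's sample-plane pitch."""
    plan = plan if plan is not None else default_channel_plan()
    cam = cam if cam is not None else CameraSpec()
    rng = np.random.default_rng(seed)
    images: dict[str, np.ndarray] = {}
    for ch in plan.channels:
        rate = channel_flux(phantom, ch)
        images[ch.name] = camera_image(rate, phantom.pitch, cam, ch.exposure, rng=rng)
    return AFImageSet(images=images, pitch=cam.pixel_pitch_sample, plan=plan, seed=seed)
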