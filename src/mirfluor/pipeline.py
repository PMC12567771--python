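"""Orchestration: simulate → preprocess → segment → evaluate as reproducible,
configured runs.

A run generates one phantom, simulates every requested modality from it,
processes each into a datacube, clusters with K-means (k = 5 by default),
and evaluates every segmentation against the ground truth and against every
other segmentation with the adjusted Rand index.  All randomness derives from
a single seed through ``numpy.random.SeedSequence`` spawning, so a config
fully reconstructs a run.

Modalities
----------
mir20       four-laser scan, 20 µm raster, scatter-corrected target layers
            upscaled to the 4 µm fusion grid
mir10       the same with the 5 µm super-sampling raster (10 µm resolution)
ftir6.25    ten-band FTIR-like absorbance imaging at 6.25 µm
ftir25      the same at 25 µm
af          four-channel autofluorescence at 4 µm
multimodal  mir10 corrected layers fused with the af channels at 4 µm
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Iterable

import numpy as np

from . import af as af_mod
from . import mir as mir_mod
from .metrics import (
    DEFAULT_LADDER,
    ContrastCurve,
    compare_segmentations,
    contrast_curve,
    davies_bouldin,
    resolution_limit,
)
from .phantom import Phantom, PhantomConfig, generate_brain_phantom
from .preprocess import (
    DataCube,
    Image2D,
    assemble_cube,
    normalize_counts,
    scatter_correct,
    to_absorbance,
)
from .segment import SegmentationMap, fit_kmeans, segment_cube

MODALITIES = ("mir20", "mir10", "ftir6.25", "ftir25", "af", "multimodal")

__all__ = [
    "MODALITIES",
    "RunConfig",
    "ExperimentReport",
    "mir_layers",
    "af_layers",
    "ftir_layers",
    "modality_cube",
    "ideal_multimodal_cube",
    "truth_segmentation",
    "run_experiment",
    "run_grating_validation",
]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    modalities: tuple[str, ...] = ("mir20", "multimodal")
    bands: int = 10  # FTIR band count: 4 or 10
    k: int = 5
    n_init: int = 10
    mir_noise_sd: float = 50.0
    ftir_noise_sd: float = 0.01
    af_exposure_scale: float = 1.0
    use_corrected: bool = True  # cluster scatter-corrected MIR absorbances
    fusion_pitch: float = 4.0

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ValueError("at least one modality required")
        for m in self.modalities:
            if m not in MODALITIES:
                raise ValueError(f"unknown modality {m!r}")
        if self.bands not in (4, 10):
            raise ValueError("bands must be 4 or 10")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phantom"] = asdict(self.phantom)
        d["modalities"] = list(self.modalities)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["phantom"] = PhantomConfig(**d.get("phantom", {}))
        d["modalities"] = tuple(d.get("modalities", ("mir20", "multimodal")))
        return cls(**d)


@dataclass
class ExperimentReport:
    config: RunConfig
    dbi: dict[str, float]
    ari_truth: dict[str, float]
    ari_pairwise: dict[str, dict[str, float]]
    segmentations: dict[str, SegmentationMap]

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "dbi": self.dbi,
            "ari_truth": self.ari_truth,
            "ari_pairwise": self.ari_pairwise,
        }


def _spawn_seed(seed: int, key: int) -> int:
    # stable per-stage seed below 2**31
    return int(np.random.SeedSequence([seed, key]).generate_state(1)[0] % (2**31))


def mir_layers(
    phantom: Phantom,
    step: float,
    noise_sd: float = 50.0,
    seed: int = 0,
    corrected: bool = True,
) -> list[Image2D]:
    """Scan, normalize, convert to absorbance against the gold reference and
    (by default) scatter-correct; returns the target layers at the scan pitch."""
    scan = mir_mod.simulate_mir(
        phantom,
        grid=mir_mod.RasterGrid(step=step),
        noise_sd=noise_sd,
        seed=seed,
    )
    i_ref_norm = scan.i_ref / mir_mod.FULL_SCALE
    absorb = [
        replace(
            to_absorbance(
                normalize_counts(img, channel=name, pitch=scan.pitch), i_ref_norm
            ),
            source="mir",
        )
        for name, img in scan.images.items()
    ]
    cube = DataCube(layers=absorb, pitch=scan.pitch)
    if corrected:
        return list(scatter_correct(cube, scan.bands).layers)
    return [l for l in absorb if scan.bands.get(l.channel).role == "target"]


def af_layers(phantom: Phantom, seed: int = 0, exposure_scale: float = 1.0) -> list[Image2D]:
    plan = af_mod.default_channel_plan()
    if exposure_scale != 1.0:
        plan = af_mod.AFChannelPlan(
            tuple(
                af_mod.AFChannel(
                    c.name, c.leds, c.emission_filter,
                    float(np.clip(c.exposure * exposure_scale, 5.0, 50.0)),
                )
                for c in plan.channels
            )
        )
    imgs = af_mod.simulate_af(phantom, plan=plan, seed=seed)
    return [
        replace(
            normalize_counts(img, channel=name, pitch=imgs.pitch), source="af"
        )
        for name, img in imgs.images.items()
    ]


def ftir_layers(
    phantom: Phantom,
    pixel_pitch: float,
    bands: int = 10,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> list[Image2D]:
    band_set = mir_mod.default_ftir_bands() if bands == 10 else mir_mod.default_mir_bands()
    scan = mir_mod.simulate_ftir(
        phantom, bands=band_set, pixel_pitch=pixel_pitch, noise_sd=noise_sd, seed=seed
    )
    return [
        Image2D(values=img, pitch=scan.pitch, channel=name, source="ftir")
        for name, img in scan.images.items()
    ]


def modality_cube(phantom: Phantom, modality: str, config: RunConfig) -> DataCube:
    """Build the clustering input for one modality."""
    seed = _spawn_seed(config.seed, MODALITIES.index(modality))
    if modality in ("mir20", "mir10"):
        step = 20.0 if modality == "mir20" else 5.0
        layers = mir_layers(
            phantom, step, noise_sd=config.mir_noise_sd, seed=seed,
            corrected=config.use_corrected,
        )
        return assemble_cube(layers, target_pitch=config.fusion_pitch, register=False)
    if modality in ("ftir6.25", "ftir25"):
        pitch = 6.25 if modality == "ftir6.25" else 25.0
        layers = ftir_layers(
            phantom, pitch, bands=config.bands, noise_sd=config.ftir_noise_sd, seed=seed
        )
        return assemble_cube(layers, target_pitch=pitch, register=False)
    if modality == "af":
        layers = af_layers(phantom, seed=seed, exposure_scale=config.af_exposure_scale)
        return assemble_cube(layers, target_pitch=config.fusion_pitch, register=False)
    if modality == "multimodal":
        mir = mir_layers(
            phantom, 5.0, noise_sd=config.mir_noise_sd,
            seed=_spawn_seed(config.seed, MODALITIES.index("mir10")),
            corrected=config.use_corrected,
        )
        fluo = af_layers(
            phantom, seed=_spawn_seed(config.seed, MODALITIES.index("af")),
            exposure_scale=config.af_exposure_scale,
        )
        return assemble_cube(fluo + mir, target_pitch=config.fusion_pitch)
    raise ValueError(f"unknown modality {modality!r}")


def ideal_multimodal_cube(phantom: Phantom) -> DataCube:
    """Degradation-free multimodal cube on the ground-truth grid.

    Exact scatter-corrected Beer-Lambert absorbances of the two target lasers
    plus exact per-channel photoelectron-rate fields: no spot, PSF, sampling
    or noise.  On a cv=0 phantom every pixel vector is exactly its class
    vector, which is what makes exact segmentation recovery attainable.
    """
    bands = mir_mod.default_mir_bands()
    layers = [
        Image2D(
            values=mir_mod.absorbance_field(phantom, line),
            pitch=phantom.pitch,
            channel=line.id,
            source="mir",
        )
        for line in bands
        if line.role == "target"
    ]
    for ch in af_mod.default_channel_plan().channels:
        layers.append(
            Image2D(
                values=af_mod.channel_flux(phantom, ch),
                pitch=phantom.pitch,
                channel=ch.name,
                source="af",
            )
        )
    return assemble_cube(layers, target_pitch=phantom.pitch, register=False)


def truth_segmentation(phantom: Phantom) -> SegmentationMap:
    return SegmentationMap(labels=phantom.labels, pitch=phantom.pitch, model=None)


def run_experiment(config: RunConfig) -> ExperimentReport:
    """Simulate, process, segment and evaluate every configured modality."""
    phantom = generate_brain_phantom(replace(config.phantom, seed=config.seed))
    truth = truth_segmentation(phantom)
    segmentations: dict[str, SegmentationMap] = {}
    dbi: dict[str, float] = {}
    for modality in config.modalities:
        cube = modality_cube(phantom, modality, config)
        model = fit_kmeans(cube, k=config.k, n_init=config.n_init, seed=config.seed)
        seg = segment_cube(cube, model)
        segmentations[modality] = seg
        dbi[modality] = davies_bouldin(cube.stack(), seg.labels.ravel())
    ari_truth = {
        m: compare_segmentations(truth, s, register=False).ari
        for m, s in segmentations.items()
    }
    ari_pairwise: dict[str, dict[str, float]] = {}
    for ma in config.modalities:
        ari_pairwise[ma] = {}
        for mb in config.modalities:
            if ma == mb:
                ari_pairwise[ma][mb] = 1.0
            elif mb in ari_pairwise and ma in ari_pairwise[mb]:
                ari_pairwise[ma][mb] = ari_pairwise[mb][ma]
            else:
                ari_pairwise[ma][mb] = compare_segmentations(
                    segmentations[ma], segmentations[mb], register=False
                ).ari
    return ExperimentReport(
        config=config,
        dbi=dbi,
        ari_truth=ari_truth,
        ari_pairwise=ari_pairwise,
        segmentations=segmentations,
    )


def run_grating_validation(
    spot_diameter: float = 22.0,
    raster_step: float = 5.0,
    ladder: Iterable[float] = DEFAULT_LADDER,
    threshold: float = 0.2,
    field_pitch: float = 1.0,
) -> tuple[ContrastCurve, float]:
    """Scan the frequency ladder with the configured spot/raster and report
    the contrast curve plus the resolved frequency limit."""
    curve = contrast_curve(
        mir_mod.SpotProfile(diameter_1e2=spot_diameter),
        mir_mod.RasterGrid(step=raster_step),
        ladder=tuple(ladder),
        field_pitch=field_pitch,
    )
    return curve, resolution_limit(curve, threshold=threshold)
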