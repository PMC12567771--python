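"""TIFF + JSON sidecar persistence for phantoms, scan sets, datacubes and
segmentations.

Float fields go to multi-page 32-bit float TIFF, label maps to 16-bit TIFF,
segmentations to 8-bit indexed TIFF; acquisition and provenance metadata live
in a JSON sidecar next to each image file.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile

from .phantom import FLUOROPHORES, SPECIES, Phantom, PhantomConfig, TissueClassSpec
from .preprocess import DataCube, Image2D
from .segment import SegmentationMap

__all__ = [
    "save_phantom",
    "load_phantom",
    "save_scanset",
    "save_cube",
    "load_cube",
    "save_segmentation",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_phantom(phantom: Phantom, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fields = [phantom.chem[s] for s in SPECIES]
    fields += [phantom.fluor[f] for f in FLUOROPHORES]
    fields.append(phantom.scatter)
    tifffile.imwrite(path, np.stack(fields).astype(np.float32), photometric="minisblack")
    tifffile.imwrite(
        path.with_name(path.stem + "_labels.tif"), phantom.labels.astype(np.uint16)
    )
    meta = {
        "pitch": phantom.pitch,
        "field_order": list(SPECIES) + list(FLUOROPHORES) + ["scatter"],
        "config": asdict(phantom.config),
        "classes": [asdict(c) for c in phantom.classes],
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_phantom(path: str | Path) -> Phantom:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    stack = tifffile.imread(path).astype(float)
    labels = tifffile.imread(path.with_name(path.stem + "_labels.tif")).astype(np.int16)
    order = meta["field_order"]
    fields = {name: stack[i] for i, name in enumerate(order)}
    classes = tuple(TissueClassSpec(**c) for c in meta["classes"])
    return Phantom(
        labels=labels,
        chem={s: fields[s] for s in SPECIES},
        fluor={f: fields[f] for f in FLUOROPHORES},
        scatter=fields["scatter"],
        pitch=meta["pitch"],
        classes=classes,
        config=PhantomConfig(**meta["config"]),
    )


def save_scanset(images: dict[str, np.ndarray], pitch: float, path_prefix: str | Path,
                 meta: dict | None = None, dtype: str = "uint16") -> None:
    """One TIFF per channel (counts rounded to 16-bit, absorbance as float32)
    plus a JSON sidecar with pitch and acquisition metadata."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    for name, img in images.items():
        out = prefix.with_name(f"{prefix.name}_{name}.tif")
        if dtype == "uint16":
            tifffile.imwrite(out, np.rint(img).astype(np.uint16))
        else:
            tifffile.imwrite(out, img.astype(np.float32))
    sidecar = prefix.with_name(prefix.name + ".json")
    sidecar.write_text(json.dumps({"pitch": pitch, **(meta or {})}, indent=2))


def save_cube(cube: DataCube, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        np.stack([l.values for l in cube.layers]).astype(np.float32),
        photometric="minisblack",
    )
    meta = {
        "pitch": cube.pitch,
        "layers": [{"channel": l.channel, "source": l.source} for l in cube.layers],
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_cube(path: str | Path) -> DataCube:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    stack = tifffile.imread(path).astype(float)
    layers = [
        Image2D(values=stack[i], pitch=meta["pitch"],
                channel=l["channel"], source=l.get("source", ""))
        for i, l in enumerate(meta["layers"])
    ]
    return DataCube(layers=layers, pitch=meta["pitch"])


def save_segmentation(seg: SegmentationMap, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, seg.labels.astype(np.uint8))
    meta: dict = {"pitch": seg.pitch}
    if seg.model is not None:
        meta["k"] = seg.model.k
        meta["inertia"] = seg.model.inertia
        meta["seed"] = seg.model.seed
        meta["centroids"] = np.asarray(seg.model.centroids).tolist()
        meta["layer_names"] = list(seg.model.layer_names)
    _sidecar(path).write_text(json.dumps(meta, indent=2))
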