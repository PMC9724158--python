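"""Readers/writers and configuration for the command-line pipeline.

Canonical on-disk image format: 16-bit grayscale PNG holding 12-bit
intensities ([0, 4095]); 8-bit PNGs are accepted and scaled by 4095/255.
NIfTI volumes are read slice-wise. Coordinate convention throughout:
row-major, origin top-left, (row, col) indexing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from PIL import Image as PILImage
from skimage.transform import resize

from .losses import LossWeights
from .metrics import SSIMParams
from .nets import DiscriminatorConfig, EdgeNetConfig, GeneratorConfig
from .phantoms import INTENSITY_MAX, Image2D, MotionSpec, PhantomSpec, SampleSet
from .train import AugmentConfig, TrainConfig

MANIFEST_NAME = "manifest.csv"
MANIFEST_VERSION = 1


def read_image(path, slice_index: int | None = None,
               domain_tag: str = "A") -> Image2D:
    """Load a grayscale PNG (8/16-bit) or a NIfTI slice onto [0, 4095]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
        if vol.ndim == 3:
            if slice_index is None:
                raise ValueError(f"{path}: 3-D NIfTI needs a slice index")
            if not 0 <= slice_index < vol.shape[2]:
                raise ValueError(f"{path}: slice {slice_index} out of range")
            vol = vol[:, :, slice_index]
        elif vol.ndim != 2:
            raise ValueError(f"{path}: unsupported NIfTI dimensionality {vol.ndim}")
        return Image2D(np.clip(vol, 0, INTENSITY_MAX), INTENSITY_MAX, domain_tag)
    if path.suffix.lower() == ".png":
        img = PILImage.open(path)
        if img.mode == "I;16":
            arr = np.asarray(img, dtype=np.float64)
        elif img.mode in ("L", "I"):
            arr = np.asarray(img.convert("I"), dtype=np.float64)
            if img.mode == "L":
                arr = arr * (INTENSITY_MAX / 255.0)
        else:
            raise ValueError(
                f"{path}: unsupported PNG mode {img.mode!r} (grayscale only)"
            )
        return Image2D(np.clip(arr, 0, INTENSITY_MAX), INTENSITY_MAX, domain_tag)
    raise ValueError(f"{path}: unsupported format {path.suffix!r}")


def write_image(path, img: Image2D):
    """Write as 16-bit grayscale PNG (rounded 12-bit values)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.clip(np.round(img.pixels), 0, 65535).astype(np.uint16)
    PILImage.fromarray(arr).save(path)


def resample_to_input(img: Image2D, size: int = 256) -> Image2D:
    """Bilinear resample to size x size (the networks' input grid)."""
    if img.pixels.shape == (size, size):
        return Image2D(img.pixels.copy(), img.intensity_max, img.domain_tag)
    out = resize(img.pixels, (size, size), order=1, preserve_range=True,
                 anti_aliasing=img.pixels.shape[0] > size)
    return Image2D(out, img.intensity_max, img.domain_tag)


# -- manifests -------------------------------------------------------------

def write_dataset(out_dir, samples: SampleSet, seed: int) -> Path:
    """Write 16-bit PNG pairs plus a CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (src, tgt) in enumerate(zip(samples.sources, samples.targets)):
        src_name = f"{i:05d}_A.png"
        tgt_name = f"{i:05d}_B.png"
        write_image(out_dir / src_name, src)
        write_image(out_dir / tgt_name, tgt)
        rows.append({
            "index": i,
            "source_path": src_name,
            "target_path": tgt_name,
            "permutation_index": int(samples.pairing_permutation[i]),
            "seed": seed,
        })
    df = pd.DataFrame(rows)
    df.insert(0, "format_version", MANIFEST_VERSION)
    manifest = out_dir / MANIFEST_NAME
    df.to_csv(manifest, index=False)
    return manifest


def read_dataset(manifest_path) -> SampleSet:
    """Rebuild a SampleSet from a manifest written by ``write_dataset``."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    df = pd.read_csv(manifest_path)
    base = manifest_path.parent
    indices = df["index"].tolist()
    if indices != list(range(len(df))):
        raise ValueError(f"{manifest_path}: indices must be contiguous from 0")
    sources, targets = [], []
    for _, row in df.iterrows():
        sources.append(read_image(base / row["source_path"], domain_tag="A"))
        targets.append(read_image(base / row["target_path"], domain_tag="B"))
    perm = df["permutation_index"].to_numpy()
    paired = bool(np.array_equal(perm, np.arange(len(perm))))
    return SampleSet(sources, targets, paired, perm)


# -- config ----------------------------------------------------------------

@dataclass
class RunConfig:
    """Nested run configuration; round-trips losslessly through YAML."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)
    edge_net: EdgeNetConfig = field(default_factory=EdgeNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    ssim: SSIMParams = field(default_factory=SSIMParams)
    motion: MotionSpec = field(default_factory=MotionSpec)


_NESTED = {
    "loss_weights": LossWeights,
    "augment": AugmentConfig,
}


def _build(cls, data: dict, context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {context}")
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED and isinstance(value, dict):
            kwargs[key] = _build(_NESTED[key], value, f"{context}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_run_config(path) -> RunConfig:
    """Parse a YAML run config, rejecting unknown keys explicitly."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    top = {f.name: f for f in fields(RunConfig)}
    unknown = set(data) - set(top)
    if unknown:
        raise ValueError(f"unknown section(s) {sorted(unknown)} in {path}")
    kwargs = {}
    for name, f in top.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ValueError(f"section {name!r} must be a mapping")
        cls = f.default_factory().__class__
        kwargs[name] = _build(cls, section, name)
    return RunConfig(**kwargs)


def save_run_config(path, cfg: RunConfig):
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(clean(cfg), fh, sort_keys=False)
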