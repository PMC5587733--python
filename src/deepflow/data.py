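"""Loading, validation and normalization of multi-channel cell image sets.

A dataset is a manifest CSV plus one single-channel image file (TIFF or
PNG) per cell and channel.  The manifest has columns
``cell_id, label, <channel_1>, ..., <channel_C>`` and optionally numeric
covariate columns such as ``dna_content``.  Images are uniformly resized
to a common square side and intensities are brought into [0, 1]; by
default each image is rescaled by its own 1st/99th percentile (robust to
hot pixels) and clipped.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.transform import resize

from .errors import (
    ConfigurationError,
    ImageFormatError,
    ImageLoadError,
    ManifestError,
    ValidationError,
)

__all__ = ["CellImageSet", "load_dataset", "resize_uniform", "save_dataset"]

_IMAGE_EXT = (".tif", ".tiff", ".png")
_RESERVED = ("cell_id", "label")

#: minimal input side the network architecture can reduce
MIN_SIDE = 8


@dataclass
class CellImageSet:
    """n cells x C channels x S x S intensities with labels and covariates."""

    cell_ids: list[str]
    images: np.ndarray  # (n, C, S, S) float32 in [0, 1]
    channel_names: list[str]
    labels: np.ndarray  # (n,) int, values in {0..K-1}
    label_names: list[str]
    covariates: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    @property
    def n_channels(self) -> int:
        return self.images.shape[1]

    @property
    def side(self) -> int:
        return self.images.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.label_names)

    def validate(self) -> None:
        n, c, h, w = self.images.shape
        if h != w:
            raise ValidationError(f"images not square: {h} x {w}")
        if n != len(self.cell_ids) or n != len(self.labels):
            raise ValidationError("cell_ids, images and labels disagree in length")
        if len(set(self.cell_ids)) != n:
            raise ValidationError("cell_ids are not unique")
        if c != len(self.channel_names):
            raise ValidationError("channel_names length != image channel count")
        if not np.all(np.isfinite(self.images)):
            raise ValidationError("non-finite intensities")
        if self.images.min() < 0 or self.images.max() > 1:
            raise ValidationError("intensities outside [0, 1]")
        if len(self.labels) and (self.labels.min() < 0
                                 or self.labels.max() >= len(self.label_names)):
            raise ValidationError("label index outside {0..K-1}")
        for name, v in self.covariates.items():
            if len(v) != n:
                raise ValidationError(f"covariate {name!r} length != n")

    def select_channels(self, channels: list[str]) -> "CellImageSet":
        missing = [c for c in channels if c not in self.channel_names]
        if missing:
            raise ConfigurationError(f"unknown channels: {missing}")
        idx = [self.channel_names.index(c) for c in channels]
        return CellImageSet(
            cell_ids=list(self.cell_ids),
            images=self.images[:, idx],
            channel_names=list(channels),
            labels=self.labels.copy(),
            label_names=list(self.label_names),
            covariates={k: v.copy() for k, v in self.covariates.items()},
        )

    def subset(self, indices: np.ndarray) -> "CellImageSet":
        indices = np.asarray(indices)
        return CellImageSet(
            cell_ids=[self.cell_ids[i] for i in indices],
            images=self.images[indices],
            channel_names=list(self.channel_names),
            labels=self.labels[indices],
            label_names=list(self.label_names),
            covariates={k: v[indices] for k, v in self.covariates.items()},
        )

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)


def resize_uniform(image: np.ndarray, side: int) -> np.ndarray:
    """Resize a 2-D image to side x side, bilinear, anti-aliased on downscale.

    Constant images stay constant; an image already at the target side is
    returned unchanged.
    """
    if side < MIN_SIDE:
        raise ConfigurationError(f"side {side} below minimal network input {MIN_SIDE}")
    if image.ndim != 2:
        raise ImageFormatError(f"expected a 2-D image, got shape {image.shape}")
    if image.shape == (side, side):
        return image
    downscale = image.shape[0] > side or image.shape[1] > side
    return resize(
        image.astype(np.float64),
        (side, side),
        order=1,
        anti_aliasing=downscale,
        mode="reflect",
        preserve_range=True,
    )


def _to_unit_range(raw: np.ndarray) -> np.ndarray:
    """Map an image's native dtype range into [0, 1]."""
    if np.issubdtype(raw.dtype, np.integer):
        return raw.astype(np.float64) / np.iinfo(raw.dtype).max
    return raw.astype(np.float64)


def _normalize(img: np.ndarray, rule: str) -> np.ndarray:
    if rule == "percentile":
        lo, hi = np.percentile(img, [1, 99])
        if hi <= lo:
            return np.zeros_like(img)
        return np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    if rule == "minmax":
        lo, hi = img.min(), img.max()
        if hi <= lo:
            return np.zeros_like(img)
        return (img - lo) / (hi - lo)
    if rule == "none":
        return np.clip(img, 0.0, 1.0)
    raise ConfigurationError(f"unknown normalization rule {rule!r}")


def _read_image(path: str) -> np.ndarray:
    try:
        if path.lower().endswith((".tif", ".tiff")):
            raw = tifffile.imread(path)
        else:
            raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt file, wrong codec, ...
        raise ImageLoadError(f"cannot decode image {path!r}: {exc}") from exc
    if raw.ndim != 2:
        raise ImageFormatError(
            f"image {path!r} is not 2-D single-channel (shape {raw.shape})"
        )
    return raw


def _infer_channel_columns(df: pd.DataFrame) -> list[str]:
    """Channel columns hold file paths; covariates are numeric."""
    channels = []
    for col in df.columns:
        if col in _RESERVED:
            continue
        first = df[col].dropna()
        if len(first) and isinstance(first.iloc[0], str) \
                and first.iloc[0].lower().endswith(_IMAGE_EXT):
            channels.append(col)
    return channels


def load_dataset(
    manifest_path: str,
    image_root: str,
    channels: list[str] | None = None,
    side: int = 64,
    normalize: str = "percentile",
) -> CellImageSet:
    """Load a manifest-indexed image set restricted to ``channels``.

    Every image is resized to ``side`` x ``side`` and brought into
    [0, 1] under the ``normalize`` rule ("percentile" rescales each
    image by its 1st/99th percentile and clips; "minmax" by min/max;
    "none" trusts the stored values, which lets already-normalized
    float TIFFs round-trip exactly).
    """
    if not os.path.exists(manifest_path):
        raise ManifestError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path)
    for col in _RESERVED:
        if col not in df.columns:
            raise ManifestError(f"manifest lacks required column {col!r}")
    available = _infer_channel_columns(df)
    if channels is None:
        channels = available
    unknown = [c for c in channels if c not in available]
    if unknown:
        raise ConfigurationError(
            f"requested channels {unknown} not in manifest columns {available}"
        )
    if not channels:
        raise ManifestError("manifest defines no channel columns")

    label_names = sorted(df["label"].astype(str).unique())
    label_index = {name: i for i, name in enumerate(label_names)}
    n = len(df)
    images = np.empty((n, len(channels), side, side), dtype=np.float32)
    cell_ids = [str(c) for c in df["cell_id"]]
    labels = np.array([label_index[str(l)] for l in df["label"]], dtype=np.intp)

    for i, row in enumerate(df.itertuples(index=False)):
        for j, ch in enumerate(channels):
            rel = getattr(row, ch, None) or df.iloc[i][ch]
            path = os.path.join(image_root, str(rel))
            try:
                raw = _read_image(path)
            except FileNotFoundError as exc:
                raise ImageLoadError(
                    f"cell {cell_ids[i]!r}: missing image {path!r}"
                ) from exc
            img = _normalize(_to_unit_range(raw), normalize)
            images[i, j] = resize_uniform(img, side)

    covariates = {}
    for col in df.columns:
        if col in _RESERVED or col in available:
            continue
        v = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=np.float64)
        covariates[col] = v

    out = CellImageSet(
        cell_ids=cell_ids,
        images=np.clip(images, 0.0, 1.0),
        channel_names=list(channels),
        labels=labels,
        label_names=label_names,
        covariates=covariates,
    )
    out.validate()
    return out


def save_dataset(
    dataset: CellImageSet,
    out_dir: str,
    fmt: str = "tiff",
    extra_columns: dict[str, np.ndarray] | None = None,
) -> str:
    """Write images plus ``manifest.csv``; returns the manifest path.

    ``fmt="tiff"`` stores lossless float32; ``fmt="png"`` stores 16-bit
    integers (quantized).
    """
    if fmt not in ("tiff", "png"):
        raise ConfigurationError(f"unknown image format {fmt!r}")
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)
    ext = ".tiff" if fmt == "tiff" else ".png"
    rows = []
    for i, cid in enumerate(dataset.cell_ids):
        row = {"cell_id": cid, "label": dataset.label_names[dataset.labels[i]]}
        for j, ch in enumerate(dataset.channel_names):
            rel = os.path.join("images", f"{cid}_{ch}{ext}")
            path = os.path.join(out_dir, rel)
            img = dataset.images[i, j]
            if fmt == "tiff":
                tifffile.imwrite(path, img.astype(np.float32))
            else:
                iio.imwrite(path, np.round(img * 65535).astype(np.uint16))
            row[ch] = rel
        for name, v in dataset.covariates.items():
            row[name] = v[i]
        if extra_columns:
            for name, v in extra_columns.items():
                row[name] = v[i]
        rows.append(row)
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
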