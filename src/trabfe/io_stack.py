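"""Reading, writing and preprocessing of microCT slice stacks.

A specimen is represented as an :class:`ImageStack`: an ordered stack of
binary 2-D slices (1 = bone) with physical calibration (in-plane pixel size
and axial slice increment, both in µm) and an optional in-plane region-of-
interest mask (the cylindrical specimen cross-section).

On disk a stack is either a multi-page TIFF or a directory of numbered PNG
slices, in both cases accompanied by a small JSON sidecar carrying the µm
calibration (image formats store µm calibration too inconsistently to rely
on). Binary data round-trips losslessly.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import ConfigurationError, StackStructureError

__all__ = [
    "ImageStack",
    "read_stack",
    "write_stack",
    "threshold_stack",
    "apply_cylinder_mask",
]

SIDECAR_NAME = "metadata.json"


@dataclass
class ImageStack:
    """Ordered binary slice stack with physical calibration.

    Parameters
    ----------
    slices
        ``(n_slices, ny, nx)`` array; values strictly in {0, 1} (1 = bone).
    pixel_size
        In-plane pixel edge length in µm (square pixels).
    slice_increment
        Axial distance between consecutive slices in µm.
    mask
        Optional ``(ny, nx)`` boolean in-plane region of interest. When
        present, every bone pixel lies inside the mask.
    """

    slices: np.ndarray
    pixel_size: float
    slice_increment: float
    mask: np.ndarray | None = None
    mask_diameter_mm: float | None = field(default=None)

    def __post_init__(self):
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3:
            raise StackStructureError(
                f"slices must be a (n, ny, nx) array, got ndim={self.slices.ndim}")
        vals = np.unique(self.slices)
        if not np.isin(vals, [0, 1]).all():
            raise StackStructureError("slice values must be strictly binary {0,1}")
        self.slices = self.slices.astype(np.uint8)
        if self.pixel_size <= 0 or self.slice_increment <= 0:
            raise ConfigurationError("pixel_size and slice_increment must be > 0")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.slices.shape[1:]:
                raise StackStructureError("mask shape must match slice shape")
            if (self.slices[:, ~self.mask] != 0).any():
                raise StackStructureError("bone pixels found outside the mask")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """(n_slices, ny, nx)."""
        return self.slices.shape

    def bone_pixel_count(self) -> int:
        return int(self.slices.sum())

    def __eq__(self, other) -> bool:
        if not isinstance(other, ImageStack):
            return NotImplemented
        same_mask = (
            (self.mask is None and other.mask is None)
            or (self.mask is not None and other.mask is not None
                and np.array_equal(self.mask, other.mask))
        )
        return (
            np.array_equal(self.slices, other.slices)
            and self.pixel_size == other.pixel_size
            and self.slice_increment == other.slice_increment
            and same_mask
        )


def _numeric_key(path: Path):
    """Sort key: numeric value of digit runs in the stem, then the name."""
    m = re.findall(r"\d+", path.stem)
    return (tuple(int(x) for x in m), path.name)


def _load_sidecar(path: Path) -> dict:
    if not path.exists():
        raise ConfigurationError(f"missing metadata sidecar {path}")
    with open(path) as fh:
        meta = json.load(fh)
    for key in ("pixel_size_um", "slice_increment_um"):
        if key not in meta:
            raise ConfigurationError(f"sidecar {path} lacks required key {key!r}")
    return meta


def read_stack(path, format_hint: str | None = None) -> ImageStack:
    """Read an :class:`ImageStack` from a multi-page TIFF or a PNG directory.

    ``path`` is either a ``.tif``/``.tiff`` file (sidecar ``<stem>.json``
    alongside it) or a directory of numbered single-slice images with a
    ``metadata.json`` sidecar inside. Slices are ordered by page index or by
    numeric filename sort. Values are binarized strictly to {0, 1}.
    """
    path = Path(path)
    if path.is_dir() or format_hint == "png_dir":
        meta = _load_sidecar(path / SIDECAR_NAME)
        files = sorted(
            (p for p in path.iterdir()
             if p.suffix.lower() in {".png", ".tif", ".tiff"}
             and not p.name.startswith("mask")),
            key=_numeric_key,
        )
        if not files:
            raise StackStructureError(f"no slice images found in {path}")
        imgs = [np.asarray(iio.imread(f)) for f in files]
        shapes = {im.shape for im in imgs}
        if len(shapes) != 1:
            raise StackStructureError(f"inconsistent slice shapes: {sorted(shapes)}")
        arr = np.stack(imgs)
        mask = None
        if (path / "mask.png").exists():
            mask = np.asarray(iio.imread(path / "mask.png")) > 0
    else:
        meta = _load_sidecar(path.with_suffix(".json"))
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        mask_path = path.with_name(path.stem + ".mask.png")
        mask = np.asarray(iio.imread(mask_path)) > 0 if mask_path.exists() else None
    arr = (arr > 0).astype(np.uint8)
    return ImageStack(
        slices=arr,
        pixel_size=float(meta["pixel_size_um"]),
        slice_increment=float(meta["slice_increment_um"]),
        mask=mask,
        mask_diameter_mm=meta.get("mask_diameter_mm"),
    )


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack readable by :func:`read_stack` (lossless for binary data).

    ``path`` ending in ``.tif``/``.tiff`` writes a multi-page TIFF plus a
    JSON sidecar; any other path is treated as a directory and receives
    zero-padded numbered PNGs plus ``metadata.json``.
    """
    path = Path(path)
    meta = {
        "pixel_size_um": stack.pixel_size,
        "slice_increment_um": stack.slice_increment,
    }
    if stack.mask_diameter_mm is not None:
        meta["mask_diameter_mm"] = stack.mask_diameter_mm
    data = (stack.slices * 255).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, data, photometric="minisblack")
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=1)
        if stack.mask is not None:
            iio.imwrite(path.with_name(path.stem + ".mask.png"),
                        (stack.mask * 255).astype(np.uint8))
    else:
        path.mkdir(parents=True, exist_ok=True)
        width = max(3, len(str(stack.n_slices - 1)))
        for i in range(stack.n_slices):
            iio.imwrite(path / f"{i:0{width}d}.png", data[i])
        with open(path / SIDECAR_NAME, "w") as fh:
            json.dump(meta, fh, indent=1)
        if stack.mask is not None:
            iio.imwrite(path / "mask.png", (stack.mask * 255).astype(np.uint8))


def threshold_stack(grey_stack, threshold: float, pixel_size: float,
                    slice_increment: float) -> ImageStack:
    """Binarize a grey-value stack: a pixel is bone iff grey ≥ threshold.

    The ≥ rule is a documented convention (the boundary case is not fixed by
    the source device settings); it makes thresholding monotone — raising the
    threshold never adds bone pixels.
    """
    grey = np.asarray(grey_stack)
    if grey.ndim != 3:
        raise StackStructureError("grey stack must be (n, ny, nx)")
    lo, hi = _representable_range(grey.dtype)
    if not (lo <= threshold <= hi):
        raise ValueError(
            f"threshold {threshold} outside representable grey range [{lo}, {hi}]")
    return ImageStack(
        slices=(grey >= threshold).astype(np.uint8),
        pixel_size=pixel_size,
        slice_increment=slice_increment,
    )


def _representable_range(dtype) -> tuple[float, float]:
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return float(info.min), float(info.max)
    info = np.finfo(dtype)
    return float(info.min), float(info.max)


def apply_cylinder_mask(stack: ImageStack, diameter_mm: float) -> ImageStack:
    """Mask the stack to a centred circular cross-section (specimen cylinder).

    A pixel belongs to the disc iff its centre lies within ``diameter_mm/2``
    of the in-plane image centre (pixel-centre-in-disc rule — unambiguous for
    partial pixels). Bone outside the disc is cleared; the mask is stored on
    the result. Idempotent for a fixed diameter.
    """
    n, ny, nx = stack.shape
    p = stack.pixel_size  # µm
    radius_um = diameter_mm * 1000.0 / 2.0
    if 2 * radius_um > min(nx, ny) * p:
        raise ValueError(
            f"mask diameter {diameter_mm} mm exceeds the field of view "
            f"({nx * p / 1000:.3f} x {ny * p / 1000:.3f} mm)")
    cx, cy = nx * p / 2.0, ny * p / 2.0
    xs = (np.arange(nx) + 0.5) * p
    ys = (np.arange(ny) + 0.5) * p
    dist2 = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2
    mask = dist2 <= radius_um**2
    return ImageStack(
        slices=stack.slices * mask.astype(np.uint8),
        pixel_size=stack.pixel_size,
        slice_increment=stack.slice_increment,
        mask=mask,
        mask_diameter_mm=diameter_mm,
    )
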