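"""Voxel-model construction and resolution coarsening.

The basic model is built at the native 36 µm resolution: a voxel between
two consecutive slices is bone only when the pixel at that (i, j) position
is bone in *both* bounding slices (the AND rule). Four coarsening schemes
then emulate lower-resolution acquisition:

* **Hexahedral (H)** — tile the basic model with cubes (cuberrilles) of side
  s; an output voxel is bone when bone fills strictly more than 50 % of the
  full nominal cuberrille volume. In-plane and axial resolution degrade
  together; no slices are discarded.
* **First-Last (F-L)** — keep only every m-th slice (m = d / 36 µm) and AND
  the two slices bounding each d-long layer: the pair is d apart.
* **First-Second (F-S)** — AND the two *successive* slices (36 µm apart) at
  the start of each d-long layer, then extrude to length d.
* **First-Third (F-T)** — like F-S but the pair is 72 µm apart (slices k·m
  and k·m + 2); d is restricted to multiples of 72 µm.

F-L/F-S/F-T voxels are 36 × 36 × d µm prisms; layers tile the axis from
slice 0 without overlap and trailing slices that do not complete a layer
are dropped, so the model never exceeds the source extent.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_stack import ImageStack

__all__ = [
    "VoxelModel",
    "build_basic_model",
    "coarsen_h",
    "coarsen_fl",
    "coarsen_fs",
    "coarsen_ft",
    "coarsen",
]

BASE_UM = 36.0
H_RANGE_UM = (72.0, 288.0)
D_RANGE_UM = (72.0, 1080.0)


@dataclass
class VoxelModel:
    """3-D bone occupancy grid with anisotropic voxel dimensions.

    ``occupancy`` is ``(nz, ny, nx)`` boolean; ``dx = dy`` is the in-plane
    voxel size and ``dz`` the axial voxel length, all in µm. ``method`` is
    one of ``basic | H | FL | FS | FT`` with ``param`` the cuberrille side s
    or voxel length d. ``mask`` (optional, in source-pixel resolution)
    carries the specimen cross-section for nominal-area purposes.
    """

    occupancy: np.ndarray
    dx: float
    dy: float
    dz: float
    method: str = "basic"
    param: float | None = None
    mask: np.ndarray | None = None
    mask_pixel_size: float | None = None

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy).astype(bool)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be 3-D (nz, ny, nx)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return self.dx * self.dy * self.dz * 1e-9

    @property
    def nominal_area_mm2(self) -> float:
        """Specimen cross-section: mask area when present, else the grid box."""
        if self.mask is not None:
            return float(self.mask.sum()) * (self.mask_pixel_size ** 2) * 1e-6
        nz, ny, nx = self.occupancy.shape
        return nx * self.dx * ny * self.dy * 1e-6

    @property
    def height_mm(self) -> float:
        return self.occupancy.shape[0] * self.dz * 1e-3

    def bone_voxel_count(self) -> int:
        return int(self.occupancy.sum())


def build_basic_model(stack: ImageStack) -> VoxelModel:
    """Basic 36 µm model: voxel k bone ⇔ pixel bone in slices k AND k+1.

    N slices produce N−1 voxel layers; requires cubic base voxels
    (slice increment equal to pixel size).
    """
    if stack.n_slices < 2:
        raise ValueError("basic model needs at least 2 slices")
    if stack.slice_increment != stack.pixel_size:
        raise ValueError(
            "basic model requires slice_increment == pixel_size (cubic voxels)")
    s = stack.slices.astype(bool)
    occ = s[:-1] & s[1:]
    return VoxelModel(occ, stack.pixel_size, stack.pixel_size,
                      stack.slice_increment, method="basic",
                      param=stack.pixel_size, mask=stack.mask,
                      mask_pixel_size=stack.pixel_size if stack.mask is not None else None)


def _check_multiple(value: float, step: float, name: str) -> int:
    m = value / step
    if abs(m - round(m)) > 1e-9 or round(m) < 1:
        raise ValueError(f"{name}={value} µm must be a positive multiple of {step} µm")
    return int(round(m))


def _check_range(value: float, rng: tuple[float, float], name: str,
                 enforce: bool) -> None:
    if enforce and not (rng[0] <= value <= rng[1]):
        raise ValueError(
            f"{name}={value} µm outside the study range [{rng[0]}, {rng[1]}] "
            "(pass enforce_range=False to override)")


def coarsen_h(model: VoxelModel, s: float, enforce_range: bool = True) -> VoxelModel:
    """Hexahedral coarsening: cubes of side s, strict >50 % fill rule.

    Cuberrilles are anchored at the grid origin; partial cuberrilles at the
    far boundaries are evaluated over the full nominal cuberrille volume
    (missing sub-voxels count as empty).
    """
    if not (model.dx == model.dy == model.dz):
        raise ValueError("H coarsening requires a cubic-voxel (basic) model")
    k = _check_multiple(s, model.dx, "s")
    if k < 2:
        raise ValueError("s must be at least twice the base voxel size")
    _check_range(s, H_RANGE_UM, "s", enforce_range)
    occ = model.occupancy
    nz, ny, nx = occ.shape
    pad = [(0, (-n) % k) for n in (nz, ny, nx)]
    occp = np.pad(occ, pad, constant_values=False)
    counts = occp.reshape(occp.shape[0] // k, k,
                          occp.shape[1] // k, k,
                          occp.shape[2] // k, k).sum(axis=(1, 3, 5))
    out = counts * 2 > k**3  # strictly more than 50 %
    return VoxelModel(out, s, s, s, method="H", param=s,
                      mask=model.mask, mask_pixel_size=model.mask_pixel_size)


def _layered(stack: ImageStack, d: float, second_offset, method: str,
             enforce_range: bool) -> VoxelModel:
    """Common machinery for F-L / F-S / F-T: AND of two source slices per layer."""
    m = _check_multiple(d, stack.slice_increment, "d")
    _check_range(d, D_RANGE_UM, "d", enforce_range)
    n = stack.n_slices
    min_slices = m + 1 if method != "FT" else m + 2
    if n < min_slices:
        raise ValueError(f"{method} with d={d} needs at least {min_slices} slices")
    n_layers = (n - 1) // m  # extent-limited: model height <= stack height
    s = stack.slices.astype(bool)
    first = np.arange(n_layers) * m
    second = first + (m if second_offset is None else second_offset)
    # layers whose second slice is missing cannot be built (F-T near the end)
    valid = second <= n - 1
    first, second = first[valid], second[valid]
    occ = s[first] & s[second]
    return VoxelModel(occ, stack.pixel_size, stack.pixel_size, d,
                      method=method, param=d, mask=stack.mask,
                      mask_pixel_size=stack.pixel_size if stack.mask is not None else None)


def coarsen_fl(stack: ImageStack, d: float, enforce_range: bool = True) -> VoxelModel:
    """First-Last: layer k from slices k·m and (k+1)·m — the pair is d apart."""
    _check_multiple(d, BASE_UM, "d")
    return _layered(stack, d, None, "FL", enforce_range)


def coarsen_fs(stack: ImageStack, d: float, enforce_range: bool = True) -> VoxelModel:
    """First-Second: layer k from the successive pair k·m, k·m + 1 (36 µm apart)."""
    _check_multiple(d, BASE_UM, "d")
    return _layered(stack, d, 1, "FS", enforce_range)


def coarsen_ft(stack: ImageStack, d: float, enforce_range: bool = True) -> VoxelModel:
    """First-Third: layer k from the pair k·m, k·m + 2 (72 µm apart); d ∈ 72·ℕ."""
    _check_multiple(d, 2 * BASE_UM, "d")
    return _layered(stack, d, 2, "FT", enforce_range)


_COARSENERS = {"FL": coarsen_fl, "FS": coarsen_fs, "FT": coarsen_ft}


def coarsen(stack: ImageStack, method: str, d: float,
            enforce_range: bool = True) -> VoxelModel:
    """Dispatch a coarsening method by name (``H | FL | FS | FT``).

    For H the basic model is built first and then coarsened; for the others
    the stack is consumed directly.
    """
    if method == "H":
        return coarsen_h(build_basic_model(stack), d, enforce_range)
    try:
        return _COARSENERS[method](stack, d, enforce_range)
    except KeyError:
        raise ValueError(f"unknown coarsening method {method!r}") from None
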