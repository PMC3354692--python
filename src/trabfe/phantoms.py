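"""Synthetic specimen generators.

The study's patient scans are not available, so validation and cohort
experiments run on synthetic stacks. Two families are provided:

* deterministic analytic fixtures — solid block, prism column, plate
  lattice, rod lattice — whose morphometric indices and apparent moduli
  have closed forms (a uniform prism occupying an area fraction φ of the
  cross-section carries apparent modulus φ·E under prescribed axial strain;
  an infinite slab of thickness t has local thickness t);
* a stochastic Gaussian-random-field (grf) phantom — seeded white noise
  blurred to a chosen correlation length and thresholded at the empirical
  quantile — which spans the study's BV/TV range (0.068–0.392) with a
  trabecular-like bicontinuous geometry.

Defaults mirror the study's acquisition: 36 µm pixels and slice increment.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_stack import ImageStack

__all__ = [
    "PhantomSpec",
    "make_solid_block",
    "make_prism_column",
    "make_plate_lattice",
    "make_rod_lattice",
    "make_grf_phantom",
    "make_phantom",
]

DEFAULT_PIXEL_UM = 36.0
#: Default stochastic-phantom grid: 64x64 pixels x 120 slices at 36 µm
#: (about 2.3 x 2.3 x 4.3 mm) — desk-scale FE solves with >= 10 coarsening
#: steps along the axis.
DEFAULT_GRF_SHAPE = (64, 64, 120)


@dataclass
class PhantomSpec:
    """Declarative phantom description, expressible in the pipeline config."""

    kind: str  # solid_block | prism_column | plate_lattice | rod_lattice | grf
    shape: tuple[int, int, int] = DEFAULT_GRF_SHAPE  # (nx, ny, nz)
    pixel_size: float = DEFAULT_PIXEL_UM
    slice_increment: float = DEFAULT_PIXEL_UM
    target_bvtv: float = 0.22
    correlation_length: float = 80.0  # µm in-plane, grf only
    axial_elongation: float = 3.0  # axial/in-plane correlation ratio, grf only
    seed: int = 0  # grf only; deterministic kinds ignore it
    params: dict = field(default_factory=dict)  # phi / thickness_px / ...


def _stack(arr_xyz_last, pixel_size, slice_increment) -> ImageStack:
    return ImageStack(slices=arr_xyz_last, pixel_size=pixel_size,
                      slice_increment=slice_increment)


def make_solid_block(shape, pixel_size=DEFAULT_PIXEL_UM,
                     slice_increment=DEFAULT_PIXEL_UM) -> ImageStack:
    """Fully solid stack: ``shape`` = (nx, ny, nz) pixels/slices, all bone."""
    nx, ny, nz = shape
    if min(shape) <= 0:
        raise ValueError("shape must be positive")
    return _stack(np.ones((nz, ny, nx), np.uint8), pixel_size, slice_increment)


def make_prism_column(shape, phi, pixel_size=DEFAULT_PIXEL_UM,
                      slice_increment=DEFAULT_PIXEL_UM) -> ImageStack:
    """Axis-aligned solid rectangular column occupying area fraction ``phi``.

    Every slice carries the same whole-pixel rectangle, so the column spans
    all slices and the apparent-modulus identity E_app = phi * E_tissue holds
    exactly. ``phi`` must be representable as a whole-pixel rectangle
    (exactness is the point of this fixture).
    """
    nx, ny, nz = shape
    if not 0 < phi <= 1:
        raise ValueError("phi must be in (0, 1]")
    area = phi * nx * ny
    if abs(area - round(area)) > 1e-9:
        raise ValueError(f"phi={phi} does not give a whole-pixel area on {nx}x{ny}")
    area = int(round(area))
    # most-square divisor pair fitting the slice
    best = None
    for wx in range(1, nx + 1):
        if area % wx == 0 and area // wx <= ny:
            wy = area // wx
            score = abs(wx / nx - wy / ny)
            if best is None or score < best[0]:
                best = (score, wx, wy)
    if best is None:
        raise ValueError(f"phi={phi} not representable as a rectangle in {nx}x{ny}")
    _, wx, wy = best
    x0, y0 = (nx - wx) // 2, (ny - wy) // 2
    sl = np.zeros((ny, nx), np.uint8)
    sl[y0:y0 + wy, x0:x0 + wx] = 1
    return _stack(np.repeat(sl[None], nz, axis=0), pixel_size, slice_increment)


def make_plate_lattice(shape, thickness_px, period_px,
                       pixel_size=DEFAULT_PIXEL_UM,
                       slice_increment=DEFAULT_PIXEL_UM) -> ImageStack:
    """Parallel slabs: thickness t, period p along x, constant along y and z.

    An analytic fixture for the plate-model indices: BV/TV = t/p, Tb.Th = t,
    Tb.N = 1/p. Slabs are centred within each period so that (for p ≥ t + 2)
    no slab touches the lateral image border, keeping the local-thickness
    value exactly t.
    """
    nx, ny, nz = shape
    if not 0 < thickness_px < period_px:
        raise ValueError("need 0 < thickness_px < period_px")
    if period_px > nx:
        raise ValueError("period exceeds in-plane extent")
    start = (period_px - thickness_px) // 2
    x = np.arange(nx)
    row = ((x - start) % period_px < thickness_px).astype(np.uint8)
    sl = np.repeat(row[None], ny, axis=0)
    return _stack(np.repeat(sl[None], nz, axis=0), pixel_size, slice_increment)


def make_rod_lattice(shape, width_px, spacing_px,
                     pixel_size=DEFAULT_PIXEL_UM,
                     slice_increment=DEFAULT_PIXEL_UM) -> ImageStack:
    """Square grid of axial rods: width w, period (w + spacing) in-plane."""
    nx, ny, nz = shape
    period = width_px + spacing_px
    if width_px <= 0 or spacing_px < 0 or period > min(nx, ny):
        raise ValueError("invalid rod geometry for this shape")
    gx = np.arange(nx) % period < width_px
    gy = np.arange(ny) % period < width_px
    sl = np.outer(gy, gx).astype(np.uint8)
    return _stack(np.repeat(sl[None], nz, axis=0), pixel_size, slice_increment)


def make_grf_phantom(shape=DEFAULT_GRF_SHAPE, target_bvtv=0.22,
                     correlation_length=80.0, seed=0,
                     axial_elongation=3.0,
                     pixel_size=DEFAULT_PIXEL_UM,
                     slice_increment=DEFAULT_PIXEL_UM) -> ImageStack:
    """Thresholded Gaussian random field with controlled bone fraction.

    Seeded white noise is blurred with a (periodic) anisotropic Gaussian
    kernel — in-plane standard deviation ``correlation_length`` (µm, an
    analogue of trabecular feature size) and ``axial_elongation`` times that
    along the specimen axis, emulating the preferential alignment of
    femoral-head trabeculae with the loading direction — then thresholded
    at the empirical ``1 - target_bvtv`` quantile, so the realized pixel
    bone fraction is within ±0.01 of the target by construction.
    Bit-reproducible for a fixed seed.
    """
    nx, ny, nz = shape
    if not 0.02 < target_bvtv < 0.6:
        raise ValueError("target_bvtv must lie in (0.02, 0.6)")
    if correlation_length <= 0:
        raise ValueError("correlation_length must be > 0")
    if axial_elongation < 1:
        raise ValueError("axial_elongation must be >= 1")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((nz, ny, nx))
    sigma = (axial_elongation * correlation_length / slice_increment,
             correlation_length / pixel_size,
             correlation_length / pixel_size)
    fieldv = gaussian_filter(noise, sigma=sigma, mode="wrap")
    thr = np.quantile(fieldv, 1.0 - target_bvtv)
    bone = (fieldv >= thr).astype(np.uint8)
    realized = bone.mean()
    if abs(realized - target_bvtv) > 0.01:
        raise ValueError(
            f"target BV/TV {target_bvtv} unreachable on grid {shape} "
            f"(realized {realized:.3f}); use a larger grid")
    return _stack(bone, pixel_size, slice_increment)


def make_grf_cohort(n: int, target_bvtv: float, shape=DEFAULT_GRF_SHAPE,
                    base_seed: int = 0, correlation_length: float = 80.0,
                    axial_elongation: float = 3.0,
                    pixel_size: float = DEFAULT_PIXEL_UM,
                    slice_increment: float = DEFAULT_PIXEL_UM,
                    max_tries: int | None = None) -> list[tuple[int, ImageStack]]:
    """``n`` mechanically measurable grf specimens as ``(seed, stack)`` pairs.

    Specimens are drawn at consecutive seeds from ``base_seed`` and screened
    for a load path: the largest face-connected component of the basic voxel
    model must touch both end layers, otherwise the specimen has zero
    apparent stiffness and no relative-modulus curve exists for it. The
    screen is a fixed measurability rule applied identically at every
    density (at low BV/TV a finite window of a random field is occasionally
    disconnected, where an intact specimen of the real material would not
    be). Deterministic for a fixed ``base_seed``.
    """
    from scipy import ndimage

    from .model_build import build_basic_model

    if max_tries is None:
        max_tries = 20 * n
    out: list[tuple[int, ImageStack]] = []
    structure = ndimage.generate_binary_structure(3, 1)
    for attempt in range(max_tries):
        seed = base_seed + attempt
        stack = make_grf_phantom(shape, target_bvtv, correlation_length, seed,
                                 axial_elongation, pixel_size, slice_increment)
        occ = build_basic_model(stack).occupancy
        labels, ncomp = ndimage.label(occ, structure=structure)
        if ncomp == 0:
            continue
        counts = np.bincount(labels.ravel())[1:]
        comp = labels == (int(np.argmax(counts)) + 1)
        if comp[0].any() and comp[-1].any():
            out.append((seed, stack))
            if len(out) == n:
                return out
    raise ValueError(
        f"could not draw {n} load-bearing specimens at BV/TV {target_bvtv} "
        f"on grid {shape} within {max_tries} tries")


def make_phantom(spec: PhantomSpec) -> ImageStack:
    """Build the stack described by a :class:`PhantomSpec`."""
    kw = dict(pixel_size=spec.pixel_size, slice_increment=spec.slice_increment)
    if spec.kind == "solid_block":
        return make_solid_block(spec.shape, **kw)
    if spec.kind == "prism_column":
        return make_prism_column(spec.shape, spec.params["phi"], **kw)
    if spec.kind == "plate_lattice":
        return make_plate_lattice(spec.shape, spec.params["thickness_px"],
                                  spec.params["period_px"], **kw)
    if spec.kind == "rod_lattice":
        return make_rod_lattice(spec.shape, spec.params["width_px"],
                                spec.params["spacing_px"], **kw)
    if spec.kind == "grf":
        return make_grf_phantom(spec.shape, spec.target_bvtv,
                                spec.correlation_length, spec.seed,
                                spec.axial_elongation, **kw)
    raise ValueError(f"unknown phantom kind {spec.kind!r}")
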