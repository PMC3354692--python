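"""Voxel-to-element conversion and connectivity filtering.

Each bone voxel is converted directly into 8-node cubic (trilinear
hexahedral) elements on a regular lattice: a cubic voxel becomes one
element; an elongated 36 × 36 × d voxel becomes d/36 stacked cubic
elements. Shared nodes merge exactly through integer lattice addressing.

Elements connected to the rest of the model only through edges or corners
transmit no stiffness through conforming hexahedra and make the stiffness
matrix singular, so before solving, everything outside the largest
face-connected component is eliminated (ties between equally sized
components are broken towards the component containing the lowest element
index).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .model_build import VoxelModel

__all__ = ["HexMesh", "voxels_to_elements", "filter_connectivity", "write_mesh_text"]

#: Standard node ordering of a hexahedron: bottom face counter-clockwise,
#: then top face; offsets in (x, y, z).
NODE_OFFSETS = np.array([
    (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
    (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
], dtype=np.int64)


@dataclass
class HexMesh:
    """Regular lattice of identical cubic elements.

    ``element_grid`` is (nez, ney, nex) boolean; ``h`` the common element
    edge length in µm; ``nominal_area_mm2`` the specimen cross-section used
    for the apparent modulus. Node numbering is derived lazily from the
    integer lattice of referenced element corners.
    """

    element_grid: np.ndarray
    h: float
    nominal_area_mm2: float
    provenance: str = ""
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.element_grid = np.asarray(self.element_grid, bool)
        if self.element_grid.ndim != 3:
            raise ValueError("element_grid must be 3-D (nez, ney, nex)")

    @property
    def n_elements(self) -> int:
        return int(self.element_grid.sum())

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.element_grid.shape

    @property
    def height_mm(self) -> float:
        return self.element_grid.shape[0] * self.h * 1e-3

    def _build_tables(self):
        if "nodes" in self._cache:
            return
        nez, ney, nex = self.element_grid.shape
        ez, ey, ex = np.nonzero(self.element_grid)
        # corner lattice keys (nex+1, ney+1, nez+1 wide)
        kx, ky, kz = nex + 1, ney + 1, nez + 1
        keys = np.empty((ez.size, 8), np.int64)
        for a, (ox, oy, oz) in enumerate(NODE_OFFSETS):
            keys[:, a] = ((ez + oz) * ky + (ey + oy)) * kx + (ex + ox)
        uniq, inv = np.unique(keys, return_inverse=True)
        elements = inv.reshape(ez.size, 8).astype(np.int64)
        gz, rem = np.divmod(uniq, ky * kx)
        gy, gx = np.divmod(rem, kx)
        nodes = np.column_stack([gx, gy, gz]).astype(float) * self.h  # µm
        self._cache.update(nodes=nodes, elements=elements,
                           element_index=(ez, ey, ex))

    @property
    def nodes(self) -> np.ndarray:
        """(n_nodes, 3) coordinates in µm, (x, y, z)."""
        self._build_tables()
        return self._cache["nodes"]

    @property
    def elements(self) -> np.ndarray:
        """(n_elements, 8) node indices per element, standard hex ordering."""
        self._build_tables()
        return self._cache["elements"]

    @property
    def element_voxel_index(self):
        """(ez, ey, ex) arrays: element-grid position of each element (provenance)."""
        self._build_tables()
        return self._cache["element_index"]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def voxels_to_elements(model: VoxelModel, h: float | None = None) -> HexMesh:
    """Convert a voxel model to cubic hexahedral elements of edge ``h``.

    By default ``h`` is the model's in-plane voxel size, so a cubic voxel
    (basic or H model) maps to one element and a 36 × 36 × d voxel maps to
    d/36 stacked elements. All voxel dimensions must be integer multiples
    of ``h``.
    """
    if model.dx != model.dy:
        raise ValueError("in-plane voxel dimensions must be square")
    if h is None:
        h = model.dx
    reps = []
    for dim, name in ((model.dz, "dz"), (model.dy, "dy"), (model.dx, "dx")):
        r = dim / h
        if abs(r - round(r)) > 1e-9 or round(r) < 1:
            raise ValueError(f"voxel {name}={dim} µm is not a multiple of h={h} µm")
        reps.append(int(round(r)))
    grid = model.occupancy
    for ax, r in enumerate(reps):
        if r > 1:
            grid = np.repeat(grid, r, axis=ax)
    return HexMesh(grid, h, model.nominal_area_mm2,
                   provenance=f"{model.method}:{model.param}")


def filter_connectivity(mesh: HexMesh) -> HexMesh:
    """Keep only the largest face-connected component of the element graph.

    Face adjacency (6-connectivity) is the standard micro-FE criterion:
    edge- and corner-only contacts are removed. Idempotent; never increases
    the element count.
    """
    if mesh.n_elements == 0:
        raise ValueError("cannot filter an empty mesh")
    structure = ndimage.generate_binary_structure(3, 1)
    labels, n = ndimage.label(mesh.element_grid, structure=structure)
    if n <= 1:
        return mesh
    counts = np.bincount(labels.ravel())[1:]
    # np.argmax keeps the smallest label on ties = lowest first element index
    keep = int(np.argmax(counts)) + 1
    return HexMesh(labels == keep, mesh.h, mesh.nominal_area_mm2,
                   provenance=mesh.provenance)


def write_mesh_text(mesh: HexMesh, path) -> None:
    """Plain-text node/element blocks (coordinates in µm, 1-based indices)."""
    nodes, elements = mesh.nodes, mesh.elements
    with open(path, "w") as fh:
        fh.write(f"# hex mesh h={mesh.h} um, {len(nodes)} nodes, "
                 f"{len(elements)} elements\n*NODES\n")
        for i, (x, y, z) in enumerate(nodes, 1):
            fh.write(f"{i} {x:.1f} {y:.1f} {z:.1f}\n")
        fh.write("*ELEMENTS\n")
        for i, conn in enumerate(elements, 1):
            fh.write(f"{i} " + " ".join(str(c + 1) for c in conn) + "\n")
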