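"""Linear-elastic uniaxial compression of a hexahedral voxel mesh.

The specimen is compressed along the slice axis between two rigid,
frictionless platens: every node on the bottom face gets zero axial
displacement, every node on the top face gets the prescribed axial
displacement −ε·H (ε the apparent compressive strain, H the model height),
and lateral displacements are free everywhere. Because the bases constrain
only the axial direction, three lateral rigid-body modes remain; they are
suppressed minimally by pinning one bottom-face node in both lateral
directions and a second, non-collinear bottom-face node (same y, different
x) in y only. Both pins are compatible with the exact homogeneous solution
(uniform strain with free Poisson expansion about the first pin), so the
patch test is exact and the measured force is insensitive to the pin
choice.

All elements share one geometry and one isotropic material (tissue modulus
E, Poisson ratio ν), so a single 24 × 24 trilinear-hexahedron stiffness
matrix (2 × 2 × 2 Gauss quadrature — exact for this element) is reused for
every element. The assembled system is solved either by sparse direct
factorization or by Jacobi-preconditioned conjugate gradients started from
the homogeneous-strain field.

The outcome is the total axial reaction force F on the driven platen and
the apparent modulus E_app = (F / A) / ε, with A the *nominal* specimen
cross-section (mask or grid box), not the bone area.

Internal units: mm, GPa ⇒ forces in kN (reported in N).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg, splu

from .errors import MeshStructureError, SolverError
from .femesh import NODE_OFFSETS, HexMesh, filter_connectivity, voxels_to_elements
from .model_build import VoxelModel

__all__ = [
    "MaterialProps",
    "LoadCase",
    "FEResult",
    "element_stiffness",
    "assemble_and_solve",
    "apparent_modulus",
    "compute_apparent_modulus",
]

#: Direct factorization below this many free DOFs, CG above ("auto" policy).
#: Sparse LU of a voxel elasticity system at this size fits in a few GB and
#: beats Jacobi-CG by a wide margin on trabecular structures.
_DIRECT_DOF_LIMIT = 250_000


@dataclass(frozen=True)
class MaterialProps:
    """Homogeneous isotropic tissue: E in GPa (default 10), ν (default 0.3)."""

    e_tissue: float = 10.0
    nu: float = 0.3

    def __post_init__(self):
        if self.e_tissue <= 0:
            raise ValueError("e_tissue must be > 0")
        if not 0 <= self.nu < 0.5:
            raise ValueError("nu must be in [0, 0.5)")


@dataclass(frozen=True)
class LoadCase:
    """Uniaxial compression along the slice axis; ε defaults to 0.8 %."""

    strain: float = 0.008

    def __post_init__(self):
        if not 0 < self.strain < 0.05:
            raise ValueError("strain must be in (0, 0.05)")


@dataclass
class FEResult:
    displacements_um: np.ndarray  # (n_nodes, 3)
    force_n: float                # axial reaction magnitude on the driven face
    e_app_gpa: float
    iterations: int
    residual: float
    equilibrium_error: float      # |F_fixed + F_driven| / |F_driven|


@lru_cache(maxsize=32)
def element_stiffness(mat: MaterialProps, h: float, n_gauss: int = 2) -> np.ndarray:
    """24 × 24 stiffness of a cubic trilinear hexahedron of edge ``h`` µm.

    Symmetric positive-semidefinite with exactly six rigid-body zero-energy
    modes. The B-matrix integrand is quadratic per axis, so 2-point Gauss
    quadrature per axis is already exact; higher ``n_gauss`` serves as an
    independent refinement check.
    """
    E, nu = mat.e_tissue, mat.nu
    h_mm = h * 1e-3
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.array([
        [lam + 2 * mu, lam, lam, 0, 0, 0],
        [lam, lam + 2 * mu, lam, 0, 0, 0],
        [lam, lam, lam + 2 * mu, 0, 0, 0],
        [0, 0, 0, mu, 0, 0],
        [0, 0, 0, 0, mu, 0],
        [0, 0, 0, 0, 0, mu],
    ])
    xi_a = 2.0 * NODE_OFFSETS - 1.0  # local node coords, (8, 3) in (x, y, z)
    gp, gw = np.polynomial.legendre.leggauss(n_gauss)
    K = np.zeros((24, 24))
    detJ = (h_mm / 2.0) ** 3
    dxdxi = 2.0 / h_mm
    for p, wp in zip(gp, gw):
        for q, wq in zip(gp, gw):
            for r, wr in zip(gp, gw):
                xi = np.array([p, q, r])
                # dN/dxi_k for each node a
                dN = np.empty((8, 3))
                for a in range(8):
                    terms = 1.0 + xi_a[a] * xi
                    for k in range(3):
                        prod = 0.125 * xi_a[a, k]
                        for m2 in range(3):
                            if m2 != k:
                                prod *= terms[m2]
                        dN[a, k] = prod
                dNdx = dN * dxdxi
                B = np.zeros((6, 24))
                for a in range(8):
                    c = 3 * a
                    bx, by, bz = dNdx[a]
                    B[0, c] = bx
                    B[1, c + 1] = by
                    B[2, c + 2] = bz
                    B[3, c] = by
                    B[3, c + 1] = bx
                    B[4, c + 1] = bz
                    B[4, c + 2] = by
                    B[5, c] = bz
                    B[5, c + 2] = bx
                K += wp * wq * wr * detJ * (B.T @ D @ B)
    return 0.5 * (K + K.T)


def _assemble(mesh: HexMesh, Ke: np.ndarray) -> sparse.csr_array:
    """Global stiffness (3·n_nodes square) from one shared element matrix."""
    elements = mesh.elements
    ndof = 3 * mesh.n_nodes
    K = sparse.csr_array((ndof, ndof))
    edof = (3 * elements[:, :, None] + np.arange(3)).reshape(-1, 24)
    chunk = 20_000
    for lo in range(0, len(edof), chunk):
        dm = edof[lo:lo + chunk]
        rows = np.repeat(dm, 24, axis=1).ravel()
        cols = np.tile(dm, (1, 24)).ravel()
        vals = np.tile(Ke.ravel(), len(dm))
        K = K + sparse.coo_array((vals, (rows, cols)), shape=(ndof, ndof)).tocsr()
    return K


def _face_nodes(mesh: HexMesh):
    nodes = mesh.nodes
    h = mesh.h
    z_top = mesh.grid_shape[0] * h
    fixed = np.nonzero(np.abs(nodes[:, 2]) < 1e-9 * max(h, 1))[0]
    driven = np.nonzero(np.abs(nodes[:, 2] - z_top) < 1e-9 * z_top)[0]
    if fixed.size == 0:
        raise MeshStructureError("mesh has no nodes on the fixed loading face")
    if driven.size == 0:
        raise MeshStructureError("mesh has no nodes on the driven loading face")
    return fixed, driven


def assemble_and_solve(mesh: HexMesh, mat: MaterialProps = MaterialProps(),
                       load: LoadCase = LoadCase(), solver: str = "auto",
                       tol: float = 1e-8, maxiter: int | None = None) -> FEResult:
    """Solve prescribed-displacement compression on a filtered mesh.

    ``solver``: ``auto`` (direct for small systems, CG otherwise),
    ``direct`` or ``iterative``. CG uses a Jacobi preconditioner, relative
    residual ``tol``, and the homogeneous-strain field as the start vector.
    """
    if mesh.n_elements == 0:
        raise MeshStructureError("cannot solve an empty mesh")
    nodes = mesh.nodes * 1e-3  # mm
    fixed, driven = _face_nodes(mesh)
    height = mesh.height_mm

    Ke = element_stiffness(mat, mesh.h)
    K = _assemble(mesh, Ke)
    ndof = K.shape[0]

    # constrained axial DOFs on both faces
    prescribed = np.zeros(ndof)
    is_con = np.zeros(ndof, bool)
    is_con[3 * fixed + 2] = True
    is_con[3 * driven + 2] = True
    prescribed[3 * driven + 2] = -load.strain * height

    # minimal lateral rigid-body suppression on the fixed face
    fnodes = nodes[fixed]
    a_local = np.lexsort((fnodes[:, 0], fnodes[:, 1]))[0]
    node_a = fixed[a_local]
    same_y = fixed[np.abs(fnodes[:, 1] - fnodes[a_local, 1]) < 1e-12]
    others = same_y[same_y != node_a]
    if others.size == 0:  # degenerate single-column face
        others = fixed[fixed != node_a]
    node_b = others[np.argmax(np.abs(nodes[others, 0] - nodes[node_a, 0]))]
    is_con[3 * node_a] = True
    is_con[3 * node_a + 1] = True
    is_con[3 * node_b + 1] = True

    free = ~is_con
    Kff = K[free][:, free]
    rhs = -K[free][:, is_con] @ prescribed[is_con]

    u = prescribed.copy()
    n_free = int(free.sum())
    iterations = 0
    if solver == "auto":
        solver = "direct" if n_free <= _DIRECT_DOF_LIMIT else "iterative"
    if solver == "direct":
        u[free] = splu(Kff.tocsc()).solve(rhs)
    elif solver == "iterative":
        # homogeneous-strain start vector (exact for a solid prism)
        x0 = np.empty((len(nodes), 3))
        x0[:, 0] = mat.nu * load.strain * (nodes[:, 0] - nodes[node_a, 0])
        x0[:, 1] = mat.nu * load.strain * (nodes[:, 1] - nodes[node_a, 1])
        x0[:, 2] = -load.strain * nodes[:, 2]
        x0 = x0.ravel()[free]
        diag = Kff.diagonal()
        M = sparse.dia_array((1.0 / diag[None, :], [0]), shape=Kff.shape)
        count = [0]

        def cb(_):
            count[0] += 1

        sol, info = cg(Kff, rhs, x0=x0, rtol=tol, atol=0.0, M=M,
                       maxiter=maxiter or max(20_000, 60 * int(np.sqrt(n_free))),
                       callback=cb)
        iterations = count[0]
        if info != 0:
            res = float(np.linalg.norm(Kff @ sol - rhs) / np.linalg.norm(rhs))
            raise SolverError(f"CG failed to converge (info={info})",
                              iterations=iterations, residual=res)
        u[free] = sol
    else:
        raise ValueError(f"unknown solver {solver!r}")

    rhs_norm = float(np.linalg.norm(rhs)) or 1.0
    residual = float(np.linalg.norm(Kff @ u[free] - rhs)) / rhs_norm

    reactions = K @ u
    f_driven = float(reactions[3 * driven + 2].sum())  # kN, negative = compression
    f_fixed = float(reactions[3 * fixed + 2].sum())
    denom = max(abs(f_driven), 1e-300)
    equilibrium = abs(f_fixed + f_driven) / denom
    force_n = abs(f_driven) * 1e3
    e_app = apparent_modulus(force_n, mesh.nominal_area_mm2, load.strain,
                             warn_on_zero=False)
    return FEResult(displacements_um=(u.reshape(-1, 3) * 1e3), force_n=force_n,
                    e_app_gpa=e_app, iterations=iterations, residual=residual,
                    equilibrium_error=equilibrium)


def apparent_modulus(force_n: float, area_mm2: float, strain: float,
                     warn_on_zero: bool = True) -> float:
    """E_app = (F / A_nominal) / ε in GPa; A is the specimen cross-section."""
    if area_mm2 <= 0:
        raise ValueError("nominal area must be > 0")
    if strain <= 0:
        raise ValueError("strain must be > 0")
    if force_n == 0 and warn_on_zero:
        warnings.warn("zero reaction force: disconnected load path; E_app = 0",
                      stacklevel=2)
    return (force_n * 1e-3 / area_mm2) / strain


def compute_apparent_modulus(model: VoxelModel, mat: MaterialProps = MaterialProps(),
                             load: LoadCase = LoadCase(), solver: str = "auto",
                             tol: float = 1e-8) -> float:
    """Full chain model → mesh → filter → solve → E_app (GPa).

    A model whose filtered mesh does not reach both platens carries no load;
    it yields E_app = 0 with a warning rather than an error.
    """
    mesh = voxels_to_elements(model)
    if mesh.n_elements == 0:
        warnings.warn("empty model: E_app = 0", stacklevel=2)
        return 0.0
    mesh = filter_connectivity(mesh)
    try:
        result = assemble_and_solve(mesh, mat, load, solver=solver, tol=tol)
    except MeshStructureError as exc:
        warnings.warn(f"disconnected load path ({exc}); E_app = 0", stacklevel=2)
        return 0.0
    return result.e_app_gpa
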