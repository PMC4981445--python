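"""Voxel micro-FE homogenization under kinematic uniform boundary conditions.

Every bone voxel becomes one linear isotropic eight-node hexahedral element
(tissue modulus 12 GPa, Poisson ratio 0.3 by default).  Apparent elastic
properties follow from six load cases — three uniaxial normal strains and
three engineering shears — applied as kinematic uniform boundary conditions
(KUBC): every node on the surface of the bounding cube is displaced by
``u = eps_bar @ x`` and the interior is solved in equilibrium.  The
macroscopic stress of a case is the volume average of the element stresses
over the *total* cube volume (pores carry zero stress); the six stress
vectors assemble the 6x6 apparent stiffness ``C`` (Voigt order
xx, yy, zz, yz, xz, xy with engineering shear strains).  Young's moduli come
from the compliance ``S = C^-1`` as ``E_i = 1/S_ii``, relabelled so that
``E3`` is the largest; ``Gmin`` is the smallest of the three shear moduli.

KUBC yields an upper bound on the apparent stiffness; diagonal entries of
``C`` can only decrease when material is removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import LinearOperator, cg

from .volume import BinaryVolume, crop_centered

__all__ = [
    "FEModel",
    "LoadCase",
    "StiffnessResult",
    "CANONICAL_CASES",
    "extract_fe_cube",
    "element_stiffness",
    "build_model",
    "solve_case",
    "homogenize",
]

log = logging.getLogger(__name__)

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)

# local node order: index = dx + 2*dy + 4*dz over the unit-cube corners
_CORNERS = np.array(
    [[dx, dy, dz] for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)]
)[np.argsort([dx + 2 * dy + 4 * dz for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)])]


def isotropic_stiffness_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix (Voigt, engineering shear)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def _shape_gradients(xi: float, eta: float, zeta: float) -> np.ndarray:
    """(8,3) gradients of trilinear shape functions in natural coords."""
    g = np.empty((8, 3))
    for a in range(8):
        sx, sy, sz = 2 * _CORNERS[a] - 1
        g[a, 0] = sx * (1 + sy * eta) * (1 + sz * zeta) / 8.0
        g[a, 1] = (1 + sx * xi) * sy * (1 + sz * zeta) / 8.0
        g[a, 2] = (1 + sx * xi) * (1 + sy * eta) * sz / 8.0
    return g


def _b_matrix(grad_phys: np.ndarray) -> np.ndarray:
    """6x24 strain-displacement matrix from physical shape gradients."""
    B = np.zeros((6, 24))
    for a in range(8):
        gx, gy, gz = grad_phys[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c + 1] = gz  # gamma_yz
        B[3, c + 2] = gy
        B[4, c] = gz  # gamma_xz
        B[4, c + 2] = gx
        B[5, c] = gy  # gamma_xy
        B[5, c + 1] = gx
    return B


def element_stiffness(
    voxel_mm: float, E: float, nu: float, n_gauss: int = 2
) -> np.ndarray:
    """24x24 stiffness of a cubic trilinear hexahedron, Gauss-integrated.

    2x2x2 quadrature integrates the (per-variable quadratic) integrand
    exactly for a constant-Jacobian cube; higher ``n_gauss`` serves as an
    independent cross-check.
    """
    if E <= 0:
        raise ValueError("E must be positive")
    if not 0 <= nu < 0.5:
        raise ValueError("nu must lie in [0, 0.5)")
    D = isotropic_stiffness_matrix(E, nu)
    pts, wts = np.polynomial.legendre.leggauss(n_gauss)
    h = voxel_mm
    detJ = (h / 2.0) ** 3
    K = np.zeros((24, 24))
    for xi, wx in zip(pts, wts):
        for eta, wy in zip(pts, wts):
            for zeta, wz in zip(pts, wts):
                grad = _shape_gradients(xi, eta, zeta) * (2.0 / h)
                B = _b_matrix(grad)
                K += (wx * wy * wz * detJ) * (B.T @ D @ B)
    return 0.5 * (K + K.T)


def mean_b_matrix(voxel_mm: float) -> np.ndarray:
    """Volume-averaged 6x24 B matrix of a cube element (exact mean strain)."""
    pts, wts = np.polynomial.legendre.leggauss(2)
    B = np.zeros((6, 24))
    for xi, wx in zip(pts, wts):
        for eta, wy in zip(pts, wts):
            for zeta, wz in zip(pts, wts):
                grad = _shape_gradients(xi, eta, zeta) * (2.0 / voxel_mm)
                B += (wx * wy * wz / 8.0) * _b_matrix(grad)
    return B


@dataclass(frozen=True)
class LoadCase:
    """One canonical macroscopic strain (Voigt component ``index`` = 1)."""

    index: int  # 0..5 in (xx, yy, zz, yz, xz, xy)

    def __post_init__(self) -> None:
        if not 0 <= self.index < 6:
            raise ValueError("index must be in 0..5")

    @property
    def strain_tensor(self) -> np.ndarray:
        """Symmetric 3x3 tensor; engineering shear 1 -> tensor shear 1/2."""
        eps = np.zeros((3, 3))
        if self.index < 3:
            eps[self.index, self.index] = 1.0
        else:
            pairs = {3: (1, 2), 4: (0, 2), 5: (0, 1)}
            i, j = pairs[self.index]
            eps[i, j] = eps[j, i] = 0.5
        return eps


CANONICAL_CASES = tuple(LoadCase(i) for i in range(6))


@dataclass
class FEModel:
    """Assembled voxel mesh restricted to the largest face-connected component."""

    occupancy: np.ndarray  # bool (nx, ny, nz)
    voxel_mm: float
    tissue_E: float = 12.0  # GPa
    tissue_nu: float = 0.3
    removed_fraction: float = 0.0
    # assembly products (filled by build_model)
    node_ids: np.ndarray = field(default=None, repr=False)
    elem_nodes: np.ndarray = field(default=None, repr=False)
    node_coords: np.ndarray = field(default=None, repr=False)
    boundary_nodes: np.ndarray = field(default=None, repr=False)

    @property
    def n_elements(self) -> int:
        return int(self.occupancy.sum())

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def total_volume_mm3(self) -> float:
        return float(np.prod(self.occupancy.shape)) * self.voxel_mm**3


def build_model(
    mask: BinaryVolume,
    tissue_E: float = 12.0,
    tissue_nu: float = 0.3,
) -> FEModel:
    """Mesh a mask, keeping only its largest face-connected component.

    Edge/corner-only contacts transmit no well-posed hexahedral stiffness and
    floating fragments make the system singular, so anything outside the
    largest 6-connected component is dropped (the removed fraction is
    logged).  Equal-size ties break to the component containing the lowest
    lexicographic voxel.
    """
    if not mask.data.any():
        raise ValueError("empty mask")
    labels, n = ndimage.label(mask.data, structure=_FACE_STRUCT)
    sizes = np.bincount(labels.ravel())[1:]
    best = sizes.max()
    tied = np.flatnonzero(sizes == best) + 1
    if len(tied) > 1:
        # first label in a raster scan is the lowest lexicographic voxel
        first = labels.ravel()[np.isin(labels.ravel(), tied).argmax()]
        log.warning("component-size tie: keeping component at lowest voxel")
        keep = first
    else:
        keep = tied[0]
    occ = labels == keep
    removed = 1.0 - occ.sum() / mask.data.sum()
    if removed > 0:
        log.info("removed %.2f%% of bone voxels (disconnected)", 100 * removed)

    nx, ny, nz = occ.shape
    # global lattice node numbering restricted to nodes touching bone
    node_used = np.zeros((nx + 1, ny + 1, nz + 1), dtype=bool)
    ei, ej, ek = np.nonzero(occ)
    for dx, dy, dz in _CORNERS:
        node_used[ei + dx, ej + dy, ek + dz] = True
    node_ids = -np.ones(node_used.shape, dtype=np.int64)
    node_ids[node_used] = np.arange(node_used.sum())
    ni, nj, nk = np.nonzero(node_used)
    node_coords = np.stack([ni, nj, nk], axis=1).astype(np.float64) * mask.voxel_mm
    elem_nodes = np.empty((len(ei), 8), dtype=np.int64)
    for a, (dx, dy, dz) in enumerate(_CORNERS):
        elem_nodes[:, a] = node_ids[ei + dx, ej + dy, ek + dz]
    on_surface = (
        (ni == 0) | (ni == nx) | (nj == 0) | (nj == ny) | (nk == 0) | (nk == nz)
    )
    return FEModel(
        occupancy=occ,
        voxel_mm=mask.voxel_mm,
        tissue_E=tissue_E,
        tissue_nu=tissue_nu,
        removed_fraction=float(removed),
        node_ids=node_ids,
        elem_nodes=elem_nodes,
        node_coords=node_coords,
        boundary_nodes=np.flatnonzero(on_surface),
    )


def extract_fe_cube(mask: BinaryVolume, side_mm: float) -> BinaryVolume:
    """Centered sub-cube of physical side ``side_mm`` (whole-voxel rounding)."""
    return crop_centered(mask, side_mm)


def _assemble(model: FEModel) -> sparse.csr_matrix:
    Ke = element_stiffness(model.voxel_mm, model.tissue_E, model.tissue_nu)
    dofs = (3 * model.elem_nodes[:, :, None] + np.arange(3)).reshape(-1, 24)
    ne = dofs.shape[0]
    rows = np.repeat(dofs, 24, axis=1).ravel()
    cols = np.tile(dofs, (1, 24)).ravel()
    vals = np.tile(Ke.ravel(), ne)
    ndof = 3 * model.n_nodes
    K = sparse.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsr()
    return K


class _KUBCSystem:
    """Factor the free-free block once; reuse across the six load cases."""

    def __init__(self, model: FEModel):
        if len(model.boundary_nodes) == 0:
            raise ValueError("model touches no face of the cube: KUBC ill-posed")
        self.model = model
        self.K = _assemble(model)
        ndof = self.K.shape[0]
        pres = np.zeros(ndof, dtype=bool)
        for d in range(3):
            pres[3 * model.boundary_nodes + d] = True
        self.pres = np.flatnonzero(pres)
        self.free = np.flatnonzero(~pres)
        self.Kff = self.K[self.free][:, self.free].tocsr()
        self.Kfp = self.K[self.free][:, self.pres].tocsr()
        self._M = None
        if len(self.free):
            # Jacobi preconditioning: cheap, symmetric (a CG requirement),
            # and effective because all elements share one stiffness scale
            dinv = 1.0 / self.Kff.diagonal()
            self._M = LinearOperator(self.Kff.shape, lambda v: dinv * v)

    def solve(self, case: LoadCase, rtol: float = 1e-8, maxiter: int = 60000):
        model = self.model
        ndof = self.K.shape[0]
        # affine field is exact for a homogeneous body; use it everywhere as
        # the boundary condition and the interior initial guess
        u = (model.node_coords @ case.strain_tensor.T).reshape(-1)
        if len(self.free) == 0:
            return u
        rhs = -self.Kfp @ u[self.pres]
        rhs_norm = np.linalg.norm(rhs)
        if rhs_norm == 0:
            return u
        x, info = cg(
            self.Kff, rhs, x0=u[self.free], rtol=rtol, maxiter=maxiter, M=self._M
        )
        if info != 0:
            res = np.linalg.norm(self.Kff @ x - rhs) / rhs_norm
            raise RuntimeError(
                f"CG failed to converge (info={info}, rel. residual {res:.2e})"
            )
        u[self.free] = x
        return u


def solve_case(
    model: FEModel, case: LoadCase, rtol: float = 1e-8
) -> np.ndarray:
    """Displacement field (n_nodes, 3) for one KUBC load case."""
    u = _KUBCSystem(model).solve(case, rtol=rtol)
    return u.reshape(-1, 3)


@dataclass
class StiffnessResult:
    C: np.ndarray  # 6x6 apparent stiffness, GPa
    E1: float  # GPa, E1 <= E2 <= E3 after relabelling
    E2: float
    E3: float
    Gmin: float  # GPa
    asymmetry: float = 0.0  # relative asymmetry of C before symmetrization

    def as_dict(self) -> dict:
        return {
            "C_GPa": self.C.tolist(),
            "E1_GPa": self.E1,
            "E2_GPa": self.E2,
            "E3_GPa": self.E3,
            "Gmin_GPa": self.Gmin,
            "asymmetry": self.asymmetry,
        }


def homogenize(model: FEModel, rtol: float = 1e-8) -> StiffnessResult:
    """Apparent stiffness tensor and engineering constants of a model.

    Each canonical case contributes one column of ``C`` as the element-stress
    volume average over the total cube volume.  ``C`` is symmetrized (the
    relative asymmetry, a solver-tolerance effect, is logged), engineering
    constants are read off the compliance, and the Young's moduli are sorted
    so that ``E3`` is the maximum.
    """
    system = _KUBCSystem(model)
    D = isotropic_stiffness_matrix(model.tissue_E, model.tissue_nu)
    Bbar = mean_b_matrix(model.voxel_mm)
    DB = D @ Bbar  # maps element displacements to mean element stress
    v_elem = model.voxel_mm**3
    v_total = model.total_volume_mm3
    dofs = (3 * model.elem_nodes[:, :, None] + np.arange(3)).reshape(-1, 24)
    C = np.zeros((6, 6))
    for case in CANONICAL_CASES:
        u = system.solve(case, rtol=rtol)
        ue = u[dofs]  # (ne, 24)
        sig = ue @ DB.T  # (ne, 6) mean stress per element
        C[:, case.index] = sig.sum(axis=0) * v_elem / v_total
    asym = np.abs(C - C.T).max() / max(np.abs(C).max(), 1e-300)
    if asym > 1e-6:
        log.warning("stiffness asymmetry %.2e exceeds 1e-6", asym)
    C = 0.5 * (C + C.T)
    try:
        S = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("singular apparent stiffness tensor") from exc
    E = np.sort(1.0 / np.diag(S)[:3])
    G = 1.0 / np.diag(S)[3:]
    return StiffnessResult(
        C=C,
        E1=float(E[0]),
        E2=float(E[1]),
        E3=float(E[2]),
        Gmin=float(G.min()),
        asymmetry=float(asym),
    )


def export_mesh(model: FEModel, path: str) -> None:
    """Plain-text node/element export for cross-checks with external codes."""
    with open(path, "w") as fh:
        fh.write(f"# nodes {model.n_nodes} elements {model.n_elements}\n")
        fh.write(f"# tissue_E_GPa {model.tissue_E} nu {model.tissue_nu}\n")
        for i, (x, y, z) in enumerate(model.node_coords):
            fh.write(f"N {i} {x:.6g} {y:.6g} {z:.6g}\n")
        for e, nodes in enumerate(model.elem_nodes):
            fh.write("E " + str(e) + " " + " ".join(map(str, nodes)) + "\n")
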