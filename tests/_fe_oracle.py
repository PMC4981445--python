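"""Independent dense micro-FE oracle for cross-checking the sparse solver.

Deliberately separate implementation: explicit per-node shape-function
derivatives, 3x3x3 Gauss quadrature, dense assembly with Python loops, and a
dense direct factorization.  Only suitable for tiny models.
"""

import numpy as np

_GP3, _GW3 = np.polynomial.legendre.leggauss(3)

# corner sign pattern, node order dx + 2*dy + 4*dz
_SIGNS = [
    (-1, -1, -1), (1, -1, -1), (-1, 1, -1), (1, 1, -1),
    (-1, -1, 1), (1, -1, 1), (-1, 1, 1), (1, 1, 1),
]


def _dmat(E, nu):
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.diag([lam + 2 * mu] * 3 + [mu] * 3).astype(float)
    for i in range(3):
        for j in range(3):
            if i != j:
                D[i, j] = lam
    return D


def _bmat(xi, eta, zeta, h):
    B = np.zeros((6, 24))
    for a, (sx, sy, sz) in enumerate(_SIGNS):
        dN = np.array(
            [
                sx * (1 + sy * eta) * (1 + sz * zeta),
                (1 + sx * xi) * sy * (1 + sz * zeta),
                (1 + sx * xi) * (1 + sy * eta) * sz,
            ]
        ) / 8.0 * (2.0 / h)
        B[0, 3 * a + 0] = dN[0]
        B[1, 3 * a + 1] = dN[1]
        B[2, 3 * a + 2] = dN[2]
        B[3, 3 * a + 1] = dN[2]
        B[3, 3 * a + 2] = dN[1]
        B[4, 3 * a + 0] = dN[2]
        B[4, 3 * a + 2] = dN[0]
        B[5, 3 * a + 0] = dN[1]
        B[5, 3 * a + 1] = dN[0]
    return B


def element_stiffness_dense(h, E, nu):
    D = _dmat(E, nu)
    K = np.zeros((24, 24))
    detJ = (h / 2.0) ** 3
    for xi, wx in zip(_GP3, _GW3):
        for eta, wy in zip(_GP3, _GW3):
            for zeta, wz in zip(_GP3, _GW3):
                B = _bmat(xi, eta, zeta, h)
                K += wx * wy * wz * detJ * B.T @ D @ B
    return K


def homogenize_dense(occ: np.ndarray, h: float, E: float, nu: float) -> np.ndarray:
    """6x6 apparent stiffness of a voxel mask by dense direct solve (KUBC)."""
    occ = np.asarray(occ, bool)
    nx, ny, nz = occ.shape
    nid = -np.ones((nx + 1, ny + 1, nz + 1), dtype=int)
    corners = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
               (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
    count = 0
    elems = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not occ[i, j, k]:
                    continue
                ids = []
                for dx, dy, dz in corners:
                    if nid[i + dx, j + dy, k + dz] < 0:
                        nid[i + dx, j + dy, k + dz] = count
                        count += 1
                    ids.append(nid[i + dx, j + dy, k + dz])
                elems.append(((i, j, k), ids))
    coords = np.zeros((count, 3))
    boundary = np.zeros(count, bool)
    for idx in np.argwhere(nid >= 0):
        n = nid[tuple(idx)]
        coords[n] = idx * h
        if (
            idx[0] in (0, nx) or idx[1] in (0, ny) or idx[2] in (0, nz)
        ):
            boundary[n] = True
    Ke = element_stiffness_dense(h, E, nu)
    ndof = 3 * count
    K = np.zeros((ndof, ndof))
    for _, ids in elems:
        dofs = np.concatenate([[3 * n, 3 * n + 1, 3 * n + 2] for n in ids])
        K[np.ix_(dofs, dofs)] += Ke
    pres = np.repeat(boundary, 3)
    free = ~pres
    D = _dmat(E, nu)
    # volume-averaged B over the element (mean of Gauss-point B's)
    Bbar = np.zeros((6, 24))
    wsum = 0.0
    for xi, wx in zip(_GP3, _GW3):
        for eta, wy in zip(_GP3, _GW3):
            for zeta, wz in zip(_GP3, _GW3):
                Bbar += wx * wy * wz * _bmat(xi, eta, zeta, h)
                wsum += wx * wy * wz
    Bbar /= wsum
    C = np.zeros((6, 6))
    cases = []
    for v in range(6):
        eps = np.zeros((3, 3))
        if v < 3:
            eps[v, v] = 1.0
        else:
            i, j = {3: (1, 2), 4: (0, 2), 5: (0, 1)}[v]
            eps[i, j] = eps[j, i] = 0.5
        cases.append(eps)
    vtot = nx * ny * nz * h**3
    for v, eps in enumerate(cases):
        u = np.zeros(ndof)
        ub = coords @ eps.T
        u[0::3] = np.where(boundary, ub[:, 0], 0.0)
        u[1::3] = np.where(boundary, ub[:, 1], 0.0)
        u[2::3] = np.where(boundary, ub[:, 2], 0.0)
        if free.any():
            rhs = -K[np.ix_(free, pres)] @ u[pres]
            u[free] = np.linalg.solve(K[np.ix_(free, free)], rhs)
        for _, ids in elems:
            dofs = np.concatenate([[3 * n, 3 * n + 1, 3 * n + 2] for n in ids])
            sig = D @ (Bbar @ u[dofs])
            C[:, v] += sig * h**3 / vtot
    return 0.5 * (C + C.T)
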