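"""Taylor–Hood (P2/P1) finite-element space on a labeled tet mesh.

Displacement dofs are vector P2 (vertices + edge midpoints, node-major
``3*node + component``); pressure dofs are scalar P1 on the vertices and
follow the displacement block.  Contraction runs append six scalar
Lagrange multipliers enforcing L2-orthogonality to the rigid-body modes.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from . import geometry as geo
from .quadrature import tet_rule

# P2 edge local numbering within a tet
_EDGES = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])


def p2_shape_values(bary: np.ndarray) -> np.ndarray:
    """P2 shape values at barycentric points, shape (nq, 10)."""
    lam = np.asarray(bary)
    out = np.empty(lam.shape[:-1] + (10,))
    for a in range(4):
        out[..., a] = lam[..., a] * (2 * lam[..., a] - 1)
    for i, (a, b) in enumerate(_EDGES):
        out[..., 4 + i] = 4 * lam[..., a] * lam[..., b]
    return out


def p2_ref_gradients(bary: np.ndarray) -> np.ndarray:
    """Reference-coordinate P2 gradients at barycentric points (nq, 10, 3)."""
    lam = np.asarray(bary)
    dlam = np.array([[-1.0, -1.0, -1.0],
                     [1.0, 0.0, 0.0],
                     [0.0, 1.0, 0.0],
                     [0.0, 0.0, 1.0]])
    nq = lam.shape[0]
    out = np.zeros((nq, 10, 3))
    for a in range(4):
        out[:, a, :] = (4 * lam[:, a] - 1)[:, None] * dlam[a]
    for i, (a, b) in enumerate(_EDGES):
        out[:, 4 + i, :] = 4 * (lam[:, a][:, None] * dlam[b]
                                + lam[:, b][:, None] * dlam[a])
    return out


class TaylorHoodSpace:
    """P2/P1 mixed space with precomputed element data for assembly."""

    def __init__(self, mesh: geo.MeshBundle, quad_degree: int = 5):
        self.mesh = mesh
        tets = mesh.tets
        nv = len(mesh.vertices)
        # global edges
        epairs = np.sort(tets[:, _EDGES].reshape(-1, 2), axis=1)
        uniq, inv = np.unique(epairs, axis=0, return_inverse=True)
        self.edges = uniq
        ne = len(uniq)
        self.conn10 = np.concatenate(
            [tets, nv + inv.reshape(-1, 6)], axis=1).astype(np.int64)
        self.connp = tets.astype(np.int64)
        self.n2 = nv + ne
        self.nv = nv
        self.nu = 3 * self.n2
        self.ndof = self.nu + nv
        self.p2_coords = np.concatenate(
            [mesh.vertices, 0.5 * (mesh.vertices[uniq[:, 0]]
                                   + mesh.vertices[uniq[:, 1]])])

        # affine geometry
        v = mesh.vertices[tets]
        Jmat = np.stack([v[:, 1] - v[:, 0], v[:, 2] - v[:, 0],
                         v[:, 3] - v[:, 0]], axis=2)     # dx_i/dxi_k
        self.detJ = np.linalg.det(Jmat)
        if np.any(self.detJ <= 0):
            raise geo.MeshingError("negatively oriented element")
        Jinv = np.linalg.inv(Jmat)

        bary, w = tet_rule(quad_degree)
        self.qp_bary = bary
        self.qw = w
        Gref = p2_ref_gradients(bary)                    # (nq, 10, 3)
        # physical grads: G[e, q, n, j] = Gref[q, n, k] Jinv[e, k, j]
        self.grads = np.einsum("qnk,ekj->eqnj", Gref, Jinv)
        self.N2 = p2_shape_values(bary)
        self.N1 = bary.copy()                            # P1 values = bary
        self.qp_phys = np.einsum("qa,eai->eqi", bary, v)

        self.intra_el = mesh.tet_labels > 0
        # sparse assembly index arrays
        edof = np.empty((len(tets), 34), dtype=np.int64)
        for n in range(10):
            for c in range(3):
                edof[:, 3 * n + c] = 3 * self.conn10[:, n] + c
        edof[:, 30:] = self.nu + self.connp
        self._edof = edof
        self._rows = np.repeat(edof, 34, axis=1).ravel().astype(np.int32)
        self._cols = np.tile(edof, (1, 34)).ravel().astype(np.int32)

    # -- dof helpers --------------------------------------------------------
    def facet_nodes(self, label: int) -> np.ndarray:
        """All P2 node indices lying on the facet set ``label``."""
        facets = self.mesh.facets[label]
        if len(facets) == 0:
            return np.empty(0, dtype=int)
        vset = np.unique(facets)
        pairs = np.sort(np.concatenate(
            [facets[:, [0, 1]], facets[:, [0, 2]], facets[:, [1, 2]]]), axis=1)
        idx = self._edge_lookup(pairs)
        return np.unique(np.concatenate([vset, self.nv + idx]))

    def _edge_lookup(self, pairs: np.ndarray) -> np.ndarray:
        key = pairs[:, 0].astype(np.int64) * (self.nv + 1) + pairs[:, 1]
        ekey = self.edges[:, 0].astype(np.int64) * (self.nv + 1) \
            + self.edges[:, 1]
        order = np.argsort(ekey)
        pos = np.searchsorted(ekey, key, sorter=order)
        found = order[pos]
        if not np.all(ekey[found] == key):
            raise KeyError("facet edge not present in mesh")
        return found

    def u_dofs_of_nodes(self, nodes: np.ndarray, comp=None) -> np.ndarray:
        if comp is None:
            return (3 * nodes[:, None] + np.arange(3)[None, :]).ravel()
        return 3 * nodes + comp

    # -- rigid body modes ---------------------------------------------------
    def rigid_modes(self) -> np.ndarray:
        """Rigid modes evaluated at P2 nodes, shape (6, n2, 3).

        Three translations and three infinitesimal rotations about the
        domain centroid.
        """
        x = self.p2_coords - np.mean(self.mesh.vertices, axis=0)
        modes = np.zeros((6, self.n2, 3))
        for c in range(3):
            modes[c, :, c] = 1.0
        axes = np.eye(3)
        for c in range(3):
            modes[3 + c] = np.cross(axes[c][None, :], x)
        return modes

    def rigid_constraint_matrix(self) -> sp.csr_matrix:
        """C with C[m, :] u = int_Omega u . r_m dX, shape (6, ndof)."""
        x0 = np.mean(self.mesh.vertices, axis=0)
        xq = self.qp_phys - x0                       # (nt, nq, 3)
        nt, nq, _ = xq.shape
        C = np.zeros((6, self.n2, 3))
        w = (self.qw[None, :] * self.detJ[:, None])  # (nt, nq)
        axes = np.eye(3)
        for m in range(6):
            if m < 3:
                r = np.broadcast_to(axes[m], (nt, nq, 3))
            else:
                r = np.cross(axes[m - 3][None, None, :], xq)
            # contributions w * N2[q, n] * r[e, q, c] at node conn10[e, n]
            contrib = np.einsum("eq,qn,eqc->enc", w, self.N2, r)
            np.add.at(C[m], self.conn10, contrib)
        Cflat = C.reshape(6, self.nu)
        out = sp.lil_matrix((6, self.ndof))
        out[:, :self.nu] = Cflat
        return out.tocsr()

    # -- assembly -----------------------------------------------------------
    def assemble(self, u: np.ndarray, p: np.ndarray, gamma_el: np.ndarray,
                 params, need_matrix: bool, kappa: float = 0.0):
        """Residual (nu+nv,), optional stiffness csr, and max|J-1| at qps."""
        from ._kernels import assemble_system
        prm = params.as_array()
        Ru, Rp, Kel, maxdev, ok = assemble_system(
            self.conn10, self.connp, self.grads, self.detJ, self.qw,
            np.zeros(1), self.N1, u, p, gamma_el,
            self.intra_el, prm, kappa, need_matrix)
        if not ok:
            raise FloatingPointError("element inverted during assembly "
                                     "(det F <= 0 at a quadrature point)")
        R = np.concatenate([Ru.ravel(), Rp])
        K = None
        if need_matrix:
            K = sp.coo_matrix(
                (Kel.ravel(), (self._rows, self._cols)),
                shape=(self.ndof, self.ndof)).tocsr()
        return R, K, maxdev
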