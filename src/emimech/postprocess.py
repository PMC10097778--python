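"""Reported quantities: subdomain averages, surface loads, spatial fields.

All integrals are evaluated in the reference (Lagrangian) configuration
with fourth-order Gaussian quadrature; directions are the fixed frame axes
f0, s0, n0.  Surface loads follow the normalized convention

    L(lambda, e) = int_S P N . e dS / int_S (F N) . (F^T N) dS

with the numerator evaluated variationally (the reaction of the residual
on the face indicator function, i.e. the consistent flux) and the
denominator integrated directly on the reference surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry as geo
from .fem import TaylorHoodSpace, p2_ref_gradients
from .materials import MaterialParams
from .quadrature import triangle_rule

__all__ = [
    "AveragedTrace",
    "LoadCurve",
    "averaged_component",
    "averaged_trace",
    "surface_load",
    "export_spatial_fields",
    "read_vtu",
]

_DIRS = {"f0": np.array([1.0, 0.0, 0.0]),
         "s0": np.array([0.0, 1.0, 0.0]),
         "n0": np.array([0.0, 0.0, 1.0])}
_VTK_P2_PERM = np.array([0, 1, 2, 3, 4, 7, 5, 6, 8, 9])


@dataclass
class LoadCurve:
    """Normalized normal/shear loads (kPa) on the moved face of a protocol."""

    mode: str
    step_values: np.ndarray
    normal_load: np.ndarray
    shear_load: np.ndarray

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "step_value": self.step_values,
            "normal_load_kPa": self.normal_load,
            "shear_load_kPa": self.shear_load,
        }).to_csv(path, index=False)


@dataclass
class AveragedTrace:
    """Per-step subdomain-averaged strain/stress components."""

    step_values: np.ndarray
    data: dict = field(default_factory=dict)  # (tensor, dir, subdomain) -> arr

    def series(self, tensor: str, direction: str, subdomain) -> np.ndarray:
        return self.data[(tensor, direction, str(subdomain))]

    def to_csv(self, path) -> None:
        rows = []
        for (tensor, direction, sub), arr in self.data.items():
            for t, v in zip(self.step_values, arr):
                rows.append((t, f"{tensor}_{direction[0]}{direction[0]}",
                             sub, v))
        pd.DataFrame(rows, columns=["step_or_time", "quantity",
                                    "subdomain", "value"]).to_csv(
            path, index=False)


def _resolve(state, space):
    space = space or getattr(state, "space", None)
    if space is None:
        raise ValueError("a TaylorHoodSpace must be supplied")
    return space


def _element_mask(space: TaylorHoodSpace, label) -> np.ndarray:
    labels = space.mesh.tet_labels
    if label in ("i", "intracellular"):
        mask = labels > 0
    elif label in ("e", "extracellular"):
        mask = labels == 0
    else:
        mask = labels == int(label)
    if not mask.any():
        raise ValueError(f"unknown subdomain label {label!r}")
    return mask


def averaged_component(state, tensor: str, direction, label,
                       space: TaylorHoodSpace = None,
                       params: MaterialParams = None) -> float:
    """Volume-averaged e0.(T e0) over a subdomain (Lagrangian integral).

    ``tensor`` is 'E' (Green–Lagrange) or 'sigma' (Cauchy); ``direction``
    one of 'f0'/'s0'/'n0' or a unit vector; ``label`` a subdomain id, or
    'intracellular'/'extracellular' ('i'/'e') for the unions.
    """
    from ._kernels import subdomain_integrals
    space = _resolve(state, space)
    params = params or getattr(state, "params", None)
    if tensor not in ("E", "sigma"):
        raise ValueError("tensor must be 'E' or 'sigma'")
    if tensor == "sigma" and params is None:
        raise ValueError("Cauchy stress averaging needs material parameters")
    e0 = _DIRS[direction] if isinstance(direction, str) else \
        np.asarray(direction, float)
    mask = _element_mask(space, label)
    gamma_el = np.where(space.intra_el, state.gamma, 0.0)
    prm = (params or MaterialParams()).as_array()
    total, vol = subdomain_integrals(
        space.conn10, space.connp, space.grads, space.detJ, space.qw,
        space.N1, state.u, state.p, gamma_el, space.intra_el, prm,
        getattr(state, "kappa", 0.0), mask, e0, tensor == "sigma")
    return total / vol


def averaged_trace(states, space: TaylorHoodSpace = None,
                   params: MaterialParams = None,
                   per_cell: bool = False) -> AveragedTrace:
    """Averaged E and sigma normal components per subdomain per step."""
    space = _resolve(states[0], space)
    params = params or getattr(states[0], "params", None)
    subs = ["i", "e"]
    if per_cell:
        subs += [k for k in space.mesh.labels() if k > 0]
    values = np.array([0.0] + [s.step_value for s in states])
    data = {}
    for tensor in ("E", "sigma"):
        for direction in ("f0", "s0", "n0"):
            for sub in subs:
                arr = [0.0] + [
                    averaged_component(s, tensor, direction, sub,
                                       space=space, params=params)
                    for s in states]
                data[(tensor, direction, str(sub))] = np.array(arr)
    return AveragedTrace(step_values=values, data=data)


def surface_load(state, surface: int, direction,
                 space: TaylorHoodSpace = None) -> float:
    """Normalized load (kPa) on an outer surface in direction ``e``."""
    space = _resolve(state, space)
    e = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(e)
    if abs(nrm - 1.0) > 1e-12:
        warnings.warn("load direction was not a unit vector; normalizing")
        e = e / nrm
    if state.raw_residual is None:
        raise ValueError("state carries no residual (not solver-produced)")
    nodes = space.facet_nodes(surface)
    dofs = space.u_dofs_of_nodes(nodes).reshape(-1, 3)
    numer = float((state.raw_residual[dofs.ravel()].reshape(-1, 3) @ e).sum())
    denom = _load_denominator(state, surface, space)
    return numer / denom


def _load_denominator(state, surface, space) -> float:
    """int_S (F N).(F^T N) dS on the reference surface."""
    mesh = space.mesh
    facets = mesh.facets[surface]
    if len(facets) == 0:
        raise ValueError(f"surface {surface} has no facets")
    owners = _facet_owners(space, surface)
    v = mesh.vertices
    tri_b, tri_w = triangle_rule()
    total = 0.0
    Jinv = getattr(space, "_Jinv", None)
    if Jinv is None:
        tets = mesh.tets
        vv = v[tets]
        Jmat = np.stack([vv[:, 1] - vv[:, 0], vv[:, 2] - vv[:, 0],
                         vv[:, 3] - vv[:, 0]], axis=2)
        Jinv = np.linalg.inv(Jmat)
        space._Jinv = Jinv
    for f, e in zip(facets, owners):
        p0, p1, p2 = v[f]
        cr = np.cross(p1 - p0, p2 - p0)
        area2 = np.linalg.norm(cr)
        N = cr / area2
        tc = v[mesh.tets[e]].mean(axis=0)
        if N @ ((p0 + p1 + p2) / 3 - tc) < 0:
            N = -N
        xq = tri_b @ np.stack([p0, p1, p2])          # (nq, 3)
        v0 = v[mesh.tets[e, 0]]
        xi = (xq - v0) @ Jinv[e].T
        # barycentric in owner tet
        bary = np.concatenate([(1 - xi.sum(axis=1))[:, None], xi], axis=1)
        G = p2_ref_gradients(bary) @ Jinv[e]         # (nq, 10, 3)
        ue = state.u[space.conn10[e]]                # (10, 3)
        F = np.einsum("ni,qnj->qij", ue, G) + np.eye(3)
        FN = F @ N
        FTN = np.einsum("qji,j->qi", F, N)
        vals = np.einsum("qi,qi->q", FN, FTN)
        total += area2 * float(tri_w @ vals)
    return total


def _facet_owners(space, surface):
    cache = getattr(space, "_owner_cache", None)
    if cache is None:
        cache = space._owner_cache = {}
    if surface in cache:
        return cache[surface]
    mesh = space.mesh
    faces, counts, pair = geo._face_table(mesh.tets)
    key = {tuple(f): pair[i, 0] for i, f in enumerate(faces)}
    owners = np.array([key[tuple(sorted(f))] for f in mesh.facets[surface]])
    cache[surface] = owners
    return owners


# ---------------------------------------------------------------------------
# spatial field export (DG2 projection, ASCII VTU)
# ---------------------------------------------------------------------------

_COMPONENTS = ("E_ff", "E_ss", "E_nn", "sigma_ff", "sigma_ss", "sigma_nn")


def _pointwise_components(state, space, params):
    """E and sigma normal components at quadrature points, (nt, nq, 6)."""
    from ._kernels import piola_cplx
    u = state.u
    F = np.einsum("eni,eqnj->eqij", u[space.conn10], space.grads)
    F += np.eye(3)
    nt, nq = F.shape[:2]
    out = np.empty((nt, nq, 6))
    C = np.einsum("eqki,eqkj->eqij", F, F)
    for c in range(3):
        out[:, :, c] = 0.5 * (C[:, :, c, c] - 1.0)
    pq = np.einsum("qc,ec->eq", space.N1, state.p[space.connp])
    prm = params.as_array()
    Pbuf = np.zeros((3, 3), dtype=np.complex128)
    for e in range(nt):
        intra = space.intra_el[e]
        a, b, af, bf = (prm[0], prm[1], prm[2], prm[3]) if intra else \
            (prm[4], prm[5], 0.0, 0.0)
        gam = state.gamma if intra else 0.0
        for q in range(nq):
            Fc = F[e, q].astype(np.complex128)
            J = piola_cplx(Fc, gam, pq[e, q], a, b, af, bf,
                           getattr(state, "kappa", 0.0), Pbuf)
            sig = (Pbuf.real @ F[e, q].T) / J
            out[e, q, 3:] = np.diag(sig)
    return out


def export_spatial_fields(state, mesh: geo.MeshBundle, path,
                          space: TaylorHoodSpace = None,
                          params: MaterialParams = None) -> None:
    """Project E/sigma normal components to DG2 and write an ASCII VTU.

    Each element carries its own 10 quadratic nodes, so fields may jump
    across the membrane.
    """
    space = _resolve(state, space)
    params = params or getattr(state, "params", None) or MaterialParams()
    vals = _pointwise_components(state, space, params)      # (nt, nq, 6)
    # local L2 projection: (detJ Mref) c = detJ sum_q w N f  ->  independent
    # of detJ; Mref is identical for every affine element
    Mref = np.einsum("q,qa,qb->ab", space.qw, space.N2, space.N2)
    rhs = np.einsum("q,qa,eqc->eac", space.qw, space.N2, vals)
    coef = np.linalg.solve(Mref, rhs)
    nt = len(mesh.tets)
    pts = space.p2_coords[space.conn10][:, _VTK_P2_PERM, :].reshape(-1, 3)
    fields = {name: coef[:, _VTK_P2_PERM, i].reshape(-1)
              for i, name in enumerate(_COMPONENTS)}
    _write_vtu(path, pts, nt, fields, mesh.tet_labels)


def _write_vtu(path, pts, nt, point_fields, cell_labels):
    def arr(a, fmt="%.10g"):
        return " ".join(fmt % x for x in np.asarray(a).ravel())

    conn = np.arange(10 * nt).reshape(nt, 10)
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n'
                 '<VTKFile type="UnstructuredGrid" version="0.1" '
                 'byte_order="LittleEndian">\n<UnstructuredGrid>\n')
        fh.write(f'<Piece NumberOfPoints="{10*nt}" NumberOfCells="{nt}">\n')
        fh.write('<Points><DataArray type="Float64" NumberOfComponents="3" '
                 'format="ascii">\n')
        fh.write(arr(pts))
        fh.write('\n</DataArray></Points>\n<Cells>\n')
        fh.write('<DataArray type="Int64" Name="connectivity" '
                 'format="ascii">\n' + arr(conn, "%d"))
        fh.write('\n</DataArray>\n<DataArray type="Int64" Name="offsets" '
                 'format="ascii">\n'
                 + arr(10 * np.arange(1, nt + 1), "%d"))
        fh.write('\n</DataArray>\n<DataArray type="UInt8" Name="types" '
                 'format="ascii">\n' + arr(np.full(nt, 24), "%d"))
        fh.write('\n</DataArray>\n</Cells>\n<PointData>\n')
        for name, vals in point_fields.items():
            fh.write(f'<DataArray type="Float64" Name="{name}" '
                     'format="ascii">\n' + arr(vals))
            fh.write('\n</DataArray>\n')
        fh.write('</PointData>\n<CellData>\n')
        fh.write('<DataArray type="Int64" Name="subdomain" format="ascii">\n'
                 + arr(cell_labels, "%d"))
        fh.write('\n</DataArray>\n</CellData>\n</Piece>\n'
                 '</UnstructuredGrid>\n</VTKFile>\n')


def read_vtu(path):
    """Read back a VTU written by :func:`export_spatial_fields`.

    Returns (points, connectivity, point_data dict, cell_labels).
    """
    import re
    with open(path) as fh:
        text = fh.read()
    arrays = {}
    for m in re.finditer(r'<DataArray([^>]*)>\n?(.*?)</DataArray>',
                         text, re.S):
        attrs, payload = m.group(1), m.group(2)
        nm = re.search(r'Name="([^"]*)"', attrs)
        name = nm.group(1) if nm else None
        arrays.setdefault(name, []).append(
            np.array(payload.split(), dtype=float))
    pts = arrays[None][0].reshape(-1, 3)
    conn = arrays["connectivity"][0].astype(int).reshape(-1, 10)
    fields = {k: v[0] for k, v in arrays.items()
              if k in _COMPONENTS}
    labels = arrays["subdomain"][0].astype(int)
    return pts, conn, fields, labels
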