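"""Mesh serialization: Gmsh MSH 2.2 ASCII with the package label table.

Volume elements (4-node tets) carry the subdomain label as their physical
tag (0 extracellular, 1..N per cell); facet triangles carry 1..6 for the
outer box surfaces S1..S6, 7 for the membrane and 8 for connection
patches.
"""

from __future__ import annotations

import numpy as np

from .geometry import CellGeometrySpec, MeshBundle

__all__ = ["write_msh", "read_msh"]


def write_msh(mesh: MeshBundle, path) -> None:
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{len(mesh.vertices)}\n")
        for i, (x, y, z) in enumerate(mesh.vertices, start=1):
            fh.write(f"{i} {x:.12g} {y:.12g} {z:.12g}\n")
        fh.write("$EndNodes\n")
        n_fac = sum(len(v) for v in mesh.facets.values())
        fh.write(f"$Elements\n{n_fac + len(mesh.tets)}\n")
        eid = 1
        for label in sorted(mesh.facets):
            for tri in mesh.facets[label]:
                fh.write(f"{eid} 2 2 {label} {label} "
                         f"{tri[0]+1} {tri[1]+1} {tri[2]+1}\n")
                eid += 1
        for tet, lab in zip(mesh.tets, mesh.tet_labels):
            fh.write(f"{eid} 4 2 {lab} {lab} "
                     f"{tet[0]+1} {tet[1]+1} {tet[2]+1} {tet[3]+1}\n")
            eid += 1
        fh.write("$EndElements\n")


def read_msh(path, spec: CellGeometrySpec | None = None,
             resolution: float = float("nan")) -> MeshBundle:
    """Read back a mesh written by :func:`write_msh`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = lines.index("$Nodes")
    nv = int(lines[i + 1])
    verts = np.array([[float(t) for t in lines[i + 2 + k].split()[1:4]]
                      for k in range(nv)])
    j = lines.index("$Elements")
    ne = int(lines[j + 1])
    tets, labels = [], []
    facets: dict[int, list] = {}
    for k in range(ne):
        parts = lines[j + 2 + k].split()
        etype = int(parts[1])
        ntags = int(parts[2])
        tag = int(parts[3])
        conn = [int(t) - 1 for t in parts[3 + ntags:]]
        if etype == 2:
            facets.setdefault(tag, []).append(conn)
        elif etype == 4:
            tets.append(conn)
            labels.append(tag)
    tets = np.array(tets)
    labels = np.array(labels)
    lo = verts.min(axis=0)
    hi = verts.max(axis=0)
    return MeshBundle(
        vertices=verts, tets=tets, tet_labels=labels,
        facets={k: np.array(v) for k, v in facets.items()},
        frame=np.eye(3), resolution=resolution,
        box=tuple(hi - lo), n_cells=int(labels.max()),
        spec=spec or CellGeometrySpec(), tiling=(0, 0, 0))
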