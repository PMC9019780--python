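"""Synthetic left-ventricular geometry.

Generates a truncated-ellipsoid LV wall meshed with 10-node (quadratic)
tetrahedra, standing in for CT-derived patient geometry.  The endocardial
surface is an ellipsoid of revolution (semi-axes ``rs, rs, rl``) truncated by
a flat basal plane a configurable height above the equator; the epicardial
surface is an outward normal offset whose thickness tapers linearly from base
to apex.  The mesh carries endocardial/epicardial/basal surface tags, a
transmural coordinate (0 endo, 1 epi) and AHA 17-segment element labels.

Axis convention: the long axis is z, the apex points toward -z and the basal
cut plane is at z = +truncation_height.  The segment-1 azimuth is the +x
direction (an arbitrary fixed reference; the synthetic LV has no anatomical
landmarks).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "LVGeometrySpec",
    "VolumetricMesh",
    "build_lv_mesh",
    "build_cube_mesh",
    "label_aha17",
    "transmural_coordinate",
    "truncated_ellipsoid_volume",
    "reference_cavity_volume",
    "write_vtk",
]


class GeometryError(ValueError):
    """Raised when a geometry spec is infeasible or a mesh is malformed."""


# --------------------------------------------------------------------------
# spec
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LVGeometrySpec:
    """Parameters of the synthetic truncated-ellipsoid LV wall.

    Lengths in mm, volumes in mL.  ``target_edv`` is the cavity volume the
    endocardial surface (closed by the basal plane) should enclose; the short
    radius is rescaled to reach it.  ``target_edv=None`` keeps the radii
    exactly as given (used by analytic benchmarks).
    """

    endo_long_radius: float = 46.0
    endo_short_radius: float = 36.8
    wall_thickness_base: float = 12.0
    wall_thickness_apex: float = 9.0
    truncation_height: float = 12.0
    target_edv: Optional[float] = 180.0
    mesh_edge_length: float = 12.0

    def validate(self) -> None:
        for name in ("endo_long_radius", "endo_short_radius",
                     "wall_thickness_base", "wall_thickness_apex",
                     "truncation_height", "mesh_edge_length"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.endo_short_radius > self.endo_long_radius:
            raise GeometryError(
                "endo_short_radius must not exceed endo_long_radius "
                f"({self.endo_short_radius} > {self.endo_long_radius})")
        if self.truncation_height >= self.endo_long_radius:
            raise GeometryError(
                "truncation_height must be below the long radius "
                f"({self.truncation_height} >= {self.endo_long_radius})")
        if self.target_edv is not None and self.target_edv <= 0:
            raise GeometryError("target_edv must be > 0 or None")


def truncated_ellipsoid_volume(rs: float, rl: float, z_cut: float) -> float:
    """Volume (mL) enclosed by x^2/rs^2 + y^2/rs^2 + z^2/rl^2 = 1 below z=z_cut.

    Closed form: pi rs^2 [(z + rl) - (z^3 + rl^3)/(3 rl^2)].
    """
    return np.pi * rs ** 2 * ((z_cut + rl) - (z_cut ** 3 + rl ** 3) / (3 * rl ** 2)) / 1000.0


# --------------------------------------------------------------------------
# mesh container
# --------------------------------------------------------------------------

@dataclass
class VolumetricMesh:
    """Quadratic tetrahedral LV wall mesh.

    ``elements`` follow the VTK quadratic-tetra node ordering (4 corners then
    edge midpoints 01, 12, 02, 03, 13, 23).  ``surface_tags`` maps tag name to
    six-node triangle facets oriented outward from the solid.
    ``endo_basal_ring`` lists the endocardial basal-ring nodes in azimuthal
    order; they close the cavity with a flat cap for volume evaluation.
    """

    nodes: np.ndarray                     # (N, 3) mm
    elements: np.ndarray                  # (E, 10) int
    surface_tags: Dict[str, np.ndarray]   # name -> (F, 6) int
    endo_basal_ring: np.ndarray           # ordered node ids
    z_base: float
    transmural_coord: Optional[np.ndarray] = None   # (N,)
    segment_label: Optional[np.ndarray] = None      # (E,) in 1..17
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def corner_nodes(self) -> np.ndarray:
        return np.unique(self.elements[:, :4])

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements[:, :4]].mean(axis=1)

    def element_volumes(self) -> np.ndarray:
        """Reference volumes from the corner tetrahedra (mm^3)."""
        x = self.nodes[self.elements[:, :4]]
        d1, d2, d3 = x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]
        return np.einsum("ei,ei->e", d1, np.cross(d2, d3)) / 6.0

    def long_axis_span(self) -> tuple[float, float]:
        return float(self.nodes[:, 2].min()), float(self.z_base)


# --------------------------------------------------------------------------
# structured grid -> Kuhn tetrahedra
# --------------------------------------------------------------------------

_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def _kuhn_tets_of_cell():
    """Corner offsets of the 6 Kuhn tetrahedra of a unit cell.

    Every face diagonal runs from the local (0,0,0) corner pattern to the
    (1,1,1) pattern, so the split is conforming between adjacent cells.
    """
    tets = []
    for perm in _KUHN_PERMS:
        v = [np.zeros(3, dtype=int)]
        cur = np.zeros(3, dtype=int)
        for axis in perm:
            cur = cur.copy()
            cur[axis] = 1
            v.append(cur)
        tets.append(v)
    return tets


_CELL_TETS = _kuhn_tets_of_cell()

# VTK quadratic tetra edge list (midpoint node k+4 sits on edge _TET_EDGES[k])
_TET_EDGES = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]


def _orient_positive(corners: np.ndarray, coords: np.ndarray) -> np.ndarray:
    x = coords[corners]
    vol = np.einsum("ei,ei->e", x[:, 1] - x[:, 0],
                    np.cross(x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]))
    flip = vol < 0
    out = corners.copy()
    out[flip, 1], out[flip, 2] = corners[flip, 2], corners[flip, 1]
    return out


def _attach_midside(corners: np.ndarray, node_xyz: list, midpoint_of) -> np.ndarray:
    """Create TET10 connectivity by inserting edge midpoints.

    ``midpoint_of(i, j)`` returns the node id of the midpoint of edge (i, j),
    creating it if needed.
    """
    elems = np.empty((corners.shape[0], 10), dtype=int)
    elems[:, :4] = corners
    for k, (i, j) in enumerate(_TET_EDGES):
        elems[:, 4 + k] = [midpoint_of(int(a), int(b)) for a, b in
                           zip(corners[:, i], corners[:, j])]
    return elems


# --------------------------------------------------------------------------
# LV wall mesh
# --------------------------------------------------------------------------

def _resolution(spec: LVGeometrySpec) -> tuple[int, int, int]:
    rl, rs = spec.endo_long_radius, spec.endo_short_radius
    h_mean = 0.5 * (spec.wall_thickness_base + spec.wall_thickness_apex)
    r_mid = rs + 0.5 * h_mean
    theta_max = np.arccos(np.clip(-spec.truncation_height / rl, -1.0, 1.0))
    arc = theta_max * (0.5 * (rl + rs) + 0.5 * h_mean)
    L = spec.mesh_edge_length
    n_theta = max(4, int(round(arc / L)))
    n_phi = max(8, int(round(0.55 * 2 * np.pi * r_mid / L)))
    n_w = max(2, int(round(h_mean / L)))
    return n_theta, n_phi, n_w


def build_lv_mesh(spec: LVGeometrySpec, seed: int = 0) -> VolumetricMesh:
    """Build the tagged quadratic-tet LV wall mesh.

    Deterministic for a fixed spec and seed (the construction is analytic; the
    seed is stored in ``meta`` for provenance).  The endocardial short radius
    is rescaled so the cavity, closed by the basal plane, encloses
    ``target_edv`` within a small tolerance; an out-of-range rescale raises
    :class:`GeometryError` naming the violated constraint.
    """
    spec.validate()
    rl = spec.endo_long_radius
    rs = spec.endo_short_radius
    zb = spec.truncation_height

    if spec.target_edv is not None:
        v0 = truncated_ellipsoid_volume(rs, rl, zb)
        scale = np.sqrt(spec.target_edv / v0)
        if not 0.5 <= scale <= 2.0:
            raise GeometryError(
                "infeasible spec: target_edv requires rescaling endo_short_radius "
                f"by {scale:.2f} (allowed 0.5-2.0); adjust radii or target_edv")
        rs = rs * scale
        if rs > rl:
            raise GeometryError(
                "infeasible spec: target_edv pushes endo_short_radius above "
                f"endo_long_radius ({rs:.1f} > {rl:.1f} mm)")

    n_t, n_p, n_w = _resolution(spec)
    theta_max = np.arccos(-zb / rl)
    NT, NP, NW = 2 * n_t, 2 * n_p, 2 * n_w   # refined (half-step) grid

    def point(i_t: int, i_p: int, i_w: int) -> np.ndarray:
        th = theta_max * i_t / NT
        ph = 2 * np.pi * i_p / NP
        w = i_w / NW
        st, ct = np.sin(th), np.cos(th)
        endo = np.array([rs * st * np.cos(ph), rs * st * np.sin(ph), -rl * ct])
        nrm = np.array([endo[0] / rs ** 2, endo[1] / rs ** 2, endo[2] / rl ** 2])
        nrm /= np.linalg.norm(nrm)
        s = (endo[2] + rl) / (zb + rl)
        h = spec.wall_thickness_apex + (spec.wall_thickness_base - spec.wall_thickness_apex) * s
        p = endo + w * h * nrm
        if i_t == NT:                         # flatten the basal cut plane
            p[2] = zb
        return p

    node_xyz: list = []
    grid_id: Dict[tuple, int] = {}

    def nid(i_t: int, i_p: int, i_w: int) -> int:
        if i_t == 0:
            key = ("pole", i_w)
        else:
            key = (i_t, i_p % NP, i_w)
        if key not in grid_id:
            if i_t == 0:
                h = spec.wall_thickness_apex
                p = np.array([0.0, 0.0, -rl - h * i_w / NW])
            else:
                p = point(i_t, i_p % NP, i_w)
            grid_id[key] = len(node_xyz)
            node_xyz.append(p)
        return grid_id[key]

    # --- corner connectivity -------------------------------------------------
    corner_cells = []
    # hex region between corner rings j_t = 1 .. n_t-1
    for jt in range(1, n_t):
        for jp in range(n_p):
            for jw in range(n_w):
                base = np.array([2 * jt, 2 * jp, 2 * jw])
                for tet in _CELL_TETS:
                    corner_cells.append([nid(*(base + 2 * off)) for off in tet])
    # pole prisms between the apex edge and ring j_t = 1
    for jp in range(n_p):
        for jw in range(n_w):
            P0 = nid(0, 0, 2 * jw)
            P1 = nid(0, 0, 2 * jw + 2)
            A0 = nid(2, 2 * jp, 2 * jw)
            A1 = nid(2, 2 * jp, 2 * jw + 2)
            B0 = nid(2, 2 * jp + 2, 2 * jw)
            B1 = nid(2, 2 * jp + 2, 2 * jw + 2)
            # split honoring the low-to-high diagonal rule of the hex region
            corner_cells.append([P0, A0, B0, B1])
            corner_cells.append([P0, A0, B1, A1])
            corner_cells.append([P0, A1, B1, P1])

    corners = np.asarray(corner_cells, dtype=int)
    coords = np.asarray(node_xyz)
    corners = _orient_positive(corners, coords)

    # --- edge midpoints ------------------------------------------------------
    inv_id = {v: k for k, v in grid_id.items()}
    edge_mid: Dict[tuple, int] = {}

    def midpoint_of(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        if key in edge_mid:
            return edge_mid[key]
        ka, kb = inv_id[a], inv_id[b]
        if ka[0] == "pole" and kb[0] == "pole":
            m = nid(0, 0, (ka[1] + kb[1]) // 2)
        elif ka[0] == "pole" or kb[0] == "pole":
            if kb[0] == "pole":
                ka, kb = kb, ka
            _, iwp = ka
            it, ip, iw = kb
            m = nid(it // 2, ip, (iwp + iw) // 2)
        else:
            it = (ka[0] + kb[0]) // 2
            d = (kb[1] - ka[1]) % NP
            if d > NP // 2:
                d -= NP
            ip = (ka[1] + d // 2) % NP
            iw = (ka[2] + kb[2]) // 2
            m = nid(it, ip, iw)
        edge_mid[key] = m
        return m

    elements = _attach_midside(corners, node_xyz, midpoint_of)
    nodes = np.asarray(node_xyz)

    # --- boundary facets ------------------------------------------------------
    faces = _finalize_faces(_boundary_faces(elements), nodes)

    def classify(face_corners):
        keys = [inv_id[int(c)] for c in face_corners]
        if all((k[0] == "pole" and k[1] == 0) or (k[0] != "pole" and k[2] == 0)
               for k in keys):
            return "endocardium"
        if all((k[0] == "pole" and k[1] == NW) or (k[0] != "pole" and k[2] == NW)
               for k in keys):
            return "epicardium"
        if all(k[0] != "pole" and k[0] == NT for k in keys):
            return "base"
        return None

    tags: Dict[str, list] = {"endocardium": [], "epicardium": [], "base": []}
    for f in faces:
        tag = classify(f[:3])
        if tag is None:
            raise GeometryError("untaggable boundary facet; mesh is not watertight")
        tags[tag].append(f)
    surface_tags = {k: np.asarray(v, dtype=int) for k, v in tags.items()}

    ring = np.array([nid(NT, ip, 0) for ip in range(NP)], dtype=int)

    mesh = VolumetricMesh(
        nodes=nodes, elements=elements, surface_tags=surface_tags,
        endo_basal_ring=ring, z_base=zb,
        meta={"spec": replace(spec, endo_short_radius=rs), "seed": seed,
              "resolution": (n_t, n_p, n_w)})

    vol = reference_cavity_volume(mesh)
    if spec.target_edv is not None and abs(vol - spec.target_edv) > 0.02 * spec.target_edv:
        raise GeometryError(
            f"cavity volume {vol:.1f} mL misses target_edv {spec.target_edv:.1f} mL by >2%")

    mesh.transmural_coord = transmural_coordinate(mesh)
    mesh = label_aha17(mesh)
    return mesh


def _boundary_faces(elements: np.ndarray) -> np.ndarray:
    """Outward-oriented six-node boundary facets of a TET10 mesh."""
    # local faces as (corner triple, opposite corner, midside triple)
    local = [((0, 1, 2), 3, (4, 5, 6)),
             ((0, 1, 3), 2, (4, 8, 7)),
             ((1, 2, 3), 0, (5, 9, 8)),
             ((0, 2, 3), 1, (6, 9, 7))]
    count: Dict[tuple, list] = {}
    for e in elements:
        for (tri, opp, mids) in local:
            c = (int(e[tri[0]]), int(e[tri[1]]), int(e[tri[2]]))
            key = tuple(sorted(c))
            rec = count.setdefault(key, [])
            rec.append((c, int(e[opp]), tuple(int(e[m]) for m in mids)))
    faces = []
    for key, recs in count.items():
        if len(recs) != 1:
            continue
        (a, b, c), opp, mids = recs[0]
        faces.append([a, b, c, mids[0], mids[1], mids[2], opp])
    return faces


def _finalize_faces(raw, nodes):
    out = []
    for a, b, c, mab, mbc, mca, opp in raw:
        n = np.cross(nodes[b] - nodes[a], nodes[c] - nodes[a])
        if np.dot(n, nodes[opp] - nodes[a]) > 0:     # flip to outward
            a, b = b, a
            mbc, mca = mca, mbc
        out.append([a, b, c, mab, mbc, mca])
    return np.asarray(out, dtype=int)


# --------------------------------------------------------------------------
# cavity volume of the reference configuration
# --------------------------------------------------------------------------

def reference_cavity_volume(mesh: VolumetricMesh) -> float:
    """Cavity volume (mL) enclosed by the endocardium plus the basal cap."""
    from .fem import cavity_volume   # deferred: divergence-theorem oracle lives there
    return cavity_volume(mesh, np.zeros_like(mesh.nodes))


# --------------------------------------------------------------------------
# transmural coordinate
# --------------------------------------------------------------------------

def transmural_coordinate(mesh: VolumetricMesh) -> np.ndarray:
    """Normalized wall-depth field: 0 on the endocardium, 1 on the epicardium.

    Computed as the normalized distance d_endo/(d_endo + d_epi) to the two
    tagged surfaces (distances to the surface node clouds; the quadratic
    surface sampling keeps the chord error well below the mesh size).
    """
    for tag in ("endocardium", "epicardium"):
        if tag not in mesh.surface_tags or len(mesh.surface_tags[tag]) == 0:
            raise GeometryError(f"mesh is missing the {tag} surface tag")
    endo_nodes = np.unique(mesh.surface_tags["endocardium"].ravel())
    epi_nodes = np.unique(mesh.surface_tags["epicardium"].ravel())
    d_endo, _ = cKDTree(mesh.nodes[endo_nodes]).query(mesh.nodes)
    d_epi, _ = cKDTree(mesh.nodes[epi_nodes]).query(mesh.nodes)
    w = d_endo / np.maximum(d_endo + d_epi, 1e-12)
    w[endo_nodes] = 0.0
    w[epi_nodes] = 1.0
    return np.clip(w, 0.0, 1.0)


# --------------------------------------------------------------------------
# AHA 17-segment labels
# --------------------------------------------------------------------------

CAP_FRACTION = 0.15   # long-axis fraction assigned to the apical cap (segment 17)


def label_aha17(mesh: VolumetricMesh) -> VolumetricMesh:
    """Label every element with its AHA 17-segment id.

    The long axis (apex -> base) is split into the apical cap plus three equal
    thirds; basal (1-6) and mid (7-12) rings get six azimuthal sectors, the
    apical ring (13-16) four.  Sector boundaries sit at fixed azimuths so that
    rotating the mesh by 60 deg about the long axis permutes basal labels
    cyclically.
    """
    if "base" not in mesh.surface_tags or len(mesh.surface_tags["base"]) == 0:
        raise GeometryError("mesh has no basal surface tag; cannot orient long axis")
    cen = mesh.element_centroids()
    z_apex = mesh.nodes[:, 2].min()
    z_base = mesh.z_base
    lam = (cen[:, 2] - z_apex) / (z_base - z_apex)
    phi = np.arctan2(cen[:, 1], cen[:, 0])

    labels = np.zeros(mesh.n_elements, dtype=int)
    cap = lam < CAP_FRACTION
    labels[cap] = 17
    third = (1.0 - CAP_FRACTION) / 3.0
    apical = (~cap) & (lam < CAP_FRACTION + third)
    mid = (~cap) & (~apical) & (lam < CAP_FRACTION + 2 * third)
    basal = (~cap) & (~apical) & (~mid)

    sec6 = (np.floor((phi + np.pi / 6) / (np.pi / 3)).astype(int)) % 6   # 0..5, sector 0 centred on +x
    sec4 = (np.floor((phi + np.pi / 4) / (np.pi / 2)).astype(int)) % 4
    labels[basal] = 1 + sec6[basal]
    labels[mid] = 7 + sec6[mid]
    labels[apical] = 13 + sec4[apical]

    mesh.segment_label = labels
    missing = set(range(1, 18)) - set(np.unique(labels).tolist())
    if missing:
        raise GeometryError(f"AHA labeling left segments empty: {sorted(missing)}")
    return mesh


# --------------------------------------------------------------------------
# cube mesh (verification fixture: patch tests etc.)
# --------------------------------------------------------------------------

def build_cube_mesh(n: int = 2, L: float = 1.0) -> VolumetricMesh:
    """Structured quadratic-tet mesh of the cube [0, L]^3 (test fixture)."""
    NR = 2 * n
    ids: Dict[tuple, int] = {}
    xyz: list = []

    def nid(i, j, k):
        key = (i, j, k)
        if key not in ids:
            ids[key] = len(xyz)
            xyz.append(np.array([i, j, k], dtype=float) * (L / NR))
        return ids[key]

    cells = []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                base = np.array([2 * i, 2 * j, 2 * k])
                for tet in _CELL_TETS:
                    cells.append([nid(*(base + 2 * off)) for off in tet])
    corners = _orient_positive(np.asarray(cells, dtype=int), np.asarray(xyz))

    inv = {v: k for k, v in ids.items()}
    mids: Dict[tuple, int] = {}

    def midpoint_of(a, b):
        key = (a, b) if a < b else (b, a)
        if key not in mids:
            ia, ib = inv[a], inv[b]
            mids[key] = nid(*(((np.array(ia) + np.array(ib)) // 2)))
        return mids[key]

    elements = _attach_midside(corners, xyz, midpoint_of)
    nodes = np.asarray(xyz)
    raw = _boundary_faces(elements)
    faces = _finalize_faces(raw, nodes)
    return VolumetricMesh(nodes=nodes, elements=elements,
                          surface_tags={"boundary": faces},
                          endo_basal_ring=np.array([], dtype=int),
                          z_base=L, meta={"cube": True})


# --------------------------------------------------------------------------
# export
# --------------------------------------------------------------------------

def write_vtk(mesh: VolumetricMesh, path, point_data: Optional[dict] = None,
              cell_data: Optional[dict] = None) -> None:
    """Write the mesh as a legacy-VTK ASCII unstructured grid.

    Point/cell data arrays may be scalars (N,) or vectors (N, 3).  Readable by
    ParaView and other VTK-family tools.
    """
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    if mesh.transmural_coord is not None:
        point_data.setdefault("transmural", mesh.transmural_coord)
    if mesh.segment_label is not None:
        cell_data.setdefault("aha_segment", mesh.segment_label.astype(float))

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nlvmech mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.9g")
        E = mesh.n_elements
        fh.write(f"CELLS {E} {E * 11}\n")
        np.savetxt(fh, np.hstack([np.full((E, 1), 10), mesh.elements]), fmt="%d")
        fh.write(f"CELL_TYPES {E}\n")
        np.savetxt(fh, np.full(E, 24, dtype=int), fmt="%d")

        def _write_block(fh, data, n):
            for name, arr in data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr, fmt="%.9g")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr, fmt="%.9g")

        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            _write_block(fh, point_data, mesh.n_nodes)
        if cell_data:
            fh.write(f"CELL_DATA {E}\n")
            _write_block(fh, cell_data, E)
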