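"""Unstructured triangle meshing of the planar bifurcation.

Strategy: the geometry's tagged boundary polyline is resampled at the target
edge length; interior points are laid on a hexagonal lattice (trimmed away
from the boundary), the cloud is Delaunay-triangulated, triangles outside
the domain polygon are discarded, and interior nodes are relaxed by a few
Laplacian smoothing passes with re-triangulation.  This produces
near-isotropic meshes whose boundary edges coincide exactly with the
resampled polygon, so boundary tags partition the boundary by construction.

Wall boundary nodes carry their (vessel, side, arc-length) coordinates for
wall shear reporting; caps are tagged ``inlet`` / ``outlet_<name>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon

from .errors import GeometryError, ValidationError
from .geometry import BifurcationGeometry

__all__ = ["Mesh2D", "mesh", "channel_mesh", "write_vtk"]


def _resample_polyline(points: np.ndarray, spacing) -> np.ndarray:
    """Resample a polyline at (possibly spatially varying) spacing.

    ``spacing`` is either a float or a callable mapping (n, 2) points to
    per-point target edge lengths.  Both endpoints are kept; interior
    samples are placed by arc-length marching against the local target,
    then rescaled so the last step lands exactly on the endpoint.
    """
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]

    def interp_at(s):
        return np.column_stack(
            [np.interp(s, arc, points[:, 0]), np.interp(s, arc, points[:, 1])]
        )

    if not callable(spacing):
        n = max(1, int(round(total / spacing)))
        s_new = np.linspace(0.0, total, n + 1)
    else:
        s_new = [0.0]
        while s_new[-1] < total:
            h = float(spacing(interp_at([s_new[-1]]))[0])
            s_new.append(s_new[-1] + max(h, 1e-12))
        s_new = np.asarray(s_new)
        if s_new.size > 2:
            # rescale so the march ends exactly at the endpoint
            s_new = s_new * (total / s_new[-1])
        else:
            s_new = np.array([0.0, total])
    out = interp_at(s_new)
    out[0], out[-1] = points[0], points[-1]
    return out


@dataclass
class Mesh2D:
    """Triangle mesh with a tagged, ordered boundary.

    ``nodes[:n_boundary]`` are the boundary nodes in CCW polygon order;
    boundary edge ``i`` joins loop nodes ``i`` and ``(i+1) % n_boundary``
    and carries ``edge_tags[i]``.  ``wall_vessel``/``wall_side``/``wall_s``
    give, for each boundary node emitted from a wall piece, the vessel name,
    wall side (+1 left / -1 right of the centerline) and arc-length
    coordinate; cap nodes have vessel ``""``.
    """

    nodes: np.ndarray
    cells: np.ndarray
    n_boundary: int
    edge_tags: np.ndarray  # (n_boundary,) str, per boundary loop edge
    wall_vessel: np.ndarray  # (n_boundary,) str
    wall_side: np.ndarray  # (n_boundary,) int
    wall_s: np.ndarray  # (n_boundary,) float
    resolution: float
    _node_sets: dict = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    def boundary_edges(self) -> np.ndarray:
        nb = self.n_boundary
        return np.column_stack([np.arange(nb), (np.arange(nb) + 1) % nb])

    @property
    def tags(self) -> list[str]:
        return sorted(set(self.edge_tags.tolist()))

    def edges_of(self, tag: str) -> np.ndarray:
        """Boundary edges (node index pairs) carrying ``tag``."""
        mask = self.edge_tags == tag
        return self.boundary_edges()[mask]

    def nodes_of(self, tag: str) -> np.ndarray:
        """All nodes incident to an edge of ``tag`` (sorted)."""
        if tag not in self._node_sets:
            self._node_sets[tag] = np.unique(self.edges_of(tag))
        return self._node_sets[tag]

    def cell_areas(self) -> np.ndarray:
        p = self.nodes[self.cells]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def min_angle_deg(self) -> float:
        p = self.nodes[self.cells]
        angles = []
        for i in range(3):
            a = p[:, (i + 1) % 3] - p[:, i]
            b = p[:, (i + 2) % 3] - p[:, i]
            cosang = np.sum(a * b, axis=1) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        return float(np.min(angles))

    def wall_arclength_weights(self) -> np.ndarray:
        """Per-boundary-node wall arc length (half of adjacent wall edges)."""
        nb = self.n_boundary
        w = np.zeros(nb)
        edges = self.boundary_edges()
        lens = np.linalg.norm(
            self.nodes[edges[:, 1]] - self.nodes[edges[:, 0]], axis=1
        )
        for i in range(nb):
            if self.edge_tags[i] == "wall":
                w[edges[i, 0]] += 0.5 * lens[i]
                w[edges[i, 1]] += 0.5 * lens[i]
        return w

    def boundary_tag_codes(self) -> tuple[np.ndarray, dict[str, int]]:
        """Integer tag per node (0 = interior) and the code legend."""
        legend = {"interior": 0}
        codes = np.zeros(self.n_nodes, dtype=int)
        for i, tag in enumerate(self.tags, start=1):
            legend[tag] = i
            codes[self.nodes_of(tag)] = i
        return codes, legend

    def euler_characteristic(self) -> int:
        edges = np.sort(
            np.vstack(
                [self.cells[:, [0, 1]], self.cells[:, [1, 2]], self.cells[:, [2, 0]]]
            ),
            axis=1,
        )
        n_edges = np.unique(edges, axis=0).shape[0]
        return self.n_nodes - n_edges + self.n_cells


def _hex_lattice(bbox, h):
    """Hexagonal lattice covering bbox; returns points and (col, row) parity."""
    (xmin, ymin), (xmax, ymax) = bbox
    dy = h * np.sqrt(3.0) / 2.0
    rows = int(np.ceil((ymax - ymin) / dy)) + 1
    cols = int(np.ceil((xmax - xmin) / h)) + 1
    pts, ij = [], []
    for j in range(rows):
        y = ymin + j * dy
        offset = 0.5 * h if j % 2 else 0.0
        x = xmin + offset + np.arange(cols) * h
        pts.append(np.column_stack([x, np.full(cols, y)]))
        ij.append(np.column_stack([np.arange(cols), np.full(cols, j, dtype=int)]))
    return np.vstack(pts), np.vstack(ij)


def _triangulate(points, poly):
    tri = Delaunay(points)
    cells = tri.simplices
    # drop slivers first: Delaunay fills the convex-hull region beyond the
    # straight caps with near-zero-area triangles of almost-collinear
    # boundary points, whose centroid-in-polygon test is unreliable
    p = points[cells]
    area = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    edges = np.stack(
        [p[:, 1] - p[:, 0], p[:, 2] - p[:, 1], p[:, 0] - p[:, 2]], axis=1
    )
    lmax2 = (edges**2).sum(axis=2).max(axis=1)
    cells = cells[area > 1e-2 * lmax2]
    cent = points[cells].mean(axis=1)
    keep = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
    return cells[keep]


def mesh(
    geom: BifurcationGeometry,
    resolution: float,
    smoothing_passes: int = 4,
    min_angle_deg: float = 10.0,
    refine_lesions: bool = True,
    refine_downstream: float = 6.0e-3,
) -> Mesh2D:
    """Mesh the bifurcation at a target edge length ``resolution`` (m).

    With ``refine_lesions`` (default) the target edge length is halved
    inside each lesion and for ``refine_downstream`` meters past its distal
    shoulder — the post-stenotic jet and its separation pocket are the
    regions that drive the wall shear metrics and are otherwise the first
    to be under-resolved.

    Raises :class:`GeometryError` if the boundary cannot be recovered in the
    triangulation or the resulting cell quality falls below
    ``min_angle_deg``.
    """
    if resolution <= 0:
        raise ValidationError("resolution must be positive")
    wmin = geom.min_width()
    if resolution >= wmin:
        raise ValidationError(
            f"resolution {resolution:.4g} m must be below the minimum local "
            f"half-width {wmin:.4g} m"
        )
    spacing = resolution
    if refine_lesions and geom.lesions:
        zones = []
        for les in geom.lesions:
            v = geom.vessel(les.vessel)
            zones.append(
                (
                    les.vessel,
                    max(0.0, les.s_start - 1.0e-3),
                    min(v.length, les.s_end + refine_downstream),
                    1.6 * v.nominal_radius,
                )
            )
        ramp = 2.0e-3  # coarse-to-fine transition band, m

        def spacing(pts):
            pts = np.atleast_2d(pts)
            h = np.full(pts.shape[0], resolution)
            for vname, s0, s1, lat in zones:
                origin = geom.centerline_origin(vname)
                d = geom.centerline_direction(vname)
                nrm = geom.centerline_normal(vname)
                rel = pts - origin[None, :]
                s = rel @ d
                p = np.abs(rel @ nrm)
                d_out = np.maximum.reduce(
                    [s0 - s, s - s1, p - lat, np.zeros_like(s)]
                )
                factor = 0.5 + 0.5 * np.clip(d_out / ramp, 0.0, 1.0)
                h = np.minimum(h, resolution * factor)
            return h

    return _mesh_from_pieces(
        geom.boundary_pieces(),
        spacing,
        geom.arclength_of,
        smoothing_passes,
        min_angle_deg,
        base_resolution=resolution,
    )


def channel_mesh(
    length: float,
    half_width: float,
    resolution: float,
    smoothing_passes: int = 4,
    min_angle_deg: float = 10.0,
) -> Mesh2D:
    """Mesh a straight channel ``[0, length] x [-a, a]`` (oracle geometry).

    The single outlet is tagged ``outlet_OUT``; wall arc length is the x
    coordinate on the pseudo-vessel ``CHAN``.
    """
    if resolution <= 0 or resolution >= half_width:
        raise ValidationError("need 0 < resolution < half_width")
    L, a = length, half_width
    pieces = [
        dict(points=np.array([[0.0, -a], [L, -a]]), tag="wall",
             vessel="CHAN", side=-1),
        dict(points=np.array([[L, -a], [L, a]]), tag="outlet_OUT"),
        dict(points=np.array([[L, a], [0.0, a]]), tag="wall",
             vessel="CHAN", side=+1),
        dict(points=np.array([[0.0, a], [0.0, -a]]), tag="inlet"),
    ]

    def arclength(_name, pts):
        return np.atleast_2d(pts)[:, 0]

    return _mesh_from_pieces(
        pieces, resolution, arclength, smoothing_passes, min_angle_deg
    )


def _mesh_from_pieces(
    pieces,
    spacing,
    arclength_of,
    smoothing_passes,
    min_angle_deg,
    base_resolution=None,
) -> Mesh2D:
    resolution = base_resolution if base_resolution is not None else (
        spacing if not callable(spacing) else None
    )
    bpts, etags, wvessel, wside = [], [], [], []
    for piece in pieces:
        pts = _resample_polyline(piece["points"], spacing)
        npts = pts.shape[0] - 1  # drop shared endpoint (owned by next piece)
        bpts.append(pts[:npts])
        etags.extend([piece["tag"]] * npts)
        wvessel.extend([piece.get("vessel", "")] * npts)
        wside.extend([piece.get("side", 0)] * npts)
    boundary = np.vstack(bpts)
    nb = boundary.shape[0]
    poly = Polygon(boundary)
    if not poly.is_valid:
        raise GeometryError("boundary polygon is self-intersecting")
    if poly.exterior.is_ccw is False:
        raise GeometryError("boundary polygon is not counter-clockwise")

    bbox = (boundary.min(axis=0), boundary.max(axis=0))
    if not callable(spacing):
        lattice, _ = _hex_lattice(bbox, spacing)
        local_h = np.full(lattice.shape[0], spacing)
    else:
        # two-level lattice: fine everywhere, thinned to the coarse
        # sub-lattice (every other column of every other row) where the
        # local target is the base resolution
        fine, ij = _hex_lattice(bbox, 0.5 * resolution)
        h = spacing(fine)
        coarse_sub = (ij[:, 0] % 2 == 0) & (ij[:, 1] % 2 == 0)
        keep = (h < 0.75 * resolution) | coarse_sub
        lattice, local_h = fine[keep], h[keep]
    # guard row: one interior point facing each boundary edge keeps the
    # triangulation from skipping over collinear boundary runs (caps)
    nxt = np.roll(np.arange(nb), -1)
    tvec = boundary[nxt] - boundary
    elen = np.linalg.norm(tvec, axis=1)
    n_in = np.column_stack([-tvec[:, 1], tvec[:, 0]]) / elen[:, None]
    guards = 0.5 * (boundary + boundary[nxt]) + 0.7 * elen[:, None] * n_in
    gkeep = shapely.contains_xy(poly, guards[:, 0], guards[:, 1])
    # at corners the guard rows of adjacent walls cross: drop guards that
    # crowd the boundary or an already-kept guard
    gdist = shapely.distance(
        poly.exterior, shapely.points(guards[:, 0], guards[:, 1])
    )
    gkeep &= gdist >= 0.5 * elen
    guards, gelen = guards[gkeep], elen[gkeep]
    if guards.shape[0]:
        tree = cKDTree(guards)
        drop = np.zeros(guards.shape[0], dtype=bool)
        for i, j in sorted(tree.query_pairs(r=float(np.max(gelen)) * 0.8)):
            if np.linalg.norm(guards[i] - guards[j]) < 0.6 * min(
                gelen[i], gelen[j]
            ) and not drop[i]:
                drop[j] = True
        guards = guards[~drop]

    inside = shapely.contains_xy(poly, lattice[:, 0], lattice[:, 1])
    lattice, local_h = lattice[inside], local_h[inside]
    d = shapely.distance(
        poly.exterior, shapely.points(lattice[:, 0], lattice[:, 1])
    )
    keep = d >= 1.05 * local_h
    lattice = np.vstack([guards, lattice[keep]])
    n_fixed = nb + guards.shape[0]  # boundary and guard row stay put

    points = np.vstack([boundary, lattice])
    cells = _triangulate(points, poly)

    # Laplacian relaxation of interior nodes, then re-triangulate
    for _ in range(smoothing_passes):
        nbr_sum = np.zeros_like(points)
        nbr_cnt = np.zeros(points.shape[0])
        for a, b in ((0, 1), (1, 2), (2, 0)):
            np.add.at(nbr_sum, cells[:, a], points[cells[:, b]])
            np.add.at(nbr_cnt, cells[:, a], 1.0)
            np.add.at(nbr_sum, cells[:, b], points[cells[:, a]])
            np.add.at(nbr_cnt, cells[:, b], 1.0)
        interior = np.arange(points.shape[0]) >= n_fixed
        ok = interior & (nbr_cnt > 0)
        points[ok] = nbr_sum[ok] / nbr_cnt[ok, None]
        cells = _triangulate(points, poly)

    # drop unused points (lattice points that lost all triangles)
    used = np.zeros(points.shape[0], dtype=bool)
    used[: nb] = True
    used[cells.ravel()] = True
    remap = -np.ones(points.shape[0], dtype=int)
    remap[used] = np.arange(used.sum())
    points = points[used]
    cells = remap[cells]

    # orient CCW
    p = points[cells]
    det = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    flip = det < 0
    cells[flip] = cells[flip][:, [0, 2, 1]]

    # verify boundary recovery: free edges must be exactly the polygon edges
    all_edges = np.sort(
        np.vstack([cells[:, [0, 1]], cells[:, [1, 2]], cells[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(all_edges, axis=0, return_counts=True)
    free = {tuple(e) for e in uniq[counts == 1]}
    loop = {
        tuple(sorted((i, (i + 1) % nb))) for i in range(nb)
    }
    if free != loop:
        bad = list(free ^ loop)[:5]
        where = ", ".join(
            "(%.4g, %.4g)" % tuple(points[[a, b]].mean(axis=0)) for a, b in bad
        )
        raise GeometryError(
            "triangulation failed to recover the tagged boundary "
            f"({len(free ^ loop)} mismatched edges, near {where}); "
            "refine the resolution"
        )

    wall_s = np.zeros(nb)
    wv = np.array(wvessel, dtype=object)
    for vname in {v for v in wvessel if v}:
        sel = wv == vname
        wall_s[sel] = arclength_of(vname, boundary[sel])

    m = Mesh2D(
        nodes=points,
        cells=cells,
        n_boundary=nb,
        edge_tags=np.array(etags, dtype=object),
        wall_vessel=wv,
        wall_side=np.array(wside, dtype=int),
        wall_s=wall_s,
        resolution=resolution,
    )
    q = m.min_angle_deg()
    if q < min_angle_deg:
        raise GeometryError(
            f"mesh quality too low: minimum cell angle {q:.2f} deg "
            f"< {min_angle_deg} deg"
        )
    return m


def write_vtk(mesh: Mesh2D, path, point_data=None, cell_data=None) -> None:
    """Write the mesh (and optional fields) as a legacy-ASCII VTK file.

    Point/cell data arrays may be scalar ``(n,)`` or vector ``(n, 2)``;
    vectors are padded with a zero z-component.
    """
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ngraftflow mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y in mesh.nodes:
            f.write(f"{x:.10g} {y:.10g} 0\n")
        f.write(f"CELLS {mesh.n_cells} {4 * mesh.n_cells}\n")
        for a, b, c in mesh.cells:
            f.write(f"3 {a} {b} {c}\n")
        f.write(f"CELL_TYPES {mesh.n_cells}\n")
        f.write("5\n" * mesh.n_cells)
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2:
                    f.write(f"VECTORS {name} double\n")
                    for vx, vy in arr:
                        f.write(f"{vx:.8g} {vy:.8g} 0\n")
                else:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    for v in arr:
                        f.write(f"{v:.8g}\n")
        if cell_data:
            f.write(f"CELL_DATA {mesh.n_cells}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr)
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in arr:
                    f.write(f"{v:.8g}\n")
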