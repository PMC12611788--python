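"""Structured quarter-domain mesh for the axisymmetric cardiomyocyte model.

The quarter cell (r in [0, R], z in [0, L/2]) is meshed with a single
"spider-web" family of rays from the nuclear centre at the origin.  Along
each ray the node radii are placed on the four material interfaces
(nucleoplasm sphere, NE shell, cage ellipse, outer rectangle), so every
element lies entirely inside one subdomain and interfaces are resolved
exactly (up to the polygonal approximation of the curved boundaries).
The nuclear radius includes the envelope: the nucleoplasm reaches
radius - thickness, the NE shell spans the outer ``ne_thickness`` of the
nucleus, and the MT cage fills the gap out to its bounding ellipse.

Subdomain ids: 0 nucleoplasm, 1 NE + lamina, 2 MT cage, 3 cytoplasm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import Geometry

NUCLEOPLASM, NE, CAGE, CYTOPLASM = 0, 1, 2, 3
SUBDOMAIN_NAMES = {0: "nucleoplasm", 1: "ne", 2: "cage", 3: "cytoplasm"}


@dataclass
class QuarterMesh:
    points: np.ndarray        # (n_nodes, 2) (r, z) coordinates, µm; P2 nodes
    triangles: np.ndarray     # (n_elem, 6) P2 connectivity (3 corners, 3 mids)
    subdomain: np.ndarray     # (n_elem,) int subdomain id
    corner_points: np.ndarray  # (n_p1, 2) P1 corner coordinates
    corner_triangles: np.ndarray  # (n_elem, 3) P1 connectivity
    ring_nodes: dict          # interface name -> P1 node ids (ordered by ray)
    n_theta: int

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    def element_areas(self) -> np.ndarray:
        p = self.corner_points
        t = self.corner_triangles
        a, b, c = p[t[:, 0]], p[t[:, 1]], p[t[:, 2]]
        ab, ac = b - a, c - a
        return 0.5 * np.abs(ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])

    def subdomain_areas(self) -> dict:
        areas = self.element_areas()
        return {SUBDOMAIN_NAMES[s]: float(areas[self.subdomain == s].sum())
                for s in range(4)}


def _ray_radii(geom: Geometry, theta: float, n_nuc: int, n_ne: int,
               n_cage: int, n_cyto: int, grading: float) -> np.ndarray:
    """Node radii along one ray (excluding the shared origin node)."""
    s, c = np.sin(theta), np.cos(theta)
    rho_ne = geom.nuclear_radius                     # NE outer = nucleus
    rho_np = rho_ne - geom.ne_thickness              # nucleoplasm outer
    rho_cage = 1.0 / np.sqrt((s / geom.cage_semi_axis_r) ** 2
                             + (c / geom.cage_semi_axis_z) ** 2)
    zh = geom.cell_length / 2.0
    with np.errstate(divide="ignore"):
        rho_out = min(zh / c if c > 1e-12 else np.inf,
                      geom.cell_radius / s if s > 1e-12 else np.inf)
    radii = [rho_np * (k + 1) / n_nuc for k in range(n_nuc)]
    radii += [rho_np + geom.ne_thickness * (k + 1) / n_ne for k in range(n_ne)]
    radii += [rho_ne + (rho_cage - rho_ne) * (k + 1) / n_cage
              for k in range(n_cage)]
    # geometric grading through the cytoplasm: fine near the cage
    q = grading
    w = np.array([q ** k for k in range(n_cyto)])
    frac = np.cumsum(w) / w.sum()
    radii += list(rho_cage + (rho_out - rho_cage) * frac)
    return np.asarray(radii)


def build_quarter_mesh(geom: Geometry, n_theta: int = 32, n_nuc: int = 5,
                       n_ne: int = 2, n_cage: int = 5, n_cyto: int = 14,
                       grading: float = 1.3) -> QuarterMesh:
    """Mesh the quarter domain with quadratic (P2) triangles.

    ``n_theta`` rays span the quadrant; the ray through the outer corner of
    the rectangle is always included so the outer boundary is exact.
    ``n_ne`` >= 2 keeps at least two elements across the NE shell.
    """
    geom.validate()
    if n_ne < 2:
        raise ValueError("NE shell needs at least 2 element layers")

    zh = geom.cell_length / 2.0
    thetas = np.linspace(0.0, np.pi / 2.0, n_theta + 1)
    corner = np.arctan2(geom.cell_radius, zh)
    if not np.any(np.isclose(thetas, corner, atol=1e-12)):
        thetas = np.sort(np.append(thetas, corner))
    n_rays = len(thetas)

    n_layers = n_nuc + n_ne + n_cage + n_cyto
    pts = [np.array([0.0, 0.0])]
    ring_ids = np.empty((n_layers, n_rays), dtype=int)
    nid = 1
    for j, th in enumerate(thetas):
        radii = _ray_radii(geom, th, n_nuc, n_ne, n_cage, n_cyto, grading)
        d = np.array([np.sin(th), np.cos(th)])
        for k, rho in enumerate(radii):
            pts.append(rho * d)
            ring_ids[k, j] = nid
            nid += 1
    pts = np.array(pts)
    # snap coordinates that should be exactly on the axis / midplane / ends
    pts[np.isclose(pts[:, 0], 0.0, atol=1e-9), 0] = 0.0
    pts[np.isclose(pts[:, 1], 0.0, atol=1e-9), 1] = 0.0
    pts[np.isclose(pts[:, 1], zh, atol=1e-9), 1] = zh
    pts[np.isclose(pts[:, 0], geom.cell_radius, atol=1e-9), 0] = geom.cell_radius

    def layer_subdomain(k: int) -> int:
        if k < n_nuc:
            return NUCLEOPLASM
        if k < n_nuc + n_ne:
            return NE
        if k < n_nuc + n_ne + n_cage:
            return CAGE
        return CYTOPLASM

    tris, sub = [], []
    for j in range(n_rays - 1):           # innermost fan around the origin
        tris.append((0, ring_ids[0, j], ring_ids[0, j + 1]))
        sub.append(NUCLEOPLASM)
    for k in range(n_layers - 1):
        sd = layer_subdomain(k + 1)
        for j in range(n_rays - 1):
            a = ring_ids[k, j]
            b = ring_ids[k, j + 1]
            c = ring_ids[k + 1, j + 1]
            d = ring_ids[k + 1, j]
            tris.append((a, b, c))
            tris.append((a, c, d))
            sub.extend([sd, sd])
    tris = np.array(tris, dtype=int)
    sub = np.array(sub, dtype=int)

    # enforce counter-clockwise orientation (positive area)
    a, b, c = pts[tris[:, 0]], pts[tris[:, 1]], pts[tris[:, 2]]
    ab, ac = b - a, c - a
    det = ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0]
    flip = det < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    if np.any(np.isclose(np.abs(det), 0.0)):
        raise RuntimeError("degenerate element in mesh generation")

    ring_nodes = {
        "nucleus": ring_ids[n_nuc - 1],
        "ne_outer": ring_ids[n_nuc + n_ne - 1],
        "cage_outer": ring_ids[n_nuc + n_ne + n_cage - 1],
        "outer": ring_ids[-1],
    }

    points6, tri6 = _promote_p2(pts, tris)
    return QuarterMesh(points=points6, triangles=tri6, subdomain=sub,
                       corner_points=pts, corner_triangles=tris,
                       ring_nodes=ring_nodes, n_theta=n_theta)


def _promote_p2(pts: np.ndarray, tris: np.ndarray):
    """Add midside nodes: element nodes (v0, v1, v2, m01, m12, m20)."""
    edge_mid: dict[tuple[int, int], int] = {}
    new_pts = [pts]
    next_id = len(pts)
    tri6 = np.empty((len(tris), 6), dtype=int)
    mids_buf = []
    for e, (v0, v1, v2) in enumerate(tris):
        tri6[e, :3] = (v0, v1, v2)
        for m, (p, q) in enumerate(((v0, v1), (v1, v2), (v2, v0))):
            key = (p, q) if p < q else (q, p)
            mid = edge_mid.get(key)
            if mid is None:
                mid = next_id
                edge_mid[key] = mid
                mids_buf.append(0.5 * (pts[p] + pts[q]))
                next_id += 1
            tri6[e, 3 + m] = mid
    if mids_buf:
        new_pts.append(np.array(mids_buf))
    return np.vstack(new_pts), tri6


def refine(geom: Geometry, level: int = 1, **kw) -> QuarterMesh:
    """Uniformly refined mesh (ray and layer counts scaled by 2**level)."""
    f = 2 ** level
    base = dict(n_theta=32, n_nuc=5, n_ne=2, n_cage=5, n_cyto=14)
    base.update(kw)
    return build_quarter_mesh(
        geom, n_theta=base["n_theta"] * f, n_nuc=base["n_nuc"] * f,
        n_ne=base["n_ne"] * f, n_cage=base["n_cage"] * f,
        n_cyto=base["n_cyto"] * f)
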