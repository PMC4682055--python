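"""Polygonal tiling data structures and geometric primitives.

An epithelial sheet is represented as a planar tiling: cells are polygonal
faces, cell-cell junctions are edges, and the tissue state is carried entirely
by the vertex positions.  The same structures back both the mechanical
simulation and the quantification of boundary-angle statistics.

Angle convention (shared by every module): the anterior-posterior (AP) axis is
a direction field (uniform for a flat strip, radial for ring-shaped tissue).
The angle theta of an undirected cell boundary is the signed acute angle from
the local AP direction to the boundary line, folded into (-90, 90] degrees.
Positive theta means the boundary is tilted clockwise from the AP axis when
the tissue is drawn with the AP axis down the page ("right oblique");
negative theta is "left oblique".  Exactly perpendicular boundaries fold to
+90.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "INTERIOR",
    "UPPER_BORDER",
    "LOWER_BORDER",
    "A7_BORDER",
    "INNER_BORDER",
    "ROLE_NAMES",
    "ROLE_IDS",
    "TopologyError",
    "DegenerateGeometryError",
    "APFrame",
    "TissueMesh",
    "fold_angle_deg",
    "edge_angle",
    "junction_angles",
    "cell_area",
    "cell_perimeter",
    "build_hexagonal_sheet",
    "build_annulus_mesh",
    "validate_mesh",
    "save_mesh",
    "load_mesh",
]

# Vertex role tags.
INTERIOR = 0
UPPER_BORDER = 1
LOWER_BORDER = 2
A7_BORDER = 3
INNER_BORDER = 4

ROLE_NAMES = {
    INTERIOR: "interior",
    UPPER_BORDER: "upper_border",
    LOWER_BORDER: "lower_border",
    A7_BORDER: "a7_border",
    INNER_BORDER: "inner_border",
}
ROLE_IDS = {v: k for k, v in ROLE_NAMES.items()}

SNAPSHOT_FORMAT_VERSION = 1


class TopologyError(ValueError):
    """A mesh violates a structural invariant (winding, incidence, ...)."""


class DegenerateGeometryError(ValueError):
    """Geometric input is degenerate (zero-length edge, <3 vertices, ...)."""


# ---------------------------------------------------------------------------
# AP frame and angles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class APFrame:
    """Direction field of the anterior-posterior axis.

    mode "cartesian": one fixed unit vector ``ap_vector`` everywhere.
    mode "radial": the AP axis at a query point points from the outside
    toward ``centre`` (matching ring-shaped tissue whose anterior lies on the
    outer rim and whose posterior is the central structure).
    """

    mode: str
    ap_vector: tuple[float, float] | None = None
    centre: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("cartesian", "radial"):
            raise ValueError(f"unknown APFrame mode: {self.mode!r}")
        if self.mode == "cartesian":
            if self.ap_vector is None:
                raise ValueError("cartesian frame requires ap_vector")
            v = np.asarray(self.ap_vector, dtype=float)
            n = float(np.hypot(*v))
            if n == 0.0:
                raise ValueError("ap_vector must be nonzero")
            object.__setattr__(self, "ap_vector", (float(v[0] / n), float(v[1] / n)))
        else:
            if self.centre is None:
                raise ValueError("radial frame requires centre")
            c = np.asarray(self.centre, dtype=float)
            object.__setattr__(self, "centre", (float(c[0]), float(c[1])))

    def ap_direction(self, points: np.ndarray) -> np.ndarray:
        """Unit AP direction at each query point, shape (..., 2)."""
        pts = np.asarray(points, dtype=float)
        if self.mode == "cartesian":
            out = np.empty_like(pts)
            out[..., 0] = self.ap_vector[0]
            out[..., 1] = self.ap_vector[1]
            return out
        d = np.asarray(self.centre, dtype=float) - pts
        norm = np.linalg.norm(d, axis=-1, keepdims=True)
        if np.any(norm == 0.0):
            raise DegenerateGeometryError("query point coincides with the frame centre")
        return d / norm

    def rightward(self, points: np.ndarray) -> np.ndarray:
        """Unit vector pointing 'rightward': the AP direction rotated +90 deg.

        With the AP axis drawn down the page this is the rightward direction
        on the page; for a radial frame (AP pointing inward) it is the
        clockwise tangential direction.
        """
        ap = self.ap_direction(points)
        out = np.empty_like(ap)
        out[..., 0] = -ap[..., 1]
        out[..., 1] = ap[..., 0]
        return out


def fold_angle_deg(angle_deg):
    """Fold an angle (degrees) into (-90, 90], mapping -90 to +90."""
    a = (np.asarray(angle_deg, dtype=float) + 90.0) % 180.0 - 90.0
    a = np.where(np.abs(a + 90.0) < 1e-9, 90.0, a)
    if a.ndim == 0:
        return float(a)
    return a


def edge_angle(p1, p2, frame: APFrame, period_x: float | None = None) -> float:
    """Signed acute angle theta (degrees) of the undirected edge p1-p2.

    The AP direction is evaluated at the edge midpoint.  theta lies in
    (-90, 90]; positive values are right oblique (clockwise from the AP
    axis), and edges perpendicular to the AP axis fold to +90.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = p2 - p1
    if period_x is not None:
        d[0] = _wrap_scalar(d[0], period_x)
    if np.allclose(d, 0.0):
        raise DegenerateGeometryError("zero-length edge has no angle")
    mid = p1 + d / 2.0
    ap = frame.ap_direction(mid)
    alpha_edge = np.degrees(np.arctan2(d[1], d[0]))
    alpha_ap = np.degrees(np.arctan2(ap[1], ap[0]))
    return fold_angle_deg(alpha_ap - alpha_edge)


def junction_angles(mesh: "TissueMesh", frame: APFrame) -> np.ndarray:
    """theta for every junction of the mesh (vectorised edge_angle)."""
    p1 = mesh.positions[mesh.junctions[:, 0]]
    d = mesh.wrap_delta(mesh.positions[mesh.junctions[:, 1]] - p1)
    return angles_from_vectors(d, p1 + d / 2.0, frame)


def angles_from_vectors(d: np.ndarray, midpoints: np.ndarray, frame: APFrame) -> np.ndarray:
    """theta for precomputed edge vectors and midpoints."""
    ap = frame.ap_direction(midpoints)
    alpha_edge = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    alpha_ap = np.degrees(np.arctan2(ap[:, 1], ap[:, 0]))
    return fold_angle_deg(alpha_ap - alpha_edge)


def _wrap_scalar(dx: float, period: float) -> float:
    return (dx + period / 2.0) % period - period / 2.0


# ---------------------------------------------------------------------------
# TissueMesh
# ---------------------------------------------------------------------------


class TissueMesh:
    """Polygonal tiling: vertices, junctions and cell faces.

    Faces are stored as counter-clockwise vertex loops plus a junction table
    with incidence maps -- the simplest structure that supports T1
    reconnection.  ``period_x`` turns on periodic wrapping in x (used by the
    flat-strip scenario); all geometric routines then use minimum-image
    differences.

    Vertices carry a friction coefficient mu (force*time/length; np.inf pins
    a vertex) and a role tag used for friction maps and confinement.
    """

    def __init__(
        self,
        positions: np.ndarray,
        junctions: np.ndarray,
        faces: Sequence[Sequence[int]],
        friction: np.ndarray | None = None,
        role: np.ndarray | None = None,
        passive: np.ndarray | None = None,
        period_x: float | None = None,
        expected_euler: int = 1,
    ) -> None:
        self.positions = np.asarray(positions, dtype=float).copy()
        n = len(self.positions)
        self.junctions = np.asarray(junctions, dtype=np.int64).copy()
        self.faces = [list(map(int, loop)) for loop in faces]
        self.friction = (
            np.ones(n) if friction is None else np.asarray(friction, dtype=float).copy()
        )
        self.role = (
            np.zeros(n, dtype=np.int8)
            if role is None
            else np.asarray(role, dtype=np.int8).copy()
        )
        self.passive = (
            np.zeros(len(self.faces), dtype=bool)
            if passive is None
            else np.asarray(passive, dtype=bool).copy()
        )
        self.period_x = period_x
        self.expected_euler = expected_euler
        self._cache: dict | None = None

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def invalidate(self) -> None:
        """Drop cached topology (call after any T1 / loop mutation)."""
        self._cache = None

    def copy(self) -> "TissueMesh":
        return TissueMesh(
            self.positions,
            self.junctions,
            self.faces,
            self.friction,
            self.role,
            self.passive,
            self.period_x,
            self.expected_euler,
        )

    def topology(self) -> dict:
        """Corner arrays and incidence maps, cached until invalidated.

        Corner k is the appearance of vertex cv[k] in face cf[k]; cn/cp are
        the next/previous vertices around that face's loop.  face_start holds
        the first corner index of each face, first_vertex its anchor vertex
        (used to unwrap periodic coordinates).
        """
        if self._cache is not None:
            return self._cache
        cv, cn, cp, cf = [], [], [], []
        face_start = np.empty(len(self.faces) + 1, dtype=np.int64)
        pos = 0
        for fi, loop in enumerate(self.faces):
            face_start[fi] = pos
            m = len(loop)
            for k, v in enumerate(loop):
                cv.append(v)
                cn.append(loop[(k + 1) % m])
                cp.append(loop[(k - 1) % m])
                cf.append(fi)
            pos += m
        face_start[-1] = pos
        cv = np.array(cv, dtype=np.int64)
        cn = np.array(cn, dtype=np.int64)
        cp = np.array(cp, dtype=np.int64)
        cf = np.array(cf, dtype=np.int64)
        # Previous corner index within each face (the corner whose edge
        # vector ends at this corner's vertex).
        pc = np.empty(len(cv), dtype=np.int64)
        for fi in range(len(self.faces)):
            s, t = face_start[fi], face_start[fi + 1]
            pc[s] = t - 1
            pc[s + 1 : t] = np.arange(s, t - 1)

        pair_to_junction: dict[tuple[int, int], int] = {}
        for j, (a, b) in enumerate(self.junctions):
            pair_to_junction[(min(a, b), max(a, b))] = j

        junction_faces = np.full((len(self.junctions), 2), -1, dtype=np.int64)
        for k in range(len(cv)):
            a, b = int(cv[k]), int(cn[k])
            j = pair_to_junction.get((min(a, b), max(a, b)))
            if j is None:
                continue
            if junction_faces[j, 0] == -1:
                junction_faces[j, 0] = cf[k]
            elif junction_faces[j, 1] == -1 and junction_faces[j, 0] != cf[k]:
                junction_faces[j, 1] = cf[k]

        valence = np.zeros(self.n_vertices, dtype=np.int64)
        np.add.at(valence, self.junctions[:, 0], 1)
        np.add.at(valence, self.junctions[:, 1], 1)

        vertex_faces: list[set[int]] = [set() for _ in range(self.n_vertices)]
        for k in range(len(cv)):
            vertex_faces[cv[k]].add(int(cf[k]))

        vertex_junctions: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for j, (a, b) in enumerate(self.junctions):
            vertex_junctions[a].append(j)
            vertex_junctions[b].append(j)

        # Junctions carrying line tension: those bordering at least one
        # active (non-passive) face.  Junctions between two passive cells
        # are inert geometry.
        tension_mask = np.zeros(len(self.junctions), dtype=bool)
        for j in range(len(self.junctions)):
            for f in junction_faces[j]:
                if f >= 0 and not self.passive[f]:
                    tension_mask[j] = True

        self._cache = {
            "tension_mask": tension_mask,
            "pc": pc,
            "cv": cv,
            "cn": cn,
            "cp": cp,
            "cf": cf,
            "face_start": face_start,
            "pair_to_junction": pair_to_junction,
            "junction_faces": junction_faces,
            "valence": valence,
            "vertex_faces": vertex_faces,
            "vertex_junctions": vertex_junctions,
        }
        return self._cache

    # -- geometry ----------------------------------------------------------

    def wrap_delta(self, d: np.ndarray) -> np.ndarray:
        """Minimum-image displacement(s) for periodic meshes."""
        if self.period_x is None:
            return d
        d = np.array(d, dtype=float, copy=True)
        L = self.period_x
        d[..., 0] = (d[..., 0] + L / 2.0) % L - L / 2.0
        return d

    def junction_vectors(self) -> np.ndarray:
        return self.wrap_delta(
            self.positions[self.junctions[:, 1]] - self.positions[self.junctions[:, 0]]
        )

    def junction_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.junction_vectors(), axis=1)

    def corner_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Unwrapped corner positions p and edge vectors e = p_next - p.

        For periodic meshes each face's loop is unwrapped starting from its
        first vertex so the shoelace formula applies unchanged.
        """
        topo = self.topology()
        cv, cn, cf, face_start = topo["cv"], topo["cn"], topo["cf"], topo["face_start"]
        e = self.wrap_delta(self.positions[cn] - self.positions[cv])
        if self.period_x is None:
            return self.positions[cv], e
        cs = np.cumsum(e, axis=0)
        pre = np.vstack([np.zeros(2), cs[:-1]])
        start_pre = pre[face_start[:-1]]
        first_vertex = cv[face_start[:-1]]
        p = self.positions[first_vertex][cf] + (pre - start_pre[cf])
        return p, e

    def face_areas(self) -> np.ndarray:
        """Signed shoelace areas (positive for CCW loops)."""
        topo = self.topology()
        p, e = self.corner_coordinates()
        cross = p[:, 0] * e[:, 1] - p[:, 1] * e[:, 0]
        return 0.5 * np.bincount(topo["cf"], weights=cross, minlength=self.n_faces)

    def face_perimeters(self) -> np.ndarray:
        topo = self.topology()
        _, e = self.corner_coordinates()
        return np.bincount(
            topo["cf"], weights=np.linalg.norm(e, axis=1), minlength=self.n_faces
        )

    def face_centroids(self) -> np.ndarray:
        """Mean of (unwrapped) loop vertices; periodic meshes wrap into [0, L)."""
        topo = self.topology()
        p, _ = self.corner_coordinates()
        counts = np.bincount(topo["cf"], minlength=self.n_faces).astype(float)
        cx = np.bincount(topo["cf"], weights=p[:, 0], minlength=self.n_faces) / counts
        cy = np.bincount(topo["cf"], weights=p[:, 1], minlength=self.n_faces) / counts
        c = np.column_stack([cx, cy])
        if self.period_x is not None:
            c[:, 0] %= self.period_x
        return c


def _face_loop_coords(mesh: TissueMesh, loop: Sequence[int]) -> np.ndarray:
    """Unwrapped coordinates of one face loop (periodic-safe)."""
    pts = mesh.positions[list(loop)]
    if mesh.period_x is None:
        return pts
    out = np.empty_like(pts)
    out[0] = pts[0]
    for k in range(1, len(pts)):
        out[k] = out[k - 1] + mesh.wrap_delta(pts[k] - pts[k - 1])
    return out


def cell_area(mesh: TissueMesh, face: int | Sequence[int]) -> float:
    """Signed shoelace area of one face (positive = counter-clockwise)."""
    loop = mesh.faces[face] if isinstance(face, (int, np.integer)) else list(face)
    if len(loop) < 3:
        raise TopologyError("face with fewer than 3 vertices has no area")
    p = _face_loop_coords(mesh, loop)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def cell_perimeter(mesh: TissueMesh, face: int | Sequence[int]) -> float:
    loop = mesh.faces[face] if isinstance(face, (int, np.integer)) else list(face)
    if len(loop) < 3:
        raise TopologyError("face with fewer than 3 vertices has no perimeter")
    p = _face_loop_coords(mesh, loop)
    return float(np.sum(np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)))


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def build_hexagonal_sheet(
    rows: int,
    cols: int,
    edge_length: float,
    periodic_x: bool = False,
) -> TissueMesh:
    """Regular hexagonal tiling of ``rows`` x ``cols`` cells.

    Pointy-top hexagons in offset rows.  Vertices on the upper boundary of
    the sheet are tagged ``upper_border``, those on the lower boundary
    ``lower_border``.  With ``periodic_x`` the strip closes on itself in x
    with period cols * sqrt(3) * edge_length (a cylinder).
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if edge_length <= 0:
        raise ValueError("edge_length must be positive")
    a = float(edge_length)
    w = np.sqrt(3.0) * a
    period = cols * w if periodic_x else None

    def vkey(x: float, y: float) -> tuple[float, float]:
        if period is not None:
            x = x % period
            x = round(x, 9)
            if x >= round(period, 9):
                x = 0.0
        else:
            x = round(x, 9)
        return (x, round(y, 9))

    offsets = [
        (a * np.cos(np.radians(ang)), a * np.sin(np.radians(ang)))
        for ang in (30, 90, 150, 210, 270, 330)
    ]
    vindex: dict[tuple[float, float], int] = {}
    coords: list[tuple[float, float]] = []
    faces: list[list[int]] = []
    for j in range(rows):
        cy = j * 1.5 * a
        for i in range(cols):
            cx = i * w + (j % 2) * (w / 2.0)
            loop = []
            for ox, oy in offsets:
                key = vkey(cx + ox, cy + oy)
                if key not in vindex:
                    vindex[key] = len(coords)
                    coords.append(key)
                loop.append(vindex[key])
            faces.append(loop)

    positions = np.array(coords, dtype=float)
    junctions = _junctions_from_faces(faces)
    role = np.zeros(len(positions), dtype=np.int8)
    y_top = (rows - 1) * 1.5 * a + 0.25 * a
    y_bot = -0.25 * a
    role[positions[:, 1] > y_top] = UPPER_BORDER
    role[positions[:, 1] < y_bot] = LOWER_BORDER
    expected_euler = 0 if periodic_x else 1
    return TissueMesh(
        positions,
        junctions,
        faces,
        role=role,
        period_x=period,
        expected_euler=expected_euler,
    )


def build_annulus_mesh(
    r_inner: float,
    r_outer: float,
    n_rings: int,
    cells_per_ring: int,
) -> TissueMesh:
    """Concentric rings of hexagon-like cells between two circles.

    Rings follow a brick-wall pattern (alternate rings offset by half a cell)
    so that radial-edge endpoints are 3-valent, which is required for T1
    remodelling.  The outermost ring of faces is tagged passive (the immobile
    neighbouring-tissue layer); its outer-circle vertices carry the
    ``a7_border`` role and the innermost-circle vertices ``inner_border``.
    """
    if not (0 < r_inner < r_outer):
        raise ValueError("need 0 < r_inner < r_outer")
    if n_rings < 2:
        raise ValueError("n_rings must be >= 2")
    if cells_per_ring < 6:
        raise ValueError("cells_per_ring must be >= 6")

    C = cells_per_ring
    half = np.pi / C  # half a cell, in angle
    radii = np.linspace(r_inner, r_outer, n_rings + 1)

    # Vertices: every circle k holds 2C nodes at angles m * half.
    positions = np.empty(((n_rings + 1) * 2 * C, 2), dtype=float)
    for k in range(n_rings + 1):
        m = np.arange(2 * C)
        ang = m * half
        positions[k * 2 * C + m, 0] = radii[k] * np.cos(ang)
        positions[k * 2 * C + m, 1] = radii[k] * np.sin(ang)

    def vid(k: int, m: int) -> int:
        return k * 2 * C + (m % (2 * C))

    faces: list[list[int]] = []
    for k in range(n_rings):
        off = k % 2  # brick offset in units of `half`
        for j in range(C):
            m0 = 2 * j + off
            # CCW: inner arc in decreasing angle, outer arc in increasing angle.
            faces.append(
                [
                    vid(k, m0 + 2),
                    vid(k, m0 + 1),
                    vid(k, m0),
                    vid(k + 1, m0),
                    vid(k + 1, m0 + 1),
                    vid(k + 1, m0 + 2),
                ]
            )

    junctions = _junctions_from_faces(faces)
    role = np.zeros(len(positions), dtype=np.int8)
    role[: 2 * C] = INNER_BORDER
    # The passive outermost ring models the immobile neighbouring epidermis:
    # all of its vertices (outer circle and interface circle) carry the
    # a7_border role, so border friction acts on the attachment points of
    # the peripheral active cells as well.
    role[(n_rings - 1) * 2 * C :] = A7_BORDER
    passive = np.zeros(len(faces), dtype=bool)
    passive[(n_rings - 1) * C :] = True
    return TissueMesh(
        positions,
        junctions,
        faces,
        role=role,
        passive=passive,
        expected_euler=0,
    )


def _junctions_from_faces(faces: Sequence[Sequence[int]]) -> np.ndarray:
    pairs: dict[tuple[int, int], None] = {}
    for loop in faces:
        m = len(loop)
        for k in range(m):
            a, b = loop[k], loop[(k + 1) % m]
            pairs[(min(a, b), max(a, b))] = None
    return np.array(list(pairs.keys()), dtype=np.int64)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_mesh(mesh: TissueMesh) -> list[str]:
    """Report all structural violations (empty list = valid mesh).

    Checks: finite positions, positive friction, distinct junction endpoints,
    1-2 incident faces per junction, every face edge backed by exactly one
    junction, loop length >= 3, counter-clockwise winding, simple polygons,
    and the Euler relation V - E + F for the mesh's topology class.
    """
    report: list[str] = []
    if not np.all(np.isfinite(mesh.positions)):
        report.append("non-finite vertex positions")
    if not np.all(mesh.friction > 0):
        report.append("non-positive friction coefficient")
    if np.any(mesh.junctions[:, 0] == mesh.junctions[:, 1]):
        report.append("junction with identical endpoints")

    seen: dict[tuple[int, int], int] = {}
    for loop in mesh.faces:
        if len(loop) < 3:
            report.append(f"face loop shorter than 3: {loop}")
            continue
        if len(set(loop)) != len(loop):
            report.append(f"face loop repeats a vertex: {loop}")
        m = len(loop)
        for k in range(m):
            key = (min(loop[k], loop[(k + 1) % m]), max(loop[k], loop[(k + 1) % m]))
            seen[key] = seen.get(key, 0) + 1

    junction_set = {
        (min(int(a), int(b)), max(int(a), int(b))) for a, b in mesh.junctions
    }
    for key, count in seen.items():
        if key not in junction_set:
            report.append(f"face edge {key} missing from junction table")
        if count > 2:
            report.append(f"edge {key} bordered by {count} faces")
    for key in junction_set:
        if key not in seen:
            report.append(f"junction {key} borders no face")

    for fi, loop in enumerate(mesh.faces):
        if len(loop) < 3:
            continue
        p = _face_loop_coords(mesh, loop)
        x, y = p[:, 0], p[:, 1]
        area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        if area <= 0:
            report.append(f"face {fi} wound clockwise (signed area {area:.3g})")
        if not _is_simple_polygon(p):
            report.append(f"face {fi} is self-intersecting")

    euler = mesh.n_vertices - mesh.n_junctions + mesh.n_faces
    if euler != mesh.expected_euler:
        report.append(
            f"Euler relation violated: V-E+F={euler}, expected {mesh.expected_euler}"
        )
    return report


def _is_simple_polygon(p: np.ndarray) -> bool:
    try:
        from shapely.geometry import Polygon

        return Polygon(p).is_valid
    except Exception:  # pragma: no cover - shapely is a hard dependency
        return True


# ---------------------------------------------------------------------------
# Snapshot I/O (versioned JSON-style text format)
# ---------------------------------------------------------------------------


def save_mesh(mesh: TissueMesh, path) -> None:
    """Write a mesh snapshot as structured JSON text (model units)."""
    doc = {
        "format": "chiralsheet-mesh",
        "version": SNAPSHOT_FORMAT_VERSION,
        "period_x": mesh.period_x,
        "expected_euler": mesh.expected_euler,
        "vertices": [
            [i, float(x), float(y), float(mu), ROLE_NAMES[int(r)]]
            for i, ((x, y), mu, r) in enumerate(
                zip(mesh.positions, mesh.friction, mesh.role)
            )
        ],
        "junctions": [[j, int(a), int(b)] for j, (a, b) in enumerate(mesh.junctions)],
        "faces": [
            [f, list(map(int, loop)), bool(p)]
            for f, (loop, p) in enumerate(zip(mesh.faces, mesh.passive))
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_mesh(path) -> TissueMesh:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "chiralsheet-mesh":
        raise ValueError("not a chiralsheet mesh snapshot")
    if doc.get("version") != SNAPSHOT_FORMAT_VERSION:
        raise ValueError(f"unsupported snapshot version {doc.get('version')}")
    verts = sorted(doc["vertices"], key=lambda r: r[0])
    positions = np.array([[v[1], v[2]] for v in verts])
    friction = np.array([v[3] for v in verts])
    role = np.array([ROLE_IDS[v[4]] for v in verts], dtype=np.int8)
    juncs = sorted(doc["junctions"], key=lambda r: r[0])
    junctions = np.array([[j[1], j[2]] for j in juncs], dtype=np.int64)
    fcs = sorted(doc["faces"], key=lambda r: r[0])
    faces = [f[1] for f in fcs]
    passive = np.array([f[2] for f in fcs], dtype=bool)
    return TissueMesh(
        positions,
        junctions,
        faces,
        friction,
        role,
        passive,
        doc.get("period_x"),
        doc.get("expected_euler", 1),
    )
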