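"""Boundary, vertex and intensity extraction from segmented label images.

This is the in-vivo-facing quantification arm: it consumes already-labelled
masks (0 = boundary/background, positive integers = cell regions) produced by
any external segmentation, and reconstructs the region-adjacency structure
the angle and intensity statistics need:

* boundary pixels are zero pixels whose 8-neighbourhood contains exactly two
  distinct regions; pixels adjacent to three or more regions are vertex
  candidates, clustered (radius 2 px) into single vertices -- the points
  where three or four boundary lines meet;
* each boundary's angle is taken from the chord joining its two incident
  vertices (or its extremal pixels where it meets the tissue rim), after
  converting image row/col to y-up math coordinates so one sign convention
  governs the whole codebase;
* boundary intensities are averaged over the boundary's own pixel set
  (vertex-cluster pixels belong to no boundary) and normalised by the mean
  over all boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mesh import APFrame, DegenerateGeometryError, edge_angle

__all__ = [
    "Boundary",
    "ImagedVertex",
    "SegmentedTissue",
    "BoundaryIntensityResult",
    "extract_boundaries",
    "boundary_angle_from_pixels",
    "boundary_intensity",
    "read_label_image",
]


@dataclass
class Boundary:
    pair: tuple[int, int]               # the two region labels, sorted
    pixels: np.ndarray                  # (n, 2) row/col indices
    endpoints_xy: np.ndarray | None     # (2, 2) math coordinates, or None
    touches_border: bool                # meets the image frame -> excluded
    #                                     from angle statistics

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


@dataclass
class ImagedVertex:
    position_xy: np.ndarray             # math coordinates (x right, y up)
    labels: frozenset[int]              # regions meeting at this vertex
    pixels: np.ndarray                  # (n, 2) row/col of the cluster


@dataclass
class SegmentedTissue:
    shape: tuple[int, int]
    boundaries: dict[tuple[int, int], Boundary]
    vertices: list[ImagedVertex]
    adjacency: nx.Graph = field(default_factory=nx.Graph)


@dataclass
class BoundaryIntensityResult:
    per_boundary: pd.DataFrame          # pair, n_pixels, theta_deg,
    #                                     mean_intensity, normalized_ratio
    bin_edges: np.ndarray               # 30-degree bins over (-90, 90]
    binned_mean_ratio: np.ndarray       # mean normalised ratio per bin (nan
    #                                     for empty bins)
    left_mean: float                    # theta in (-90, 0]
    right_mean: float                   # theta in (0, 90]


def _to_xy(rc: np.ndarray, height: int) -> np.ndarray:
    """(row, col) -> (x, y) with y pointing up."""
    rc = np.atleast_2d(rc)
    return np.column_stack([rc[:, 1].astype(float), (height - 1 - rc[:, 0]).astype(float)])


def extract_boundaries(labels: np.ndarray, vertex_cluster_radius: float = 2.0) -> SegmentedTissue:
    """Build the SegmentedTissue (boundaries, vertices, adjacency) of a mask."""
    lab = np.asarray(labels)
    if lab.ndim != 2:
        raise ValueError("label image must be 2D")
    if np.any(lab < 0):
        raise ValueError("labels must be nonnegative")
    regions = np.unique(lab[lab > 0])
    if regions.size < 2:
        raise ValueError("boundary analysis needs at least 2 labelled regions")
    H, W = lab.shape

    padded = np.pad(lab, 1)
    neighbours = np.stack(
        [
            padded[1 + dr : H + 1 + dr, 1 + dc : W + 1 + dc]
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)
        ]
    )

    boundary_pixels: dict[tuple[int, int], list[tuple[int, int]]] = {}
    vertex_candidates: list[tuple[int, int, frozenset[int]]] = []
    for r, c in np.argwhere(lab == 0):
        labs = np.unique(neighbours[:, r, c])
        labs = labs[labs > 0]
        if labs.size == 2:
            pair = (int(labs[0]), int(labs[1]))
            boundary_pixels.setdefault(pair, []).append((r, c))
        elif labs.size >= 3:
            vertex_candidates.append((r, c, frozenset(int(v) for v in labs)))

    # Cluster vertex candidates within the given radius.
    vertices: list[ImagedVertex] = []
    if vertex_candidates:
        coords = np.array([(r, c) for r, c, _ in vertex_candidates], dtype=float)
        tree = cKDTree(coords)
        g = nx.Graph()
        g.add_nodes_from(range(len(coords)))
        g.add_edges_from(tree.query_pairs(vertex_cluster_radius))
        for comp in nx.connected_components(g):
            members = sorted(comp)
            rc = coords[members]
            labs = frozenset().union(*(vertex_candidates[m][2] for m in members))
            vertices.append(
                ImagedVertex(
                    position_xy=_to_xy(rc, H).mean(axis=0),
                    labels=labs,
                    pixels=rc.astype(int),
                )
            )

    boundaries: dict[tuple[int, int], Boundary] = {}
    adjacency = nx.Graph()
    adjacency.add_nodes_from(int(r) for r in regions)
    for pair, pix_list in boundary_pixels.items():
        pix = np.array(pix_list, dtype=int)
        touches = bool(
            np.any(pix[:, 0] == 0)
            or np.any(pix[:, 0] == H - 1)
            or np.any(pix[:, 1] == 0)
            or np.any(pix[:, 1] == W - 1)
        )
        endpoints = _boundary_endpoints(pix, pair, vertices, H)
        boundaries[pair] = Boundary(pair, pix, endpoints, touches)
        adjacency.add_edge(*pair)
    return SegmentedTissue(shape=(H, W), boundaries=boundaries, vertices=vertices,
                           adjacency=adjacency)


def _boundary_endpoints(
    pix: np.ndarray,
    pair: tuple[int, int],
    vertices: list[ImagedVertex],
    height: int,
    attach_radius: float = 3.0,
) -> np.ndarray | None:
    """Endpoint pair of a boundary: its two incident vertices when both
    exist, otherwise the extremal pixels along the boundary's main axis."""
    xy = _to_xy(pix, height)
    incident = []
    for v in vertices:
        if not (pair[0] in v.labels and pair[1] in v.labels):
            continue
        d = np.min(np.linalg.norm(xy - v.position_xy, axis=1))
        if d <= attach_radius:
            incident.append(v.position_xy)
    if len(incident) >= 2:
        pts = np.array(incident)
        if len(pts) > 2:
            # keep the two farthest apart
            d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
            i, j = np.unravel_index(np.argmax(d2), d2.shape)
            pts = pts[[i, j]]
        return pts
    # Fallback: extremal pixels along the principal axis.
    if len(xy) < 2:
        return None
    centred = xy - xy.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    proj = centred @ vt[0]
    e1, e2 = xy[np.argmin(proj)], xy[np.argmax(proj)]
    if np.allclose(e1, e2):
        return None
    return np.array([e1, e2])


def boundary_angle_from_pixels(boundary: Boundary, frame: APFrame) -> float | None:
    """theta of the chord joining the boundary's endpoints (None if the
    boundary is degenerate)."""
    if boundary.endpoints_xy is None:
        return None
    e1, e2 = boundary.endpoints_xy
    if np.allclose(e1, e2):
        return None
    try:
        return edge_angle(e1, e2, frame)
    except DegenerateGeometryError:
        return None


def boundary_intensity(
    seg: SegmentedTissue,
    intensity: np.ndarray,
    frame: APFrame,
    bin_width: float = 30.0,
) -> BoundaryIntensityResult:
    """Per-boundary mean intensity, normalised ratios, angle binning and
    left/right aggregate means.

    The normalisation divides each boundary's mean by the mean over all
    boundary means, so the normalised ratios average to 1 exactly.  Angle
    statistics (bins, left/right aggregates) use only boundaries with a
    measurable angle that do not touch the image frame.
    """
    img = np.asarray(intensity, dtype=float)
    if img.shape != seg.shape:
        raise ValueError("intensity image shape differs from the label image")
    rows = []
    for pair, b in sorted(seg.boundaries.items()):
        mean_int = float(img[b.pixels[:, 0], b.pixels[:, 1]].mean())
        theta = None if b.touches_border else boundary_angle_from_pixels(b, frame)
        rows.append(
            {
                "face_a": pair[0],
                "face_b": pair[1],
                "n_pixels": b.n_pixels,
                "theta_deg": np.nan if theta is None else theta,
                "mean_intensity": mean_int,
            }
        )
    per = pd.DataFrame(rows, columns=["face_a", "face_b", "n_pixels", "theta_deg",
                                      "mean_intensity"])
    if per.empty:
        raise ValueError("segmentation contains no boundaries")
    per["normalized_ratio"] = per["mean_intensity"] / per["mean_intensity"].mean()

    n_bins = int(round(180.0 / bin_width))
    edges = -90.0 + bin_width * np.arange(n_bins + 1)
    binned = np.full(n_bins, np.nan)
    scored = per.dropna(subset=["theta_deg"])
    if not scored.empty:
        idx = np.ceil((scored["theta_deg"].to_numpy() + 90.0) / bin_width).astype(int) - 1
        idx = np.clip(idx, 0, n_bins - 1)
        for k in range(n_bins):
            sel = scored["normalized_ratio"].to_numpy()[idx == k]
            if sel.size:
                binned[k] = float(sel.mean())
    left = scored[scored["theta_deg"] <= 0.0]["normalized_ratio"]
    right = scored[scored["theta_deg"] > 0.0]["normalized_ratio"]
    return BoundaryIntensityResult(
        per_boundary=per,
        bin_edges=edges,
        binned_mean_ratio=binned,
        left_mean=float(left.mean()) if len(left) else float("nan"),
        right_mean=float(right.mean()) if len(right) else float("nan"),
    )


def read_label_image(path) -> np.ndarray:
    """Read a TIFF/PNG label or intensity image as an integer array."""
    import tifffile

    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        return np.asarray(tifffile.imread(path))
    from PIL import Image

    return np.asarray(Image.open(path))
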