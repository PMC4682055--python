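"""Generators producing meshes, images and tracks with known ground truth.

These emulate the three kinds of measured data the quantification pipeline
consumes, with dials for the left-right asymmetries of interest:

* ``make_chiral_mesh`` -- an epithelial sheet whose boundary-angle
  distribution carries a controllable right bias, produced by simple shear
  (shear preserves polygon validity; the exact bias is delivered by
  exhaustively classifying every edge, never by a formula);
* ``render_labeled_tissue`` -- a label image plus an intensity channel in
  which boundary intensity varies as background * (1 + b cos 2(theta - 45)),
  the polarized-myosin pattern;
* ``make_drift_tracks`` -- cell tracks with a controllable rightward drift.

Every generator is deterministic under a fixed seed, and each returns the
ground truth needed to check the downstream metric without re-deriving
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh import APFrame, TissueMesh, build_hexagonal_sheet, edge_angle

__all__ = [
    "SyntheticMeshSpec",
    "RenderSpec",
    "SyntheticTrackSpec",
    "CANONICAL_FRAME",
    "make_chiral_mesh",
    "render_labeled_tissue",
    "make_drift_tracks",
    "write_rendered_tiffs",
]

# The generators measure angles against a fixed AP axis pointing down the
# page (anterior at the top), the convention shared by the whole package.
CANONICAL_FRAME = APFrame(mode="cartesian", ap_vector=(0.0, -1.0))


@dataclass
class SyntheticMeshSpec:
    rows: int = 10
    cols: int = 10
    edge_length: float = 1.0
    shear_bias: float = 0.3     # s: x -> x + s*y; s=0 is symmetric
    jitter: float = 0.01        # position jitter (x edge_length) breaking ties
    seed: int = 0


@dataclass
class RenderSpec:
    pixels_per_unit: float = 30.0
    intensity_bias: float = 0.5     # b in [0, 1)
    preferred_angle: float = 45.0   # degrees; intensity peaks at this theta
    noise_sd: float = 0.0           # additive intensity noise
    background: float = 100.0       # boundary baseline intensity
    interior_level: float = 0.3     # cell-interior intensity, x background
    margin: float = 1.0             # model units of canvas padding
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.intensity_bias < 1.0):
            raise ValueError("intensity_bias must be in [0, 1)")
        if self.pixels_per_unit < 4:
            raise ValueError("pixels_per_unit must be >= 4")


@dataclass
class SyntheticTrackSpec:
    n_cells: int = 15
    drift: float = 0.5          # rightward length units per frame
    noise_sd: float = 0.0       # isotropic positional noise per frame
    n_frames: int = 10
    spread: float = 10.0        # spatial spread of starting positions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")


def make_chiral_mesh(spec: SyntheticMeshSpec) -> tuple[TissueMesh, float]:
    """Hexagonal sheet under simple shear, plus its exact right-fraction.

    The returned fraction is obtained by exhaustively classifying every
    junction of the generated mesh (theta > 0 against the canonical frame);
    it is the ground truth for PCC recovery tests.
    """
    mesh = build_hexagonal_sheet(spec.rows, spec.cols, spec.edge_length)
    rng = np.random.default_rng(spec.seed)
    mesh.positions += rng.normal(
        0.0, spec.jitter * spec.edge_length, mesh.positions.shape
    )
    mesh.positions[:, 0] += spec.shear_bias * mesh.positions[:, 1]

    # Exhaustive classification, written out in elementary trigonometry.
    n_right = 0
    ap = np.degrees(np.arctan2(-1.0, 0.0))  # AP axis pointing down the page
    for a, b in mesh.junctions:
        dx, dy = mesh.positions[b] - mesh.positions[a]
        alpha = np.degrees(np.arctan2(dy, dx))
        theta = (ap - alpha + 90.0) % 180.0 - 90.0
        if np.isclose(theta, -90.0):
            theta = 90.0
        if theta > 0.0:
            n_right += 1
    return mesh, n_right / mesh.n_junctions


def render_labeled_tissue(
    mesh: TissueMesh,
    spec: RenderSpec,
    frame: APFrame = CANONICAL_FRAME,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Rasterise a mesh into (label image, intensity image, ground truth).

    Faces become labelled regions (label = face index + 1) separated by
    one-pixel zero-valued boundary lines.  The intensity of each boundary's
    pixels is background * (1 + b cos 2(theta - preferred_angle)) plus
    noise, where theta is the true junction angle; pixels where three or
    more regions meet (vertex pixels) stay at background.  The ground-truth
    table lists each interior junction's region pair, true theta and
    noiseless intensity.

    Rasterisation uses pixel-centre membership with faces scanned in index
    order (deterministic tie-breaking).
    """
    from matplotlib.path import Path as MplPath

    if mesh.period_x is not None:
        raise ValueError("cannot render a periodic mesh")
    pad = spec.margin
    ppu = spec.pixels_per_unit
    xmin, ymin = mesh.positions.min(axis=0) - pad
    xmax, ymax = mesh.positions.max(axis=0) + pad
    W = int(np.ceil((xmax - xmin) * ppu))
    H = int(np.ceil((ymax - ymin) * ppu))
    if W <= 0 or H <= 0 or W * H > 4_000_000:
        raise ValueError("mesh does not fit a reasonable canvas")

    cols = np.arange(W)
    rows = np.arange(H)
    px = xmin + (cols + 0.5) / ppu
    py = ymax - (rows + 0.5) / ppu          # row 0 at the top (y down)
    XX, YY = np.meshgrid(px, py)
    points = np.column_stack([XX.ravel(), YY.ravel()])

    labels = np.zeros(H * W, dtype=np.int32)
    for fi, loop in enumerate(mesh.faces):
        poly = mesh.positions[loop]
        lo = poly.min(axis=0) - 1.0 / ppu
        hi = poly.max(axis=0) + 1.0 / ppu
        box = (
            (points[:, 0] >= lo[0])
            & (points[:, 0] <= hi[0])
            & (points[:, 1] >= lo[1])
            & (points[:, 1] <= hi[1])
            & (labels == 0)
        )
        idx = np.flatnonzero(box)
        if idx.size == 0:
            continue
        inside = MplPath(poly).contains_points(points[idx])
        labels[idx[inside]] = fi + 1
    labels = labels.reshape(H, W)

    # Carve one-pixel boundary lines where the right or down neighbour
    # belongs to a different region.
    carve = np.zeros_like(labels, dtype=bool)
    carve[:, :-1] |= (labels[:, :-1] != labels[:, 1:]) & (labels[:, :-1] > 0) & (labels[:, 1:] > 0)
    carve[:-1, :] |= (labels[:-1, :] != labels[1:, :]) & (labels[:-1, :] > 0) & (labels[1:, :] > 0)
    labels = labels.copy()
    labels[carve] = 0

    # Ground truth per interior junction.
    topo = mesh.topology()
    jf = topo["junction_faces"]
    pair_theta: dict[tuple[int, int], float] = {}
    records = []
    for j, (f1, f2) in enumerate(jf):
        if f1 < 0 or f2 < 0:
            continue
        va, vb = mesh.junctions[j]
        theta = edge_angle(mesh.positions[va], mesh.positions[vb], frame)
        pair = (min(f1, f2) + 1, max(f1, f2) + 1)
        pair_theta[pair] = theta
        records.append(
            {
                "face_a": pair[0],
                "face_b": pair[1],
                "theta_deg": theta,
                "intensity": spec.background
                * (
                    1.0
                    + spec.intensity_bias
                    * np.cos(2.0 * np.radians(theta - spec.preferred_angle))
                ),
            }
        )
    truth = pd.DataFrame(records, columns=["face_a", "face_b", "theta_deg", "intensity"])

    # Intensity channel.
    intensity = np.full((H, W), spec.interior_level * spec.background)
    padded = np.pad(labels, 1)
    neighbours = np.stack(
        [
            padded[1 + dr : H + 1 + dr, 1 + dc : W + 1 + dc]
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)
        ]
    )
    zero_rc = np.argwhere(labels == 0)
    for r, c in zero_rc:
        labs = np.unique(neighbours[:, r, c])
        labs = labs[labs > 0]
        if labs.size == 2:
            pair = (int(labs[0]), int(labs[1]))
            theta = pair_theta.get(pair)
            if theta is None:
                intensity[r, c] = spec.background
            else:
                intensity[r, c] = spec.background * (
                    1.0
                    + spec.intensity_bias
                    * np.cos(2.0 * np.radians(theta - spec.preferred_angle))
                )
        elif labs.size >= 3:
            intensity[r, c] = spec.background

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = np.clip(
            intensity + rng.normal(0.0, spec.noise_sd, intensity.shape), 0.0, None
        )
    return labels, intensity, truth


def write_rendered_tiffs(labels, intensity, label_path, intensity_path) -> None:
    """Write the rendered pair as 16-bit TIFFs."""
    import tifffile

    tifffile.imwrite(label_path, labels.astype(np.uint16))
    scaled = np.clip(intensity, 0, None)
    scale = 65535.0 / max(float(scaled.max()), 1.0)
    tifffile.imwrite(intensity_path, (scaled * scale).astype(np.uint16))


def make_drift_tracks(spec: SyntheticTrackSpec) -> pd.DataFrame:
    """Cell tracks start + t*(drift, 0) + noise, as a tidy table.

    Columns: cell_id, time (frame index), x, y.  The drift is along the
    rightward direction of the canonical frame (+x).
    """
    rng = np.random.default_rng(spec.seed)
    starts = rng.uniform(0.0, spec.spread, size=(spec.n_cells, 2))
    rows = []
    for cid in range(spec.n_cells):
        for t in range(spec.n_frames):
            noise = (
                rng.normal(0.0, spec.noise_sd, 2)
                if spec.noise_sd > 0
                else np.zeros(2)
            )
            rows.append(
                {
                    "cell_id": cid,
                    "time": float(t),
                    "x": starts[cid, 0] + t * spec.drift + noise[0],
                    "y": starts[cid, 1] + noise[1],
                }
            )
    return pd.DataFrame(rows, columns=["cell_id", "time", "x", "y"])
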