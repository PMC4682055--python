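"""Forces, energies, chiral line tension, noise and the overdamped update.

The vertex energy is the standard form for epithelial sheets:

    E = sum_cells K/2 (A - A0)^2  +  sum_cells Gamma/2 P^2
      + sum_junctions (gamma_ij + noise_ij) * l_ij

The area term is the hydrostatic pressure of the cytoplasm, the P^2 term the
tendency of the cell perimeter to contract, and the line-tension term the
junctional contraction.  Left-right asymmetry enters only through the
junctional tension

    gamma_ij = gamma0 * 0.5 * (1 + cos 2(theta_ij - theta_pref)),

which is maximal for boundaries tilted +45 deg (right oblique) from the AP
axis and vanishes at -45 deg when theta_pref = +45 deg.  Passive (confining)
cells contribute no area or perimeter energy, but junctions they share with
active cells still carry tension.

Forces treat gamma_ij as frozen at its current value (a tension acting along
the junction); the angular gradient of gamma can be switched on via
``ChiralityParams.include_angle_gradient`` for sensitivity analysis, making
the force the exact gradient of E.

Dynamics are overdamped: dx_i/dt = F_i / mu_i, integrated with explicit
Euler.  Friction heterogeneity (mu per vertex) encodes attachment to
immobile neighbouring structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import (
    APFrame,
    TissueMesh,
    DegenerateGeometryError,
    angles_from_vectors,
    fold_angle_deg,
    junction_angles,
)

__all__ = [
    "MechanicalParams",
    "ChiralityParams",
    "NoiseParams",
    "ConfinementSpec",
    "NumericalInstabilityError",
    "chiral_line_tension",
    "junction_tensions",
    "total_energy",
    "compute_forces",
    "confinement_force",
    "sample_tension_noise",
    "step",
]


class NumericalInstabilityError(RuntimeError):
    """Vertex positions became non-finite; reduce dt."""


@dataclass
class MechanicalParams:
    """Mechanical moduli in model units (lengths scaled so A0 ~ 1)."""

    K: float = 1.0          # area stiffness, energy / length^4
    A0: float = 1.0         # target cell area, length^2
    Gamma: float = 0.04     # perimeter contractility, energy / length^2
    gamma0: float = 0.12    # line-tension scale, energy / length

    def __post_init__(self) -> None:
        if min(self.K, self.Gamma, self.gamma0) < 0 or self.A0 <= 0:
            raise ValueError("require K, Gamma, gamma0 >= 0 and A0 > 0")


@dataclass
class ChiralityParams:
    """Angle dependence of the junctional tension.

    dispersion > 0 draws a per-junction preferred angle from
    N(theta_pref, dispersion^2), modelling cell polarity directions that are
    broadly distributed rather than uniformly +45 deg.
    """

    theta_pref: float = 45.0    # degrees, in (-90, 90]
    enabled: bool = True
    dispersion: float = 0.0     # degrees
    include_angle_gradient: bool = False

    def __post_init__(self) -> None:
        if not (-90.0 < self.theta_pref <= 90.0):
            raise ValueError("theta_pref must lie in (-90, 90]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def mirrored(self) -> "ChiralityParams":
        return ChiralityParams(
            fold_angle_deg(-self.theta_pref),
            self.enabled,
            self.dispersion,
            self.include_angle_gradient,
        )


@dataclass
class NoiseParams:
    """Ornstein-Uhlenbeck tension noise per junction.

    The offset o_j relaxes with correlation time tau and has stationary
    standard deviation sigma, fluctuating the contraction force on each
    boundary (smooth in time, so the effective noise strength does not
    depend on dt).
    """

    sigma: float = 0.0      # tension units
    tau: float = 1.0        # time units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.tau <= 0:
            raise ValueError("require sigma >= 0 and tau > 0")


@dataclass
class ConfinementSpec:
    """Harmonic walls confining tagged vertices to circles.

    ``radius_by_role`` maps a vertex role tag to the radius of its circle;
    excursions beyond (or inside) the circle are pulled back with a radial
    spring of stiffness k_wall.  Vertices slide freely along the circle.
    """

    r_inner: float
    r_outer: float
    k_wall: float = 100.0
    radius_by_role: dict[int, float] = field(default_factory=dict)
    centre: tuple[float, float] = (0.0, 0.0)
    # Optional per-vertex target radius (NaN = unconfined).  When present it
    # overrides radius_by_role; scenarios use it to hold border vertices at
    # their individual initial radii.
    target_radius: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        if not (0 < self.r_inner < self.r_outer):
            raise ValueError("need 0 < r_inner < r_outer")
        if self.k_wall <= 0:
            raise ValueError("k_wall must be positive")


# ---------------------------------------------------------------------------
# Tension
# ---------------------------------------------------------------------------


def chiral_line_tension(
    theta_deg,
    params: ChiralityParams,
    gamma0: float,
    theta_pref_deg=None,
):
    """gamma(theta) = gamma0 * 0.5 * (1 + cos 2(theta - theta_pref)).

    With ``enabled=False`` the tension is the symmetric control gamma0 for
    every boundary.  ``theta_pref_deg`` overrides the preferred angle (array
    allowed, for per-junction dispersion).
    """
    theta = np.asarray(theta_deg, dtype=float)
    if not params.enabled:
        out = np.full_like(theta, float(gamma0))
        return float(out) if out.ndim == 0 else out
    pref = params.theta_pref if theta_pref_deg is None else theta_pref_deg
    val = gamma0 * 0.5 * (1.0 + np.cos(2.0 * np.radians(theta - pref)))
    return float(val) if val.ndim == 0 else val


def junction_tensions(
    mesh: TissueMesh,
    mech: MechanicalParams,
    chir: ChiralityParams,
    frame: APFrame,
    theta_pref_per_junction: np.ndarray | None = None,
) -> np.ndarray:
    """Current gamma_ij for every junction."""
    if not chir.enabled:
        return np.full(mesh.n_junctions, mech.gamma0)
    theta = junction_angles(mesh, frame)
    return chiral_line_tension(theta, chir, mech.gamma0, theta_pref_per_junction)


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------


def total_energy(
    mesh: TissueMesh,
    mech: MechanicalParams,
    chir: ChiralityParams,
    frame: APFrame,
    noise_offsets: np.ndarray | None = None,
    confinement: ConfinementSpec | None = None,
    theta_pref_per_junction: np.ndarray | None = None,
) -> float:
    """Vertex energy of the whole mesh (passive faces excluded from the
    area/perimeter sums; the optional wall energy 1/2 k d^2 is included when
    a confinement spec is given)."""
    active = ~mesh.passive
    A = mesh.face_areas()[active]
    P = mesh.face_perimeters()[active]
    E = float(
        0.5 * mech.K * np.sum((A - mech.A0) ** 2) + 0.5 * mech.Gamma * np.sum(P**2)
    )
    gamma = junction_tensions(mesh, mech, chir, frame, theta_pref_per_junction)
    if noise_offsets is not None:
        gamma = gamma + noise_offsets
    gamma = gamma * mesh.topology()["tension_mask"]
    E += float(np.sum(gamma * mesh.junction_lengths()))
    if confinement is not None:
        E += _wall_energy(mesh, confinement)
    return E


def _wall_excursion(mesh: TissueMesh, spec: ConfinementSpec):
    """Signed excursion d and outward unit vector for confined vertices."""
    if spec.target_radius is not None:
        target = np.asarray(spec.target_radius, dtype=float)
    else:
        target = np.full(mesh.n_vertices, np.nan)
        for r, rad in spec.radius_by_role.items():
            target[mesh.role == r] = rad
    mask = ~np.isnan(target)
    rel = mesh.positions[mask] - np.asarray(spec.centre)
    dist = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.where(dist[:, None] > 0, rel / np.maximum(dist, 1e-300)[:, None], 0.0)
    d = dist - target[mask]
    return mask, d, rhat


def _wall_energy(mesh: TissueMesh, spec: ConfinementSpec) -> float:
    mask, d, _ = _wall_excursion(mesh, spec)
    return float(0.5 * spec.k_wall * np.sum(d**2))


def confinement_force(position, role: int, spec: ConfinementSpec) -> np.ndarray:
    """Radial harmonic restoring force -k_wall * d * rhat for one vertex."""
    if int(role) not in spec.radius_by_role:
        return np.zeros(2)
    rel = np.asarray(position, dtype=float) - np.asarray(spec.centre)
    dist = float(np.linalg.norm(rel))
    if dist == 0.0:
        return np.zeros(2)
    d = dist - spec.radius_by_role[int(role)]
    return -spec.k_wall * d * rel / dist


# ---------------------------------------------------------------------------
# Forces
# ---------------------------------------------------------------------------


def compute_forces(
    mesh: TissueMesh,
    mech: MechanicalParams,
    chir: ChiralityParams,
    frame: APFrame,
    confinement: ConfinementSpec | None = None,
    noise_offsets: np.ndarray | None = None,
    theta_pref_per_junction: np.ndarray | None = None,
    edge_floor: float | None = None,
    k_floor: float = 1.0,
) -> np.ndarray:
    """Per-vertex force -dE/dx (gamma frozen unless include_angle_gradient).

    ``edge_floor`` switches on a short-range excluded-volume repulsion
    between junction endpoints closer than that length (magnitude
    k_floor * (1 - l/edge_floor), i.e. k_floor at contact).  It guards the
    junction classes that cannot relieve contraction through a T1 --
    boundary edges and passive-interface edges -- from being driven through
    zero length.  Scenario drivers set it to half the T1 threshold so it
    never engages before a remodelling-eligible junction triggers its T1.

    Fully vectorised over corners and junctions; this is the hot loop of the
    simulation.
    """
    topo = mesh.topology()
    cv, cn, cf, pcorner = topo["cv"], topo["cn"], topo["cf"], topo["pc"]
    pos = mesh.positions
    n = mesh.n_vertices
    n_faces = mesh.n_faces
    F = np.zeros_like(pos)

    # One geometry pass: corner edge vectors, areas, perimeters.
    e = pos[cn] - pos[cv]
    if mesh.period_x is not None:
        L = mesh.period_x
        e[:, 0] = (e[:, 0] + L / 2.0) % L - L / 2.0
        cs = np.cumsum(e, axis=0)
        pre = np.empty_like(cs)
        pre[0] = 0.0
        pre[1:] = cs[:-1]
        face_start = topo["face_start"]
        start_pre = pre[face_start[:-1]]
        first_vertex = cv[face_start[:-1]]
        p = pos[first_vertex][cf] + (pre - start_pre[cf])
    else:
        p = pos[cv]
    cross = p[:, 0] * e[:, 1] - p[:, 1] * e[:, 0]
    A = 0.5 * np.bincount(cf, weights=cross, minlength=n_faces)
    ln = np.sqrt(e[:, 0] * e[:, 0] + e[:, 1] * e[:, 1])
    P = np.bincount(cf, weights=ln, minlength=n_faces)

    coefA = np.where(mesh.passive, 0.0, -mech.K * (A - mech.A0))[cf]
    coefP = np.where(mesh.passive, 0.0, mech.Gamma * P)[cf]
    wn = e
    wp = -e[pcorner]
    un = wn / np.maximum(ln, 1e-300)[:, None]
    up = wp / np.maximum(ln[pcorner], 1e-300)[:, None]
    # dA/dp_v = 0.5 (y_next - y_prev, x_prev - x_next)
    gAx = 0.5 * (wn[:, 1] - wp[:, 1])
    gAy = 0.5 * (wp[:, 0] - wn[:, 0])
    # F_perim = Gamma * P * (un + up);  F_area = coefA * dA/dp.
    F[:, 0] += np.bincount(cv, weights=coefA * gAx + coefP * (un[:, 0] + up[:, 0]), minlength=n)
    F[:, 1] += np.bincount(cv, weights=coefA * gAy + coefP * (un[:, 1] + up[:, 1]), minlength=n)

    # Line tension: endpoints pulled together with magnitude gamma + noise.
    j1, j2 = mesh.junctions[:, 0], mesh.junctions[:, 1]
    vec = pos[j2] - pos[j1]
    if mesh.period_x is not None:
        L = mesh.period_x
        vec = vec.copy()
        vec[:, 0] = (vec[:, 0] + L / 2.0) % L - L / 2.0
    lengths = np.sqrt(vec[:, 0] * vec[:, 0] + vec[:, 1] * vec[:, 1])
    if np.any(lengths == 0.0):
        raise DegenerateGeometryError("zero-length junction in force computation")
    if chir.enabled:
        theta = angles_from_vectors(vec, pos[j1] + vec / 2.0, frame)
        gamma = chiral_line_tension(theta, chir, mech.gamma0, theta_pref_per_junction)
    else:
        gamma = np.full(mesh.n_junctions, mech.gamma0)
    if noise_offsets is not None:
        gamma = gamma + noise_offsets
    gamma = gamma * topo["tension_mask"]
    uhat = vec / lengths[:, None]
    pull = gamma[:, None] * uhat
    if edge_floor is not None:
        close = lengths < edge_floor
        if np.any(close):
            mag = np.where(close, k_floor * (1.0 - lengths / edge_floor), 0.0)
            pull = pull - mag[:, None] * uhat
    ends = np.concatenate([j1, j2])
    F[:, 0] += np.bincount(ends, weights=np.concatenate([pull[:, 0], -pull[:, 0]]), minlength=n)
    F[:, 1] += np.bincount(ends, weights=np.concatenate([pull[:, 1], -pull[:, 1]]), minlength=n)

    if chir.enabled and chir.include_angle_gradient:
        F += _tension_angle_gradient_force(
            mesh, mech, chir, frame, lengths, vec, theta_pref_per_junction
        )

    if confinement is not None:
        mask, d, rhat = _wall_excursion(mesh, confinement)
        F[mask] += -confinement.k_wall * d[:, None] * rhat
    return F


def _tension_angle_gradient_force(
    mesh: TissueMesh,
    mech: MechanicalParams,
    chir: ChiralityParams,
    frame: APFrame,
    lengths: np.ndarray,
    vec: np.ndarray,
    theta_pref_per_junction: np.ndarray | None,
) -> np.ndarray:
    """Extra force -l * dgamma/dtheta * grad(theta), the term dropped by the
    frozen-gamma convention.  theta = alpha_ap(midpoint) - alpha_edge."""
    theta = junction_angles(mesh, frame)
    pref = chir.theta_pref if theta_pref_per_junction is None else theta_pref_per_junction
    dgamma = -mech.gamma0 * np.sin(2.0 * np.radians(theta - pref))  # per radian
    dgamma = dgamma * mesh.topology()["tension_mask"]

    perp = np.column_stack([-vec[:, 1], vec[:, 0]])
    grad_alpha_edge_p2 = perp / (lengths**2)[:, None]  # d(alpha_edge)/dp2

    Fex = np.zeros_like(mesh.positions)
    j1, j2 = mesh.junctions[:, 0], mesh.junctions[:, 1]
    # alpha_edge contribution: dtheta/dp = -d(alpha_edge)/dp.
    contrib2 = (lengths * dgamma)[:, None] * grad_alpha_edge_p2
    np.add.at(Fex[:, 0], j2, contrib2[:, 0])
    np.add.at(Fex[:, 1], j2, contrib2[:, 1])
    np.add.at(Fex[:, 0], j1, -contrib2[:, 0])
    np.add.at(Fex[:, 1], j1, -contrib2[:, 1])

    if frame.mode == "radial":
        # alpha_ap depends on the midpoint: ap dir = centre - m.
        mid = mesh.positions[j1] + vec / 2.0
        dvec = np.asarray(frame.centre) - mid
        dist2 = np.sum(dvec**2, axis=1)
        perp_ap = np.column_stack([-dvec[:, 1], dvec[:, 0]])
        # d(alpha_ap)/dm = -perp_ap / |d|^2 (since d = centre - m).
        grad_ap_m = -perp_ap / dist2[:, None]
        contrib_m = -(lengths * dgamma)[:, None] * 0.5 * grad_ap_m
        np.add.at(Fex[:, 0], j1, contrib_m[:, 0])
        np.add.at(Fex[:, 1], j1, contrib_m[:, 1])
        np.add.at(Fex[:, 0], j2, contrib_m[:, 0])
        np.add.at(Fex[:, 1], j2, contrib_m[:, 1])
    return Fex


# ---------------------------------------------------------------------------
# Noise and time stepping
# ---------------------------------------------------------------------------


def sample_tension_noise(
    offsets: np.ndarray,
    params: NoiseParams,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact Ornstein-Uhlenbeck update of the per-junction tension offsets.

    o' = o e^{-dt/tau} + sigma sqrt(1 - e^{-2 dt/tau}) xi,  xi ~ N(0, 1).
    Stationary distribution N(0, sigma^2) for any dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if params.sigma == 0.0:
        return offsets.copy()
    decay = np.exp(-dt / params.tau)
    kick = params.sigma * np.sqrt(1.0 - decay**2)
    return offsets * decay + kick * rng.standard_normal(len(offsets))


def step(mesh: TissueMesh, forces: np.ndarray, dt: float) -> TissueMesh:
    """Overdamped explicit Euler update x_i <- x_i + (F_i / mu_i) dt.

    Mutates and returns the mesh.  Vertices with mu = inf do not move.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    with np.errstate(divide="ignore"):
        mesh.positions += forces / mesh.friction[:, None] * dt
    if mesh.period_x is not None:
        mesh.positions[:, 0] %= mesh.period_x
    if not np.all(np.isfinite(mesh.positions)):
        raise NumericalInstabilityError(
            "non-finite vertex positions after update; reduce dt"
        )
    return mesh
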