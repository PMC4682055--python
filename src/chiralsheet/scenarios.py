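"""End-to-end simulation drivers for the two in-silico experiments.

``flat``: a rectangular strip of cells, periodic in the direction of motion,
with a passive top row representing the immobile neighbouring layer.  The AP
axis is a fixed vector perpendicular to the direction of motion.  Friction
contrast between the upper border (mu_upper) and the rest (mu_lower) breaks
the up/down symmetry, so chiral junction remodelling translates the mobile
rows sideways.

``annulus``: rings of cells confined between two circles, with a passive
outermost ring whose outer vertices carry high friction (the immobile
epidermis) and are held on the outer circle by a harmonic wall; the inner
circle confines the innermost vertices.  The AP axis is radial, so
"rightward" is one fixed tangential sense and sustained rightward motion is
rotation of the whole ring.

Every run is bitwise deterministic given its config and seed.  Initial
vertex positions receive a small seeded jitter so that the starting
boundary-angle distribution is unbiased rather than locked to the lattice
directions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import (
    A7_BORDER,
    INNER_BORDER,
    ROLE_IDS,
    UPPER_BORDER,
    APFrame,
    TissueMesh,
    build_annulus_mesh,
    build_hexagonal_sheet,
    save_mesh,
    validate_mesh,
)
from .mechanics import (
    ChiralityParams,
    ConfinementSpec,
    MechanicalParams,
    NoiseParams,
    compute_forces,
    sample_tension_noise,
    step,
)
from .remodeling import IntercalationEvent, RemodelingParams, remodel_pass

__all__ = ["ScenarioConfig", "Trajectory", "run_flat_scenario", "run_annulus_scenario",
           "flat_default", "annulus_default", "run_scenario"]


@dataclass
class ScenarioConfig:
    scenario: str = "flat"              # "flat" | "annulus"
    # flat geometry
    rows: int = 8
    cols: int = 14
    edge_length: float = 0.6204         # hexagon edge giving unit cell area
    # annulus geometry
    r_inner: float = 6.0
    r_outer: float = 10.0
    n_rings: int = 5                    # total rings; outermost is passive
    cells_per_ring: int = 40
    # physics
    mechanics: MechanicalParams = field(default_factory=MechanicalParams)
    chirality: ChiralityParams = field(default_factory=ChiralityParams)
    noise: NoiseParams = field(default_factory=lambda: NoiseParams(sigma=0.0))
    # remodelling (t1_threshold=None -> 0.1 x initial mean edge length)
    t1_threshold: float | None = None
    post_factor: float = 1.5
    cooldown_steps: int = 10
    # friction by vertex role (model units)
    friction: dict[str, float] = field(
        default_factory=lambda: {
            "interior": 1.0,
            "upper_border": 100.0,
            "lower_border": 1.0,
            "a7_border": 100.0,
            "inner_border": 1.0,
        }
    )
    k_wall: float = 100.0
    # integration
    dt: float = 0.01
    n_steps: int = 20000
    snapshot_every: int = 200
    seed: int = 0
    init_jitter: float = 0.05           # st.dev. of position jitter, x mean edge

    def __post_init__(self) -> None:
        if self.scenario not in ("flat", "annulus"):
            raise ValueError("scenario must be 'flat' or 'annulus'")
        if self.dt <= 0 or self.n_steps < 1:
            raise ValueError("require dt > 0 and n_steps >= 1")


def flat_default(**overrides) -> ScenarioConfig:
    """Flat-strip conditions, with fluctuating junctional shrinkage
    (sigma = 0.5 gamma0) so that junctions reach the remodelling threshold."""
    cfg = ScenarioConfig(scenario="flat", **overrides)
    if "noise" not in overrides:
        cfg.noise = NoiseParams(sigma=0.5 * cfg.mechanics.gamma0)
    return cfg


def annulus_default(**overrides) -> ScenarioConfig:
    """Ring conditions: fluctuating junctional shrinkage, sigma = 0.5 gamma0."""
    cfg = ScenarioConfig(scenario="annulus", **overrides)
    if "noise" not in overrides:
        cfg.noise = NoiseParams(sigma=0.5 * cfg.mechanics.gamma0)
    return cfg


@dataclass
class Trajectory:
    config: ScenarioConfig
    frame: APFrame
    times: list[float]
    snapshots: list[TissueMesh]
    events: list[IntercalationEvent]
    tracks: pd.DataFrame                # cell_id, time, x, y (x unwrapped)
    issues: list[str]

    @property
    def n_events(self) -> int:
        return len(self.events)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "time": e.time,
                    "junction_id": e.junction_id,
                    "pre_angle_deg": e.pre_angle_deg,
                    "x": e.location[0],
                    "y": e.location[1],
                }
                for e in self.events
            ],
            columns=["time", "junction_id", "pre_angle_deg", "x", "y"],
        )

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.tracks.to_csv(out / "tracks.csv", index=False)
        self.events_frame().to_csv(out / "events.csv", index=False)
        save_mesh(self.snapshots[0], out / "mesh_initial.json")
        save_mesh(self.snapshots[-1], out / "mesh_final.json")
        (out / "config.txt").write_text(config_to_text(self.config))


def run_flat_scenario(config: ScenarioConfig) -> Trajectory:
    if config.scenario != "flat":
        raise ValueError("config.scenario must be 'flat'")
    mesh = build_hexagonal_sheet(
        config.rows, config.cols, config.edge_length, periodic_x=True
    )
    # Top row of cells is the passive layer attached to the upper plate;
    # all of its vertices (top chain and interface chain) are "upper".
    mesh.passive[(config.rows - 1) * config.cols :] = True
    for fi in np.flatnonzero(mesh.passive):
        for v in mesh.faces[fi]:
            mesh.role[v] = UPPER_BORDER
    frame = APFrame(mode="cartesian", ap_vector=(0.0, -1.0))
    return _run(mesh, frame, config, confinement=None)


def run_annulus_scenario(config: ScenarioConfig) -> Trajectory:
    if config.scenario != "annulus":
        raise ValueError("config.scenario must be 'annulus'")
    mesh = build_annulus_mesh(
        config.r_inner, config.r_outer, config.n_rings, config.cells_per_ring
    )
    frame = APFrame(mode="radial", centre=(0.0, 0.0))
    # Confine inner-border vertices to the inner circle and every passive
    # (A7) vertex to its own initial radius -- the outer circle for the
    # outer chain, the interface circle for the attachment chain.
    target = np.full(mesh.n_vertices, np.nan)
    radii = np.linalg.norm(mesh.positions, axis=1)
    target[mesh.role == INNER_BORDER] = config.r_inner
    target[mesh.role == A7_BORDER] = radii[mesh.role == A7_BORDER]
    confinement = ConfinementSpec(
        r_inner=config.r_inner,
        r_outer=config.r_outer,
        k_wall=config.k_wall,
        radius_by_role={A7_BORDER: config.r_outer, INNER_BORDER: config.r_inner},
        target_radius=target,
    )
    return _run(mesh, frame, config, confinement)


def run_scenario(config: ScenarioConfig) -> Trajectory:
    if config.scenario == "flat":
        return run_flat_scenario(config)
    return run_annulus_scenario(config)


def _run(
    mesh: TissueMesh,
    frame: APFrame,
    cfg: ScenarioConfig,
    confinement: ConfinementSpec | None,
) -> Trajectory:
    rng = np.random.default_rng(cfg.seed)
    for role_name, mu in cfg.friction.items():
        mesh.friction[mesh.role == ROLE_IDS[role_name]] = mu

    mean_edge = float(mesh.junction_lengths().mean())
    mesh.positions += rng.normal(0.0, cfg.init_jitter * mean_edge, mesh.positions.shape)
    if mesh.period_x is not None:
        mesh.positions[:, 0] %= mesh.period_x

    remodel = RemodelingParams(
        t1_threshold=cfg.t1_threshold if cfg.t1_threshold is not None else 0.1 * mean_edge,
        post_factor=cfg.post_factor,
        cooldown_steps=cfg.cooldown_steps,
    )
    theta_pref_j = None
    if cfg.chirality.dispersion > 0:
        theta_pref_j = cfg.chirality.theta_pref + rng.normal(
            0.0, cfg.chirality.dispersion, mesh.n_junctions
        )

    offsets = np.zeros(mesh.n_junctions)
    cooldown: dict[int, int] = {}
    events: list[IntercalationEvent] = []
    issues: list[str] = list(validate_mesh(mesh))
    counts0 = (mesh.n_vertices, mesh.n_junctions, mesh.n_faces)
    passive0 = mesh.passive.copy()

    times = [0.0]
    snapshots = [mesh.copy()]
    for i in range(cfg.n_steps):
        offsets = sample_tension_noise(offsets, cfg.noise, cfg.dt, rng)
        forces = compute_forces(
            mesh,
            cfg.mechanics,
            cfg.chirality,
            frame,
            confinement=confinement,
            noise_offsets=offsets,
            theta_pref_per_junction=theta_pref_j,
            edge_floor=0.5 * remodel.t1_threshold,
        )
        step(mesh, forces, cfg.dt)
        t = (i + 1) * cfg.dt
        new_events = remodel_pass(
            mesh, remodel, t, frame, cooldown, i, noise_offsets=offsets
        )
        if new_events:
            events.extend(new_events)
            if (mesh.n_vertices, mesh.n_junctions, mesh.n_faces) != counts0:
                issues.append(f"topology counts changed at t={t}")
            if not np.array_equal(mesh.passive, passive0):
                issues.append(f"passive-face set changed at t={t}")
        if (i + 1) % cfg.snapshot_every == 0:
            times.append(t)
            snapshots.append(mesh.copy())
    issues.extend(validate_mesh(mesh))

    tracks = _centroid_tracks(snapshots, times)
    return Trajectory(cfg, frame, times, snapshots, events, tracks, issues)


def _centroid_tracks(snapshots: list[TissueMesh], times: list[float]) -> pd.DataFrame:
    """Per-cell centroid time series; x unwrapped for periodic meshes so
    displacements are continuous across the seam."""
    period = snapshots[0].period_x
    cents = np.stack([m.face_centroids() for m in snapshots])  # (T, F, 2)
    if period is not None:
        dx = np.diff(cents[:, :, 0], axis=0)
        dx = (dx + period / 2.0) % period - period / 2.0
        cents[1:, :, 0] = cents[0, :, 0] + np.cumsum(dx, axis=0)
    n_t, n_f, _ = cents.shape
    return pd.DataFrame(
        {
            "cell_id": np.tile(np.arange(n_f), n_t),
            "time": np.repeat(times, n_f),
            "x": cents[:, :, 0].ravel(),
            "y": cents[:, :, 1].ravel(),
        }
    )


# ---------------------------------------------------------------------------
# Config file I/O: flat dotted-key text, all defaults overridable
# ---------------------------------------------------------------------------

_SUBSECTIONS = {"mechanics": MechanicalParams, "chirality": ChiralityParams,
                "noise": NoiseParams}


def config_to_text(cfg: ScenarioConfig) -> str:
    lines = []
    for f in dataclasses.fields(cfg):
        val = getattr(cfg, f.name)
        if f.name in _SUBSECTIONS:
            for sub in dataclasses.fields(val):
                lines.append(f"{f.name}.{sub.name} = {getattr(val, sub.name)!r}")
        elif f.name == "friction":
            for role, mu in val.items():
                lines.append(f"friction.{role} = {mu!r}")
        else:
            lines.append(f"{f.name} = {val!r}")
    return "\n".join(lines) + "\n"


def config_from_text(text: str) -> ScenarioConfig:
    import ast

    cfg = ScenarioConfig()
    sub_kwargs: dict[str, dict] = {name: {} for name in _SUBSECTIONS}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), ast.literal_eval(value.strip())
        if "." in key:
            section, sub = key.split(".", 1)
            if section in _SUBSECTIONS:
                valid = {f.name for f in dataclasses.fields(_SUBSECTIONS[section])}
                if sub not in valid:
                    raise ValueError(f"unknown config key {key!r}")
                sub_kwargs[section][sub] = value
            elif section == "friction":
                if sub not in ROLE_IDS:
                    raise ValueError(f"unknown vertex role {sub!r}")
                cfg.friction[sub] = value
            else:
                raise ValueError(f"unknown config section {section!r}")
        else:
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(cfg, key, value)
    for name, cls in _SUBSECTIONS.items():
        if sub_kwargs[name]:
            setattr(cfg, name, cls(**{**dataclasses.asdict(getattr(cfg, name)),
                                      **sub_kwargs[name]}))
    cfg.__post_init__()
    return cfg


def load_config(path) -> ScenarioConfig:
    return config_from_text(Path(path).read_text())


def save_config(cfg: ScenarioConfig, path) -> None:
    Path(path).write_text(config_to_text(cfg))
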