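"""Ensemble experiments over the flat-strip and annulus scenarios.

These wrap the scenario drivers into the replicated experiments the
directional-motion analysis needs: for each variant (chiral, mirrored
chirality, chirality disabled) a set of seeded runs is summarised into the
per-run quantities of interest -- mean rightward displacement or tangential
velocity of the active cells, logged intercalation angles, the left/right
boundary-angle census at the start and end of the run, and mesh-integrity
flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mechanics import ChiralityParams
from .mesh import validate_mesh
from .quantify import boundary_angles, mean_tangential_velocity, pcc_fraction
from .scenarios import (
    Trajectory,
    annulus_default,
    flat_default,
    run_annulus_scenario,
    run_flat_scenario,
)

__all__ = ["RunSummary", "run_variant", "run_ensemble", "sign_test_p", "VARIANTS"]

VARIANTS = ("chiral", "mirrored", "control")


def _chirality(variant: str) -> ChiralityParams:
    if variant == "chiral":
        return ChiralityParams(theta_pref=45.0)
    if variant == "mirrored":
        return ChiralityParams(theta_pref=-45.0)
    if variant == "control":
        return ChiralityParams(enabled=False)
    raise ValueError(f"unknown variant {variant!r}")


@dataclass
class RunSummary:
    scenario: str
    variant: str
    seed: int
    n_events: int
    event_angles: np.ndarray          # pre-remodelling theta of each T1
    rightward: float                  # flat: mean displacement of active
    #                                   cells; annulus: mean tangential
    #                                   velocity of active cells
    pcc_t0: tuple[int, int]           # (n_left, n_right) at t = 0
    pcc_end: tuple[int, int]          # (n_left, n_right) at end of run
    n_boundaries: int                 # scored boundaries per snapshot
    topology_ok: bool
    issues: list[str] = field(default_factory=list)


def run_variant(
    scenario: str,
    variant: str,
    seed: int,
    n_steps: int = 20000,
) -> RunSummary:
    """One full scenario run, summarised."""
    chir = _chirality(variant)
    if scenario == "flat":
        cfg = flat_default(seed=seed, n_steps=n_steps, chirality=chir)
        traj = run_flat_scenario(cfg)
    elif scenario == "annulus":
        cfg = annulus_default(seed=seed, n_steps=n_steps, chirality=chir)
        traj = run_annulus_scenario(cfg)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return summarize(traj)


def summarize(traj: Trajectory) -> RunSummary:
    first = traj.snapshots[0]
    last = traj.snapshots[-1]
    active = np.flatnonzero(~first.passive)
    tracks = traj.tracks[traj.tracks.cell_id.isin(active)]

    if traj.config.scenario == "flat":
        t_first = tracks[tracks.time == tracks.time.min()].set_index("cell_id")
        t_last = tracks[tracks.time == tracks.time.max()].set_index("cell_id")
        # rightward = +x for the downward AP axis of the flat strip
        rightward = float((t_last.x - t_first.x).mean())
    else:
        rightward = mean_tangential_velocity(tracks, traj.frame, 1.0).grand_mean

    p0 = pcc_fraction(boundary_angles(first, traj.frame))
    p1 = pcc_fraction(boundary_angles(last, traj.frame))
    issues = list(traj.issues) + validate_mesh(last)
    return RunSummary(
        scenario=traj.config.scenario,
        variant="chiral" if traj.config.chirality.enabled
        and traj.config.chirality.theta_pref > 0
        else ("mirrored" if traj.config.chirality.enabled else "control"),
        seed=traj.config.seed,
        n_events=traj.n_events,
        event_angles=np.array([e.pre_angle_deg for e in traj.events]),
        rightward=rightward,
        pcc_t0=(p0.n_left, p0.n_right),
        pcc_end=(p1.n_left, p1.n_right),
        n_boundaries=p0.total,
        topology_ok=not issues,
        issues=issues,
    )


def run_ensemble(
    scenario: str,
    variant: str,
    seeds,
    n_steps: int = 20000,
) -> list[RunSummary]:
    return [run_variant(scenario, variant, int(s), n_steps) for s in seeds]


def sign_test_p(values) -> float:
    """One-sided sign test: P(#positive >= observed | p = 1/2)."""
    from scipy.stats import binomtest

    values = np.asarray(values, dtype=float)
    n = len(values)
    k = int(np.count_nonzero(values > 0))
    return float(binomtest(k, n, alternative="greater").pvalue)


def derive_seeds(base_seed: int, n: int, salt: int = 0) -> list[int]:
    """Deterministic child seeds below 2^31."""
    ss = np.random.SeedSequence([base_seed, salt])
    return [int(s) % (2**31) for s in ss.generate_state(n)]
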