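"""T1 junction reconnection (cell intercalation) and event logging.

A junction shorter than the threshold l_T1 whose endpoints are both
3-valent interior vertices collapses to its midpoint and reopens rotated
90 degrees at length post_factor * l_T1.  The two cells that shared the
junction separate and the two flanking cells gain a shared boundary.  The
operation is atomic (no persistent 4-valent vertex) and conserves V, E, F.

Each event records the angle theta of the shrinking boundary immediately
before reconnection -- the quantity measured on intercalating boundaries in
live imaging ("before remodelling").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import APFrame, TissueMesh, edge_angle

__all__ = [
    "RemodelingParams",
    "IntercalationEvent",
    "T1Skip",
    "find_t1_candidates",
    "apply_t1",
    "remodel_pass",
]


@dataclass
class RemodelingParams:
    t1_threshold: float = 0.06      # l_T1, model length units
    post_factor: float = 1.5        # new edge length = post_factor * l_T1
    cooldown_steps: int = 10        # steps a remodelled junction is frozen

    def __post_init__(self) -> None:
        if self.t1_threshold <= 0:
            raise ValueError("t1_threshold must be positive")
        if self.post_factor <= 1:
            raise ValueError("post_factor must exceed 1")
        if self.cooldown_steps < 0:
            raise ValueError("cooldown_steps must be >= 0")


@dataclass
class IntercalationEvent:
    time: float
    junction_id: int
    pre_angle_deg: float    # theta of the shrinking boundary, in (-90, 90]
    location: tuple[float, float]
    pre_endpoints: tuple[tuple[float, float], tuple[float, float]] = None


class T1Skip(RuntimeError):
    """The junction cannot be remodelled (boundary, 4-valent, 2-gon...)."""


def find_t1_candidates(
    mesh: TissueMesh,
    params: RemodelingParams,
    cooldown: dict[int, int] | None = None,
    now_step: int = 0,
) -> list[int]:
    """Junction ids eligible for a T1, sorted by (length, id) ascending.

    Eligible: length < l_T1; two incident faces, neither passive; both
    endpoints 3-valent with three incident faces (true interior); not in
    cooldown.
    """
    topo = mesh.topology()
    lengths = mesh.junction_lengths()
    jf = topo["junction_faces"]
    valence = topo["valence"]
    vertex_faces = topo["vertex_faces"]

    short = np.flatnonzero(lengths < params.t1_threshold)
    out: list[tuple[float, int]] = []
    for j in short:
        j = int(j)
        if cooldown is not None and cooldown.get(j, -(10**9)) + params.cooldown_steps >= now_step:
            continue
        f1, f2 = jf[j]
        if f1 < 0 or f2 < 0 or mesh.passive[f1] or mesh.passive[f2]:
            continue
        a, b = map(int, mesh.junctions[j])
        if valence[a] != 3 or valence[b] != 3:
            continue
        if len(vertex_faces[a]) != 3 or len(vertex_faces[b]) != 3:
            continue
        if len(mesh.faces[f1]) < 4 or len(mesh.faces[f2]) < 4:
            continue
        out.append((float(lengths[j]), j))
    out.sort()
    return [j for _, j in out]


def apply_t1(
    mesh: TissueMesh,
    junction: int,
    params: RemodelingParams,
    time: float,
    frame: APFrame,
) -> IntercalationEvent:
    """Execute one T1 on ``junction`` (must satisfy the candidate rules).

    Mutates the mesh in place and returns the event carrying the
    pre-remodelling boundary angle.  Raises ``T1Skip`` for configurations
    that cannot be reconnected.
    """
    topo = mesh.topology()
    jf = topo["junction_faces"]
    vertex_faces = topo["vertex_faces"]
    vertex_junctions = topo["vertex_junctions"]

    a, b = map(int, mesh.junctions[junction])
    f1, f2 = map(int, jf[junction])
    if f1 < 0 or f2 < 0:
        raise T1Skip("boundary junction cannot remodel")
    if topo["valence"][a] != 3 or topo["valence"][b] != 3:
        raise T1Skip("T1 requires 3-valent endpoints")
    if len(mesh.faces[f1]) < 4 or len(mesh.faces[f2]) < 4:
        raise T1Skip("T1 would create a 2-gon")
    fa_set = vertex_faces[a] - {f1, f2}
    fb_set = vertex_faces[b] - {f1, f2}
    if len(fa_set) != 1 or len(fb_set) != 1:
        raise T1Skip("endpoint lacks a flanking face")
    fa, fb = fa_set.pop(), fb_set.pop()

    pa = mesh.positions[a].copy()
    pb = mesh.positions[b].copy()
    d = mesh.wrap_delta(pb - pa)
    ell = float(np.hypot(*d))
    if ell == 0.0:
        raise T1Skip("zero-length junction")
    mid = pa + d / 2.0
    dhat = d / ell
    nhat = np.array([-dhat[1], dhat[0]])  # rotate edge direction +90 deg

    event = IntercalationEvent(
        time=time,
        junction_id=int(junction),
        pre_angle_deg=edge_angle(pa, pb, frame, mesh.period_x),
        location=(float(mid[0]), float(mid[1])),
        pre_endpoints=((float(pa[0]), float(pa[1])), (float(pb[0]), float(pb[1]))),
    )

    # Topological rewiring, read off the two sharing faces' loops.  In each
    # sharing face the pair appears as ...x, first, second...: the junction
    # (x, first) is reattached to `second` and the face drops `first`.  The
    # edge is traversed in opposite senses by the two faces, so each face
    # drops a different endpoint and each endpoint trades one neighbour.
    neighbours_a = set()
    neighbours_b = set()
    for j in vertex_junctions[a]:
        if j != junction:
            neighbours_a.add(int(mesh.junctions[j].sum() - a))
    for j in vertex_junctions[b]:
        if j != junction:
            neighbours_b.add(int(mesh.junctions[j].sum() - b))
    if neighbours_a & neighbours_b:
        raise T1Skip("endpoints share a neighbour (would duplicate a junction)")
    if fa == fb:
        raise T1Skip("flanking faces coincide")

    pair_to_junction = topo["pair_to_junction"]
    rewired: list[tuple[int, int, int, int]] = []  # (junction, old_end, new_end, x)
    for f in (f1, f2):
        loop = mesh.faces[f]
        ia, ib = loop.index(a), loop.index(b)
        m = len(loop)
        if (ia + 1) % m == ib:
            first, second = a, b
            x = loop[(ia - 1) % m]
        elif (ib + 1) % m == ia:
            first, second = b, a
            x = loop[(ib - 1) % m]
        else:
            raise T1Skip("junction endpoints not adjacent in sharing face")
        j = pair_to_junction.get((min(x, first), max(x, first)))
        if j is None or j == junction:
            raise T1Skip("inconsistent incidence at sharing face")
        rewired.append((j, first, second, x))

    for j, old_end, new_end, _ in rewired:
        if mesh.junctions[j, 0] == old_end:
            mesh.junctions[j, 0] = new_end
        else:
            mesh.junctions[j, 1] = new_end

    # Sharing faces drop the endpoint they rewired away from.
    for (f, (_, first, _, _)) in zip((f1, f2), rewired):
        mesh.faces[f].remove(first)

    # Flanking faces gain the opposite endpoint, inserted between the
    # rewired neighbour x and the kept endpoint.
    for f, kept, gained in ((fa, a, b), (fb, b, a)):
        loop = mesh.faces[f]
        ik = loop.index(kept)
        m = len(loop)
        inserted = False
        for _, old_end, new_end, x in rewired:
            if old_end == kept and new_end == gained:
                prev_v, next_v = loop[(ik - 1) % m], loop[(ik + 1) % m]
                if prev_v == x:
                    loop.insert(ik, gained)
                elif next_v == x:
                    loop.insert(ik + 1, gained)
                else:
                    raise T1Skip("flanking face does not contain rewired neighbour")
                inserted = True
        if not inserted:
            raise T1Skip("could not resolve flanking-face update")

    # Reopen perpendicular: place each endpoint towards the mean direction
    # of its new non-partner neighbours (deterministic and consistent with
    # the rewiring above); the axis is the 90-degree rotation of the old
    # edge up to which endpoint sits on which side.
    new_half = 0.5 * params.post_factor * params.t1_threshold
    dir_a = np.zeros(2)
    for j2 in range(mesh.n_junctions):
        va, vb = mesh.junctions[j2]
        if j2 == junction:
            continue
        if va == a or vb == a:
            other = int(va + vb - a)
            rel = mesh.wrap_delta(mesh.positions[other] - mid)
            n = np.linalg.norm(rel)
            if n > 0:
                dir_a += rel / n
    sign = 1.0 if float(dir_a @ nhat) >= 0.0 else -1.0
    new_a = mid + sign * new_half * nhat
    new_b = mid - sign * new_half * nhat
    if mesh.period_x is not None:
        new_a[0] %= mesh.period_x
        new_b[0] %= mesh.period_x
    mesh.positions[a] = new_a
    mesh.positions[b] = new_b
    mesh.invalidate()
    return event


def remodel_pass(
    mesh: TissueMesh,
    params: RemodelingParams,
    time: float,
    frame: APFrame,
    cooldown: dict[int, int] | None = None,
    now_step: int = 0,
    noise_offsets: np.ndarray | None = None,
    max_events: int = 50,
) -> list[IntercalationEvent]:
    """Remodel all current T1 candidates, shortest first.

    After each T1 the candidate set is recomputed (a reconnection changes
    neighbouring lengths).  Junctions touched by a T1 enter cooldown; the
    remodelled junction's tension-noise offset is reset to zero.
    """
    events: list[IntercalationEvent] = []
    for _ in range(max_events):
        candidates = find_t1_candidates(mesh, params, cooldown, now_step)
        done = False
        for j in candidates:
            touched = _incident_junctions(mesh, j)
            try:
                event = apply_t1(mesh, j, params, time, frame)
            except T1Skip:
                continue
            events.append(event)
            if noise_offsets is not None:
                noise_offsets[j] = 0.0
            if cooldown is not None:
                for t in touched:
                    cooldown[t] = now_step
            done = True
            break
        if not done:
            break
    return events


def _incident_junctions(mesh: TissueMesh, junction: int) -> list[int]:
    topo = mesh.topology()
    a, b = map(int, mesh.junctions[junction])
    out = set(topo["vertex_junctions"][a]) | set(topo["vertex_junctions"][b])
    return sorted(out)
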