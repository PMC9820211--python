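"""Scripted trajectories: exact, hand-authored particle itineraries.

A script is an ordered list of steps; each step holds a dwell time (ps) and
a mapping ``particle_id -> region name`` (any particle omitted from a step
sits in the intracellular reservoir). The builder emits a trajectory whose
frame-wise site assignment reproduces the script exactly, so occupancy
codes, permeation counts and mechanism labels on the result are known by
construction — the independent oracle for the analysis modules.

Region names are those of the :class:`~knockon.trajio.SiteMap`; particles
are placed at the centre of their region (stacked with small offsets when
several share a reservoir).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajio import SITE_ORDER, Particle, SiteMap, Trajectory

FILTER_REGION_NAMES = ("Scav", "S4", "S3", "S2", "S1", "S0")


class ScriptError(ValueError):
    pass


@dataclass
class ScriptStep:
    dwell_ps: float
    where: dict  # particle id -> region name


def build_scripted_trajectory(steps: list[ScriptStep], sitemap: SiteMap,
                              species: dict, dt_ps: float = 1.0,
                              ) -> Trajectory:
    """Realise a script as a trajectory sampled every ``dt_ps``.

    ``species`` maps each particle id to its species letter. Raises
    :class:`ScriptError` for an empty script, non-positive dwell, an unknown
    region, a particle teleporting across a site that stays occupied, or a
    single-file order violation inside the filter.
    """
    if not steps:
        raise ScriptError("empty script")
    names = sitemap.names
    order = {n: i for i, n in enumerate(names)}
    pids = sorted(species)
    prev = None
    for k, st in enumerate(steps):
        if st.dwell_ps <= 0:
            raise ScriptError(f"step {k}: dwell time must be > 0")
        for pid, region in st.where.items():
            if pid not in species:
                raise ScriptError(f"step {k}: unknown particle {pid!r}")
            if region not in order:
                raise ScriptError(f"step {k}: unknown region {region!r}")
        cur = {pid: st.where.get(pid, "intracellular") for pid in pids}
        if prev is not None:
            _check_moves(k, cur, prev, order)
        prev = cur

    # realise frames
    times, frames = [], []
    t = 0.0
    for st in steps:
        n = max(1, int(round(st.dwell_ps / dt_ps)))
        placed = _place(st, pids, sitemap)
        for _ in range(n):
            times.append(t)
            frames.append(placed)
            t += dt_ps
    coords = np.array(frames)  # (n_frames, n_pids)
    particles = [Particle(pid, species[pid], coords[:, j])
                 for j, pid in enumerate(pids)]
    return Trajectory(np.asarray(times), particles,
                      box_z=sitemap.intervals[-1][2]
                      - sitemap.intervals[0][1])


def _check_moves(k, cur, prev, order):
    movers = {p for p in cur if cur[p] != prev[p]}
    for p in movers:
        a, b = order[prev[p]], order[cur[p]]
        lo, hi = min(a, b), max(a, b)
        # a reservoir-to-reservoir jump is a recycling wrap, always legal
        if {prev[p], cur[p]} <= {"intracellular", "extracellular"}:
            continue
        for q in cur:
            if q == p or q in movers:
                continue
            oq = order[cur[q]]
            if lo < oq < hi and cur[q] in FILTER_REGION_NAMES:
                raise ScriptError(
                    f"step {k}: particle {p!r} teleports over occupied "
                    f"site {cur[q]!r}")
    # single-file order inside the filter must be preserved
    prev_in = sorted((order[prev[p]], p) for p in cur
                     if prev[p] in FILTER_REGION_NAMES)
    cur_in = sorted((order[cur[p]], p) for p in cur
                    if cur[p] in FILTER_REGION_NAMES)
    common = {p for _, p in prev_in} & {p for _, p in cur_in}
    seq_prev = [p for _, p in prev_in if p in common]
    seq_cur = [p for _, p in cur_in if p in common]
    if seq_prev != seq_cur:
        raise ScriptError(f"step {k}: single-file order violated in the "
                          "filter")


def _place(st: ScriptStep, pids, sitemap: SiteMap):
    count: dict = {}
    out = []
    for pid in pids:
        region = st.where.get(pid, "intracellular")
        c = sitemap.center(region)
        k = count.get(region, 0)
        count[region] = k + 1
        # stack multiple occupants of a reservoir; sites keep the first at
        # centre so the nearest-to-centre tie rule is deterministic
        out.append(c + 0.02 * k)
    return out


# --------------------------------------------------------------------------
# canonical knock-on event templates
# --------------------------------------------------------------------------

def soft_event_steps(ion_a="Ka", ion_b="Kb", water="Wa") -> list[ScriptStep]:
    """One outward permeation of ``ion_a`` that is water-mediated
    throughout: every multi-ion frame shows a W between the two ions
    (the 'K-W-K-W' conduction pattern)."""
    return [
        ScriptStep(2, {ion_a: "Scav"}),
        ScriptStep(2, {ion_a: "S4"}),
        ScriptStep(2, {ion_a: "S3", water: "S4"}),
        ScriptStep(2, {ion_a: "S2", water: "S3", ion_b: "Scav"}),
        ScriptStep(2, {ion_a: "S2", water: "S3", ion_b: "S4"}),
        ScriptStep(2, {ion_a: "S1", water: "S2", ion_b: "S3"}),
        ScriptStep(2, {ion_a: "S0", water: "S1", ion_b: "S2"}),
        ScriptStep(2, {ion_a: "extracellular", water: "S1", ion_b: "S2"}),
        ScriptStep(2, {water: "S0", ion_b: "S2"}),
        ScriptStep(2, {water: "extracellular", ion_b: "Scav"}),
        ScriptStep(2, {}),
    ]


def direct_event_steps(ion_a="Ka", ion_b="Kb") -> list[ScriptStep]:
    """One outward permeation of ``ion_a`` with direct ion-ion contact: the
    two ions occupy adjacent filter sites with no intervening water (the
    'K-K-K-K' conduction pattern)."""
    return [
        ScriptStep(2, {ion_a: "Scav"}),
        ScriptStep(2, {ion_a: "S4"}),
        ScriptStep(2, {ion_a: "S3", ion_b: "Scav"}),
        ScriptStep(2, {ion_a: "S2", ion_b: "S4"}),
        ScriptStep(2, {ion_a: "S1", ion_b: "S2"}),
        ScriptStep(2, {ion_a: "S0", ion_b: "S1"}),
        ScriptStep(2, {ion_a: "extracellular", ion_b: "S1"}),
        ScriptStep(2, {ion_b: "Scav"}),
        ScriptStep(2, {}),
    ]


def lone_event_steps(ion="Ka") -> list[ScriptStep]:
    """One outward permeation with the filter otherwise empty
    (unassignable mechanism)."""
    return [ScriptStep(2, {ion: s}) for s in
            ("Scav", "S4", "S3", "S2", "S1", "S0", "extracellular")] + \
        [ScriptStep(2, {})]


def knock_on_script(n_soft: int, n_direct: int, n_lone: int = 0
                    ) -> tuple[list[ScriptStep], dict]:
    """Concatenate event templates: ``n_soft`` water-mediated and
    ``n_direct`` direct outward events (plus optional lone transits),
    separated by empty-filter steps so event windows never overlap.

    Returns (steps, species map). The scripted mechanism bookkeeping is
    exact: the permeation detector must find ``n_soft + n_direct + n_lone``
    outward events with exactly those labels.
    """
    steps: list[ScriptStep] = [ScriptStep(2, {})]
    for _ in range(n_soft):
        steps += soft_event_steps()
    for _ in range(n_direct):
        steps += direct_event_steps()
    for _ in range(n_lone):
        steps += lone_event_steps()
    species = {"Ka": "K", "Kb": "K", "Wa": "W"}
    return steps, species
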