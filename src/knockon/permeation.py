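"""Permeation-event detection and ionic current.

An outward event: an ion enters the binding-site region from the
intracellular side and later crosses the extracellular boundary without
having re-crossed the intracellular boundary in between (two committor
planes, immune to rapid single-plane recrossing noise). Inward events are
the mirror image and are counted separately; the reported current is net
outward. Recycling jumps (extracellular reservoir -> intracellular
reservoir) pass through no site and therefore never create events.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import PA_PER_EVENT_PER_NS
from .trajio import ContractViolation, SiteMap, Trajectory


@dataclass
class PermeationEvent:
    ion_id: str
    t_entry_ps: float     # first binding-site entry of the transit
    t_exit_ps: float      # first frame beyond the far boundary
    direction: str        # "outward" | "inward"
    mechanism: str = "unassigned"

    def __post_init__(self):
        if self.direction == "outward" and self.t_exit_ps <= self.t_entry_ps:
            raise ContractViolation("outward event must exit after entry")


def detect_permeations(traj: Trajectory, sitemap: SiteMap
                       ) -> list[PermeationEvent]:
    """Complete ion transits through the site region; empty list if none."""
    events: list[PermeationEvent] = []
    n_regions = len(sitemap.names)
    first, last = 0, n_regions - 1  # intracellular, extracellular
    for p in traj.by_species("K"):
        reg = sitemap.region_indices(p.z)
        # run-length encode the region sequence
        change = np.flatnonzero(np.diff(reg)) + 1
        starts = np.concatenate(([0], change))
        vals = reg[starts]
        side = None          # which reservoir the ion last occupied
        t_entry = None
        for s, v in zip(starts, vals):
            t = traj.times[s]
            if v == first:
                side, t_entry = "bottom", None
            elif v == last:
                if side == "bottom" and t_entry is not None:
                    events.append(PermeationEvent(p.pid, t_entry, t,
                                                  "outward"))
                side, t_entry = "top", None
            else:
                if t_entry is None and side is not None:
                    t_entry = t
        # inward pass (mirror), kept separate to preserve entry times
        side, t_entry = None, None
        for s, v in zip(starts, vals):
            t = traj.times[s]
            if v == last:
                side, t_entry = "top", None
            elif v == first:
                if side == "top" and t_entry is not None:
                    events.append(PermeationEvent(p.pid, t_entry, t,
                                                  "inward"))
                side, t_entry = "bottom", None
            else:
                if t_entry is None and side is not None:
                    t_entry = t
    events.sort(key=lambda e: e.t_exit_ps)
    return events


def count_plane_crossings(traj: Trajectory, z_plane: float,
                          jump_tol_nm: float = 0.8) -> tuple[int, int]:
    """(up, down) crossings of a z plane by ions, ignoring recycling jumps
    (displacements larger than ``jump_tol_nm`` in one frame)."""
    up = down = 0
    for p in traj.by_species("K"):
        dz = np.diff(p.z)
        real = np.abs(dz) <= jump_tol_nm
        above = p.z >= z_plane
        crossed_up = (~above[:-1]) & above[1:] & real
        crossed_dn = above[:-1] & (~above[1:]) & real
        up += int(crossed_up.sum())
        down += int(crossed_dn.sum())
    return up, down


@dataclass
class CurrentResult:
    n_outward: int
    n_inward: int
    duration_ns: float        # analysed (post-discard) span
    flux_per_ns: float        # net outward events per ns
    current_pa: float         # I = N_net * e / T
    window_ns: float = 0.0
    window_times_ns: np.ndarray | None = None
    window_flux: np.ndarray | None = None

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# n_outward\tn_inward\tduration_ns\tflux_per_ns\t"
                     "current_pA\n")
            fh.write(f"{self.n_outward}\t{self.n_inward}\t"
                     f"{self.duration_ns:.6f}\t{self.flux_per_ns:.6f}\t"
                     f"{self.current_pa:.6f}\n")


def compute_current(events: list[PermeationEvent], traj: Trajectory,
                    discard_time_ns: float = 0.0,
                    window_ns: float = 0.0) -> CurrentResult:
    """Net outward current over the post-discard span, in pA.

    Events whose exit precedes the discard time are excluded; the windowed
    flux series supports cumulative-flux plots.
    """
    t0_ns = traj.times[0] / 1e3
    t_end_ns = traj.times[-1] / 1e3
    analysed = t_end_ns - t0_ns - discard_time_ns
    if analysed <= 0:
        raise ContractViolation("discard time leaves zero analysed duration")
    cut_ps = (t0_ns + discard_time_ns) * 1e3
    kept = [e for e in events if e.t_exit_ps >= cut_ps]
    n_out = sum(1 for e in kept if e.direction == "outward")
    n_in = sum(1 for e in kept if e.direction == "inward")
    net = n_out - n_in
    flux = net / analysed
    res = CurrentResult(n_out, n_in, analysed, flux,
                        flux * PA_PER_EVENT_PER_NS, window_ns)
    if window_ns > 0:
        edges = np.arange(cut_ps / 1e3, t_end_ns + window_ns, window_ns)
        exits = np.array([e.t_exit_ps / 1e3 for e in kept
                          if e.direction == "outward"])
        counts, _ = np.histogram(exits, bins=edges)
        res.window_times_ns = 0.5 * (edges[:-1] + edges[1:])
        res.window_flux = counts / window_ns
    return res


def current_ratio(a: CurrentResult, b: CurrentResult) -> float:
    """a / b current fold change (the with-field vs without-field figure)."""
    if b.current_pa == 0:
        raise ZeroDivisionError("reference current is zero")
    return a.current_pa / b.current_pa
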