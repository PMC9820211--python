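"""Pore-radius profiling from symmetric carbonyl-oxygen pairs.

The pore radius at a residue ring is r = l/2 - r_o, with l the cross-pore
distance between the carbonyl oxygen and its symmetry mate and r_o the
oxygen van der Waals radius (default 1.52 A, configurable). The residue's
"vibration amplitude" is the post-discard standard deviation of l.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trajio import ContractViolation, Trajectory

log = logging.getLogger(__name__)

OXYGEN_RADIUS_A = 1.52


def pair_distance(a, b) -> float:
    """Euclidean distance between two 3-D coordinates (same units in/out)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != (3,) or b.shape != (3,):
        raise ContractViolation("pair_distance needs two 3-D coordinates")
    return float(np.linalg.norm(a - b))


def pore_radius(l_a: float, r_o: float = OXYGEN_RADIUS_A) -> float:
    """r = l/2 - r_o (Angstrom). Negative values are flagged, not errors."""
    if l_a < 0 or r_o < 0:
        raise ContractViolation("l and r_o must be >= 0")
    r = l_a / 2.0 - r_o
    if r < 0:
        log.warning("pore_radius: overlapping atoms (l=%.3f A < 2 r_o)", l_a)
    return r


@dataclass
class PorePairSeries:
    label: str
    times_ns: np.ndarray
    l_a: np.ndarray             # cross-pore O-O distance, Angstrom
    r_a: np.ndarray             # derived radius
    r_o: float
    mean_l_a: float             # post-discard
    amplitude_a: float          # post-discard std of l
    overlap_flag: bool
    n_replicates: int = 1

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# residue={self.label} r_o_A={self.r_o} "
                     f"mean_l_A={self.mean_l_a:.4f} "
                     f"amplitude_A={self.amplitude_a:.4f}\n")
            fh.write("# t_ns\tl_A\tr_A\n")
            for t, l, r in zip(self.times_ns, self.l_a, self.r_a):
                fh.write(f"{t:.6f}\t{l:.4f}\t{r:.4f}\n")


def _pair_l(traj: Trajectory, pid_a: str, pid_b: str) -> np.ndarray:
    pa, pb = traj.particle(pid_a), traj.particle(pid_b)
    for p in (pa, pb):
        if p.x is None or p.y is None:
            raise ContractViolation(
                f"particle {p.pid!r}: 3-D coordinates required")
    d = np.sqrt((pa.x - pb.x) ** 2 + (pa.y - pb.y) ** 2
                + (pa.z - pb.z) ** 2)
    return d * 10.0  # nm -> Angstrom


def radius_series(trajs, pairs: dict, r_o: float = OXYGEN_RADIUS_A,
                  smoothing_window: int = 0,
                  discard_time_ns: float = 0.0) -> dict:
    """Per-residue pore-radius series, averaged across replicates.

    ``trajs`` is one trajectory or a list of replicate trajectories (equal
    length and sampling); ``pairs`` maps a residue label to a 2-tuple of
    particle ids (one symmetric pair) or a 4-tuple (two diagonal pairs,
    averaged). Returns label -> :class:`PorePairSeries`.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not trajs:
        raise ContractViolation("no trajectories given")
    n = trajs[0].n_frames
    for t in trajs[1:]:
        if t.n_frames != n:
            raise ContractViolation("replicates must have equal length")
    out = {}
    times_ns = trajs[0].times / 1e3
    for label, ids in pairs.items():
        reps = []
        for traj in trajs:
            if len(ids) == 2:
                l = _pair_l(traj, ids[0], ids[1])
            elif len(ids) == 4:
                l = 0.5 * (_pair_l(traj, ids[0], ids[2])
                           + _pair_l(traj, ids[1], ids[3]))
            else:
                raise ContractViolation(
                    f"residue {label}: need 2 or 4 particle ids")
            reps.append(l)
        l_mean = np.mean(reps, axis=0)
        if smoothing_window > 1:
            kernel = np.ones(smoothing_window) / smoothing_window
            l_mean = np.convolve(l_mean, kernel, mode="same")
        keep = times_ns >= times_ns[0] + discard_time_ns
        post = l_mean[keep]
        r = np.array([l / 2.0 - r_o for l in l_mean])
        out[label] = PorePairSeries(
            label, times_ns, l_mean, r, r_o,
            mean_l_a=float(post.mean()),
            amplitude_a=float(post.std(ddof=0)),
            overlap_flag=bool(np.any(r < 0)),
            n_replicates=len(trajs))
        if out[label].overlap_flag:
            log.warning("residue %s: negative pore radius in series "
                        "(overlapping atoms)", label)
    return out
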