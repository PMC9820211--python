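"""Selectivity-filter occupancy states and their census.

Each frame is condensed to a 4-character code over {K, W, 0} describing the
contents of S1..S4 (leftmost character = S1, the extracellular end of the
filter): K if a potassium ion sits in the site's z interval, else W if a
water does, else 0 for a vacancy. 'KKKW' and 'K0KK' are the canonical
high-population codes of direct knock-on conduction.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .trajio import ContractViolation, FILTER_SITES, SiteMap, Trajectory

log = logging.getLogger(__name__)

# the six direct-contact codes tracked by default, plus everything else
DEFAULT_TRACKED = ("KKKW", "K0KK", "KK0K", "0KKK", "KKK0", "KKKK")


@dataclass
class OccupancyState:
    code: str
    frame: int
    time_ps: float

    def __post_init__(self):
        if len(self.code) != 4 or any(c not in "KW0" for c in self.code):
            raise ContractViolation(f"bad occupancy code {self.code!r}")


class StateSeries:
    """Sequence of per-frame occupancy states (vectorised storage)."""

    def __init__(self, times_ps: np.ndarray, codes: np.ndarray):
        self.times_ps = np.asarray(times_ps, dtype=float)
        self.codes = np.asarray(codes)
        if self.times_ps.shape != self.codes.shape:
            raise ContractViolation("times/codes length mismatch")

    def __len__(self):
        return self.codes.size

    def __getitem__(self, i):
        if isinstance(i, slice):
            return StateSeries(self.times_ps[i], self.codes[i])
        return OccupancyState(str(self.codes[i]), int(i),
                              float(self.times_ps[i]))

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def window(self, t_lo_ps: float, t_hi_ps: float) -> "StateSeries":
        m = (self.times_ps >= t_lo_ps) & (self.times_ps <= t_hi_ps)
        return StateSeries(self.times_ps[m], self.codes[m])

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# t_fs\tcode\n")
            for t, c in zip(self.times_ps, self.codes):
                fh.write(f"{t * 1e3:.3f}\t{c}\n")


def assign_sites(traj: Trajectory, sitemap: SiteMap) -> StateSeries:
    """Per-frame S1..S4 occupancy codes.

    An ion in the interval beats a water (the ion is the species the site
    coordinates); two same-species particles in one interval are resolved
    nearest-to-centre, with a logged warning.
    """
    for s in FILTER_SITES:
        if s not in sitemap.names:
            raise ContractViolation(f"site map lacks {s}")
    n = traj.n_frames
    chars = np.full((4, n), "0", dtype="<U1")
    n_ties = 0
    for col, site in enumerate(FILTER_SITES):  # S1 first
        lo, hi = sitemap.interval(site)
        centre = 0.5 * (lo + hi)
        best_d = {"K": np.full(n, np.inf), "W": np.full(n, np.inf)}
        count = {"K": np.zeros(n, dtype=int), "W": np.zeros(n, dtype=int)}
        for p in traj.particles:
            if p.species not in ("K", "W"):
                continue
            inside = (p.z >= lo) & (p.z < hi)
            d = np.abs(p.z - centre)
            sel = inside & (d < best_d[p.species])
            best_d[p.species][sel] = d[sel]
            count[p.species] += inside
        occupied_k = count["K"] > 0
        occupied_w = count["W"] > 0
        chars[col][occupied_w] = "W"
        chars[col][occupied_k] = "K"
        n_ties += int(np.sum(count["K"] > 1) + np.sum(count["W"] > 1))
    if n_ties:
        log.warning("assign_sites: %d frame-site slots had multiple "
                    "same-species occupants; nearest-to-centre kept", n_ties)
    codes = np.array(["".join(chars[:, i]) for i in range(n)])
    return StateSeries(traj.times.copy(), codes)


@dataclass
class StateCensus:
    fractions: dict          # code (or "Others") -> fraction of frames
    counts: dict
    total_frames: int
    tracked: tuple = field(default_factory=tuple)

    def __post_init__(self):
        s = sum(self.fractions.values())
        if self.total_frames and abs(s - 1.0) > 1e-12:
            raise ContractViolation("census fractions must sum to 1")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# code\tframes\tfraction\n")
            for code, frac in self.fractions.items():
                fh.write(f"{code}\t{self.counts[code]}\t{frac:.6f}\n")


def census(states: StateSeries, tracked=DEFAULT_TRACKED,
           discard_time_ns: float = 0.0) -> StateCensus:
    """Frame-weighted census of occupancy codes after the discard time;
    codes outside ``tracked`` pool into "Others"."""
    if len(states) == 0:
        raise ContractViolation("empty state sequence")
    use = states.window(discard_time_ns * 1e3, np.inf)
    if len(use) == 0:
        raise ContractViolation("no frames after discard_time")
    raw = Counter(use.codes.tolist())
    counts = {c: raw.get(c, 0) for c in tracked}
    counts["Others"] = sum(v for c, v in raw.items() if c not in tracked)
    total = len(use)
    fractions = {c: v / total for c, v in counts.items()}
    return StateCensus(fractions, counts, total, tuple(tracked))
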