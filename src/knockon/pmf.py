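"""Potential of mean force along the pore axis by Boltzmann inversion.

W(z) = -kT ln(rho(z)/rho_max) from the equilibrium density of a species'
z samples; the global minimum is referenced to zero. For driven
(field/voltage) trajectories the same inversion yields a *quasi*-PMF; the
profile records which it is in ``equilibrium``. Empty bins are flagged
(NaN + mask), never silently interpolated.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajio import ContractViolation, SiteMap, Trajectory


@dataclass
class PMFProfile:
    z_centers: np.ndarray   # nm
    w_kt: np.ndarray        # NaN on empty bins
    counts: np.ndarray
    bin_width: float
    temperature: float
    equilibrium: bool = True

    @property
    def valid(self) -> np.ndarray:
        return self.counts > 0

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# z_nm\tW_kT\tn_samples\n")
            for z, w, n in zip(self.z_centers, self.w_kt, self.counts):
                wtxt = f"{w:.6f}" if np.isfinite(w) else "nan"
                fh.write(f"{z:.4f}\t{wtxt}\t{int(n)}\n")


def compute_pmf(traj: Trajectory, species: str = "K",
                z_range: tuple[float, float] | None = None,
                bin_width: float = 0.02,
                discard_time_ns: float = 0.0) -> PMFProfile:
    """Boltzmann-inverted free-energy profile of one species' z density."""
    parts = traj.by_species(species)
    if not parts:
        raise ContractViolation(f"no particles of species {species!r}")
    keep = traj.times >= traj.times[0] + discard_time_ns * 1e3
    samples = np.concatenate([p.z[keep] for p in parts])
    if z_range is None:
        z_range = (samples.min(), samples.max())
    lo, hi = z_range
    if hi <= lo:
        raise ContractViolation("empty z range")
    samples = samples[(samples >= lo) & (samples < hi)]
    if samples.size == 0:
        raise ContractViolation("no samples in range after discard")
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    counts, edges = np.histogram(samples, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore"):
        w = -np.log(counts / counts.max())
    w[counts == 0] = np.nan
    meta = traj.metadata
    equilibrium = (meta.get("field_e0_V_nm", 0.0) == 0.0
                   and meta.get("membrane_voltage_mV", 0.0) == 0.0)
    return PMFProfile(centers, w, counts, (hi - lo) / n_bins,
                      meta.get("temperature_K", 300.0), equilibrium)


@dataclass
class TransitionBarrier:
    donor: str
    acceptor: str
    barrier_kt: float     # saddle max minus donor minimum
    z_donor_min: float
    z_saddle: float


def site_barriers(profile: PMFProfile, sitemap: SiteMap,
                  sites: tuple = ("Scav", "S4", "S3", "S2", "S1", "S0")
                  ) -> list[TransitionBarrier]:
    """Outward barrier for each adjacent site pair present in the profile.

    The donor minimum is the lowest sampled bin inside the donor site's
    interval; the barrier is the highest sampled bin between the two
    minima.
    """
    present = [s for s in sites if s in sitemap.names]
    minima = {}
    for s in present:
        lo, hi = sitemap.interval(s)
        m = (profile.z_centers >= lo) & (profile.z_centers < hi)
        if not np.any(m & profile.valid):
            raise ContractViolation(f"site {s}: all bins empty")
        w = np.where(profile.valid, profile.w_kt, np.inf)[m]
        i_local = int(np.argmin(w))
        idx = np.flatnonzero(m)[i_local]
        minima[s] = idx
    out = []
    for donor, acceptor in zip(present[:-1], present[1:]):
        i, j = minima[donor], minima[acceptor]
        lo, hi = min(i, j), max(i, j)
        seg = np.where(profile.valid, profile.w_kt, -np.inf)[lo:hi + 1]
        k = int(np.argmax(seg)) + lo
        out.append(TransitionBarrier(
            donor, acceptor,
            float(profile.w_kt[k] - profile.w_kt[i]),
            float(profile.z_centers[i]), float(profile.z_centers[k])))
    return out


def write_barriers(barriers: list[TransitionBarrier], path) -> None:
    with open(path, "w") as fh:
        fh.write("# donor\tacceptor\tbarrier_kT\tz_donor_nm\tz_saddle_nm\n")
        for b in barriers:
            fh.write(f"{b.donor}\t{b.acceptor}\t{b.barrier_kt:.4f}\t"
                     f"{b.z_donor_min:.4f}\t{b.z_saddle:.4f}\n")
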