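"""Multi-well free-energy landscape along the pore axis.

The selectivity-filter binding landscape is represented by alternating
well / saddle nodes joined by a monotone piecewise-cubic (PCHIP)
interpolant, so the stated well depths and barrier heights are *exact*
extrema of the curve. Energies are in units of k_B * 300 K; the potential
is zero in the reservoirs outside ``[pore_lo, pore_hi]`` and continuous
everywhere.

Barrier convention: wells sit at ``-depths[i]`` below the reservoir level
(zero) and ``barriers[i]`` is the *absolute* height of the saddle between
wells i and i+1 on the same scale, so the climb out of well i is
``depths[i] + barriers[i]``. A ``well_halfwidth`` turns each saddle into a
flat-topped plateau spanning from ``center_i + halfwidth`` to
``center_{i+1} - halfwidth``: broad saddles and narrow wells keep transit
times barrier-dominated (the clean Kramers regime the rate oracles assume).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from .trajio import ContractViolation, SiteMap


@dataclass
class LandscapePotential:
    well_centers: np.ndarray      # nm, strictly increasing
    well_depths: np.ndarray       # kT, > 0 (well minimum at -depth)
    barriers: np.ndarray          # kT, absolute saddle height, len n - 1
    pore_lo: float
    pore_hi: float
    well_halfwidth: float | None = None  # nm; plateau saddles if set
    kappa: float = 0.0            # kT lowered from the S1 saddle per unit
                                  # normalized oscillator energy
    s1_transition: int | None = None  # index into barriers (S2 -> S1 saddle)
    well_names: tuple = ()

    def __post_init__(self):
        self.well_centers = np.asarray(self.well_centers, dtype=float)
        self.well_depths = np.asarray(self.well_depths, dtype=float)
        self.barriers = np.asarray(self.barriers, dtype=float)
        n = self.well_centers.size
        if self.well_depths.size != n or self.barriers.size != n - 1:
            raise ContractViolation(
                "need one depth per well and one barrier per adjacent pair")
        if np.any(np.diff(self.well_centers) <= 0):
            raise ContractViolation("well centers must be strictly "
                                    "increasing")
        if self.well_centers[0] <= self.pore_lo or \
                self.well_centers[-1] >= self.pore_hi:
            raise ContractViolation("well centers must lie inside the pore")
        if np.any(self.well_depths <= 0):
            raise ContractViolation("well depths must be positive")
        if self.kappa < 0:
            raise ContractViolation("kappa must be >= 0")
        # every saddle must sit above both neighbouring minima
        if np.any(self.barriers <= -self.well_depths[:-1]) or \
                np.any(self.barriers <= -self.well_depths[1:]):
            raise ContractViolation(
                "each barrier must rise above both adjacent well minima")
        if self.well_halfwidth is not None:
            gaps = np.diff(self.well_centers)
            if self.well_halfwidth <= 0 or \
                    np.any(2 * self.well_halfwidth >= gaps):
                raise ContractViolation(
                    "well_halfwidth must be positive and smaller than half "
                    "the well spacing")
        self._build()

    def _build(self):
        zs = [self.pore_lo]
        vs = [0.0]
        hw = self.well_halfwidth
        for i, (c, d) in enumerate(zip(self.well_centers, self.well_depths)):
            zs.append(c)
            vs.append(-d)
            if i < self.barriers.size:
                b = self.barriers[i]
                if hw is None:
                    zs.append(0.5 * (c + self.well_centers[i + 1]))
                    vs.append(b)
                else:
                    zs.extend([c + hw, self.well_centers[i + 1] - hw])
                    vs.extend([b, b])
        zs.append(self.pore_hi)
        vs.append(0.0)
        self._nodes_z = np.asarray(zs)
        self._nodes_v = np.asarray(vs)
        self._pchip = PchipInterpolator(self._nodes_z, self._nodes_v)
        self._dpchip = self._pchip.derivative()

    def potential(self, z) -> np.ndarray:
        """V(z) in kT; zero outside the pore region."""
        z = np.asarray(z, dtype=float)
        v = np.where((z >= self.pore_lo) & (z <= self.pore_hi),
                     self._pchip(np.clip(z, self.pore_lo, self.pore_hi)),
                     0.0)
        return v if v.ndim else float(v)

    def gradient(self, z) -> np.ndarray:
        """dV/dz in kT/nm; zero outside the pore region."""
        z = np.asarray(z, dtype=float)
        g = np.where((z >= self.pore_lo) & (z <= self.pore_hi),
                     self._dpchip(np.clip(z, self.pore_lo, self.pore_hi)),
                     0.0)
        return g if g.ndim else float(g)

    @property
    def saddle_values(self) -> np.ndarray:
        """Absolute potential at each inter-well saddle (kT)."""
        return self.barriers.copy()

    @property
    def climbs(self) -> np.ndarray:
        """Outward activation energy per transition (donor well to saddle)."""
        return self.well_depths[:-1] + self.barriers

    def with_barrier_shift(self, delta: float) -> "LandscapePotential":
        """Uniformly shift every inter-site saddle by +delta kT
        (wells unchanged)."""
        return replace(self, barriers=self.barriers + delta)


def modulated_barrier(landscape: LandscapePotential,
                      osc_energy: float) -> LandscapePotential:
    """Lower the S1 saddle by kappa * osc_energy kT; other barriers and all
    wells are untouched.

    ``osc_energy`` is the carbonyl oscillator's (normalized) steady-state
    energy; the coupling encodes resonance-stabilised conduction: a strongly
    excited carbonyl band leaves the filter more ordered and the S1 exit
    barrier lower.
    """
    if landscape.kappa == 0.0 or osc_energy == 0.0:
        return landscape
    if landscape.s1_transition is None:
        raise ContractViolation("landscape has no designated S1 transition")
    i = landscape.s1_transition
    new = landscape.barriers.copy()
    new[i] -= landscape.kappa * float(osc_energy)
    if new[i] <= max(-landscape.well_depths[i],
                     -landscape.well_depths[i + 1]):
        raise ContractViolation(
            "modulation would flatten or invert the S1 barrier")
    return replace(landscape, barriers=new)


def default_landscape(sitemap: SiteMap, depth: float = 1.2,
                      barrier: float = 3.0, kappa: float = 0.0,
                      halfwidth: float | None = 0.04,
                      wells: tuple = ("Scav", "S4", "S3", "S2", "S1"),
                      s1_pair: tuple = ("S2", "S1")) -> LandscapePotential:
    """Landscape with one well per named site and uniform depths/barriers.

    The default five narrow wells (Scav..S1) between broad 3 kT saddle
    plateaus, with a flat shoulder through S0, give a single-file
    conduction pathway whose rates are barrier-controlled; the exit saddle
    is the S2->S1 barrier.
    """
    centers = np.array([sitemap.center(s) for s in wells])
    depths = np.full(len(wells), float(depth))
    bars = np.full(len(wells) - 1, float(barrier))
    s1_idx = wells.index(s1_pair[1]) - 1
    return LandscapePotential(
        centers, depths, bars, pore_lo=sitemap.pore_lo,
        pore_hi=sitemap.pore_hi, well_halfwidth=halfwidth, kappa=kappa,
        s1_transition=s1_idx, well_names=tuple(wells))
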