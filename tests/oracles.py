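"""Independent numerical oracles for the channel simulator.

These deliberately avoid the package's dynamics code paths: they integrate
closed-form 1-D diffusion formulas (mean first-passage time, Boltzmann
weights) on a dense grid from the landscape's potential curve alone.
"""
import numpy as np
from scipy.integrate import cumulative_trapezoid

import knockon.constants as C


def effective_potential(landscape, z, tilt_mv=0.0):
    """Landscape plus linear membrane-voltage tilt across the pore (kT)."""
    frac = np.clip((z - landscape.pore_lo)
                   / (landscape.pore_hi - landscape.pore_lo), 0.0, 1.0)
    return landscape.potential(z) - C.voltage_mv_to_kt(tilt_mv) * frac


def cycle_time_ps(landscape, sitemap, tilt_mv=0.0, friction=5.0,
                  mass_amu=39.0983, n_grid=12000):
    """Mean first-passage time of one conduction cycle: reflecting bottom
    boundary, start at the re-injection point (middle of the intracellular
    reservoir), absorb at the top of the extracellular reservoir."""
    z_lo = sitemap.intervals[0][1]
    z_hi = sitemap.intervals[-1][2]
    zg = np.linspace(z_lo, z_hi, n_grid)
    v = effective_potential(landscape, zg, tilt_mv)
    d = C.diffusion_nm2_ps(mass_amu, friction)
    inner = cumulative_trapezoid(np.exp(-v), zg, initial=0.0)
    i0 = np.searchsorted(zg, 0.5 * (z_lo + landscape.pore_lo))
    return float(np.trapezoid((np.exp(v) * inner)[i0:], zg[i0:]) / d)


def mfpt_current_ratio(land_a, land_b, sitemap, tilt_mv=0.0):
    """Predicted current ratio I_b / I_a = T_a / T_b."""
    return cycle_time_ps(land_a, sitemap, tilt_mv) \
        / cycle_time_ps(land_b, sitemap, tilt_mv)


def boltzmann_site_weights(landscape, sitemap, sites, n_grid=20000):
    """Equilibrium occupancy probability per named region for one particle
    confined between the two reflecting reservoir walls."""
    z_lo = sitemap.intervals[0][1]
    z_hi = sitemap.intervals[-1][2]
    zg = np.linspace(z_lo, z_hi, n_grid)
    w = np.exp(-landscape.potential(zg))
    total = np.trapezoid(w, zg)
    out = {}
    for s in sites:
        lo, hi = sitemap.interval(s)
        m = (zg >= lo) & (zg < hi)
        out[s] = float(np.trapezoid(w[m], zg[m]) / total)
    return out
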