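"""Reduced-scale overdamped Langevin simulator of single-file channel
permeation.

Ions (K+) and waters move on the pore axis z in a multi-well binding
landscape. Forces on each particle:

* landscape gradient (waters see the landscape scaled down — they bind,
  but more weakly than the dehydrated ion);
* a constant membrane-voltage tilt across the pore (ions only);
* the applied oscillating field E0 cos(2*pi*f t + phi) (ions only),
  entered as its exact per-step time integral so the ~19 fs period does not
  alias against the 10 fs particle step;
* screened Coulomb repulsion between ion pairs (the direct knock-on drive);
* a soft-core exclusion between all particle pairs, plus an order
  constraint that forbids passing inside the selectivity filter
  (single-file conduction).

Thermal noise satisfies fluctuation-dissipation at the configured
temperature: D_i = k_B T/(m_i gamma). The bottom boundary reflects; the top
boundary either recycles an exiting particle into the intracellular
reservoir (the double-membrane periodic setup, default) or reflects
(equilibrium analyses, where recycling would break detailed balance).

Landscape/tilt energies are in units of k_B * 300 K, so the T -> 0 limit
keeps a finite drift while the noise amplitude vanishes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .constants import (C_LIGHT, COULOMB_KT_NM, E_CHARGE, KT_REF_J,
                        SPECIES_CHARGE_E, SPECIES_MASS_AMU, T_REF,
                        diffusion_nm2_ps, voltage_mv_to_kt)
from .landscape import LandscapePotential
from .oscillator import CarbonylOscillator, drive_oscillator
from .spectra import DipoleTrace
from .trajio import (ContractViolation, FieldSpec, Particle, RunConfig,
                     Trajectory)

log = logging.getLogger(__name__)

_GRID_N = 4096
_CORE_NM = 0.28        # soft-core exclusion diameter
_KEX = 400.0           # kT/nm^2 exclusion spring
_SOFT2 = 0.01          # nm^2 Coulomb softening; recycled particles re-enter
                       # at the middle of the intracellular reservoir
_FCAP = 400.0          # kT/nm cap on any pairwise force (regularisation)


@dataclass
class SimResult:
    trajectory: Trajectory
    dipole_trace: DipoleTrace | None
    field: FieldSpec
    seed: int
    n_recycled: int
    config: RunConfig
    landscape: LandscapePotential


class StepInstability(RuntimeError):
    pass


@njit(cache=True)
def _kernel(z, charge, vscale, drift_c, diff_c, n_steps, dt,
            grid_lo, grid_dz, grad,          # dense dV/dz table (kT/nm)
            tilt_f, pore_lo, pore_hi,
            famp, omega, phi,
            cpref, lam, core, kex,
            sf_lo, sf_hi,
            z_lo, z_hi, z_rein, recycle,
            stride, seed, out, max_step):
    np.random.seed(seed)
    n_p = z.size
    forces = np.zeros(n_p)
    out[0, :] = z
    n_rec = 0
    for step in range(n_steps):
        t = step * dt
        # per-step average of the oscillating field (exact integral)
        if omega > 0.0:
            favg = famp * (np.sin(omega * (t + dt) + phi)
                           - np.sin(omega * t + phi)) / (omega * dt)
        else:
            favg = famp * np.cos(phi)
        for i in range(n_p):
            zi = z[i]
            f = 0.0
            if pore_lo <= zi <= pore_hi:
                k = int((zi - grid_lo) / grid_dz)
                if k < 0:
                    k = 0
                if k >= grad.size - 1:
                    k = grad.size - 2
                frac = (zi - (grid_lo + k * grid_dz)) / grid_dz
                dv = grad[k] * (1.0 - frac) + grad[k + 1] * frac
                f -= vscale[i] * dv
                f += charge[i] * tilt_f
            f += charge[i] * favg
            forces[i] = f
        for i in range(n_p):
            for j in range(i + 1, n_p):
                dz = z[i] - z[j]
                r = np.sqrt(dz * dz + _SOFT2)
                fij = 0.0
                qq = charge[i] * charge[j]
                if qq != 0.0:
                    fij += cpref * qq * np.exp(-r / lam) \
                        * (1.0 / r + 1.0 / lam) / r
                if r < core:
                    fij += kex * (core - r)
                if fij > _FCAP:  # regularise unphysical close contacts
                    fij = _FCAP
                if fij != 0.0:
                    d = fij * dz / r
                    forces[i] += d
                    forces[j] -= d
        bad = -1
        for i in range(n_p):
            move = drift_c[i] * forces[i] * dt \
                + diff_c[i] * np.random.normal()
            if np.abs(move) > max_step:
                bad = step
            zn = z[i] + move
            if zn < z_lo:
                zn = 2.0 * z_lo - zn
            if zn > z_hi:
                if recycle:
                    zn = z_rein
                    n_rec += 1
                else:
                    zn = 2.0 * z_hi - zn
            # single-file order inside the filter: no passing
            for j in range(n_p):
                if j == i:
                    continue
                if sf_lo <= z[j] <= sf_hi and sf_lo <= zn <= sf_hi:
                    if (z[i] - z[j]) * (zn - z[j]) < 0.0:
                        zn = z[j] + (0.02 if z[i] > z[j] else -0.02)
            z[i] = zn
        if bad >= 0:
            return bad, n_rec
        if (step + 1) % stride == 0:
            out[(step + 1) // stride, :] = z
    return -1, n_rec


def _initial_positions(landscape: LandscapePotential, n_ions: int,
                       n_waters: int, z_lo: float) -> tuple[np.ndarray, list]:
    """Deterministic start: alternate ions/waters over the deepest wells
    from the bottom up; overflow queues in the intracellular reservoir."""
    roster = []
    for k in range(max(n_ions, n_waters)):
        if k < n_ions:
            roster.append(("K", f"K{k + 1}"))
        if k < n_waters:
            roster.append(("W", f"W{k + 1}"))
    centers = list(landscape.well_centers)
    pos, tagged = [], []
    for idx, (sp, pid) in enumerate(roster):
        if idx < len(centers):
            pos.append(centers[len(centers) - 1 - idx])  # fill from the top
        else:
            pos.append(z_lo + 0.05 * (idx - len(centers) + 1))
        tagged.append((sp, pid))
    return np.asarray(pos, dtype=float), tagged


def simulate(config: RunConfig, landscape: LandscapePotential,
             n_ions: int = 1, n_waters: int = 0, *,
             oscillator: CarbonylOscillator | None = None,
             dipole_ps: float = 50.0,
             oxygen_pair: dict | None = None) -> SimResult:
    """Run the Langevin channel simulator.

    Same config + seed gives bit-identical output. ``oscillator`` attaches
    a dipole trace (the carbonyl mode driven by ``config.field`` for
    ``dipole_ps`` picoseconds at 0.5 fs). ``oxygen_pair`` (keys ``l0_A``,
    ``amp_A``, optional ``tau_ps``) attaches a symmetric S1 carbonyl-oxygen
    pair whose cross-pore distance breathes as an Ornstein-Uhlenbeck
    process of the given stationary amplitude, for the geometry module.
    """
    if n_ions < 0 or n_waters < 0:
        raise ContractViolation("particle counts must be >= 0")
    if n_ions + n_waters == 0:
        raise ContractViolation("need at least one particle")
    sm = config.sitemap
    z_lo = sm.intervals[0][1]
    z_hi = sm.intervals[-1][2]
    pore_lo, pore_hi = landscape.pore_lo, landscape.pore_hi
    sf_lo, _ = sm.interval("Scav")
    _, sf_hi = sm.interval("S0")

    z0, tagged = _initial_positions(landscape, n_ions, n_waters, z_lo)
    species = [sp for sp, _ in tagged]
    pids = [pid for _, pid in tagged]
    charge = np.array([SPECIES_CHARGE_E[s] for s in species])
    vscale = np.array([1.0 if s == "K" else config.water_depth_scale
                       for s in species])
    mass = np.array([SPECIES_MASS_AMU[s] for s in species])
    drift_c = np.array([diffusion_nm2_ps(m, config.friction, T_REF)
                        for m in mass])              # mobility * kT_ref
    diff = np.array([diffusion_nm2_ps(m, config.friction,
                                      config.temperature) for m in mass])
    dt = config.dt_ps
    diff_c = np.sqrt(2.0 * diff * dt)

    zg = np.linspace(pore_lo, pore_hi, _GRID_N)
    grad = np.asarray(landscape.gradient(zg), dtype=float)
    # outward-positive tilt force for positive membrane voltage, kT/nm per e
    tilt_f = voltage_mv_to_kt(config.membrane_voltage_mv) / (pore_hi - pore_lo)
    # field force amplitude per unit charge: e * E0 in kT_ref/nm
    famp = config.field.e0 * E_CHARGE / KT_REF_J

    max_step = 0.5 * float(np.min(np.diff(
        [lo for _, lo, _ in sm.intervals] + [z_hi])))

    n_frames = config.n_steps // config.sample_stride + 1
    out = np.empty((n_frames, z0.size))
    z = z0.copy()
    bad, n_rec = _kernel(
        z, charge, vscale, drift_c, diff_c, config.n_steps, dt,
        pore_lo, (pore_hi - pore_lo) / (_GRID_N - 1), grad,
        tilt_f, pore_lo, pore_hi,
        famp, config.field.omega_per_ps, config.field.phi,
        COULOMB_KT_NM / config.eps_r, config.lambda_debye_nm,
        _CORE_NM, _KEX, sf_lo, sf_hi,
        z_lo, z_hi, 0.5 * (z_lo + pore_lo),
        config.boundary == "recycle",
        config.sample_stride, int(config.seed) & 0x7FFFFFFF, out, max_step)
    if bad >= 0:
        raise StepInstability(
            f"|dz| exceeded half the smallest site width at step {bad}; "
            "reduce dt_fs")

    times = np.arange(n_frames) * dt * config.sample_stride
    particles = [Particle(pid, sp, out[:, i].copy())
                 for i, (sp, pid) in enumerate(zip(species, pids))]

    rng = np.random.default_rng((int(config.seed) * 7919 + 17) & 0x7FFFFFFF)
    if oxygen_pair is not None:
        particles += _oxygen_pair_particles(times, sm, rng, **oxygen_pair)

    dip = None
    if oscillator is not None:
        n_osc = int(dipole_ps / 0.5e-3)
        dip = drive_oscillator(oscillator, config.field, dt_fs=0.5,
                               n_steps=n_osc)

    meta = {"temperature_K": config.temperature,
            "field_e0_V_nm": config.field.e0,
            "field_f_THz": config.field.f_thz,
            "field_phi_rad": config.field.phi,
            "membrane_voltage_mV": config.membrane_voltage_mv,
            "charge_imbalance_dq_e": config.charge_imbalance_dq,
            "seed": int(config.seed), "boundary": config.boundary}
    traj = Trajectory(times, particles, box_z=z_hi - z_lo, metadata=meta)
    log.info("simulate: %d steps, %d particles, %d recycled exits",
             config.n_steps, len(particles), n_rec)
    return SimResult(traj, dip, config.field, int(config.seed), n_rec,
                     config, landscape)


def _oxygen_pair_particles(times_ps, sitemap, rng, l0_A: float = 5.84,
                           amp_A: float = 0.25, tau_ps: float = 2.0) -> list:
    """Symmetric S1 oxygen pair breathing as a stationary OU process."""
    n = times_ps.size
    dt = times_ps[1] - times_ps[0] if n > 1 else 1.0
    a = np.exp(-dt / tau_ps)
    s = amp_A * np.sqrt(1.0 - a * a)
    dl = np.empty(n)
    dl[0] = amp_A * rng.standard_normal()
    eta = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    for k in range(1, n):
        dl[k] = a * dl[k - 1] + s * eta[k - 1]
    l_nm = (l0_A + dl) / 10.0
    z_s1 = np.full(n, sitemap.center("S1"))
    zero = np.zeros(n)
    return [Particle("OS1A", "O", z_s1.copy(), x=-l_nm / 2.0, y=zero.copy()),
            Particle("OS1B", "O", z_s1.copy(), x=l_nm / 2.0, y=zero.copy())]


def force_ratio(speed_m_s: float) -> float:
    """Magnetic-to-electric force ratio for an ion moving at the given
    speed in an electromagnetic wave: |F_B|/|F_E| = v/c."""
    if speed_m_s < 0:
        raise ValueError("speed must be >= 0")
    if speed_m_s > C_LIGHT:
        raise ValueError("speed exceeds the speed of light")
    return speed_m_s / C_LIGHT
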