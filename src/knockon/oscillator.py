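"""Resonant carbonyl (-C=O) stretch as a damped driven harmonic oscillator.

The filter carbonyls' collective stretch mode is modelled as one effective
underdamped oscillator with natural frequency f0 (default 51.87 THz, the
carbonyl fingerprint band), damping gamma and effective charge q_eff. An
applied field E(t) = E0 cos(2*pi*f*t + phi) drives it; the steady-state
displacement amplitude follows the Lorentzian

    A(omega) = (q_eff E0 / m') / sqrt((omega0^2 - omega^2)^2
                                      + gamma^2 omega^2).

The dipole trace mu(t) = q_eff * x(t) feeds the spectra module, and the
normalized steady-state energy feeds the S1-barrier modulation in the
channel simulator.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .constants import AMU, E_CHARGE
from .spectra import DipoleTrace
from .trajio import ContractViolation, FieldSpec


@dataclass
class CarbonylOscillator:
    f0_thz: float = 51.87
    gamma_per_ps: float = 3.0     # amplitude linewidth ~ gamma/2pi < 2 THz
    q_eff_e: float = 0.8
    mass_amu: float = 15.999
    x0_nm: float = 0.0
    v0_nm_ps: float = 0.0

    def __post_init__(self):
        if self.f0_thz <= 0 or self.gamma_per_ps <= 0 or self.mass_amu <= 0:
            raise ContractViolation("f0, gamma and mass must be positive")
        if self.gamma_per_ps / 2.0 >= self.omega0:
            raise ContractViolation(
                "oscillator must be underdamped (gamma/2 < 2*pi*f0)")

    @property
    def omega0(self) -> float:
        """Natural angular frequency in rad/ps."""
        return 2.0 * math.pi * self.f0_thz

    def drive_accel(self, e0_v_nm: float) -> float:
        """q_eff*E0/m in nm/ps^2 for a field amplitude in V/nm."""
        force_n = self.q_eff_e * E_CHARGE * e0_v_nm * 1e9  # N
        return force_n / (self.mass_amu * AMU) * 1e-15     # nm/ps^2

    def steady_amplitude(self, field: FieldSpec) -> float:
        """Closed-form steady-state displacement amplitude (nm)."""
        w = field.omega_per_ps
        a0 = self.drive_accel(field.e0)
        return a0 / math.sqrt((self.omega0 ** 2 - w ** 2) ** 2
                              + (self.gamma_per_ps * w) ** 2)


def drive_oscillator(osc: CarbonylOscillator, field: FieldSpec,
                     dt_fs: float = 0.5, n_steps: int = 100_000,
                     noise_rms_nm_ps2: float = 0.0,
                     seed: int | None = None) -> DipoleTrace:
    """Integrate x'' = -omega0^2 x - gamma x' + (q_eff/m) E(t) [+ noise].

    Deterministic by default (exact discretisation of the linear system via
    ``scipy.signal``); optional white acceleration noise of the given RMS
    turns the free oscillator into a thermally rattling one whose spectrum
    shows the fingerprint band without a drive.
    """
    if dt_fs > 1000.0 / (20.0 * osc.f0_thz):
        raise ValueError(
            f"dt = {dt_fs} fs cannot resolve f0 = {osc.f0_thz} THz; need "
            f"dt <= {1000.0 / (20.0 * osc.f0_thz):.3f} fs")
    dt_ps = dt_fs * 1e-3
    t_ps = np.arange(n_steps + 1) * dt_ps
    u = osc.drive_accel(field.e0) * np.cos(field.omega_per_ps * t_ps
                                           + field.phi)
    if noise_rms_nm_ps2 > 0.0:
        rng = np.random.default_rng(seed)
        u = u + noise_rms_nm_ps2 * rng.standard_normal(u.size)
    sys = _signal.StateSpace([[0.0, 1.0],
                              [-osc.omega0 ** 2, -osc.gamma_per_ps]],
                             [[0.0], [1.0]], [[1.0, 0.0]], [[0.0]])
    _, x, _ = _signal.lsim(sys, u, t_ps, X0=[osc.x0_nm, osc.v0_nm_ps])
    return DipoleTrace(times_fs=t_ps * 1e3, mu=osc.q_eff_e * x)


def measured_amplitude(trace: DipoleTrace, osc: CarbonylOscillator,
                       tail_fraction: float = 0.25) -> float:
    """Steady-state displacement amplitude from the trace tail (RMS*sqrt2)."""
    n = trace.mu.size
    tail = trace.mu[int((1 - tail_fraction) * n):] / osc.q_eff_e
    return float(np.sqrt(2.0 * np.mean(tail ** 2)))


def steady_energy(trace: DipoleTrace, osc: CarbonylOscillator,
                  tail_fraction: float = 0.25) -> float:
    """Mean oscillator energy over the trace tail, arbitrary (amu nm^2/ps^2)
    units: E = 1/2 m (v^2 + omega0^2 x^2)."""
    n = trace.mu.size
    x = trace.mu[int((1 - tail_fraction) * n):] / osc.q_eff_e
    dt_ps = trace.dt_fs * 1e-3
    v = np.gradient(x, dt_ps)
    return float(0.5 * osc.mass_amu
                 * np.mean(v ** 2 + osc.omega0 ** 2 * x ** 2))


def normalized_excitation(osc: CarbonylOscillator, field: FieldSpec,
                          dt_fs: float = 0.5, n_steps: int = 40_000) -> float:
    """Steady-state oscillator energy at the field's frequency, normalized
    to the energy under the same-amplitude resonant drive (so u = 1 exactly
    on resonance, u -> 0 far off resonance).

    This is the dimensionless excitation the S1-barrier modulation consumes.
    """
    if field.e0 == 0.0 or field.f_thz == 0.0:
        return 0.0
    tr = drive_oscillator(osc, field, dt_fs=dt_fs, n_steps=n_steps)
    res = FieldSpec(e0=field.e0, f_thz=osc.f0_thz, phi=field.phi)
    tr0 = drive_oscillator(osc, res, dt_fs=dt_fs, n_steps=n_steps)
    return steady_energy(tr, osc) / steady_energy(tr0, osc)
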