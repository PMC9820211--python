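"""Trajectory / site-map / run-configuration data model and file I/O.

This is the contract every analysis module consumes: a :class:`Trajectory`
of labeled particles (K ions, W waters, O carbonyl oxygens, CL) with a
pore-axis coordinate per frame, a :class:`SiteMap` of ordered half-open
binding-site intervals (intracellular, Scav, S4..S0, extracellular, low z
to high z), an oscillating-field description and a run configuration.

Files: a tab-separated columnar trajectory dialect
(``t_fs  particle_id  species  z_nm  [x_nm  y_nm]``, ``#`` comments),
a MODEL-separated PDB snapshot series (coordinates in Angstrom at the PDB
boundary, nm internally), and a YAML run-configuration file.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field, replace
import numpy as np
import yaml

from .constants import SPECIES

log = logging.getLogger(__name__)

SITE_ORDER = ("intracellular", "Scav", "S4", "S3", "S2", "S1", "S0",
              "extracellular")
FILTER_SITES = ("S1", "S2", "S3", "S4")  # occupancy-code order, S1 leftmost


class ContractViolation(ValueError):
    """A data-model invariant does not hold."""


class ParseError(ValueError):
    """A file does not parse under the declared dialect."""


# --------------------------------------------------------------------------
# particles / trajectory
# --------------------------------------------------------------------------

@dataclass
class Particle:
    """One labeled particle with per-frame coordinates (nm)."""
    pid: str
    species: str
    z: np.ndarray
    x: np.ndarray | None = None
    y: np.ndarray | None = None

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ContractViolation(
                f"particle {self.pid!r}: species {self.species!r} not in "
                f"{SPECIES}")
        self.z = np.asarray(self.z, dtype=float)
        for attr in ("x", "y"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, np.asarray(v, dtype=float))


@dataclass
class Trajectory:
    """Time-ordered frames of labeled particles on the pore axis.

    ``times`` are in ps with strictly uniform spacing (to 1 part in 1e6);
    every particle has a coordinate in every frame.
    """
    times: np.ndarray          # ps
    particles: list[Particle]
    box_z: float = 0.0         # nm, informational extent of the cell
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size < 1:
            raise ContractViolation("times must be a nonempty 1-D array")
        if self.times.size > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise ContractViolation("times must be strictly increasing")
            if (dts.max() - dts.min()) > 1e-6 * max(abs(dts.mean()), 1e-30):
                raise ContractViolation(
                    "non-uniform time step (beyond 1 part in 1e6)")
        n = self.times.size
        for p in self.particles:
            for arr, name in ((p.z, "z"), (p.x, "x"), (p.y, "y")):
                if arr is not None and arr.shape != (n,):
                    raise ContractViolation(
                        f"particle {p.pid!r}: {name} has {arr.shape} values "
                        f"for {n} frames (gap)")
        pids = [p.pid for p in self.particles]
        if len(set(pids)) != len(pids):
            raise ContractViolation("particle ids must be unique")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def dt_ps(self) -> float:
        if self.times.size < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    @property
    def duration_ns(self) -> float:
        return float(self.times[-1] - self.times[0]) / 1e3

    def by_species(self, species: str) -> list[Particle]:
        return [p for p in self.particles if p.species == species]

    def particle(self, pid: str) -> Particle:
        for p in self.particles:
            if p.pid == pid:
                return p
        raise KeyError(f"no particle with id {pid!r}")


# --------------------------------------------------------------------------
# site map
# --------------------------------------------------------------------------

@dataclass
class SiteMap:
    """Ordered, contiguous half-open intervals [z_lo, z_hi) along the pore.

    Ordered from intracellular (low z) to extracellular (high z); membership
    is total: z below the first interval maps to ``intracellular``, above
    the last to ``extracellular``.
    """
    intervals: list[tuple[str, float, float]]

    def __post_init__(self):
        names = [n for n, _, _ in self.intervals]
        if len(set(names)) != len(names):
            raise ContractViolation("site names must be unique")
        for s in FILTER_SITES:
            if s not in names:
                raise ContractViolation(f"site map must contain {s}")
        prev_hi = None
        for name, lo, hi in self.intervals:
            if hi <= lo:
                raise ContractViolation(f"site {name}: z_hi <= z_lo")
            if prev_hi is not None and abs(lo - prev_hi) > 1e-9:
                raise ContractViolation(
                    f"site {name}: intervals must be contiguous")
            prev_hi = hi
        order = [n for n in names if n in SITE_ORDER]
        if order != [n for n in SITE_ORDER if n in names]:
            raise ContractViolation(
                "sites must be ordered intracellular -> extracellular")

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.intervals]

    @property
    def boundaries(self) -> np.ndarray:
        """Internal boundaries between consecutive regions (len = n-1)."""
        return np.array([lo for _, lo, _ in self.intervals[1:]])

    def interval(self, name: str) -> tuple[float, float]:
        for n, lo, hi in self.intervals:
            if n == name:
                return lo, hi
        raise KeyError(name)

    def center(self, name: str) -> float:
        lo, hi = self.interval(name)
        return 0.5 * (lo + hi)

    def region_of(self, z: float) -> str:
        return self.names[int(np.searchsorted(self.boundaries, z,
                                              side="right"))]

    def region_indices(self, z: np.ndarray) -> np.ndarray:
        """Vectorised region index (0 = intracellular .. n-1)."""
        return np.searchsorted(self.boundaries, np.asarray(z), side="right")

    @property
    def pore_lo(self) -> float:
        """Lower edge of the first binding site (the entry plane)."""
        return self.intervals[1][1] if self.intervals[0][0] == \
            "intracellular" else self.intervals[0][1]

    @property
    def pore_hi(self) -> float:
        """Upper edge of the last binding site (the exit plane)."""
        if self.intervals[-1][0] == "extracellular":
            return self.intervals[-1][1]
        return self.intervals[-1][2]


def default_sitemap(site_width: float = 0.35, reservoir: float = 0.3,
                    pore_lo: float = 0.0) -> SiteMap:
    """Canonical map: thin reservoirs flanking Scav, S4..S0 of equal width."""
    sites = ["Scav", "S4", "S3", "S2", "S1", "S0"]
    iv = [("intracellular", pore_lo - reservoir, pore_lo)]
    z = pore_lo
    for s in sites:
        iv.append((s, z, z + site_width))
        z += site_width
    iv.append(("extracellular", z, z + reservoir))
    return SiteMap(iv)


# --------------------------------------------------------------------------
# field / run configuration
# --------------------------------------------------------------------------

@dataclass
class FieldSpec:
    """Oscillating field E(t) = E0 cos(2*pi*f*t + phi) along the pore axis z."""
    e0: float = 0.0       # V/nm
    f_thz: float = 0.0    # THz
    phi: float = 0.0      # rad

    def __post_init__(self):
        if self.e0 < 0:
            raise ContractViolation("field amplitude e0 must be >= 0")
        if self.f_thz < 0:
            raise ContractViolation("field frequency must be >= 0")

    @property
    def omega_per_ps(self) -> float:
        return 2.0 * math.pi * self.f_thz


@dataclass
class RunConfig:
    """Channel-simulator run configuration.

    ``charge_imbalance_dq`` (the ion-imbalance Δq of the double-membrane
    setup) is metadata only: the simulator takes ``membrane_voltage_mv``
    directly, since a Δq does not by itself fix a voltage.
    """
    dt_fs: float = 10.0
    n_steps: int = 100_000
    temperature: float = 300.0       # K
    friction: float = 5.0            # 1/ps
    membrane_voltage_mv: float = 0.0
    charge_imbalance_dq: float = 0.0  # e, metadata only
    field: FieldSpec = dc_field(default_factory=FieldSpec)
    sitemap: SiteMap = dc_field(default_factory=default_sitemap)
    seed: int = 2023
    discard_time_ns: float = 0.0
    sample_stride: int = 10
    boundary: str = "recycle"        # "recycle" | "reflect"
    eps_r: float = 2.0               # relative permittivity inside the SF
    lambda_debye_nm: float = 0.8
    water_depth_scale: float = 0.5

    def __post_init__(self):
        for name in ("dt_fs", "n_steps", "temperature", "friction"):
            if getattr(self, name) <= 0:
                raise ContractViolation(f"{name} must be > 0")
        if self.sample_stride < 1:
            raise ContractViolation("sample_stride must be >= 1")
        if self.boundary not in ("recycle", "reflect"):
            raise ContractViolation("boundary must be 'recycle' or 'reflect'")
        if self.discard_time_ns >= self.total_time_ns and self.n_steps > 0 \
                and self.discard_time_ns > 0:
            raise ContractViolation(
                "discard_time must be smaller than the total simulated time")

    @property
    def dt_ps(self) -> float:
        return self.dt_fs * 1e-3

    @property
    def total_time_ns(self) -> float:
        return self.n_steps * self.dt_fs * 1e-6


_CONFIG_DEFAULTS = {
    "dt_fs": 10.0, "n_steps": 100_000, "temperature": 300.0, "friction": 5.0,
    "membrane_voltage_mv": 0.0, "charge_imbalance_dq": 0.0, "seed": 2023,
    "discard_time_ns": 0.0, "sample_stride": 10, "boundary": "recycle",
    "eps_r": 2.0, "lambda_debye_nm": 0.8, "water_depth_scale": 0.5,
}
_FIELD_KEYS = {"e0", "f_thz", "phi"}
_SITEMAP_KEYS = {"site_width", "reservoir", "pore_lo", "intervals"}


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, applying (and logging) defaults.

    Unknown keys raise with the list of valid keys; invariant breaches
    surface as :class:`ContractViolation` naming the offending field.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: top level must be a mapping")
    valid = set(_CONFIG_DEFAULTS) | {"field", "sitemap"}
    unknown = set(raw) - valid
    if unknown:
        raise ParseError(
            f"{path}: unknown keys {sorted(unknown)}; valid keys are "
            f"{sorted(valid)}")
    kwargs = {}
    for key, default in _CONFIG_DEFAULTS.items():
        if key in raw:
            kwargs[key] = type(default)(raw[key])
        else:
            log.info("config %s: applying default %s = %r", path, key,
                     default)
            kwargs[key] = default
    fraw = raw.get("field", {})
    unknown = set(fraw) - _FIELD_KEYS
    if unknown:
        raise ParseError(f"{path}: unknown field keys {sorted(unknown)}; "
                         f"valid keys are {sorted(_FIELD_KEYS)}")
    kwargs["field"] = FieldSpec(**{k: float(v) for k, v in fraw.items()})
    sraw = raw.get("sitemap", {})
    unknown = set(sraw) - _SITEMAP_KEYS
    if unknown:
        raise ParseError(f"{path}: unknown sitemap keys {sorted(unknown)}; "
                         f"valid keys are {sorted(_SITEMAP_KEYS)}")
    if "intervals" in sraw:
        kwargs["sitemap"] = SiteMap([(str(n), float(lo), float(hi))
                                     for n, lo, hi in sraw["intervals"]])
    else:
        kwargs["sitemap"] = default_sitemap(
            **{k: float(v) for k, v in sraw.items()})
    return RunConfig(**kwargs)


# --------------------------------------------------------------------------
# columnar trajectory I/O
# --------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path, format: str = "columnar") -> None:
    """Write a trajectory (``columnar`` dialect or ``pdb-series``)."""
    if not traj.particles:
        raise ContractViolation("nothing to write: trajectory has no "
                                "particles")
    if format == "columnar":
        _write_columnar(traj, path)
    elif format == "pdb-series":
        _write_pdb(traj, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_trajectory(path, format: str = "columnar") -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    if format == "columnar":
        traj = _read_columnar(path)
    elif format == "pdb-series":
        traj = _read_pdb(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    log.info("read %s: %d frames, %d particles (%s)", path, traj.n_frames,
             len(traj.particles),
             ", ".join(f"{p.pid}:{p.species}" for p in traj.particles[:8]))
    return traj


def _write_columnar(traj: Trajectory, path) -> None:
    has_xy = all(p.x is not None and p.y is not None for p in traj.particles)
    with open(path, "w") as fh:
        fh.write("# t_fs\tparticle_id\tspecies\tz_nm")
        fh.write("\tx_nm\ty_nm\n" if has_xy else "\n")
        fh.write(f"# box_z_nm={traj.box_z:.6f}\n")
        for k, t in enumerate(traj.times):
            t_fs = t * 1e3
            for p in traj.particles:
                row = f"{t_fs:.6f}\t{p.pid}\t{p.species}\t{p.z[k]:.6f}"
                if has_xy:
                    row += f"\t{p.x[k]:.6f}\t{p.y[k]:.6f}"
                fh.write(row + "\n")


def _read_columnar(path) -> Trajectory:
    frames: dict[float, dict[str, tuple]] = {}
    species: dict[str, str] = {}
    box_z = 0.0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if s.startswith("#"):
                if "box_z_nm=" in s:
                    box_z = float(s.split("box_z_nm=")[1])
                continue
            if not s:
                continue
            cols = s.split("\t") if "\t" in s else s.split()
            if len(cols) not in (4, 6):
                raise ParseError(
                    f"{path}:{lineno}: expected 4 or 6 columns, got "
                    f"{len(cols)}")
            try:
                t_fs = float(cols[0])
                z = float(cols[3])
                xy = (float(cols[4]), float(cols[5])) if len(cols) == 6 \
                    else None
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            pid, sp = cols[1], cols[2]
            if sp not in SPECIES:
                raise ParseError(
                    f"{path}:{lineno}: unknown species {sp!r}")
            if pid in species and species[pid] != sp:
                raise ParseError(
                    f"{path}:{lineno}: particle {pid!r} changes species")
            species[pid] = sp
            frames.setdefault(t_fs, {})[pid] = (z, xy)
    if not frames:
        raise ParseError(f"{path}: no data rows")
    times_fs = sorted(frames)
    pids = list(species)
    n = len(times_fs)
    has_xy = any(v[1] is not None
                 for f in frames.values() for v in f.values())
    arrays = {pid: (np.empty(n), np.empty(n) if has_xy else None,
                    np.empty(n) if has_xy else None) for pid in pids}
    for k, t in enumerate(times_fs):
        frame = frames[t]
        for pid in pids:
            if pid not in frame:
                raise ContractViolation(
                    f"{path}: frame t={t} fs is missing particle {pid!r} "
                    "(gap)")
            z, xy = frame[pid]
            arrays[pid][0][k] = z
            if has_xy:
                if xy is None:
                    raise ContractViolation(
                        f"{path}: frame t={t} fs: particle {pid!r} lacks "
                        "x/y present elsewhere")
                arrays[pid][1][k] = xy[0]
                arrays[pid][2][k] = xy[1]
    particles = [Particle(pid, species[pid], arrays[pid][0], arrays[pid][1],
                          arrays[pid][2]) for pid in pids]
    return Trajectory(np.asarray(times_fs) * 1e-3, particles, box_z=box_z)


# --------------------------------------------------------------------------
# PDB snapshot series (one MODEL per frame; Angstrom at the boundary)
# --------------------------------------------------------------------------

_PDB_ELEMENT = {"K": "K", "W": "O", "O": "O", "CL": "CL"}


def _write_pdb(traj: Trajectory, path) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_p = len(traj.particles)
    stack = struc.AtomArrayStack(traj.n_frames, n_p)
    coord = np.zeros((traj.n_frames, n_p, 3))
    for j, p in enumerate(traj.particles):
        coord[:, j, 2] = p.z * 10.0  # nm -> Angstrom
        if p.x is not None:
            coord[:, j, 0] = p.x * 10.0
        if p.y is not None:
            coord[:, j, 1] = p.y * 10.0
    stack.coord = coord
    stack.res_id = np.arange(1, n_p + 1)
    stack.res_name = np.array([p.species for p in traj.particles])
    stack.atom_name = np.array([p.pid[:4] for p in traj.particles])
    stack.element = np.array([_PDB_ELEMENT[p.species]
                              for p in traj.particles])
    stack.chain_id = np.array(["A"] * n_p)
    stack.hetero = np.array([True] * n_p)
    pdb = PDBFile()
    pdb.set_structure(stack)
    # carry the time step so the series is self-describing
    pdb.lines.insert(0, f"REMARK   6 DT_PS {traj.dt_ps:.9f} "
                        f"T0_PS {traj.times[0]:.9f}")
    pdb.write(str(path))


def _read_pdb(path) -> Trajectory:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    dt_ps, t0 = 1.0, 0.0
    for line in pdb.lines:
        if line.startswith("REMARK   6 DT_PS"):
            parts = line.split()
            dt_ps, t0 = float(parts[3]), float(parts[5])
            break
    stack = pdb.get_structure(model=None)
    n_frames = stack.stack_depth()
    particles = []
    for j in range(stack.array_length()):
        sp = str(stack.res_name[j]).strip()
        if sp not in SPECIES:
            raise ParseError(f"{path}: unknown species residue {sp!r}")
        particles.append(Particle(
            str(stack.atom_name[j]).strip(), sp,
            z=stack.coord[:, j, 2] / 10.0,
            x=stack.coord[:, j, 0] / 10.0,
            y=stack.coord[:, j, 1] / 10.0))
    times = t0 + dt_ps * np.arange(n_frames)
    return Trajectory(times, particles)
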