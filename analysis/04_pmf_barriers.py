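#!/usr/bin/env python
"""Potential of mean force along the pore and per-site barriers.

(a) Parameter recovery: Boltzmann inversion of a long reflecting-wall
equilibrium run must reproduce the input landscape (reports the RMS
residual, expected < 0.3 kT). (b) Barrier modulation read-out: the same
inversion on a landscape whose S1 saddle is lowered by the resonant
carbonyl coupling shows the S2->S1 barrier drop while the others are
unchanged.

Writes results/pmf/{profile_reference.tsv,profile_modulated.tsv,
barriers.tsv}.
"""
import sys
from pathlib import Path

import numpy as np

import knockon as kn
from knockon.pmf import write_barriers

OUT = Path(__file__).resolve().parents[1] / "results" / "pmf"


def equilibrium_profile(landscape, sitemap, seed):
    cfg = kn.RunConfig(dt_fs=5, n_steps=10_000_000, seed=seed,
                       boundary="reflect", sitemap=sitemap,
                       sample_stride=10)
    res = kn.simulate(cfg, landscape, n_ions=1)
    lo = sitemap.interval("Scav")[0] + 0.05
    hi = sitemap.interval("S1")[1] - 0.05
    return kn.compute_pmf(res.trajectory, "K", z_range=(lo, hi),
                          bin_width=0.02)


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    sitemap = kn.default_sitemap()
    sites = ("Scav", "S4", "S3", "S2", "S1")
    land = kn.default_landscape(sitemap, depth=1.2, barrier=1.6,
                                halfwidth=0.05, kappa=0.8)

    prof = equilibrium_profile(land, sitemap, seed=11)
    prof.write(OUT / "profile_reference.tsv")
    v = land.potential(prof.z_centers[prof.valid])
    resid = prof.w_kt[prof.valid] - v
    rms = float(np.sqrt(np.mean((resid - resid.mean()) ** 2)))
    print(f"landscape recovery RMS residual: {rms:.3f} kT "
          f"({np.sum(prof.valid)} bins)")

    bars_ref = kn.site_barriers(prof, sitemap, sites=sites)
    write_barriers(bars_ref, OUT / "barriers.tsv")

    # resonant modulation: S1 saddle lowered by kappa * u with u = 1
    land_mod = kn.modulated_barrier(land, 1.0)
    prof_mod = equilibrium_profile(land_mod, sitemap, seed=12)
    prof_mod.write(OUT / "profile_modulated.tsv")
    bars_mod = kn.site_barriers(prof_mod, sitemap, sites=sites)
    print("transition    reference   modulated   (kT, outward)")
    for a, b in zip(bars_ref, bars_mod):
        print(f"{a.donor:>5} -> {a.acceptor:<4} {a.barrier_kt:9.2f}"
              f"{b.barrier_kt:12.2f}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
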