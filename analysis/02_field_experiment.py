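#!/usr/bin/env python
"""Frequency-contrast conduction experiment at reduced scale.

Runs the four-condition design — no field, 50 THz (off-resonance),
51.87 THz (carbonyl resonance), 53 THz (near-resonance) at 0.4 V/nm —
through the full pipeline: oscillator excitation -> S1-barrier modulation
-> Langevin simulation -> permeation/current, occupancy census, mechanism
census, quasi-PMF barriers and S1 pore-radius amplitude. Replicates are
seeded and the whole run is bit-reproducible.

Expected ordering (the resonance story): current(51.87) > current(53) >
current(50) ~ current(no-field); the S1 oxygen-pair vibration amplitude is
smallest at resonance.

Writes results/experiment/{report.tsv,summary.txt}.
"""
import sys
from pathlib import Path

import knockon as kn

OUT = Path(__file__).resolve().parents[1] / "results" / "experiment"


def main() -> int:
    sitemap = kn.default_sitemap()
    cfg = kn.RunConfig(dt_fs=5, n_steps=8_000_000,  # 40 ns per replicate
                       membrane_voltage_mv=25.0, sitemap=sitemap,
                       sample_stride=20, discard_time_ns=2.0, seed=2023)
    # resonance lowers only the S2->S1 saddle (kappa per unit excitation);
    # with one of ~4 rate-limiting saddles modulated the resonant fold
    # change is bounded near (3 + exp(-kappa))/4, so kappa = 1.2 gives a
    # clearly resolvable ~1.2x enhancement at desk scale
    landscape = kn.default_landscape(sitemap, depth=1.2, barrier=3.0,
                                     halfwidth=0.05, kappa=1.2)
    plan = kn.default_plan(cfg, landscape, e0=0.4, n_replicates=2)
    plan.n_ions, plan.n_waters = 2, 2
    report = kn.run_experiment(plan, out_dir=OUT)

    cols = ["condition", "excitation_u", "n_outward", "current_pA",
            "current_ratio_vs_ref", "soft_pct", "s2_s1_barrier_kT",
            "s1_radius_amp_A"]
    print(report.table[cols].to_string(index=False,
                                       float_format=lambda v: f"{v:.3f}"))
    if report.failures:
        print("FAILURES:", report.failures)
        return 1
    return 0


if __name__ == "__main__":
    sys.exit(main())
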