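# knockon

Analysis pipeline for single-file K⁺ permeation through a potassium-channel
selectivity filter (SF) under an oscillating midinfrared field, with a
reduced-scale Langevin channel simulator as its synthetic-data generator.

Potassium channels conduct dehydrated K⁺ through a ladder of binding sites
(Scav, S4–S1, S0) by knock-on. Two conduction modes compete: **direct**
knock-on (ions in contact, or separated only by a vacancy, driven by
unscreened Coulomb repulsion) and **soft** knock-on (co-permeating waters
always between the ions, the K-W-K-W pattern). The filter's carbonyl
(-C=O) groups absorb in a narrow band near **51.87 THz**; resonant driving
of that band stabilises the S1 geometry, lowers the exit barrier and
enhances conduction. This package provides the complete post-processing
stack a study of that effect needs, exercised end to end on synthetic
trajectories:

* `trajio` — trajectory/site-map/config data model and I/O (columnar TSV,
  MODEL-per-frame PDB series, YAML configs);
* `simulate` + `landscape` + `oscillator` + `scripted` — the overdamped
  Langevin channel generator: multi-well PCHIP landscape W(z), voltage
  tilt, field E(t) = E₀cos(2πft + φ), screened Coulomb knock-on, single
  file order, recycling boundary; a Lorentzian carbonyl oscillator whose
  excitation u lowers the S1 saddle by κ·u; and an exact scripted-
  trajectory builder for ground-truth fixtures;
* `occupancy` — per-frame S1…S4 codes over {K, W, 0} ('KKKW', 'K0KK', …)
  and their census;
* `permeation` — two-plane transit detection, flux and current
  I = N·e/T (pA);
* `mechanism` — per-event soft/direct classification and census;
* `pmf` — Boltzmann inversion W(z) = −kT ln ρ(z)/ρ_max and per-site
  barriers;
* `spectra` — IR absorption from dipole traces (ω²-weighted windowed
  power spectrum), peak finding, 5.6 µm ↔ 53.53 THz conversions;
* `geometry` — pore radius r = l/2 − r_o from symmetric carbonyl-oxygen
  pairs;
* `experiment` — the four-condition comparative design (no field /
  50 / 51.87 / 53 THz at 0.4 V/nm) as one reproducible report.

## Worked example

```python
import numpy as np
import knockon as kn

sitemap = kn.default_sitemap()                    # Scav, S4..S0 + reservoirs
land = kn.default_landscape(sitemap)              # 5 wells, 3 kT saddles
cfg = kn.RunConfig(dt_fs=2, n_steps=25_000_000,   # 50 ns
                   membrane_voltage_mv=10, seed=11, discard_time_ns=1.0)
res = kn.simulate(cfg, land, n_ions=1)

events = kn.detect_permeations(res.trajectory, sitemap)
cur = kn.compute_current(events, res.trajectory, discard_time_ns=1.0)
print(f"{cur.n_outward} outward events in {cur.duration_ns:.0f} ns "
      f"-> {cur.current_pa:.0f} pA")

low = land.with_barrier_shift(-np.log(1.8))       # drop every saddle 0.588 kT
res2 = kn.simulate(cfg, low, n_ions=1)
cur2 = kn.compute_current(kn.detect_permeations(res2.trajectory, sitemap),
                          res2.trajectory, discard_time_ns=1.0)
print(f"current ratio {kn.current_ratio(cur2, cur):.2f}")
```

prints (platform-identical under the same seed):

```
33 outward events in 49 ns -> 101 pA
current ratio 1.58
```

The ratio tracks the Arrhenius factor e^0.588 = 1.8, diluted slightly by
the diffusive part of each transit — the mean-first-passage-time analysis
in `docs/methods.md` quantifies this (predicted ≈1.65 for these settings;
a single 50 ns pair carries ±0.3 of sampling error, hence the 1.58 here).

The numbered drivers under `analysis/` run the full study and write their
tables under `results/`:

```
01_fingerprint_spectrum.py   fingerprint peak at 51.87 THz, resonance sweep
02_field_experiment.py       4-condition currents, censuses, barriers
03_mechanism_census.py       soft/direct percentages on scripted events
04_pmf_barriers.py           PMF recovery and S1-barrier modulation
05_pore_radius.py            S1 radius series and vibration amplitudes
```

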