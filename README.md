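# ifd — interface force dynamics

`ifd` is a Python toolkit for analyzing a protein–protein interface across
scales, built around the von Willebrand factor (VWF) A1/A2 domain pair.  In
circulating VWF the A2 domain shields the GPIbα-binding site on A1
(autoinhibition); which interfacial contacts hold that arrangement together
is a question that spans docking models, equilibrium and steered molecular
dynamics, biolayer interferometry (BLI) and AFM single-molecule force
spectroscopy.  `ifd` implements the analysis layer of that workflow as a
tested, reusable library:

- **Pose screening** — score docked A1/A2 poses by how completely A2
  occludes the GPIbα footprint on A1 taken from a reference A1/GPIbα
  complex (covered-fraction statistic after Cα superposition).
- **Interface contacts** — per-frame hydrogen bonds (donor–acceptor
  distance < 3.5 Å, angle < 30°) and salt bridges (acidic O to basic
  N < 4 Å) between two partners, from multi-model PDB trajectories.
- **Occupancy statistics** — survival rates per contact, multi-run
  mean ± SEM tables (SEM = s/√n with the n−1 sample standard deviation),
  strict threshold filters, residue-pair heat-map matrices, and Gaussian
  fits of the per-frame H-bond count distribution.
- **Core geometry** — Kabsch superposition, per-frame Cα-RMSD, and
  deterministic Shrake–Rupley SASA with buried interface area
  SASA(A) + SASA(B) − SASA(AB).
- **Force spectroscopy** — rupture force and dissociation time from
  spring-model pulling curves (F = k(vt − x), k = 69.48 pN/Å, v = 5 Å/ns by
  default); AFM adhesion frequency per substrate and the most probable
  rupture force X_C from a Gaussian fit of the pooled force histogram.
- **Binding kinetics** — 1:1 Langmuir sensorgram simulation and global
  fitting of (k_on, k_off, R_max) across serial analyte dilutions, with
  K_D = k_off/k_on.
- **Synthetic data** — seed-deterministic generators for every input class
  (toy complexes with planted contacts, occupancy-driven trajectories,
  pulling curves, sensorgram sets, AFM cycle sets), each with a
  ground-truth manifest.

## Worked example

Simulate a noisy BLI experiment at the wild-type A1/A2 kinetics
(k_on = 1.7 × 10⁴ M⁻¹s⁻¹, k_off = 3.7 × 10⁻² s⁻¹; six dilutions
125–4000 nM, 60 s association / 120 s dissociation, 2% noise) and refit it:

```bash
$ ifd simulate --kind bli --seed 1 --noise 0.02 --out bli_data
$ ifd bli-fit --data-dir bli_data --out bli_fit
{"kon_per_M_per_s": 17208.45, "koff_per_s": 0.037087, "Rmax_nm": 0.9930,
 "KD_M": 2.155e-06, "rss": 2.167, "rmse_nm": 0.0200}
```

The global fit recovers the generating rates to about 1% and the fitted
K_D ≈ 2.16 μM; `rmse_nm` matching the injected 0.02 nm noise says the 1:1
model fully explains the data.  The same round-trip for a pulling curve:

```bash
$ ifd simulate --kind smd --seed 1 --out smd
$ ifd pulling --curve smd/force_curve.csv --out pull
{"rupture_force_pN": 358.7, "rupture_time_ns": 20.0,
 "dissociation_time_ns": 21.6, "smooth_window": 1}
```

The rupture force is the force peak before the instant at which interface
H-bond count and buried SASA jointly reach zero (21.6 ns here).

In the library, aggregating three equilibrium runs of per-contact survival
percentages and keeping pairs above 50% mean survival:

```python
>>> from ifd import occupancy_stats as osm, presets
>>> runs = [{k: v[i] for k, v in presets.HBOND_SURVIVAL_RUNS.items()}
...         for i in range(3)]
>>> osm.filter_table(osm.aggregate_runs(runs), 50.0).data.round(1)
             run_1  run_2  run_3  mean   sem
R1334-E1598   79.3   59.1   51.1  63.2   8.4
Q1367-V1546   78.1   74.8   27.9  60.3  16.2
D1323-R1575   67.7    5.7   88.7  54.0  24.9
```

These three pairs — R1334–E1598, Q1367–V1546, D1323–R1575 — are the
strong interdomain hydrogen bonds that hold the A1/A2 interface together.

## Command line

`ifd <subcommand>` with `screen-poses`, `contacts`, `survival`, `pulling`,
`bli-fit`, `afm`, and `simulate`.  Options may be given in a YAML/JSON
config (`--config`, one section per subcommand); flags override config
values.  Every run writes its outputs as unit-suffixed CSV/JSON plus a
`run_log.json`; identical inputs and seed reproduce byte-identical data
files.

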