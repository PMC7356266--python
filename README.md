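# dpikit

Analytics for carrier-based dry-powder-inhaler (DPI) formulation work:

- **`dpikit.energetics`** — inversion of two-liquid contact angles to
  dispersive/polar surface-energy components via the harmonic-mean (Wu)
  system, plus the derived pair metrics: work of cohesion and adhesion,
  Derjaguin sphere–sphere adhesion force, and spreading coefficients.
- **`dpikit.blend`** — blend mass fractions, capsule fill mass from a target
  dose, UV-calibration concentration with LOD/LOQ gating, and content
  uniformity against pharmacopeial (85–115 %, RSD ≤ 6 %) and industry
  (90–110 %) rules.
- **`dpikit.impactor`** — Andersen cascade-impactor reduction: emitted
  fraction, cumulative undersize, log-probit regression to MMAD and GSD,
  and fine-particle fractions below 5 µm and 3 µm on a configurable mass
  basis (emitted / recovered / sized).
- **`dpikit.lungsim`** — stochastic whole-lung Monte Carlo deposition:
  mass-weighted particle sampling from an APSD, empirical extrathoracic
  capture, generation-by-generation impaction / sedimentation / diffusion
  through a randomly perturbed 24-generation airway tree, breath-hold and
  exhalation phases, reporting ET / LUNG (bronchial + acinar) / EXH
  fractions.
- **`dpikit.synthetic`** — seeded generators for every input the pipeline
  consumes (contact-angle replicates, impactor runs, uniformity samples),
  exactly invertible by their downstream stage at zero noise.
- **`dpikit.cli` / `dpikit.pipeline`** — shared IO, schema-validated
  configuration, and an umbrella CLI tying the stages into one reproducible
  run.

Unit contract: energies in mN/m, diameters in µm, masses in µg (blends in
g, fill mass in mg), forces in mN, flows in L/min.

## CLI

```bash
dpikit synth all --seed 3 -o data/                  # synthetic input tables
dpikit energetics solve --angles data/angles.csv -o out/
dpikit blend fill-mass --dose-mg 1.3 --blend blend.csv --drug drug
dpikit blend uniformity --contents contents.csv
dpikit impactor reduce --runs data/impactor_runs.csv -o apsd.csv
dpikit lungsim run --mmad 3.41 --gsd 1.8 --n 100000 --seed 42 -o dep/
dpikit pipeline run --config config.json --seed 1 -o out/
```

`dpikit pipeline run` executes synth → energetics → blend → impactor →
lungsim, writes unit-suffixed CSV/JSON artifacts plus the resolved
configuration, and is byte-for-byte reproducible for a fixed config + seed.

## Notes on conventions

- Impactor stage cut-offs default to the published Andersen set at
  28.3 L/min: 9.0, 5.8, 4.7, 3.3, 2.1, 1.1, 0.7, 0.4 µm (stages 0–7),
  overridable in config.
- FPF denominators are configurable because conventions differ between
  laboratories; the default is the emitted mass.
- The lung model is a Weibel-type symmetric scaffold with per-particle
  lognormal geometry perturbation — a documented simplification of
  cast-measurement morphometry distributions; airway physics uses standard
  analytic tube formulas (Stokes-number bend impaction, inclined-tube
  settling, Gormley–Kennedy diffusion) combined as independent mechanisms.
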