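# smtether

Single-molecule tether force-spectroscopy and ensemble binding analysis for
a tandem-HEAT-repeat scaffold protein pulled through dsDNA handles in a
dual optical trap, together with seeded synthetic-data generators so every
stage is testable without instrument data.

The pipeline covers:

* **polymer** — extensible worm-like-chain (Marko–Siggia with enthalpic
  stretching) elasticity for the DNA handles and the unfolded polypeptide,
  serial tether composition, and forward/inverse solvers.
* **fec** — force-extension-curve analysis: block-mean downsampling
  (78 kHz → 100 Hz), rip detection gated at a 10 nm branch-to-branch
  extension jump, per-branch WLC contour-length fits, ΔLc accounting with
  per-rip/total conservation, kernel-density peak reports with bootstrap
  mode uncertainty, and single-tether QC (expected-length check + single
  rupture).
* **classify** — per-cycle fate assignment (complete / misfolded /
  locked-unfolded), maximum unfolding/refolding forces, hysteresis area,
  and per-condition box-plot statistics with Welch t-tests.
* **binding** — fluorescence polarization (mP) and one-site Kd fits with
  background subtraction; nanoDSF melt curves reduced to the 350/330
  fluorescence ratio with Tm from the refined extremum of its first
  derivative.
* **synth** — kinetic Monte Carlo generator for constant-velocity pulling
  with Bell-rate unfolding/refolding, misfolded and locked subpopulations,
  tether-rupture modes, plus titration and melt-curve generators.
  Condition presets `no_smap`, `atux`, `dbk`; a calibration mode bisects
  the zero-force unfolding rates to hit a target mean unfolding force.

## CLI

```bash
smtether simulate   --preset no_smap --seed 1 -o traces/         # synthetic ensemble
smtether analyze-fec -i traces/ -o analysis/                     # transitions + ΔLc report
smtether classify    -i traces/ -o fates/                        # per-cycle fates
smtether fit-binding -i titration.csv -o kd.json                 # FP one-site fit
smtether fit-melt    -i melt.csv -o tm.json                      # nanoDSF Tm
smtether report      --seed 1 -o report/                         # all three conditions
```

Trace files are plain CSV (one sweep per file) with `# key=value` metadata
headers; simulated ensembles come with a `ground_truth.json` sidecar.
All parameters live in a single config (see `smtether.config.DEFAULTS`);
pass `-c config.yaml` to override. Every output embeds the config hash and
seed.

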