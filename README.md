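# eprstab

Toolkit for studying the thermal oxidative stability of seed oils with EPR
spin trapping, plus the supporting assay calibrations and chemometrics:

- **spin_sim** — isotropic first-derivative EPR spectra of nitroxide
  spin-adduct species (nitrogen triplet × β-hydrogen doublet) from
  spin-Hamiltonian parameters (g, a_N, a_H, linewidth, lineshape).
- **spin_quant** — baseline correction, double integration
  (derivative → absorption → area ∝ adduct concentration), and
  non-negative least-squares decomposition of mixture spectra.
- **kinetics** — intensity–time series summaries: four-parameter Boltzmann
  sigmoid fit with tangent-intercept induction period (IP = t0 − 2·dt) and
  trapezoidal area under the curve (AUC).
- **stability_model** — the no-intercept empirical model
  `AUC/1e6 = c_PV·PV + c_TPC·TPC + c_FFA·FFA` (prediction, refitting,
  residual flagging) and fatty-acid summary ratios.
- **assays** — linear calibrations converting photometric readings into
  peroxide value (µeq O2/g), total phenolics (mg caffeic acid/g) and DPPH
  radical-scavenging activity (µmol trolox/g), with explicit forward models
  for round-trip verification; spin-trap dilution and yield arithmetic.
- **chemometrics** — total-signal normalisation, fusion of assay variables
  into the feature table, Pareto scaling, and SVD-based PCA with
  per-component explained variance; pipeline order is enforced.
- **synthetic_data** — seeded generators for every input (EPR time series
  with known kinetics, group-structured log-normal feature tables) plus the
  published per-oil summary fixtures.
- **io / cli / pipeline** — plain-text CSV/JSON/YAML formats (including a
  minimal JCAMP-DX reader) and a `click` CLI.

## CLI

```bash
eprstab simulate --config systems.yaml --out spectrum.csv
eprstab integrate --in spectrum.csv
eprstab decompose --in spectrum.csv --systems systems.yaml
eprstab generate epr --seed 3 --out gen/        # synthetic kinetic series
eprstab kinetics --in gen/series.csv
eprstab generate fixtures --out gen/            # published oil records
eprstab predict-auc --records gen/oils.csv      # Eq.-style AUC predictions
eprstab pca --in features.csv --fuse assays.csv --components 2 --out pca/
eprstab run --config pipeline.yaml              # multi-stage run + manifest
```

A `systems.yaml` declares spin systems:

```yaml
systems:
  - {label: A, g: 2.00573, a_N: 14.90, a_H: 2.48, weight: 0.65}
  - {label: B, g: 2.00573, a_N: 14.70, a_H: 2.88, weight: 0.35}
```

## Known limitations

- Field modulation broadening is not modelled (modulation amplitude is
  carried as metadata only); spectra are isotropic solution spectra.
- The Boltzmann stage reports `converged=False` for non-sigmoidal series
  (e.g. rise-then-decay curves); AUC is still computed on the raw points.
- Lorentzian double integrals converge slowly with sweep width; use wide
  windows (or Gaussian/pseudo-Voigt lineshapes) for absolute-area work.
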