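# ftirchemo

An ATR-FTIR chemometrics pipeline for discriminating processing classes of
a food matrix and predicting taste-compound concentrations from infrared
spectra. Because the motivating study's raw data are confidential, the
package ships a first-class synthetic-data generator with the same
statistical structure, so every stage is reproducible and testable offline.

## What's inside

| Module | Purpose |
| --- | --- |
| `ftirchemo.synthetic_data` | Gaussian-band spectrum simulator (5 temperature classes, 4000–400 cm⁻¹ at 4 cm⁻¹, multiplicative scatter, polynomial baseline, noise) and concentration tables linearly coupled to the 1800–1200 cm⁻¹ band |
| `ftirchemo.preprocess` | MSC, SNV, Savitzky–Golay smoothing/derivatives and named chains (`"FD+MSC"`, …) with calibration-only state |
| `ftirchemo.sampling` | Deterministic Kennard–Stone ordering and largest-remainder splits (70/30, 60/30/10) |
| `ftirchemo.twodcos` | Dynamic spectra, synchronous 2D correlation maps, rank-1 per-sample maps and raster rendering |
| `ftirchemo.chemometrics` | PCA, PLS-DA (R²X/R²Y/Q²/RMSECV/RMSEP, accuracies), VIP scores, label-permutation testing, per-compound PLSR with RPD, and chain search |
| `ftirchemo.cnn_classifier` | A small residual CNN in pure NumPy (im2col convolutions, batch norm, Adam) with SEN/SPE/EFF metrics |
| `ftirchemo.metabolomics_screen` | Differential-compound screening (VIP > 1 and p < 0.05), concentration PCA, cluster-heatmap leaf orders |
| `ftirchemo.pipeline_cli` | YAML-configured end-to-end studies, CSV/JSON I/O, `ftirchemo` CLI |

The CNN is implemented directly in NumPy (no deep-learning framework is
required); its gradients are validated by finite-difference checks in the
test suite.

## CLI

All commands are driven by a YAML config with a mandatory `seed`; every
source of randomness (simulation, permutations, CNN init and shuffling)
derives from it.

```bash
cat > config.yaml <<EOF
seed: 1
out_dir: runs
EOF

ftirchemo simulate --config config.yaml --out data/
ftirchemo run-discrimination --config config.yaml
ftirchemo run-quantification --config config.yaml
ftirchemo split --spectra data/spectra.csv --fractions 0.6,0.3,0.1 \
    --names train,test,external --out split.csv
ftirchemo twodcos --spectra data/spectra.csv --labels data/labels.csv \
    --out maps/ --size 224
ftirchemo screen --concentrations data/concentrations.csv --labels data/labels.csv
```

`run-discrimination` produces a pretreatment-chain PLS-DA table, per-sample
synchronous 2DCOS images, and a trained residual CNN evaluated on an
untouched external partition. `run-quantification` restricts spectra to the
1800–1200 cm⁻¹ fingerprint band and searches pretreatment chains per
compound, reporting R²c, R²p, RMSEP and RPD.

## File formats

Spectra are wide CSV (`wavenumber_cm-1` column plus one column per sample);
labels and splits are two-column CSVs; concentrations are samples × compounds
CSV; metrics are JSON. Ascending wavenumber grids are accepted and flipped
to the descending FTIR convention on read.
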