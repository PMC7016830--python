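# rbetrans

Analysis toolkit for rectal dose constraints in carbon-ion therapy when two
RBE (relative biological effectiveness) languages are in play: LEM-optimized
plans evaluated against mMKM-derived limits. The package provides

- **DVH engine** (`rbetrans.dvh`): cumulative dose-volume histograms from
  voxel dose grids + binary structure masks, `D_v%` / `D_vcc` metrics,
  generalized EUD, cohort-averaged DVH bands, isotropic PRV mask expansion.
- **RBE translation** (`rbetrans.translation`): per-volume-level quadratic
  OLS fits of paired (D_LEM|v, D_MKM|v) points, 95% confidence bands on the
  mean response, and CI-based inversion translating MKM-language dose
  constraints into conservative LEM-language values (the lower CI bound).
- **NTCP model** (`rbetrans.ntcp`): Lyman-Kutcher-Burman probit NTCP for
  late rectal toxicity (defaults n=0.035, m=0.10, TD50=63.6 Gy(RBE)) with
  seeded bootstrap group summaries.
- **Fractionation** (`rbetrans.fractionation`): linear-quadratic BED and
  isoeffective total-dose conversion between schedules (rectal
  alpha/beta = 3.9 Gy); e.g. 57.3 Gy(RBE)/20 fx -> 53.5 Gy(RBE)/16 fx.
- **Constraint evaluation** (`rbetrans.constraints`): built-in clinical
  constraint sets (`OLD_MKM`, `SACRUM_PRV`, `TRANSLATED_LEM`, `NEW_CC`),
  per-patient compliance rows and cohort exceedance fractions.
- **Synthetic cohort** (`rbetrans.cohort`): seeded generator of paired
  LEM/mMKM rectum DVHs for a 63-patient cohort (22 prostate / 28 L_SAC /
  13 H_SAC at 66.4 / 70.4 / 73.6 Gy(RBE) in 16 fractions), linked by a
  known quadratic ground-truth dose map plus configurable noise — so every
  stage of the pipeline is testable without any clinical data.
- **Pipeline & CLI** (`rbetrans.pipeline`, `rbetrans.cli`): one-command
  end-to-end run emitting translation tables, NTCP tables and summaries,
  compliance reports, averaged DVH bands and a run manifest.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (BED conversion,
LKB-vs-quadrature equivalence, DVH sort-oracle equivalence, gEUD limits,
regression recovery and confidence-band coverage, translation round trip,
printed-table compliance, BED conservation), each at its stated tolerance.

## CLI

```sh
rbetrans bed-convert --dose 57.3 --from-fractions 20 --to-fractions 16 --alpha-beta 3.9
rbetrans simulate-cohort --seed 1 --out runs/cohort
rbetrans ntcp --manifest runs/cohort/manifest.csv --out runs/ntcp.csv
rbetrans check-constraints --dvh runs/cohort/dvh/P001_mkm.csv --constraint-set OLD_MKM
rbetrans run-pipeline --seed 1 --out runs/pipeline
rbetrans init-config --out config.yaml   # full cohort-generator defaults
rbetrans fit-translate --pairs runs/pipeline/pairs.csv --out runs/translation.csv
```

All commands are deterministic given `--seed` and exit non-zero with a
one-line cause on error.

## File formats

Everything is plain text: DVH CSVs with `# key=value` metadata headers,
cohort manifest CSV, YAML constraint sets and cohort configs, JSON-sidecar
dose-grid/mask fixtures (see `rbetrans.io` docstrings for the exact
layouts).
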