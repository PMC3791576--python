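# chromval

Chromatographic method-validation statistics and GUM-style measurement
uncertainty budgets, computed end to end on synthetic HPLC data.

A seeded generator stands in for the instrument: it emulates a linear UV
detector response (`area = 44446.17 x + 5597.38` by default, with
per-level relative replicate noise), first-order forced degradation of a
parent compound into one or two impurity peaks, and raw chromatogram
traces built from Gaussian or exponentially-modified-Gaussian peaks.
Downstream modules integrate the traces, fit the calibration line,
compute ICH-style validation statistics and assemble the four-component
expanded uncertainty budget.

## Modules

| module | what it does |
| --- | --- |
| `chromval.synth` | seeded generators: calibration/replicate area tables, stress tables, chromatogram traces |
| `chromval.chromatograms` | peak detection/integration; USP plate count, tailing factor, resolution |
| `chromval.calibration` | OLS calibration fit, inverse prediction with its standard deviation, relative calibration uncertainty, LOQ rule |
| `chromval.validation` | RSD, accuracy, spiked recovery, two-wavelength F-factor check, stress summaries, robustness evaluation |
| `chromval.uncertainty` | standard/calibration/precision/accuracy components, expanded uncertainty, budget report |
| `chromval.config` / `chromval.pipeline` / `chromval.cli` | run configuration, end-to-end orchestration, command line |

## Command line

```sh
chromval all --seed 1 --out-dir out            # full run, complete bundle
chromval generate --seed 1 --out-dir out       # synthetic inputs only
chromval integrate --chromatogram out/chromatogram.csv --out out/peaks.csv
chromval calibrate --seed 1 --out-dir out      # pooled fit record
chromval validate --seed 1 --out-dir out       # validation + stress summaries
chromval budget --seed 1 --out-dir out         # uncertainty budget
chromval all --config run.yaml                 # YAML/JSON config drives everything
```

Every stage draws from its own child of the run seed, so two runs with
the same configuration produce byte-identical bundles and any subcommand
recomputes its slice in isolation. `chromval all` exits nonzero when the
run's own validation criteria (precision RSD < 2% at the criterion
levels, the LOQ rule, the robustness grid) fail; with the default
paper-anchored noise levels this is a frequent, honest outcome for many
seeds. All outputs are delimited text plus one `results.json`.

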