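# qepsgrowth

Four-component parametric modelling of human height growth from fetal life
to adulthood, with individual trajectory fitting, growth-milestone
extraction, SD-score referencing, synthetic cohort generation and two-group
comparison.

Total height is decomposed additively:

```
T(age) = E(age) + QS(age) + P(age),    QS(age) = Q(age) - S(age)
```

* **Q** — quadratic *basic* growth rising from a fetal origin `t0`
  (about 6 weeks after conception) to its vertex at 21.5 y (males) /
  19.1 y (females);
* **E** — saturating exponential specific to fetal/infancy growth;
* **P** — monotone, mildly right-skewed sigmoid for the pubertal spurt;
* **S** — stop function terminating basic growth at the end of puberty.

Six parameters describe an individual: three component amplitudes (cm), two
unitless time scales, and the mid-puberty age. From a fitted parameter set
the package derives component maxima, milestone ages (end of infancy
growth, onset/middle/end of pubertal growth, age at peak height velocity),
pubertal height-gain decomposition (basic vs puberty-specific), childhood
duration, and SD scores including the mid-parental-height difference.

## Layout

| module                  | contents                                                        |
| ----------------------- | --------------------------------------------------------------- |
| `qepsgrowth.core`       | forward model, shape constants, derived-variable extraction     |
| `qepsgrowth.fitting`    | QC screening, adult-height rule, weighted NLS fitting, CSV I/O  |
| `qepsgrowth.reference`  | reference-model construction and SD-score computation           |
| `qepsgrowth.simulate`   | synthetic cohort generator with preset group moments            |
| `qepsgrowth.compare`    | two-group tests, standardized mean differences, summary tables  |
| `qepsgrowth.pipeline` / `qepsgrowth.cli` | end-to-end orchestration, manifests, figures   |

## CLI

Installed as `qeps` (also `python -m qepsgrowth.cli`):

```bash
# synthetic cohort as long-format CSV plus covariates and generating truth
qeps simulate --preset reference --n 200 --seed 1 \
    --out meas.csv --covariates-out cov.csv --truth-out truth.csv

# eligibility screening, fitting, derived variables
qeps qc  --records meas.csv --out qc.csv
qeps fit --records meas.csv --covariates cov.csv --out fits.csv --seed 1
qeps derive --fits fits.csv --out derived.csv

# two-group comparison table and SMD forest data
qeps compare --group-a ks_fits.csv --group-b ref_fits.csv \
    --out table.csv --smd-out forest.csv

# full pipeline: simulate -> qc -> fit -> reference -> sds -> compare -> report
qeps run --out-dir out --seed 1 --n-reference 100 --n-ks 20
```

`qeps run` writes every artifact (CSV/JSON/figures) along with
`manifest.json` recording the configuration hash, the seed and per-stage
timings; identical configurations yield identical manifest hashes.

## Notes

* Measurement noise follows instrument precision: infant length is rounded
  to 0.5 cm, standing height to 0.1 cm; fitting weights assume 0.6 / 0.3 cm
  SD accordingly.
* Missing gestational age is imputed as term (40 weeks) and enters only
  through the fetal origin `t0`.
* SD scores are computed against a reference model built from a fitted
  (synthetic) reference cohort, so they are internally consistent but not
  numerically comparable to scores from external national references.
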