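# agrowth

Automated LMS-based growth assessment for pediatric achondroplasia.

Children with achondroplasia must be monitored on disorder-specific growth
references — standard charts misclassify their growth — and clinicians track
nine anthropometric parameters: height, weight, BMI, head circumference,
sitting height, leg length, arm span, relative sitting height and foot
length. Each reference tabulates, per sex and age, the LMS triplet
(L, M, S): the Box-Cox power normalizing skewness, the median, and the scale.
`agrowth` automates the whole manual workflow: coefficient lookup with age
interpolation, the z-score transforms, percentile conversion, inverse centile
curves, and batch processing of patient files — for clinicians and
researchers who today do this by hand from printed charts or spreadsheets.

## The mathematics

For a measurement *X* at age *t*, the age- and sex-specific coefficients
L(t), M(t), S(t) are obtained by piecewise-linear interpolation of the
reference grid. Parameters tabulated with L = 1 (height, head circumference,
sitting height, leg length, arm span, relative sitting height, foot length)
use the standard score with S an absolute SD in measurement units:

    Z = (X − M) / S

Skewed parameters (weight, BMI) use Cole's full LMS Box-Cox transform with
S a coefficient of variation:

    Z = ((X/M)^L − 1) / (L·S),      Z = ln(X/M)/S  as L → 0

Percentiles are 100·Φ(Z) with Φ the standard normal CDF. The inverse
transform X = M·(1 + L·S·Z)^(1/L) (or M + Z·S) draws centile curves and
generates synthetic cohorts with exactly known true z.

The real European achondroplasia coefficients are published elsewhere and
are **not** shipped; you load your own bundle (CSV header
`parameter,sex,age_years,L,M,S`, or an equivalent JSON document). A seeded
synthetic generator produces structurally faithful stand-in bundles — same
nine parameters, both sexes, 6-month grid to age 4 then annual for the
birth-to-20 parameters, annual 2–20 y (proportion parameters) and 3–20 y
(foot length) — for testing and demonstration.

## Worked example

```sh
$ agrowth simulate --seed 7 --n 6 --out-dir demo
wrote reference.csv (18 curves), cohort.csv (6 patients), truth.csv to demo

$ agrowth zscore --ref demo/reference.csv --sex male --age 6.25 \
    --parameter height --value 95.0
z = 0.28
percentile = 61.1
flags = interpolated_age
```

A height of 95.0 cm for a 6.25-year-old boy lies 0.28 SD above this
reference's median — the 61.1th percentile. The `interpolated_age` flag
records that 6.25 y is not a tabulated age, so L, M and S were linearly
interpolated between the bracketing grid nodes (which the batch output also
reports per row, for auditability).

```sh
$ agrowth agreement --n 8 --seed 2
agreement: 100.0% of 62 evaluations (tol 1e-9)
...
```

Other subcommands: `agrowth validate-ref <bundle>` (schema and invariant
checks, exit 1 with one violation per line on failure), `agrowth batch --ref
<bundle> --in patients.csv --out results.csv`, and `agrowth curves --ref
<bundle> --parameter height --sex male --percentiles 5,50,95 --step 0.25
--out curves.csv`. Python users can call the same functions directly
(`agrowth.evaluate`, `agrowth.assess_patient`, `agrowth.centile_table`, …).

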