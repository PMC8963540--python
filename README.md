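# sedlab

Analytics for optical-density sedimentation assays and settling-selection
evolution experiments: Stokes'-law calibration of arbitrary-unit OD600
settling rates into physical velocities and cellular densities, selection
coefficients from competition counts, nuclear doubling times from ploidy
distributions, and broad-sense heritability by variance partitioning — plus a
synthetic-data module so every stage has a parameter-recovery test without any
external downloads.

## Modules

| module | what it does |
| --- | --- |
| `sedlab.physics` | Stokes'-law closed forms (`v = 2gR²Δρ/9μ` and its inversion), sphere geometry from perimeter, quadratic seawater-density surface in (salinity, temperature) |
| `sedlab.assay` | OD600 decay traces → arbitrary-unit settling rates (endpoint or log-linear), dilution-invariant |
| `sedlab.calibration` | joint least-squares fit of the AU→m/s log-scalar `S` and a common excess density `p_p_hat` against a reference settling compilation; 500-repetition 90%-subset ("out-of-bag") bootstrap uncertainty; per-group velocity/density estimates |
| `sedlab.fitness` | log2 selection coefficients per day from clumpy/non-clumpy counts via binomial resampling and logit2-rescaled regression; logit binomial CIs |
| `sedlab.growth` | log2 geometric-mean nuclear content, doubling time by regression over a 0–24 h window, nuclei-per-volume ratios, exact generation accounting |
| `sedlab.heritability` | H = 1 − SS_within/SS_total over genotype×environment groups, per-phenotype and pooled |
| `sedlab.synth` | seed-deterministic generators for all five input tables with ground-truth JSON sidecars |
| `sedlab.io`, `sedlab.pipeline`, `sedlab.cli` | schema-validated CSV/XLSX readers, stage orchestration with a hashed manifest, `click` CLI |

## CLI

```sh
sedlab simulate --what all --seed 1 --out sim/                  # synthetic tables + truth
sedlab calibrate --assay s1.csv --reference s2.csv --seawater s3.csv \
                 --reps 500 --seed 1 --out fit.json
sedlab density   --assay s1.csv --reference s2.csv --out s1_calibrated.csv
sedlab fitness   --counts s4.csv --geno S01 --regime YES_SEL --resamples 500 --seed 1
sedlab doubling  --table nuclei.csv
sedlab heritability --table phenotypes.csv --log-phenotypes sedimentation_rate
sedlab run --config pipeline.yaml                               # full pipeline + manifest
```

Expected table schemas (column names are validated case-sensitively):
assay `V_au,R_meters,species,genotype,temp,hours_growth`; reference
`classification,salt_percent,V_meters_per_second,R_meters` (+optional
`temp_C,Pf,Pp_,Pp,V_exp` — computed columns are regenerated, not trusted);
seawater `temp_C,salinity,density`; competition
`batch,rep,geno,time,sel_cond,NOT_CLUMPY,YES_CLUMPY,...` (time in hours);
nuclei `time_h,ploidy,fraction[,n_cells]`; phenotypes
`genotype,temp,hours,phenotype,value`.

## Conventions

Internally: lengths in meters, velocities in m/s, densities in kg/m³,
salinity in g/L, times in seconds (OD traces), hours (files) or days
(selection slopes). Excess density is always relative to distilled water
(1,000 kg/m³); the calibration's common density parameter is relative to the
assay medium (1,028.9 kg/m³). All randomness flows from explicit seeds; the
same seed gives bit-identical bootstrap/resampling results.
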