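# propolis-risk

Analysis pipeline for toxic-element measurements (As, Cd, Pb, Mn) in raw
propolis: QC acceptance of method quality parameters, censoring-aware
summaries of left-censored (below-LOD/LOQ) concentrations, regulatory
compliance screening, chemometric characterization (Pearson correlation,
PCA, Ward clustering), and deterministic dietary risk assessment
(average daily dose → hazard quotient → carcinogenic risk bands).

Because no raw per-sample concentration table is published for the study
this pipeline reproduces, the package ships:

- `build_paper_fixture(seed)` — a 12-sample reference dataset that pins
  every published cell (extremes, the two high-Pb sites P06/P10, the
  censoring pattern) and fills the remaining cells reproducibly from a
  seed within the published ranges; and
- `synthetic_data` — a correlated-lognormal generator (Gaussian copula,
  per-element LOD/LOQ censoring, outlier injection) for testing the
  chemometric and risk stages at arbitrary sample sizes.

## Library quick tour

```python
import propolis_risk as pr

samples = pr.build_paper_fixture(seed=1)
pr.detection_frequency(samples, pr.Element.AS)        # 16.67 (%)
pr.screen_sample(samples[5], pr.load_standard("efsa_2020_640"))
pr.correlation_report(samples).pair("Cd", "Mn")
results = pr.assess_dataset(samples)                  # ADD, HQ, CR + labels
```

Censored cells never store a number; they enter computations only through
an explicit substitution policy (`zero`, `half_lod`, `lod`, `half_loq`).
Defaults: `half_loq` for summaries/chemometrics, `zero` for risk.

Three regulatory standards are packaged: `efsa_2020_640` (Cd 0.1 ppm,
Pb 1 ppm, As must be absent, Mn daily-intake bound 3 mg/day),
`iram_inta_15935` (Pb 10 ppm, As 2 ppm) and `nrag_1135` (Pb 2 ppm,
As 1 ppm).

## CLI

```sh
propolis-risk fixture --out samples.csv --seed 1
propolis-risk generate --out synthetic.csv --n 100 --seed 7
propolis-risk qc                               # verdicts for the packaged QC table
propolis-risk screen --input samples.csv --standard efsa_2020_640 --outdir out/
propolis-risk chemometrics --input samples.csv --outdir out/
propolis-risk risk --input samples.csv --outdir out/
propolis-risk all --input samples.csv --outdir out/   # report.json + CSVs
```

`all` writes a versioned `report.json` (validated against the shipped
schema; reruns on identical inputs are bitwise identical) plus
`risk.csv`, `exceedance.csv`, `pca_scores.csv` and `dendrogram.nwk`.
Exposure scenarios are TOML files with keys `ingr`, `ef`, `ed`, `bw`,
`life_expectancy` (defaults: 0.001 kg/day, 90 d/y, 40 y, 75 kg, 75.5 y).

## Notes

- ppm is treated as exactly mg/kg; no density conversion.
- Carcinogenic risk defaults to the conventional CR = ADD × SF; the
  quotient form is available via `carcinogenic_risk(..., formula="divide")`.
- Outlier flagging and the P06/P10 co-clustering check operate on
  covariance-scale (unstandardized) scores/distances, where raw-magnitude
  outliers are separable; standardized PCA/clustering remain the defaults
  for loadings and the reported tree.
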