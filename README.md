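# ctmonitor

Tumor-informed monitoring of circulating tumor DNA (ctDNA) during immune
checkpoint inhibitor (ICI) therapy in advanced lung adenocarcinoma.

A somatic driver mutation found in the pretreatment tissue biopsy (most
often *KRAS*) is tracked in plasma cell-free DNA by droplet digital PCR
(ddPCR) at baseline (t₀) and again at the 4–6-week follow-up (t₁), before
the first radiological evaluation. `ctmonitor` implements the analysis
around that design:

- **Quantification** — droplet counts → Poisson-corrected concentration,
  mutant copies per mL plasma, variant allele fraction, and a three-state
  sample call. With k of N droplets positive, the mean occupancy is
  λ = −ln(1 − k/N) copies per droplet, so concentration = λ/V_d. A sample
  is *positive* at ≥ 3 mutant droplets, *negative* only when < 3 mutant
  droplets coincide with ≥ 330 informative (mutant + wildtype) droplets —
  which bounds the analytical sensitivity at −ln(1 − 3/330) ≈ 0.91% < 1% —
  and *invalid* otherwise.
- **Dynamics classification** — the relative change r = (c₁ − c₀)/c₀ is
  thresholded at 30% (the assay's technical coefficient of variation):
  *decreasing* if r < −0.30, *increasing* if r > +0.30, *stable* if
  |r| ≤ 0.30, *negative* if the mutation is undetectable at both
  timepoints; stricter 40%/50% sweeps are supported.
- **Survival stratification** — Kaplan–Meier curves, log-rank tests,
  univariate Cox hazard ratios (Breslow ties) and durable-clinical-benefit
  (DCB, progression-free ≥ 26 weeks) rates for the four-level categories,
  the binary decrease/no-decrease split, and that split crossed with the
  PD-L1 tumor proportion score (TPS ≥ 1% vs < 1%).
- **Timepoint selection** — scoring of candidate follow-up weeks from
  longitudinal series, accounting for the transient ctDNA spike many
  responders show in the first 1–2 weeks of treatment.
- **Concordance** — Pearson r² and Cohen's κ between two quantification
  platforms on paired samples.
- **Synthetic cohorts** — a seeded generator producing linked droplet,
  trajectory and clinical tables with the statistical structure above, so
  the whole pipeline is testable without patient data.

## Worked example

Simulate a 100-patient cohort and run the full pipeline from the shell:

```sh
ctmonitor --seed 7 --out-dir demo simulate
ctmonitor --out-dir demo quantify demo/droplets.csv
ctmonitor --out-dir demo classify demo/quant.csv
ctmonitor --out-dir demo survival demo/clinical.csv demo/dynamics.csv
ctmonitor --out-dir demo timepoint demo/series.csv
```

With seed 7 this classifies the cohort as 27 decreasing / 7 stable /
35 increasing / 31 ctDNA-negative, and `demo/endpoints.json` reports for
the decrease vs no-decrease comparison (ctDNA-negative patients excluded):

| quantity | decrease | no decrease |
| --- | --- | --- |
| n | 27 | 42 |
| median PFS (weeks) | 61.7 | 5.6 |
| median OS (weeks) | not reached | 28.6 |
| DCB rate | 0.78 | 0.00 |

with PFS hazard ratio 0.27 (95% CI 0.16–0.45) and log-rank p ≈ 3e-12: a
ctDNA decrease at t₁ marks the patients who go on to durable benefit,
while the follow-up step recommends week 6 (the early spike makes weeks
1–2 unreliable). The same stages are available as library calls
(`ctmonitor.quantify_table`, `classify_table`,
`stratified_endpoint_report`, …).

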