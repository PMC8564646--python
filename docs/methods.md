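# Methods

## Quantification model

Droplet digital PCR partitions a 20 µL reaction into roughly 10,000–20,000
droplets of nominal volume V_d = 0.85 nL. Template molecules distribute
over droplets approximately Poisson, so with k of N accepted droplets
positive the per-droplet mean occupancy is λ = −ln(1 − k/N) and the
reaction concentration is λ/V_d copies/µL. Mutant and wildtype channels
are corrected independently with the same formula; no co-packaging
correction is applied, since at the occupancies relevant here (mutant
λ ≪ 1) its effect is negligible. The correction itself matters only above
about 1% occupancy — below that, λ and k/N agree within 1% relative — but
it is applied uniformly.

Copies per mL plasma back-calculates through the volume chain

    copies/mL = conc_rxn × V_rxn × (V_elu / V_in) / V_pl

with defaults V_rxn = 20 µL (reaction), V_elu = 52 µL (cfDNA eluate),
V_in = 13 µL (eluate aliquot in the reaction) and V_pl = 2 mL (plasma
extracted). V_d and V_in are instrument/protocol constants not uniquely
determined by the assay description; both are configurable, and every
downstream decision (classification, survival grouping) is invariant to
them because the 30% rule is scale-free.

Replicate wells are pooled by summing droplet counts before Poisson
correction — the standard merged-well treatment, which weights wells by
their droplet counts and has lower variance than averaging per-well
concentrations.

**Sample calls.** Positive at ≥ 3 mutant droplets; negative only when
< 3 mutant droplets coincide with ≥ 330 informative (mutant-positive +
wildtype-positive) droplets; otherwise invalid. The 3/330 pair fixes the
analytical limit of detection at −ln(1 − 3/330) ≈ 0.913%, i.e. the assay
claims sub-1% sensitivity only when enough informative droplets are seen.
"Informative" counts each droplet once; the input schema has no
double-positive column, so a droplet positive in both channels cannot be
double-counted. Invalid samples propagate as missing — treating them as
negative would fabricate detection limits that were never achieved.

## Dynamics classification

The relative change r = (c₁ − c₀)/c₀ between baseline and the 4–6-week
follow-up is compared with a threshold equal to the assay's replicate
coefficient of variation (30%), so that only changes exceeding technical
noise count: decreasing iff r < −0.30, increasing iff r > +0.30, stable
iff |r| ≤ 0.30 (the boundary is deliberately assigned to stable — a
change *equal* to the technical CV is not evidence of change). Stricter
40%/50% thresholds are available as a sweep; because the decision is a
pointwise comparison of |r| with the threshold, the decreasing (and
increasing) sets at a stricter threshold are always subsets of those at a
looser one.

Edge conventions, each selectable but defaulted as follows:

- negative at both timepoints → *negative* (its own survival stratum);
- negative at t₀, positive at t₁ → *increasing* (new detection);
- positive at t₀, negative at t₁ → *decreasing* with r = −1.0 (a valid
  negative call bounds the t₁ level below the detection limit);
- invalid at either timepoint → excluded, with the reason recorded.

Binary grouping for survival comparisons: *decrease* vs *no decrease*
(increasing + stable), with ctDNA-negative patients either excluded (the
head-to-head comparison) or folded into no-decrease (the PD-L1-stratified
comparison). Both labelings are emitted side by side.

## Survival analysis

PFS and OS run from treatment start, in weeks, right-censored at last
follow-up. Kaplan–Meier estimation and the Mantel–Cox log-rank test are
delegated to `lifelines`; the KM median is the earliest time with
S(t) ≤ 0.5 and is reported as "not reached" when the curve never crosses
0.5. Univariate Cox hazard ratios use the partial likelihood with Breslow
tie handling (adequate at weekly time resolution) via `statsmodels`
PHReg; 95% CI as exp(β ± 1.96·SE). Monotone likelihoods (complete
separation of event times between groups) are returned as flagged
non-convergence, not an exception or a spuriously huge HR.

Durable clinical benefit (DCB) is progression-free survival ≥ 26 weeks.
Patients censored before 26 weeks are *indeterminate* and are excluded
from DCB-rate denominators rather than counted as failures, which would
bias rates downward in cohorts with short follow-up. DCB rates between
groups are compared with the Mann–Whitney U test on the 0/1 benefit
indicators; the U test uses exact enumeration when the pooled sample is
≤ 16 without ties and the tie/continuity-corrected normal approximation
otherwise.

A known small-sample caveat, quantified by the test suite: with ≤ 8
subjects per group the chi-square upper-tail p of the log-rank test can
deviate from the exact label-permutation tail probability by up to about
0.05. This is a property of the asymptotic approximation common to all
standard implementations, not of this one — the statistic itself matches
the defining O−E and hypergeometric-variance sums to numerical precision.

## Concordance

Paired copies/mL from two platforms are summarized by the squared Pearson
correlation, optionally recomputed after excluding pairs above an
explicit copies/mL cutoff (very high-level samples otherwise dominate the
moment sums; the cutoff is configuration, not automated outlier hunting).
Categorical agreement uses Cohen's κ = (p_o − p_e)/(1 − p_e) with chance
agreement from the marginal products, applied by default to the binary
decrease/no-decrease calls (configurable to the four-level categories).
When both raters are constant and identical, p_e = 1 and κ is defined as
1 by convention.

## Timepoint selection

Responders often show a transient ctDNA spike in the first 1–2 weeks of
ICI treatment (tumor DNA released by dying cells), so sampling too early
misreads response as progression. `detect_spike` flags any observation
within the spike window (default 2 weeks) exceeding baseline by more
than the change threshold. Candidate follow-up weeks (default 1, 2, 4, 6)
are scored by applying the change rule between baseline and the
observation nearest each candidate week (within ±1 week; distance ties
break to the earlier sample); the score is the sum of the responder
fraction called decreasing and the non-responder fraction called
non-decreasing, and the recommended week is the earliest maximizer.
"Responder" defaults to the durable-benefit flag, switchable to RECIST
best response.

## Synthetic cohorts

The generator produces what the analysis consumes — droplet tables,
weekly trajectories, and a clinical table — from a few interpretable
knobs, with every draw funneled through seeds derived from one
`SeedSequence` (identical seeds ⇒ byte-identical tables).

- **Archetype mix** (CR 5%, PR 25%, SD 14%, PD 25%, ctDNA-negative 31%):
  roughly 30% responders and 31% of patients with the tissue mutation
  undetectable in baseline plasma, the fractions typical of single-locus
  tumor-informed assays in metastatic NSCLC.
- **Baseline** mutant load lognormal, ln-mean ln(200) copies/mL, ln-sd
  1.2. The spread spans ~10–5,000 copies/mL; the lower tail is kept above
  the ~10 copies/mL effective detection limit so that baseline negativity
  is governed by the archetype, not by sampling accidents.
- **Kinetics**, multiplicative per week — the simplest form consistent
  with the observed patterns: responders spike ×2 at week 1 with
  probability 0.7 then decay (CR ×0.50/week, clearing below the detection
  limit; PR ×0.65/week), SD flat, PD grows ×1.2/week. Every observation
  is multiplied by lognormal noise with CV 0.30, the assay's replicate
  variability. Under these settings roughly 70–90% of responders show a
  > 30% decrease at weeks 4–6 while most do not yet at week 1 — the
  regime in which the timepoint question is non-trivial.
- **Survival**: exponential PFS with archetype medians 60/43/8/5/20 weeks
  (CR/PR/SD/PD/negative), OS = PFS plus an independent exponential
  remainder targeting medians 150/125/30/25/60 weeks, administrative
  censoring at week 160. The negative-archetype medians sit between the
  responder and non-responder groups (mostly early progression but
  markedly better OS than the increasing/stable group).
- **PD-L1 TPS** drawn independently of dynamics (34% < 1%, 17% 1–49%,
  35% ≥ 50%, 14% unavailable) — the two markers behave as independent
  biomarkers; a dependence knob exists for sensitivity analyses and is
  off by default.
- **Sampling** at weeks 0, 1, 2, 4, 6, then every 6 weeks to week 24; the
  t₁ droplet sample is drawn at week 4 or 6 per patient. Wildtype
  background is lognormal around 2,500 copies/mL, high enough that
  negative calls almost always reach the 330-informative-droplet bar
  (a few percent of samples fail it and exercise the invalid path).

What the generator does *not* emulate: pre-analytical effects (tube
type, processing delay, extraction efficiency), clonal hematopoiesis
false positives, inter-assay differences between mutation targets,
non-exponential hazards, and dependence between ctDNA kinetics and
censoring. Passing tests therefore demonstrate that the pipeline
recovers planted structure under its own model assumptions — not that
those assumptions hold in any given clinical cohort.

## Numerical and scale choices

Poisson correction uses `log1p` for accuracy at low occupancy; saturation
(k = N) raises a dedicated error rather than returning infinity. The
classifier compares floats directly — the boundary convention (≤) is
exact for the representable threshold values used. The end-to-end
reproduction check runs 100 seeded cohorts of 200 patients (about half a
minute), large enough that the planted decrease/no-decrease separation
is essentially always recovered while keeping the default suite quick;
estimator-recovery checks use 200 replicate wells of 15,000 droplets at
three loads spanning 1–1,000 copies/mL plasma.
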