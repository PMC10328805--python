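# Methods

`glycopipe` implements a genetically supported drug-repurposing pipeline for
glycemic control: candidate discovery from transcriptome-wide association
results, observational validation with a self-controlled case series (SCCS)
over EHR-style tables, cross-site random-effects meta-analysis, and
two-sample Mendelian randomization (MR) with tissue-level genetically
predicted gene expression (GPGE) as the instrument. This note records the
models, conventions and design choices; nothing here states a result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Candidate discovery

A gene × tissue TWAS table (columns `gene_id, tissue, beta, p, pp_h4`) is
filtered to genes whose minimum p across tissues is ≤ 1.92×10⁻⁷ *and* whose
maximum colocalization posterior PP.H4 across tissues is ≥ 0.8. The GPGE
effect sign per SD of predicted expression is taken from the minimum-p
tissue; ties break by larger |β|, then lexicographic tissue label, making
the selection order-invariant. The min-p rule is a declared convention —
with 52 tissues a gene can show conflicting signs, and no aggregation rule
is canonical; this one is deterministic and auditable.

Surviving genes are joined to a drug–gene interaction catalog. Mechanism
labels are normalized onto a closed vocabulary (agonist, activator,
antagonist, inhibitor, blocker, other) through an editable synonym map
(`data/action_synonyms.csv`). The direction-of-effect rule keeps a pair when
the drug pushes target activity in the risk-lowering direction: sign −1
(more expression, less risk) requires agonist/activator; sign +1 requires
antagonist/inhibitor/blocker; `other` never qualifies. A drug is a candidate
if at least one of its pairs is concordant; discordant pairs are retained
with `concordant=False` for audit. Drugs already used in diabetes management
are removed before any counting. The summary's targeted-gene percentage is
reported truncated to one decimal (`targeted_gene_percentage`), matching the
convention of the source counts it reproduces; full precision is available
from the raw counts in the same summary.

## Self-controlled case series

Each patient serves as their own control. Time is integer day offsets from
an arbitrary origin; "six months" is fixed at 180 days and "nine months" at
270 days everywhere, since calendar months are not well defined for day
arithmetic and both sites must be comparable.

* **Index date** t0: earliest prescription/mention of the series drug.
* **Exclusion screen**: any event for a drug from one of the *other* two
  medication groups (experimental / glucose-decreasing / glucose-increasing)
  on or before t0, or within `(t0, t0+180]`, removes the patient.
  Same-group co-prescription never excludes. "Simultaneously at t0" is read
  as same calendar day; the "ever before" lookback is unbounded within the
  supplied extract.
* **Persistence**, two site dialects: `fills` (pharmacy-complete EHR)
  requires ≥1 refill in `(t0, t0+180]` *and* ≥90 days cumulative
  days-supply over fills in `[t0, t0+180]` (the cumulative sum is
  restricted to the window — the unrestricted reading is defensible but the
  restricted one is stricter and self-consistent); `mentions`
  (pharmacy-incomplete EHR) requires ≥2 mentions in `[t0, t0+180]`, the
  initial mention counting as one.
* **Lab QC**: outpatient rows only; HbA1c kept in [3, 18] % and glucose in
  [5, 2750] mg/dL — bounds inclusive because the exclusions are strict
  inequalities. With the pregnancy screen on (default only for the
  `mentions` dialect, mirroring a discovery population that is >90% male),
  any lab within 270 days of a pregnancy event for the same patient is
  dropped.
* **Outcomes**: HbA1c baseline is the most recent measure in `[t0−180, t0)`
  (half-open: a same-day lab may already reflect treatment) and follow-up
  the first measure in `(t0+30, t0+180]` ("after 30 days" read strictly);
  glucose uses the mean of all measures in `[t0−180, t0)` and `(t0, t0+180]`
  respectively. Two qualifying measures on the same day are averaged, so
  record order never matters. Patients missing either window are absent, not
  errors.
* **Suppression**: a series with fewer than `min_n` (default 30) cases is
  flagged and emptied rather than emitted.

## Inference

Per drug and site, within-patient changes Δ = follow-up − baseline are
tested with a paired t-test: t = Δ̄/(s/√n), df = n−1, two-sided p, 95% CI
from the same t quantile. A zero-variance sample with nonzero mean reports
p = 0 with an explicit flag.

Published site rows carry a mean and 95% CI; the SE is reconstructed as
(CI width)/(2q), with q the t quantile at n−1 df by default (the rows come
from paired t-tests) or the normal 1.96 under a sensitivity flag. A CI whose
midpoint strays from the mean triggers a warning, since the reconstruction
assumes symmetry.

Pooling uses DerSimonian–Laird random effects: fixed weights w = se⁻²,
Q = Σw(θ−θ̄_FE)², τ² = max(0, (Q−(k−1))/(Σw−Σw²/Σw)), RE weights
1/(se²+τ²), normal-quantile CI and p. k = 1 passes through. The estimator
choice is declared in output metadata; the implementation is validated
against an independent brute-force transcription of the formulas on random
instances to 1e-10 relative tolerance.

Dual-site evidence classification: for a chosen direction and α = 0.05
(two-sided throughout; α is not stated by convention in the source tables
but matches their narrative counts), a drug is `both_sites` when the mean
change has the requested sign and p < α at discovery *and* replication;
`discovery_only` / `replication_only` / `neither` follow analogously. Drugs
missing a site row are skipped with a warning.

Class-level meta-analysis pools all site × drug rows sharing a
pharmacological class (packaged map `data/medication_groups.csv`, editable).
The published class-level pooled numbers are deliberately not reproduction
targets: they cannot be recovered from the two printed site rows alone under
standard DL, implying additional strata entered the published pools.

## Mendelian randomization

For one gene, tissues with a significant indication-side GPGE association
(p < 0.05; exposure side only by default, T2D-side filtering available as a
sensitivity flag) form the instrument set. The IVW estimator is

    β̂ = Σᵢ βtrait,i βT2D,i σᵢ⁻² / Σᵢ β²trait,i σᵢ⁻² ,
    se(β̂) = (Σᵢ β²trait,i σᵢ⁻²)^(−1/2) ,

with σᵢ the T2D-side SE — algebraically the no-intercept weighted-regression
slope of outcome on exposure betas, which the tests verify numerically. ORs
and CIs are exp-transformed with normal quantiles; all MR z-tests use the
normal reference distribution, the standard convention for two-sample MR
summary statistics. Egger regression frees the intercept (weighted least
squares, weights σ⁻², fixed-weight covariance, normal p for the intercept)
and needs ≥3 tissues; MVMR regresses the outcome betas jointly on several
exposures' tissue-level betas without intercept (tissue-level joint
regression, rather than regressing on per-trait summaries, keeps the
per-tissue weighting); an all-zero exposure is uninformative and is dropped
from the design with a null estimate rather than raising the collinearity
error. The negative control runs IVW against an outcome the exposures
should not affect and flags p < 0.05 as a bias signal.

Known limitation, reproduced as printed: GPGE instruments for one gene are
correlated across tissues, and the estimator treats them as independent, so
its SE is anti-conservative to a degree that grows with cross-tissue
correlation. Matching is exact on gene × tissue labels; unmatched tissues
are dropped.

## Synthetic data

The generator emulates the structure of the study inputs, not their
content:

* **TWAS catalog**: an exact, seeded fraction of genes is built to pass both
  discovery filters; the rest fail p, colocalization, or both. Truth records
  the designed set and each significant gene's sign at its min-p tissue.
* **Drug catalog**: each drug targets a random significant gene; a seeded
  fraction receives a direction-concordant action, the rest a discordant or
  uninformative one; a sub-fraction of concordant drugs is tagged as
  existing diabetes medications to exercise that exclusion; some pairs are
  duplicated under a second source database to exercise set semantics.
* **EHR**: per patient, one series drug (round-robin so every drug appears),
  t0 ≥ 180 days from either end of a 900-day span, lab times from a
  homogeneous Poisson process (rate 3 per 180 days per analyte — lab
  frequency is unreported for either source system, so this is a free
  modelling choice), values = patient baseline (HbA1c 7.0 ± 0.8 %, glucose
  140 ± 25 mg/dL) + injected drug effect after an onset lag (30 days for
  HbA1c, matching the follow-up blank; 0 for glucose) + Gaussian noise
  (0.3 % / 20 mg/dL). 85% of patients are persistent (refills/mentions per
  dialect), 10% receive an other-group contaminant uniformly before/at/after
  t0, 2% have a pregnancy event, 10% of labs are inpatient, 1% are
  non-physiologic outliers, and 5% of patients lose their pre-t0 labs —
  each nuisance exercises one screen. Injected effects: −0.5 % / −10 mg/dL
  (experimental), −1.0 % / −30 mg/dL (glucose-decreasing), +0.3 % / +5 mg/dL
  (glucose-increasing) — magnitudes in the range the site tables display for
  those groups.
* **GPGE summaries**: trait-side betas N(0.5, 0.2²) with SE 0.05; outcome
  betas θ·βtrait + α + N(0, se²) with θ = −0.2 by default; the negative
  control uses θ = α = 0.

What passing tests show — and do not show — about real data: the generator
has additive, homogeneous, instantaneous-after-lag drug effects,
uncorrelated tissues, no confounding by indication, no adherence decay, no
dose titration and no secular trends. Recovery under these conditions
validates the *machinery* (windows, screens, estimators, plumbing), not
robustness to the violations real EHRs exhibit; the SCCS design itself
remains vulnerable to time-varying confounding that the synthetic model does
not emulate.

## Numerical and reporting conventions

Computation is at full precision; rounding (changes and CIs to 4 decimals,
p to 4) happens only in the reporting layer (`emit_tables`), with a stable
sort (group, discovery p, drug). Every CLI run writes a manifest with
parameters, derived per-stage seeds (SHA-256 of `seed:stage`, kept below
2³¹) and SHA-256 checksums of outputs; reruns with identical configuration
reproduce identical checksums. Exit codes: 0 success, 2 validation, 3
missing upstream artifact, 4 data quality (e.g. all series suppressed).

Problem sizes used by the verification suites: 200 SCCS replicates of 500
patients for CI coverage of the injected HbA1c effect; 500 IVW replicates
(10 tissues) for bias and coverage; 1,000 Egger replicates for type-I error;
1,000 random instances for each estimator-vs-oracle identity. These sizes
give binomial standard errors comfortably inside the asserted bands while
keeping the default suite fast.
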