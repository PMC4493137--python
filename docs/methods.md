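# Methods

## The setting

A phenotyping screen compares two genotype groups — a reference line and a
test (mutant) line — on one measured variable at a time. Screens run for
months: controls accumulate across many assay days while mutant cohorts are
small (often 3–10 animals) and concentrated in a few days. A **batch** is
the set of readings taken on the same day; batch identifiers are treated as
opaque labels, compared only for equality, because dates arrive in
arbitrary formats and assay days carry no meaningful order for analysis.
Sex and body weight are the other dominant sources of variation. Every
framework in the package is a different answer to the question "how should
batch variation be handled given this design?".

## Dataset layer

`build_phenlist` turns a raw delimited table into the validated
two-genotype dataset all frameworks consume. Choices made here:

* **Terminology.** A default synonym map translates Gender→Sex,
  Assay.Date/Assay_Date/Date→Batch, Body.Weight/BodyWeight→Weight
  (case-insensitive), extensible via config. Sex labels M/F/Male/Female are
  normalised case-insensitively to male/female; anything else becomes
  missing and the row is dropped (and logged), because every analysis is
  sex-stratified and needs a binary, known sex.
* **Variable kind.** A column is continuous when ≥ 95% of its non-missing
  values parse as numbers, else categorical; an explicit override always
  wins. The 95% tolerance admits occasional typed artefacts ("<LOD")
  without reclassifying a numeric column.
* **Missing weight never drops a row at build time.** Weight is desirable
  but not required; only weight-including model fits exclude such rows (the
  fitted `n_used` is reported so with/without-weight comparisons are
  transparent).
* **Cleaning is conservative and fully logged**: row counts for every
  removal (missing genotype/sex, other genotypes) are appended to the
  cleaning log, which is carried into every result and serialisation.

## Mixed-model framework

Model: `y = Genotype + Sex + Genotype×Sex [+ Weight] + (1|Batch) + ε`,
batch intercepts i.i.d. normal, residuals normal with either a shared
variance or one variance per genotype group. Treatment coding with the
reference genotype and female sex as baselines, so the Genotype coefficient
is the female effect and Genotype + Genotype×Sex the male effect, both
reported test-minus-reference in response units.

**Fitting.** The engine profiles fixed effects out by generalised least
squares and optimises the remaining 1–3 variance parameters numerically
(L-BFGS-B on variances scaled by the OLS residual variance, zero lower
bound for the batch variance; Nelder–Mead fallback; relative tolerance
1e-8, 200 iterations; non-convergence raises, it is never silently
accepted). Each batch's marginal covariance is a rank-one update of a
diagonal, so Sherman–Morrison gives the blockwise inverse and determinant
in closed form, vectorised over batches. The homogeneous no-batch case is
solved in closed form (OLS). Against statsmodels `MixedLM` on homogeneous
random-intercept problems the log-likelihoods agree to ~1e-4 and
coefficients to ~1e-4 relative (see tests); the engine exists because the
per-genotype residual-variance structure is outside `MixedLM`'s scope.

**Top-down optimisation.** In order: (1) random batch term kept iff the
REML likelihood-ratio test retains it, using the equal mixture of χ²₀ and
χ²₁ as the reference distribution because the null pins the variance to the
boundary of its space; (2) residual structure chosen by REML LRT of shared
vs per-genotype variance (χ²₁); (3) Genotype×Sex dropped iff its ML LRT
p > 0.05; (4) Weight dropped iff its ML LRT p > 0.05. Sex is retained
whenever both sexes are present; Genotype is always retained so the final
test is defined. REML likelihoods are compared only between models sharing
fixed effects; fixed-term LRTs use ML — mixing objectives raises an error
by construction. α = 0.05 at every decision point.

**Genotype test and classification.** The final model is compared by ML LRT
against the same model with every genotype term removed (df = number of
terms removed). Per-sex effects ± SE come from the final REML coefficient
covariance. The classification tag is drawn from a closed set: not
significant; both sexes equally (interaction absent); with an interaction,
per-sex Wald tests at α separate male only / female only / different
directions, and otherwise magnitudes are compared (different sizes — males
or females greater).

**A deliberate property worth knowing.** Because the interaction is
selected at α = 0.05 and the final test then includes it (df = 2), the
end-to-end pipeline is anti-conservative under the global null: the
interaction survives selection ~5% of the time and those replicates
usually reject. Simulation (see `calibration.mm_type1`) puts the pipeline's
type-I error near 0.08–0.12 depending on design, while the same genotype
test without the selection branch is calibrated at ~0.05. A further
contribution arises when batch variation is too small for the boundary LRT
to detect yet the mutants sit in very few batches: the correlation is then
ignored and the genotype SE understated — precisely the failure mode that
motivates modelling batch in the first place. The decision tree is kept as
specified because it is the procedure screens actually run; the calibration
module quantifies the cost rather than hiding it.

## Time-as-fixed-effect framework

For concurrent designs, batch enters as dummy-coded fixed effects
(first batch as baseline). "Concurrent" means the same batch identifier,
exactly — no date-window widening, since equality-of-day is the definition
of a batch. The reduction keeps batches containing at least one treated and
one control animal with a usable response; everything else is removed and
itemised (control-only rows, orphan treated rows, unusable rows). The
framework accepts 2–5 treated batches: below 2 batch and genotype are
inseparable; above 5 the mixed model is the right tool and the refusal says
so. The optimisation mirrors the mixed-model tree with the random-effect
test replaced by an ML LRT on the batch fixed effect (df = batches − 1);
the batch term may be dropped when non-significant. A single shared batch
after reduction is unidentifiable and excluded with a note.

## Reference-range framework

Thresholds are the (1−p)/2 and 1−(1−p)/2 quantiles of the control values
(default p = 0.95), computed with linear interpolation between order
statistics — the numpy default estimator, declared so small count
differences against other quantile conventions can be reconciled.
Comparisons at the thresholds are strict (a value equal to a threshold is
Normal), keeping the control extreme fraction at or below 1 − p. Thresholds
are computed per sex when every present sex has at least 60 usable
controls; otherwise combined-sex thresholds are used everywhere and
flagged. The floor of 60 keeps the 2.5th/97.5th percentiles inside the
data with some margin; the suitability check applies it to the pooled
control count so that e.g. a 100-control single-batch design remains
analysable (with the combined-sex fallback). Both tails are always tested
— the "majority outside the range" idea motivates the method but inference
is delegated to the exact test — and p = 1.0 is returned with a warning
for uninformative (zero-margin) tables. No batch adjustment is attempted:
the method exists for designs where a batch model cannot be fitted.

## Exact tests

2×2 tables use the classical two-sided rule: sum the probabilities of all
tables with the observed margins whose point probability does not exceed
the observed table's (with a 1e-7 relative tie tolerance). r×c tables use
the Freeman–Halton generalisation: the number of tables sharing the margins
is counted exactly by a memoised recursion, full enumeration is used up to
2×10⁵ tables, and beyond that a Monte Carlo estimate with 2×10⁵ draws from
the fixed-margin distribution (seeded, default 20150706, reported as
(hits+1)/(draws+1)). The enumeration bound is set where pure-Python
enumeration stays fast; the Monte Carlo path agrees with enumeration within
three binomial standard errors where both run. No multiple-testing
correction is applied across sexes or tails — every p-value is reported
raw, matching per-sex reporting practice. The effect size is always a
difference in proportions (penetrance change), not an odds ratio.

## Synthetic data

The generator emulates the structure the frameworks assume, not any
particular assay's biology: response = baseline + sex effect + per-sex
genotype effect + weight slope × centred weight + batch draw + residual,
with weight generated per sex (heavier males: means 300/200, SDs 30/20 —
rat-scale grams), normal batch effects, and per-genotype residual SDs for
heterogeneous scenarios. Categorical phenotypes draw each animal's category
from a per-genotype rate vector (defaults: 2% abnormal controls, 40%
abnormal mutants — a rare-event classification with a strong mutant
signal). Three named designs fix the batch-membership pattern:
`multi_batch_mm` (controls over 20 batches, mutants concentrated in 2 of
their own — no concurrency), `concurrent_tf` (every treated batch has
controls, plus control-only batches), `one_batch_rr` (one batch, large
control pool, few mutants). Defaults: 70 controls and 7 mutants per sex,
baseline 50, sex effect 10, genotype effects −25 (male) / −15 (female),
batch SD 5, residual SD 8. A single integer seed determines every draw,
and the truth record carries every realised parameter (including the
per-batch effects) so recovery tests never re-derive truth from data.
Passing tests on these data demonstrate correctness of the machinery under
the generating model — normal, additive, missing-completely-at-random —
and say nothing about robustness to skewed responses, outliers, or
batch-confounded husbandry effects in real screens.

## Calibration studies

`phenokit.calibration` holds the self-contained experiments rerun by
`scripts/acceptance.py` and the acceptance tests, with sizes chosen for a
single CPU:

* exact-test sweep: every 2×2 table with all margins ≤ 12 (5238 tables)
  against an independent hypergeometric enumeration;
* type-I: 2000 null replicates of a scaled multi-batch screen (118 male /
  29 female controls over 43 / 5 batches, 10+10 mutants in 2 batches per
  sex, batch SD 2, residual SD 8.5) through the full pipeline;
* recovery: 500 replicates at n = 300 (75 per cell, 15 shared batches,
  batch SD 5, residual SD 8, effects −25/−15), full-model fits, mean
  per-sex estimates vs truth on the 3-standard-error scale;
* degenerate batch: replicates generated with batch SD 0; every fit whose
  REML batch variance lands on the zero boundary must match an independent
  least-squares solution to 1e-6 relative (observed ~1e-13);
* structural checks: the concurrent reduction must remove exactly the
  control-only and orphan-treated batches of constructed designs, and
  reference-range classification must conserve counts and be invariant to
  shifting all measurements by a constant.

## Known limitations

* No response transformation (e.g. Box–Cox) and no covariates beyond sex,
  weight and batch; litter, cage and operator effects are subsumed into
  batch by assumption.
* χ²-based LRTs are asymptotic; with very few mutant batches the effective
  degrees of freedom for the genotype contrast are small and no
  small-sample correction (Satterthwaite/Kenward–Roger) is applied.
* The dimorphism classification is only available for continuous
  variables; categorical analyses report per-sex tests without a
  dimorphism call.
* Reference-range thresholds are plain quantiles — no robust or trimmed
  variants — and the method ignores batch entirely.
* The vector-output schema (version 1) is fixed and method-independent;
  new fields require a schema version bump.
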