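# phenokit

Statistical analysis of high-throughput animal phenotyping data.

Large phenotyping screens compare a mutant (e.g. knockout) line against a
reference line, one measured variable at a time, with a handful of mutant
animals set against a large rolling pool of controls. The dominant nuisance
in such screens is **batch** — the set of readings collected on the same
assay day — together with sex and body weight. phenokit provides four
statistical frameworks tailored to the experimental designs these screens
actually use, plus the dataset checking, method recommendation,
sexual-dimorphism classification and fixed-schema output needed to run them
reproducibly at scale.

## The frameworks

**Mixed model (MM)** — for continuous variables measured over multiple
batches (no concurrency required). The start model is

    y = Genotype + Sex + Genotype×Sex [+ Weight] + (1 | Batch) + ε

with a normally distributed random batch intercept and optionally
genotype-specific residual variances. A top-down optimisation fixes the
structure before testing: the random batch term is kept only if a
boundary-corrected REML likelihood-ratio test retains it (otherwise the
model collapses to a linear model), residual-variance homogeneity is chosen
by REML LRT, and the Genotype×Sex interaction and weight covariate are
dropped when non-significant (ML LRT, α = 0.05 throughout). Genotype is
then tested by an ML likelihood ratio removing every genotype term from the
final model; per-sex effects ± SE come from the final REML fit, and the
effect is classified into a closed tag set ("both sexes equally",
"male only", "different directions", …).

**Time as fixed effect (TF)** — for concurrent-control designs with 2–5
batches of treated animals: batch enters as a fixed effect so each batch
offset is estimated explicitly. A reduction step (`tf_dataset`) first
removes control-only batches and treated records lacking concurrent
controls, reporting the impact.

**Reference range plus (RR)** — a conservative method for one-batch or
low-n designs: the central 95% (configurable) of the control distribution
defines Low/Normal/High thresholds per sex; each tail is tested with a
Fisher exact test of the (tail vs rest) × (control, mutant) table, and the
effect size is the **change in penetrance** (mutant minus control tail
proportion).

**Fisher exact (FE)** — for categorical (mostly rare-event) variables:
category proportions compared between genotypes per sex and combined,
pooling all control data and ignoring batch. 2×2 tables use the classical
probability-ordering two-sided rule; r×c tables use the Freeman–Halton
generalisation (full enumeration, or seeded Monte Carlo for large tables).

`recommend_method` runs every framework's suitability checks (variable
kind, variability, batch coverage, concurrency, control-pool size) and
returns the frameworks that apply, in preference order.

## Worked example

Simulate a multi-batch screen (140 controls over 20 batches, 14 mutants in
2 separate batches, batch SD 5, residual SD 8, per-sex genotype effects
−25/−15) and analyse it:

```sh
$ phenokit simulate --design multi_batch_mm --seed 42 --out screen.csv --truth truth.json
154 rows written to screen.csv

$ phenokit recommend --input screen.csv --dep-var response \
    --test-genotype mutant --ref-genotype control
MM and RR

$ phenokit analyse --input screen.csv --dep-var response \
    --test-genotype mutant --ref-genotype control --method MM --out-dir out
phenokit v0.1.0 — MM analysis of 'response'
genotypes: mutant (test) vs control (reference)

Animals analysed (non-missing response):
  control: 70 male, 70 female
  mutant: 7 male, 7 female

Model optimisation:
  batch effect: significant, kept (p = 9.13e-06)
  residual variance: homogeneous (p = 0.895)
  genotype-by-sex interaction: kept (p = 0.0137)

Genotype test: p = 1.18e-06
  male effect: -29 ± 4.69 (test − reference)
  female effect: -18.1 ± 4.69 (test − reference)
  classification: different sizes — males greater
```

The optimisation correctly keeps the random batch term and the interaction,
the genotype test is decisive, and the per-sex estimates bracket the
generating effects (−25 male, −15 female) within their standard errors. The
same numbers are written to `out/MM_response.vector.json` — the strictly
defined, method-independent record (every field present for every method,
inapplicable entries null) that database pipelines can load directly.

The same flow works from Python:

```python
import phenokit as pk

pl, truth = pk.synthetic_phenlist()          # or build_phenlist(load_table("my.csv"), ...)
pk.recommend_method(pl, "response")          # ['MM', 'RR']
res = pk.mm_analyse(pl, "response")
print(pk.summary_output(res))
vec = pk.vector_output(res)
```

Exploratory and diagnostic figures (genotype×sex boxplots, per-batch
scatter, per-genotype residual Q–Q, weight scatter with regression and
lowess lines) are available via `phenokit plot` or `phenokit.plots`.

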