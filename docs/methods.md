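# Methods

## Problem and model

Plasma cell-free DNA (cfDNA) carries somatic variants from two main
compartments: the tumor, and blood stem-cell clones (clonal hematopoiesis,
CH). Without matched white-blood-cell sequencing the two are easily
confused, which inflates false positives in liquid-biopsy assays. `metach`
scores each observed cfDNA variant with the probability that it is
CH-derived, using a three-stage architecture:

1. **Self-supervised representations.** Each variant is a bag of discrete
   tokens: overlapping 2–5-mers of an alt-centered 21-character sequence
   context, a variant-identity token, a gene token, and (training only) a
   cancer-type token. A contrastive margin-ranking objective over patients'
   bags of variants yields variant embeddings `Ev` (128-d). Independently, a
   Continuous Bag-of-Mutated-Genes model (CBOW with negative sampling over
   per-patient gene sets) yields gene embeddings `Eg` (8-d). Patient-level
   embeddings `Epv` and `Epg` are plain means over a patient's variants and
   genes. A fixed 37-channel block of functional-prediction scores `Ef`
   (deleteriousness-style annotations for non-synonymous variants) completes
   the representation.
2. **Base classifiers.** Three gradient-boosted binary classifiers:
   the *cfDNA-based* classifier on `Ev ⊕ Eg ⊕ Epv ⊕ Epg ⊕ Ef ⊕ VAF ⊕ Ct`
   (CH vs tumor, on cfDNA-style data), and two *sequence-based* classifiers
   on `Ev ⊕ Eg ⊕ Ef ⊕ Ct` trained on deduplicated three-class data
   (CH-oncogenic vs rest; CH-non-oncogenic vs rest). Each produces a
   probability of blood origin: `S_cfDNA`, `S_Sequence1`, `S_Sequence2`.
3. **Stacking.** An unregularized logistic regression on the three scores:
   `S_Meta = σ(α·S_cfDNA + β·S_Sequence1 + γ·S_Sequence2 + b)`, trained on
   *out-of-fold* `S_cfDNA` (each variant scored only by fold models that
   never saw it) and evaluated on the exact fold assignments recorded by the
   cfDNA classifier, so no stage sees its own training predictions.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| context window | 10 bp each side + alt allele (21 chars for SNVs) | the alt base is what distinguishes the variant; flank-only windows would collapse ref→A and ref→T |
| k-mer sizes | 2–5 | longer k-mers memorize, shorter ones lose the substitution signal |
| `Ev` dim / epochs / lr / margin / negatives / min-count | 128 / 5 / 0.05 (linear decay) / 0.05 / 10 / 2 | StarSpace-style defaults; min-count 2 deliberately drops singleton variant-identity tokens so inference generalizes through k-mer and gene tokens |
| `Eg` dim / epochs / lr / negatives / negative power | 8 / 20 / 0.025 / 5 / 0.75 | word2vec-style settings scaled to small vocabularies; `Eg` is the input-vector table |
| `Ef` channels | 37 | fixed-width block; per-channel **training** medians fill missing cells and whole unannotated variants (no missingness indicators, keeping the width fixed) |
| GBM grid | lr {0.1} × trees {50, 150} × depth {3, 6} | small deterministic grid selected by pooled out-of-fold auPR; a reproducible alternative to time-budgeted AutoML |
| CV | stratified 5-fold | cfDNA folds are additionally grouped by patient, because `Epv`/`Epg` would leak patient identity across folds; sequence folds are stratified on the three-class label and shared by both sequence models |
| class imbalance | inverse-frequency class weights | keeps out-of-fold probabilities interpretable (no resampling) |
| meta stage | logistic regression, no penalty, raw probabilities | three features need no regularization; the link operates on scores directly |

Indels: insertions embed the full alt sequence between the flanks;
deletions omit the deleted span (the context reads like the altered
molecule). Windows truncate at contig ends (never padded) and are flagged.
Cancer types unseen at inference map to a dedicated UNKNOWN one-hot slot;
missing VAF takes the training median.

## Evaluation battery

* **auROC** is the Mann–Whitney U statistic normalized by `n_pos · n_neg`,
  ties counted one half.
* **auPR** is average precision with tied scores processed as one block —
  the step-wise integral, not trapezoidal PR interpolation, because it is
  conservative and exactly reproducible by a brute-force staircase oracle.
* **Grouped permutation importance** (the per-feature-group analysis):
  baseline auPR computed once; each group's columns shuffled jointly across
  rows, 30 seeded repeats; mean and standard deviation of the auPR drop per
  group. Importance should be measured on data the model was not fit on:
  a boosted model memorizes even pure-noise training data, so in-sample
  importances reflect memorization rather than association (the null
  calibration checks do exactly this split).
* **Subset analyses**: metrics inside vs outside a gene set (canonical CH
  genes DNMT3A/TET2/ASXL1, or a panel list); single-class strata are flagged
  not-computable rather than raising.

## Synthetic cohort generator

The generator emulates the statistical structure the method assumes, so the
whole stack is testable at desk scale:

* patients as bags of variants (negative-binomial counts, mean 8,
  dispersion 8, over 400 patients by default);
* three variant classes mixed 0.40 / 0.35 / 0.25
  (tumor / CH-oncogenic / CH-non-oncogenic), i.e. roughly one third tumor —
  the balance typical of matched-WBC-annotated cfDNA cohorts;
* a **patient-level class propensity**: each patient's class mixture is a
  Dirichlet draw around the cohort mix (concentration 1.0). This is the
  design decision that makes the contrastive objective recover class
  structure: real training corpora are CH-heavy (blood cohorts) or
  tumor-only (tumor panels), so within-patient co-occurrence genuinely
  carries origin signal. With concentration → ∞ patients become identical
  mixtures and co-occurrence carries no class information;
* per-class trinucleotide-substitution signatures (smoking-like C>A for
  tumor, aging-like C>T-at-CpG for CH-oncogenic, clock-like T>C for
  CH-non-oncogenic), written into per-gene synthetic contigs so that
  context extraction from the emitted FASTA reproduces each variant's
  context exactly;
* per-class gene-usage weights with patient-level co-occurrence modules
  (an active module multiplies its member genes' weights), giving the gene
  embedder a recoverable structure;
* per-class Beta VAF models (tumor mean ≈ 0.17; CH ≈ 0.03–0.05, reflecting
  the low clonal fractions of CH in plasma);
* a 37-channel functional-score block with class-dependent means, 20 %
  cell-level missingness and 10 % whole-variant dropout (mimicking
  synonymous/non-coding variants that receive no annotation).

What it does **not** emulate: real human coordinates, germline variation,
sequencing error, panel footprints, read-level properties, or the
between-cohort batch effects of real external validation sets. Passing the
synthetic recovery tests therefore demonstrates that the machinery learns
and stacks the intended signals under its own assumptions — not that the
paper-scale external-validation performance would be reproduced on real
cohorts.

Test fixtures use two deliberate variations of the default conditions:
a *two-signature* configuration (two classes, near-pure patients,
concentration 0.25) for embedding-geometry checks, and a *gene-driven*
configuration where class signatures/VAFs overlap substantially and CH is
concentrated in the three canonical genes, so that removing those genes
measurably lowers auROC while the remaining variants stay classifiable —
the desk-scale analog of the canonical-CH-gene removal analysis.

## Problem sizes and numerical choices

End-to-end checks run at ≈400 patients / ≈3,000 variants with a 70/30
patient-level split; stacking-dominance checks use five cohorts of 150
patients; null-calibration checks use n = 2,000 with labels independent of
features. Embedding training in multi-cohort tests uses 3 epochs (the
objective is close to converged on these cohort sizes). All randomness
flows from explicit seeds; one run seed fans out to per-stage seeds via a
CRC32 hash of the stage name, so stages are independently reproducible and
two runs with the same seed produce byte-identical artifacts. Zero-norm
bag embeddings are skipped during contrastive updates; sigmoid arguments
are clipped to ±30 in the CBOW objective; duplicate survivors and tie
handling are first-occurrence / deterministic throughout.

## Known limitations

* The contrastive and CBOW trainers are plain-NumPy SGD: appropriate for
  desk-scale cohorts (10³–10⁴ variants), not for pan-cancer corpora.
* Out-of-fold grid selection reuses the same folds that produce the
  out-of-fold scores, a mild optimism shared by any CV-selected stacker.
* Probabilities are the GBM's native outputs; no post-hoc calibration.
* Sequence-classifier folds are stratified but not patient-grouped (their
  feature set contains no patient-level blocks); the cfDNA folds are
  patient-grouped.
* No bootstrap confidence intervals or significance tests on metric
  differences.
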