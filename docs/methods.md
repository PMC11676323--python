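# Methods

## Model

The network maps a species relative-abundance vector `x` (composition,
renormalised to sum to one) to five outputs.

**Trunk.** `h = ReLU((W ⊙ M)ᵀ x + b)` where `M` is a binary
species × hidden-node mask frozen at construction time. Hidden nodes are
named entities: per metabolite one production node (connected to producer
species) and one consumption node (consumers); one node per genus; one node
per community. Species unmapped in a knowledge source share a per-source
catch-all node, which guarantees every species at least one connection
while keeping the layer sparse. Node order is deterministic (metabolites
sorted, production before consumption; then genera; then communities; then
catch-alls), so masks are reproducible byte-for-byte from the same inputs.
A role node whose restricted member set is empty (e.g. a metabolite with
producers but no consumers among the input species) is omitted rather than
kept as an all-zero column.

**Decoders.** Each metadata task has a single affine map from `h` to its
logits — the smallest architecture consistent with "one fully connected
layer" — followed by softmax (age 6, BMI 4, body site K classes) or a
sigmoid (gender, one unit). The disease decoder is a single affine map +
softmax over `[h ; fused_age ; fused_gender ; fused_bmi ; fused_body_site]`.

**Fusion.** Per sample and per task: the exact one-hot of the observed
label (gender: the 0/1 scalar) when the value is known, otherwise the
decoder's probability vector. Probability fusion (rather than hard argmax
one-hots) is the default because it is differentiable and preserves
uncertainty; hard one-hot fusion is available behind
`ModelConfig(fusion="hard_one_hot")`. Observed values are constants with
respect to gradients. For missing values the disease loss backpropagates
through the decoder into the trunk by default
(`gradient_through_predicted_metadata=True`), which realises the multitask
coupling; the flag turns the fused prediction into a stop-gradient
constant.

## Objective and optimisation

```
L = Σ_t (n / n_t) Σ_{i: t observed} CE_t(i)  +  Σ_i CE_disease(i)
```

Per-task terms are plain sums of cross-entropies (not means), evaluated per
batch; the weights `n / n_t` are computed once from the optimisation split.
A task with no observed labels is dropped from the loss with a warning.
Gender uses binary cross-entropy. Gradients are computed analytically
(NumPy); the trunk gradient is multiplied by the mask and weights are
re-masked after every update, so `W ⊙ (1 − M) = 0` holds exactly at all
times, including under AdamW's decoupled weight decay.

Hyperparameters: AdamW, learning rate 1e-3, batch size 16, weight decay
1e-2, at most 200 epochs. A stratified 10% of the training split (by
phenotype) is held out; task weights use the remaining 90% only. Early
stopping monitors the **mean disease cross-entropy** on that hold-out with
patience 10 and returns the best state seen. We deliberately do not monitor
the full weighted objective: a scarce metadata task (BMI is observed for
~6% of samples and carries weight n/n_bmi ≈ 16) overfits within a few
epochs and dominates the weighted sum, which in experiments stopped
training long before the disease head converged (held-out disease macro-F1
collapsed to ~0.2 on some folds). Monitoring the primary task removed
those collapses without changing the training objective itself.

Determinism: a single seeded generator drives initialisation, batching and
the validation split; two runs with the same seed produce bitwise-identical
logs. Cross-validation derives fold seeds as base seed + fold index.

## Evaluation

Accuracy, macro F1, macro AUC and macro AUPRC, each computed per class and
averaged *without* support weighting so rare phenotypes count equally.
Conventions for degenerate classes: a class absent from both predictions
and truth contributes F1 = 0; AUC skips classes without both a positive
and a negative; AUPRC skips classes without positives (warnings in both
cases). AUC uses the exact rank (Mann–Whitney) statistic with midranks, so
ties receive half credit rather than depending on interpolation; AUPRC is
the step-wise average precision evaluated at distinct score thresholds.
All four agree with brute-force O(n²) reference implementations to 1e-9 in
the test suite.

## Interpretation

Integrated Gradients along the straight path from baseline to input,
midpoint Riemann rule, 50 steps by default (configurable; ≥8 enforced).
The baseline is the zero-abundance vector with all metadata missing — an
"absence of signal" reference. Layer Conductance multiplies the output
gradient with respect to each hidden activation (at segment midpoints) by
that activation's change over the segment; per-node scores sum to
F(x) − F(baseline) up to discretisation.

Metadata impact on disease prediction is attributed with respect to the
*fused* metadata vectors — the quantity the disease decoder actually
consumes — along the joint path of the decoder's input. Attributions are
converted to importance scores by absolute value, then averaged over
samples, then over the classes of the target task, and finally over models
retrained from R random restarts (R = 20 by default; tests and the
acceptance script use R = 5 to stay cheap). Per-restart raw scores are
retained so any aggregate can be recomputed.

## Synthetic cohorts

The generator emulates the structure the architecture assumes — signal
organised at the level of knowledge groups — and is the basis of all tests:

1. knowledge: a balanced random species → genus partition, random
   producer/consumer sets per metabolite, random overlapping communities;
2. metadata: uniform categorical draws (age 6 classes, BMI 4, body sites,
   balanced gender) and a project label per sample;
3. phenotype: softmax draw with logit `coupling` on the preferred class of
   the sample's (age class × body site) cell; the preference table tiles
   the phenotype classes evenly over cells so marginals stay balanced
   while metadata genuinely carry phenotype information;
4. abundances: per-sample Dirichlet baseline on the log scale, plus
   additive log-fold shifts (`effect_*`) on the driver group of each class
   the sample belongs to — phenotype and age use driver genera, body site
   driver communities, BMI driver producer sets, gender driver consumer
   sets — plus i.i.d. Gaussian log-noise and a per-project per-species
   offset, renormalised to percent (rows sum to 100 exactly);
5. missingness: each metadata field masked missing-at-random at its rate.

Default rates mirror a large public human-microbiome corpus in which body
site is always recorded while age (~81%), gender (~30%) and BMI (~94%) are
missing. Defaults: 600 samples, 50 species, 12 genera, 10 metabolites, 5
communities, 4 phenotypes, 3 body sites, 4 projects, effect sizes 1.0–2.5
log-fold, noise σ = 0.3, project offset σ = 0.3. Regeneration from the
same spec is bitwise identical.

The project-held-out shift scenario splits projects into disjoint train
and test sets; the metadata → phenotype mechanism is shared but per-project
abundance offsets differ, emulating cross-study dataset shift. The
acceptance configuration uses strong offsets (σ = 2.0), strong coupling
(4.0), a moderate direct abundance effect (1.0) and mostly observed age
(80%), i.e. the regime where phenotype information travels mainly through
metadata and the abundance channel is study-confounded — the setting in
which fusing metadata should, and does, generalise better.

**What passing tests do and do not show.** The generator plants clean
group-aligned multiplicative signal under a Dirichlet/log-normal model with
missing-at-random metadata. Real microbiome data add zero-inflation,
compositional artefacts of variable sequencing depth, correlated taxa,
non-random missingness and label noise; recovery results here demonstrate
the *mechanisms* (mask wiring, fusion, weighting, attribution) function as
specified, not that comparable accuracy is attainable on any real cohort.

## Numerical choices and degenerate inputs

- Cross-entropies clip probabilities at 1e-12; a non-finite training loss
  aborts with a diagnostic.
- Hard labels: argmax with lowest-index tie-break; gender threshold 0.5
  with ties to class 0.
- Stratified folds: per-class shuffled round-robin with a rotating offset;
  per-class fold counts differ by at most one; classes smaller than k are
  tolerated with a warning.
- The abundance-sum quality filter is strict (`< 90` percent dropped, 90
  kept); the rare-phenotype filter is strict (`< 50` dropped, 50 kept) and
  applied uniformly, including to the healthy class (for which it never
  triggers at realistic cohort sizes).
- Age/BMI binning uses the half-open intervals: age ≤3, (3,18], (18,35],
  (35,50], (50,65], >65; BMI <18.5, [18.5,25), [25,30), ≥30.
- QC keeps the percent scale; rows are renormalised to sum to one
  immediately before model input (flag `renormalize`, default on).

## Problem sizes

Tests and the acceptance script train on cohorts of 150–600 samples with
24–50 species (hidden widths ~30–40), where a full 5-fold CV takes a few
seconds per fold on one CPU. These sizes were chosen so the planted signal
is comfortably recoverable while the whole suite stays fast; nothing in the
implementation is specific to them.

## Known limitations

- Single-label phenotype prediction only; no multi-disease outputs.
- No probability calibration or out-of-distribution rejection; softmax
  confidences on shifted data should not be taken at face value.
- The taxonomic rank is fixed to genus; other ranks are not configurable.
- Attribution identifies associations the trained model uses, not causal
  microbe–phenotype relationships.
- Community memberships are consumed as given; inferring them from
  co-occurrence data is out of scope.
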