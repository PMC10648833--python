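# Methods

## Problem setting

In a multi-cat household, litter-box visits are the natural observation unit
for urinary-health monitoring (FLUTD surveillance): each visit yields a burst
of body-crop frames of exactly one cat, and the owner can label a whole visit
at once.  Two things make a fixed identification model decay over time:
cats themselves change (kitten-to-adult growth, coat maturation) and the
population changes (adoption, departure).  `driftreid` implements a
classification module that adapts to this concept drift by periodic,
label-driven retraining — there is no drift-detection statistic; the policy
triggers alone decide when to adapt.

The inference path is a two-component composition: a convolutional feature
extractor maps a body crop to a point on the unit hypersphere in R^128, and
a classical classifier (KNN / random forest / SVM) assigns the identity from
a gallery of stored embeddings.

## Metric learning

The extractor is trained with the hinge triplet loss on **squared** Euclidean
distances,

    L(a, p, n) = max(0, d²(a, p) − d²(a, n) + α),    α = 0.2,

over mined triples, plus a global orthogonal regularizer.  With s_ij the dot
products over different-identity pairs in a batch, M1 their mean and M2 their
mean square, the regularizer is

    L_GOR = M1² + max(0, M2 − 1/d),    d = 128,

which drives different-identity embeddings toward the moments of uniformly
spread unit vectors.  Training is a three-stage curriculum over mining
difficulty:

1. **semi-hard** — negatives with d²(a,p) < d²(a,n) < d²(a,p) + α;
2. **hard** — negatives with d²(a,n) < d²(a,p);
3. **hardest** — per (anchor, positive), only the batch-minimal negative
   (ties to the lowest index).

Each stage runs Adam (lr 0.001, β₁ 0.9, β₂ 0.999) for at most 100 epochs on
P×K batches (P identities × K images, defaults 4×4, guaranteeing every anchor
a positive), with epoch-level validation on a stratified 80:20 split, early
stop after 5 epochs without validation improvement, and best-weights
restoration.  Embeddings are L2-normalized; the 1/d limit in L_GOR assumes
unit vectors, and normalization makes Euclidean and cosine ranking agree.

**Backbone.**  The default backbone is a compact two-block strided CNN
(3→12→24 channels, 3×3 kernels, stride 2) with a dense 128-d head,
implemented directly on numpy: im2col convolutions, analytic backprop
(verified against central differences), and a hand-rolled Adam.  At the
32×32 input size used throughout the tests this trains in seconds on one
CPU.  Any network honoring the embed contract (unit-norm 128-vector per
image) can stand in; the architecture is deliberately not the point.

**Fine-tuning** is a single hardest-mode stage at one tenth of the learning
rate.  Two deliberate asymmetries with initial training: the spread
regularizer is off (once the triplet hinge is satisfied the GOR term keeps
pushing weights and measurably inflates intra-identity spread without
improving identification), and the incoming weights are kept unless the
stage improves validation loss, so fine-tuning never degrades a model that
still fits the current data.

## Adaptive embedding store

Per identity the store keeps a bounded gallery of at most N embedding
records plus a staging area of newly relabeled frames.  The policy
(T, M, N, C) governs maintenance:

* every **T** ticks (default 1) triggers are checked;
* once an identity has **M** staged records, the arithmetic mean of
  (gallery ∪ staged) is computed and the N records nearest that mean
  (Euclidean on the raw unit vectors; the mean itself is only a reference
  point and is not renormalized) are retained — outliers such as mislabeled
  or off-distribution frames fall away, and memory stays bounded.  Ties
  break by earlier input position, existing records first.  After any
  selection the classifier is refitted on the updated galleries;
* when **every** registered identity has accumulated **C** litter-box
  records since the last fine-tune, a fine-tune of the extractor is
  requested; afterwards all stored records are re-embedded with the updated
  extractor and the classifier is refitted.  C counts raw ingested frames,
  not post-selection survivors.

Registration inserts user-supplied photos as gallery records directly
(selection-bounded if they exceed N), so a new identity participates in the
next refit; deregistration deletes every record of the identity, and the
subsequent refit removes it from the classifier's class set.  Sessions are
labeled atomically — all frames of a visit carry one identity.

Library defaults are T=1, M=20, N=200, C=500; the desk-scale experiments in
the tests and the acceptance script set M=6, N=40, C=12 so that every
trigger (including fine-tuning) actually fires within a 10-tick run.

## Classifier bank

Six classifiers are compared: KNN with K ∈ {3, 5, 7}, a random forest
(100 trees, seeded), and SVMs with linear and RBF kernels (C = 1.0,
RBF gamma = 1/(d·Var), Platt-calibrated probabilities).  All expose
per-class scores summing to one.  The KNN vote uses Euclidean distance on
the unit-normalized embeddings; ties between top-vote classes go to the
class owning the nearest-ranked neighbor, a rule encoded into the score
vector as an infinitesimal rank bonus (1e-6, below any vote gap) so the
argmax always agrees with the tie rule.

## Evaluation protocol

Per-frame accuracy, raw and row-normalized confusion matrices, and
one-vs-rest ROC and precision-recall curves per class, with trapezoidal AUC
and step-wise average precision AP = Σ (Rᵢ − Rᵢ₋₁)·Pᵢ.  ROC curves are
anchored at (0,0) and (1,1).  The split protocol is stratified 80:20 with a
per-class test share of max(1, round(0.2·n)) (round half up), so every class
appears in the test set.  A session-level majority-vote accuracy is
available as an optional extra; all headline numbers are per-frame.

## Synthetic world

No public dataset of labeled litter-box body crops exists, so the package
carries a generator that emulates the relevant structure rather than the
pixels of real cats:

* an identity is an **appearance genotype**: base coat color, sinusoidal
  stripe frequency and phase, kitten body scale, and a growth rate;
* a frame renders the identity as a striped ellipse on a shared textured
  backdrop with seeded Gaussian pixel noise (default σ = 0.02);
* **drift** acts through age: body scale saturates logistically toward an
  adult size (1.6× kitten, capped), and the coat matures — the base color
  moves up to 60 % of the way toward its complement at a rate set by the
  genotype's growth rate.  The color shift is what makes stale classifiers
  genuinely fail: identities can drift toward each other's original coats;
* **lighting** is a diagonal per-channel gain from a standard blackbody RGB
  approximation, normalized at 6500 K so the cool-white filter is exactly
  the identity map; supported temperatures are 2700/4100/6500/10000 K;
* a **stream** draws sessions per tick by cycling a seeded permutation of
  the currently alive identities (near-uniform per-identity coverage, which
  keeps the all-identities fine-tune trigger reachable), renders frames at
  age = tick × morph_rate, and honors add/remove population events.

Everything is a pure function of explicit seeds.

What the simulator does *not* model: pose, occlusion and deformation, real
background clutter, detector errors (crops are ground truth by
construction), camera noise statistics, and between-identity similarity
structure of real coats.  Passing tests therefore demonstrate the
correctness and the adaptive behavior of the machinery — selection, triggers,
refits, fine-tuning, lifecycle — not field-level identification accuracy on
real animals, which will be lower and harder.

## Drift experiment

`run_drift_experiment` bootstraps both arms identically at tick 0
(registration photos of every initial identity train the extractor and fit
the classifier), then replays the stream.  The adaptive arm ingests
relabeled sessions (a simulated cooperative user returns ground-truth
session labels; an error rate is available), runs the policy triggers, and
reacts to churn by registering or deregistering; the frozen arm never
changes.  Both arms are scored each tick on held-out sessions generated that
tick and never ingested.  Default desk-scale geometry: 5 identities, 32×32
frames, 3 frames/session, 5 ingest + 3 eval sessions per tick, 10 ticks;
one full two-arm run takes on the order of a second on one CPU.

Under strong drift (morph_rate 2.0) the frozen arm's accuracy decays over
the run while the adaptive arm stays near ceiling; with morph_rate 0 the two
arms coincide, confirming adaptation is neutral when nothing changes.

## Numerical choices and edge cases

* Squared distances are clipped at 0 before mining (guards tiny negative
  values from the Gram-matrix identity).
* `gor_term` of a single-label batch (no different-label pair) is defined
  as 0; likewise mining in a single-label batch returns no triples.
* Embedding normalization guards against zero vectors with a 1e-12 floor.
* Early stopping counts *consecutive* non-improving epochs; "improvement"
  is a strict decrease of validation loss.
* Selection ties (equidistant from the mean) resolve by input order via a
  stable sort, making selection fully deterministic.
* PNG round-trips quantize frames to 8 bits; tests compare with a half-level
  tolerance.

## Known limitations

* The backbone is far smaller than production re-identification networks;
  it is sized for CPU test cycles, not accuracy headroom on real imagery.
* The fine-tune trigger requires *all* identities to reach C; a rarely seen
  identity can therefore postpone fine-tuning indefinitely (a faithful
  reading of the all-cats condition, but operationally conservative).
* The classifier refit runs on every selection event rather than on the
  period T only; with many identities triggering at once this refits more
  often than strictly necessary.
* The user-relabeling oracle is perfect by default; real label noise will
  slow or corrupt adaptation (the error-rate knob exists but the shipped
  experiments do not sweep it).
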