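# Methods

## Problem setting

Papillary thyroid carcinoma management hinges on two linked predictions:
whether a patient harbors lymph-node metastasis (LNM) and how long they
remain disease-free (DFS). Whole-slide images carry morphological signal for
both, but only slide-level labels exist — a weak-supervision regime handled
here with multiple-instance learning (MIL): each slide is a bag of
256×256 px tiles taken at the 20×-equivalent magnification, and a learned
attention mechanism decides which tiles matter. Molecular context (mRNA
expression, mutation indicators, immune-cell abundances, optionally
clinical covariates) enters by concatenation after pooling.

## Pipeline

**Tissue segmentation.** The slide is mean-pooled to a working downsample
(default 16×), converted to HSV, and the saturation channel is thresholded
by Otsu with an absolute floor of 0.05 (glass is near-white and therefore
low-saturation; the floor keeps near-constant scans from splitting into
noise). Morphological closing (disk radius 2 at the downsample) bridges
small gaps and connected components under 64 downsampled pixels are
removed. These parameters are package defaults, not measured constants;
they follow common weakly-supervised-pathology preprocessing.

**Patching.** Tiles form a pure non-overlapping grid: corners at multiples
of the 256 px tile size, row-major order. A tile is kept when the fraction
of its footprint covered by tissue is at least `min_tissue_fraction`
(default 0.5). Coverage is computed on the upsampled mask, so the rule is
exact and testable against a brute-force scan.

**Patch encoding.** The encoder is a contract: any callable mapping one RGB
tile to a fixed-length vector. Production pipelines typically use
pre-trained CNN features (the checkpoint schema records the encoder id and
its dimension); the package ships small deterministic encoders (per-channel
means; channel statistics) that make the geometry and bookkeeping fully
verifiable on synthetic slides. No pre-trained weights are bundled, and the
model core is encoder-agnostic.

**Model.** Patch embeddings pass a learned linear projection to `d_img`
(default 512; the projection decouples the fusion width from the encoder),
then gated attention `a_k = wᵀ(tanh(V h_k) ⊙ σ(U h_k))` with hidden size
256 scores each patch; softmax weights pool the bag. One shared attention
backbone serves all three heads. Omics blocks are standardized with
training-split mean/SD (mutation indicators stay binary) and concatenated
after the pooled vector in a fixed block order. Each task head is a single
affine map: sigmoid for the LNM probability, identity for the risk score,
softplus for the predicted time (times are nonnegative; the smooth map
keeps gradients well-behaved near zero).

**Losses.** The survival loss is the negative log Cox partial likelihood
with the Breslow convention for ties, summed over events; it is
shift-invariant in the risk scores and zero for an event-free batch (a
deliberate contract: bag-level minibatches often contain no event).
Cross-entropy averages over samples with a known LNM label; squared error
on time averages over uncensored samples only, since a censored time is
only a lower bound. The total is `NLL + λ_CE·CE + λ_MSE·MSE`.

**λ defaults.** `λ_CE = 1.0`, `λ_MSE = 0.01`. The two likelihood terms are
O(1) per sample while squared errors on DFS times measured in months run
two to three orders of magnitude larger; at equal weight the time
regression dominates every gradient and, in particular, drags the shared
attention backbone toward time-regression noise before the discriminative
tasks can shape it. `λ_MSE = 0.01` restores gradient balance. Both weights
are configuration knobs, not fitted constants.

**Optimization.** Adam, learning rate 1e-4, weight decay 1e-5 (folded into
the gradient), dropout 0.25 on the fused vector, at most 20 epochs.
Gradients accumulate over windows of 8 bags and the Cox likelihood is
evaluated over the same window, so its risk sets are non-degenerate — a
partial likelihood over a single bag is identically zero. Early stopping
monitors the total combined validation loss with patience 5 (the
improvement criterion and patience are package choices); the parameters of
the best validation epoch are returned. The backbone is initialized
fan-in-scaled uniform; the three heads start at zero, so their first
updates write each task's discriminative direction directly, which in turn
gives the attention gate a coherent gradient from the first epochs — this
matters in the short 20-epoch schedule. All randomness (initialization,
shuffling, dropout) flows from one seed; runs are bit-reproducible on one
CPU. Forward and backward passes are explicit array code; gradient
correctness is enforced by a central-finite-difference check in the tests.

**Missing-modality protocol.** To evaluate on image-only cohorts, all
weights are frozen (guarded by a parameter checksum) and the omics inputs
are replaced by exact zeros injected at the fusion input, bypassing
standardization. The architecture and parameter count are unchanged.

**Evaluation.** ROC/AUC via the Mann–Whitney convention (ties count ½);
horizon AUCs use cumulative cases (event by the horizon) versus dynamic
controls (under observation past it), excluding subjects censored earlier —
no inverse-probability weighting in this version. Risk groups split at the
training-set median risk (ties to low). Kaplan–Meier curves and the
two-sample log-rank test come from lifelines behind the package's own
surface; the test suite checks both against hand tabulations.

**Heatmaps.** Softmax attention weights shrink as 1/K with bag size, so
tiles are colored by rank percentile within the bag (average rank for ties,
divided by K; a singleton bag scores 1). The colormap is a fixed tabulated
blue→white→red ramp with integer anchors at 0, 0.5 and 1, making rendered
colors exactly reproducible; tiles are filled at a stated downsample and
optionally alpha-blended over the downsampled slide. Background pixels are
never touched.

## Synthetic cohort

The simulator provides the statistical structure the model assumes, with
closed-form checkable pieces:

* a latent binary class per sample (fair coin);
* bags of `K ~ Uniform{40..60}` patches (d = 32 by default), background
  `N(0, I)`; in latent-positive bags an exact 20% of patches are shifted by
  2.5 along the fixed axis `e_1` — one fixed signal direction keeps
  attention-enrichment checks interpretable;
* omics blocks with means shifted by `omics_effect · latent` (default 1.0;
  mutations get the shift on the logit scale from a 15% base rate);
* LNM label `Bernoulli(σ(4.0 · (2·latent − 1)))` — about 1.8% label noise;
* DFS time exponential with hazard `0.03 · exp(2.0 · latent)` per month and
  independent `Uniform(0, T_max)` censoring, `T_max` solved by root-finding
  so the expected censored fraction is 0.25.

These defaults are deliberately strong, clearly-separable conditions: they
make end-to-end recovery a sharp test of the machinery rather than of
statistical power. What the simulator does **not** emulate: histology
texture, stain variation, batch effects, correlated omics structure,
informative censoring, or label noise beyond the logistic link — so passing
tests demonstrate correctness of the pipeline under its own assumptions,
not clinical-grade performance on real slides. The flat synthetic slide
images (white glass, textured pink/purple rectangles) exercise
segmentation and patching geometry only.

## Desk-scale study and problem sizes

The reference experiment (`pathomil.pipeline.run_synthetic_study`) uses
200 slides × 50 patches × 32 dims, a 70/30 split, and a model sized down to
`d_img = 64`, attention hidden 64 — small enough that a full
simulate/train/evaluate cycle takes about a second on one CPU while
exercising every code path; the production-sized defaults (512/256) change
nothing structurally. Across seeds, held-out LNM AUC and risk/latent
concordance are very stable; attention enrichment is the most
seed-sensitive quantity, since localization depends on how quickly the
attention gate aligns during the short schedule.

## Numerical choices and degenerate inputs

Log-sum-exp stabilization in the Cox likelihood and softmax; probabilities
clamped at 1e-12 inside the cross-entropy; standard deviations floored at
1e-8 in the standardizer; an all-censored batch yields NLL 0 and an
all-missing label batch yields CE 0 with a warning; a slide smaller than
one tile yields an empty grid with a warning; single-class AUC and
event-free log-rank raise an explicit undefined-metric error. Risk-group
ties go to the low group; attention rank ties take the average rank.

## Known limitations

No pyramidal/SVS reader is wired in (flat TIFF/PNG only; the slide-reader
surface accepts arrays, so a pyramidal backend can be plugged in upstream);
no pre-trained CNN encoder is bundled; no IPCW horizon AUC; no per-task
attention branches; the λ weights are not auto-tuned. The Cox likelihood is
computed per accumulation window, so very small windows weaken the survival
signal.
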