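# pathomil

Weakly-supervised, multi-modal, multi-task deep learning for papillary
thyroid carcinoma histopathology: attention-gated multiple-instance learning
(MIL) over whole-slide-image patch bags, fused by concatenation with
molecular/immune/clinical feature vectors, and trained jointly to classify
lymph-node metastasis (LNM) and to prognosticate disease-free survival
(DFS) under right-censoring. Per-patch attention weights double as an
interpretation layer, rendered as slide-aligned RGB heatmaps.

The package is aimed at computational-pathology researchers who want a
fully-offline, testable implementation of this model family: every stage —
tissue segmentation, 256 px grid patching at the 20×-equivalent level,
patch encoding, gated-attention pooling, omics fusion, the three task
losses, training with early stopping, evaluation, and heatmaps — runs on a
built-in synthetic-cohort simulator, with no external slides or downloads.

## Model

A slide is a bag of patch embeddings `h_1 … h_K` (only the slide-level
label is known). A gated attention module scores each patch

    a_k = wᵀ ( tanh(V h_k) ⊙ σ(U h_k) ),     α = softmax(a),

and pools the bag into `z = Σ_k α_k h_k`. The pooled image vector is
concatenated with the omics blocks (1,004 mRNA features, 22 binary mutation
indicators, 64 immune-cell abundances, optional clinical covariates) into a
fused vector that feeds three single fully-connected heads:

* **LNM classifier** — `p = σ(c·f + b)`, trained with binary cross-entropy;
* **DFS risk score** — linear head trained with the negative log Cox
  partial likelihood (Breslow ties), so higher scores mean worse prognosis;
* **DFS time regressor** — softplus-positive head trained with MSE on
  uncensored samples only.

The combined objective is `NLL + λ_CE·CE + λ_MSE·MSE`, optimized with Adam
(lr 1e-4, weight decay 1e-5), dropout 0.25, at most 20 epochs, and early
stopping on the validation loss. The missing-modality protocol freezes all
weights and zeroes the omics inputs, measuring what the model can do from
the image alone.

## Worked example

```python
from pathomil.pipeline import run_synthetic_study

r = run_synthetic_study(seed=0)
print(f"held-out LNM AUC        {r.lnm_auc:.3f}")
print(f"zero-masked omics AUC   {r.masked_lnm_auc:.3f}")
print(f"risk/latent concordance {r.risk_latent_concordance:.3f}")
print(f"attention enrichment    {r.attention_enrichment:.3f}")
print(f"log-rank chi2, p        {r.logrank_chi_square:.2f}, {r.logrank_p:.2e}")
```

prints (seed 0):

```
held-out LNM AUC        0.982
zero-masked omics AUC   0.932
risk/latent concordance 1.000
attention enrichment    1.000
log-rank chi2, p        27.87, 1.30e-07
```

This simulates a 200-slide cohort (50 patches per bag, 32-dim embeddings,
20% of patches in positive slides carrying a planted signal), trains the
model on 70% of it, and evaluates the held-out 30%. The AUC is the
discrimination of the LNM head; the masked AUC is the same model with all
omics zeroed under frozen weights (image-only performance); concordance
asks whether the DFS risk score ranks the adverse latent class higher;
attention enrichment is the fraction of positive held-out slides in which
planted-signal patches receive more mean attention than background; the
log-rank test compares KM curves between median-split risk groups.

The same stages are scriptable from a shell:

```
pathomil simulate --out data/ --seed 0
pathomil train --features data/bags --omics data/omics.tsv \
    --outcomes data/outcomes.csv --out run/
pathomil evaluate --checkpoint run/checkpoint.npz --features data/bags \
    --omics data/omics.tsv --outcomes data/outcomes.csv --out metrics.json
pathomil heatmap --checkpoint run/checkpoint.npz --slide slide.tiff --out heat.png
```

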