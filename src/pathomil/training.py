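"""Optimization loop, early stopping, and the frozen-weights missing-modality
evaluation protocol.

Training uses Adam (lr 1e-4, weight decay 1e-5 by default) for at most 20
epochs with dropout 0.25, stopping early when the total combined validation
loss has not improved for ``patience`` consecutive epochs; the parameters of
the best validation epoch are returned. Gradients accumulate over windows of
``batch_bags`` slides, and the Cox partial likelihood is evaluated over that
window so its risk sets are non-trivial. Everything is seeded: the same
configuration reproduces the same loss trajectory on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .losses import (
    BatchOutcomes,
    LossWeights,
    ce_grad_wrt_logit,
    combined_loss,
    mse_time_grad,
    survival_nll_grad,
)
from .model import FusionMILModel, ModelConfig, ModelParams, OmicsStandardizer, init_params
from .types import RiskPrediction, Sample, masked_copy

__all__ = ["TrainConfig", "TrainReport", "AdamState", "train", "predict_frozen", "mask_omics"]


def mask_omics(sample: Sample) -> Sample:
    """Zero every omics entry of a sample (idempotent); image features untouched."""
    return masked_copy(sample)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    max_epochs: int = 20
    dropout: float = 0.25
    patience: int = 5
    batch_bags: int = 8
    loss_weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be > 0 and weight_decay >= 0")
        if self.max_epochs < 1 or self.patience < 1 or self.batch_bags < 1:
            raise ValueError("max_epochs, patience and batch_bags must be >= 1")


@dataclass
class TrainReport:
    epochs: list[dict]
    best_epoch: int
    stop_reason: str  # "max_epochs" | "early_stop"

    @property
    def best_val_loss(self) -> float:
        return self.epochs[self.best_epoch]["val_total"]


class AdamState:
    """Plain Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: ModelParams, lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.wd, self.b1, self.b2, self.eps = lr, weight_decay, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.tensors.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.tensors.items()}
        self.t = 0

    def step(self, params: ModelParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, theta in params.tensors.items():
            g = grads[key] + self.wd * theta
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            m_hat = self.m[key] / (1 - self.b1**self.t)
            v_hat = self.v[key] / (1 - self.b2**self.t)
            theta -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _batch_outputs(model: FusionMILModel, samples: list[Sample], mode: str,
                   rng: np.random.Generator | None):
    """Forward a list of samples; returns BatchOutcomes plus per-sample caches."""
    probs, risks, taus, caches = [], [], [], []
    for s in samples:
        pred, _, cache = model.forward(s.bag, s.omics, mode=mode, rng=rng, return_cache=True)
        probs.append(pred.lnm_probability)
        risks.append(pred.dfs_risk_score)
        taus.append(pred.predicted_time)
        caches.append(cache)
    batch = BatchOutcomes(
        times=np.array([s.outcome.time_months for s in samples]),
        events=np.array([float(s.outcome.event) for s in samples]),
        lnm_labels=np.array([s.outcome.lnm for s in samples]),
        risk_scores=np.array(risks),
        lnm_probs=np.array(probs),
        predicted_times=np.array(taus),
    )
    return batch, caches


def batch_loss_and_grads(
    model: FusionMILModel,
    samples: list[Sample],
    weights: LossWeights,
    mode: str = "train",
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, float], dict[str, np.ndarray]]:
    """Combined loss over a window of bags and its exact parameter gradients."""
    batch, caches = _batch_outputs(model, samples, mode, rng)
    total, breakdown = combined_loss(batch, weights)

    d_risk = survival_nll_grad(batch.risk_scores, batch.times, batch.events)
    d_logit = weights.lambda_ce * ce_grad_wrt_logit(batch.lnm_probs, batch.lnm_labels)
    d_time = weights.lambda_mse * mse_time_grad(batch.predicted_times, batch.times, batch.events)

    grads: dict[str, np.ndarray] = {k: np.zeros_like(v) for k, v in model.params.tensors.items()}
    for i, cache in enumerate(caches):
        sample_grads = model.backward(cache, float(d_logit[i]), float(d_risk[i]), float(d_time[i]))
        for key, g in sample_grads.items():
            grads[key] += g
    return total, breakdown, grads


def train(
    dataset: list[Sample],
    split: tuple[list[int], list[int]],
    config: TrainConfig,
    model_config: ModelConfig,
) -> tuple[FusionMILModel, TrainReport]:
    """Fit the fusion-MIL model on a train/validation split.

    Omics standardization statistics are fit on the training split only.
    The returned model carries the parameters of the epoch with the best
    total validation loss.
    """
    train_idx, val_idx = split
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("train and validation splits must both be non-empty")
    if set(train_idx) & set(val_idx):
        raise ValueError("train and validation splits overlap")

    train_samples = [dataset[i] for i in train_idx]
    val_samples = [dataset[i] for i in val_idx]

    model_config = ModelConfig(
        feature_dim=model_config.feature_dim,
        omics_schema=model_config.omics_schema,
        d_img=model_config.d_img,
        attention_hidden=model_config.attention_hidden,
        dropout=config.dropout,
    )
    standardizer = OmicsStandardizer.fit(
        [s.omics for s in train_samples], model_config.omics_schema
    )
    model = FusionMILModel(
        model_config,
        params=init_params(model_config, seed=config.seed),
        standardizer=standardizer,
    )
    optimizer = AdamState(model.params, config.learning_rate, config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)

    best_params: ModelParams | None = None
    best_val = np.inf
    best_epoch = -1
    epochs_since_improvement = 0
    report_epochs: list[dict] = []
    stop_reason = "max_epochs"

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_samples))
        train_totals = {"nll": 0.0, "ce": 0.0, "mse": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, len(order), config.batch_bags):
            window = [train_samples[i] for i in order[start : start + config.batch_bags]]
            _, breakdown, grads = batch_loss_and_grads(
                model, window, config.loss_weights, mode="train", rng=rng
            )
            optimizer.step(model.params, grads)
            for key in train_totals:
                train_totals[key] += breakdown[key]
            n_batches += 1
        for key in train_totals:
            train_totals[key] /= max(n_batches, 1)

        val_batch, _ = _batch_outputs(model, val_samples, mode="eval", rng=None)
        val_total, val_breakdown = combined_loss(val_batch, config.loss_weights)

        report_epochs.append(
            {
                "epoch": epoch,
                **{f"train_{k}": v for k, v in train_totals.items()},
                **{f"val_{k}": v for k, v in val_breakdown.items()},
                "val_total": val_total,
            }
        )

        if val_total < best_val - 1e-12:
            best_val = val_total
            best_epoch = epoch
            best_params = model.params.copy()
            epochs_since_improvement = 0
        else:
            epochs_since_improvement += 1
            if epochs_since_improvement >= config.patience:
                stop_reason = "early_stop"
                break

    assert best_params is not None
    model.params = best_params
    return model, TrainReport(epochs=report_epochs, best_epoch=best_epoch, stop_reason=stop_reason)


def predict_frozen(
    dataset: list[Sample],
    model: FusionMILModel,
    mask_modalities: frozenset[str] | set[str] = frozenset(),
) -> list[RiskPrediction]:
    """Eval-mode predictions with all weights frozen.

    ``mask_modalities={'omics'}`` applies the zero-masking protocol: gene,
    mutation and immune inputs are replaced by zeros while the architecture
    and parameter count stay unchanged. A checksum guard verifies that no
    parameter was mutated.
    """
    unknown = set(mask_modalities) - {"omics"}
    if unknown:
        raise ValueError(f"unknown modalities to mask: {sorted(unknown)}")
    before = model.params.checksum()
    preds = []
    for sample in dataset:
        if "omics" in mask_modalities:
            sample = mask_omics(sample)
        pred, _ = model.forward(sample.bag, sample.omics, mode="eval")
        preds.append(pred)
    after = model.params.checksum()
    if before != after:
        raise RuntimeError("model parameters changed during frozen prediction")
    return preds
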