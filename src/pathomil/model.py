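"""Model core: gated-attention pooling over a patch bag, concatenative fusion
with omics blocks, and three single-layer task heads.

The attention gate assigns each patch embedding ``h_k`` a raw score

    a_k = w^T ( tanh(V h_k) * sigmoid(U h_k) )

softmax-normalized into weights that pool the bag into one slide vector.
Patch embeddings first pass a learned linear projection to ``d_img`` so the
fusion width is decoupled from the encoder's output size. The fused vector
``[pooled | mRNA | mutations | immune | clinical]`` feeds one fully
connected layer per task: a sigmoid LNM classifier, a linear DFS risk score
(higher = worse), and a softplus-positive predicted time in months.

Forward and backward passes are written out explicitly over numpy arrays;
the gradients are exact and are verified against central finite differences
in the test suite. Dropout (on the fused vector) is active only in train
mode; eval mode is fully deterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.special import expit

from .types import AttentionProfile, FeatureBag, OmicsSchema, OmicsVector, RiskPrediction, Sample

__all__ = [
    "ModelConfig",
    "ModelParams",
    "OmicsStandardizer",
    "FusionMILModel",
    "gated_attention",
    "fuse",
    "init_params",
]


@dataclass(frozen=True)
class ModelConfig:
    feature_dim: int
    omics_schema: OmicsSchema = field(default_factory=OmicsSchema)
    d_img: int = 512
    attention_hidden: int = 256
    dropout: float = 0.25

    @property
    def fused_dim(self) -> int:
        return self.d_img + self.omics_schema.total


@dataclass
class ModelParams:
    """All learnable tensors, keyed by name."""

    tensors: dict[str, np.ndarray]

    def copy(self) -> "ModelParams":
        return ModelParams({k: v.copy() for k, v in self.tensors.items()})

    def checksum(self) -> str:
        digest = hashlib.sha256()
        for key in sorted(self.tensors):
            digest.update(key.encode())
            digest.update(np.ascontiguousarray(self.tensors[key]).tobytes())
        return digest.hexdigest()


def init_params(config: ModelConfig, seed: int = 0) -> ModelParams:
    """Initialize the backbone fan-in-scaled uniform; task heads start at zero.

    Zeroed heads make the first optimizer updates write each task's
    discriminative direction directly into its head, which in turn gives the
    attention gate a coherent gradient from the start — useful in the
    short-schedule regime (20 epochs at lr 1e-4) this model trains under.
    """
    rng = np.random.default_rng(seed)

    def uniform(shape: tuple[int, ...], fan_in: int) -> np.ndarray:
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape)

    d, di, h, df = config.feature_dim, config.d_img, config.attention_hidden, config.fused_dim
    return ModelParams(
        {
            "proj_W": uniform((di, d), d),
            "proj_b": uniform((di,), d),
            "att_V": uniform((h, di), di),
            "att_U": uniform((h, di), di),
            "att_w": uniform((h,), h),
            "cls_w": np.zeros(df),
            "cls_b": np.zeros(1),
            "risk_w": np.zeros(df),
            "risk_b": np.zeros(1),
            "time_w": np.zeros(df),
            "time_b": np.zeros(1),
        }
    )


@dataclass
class OmicsStandardizer:
    """Train-set mean/SD for the continuous omics blocks.

    Mutation indicators are kept binary (identity transform). Fit once on
    the training split; the statistics travel with the checkpoint.
    """

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def identity(cls, schema: OmicsSchema) -> "OmicsStandardizer":
        return cls(mean=np.zeros(schema.total), scale=np.ones(schema.total))

    @classmethod
    def fit(cls, omics: Iterable[OmicsVector], schema: OmicsSchema) -> "OmicsStandardizer":
        mat = np.stack([o.concatenated() for o in omics])
        if mat.shape[1] != schema.total:
            raise ValueError(f"omics width {mat.shape[1]} does not match schema {schema.total}")
        mean = mat.mean(axis=0)
        scale = np.maximum(mat.std(axis=0), 1e-8)
        mut = schema.block_slices()["mutations"]
        mean[mut] = 0.0
        scale[mut] = 1.0
        return cls(mean=mean, scale=scale)

    def transform(self, omics: OmicsVector) -> np.ndarray:
        if omics.masked:
            return np.zeros_like(self.mean)  # zeros injected at the fusion input
        return (omics.concatenated() - self.mean) / self.scale


def _softmax(a: np.ndarray) -> np.ndarray:
    e = np.exp(a - a.max())
    return e / e.sum()


def gated_attention(
    bag: FeatureBag | np.ndarray,
    V: np.ndarray,
    U: np.ndarray,
    w: np.ndarray,
) -> tuple[AttentionProfile, np.ndarray]:
    """Gated attention pooling of a bag of embeddings.

    Returns the attention profile (raw scores and softmax weights) and the
    pooled vector ``sum_k weight_k * h_k``. Permutation-equivariant in the
    patch order; the pooled vector is permutation-invariant.
    """
    h = bag.features if isinstance(bag, FeatureBag) else np.asarray(bag, dtype=float)
    if h.ndim != 2 or h.shape[0] < 1:
        raise ValueError("bag must be a (K, d) matrix with K >= 1")
    if V.shape[1] != h.shape[1] or U.shape != V.shape or w.shape != (V.shape[0],):
        raise ValueError(
            f"attention parameter shapes {V.shape}/{U.shape}/{w.shape} do not match bag dim {h.shape[1]}"
        )
    gate = np.tanh(h @ V.T) * expit(h @ U.T)
    raw = gate @ w
    weights = _softmax(raw)
    return AttentionProfile(raw_scores=raw, weights=weights), weights @ h


def fuse(
    pooled: np.ndarray,
    omics: OmicsVector,
    schema: OmicsSchema,
    standardizer: OmicsStandardizer | None = None,
) -> np.ndarray:
    """Concatenate the pooled slide vector with the (standardized) omics blocks.

    Block order is fixed: image, mRNA, mutations, immune, clinical. A masked
    omics vector contributes exact zeros.
    """
    for name, width in (
        ("mrna", schema.n_mrna),
        ("mutations", schema.n_mutations),
        ("immune", schema.n_immune),
        ("clinical", schema.n_clinical),
    ):
        got = getattr(omics, name).size
        if got != width:
            raise ValueError(f"omics block {name!r} has width {got}, schema expects {width}")
    standardizer = standardizer or OmicsStandardizer.identity(schema)
    o = standardizer.transform(omics)
    if not np.all(np.isfinite(o)):
        raise ValueError("non-finite values in omics input")
    return np.concatenate([np.asarray(pooled, dtype=float), o])


class FusionMILModel:
    """Bundles configuration, parameters and standardization statistics."""

    def __init__(
        self,
        config: ModelConfig,
        params: ModelParams | None = None,
        standardizer: OmicsStandardizer | None = None,
        seed: int = 0,
    ) -> None:
        self.config = config
        self.params = params if params is not None else init_params(config, seed)
        self.standardizer = standardizer or OmicsStandardizer.identity(config.omics_schema)

    # ------------------------------------------------------------------ forward

    def forward(
        self,
        bag: FeatureBag,
        omics: OmicsVector,
        mode: str = "eval",
        rng: np.random.Generator | None = None,
        return_cache: bool = False,
    ):
        """Full forward pass for one sample.

        ``mode='train'`` applies dropout to the fused vector (an ``rng`` is
        then required); ``mode='eval'`` is deterministic. Returns
        ``(RiskPrediction, AttentionProfile)`` and, when requested, the
        cache of intermediates consumed by :meth:`backward`.
        """
        if mode not in ("train", "eval"):
            raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
        p = self.params.tensors
        cfg = self.config
        h = bag.features
        if h.shape[1] != cfg.feature_dim:
            raise ValueError(
                f"bag feature dim {h.shape[1]} does not match model feature_dim {cfg.feature_dim}"
            )

        z = h @ p["proj_W"].T + p["proj_b"]
        t = np.tanh(z @ p["att_V"].T)
        s = expit(z @ p["att_U"].T)
        gate = t * s
        raw = gate @ p["att_w"]
        alpha = _softmax(raw)
        pooled = alpha @ z
        fused = fuse(pooled, omics, cfg.omics_schema, self.standardizer)

        if mode == "train" and cfg.dropout > 0:
            if rng is None:
                raise ValueError("train mode with dropout requires an rng")
            keep = rng.random(fused.size) >= cfg.dropout
            f = fused * keep / (1.0 - cfg.dropout)
        else:
            keep = None
            f = fused

        logit = float(f @ p["cls_w"] + p["cls_b"][0])
        prob = float(expit(logit))
        risk = float(f @ p["risk_w"] + p["risk_b"][0])
        tau_raw = float(f @ p["time_w"] + p["time_b"][0])
        tau = float(np.logaddexp(0.0, tau_raw))  # softplus

        pred = RiskPrediction(lnm_probability=prob, dfs_risk_score=risk, predicted_time=tau)
        profile = AttentionProfile(raw_scores=raw, weights=alpha)
        if not return_cache:
            return pred, profile
        cache = {
            "h": h, "z": z, "t": t, "s": s, "gate": gate, "alpha": alpha,
            "f": f, "keep": keep, "tau_raw": tau_raw,
        }
        return pred, profile, cache

    # ----------------------------------------------------------------- backward

    def backward(
        self,
        cache: dict,
        d_logit: float,
        d_risk: float,
        d_time: float,
    ) -> dict[str, np.ndarray]:
        """Exact gradients of the loss for one sample.

        ``d_logit``, ``d_risk`` and ``d_time`` are the loss gradients with
        respect to the classifier logit, the risk score and the (softplus)
        predicted time.
        """
        p = self.params.tensors
        cfg = self.config
        h, z, t, s = cache["h"], cache["z"], cache["t"], cache["s"]
        alpha, f = cache["alpha"], cache["f"]

        d_tau_raw = d_time * expit(cache["tau_raw"])  # softplus' = sigmoid
        grads = {
            "cls_w": d_logit * f,
            "cls_b": np.array([d_logit]),
            "risk_w": d_risk * f,
            "risk_b": np.array([d_risk]),
            "time_w": d_tau_raw * f,
            "time_b": np.array([d_tau_raw]),
        }
        df = d_logit * p["cls_w"] + d_risk * p["risk_w"] + d_tau_raw * p["time_w"]
        if cache["keep"] is not None:
            df = df * cache["keep"] / (1.0 - cfg.dropout)
        d_pooled = df[: cfg.d_img]  # omics slots carry no upstream parameters

        dz = np.outer(alpha, d_pooled)
        d_alpha = z @ d_pooled
        da = alpha * (d_alpha - alpha @ d_alpha)  # softmax backward
        grads["att_w"] = cache["gate"].T @ da
        dgate = np.outer(da, p["att_w"])
        dt = dgate * s
        ds = dgate * t
        dpre_v = dt * (1.0 - t**2)
        dpre_u = ds * s * (1.0 - s)
        dz += dpre_v @ p["att_V"] + dpre_u @ p["att_U"]
        grads["att_V"] = dpre_v.T @ z
        grads["att_U"] = dpre_u.T @ z
        grads["proj_W"] = dz.T @ h
        grads["proj_b"] = dz.sum(axis=0)
        return grads

    # --------------------------------------------------------------- prediction

    def predict(self, sample: Sample) -> tuple[RiskPrediction, AttentionProfile]:
        return self.forward(sample.bag, sample.omics, mode="eval")

    # --------------------------------------------------------------- checkpoint

    def save(self, path: str) -> None:
        schema = {
            "feature_dim": self.config.feature_dim,
            "d_img": self.config.d_img,
            "attention_hidden": self.config.attention_hidden,
            "dropout": self.config.dropout,
            "omics_blocks": {
                "mrna": self.config.omics_schema.n_mrna,
                "mutations": self.config.omics_schema.n_mutations,
                "immune": self.config.omics_schema.n_immune,
                "clinical": self.config.omics_schema.n_clinical,
            },
            "block_order": ["image", "mrna", "mutations", "immune", "clinical"],
        }
        np.savez(
            path,
            _schema=np.array(json.dumps(schema)),
            _std_mean=self.standardizer.mean,
            _std_scale=self.standardizer.scale,
            **self.params.tensors,
        )

    @classmethod
    def load(cls, path: str) -> "FusionMILModel":
        with np.load(path, allow_pickle=False) as data:
            schema = json.loads(str(data["_schema"]))
            blocks = schema["omics_blocks"]
            config = ModelConfig(
                feature_dim=schema["feature_dim"],
                omics_schema=OmicsSchema(
                    n_mrna=blocks["mrna"],
                    n_mutations=blocks["mutations"],
                    n_immune=blocks["immune"],
                    n_clinical=blocks["clinical"],
                ),
                d_img=schema["d_img"],
                attention_hidden=schema["attention_hidden"],
                dropout=schema["dropout"],
            )
            std = OmicsStandardizer(mean=data["_std_mean"], scale=data["_std_scale"])
            tensors = {k: data[k] for k in data.files if not k.startswith("_")}
        return cls(config=config, params=ModelParams(tensors), standardizer=std)
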