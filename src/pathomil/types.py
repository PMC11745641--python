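"""Shared container types for slide bags, omics vectors, outcomes and predictions.

A slide is represented as a *bag* of patch embeddings (multiple-instance
learning): only the slide-level label is known, never per-patch labels.
Omics measurements ride alongside as fixed-length vectors partitioned into
blocks (mRNA expression, binary mutation indicators, immune-cell abundances,
optional clinical covariates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FeatureBag",
    "OmicsSchema",
    "OmicsVector",
    "SurvivalOutcome",
    "Sample",
    "AttentionProfile",
    "RiskPrediction",
]


@dataclass
class FeatureBag:
    """Variable-length set of patch embeddings for one slide.

    ``features`` is a ``(K, d)`` float matrix, row ``k`` the embedding of the
    tile whose top-left corner is ``coords[k]`` (x=column, y=row, 0-based,
    half-open ``[x, x+tile) x [y, y+tile)``).
    """

    sample_id: str
    features: np.ndarray  # (K, d)
    coords: np.ndarray  # (K, 2) int
    encoder_id: str = "unknown"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.coords = np.asarray(self.coords)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("features must be a (K, d) matrix with K >= 1")
        if not np.all(np.isfinite(self.features)):
            raise ValueError(f"non-finite feature values in bag {self.sample_id!r}")
        if self.coords.shape != (self.features.shape[0], 2):
            raise ValueError("coords must align row-for-row with features")

    @property
    def n_patches(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


@dataclass(frozen=True)
class OmicsSchema:
    """Widths of the omics blocks, in their fixed fusion order."""

    n_mrna: int = 1004
    n_mutations: int = 22
    n_immune: int = 64
    n_clinical: int = 0

    @property
    def total(self) -> int:
        return self.n_mrna + self.n_mutations + self.n_immune + self.n_clinical

    def block_slices(self) -> dict[str, slice]:
        out: dict[str, slice] = {}
        start = 0
        for name, width in (
            ("mrna", self.n_mrna),
            ("mutations", self.n_mutations),
            ("immune", self.n_immune),
            ("clinical", self.n_clinical),
        ):
            out[name] = slice(start, start + width)
            start += width
        return out


@dataclass
class OmicsVector:
    """One sample's omics measurements, block by block.

    ``masked`` records the missing-modality protocol: a masked vector
    contributes exact zeros to the fused representation, bypassing
    standardization.
    """

    mrna: np.ndarray
    mutations: np.ndarray
    immune: np.ndarray
    clinical: np.ndarray = field(default_factory=lambda: np.zeros(0))
    masked: bool = False

    def __post_init__(self) -> None:
        self.mrna = np.asarray(self.mrna, dtype=float).ravel()
        self.mutations = np.asarray(self.mutations, dtype=float).ravel()
        self.immune = np.asarray(self.immune, dtype=float).ravel()
        self.clinical = np.asarray(self.clinical, dtype=float).ravel()

    @property
    def schema(self) -> OmicsSchema:
        return OmicsSchema(
            n_mrna=self.mrna.size,
            n_mutations=self.mutations.size,
            n_immune=self.immune.size,
            n_clinical=self.clinical.size,
        )

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.mrna, self.mutations, self.immune, self.clinical])

    def zeroed(self) -> "OmicsVector":
        """Return a copy with every entry set to zero and the mask recorded."""
        return OmicsVector(
            mrna=np.zeros_like(self.mrna),
            mutations=np.zeros_like(self.mutations),
            immune=np.zeros_like(self.immune),
            clinical=np.zeros_like(self.clinical),
            masked=True,
        )


@dataclass
class SurvivalOutcome:
    """Right-censored disease-free-survival outcome plus the LNM label.

    ``time_months > 0``; ``event`` is 1 if recurrence was observed at
    ``time_months``, 0 if follow-up ended event-free (censored). ``lnm`` may
    be NaN when the nodal status is unknown.
    """

    time_months: float
    event: int
    lnm: float

    def __post_init__(self) -> None:
        if not self.time_months > 0:
            raise ValueError("time_months must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class Sample:
    bag: FeatureBag
    omics: OmicsVector
    outcome: SurvivalOutcome


@dataclass
class AttentionProfile:
    """Per-patch raw attention scores and their softmax weights."""

    raw_scores: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.raw_scores = np.asarray(self.raw_scores, dtype=float).ravel()
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.raw_scores.size != self.weights.size:
            raise ValueError("raw_scores and weights must have equal length")


@dataclass
class RiskPrediction:
    """Model outputs for one sample."""

    lnm_probability: float
    dfs_risk_score: float
    predicted_time: float


def masked_copy(sample: Sample) -> Sample:
    """Missing-modality protocol: zero every omics entry of a sample.

    Idempotent; the image features are untouched and the modality mask is
    recorded on the omics vector.
    """
    return replace(sample, omics=sample.omics.zeroed())
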