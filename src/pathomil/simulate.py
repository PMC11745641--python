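"""Synthetic cohort generator with the statistical structure the model assumes.

A latent binary class per sample drives everything downstream, mirroring the
weak-supervision regime of slide-level labels:

* **bags** — each slide is a bag of ``K`` patch embeddings. Background
  patches are standard Gaussian ``N(0, I_d)``; in latent-positive bags an
  exact ``signal_fraction`` of patches is shifted by ``signal_shift`` along
  the fixed unit direction ``u = e_1``, giving attention something concrete
  to localize.
* **omics** — continuous blocks (mRNA, immune) have their means shifted by
  ``omics_effect * latent``; binary mutation indicators get the same shift on
  the logit scale from a 15% base rate.
* **outcomes** — the LNM label is ``Bernoulli(sigmoid(lnm_logit_scale *
  (2*latent - 1)))``; the DFS time is exponential with hazard
  ``baseline_hazard * exp(hazard_log_ratio * latent)``, right-censored by an
  independent Uniform(0, T_max) censoring time with T_max solved numerically
  so the expected censored fraction equals ``censor_rate``.

Everything is drawn from one seeded generator: identical configs (seed
included) reproduce the cohort exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .types import FeatureBag, OmicsVector, Sample, SurvivalOutcome

__all__ = ["SimConfig", "SyntheticCohort", "simulate_cohort", "simulate_slide_image"]

_MUTATION_BASE_RATE = 0.15
_TILE = 256


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the strong-signal regime used throughout the test suite:
    clearly separable classes in both the image and omics channels, a 2.0
    log hazard ratio, and a quarter of follow-ups censored.
    """

    n_samples: int = 200
    patches_min: int = 40
    patches_max: int = 60
    feature_dim: int = 32
    signal_fraction: float = 0.2
    signal_shift: float = 2.5
    omics_effect: float = 1.0
    lnm_logit_scale: float = 4.0
    baseline_hazard: float = 0.03  # events per month in the latent-negative class
    hazard_log_ratio: float = 2.0
    censor_rate: float = 0.25
    n_mrna: int = 1004
    n_mutations: int = 22
    n_immune: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "patches_min": self.patches_min,
            "patches_max": self.patches_max,
            "feature_dim": self.feature_dim,
            "n_mrna": self.n_mrna,
            "n_mutations": self.n_mutations,
            "n_immune": self.n_immune,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.patches_min > self.patches_max:
            raise ValueError("patches_min must not exceed patches_max")
        if not 0.0 < self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must lie in (0, 1]")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")


@dataclass
class SyntheticCohort:
    bags: list[FeatureBag]
    omics: list[OmicsVector]
    outcomes: list[SurvivalOutcome]
    latent_labels: np.ndarray
    signal_patch_index: list[np.ndarray] = field(repr=False)
    config: SimConfig | None = None

    def samples(self) -> list[Sample]:
        return [Sample(b, o, y) for b, o, y in zip(self.bags, self.omics, self.outcomes)]

    def __len__(self) -> int:
        return len(self.bags)


def _grid_coords(n: int) -> np.ndarray:
    """Row-major tile corners for n patches on a near-square grid."""
    cols = int(np.ceil(np.sqrt(n)))
    idx = np.arange(n)
    return np.stack([(idx % cols) * _TILE, (idx // cols) * _TILE], axis=1)


def _censoring_horizon(hazards: np.ndarray, censor_rate: float) -> float:
    """T_max of the Uniform(0, T_max) censoring law hitting the target rate.

    For T ~ Exp(h) and C ~ U(0, T_max), P(C < T) = (1 - exp(-h*T_max)) / (h*T_max);
    averaged over the cohort's realized hazards this is monotone decreasing in
    T_max, so a bracketed root always exists for censor_rate in (0, 1).
    """

    def expected_censored(t_max: float) -> float:
        x = hazards * t_max
        return float(np.mean(-np.expm1(-x) / x)) - censor_rate

    lo, hi = 1e-9, 1e3 / hazards.min()
    while expected_censored(hi) > 0:
        hi *= 10.0
    return float(brentq(expected_censored, lo, hi, xtol=1e-10, rtol=1e-12))


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort (bags, omics, censored outcomes) from one seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    d = config.feature_dim

    latent = rng.integers(0, 2, size=n)

    bags: list[FeatureBag] = []
    signal_index: list[np.ndarray] = []
    for i in range(n):
        k = int(rng.integers(config.patches_min, config.patches_max + 1))
        feats = rng.standard_normal((k, d))
        if latent[i] == 1:
            n_sig = int(round(config.signal_fraction * k))
            sig = np.sort(rng.choice(k, size=n_sig, replace=False))
            feats[sig, 0] += config.signal_shift  # planted signal along u = e_1
        else:
            sig = np.zeros(0, dtype=int)
        bags.append(
            FeatureBag(
                sample_id=f"S{i:04d}",
                features=feats,
                coords=_grid_coords(k),
                encoder_id="synthetic",
            )
        )
        signal_index.append(sig)

    shift = config.omics_effect * latent.astype(float)
    mrna = rng.standard_normal((n, config.n_mrna)) + shift[:, None]
    immune = rng.standard_normal((n, config.n_immune)) + shift[:, None]
    mut_logit = logit(_MUTATION_BASE_RATE) + shift
    mutations = (rng.random((n, config.n_mutations)) < expit(mut_logit)[:, None]).astype(float)
    omics = [OmicsVector(mrna=mrna[i], mutations=mutations[i], immune=immune[i]) for i in range(n)]

    lnm_prob = expit(config.lnm_logit_scale * (2.0 * latent.astype(float) - 1.0))
    lnm = (rng.random(n) < lnm_prob).astype(float)

    hazards = config.baseline_hazard * np.exp(config.hazard_log_ratio * latent.astype(float))
    event_times = rng.exponential(1.0 / hazards)
    if config.censor_rate > 0:
        t_max = _censoring_horizon(hazards, config.censor_rate)
        censor_times = rng.uniform(0.0, t_max, size=n)
        observed = np.minimum(event_times, censor_times)
        events = (event_times <= censor_times).astype(int)
    else:
        observed = event_times
        events = np.ones(n, dtype=int)
    observed = np.maximum(observed, 1e-9)  # times must stay strictly positive
    outcomes = [
        SurvivalOutcome(time_months=float(observed[i]), event=int(events[i]), lnm=float(lnm[i]))
        for i in range(n)
    ]

    return SyntheticCohort(
        bags=bags,
        omics=omics,
        outcomes=outcomes,
        latent_labels=latent.astype(int),
        signal_patch_index=signal_index,
        config=config,
    )


# H&E-like fill colors for the slide fixture (eosin pink / hematoxylin purple).
_TISSUE_COLORS = np.array([[228, 132, 181], [150, 80, 170]], dtype=float)
_NOISE_AMPLITUDE = 25


def simulate_slide_image(
    width: int,
    height: int,
    tissue_boxes: list[tuple[int, int, int, int]],
    seed: int = 0,
) -> np.ndarray:
    """Render a flat RGB slide fixture: white glass, textured tissue rectangles.

    ``tissue_boxes`` are ``(x, y, w, h)`` with the usual raster convention
    (x = column). Pixels inside boxes are pink/purple with seeded texture
    noise, clamped away from white so tissue segmentation has an unambiguous
    foreground. Deterministic for a given seed.
    """
    if width < 1 or height < 1:
        raise ValueError("canvas must be at least 1x1 px")
    img = np.full((height, width, 3), 255, dtype=np.uint8)
    rng = np.random.default_rng(seed)
    for x, y, w, h in tissue_boxes:
        if w < 1 or h < 1:
            raise ValueError("tissue boxes must have positive size")
        if x < 0 or y < 0 or x + w > width or y + h > height:
            raise ValueError(f"box {(x, y, w, h)} exceeds the {width}x{height} canvas")
        base = _TISSUE_COLORS[rng.integers(0, len(_TISSUE_COLORS))]
        noise = rng.integers(-_NOISE_AMPLITUDE, _NOISE_AMPLITUDE + 1, size=(h, w, 3))
        img[y : y + h, x : x + w] = np.clip(base[None, None, :] + noise, 10, 245).astype(np.uint8)
    return img
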