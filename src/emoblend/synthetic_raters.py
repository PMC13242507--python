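"""Generative rater simulation for blended-emotion judgment studies.

The simulator produces datasets with the statistical structure the analysis
assumes: a fully crossed design of actors x 10 pairwise emotion combinations
x 3 prominence conditions, judged by N simulated participants.

Generative model
----------------
Each stimulus carries a latent intensity vector over the five scales,

    mu_j = A * sum_{i in targets} w_i * C[i, j],

where A is the gain (peak expected rating of a fully expressed emotion),
w are the prominence weights of the condition (defaults (0.3, 0.7), (0.5,
0.5), (0.7, 0.3) -- a simulator convention encoding ordering, not a claim
of exact percentages), and C is a 5x5 confusion kernel with unit diagonal
whose off-diagonal entries describe how intended-emotion signal leaks into
other scales.  A rater perceives mu + Gaussian noise, clipped to [0, 10] and
(by default) rounded to the integer rating grid, then selects scales:
``top2`` (forced-two-scale format) keeps the two highest ratings with
random tie-breaking; ``threshold`` (free format) keeps every scale rated at
least tau, falling back to the single highest scale so that at least one
rating is always given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    ALL_COMBINATIONS,
    EMOTIONS,
    PROPORTIONS,
    Dataset,
    DataError,
    ResponseRecord,
    StimulusSpec,
    build_stimuli_index,
)

_E_INDEX = {e: i for i, e in enumerate(EMOTIONS)}


def default_confusion_kernel() -> np.ndarray:
    """Default leakage kernel: qualitative same-valence confusability.

    Encodes elevated leakage between anger and disgust and between fear and
    sadness, mild leakage among the remaining negative pairs, and near-zero
    cross-valence leakage with happiness.  Values are tunable conventions,
    not empirical fits.
    """
    c = np.eye(5)

    def set_pair(a: str, b: str, v: float) -> None:
        c[_E_INDEX[a], _E_INDEX[b]] = v
        c[_E_INDEX[b], _E_INDEX[a]] = v

    set_pair("anger", "disgust", 0.25)
    set_pair("fear", "sadness", 0.30)
    set_pair("anger", "fear", 0.10)
    set_pair("disgust", "sadness", 0.10)
    set_pair("disgust", "fear", 0.10)
    set_pair("anger", "sadness", 0.05)
    return c


DEFAULT_WEIGHTS: dict[str, tuple[float, float]] = {
    "30:70": (0.3, 0.7),
    "50:50": (0.5, 0.5),
    "70:30": (0.7, 0.3),
}


@dataclass
class RaterModelParams:
    """Generative parameters for the synthetic rater.

    Parameters
    ----------
    gain
        Peak expected rating of a fully expressed emotion (rating units).
    sigma
        SD of the additive Gaussian perception noise (rating units).
    weights
        Prominence weights per proportion condition, applied to the stored
        (first, second) emotion order; each pair sums to 1.
    kernel
        5x5 confusion kernel; unit diagonal, nonnegative entries.  Rows need
        not normalize (it models leakage, not a distribution).
    tau
        Selection threshold for the free (``threshold``) response format.
    discretize
        Round reported ratings to the integer 0-10 grid (the empirical
        response format).  Continuous ratings are used for null-calibration
        work where integer ties would bias the ordered index.
    actor_gain
        Optional per-actor multiplicative gain (defaults to 1 for all).
    seed
        Seed for the dataset-level random generator.
    """

    gain: float = 8.0
    sigma: float = 1.0
    weights: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS)
    )
    kernel: np.ndarray = field(default_factory=default_confusion_kernel)
    tau: float = 2.0
    discretize: bool = True
    actor_gain: Mapping[str, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kernel.shape != (5, 5):
            raise ValueError("confusion kernel must be 5x5")
        if not np.allclose(np.diag(self.kernel), 1.0):
            raise ValueError("confusion kernel diagonal must be 1")
        if (self.kernel < 0).any():
            raise ValueError("confusion kernel entries must be nonnegative")
        if self.sigma < 0:
            raise ValueError("noise sd must be >= 0")
        for prop, (w1, w2) in self.weights.items():
            if prop not in PROPORTIONS:
                raise ValueError(f"unknown proportion condition {prop!r}")
            if abs(w1 + w2 - 1.0) > 1e-9:
                raise ValueError(f"weights for {prop} must sum to 1")


def params_from_config(source: str | Path | Mapping) -> RaterModelParams:
    """Build params from a YAML/JSON file or a mapping.

    Recognized keys: gain, sigma, tau, discretize, seed, weights (mapping
    proportion -> [w1, w2]), kernel (5x5 nested list).  Unknown keys raise.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    if not isinstance(cfg, Mapping):
        raise ValueError("rater config must be a mapping")
    allowed = {"gain", "sigma", "tau", "discretize", "seed", "weights", "kernel",
               "actor_gain"}
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown rater config keys: {sorted(unknown)}")
    kwargs = dict(cfg)
    if "weights" in kwargs:
        kwargs["weights"] = {p: tuple(v) for p, v in kwargs["weights"].items()}
    if "kernel" in kwargs:
        kwargs["kernel"] = np.asarray(kwargs["kernel"], dtype=float)
    return RaterModelParams(**kwargs)


def build_design(
    n_actors: int = 6,
    combinations: tuple[tuple[str, str], ...] = ALL_COMBINATIONS,
    proportions: tuple[str, ...] = PROPORTIONS,
) -> list[StimulusSpec]:
    """Fully crossed stimulus design: n_actors x combinations x proportions.

    With the defaults (6 actors, 10 combinations, 3 proportions) this yields
    the 180-stimulus layout of the studies being emulated.
    """
    if n_actors < 1:
        raise ValueError("need at least 1 actor")
    specs = []
    for a in range(1, n_actors + 1):
        actor_id = f"actor{a:02d}"
        for first, second in combinations:
            for prop in proportions:
                sid = f"{actor_id}_{first[:4]}-{second[:4]}_{prop.replace(':', '')}"
                specs.append(
                    StimulusSpec(
                        stimulus_id=sid,
                        actor_id=actor_id,
                        emotion_first=first,
                        emotion_second=second,
                        proportion=prop,
                    )
                )
    return specs


def latent_means(s: StimulusSpec, p: RaterModelParams) -> np.ndarray:
    """Deterministic latent intensity vector mu for a stimulus (clipped)."""
    w1, w2 = p.weights[s.proportion]
    gain = p.gain
    if p.actor_gain is not None:
        gain = gain * float(p.actor_gain.get(s.actor_id, 1.0))
    mu = gain * (
        w1 * p.kernel[_E_INDEX[s.emotion_first]]
        + w2 * p.kernel[_E_INDEX[s.emotion_second]]
    )
    return np.clip(mu, 0.0, 10.0)


def perceive(
    s: StimulusSpec, p: RaterModelParams, rng: np.random.Generator
) -> np.ndarray:
    """One rater's full (pre-selection) rating vector over the 5 scales.

    mu + Gaussian noise, clipped to [0, 10]; rounded to integers when
    ``p.discretize`` (the default, matching the response format).
    """
    mu = latent_means(s, p)
    vals = np.clip(mu + rng.normal(0.0, p.sigma, size=5), 0.0, 10.0)
    if p.discretize:
        vals = np.round(vals)
    return vals


def select_scales(
    ratings: np.ndarray,
    policy: str,
    rng: np.random.Generator,
    tau: float = 2.0,
    participant_id: str = "",
    stimulus_id: str = "",
) -> ResponseRecord:
    """Turn a full rating vector into a selected-scales response.

    ``top2``: the two highest-rated scales, ties broken uniformly at random.
    ``threshold``: every scale rated >= tau; if none qualifies, the single
    highest-rated scale (ties random), so at least one rating is always
    given.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.shape != (5,):
        raise ValueError("expected a complete rating vector over the 5 scales")
    jitter = rng.random(5)  # random tie-break key
    order = np.lexsort((jitter, ratings))  # ascending ratings
    if policy == "top2":
        chosen = order[-2:]
    elif policy == "threshold":
        chosen = np.flatnonzero(ratings >= tau)
        if chosen.size == 0:
            chosen = order[-1:]
    else:
        raise ValueError(f"unknown selection policy {policy!r}")
    return ResponseRecord(
        participant_id=participant_id,
        stimulus_id=stimulus_id,
        ratings={EMOTIONS[i]: float(ratings[i]) for i in chosen},
    )


@dataclass
class SimulatedDataset:
    """A simulated :class:`Dataset` plus its generating latent means."""

    dataset: Dataset
    latent_means: pd.DataFrame  # stimulus_id x 5 scales

    def __getattr__(self, name):  # delegate convenience access
        return getattr(self.dataset, name)


def simulate_study(
    design: list[StimulusSpec],
    n_participants: int,
    params: RaterModelParams,
    mode: str = "forced2",
) -> SimulatedDataset:
    """Simulate a fully crossed study: every participant judges every stimulus.

    ``forced2`` uses the ``top2`` selection policy, ``free`` the
    ``threshold`` policy with ``params.tau``.  Regeneration with the same
    params (including seed) is byte-identical.
    """
    if mode not in ("forced2", "free"):
        raise DataError(f"unknown mode {mode!r}")
    if n_participants < 1:
        raise ValueError("need at least 1 participant")
    policy = "top2" if mode == "forced2" else "threshold"
    rng = np.random.default_rng(params.seed)
    stimuli = build_stimuli_index(design)
    responses: list[ResponseRecord] = []
    for pi in range(1, n_participants + 1):
        pid = f"p{pi:03d}"
        for s in design:
            ratings = perceive(s, params, rng)
            responses.append(
                select_scales(
                    ratings,
                    policy,
                    rng,
                    tau=params.tau,
                    participant_id=pid,
                    stimulus_id=s.stimulus_id,
                )
            )
    ds = Dataset(stimuli=stimuli, responses=responses, mode=mode)
    mu = pd.DataFrame(
        [latent_means(s, params) for s in design],
        index=[s.stimulus_id for s in design],
        columns=list(EMOTIONS),
    )
    return SimulatedDataset(dataset=ds, latent_means=mu)
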