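"""Exact chance levels for the accuracy indices under random responding.

A random responder picks an unordered subset of k of the m emotion scales
uniformly at random and fills the selected scales with independent,
exchangeable continuous ratings.  Against a stimulus with t = 2 intended
emotions, the probability of a correct response under each index is then a
pure combinatorial quantity, computed here by *exact enumeration* of all
C(m, k) selections (closed forms exist and are asserted equal in the test
suite).

Under the continuous-rating null, ties between the two target ratings have
probability zero, so the very-strict index equals the strict probability
times 1/2 (either prominence ordering is equally likely).  With integer
ratings ties are possible and score 0, pushing the simulated null slightly
below that value; the Monte-Carlo oracle therefore draws continuous ratings
by default, with an integer-rating option available as a conservative
variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations, permutations
from math import sqrt
from typing import Mapping

import numpy as np

from .data_model import EMOTIONS, ResponseRecord, StimulusSpec
from . import scoring

INDICES = ("generous", "strict", "very_strict")


@dataclass(frozen=True)
class ChanceLevel:
    """A chance probability for one index under one selection-count model."""

    index: str
    k_model: object  # fixed int k, or a mapping k -> weight
    probability: float


def _check_index(index: str) -> None:
    if index not in INDICES:
        raise ValueError(f"unknown accuracy index {index!r}")


def analytic_chance(index: str, k: int, m: int = 5, t: int = 2) -> float:
    """Exact chance probability for ``index`` with a fixed selection count k.

    Enumerates all C(m, k) unordered selections of k out of m scales against
    a fixed set of t target emotions:

    * generous -- selection intersects the targets;
    * strict -- selection covers all targets;
    * very_strict -- strict times 1/2 (continuous exchangeable ratings make
      either prominence ordering equally likely; ties have measure zero).
      Only defined for t = 2.
    """
    _check_index(index)
    if not 1 <= k <= m:
        raise ValueError(f"selection count k={k} outside [1, {m}]")
    if not 1 <= t <= m:
        raise ValueError(f"target count t={t} outside [1, {m}]")
    if index == "very_strict" and t != 2:
        raise ValueError("very_strict chance is only defined for t = 2 targets")
    targets = set(range(t))
    hits = 0
    covers = 0
    total = 0
    for sel in combinations(range(m), k):
        total += 1
        s = set(sel)
        if s & targets:
            hits += 1
        if targets <= s:
            covers += 1
    if index == "generous":
        return float(Fraction(hits, total))
    if index == "strict":
        return float(Fraction(covers, total))
    return float(Fraction(covers, total) / 2)


def forced_two_derivations(m: int = 5, t: int = 2) -> dict[str, float]:
    """The forced-two-scale chance quantities, by exact enumeration.

    Enumerates ordered pairs of distinct picks (for the sequential argument)
    and unordered 2-subsets (for the index probabilities); returns:

    * ``p_both_miss`` -- both selections miss the targets (0.30 for m=5, t=2);
    * ``generous`` -- at least one hit (0.70);
    * ``p_first_correct`` -- first of two sequential picks hits (0.40);
    * ``p_second_given_first`` -- second pick hits the remaining target,
      given the first hit (0.25);
    * ``strict`` -- both targets covered (0.10);
    * ``very_strict`` -- both covered with correct prominence order (0.05).
    """
    targets = set(range(t))
    pairs = list(combinations(range(m), 2))
    both_miss = sum(1 for p in pairs if not (set(p) & targets))
    covers = sum(1 for p in pairs if targets <= set(p))
    ordered = list(permutations(range(m), 2))
    first_hit = [o for o in ordered if o[0] in targets]
    both_hit = [o for o in first_hit if o[1] in targets]
    return {
        "p_both_miss": float(Fraction(both_miss, len(pairs))),
        "generous": float(1 - Fraction(both_miss, len(pairs))),
        "p_first_correct": float(Fraction(len(first_hit), len(ordered))),
        "p_second_given_first": float(Fraction(len(both_hit), len(first_hit))),
        "strict": float(Fraction(covers, len(pairs))),
        "very_strict": float(Fraction(covers, len(pairs)) / 2),
    }


def closed_form_chance(index: str, k: int, m: int = 5, t: int = 2) -> float:
    """Closed-form counterpart of :func:`analytic_chance` (binomial ratios)."""
    from math import comb

    _check_index(index)
    if not 1 <= k <= m:
        raise ValueError(f"selection count k={k} outside [1, {m}]")
    if index == "generous":
        return 1.0 - comb(m - t, k) / comb(m, k) if k <= m - t else 1.0
    strict = comb(m - t, k - t) / comb(m, k) if k >= t else 0.0
    if index == "strict":
        return strict
    return strict / 2


def mixture_chance(
    index: str, d: Mapping[int, float], m: int = 5, t: int = 2
) -> float:
    """Chance level under a distribution over selection counts k.

    ``d`` maps k in 1..m to nonnegative weights summing to 1 (within 1e-12).
    With a point mass at k this reduces to the fixed-k value.
    """
    _check_index(index)
    if not d:
        raise ValueError("empty selection-count distribution")
    total = float(sum(d.values()))
    if abs(total - 1.0) > 1e-12:
        raise ValueError(f"selection-count weights sum to {total!r}, not 1")
    if any(w < 0 for w in d.values()):
        raise ValueError("selection-count weights must be nonnegative")
    return float(
        sum(w * analytic_chance(index, k, m, t) for k, w in d.items() if w > 0)
    )


def empirical_k_distribution(ks: np.ndarray | list[int], m: int = 5) -> dict[int, float]:
    """Observed selection-count distribution from per-response counts."""
    ks = np.asarray(ks)
    if ks.size == 0:
        raise ValueError("no selection counts supplied")
    return {k: float((ks == k).mean()) for k in range(1, m + 1) if (ks == k).any()}


def simulate_random_responder(
    index: str,
    mode: str = "forced2",
    n_trials: int = 100_000,
    seed: int | None = None,
    k_weights: Mapping[int, float] | None = None,
    ratings: str = "continuous",
) -> tuple[float, float]:
    """Monte-Carlo estimate of a chance level, scored by the real scorers.

    Draws uniform unordered selections (size 2 under ``forced2``, size
    k ~ ``k_weights`` under ``free``) and independent uniform ratings on the
    selected scales, scores each trial with the :mod:`scoring` functions
    against a random target pair with random prominence, and returns
    ``(estimate, standard_error)``.  Reproducible given ``seed``.

    ``ratings='continuous'`` (default) matches the analytic null exactly;
    ``'integer'`` rounds ratings to the 0-10 grid, a conservative variant in
    which rating ties can fail the very-strict index.
    """
    _check_index(index)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if mode not in ("forced2", "free"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    m = len(EMOTIONS)

    if mode == "forced2":
        ks = np.full(n_trials, 2)
    else:
        if k_weights is None:
            raise ValueError("free mode requires k_weights")
        kvals = sorted(k_weights)
        probs = np.array([k_weights[k] for k in kvals], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("k_weights must sum to 1")
        ks = rng.choice(kvals, size=n_trials, p=probs)

    # fixed target pair with random prominence per trial
    target_pair = (EMOTIONS[0], EMOTIONS[1])
    prominence = rng.integers(0, 2, size=n_trials)  # 0 -> 70:30, 1 -> 30:70

    hits = np.empty(n_trials, dtype=float)
    spec_7030 = StimulusSpec("s", "a", target_pair[0], target_pair[1], "70:30")
    spec_3070 = StimulusSpec("s", "a", target_pair[0], target_pair[1], "30:70")
    scorer = {
        "generous": scoring.score_generous,
        "strict": scoring.score_strict,
        "very_strict": scoring.score_very_strict,
    }[index]
    for i in range(n_trials):
        k = int(ks[i])
        sel = rng.choice(m, size=k, replace=False)
        vals = rng.uniform(0.0, 10.0, size=k)
        if ratings == "integer":
            vals = np.round(vals)
        elif ratings != "continuous":
            raise ValueError(f"unknown ratings model {ratings!r}")
        record = ResponseRecord(
            "p", "s", {EMOTIONS[j]: float(v) for j, v in zip(sel, vals)}
        )
        spec = spec_3070 if prominence[i] else spec_7030
        hits[i] = float(scorer(record, spec))
    est = float(hits.mean())
    se = float(sqrt(est * (1.0 - est) / n_trials))
    return est, se


def chance_table(
    mode: str = "forced2",
    k_weights: Mapping[int, float] | None = None,
    m: int = 5,
):
    """Reference chance levels for all three indices as a DataFrame.

    In ``forced2`` mode (and as the free-mode general reference point) the
    fixed k = 2 anchors are reported; when an empirical selection-count
    distribution is supplied, the mixture values are reported alongside.
    """
    import pandas as pd

    rows = []
    for index in INDICES:
        rows.append(
            {
                "index": index,
                "k_model": "fixed k=2",
                "probability": analytic_chance(index, 2, m=m),
            }
        )
    if mode == "free" and k_weights is not None:
        for index in INDICES:
            rows.append(
                {
                    "index": index,
                    "k_model": "empirical mixture",
                    "probability": mixture_chance(index, k_weights, m=m),
                }
            )
    return pd.DataFrame(rows)
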