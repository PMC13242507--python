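"""Trial scoring under the three accuracy indices, and their aggregation.

Indices
-------
generous
    Correct if at least one selected scale names an intended emotion.
strict
    Correct if the selected scales cover *both* intended emotions.  In free
    mode the default policy is ``'superset'`` (extra selections allowed); an
    ``'exact'`` policy (selection == target pair) is available for
    sensitivity analysis.
very_strict
    Strict, plus the intended more-prominent emotion must receive a strictly
    higher rating than the less-prominent one.  Ties fail.  Defined only for
    the unequal-proportion conditions; equal-proportion trials are
    not-applicable (scored as missing, never 0).
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .data_model import Dataset, ResponseRecord, StimulusSpec

StrictPolicy = Literal["superset", "exact"]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class EmptyCellError(ValueError):
    """Raised when accuracy is requested for a cell with no trials."""


def score_generous(r: ResponseRecord, s: StimulusSpec) -> int:
    """1 iff the selected scales intersect the intended emotion pair."""
    return int(bool(r.selected & s.targets))


def score_strict(
    r: ResponseRecord, s: StimulusSpec, policy: StrictPolicy = "superset"
) -> int:
    """1 iff the selected scales cover both intended emotions.

    ``policy='superset'`` permits extra selections; ``'exact'`` requires the
    selection to equal the target pair.
    """
    if policy == "superset":
        return int(s.targets <= r.selected)
    if policy == "exact":
        return int(r.selected == s.targets)
    raise ValueError(f"unknown strict policy {policy!r}")


def score_very_strict(
    r: ResponseRecord, s: StimulusSpec, policy: StrictPolicy = "superset"
) -> int | None:
    """Strict correctness plus correct prominence ordering; ``None`` for 50:50.

    The more-prominent intended emotion must be rated *strictly* higher than
    the less-prominent one; equal ratings score 0.
    """
    if s.proportion == "50:50":
        return None
    if not score_strict(r, s, policy):
        return 0
    more, less = s.more_prominent, s.less_prominent
    assert more is not None and less is not None
    return int(r.ratings[more] > r.ratings[less])


def score_dataset(ds: Dataset, strict_policy: StrictPolicy = "superset") -> pd.DataFrame:
    """Score every trial; one row per response.

    Columns: participant_id, stimulus_id, actor_id, combination, proportion,
    k_selected, generous, strict, very_strict (NaN where not applicable).
    """
    rows = []
    for r in ds.responses:
        s = ds.stimulus_for(r)
        vs = score_very_strict(r, s, strict_policy)
        rows.append(
            (
                r.participant_id,
                r.stimulus_id,
                s.actor_id,
                s.combination_label,
                s.proportion,
                r.k_selected,
                score_generous(r, s),
                score_strict(r, s, strict_policy),
                math.nan if vs is None else float(vs),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "stimulus_id",
            "actor_id",
            "combination",
            "proportion",
            "k_selected",
            "generous",
            "strict",
            "very_strict",
        ],
    )


def _proportion_ci(
    successes: float, n: int, method: str
) -> tuple[float, float]:
    if method == "wald":
        low, high = proportion_confint(successes, n, alpha=0.05, method="normal")
    elif method == "wilson":
        low, high = proportion_confint(successes, n, alpha=0.05, method="wilson")
    else:
        raise ValueError(f"unknown ci_method {method!r}")
    return max(0.0, float(low)), min(1.0, float(high))


def _summarize_binary(
    values: np.ndarray, ci_method: str, chance: float
) -> dict[str, float | bool | int]:
    n = len(values)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    ci_low, ci_high = _proportion_ci(values.sum(), n, ci_method)
    return {
        "n": n,
        "mean": mean,
        "sd": sd,
        "ci_low": ci_low,
        "ci_high": ci_high,
        "chance": chance,
        "above_chance": bool(ci_low > chance),
    }


def _summarize_participant_means(
    frame: pd.DataFrame, index: str, chance: float
) -> dict[str, float | bool | int]:
    """Participant-level aggregation: mean/CI over per-participant proportions."""
    per_p = frame.groupby("participant_id")[index].mean()
    n = len(per_p)
    mean = float(per_p.mean())
    sd = float(per_p.std(ddof=1)) if n > 1 else 0.0
    half = Z_95 * sd / math.sqrt(n) if n > 1 else 0.0
    return {
        "n": n,
        "mean": mean,
        "sd": sd,
        "ci_low": max(0.0, mean - half),
        "ci_high": min(1.0, mean + half),
        "chance": chance,
        "above_chance": bool(mean - half > chance),
    }


def aggregate_accuracy(
    scores: pd.DataFrame,
    index: str,
    chance: float,
    by: tuple[str, ...] | None = ("combination", "proportion"),
    ci_method: str = "wald",
    unit: Literal["trial", "participant"] = "trial",
) -> pd.DataFrame:
    """Aggregate 0/1 trial scores for one index into accuracy cells.

    ``by=None`` produces a single overall row.  Default aggregation pools
    trials across participants and actors; ``unit='participant'`` instead
    averages per-participant proportions.  Equal-proportion trials are
    excluded for the very-strict index (not applicable there).

    Returns a frame with columns: index, [grouping...], n, mean, sd, ci_low,
    ci_high, chance, above_chance.
    """
    if index not in ("generous", "strict", "very_strict"):
        raise ValueError(f"unknown accuracy index {index!r}")
    sub = scores.dropna(subset=[index])
    if by:
        groups = list(sub.groupby(list(by), sort=True))
    else:
        groups = [((), sub)]
    if not groups or any(len(g) == 0 for _, g in groups):
        raise EmptyCellError(f"no trials to aggregate for index {index!r}")
    rows = []
    for key, g in groups:
        if not isinstance(key, tuple):
            key = (key,)
        if unit == "trial":
            summary = _summarize_binary(
                g[index].to_numpy(dtype=float), ci_method, chance
            )
        elif unit == "participant":
            summary = _summarize_participant_means(g, index, chance)
        else:
            raise ValueError(f"unknown aggregation unit {unit!r}")
        row: dict[str, object] = {"index": index}
        row.update(dict(zip(by or (), key)))
        row.update(summary)
        rows.append(row)
    out = pd.DataFrame(rows)
    if by is None:
        out.insert(1, "cell", "overall")
    return out


def scale_usage_summary(ds: Dataset) -> dict[str, object]:
    """Distribution of the number of scales selected per response.

    Returns counts and percentages by k (1-5), plus the mean and sample
    (n-1) standard deviation of k over responses.  Intended for free-mode
    data but defined for any dataset.
    """
    if not ds.responses:
        raise EmptyCellError("empty dataset: no responses to summarize")
    ks = np.array([r.k_selected for r in ds.responses])
    counts = {k: int((ks == k).sum()) for k in range(1, 6)}
    n = len(ks)
    return {
        "counts": counts,
        "percentages": {k: 100.0 * c / n for k, c in counts.items()},
        "mean": float(ks.mean()),
        "sd": float(ks.std(ddof=1)) if n > 1 else 0.0,
        "n": n,
    }


def cell_mean_ratings(ds: Dataset) -> pd.DataFrame:
    """Mean (and SD) rating per (combination, proportion, scale).

    Unselected scales contribute 0 to the averages: every response carries an
    implicit 0 on each scale it did not select.  Per-trial ratings are first
    averaged within participant (so each participant weighs equally in a
    cell), then across participants.
    """
    from .data_model import EMOTIONS

    rows = []
    for r in ds.responses:
        s = ds.stimulus_for(r)
        for e in EMOTIONS:
            rows.append(
                (
                    r.participant_id,
                    s.combination_label,
                    s.proportion,
                    e,
                    float(r.ratings.get(e, 0.0)),
                )
            )
    long = pd.DataFrame(
        rows, columns=["participant_id", "combination", "proportion", "scale", "rating"]
    )
    per_participant = (
        long.groupby(["combination", "proportion", "scale", "participant_id"])[
            "rating"
        ]
        .mean()
        .reset_index()
    )
    out = (
        per_participant.groupby(["combination", "proportion", "scale"])["rating"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0)
        .reset_index()
    )
    return out
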