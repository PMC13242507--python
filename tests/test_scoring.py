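"""Per-trial index scoring and accuracy aggregation."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emoblend import scoring
from emoblend.data_model import (
    Dataset,
    EMOTIONS,
    PROPORTIONS,
    ResponseRecord,
    StimulusSpec,
    build_stimuli_index,
)


def stim(first="anger", second="disgust", proportion="50:50"):
    return StimulusSpec("s", "a", first, second, proportion)


def resp(ratings):
    return ResponseRecord("p", "s", ratings)


class TestGenerous:
    @pytest.mark.parametrize(
        "ratings,first,second,expected",
        [
            ({"anger": 6, "fear": 2}, "anger", "disgust", 1),
            ({"fear": 3, "sadness": 5}, "anger", "disgust", 0),
            ({"anger": 1}, "anger", "happiness", 1),  # free-mode singleton
            ({"anger": 6, "disgust": 4}, "anger", "disgust", 1),
        ],
    )
    def test_definition(self, ratings, first, second, expected):
        assert scoring.score_generous(resp(ratings), stim(first, second)) == expected


class TestStrict:
    @pytest.mark.parametrize(
        "ratings,expected",
        [
            ({"anger": 6, "disgust": 4}, 1),
            ({"anger": 6, "fear": 4}, 0),
            ({"anger": 6, "disgust": 4, "fear": 1}, 1),  # superset allowed
        ],
    )
    def test_superset_policy(self, ratings, expected):
        assert scoring.score_strict(resp(ratings), stim()) == expected

    def test_exact_policy_rejects_superset(self):
        r = resp({"anger": 6, "disgust": 4, "fear": 1})
        assert scoring.score_strict(r, stim(), policy="exact") == 0
        assert scoring.score_strict(resp({"anger": 6, "disgust": 4}), stim(),
                                    policy="exact") == 1


class TestVeryStrict:
    def test_correct_order_scores_one(self):
        r = resp({"anger": 3, "disgust": 7})
        assert scoring.score_very_strict(r, stim(proportion="30:70")) == 1

    def test_tie_fails_strict_inequality(self):
        r = resp({"anger": 5, "disgust": 5})
        assert scoring.score_very_strict(r, stim(proportion="30:70")) == 0

    def test_wrong_order_fails(self):
        r = resp({"anger": 7, "disgust": 3})
        assert scoring.score_very_strict(r, stim(proportion="30:70")) == 0
        assert scoring.score_very_strict(r, stim(proportion="70:30")) == 1

    def test_equal_proportion_not_applicable(self):
        r = resp({"fear": 9, "sadness": 1})
        assert scoring.score_very_strict(r, stim("fear", "sadness", "50:50")) is None

    def test_requires_strict(self):
        r = resp({"anger": 3, "fear": 7})
        assert scoring.score_very_strict(r, stim(proportion="30:70")) == 0


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    sel=st.sets(st.sampled_from(EMOTIONS), min_size=1, max_size=5),
    vals=st.lists(st.integers(0, 10), min_size=5, max_size=5),
    pair=st.sampled_from(
        [(a, b) for a in EMOTIONS for b in EMOTIONS if a < b]
    ),
    proportion=st.sampled_from(PROPORTIONS),
)
def test_index_ordering_invariant(sel, vals, pair, proportion):
    """generous >= strict >= very_strict on arbitrary trials."""
    r = resp({e: v for e, v in zip(sorted(sel), vals)})
    s = stim(pair[0], pair[1], proportion)
    g = scoring.score_generous(r, s)
    st_ = scoring.score_strict(r, s)
    vs = scoring.score_very_strict(r, s)
    assert g >= st_
    if vs is not None:
        assert st_ >= vs


class TestAggregateAccuracy:
    def _scores(self, values, participant=None):
        n = len(values)
        return pd.DataFrame(
            {
                "participant_id": participant or ["p1"] * n,
                "combination": ["anger-disgust"] * n,
                "proportion": ["30:70"] * n,
                "generous": values,
                "strict": values,
                "very_strict": values,
                "k_selected": [2] * n,
            }
        )

    def test_all_correct_degenerate_ci(self):
        out = scoring.aggregate_accuracy(
            self._scores([1.0] * 10), "strict", chance=0.10, by=None
        )
        row = out.iloc[0]
        assert row["mean"] == 1.0 and row["sd"] == 0.0
        assert row["ci_low"] == pytest.approx(1.0) and row["ci_high"] == 1.0

    def test_wald_interval_closed_form(self):
        # n=100, 50 successes: 0.5 +/- 1.96 * sqrt(0.25/100)
        out = scoring.aggregate_accuracy(
            self._scores([1.0] * 50 + [0.0] * 50), "strict", chance=0.10, by=None
        )
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(0.5)
        assert row["ci_low"] == pytest.approx(0.402, abs=0.001)
        assert row["ci_high"] == pytest.approx(0.598, abs=0.001)

    def test_above_chance_decision_uses_ci_low(self):
        out = scoring.aggregate_accuracy(
            self._scores([1.0] * 50 + [0.0] * 50), "strict", chance=0.70, by=None
        )
        assert not out.iloc[0]["above_chance"]  # 0.598 < 0.70
        out2 = scoring.aggregate_accuracy(
            self._scores([1.0] * 50 + [0.0] * 50), "strict", chance=0.30, by=None
        )
        assert out2.iloc[0]["above_chance"]

    def test_pooling_of_disjoint_cells_is_trial_weighted(self):
        a = self._scores([1.0] * 30)
        a["combination"] = "anger-disgust"
        b = self._scores([0.0] * 10 + [1.0] * 10)
        b["combination"] = "fear-sadness"
        both = pd.concat([a, b], ignore_index=True)
        pooled = scoring.aggregate_accuracy(both, "strict", 0.1, by=None).iloc[0]
        expected = (30 * 1.0 + 20 * 0.5) / 50
        assert pooled["mean"] == pytest.approx(expected)
        assert pooled["n"] == 50

    def test_empty_cell_raises(self):
        empty = self._scores([]).astype({"generous": float})
        with pytest.raises(scoring.EmptyCellError):
            scoring.aggregate_accuracy(empty, "strict", 0.1, by=None)

    def test_participant_level_aggregation(self):
        scores = self._scores(
            [1.0, 1.0, 0.0, 0.0], participant=["p1", "p1", "p2", "p2"]
        )
        out = scoring.aggregate_accuracy(
            scores, "strict", 0.1, by=None, unit="participant"
        )
        row = out.iloc[0]
        assert row["n"] == 2  # participants, not trials
        assert row["mean"] == pytest.approx(0.5)

    def test_wilson_interval_available(self):
        out = scoring.aggregate_accuracy(
            self._scores([1.0] * 9 + [0.0]), "strict", 0.1, by=None,
            ci_method="wilson",
        )
        row = out.iloc[0]
        # Wilson interval never collapses to the point estimate
        assert 0 < row["ci_low"] < 0.9 < row["ci_high"] < 1


class TestScaleUsage:
    def test_all_two_scale(self, sim_forced2_small):
        usage = scoring.scale_usage_summary(sim_forced2_small.dataset)
        assert usage["mean"] == 2.0 and usage["sd"] == 0.0
        assert usage["percentages"][2] == 100.0

    def test_equal_mix_mean_and_sd(self):
        stimuli = build_stimuli_index(
            [StimulusSpec("s1", "a1", "anger", "disgust", "50:50")]
        )
        responses = []
        for i in range(200):
            for k, sel in [(1, ["anger"]), (2, ["anger", "disgust"]),
                           (3, ["anger", "disgust", "fear"])]:
                responses.append(
                    ResponseRecord(f"p{i}_{k}", "s1", {e: 5 for e in sel})
                )
        ds = Dataset(stimuli, responses, mode="free")
        usage = scoring.scale_usage_summary(ds)
        assert usage["mean"] == pytest.approx(2.0)
        assert usage["sd"] == pytest.approx(math.sqrt(2 / 3), abs=0.005)
        assert sum(usage["percentages"].values()) == pytest.approx(100.0)

    def test_empty_dataset_raises(self):
        ds = Dataset(stimuli={}, responses=[], mode="free")
        with pytest.raises(scoring.EmptyCellError):
            scoring.scale_usage_summary(ds)


class TestCellMeanRatings:
    def test_zero_imputation_single_response(self):
        stimuli = build_stimuli_index(
            [StimulusSpec("s1", "a1", "anger", "disgust", "50:50")]
        )
        ds = Dataset(
            stimuli,
            [ResponseRecord("p1", "s1", {"anger": 6, "disgust": 4})],
            mode="forced2",
        )
        table = scoring.cell_mean_ratings(ds).set_index("scale")
        assert table.loc["anger", "mean"] == 6
        assert table.loc["disgust", "mean"] == 4
        assert table.loc["fear", "mean"] == 0
        assert table.loc["happiness", "mean"] == 0

    def test_mean_over_responses(self):
        stimuli = build_stimuli_index(
            [
                StimulusSpec("s1", "a1", "anger", "disgust", "50:50"),
                StimulusSpec("s2", "a2", "anger", "disgust", "50:50"),
            ]
        )
        ds = Dataset(
            stimuli,
            [
                ResponseRecord("p1", "s1", {"anger": 6, "disgust": 4}),
                ResponseRecord("p1", "s2", {"anger": 4, "disgust": 4}),
            ],
            mode="forced2",
        )
        table = scoring.cell_mean_ratings(ds).set_index("scale")
        assert table.loc["anger", "mean"] == pytest.approx(5.0)

    def test_noise_free_simulation_recovers_latent_means(self, sim_noise_free):
        """With sigma=0 and identity kernel, cell means equal the rounded mu."""
        table = scoring.cell_mean_ratings(sim_noise_free.dataset)
        mu = sim_noise_free.latent_means
        ds = sim_noise_free.dataset
        by_cell = {}
        for sid, s in ds.stimuli.items():
            by_cell[(s.combination_label, s.proportion)] = np.round(
                mu.loc[sid].to_numpy()
            )
        for _, row in table.iterrows():
            expected_vec = by_cell[(row["combination"], row["proportion"])]
            e_idx = list(EMOTIONS).index(row["scale"])
            expected = expected_vec[e_idx]
            # only the two selected (target) scales carry the rounded mu;
            # unselected scales were imputed 0 and mu is 0 there too
            assert row["mean"] == pytest.approx(expected)


def test_forced2_trials_all_two_selections(sim_forced2_small):
    scores = scoring.score_dataset(sim_forced2_small.dataset)
    assert (scores["k_selected"] == 2).all()


def test_very_strict_na_exactly_for_equal_proportion(sim_forced2_small):
    scores = scoring.score_dataset(sim_forced2_small.dataset)
    na = scores["very_strict"].isna()
    assert (na == (scores["proportion"] == "50:50")).all()
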