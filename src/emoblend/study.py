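"""Model/Results interface for a blended-emotion perception study.

:class:`BlendedEmotionStudy` wraps a trial-level dataset (loaded from CSV or
simulated) the way a statsmodels model wraps its endog/exog: construction
binds the data, :meth:`~BlendedEmotionStudy.fit` runs the full analysis and
returns a :class:`StudyResults` object carrying accuracy tables, chance
levels, ANOVA summaries, post-hoc families, and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import chance, rm_stats, scoring
from .data_model import Dataset, PROPORTIONS, load_dataset, validate
from .synthetic_raters import (
    RaterModelParams,
    SimulatedDataset,
    build_design,
    simulate_study,
)

__version__ = "0.1.0"


@dataclass
class StudyResults:
    """Fitted results of a blended-emotion perception analysis.

    Attributes
    ----------
    trial_scores : DataFrame
        Per-trial 0/1 scores under the three indices.
    accuracy : DataFrame
        Per (combination x proportion) accuracy cells for all indices, with
        95% CIs, chance levels, and above-chance decisions.
    overall_accuracy : DataFrame
        Pooled overall accuracy per index.
    chance_levels : DataFrame
        The chance reference used for the above-chance decisions.
    anovas : DataFrame
        One repeated-measures ANOVA per scale x proportion (15 rows).
    target_contrasts : DataFrame
        The 24-contrast target-vs-non-target family per ANOVA (360 rows).
    order_tests : DataFrame
        The 20 prominence-order paired t-tests.
    scale_usage : dict or None
        Selection-count distribution (free-selection datasets).
    """

    mode: str
    ci_method: str
    strict_policy: str
    chance_reference: str
    trial_scores: pd.DataFrame
    accuracy: pd.DataFrame
    overall_accuracy: pd.DataFrame
    chance_levels: pd.DataFrame
    anovas: pd.DataFrame
    target_contrasts: pd.DataFrame
    order_tests: pd.DataFrame
    scale_usage: dict | None = None
    cell_means: pd.DataFrame | None = None

    def summary(self) -> str:
        """Readable multi-table overview of the fitted study."""
        lines = []
        lines.append("Blended-emotion perception study")
        lines.append("=" * 60)
        lines.append(
            f"mode: {self.mode}   ci: {self.ci_method}   "
            f"strict policy: {self.strict_policy}   "
            f"chance ref: {self.chance_reference}"
        )
        lines.append("")
        lines.append("Overall accuracy (pooled trials)")
        lines.append("-" * 60)
        for _, row in self.overall_accuracy.iterrows():
            lines.append(
                f"  {row['index']:<12} M = {row['mean']:.2f}  SD = {row['sd']:.2f}  "
                f"95% CI [{row['ci_low']:.2f}, {row['ci_high']:.2f}]  "
                f"chance = {row['chance']:.2f}  "
                f"{'above' if row['above_chance'] else 'NOT above'} chance"
            )
        if self.scale_usage is not None:
            lines.append("")
            lines.append(
                f"Scales used per response: M = {self.scale_usage['mean']:.2f} "
                f"(SD = {self.scale_usage['sd']:.2f})"
            )
        lines.append("")
        lines.append("Repeated-measures ANOVAs (one per scale x proportion)")
        lines.append("-" * 60)
        for _, row in self.anovas.iterrows():
            lines.append(
                f"  {row['scale']:<10} [{row['proportion']}]  "
                f"F({row['df_num']}, {row['df_den']}) = {row['F']:.2f}, "
                f"p_GG = {row['p_gg']:.2g}, eps = {row['gg_epsilon']:.2f}, "
                f"eta2_p = {row['eta2_partial']:.2f}, "
                f"eta2_G = {row['eta2_generalized']:.2f}"
            )
        n_sig_t = int(self.target_contrasts["significant"].sum())
        n_sig_o = int(self.order_tests["significant"].sum())
        lines.append("")
        lines.append(
            f"Target vs non-target contrasts: {n_sig_t}/"
            f"{len(self.target_contrasts)} significant at alpha = "
            f"{rm_stats.ALPHA_TARGET_CONTRASTS}"
        )
        lines.append(
            f"Prominence-order tests: {n_sig_o}/{len(self.order_tests)} "
            f"significant at alpha = {rm_stats.ALPHA_ORDER_TESTS}"
        )
        return "\n".join(lines)


class BlendedEmotionStudy:
    """A blended-emotion perception study bound to trial-level data.

    Parameters
    ----------
    dataset
        A validated :class:`~emoblend.data_model.Dataset` (or
        :class:`~emoblend.synthetic_raters.SimulatedDataset`).
    """

    def __init__(self, dataset: Dataset | SimulatedDataset):
        if isinstance(dataset, SimulatedDataset):
            self.latent_means = dataset.latent_means
            dataset = dataset.dataset
        else:
            self.latent_means = None
        errors = [f for f in validate(dataset) if f.startswith("ERROR")]
        if errors:
            raise ValueError(
                "dataset failed validation:\n" + "\n".join(errors[:10])
            )
        self.dataset = dataset

    @classmethod
    def from_csv(cls, path: str | Path, mode: str = "forced2") -> "BlendedEmotionStudy":
        return cls(load_dataset(path, mode=mode))

    @classmethod
    def from_simulation(
        cls,
        params: RaterModelParams | None = None,
        n_participants: int = 40,
        n_actors: int = 6,
        mode: str = "forced2",
        seed: int | None = None,
    ) -> "BlendedEmotionStudy":
        """Simulate a fully crossed study and bind it as model data."""
        if params is None:
            params = RaterModelParams(seed=seed)
        elif seed is not None:
            from dataclasses import replace

            params = replace(params, seed=seed)
        sim = simulate_study(build_design(n_actors), n_participants, params, mode)
        return cls(sim)

    def fit(
        self,
        ci_method: str = "wald",
        strict_policy: str = "superset",
        chance_reference: str = "fixed2",
        unit: str = "trial",
    ) -> StudyResults:
        """Run scoring, chance comparison, and rating-level inference.

        Parameters
        ----------
        ci_method : {'wald', 'wilson'}
            Interval for accuracy proportions.
        strict_policy : {'superset', 'exact'}
            Strict-index policy for free-selection data.
        chance_reference : {'fixed2', 'empirical'}
            ``fixed2`` anchors all indices at the two-selection chance
            levels (0.70 / 0.10 / 0.05); ``empirical`` mixes the exact
            per-k levels over the observed selection-count distribution.
        unit : {'trial', 'participant'}
            Pool binary trials (default) or aggregate per-participant
            proportions.
        """
        ds = self.dataset
        scores = scoring.score_dataset(ds, strict_policy=strict_policy)

        if chance_reference == "fixed2":
            chance_of = {i: chance.analytic_chance(i, 2) for i in chance.INDICES}
            k_weights = None
        elif chance_reference == "empirical":
            k_weights = chance.empirical_k_distribution(
                scores["k_selected"].to_numpy()
            )
            chance_of = {
                i: chance.mixture_chance(i, k_weights) for i in chance.INDICES
            }
        else:
            raise ValueError(f"unknown chance reference {chance_reference!r}")
        chance_tbl = chance.chance_table(
            mode=ds.mode, k_weights=k_weights
        )

        accuracy = pd.concat(
            [
                scoring.aggregate_accuracy(
                    scores, i, chance_of[i], by=("combination", "proportion"),
                    ci_method=ci_method, unit=unit,
                )
                for i in chance.INDICES
            ],
            ignore_index=True,
        )
        overall = pd.concat(
            [
                scoring.aggregate_accuracy(
                    scores, i, chance_of[i], by=None, ci_method=ci_method, unit=unit
                )
                for i in chance.INDICES
            ],
            ignore_index=True,
        )

        anovas = rm_stats.anova_table(ds)
        contrasts = pd.concat(
            [
                rm_stats.target_vs_nontarget_contrasts(ds, scale, prop)
                for scale in ("anger", "disgust", "fear", "happiness", "sadness")
                for prop in PROPORTIONS
            ],
            ignore_index=True,
        )
        order = rm_stats.proportion_order_tests(ds)

        usage = scoring.scale_usage_summary(ds) if ds.mode == "free" else None
        cell_means = scoring.cell_mean_ratings(ds)

        return StudyResults(
            mode=ds.mode,
            ci_method=ci_method,
            strict_policy=strict_policy,
            chance_reference=chance_reference,
            trial_scores=scores,
            accuracy=accuracy,
            overall_accuracy=overall,
            chance_levels=chance_tbl,
            anovas=anovas,
            target_contrasts=contrasts,
            order_tests=order,
            scale_usage=usage,
            cell_means=cell_means,
        )
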