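"""Rating-level inference: one-way within-subject ANOVA and post-hoc families.

The design analyzed here is a one-way repeated-measures layout: each
participant contributes one mean rating per emotion-combination condition
(10 levels) for a given rating scale within a given proportion condition.
The ANOVA uses the classical within-subject sum-of-squares decomposition

    SS_total = SS_subject + SS_condition + SS_error,

with F = MS_condition / MS_error on ((c-1), (c-1)(n-1)) degrees of freedom.
Sphericity is assessed with Mauchly's W; the primary p-value is the
Greenhouse-Geisser corrected one (epsilon-scaled degrees of freedom), since
rating data of this kind routinely violate sphericity.  Both partial eta
squared SS_c/(SS_c+SS_e) and generalized eta squared SS_c/(SS_c+SS_s+SS_e)
are reported; the latter is comparable across designs because it keeps
subject variance in the denominator.

Two Bonferroni-corrected post-hoc families are provided:

* target vs non-target contrasts: for each scale x proportion ANOVA, each of
  the 4 combinations containing the scale's emotion against each of the 6
  that do not (24 paired t-tests, alpha = 0.05/24 = 0.0021);
* prominence-order tests: for each combination in each unequal-proportion
  condition, the more-prominent target scale against the less-prominent one
  (20 paired t-tests, alpha = 0.05/20 = 0.0025).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    ALL_COMBINATIONS,
    EMOTIONS,
    Dataset,
)

#: Bonferroni-corrected alphas, reported at 4 decimals as is conventional.
ALPHA_TARGET_CONTRASTS = round(0.05 / 24, 4)  # 0.0021
ALPHA_ORDER_TESTS = round(0.05 / 20, 4)  # 0.0025


@dataclass(frozen=True)
class AnovaResult:
    """One-way repeated-measures ANOVA summary."""

    F: float
    df_num: int
    df_den: int
    p: float
    mauchly_w: float
    mauchly_p: float
    gg_epsilon: float
    p_gg: float
    eta2_partial: float
    eta2_generalized: float
    ss_condition: float
    ss_subject: float
    ss_error: float
    n_participants: int
    n_conditions: int
    degenerate: bool = False


def participant_cell_means(
    ds: Dataset, scale: str, proportion: str
) -> pd.DataFrame:
    """Per-participant mean rating on one scale per combination condition.

    Returns a wide frame (participants x 10 combinations).  Unselected
    scales contribute 0, consistently with the cell-mean tables.

    Raises
    ------
    ValueError
        If any participant has no trial in some combination condition.
    """
    if scale not in EMOTIONS:
        raise ValueError(f"unknown rating scale {scale!r}")
    rows = []
    for r in ds.responses:
        s = ds.stimulus_for(r)
        if s.proportion != proportion:
            continue
        rows.append(
            (r.participant_id, s.combination_label, float(r.ratings.get(scale, 0.0)))
        )
    if not rows:
        raise ValueError(f"no trials in proportion condition {proportion!r}")
    long = pd.DataFrame(rows, columns=["participant_id", "combination", "rating"])
    wide = long.pivot_table(
        index="participant_id", columns="combination", values="rating", aggfunc="mean"
    )
    expected = ["-".join(c) for c in ALL_COMBINATIONS]
    missing_cols = [c for c in expected if c not in wide.columns]
    if missing_cols or wide.isna().any().any():
        empty = list(missing_cols)
        for c in wide.columns:
            for p in wide.index[wide[c].isna()]:
                empty.append(f"{p}/{c}")
        raise ValueError(f"incomplete layout: empty participant cells: {empty[:10]}")
    return wide[expected]


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """A k x (k-1) orthonormal basis of the contrast space (Helmert-style)."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.linalg.norm(h[:, j - 1])
    return h


def rm_anova_oneway(wide: pd.DataFrame | np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA on a participants x conditions table.

    Implements the classical decomposition directly (rather than through a
    generic linear-model backend) so that the sum-of-squares components are
    exposed for effect sizes and invariant checks; results are cross-checked
    against an independent implementation in the test suite.

    Degenerate layouts with zero error variance are returned flagged
    (``degenerate=True``) rather than raising on division.
    """
    y = np.asarray(wide, dtype=float)
    if y.ndim != 2:
        raise ValueError("expected a 2-D participants x conditions table")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 participants and 2 conditions")
    if np.isnan(y).any():
        raise ValueError("incomplete layout: NaN cells present")

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_subject = float(k * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_condition = float(n * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_error = ss_total - ss_subject - ss_condition

    df_num = k - 1
    df_den = (k - 1) * (n - 1)

    # Sphericity quantities from the covariance of the orthonormalized
    # condition contrasts.
    s = np.cov(y, rowvar=False, ddof=1)
    c = _orthonormal_contrasts(k)
    a = c.T @ s @ c
    tr_a = float(np.trace(a))
    eps_floor = 1.0 / df_num

    scale = ss_error / df_den  # MS_error
    degenerate = ss_error <= 1e-12 * max(ss_total, 1.0)
    if degenerate:
        f_stat = 0.0 if ss_condition <= 1e-12 * max(ss_total, 1.0) else float("inf")
        p = 1.0 if f_stat == 0.0 else 0.0
        return AnovaResult(
            F=f_stat,
            df_num=df_num,
            df_den=df_den,
            p=p,
            mauchly_w=float("nan"),
            mauchly_p=float("nan"),
            gg_epsilon=float("nan"),
            p_gg=p,
            eta2_partial=0.0 if f_stat == 0.0 else 1.0,
            eta2_generalized=0.0
            if f_stat == 0.0
            else ss_condition / (ss_condition + ss_subject + ss_error),
            ss_condition=ss_condition,
            ss_subject=ss_subject,
            ss_error=ss_error,
            n_participants=n,
            n_conditions=k,
            degenerate=True,
        )

    f_stat = (ss_condition / df_num) / scale
    p = float(stats.f.sf(f_stat, df_num, df_den))

    # Mauchly's W with the standard chi-square approximation.
    det_a = float(np.linalg.det(a))
    w = det_a / (tr_a / df_num) ** df_num if tr_a > 0 else float("nan")
    if w <= 0 or not np.isfinite(w):
        mauchly_p = 0.0 if np.isfinite(w) else float("nan")
        w = max(w, 0.0) if np.isfinite(w) else float("nan")
    else:
        # Box's chi-square series to second order (as in R's ezANOVA).
        d = df_num
        f_corr = 1.0 - (2.0 * d**2 + d + 2.0) / (6.0 * d * (n - 1))
        w2 = (
            (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
            / (288.0 * ((n - 1) * d * f_corr) ** 2)
        )
        chi2 = -(n - 1) * f_corr * np.log(w)
        df_chi = k * (k - 1) // 2 - 1
        p1 = stats.chi2.sf(chi2, df_chi)
        p2 = stats.chi2.sf(chi2, df_chi + 4)
        mauchly_p = float(p1 + w2 * (p2 - p1))

    # Greenhouse-Geisser epsilon from the eigenstructure of the contrast
    # covariance; bounded in [1/(k-1), 1].
    gg_eps = tr_a**2 / (df_num * float(np.trace(a @ a)))
    gg_eps = float(min(1.0, max(eps_floor, gg_eps)))
    p_gg = float(stats.f.sf(f_stat, gg_eps * df_num, gg_eps * df_den))

    return AnovaResult(
        F=float(f_stat),
        df_num=df_num,
        df_den=df_den,
        p=p,
        mauchly_w=float(w),
        mauchly_p=mauchly_p,
        gg_epsilon=gg_eps,
        p_gg=p_gg,
        eta2_partial=ss_condition / (ss_condition + ss_error),
        eta2_generalized=ss_condition / (ss_condition + ss_subject + ss_error),
        ss_condition=ss_condition,
        ss_subject=ss_subject,
        ss_error=ss_error,
        n_participants=n,
        n_conditions=k,
    )


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired_t expects two equal-length 1-D samples, n >= 2")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), len(x) - 1, float(res.pvalue)


def target_combinations(scale: str) -> list[str]:
    """The 4 combinations containing ``scale``'s emotion (target conditions)."""
    if scale not in EMOTIONS:
        raise ValueError(f"unknown rating scale {scale!r}")
    return ["-".join(c) for c in ALL_COMBINATIONS if scale in c]


def target_vs_nontarget_contrasts(
    ds: Dataset, scale: str, proportion: str
) -> pd.DataFrame:
    """All 24 target-vs-non-target paired contrasts for one scale x proportion.

    Each of the 4 target combinations is tested against each of the 6
    non-target combinations on participants' cell means, two-sided, at the
    Bonferroni-corrected alpha 0.05/24.
    """
    wide = participant_cell_means(ds, scale, proportion)
    targets = target_combinations(scale)
    nontargets = [c for c in wide.columns if c not in targets]
    if len(targets) != 4 or len(nontargets) != 6:
        raise ValueError(
            f"expected a 4/6 target split for scale {scale!r}, got "
            f"{len(targets)}/{len(nontargets)}"
        )
    rows = []
    for tgt in targets:
        for non in nontargets:
            t_stat, df, p = paired_t(wide[tgt].to_numpy(), wide[non].to_numpy())
            rows.append(
                {
                    "scale": scale,
                    "proportion": proportion,
                    "contrast": f"{tgt} vs {non}",
                    "target": tgt,
                    "nontarget": non,
                    "mean_target": float(wide[tgt].mean()),
                    "mean_nontarget": float(wide[non].mean()),
                    "t": t_stat,
                    "df": df,
                    "p": p,
                    "alpha_corrected": ALPHA_TARGET_CONTRASTS,
                    "significant": bool(p < ALPHA_TARGET_CONTRASTS),
                    "family": "target_vs_nontarget",
                }
            )
    return pd.DataFrame(rows)


def proportion_order_tests(ds: Dataset) -> pd.DataFrame:
    """The 20 prominence-order paired t-tests (10 combinations x 2 conditions).

    For each combination in each unequal-proportion condition, participants'
    mean rating on the intended more-prominent emotion's scale is tested
    against their mean rating on the less-prominent emotion's scale,
    two-sided, at the Bonferroni-corrected alpha 0.05/20.  ``direction``
    records which emotion actually scored higher.
    """
    rows = []
    for combo in ALL_COMBINATIONS:
        label = "-".join(combo)
        for proportion in ("30:70", "70:30"):
            # relative to the canonical (alphabetical) stored order
            first, second = combo
            more, less = (
                (second, first) if proportion == "30:70" else (first, second)
            )
            means_more = participant_cell_means(ds, more, proportion)[label]
            means_less = participant_cell_means(ds, less, proportion)[label]
            t_stat, df, p = paired_t(means_more.to_numpy(), means_less.to_numpy())
            diff = float(means_more.mean() - means_less.mean())
            rows.append(
                {
                    "combination": label,
                    "proportion": proportion,
                    "more_prominent": more,
                    "less_prominent": less,
                    "mean_more": float(means_more.mean()),
                    "mean_less": float(means_less.mean()),
                    "mean_diff": diff,
                    "t": t_stat,
                    "df": df,
                    "p": p,
                    "alpha_corrected": ALPHA_ORDER_TESTS,
                    "significant": bool(p < ALPHA_ORDER_TESTS),
                    "direction": "more_rated_higher" if diff > 0 else "less_rated_higher",
                    "family": "proportion_order",
                }
            )
    return pd.DataFrame(rows)


def anova_table(ds: Dataset) -> pd.DataFrame:
    """One ANOVA per scale x proportion (15 rows), in reporting layout."""
    rows = []
    for scale in EMOTIONS:
        for proportion in PROPORTIONS_ORDER:
            wide = participant_cell_means(ds, scale, proportion)
            res = rm_anova_oneway(wide)
            rows.append(
                {
                    "scale": scale,
                    "proportion": proportion,
                    "F": res.F,
                    "df_num": res.df_num,
                    "df_den": res.df_den,
                    "p": res.p,
                    "p_gg": res.p_gg,
                    "gg_epsilon": res.gg_epsilon,
                    "mauchly_w": res.mauchly_w,
                    "mauchly_p": res.mauchly_p,
                    "eta2_partial": res.eta2_partial,
                    "eta2_generalized": res.eta2_generalized,
                    "degenerate": res.degenerate,
                }
            )
    return pd.DataFrame(rows)


PROPORTIONS_ORDER = ("30:70", "50:50", "70:30")
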