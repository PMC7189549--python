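"""Cohort grouping and statistical comparison of slide-level scores.

Slides carry ordinal severity ratings (a four-level none < sparse <
moderate < frequent scale per pathology), clinicopathological diagnosis
flags (control, AD, concomitant TDP-43 inclusions or Lewy body disease) and
an NIA-Reagan likelihood level.  Scores are compared across these groupings
with one-way ANOVA plus Tukey's HSD post-hoc test, two-sided independent
t-tests, Kruskal-Wallis (for outlier-heavy classes) and Spearman rank
correlation against the ordinal scales.

Diagnosis grouping rules:

* ``control``       -- no significant neurodegenerative pathology;
* ``pure_AD``       -- AD with no secondary diagnosis;
* ``all_AD``        -- every case with AD pathology;
* ``AD_TDP``        -- AD with TDP-43-positive inclusions;
* ``AD_LBD``        -- AD with Lewy body disease, excluding cases whose
  Lewy bodies are amygdala-predominant only;
* cases that are clinically control but show AD pathology at autopsy are
  excluded by default (toggleable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

CERAD_LEVELS = ("none", "sparse", "moderate", "frequent")
REAGAN_LEVELS = ("no", "low", "intermediate", "high")
REAGAN_MERGED = ("no/low", "intermediate", "high")


@dataclass(frozen=True)
class CohortRecord:
    """One slide's labels, diagnosis flags and scores."""

    slide_id: str
    cerad: Mapping[str, str] = field(default_factory=dict)  # class -> level
    reagan: str | None = None
    is_control: bool = False
    has_ad: bool = False
    has_tdp: bool = False
    has_lbd: bool = False
    amygdala_lbd_only: bool = False
    clinical_control_with_ad: bool = False
    scores_whole_tissue: Mapping[str, float] = field(default_factory=dict)
    scores_gray_matter: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for cls, lv in self.cerad.items():
            if lv not in CERAD_LEVELS:
                raise ValueError(f"unknown CERAD-like level {lv!r}")
        if self.reagan is not None and self.reagan not in REAGAN_LEVELS:
            raise ValueError(f"unknown NIA-Reagan level {self.reagan!r}")
        if self.is_control and self.has_ad:
            raise ValueError("a control record cannot carry an AD flag")


def assign_diagnosis_groups(
    records: Sequence[CohortRecord], exclude_clinical_controls: bool = True
):
    """Map diagnosis group name -> list of slide ids under the stated rules."""
    groups = {"control": [], "pure_AD": [], "all_AD": [], "AD_TDP": [], "AD_LBD": []}
    for rec in records:
        if exclude_clinical_controls and rec.clinical_control_with_ad:
            continue
        if rec.is_control and not rec.clinical_control_with_ad:
            groups["control"].append(rec.slide_id)
            continue
        has_ad = rec.has_ad or rec.clinical_control_with_ad
        if not has_ad:
            continue
        groups["all_AD"].append(rec.slide_id)
        lbd_counts = rec.has_lbd and not rec.amygdala_lbd_only
        if rec.has_tdp:
            groups["AD_TDP"].append(rec.slide_id)
        if lbd_counts:
            groups["AD_LBD"].append(rec.slide_id)
        if not rec.has_tdp and not rec.has_lbd and not rec.amygdala_lbd_only:
            groups["pure_AD"].append(rec.slide_id)
    return groups


def merge_reagan_levels(records: Sequence[CohortRecord]):
    """Collapse the NIA-Reagan 'no' and 'low' levels into one ordered group.

    Returns a dict over ``('no/low', 'intermediate', 'high')``; records
    without a Reagan level are dropped with a warning.
    """
    import warnings

    groups = {lv: [] for lv in REAGAN_MERGED}
    for rec in records:
        if rec.reagan is None:
            warnings.warn(f"record {rec.slide_id} has no Reagan level; dropped")
            continue
        merged = "no/low" if rec.reagan in ("no", "low") else rec.reagan
        groups[merged].append(rec.slide_id)
    return groups


@dataclass
class GroupComparison:
    grouping: str
    group_names: list
    group_sizes: list
    f_statistic: float
    anova_p: float
    tukey: list  # dicts: group1, group2, p_adj, reject, adjacent
    kruskal_h: float | None = None
    kruskal_p: float | None = None
    t_statistic: float | None = None
    t_p: float | None = None
    alpha: float = 0.05


def significance_stars(p: float) -> str:
    """Conventional star annotation at 0.05 / 0.01 / 0.001 / 0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return ""


def anova_tukey(scores_by_group: Mapping[str, Sequence[float]], alpha: float = 0.05,
                ordered: bool = True, grouping: str = "") -> GroupComparison:
    """One-way ANOVA with Tukey HSD post-hoc over all group pairs.

    ``ordered=True`` flags pairs of adjacent groups (in dict insertion
    order), mirroring how ordinal severity groups are reported.
    """
    names = list(scores_by_group)
    samples = [np.asarray(scores_by_group[g], dtype=float) for g in names]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least two observations")
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("zero within-group variance everywhere: F undefined")

    f_stat, p = sps.f_oneway(*samples)
    values = np.concatenate(samples)
    labels = np.concatenate([[g] * len(s) for g, s in zip(names, samples)])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    order = {g: i for i, g in enumerate(names)}
    tukey_rows = []
    for row in tk.summary().data[1:]:
        g1, g2 = str(row[0]), str(row[1])
        tukey_rows.append(
            {
                "group1": g1,
                "group2": g2,
                "p_adj": float(row[3]),
                "reject": bool(row[6]),
                "adjacent": ordered and abs(order[g1] - order[g2]) == 1,
            }
        )
    return GroupComparison(
        grouping=grouping,
        group_names=names,
        group_sizes=[len(s) for s in samples],
        f_statistic=float(f_stat),
        anova_p=float(p),
        tukey=tukey_rows,
        alpha=alpha,
    )


def two_sided_ttest(a, b):
    """Independent two-sample t-test (pooled variance), two-sided.

    Degenerate case: both samples constant with equal means -> (0.0, 1.0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def kruskal_wallis(scores_by_group: Mapping[str, Sequence[float]]):
    """Kruskal-Wallis H (tie-corrected) and chi-square p-value.

    Returns ``(nan, nan)`` when every observation is tied, for which the
    statistic is undefined.
    """
    samples = [np.asarray(v, dtype=float) for v in scores_by_group.values()]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    allv = np.concatenate(samples)
    if np.ptp(allv) == 0:
        return float("nan"), float("nan")
    h, p = sps.kruskal(*samples)
    return float(h), float(p)


def spearman_ordinal(scores, ordinal_labels, level_order=None):
    """Spearman rho between scores and ordinal labels (midrank ties).

    ``ordinal_labels`` may be integers or strings; strings are encoded by
    their position in ``level_order`` (default: the CERAD-like scale).
    Returns NaN when either variable is constant.
    """
    scores = np.asarray(scores, dtype=float)
    labels = list(ordinal_labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels differ in length")
    if len(scores) < 3:
        raise ValueError("need at least 3 observations")
    if labels and isinstance(labels[0], str):
        order = list(level_order) if level_order is not None else list(CERAD_LEVELS)
        labels = [order.index(lv) for lv in labels]
    labels = np.asarray(labels, dtype=float)
    if np.ptp(scores) == 0 or np.ptp(labels) == 0:
        return float("nan")
    return float(sps.spearmanr(scores, labels).statistic)
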