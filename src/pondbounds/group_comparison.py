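"""Metric comparisons across scientist-assigned waterbody types.

One-way ANOVA on the (optionally transformed) metric, Fisher's protected LSD
pairwise tests with a compact letter display, per-group coefficient of
variation on the raw scale, and a Levene/Brown-Forsythe homogeneity-of-variance
test.

The LSD letters satisfy: two groups share a letter iff their pairwise test
(pooled within-group mean square, its df) fails to reject at alpha.  Letters
are the maximal cliques of the non-significance graph, ordered by group mean.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .models import IDENTITY, LOG10

logger = logging.getLogger("pondbounds")


@dataclass
class GroupComparisonResult:
    """ANOVA + LSD letters + CV + Levene for one metric across waterbody types."""

    metric: str
    groups: dict[str, int]            # group label -> n
    f_stat: float
    df_between: int
    df_within: int
    anova_p: float
    lsd_letters: dict[str, str]       # group -> compact letter display ("" if LSD not run)
    pairwise_p: dict[tuple[str, str], float]
    cv: dict[str, float]              # on untransformed values
    levene_w: float
    levene_df: tuple[int, int]
    levene_p: float
    transform: str
    alpha: float


def _apply_transform(values: np.ndarray, transform: str, metric: str) -> np.ndarray:
    if transform == IDENTITY:
        return values
    if transform == LOG10:
        ok = values > 0
        dropped = int((~ok).sum())
        if dropped:
            logger.info("%s: dropped %d non-positive value(s) before log10", metric, dropped)
        return np.log10(values[ok])
    raise ValueError(f"unknown transform {transform!r}")


def compact_letter_display(
    groups: list[str], nonsig: set[frozenset], means: dict[str, float]
) -> dict[str, str]:
    """Letters from the maximal cliques of the non-significance graph.

    Every edge (non-significant pair) lies in some maximal clique, so sharing a
    letter is exactly failure to reject; singleton groups form their own clique.
    Cliques are lettered in order of their lowest group mean.
    """
    graph = nx.Graph()
    graph.add_nodes_from(groups)
    graph.add_edges_from(tuple(pair) for pair in nonsig)
    cliques = sorted(
        (sorted(c, key=lambda g: means[g]) for c in nx.find_cliques(graph)),
        key=lambda c: (min(means[g] for g in c), c),
    )
    letters: dict[str, list[str]] = {g: [] for g in groups}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for g in clique:
            letters[g].append(letter)
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def anova_lsd(
    records: pd.DataFrame,
    metric: str,
    group_col: str = "type",
    alpha: float = 0.05,
    transform: str = IDENTITY,
    protected: bool = True,
    levene_center: str = "median",
) -> GroupComparisonResult:
    """Classical one-way ANOVA with LSD post-hoc letters, CV and Levene's test.

    Parameters
    ----------
    transform
        Scale for the ANOVA/LSD ("log10" or "identity"); CV is always computed
        on the untransformed values.
    protected
        Run the LSD pairwise tests only when the omnibus ANOVA is significant
        at ``alpha`` (Fisher-protected LSD, default).  When the omnibus test is
        not significant all groups share one letter.
    levene_center
        "median" (Brown-Forsythe, default) or "mean".
    """
    if metric not in records.columns:
        raise ValueError(f"metric column {metric!r} missing")
    if group_col not in records.columns:
        raise ValueError(f"group column {group_col!r} missing")
    frame = records[[group_col, metric]].dropna()
    if frame.empty:
        raise ValueError(f"metric column {metric!r} has no data")
    raw: dict[str, np.ndarray] = {}
    trans: dict[str, np.ndarray] = {}
    for label, sub in frame.groupby(group_col, observed=True):
        values = sub[metric].to_numpy(dtype=float)
        t = _apply_transform(values, transform, metric)
        if len(t) >= 2:
            raw[label] = values
            trans[label] = t
    labels = sorted(trans)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations each")

    samples = [trans[g] for g in labels]
    ns = {g: len(trans[g]) for g in labels}
    means = {g: float(np.mean(trans[g])) for g in labels}
    n_total = sum(ns.values())
    df_between = len(labels) - 1
    df_within = n_total - len(labels)
    f_stat, anova_p = stats.f_oneway(*samples)
    # pooled within-group mean square for the LSD tests
    ms_within = sum(float(np.sum((trans[g] - means[g]) ** 2)) for g in labels) / df_within

    pairwise: dict[tuple[str, str], float] = {}
    for i, gi in enumerate(labels):
        for gj in labels[i + 1:]:
            se = np.sqrt(ms_within * (1.0 / ns[gi] + 1.0 / ns[gj]))
            t = (means[gi] - means[gj]) / se
            pairwise[(gi, gj)] = float(2.0 * stats.t.sf(abs(t), df_within))

    run_lsd = (not protected) or (anova_p < alpha)
    if run_lsd:
        nonsig = {frozenset(pair) for pair, p in pairwise.items() if p >= alpha}
        letters = compact_letter_display(labels, nonsig, means)
    else:
        letters = {g: "a" for g in labels}

    cv = {g: float(np.std(raw[g], ddof=1) / np.mean(raw[g])) for g in labels}
    levene_w, levene_p = stats.levene(*samples, center=levene_center)

    return GroupComparisonResult(
        metric=metric,
        groups=ns,
        f_stat=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        anova_p=float(anova_p),
        lsd_letters=letters,
        pairwise_p=pairwise,
        cv=cv,
        levene_w=float(levene_w),
        levene_df=(df_between, df_within),
        levene_p=float(levene_p),
        transform=transform,
        alpha=alpha,
    )
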