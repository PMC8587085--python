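"""Sensor ranking from channel-wise attention weights.

Each test-set window contributes one attention vector (length 20); per
channel these values form the groups of a classical fixed-effects one-way
ANOVA. When the ANOVA rejects, a post-hoc Tukey HSD test with pairwise
p-values from the studentized-range distribution identifies homogeneous
subsets — runs of channels, consecutive in mean-sorted order, with no
significant pairwise difference — reproducing the staircase-style subset
table used to read off which sensors matter. A separate axis-grouped
comparison pools accelerometer and gyroscope channels by axis (x, y, z)
to test vertical- versus horizontal-axis contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .channels import AXIS_GROUPS, CHANNEL_IDS, N_CHANNELS


@dataclass
class AnovaTable:
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    df_total: int
    ms_between: float
    ms_within: float
    f_statistic: float
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        """SS/df/MS/F/p table in the conventional three-row layout."""
        return pd.DataFrame(
            {
                "SS": [self.ss_between, self.ss_within, self.ss_total],
                "df": [self.df_between, self.df_within, self.df_total],
                "MS": [self.ms_between, self.ms_within, np.nan],
                "F": [self.f_statistic, np.nan, np.nan],
                "p": [self.p_value, np.nan, np.nan],
            },
            index=["between groups", "within groups", "total"],
        )


@dataclass
class TukeyResult:
    group_names: list[str]
    group_means: np.ndarray
    group_ns: np.ndarray
    pairwise_p: np.ndarray  # (k, k) symmetric, 1 on the diagonal
    alpha: float
    ms_within: float
    df_within: int
    homogeneous_subsets: list[dict] | None = None  # filled by homogeneous_subsets()


def one_way_anova(groups: list[np.ndarray]) -> AnovaTable:
    """Classical fixed-effects one-way ANOVA over k groups of observations."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    ns = np.array([len(g) for g in groups])
    N = int(ns.sum())
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - m) ** 2) for g, m in zip(groups, means)))
    df_between, df_within = k - 1, N - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        raise ValueError("zero within-group variance: ANOVA degenerate")
    f = ms_between / ms_within
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaTable(
        ss_between=ss_between,
        ss_within=ss_within,
        ss_total=ss_between + ss_within,
        df_between=df_between,
        df_within=df_within,
        df_total=N - 1,
        ms_between=ms_between,
        ms_within=ms_within,
        f_statistic=f,
        p_value=p,
    )


def tukey_hsd(
    groups: list[np.ndarray],
    alpha: float = 0.05,
    group_names: list[str] | None = None,
) -> TukeyResult:
    """All-pairs Tukey HSD using the studentized-range distribution.

    The pairwise standard error is sqrt(ms_within/2 * (1/n_a + 1/n_b)), which
    reduces to the textbook sqrt(ms_within/n) for equal group sizes
    (harmonic-mean convention for unequal ones).
    """
    anova = one_way_anova(groups)
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    names = list(group_names) if group_names else [f"g{i}" for i in range(k)]
    means = np.array([g.mean() for g in groups])
    ns = np.array([len(g) for g in groups])
    p = np.ones((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            se = np.sqrt(anova.ms_within / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q = abs(means[a] - means[b]) / se
            pv = float(sps.studentized_range.sf(q, k, anova.df_within))
            p[a, b] = p[b, a] = min(1.0, pv)
    return TukeyResult(
        group_names=names,
        group_means=means,
        group_ns=ns,
        pairwise_p=p,
        alpha=alpha,
        ms_within=anova.ms_within,
        df_within=anova.df_within,
    )


def homogeneous_subsets(tukey: TukeyResult) -> list[dict]:
    """Maximal runs of mean-sorted groups with no significant pairwise gap.

    Groups are sorted by mean ascending; every maximal consecutive run whose
    pairwise p-values all exceed alpha forms one subset (overlaps allowed, as
    in staircase subset tables). Each subset reports the extreme-pair p (the
    smallest-mean vs largest-mean member), the value printed in the table
    footer. Singleton subsets (p = 1) appear for groups in no wider run.
    """
    order = np.argsort(tukey.group_means, kind="stable")
    k = len(order)
    p = tukey.pairwise_p
    runs: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and all(
            p[order[a], order[j + 1]] > tukey.alpha for a in range(i, j + 1)
        ):
            j += 1
        runs.append((i, j))
    # keep maximal runs only
    maximal = [(i, j) for (i, j) in runs
               if not any(a <= i and j <= b and (a, b) != (i, j) for a, b in runs)]
    subsets = []
    for i, j in maximal:
        members = [tukey.group_names[order[t]] for t in range(i, j + 1)]
        extreme_p = 1.0 if i == j else float(p[order[i], order[j]])
        subsets.append({"members": members, "p": extreme_p})
    tukey.homogeneous_subsets = subsets
    return subsets


def subset_table(tukey: TukeyResult) -> pd.DataFrame:
    """Staircase subset table: sensor rows (mean-ascending), subset columns.

    Cells hold the group mean where the sensor belongs to the column's
    subset; the last row holds each subset's extreme-pair p-value.
    """
    subsets = tukey.homogeneous_subsets or homogeneous_subsets(tukey)
    order = np.argsort(tukey.group_means, kind="stable")
    rows = [tukey.group_names[i] for i in order]
    table = pd.DataFrame(index=rows + ["p-value"],
                         columns=[str(c + 1) for c in range(len(subsets))],
                         dtype=float)
    for c, sub in enumerate(subsets):
        for name in sub["members"]:
            i = tukey.group_names.index(name)
            table.loc[name, str(c + 1)] = tukey.group_means[i]
        table.loc["p-value", str(c + 1)] = sub["p"]
    return table


def axis_group_comparison(att_matrix: np.ndarray, alpha: float = 0.05) -> dict:
    """Pool IMU channels by axis and compare x vs y vs z attention weights.

    Pressure channels are excluded; each axis group pools 4 channels
    (accelerometer + gyroscope, both feet) over all windows, so group sizes
    are 4 x n_windows.
    """
    att_matrix = np.asarray(att_matrix, dtype=float)
    if att_matrix.ndim != 2 or att_matrix.shape[1] != N_CHANNELS:
        raise ValueError(f"att_matrix must be (n_windows, {N_CHANNELS})")
    groups = {ax: att_matrix[:, cols].ravel() for ax, cols in AXIS_GROUPS.items()}
    names = list(groups)
    anova = one_way_anova([groups[ax] for ax in names])
    tukey = tukey_hsd([groups[ax] for ax in names], alpha=alpha, group_names=names)
    homogeneous_subsets(tukey)
    return {
        "axis_means": {ax: float(groups[ax].mean()) for ax in names},
        "anova": anova,
        "tukey": tukey,
        "pairwise_p": {
            f"{a}-{b}": float(tukey.pairwise_p[names.index(a), names.index(b)])
            for a, b in (("x", "y"), ("x", "z"), ("y", "z"))
        },
    }


def rank_sensors(fold_results, alpha: float = 0.05) -> dict:
    """Pool attention vectors across LOSO folds and rank the 20 channels.

    Returns the ANOVA table, the Tukey result with homogeneous subsets, and a
    report DataFrame with channels sorted by mean attention (descending) and
    their subset memberships.
    """
    mats = [f.att_matrix for f in fold_results]
    if not mats or any(m is None for m in mats):
        raise ValueError("attention disabled in at least one fold; cannot rank")
    att = np.vstack(mats)
    groups = [att[:, c] for c in range(N_CHANNELS)]
    anova = one_way_anova(groups)
    tukey = tukey_hsd(groups, alpha=alpha, group_names=list(CHANNEL_IDS))
    subsets = homogeneous_subsets(tukey)
    membership = {
        name: [i + 1 for i, s in enumerate(subsets) if name in s["members"]]
        for name in CHANNEL_IDS
    }
    report = pd.DataFrame(
        {
            "channel": CHANNEL_IDS,
            "mean_attention": tukey.group_means,
            "subsets": [membership[c] for c in CHANNEL_IDS],
        }
    ).sort_values("mean_attention", ascending=False, ignore_index=True)
    return {"anova": anova, "tukey": tukey, "subsets": subsets, "report": report,
            "att_matrix": att}
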