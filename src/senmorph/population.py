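"""Population-level metrics: cumulative population doubling, coefficient of
variation, and the standard statistical comparison battery.

Population doubling between two counts is PD = log2(N(t)/N(t0)) — one literal
doubling contributes exactly 1 — and the cumulative population doubling (CPD)
is the running sum of per-passage PDs, the standard long-term proliferation
readout for cultures that are repeatedly counted and reseeded.

Group comparisons follow the conventional decision tree: Shapiro-Wilk
normality screen on every group; all normal -> t-test (two groups) or one-way
ANOVA with Tukey HSD (three or more); otherwise Mann-Whitney U (two) or
Kruskal-Wallis with Bonferroni-corrected pairwise Mann-Whitney (three or
more).  Proportions are compared by chi-square.  Everything is delegated to
scipy.stats / statsmodels; significance stars follow * p<=0.05, ** p<=0.01,
*** p<=0.001.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import InputError, UndefinedStatisticError

__all__ = [
    "GrowthSeries",
    "population_doubling",
    "cumulative_pd",
    "coefficient_of_variation",
    "compare_groups",
    "chi_square_proportions",
    "stars",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


def stars(p: float) -> str:
    """Significance stars: * p<=0.05, ** p<=0.01, *** p<=0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def population_doubling(n_t: float, n_t0: float) -> float:
    """Population doublings between two counts: log2(n_t / n_t0)."""
    if n_t <= 0 or n_t0 <= 0:
        raise InputError("cell counts must be positive")
    return (math.log(n_t) - math.log(n_t0)) / math.log(2)


@dataclass
class GrowthSeries:
    """Passage-wise growth record with per-interval PD and cumulative PD."""

    timepoints: np.ndarray   # days, one per passage boundary (first = t0)
    counts: np.ndarray       # counted cells per well at each timepoint
    seeded: np.ndarray       # cells seeded at the start of each interval
    pd_per_interval: np.ndarray
    cpd: np.ndarray          # running sum; cpd[0] = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "timepoint": self.timepoints,
            "count": self.counts,
            "seeded": self.seeded,
            "pd": self.pd_per_interval,
            "cpd": self.cpd,
        })


def cumulative_pd(
    timepoints: Sequence[float],
    counts: Sequence[float],
    seeded: Sequence[float] | float,
) -> GrowthSeries:
    """Cumulative population doubling over passages.

    ``counts[i]`` is the cell number counted at ``timepoints[i]`` (i >= 1) and
    ``seeded`` the number plated at the start of each interval (a scalar if
    constant).  ``counts[0]`` is the initial seeding; its PD is 0 by
    definition.  CPD is monotone nondecreasing iff every passage grew.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if len(timepoints) < 2 or len(timepoints) != len(counts):
        raise InputError("need >= 2 matched timepoints and counts")
    if np.any(np.diff(timepoints) <= 0):
        raise InputError("timepoints must be strictly increasing")
    if np.isscalar(seeded):
        seeded = np.full(len(counts), float(seeded))
    else:
        seeded = np.asarray(seeded, dtype=float)
    pds = np.zeros(len(counts))
    for i in range(1, len(counts)):
        pds[i] = population_doubling(counts[i], seeded[i - 1])
    return GrowthSeries(
        timepoints=timepoints,
        counts=counts,
        seeded=seeded,
        pd_per_interval=pds,
        cpd=np.cumsum(pds),
    )


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample coefficient of variation: SD (n-1 denominator) / mean."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise InputError("need >= 2 values for a CV")
    mean = values.mean()
    if mean == 0:
        raise UndefinedStatisticError("CV undefined for zero mean")
    return float(values.std(ddof=1) / mean)


def _normality_screen(groups: Mapping[str, np.ndarray]) -> tuple[bool, dict[str, float]]:
    """Shapiro-Wilk on every group; returns (all_normal, p-values)."""
    pvals: dict[str, float] = {}
    for name, vals in groups.items():
        if len(vals) < 3:
            logger.info("group %s has n < 3; forcing non-parametric branch", name)
            return False, pvals
        if np.ptp(vals) == 0:
            return False, pvals  # Shapiro undefined for constant data
        pvals[name] = float(stats.shapiro(vals).pvalue)
    return all(p > ALPHA for p in pvals.values()), pvals


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Standard comparison battery over named groups of values.

    Normality screen, then t-test / ANOVA+Tukey (normal) or Mann-Whitney /
    Kruskal-Wallis + Bonferroni-corrected pairwise Mann-Whitney (non-normal).
    Returns one row per comparison with test name, statistic, raw and adjusted
    p-values, and significance stars.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(groups) < 2:
        raise InputError("need >= 2 groups")
    names = list(groups)
    all_normal, _ = _normality_screen(groups)
    rows: list[dict] = []
    if len(groups) == 2:
        a, b = (groups[n] for n in names)
        if all_normal:
            res = stats.ttest_ind(a, b)
            test = "t-test"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "mann-whitney"
        p = float(res.pvalue)
        rows.append({"group_a": names[0], "group_b": names[1], "test": test,
                     "statistic": float(res.statistic), "p": p, "p_adjusted": p,
                     "stars": stars(p)})
    elif all_normal:
        values = np.concatenate([groups[n] for n in names])
        labels = np.concatenate([[n] * len(groups[n]) for n in names])
        omni = stats.f_oneway(*(groups[n] for n in names))
        rows.append({"group_a": "all", "group_b": "all", "test": "anova",
                     "statistic": float(omni.statistic), "p": float(omni.pvalue),
                     "p_adjusted": float(omni.pvalue), "stars": stars(float(omni.pvalue))})
        tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
        tk = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
        for _, row in tk.iterrows():
            p = float(row["p-adj"])
            rows.append({"group_a": str(row["group1"]), "group_b": str(row["group2"]),
                         "test": "tukey", "statistic": float(row["meandiff"]),
                         "p": p, "p_adjusted": p, "stars": stars(p)})
    else:
        omni = stats.kruskal(*(groups[n] for n in names))
        rows.append({"group_a": "all", "group_b": "all", "test": "kruskal-wallis",
                     "statistic": float(omni.statistic), "p": float(omni.pvalue),
                     "p_adjusted": float(omni.pvalue), "stars": stars(float(omni.pvalue))})
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        m = len(pairs)
        for a, b in pairs:
            res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            p = float(res.pvalue)
            p_adj = min(1.0, p * m)  # Bonferroni
            rows.append({"group_a": a, "group_b": b, "test": "mann-whitney+bonferroni",
                         "statistic": float(res.statistic), "p": p,
                         "p_adjusted": p_adj, "stars": stars(p_adj)})
    return pd.DataFrame(rows)


def chi_square_proportions(table: np.ndarray | pd.DataFrame) -> dict:
    """Chi-square test on a contingency table of counts."""
    table = np.asarray(table, dtype=float)
    chi2, p, dof, _ = stats.chi2_contingency(table)
    return {"test": "chi-square", "statistic": float(chi2), "p": float(p),
            "dof": int(dof), "stars": stars(float(p))}
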