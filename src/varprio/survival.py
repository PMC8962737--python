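"""Mutation-stratified survival comparison.

Patients are split by deleterious-mutation status in a gene (within one
tumor group) and their disease-free survival times are compared with an
exact two-tailed unpaired Wilcoxon rank-sum (Mann-Whitney U) test.  For
small tie-free samples the p-value comes from the full null distribution of
U (every rank assignment equally likely); ties or larger samples fall back
to the mid-rank normal approximation with tie and continuity correction.

Kaplan-Meier curves and the one-degree-of-freedom log-rank test support
expression- or mutation-stratified survival of larger (synthetic or
user-supplied) cohorts; they are backed by lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .classify import DeleteriousVerdict
from .io import ClinicalRecord, TumorGroup

__all__ = [
    "SurvivalComparison",
    "KMCurve",
    "DegenerateStratificationError",
    "stratify_by_mutation",
    "wilcoxon_rank_sum",
    "group_means",
    "compare_survival",
    "km_estimate",
    "logrank_test",
    "survival_gain_at",
]


class DegenerateStratificationError(ValueError):
    """One of the two comparison groups is empty."""


@dataclass
class SurvivalComparison:
    """Two-group rank-sum comparison of survival times for one gene."""

    gene: str
    group_mutant: list[float]
    group_wildtype: list[float]
    mean_mutant: float
    mean_wildtype: float
    u_statistic: float
    p_two_tailed: float
    method: str  # "exact_enumeration" | "normal_approximation"


def stratify_by_mutation(
    clinical: Sequence[ClinicalRecord],
    verdicts: Iterable[DeleteriousVerdict],
    gene: str,
    group: TumorGroup | str,
) -> tuple[list[float], list[float]]:
    """Partition the cohort's DFS times by deleterious-mutation status.

    A patient is *mutant* when they carry at least one deleterious verdict
    in *gene* within the requested tumor *group*; everyone else in the
    clinical table is wild-type.  Every patient lands in exactly one list
    (ordered as in the clinical table).
    """
    group = TumorGroup(group)
    mutant_ids = {
        verd.variant.patient_id
        for verd in verdicts
        if verd.deleterious
        and verd.variant.gene == gene
        and verd.variant.tumor_group is group
    }
    known = {rec.patient_id for rec in clinical}
    missing = sorted(mutant_ids - known)
    if missing:
        raise KeyError(
            f"patients with verdicts but no clinical record: {', '.join(missing)}"
        )
    mutant = [r.dfs_months for r in clinical if r.patient_id in mutant_ids]
    wildtype = [r.dfs_months for r in clinical if r.patient_id not in mutant_ids]
    return mutant, wildtype


@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> tuple[int, ...]:
    """Null distribution of the Mann-Whitney U statistic of the size-``n``
    group against size ``m``: counts of rank assignments per U in 0..n*m.

    Classic counting recurrence: f(n, m, u) = f(n-1, m, u-m) + f(n, m-1, u).
    """
    if n == 0 or m == 0:
        return (1,)
    counts = np.zeros((n + 1, m + 1, n * m + 1), dtype=object)
    counts[0, :, 0] = 1
    counts[:, 0, 0] = 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            for u in range(i * j + 1):
                c = counts[i, j - 1, u] if u <= i * (j - 1) else 0
                if u >= j:
                    c += counts[i - 1, j, u - j]
                counts[i, j, u] = c
    return tuple(int(x) for x in counts[n, m, : n * m + 1])


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    exact_limit: int = 12,
) -> tuple[float, float, str]:
    """Two-tailed unpaired Wilcoxon rank-sum test.

    Returns ``(u, p, method)`` where ``u = min(U_x, U_y)``.  When
    ``len(x) + len(y) <= exact_limit`` and the pooled values are tie-free,
    the p-value is exact: with T the rank assignment uniform over the
    C(n+m, n) possibilities, ``p = min(1, 2 * min(P(U <= u), P(U >= u)))``.
    Otherwise the mid-rank normal approximation with tie and continuity
    correction is used.
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    if not x or not y:
        raise DegenerateStratificationError("degenerate stratification: empty group")
    n, m = len(x), len(y)
    pooled = x + y
    has_ties = len(set(pooled)) < len(pooled)

    # U_x from mid-ranks (equals the tie-free definition when no ties)
    ranks = stats.rankdata(pooled)
    u_x = float(np.sum(ranks[:n]) - n * (n + 1) / 2.0)
    u_y = n * m - u_x
    u_min = min(u_x, u_y)

    if n + m <= exact_limit and not has_ties:
        counts = _u_counts(n, m)
        total = sum(counts)
        u_obs = int(round(u_x))
        p_le = sum(counts[: u_obs + 1]) / total
        p_ge = sum(counts[u_obs:]) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u_min, p, "exact_enumeration"

    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return u_min, float(res.pvalue), "normal_approximation"


def group_means(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Arithmetic means of the two groups and their ratio ``mean_x/mean_y``."""
    if not len(x) or not len(y):
        raise DegenerateStratificationError("degenerate stratification: empty group")
    mx, my = float(np.mean(x)), float(np.mean(y))
    return mx, my, mx / my if my != 0 else float("inf")


def compare_survival(
    clinical: Sequence[ClinicalRecord],
    verdicts: Iterable[DeleteriousVerdict],
    gene: str,
    group: TumorGroup | str,
    exact_limit: int = 12,
) -> SurvivalComparison:
    """Stratify by mutation status and run the rank-sum comparison."""
    mutant, wildtype = stratify_by_mutation(clinical, verdicts, gene, group)
    if not mutant or not wildtype:
        raise DegenerateStratificationError(
            f"gene {gene}: {'mutant' if not mutant else 'wild-type'} group is empty"
        )
    u, p, method = wilcoxon_rank_sum(mutant, wildtype, exact_limit)
    mean_m, mean_w, _ = group_means(mutant, wildtype)
    return SurvivalComparison(
        gene=gene,
        group_mutant=mutant,
        group_wildtype=wildtype,
        mean_mutant=mean_m,
        mean_wildtype=mean_w,
        u_statistic=u,
        p_two_tailed=p,
        method=method,
    )


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate as an explicit step function.

    ``survival_prob[i]`` is S(t) for t in ``[event_times[i],
    event_times[i+1])``; S(t) = 1 before the first event.  ``at_risk[i]``
    is the risk-set size just before ``event_times[i]``.
    """

    event_times: list[float]
    survival_prob: list[float]
    at_risk: list[int]
    censored_times: list[float]
    max_followup: float

    def survival_at(self, t: float) -> float:
        """Step-function value: S at the latest event time <= t."""
        if t < 0:
            raise ValueError("t must be >= 0")
        s = 1.0
        for time, prob in zip(self.event_times, self.survival_prob):
            if time <= t:
                s = prob
            else:
                break
        return s


def km_estimate(
    times: Sequence[float], events: Sequence[bool] | None = None
) -> KMCurve:
    """Kaplan-Meier estimate of the survival function.

    ``events[i]`` is True when subject *i* relapsed at ``times[i]`` and
    False when censored there (censored subjects leave the risk set after
    their time).  Defaults to all events observed.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    events = (
        np.ones(times.size, dtype=bool)
        if events is None
        else np.asarray(events, dtype=bool)
    )
    if events.size != times.size:
        raise ValueError("times and events must align")

    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    event_times = [float(t) for t in event_rows.index]
    survival_prob = [
        float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times
    ]
    at_risk = [int(r) for r in event_rows["at_risk"]]
    return KMCurve(
        event_times=event_times,
        survival_prob=survival_prob,
        at_risk=at_risk,
        censored_times=sorted(float(t) for t in times[~events]),
        max_followup=float(times.max()),
    )


def logrank_test(
    group_a: tuple[Sequence[float], Sequence[bool]],
    group_b: tuple[Sequence[float], Sequence[bool]],
) -> tuple[float, float]:
    """One-degree-of-freedom log-rank comparison of two survival curves.

    Returns ``(chi_square_statistic, p_value)``.  Raises when no events
    were observed in either group (the statistic is undefined).
    """
    t_a, e_a = (np.asarray(group_a[0], float), np.asarray(group_a[1], bool))
    t_b, e_b = (np.asarray(group_b[0], float), np.asarray(group_b[1], bool))
    if t_a.size == 0 or t_b.size == 0:
        raise DegenerateStratificationError("empty group")
    if not (e_a.any() or e_b.any()):
        raise ValueError("no events in either group")

    from lifelines.statistics import logrank_test as _ll_logrank

    res = _ll_logrank(t_a, t_b, event_observed_A=e_a, event_observed_B=e_b)
    return float(res.test_statistic), float(res.p_value)


def survival_gain_at(curve_a: KMCurve, curve_b: KMCurve, t: float) -> float:
    """Difference in survival probability S_A(t) - S_B(t) at time *t*.

    Uses each curve's step-function value at the latest event time <= t;
    warns when *t* exceeds both curves' follow-up (the value is then an
    extrapolation of the last step).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t > curve_a.max_followup and t > curve_b.max_followup:
        warnings.warn(
            f"t={t:g} beyond both curves' follow-up "
            f"({curve_a.max_followup:g}, {curve_b.max_followup:g}); "
            "value extrapolates the last step"
        )
    return curve_a.survival_at(t) - curve_b.survival_at(t)
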