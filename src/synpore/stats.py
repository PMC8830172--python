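"""Replicate statistics: one-way ANOVA with Student-Newman-Keuls post hoc.

Conditions are compared the way triplicate nanopore experiments are reported:
a fixed-effects one-way ANOVA over per-replicate metric values (or over
summary records reconstructed from mean, SEM and n), followed by the
stepwise Newman-Keuls procedure on the studentized range, with the usual
``ns`` / ``*`` / ``**`` / ``***`` significance ladder (p < 0.05, 0.01,
0.001, strict inequalities).

Summary-statistic mode is first class so published table rows
(mean +/- SEM, n) can be compared without raw events: within-group sums of
squares are reconstructed via ``SD = SEM * sqrt(n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

LABEL_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_label(p: float) -> str:
    """``***``/``**``/``*``/``ns`` at p < 0.001 / 0.01 / 0.05 (strict)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    for threshold, label in LABEL_THRESHOLDS:
        if p < threshold:
            return label
    return "ns"


@dataclass(frozen=True)
class GroupData:
    """One group: either raw per-replicate values or (mean, sem, n)."""

    name: str
    values: tuple | None = None
    mean: float | None = None
    sem: float | None = None
    n: int | None = None

    @classmethod
    def from_values(cls, name, values) -> "GroupData":
        values = tuple(float(v) for v in values)
        return cls(name, values=values)

    @classmethod
    def from_summary(cls, name, mean, sem, n) -> "GroupData":
        if sem < 0:
            raise ValueError("SEM must be >= 0")
        return cls(name, mean=float(mean), sem=float(sem), n=int(n))

    def moments(self) -> tuple[float, float, int]:
        """(mean, within-group sum of squares, n)."""
        if self.values is not None:
            arr = np.asarray(self.values, float)
            if arr.size < 2:
                raise ValueError(f"group {self.name!r} needs n >= 2")
            return float(arr.mean()), float(np.sum((arr - arr.mean()) ** 2)), arr.size
        if self.mean is None or self.sem is None or self.n is None:
            raise ValueError(f"group {self.name!r} has neither values nor (mean, sem, n)")
        if self.n < 2:
            raise ValueError(f"group {self.name!r} needs n >= 2")
        sd = self.sem * np.sqrt(self.n)
        return self.mean, float(sd * sd * (self.n - 1)), self.n


def _coerce_groups(groups) -> list[GroupData]:
    out = []
    for i, g in enumerate(groups):
        if isinstance(g, GroupData):
            out.append(g)
        elif isinstance(g, dict):
            if "values" in g:
                out.append(GroupData.from_values(g.get("name", f"group{i}"), g["values"]))
            else:
                out.append(GroupData.from_summary(
                    g.get("name", f"group{i}"), g["mean"], g["sem"], g["n"]))
        else:
            out.append(GroupData.from_values(f"group{i}", g))
    return out


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    ms_within: float
    group_means: dict[str, float]
    group_n: dict[str, int]
    degenerate: bool = False


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    diff: float
    q: float
    r: int  # number of means spanned in the ordered sequence
    p: float  # own studentized-range p at this pair's r
    p_adj: float  # after SNK blocking (>= p)
    label: str
    blocked: bool = False


@dataclass
class ComparisonResult:
    F: float
    p: float
    df: tuple[int, int]
    pairwise: list[PairwiseComparison] = field(default_factory=list)

    def pair(self, a: str, b: str) -> PairwiseComparison:
        for pc in self.pairwise:
            if set(pc.pair) == {a, b}:
                return pc
        raise KeyError(f"no comparison for pair ({a!r}, {b!r})")


def one_way_anova(groups) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA, raw or summary mode."""
    gs = _coerce_groups(groups)
    if len(gs) < 2:
        raise ValueError("ANOVA needs at least two groups")
    moments = [g.moments() for g in gs]
    ns = np.array([m[2] for m in moments])
    means = np.array([m[0] for m in moments])
    ssw = float(sum(m[1] for m in moments))
    grand = float(np.sum(ns * means) / np.sum(ns))
    ssb = float(np.sum(ns * (means - grand) ** 2))
    dfb = len(gs) - 1
    dfw = int(np.sum(ns)) - len(gs)
    if dfw < 1:
        raise ValueError("within-group degrees of freedom < 1")
    msw = ssw / dfw
    if msw == 0.0:
        if ssb == 0.0:
            f_stat, p, degenerate = 0.0, 1.0, False
        else:
            f_stat, p, degenerate = np.inf, 0.0, True
    else:
        f_stat = (ssb / dfb) / msw
        p = float(sps.f.sf(f_stat, dfb, dfw))
        degenerate = False
    return AnovaResult(
        float(f_stat), p, dfb, dfw, msw,
        {g.name: m[0] for g, m in zip(gs, moments)},
        {g.name: m[2] for g, m in zip(gs, moments)},
        degenerate,
    )


def snk_posthoc(groups, alpha: float = 0.05, anova: AnovaResult | None = None) -> list[PairwiseComparison]:
    """Stepwise Student-Newman-Keuls comparisons on the studentized range.

    Means are rank ordered; a pair spanning ``r`` ordered means is tested
    against ``q(alpha, r, df_within)``; once a range tests non-significant,
    every pair it encloses is declared non-significant too (its reported
    ``p_adj`` is raised to the blocking range's p so labels stay monotone).
    Unequal group sizes use the harmonic mean n of the two groups compared.
    """
    gs = _coerce_groups(groups)
    res = anova or one_way_anova(gs)
    if res.df_within < 1:
        raise ValueError("SNK requires df_within >= 1")
    order = sorted(res.group_means, key=res.group_means.get)
    k = len(order)
    msw = res.ms_within
    comps: dict[tuple[int, int], PairwiseComparison] = {}
    blocked_p: dict[tuple[int, int], float] = {}
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            a, b = order[i], order[j]
            diff = res.group_means[b] - res.group_means[a]
            nh = 2.0 / (1.0 / res.group_n[a] + 1.0 / res.group_n[b])
            if msw == 0.0:
                q = np.inf if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
            else:
                q = abs(diff) / np.sqrt(msw / nh)
                p = float(np.clip(sps.studentized_range.sf(q, span, res.df_within), 0.0, 1.0))
            key = (i, j)
            if key in blocked_p:
                p_adj = max(p, blocked_p[key])
                comps[key] = PairwiseComparison(
                    (a, b), diff, float(q), span, p, p_adj,
                    significance_label(p_adj), blocked=True,
                )
            else:
                comps[key] = PairwiseComparison(
                    (a, b), diff, float(q), span, p, p, significance_label(p)
                )
                if p >= alpha:
                    # block every enclosed pair
                    for ii in range(i, j + 1):
                        for jj in range(ii + 1, j + 1):
                            if (ii, jj) != key:
                                blocked_p[(ii, jj)] = max(blocked_p.get((ii, jj), 0.0), p)
    return [comps[key] for key in sorted(comps)]


def compare_groups(groups, alpha: float = 0.05) -> ComparisonResult:
    """One-way ANOVA plus SNK pairwise records for a set of groups."""
    gs = _coerce_groups(groups)
    res = one_way_anova(gs)
    pairwise = snk_posthoc(gs, alpha=alpha, anova=res)
    return ComparisonResult(res.F, res.p, (res.df_between, res.df_within), pairwise)


def compare_summaries(summaries, metric: str, alpha: float = 0.05) -> ComparisonResult:
    """Compare one profile metric across ConditionSummary objects.

    ``metric`` is ``field.class``, e.g. ``population_pct.translocation``,
    ``tau_ms.bumping`` or ``peak_pA.translocation``; per-replicate values are
    used when retained, otherwise the stored mean/SEM/n summary.
    """
    fld, _, cls = metric.partition(".")
    groups = []
    for summary in summaries:
        per = summary.per_replicate.get(cls, {}).get(fld)
        if per and len(per) >= 2:
            groups.append(GroupData.from_values(summary.condition, per))
        else:
            cs = summary.classes.get(cls)
            attr = {"population_pct": "population", "peak_pA": "peak_I", "tau_ms": "tau_T"}[fld]
            stat = getattr(cs, attr) if cs else None
            if stat is None or stat.sem is None:
                raise ValueError(
                    f"condition {summary.condition!r} lacks replicate data for {metric!r}"
                )
            groups.append(GroupData.from_summary(summary.condition, stat.mean, stat.sem, stat.n))
    return compare_groups(groups, alpha=alpha)
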