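"""Binding verdicts and knot/loop conformation calls.

A drug that binds alpha-synuclein and folds it produces a characteristic
profile shift: fewer translocation events (the folded protein no longer
threads the pore) and more bumping events.  ``call_binding`` encodes that
directional signature.  Separately, a drug can interact with an isolated
domain construct without producing the folding signature (e.g. turning a
bumping-only fragment profile into one with a translocation peak), so each
call also carries ``altered`` — whether the profile changed significantly in
any qualifying way (translocation population, bumping population, or the
appearance/disappearance of a fitted component class).

The domain panel (full-length, N-terminus, C-terminus, delta-NAC) decides
the binding mode: a drug interacting with the N-terminus but not the
C-terminus pins the protein into a "knot" that leaves the aggregation-prone
NAC region free; a drug bridging both termini closes a protective "loop"
around it.

Significance gating combines the SNK p-value (p < alpha) with a practical
effect-size floor on population changes (default 8 percentage points —
half the smallest population shift reported as significant in comparable
experiments) so that a panel of null comparisons does not accumulate
false binding calls at the familywise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .profile import ConditionSummary
from .stats import ComparisonResult, compare_summaries, significance_label

CONSTRUCTS = ("full_length", "n_term", "c_term", "delta_nac")
POPULATION_METRICS = ("translocation", "bumping")


@dataclass(frozen=True)
class Evidence:
    metric: str       # e.g. "population_pct.translocation" or "component_set"
    direction: str    # "increase" / "decrease" / "appeared" / "disappeared"
    delta: float | None
    p: float | None
    label: str
    qualifying: bool  # counts toward bound/altered


@dataclass
class BindingCall:
    bound: str        # "yes" / "no" — directional folding signature
    strength: str     # "strong" / "weak" / "none"
    altered: bool     # any qualifying significant profile change
    construct: str | None
    evidence: list[Evidence] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "bound": self.bound,
            "strength": self.strength,
            "altered": self.altered,
            "construct": self.construct,
            "evidence": [vars(e) for e in self.evidence],
        }


@dataclass
class BindingModeCall:
    mode: str  # "knot" / "loop" / "indeterminate" / "none"
    rationale: str
    panel: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"mode": self.mode, "rationale": self.rationale, "panel": self.panel}


def _population_evidence(
    control: ConditionSummary,
    drug: ConditionSummary,
    comparison: ComparisonResult | None,
    cls: str,
    alpha: float,
    min_effect_pp: float,
) -> Evidence:
    c_stat = control.classes.get(cls)
    d_stat = drug.classes.get(cls)
    c_mean = c_stat.population.mean if c_stat else 0.0
    d_mean = d_stat.population.mean if d_stat else 0.0
    delta = d_mean - c_mean
    metric = f"population_pct.{cls}"
    if comparison is None:
        try:
            comparison = compare_summaries([control, drug], metric, alpha=alpha)
        except (ValueError, KeyError):
            return Evidence(metric, "increase" if delta > 0 else "decrease", delta, None, "ns", False)
    try:
        p = comparison.pair(control.condition, drug.condition).p_adj
    except KeyError:
        p = comparison.p
    qualifying = p < alpha and abs(delta) >= min_effect_pp
    return Evidence(
        metric, "increase" if delta > 0 else "decrease", delta, p,
        significance_label(p), qualifying,
    )


def call_binding(
    control: ConditionSummary,
    drug: ConditionSummary,
    comparisons: dict[str, ComparisonResult] | None = None,
    alpha: float = 0.05,
    min_effect_pp: float = 8.0,
) -> BindingCall:
    """Bound/unbound verdict from a control-vs-drug condition pair.

    ``bound = yes`` when the translocation population decreases significantly
    or the bumping population increases significantly (``strong`` when both,
    ``weak`` when one).  ``altered`` additionally admits any significant
    population change in either direction and changes in the fitted
    component-class set (e.g. an intercalation peak appearing).
    ``comparisons`` may supply precomputed per-metric results keyed like
    ``population_pct.translocation``.
    """
    if control.construct and drug.construct and control.construct != drug.construct:
        raise ValueError(
            f"cannot compare constructs {control.construct!r} and {drug.construct!r}"
        )
    comparisons = comparisons or {}
    evidence = []
    by_class = {}
    for cls in POPULATION_METRICS:
        ev = _population_evidence(
            control, drug, comparisons.get(f"population_pct.{cls}"), cls, alpha, min_effect_pp
        )
        by_class[cls] = ev
        evidence.append(ev)

    # component-set change: classes present in the majority of replicate fits
    def modal_set(summary: ConditionSummary) -> frozenset:
        if not summary.class_sets:
            return frozenset(summary.classes)
        counts: dict[frozenset, int] = {}
        for s in summary.class_sets:
            counts[s] = counts.get(s, 0) + 1
        return max(counts, key=counts.get)

    c_set, d_set = modal_set(control), modal_set(drug)
    set_changed = c_set != d_set
    if set_changed:
        appeared = sorted(d_set - c_set)
        gone = sorted(c_set - d_set)
        desc = "appeared" if appeared else "disappeared"
        evidence.append(Evidence(
            "component_set", desc, None, None,
            "+" + "/".join(appeared) if appeared else "-" + "/".join(gone), True,
        ))

    trans_down = by_class["translocation"].qualifying and by_class["translocation"].delta < 0
    bump_up = by_class["bumping"].qualifying and by_class["bumping"].delta > 0
    if trans_down and bump_up:
        bound, strength = "yes", "strong"
    elif trans_down or bump_up:
        bound, strength = "yes", "weak"
    else:
        bound, strength = "no", "none"
    altered = set_changed or any(ev.qualifying for ev in evidence)
    return BindingCall(bound, strength, altered, drug.construct or control.construct, evidence)


def infer_binding_mode(panel: dict[str, BindingCall]) -> BindingModeCall:
    """Knot/loop/indeterminate/none from a domain-construct panel.

    Requires at least the N- and C-terminal calls.  The termini decide the
    mode: N altered and C not -> knot (NAC region left exposed); both
    altered -> loop (NAC shielded); C only, or nothing but delta-NAC ->
    indeterminate; no construct altered -> none.  The delta-NAC result is
    recorded as supporting evidence only.
    """
    if not panel:
        raise ValueError("empty domain panel")
    unknown = set(panel) - set(CONSTRUCTS)
    if unknown:
        raise ValueError(f"unknown constructs in panel: {sorted(unknown)}")
    if "n_term" not in panel or "c_term" not in panel:
        raise ValueError("binding-mode inference needs both n_term and c_term calls")
    altered = {name for name, call in panel.items() if call.altered}
    missing = sorted(set(CONSTRUCTS) - set(panel))
    n_alt, c_alt = "n_term" in altered, "c_term" in altered
    if not altered:
        mode = "none"
        rationale = "no construct shows a significant profile change: no binding detected"
    elif n_alt and not c_alt:
        mode = "knot"
        rationale = (
            "drug interacts with the N-terminus but not the C-terminus: the protein is "
            "pinned into a knot, leaving the NAC region exposed"
        )
    elif n_alt and c_alt:
        mode = "loop"
        rationale = (
            "drug interacts with both termini: the protein closes into a loop "
            "shielding the NAC region"
        )
    else:
        mode = "indeterminate"
        rationale = (
            f"only {sorted(altered)} altered; terminal evidence is insufficient to "
            "assign a knot or loop conformation"
        )
    if "delta_nac" in panel:
        rationale += (
            "; delta-NAC construct "
            + ("altered" if "delta_nac" in altered else "unchanged")
            + " (supporting evidence only)"
        )
    if missing:
        rationale += f"; constructs missing from panel: {missing}"
    snapshot = {name: call.to_dict() for name, call in panel.items()}
    return BindingModeCall(mode, rationale, snapshot)
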