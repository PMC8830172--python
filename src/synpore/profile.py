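"""Blockade-current populations and dwell-time characteristic times.

This module turns a detected event table into the per-condition profile used
for binding analysis: a histogram of blockade amplitudes, a 1-3 component
Gaussian fit of the amplitude distribution (peak current *I*, width, and the
population percentage *P* of all detected events falling in each component's
window), a single-exponential characteristic time *T* per event class, and
replicate pooling with mean +/- SEM summaries.

Population percentages are shares of ALL detected events: events farther than
``z_max`` standard deviations from every component peak stay unclassified, so
percentages need not sum to 100 (real recordings of a disordered protein
always contain events outside the fitted peaks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.mixture import GaussianMixture

from .detect import EventTable

CLASS_ORDER = ("translocation", "intercalation", "bumping")

#: single-component fits cannot be labelled ordinally; a lone peak deeper than
#: this is called translocation, shallower bumping (midpoint of the deepest
#: reported bumping-only and shallowest translocation peaks)
SINGLE_PEAK_SPLIT_PA = -50.0


class DegenerateFitError(ValueError):
    """Two mixture components collapsed onto the same peak."""


@dataclass(frozen=True)
class Histogram:
    counts: np.ndarray
    edges: np.ndarray
    bin_width: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass(frozen=True)
class GaussianComponent:
    class_label: str
    peak_pA: float
    sigma_pA: float
    population_pct: float
    mixture_weight: float

    def __post_init__(self):
        if self.sigma_pA <= 0:
            raise ValueError("sigma_pA must be > 0")
        if not 0.0 <= self.population_pct <= 100.0:
            raise ValueError("population_pct must be in [0, 100]")


@dataclass
class PopulationFit:
    components: list[GaussianComponent]
    bin_width: float
    unclassified_pct: float
    method: str
    bic: float
    goodness: dict
    n_events: int
    n_excluded_low_confidence: int = 0

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def class_set(self) -> frozenset:
        return frozenset(c.class_label for c in self.components)

    def component(self, label: str) -> GaussianComponent | None:
        for c in self.components:
            if c.class_label == label:
                return c
        return None


@dataclass(frozen=True)
class DwellFit:
    class_label: str
    tau_ms: float
    n_events: int
    method: str
    truncation_ms: float
    goodness: float

    def __post_init__(self):
        if self.tau_ms <= 0:
            raise ValueError("tau_ms must be > 0")


def build_blockade_histogram(events, bin_width: float = 2.0) -> Histogram:
    """Counts of blockade amplitudes over uniform bins spanning their range."""
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    amps = events.amplitudes() if isinstance(events, EventTable) else np.asarray(events, float)
    if amps.size == 0:
        raise ValueError("need at least one event to build a histogram")
    lo = math.floor(amps.min() / bin_width) * bin_width
    hi = math.ceil(amps.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(amps, bins=edges)
    return Histogram(counts, edges, bin_width)


def _labels_for(means: np.ndarray) -> list[str]:
    """Ordinal class labels for peak means sorted most-negative first."""
    k = len(means)
    if k == 1:
        return ["translocation" if means[0] <= SINGLE_PEAK_SPLIT_PA else "bumping"]
    if k == 2:
        return ["translocation", "bumping"]
    return ["translocation", "intercalation", "bumping"]


def _assign(amps: np.ndarray, means: np.ndarray, sigmas: np.ndarray, z_max: float) -> np.ndarray:
    """Component index per amplitude (-1 = unclassified); nearest z-score wins,
    exact ties go to the deeper (more negative) peak."""
    z = np.abs(amps[:, None] - means[None, :]) / sigmas[None, :]
    # means are sorted deepest-first, so argmin resolves exact ties deeper
    best = np.argmin(z, axis=1)
    out = np.where(z[np.arange(amps.size), best] <= z_max, best, -1)
    return out


def _gauss_sum(x, *params):
    k = len(params) // 3
    y = np.zeros_like(x, dtype=float)
    for j in range(k):
        a, mu, sd = params[3 * j: 3 * j + 3]
        y = y + a * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return y


def _fit_histogram_ls(amps: np.ndarray, k: int, bin_width: float):
    hist = build_blockade_histogram(amps, bin_width)
    x, y = hist.centers, hist.counts.astype(float)
    # initialise from amplitude quantile slices
    qs = np.quantile(amps, np.linspace(0, 1, k + 1))
    p0 = []
    for j in range(k):
        sel = amps[(amps >= qs[j]) & (amps <= qs[j + 1])]
        mu = float(np.mean(sel)) if sel.size else float(qs[j])
        sd = float(np.std(sel)) if sel.size > 1 and np.std(sel) > 0 else bin_width
        amp0 = max(float(y.max()) / k, 1.0)
        p0 += [amp0, mu, sd]
    lb = [0.0, amps.min() - 10, 1e-3] * k
    ub = [np.inf, amps.max() + 10, (amps.max() - amps.min()) + 10] * k
    popt, _ = curve_fit(_gauss_sum, x, y, p0=p0, bounds=(lb, ub), maxfev=20000)
    means = popt[1::3]
    sigmas = popt[2::3]
    heights = popt[0::3]
    weights = heights * sigmas  # proportional to component area
    weights = weights / weights.sum()
    resid = y - _gauss_sum(x, *popt)
    rss = float(np.sum(resid**2))
    n_bins = x.size
    bic = n_bins * math.log(max(rss / n_bins, 1e-300)) + 3 * k * math.log(n_bins)
    goodness = {"rss": rss, "n_bins": n_bins}
    return means, sigmas, weights, bic, goodness


def _fit_mixture_mle(amps: np.ndarray, k: int, random_state: int):
    gm = GaussianMixture(
        n_components=k, covariance_type="full", n_init=2,
        reg_covar=1e-4, random_state=random_state, max_iter=300,
    ).fit(amps[:, None])
    if not gm.converged_:
        raise RuntimeError(f"mixture fit with k={k} did not converge")
    means = gm.means_.ravel()
    sigmas = np.sqrt(gm.covariances_.reshape(-1))
    weights = gm.weights_.ravel()
    bic = float(gm.bic(amps[:, None]))
    goodness = {"log_likelihood_per_event": float(gm.score(amps[:, None]))}
    return means, sigmas, weights, bic, goodness


def fit_population_model(
    events,
    k="auto",
    method: str = "mle",
    bin_width: float = 2.0,
    z_max: float = 2.5,
    include_low_confidence: bool = False,
    random_state: int = 0,
    min_component_weight: float = 0.05,
) -> PopulationFit:
    """Fit 1-3 Gaussian components to the blockade-amplitude distribution.

    ``method='mle'`` fits the mixture by maximum likelihood on the raw
    amplitudes; ``method='histogram_ls'`` least-squares fits a sum of
    Gaussians to the binned histogram, mirroring how published profiles were
    produced.  ``k='auto'`` selects 1-3 components by BIC, preferring
    solutions whose components all carry at least ``min_component_weight`` of
    the mixture — BIC alone happily spends a tiny component on the shallow
    tail of marginally resolved events, which would then masquerade as the
    shallowest event class.
    """
    if isinstance(events, EventTable):
        amps = events.amplitudes(include_low_confidence=include_low_confidence)
        n_excluded = len(events) - amps.size
    else:
        amps = np.asarray(events, float)
        n_excluded = 0
    if amps.size < 50:
        raise ValueError(
            f"only {amps.size} events: population fitting needs >= 50; "
            "record longer or pool replicates"
        )
    candidates = (1, 2, 3) if k == "auto" else (int(k),)
    if any(c < 1 or c > 3 for c in candidates):
        raise ValueError("k must be in 1..3 or 'auto'")
    fitter = _fit_mixture_mle if method == "mle" else _fit_histogram_ls
    fits = {}
    errors = []
    for kk in candidates:
        try:
            if method == "mle":
                fits[kk] = fitter(amps, kk, random_state)
            else:
                fits[kk] = fitter(amps, kk, bin_width)
        except (RuntimeError, ValueError) as exc:
            errors.append(f"k={kk}: {exc}")
    if not fits:
        raise RuntimeError("population fit failed for all k: " + "; ".join(errors))
    solid = {kk: f for kk, f in fits.items() if np.min(f[2]) >= min_component_weight}
    pool = solid or fits
    k_sel = min(pool, key=lambda kk: pool[kk][3])
    means, sigmas, weights, bic, goodness = pool[k_sel]

    order = np.argsort(means)  # deepest (most negative) first
    means, sigmas, weights = means[order], sigmas[order], weights[order]
    labels = _labels_for(means)
    assign = _assign(amps, means, sigmas, z_max)
    n = amps.size
    components = [
        GaussianComponent(
            labels[j], float(means[j]), float(sigmas[j]),
            100.0 * float(np.sum(assign == j)) / n, float(weights[j]),
        )
        for j in range(k_sel)
    ]
    unclassified = 100.0 * float(np.sum(assign == -1)) / n
    return PopulationFit(
        components, bin_width, unclassified, method, bic, goodness, n, n_excluded
    )


def assign_event_classes(events: EventTable, fit: PopulationFit, z_max: float = 2.5) -> EventTable:
    """Label each event by its nearest fitted component (within ``z_max`` sd).

    Components are labelled by peak depth order — deepest = translocation,
    shallowest = bumping, middle = intercalation; a single component is
    labelled by absolute depth.  Exact z-score ties go to the deeper peak.
    """
    means = np.array([c.peak_pA for c in fit.components])
    sigmas = np.array([c.sigma_pA for c in fit.components])
    if len(means) > 1 and np.min(np.diff(np.sort(means))) < 1e-6:
        raise DegenerateFitError("two components share the same peak current")
    labels = [c.class_label for c in fit.components]
    amps = np.array([r.blockade_pA for r in events.records])
    if amps.size:
        assign = _assign(amps, means, sigmas, z_max)
    else:
        assign = np.empty(0, int)
    for rec, j in zip(events.records, assign):
        rec.class_label = labels[j] if j >= 0 else None
    return events


def fit_dwell_time(
    dwells,
    class_label: str = "unspecified",
    method: str = "mle",
    min_dwell_ms: float | None = None,
    bins: int = 40,
) -> DwellFit:
    """Single-exponential characteristic time for one event class.

    ``mle`` uses the closed-form estimator ``tau = mean(d) - c`` on dwells at
    or above the truncation point ``c`` (``c = 0`` when ``min_dwell_ms`` is
    None) — the exact maximum-likelihood solution for a left-truncated
    exponential.  ``histogram_ls`` least-squares fits ``A exp(-t/tau)`` to the
    dwell histogram, mirroring the published analysis.
    """
    if isinstance(dwells, EventTable):
        dwells = dwells.dwells()
    d = np.asarray(dwells, float)
    c = float(min_dwell_ms) if min_dwell_ms else 0.0
    d = d[d >= c]
    if d.size < 20:
        raise ValueError(
            f"only {d.size} usable {class_label} events (>= 20 required for a dwell fit)"
        )
    if method == "mle":
        tau = float(np.mean(d)) - c
        if tau <= 0:
            raise ValueError("degenerate dwell sample: non-positive tau")
        loglik = float(np.sum(-np.log(tau) - (d - c) / tau))
        return DwellFit(class_label, tau, d.size, "mle", c, loglik)
    if method == "histogram_ls":
        counts, edges = np.histogram(d, bins=bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        tau0 = max(float(np.mean(d)) - c, 1e-6)

        def model(t, a, tau):
            return a * np.exp(-(t - c) / tau)

        popt, _ = curve_fit(
            model, centers, counts.astype(float),
            p0=[max(counts.max(), 1.0), tau0],
            bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=10000,
        )
        resid = counts - model(centers, *popt)
        ss_tot = float(np.sum((counts - counts.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        return DwellFit(class_label, float(popt[1]), d.size, "histogram_ls", c, r2)
    raise ValueError(f"unknown dwell fit method {method!r}")


@dataclass
class ReplicateProfile:
    """Population fit plus per-class dwell fits for one replicate."""

    condition: str
    replicate: int
    fit: PopulationFit
    dwell: dict[str, DwellFit]
    n_events: int

    def population(self, label: str) -> float:
        comp = self.fit.component(label)
        return comp.population_pct if comp else 0.0

    def corrected_weights(self) -> dict[str, float]:
        """Class weights corrected for events censored below the dwell
        truncation point: w_j proportional to n_j / exp(-c/tau_j)."""
        raw = {}
        for comp in self.fit.components:
            dw = self.dwell.get(comp.class_label)
            if dw is None:
                raw[comp.class_label] = comp.population_pct
            else:
                raw[comp.class_label] = comp.population_pct / math.exp(-dw.truncation_ms / dw.tau_ms)
        total = sum(raw.values())
        return {lbl: v / total for lbl, v in raw.items()} if total else raw


def profile_replicate(
    table: EventTable,
    k="auto",
    method: str = "mle",
    min_dwell_ms="auto",
    dwell_method: str = "mle",
    bin_width: float = 2.0,
    z_max: float = 2.5,
    random_state: int = 0,
    min_class_events: int = 20,
) -> ReplicateProfile:
    """Full per-replicate profile: population fit, class labels, dwell fits.

    ``min_dwell_ms='auto'`` takes the detector's resolution limit from the
    table metadata (absent for event-level tables, in which case no
    truncation is applied).
    """
    fit = fit_population_model(
        table, k=k, method=method, bin_width=bin_width, z_max=z_max, random_state=random_state
    )
    assign_event_classes(table, fit, z_max=z_max)
    if min_dwell_ms == "auto":
        min_dwell_ms = table.meta.get("resolved_limit_ms")
    dwell = {}
    for comp in fit.components:
        dsel = np.array(
            [r.dwell_ms for r in table.records
             if r.class_label == comp.class_label and not r.low_confidence]
        )
        if dsel.size >= min_class_events:
            try:
                dwell[comp.class_label] = fit_dwell_time(
                    dsel, comp.class_label, method=dwell_method, min_dwell_ms=min_dwell_ms
                )
            except ValueError:
                pass
    return ReplicateProfile(
        table.meta.get("condition", ""), table.meta.get("replicate", 0),
        fit, dwell, len(table),
    )


def pool_replicates(tables: list[EventTable]) -> EventTable:
    """Concatenate replicate event tables for display histograms."""
    if not tables:
        raise ValueError("need at least one replicate")
    conditions = {t.meta.get("condition") for t in tables}
    if len(conditions) > 1:
        raise ValueError(f"replicates come from different conditions: {sorted(map(str, conditions))}")
    records = [r for t in tables for r in t.records]
    meta = dict(tables[0].meta)
    meta["n_replicates"] = len(tables)
    meta.pop("replicate", None)
    return EventTable(records, meta)


@dataclass(frozen=True)
class MeanSem:
    mean: float
    sem: float | None  # None when only one replicate
    n: int


def _mean_sem(values: list[float]) -> MeanSem:
    arr = np.asarray(values, float)
    if arr.size >= 2:
        return MeanSem(float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size)), arr.size)
    return MeanSem(float(arr.mean()), None, arr.size)


@dataclass
class ClassSummary:
    population: MeanSem
    peak_I: MeanSem | None
    tau_T: MeanSem | None
    flagged: bool = False  # class absent from some replicates


@dataclass
class ConditionSummary:
    """Per-condition, per-class mean +/- SEM across replicates — the shape of
    a published population/blockade-time table column."""

    condition: str
    n_replicates: int
    classes: dict[str, ClassSummary]
    unclassified: MeanSem
    per_replicate: dict = field(default_factory=dict)
    class_sets: list = field(default_factory=list)
    construct: str | None = None

    def to_dict(self) -> dict:
        def ms(v):
            return None if v is None else {"mean": v.mean, "sem": v.sem, "n": v.n}

        return {
            "condition": self.condition,
            "construct": self.construct,
            "n_replicates": self.n_replicates,
            "classes": {
                lbl: {
                    "population_pct": ms(cs.population),
                    "peak_pA": ms(cs.peak_I),
                    "tau_ms": ms(cs.tau_T),
                    "flagged": cs.flagged,
                }
                for lbl, cs in self.classes.items()
            },
            "unclassified_pct": ms(self.unclassified),
            "per_replicate": self.per_replicate,
            "class_sets": [sorted(s) for s in self.class_sets],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ConditionSummary":
        def ms(v):
            return None if v is None else MeanSem(v["mean"], v["sem"], v["n"])

        classes = {
            lbl: ClassSummary(ms(c["population_pct"]), ms(c["peak_pA"]), ms(c["tau_ms"]),
                              c.get("flagged", False))
            for lbl, c in data["classes"].items()
        }
        return cls(
            data["condition"], data["n_replicates"], classes,
            ms(data["unclassified_pct"]), data.get("per_replicate", {}),
            [frozenset(s) for s in data.get("class_sets", [])], data.get("construct"),
        )


def summarize_condition(
    profiles: list[ReplicateProfile], condition: str | None = None, construct: str | None = None
) -> ConditionSummary:
    """Mean +/- SEM of population, peak current and characteristic time per
    class across replicate profiles.  SEM is reported only with >= 2
    replicates; classes missing from some replicates are flagged and their
    SEM computed over the replicates where they appear."""
    if not profiles:
        raise ValueError("need at least one replicate profile")
    condition = condition or profiles[0].condition
    n_rep = len(profiles)
    all_labels = sorted(
        {c.class_label for p in profiles for c in p.fit.components},
        key=CLASS_ORDER.index,
    )
    classes = {}
    per_replicate = {}
    for lbl in all_labels:
        pops = [p.population(lbl) for p in profiles]  # absent => 0% of events
        peaks = [p.fit.component(lbl).peak_pA for p in profiles if p.fit.component(lbl)]
        taus = [p.dwell[lbl].tau_ms for p in profiles if lbl in p.dwell]
        present = sum(1 for p in profiles if p.fit.component(lbl))
        classes[lbl] = ClassSummary(
            population=_mean_sem(pops),
            peak_I=_mean_sem(peaks) if peaks else None,
            tau_T=_mean_sem(taus) if taus else None,
            flagged=present < n_rep,
        )
        per_replicate[lbl] = {
            "population_pct": pops,
            "peak_pA": peaks,
            "tau_ms": taus,
        }
    unclassified = _mean_sem([p.fit.unclassified_pct for p in profiles])
    return ConditionSummary(
        condition, n_rep, classes, unclassified, per_replicate,
        [p.fit.class_set for p in profiles], construct,
    )
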