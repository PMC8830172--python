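"""Synthetic single-channel current traces with ground truth.

Emulates DC voltage-clamp recordings of an alpha-hemolysin pore interacting
with alpha-synuclein (or one of its domain constructs): an open-pore baseline
carrying Gaussian noise, interrupted by square blockade pulses drawn from up
to three event classes — translocation (deep, long), intercalation
(intermediate) and bumping (shallow, brief).  Event arrivals are Poisson with
an enforced dead time, dwell times are exponential per class, and blockade
amplitudes are Gaussian per class.  The rendered trace is low-pass filtered
with a Gaussian kernel whose -3 dB point sits at the recording bandwidth,
mimicking the analogue filter of a patch-clamp amplifier.

Every generated event is returned as ground truth so the downstream detector
and fitters can be validated for recall, precision and parameter recovery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

CLASS_LABELS = ("translocation", "intercalation", "bumping")

#: -3 dB Gaussian kernel width: |H(f)| = exp(-2 pi^2 f^2 sigma_t^2) = 1/sqrt(2)
#: at f = bandwidth  =>  sigma_t = sqrt(ln 2) / (2 pi * bandwidth).
_SIGMA_LN2 = math.sqrt(math.log(2.0))


class SimulationWarning(UserWarning):
    """Raised (as a warning) for degenerate but legal simulation requests."""


class ValidationError(ValueError):
    """A condition/class model field violates its contract."""


def filter_sigma_samples(sampling_rate: float, bandwidth: float) -> float:
    """Gaussian kernel sigma (in samples) with -3 dB point at *bandwidth*."""
    return _SIGMA_LN2 / (2.0 * math.pi * bandwidth) * sampling_rate


@dataclass(frozen=True)
class ClassModel:
    """Generative parameters of one blockade-event class.

    ``mean_blockade`` is the deflection from the open-pore baseline in pA
    (negative: the pore conducts less while occupied); ``dwell_scale`` is the
    mean of the exponential dwell-time distribution in ms.
    """

    label: str
    weight: float
    mean_blockade: float
    sd_blockade: float
    dwell_scale: float

    def __post_init__(self):
        if self.label not in CLASS_LABELS:
            raise ValidationError(f"label must be one of {CLASS_LABELS}, got {self.label!r}")
        if not 0.0 <= self.weight <= 1.0:
            raise ValidationError(f"weight must be in [0, 1], got {self.weight} ({self.label})")
        if self.mean_blockade >= 0:
            raise ValidationError(
                f"mean_blockade must be negative (a blockade), got {self.mean_blockade} ({self.label})"
            )
        if self.sd_blockade <= 0:
            raise ValidationError(f"sd_blockade must be > 0, got {self.sd_blockade} ({self.label})")
        if self.dwell_scale <= 0:
            raise ValidationError(f"dwell_scale must be > 0, got {self.dwell_scale} ({self.label})")


@dataclass(frozen=True)
class ConditionModel:
    """One recording condition (protein construct x drug) and its acquisition."""

    name: str
    classes: tuple[ClassModel, ...]
    event_rate: float = 25.0          # events / s
    baseline_current: float = 100.0   # pA, open pore at +100 mV
    noise_sd: float = 1.5             # pA, white Gaussian before filtering
    sampling_rate: float = 100_000.0  # Hz
    filter_bandwidth: float = 10_000.0  # Hz, -3 dB
    voltage: float = 100.0            # mV
    duration: float = 100.0           # s
    dead_time: float = 1e-3           # s between events
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "classes", tuple(self.classes))
        if not self.classes:
            raise ValidationError("a condition needs at least one event class")
        total = sum(c.weight for c in self.classes)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class weights must sum to 1 (got {total!r})")
        if self.event_rate < 0:
            raise ValidationError(f"event_rate must be >= 0, got {self.event_rate}")
        if self.baseline_current <= 0:
            raise ValidationError(f"baseline_current must be > 0, got {self.baseline_current}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.sampling_rate <= 0 or self.filter_bandwidth <= 0:
            raise ValidationError("sampling_rate and filter_bandwidth must be > 0")
        if self.sampling_rate < 2 * self.filter_bandwidth:
            raise ValidationError(
                f"sampling_rate ({self.sampling_rate}) must be >= 2 x filter_bandwidth "
                f"({self.filter_bandwidth})"
            )
        for c in self.classes:
            if abs(c.mean_blockade) > self.baseline_current:
                raise ValidationError(
                    f"|mean_blockade| of class {c.label!r} ({abs(c.mean_blockade)} pA) exceeds "
                    f"baseline_current ({self.baseline_current} pA): blocked current below zero"
                )

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.classes])

    def with_seed(self, seed: int) -> "ConditionModel":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class GroundTruthEvent:
    """Simulator truth for one blockade event."""

    label: str
    start_s: float
    dwell_ms: float
    amplitude_pA: float  # negative deflection


@dataclass
class CurrentTrace:
    """A sampled single-channel current recording, in pA."""

    samples: np.ndarray
    sampling_rate: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValidationError("trace samples must be one-dimensional")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValidationError("trace samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


def build_condition_model(
    class_specs,
    acquisition: dict | None = None,
    *,
    name: str = "condition",
    renormalize: bool = True,
) -> ConditionModel:
    """Validate class specs (dicts or ``ClassModel``) into a ``ConditionModel``.

    Weights may be given as fractions summing to one or — as in published
    population tables, which need not sum to 100% — as raw percentages that
    are renormalized (w_i = p_i / sum p).  Renormalization is recorded in the
    returned model's metadata.
    """
    fields = []
    for spec in class_specs:
        if isinstance(spec, ClassModel):
            fields.append(
                dict(label=spec.label, weight=spec.weight, mean_blockade=spec.mean_blockade,
                     sd_blockade=spec.sd_blockade, dwell_scale=spec.dwell_scale)
            )
        else:
            fields.append(dict(spec))
    raw = np.array([f["weight"] for f in fields], dtype=float)
    if np.any(raw < 0):
        raise ValidationError("negative weight in class specs")
    total = raw.sum()
    meta = {}
    if abs(total - 1.0) > 1e-9:
        if not renormalize:
            raise ValidationError(f"class weights sum to {total!r}, not 1, and renormalize=False")
        if total <= 0:
            raise ValidationError("class weights sum to zero; cannot renormalize")
        for f, w in zip(fields, raw / total):
            f["weight"] = float(w)
        meta = {"weights_renormalized": True, "raw_weights": raw.tolist()}
    classes = [ClassModel(**f) for f in fields]
    acq = dict(acquisition or {})
    acq_meta = acq.pop("metadata", {})
    return ConditionModel(name=name, classes=tuple(classes), metadata={**meta, **acq_meta}, **acq)


def replicate_seed(master_seed: int, replicate: int) -> int:
    """Deterministic per-replicate seed derived from a master seed (< 2^31)."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=(int(replicate),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _rng(model: ConditionModel, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(model.seed, spawn_key=(stream,)))


def simulate_events(model: ConditionModel, rng: np.random.Generator | None = None) -> list[GroundTruthEvent]:
    """Draw a ground-truth event stream for one recording.

    Inter-event gaps are exponential at ``event_rate``; after each event the
    pore is held unoccupied for ``dead_time`` so events never overlap.  Class
    membership, dwell and amplitude are drawn per the class models.
    """
    if rng is None:
        rng = _rng(model, 0)
    if model.event_rate == 0:
        return []
    weights = model.weights
    events: list[GroundTruthEvent] = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / model.event_rate)
        idx = rng.choice(len(model.classes), p=weights)
        cls = model.classes[idx]
        dwell_ms = rng.exponential(cls.dwell_scale)
        amp = rng.normal(cls.mean_blockade, cls.sd_blockade)
        amp = -min(abs(amp), model.baseline_current)  # blocked current cannot go below zero
        if t + dwell_ms * 1e-3 > model.duration:
            break
        events.append(GroundTruthEvent(cls.label, t, dwell_ms, amp))
        t += dwell_ms * 1e-3 + model.dead_time
    if not events:
        warnings.warn(
            f"duration {model.duration} s too short to host any event at rate "
            f"{model.event_rate}/s",
            SimulationWarning,
            stacklevel=2,
        )
    return events


def render_trace(
    events: list[GroundTruthEvent],
    model: ConditionModel,
    rng: np.random.Generator | None = None,
) -> CurrentTrace:
    """Render events onto a noisy baseline and apply the bandwidth filter."""
    if rng is None:
        rng = _rng(model, 1)
    n = int(model.duration * model.sampling_rate)
    fs = model.sampling_rate
    if model.noise_sd > 0:
        x = rng.normal(model.baseline_current, model.noise_sd, n)
    else:
        x = np.full(n, model.baseline_current, dtype=np.float64)
    prev_end = -1
    for ev in sorted(events, key=lambda e: e.start_s):
        i0 = int(round(ev.start_s * fs))
        i1 = i0 + max(1, int(round(ev.dwell_ms * 1e-3 * fs)))
        if i0 < prev_end:
            raise ValidationError(f"overlapping events at t={ev.start_s:.6f} s")
        if i0 < 0 or ev.start_s + ev.dwell_ms * 1e-3 > model.duration + 1.0 / fs:
            raise ValidationError(f"event at t={ev.start_s:.6f} s lies outside [0, duration]")
        x[i0:min(i1, n)] += ev.amplitude_pA
        prev_end = i1
    sigma = filter_sigma_samples(fs, model.filter_bandwidth)
    if sigma > 0:
        x = gaussian_filter1d(x, sigma, mode="nearest")
    meta = {
        "condition": model.name,
        "voltage_mV": model.voltage,
        "seed": model.seed,
        "filter_bandwidth_Hz": model.filter_bandwidth,
        "noise_sd_pA": model.noise_sd,
    }
    return CurrentTrace(x, fs, meta)


def simulate_recording(model: ConditionModel) -> tuple[CurrentTrace, list[GroundTruthEvent]]:
    """Convenience: event stream plus rendered trace for one condition/seed."""
    events = simulate_events(model)
    return render_trace(events, model), events


# ---------------------------------------------------------------------------
# Condition presets
#
# Class mixtures follow the published population tables for full-length
# alpha-synuclein and its N-terminal, C-terminal and delta-NAC constructs,
# alone and with adenosine, CPA or DPCPX; raw percentages are renormalized to
# mixture weights.  Component widths and the dwell scales of classes whose
# times were not tabulated are generator choices (see docs/methods.md).
# ---------------------------------------------------------------------------

def _c(label, mean, sd, dwell, pct):
    return dict(label=label, weight=pct, mean_blockade=mean, sd_blockade=sd, dwell_scale=dwell)


_PRESET_CLASSES: dict[str, list[dict]] = {
    # full-length alpha-synuclein
    "full_length": [_c("translocation", -85, 5, 0.52, 66), _c("bumping", -30, 3, 0.05, 24)],
    "full_length:adenosine": [_c("translocation", -86, 5, 0.46, 52), _c("bumping", -30, 3, 0.12, 25)],
    "full_length:cpa": [_c("translocation", -89, 5, 0.47, 40), _c("bumping", -30, 3, 0.09, 37)],
    "full_length:dpcpx": [_c("translocation", -84, 5, 0.42, 37), _c("bumping", -30, 3, 0.07, 46)],
    # N-terminal domain (positively charged; bumping only when alone)
    "n_term": [_c("bumping", -30, 3, 0.05, 70)],
    "n_term:cpa": [_c("translocation", -66, 6, 0.50, 35), _c("bumping", -26, 3, 0.08, 46)],
    "n_term:dpcpx": [
        _c("translocation", -72, 7, 0.50, 36),
        _c("intercalation", -51, 4, 0.20, 21),
        _c("bumping", -30, 3, 0.08, 41),
    ],
    # C-terminal domain (12 negative charges; translocates readily)
    "c_term": [_c("translocation", -69, 4, 0.50, 77), _c("bumping", -30, 3, 0.05, 20)],
    # CPA leaves the C-terminus profile unchanged (non-significant shifts)
    "c_term:cpa": [_c("translocation", -69, 4, 0.50, 77), _c("bumping", -30, 3, 0.05, 20)],
    "c_term:dpcpx": [
        _c("translocation", -64, 4, 0.45, 38),
        _c("intercalation", -31, 3, 0.20, 33),
        _c("bumping", -19, 2, 0.05, 7),
    ],
    # delta-NAC construct (NAC region deleted)
    "delta_nac": [_c("translocation", -86, 5, 0.50, 58), _c("bumping", -27, 3, 0.05, 19)],
    "delta_nac:cpa": [_c("intercalation", -36, 4, 0.15, 66)],
    "delta_nac:dpcpx": [_c("intercalation", -39, 4, 0.20, 35), _c("bumping", -24, 3, 0.06, 34)],
}


def preset_names() -> list[str]:
    return sorted(_PRESET_CLASSES)


def condition_preset(name: str, seed: int = 0, **overrides) -> ConditionModel:
    """A ready-made ``ConditionModel`` for a construct/drug combination.

    ``name`` is ``construct`` or ``construct:drug``, e.g. ``full_length``,
    ``full_length:cpa``, ``n_term:dpcpx``.  Acquisition defaults can be
    overridden via keyword arguments (``duration=20`` etc.).
    """
    try:
        classes = _PRESET_CLASSES[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {preset_names()}") from None
    overrides = dict(overrides, seed=int(seed))
    return build_condition_model(classes, overrides, name=name)
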