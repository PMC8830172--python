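import numpy as np
import pytest

import synpore as sp


@pytest.fixture(scope="session")
def short_model():
    """Default alpha-syn-alone condition, shortened recording (~970 events)."""
    return sp.condition_preset("full_length", seed=42, duration=40.0)


@pytest.fixture(scope="session")
def short_recording(short_model):
    trace, events = sp.simulate_recording(short_model)
    return trace, events


@pytest.fixture(scope="session")
def detected_table(short_recording):
    trace, _ = short_recording
    return sp.detect_events(trace)


def make_summary(condition, per_class, construct=None, unclassified=(2.0, 2.1, 1.9),
                 class_sets=None):
    """Hand-built ConditionSummary from per-replicate metric lists.

    ``per_class`` maps class label -> dict with 'population' (list of %),
    optional 'peak' (list of pA) and 'tau' (list of ms).
    """
    from synpore.profile import ClassSummary, ConditionSummary, MeanSem

    def ms(vals):
        arr = np.asarray(vals, float)
        return MeanSem(float(arr.mean()),
                       float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else None,
                       arr.size)

    classes = {}
    per_replicate = {}
    for lbl, d in per_class.items():
        classes[lbl] = ClassSummary(
            population=ms(d["population"]),
            peak_I=ms(d["peak"]) if "peak" in d else None,
            tau_T=ms(d["tau"]) if "tau" in d else None,
        )
        per_replicate[lbl] = {
            "population_pct": list(d["population"]),
            "peak_pA": list(d.get("peak", [])),
            "tau_ms": list(d.get("tau", [])),
        }
    n_rep = len(next(iter(per_class.values()))["population"])
    if class_sets is None:
        class_sets = [frozenset(per_class)] * n_rep
    return ConditionSummary(condition, n_rep, classes, ms(unclassified),
                            per_replicate, list(class_sets), construct)
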