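"""Config-driven end-to-end runs with a reproducibility manifest.

One structured config file describes a whole experiment — conditions
(simulated presets, explicit class models, or existing trace files),
replicate counts, which condition pairs to compare, and which constructs
form a domain panel — and ``run_pipeline`` executes simulation/ingestion,
detection, profiling, statistics and binding calls, writing every artifact
plus a manifest of input/output digests and derived seeds under one run
directory.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .binding import BindingCall, call_binding, infer_binding_mode
from .detect import DetectionParams, EventTable, detect_events
from .profile import (
    ConditionSummary,
    ReplicateProfile,
    profile_replicate,
    summarize_condition,
)
from .simulate import (
    ConditionModel,
    GroundTruthEvent,
    build_condition_model,
    condition_preset,
    render_trace,
    simulate_events,
)
from .stats import compare_summaries
from .traceio import read_trace, write_ground_truth


class ConfigError(ValueError):
    """Invalid run configuration; message carries the offending field path."""


def events_to_table(
    events: list[GroundTruthEvent], model: ConditionModel, replicate: int = 0
) -> EventTable:
    """Ground-truth events as an EventTable (event-level analysis mode)."""
    from .detect import EventRecord

    fs = model.sampling_rate
    records = []
    for ev in events:
        i0 = int(round(ev.start_s * fs))
        i1 = i0 + max(1, int(round(ev.dwell_ms * 1e-3 * fs)))
        records.append(EventRecord(i0, i1, ev.start_s, ev.dwell_ms, ev.amplitude_pA))
    meta = {"condition": model.name, "replicate": replicate, "seed": model.seed,
            "sampling_rate_Hz": fs}
    return EventTable(records, meta)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunResult:
    """In-memory view of one pipeline run."""

    run_dir: Path
    summaries: dict[str, ConditionSummary]
    profiles: dict[str, list[ReplicateProfile]]
    comparisons: dict[str, dict]
    binding_calls: dict[str, BindingCall]
    mode_calls: dict[str, dict]
    manifest: dict = field(default_factory=dict)


def _condition_model(name: str, spec: dict, acquisition: dict, seed: int) -> ConditionModel:
    if "preset" in spec:
        acq = dict(acquisition)
        acq.update(spec.get("acquisition", {}))
        return condition_preset(spec["preset"], seed=seed, **acq)
    if "classes" in spec:
        acq = dict(acquisition)
        acq.update(spec.get("acquisition", {}))
        acq["seed"] = seed
        return build_condition_model(spec["classes"], acq, name=name)
    raise ConfigError(f"conditions.{name}: needs either 'preset', 'classes' or 'traces'")


def _validate_config(config: dict) -> None:
    if "conditions" not in config or not isinstance(config["conditions"], dict):
        raise ConfigError("config needs a 'conditions' mapping")
    for cname, spec in config["conditions"].items():
        if not isinstance(spec, dict):
            raise ConfigError(f"conditions.{cname}: must be a mapping")
        if not any(k in spec for k in ("preset", "classes", "traces")):
            raise ConfigError(f"conditions.{cname}: needs 'preset', 'classes' or 'traces'")
        for path in spec.get("traces", []):
            if not Path(path).exists():
                raise ConfigError(f"conditions.{cname}.traces: missing trace file {path}")
    for i, comp in enumerate(config.get("comparisons", [])):
        for side in ("control", "drug"):
            if comp.get(side) not in config["conditions"]:
                raise ConfigError(
                    f"comparisons[{i}].{side}: unknown condition {comp.get(side)!r}"
                )
    for drug, panel in (config.get("panel") or {}).items():
        for construct, pair in panel.items():
            for side in ("control", "drug"):
                if pair.get(side) not in config["conditions"]:
                    raise ConfigError(
                        f"panel.{drug}.{construct}.{side}: unknown condition {pair.get(side)!r}"
                    )


def run_pipeline(
    config: dict | str | Path,
    run_dir: str | Path,
    seed: int | None = None,
    detection_params: DetectionParams | None = None,
) -> RunResult:
    """Execute a full experiment described by a config mapping or YAML path."""
    if isinstance(config, (str, Path)):
        config_path = Path(config)
        config = yaml.safe_load(config_path.read_text())
        config_digest = hashlib.sha256(config_path.read_bytes()).hexdigest()
    else:
        config_digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()
    _validate_config(config)
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    master_seed = int(seed if seed is not None else config.get("seed", 0))
    n_rep = int(config.get("replicates", 3))
    mode = config.get("mode", "trace")
    acquisition = dict(config.get("acquisition", {}))
    profile_opts = dict(config.get("profile", {}))
    detection_params = detection_params or DetectionParams(**config.get("detection", {}))

    outputs: dict[str, str] = {}
    try:
        return _run_stages(
            config, run_dir, master_seed, n_rep, mode, acquisition, profile_opts,
            detection_params, config_digest, outputs,
        )
    except Exception:
        # remove partial artifacts so a failed run leaves no half-bundle
        for name in outputs:
            (run_dir / name).unlink(missing_ok=True)
        raise


def _run_stages(config, run_dir, master_seed, n_rep, mode, acquisition,
                profile_opts, detection_params, config_digest, outputs):
    seeds: dict[str, list[int]] = {}
    profiles: dict[str, list[ReplicateProfile]] = {}
    summaries: dict[str, ConditionSummary] = {}

    for ci, (cname, spec) in enumerate(sorted(config["conditions"].items())):
        reps: list[ReplicateProfile] = []
        cond_seeds = []
        if "traces" in spec:
            tables = []
            for r, path in enumerate(spec["traces"]):
                trace = read_trace(path)
                table = detect_events(trace, detection_params)
                table.meta.update({"condition": cname, "replicate": r})
                tables.append(table)
        else:
            tables = []
            for r in range(n_rep):
                ss = np.random.SeedSequence(master_seed, spawn_key=(ci, r))
                rep_seed = int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
                cond_seeds.append(rep_seed)
                model = _condition_model(cname, spec, acquisition, rep_seed)
                events = simulate_events(model)
                truth_path = run_dir / f"truth_{cname}_r{r}.csv"
                write_ground_truth(events, truth_path)
                outputs[truth_path.name] = _sha256(truth_path)
                if mode == "trace":
                    trace = render_trace(events, model)
                    table = detect_events(trace, detection_params)
                else:
                    table = events_to_table(events, model, r)
                table.meta.update({"condition": cname, "replicate": r})
                tables.append(table)
        for r, table in enumerate(tables):
            csv_path = run_dir / f"events_{cname}_r{r}.csv"
            table.write_csv(csv_path)
            outputs[csv_path.name] = _sha256(csv_path)
            reps.append(profile_replicate(table, **profile_opts))
        seeds[cname] = cond_seeds
        profiles[cname] = reps
        summaries[cname] = summarize_condition(
            reps, condition=cname, construct=spec.get("construct")
        )
        prof_path = run_dir / f"profile_{cname}.json"
        prof_path.write_text(json.dumps(summaries[cname].to_dict(), indent=1, default=str))
        outputs[prof_path.name] = _sha256(prof_path)

    comparisons: dict[str, dict] = {}
    for comp in config.get("comparisons", []):
        pair_name = f"{comp['control']}_vs_{comp['drug']}"
        metrics = comp.get(
            "metrics", ["population_pct.translocation", "population_pct.bumping"]
        )
        entry = {}
        for metric in metrics:
            try:
                result = compare_summaries(
                    [summaries[comp["control"]], summaries[comp["drug"]]], metric
                )
            except (ValueError, KeyError) as exc:
                entry[metric] = {"error": str(exc)}
                continue
            entry[metric] = {
                "F": result.F,
                "p": result.p,
                "df": list(result.df),
                "pairs": [
                    {"pair": list(pc.pair), "diff": pc.diff, "p": pc.p_adj, "label": pc.label}
                    for pc in result.pairwise
                ],
            }
        comparisons[pair_name] = entry
    if comparisons:
        comp_path = run_dir / "comparisons.json"
        comp_path.write_text(json.dumps(comparisons, indent=1))
        outputs[comp_path.name] = _sha256(comp_path)

    binding_calls: dict[str, BindingCall] = {}
    for pair in config.get("binding", []):
        call = call_binding(summaries[pair["control"]], summaries[pair["drug"]])
        binding_calls[f"{pair['control']}_vs_{pair['drug']}"] = call
    mode_calls: dict[str, dict] = {}
    for drug, panel_spec in (config.get("panel") or {}).items():
        panel = {
            construct: call_binding(
                summaries[pair["control"]], summaries[pair["drug"]]
            )
            for construct, pair in panel_spec.items()
        }
        mode_calls[drug] = infer_binding_mode(panel).to_dict()
    if binding_calls or mode_calls:
        call_path = run_dir / "binding_calls.json"
        call_path.write_text(json.dumps(
            {
                "binding": {k: v.to_dict() for k, v in binding_calls.items()},
                "modes": mode_calls,
            },
            indent=1,
        ))
        outputs[call_path.name] = _sha256(call_path)

    manifest = {
        "synpore_version": __version__,
        "config_digest": config_digest,
        "master_seed": master_seed,
        "replicate_seeds": seeds,
        "mode": mode,
        "outputs": outputs,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return RunResult(run_dir, summaries, profiles, comparisons, binding_calls,
                     mode_calls, manifest)


def _fmt(stat, unit="", nd=2) -> str:
    if stat is None:
        return "-"
    if stat.sem is None:
        return f"{stat.mean:.{nd}f}{unit}"
    return f"{stat.mean:.{nd}f} ± {stat.sem:.{nd}f}{unit}"


def render_report(result: RunResult) -> str:
    """Human-readable summary table (per-class I, P, T, mean +/- SEM, with
    significance labels against the compared control where available)."""
    lines = [f"synpore run report — {result.run_dir}", ""]
    label_index: dict[tuple[str, str], str] = {}
    for pair_name, entry in result.comparisons.items():
        for metric, res in entry.items():
            if "pairs" not in res:
                continue
            cls = metric.partition(".")[2]
            for pc in res["pairs"]:
                drug = pair_name.split("_vs_")[1]
                if drug in pc["pair"]:
                    label_index[(drug, cls)] = pc["label"]
    for cname, summary in result.summaries.items():
        lines.append(f"condition: {cname}"
                     + (f"  (construct: {summary.construct})" if summary.construct else ""))
        lines.append(f"  replicates: {summary.n_replicates}")
        header = f"  {'class':<14}{'I (pA)':>16}{'P (%)':>16}{'T (ms)':>16}{'vs control':>12}"
        lines.append(header)
        for lbl, cs in summary.classes.items():
            sig = label_index.get((cname, lbl), "")
            lines.append(
                f"  {lbl:<14}{_fmt(cs.peak_I):>16}{_fmt(cs.population):>16}"
                f"{_fmt(cs.tau_T, nd=3):>16}{sig:>12}"
            )
        lines.append(f"  {'unclassified':<14}{'':>16}{_fmt(summary.unclassified):>16}")
        lines.append("")
    for drug, mode in result.mode_calls.items():
        lines.append(f"binding mode [{drug}]: {mode['mode']}")
        lines.append(f"  rationale: {mode['rationale']}")
    incomplete = [c for c in result.summaries.values() if c.n_replicates < 1]
    if incomplete:
        lines.append(f"INCOMPLETE: {incomplete}")
    return "\n".join(lines)
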