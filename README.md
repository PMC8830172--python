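# synpore

Single-molecule nanopore analysis of α-synuclein–drug binding.

α-synuclein (α-syn) is the intrinsically disordered protein whose misfolding
drives Parkinson's disease and other synucleinopathies.  In an α-hemolysin
nanopore assay, single α-syn molecules interrupt the open-pore ionic current
(+100 mV DC, 10 kHz bandwidth); each blockade event is characterised by its
depth *I* (pA) and dwell time *T* (ms) and belongs to one of three classes —
**translocation** (deep, long: the protein threads the pore),
**intercalation** (intermediate: it lodges in the vestibule) and **bumping**
(shallow, brief: it collides and diffuses away).  A drug that binds and
folds α-syn shifts events from translocation to bumping; testing the
N-terminal, C-terminal and ΔNAC domain constructs separately reveals *where*
it binds, and hence whether the complex adopts an aggregation-prone **knot**
(N-terminus only) or a protective **loop** (both termini).

`synpore` implements the full analysis as a tested, reusable pipeline:

* **simulate** — ground-truthed synthetic recordings: Poisson event arrivals,
  exponential dwells, Gaussian blockade amplitudes, Gaussian baseline noise,
  10 kHz low-pass filtering; presets for every construct/drug condition;
* **detect** — robust baseline estimation, hysteresis thresholding, and
  bandwidth-aware feature extraction (filtered-pulse template fits for short
  events);
* **profile** — blockade histograms, 1–3-component Gaussian population fits
  (peak *I*, population *P*), single-exponential dwell fits (characteristic
  time *T*), replicate pooling with mean ± SEM;
* **stats** — one-way ANOVA + Student–Newman–Keuls post hoc with ns/*/**/***
  labels, raw or summary (mean, SEM, n) inputs;
* **binding** — bound/unbound verdicts and knot/loop/indeterminate/none mode
  calls from a domain panel;
* **CLI** — `synpore simulate|detect|profile|compare|call|run|report`, with
  config-driven end-to-end runs and a reproducibility manifest.

## The statistics in brief

Blockade amplitudes are modelled as a Gaussian mixture; the population of
class *j* is the share of all detected events within ±2.5σ of its peak.
Dwell times per class follow a single exponential; the characteristic time
is the left-truncated maximum-likelihood estimate `τ̂ = mean(d | d ≥ c) − c`,
with `c` the detector's resolution limit, and generative class weights are
recovered via the missed-event correction `w_j ∝ n_j / exp(−c/τ̂_j)`.
Conditions are compared per metric by one-way ANOVA with SNK stepwise
comparisons on the studentized range, `q = Δx̄ / √(MS_w/n)`.

## Worked example

```python
import synpore as sp

# one replicate of the alpha-syn-alone condition (~2400 events, 100 s)
model = sp.condition_preset("full_length", seed=1)
trace, truth = sp.simulate_recording(model)
table = sp.detect_events(trace)
prof = sp.profile_replicate(table)
for c in prof.fit.components:
    print(f"{c.class_label:>13}: I = {c.peak_pA:.1f} pA, P = {c.population_pct:.1f}%")
for lbl, dw in prof.dwell.items():
    print(f"{lbl:>13}: T = {dw.tau_ms:.3f} ms (n = {dw.n_events})")
```

prints

```
translocation: I = -85.0 pA, P = 79.7%
      bumping: I = -29.5 pA, P = 18.1%
translocation: T = 0.523 ms (n = 1713)
      bumping: T = 0.048 ms (n = 388)
```

— the fitted translocation peak sits at −85 pA with characteristic time
0.52 ms and bumping at −30 pA with 0.05 ms, matching the generative model
(detected shares differ from the generative 73%/27% mixture because the
shortest bumping events fall below the 10 kHz resolution limit; the
truncation-corrected weights `prof.corrected_weights()` give 0.75/0.25).

A whole experiment — conditions, replicates, comparisons, domain panel — is
one YAML config:

```bash
synpore run --config experiment.yaml --seed 7 --out runs/demo
```

which writes per-replicate event CSVs, per-condition profile JSONs, the
ANOVA/SNK comparison table, binding calls and a manifest, and prints a
population/blockade-time table per condition with significance labels.

## Layout

```
src/synpore/      simulate, traceio, detect, profile, stats, binding,
                  pipeline, cli
tests/            unit + property + end-to-end acceptance tests
docs/methods.md   model assumptions, estimator details, design choices
```
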