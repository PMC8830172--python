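# Methods

## What the package models

`synpore` analyses single-channel voltage-clamp recordings of an
α-hemolysin nanopore interacting with α-synuclein (α-syn) or one of its
domain constructs (N-terminus, C-terminus, ΔNAC).  Under a +100 mV DC bias
the open pore carries a steady ionic current; each protein–pore encounter
transiently blocks part of that current.  Three event classes are
distinguished by blockade depth *I* and dwell time *T*:

| class         | physical picture                       | typical *I*   | typical *T* |
|---------------|----------------------------------------|---------------|-------------|
| translocation | protein threads through the pore       | ≈ −85 pA      | ≈ 0.5 ms    |
| intercalation | protein lodges in the vestibule        | ≈ −50 pA      | intermediate |
| bumping       | protein collides and diffuses away     | ≈ −30 pA      | ≈ 0.05 ms   |

A drug that binds and folds α-syn shifts events from translocation to
bumping; which domain constructs show altered profiles determines whether
the drug pins the protein into a "knot" (N-terminal binding only, NAC region
left free) or closes a "loop" (both termini bound, NAC shielded).

## Synthetic recordings

The generator (`synpore.simulate`) draws a marked point process and renders
it onto a noisy baseline:

* arrivals — exponential gaps at `event_rate`, plus an enforced dead time
  (default 1 ms) so events never overlap; real recordings at the
  concentrations modelled show well-separated events;
* class — categorical draw from the mixture weights.  Preset weights are
  published population percentages renormalised to sum to one (populations
  in the source tables do not sum to 100% because some events fall outside
  the fitted peaks);
* dwell — exponential with per-class scale (ms); amplitude — Gaussian with
  per-class mean and sd, clamped so the blocked current never goes below
  zero;
* rendering — square pulses on a `baseline_current` (+100 pA default, a
  typical α-hemolysin open-pore magnitude at +100 mV) with white Gaussian
  noise (sd 1.5 pA), then low-pass filtered by a Gaussian kernel whose
  −3 dB point sits at `filter_bandwidth` (10 kHz default, matching the
  recording amplifier).  The Gaussian kernel is a deliberate simplification
  of a Bessel filter: monotone step response, analytically tractable
  (`sigma_t = sqrt(ln 2) / (2π f_c)`).

Defaults: 100 kHz sampling (10× oversampling of the filter bandwidth so a
0.05 ms bumping event spans ~5 samples), 25 events/s for 100 s giving
~2400 events per replicate.  These sizes were chosen up front by a power
analysis: the detected-bumping dwell fit has a relative standard error of
roughly `tau/sqrt(n)` ≈ 5% at this n, which is what the recovery guarantees
below require.  Component widths (5/4/3 pA for translocation/intercalation/
bumping) are generator choices — the source histogram widths are not
tabulated.  Per-replicate seeds are derived from a master seed with
`numpy.random.SeedSequence` spawn keys, so triplicates are independent and
individually reproducible.

The generator does **not** emulate: multi-pore recordings, voltage
dependence and capture-rate physics, 1/f and flicker noise, baseline drift,
event substructure (level flickering), or heavy-tailed dwell mixtures.
Passing tests therefore demonstrate correctness of the analysis under the
stated statistical model, not robustness to every instrument artefact.

## Event detection and bandwidth-aware features

Baseline: iterated sigma-clipped median with MAD-derived sd (robust up to
~30% blocked time).  Detection: hysteresis thresholding — open below
`level − 5σ`, close above `level − 2.5σ`; runs shorter than 3 samples are
discarded.  At Gaussian noise, a 5σ opening threshold yields well under one
false event per 10⁶ samples.  Detection operates on deflections from the
estimated level, so it is invariant to constant offsets.

The 10 kHz filter smears and attenuates short events (a 2-sample pulse is
attenuated to ~55% of its nominal depth), so features are extracted
bandwidth-aware using the filter sigma carried in the trace metadata:

* long events (half-amplitude width ≥ max(10, 8·σ_f) samples): dwell from
  interpolated half-amplitude crossings (the half-amplitude width of a
  filtered square pulse equals the pulse width); amplitude from the mean of
  core samples, excluding ceil(3·σ_f) edge samples per side so the filter
  rise does not bias the mean.  (With no filter information the classic
  rule — exclude one edge sample — applies.)
* short events: least-squares fit of the box⊗Gaussian template
  `A·[Φ((t−t₀+w/2)/σ_f) − Φ((t−t₀−w/2)/σ_f)]` with physical bounds
  (w ≥ 1 sample, A ≤ open-pore level).  This removes both the
  half-amplitude-width bias and the attenuation bias.

Events whose fitted width falls below the resolution limit
(max(2, 1.5·σ_f) samples) keep an ill-conditioned amplitude/width trade-off;
they are flagged `low_confidence`, excluded from population and dwell fits,
and accounted for statistically (below).

## Population and dwell fits

Blockade amplitudes are fitted with 1–3 Gaussian components, by default via
mixture maximum likelihood on the raw amplitudes (scikit-learn
`GaussianMixture`); a histogram least-squares variant (default bin width
2 pA) is available to mirror how published profiles were produced.  `k` is
chosen by BIC, with the proviso that solutions containing a component
carrying < 5% of the mixture are deprioritised: BIC otherwise spends a tiny
component on the shallow tail of marginally resolved events, which would
then masquerade as the shallowest class.  The smallest genuine class
population in the conditions modelled is ~9%.

Components are labelled ordinally — deepest peak = translocation,
shallowest = bumping, middle = intercalation.  A single component cannot be
labelled ordinally; it is called translocation if deeper than −50 pA
(midpoint between the shallowest reported translocation peak, −69 pA, and
the deepest bumping peak) and bumping otherwise.  Events are assigned to the
component whose peak is nearest in z-score, within ±2.5σ (≈ 98.8% of a
component's mass; ties go to the deeper peak); events outside every window
stay unclassified.  Population percentages are shares of all detected
events, so they need not sum to 100.

Dwell times per class are fitted with a single exponential.  The default
estimator is the closed-form MLE `tau = mean(d | d ≥ c) − c`, exact for a
left-truncated exponential; the truncation point `c` defaults to the
detector's resolution limit (0.02 ms at the default rates), because events
shorter than that are excluded as unresolvable.  A histogram least-squares
variant mirrors the published single-exponential-decay fits.  Generative
class weights can be recovered from the detected shares by inverting the
truncation loss, `w_j ∝ n_j / exp(−c/τ̂_j)` — the classic missed-event
correction for exponentially distributed dwells.

Verified end-to-end guarantees (see `tests/test_acceptance.py`): across
seeds, the pipeline recovers class weights within ±5 percentage points,
peak deflections within ±1 pA and dwell scales within ±10% in ≥ 90% of
runs at default event counts, and detector recall/precision exceed 0.95
against simulator ground truth.

## Replicate statistics

Per-replicate profile metrics are compared with a fixed-effects one-way
ANOVA followed by the stepwise Student–Newman–Keuls procedure on the
studentized range (SciPy's `studentized_range` distribution; the test suite
cross-checks decisions against an independent brute-force quadrature of the
same distribution).  Summary-statistic mode reconstructs within-group sums
of squares from (mean, SEM, n) via `SD = SEM·√n`, so published table rows
can be compared without raw events.  Unequal group sizes use the harmonic
mean n of the two groups compared.  Blocked pairs (enclosed by a
non-significant range) report `p_adj = max(own p, blocking p)` so the
ns/*/**/*** labels (p < 0.05/0.01/0.001, strict) remain monotone in the
reported p.

## Binding calls

`call_binding` encodes the folding signature: bound = yes when the
translocation population decreases significantly or the bumping population
increases significantly (strong when both).  Each call also carries
`altered`: any significant population change in either direction, or a
change in the fitted component-class set (an intercalation peak appearing is
binding evidence even without the folding signature).  Peak-current shifts
are recorded as supporting evidence only — no published threshold exists
for how large a shift counts.

Qualifying changes require both p < 0.05 (SNK) and an absolute population
change ≥ 8 percentage points.  The effect-size floor is half the smallest
population change reported as significant in comparable experiments
(66% → 52%); without it, a four-construct panel of null comparisons at
α = 0.05 per metric would produce a familywise false "binding" in roughly
one run in five, which would contradict the endpoint behaviour the package
guarantees (a null drug yields mode = none in ≥ 95% of runs).

`infer_binding_mode` then reads the panel: N-terminus altered but C-terminus
not → knot; both termini altered → loop; only C-terminus or only ΔNAC
altered → indeterminate; nothing altered → none.  ΔNAC evidence is recorded
in the rationale but does not decide the mode — the termini do.

## Numerical and interface choices

* Half-open, 0-based sample indexing throughout; dwell in ms, currents in
  pA, blockades negative.
* Traces: tabular text (header + two columns) or a compact binary format
  (magic + JSON header + float32 samples); ABF ingestion is delegated to
  the optional `pyabf` reader.
* Determinism: identical config + master seed reproduce byte-identical
  event CSVs; manifests record SHA-256 digests of every artifact.
* Degenerate inputs raise informative errors: zero-noise traces need an
  absolute detection threshold, fits refuse < 50 events (populations) or
  < 20 events (dwells), mixture components with coincident peaks are
  rejected rather than arbitrarily assigned.

## Known limitations

* The Gaussian filter model is an approximation to the true (Bessel)
  analogue filter; attenuation corrections inherit that approximation.
* Sub-resolution events are excluded and corrected statistically, not
  reconstructed; a heavy excess of sub-resolution events (dwell scale well
  below one sample) would bias the corrected weights.
* The SNK procedure controls multiplicity within one metric family only;
  across-construct multiplicity is handled by the effect-size floor, not by
  a formal familywise correction.
* Binding-mode inference is qualitative by design: it reports where the
  profiles changed, not affinities or kinetics.
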