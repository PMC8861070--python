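# Methods

`optoclean` manages photovoltaic-response (PVR) artifacts in extracellular
recordings acquired during temporally aligned optogenetic stimulation, and
quantifies the optics and inhibition statistics that go with such
experiments. This note describes the models and procedures, the parameters
that matter, the synthetic data the package is validated on, and the
numerical choices made where the design was genuinely open.

## The artifact and the cleaning model

Light striking a silicon probe induces a voltage transient on the electrodes
(the photovoltaic or Becquerel effect). The artifact is time-locked to light
onset and offset, grows linearly with light intensity up to roughly 1000 µV,
saturates near +6000 µV, and its sharpest temporal derivative occurs ~260 µs
after light onset and persists for ~300 µs. Because the artifact is highly
reproducible across pulses of similar intensity while spikes and noise are
not, a per-pulse template built from similar pulses estimates the artifact
without a biophysical model.

The procedure, stage by stage:

1. **Pulse timing** — light onset/offset are the half-maximum crossings of
   the patch-cord photodiode trace, computed per pulse from that pulse's own
   plateau peak (commanded intensities differ across trials). Intervals are
   half-open `[onset, offset)`, 0-based, at the recording rate (30 kHz
   nominal).
2. **Snippets** — peri-pulse segments from 30 ms before onset to 30 ms after
   offset (70 ms for a 10 ms pulse), grouped by (fiber, shank) — eight groups
   for four fibers and two shanks — because the artifact depends on which
   fiber emits and which shank receives.
3. **Preprocessing** — high-pass then supersample ×4 (band-limited Fourier
   resampling; cubic-spline selectable). See "Numerical choices" for the
   high-pass at snippet scale.
4. **Per-pulse template** — the mean of the `k_neighbors = 20` snippets with
   the smallest mean squared error to the pulse of interest, the pulse
   itself included. Onset-aligned and offset-aligned templates are built
   separately (pulse durations vary) and joined by a linear cross-fade over
   100 base-rate samples (3.3 ms at 30 kHz) centred on the pulse midpoint.
   Including the cleaned pulse in its own template costs 1/k of any spike
   unique to it — about 5% at k = 20 — which is the accepted price of the
   method and is verified exactly by the test suite.
5. **Residual detection** — whatever survives subtraction is found on the
   rectified time-derivative of the residual: trials are ordered by light
   intensity and, for each trial/channel/time point, the rectified
   derivative is averaged over a window of 7 intensity-adjacent trials after
   dropping the window's single largest value (which protects spikes, since
   a spike is large in one trial only). Samples where this statistic exceeds
   4× the pre-stimulation standard deviation are *blackout* samples for that
   trial. At the extremes of the intensity ordering the window shrinks
   symmetrically, never below 3 trials.
6. **Blackout expansion** — after spike matching, every blackout interval
   `[a, b)` grows to `[a − 40, b + 20)` base-rate samples, then intervals are
   merged; a spike whose −20/+40 window touches the expanded mask can never
   be trusted. Masks are stored as run-length intervals per snippet and
   channel, not sentinel values.
7. **Spike recovery** — units are sorted from the concatenated PVR-free
   inter-pulse periods (sorting is pluggable; the built-in sorter thresholds
   at −30 µV, clusters waveforms into 2× n_channels clusters via PCA+k-means,
   merges near-identical clusters and applies amplitude curation). Inside
   cleaned snippets, spikes are recovered greedily: channels are normalized
   to unit SD, the most negative unmasked sample is picked, its three
   probe-adjacent channels over the −20/+40 window are compared against every
   unit's waveform in the same normalized units, and the best unit is
   accepted if the mean squared error is below one (i.e. the residual is
   smaller than the data itself). The loop stops when nothing below −4 SD
   remains. Events on the expanded mask are kept but flagged invalid.
8. **Weighted PSTH** — per peri-stimulus bin, the rate is averaged over only
   the trials whose bin lies outside the expanded mask, and the percentage
   of masked ("remaining PVR") trials is reported per bin; a bin masked in
   every trial is undefined, not zero.

## Optics quantifications

* **Emission profile** — the emission at a viewing angle is the sum of
  gamma-uncorrected pixel intensities over the region of interest delineating
  the polished fiber segment; angles are measured from the radial direction
  in 25° steps.
* **Lambertian fit** — a single-amplitude least-squares fit of
  `I = I0 cos(angle)`; the residual norm is the goodness of fit. A diffusely
  emitting (Lambertian) surface is what makes side illumination even in
  scattering tissue.
* **Power density** — emitted power is assumed to pass through the lateral
  surface of a cylinder around the emitting segment:
  `density = P / (2π r L)`. For 10 mW over a 2 mm segment this gives
  53 mW/mm² at the 15 µm fiber surface and 7.96 mW/mm² at the 100 µm
  spike-detection radius.
* **Grid addressability** — fibers on a square lattice at the smallest
  optically resolvable pitch (100 µm) give 100 individually addressable
  fibers per mm²; the count per side is floored.
* **Intensity ratio** — to compare two fiber configurations, the time point
  where configuration A's maximal-intensity PVR is closest to the 1000 µV
  linear limit is found per electrode (the time of maximal amplitude if A
  never reaches the limit); the intensity of configuration B whose PVR at
  that time is closest is located by linear interpolation between measured
  levels (nearest-level mode available), and the ratio is A's maximal
  intensity over that B intensity. Channels whose target amplitude is not
  bracketed by B's measurements are flagged and excluded from the mean. Note
  the procedure is directional: it is well-posed when B can reach A's target
  amplitude, so the inverse-symmetry property holds only for transfer curves
  with comparable output ranges.

## Inhibition statistics

* **Bootstrap latency** — per-unit peri-onset histograms (0.5 ms bins by
  default) are pooled over units resampled with replacement (1000 replicates;
  trial-level resampling available as an option). The latency at a level `p`
  is the left edge of the first post-onset bin whose rate is at or below
  `p`% of the pre-onset baseline (30 ms window); medians and quartiles are
  taken over replicates. Deeper suppression levels can only be reached later,
  which the estimator preserves replicate by replicate.
* **Pre-inhibition split** — per unit, trials are rank-split at the median
  pre-inhibition spike count (middle trial of an odd count belongs to
  neither half; units with all-identical counts are excluded and logged);
  the effect is the mean post-onset rate of high minus low trials. Units are
  grouped into low/moderate/high firing-rate terciles (data-driven
  boundaries by default) and each group gets a two-sided one-sample t-test
  against zero, without multiple-comparison adjustment.

## The synthetic-data generator

Sessions are built additively — `block = noise + spikes + artifact`, exact to
the bit — so every stage of the pipeline can be scored against ground truth.

* Gaussian background noise, default SD 4.5 µV (typical spike-band RMS of a
  good silicon-probe recording; the −30 µV detection threshold then sits at
  ≈6.7σ).
* Biphasic difference-of-Gaussians spike waveforms with troughs drawn from
  100–200 µV, spread over ±2 neighbouring channels with weights
  (1.0, 0.6, 0.3); 12 units on 16 channels by default (≈0.75 sortable units
  per electrode), 10 Hz mean rate, 2 ms refractory period. Firing is a
  thinned Poisson process: suppression to 5% of baseline with 1 ms latency
  and a 1 ms transition constant during pulses, exponential recovery after
  offset.
* 500 pulses of 10 ms with a 0.1 ms commanded slope, four fibers on two
  shanks, five light-power levels balanced within each fiber so every
  (fiber, shank) group sees at least 20 trials per level — the condition
  under which 20 nearest-neighbour pulses share a level.
* The PVR amplitude follows an exponential-approach saturation law
  `A(I) = S (1 − e^{−mI/S})` with `S = 6000 µV`, linear within 10% below
  1000 µV; the time course has an onset transient whose absolute derivative
  peaks 260 µs after onset with a 300 µs full width at half maximum, a
  near-flat plateau, and a mirrored offset transient; amplitude varies over
  depth and fiber–shank pairing. Positive polarity by default (configurable).

What the generator does **not** emulate: electrode drift, bursting and rate
non-stationarity, spatially correlated or 1/f noise, line interference,
overlapping light pulses, waveform variability within a unit, and the
continuous intensity jitter of a real photodiode. Passing tests therefore
demonstrate the pipeline's correctness under the stated statistical
structure, not robustness to every pathology of real recordings.

Tests and the acceptance properties run on a desk-scale session with the same
statistical structure — 200 pulses, 8 channels on two shanks, two fibers, six
units — which preserves the per-level trial counts (20 per level per group)
and unit density of the full-scale default while cleaning in seconds.

## Numerical choices

* **High-pass at snippet scale.** The acquisition chain's digital high-pass
  (1.0 Hz, first-order Butterworth) has a time constant of ≈160 ms — longer
  than a 70 ms snippet. A forward-backward recursive filter is then
  ill-conditioned: its initial-condition transient spans the whole snippet
  and injects a trial-specific baseline on the order of twice the noise RMS,
  which both masquerades as residual artifact and corrupts the spike-match
  error. When a snippet contains less than one cutoff period, the filter's
  only attainable effect is DC removal, which `preprocess` applies exactly;
  the Butterworth is used whenever it is well-posed (≥ one cutoff period of
  data). The cutoff remains a configuration field.
* **Supersampling edges.** Fourier resampling assumes periodicity; snippets
  are reflect-padded internally (up to 256 samples) so wrap-around ringing
  does not contaminate the snippet edges, then trimmed.
* **Residual threshold.** The paper-style criterion "4× the standard
  deviation of the pre-stimulation period" is applied with the SD of the
  rectified derivative itself (pooled per channel across trials over the
  30 ms pre-onset span). Taking instead the SD of the *windowed* statistic —
  which has a positive mean about 2.9× its own SD — would flag ≈13% of
  pure-noise samples; the implemented reading has a near-zero false-positive
  rate and full sensitivity to the constructed positive controls.
* **Match normalization.** The unit waveforms are compared in the same
  normalized units as the data: both are divided by the trial's per-channel
  SD (computed over unmasked samples). The acceptance rule "error < 1" then
  means "the residual of the match is smaller than the data", which is
  scale-free: multiplying the recording (and therefore the unit waveforms
  sorted from it) by any gain leaves every decision unchanged.
* **Alignment.** Noisy trough detection jitters by ±1 sample, which is
  expensive at spike slew rates; the matcher evaluates window shifts of up
  to ±2 samples and keeps the best. Rejected picks consume only a narrow
  span on neighbouring channels (so nearby spikes of other units remain
  pickable); accepted spikes consume their full ±2-channel neighbourhood
  (so one spike cannot be accepted twice via its neighbour-channel
  deflections).
* **Ties and determinism.** All sorts are stable, the greedy matcher breaks
  ties by array order, and every stochastic routine takes an explicit seed;
  identical inputs yield identical outputs.

## Known limitations

* Coincident spikes of different units inside one −20/+40 window are not
  separable: the matcher marks samples as consumed but does not subtract
  accepted waveforms (no template peeling). On artifact-free synthetic data
  this caps the agreement between template matching and plain threshold
  detection at ≈0.95–0.97 F1.
* The error<1 acceptance rule loses margin when a channel's SD is close to
  the unexplained background; units with troughs near the 100 µV floor are
  the first to lose spikes.
* The built-in sorter is deliberately simple (threshold + PCA + k-means with
  merging and amplitude curation). It is the hermetic test vehicle and the
  default, not a replacement for a production sorter; any sorter that
  produces per-unit mean waveforms can be plugged in through
  `UnitTemplate`.
* The intensity-ratio procedure is directional (see above) and inherits the
  quantization of the measured intensity levels in nearest-level mode.
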