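# Methods

This note documents the models, parameter choices and limitations behind
`calscreen`: what the synthetic screen emulates, how traces are reduced to
features, how compounds are scored, and where the open design decisions were
resolved.

## Synthetic screen model

### Calcium traces

A whole-well fluorescence trace is modeled as a baseline plus a superposition
of oscillation-event kernels plus i.i.d. Gaussian noise. Events arrive as a
homogeneous Poisson process; each kernel rises linearly over `rise_tau_s` to
a Gaussian-sampled amplitude and decays exponentially with `decay_tau_s`.
Kernels superpose additively, so events closer than the rise time merge into
taller compound peaks — a deliberate source of realistic irregularity. With
probability `subpeak_prob` an event carries one secondary kernel (relative
amplitude `subpeak_rel_amp`) starting 45% of a decay constant into the
parent's decay, producing a shoulder on the descent.

Defaults (all configurable):

| parameter | default | rationale |
|---|---|---|
| `duration_s`, `sampling_hz` | 600 s, 3 Hz | acquisition protocol of the emulated assay (1800 samples) |
| `baseline` | 100 a.u. | arbitrary fluorescence offset; the analysis is offset- and scale-invariant |
| `event_rate_hz` | 0.1 Hz | one oscillation per ~10 s, typical of mature synchronized spheroid networks; high enough that per-well count statistics resolve the disease effect |
| `amp_mean`, `amp_sd` | 50 ± 5 a.u. | ~10% event-to-event amplitude variability |
| `rise_tau_s`, `decay_tau_s` | 1 s, 3 s | sharp-rise/slow-decay calcium transient kinetics |
| `noise_sd` | 1 a.u. | high signal-to-noise of whole-well kinetic reads |
| `subpeak_prob`, `subpeak_rel_amp` | 0.15, 0.30 | occasional interrupted oscillations in healthy wells |

The disease model (CDD genotype) multiplies the event rate by 1.8, the
amplitude scale by 0.6 and the subpeak probability by 2 — faster, smaller,
more irregular oscillations. A compound's `rescue_fraction` r linearly
interpolates each multiplier between the disease value (r = 0) and 1
(r = 1), so a fully rescued well has exactly the control generative
parameters. Dose–response wells apply an effective rescue
`r · c^h/(c^h + EC50^h)`.

An earlier, slower parameterization (0.02 Hz events, 2 s/8 s kinetics) was
rejected during design: with ~12 events per trace, Poisson counting noise
across wells is comparable to the planted genotype shift, and the screen's
defining property — near-complete separation of disease and control
signatures — is lost. The defaults above restore that separation while
staying within physiological ranges.

### Plates

Default layout: 384 wells; per vehicle kind (DMSO, water) 12 control-vehicle
and 12 disease-vehicle wells; compound wells are disease-genotype wells in
triplicate at 1 µM. Viability is `1 − toxicity` plus Gaussian noise
(SD 0.03, clipped to [0, 1]); spheroid area is a pass-through column.
Randomness uses one master seed with an independent substream per
`(seed, plate, well)` (CRC-32 of the identifiers feeding a `SeedSequence`),
so adding wells never perturbs existing ones and plates reproduce bit for
bit.

### MEA recordings

Per-electrode spike trains superpose three processes: Poisson singles
(`base_rate_hz`), within-electrode bursts (`spikes_per_burst` spikes at
`intraburst_isi_s`) and plate-wide network events that recruit each
electrode with `participation_prob` — the knob that controls cross-electrode
synchrony. Voltage rendering adds a negative biphasic waveform (0.4 ms
trough, 0.6 ms rebound) at each spike time on Gaussian noise; the parameter
contract requires `spike_amp/noise_sd > 5.5` so rendered spikes are
detectable by the 5.5-SD threshold.

## Trace featurization

Traces are smoothed with a centered moving average (default 1 s = 3 samples)
before detection. A **parent peak** is a smoothed local maximum whose
prominence reaches `min_prominence_frac` (default 0.10) of the smoothed
dynamic range. Each parent spans one full oscillation cycle: its troughs are
the smoothed-trace minima between its apex and the adjacent parent apexes
(or the trace edges). This trough definition was a genuinely open choice; the
alternative — the nearest flanking local minima — makes the subpeak scan
vacuous, because any interrupting shoulder creates a local dip that would
itself become the trough, leaving no secondary maxima between troughs.
Bounding at the inter-parent minima keeps shoulders inside the parent's
segment, at the cost of making rise/decay times partly gap-dependent on
near-flat baselines.

Per parent: height = apex minus left trough; width = full width at half
prominence (robust to elevated baselines, unlike half maximum); rise/decay
times = trough→apex and apex→trough. Relative height r = height / tallest
parent is binned right-closed at (1/3, 2/3) into classes 1–3 (the tallest
peak is always class 3). Secondary maxima between a parent's troughs with
within-segment prominence ≥ `subpeak_prominence_frac` (default 0.10) of the
parent prominence are **subpeaks**; a parent is **singular** iff it has
none. Note an implied band: a bump is a subpeak only while its prominence
stays below the parent-detection threshold, otherwise it is a (typically
class-1) parent in its own right. Both outcomes express irregularity and
both are counted by the feature set.

The 17 descriptors, in fixed order: peak count; mean/SD of height, width,
spacing (successive apex times), rise time, decay time; class-1/2/3 counts;
singular/irregular counts; total subpeak count. SDs are sample SDs (n−1).
Degenerate conventions keep the vector finite: zero peaks → all entries 0;
one peak → spacing mean and all SDs 0. Features are computed on the trace as
given (raw fluorescence); an explicit ΔF/F step was left out because the
analysis is scale-invariant end to end (median normalization cancels common
factors), so it would not change any score.

## Compound scoring

Normalization is per plate × vehicle: each feature is divided by the median
of the reference wells (control-genotype vehicle wells of the same vehicle;
at least 3 required), log-transformed (natural log; the base only rescales z
uniformly) and z-scored against the reference wells' log values. Count
features use a +1 offset inside the log; continuous features a 10⁻⁶·median
offset. A reference feature with zero spread yields z = 0 at the reference
mean and ±10 elsewhere, and is flagged in the stats table.

The reference group is configurable. The default is the healthy-control
vehicle wells, so a low Scalar Perturbation means "close to the control
signature", which is what makes the lowest-SP compounds the lead candidates;
the alternative reading (distance from untreated disease wells) is available
via `reference_group="CDD"`. Note that a replicate drawn from the reference
distribution itself has expected SP ≈ √17 ≈ 4.1, not 0; SP is exactly 0 only
at the reference center.

SP is computed per replicate (Euclidean norm of selected z-scores; default
all 17) and averaged over replicates — not on replicate-averaged vectors.
Rescue boundaries default to the min–max of control-vehicle features, per
vehicle kind, with percentile and mean ± k·SD methods available. PR per
replicate is 100 × (features inside)/17, averaged over replicates.

Ranking: SP ascending (rank 1 = smallest), PR descending (rank 1 = largest),
ties broken lexicographically by compound id. Selection: top-50 SP, PR
strictly greater than 60%, and compound mean viability ≥ 0.7 × the vehicle
median (the threshold is a package choice; the screen protocol excludes
hits that impair survival without quantifying the cutoff). A lead satisfies
all three.

Dose–response fits the four-parameter Hill model to mean PR per
concentration by least squares, with EC50 parameterized on the log10 scale
(bounds: responses in [−20, 120] PR points, Hill slope in [0.05, 100]).
Fewer than four distinct concentrations, a response range under 5 PR points,
or optimizer failure give `converged = False` with absent parameters.

## MEA metrics

Spike detection estimates the noise SD robustly as MAD/0.6745 (immune to the
spikes themselves) and takes the local minimum within a 1 ms refractory
window after each negative crossing of 5.5 SDs (polarity configurable).
Active electrodes fire ≥ 5 spikes/min (boundary inclusive). Bursts are
maximal runs of ≥ 5 spikes with every inter-spike interval ≤ 100 ms; network
bursts are pooled runs (across active electrodes) of ≥ 10 spikes from
≥ ⌈25% of active electrodes⌉. The synchrony index is the fraction of
reference spikes with a partner spike within ±20 ms, averaged over ordered
pairs of non-empty trains — bounded in [0, 1], equal to 1 for identical
trains, and ≈ 1 − exp(−2rw) for independent Poisson trains at rate r.
Commercial MEA software computes a proprietary cross-correlogram statistic
under the same window; the coincidence fraction is this package's documented
stand-in and is named in the output metadata.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis relies on: plate layout
and replicate structure, vehicle-matched controls, a multidimensional
disease signature, planted rescue with known ground truth, viability
confounds, and MEA burst/synchrony structure. It does **not** model
photobleaching or baseline drift, instrument-specific fluorescence units,
biophysical calcium dynamics, quasi-periodic (non-Poisson) oscillation
timing, spheroid size dynamics, or real compound pharmacology. Passing tests
therefore demonstrate that the *analysis* recovers planted effects under the
assumed noise model — not that any particular real compound would score
well.

Two quantitative limitations worth knowing:

* **Min–max boundaries have heavy sampling tails.** With 12 control wells
  per vehicle, an outlier control well widens a boundary for the whole
  plate; conversely a tight control draw deflates every replicate's PR on
  that feature. In planted screens of 100 inert decoys, a handful of decoys
  (0–5, seed-dependent) can exceed 60% PR and surface as false-positive
  leads; real screens counter this with follow-up assays. The percentile and
  mean ± k·SD boundary methods trade this tail sensitivity for a fixed
  nominal coverage.
* **Relative-height classes are max-sensitive.** One merged double-height
  peak rescales every other peak's relative height in that trace, so the
  class-count features are the noisiest of the 17. They are retained because
  the aggregate scores are robust to a few noisy coordinates.

## Problem sizes used in the test suite

The suite exercises the full screen at its native scale — 384-well plates
(330 compound wells) over a 5-seed battery, 500-trace detector/oracle
comparisons, and 20 seeded dose–response series — which completes in well
under a minute of simulation and scoring on one core; the MEA closed-form
checks use minutes-long recordings at 12.5 kHz. These sizes were chosen so
every statistical assertion has comfortable Monte-Carlo margins.
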