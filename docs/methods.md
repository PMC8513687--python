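# Models and methods

This note documents the generative models behind the synthetic data, the
extraction rules, the numerical choices, and the limits of what the test
suite demonstrates.

## Array geometry

A rectangular grid of multimodal pixels (default 32 × 32 at 58 µm pitch,
four photodiode sites per pixel on a 2 × 2 subgrid), giving 1024 electrode
sites and 4096 optical sites over a 1.85 mm field of view.  Radial
quantities are measured from the mean of the pixel centres.  The field of
view must agree with `rows × pitch` within 2 %; grids of other sizes are
accepted for testing and scaled-down runs.

## Stimulation and the refractory capture model

A stimulation protocol is a train of charge-balanced biphasic current
pulses (equal-and-opposite phases of `pulse_width_ms` each, so charge
balance holds by construction).  Capture follows a deterministic rule: the
first pulse captures; a later pulse captures iff the time since the last
*captured* pulse is ≥ ARP.  The boundary is deliberately closed — an
inter-beat interval exactly equal to the ARP still captures — so that a
222 ms ARP yields 50 % capture at a 111 ms period (9 Hz), matching the
standard half-capture readout.  For a periodic train the pattern is
periodic and the asymptotic fraction equals 1/⌈ARP/T⌉; the model reports
the asymptotic fraction for trains of ≥ 20 pulses and the finite ratio
otherwise.  `estimate_arp` supports the classical doubling readout
(ARP = 2 × period at the highest ~50 % frequency) and a grid inversion
(smallest ARP on a 1 ms grid consistent with every observed rate within
±0.05).

The model treats the relative refractory period only as beat-timing jitter;
systematic latency prolongation near the ARP is not modelled.

## Optical beat waveform

The study conditions specify the beat through its fiducials, not a curve
family, so the generator's contract is on *realized* fiducials: the sampled
waveform's maximum rise slope falls at CT′, its maximum at CT, its most
negative decay slope at RX′, and its first decay below 10 % of the peak at
T_d, each exact up to sampling.

The family is a piecewise two-component sigmoid.  The rise mixes a broad
logistic (time constant `min(CT′, CT − CT′)/2.5`) with a sharper one
(τ = 10 ms), both centred at CT′, affinely normalized to 0 at the stimulus
and 1 at CT; because both components have their steepest slope at CT′ and
are symmetric there, the mixture's realized CT′ is exact.  The decay mixes
a broad logistic centred at RX′ with a sharp one (τ = 12 ms, weight 0.25),
normalized to 1 at CT; the broad time constant is solved by bisection so
the decay crosses the 10 % criterion exactly at T_d.  When T_d sits too
close to RX′ for the sharp component to fit under the criterion the
calibration falls back to a pure logistic.  The sharp components exist for
identifiability: a single broad logistic satisfies the same fiducials but
has derivative extrema so flat (the decay time constant forced by the
CT→RX′→T_d spacing is ≈ 70–80 ms) that their locations are statistically
ill-determined under measurement noise.  The mixture keeps the transient
smooth and monotone per phase while concentrating curvature at the
fiducials.

Beat-to-beat variability is one Gaussian timing shift per beat
(`jitter_sd_ms`), rigidly translating the whole transient.  Consequently
all timing features share a single per-beat jitter; the per-feature spreads
of real recordings (e.g. σ 9.1 ms for CT_PKS but 23.6 ms for T_d at
baseline) are only partially emulated — the presets carry the printed σ
values as metadata, and the generator uses the CT_PKS σ as the common
timing jitter.

## Extracellular potential complex

Per pulse: a biphasic rectangular artefact (±`artefact_amp_uv`, one phase
width each; artefacts appear for every pulse, captured or not), and for
captured pulses an evoked spike plus T-wave.  The spike is a dominant
negative Gaussian lobe (σ = `spike_width_ms`, default 1.5 ms) preceded by a
0.55-weight positive lobe 2.5 σ earlier; the template's realized trough
position and peak-to-peak span are calibrated numerically once so the
trough lands exactly at stimulus + T_ap with peak-to-peak exactly
`spike_amp_uv`.  The T-wave is a unipolar Gaussian (FWHM
`twave_width_ms`) with apex exactly FPD after the spike trough.  Additive
white Gaussian noise comes from the call's seed.  Defaults: T_ap 13.6 ms
(678 µm recording–stimulation separation at a 50 µm/ms monolayer
conduction speed), spike 100 µV, artefact 2 mV, T-wave 30 µV.

FPD is operationally defined here as spike extremum → T-wave apex, and T_d
as stimulus → first decay below 10 % of beat peak; both quantities are
marked on published waveforms without printed endpoint definitions, so
these operational definitions are package conventions applied consistently
by generator and extractor.

## Paced multimodal recordings

Each captured pulse spawns one optical beat per pixel with onset
`stim + intercept + slope · r(pixel) + jitter`; a negative radial slope
makes the periphery contract first (the observed pattern in confluent
monolayers, attributed to mechanical constraints rather than electrical
conduction).  Designated pixels also record the extracellular complex with
the spike delayed by `r / conduction_speed`.  All stochastic draws derive
from the single `seed` in the parameter object; identical parameters and
seed give bit-identical recordings.

## Feature extraction

Optical traces are smoothed by Savitzky–Golay least-squares local
polynomials (default 7 ms window, order 3; mirrored edges) and
differentiated per ms.  Each stimulus window (one pacing period) is
baseline-referenced: by the mean raw intensity over the
`baseline_window_ms` (default 25 ms) *preceding* the stimulus when
available — averaging keeps the reference noise-robust, and the previous
beat has decayed there at the pacing rates where full fiducials are
measurable — else by the smoothed onset sample, which is exact at zero
noise.  Within a window: CT′ = earliest derivative maximum up to the peak
(ties take the earliest sample), CT = the window maximum, RX′ = derivative
minimum after the peak, T_d = the 10 % decay crossing, located coarsely as
five consecutive sub-threshold smoothed samples and refined by a local
quadratic fit of the raw samples (±40 samples), which averages noise
without the bias a straight line picks up from the decay's curvature.
Windows whose peak falls below 30 % of the median candidate peak (windows
reaching ≥ 20 % of the largest peak) count as non-captured; beats truncated
by the recording end are dropped.  The median is taken over candidate
windows rather than all windows because at capture rates below 50 % most
windows contain no beat and a plain median would collapse to noise level.

For noisy data the config offers an optional zero-phase third-order
Butterworth low-pass (`lowpass_hz`) as the conditioning stage; at 10 Hz it
leaves the ≤ 16 Hz transient essentially untouched while attenuating
wide-band noise far more strongly than a short local-polynomial window.

Potential traces: the artefact window (two phase widths + 5 ms guard) is
excluded — blanking is the software analogue of recording at a distance
from the stimulation site; the spike is the largest absolute excursion
within `spike_search_ms` (80 ms), thresholded at 4 × the trace's median
absolute deviation; amplitude is the local peak-to-peak over ±6 ms; the
T-wave apex is the largest smoothed extremum from 40 ms after the spike to
one smoothing width before the next pulse (so the next artefact cannot
leak into the search through the kernel).

### Error propagation and noise tolerances

For fiducials defined by threshold crossings or extrema, timing precision
under additive noise is bounded by (residual noise amplitude)/(local
slope) or by the curvature at the extremum.  The T_d crossing is the
shallow case: at the 10 % level the decay slope is ≈ 0.001 amplitude/ms,
so even a baseline reference averaged over 50 ms of pre-stimulus samples
(residual ≈ 0.7 % of amplitude at 5 % sample noise) propagates to ≈ 7 ms,
and the noise-robustness test therefore asserts 5 ms for the slope/peak
fiducials but 10 ms for T_d at 5 % noise.  This bound is a property of the
definition, not of the implementation; real transients have comparably
shallow terminal decays.

Capture detection on raw traces does not reuse full fiducial extraction:
at pacing periods shorter than T_d successive beats overlap and truncated
beats carry no complete fiducial set.  Instead beats are counted as
supra-threshold local maxima of the smoothed derivative (one per
contraction upstroke, ≥ 50 ms apart); because the mechanical latency
(~140 ms to CT′) can exceed the pacing period, upstrokes are counted
rather than attributed to individual pulses.

## Time-lapse opacity and impedance

Opacity frames are sums of radial Gaussian blobs, one per aggregate, with
radius growing linearly (`growth_rate_um_per_h`) and amplitude decaying
exponentially (`opacity_decay_per_h` — cells migrating away).  Impedance
frames are baseline plus, per aggregate, a smooth disc (sigmoid edge of
width pitch/4) scaled by a saturating adhesion ramp `1 − exp(−Δt/τ)`
(default τ = 6 h) toward the plateau; overlapping aggregates combine by
maximum so the excess never exceeds the plateau.  Per-pixel impedance is
therefore non-decreasing until detachment.  After trypsin administration
the impedance excess decays exponentially, slowly at room temperature and
faster once 37 °C incubation starts (`DetachmentParams`, absolute assay
minutes).  Preset plateaus: fibroblasts 1.1 MΩ (strong adherence, ECM
secretion), cardiomyocyte spheroids 0.65 MΩ, over a 0.25 MΩ cell-free
baseline.  Detachment kinetics are fitted per temperature phase by
log-linear least squares on the region-mean excess; fitted rates below
1e−8/min are reported as non-decaying (infinite half-time).

The time-lapse model does not emulate cell migration texture, internal
opacity gradients, confluent-sheet percolation, or impedance drift; its
role is to give the imaging metrics a ground truth with the right
monotonic structure and magnitudes.

## Dose-response aggregation and trend testing

Per (dose, feature): arithmetic mean, sample sd (n − 1), count.  The trend
statistic is the least-squares slope of per-beat values against dose
*rank* — with only a handful of doses no concentration–response curve is
fitted, and rank keeps the statistic monotone-invariant.  Significance
comes from a two-sided permutation test on dose labels: exhaustive
enumeration of distinct label assignments when their number does not
exceed the requested permutation count (exact p = proportion of
assignments with |slope| ≥ |observed|, ties counted), otherwise seeded
Monte-Carlo shuffling with the add-one correction.  Note the exhaustive p
on tiny designs is bounded below (2/20 for two doses of three beats), so
direction calls at α = 0.05 require more data.  The null rejection rate is
verified at ≈ 400 seeded replicates of a three-dose null design.

## Problem sizes and determinism

The test suite and the acceptance script run on deliberately small
configurations — single-pixel or ≤ 8 × 8-grid recordings of 2–20 pulses at
1 kHz, one full 32 × 32 two-pulse reconstruction, 400-replicate null
calibration — chosen so the whole suite completes in seconds while still
exercising every code path at the study's parameter values.  Every
stochastic step takes an explicit integer seed; identical seeds give
bit-identical outputs.

## Known limitations

- Single rigid timing jitter per beat; no per-feature variability, no
  amplitude jitter, no drift or photobleaching.
- Measurement noise is white and Gaussian; no 1/f, line interference, or
  motion artefacts.
- No spontaneous (unpaced) beating; capture is strictly deterministic.
- Aggregate centres for front-radius metrics are supplied, not segmented.
- The 10 nM isoproterenol preset extrapolates the 3 nM shortening ratio and
  is flagged non-authoritative in the preset file.
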