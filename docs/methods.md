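# Methods

## The ion-current length-control model

Flagellar length sensing by an "ion current" works as follows: Ca²⁺
channels are distributed uniformly along the flagellar membrane, so total
Ca²⁺ entry — and hence the time-averaged Ca²⁺ concentration at the base —
grows in proportion to length, `Ca = α·L`.  The calcium-dependent kinase
CDPK1 reads this signal.  Its calcium binding equilibrates much faster
than length changes, so the active fraction is the saturable binding curve

    F = αL / (αL + K_D).

CDPK1 phosphorylates the anterograde IFT motor kinesin-2, blocking its
entry into the flagellum; phosphorylation and dephosphorylation are again
fast, so the phosphorylated fraction takes its Michaelis–Menten
quasi-steady-state `F/(F + K_M)` and the *entry-competent* fraction is

    K = 1 − F / (F + K_M).

Assembly is carried by competent kinesins loaded with precursor from a
shared cytoplasmic pool; binding is unsaturated, so cargo loading is
proportional to the free pool `(P − 2L)` (two flagella draw on one pool).
With a constant disassembly rate `D`,

    dL/dt = A·K·(P − 2L) − D.

Longer flagella admit more Ca²⁺, activate more CDPK1, phosphorylate more
kinesin, inject less IFT, and stop growing where assembly balances
disassembly — a negative feedback with a single stable set-point `L*` on
(0, P/2), located by bracketed root search (`steady_state`) to
|dL/dt| < 1e-10 µm/s.

Integration is forward Euler with `dt = 0.02 s`, states recorded every 50
steps (1 s).  Length is clamped at zero from below after every step;
amputation events reset L to 0 and the flagellum regrows from the intact
pool.  In the degenerate case `α = 0` the feedback disconnects and the
model collapses to the linear ODE `dL/dt = (AP − D) − 2A·L` with the
closed form `L(t) = L*(1 − e^{−2At})`, which the tests use as an analytic
oracle; the Euler error is O(dt) and halving dt demonstrably halves it.

### Default parameters

No parameter table accompanies the published simulation figures, so the
defaults here are *illustrative, not fitted*: they are chosen to place the
set-point near a wild-type length and regeneration on the tens-of-minutes
scale.

| parameter | default | units | meaning |
|---|---|---|---|
| alpha | 1.0 | conc·µm⁻¹ | Ca²⁺ per unit length |
| K_D | 10.0 | conc | CDPK1–Ca²⁺ dissociation constant |
| K_M | 0.48 | – | CDPK1–kinesin Michaelis constant |
| A | 4.0e-4 | µm·s⁻¹ per µm pool | assembly constant × kinesin pool |
| P | 40.0 | µm-equivalents | total precursor pool (two flagella) |
| D | 3.0e-3 | µm/s | constant disassembly rate |

These give `L* ≈ 12.0 µm`, an initial regrowth rate of ≈0.8 µm/min and
recovery to within 1% of the plateau in a few hours of simulated time.
Only ratios matter for the fixed point; A and D jointly set the time
scale.

## Free Ca²⁺ in EGTA-buffered media

Single-site 1:1 binding: with x = free Ca²⁺ and b = Ca_t − x bound,
mass action `x(E_t − b) = Kd_app·b` reduces to
`x² + (E_t − Ca_t + Kd)x − Kd·Ca_t = 0`, solved with the
cancellation-free quadratic form and cross-checked by bisection on the
(monotone) residual.  EGTA protonation is folded into the apparent
constant `Kd_app = Kd_abs(1 + 10^(pKa1−pH) + 10^(pKa1+pKa2−2pH))` with
EGTA constants Kd_abs = 1.07e-11 M, pKa 9.40 and 8.79.  Mg²⁺ competition
and ionic-strength/temperature corrections are out of scope; pass the
apparent Kd for your conditions (≈150 nM at pH 7.2, 0.1 M ionic
strength).  The solver reproduces 170 µM for TAP medium (0.17 mM CaCl₂,
no chelator) and ≈39 µM for the 10 mM CaEGTA calibration standard.  The
figure of ~150 nM free Ca²⁺ for TAP + 1 mM EGTA is reproduced in order of
magnitude only: the constants behind a three-significant-figure value are
not determinable from the stated recipe.

## Synthetic kymographs and what they do (not) emulate

All generators are pure functions of (config, seed) and return exact
ground truth.  Default geometry: 12 µm flagellum, 0.16 µm px⁻¹ (76 rows),
20 frames s⁻¹, 60 s.

* **Ca²⁺ channel** — background 50 a.u. plus spikes: separable
  half-sine temporal pulse (1 s) × Gaussian spatial profile
  (σ = extent/2 = 1.5 µm) of peak 300 a.u., at renewal-process times
  (exponential, or gamma with shape > 1 for the regularised non-Poisson
  regime); the whole frame is scaled by `exp(−bleach·t)` and Gaussian
  read noise (σ = 8 a.u.) is added.  Truth area is the pre-noise,
  pre-bleach spatial sum × frame interval.
* **IFT channel** — anterograde trains base→tip at 2 µm/s and retrograde
  tip→base at 3 µm/s, Poisson entries at 1.2 s⁻¹ each, per-train
  amplitude N(100, 15) a.u. deposited one pixel per frame along the
  path.  Retrograde trains may pause once mid-course; with
  `reactivate_on_spike` the pause ends at the first Ca²⁺ spike after its
  start (never, if none follows).  Trains cut by the movie end are
  flagged truncated.
* **Dual channel** — one spike process drives both channels; the
  observed GCaMP image is `clean_gcamp + fraction × observed_ift` with
  fraction 0.2, making the scaled subtraction exactly invertible at zero
  noise.

Not emulated: optical PSF and sub-pixel anti-aliasing, cell-body
fluorescence, gliding motility, train-size variation along a track,
tip-turnaround remodeling.  Passing tests therefore demonstrate the
correctness of the measurement pipeline under the stated statistical
structure, not robustness to every optical artefact of real TIRF data.
A deliberate realism limit: Poisson entries occasionally start two trains
within a frame or two of each other; such pairs are physically one
brighter train for any tracer and are the dominant source of frequency
undercounting (see below).

## GCaMP quantification

Pipeline: 2-D Gaussian smoothing (default σ = 1 px × 1 frame, reflective
boundaries) → photobleach correction → spike detection → influx metrics.

* **Bleach correction** fits `a·e^{−kt}` to the per-frame spatial mean
  over frames that a robust pre-pass classifies as spike-free, then
  divides by the envelope.  Non-decaying fits return k = 0 with a logged
  warning (an unbleached movie is not an error).
* **Detection trace** is the per-frame spatial *sum*: the indicator is
  anchored at fixed density, so influx is an extensive quantity.
* **Baseline** is a 5-s rolling median; a second pass re-estimates it
  with detected event frames interpolated away, so clustered events do
  not inflate it and clip their own areas.
* **Threshold**: 5 × the MAD noise scale of the baseline residual,
  bounding both peak height *and* prominence.  (Prominence alone is
  peak-to-valley; beside a noise dip, a noise bump can double its
  apparent prominence.)  A differenced-trace noise estimate would
  collapse on smoothed input and is not used.  Peaks narrower than
  0.15 s are rejected; spans closer than the 0.5 s separation limit merge
  into one event.
* **Onset/end** are reported at the 10%-of-peak crossings (the baseline
  zero crossing drifts frames early under correlated noise); the area
  integrates the full above-baseline span.  Influx intensity is total
  event area per unit imaging time; frequency is events per second.

On 20 seeded kymographs with mild bleaching, recall and precision are
1.0 and influx intensity is within 6% of truth (10% required).

## IFT trajectory extraction and metrics

The published analysis used an external deep-learning tracer; here a
classical method serves: for each hinted speed the background-subtracted
image is averaged along lines of the matching slope (±3 frames), which
amplifies in-direction ridges by the kernel length and dilutes crossing
traces to a known leakage floor of ~amplitude/7.  Ridge maxima per column
(edge-padded, ≥2 px apart) are linked greedily frame-to-frame with the
hinted slope as motion model (gap ≤ 3 frames, offset ≤ 2 px).  The ridge
threshold is `max(3σ_filter, 0.35 × robust train amplitude)`; the second
term sits above the leakage floor and below attenuated ridge endpoints.
Tracks are refined to sub-pixel positions by local centre of mass; the
per-point intensity sample sums a ±1-row window (a train deposits one
pixel per frame, so this is unbiased under a one-pixel centroid error).
Phantom tracks are removed by two tests: median raw sample above the
noise floor, and fitted slope within 30% of the traced orientation.
Pixels claimed by two crossing tracks split their intensity in proportion
to each claimant's median amplitude.

`link_and_dedupe` then reconnects fragments (extrapolation agreement
within 3 px over gaps ≤ 5 frames, slopes within 0.3 px/frame) and drops
the lower-intensity member of any pair sharing >50% of its pixels; it is
idempotent and never increases the track count.

Metrics: injection intensity = Σ anterograde per-point intensities /
(length × duration); frequency counts direction-matching tracks crossing
a reference line 2 px above the base, extrapolating a track's fitted line
by up to 6 px (the base region is saturated by crossing traffic and
tracks lose endpoints there; retrograde extrapolated crossings must fall
inside the movie).  Velocity is a least-squares slope over *moving*
segments — runs whose local speed (measured over ±2 points, not adjacent
pixel-quantised differences) exceeds 10% of the global fit — averaged
with duration weights, which stays exact across pause gaps.  Tracks with
net displacement < 2 px are "paused-mixed" and excluded from frequency
and velocity but still mask the background.  Returning (injecting)
intensity sums per-trajectory mean intensities of retrograde trains
ending (anterograde trains starting) within 2 px of the base inside a
half-open window.

On 20 seeded dense kymographs: injection within 4.4%, velocities within
4.2%, base-crossing counts within 1.2·√n of the realised truth counts.
Computed from imported complete ground-truth coordinates (extrapolation
off), injection, both frequencies and both velocities are exact.

## Dual-channel and event-triggered analysis

Bleed-through correction subtracts `fraction × mscarlet` (default 0.2)
from the GCaMP channel without clipping, so adding it back reconstructs
the input exactly.  Burst selection merges spike events separated by
< 1 s into bursts, then keeps onsets with ≥ 10 s of preceding quiet,
merged area > 2000 a.u.·s (a camera-scale-dependent default), and a full
[−10, +15) s window frame inside the movie.

Windowed metrics use five half-open 5-s windows a–e at offsets −10, −5,
0, +5, +10 s from the burst onset; window c starts at the burst.
Injection/returning intensities assign each trajectory to the window
containing its base crossing; frequencies count base crossings inside the
window; speeds fit each train's in-window segment and *include* paused
trains (speed ≈ 0) — the reactivation effect is precisely that the
average rises when paused trains start moving; a flag excludes them.
The per-window background masks only moving segments: a ridge tracer
cannot see horizontal traces, so paused (accumulated) material is
operationally background, and its clearance after a burst is what the
background drop measures.

`paired_window_test` runs paired two-tailed t tests on the four adjacent
window pairs; identical columns give p = 1, a zero-variance non-zero
shift is flagged degenerate rather than reported as p = 0.

## Statistics

* Pearson ρ with r² = ρ²; constant input is an explicit error.
* `residual_shift_test`: fit the control mean relation (linear `a + bx`
  or decay `a + b/x`), take both groups' residuals about it, Welch
  (unequal-variance) unpaired two-tailed t — Welch because nothing in the
  procedure guarantees equal spread.
* `interval_dispersion_test`: KS distance of inter-event intervals to an
  exponential with the rate estimated from the data; because of the
  estimation step the null distribution comes from a parametric bootstrap
  (replicates drawn from the fitted exponential, each refit), not the
  asymptotic KS table.  The KS routine is vectorised in-package for the
  bootstrap's sake and agrees with the scipy reference to 1e-12.
  Calibration: type-I error 0.042 at α = 0.05 under the Poisson null
  (1000 reps); power 0.99 against a gamma(shape 4) renewal with 30 events
  (500 reps).
* Hill calibration `I = I_min + (I_max − I_min)Cⁿ/(EC50ⁿ + Cⁿ)` is fit
  in log₁₀ EC50 parametrisation (nanomolar EC50s are otherwise badly
  conditioned); inversion clips to just inside (I_min, I_max) and flags
  out-of-range intensities as saturation bounds, not measurements.

## Numerical and testing choices

Tolerances asserted in the test suite are those stated above; problem
sizes were chosen as the smallest that leave Monte-Carlo standard errors
well inside the asserted bands: 20 seeded kymographs per detection
criterion, a 60-matrix stationary pool with 1000 centred-bootstrap
resamples of 8 bursts for the null window calibration, 4 reactivation
movies, 199 bootstrap replicates inside each dispersion test (1000
type-I / 500 power repetitions outside).  Speed-metric calibration under
the no-pause null is skipped in favour of the continuous metrics because
window speeds there are nearly deterministic and the paired t is
degenerate.  All randomness flows through explicit integer seeds;
hypothesis-based property tests run derandomised.

## Known limitations

* The tracer resolves parallel same-direction trains only when separated
  by ≳2 px; co-entering train pairs (a Poisson-entry artefact) count as
  one brighter train, the dominant residual error in frequency.
* Bleach correction assumes a mono-exponential envelope.
* The length-control model treats both flagella as identical; no
  per-flagellum asymmetry or fluctuating Ca²⁺ input.
* Buffer chemistry is single-metal, single-ligand; no Mg²⁺ or
  ionic-strength corrections.
* `build_kymograph` extracts along a fixed hand-traced polyline; curved,
  moving flagella need per-frame re-tracing, which is out of scope.
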