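# Methods

## Signal model and assumptions

A training session is modeled as alternating rest and swimming bouts. The
swimmer stands or rests upright between bouts and is horizontal (prone, or
supine for backstroke) while swimming; each bout contains one or more
25-m laps separated by turns; each lap passes through five phases in fixed
order — wall push-off, glide, strokes preparation, swimming, turn. All
detection operates on anatomical-frame signals: y along the longitudinal
axis of the segment pointing up, x anterior–posterior pointing forward,
z mediolateral pointing right. In this frame gravity puts ≈ +1 g on Acc_y
when upright, and ≈ −1 g (prone) or +1 g (supine) on Acc_x when horizontal;
these gravity signatures, not any motion model, carry the macro structure.

Sensors are assumed synchronized, sampled at a common rate (500 Hz default)
and free of long-term drift over a session; accelerometers are in g,
gyroscopes in °/s. Analysis is per location — sacrum (SA), head (HE), right
wrist (RW, plus LW for one rule), right shank (RS) — and locations are never
fused, so their results can be compared.

## Detector architecture

Every detector composes a small set of primitives on low-pass filtered
signals (2nd-order Butterworth, f_c = 10 Hz). Filtering is zero-phase
(forward–backward), so detected event times carry no filter lag; the
effective magnitude response is the squared Butterworth gain. The
primitives: strict local extremum detection against a threshold (a negative
threshold on a signed signal expresses trough detection; flat-topped peaks
from exactly sampled extrema report their midpoint), sharp-change detection
(derivative of the filtered signal thresholded at ±fraction × its global
maximum, default fraction 0.3), analytic-signal envelopes and instantaneous
energy (squared analytic amplitude of the mean-removed signal), principal
component analysis, single-sided spectra (boxcar periodogram; the discrete
Parseval identity holds to numerical precision, and a separate amplitude
spectrum whose bins read in signal units backs the technique thresholds
quoted in g), and empirical mode decomposition.

### Macro level

**Bouts.** On SA/HE/RS the posture level shift of Acc_y is isolated with a
dedicated very-low cutoff (0.15 Hz): swim dynamics are zero-mean
oscillations that this filter removes, while the sustained 1 g ↔ 0 g shift
survives. Sharp-change troughs are approximate starts, peaks approximate
ends, paired in temporal order. Two safeguards make pairing robust: a
candidate edge must actually separate a sustained high (>0.5 g) from a
sustained low (<0.5 g) Acc_y level (means over [t−4, t−1] and [t+1, t+4] s),
and same-polarity events within 5 s collapse to the strongest. On the wrist,
bouts are intervals where the |Acc| envelope (1 s window) exceeds
TH_BW = 1.6 g; because the envelope drops during the mid-bout turn gap,
sub-intervals closer than 10 s are merged, and intervals shorter than 5 s
discarded. The wrist interval starts with the first arm cycles — several
seconds after the push-off — so *phase* analysis at the wrist is anchored on
posture-change bouts computed from the wrist's own Acc_y instead
(`detect_bouts(..., method="posture")`); the envelope rule remains the
wrist's bout detector proper.

**Laps (approximate turns).** SA/HE: peaks on forward acceleration and on
|Acc_y,z| exceeding 60% of the bout maximum (measured above the bout median)
and an absolute floor of 1.2 g, separated by at least the minimal lap time
(10 s). The floor prevents the purely relative rule from firing on ordinary
swim dynamics in turn-less bouts; the median reference makes the rule
posture-independent. Because a turn separates two laps, candidates within
half a lap time of either bout edge are excluded — this also rejects the
final wall-touch transient. RS: threshold peaks on Acc_z or Gyr_z (the
earlier channel wins) against TH_LS, the highest peak in a 2-s reference
window during swimming; the reference window is chosen as the max-RMS 2-s
window of |Gyr| whose crest factor stays below 2 (so it reflects sustained
kicking, not the turn transient itself), and candidates must exceed
1.2 × TH_LS, 60% of the bout maximum, and per-channel floors (100 °/s,
0.5 g). RW: the wrist rotation rate falls during the turn; interior
intervals of low-passed |Gyr| < TH_LW = 200 °/s lasting 0.4–8 s are turns,
reported at their midpoint (which trails the turn begin by about half the
turn duration, ~0.6 s).

**Technique.** A 6-s window of upper-limb cycles is taken at 65% of the lap
span (the swimming phase occupies the later part of a lap; at the default
stroke rate of 0.6 Hz the window holds ≥ 2 arm cycles and ≥ 5 kicks); on the
wrist it is centered on the envelope-above-threshold interval instead.
SA/HE: the first principal axis of the gyroscope separates rolling
(|PC1·ŷ| larger — front crawl/backstroke) from pitching (butterfly/
breaststroke); mean Acc_x > 0 identifies the supine backstroke; within the
pitching pair, the amplitude-spectrum peak in the arm-stroke band
(0.3–1.5 Hz) of Acc_x (SA, threshold 0.16 g) or |Acc_x,y| (HE, 0.2 g)
identifies butterfly. Restricting the peak search to the stroke band keeps
the faster kick harmonic from masquerading as the stroke peak. RS: gravity
sign, then dominant gyroscope axis x (screw-kick) → breaststroke, else the
roll-to-pitch variance ratio var(Gyr_y)/var(Gyr_z) ≥ 0.05 separates front
crawl (flutter kicks carry hip roll) from butterfly; the paper-style inputs
(gravity + PCA) under-determine a four-way split, so this ratio rule is this
package's design choice. RW: acceleration PCA dominant on x → backstroke;
mean |Acc| > 1.7 g → butterfly; variance of the smoothed |Acc| < 0.01 g² →
front crawl; else breaststroke. The "variation" feature is computed on a
moving average over ~half an arm cycle (0.83 s): raw |Acc| variance cannot
be small for any signal whose envelope exceeds 1.6 g, so the feature is
defined at the cycle scale, where breaststroke's intra-cycle glide leaves
strong modulation and the continuous strokes of front crawl do not.

### Micro level

Detectors chain forward, each anchored on the previous event, with
configurable search windows: Push_B in [anchor − 1 s, anchor + 2 s] from the
approximate start, or [anchor + 0.3 s, anchor + 2 s] when anchored at a turn
(the turn spike sits at the anchor and must not be mistaken for the push
peak); Glid_B within 3 s after Push_B; StPr_B within 8 s after Glid_B;
Swim_B within 10 s after StPr_B; Turn_B in [approximate turn − 3 s, + 1 s].
When several extrema qualify, the first in time wins (events are phase
*beginnings*), except where noted.

- **Push_B** — SA: the push complex on Acc_y after removing the posture
  trend (a 0.5 Hz low-pass tracks the posture change closely, so its
  residual near the transition stays below the push amplitude); backstroke
  takes the Acc_y peak directly, other techniques take the concavity change
  (last zero crossing of the second derivative, computed on a 4 Hz-smoothed
  copy so double differencing does not amplify noise) before the push peak.
  HE: |Acc| peak (Acc_y peak for backstroke). RW: deepest trough of the
  detrended Acc_y (downward hand motion). RS: first |Gyr| peak above
  max(150 °/s, half the window maximum).
- **Glid_B** — SA/HE: first Acc_y trough below −0.1 g after Push_B; RS:
  first |Gyr| peak above 80 °/s after the push pulse; RW: first detrended
  Acc_y peak with prominence ≥ 0.15 g (the signal is near zero in glide, so
  prominence, not amplitude, rejects noise).
- **StPr_B** — SA: first |Acc_x| peak ≥ 1 g whose local Acc_x variance
  (0.5 s window) exceeds 0.06 g²; HE: first Acc_y trough ≤ −0.5 g with
  prominence ≥ 0.1 g; RW: first trough of |Acc| − 1 g below −0.9 g (the
  printed threshold is negative although a norm is nonnegative; it is read
  as a trough criterion about the 1 g baseline, i.e. a near-free-fall dip);
  RS: backstroke takes the first positive Acc_y peak (≥ 0.25 g), other
  techniques the first |Acc_x| kick peak ≥ 1.3 g followed by the next
  crossing of |Acc| through 1 g.
- **Swim_B** — SA: front crawl/backstroke, first |Gyr_y| roll peak
  ≥ 200 °/s; breaststroke, upward instantaneous-energy crossing of
  550 (°/s)² on the second intrinsic mode of Gyr_z; butterfly, first peak
  ≥ 0.1 g of the second intrinsic mode of Acc_y. HE: energy crossings on
  Gyr_y (front crawl, 5000 (°/s)²) or Gyr_z (breaststroke/butterfly,
  12000 (°/s)²; backstroke, first drop below 1000 (°/s)² after the kick
  energy peak). Wrists: the trough immediately before the first cycle peak
  (≥ half the window maximum after removing the window median, so the
  gravity offset on the chosen axis does not distort the fraction rule) on
  Acc_y (front crawl, butterfly), Acc_x (backstroke) or Gyr_y
  (breaststroke), evaluated on both wrists, earliest wins. RS: the trough
  before the first peak ≥ 1.7 g of the second intrinsic mode of Acc_x
  (Acc_y for breaststroke).
- **Turn_B** — backstroke (non-final laps): the approximate turn itself.
  SA: last prominent trough (prominence ≥ 0.2 g) before the large forward-
  acceleration peak. HE: largest qualifying peak of |Acc| (tumble) or Gyr_x
  (simple) before the approximate turn; RW: last qualifying Acc_y peak
  before it; RS: latest qualifying Gyr_z (tumble) or Acc_z (simple) peak in
  the window. The last lap of a bout has no turn; its "turn" event is the
  end of swimming at the final wall, detected with the same rules anchored
  at the approximate end, and its ΔTurn ends at the bout end. Turn type
  defaults to the competition convention (flip turns for front crawl and
  backstroke, open turns for breaststroke and butterfly) and can be
  overridden per lap.

### EMD-based rules

Signals feeding EMD are first low-passed at 3 Hz (`emd_fc`): this sits above
the kick rate (2.5 Hz) and below its harmonics, so the decomposition yields
the kick oscillation as the first intrinsic mode and the stroke-rate
undulation as the second — which is what the "second intrinsic mode" rules
address. Sifting uses the standard-deviation stop criterion (0.2), cubic-
spline envelopes and mirror boundary extension; the residual is defined by
subtraction, so reconstruction is exact. EMD separates modes reliably only
when the faster mode's derivative amplitude exceeds the slower mode's —
amplitude ratios beyond ~10:1 between neighboring modes mix.

## Thresholds and parameters

All thresholds live in `ThresholdSet`, one field per constant, defaults as
listed above and in the field comments (units: g, °/s, (°/s)², s, Hz).
Fields added by this package beyond the published constants — the bout
filter cutoff (0.15 Hz), push detrend cutoff (0.5 Hz), EMD cutoff (3 Hz),
search windows, floors, prominences, the stroke band and the turn exclusion
margin — are design choices where the rule family was stated without its
auxiliary constants; each is configurable and swept by the sensitivity
harness like any other threshold. TH_B (bout derivative threshold) and
TH_LS (shank turn reference) are computed at run time from the data and are
not stored.

## The simulator

`simulate_session` generates six-location sessions from piecewise-smooth
templates — raised-cosine pulses, amplitude-modulated sinusoids, pulse
trains, posture level steps — not from biomechanics. This is sufficient
because every detector is a rule on exactly these features; the templates
contain each trigger with a deliberate margin (≥ ~20%) to its threshold,
and each trigger time is stamped into the ground truth. Phase durations are
drawn per lap from truncated normal distributions (±3 sd, floored to stay
positive: glide 300 ms, strokes preparation 800 ms) with defaults
ΔPush 218 ± 29 ms, ΔGlid 880 ± 476 ms, ΔStPr 2673 ± 1268 ms,
ΔSwim 12423 ± 1905 ms, ΔTurn 1223 ± 166 ms; stroke rate 0.6 Hz, kick rate
2.5 Hz, 20 s rests, white noise of 0.05 g / 5 °/s by default. One seed
drives all sampling; identical seeds give bit-identical sessions.

Oscillatory bursts that switch on and off are snapped to whole cycles where
a phase step would leak into the very-low-frequency band the bout detector
watches. Small timing offsets are built in deliberately (first kick peak at
the strokes-preparation begin, head dip 50 ms after it, wrist trough 80 ms
after the swim begin, shank turn spike 100 ms after the turn begin) so that
detector errors are realistic rather than identically zero.

What the simulator does **not** emulate: inter-swimmer style variability,
stroke-to-stroke irregularity, drag and hydrodynamics, sensor drift or
soft-tissue artifacts, dive starts, mixed-technique laps. Passing tests on
synthetic sessions therefore demonstrate that the implementation realizes
the detection rules faithfully and recovers events whose signatures are
present; they do not certify accuracy on real swimmers.

## Expected systematic biases

Threshold-crossing and first-cycle rules have inherent latency: the sacrum
swim-onset rule waits for the first roll peak (≈ +0.3 s at a 0.6 Hz stroke
rate), the wrist turn midpoint trails the turn begin by half the turn
duration, the shank strokes-preparation rule adds the |Acc|-crossing delay
(≈ +50 ms). Anchor-level detectors (push, glide, turn at the sacrum; swim
at the wrist) recover events within tens of ms on clean data. The
validation default matches detections to truth within 300 ms, larger than
realistic inter-observer disagreement for these events; macro boundaries
use 500 ms.

## Numerical choices and degenerate inputs

Times are seconds from recording start, converted to sample indices by
rounding; reports serialize all times as integer ms so repeated runs are
byte-identical. Sample (n−1) standard deviations throughout. Precision is
defined as 0 when nothing is detected but events exist, and all scores are
1 in the fully vacuous case. Empty windows, missing extrema or a too-shallow
decomposition raise a `DetectionError` naming the event and location;
`run_full_analysis` records these per lap and continues. Constant input to
EMD returns no modes; rank-0 input to PCA raises. The threshold sweep
records per-row failures instead of raising.

## Limitations

- Validated against its own simulator, not against recorded swimmers; the
  thresholds are the published constants, but their adequacy for a given
  pool, pace range or population must be established with annotated data.
- Dive starts are out of scope (sessions must start in the water), as are
  stroke-cycle sub-phases, open-water swimming and mid-lap technique
  changes.
- The simplified functional calibration estimates segment axes from
  standing gravity and a dominant rotation axis; it resolves axis sign from
  the dominant rotation direction and will fail on perfectly symmetric
  calibration movements.
- EMD-based rules are the most fragile component: mode ordering depends on
  the spectral gap between kicks and strokes, and very unequal mode
  amplitudes mix.
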