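# Methods

## Data model and units

All computation happens in micrometres and minutes; conversion from pixel
coordinates (`scale`, μm per unit) and from 1-based frame numbering
happens once, at the I/O boundary. A track needs at least two frames;
frames are strictly increasing and may have gaps (a cell undetected for
some frames). Analysis is strictly 2D — the assay tracks maximum-intensity
projections — and a z column in an input table is ignored with a warning.
The wound is a user-supplied polyline in the same coordinate system
(commonly a single near-vertical segment at the cut; the pixel size and
wound outline are never inferable from a track table, so both must come
from the experiment configuration). The anteroposterior (AP) axis is a
unit vector oriented so that positive points toward the wound, which fixes
the sign of V_AP.

## Per-track measures

Net displacement, total displacement, meandering index and mean speed are
computed exactly as defined (see README). Two conventions matter:

- **Gaps.** A step spanning a detection gap contributes its chord length
  to d_tot and its true elapsed time to the speed denominator. No
  interpolation is invented; stepwise path length underestimates the true
  path, and comparability across groups rests on the constant 1-min frame
  rate, not on gap filling.
- **Stationary cells.** A cell with d_tot = 0 has no meandering index;
  the value is NaN (logged) and excluded from group statistics rather than
  coerced to 0 or 1.

Distance to the wound is the minimum over edge segments of the
point-to-segment distance (orthogonal projection clamped to endpoints),
vectorised over points. Classification uses only the first-frame position:
strictly beyond 200 μm is *distant*; at or within 200 μm is
*local resident* (the band is inclusive). Arrival uses the 20 μm band,
also inclusive; retention means every frame after first arrival stays
within it. Recruited-cell counting is inclusive at its 200 μm band too.

## Cohort MSD and the persistent-random-walk fit

The MSD is anchored at each cell's first tracked frame and averaged across
cells per lag; cells whose track lacks the frame at a given lag drop out
of that lag, and the per-lag SEM is the across-cell sample SD over √K.
Cells entering the field late are anchored at their own first frame — the
cohorts' cells appear asynchronously and no alignment rule to absolute
movie time would be well defined; the number of late entries is logged.
The time-averaged MSD familiar from single-particle tracking is available
behind `time_averaged=True` for comparison, but the anchored form is the
canonical one here.

Fürth's formula is fitted by bounded nonlinear least squares
(`scipy.optimize.curve_fit`, v ∈ (0, 100] μm/min, τ ∈ (0, 10³] min) over
the positive lags within the fit window. Weighting is **relative**
(residuals divided by the curve value) by default: the across-cell scatter
of an anchored squared displacement scales with the MSD itself, so
relative weighting is inverse-variance weighting up to a constant. Plain
unweighted residuals let the large, noisy long-lag values drown out the
small-lag curvature that identifies v and τ separately — in practice the
unweighted fit frequently runs v into its bound — so `weights="none"`
and `weights="sem"` exist only as explicit options. Initial guesses are
deterministic: v₀ = √MSD/t at the earliest positive lag (overridable by a
cohort mean speed), τ₀ = 10 min. A fit with τ pinned at a bound is flagged
(`tau_at_bound`): the window then contains no persistence information and
D = v²τ/2 should not be quoted. Standard errors come from the
least-squares covariance.

Default fit windows: 80 min for neutrophil cohorts, the full track span
for macrophage cohorts; both overridable. The parameter-recovery harness
fits the first 40 min (a third of the movie and ≥8 persistence times at
the default τ) — long lags of an anchored 50-cell curve carry mostly
noise, and standard MSD-fitting practice restricts the window similarly.

## Anteroposterior velocity

Per-step V_AP is (step displacement · AP unit vector)/Δt, positive toward
the wound; a track's mean V_AP averages its steps. The cohort time course
pools every cell's steps by the frame at which the step starts and
averages non-overlapping windows of three consecutive frames (each
cell-step weighted equally, i.e. pooled rather than per-cell averaging);
an empty window is reported as a gap, never as zero. A sliding-window
variant exists behind `sliding=True` but is off by default. Because steps
of one cell within a window are persistence-correlated, the pooled SEM is
mildly anti-conservative; the tests account for this by using 3·SEM bands
when checking that unbiased cohorts are consistent with zero drift.

## Synthetic cohorts

The generator emulates the quantified assay: 2 h movies at 1 min frame
interval, cells seeded 250–500 μm from a vertical wound edge. Defaults:
25 cells per cohort (the scale of a tracked group in such an assay),
v = 10 μm/min and τ = 5 min — realistic zebrafish-leukocyte values giving
D = v²τ/2 = 250 μm²/min, the order measured for neutrophils in this kind
of wound assay.

The walker is a discrete correlated random walk: per step the heading
angle receives Gaussian noise of SD √(2Δt/τ), making the heading
autocorrelation exactly e^(−Δt/τ), and the step length is vΔt (optionally
modulated by unit-mean gamma noise, `speed_cv`; the canonical PRW has
`speed_cv=0`). This walk's MSD converges to Fürth's formula for Δt ≪ τ;
fitting the exact discrete-walk curve with the continuous formula leaves
only a small residual bias (v +1.4%, τ −3% at Δt/τ = 0.2), which the
recovery tolerances comfortably absorb. An Ornstein–Uhlenbeck velocity
process would remove even that bias but was rejected: the constant step
length gives the simple, exactly verifiable invariant "per-step speed =
v", and seeding is trivially deterministic.

With `bias` b > 0 the heading of a free cell is re-normalised from
(1−b)·heading + b·woundward each step, producing chemotactic runs; b = 1
is straight-to-the-wound motion. Cells reaching the 20 μm arrest radius
are retained there. **Retention keeps cells moving**: a retained cell
keeps stepping at full speed with its heading reflected toward the wound
whenever a step would leave the band. A zero-motion stop was considered
and rejected as the default because it contradicts the assay's own
signature — chemotactic and control groups show the *same* mean speed,
which cannot happen if arrived cells freeze while d_tot keeps dividing by
elapsed time; wound-retained leukocytes in fact keep crawling along the
margin. The absorbing full stop remains available as
`arrest_mode="stop"`, and `leave_prob` lets a per-frame fraction of
retained cells depart for good (they revert to unbiased walking and are
not recaptured), emulating mutant local residents that migrate away.

What the generator does **not** emulate: cell–cell interactions and
crowding at the wound, shape changes and segmentation noise, drift of the
larva, the slow decay of the chemoattractant field, and cells entering or
leaving the imaging field. Passing tests therefore validate the
estimators and rules on data satisfying the model assumptions, not the
biology of any particular experiment.

The phenotype-comparison condition (chemotactic vs control at equal
intrinsic speed) uses 50 cells per group, bias 0.5 and `speed_cv` 0.3:
bias 0.5 drives essentially complete arrival within 2 h from the
250–500 μm band, and the speed noise gives the mean-speed t-test a
non-degenerate within-group variance. These values were fixed once, from
the qualitative pattern they must embody, and are not tuned per seed.

## Detection movies and the Viterbi linker

`simulate_detection_movie` drops each cell independently per frame with
probability `miss_rate` (≤ 0.3), drawing dropouts from a stream derived
from the cohort seed, and keeps ground-truth identities for scoring.

The linker follows a global linking strategy: tracks are created one at a
time, each the highest-scoring path through the remaining detections by
dynamic programming over frames. Scores are log-likelihood-style: each
claimed detection earns `det_logp`, a k-frame link costs ‖Δx‖²/(2kσ²)
plus `gap_logp` per missed frame (k ≤ `max_gap`), and each track pays
`appear_logp` + `disappear_logp` once. Track creation stops when the best
remaining path's full score is no longer positive — its evidence must
clear the appear+disappear floor, otherwise its detections are better
left as noise (score 0). Mitosis and apoptosis are not modelled. The
swap pass then repairs earlier links: for every track pair and frame
boundary the tails are exchanged whenever that raises the total score,
iterated to a fixed point, so the total score is non-decreasing; spliced
remnants with fewer than two detections or non-positive score dissolve
back to noise. On random small instances this greedy-plus-swaps scheme
reaches the exhaustive-enumeration optimum (verified exactly in the
tests); no global-optimality guarantee exists in general. Scoring
parameters are calibrated on synthetic data only (σ ≈ expected
frame-to-frame movement; the defaults suit v ≈ 10 μm/min at 1 min
spacing).

## Group statistics

Group comparisons use the classical unpaired two-tailed Student t-test
with pooled variance; Welch's correction is available behind a flag but
is not the default, matching the conventional analysis of this assay.
Stars map p at 0.05/0.01/0.001/0.0001. When both samples are constant and
equal the comparison is degenerate and p = 1 by convention (logged).
Non-finite metric values (stationary-cell meandering index) are dropped
before testing. No multiple-testing correction is applied — the report
carries raw p-values and says so explicitly. Scalars are summarised as
mean ± SD; MSD and V_AP curves carry the across-cell SEM used for
shading.

## Problem sizes and numerical choices

The test-suite and acceptance-script problem sizes — 200 random cohorts of
≤10×20 for the MSD oracle, 50 cells × 120 frames × 10 seeds for parameter
recovery, 10⁴ random tracks for metric invariants, a 100-case enumeration
suite for the linker, 2000 replicates for t-test calibration — were chosen
as the smallest scales at which each property is sharply testable; all
run in seconds on one core. Tolerances: exact identities are asserted to
float roundoff (1e-9 … 1e-12 relative); the closed-form fit round trip to
1e-6 relative; stochastic recoveries at 10% (v) and 25% (τ) reflecting
anchored-MSD scatter at K = 50. Tie-breaks: boundary distances are
inclusive (≤) everywhere; the linker rejects zero-score paths; fit
initial guesses and bounds are fixed constants, so every fit is
deterministic given its curve.

## Known limitations

- The anchored MSD uses each cell's own first frame as anchor; if cells
  enter the field at very different times after wounding, lags mix
  different absolute times post wounding.
- Fürth-fit standard errors assume independent per-lag residuals, which
  anchored curves violate (the same cells contribute to every lag); treat
  them as indicative, not exact.
- The linker is 2D, has no mitosis/apoptosis model, and its greedy search
  is only empirically optimal at small scale.
- The t-test inherits its usual normality assumptions; meandering indices
  near the [0, 1] boundary are skewed, and rank tests may be preferable
  for strongly confined cohorts.
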