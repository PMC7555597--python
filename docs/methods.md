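# Methods

## Mamdani inference core

Both risk engines are classical Mamdani systems: crisp inputs are fuzzified
against trapezoidal sets, rules combine antecedent degrees with min (AND)
or max (OR), the consequent set is truncated at the rule activation (min
implication), truncated consequents are max-aggregated, and the output is
the centroid of the aggregate.

Numerical choices:

* **Membership at breakpoints.** A trapezoid (a, b, c, d) is 1 on [b, c],
  linear on the edges, 0 outside [a, d]. At a breakpoint shared between an
  edge and the plateau (including degenerate b = c triangles and vertical
  edges a = b) the limiting plateau value 1 applies, so plateaus are closed
  intervals.
* **Exact centroid.** The aggregate is sampled on a uniform grid (default
  1001 points) augmented with every trapezoid corner, every
  truncation-level crossing, and every pairwise intersection of the active
  sets' linear segments. The aggregate is therefore piecewise linear
  *between* grid points: its area is exact under the trapezoidal rule, and
  its first moment (piecewise quadratic) is exact under per-interval
  Simpson integration. The returned centroid is exact to floating-point
  rounding, which is why doubling the grid moves the output by ~1e-13 and
  why the engine outputs are monotone without numerical jitter.
* **No rule fired.** An identically-zero aggregate raises an error rather
  than returning a default; silently reporting a fabricated risk value is
  worse than failing loudly. Callers decide any fallback.
* **Rule weights** in [0, 1] (default 1) scale activations; the shipped
  configurations do not use them, but they allow fine calibration without
  touching set shapes.

## Default engine configurations

The membership functions and rule tables are this package's own: the
methodology defines the engines' structure but its original breakpoints and
rule tables exist only as illustration screenshots and are not recoverable.
The shipped defaults (in `src/woundrisk/configs/`) were designed to the
published anchor behavior and are a documented, versioned fixture — users
can replace them wholesale via YAML.

Design of the defaults:

* Three input sets per variable (an overlapping Ruspini-style partition:
  degrees sum to 1 in every crossover), five output sets on [10, 100].
* **Symmetric output trapezoids.** A symmetric set's centroid is invariant
  under truncation, so a rule firing at any level contributes mass at the
  same location.
* **Smooth, monotone rule tables.** Full-factorial tables whose consequents
  never decrease along a risk-increasing direction and never jump more than
  one output level between adjacent cells. Smoothness matters: with a
  two-level jump, a weakly-firing intermediate rule can inject mass *below*
  the current centroid as its input rises, producing local dips. With
  smoothness plus symmetric consequents the defuzzified surface is monotone
  to machine precision (verified by dense grid sweeps in the test suite).
* **Unequally spaced output centroids** (technical: 15/40/57.5/75/90;
  expert: 15/35/52.5/70/90) reconcile smoothness with the required dynamic
  range and the calibration anchors.
* **Calibration anchors.** The canonical case shipped with the package
  (`woundrisk.engines.WORKED_CASE`) is a Braden total of 14 with a wound
  shrinking at 1 % of its reference area per day, and expert ratings
  3/8/4; the defaults yield Technical Risk 40.0 and Expert Risk 70.0 on it.
  The individual Braden subscales (2, 3, 1, 2, 4, 2) and the 10 → 7 cm²
  area pair are this package's documented reconstruction: only the engine
  outputs (40 and 70), the 30-day interval, the expert ratings and the
  qualitative wound trajectory are published. The published photograph
  dates (25 June / 23 July 2019) actually span 28 days; the canonical case
  follows the stated 30-day interval.
* The technical engine consumes the Braden **total** (6–23), not the six
  subscales individually; the published account reports a single scale
  value driving the engine, and a six-input rule base would need 3^6-scale
  rule authoring with no anchor to calibrate it. The health-history rating
  carries double weight in the expert table's severity score, reflecting
  that a 3/8/4 rating pattern must map to a clearly-high risk (70).
* **Area-rate normalization.** The technical engine fuzzifies percent of
  reference area per day on [−5, 5], making it scale-free across wound
  sizes; rates beyond the domain are clamped to its edges (faster growth or
  shrinkage is already maximally informative). −5 %/day sustained for a
  month would more than halve a wound's area, so the domain covers the
  clinically plausible range.

## Decision Factor and Global Risk

The fusion surface is evaluated lazily from closed forms (no precomputed
grids), so corrections compose without interpolation error. Decisions made
where the published formulation was ambiguous:

* The exponential-zone formula is implemented as f1(RT) **raised to**
  (RE − f2(RT)), plus the floor of 10. Typography permits reading a
  product, but only exponentiation reproduces the reported DF = 11.58 at
  (40, 70) — verified by hand before implementation. The trivial-exponent
  identity DF(RT, f2(RT)) = 11 is a consequence and is tested.
* RT exactly at the zone boundary (default 50) uses the exponential branch
  ("up to 50" read as inclusive); the boundary is configurable.
* The logarithmic-zone certainty correction multiplies the Decision Factor
  by 100/security, so full certainty (security = 100 %) is the identity and
  lower certainty inflates DF — consistent with its stated purpose of
  counteracting expert under-valuation. The literal printed form
  ("f(RE)·100 % Security") is not computable as written; this
  interpretation is a documented choice, isolated in
  `correct_logarithmic`, and swappable.
* The exponential-zone correction interpolates between the surface f and
  the chord g through the interval endpoints with weights c1 + c2 = 1, and
  caps the result at g(RE). The upper-limit rule is implemented as the
  chord cap — the simplest rule satisfying the stated intent of bounding
  the corrected value; outside the user's RE interval the correction is the
  identity (logged, not an error).
* The sigmoidal second-level correction blends RG between its values at RT1
  and RT2 with a logistic curve; RT1 ≥ 25, RT2 ≤ 75 and the zone boundary
  must lie inside [RT1, RT2], all validated. It composes with first-level
  corrections because the surface passed to it is evaluated with them
  applied.
* A further correction of the worked case (reported corrected DF = 20.32)
  used an RE interval and weights that were never published; it is out of
  scope and deliberately not reproduced.

Global Risk is clamped at 100. At the Technical-Risk floor RT = 10,
RG = DF exactly, so the decision reduces to the expert side.

## Image quantification

Preprocessing extracts the HSV saturation plane, inverts it (wound tissue —
pale granulation/epithelial tissue — is low-saturation, hence bright after
inversion) and applies five 3×3 median-filter passes by default. The
original pipeline says only "filtered"; the median was chosen because it
suppresses pixel noise without blurring the wound boundary, and both the
filter count and (in the library) the filter itself are configurable.

Segmentation is seeded region growing: a FIFO frontier absorbs 4-connected
neighbors whose intensity deviates from the running region mean by at most
the sensitivity threshold (default 0.15 on the [0, 1] channel). The exact
growth criterion of the original segmentation script is not published; this
variant is documented and oracle-tested against flood fill on two-level
images, where the two coincide. A 1e-12 guard on the comparison absorbs
floating-point drift of the running mean, so sensitivity 0 grows exactly
the seed's flat plateau. FIFO order makes masks deterministic.

Calibration divides the marker's known physical area by its segmented
pixel count; the marker is located by a user-supplied seed and the same
region grower. Physical areas are invariant (±3 %) under uniform image
rescaling. The area change rate is (A_now − A_ref)/Δdays, also expressed
as percent of the reference area per day for the technical engine.

## Synthetic data generator

The generator emulates the study's input material: an elliptical wound of
low saturation (pale pink, RGB 233/213/205) on a skin-tone background
(RGB 198/144/114), with a saturated red reference square (RGB 190/32/38,
1 cm² by default) and Gaussian pixel noise (σ = 0.02 on the [0, 1] scale by
default), on a 256×256 canvas. Analytic areas (π·a·b, side²) and rasterized
ground-truth masks are returned alongside; images are reproducible from the
spec's seed.

What it does *not* emulate: lighting gradients, specular highlights,
mixed tissue types inside the wound, camera perspective and lens
distortion, or marker placement at a different depth than the wound. Tests
passing on these fixtures therefore validate the measurement chain's
correctness (segmentation, calibration, rate arithmetic), not robustness
to real photographic conditions.

## Alerts and orchestration

Alert bands are left-closed/right-open with the final band closed
([0–60), [60–80), [80–100] by default), implemented literally so RG = 60
maps to *evaluate alternatives* and RG = 80 to *change immediately*. Band
boundaries — and, through a generic helper, the number of bands — are
reconfigurable; reconfiguring thresholds never changes the computed risk
values, only the label. Manual overrides require a reason and are recorded
in the report's append-only audit trail. `run_case` composes imaging →
engines → fusion → alert deterministically and tags any stage failure with
the stage name.

## Problem sizes in the test and acceptance suites

Grid sweeps use 1-unit steps on the risk scales (91×91 for the clamping
check), dense sweeps for monotonicity, 25 random aggregates against a
900k-point integration oracle for the centroid check, and 256×256 (one
512×512) synthetic images for the segmentation checks; the full suite runs
in well under a minute on one CPU.

## Known limitations

* The engine defaults are calibrated to a single published case; they are a
  demonstration configuration, not a clinically validated rule base.
* Technical Risk treats the Braden total as sufficient; subscale-specific
  interactions (e.g. moisture × friction) are not modeled.
* Region growing assumes the wound is a single connected low-saturation
  region; satellite lesions need separate seeds and are not merged.
* No cross-visit persistence beyond the CSV case log; each run is
  self-contained by design.
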