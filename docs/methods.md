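# Methods

This note records how the analyses are defined, which choices were open,
and what the synthetic generator does and does not emulate.

## Ratio imaging and trace extraction

The ratio image is the pixel-wise quotient of the 340 nm and 380 nm
excitation channels. Pixels whose 380 nm signal does not exceed
`bg_threshold` (default 0, i.e. only strictly zero pixels) are masked and
never contribute to measurements. Two scales coexist deliberately:

- *measurement*: the raw, unclipped ratio — measured maxima in this assay
  exceed 2, so clipping would truncate real signal;
- *display*: a linear 16-bit mapping with min/max at 0.5/2.0 and an
  optional banded false-color LUT, for visual inspection only.

Trace extraction mimics point measurements along a manual track: the ROI
is a circle of `roi_diameter_px` (default 20 px, read as a diameter; the
convention is exposed as a parameter) centred on the nearest pixel to the
track position. A pixel belongs to the ROI iff its center lies within the
radius — no area weighting — so membership is integer-exact and matches a
brute-force enumeration oracle. The trace value is the mean ratio over
unmasked ROI pixels; a sample with no unmasked pixel (or outside the
image) is flagged, not fatal. Pixel convention: 0-based indices, centers
at integer coordinates, x right / y down, µm→px via the pixel size.

## The thirteen measures

Tracks shorter than 5 min (last minus first timestamp < 300 s; the 300 s
boundary is kept) are excluded before anything else. The assay baseline is
the median of the pooled ratio samples of the ten tracks with the smallest
ratio range ("pooled" rather than median-of-medians; the alternative is
available via `per_track_median`). Per kept track:

- min/max/median ratio; t_max = time of the *first* occurrence of the
  maximum (onset semantics for plateaus);
- AUC = trapezoidal integral of max(r − baseline, 0) divided by track
  duration. The positive part is used because dips below baseline should
  not cancel calcium rises; a signed variant is available;
- R2B counts downward crossings from above (1 + 0.20)·baseline back to at
  or below it. The band is one-sided (+20%) since calcium excursions are
  positive; the width is a parameter;
- mobile fraction = fraction of steps faster than 2 µm/min; path length,
  Euclidean displacement, MI = Euclidean/length (1 for a zero-length
  path), speed = length/duration, and % of track length accumulated at
  t_max;
- pre/post ratios: the track splits at the t_max sample (assigned to both
  segment endpoints); length, speed, MI and Euclidean ratios are
  pre/post. A zero post-segment value yields NaN, never infinity. Tracks
  with fewer than three datapoints strictly before or after t_max have
  these four ratios flagged (`excluded_few_points`); the other nine
  measures are still reported, because the exclusion belongs to the
  pre/post construction, not to the track.

Responders (max ratio ≥ 1, inclusive) are compared against basal cells
(max ratio ≤ 1) after greedy t_max matching: acute cells in ascending
t_max order each take the unused basal cell with the closest t_max (lower
track id on ties). Matching on t_max absorbs the slow decay of perfusion
flow over the assay. Each basal cell is split at its *own* maximum — the
natural reading, exposed as an option — rather than at its partner's
t_max.

## Signature classification

The four classes were originally assigned visually; here they are
operationalised with explicit thresholds (all exposed in
`ClassifierParams`):

1. *flat* — no excursion above (1 + 0.20)·baseline lasting more than
   `spike_max_frames` (2) frames. Short spikes are treated as noise and do
   not disqualify flatness; otherwise "no rise or sharp spikes" would be
   self-contradictory.
2. *high* — max > 2.0, **or** the trace crosses 1.5 and every later sample
   stays above 1.0 (a tolerance of frames below is configurable, default
   strict).
3. *transient* — a qualifying rise that ends before the trace does (i.e.
   at least one return to the baseline band).
4. *low* — everything else: a sustained rise below the 'high' criteria.

Rise detection is tied to the baseline (relative band) rather than the
absolute responder threshold because baselines vary between fields of
view. The rule order makes classification deterministic and
batch-order-independent, and any 'high' trace necessarily exceeds the
responder threshold, keeping single-cell and population analyses
consistent.

Fisher's exact test is two-sided by the minimum-likelihood method (scipy's
implementation; an enumeration oracle checks it in the tests).
Mann-Whitney uses midranks; the p-value is an exact permutation
enumeration when both groups have ≤ 8 observations (ties handled
correctly) and the tie-corrected normal approximation otherwise. No
multiple-testing correction is applied.

## Multivariate analysis

Columns are z-scored (sample SD); zero-variance columns are dropped with a
warning. PCA is the SVD of the scaled matrix with components beyond the
numerical rank omitted. LDA is Fisher's between/within eigenproblem
(sklearn's eigen solver) with priors proportional to the observed class
frequencies — the classes are highly imbalanced; equal priors are an
option. Accuracy is resubstitution, since the original analysis reports
class-prediction plots without cross-validation; k-fold CV can be layered
on by the user. If the within-class scatter is singular a small shrinkage
(1e-8) is applied and flagged on the result. Loading/scaling vectors are
oriented so their largest-magnitude element is positive, making plots
reproducible. Confidence ellipses use the group mean and covariance at the
chi-square(2) quantile; collinear groups are flagged degenerate.
`load_measures_csv` maps externally produced per-cell measure tables
(arbitrary column names, user-supplied mapping) onto the canonical
13-column layout so published datasets can be fed directly to the same
PCA/LDA path.

## Interface quantification

MFI is the arithmetic mean of raw pixel values; no background subtraction
by default (an optional constant can be supplied — and an invariant test
documents that any uniform offset biases the accumulation ratio toward 1).
A membrane trace is the set of pixels whose centers lie within width/2
(perpendicular distance) of the annotation polyline, each pixel counted
once; pixels claimed by both the interface and rest bands go to the
interface. For polarization, four square ROIs (50 px, i.e. 3.37 µm at the
reference pixel size) sit at center ± offset along the interface direction
and its perpendicular; the offset defaults to one ROI size (not specified
in the original protocol). Percentages are of the four-ROI MFI sum;
polarity is signed (front-back = %interface − %away on y, side-side =
%(+90°) − %(−90°) on x); a magnitude-only reading is trivially derived.
Annotations are explicit JSON inputs — manual tracing is replaced by
annotation files, which the generator also emits.

## Flow cytometry

Gating is live (DAPI < threshold) → conjugate (PKH26⁺DiD⁺) → signal gate
(pulse width > 100, excluding small double-positive debris from dye
transfer). Quadrant thresholds are explicit configuration — the original
gates were set from compensation controls, not reported numerically — and
default to the synthetic generator's channel scales. Relative calcium is
the Fluo-2 MFI (arithmetic mean; geometric available) inside the chosen
gate, as a percentage of the identical gate on the post-ionomycin
re-acquisition. The gate defaults to conjugate ∧ pulse-width; the plain
DiD⁺ gate is selectable. Compensation/spillover is out of scope; inputs
are assumed compensated. Event tables are CSV/DataFrame only.

## The synthetic generator

The generator fixes the study conditions: 470×470 µm field, 10 s frames,
121 frames (~20 min), 107 T cells and 198 MDMs per field, and a
with-superantigen class mixture of 63% flat / 15% transient / 12% low /
10% high (without superantigen: 72/20/8/0). Only the flat fraction is
constrained by the population frequencies the assay reports; the split of
the remainder follows its qualitative description — transients predominate
among responders without stimulation, 'high' appears only with
superantigen — and is fixed here once.

Traces are piecewise-linear templates (baseline 0.8; onset uniform in
60–600 s; 30 s rise): transient peaks at ~1.3 and decays fully back; low
plateaus at ~1.3; high peaks at ~2.2 and settles to ~1.6. Per-cell levels
jitter uniformly ±0.1 (baseline ±0.03) — enough that transient and low
overlap in amplitude and are told apart only by their time course —
plus additive Gaussian measurement noise (SD 0.03 ratio units, off for
exactness tests). The default jitter windows keep every noiseless template
on its class's side of the classification thresholds, which is what makes
the round-trip property exact.

Motion is a persistent random walk (von Mises turning angles, κ = 4) at
10 µm/min with stop-and-go pauses (10% of steps below 2 µm/min), seeded on
a jittered grid and confined within 12 µm of the seed point. On calcium
onset, 'high' cells (and half of 'low' cells) collapse their confinement
to 2.5 µm while keeping the same step speed: they are corralled, not
slowed, which reproduces the observed arrest signature — Euclidean
distance and MI drop after t_max while path length and speed do not. The
`arrest_speed` parameter allows a true stop (set it to 0). Track tables
are trimmed at the ends (up to 120 s late start, 240 s early loss, 5%
dropped before 5 min) to emulate imperfect tracking and keep duration and
t_max informative measures.

Rendering uses the closed-form invertible forward model
E340 = B·G·2c/(1+c), E380 = B·G·2/(1+c) for a cell with true ratio c and
truncated-Gaussian footprint G (σ = 2.5 µm, cutoff 0.2): the 340 channel
rises and the 380 channel falls with calcium, and the per-pixel quotient
is exactly c for any footprint, so a noiseless movie reproduces ground
truth up to 16-bit quantisation (< 1e-3; peak counts are kept at 30000 so
the 340 channel never saturates). The background is zero and therefore
masked. Optional Poisson shot noise and Gaussian read noise are off by
default. Movies render at 1 µm/px by default — coarser than the real
instrument (~0.337 µm/px) to keep desk-scale stacks small; the pixel size
is a free parameter throughout.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: cells never cross (the grid confinement keeps
every ROI unambiguous, whereas real tracks do cross and manual tracking
resolves the conflicts); there is no directed perfusion drift, no
photobleaching, focus drift or cell division; trace shapes are stylised
templates rather than stochastic calcium dynamics; and conjugate images
are painted with the same band geometry the quantification measures, so
interface recovery is exact by construction in the noise-free case (the
Poisson tests probe estimator robustness, not segmentation error).

## Numerical choices

- ROI and band membership are center-in tests (≤), reproducible against
  integer enumeration; no subpixel interpolation anywhere.
- Baseline selection sorts stably by (range, track id); t_max ties take
  the first occurrence; matching ties take the lower track id.
- PCA rank tolerance 1e-10 relative to the largest singular value.
- All randomness flows from explicit `numpy` Generators; identical
  configs (including seed) produce byte-identical CSV outputs.
- Statistical exactness thresholds: Mann-Whitney switches from
  enumeration to the normal approximation above 8 per group (12,870
  assignments at 8 + 8 — still instant, and the approximation is within
  0.02 of exact there).

## Problem sizes

The test suite runs the full default-scale rendering check (107 cells,
121 frames, 470×470 px) once and otherwise uses small fields and short
recordings; population analyses use 300–500 simulated cells, which is
enough for the arrest and separation patterns to be decisive while keeping
the whole suite under half a minute. `scripts/acceptance.py` uses the same
sizes.
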