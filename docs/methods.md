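# Methods

## Problem and model

A cropped mouth photograph is graded for dental fluorosis by measuring the
fractions of the tooth surface covered by opaque-white patches
(`r_opaque`) and brown stains (`r_brown`), then applying an ordered
threshold rule. The measurement chain is: per-pixel color classification
against a trained multi-prototype model, mask construction and cleanup,
and area accounting.

### Pixel features

Each pixel is the six-vector `(R, G, B, H, S, I)` with unit-interval RGB
and

    H = atan2(√3(G−B), (R−G)+(R−B)) mod 2π
    S = 1 − 3·min(R,G,B)/(R+G+B)
    I = (R+G+B)/3.

The arctangent is printed in single-argument form in the source
literature, whose range covers only half the hue circle; the two-argument
form with wrap-around is the reading consistent with the stated range
`H ∈ [0, 2π]`. Achromatic pixels (`R = G = B`) take `H = 0, S = 0`: the
defining expressions are 0/0 there, and since `S = 0` removes hue
influence, any fixed hue is equivalent — `0` is chosen for determinism.
Hue is divided by `2π` by default so all six features share the `[0, 1]`
scale inside Euclidean distances; unscaled hue (range `[0, 2π)`) would
dominate them. The scaling is a configuration flag because the original
description is silent on it.

### UPFC

The clustering objective is

    J(μ, t, C) = Σᵢⱼ (a μᵢⱼᵐ + b tᵢⱼⁿ) ‖xᵢ−cⱼ‖²
               + β/(n²√N_C) Σᵢⱼ (tᵢⱼⁿ ln tᵢⱼⁿ − tᵢⱼⁿ),   Σⱼ μᵢⱼ = 1.

The printed form of the typicality update and the entropy coefficient are
typographically damaged in the source ("exp(−bnc‖x−c‖²/β)", "βn2c"); this
package implements the derivative-consistent pair: with entropy
coefficient `β/(n²√N_C)`, setting `∂J/∂t = 0` gives exactly

    tᵢⱼ = exp(−(b·n·√N_C / β)·‖xᵢ−cⱼ‖²),

which also matches the original clustering literature this hybrid derives
from. `β` is the sample variance of distances to the data mean. The three
updates (membership, typicality, centroid) are exact coordinate
minimizers, so `J` is monotonically non-increasing; the data term alone is
**not** (small increases are observed and expected), which is why the
implementation records both traces and the tests assert descent of `J`.

Numerical choices:

- **Initialization:** centroids are a seeded random sample of distinct
  data points.
- **Convergence:** maximum centroid displacement `< tol` (default `1e-5`)
  or 300 sweeps.
- **Singularities:** a sample coinciding with centroids splits membership
  equally among the coincident centroids; zero-weight clusters keep their
  previous centroid; `β = 0` (all samples identical) is rejected before
  the typicality update.
- **Coincident centroids** are permitted (a known hazard of possibilistic
  methods) and logged at debug level. In practice, with `a = b = 0.5` and
  many clusters the typicality term dominates and large fractions of the
  centroids collapse onto shared density modes; the labeled-prototype
  classifier still works because majority-vote labeling is untouched by
  duplication, but held-out pixel accuracy saturates around 92–94% on the
  synthetic color model — the same band the original study reports for
  its pixel classification. In the `b → 0` limit the algorithm reduces to
  a pure membership-weighted (FCM-like) run and the same data reach ~99%.

### Cuckoo search

Nests hold integer cluster counts `η ∈ [L_b, U_b]`. Proposals take the
step `s = α(η − η_best)·Lévy(β)` with Mantegna's generator
(`σ_v = 1`, `σ_u(β=1.5) ≈ 0.6966`), rounded and clamped to the bounds —
the minimal reconciliation of an integer search space with a real-valued
flight. The best nest perturbs by a pure `α`-scaled Lévy draw so the
incumbent keeps exploring. A cuckoo replaces a *randomly chosen* nest when
its fitness is lower; each generation every non-best nest is rebuilt with
probability `p_a` (the printed description of the abandonment indicator is
self-contradictory; rebuilding with probability `p_a` is the reading
consistent with "a fraction p_a of the worst nests are abandoned"). The
globally best evaluation, including its trained centroids, is cached so
elitism is exact and no UPFC run is repeated. Fitness evaluations derive
their seeds from `(global seed, nest id, generation)`, making every search
bit-reproducible.

Fitness of `η`: train UPFC with `η` clusters on the training fold, label
centroids by majority vote (ties break by the fixed class order white <
yellow < opaque < brown < background; empty clusters inherit the nearest
non-empty centroid's label), classify the validation fold with FKNN
`k = 1`, return `(accuracy − ŷ)²` with expected accuracy `ŷ = 0.99`.
Cross-validation uses the study's inverted direction: **one** fold trains
and the remaining folds validate. A nest exceeding the training-fold size
is clamped to `N_train − 1` (the full-scale bounds [1000, 2500] can exceed
a one-fold sample).

### FKNN

Class memberships are convex combinations of crisp prototype indicators
weighted by `d^(−2/(m−1))` over the `k` nearest prototypes (`m = 1.5`,
so weights `d⁻⁴`). A query coinciding with prototypes takes membership 1
split equally over *all* zero-distance prototypes. Argmax ties break by
the fixed class order. Neighbor search uses a k-d tree; distances are
computed in the same (hue-scaled) space used in training.

### Segmentation pipeline

1. 5-class map by FKNN `k = 1`.
2. Tooth mask = non-background pixels; opening with a disk of radius
   `max(1, round(0.002·image diagonal))` (size-invariant by construction)
   then dilation with radius 1, both configurable.
3. Background pixels *enclosed* by the tooth (hole-filling difference) are
   reclassified with FKNN `k = 5` restricted to the four tooth classes;
   unrestricted reclassification could return background again and make
   the step a no-op. Pixels outside holes never change.
4. White and yellow collapse to a single healthy class; opaque/brown
   components (8-connectivity) smaller than 0.55% / 0.05% of the tooth
   pixel count are reassigned to white_yellow — removal must never create
   new disease evidence, hence the neutral target class.
5. `r_opaque = |opaque|/|tooth|`, `r_brown = |brown|/|tooth|` with
   `|tooth| = |white_yellow| + |opaque| + |brown|` (mask pixels still
   labeled background, e.g. the dilation ring, are excluded from the
   denominator).

### Staging rule and metrics

Thresholds `0 ≤ θ₁ < θ₂ < θ₃ ≤ 1` and brown tolerance `δ`, defaults
`(0.05, 0.1, 0.3)` and `0.007`, comparisons all `≤`, branches evaluated in
order (see README). The first branch — Normal whenever `r_opaque ≤ θ₁`
regardless of `r_brown` — encodes that brown pixels only indicate severe
fluorosis in the presence of substantial opaque enamel; dropping it (the
ablated variant, kept for comparison) turns shadow-induced brown pixels on
healthy teeth into spurious Stage 3 calls. The rule is total and, for
`r_brown ≤ δ`, monotone in `r_opaque`.

Confusion matrices are oriented rows = actual. One-vs-rest rates
(TPR/TNR/FPR/FNR/PPV/NPV/ACC) are percentages; reported values round
half-up to two decimals (matching the reporting convention; banker's
rounding would differ on exact halves), raw values are retained. `Acc3`
(three-class accuracy inside the tooth) is computed over *ground-truth*
tooth pixels — the stricter, label-complete choice; the restriction is
configurable since the original description does not fix it. Weighted
averages across stages weight by image counts.

## Synthetic data

The generator emulates the private clinical images: gum-colored
background, a row of elliptical teeth with alternating white/yellow
enamel, opaque patches and brown stains grown as connected pixel blobs
until the realized ratios equal the targets exactly (count rounding only).
Class colors are truncated Gaussians around means white (0.92, 0.90,
0.86), yellow (0.88, 0.82, 0.58), opaque (0.96, 0.96, 0.97), brown (0.45,
0.30, 0.20), background (0.72, 0.42, 0.45), σ = 0.03 per channel —
artifact choices matching the qualitative clinical descriptions
(paper-white opacity, brown stains, pink gums) while keeping classes
separable. An optional linear shadow gradient reproduces the known
failure mode of shaded enamel drifting toward background/brown colors.

Passing tests on these images show that the pipeline recovers known
lesion areas and stages under controlled color statistics; they do not
certify performance on real photographs, which add specular highlights,
saliva/plaque artifacts, uncontrolled illumination and camera response.

The 12-image fixture suite targets three images per stage with every
target ratio at least two percentage points clear of a threshold, so
sub-point measurement error cannot flip a stage.

## Problem sizes

Tests and examples run at desk scale: 1,280 training pixels
(400/400/200/100/180 per class, the same proportions as the study's
~4,000/4,000/2,000/1,000/1,800), cuckoo-search bounds [20, 120] with 10
nests and 3 generations, 256×384 fixture images. The full-scale published
configuration (bounds [1000, 2500], 30 nests, 100 generations) is the
package default (`CSConfig()`/`PipelineConfig()`).

## Known limitations

- No color calibration, white-balance or specular-highlight handling
  (reflections fold into the white class by convention).
- Per-tooth analysis is out of scope: ratios are pooled over the whole
  tooth region.
- The possibilistic centroid collapse described above caps multi-prototype
  pixel accuracy well below a nearest-neighbor ceiling; this is a property
  of the published objective with its default weights, not of the
  implementation.
- The staging thresholds are fixed clinical choices, not learned.
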