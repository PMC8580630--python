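# Methods

This note records the models implemented in `dermelm`, the parameter
choices that matter, the numerical decisions taken where the design was
genuinely open, and the limits of what the synthetic experiments show.

## Thermal exchange optimization

### Model

The minimiser maintains `population_size` candidate vectors inside a box
`[bounds_low, bounds_high]`.  Per iteration `k` (1-based, `t = k /
max_iterations`):

1. Candidates are sorted ascending by cost (stable sort, so ties keep
   candidate order).  The better half are environment objects, the worse
   half cooling objects; cooling object at sorted position `n/2 + i`
   pairs with environment object at position `i`.
2. Costs are shifted by `-min + 1e-12` before the cooling coefficient
   `gamma_i = c_i / c_worst` is computed, so the ratio is well defined
   for zero or negative objective values; an all-equal population takes
   `gamma = 1` by convention.  Candidates with non-finite cost (a failed
   objective evaluation is recorded as `+inf` and logged) take the worst
   ratio 1.
3. Each cooling object moves to
   `env' + (T_old - env') * exp(-gamma * t)` with
   `env' = (1 - (m1 + m2*(1-t)) * r) * T_env`.  Defaults `m1 = 0,
   m2 = 1` make the environment perturbation decay linearly over the
   run.  `r` comes from the uniform stream (TEO) or the chaotic stream
   (dTEO).
4. With probability `pr = 0.3` one uniformly chosen coordinate is
   re-drawn as `low + r * span * exp(-gamma * t)`.  The exponential
   damping follows the published update; `reset_style="plain"` switches
   to the undamped classical form.
5. dTEO only: each updated candidate is mutated multiplicatively,
   `x * (1 + u*(1-t) * g)` with `u ~ U(0,1)` per candidate and `g`
   standard normal per component.  Mutation is restricted to the cooling
   half by default (`mutate_whole_population` flips this).
6. Candidates are clipped to the box and re-evaluated; a thermal memory
   of the `memory_size = max(2, population//10)` best-ever pairs replaces
   the same number of worst candidates, which makes the best-ever cost
   non-increasing.

Environment objects stay fixed within an iteration; a `swap_roles` flag
exists for the variant in which the halves exchange roles in a second
pass, but it is off by default because the published description of that
reverse pass is too terse to pin down.

### The chaotic stream

dTEO draws its `r` values, and its initial population, from the
sinusoidal map `f -> alpha * f^2 * sin(pi f)` with `alpha = 2.3`.  Two
numerical facts matter:

* For `alpha = 2.3` the chaotic attractor's support is roughly
  `[0.49, 0.92]`.  The map also has an **absorbing fixed point at 0**:
  orbits started below ~0.45 (or above ~0.93) decay monotonically to
  zero and the stream stops being random at all.  Auto-drawn seeds
  therefore come from `U(0.5, 0.9)`, inside the attractor's basin.  An
  explicitly supplied `chaos_f0` anywhere in (0, 1) is accepted
  unchanged, so the degenerate regime remains reachable for study.
* Iterates that leave `(0, 1)` (possible for `alpha` near 4) are
  reflected to `1 - 1e-12` / `1e-12` so the map can always be iterated.

### Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `population_size` | 120 | candidate count (must be even for pairing) |
| `max_iterations` | 100 | cooling iterations |
| `pr` | 0.3 | per-candidate coordinate-reset probability |
| `m1`, `m2` | 0, 1 | environment-perturbation control bits |
| `memory_size` | pop/10 | elitist archive size |
| `chaos_alpha` | 2.3 | chaotic-map gain |
| `variant` | dteo | `teo` disables chaos and mutation |

With this protocol the 2-D sphere is solved to ~1e-12 and a sphere
optimum shifted to a random point in `[-3,3]^2` is recovered to a median
L2 error of ~5e-4 over 20 seeds.  The precision floor for shifted optima
comes from the environment perturbation `(1-t) * r * |T|`, which is
anchored at the origin and only vanishes at the final iteration.

## Benchmark functions

F1 (sphere), F2 (Rosenbrock), F6 (Rastrigin) and F7 (Griewank) are the
standard forms with analytic minimum 0; F4 is the bivariate
`x sin(4x) + 1.1 y sin(2y)` on `[0,10]^2` with minimum −18.5547; F5 is
the index-weighted quartic with a fresh standard-normal noise draw per
evaluation (its minimum therefore varies and it is flagged `noisy` so
equality checks skip it).  Unbounded domains use the standard literature
boxes (±100, ±30, ±5.12, ±1.28, ±600).  Two functions are implemented
exactly as printed in their source despite internal inconsistencies, and
are excluded from exact-minimum checks: F3 (`sum(x - 10 cos(10x))`,
whose true minimum on the box is far below the quoted 0) and F8 (a
Schaffer-like ratio whose quoted minimum does not match the canonical
Schaffer value).  `grid_refine_min` (dense grid plus bounded Nelder–Mead
polish) serves as the deterministic oracle for the bivariate minima.

The comparison protocol performs `reps = 20` independent runs per
(function, algorithm) at population 120 / 100 iterations and reports the
minimum and standard deviation of the per-run best costs, with paired
per-rep seeds across algorithms so that algorithm contrasts are not
confounded by seed luck.

## Preprocessing

The denoiser is a Wang–Mendel style fuzzy system.  The published
description names the method but not its variables, so the antecedent
design is this package's choice: three inputs — 3x3 neighborhood center,
median and mean — fuzzified over 7 triangular partitions of [0, 1];
one candidate rule per training pair (degree = product of memberships,
consequent = clean center value); max-degree wins per cell; product
inference with degree-weighted-average defuzzification; cells firing no
rule fall back to the neighborhood median.  Without a trained rulebase
the stage is a plain 3x3 median filter, which keeps the pipeline usable
with zero training data.  RGB channels are processed independently.

Contrast stretching maps the observed range onto [0, 1] through a
256-entry lookup table (inputs floored onto the levels).  For RGB images
one shared table over the global min/max is used: per-channel tables
would distort the color ratios the segmentation stage depends on.  Even
the shared table shifts the channel origin, which compresses
chromaticity differences, so the pipeline feeds segmentation the
*denoised, unstretched* image and keeps the stretched copy for
inspection and intensity-based display.

## Segmentation

Lesions are separated from skin in two illumination-robust channels:
`Rhat = R/|RGB|` and `Xhat = X/|XYZ|`, with XYZ from the CIE 1931 matrix
scaled by 1/0.17697 (black maps to 0 by convention).  Each channel is
Otsu-thresholded — the threshold maximises `w1 w2 (m1-m2)^2` over a
256-bin histogram of the observed range, ties resolved toward the lowest
threshold — and in each channel the class with the **lower mean** is
taken as lesion.  Whether the two channels should be thresholded jointly
or separately was not specified in the source; separate thresholds
combined with AND is the implemented reading (`or`, `r_only`, `x_only`
are available).  The mask is hole-filled, opened, closed, and reduced to
its largest 4-connected component.

The published structuring element is a "5x5 identity matrix" — a
diagonal line.  It is kept as the default for fidelity, but it is almost
certainly unintended (it erodes anisotropically and can chain blobs
lying along the image diagonal); `disk5` is provided and recommended for
real data.

## Features

Nineteen named features per (image, mask) pair.  Statistical moments and
a 64-bin histogram entropy (natural log, `0 log 0 = 0`) are computed
over the masked luminance (Rec. 709 weights).  Geometry uses the pixel
count as area, the count of region pixels 4-adjacent to background as
perimeter, and the second-moment ellipse axes `a >= b`; derived ratios
are rectangularity `A/(ab)`, irregularity index `4 pi A / P^2`, form
factor `A/a^2`, eccentricity `(2/a) sqrt(a^2-b^2)` (as printed — it can
exceed 1 for elongated shapes), elongation `2 sqrt(A/pi) / a`, and
solidity.  Because the perimeter is a boundary-pixel count rather than a
contour length, the irregularity index of a rasterised disk is slightly
above 1; the feature is used comparatively, not as an absolute disk
score.  Texture features come from a 32-level symmetric GLCM averaged
over offsets (0,1) and (1,0), restricted to pixel pairs inside the mask.
The default `standard` mode uses the canonical contrast / energy /
homogeneity / correlation definitions; a `literal` mode reproduces a
published variant in which contrast duplicates energy (`sum p^2`) and
correlation reads `(sum p - mu_r mu_c)/(sigma_r sigma_c)` — retained so
the discrepancy is documented and testable.  Moment invariants phi1–phi3
use central moments normalised by `mu00^(1+(p+q)/2)`, giving translation
and scale invariance.

## Feature selection

Wrapper search over the unit hypercube; components above 0.5 select
features; candidates are scored by the mean per-fold MCC of an inner ELM
(30 hidden neurons, stratified 5-fold, features z-scored with train-fold
statistics, fixed per-fold seeds so all masks see identical hidden
layers).  The published text says to *minimise* the MCC expression, but
the MCC is a correlation whose maximum marks the best classifier —
minimising it would reward inverted classifiers — so the implemented
objective is `1 - MCC`.  Empty masks score `+inf`, hence the returned
mask is never empty.

## Extreme learning machine

Input weights and biases `~ U(-1, 1)` from the seed; output weights by
`numpy.linalg.lstsq` (equivalent to the pseudoinverse solution and
satisfying the normal-equation certificate `||H^T(H beta - T)|| < 1e-8`).
Each neuron has a sigmoid shape parameter `bs_m` entering as
`sigmoid(as*s + bs)`; `as` is fixed at 1 since the two parameters shape
the curve almost interchangeably, and `bs` starts at 1 for every neuron.
`optimize_activation` runs dTEO over `bs in [-5, 5]^M` (default budget
700 iterations with a 20-candidate population — the hidden count M = 50
and the population are this package's defaults, as the source fixes only
the iteration budget), refits `beta` per candidate, and returns the
baseline fit whenever the search fails to beat it, so tuning can never
hurt the training error.

## Evaluation protocol

15 repeats (configurable; a related published protocol uses 30) of:
stratified 80/20 split → wrapper selection on the training split →
activation-optimised ELM on the selected, z-scored features → confusion
counts on the held-out split with melanoma as the positive class.
Metric means are averaged over repeats and the pooled counts are kept.
Stratification guarantees both classes in every split; selection is
re-run inside each repeat so no test information leaks into the feature
subset.  The prevalence identity
`accuracy = (sens*P + spec*N)/(P+N)` is asserted on every single-table
report; zero-denominator metrics are reported as NaN with a warning.

## Synthetic data

The generator emulates the properties the pipeline actually exploits:
a skin-toned background (default RGB 0.80/0.60/0.50) under a ±3 %
multiplicative illumination gradient; one darker lesion (default RGB
0.30/0.26/0.24, chosen to be lower than skin in luminance *and* in both
normalised-R and normalised-X chromaticity); a radial-harmonic boundary
(harmonics k = 2..6, weights normalised so `irregularity` is the exact
relative wave amplitude, clamped to keep the shape star-shaped and hence
one connected component); a smooth multiplicative pigment field with
standard deviation `color_variance`; optional dark hair arcs; iid
Gaussian pixel noise (sigma 0.02).  Class defaults: benign irregularity
0.06 / asymmetry 0.05 / color variance 0.02; melanoma 0.35 / 0.30 /
0.08 with a slightly larger radius.  Images default to 256x256 as a
desk-scale stand-in for full-resolution dermoscopy.

What it does **not** emulate: specular highlights, rulers and gel
artifacts, multi-component or border-touching lesions, camera color
profiles, and realistic pigment network texture.  Class separation is by
construction strong in the geometric and statistical features, so the
near-perfect synthetic classification scores certify that the chain is
wired correctly — they say nothing about accuracy on clinical data.

## Problem sizes and runtimes

The test suite's end-to-end study uses 200 generated images, selection
at 50 dTEO iterations and activation search at 100 iterations with 15
protocol repeats; segmentation quality is the median Dice over 50
images.  The acceptance script evaluates F4 on a 400x400 grid and runs
the 20x dTEO protocol at population 120 / 100 iterations.  Everything
runs in a few minutes on one CPU.

## Known limitations

* TEO's environment perturbation scales with the candidate's distance
  from the origin, so precision on optima far from the origin is budget-
  limited (~1e-3 at the default protocol) while origin optima are found
  to near machine precision.
* The diagonal default structuring element is kept for fidelity but is a
  poor morphological choice; use `disk5` on real images.
* The fuzzy denoiser's antecedent design is a documented reconstruction,
  not a published specification; its rulebase generalises only to
  neighborhoods resembling its training windows.
* Only binary (benign vs melanoma) classification is supported.
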