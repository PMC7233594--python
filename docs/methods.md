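# Methods

## Geometric model

All per-eye landmarks live in one planar fundus-style frame (µm, y increasing
superiorly); axial depths are separate scalars. Left-eye records are mirrored
about the vertical axis through the BMO centroid before any measurement, so
nasal/temporal semantics match a right eye; superior/inferior offsets are
preserved and the operation is an involution on the coordinates.

The **BMO centre** is the area (shoelace) centroid of the closed
piecewise-linear polygon through the delineated margin points — not the
vertex mean — so it is robust to uneven spacing of the delineation. This was
a genuinely open choice (a device may report either); the centroid is used
throughout and `bmo_centroid` is the single place to change it.

The **fovea–BMO axis** is the unit vector from the BMO centre to the fovea.
Its negation is the nasal reference ray for the trunk angle α; the vector
itself is the temporal reference ray for the PPA angle β. Both angles are
two-argument arctangents of (cross, dot) components against their reference
ray, signed so that *positive = superior side of the reference line*; this
encodes the clockwise/counter-clockwise reading of a fundus image without
ever referencing image handedness. Angles live in (−180°, 180°].

The **shift index** is a/b with a = ‖trunk − centre‖ and b = the distance
from the centre to the first crossing of the margin polygon along the
centre→trunk ray. b uses exact ray/segment intersection against the
piecewise-linear margin (shapely), taking the nearest forward crossing. The
interpolation scheme between delineated dots is not observable from a
published measurement protocol; piecewise-linear is the least-assumption
choice and is validated against two independent routes (circle closed form;
dense boundary sampling with bisection) to machine precision. A trunk outside
the BMO has no measurable position: shift index 1.0 exactly, α missing.
Severity groups: A <0.5, B [0.5, 1), C = 1 (within 1e-9; measured indices
reach 1.0 only via the outside-BMO convention). A trunk coincident with the
centre yields α = 0 with a warning rather than a rejection, so batch
pipelines survive degenerate synthetic draws.

**Obliqueness** is the in-quadrant angle from the horizontal,
`90 − ||α| − 90|` ∈ [0, 90]; it is invariant under α → −α and α → 180 − α.
**LCD** is trunk axial depth minus BMO-plane depth, floored at 0 with a
warning (an anterior trunk is a measurement artefact, not physiology).

## Visual-field model

The 24-2 grid is the standard 54-point 6° lattice (rows y = ±3…±21; the 27°
column only on the ±3 rows, nasal side), with the two blind-spot points at
(+15°, ±3°) never scored: 52 scoreable points, 26 per hemifield.
Pattern-deviation categories are coded 0 (normal) through 4 (p < 0.5%).

A **qualifying cluster** is a maximal connected component of abnormal points
within one hemifield with ≥ `min_size` (3) members at or beyond the
abnormality level and ≥ 1 member at the strict level. The default "methods"
rule is p<5% with one point at p<1%; a stricter "abstract" variant (all
points p<0.5%) ships as a named alternative because the two thresholds both
circulate in the defect-definition literature. Connectivity is 8-neighbour by
default (4-neighbour selectable); the choice is surfaced in every report.
Clusters never span the horizontal meridian — hemisphere assignment is only
well-defined under confinement — and blind-spot points neither count as
abnormal nor bridge components.

**Reliability**: fixation losses ≤ 20% and false-positive/negative error
rates ≤ 25%, all inclusive; exams failing (or missing) any index are skipped,
never imputed. **Longitudinal rule**: scanning reliable exams in order, a
hemifield's defect is *established* when its qualifying cluster appears in
`confirm_n` consecutive reliable exams (default 2, mirroring the
two-consecutive-tests confirmation used for diagnosis). The initial
hemisphere is the first to establish; both establishing at the same exam —
including the very first — is bi-hemispheric; neither establishing is
"undetermined" and the eye is excluded with a logged reason. The final label
applies the same cluster test to the last `confirm_n` reliable exams,
requiring presence in all of them.

## Synthetic cohort

The generator emulates a myopic high-tension-glaucoma cohort with known
ground truth; every default is a stated study condition or a documented
calibration:

| parameter | default | note |
|---|---|---|
| age | 54.7 ± 14.2 y, ≥ 20 | truncated normal, re-parameterized so the *observed* moments equal the targets |
| axial length | 25.5 ± 1.3 mm, ≥ 24.0 | myopia eligibility bound |
| highest IOP | 25.2 ± 4.1 mmHg, > 21 | high-tension eligibility bound |
| baseline MD | −8.11 ± 5.85 dB, [−30, 0] | |
| follow-up | 5.0 ± 2.7 y, ≥ 2 | |
| α | 0.55·N(40°, 35°) + 0.45·N(−35°, 30°) | superior-biased mixture; only group-level magnitudes are published, so the mixture is a calibration, not a claim |
| shift index | Beta(2.0, 2.3) + point mass 6/81 at 1 | Beta body splits mild/moderate roughly evenly around 0.5 |
| BMO area | 2.65 ± 0.55 mm² | near-elliptical 24-vertex polygon, star-shaped so always simple |
| onset effect | log-odds ln(0.83) per degree of α | P(inferior onset) = logistic(α); this is the quantity the recovery study re-estimates |
| bi-hemispheric onset | logit = −3.18 + ln(0.817)·MD₀ (+2.0 if severe shift) | intercept calibrated so the *marginal* bi rate ≈ 22% after averaging over the MD distribution (a naive logit(0.22) intercept overshoots); the severe-shift bonus reproduces a ~2/3 bi rate in that group |
| progression | −0.5 dB/y; bi-conversion hazard 0.06/y | ~26% of single-hemisphere eyes convert over 5 y |
| noise | false-positive point rate 0.01; unreliable-exam rate 0.10 | |

Exam series seed a template cluster (core points p<0.5%, edge points p<2%)
in the onset hemifield from presentation (second visit for eyes with MD₀ >
−2 dB), add the opposite hemifield at the drawn conversion time, sprinkle
isolated p<5% false positives, and mark unreliable exams by inflating
fixation losses. Per-eye substreams are keyed by (seed, eye index), so
enlarging a cohort never perturbs existing eyes, and fixed seeds give
byte-identical output files.

What the generator does **not** emulate: spatial correlation of
pattern-deviation noise, defect deepening/enlargement within a hemifield,
test–retest fluctuation of MD, measurement error in the landmark positions,
and inter-eye correlation. Consequently, a passing closed-loop test shows
that the classification and statistics recover the *configured* structure,
not that they are robust to every artefact of real perimetry; the
false-positive and unreliability knobs probe only first-order noise.

## Statistics

- **Chi-square**: Pearson, no continuity correction — recomputing the
  published categorical rows reproduces their printed p-values only without
  correction, which fixes the convention.
- **Summary ANOVA**: between-groups SS from (n, mean), within-groups
  SS = Σ(nᵢ−1)sdᵢ²; algebraically identical to raw-data one-way ANOVA, which
  the agreement study verifies to 1e-10. **Scheffé**: pairwise contrast F
  divided by (k−1) against F(k−1, N−k); every pairwise p ≥ the overall p.
- **Logistic regression**: maximum likelihood (Newton/IRLS via statsmodels)
  with Wald 95% CIs exp(b ± 1.96·se) — symmetric on the log scale, matching
  the way cohort odds ratios are conventionally reported. Rank-deficient
  designs are rejected; separation/non-convergence is flagged on the result
  (`converged`, `note`), never silently returned. The screen keeps
  candidates with univariate Wald p < 0.20 and refits them jointly; both
  stages are always reported.
- **Conditional-inference tree**: at each node, each covariate is tested by
  a Monte-Carlo permutation test (default 9 999 permutations; 999 in the
  pipeline default for speed) on the per-class linear statistic Σxᵢ1(yᵢ=k),
  standardized by the permutation sample's own moments, max-abs over
  classes; Bonferroni across covariates; stop when min adjusted p ≥ α
  (0.05) or the node has < 10 observations. The selected covariate is split
  at the midpoint maximizing the left/right Pearson chi-square of the class
  distribution (children ≥ 5; ties to the smaller threshold). Separating
  selection from cut-point search is what removes the bias toward
  many-valued covariates; the implementation targets that idea, not
  bit-compatibility with any existing partitioning package, and split values
  found on synthetic data are compared to expectations only qualitatively.

## Pipeline

Eligibility: axial length ≥ 24 mm, highest IOP > 21 mmHg, follow-up ≥ 2 y,
optional image-quality score ≥ 15; one study eye per subject by a seeded
draw when a `subject_id` column is present. Every exclusion is logged with
its triggering rule. The three logistic reports condition differently:
initial-inferior uses signed α among single-hemisphere eyes with a
measurable trunk; initial-bi uses |α|; final-single uses obliqueness and
final MD. Severe-shift eyes (no α) are necessarily absent from α-based
models. Reports are CSV/JSON/SVG only, deterministic under a fixed seed
(matplotlib's hash salt pinned, no timestamps).

## Validation studies and problem sizes

`lcshift.studies` re-certifies the numerics from scratch: odds-ratio
recovery over 200 cohorts × 2 000 eyes (mean estimate and 95%-CI coverage);
tree-hierarchy recovery over 100 cohorts × 200 eyes; shift-index agreement
with the circle closed form (ray aimed through a margin vertex, where the
piecewise-linear margin coincides with the circle) and with a dense-sampling
boundary oracle on random convex polygons; cluster-rule agreement with an
exhaustive union-find enumeration over 1 000 random maps; summary-vs-raw
ANOVA agreement over 200 random datasets. These sizes keep the full
certification under a minute while leaving Monte-Carlo error well inside the
margins being checked; they are the package's chosen defaults, and each
function takes explicit size arguments.

## Known limitations

- The hemisphere rule treats hemifields symmetrically; real perimetric noise
  is spatially structured and asymmetric.
- The tree's permutation p-values are Monte-Carlo estimates; with very small
  `n_perm` the Bonferroni-adjusted minimum attainable p is `k/(n_perm+1)`.
- Left-eye handling assumes the mirror axis through the BMO centroid; a
  cyclotorted image would need upstream correction.
- The generator's α mixture and shift-index Beta body are calibration
  choices constrained only by group-level summaries.
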