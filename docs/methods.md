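# Methods

## The measurement model

The package analyses a polydomous ant colony as an attributed undirected
graph. All quantities derive from four field measurements per object:

* **Trail activity.** The distance along a central portion of a trail
  needed to count 10 ants. Its reciprocal times 10 is the density
  *w* in ants·m⁻¹; unlike rate-based measures it does not depend on
  walking speed. A nest→tree trail qualifies as a *clear* foraging trail
  only when *w* strictly exceeds 25 ants·m⁻¹ (more than 10 ants in
  40 cm).
* **Internest trail strength.** S = w·l / p̄, the estimated number of
  ants on the trail divided by the mean worker population of its two
  endpoint nests. Dividing by population converts raw flow into the
  per-capita investment the two nests make in the connection; S is
  invariant under rescaling (w, l) → (k·w, l/k) and halves when both
  populations double. Foraging-trail strength divides by the origin
  nest's population only, controlling for its internal demand; the
  number of ants on a foraging trail is taken as w·l, measured the same
  way as on internest trails.
* **Amount of foraging and differentials.** A nest's amount of foraging
  is the sum of its qualifying foraging-trail strengths; a nest with
  none is *nonforaging* (which does not exclude diffuse scavenging —
  only tree trails are scored). Internest trails are classed F-F, nF-F
  or nF-nF by endpoint status. The foraging differential of a trail is
  the **absolute** difference of the endpoint amounts: trails are
  undirected, so a signed difference has no canonical orientation.
  nF-nF trails carry a differential of exactly 0 and are flagged
  excluded from differential analyses.
* **Population and canopy.** Mound volume is half an ellipsoid,
  V = π·d₁·d₂·h/6, reading the height as the vertical semi-axis (the
  mound is the ellipsoid's upper half — the only reading consistent with
  "half an ellipsoid"). Population is predicted from V by an ordinary
  least-squares site calibration against mark–release–recapture counts,
  floored at zero because a regression may extrapolate negative workers
  for tiny mounds; an explicitly supplied population column always takes
  precedence over the calibration path. Canopy cover is the fraction of
  pixels *strictly below* an intensity threshold in an 8-bit grayscale
  vertical photograph. The default threshold of 255 counts every
  non-pure-white pixel, which is what a binarised (thresholded)
  photograph expects; the threshold is configurable for raw images.

## Network metrics

Degree and weighted degree (sum of incident strengths), node and trail
betweenness, closeness and Newman's assortativity coefficient come in
unweighted and strength-weighted forms.

* **Distance transform.** Weighted shortest paths cost 1/S per trail by
  default — a stronger trail is a shorter channel, the standard
  flow-network reading. A −ln S transform (additive over multiplicative
  capacities, valid for S < 1) is available and labelled in output,
  since the field convention is not settled.
* **Betweenness accounting.** All tied shortest paths share credit
  fractionally; values are reported raw (per unordered source–target
  pair) with normalisation available behind a flag.
* **Disconnection.** Closeness and betweenness on a disconnected graph
  are computed per component and flagged, never silently mixed; a
  singleton component's closeness is undefined (NaN with flag). Loading
  a disconnected colony warns rather than fails, because partial data
  may be loaded deliberately.
* **Assortativity.** Newman's r is the Pearson correlation of an
  attribute across the two ends of every trail, symmetrised so each
  undirected trail contributes both orderings; the weighted form weights
  each trail's contribution by its strength. Zero attribute variance
  over the endpoints makes r undefined and is flagged explicitly rather
  than propagated as NaN. Note that r is invariant under *any* affine
  attribute transform with non-zero scale: both endpoints transform
  together, so a negative scale cancels. The degree correlation uses
  weighted degree as the attribute with the focal trail included in both
  endpoint degrees (simplest reading); an excess-degree variant that
  subtracts the focal trail is available behind a flag.

## QAP permutation inference

Nest attributes are autocorrelated through the trail structure, so
classical tests overstate significance. The quadratic assignment
procedure holds the graph fixed and permutes the per-nest attribute
bundles uniformly at random; for data pooled over colonies the
permutations are blocked, shuffling each colony independently so no
attribute ever crosses a colony boundary.

* **Recompute, don't permute, derived quantities.** Trail strength,
  categories, differentials and weighted degree depend jointly on
  structure and attributes; they are recomputed from the permuted
  attributes on every draw. Statistics are therefore callables that
  receive the permutation and do their own recomputation.
* **Two pairing modes.** Tests of an attribute against a structural or
  structure-derived quantity permute the whole bundle against the fixed
  graph. Tests of one attribute against another (e.g. nest size by
  foraging status) permute one attribute relative to the other, still
  blocked within colony — permuting the whole bundle would leave the
  pairing intact and the statistic constant.
* **p-value convention.** p = (1 + #extreme)/(1 + N): never zero, exact
  under exchangeability, and reproducible from the recorded seed.
  Two-sided tests compare magnitudes (|T_perm| ≥ |T_obs|), which is
  sign-flip invariant and appropriate for statistics centred at zero
  under the null; F-type statistics use the one-sided "greater"
  alternative. Default N = 1000 in the pipeline.
* **Degenerate permutations.** A permutation on which the statistic is
  undefined (zero variance, too few edges in a recomputed category) is
  resampled, up to 10·N total draws, after which the test aborts with a
  diagnostic. An undefined statistic on the *observed* data skips the
  test with a logged reason.
* **Multiple testing.** Per-colony assortativity tests (nest size,
  amount of foraging, weighted degree) form a family of m = 3 per
  colony; Bonferroni-adjusted p-values and the family size are echoed in
  the output.

## The synthetic colony generator

The generator provides studies with the statistical shape of a mapped
upland *F. lugubris* population, as ground truth for calibration and
power work. Defaults, with the reasoning:

| parameter | default | why |
| --- | --- | --- |
| colonies per study | 10 | scale of a season's field campaign |
| nests per colony | 7–22 | observed colony size range |
| internest trails | edge/node ratio 1.0–1.4, max 30 | field networks are barely denser than spanning trees |
| foraging fraction | 75/140 ≈ 0.54 | pooled share of foraging nests |
| nest size | lognormal; F: mean 72 630, nF: 22 760 workers | right-skewed, strictly positive; class contrast |
| size SD | F: ≈207 000, nF: ≈39 700 | reconstructed as SE·√n from class means ± SE; approximate |
| canopy cover | beta; F: 0.30, nF: 0.21 (SD ≈ 0.23/0.19) | bounded in [0,1]; foraging nests sit in darker spots |
| trail length | lognormal per category; F-F 6.72 m, nF-F 3.18 m, nF-nF 2.61 m | F-F trails are the long ones |
| baseline trail load | lognormal, mean 150 ants, CV 1.0 | ~50 ants·m⁻¹ on a 3 m trail |
| coupling target ρ | 0.36 on nF-F trails | the effect size the analysis is designed to detect |

Topology is a Euclidean minimum spanning tree over uniformly placed
nests plus a few short extra edges — spatial and sparse, not
Erdős–Rényi or scale-free. Trees are placed in clusters; each foraging
nest runs 1–3 qualifying trails to its nearest trees.

**Strength model and exchangeability.** Each internest trail gets a
baseline ant load A₀ drawn independently of every nest attribute; on
nF-F trails the load becomes A = A₀ + β·differential·p̄, so the strength
S = A/p̄ is the baseline strength plus β·differential. β is solved in
closed form against the realised pooled sample so that the pooled nF-F
differential–strength Pearson correlation equals ρ_target exactly
(negative loads, which can arise when the solved β is negative, are
clipped at a small positive value, leaving the realised correlation a
little above target in those studies). Measured foraging-trail lengths
are drawn from a lognormal rather than taken from the spatial embedding,
so nest attribute bundles are independent of the graph. With
ρ_target = 0 this makes the attribute bundles exactly exchangeable over
the nests of a colony given the trail structure — the QAP null — which
is what makes the generator usable for type-I calibration. Note that
even under this null the *raw* differential–strength correlation is
typically positive: strength and differential share the 1/population
denominator. That is precisely the autocorrelation the QAP corrects
for, and why classical correlation tests are not trusted on this data.

Mound dimensions are back-computed from the generated population at a
nominal packing density of 50 000 workers·m⁻³ so that the
dimensions+calibration path of the pipeline is exercised consistently.

**What the generator does not emulate.** No individual-ant or food-flow
dynamics; no spatial correlation between nest attributes and position
(real insolation and forage vary smoothly in space); no measurement
error model for the trundle-wheel mapping; trail lengths are drawn, not
geometric. Tests passing on this generator therefore demonstrate the
correctness and calibration of the *statistical machinery*, not that
real colonies satisfy the exchangeability null.

## Problem sizes and numerical choices

* Oracle validation enumerates all simple paths on 200 random connected
  graphs of ≤ 8 nodes (agreement to 1e-9, absolute).
* Null calibration uses 500 independently generated 10-colony studies
  with 199 permutations each — 199 puts α = 0.05 exactly on the
  (1+k)/(1+N) lattice. Coupling recovery uses 200 studies.
* The law-of-large-numbers check on the moment-matched samplers uses
  20 000 draws per class: the foraging-class size law has CV ≈ 2.85, so
  smaller samples cannot pin the mean to the 5% tolerance used.
* All randomness flows from numpy Generators seeded per run; reports and
  fixtures are byte-reproducible given (inputs, config, seed), with
  floats written at 12 significant digits.
* Zero-range attribute vectors are detected exactly (via the range, not
  a variance tolerance) before any correlation is formed.

## Known limitations

* The exact-sample β calibration makes the realised coupling
  deterministic given the skeleton; studies where the solved β is
  negative deviate slightly upward because of load clipping.
* Pearson correlations on these heavy-tailed quantities are dominated by
  their largest values; the Spearman variants reported alongside are the
  robust check.
* GraphML export covers the nest graph and its listed attributes only;
  trees and foraging trails round-trip through the CSV schema.
* The trail-strength-vs-betweenness tests use unweighted trail
  betweenness (structure-fixed under permutation); a weighted variant
  would require recomputing shortest paths inside every permutation and
  is available through the metrics API for one-off use.
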