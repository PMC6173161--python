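# Methods

This note documents the models, conventions and numerical choices behind
`frogdiet`, and what the synthetic-data tests do and do not establish
about real stomach-flush data.

## Data model

Diet data are long-format: one CSV row per prey item, with the predator's
identity, morphometrics (SVL, head width, lower-jaw length, mm) and
stratum (site, habitat ∈ {agriculture, plantation, disturbed_forest,
undisturbed_forest}, season ∈ {dry, wet}) repeated on each of its rows.
An empty stomach is an explicit sentinel row (`prey_taxon = NONE`) so the
vacuity index is computable from the same file. Availability data are one
row per trapped item, keyed by trap and occasion (1–30, the pitfall
design's trap-visits per plot). Functional traits (hardness
soft/medium/hard; motility sedentary/medium/evasive; habitat origin;
vertebrate class) are a separate lookup joined at read time. The shipped
default trait table is authored configuration, not data: trait
assignment is a field judgement, so every trait-based output should cite
which table produced it. Recaptured individuals (toe-clip records exist
in the original design) are not given special treatment; an individual
re-entered under a new id would be counted twice — a documented caveat,
not a detectable condition.

## Prey volumetrics

Volume is the ellipsoid `(4/3)π(l/2)(w/2)²` in mm³. Fragmented prey get
the median volume of measured items of the same taxon; with an even donor
count the median is the mean of the central pair. The default imputation
scope pools donors across predator species (the per-species scope is a
config switch); a taxon with no donors falls back to the global median,
or errors if configured strictly. Imputation is idempotent, never alters
measured items, flags imputed ones, and emits an audit table
(individual, taxon, assigned volume, donor count).

## Composition

`N%` and `V%` are normalized within predator taxon; `F%` divides by all
sampled individuals including empty stomachs (the alternative
non-empty-denominator convention is a switch — the choice changes `F%`
and hence IRI levels but not rankings). IRI uses the Pinkas form
`(N% + V%) × F%`; recomputing it from the packaged table's own rounded
inputs reproduces the published cells within 0.1 % relative, which is
the expected rounding propagation. Category counts exclude the residual
`Unidentified` label by default (that convention reproduces the
published 29/25/14 richness figures) while composition tables retain it
as a printed row. The packaged count matrix is reconstructed from the
published percentages by largest-remainder apportionment so each row
sums exactly to the published item totals (687/618/173); per-cell
half-up rounding — also provided, as `reconstruct_counts` — loses one
item of 687 for the bullfrog because the printed percentages only sum
to 99.84.

## Overlap and null models

Both MacArthur–Levins asymmetric forms and the symmetric Pianka form are
implemented; the symmetric form is the default because it is the one the
assemblage's published pairwise values correspond to (the identity
`symmetric² = asymmetric_jk × asymmetric_kj` is asserted in tests).
Null models randomize only the two consumers of the tested pair, since
conclusions are reported per pair. RA3 (reshuffle each row across all
categories, preserving niche breadth) is the default with 1,000
iterations; RA1 (all cells uniform), RA2 (non-zero cells uniform, zeros
kept) and RA4 (non-zero cells reshuffled among non-zero positions) are
available. Tail probabilities use the add-one convention with ties
counted in both tails, so `p ∈ [1/(B+1), 1]` and `p_lower + p_upper ≥ 1`.
A tie tolerance of 1e−12 guards equality comparisons of reshuffled
floating-point overlaps. Correctness anchors: exhaustive enumeration of
all reshuffle pairs on small matrices (the independent oracle for the
Monte-Carlo tails), and a calibration check that p-values are uniform
when the observed data are themselves a null draw.

On the packaged count matrix the bullfrog–*Limnonectes* overlap (0.869)
exceeds every one of 10,000 RA3 draws (null mean ≈ 0.24), the
bullfrog–*Fejervarya* overlap (0.344) does not (upper-tail p ≈ 0.07),
and the native–native pair computes to 0.62 from the packaged
percentages — conventions for that published pair evidently differed,
and the value is reported as computed.

## Electivity

Relativized electivity is computed over the groups retained after two
screens: a minimum consumed-sample filter (≥10 items for the two larger
predators, ≥5 for *Fejervarya*, matching the published cut-offs) and
availability support (groups consumed but absent from traps are dropped
with a warning rather than smoothed — the pitfall design cannot estimate
volant or vertebrate availability at all, and such taxa are rejected at
read time). Both vectors are renormalized over the retained set. Note
that `E*` compares `W_i` with `1/n`, so its value — and even its sign —
is relative to the included group set; merging or dropping groups
legitimately moves other groups' electivities. Default size bins
(0,10], (10,100], (100,500], (500,∞) mm³ bracket the small/medium/large
anchors used in the study and are overridable. Simpson diversity
defaults to the complement form `1 − Σp²`; the finite-sample variant is
available. Default stratum restrictions follow the sampling design (the
bullfrog scored only in agriculture/plantation; *Fejervarya* only at its
one adequately sampled site).

## Size–prey regression

One point per prey item: cube-root volume against log SVL, OLS per
predator taxon (the published analysis "accounted for taxonomic
identity" without stating the model structure; separate per-species fits
are the transparent reading and are what this package reports).
Requires ≥3 items and non-degenerate SVL variance.

## Synthetic assemblage generator

Defaults are the study conditions: diet compositions are the packaged
numeric proportions; individuals per site × habitat × season follow the
published effort design (798 individuals); stomachs are empty with
probability 0.1968 (dry) / 0.0867 (wet) and otherwise hold a
zero-truncated Poisson(2.1) number of items drawn multinomially.
Cube-root prey volume is `α_sp + β_sp · log(SVL) + ε`, `ε ~ N(0, 1)`,
with the published per-species slopes (1.93, 0.88, −0.07) as defaults,
`α_sp` set so invertebrate prey average ≈27/16/6 mm³ for the three
species, a +3 offset on the cube-root scale for vertebrate prey, and a
floor at 0.3 (0.027 mm³). Length and width are back-solved from the
volume through a Beta(2, 5) width:length aspect ratio, giving
heavy-right-tailed volumes; SVL is log-normal with medians 100/45/32 mm.
A fragmentation process deletes dimensions with probability 0.1 to
exercise imputation. Pitfall items are Poisson(3) per trap occasion from
a pooled terrestrial-invertebrate composition. All draws come from one
seeded generator; identical configs give identical datasets.

What passing recovery tests show: the analysis chain is consistent — it
recovers generating compositions within multinomial error, generating
slopes within OLS error, analytic electivity signs, and calibrated null
p-values. What they do not show: robustness to real-data features the
generator omits — prey-size dependence on category beyond the vertebrate
offset, trap biases (e.g. over-capture of social insects), digestion
gradients in identifiability, individual diet specialization, spatial
autocorrelation, or recapture-induced pseudoreplication.

## Problem sizes

Tests and drivers run the generator at the study's own effort (≈800
individuals, ≈1,500–1,700 items) and use 10⁴ null iterations for
headline tails, 99 iterations × 500 replicates for calibration, and
10⁴-item diets for convergence checks — sizes chosen because the
targeted standard errors (±0.02 on overlap, 3·SE on slopes) are already
reached there.

## Known limitations

- Availability is pitfall-based: electivity is undefined for volant and
  vertebrate prey, and ant trappability likely overstates availability.
- `E*` values are comparable only across identical group sets.
- The published native–native overlap is not reproducible from the
  published percentage table (see overlap section).
- Percentage reconstruction to integer counts is a fixture utility;
  half-up rounding and apportionment can disagree by one item where the
  printed percentages lost mass to rounding.
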