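# Methods

This note documents the quantitative choices behind `buzznet`: what each
stage computes, which parameters matter, what the synthetic community does
and does not emulate, and where the design was genuinely open.

## Single-visit accounting

Anther pollen is counted from a haemocytometer aliquot of a macerated-anther
suspension; counts are scaled to whole-flower totals by
`total_volume / aliquot_volume` (default 240 µl / 10 µl = 24). Removal per
visit is the mean aliquot-scaled grain count of unvisited bagged reference
flowers minus the grains remaining after one visit; deposition per visit is
the stigma count minus the mean count on unvisited control flowers
(self-pollination baseline). Stigmas are counted exhaustively, so deposition
is never aliquot-scaled. Negative differences — possible whenever a visited
flower happened to carry more pollen than the reference mean — are clamped
to zero and counted in a diagnostics object; clamp counts are part of every
pipeline report.

Reference flowers carry six replicate aliquot counts. The coefficient of
variation (sample SD / mean) across replicates flags inconsistent counts;
flowers with CV above the threshold (default 0.2, configurable) are excluded
from the reference mean by default. The 0.2 default is our choice of a
conventional "acceptable assay variability" cutoff; the underlying field
protocol prescribes the CV screen but not a numeric threshold.

## Network currencies

The visitation matrix tallies one unit per recorded visit. By default all
recorded visits count; a `require_touch` switch restricts to visits that
contacted the reproductive structures, since the raw records keep that flag.

Efficacy matrices (DN, RN) hold the mean per-visit efficacy per plant × bee
pair. Pairs that were visited but never captured in a single-visit
experiment are imputed (default: mean over the bee's functional group on
that plant, falling back to the group mean, then zero); every imputed cell
is flagged and counted. The rationale is to preserve observed visitation
topology without inventing efficacy for behaviours never measured.
Alternative policies (`zero`, `bee_mean`) are selectable.

Performance networks are plain cell-wise products, FPN = VN ∘ DN and
MPN = VN ∘ RN — the quantity × quality reading of effectiveness — with no
renormalisation. Zero-visit cells therefore stay zero regardless of
efficacy.

## Network metrics

**H2′.** H2 is the Shannon entropy of the cell distribution; H2′
standardizes it between marginal-constrained extremes. Two standardizations
are provided. *Continuous*: H2_max is the independence surface (sum of the
two marginal entropies) and H2_min = max of the marginal entropies, the
joint-entropy lower bound for a maximally specialised coupling. *Integer*:
both extremes are integer tables sharing the observed (integer) marginals —
the maximum built by largest-remainder allocation of the independence
expectations with marginal repair, the minimum by greedy packing
(largest-pair, exact-fit-first and subset-sum variants) — each polished by
marginal-preserving cycle transfers. Because table entropy is concave along
any transfer direction, the ascent uses unit steps and the descent endpoint
(block) steps; 3×3 six-cycles are added for small tables. On random
matrices with grand total ≤ 12 these polished allocations match exhaustive
enumeration exactly (tested over thousands of cases); the two modes agree
within 0.02 once the grand total exceeds ~1000. Degenerate matrices (one
non-empty row or column) return H2′ = 0 with a flag instead of erroring, so
sparse currencies survive batch runs.

**NODF** is computed on the binarized matrix (presence = weight > 0),
matching the classic binary definition; pairs with equal fills contribute
zero. A weighted variant is deliberately out of scope. Our implementation
agrees with `vegan::nestednodf` to machine precision.

**Modularity.** Q_w is the Barber bipartite modularity on raw weights. The
optimizer is weighted label propagation: node-wise best-label moves (a row
moves to the column-label whose members maximize its own Q contribution,
and symmetrically), iterated to a local optimum, with 20 restarts over
random initial module counts and ties broken toward the lowest module id —
fully deterministic under the seed. On small matrices the optimizer
reaches the exhaustively enumerated optimum in ≥ 95% of seeded runs.

**Generality** is the totals-weighted mean of 2^H (base-2 entropy of each
species' partner distribution) at a level.

**d′.** For focal species k with partner availabilities q_j = A_j/m,
d = Σ p′_j ln(p′_j/q_j). d_max concentrates A_k on the rarest partners
(greedy ascending q_j, capped at partner totals, with one-partner-anchored
restarts and endpoint-exchange ascent, since concentrating on a single
slightly-commoner partner can beat splitting across rare ones); d_min is
the largest-remainder proportional allocation refined by unit-exchange
descent, which is exact for this separable-convex minimization. d_min is
computed, not assumed zero: proportional use is generally unattainable with
integers. Real-valued currencies are rounded to faithful integer counts
first (below); species whose profile rounds to zero report d′ as missing.

**c/z.** Participation c = 1 − Σ_t (k_{i,t}/k_i)² over joint modules;
z standardizes the within-own-module degree against same-level members of
the same module (cross-level degree scales differ, so levels are never
pooled). Degrees are binary by default — the role taxonomy is degree-based
— with a weighted mode for sensitivity analysis. Modules with one member at
a level, or zero SD, report z = 0 with a flag. Role thresholds are
z = 2.5 and c = 0.62, boundaries inclusive downward.

## Null models

The null family fixes both marginals and samples uniformly from the
association-free distribution of contingency tables by permuting the
column-label multiset against the fixed row-label multiset. Significance
is the 2.5th/97.5th percentile interval (linear interpolation) of 1000
metric values; an observation strictly outside is significant, with its
direction reported. Calibration properties (every draw conserves marginals;
the two-table space is sampled uniformly; the type-I rate of the CI test is
≈ 5% when the observed matrix is itself a null draw) are asserted in the
test suite.

The sampler is defined for integer tables, but performance currencies are
real-valued. They are rescaled by the smallest power of ten that keeps the
per-cell rounding error within 0.5% of the grand total while leaving at
least ~10³ counts, then rounded; the scale is recorded in every ensemble.
This keeps the null ensemble faithful to the matrix while keeping O(m)
sampling fast even for matrices whose raw totals run to millions of
grain-visits.

## Cross-currency statistics

Species-level metrics are compared across currencies by paired t-tests
(species paired with themselves; species missing from either currency are
dropped pairwise and counted) between VN, FPN and MPN. Pearson correlation
tests (t = r√(df/(1−r²)), df = n−2) are reported only among VN, DN and RN:
the performance currencies share the visitation component by construction,
which would force positive correlations. Zero-variance inputs return
flagged degenerate results rather than raising. The comparison report is a
canonical JSON document (sorted keys, rounded floats), so regeneration from
identical inputs is byte-identical.

## Synthetic community

The generator emulates a Campo-Rupestre-style buzz-pollination assemblage:
10 plant species and 29 bees in four behavioural groups — 6 flower-buzzing,
17 anther-buzzing, 2 robber, 4 thief — with an expected 1838 recorded
visits of which the buzzing groups carry 79% of the rate mass
(flower-buzzing 45%, anther-buzzing 34%, robber 13%, thief 8% — the first
two anchored, the split among the rest our choice). Within groups, species
abundances follow geometric series (one dominant flower-buzzing species at
~23% of all visits). Group-by-plant rates follow smooth preference profiles:
buzzing groups range widely over plants, robbers concentrate on a couple of
hosts. Pair-level visit counts are zero-inflated negative binomials
(group-level zero inflation 0.2–0.5 and dispersion 0.5–1.0; the emulated
study reports a hurdle/zero-inflated model family but no dispersion
estimates, so these are stated assumptions).

Per-visit efficacies are zero-inflated lognormal bodies moment-matched so
the mixture has exactly the configured (mean, SD). Anchored moments:
flower-buzzing deposition 24.4 ± 14.8 grains, thief/robber deposition
3.6 ± 3.3, robber removal 25 671.2 ± 2418.3, thief removal 141.22 ± 320.4.
Unanchored pairs are interpolations, not claims: anther-buzzing deposition
18 ± 12 (close to flower-buzzing, since deposition varies little among
vibrating bees, which contact the stigma on most visits), flower-buzzing
removal 12 000 ± 8000 and anther-buzzing removal 4000 ± 3500 (male
performance varies widely between species). Deposition zero-inflation is
0.05 for vibrating groups and 0.25 for robbers/thieves. Removal draws are
truncated at the plant's realized reference total (a robber cannot remove
more pollen than the flower holds); reference totals are ~28 000–33 400
grains per flower.

Per-visit removal additionally carries a pair-level *matching* factor:
for bee b with visit shares s_p over plants, the removal mean on plant p is
scaled by s_p^γ (γ = 1.5), renormalized so the bee's visit-weighted mean
stays at the group anchor. This encodes that vibration-mediated pollen
extraction tracks the same flower–bee morphological fit that drives
visitation, and it is what makes the male-performance network more
specialised than the female one; deposition has γ = 0. Single-visit
experiments sample ~91 flowers per plant (≈ 910 total, emulating the ~908
of the field protocol), choosing the visiting bee proportionally to pair
rates; reference flowers get 6 Poisson replicate aliquot counts, stigma
controls a Poisson selfing baseline (mean 2 grains).

What the generator does **not** emulate: phenology and spatial structure,
heterospecific pollen, within-species behavioural variation, observer
effort imbalance, and the non-significant NODF the field study reported
(synthetic communities built from smooth preference profiles tend to be
significantly nested either way). Passing tests therefore show that the
pipeline recovers planted structure of this kind — not that any particular
field system behaves this way.

## Reproducibility

Every stochastic component takes an explicit seed; the pipeline derives
per-stage seeds deterministically from one master seed so stages can be
rerun in isolation, and writes a manifest with config hash, seeds, package
version and artifact digests. Reruns reproduce every artifact
byte-for-byte.

## Problem sizes

Default analysis scale is the emulated study scale (10 × 29, ~1800 visits).
Oracle-equivalence tests run on matrices with grand total ≤ 12 and
dimensions ≤ 4 × 4, where exhaustive enumeration of tables, compositions
and joint partitions is feasible; null-model calibration uses 8 × 8 count
matrices, 1000-run ensembles and 200–400 replicates; direction-recovery
checks use 25–50 full replicates of the default community.

## Known limitations

- The discrete H2′/d′ extremes are polished heuristics; they are exact on
  all enumerable cases we test but carry no global-optimality proof at
  field scale (the standardizing constants are insensitive to the last
  unit of entropy there).
- Label propagation can in principle miss the global Q_w optimum on
  adversarial matrices; restarts mitigate this.
- The integer-rounding step for real-valued currencies makes null
  ensembles and d′ depend mildly on the chosen scale; the scale is always
  reported.
- Imputation of unmeasured pair efficacies biases DN/RN toward group
  means; the imputed-cell count is reported so sensitivity can be checked
  under `imputation="zero"`.
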