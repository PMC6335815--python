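# Methods notes

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical choices a maintainer would want to know.

## Study system and species tree

The default tree is the five-species *repleta* group —
*D. repleta*, *D. hydei*, *D. buzzatii*, *D. aldrichi*, *D. mojavensis* —
with named internal branches (`ancestral_repleta`, `cactus_use`,
`cactus_specialisation`, `mulleri_complex`) and **two** outgroups
(*D. melanogaster*, *D. virilis*) placed as a basal trichotomy.  Two
outgroups rather than one is deliberate: with a single outgroup the root
has degree 2 and, once the tree is unrooted for distance fitting, the
outgroup stem and the ancestral-repleta stem merge into one edge, making
the ancestral-repleta silent length — needed for the per-branch rate
normalisation — unidentifiable from pairwise distances.  Branch lengths
are silent-site divergences (substitutions per 4-fold degenerate site);
the defaults (terminals 0.10–0.35, internals 0.05–0.25) are plausible
magnitudes for these divergence depths and are freely configurable.

## Synthetic generator

The generator's defaults are the study conditions at desk scale:

- **Gene families.** `n_families = 500` families present since the root,
  plus per-branch orthogroup births drawn Poisson(rate × silent length).
  Default birth rates are proportional to the observed per-branch
  origination counts of the study system (265 : 394 : 194 : 22 across the
  four internal branches) over the default lengths, scaled to about one
  fifth of the original size so a full run takes seconds.
- **Duplications.** Terminal-branch inparalogue copies arise per gene at
  0.75 events per unit silent length (≈ one duplication per ten genes on
  a typical terminal branch, matching the observed inparalogue-to-gene
  ratios).  A copy is inserted adjacent to its template with probability
  `p_adjacent = 0.7`, otherwise uniformly — this carries the synteny
  signal.  Copies carry `duplicate_divergence = 0.05` extra silent
  length, so the template is almost always the better cross-species hit.
- **Selection flags.** ~4.5% of terminal-branch genes and 3% of
  internal-branch families are flagged, with genes whose family generated
  an inparalogue in that species 1.7× as likely to be flagged — the
  association the duplication–selection analysis is meant to detect.
- **Loss.** Default loss rate is 0 (Dollo-clean presence patterns), so
  origin assignment is exact and recovery tests have a sharp truth;
  a nonzero rate is available to probe robustness.
- **Codon sequences.** A nucleotide-level proposal process at rate equal
  to the branch's silent length per site: proposals are
  transition-biased (kappa = 2), proposals creating stops are rejected,
  synonymous proposals are always accepted and nonsynonymous ones with
  probability omega (default 0.2).  Consequently 4-fold degenerate third
  positions accrue substitutions at exactly the silent rate, which is
  what makes silent branch lengths controllable.  The residual bias from
  applying a Jukes–Cantor correction to kappa = 2 data was measured on
  exact expected distances at < 3.5% per branch, well inside the 10%
  recovery tolerance.  No indels, no alignment error.
- **Expression.** Two species share a universe of 1:1 orthologous gene
  ids (3000 by default).  Eight trajectory templates over the 8 time
  points (pre-exposure control, mid-exposure, post-exposure, five
  recovery points) are standardised shapes; DE genes follow their
  cluster's template scaled by 2 log2-units, non-DE genes are flat, and
  counts are negative binomial (dispersion 0.05) with library sizes
  uniform in 0.8–1.2 M.  240 genes per species are responsive, 35 of
  them shared — about twice the expectation under independence, the same
  fold-excess regime as the real comparison.  Shared responders take the
  same trajectory cluster in both species (a conserved response);
  species-specific responders are assigned independently.  100 genes sit
  below the 50-read inclusion filter.  Counts are generated directly; no
  read-level simulation.
- **GO.** A toy DAG (250 terms, depth ≤ 5) of disjoint subtrees under a
  single root; genes annotate to leaves of a home subtree and one
  subtree's genes are 5× over-represented in a planted study list.

Everything flows from one seeded `numpy` generator; identical
configuration and seed give byte-identical outputs (asserted per run via
manifest checksums).

What passing on these data does **not** show: robustness to annotation
error, alignment error, assembly fragmentation, unequal family sizes,
correlated gene loss, batch structure in the RNA-seq design, or ontology
releases with multiple namespaces — none of which the generator emulates.

## Orthology classification

Similarity scores are abstract (any symmetric table; the synthetic path
uses negative p-distance), so real-data users can plug in BLAST-like
scores.  The synteny criterion is operationalised as: among the up-to-`w`
nearest neighbours on either side of a gene (so ≤ 2w genes), at least one
must have a reciprocal-best partner within `w` positions of the focal
gene's partner (`w = 5`; both the window and the support threshold are
configurable).  The original method's synteny test is not quantitatively
published, so this window rule is a stand-in and labelled as such.
Criterion 3 avoids gene-tree inference: among tied same-species
candidates, the copy whose distances to third species best mirror the
partner's wins; losers and all extra copies in multi-copy components are
demoted to inparalogues (conservative — some true orthologues may land in
the inparalogue class, which matches the known behaviour of strict
criteria).  Genes with similarity but no resolvable template are reported
as inparalogues with a null template rather than births.

## Silent branch lengths

4-fold degenerate columns require degeneracy in **every** sequence
(strict intersection) so that a column's degeneracy class cannot differ
between species.  Distances use the JC correction; pairs at p ≥ 3/4 are
flagged saturated and dropped from fitting.  Branch lengths come from
non-negative least squares on the fixed topology with Fitch–Margoliash
1/d² weights (plain OLS is available); NNLS is deterministic and exactly
reproduces additive inputs.  Whether the original study fitted silent
lengths by ML or otherwise is unstated; this choice is documented rather
than claimed equivalent.

## Ka/Ks and the phylogenomic filter

NG86 with all minimal substitution pathways enumerated per codon pair,
pathways through stops excluded (if every pathway passes through a stop,
all are used rather than dropping the codon), site counts averaged over
the two sequences, JC correction of both proportions, ratio undefined at
Ks = 0.  The filter applies its four criteria in order and logs the first
failure: (1) no inparalogues anywhere in the group; (2) no member pair
against the designated reference member with Ka/Ks > 1; (3) members
> 200 aa unless all are within five residues of each other; (4) every
member within 1.5 MAD of the median length.  The MAD is floored at one
residue: otherwise a group of near-identical lengths (MAD = 0) would be
rejected by any 1-residue deviation, which inverts the criterion's
intent.

## Branch rates and association

Expected counts are fitted per event class over the branches where the
class is defined (originations on internal branches, inparalogue classes
on terminals, selection wherever flags exist), so excesses sum to zero
within each class.  "Disproportionate" is formalised as upper/lower
Poisson tails at the fitted expectation — an addition; the original
presentation was graphical.  Percentages are rounded half-even to two
decimals.  The shared-response overlap test returns the standard Pearson
chi-square on the implied 2×2 (df = 1).  Note the worked-example counts
(123 shared, 702 and 681 single-species, 10,443 total) give expected
63.5 and fold 1.94, but a printed chi-square of 12.4 for that table is
not reproducible by the standard formula (which gives ≈ 65.5); this
implementation returns the standard statistic and makes no guess at the
original computation.

## GO sets

Lin similarity was chosen for the edge weights because it is bounded in
[0, 1], standard, and computable on parent–child edges (where the parent
is the pair's most informative common ancestor); an ancestor-Jaccard
weighting is available behind a switch.  Louvain runs seeded with a fixed
node order, so partitions are reproducible byte-for-byte; subsets come
from re-running Louvain inside each set.  Set/subset counts depend on the
ontology release, the weighting and the seed, so they are checked as
properties (mutual exclusivity, coverage, modularity optimality on small
graphs) rather than as numbers.  Zero-annotation terms take a 0.5
pseudo-count for IC.  Labels are the name of the member term with the
largest closed annotation count, ties to the smallest id.

## Heat response

The inclusion filter is strict (> 50 reads summed over all 24 samples).
TMM follows the standard recipe (reference = sample with upper quartile
closest to the mean; 30%/5% two-tailed trims on M and A;
inverse-variance weights; factors normalised to geometric mean 1) and was
cross-checked against the Bioconductor implementation to 6 decimals.
log2cpm uses a 0.5 pseudo-count on TMM-effective library sizes.  The DE
test is a two-sample t per post-control time point with the gene's pooled
within-group variance (all 8 time points, df 16) shrunk toward the mean
gene-wise variance with a fixed prior df of 4 — a deliberate
simplification of precision-weight/batch-correction pipelines, since the
synthetic data have no batch structure to correct.  BH is applied jointly
across all gene × time tests (per-time-point scope available).  The
"≥ 2 time points" rule is sign-free: two qualifying time points of
opposite sign count.  Fuzzy c-means uses m = 2, tolerance 1e-6, best of 5
restarts, clusters renumbered by centroid values for stable output; the
objective is asserted non-increasing every iteration.  The partition
coefficient (mean squared membership) selects c over 4..20, ties to the
smaller c.  Core genes require membership > 0.5; genes whose maximum
membership is ≤ 0.5 are reported unclustered.

## Problem sizes in tests

The recovery studies run at deliberately modest sizes chosen as the
package's own desk-scale defaults: ~1,000 planted originations × 20 seeds
for excess detection; 200 families × 300 codons × 5 replicate
simulations (estimates averaged over replicates, since a single short
internal edge of length 0.05–0.08 carries ~6% sampling noise at that
alignment size) for branch-length recovery; 20 seeds of the full
filter → TMM → DE → standardise → select-c path for cluster-number
recovery; 1,000-gene simulations for DE error rates.

## Known limitations

- The synteny rule and the distance-based sister test are stand-ins for
  a richer published method; on real data with tandem arrays or
  assembly-fragmented scaffolds they will under-call orthologues.
- Silent lengths assume the JC correction is adequate at the simulated
  depths; beyond p ≈ 0.6 the estimator degrades quickly.
- The DE test is a moderated t on log2cpm, not a count model; at very low
  counts a negative-binomial GLM would behave better.
- Selection calls are consumed as flags (or planted); no branch-site
  likelihood machinery is included.
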