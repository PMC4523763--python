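# Methods

This note documents the models, conventions and numerical choices behind
`stenobarcode`, roughly in pipeline order.

## Distances

**Site classification.** Sequences are encoded over {A, C, G, T}; gaps,
N and IUPAC ambiguity codes are treated as missing data at that site.
A mismatch is a *transition* if it stays within purines (A↔G) or
pyrimidines (C↔T), otherwise a *transversion*.

**Deletion policies.** *Pairwise deletion* excludes, per pair, only the
sites missing in that pair. *Partial deletion* (the default, coverage
cutoff 0.95) first computes one alignment-wide mask keeping columns whose
fraction of non-missing states across all sequences is at least the
cutoff, then applies pairwise exclusion within the retained columns. The
cutoff follows the convention of mainstream distance software; both
policies coincide on gap-free alignments. The coverage comparison uses a
1e-12 tolerance so that, e.g., 19/20 rows present passes a 0.95 cutoff
exactly.

**Models.** With transition proportion `P = n_ts/L` and transversion
proportion `Q = n_tv/L`:

- p-distance: `d = P + Q`
- K2P: `d = -1/2·ln(1-2P-Q) - 1/4·ln(1-2Q)`

K2P corrects for multiple hits and therefore always dominates the
p-distance; at low divergence the two agree to first order. Saturated
pairs (`1-2P-Q ≤ 0` or `1-2Q ≤ 0`) and pairs with no shared sites are
recorded as NaN with a warning — flagged, never silently zero, and never
fatal to the rest of the matrix.

**Bootstrap standard errors.** Alignment columns (of the
partial-deletion-retained alignment) are resampled with replacement B
times (default 500); every pairwise distance is recomputed on each
pseudoreplicate and the SE is the standard deviation (ddof = 1) across
replicates in which the pair is defined. Resampling is global (one
column sample per replicate, shared by all pairs), so replicate matrices
are internally consistent. Undefined replicates are excluded per pair; a
pair undefined in every replicate gets a NaN SE.

**Units.** All computation is in substitutions/site; the reporting layer
(combined-table writer, bundled published matrices) uses percent with one
decimal, matching how such tables are printed. `DistanceMatrix` carries
its units and converts explicitly — nothing guesses.

## Bundled published matrices

The package ships the published 12-specimen *COI* matrices (K2P upper
triangle, p-distance lower triangle, percent, one decimal) with their
bootstrap SEs, the specimen table (label, region, ingroup/outgroup), and
the Italian-region set (all sampled regions except Cyprus and the Alborz
Mountains). One printed K2P SE (Barbarano–Frosinone, "0.17" where every
other SE has one decimal) is anomalous; it is stored as printed and
flagged in `coi_fixture_notes.json` rather than corrected by guesswork.
Region membership is data (a text file), not code.

## Composition screen

GC-content `(G+C)/(A+C+G+T)` and GC-skew `(G−C)/(G+C)` are computed over
unambiguous bases only. The skew orientation `(G−C)/(G+C)` reproduces
the negative *COI* skews of the deposited strands. Outgroups are
compared against the ingroup min–max range per statistic; a value
outside the range is flagged "above"/"below" with the range attached. A
single-member ingroup degenerates to a point range, so any difference is
flagged — the report is advisory, not a filter.

## Barcoding gap and delimitation

Gap detection works on the exact sorted distinct distances of the upper
triangle, not on histogram bins (the histogram, default bin width 1
percentage point, exists only for plotting). Every interval between
consecutive distinct values is a candidate; candidates are ranked by
width, ties broken by the smaller lower endpoint. Undefined entries are
excluded.

Delimitation takes the connected components of the graph linking pairs
with `d ≤ threshold` (single linkage — the natural rule for barcode
clusters, since a chain of small distances should not be split;
complete linkage is available behind a flag). The threshold for a gap is
the gap's **lower endpoint, inclusive**: the largest observed distance
below the gap must itself be intraspecific under that gap. With single
linkage the inclusive and exclusive rules give identical partitions on
the bundled matrices; inclusive is used and documented. Cluster ids are
assigned by the matrix position of each cluster's first member, so
partitions are deterministic. Undefined entries are treated as
above-threshold with a warning. Region-stratified counts count clusters
with at least one member sampled in the region set.

## Surrogate phylogeny and dating

The published analysis this pipeline mirrors used ML and Bayesian
inference with model selection, and a Bayesian relaxed (random local)
clock for dating. Those stages are deliberately replaced here by a
distance-based surrogate — the package's claim is the delimitation
analysis, not the reproduction of any particular tree figure or
posterior date. Published relaxed-clock node ages are treated as
qualitative context only.

**Neighbor joining** is implemented directly (classic Q-matrix
agglomeration) so that tie-breaking is deterministic: the first minimal
Q entry in cluster-creation order (initially label order) wins. Negative
branch-length estimates, possible on non-additive input, are clamped to
zero with a warning reporting the count. On additive (tree-derived)
matrices NJ provably recovers the generating tree; the tests assert
exact recovery up to 8 taxa.

**Rooting.** Midpoint rooting places the root at the middle of the
longest tip-to-tip path (after collapsing any degree-2 seed node, which
otherwise misleads placement when path lengths tie). Outgroup rooting
roots on the edge whose bipartition exactly separates outgroups from
ingroup; if no such edge exists the edge misclassifying the fewest tips
is chosen deterministically, with a warning.

**Ultrametricization.** Each internal node's height is the mean of the
path lengths from that node to its subtended tips (a per-node
least-squares fit of a clock, computed bottom-up with tip counts as
weights); tips sit at height 0. Violations of child < parent are
projected to `max(children) + 1e-12` with a warning. An ultrametric tree
is a fixed point.

**Strict clock.** Ages are `height / rate` with rate default 0.0016
substitutions/site/Ma (SD 0.0010) — an arthropod nuclear-rRNA estimate
adopted for want of a centipede-specific rate. Uncertainty intervals are
the 2.5–97.5 percentiles of `height / r` over 1000 seeded draws of `r`
from a normal truncated at zero. The root-age prior (200 ± 50 Ma) is
used only as a plausibility check: a warning fires if the estimated root
age leaves mean ± 3 SD. This is not a Bayesian analysis and does not
attempt to match relaxed-clock posteriors; differences of tens of Ma
against a random-local-clock analysis are plausible and are not asserted
anywhere.

## Simulators

**Yule trees.** Pure birth: with k lineages the next split arrives after
Exp(k·λ) and a uniform lineage splits. The n-tip tree is observed during
the wait before the (n+1)-th birth (tips are extended by one further
Exp(n·λ) draw), so the expected root age is `(1/λ)·Σ_{k=2..n} 1/k` —
the quantity the Monte-Carlo test checks. Default λ = 0.04/Ma with 10
tips gives root ages around 45–50 Ma, i.e. heights around 0.07–0.08
substitutions/site at the default rate: deep enough to be informative,
shallow enough to avoid saturation.

**Sequence evolution.** The root sequence is uniform over {A,C,G,T};
along each branch of duration t the expected divergence is
`clock_rate·t` and each site draws its fate from the exact K2P
transition probabilities (κ = 4 by default, a typical
transition/transversion rate ratio for mitochondrial coding data;
L = 5000 so that distance noise ~√(d/L) is small relative to the 20%
recovery tolerance used in the end-to-end test). No indels and no
among-site rate variation are simulated — real barcodes have both, so
passing recovery tests demonstrates correctness of the estimators under
their own model, not robustness to model violation.

**Planted partitions.** Within-species distances are i.i.d. uniform on
(0, a) and between-species distances on (b, c) with a < b (defaults
a = 1%, b = 10%, c = 28%, mimicking the bimodal shape of the observed
distribution). Such matrices need not satisfy the triangle inequality;
delimitation is graph-based and does not require metricity, and all
tree-building tests use additive matrices instead. Recovery is
guaranteed whenever the planted band gap exceeds every within-band
spacing, which the defaults ensure with large margin.

## Determinism and problem sizes

Every stochastic component takes a seed (numpy `default_rng`;
scipy truncated normal for rate draws) and reruns of the pipeline with
identical configuration produce byte-identical numeric outputs, which a
test enforces. Monte-Carlo test sizes (50 seeds for estimator bias and
end-to-end clock recovery, 100 for planted partitions, 10 repetitions
for the bootstrap-scaling check, 1000 draws for the Yule expectation)
were chosen so each check's sampling error is several times smaller than
the tolerance it asserts, while the whole suite stays fast.

## Known limitations

- Distances from sequences depend on the alignment given; no alignment
  is computed.
- The gap procedure pins the printed one-decimal distances when run on
  the bundled matrices; unrounded distances could shift gap endpoints
  slightly.
- The NJ + strict-clock stage is exploratory: no support values, no
  rate heterogeneity, no topological uncertainty.
- GMYC/PTP/ABGD-style model-based delimitation is intentionally absent;
  only the zero-frequency-interval + threshold procedure is implemented.
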