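# Methods

This note records the models implemented in `reefpop`, the conventions and
numerical choices behind them, what the synthetic-data generators do and do
not emulate, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Diversity statistics from the folded SFS

The folded site frequency spectrum is the package's central exchange
object: counts η<sub>j</sub> of sites with minor-allele count
j = 1..⌊n/2⌋ over n haploid sequences, plus the total number of surveyed
sites L *including monomorphic sites*, so per-site diversities are
comparable across datasets with different amounts of invariant sequence.

* θ<sub>π</sub> = Σ<sub>j</sub> j(n−j) η<sub>j</sub> / C(n,2) / L. Because
  j(n−j) is symmetric under j → n−j, folding loses nothing and the formula
  is exact (verified in the tests against the mean pairwise Hamming
  distance of explicit haplotype matrices, to 1e-12).
* θ<sub>w</sub> = S / a<sub>n−1</sub> / L with
  a<sub>n−1</sub> = Σ<sub>i<n</sub> 1/i.
* Tajima's D uses the classical 1989 normalization constants and *total*
  (not per-site) π and S; per-site reporting is a display convention only.
  D is undefined for S = 0 and for n < 4 (the normalizing variance
  degenerates); both raise a typed error rather than returning a number.

**Significance of D** is parametric-bootstrap: simulate `nsim` datasets
under a constant-size panmictic coalescent whose per-site scaled mutation
rate 4Nμ equals the *observed* θ<sub>π</sub>, matched n and L, and return
the two-tailed p = 2·min(P(D<sub>sim</sub> ≤ D<sub>obs</sub>),
P(D<sub>sim</sub> ≥ D<sub>obs</sub>)) with the (1+x)/(1+m) correction,
capped at 1. Two-tailed because both strongly negative (expansion-like) and
strongly positive (structure-like) values are scientifically meaningful
departures. The null's locus structure (`n_loci` independent loci) should
match the observed data; the default single locus spanning L maximizes the
genealogical variance of the null and is therefore the conservative choice
when the structure is unknown. Simulated monomorphic datasets are dropped
from the null rather than counted as ties. Test calibration: under a
matched constant-size truth the rejection rate at α = 0.05 sits inside the
exact binomial 99% band (computed in the suite).

## The structured-coalescent simulator

Backward-in-time, continuous-time (exponential racing). Conventions:

* diploid sizes; a lineage pair in a deme of size N coalesces at rate
  1/(2N) per generation;
* each lineage emigrates at total rate m, split uniformly over its
  neighbor set — all other demes (FIM) or the 2–4 lattice neighbors (SST,
  non-toroidal by default with the total emigration rate renormalized over
  the available neighbors; a torus is a constructor flag);
* "Nm migrants" therefore means N·m expected diploid immigrants per deme
  per generation, the fastsimcoal-style convention;
* at T<sub>col</sub> (or T<sub>c</sub> for the panmictic scenario) all
  lineages drop into a single pool of size N<sub>anc</sub>;
* mutations are infinite-sites: Poisson(μ · locus length · branch length)
  per branch, each mutation segregating at the branch's number of sampled
  descendants; loci are independent non-recombining blocks (default 100 bp,
  a RAD-locus-sized unit) and the default rate is μ = 1.93×10⁻⁸ per site
  per generation with a 10-year generation time (metadata only — nothing
  in the machinery depends on calendar units).

The sampled deme for the grid scenarios defaults to cell (4,4), a central
cell of the default 10×10 grid; edge demes have fewer neighbors under the
non-toroidal default, so the choice is exposed in `SampleSpec`.

### Exact event aggregation

A naive event loop spends almost all its time on migration hops of
lineages that sit alone in a deme, and, at high Nm, on meet-and-separate
cycles of lineage pairs. Two *exact* reformulations remove most of this
work (both are validated in-suite against the retained naive loop and
against msprime):

* **Scattered phase.** While every deme holds ≤ 1 lineage no coalescence
  is possible, so the hop sequence is a pure jump chain; the phase duration
  is Gamma(#hops, 1/(k·m)) and needs one draw. The stepping-stone walk is
  still stepped hop by hop (lattice geometry matters), but with a single
  uniform draw per hop; the island model draws the number of hops to the
  next co-occupancy geometrically, since its deme labels are exchangeable.
* **Island meet/separate compression.** From a scattered island state the
  cycle (meet, fail to coalesce, separate) is iid, so the number of failed
  cycles is geometric, the total hop count is negative-binomial (drawn as
  a gamma–Poisson mixture) and the total duration is a gamma sum. The rare
  exits that create triples or two simultaneous pairs are enumerated with
  their exact rates and handled by the general event loop. Migrations of a
  lone island lineage into an empty deme never change the exchangeable
  configuration and are thinned out of the general loop as well.

Because positions after T<sub>col</sub> are irrelevant (everything merges),
aggregated phase durations that overshoot T<sub>col</sub> simply terminate
the structured phase — no interpolation of the walk state is needed, which
is what keeps the aggregation exact.

The hot loops are numba-compiled; a genealogy is returned as its n−1
coalescence events, from which per-frequency-class branch lengths (for SFS
simulation) or full trees (for genotype matrices) are reconstructed.
`_gen_struct_naive` keeps the plain one-event-at-a-time loop as an
in-repository oracle: the suite checks fast-vs-naive distributional
agreement, and compares mean/variance of S and Tajima's D against msprime
(an independent implementation) for the panmictic and island models at
5000 replicates, plus closed forms (E[T₂] = 2N, E[total length] =
4N·a<sub>n−1</sub>, the island-model F<sub>ST</sub> ≈ 1/(1+4Nm)).

## ABC with random forests

* **Priors** (per the three-scenario design): Nm is the product of
  independent uniforms N ~ U[100; 10,000] (integer) and m ~ U[10⁻⁶; 10⁻²],
  rejected to Nm ∈ [10⁻⁴; 100]; T<sub>col</sub> ~ U[100; 1.5×10⁶];
  N<sub>anc</sub> ~ U[100; 10⁵]. The panmictic scenario mirrors these
  ranges (N<sub>mod</sub>, N<sub>anc</sub> ~ U[100; 10⁵],
  T<sub>c</sub> ~ U[100; 1.5×10⁶]) so no model is privileged by prior
  width.
* **Summaries**: the folded SFS normalized by S (shape, decoupled from the
  mutation scale), S itself, θ<sub>π</sub>, θ<sub>w</sub>, Tajima's D, and
  the first two linear-discriminant axes fitted on the table with model
  labels. The same LDA axes are reused for the regression step — a
  deliberate simplification over re-fitting a response-binned projection
  per parameter.
* **Model choice**: a random-forest classifier (default 500 trees; an
  OOB-error-versus-trees curve is exported for choosing the size); the
  reported posterior probability is the plurality vote fraction, a
  monotone proxy for the regression-corrected posterior of the abcRF
  literature — simpler, and sufficient for ranking models.
* **Parameter estimation**: quantile-regression-forest weights (per-tree
  leaf co-membership of the observed vector over the training responses)
  give the weighted median and 2.5/97.5% quantiles; OOB MSE/RMSE quantify
  forest fit. Monomorphic simulated datasets are resampled with fresh
  parameter draws (bounded retries); a constant response collapses the
  posterior to that constant and is flagged.

**Identifiability caveat.** A single-deme sample from a strongly connected
grid (Nm ≳ 5–10) is statistically close to a panmictic population of size
d·N with a size change at T<sub>col</sub> — i.e., to a history inside the
unstructured model's own prior support. In that overlap region the
three-way model choice is uninformative with SFS-type summaries (the OOB
confusion matrix shows exactly where), even though the structured models'
*parameters* (notably Nm) remain well estimated once the structured model
is conditioned on. The acceptance suite exposes both facts deliberately:
OOB error far above chance and factor-2 Nm recovery on one hand, and
NS-preference for high-migration stepping-stone pseudo-observations on the
other.

## Landscape least-cost analysis

Habitat codes {0 land, 1 open sea, 2 seamount, 3 reef} with permeabilities
p<sub>land</sub> = 0 and p<sub>sea</sub> = 1 fixed;
p<sub>reef</sub> ∈ [1, 100] and p<sub>seamount</sub> ∈ [1, p<sub>reef</sub>]
(reef is the focal species' prime habitat, so it is constrained to the
maximum). The cost graph is 8-connected; an edge costs step length (cell
size, ×√2 on diagonals) times the mean of the two cells' *resistances*
(1/permeability). The conductance-mean alternative is available behind a
flag; direction count (4 vs 8) likewise. Distances are Dijkstra shortest
paths (scipy.sparse.csgraph), exact-checked against networkx and against
brute-force simple-path enumeration on small rasters.

**Permeability fitting** maximizes the plain Pearson correlation between
pairwise LC distances and F<sub>ST</sub>/(1−F<sub>ST</sub>) (negative
F<sub>ST</sub> clamped to 0 first; raw F<sub>ST</sub> behind a flag). The
search is a coarse logarithmic grid {1, 2, 5, 10, 20, 50, 100}² under the
ordering constraint, followed by repeated 9×9 zooming between the coarse
neighbors of the optimum down to a 0.01 step (sub-0.1 granularity in the
final pass). Ties prefer the lexicographically smallest pair, so a flat
objective (e.g. no reef on any best path) reports (1, 1) rather than an
arbitrary plateau point. Pearson on the distance vectors (not a Mantel
permutation r) is used as the objective: the argmax is identical for any
monotone-invariant variant and the permutation null is not needed for
optimization.

**Origin map**: for every marine cell c, r(c) = Pearson correlation between
per-site θ<sub>π</sub> and LC(c, site); cells that cannot reach all sites,
or with zero distance variance, are undefined (NaN, written as the nodata
value in ESRI ASCII output). The argmin (most negative r) is the inferred
range-expansion origin, following the expectation that diversity decays
with distance from an expansion origin. At least 3 sites are required —
with 2 the correlation is ±1 everywhere and the map is meaningless, so
that input is rejected rather than mapped. Distances are flat-earth grid
distances in cell units; geo-referenced rasters use the supplied cell size
with no spherical correction (a documented limitation — the synthetic
rasters are abstract).

## Population structure

Hudson's nucleotide F<sub>ST</sub> = 1 − H<sub>w</sub>/H<sub>b</sub>, with
H<sub>w</sub> the average of the two within-population mean pairwise
differences and H<sub>b</sub> the between-population mean pairwise
difference (no small-sample correction terms; the tests use ≥ 10
haplotypes). Slightly negative estimates are reported raw and clamped to 0
only inside the linearization. A Nei-style G<sub>ST</sub> variant is
available. The overall F<sub>ST</sub> over k populations pools the mean
within-population diversity against the mean between-pair diversity
(unweighted means).

Permutation tests move *diploid individuals* (haplotype pairs) between
labels, matching the sampling design; Mantel permutes rows/columns of the
second matrix jointly and is one-sided for positive association (the
isolation-by-distance alternative is directional). Both use the
(1+x)/(1+n) correction, are deterministic given a seed, and are calibrated
in-suite (α = 0.05 rejection inside exact binomial bands; the 4×4 Mantel p
matches exhaustive 4!-enumeration).

## Synthetic data

The generators produce every input the pipeline consumes, as pure
functions of their seeds:

* **Archipelago rasters** (default 60×80): sea background, rectangular
  land masses, disk-shaped reef patches (site cells at patch centers),
  seamount speckle; mutual marine reachability of the returned sites is
  verified, with bounded re-draws.
* **Planted origin**: θ<sub>π,i</sub> = max(0, a − b·LC(origin, site_i) +
  N(0, sd)). The decay is phenomenological (linear + noise), *not* a
  spatially explicit expansion simulation — sufficient for validating the
  origin map, which only assumes a monotone decay. Consequently, passing
  the planted-origin tests says nothing about serial-founder allele
  surfing or any other mechanism of real expansions.
* **Planted isolation by distance**: F<sub>ST,ij</sub> = x/(1+x) with
  x = max(0, c·d<sub>ij</sub> + ε), the exact inverse of the linearization
  used downstream, so noiseless recovery is an identity check.
* Demographic inputs (folded SFS, two-deme genotype matrices) come from
  the coalescent simulator itself.

What the generators do *not* emulate: genotyping error, missing data,
linked loci, reference bias, unequal sample sizes per site, and real
Indo-Pacific geography. Green tests certify the inference machinery on
data satisfying its assumptions, not robustness to those artifacts.

## Problem sizes used by the checks

Chosen once, at desk scale: coalescent closed-form calibration at 20,000
replicates; msprime agreement at 5,000 replicates × 12 loci of 1 kb (9-deme
island model, so the reference implementation stays fast); island-model
F<sub>ST</sub> at 200 replicate sets of 50 loci; the ABC experiment at a
3×1000-row table of 500 × 100 bp loci with 20 pseudo-observations; origin
recovery over 50 noise seeds at sd = 5% of the decay range;
permeability recovery at planted (2, 1.5), (10, 5), (50, 10);
permutation calibration over 200–300 runs of 199 permutations.
`scripts/acceptance.py` re-runs the same experiments at modestly reduced
replicate counts (stated in its JSON output as `n`), all derived from one
command-line seed.

## Known limitations

* No recombination within loci, no selection, no finite-sites mutation.
* The stepping-stone walk is simulated hop-by-hop; very large lattices
  (≫ 10×10) with high migration would be slow.
* The plurality-vote posterior probability is not the abcRF
  regression-corrected posterior; absolute PP values are therefore not
  comparable to abcRF output, though model rankings are.
* The permeability objective assumes a monotone distance–differentiation
  relationship; strong non-equilibrium structure can defeat it.
* Pseudo-haplotype expansion of unphased 012 genotypes randomizes phase;
  allele-frequency-based statistics (everything used here) are unaffected,
  but haplotype-structure statistics would be invalid.
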