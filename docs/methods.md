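# Methods

This note documents the statistical models, algorithms and design choices
behind `diffnet`, what the synthetic-study generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Differential expression and the signature filter

Counts are library-size normalized before testing. The default is the
median-of-ratios method: with reference profile
rᵍ = geometric mean of gene g across samples (over genes positive in every
sample), the size factor of sample j is median_g(c_gj / r_g). CPM (column
totals scaled to 10⁶) is available as a lighter alternative. An all-zero
sample, or the absence of any everywhere-positive gene for median-of-ratios,
is an error rather than a silent fallback.

Two self-contained per-gene tests are provided, rather than a wrapper
around an external DE package, because the pipeline must also run on
abundance matrices that are not integer counts:

- **welch_log** (default): Welch's unequal-variance t on log₂(x + c). When
  both groups have zero variance the t statistic is undefined; the p-value
  is then set by separation (1 if the group means agree, 0 otherwise).
- **permutation** (the reference test): two-sided label permutation of the
  mean log₂ difference. All C(n, n_b) label splits are enumerated when
  there are at most 2000 (the p-value is then exact, with the observed
  split counted in the numerator); otherwise Monte-Carlo with add-one
  smoothing, seeded.

Fold changes are log₂((mean_b + c)/(mean_a + c)) with pseudocount c = 0.5
(configurable); the pseudocount keeps zero-mean genes finite and shrinks
fold changes of barely expressed genes.

The signature keeps genes with |fold change| strictly greater than 2.0 and
raw p < 0.05, and when several contrasts are configured a gene must pass in
*all* of them. Raw p is used in the filter (Benjamini–Hochberg adjusted
values are reported alongside in the DE table) — the filter is a screening
rule, not an inference claim. Both thresholds are configurable; the fold
bound is strict, so an exactly 2.0-fold gene is excluded.

## Consensus NMF subtype discovery

Factorization is Frobenius NMF by multiplicative updates from random
non-negative initializations (uniform, scaled to the data mean), tolerance
1e-6 on the relative objective decrease, at most 2000 iterations. The
objective is non-increasing per update, which the tests assert directly. A
sample's hard label is the argmax metagene of its H column.

Consensus clustering at a given K runs the factorization `n_runs` times
with seeds spawned from a master seed; the consensus matrix is the average
connectivity (fraction of runs co-clustering each sample pair), symmetric
with unit diagonal by construction. Final labels come from average-linkage
hierarchical clustering of 1 − consensus cut at K — "average connectivity"
makes average linkage the natural choice — and the stability score is the
cophenetic correlation between 1 − consensus and the dendrogram's
cophenetic distances. When those distances are degenerate (a perfectly
binary consensus collapses all within/between distances to 0/1), the
correlation is defined as 1 if the dendrogram reproduces the distances
exactly, else 0.

K is selected by maximizing cophenetic correlation over a candidate range,
ties toward the smaller K; per-K consensus matrices are exportable so the
usual heatmap inspection remains possible. The pipeline clusters the
tumor-condition samples only (subtypes are a property of the tumors, and
the tumor/reference contrast would otherwise dominate the factorization),
falling back to all samples when fewer than four tumor samples exist.
Signature rows are scaled to unit maximum before factorization so
high-abundance genes do not dominate.

The run count is a cost dial, not a result dial: 1000 runs is the pipeline
default; tests and the acceptance script use 100–200 runs, which the
planted-block experiments show is already stable at the problem sizes used
(tens of genes × ~10 samples).

## FI networks and subtraction

The reference interactome is an attributed undirected protein graph. Edge
identity is (unordered endpoint pair, provenance), where provenance is
`pathway` (curated) or `predicted` (classifier-derived); direction and an
effect class (activation, expression regulation, catalysis, inhibition,
unknown) are carried as annotations. Duplicate edges merge; conflicting
annotations on the same pair+provenance are kept as parallel variants. All
symbols are upper-cased and passed through a small alias table
(Lyk→LCK, PDGFR→PDGFRB, BCR-ABL→ABL1, Yes→YES1, c-KIT→KIT, …) with raw
spellings preserved; "Lyk" is reproduced in the Dasatinib record as the
catalogs print it and aliased to LCK, which is the kinase that informal
name denotes.

A condition network is the subgraph induced on the condition's altered
genes (genes missing from the interactome are counted and reported, not
errors; an empty induced network is an error). Subtraction of two condition
networks induced from the same reference (enforced by checksum) is pure set
algebra on edge keys: unique-to-A, unique-to-B, shared. Direction and
effect are deliberately ignored in matching — subtraction compares
topology, not annotation — with strict-attribute matching available. With
two tumor conditions the pipeline induces one network per condition from
its own contrast; with a single tumor condition it splits the signature by
fold-change sign (up-network vs down-network).

## Modules, enrichment, GSEA

Community detection is Girvan–Newman: repeatedly remove the edge of
maximal edge-betweenness (recomputed after each removal, Brandes, raw
pair-count convention), collecting a candidate partition whenever a
component splits. Ties in edge-betweenness (within 1e-9) are broken toward
the lexicographically smallest sorted edge, which makes the removal
dendrogram deterministic. The default cut maximizes Newman–Girvan
modularity over the candidates, with the initial connected-component
partition included as the Q ≥ 0 baseline so graphs without a
positive-modularity split stay unsplit; a fixed module count is available
for figure-style layouts. Disconnected inputs are allowed — components seed
the initial partition.

Module enrichment is the hypergeometric upper tail P(X ≥ k) for overlap k
between a module (size n) and a gene set (size K) in a stated universe
(size N). The universe is explicit everywhere — the pipeline default is all
profiled genes, and the signature itself can be used instead. BH adjustment
runs within each module by default (globally across modules as an option);
defaults flag module pathways at FDR < 0.001 and differential pathways at
FDR < 0.0001, with 0.05 for GO-style screens. Note that BH adjusted
p-values are *not* a fixed point of the procedure: re-adjusting adjusted
values inflates them (only the cumulative-minimum monotone envelope is
idempotent), so adjusted values are computed exactly once from raw p.
DAVID's EASE-score variant (which decrements the overlap by one) is
intentionally not reproduced.

The enrichment map has significant sets as nodes (size attribute = member
count), connected by parent→child edges when a set hierarchy is supplied,
otherwise by overlap coefficient |A∩B|/min(|A|,|B|) at a 0.5 cutoff.

Preranked GSEA is the classic weighted running sum: walking the ranked
list, in-set genes add |score|^p (p = 1 default) normalized by the in-set
total, others subtract 1/(N−K); ES is the maximum deviation from zero. A
set covering the whole list has no miss steps and ES ≡ 1. The null
permutes gene labels (random same-size subsets) — appropriate for a
preranked list, where no sample phenotypes are available to permute — with
NES = ES / mean |null ES| of the same sign and the standard NES-based FDR.
Sets with fewer than two usable members are skipped with a warning.

## Centrality and drug scoring

Node betweenness is stored in both the raw pair-count convention
(Σ_{s<t} σ_st(v)/σ_st — "the number of shortest paths that cross the
node") and normalized by (n−1)(n−2)/2; ranking uses the raw value, ties
broken by higher degree then symbol order. The top-n ranked nodes (default
18) are flagged bottlenecks; hubs have degree at or above the 0.9 empirical
quantile (an absolute degree threshold is available). Centrality runs on
the case condition network by default and is additionally emitted for the
case-unique differential subgraph.

The drug score is a deliberate formalization of "multi-target drugs
covering central proteins win": restrict the drug→target table to network
proteins (drugs with no in-network target drop out), then
score(d) = w_b·n_bottleneck + w_h·n_hub + w_m·n_member with default weights
(3, 2, 1), each covered target counted once in its highest-weight role.
The score is monotone in coverage and invariant to uniform weight scaling;
ties break toward more covered targets, then drug id. The weights are not
fitted to anything — the justification is the planted-recovery experiment,
where the planted multi-target drug ranks first against 49 decoys in 100
of 100 seeds. No drug catalog is bundled beyond the 8-target Dasatinib
record; tables are user-supplied or synthetic.

## Limiting-dilution analysis

The single-hit model: an injection of d cells forms a tumor with
probability 1 − e^(−f·d), f the per-cell frequency of tumor-initiating
cells. The log-likelihood over dose rows is concave in f, so the score
equation has a unique root, found by bracketed root-finding; the single-dose
case has the closed form f = −ln(1 − k/n)/d, which the optimizer reproduces
to 1e-10. Confidence intervals are 95% profile likelihood (χ²₁ cutoff
3.841), preferred to Wald for boundary robustness. Degenerate data are
flagged, not errored: all-negative gives f = 0 with the closed-form upper
bound 1.92/Σ(nᵢdᵢ); all-positive gives a lower bound only with the
estimate pinned at 1. Estimates are invariant to splitting dose rows into
replicates with the same totals.

Comparison of two experiments reports the frequency ratio with a
delta-method CI on the log scale (standard errors from the observed
information) and a likelihood-ratio test of the shared-frequency null over
the pooled rows. A zero-frequency denominator yields a lower-bound fold
against the denominator's upper confidence limit.

## The synthetic study

The generator emulates the *design* of a two-condition tumor profiling
study with planted, recoverable structure; each sub-generator draws from
its own seeded RNG stream so inputs can be regenerated independently.

- **Counts**: negative binomial with a log-normal baseline
  (log-mean ln 150, log-sd 1.0) and shared dispersion 0.1 — typical
  moderate RNA-seq overdispersion. The first 120 of 600 genes are
  differential between the reference and tumor conditions at ±2 log₂ units
  (first half up, second half down); at 6 samples per condition this puts
  the signature filter's recovery near 100%, i.e. the study is powered the
  way a designed experiment would be. Up-genes are divided into 3 subtype
  blocks boosted by 1.5 log₂ units in the samples (round-robin assignment)
  carrying that subtype.
- **Interactome**: 3 planted communities of 8 nodes drawn from the
  up-regulated genes (spanning cycle plus within-community edges at
  probability 0.9), joined *only* through explicitly inserted bridge nodes
  (default 2), each wired to 3 anchors on both sides of one community pair.
  Because all inter-community shortest paths cross a bridge, bridges are
  articulation points with the strictly largest betweenness — the
  bottleneck ground truth is unambiguous, which a degree-matched rewiring
  model would not give. A sparse background component over the
  down-regulated and nearby non-differential genes makes the reference
  cover genes outside the planted modules. Edge attributes are sampled
  (70% pathway, 50% directed, effects uniform over the directed classes).
- **Gene sets**: one exact set per planted community under a common parent
  set, plus size-matched decoys drawn uniformly from the gene universe.
- **Drugs**: one planted multi-target drug covering 4 bridge/hub nodes of
  the case network, 49 decoy drugs with 1–3 uniform targets, and the
  Dasatinib record (Fyn, Yes, Src, Lyk, BCR-ABL, EphA2, PDGFR, c-KIT —
  verbatim catalog spellings, normalized on load).
- **Limiting dilution**: binomial takes at doses 10⁶…10³ cells with 10
  injections per dose, case frequency 10⁻³ vs reference 10⁻⁶ (a planted
  1000-fold difference).

What it does **not** emulate — and hence what passing tests do not show
about real data: batch effects and library-composition artifacts;
gene–gene correlation beyond the planted blocks; hub-dominated scale-free
interactome topology (real bottlenecks are rarely clean articulation
points); incomplete and biased pathway annotation; drug catalogs with
correlated target profiles; and tumor latency or size in the dilution
assays (outcomes are binary takes).

## Reproducibility and numerics

Every stochastic component takes an explicit seed; the pipeline manifest
records a config hash (excluding the output directory), input checksums and
per-stage counts, and two runs with the same seed produce identical
manifests up to timestamps. Floating-point tie tolerance in Girvan–Newman
is 1e-9; permutation-test comparisons use a 1e-12 slack so ties count as
exceedances; NMF uses an epsilon of 1e-10 in the multiplicative updates to
avoid division by zero. Profile-likelihood brackets expand geometrically
until they straddle the root.

## Known limitations

- Girvan–Newman recomputes all-pairs betweenness per removal, O(|E|²|V|)
  overall: fine for signature-scale networks (tens to a few hundred nodes),
  not for genome-scale graphs.
- The welch_log test is a pragmatic default, not a count model; for deep
  RNA-seq designs a dedicated negative-binomial DE engine is preferable,
  and the permutation test is the in-package reference.
- GSEA FDR uses the standard NES-pooling heuristic, which is conservative
  with very few sets.
- Drug scoring is set coverage only: no binding affinities, no
  dose–response modeling, no polypharmacology beyond the target list.
- Transcript-level (isoform) analysis is out of scope; the pipeline starts
  from a gene-level count matrix.
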