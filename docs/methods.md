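# Methods

This note documents the models and procedures `archdc` implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that affect results.

## The divide-and-conquer procedure

Deep-phylogeny supermatrix analyses face two coupled problems: the markers
shared by all three domains of life are few, and distant outgroups plus
fast-evolving lineages invite long-branch attraction. The divide-and-conquer
response is to build several supermatrices from one curated marker panel,
each with a taxon sampling suited to one question, and to integrate their
branch supports rather than trust any single matrix:

- **A** — all retained families, archaeal taxa only: the richest matrix,
  resolves the unrooted archaeal topology.
- **AE** — universal plus archaea+eucarya families over archaea and
  eukaryotes: places the eukaryotes without bacterial interference.
- **AB** — universal plus archaea+bacteria families over archaea and
  bacteria: roots the archaeal tree with the bacterial outgroup.

The root found on the AB tree is then *transferred* onto the unrooted A
topology: the AB root bipartition, restricted to the archaeal taxa the two
trees share, must occur as a branch of the A tree; the root is placed
there. The transfer refuses to guess when the restricted bipartition is
absent or degenerate — an incompatibility is reported, never silently
resolved.

## Curation

Families whose gene trees conflict with trusted taxonomy are excluded
before concatenation. The screen is a monophyly test: for each group
(e.g. an archaeal order), the group is violated iff no branch of the gene
tree induces a bipartition separating exactly the group's members present
in that tree. A family is *complex* when it violates more than `tolerance`
groups (default 0). This operationalises what is usually a visual
inspection of gene trees for transfers, duplications and losses; it is
deliberately conservative and reproducible. Case-by-case removal of single
transferred sequences is supported through a per-family drop-list in the
pipeline config rather than auto-detection.

Taxon subsampling keeps one strain per species and, per archaeal order,
the `min_per_order` (default 3) species ranked by completeness — the
fraction of retained families containing the taxon — with lexicographic
tie-breaks. Ranking by completeness favours data-rich taxa and makes the
sample deterministic and idempotent; the choice of rule is ours, since
a representative-selection protocol of this kind is rarely specified
exactly.

## Supermatrix construction

Column trimming keeps a column iff its gap+missing fraction is at most
`max_gap_fraction` (default 0.4) and its Shannon entropy over observed
residues is at most `max_entropy` (default 0.7·ln 20 ≈ 2.10 nats). This is
a fully specified stand-in for similarity-matrix trimmers such as BMGE:
the contract (gap share + entropy, column order preserved) is what the
rest of the pipeline relies on, so an external trimmer honouring it can be
substituted. Each subset matrix is re-trimmed on its own taxon sampling —
a column too gappy over 285 taxa may be clean over 218 — which is why the
A, AE and AB matrices are built from the untrimmed families, not from one
master matrix.

Missing data conventions: `?` is the missing character; `X B Z J U O` are
read as missing; `-` is a gap and counts with missing for trimming but is
preserved verbatim. A taxon absent from a family receives a `?` block
across that partition. Partitions are RAxML-style 1-based inclusive ranges
tiling the matrix exactly.

Dayhoff recoding maps the 20 amino acids onto biochemical classes written
as digits `1`…`6`: four classes with cysteine treated as missing
(`dayhoff4`), or six with cysteine its own class (`dayhoff6`). Recoding
commutes with concatenation and is idempotent under the induced identity;
recoded matrices are analysed with an equal-exchangeability k-state model
using the matrix's empirical class frequencies — the simplest defensible
stand-in for a recoded substitution model.

## Slow-Fast desaturation

The Slow-Fast score of column *i* is

    s(i) = Σ_g max(0, |distinct non-missing states of column i within g| − 1)

over predefined, pairwise-disjoint monophyletic groups *g* of 2–7
representatives; taxa not covered by any group contribute nothing (the
packaged 19-group archaeal configuration deliberately leaves Halobacteria
uncovered — their long stem makes them a poor rate witness). Each distinct
extra state within a group certifies at least one substitution regardless
of the within-group topology: s(i) equals the minimum Fitch parsimony
length over all resolved within-group topologies (attained by grouping
identical states) and is a lower bound on the Fitch length of any
particular one. The star-tree counting is classic Slow-Fast practice and
needs no within-group tree.

Desaturation removes the ⌈(1−keep)·L⌉ highest-scoring columns; ties break
by position, higher index removed first, so the step series (default keep
fractions 1.0, 0.9, 0.82, 0.7, 0.6, 0.5) is nested and deterministic.
Steps are labelled `S_<round(100·kept/L)>`. The published protocol states
its steps only by example labels, so the series is a config knob; a
class-threshold mode (drop all columns with s(i) > k) is available as
well. At each step a tree is inferred through the pluggable callback and
every reference branch is re-classified, yielding the support trace.

## Substitution model and inference

Simulation and distance/likelihood computations use the LG empirical
exchangeability matrix with its published stationary frequencies,
normalised so branch lengths are expected substitutions per site.
Across-site rate variation is the standard discrete gamma with four
equal-probability categories represented by their means (shape `alpha`;
`alpha = None` disables it). Transition matrices come from the symmetrised
eigendecomposition of Q, clipped to non-negative and row-renormalised —
cheap, exact to ~1e-14 against `expm`, and cached per model.

The inference stage is deliberately desk-scale. Full Bayesian mixture
(CAT+GTR) and profile-mixture ML (LG+C20) analyses are out of scope; in
their place:

- **ml_distance** maximises the two-sequence log-likelihood
  Σ N_ab log(π_a · mean_c P_c(a→b; t)) by bounded scalar search
  (tolerance 1e-10, cap 10 substitutions/site; capped pairs are flagged
  saturated). In the Poisson/no-gamma special case it reproduces the
  closed form −(19/20)·ln(1 − (20/19)p) to 1e-6.
- **nj** is Saitou–Nei neighbor joining with a first-minimum (row-major)
  tie-break and negative branch estimates clamped to zero, so output is
  invariant to input order up to topology and fully deterministic.
- **bootstrap_support** resamples columns with replacement (default 100
  replicates), rebuilds distance+NJ trees, and supports each original
  bipartition by its replicate frequency.
- **pruning_loglik** is Felsenstein's algorithm over unique column
  patterns with gamma-category averaging; missing tips contribute
  likelihood one. It matches brute-force state summation to 1e-8 on
  small instances.
- **estimate_alpha** is a bounded golden-section search of the pruning
  likelihood in alpha ∈ [0.05, 20] at fixed topology.
- **nni_search** (optional) is a greedy nearest-neighbour-interchange
  hill-climb on the pruning likelihood, keeping branch lengths.

Any external engine can replace these through the `matrix → tree with
supports` callback used by the desaturation series and the pipeline.

## Support integration

Supports are normalised to [0, 1] on input (values above 1 are read as
percentages), so posterior probabilities and bootstrap percentages share
one scale with thresholds 0.95 / 95%. Branch calls across analyses use
bipartitions restricted to shared taxa: *supported* when the restricted
reference bipartition occurs in the test tree (support = that branch's
value), *conflicting* otherwise, with the conflict support defined as the
maximum support among test-tree bipartitions incompatible with the
reference (four-intersection test). Taking the maximum is the conservative
reading of "alternative branching" support — it makes weak-conflict calls
as hard as possible. Branches with fewer than four shared taxa are
*absent*: no quartet, no signal. The four categories are green / light
green / light red / red as defined in the README.

`maxdiff` between two tree samples is the largest absolute difference in
bipartition frequencies; below 0.3 the samples are considered to agree.
The pipeline config carries a burn-in default of 1,500 trees for ingesting
external MCMC samples.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes:
a rooted species tree whose ingroup root splits cluster I from cluster II
(stems of `cluster_split_depth`/2, default 0.3/2 each); a bacterial
outgroup on a long stem (default 0.8 substitutions/site); eukaryotes
nested as sister to cluster I (the Asgard-like position, stem 0.5);
archaeal orders built as subtrees so they are monophyletic by
construction; an optional fast "nano" clade with all branches scaled by a
rate multiplier (long-branch bait); families in the four presence classes
with full occupancy within their domains; per-family HGT events that
re-evolve one taxon's sequence from inside a donor clade; and optional
second strains glued next to their species-mates.

Branch lengths are drawn as floor + Exp(mean) with floor 0.01 and mean
0.05 substitutions/site. The floor keeps every internal branch long enough
(≈ 20 expected substitutions at 2,000 columns) that the generating
topology is identifiable — a recovery benchmark against trees with
effectively zero-length branches would measure the random tie-breaking of
the inference, not its accuracy. All randomness flows from one master
seed, with per-family streams derived via `SeedSequence`, so datasets are
byte-reproducible.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: compositional heterogeneity across
lineages and sites (no CAT-like profiles), heterotachy and covarion
behaviour, indel processes (gaps appear only by explicit injection),
alignment error (sequences are generated aligned), model misspecification
(data are simulated under the same LG+G4 family used for inference), and
incomplete lineage sorting. Clean-simulation results are best-case floors:
they validate the machinery, not the biology.

## Numerical choices and degenerate inputs

- Distance optimisation bounds (1e-9, 10); pairs at the cap are flagged,
  and identical sequences short-circuit to 0.
- NJ requires ≥3 taxa; a symmetric, zero-diagonal, non-negative matrix is
  enforced.
- Zero-length branches are legal everywhere (P(0) = I); negative lengths
  are errors in both simulation and likelihood code.
- Site-rate ties and desaturation use a fixed total order (score
  descending, index descending), making step sets nested.
- The desaturation ceiling subtracts 1e-9 before rounding up to absorb
  float slop (0.18 × 100 → 18, not 19).
- Groups with fewer than two members present are skipped by the monophyly
  screen but are an error for site-rate estimation (a one-member group
  cannot witness a substitution).
- Support values are formatted with 4 significant digits on write;
  round-trips preserve them to that precision.

## Problem sizes

The test suite and acceptance script run everything at sizes a laptop
handles in minutes: 10–21 taxa and 100–2,000 columns for simulations,
50 seeds for topology recovery, 40 bootstrap replicates inside the
desaturation series, exhaustive oracle checks up to 8 leaves (10,395
topologies) for monophyly and 6 leaves for compatibility and Fitch
parsimony. These sizes are the package's own validation design: large
enough for the statistical claims being checked, small enough to run
everywhere.

## Known limitations

- The screen's sensitivity to HGT depends on divergence; very recent
  transfers inside a donor clade close to the recipient can evade it.
- NJ+bootstrap is a stand-in: on real saturated matrices its supports are
  not comparable to CAT+GTR posteriors, which is precisely why the
  inference stage is a callback.
- The entropy trimmer ignores residue similarity (D↔E costs as much as
  D↔W); BMGE-style smoothing would keep more conservative columns.
- `maxdiff` here compares any two tree samples; it does not implement
  chain management (burn-in/thinning are the caller's responsibility,
  with config defaults provided).
- Printed position counts of real matrices (e.g. 16,006 amino acids for a
  218-taxon archaeal matrix) depend on database versions and the exact
  trimmer and are not reproduction targets; the composition counts
  (families, taxa) are.
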