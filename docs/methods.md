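# Methods

This note documents the models and procedures implemented in
`tiratlas`, the parameters that matter and why their defaults were
chosen, what the synthetic benchmarks demonstrate, and the package's
known limitations.

## Search engine

### Scoring model

The discovery engine is a position-specific scoring model (PSSM) with
affine gap costs, not a full Plan7 profile HMM. This preserves every
behavior the iterative-search procedure depends on — profile
broadening, E-thresholded envelopes, boundary calling — at desk scale,
with far simpler and fully inspectable scoring. The `iterate_search` /
`scan_database` contracts are engine-agnostic, so an external
profile-HMM engine can be substituted behind the same interface.

Match scores, in bits, for residue *a* at column *c*:

    score(a, c) = log2( (W·f_c(a) + α·p(a)) / ((W + α)·p(a)) )

where `f_c` are weighted observed frequencies under position-based
(Henikoff-style) sequence weights with total weight `W`, `α` is the
pseudocount weight (default 1), and `p` the bundled 20-letter
background composition. The weights are deliberately left
unnormalized per sequence so that duplicating every row of an
alignment leaves the profile unchanged. Columns with gap fraction
above 0.5 are excluded from the match model. Gap penalties default to
open 11 / extend 1 bits — conventional protein-search values, made
explicit because nothing in the procedure pins them.

The alignment dynamic programming runs through Biopython's C
`PairwiseAligner`: the profile's columns are encoded as a custom
alphabet and the L×20 score table as a substitution matrix, so the
optimal local alignment is exactly the PSSM optimum at C speed.

### E-value calibration

Optimal local scores of a profile against random sequences follow an
extreme-value (Gumbel) law. Each profile is calibrated by scoring ≥ 100
background-composition decoys (defaults: 200 decoys of 400 residues)
and fitting a Gumbel by maximum likelihood; with location μ and scale
β, λ = 1/β and K = e^{λμ}/(m·n) gives

    E(S) = K · m · N · e^{−λS}

with m the profile length and N the total residue count of the scanned
database. The reporting threshold `E ≤ 10⁻³` is applied inclusively;
the same threshold is reused as the inclusion threshold during
iteration (the procedure distinguishes them in principle; both are
exposed as parameters). The calibration is Monte-Carlo-validated in
the tests: on a fresh decoy database, the number of records passing
`E ≤ 1` is ≈ 1.

### Envelopes, overlap resolution, iteration

The envelope of a hit is the target interval of the optimal local
alignment; additional non-overlapping envelopes per target come from
iterated optimal-subalignment extraction (re-scan of the flanking
segments). Overlapping domain calls on one target are resolved
greedily by decreasing envelope length, with ties broken by lower
E-value, then lower start, then profile id — a total order, so the
output is independent of input row order; the greedy output is checked
exhaustively against an independent longest-first oracle on all small
instances.

Iteration per seed: accepted envelopes are stacked by their
profile-aligned coordinates (target insertions dropped, deletions
gapped — no MSA recomputation inside the loop), the profile is rebuilt
and recalibrated, and the database rescanned. New hits must pass the E
threshold, a minimum envelope length (default 50 residues), and the
fold gate when one is supplied. Two envelopes on the same record count
as the same domain when they overlap reciprocally by ≥ 50%. Stopping:
at least two scans per seed, then stop when a scan yields no new
domains, or when every new candidate was vetoed by the fold gate.
Accepted sets are nested across iterations, so termination is
guaranteed in a finite database. Seeds run in a fixed order; after all
seeds saturate, every accepted record is rescanned with all final
profiles and the union of calls is overlap-resolved and trimmed to its
envelope(s).

## Tree stage

The package does not reimplement external aligners or ML tree
inference; it ingests their outputs at atlas scale. For hermetic runs
it provides:

* **Profile-anchored MSA** (pipeline default): each accepted domain is
  stacked on the profile that called it; each profile's columns are
  mapped onto the profile with the most assigned records via a global
  alignment of consensus sequences. Within a family the alignment
  quality is that of the profile model; across families the mapping is
  crude but consistent per family, which is what p-distance trees
  need. A simpler single-template stacking (`stack_alignment`) is kept
  for small ad-hoc uses.
* **Trimming**: a column is kept iff its fraction of non-gap residues
  is ≥ gt (defaults 0.10 and 0.20, the two atlas trim levels).
* **Neighbor joining** on p-distances (pairwise deletion). Tie-breaks
  in the Q criterion are lexicographic on leaf ids; negative branch
  estimates are clamped to 0 with the deficit moved to the sibling
  edge. NJ exactly reconstructs trees from their additive matrices
  (verified on random trees up to 16 leaves, and cross-checked against
  scikit-bio's independent NJ implementation).
* **Bootstrap supports**: columns resampled with replacement, NJ per
  replicate, support of each internal branch of the point tree = the
  percentage of replicates containing the same bipartition (canonical
  orientation via the lexicographically smallest taxon).

The four atlas tree variants (two aligners × two trim levels) are
realized hermetically as two trim levels × two bootstrap seeds; real
runs may point the variant slots at externally produced Newick files.

## Consensus clades

Per tree, a supported clade is an internal node with support strictly
greater than `min_support` (default 70 on the 0–100 scale) and at
least `min_size` descendants (atlas default 100; desk profile 8).
Trees are rooted on an outgroup when one is given; otherwise each
split contributes its smaller side (logged fallback) — necessary
because an arbitrary NJ rooting can fall inside a family.

Candidates are the union of supported clades across trees. A candidate
is "found" in another tree when its best-match supported clade there
(max Jaccard; ties to higher support, then smaller clade, then
lexicographic members) has Jaccard ≥ `j_min` (default 0.5 — the
matching rule is a package choice, exposed as a parameter). A
candidate survives when found in ≥ `min_trees` of the trees, counting
its own source tree. Members are pruned unless they sit inside the
matched clade in ≥ `min_trees` trees; clades retaining strictly more
than `min_retained` members (atlas 20; desk 5) are reported, sorted by
retained size, with nesting relations recorded and an optional
disjoint post-filter. Both nested-inclusive and disjoint outputs are
available because robust clades genuinely nest. Every reported clade
is re-verified in the tests by an independent per-leaf recount over
the input trees.

## PD downsampling

Phylogenetic diversity of a leaf subset is the branch length of the
minimal spanning subtree, in the unrooted convention (the root edge is
never charged; singletons score 0). Greedy selection — seed with a
maximal-distance leaf pair (double-sweep diameter), then repeatedly
add the leaf with the largest PD increment, ties to the smaller id —
attains the exact optimum for every k (verified against exhaustive
enumeration on hundreds of small trees). Group downsampling applies
per-group caps (eukaryote budget 1000; per-family prokaryote budget
100) with exempt groups passed through.

## Fold gate

Secondary structure is assigned from backbone φ/ψ dihedrals by
Ramachandran-region classification (helix: φ ∈ [−100°, −30°],
ψ ∈ [−80°, −5°]; strand: φ ∈ [−170°, −70°], ψ ∈ [90°, 180°] ∪
[−180°, −170°]; else coil), with single-residue islands smoothed.
This is deliberately simpler than hydrogen-bond-based assignment:
dependency-free and sufficient for counting elements on predicted
models; externally produced {H,E,C} strings are accepted on equal
footing. Elements are maximal runs meeting per-type minimum lengths
(helix 4, strand 3 — the assigner's own floor; whether the original
visual assessment used one is unknowable, so both are parameters). The
verdict is a pure lower-bound count rule: pass iff ≥ 4 helices and
≥ 3 strands of the expected (5, 5); "sheets" is read as strand
elements since the fold's five strands form a single sheet, and extra
elements never cause failure. No alternation or sheet-topology test is
applied; parallel-vs-antiparallel discrimination and loop extensions
are out of scope.

## Gain/loss

Dollo mode imposes a single origin — the natural model for a
horizontally transferred gene family — at the MRCA of the present
species; a branch below the origin is a loss iff its subtree contains
no present species while its parent's does. This loss set is minimal
(certified against brute-force search over all loss placements on
small trees). Count-parsimony mode relaxes single-origin: a Sankoff DP
over copy-number states 0..max_count (bounded at 10) with unit cost
per ±1 change labels internal nodes at minimal total cost; ties
resolve toward later (leafward) events by preferring the child state
closest to its parent, then the smaller state. Duplications are the
positive increment units minus the single origin unit (counted on a
virtual absent stem above the root); losses are the decrement units.
Parsimony counts are lower bounds on the true event count: equality
holds when planted losses are phylogenetically independent and do not
sever the MRCA of the survivors, and both behaviors are asserted in
the tests. The distinction between observed losses (pseudogenes) and
inferred losses is an input annotation, not inferred.

## Synthetic data: what it emulates, and what it does not

The generator plants a known truth behind every pipeline stage. The
desk profile — the study condition used by the test suite and the
acceptance script — is 6 families × 40 members, 120-residue domains,
substitution rate 0.15/site per unit branch, indel rate 0.01/site
(geometric lengths, mean 2), intra-family branch lengths U(0.05, 0.25)
versus fixed inter-family branches of 5.0 (≥ 5× the intra mean),
flanks of 30–60 residues, 600 decoys. A single root ancestor is
evolved down the whole tree, so families are remote homologs of one
another (as domain superfamilies are) at roughly twilight-zone
inter-family identity, while intra-family identity stays near 80–90% —
the regime where iterative search, consensus clades and PD selection
are all exercised but not trivially. Substitutions use uniform
replacement over the 19 alternatives (no rate matrix): the pipeline
nowhere assumes a substitution model, so nested divergence is all that
is required. Decoys are residue-shuffled copies of embedded records,
preserving composition so the E-value calibration is tested honestly.

What passing these benchmarks does **not** show: real proteomes have
biased composition, repeats and low-complexity tracts; real domain
families have rate heterogeneity, structure-constrained indels and
family sizes far from uniform; real trees come from ML inference with
model selection, not NJ on p-distances. Atlas-scale figures from real
databases (thousands of domains, specific clade counts) depend on
those inputs and on stochastic tree inference, and are out of reach of
a hermetic benchmark by design — the tests certify the *rules*
(thresholds, stopping, pruning, minimality, optimality), not
real-data recall.

## Numerical and design notes

* Coordinates are 1-based inclusive at every interface; algorithms
  convert internally.
* All randomness flows through `numpy` Generators seeded from a master
  seed via `SeedSequence` substreams (kept below 2³¹); a fixed config
  is byte-reproducible end to end, and the pipeline embeds a config
  hash in every output header.
* Strict versus inclusive thresholds follow their sources exactly:
  support > 70 (strict), clade size ≥ 100 (inclusive), retained > 20
  (strict), fold counts ≥ 4 / ≥ 3 (inclusive), `E ≤ 10⁻³` (inclusive).
* NJ floating-point caveat: the Q matrix is symmetric only to the last
  ulp, so tie detection canonicalizes index pairs before applying the
  lexicographic tie-break.
* Degenerate inputs: all-gap alignment columns drop from profiles
  (error if none remain); an all-absent presence vector has no origin
  and errors; bootstrap replicates that lose all comparable columns
  for some pair are skipped with the support denominator unchanged.
* Problem sizes in the default test run (desk profile, 50 bootstrap
  replicates, oracle suites on trees of ≤ 16 leaves) were chosen so the
  whole suite certifies every rule at exhaustive-oracle fidelity while
  staying desk-scale; all sizes are parameters.

## Known limitations

* The PSSM engine is not score-compatible with HMMER; E-values agree
  in law, not in digits.
* The profile-anchored MSA is a stand-in: between-family columns are
  only as good as one consensus-consensus alignment.
* Percent identity depends on alignment parameters (BLOSUM62, open
  11, extend 1, identity over mutually ungapped columns); printed
  identities from other tools will differ by convention.
* Dollo reconstruction cannot recover losses that sever the origin
  MRCA (it reports the smaller origin instead, by construction).
* Single-chain, N/CA/C-only structure handling; no altlocs, insertion
  codes, or multi-chain complexes.
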