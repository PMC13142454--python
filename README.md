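# tiratlas

Building blocks for cross-kingdom protein-domain atlases, built around
the Toll/interleukin-1 receptor (TIR) domain — an ancient immune module
shared by animals, plants, amoebae, bacteria and archaea. Cataloguing a
domain family across the whole tree of life means finding extremely
diverged homologs, deciding which groupings are robust, and tracing how
families are gained, duplicated and lost. `tiratlas` implements that
computational pipeline as a tested, reusable library:

* **Iterative profile search with saturation stopping.** A
  position-specific scoring model (PSSM, log-odds
  `log2((W·f_c(a) + α·p(a)) / ((W+α)·p(a)))` with position-based
  sequence weights) is built from a seed alignment, scanned against a
  protein database with affine-gap local alignment, and calibrated
  against composition-matched shuffled decoys so scores map to E-values
  via the extreme-value law `E(S) = K·m·n·e^(−λS)`. Hits at
  `E ≤ 10⁻³` are folded back into the profile and the scan repeats
  until saturation: at least two iterations per seed, stopping when a
  scan finds no new domains or when every new candidate fails the
  structural gate. Multiple seeds run in a fixed order; a final
  boundary pass rescans with all profiles and resolves overlapping
  domain calls by keeping the longest envelope.
* **Phylogenetic-diversity (PD) downsampling.** Greedy max-PD subset
  selection (provably optimal for PD on trees) reduces over-sampled
  groups to fixed budgets — non-exempt eukaryote groups to 1000
  sequences, per-family prokaryote sets to 100 — while exempt groups
  (Metazoa, Amoebozoa by default) pass through untouched.
* **A desk-scale tree engine.** Gap-threshold column trimming
  (keep a column iff its non-gap fraction ≥ gt), p-distances with
  pairwise deletion, neighbor joining with deterministic tie-breaks,
  and classical nonparametric bootstrap supports. Production atlases
  would use an external ML tree program; this engine makes the whole
  pipeline runnable and testable hermetically.
* **Cross-tree consensus clades.** Over replicate trees (e.g. 2 trim
  levels × 2 bootstrap seeds), a clade counts as robust when a
  supported version of it (support > 70, ≥ 100 members at atlas scale)
  appears in ≥ 3 of 4 trees (best-match Jaccard ≥ 0.5); members lacking
  3-of-4 co-support are pruned, and only clades retaining > 20 members
  are reported. Leaves outside every reported clade are listed as
  unassigned.
* **Structure-topology fold gate.** The TIR fold is five α-helices
  wrapping five β-strands. Candidate backbones (minimal N/CA/C PDB) are
  assigned secondary structure from φ/ψ dihedrals; a candidate passes
  with ≥ 4 helices and ≥ 3 strands of the expected (5, 5).
* **Gain/loss reconstruction.** Dollo parsimony (single origin at the
  MRCA of present species, minimal losses below it) from
  presence/absence, and Sankoff count parsimony (unit cost per ±1 copy
  change) for duplication/loss counts from per-species gene counts.
* **A synthetic-data generator with planted truth.** Divergent domain
  families evolved along a simulated tree, embedded in host proteins
  between random flanks, plus residue-shuffled decoys; species trees
  with planted origins/losses/duplications; idealized backbones of
  prescribed α/β topology. Every downstream claim in the test suite is
  scored against this planted truth.

## Worked example

Run the bundled desk profile — 6 planted domain families × 40 members
embedded in host proteins, 600 shuffled decoys — end to end:

```bash
tiratlas run --simulate --seed 1 --out atlas_run
cat atlas_run/summary.tsv
```

```
# config_hash=684296a02305 seed=1
database_records	840
planted_domains	240
domain_hits	240
planted_recovered	240
decoy_hits	0
reported_clades	13
unassigned_leaves	0
fold_pass	240/240
gainloss_famA	losses=0
gainloss_famB	losses=1
gainloss_famC	losses=2
```

Reading this: the iterative search recovered all 240 planted domains
with zero false positives among 600 decoys; the four tree variants
agreed on 13 consensus clades (the 6 planted families, each recovered
exactly, plus their nested sub/super-groupings, with nesting recorded
in `clades.tsv`); every accepted domain passed the 4-helix/3-strand
fold gate; and the three simulated gene-family histories were
reconstructed with exactly their planted loss counts (0, 1 and 2
independent losses). `collector_curve.tsv` holds the per-seed,
per-iteration new-hit counts (the collector's curve of searches), and
`hits.tsv` the domain envelopes in 1-based inclusive coordinates.

Individual stages are exposed as subcommands (`simulate`, `search`,
`trim`, `identity`, `tree`, `downsample`, `clades`, `foldcheck`,
`gainloss`) and as plain library functions.

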