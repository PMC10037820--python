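# Methods

## Coordinate system: the focal lineage

All ages are indices into the focal species' lineage, built by walking
the taxonomy's parent chain from the focal taxid to the root: level 1
is the species, level N the root. A subject taxon's *divergence level*
is the smallest lineage index whose clade contains it — the lowest
common ancestor with the focal species in lineage coordinates. This
assumes the lineage levels are monophyletic; known non-monophyletic
levels (e.g. a contested subkingdom) are removed by explicit name
exclusion (`--exclude-level`), never auto-detected.

Taxonomies are read from local files only: NCBI-taxdump-dialect
`nodes.dmp`/`names.dmp` (scientific names only) or a 4-column TSV.
Validation enforces exactly one root, resolvable parents and acyclic
chains; merged/deleted-node remapping is out of scope.

### Level collapsing

Public databases represent some clades by a handful of stray proteins
rather than genomes; keeping such levels manufactures phantom gene-loss
patterns. A level is retained only if at least one species diverging
at it matches **strictly more than 10 %** of the query proteome (the
denominator is all query genes, not only age-assignable ones — the
stricter reading; fractions come from the filtered hit table itself).
Level 1 and level N are always retained, including against explicit
exclusion: removing the focal species or the root would break the
coordinate system. Retained levels are renumbered contiguously;
because the divergence-level lookup takes the youngest *retained*
containing clade, hits to a collapsed ring migrate to the next older
retained level, which is the intended merge. Collapsing is idempotent.

## Hit ingestion

Tab-separated `outfmt 6`-style tables with configurable column
positions for (qseqid, sseqid, evalue, bitscore, staxids). Filtering
is by e-value only, **inclusive** (e ≤ E_thr, default 1e−5): aligner
thresholds report hits at or below the given value, and the choice is
recorded in `run_metadata.json`. e-value 0.0 (underflow) is the
strongest possible hit. Semicolon-separated taxid cells expand to one
record per taxid; malformed lines are counted, never fatal; there is
deliberately **no per-query hit cap** — a ranked top-k cap can cover at
most k subject species and silently discards exactly the distant
evidence this method needs. Genes with zero surviving records
(including self-matches lost to a stringent threshold) get status
`absent`. Six-frame protein-vs-genome hits, when given, merge as a
tagged union with protein hits and count identically toward ages and
representativeness; duplicated (query, subject) pairs across sources
are kept as distinct records, since deduplication rules across search
modes have no principled basis.

## Age, representativeness, flagging

Per gene: the set of divergence levels of its hits; age k = the
maximum; RP = |levels ∩ {2..k}|; L = 100·RP/(k−1). Level k itself
always counts toward RP (it carries the age-defining hit), giving the
scale minimum 100/(k−1). For k = 1 the formula is undefined and L is
set to 100: presence in the focal species is self-confirming. Genes
with L strictly below the 30 % default are `flagged` (putative
contamination, horizontal transfer or false positives) but stay in the
output with their k and L so users can re-threshold. The best distant
hit at level k is reported with deterministic tie-breaking: highest
bitscore, then smallest e-value, then lexicographic subject id.

## Family clustering and dating

The all-vs-all similarity graph has edge weight
w(u,v) = min(−log₁₀ e, 200) using the best e-value of the two
directions (MCL needs a symmetric matrix; the cap handles underflowed
e-values). Markov clustering is implemented directly on dense
matrices, per connected component, with canonical lexicographic vertex
order: self-loops at each vertex's maximum incident weight (1.0 for
isolated vertices), column normalization, expansion by squaring,
entrywise inflation (default 2.0), pruning below 1e−6, convergence at
max-entry change < 1e−8, at most 100 iterations (non-convergence
yields the current hard clustering plus a warning). Clusters are read
from the limit matrix: attractors are vertices with positive
self-flow; attractor systems join only through attractor-to-attractor
flow; every vertex joins the system receiving its largest total flow,
ties (to 1e−9) to the system containing the lexicographically smallest
attractor. The result is a deterministic partition invariant under
vertex relabeling.

A family's founder age is the maximum age over members with status
`assigned` — flagged members never set it, since their deep hits are
precisely the evidence being distrusted. All-flagged families are
unassigned. Per-level founder-event counts are family counts, not gene
counts.

## Homology detection failure

Model: per gene, the best bitscore in a species at distance d is
S(d) ~ Normal(μ(d), (c·μ(d))²) with μ(d) = a·e^(−r·d). The fit
minimizes the plain sum of squared residuals with bounds a > 0, r ≥ 0
(scipy trust-region reflective), deterministically initialized at
a₀ = max S and r₀ = log-ratio of the scores at the distance extremes,
clipped to ≥ 0. The relative noise scale c is the RMS of
(S − μ)/μ. At least 3 points are required (2 parameters + noise);
all-equal distances leave r unidentifiable (`degenerate`). Both
conditions propagate to verdict `untestable`. This relative-noise
Gaussian is a concrete, testable parameterization of the
bitscore-decay null; it is not claimed to be bit-compatible with other
decay-based tools.

Decay points are the per-species best bitscores restricted to the
distance table; distance tables sample several genomes per taxonomic
level, and such replicated-distance designs are exactly what makes the
two-parameter exponential well conditioned under unweighted least
squares (a classic two-support design; the simulator reproduces this
structure).

The detectability threshold is S_thr = log₂(m·n/E_thr) (Karlin–Altschul
with the pipeline's own e-value threshold; m = query length, n =
database size in residues; a fixed `--s-thr` overrides). The HDF
probability for the nearest species beyond the assigned level (ties by
taxid) is p = Φ((S_thr − μ(d*))/(c·μ(d*))); with c = 0 it degenerates
to a step function. p is monotonically non-decreasing in d*. The
verdict is `high_confidence` iff p < α (default 0.05, strict),
`untestable` when no sampled species diverges deeper than k — the
test's reach is bounded by the distance table's taxonomic sampling.

A family founder event is high confidence iff at least one member is
itself high confidence **and** that member's age equals the family
founder age; a confident young member cannot vouch for a deeper
founder. Consequently the filtered founder profile is bounded above by
the raw profile at every level.

## Simulator

`founder-sim` emulates the generative picture the pipeline assumes: a
ladder taxonomy (default 7 levels, 2 species per level ring, per-level
distances 0.1 → 1.8 substitutions/site on a mildly accelerating grid),
30 families of 1–4 genes with a uniform birth-level distribution,
per-gene a ~ LogNormal(ln 150, 0.3) bits and r ~ Gamma(2, 0.4), 5 %
relative score noise, and a 5 % per-(gene, ring) loss rate. Hits are
emitted iff the realized score clears S_thr (≈ 58.5 bits at the
defaults), with e-values back-computed from E = m·n·2^(−S), so the
files are exactly self-consistent with the HDF threshold transform.
Within-family self-hit e-values are uniform in exponent between 1e−30
and 1e−80; cross-family pairs get none, so family recovery is
identifiable by construction. Contaminant genes (off by default) hit
only the focal species and one ring drawn from levels ≥ 5, producing
the planted two-ring pattern with closed-form L = 100/(k−1) ≤ 25.

`noiseless_config()` is the exact-recovery regime (c = 0, no loss, no
contamination, r ~ Gamma(2, 0.03), a around 200 bits): every homolog
inside the birth clade clears the threshold, so the pipeline must
recover every birth level exactly and score L = 100 everywhere.

What the simulator does **not** emulate: sequences themselves (no
alignment is run; scores are drawn, not computed), rate variation
along lineages, correlated losses, database redundancy, annotation
error (genome-mode hits are not simulated), or non-ladder topologies.
Passing tests on simulated data therefore validate the pipeline's
bookkeeping and statistics under its own model assumptions, not the
biological accuracy of any particular age assignment.

## Problem sizes and determinism

Default test/demo datasets are tens of families over 7 levels — small
enough that every stage is exact and the whole suite runs in seconds,
while still exercising collapsing, flagging, clustering and the HDF
sampling limit. All randomness flows through a single seed
(`numpy.random.default_rng`); identical config and inputs produce
byte-identical output files (sorted tables, fixed float formats).

## Known limitations

- The representativeness score assumes ladder-like (monophyletic)
  levels; violations must be handled by explicit level exclusion.
- The HDF noise model is the relative-noise Gaussian described above;
  other decay-based tools parameterize noise differently, so p-values
  are comparable in spirit, not in bits.
- Whether a level's support should count genome-mode-only matches is
  unsettled; both are counted here (logged in the output metadata
  through the merged source tags).
- MCL granularity depends on inflation; 2.0 is the conventional
  default, not a fitted value.
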