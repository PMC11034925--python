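# Methods

`cnekit` re-implements, at desk scale, a teleost-centric comparative-genomics
workflow for conserved noncoding elements (CNEs): detect elements de novo
from two focal pairwise genome alignments, search them across a genome
panel, infer the ancestral teleost repertoire and date each element's
origin, profile their genomic clustering, associate them with candidate
target genes through orthology-guided synteny, cluster duplicated elements,
and use universal single-copy elements as phylogenomic markers. Every stage
is exercised end to end on a bundled genome-evolution simulator with full
ground truth. This note records the models, the parameters that matter, and
the design choices made where the design was genuinely open.

## The detection model

A CNE here is a reference-genome segment of at least `min_length` bp (default
100) whose alignment to a second, distantly related genome keeps at least
`min_identity` (default 70%) identity in every position of a sliding window
of `window` alignment columns (default 100). The scan runs over netted
pairwise alignments after removing exonic and repetitive reference
positions, and elements seen more than `max_hits` times (default 4) in
either genome of the pair are discarded as repeat-derived. The boundary is
inclusive: exactly four hits survive.

Choices the recipe leaves open, fixed here:

- **Window identity** counts gap columns as mismatches, and windows never
  span an excluded (exon/repeat) column. Both are the stricter, simpler
  readings; both are config switches (`DetectParams`).
- **Merging**: maximal runs of window-marked reference positions become
  elements; runs separated by even one unmarked base stay separate.
- **Edge refinement** (`DetectParams.edge_trim`, on by default): a
  qualifying 100-bp window that straddles an element boundary marks a few
  tens of neutral flanking bases, because a window that is ~60% inside a
  well-conserved element still clears 70% identity overall. Elements are
  therefore trimmed inward until both terminal 20-column stretches reach the
  identity threshold and the element starts and ends on a match column.
  Disabling the trim recovers the plain marked-run merge (which the
  run-length-encoding oracle tests exercise).

## Alignment, chaining, netting

The built-in aligner is deliberately simple - exact 12-mer seeds on both
strands, ungapped x-drop extension (x-drop 20), minimum block score 30 -
because the simulator is substitution-only and real-data users are expected
to import externally produced AXT (external aligner settings ride along
untouched in `AlignerParams.external_params`). A second alignment round
runs after hard-masking everything the first round covered, so diverged or
duplicated copies hidden behind a better partner get their own chance.

Chaining joins blocks that are collinear on both genomes per (reference
chromosome, query chromosome, strand) group, by maximum-score dynamic
programming with cost `gap_open + per_bp_gap_cost * (ref_gap + query_gap)`
and both-side gaps capped at `max_gap` (defaults 50 / 0.5 / 10 kb; the
upstream recipe delegates these to a library without stating them, so they
are package defaults and config-exposed). Chain scores include the link
costs. Netting then greedily keeps chains by descending score on reference
space not yet covered, slicing partially covered blocks at base resolution;
slivers under 20 bp are dropped rather than kept as shards. Two
consequences worth noting: reference overlap in the net is exactly zero
(asserted on every run), and competing homologies from different query
chromosomes (for example the two post-duplication copies) are arbitrated by
net score, never by pre-trimming.

## Cross-genome search and E-values

The search engine is BLAST-flavoured: exact 6-mer words on both strands,
a two-hit requirement (two non-overlapping word hits on the same diagonal
within 40 bp) before extension, ungapped x-drop extension (x-drop 30), and
a banded gapped x-drop re-extension of HSPs that stop short of the query
ends. Pure single 6-mer seeding is quadratic noise at genome scale; two-hit
seeding loses nothing measurable for the >=100 bp, >=70% identity targets
this pipeline hunts (sensitivity on simulated cohorts is at ceiling).
Best-hit semantics: lowest E-value, then highest score, then leftmost
(chromosome, start); one hit per (query, species) in the presence matrix,
with the count of distinct hit loci recorded alongside for the copy-number
filter and single-copy marker selection. Reference-species cells are filled
from the element's own coordinates without a search.

E-values use ungapped Karlin-Altschul statistics applied to the (possibly
gapped) scores - the standard practical approximation. Lambda solves
`sum p_i p_j exp(lambda s_ij) = 1` by bisection to 1e-9; K uses the lattice
Spitzer-series formula `K = lambda' exp(-2 sigma) / E[S exp(lambda S)]`
with `sigma = sum_k (1/k)[P(S_k >= 0) + E(exp(lambda S_k); S_k < 0)]`,
which reproduces the published ungapped blastn constant for +1/-2
(lambda ~= 1.333, K ~= 0.61). The search length `n` is the target genome's
total sequence length summed over chromosomes. The default acceptance
threshold is E <= 1e-6.

## Ancestry, categories, zones, conservation

Elements detected in one basal teleost clade and found by search in at
least one species of the other basal clade are ancestral teleost elements
(atCNEs). The clade-2-referenced set is deduplicated against the kept
clade-1 set by >= 1 bp overlap, assessed via the element's hit in the
clade-1 reference species first and in any shared species as a fallback;
the clade-1 record wins. Origin categories follow outgroup presence with
vertebrate precedence: any non-gar vertebrate hit -> "vertebrate", else a
gar hit -> "neopterygian", else "3R" (teleost-specific). The partition is
exhaustive and disjoint by construction, so category counts always sum to
the set size.

Loss rates are per-species absences as a percentage of all atCNEs, reported
per category plus the additive total. Zone profiling tiles each reference
chromosome into fixed windows (spec default 500 kb; the simulated-cohort
default is 50 kb, scaled to the simulated chromosome lengths), assigns each
element to the zone containing its start (midpoint assignment is a switch),
counts the terminal partial window as a zone, and classes zones as empty /
novel-3R / novel-neopterygian / vertebrate-containing.

The conservation score is the mean pairwise identity of an element's hit
sequences across all species where it is present - a column-identity
substitute for model-based conservation scoring, which is out of scope.
It is undefined (reported missing) below two species.

## Target association and the bootstrap null

Candidates are all genes whose body lies within `window` (default 1 Mb) of
the element in each species where it is present; distance is the gap to the
gene body (0 for overlap), measured in each species from that species' hit.
Synteny score of an orthogroup = number of species with a member among the
candidates; proximity rank = mean over those species of the member's
1-based rank by increasing distance, with fractional ranks for ties and the
best member per orthogroup per species. Targets: orthogroups passing the
`min_synteny_species` cutoff (default 5) with maximal score, then minimal
rank, all exact ties kept. Targets whose orthogroup is also a target of the
vertebrate reference CNE set are "ancestral", others "novel". The
vertebrate target set is built with the same machinery on the
vertebrate-pair CNEs with a permissive cutoff of 2 species, since only
three outgroup genomes carry them.

The bootstrap null re-labels each associated element using a random gene
subset of its real candidate-list size drawn uniformly without replacement
from the reference species' full gene list, and recounts ancestral labels
over 10,000 replicates (z = (observed - mean)/sd; sd of zero is flagged and
reported as infinite z). Under the null the subset members are
exchangeable, so any synteny/rank selection rule picks a uniformly
distributed member; the implementation therefore realizes each
subset-then-select draw as a single uniform gene draw, which is
distributionally identical (and is checked against full enumeration of the
subset draws on a tiny case). The shuffle calibration relocates every
associated element to a random gene neighbourhood consistently across
species (anchored on gene identity, with a random +-20 kb offset), re-runs
selection and classification, and reports the mean z over three
relocations - one relocation is itself a single binomial draw with unit
z-variance, so a fixed-seed single draw would fail ~5% of the time for no
scientific reason.

## Paralogy clustering

Elements are searched against the element set itself, not the genome, so
repeat contamination cannot fabricate clusters; any above-threshold nonself
hit is an edge candidate (reciprocity is not required). An edge survives
only if the two elements' selected targets are the same gene or annotated
paralogs. Clusters are connected components of surviving edges. Dating
derives each anchoring gene pair's origin structurally: same orthogroup +
annotated paralogs = WGD copies (post-WGD); different orthogroups +
annotated paralogs = older duplicates (pre-WGD). A cluster is pre-WGD if
any anchor pair is, post-WGD if its informative anchors all are, and
"mixed" otherwise (the upstream recipe reports only two classes and leaves
conflicts unaddressed). Clusters from two reference groups are "common"
when their anchor orthogroup sets intersect, one-to-many matches counted
once per pair.

## Phylogenomic markers

Universal single-copy elements are those with exactly one hit locus in
every species of the chosen subset (hit-locus counts come from the search
with best-hit restrictions relaxed, since best-hit-only output masks true
copy number). Two designs are built: including all outgroups, and
teleost-only; the outgroup-inclusive set is necessarily a subset of the
teleost-only set over the shared species. Marker sequences are the hit
coordinates extended to the full query span (using the hit's query
footprint) plus a 50 bp flank, clipped at chromosome ends with gap padding
so columns stay positionally homologous, and reverse-complemented into
marker orientation for minus-strand hits. On substitution-only cohorts the
per-marker sequences are already aligned and are concatenated directly; an
`msa_hook` (FASTA-in/FASTA-out callable) slots in an external aligner for
real data. Columns with more than 50% gaps are trimmed. The built-in tree
estimate is neighbor joining on p-distances with pairwise deletion of
gap/N sites (optional Jukes-Cantor correction); ML inference is
deliberately delegated to external tools. Tree comparison is unrooted
Robinson-Foulds after pruning both trees to their common leaf set.

## Motif scan

A single fixed consensus (default TAATTA, the homeodomain-binding core) is
scanned exactly with IUPAC expansion on both strands; positions where the
forward and reverse-complement patterns coincide (TAATTA is its own reverse
complement) count once. "Centrally positioned" is operationalized as the
occurrence midpoint falling in the middle tercile of the element. PWM
scanning, de novo discovery and database enrichment are out of scope.

## The simulator: what it emulates and what it does not

The simulator is the stand-in for a real multi-gigabase genome panel. Its
defaults define the study conditions:

- **Species and tree** (8 leaves): two basal teleost clades
  (`dre`,`ame`,`phy` and `tru`,`sau`), a gar-like neopterygian outgroup
  (`loc`) and two vertebrate outgroups (`hsa`, `cmi`). Branch lengths put
  both focal pairs at ~1.0 substitutions/site of neutral divergence: deep
  enough that neutral DNA is unalignable (~45% identity) while elements
  stay well above the 70% window threshold.
- **Genome**: 1.2 Mb root genome over 4 chromosomes; 40 genes (3-exon
  bodies, exons at 0.25x the neutral rate); the first two chromosomes carry
  the "ancestral regulatory" developmental loci, the last two carry
  novel-target loci. A whole-genome duplication on the teleost stem copies
  every chromosome and keeps each duplicated locus (a developmental gene
  together with its satellite elements; other genes independently) with
  probability 0.6, giving teleost genomes of ~2.3 Mb.
- **Elements**: 40 "vertebrate"-age elements planted in the root genome
  (including 3 pre-WGD paralogous locus pairs with 2 duplicated elements
  each, the older-duplication analog), 45 "neopterygian"-age elements
  planted in the gar+teleost ancestor, 75 "3R"-age elements planted in the
  teleost ancestor immediately after the WGD. Lengths are uniform on
  400-800 bp; planting is by replacement of feature-free sequence within
  8 kb of a developmental gene (30% of 3R and 15% of neopterygian elements
  near novel-target loci). Rate scales are age-graded - 0.05 / 0.10 / 0.15
  of the neutral rate - which is what makes the observable
  older-more-conserved ordering a planted fact rather than an accident
  (the single shared scale the plainest parameterization would use cannot
  express it). TAATTA is inserted at the center of 20% of elements (element
  sequence is rejection-sampled to contain no background occurrence at
  planting time, and the motif's 6 bp evolve at rate 0 - conserved binding
  core).
- **Structural noise**: whole-element losses at 0.02 per element per
  branch; ~1 inversion per branch (15-50 kb, breakpoints outside
  features); an interspersed repeat family (400 bp consensus, 5% per-copy
  divergence) inserted on terminal branches at 20 copies/Mb with only 70%
  of copies annotated in the repeat BED - the unannotated copies are what
  gives the copy-number filter real work.
- **Determinism**: every branch and event class draws from its own
  seed-derived stream; identical configs produce byte-identical outputs.

Ground truth records per-species element coordinates, age classes, loss
events, paralogous element pairs with origin, and each element's true
target gene.

What the simulator does **not** emulate, hence what passing tests do not
show about real data: indels within alignable sequence (substitution-only
by default, so detection boundaries and supermatrix columns are exact;
`indel_mode` exists but is off for all validation runs), realistic
transposon families and nested repeats, gene gain/loss outside the WGD,
rate variation across lineages or sites beyond the fixed per-feature
scales, assembly artifacts, and genome-scale sequence composition. The
divergence-gain scenario (an ancestral element erased by a burst of neutral
evolution on one branch) exists as `n_diverged` but defaults to 0.

## Validation problem sizes

All quantitative validation is simulation-based, at sizes chosen so the
whole suite runs comfortably on a single CPU: the default cohort above for
the headline recovery metrics (detection bp recall/precision, atCNE recall,
category accuracy, target accuracy, bootstrap z and its shuffle
calibration, conservation ordering, tree recovery); four additional reduced
cohorts (0.4 Mb root genomes, 62 elements) for the multi-seed tree and
ordering checks; and a still smaller cohort, run twice, for byte-identity
determinism. `scripts/acceptance.py` re-runs all of this from scratch and
also recomputes the arithmetic identities among the published headline
counts (category additivity, zone totals, gained-element shares, paralog
cluster shares) through the same bookkeeping code the pipeline uses.

## Known limitations

- The internal aligner and search engine are desk-scale tools; multi-Mb
  mammalian-genome inputs want an external aligner and BLAST, imported via
  AXT and the documented Hit/presence TSV schema.
- Ungapped Karlin-Altschul parameters applied to gapped scores slightly
  mis-state E-values for gap-rich alignments (standard approximation).
- Proximity ranks average only over species where the orthogroup occurs
  near the element; a gene family absent near the element everywhere is
  simply not a candidate.
- With 1 Mb windows on sub-Mb simulated chromosomes, candidate lists span
  whole chromosomes and target selection is driven by proximity rank; this
  is the intended scaled-down regime, not a bug, but it means window-size
  sensitivity is untested at desk scale.
- The conservation score ignores phylogenetic structure (every present
  species pair weighs equally).
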