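# Methods

`metannot` re-implements the bespoke computational stages of a
metagenome annotation pipeline as a tested, modular library. External
bioinformatics tools (gene callers, tRNA/rRNA predictors, profile and
homology searches, an alternative CRISPR finder) are never executed;
their outputs are consumed as standard-format evidence files, and the
package implements everything between them: filtering, detection,
consensus, conflict resolution, assignment rules, and naming.

All coordinates are 1-based closed intervals (GFF3 convention)
throughout; FASTQ/FASTA offsets are converted on ingest.

## Sequence pre-processing

Applied to unassembled reads in this order, with telescoping per-stage
accounting (kept of stage *k* = input of stage *k*+1):

1. **Sanitization** (all inputs, including assembled): IUPAC ambiguity
   codes `RYSWKMBDHVU` become `N`; any other character outside
   `{A,C,G,T,N}` rejects the whole sequence. `U` is treated as
   ambiguous rather than transliterated to `T` because the working
   alphabet is strictly `{A,C,G,T,N}`.
2. **Renaming** (all inputs): sequential tool-safe ids
   (`SEQ_000001` …) with a two-column TSV name map; bijective even for
   duplicate submitted names (duplicates are disambiguated with a
   `#<ordinal>` suffix in the map).
3. **Length pre-filter**: reads shorter than 150 bp are removed
   (strict: 150 bp survives); unassembled 454 reads longer than
   1000 bp are removed.
4. **Quality trimming**: Illumina keeps the longest contiguous
   substring whose every base is ≥ Q13 (leftmost on ties); 454 trims
   both ends while the end base is < Q20 (a deliberately simple
   two-ended trim — the thresholds, not the original trimmer's
   chromatogram logic, are the contract). Trailing `N`s are then
   stripped in all cases.
5. **N-count filter**: more than five `N`s removes the read (strict).
6. **Length post-filter**: the 150-bp minimum again.
7. **Low-complexity filter**: classical symmetric DUST. Each window of
   64 bases (step 1; shorter sequences are one window) is scored
   `10 · Σ_t c_t(c_t−1)/2 / (n_triplets − 1)` over its triplet counts
   `c_t`; windows scoring above level 20 are masked whole. A read is
   removed when the masked fraction reaches `removal_fraction`
   (default 0.5, configurable): masking alone defines no keep/remove
   decision for reads, and removing any read with a single masked
   window would be destructive.
8. **De-replication**: reads bucketed by exact prefix (3 bp for 454,
   5 bp for Illumina); within a bucket a shorter read is a replicate
   of a longer retained read when the prefix-anchored, gap-free
   comparison over the shorter length matches ≥ 95 %. The longest copy
   is retained (equal lengths: lexicographically smallest id). No
   alignment is attempted — the definition is gap-free by design.
9. **454 homopolymer clustering**: each read is homopolymer-compressed
   ("non-tandem" form) and the compressed sequence split into
   consecutive k-mers (default k = 16, trailing partial k-mer
   dropped); identical ordered k-mer lists form one cluster, retaining
   the longest member. Compression is applied before chunking —
   splitting first and compressing each chunk would let a single
   run-length difference shift every later chunk boundary, defeating
   the purpose.

PacBio reads get sanitization, renaming and the 150-bp minimum only;
no quality or replicate-artifact model applies to them. Assembled
sequences skip all read-level filters.

## CRISPR detection (modified-CRT style)

Defaults: repeat length 20–50 bp, spacer length 20–60 bp, mean
spacer:repeat length ratio within [0.6, 2.5], search window 7 bp with
step 1, at least 3 repeats, minimum 70 % all-vs-all repeat identity.
All overridable (CLI flags mirror the parameters).

Detection on one contig (given strand only — arrays are not palindromic
enough for reverse-strand duplication to matter):

1. **Seeding**: at every position, the 7-bp window is searched for an
   exact recurrence at a distance compatible with one repeat plus one
   spacer (40–110 bp by default). Occurrences are chained in both
   directions at legal spacings; upstream chaining matters because a
   seed may first recur late in an array, and boundary placement is far
   more reliable when every exact copy participates.
2. **Boundary refinement**: with occurrences aligned at their seed
   anchors, the repeat window is the contiguous column range
   maximizing Σ(conservation − λ), where conservation is the
   majority-base fraction of a column (N never counts) and λ = 0.70.
   The search may both extend beyond and trim inside the seed frame;
   its length is capped by the maximum repeat length and by the
   inter-occurrence gaps so no implied spacer falls below the minimum.
   For 2-copy alignments a column is either exact or not — nearly
   signal-free — so λ = 0.75 there (exact columns only) and the
   refinement is re-run after re-chaining.
3. **Consensus re-chaining**: the per-column majority consensus is
   searched up- and downstream at legal spacer distances for further
   copies at ≥ 70 % identity, recruiting degenerate copies the exact
   seed missed. A partial copy clipped by a contig end is kept when at
   least 7 of its bases remain, and flagged truncated.
4. **Near-bound re-fit**: when the freely-placed optimum violates a
   repeat/spacer length or ratio bound, boundaries are re-optimized
   under those bounds and the re-fit accepted only if it costs at most
   0.12 score per moved column. A genuinely conserved column with one
   mutated copy costs ~0.03–0.10; a random column costs ≥ 0.2 — so
   framing noise at a parameter edge is repaired while truly
   out-of-bounds arrays stay rejected.
5. **Validation** (re-applied verbatim to every emitted array):
   minimum repeat count; full-repeat and spacer length bounds; ratio of
   mean spacer to mean repeat length; all-vs-all gap-free repeat
   identity over the shorter length with N matching nothing; and
   rejection of near-identical spacers (≥ 70 % pairwise) as spacer
   artifacts. Failures carry one reason code each, checked in that
   order.

External CRISPR predictions are ingested as GFF3 `repeat_region`
records, trusted for their span only. Merging keeps every internal
array and drops any external array overlapping one by ≥ 1 bp.

## RNA merging

tRNA and rRNA predictors are domain-parameterized, so each is run per
domain (bacteria, archaea, eukaryota) upstream; the package merges the
1–3 runs. A locus is same contig, same strand, span overlap ≥ 50 % of
the shorter span (transitively clustered); each locus keeps the highest
score, ties broken bacteria > archaea > eukaryota, then smaller start.
tRNAs and rRNAs never compete with each other: their tool scores are
not comparable. The operation is idempotent and input-order invariant.

## Consensus gene calling

Callers agree on stop codons far more than starts, so a *vote group* is
(contig, strand, 3′-stop coordinate); start disagreement does not split
a group. Translations shorter than 32 aa (stop codon excluded) are
deleted before voting. Competing groups — same strand, overlapping
spans — are resolved by caller majority, ties by the preference order
GeneMark > Prodigal > MetaGeneAnnotator > FragGeneScan; the winning
group's start comes from its most-preferred caller. Non-competing
singletons are retained (union semantics: the majority rule is read as
arbitrating between competing models, not as a quorum requirement).
Opposite-strand overlaps are left alone. Greedy resolution order
(votes, preference, coordinate) makes the outcome deterministic.

Conflicts with other feature types, in order: tRNA-vs-rRNA overlaps
delete the lower-scoring prediction; a CDS fully inside an rRNA is
deleted; a CDS partially overlapping an rRNA (or a CRISPR array) tries
an alternative start — the first in-frame ATG/GTG/TTG strictly past the
blocker, kept only if ≥ 32 aa remain — else is deleted; a CDS
overlapping a tRNA survives alongside it only with a Pfam hit,
otherwise the alternative-start rule applies. Overlap means ≥ 1 bp of
shared span.

Features are lifted back to scaffold coordinates (scaffolds are split
at runs of ≥ 50 N for gene calling; offsets are retained) and receive
locus tags `PREFIX_<d><ssssss><gggg>`: a platform digit (1 assembled,
2 = 454, 3 Illumina, 4 PacBio), a 6-digit sequence ordinal and a
4-digit per-sequence gene ordinal. Fixed widths make uniqueness
structural; exceeding either width is a hard error.

## Functional annotation

- **COG**: RPS-BLAST tabular hits against COG PSSMs; e-value ≤ 0.1
  re-enforced on ingest; unknown COG ids dropped with a warning.
- **Pfam**: HMMER domain-table hits produced under model trusted
  cutoffs (`--cut_tc`), so no score filtering is re-applied.
- Both pass **overlap filtering**: for any two hits whose query spans
  overlap more than half of the shorter *model's* length, the loser by
  bit score → e-value → alignment length → percent identity is
  removed. Elimination runs in descending bit-score order, which makes
  the survivor set a fixed point independent of input order (unordered
  pairwise elimination is not confluent — order had to be pinned).
- **KO/EC**: among ranked protein hits (rank ≤ 5) whose subjects are in
  the KO index, those with ≥ 30 % identity and ≥ 70 % subject coverage
  (subject length from the KO index, since tabular hit formats lack it)
  contribute their KO; all qualifying distinct KOs are kept, in rank
  order. EC numbers are the union of the KO→EC mapping over assigned
  KOs — never assigned independently. The rank-1 subject is retained as
  the gene's top hit regardless of KO eligibility.
- **Scaffold lineage**: if ≥ 30 % (inclusive) of a scaffold's genes
  have a top hit, the lineage is the longest common rank-prefix of the
  hit lineages; otherwise none.
- **Estimated gene copies**: a category's abundance is the sum over its
  genes of the mean read coverage of the carrying sequence (1.0 when
  unknown), correcting for assembly collapsing many reads into one
  contig. Coverage is accepted per input sequence and inherited by
  split contigs.

Evidence files identify proteins by the coordinate key
`contig:start-end:strand` of the consensus CDS: locus tags are assigned
only after conflict resolution, but the tRNA conflict rule already
needs Pfam evidence. Results are reported under the final locus tags.

## Product naming

Four mutually exclusive branches, tried in order, each recorded in a
rule trace: (1) COG name when the hit has ≥ 20 % identity and the
alignment covers ≥ 70 % of the COG consensus length; (2) COG name via
the COG–Pfam correspondence table when the thresholds fail but one of
the gene's Pfams corresponds to the COG; (3) the strongest Pfam's name;
(4) `hypothetical protein`. COG names equal to "uncharacterized
conserved protein" or containing "predicted" (case-insensitive) are
reformatted as `COG name - COG ID`.

## Synthetic data generator

`metannot.fixtures` emits a complete seeded submission: scaffolds built
left-to-right from blocks (random flank, stop-free ORFs on both
strands, CRISPR arrays, rRNA/tRNA loci, random intergenic spacers), one
scaffold with a 60-N gap to exercise splitting; four caller GFFs
derived from the planted genes with per-caller drop (10 %), in-frame
start-shift (20 %) and spurious-call (5 %) perturbations — stops are
never perturbed, mirroring how real callers disagree; per-domain
tRNA/rRNA tables with the true domain scoring highest; COG/Pfam/KO hit
tables whose identities and coverages straddle the assignment
thresholds; small fixed reference tables; a coverage map; and a
ground-truth manifest.

Planted CRISPR arrays draw repeat length, spacer lengths (constrained
so the ratio stays in band), copy number (3–6) and per-copy mutation
rate (0–10 %) uniformly; mutation draws are repeated until the copies
respect the 70 % all-vs-all identity bound the array is claimed to
satisfy. Bound-violation fixtures (2 copies / 19-bp repeat / ratio
2.75) are mutation-free, use repeat units without shifted
self-similarity, and pin the spacer-boundary columns to be pairwise
distinct across copies — otherwise chance conservation or an off-phase
sub-array can make the fixture violate something other than the one
intended bound.

What the generator does *not* emulate: codon usage, GC structure,
genuine rRNA/tRNA sequence content (loci are random sequence placed at
known coordinates; only coordinates and scores matter to the merge
logic), homology-score correlations, or read-level error profiles.
Passing tests therefore demonstrate the correctness of the decision
rules on well-formed evidence, not caller- or search-level accuracy on
real genomes.

## Numerical and procedural choices

- FASTQ is read by a tolerant 4-line reader so a record with mismatched
  sequence/quality lengths is rejected and logged without aborting the
  file; multi-line FASTQ is not supported.
- Degenerate inputs: empty files give empty outputs; a sequence shorter
  than the DUST window is scored as one window; arrays at contig ends
  keep clipped repeat copies flagged truncated.
- Determinism: every tie in every selection rule has an explicit
  deterministic tie-break (documented at each site); reruns on
  identical inputs and config are byte-identical.
- Problem sizes in tests and the acceptance script (200 planted arrays,
  100–500 oracle trials, 5-scaffold end-to-end datasets) are chosen to
  give stable rates while keeping the full suite around a minute.

## Known limitations

- The CRISPR detector is single-strand and seed-exact; arrays whose
  every adjacent copy pair lacks a shared exact 7-mer can only be
  recovered through consensus re-chaining from a neighboring pair.
- Planted arrays whose pairwise repeat identity sits exactly at the
  70 % bound are intrinsically fragile: a one-column framing difference
  legitimately drops them below threshold (~1–3 % of random plants).
- De-replication is quadratic within a prefix bucket; adequate for the
  artifact-removal use case it models, not for arbitrary-scale
  clustering.
- The majority rule arbitrates only same-strand overlaps; convergent
  opposite-strand overlaps are both kept by design.
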