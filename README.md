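# metannot

Structural and functional annotation of metagenomic sequences, built
as a tested, modular re-implementation of the bespoke stages of a
production annotation pipeline. The heavy external tools — *ab initio*
gene callers, tRNA/rRNA predictors, profile and homology searches,
alternative CRISPR finders — are **not** executed; their outputs are
consumed as standard-format evidence files (GFF3, tRNA scanner tables,
HMMER `--tblout`/`--domtblout`, BLAST/USEARCH tabular), and `metannot`
implements everything between them:

- **Pre-processing** of unassembled reads: sanitization to
  `{A,C,G,T,N}`, collision-free renaming with a name map, strict
  length filters (150 bp minimum, 1000 bp maximum for 454), quality
  trimming (longest contiguous ≥ Q13 substring for Illumina, two-ended
  Q20 trim for 454), an N-count filter (> 5 N removes), classical DUST
  low-complexity filtering, prefix-anchored de-replication at 95 %
  identity (3-bp prefix for 454, 5-bp for Illumina), and
  homopolymer-aware 454 clustering.
- **CRISPR array detection**: a from-scratch sliding-window detector
  (7-bp exact seed, step 1) with conservation-driven boundary
  refinement, consensus re-chaining of degenerate copies, truncated
  end-repeat handling, and validation against repeat length 20–50 bp,
  spacer length 20–60 bp, spacer:repeat ratio 0.6–2.5, ≥ 3 repeats at
  ≥ 70 % all-vs-all identity. External predictions are merged in, with
  internal predictions winning overlaps.
- **RNA merging**: per-domain (bacteria/archaea/eukaryota) tRNA and
  rRNA runs collapsed to the best-scoring prediction per locus.
- **Consensus gene calling**: four callers vote by shared stop
  coordinate; majority wins, ties resolved GeneMark > Prodigal >
  MetaGeneAnnotator > FragGeneScan; translations under 32 aa deleted;
  conflicts against rRNA/tRNA/CRISPR features resolved with
  alternative-start rescue; locus tags
  `PREFIX_<platform digit><seq ordinal:06><gene ordinal:04>`.
- **Functional annotation**: COG and Pfam assignment with
  overlap-filtering of competing hits (bit score → e-value → alignment
  length → identity over spans exceeding half the shorter model); KO
  terms from the top 5 ranked hits at ≥ 30 % identity and ≥ 70 %
  subject coverage; EC numbers via the KO→EC mapping; per-scaffold
  last-common-ancestor lineage when ≥ 30 % of genes have hits; and
  coverage-weighted "estimated gene copies" abundances.
- **Product naming**: COG name when identity ≥ 20 % and alignment
  ≥ 70 % of the COG consensus length (vague names reformatted as
  `COG name - COG ID`), COG–Pfam correspondence rescue, Pfam-derived
  names, `hypothetical protein` fall-through — with a per-gene rule
  trace.

A seeded synthetic-data generator (`metannot.fixtures`) produces
complete submissions — sequences with planted genes, CRISPR arrays and
RNA loci, perturbed caller GFFs, evidence tables, reference tables and
a ground-truth manifest — and backs the test suite.

See `docs/methods.md` for the full model description, parameter
rationale, and limitations.

## Worked example

Generate a 3-sequence synthetic submission and annotate it:

```sh
$ metannot fixtures --seed 11 --out demo --contigs 3
fixtures written to demo (3 sequences, seed 11)
$ metannot run --config demo/config.yaml
annotation complete: demo/results
```

`demo/results/features.gff` places every feature on the input
sequences — here the first CDS, then a five-repeat CRISPR array with
its repeat/spacer children:

```
SEQ_000001  genemark    CDS            171  314  .  +  .  ID=GOLD_10000010001;locus_tag=GOLD_10000010001
SEQ_000001  crispr_crt  repeat_region  402  805  .  +  .  ID=GOLD_10000010002;...;n_repeats=5;rpt_family=CRISPR
SEQ_000001  crispr_crt  direct_repeat  402  445  .  +  .  Parent=GOLD_10000010002
SEQ_000001  crispr_crt  spacer         446  503  .  +  .  Parent=GOLD_10000010002
```

`demo/results/annotations.tsv` carries the per-gene assignments and the
product-naming branch that fired:

```
locus_tag         cog      pfams    kos              ecs                top_hit  product               branch
GOLD_10000010001  COG0444                                                        hypothetical protein  hypothetical
GOLD_10000010003           PF01000  K00002,K00001,…  1.1.1.2,1.1.1.1,…  RG0003   RNA_pol_A_bac         pfam_name
```

The first gene has a COG hit that fails both naming thresholds and has
no correspondence-table rescue, so it falls through to `hypothetical
protein`; the second is named from its Pfam domain, and its EC numbers
are the union of the mappings of its assigned KO terms.

`metannot stats demo/results` prints the submission statistics,
recomputed from the artifacts on disk:

```
"features_by_type": { "CDS": 25, "repeat_region": 3, "rRNA": 1, "tRNA": 2, ... }
"genes_per_caller": { "genemark": 24, "prodigal": 24, "mga": 22, "fraggenescan": 21 }
"product_branches": { "cog_name": 9, "pfam_name": 9, "hypothetical": 7 }
```

25 consensus CDS from 21–24 per-caller predictions is the majority
rule at work: most models merge into stop-sharing vote groups, and a
few singleton calls survive alongside.

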