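"""End-to-end orchestration: preprocessing, structural annotation,
functional annotation, statistics.

External tools are never executed; their outputs are consumed as
standard-format evidence files listed in the config. A missing optional
evidence layer (RNA, CRISPR, COG/Pfam/KO hits) disables that layer with
a warning; at least one gene-caller GFF is required. Runs are fully
deterministic: identical inputs and config give byte-identical outputs.

Functional evidence files identify proteins by the coordinate key
``contig:start-end:strand`` of the consensus CDS (the id a caller of
the upstream searches would have used for the candidate protein);
results are reported under the final locus tags.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import consensus as cons
from . import crispr as cr
from . import functional as fn
from . import preprocess as pp
from . import products as pr
from . import rna as rnamod
from . import seqio
from .model import Feature, Platform, SequenceRecord

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration (exit code 1)."""


class DataError(ValueError):
    """Structurally invalid input data (exit code 2)."""


@dataclass
class PipelineConfig:
    fasta: str | None = None
    fastq: str | None = None
    platform: str = "assembled"   # platform of the fastq reads
    coverage: str | None = None
    prefix: str = "GOLD"
    out_dir: str = "results"
    refs_dir: str | None = None
    evidence: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.prefix:
            raise ConfigError("prefix must be nonempty")
        if self.fasta is None and self.fastq is None:
            raise ConfigError("at least one of fasta/fastq inputs is required")
        caller_gffs = self.evidence.get("caller_gffs") or {}
        if not caller_gffs:
            raise ConfigError("at least one gene-caller GFF is required")
        for p in self._all_paths():
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured path does not exist: {p}")

    def _all_paths(self):
        yield self.fasta
        yield self.fastq
        yield self.coverage
        for v in (self.evidence.get("caller_gffs") or {}).values():
            yield v
        for key in ("trna_tables", "rrna_tables"):
            for v in (self.evidence.get(key) or {}).values():
                yield v
        for key in ("external_crispr_gff", "cog_hits", "pfam_hits", "protein_hits"):
            yield self.evidence.get(key)
        if self.refs_dir:
            yield self.refs_dir


def _coord_key(contig_id: str, start: int, end: int, strand: str) -> str:
    return f"{contig_id}:{start}-{end}:{strand}"


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- ingest + rename -----------------------------------------------------
    raw: list[SequenceRecord] = []
    if cfg.fasta:
        raw += seqio.read_sequences(cfg.fasta, "fasta", Platform.ASSEMBLED)
    if cfg.fastq:
        raw += seqio.read_sequences(cfg.fastq, "fastq", Platform(cfg.platform))
    renamed, name_map = seqio.rename_sequences(raw)
    seqio.write_name_map(name_map, out / "name_map.tsv")

    # -- preprocessing -------------------------------------------------------
    assembled = [r for r in renamed if r.platform is Platform.ASSEMBLED]
    reads = [r for r in renamed if r.platform is not Platform.ASSEMBLED]

    survivors: list[SequenceRecord] = []
    report = pp.FilterReport()
    n_reject = 0
    clean_assembled = []
    for r in assembled:
        s = pp.sanitize(r)
        if s is None:
            n_reject += 1
        else:
            clean_assembled.append(s)
    if assembled:
        from collections import Counter

        report.add("sanitize_assembled", len(assembled), n_reject,
                   Counter({"foreign_characters": n_reject} if n_reject else {}))
    survivors += clean_assembled

    if reads:
        platform = Platform(cfg.platform)
        dust = pp.DustParams(**cfg.params.get("dust", {}))
        kept, read_report = pp.preprocess_reads(
            reads, platform, dust_params=dust,
            derep_identity=cfg.params.get("derep_identity", 0.95),
            declust_k=cfg.params.get("declust_k", 16),
        )
        for stage in read_report.stages:
            report.stages.append(stage)
        survivors += kept

    with open(out / "filter_report.json", "w") as fh:
        json.dump(report.as_rows(), fh, indent=1, sort_keys=True)
    with open(out / "filter_report.tsv", "w") as fh:
        fh.write("stage\tinput\tremoved\tkept\treasons\n")
        for row in report.as_rows():
            reasons = ",".join(f"{k}:{v}" for k, v in row["reasons"].items())
            fh.write(f"{row['stage']}\t{row['input']}\t{row['removed']}\t{row['kept']}\t{reasons}\n")
    seqio.write_fasta(survivors, out / "sequences.fna")

    # -- scaffold splitting --------------------------------------------------
    min_gap = cfg.params.get("min_gap", 50)
    contigs, split_map = cons.split_scaffolds(survivors, min_gap=min_gap)
    contig_seqs = {c.id: c.seq for c in contigs}
    seq_platform = {r.id: r.platform for r in survivors}

    # -- CRISPR --------------------------------------------------------------
    crt_params = cr.CrtParams(**cfg.params.get("crt", {}))
    arrays: list = []
    for c in contigs:
        found, _rej = cr.detect_crisprs(c.seq, c.id, crt_params)
        arrays += found
    ext_path = cfg.evidence.get("external_crispr_gff")
    if ext_path:
        ext = cr.external_gff_to_arrays(seqio.read_gff(ext_path))
        arrays = cr.merge_crispr(arrays, ext)
    else:
        arrays = sorted(arrays, key=lambda a: (a.contig_id, a.start))

    # -- RNA evidence --------------------------------------------------------
    rna_preds = []
    for domain, path in sorted((cfg.evidence.get("trna_tables") or {}).items()):
        rna_preds += rnamod.read_trna_table(path, domain)
    for domain, path in sorted((cfg.evidence.get("rrna_tables") or {}).items()):
        rna_preds += rnamod.read_rrna_tblout(path, domain)
    merged_rna = rnamod.merge_domain_runs(rna_preds)
    rnamod.write_rna_tsv(merged_rna, out / "rna_merged.tsv")
    trnas = [p for p in merged_rna if p.rna_type == "tRNA"]
    rrnas = [p for p in merged_rna if p.rna_type != "tRNA"]

    # -- consensus gene calling ---------------------------------------------
    caller_feats: list[Feature] = []
    for caller, path in sorted(cfg.evidence["caller_gffs"].items()):
        caller_feats += seqio.read_gff(path)
    calls = cons.gene_models_from_gff(caller_feats, contig_seqs)
    min_aa = cfg.params.get("min_protein_aa", cons.MIN_PROTEIN_AA)
    preference = cfg.params.get("caller_preference", cons.CALLER_PREFERENCE)
    cds = cons.combine_gene_calls(calls, preference=preference, min_aa=min_aa)

    # -- functional evidence (needed for the tRNA conflict rule) -------------
    cog_hits = pfam_hits = prot_hits = None
    refs = fn.ReferenceTables.from_dir(cfg.refs_dir) if cfg.refs_dir else fn.ReferenceTables()
    if cfg.evidence.get("cog_hits"):
        cog_hits = fn.read_blast_tab(cfg.evidence["cog_hits"])
    if cfg.evidence.get("pfam_hits"):
        pfam_hits = fn.read_domtblout(cfg.evidence["pfam_hits"])
    if cfg.evidence.get("protein_hits"):
        prot_hits = fn.read_blast_tab(cfg.evidence["protein_hits"])
    pfam_positive = set(pfam_hits) if pfam_hits else set()

    # -- conflict resolution -------------------------------------------------
    for m in cds:
        if not m.translation and m.contig_id in contig_seqs:
            m.translation = cons.translate_cds(
                contig_seqs[m.contig_id], m.start, m.end, m.strand
            )
    orig_key = {id(m): _coord_key(m.contig_id, m.start, m.end, m.strand) for m in cds}
    kept_cds, trnas, rrnas = cons.resolve_conflicts(
        cds, trnas, rrnas, arrays, pfam_positive, contig_seqs, min_aa=min_aa
    )

    # -- build features, lift, tag -------------------------------------------
    feats: list[Feature] = []
    key_of_feature: dict[int, str] = {}
    for m in kept_cds:
        f = Feature(
            seqid=m.contig_id, start=m.start, end=m.end, strand=m.strand,
            ftype="CDS", source=m.caller, translation=m.translation,
        )
        key_of_feature[id(f)] = orig_key.get(
            id(m), _coord_key(m.contig_id, m.start, m.end, m.strand)
        )
        feats.append(f)
    for p in trnas:
        feats.append(Feature(seqid=p.contig_id, start=p.start, end=p.end,
                             strand=p.strand, ftype="tRNA", score=p.score,
                             source=p.domain_run, attributes={"product": p.meta}))
    for p in rrnas:
        feats.append(Feature(seqid=p.contig_id, start=p.start, end=p.end,
                             strand=p.strand, ftype="rRNA", score=p.score,
                             source=p.domain_run, attributes={"product": p.rna_type}))
    for arr in arrays:
        feats.append(cr.array_to_feature(arr))

    lifted = cons.lift_to_scaffold(feats, split_map)
    # lift preserves order, so evidence keys can be carried across by position
    for old, new in zip(feats, lifted):
        if id(old) in key_of_feature:
            key_of_feature[id(new)] = key_of_feature[id(old)]

    seq_order = [r.id for r in survivors]
    digits = {r.id: cons.SEQ_TYPE_DIGIT[r.platform] for r in survivors}
    tagged = _assign_tags(lifted, cfg.prefix, digits, seq_order)

    seq_lengths = {r.id: len(r.seq) for r in survivors}
    final_cds = [f for f in tagged if f.ftype == "CDS"]
    seqio.write_gff(tagged, out / "features.gff", seq_lengths=seq_lengths)
    seqio.write_protein_fasta(final_cds, out / "proteins.faa")

    # -- functional annotation ------------------------------------------------
    annotations: list = []
    coverage = seqio.read_coverage(cfg.coverage, known_ids=set(seq_order))
    cog_assign = fn.assign_cogs(cog_hits, refs) if cog_hits else {}
    pfam_assign = fn.assign_pfams(pfam_hits, refs) if pfam_hits else {}
    gene_contig: dict[str, str] = {}
    top_hits: dict[str, str | None] = {}
    for f in final_cds:
        key = key_of_feature.get(id(f), "")
        rec = fn.AnnotationRecord(locus_tag=f.locus_tag)
        gene_contig[f.locus_tag] = f.seqid
        if key in cog_assign:
            rec.cog = cog_assign[key][0]
        if key in pfam_assign:
            rec.pfams = pfam_assign[key]
        if prot_hits and key in prot_hits:
            rec.kos, rec.ecs, rec.top_hit = fn.assign_ko_ec(prot_hits[key], refs)
        top_hits[f.locus_tag] = rec.top_hit
        ctx = pr.NamingContext(
            cog_id=rec.cog[0] if rec.cog else None,
            cog_identity=rec.cog[1].percent_identity if rec.cog else 0.0,
            cog_alignment_length=rec.cog[1].alignment_length if rec.cog else 0,
            pfam_accessions=[acc for acc, _h in rec.pfams],
            cog_meta=refs.cog_meta, pfam_meta=refs.pfam_meta, cog_pfam=refs.cog_pfam,
        )
        rec.product, rec.product_branch = pr.assign_product_name(ctx)
        annotations.append(rec)

    with open(out / "annotations.tsv", "w") as fh:
        fh.write("locus_tag\tcog\tpfams\tkos\tecs\ttop_hit\tproduct\tbranch\n")
        for rec in annotations:
            fh.write(
                f"{rec.locus_tag}\t{rec.cog[0] if rec.cog else ''}\t"
                f"{','.join(a for a, _h in rec.pfams)}\t{','.join(rec.kos)}\t"
                f"{','.join(rec.ecs)}\t{rec.top_hit or ''}\t{rec.product}\t{rec.product_branch}\n"
            )

    # -- lineage + abundance ---------------------------------------------------
    by_scaffold: dict[str, list[str]] = {}
    for f in final_cds:
        by_scaffold.setdefault(f.seqid, []).append(f.locus_tag)
    with open(out / "lineage.tsv", "w") as fh:
        fh.write("scaffold\tn_genes\tn_hits\tlineage\n")
        for scaf in sorted(by_scaffold):
            genes = by_scaffold[scaf]
            lin = fn.scaffold_lineage(genes, top_hits, refs.taxonomy)
            n_hits = sum(1 for g in genes if top_hits.get(g))
            fh.write(f"{scaf}\t{len(genes)}\t{n_hits}\t{';'.join(lin) if lin else ''}\n")

    for group in ("cog", "pfam", "ko"):
        weighted = fn.estimated_gene_copies(annotations, gene_contig, coverage, group)
        raw_counts = fn.estimated_gene_copies(annotations, gene_contig, {}, group)
        with open(out / f"abundance_{group}.tsv", "w") as fh:
            fh.write(f"{group}\tgene_count\testimated_copies\n")
            for cat in sorted(weighted):
                fh.write(f"{cat}\t{raw_counts.get(cat, 0):g}\t{weighted[cat]:g}\n")

    # -- statistics -----------------------------------------------------------
    stats = compute_stats(out, cfg)
    with open(out / "stats.json", "w") as fh:
        json.dump(stats, fh, indent=1, sort_keys=True)
    return out


def _assign_tags(features, prefix, digits: dict[str, int], seq_order: list[str]):
    """Locus tags with a per-sequence platform digit (see consensus module)."""
    if len(seq_order) > 10**6:
        raise ValueError("locus-tag sequence ordinal width exhausted")
    seq_rank = {sid: i + 1 for i, sid in enumerate(seq_order)}
    ordered = sorted(
        features, key=lambda f: (seq_rank.get(f.seqid, 0), f.start, f.end, f.ftype)
    )
    from collections import Counter

    per_seq: Counter = Counter()
    for f in ordered:
        per_seq[f.seqid] += 1
        n = per_seq[f.seqid]
        if n > 10**4:
            raise ValueError(f"locus-tag gene ordinal width exhausted on {f.seqid}")
        digit = digits.get(f.seqid, 1)
        f.locus_tag = f"{prefix}_{digit}{seq_rank.get(f.seqid, 0):06d}{n:04d}"
        for k, child in enumerate(f.children, start=1):
            child.attributes["ID"] = f"{f.locus_tag}.{k}"
    return ordered


def compute_stats(out_dir: Path, cfg: PipelineConfig) -> dict:
    """Submission statistics recomputed from the artifacts on disk."""
    out_dir = Path(out_dir)
    seqs = seqio.read_sequences(out_dir / "sequences.fna", "fasta", Platform.ASSEMBLED)
    lengths = sorted(len(s) for s in seqs)
    import numpy as np

    length_stats = {
        "min": int(lengths[0]) if lengths else 0,
        "max": int(lengths[-1]) if lengths else 0,
        "mean": float(np.mean(lengths)) if lengths else 0.0,
        "median": float(np.median(lengths)) if lengths else 0.0,
    }
    per_caller = {}
    for caller, path in sorted((cfg.evidence.get("caller_gffs") or {}).items()):
        per_caller[caller] = sum(1 for f in seqio.read_gff(path) if f.ftype == "CDS")
    feats = seqio.read_gff(out_dir / "features.gff")
    by_type: dict[str, int] = {}
    for f in feats:
        by_type[f.ftype] = by_type.get(f.ftype, 0) + 1
    branches: dict[str, int] = {}
    assigned = {"cog": 0, "pfam": 0, "ko": 0, "ec": 0}
    ann = out_dir / "annotations.tsv"
    if ann.exists():
        with open(ann) as fh:
            next(fh)
            for line in fh:
                p = line.rstrip("\n").split("\t")
                branches[p[7]] = branches.get(p[7], 0) + 1
                if p[1]:
                    assigned["cog"] += 1
                if p[2]:
                    assigned["pfam"] += 1
                if p[3]:
                    assigned["ko"] += 1
                if p[4]:
                    assigned["ec"] += 1
    return {
        "n_sequences": len(seqs),
        "sequence_lengths": length_stats,
        "genes_per_caller": per_caller,
        "features_by_type": by_type,
        "assignments": assigned,
        "product_branches": branches,
    }
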