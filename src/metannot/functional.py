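"""Functional annotation from homology/profile evidence files.

COG assignments come from RPS-BLAST tabular hits against COG PSSMs
(e-value <= 0.1 re-enforced on ingest), Pfam assignments from HMMER
domain-table hits produced under model trusted cutoffs, and KO/EC
assignments from ranked protein hits against an isolate reference
database (top 5 hits, >= 30% identity, >= 70% subject coverage). A
scaffold's phylogenetic lineage is the last common ancestor of the
top hits of its genes, provided at least 30% of the genes have hits.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .model import AnnotationRecord, Hit

logger = logging.getLogger(__name__)

MAX_EVALUE = 0.1
KO_TOP_RANKS = 5
KO_MIN_IDENTITY = 30.0
KO_MIN_SUBJECT_COVERAGE = 0.70
LCA_MIN_HIT_FRACTION = 0.30


@dataclass
class ReferenceTables:
    """Small lookup tables shipped alongside the evidence files."""

    cog_meta: dict[str, tuple[str, int]] = field(default_factory=dict)   # id -> (name, consensus_length)
    pfam_meta: dict[str, tuple[str, int]] = field(default_factory=dict)  # acc -> (name, model_length)
    ko_index: dict[str, tuple[str, int]] = field(default_factory=dict)   # ref gene -> (KO, gene length)
    ko2ec: dict[str, list[str]] = field(default_factory=dict)
    cog_pfam: set[tuple[str, str]] = field(default_factory=set)
    taxonomy: dict[str, list[str]] = field(default_factory=dict)         # ref gene -> ranked lineage

    @classmethod
    def from_dir(cls, d) -> "ReferenceTables":
        from pathlib import Path

        d = Path(d)
        refs = cls()
        cog = pd.read_csv(d / "cog_meta.tsv", sep="\t", dtype=str)
        refs.cog_meta = {
            r.cog_id: (r.name, int(r.consensus_length)) for r in cog.itertuples()
        }
        pfam = pd.read_csv(d / "pfam_meta.tsv", sep="\t", dtype=str)
        refs.pfam_meta = {
            r.accession: (r.name, int(r.model_length)) for r in pfam.itertuples()
        }
        ko = pd.read_csv(d / "ko_index.tsv", sep="\t", dtype=str)
        refs.ko_index = {r.gene_id: (r.ko_id, int(r.gene_length)) for r in ko.itertuples()}
        ko2ec = pd.read_csv(d / "ko2ec.tsv", sep="\t", dtype=str)
        for r in ko2ec.itertuples():
            refs.ko2ec.setdefault(r.ko_id, []).append(r.ec_number)
        cp = pd.read_csv(d / "cog_pfam.tsv", sep="\t", dtype=str)
        refs.cog_pfam = {(r.cog_id, r.accession) for r in cp.itertuples()}
        tax = pd.read_csv(d / "taxonomy.tsv", sep="\t", dtype=str)
        refs.taxonomy = {r.gene_id: r.lineage.split(";") for r in tax.itertuples()}
        return refs


# ---------------------------------------------------------------------------
# evidence parsers

BLAST_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tab(path, enforce_evalue: float | None = MAX_EVALUE) -> dict[str, list[Hit]]:
    """Parse 12-column BLAST/USEARCH tabular output into per-query ranked hits.

    Rank reflects file order within a query (rank 1 = first = best).
    Hits above ``enforce_evalue`` are dropped on ingest.
    """
    try:
        df = pd.read_csv(path, sep="\t", names=BLAST_COLS, comment="#")
    except pd.errors.EmptyDataError:
        return {}
    hits: dict[str, list[Hit]] = defaultdict(list)
    for row in df.itertuples():
        if enforce_evalue is not None and row.evalue > enforce_evalue:
            continue
        q = str(row.qseqid)
        hits[q].append(
            Hit(
                query_id=q, subject_id=str(row.sseqid),
                percent_identity=float(row.pident),
                alignment_length=int(row.length),
                q_start=int(row.qstart), q_end=int(row.qend),
                s_start=int(row.sstart), s_end=int(row.send),
                e_value=float(row.evalue), bit_score=float(row.bitscore),
                rank=len(hits[q]) + 1,
            )
        )
    return dict(hits)


def read_domtblout(path) -> dict[str, list[Hit]]:
    """Parse HMMER --domtblout rows into per-query domain hits.

    Fixed whitespace columns: target, t-acc, tlen, query(model), q-acc,
    qlen, seq e-value, seq score, seq bias, dom #, dom of, c-Evalue,
    i-Evalue, dom score, dom bias, hmm from, hmm to, ali from, ali to,
    env from, env to, acc, description. Alignment coordinates on the
    protein come from ali from/to; model span from hmm from/to.
    """
    hits: dict[str, list[Hit]] = defaultdict(list)
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            target, model, qlen = f[0], f[3], int(f[5])
            i_evalue, dom_score = float(f[12]), float(f[13])
            hmm_from, hmm_to = int(f[15]), int(f[16])
            ali_from, ali_to = int(f[17]), int(f[18])
            # percent identity is not reported by hmmsearch; 0 sorts last
            hits[target].append(
                Hit(
                    query_id=target, subject_id=model, percent_identity=0.0,
                    alignment_length=ali_to - ali_from + 1,
                    q_start=ali_from, q_end=ali_to,
                    s_start=hmm_from, s_end=hmm_to,
                    e_value=i_evalue, bit_score=dom_score,
                    rank=len(hits[target]) + 1,
                )
            )
    return dict(hits)


# ---------------------------------------------------------------------------
# hit filtering


def filter_overlapping_hits(
    hits: list[Hit], model_lengths: dict[str, int]
) -> list[Hit]:
    """Resolve pairs of hits whose query spans overlap more than half the
    shorter model's length, keeping the better hit.

    "Better" is decided by the ordered chain: larger bit score, then
    lower e-value, then longer alignment, then higher percent identity
    (subject id as a final deterministic tie-break). Elimination is
    processed in descending strength order, which makes the result a
    fixed point independent of input order.
    """

    def strength(h: Hit):
        return (-h.bit_score, h.e_value, -h.alignment_length,
                -h.percent_identity, h.subject_id, h.q_start)

    ordered = sorted(hits, key=strength)
    kept: list[Hit] = []
    for h in ordered:
        conflict = False
        for k in kept:
            shorter = min(
                model_lengths.get(h.subject_id, h.alignment_length),
                model_lengths.get(k.subject_id, k.alignment_length),
            )
            ov = max(0, min(h.q_end, k.q_end) - max(h.q_start, k.q_start) + 1)
            if ov * 2 > shorter:
                conflict = True
                break
        if not conflict:
            kept.append(h)
    return sorted(kept, key=lambda h: (h.q_start, h.q_end, h.subject_id))


# ---------------------------------------------------------------------------
# assignments


def assign_cogs(
    hits_per_gene: dict[str, list[Hit]], refs: ReferenceTables
) -> dict[str, list[tuple[str, Hit]]]:
    """COG assignments from PSSM hits after overlap filtering.

    Hits naming COG ids absent from the metadata table are dropped with
    a warning. Non-overlapping surviving hits all become assignments;
    they are reported strongest (highest bit score) first.
    """
    lengths = {cid: ln for cid, (_n, ln) in refs.cog_meta.items()}
    out: dict[str, list[tuple[str, Hit]]] = {}
    for gene, hits in hits_per_gene.items():
        known = []
        for h in hits:
            if h.subject_id not in refs.cog_meta:
                logger.warning("gene %s: unknown COG id %s dropped", gene, h.subject_id)
                continue
            known.append(h)
        surv = filter_overlapping_hits(known, lengths)
        surv.sort(key=lambda h: -h.bit_score)
        if surv:
            out[gene] = [(h.subject_id, h) for h in surv]
    return out


def assign_pfams(
    hits_per_gene: dict[str, list[Hit]], refs: ReferenceTables
) -> dict[str, list[tuple[str, Hit]]]:
    """Pfam domain assignments after the same overlap-filtering rules."""
    lengths = {acc: ln for acc, (_n, ln) in refs.pfam_meta.items()}
    out: dict[str, list[tuple[str, Hit]]] = {}
    for gene, hits in hits_per_gene.items():
        surv = filter_overlapping_hits(hits, lengths)
        surv.sort(key=lambda h: -h.bit_score)
        if surv:
            out[gene] = [(h.subject_id, h) for h in surv]
    return out


def assign_ko_ec(
    hits: list[Hit], refs: ReferenceTables
) -> tuple[list[str], list[str], str | None]:
    """KO/EC assignment and top-hit retention for one gene.

    Among hits of rank <= 5 whose subjects are in the KO index, those
    with identity >= 30% and subject coverage >= 70% contribute their
    KO (distinct KOs in rank order); ECs are the union of the KO->EC
    mapping over assigned KOs; the rank-1 hit's subject is retained as
    top hit regardless of KO eligibility.
    """
    kos: list[str] = []
    top_hit = None
    for h in sorted(hits, key=lambda h: h.rank):
        if top_hit is None and h.rank == 1:
            top_hit = h.subject_id
        if h.rank > KO_TOP_RANKS:
            continue
        entry = refs.ko_index.get(h.subject_id)
        if entry is None:
            continue
        ko, subj_len = entry
        coverage = (h.s_end - h.s_start + 1) / subj_len
        if h.percent_identity >= KO_MIN_IDENTITY and coverage >= KO_MIN_SUBJECT_COVERAGE:
            if ko not in kos:
                kos.append(ko)
    ecs: list[str] = []
    for ko in kos:
        for ec in refs.ko2ec.get(ko, []):
            if ec not in ecs:
                ecs.append(ec)
    return kos, ecs, top_hit


# ---------------------------------------------------------------------------
# lineage and abundance


def lineage_lca(lineages: list[list[str]]) -> list[str]:
    """Longest common rank-prefix of the given lineages."""
    if not lineages:
        return []
    prefix = list(lineages[0])
    for lin in lineages[1:]:
        n = 0
        for a, b in zip(prefix, lin):
            if a != b:
                break
            n += 1
        prefix = prefix[:n]
    return prefix


def scaffold_lineage(
    gene_ids: list[str], top_hits: dict[str, str | None],
    taxonomy: dict[str, list[str]],
    min_fraction: float = LCA_MIN_HIT_FRACTION,
) -> list[str] | None:
    """Last-common-ancestor lineage for the genes on one scaffold.

    Requires at least ``min_fraction`` of the genes to have a top hit
    with a known lineage ('>= 30%' is inclusive); otherwise None.
    """
    if not gene_ids:
        return None
    lineages = []
    n_hits = 0
    for g in gene_ids:
        th = top_hits.get(g)
        if th is not None:
            n_hits += 1
            if th in taxonomy:
                lineages.append(taxonomy[th])
    if n_hits / len(gene_ids) < min_fraction or not lineages:
        return None
    return lineage_lca(lineages)


def estimated_gene_copies(
    annotations: list[AnnotationRecord],
    gene_contig: dict[str, str],
    coverage: dict[str, float],
    group_by: str,
) -> dict[str, float]:
    """Coverage-weighted category abundances.

    The estimate for a category is the sum over its genes of the mean
    read coverage of the contig carrying the gene (1.0 when coverage is
    unknown), correcting for assembly collapsing many reads into one
    contig. ``group_by`` is one of cog / pfam / ko.
    """
    out: dict[str, float] = defaultdict(float)
    for rec in annotations:
        cov = coverage.get(gene_contig.get(rec.locus_tag, ""), 1.0)
        if group_by == "cog":
            cats = [rec.cog[0]] if rec.cog else []
        elif group_by == "pfam":
            cats = [acc for acc, _h in rec.pfams]
        elif group_by == "ko":
            cats = list(rec.kos)
        else:
            raise ValueError(f"unknown grouping {group_by!r}")
        for c in cats:
            out[c] += cov
    return dict(out)
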