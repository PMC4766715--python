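"""Scaffold splitting, four-caller consensus CDS selection, conflict
resolution against RNA/CRISPR features, and locus tagging.

Consensus semantics: gene callers agree on stop codons far more often
than on starts, so a "vote group" is the set of models sharing (contig,
strand, 3'-stop coordinate). Competing groups — same strand, spans
overlapping — are resolved by caller majority, ties by the caller
preference order GeneMark > Prodigal > MetaGeneAnnotator > FragGeneScan;
the winning group's start is taken from its most-preferred caller.
Non-competing singletons are retained (union semantics). Translations
shorter than 32 amino acids are deleted before any voting.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass

from Bio.Seq import Seq

from .model import Feature, GeneModel, Platform, SequenceRecord, overlap_len

CALLER_PREFERENCE = ["genemark", "prodigal", "mga", "fraggenescan"]
MIN_PROTEIN_AA = 32
START_CODONS = ("ATG", "GTG", "TTG")

SEQ_TYPE_DIGIT = {
    Platform.ASSEMBLED: 1,
    Platform.ROCHE454: 2,
    Platform.ILLUMINA: 3,
    Platform.PACBIO: 4,
}


# ---------------------------------------------------------------------------
# scaffold splitting


@dataclass
class SplitMap:
    """scaffold_id -> ordered (contig_id, 1-based offset, length) parts."""

    parts: dict[str, list[tuple[str, int, int]]]

    def contig_offset(self, contig_id: str) -> tuple[str, int]:
        for scaf, items in self.parts.items():
            for cid, off, _ln in items:
                if cid == contig_id:
                    return scaf, off
        raise KeyError(contig_id)


def split_scaffolds(
    seqs: list[SequenceRecord], min_gap: int = 50
) -> tuple[list[SequenceRecord], SplitMap]:
    """Split scaffolds at N-runs of ``min_gap`` or more into gap-free contigs.

    Contigs exclude the gap N's; scaffolding information (offsets) is
    retained so features can be lifted back after structural annotation.
    Unsplit sequences map to themselves with offset 1.
    """
    contigs: list[SequenceRecord] = []
    parts: dict[str, list[tuple[str, int, int]]] = {}
    gap_re = re.compile("N{%d,}" % min_gap)
    for rec in seqs:
        pieces = []
        prev = 0
        for m in gap_re.finditer(rec.seq):
            if m.start() > prev:
                pieces.append((prev, m.start()))
            prev = m.end()
        if prev < len(rec.seq):
            pieces.append((prev, len(rec.seq)))
        if len(pieces) == 1 and pieces[0] == (0, len(rec.seq)):
            contigs.append(rec)
            parts[rec.id] = [(rec.id, 1, len(rec.seq))]
            continue
        items = []
        for k, (s, e) in enumerate(pieces, start=1):
            cid = f"{rec.id}.{k}"
            contigs.append(
                SequenceRecord(id=cid, seq=rec.seq[s:e], platform=rec.platform,
                               original_id=rec.original_id)
            )
            items.append((cid, s + 1, e - s))
        parts[rec.id] = items
    return contigs, SplitMap(parts=parts)


# ---------------------------------------------------------------------------
# translation helpers


def translate_cds(contig_seq: str, start: int, end: int, strand: str) -> str:
    """Translate a CDS interval (1-based closed) with the bacterial table,
    dropping a trailing stop symbol if present."""
    sub = contig_seq[start - 1 : end]
    if strand == "-":
        sub = str(Seq(sub).reverse_complement())
    prot = str(Seq(sub[: len(sub) - len(sub) % 3]).translate(table=11))
    return prot[:-1] if prot.endswith("*") else prot


def length_ok(model: GeneModel, min_aa: int = MIN_PROTEIN_AA) -> bool:
    """32-aa minimum, counted on the translation excluding the stop codon."""
    if model.translation:
        return len(model.translation) >= min_aa
    n_codons = (model.end - model.start + 1) // 3
    return n_codons - 1 >= min_aa


# ---------------------------------------------------------------------------
# majority-rule consensus


def combine_gene_calls(
    calls: dict[str, list[GeneModel]],
    preference: list[str] | None = None,
    min_aa: int = MIN_PROTEIN_AA,
) -> list[GeneModel]:
    """Select consensus CDS models from per-caller predictions.

    ``calls`` maps caller name -> models in contig coordinates. See the
    module docstring for the voting semantics.
    """
    preference = preference or CALLER_PREFERENCE
    pref_rank = {c: i for i, c in enumerate(preference)}

    models = [
        m for caller, ms in calls.items() for m in ms if length_ok(m, min_aa)
    ]
    groups: dict[tuple[str, str, int], list[GeneModel]] = defaultdict(list)
    for m in models:
        groups[m.vote_key].append(m)

    reps: list[tuple[tuple[str, str, int], GeneModel, int, int]] = []
    for key, ms in groups.items():
        callers = {m.caller for m in ms}
        best = min(ms, key=lambda m: (pref_rank.get(m.caller, 99), m.start, m.end))
        reps.append((key, best, len(callers), pref_rank.get(best.caller, 99)))

    # greedy resolution: strongest group first, drop groups overlapping a winner
    reps.sort(key=lambda t: (-t[2], t[3], t[1].contig_id, t[1].start, t[1].end))
    winners: list[GeneModel] = []
    for _key, rep, _n, _p in reps:
        clash = any(
            w.contig_id == rep.contig_id and w.strand == rep.strand
            and overlap_len((w.start, w.end), (rep.start, rep.end)) > 0
            for w in winners
        )
        if not clash:
            winners.append(rep)
    return sorted(winners, key=lambda m: (m.contig_id, m.start, m.end, m.strand))


# ---------------------------------------------------------------------------
# conflict resolution


def find_alternative_start(
    cds: GeneModel, blocker: tuple[int, int], contig_seq: str,
    min_aa: int = MIN_PROTEIN_AA,
) -> GeneModel | None:
    """Move the CDS start in-frame past the blocker to remove a 5' overlap.

    Scans in translation direction for the first in-frame start codon
    (ATG/GTG/TTG) strictly past the blocker boundary; succeeds only when
    the remaining translation is still >= ``min_aa``. Returns the moved
    model, or None.
    """
    if cds.strand == "+":
        pos = cds.start
        while pos + 2 <= cds.end:
            if pos > blocker[1] and contig_seq[pos - 1 : pos + 2] in START_CODONS:
                new = GeneModel(cds.contig_id, pos, cds.end, "+", cds.caller,
                                cds.partial5, cds.partial3)
                new.translation = translate_cds(contig_seq, pos, cds.end, "+")
                if len(new.translation) >= min_aa:
                    return new
                return None
            pos += 3
    else:
        pos = cds.end
        while pos - 2 >= cds.start:
            codon = str(Seq(contig_seq[pos - 3 : pos]).reverse_complement())
            if pos < blocker[0] and codon in START_CODONS:
                new = GeneModel(cds.contig_id, cds.start, pos, "-", cds.caller,
                                cds.partial5, cds.partial3)
                new.translation = translate_cds(contig_seq, cds.start, pos, "-")
                if len(new.translation) >= min_aa:
                    return new
                return None
            pos -= 3
    return None


def _overlaps(a, b) -> bool:
    return a.contig_id == b.contig_id and overlap_len((a.start, a.end), (b.start, b.end)) > 0


def resolve_conflicts(
    cds: list[GeneModel],
    trnas: list,
    rrnas: list,
    crisprs: list,
    pfam_positive: set[str] | dict,
    contig_seqs: dict[str, str],
    min_aa: int = MIN_PROTEIN_AA,
) -> tuple[list[GeneModel], list, list]:
    """Resolve overlaps between feature types.

    Rules, applied in order: (a) a CDS completely inside an rRNA is
    deleted; a CDS partially overlapping an rRNA tries an alternative
    start, else is deleted; (b) of an overlapping tRNA/rRNA pair the
    lower-scoring prediction is deleted; (c) a CDS overlapping a tRNA is
    kept alongside it if the CDS has a Pfam hit, otherwise rule (a)
    logic applies; (d) CRISPR-vs-CDS conflicts follow rule (a) logic.

    ``pfam_positive`` holds ids (``contig:start-end:strand``) of CDS with
    a Pfam hit. Returns (cds, trnas, rrnas) survivors; CRISPR arrays are
    never deleted here.
    """

    def cds_key(m: GeneModel) -> str:
        return f"{m.contig_id}:{m.start}-{m.end}:{m.strand}"

    # (b) tRNA vs rRNA: lower score loses
    dead_trna, dead_rrna = set(), set()
    for i, t in enumerate(trnas):
        for j, r in enumerate(rrnas):
            if i in dead_trna or j in dead_rrna:
                continue
            if _overlaps(t, r):
                if t.score < r.score:
                    dead_trna.add(i)
                else:
                    dead_rrna.add(j)
    trnas = [t for i, t in enumerate(trnas) if i not in dead_trna]
    rrnas = [r for j, r in enumerate(rrnas) if j not in dead_rrna]

    def rule_a(model: GeneModel, blocker_span: tuple[int, int], contig_id: str) -> GeneModel | None:
        span = (model.start, model.end)
        if blocker_span[0] <= span[0] and span[1] <= blocker_span[1]:
            return None  # completely encompassed -> deleted
        moved = find_alternative_start(
            model, blocker_span, contig_seqs[contig_id], min_aa
        )
        if moved is not None and overlap_len((moved.start, moved.end), blocker_span) == 0:
            return moved
        return None

    out_cds: list[GeneModel] = []
    for m in cds:
        survivor: GeneModel | None = m
        # (a) rRNA conflicts
        for r in rrnas:
            if survivor is not None and _overlaps(survivor, r):
                survivor = rule_a(survivor, (r.start, r.end), r.contig_id)
        # (d) CRISPR conflicts
        if survivor is not None:
            for arr in crisprs:
                span = (arr.start, arr.end)
                if (survivor.contig_id == arr.contig_id
                        and overlap_len((survivor.start, survivor.end), span) > 0):
                    survivor = rule_a(survivor, span, arr.contig_id)
                    if survivor is None:
                        break
        # (c) tRNA conflicts
        if survivor is not None:
            for t in trnas:
                if survivor is not None and _overlaps(survivor, t):
                    if cds_key(m) in pfam_positive or cds_key(survivor) in pfam_positive:
                        continue  # Pfam hit: both kept
                    survivor = rule_a(survivor, (t.start, t.end), t.contig_id)
        if survivor is not None:
            out_cds.append(survivor)
    return out_cds, trnas, rrnas


# ---------------------------------------------------------------------------
# coordinate lifting and locus tags


def lift_to_scaffold(features: list[Feature], split_map: SplitMap) -> list[Feature]:
    """Shift contig-coordinate features back onto their source scaffolds."""
    lifted = []
    lengths = {
        cid: ln for items in split_map.parts.values() for cid, _off, ln in items
    }
    for f in features:
        scaf, off = split_map.contig_offset(f.seqid)
        if f.seqid in lengths and f.end > lengths[f.seqid]:
            raise ValueError(
                f"feature [{f.start},{f.end}] exceeds contig {f.seqid} "
                f"length {lengths[f.seqid]}"
            )
        g = Feature(
            seqid=scaf, start=f.start + off - 1, end=f.end + off - 1,
            strand=f.strand, ftype=f.ftype, locus_tag=f.locus_tag,
            score=f.score, source=f.source, attributes=dict(f.attributes),
            translation=f.translation,
        )
        g.children = lift_to_scaffold(f.children, split_map)
        lifted.append(g)
    return lifted


def assign_locus_tags(
    features: list[Feature],
    prefix: str,
    seq_type_digit: int,
    seq_order: list[str],
) -> list[Feature]:
    """Tag = PREFIX_<type digit><seq ordinal:06d><gene ordinal:04d>.

    The type digit encodes 1 = assembled, 2 = 454, 3 = Illumina,
    4 = PacBio. Fixed widths guarantee uniqueness up to 10^6 sequences
    and 10^4 genes per sequence; exceeding either is a hard error.
    Features are tagged in (sequence order, start, end) order.
    """
    if len(seq_order) > 10**6:
        raise ValueError("locus-tag sequence ordinal width exhausted")
    seq_rank = {sid: i + 1 for i, sid in enumerate(seq_order)}
    ordered = sorted(
        features, key=lambda f: (seq_rank.get(f.seqid, 0), f.start, f.end, f.ftype)
    )
    per_seq: Counter = Counter()
    for f in ordered:
        per_seq[f.seqid] += 1
        n = per_seq[f.seqid]
        if n > 10**4:
            raise ValueError(f"locus-tag gene ordinal width exhausted on {f.seqid}")
        f.locus_tag = f"{prefix}_{seq_type_digit}{seq_rank.get(f.seqid, 0):06d}{n:04d}"
        for suffix_i, child in enumerate(f.children, start=1):
            if not child.attributes.get("ID"):
                child.attributes["ID"] = f"{f.locus_tag}.{suffix_i}"
    return ordered


# ---------------------------------------------------------------------------
# caller evidence ingestion

_CALLER_ALIASES = {
    "genemark": "genemark", "genemark.hmm": "genemark",
    "prodigal": "prodigal", "prodigal_v2.6": "prodigal",
    "mga": "mga", "metageneannotator": "mga",
    "fraggenescan": "fraggenescan", "fgs": "fraggenescan",
}


def gene_models_from_gff(
    features: list[Feature], contig_seqs: dict[str, str]
) -> dict[str, list[GeneModel]]:
    """Group CDS rows of caller GFFs by caller (GFF source column)."""
    calls: dict[str, list[GeneModel]] = defaultdict(list)
    for f in features:
        if f.ftype != "CDS":
            continue
        caller = _CALLER_ALIASES.get(f.source.lower(), f.source.lower())
        m = GeneModel(
            contig_id=f.seqid, start=f.start, end=f.end, strand=f.strand,
            caller=caller,
            partial5=f.attributes.get("partial5", "0") == "1",
            partial3=f.attributes.get("partial3", "0") == "1",
        )
        if f.seqid in contig_seqs:
            m.translation = translate_cds(contig_seqs[f.seqid], f.start, f.end, f.strand)
        calls[caller].append(m)
    return dict(calls)
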