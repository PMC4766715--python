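"""Scaffold splitting, majority-rule gene calling, conflict resolution, tags."""

import numpy as np
import pytest

from metannot.model import Feature, GeneModel, RnaPrediction, SequenceRecord
from metannot import consensus as cons
from metannot.fixtures import orf_seq, random_seq


# -- scaffold splitting -----------------------------------------------------

def test_split_at_60n_gap_arithmetic(rng):
    seq = random_seq(rng, 400) + "N" * 60 + random_seq(rng, 540)
    contigs, sm = cons.split_scaffolds([SequenceRecord("s1", seq)])
    assert [(c.id, len(c.seq)) for c in contigs] == [("s1.1", 400), ("s1.2", 540)]
    assert sm.parts["s1"] == [("s1.1", 1, 400), ("s1.2", 461, 540)]


def test_49n_run_does_not_split(rng):
    seq = random_seq(rng, 100) + "N" * 49 + random_seq(rng, 100)
    contigs, sm = cons.split_scaffolds([SequenceRecord("s1", seq)])
    assert len(contigs) == 1 and contigs[0].id == "s1"


def test_no_ns_identity_mapping(rng):
    rec = SequenceRecord("s1", random_seq(rng, 300))
    contigs, sm = cons.split_scaffolds([rec])
    assert contigs == [rec]
    assert sm.parts["s1"] == [("s1", 1, 300)]


# -- majority rule ----------------------------------------------------------

def _m(caller, start, end, strand="+", contig="c"):
    g = GeneModel(contig, start, end, strand, caller)
    g.translation = "M" * ((end - start + 1) // 3 - 1)
    return g


def test_three_vs_one_majority_wins():
    calls = {
        "genemark": [_m("genemark", 100, 399)],
        "prodigal": [_m("prodigal", 100, 399)],
        "mga": [_m("mga", 100, 399)],
        "fraggenescan": [_m("fraggenescan", 150, 449)],  # different stop
    }
    out = cons.combine_gene_calls(calls)
    assert [(g.start, g.end) for g in out] == [(100, 399)]


def test_two_two_tie_genemark_side_wins():
    calls = {
        "genemark": [_m("genemark", 100, 399)],
        "prodigal": [_m("prodigal", 151, 450)],
        "mga": [_m("mga", 100, 399)],
        "fraggenescan": [_m("fraggenescan", 151, 450)],
    }
    out = cons.combine_gene_calls(calls)
    assert [(g.start, g.end, g.caller) for g in out] == [(100, 399, "genemark")]


def test_winning_group_uses_preferred_callers_start():
    calls = {
        "prodigal": [_m("prodigal", 109, 399)],
        "mga": [_m("mga", 100, 399)],  # same stop, different start
    }
    out = cons.combine_gene_calls(calls)
    assert [(g.start, g.caller) for g in out] == [(109, "prodigal")]


def test_short_translation_deleted_before_voting():
    calls = {"genemark": [_m("genemark", 100, 195)]}  # 32 codons -> 31 aa
    assert cons.combine_gene_calls(calls) == []
    calls = {"genemark": [_m("genemark", 100, 198)]}  # 33 codons -> 32 aa
    assert len(cons.combine_gene_calls(calls)) == 1


def test_nonoverlapping_singletons_retained():
    calls = {
        "genemark": [_m("genemark", 100, 399)],
        "fraggenescan": [_m("fraggenescan", 1000, 1299)],
    }
    out = cons.combine_gene_calls(calls)
    assert len(out) == 2


def test_opposite_strand_overlaps_do_not_compete():
    calls = {
        "genemark": [_m("genemark", 100, 399, "+")],
        "prodigal": [_m("prodigal", 200, 499, "-")],
    }
    assert len(cons.combine_gene_calls(calls)) == 2


def _consensus_oracle(calls, preference=None):
    """Literal re-implementation: explicit vote groups, repeated best-group
    selection, pairwise same-strand overlap elimination."""
    preference = preference or cons.CALLER_PREFERENCE
    rank = {c: i for i, c in enumerate(preference)}
    models = [m for ms in calls.values() for m in ms
              if (m.end - m.start + 1) // 3 - 1 >= 32]
    groups = {}
    for m in models:
        groups.setdefault(m.vote_key, []).append(m)
    remaining = dict(groups)
    chosen = []
    while remaining:
        def group_score(key):
            ms = remaining[key]
            votes = len({m.caller for m in ms})
            best_rank = min(rank.get(m.caller, 99) for m in ms)
            rep = min(ms, key=lambda m: (rank.get(m.caller, 99), m.start, m.end))
            return (-votes, best_rank, rep.contig_id, rep.start, rep.end)

        key = min(remaining, key=group_score)
        ms = remaining.pop(key)
        rep = min(ms, key=lambda m: (rank.get(m.caller, 99), m.start, m.end))
        clash = any(
            w.contig_id == rep.contig_id and w.strand == rep.strand
            and not (rep.end < w.start or w.end < rep.start)
            for w in chosen
        )
        if not clash:
            chosen.append(rep)
    return sorted(
        [(g.contig_id, g.start, g.end, g.strand) for g in chosen]
    )


def test_combine_matches_bruteforce_oracle_on_random_inputs(rng):
    for _ in range(100):
        calls = {c: [] for c in cons.CALLER_PREFERENCE}
        n_sites = int(rng.integers(1, 6))
        sites = []
        for _s in range(n_sites):
            start = int(rng.integers(1, 2000))
            length = 3 * int(rng.integers(30, 120))
            sites.append((start, start + length - 1, "+" if rng.random() < 0.5 else "-"))
        for caller in cons.CALLER_PREFERENCE:
            for (s, e, st) in sites:
                if rng.random() < 0.25:
                    continue
                if rng.random() < 0.4:  # start disagreement, stop preserved
                    delta = 3 * int(rng.integers(1, 10))
                    s2, e2 = (s + delta, e) if st == "+" else (s, e - delta)
                else:
                    s2, e2 = s, e
                calls[caller].append(_m(caller, s2, e2, st))
        got = sorted((g.contig_id, g.start, g.end, g.strand)
                     for g in cons.combine_gene_calls(calls))
        assert got == _consensus_oracle(calls)


# -- alternative start ------------------------------------------------------

def _contig_with_gene(rng, n_codons=80):
    left = random_seq(rng, 90)
    gene = orf_seq(rng, n_codons)
    return left + gene + random_seq(rng, 60), len(left) + 1, len(left) + len(gene)


def test_alternative_start_found_downstream(rng):
    contig, gstart, gend = _contig_with_gene(rng, 90)
    # force an in-frame ATG 9 codons in
    pos0 = gstart - 1 + 27
    contig = contig[:pos0] + "ATG" + contig[pos0 + 3:]
    cds = GeneModel("c", gstart, gend, "+", "genemark")
    blocker = (gstart - 30, gstart + 20)  # overlaps the 5' end
    moved = cons.find_alternative_start(cds, blocker, contig)
    assert moved is not None
    assert moved.start > blocker[1] and (moved.start - gstart) % 3 == 0
    assert len(moved.translation) >= 32


def test_alternative_start_fails_without_inframe_start(rng):
    left = random_seq(rng, 90).replace("A", "C")
    # gene body without any in-frame start codons after codon 0
    body = "".join(["CCT"] * 60)
    contig = left + "ATG" + body + "TAA" + random_seq(rng, 30)
    gstart, gend = 91, 91 + 3 + len(body) + 3 - 1
    cds = GeneModel("c", gstart, gend, "+", "genemark")
    moved = cons.find_alternative_start(cds, (gstart - 10, gstart + 5), contig)
    assert moved is None


def test_alternative_start_fails_when_orf_too_short(rng):
    contig, gstart, gend = _contig_with_gene(rng, 40)
    cds = GeneModel("c", gstart, gend, "+", "genemark")
    # blocker reaches codon 20 -> at most 20 codons remain, below 32 aa
    blocker = (gstart - 10, gstart + 60)
    assert cons.find_alternative_start(cds, blocker, contig) is None


# -- conflict resolution ----------------------------------------------------

def _rna(start, end, score, rna_type="rRNA_16S", contig="c"):
    return RnaPrediction(contig_id=contig, start=start, end=end, strand="+",
                         rna_type=rna_type, domain_run="bacteria", score=score)


def test_cds_inside_rrna_deleted(rng):
    contig = random_seq(rng, 2000)
    cds = [GeneModel("c", 200, 400, "+", "genemark")]
    out_cds, _t, _r = cons.resolve_conflicts(
        cds, [], [_rna(100, 1600, 900.0)], [], set(), {"c": contig}
    )
    assert out_cds == []


def test_trna_rrna_conflict_lower_score_deleted():
    trna = _rna(100, 175, 40.0, rna_type="tRNA")
    rrna = _rna(150, 1500, 900.0)
    _c, trnas, rrnas = cons.resolve_conflicts([], [trna], [rrna], [], set(), {})
    assert trnas == [] and rrnas == [rrna]


def test_cds_trna_overlap_kept_with_pfam_hit(rng):
    contig = random_seq(rng, 2000)
    cds = GeneModel("c", 100, 400, "+", "genemark")
    key = "c:100-400:+"
    out_cds, trnas, _r = cons.resolve_conflicts(
        [cds], [_rna(350, 425, 40.0, rna_type="tRNA")], [], [],
        {key}, {"c": contig},
    )
    assert len(out_cds) == 1 and len(trnas) == 1


def test_cds_trna_overlap_without_pfam_resolved_like_rrna(rng):
    left = random_seq(rng, 99)
    gene = orf_seq(rng, 120)
    contig = left + gene + random_seq(rng, 100)
    cds = GeneModel("c", 100, 99 + len(gene), "+", "genemark")
    trna = _rna(60, 110, 40.0, rna_type="tRNA")  # clips the 5' end
    out_cds, _t, _r = cons.resolve_conflicts(
        [cds], [trna], [], [], set(), {"c": contig}
    )
    # either rescued past the tRNA or deleted; never left overlapping
    for g in out_cds:
        assert g.start > trna.end


# -- lifting and locus tags -------------------------------------------------

def test_lift_offset_arithmetic(rng):
    seq = random_seq(rng, 400) + "N" * 60 + random_seq(rng, 540)
    _contigs, sm = cons.split_scaffolds([SequenceRecord("s1", seq)])
    f = Feature(seqid="s1.2", start=10, end=108, strand="+", ftype="CDS")
    lifted = cons.lift_to_scaffold([f], sm)
    assert (lifted[0].seqid, lifted[0].start, lifted[0].end) == ("s1", 470, 568)


def test_lift_identity_for_unsplit(rng):
    _c, sm = cons.split_scaffolds([SequenceRecord("s1", random_seq(rng, 300))])
    f = Feature(seqid="s1", start=11, end=100, strand="-", ftype="CDS")
    lifted = cons.lift_to_scaffold([f], sm)
    assert (lifted[0].start, lifted[0].end) == (11, 100)


def test_lift_rejects_feature_exceeding_contig(rng):
    seq = random_seq(rng, 400) + "N" * 60 + random_seq(rng, 540)
    _c, sm = cons.split_scaffolds([SequenceRecord("s1", seq)])
    f = Feature(seqid="s1.1", start=10, end=450, strand="+", ftype="CDS")
    with pytest.raises(ValueError, match="exceeds"):
        cons.lift_to_scaffold([f], sm)


def test_locus_tag_layout_and_increment():
    feats = [
        Feature(seqid="s1", start=100, end=400, strand="+", ftype="CDS"),
        Feature(seqid="s1", start=500, end=900, strand="+", ftype="CDS"),
        Feature(seqid="s2", start=10, end=310, strand="+", ftype="CDS"),
    ]
    tagged = cons.assign_locus_tags(feats, "GOLD", 1, ["s1", "s2"])
    # layout: type digit + 6-digit sequence ordinal + 4-digit gene ordinal
    assert [f.locus_tag for f in tagged] == [
        "GOLD_10000010001", "GOLD_10000010002", "GOLD_10000020001"
    ]


def test_locus_tags_unique_on_random_fixture(rng):
    feats = []
    seqs = [f"s{i}" for i in range(8)]
    for _ in range(200):
        sid = seqs[int(rng.integers(0, 8))]
        start = int(rng.integers(1, 9000))
        feats.append(Feature(seqid=sid, start=start, end=start + 100,
                             strand="+", ftype="CDS"))
    tagged = cons.assign_locus_tags(feats, "GOLD", 3, seqs)
    tags = [f.locus_tag for f in tagged]
    assert len(set(tags)) == len(tags)
    assert all(t.startswith("GOLD_3") for t in tags)
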