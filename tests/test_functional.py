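"""Hit filtering, COG/Pfam/KO/EC assignment, lineage LCA, abundances."""

import pytest

from metannot.model import AnnotationRecord, Hit
from metannot import functional as fn


def _hit(subject="S1", bit=100.0, ev=1e-10, qs=1, qe=100, ss=1, se=100,
         ident=50.0, aln=None, rank=1, query="g1"):
    aln = aln if aln is not None else qe - qs + 1
    return Hit(query_id=query, subject_id=subject, percent_identity=ident,
               alignment_length=aln, q_start=qs, q_end=qe, s_start=ss, s_end=se,
               e_value=ev, bit_score=bit, rank=rank)


MODEL_LENS = {"S1": 100, "S2": 100, "S3": 100, "S4": 50}


# -- overlap filtering ------------------------------------------------------

def test_majority_overlap_keeps_higher_bitscore():
    a = _hit("S1", bit=100, qs=1, qe=100)
    b = _hit("S2", bit=90, qs=41, qe=140)  # 60% of shorter model
    assert fn.filter_overlapping_hits([a, b], MODEL_LENS) == [a]


def test_sub_half_overlap_keeps_both():
    a = _hit("S1", bit=100, qs=1, qe=100)
    b = _hit("S2", bit=90, qs=61, qe=160)  # 40 of 100 -> not > half
    assert len(fn.filter_overlapping_hits([a, b], MODEL_LENS)) == 2


def test_equal_bitscore_lower_evalue_wins():
    a = _hit("S1", bit=100, ev=1e-5, qs=1, qe=100)
    b = _hit("S2", bit=100, ev=1e-3, qs=1, qe=100)
    assert fn.filter_overlapping_hits([a, b], MODEL_LENS) == [a]


def test_overlap_uses_shorter_model_length():
    # query overlap of 30 residues; shorter model is 50 long -> 30 > 25
    a = _hit("S1", bit=100, qs=1, qe=100)
    b = _hit("S4", bit=90, qs=71, qe=120)
    assert fn.filter_overlapping_hits([a, b], MODEL_LENS) == [a]


def _filter_oracle(hits, model_lens):
    """Strongest-survivor recursion over explicit conflict pairs."""
    def conflict(h, k):
        shorter = min(model_lens.get(h.subject_id, h.alignment_length),
                      model_lens.get(k.subject_id, k.alignment_length))
        ov = max(0, min(h.q_end, k.q_end) - max(h.q_start, k.q_start) + 1)
        return ov * 2 > shorter

    def strength(h):
        return (h.bit_score, -h.e_value, h.alignment_length,
                h.percent_identity, [-ord(c) for c in h.subject_id], -h.q_start)

    pool = list(hits)
    kept = []
    while pool:
        best = max(pool, key=strength)
        kept.append(best)
        pool = [h for h in pool if h is not best and not conflict(h, best)]
    return sorted(kept, key=lambda h: (h.q_start, h.q_end, h.subject_id))


def test_filter_matches_pairwise_oracle_and_is_fixed_point(rng):
    subjects = list(MODEL_LENS)
    for _ in range(200):
        hits = []
        for i in range(int(rng.integers(1, 15))):
            qs = int(rng.integers(1, 300))
            hits.append(_hit(subjects[int(rng.integers(0, 4))],
                             bit=float(rng.integers(20, 200)),
                             ev=10.0 ** float(-rng.integers(2, 30)),
                             qs=qs, qe=qs + int(rng.integers(20, 120)),
                             ident=float(rng.integers(20, 99))))
        got = fn.filter_overlapping_hits(hits, MODEL_LENS)
        assert got == _filter_oracle(hits, MODEL_LENS)
        assert fn.filter_overlapping_hits(got, MODEL_LENS) == got  # stable


# -- COG / Pfam assignment --------------------------------------------------

def _refs():
    refs = fn.ReferenceTables()
    refs.cog_meta = {"COG0001": ("name one", 100), "COG0002": ("name two", 100)}
    refs.pfam_meta = {"PF00001": ("Dom1", 100), "PF00002": ("Dom2", 100)}
    refs.ko_index = {"RG1": ("K00001", 300), "RG2": ("K00002", 200)}
    refs.ko2ec = {"K00001": ["1.1.1.1"], "K00002": ["1.1.1.2", "2.2.2.2"]}
    refs.taxonomy = {
        "RG1": ["Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacterales"],
        "RG2": ["Bacteria", "Proteobacteria", "Alphaproteobacteria"],
    }
    return refs


def test_assign_cogs_drops_unknown_ids(caplog):
    hits = {"g1": [_hit("COG0001"), _hit("COG9999", qs=150, qe=250)]}
    with caplog.at_level("WARNING"):
        out = fn.assign_cogs(hits, _refs())
    assert [c for c, _h in out["g1"]] == ["COG0001"]
    assert any("COG9999" in m for m in caplog.messages)


def test_two_nonoverlapping_cog_hits_both_retained():
    hits = {"g1": [_hit("COG0001", qs=1, qe=100),
                   _hit("COG0002", qs=140, qe=240, bit=80)]}
    out = fn.assign_cogs(hits, _refs())
    assert len(out["g1"]) == 2


def test_blast_tab_ingest_enforces_evalue(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text(
        "g1\tCOG0001\t45.0\t100\t5\t0\t1\t100\t1\t100\t0.05\t120\n"
        "g1\tCOG0002\t45.0\t100\t5\t0\t1\t100\t1\t100\t0.2\t110\n"
    )
    hits = fn.read_blast_tab(p)
    assert [h.subject_id for h in hits["g1"]] == ["COG0001"]


# -- KO / EC ----------------------------------------------------------------

def test_ko_assigned_within_thresholds():
    hits = [_hit("RG1", rank=2, ident=35.0, ss=1, se=240)]  # 240/300 = 80%
    kos, ecs, top = fn.assign_ko_ec(hits, _refs())
    assert kos == ["K00001"] and ecs == ["1.1.1.1"] and top is None


def test_ko_rank_six_excluded():
    hits = [_hit("RG1", rank=6, ident=90.0, ss=1, se=300)]
    kos, _e, _t = fn.assign_ko_ec(hits, _refs())
    assert kos == []


@pytest.mark.parametrize(
    "ident,se,assigned",
    [(29.9, 240, False), (30.0, 210, True), (30.0, 209, False), (95.0, 300, True)],
)
def test_ko_threshold_boundaries(ident, se, assigned):
    hits = [_hit("RG1", rank=1, ident=ident, ss=1, se=se)]
    kos, _e, top = fn.assign_ko_ec(hits, _refs())
    assert (kos == ["K00001"]) == assigned
    assert top == "RG1"  # rank-1 hit retained regardless


def test_top_hit_retained_even_if_not_in_ko_index():
    hits = [_hit("UNKNOWN", rank=1, ident=90.0, ss=1, se=300),
            _hit("RG2", rank=2, ident=90.0, ss=1, se=200)]
    kos, ecs, top = fn.assign_ko_ec(hits, _refs())
    assert top == "UNKNOWN" and kos == ["K00002"]
    assert ecs == ["1.1.1.2", "2.2.2.2"]


def test_ko_monotone_in_identity_and_coverage(rng):
    refs = _refs()
    for _ in range(50):
        ident = float(rng.uniform(20, 60))
        se = int(rng.integers(150, 300))
        base = [_hit("RG1", rank=1, ident=ident, ss=1, se=se)]
        kos0, _e, _t = fn.assign_ko_ec(base, refs)
        better = [_hit("RG1", rank=1, ident=min(100.0, ident + 10), ss=1,
                       se=min(300, se + 30))]
        kos1, _e, _t = fn.assign_ko_ec(better, refs)
        assert set(kos0) <= set(kos1)


# -- lineage ----------------------------------------------------------------

def test_lineage_common_prefix():
    refs = _refs()
    genes = [f"g{i}" for i in range(10)]
    top = {g: None for g in genes}
    top["g0"], top["g1"], top["g2"], top["g3"] = "RG1", "RG1", "RG2", "RG2"
    lin = fn.scaffold_lineage(genes, top, refs.taxonomy)
    assert lin == ["Bacteria", "Proteobacteria"]


def test_lineage_requires_30_percent_hits():
    refs = _refs()
    genes = [f"g{i}" for i in range(10)]
    top = {g: None for g in genes}
    top["g0"], top["g1"] = "RG1", "RG2"
    assert fn.scaffold_lineage(genes, top, refs.taxonomy) is None
    top["g2"] = "RG1"  # exactly 30% -> emitted
    assert fn.scaffold_lineage(genes, top, refs.taxonomy) is not None


def test_lineage_is_prefix_of_every_contributor(rng):
    names = ["A", "B", "C", "D"]
    for _ in range(50):
        lineages = []
        for _i in range(int(rng.integers(1, 6))):
            depth = int(rng.integers(1, 7))
            lineages.append([names[int(rng.integers(0, 3))] for _ in range(depth)])
        lca = fn.lineage_lca(lineages)
        for lin in lineages:
            assert lin[: len(lca)] == lca


# -- abundance --------------------------------------------------------------

def _ann(tag, cog=None, kos=()):
    rec = AnnotationRecord(locus_tag=tag)
    if cog:
        rec.cog = (cog, _hit(cog))
    rec.kos = list(kos)
    return rec


def test_estimated_copies_sums_contig_coverage():
    anns = [_ann("t1", cog="COG0001"), _ann("t2", cog="COG0001")]
    contig = {"t1": "c1", "t2": "c2"}
    cov = {"c1": 3.0, "c2": 4.0}
    assert fn.estimated_gene_copies(anns, contig, cov, "cog") == {"COG0001": 7.0}


def test_estimated_copies_defaults_to_counts_without_coverage():
    anns = [_ann("t1", kos=["K00001"]), _ann("t2", kos=["K00001", "K00002"])]
    contig = {"t1": "c1", "t2": "c1"}
    out = fn.estimated_gene_copies(anns, contig, {}, "ko")
    assert out == {"K00001": 2.0, "K00002": 1.0}


def test_single_gene_weighted_by_its_coverage():
    anns = [_ann("t1", cog="COG0002")]
    out = fn.estimated_gene_copies(anns, {"t1": "c9"}, {"c9": 12.5}, "cog")
    assert out == {"COG0002": 12.5}
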