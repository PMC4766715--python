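"""Read-cleaning stages: sanitization, trimming, filters, de-replication."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metannot.model import Platform, SequenceRecord
from metannot import preprocess as pp


def _read(seq, quals=None, platform=Platform.ILLUMINA, rid="r1"):
    return SequenceRecord(rid, seq, quals, platform)


# -- sanitize ---------------------------------------------------------------

@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ACGRT", "ACGNT"),       # ambiguity code -> N
        ("ACGTN", "ACGTN"),       # already canonical
        ("acgu", "ACGN"),         # U treated as ambiguous, not T
        ("ACG-T", None),          # foreign character -> rejected
        ("ACG7T", None),
    ],
)
def test_sanitize(seq, expected):
    out = pp.sanitize(_read(seq))
    assert (out.seq if out else None) == expected


# -- length filter ----------------------------------------------------------

@pytest.mark.parametrize(
    "length,platform,stage,removed",
    [
        (149, Platform.ILLUMINA, "pre_trim", True),
        (150, Platform.ILLUMINA, "pre_trim", False),
        (1001, Platform.ROCHE454, "pre_trim", True),
        (1000, Platform.ROCHE454, "pre_trim", False),
        (1001, Platform.ROCHE454, "post_trim", False),  # upper bound pre-trim only
        (149, Platform.ROCHE454, "post_trim", True),
    ],
)
def test_length_filter_boundaries(length, platform, stage, removed):
    r = _read("A" * length, platform=platform)
    assert (pp.length_filter(r, stage) is not None) == removed


# -- quality trimming -------------------------------------------------------

def _brute_force_illumina(quals, thr=13):
    """Longest substring with min quality >= thr, leftmost on ties."""
    best = (0, 0)
    for i in range(len(quals)):
        for j in range(i, len(quals)):
            if quals[j] < thr:
                break
            if j - i + 1 > best[1] - best[0]:
                best = (i, j + 1)
    return best


def test_illumina_trim_takes_longest_clean_substring():
    r = _read("ACGTAC", [20, 20, 5, 20, 20, 20])
    out = pp.quality_trim(r)
    assert out.seq == "TAC" and out.quals == [20, 20, 20]


def test_trim_identity_when_all_pass():
    r = _read("ACGTAC", [20] * 6)
    assert pp.quality_trim(r).seq == "ACGTAC"


def test_454_trim_is_two_ended():
    r = _read("ACGTA", [10, 30, 30, 30, 15], platform=Platform.ROCHE454)
    out = pp.quality_trim(r)
    assert out.seq == "CGT" and out.quals == [30, 30, 30]


def test_trailing_ns_removed_after_trim():
    r = _read("ACGTNN", [30] * 6)
    out = pp.quality_trim(r)
    assert out.seq == "ACGT" and len(out.quals) == 4


@given(st.lists(st.integers(0, 40), min_size=0, max_size=120))
@settings(max_examples=200, deadline=None)
def test_illumina_trim_matches_bruteforce(quals):
    r = _read("A" * len(quals), list(quals))
    out = pp.quality_trim(r)
    i, j = _brute_force_illumina(quals)
    assert out.quals == quals[i:j]


# -- N-count filter ---------------------------------------------------------

@pytest.mark.parametrize("n_ns,removed", [(6, True), (5, False), (0, False)])
def test_n_count_filter_is_strict(n_ns, removed):
    r = _read("N" * n_ns + "A" * 20)
    assert (pp.n_count_filter(r) is not None) == removed


# -- DUST -------------------------------------------------------------------

def test_dust_dinucleotide_repeat_fully_masked_and_removed():
    r = _read("AC" * 30)
    intervals, remove = pp.dust_mask(r)
    assert remove
    assert intervals == [(1, 60)]


def test_dust_random_sequence_kept(rng):
    seq = "".join(rng.choice(list("ACGT"), size=200))
    r = _read(seq)
    _intervals, remove = pp.dust_mask(r)
    assert not remove


def test_dust_score_zero_for_all_distinct_triplets():
    # every triplet occurs once -> sum c(c-1)/2 == 0
    assert pp.dust_window_score("ACGTAC"[:5]) == 0.0
    assert pp.dust_window_score("AACCGGTTA") == pytest.approx(0.0)


def test_dust_window_score_equals_direct_formula(rng):
    from collections import Counter

    for _ in range(20):
        w = "".join(rng.choice(list("ACGT"), size=int(rng.integers(8, 64))))
        counts = Counter(w[i:i + 3] for i in range(len(w) - 2))
        expected = 10.0 * sum(c * (c - 1) / 2 for c in counts.values()) / (len(w) - 3)
        assert pp.dust_window_score(w) == pytest.approx(expected)


# -- de-replication ---------------------------------------------------------

def test_replicate_prefix_of_longer_read_removed_454():
    a = _read("ACG" + "T" * 97, platform=Platform.ROCHE454, rid="A")
    b = _read(a.seq[:98], platform=Platform.ROCHE454, rid="B")
    kept, removed = pp.dereplicate([a, b], Platform.ROCHE454)
    assert [r.id for r in kept] == ["A"]
    assert removed == {"B": "A"}


def test_below_identity_reads_both_kept_illumina(rng):
    prefix = "ACGTA"
    body_a = "".join(rng.choice(list("ACGT"), size=95))
    # mutate 10% of positions -> ~90% identity overall
    body_b = list(body_a)
    for i in range(0, 95, 10):
        body_b[i] = "A" if body_a[i] != "A" else "C"
    a = _read(prefix + body_a, rid="A")
    b = _read(prefix + "".join(body_b), rid="B")
    kept, _removed = pp.dereplicate([a, b], Platform.ILLUMINA)
    assert len(kept) == 2


def test_singleton_kept():
    a = _read("ACGTA" * 30, rid="A")
    kept, removed = pp.dereplicate([a], Platform.ILLUMINA)
    assert len(kept) == 1 and not removed


def test_equal_length_tie_keeps_smallest_id():
    a = _read("ACGTT" * 20, rid="B")
    b = _read("ACGTT" * 20, rid="A")
    kept, removed = pp.dereplicate([a, b], Platform.ILLUMINA)
    assert [r.id for r in kept] == ["A"]
    assert removed == {"B": "A"}


# -- 454 homopolymer clustering --------------------------------------------

def test_homopolymer_compression():
    assert pp.compress_homopolymers("AAATGGCC") == "ATGC"
    assert pp.compress_homopolymers("") == ""


def test_declust_run_length_variants_cluster_together():
    base = "ATGCATGCATGCATGCATGCATGCATGCATGC"
    a = _read("AAA" + base, platform=Platform.ROCHE454, rid="A")
    b = _read("AA" + base, platform=Platform.ROCHE454, rid="B")
    kept, clusters = pp.declust_454([a, b], k=8)
    assert [r.id for r in kept] == ["A"]  # longest representative
    assert clusters["A"] == ["A", "B"]


def test_declust_unrelated_reads_stay_apart(rng):
    a = _read("".join(rng.choice(list("ACGT"), size=300)), platform=Platform.ROCHE454, rid="A")
    b = _read("".join(rng.choice(list("ACGT"), size=300)), platform=Platform.ROCHE454, rid="B")
    kept, clusters = pp.declust_454([a, b], k=16)
    assert len(kept) == 2 and len(clusters) == 2


# -- pipeline order and accounting ------------------------------------------

def test_filter_report_telescopes(rng):
    reads = []
    for i in range(60):
        n = int(rng.integers(120, 400))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        quals = [int(q) for q in rng.integers(2, 41, size=n)]
        reads.append(_read(seq, quals, rid=f"r{i:03d}"))
    reads.append(_read("AC" * 100, [35] * 200, rid="dust_me"))
    reads.append(_read("N" * 8 + "A" * 160, [35] * 168, rid="n_heavy"))
    _kept, report = pp.preprocess_reads(reads, Platform.ILLUMINA)
    rows = report.as_rows()
    assert rows[0]["input"] == 62
    for prev, cur in zip(rows, rows[1:]):
        assert cur["input"] == prev["kept"]


def test_pacbio_reads_skip_quality_stages():
    r = _read("A" * 200, [2] * 200, platform=Platform.PACBIO)
    kept, report = pp.preprocess_reads([r], Platform.PACBIO)
    assert len(kept) == 1  # low quality irrelevant for PacBio path
    assert [s[0] for s in report.stages] == ["sanitize", "length_pre_trim"]
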