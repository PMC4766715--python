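"""Read/contig cleaning stages applied before structural annotation.

The stage order for unassembled reads is: sanitize -> pre-trim length
filter -> quality trim -> N-count filter -> post-trim length filter ->
low-complexity (DUST) filter -> de-replication -> homopolymer-aware
clustering (454 only). Assembled sequences are only sanitized and
renamed; the read-level filters do not apply to them.

Thresholds follow the pipeline's stated defaults: reads shorter than
150 bp are removed, 454 reads longer than 1000 bp are removed, quality
trimming uses Q13 (Illumina: longest contiguous all-passing substring)
or Q20 (454: both-end trim), and reads with more than five N's are
removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter, defaultdict

from .model import DEREP_PREFIX, Platform, SequenceRecord, TRIM_THRESHOLDS

MIN_READ_LEN = 150
MAX_454_LEN = 1000
MAX_N_COUNT = 5

#: IUPAC ambiguity codes replaced by N. 'U' is treated as ambiguous, not as T:
#: the working alphabet is strictly {A,C,G,T,N}.
AMBIGUOUS = set("RYSWKMBDHVU")
CANONICAL = set("ACGTN")


@dataclass
class DustParams:
    """Symmetric DUST low-complexity masking parameters.

    ``window``/``level`` are the classical defaults of the masker; a read
    is removed when at least ``removal_fraction`` of its length is masked
    (the removal criterion is exposed because masking alone does not
    define a keep/remove decision for whole reads).
    """

    window: int = 64
    level: float = 20.0
    removal_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.window <= 0 or self.level <= 0 or not (0 < self.removal_fraction <= 1):
            raise ValueError("invalid DUST parameters")


@dataclass
class FilterReport:
    """Telescoping per-stage counters: kept(stage k) == input(stage k+1)."""

    stages: list[tuple[str, int, int, Counter]] = field(default_factory=list)

    def add(self, stage: str, input_count: int, removed: int, reasons: Counter) -> None:
        if self.stages:
            prev_in, prev_rm = self.stages[-1][1], self.stages[-1][2]
            if input_count != prev_in - prev_rm:
                raise ValueError(
                    f"stage {stage}: input {input_count} != previous kept {prev_in - prev_rm}"
                )
        self.stages.append((stage, input_count, removed, reasons))

    def as_rows(self) -> list[dict]:
        return [
            {"stage": s, "input": i, "removed": r, "kept": i - r,
             "reasons": dict(sorted(c.items()))}
            for s, i, r, c in self.stages
        ]


# ---------------------------------------------------------------------------
# per-record operations


def sanitize(record: SequenceRecord) -> SequenceRecord | None:
    """Replace IUPAC ambiguity codes by N; reject on any other foreign character.

    Returns the cleaned record, or None when the sequence contains a
    character outside {A,C,G,T,N} + ambiguity codes (e.g. gaps, digits).
    """
    seq = record.seq.upper()
    chars = set(seq)
    if chars - CANONICAL - AMBIGUOUS:
        return None
    if chars & AMBIGUOUS:
        table = str.maketrans({c: "N" for c in AMBIGUOUS})
        seq = seq.translate(table)
    return SequenceRecord(
        id=record.id, seq=seq, quals=record.quals,
        platform=record.platform, original_id=record.original_id,
    )


def length_filter(record: SequenceRecord, stage: str = "pre_trim") -> str | None:
    """Return a removal reason, or None to keep.

    Both stages enforce the 150-bp minimum (strict: exactly 150 bp is
    kept); the 1000-bp maximum for 454 reads applies pre-trim only.
    """
    if len(record) < MIN_READ_LEN:
        return "shorter_than_150bp"
    if stage == "pre_trim" and record.platform == Platform.ROCHE454 and len(record) > MAX_454_LEN:
        return "454_longer_than_1000bp"
    return None


def _strip_trailing_n(seq: str, quals: list[int] | None) -> tuple[str, list[int] | None]:
    n = len(seq)
    while n > 0 and seq[n - 1] == "N":
        n -= 1
    return seq[:n], (quals[:n] if quals is not None else None)


def quality_trim(record: SequenceRecord) -> SequenceRecord:
    """Trim low-quality regions and trailing N's.

    Illumina: keep the longest contiguous substring whose every base
    quality is >= Q13 (leftmost such substring on ties). 454: trim bases
    from both ends while the end base quality is < Q20. Trailing N's are
    removed afterwards in all cases.
    """
    if record.quals is None:
        seq, quals = _strip_trailing_n(record.seq, None)
        return SequenceRecord(record.id, seq, None, record.platform, record.original_id)
    thr = TRIM_THRESHOLDS.get(record.platform)
    seq, quals = record.seq, record.quals
    if thr is not None and record.platform == Platform.ILLUMINA:
        best_start, best_len = 0, 0
        run_start, i = 0, 0
        n = len(quals)
        while i <= n:
            if i == n or quals[i] < thr:
                if i - run_start > best_len:
                    best_start, best_len = run_start, i - run_start
                run_start = i + 1
            i += 1
        seq = seq[best_start : best_start + best_len]
        quals = quals[best_start : best_start + best_len]
    elif thr is not None and record.platform == Platform.ROCHE454:
        lo, hi = 0, len(quals)
        while lo < hi and quals[lo] < thr:
            lo += 1
        while hi > lo and quals[hi - 1] < thr:
            hi -= 1
        seq, quals = seq[lo:hi], quals[lo:hi]
    seq, quals = _strip_trailing_n(seq, quals)
    return SequenceRecord(record.id, seq, quals, record.platform, record.original_id)


def n_count_filter(record: SequenceRecord) -> str | None:
    """Remove unassembled reads containing more than five N's (strict > 5)."""
    if record.seq.count("N") > MAX_N_COUNT:
        return "more_than_5_Ns"
    return None


# ---------------------------------------------------------------------------
# DUST low-complexity masking


def dust_window_score(window_seq: str) -> float:
    """Classical DUST score of one window: 10 * sum c_t(c_t-1)/2 over
    triplet counts c_t, normalized by (number of triplets - 1).

    Windows with fewer than two triplets score 0. A perfect mono- or
    dinucleotide repeat scores far above the default level of 20; a
    uniform-random window scores ~5.
    """
    n_trip = len(window_seq) - 2
    if n_trip < 2:
        return 0.0
    counts: Counter = Counter(window_seq[i : i + 3] for i in range(n_trip))
    s = sum(c * (c - 1) // 2 for c in counts.values())
    return 10.0 * s / (n_trip - 1)


def dust_mask(
    record: SequenceRecord, params: DustParams | None = None
) -> tuple[list[tuple[int, int]], bool]:
    """Mask low-complexity intervals and decide removal.

    Windows of ``params.window`` bases (step 1; a sequence shorter than
    the window is one window) whose score exceeds ``params.level`` are
    masked whole; returns merged masked intervals (1-based closed) and
    True when the masked fraction reaches ``params.removal_fraction``.
    """
    params = params or DustParams()
    seq = record.seq
    n = len(seq)
    w = min(params.window, n)
    masked = [False] * n
    if w >= 5:  # need >=2 triplets for a defined score
        for i in range(0, n - w + 1):
            if dust_window_score(seq[i : i + w]) > params.level:
                for j in range(i, i + w):
                    masked[j] = True
    intervals: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if masked[i]:
            j = i
            while j + 1 < n and masked[j + 1]:
                j += 1
            intervals.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    frac = sum(masked) / n if n else 0.0
    return intervals, frac >= params.removal_fraction


# ---------------------------------------------------------------------------
# de-replication and 454 clustering


def _is_replicate(shorter: str, longer: str, identity: float) -> bool:
    """Prefix-anchored gap-free comparison over the shorter read's length."""
    matches = sum(1 for a, b in zip(shorter, longer) if a == b)
    return matches >= identity * len(shorter)


def dereplicate(
    reads: list[SequenceRecord], platform: Platform, identity: float = 0.95
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Remove artificial replicate reads, keeping the longest copy.

    Reads are bucketed by an exact prefix (3 bp for 454, 5 bp for
    Illumina); a shorter read is a replicate of a longer retained read
    when their gap-free comparison over the shorter length matches at
    >= ``identity``. Equal-length ties retain the lexicographically
    smallest id. Returns (retained reads in input order, removed id ->
    retained id it replicated).
    """
    prefix_len = DEREP_PREFIX[platform]
    buckets: dict[str, list[SequenceRecord]] = defaultdict(list)
    for r in reads:
        buckets[r.seq[:prefix_len]].append(r)
    removed: dict[str, str] = {}
    for bucket in buckets.values():
        bucket.sort(key=lambda r: (-len(r.seq), r.id))
        kept: list[SequenceRecord] = []
        for r in bucket:
            rep_of = next(
                (k for k in kept if _is_replicate(r.seq, k.seq, identity)), None
            )
            if rep_of is not None:
                removed[r.id] = rep_of.id
            else:
                kept.append(r)
    return [r for r in reads if r.id not in removed], removed


def compress_homopolymers(seq: str) -> str:
    """Collapse runs of identical bases to a single base ('non-tandem' form)."""
    out = []
    prev = ""
    for c in seq:
        if c != prev:
            out.append(c)
            prev = c
    return "".join(out)


def declust_454(
    reads: list[SequenceRecord], k: int = 16
) -> tuple[list[SequenceRecord], dict[str, list[str]]]:
    """Cluster 454 reads that are identical up to homopolymer run lengths.

    Each read is homopolymer-compressed and the compressed sequence split
    into consecutive k-mers (trailing partial k-mer dropped); reads with
    identical ordered k-mer lists form one cluster, retaining the longest
    member (ties -> lexicographically smallest id). Returns (retained
    reads in input order, representative id -> cluster member ids).
    """
    sigs: dict[tuple[str, ...], list[SequenceRecord]] = defaultdict(list)
    for r in reads:
        comp = compress_homopolymers(r.seq)
        sig = tuple(comp[i : i + k] for i in range(0, len(comp) - k + 1, k))
        sigs[sig].append(r)
    keep_ids: set[str] = set()
    clusters: dict[str, list[str]] = {}
    for members in sigs.values():
        rep = min(members, key=lambda r: (-len(r.seq), r.id))
        keep_ids.add(rep.id)
        clusters[rep.id] = sorted(m.id for m in members)
    return [r for r in reads if r.id in keep_ids], clusters


# ---------------------------------------------------------------------------
# pipeline driver


def preprocess_reads(
    reads: list[SequenceRecord],
    platform: Platform,
    dust_params: DustParams | None = None,
    derep_identity: float = 0.95,
    declust_k: int = 16,
) -> tuple[list[SequenceRecord], FilterReport]:
    """Run the full read-cleaning cascade for one platform, with accounting.

    PacBio reads get sanitize + minimum-length only (no quality model, no
    replicate artifact model applies); 454 additionally goes through
    homopolymer clustering after de-replication.
    """
    report = FilterReport()
    cur = reads

    reasons: Counter = Counter()
    kept = []
    for r in cur:
        s = sanitize(r)
        if s is None:
            reasons["foreign_characters"] += 1
        else:
            kept.append(s)
    report.add("sanitize", len(cur), len(cur) - len(kept), reasons)
    cur = kept

    reasons = Counter()
    kept = []
    for r in cur:
        why = length_filter(r, "pre_trim")
        if why:
            reasons[why] += 1
        else:
            kept.append(r)
    report.add("length_pre_trim", len(cur), len(cur) - len(kept), reasons)
    cur = kept

    if platform is Platform.PACBIO:
        return cur, report

    cur2 = [quality_trim(r) for r in cur]
    report.add("quality_trim", len(cur), 0, Counter())
    cur = cur2

    reasons = Counter()
    kept = []
    for r in cur:
        why = n_count_filter(r)
        if why:
            reasons[why] += 1
        else:
            kept.append(r)
    report.add("n_count", len(cur), len(cur) - len(kept), reasons)
    cur = kept

    reasons = Counter()
    kept = []
    for r in cur:
        why = length_filter(r, "post_trim")
        if why:
            reasons[why] += 1
        else:
            kept.append(r)
    report.add("length_post_trim", len(cur), len(cur) - len(kept), reasons)
    cur = kept

    reasons = Counter()
    kept = []
    for r in cur:
        _, remove = dust_mask(r, dust_params)
        if remove:
            reasons["low_complexity"] += 1
        else:
            kept.append(r)
    report.add("dust", len(cur), len(cur) - len(kept), reasons)
    cur = kept

    retained, removed_map = dereplicate(cur, platform, identity=derep_identity)
    report.add("dereplicate", len(cur), len(removed_map), Counter({"replicate": len(removed_map)}))
    cur = retained

    if platform is Platform.ROCHE454:
        retained, clusters = declust_454(cur, k=declust_k)
        n_rm = len(cur) - len(retained)
        report.add("declust", len(cur), n_rm, Counter({"homopolymer_cluster": n_rm}))
        cur = retained

    return cur, report
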