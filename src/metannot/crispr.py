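"""CRT-style CRISPR array detection and merging with external predictions.

The detector slides a short exact seed window (step 1) along a contig
and looks for a recurrence of the seed at a spacing compatible with one
repeat + one spacer. Seeded occurrence chains are then extended into
full repeat boundaries by column conservation, additional degenerate
copies are chained by consensus identity, partial repeat copies at
contig ends are kept and flagged truncated, and the resulting candidate
array is validated against repeat/spacer length bounds, the
spacer:repeat length-ratio band, all-vs-all repeat identity, and an
all-vs-all spacer-similarity check that rejects spacer artifacts.

Coordinates here are 0-based internally and converted to 1-based closed
intervals on the emitted arrays.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .model import CrisprArray, Feature, overlap_len


@dataclass
class CrtParams:
    """Detector thresholds and search ranges; all overridable."""

    min_repeat_len: int = 20
    max_repeat_len: int = 50
    min_spacer_len: int = 20
    max_spacer_len: int = 60
    ratio_min: float = 0.6
    ratio_max: float = 2.5
    window: int = 7
    window_step: int = 1
    min_repeats: int = 3
    min_repeat_identity: float = 0.70

    def __post_init__(self) -> None:
        if self.min_repeat_len > self.max_repeat_len:
            raise ValueError("min_repeat_len > max_repeat_len")
        if self.min_spacer_len > self.max_spacer_len:
            raise ValueError("min_spacer_len > max_spacer_len")
        if not (0 < self.min_repeat_identity <= 1):
            raise ValueError("min_repeat_identity outside (0, 1]")


@dataclass
class Rejection:
    """A candidate array that failed validation, with the firing reason."""

    contig_id: str
    start: int  # 1-based closed span of the candidate
    end: int
    reason: str


#: Per-column penalty for repeat-boundary placement: a column belongs
#: to the repeat when its conservation exceeds this. Matches the repeat
#: identity threshold; random spacer columns (expected conservation
#: ~0.5 at 3 copies, lower with more) score negative on average and
#: stop the boundary search.
BOUNDARY_PENALTY = 0.70
#: With only two aligned copies a column is either exact (1.0) or not
#: (0.5), which carries almost no signal; boundary placement on a pair
#: is kept conservative (exact columns only) and is re-run once
#: re-chaining has recruited more copies.
PAIR_BOUNDARY_PENALTY = 0.75
#: When the freely-placed boundary violates a length bound by a
#: whisker, a bounds-constrained re-fit is accepted only if it costs at
#: most this much score per moved column. A genuinely conserved column
#: with one mutated copy costs ~0.03-0.10; a genuinely random column
#: costs >= 0.2, so near-bound framing noise is repaired while truly
#: out-of-bounds arrays stay rejected.
AMBIGUOUS_COLUMN_MARGIN = 0.12

# reason codes, checked in this order
TOO_FEW_REPEATS = "too_few_repeats"
REPEAT_LENGTH = "repeat_length_out_of_bounds"
SPACER_LENGTH = "spacer_length_out_of_bounds"
RATIO = "spacer_repeat_ratio_out_of_bounds"
REPEAT_IDENTITY = "repeat_identity_below_minimum"
SPACER_ARTIFACT = "near_identical_spacers"


def gapfree_identity(a: str, b: str) -> float:
    """Fraction of matching columns over the shorter length; N matches nothing."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    m = sum(1 for x, y in zip(a, b) if x == y and x != "N")
    return m / n


def _column_conservation(bases: list[str]) -> float:
    """Majority-base fraction of one alignment column; N never counts."""
    counts = Counter(b for b in bases if b != "N")
    if not bases:
        return 0.0
    return max(counts.values(), default=0) / len(bases)


# ---------------------------------------------------------------------------
# seed scan


def scan_candidates(seq: str, params: CrtParams) -> list[tuple[int, int]]:
    """Find positions where the seed window recurs at repeat+spacer spacing.

    Returns (pos, next_pos) seed pairs, 0-based. Exact match only; seeds
    containing N are skipped (mismatches are absorbed later, during
    extension).
    """
    w = params.window
    lo = params.min_repeat_len + params.min_spacer_len
    hi = params.max_repeat_len + params.max_spacer_len
    out = []
    n = len(seq)
    for pos in range(0, n - w + 1, params.window_step):
        seed = seq[pos : pos + w]
        if "N" in seed:
            continue
        j = seq.find(seed, pos + lo, min(n, pos + hi + w))
        if j != -1 and j - pos >= lo and j - pos <= hi:
            out.append((pos, j))
    return out


def _chain_seed(seq: str, pos: int, params: CrtParams) -> list[int]:
    """Chain exact seed occurrences in both directions at valid spacings.

    Upstream chaining matters for seeds that first recur late in an
    array: boundary placement is far more reliable when every exact
    copy of the seed participates.
    """
    w = params.window
    lo = params.min_repeat_len + params.min_spacer_len
    hi = params.max_repeat_len + params.max_spacer_len
    seed = seq[pos : pos + w]
    occs = [pos]
    cur = pos
    while True:
        j = seq.find(seed, cur + lo, min(len(seq), cur + hi + w))
        if j == -1 or j - cur > hi:
            break
        occs.append(j)
        cur = j
    cur = pos
    while True:
        lo_start = max(0, cur - hi)
        j = seq.rfind(seed, lo_start, cur - lo + w)
        if j == -1 or cur - j < lo or cur - j > hi:
            break
        occs.insert(0, j)
        cur = j
    return occs


# ---------------------------------------------------------------------------
# extension


def _consensus(seqs: list[str]) -> str:
    """Per-column majority base over equal-length strings; ties alphabetical."""
    if not seqs:
        return ""
    length = min(len(s) for s in seqs)
    cols = []
    for i in range(length):
        counts = Counter(s[i] for s in seqs if s[i] != "N")
        if not counts:
            cols.append("N")
            continue
        best = max(counts.values())
        cols.append(sorted(b for b, c in counts.items() if c == best)[0])
    return "".join(cols)


def _refine_bounds(
    seq: str, anchors: list[int], L: int, params: CrtParams,
    len_bounds: tuple[int, int] | None = None,
) -> tuple[int, int, float]:
    """Re-place repeat boundaries around aligned occurrences.

    ``anchors`` are the (possibly out-of-contig for clipped end copies)
    0-based starts of the current repeat window of length ``L``. Chooses
    the contiguous column window [a, b] (relative to the anchors, a may
    be negative = extend left, a > 0 = trim) maximizing the summed
    per-column (conservation - BOUNDARY_PENALTY) score, subject to:
    window length <= max_repeat_len and, via the inter-anchor gaps,
    every implied spacer >= min_spacer_len. This both grows boundaries
    outward and trims seed-frame columns that later copies reveal to be
    non-conserved. Ties prefer the longer, then leftmost, window.

    ``len_bounds`` (lo, hi), when given, additionally restricts the
    window length (used for the near-bound re-fit). Returns (a, b,
    score); (0, L-1, -inf) signals that no feasible window exists.
    """
    lam = BOUNDARY_PENALTY if len(anchors) >= 3 else PAIR_BOUNDARY_PENALTY
    n = len(seq)
    gaps = [anchors[i + 1] - anchors[i] for i in range(len(anchors) - 1)]
    len_cap = params.max_repeat_len
    if gaps:
        len_cap = min(len_cap, min(gaps) - params.min_spacer_len)
    len_cap = max(1, len_cap)
    len_min = 1
    if len_bounds is not None:
        len_min = max(len_min, len_bounds[0])
        len_cap = min(len_cap, len_bounds[1])
    ext = params.max_repeat_len  # candidate columns beyond current bounds
    lo_col, hi_col = -ext, L - 1 + ext

    scores = []
    for j in range(lo_col, hi_col + 1):
        bases = [seq[p + j] for p in anchors if 0 <= p + j < n]
        scores.append(_column_conservation(bases) - lam if bases else -lam)

    best = (float("-inf"), 0, 0)  # sum, length, -a
    best_ab = (0, L - 1)
    prefix = [0.0]
    for s in scores:
        prefix.append(prefix[-1] + s)
    m = len(scores)
    for ai in range(m):
        bmin = ai + len_min - 1
        bmax = min(m - 1, ai + len_cap - 1)
        for bi in range(max(ai, bmin), bmax + 1):
            sc = prefix[bi + 1] - prefix[ai]
            key = (sc, bi - ai, -ai)
            if key > best:
                best = key
                best_ab = (ai + lo_col, bi + lo_col)
    return best_ab[0], best_ab[1], best[0]


def _rechain(
    seq: str, anchors: list[int], L: int, params: CrtParams,
) -> tuple[list[int], bool, bool]:
    """Chain further (possibly degenerate or truncated) copies by consensus.

    Extends the anchor list in both directions while a downstream /
    upstream window at a legal spacer distance matches the consensus at
    the identity threshold. A partial copy clipped by a contig end is
    accepted when at least ``params.window`` of its bases are in the
    contig; its anchor may lie outside [0, n). Returns (anchors,
    truncated_left, truncated_right).
    """
    n = len(seq)
    thr = params.min_repeat_identity
    trunc_left = trunc_right = False

    def window_identity(anchor: int, cons: str) -> tuple[float, int]:
        """(identity over in-contig columns, number of in-contig columns)."""
        s, e = max(0, anchor), min(n - 1, anchor + L - 1)
        if e < s:
            return 0.0, 0
        sub = seq[s : e + 1]
        cs = cons[s - anchor : s - anchor + len(sub)]
        return gapfree_identity(cs, sub), len(sub)

    def cons_now() -> str:
        segs = []
        for p in anchors:
            s, e = max(0, p), min(n - 1, p + L - 1)
            if e - s + 1 == L:
                segs.append(seq[s : e + 1])
        return _consensus(segs) if segs else ""

    # downstream
    while True:
        cons = cons_now()
        if not cons:
            break
        last = anchors[-1]
        lo = last + L + params.min_spacer_len
        hi = last + L + params.max_spacer_len
        best = None
        for s in range(lo, hi + 1):
            if s >= n:
                break
            ident, avail = window_identity(s, cons)
            if avail >= params.window and ident >= thr:
                if best is None or ident > best[0]:
                    best = (ident, s, avail < L)
        if best is None:
            break
        anchors.append(best[1])
        if best[2]:
            trunc_right = True
            break

    # upstream
    while True:
        cons = cons_now()
        if not cons:
            break
        first = anchors[0]
        hi_anchor = first - L - params.min_spacer_len
        lo_anchor = first - L - params.max_spacer_len
        best = None
        for s in range(hi_anchor, lo_anchor - 1, -1):
            if s + L - 1 < 0:
                break
            ident, avail = window_identity(s, cons)
            if avail >= params.window and ident >= thr:
                if best is None or ident > best[0]:
                    best = (ident, s, avail < L)
        if best is None:
            break
        anchors.insert(0, best[1])
        if best[2]:
            trunc_left = True
            break

    return anchors, trunc_left, trunc_right


def extend_array(
    seq: str, contig_id: str, seed_occs: list[int], params: CrtParams
) -> CrisprArray:
    """Grow a seeded occurrence chain into a full candidate array.

    Boundary refinement runs twice: once on the exact seed chain, and
    again after consensus re-chaining has recruited degenerate or
    clipped copies — the extra copies expose misframed columns that the
    seed chain alone cannot."""
    a, b, _sc = _refine_bounds(seq, seed_occs, params.window, params)
    anchors = [p + a for p in seed_occs]
    L = b - a + 1
    anchors, trunc_left, trunc_right = _rechain(seq, anchors, L, params)
    a, b, score = _refine_bounds(seq, anchors, L, params)
    anchors = [p + a for p in anchors]
    L = b - a + 1
    return _build_array(seq, contig_id, anchors, L, trunc_left, trunc_right,
                        frame_score=score)


def _build_array(
    seq: str, contig_id: str, anchors: list[int], L: int,
    trunc_left: bool, trunc_right: bool, frame_score: float = 0.0,
) -> CrisprArray:
    n = len(seq)
    intervals = []
    for i, p in enumerate(anchors):
        s, e = max(0, p), min(n - 1, p + L - 1)
        if s > p and i == 0:
            trunc_left = True
        if e < p + L - 1 and i == len(anchors) - 1:
            trunc_right = True
        if e >= s:
            intervals.append((s, e))
    repeats = [(s + 1, e + 1) for (s, e) in intervals]
    spacers = [
        (repeats[i][1] + 1, repeats[i + 1][0] - 1) for i in range(len(repeats) - 1)
    ]
    repeat_seqs = [seq[s : e + 1] for (s, e) in intervals]
    spacer_seqs = [seq[a0 - 1 : b0] for (a0, b0) in spacers]
    arr = CrisprArray(
        contig_id=contig_id, repeats=repeats, spacers=spacers,
        repeat_seqs=repeat_seqs, spacer_seqs=spacer_seqs,
        source="crt", truncated_left=trunc_left, truncated_right=trunc_right,
    )
    full_idx = arr.full_repeat_indices()
    full = [repeat_seqs[i] for i in full_idx]
    arr.consensus_repeat = _consensus(full) if full else (repeat_seqs[0] if repeat_seqs else "")
    arr._frame = (list(anchors), L, frame_score)  # for the near-bound re-fit
    return arr


def constrained_refit(
    seq: str, arr: CrisprArray, params: CrtParams
) -> CrisprArray | None:
    """Re-place boundaries under the length bounds after a near-miss.

    When the free boundary optimum violates a repeat/spacer length or
    ratio bound, the window is re-optimized subject to: repeat length in
    [min_repeat_len, max_repeat_len] and every implied spacer within
    [min_spacer_len, max_spacer_len]. The refit is returned only when it
    sacrifices at most AMBIGUOUS_COLUMN_MARGIN of score per moved
    column — i.e. only genuinely ambiguous boundary columns moved.
    """
    frame = getattr(arr, "_frame", None)
    if frame is None or arr.truncated_left or arr.truncated_right:
        return None
    anchors, L, free_score = frame
    if len(anchors) < 2:
        return None
    gaps = [anchors[i + 1] - anchors[i] for i in range(len(anchors) - 1)]
    lo = max(params.min_repeat_len, max(gaps) - params.max_spacer_len)
    hi = min(params.max_repeat_len, min(gaps) - params.min_spacer_len)
    if lo > hi:
        return None
    a, b, score = _refine_bounds(seq, anchors, L, params, len_bounds=(lo, hi))
    if score == float("-inf"):
        return None
    moved = abs(a) + abs(b - (L - 1))
    if moved == 0 or free_score - score > AMBIGUOUS_COLUMN_MARGIN * moved:
        return None
    return _build_array(seq, arr.contig_id, [p + a for p in anchors],
                        b - a + 1, False, False, frame_score=score)


# ---------------------------------------------------------------------------
# validation


def validate_array(arr: CrisprArray, params: CrtParams) -> tuple[bool, str]:
    """Enforce all array invariants; returns (accepted, reason code)."""
    if len(arr.repeats) < params.min_repeats:
        return False, TOO_FEW_REPEATS
    full_idx = arr.full_repeat_indices()
    full_lens = [arr.repeats[i][1] - arr.repeats[i][0] + 1 for i in full_idx]
    for ln in full_lens:
        if not (params.min_repeat_len <= ln <= params.max_repeat_len):
            return False, REPEAT_LENGTH
    spacer_lens = [b - a + 1 for (a, b) in arr.spacers]
    for ln in spacer_lens:
        if not (params.min_spacer_len <= ln <= params.max_spacer_len):
            return False, SPACER_LENGTH
    if full_lens and spacer_lens:
        ratio = (sum(spacer_lens) / len(spacer_lens)) / (sum(full_lens) / len(full_lens))
        if not (params.ratio_min <= ratio <= params.ratio_max):
            return False, RATIO
    full_seqs = [arr.repeat_seqs[i] for i in full_idx]
    for i in range(len(full_seqs)):
        for j in range(i + 1, len(full_seqs)):
            if gapfree_identity(full_seqs[i], full_seqs[j]) < params.min_repeat_identity:
                return False, REPEAT_IDENTITY
    for i in range(len(arr.spacer_seqs)):
        for j in range(i + 1, len(arr.spacer_seqs)):
            if gapfree_identity(arr.spacer_seqs[i], arr.spacer_seqs[j]) >= params.min_repeat_identity:
                return False, SPACER_ARTIFACT
    return True, ""


# ---------------------------------------------------------------------------
# top-level detection


def detect_crisprs(
    seq: str, contig_id: str, params: CrtParams | None = None
) -> tuple[list[CrisprArray], list[Rejection]]:
    """Detect CRISPR arrays on one contig (given strand only).

    Returns accepted arrays plus deduplicated rejected candidates with
    reason codes. After an accepted array the scan resumes past its end;
    rejected candidates do not block the scan.
    """
    params = params or CrtParams()
    arrays: list[CrisprArray] = []
    rejections: list[Rejection] = []
    seen_rejects: set[tuple[int, int, str]] = set()
    w = params.window
    lo = params.min_repeat_len + params.min_spacer_len
    hi = params.max_repeat_len + params.max_spacer_len
    n = len(seq)
    pos = 0
    while pos <= n - w:
        seed = seq[pos : pos + w]
        if "N" in seed:
            pos += params.window_step
            continue
        j = seq.find(seed, pos + lo, min(n, pos + hi + w))
        if j == -1 or j - pos > hi:
            pos += params.window_step
            continue
        occs = _chain_seed(seq, pos, params)
        arr = extend_array(seq, contig_id, occs, params)
        ok, reason = validate_array(arr, params)
        if not ok and reason in (REPEAT_LENGTH, SPACER_LENGTH, RATIO):
            refit = constrained_refit(seq, arr, params)
            if refit is not None:
                ok2, _r2 = validate_array(refit, params)
                if ok2:
                    arr, ok = refit, True
        if ok:
            arrays.append(arr)
            pos = arr.end  # 1-based end == 0-based index past the array
        else:
            key = (arr.start, arr.end, reason)
            if key not in seen_rejects:
                seen_rejects.add(key)
                rejections.append(Rejection(contig_id, arr.start, arr.end, reason))
            pos += params.window_step
    return arrays, rejections


def merge_crispr(
    internal: list[CrisprArray], external: list[CrisprArray]
) -> list[CrisprArray]:
    """Concatenate internal and external predictions, internal wins overlaps.

    An external array whose genomic span overlaps any internal array on
    the same contig by >= 1 bp is dropped; everything else is kept,
    sorted by (contig, start).
    """
    kept = list(internal)
    for ext in external:
        clash = any(
            ext.contig_id == arr.contig_id
            and overlap_len((ext.start, ext.end), (arr.start, arr.end)) > 0
            for arr in internal
        )
        if not clash:
            kept.append(ext)
    return sorted(kept, key=lambda a: (a.contig_id, a.start))


# ---------------------------------------------------------------------------
# interchange


def array_to_feature(arr: CrisprArray, locus_tag: str = "") -> Feature:
    """Convert an array to a repeat_region Feature with repeat/spacer children."""
    parent = Feature(
        seqid=arr.contig_id, start=arr.start, end=arr.end, strand="+",
        ftype="repeat_region", locus_tag=locus_tag, source=f"crispr_{arr.source}",
        attributes={
            "rpt_family": "CRISPR",
            "consensus_repeat": arr.consensus_repeat,
            "n_repeats": str(len(arr.repeats)),
        },
    )
    for k, (s, e) in enumerate(arr.repeats, start=1):
        parent.children.append(
            Feature(seqid=arr.contig_id, start=s, end=e, strand="+",
                    ftype="direct_repeat", source=parent.source,
                    attributes={"ID": f"{locus_tag}_r{k}"} if locus_tag else {})
        )
    for k, (s, e) in enumerate(arr.spacers, start=1):
        parent.children.append(
            Feature(seqid=arr.contig_id, start=s, end=e, strand="+",
                    ftype="spacer", source=parent.source,
                    attributes={"ID": f"{locus_tag}_s{k}"} if locus_tag else {})
        )
    return parent


def external_gff_to_arrays(features: list[Feature]) -> list[CrisprArray]:
    """Interpret external repeat_region GFF records as opaque arrays.

    Only the span is trusted (no repeat/spacer substructure is required
    of external predictions); such arrays carry source='external' and
    empty repeat lists are represented by the whole span as one repeat.
    """
    out = []
    for f in features:
        if f.ftype != "repeat_region":
            continue
        out.append(
            CrisprArray(
                contig_id=f.seqid, repeats=[(f.start, f.end)], spacers=[],
                repeat_seqs=[], spacer_seqs=[], source="external",
            )
        )
    return out
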