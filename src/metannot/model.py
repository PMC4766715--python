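"""Core domain types shared across pipeline stages.

All genomic coordinates in this package are 1-based, fully closed
intervals (GFF3 convention). FASTA/FASTQ 0-based offsets are converted
on ingest, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Platform(str, Enum):
    """Sequencing platform / assembly status of an input sequence."""

    ILLUMINA = "illumina"
    ROCHE454 = "454"
    PACBIO = "pacbio"
    ASSEMBLED = "assembled"


#: Per-platform quality-trim thresholds (Phred).
TRIM_THRESHOLDS = {Platform.ILLUMINA: 13, Platform.ROCHE454: 20}

#: Exact-prefix anchor lengths for de-replication.
DEREP_PREFIX = {Platform.ROCHE454: 3, Platform.ILLUMINA: 5}


@dataclass
class SequenceRecord:
    """One nucleotide sequence with optional per-base Phred qualities.

    ``id`` is the pipeline-internal (renamed) identifier; ``original_id``
    preserves the submitter's name so the two form a bijection recorded
    in the name map.
    """

    id: str
    seq: str
    quals: Optional[list[int]] = None
    platform: Platform = Platform.ASSEMBLED
    original_id: str = ""

    def __post_init__(self) -> None:
        if not self.original_id:
            self.original_id = self.id
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quals)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class NameMap:
    """Bijective mapping between renamed ids and original ids."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        new_ids = [p[0] for p in self.pairs]
        old_ids = [p[1] for p in self.pairs]
        if len(set(new_ids)) != len(new_ids) or len(set(old_ids)) != len(old_ids):
            raise ValueError("name map is not a bijection")

    def to_original(self) -> dict[str, str]:
        return dict(self.pairs)

    def to_new(self) -> dict[str, str]:
        return {old: new for new, old in self.pairs}


@dataclass
class Feature:
    """A finalized, typed feature placed on scaffold (or contig) coordinates."""

    seqid: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str  # '+', '-' or '.'
    ftype: str   # CDS / tRNA / rRNA / repeat_region / direct_repeat / spacer
    locus_tag: str = ""
    score: Optional[float] = None
    source: str = "metannot"
    attributes: dict = field(default_factory=dict)
    children: list["Feature"] = field(default_factory=list)
    translation: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature on {self.seqid}: start {self.start} > end {self.end}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class GeneModel:
    """One caller-attributed CDS candidate in contig coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str
    caller: str  # genemark / prodigal / mga / fraggenescan
    partial5: bool = False
    partial3: bool = False
    translation: str = ""

    @property
    def stop_coord(self) -> int:
        """Coordinate of the 3' (stop) end in translation sense."""
        return self.end if self.strand == "+" else self.start

    @property
    def vote_key(self) -> tuple[str, str, int]:
        return (self.contig_id, self.strand, self.stop_coord)


@dataclass
class CrisprArray:
    """Alternating direct repeats and spacers on one contig.

    ``repeats`` / ``spacers`` are ordered, non-overlapping (start, end)
    intervals; ``truncated_left`` / ``truncated_right`` flag partial
    repeat copies clipped by a contig end.
    """

    contig_id: str
    repeats: list[tuple[int, int]]
    spacers: list[tuple[int, int]]
    repeat_seqs: list[str]
    spacer_seqs: list[str]
    consensus_repeat: str = ""
    source: str = "crt"  # crt | external
    truncated_left: bool = False
    truncated_right: bool = False

    @property
    def start(self) -> int:
        return self.repeats[0][0]

    @property
    def end(self) -> int:
        return self.repeats[-1][1]

    def full_repeat_indices(self) -> list[int]:
        """Indices of repeat copies not clipped by a contig end."""
        idx = list(range(len(self.repeats)))
        if self.truncated_left and idx:
            idx = idx[1:]
        if self.truncated_right and idx:
            idx = idx[:-1]
        return idx


@dataclass
class RnaPrediction:
    """One tRNA or rRNA prediction from a single-domain tool run."""

    contig_id: str
    start: int
    end: int
    strand: str
    rna_type: str     # tRNA / rRNA_5S / rRNA_16S / rRNA_23S
    domain_run: str   # bacteria / archaea / eukaryota
    score: float
    meta: str = ""    # anticodon or model isoform

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("RNA prediction with start > end")


@dataclass
class Hit:
    """One homology or profile match from a tabular search report."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    rank: int = 1

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("negative e-value")
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ValueError("hit with reversed coordinates")


@dataclass
class AnnotationRecord:
    """Per-gene functional assignments and product name."""

    locus_tag: str
    cog: Optional[tuple[str, Hit]] = None
    pfams: list[tuple[str, Hit]] = field(default_factory=list)
    kos: list[str] = field(default_factory=list)
    ecs: list[str] = field(default_factory=list)
    top_hit: Optional[str] = None
    product: str = ""
    product_branch: str = ""


def overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length of the intersection of two 1-based closed intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
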