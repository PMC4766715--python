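"""Reading and writing of the external formats the pipeline touches.

FASTA goes through Biopython. FASTQ is read by a small tolerant 4-line
reader so that a single record whose quality string length disagrees
with its sequence length can be rejected and logged without aborting
the whole file (the strict library parser raises and stops at the first
such record). GFF3 is written directly and read back through gffutils.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import gffutils.iterators
from Bio import SeqIO

from .model import Feature, NameMap, Platform, SequenceRecord

logger = logging.getLogger(__name__)

GFF_HEADER = "##gff-version 3"


class SeqFormatError(ValueError):
    """A structurally malformed sequence file or record."""


# ---------------------------------------------------------------------------
# sequence input


def _read_fastq_tolerant(path: Path, platform: Platform) -> list[SequenceRecord]:
    """4-line FASTQ reader; length-mismatched records are rejected and logged."""
    records: list[SequenceRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    # trailing blank lines are tolerated
    while lines and not lines[-1]:
        lines.pop()
    if len(lines) % 4 != 0:
        raise SeqFormatError(f"{path}: FASTQ line count {len(lines)} is not a multiple of 4")
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        idx = i // 4
        if not header.startswith("@") or not plus.startswith("+"):
            raise SeqFormatError(f"{path}: malformed FASTQ record at index {idx}")
        if len(seq) != len(qual):
            logger.warning(
                "rejected FASTQ record %d (%s): sequence length %d != quality length %d",
                idx, header[1:].split()[0] if len(header) > 1 else "?", len(seq), len(qual),
            )
            continue
        name = header[1:].split()[0]
        quals = [ord(c) - 33 for c in qual]
        if any(q < 0 for q in quals):
            raise SeqFormatError(f"{path}: invalid quality character in record {idx}")
        records.append(
            SequenceRecord(id=name, seq=seq.upper(), quals=quals, platform=platform)
        )
    return records


def read_sequences(path: str | Path, format: str, platform: Platform | str) -> list[SequenceRecord]:
    """Read a multi-FASTA or FASTQ file into SequenceRecords.

    Sequences are uppercased but otherwise verbatim; FASTQ records carry
    Sanger Phred+33 qualities. A FASTQ record whose sequence and quality
    lengths differ is dropped with a logged reason; any other malformed
    record is a hard error naming the record index.
    """
    path = Path(path)
    platform = Platform(platform)
    if format == "fastq":
        return _read_fastq_tolerant(path, platform)
    if format != "fasta":
        raise ValueError(f"unknown sequence format {format!r}")
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(
                SequenceRecord(id=rec.id, seq=str(rec.seq).upper(), platform=platform)
            )
    except ValueError as exc:  # pragma: no cover - biopython names the spot
        raise SeqFormatError(f"{path}: malformed FASTA near record {len(records)}: {exc}")
    return records


# ---------------------------------------------------------------------------
# renaming


def rename_sequences(
    records: Iterable[SequenceRecord], prefix: str = "SEQ"
) -> tuple[list[SequenceRecord], NameMap]:
    """Assign sequential tool-safe ids (``SEQ_000001`` ...).

    Guarantees unique new ids even when input names collide; the returned
    NameMap pairs (new_id, original_id) in input order. Duplicate original
    ids are disambiguated in the map with a ``#<ordinal>`` suffix so the
    map stays bijective while still recording the submitted name.
    """
    out: list[SequenceRecord] = []
    pairs: list[tuple[str, str]] = []
    seen_originals: dict[str, int] = {}
    for i, rec in enumerate(records, start=1):
        new_id = f"{prefix}_{i:06d}"
        orig = rec.original_id or rec.id
        n = seen_originals.get(orig, 0)
        seen_originals[orig] = n + 1
        mapped = orig if n == 0 else f"{orig}#{n + 1}"
        out.append(
            SequenceRecord(
                id=new_id, seq=rec.seq, quals=rec.quals,
                platform=rec.platform, original_id=mapped,
            )
        )
        pairs.append((new_id, mapped))
    return out, NameMap(pairs=pairs)


def write_name_map(name_map: NameMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for new_id, old_id in name_map.pairs:
            fh.write(f"{new_id}\t{old_id}\n")


def read_name_map(path: str | Path) -> NameMap:
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            new_id, old_id = line.split("\t")
            pairs.append((new_id, old_id))
    return NameMap(pairs=pairs)


# ---------------------------------------------------------------------------
# GFF3


def _fmt_attributes(feat: Feature) -> str:
    parts = []
    if feat.locus_tag:
        parts.append(f"ID={feat.locus_tag};locus_tag={feat.locus_tag}")
    for k, v in sorted(feat.attributes.items()):
        if k in ("ID", "locus_tag"):
            continue
        parts.append(f"{k}={v}")
    return ";".join(parts) if parts else "."


def write_gff(
    features: list[Feature], path: str | Path, seq_lengths: dict[str, int] | None = None
) -> None:
    """Write features (with any children, e.g. CRISPR repeat/spacer rows) as GFF3.

    ``seq_lengths``, when given, is used both for ``##sequence-region``
    pragmas and to hard-fail on features that extend beyond sequence ends.
    """
    lines = [GFF_HEADER]
    if seq_lengths:
        for sid, ln in seq_lengths.items():
            lines.append(f"##sequence-region {sid} 1 {ln}")

    def emit(feat: Feature, parent: str | None = None) -> None:
        if seq_lengths is not None and feat.seqid in seq_lengths:
            if feat.end > seq_lengths[feat.seqid] or feat.start < 1:
                raise ValueError(
                    f"feature {feat.locus_tag or feat.ftype} [{feat.start},{feat.end}] "
                    f"exceeds sequence {feat.seqid} (length {seq_lengths[feat.seqid]})"
                )
        attrs = _fmt_attributes(feat)
        if parent:
            attrs = f"Parent={parent}" if attrs == "." else f"{attrs};Parent={parent}"
        score = "." if feat.score is None else f"{feat.score:g}"
        lines.append(
            "\t".join(
                [feat.seqid, feat.source, feat.ftype, str(feat.start), str(feat.end),
                 score, feat.strand, ".", attrs]
            )
        )
        for child in feat.children:
            emit(child, parent=feat.locus_tag or None)

    for feat in features:
        emit(feat)
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff(path: str | Path) -> list[Feature]:
    """Read a GFF3 file back into flat Features (children not re-nested)."""
    feats: list[Feature] = []
    for rec in gffutils.iterators.DataIterator(str(path)):
        attrs = {k: v[0] for k, v in rec.attributes.items() if v}
        score = None if rec.score in (".", "", None) else float(rec.score)
        feats.append(
            Feature(
                seqid=rec.seqid, start=rec.start, end=rec.end,
                strand=rec.strand or ".", ftype=rec.featuretype,
                locus_tag=attrs.get("locus_tag", attrs.get("ID", "")),
                score=score, source=rec.source, attributes=attrs,
            )
        )
    return feats


# ---------------------------------------------------------------------------
# protein FASTA


def write_protein_fasta(genes: list[Feature], path: str | Path) -> None:
    """One record per CDS, header = locus tag. Missing translation is a hard error."""
    with open(path, "w") as fh:
        for gene in genes:
            if gene.ftype != "CDS":
                continue
            if not gene.translation:
                raise ValueError(f"CDS {gene.locus_tag or gene.span} has no translation")
            fh.write(f">{gene.locus_tag}\n")
            for i in range(0, len(gene.translation), 60):
                fh.write(gene.translation[i : i + 60] + "\n")


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# coverage


def read_coverage(path: str | Path | None, known_ids: set[str] | None = None) -> dict[str, float]:
    """Two-column TSV (contig id, mean depth) -> coverage map.

    Negative depths are hard errors; ids not in ``known_ids`` warn but stay.
    A ``None`` path yields an empty map (coverage is optional input).
    """
    if path is None:
        return {}
    cov: dict[str, float] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cid, depth_s = line.split("\t")[:2]
            depth = float(depth_s)
            if depth < 0:
                raise ValueError(f"{path} line {ln}: negative coverage {depth} for {cid}")
            if known_ids is not None and cid not in known_ids:
                logger.warning("coverage entry for unknown contig %s kept", cid)
            cov[cid] = depth
    return cov
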