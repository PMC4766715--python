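"""Merging per-domain tRNA and rRNA prediction runs.

A metagenome mixes the three domains of life, so each RNA predictor is
run once per domain (bacteria, archaea, eukaryota) and the per-locus
best-scoring prediction is kept. A locus is defined by same contig,
same strand, and span overlap of at least half the shorter span;
grouping is transitive. tRNA and rRNA predictions are merged in
separate competition spaces — their tool scores are not comparable.
"""

from __future__ import annotations

from collections import defaultdict

from .model import RnaPrediction, overlap_len

DOMAIN_PRIORITY = {"bacteria": 0, "archaea": 1, "eukaryota": 2}


def _locus_clusters(preds: list[RnaPrediction]) -> list[list[RnaPrediction]]:
    """Union-find clustering by >=50%-of-shorter-span overlap on one strand."""
    by_key: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, p in enumerate(preds):
        by_key[(p.contig_id, p.strand)].append(i)
    parent = list(range(len(preds)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for idxs in by_key.values():
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                pa, pb = preds[idxs[a]], preds[idxs[b]]
                ov = overlap_len((pa.start, pa.end), (pb.start, pb.end))
                shorter = min(pa.end - pa.start + 1, pb.end - pb.start + 1)
                if ov * 2 >= shorter:
                    union(idxs[a], idxs[b])
    clusters: dict[int, list[RnaPrediction]] = defaultdict(list)
    for i in range(len(preds)):
        clusters[find(i)].append(preds[i])
    return list(clusters.values())


def _pick_best(cluster: list[RnaPrediction]) -> RnaPrediction:
    """Highest score; ties broken bacteria > archaea > eukaryota, then start."""
    return min(
        cluster,
        key=lambda p: (-p.score, DOMAIN_PRIORITY.get(p.domain_run, 9), p.start,
                       p.end, p.rna_type),
    )


def merge_domain_runs(predictions: list[RnaPrediction]) -> list[RnaPrediction]:
    """Collapse 1-3 per-domain runs to one best-scoring prediction per locus.

    tRNAs and rRNAs are handled independently; output is sorted by
    (contig, start, end) and the operation is idempotent and invariant
    to input order.
    """
    trnas = [p for p in predictions if p.rna_type == "tRNA"]
    rrnas = [p for p in predictions if p.rna_type != "tRNA"]
    out: list[RnaPrediction] = []
    for group in (trnas, rrnas):
        for cluster in _locus_clusters(group):
            out.append(_pick_best(cluster))
    return sorted(out, key=lambda p: (p.contig_id, p.start, p.end, p.rna_type))


# ---------------------------------------------------------------------------
# evidence-file parsers


def read_trna_table(path, domain_run: str) -> list[RnaPrediction]:
    """Parse tRNA-scanner tabular output (one run, one domain).

    Layout (tab-separated, 3 header lines): sequence name, tRNA number,
    begin, end, tRNA type, anticodon, intron begin, intron end, score.
    Begin > end encodes the minus strand.
    """
    preds = []
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith(("Sequence", "Name", "--------")) or not line.strip():
            continue
        parts = [p.strip() for p in line.rstrip("\n").split("\t")]
        name, _num, begin, end, ttype, anticodon = parts[:6]
        score = float(parts[8])
        b, e = int(begin), int(end)
        strand = "+" if b <= e else "-"
        start, stop = min(b, e), max(b, e)
        preds.append(
            RnaPrediction(
                contig_id=name, start=start, end=stop, strand=strand,
                rna_type="tRNA", domain_run=domain_run, score=score,
                meta=f"{ttype}-{anticodon}",
            )
        )
    return preds


def read_rrna_tblout(path, domain_run: str) -> list[RnaPrediction]:
    """Parse HMMER nhmmer/hmmsearch --tblout rows into rRNA predictions.

    Whitespace-split fixed columns: target name, target accession, query
    name (model: 5S/16S/23S isoform), query accession, hmm from/to, ali
    from/to, env from/to, ..., strand, e-value, score. Only the target
    name, model name, alignment coordinates, strand and bit score are
    used. Model names must contain 5S, 16S or 23S.
    """
    preds = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            target, model = f[0], f[2]
            ali_from, ali_to = int(f[6]), int(f[7])
            strand = f[11]
            score = float(f[13])
            for iso in ("5S", "16S", "23S"):
                if iso in model:
                    rtype = f"rRNA_{iso}"
                    break
            else:
                continue
            preds.append(
                RnaPrediction(
                    contig_id=target, start=min(ali_from, ali_to),
                    end=max(ali_from, ali_to), strand=strand,
                    rna_type=rtype, domain_run=domain_run, score=score, meta=model,
                )
            )
    return preds


def write_rna_tsv(preds: list[RnaPrediction], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tstart\tend\tstrand\trna_type\tdomain_run\tscore\tmeta\n")
        for p in preds:
            fh.write(
                f"{p.contig_id}\t{p.start}\t{p.end}\t{p.strand}\t{p.rna_type}"
                f"\t{p.domain_run}\t{p.score:g}\t{p.meta}\n"
            )
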