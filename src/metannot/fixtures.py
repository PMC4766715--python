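"""Synthetic dataset and evidence-file generation.

Everything the pipeline consumes can be generated here from a seed:
scaffolds/contigs with planted protein-coding genes, CRISPR arrays and
RNA loci; four caller GFFs derived from the planted genes with seeded
start-shift/drop perturbations; per-domain tRNA/rRNA evidence tables;
COG/Pfam/protein hit tables; toy reference tables; a coverage map; and
a ground-truth manifest for assertions. Identical seeds give identical
files.

The generator emulates the *decision-relevant* structure of real data
(coordinates, scores, thresholds, conflicts), not its biological
realism: intergenic sequence is uniform random, genes are stop-free
codon runs, and hit scores are drawn from simple ranges around the
pipeline's cutoffs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .consensus import combine_gene_calls
from .model import GeneModel, SequenceRecord

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}
_NONSTOP = [a + b + c for a in BASES for b in BASES for c in BASES
            if a + b + c not in STOP_CODONS]

CALLERS = ["genemark", "prodigal", "mga", "fraggenescan"]


# ---------------------------------------------------------------------------
# sequence primitives


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def orf_seq(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-2) stop-free codons + TAA; length = 3*n_codons."""
    body = [_NONSTOP[i] for i in rng.integers(0, len(_NONSTOP), size=n_codons - 2)]
    return "ATG" + "".join(body) + "TAA"


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Point substitutions at the given per-base rate."""
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = BASES[(BASES.index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


# ---------------------------------------------------------------------------
# CRISPR planting


@dataclass
class PlantedArray:
    repeat_len: int
    spacer_lens: list[int]
    copies: int
    mutation: float
    seq: str = ""
    repeats_rel: list[tuple[int, int]] = field(default_factory=list)  # 0-based in block


def plant_crispr(
    rng: np.random.Generator,
    repeat_len: int | None = None,
    spacer_range: tuple[int, int] = (20, 60),
    copies: int | None = None,
    mutation: float | None = None,
    nonconserved_flanks: bool = False,
) -> PlantedArray:
    """Build one CRISPR array block within the detector's parameter bounds.

    Spacer lengths are drawn so the mean spacer:repeat ratio stays inside
    [0.6, 2.5]. ``nonconserved_flanks`` forces the first and last base of
    every spacer to cycle through distinct bases across copies, pinning
    the true repeat boundary (used by bound-violation fixtures).
    """
    repeat_len = int(repeat_len if repeat_len is not None else rng.integers(20, 51))
    copies = int(copies if copies is not None else rng.integers(3, 7))
    mutation = float(mutation if mutation is not None else rng.uniform(0.0, 0.10))
    lo = max(spacer_range[0], int(np.ceil(0.6 * repeat_len)))
    hi = min(spacer_range[1], int(np.floor(2.5 * repeat_len)))
    if lo > hi:
        lo = hi = max(spacer_range[0], min(spacer_range[1], repeat_len))
    spacer_lens = [int(rng.integers(lo, hi + 1)) for _ in range(copies - 1)]
    repeat = random_seq(rng, repeat_len)
    # draw mutated copies until they respect the 70% all-vs-all identity
    # bound the array is claimed to satisfy (high mutation rates on short
    # repeats can otherwise push a pair below it by chance)
    for _attempt in range(100):
        copies_seq = [mutate(rng, repeat, mutation) for _ in range(copies)]
        idents = [
            sum(a == b for a, b in zip(x, y)) / repeat_len
            for i, x in enumerate(copies_seq) for y in copies_seq[i + 1:]
        ]
        if not idents or min(idents) >= 0.70:
            break
    parts: list[str] = []
    repeats_rel: list[tuple[int, int]] = []
    pos = 0
    for c in range(copies):
        rep = copies_seq[c]
        parts.append(rep)
        repeats_rel.append((pos, pos + len(rep) - 1))
        pos += len(rep)
        if c < copies - 1:
            sp = random_seq(rng, spacer_lens[c])
            if nonconserved_flanks:
                first = BASES[(c + 1) % 4]
                last = BASES[(c + 2) % 4]
                sp = first + sp[1:-1] + last
            parts.append(sp)
            pos += len(sp)
    return PlantedArray(
        repeat_len=repeat_len, spacer_lens=spacer_lens, copies=copies,
        mutation=mutation, seq="".join(parts), repeats_rel=repeats_rel,
    )


_PIN = 8  # pinned columns on each side of the planted repeat boundary


def _nonperiodic_seq(rng: np.random.Generator, n: int) -> str:
    """Random sequence with no strong shifted self-identity or long runs.

    A self-similar repeat unit can create an alternative, off-phase but
    genuinely rule-conforming array inside a bound-violation fixture,
    voiding its 'violates exactly one bound' construction.
    """
    for _ in range(200):
        s = random_seq(rng, n)
        if max(len(list(g)) for _b, g in itertools.groupby(s)) > 3:
            continue
        shifted = max(
            (sum(a == b for a, b in zip(s[k:], s)) / (n - k) for k in range(1, n)),
            default=0.0,
        )
        if shifted <= 0.5:
            return s
    return s  # pragma: no cover - practically unreachable for n >= 12


def _pinned_spacer(rng: np.random.Generator, n: int, idx: int) -> str:
    """Spacer whose first/last _PIN bases are pairwise distinct across copies.

    For spacer index ``idx``, boundary-adjacent column j carries base
    (idx + j) mod 4 — aligned across array copies these columns are all
    different, so no boundary column can appear conserved and the
    planted repeat frame is unambiguous.
    """
    mid = random_seq(rng, n - 2 * _PIN)
    left = "".join(BASES[(idx + j) % 4] for j in range(_PIN))
    right = "".join(BASES[(idx + j) % 4] for j in range(_PIN, 0, -1))
    return left + mid + right


def plant_violation(rng: np.random.Generator, kind: str) -> PlantedArray:
    """An array violating exactly one detector bound, mutation-free.

    Kinds: ``two_repeats`` (only 2 copies), ``short_repeat`` (19-bp
    repeat), ``ratio`` (spacer:repeat ratio 2.75). Spacers and the
    array's outer margins carry pinned non-conserved boundary columns
    (see ``_pinned_spacer``) so that the planted frame cannot drift and
    exactly the intended bound is violated.
    """
    if kind == "two_repeats":
        repeat_len, copies = int(rng.integers(24, 36)), 2
        spacer_len = lambda: int(rng.integers(28, 41))  # noqa: E731
    elif kind == "short_repeat":
        repeat_len, copies = 19, int(rng.integers(4, 6))
        spacer_len = lambda: int(rng.integers(26, 41))  # noqa: E731
    elif kind == "ratio":
        repeat_len, copies = 20, int(rng.integers(3, 6))
        spacer_len = lambda: 55  # noqa: E731
    else:
        raise ValueError(f"unknown violation kind {kind!r}")
    arr = PlantedArray(repeat_len=repeat_len, spacer_lens=[], copies=copies,
                       mutation=0.0)
    repeat = _nonperiodic_seq(rng, repeat_len)
    n_sp = copies - 1
    # outer margins continue the pinned-column pattern for the end copies
    left_margin = "".join(BASES[(-1 + j) % 4] for j in range(_PIN, 0, -1))
    right_margin = "".join(BASES[(n_sp + j) % 4] for j in range(_PIN))
    parts, pos = [left_margin], _PIN
    for c in range(copies):
        parts.append(repeat)
        arr.repeats_rel.append((pos, pos + repeat_len - 1))
        pos += repeat_len
        if c < n_sp:
            n = spacer_len()
            parts.append(_pinned_spacer(rng, n, c))
            arr.spacer_lens.append(n)
            pos += n
    parts.append(right_margin)
    arr.seq = "".join(parts)
    return arr


# ---------------------------------------------------------------------------
# contig construction


@dataclass
class FixtureParams:
    """Study conditions for the default end-to-end fixture."""

    n_contigs: int = 5
    flank_len: tuple[int, int] = (150, 300)
    genes_per_contig: tuple[int, int] = (4, 8)
    gene_len_codons: tuple[int, int] = (40, 160)
    intergenic_len: tuple[int, int] = (30, 120)
    n_crispr_arrays: int = 2
    n_rrna: int = 1
    rrna_len: int = 1200
    n_trna: int = 2
    trna_len: int = 75
    with_gap_scaffold: bool = True
    gap_len: int = 60
    caller_drop_prob: float = 0.10
    caller_start_shift_prob: float = 0.20
    caller_spurious_prob: float = 0.05
    coverage_range: tuple[float, float] = (1.0, 20.0)
    prefix: str = "GOLD"


@dataclass
class PieceTruth:
    """Planted features of one gap-free contig, in contig coordinates."""

    contig_id: str = ""
    length: int = 0
    genes: list[tuple[int, int, str]] = field(default_factory=list)     # start, end, strand
    crisprs: list[tuple[int, int]] = field(default_factory=list)
    rrnas: list[tuple[int, int, str]] = field(default_factory=list)
    trnas: list[tuple[int, int, str]] = field(default_factory=list)


def build_piece(
    rng: np.random.Generator,
    params: FixtureParams,
    n_crispr: int = 0,
    n_rrna: int = 0,
    n_trna: int = 0,
) -> tuple[str, PieceTruth]:
    """One gap-free contig assembled left-to-right from feature blocks."""
    truth = PieceTruth()
    parts: list[str] = []
    pos = 0

    def pad(lo: int, hi: int) -> None:
        nonlocal pos
        n = int(rng.integers(lo, hi + 1))
        parts.append(random_seq(rng, n))
        pos += n

    pad(*params.flank_len)
    n_genes = int(rng.integers(params.genes_per_contig[0], params.genes_per_contig[1] + 1))
    blocks: list[str] = ["gene"] * n_genes + ["crispr"] * n_crispr \
        + ["rrna"] * n_rrna + ["trna"] * n_trna
    rng.shuffle(blocks)
    for kind in blocks:
        if kind == "gene":
            n_cod = int(rng.integers(params.gene_len_codons[0], params.gene_len_codons[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            seq = orf_seq(rng, n_cod)
            if strand == "-":
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                seq = "".join(comp[c] for c in reversed(seq))
            parts.append(seq)
            truth.genes.append((pos + 1, pos + len(seq), strand))
            pos += len(seq)
        elif kind == "crispr":
            arr = plant_crispr(rng)
            parts.append(arr.seq)
            truth.crisprs.append((pos + 1, pos + len(arr.seq)))
            pos += len(arr.seq)
        elif kind == "rrna":
            seq = random_seq(rng, params.rrna_len)
            parts.append(seq)
            truth.rrnas.append((pos + 1, pos + len(seq), "+"))
            pos += len(seq)
        else:
            seq = random_seq(rng, params.trna_len)
            parts.append(seq)
            truth.trnas.append((pos + 1, pos + len(seq), "+"))
            pos += len(seq)
        pad(*params.intergenic_len)
    truth.length = pos
    return "".join(parts), truth


def build_dataset(
    rng: np.random.Generator, params: FixtureParams
) -> tuple[list[SequenceRecord], dict[str, PieceTruth], dict[str, float]]:
    """Input scaffolds, per-(renamed, split) contig truth, and coverage map.

    The first scaffold (when ``with_gap_scaffold``) is two pieces joined
    by a run of N's of ``gap_len``, exercising scaffold splitting; the
    returned truth is keyed by the contig ids the pipeline will use
    after renaming (``SEQ_000001``, split parts ``SEQ_000001.1`` ...).
    """
    scaffolds: list[SequenceRecord] = []
    truth: dict[str, PieceTruth] = {}
    coverage: dict[str, float] = {}
    budget = {"crispr": params.n_crispr_arrays, "rrna": params.n_rrna, "trna": params.n_trna}

    def take(kind: str) -> int:
        if budget[kind] > 0:
            budget[kind] -= 1
            return 1
        return 0

    idx = 0
    while idx < params.n_contigs:
        new_id = f"SEQ_{idx + 1:06d}"
        if idx == 0 and params.with_gap_scaffold:
            seq_a, t_a = build_piece(rng, params, n_crispr=take("crispr"))
            seq_b, t_b = build_piece(rng, params, n_trna=take("trna"))
            scaffolds.append(
                SequenceRecord(id=f"scaffold{idx + 1:03d}",
                               seq=seq_a + "N" * params.gap_len + seq_b)
            )
            t_a.contig_id, t_b.contig_id = f"{new_id}.1", f"{new_id}.2"
            truth[t_a.contig_id] = t_a
            truth[t_b.contig_id] = t_b
        else:
            seq, t = build_piece(
                rng, params, n_crispr=take("crispr"),
                n_rrna=take("rrna"), n_trna=take("trna"),
            )
            scaffolds.append(SequenceRecord(id=f"scaffold{idx + 1:03d}", seq=seq))
            t.contig_id = new_id
            truth[new_id] = t
        coverage[new_id] = round(float(rng.uniform(*params.coverage_range)), 1)
        idx += 1
    return scaffolds, truth, coverage


# ---------------------------------------------------------------------------
# caller evidence


def caller_models(
    rng: np.random.Generator,
    truth: dict[str, PieceTruth],
    params: FixtureParams,
    drop: float | None = None,
    shift: float | None = None,
    spurious: float | None = None,
) -> dict[str, list[GeneModel]]:
    """Derive per-caller gene models from planted genes with perturbations.

    Per caller and gene: the model is dropped with probability ``drop``;
    otherwise its start is shifted in-frame downstream with probability
    ``shift`` (stop coordinates are never perturbed — callers agree on
    stops). Spurious short models are added per contig with probability
    ``spurious`` per caller.
    """
    drop = params.caller_drop_prob if drop is None else drop
    shift = params.caller_start_shift_prob if shift is None else shift
    spurious = params.caller_spurious_prob if spurious is None else spurious
    calls: dict[str, list[GeneModel]] = {c: [] for c in CALLERS}
    for cid, t in sorted(truth.items()):
        for (start, end, strand) in t.genes:
            n_codons = (end - start + 1) // 3
            for caller in CALLERS:
                if rng.random() < drop:
                    continue
                s, e = start, end
                if rng.random() < shift and n_codons > 45:
                    delta = 3 * int(rng.integers(1, min(8, n_codons - 40)))
                    if strand == "+":
                        s = start + delta
                    else:
                        e = end - delta
                calls[caller].append(GeneModel(cid, s, e, strand, caller))
        for caller in CALLERS:
            if rng.random() < spurious:
                pos = int(rng.integers(1, max(2, t.length - 200)))
                calls[caller].append(
                    GeneModel(cid, pos, pos + 104, "+" if rng.random() < 0.5 else "-", caller)
                )
    return calls


def write_caller_gff(models: list[GeneModel], caller: str, path: Path) -> None:
    lines = ["##gff-version 3"]
    for i, m in enumerate(
        sorted(models, key=lambda m: (m.contig_id, m.start, m.end)), start=1
    ):
        lines.append(
            "\t".join([m.contig_id, caller, "CDS", str(m.start), str(m.end), ".",
                       m.strand, "0", f"ID={caller}_{i}"])
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# RNA evidence


def write_trna_tables(
    rng: np.random.Generator, truth: dict[str, PieceTruth], out_dir: Path
) -> dict[str, Path]:
    """Three per-domain tRNA tables; the bacterial run scores highest."""
    paths = {}
    base_scores = {"bacteria": 0.0, "archaea": -8.0, "eukaryota": -15.0}
    for domain, delta in base_scores.items():
        rows = []
        for cid, t in sorted(truth.items()):
            for k, (start, end, strand) in enumerate(t.trnas, start=1):
                score = round(60.0 + delta + float(rng.uniform(-2, 2)), 1)
                b, e = (start, end) if strand == "+" else (end, start)
                rows.append(
                    f"{cid}\t{k}\t{b}\t{e}\tLeu\tCAA\t0\t0\t{score}"
                )
        header = ("Sequence\ttRNA #\tBegin\tEnd\tType\tAnticodon\t"
                  "Intron Begin\tIntron End\tScore\n"
                  "Name\t\t\t\t\t\t\t\t\n--------\t----\t----\t----\t----\t----\t----\t----\t----\n")
        p = out_dir / f"trna_{domain}.tsv"
        p.write_text(header + "\n".join(rows) + ("\n" if rows else ""))
        paths[domain] = p
    return paths


def write_rrna_tables(
    rng: np.random.Generator, truth: dict[str, PieceTruth], out_dir: Path
) -> dict[str, Path]:
    """Three per-domain HMMER --tblout files for planted rRNA loci."""
    paths = {}
    base_scores = {"bacteria": 0.0, "archaea": -60.0, "eukaryota": -120.0}
    for domain, delta in base_scores.items():
        lines = ["# target name        accession  query name af at hf ht ef et sqlen strand   E-value  score  bias"]
        for cid, t in sorted(truth.items()):
            for (start, end, strand) in t.rrnas:
                score = round(900.0 + delta + float(rng.uniform(-5, 5)), 1)
                model = f"16S_rRNA_{domain}"
                lines.append(
                    f"{cid} - {model} - 1 1200 {start} {end} {start} {end} {t.length} "
                    f"{strand} 1e-200 {score} 0.1"
                )
        p = out_dir / f"rrna_{domain}.tblout"
        p.write_text("\n".join(lines) + "\n")
        paths[domain] = p
    return paths


# ---------------------------------------------------------------------------
# reference tables and hit evidence

COG_TABLE = [
    ("COG0001", "Glutamate-1-semialdehyde aminotransferase", 430),
    ("COG0444", "ABC-type transporter ATP-binding protein", 250),
    ("COG0583", "Transcriptional regulator LysR family", 300),
    ("COG1234", "Predicted hydrolase of the metallo-beta-lactamase superfamily", 280),
    ("COG2000", "Uncharacterized conserved protein", 200),
    ("COG3547", "Transposase and inactivated derivatives", 220),
]

PFAM_TABLE = [
    ("PF00005", "ABC_tran", 137),
    ("PF00106", "adh_short", 195),
    ("PF00440", "TetR_N", 47),
    ("PF01000", "RNA_pol_A_bac", 150),
    ("PF07690", "MFS_1", 354),
]

COG_PFAM_PAIRS = [
    ("COG0444", "PF00005"),
    ("COG0583", "PF00440"),
    ("COG1234", "PF00106"),
]

KO_TABLE = [
    # gene_id, ko_id, gene_length, lineage
    ("RG0001", "K00001", 340, "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Enterobacteriaceae;Escherichia;Escherichia coli"),
    ("RG0002", "K00001", 350, "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Enterobacteriaceae;Salmonella;Salmonella enterica"),
    ("RG0003", "K00002", 310, "Bacteria;Proteobacteria;Gammaproteobacteria;Pseudomonadales;Pseudomonadaceae;Pseudomonas;Pseudomonas putida"),
    ("RG0004", "K00003", 420, "Bacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae;Bacillus;Bacillus subtilis"),
    ("RG0005", "K00004", 280, "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Rhizobiaceae;Rhizobium;Rhizobium leguminosarum"),
    ("RG0006", "K00005", 360, "Archaea;Euryarchaeota;Methanococci;Methanococcales;Methanococcaceae;Methanococcus;Methanococcus maripaludis"),
    ("RG0007", "K00002", 300, "Bacteria;Proteobacteria;Gammaproteobacteria;Vibrionales;Vibrionaceae;Vibrio;Vibrio cholerae"),
    ("RG0008", "K00006", 390, "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Bacteroidaceae;Bacteroides;Bacteroides fragilis"),
]

KO2EC = [
    ("K00001", "1.1.1.1"),
    ("K00002", "1.1.1.2"),
    ("K00003", "2.7.1.1"),
    ("K00004", "3.1.3.3"),
    ("K00004", "3.1.3.48"),
    ("K00005", "4.2.1.2"),
]


def write_reference_tables(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "cog_meta.tsv", "w") as fh:
        fh.write("cog_id\tname\tconsensus_length\n")
        for cid, name, ln in COG_TABLE:
            fh.write(f"{cid}\t{name}\t{ln}\n")
    with open(out_dir / "pfam_meta.tsv", "w") as fh:
        fh.write("accession\tname\tmodel_length\n")
        for acc, name, ln in PFAM_TABLE:
            fh.write(f"{acc}\t{name}\t{ln}\n")
    with open(out_dir / "cog_pfam.tsv", "w") as fh:
        fh.write("cog_id\taccession\n")
        for cid, acc in COG_PFAM_PAIRS:
            fh.write(f"{cid}\t{acc}\n")
    with open(out_dir / "ko_index.tsv", "w") as fh:
        fh.write("gene_id\tko_id\tgene_length\n")
        for gid, ko, ln, _lin in KO_TABLE:
            fh.write(f"{gid}\t{ko}\t{ln}\n")
    with open(out_dir / "ko2ec.tsv", "w") as fh:
        fh.write("ko_id\tec_number\n")
        for ko, ec in KO2EC:
            fh.write(f"{ko}\t{ec}\n")
    with open(out_dir / "taxonomy.tsv", "w") as fh:
        fh.write("gene_id\tlineage\n")
        for gid, _ko, _ln, lin in KO_TABLE:
            fh.write(f"{gid}\t{lin}\n")


def write_hit_tables(
    rng: np.random.Generator,
    gene_keys: list[tuple[str, int]],  # (coordinate key, protein length aa)
    out_dir: Path,
) -> None:
    """COG, Pfam and ranked protein hit tables keyed by CDS coordinate keys.

    Roughly 70% of genes get a COG hit, 60% a Pfam hit and 60% ranked
    protein hits; identities and coverages straddle the assignment
    thresholds so both accepting and rejecting paths are exercised.
    """
    cog_rows, pfam_rows, prot_rows = [], [], []
    for key, aa in gene_keys:
        if rng.random() < 0.7:
            cid, _name, clen = COG_TABLE[int(rng.integers(0, len(COG_TABLE)))]
            ident = round(float(rng.uniform(12, 80)), 1)
            aln = int(clen * rng.uniform(0.4, 1.0))
            ev = 10.0 ** float(rng.uniform(-30, -1.5))
            bits = round(50 + 4 * (80 - ident) * rng.random() + aln * 0.3, 1)
            qs = int(rng.integers(1, max(2, aa - 30)))
            qe = min(aa, qs + aln - 1)
            cog_rows.append(
                f"{key}\t{cid}\t{ident}\t{aln}\t5\t1\t{qs}\t{qe}\t1\t{min(aln, clen)}\t{ev:.2e}\t{bits}"
            )
        if rng.random() < 0.6:
            n_dom = 1 + (rng.random() < 0.2)
            for _ in range(int(n_dom)):
                acc, _name, mlen = PFAM_TABLE[int(rng.integers(0, len(PFAM_TABLE)))]
                af = int(rng.integers(1, max(2, aa - 40)))
                at = min(aa, af + int(mlen * rng.uniform(0.6, 1.0)))
                score = round(float(rng.uniform(25, 300)), 1)
                iev = 10.0 ** float(rng.uniform(-40, -3))
                pfam_rows.append(
                    f"{key} - {aa} {acc} - {mlen} {iev:.1e} {score} 0.1 1 1 "
                    f"{iev:.1e} {iev:.1e} {score} 0.1 1 {mlen} {af} {at} {af} {at} 0.9 -"
                )
        if rng.random() < 0.6:
            n_hits = int(rng.integers(1, 8))
            order = rng.permutation(len(KO_TABLE))[:n_hits]
            bits = sorted((float(rng.uniform(60, 400)) for _ in range(n_hits)), reverse=True)
            for r, (gi, bit) in enumerate(zip(order, bits), start=1):
                gid, _ko, glen, _lin = KO_TABLE[int(gi)]
                ident = round(float(rng.uniform(20, 95)), 1)
                cov = float(rng.uniform(0.4, 1.0))
                ss = 1
                se = max(1, int(glen * cov))
                ev = 10.0 ** float(rng.uniform(-50, -2))
                prot_rows.append(
                    f"{key}\t{gid}\t{ident}\t{se}\t5\t0\t1\t{min(aa, se)}\t{ss}\t{se}\t{ev:.2e}\t{round(bit,1)}"
                )
    (out_dir / "cog_hits.tsv").write_text("\n".join(cog_rows) + ("\n" if cog_rows else ""))
    (out_dir / "pfam_hits.domtblout").write_text("\n".join(pfam_rows) + ("\n" if pfam_rows else ""))
    (out_dir / "protein_hits.tsv").write_text("\n".join(prot_rows) + ("\n" if prot_rows else ""))


# ---------------------------------------------------------------------------
# top-level generator


def generate_fixtures(
    out_dir: str | Path, seed: int, params: FixtureParams | None = None
) -> dict:
    """Emit a complete synthetic submission under ``out_dir``.

    Writes input FASTA, coverage map, four caller GFFs, per-domain RNA
    evidence, hit tables, reference tables, a ready-to-run pipeline
    config (config.yaml) and the ground-truth manifest (manifest.json).
    Returns the manifest.
    """
    params = params or FixtureParams()
    out = Path(out_dir)
    ev = out / "evidence"
    refs = out / "refs"
    for d in (out, ev, refs):
        d.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    scaffolds, truth, coverage = build_dataset(rng, params)
    from .seqio import write_fasta

    write_fasta(scaffolds, out / "input.fna")
    with open(out / "coverage.tsv", "w") as fh:
        for cid, cov in sorted(coverage.items()):
            fh.write(f"{cid}\t{cov}\n")

    calls = caller_models(rng, truth, params)
    caller_paths = {}
    for caller in CALLERS:
        p = ev / f"{caller}.gff"
        write_caller_gff(calls[caller], caller, p)
        caller_paths[caller] = p

    trna_paths = write_trna_tables(rng, truth, ev)
    rrna_paths = write_rrna_tables(rng, truth, ev)
    write_reference_tables(refs)

    # hit tables key on the coordinate keys of the *expected* consensus CDS
    consensus = combine_gene_calls(calls)
    gene_keys = [
        (f"{m.contig_id}:{m.start}-{m.end}:{m.strand}", (m.end - m.start + 1) // 3 - 1)
        for m in consensus
    ]
    write_hit_tables(rng, gene_keys, ev)

    config = {
        "fasta": str(out / "input.fna"),
        "platform": "assembled",
        "coverage": str(out / "coverage.tsv"),
        "prefix": params.prefix,
        "out_dir": str(out / "results"),
        "refs_dir": str(refs),
        "evidence": {
            "caller_gffs": {c: str(p) for c, p in caller_paths.items()},
            "trna_tables": {d: str(p) for d, p in trna_paths.items()},
            "rrna_tables": {d: str(p) for d, p in rrna_paths.items()},
            "cog_hits": str(ev / "cog_hits.tsv"),
            "pfam_hits": str(ev / "pfam_hits.domtblout"),
            "protein_hits": str(ev / "protein_hits.tsv"),
        },
    }
    import yaml

    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))

    manifest = {
        "seed": seed,
        "scaffolds": [s.id for s in scaffolds],
        "coverage": coverage,
        "truth": {
            cid: {
                "length": t.length,
                "genes": t.genes,
                "crisprs": t.crisprs,
                "rrnas": t.rrnas,
                "trnas": t.trnas,
            }
            for cid, t in sorted(truth.items())
        },
        "expected_consensus": [k for k, _aa in gene_keys],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
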