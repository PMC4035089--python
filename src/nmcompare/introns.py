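"""Spliceosomal intron catalogues, distributions and cross-genome comparison.

The genomes this package targets carry unusually tiny ("pigmy") introns,
mostly 18–23 nt with near-universal GT-AG boundaries. Intron positions in
orthologous proteins are compared through a global protein alignment with
a comparability filter: an intron only enters the shared/unique tally
when both flanking alignment windows are gap-free and well conserved, so
that positional identity is meaningful despite sequence divergence.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from ._seq import revcomp
from .core import AnnotatedGenome, GeneModel
from .gene_content import OrthologFamilyTable


@dataclass
class IntronRecord:
    """One intron; ``start``/``end`` are genome-forward, dinucleotides are
    read in transcript orientation."""

    gene_id: str | None
    chromosome: str
    strand: str
    start: int
    end: int
    phase: int | None
    donor_dinucleotide: str
    acceptor_dinucleotide: str
    support: int | None = None
    valid: bool = True

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def donor(self) -> int:
        """Genomic position of the first intron base in transcript orientation."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def boundary(self) -> str:
        return f"{self.donor_dinucleotide}-{self.acceptor_dinucleotide}"


def _gene_intron_offsets(genome: AnnotatedGenome, gene: GeneModel) -> list[tuple[int, IntronRecord]]:
    """(spliced-CDS offset, record) per inter-exon gap, transcript order."""
    seq = genome.chromosome(gene.chromosome).sequence
    exons = gene.exons
    out = []
    if gene.strand == "+":
        upstream = 0
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            upstream += e1 - s1
            out.append((upstream, _make_record(gene, seq, e1, s2, upstream)))
    else:
        upstream = 0
        for i in range(len(exons) - 1, 0, -1):
            s_hi, e_hi = exons[i]
            upstream += e_hi - s_hi
            gap_start, gap_end = exons[i - 1][1], s_hi
            out.append((upstream, _make_record(gene, seq, gap_start, gap_end, upstream)))
    return out


def _make_record(gene: GeneModel, seq: str, gap_start: int, gap_end: int, upstream: int) -> IntronRecord:
    if gene.strand == "+":
        donor_di = seq[gap_start : gap_start + 2]
        acceptor_di = seq[gap_end - 2 : gap_end]
    else:
        donor_di = revcomp(seq[gap_end - 2 : gap_end])
        acceptor_di = revcomp(seq[gap_start : gap_start + 2])
    return IntronRecord(
        gene_id=gene.id,
        chromosome=gene.chromosome,
        strand=gene.strand,
        start=gap_start,
        end=gap_end,
        phase=upstream % 3,
        donor_dinucleotide=donor_di,
        acceptor_dinucleotide=acceptor_di,
        valid=(gap_end - gap_start) >= 4,
    )


def catalog_introns(genome: AnnotatedGenome) -> list[IntronRecord]:
    """One record per inter-exon gap of every multi-exon gene.

    Gaps shorter than 4 bp are kept but flagged invalid and excluded from
    distribution summaries.
    """
    records = []
    for gene in genome.genes:
        records.extend(rec for _, rec in _gene_intron_offsets(genome, gene))
    return records


def intron_size_distribution(records: list[IntronRecord]) -> dict:
    """Counts and proportions per integer length, plus headline summaries."""
    lengths = [r.length for r in records if r.valid]
    counts = Counter(lengths)
    n = len(lengths)
    return {
        "counts": dict(sorted(counts.items())),
        "proportions": {k: v / n for k, v in sorted(counts.items())} if n else {},
        "n": n,
        "max_length": max(lengths) if lengths else None,
        "proportion_lt20": sum(v for k, v in counts.items() if k < 20) / n if n else None,
    }


def classify_boundaries(records: list[IntronRecord]) -> dict:
    """Partition introns into GT-AG / GC-AG / GA-AG / other boundary classes."""
    classes = Counter()
    for r in records:
        if not r.valid:
            continue
        b = r.boundary
        classes[b if b in {"GT-AG", "GC-AG", "GA-AG"} else "other"] += 1
    total = sum(classes.values())
    return {
        "counts": {k: classes.get(k, 0) for k in ("GT-AG", "GC-AG", "GA-AG", "other")},
        "canonical_fraction": classes.get("GT-AG", 0) / total if total else None,
        "n": total,
    }


def splice_signal_matrix(
    records: list[IntronRecord],
    genome: AnnotatedGenome,
    exon_flank: int = 5,
) -> dict[int, pd.DataFrame]:
    """Per-length position x base count matrices over introns and exon flanks.

    Rows are labelled ``-flank..-1`` (upstream exon), ``i1..iL`` (intron)
    and ``+1..+flank`` (downstream exon), all in transcript orientation.
    """
    out: dict[int, pd.DataFrame] = {}
    grouped: dict[int, list[IntronRecord]] = defaultdict(list)
    for r in records:
        if r.valid:
            grouped[r.length].append(r)
    for length, recs in sorted(grouped.items()):
        rows = (
            [str(-k) for k in range(exon_flank, 0, -1)]
            + [f"i{k}" for k in range(1, length + 1)]
            + [f"+{k}" for k in range(1, exon_flank + 1)]
        )
        df = pd.DataFrame(0, index=rows, columns=list("ACGTN"))
        for r in recs:
            seq = genome.chromosome(r.chromosome).sequence
            if r.strand == "+":
                up = seq[r.start - exon_flank : r.start]
                intron = seq[r.start : r.end]
                down = seq[r.end : r.end + exon_flank]
            else:
                up = revcomp(seq[r.end : r.end + exon_flank])
                intron = revcomp(seq[r.start : r.end])
                down = revcomp(seq[r.start - exon_flank : r.start])
            if len(up) < exon_flank or len(down) < exon_flank:
                continue
            for label, base in zip(rows, up + intron + down):
                df.loc[label, base if base in "ACGT" else "N"] += 1
        out[length] = df
    return out


# ---------------------------------------------------------------------------
# Junction calling from spliced alignments

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def _gaps_from_cigar(pos: int, cigar: str) -> list[tuple[int, int]]:
    gaps = []
    ref = pos
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        if op == "N":
            gaps.append((ref, ref + n))
            ref += n
        elif op in "MD=X":
            ref += n
    return gaps


def _iter_gapped(source):
    """Yield (chromosome, gap_start, gap_end) from SAM path or record iterable."""
    if isinstance(source, (str, Path)):
        import pysam

        with pysam.AlignmentFile(str(source), "r", check_sq=False) as fh:
            for aln in fh:
                if aln.is_unmapped or aln.cigartuples is None:
                    continue
                ref = aln.reference_start
                for op, n in aln.cigartuples:
                    if op == 3:  # N
                        yield aln.reference_name, ref, ref + n
                        ref += n
                    elif op in (0, 2, 7, 8):  # M, D, =, X
                        ref += n
        return
    for rec in source:
        try:
            chrom, pos, cigar = rec.chrom, rec.pos, rec.cigar
        except AttributeError:
            warnings.warn(f"malformed alignment record skipped: {rec!r}")
            continue
        for s, e in _gaps_from_cigar(pos, cigar):
            yield chrom, s, e


def _canonical_shift(
    seq: str, s: int, e: int, require_boundary: set[str] | None
) -> tuple[int, int]:
    """Resolve gap-placement ambiguity: prefer a requested boundary, else leftmost."""
    candidates = [(s, e)]
    cs, ce = s, e
    while cs > 0 and seq[cs - 1] == seq[ce - 1]:
        cs, ce = cs - 1, ce - 1
        candidates.insert(0, (cs, ce))
    cs, ce = s, e
    while ce < len(seq) and seq[cs] == seq[ce]:
        cs, ce = cs + 1, ce + 1
        candidates.append((cs, ce))
    if require_boundary:
        for cand in candidates:
            fwd = f"{seq[cand[0]:cand[0]+2]}-{seq[cand[1]-2:cand[1]]}"
            rev = f"{revcomp(seq[cand[1]-2:cand[1]])}-{revcomp(seq[cand[0]:cand[0]+2])}"
            if fwd in require_boundary or rev in require_boundary:
                return cand
    return candidates[0]


def call_junctions(
    source,
    genome: AnnotatedGenome,
    min_support: int = 2,
    require_boundary: set[str] | None = frozenset({"GT-AG"}),
) -> list[IntronRecord]:
    """Call introns from gapped (spliced) alignment records.

    Gap coordinates are normalized for placement ambiguity (shiftable gaps
    move to a position giving a boundary in ``require_boundary``, else
    leftmost), tallied, and junctions supported by fewer than
    ``min_support`` records are dropped. Where a called gap coincides with
    an annotated inter-exon gap the annotated record (with phase) is
    returned; otherwise the host gene, if any, supplies the strand.
    """
    support: Counter = Counter()
    for chrom, s, e in _iter_gapped(source):
        seq = genome.chromosome(chrom).sequence
        support[(chrom,) + _canonical_shift(seq, s, e, require_boundary)] += 1

    annotated = {
        (r.chromosome, r.start, r.end): r for r in catalog_introns(genome)
    }
    called = []
    for (chrom, s, e), n in sorted(support.items()):
        if n < min_support:
            continue
        if (chrom, s, e) in annotated:
            rec = annotated[(chrom, s, e)]
            rec = IntronRecord(**{**rec.__dict__, "support": n})
        else:
            host = _host_gene(genome, chrom, s, e)
            strand = host.strand if host else "+"
            seq = genome.chromosome(chrom).sequence
            if strand == "+":
                di, ai = seq[s : s + 2], seq[e - 2 : e]
            else:
                di, ai = revcomp(seq[e - 2 : e]), revcomp(seq[s : s + 2])
            rec = IntronRecord(
                gene_id=host.id if host else None,
                chromosome=chrom,
                strand=strand,
                start=s,
                end=e,
                phase=None,
                donor_dinucleotide=di,
                acceptor_dinucleotide=ai,
                support=n,
                valid=(e - s) >= 4,
            )
        called.append(rec)
    return called


def _host_gene(genome: AnnotatedGenome, chrom: str, s: int, e: int):
    hits = [
        g
        for g in genome.genes
        if g.chromosome == chrom and g.start <= s and e <= g.end
    ]
    return min(hits, key=lambda g: g.end - g.start) if hits else None


# ---------------------------------------------------------------------------
# Global protein alignment

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALIGN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX*")


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float
    a_to_col: list[int] = field(repr=False)
    b_to_col: list[int] = field(repr=False)
    col_to_a: list[int | None] = field(repr=False)
    col_to_b: list[int | None] = field(repr=False)


def align_proteins(seq_a: str, seq_b: str, gap_open: float = 10.0, gap_extend: float = 0.5) -> AlignmentResult:
    """Optimal global alignment under BLOSUM62 with affine gap costs.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``; terminal
    gaps are penalized. Deterministic: of equal-scoring optima the
    aligner's first traceback is reported.
    """
    for name, seq in (("A", seq_a), ("B", seq_b)):
        if not seq:
            raise ValueError(f"sequence {name} is empty")
        for i, ch in enumerate(seq):
            if ch not in _ALIGN_ALPHABET:
                raise ValueError(f"sequence {name}: illegal character {ch!r} at position {i}")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    aligner.mode = "global"
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(seq_a, seq_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])

    a_to_col, b_to_col, col_to_a, col_to_b = [], [], [], []
    ia = ib = 0
    matches = 0
    for col, (x, y) in enumerate(zip(row_a, row_b)):
        if x != "-":
            a_to_col.append(col)
            col_to_a.append(ia)
            ia += 1
        else:
            col_to_a.append(None)
        if y != "-":
            b_to_col.append(col)
            col_to_b.append(ib)
            ib += 1
        else:
            col_to_b.append(None)
        if x == y and x != "-":
            matches += 1
    return AlignmentResult(
        aligned_a=row_a,
        aligned_b=row_b,
        score=float(aln.score),
        percent_identity=matches / len(row_a) if row_a else 0.0,
        a_to_col=a_to_col,
        b_to_col=b_to_col,
        col_to_a=col_to_a,
        col_to_b=col_to_b,
    )


# ---------------------------------------------------------------------------
# Intron-position comparison between two genomes

@dataclass
class IntronStatus:
    family: str
    genome: str
    gene_id: str
    column: int | None
    phase: int | None
    status: str  # "shared" | "unique" | "not-comparable"
    partner: str | None = None


@dataclass
class IntronComparison:
    entries: list[IntronStatus]
    summary: dict
    labels: tuple[str, str] = ("", "")


def compare_intron_positions(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    families: OrthologFamilyTable,
    flank_residues: int = 15,
    flank_identity: float = 0.5,
    min_pair_identity: float = 0.2,
) -> IntronComparison:
    """Classify introns of orthologous gene pairs as shared or unique.

    Each intron maps to the alignment column of the residue whose codon
    contains it (phase 1/2) or of the preceding residue (phase 0, which
    falls between codons). An intron is *comparable* when the
    ``flank_residues`` alignment columns on each side of that column are
    gap-free in both sequences and each window exceeds ``flank_identity``
    identical residues per column. Two comparable introns are *shared*
    when they occupy the same column with the same phase.
    """
    from .gene_stats import _pick_longest

    entries: list[IntronStatus] = []
    n_pairs = 0
    for fam in sorted(set(families.family_ids)):
        ids_a = families.members(fam, genome_a.label)
        ids_b = families.members(fam, genome_b.label)
        if not ids_a or not ids_b:
            continue
        ga = _pick_longest(genome_a, ids_a)
        gb = _pick_longest(genome_b, ids_b)
        if ga is None or gb is None:
            continue
        prot_a = ga.protein_sequence(genome_a.chromosome(ga.chromosome))
        prot_b = gb.protein_sequence(genome_b.chromosome(gb.chromosome))
        if not prot_a or not prot_b:
            continue
        res = align_proteins(prot_a, prot_b)
        if res.percent_identity < min_pair_identity:
            warnings.warn(f"family {fam}: pair identity below floor; skipped")
            continue
        n_pairs += 1
        placed_a = _place_introns(genome_a, ga, prot_a, res.a_to_col, res, flank_residues, flank_identity)
        placed_b = _place_introns(genome_b, gb, prot_b, res.b_to_col, res, flank_residues, flank_identity)
        by_key_b = {
            (col, ph): i for i, (col, ph, ok) in enumerate(placed_b) if ok
        }
        used_b: set[int] = set()
        for col, ph, ok in placed_a:
            if not ok:
                entries.append(IntronStatus(fam, genome_a.label, ga.id, col, ph, "not-comparable"))
                continue
            j = by_key_b.get((col, ph))
            if j is not None and j not in used_b:
                used_b.add(j)
                entries.append(IntronStatus(fam, genome_a.label, ga.id, col, ph, "shared", gb.id))
            else:
                entries.append(IntronStatus(fam, genome_a.label, ga.id, col, ph, "unique"))
        for i, (col, ph, ok) in enumerate(placed_b):
            if not ok:
                entries.append(IntronStatus(fam, genome_b.label, gb.id, col, ph, "not-comparable"))
            elif i in used_b:
                entries.append(IntronStatus(fam, genome_b.label, gb.id, col, ph, "shared", ga.id))
            else:
                entries.append(IntronStatus(fam, genome_b.label, gb.id, col, ph, "unique"))

    def _count(label, status):
        return sum(1 for e in entries if e.genome == label and e.status == status)

    la, lb = genome_a.label, genome_b.label
    summary = {
        "n_pairs": n_pairs,
        "comparable_a": _count(la, "shared") + _count(la, "unique"),
        "comparable_b": _count(lb, "shared") + _count(lb, "unique"),
        "shared": _count(la, "shared"),
        "unique_a": _count(la, "unique"),
        "unique_b": _count(lb, "unique"),
    }
    return IntronComparison(entries, summary, labels=(la, lb))


def _place_introns(genome, gene, prot, res_to_col, res, flank, flank_id):
    """(column, phase, comparable) per intron of ``gene``."""
    ncols = len(res.aligned_a)
    out = []
    for offset, rec in _gene_intron_offsets(genome, gene):
        r, phase = offset // 3, offset % 3
        idx = r - 1 if phase == 0 else r
        if idx < 0 or idx >= len(prot):
            out.append((None, phase, False))
            continue
        col = res_to_col[idx]
        ok = _flanks_comparable(res, col, ncols, flank, flank_id)
        out.append((col, phase, ok))
    return out


def _flanks_comparable(res, col, ncols, flank, flank_id) -> bool:
    if col - flank < 0 or col + flank >= ncols:
        return False
    for window in (range(col - flank, col), range(col + 1, col + flank + 1)):
        matches = 0
        for c in window:
            x, y = res.aligned_a[c], res.aligned_b[c]
            if x == "-" or y == "-":
                return False
            if x == y:
                matches += 1
        if matches / flank <= flank_id:
            return False
    return True


def polarize_introns(
    comparison: IntronComparison,
    outgroup_presence: dict[tuple[str, int, int], bool],
) -> list[dict]:
    """Polarize unshared introns against outgroup presence calls.

    A comparable intron unique to one genome that is present at the same
    position in at least one outgroup implies loss in the genome lacking
    it; with no outgroup support the direction stays ambiguous.
    """
    labels = [l for l in comparison.labels if l]
    calls = []
    for e in comparison.entries:
        if e.status != "unique":
            continue
        other = next((l for l in labels if l != e.genome), None)
        present = outgroup_presence.get((e.family, e.column, e.phase), False)
        calls.append(
            {
                "family": e.family,
                "column": e.column,
                "phase": e.phase,
                "present_in": e.genome,
                "call": f"loss-in-{other}" if present and other else "ambiguous",
            }
        )
    return calls
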