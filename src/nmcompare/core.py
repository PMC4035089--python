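"""Core data model: chromosomes, gene models, annotated genomes, summaries.

Internal coordinates are 0-based half-open throughout; GFF3 I/O converts
to/from the format's 1-based inclusive convention. Category labels travel
in a ``category=`` GFF3 attribute and are never inferred from sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import gc_fraction, is_dna, revcomp

GENE_KINDS = {"protein", "tRNA", "rRNA", "pseudogene", "orf"}
CATEGORIES = {
    "eukaryotic-conserved",
    "plastid-associated",
    "nORFan",
    "spliceosomal",
    "other",
    "unassigned",
}


@dataclass
class Chromosome:
    """A single (usually linear) chromosome sequence."""

    name: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not is_dna(self.sequence):
            raise ValueError(f"chromosome {self.name}: non-IUPAC or empty sequence")
        if self.topology not in {"linear", "circular"}:
            raise ValueError(f"chromosome {self.name}: bad topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A gene with an ordered exon structure on one chromosome.

    ``exons`` are genome-forward [start, end) intervals, sorted and
    non-overlapping; for minus-strand genes the transcript reads them
    last-to-first, reverse-complemented.
    """

    id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    kind: str = "protein"
    category: str = "unassigned"
    family_id: str | None = None
    product: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")
        if self.kind not in GENE_KINDS:
            raise ValueError(f"gene {self.id}: bad kind {self.kind!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"gene {self.id}: bad category {self.category!r}")
        exons = [(int(s), int(e)) for s, e in self.exons]
        if not exons or any(e <= s for s, e in exons):
            raise ValueError(f"gene {self.id}: empty or inverted exon")
        if exons != sorted(exons):
            raise ValueError(f"gene {self.id}: exons not sorted")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.id}: overlapping exons")
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_sequence(self, chrom: Chromosome) -> str:
        """Transcript-orientation spliced sequence (minus genes revcomped)."""
        seq = "".join(chrom.sequence[s:e] for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq

    def protein_sequence(self, chrom: Chromosome) -> str:
        """Standard-code translation (table 1), trailing stop stripped."""
        cds = self.spliced_sequence(chrom)
        cds = cds[: len(cds) - len(cds) % 3]
        aa = str(Seq(cds).translate(table=1))
        return aa[:-1] if aa.endswith("*") else aa


@dataclass
class AnnotatedGenome:
    label: str
    chromosomes: list[Chromosome]
    genes: list[GeneModel]
    warnings: list[str] = field(default_factory=list, compare=False, repr=False)

    def __post_init__(self) -> None:
        by_name = {c.name: c for c in self.chromosomes}
        if len(by_name) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        seen: set[str] = set()
        for g in self.genes:
            if g.id in seen:
                raise ValueError(f"duplicate gene id {g.id}")
            seen.add(g.id)
            chrom = by_name.get(g.chromosome)
            if chrom is None:
                raise ValueError(f"gene {g.id}: unknown chromosome {g.chromosome}")
            if g.end > len(chrom):
                raise ValueError(f"gene {g.id}: exon beyond chromosome end")
        self._by_name = by_name
        self._genes_by_id = {g.id: g for g in self.genes}

    def chromosome(self, name: str) -> Chromosome:
        return self._by_name[name]

    def gene(self, gene_id: str) -> GeneModel:
        return self._genes_by_id[gene_id]

    def genes_on(self, name: str) -> list[GeneModel]:
        return sorted(
            (g for g in self.genes if g.chromosome == name), key=lambda g: g.span
        )

    @property
    def total_size(self) -> int:
        return sum(len(c) for c in self.chromosomes)


@dataclass
class GenomeSummary:
    """Whole-genome headline numbers (sizes, GC, counts, density)."""

    label: str
    total_size: int
    chromosome_sizes: dict[str, int]
    gc_overall: float | None
    gc_excluding_regions: float | None
    n_protein_genes: int
    n_nonredundant_genes: int | None
    n_introns: int
    n_trnas: int
    mean_spacer: float | None
    gene_density: float | None

    def to_tsv(self) -> str:
        rows = [
            ("label", self.label),
            ("total_size_bp", self.total_size),
            *((f"size_bp[{n}]", s) for n, s in self.chromosome_sizes.items()),
            ("gc_overall", _fmt(self.gc_overall)),
            ("gc_excluding_regions", _fmt(self.gc_excluding_regions)),
            ("n_protein_genes", self.n_protein_genes),
            ("n_nonredundant_genes", _fmt(self.n_nonredundant_genes)),
            ("n_introns", self.n_introns),
            ("n_trnas", self.n_trnas),
            ("mean_spacer_bp", _fmt(self.mean_spacer)),
            ("gene_density_per_kbp", _fmt(self.gene_density)),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def _fmt(x) -> str:
    return "NA" if x is None else (f"{x:.6g}" if isinstance(x, float) else str(x))


# ---------------------------------------------------------------------------
# I/O


def load_genome_bundle(
    fasta_source,
    gff3_source,
    label: str = "genome",
    min_orf_codons: int | None = None,
) -> AnnotatedGenome:
    """Read a FASTA + GFF3 pair into an :class:`AnnotatedGenome`.

    GFF3 coordinates (1-based inclusive) are converted to 0-based
    half-open. A protein gene whose summed CDS length is not divisible by
    three is downgraded to a pseudogene with a warning; with
    ``min_orf_codons`` set, protein/orf genes shorter than that many
    codons are flagged with a warning (kept as annotated).
    """
    chroms = [
        Chromosome(rec.id, str(rec.seq))
        for rec in SeqIO.parse(_as_handle(fasta_source), "fasta")
    ]
    known = {c.name for c in chroms}
    warnings: list[str] = []

    gene_rows: dict[str, dict] = {}
    exon_rows: dict[str, list[tuple[int, int]]] = {}
    for line in _as_handle(gff3_source):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        seqid, _, ftype, start, end, _, strand, _, attrs = parts
        if seqid not in known:
            raise ValueError(f"GFF3 seqid {seqid!r} not found in FASTA")
        a = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        iv = (int(start) - 1, int(end))
        if ftype == "gene":
            gene_rows[a["ID"]] = {
                "chromosome": seqid,
                "strand": strand,
                "kind": a.get("kind", "protein"),
                "category": a.get("category", "unassigned"),
                "family_id": a.get("family"),
                "product": a.get("product"),
            }
        elif ftype in {"CDS", "exon"}:
            exon_rows.setdefault(a["Parent"], []).append(iv)

    genes = []
    for gid, row in gene_rows.items():
        exons = sorted(exon_rows.get(gid, []))
        if not exons:
            raise ValueError(f"gene {gid}: no CDS/exon rows")
        kind = row["kind"]
        coding = sum(e - s for s, e in exons)
        if kind == "protein" and coding % 3 != 0:
            warnings.append(f"gene {gid}: CDS length {coding} not divisible by 3; downgraded to pseudogene")
            kind = "pseudogene"
        if min_orf_codons is not None and kind in {"protein", "orf"}:
            if coding // 3 - 1 < min_orf_codons:  # excludes the stop codon
                warnings.append(f"gene {gid}: ORF shorter than {min_orf_codons} codons")
        genes.append(
            GeneModel(
                id=gid,
                chromosome=row["chromosome"],
                strand=row["strand"],
                exons=exons,
                kind=kind,
                category=row["category"],
                family_id=row["family_id"],
                product=row["product"],
            )
        )
    return AnnotatedGenome(label, chroms, genes, warnings=warnings)


def write_genome_bundle(genome: AnnotatedGenome, fasta_path, gff3_path) -> None:
    """Write FASTA (wrapped at 60 columns) and GFF3 for a genome."""
    records = [
        SeqRecord(Seq(c.sequence), id=c.name, description="") for c in genome.chromosomes
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in genome.chromosomes:
            fh.write(f"##sequence-region {c.name} 1 {len(c)}\n")
        for g in sorted(genome.genes, key=lambda g: (g.chromosome, g.span)):
            attrs = [f"ID={g.id}", f"kind={g.kind}", f"category={g.category}"]
            if g.family_id:
                attrs.append(f"family={g.family_id}")
            if g.product:
                attrs.append(f"product={g.product}")
            fh.write(
                f"{g.chromosome}\tnmcompare\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{';'.join(attrs)}\n"
            )
            part = "CDS" if g.kind in {"protein", "orf", "pseudogene"} else "exon"
            for s, e in g.exons:
                fh.write(
                    f"{g.chromosome}\tnmcompare\t{part}\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\tParent={g.id}\n"
                )


def _as_handle(source):
    if isinstance(source, (str, Path)):
        return open(source)
    return source


# ---------------------------------------------------------------------------
# Summaries


def genome_summary(
    genome: AnnotatedGenome,
    exclude_regions: dict[str, list[tuple[int, int]]] | None = None,
    n_nonredundant: int | None = None,
) -> GenomeSummary:
    """Table-1-style summary: sizes, GC, gene/intron counts, mean spacer.

    ``exclude_regions`` (chromosome -> intervals) additionally reports GC
    over the complement of the given intervals, the convention used to
    quote internal GC with sub-telomeric repeats masked out.
    """
    sizes = {c.name: len(c) for c in genome.chromosomes}
    total = sum(sizes.values())
    all_seq = "".join(c.sequence for c in genome.chromosomes)
    gc_all = gc_fraction(all_seq) if all_seq else None

    gc_excl = None
    if exclude_regions is not None:
        kept = []
        for c in genome.chromosomes:
            mask = bytearray(len(c))
            for s, e in exclude_regions.get(c.name, []):
                for i in range(max(0, s), min(len(c), e)):
                    mask[i] = 1
            kept.append("".join(ch for ch, m in zip(c.sequence, mask) if not m))
        joined = "".join(kept)
        gc_excl = gc_fraction(joined) if joined else None

    n_protein = sum(1 for g in genome.genes if g.kind in {"protein", "orf"})
    n_trna = sum(1 for g in genome.genes if g.kind == "tRNA")
    n_introns = sum(len(g.exons) - 1 for g in genome.genes)

    spacers: list[int] = []
    for c in genome.chromosomes:
        spans = sorted(g.span for g in genome.genes_on(c.name))
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            spacers.append(max(0, s2 - e1))
    mean_spacer = (sum(spacers) / len(spacers)) if spacers else None
    density = (len(genome.genes) / (total / 1000.0)) if total else None

    return GenomeSummary(
        label=genome.label,
        total_size=total,
        chromosome_sizes=sizes,
        gc_overall=gc_all,
        gc_excluding_regions=gc_excl,
        n_protein_genes=n_protein,
        n_nonredundant_genes=n_nonredundant,
        n_introns=n_introns,
        n_trnas=n_trna,
        mean_spacer=mean_spacer,
        gene_density=density,
    )
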