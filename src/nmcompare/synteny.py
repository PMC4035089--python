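"""Gene-order extraction and syntenic-block detection between two genomes.

A syntenic block is a maximal run of ortholog families occurring
consecutively and in conserved (or, optionally, inverted) order in both
genomes. The criterion follows the convention used for nucleomorph
comparisons: runs of at least ``min_genes`` homologous genes in the same
order, with strict consecutiveness by default.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import AnnotatedGenome
from .gene_content import OrthologFamilyTable


@dataclass
class GeneOrder:
    """Per chromosome: ordered (family_id, strand, original_index) tuples."""

    genome: str
    per_chromosome: dict[str, list[tuple[str, str, int]]]

    def chromosomes(self) -> list[str]:
        return list(self.per_chromosome)


@dataclass
class SyntenyBlock:
    chromosome_a: str
    chromosome_b: str
    families: tuple[str, ...]
    orientation: str  # "same" | "inverted"
    positions_a: tuple[int, ...]
    positions_b: tuple[int, ...]

    @property
    def gene_count(self) -> int:
        return len(self.families)


def gene_order(
    genome: AnnotatedGenome,
    families: OrthologFamilyTable,
    shared_only: bool = False,
    partner_label: str | None = None,
) -> GeneOrder:
    """Ordered family lists per chromosome, ascending by gene start.

    With ``shared_only`` (requires ``partner_label``) families absent from
    the partner genome are dropped; the original coordinate rank is kept
    so gap allowances can still be applied downstream.
    """
    if shared_only and partner_label is None:
        raise ValueError("shared_only requires partner_label")
    fam_of_gene: dict[str, str] = {}
    for fam in families.family_ids:
        for gid in families.members(fam, genome.label):
            fam_of_gene[gid] = fam
    per_chrom: dict[str, list[tuple[str, str, int]]] = {}
    for c in genome.chromosomes:
        entries = []
        idx = 0
        for g in genome.genes_on(c.name):
            fam = fam_of_gene.get(g.id, g.family_id)
            if fam is None:
                idx += 1
                continue
            if shared_only and not families.present(fam, partner_label):
                idx += 1
                continue
            entries.append((fam, g.strand, idx))
            idx += 1
        per_chrom[c.name] = entries
    return GeneOrder(genome.label, per_chrom)


def detect_synteny_blocks(
    order_a: GeneOrder,
    order_b: GeneOrder,
    min_genes: int = 3,
    allow_inversion: bool = True,
    max_gap: int = 0,
) -> list[SyntenyBlock]:
    """Maximal conserved runs of families between two gene orders.

    A run extends while consecutive entries (allowing up to ``max_gap``
    intervening genes by original coordinate rank) carry the same family
    in both genomes, in the same direction or — when ``allow_inversion``
    — in reversed order. Candidate runs are resolved greedily by length
    then leftmost position; each gene placement joins at most one block.
    """
    candidates: list[SyntenyBlock] = []
    for chrom_a, ents_a in order_a.per_chromosome.items():
        for chrom_b, ents_b in order_b.per_chromosome.items():
            candidates.extend(
                _runs(chrom_a, ents_a, chrom_b, ents_b, max_gap, allow_inversion)
            )
    candidates.sort(
        key=lambda blk: (-blk.gene_count, blk.chromosome_a, blk.positions_a, blk.chromosome_b)
    )
    used_a: set[tuple[str, int]] = set()
    used_b: set[tuple[str, int]] = set()
    blocks = []
    for blk in candidates:
        if blk.gene_count < min_genes:
            continue
        keys_a = [(blk.chromosome_a, p) for p in blk.positions_a]
        keys_b = [(blk.chromosome_b, p) for p in blk.positions_b]
        if any(k in used_a for k in keys_a) or any(k in used_b for k in keys_b):
            continue
        used_a.update(keys_a)
        used_b.update(keys_b)
        blocks.append(blk)
    return blocks


def _runs(chrom_a, ents_a, chrom_b, ents_b, max_gap, allow_inversion):
    pos_b: dict[str, list[int]] = {}
    for j, (fam, _, _) in enumerate(ents_b):
        pos_b.setdefault(fam, []).append(j)

    runs = []
    for direction in (1, -1) if allow_inversion else (1,):
        seen_starts: set[tuple[int, int]] = set()
        for i, (fam, _, _) in enumerate(ents_a):
            for j in pos_b.get(fam, []):
                if (i, j) in seen_starts:
                    continue
                ii, jj, members = i, j, [(i, j)]
                while True:
                    ni, nj = ii + 1, jj + direction
                    if ni >= len(ents_a) or nj < 0 or nj >= len(ents_b):
                        break
                    if ents_a[ni][0] != ents_b[nj][0]:
                        break
                    if ents_a[ni][2] - ents_a[ii][2] > max_gap + 1:
                        break
                    if abs(ents_b[nj][2] - ents_b[jj][2]) > max_gap + 1:
                        break
                    ii, jj = ni, nj
                    members.append((ii, jj))
                for mi, mj in members:
                    seen_starts.add((mi, mj))
                # length-1 runs only once (orientation is moot for singletons)
                if len(members) >= 2 or direction == 1:
                    fams = tuple(ents_a[mi][0] for mi, _ in members)
                    runs.append(
                        SyntenyBlock(
                            chromosome_a=chrom_a,
                            chromosome_b=chrom_b,
                            families=fams,
                            orientation="same" if direction == 1 else "inverted",
                            positions_a=tuple(mi for mi, _ in members),
                            positions_b=tuple(mj for _, mj in members),
                        )
                    )
    return runs


def synteny_stats(blocks: list[SyntenyBlock]) -> dict:
    """Block count, mean genes per block, and total genes in blocks."""
    n = len(blocks)
    total = sum(b.gene_count for b in blocks)
    return {
        "count": n,
        "mean_genes": total / n if n else None,
        "total_genes": total,
    }
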