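"""Intergenic spacers, protein lengths, redundancy collapse, Welch tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy import stats

from .core import AnnotatedGenome
from .gene_content import OrthologFamilyTable


@dataclass
class SpacerStats:
    lengths: list[int]
    per_chromosome: dict[str, list[int]]
    n_overlapping: int = 0

    @property
    def count(self) -> int:
        return len(self.lengths)

    @property
    def mean(self) -> float | None:
        return sum(self.lengths) / len(self.lengths) if self.lengths else None


@dataclass
class TestResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float


def intergenic_spacers(
    genome: AnnotatedGenome,
    exclude_regions: dict[str, list[tuple[int, int]]] | None = None,
) -> SpacerStats:
    """Gaps between transcriptional-unit extents of adjacent genes.

    Genes are sorted by start per chromosome regardless of strand;
    overlapping genes contribute a spacer of 0 (flagged). A spacer whose
    interval overlaps any excluded region is dropped — used to avoid
    counting gaps that merely bridge masked features such as boundary
    tandem arrays.
    """
    lengths: list[int] = []
    per_chrom: dict[str, list[int]] = {}
    n_overlap = 0
    for c in genome.chromosomes:
        spans = sorted(g.span for g in genome.genes_on(c.name))
        excl = sorted(exclude_regions.get(c.name, [])) if exclude_regions else []
        chrom_lengths = []
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                n_overlap += 1
                chrom_lengths.append(0)
                continue
            if any(s < s2 and e > e1 for s, e in excl):
                continue
            chrom_lengths.append(s2 - e1)
        per_chrom[c.name] = chrom_lengths
        lengths.extend(chrom_lengths)
    return SpacerStats(lengths, per_chrom, n_overlap)


def protein_length_stats(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    mode: str = "all",
    families: OrthologFamilyTable | None = None,
    exclude_categories: frozenset = frozenset({"nORFan"}),
) -> dict:
    """Per-genome protein lengths (aa, stop excluded) and their means.

    ``mode='all'`` measures every protein/ORF gene. ``mode='shared-only'``
    measures one protein per ortholog family present in both genomes,
    excluding ORFan-type families; a family with several members in one
    genome contributes its longest member (with a warning).
    """
    if mode == "all":
        la = _all_lengths(genome_a)
        lb = _all_lengths(genome_b)
        pairs = None
    elif mode == "shared-only":
        if families is None:
            raise ValueError("shared-only mode requires a family table")
        la, lb, pairs = [], [], []
        for fam in sorted(families.family_ids):
            if families.category(fam) in exclude_categories:
                continue
            ga = _pick_longest(genome_a, families.members(fam, genome_a.label))
            gb = _pick_longest(genome_b, families.members(fam, genome_b.label))
            if ga is None or gb is None:
                continue
            if ga.kind != "protein" or gb.kind != "protein":
                continue
            la.append(len(ga.protein_sequence(genome_a.chromosome(ga.chromosome))))
            lb.append(len(gb.protein_sequence(genome_b.chromosome(gb.chromosome))))
            pairs.append((fam, ga.id, gb.id))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {
        "lengths_a": la,
        "lengths_b": lb,
        "mean_a": sum(la) / len(la) if la else None,
        "mean_b": sum(lb) / len(lb) if lb else None,
        "pairs": pairs,
    }


def _all_lengths(genome: AnnotatedGenome) -> list[int]:
    return [
        len(g.protein_sequence(genome.chromosome(g.chromosome)))
        for g in genome.genes
        if g.kind in {"protein", "orf"}
    ]


def _pick_longest(genome: AnnotatedGenome, ids: list[str]):
    genes = [genome.gene(i) for i in ids if i in genome._genes_by_id]
    if not genes:
        return None
    if len(genes) > 1:
        warnings.warn(f"family with {len(genes)} members in {genome.label}; longest used")
    return max(genes, key=lambda g: g.coding_length)


def collapse_redundant(
    genome: AnnotatedGenome,
    identity_threshold: float = 0.98,
    coverage_threshold: float = 0.95,
) -> tuple[dict[str, int], int]:
    """Single-linkage clustering of near-identical proteins.

    Two proteins link when their global-alignment identity is at least
    ``identity_threshold`` over at least ``coverage_threshold`` of the
    longer sequence; the non-redundant count is the number of clusters.
    This collapses conversion-homogenized multicopy genes (e.g. the six
    sub-telomeric copies of each repeat ORF) without merging diverged
    paralogs. Returns (gene_id -> cluster index, number of clusters).
    """
    from .introns import align_proteins  # one aligner, one behaviour

    prots = [
        (g.id, g.protein_sequence(genome.chromosome(g.chromosome)))
        for g in genome.genes
        if g.kind in {"protein", "orf"}
    ]
    n = len(prots)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # identical sequences short-circuit the aligner
    by_seq: dict[str, int] = {}
    reps = []
    for i, (_, seq) in enumerate(prots):
        if seq in by_seq:
            union(by_seq[seq], i)
        else:
            by_seq[seq] = i
            reps.append(i)

    for ai in range(len(reps)):
        for bi in range(ai + 1, len(reps)):
            i, j = reps[ai], reps[bi]
            sa, sb = prots[i][1], prots[j][1]
            if not sa or not sb:
                continue
            longer = max(len(sa), len(sb))
            if min(len(sa), len(sb)) / longer < coverage_threshold:
                continue
            res = align_proteins(sa, sb)
            cols = list(zip(res.aligned_a, res.aligned_b))
            aligned = sum(1 for x, y in cols if x != "-" and y != "-")
            matches = sum(1 for x, y in cols if x == y and x != "-")
            if aligned / longer >= coverage_threshold and (
                aligned > 0 and matches / aligned >= identity_threshold
            ):
                union(i, j)

    roots = {find(i) for i in range(n)}
    index = {r: k for k, r in enumerate(sorted(roots))}
    assignment = {prots[i][0]: index[find(i)] for i in range(n)}
    return assignment, len(roots)


def welch_t_test(sample_a, sample_b) -> TestResult:
    """Welch's unequal-variance two-sided t-test."""
    a = list(map(float, sample_a))
    b = list(map(float, sample_b))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    var_a = stats.tvar(a) if len(set(a)) > 1 else 0.0
    var_b = stats.tvar(b) if len(set(b)) > 1 else 0.0
    if var_a == 0.0 and var_b == 0.0:
        if a == b:
            return TestResult(0.0, float(len(a) + len(b) - 2), 1.0)
        raise ValueError("both samples are degenerate (zero variance)")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue))
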