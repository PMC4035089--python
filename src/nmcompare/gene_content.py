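"""Ortholog family tables, pairwise Venn overlaps and core gene sets.

Homology is *input* here: families come from a user-supplied table (the
kind of thing produced by reciprocal similarity searches), and the
operations only count presence/absence. A multicopy family counts once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd


@dataclass
class OrthologFamilyTable:
    """family_id -> {genome label -> [gene ids]} plus a category per family."""

    families: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def add(self, family_id: str, genome: str, gene_id: str, category: str = "unassigned") -> None:
        fam = self.families.setdefault(family_id, {})
        fam.setdefault(genome, []).append(gene_id)
        prev = self.categories.setdefault(family_id, category)
        if prev != category:
            raise ValueError(f"family {family_id}: inconsistent categories {prev!r}/{category!r}")

    @property
    def family_ids(self) -> list[str]:
        return list(self.families)

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for fam in self.families.values():
            for label in fam:
                seen.setdefault(label)
        return list(seen)

    def category(self, family_id: str) -> str:
        return self.categories.get(family_id, "unassigned")

    def members(self, family_id: str, genome: str) -> list[str]:
        return self.families.get(family_id, {}).get(genome, [])

    def present(self, family_id: str, genome: str) -> bool:
        return bool(self.members(family_id, genome))

    def families_of(self, genome: str, category: str | None = None) -> set[str]:
        return {
            f
            for f in self.families
            if self.present(f, genome)
            and (category is None or self.category(f) == category)
        }

    # -- TSV round trip ----------------------------------------------------
    def to_tsv(self, path) -> None:
        rows = [
            {"family_id": f, "category": self.category(f), "genome": g, "gene_id": gid}
            for f, by_genome in self.families.items()
            for g, ids in by_genome.items()
            for gid in ids
        ]
        pd.DataFrame(rows, columns=["family_id", "category", "genome", "gene_id"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "OrthologFamilyTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        table = cls()
        for row in df.itertuples(index=False):
            table.add(row.family_id, row.genome, row.gene_id, row.category)
        return table


@dataclass
class VennCounts:
    shared: int
    unique_a: int
    unique_b: int
    pct_shared_a: float | None
    pct_shared_b: float | None
    per_category: dict[str, tuple[int, int, int]]


def set_overlap(
    families: OrthologFamilyTable,
    label_a: str,
    label_b: str,
    category: str | None = None,
) -> VennCounts:
    """Shared / unique family counts between two genomes.

    A family is shared iff it has members in both genomes. The two
    percentages use each side's own family total as denominator, so they
    are generally unequal even though the shared count is symmetric.
    """
    known = set(families.labels)
    for lab in (label_a, label_b):
        if lab not in known:
            raise ValueError(f"unknown genome label {lab!r}")
    fams_a = families.families_of(label_a, category)
    fams_b = families.families_of(label_b, category)
    shared = fams_a & fams_b
    per_cat: dict[str, tuple[int, int, int]] = {}
    for f in fams_a | fams_b:
        cat = families.category(f)
        s, ua, ub = per_cat.get(cat, (0, 0, 0))
        if f in shared:
            s += 1
        elif f in fams_a:
            ua += 1
        else:
            ub += 1
        per_cat[cat] = (s, ua, ub)
    return VennCounts(
        shared=len(shared),
        unique_a=len(fams_a - fams_b),
        unique_b=len(fams_b - fams_a),
        pct_shared_a=100.0 * len(shared) / len(fams_a) if fams_a else None,
        pct_shared_b=100.0 * len(shared) / len(fams_b) if fams_b else None,
        per_category=per_cat,
    )


def core_set(
    families: OrthologFamilyTable,
    group: list[str],
    exclude_categories: frozenset = frozenset({"plastid-associated", "spliceosomal"}),
) -> list[str]:
    """Families present in *every* genome of ``group``, minus excluded categories."""
    if not group:
        raise ValueError("empty genome group")
    core = None
    for label in group:
        fams = families.families_of(label)
        core = fams if core is None else core & fams
    return sorted(f for f in core if families.category(f) not in exclude_categories)


def overlap_with(
    core_a: list[str],
    families: OrthologFamilyTable,
    group_b: list[str],
) -> tuple[int, float | None]:
    """How many core-A families occur in at least one genome of group B."""
    if not core_a:
        warnings.warn("empty core set; overlap is 0")
        return 0, None
    present_b = set()
    for label in group_b:
        present_b |= families.families_of(label)
    shared = sum(1 for f in core_a if f in present_b)
    return shared, 100.0 * shared / len(core_a)
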