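"""Seeded generator of paired annotated genomes with planted ground truth.

The generator emulates the architecture of a reduced nucleomorph-style
genome pair: three linear chromosomes; near-identical GC-rich terminal
repeats on all six ends (differing by a handful of substitutions in
total); a degenerate 36 nt tandem repeat at the boundary between each
terminal repeat and the internal single-copy region; AT-rich internal
regions densely packed with short protein genes separated by small
spacers; tiny GT-AG introns (18–23 nt, 19 nt modal) whose positions are
partially conserved between the two genomes; planted syntenic blocks;
and a drastic expression deficit of the sub-telomeric ORFs relative to
internal genes.

Everything is deterministic for a fixed (config, seed); the returned
:class:`TruthSet` is sufficient to score every detector in the package
exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from ._seq import random_dna, random_dna_exact, resolve_iupac, revcomp
from .core import AnnotatedGenome, Chromosome, GeneModel
from .gene_content import OrthologFamilyTable

_STOPS = {"TAA", "TAG", "TGA"}
_CATEGORY_PROBS = {
    "eukaryotic-conserved": 0.55,
    "plastid-associated": 0.06,
    "nORFan": 0.22,
    "spliceosomal": 0.05,
    "other": 0.12,
}
_FLANK_RESIDUES = 15  # introns are planted clear of protein ends by this margin


def _default_intron_lengths() -> dict[int, float]:
    # mass on 18-23 nt with 19 nt modal
    return {18: 0.12, 19: 0.50, 20: 0.12, 21: 0.10, 22: 0.09, 23: 0.07}


@dataclass
class GeneratorConfig:
    """All knobs of the paired-genome generator (desk-scale defaults)."""

    n_chromosomes: int = 3
    chromosome_length: int = 20_000
    subtel_length: int = 3_500
    subtel_gc: float = 0.494
    internal_gc: float = 0.24
    subtel_mismatches: int = 3
    boundary_unit: str = "RTAYCTRGTTRCCTTATCGTATGCCATGGCTTTATC"
    boundary_copies_range: tuple[int, int] = (5, 29)
    genes_per_chromosome: int = 10
    mean_spacer: float = 147.4
    mean_cds_codons: int = 170
    sd_cds_codons: int = 30
    min_cds_codons: int = 60
    introns_per_gene_mean: float = 2.0
    intron_length_distribution: dict[int, float] = field(default_factory=_default_intron_lengths)
    fraction_phase0: float = 0.583
    n_gc_ag: int = 0
    n_ga_ag: int = 0
    longest_intron_length: int | None = None
    n_subtel_orfs: int = 5
    subtel_orf_codons: int = 80
    subtel_rrna_length: int = 600
    shared_fraction: float = 0.85
    shared_intron_fraction: float = 0.9
    unique_b_introns_per_gene: float = 0.3
    synteny_blocks: tuple[int, ...] = (4, 5, 6)
    codon_mutation_rate: float = 0.08
    n_private_b: int = 3
    expression_ratio: float = 2500.0
    internal_depth: float = 100.0
    intergenic_depth: float | None = None
    collapsed_copies: int = 5
    collapsed_region_length: int = 600
    label_a: str = "genomeA"
    label_b: str = "genomeB"

    def __post_init__(self) -> None:
        if 2 * self.subtel_length >= self.chromosome_length:
            raise ValueError("2*subtel_length must be < chromosome_length")
        total = sum(self.intron_length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("intron length probabilities must sum to 1")
        for name in ("subtel_gc", "internal_gc", "fraction_phase0",
                     "shared_fraction", "shared_intron_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")

    @classmethod
    def full_scale(cls, **overrides) -> "GeneratorConfig":
        """Preset approximating the deposited genomes' physical scale."""
        base = dict(
            chromosome_length=200_000,
            subtel_length=35_000,
            genes_per_chromosome=40,
            mean_cds_codons=247,
            sd_cds_codons=60,
            n_subtel_orfs=20,
        )
        base.update(overrides)
        return cls(**base)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["boundary_copies_range"] = list(self.boundary_copies_range)
        data["synteny_blocks"] = list(self.synteny_blocks)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["boundary_copies_range"] = tuple(data["boundary_copies_range"])
        data["synteny_blocks"] = tuple(data["synteny_blocks"])
        data["intron_length_distribution"] = {
            int(k): float(v) for k, v in data["intron_length_distribution"].items()
        }
        return cls(**data)


@dataclass
class TruthIntron:
    genome: str
    gene_id: str
    family: str | None
    chromosome: str
    strand: str
    start: int
    end: int
    offset: int  # spliced-CDS bases upstream of the intron
    phase: int
    donor_dinucleotide: str
    acceptor_dinucleotide: str
    shared: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    """Planted features, sufficient to score every detector exactly."""

    subtel_regions: dict[str, dict[str, list[tuple[int, int]]]]
    boundary_arrays: dict[str, list[tuple[str, int, int, int]]]
    introns: dict[str, list[TruthIntron]]
    families: OrthologFamilyTable
    planted_blocks: list[tuple[str, ...]]
    expression_class: dict[str, dict[str, str]]
    collapsed_regions: dict[str, list[tuple[str, int, int, int]]]


# ---------------------------------------------------------------------------
# gene-level building blocks


@dataclass
class _IntronPlan:
    offset: int
    length: int
    donor: str
    acceptor: str
    shared: bool = False
    sequence: str = ""


@dataclass
class _GenePlan:
    family: str | None
    category: str
    cds: str  # includes the terminal stop codon
    introns: list[_IntronPlan]


def _sample_cds(rng: np.random.Generator, cfg: GeneratorConfig, n_codons: int) -> str:
    body = random_dna(rng, 3 * (n_codons - 2), gc=cfg.internal_gc)
    codons = ["ATG"] + [body[i : i + 3] for i in range(0, len(body), 3)] + ["TAA"]
    for i in range(1, len(codons) - 1):
        if codons[i] in _STOPS:
            codons[i] = "TTA"
    return "".join(codons)


def _sample_intron_length(rng: np.random.Generator, cfg: GeneratorConfig) -> int:
    lengths = sorted(cfg.intron_length_distribution)
    probs = [cfg.intron_length_distribution[k] for k in lengths]
    return int(rng.choice(lengths, p=probs))


def _intron_sequence(rng: np.random.Generator, plan: _IntronPlan) -> str:
    interior = random_dna(rng, plan.length - 4, gc=0.15)
    return plan.donor + interior + plan.acceptor


def _allowed_residues(cfg: GeneratorConfig, n_codons: int) -> range:
    return range(_FLANK_RESIDUES + 1, n_codons - _FLANK_RESIDUES - 1)


def _plan_introns(
    rng: np.random.Generator, cfg: GeneratorConfig, n_codons: int,
    n_introns: int, exclude_residues: set[int] = frozenset(),
) -> list[_IntronPlan]:
    allowed = [r for r in _allowed_residues(cfg, n_codons) if r not in exclude_residues]
    n = min(n_introns, len(allowed))
    if n <= 0:
        return []
    residues = sorted(rng.choice(allowed, size=n, replace=False).tolist())
    plans = []
    for r in residues:
        phase = 0 if rng.random() < cfg.fraction_phase0 else int(rng.integers(1, 3))
        length = _sample_intron_length(rng, cfg)
        if length < 4:
            continue
        plans.append(_IntronPlan(offset=3 * r + phase, length=length, donor="GT", acceptor="AG"))
    return plans


def _apply_minus2_bias(cds: str, introns: list[_IntronPlan], rng: np.random.Generator) -> str:
    """Favour A at the exonic position two bases upstream of each donor."""
    chars = list(cds)
    for ip in introns:
        pos = ip.offset - 2
        if pos < 0 or rng.random() >= 0.85:
            continue
        codon_start = (pos // 3) * 3
        trial = chars[:]
        trial[pos] = "A"
        if "".join(trial[codon_start : codon_start + 3]) not in _STOPS:
            chars[pos] = "A"
    return "".join(chars)


def _assemble_block(plan: _GenePlan, rng: np.random.Generator):
    """Transcript-orientation block, exon transcript-intervals, intron layout."""
    introns = sorted(plan.introns, key=lambda ip: ip.offset)
    parts, exons_t, introns_t = [], [], []
    prev = 0
    t = 0
    for ip in introns:
        exon = plan.cds[prev : ip.offset]
        parts.append(exon)
        exons_t.append((t, t + len(exon)))
        t += len(exon)
        seq = ip.sequence or _intron_sequence(rng, ip)
        ip.sequence = seq
        parts.append(seq)
        introns_t.append((t, ip))
        t += len(seq)
        prev = ip.offset
    exon = plan.cds[prev:]
    parts.append(exon)
    exons_t.append((t, t + len(exon)))
    t += len(exon)
    return "".join(parts), exons_t, introns_t


# ---------------------------------------------------------------------------
# genome-level assembly


@dataclass
class _SubtelTemplate:
    sequence: str
    orf_intervals: list[tuple[int, int]]  # within-template coordinates
    orf_families: list[str]
    rrna_interval: tuple[int, int] | None


def _make_subtel_template(rng, cfg: GeneratorConfig, label: str) -> _SubtelTemplate:
    # exact composition: the repeat's GC level is a property, not a mean
    seq = random_dna_exact(rng, cfg.subtel_length, cfg.subtel_gc)
    orf_len = 3 * cfg.subtel_orf_codons
    cursor = 100
    rrna = None
    if cfg.subtel_rrna_length and cursor + cfg.subtel_rrna_length < cfg.subtel_length - 100:
        rrna = (cursor, cursor + cfg.subtel_rrna_length)
        cursor = rrna[1]
    intervals, fams = [], []
    for k in range(cfg.n_subtel_orfs):
        cursor += int(rng.geometric(1.0 / cfg.mean_spacer))
        if cursor + orf_len > cfg.subtel_length - 50:
            break
        intervals.append((cursor, cursor + orf_len))
        fams.append(f"{label}.storf{k:02d}")
        cursor += orf_len
    return _SubtelTemplate(seq, intervals, fams, rrna)


def _subtel_copies(rng, cfg: GeneratorConfig, template: _SubtelTemplate) -> list[str]:
    """Six end copies differing by exactly ``subtel_mismatches`` substitutions in total."""
    n_ends = 2 * cfg.n_chromosomes
    copies = [list(template.sequence) for _ in range(n_ends)]
    hit: set[tuple[int, int]] = set()
    while len(hit) < cfg.subtel_mismatches:
        end = int(rng.integers(n_ends))
        pos = int(rng.integers(cfg.subtel_length))
        if (end, pos) in hit:
            continue
        hit.add((end, pos))
        old = copies[end][pos]
        alt = "ACGT".replace(old, "")
        copies[end][pos] = alt[int(rng.integers(3))]
    return ["".join(c) for c in copies]


def _boundary_array(rng, cfg: GeneratorConfig) -> tuple[str, int]:
    lo, hi = cfg.boundary_copies_range
    copies = int(rng.integers(lo, hi + 1))
    seq = "".join(resolve_iupac(rng, cfg.boundary_unit) for _ in range(copies))
    return seq, copies


def _plan_layout(rng, cfg: GeneratorConfig) -> list[list[int]]:
    """Unit sizes (blocks then singleton fill) per chromosome for genome A."""
    capacity = [cfg.genes_per_chromosome] * cfg.n_chromosomes
    units: list[list[int]] = [[] for _ in range(cfg.n_chromosomes)]
    for size in cfg.synteny_blocks:
        order = sorted(range(cfg.n_chromosomes), key=lambda i: -capacity[i])
        target = next((i for i in order if capacity[i] >= size), None)
        if target is None:
            raise ValueError("synteny block budget exceeds genes_per_chromosome capacity")
        units[target].append(size)
        capacity[target] -= size
    for i in range(cfg.n_chromosomes):
        units[i].extend([1] * capacity[i])
        perm = rng.permutation(len(units[i]))
        units[i] = [units[i][k] for k in perm]
    return units


def generate_genome_pair(
    config: GeneratorConfig, seed: int
) -> tuple[AnnotatedGenome, AnnotatedGenome, OrthologFamilyTable, TruthSet]:
    """Generate a deterministic annotated genome pair with full ground truth."""
    cfg = config
    ss = np.random.SeedSequence(seed)
    r_layout, r_a, r_b = (np.random.default_rng(s) for s in ss.spawn(3))

    # --- genome-A unit layout and family bookkeeping
    unit_sizes = _plan_layout(r_layout, cfg)
    families = OrthologFamilyTable()
    fam_counter = 0
    chrom_units: list[list[list[str]]] = []  # per chrom: list of units (family lists)
    planted_blocks: list[tuple[str, ...]] = []
    for sizes in unit_sizes:
        units = []
        for size in sizes:
            fams = [f"fam{fam_counter + k:04d}" for k in range(size)]
            fam_counter += size
            units.append(fams)
            if size >= 2:
                planted_blocks.append(tuple(fams))
        chrom_units.append(units)

    cats = list(_CATEGORY_PROBS)
    probs = list(_CATEGORY_PROBS.values())
    category_of = {}
    block_fams = {f for blk in planted_blocks for f in blk}
    shared_of = {}
    for i in range(fam_counter):
        fam = f"fam{i:04d}"
        category_of[fam] = cats[int(r_layout.choice(len(cats), p=probs))]
        shared_of[fam] = fam in block_fams or r_layout.random() < cfg.shared_fraction

    # --- genome-A gene plans
    plans_a: dict[str, _GenePlan] = {}
    for fam in sorted(category_of):
        n_codons = max(cfg.min_cds_codons,
                       int(round(r_a.normal(cfg.mean_cds_codons, cfg.sd_cds_codons))))
        cds = _sample_cds(r_a, cfg, n_codons)
        introns = _plan_introns(r_a, cfg, n_codons, int(r_a.poisson(cfg.introns_per_gene_mean)))
        cds = _apply_minus2_bias(cds, introns, r_a)
        plans_a[fam] = _GenePlan(fam, category_of[fam], cds, introns)

    _allocate_special_introns(r_a, cfg, plans_a)

    # --- genome-B plans derived from shared families
    plans_b: dict[str, _GenePlan] = {}
    for fam, pa in plans_a.items():
        if not shared_of[fam]:
            continue
        cds = _mutate_cds(r_b, cfg, pa.cds)
        introns_b: list[_IntronPlan] = []
        used = set()
        for ip in pa.introns:
            used.add(ip.offset // 3)
            if r_b.random() < cfg.shared_intron_fraction:
                introns_b.append(
                    _IntronPlan(ip.offset, _sample_intron_length(r_b, cfg), "GT", "AG", shared=True)
                )
                ip.shared = True
        extra = _plan_introns(
            r_b, cfg, len(cds) // 3, int(r_b.poisson(cfg.unique_b_introns_per_gene)),
            exclude_residues=used,
        )
        introns_b.extend(extra)
        cds = _apply_minus2_bias(cds, introns_b, r_b)
        plans_b[fam] = _GenePlan(fam, pa.category, cds, introns_b)
    for k in range(cfg.n_private_b):
        fam = f"famB{k:03d}"
        n_codons = max(cfg.min_cds_codons,
                       int(round(r_b.normal(cfg.mean_cds_codons, cfg.sd_cds_codons))))
        cds = _sample_cds(r_b, cfg, n_codons)
        introns = _plan_introns(r_b, cfg, n_codons, int(r_b.poisson(cfg.introns_per_gene_mean)))
        plans_b[fam] = _GenePlan(fam, "nORFan", cds, introns)

    # --- genome-B unit order (no A-adjacency preserved)
    order_a_units: list[list[list[str]]] = chrom_units
    b_units = [list(u) for units in chrom_units for u in units
               if all(shared_of[f] for f in u)]
    b_units += [[f"famB{k:03d}"] for k in range(cfg.n_private_b)]
    b_chrom_units = _shuffle_b_units(r_b, cfg, order_a_units, b_units, shared_of)

    # --- assemble both genomes
    genome_a, truth_a = _assemble_genome(
        r_a, cfg, cfg.label_a, order_a_units, plans_a, reserve_collapsed=True
    )
    genome_b, truth_b = _assemble_genome(
        r_b, cfg, cfg.label_b, b_chrom_units, plans_b, reserve_collapsed=False
    )

    # --- family table
    for genome, truth in ((genome_a, truth_a), (genome_b, truth_b)):
        for g in genome.genes:
            if g.family_id is not None:
                families.add(g.family_id, genome.label, g.id, g.category)

    # mark shared flags on A's truth introns (partner decided during B planning)
    shared_offsets = {
        (fam, ip.offset)
        for fam, pb in plans_b.items()
        for ip in pb.introns
        if ip.shared
    }
    for ti in truth_a["introns"]:
        ti.shared = (ti.family, ti.offset) in shared_offsets
    for ti in truth_b["introns"]:
        ti.shared = (ti.family, ti.offset) in shared_offsets

    truth = TruthSet(
        subtel_regions={cfg.label_a: truth_a["subtel"], cfg.label_b: truth_b["subtel"]},
        boundary_arrays={cfg.label_a: truth_a["arrays"], cfg.label_b: truth_b["arrays"]},
        introns={cfg.label_a: truth_a["introns"], cfg.label_b: truth_b["introns"]},
        families=families,
        planted_blocks=planted_blocks,
        expression_class={cfg.label_a: truth_a["expression"], cfg.label_b: truth_b["expression"]},
        collapsed_regions={cfg.label_a: truth_a["collapsed"], cfg.label_b: truth_b["collapsed"]},
    )
    return genome_a, genome_b, families, truth


def _allocate_special_introns(rng, cfg: GeneratorConfig, plans: dict[str, _GenePlan]) -> None:
    all_introns = [ip for p in plans.values() for ip in p.introns]
    if not all_introns:
        return
    idx = rng.permutation(len(all_introns))
    k = 0
    for _ in range(cfg.n_gc_ag):
        if k < len(idx):
            all_introns[idx[k]].donor = "GC"
            k += 1
    for _ in range(cfg.n_ga_ag):
        if k < len(idx):
            all_introns[idx[k]].donor = "GA"
            k += 1
    if cfg.longest_intron_length is not None:
        all_introns[idx[k % len(idx)]].length = cfg.longest_intron_length


def _mutate_cds(rng, cfg: GeneratorConfig, cds: str) -> str:
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i in range(1, len(codons) - 1):
        if rng.random() < cfg.codon_mutation_rate:
            new = random_dna(rng, 3, gc=cfg.internal_gc)
            codons[i] = "TTA" if new in _STOPS else new
    return "".join(codons)


def _shuffle_b_units(rng, cfg, a_chrom_units, b_units, shared_of):
    """Distribute B's units over chromosomes avoiding any preserved A adjacency."""
    forbidden: set[tuple[str, str]] = set()
    for units in a_chrom_units:
        shared_units = [tuple(u) for u in units if all(shared_of[f] for f in u)]
        for u, v in zip(shared_units, shared_units[1:]):
            forbidden.add((u[-1], v[0]))
            forbidden.add((v[0], u[-1]))
    for _ in range(1000):
        perm = [b_units[i] for i in rng.permutation(len(b_units))]
        # balance gene counts, not unit counts, across chromosomes
        chroms: list[list[list[str]]] = [[] for _ in range(cfg.n_chromosomes)]
        totals = [0] * cfg.n_chromosomes
        for unit in perm:
            k = int(np.argmin(totals))
            chroms[k].append(unit)
            totals[k] += len(unit)
        ok = True
        for units in chroms:
            for u, v in zip(units, units[1:]):
                if (u[-1], v[0]) in forbidden:
                    ok = False
        if ok:
            return chroms
    raise RuntimeError("could not shuffle genome-B units without preserved adjacency")


def _assemble_genome(rng, cfg: GeneratorConfig, label, chrom_units, plans, reserve_collapsed):
    template = _make_subtel_template(rng, cfg, label)
    copies = _subtel_copies(rng, cfg, template)
    chromosomes, genes = [], []
    truth = {"subtel": {}, "arrays": [], "introns": [], "expression": {}, "collapsed": []}

    for ci in range(cfg.n_chromosomes):
        name = f"{label}_chr{ci + 1}"
        left_copy, right_copy = copies[2 * ci], copies[2 * ci + 1]
        arr_l, copies_l = _boundary_array(rng, cfg)
        arr_r, copies_r = _boundary_array(rng, cfg)
        internal_space = (
            cfg.chromosome_length - 2 * cfg.subtel_length - len(arr_l) - len(arr_r)
        )
        reserve = cfg.collapsed_region_length if (reserve_collapsed and ci == 0) else 0

        fams = [f for unit in chrom_units[ci] for f in unit] if ci < len(chrom_units) else []
        blocks = []
        for fam in fams:
            plan = plans[fam]
            strand = "+" if rng.random() < 0.5 else "-"
            block, exons_t, introns_t = _assemble_block(plan, rng)
            spacer = int(rng.geometric(1.0 / cfg.mean_spacer))
            blocks.append((fam, plan, strand, block, exons_t, introns_t, spacer))
        need = sum(len(b[3]) + b[6] for b in blocks) + reserve
        if need > internal_space:
            raise ValueError(
                f"{name}: genes+spacers ({need} bp) exceed internal region ({internal_space} bp)"
            )

        parts = [left_copy, arr_l]
        cursor = cfg.subtel_length + len(arr_l)
        internal_start = cursor
        for gi, (fam, plan, strand, block, exons_t, introns_t, spacer) in enumerate(blocks):
            parts.append(random_dna(rng, spacer, cfg.internal_gc))
            cursor += spacer
            gstart = cursor
            gseq = block if strand == "+" else revcomp(block)
            parts.append(gseq)
            cursor += len(block)
            L = len(block)
            if strand == "+":
                exons = [(gstart + s, gstart + e) for s, e in exons_t]
            else:
                exons = sorted((gstart + L - e, gstart + L - s) for s, e in exons_t)
            gid = f"{label}_c{ci + 1}g{gi:03d}"
            genes.append(
                GeneModel(
                    id=gid, chromosome=name, strand=strand, exons=exons,
                    kind="protein", category=plan.category, family_id=fam,
                )
            )
            truth["expression"][gid] = "internal"
            for t_start, ip in introns_t:
                if strand == "+":
                    s, e = gstart + t_start, gstart + t_start + ip.length
                else:
                    s, e = gstart + L - t_start - ip.length, gstart + L - t_start
                truth["introns"].append(
                    TruthIntron(
                        genome=label, gene_id=gid, family=fam, chromosome=name,
                        strand=strand, start=s, end=e, offset=ip.offset,
                        phase=ip.offset % 3, donor_dinucleotide=ip.donor,
                        acceptor_dinucleotide=ip.acceptor, shared=ip.shared,
                    )
                )
        filler = internal_space - sum(len(b[3]) + b[6] for b in blocks)
        if reserve:
            truth["collapsed"].append(
                (name, cursor, cursor + cfg.collapsed_region_length, cfg.collapsed_copies)
            )
        parts.append(random_dna(rng, filler, cfg.internal_gc))
        cursor += filler
        parts.append(arr_r)
        arr_r_start = cursor
        cursor += len(arr_r)
        parts.append(revcomp(right_copy))
        seq = "".join(parts)
        assert len(seq) == cfg.chromosome_length
        chromosomes.append(Chromosome(name, seq))

        clen = cfg.chromosome_length
        truth["subtel"][name] = [(0, cfg.subtel_length), (clen - cfg.subtel_length, clen)]
        truth["arrays"].append((name, cfg.subtel_length, cfg.subtel_length + len(arr_l), copies_l))
        truth["arrays"].append((name, arr_r_start, arr_r_start + len(arr_r), copies_r))

        # annotate the terminal-repeat genes on both ends
        for side, offset_map, strand in (
            ("L", lambda s, e: (s, e), "+"),
            ("R", lambda s, e: (clen - e, clen - s), "-"),
        ):
            if template.rrna_interval:
                s, e = offset_map(*template.rrna_interval)
                gid = f"{label}_c{ci + 1}{side}_rrn"
                genes.append(GeneModel(gid, name, strand, [(s, e)], kind="rRNA",
                                       category="other", family_id=None))
                truth["expression"][gid] = "subtelomeric"
            for (os_, oe), fam in zip(template.orf_intervals, template.orf_families):
                s, e = offset_map(os_, oe)
                gid = f"{label}_c{ci + 1}{side}_{fam.split('.')[-1]}"
                genes.append(GeneModel(gid, name, strand, [(s, e)], kind="orf",
                                       category="nORFan", family_id=fam))
                truth["expression"][gid] = "subtelomeric"

    genome = AnnotatedGenome(label, chromosomes, genes)
    return genome, truth


# ---------------------------------------------------------------------------
# coverage and junction evidence


def generate_coverage_track(genome, truth: TruthSet, config: GeneratorConfig, seed: int):
    """Per-base Poisson depth with the configured expression contrast.

    Internal genes (and intergenic baseline) draw at ``internal_depth``;
    everything inside the terminal repeats draws at
    ``internal_depth / expression_ratio``; planted collapsed regions draw
    at ``collapsed_copies`` times the baseline.
    """
    from .expression import CoverageTrack

    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
    base = cfg.intergenic_depth if cfg.intergenic_depth is not None else cfg.internal_depth
    low = cfg.internal_depth / cfg.expression_ratio
    depths = {}
    label = genome.label
    for c in genome.chromosomes:
        mean = np.full(len(c), float(base))
        for s, e in truth.subtel_regions[label].get(c.name, []):
            mean[s:e] = low
        for g in genome.genes:
            if g.chromosome != c.name:
                continue
            cls = truth.expression_class[label].get(g.id)
            if cls == "internal":
                mean[g.start : g.end] = cfg.internal_depth
        for chrom, s, e, copies in truth.collapsed_regions.get(label, []):
            if chrom == c.name:
                mean[s:e] *= copies
        depths[c.name] = rng.poisson(mean).astype(float)
    return CoverageTrack(depths)


@dataclass
class SamRead:
    qname: str
    chrom: str
    pos: int
    cigar: str
    seq: str


def generate_junction_records(
    genome, truth: TruthSet, reads_per_junction: int = 5, seed: int = 0, anchor: int = 20
) -> list[SamRead]:
    """Gapped (spliced) reads exactly spanning every planted intron."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5A11]))
    reads = []
    for ti in truth.introns.get(genome.label, []):
        seq = genome.chromosome(ti.chromosome).sequence
        for k in range(reads_per_junction):
            a = max(5, anchor + int(rng.integers(-5, 6)))
            b = max(5, anchor + int(rng.integers(-5, 6)))
            pos = max(0, ti.start - a)
            left = seq[pos : ti.start]
            right = seq[ti.end : ti.end + b]
            cigar = f"{len(left)}M{ti.length}N{len(right)}M"
            reads.append(
                SamRead(
                    qname=f"{ti.gene_id}_{ti.start}_{k}",
                    chrom=ti.chromosome,
                    pos=pos,
                    cigar=cigar,
                    seq=left + right,
                )
            )
    return reads


def write_sam(reads: list[SamRead], genome, path) -> None:
    """Minimal valid SAM with gapped alignments encoded via N operations."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for c in genome.chromosomes:
            fh.write(f"@SQ\tSN:{c.name}\tLN:{len(c)}\n")
        for r in reads:
            fh.write(
                f"{r.qname}\t0\t{r.chrom}\t{r.pos + 1}\t60\t{r.cigar}\t*\t0\t0\t{r.seq}\t*\n"
            )
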