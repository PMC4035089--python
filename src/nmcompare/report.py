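"""End-to-end comparison report stitching all analysis stages together."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

from . import (
    core,
    expression as expr,
    gene_content,
    gene_stats,
    introns as intr,
    repeats,
    synteny,
    synthetic,
)

log = logging.getLogger("nmcompare")


@dataclass
class ComparisonReport:
    summaries: dict
    repeat_regions: dict
    tandem_arrays: dict
    spacer_stats: dict
    spacer_test: object
    protein_stats_all: dict
    protein_stats_shared: dict
    nonredundant: dict
    intron_catalogs: dict
    intron_distributions: dict
    boundary_classes: dict
    intron_comparison: object
    synteny_blocks: list
    synteny_summary: dict
    venn: object
    core_families: list
    expression_contrast: dict | None


def run_comparison(
    genome_a,
    genome_b,
    families,
    tracks: dict | None = None,
    expression_groups: dict | None = None,
    min_block_genes: int = 3,
    outdir: str | Path | None = None,
) -> ComparisonReport:
    """Run every analysis stage on a genome pair and collect the results.

    ``tracks`` optionally maps genome label -> CoverageTrack;
    ``expression_groups`` maps genome label -> (group_a_ids, group_b_ids)
    for the expression contrast. With ``outdir`` set, per-stage TSV files
    are written.
    """
    t0 = time.time()
    report = {}

    def stage(name, fn):
        t = time.time()
        try:
            out = fn()
        except Exception:
            log.error("stage %s failed", name)
            raise
        log.info("stage %-14s %6.2fs", name, time.time() - t)
        return out

    la, lb = genome_a.label, genome_b.label

    repeat_regions, tandem_arrays = {}, {}
    for g in (genome_a, genome_b):
        regions, _ = stage(f"repeats:{g.label}", lambda g=g: repeats.detect_subtelomeric_repeats(g))
        repeat_regions[g.label] = regions
        # scan just inside each detected terminal repeat for a boundary tandem array
        arrays = []
        for r in regions:
            chrom = g.chromosome(r.chromosome)
            if r.end == "left":
                window = chrom.sequence[r.interval[1] : r.interval[1] + 1500]
            else:
                window = chrom.sequence[max(0, r.interval[0] - 1500) : r.interval[0]]
            arr = repeats.detect_tandem_array(window, (2, 60), min_copies=3)
            if arr is not None:
                arrays.append((r.chromosome, r.end, arr))
        tandem_arrays[g.label] = arrays

    summaries = {
        g.label: core.genome_summary(
            g,
            exclude_regions={
                r.chromosome: [r.interval]
                for r in repeat_regions[g.label]
            } if repeat_regions[g.label] else None,
        )
        for g in (genome_a, genome_b)
    }
    for g in (genome_a, genome_b):
        _, n_nr = gene_stats.collapse_redundant(g)
        summaries[g.label].n_nonredundant_genes = n_nr

    spacer_stats = {
        g.label: stage(f"spacers:{g.label}", lambda g=g: gene_stats.intergenic_spacers(g))
        for g in (genome_a, genome_b)
    }
    spacer_test = None
    if spacer_stats[la].count >= 2 and spacer_stats[lb].count >= 2:
        spacer_test = gene_stats.welch_t_test(
            spacer_stats[la].lengths, spacer_stats[lb].lengths
        )

    prot_all = stage("protein:all", lambda: gene_stats.protein_length_stats(genome_a, genome_b, "all"))
    prot_shared = stage(
        "protein:shared",
        lambda: gene_stats.protein_length_stats(genome_a, genome_b, "shared-only", families),
    )
    nonredundant = {
        g.label: summaries[g.label].n_nonredundant_genes for g in (genome_a, genome_b)
    }

    catalogs = {g.label: intr.catalog_introns(g) for g in (genome_a, genome_b)}
    distributions = {k: intr.intron_size_distribution(v) for k, v in catalogs.items()}
    boundaries = {k: intr.classify_boundaries(v) for k, v in catalogs.items()}
    comparison = stage(
        "intron:compare", lambda: intr.compare_intron_positions(genome_a, genome_b, families)
    )

    order_a = synteny.gene_order(genome_a, families, shared_only=True, partner_label=lb)
    order_b = synteny.gene_order(genome_b, families, shared_only=True, partner_label=la)
    blocks = stage(
        "synteny", lambda: synteny.detect_synteny_blocks(order_a, order_b, min_genes=min_block_genes)
    )
    block_stats = synteny.synteny_stats(blocks)

    venn = stage("content:venn", lambda: gene_content.set_overlap(families, la, lb))
    core_fams = gene_content.core_set(families, [la, lb])

    contrast = None
    if tracks and expression_groups:
        label = la if la in tracks else lb
        depths = expr.gene_depth(tracks[label], genome_a if label == la else genome_b)
        ga, gb = expression_groups[label]
        contrast = expr.expression_contrast(depths, ga, gb)

    report = ComparisonReport(
        summaries=summaries,
        repeat_regions=repeat_regions,
        tandem_arrays=tandem_arrays,
        spacer_stats=spacer_stats,
        spacer_test=spacer_test,
        protein_stats_all=prot_all,
        protein_stats_shared=prot_shared,
        nonredundant=nonredundant,
        intron_catalogs=catalogs,
        intron_distributions=distributions,
        boundary_classes=boundaries,
        intron_comparison=comparison,
        synteny_blocks=blocks,
        synteny_summary=block_stats,
        venn=venn,
        core_families=core_fams,
        expression_contrast=contrast,
    )
    if outdir is not None:
        write_report(report, outdir)
    log.info("comparison finished in %.2fs", time.time() - t0)
    return report


def write_report(report: ComparisonReport, outdir: str | Path) -> None:
    """Write the per-stage TSV bundle; byte-stable for identical inputs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "summary.tsv", "w") as fh:
        for label, s in report.summaries.items():
            fh.write(s.to_tsv())
            fh.write("\n")
    with open(out / "repeats.bed", "w") as fh:
        for label, regions in report.repeat_regions.items():
            for r in regions:
                fh.write(
                    f"{r.chromosome}\t{r.interval[0]}\t{r.interval[1]}\t"
                    f"{label}_{r.end}\t{r.identity_to_consensus:.4f}\n"
                )
    with open(out / "spacers.tsv", "w") as fh:
        fh.write("genome\tcount\tmean_bp\n")
        for label, s in report.spacer_stats.items():
            fh.write(f"{label}\t{s.count}\t{'NA' if s.mean is None else f'{s.mean:.2f}'}\n")
        if report.spacer_test is not None:
            fh.write(
                f"# welch_t={report.spacer_test.statistic:.4f} "
                f"df={report.spacer_test.degrees_of_freedom:.2f} "
                f"p={report.spacer_test.p_value:.3e}\n"
            )
    with open(out / "introns.tsv", "w") as fh:
        fh.write("genome\tn_introns\tmax_length\tproportion_lt20\tcanonical_fraction\n")
        for label in report.intron_distributions:
            d = report.intron_distributions[label]
            b = report.boundary_classes[label]
            lt20 = "NA" if d["proportion_lt20"] is None else f"{d['proportion_lt20']:.4f}"
            canon = "NA" if b["canonical_fraction"] is None else f"{b['canonical_fraction']:.4f}"
            fh.write(f"{label}\t{d['n']}\t{d['max_length']}\t{lt20}\t{canon}\n")
    with open(out / "intron_comparison.tsv", "w") as fh:
        fh.write("family\tgenome\tgene\tcolumn\tphase\tstatus\tpartner\n")
        for e in report.intron_comparison.entries:
            fh.write(
                f"{e.family}\t{e.genome}\t{e.gene_id}\t{e.column}\t{e.phase}\t"
                f"{e.status}\t{e.partner or ''}\n"
            )
    with open(out / "synteny.tsv", "w") as fh:
        fh.write("chrom_a\tchrom_b\torientation\tn_genes\tfamilies\n")
        for b in report.synteny_blocks:
            fh.write(
                f"{b.chromosome_a}\t{b.chromosome_b}\t{b.orientation}\t"
                f"{b.gene_count}\t{','.join(b.families)}\n"
            )
    with open(out / "content.tsv", "w") as fh:
        v = report.venn
        fh.write("metric\tvalue\n")
        fh.write(f"shared\t{v.shared}\nunique_a\t{v.unique_a}\nunique_b\t{v.unique_b}\n")
        fh.write(f"core_families\t{len(report.core_families)}\n")
    if report.expression_contrast is not None:
        with open(out / "expression.tsv", "w") as fh:
            for k, v in report.expression_contrast.items():
                fh.write(f"{k}\t{v}\n")


def simulate_and_compare(config: synthetic.GeneratorConfig, seed: int, outdir=None) -> ComparisonReport:
    """Convenience wrapper: generate a pair, coverage and report in one go."""
    ga, gb, families, truth = synthetic.generate_genome_pair(config, seed)
    track = synthetic.generate_coverage_track(ga, truth, config, seed)
    cls = truth.expression_class[ga.label]
    internal = [g for g, c in cls.items() if c == "internal"]
    subtel = [g for g, c in cls.items() if c == "subtelomeric" and ga.gene(g).kind == "orf"]
    return run_comparison(
        ga, gb, families,
        tracks={ga.label: track},
        expression_groups={ga.label: (internal, subtel)},
        outdir=outdir,
    )
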