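"""Intron catalogues, junction calling, alignment and position comparison."""

import numpy as np
import pytest

from nmcompare import core, introns, synthetic
from nmcompare.gene_content import OrthologFamilyTable

from conftest import DESK_SEED


# ---------------------------------------------------------------------------
# catalogue and distributions


def test_single_exon_genes_yield_empty_catalog():
    genome = core.AnnotatedGenome(
        "t", [core.Chromosome("c", "ACGT" * 50)],
        [core.GeneModel("g", "c", "+", [(0, 90)])],
    )
    assert introns.catalog_introns(genome) == []


def test_catalog_equals_planted_truth(desk_pair):
    for genome_idx in (0, 1):
        genome = desk_pair[genome_idx]
        truth = desk_pair[3]
        cat = {
            (r.gene_id, r.start, r.end, r.phase, r.donor_dinucleotide, r.acceptor_dinucleotide)
            for r in introns.catalog_introns(genome)
        }
        planted = {
            (t.gene_id, t.start, t.end, t.phase, t.donor_dinucleotide, t.acceptor_dinucleotide)
            for t in truth.introns[genome.label]
        }
        assert cat == planted


def test_forced_longest_intron_dominates_distribution():
    cfg = synthetic.GeneratorConfig(longest_intron_length=32)
    genome, _, _, _ = synthetic.generate_genome_pair(cfg, DESK_SEED)
    dist = introns.intron_size_distribution(introns.catalog_introns(genome))
    assert dist["max_length"] == 32
    assert sum(1 for r in introns.catalog_introns(genome) if r.length == 32) == 1


def test_empty_catalog_gives_empty_histogram():
    dist = introns.intron_size_distribution([])
    assert dist["counts"] == {} and dist["n"] == 0 and dist["max_length"] is None


def test_proportions_sum_to_one(desk_pair):
    dist = introns.intron_size_distribution(introns.catalog_introns(desk_pair[0]))
    assert sum(dist["proportions"].values()) == pytest.approx(1.0)


def test_planted_noncanonical_boundaries_counted():
    cfg = synthetic.GeneratorConfig(n_gc_ag=2, n_ga_ag=1)
    genome, _, _, _ = synthetic.generate_genome_pair(cfg, DESK_SEED)
    classes = introns.classify_boundaries(introns.catalog_introns(genome))
    assert classes["counts"]["GC-AG"] == 2
    assert classes["counts"]["GA-AG"] == 1
    assert classes["counts"]["other"] == 0


def test_boundary_classes_match_sequence_re_read(desk_pair):
    genome = desk_pair[0]
    cat = introns.catalog_introns(genome)
    classes = introns.classify_boundaries(cat)
    from nmcompare._seq import revcomp

    gt_ag = 0
    for r in cat:
        seq = genome.chromosome(r.chromosome).sequence
        if r.strand == "+":
            d, a = seq[r.start : r.start + 2], seq[r.end - 2 : r.end]
        else:
            d, a = revcomp(seq[r.end - 2 : r.end]), revcomp(seq[r.start : r.start + 2])
        if d == "GT" and a == "AG":
            gt_ag += 1
    assert classes["counts"]["GT-AG"] == gt_ag


def test_signal_matrix_columns_conserve_counts(desk_pair):
    genome = desk_pair[0]
    cat = [r for r in introns.catalog_introns(genome) if r.length == 19]
    mats = introns.splice_signal_matrix(cat, genome, exon_flank=5)
    df = mats[19]
    assert (df.sum(axis=1) == len(cat)).all()


def test_signal_matrix_shows_a_bias_at_minus_two(desk_pair):
    genome = desk_pair[0]
    cat = introns.catalog_introns(genome)
    mats = introns.splice_signal_matrix(cat, genome, exon_flank=5)
    total = None
    for df in mats.values():
        row = df.loc["-2"]
        total = row if total is None else total + row
    assert total.idxmax() == "A"


def test_one_intron_signal_matrix_is_one_hot(desk_pair):
    genome = desk_pair[0]
    rec = introns.catalog_introns(genome)[0]
    mats = introns.splice_signal_matrix([rec], genome, exon_flank=3)
    df = mats[rec.length]
    assert ((df == 0) | (df == 1)).all().all()
    assert (df.sum(axis=1) == 1).all()


# ---------------------------------------------------------------------------
# junction calling


def test_no_gapped_records_calls_nothing(desk_pair):
    assert introns.call_junctions([], desk_pair[0]) == []


def test_support_threshold_is_strict(desk_pair):
    genome, _, _, truth = desk_pair
    reads = synthetic.generate_junction_records(genome, truth, reads_per_junction=1, seed=0)
    assert introns.call_junctions(reads, genome, min_support=2) == []
    called = introns.call_junctions(reads, genome, min_support=1)
    assert len(called) == len(truth.introns[genome.label])


def test_generated_evidence_recovers_planted_truth(desk_pair):
    genome, _, _, truth = desk_pair
    reads = synthetic.generate_junction_records(genome, truth, reads_per_junction=5, seed=0)
    called = introns.call_junctions(reads, genome, min_support=2)
    got = {(r.chromosome, r.start, r.end) for r in called}
    want = {(t.chromosome, t.start, t.end) for t in truth.introns[genome.label]}
    assert got == want
    assert all(r.support >= 5 for r in called)


def test_called_junctions_match_catalog_records(desk_pair):
    """Calling at min_support 1 on perfect evidence reproduces the catalogue."""
    genome, _, _, truth = desk_pair
    reads = synthetic.generate_junction_records(genome, truth, reads_per_junction=2, seed=3)
    called = introns.call_junctions(reads, genome, min_support=1)
    cat = introns.catalog_introns(genome)
    key = lambda r: (r.chromosome, r.start, r.end, r.phase, r.gene_id)
    assert sorted(map(key, called)) == sorted(map(key, cat))


def test_ambiguous_gap_shifted_to_canonical_boundary():
    #            0123456789...
    seq = "TTTGGTAAATAGGGTTT"
    # true intron (4,12) = GTAAATAG; shifting left once gives GGTAAATA (non-GT-AG)
    assert seq[4:12] == "GTAAATAG"
    assert seq[3] == seq[11]  # ambiguity: the gap can shift left
    genome = core.AnnotatedGenome("t", [core.Chromosome("c", seq)], [])
    reads = [synthetic.SamRead("r%d" % i, "c", 1, "3M8N3M", seq[1:4] + seq[12:15])
             for i in range(2)]
    called = introns.call_junctions(reads, genome, min_support=2)
    assert [(r.start, r.end) for r in called] == [(4, 12)]
    # without a boundary preference the leftmost placement wins
    called_left = introns.call_junctions(reads, genome, min_support=2, require_boundary=None)
    assert [(r.start, r.end) for r in called_left] == [(3, 11)]


# ---------------------------------------------------------------------------
# alignment


def test_identical_sequences_align_gapless_at_full_identity():
    res = introns.align_proteins("MKLVINTW", "MKLVINTW")
    assert res.percent_identity == 1.0
    assert "-" not in res.aligned_a + res.aligned_b


def test_alignment_score_matches_exhaustive_dp_oracle():
    from Bio.Align import substitution_matrices

    M = substitution_matrices.load("BLOSUM62")

    def gotoh(a, b, open_=10.0, ext=0.5):
        n, m = len(a), len(b)
        NEG = float("-inf")
        Mx = np.full((n + 1, m + 1), NEG)
        Ix = np.full((n + 1, m + 1), NEG)
        Iy = np.full((n + 1, m + 1), NEG)
        Mx[0, 0] = 0.0
        for i in range(1, n + 1):
            Ix[i, 0] = -open_ - (i - 1) * ext
        for j in range(1, m + 1):
            Iy[0, j] = -open_ - (j - 1) * ext
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                s = M[a[i - 1], b[j - 1]]
                Mx[i, j] = max(Mx[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
                Ix[i, j] = max(Mx[i - 1, j] - open_, Ix[i - 1, j] - ext, Iy[i - 1, j] - open_)
                Iy[i, j] = max(Mx[i, j - 1] - open_, Iy[i, j - 1] - ext, Ix[i, j - 1] - open_)
        return max(Mx[n, m], Ix[n, m], Iy[n, m])

    rng = np.random.default_rng(1)
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(40):
        a = "".join(rng.choice(letters, size=rng.integers(1, 9)))
        b = "".join(rng.choice(letters, size=rng.integers(1, 9)))
        assert introns.align_proteins(a, b).score == pytest.approx(gotoh(a, b))


def test_empty_or_illegal_sequences_raise():
    with pytest.raises(ValueError, match="empty"):
        introns.align_proteins("", "MKL")
    with pytest.raises(ValueError, match="position 2"):
        introns.align_proteins("MK7L", "MKL")


def test_alignment_maps_are_mutually_consistent():
    res = introns.align_proteins("MKLWVNT", "MKLNT")
    degapped_a = res.aligned_a.replace("-", "")
    degapped_b = res.aligned_b.replace("-", "")
    assert degapped_a == "MKLWVNT" and degapped_b == "MKLNT"
    for i, col in enumerate(res.a_to_col):
        assert res.col_to_a[col] == i


# ---------------------------------------------------------------------------
# cross-genome comparison


def _pair_with_introns(intron_a, intron_b, n_codons=60):
    """Two genomes with one orthologous identical gene; plant given introns."""
    rng = np.random.default_rng(0)
    cfg = synthetic.GeneratorConfig()
    from nmcompare.synthetic import _GenePlan, _IntronPlan, _assemble_block, _sample_cds

    cds = _sample_cds(rng, cfg, n_codons)
    genomes = []
    for label, planted in (("A", intron_a), ("B", intron_b)):
        plans = [_IntronPlan(off, 19, "GT", "AG") for off in planted]
        block, exons_t, _ = _assemble_block(_GenePlan("fam1", "other", cds, plans), rng)
        chrom = core.Chromosome("c", block + "ACGT")
        gene = core.GeneModel("gene" + label, "c", "+", exons_t, family_id="fam1")
        genomes.append(core.AnnotatedGenome(label, [chrom], [gene]))
    fams = OrthologFamilyTable()
    fams.add("fam1", "A", "geneA")
    fams.add("fam1", "B", "geneB")
    return genomes[0], genomes[1], fams


def test_identical_orthologues_share_identically_placed_intron():
    ga, gb, fams = _pair_with_introns([3 * 20], [3 * 20])
    comp = introns.compare_intron_positions(ga, gb, fams)
    assert comp.summary["shared"] == 1
    assert comp.summary["unique_a"] == comp.summary["unique_b"] == 0


def test_same_column_different_phase_is_not_shared():
    ga, gb, fams = _pair_with_introns([3 * 20 + 1], [3 * 20 + 2])
    comp = introns.compare_intron_positions(ga, gb, fams)
    assert comp.summary["shared"] == 0
    assert comp.summary["unique_a"] == comp.summary["unique_b"] == 1


def test_fourteen_flanking_residues_are_not_comparable():
    # intron after codon 15: only 14 gap-free residues on the upstream side
    ga, gb, fams = _pair_with_introns([3 * 15], [3 * 15])
    comp = introns.compare_intron_positions(ga, gb, fams)
    statuses = {e.status for e in comp.entries}
    assert statuses == {"not-comparable"}
    assert comp.summary["shared"] == 0


def test_synthetic_pair_confusion_matrix_is_perfect(desk_pair):
    ga, gb, fams, truth = desk_pair
    comp = introns.compare_intron_positions(ga, gb, fams)
    shared_fams = {
        f for f in fams.family_ids
        if fams.present(f, ga.label) and fams.present(f, gb.label)
    }
    expect_shared = sum(
        1 for t in truth.introns[ga.label] if t.shared and t.family in shared_fams
    )
    expect_unique_a = sum(
        1 for t in truth.introns[ga.label] if not t.shared and t.family in shared_fams
    )
    expect_unique_b = sum(
        1 for t in truth.introns[gb.label] if not t.shared and t.family in shared_fams
    )
    assert comp.summary["shared"] == expect_shared
    assert comp.summary["unique_a"] == expect_unique_a
    assert comp.summary["unique_b"] == expect_unique_b


def test_comparison_symmetric_under_genome_swap(desk_pair):
    ga, gb, fams, _ = desk_pair
    fwd = introns.compare_intron_positions(ga, gb, fams)
    rev = introns.compare_intron_positions(gb, ga, fams)
    assert fwd.summary["shared"] == rev.summary["shared"]
    assert fwd.summary["unique_a"] == rev.summary["unique_b"]
    assert fwd.summary["unique_b"] == rev.summary["unique_a"]


def test_self_comparison_shares_every_comparable_intron(desk_pair):
    ga = desk_pair[0]
    fams = desk_pair[2]
    import copy

    gb = core.AnnotatedGenome(
        "selfB",
        [core.Chromosome(c.name, c.sequence) for c in ga.chromosomes],
        [copy.deepcopy(g) for g in ga.genes],
    )
    fams2 = OrthologFamilyTable()
    for f in fams.family_ids:
        for gid in fams.members(f, ga.label):
            fams2.add(f, ga.label, gid, fams.category(f))
            fams2.add(f, "selfB", gid, fams.category(f))
    comp = introns.compare_intron_positions(ga, gb, fams2)
    assert comp.summary["unique_a"] == comp.summary["unique_b"] == 0
    assert comp.summary["shared"] > 0
    assert comp.summary["shared"] == comp.summary["comparable_a"]


# ---------------------------------------------------------------------------
# polarization


def test_intron_in_b_and_outgroup_absent_in_a_is_loss_in_a():
    ga, gb, fams = _pair_with_introns([], [3 * 20])
    comp = introns.compare_intron_positions(ga, gb, fams)
    [entry] = [e for e in comp.entries if e.status == "unique"]
    calls = introns.polarize_introns(comp, {("fam1", entry.column, entry.phase): True})
    assert calls == [
        {"family": "fam1", "column": entry.column, "phase": entry.phase,
         "present_in": "B", "call": "loss-in-A"}
    ]


def test_intron_absent_from_outgroups_is_ambiguous():
    ga, gb, fams = _pair_with_introns([3 * 25], [])
    comp = introns.compare_intron_positions(ga, gb, fams)
    calls = introns.polarize_introns(comp, {})
    assert [c["call"] for c in calls] == ["ambiguous"]


def test_polarization_matches_case_enumeration():
    """Exhaustive 2x2 toy: (unique side) x (outgroup presence)."""
    for side, planted in (("A", ([3 * 22], [])), ("B", ([], [3 * 22]))):
        for present in (True, False):
            ga, gb, fams = _pair_with_introns(*planted)
            comp = introns.compare_intron_positions(ga, gb, fams)
            [entry] = [e for e in comp.entries if e.status == "unique"]
            calls = introns.polarize_introns(
                comp, {("fam1", entry.column, entry.phase): present}
            )
            other = "B" if side == "A" else "A"
            expected = f"loss-in-{other}" if present else "ambiguous"
            assert calls[0]["call"] == expected
            assert calls[0]["present_in"] == side
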