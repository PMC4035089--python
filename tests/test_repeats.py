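"""Terminal-repeat detection, tandem arrays and GC profiling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmcompare import core, repeats
from nmcompare._seq import random_dna, revcomp

PRINTED_UNIT = "RTAYCTRGTTRCCTTATCGTATGCCATGGCTTTATC"


def test_desk_scale_genome_yields_six_regions_near_truth(desk_pair, desk_config):
    genome, _, _, truth = desk_pair
    regions, consensus = repeats.detect_subtelomeric_repeats(genome)
    assert len(regions) == 6
    for r in regions:
        planted = dict(
            zip(("left", "right"), sorted(truth.subtel_regions[genome.label][r.chromosome]))
        )[r.end]
        assert abs(r.interval[0] - planted[0]) <= 50
        assert abs(r.interval[1] - planted[1]) <= 50
        assert r.identity_to_consensus >= 0.995
    assert consensus is not None


def test_random_ends_yield_no_repeat_regions():
    rng = np.random.default_rng(0)
    chroms = [core.Chromosome(f"c{i}", random_dna(rng, 8000, 0.3)) for i in range(3)]
    genome = core.AnnotatedGenome("rand", chroms, [])
    regions, consensus = repeats.detect_subtelomeric_repeats(genome)
    assert regions == []
    assert consensus is None


def test_detection_invariant_under_chromosome_order_and_revcomp(desk_pair):
    genome, _, _, _ = desk_pair
    base, _ = repeats.detect_subtelomeric_repeats(genome)
    flipped = core.AnnotatedGenome(
        genome.label,
        [core.Chromosome(c.name, revcomp(c.sequence)) for c in reversed(genome.chromosomes)],
        [],
    )
    mirrored, _ = repeats.detect_subtelomeric_repeats(flipped)
    # reverse-complementing swaps left and right but preserves the six regions
    assert len(mirrored) == len(base) == 6
    base_lengths = sorted(r.interval[1] - r.interval[0] for r in base)
    mirr_lengths = sorted(r.interval[1] - r.interval[0] for r in mirrored)
    assert base_lengths == mirr_lengths


def test_printed_unit_array_recovers_36nt_period():
    unit = PRINTED_UNIT.replace("R", "A").replace("Y", "C")
    arr = repeats.detect_tandem_array(unit * 10, (2, 60), min_copies=3)
    assert arr is not None
    assert arr.unit_length == 36
    assert arr.copy_number == pytest.approx(10.0)
    assert arr.match_fraction == pytest.approx(1.0)


def test_homopolymer_has_unit_length_one():
    arr = repeats.detect_tandem_array("A" * 50, (1, 10), min_copies=3)
    assert arr.unit_length == 1


def test_random_sequence_has_no_tandem_array():
    rng = np.random.default_rng(5)
    assert repeats.detect_tandem_array(random_dna(rng, 400, 0.5), (2, 60), 3) is None


@pytest.mark.parametrize("seed", range(5))
def test_random_unit_recovered_against_autocorrelation_oracle(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(5, 41))
    unit = random_dna(rng, k, 0.5)
    seq = unit * 6
    arr = repeats.detect_tandem_array(seq, (2, 45), min_copies=3)
    # brute-force autocorrelation oracle: best period by total matches
    def matches(p):
        return sum(1 for i in range(len(seq) - p) if seq[i] == seq[i + p])
    best = max(range(2, 46), key=lambda p: (matches(p), -p))
    assert arr is not None
    assert arr.unit_length == best
    # truth period divides the detected one only at the primitive period
    assert arr.unit_length == k or k % arr.unit_length == 0


def test_tandem_array_invariant_under_rotation():
    rng = np.random.default_rng(9)
    unit = random_dna(rng, 17, 0.5)
    seq = unit * 6
    base = repeats.detect_tandem_array(seq, (2, 30), 3)
    for shift in (1, 5, 12):
        rotated = repeats.detect_tandem_array(seq[shift:] + seq[:shift], (2, 30), 3)
        assert rotated.unit_length == base.unit_length
        # rotated consensus is a cyclic shift of the base consensus
        doubled = base.consensus + base.consensus
        assert rotated.consensus in doubled


def test_degenerate_positions_get_iupac_codes():
    # alternate A/G at position 0 across copies -> R in consensus
    seq = ("ACGTACGTCC" "GCGTACGTCC") * 3
    arr = repeats.detect_tandem_array(seq, (2, 15), 3)
    assert arr.unit_length == 10
    assert arr.consensus[0] == "R"


def test_all_g_sequence_profiles_to_one():
    prof = repeats.gc_profile("G" * 100, window=10, step=10)
    assert all(g == 1.0 for g in prof.gc)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    seq=st.text(alphabet="ACGT", min_size=1, max_size=300),
    window=st.integers(min_value=1, max_value=60),
)
def test_gc_conservation_holds_for_arbitrary_sequences(seq, window):
    """Tiling windows: length-weighted window GC equals whole-sequence GC."""
    from nmcompare._seq import gc_fraction

    prof = repeats.gc_profile(seq, window=window, step=window)
    weights = [e - s for s, e in zip(prof.starts, prof.ends)]
    weighted = sum(g * w for g, w in zip(prof.gc, weights)) / sum(weights)
    assert weighted == pytest.approx(gc_fraction(seq), abs=1e-9)


def test_window_gc_weighted_mean_equals_whole_sequence_gc():
    rng = np.random.default_rng(3)
    seq = random_dna(rng, 1037, 0.37)
    prof = repeats.gc_profile(seq, window=100, step=100)
    weights = [e - s for s, e in zip(prof.starts, prof.ends)]
    weighted = sum(g * w for g, w in zip(prof.gc, weights)) / sum(weights)
    from nmcompare._seq import gc_fraction

    assert weighted == pytest.approx(gc_fraction(seq), abs=1e-12)
    assert prof.partial[-1] and not any(prof.partial[:-1])


def test_window_larger_than_sequence_gives_single_window():
    prof = repeats.gc_profile("ACGT", window=100, step=50)
    assert prof.starts == [0] and prof.ends == [4]


def test_subtelomeric_windows_average_to_planted_gc(desk_pair, desk_config):
    genome, _, _, truth = desk_pair
    gcs = []
    for c in genome.chromosomes:
        s, e = truth.subtel_regions[genome.label][c.name][0]
        prof = repeats.gc_profile(c.sequence[s:e], window=500, step=500)
        gcs.extend(g for g, p in zip(prof.gc, prof.partial) if not p)
    assert np.mean(gcs) == pytest.approx(desk_config.subtel_gc, abs=0.01)


def test_region_gc_whole_chromosome_equals_overall(desk_pair):
    genome, _, _, _ = desk_pair
    c = genome.chromosomes[0]
    single = core.AnnotatedGenome("one", [core.Chromosome(c.name, c.sequence)], [])
    inside, _ = repeats.region_gc(single, {c.name: [(0, len(c))]})
    assert inside == pytest.approx(core.genome_summary(single).gc_overall)


def test_region_gc_recovers_generator_parameters(desk_pair, desk_config):
    genome, _, _, truth = desk_pair
    regions = {c: list(ivs) for c, ivs in truth.subtel_regions[genome.label].items()}
    inside, _ = repeats.region_gc(genome, regions)
    assert inside == pytest.approx(desk_config.subtel_gc, abs=0.01)
    # outside the repeats *and* the boundary arrays: the internal composition
    for chrom, s, e, _ in truth.boundary_arrays[genome.label]:
        regions[chrom].append((s, e))
    _, outside = repeats.region_gc(genome, regions)
    assert outside == pytest.approx(desk_config.internal_gc, abs=0.01)


def test_disjoint_halves_combine_to_whole_gc():
    seq = "GGGGAAAATTCC"
    genome = core.AnnotatedGenome("g", [core.Chromosome("c", seq)], [])
    inside, outside = repeats.region_gc(genome, {"c": [(0, 6)]})
    n_in, n_out = 6, 6
    combined = (inside * n_in + outside * n_out) / (n_in + n_out)
    from nmcompare._seq import gc_fraction

    assert combined == pytest.approx(gc_fraction(seq))


def test_empty_region_set_reports_not_available(desk_pair):
    genome, _, _, _ = desk_pair
    inside, outside = repeats.region_gc(genome, {})
    assert inside is None
    assert outside is not None
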