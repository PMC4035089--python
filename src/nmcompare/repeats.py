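"""Sub-telomeric repeat discovery, tandem arrays and GC profiling.

Reduced genomes of the kind this package targets carry long, nearly
identical repeats on every chromosome end, kept homogeneous by gene
conversion, with a short degenerate tandem repeat marking the boundary
between the repeat and the internal single-copy region. The detectors
here recover those features from sequence alone.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._seq import IUPAC_BY_SET, gc_fraction, revcomp
from .core import AnnotatedGenome


@dataclass
class RepeatRegion:
    """One terminal repeat copy; right ends were compared reverse-complemented."""

    chromosome: str
    end: str  # "left" | "right"
    interval: tuple[int, int]
    identity_to_consensus: float


@dataclass
class TandemArray:
    interval: tuple[int, int]
    unit_length: int
    consensus: str
    copy_number: float
    match_fraction: float


@dataclass
class GCProfile:
    window: int
    step: int
    starts: list[int]
    ends: list[int]
    gc: list[float]
    partial: list[bool]

    def to_bedgraph(self, chrom: str) -> str:
        return "".join(
            f"{chrom}\t{s}\t{e}\t{g:.6f}\n"
            for s, e, g in zip(self.starts, self.ends, self.gc)
        )


def _oriented_ends(genome: AnnotatedGenome) -> list[tuple[str, str, str]]:
    """(chromosome, end, telomere-inward sequence) for both ends of each chromosome."""
    ends = []
    for c in genome.chromosomes:
        ends.append((c.name, "left", c.sequence))
        ends.append((c.name, "right", revcomp(c.sequence)))
    return ends


def detect_subtelomeric_repeats(
    genome: AnnotatedGenome,
    min_length: int = 1000,
    min_identity: float = 0.995,
) -> tuple[list[RepeatRegion], str | None]:
    """Find the maximal terminal repeat shared by the chromosome ends.

    Every chromosome end is oriented telomere-inward (right ends reverse
    complemented) and, for each end, the longest terminal prefix whose
    identity to *every* other end stays at or above ``min_identity`` is
    reported, provided it reaches ``min_length``. Returns the regions and
    the majority consensus of the reported prefixes.
    """
    ends = _oriented_ends(genome)
    if len(ends) < 2:
        return [], None
    usable = []
    for name, side, seq in ends:
        if len(seq) < min_length:
            warnings.warn(f"{name} {side} end shorter than min_length; skipped")
        else:
            usable.append((name, side, seq))
    if len(usable) < 2:
        return [], None

    arrs = [np.frombuffer(seq.encode(), dtype=np.uint8) for _, _, seq in usable]
    n = len(arrs)
    # max prefix length per ordered pair at >= min_identity
    best = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            m = min(len(arrs[i]), len(arrs[j]))
            mis = np.cumsum(arrs[i][:m] != arrs[j][:m])
            lens = np.arange(1, m + 1)
            ok = mis <= (1.0 - min_identity) * lens
            val = int(np.max(np.nonzero(ok)[0]) + 1) if ok.any() else 0
            best[i, j] = best[j, i] = val

    lengths = [min(best[i, j] for j in range(n) if j != i) for i in range(n)]
    keep = [i for i, L in enumerate(lengths) if L >= min_length]
    if len(keep) < 2:
        return [], None

    # majority consensus over the kept prefixes
    width = min(lengths[i] for i in keep)
    stack = np.stack([arrs[i][:width] for i in keep])
    consensus_codes = []
    for col in stack.T:
        consensus_codes.append(Counter(col.tolist()).most_common(1)[0][0])
    consensus = bytes(consensus_codes).decode()

    regions = []
    for i in keep:
        name, side, _ = usable[i]
        L = lengths[i]
        chrom_len = len(genome.chromosome(name))
        iv = (0, L) if side == "left" else (chrom_len - L, chrom_len)
        matches = int(np.sum(arrs[i][:width] == np.frombuffer(consensus.encode(), np.uint8)))
        regions.append(RepeatRegion(name, side, iv, matches / width))
    return regions, consensus


def detect_tandem_array(
    sequence: str,
    unit_range: tuple[int, int],
    min_copies: int = 3,
    min_match_fraction: float = 0.8,
) -> TandemArray | None:
    """Detect the dominant tandem periodicity of ``sequence``.

    Scores each candidate unit length k by the number of positions i with
    s[i] == s[i+k]; the best-scoring k wins, ties going to the smallest
    (canonical primitive period). The per-column consensus uses the
    smallest IUPAC code covering bases observed at >= 20% frequency.
    Returns None when no unit supports ``min_copies`` full copies at
    ``min_match_fraction`` agreement.
    """
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    lo, hi = unit_range
    best_k, best_matches, best_frac = None, -1, 0.0
    for k in range(max(1, lo), hi + 1):
        if n < k * min_copies or n <= k:
            continue
        matches = int(np.sum(arr[:-k] == arr[k:]))
        frac = matches / (n - k)
        if frac >= min_match_fraction and matches > best_matches:
            best_k, best_matches, best_frac = k, matches, frac
    if best_k is None:
        return None

    consensus = []
    for col in range(best_k):
        counts = Counter(seq[col::best_k])
        total = sum(counts.values())
        covered = frozenset(b for b, c in counts.items() if c / total >= 0.2)
        if not covered:
            covered = frozenset([counts.most_common(1)[0][0]])
        consensus.append(IUPAC_BY_SET.get(covered, "N"))
    return TandemArray(
        interval=(0, n),
        unit_length=best_k,
        consensus="".join(consensus),
        copy_number=n / best_k,
        match_fraction=best_frac,
    )


def gc_profile(sequence: str, window: int, step: int) -> GCProfile:
    """Sliding-window GC; a final partial window is included and flagged."""
    if not (window >= step >= 1):
        raise ValueError("require window >= step >= 1")
    n = len(sequence)
    if window > n:
        return GCProfile(window, step, [0], [n], [gc_fraction(sequence) or 0.0], [True])
    starts = list(range(0, n - window + 1, step))
    ends = [s + window for s in starts]
    partial = [False] * len(starts)
    if ends[-1] < n:
        starts.append(starts[-1] + step)
        ends.append(n)
        partial.append(True)
    gcs = [gc_fraction(sequence[s:e]) or 0.0 for s, e in zip(starts, ends)]
    return GCProfile(window, step, starts, ends, gcs, partial)


def region_gc(
    genome: AnnotatedGenome,
    regions: dict[str, list[tuple[int, int]]],
) -> tuple[float | None, float | None]:
    """GC inside the union of ``regions`` and over its complement."""
    inside_parts, outside_parts = [], []
    for c in genome.chromosomes:
        merged = _merge(sorted(regions.get(c.name, [])))
        for s, e in merged:
            if not (0 <= s <= e <= len(c)):
                raise ValueError(f"region ({s},{e}) out of bounds on {c.name}")
        pos = 0
        for s, e in merged:
            outside_parts.append(c.sequence[pos:s])
            inside_parts.append(c.sequence[s:e])
            pos = e
        outside_parts.append(c.sequence[pos:])
    inside = "".join(inside_parts)
    outside = "".join(outside_parts)
    return (
        gc_fraction(inside) if inside else None,
        gc_fraction(outside) if outside else None,
    )


def _merge(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]
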