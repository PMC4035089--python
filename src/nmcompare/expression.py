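"""Per-gene depth, expression contrasts and depth-based copy number.

Coverage is consumed as a per-base depth track (bedGraph in, bedGraph
out). Per-gene depth is the paper-standard normalization: summed per-base
coverage over the gene divided by gene length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnnotatedGenome


@dataclass
class CoverageTrack:
    """chromosome -> dense per-base non-negative depth."""

    depths: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, arr in self.depths.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"negative depth on {name}")
            self.depths[name] = arr

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for name, arr in self.depths.items():
                if len(arr) == 0:
                    continue
                # run-length encode equal-depth stretches
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [len(arr)]])
                for s, e in zip(starts, ends):
                    fh.write(f"{name}\t{s}\t{e}\t{arr[s]:g}\n")

    @classmethod
    def from_bedgraph(cls, path, chromosome_lengths: dict[str, int]) -> "CoverageTrack":
        depths = {
            name: np.zeros(n, dtype=float) for name, n in chromosome_lengths.items()
        }
        covered = {name: np.zeros(n, dtype=bool) for name, n in chromosome_lengths.items()}
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "depth"],
            comment="#",
        )
        for row in df.itertuples(index=False):
            if row.chrom not in depths:
                raise ValueError(f"bedGraph chromosome {row.chrom!r} unknown")
            s, e = int(row.start), int(row.end)
            if covered[row.chrom][s:e].any():
                raise ValueError(f"overlapping bedGraph intervals on {row.chrom}")
            covered[row.chrom][s:e] = True
            depths[row.chrom][s:e] = float(row.depth)
        return cls(depths)


@dataclass
class GeneDepth:
    mean_depth: dict[str, float]
    zero_coverage: dict[str, bool]


def gene_depth(
    track: CoverageTrack,
    genome: AnnotatedGenome,
    exonic_only: bool = False,
) -> GeneDepth:
    """Mean per-base depth per gene (optionally over exonic positions only)."""
    means: dict[str, float] = {}
    zero: dict[str, bool] = {}
    for g in genome.genes:
        arr = track.depths.get(g.chromosome)
        if arr is None or g.end > len(arr):
            raise ValueError(f"gene {g.id} beyond coverage track extent")
        if exonic_only:
            vals = np.concatenate([arr[s:e] for s, e in g.exons])
        else:
            vals = arr[g.start : g.end]
        means[g.id] = float(vals.mean())
        zero[g.id] = bool((vals == 0).all())
    return GeneDepth(means, zero)


def expression_contrast(
    depths: GeneDepth,
    group_a: list[str],
    group_b: list[str],
) -> dict:
    """Ratio of group mean depths (A:B) with zero-coverage tallies."""
    if not group_a or not group_b:
        raise ValueError("both gene groups must be non-empty")
    mean_a = float(np.mean([depths.mean_depth[g] for g in group_a]))
    mean_b = float(np.mean([depths.mean_depth[g] for g in group_b]))
    infinite = mean_b == 0.0
    return {
        "mean_a": mean_a,
        "mean_b": mean_b,
        "ratio": float("inf") if infinite else mean_a / mean_b,
        "infinite": infinite,
        "zero_a": sum(depths.zero_coverage[g] for g in group_a),
        "zero_b": sum(depths.zero_coverage[g] for g in group_b),
    }


def estimate_copy_number(
    track: CoverageTrack,
    region: tuple[str, int, int],
    baseline: float | None = None,
    single_copy_regions: list[tuple[str, int, int]] | None = None,
    floor_report: bool = False,
) -> float | str:
    """Copy number of ``region`` as mean depth over a single-copy baseline.

    The default baseline is the median per-base depth over the supplied
    single-copy regions (or the whole track), robust against other repeat
    peaks. With ``floor_report`` the estimate is returned as an
    ``"at least N"`` string, the convention for collapsed assemblies.
    """
    chrom, s, e = region
    arr = track.depths.get(chrom)
    if arr is None or not (0 <= s < e <= len(arr)):
        raise ValueError("region outside track")
    if baseline is None:
        if single_copy_regions:
            pool = np.concatenate(
                [track.depths[c][a:b] for c, a, b in single_copy_regions]
            )
        else:
            pool = np.concatenate(list(track.depths.values()))
        baseline = float(np.median(pool))
    if baseline == 0:
        raise ValueError("zero baseline depth")
    ratio = float(arr[s:e].mean()) / baseline
    if floor_report:
        return f"at least {int(np.floor(ratio))}"
    return ratio
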