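"""Low-level DNA helpers shared across modules.

All sequences are plain upper-case strings over the IUPAC DNA alphabet;
coordinates everywhere in the package are 0-based, half-open.
"""

from __future__ import annotations

import numpy as np

# IUPAC one-letter codes keyed by the set of bases they cover.
IUPAC_BY_SET: dict[frozenset, str] = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}
BASES_BY_CODE: dict[str, str] = {
    code: "".join(sorted(bases)) for bases, code in IUPAC_BY_SET.items()
}
IUPAC_ALPHABET = frozenset(BASES_BY_CODE)

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


def revcomp(seq: str) -> str:
    """Reverse complement, ambiguity codes included."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float | None:
    """GC over unambiguous bases only; None if no A/C/G/T present."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return None
    return gc / (gc + at)


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    """Random sequence with expected GC content ``gc``."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p)) if n > 0 else ""


def random_dna_exact(rng: np.random.Generator, n: int, gc: float) -> str:
    """Random permutation of a base pool with *exact* GC count round(gc*n).

    Used where a region's composition is a stated property of the data
    rather than a sampling mean, so short regions do not drift.
    """
    n_gc = int(round(gc * n))
    n_at = n - n_gc
    pool = (
        ["G"] * (n_gc // 2) + ["C"] * (n_gc - n_gc // 2)
        + ["A"] * (n_at // 2) + ["T"] * (n_at - n_at // 2)
    )
    return "".join(rng.permutation(pool)) if n > 0 else ""


def resolve_iupac(rng: np.random.Generator, seq: str) -> str:
    """Replace each degenerate letter by a uniform choice among its bases."""
    out = []
    for ch in seq.upper():
        bases = BASES_BY_CODE[ch]
        out.append(bases if len(bases) == 1 else bases[rng.integers(len(bases))])
    return "".join(out)


def is_dna(seq: str) -> bool:
    return bool(seq) and set(seq.upper()) <= IUPAC_ALPHABET
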