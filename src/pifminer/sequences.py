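"""Low-level DNA sequence helpers shared across the package."""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}


def revcomp(seq: str) -> str:
    """Reverse complement, supporting IUPAC degeneracy codes."""
    if set(seq) <= set("ACGTN"):
        return str(Seq(seq).reverse_complement())
    return "".join(_IUPAC_COMPLEMENT[b] for b in reversed(seq.upper()))


def complement_base(base: str) -> str:
    return _IUPAC_COMPLEMENT[base]


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random sequence over ACGT with expected GC fraction ``gc``."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return "".join(np.array(list("ACGT"))[codes])


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply uniform substitutions at ``rate`` per site (always to a new base)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        choices = alphabet[alphabet != arr[i]]
        arr[i] = choices[rng.integers(0, choices.size)]
    return arr.tobytes().decode("ascii")


def encode(seq: str) -> np.ndarray:
    """Byte-encode a DNA string for vectorized scanning."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
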