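"""Reference element templates for PIF/Harbinger-like transposons.

A PIF-like autonomous element has the anatomy::

    [TIR] [sub-terminal 5'] ... ORF1 ... TPase ... [sub-terminal 3'] [rc TIR]

where the 19-bp terminal inverted repeat (TIR) at the 3' end is the reverse
complement of the 5' TIR, the element is flanked on insertion by a 3-bp
target-site duplication (typically TTA), ORF1 encodes a 272-aa Myb/SANT
protein of unknown function and the transposase (TPase) is a 427-aa protein
carrying the catalytic DDE triad.

Two families, A and B, share the identical TIR and TSD but diverge in their
sub-terminal and coding sequences: the family-B TPase and ORF1 proteins are
built at ~51.6% and ~37.4% identity to family A, the divergence that splits
the two families under the 80-80-80 rule.

All fixture sequences here are *synthetic*: they are generated
deterministically from a fixed seed with the published lengths, TIR
consensus and inter-family identities, not downloaded from any repository.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .sequences import revcomp

#: Degenerate 19-bp TIR consensus (Y = C/T).
TIR_CONSENSUS = "GGGYCYGTTTGGGGCAGCT"
#: Concrete TIR used in templates (Y positions resolved to C).
TIR = "GGGCCCGTTTGGGGCAGCT"
#: Preferred 3-bp target-site duplication.
TSD = "TTA"

ORF1_LEN_AA = 272
TPASE_LEN_AA = 427

#: Identity (fraction of residues kept) of family-B proteins relative to A.
TPASE_B_IDENTITY = 0.516
ORF1_B_IDENTITY = 0.374

#: Full length of an intact autonomous element, per family.
AUTONOMOUS_LENGTH = {"A": 5053, "B": 7053}

SUBTERMINAL_LEN = 60

#: Structural classes (one per row of the class taxonomy).
CLASSES = (
    "AUTONOMOUS",
    "DEF_NO_ORF1",
    "DEF_NO_TPASE",
    "DEF_NO_CODING",
    "DEF_ONE_TIR",
    "DEF_NO_TIR_FRAGMENT",
    "MITE_LIKE",
)

MITE_LEN_RANGE = (200, 300)
DEF_NO_CODING_INTERIOR_RANGE = (1000, 2000)

_FIXTURE_SEED = 20190109

_AA = "ACDEFGHIKLMNPQRSTVWY"

# Standard-code codon preferences for back-translation (one codon per residue
# keeps copies of a family byte-identical before per-copy mutation).
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_STOP = "TAA"


def _random_dna(rng: np.random.Generator, length: int, forbid: str | None = None) -> str:
    bases = np.array(list("ACGT"))
    while True:
        seq = "".join(bases[rng.integers(0, 4, size=length)])
        if forbid is None or forbid not in seq:
            return seq


def _random_protein(rng: np.random.Generator, length: int) -> str:
    aa = np.array(list(_AA))
    body = "".join(aa[rng.integers(0, len(_AA), size=length - 1)])
    return "M" + body


def _diverge_protein(rng: np.random.Generator, protein: str, identity: float) -> str:
    """Derive a protein keeping ``identity`` of positions, substituting the rest.

    Substituted positions always receive a different residue, so the realized
    gapless identity equals the kept fraction.
    """
    n = len(protein)
    n_keep = int(round(identity * n))
    keep = {0}  # initial Met always kept
    keep.update(rng.choice(np.arange(1, n), size=n_keep - 1, replace=False).tolist())
    out = []
    for i, res in enumerate(protein):
        if i in keep:
            out.append(res)
        else:
            choices = [a for a in _AA if a != res]
            out.append(choices[rng.integers(0, len(choices))])
    return "".join(out)


def back_translate(protein: str) -> str:
    """Intronless CDS for ``protein`` (fixed codon per residue, TAA stop)."""
    return "".join(_CODON[res] for res in protein) + _STOP


@dataclass(frozen=True)
class ElementTemplate:
    """Master copy of one family, from which every planted copy derives."""

    family: str
    tir_5prime: str
    subterminal_5prime: str
    subterminal_3prime: str
    orf1_protein: str
    tpase_protein: str
    orf1_cds: str = field(repr=False)
    tpase_cds: str = field(repr=False)
    spacer1: str = field(repr=False)
    spacer2: str = field(repr=False)
    spacer3: str = field(repr=False)
    noncoding_spacer: str = field(repr=False)

    @property
    def tir_3prime(self) -> str:
        return revcomp(self.tir_5prime)

    def build(
        self,
        class_name: str,
        rng: np.random.Generator | None = None,
        *,
        keep_subterminals: bool = True,
        interior_length: int | None = None,
        keep_left_tir: bool | None = None,
    ) -> str:
        """Assemble the element sequence for one structural class.

        ``interior_length`` fixes the non-coding interior of MITE_LIKE /
        DEF_NO_CODING copies (drawn from the class range when omitted);
        ``keep_left_tir`` picks the surviving TIR of DEF_ONE_TIR copies.
        """
        if class_name not in CLASSES:
            raise ValueError(f"unknown structural class: {class_name!r}")
        rng = np.random.default_rng(0) if rng is None else rng
        st5 = self.subterminal_5prime if keep_subterminals else ""
        st3 = self.subterminal_3prime if keep_subterminals else ""
        coding_core = {
            "AUTONOMOUS": self.spacer1 + self.orf1_cds + self.spacer2
            + self.tpase_cds + self.spacer3,
            "DEF_NO_ORF1": self.spacer1 + self.spacer2 + self.tpase_cds + self.spacer3,
            "DEF_NO_TPASE": self.spacer1 + self.orf1_cds + self.spacer2 + self.spacer3,
        }
        if class_name in coding_core:
            return self.tir_5prime + st5 + coding_core[class_name] + st3 + self.tir_3prime
        if class_name in ("MITE_LIKE", "DEF_NO_CODING"):
            lo, hi = (
                MITE_LEN_RANGE if class_name == "MITE_LIKE"
                else DEF_NO_CODING_INTERIOR_RANGE
            )
            if class_name == "MITE_LIKE":
                # range is on the total length; interior absorbs the rest
                fixed = 2 * len(self.tir_5prime) + len(st5) + len(st3)
                lo, hi = lo - fixed, hi - fixed
            n = interior_length if interior_length is not None else int(rng.integers(lo, hi + 1))
            interior = self.noncoding_spacer[:n]
            return self.tir_5prime + st5 + interior + st3 + self.tir_3prime
        full_interior = coding_core["AUTONOMOUS"]
        if class_name == "DEF_ONE_TIR":
            left = keep_left_tir if keep_left_tir is not None else bool(rng.integers(0, 2))
            if left:
                return self.tir_5prime + st5 + full_interior + st3
            return st5 + full_interior + st3 + self.tir_3prime
        # DEF_NO_TIR_FRAGMENT: internal fragment keeping the coding core
        return st5 + full_interior + st3


def _make_template(rng: np.random.Generator, family: str,
                   orf1_protein: str, tpase_protein: str) -> ElementTemplate:
    orf1_cds = back_translate(orf1_protein)
    tpase_cds = back_translate(tpase_protein)
    fixed = 2 * len(TIR) + 2 * SUBTERMINAL_LEN + len(orf1_cds) + len(tpase_cds)
    spacer_total = AUTONOMOUS_LENGTH[family] - fixed
    s1 = spacer_total // 3
    s2 = spacer_total // 3
    s3 = spacer_total - s1 - s2
    return ElementTemplate(
        family=family,
        tir_5prime=TIR,
        subterminal_5prime=_random_dna(rng, SUBTERMINAL_LEN, forbid="CTAG"),
        subterminal_3prime=_random_dna(rng, SUBTERMINAL_LEN, forbid="CTAG"),
        orf1_protein=orf1_protein,
        tpase_protein=tpase_protein,
        orf1_cds=orf1_cds,
        tpase_cds=tpase_cds,
        spacer1=_random_dna(rng, s1),
        spacer2=_random_dna(rng, s2),
        spacer3=_random_dna(rng, s3),
        noncoding_spacer=_random_dna(rng, 2200),
    )


@lru_cache(maxsize=1)
def default_templates() -> dict[str, ElementTemplate]:
    """The packaged family-A and family-B templates (deterministic)."""
    rng = np.random.default_rng(_FIXTURE_SEED)
    orf1_a = _random_protein(rng, ORF1_LEN_AA)
    tpase_a = _random_protein(rng, TPASE_LEN_AA)
    fam_a = _make_template(rng, "A", orf1_a, tpase_a)
    orf1_b = _diverge_protein(rng, orf1_a, ORF1_B_IDENTITY)
    tpase_b = _diverge_protein(rng, tpase_a, TPASE_B_IDENTITY)
    fam_b = _make_template(rng, "B", orf1_b, tpase_b)
    return {"A": fam_a, "B": fam_b}


def reference_proteins() -> dict[str, str]:
    """Reference protein set for coding-evidence detection.

    Keys are ``ORF1_A``, ``ORF1_B``, ``TPASE_A``, ``TPASE_B``; family suffixes
    act as labels on the reference set (TPaseA/TPaseB), not separate classes.
    """
    t = default_templates()
    return {
        "ORF1_A": t["A"].orf1_protein,
        "ORF1_B": t["B"].orf1_protein,
        "TPASE_A": t["A"].tpase_protein,
        "TPASE_B": t["B"].tpase_protein,
    }
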