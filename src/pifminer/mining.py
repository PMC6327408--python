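"""TIR mining: degenerate motif scanning, de novo inverted-repeat discovery,
TIR pairing into candidate elements, and target-site-duplication extraction.

Coordinates are 0-based half-open throughout. A genome is either a plain
string (treated as a single scaffold named ``"seq"``) or a mapping from
scaffold id to sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .sequences import IUPAC_CODES, encode, revcomp

GenomeLike = str | Mapping[str, str]

FORWARD = "forward"
REVCOMP = "revcomp"

DEFAULT_MAX_SPAN = 30_000
DEFAULT_MIN_SPAN = 50
DEFAULT_TSD_LEN = 3
DEFAULT_MAX_MISMATCH = 2
DEFAULT_MIN_IR_MATCH = 12


def as_scaffolds(genome: GenomeLike) -> dict[str, str]:
    if isinstance(genome, str):
        return {"seq": genome}
    return dict(genome)


@dataclass(frozen=True)
class IUPACMotif:
    """A degenerate DNA pattern over the IUPAC alphabet."""

    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        bad = set(pat) - set(IUPAC_CODES)
        if bad or not pat:
            raise ValueError(f"invalid IUPAC motif {self.pattern!r}")
        object.__setattr__(self, "pattern", pat)

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def length(self) -> int:
        return len(self.pattern)

    def reverse_complement(self) -> "IUPACMotif":
        return IUPACMotif(revcomp(self.pattern))

    def allowed_table(self) -> np.ndarray:
        """Boolean table (256 x len): does byte b satisfy motif position j?

        N bases in the genome never satisfy any motif position.
        """
        table = np.zeros((256, len(self.pattern)), dtype=bool)
        for j, code in enumerate(self.pattern):
            for base in IUPAC_CODES[code]:
                table[ord(base), j] = True
        return table

    def mismatches(self, window: str) -> int:
        """Mismatch count of a window against the pattern (same length)."""
        return sum(
            1
            for base, code in zip(window.upper(), self.pattern)
            if base not in IUPAC_CODES[code] or base == "N"
        )


def default_tir_motif() -> IUPACMotif:
    from .templates import TIR_CONSENSUS

    return IUPACMotif(TIR_CONSENSUS)


@dataclass(frozen=True)
class TIRHit:
    scaffold_id: str
    start: int
    end: int
    orientation: str  # FORWARD or REVCOMP
    matched_seq: str
    mismatches: int


@dataclass(frozen=True)
class CandidateElement:
    """A paired left/right TIR with TSD evidence."""

    scaffold_id: str
    left_tir: TIRHit
    right_tir: TIRHit
    tsd_left: str
    tsd_right: str
    tsd_valid: bool

    @property
    def start(self) -> int:
        return self.left_tir.start

    @property
    def end(self) -> int:
        return self.right_tir.end

    @property
    def span(self) -> int:
        return self.right_tir.end - self.left_tir.start


def _scan_one(seq: str, motif: IUPACMotif, max_mismatch: int,
              orientation: str, scaffold_id: str) -> list[TIRHit]:
    L = len(motif)
    n = len(seq)
    if n < L:
        return []
    table = motif.allowed_table()
    enc = encode(seq.upper())
    m = n - L + 1
    counts = np.zeros(m, dtype=np.int32)
    for j in range(L):
        counts += ~table[enc[j : j + m], j]
    starts = np.nonzero(counts <= max_mismatch)[0]
    return [
        TIRHit(scaffold_id, int(s), int(s) + L, orientation,
               seq[int(s) : int(s) + L], int(counts[s]))
        for s in starts
    ]


def scan_motif(genome: GenomeLike, motif: IUPACMotif | str = None,
               max_mismatch: int = DEFAULT_MAX_MISMATCH) -> list[TIRHit]:
    """Find every match of ``motif`` in both orientations.

    A position contributes one mismatch whenever the genome base falls
    outside the IUPAC class at that motif position (degenerate classes match
    at zero cost); hits with ≤ ``max_mismatch`` mismatches are reported,
    sorted by (scaffold, start). Overlapping hits are allowed.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be non-negative")
    if motif is None:
        motif = default_tir_motif()
    elif isinstance(motif, str):
        motif = IUPACMotif(motif)
    hits: list[TIRHit] = []
    rc = motif.reverse_complement()
    for scaffold_id, seq in as_scaffolds(genome).items():
        hits.extend(_scan_one(seq, motif, max_mismatch, FORWARD, scaffold_id))
        hits.extend(_scan_one(seq, rc, max_mismatch, REVCOMP, scaffold_id))
    hits.sort(key=lambda h: (h.scaffold_id, h.start, h.orientation))
    return hits


def discover_inverted_repeats(
    region: str, min_match: int = DEFAULT_MIN_IR_MATCH,
    max_span: int = DEFAULT_MAX_SPAN,
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """All maximal exact inverted-repeat pairs in ``region``.

    A pair is two non-overlapping intervals (left before right) of equal
    length ≥ ``min_match`` where the left substring equals the reverse
    complement of the right one, total span (right end − left start) at most
    ``max_span``, and not extendable outward or inward while staying a valid
    non-overlapping pair. Found by exact k-mer anchoring (k = ``min_match``)
    with maximal extension.
    """
    if min_match < 4:
        raise ValueError("min_match must be at least 4")
    region = region.upper()
    n = len(region)
    k = min_match
    if n < 2 * k:
        return []
    rc_region = revcomp(region)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    index: dict[str, list[int]] = {}
    # rc(region[b:b+k]) == rc_region[n-b-k : n-b]
    for b in range(n - k + 1):
        index.setdefault(rc_region[n - b - k : n - b], []).append(b)
    found: set[tuple[int, int, int, int]] = set()
    for a in range(n - k + 1):
        for b in index.get(region[a : a + k], ()):
            if b < a + k:
                continue
            aa, bb, L = a, b, k
            # outward: left start left, right end right
            while aa > 0 and bb + L < n and region[aa - 1] == comp.get(region[bb + L], "?"):
                aa -= 1
                L += 1
            # inward: left end right, right start left
            while bb - 1 >= aa + L + 1 and region[aa + L] == comp.get(region[bb - 1], "?"):
                bb -= 1
                L += 1
            if (bb + L) - aa <= max_span:
                found.add((aa, aa + L, bb, bb + L))
    return sorted(((a0, a1), (b0, b1)) for a0, a1, b0, b1 in found)


def extract_tsd(genome_seq: str, left_start: int, right_end: int,
                tsd_len: int = DEFAULT_TSD_LEN) -> tuple[str, str, bool]:
    """Flanking ``tsd_len``-mers of an element and whether they agree.

    Elements too close to a scaffold edge get the sentinel ``"N"*tsd_len``
    and ``tsd_valid=False``.
    """
    sentinel = "N" * tsd_len
    if left_start < tsd_len or right_end + tsd_len > len(genome_seq):
        return sentinel, sentinel, False
    left = genome_seq[left_start - tsd_len : left_start]
    right = genome_seq[right_end : right_end + tsd_len]
    return left, right, left == right


def pair_tirs(
    genome: GenomeLike,
    hits: Iterable[TIRHit],
    max_span: int = DEFAULT_MAX_SPAN,
    min_span: int = DEFAULT_MIN_SPAN,
    tsd_len: int = DEFAULT_TSD_LEN,
) -> list[CandidateElement]:
    """Greedily pair forward TIR hits with downstream reverse-complement hits.

    Scanning left to right, each forward hit takes the best unused
    reverse-complement hit with span within [min_span, max_span]; ties are
    broken by TSD validity first, then smallest span, then leftmost right
    TIR. Each hit is used in at most one element. TSD preference is global:
    a first pass forms only TSD-valid pairs, so a stray unpaired TIR cannot
    steal the partner of a downstream intact element; leftover hits are
    paired (TSD-invalid) in a second pass.
    """
    scaffolds = as_scaffolds(genome)
    by_scaffold: dict[str, tuple[list[TIRHit], list[TIRHit]]] = {}
    for h in hits:
        fwd, rev = by_scaffold.setdefault(h.scaffold_id, ([], []))
        (fwd if h.orientation == FORWARD else rev).append(h)
    elements: list[CandidateElement] = []
    for scaffold_id, (fwd, rev) in sorted(by_scaffold.items()):
        seq = scaffolds[scaffold_id]
        fwd.sort(key=lambda h: h.start)
        rev.sort(key=lambda h: h.start)
        used_rev: set[int] = set()
        used_fwd: set[int] = set()
        for require_valid in (True, False):
            for fi, f in enumerate(fwd):
                if fi in used_fwd:
                    continue
                best = None
                for i, r in enumerate(rev):
                    if i in used_rev or r.start < f.end:
                        continue
                    span = r.end - f.start
                    if span < min_span:
                        continue
                    if span > max_span:
                        break
                    tl, tr, valid = extract_tsd(seq, f.start, r.end, tsd_len)
                    if require_valid and not valid:
                        continue
                    key = (not valid, span, r.start)
                    if best is None or key < best[0]:
                        best = (key, i,
                                CandidateElement(scaffold_id, f, r, tl, tr, valid))
                if best is not None:
                    used_rev.add(best[1])
                    used_fwd.add(fi)
                    elements.append(best[2])
    elements.sort(key=lambda e: (e.scaffold_id, e.start))
    return elements
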