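"""Structural classification of candidate elements.

Coding evidence (ORF1 / TPase) is detected by six-frame translated local
alignment of the element sequence against reference proteins (BLOSUM62,
gap open 11 / extend 1), and the TIR/coding presence pattern maps
deterministically onto the structural-class taxonomy: intact autonomous
copies, the defective spectrum, and short non-coding MITE-like copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .sequences import revcomp

DEFAULT_MIN_IDENTITY = 30.0
DEFAULT_MIN_COVERAGE = 50.0
DEFAULT_MITE_MAX_LEN = 800


@dataclass(frozen=True)
class CodingEvidence:
    element_id: str
    reference: str
    frame: int  # 1..3 forward, -1..-3 reverse
    identity: float  # percent over aligned columns
    coverage: float  # percent of reference residues aligned
    aligned_start: int  # on the element, 0-based half-open, nt
    aligned_end: int


@dataclass(frozen=True)
class ElementAnnotation:
    element_id: str
    scaffold_id: str
    start: int
    end: int
    has_left_tir: bool
    has_right_tir: bool
    has_orf1: bool
    has_tpase: bool
    class_name: str
    family: str | None = None
    tsd: str | None = None
    tsd_valid: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@lru_cache(maxsize=1)
def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _identity_from_alignment(alignment, target: str, query: str):
    """(identity%, aligned columns, target span, query residues aligned)."""
    t_blocks, q_blocks = alignment.aligned
    matches = 0
    block_cols = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        block_cols += te - ts
        matches += sum(1 for a, b in zip(target[ts:te], query[qs:qe]) if a == b)
    gap_cols = 0
    for i in range(1, len(t_blocks)):
        gap_cols += max(
            t_blocks[i][0] - t_blocks[i - 1][1], q_blocks[i][0] - q_blocks[i - 1][1]
        )
    columns = block_cols + gap_cols
    if columns == 0:
        return 0.0, 0, (0, 0), 0
    identity = 100.0 * matches / columns
    t_span = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    q_res = sum(qe - qs for _, (qs, qe) in zip(t_blocks, q_blocks))
    return identity, columns, t_span, q_res


def _frames(seq: str) -> list[tuple[int, int, str]]:
    """Six-frame translations: (frame, offset, protein)."""
    out = []
    rc = revcomp(seq)
    for frame in (1, 2, 3, -1, -2, -3):
        src = seq if frame > 0 else rc
        off = abs(frame) - 1
        sub = src[off : off + 3 * ((len(src) - off) // 3)]
        out.append((frame, off, str(Seq(sub).translate())))
    return out


def _longest_orf_run(protein: str) -> int:
    best = cur = 0
    for ch in protein:
        if ch == "*":
            best = max(best, cur)
            cur = 0
        else:
            cur += 1
    return max(best, cur)


def detect_coding(
    element_seq: str,
    references: Mapping[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    element_id: str = "",
    prefilter: bool = True,
) -> list[CodingEvidence]:
    """Best local translated alignment per reference per strand-frame.

    Evidence is reported only where identity ≥ ``min_identity`` and reference
    coverage ≥ ``min_coverage`` (both percent). With ``prefilter`` on, frames
    whose longest stop-free stretch cannot plausibly cover half the required
    reference fraction are skipped before alignment; alignments do not splice
    across introns, so coverage reflects the best single local alignment.
    """
    if not references:
        raise ValueError("reference protein set is empty")
    if len(element_seq) < 3:
        return []
    aligner = _protein_aligner()
    n = len(element_seq)
    evidence: list[CodingEvidence] = []
    frames = _frames(element_seq)
    runs = {frame: _longest_orf_run(prot) for frame, _, prot in frames}
    for ref_name, ref in references.items():
        need = min_coverage / 100.0 * len(ref)
        for frame, off, prot in frames:
            if not prot:
                continue
            if prefilter and runs[frame] < 0.5 * need:
                continue
            alignments = aligner.align(prot, ref)
            if len(alignments) == 0:
                continue
            best = alignments[0]
            identity, columns, t_span, q_res = _identity_from_alignment(best, prot, ref)
            coverage = 100.0 * q_res / len(ref)
            if identity < min_identity or coverage < min_coverage:
                continue
            if frame > 0:
                nt_start = off + 3 * t_span[0]
                nt_end = off + 3 * t_span[1]
            else:
                nt_start = n - (off + 3 * t_span[1])
                nt_end = n - (off + 3 * t_span[0])
            evidence.append(
                CodingEvidence(
                    element_id=element_id,
                    reference=ref_name,
                    frame=frame,
                    identity=identity,
                    coverage=coverage,
                    aligned_start=nt_start,
                    aligned_end=nt_end,
                )
            )
    evidence.sort(key=lambda e: (e.reference, -e.identity, e.frame))
    return evidence


def coding_presence(evidence: Iterable[CodingEvidence]) -> dict[str, bool]:
    """ORF1/TPase presence flags (reference names prefixed ORF1/TPASE)."""
    has_orf1 = any(e.reference.upper().startswith("ORF1") for e in evidence)
    has_tpase = any(e.reference.upper().startswith("TPASE") for e in evidence)
    return {"has_orf1": has_orf1, "has_tpase": has_tpase}


def classify(
    element_id: str,
    scaffold_id: str,
    start: int,
    end: int,
    *,
    has_left_tir: bool,
    has_right_tir: bool,
    has_orf1: bool,
    has_tpase: bool,
    mite_max_len: int = DEFAULT_MITE_MAX_LEN,
    family: str | None = None,
    tsd: str | None = None,
    tsd_valid: bool = False,
) -> ElementAnnotation:
    """Deterministic structural class from the presence flags.

    Both TIRs with ORF1+TPase → AUTONOMOUS; with TPase only → DEF_NO_ORF1;
    with ORF1 only → DEF_NO_TPASE; with no coding → MITE_LIKE when at most
    ``mite_max_len`` long, else DEF_NO_CODING. One TIR → DEF_ONE_TIR; no TIR
    → DEF_NO_TIR_FRAGMENT (coding-bearing remnants; TIR-less candidates are
    only ever raised on coding/sub-terminal evidence).
    """
    length = end - start
    if has_left_tir and has_right_tir:
        if has_orf1 and has_tpase:
            class_name = "AUTONOMOUS"
        elif has_tpase:
            class_name = "DEF_NO_ORF1"
        elif has_orf1:
            class_name = "DEF_NO_TPASE"
        else:
            class_name = "MITE_LIKE" if length <= mite_max_len else "DEF_NO_CODING"
    elif has_left_tir or has_right_tir:
        class_name = "DEF_ONE_TIR"
    else:
        class_name = "DEF_NO_TIR_FRAGMENT"
    return ElementAnnotation(
        element_id=element_id,
        scaffold_id=scaffold_id,
        start=start,
        end=end,
        has_left_tir=has_left_tir,
        has_right_tir=has_right_tir,
        has_orf1=has_orf1,
        has_tpase=has_tpase,
        class_name=class_name,
        family=family,
        tsd=tsd,
        tsd_valid=tsd_valid,
    )


def length_histogram(
    annotations: Sequence[ElementAnnotation], bin_width: int = 1_000
) -> pd.DataFrame:
    """Per-class length distribution: rows classes, columns bin lower bounds."""
    if not annotations:
        return pd.DataFrame()
    rows = [
        {"class": a.class_name, "bin": (a.length // bin_width) * bin_width}
        for a in annotations
    ]
    df = pd.DataFrame(rows)
    out = df.groupby(["class", "bin"]).size().unstack(fill_value=0)
    return out.reindex(sorted(out.columns), axis=1)
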