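"""Pairwise identity and 80-80-80 family clustering.

Two element copies belong to the same family when they share at least 80%
identity over at least 80% of both sequences across at least 80 aligned
units; families are the single-linkage closure of that pairwise relation
(complete linkage available for comparison). DNA-level identity uses a
bit-parallel global aligner (edlib); protein-level identity uses a BLOSUM62
global alignment with free end gaps.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import edlib
from Bio.Align import PairwiseAligner, substitution_matrices

LEVELS = ("dna", "protein_orf1", "protein_tpase")


@dataclass(frozen=True)
class IdentityRecord:
    element_a: str
    element_b: str
    level: str
    identity: float  # percent over alignment columns, terminal gaps excluded
    aligned_length: int  # alignment columns (bases or residues)
    coverage_a: float  # percent of sequence a inside the aligned span
    coverage_b: float


@dataclass(frozen=True)
class FamilyAssignment:
    assignments: dict[str, str]
    min_identity: float = 80.0
    min_coverage: float = 80.0
    min_aligned: int = 80
    level: str = "dna"
    linkage: str = "single"
    records: tuple[IdentityRecord, ...] = field(default=(), repr=False)


@lru_cache(maxsize=1)
def _global_protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.end_gap_score = 0.0
    return aligner


def _stats_from_rows(row_a: str, row_b: str, len_a: int, len_b: int):
    cols = [
        i for i in range(len(row_a)) if row_a[i] != "-" and row_b[i] != "-"
    ]
    if not cols:
        return 0.0, 0, 0.0, 0.0
    first, last = cols[0], cols[-1]
    span_a = row_a[first : last + 1]
    span_b = row_b[first : last + 1]
    columns = last - first + 1
    matches = sum(1 for a, b in zip(span_a, span_b) if a == b and a != "-")
    identity = 100.0 * matches / columns
    cov_a = 100.0 * sum(1 for c in span_a if c != "-") / len_a
    cov_b = 100.0 * sum(1 for c in span_b if c != "-") / len_b
    return identity, columns, cov_a, cov_b


def pairwise_identity(
    seq_a: str, seq_b: str, level: str = "dna",
    id_a: str = "a", id_b: str = "b",
) -> IdentityRecord:
    """Global alignment identity between two sequences.

    Identity is matches over alignment columns excluding terminal gaps;
    coverage is the fraction of each sequence lying inside the aligned span.
    Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    if level == "dna":
        res = edlib.align(seq_a, seq_b, task="path", mode="NW")
        nice = edlib.getNiceAlignment(res, seq_a, seq_b)
        identity, columns, cov_a, cov_b = _stats_from_rows(
            nice["query_aligned"], nice["target_aligned"], len(seq_a), len(seq_b)
        )
    else:
        aligner = _global_protein_aligner()
        best = aligner.align(seq_a, seq_b)[0]
        row_a, row_b = str(best[0]), str(best[1])
        identity, columns, cov_a, cov_b = _stats_from_rows(
            row_a, row_b, len(seq_a), len(seq_b)
        )
    return IdentityRecord(id_a, id_b, level, identity, columns, cov_a, cov_b)


def _same_family(rec: IdentityRecord, min_identity, min_coverage, min_aligned) -> bool:
    return (
        rec.identity >= min_identity
        and rec.coverage_a >= min_coverage
        and rec.coverage_b >= min_coverage
        and rec.aligned_length >= min_aligned
    )


def cluster_families(
    elements: Mapping[str, str],
    min_identity: float = 80.0,
    min_coverage: float = 80.0,
    min_aligned: int = 80,
    level: str = "dna",
    linkage: str = "single",
) -> FamilyAssignment:
    """Partition sequences into families under the 80-80-80 rule.

    Single linkage (default) takes the transitive closure of the pairwise
    same-family relation; complete linkage requires every cross pair of a
    merged cluster to satisfy it. Family labels (A, B, ...) are ordered by
    the lexicographically smallest member id, so the partition and labels
    are independent of input order.
    """
    ids = sorted(elements)
    records = []
    edges: set[tuple[str, str]] = set()
    for a, b in itertools.combinations(ids, 2):
        rec = pairwise_identity(elements[a], elements[b], level, a, b)
        records.append(rec)
        if _same_family(rec, min_identity, min_coverage, min_aligned):
            edges.add((a, b))

    if linkage == "single":
        parent = {i: i for i in ids}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in edges:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
        groups: dict[str, list[str]] = {}
        for i in ids:
            groups.setdefault(find(i), []).append(i)
        clusters = list(groups.values())
    elif linkage == "complete":
        clusters = [[i] for i in ids]
        merged = True
        while merged:
            merged = False
            for i, j in itertools.combinations(range(len(clusters)), 2):
                if all(
                    (min(a, b), max(a, b)) in edges
                    for a in clusters[i]
                    for b in clusters[j]
                ):
                    clusters[i] = sorted(clusters[i] + clusters[j])
                    del clusters[j]
                    merged = True
                    break
    else:
        raise ValueError("linkage must be 'single' or 'complete'")

    clusters.sort(key=lambda c: min(c))
    labels = list(string.ascii_uppercase) + [
        f"F{i}" for i in range(1, len(clusters) + 1)
    ]
    assignments = {
        member: labels[k] for k, cluster in enumerate(clusters) for member in cluster
    }
    return FamilyAssignment(
        assignments=assignments,
        min_identity=min_identity,
        min_coverage=min_coverage,
        min_aligned=min_aligned,
        level=level,
        linkage=linkage,
        records=tuple(records),
    )
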