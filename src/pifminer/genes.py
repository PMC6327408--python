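"""Gene models and exon/intron/intergenic annotation of element insertions.

Internally 0-based half-open; GFF3 on disk is 1-based closed. The GFF3
subset handled here is the three-level gene → mRNA → exon hierarchy this
package writes (first mRNA per gene is used).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

Interval = tuple[int, int]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    scaffold: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        exons = tuple(sorted(tuple(e) for e in self.exons))
        if not exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        for s, e in exons:
            if e <= s:
                raise ValueError(f"gene {self.gene_id}: empty exon interval")
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        )


@dataclass(frozen=True)
class InsertionCall:
    element_id: str
    context: str  # "exon" | "intron" | "intergenic"
    gene_id: str | None
    distance_to_nearest_gene: int
    flank_left_gene: str | None = None
    flank_right_gene: str | None = None


def write_gff3_genes(genes: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.scaffold, g.start)):
            gid, mid = g.gene_id, f"{g.gene_id}.t1"
            base = f"{g.scaffold}\tpifminer\t"
            span = f"{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
            fh.write(base + "gene\t" + span + f"ID={gid}\n")
            fh.write(base + "mRNA\t" + span + f"ID={mid};Parent={gid}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    base + "exon\t" + f"{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mid}.exon{i};Parent={mid}\n"
                )


def _attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3_genes(path: str) -> list[GeneModel]:
    """Read gene models (gene/mRNA/exon features; first mRNA per gene)."""
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            scaffold, _, ftype, start, end, _, strand, _, attrs = f[:9]
            a = _attrs(attrs)
            if ftype == "gene":
                genes[a["ID"]] = {"scaffold": scaffold, "strand": strand, "exons": []}
            elif ftype == "mRNA":
                gid = a.get("Parent")
                if gid in genes and not any(
                    m == gid for m in mrna_to_gene.values()
                ):
                    mrna_to_gene[a["ID"]] = gid
            elif ftype == "exon":
                gid = mrna_to_gene.get(a.get("Parent", ""))
                if gid is not None:
                    genes[gid]["exons"].append((int(start) - 1, int(end)))
    return [
        GeneModel(gid, d["scaffold"], d["strand"], tuple(sorted(d["exons"])))
        for gid, d in genes.items()
        if d["exons"]
    ]


def annotate_insertions(
    elements: Iterable[tuple[str, str, int, int]],
    genes: Sequence[GeneModel],
) -> list[InsertionCall]:
    """Assign exon/intron/intergenic context to each element interval.

    ``elements`` yields (element_id, scaffold, start, end) tuples. Context is
    ``exon`` when the element overlaps any exon base (exon takes priority
    over intron at boundaries), ``intron`` when it overlaps a gene span but
    no exon, and ``intergenic`` otherwise, with distance to the nearest gene
    boundary (ties broken toward the lower-coordinate gene). Strand plays no
    role: context is purely positional.
    """
    for g in genes:
        GeneModel(g.gene_id, g.scaffold, g.strand, g.exons)  # re-validate

    exon_trees: dict[str, IntervalTree] = {}
    span_trees: dict[str, IntervalTree] = {}
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
        et = exon_trees.setdefault(g.scaffold, IntervalTree())
        for s, e in g.exons:
            et[s:e] = g
        span_trees.setdefault(g.scaffold, IntervalTree())[g.start:g.end] = g
    for gl in by_scaffold.values():
        gl.sort(key=lambda g: (g.start, g.end))

    calls: list[InsertionCall] = []
    for element_id, scaffold, start, end in elements:
        exon_hits = sorted(
            {iv.data for iv in exon_trees.get(scaffold, IntervalTree()).overlap(start, end)},
            key=lambda g: (g.start, g.gene_id),
        )
        if exon_hits:
            calls.append(InsertionCall(element_id, "exon", exon_hits[0].gene_id, 0))
            continue
        span_hits = sorted(
            {iv.data for iv in span_trees.get(scaffold, IntervalTree()).overlap(start, end)},
            key=lambda g: (g.start, g.gene_id),
        )
        if span_hits:
            calls.append(InsertionCall(element_id, "intron", span_hits[0].gene_id, 0))
            continue
        best_dist = None
        left = right = None
        for g in by_scaffold.get(scaffold, []):
            if g.end <= start:
                if left is None or g.end > left.end:
                    left = g
            elif g.start >= end:
                if right is None or g.start < right.start:
                    right = g
        for g in (left, right):
            if g is None:
                continue
            d = start - g.end if g.end <= start else g.start - end
            if best_dist is None or d < best_dist:
                best_dist = d
        calls.append(
            InsertionCall(
                element_id, "intergenic", None,
                best_dist if best_dist is not None else -1,
                flank_left_gene=left.gene_id if left else None,
                flank_right_gene=right.gene_id if right else None,
            )
        )
    return calls


def summarize_insertions(calls: Sequence[InsertionCall]) -> dict:
    """Gene-level summary of insertion calls.

    ``n_elements_in_genes`` counts exon+intron calls; ``n_distinct_genes``
    the genes they hit. For intergenic elements both counting conventions
    are reported: the number of intergenic elements and the number of
    distinct genes flanking them (both neighbours counted).
    """
    in_genes = [c for c in calls if c.context in ("exon", "intron")]
    per_context = {"exon": 0, "intron": 0, "intergenic": 0}
    for c in calls:
        per_context[c.context] += 1
    flanking = {
        g
        for c in calls
        if c.context == "intergenic"
        for g in (c.flank_left_gene, c.flank_right_gene)
        if g is not None
    }
    return {
        "n_elements_in_genes": len(in_genes),
        "n_distinct_genes": len({c.gene_id for c in in_genes}),
        "per_context_counts": per_context,
        "n_intergenic_elements": per_context["intergenic"],
        "n_intergenic_flanking_genes": len(flanking),
    }
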