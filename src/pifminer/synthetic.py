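"""Synthetic genomes with planted transposon copies and known ground truth.

The generator emulates the study system: a random background genome into
which copies of every structural class are planted (each insertion creating
a 3-bp target-site duplication), gene models overlapping a configurable
fraction of the insertions, and a "variant" genome of a later clonal
generation differing by a small number of new insertions, for transposon
display testing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from . import templates as T
from .genes import GeneModel, write_gff3_genes
from .io import write_fasta, write_truth_tsv
from .sequences import mutate, random_dna, revcomp

SCAFFOLD_ID = "scaffold_1"

TRUTH_COLUMNS = ("element_id", "scaffold", "class", "family", "start", "end", "tsd")


class GenerationError(RuntimeError):
    """Raised when planting positions cannot be drawn without overlap."""


@dataclass(frozen=True)
class PlantedTruth:
    element_id: str
    scaffold_id: str
    insert_position: int  # 0-based offset into the pre-insertion background
    class_name: str
    family: str
    element_length: int
    tsd: str
    start: int  # final-genome coordinates, 0-based half-open
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.class_name not in T.CLASSES:
            raise ValueError(f"unknown class {self.class_name!r}")
        if self.element_length < 50:
            raise ValueError("element_length must be >= 50")
        if len(self.tsd) != 3:
            raise ValueError("tsd must be 3 bases")


def default_class_counts() -> dict[str, int]:
    """Class inventory for the standard 200-element recovery benchmark."""
    return {
        "AUTONOMOUS": 30,
        "DEF_NO_ORF1": 25,
        "DEF_NO_TPASE": 25,
        "DEF_NO_CODING": 25,
        "DEF_ONE_TIR": 25,
        "DEF_NO_TIR_FRAGMENT": 20,
        "MITE_LIKE": 50,
    }


def scaled_class_counts(n_elements: int) -> dict[str, int]:
    """The default class mix rescaled to ``n_elements`` total copies."""
    base = default_class_counts()
    total = sum(base.values())
    counts = {c: (k * n_elements) // total for c, k in base.items()}
    # distribute the rounding remainder over the largest classes
    for c in sorted(base, key=base.get, reverse=True):
        if sum(counts.values()) >= n_elements:
            break
        counts[c] += 1
    return counts


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults are the standard study conditions: a 5-Mb background at 40% GC,
    200 planted copies across all structural classes, 2% per-site divergence
    of planted copies, gene models over ~40% of insertions with the
    exon share at 24% (the intron/exon split observed for real insertions),
    and a variant genome carrying two extra MITE insertions.
    """

    genome_length: int = 5_000_000
    gc_fraction: float = 0.40
    seed: int = 0
    class_counts: dict[str, int] = field(default_factory=default_class_counts)
    mutation_rate: float = 0.02
    n_genes: int = 120
    variant_extra_insertions: int = 2
    # study-condition knobs
    tsd_force_tta: bool = True
    keep_subterminals: bool = True
    frac_elements_in_genes: float = 0.40
    exon_fraction: float = 0.24
    min_separation: int = 1_200
    variant_class: str = "MITE_LIKE"
    variant_family: str = "B"

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if not 0.0 <= self.mutation_rate < 0.5:
            raise ValueError("mutation_rate must lie in [0, 0.5)")
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be non-negative")
        if self.n_genes < 0 or self.variant_extra_insertions < 0:
            raise ValueError("counts must be non-negative")
        unknown = set(self.class_counts) - set(T.CLASSES)
        if unknown:
            raise ValueError(f"unknown classes: {sorted(unknown)}")


def generate_background(length: int, gc: float, seed: int) -> str:
    """Seeded random background genome over {A,C,G,T}."""
    return random_dna(length, gc, np.random.default_rng(seed))


def plant_element(
    genome: str,
    template: T.ElementTemplate,
    class_name: str,
    position: int,
    rng: np.random.Generator,
    *,
    mutation_rate: float = 0.0,
    strand: str = "+",
    keep_subterminals: bool = True,
    element_id: str = "E0001",
    scaffold_id: str = SCAFFOLD_ID,
    tsd_len: int = 3,
) -> tuple[str, PlantedTruth]:
    """Insert one element at ``position``, duplicating the 3-bp target site.

    The ``tsd_len`` bases at [position, position+tsd_len) of the background
    end up immediately on both sides of the inserted element, so the genome
    grows by element length + tsd_len.
    """
    if not tsd_len <= position <= len(genome) - tsd_len:
        raise ValueError(f"position {position} out of plantable range")
    element = template.build(class_name, rng, keep_subterminals=keep_subterminals)
    element = mutate(element, mutation_rate, rng)
    if strand == "-":
        element = revcomp(element)
    tsd = genome[position : position + tsd_len]
    new_genome = genome[: position + tsd_len] + element + genome[position:]
    truth = PlantedTruth(
        element_id=element_id,
        scaffold_id=scaffold_id,
        insert_position=position,
        class_name=class_name,
        family=template.family,
        element_length=len(element),
        tsd=tsd,
        start=position + tsd_len,
        end=position + tsd_len + len(element),
        strand=strand,
    )
    return new_genome, truth


def _draw_positions(
    background: str,
    n: int,
    rng: np.random.Generator,
    *,
    force_tta: bool,
    min_separation: int,
    margin: int = 2_000,
    max_redraws: int = 1_000,
) -> list[int]:
    lo, hi = margin, len(background) - margin
    if force_tta:
        candidates = np.array(
            [i for i in _find_all(background, "TTA") if lo <= i < hi], dtype=np.int64
        )
        if candidates.size == 0:
            raise GenerationError("no TTA target sites in plantable range")
    accepted: list[int] = []
    redraws = 0
    while len(accepted) < n:
        if force_tta:
            pos = int(candidates[rng.integers(0, candidates.size)])
        else:
            pos = int(rng.integers(lo, hi))
        if all(abs(pos - p) >= min_separation for p in accepted):
            accepted.append(pos)
        else:
            redraws += 1
            if redraws > max_redraws:
                raise GenerationError(
                    f"could not place {n} insertions after {max_redraws} re-draws"
                )
    return accepted


def _find_all(seq: str, sub: str) -> list[int]:
    out, i = [], seq.find(sub)
    while i != -1:
        out.append(i)
        i = seq.find(sub, i + 1)
    return out


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    genome: dict[str, str]
    variant_genome: dict[str, str]
    truth: list[PlantedTruth]
    variant_truth: list[PlantedTruth]  # extra insertions only, variant coords
    genes: list[GeneModel]
    paths: dict[str, str] = field(default_factory=dict)


def _plant_many(
    background: str,
    jobs: list[tuple[str, str, str]],  # (class, family, strand)
    positions: list[int],
    rng: np.random.Generator,
    spec: SyntheticSpec,
    id_offset: int = 0,
) -> tuple[str, list[PlantedTruth]]:
    order = np.argsort(positions)
    tmpl = T.default_templates()
    parts: list[str] = []
    truths: list[PlantedTruth] = []
    prev = 0
    cum = 0
    for rank, idx in enumerate(order):
        pos = positions[idx]
        class_name, family, strand = jobs[idx]
        element = tmpl[family].build(
            class_name, rng, keep_subterminals=spec.keep_subterminals
        )
        element = mutate(element, spec.mutation_rate, rng)
        if strand == "-":
            element = revcomp(element)
        parts.append(background[prev : pos + 3])
        cum += (pos + 3) - prev
        start = cum
        parts.append(element)
        cum += len(element)
        truths.append(
            PlantedTruth(
                element_id=f"E{id_offset + rank + 1:04d}",
                scaffold_id=SCAFFOLD_ID,
                insert_position=pos,
                class_name=class_name,
                family=family,
                element_length=len(element),
                tsd=background[pos : pos + 3],
                start=start,
                end=start + len(element),
                strand=strand,
            )
        )
        prev = pos
    parts.append(background[prev:])
    return "".join(parts), truths


def _place_genes(
    genome_len: int,
    truths: list[PlantedTruth],
    rng: np.random.Generator,
    spec: SyntheticSpec,
) -> list[GeneModel]:
    genes: list[GeneModel] = []
    occupied: list[tuple[int, int]] = [(t.start, t.end) for t in truths]

    def free(s: int, e: int) -> bool:
        return s >= 0 and e <= genome_len and all(
            e <= gs or s >= ge for gs, ge in occupied
        )

    n_in_genes = min(
        int(round(spec.frac_elements_in_genes * len(truths))), spec.n_genes, len(truths)
    )
    chosen = rng.choice(len(truths), size=n_in_genes, replace=False) if n_in_genes else []
    strands = "+-"
    for j, idx in enumerate(sorted(int(i) for i in np.atleast_1d(chosen))):
        t = truths[idx]
        strand = strands[int(rng.integers(0, 2))]
        gid = f"G{j + 1:04d}"
        if rng.random() < spec.exon_fraction:
            exons = ((t.start - 200, t.end + 200),)
        else:
            exons = ((t.start - 400, t.start - 100), (t.end + 100, t.end + 400))
        gs, ge = exons[0][0], exons[-1][1]
        span_ok = 0 <= gs and ge <= genome_len and all(
            ge <= s or gs >= e
            for k, (s, e) in enumerate(occupied)
            if k != idx  # the gene may (and should) contain its own element
        )
        if not span_ok:
            continue
        genes.append(GeneModel(gid, SCAFFOLD_ID, strand, exons))
        occupied.append((gs, ge))
    # intergenic filler genes in element-free space
    n_extra = spec.n_genes - len(genes)
    attempts = 0
    while n_extra > 0 and attempts < 1_000:
        attempts += 1
        gs = int(rng.integers(1_000, genome_len - 3_000))
        exons = ((gs, gs + 400), (gs + 700, gs + 1_200))
        if free(gs - 200, gs + 1_400):
            genes.append(
                GeneModel(
                    f"G{len(genes) + 1:04d}", SCAFFOLD_ID,
                    strands[int(rng.integers(0, 2))], exons,
                )
            )
            occupied.append((gs - 200, gs + 1_400))
            n_extra -= 1
    return sorted(genes, key=lambda g: g.start)


def generate_dataset(spec: SyntheticSpec, outdir: str | None = None) -> SyntheticDataset:
    """Generate base + variant genomes, gene models and the truth tables.

    When ``outdir`` is given, writes ``genome.fasta``, ``genes.gff3``,
    ``truth.tsv``, ``variant.fasta`` and ``variant_truth.tsv`` there.
    Identical spec (including seed) reproduces byte-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    background = random_dna(spec.genome_length, spec.gc_fraction, rng)

    jobs: list[tuple[str, str, str]] = []
    for class_name in T.CLASSES:  # fixed order for determinism
        for _ in range(spec.class_counts.get(class_name, 0)):
            family = "AB"[int(rng.integers(0, 2))]
            strand = "+-"[int(rng.integers(0, 2))]
            jobs.append((class_name, family, strand))
    positions = _draw_positions(
        background, len(jobs), rng,
        force_tta=spec.tsd_force_tta, min_separation=spec.min_separation,
    )
    genome, truths = _plant_many(background, jobs, positions, rng, spec)

    genes = _place_genes(len(genome), truths, rng, spec)

    # variant generation: extra insertions into the finished base genome
    v_jobs = [
        (spec.variant_class, spec.variant_family, "+-"[int(rng.integers(0, 2))])
        for _ in range(spec.variant_extra_insertions)
    ]
    if v_jobs:
        v_candidates_ok = False
        for _ in range(1_000):
            v_positions = _draw_positions(
                genome, len(v_jobs), rng,
                force_tta=spec.tsd_force_tta, min_separation=spec.min_separation,
            )
            # avoid landing inside an existing element or gene
            blocked = [(t.start - 50, t.end + 50) for t in truths]
            blocked += [(g.start - 50, g.end + 50) for g in genes]
            if all(
                all(p + 3 <= s or p >= e for s, e in blocked) for p in v_positions
            ):
                v_candidates_ok = True
                break
        if not v_candidates_ok:
            raise GenerationError("could not place variant insertions")
        # new transposition events are fresh copies of the master element,
        # so they carry none of the divergence of the resident copies
        variant_genome, v_truths = _plant_many(
            genome, v_jobs, v_positions, rng,
            replace(spec, mutation_rate=0.0), id_offset=len(truths),
        )
    else:
        variant_genome, v_truths = genome, []

    ds = SyntheticDataset(
        spec=spec,
        genome={SCAFFOLD_ID: genome},
        variant_genome={SCAFFOLD_ID: variant_genome},
        truth=truths,
        variant_truth=v_truths,
        genes=genes,
    )
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "fasta": os.path.join(outdir, "genome.fasta"),
            "gff3": os.path.join(outdir, "genes.gff3"),
            "truth": os.path.join(outdir, "truth.tsv"),
            "variant_fasta": os.path.join(outdir, "variant.fasta"),
            "variant_truth": os.path.join(outdir, "variant_truth.tsv"),
        }
        write_fasta(ds.genome, paths["fasta"])
        write_gff3_genes(genes, paths["gff3"])
        write_truth_tsv(truths, paths["truth"])
        write_fasta(ds.variant_genome, paths["variant_fasta"])
        write_truth_tsv(v_truths, paths["variant_truth"])
        ds.paths = paths
    return ds
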