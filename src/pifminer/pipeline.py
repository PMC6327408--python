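"""End-to-end orchestration: scan → assemble → classify → cluster →
annotate → display → report, with a single serializable config and a
planted-truth evaluator.

Candidate discovery combines two routes. TIR pairing alone finds every
two-TIR copy, but one-TIR and TIR-less remnants are invisible to it, so the
pipeline also maps the known family sub-terminal reference sequences
(exactly as the original element ends are mapped to a genome to find
copies) and assembles element boundaries from paired sub-terminal hits,
with TIR hits adjacent to those boundaries setting the presence flags.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .classify import (
    ElementAnnotation,
    classify,
    coding_presence,
    detect_coding,
    length_histogram,
)
from .display import (
    DEFAULT_NN,
    DisplayProfile,
    diff_profiles,
    merge_profiles,
    simulate_display,
)
from .families import cluster_families
from .genes import annotate_insertions, read_gff3_genes, summarize_insertions
from .io import read_fasta, write_elements_gff3
from .mining import (
    CandidateElement,
    IUPACMotif,
    TIRHit,
    as_scaffolds,
    extract_tsd,
    pair_tirs,
    scan_motif,
)
from .templates import TIR_CONSENSUS, ElementTemplate, default_templates, reference_proteins

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All tunable parameters of one run; round-trips through YAML."""

    # mining
    motif: str = TIR_CONSENSUS
    max_mismatch: int = 2
    max_span: int = 30_000
    min_span: int = 50
    tsd_len: int = 3
    min_ir_match: int = 12
    use_subterminals: bool = True
    subterminal_max_mismatch: int = 6
    # coding detection / classification
    min_identity: float = 30.0
    min_coverage: float = 50.0
    mite_max_len: int = 800
    # family rule
    family_min_identity: float = 80.0
    family_min_coverage: float = 80.0
    family_min_aligned: int = 80
    family_level: str = "dna"
    family_linkage: str = "single"
    # display
    display_site: str = "CTAG"
    display_cut_offset: int = 1
    display_window: tuple[int, int] = (50, 700)
    display_adapter_len: int = 20
    display_nn: tuple[str, ...] = DEFAULT_NN
    display_primer_mismatch: int = 0
    # run
    seed: int = 0
    genome_fasta: str | None = None
    genes_gff3: str | None = None
    variant_fasta: str | None = None
    outdir: str = "pifminer_out"

    def __post_init__(self) -> None:
        if self.max_mismatch < 0 or self.subterminal_max_mismatch < 0:
            raise ValueError("mismatch budgets must be non-negative")
        if not 0 < self.min_span <= self.max_span:
            raise ValueError("need 0 < min_span <= max_span")
        if self.tsd_len < 1:
            raise ValueError("tsd_len must be positive")
        IUPACMotif(self.motif)  # validates the alphabet
        self.display_window = tuple(self.display_window)  # type: ignore[assignment]
        self.display_nn = tuple(self.display_nn)  # type: ignore[assignment]

    def to_yaml(self, path: str | None = None) -> str:
        text = yaml.safe_dump(
            {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(self).items()},
            sort_keys=True,
        )
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str) -> "PipelineConfig":
        data = yaml.safe_load(open(source).read() if os.path.exists(source) else source)
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    tir_hits: list[TIRHit]
    candidates: list["AssembledCandidate"]
    annotations: list[ElementAnnotation]
    families: dict[str, str]
    insertion_calls: list
    insertion_summary: dict
    profiles: list[DisplayProfile]
    differential_bands: list
    class_summary: pd.DataFrame
    paths: dict[str, str] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


@dataclass(frozen=True)
class AssembledCandidate:
    element_id: str
    scaffold_id: str
    start: int
    end: int
    has_left_tir: bool
    has_right_tir: bool
    family_hint: str | None
    tsd_left: str
    tsd_right: str
    tsd_valid: bool


def _pair_adjacent(
    left_hits: list[TIRHit], right_hits: list[TIRHit], max_span: int
) -> list[tuple[TIRHit, TIRHit]]:
    """Greedy left-to-right pairing of a 5' mark with its nearest 3' mark."""
    pairs = []
    right_sorted = sorted(right_hits, key=lambda h: h.start)
    used: set[int] = set()
    for lh in sorted(left_hits, key=lambda h: h.start):
        best = None
        for i, rh in enumerate(right_sorted):
            if i in used or rh.start < lh.end:
                continue
            if rh.end - lh.start > max_span:
                break
            best = i
            break
        if best is not None:
            used.add(best)
            pairs.append((lh, right_sorted[best]))
    return pairs


def assemble_candidates(
    genome: Mapping[str, str],
    tir_hits: Sequence[TIRHit],
    config: PipelineConfig,
    templates: Mapping[str, ElementTemplate] | None = None,
) -> list[AssembledCandidate]:
    """Candidate element intervals from sub-terminal pairing plus TIR pairing.

    Sub-terminal 5'/3' hits of each family are paired per strand into core
    intervals; a TIR hit abutting a core edge extends the boundary by the
    TIR and sets the corresponding presence flag. Two-TIR candidates found
    only by plain TIR pairing are appended, so discovery degrades gracefully
    when sub-terminal references are ablated or absent.
    """
    scaffolds = as_scaffolds(genome)
    templates = default_templates() if templates is None else templates
    tir_len = len(config.motif)
    fwd_tir_by_end = {(h.scaffold_id, h.end) for h in tir_hits if h.orientation == "forward"}
    rev_tir_by_start = {(h.scaffold_id, h.start) for h in tir_hits if h.orientation == "revcomp"}

    raw: list[tuple[str, int, int, bool, bool, str | None]] = []
    if config.use_subterminals:
        for family, tmpl in sorted(templates.items()):
            st5 = scan_motif(genome, tmpl.subterminal_5prime, config.subterminal_max_mismatch)
            st3 = scan_motif(genome, tmpl.subterminal_3prime, config.subterminal_max_mismatch)
            for scaffold in scaffolds:
                f5 = [h for h in st5 if h.scaffold_id == scaffold and h.orientation == "forward"]
                f3 = [h for h in st3 if h.scaffold_id == scaffold and h.orientation == "forward"]
                r5 = [h for h in st5 if h.scaffold_id == scaffold and h.orientation == "revcomp"]
                r3 = [h for h in st3 if h.scaffold_id == scaffold and h.orientation == "revcomp"]
                # plus strand: ST5 ... ST3 ; minus strand: rc(ST3) ... rc(ST5)
                cores = _pair_adjacent(f5, f3, config.max_span)
                cores += _pair_adjacent(r3, r5, config.max_span)
                for lh, rh in cores:
                    start, end = lh.start, rh.end
                    has_left = (scaffold, start) in fwd_tir_by_end
                    has_right = (scaffold, end) in rev_tir_by_start
                    if has_left:
                        start -= tir_len
                    if has_right:
                        end += tir_len
                    raw.append((scaffold, start, end, has_left, has_right, family))

    # plain TIR pairing catches two-TIR elements lacking sub-terminal evidence
    for cand in pair_tirs(genome, tir_hits, config.max_span, config.min_span, config.tsd_len):
        if not any(
            s == cand.scaffold_id and cand.start < e2 and cand.end > s2
            for s, s2, e2, *_ in raw
        ):
            raw.append((cand.scaffold_id, cand.start, cand.end, True, True, None))

    raw.sort(key=lambda r: (r[0], r[1]))
    out = []
    for i, (scaffold, start, end, has_left, has_right, family) in enumerate(raw, 1):
        tl, tr, valid = extract_tsd(scaffolds[scaffold], start, end, config.tsd_len)
        out.append(
            AssembledCandidate(
                element_id=f"P{i:04d}",
                scaffold_id=scaffold,
                start=start,
                end=end,
                has_left_tir=has_left,
                has_right_tir=has_right,
                family_hint=family,
                tsd_left=tl,
                tsd_right=tr,
                tsd_valid=valid,
            )
        )
    return out


def candidates_from_pairing(
    paired: Sequence[CandidateElement],
) -> list[AssembledCandidate]:
    """Adapt plain pair_tirs output to the classification stage."""
    return [
        AssembledCandidate(
            element_id=f"P{i:04d}",
            scaffold_id=c.scaffold_id,
            start=c.start,
            end=c.end,
            has_left_tir=True,
            has_right_tir=True,
            family_hint=None,
            tsd_left=c.tsd_left,
            tsd_right=c.tsd_right,
            tsd_valid=c.tsd_valid,
        )
        for i, c in enumerate(paired, 1)
    ]


def classify_candidates(
    genome: Mapping[str, str],
    candidates: Sequence[AssembledCandidate],
    config: PipelineConfig,
    references: Mapping[str, str] | None = None,
) -> list[ElementAnnotation]:
    scaffolds = as_scaffolds(genome)
    references = reference_proteins() if references is None else references
    annotations = []
    for cand in candidates:
        seq = scaffolds[cand.scaffold_id][cand.start : cand.end]
        evidence = detect_coding(
            seq, references, config.min_identity, config.min_coverage,
            element_id=cand.element_id,
        )
        flags = coding_presence(evidence)
        annotations.append(
            classify(
                cand.element_id,
                cand.scaffold_id,
                cand.start,
                cand.end,
                has_left_tir=cand.has_left_tir,
                has_right_tir=cand.has_right_tir,
                mite_max_len=config.mite_max_len,
                family=cand.family_hint,
                tsd=cand.tsd_left if cand.tsd_valid else None,
                tsd_valid=cand.tsd_valid,
                **flags,
            )
        )
    return annotations


def _family_stage(genome, annotations, config):
    autonomous = [a for a in annotations if a.class_name == "AUTONOMOUS"]
    if len(autonomous) < 2:
        return {a.element_id: a.family or "A" for a in autonomous}, annotations
    scaffolds = as_scaffolds(genome)
    seqs = {
        a.element_id: scaffolds[a.scaffold_id][a.start : a.end] for a in autonomous
    }
    fa = cluster_families(
        seqs,
        config.family_min_identity,
        config.family_min_coverage,
        config.family_min_aligned,
        level=config.family_level,
        linkage=config.family_linkage,
    )
    # relabel clusters by the majority sub-terminal family hint, if any
    label_map: dict[str, str] = {}
    for label in sorted(set(fa.assignments.values())):
        hints = [
            a.family for a in autonomous
            if fa.assignments[a.element_id] == label and a.family
        ]
        label_map[label] = max(set(hints), key=hints.count) if hints else label
    assignments = {eid: label_map[lab] for eid, lab in fa.assignments.items()}
    updated = []
    for a in annotations:
        if a.element_id in assignments:
            a = ElementAnnotation(
                **{**asdict(a), "family": assignments[a.element_id]}
            )
        updated.append(a)
    return assignments, updated


def _display_stage(config, genome, variant, templates):
    profiles, diffs = [], []
    kw = dict(
        nn_set=config.display_nn,
        window=config.display_window,
        adapter_len=config.display_adapter_len,
        site=config.display_site,
        cut_offset=config.display_cut_offset,
        primer_mismatch=config.display_primer_mismatch,
    )
    from .sequences import revcomp as _rc

    for family, tmpl in sorted(templates.items()):
        sample_profiles = []
        for sample_id, g in (("base", genome), ("variant", variant)):
            right = simulate_display(
                g, tmpl.subterminal_3prime, sample_id, family, **kw
            )
            left = simulate_display(
                g, _rc(tmpl.subterminal_5prime), sample_id, family, **kw
            )
            sample_profiles.append(merge_profiles(right, left))
        profiles.extend(sample_profiles)
        diffs.extend(diff_profiles(sample_profiles))
    return profiles, diffs


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage on the configured inputs and write the report bundle."""
    if not config.genome_fasta:
        raise PipelineError("input", "genome_fasta is required")
    try:
        genome = read_fasta(config.genome_fasta)
    except OSError as exc:
        raise PipelineError("input", str(exc)) from exc
    os.makedirs(config.outdir, exist_ok=True)
    templates = default_templates()

    tir_hits = scan_motif(genome, config.motif, config.max_mismatch)
    logger.info("scan: %d TIR hits", len(tir_hits))

    candidates = assemble_candidates(genome, tir_hits, config, templates)
    logger.info("assemble: %d candidate elements", len(candidates))

    annotations = classify_candidates(genome, candidates, config)
    counts = pd.Series([a.class_name for a in annotations]).value_counts()
    logger.info("classify: %s", counts.to_dict())

    families, annotations = _family_stage(genome, annotations, config)

    insertion_calls, insertion_summary = [], {}
    if config.genes_gff3:
        genes = read_gff3_genes(config.genes_gff3)
        insertion_calls = annotate_insertions(
            [(a.element_id, a.scaffold_id, a.start, a.end) for a in annotations],
            genes,
        )
        insertion_summary = summarize_insertions(insertion_calls)
        logger.info("annotate: %s", insertion_summary)

    profiles, diffs = [], []
    if config.variant_fasta:
        variant = read_fasta(config.variant_fasta)
        profiles, diffs = _display_stage(config, genome, variant, templates)
        logger.info("display: %d differential bands", len(diffs))

    hist = length_histogram(annotations) if annotations else pd.DataFrame()
    class_summary = hist.copy()
    if not class_summary.empty:
        class_summary.insert(0, "count", pd.Series(counts))
        class_summary = class_summary.fillna(0).astype(int)

    paths = _write_outputs(
        config, annotations, families, insertion_calls, insertion_summary,
        profiles, diffs, class_summary,
    )
    manifest = {
        "pifminer_version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "n_tir_hits": len(tir_hits),
        "n_candidates": len(candidates),
        "class_counts": {k: int(v) for k, v in counts.items()},
        "outputs": paths,
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = os.path.join(config.outdir, "manifest.json")

    return PipelineResult(
        config=config,
        tir_hits=tir_hits,
        candidates=candidates,
        annotations=annotations,
        families=families,
        insertion_calls=insertion_calls,
        insertion_summary=insertion_summary,
        profiles=profiles,
        differential_bands=diffs,
        class_summary=class_summary,
        paths=paths,
        manifest=manifest,
    )


def _write_outputs(config, annotations, families, calls, summary, profiles,
                   diffs, class_summary) -> dict[str, str]:
    out = config.outdir
    paths = {"elements_gff3": os.path.join(out, "elements.gff3")}
    write_elements_gff3(annotations, paths["elements_gff3"])
    paths["class_summary"] = os.path.join(out, "class_summary.tsv")
    class_summary.to_csv(paths["class_summary"], sep="\t")
    paths["families"] = os.path.join(out, "families.tsv")
    pd.DataFrame(
        sorted(families.items()), columns=["element_id", "family"]
    ).to_csv(paths["families"], sep="\t", index=False)
    if calls:
        paths["insertions"] = os.path.join(out, "insertions.tsv")
        pd.DataFrame([c.__dict__ for c in calls]).to_csv(
            paths["insertions"], sep="\t", index=False
        )
        paths["insertion_summary"] = os.path.join(out, "insertion_summary.json")
        with open(paths["insertion_summary"], "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    if profiles:
        paths["display_profiles"] = os.path.join(out, "display_profiles.tsv")
        rows = [
            {"sample": p.sample_id, "family": p.family_primer, "NN": nn, "length": ln}
            for p in profiles
            for nn, lengths in sorted(p.bands.items())
            for ln in lengths
        ]
        pd.DataFrame(rows, columns=["sample", "family", "NN", "length"]).to_csv(
            paths["display_profiles"], sep="\t", index=False
        )
        paths["differential_bands"] = os.path.join(out, "differential_bands.tsv")
        pd.DataFrame(
            [
                {
                    "family": d.family_primer,
                    "NN": d.nn,
                    "length": d.length,
                    "presence": "".join("1" if x else "0" for x in d.presence),
                }
                for d in diffs
            ],
            columns=["family", "NN", "length", "presence"],
        ).to_csv(paths["differential_bands"], sep="\t", index=False)
    return paths


def evaluate_against_truth(
    calls: Sequence,
    truth: Sequence,
    boundary_tolerance: int = 2,
) -> dict[str, float]:
    """Recall/precision of calls against planted truth, plus class accuracy.

    An element is recovered when both boundaries match a truth row within
    ``boundary_tolerance`` bases (one-to-one). Class accuracy is computed
    over recovered elements. Items may be ElementAnnotation / PlantedTruth
    objects or any objects exposing scaffold, start, end and a class label.
    Raises on an apparent coordinate-convention mismatch (a uniform ±1 shift
    recovering most calls while the raw comparison recovers none).
    """

    def _norm(x):
        scaffold = getattr(x, "scaffold_id", None) or getattr(x, "scaffold")
        cls = getattr(x, "class_name", None) or getattr(x, "class_", None)
        return scaffold, int(x.start), int(x.end), cls

    calls_n = [_norm(c) for c in calls]
    truth_n = [_norm(t) for t in truth]

    def _match(shift: int) -> list[tuple[int, int]]:
        matched = []
        used: set[int] = set()
        for ci, (cs, c0, c1, _) in enumerate(calls_n):
            best = None
            for ti, (ts, t0, t1, _) in enumerate(truth_n):
                if ti in used or ts != cs:
                    continue
                if (
                    abs(c0 + shift - t0) <= boundary_tolerance
                    and abs(c1 + shift - t1) <= boundary_tolerance
                ):
                    d = abs(c0 + shift - t0) + abs(c1 + shift - t1)
                    if best is None or d < best[0]:
                        best = (d, ti)
            if best is not None:
                used.add(best[1])
                matched.append((ci, best[1]))
        return matched

    matched = _match(0)
    if not matched and calls_n and truth_n:
        for shift in (-1, 1):
            if len(_match(shift)) >= 0.5 * min(len(calls_n), len(truth_n)):
                raise ValueError(
                    "coordinate convention mismatch: calls match truth only "
                    f"after a uniform shift of {shift} (1-based vs 0-based?)"
                )
    recall = len(matched) / len(truth_n) if truth_n else 1.0
    precision = len(matched) / len(calls_n) if calls_n else 1.0
    correct = sum(1 for ci, ti in matched if calls_n[ci][3] == truth_n[ti][3])
    class_accuracy = correct / len(matched) if matched else 0.0
    return {
        "recall": recall,
        "precision": precision,
        "class_accuracy": class_accuracy,
        "n_recovered": float(len(matched)),
    }
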