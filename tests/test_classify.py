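"""Coding-evidence detection and structural classification."""

import numpy as np
import pandas as pd
import pytest

from pifminer.classify import (
    classify,
    coding_presence,
    detect_coding,
    length_histogram,
)
from pifminer.families import pairwise_identity
from pifminer.sequences import random_dna, revcomp
from pifminer.templates import back_translate, default_templates, reference_proteins


class TestDetectCoding:
    def test_exact_embedded_tpase_gives_full_identity_and_coverage(self, templates):
        t = templates["A"]
        elem = "ACGT" * 25 + t.tpase_cds + "TTGCA" * 20
        refs = {"TPASE_A": t.tpase_protein}
        ev = detect_coding(elem, refs)
        assert ev, "embedded CDS must be detected"
        best = ev[0]
        assert best.identity == pytest.approx(100.0)
        assert best.coverage == pytest.approx(100.0)
        assert coding_presence(ev) == {"has_orf1": False, "has_tpase": True}

    def test_reverse_strand_cds_detected_in_negative_frame(self, templates):
        t = templates["A"]
        elem = revcomp("ACGT" * 25 + t.orf1_cds + "TTGCA" * 20)
        ev = detect_coding(elem, {"ORF1_A": t.orf1_protein})
        assert ev and ev[0].frame < 0
        assert ev[0].identity == pytest.approx(100.0)

    def test_random_noncoding_sequence_has_no_evidence(self):
        seq = random_dna(3000, 0.4, np.random.default_rng(13))
        assert detect_coding(seq, reference_proteins()) == []

    def test_sub_codon_element_yields_empty_evidence(self):
        assert detect_coding("AC", reference_proteins()) == []

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            detect_coding("ACGTACGT", {})

    def test_mutated_orf1_identity_tracks_direct_protein_alignment(self, templates):
        # mutate 10% of ORF1 codons to random sense codons, then compare the
        # detected identity with a direct alignment of the realized protein
        t = templates["A"]
        rng = np.random.default_rng(7)
        codons = [t.orf1_cds[i : i + 3] for i in range(0, len(t.orf1_cds) - 3, 3)]
        sense = sorted(
            {back_translate(aa)[:3] for aa in "ACDEFGHIKLMNPQRSTVWY"}
        )
        n_mut = len(codons) // 10
        for i in rng.choice(len(codons), size=n_mut, replace=False):
            codons[i] = sense[rng.integers(0, len(sense))]
        mut_cds = "".join(codons) + "TAA"
        from Bio.Seq import Seq

        realized = str(Seq("".join(codons)).translate())
        direct = pairwise_identity(realized, t.orf1_protein, "protein_orf1").identity
        elem = "GGTTC" * 30 + mut_cds + "CCAAT" * 30
        ev = detect_coding(elem, {"ORF1_A": t.orf1_protein})
        assert ev
        assert abs(ev[0].identity - direct) <= 10.0

    def test_raising_min_identity_never_adds_evidence(self, templates):
        t = templates["A"]
        rng = np.random.default_rng(3)
        from pifminer.sequences import mutate

        elem = mutate("AC" * 60 + t.tpase_cds + "GT" * 60, 0.05, rng)
        refs = {"TPASE_A": t.tpase_protein}
        n = [len(detect_coding(elem, refs, min_identity=mi)) for mi in (30, 60, 90, 99)]
        assert n == sorted(n, reverse=True)


class TestClassify:
    @pytest.mark.parametrize(
        "flags,length,expected",
        [
            ((True, True, True, True), 5053, "AUTONOMOUS"),
            ((True, True, False, True), 4234, "DEF_NO_ORF1"),
            ((True, True, True, False), 3769, "DEF_NO_TPASE"),
            ((True, True, False, False), 250, "MITE_LIKE"),
            ((True, True, False, False), 1500, "DEF_NO_CODING"),
            ((True, False, True, True), 5034, "DEF_ONE_TIR"),
            ((False, True, False, True), 4215, "DEF_ONE_TIR"),
            ((False, False, True, True), 5015, "DEF_NO_TIR_FRAGMENT"),
        ],
    )
    def test_rule_table(self, flags, length, expected):
        left, right, orf1, tpase = flags
        ann = classify(
            "E1", "s", 0, length,
            has_left_tir=left, has_right_tir=right,
            has_orf1=orf1, has_tpase=tpase,
        )
        assert ann.class_name == expected
        assert ann.length == length

    def test_mite_threshold_boundary(self):
        at = classify("E1", "s", 0, 800, has_left_tir=True, has_right_tir=True,
                      has_orf1=False, has_tpase=False)
        above = classify("E2", "s", 0, 801, has_left_tir=True, has_right_tir=True,
                         has_orf1=False, has_tpase=False)
        assert at.class_name == "MITE_LIKE"
        assert above.class_name == "DEF_NO_CODING"

    def test_confusion_matrix_is_diagonal_on_divergent_copies(self, small_dataset):
        """Classified classes equal planted classes at 2% divergence."""
        from pifminer.pipeline import (
            PipelineConfig,
            assemble_candidates,
            classify_candidates,
        )
        from pifminer.mining import scan_motif

        config = PipelineConfig(genome_fasta="unused")
        genome = small_dataset.genome
        hits = scan_motif(genome, config.motif, config.max_mismatch)
        candidates = assemble_candidates(genome, hits, config)
        annotations = classify_candidates(genome, candidates, config)
        truth_by_start = {t.start: t.class_name for t in small_dataset.truth}
        matched = 0
        for a in annotations:
            if a.start in truth_by_start:
                assert truth_by_start[a.start] == a.class_name
                matched += 1
        assert matched >= 0.9 * len(small_dataset.truth)


class TestLengthHistogram:
    def test_published_element_falls_in_5_to_6_kb_bin(self):
        ann = classify("E1", "s", 0, 5053, has_left_tir=True, has_right_tir=True,
                       has_orf1=True, has_tpase=True)
        hist = length_histogram([ann])
        assert hist.loc["AUTONOMOUS", 5000] == 1

    def test_empty_input_gives_empty_frame(self):
        assert length_histogram([]).empty

    def test_mite_cohort_mass_in_first_kb_and_fine_bins(self, rng):
        anns = [
            classify(f"E{i}", "s", 0, int(rng.integers(200, 301)),
                     has_left_tir=True, has_right_tir=True,
                     has_orf1=False, has_tpase=False)
            for i in range(40)
        ]
        coarse = length_histogram(anns, 1000)
        assert coarse.loc["MITE_LIKE", 0] == 40
        fine = length_histogram(anns, 100)
        assert set(fine.columns) <= {200, 300}
        assert fine.loc["MITE_LIKE"].sum() == 40

    def test_counts_sum_to_class_totals(self, rng):
        anns = [
            classify(f"E{i}", "s", 0, int(rng.integers(100, 9000)),
                     has_left_tir=True, has_right_tir=True,
                     has_orf1=bool(i % 2), has_tpase=True)
            for i in range(30)
        ]
        hist = length_histogram(anns)
        totals = pd.Series([a.class_name for a in anns]).value_counts()
        for cls in totals.index:
            assert hist.loc[cls].sum() == totals[cls]
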