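"""TIR motif scanning, inverted-repeat discovery, pairing and TSD checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pifminer.mining import (
    IUPACMotif,
    discover_inverted_repeats,
    extract_tsd,
    pair_tirs,
    scan_motif,
)
from pifminer.sequences import random_dna, revcomp
from pifminer.templates import TIR, TIR_CONSENSUS

from .oracles import brute_inverted_repeats, brute_scan

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)


class TestScanMotif:
    def test_consensus_match_with_y_resolved_c(self):
        seq = "TTTTT" + "GGGCCCGTTTGGGGCAGCT" + "AAAAA"
        hits = scan_motif(seq, TIR_CONSENSUS, 0)
        fwd = [h for h in hits if h.orientation == "forward"]
        assert len(fwd) == 1
        assert fwd[0].end - fwd[0].start == 19
        assert fwd[0].mismatches == 0

    def test_poly_a_has_no_hits(self):
        assert scan_motif("A" * 500, TIR_CONSENSUS, 0) == []

    def test_invalid_motif_character_rejected(self):
        with pytest.raises(ValueError):
            scan_motif("ACGT" * 10, "ACGX", 0)

    def test_negative_mismatch_budget_rejected(self):
        with pytest.raises(ValueError):
            scan_motif("ACGT" * 10, "ACGT", -1)

    def test_n_bases_never_match(self):
        seq = TIR[:-1] + "N"
        assert scan_motif(seq, TIR_CONSENSUS, 0) == []
        assert len([h for h in scan_motif(seq, TIR_CONSENSUS, 1)
                    if h.orientation == "forward"]) == 1

    def test_matches_exhaustive_scan_on_random_sequence(self):
        seq = random_dna(10_000, 0.4, np.random.default_rng(11))
        # plant a few degraded copies so the comparison is not vacuous
        seq = seq[:100] + TIR + seq[119:4000] + "GGGTCTGTTTGGGGCAGCT" \
            + seq[4019:7000] + revcomp(TIR) + seq[7019:]
        hits = scan_motif(seq, TIR_CONSENSUS, 2)
        got = sorted((h.start, h.end, h.orientation, h.mismatches) for h in hits)
        assert got == brute_scan(seq, TIR_CONSENSUS, 2)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(dna)
    def test_reverse_complement_symmetry(self, seq):
        n = len(seq)
        fwd = scan_motif(seq, "GGYCT", 1)
        mirror = scan_motif(revcomp(seq), "GGYCT", 1)
        flipped = sorted(
            (n - h.end, n - h.start,
             "forward" if h.orientation == "revcomp" else "revcomp",
             h.mismatches)
            for h in mirror
        )
        assert flipped == sorted(
            (h.start, h.end, h.orientation, h.mismatches) for h in fwd
        )


class TestInvertedRepeats:
    def test_planted_ir_recovered_at_exact_coordinates(self, rng):
        arm = "GATTACAGATTACAGATTA"  # 19 bases
        region = (
            random_dna(500, 0.5, rng) + arm + random_dna(1000, 0.5, rng)
            + revcomp(arm) + random_dna(500, 0.5, rng)
        )
        pairs = discover_inverted_repeats(region, min_match=19, max_span=5000)
        assert ((500, 519), (1519, 1538)) in pairs

    def test_region_shorter_than_twice_min_match_is_empty(self):
        assert discover_inverted_repeats("ACGTACGTACGTACG", 12, 1000) == []

    def test_min_match_below_four_rejected(self):
        with pytest.raises(ValueError):
            discover_inverted_repeats("ACGT" * 100, 3, 1000)

    @pytest.mark.parametrize("seed,length", [(11, 800), (23, 1500)])
    def test_matches_exhaustive_diagonal_enumeration(self, seed, length):
        rng = np.random.default_rng(seed)
        region = random_dna(length, 0.5, rng)
        arm = random_dna(14, 0.5, rng)
        region = region[:100] + arm + region[114:600] + revcomp(arm) + region[614:]
        got = discover_inverted_repeats(region, min_match=8, max_span=len(region))
        assert got == brute_inverted_repeats(region, 8, len(region))


class TestExtractTsd:
    def test_planted_tta_duplication_is_valid(self):
        seq = "CCCCTTA" + "GGGG" + "TTACCCC"
        assert extract_tsd(seq, 7, 11) == ("TTA", "TTA", True)

    def test_disagreeing_flanks_are_invalid(self):
        seq = "CCCCTTA" + "GGGG" + "GGCCCCC"
        left, right, valid = extract_tsd(seq, 7, 11)
        assert (left, right, valid) == ("TTA", "GGC", False)

    def test_scaffold_edge_gives_sentinel(self):
        assert extract_tsd("ACGTACGT", 1, 5) == ("NNN", "NNN", False)
        assert extract_tsd("ACGTACGT", 4, 7) == ("NNN", "NNN", False)


class TestPairTirs:
    def _genome_with(self, gap: int, rng, tsd: str = "TTA"):
        left = random_dna(200, 0.5, rng)
        interior = random_dna(gap, 0.5, rng)
        right = random_dna(200, 0.5, rng)
        return left + tsd + TIR + interior + revcomp(TIR) + tsd + right

    def test_span_beyond_30kb_is_not_paired(self, rng):
        genome = self._genome_with(35_000, rng)
        hits = scan_motif(genome, TIR_CONSENSUS, 0)
        assert pair_tirs(genome, hits) == []

    def test_span_of_5kb_is_paired(self, rng):
        genome = self._genome_with(5_000, rng)
        hits = scan_motif(genome, TIR_CONSENSUS, 0)
        elements = pair_tirs(genome, hits)
        assert len(elements) == 1
        assert elements[0].tsd_valid and elements[0].tsd_left == "TTA"
        assert elements[0].span == 5_000 + 38

    def test_single_hit_yields_no_pair(self, rng):
        genome = random_dna(300, 0.5, rng) + TIR + random_dna(300, 0.5, rng)
        hits = scan_motif(genome, TIR_CONSENSUS, 0)
        assert pair_tirs(genome, hits) == []

    def test_tsd_valid_candidate_preferred_over_nearer_invalid(self, rng):
        # forward TIR at 203; rc candidates at ~700 (no TSD) and ~1000 (TTA TSD)
        left = random_dna(200, 0.5, rng)
        genome = (
            left + "TTA" + TIR + random_dna(478, 0.5, rng) + revcomp(TIR)
            + "GGG" + random_dna(297, 0.5, rng) + revcomp(TIR) + "TTA"
            + random_dna(200, 0.5, rng)
        )
        hits = scan_motif(genome, TIR_CONSENSUS, 0)
        elements = pair_tirs(genome, hits)
        assert len(elements) == 1
        assert elements[0].tsd_valid
        assert genome[elements[0].end : elements[0].end + 3] == "TTA"

    def test_clean_synthetic_candidates_coincide_with_planted_truth(self):
        from pifminer.synthetic import SyntheticSpec, generate_dataset

        spec = SyntheticSpec(
            genome_length=400_000,
            seed=5,
            mutation_rate=0.0,
            class_counts={
                "AUTONOMOUS": 3, "DEF_NO_ORF1": 2, "DEF_NO_TPASE": 2,
                "DEF_NO_CODING": 3, "MITE_LIKE": 6,
            },
            n_genes=0,
            variant_extra_insertions=0,
        )
        ds = generate_dataset(spec)
        genome = ds.genome
        hits = scan_motif(genome, TIR_CONSENSUS, 0)
        elements = pair_tirs(genome, hits)
        assert {(e.start, e.end) for e in elements} == {
            (t.start, t.end) for t in ds.truth
        }
        assert all(e.tsd_valid and e.tsd_left == "TTA" for e in elements)


def test_motif_length_and_validation():
    m = IUPACMotif(TIR_CONSENSUS)
    assert m.length == 19
    assert m.reverse_complement().pattern == revcomp(TIR_CONSENSUS)
    with pytest.raises(ValueError):
        IUPACMotif("")
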