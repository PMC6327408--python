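"""Restriction digest and in-silico transposon display."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pifminer.display import (
    ALL_NN,
    diff_profiles,
    digest,
    merge_profiles,
    simulate_display,
)
from pifminer.sequences import random_dna, revcomp

from .oracles import brute_digest_boundaries

dna = st.text(alphabet="ACGT", min_size=1, max_size=500)


class TestDigest:
    def test_bfai_cut_rule(self):
        frags = digest("AACTAGAA")
        assert [f.sequence for f in frags] == ["AAC", "TAGAA"]

    def test_site_free_sequence_is_one_fragment(self):
        frags = digest("AAAACCCCGGGG")
        assert len(frags) == 1
        assert frags[0].sequence == "AAAACCCCGGGG"

    def test_degenerate_site_rejected(self):
        with pytest.raises(ValueError):
            digest("ACGT", site="CTNG")

    def test_boundaries_match_string_search_on_random_sequence(self):
        seq = random_dna(100_000, 0.5, np.random.default_rng(17))
        frags = digest(seq)
        bounds = [0] + [f.end for f in frags]
        assert bounds == brute_digest_boundaries(seq, "CTAG", 1)
        assert sum(f.end - f.start for f in frags) == len(seq)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(dna)
    def test_fragments_reconstruct_input(self, seq):
        assert "".join(f.sequence for f in digest(seq)) == seq


def _construct(primer: str, gap_to_cut: int, rng) -> str:
    """Genome with one primer site and the nearest cut exactly gap_to_cut
    downstream of the primer 3' end (no CTAG elsewhere)."""
    def ctag_free(n):
        while True:
            s = random_dna(n, 0.5, rng)
            if "CTAG" not in s and "CTAG" not in (s[-3:] + primer) \
               and "CTAG" not in (primer + s[:3]):
                return s

    left = ctag_free(300)
    mid = ctag_free(gap_to_cut - 1)  # C of CTAG sits gap-1 after primer end
    right = ctag_free(300)
    genome = left + primer + mid + "CTAG" + right
    assert genome.count("CTAG") == 1
    return genome


class TestSimulateDisplay:
    def test_band_length_is_primer_plus_gap_plus_adapter(self, rng):
        primer = random_dna(19, 0.5, rng)
        genome = _construct(primer, 180, rng)
        profile = simulate_display(
            genome, primer, nn_set=ALL_NN, adapter_len=20, window=(50, 700)
        )
        bands = profile.band_set()
        assert len(bands) == 1
        (nn, length), = bands
        assert length == 180 + len(primer) + 20
        # NN: two bases interior to the cut, primer-bearing strand
        c = genome.find("CTAG") + 1
        assert nn == genome[c - 2 : c]

    def test_no_downstream_cut_site_gives_no_band(self, rng):
        # the only cut lies upstream of the forward primer hit, so the
        # rightward amplicon runs off the scaffold and no band is produced
        primer = random_dna(19, 0.5, rng)

        def ctag_free(n):
            while True:
                s = random_dna(n, 0.5, rng)
                if "CTAG" not in (s + primer) and "CTAG" not in (primer + s):
                    return s

        genome = ctag_free(300) + "CTAG" + ctag_free(100) + primer + ctag_free(300)
        profile = simulate_display(genome, primer, nn_set=ALL_NN)
        assert profile.band_set() == set()

    def test_absent_primer_gives_empty_profile(self, rng, caplog):
        genome = random_dna(2_000, 0.5, rng)
        primer = "G" * 25
        with caplog.at_level("WARNING"):
            profile = simulate_display(genome, primer)
        assert profile.bands == {}
        assert any("not found" in r.message for r in caplog.records)

    def test_each_amplicon_in_exactly_one_nn_bin(self, rng):
        primer = random_dna(19, 0.5, rng)
        genome = random_dna(50_000, 0.5, rng)
        # plant several primer copies
        for pos in (5_000, 15_000, 30_000, 44_000):
            genome = genome[:pos] + primer + genome[pos + len(primer):]
        full = simulate_display(genome, primer, nn_set=ALL_NN, window=(1, 10**9))
        # running one NN at a time partitions the unbinned amplicon set
        per_bin = {
            nn: simulate_display(genome, primer, nn_set=(nn,), window=(1, 10**9))
            for nn in ALL_NN
        }
        union = {}
        for nn, p in per_bin.items():
            for key, lengths in p.bands.items():
                assert key == nn  # an amplicon never lands in a foreign bin
                union.setdefault(nn, []).extend(lengths)
        assert {k: sorted(v) for k, v in union.items()} == full.bands
        assert sum(len(v) for v in full.bands.values()) >= 4


class TestDiffProfiles:
    def test_identical_genomes_diff_empty(self, rng):
        genome = random_dna(20_000, 0.5, rng)
        primer = genome[8_000:8_019]
        p1 = simulate_display(genome, primer, "s1", nn_set=ALL_NN)
        p2 = simulate_display(genome, primer, "s2", nn_set=ALL_NN)
        assert diff_profiles([p1, p2]) == []

    def test_lost_insertion_pattern_present_absent_present(self, rng):
        """A band seen in samples 1 and 3 but lost from sample 2."""
        primer = random_dna(19, 0.5, rng)
        base = _construct(primer, 150, rng)
        deleted = base.replace(primer, random_dna(19, 0.5, rng))
        profiles = [
            simulate_display(g, primer, s, nn_set=ALL_NN)
            for s, g in (("wt", base), ("m2", deleted), ("m1", base))
        ]
        diffs = diff_profiles(profiles)
        assert len(diffs) == 1
        assert diffs[0].presence == (True, False, True)
        assert diffs[0].length == 150 + 19 + 20

    def test_mixed_family_primers_rejected(self):
        from pifminer.display import DisplayProfile

        p1 = DisplayProfile("s1", "A", {})
        p2 = DisplayProfile("s2", "B", {})
        with pytest.raises(ValueError):
            diff_profiles([p1, p2])

    def test_single_profile_rejected(self):
        from pifminer.display import DisplayProfile

        with pytest.raises(ValueError):
            diff_profiles([DisplayProfile("s1", "A", {})])

    def test_tolerance_merges_nearby_lengths(self):
        from pifminer.display import DisplayProfile

        p1 = DisplayProfile("s1", "A", {"AA": [100]})
        p2 = DisplayProfile("s2", "A", {"AA": [102]})
        assert diff_profiles([p1, p2], tolerance=2) == []
        assert len(diff_profiles([p1, p2], tolerance=0)) == 2


def test_merge_profiles_pools_bands():
    from pifminer.display import DisplayProfile

    p1 = DisplayProfile("s", "A", {"AA": [100], "CT": [300]})
    p2 = DisplayProfile("s", "A", {"AA": [250]})
    merged = merge_profiles(p1, p2)
    assert merged.bands == {"AA": [100, 250], "CT": [300]}
    with pytest.raises(ValueError):
        merge_profiles(p1, DisplayProfile("other", "A", {}))
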