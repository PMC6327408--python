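"""In-silico transposon display (AFLP-style).

The assay is simulated at the level that fixes band positions: restriction
digest of the genome (BfaI, C^TAG), adapter ligation at every cut, and
amplification from a TE-specific sub-terminal primer outward to the nearest
cut site. Each amplicon is binned by the two genomic bases immediately
interior to the cut site — the +NN selective bases of the nested selective
primer, read on the primer-bearing strand — and falls in a gel window.
Differential bands between samples mark transposition events.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .mining import FORWARD, GenomeLike, IUPACMotif, as_scaffolds, scan_motif
from .sequences import revcomp

logger = logging.getLogger(__name__)

BFAI_SITE = "CTAG"
BFAI_CUT_OFFSET = 1  # C^TAG

#: The eight selective dinucleotides used on the published gels.
DEFAULT_NN = ("AA", "AT", "AC", "AG", "CA", "CT", "CC", "CG")
ALL_NN = tuple(a + b for a in "ACGT" for b in "ACGT")

DEFAULT_WINDOW = (50, 700)
DEFAULT_ADAPTER_LEN = 20


@dataclass(frozen=True)
class DigestFragment:
    scaffold: str
    start: int
    end: int
    sequence: str


@dataclass
class DisplayProfile:
    sample_id: str
    family_primer: str
    bands: dict[str, list[int]] = field(default_factory=dict)

    def band_set(self) -> set[tuple[str, int]]:
        return {(nn, ln) for nn, lns in self.bands.items() for ln in lns}


@dataclass(frozen=True)
class DifferentialBand:
    family_primer: str
    nn: str
    length: int
    presence: tuple[bool, ...]


def digest(
    genome: GenomeLike, site: str = BFAI_SITE, cut_offset: int = BFAI_CUT_OFFSET
) -> list[DigestFragment]:
    """Cut every occurrence of ``site``; fragments tile each scaffold.

    ``cut_offset`` is the cut position within the site (1 for BfaI's C^TAG).
    A site-free scaffold yields a single fragment spanning it.
    """
    site = site.upper()
    if not site or set(site) - set("ACGT"):
        raise ValueError("restriction site must be non-degenerate DNA")
    if not 0 <= cut_offset <= len(site):
        raise ValueError("cut_offset outside the site")
    fragments = []
    for scaffold, seq in as_scaffolds(genome).items():
        cuts = sorted(
            {i + cut_offset for i in _find_all(seq.upper(), site)
             if 0 < i + cut_offset < len(seq)}
        )
        bounds = [0] + cuts + [len(seq)]
        for s, e in zip(bounds, bounds[1:]):
            fragments.append(DigestFragment(scaffold, s, e, seq[s:e]))
    return fragments


def _find_all(seq: str, sub: str) -> list[int]:
    out, i = [], seq.find(sub)
    while i != -1:
        out.append(i)
        i = seq.find(sub, i + 1)
    return out


def cut_positions(seq: str, site: str = BFAI_SITE,
                  cut_offset: int = BFAI_CUT_OFFSET) -> list[int]:
    return sorted(
        {i + cut_offset for i in _find_all(seq.upper(), site.upper())
         if 0 < i + cut_offset < len(seq)}
    )


def simulate_display(
    genome: GenomeLike,
    primer: str,
    sample_id: str = "sample",
    family_primer: str = "A",
    nn_set: Sequence[str] = DEFAULT_NN,
    window: tuple[int, int] = DEFAULT_WINDOW,
    adapter_len: int = DEFAULT_ADAPTER_LEN,
    site: str = BFAI_SITE,
    cut_offset: int = BFAI_CUT_OFFSET,
    primer_mismatch: int = 0,
    elements: Iterable[tuple[int, int]] | None = None,
) -> DisplayProfile:
    """Amplicon lengths per selective NN for one TE-specific primer.

    Every primer annealing site (both orientations, ``primer_mismatch``
    substitutions allowed) yields one amplicon running from the primer
    outward to the nearest restriction cut site on that side; its length is
    primer-to-cut genomic span plus ``adapter_len``. The amplicon is binned
    by the two bases interior to the cut (primer-bearing strand) and kept if
    its length falls inside the gel ``window``. ``elements`` optionally
    restricts annealing sites to the given (start, end) intervals.
    """
    motif = IUPACMotif(primer)
    lo, hi = window
    profile = DisplayProfile(sample_id, family_primer, {})
    any_hit = False
    for scaffold, seq in as_scaffolds(genome).items():
        hits = scan_motif({scaffold: seq}, motif, primer_mismatch)
        if elements is not None:
            spans = sorted(elements)
            hits = [
                h for h in hits
                if any(h.start < e and h.end > s for s, e in spans)
            ]
        if not hits:
            continue
        any_hit = True
        cuts = cut_positions(seq, site, cut_offset)
        for h in hits:
            if h.orientation == FORWARD:
                i = bisect.bisect_left(cuts, h.end)
                if i == len(cuts):
                    continue  # runs off the scaffold: no band
                c = cuts[i]
                length = (c - h.start) + adapter_len
                nn = seq[c - 2 : c]
            else:
                i = bisect.bisect_right(cuts, h.start) - 1
                if i < 0:
                    continue
                c = cuts[i]
                length = (h.end - c) + adapter_len
                nn = revcomp(seq[c : c + 2])
            if nn in nn_set and lo <= length <= hi:
                profile.bands.setdefault(nn, []).append(length)
    if not any_hit:
        logger.warning("primer %s not found in sample %s", primer, sample_id)
    for lengths in profile.bands.values():
        lengths.sort()
    return profile


def merge_profiles(*profiles: DisplayProfile) -> DisplayProfile:
    """Pool bands of profiles from the same sample and family primer."""
    ids = {(p.sample_id, p.family_primer) for p in profiles}
    if len(ids) != 1:
        raise ValueError("profiles must share sample_id and family_primer")
    merged = DisplayProfile(*ids.pop(), {})
    for p in profiles:
        for nn, lengths in p.bands.items():
            merged.bands.setdefault(nn, []).extend(lengths)
    for lengths in merged.bands.values():
        lengths.sort()
    return merged


def diff_profiles(
    profiles: Sequence[DisplayProfile], tolerance: int = 0
) -> list[DifferentialBand]:
    """Bands present in some samples and absent in others.

    With ``tolerance`` > 0, lengths within that many bases (per NN) are
    treated as the same band (reported at the smallest length of the group).
    Identical profiles give an empty list.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to diff")
    fams = {p.family_primer for p in profiles}
    if len(fams) != 1:
        raise ValueError(f"mixed family primers: {sorted(fams)}")
    family = fams.pop()
    nns = sorted({nn for p in profiles for nn in p.bands})
    out: list[DifferentialBand] = []
    for nn in nns:
        all_lengths = sorted({ln for p in profiles for ln in p.bands.get(nn, [])})
        groups: list[list[int]] = []
        for ln in all_lengths:
            if groups and ln - groups[-1][-1] <= tolerance:
                groups[-1].append(ln)
            else:
                groups.append([ln])
        for group in groups:
            presence = tuple(
                any(ln in group for ln in p.bands.get(nn, [])) for p in profiles
            )
            if any(presence) and not all(presence):
                out.append(DifferentialBand(family, nn, group[0], presence))
    return out


def render_gel(
    profiles: Sequence[DisplayProfile], nn: str, width: int = 60
) -> str:
    """Text-art gel lane rendering of one NN across samples (for docs)."""
    lo = min((min(p.bands[nn]) for p in profiles if p.bands.get(nn)), default=0)
    hi = max((max(p.bands[nn]) for p in profiles if p.bands.get(nn)), default=1)
    span = max(hi - lo, 1)
    lines = [f"NN={nn}  ({lo}-{hi} bp)"]
    for p in profiles:
        lane = [" "] * width
        for ln in p.bands.get(nn, []):
            lane[min(int((ln - lo) / span * (width - 1)), width - 1)] = "|"
        lines.append(f"{p.sample_id:>10s} {''.join(lane)}")
    return "\n".join(lines)
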