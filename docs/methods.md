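# Methods

This note records the models, parameter choices and numerical conventions
behind `pifminer`, and what the synthetic benchmarks do and do not show.

## Element model

An intact autonomous PIF/Harbinger-like element is modelled as

```
[TIR 19] [sub-terminal 60] ... ORF1 (272 aa) ... TPase (427 aa) ... [sub-terminal 60] [rc TIR 19]
```

with the 3' TIR the reverse complement of the 5' TIR, and the whole element
flanked by a 3-bp target-site duplication (TSD) created at insertion. The
TIR consensus is the 19-bp degenerate pattern `GGGYCYGTTTGGGGCAGCT`; the
preferred TSD is `TTA`. Two families, A and B, share the identical TIR and
TSD but differ in their sub-terminal and coding sequences; the packaged
family templates are intact autonomous copies of 5,053 bp (A) and 7,053 bp
(B). The family-A length reproduces the published full length of the
element this model describes; no exact family-B length is published, so
7,053 bp was chosen to sit in the reported 6–8 kb mode of that family.

### Synthetic reference fixtures

The ORF1/TPase reference proteins and sub-terminal sequences are
**synthetic**: generated once from a fixed seed, with the published lengths
(272 aa, 427 aa) and the published inter-family divergence — family-B TPase
and ORF1 are derived from family A keeping 51.6% and 37.4% of residues
respectively, with every substituted position forced to a different residue
so the realized gapless identity equals the kept fraction. CDSs are
intronless back-translations using one fixed codon per residue, so all
copies of a family are byte-identical before per-copy mutation. Intron
structure of real ORFs is deliberately not modelled (see limitations).
Sub-terminal 60-mers are random but constrained to contain no BfaI site, so
the display primer annealing region is never cut.

## Mining

**Motif scan.** A degenerate IUPAC motif is scanned over both strands with
a vectorized per-position table lookup. A position counts one mismatch when
the genome base falls outside the motif position's IUPAC class; degenerate
classes (e.g. Y = C/T) match at zero cost; `N` never matches. The default
genome-wide budget is 2 mismatches on the 19-bp TIR. The published screen
used BLAST at E ≤ 1e-10, which has no exact mismatch equivalent; no
equivalence is claimed.

**De novo inverted repeats.** All maximal exact inverted-repeat pairs with
arm length ≥ 12 (reading "more than 11-bp matches" as ≥ 12) and span ≤ 30 kb
are found by exact k-mer anchoring against the reverse complement with
bidirectional maximal extension; pairs are non-overlapping (a pair blocked
from inward extension by arm collision is reported as is). The unit tests
prove exact equality with an independent anti-diagonal enumeration.

**TIR pairing.** Forward hits are paired greedily left-to-right with
downstream reverse-complement hits at span 50 bp – 30 kb. Preference order:
TSD-valid pairing, then smallest span, then leftmost right TIR; each hit is
used once. The TSD preference is applied globally (a first pass forms only
TSD-valid pairs) so a stray orphan TIR cannot capture the partner of a
downstream intact element. TSDs are the 3-mers immediately flanking the
candidate; elements at scaffold edges get the sentinel `NNN`/invalid.

**Candidate assembly (pipeline).** TIR pairing alone cannot see one-TIR or
TIR-less remnants. The pipeline therefore also maps the known family
sub-terminal sequences (the same move as mapping the known element ends to
a genome with BLAST): 5'/3' sub-terminal hits of a family are paired per
strand into core intervals (mismatch budget 6 on the 60-mers, i.e. 10%),
and a TIR hit exactly abutting a core edge extends the boundary and sets
the presence flag. Elements found only by plain TIR pairing are appended,
so discovery degrades gracefully when sub-terminal references are ablated.

## Classification

Coding evidence is the best local alignment per reference per strand-frame
between the six-frame translation of the candidate and each reference
protein (BLOSUM62, gap open 11 / extend 1 — standard protein defaults).
Evidence requires identity ≥ 30% and reference coverage ≥ 50%. The 30%
floor is set below the weakest published homology accepted for this element
family (ORF1 at 36% identity to its nearest relative), so comparably
diverged copies are still detected; 50% coverage lets the largest exon of a
multi-exon gene pass, since alignments are not spliced. A cheap prefilter
skips frames whose longest stop-free stretch is under half the required
coverage; a local alignment cannot realistically bridge that many stops at
gap cost 11/1.

Class assignment is the deterministic table in the README. `mite_max_len`
defaults to 800 bp: observed MITE-like copies are 200–300 bp, and 800 gives
headroom without absorbing 1–2-kb defective copies. TPaseA/TPaseB are
labels on the reference set, not separate classes.

## Families

The 80-80-80 rule (identity ≥ 80% over ≥ 80% of both sequences across ≥ 80
aligned units) is applied pairwise and closed by single linkage; complete
linkage is available for comparison. The rule is stated at the DNA level
over the full element, which is the default; protein-level identities for
the ORF1/TPase regions are also exposed because published inter-family
divergence is protein-level. DNA identity uses a bit-parallel global
aligner (edlib) — exact edit-distance alignment, needed because all-pairs
full-element alignment at 5–7 kb is infeasible with a plain dynamic
program; protein identity uses a BLOSUM62 global alignment with free end
gaps. Identity is matches over alignment columns excluding terminal gaps;
coverage is the fraction of each sequence inside the aligned span. Family
labels are ordered by lexicographically smallest member, so the partition
and labels are independent of input order.

## Insertion annotation

Gene models are gene → mRNA → exon (first mRNA per gene). Context is
`exon` on any exon overlap (exon wins at boundaries — coding disruption is
the stronger call), `intron` on any remaining gene-span overlap ("inserted
in a gene" means any overlap with the gene span), else `intergenic` with
distance to the nearest gene boundary (ties toward the lower coordinate).
Context is positional; strand plays no role. The summary reports both
intergenic conventions: the element count and the count of distinct
flanking genes (both neighbours).

## Transposon display

Only the band-position-determining steps are modelled: BfaI digest (`C^TAG`,
cut after position 1), adapter ligation at every cut, and amplification
from a TE-specific sub-terminal primer outward to the nearest cut site on
that side. Pre-selective amplification and touchdown cycling affect
efficiency, not band positions, and are omitted. Amplicon length =
primer-to-cut genomic span + primer length + adapter length (adapter 20 bp
by default; the real adapter is unpublished, so every quantitative
construction pins it explicitly). Each amplicon is binned by the two
genomic bases immediately interior to the cut site, read on the
primer-bearing strand — the +NN selective bases of the nested primer. All
16 NN are supported; the default set is the eight used on the published
gels. The gel window defaults to 50–700 bp (typical polyacrylamide range;
not published). Both element ends are amplified (3' sub-terminal primer
rightward, reverse-complemented 5' sub-terminal primer leftward), so an
intact copy can give up to two bands per family. Primer matching is exact
by default (`primer_mismatch` available): a resident copy whose sub-terminal
has drifted simply gives no band, which mirrors the incomplete sampling of
real displays.

## Synthetic data: what it emulates, and what it does not

The generator plants copies of all seven structural classes into a uniform
random background (default 5 Mb at 40% GC), each insertion duplicating the
3 bases at its target site. By default target sites are re-drawn until they
are `TTA` (`tsd_force_tta`), matching the observed preference while leaving
open whether it is a requirement; per-copy divergence is 2% substitutions
(defaults chosen as the benchmark study condition); insertion sites keep
≥ 1.2 kb separation (no nested insertions by default); defective copies
retain their sub-terminal regions (needed for display; a flag ablates
them). Gene models are placed so ~40% of elements fall inside genes, with
the exonic share at 24% — the intronic/exonic split observed for real
insertions in genes. The variant genome adds fresh, unmutated insertions
(new transposition events are copies of the master element), MITE-like
family B by default, mirroring the published active scenario.

Passing the recovery benchmark (recall/precision ≥ 0.95, class accuracy
≥ 0.90 on 200 copies at 2% divergence) shows the machinery is correct and
calibrated for its stated mismatch budgets. It does **not** show
performance on real assemblies: the background has no repeat structure, no
N-gaps, no assembly collapse of near-identical copies, divergence is
uniform rather than age-structured, there are no nested or truncated-by-
assembly insertions, and coding genes are intronless. The published
genome-scale counts depend on a 1.1-Gb assembly and are not reproduced at
desk scale.

## Numerical conventions and problem sizes

Coordinates are 0-based half-open internally; GFF3 output is 1-based
closed. All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical spec + seed gives byte-identical
FASTA/GFF3/TSV outputs, and the pipeline writes a manifest with a SHA-256
hash of its canonical YAML config. The evaluator counts an element as
recovered when both boundaries match a truth row within ±2 bp (one-to-one
matching, smallest total offset first) and raises on an apparent 0/1-based
convention mismatch. Benchmarks in the test suite run at 5 Mb / 200
elements (recovery), 10 kb (scan oracle), ~1 kb (inverted-repeat oracle),
50–100 kb (digest oracle) and 1 Mb (display differential) — sizes chosen so
the whole suite completes in a couple of minutes on one core while keeping
every class represented.

## Known limitations

- No spliced-ORF reconstruction; heavily fragmented coding regions can fall
  below 50% coverage and demote a copy to a non-coding class.
- TIRs diverged beyond the mismatch budget are invisible to the scan;
  one-TIR/no-TIR copies are only found when sub-terminal references exist.
- The 80-80-80 implementation offers DNA- and protein-level identity but
  takes no position on which the original analyses used (ambiguous in the
  source); defaults to DNA.
- Display simulation ignores PCR bias, fluorescence intensity and gel
  nonlinearity; band identity is (NN, length) only.
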