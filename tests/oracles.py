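"""Independent brute-force oracles used to validate the optimized code paths.

Each function here re-derives a result by direct enumeration, sharing no
code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
        "W": "W", "K": "M", "M": "K", "B": "V", "D": "H", "H": "D", "V": "B",
        "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def brute_scan(seq: str, pattern: str, max_mismatch: int):
    """Per-offset IUPAC comparison, both orientations."""
    hits = []
    for orient, pat in (("forward", pattern), ("revcomp", rc(pattern))):
        L = len(pat)
        for i in range(len(seq) - L + 1):
            window = seq[i : i + L]
            mm = sum(
                1
                for b, code in zip(window, pat)
                if b == "N" or b not in IUPAC[code]
            )
            if mm <= max_mismatch:
                hits.append((i, i + L, orient, mm))
    return sorted(hits)


def brute_inverted_repeats(region: str, min_match: int, max_span: int):
    """Maximal inverted-repeat pairs via exhaustive anti-diagonal runs."""
    n = len(region)
    comp = np.zeros(n, dtype="<U1")
    for i, b in enumerate(region):
        comp[i] = COMP[b]
    chars = np.array(list(region))
    pairs = set()
    for c in range(1, 2 * n - 2):  # c = i + j over matched base pairs
        i_lo = max(0, c - n + 1)
        i_hi = (c - 1) // 2  # ensures i < j = c - i
        if i_hi < i_lo:
            continue
        i_vals = np.arange(i_lo, i_hi + 1)
        ok = chars[i_vals] == comp[c - i_vals]
        run_start = None
        for k, flag in enumerate(list(ok) + [False]):
            if flag and run_start is None:
                run_start = k
            elif not flag and run_start is not None:
                i0, i1 = int(i_vals[run_start]), int(i_vals[k - 1])
                L = i1 - i0 + 1
                a0, a1 = i0, i1 + 1
                b0, b1 = c - i1, c - i0 + 1
                if L >= min_match and (b1 - a0) <= max_span:
                    pairs.add(((a0, a1), (b0, b1)))
                run_start = None
    return sorted(pairs)


def brute_digest_boundaries(seq: str, site: str, cut_offset: int):
    cuts = []
    i = seq.find(site)
    while i != -1:
        p = i + cut_offset
        if 0 < p < len(seq):
            cuts.append(p)
        i = seq.find(site, i + 1)
    return [0] + sorted(set(cuts)) + [len(seq)]


def brute_annotate(elements, genes):
    """O(n*m) interval intersection; mirrors exon-over-intron priority."""
    out = []
    for eid, scaffold, start, end in elements:
        context, gene_id, dist = "intergenic", None, None
        exon_genes = []
        span_genes = []
        for g in genes:
            if g.scaffold != scaffold:
                continue
            if any(start < e and end > s for s, e in g.exons):
                exon_genes.append(g)
            elif start < g.end and end > g.start:
                span_genes.append(g)
        if exon_genes:
            g = min(exon_genes, key=lambda g: (g.start, g.gene_id))
            out.append((eid, "exon", g.gene_id, 0))
            continue
        if span_genes:
            g = min(span_genes, key=lambda g: (g.start, g.gene_id))
            out.append((eid, "intron", g.gene_id, 0))
            continue
        dists = []
        for g in genes:
            if g.scaffold != scaffold:
                continue
            if g.end <= start:
                dists.append(start - g.end)
            elif g.start >= end:
                dists.append(g.start - end)
        out.append((eid, "intergenic", None, min(dists) if dists else -1))
    return out


def transitive_closure_partition(ids, same):
    """Partition from a pairwise boolean relation via matrix closure."""
    n = len(ids)
    m = np.eye(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if i != j and same(ids[i], ids[j]):
                m[i, j] = True
    changed = True
    while changed:
        nxt = m | (m @ m)
        changed = bool((nxt != m).any())
        m = nxt
    groups = {}
    for i in range(n):
        root = min(j for j in range(n) if m[i, j])
        groups.setdefault(root, set()).add(ids[i])
    return {frozenset(g) for g in groups.values()}
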