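"""Independent oracles used across the test suite.

Each oracle re-derives an expected result with machinery deliberately
different from the implementation under test (regex run extension,
position-by-position scans, scipy linkage), never by calling the code
path it checks.
"""

from __future__ import annotations

import re

import numpy as np

COMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(COMP)[::-1]


def oracle_scan(s: str, min_repeats: dict[int, int], min_len: int = 10):
    """Brute-force SSR finder: same policy (left-to-right, smallest
    qualifying period wins, resume after run), independent machinery
    (regex run extension, doubling trick for minimal period).

    Returns (motif, repeats, start, end) tuples, 1-based inclusive.
    """
    out = []
    pos = 0
    L = len(s)
    while pos < L:
        emitted = False
        for k in sorted(min_repeats):
            motif = s[pos : pos + k]
            if len(motif) < k or "N" in motif:
                continue
            if (motif + motif).find(motif, 1) != k:  # smaller period exists
                continue
            m = re.match(f"(?:{re.escape(motif)})+", s[pos:])
            n = m.end() // k
            if n >= min_repeats[k] and k * n >= min_len:
                out.append((motif, n, pos + 1, pos + k * n))
                pos += k * n
                emitted = True
                break
        if not emitted:
            pos += 1
    return out


def oracle_map(primer: str, seq: str, max_mm: int):
    """Quadratic position-by-position primer mapping on both strands."""
    hits = []
    k = len(primer)
    for strand, probe in (("+", primer), ("-", rc(primer))):
        for pos in range(len(seq) - k + 1):
            mm = sum(a != b for a, b in zip(seq[pos : pos + k], probe))
            if mm <= max_mm:
                hits.append((pos + 1, strand, mm))
    return sorted(hits)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.42) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def cophenetic_from_tree(tree, labels):
    """Pairwise root-path distances (2x LCA height) from an ultrametric
    tree, ordered like ``labels``."""
    n = len(labels)
    index = {l: i for i, l in enumerate(labels)}
    out = np.zeros((n, n))

    def visit(node):
        if node.is_leaf:
            return [node.label]
        below = [visit(c) for c in node.children]
        for a_leaves in below:
            for b_leaves in below:
                if a_leaves is b_leaves:
                    continue
                for a in a_leaves:
                    for b in b_leaves:
                        out[index[a], index[b]] = 2 * node.height
        return [l for leaves in below for l in leaves]

    visit(tree.root)
    return out
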