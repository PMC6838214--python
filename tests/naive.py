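"""Independent brute-force re-implementations used as oracles.

Everything here is deliberately naive (full DP edit distance, sliding-window
motif scans, explicit loops) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
GAPS = ".-"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def levenshtein(a: str, b: str) -> int:
    """Classic full-matrix DP edit distance."""
    la, lb = len(a), len(b)
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[lb]


def strip_gaps(s: str) -> str:
    return "".join(c for c in s if c not in GAPS)


def pair_degap(a: str, b: str) -> tuple[str, str]:
    keep = [(x, y) for x, y in zip(a, b) if x not in GAPS and y not in GAPS]
    return "".join(x for x, _ in keep), "".join(y for _, y in keep)


def gc_content(seq: str) -> float | None:
    seq = strip_gaps(seq)
    denom = sum(seq.count(b) for b in "ACGT")
    if denom == 0:
        return None
    return (seq.count("G") + seq.count("C")) / denom


def pairwise_distances(seqs) -> list[int]:
    return [levenshtein(a, b) for a, b in itertools.combinations(seqs, 2)]


def kth_nn(seqs, k=1) -> list[int]:
    out = []
    for i, s in enumerate(seqs):
        ds = sorted(levenshtein(s, t) for j, t in enumerate(seqs) if j != i)
        out.append(ds[k - 1])
    return out


def motif_count(seq: str, motifs) -> int:
    total = 0
    for m in motifs:
        w = len(m)
        for i in range(len(seq) - w + 1):
            window = seq[i : i + w]
            if all(c in IUPAC[p] for c, p in zip(window, m)):
                total += 1
    return total


def transition_counts(insertions) -> np.ndarray:
    idx = {b: i for i, b in enumerate("ACGT")}
    counts = np.zeros((4, 4), dtype=int)
    for s in insertions:
        for i in range(len(s) - 1):
            a, b = s[i], s[i + 1]
            if a in idx and b in idx:
                counts[idx[a], idx[b]] += 1
    return counts


def mutated_positions(germ: str, seq: str) -> list[int]:
    g, s = pair_degap(germ, seq)
    return [
        i
        for i, (x, y) in enumerate(zip(g, s))
        if x != y and x in "ACGT" and y in "ACGT"
    ]


def consecutive_gaps(positions) -> list[int]:
    return [b - a for a, b in zip(positions, positions[1:])]


def hill(counts, q: float) -> float:
    counts = [c for c in counts if c > 0]
    total = sum(counts)
    ps = [c / total for c in counts]
    if q == 0:
        return float(len(ps))
    if q == 1:
        return math.exp(-sum(p * math.log(p) for p in ps))
    return sum(p**q for p in ps) ** (1.0 / (1.0 - q))


def jensen_shannon_discrete(p, q) -> float:
    """JSD of two aligned probability vectors, natural log."""
    val = 0.0
    for pi, qi in zip(p, q):
        mi = (pi + qi) / 2
        if pi > 0:
            val += 0.5 * pi * math.log(pi / mi)
        if qi > 0:
            val += 0.5 * qi * math.log(qi / mi)
    return val


# -- tiny rooted trees as nested tuples: leaf = "name", node = (child, ...) --

def tree_leaf_depths(tree, depth=0):
    if isinstance(tree, str):
        return [depth]
    out = []
    for child in tree:
        out.extend(tree_leaf_depths(child, depth + 1))
    return out


def sackin(tree) -> int:
    return sum(tree_leaf_depths(tree))


def _leaves(tree):
    if isinstance(tree, str):
        return [tree]
    out = []
    for c in tree:
        out.extend(_leaves(c))
    return out


def cophenetic(tree) -> int:
    """Sum over unordered leaf pairs of MRCA depth, by explicit enumeration."""

    def mrca_depth(tree, x, y, depth=0):
        if isinstance(tree, str):
            return None
        for child in tree:
            lv = set(_leaves(child))
            if x in lv and y in lv:
                return mrca_depth(child, x, y, depth + 1)
        return depth

    leaves = _leaves(tree)
    return sum(
        mrca_depth(tree, x, y) for x, y in itertools.combinations(leaves, 2)
    )


def colless_like(tree, f=lambda n: math.log(n + math.e)) -> float:
    """Sum over internal nodes of mean-deviation of children's f-sizes."""

    def fsize(t):
        if isinstance(t, str):
            return f(0)
        return f(len(t)) + sum(fsize(c) for c in t)

    def walk(t):
        if isinstance(t, str):
            return 0.0
        xs = [fsize(c) for c in t]
        mean = sum(xs) / len(xs)
        here = sum(abs(x - mean) for x in xs) / len(xs)
        return here + sum(walk(c) for c in t)

    return walk(tree)


def to_newick(tree) -> str:
    if isinstance(tree, str):
        return tree
    return "(" + ",".join(to_newick(c) for c in tree) + ")"
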