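"""Repertoire summary statistics.

Every public function maps a :class:`~repsum.airr_io.RepertoireTable` (or a
plain sequence list / tree set) to one of four result shapes:

* :class:`SummaryDistribution` — a multiset of scalars, one value per record
  (or per pair, per tree, ...);
* :class:`CategoricalCounts` — category -> count (gene usage, k-mers);
* :class:`TransitionMatrix` — 4x4 row-stochastic nucleotide transitions
  estimated from non-templated insertion strings;
* a plain scalar (in-frame percentage, Hill diversity).

The :data:`SUMMARY_REGISTRY` at the bottom names each summary, the capability
level it requires, how two repertoires are compared on it (Jensen–Shannon
divergence for scalar distributions, l1 for counts and matrices), and whether
it is sequence-level (exactly one value per record) and hence usable as a
lasso covariate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from . import aa_properties as aap
from .airr_io import (
    CapabilityLevel,
    CloneTreeSet,
    RepertoireTable,
    degap,
    degap_pair,
    normalize_gene_call,
)

__all__ = [
    "SummaryDistribution",
    "CategoricalCounts",
    "TransitionMatrix",
    "EmptySummaryError",
    "string_distance",
    "gc_content_distribution",
    "pairwise_distance_distribution",
    "nearest_neighbor_distribution",
    "motif_count_distribution",
    "cdr3_length_distribution",
    "gene_usage_counts",
    "aa_property_distribution",
    "aa_kmer_counts",
    "rearrangement_length_distribution",
    "insertion_transition_matrix",
    "germline_distance_distribution",
    "positional_mutation_distances",
    "per_gene_substitution_rates",
    "in_frame_percentage",
    "cluster_size_distribution",
    "hill_diversity",
    "tree_shape_indices",
    "HOTSPOT_MOTIFS",
    "COLDSPOT_MOTIFS",
    "SUMMARY_REGISTRY",
    "SummarySpec",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Canonical AID targeting motifs (configurable in every motif function).
HOTSPOT_MOTIFS = ("WRC", "GYW", "WA", "TW")
COLDSPOT_MOTIFS = ("SYC", "GRS")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


class EmptySummaryError(ValueError):
    """No record in the table can contribute to the requested summary."""


# -- result containers ----------------------------------------------------

@dataclass
class SummaryDistribution:
    """An unordered sample of scalar values from one summary."""

    values: np.ndarray
    name: str
    n_source: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in summary {self.name!r}")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class CategoricalCounts:
    """Nonnegative integer counts over categories."""

    counts: dict
    name: str

    def __post_init__(self) -> None:
        for k, v in self.counts.items():
            if v < 0:
                raise ValueError(f"negative count for {k!r}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequencies(self) -> dict:
        t = self.total
        if t == 0:
            return {k: 0.0 for k in self.counts}
        return {k: v / t for k, v in self.counts.items()}


@dataclass
class TransitionMatrix:
    """Row-stochastic 4x4 nucleotide transition frequencies with raw counts."""

    entries: np.ndarray
    counts: np.ndarray
    name: str = "transition_matrix"

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.entries.shape != (4, 4) or self.counts.shape != (4, 4):
            raise ValueError("transition matrices must be 4x4 over A,C,G,T")
        rowsums = self.entries.sum(axis=1)
        for i, s in enumerate(rowsums):
            expect = 0.0 if self.counts[i].sum() == 0 else 1.0
            if not math.isclose(s, expect, abs_tol=1e-9):
                raise ValueError(f"row {BASES[i]} sums to {s}, expected {expect}")

    @classmethod
    def from_counts(cls, counts: np.ndarray, name: str = "transition_matrix"):
        counts = np.asarray(counts, dtype=int)
        entries = np.zeros((4, 4))
        rows = counts.sum(axis=1)
        nz = rows > 0
        entries[nz] = counts[nz] / rows[nz, None]
        return cls(entries=entries, counts=counts, name=name)


# -- string metrics -------------------------------------------------------

def string_distance(a: str, b: str, metric: str = "levenshtein") -> int:
    """Distance between two strings: Levenshtein (default) or Hamming.

    Hamming requires equal lengths.
    """
    if metric == "levenshtein":
        if a == b:
            return 0
        return edlib.align(a, b, task="distance")["editDistance"]
    if metric == "hamming":
        if len(a) != len(b):
            raise ValueError("hamming distance requires equal-length strings")
        return sum(x != y for x, y in zip(a, b))
    raise ValueError(f"unknown string metric {metric!r}")


def _sequences(table: RepertoireTable, column: str, degapped: bool = True) -> list[str]:
    seqs = [s for s in table.column(column)]
    return [degap(s) for s in seqs] if degapped else seqs


# -- alignment-level summaries --------------------------------------------

def gc_content_distribution(table: RepertoireTable) -> SummaryDistribution:
    """Per-record GC fraction of the degapped sequence_alignment.

    Ambiguous bases (N etc.) are excluded from the denominator; records with
    zero unambiguous bases are skipped.
    """
    values = []
    for seq in _sequences(table, "sequence_alignment"):
        gc = sum(1 for c in seq if c in "GC")
        denom = sum(1 for c in seq if c in BASES)
        if denom:
            values.append(gc / denom)
    if not values:
        raise EmptySummaryError("no sequences with unambiguous bases")
    return SummaryDistribution(values, "gc_content", n_source=len(values))


def pairwise_distance_distribution(
    seqs: Sequence[str], metric: str = "levenshtein"
) -> SummaryDistribution:
    """All n(n-1)/2 pairwise string distances."""
    if len(seqs) < 2:
        raise ValueError("pairwise distances need >= 2 sequences")
    vals = [
        string_distance(a, b, metric) for a, b in itertools.combinations(seqs, 2)
    ]
    return SummaryDistribution(vals, "pairwise_distance", n_source=len(seqs))


def nearest_neighbor_distribution(
    seqs: Sequence[str], k: int = 1, metric: str = "levenshtein"
) -> SummaryDistribution:
    """k-th nearest-neighbor distance of each sequence to the rest.

    Multiset semantics: a duplicate of s_i elsewhere in the list gives
    distance 0.  Requires k < n.
    """
    n = len(seqs)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} requires more than k sequences (got {n})")
    vals = []
    for i, s in enumerate(seqs):
        d = sorted(string_distance(s, t, metric) for j, t in enumerate(seqs) if j != i)
        vals.append(d[k - 1])
    return SummaryDistribution(
        vals, f"nearest_neighbor_k{k}" if k != 1 else "nearest_neighbor", n_source=n
    )


def _compile_motif(motif: str) -> list[frozenset]:
    try:
        return [frozenset(IUPAC[c]) for c in motif.upper()]
    except KeyError as e:
        raise ValueError(f"invalid IUPAC character {e.args[0]!r} in motif {motif!r}")


def count_motifs(seq: str, motifs: Sequence[str]) -> int:
    """Total overlapping matches of any motif in ``seq``.

    IUPAC degeneracies are expanded; ambiguous sequence characters (e.g. N)
    match nothing.
    """
    compiled = [_compile_motif(m) for m in motifs]
    total = 0
    for pat in compiled:
        w = len(pat)
        for i in range(len(seq) - w + 1):
            if all(seq[i + j] in pat[j] for j in range(w)):
                total += 1
    return total


def motif_count_distribution(
    table: RepertoireTable, motifs: Sequence[str]
) -> SummaryDistribution:
    """Per-record count of (possibly overlapping) IUPAC motif matches."""
    if not motifs:
        raise ValueError("motif list must be non-empty")
    for m in motifs:
        _compile_motif(m)
    vals = [count_motifs(seq, motifs) for seq in _sequences(table, "sequence_alignment")]
    if not vals:
        raise EmptySummaryError("no sequences available for motif counting")
    return SummaryDistribution(vals, "motif_count", n_source=len(vals))


# -- annotation-level summaries -------------------------------------------

def cdr3_length_distribution(table: RepertoireTable, unit: str = "nt") -> SummaryDistribution:
    """Junction (nt) or junction_aa (aa) length per record; missing skipped."""
    col = {"nt": "junction", "aa": "junction_aa"}.get(unit)
    if col is None:
        raise ValueError("unit must be 'nt' or 'aa'")
    seqs = table.column(col)
    if len(seqs) == 0:
        raise EmptySummaryError(f"{col} missing for all records")
    vals = seqs.str.len().to_numpy(dtype=float)
    return SummaryDistribution(vals, f"cdr3_length_{unit}", n_source=len(vals))


def gene_usage_counts(
    table: RepertoireTable,
    axes: Sequence[str] = ("V", "D", "J"),
    collapse_allele: bool = True,
) -> CategoricalCounts:
    """Joint (or marginal) usage counts of normalized gene names.

    Ambiguous comma-separated calls keep only the first gene; allele
    suffixes are collapsed unless ``collapse_allele=False``.  Marginal
    counts equal the axis-sums of the joint counts by construction.
    """
    cols = {"V": "v_call", "D": "d_call", "J": "j_call"}
    axes = tuple(a.upper() for a in axes)
    for a in axes:
        if a not in cols:
            raise ValueError(f"unknown axis {a!r}")
        if cols[a] not in table.df.columns:
            raise EmptySummaryError(f"column {cols[a]!r} absent")
    sub = table.df[[cols[a] for a in axes]].dropna()
    counts: dict = {}
    for row in sub.itertuples(index=False):
        key = tuple(normalize_gene_call(c, collapse_allele) for c in row)
        if len(axes) == 1:
            key = key[0]
        counts[key] = counts.get(key, 0) + 1
    return CategoricalCounts(counts, name=f"{''.join(axes).lower()}_usage")


_STANDARD_AA = frozenset(aap.AA_LETTERS)


def _usable_junction_aas(table: RepertoireTable) -> list[str]:
    out = []
    for s in table.column("junction_aa"):
        if s and set(s) <= _STANDARD_AA:
            out.append(s)
    return out


def aa_property_distribution(table: RepertoireTable, prop: str) -> SummaryDistribution:
    """One physicochemical value per usable junction_aa.

    ``prop`` is one of the mean-of-weights scales ("gravy", "polarity",
    "bulkiness", "basicity", "acidity"), a formula property ("aromaticity",
    "charge", "aliphatic_index"), or a factor component "kidera_1".."kidera_10"
    / "atchley_1".."atchley_5".  Records containing non-standard letters
    (X, *, gaps) are skipped.
    """
    fn = _property_fn(prop)
    seqs = _usable_junction_aas(table)
    if not seqs:
        raise EmptySummaryError("no junction_aa with standard residues")
    return SummaryDistribution([fn(s) for s in seqs], prop, n_source=len(seqs))


def _property_fn(prop: str) -> Callable[[str], float]:
    if prop in aap.SCALES:
        scale = aap.SCALES[prop]
        return lambda s: aap.mean_weight(s, scale.weights)
    if prop == "aromaticity":
        return aap.aromaticity
    if prop == "charge":
        return aap.net_charge
    if prop == "aliphatic_index":
        return aap.aliphatic_index
    if prop.startswith("kidera_"):
        i = int(prop.split("_")[1]) - 1
        if not 0 <= i < 10:
            raise ValueError(f"Kidera factor index out of range in {prop!r}")
        return lambda s: sum(aap.KIDERA_FACTORS[aa][i] for aa in s) / len(s)
    if prop.startswith("atchley_"):
        i = int(prop.split("_")[1]) - 1
        if not 0 <= i < 5:
            raise ValueError(f"Atchley factor index out of range in {prop!r}")
        return lambda s: sum(aap.ATCHLEY_FACTORS[aa][i] for aa in s) / len(s)
    raise ValueError(f"unknown amino-acid property {prop!r}")


def aa_kmer_counts(table: RepertoireTable, k: int = 2) -> CategoricalCounts:
    """Counts of overlapping amino-acid k-mers pooled over junction_aa."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict = {}
    for s in table.column("junction_aa"):
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    return CategoricalCounts(counts, name=f"aa_{k}mer")


DELETION_FIELDS = (
    "v_3p_deletion",
    "v_5p_deletion",
    "d_3p_deletion",
    "d_5p_deletion",
    "j_3p_deletion",
    "j_5p_deletion",
)


def rearrangement_length_distribution(
    table: RepertoireTable, field_name: str
) -> SummaryDistribution:
    """Deletion lengths from their columns, or np1/np2 insertion lengths.

    Insertion lengths are the np string lengths; an np column that is
    present-but-empty for a record counts as length 0 only if stored as an
    explicit empty-string-missing convention upstream (missing -> skipped).
    """
    if field_name in DELETION_FIELDS:
        vals = table.column(field_name)
        if len(vals) == 0:
            raise EmptySummaryError(f"{field_name} missing for all records")
        arr = vals.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError(f"negative {field_name} length")
        return SummaryDistribution(arr, field_name, n_source=len(arr))
    if field_name in ("np1_length", "np2_length"):
        col = field_name.split("_")[0]
        if col not in table.df.columns:
            raise EmptySummaryError(f"{col} column absent")
        s = table.df[col]
        present = s.notna()
        # a record annotated with np columns but an empty insertion has length 0
        lengths = s.fillna("").str.len().to_numpy(dtype=float)
        if not present.any() and len(lengths) == 0:
            raise EmptySummaryError(f"{col} missing for all records")
        return SummaryDistribution(lengths, field_name, n_source=len(lengths))
    raise ValueError(f"unknown rearrangement length field {field_name!r}")


def insertion_transition_matrix(table: RepertoireTable, which: str = "np1") -> TransitionMatrix:
    """Nucleotide transition frequencies pooled over insertion strings.

    Counts adjacent (b1, b2) pairs over all np1 (or np2) strings; rows are
    normalized to frequencies.  Insertions of length <= 1 contribute nothing.
    """
    if which not in ("np1", "np2"):
        raise ValueError("which must be 'np1' or 'np2'")
    if which not in table.df.columns:
        raise EmptySummaryError(f"{which} column absent")
    counts = np.zeros((4, 4), dtype=int)
    for s in table.column(which):
        for a, b in zip(s, s[1:]):
            if a in _BASE_INDEX and b in _BASE_INDEX:
                counts[_BASE_INDEX[a], _BASE_INDEX[b]] += 1
    if counts.sum() == 0:
        raise EmptySummaryError(f"no {which} insertion of length >= 2")
    return TransitionMatrix.from_counts(counts, name=f"{which}_transition")


def _aligned_pairs(table: RepertoireTable):
    df = table.df
    for col in ("sequence_alignment", "germline_alignment"):
        if col not in df.columns:
            raise EmptySummaryError(f"{col} column absent")
    sub = df[["germline_alignment", "sequence_alignment"]].dropna()
    for germ, seq in sub.itertuples(index=False):
        yield germ, seq


def germline_distance_distribution(
    table: RepertoireTable, metric: str = "levenshtein"
) -> SummaryDistribution:
    """Distance from each record's germline to its observed sequence.

    Both strings are degapped pairwise-consistently before measuring.
    """
    vals = []
    for germ, seq in _aligned_pairs(table):
        g, s = degap_pair(germ, seq)
        vals.append(string_distance(g, s, metric))
    if not vals:
        raise EmptySummaryError("no germline/sequence alignment pairs")
    return SummaryDistribution(vals, "germline_distance", n_source=len(vals))


def _mutated_positions(germ: str, seq: str) -> list[int]:
    g, s = degap_pair(germ, seq)
    return [
        i for i, (a, b) in enumerate(zip(g, s)) if a != b and a in BASES and b in BASES
    ]


def positional_mutation_distances(table: RepertoireTable) -> SummaryDistribution:
    """Gaps between consecutive mutated positions along each alignment.

    Mutations are positions where aligned germline and sequence bases differ
    with both unambiguous; records with < 2 mutations contribute nothing.
    """
    vals: list[int] = []
    n_source = 0
    any_pair = False
    for germ, seq in _aligned_pairs(table):
        any_pair = True
        pos = _mutated_positions(germ, seq)
        if len(pos) >= 2:
            n_source += 1
            vals.extend(b - a for a, b in zip(pos, pos[1:]))
    if not any_pair:
        raise EmptySummaryError("no germline/sequence alignment pairs")
    return SummaryDistribution(vals, "positional_mutation_distances", n_source=n_source)


def per_gene_substitution_rates(
    table: RepertoireTable, per_position: bool = False
) -> dict:
    """Pooled substitution rate per V gene (optionally per alignment position).

    Rate = mismatched / compared positions over all records assigned to the
    gene; positions with a gap or ambiguity in either string are not
    compared.  With ``per_position``, returns gene -> vector of positional
    mismatch frequencies along the (gapped) alignment coordinate, NaN where
    a position was never compared.
    """
    df = table.df
    needed = ("v_call", "sequence_alignment", "germline_alignment")
    for col in needed:
        if col not in df.columns:
            raise EmptySummaryError(f"{col} column absent")
    sub = df[list(needed)].dropna()
    if len(sub) == 0:
        raise EmptySummaryError("no annotated alignment pairs")
    by_gene: dict[str, list[tuple[str, str]]] = {}
    for call, seq, germ in sub.itertuples(index=False):
        by_gene.setdefault(normalize_gene_call(call), []).append((germ, seq))
    out: dict = {}
    for gene, pairs in by_gene.items():
        if per_position:
            width = max(len(g) for g, _ in pairs)
            mism = np.zeros(width)
            comp = np.zeros(width)
            for germ, seq in pairs:
                for i, (a, b) in enumerate(zip(germ, seq)):
                    if a in BASES and b in BASES:
                        comp[i] += 1
                        if a != b:
                            mism[i] += 1
            with np.errstate(invalid="ignore"):
                out[gene] = np.where(comp > 0, mism / np.maximum(comp, 1), np.nan)
        else:
            mismatches = compared = 0
            for germ, seq in pairs:
                for a, b in zip(germ, seq):
                    if a in BASES and b in BASES:
                        compared += 1
                        if a != b:
                            mismatches += 1
            out[gene] = mismatches / compared if compared else float("nan")
    return out


def in_frame_percentage(table: RepertoireTable) -> float:
    """Percentage of records whose junction length is a multiple of 3."""
    juncs = table.column("junction")
    if len(juncs) == 0:
        raise EmptySummaryError("junction missing for all records")
    lengths = juncs.str.len()
    return 100.0 * float((lengths % 3 == 0).mean())


# -- clustered-level summaries --------------------------------------------

def cluster_size_distribution(table: RepertoireTable) -> SummaryDistribution:
    """Clonal family sizes; their sum equals the number of clustered records."""
    if "clone_id" not in table.df.columns:
        raise EmptySummaryError("clone_id column absent")
    ids = table.column("clone_id")
    if len(ids) == 0:
        raise EmptySummaryError("clone_id missing for all records")
    sizes = ids.value_counts().to_numpy(dtype=float)
    return SummaryDistribution(sizes, "cluster_size", n_source=int(sizes.sum()))


def hill_diversity(cluster_counts: CategoricalCounts, q: float) -> float:
    """Hill number of order q from clonal abundances.

    q=0 is richness, q=1 the exponential Shannon entropy, q=2 the inverse
    Simpson index.
    """
    if q < 0:
        raise ValueError("q must be nonnegative")
    counts = np.array([c for c in cluster_counts.counts.values() if c > 0], dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one nonzero count")
    p = counts / counts.sum()
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


# -- phylogenetic summaries -----------------------------------------------

def _node_depths(tree) -> dict:
    """Edge-count depth of every node from the root."""
    depths = {}
    for node in tree.preorder_node_iter():
        depths[node] = 0 if node.parent_node is None else depths[node.parent_node] + 1
    return depths


def sackin_index(tree) -> float:
    """Sum of leaf depths (edge counts from the root)."""
    depths = _node_depths(tree)
    return float(sum(depths[leaf] for leaf in tree.leaf_node_iter()))


def cophenetic_index(tree) -> float:
    """Sum over unordered leaf pairs of their MRCA's depth."""
    depths = _node_depths(tree)
    total = 0.0
    leaf_counts = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leaf_counts[node] = 1
        else:
            child_counts = [leaf_counts[c] for c in node.child_nodes()]
            pairs = 0
            s = 0
            for c in child_counts:
                pairs += s * c
                s += c
            total += depths[node] * pairs
            leaf_counts[node] = s
    return float(total)


def colless_like_index(
    tree,
    f: Callable[[int], float] = lambda n: math.log(n + math.e),
    dissimilarity: str = "mdm",
) -> float:
    """Colless-like balance index for arbitrary (multifurcating) trees.

    The f-size of a subtree is the sum of f(number of children) over its
    nodes; each internal node contributes the mean deviation from the mean
    ("mdm", the default) or the sample variance ("var") of its children's
    f-sizes; the index is the sum of these contributions.
    """
    fsize = {}
    total = 0.0
    for node in tree.postorder_node_iter():
        children = node.child_nodes()
        fsize[node] = f(len(children)) + sum(fsize[c] for c in children)
        if children:
            xs = np.array([fsize[c] for c in children], dtype=float)
            if dissimilarity == "mdm":
                total += float(np.abs(xs - xs.mean()).mean())
            elif dissimilarity == "var":
                total += float(xs.var())
            else:
                raise ValueError(f"unknown dissimilarity {dissimilarity!r}")
    return total


_TREE_INDICES = {
    "sackin": sackin_index,
    "colless_like": colless_like_index,
    "cophenetic": cophenetic_index,
}


def tree_shape_indices(trees: CloneTreeSet, index: str = "sackin") -> SummaryDistribution:
    """One imbalance index value per clonal-family tree with >= 2 leaves."""
    if index not in _TREE_INDICES:
        raise ValueError(f"unknown tree index {index!r}")
    if trees is None or len(trees) == 0:
        raise EmptySummaryError("empty tree set")
    fn = _TREE_INDICES[index]
    vals = [
        fn(t) for t in trees.trees.values() if len(t.leaf_nodes()) >= 2
    ]
    if not vals:
        raise EmptySummaryError("no tree with >= 2 leaves")
    return SummaryDistribution(vals, f"{index}_index", n_source=len(vals))


# -- summary registry -----------------------------------------------------

@dataclass(frozen=True)
class SummarySpec:
    """How one summary is computed and compared between repertoires."""

    name: str
    kind: str  # scalar_dist | categorical | matrix | scalar
    level: CapabilityLevel
    compute: Callable
    sequence_level: bool = False
    factor_set: str | None = None  # "kidera" / "atchley" for default exclusion


def _dist(fn):
    return fn


def _registry() -> dict[str, SummarySpec]:
    L = CapabilityLevel
    specs: list[SummarySpec] = [
        SummarySpec(
            "gc_content", "scalar_dist", L.alignment_only,
            gc_content_distribution, sequence_level=True,
        ),
        SummarySpec(
            "pairwise_distance", "scalar_dist", L.alignment_only,
            lambda t: pairwise_distance_distribution(_sequences(t, "sequence_alignment")),
        ),
        SummarySpec(
            "nearest_neighbor", "scalar_dist", L.alignment_only,
            lambda t: nearest_neighbor_distribution(_sequences(t, "sequence_alignment")),
        ),
        SummarySpec(
            "hotspot_count", "scalar_dist", L.alignment_only,
            lambda t: motif_count_distribution(t, HOTSPOT_MOTIFS), sequence_level=True,
        ),
        SummarySpec(
            "coldspot_count", "scalar_dist", L.alignment_only,
            lambda t: motif_count_distribution(t, COLDSPOT_MOTIFS), sequence_level=True,
        ),
        SummarySpec(
            "cdr3_length", "scalar_dist", L.annotated,
            lambda t: cdr3_length_distribution(t, "nt"), sequence_level=True,
        ),
        SummarySpec(
            "cdr3_pairwise_distance", "scalar_dist", L.annotated,
            lambda t: pairwise_distance_distribution(list(t.column("junction"))),
        ),
        SummarySpec(
            "v_usage", "categorical", L.annotated, lambda t: gene_usage_counts(t, ("V",)),
        ),
        SummarySpec(
            "d_usage", "categorical", L.annotated, lambda t: gene_usage_counts(t, ("D",)),
        ),
        SummarySpec(
            "j_usage", "categorical", L.annotated, lambda t: gene_usage_counts(t, ("J",)),
        ),
        SummarySpec(
            "vdj_usage", "categorical", L.annotated,
            lambda t: gene_usage_counts(t, ("V", "D", "J")),
        ),
        SummarySpec(
            "aa_2mer", "categorical", L.annotated, lambda t: aa_kmer_counts(t, 2),
        ),
        SummarySpec(
            "aa_frequency", "categorical", L.annotated, lambda t: aa_kmer_counts(t, 1),
        ),
        SummarySpec(
            "np1_transition", "matrix", L.annotated,
            lambda t: insertion_transition_matrix(t, "np1"),
        ),
        SummarySpec(
            "np2_transition", "matrix", L.annotated,
            lambda t: insertion_transition_matrix(t, "np2"),
        ),
        SummarySpec(
            "germline_distance", "scalar_dist", L.annotated,
            germline_distance_distribution, sequence_level=True,
        ),
        SummarySpec(
            "positional_mutation_distances", "scalar_dist", L.annotated,
            positional_mutation_distances,
        ),
        SummarySpec(
            "in_frame_percentage", "scalar", L.annotated, in_frame_percentage,
        ),
        SummarySpec(
            "cluster_size", "scalar_dist", L.clustered, cluster_size_distribution,
        ),
    ]
    for fld in DELETION_FIELDS + ("np1_length", "np2_length"):
        specs.append(
            SummarySpec(
                fld, "scalar_dist", L.annotated,
                (lambda f: lambda t: rearrangement_length_distribution(t, f))(fld),
                sequence_level=True,
            )
        )
    for prop in (
        "gravy", "polarity", "bulkiness", "basicity", "acidity",
        "aromaticity", "charge", "aliphatic_index",
    ):
        specs.append(
            SummarySpec(
                prop, "scalar_dist", L.annotated,
                (lambda p: lambda t: aa_property_distribution(t, p))(prop),
                sequence_level=True,
            )
        )
    for i in range(1, 11):
        specs.append(
            SummarySpec(
                f"kidera_{i}", "scalar_dist", L.annotated,
                (lambda p: lambda t: aa_property_distribution(t, p))(f"kidera_{i}"),
                sequence_level=True, factor_set="kidera",
            )
        )
    for i in range(1, 6):
        specs.append(
            SummarySpec(
                f"atchley_{i}", "scalar_dist", L.annotated,
                (lambda p: lambda t: aa_property_distribution(t, p))(f"atchley_{i}"),
                sequence_level=True, factor_set="atchley",
            )
        )
    for index in ("sackin", "colless_like", "cophenetic"):
        specs.append(
            SummarySpec(
                f"{index}_index", "scalar_dist", L.phylogenetic,
                (lambda ix: lambda t: tree_shape_indices(t.trees, ix))(index),
            )
        )
    return {s.name: s for s in specs}


SUMMARY_REGISTRY: dict[str, SummarySpec] = _registry()


def sequence_level_values(table: RepertoireTable, name: str) -> np.ndarray:
    """Per-row values of a sequence-level summary, NaN where not computable.

    Unlike the distribution functions (which skip unusable records), this
    keeps row alignment, as needed to build regression design matrices.
    """
    spec = SUMMARY_REGISTRY.get(name)
    if spec is None or not spec.sequence_level:
        raise ValueError(f"{name!r} is not a sequence-level summary")
    n = len(table)
    out = np.full(n, np.nan)
    df = table.df

    def seq_col(col):
        return df[col] if col in df.columns else pd.Series([pd.NA] * n)

    if name == "gc_content":
        for i, s in enumerate(seq_col("sequence_alignment")):
            if not pd.isna(s):
                s = degap(s)
                denom = sum(1 for c in s if c in BASES)
                if denom:
                    out[i] = sum(1 for c in s if c in "GC") / denom
    elif name in ("hotspot_count", "coldspot_count"):
        motifs = HOTSPOT_MOTIFS if name == "hotspot_count" else COLDSPOT_MOTIFS
        for i, s in enumerate(seq_col("sequence_alignment")):
            if not pd.isna(s):
                out[i] = count_motifs(degap(s), motifs)
    elif name == "cdr3_length":
        for i, s in enumerate(seq_col("junction")):
            if not pd.isna(s):
                out[i] = len(s)
    elif name in DELETION_FIELDS:
        for i, v in enumerate(seq_col(name)):
            if not pd.isna(v):
                out[i] = float(v)
    elif name in ("np1_length", "np2_length"):
        col = name.split("_")[0]
        if col in df.columns:
            out = df[col].fillna("").str.len().to_numpy(dtype=float)
    elif name == "germline_distance":
        germs, seqs = seq_col("germline_alignment"), seq_col("sequence_alignment")
        for i, (g, s) in enumerate(zip(germs, seqs)):
            if not (pd.isna(g) or pd.isna(s)):
                gg, ss = degap_pair(g, s)
                out[i] = string_distance(gg, ss)
    else:  # amino-acid property of the junction
        fn = _property_fn(name)
        for i, s in enumerate(seq_col("junction_aa")):
            if not pd.isna(s) and s and set(s) <= _STANDARD_AA:
                out[i] = fn(s)
    return out


def sequence_level_summaries(include_factors: bool = False) -> list[str]:
    """Names of summaries yielding exactly one value per record."""
    return [
        s.name
        for s in SUMMARY_REGISTRY.values()
        if s.sequence_level and (include_factors or s.factor_set is None)
    ]
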