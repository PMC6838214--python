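"""Generative model for AIRR-schema repertoires with known ground truth.

The generator emulates the structure of V(D)J recombination: a (V, D, J)
germline triple is drawn from specified usage probabilities, gene ends are
trimmed by per-end deletion-length distributions, non-templated np1/np2
insertions are drawn from a first-order nucleotide Markov chain, and the
parts are concatenated into a naive (germline) rearrangement.  Clonal
families share one naive ancestor; each member receives i.i.d. point
mutations at a per-site rate (star genealogy — no tree-structured lineage).
Every distributional parameter is recorded in the :class:`GenerativeSpec`,
so summaries computed on generated repertoires can be checked against the
parameters that produced them.

Germline gene sequences are synthetic random sequences of realistic lengths
(V ~ 300 nt, D ~ 20 nt, J ~ 50 nt); real IMGT sequences can be supplied
through a custom :class:`GenePool`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from .airr_io import RepertoireTable

__all__ = [
    "GenePool",
    "GenerativeSpec",
    "default_spec",
    "spec_from_config",
    "generate_repertoire",
    "perturb_repertoire",
]

BASES = "ACGT"

#: Default np-insertion transition matrix (rows: from-base A,C,G,T).
DEFAULT_TRANSITION = np.array(
    [
        [0.45, 0.15, 0.25, 0.15],
        [0.20, 0.40, 0.15, 0.25],
        [0.25, 0.20, 0.40, 0.15],
        [0.10, 0.25, 0.20, 0.45],
    ]
)
DEFAULT_INITIAL = np.array([0.30, 0.20, 0.30, 0.20])


@dataclass
class GenePool:
    """Named germline segments with usage probabilities."""

    names: list[str]
    sequences: list[str]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if not (len(self.names) == len(self.sequences) == self.probs.size):
            raise ValueError("gene pool fields must have equal lengths")
        if not np.isclose(self.probs.sum(), 1.0):
            raise ValueError("usage probabilities must sum to 1")
        if (self.probs < 0).any():
            raise ValueError("usage probabilities must be nonnegative")

    @classmethod
    def random(
        cls,
        prefix: str,
        n: int,
        length: int,
        rng: np.random.Generator,
        t_free_5p: int = 0,
        t_free_3p: int = 0,
    ) -> "GenePool":
        """Random germline pool with mildly skewed usage probabilities.

        ``t_free_5p``/``t_free_3p`` draw that many terminal bases from
        {A,C,G}: no stop codon can form without a T, so junction-proximal
        windows built this way translate cleanly in any frame, mimicking
        the stop-depletion of productive rearrangements without
        conditioning any sampled quantity.
        """
        names = [f"{prefix}{i + 1}" for i in range(n)]
        seqs = []
        for _ in range(n):
            head = "".join(rng.choice(list("ACG"), size=min(t_free_5p, length)))
            tail_len = min(t_free_3p, length - len(head))
            mid_len = length - len(head) - tail_len
            mid = "".join(rng.choice(list(BASES), size=mid_len))
            tail = "".join(rng.choice(list("ACG"), size=tail_len))
            seqs.append(head + mid + tail)
        raw = 1.0 / np.arange(1, n + 1)
        return cls(names, seqs, raw / raw.sum())


@dataclass
class GenerativeSpec:
    """Full parameterization of the repertoire generator."""

    v_pool: GenePool
    d_pool: GenePool
    j_pool: GenePool
    deletion_p: dict = field(
        default_factory=lambda: {
            "v_3p_deletion": 0.3,
            "d_5p_deletion": 0.3,
            "d_3p_deletion": 0.3,
            "j_5p_deletion": 0.3,
        }
    )
    deletion_cap: int = 10
    insertion_p: dict = field(default_factory=lambda: {"np1": 0.25, "np2": 0.25})
    insertion_cap: int = 15
    insertion_transition: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITION.copy()
    )
    insertion_initial: np.ndarray = field(default_factory=lambda: DEFAULT_INITIAL.copy())
    mutation_rate: float = 0.02
    clone_size_p: float = 0.5
    n_sequences: int = 1000
    seed: int = 0
    locus: str = "IGH"
    v_anchor: int = 6  # junction nt retained from the trimmed V end
    j_anchor: int = 9  # junction nt retained from the trimmed J start

    def __post_init__(self) -> None:
        self.insertion_transition = np.asarray(self.insertion_transition, dtype=float)
        self.insertion_initial = np.asarray(self.insertion_initial, dtype=float)
        if self.insertion_transition.shape != (4, 4):
            raise ValueError("insertion transition matrix must be 4x4")
        if not np.allclose(self.insertion_transition.sum(axis=1), 1.0):
            raise ValueError("insertion transition rows must sum to 1")
        if not np.isclose(self.insertion_initial.sum(), 1.0):
            raise ValueError("insertion initial distribution must sum to 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        for k, p in {**self.deletion_p, **self.insertion_p}.items():
            if not 0.0 < p <= 1.0:
                raise ValueError(f"geometric parameter {k}={p} outside (0, 1]")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")


def default_spec(seed: int = 0, **overrides) -> GenerativeSpec:
    """A realistic default spec with synthetic germline pools.

    Pools (10 V of 300 nt, 5 D of 20 nt, 4 J of 50 nt) are drawn from a
    seed-derived stream so the same seed always yields the same germlines.
    """
    pool_rng = np.random.default_rng((seed, 0xA1FF))
    spec = GenerativeSpec(
        v_pool=GenePool.random("IGHV1-", 10, 300, pool_rng, t_free_3p=18),
        d_pool=GenePool.random("IGHD2-", 5, 20, pool_rng, t_free_5p=20),
        j_pool=GenePool.random("IGHJ", 4, 50, pool_rng, t_free_5p=12),
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def spec_from_config(path: str) -> GenerativeSpec:
    """Build a spec from a YAML key-value file.

    Recognized keys: seed, n_sequences, mutation_rate, clone_size_p,
    deletion_p (mapping), deletion_cap, insertion_p (mapping),
    insertion_cap, insertion_transition (4x4 list), insertion_initial,
    locus, n_v/n_d/n_j (pool sizes).  Unspecified keys take defaults.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    seed = int(cfg.pop("seed", 0))
    pool_sizes = {k: cfg.pop(k, None) for k in ("n_v", "n_d", "n_j")}
    spec = default_spec(seed)
    if any(v is not None for v in pool_sizes.values()):
        pool_rng = np.random.default_rng((seed, 0xA1FF))
        spec = replace(
            spec,
            v_pool=GenePool.random(
                "IGHV1-", int(pool_sizes["n_v"] or 10), 300, pool_rng, t_free_3p=18
            ),
            d_pool=GenePool.random(
                "IGHD2-", int(pool_sizes["n_d"] or 5), 20, pool_rng, t_free_5p=20
            ),
            j_pool=GenePool.random(
                "IGHJ", int(pool_sizes["n_j"] or 4), 50, pool_rng, t_free_5p=12
            ),
        )
    return replace(spec, **cfg) if cfg else spec


def _capped_geometric(rng: np.random.Generator, p: float, cap: int) -> int:
    # number of failures before first success, truncated at cap
    return min(int(rng.geometric(p) - 1), cap)


def _markov_string(
    rng: np.random.Generator, length: int, initial: np.ndarray, transition: np.ndarray
) -> str:
    if length == 0:
        return ""
    out = [int(rng.choice(4, p=initial))]
    for _ in range(length - 1):
        out.append(int(rng.choice(4, p=transition[out[-1]])))
    return "".join(BASES[i] for i in out)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        alternatives = [b for b in BASES if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(3))]
    return "".join(chars)


def _translate(junction: str) -> str | None:
    if len(junction) == 0 or len(junction) % 3 != 0:
        return None
    return str(Seq(junction).translate())


def generate_repertoire(spec: GenerativeSpec) -> RepertoireTable:
    """Generate an AIRR-schema repertoire from the spec.

    One naive ancestor per clonal family; descendants are i.i.d. mutated
    copies.  Junction coordinates use fixed anchor offsets (``v_anchor`` nt
    from the trimmed V end through ``j_anchor`` nt into the trimmed J), so
    junction fields are internally consistent with the alignments.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[dict] = []
    clone = 0
    while len(records) < spec.n_sequences:
        clone += 1
        size = min(
            int(rng.geometric(spec.clone_size_p)),
            spec.n_sequences - len(records),
        )
        vi = int(rng.choice(len(spec.v_pool.names), p=spec.v_pool.probs))
        di = int(rng.choice(len(spec.d_pool.names), p=spec.d_pool.probs))
        ji = int(rng.choice(len(spec.j_pool.names), p=spec.j_pool.probs))
        dels = {
            end: _capped_geometric(rng, p, spec.deletion_cap)
            for end, p in spec.deletion_p.items()
        }
        v_seq = spec.v_pool.sequences[vi]
        d_seq = spec.d_pool.sequences[di]
        j_seq = spec.j_pool.sequences[ji]
        v_trim = v_seq[: len(v_seq) - dels.get("v_3p_deletion", 0)]
        d_trim = d_seq[
            dels.get("d_5p_deletion", 0) : len(d_seq) - dels.get("d_3p_deletion", 0)
        ]
        if len(d_trim) < 0 or dels.get("d_5p_deletion", 0) + dels.get(
            "d_3p_deletion", 0
        ) >= len(d_seq):
            d_trim = ""
        j_trim = j_seq[dels.get("j_5p_deletion", 0) :]
        np1 = _markov_string(
            rng,
            _capped_geometric(rng, spec.insertion_p["np1"], spec.insertion_cap),
            spec.insertion_initial,
            spec.insertion_transition,
        )
        np2 = _markov_string(
            rng,
            _capped_geometric(rng, spec.insertion_p["np2"], spec.insertion_cap),
            spec.insertion_initial,
            spec.insertion_transition,
        )
        germline = v_trim + np1 + d_trim + np2 + j_trim
        junc_start = max(len(v_trim) - spec.v_anchor, 0)
        junc_end = min(
            len(v_trim) + len(np1) + len(d_trim) + len(np2) + spec.j_anchor,
            len(germline),
        )
        for _ in range(size):
            seq = _mutate(rng, germline, spec.mutation_rate)
            junction = seq[junc_start:junc_end]
            junction_aa = _translate(junction)
            records.append(
                {
                    "sequence_alignment": seq,
                    "germline_alignment": germline,
                    "junction": junction,
                    "junction_aa": junction_aa,
                    "v_call": f"{spec.v_pool.names[vi]}*01",
                    "d_call": f"{spec.d_pool.names[di]}*01",
                    "j_call": f"{spec.j_pool.names[ji]}*01",
                    "v_3p_deletion": dels.get("v_3p_deletion", 0),
                    "v_5p_deletion": 0,
                    "d_3p_deletion": dels.get("d_3p_deletion", 0),
                    "d_5p_deletion": dels.get("d_5p_deletion", 0),
                    "j_3p_deletion": 0,
                    "j_5p_deletion": dels.get("j_5p_deletion", 0),
                    "np1": np1,
                    "np2": np2,
                    "clone_id": str(clone),
                    "productive": junction_aa is not None and "*" not in junction_aa,
                    "locus": spec.locus,
                }
            )
    return RepertoireTable.from_records(records)


# -- targeted perturbations ----------------------------------------------

def perturb_repertoire(
    table: RepertoireTable, knob: str, magnitude: float, seed: int = 0
) -> RepertoireTable:
    """Return a copy with exactly one summary-targeted property altered.

    Knobs:

    * ``junction_length`` — insert ``magnitude`` random nt (an integer) into
      the middle of every junction; junction_aa is re-derived.  Gene calls,
      alignments and usage distributions are untouched.
    * ``gene_shuffle`` — independently permute the v/d/j_call columns over a
      ``magnitude`` fraction of rows: marginal usage is exactly preserved,
      joint usage is scrambled.
    * ``mutation_rate`` — apply additional i.i.d. point substitutions to
      sequence_alignment at per-site rate ``magnitude``.

    ``magnitude`` 0 always returns an identical table.
    """
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    if knob == "junction_length":
        shift = int(magnitude)
        if shift < 0:
            raise ValueError("junction_length shift must be >= 0")
        if shift:
            def stretch(j):
                if pd.isna(j):
                    return j
                mid = len(j) // 2
                ins = "".join(rng.choice(list(BASES), size=shift))
                return j[:mid] + ins + j[mid:]

            df["junction"] = df["junction"].map(stretch)
            if "junction_aa" in df.columns:
                df["junction_aa"] = df["junction"].map(
                    lambda j: _translate(j) if not pd.isna(j) else j
                )
    elif knob == "gene_shuffle":
        if not 0.0 <= magnitude <= 1.0:
            raise ValueError("gene_shuffle magnitude is a fraction in [0, 1]")
        n = len(df)
        n_rows = int(round(magnitude * n))
        if n_rows >= 2:
            rows = rng.choice(n, size=n_rows, replace=False)
            for col in ("v_call", "d_call", "j_call"):
                if col in df.columns:
                    perm = rng.permutation(n_rows)
                    df.iloc[rows, df.columns.get_loc(col)] = (
                        df.iloc[rows[perm]][col].to_numpy()
                    )
    elif knob == "mutation_rate":
        if not 0.0 <= magnitude <= 1.0:
            raise ValueError("mutation_rate magnitude must be in [0, 1]")
        if magnitude:
            df["sequence_alignment"] = df["sequence_alignment"].map(
                lambda s: _mutate(rng, s, magnitude) if not pd.isna(s) else s
            )
    else:
        raise ValueError(f"unsupported perturbation knob {knob!r}")
    return RepertoireTable(df, trees=table.trees)
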