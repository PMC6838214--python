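"""Divergences between repertoire summaries.

Scalar summary distributions are compared with the Jensen–Shannon divergence
(natural log, so JSD <= ln 2) after a shared equal-width discretization;
categorical counts and transition matrices with the l1 divergence (sum of
absolute count or frequency differences).  ``compare_repertoires`` dispatches
every summary in the registry that both tables' capability levels support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .airr_io import RepertoireTable, capability
from .summaries import (
    SUMMARY_REGISTRY,
    CategoricalCounts,
    EmptySummaryError,
    SummaryDistribution,
    TransitionMatrix,
)

__all__ = [
    "DivergenceResult",
    "BinnedDensity",
    "discretize",
    "jsd",
    "l1_divergence",
    "matrix_l1",
    "compare_repertoires",
    "results_to_frame",
    "LN2",
]

LN2 = float(np.log(2.0))


@dataclass
class DivergenceResult:
    summary_name: str
    value: float
    method: str  # jsd | l1
    n_left: int = 0
    n_right: int = 0
    skipped: bool = False
    reason: str | None = None


@dataclass
class BinnedDensity:
    """A discretized sample: probabilities over retained shared bins."""

    bin_edges: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.probs.size and not np.isclose(self.probs.sum(), 1.0):
            raise ValueError("probabilities must sum to 1")


def _values(sample) -> np.ndarray:
    if isinstance(sample, SummaryDistribution):
        return sample.values
    return np.asarray(sample, dtype=float)


def discretize(p_values, q_values) -> tuple[BinnedDensity, BinnedDensity]:
    """Bin two samples on shared equal-width edges.

    The number of bins is B = max(min(m, n), 2) where m and n are the two
    samples' support sizes (counts of distinct values), so the resolution
    scales with the simpler sample.  Bins in which exactly one density is
    zero (which would make a KL term infinite before mixing) are discarded
    from both and the remaining masses renormalized.
    """
    p = _values(p_values)
    q = _values(q_values)
    if p.size == 0 or q.size == 0:
        raise ValueError("cannot discretize an empty sample")
    m = np.unique(p).size
    n = np.unique(q).size
    B = max(min(m, n), 2)
    lo = min(p.min(), q.min())
    hi = max(p.max(), q.max())
    if lo == hi:  # all values identical across both samples
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, B + 1)
    pc, _ = np.histogram(p, bins=edges)
    qc, _ = np.histogram(q, bins=edges)
    pp = pc / pc.sum()
    qq = qc / qc.sum()
    keep = ~((pp > 0) ^ (qq > 0))
    pp, qq = pp[keep], qq[keep]
    if pp.sum() == 0 or qq.sum() == 0:
        return (
            BinnedDensity(edges, np.array([])),
            BinnedDensity(edges, np.array([])),
        )
    return BinnedDensity(edges, pp / pp.sum()), BinnedDensity(edges, qq / qq.sum())


def _kld(p: np.ndarray, m: np.ndarray) -> float:
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / m[nz])))


def jsd(P, Q, name: str = "jsd") -> DivergenceResult:
    """Jensen–Shannon divergence of two scalar samples (natural log).

    JSD(P||Q) = (KLD(P||M) + KLD(Q||M)) / 2 with M the equal mixture,
    computed on the shared discretization.  If the bin-removal rule discards
    every bin the samples are treated as maximally divergent (ln 2).
    """
    p_vals, q_vals = _values(P), _values(Q)
    if p_vals.size == 0 or q_vals.size == 0:
        raise ValueError("jsd requires two non-empty samples")
    bp, bq = discretize(p_vals, q_vals)
    if bp.probs.size == 0:
        warnings.warn(
            "all shared bins discarded; reporting maximal divergence ln 2",
            stacklevel=2,
        )
        value = LN2
    else:
        m = (bp.probs + bq.probs) / 2.0
        value = 0.5 * _kld(bp.probs, m) + 0.5 * _kld(bq.probs, m)
        value = min(max(value, 0.0), LN2)  # clip solver-level float noise
    return DivergenceResult(
        summary_name=name, value=value, method="jsd",
        n_left=int(p_vals.size), n_right=int(q_vals.size),
    )


def l1_divergence(
    c1: CategoricalCounts,
    c2: CategoricalCounts,
    normalize: bool = False,
    name: str | None = None,
) -> DivergenceResult:
    """Sum of absolute count (or relative-frequency) differences.

    Iterates over the union of categories; categories absent from one side
    count as zero.  Normalization to relative frequencies is preferable when
    dataset sizes differ notably.
    """
    if c1.total == 0 and c2.total == 0:
        raise ValueError("both count sets are empty")
    a = c1.frequencies() if normalize else c1.counts
    b = c2.frequencies() if normalize else c2.counts
    cats = set(a) | set(b)
    value = float(sum(abs(a.get(c, 0) - b.get(c, 0)) for c in cats))
    return DivergenceResult(
        summary_name=name or c1.name, value=value, method="l1",
        n_left=c1.total, n_right=c2.total,
    )


def matrix_l1(m1: TransitionMatrix, m2: TransitionMatrix, name: str | None = None) -> DivergenceResult:
    """l1 divergence over the 16 row-normalized transition-matrix cells."""
    value = float(np.abs(m1.entries - m2.entries).sum())
    return DivergenceResult(
        summary_name=name or m1.name, value=value, method="l1",
        n_left=int(m1.counts.sum()), n_right=int(m2.counts.sum()),
    )


def divergence_for(spec_name: str, left, right, normalize_counts: bool = True) -> DivergenceResult:
    """Compare two already-computed summary results of the same summary."""
    spec = SUMMARY_REGISTRY[spec_name]
    if spec.kind == "scalar_dist":
        return jsd(left, right, name=spec_name)
    if spec.kind == "categorical":
        return l1_divergence(left, right, normalize=normalize_counts, name=spec_name)
    if spec.kind == "matrix":
        return matrix_l1(left, right, name=spec_name)
    if spec.kind == "scalar":
        return DivergenceResult(
            summary_name=spec_name, value=abs(float(left) - float(right)),
            method="l1", n_left=1, n_right=1,
        )
    raise ValueError(f"unknown summary kind {spec.kind!r}")


def compare_repertoires(
    t1: RepertoireTable,
    t2: RepertoireTable,
    summaries: list[str] | str = "all",
    normalize_counts: bool = True,
) -> list[DivergenceResult]:
    """One divergence per summary computable on both tables.

    Summaries above the shared capability level (or failing on either table,
    e.g. no insertions of length >= 2) are reported as skipped rather than
    raised.
    """
    shared = min(capability(t1), capability(t2))
    if summaries == "all":
        names = list(SUMMARY_REGISTRY)
    else:
        names = list(summaries)
        unknown = [n for n in names if n not in SUMMARY_REGISTRY]
        if unknown:
            raise ValueError(f"unknown summaries: {unknown}")
    results: list[DivergenceResult] = []
    for name in names:
        spec = SUMMARY_REGISTRY[name]
        if spec.level > shared:
            results.append(
                DivergenceResult(
                    name, float("nan"), method="", skipped=True,
                    reason=f"requires capability {spec.level.name}, have {shared.name}",
                )
            )
            continue
        try:
            left = spec.compute(t1)
            right = spec.compute(t2)
            results.append(divergence_for(name, left, right, normalize_counts))
        except (EmptySummaryError, ValueError) as e:
            results.append(
                DivergenceResult(name, float("nan"), method="", skipped=True, reason=str(e))
            )
    if all(r.skipped for r in results):
        raise ValueError("no summary computable on both tables")
    return results


def results_to_frame(results: list[DivergenceResult]) -> pd.DataFrame:
    """Tidy frame (summary, method, value, n_left, n_right, skipped, reason)."""
    return pd.DataFrame(
        {
            "summary": [r.summary_name for r in results],
            "method": [r.method for r in results],
            "value": [r.value for r in results],
            "n_left": [r.n_left for r in results],
            "n_right": [r.n_right for r in results],
            "skipped": [r.skipped for r in results],
            "reason": [r.reason for r in results],
        }
    )
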