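"""Scoring generative repertoire simulators and embedding divergence matrices.

A simulator fitted to k observed repertoires produces k paired simulations.
For each summary s, the log relative average divergence compares the mean
divergence across repertoires to the mean divergence within observed/
simulated pairs:

    LRAD-data(s) = ln( mean_{i != j} D_s(R_i_obs, R_j_obs)
                       / mean_i D_s(R_i_obs, R_i_sim) )

LRAD-sim replaces the numerator pairs with simulated-simulated pairs.  A
positive score means simulations look more like their own observations than
repertoires look like each other — the summary is well replicated; both
scores share the same denominator, so data- and sim-based views are
directly comparable.

Divergence matrices over collections of repertoires are embedded with
classical (Torgerson) multidimensional scaling for visualization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .airr_io import RepertoireTable
from .divergence import SUMMARY_REGISTRY, divergence_for
from .summaries import EmptySummaryError

__all__ = [
    "PairedRepertoireSet",
    "LRADScore",
    "DivergenceMatrix",
    "ScoreReport",
    "lrad",
    "score_report",
    "divergence_matrix",
    "mds_embed",
]


@dataclass
class PairedRepertoireSet:
    """k observed repertoires, each with its simulated counterpart."""

    pairs: list[tuple[RepertoireTable, RepertoireTable]]

    def __post_init__(self) -> None:
        if len(self.pairs) < 2:
            raise ValueError("LRAD numerators need >= 2 observed/simulated pairs")

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def observed(self) -> list[RepertoireTable]:
        return [o for o, _ in self.pairs]

    @property
    def simulated(self) -> list[RepertoireTable]:
        return [s for _, s in self.pairs]


@dataclass
class LRADScore:
    summary_name: str
    mode: str  # data | sim
    value: float  # may be +/-inf or nan (undefined: both means zero)
    numerator_mean: float
    denominator_mean: float


@dataclass
class DivergenceMatrix:
    labels: list[str]
    D: np.ndarray
    summary_name: str = ""

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.D, self.D.T, atol=1e-9):
            raise ValueError("divergence matrix must be symmetric")
        if np.any(np.diag(self.D) != 0):
            raise ValueError("divergence matrix diagonal must be zero")
        if np.any(self.D < 0):
            raise ValueError("divergences must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)


@dataclass
class ScoreReport:
    scores: list[LRADScore] = field(default_factory=list)
    skipped: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for s in self.scores:
            row = rows.setdefault(
                s.summary_name, {"summary": s.summary_name}
            )
            row[f"lrad_{s.mode}"] = s.value
            row[f"numerator_{s.mode}"] = s.numerator_mean
            row["denominator"] = s.denominator_mean
        df = pd.DataFrame(rows.values())
        return df.sort_values("lrad_data", ascending=False).reset_index(drop=True)


def _pair_divergence(summary: str, t1: RepertoireTable, t2: RepertoireTable) -> float:
    spec = SUMMARY_REGISTRY[summary]
    return divergence_for(summary, spec.compute(t1), spec.compute(t2)).value


def _log_ratio(num: float, den: float) -> float:
    if num > 0 and den > 0:
        return math.log(num / den)
    if den == 0 and num > 0:
        return math.inf
    if num == 0 and den > 0:
        return -math.inf
    return math.nan  # both zero: undefined


def lrad_from_divergences(
    cross: list[float], within: list[float], summary: str = "", mode: str = "data"
) -> LRADScore:
    """LRAD from precomputed cross-pair and within-pair divergences."""
    num = float(np.mean(cross))
    den = float(np.mean(within))
    return LRADScore(
        summary_name=summary, mode=mode, value=_log_ratio(num, den),
        numerator_mean=num, denominator_mean=den,
    )


def lrad(pairs: PairedRepertoireSet, summary: str, mode: str = "data") -> LRADScore:
    """Log relative average divergence of one summary.

    Denominator: mean within-pair divergence D_s(R_i_obs, R_i_sim).
    Numerator: mean cross-pair divergence over observed (mode="data") or
    simulated (mode="sim") repertoires; since D_s is symmetric, the ordered
    double sum with its 2/(k(k-1)) weight equals the unordered-pair mean.
    """
    if mode not in ("data", "sim"):
        raise ValueError("mode must be 'data' or 'sim'")
    if summary not in SUMMARY_REGISTRY:
        raise ValueError(f"unknown summary {summary!r}")
    within = [_pair_divergence(summary, o, s) for o, s in pairs.pairs]
    cross_tables = pairs.observed if mode == "data" else pairs.simulated
    cross = [
        _pair_divergence(summary, a, b) for a, b in combinations(cross_tables, 2)
    ]
    return lrad_from_divergences(cross, within, summary=summary, mode=mode)


def score_report(
    pairs: PairedRepertoireSet, summaries: list[str] | str = "all"
) -> ScoreReport:
    """LRAD-data and LRAD-sim per computable summary, sorted by LRAD-data.

    Summaries unavailable on any of the 2k tables are listed as skipped
    with the failure reason.
    """
    names = list(SUMMARY_REGISTRY) if summaries == "all" else list(summaries)
    report = ScoreReport()
    for name in names:
        try:
            data_score = lrad(pairs, name, "data")
            sim_score = lrad(pairs, name, "sim")
            report.scores.extend([data_score, sim_score])
        except (EmptySummaryError, ValueError) as e:
            report.skipped[name] = str(e)
    if not report.scores:
        raise ValueError("no summary computable on the paired set")
    return report


def divergence_matrix(
    tables: list[RepertoireTable],
    summary: str,
    labels: list[str] | None = None,
) -> DivergenceMatrix:
    """Pairwise divergence matrix of one summary over >= 2 repertoires.

    Each unordered pair is computed once and mirrored, so the matrix is
    exactly symmetric with a zero diagonal.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 tables")
    labels = labels or [f"repertoire_{i}" for i in range(len(tables))]
    spec = SUMMARY_REGISTRY[summary]
    computed = [spec.compute(t) for t in tables]
    n = len(tables)
    D = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        D[i, j] = D[j, i] = divergence_for(summary, computed[i], computed[j]).value
    return DivergenceMatrix(labels=labels, D=D, summary_name=summary)


def mds_embed(D: DivergenceMatrix | np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS coordinates of a dissimilarity matrix.

    Double-centers the squared dissimilarities and takes the top
    eigenvectors scaled by the square roots of their (nonnegative)
    eigenvalues; coordinates are centered at the origin, and Euclidean
    distances reproduce a Euclidean-realizable D exactly when dims is
    sufficient.
    """
    mat = D.D if isinstance(D, DivergenceMatrix) else np.asarray(D, dtype=float)
    n = mat.shape[0]
    if dims >= n:
        raise ValueError("dims must be smaller than the number of labels")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (mat**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:dims]
    lam = np.clip(eigval[order], 0.0, None)
    lam[lam < 1e-12 * max(lam.max(), 1.0)] = 0.0  # degenerate axes carry no spread
    coords = eigvec[:, order] * np.sqrt(lam)
    return coords
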