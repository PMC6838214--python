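"""Ranking sequence-level summaries by how well they discriminate datasets.

The covariates of a multinomial l1-penalized (lasso) regression are
per-sequence summary values pooled over datasets; the response is dataset
identity.  As the regularization weight shrinks along a decreasing grid,
coefficients "branch off" from zero one by one, and the branch-off order is
a natural informativeness ordering: a summary whose coefficient activates
early (at a large penalty) carries more discriminative signal.  Because the
multinomial fit yields one coefficient vector per dataset class, per-class
orderings are aggregated by their median, and ties are broken by seeded
randomization to avoid alphabetization artifacts.

Only sequence-level summaries (exactly one value per sequence) are valid
covariates — a pairwise-distance distribution has no per-row representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .airr_io import RepertoireTable
from .summaries import SUMMARY_REGISTRY, sequence_level_summaries, sequence_level_values

__all__ = [
    "DesignMatrix",
    "RankResult",
    "build_design_matrix",
    "default_lambda_grid",
    "rank_summaries",
]

#: Coefficient magnitudes below this absorb solver noise and count as zero.
NONZERO_TOL = 1e-8


@dataclass
class DesignMatrix:
    """Standardized per-sequence summary values with dataset labels."""

    X: np.ndarray
    y: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X rows and y labels must align")
        if np.isnan(self.X).any():
            raise ValueError("design matrix contains missing entries")
        if np.unique(self.y).size < 2:
            raise ValueError("need >= 2 distinct dataset labels")

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.y).size)


@dataclass
class RankResult:
    """Final ranks (1 = most informative) with per-class detail."""

    ranks: dict[str, int]
    per_class_ranks: pd.DataFrame  # rows: classes, columns: summaries
    branch_lambdas: pd.DataFrame  # t_{d,s}: largest stable-activation lambda
    median_ranks: dict[str, float]


def build_design_matrix(
    tables: list[RepertoireTable],
    summaries: list[str] | None = None,
    include_factors: bool = False,
) -> DesignMatrix:
    """Stack per-sequence summary values over datasets and standardize.

    Kidera and Atchley factor components are excluded by default (they are
    orthogonal-by-construction descriptor sets; re-include with
    ``include_factors=True``).  Rows with any missing summary value are
    dropped; zero-variance columns are dropped with a warning.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 datasets")
    if summaries is None:
        summaries = sequence_level_summaries(include_factors=include_factors)
    for name in summaries:
        spec = SUMMARY_REGISTRY.get(name)
        if spec is None:
            raise ValueError(f"unknown summary {name!r}")
        if not spec.sequence_level:
            raise ValueError(
                f"{name!r} is not a sequence-level summary; only sequence-level "
                "summary statistics can be used as covariates"
            )
    blocks = []
    labels = []
    for d, table in enumerate(tables):
        block = pd.DataFrame(
            {name: sequence_level_values(table, name) for name in summaries}
        )
        blocks.append(block)
        labels.append(np.full(len(table), d))
    X = pd.concat(blocks, ignore_index=True)
    y = np.concatenate(labels)
    keep_rows = X.notna().all(axis=1).to_numpy()
    X, y = X.loc[keep_rows], y[keep_rows]
    sd = X.std(ddof=0)
    dead = sd[sd == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping zero-variance column(s): {dead}", stacklevel=2)
        X = X.drop(columns=dead)
    Xs = (X - X.mean()) / X.std(ddof=0)
    return DesignMatrix(Xs.to_numpy(), y, list(X.columns))


def default_lambda_grid(design: DesignMatrix, n_lambdas: int = 100, ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced decreasing grid from the KKT lambda_max down to ratio*max.

    lambda_max is the smallest penalty at which every coefficient is zero:
    max over classes d and columns s of |X_s . (1{y=d} - pi_d)| / n.
    """
    X, y = design.X, design.y
    n = X.shape[0]
    classes = np.unique(y)
    lam_max = 0.0
    for d in classes:
        resid = (y == d).astype(float) - np.mean(y == d)
        lam_max = max(lam_max, np.abs(X.T @ resid).max() / n)
    if lam_max <= 0:
        raise ValueError("degenerate design: lambda_max is zero")
    return np.geomspace(lam_max, ratio * lam_max, n_lambdas)


def _lasso_path(design: DesignMatrix, lambdas: np.ndarray) -> np.ndarray:
    """Multinomial l1 coefficient path.

    Returns an array of shape (n_lambdas, n_classes, n_features).
    """
    X, y = design.X, design.y
    n = X.shape[0]
    model = LogisticRegression(
        l1_ratio=1.0, solver="saga", C=1.0, max_iter=5000,
        warm_start=True, tol=1e-6, fit_intercept=True,
    )
    coefs = np.empty((len(lambdas), design.n_classes, X.shape[1]))
    for i, lam in enumerate(lambdas):
        model.C = 1.0 / (n * lam)
        with warnings.catch_warnings():
            # branch-off detection only needs the active set, which settles
            # well before full coefficient convergence at path ends
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X, y)
        if model.coef_.shape[0] == design.n_classes:
            coefs[i] = model.coef_
        else:  # binary fit returns a single contrast vector
            coefs[i] = np.vstack([-model.coef_, model.coef_])
    return coefs


def _branch_lambdas(coefs: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """t_{d,s}: largest grid lambda at which beta_{d,s} is nonzero and stays
    nonzero for every smaller grid lambda; NaN when never stably active."""
    n_lam, n_cls, n_feat = coefs.shape
    active = np.abs(coefs) > NONZERO_TOL  # (lam, class, feat)
    t = np.full((n_cls, n_feat), np.nan)
    for d in range(n_cls):
        for s in range(n_feat):
            stable_from = None
            # scan from smallest lambda upward; the stable activation point is
            # the largest lambda index i such that active for all j >= i
            for i in range(n_lam - 1, -1, -1):
                if active[i, d, s]:
                    stable_from = i
                else:
                    break
            if stable_from is not None:
                t[d, s] = lambdas[stable_from]
    return t


def _rank_with_ties(values: np.ndarray, rng: np.random.Generator, larger_better: bool) -> np.ndarray:
    """Dense 1..n ranks; NaN ranks strictly worst; ties seeded-randomized."""
    n = values.size
    key = np.where(np.isnan(values), -np.inf if larger_better else np.inf, values)
    if larger_better:
        key = -key
    jitter = rng.random(n)
    order = np.lexsort((jitter, key))
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def rank_summaries(
    design: DesignMatrix,
    lambdas: np.ndarray | None = None,
    seed: int = 0,
    n_lambdas: int = 100,
) -> RankResult:
    """Rank summaries by their lasso-path branch-off order.

    Fits the l1 multinomial path over a strictly decreasing lambda grid,
    finds each (class, summary) branch-off penalty, ranks summaries within
    each class (earlier branch-off = better rank, never-active worst), and
    ranks the per-summary medians across classes for the final ordering.
    All ties are broken by seeded randomization.
    """
    if lambdas is None:
        lambdas = default_lambda_grid(design, n_lambdas=n_lambdas)
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size < 2 or np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda grid must be strictly decreasing with >= 2 values")
    rng = np.random.default_rng(seed)
    coefs = _lasso_path(design, lambdas)
    t = _branch_lambdas(coefs, lambdas)
    classes = [f"class_{d}" for d in range(design.n_classes)]
    per_class = np.vstack(
        [_rank_with_ties(t[d], rng, larger_better=True) for d in range(t.shape[0])]
    )
    medians = np.median(per_class, axis=0)
    final = _rank_with_ties(medians, rng, larger_better=False)
    names = design.column_names
    return RankResult(
        ranks={s: int(r) for s, r in zip(names, final)},
        per_class_ranks=pd.DataFrame(per_class, index=classes, columns=names),
        branch_lambdas=pd.DataFrame(t, index=classes, columns=names),
        median_ranks={s: float(m) for s, m in zip(names, medians)},
    )
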