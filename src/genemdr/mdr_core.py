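"""Generalized-MDR engine.

Multifactor dimensionality reduction (MDR) pools the cells of a multi-locus
genotype table into two classes, high risk and low risk, and evaluates the
resulting one-dimensional classifier by balanced accuracy under k-fold
cross-validation.  The generalized form used here replaces raw case/control
counts with per-sample scores s_i = y_i - p_hat_i, the residuals of a null
logistic model of phenotype on covariates only, so that covariates (sex, age,
principal components, ...) are adjusted without entering the genotype search.
A cell is labeled high risk iff the sum of its samples' scores is positive;
with no covariates this reduces exactly to the classic MDR rule that compares
the cell case/control ratio to the overall case/control ratio.

Two selection statistics are produced for every attribute combination:

* cross-validation consistency (CVC): the number of folds in which the
  combination is the fold's best model (highest training balanced accuracy);
* mean test balanced accuracy: the average over folds of the held-out
  balanced accuracy.

The best combination has the highest CVC; CVC ties are broken by mean test
balanced accuracy, then by the lexicographic order of the sorted attribute-id
tuple so the search is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: score sums within this tolerance of zero are treated as exact ties -> low risk
TIE_ATOL = 1e-9


class PerfectSeparationError(RuntimeError):
    """Null logistic model could not be fit (separation / non-convergence)."""


# ---------------------------------------------------------------------------
# covariate-adjusted scores
# ---------------------------------------------------------------------------

def null_model_scores(
    phenotype: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> np.ndarray:
    """Per-sample scores s_i = y_i - p_hat_i from the null phenotype model.

    ``p_hat`` comes from a maximum-likelihood logistic fit of phenotype on the
    covariates plus an intercept; with no covariates it is the overall case
    proportion.  The score equation of the MLE forces ``sum(s) == 0`` (to
    numerical tolerance), which in turn guarantees that the all-high and
    all-low cell labelings are essentially unreachable.
    """
    y = np.asarray(phenotype, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("phenotype must contain both classes")
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        return y - y.mean()

    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    if X.shape[0] != y.shape[0]:
        raise ValueError("covariates and phenotype have different lengths")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < X.shape[1] + 1:
        raise ValueError("covariate columns are collinear (including intercept)")

    design = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as exc:  # statsmodels raises various convergence errors
        raise PerfectSeparationError(
            f"null logistic model failed ({exc}); offending covariate likely "
            f"among {_separating_covariates(y, X, names) or names}"
        ) from exc
    p_hat = np.asarray(fit.fittedvalues, dtype=float)
    if not np.all(np.isfinite(p_hat)) or p_hat.min() <= 1e-10 or p_hat.max() >= 1 - 1e-10:
        raise PerfectSeparationError(
            "null logistic model shows (quasi-)perfect separation; offending "
            f"covariate likely among {_separating_covariates(y, X, names) or names}"
        )
    return y - p_hat


def _separating_covariates(y: np.ndarray, X: np.ndarray, names: list[str]) -> list[str]:
    """Heuristic: covariates whose case/control ranges do not overlap."""
    out = []
    for j, name in enumerate(names):
        a, b = X[y == 1, j], X[y == 0, j]
        if a.min() > b.max() or b.min() > a.max():
            out.append(name)
    return out


# ---------------------------------------------------------------------------
# cell labeling and balanced accuracy
# ---------------------------------------------------------------------------

def _radices(columns: np.ndarray) -> np.ndarray:
    """Number of levels per attribute column (levels are small non-negative ints)."""
    columns = np.asarray(columns)
    if columns.ndim != 2:
        raise ValueError("attribute columns must be 2-D (samples x attributes)")
    if columns.min(initial=0) < 0:
        raise ValueError("attribute levels must be non-negative integers")
    return columns.max(axis=0).astype(np.int64) + 1


def _encode_cells(columns: np.ndarray, radices: np.ndarray) -> tuple[np.ndarray, int]:
    """Mixed-radix cell index per sample and total number of cells."""
    columns = np.asarray(columns, dtype=np.int64)
    idx = np.zeros(columns.shape[0], dtype=np.int64)
    n_cells = 1
    for j in range(columns.shape[1]):
        idx = idx * radices[j] + columns[:, j]
        n_cells *= int(radices[j])
    return idx, n_cells


@dataclass
class CellLabels:
    """High/low-risk labeling of the full cell space of an attribute tuple.

    ``high`` is a boolean array over all mixed-radix cells; cells never seen
    during fitting keep the default low label (predict control).
    """

    radices: np.ndarray
    high: np.ndarray
    observed: np.ndarray  # cells with >=1 fitting sample

    def predict(self, columns: np.ndarray) -> np.ndarray:
        idx, _ = _encode_cells(columns, self.radices)
        return self.high[idx]

    def as_dict(self) -> dict[tuple[int, ...], str]:
        """Mapping level-tuple -> 'high'/'low' for every observed cell."""
        out: dict[tuple[int, ...], str] = {}
        for cell in np.flatnonzero(self.observed):
            levels = []
            rem = int(cell)
            for r in self.radices[::-1]:
                levels.append(rem % int(r))
                rem //= int(r)
            out[tuple(reversed(levels))] = "high" if self.high[cell] else "low"
        return out


def classify_cells(
    columns: np.ndarray,
    scores: np.ndarray,
    sample_idx: np.ndarray | None = None,
    radices: np.ndarray | None = None,
) -> CellLabels:
    """Label every cell of the attribute combination high or low risk.

    A cell is high risk iff the sum of the scores of its samples (restricted
    to ``sample_idx`` when given) exceeds zero; exact ties and unobserved
    cells are low.  ``radices`` may be passed to fix the cell space from the
    full data when fitting on a training subset.
    """
    columns = np.asarray(columns)
    scores = np.asarray(scores, dtype=float)
    if radices is None:
        radices = _radices(columns)
    idx, n_cells = _encode_cells(columns, radices)
    if sample_idx is not None:
        sample_idx = np.asarray(sample_idx)
        if sample_idx.dtype == bool:
            sample_idx = np.flatnonzero(sample_idx)
        if sample_idx.size == 0:
            raise ValueError("empty sample set")
        idx_fit = idx[sample_idx]
        s_fit = scores[sample_idx]
    else:
        if columns.shape[0] == 0:
            raise ValueError("empty sample set")
        idx_fit, s_fit = idx, scores
    sums = np.bincount(idx_fit, weights=s_fit, minlength=n_cells)
    counts = np.bincount(idx_fit, minlength=n_cells)
    return CellLabels(radices=radices, high=sums > TIE_ATOL, observed=counts > 0)


def balanced_accuracy(
    labels: CellLabels,
    columns: np.ndarray,
    phenotype: np.ndarray,
    sample_idx: np.ndarray | None = None,
) -> float:
    """(sensitivity + specificity) / 2 of the high/low-risk classifier.

    Samples in high cells are predicted cases, all others controls.
    """
    phenotype = np.asarray(phenotype)
    pred = labels.predict(np.asarray(columns))
    if sample_idx is not None:
        sample_idx = np.asarray(sample_idx)
        if sample_idx.dtype == bool:
            sample_idx = np.flatnonzero(sample_idx)
        pred = pred[sample_idx]
        phenotype = phenotype[sample_idx]
    is_case = phenotype == 1
    n_case = int(is_case.sum())
    n_ctrl = int((~is_case).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("balanced accuracy undefined: sample set lacks a phenotype class")
    tp = int((pred & is_case).sum())
    tn = int((~pred & ~is_case).sum())
    sens = tp / n_case
    spec = tn / n_ctrl
    return (sens + spec) / 2.0


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVPlan:
    """Stratified k-fold assignment: ``fold[i]`` is sample i's fold index."""

    k: int
    fold: np.ndarray
    seed: int

    def train_mask(self, f: int) -> np.ndarray:
        return self.fold != f

    def test_mask(self, f: int) -> np.ndarray:
        return self.fold == f


def make_cv_plan(phenotype: np.ndarray, k: int = 10, seed: int = 0) -> CVPlan:
    """Case/control-stratified fold assignment from a seeded shuffle.

    Stratification guarantees every fold contains both classes (hence balanced
    accuracy is defined per fold), which requires at least ``k`` samples of
    each class.
    """
    phenotype = np.asarray(phenotype)
    rng = np.random.default_rng(seed)
    fold = np.empty(len(phenotype), dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(phenotype == cls)
        if len(idx) < k:
            raise ValueError(
                f"stratified {k}-fold CV needs >= {k} samples of class {cls}, "
                f"got {len(idx)}"
            )
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return CVPlan(k=k, fold=fold, seed=seed)


@dataclass
class CVResult:
    """Per-fold training and test balanced accuracies for one attribute set."""

    train_ba: np.ndarray
    test_ba: np.ndarray

    @property
    def mean_test_ba(self) -> float:
        return float(self.test_ba.mean())

    @property
    def mean_train_ba(self) -> float:
        return float(self.train_ba.mean())


def cross_validate(
    columns: np.ndarray,
    scores: np.ndarray,
    phenotype: np.ndarray,
    plan: CVPlan,
) -> CVResult:
    """Fit the cell labeling on each training split and score train/test BA.

    Cells of the test fold never observed in training keep the low label.
    """
    columns = np.asarray(columns)
    radices = _radices(columns)
    train_ba = np.empty(plan.k)
    test_ba = np.empty(plan.k)
    for f in range(plan.k):
        tr = np.flatnonzero(plan.train_mask(f))
        te = np.flatnonzero(plan.test_mask(f))
        labels = classify_cells(columns, scores, sample_idx=tr, radices=radices)
        train_ba[f] = balanced_accuracy(labels, columns, phenotype, sample_idx=tr)
        test_ba[f] = balanced_accuracy(labels, columns, phenotype, sample_idx=te)
    return CVResult(train_ba=train_ba, test_ba=test_ba)


# ---------------------------------------------------------------------------
# exhaustive combination search
# ---------------------------------------------------------------------------

@dataclass
class RiskModel:
    """A fitted MDR classifier for one attribute combination."""

    attributes: tuple[str, ...]
    labels: CellLabels  # refit on all samples
    train_ba: np.ndarray
    test_ba: np.ndarray

    @property
    def mean_test_ba(self) -> float:
        return float(self.test_ba.mean())

    @property
    def order(self) -> int:
        return len(self.attributes)


@dataclass
class SearchResult:
    """Outcome of an exhaustive combination search."""

    best: RiskModel
    cvc: int
    mean_test_ba: float
    evaluated: int
    fold_winners: list[tuple[str, ...]] = field(default_factory=list)


def count_combinations(p: int, m: int) -> int:
    """Exact C(p, m) with arbitrary-precision integer arithmetic."""
    if m < 0 or p < 0:
        raise ValueError("p and m must be non-negative")
    if m > p:
        raise ValueError(f"order m={m} exceeds number of attributes p={p}")
    return math.comb(p, m)


def _enumerate_combos(
    ids: Sequence[str], orders: Iterable[int]
) -> list[tuple[str, ...]]:
    """All combinations, ascending order then lexicographic within an order.

    This enumeration order, together with strict ``>`` comparisons on training
    BA, realizes the tie-break rule: smaller order wins, then the
    lexicographically smallest attribute tuple.
    """
    ids = sorted(ids)
    orders = sorted(set(orders))
    if not orders:
        raise ValueError("orders must be non-empty")
    if orders[0] < 1:
        raise ValueError("orders must be >= 1")
    if orders[-1] > len(ids):
        raise ValueError(
            f"max order {orders[-1]} exceeds number of candidates {len(ids)}"
        )
    out: list[tuple[str, ...]] = []
    for m in orders:
        out.extend(combinations(ids, m))
    return out


def search_best(
    candidates: Mapping[str, np.ndarray],
    orders: Iterable[int],
    scores: np.ndarray,
    phenotype: np.ndarray,
    plan: CVPlan,
) -> SearchResult:
    """Exhaustive search over attribute combinations of the given orders.

    For each fold the combination with the highest training balanced accuracy
    is the fold's winner; a combination's CVC is the number of folds it wins.
    The best combination maximizes (CVC, mean test BA) with a final
    lexicographic tie-break, and its cell labeling is refit on all samples.
    """
    if not candidates:
        raise ValueError("no candidate attributes")
    combos = _enumerate_combos(list(candidates), orders)
    scores = np.asarray(scores, dtype=float)
    phenotype = np.asarray(phenotype)

    cols_cache = {cid: np.asarray(col) for cid, col in candidates.items()}
    train_idx = [np.flatnonzero(plan.train_mask(f)) for f in range(plan.k)]

    # pass 1: per-fold training-BA winners
    best_ba = np.full(plan.k, -1.0)
    winner: list[tuple[str, ...] | None] = [None] * plan.k
    for combo in combos:
        columns = np.column_stack([cols_cache[c] for c in combo])
        radices = _radices(columns)
        for f in range(plan.k):
            tr = train_idx[f]
            labels = classify_cells(columns, scores, sample_idx=tr, radices=radices)
            ba = balanced_accuracy(labels, columns, phenotype, sample_idx=tr)
            if ba > best_ba[f]:
                best_ba[f] = ba
                winner[f] = combo

    # pass 2: cross-validate the distinct winners only
    winners = sorted({w for w in winner if w is not None}, key=lambda t: (len(t), t))
    stats: dict[tuple[str, ...], tuple[int, CVResult]] = {}
    for combo in winners:
        columns = np.column_stack([cols_cache[c] for c in combo])
        cvres = cross_validate(columns, scores, phenotype, plan)
        cvc = sum(1 for w in winner if w == combo)
        stats[combo] = (cvc, cvres)

    best_combo = min(
        winners,
        key=lambda c: (-stats[c][0], -stats[c][1].mean_test_ba, tuple(sorted(c))),
    )
    cvc, cvres = stats[best_combo]
    columns = np.column_stack([cols_cache[c] for c in best_combo])
    labels = classify_cells(columns, scores)  # refit on all samples
    model = RiskModel(
        attributes=best_combo,
        labels=labels,
        train_ba=cvres.train_ba,
        test_ba=cvres.test_ba,
    )
    return SearchResult(
        best=model,
        cvc=cvc,
        mean_test_ba=cvres.mean_test_ba,
        evaluated=len(combos) * plan.k,
        fold_winners=[w for w in winner if w is not None],
    )
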