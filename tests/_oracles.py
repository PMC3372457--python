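"""Independent, deliberately naive reference implementations used as oracles.

Everything here is loop/dict based and shares no code with the package: cells
are dict keys, confusion matrices are integer counts, and the classic-MDR
rule is evaluated in exact integer arithmetic.  Balanced accuracies are
computed with the same arithmetic expression (sens + spec) / 2 so that exact
float comparison against the package is meaningful.

Note on thresholds: with no covariates the residual score is y - pbar with
pbar the FULL-data case proportion, so a training-subset cell is high risk
iff nc/nu exceeds the full-data case/control ratio (not the subset's own).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def cell_counts(columns, phenotype):
    """dict cell-tuple -> (n_cases, n_controls) over the given samples."""
    cells = {}
    for row, y in zip(np.asarray(columns).tolist(), list(phenotype)):
        key = tuple(row)
        nc, nu = cells.get(key, (0, 0))
        cells[key] = (nc + (y == 1), nu + (y == 0))
    return cells


def ratio_threshold_labels(columns, phenotype, total_case, total_ctrl):
    """Classic MDR: a cell is high risk iff its case/control ratio exceeds
    total_case/total_ctrl, in exact integer arithmetic; ties are low.

    Returns dict cell-tuple -> 'high'/'low' over observed cells.
    """
    out = {}
    for key, (nc, nu) in cell_counts(columns, phenotype).items():
        # nc/nu > total_case/total_ctrl  <=>  nc*total_ctrl > nu*total_case
        out[key] = "high" if nc * total_ctrl > nu * total_case else "low"
    return out


def ba_from_labels(labels, columns, phenotype):
    """Balanced accuracy of a cell labeling; unobserved cells predict low."""
    tp = fn = tn = fp = 0
    for row, y in zip(np.asarray(columns).tolist(), list(phenotype)):
        pred_case = labels.get(tuple(row), "low") == "high"
        if y == 1:
            tp += pred_case
            fn += not pred_case
        else:
            fp += pred_case
            tn += not pred_case
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return (sens + spec) / 2


def brute_force_search(candidates, orders, phenotype, fold, k):
    """Exhaustive re-enumeration of the cross-validated MDR search.

    ``candidates``: dict id -> genotype column.  No covariates: the high/low
    rule is the exact-integer full-data case/control-ratio threshold, which
    is what the residual-score rule reduces to.  Tie-breaks follow the
    documented rules: per-fold winner = first combo (ascending order,
    lexicographic) with strictly greater training BA; final best maximizes
    (CVC, mean test BA) with a lexicographic tie-break.

    Returns (per-fold winners, best combo, cvc, mean test BA of best).
    """
    phenotype = list(phenotype)
    n = len(phenotype)
    total_case = sum(1 for y in phenotype if y == 1)
    total_ctrl = n - total_case
    ids = sorted(candidates)
    combos = []
    for m in sorted(set(orders)):
        combos.extend(combinations(ids, m))

    def cols(combo):
        return np.column_stack([candidates[c] for c in combo])

    def fit_and_score(combo, fit_idx, eval_idx):
        c = np.asarray(cols(combo))
        labels = ratio_threshold_labels(
            c[fit_idx], [phenotype[i] for i in fit_idx], total_case, total_ctrl
        )
        return ba_from_labels(labels, c[eval_idx], [phenotype[i] for i in eval_idx])

    winners = []
    for f in range(k):
        tr = [i for i in range(n) if fold[i] != f]
        best_ba, best_combo = -1.0, None
        for combo in combos:
            ba = fit_and_score(combo, tr, tr)
            if ba > best_ba:
                best_ba, best_combo = ba, combo
        winners.append(best_combo)

    def mean_test_ba(combo):
        bas = []
        for f in range(k):
            tr = [i for i in range(n) if fold[i] != f]
            te = [i for i in range(n) if fold[i] == f]
            bas.append(fit_and_score(combo, tr, te))
        return float(np.mean(bas))

    distinct = sorted(set(winners), key=lambda t: (len(t), t))
    scored = {c: (winners.count(c), mean_test_ba(c)) for c in distinct}
    best = min(distinct, key=lambda c: (-scored[c][0], -scored[c][1], tuple(sorted(c))))
    return winners, best, scored[best][0], scored[best][1]


def max_achievable_ba(columns, phenotype):
    """Best balanced accuracy over all cell labelings: label a cell high iff
    it gains more sensitivity than it loses specificity."""
    phenotype = list(phenotype)
    n_case = sum(1 for y in phenotype if y == 1)
    n_ctrl = len(phenotype) - n_case
    cells = cell_counts(columns, phenotype)
    sens = sum(nc for nc, nu in cells.values() if nc * n_ctrl > nu * n_case) / n_case
    spec = sum(nu for nc, nu in cells.values() if nc * n_ctrl <= nu * n_case) / n_ctrl
    return (sens + spec) / 2
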