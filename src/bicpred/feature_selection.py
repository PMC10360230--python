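"""Two-phase feature selection.

Phase 1 is a loose univariate screen designed to discard clearly
uninformative features without risking the removal of potentially
relevant genes: a two-sided Wilcoxon rank-sum test of the two
class-conditional distributions, and a permutation test on the mutual
information between each feature and the outcome, combined at a
significance threshold of 0.1 (union rule by default: a feature survives
if *either* test is significant). Expression data are heavy-tailed and
mostly non-normal — :func:`normality_screen` quantifies this — which is
why both phase-1 criteria are distribution-free.

Phase 2 is SVM-RFE: recursive feature elimination ranked by the squared
weights of a linear soft-margin SVM, iterated down to a compact
signature (14 features by default).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.feature_selection import mutual_info_classif
from sklearn.svm import SVC

from .cohort import CLINICAL_COLUMNS, ExpressionCohort

logger = logging.getLogger("bicpred")

__all__ = [
    "SelectionResult",
    "normality_screen",
    "wilcoxon_pvalues",
    "mi_permutation_pvalues",
    "univariate_filter",
    "svm_rfe",
    "select_features",
    "cohort_feature_matrix",
]


@dataclass
class SelectionResult:
    """Audit trail of both selection phases.

    ``rfe_ranking`` assigns rank 1 to features retained to the end and
    increasing ranks to features eliminated in later-to-earlier rounds;
    features never entering RFE (phase-1 casualties, or clinical
    covariates when excluded) carry rank 0.
    """

    feature_ids: list[str]
    pvalues_wilcoxon: np.ndarray
    pvalues_mi: np.ndarray
    phase1_mask: np.ndarray
    rfe_ranking: np.ndarray
    selected: list[str]

    def to_json(self, path) -> None:
        payload = {
            "feature_ids": self.feature_ids,
            "pvalues_wilcoxon": np.asarray(self.pvalues_wilcoxon).tolist(),
            "pvalues_mi": np.asarray(self.pvalues_mi).tolist(),
            "phase1_mask": np.asarray(self.phase1_mask).astype(bool).tolist(),
            "rfe_ranking": np.asarray(self.rfe_ranking).astype(int).tolist(),
            "selected": self.selected,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def cohort_feature_matrix(
    cohort: ExpressionCohort, include_clinical: bool = True
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """(X, feature ids, is_clinical mask) with clinical covariates
    appended after the gene columns (they compete in phase 1 too)."""
    if include_clinical:
        clin, cols = cohort.clinical_matrix()
        X = np.hstack([cohort.expr, clin])
        ids = list(cohort.gene_ids) + list(cols)
        is_clin = np.array([False] * cohort.n_genes + [True] * len(cols))
    else:
        X = cohort.expr.copy()
        ids = list(cohort.gene_ids)
        is_clin = np.zeros(cohort.n_genes, dtype=bool)
    return X, ids, is_clin


def normality_screen(
    cohort: ExpressionCohort, alpha: float = 0.05
) -> tuple[float, np.ndarray]:
    """Fraction of genes rejecting Shapiro-Wilk normality at ``alpha``.

    Constant genes cannot be tested and are skipped (p = NaN), counted
    separately from the rejection fraction.
    """
    if cohort.n_samples < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 samples")
    pvals = np.full(cohort.n_genes, np.nan)
    n_const = 0
    for j in range(cohort.n_genes):
        x = cohort.expr[:, j]
        if np.ptp(x) == 0:
            n_const += 1
            continue
        pvals[j] = stats.shapiro(x).pvalue
    if n_const:
        logger.warning("normality_screen skipped %d constant genes", n_const)
    tested = ~np.isnan(pvals)
    frac = float((pvals[tested] < alpha).mean()) if tested.any() else 0.0
    return frac, pvals


def wilcoxon_pvalues(X: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p-value per feature for H0: y|z=0 ~ y|z=1.

    Uses exact enumeration when both class sizes are <= 8 and the feature
    has no ties, the tie-corrected normal approximation otherwise.
    """
    X = np.asarray(X, dtype=float)
    z = np.asarray(z).astype(int)
    if len(np.unique(z)) < 2:
        raise ValueError("outcome has a single class")
    x0, x1 = X[z == 0], X[z == 1]
    small = x0.shape[0] <= 8 and x1.shape[0] <= 8
    pvals = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        col0, col1 = x0[:, j], x1[:, j]
        no_ties = len(np.unique(np.concatenate([col0, col1]))) == len(col0) + len(col1)
        method = "exact" if (small and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(
            col0, col1, alternative="two-sided", method=method, use_continuity=False
        )
        pvals[j] = min(1.0, res.pvalue)
    return pvals


def mi_permutation_pvalues(
    X: np.ndarray,
    z: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    n_neighbors: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Mutual information with one-sided permutation p-values.

    MI(feature; z) is estimated with the k-nearest-neighbor estimator
    (k=3 by default) on *rank-transformed* features: MI is invariant to
    strictly monotone transforms, and working on ranks makes the estimate
    (hence the p-value) exactly so. The p-value follows the add-one
    convention p = (1 + #{MI_perm >= MI_obs}) / (1 + n_perm), so the
    smallest attainable p is 1/(1+n_perm), never zero.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    X = np.asarray(X, dtype=float)
    z = np.asarray(z).astype(int)
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    rng = np.random.default_rng(seed)
    jitter_seed = int(rng.integers(2**31 - 1))
    mi_obs = mutual_info_classif(
        ranks, z, n_neighbors=n_neighbors, random_state=jitter_seed
    )
    exceed = np.ones(X.shape[1])  # add-one numerator
    for _ in range(n_perm):
        zp = rng.permutation(z)
        mi_perm = mutual_info_classif(
            ranks, zp, n_neighbors=n_neighbors, random_state=jitter_seed
        )
        exceed += mi_perm >= mi_obs
    pvals = exceed / (1.0 + n_perm)
    return mi_obs, pvals


def univariate_filter(
    wilcoxon_p: np.ndarray,
    mi_p: np.ndarray,
    alpha: float = 0.1,
    mode: str = "union",
) -> np.ndarray:
    """Phase-1 retention mask at threshold ``alpha``.

    ``union`` (default) retains a feature when either test is below
    alpha — the permissive rule matching the screen's stated intent of
    not discarding potentially relevant genes; ``intersection`` requires
    both.
    """
    wilcoxon_p = np.asarray(wilcoxon_p)
    mi_p = np.asarray(mi_p)
    if wilcoxon_p.shape != mi_p.shape:
        raise ValueError("p-value vectors must have equal length")
    if mode == "union":
        return np.minimum(wilcoxon_p, mi_p) < alpha
    if mode == "intersection":
        return np.maximum(wilcoxon_p, mi_p) < alpha
    raise ValueError(f"unknown mode {mode!r}")


def svm_rfe(
    X: np.ndarray,
    z: np.ndarray,
    n_select: int = 14,
    step_fraction: float = 0.1,
    C: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Recursive feature elimination by linear-SVM squared weights.

    Features are standardized internally on the given data; each round a
    soft-margin linear SVM (default C=1) is fit and the lowest-|w|^2
    ``max(1, ceil(step_fraction * current))`` features are dropped, until
    ``n_select`` remain. Fully deterministic.

    Returns ``(selected_idx, ranking)`` where ranking is 1 for survivors
    and grows with earlier elimination.
    """
    X = np.asarray(X, dtype=float)
    z = np.asarray(z).astype(int)
    if len(np.unique(z)) < 2:
        raise ValueError("outcome has a single class")
    p = X.shape[1]
    if n_select > p:
        raise ValueError(f"n_select={n_select} exceeds {p} features")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    active = list(range(p))
    rounds: list[list[int]] = []
    while len(active) > n_select:
        svc = SVC(kernel="linear", C=C).fit(Xs[:, active], z)
        w2 = np.ravel(svc.coef_) ** 2
        n_rm = min(
            len(active) - n_select,
            max(1, math.ceil(step_fraction * len(active))),
        )
        worst = np.argsort(w2, kind="stable")[:n_rm]
        removed = sorted(active[i] for i in worst)
        rounds.append(removed)
        active = [f for f in active if f not in set(removed)]

    ranking = np.ones(p, dtype=int)
    for depth, removed in enumerate(reversed(rounds), start=2):
        for f in removed:
            ranking[f] = depth
    return np.array(active), ranking


def select_features(
    cohort: ExpressionCohort,
    alpha: float = 0.1,
    n_select: int = 14,
    mode: str = "union",
    n_perm: int = 999,
    seed: int = 0,
    step_fraction: float = 0.1,
    include_clinical: bool = True,
    rfe_include_clinical: bool = False,
) -> SelectionResult:
    """Run both phases end-to-end on a cohort.

    Clinical covariates compete in phase 1 alongside genes but are kept
    out of SVM-RFE by default (the final signature is genes-only unless
    ``rfe_include_clinical``). If phase 1 retains fewer features than
    ``n_select``, RFE degenerates to the identity on the survivors.
    """
    X, ids, is_clin = cohort_feature_matrix(cohort, include_clinical)
    z = cohort.outcome_int()
    pw = wilcoxon_pvalues(X, z)
    mi, pmi = mi_permutation_pvalues(X, z, n_perm=n_perm, seed=seed)
    mask = univariate_filter(pw, pmi, alpha=alpha, mode=mode)
    if not mask.any():
        best = int(np.argmin(np.minimum(pw, pmi)))
        logger.warning("phase 1 retained nothing at alpha=%.3g; keeping the "
                       "single best feature %s", alpha, ids[best])
        mask = np.zeros_like(mask)
        mask[best] = True

    rfe_pool = np.flatnonzero(mask if rfe_include_clinical else (mask & ~is_clin))
    if len(rfe_pool) == 0:
        rfe_pool = np.flatnonzero(mask)
    ranking = np.zeros(len(ids), dtype=int)
    if n_select >= len(rfe_pool):
        selected_idx = rfe_pool
        ranking[rfe_pool] = 1
    else:
        sel_local, rank_local = svm_rfe(
            X[:, rfe_pool], z, n_select=n_select, step_fraction=step_fraction
        )
        selected_idx = rfe_pool[sel_local]
        ranking[rfe_pool] = rank_local
    return SelectionResult(
        feature_ids=ids,
        pvalues_wilcoxon=pw,
        pvalues_mi=pmi,
        phase1_mask=mask,
        rfe_ranking=ranking,
        selected=[ids[i] for i in selected_idx],
    )
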