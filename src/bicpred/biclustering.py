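"""Discriminative pattern-based biclustering.

The transformation at the heart of this package views a coherent
expression module as a *pattern*: a set of genes each pinned to one
discrete expression level, supported by the set of samples that exhibit
exactly those levels. Mining proceeds in four steps, repeated with
masking:

1. discretize each gene into ``L`` equal-frequency labels;
2. mine all *closed* frequent itemsets over items ``(gene = label)``
   (closed: no supergene-set pattern has the identical supporting rows),
   each with its exact supporting row set;
3. assemble each itemset into a :class:`Bicluster`, attach per-gene
   expected expression (mean over supporting rows) and a class *lift*
   ``max_c P(z=c | rows) / P(z=c)`` measuring how discriminative the
   pattern is for either outcome class;
4. keep biclusters with lift >= ``min_lift``, mask their cells, and mine
   again — masking forces later iterations onto less trivial patterns.

The module is fully deterministic: no randomness anywhere, and the final
set is ordered by (lift desc, area desc, gene ids) so top-k truncation is
reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import ExpressionCohort

logger = logging.getLogger("bicpred")

#: Sentinel label for masked cells; masked cells support no item.
MASKED = -1

__all__ = [
    "MASKED",
    "LabelMatrix",
    "Bicluster",
    "BiclusterSet",
    "MiningParams",
    "discretize",
    "labels_from_edges",
    "mine_closed_patterns",
    "compute_lift",
    "assemble_biclusters",
    "mine_discriminative",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class LabelMatrix:
    """Discretized expression: per-cell symbol in ``0..L-1`` or MASKED."""

    labels: np.ndarray  # (n_samples, n_genes) int
    n_labels: int
    bin_edges: list[np.ndarray]  # per-gene interior breakpoints (log2 units)

    def __post_init__(self) -> None:
        if self.n_labels < 2:
            raise ValueError("n_labels must be >= 2")
        self.labels = np.asarray(self.labels, dtype=np.int64)


@dataclass(frozen=True)
class Bicluster:
    """A mined pattern: genes, per-gene label, supporting samples, lift."""

    genes: tuple[str, ...]
    pattern: tuple[int, ...]
    rows: tuple[str, ...]
    expected_values: tuple[float, ...]
    lift: float
    enriched_class: int

    @property
    def area(self) -> int:
        return len(self.rows) * len(self.genes)


@dataclass(frozen=True)
class MiningParams:
    """Knobs of the iterated discriminative mining loop.

    Defaults follow the parameterization used for the study-scale
    analysis: 9 masking iterations, minimum lift 1.3, 10 expression
    labels, at most 250 biclusters retained. ``min_support`` defaults to
    ``ceil(0.1 * n_samples)`` at mining time; ``min_genes`` to 3.
    """

    n_iterations: int = 9
    min_lift: float = 1.3
    n_labels: int = 10
    max_biclusters: int = 250
    min_support: int | None = None
    min_genes: int = 3


@dataclass
class BiclusterSet:
    """Mined biclusters plus the fitted discretization (for reuse on
    held-out samples), ordered by (lift desc, area desc, gene ids)."""

    biclusters: list[Bicluster]
    mining_params: MiningParams
    bin_edges: list[np.ndarray]
    n_labels: int
    gene_ids: list[str]

    def __len__(self) -> int:
        return len(self.biclusters)


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------


def _gene_edges(values: np.ndarray, n_labels: int) -> np.ndarray:
    """Interior breakpoints for one gene (equal-frequency bins).

    A gene with fewer distinct values than labels is binned on its
    distinct values (midpoint edges) with a warning; a constant gene gets
    no edges, i.e. every cell labelled 0.
    """
    uniq = np.unique(values)
    if len(uniq) < n_labels:
        logger.warning(
            "gene has %d distinct values < %d labels; binning on distinct values",
            len(uniq),
            n_labels,
        )
        return (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.empty(0)
    qs = np.arange(1, n_labels) / n_labels
    return np.unique(np.quantile(values, qs))


def labels_from_edges(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Label assignment for given breakpoints; ties at an edge go to the
    lower label (value == edge falls in the bin below)."""
    return np.searchsorted(edges, values, side="left")


def discretize(cohort: ExpressionCohort, n_labels: int = 10) -> LabelMatrix:
    """Per-gene equal-frequency (quantile) discretization into L labels."""
    if n_labels < 2:
        raise ValueError("n_labels must be >= 2")
    if np.isnan(cohort.expr).any():
        raise ValueError("expression contains missing cells; run drop_missing")
    edges = [_gene_edges(cohort.expr[:, j], n_labels) for j in range(cohort.n_genes)]
    labels = np.column_stack(
        [labels_from_edges(cohort.expr[:, j], edges[j]) for j in range(cohort.n_genes)]
    )
    return LabelMatrix(labels=labels, n_labels=n_labels, bin_edges=edges)


# ---------------------------------------------------------------------------
# Closed frequent pattern mining
# ---------------------------------------------------------------------------


def _closure(lab: np.ndarray, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Genes on which all ``rows`` agree on one unmasked label.

    Returns (boolean per gene, label per gene — valid where boolean).
    """
    sub = lab[rows]
    first = sub[0]
    ok = (first != MASKED) & (sub == first[None, :]).all(axis=0)
    return ok, first


def mine_closed_patterns(
    label_matrix: LabelMatrix, min_support: int, min_genes: int = 1
) -> list[tuple[tuple[tuple[int, int], ...], np.ndarray]]:
    """All closed frequent patterns with their exact supporting rows.

    A pattern is a set of items ``(gene, label)`` (at most one per gene);
    its support set is every row matching all items on unmasked cells.
    Only *closed* patterns are returned: no strict super-pattern has the
    identical support set, so no (pattern, row-set) pair is lost while the
    output stays bounded. Enumeration is depth-first with
    prefix-preserving closure extension, which visits each closed pattern
    exactly once.

    Returns a list of ``(items, rows)`` with items sorted by gene index
    and rows as a sorted integer array.
    """
    if min_support < 2:
        raise ValueError("min_support must be >= 2")
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    lab = label_matrix.labels
    n, p = lab.shape
    L = label_matrix.n_labels
    results: list[tuple[tuple[tuple[int, int], ...], np.ndarray]] = []
    if min_support > n:
        return results

    def record(clo_ok: np.ndarray, clo_lab: np.ndarray, rows: np.ndarray) -> None:
        genes = np.flatnonzero(clo_ok)
        if len(genes) >= min_genes:
            items = tuple((int(g), int(clo_lab[g])) for g in genes)
            results.append((items, rows))

    def dfs(
        rows: np.ndarray, clo_ok: np.ndarray, clo_lab: np.ndarray, core: tuple[int, int]
    ) -> None:
        core_g, core_l = core
        for g in range(core_g, p):
            if clo_ok[g]:
                continue
            col = lab[rows, g]
            start_l = core_l + 1 if g == core_g else 0
            for l in range(start_l, L):
                new_rows = rows[col == l]
                if len(new_rows) < min_support:
                    continue
                nok, nlab = _closure(lab, new_rows)
                # prefix-preserving check: the closure must add no item
                # ordered before (g, l) — otherwise this closed pattern is
                # reached from a smaller branch and would be a duplicate.
                added = nok & ~clo_ok
                added_genes = np.flatnonzero(added)
                if len(added_genes) and (
                    added_genes[0] < g
                    or (added_genes[0] == g and nlab[g] < l)
                ):
                    continue
                record(nok, nlab, new_rows)
                dfs(new_rows, nok, nlab, (g, l))

    all_rows = np.arange(n)
    root_ok, root_lab = _closure(lab, all_rows)
    record(root_ok, root_lab, all_rows)
    dfs(all_rows, root_ok, root_lab, (0, -1))
    return results


# ---------------------------------------------------------------------------
# Lift scoring and bicluster assembly
# ---------------------------------------------------------------------------


def compute_lift(rows: np.ndarray, outcome: np.ndarray) -> tuple[float, int]:
    """Class lift of a supporting row set.

    ``lift_c = P(z=c | rows) / P(z=c)``; returns the max over the two
    classes and its argmax (ties resolved to class 0). Classes absent
    from the cohort are skipped.
    """
    rows = np.asarray(rows)
    if len(rows) == 0:
        raise ValueError("rows must be non-empty")
    y = np.asarray(outcome)
    best = (-1.0, 0)
    for c in (0, 1):
        prev = float((y == c).mean())
        if prev == 0.0:
            continue
        in_rows = float((y[rows] == c).mean())
        lift_c = in_rows / prev
        if lift_c > best[0]:
            best = (lift_c, c)
    return best


def assemble_biclusters(
    patterns: list[tuple[tuple[tuple[int, int], ...], np.ndarray]],
    cohort: ExpressionCohort,
    outcome: np.ndarray,
) -> list[Bicluster]:
    """Turn mined (items, rows) pairs into scored biclusters.

    ``expected_values[j]`` is the mean expression of gene j over the
    supporting rows — computed on the data the patterns were mined from
    (training data only, by the caller's contract).
    """
    out = []
    for items, rows in patterns:
        genes = [g for g, _ in items]
        lift, enriched = compute_lift(rows, outcome)
        out.append(
            Bicluster(
                genes=tuple(cohort.gene_ids[g] for g in genes),
                pattern=tuple(l for _, l in items),
                rows=tuple(cohort.sample_ids[r] for r in rows),
                expected_values=tuple(
                    float(cohort.expr[rows, g].mean()) for g in genes
                ),
                lift=lift,
                enriched_class=enriched,
            )
        )
    return out


def _sort_key(b: Bicluster) -> tuple:
    return (-b.lift, -b.area, b.genes)


def mine_discriminative(
    cohort: ExpressionCohort,
    outcome: np.ndarray | None = None,
    params: MiningParams = MiningParams(),
) -> BiclusterSet:
    """Iterated mining with masking of found biclusters.

    Each iteration mines closed patterns on the current (partially
    masked) label matrix, keeps those with lift >= ``min_lift`` and masks
    every cell they cover, forcing subsequent iterations to discover less
    trivial structure. Discretization happens once, on the first
    iteration. The final set is sorted by (lift desc, area desc, gene
    ids) and truncated to ``max_biclusters``.
    """
    y = cohort.outcome_int() if outcome is None else np.asarray(outcome, dtype=int)
    min_support = params.min_support
    if min_support is None:
        min_support = math.ceil(0.1 * cohort.n_samples)
    min_support = max(2, min_support)

    lm = discretize(cohort, params.n_labels)
    sample_pos = {s: i for i, s in enumerate(cohort.sample_ids)}
    gene_pos = {g: j for j, g in enumerate(cohort.gene_ids)}

    kept: list[Bicluster] = []
    for it in range(params.n_iterations):
        patterns = mine_closed_patterns(lm, min_support, params.min_genes)
        bics = assemble_biclusters(patterns, cohort, y)
        new = [b for b in bics if b.lift >= params.min_lift]
        if not new:
            logger.info("mining stopped after iteration %d: no bicluster "
                        "reached min_lift", it + 1)
            break
        kept.extend(new)
        for b in new:
            r = [sample_pos[s] for s in b.rows]
            g = [gene_pos[gid] for gid in b.genes]
            lm.labels[np.ix_(r, g)] = MASKED

    if not kept:
        logger.warning("mine_discriminative found no bicluster at lift >= %.3g",
                       params.min_lift)
    kept.sort(key=_sort_key)
    return BiclusterSet(
        biclusters=kept[: params.max_biclusters],
        mining_params=params,
        bin_edges=[e.copy() for e in lm.bin_edges],
        n_labels=params.n_labels,
        gene_ids=list(cohort.gene_ids),
    )
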