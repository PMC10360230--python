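"""Pattern-centric feature space.

Maps a cohort from the gene-centric space to one feature per mined
bicluster: the dissimilarity between a sample's expression and the
pattern's per-gene expectation. Two criteria are supported:

- ``euclidean``: sqrt of the summed squared deviations from the pattern's
  expected expression over its genes (0 = perfect match), computed in
  log2 units;
- ``binary``: 1 iff the sample's discrete label (using the *training*
  bin edges) is within ``tolerance`` labels of the pattern on every gene.

Everything is fit on training data only — bin edges, supporting rows,
expected values — and then applied unchanged to held-out samples, which
is what makes the transformation usable inside a leakage-controlled
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biclustering import BiclusterSet, MiningParams, labels_from_edges, mine_discriminative
from .cohort import ExpressionCohort

__all__ = [
    "PatternFeatureMatrix",
    "transform_euclidean",
    "transform_binary",
    "fit_transform_pipeline",
]


@dataclass
class PatternFeatureMatrix:
    """Samples x biclusters dissimilarity matrix.

    Columns are named ``bic_0001 ...`` in the bicluster set's order;
    ``provenance`` keeps a reference to the fitted set so downstream
    reports can recover genes and patterns.
    """

    values: np.ndarray  # (n_samples, n_biclusters)
    sample_ids: list[str]
    criterion: str  # "euclidean" | "binary"
    tolerance: float | None
    provenance: BiclusterSet

    @property
    def feature_names(self) -> list[str]:
        return [f"bic_{i + 1:04d}" for i in range(self.values.shape[1])]


def _gene_columns(cohort: ExpressionCohort, bics: BiclusterSet) -> dict[str, int]:
    pos = {g: j for j, g in enumerate(cohort.gene_ids)}
    for b in bics.biclusters:
        for g in b.genes:
            if g not in pos:
                raise ValueError(f"bicluster gene {g!r} absent from cohort")
    return pos


def transform_euclidean(
    cohort: ExpressionCohort, bics: BiclusterSet, normalize: bool = False
) -> PatternFeatureMatrix:
    """Euclidean distance from each sample to each pattern's expectation.

    ``normalize=True`` divides each column by sqrt(|genes|) so biclusters
    of different sizes are on a comparable scale (off by default).
    """
    pos = _gene_columns(cohort, bics)
    n = cohort.n_samples
    vals = np.empty((n, len(bics.biclusters)))
    for k, b in enumerate(bics.biclusters):
        cols = [pos[g] for g in b.genes]
        diff = cohort.expr[:, cols] - np.asarray(b.expected_values)
        vals[:, k] = np.sqrt((diff**2).sum(axis=1))
        if normalize:
            vals[:, k] /= np.sqrt(len(cols))
    return PatternFeatureMatrix(
        values=vals,
        sample_ids=list(cohort.sample_ids),
        criterion="euclidean",
        tolerance=None,
        provenance=bics,
    )


def transform_binary(
    cohort: ExpressionCohort, bics: BiclusterSet, tolerance: float = 0.0
) -> PatternFeatureMatrix:
    """Pattern-possession indicators under a label tolerance.

    Sample labels are computed with the bin edges fitted at mining time,
    never re-estimated on the incoming cohort. With integer labels a
    fractional tolerance below 1 (e.g. 0.5) admits exact matches only,
    i.e. behaves as tolerance 0.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    pos = _gene_columns(cohort, bics)
    fitted_pos = {g: j for j, g in enumerate(bics.gene_ids)}
    n = cohort.n_samples
    vals = np.empty((n, len(bics.biclusters)))
    label_cache: dict[str, np.ndarray] = {}
    for k, b in enumerate(bics.biclusters):
        ok = np.ones(n, dtype=bool)
        for g, pat in zip(b.genes, b.pattern):
            if g not in label_cache:
                edges = bics.bin_edges[fitted_pos[g]]
                label_cache[g] = labels_from_edges(cohort.expr[:, pos[g]], edges)
            ok &= np.abs(label_cache[g] - pat) <= tolerance
        vals[:, k] = ok.astype(float)
    return PatternFeatureMatrix(
        values=vals,
        sample_ids=list(cohort.sample_ids),
        criterion="binary",
        tolerance=tolerance,
        provenance=bics,
    )


def fit_transform_pipeline(
    train_cohort: ExpressionCohort,
    test_cohort: ExpressionCohort,
    params: MiningParams = MiningParams(),
    criterion: str = "euclidean",
    tolerance: float = 0.0,
    normalize: bool = False,
) -> tuple[PatternFeatureMatrix, PatternFeatureMatrix]:
    """Mine on the training cohort only; transform both cohorts.

    Bin edges, supporting rows, expected values and lifts all derive from
    ``train_cohort``; ``test_cohort`` only passes through the fitted
    transformation. Sample ids must be disjoint.
    """
    overlap = set(train_cohort.sample_ids) & set(test_cohort.sample_ids)
    if overlap:
        raise ValueError(f"train/test sample ids overlap: {sorted(overlap)[:5]}")
    bics = mine_discriminative(train_cohort, params=params)
    if criterion == "euclidean":
        tr = transform_euclidean(train_cohort, bics, normalize=normalize)
        te = transform_euclidean(test_cohort, bics, normalize=normalize)
    elif criterion == "binary":
        tr = transform_binary(train_cohort, bics, tolerance=tolerance)
        te = transform_binary(test_cohort, bics, tolerance=tolerance)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return tr, te
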