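"""Cohort ingestion and preprocessing.

The unit of analysis is a cohort of tumor samples profiled at diagnosis:
a samples x genes expression matrix (log2 scale after preprocessing), a
small set of clinical covariates (age, gender, ordinal Lugano stage,
dichotomized lymphocyte-to-monocyte ratio LMR>2.1) and a binary outcome,
the interim PET after two courses of ABVD chemotherapy (iPET2; positive =
Deauville score >= 4, i.e. treatment-refractory).

All downstream stages (feature selection, discriminative biclustering,
nested-CV evaluation) consume the :class:`ExpressionCohort` built here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("bicpred")

# ---------------------------------------------------------------------------
# Encoding conventions (fixed package-wide)
# ---------------------------------------------------------------------------

#: Binary coding of the categorical covariates. The choice is arbitrary but
#: must be consistent between fit and transform, so it is fixed here.
GENDER_CODES = {"male": 0, "female": 1}
#: LMR>2.1 is stored as a boolean; when a numeric matrix is needed it is
#: coded False -> 0, True -> 1.

#: Columns every clinical table must provide (outcome column is separate).
CLINICAL_COLUMNS = ("age", "gender", "stage_code", "lmr_gt_2_1")

#: Name of the outcome column in clinical tables.
OUTCOME_COLUMN = "ipet2"

_STAGE_ROMANS = ("I", "II", "III", "IV")
_STAGE_VARIANTS = ("A", "B")

#: Deauville scores at or above this value define a positive iPET2.
DEAUVILLE_POSITIVE_THRESHOLD = 4


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionCohort:
    """Samples x genes expression plus clinical covariates and outcome.

    Parameters
    ----------
    sample_ids, gene_ids
        Unique identifiers; ``expr`` rows/columns follow their order.
    expr
        ``(n_samples, n_genes)`` float matrix. ``NaN`` marks a missing
        measurement (removed by :func:`drop_missing`).
    clinical
        DataFrame indexed by ``sample_ids`` with columns ``age`` (years),
        ``gender`` (coded 0/1 per :data:`GENDER_CODES`), ``stage_code``
        (ordinal 1..8, see :func:`encode_stage`) and ``lmr_gt_2_1`` (bool).
    outcome
        Per-sample binary iPET2 (1 = positive/refractory). Stored as float
        so ``NaN`` can mark a missing outcome before :func:`drop_missing`.
    log2_transformed
        Whether :func:`log2_transform` has been applied.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    expr: np.ndarray
    clinical: pd.DataFrame
    outcome: np.ndarray
    log2_transformed: bool = False

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        self.expr = np.asarray(self.expr, dtype=float)
        if self.expr.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"expr shape {self.expr.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        self.outcome = np.asarray(self.outcome, dtype=float)
        if self.outcome.shape != (len(self.sample_ids),):
            raise ValueError("outcome length does not match n_samples")
        obs = self.outcome[~np.isnan(self.outcome)]
        if not np.isin(obs, (0.0, 1.0)).all():
            raise ValueError("outcome values must be 0 or 1 (NaN = missing)")
        if list(self.clinical.index.astype(str)) != self.sample_ids:
            self.clinical = self.clinical.reindex(self.sample_ids)
        missing_cols = set(CLINICAL_COLUMNS) - set(self.clinical.columns)
        if missing_cols:
            raise ValueError(f"clinical table missing columns {sorted(missing_cols)}")
        stage = self.clinical["stage_code"].dropna()
        if not stage.isin(range(1, 9)).all():
            raise ValueError("stage_code must lie in 1..8")

    # -- conveniences -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_samples(self, idx: np.ndarray) -> "ExpressionCohort":
        """Cohort restricted to the given sample positions (order kept)."""
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        ids = [self.sample_ids[i] for i in idx]
        return ExpressionCohort(
            sample_ids=ids,
            gene_ids=list(self.gene_ids),
            expr=self.expr[idx],
            clinical=self.clinical.iloc[idx],
            outcome=self.outcome[idx],
            log2_transformed=self.log2_transformed,
        )

    def clinical_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Numeric (n_samples, 4) covariate matrix and its column names."""
        cols = list(CLINICAL_COLUMNS)
        mat = np.column_stack(
            [self.clinical[c].to_numpy(dtype=float) for c in cols]
        )
        return mat, cols

    def outcome_int(self) -> np.ndarray:
        """Outcome as an int vector; raises if any outcome is missing."""
        if np.isnan(self.outcome).any():
            raise ValueError("outcome contains missing values; run drop_missing")
        return self.outcome.astype(int)


@dataclass(frozen=True)
class CohortSummary:
    """Class balance bookkeeping (percentages to one decimal place)."""

    n_samples: int
    n_genes: int
    n_positive: int
    n_negative: int
    pct_positive: float
    pct_negative: float


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_cohort(
    expr_path: str | Path,
    clinical_path: str | Path,
    orientation: str = "genes-in-rows",
    log2_transformed: bool = False,
) -> ExpressionCohort:
    """Read expression + clinical TSV/CSV tables into a cohort.

    The expression table holds genes in rows and samples in columns by
    default (series-matrix convention); pass ``orientation="samples-in-rows"``
    for the transpose. The clinical table holds samples in rows with columns
    ``age, gender, stage_code, lmr_gt_2_1`` and optionally ``ipet2``.
    Samples are aligned on the intersection of the two tables, preserving
    the expression table's sample order; a shrinking intersection is logged.
    """
    if orientation not in ("genes-in-rows", "samples-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    expr_df = _read_table(expr_path)
    if orientation == "genes-in-rows":
        expr_df = expr_df.T  # -> samples x genes
    clin_df = _read_table(clinical_path)
    clin_df.index = clin_df.index.astype(str)
    expr_df.index = expr_df.index.astype(str)

    for col in expr_df.columns:
        coerced = pd.to_numeric(expr_df[col], errors="coerce")
        bad = coerced.isna() & expr_df[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"non-numeric expression value {expr_df.loc[row, col]!r} "
                f"at sample {row!r}, gene {col!r}"
            )
        expr_df[col] = coerced

    shared = [s for s in expr_df.index if s in set(clin_df.index)]
    if not shared:
        raise ValueError("expression and clinical tables share no sample ids")
    n_drop = (len(expr_df) - len(shared)) + (len(clin_df) - len(shared))
    if n_drop:
        logger.warning(
            "sample intersection dropped %d table rows (%d samples kept)",
            n_drop,
            len(shared),
        )
    expr_df = expr_df.loc[shared]
    clin_df = clin_df.loc[shared]

    if "gender" in clin_df and clin_df["gender"].dtype == object:
        clin_df = clin_df.assign(
            gender=clin_df["gender"].str.strip().str.lower().map(GENDER_CODES)
        )
    if OUTCOME_COLUMN in clin_df:
        outcome = clin_df[OUTCOME_COLUMN].to_numpy(dtype=float)
    else:
        outcome = np.full(len(shared), np.nan)
    clin_df = clin_df.reindex(columns=list(CLINICAL_COLUMNS))

    return ExpressionCohort(
        sample_ids=shared,
        gene_ids=[str(g) for g in expr_df.columns],
        expr=expr_df.to_numpy(dtype=float),
        clinical=clin_df,
        outcome=outcome,
        log2_transformed=log2_transformed,
    )


def write_cohort(cohort: ExpressionCohort, out_dir: str | Path) -> None:
    """Write the TSV pair ``read_cohort`` reads (genes-in-rows expression)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr_df = pd.DataFrame(
        cohort.expr.T, index=cohort.gene_ids, columns=cohort.sample_ids
    )
    expr_df.index.name = "gene_id"
    expr_df.to_csv(out / "expression.tsv", sep="\t")
    clin = cohort.clinical.copy()
    clin[OUTCOME_COLUMN] = cohort.outcome
    clin.index.name = "sample_id"
    clin.to_csv(out / "clinical.tsv", sep="\t")


def log2_transform(
    cohort: ExpressionCohort, pseudocount: float = 1.0
) -> ExpressionCohort:
    """log2(x + pseudocount) on every expression cell.

    Normalized counts can fall below 1, so the default pseudocount of 1
    keeps transformed values non-negative. Double application is refused.
    """
    if cohort.log2_transformed:
        raise ValueError("cohort is already log2 transformed")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if np.nanmin(cohort.expr) < 0:
        raise ValueError("negative expression values cannot be log2 transformed")
    return replace(
        cohort, expr=np.log2(cohort.expr + pseudocount), log2_transformed=True
    )


def encode_stage(stage_label: str) -> int:
    """Map a Lugano stage label like ``"II B"`` to its ordinal code 1..8.

    Both a larger stage numeral and the B variant are worse prognostic
    factors, giving the strict ordering
    I A < I B < II A < II B < III A < III B < IV A < IV B -> 1..8.
    """
    m = re.fullmatch(r"\s*(IV|III|II|I)\s*([AB])\s*", str(stage_label).upper())
    if not m:
        valid = [f"{r} {v}" for r in _STAGE_ROMANS for v in _STAGE_VARIANTS]
        raise ValueError(
            f"unrecognized stage label {stage_label!r}; expected one of {valid}"
        )
    roman, variant = m.groups()
    return 2 * _STAGE_ROMANS.index(roman) + _STAGE_VARIANTS.index(variant) + 1


def encode_ipet2(deauville: int) -> int:
    """Binarize a Deauville 5-point score: positive (1) iff score >= 4."""
    if deauville not in (1, 2, 3, 4, 5):
        raise ValueError(f"Deauville score must be in 1..5, got {deauville!r}")
    return int(deauville >= DEAUVILLE_POSITIVE_THRESHOLD)


def drop_missing(cohort: ExpressionCohort) -> ExpressionCohort:
    """Remove samples with any missing expression, clinical or outcome cell."""
    expr_ok = ~np.isnan(cohort.expr).any(axis=1)
    clin_ok = cohort.clinical[list(CLINICAL_COLUMNS)].notna().all(axis=1).to_numpy()
    out_ok = ~np.isnan(cohort.outcome)
    keep = expr_ok & clin_ok & out_ok
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("drop_missing would remove every sample")
    if n_removed:
        logger.info("drop_missing removed %d of %d samples", n_removed, len(keep))
    return cohort.subset_samples(keep)


def summarize(cohort: ExpressionCohort) -> CohortSummary:
    """Class-balance summary; percentages reported to one decimal place."""
    if np.isnan(cohort.outcome).any():
        raise ValueError("outcome contains missing values; run drop_missing first")
    y = cohort.outcome.astype(int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    return CohortSummary(
        n_samples=cohort.n_samples,
        n_genes=cohort.n_genes,
        n_positive=n_pos,
        n_negative=n_neg,
        pct_positive=round(100.0 * n_pos / len(y), 1),
        pct_negative=round(100.0 * n_neg / len(y), 1),
    )
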