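"""Synthetic cohorts with planted discriminative regulatory modules.

Generates samples x genes log2-scale expression with the statistical
features the analysis has to survive on real data: heavy-tailed per-gene
variability, a small rate of extreme outlier cells, an imbalanced binary
outcome (~80/20 by default at study scale), a handful of clinical
covariates, and — crucially — *planted biclusters*: subsets of genes whose
carriers (a fraction of one outcome class) express them coherently near a
shared per-gene level. The planted structure, with its recorded carrier
sets, is the ground truth against which pattern mining and the
pattern-space transformation are validated.

All randomness flows from a single `numpy` Generator seeded by the spec;
two calls with the same spec produce bitwise-identical cohorts. Outcome
assignment is stratified (exactly ``round(prevalence * n)`` positives),
never Bernoulli, so class counts are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CLINICAL_COLUMNS, ExpressionCohort

__all__ = [
    "BaselineHyper",
    "PlantedBicluster",
    "SyntheticSpec",
    "generate_cohort",
    "null_cohort",
]


@dataclass(frozen=True)
class BaselineHyper:
    """Hyperparameters for the background expression distribution.

    Per-gene mean ``mean_j ~ Normal(mean_loc, mean_scale)`` and per-gene
    standard deviation ``sd_j ~ LogUniform(sd_low, sd_high)`` (log2 units).
    The log-uniform spread of sds emulates the strong between-gene
    variability of normalized expression panels.
    """

    mean_loc: float = 8.0
    mean_scale: float = 2.0
    sd_low: float = 0.5
    sd_high: float = 2.0


@dataclass(frozen=True)
class PlantedBicluster:
    """A planted class-discriminative regulatory module.

    Carriers are drawn from the ``enriched_class`` samples (a fraction
    ``penetrance`` of them); over ``gene_idx`` their cells are redrawn
    ``Normal(pattern_levels, noise_sd)``. When ``pattern_levels`` is None
    the module is planted *upregulated* relative to its own background:
    ``pattern_levels[j] = mean_j + level_shift_sd * sd_j`` — the canonical
    differentially-active-module scenario.

    ``carriers`` and realized ``pattern_levels`` are filled in on the
    ground-truth copies returned by :func:`generate_cohort`.
    """

    gene_idx: tuple[int, ...]
    enriched_class: int = 1
    penetrance: float = 1.0
    noise_sd: float = 0.1
    pattern_levels: tuple[float, ...] | None = None
    level_shift_sd: float = 4.0
    carriers: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_idx", tuple(int(g) for g in self.gene_idx))
        if not self.gene_idx:
            raise ValueError("planted bicluster needs a non-empty gene set")
        if not 0 < self.penetrance <= 1:
            raise ValueError("penetrance must lie in (0, 1]")
        if self.enriched_class not in (0, 1):
            raise ValueError("enriched_class must be 0 or 1")
        if self.pattern_levels is not None:
            levels = tuple(float(v) for v in self.pattern_levels)
            if len(levels) != len(self.gene_idx):
                raise ValueError("pattern_levels length must match gene_idx")
            object.__setattr__(self, "pattern_levels", levels)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic cohort."""

    n_samples: int
    n_genes: int
    prevalence: float = 0.204
    baseline: BaselineHyper = field(default_factory=BaselineHyper)
    outlier_rate: float = 0.01
    planted: tuple[PlantedBicluster, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        object.__setattr__(self, "planted", tuple(self.planted))
        for pb in self.planted:
            if max(pb.gene_idx) >= self.n_genes:
                raise ValueError(
                    f"planted gene index {max(pb.gene_idx)} out of range "
                    f"for {self.n_genes} genes"
                )


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[ExpressionCohort, list[PlantedBicluster]]:
    """Generate a cohort and the ground-truth planted modules.

    Returns the cohort (flagged log2-transformed: values are already on
    the log2 scale) and one :class:`PlantedBicluster` per planted module
    with ``carriers`` and realized ``pattern_levels`` filled in.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_genes

    # stratified outcome: exact positive count for every seed
    n_pos = int(round(spec.prevalence * n))
    outcome = np.zeros(n, dtype=float)
    outcome[rng.permutation(n)[:n_pos]] = 1.0

    base = spec.baseline
    mean_j = rng.normal(base.mean_loc, base.mean_scale, size=p)
    sd_j = np.exp(rng.uniform(np.log(base.sd_low), np.log(base.sd_high), size=p))
    expr = mean_j + sd_j * rng.standard_normal((n, p))

    ground_truth: list[PlantedBicluster] = []
    for pb in spec.planted:
        genes = np.array(pb.gene_idx)
        enriched = np.flatnonzero(outcome == pb.enriched_class)
        n_carriers = max(1, int(round(pb.penetrance * len(enriched))))
        carriers = np.sort(rng.choice(enriched, size=n_carriers, replace=False))
        if pb.pattern_levels is not None:
            levels = np.array(pb.pattern_levels)
        else:
            levels = mean_j[genes] + pb.level_shift_sd * sd_j[genes]
        expr[np.ix_(carriers, genes)] = levels + pb.noise_sd * rng.standard_normal(
            (n_carriers, len(genes))
        )
        ground_truth.append(
            replace(
                pb,
                carriers=tuple(int(c) for c in carriers),
                pattern_levels=tuple(float(v) for v in levels),
            )
        )

    # heavy-tailed outliers: cells replaced by mean_j +/- 6 sd_j draws
    n_out = int(round(spec.outlier_rate * n * p))
    if n_out:
        cells = rng.choice(n * p, size=n_out, replace=False)
        signs = rng.choice((-1.0, 1.0), size=n_out)
        cols = cells % p
        expr.flat[cells] = mean_j[cols] + signs * 6.0 * sd_j[cols]

    clinical = pd.DataFrame(
        {
            "age": rng.integers(15, 71, size=n),
            "gender": rng.integers(0, 2, size=n),
            "stage_code": rng.integers(1, 9, size=n),
            "lmr_gt_2_1": rng.integers(0, 2, size=n).astype(bool),
        },
        index=[f"S{i:04d}" for i in range(n)],
    )
    clinical = clinical.reindex(columns=list(CLINICAL_COLUMNS))

    cohort = ExpressionCohort(
        sample_ids=[f"S{i:04d}" for i in range(n)],
        gene_ids=[f"G{j:04d}" for j in range(p)],
        expr=expr,
        clinical=clinical,
        outcome=outcome,
        log2_transformed=True,
    )
    return cohort, ground_truth


def null_cohort(
    n_samples: int, n_genes: int, prevalence: float = 0.204, seed: int = 0
) -> ExpressionCohort:
    """A cohort whose outcome carries no signal (negative control)."""
    spec = SyntheticSpec(
        n_samples=n_samples,
        n_genes=n_genes,
        prevalence=prevalence,
        planted=(),
        seed=seed,
    )
    cohort, _ = generate_cohort(spec)
    return cohort
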