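import numpy as np
import pandas as pd
import pytest

from bicpred.cohort import ExpressionCohort
from bicpred.synthetic import PlantedBicluster, SyntheticSpec, generate_cohort


def make_cohort(expr, outcome, clinical=None, **kw):
    """Handcrafted cohort around an expression matrix."""
    expr = np.asarray(expr, dtype=float)
    n, p = expr.shape
    ids = [f"s{i}" for i in range(n)]
    if clinical is None:
        clinical = pd.DataFrame(
            {
                "age": np.linspace(20, 60, n).astype(int),
                "gender": [i % 2 for i in range(n)],
                "stage_code": [(i % 8) + 1 for i in range(n)],
                "lmr_gt_2_1": [bool(i % 2) for i in range(n)],
            },
            index=ids,
        )
    return ExpressionCohort(
        sample_ids=ids,
        gene_ids=[f"g{j}" for j in range(p)],
        expr=expr,
        clinical=clinical,
        outcome=np.asarray(outcome, dtype=float),
        **kw,
    )


def planted_cohort(
    seed,
    n_samples=60,
    n_genes=40,
    module=range(8),
    penetrance=1.0,
    noise_sd=0.1,
    level_shift_sd=4.0,
    prevalence=0.25,
    **kw,
):
    """One upregulated planted module; returns (cohort, ground truth)."""
    spec = SyntheticSpec(
        n_samples=n_samples,
        n_genes=n_genes,
        prevalence=prevalence,
        seed=seed,
        planted=(
            PlantedBicluster(
                gene_idx=tuple(module),
                penetrance=penetrance,
                noise_sd=noise_sd,
                level_shift_sd=level_shift_sd,
                enriched_class=1,
            ),
        ),
        **kw,
    )
    return generate_cohort(spec)


@pytest.fixture
def toy_cohort():
    rng = np.random.default_rng(7)
    expr = rng.normal(8, 1, size=(12, 5))
    outcome = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0], dtype=float)
    return make_cohort(expr, outcome, log2_transformed=True)
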