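import numpy as np
import pandas as pd
import pytest

from genesync import (
    AnalysisConfig,
    ExpressionMatrix,
    PairedDataset,
    SubjectTable,
)
from genesync.simulate import RhoDistribution, SimConfig, generate_paired_cohort


def make_matrix(rng, n_genes=5, n_subjects=6, region="region_a", prefix="G"):
    return ExpressionMatrix(
        gene_ids=np.array([f"{prefix}{i+1}" for i in range(n_genes)], dtype=object),
        subject_ids=np.array([f"s{j+1}" for j in range(n_subjects)], dtype=object),
        values=rng.normal(8, 1.5, (n_genes, n_subjects)),
        region_label=region,
    )


def make_subjects(subject_ids, group="control", rng=None):
    rng = rng or np.random.default_rng(0)
    return SubjectTable(
        pd.DataFrame(
            {
                "subject_id": list(subject_ids),
                "group": group,
                "age": rng.uniform(20, 70, len(subject_ids)),
            }
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_paired(rng):
    """A small correlated paired dataset (20 genes x 10 subjects)."""
    cfg = SimConfig(
        n_subjects_per_group=10,
        n_genes=20,
        rho_distribution=RhoDistribution(family="constant", value=0.5),
        groups=("control",),
        rng_seed=0,
    )
    datasets, _ = generate_paired_cohort(cfg)
    return datasets["control"]


@pytest.fixture
def quick_config():
    return AnalysisConfig(n_bootstrap=200, n_permutations=20, rng_seed=0)
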