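import warnings

import numpy as np
import pytest

from ddgstack import (
    FeatureTable,
    MutationRecord,
    PredictorMeta,
    generate_feature_table,
    sipmab_like_config,
)

# GPR fits on tiny/degenerate targets legitimately push hyperparameters to
# their bounds; the resulting sklearn ConvergenceWarnings are expected.
warnings.filterwarnings("ignore", module="sklearn")


def build_table(scores, ddg, seed=0, predictor_names=None, firewall=()):
    """Construct a FeatureTable from raw arrays with synthetic labels."""
    scores = np.asarray(scores, dtype=float)
    ddg = np.asarray(ddg, dtype=float)
    n, p = scores.shape
    rng = np.random.default_rng(seed)
    aa = sorted("ACDEFGHIKLMNPQRSTVWY")
    records = []
    for i in range(n):
        wt, mut = rng.choice(aa, size=2, replace=False)
        records.append(
            MutationRecord(
                record_id=f"R{i:03d}",
                complex_id="CPLX1",
                chain="H",
                position=30 + i,
                wt_residue=str(wt),
                mut_residue=str(mut),
                ddg_exp=float(ddg[i]),
            )
        )
    names = predictor_names or [f"P{j}" for j in range(p)]
    predictors = [
        PredictorMeta(
            name=nm,
            approach="machine_learning" if nm in firewall else "molecular_mechanics",
            scoring_function="synthetic",
            needs_leakage_firewall=nm in firewall,
        )
        for nm in names
    ]
    return FeatureTable(records=records, predictors=predictors, scores=scores)


@pytest.fixture
def random_table():
    """Factory for small random feature tables."""

    def _make(n=6, p=3, seed=0):
        rng = np.random.default_rng(seed)
        return build_table(rng.normal(size=(n, p)), rng.normal(size=n), seed=seed)

    return _make


@pytest.fixture(scope="session")
def sipmab_table():
    """One benchmark-scale synthetic table (212 records x 12 predictors)."""
    return generate_feature_table(sipmab_like_config(seed=0))
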