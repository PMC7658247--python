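"""Single-predictor evaluation and the consensus Z-score baseline.

Consensus scoring ranks mutants by the unweighted average of per-predictor
Z scores: each selected predictor column is standardized over the whole
table (the transform touches no experimental target, so it leaks no
labels), then the standardized columns are averaged row-wise.  The two
historical subsets are exposed as ``CONS3`` (SIE-Scwrl_mut, Ros_mut,
FoldX-S) and ``CONS4`` (CONS3 plus FoldX-B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SchemaError, TableValidationError, ZeroVarianceError
from .evalharness import pearson_r
from .tables import FeatureTable

__all__ = [
    "CONS3",
    "CONS4",
    "ConsensusSpec",
    "zscore",
    "consensus_score",
    "evaluate_single_predictor",
]

CONS3: tuple[str, ...] = ("SIE-Scwrl_mut", "Ros_mut", "FoldX-S")
CONS4: tuple[str, ...] = CONS3 + ("FoldX-B",)


@dataclass(frozen=True)
class ConsensusSpec:
    """Which predictors to average, and the Z-score denominator.

    ``zscore_ddof=1`` (sample standard deviation) is the default; 0 gives
    the population denominator.  The choice does not affect rank-based
    comparisons but is fixed here for reproducibility.
    """

    predictor_names: tuple[str, ...]
    zscore_ddof: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "predictor_names", tuple(self.predictor_names))
        if not self.predictor_names:
            raise TableValidationError("consensus needs at least one predictor")
        if len(set(self.predictor_names)) != len(self.predictor_names):
            raise TableValidationError("duplicate predictor names in consensus spec")
        if self.zscore_ddof not in (0, 1):
            raise TableValidationError("zscore_ddof must be 0 or 1")


def zscore(values, ddof: int = 1, name: str = "values") -> np.ndarray:
    """Standardize a vector to mean 0, sd 1 (order preserved)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise TableValidationError(f"{name}: z-score needs a vector of length >= 2")
    sd = v.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ZeroVarianceError(f"{name}: zero variance, z-score undefined")
    return (v - v.mean()) / sd


def consensus_score(table: FeatureTable, spec: ConsensusSpec) -> np.ndarray:
    """Per-record consensus score: row-mean of the selected Z-scored columns.

    Z scores are computed over all rows of the supplied table.  The output
    is invariant under positive affine rescaling of any selected column and
    has mean zero over the table.
    """
    cols = []
    for name in spec.predictor_names:
        if name not in table.predictor_names:
            raise SchemaError(
                f"consensus predictor {name!r} not in table ({table.predictor_names})"
            )
        cols.append(zscore(table.column(name), ddof=spec.zscore_ddof, name=name))
    return np.mean(np.column_stack(cols), axis=1)


def evaluate_single_predictor(table: FeatureTable, predictor_name: str) -> float:
    """Pearson correlation of one raw predictor column with ddg_exp."""
    return pearson_r(table.column(predictor_name), table.ddg_exp)
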