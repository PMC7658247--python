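"""Data model and delimited-text I/O for mutation feature tables.

The central object is the :class:`FeatureTable`: one row per single-point
antibody mutant, one numeric score column per constituent ddG predictor,
plus the experimentally measured change in binding free energy
(``ddg_exp``, kcal/mol).  Downstream modules (baselines, stacking,
evaluation) all consume this container.

A built-in registry describes the twelve constituent predictors of the
reference ensemble: eleven molecular-mechanics protocols (combinations of
scoring function, mutant-structure regeneration and unbound-state
regeneration, targeting either the binding free energy or the fold
stability) and one machine-learning predictor (mCSM-AB) whose published
training data overlaps public affinity databases and therefore needs a
leakage firewall during evaluation.  The molecular-mechanics computations
themselves are outside this package; their outputs arrive as feature
columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .errors import SchemaError, TableParseError, TableValidationError

__all__ = [
    "AMINO_ACIDS",
    "MutationRecord",
    "PredictorMeta",
    "FeatureTable",
    "ColumnMap",
    "Diagnostic",
    "read_feature_table",
    "write_feature_table",
    "builtin_predictor_registry",
    "validate_table",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_APPROACHES = ("molecular_mechanics", "machine_learning")
_EQUATIONS = ("binding", "folding")


@dataclass(frozen=True)
class MutationRecord:
    """One single-point antibody mutant with its measured ddG_binding.

    ``position`` uses author (PDB-style) numbering and is treated as an
    opaque label; ``ddg_exp`` is in kcal/mol, positive = weakened binding.
    """

    record_id: str
    complex_id: str
    chain: str
    position: int
    wt_residue: str
    mut_residue: str
    ddg_exp: float

    def __post_init__(self) -> None:
        if self.wt_residue not in AMINO_ACIDS:
            raise TableValidationError(
                f"record {self.record_id!r}: invalid wild-type residue {self.wt_residue!r}"
            )
        if self.mut_residue not in AMINO_ACIDS:
            raise TableValidationError(
                f"record {self.record_id!r}: invalid mutant residue {self.mut_residue!r}"
            )
        if self.wt_residue == self.mut_residue:
            raise TableValidationError(
                f"record {self.record_id!r}: wild-type and mutant residue are both "
                f"{self.wt_residue!r}"
            )
        if not np.isfinite(self.ddg_exp):
            raise TableValidationError(
                f"record {self.record_id!r}: non-finite ddg_exp {self.ddg_exp!r}"
            )


@dataclass(frozen=True)
class PredictorMeta:
    """Identity and provenance of one constituent predictor.

    ``energy_equation`` distinguishes predictors that estimate the change
    in binding free energy from those that estimate the change in fold
    stability.  ``needs_leakage_firewall`` is true only for
    machine-learning predictors trained on external affinity databases,
    whose raw predictions may leak test labels into an evaluation.
    """

    name: str
    approach: str
    scoring_function: str
    mutant_regeneration: str = ""
    unbound_regeneration: str = ""
    energy_equation: str = "binding"
    needs_leakage_firewall: bool = False

    def __post_init__(self) -> None:
        if self.approach not in _APPROACHES:
            raise TableValidationError(
                f"predictor {self.name!r}: unknown approach {self.approach!r}"
            )
        if self.energy_equation not in _EQUATIONS:
            raise TableValidationError(
                f"predictor {self.name!r}: unknown energy equation {self.energy_equation!r}"
            )
        if self.approach == "machine_learning" and (
            self.mutant_regeneration or self.unbound_regeneration
        ):
            raise TableValidationError(
                f"predictor {self.name!r}: machine-learning predictors have no "
                "structure-regeneration protocol"
            )


@dataclass
class FeatureTable:
    """Records x predictor-score matrix plus the experimental target.

    ``scores`` is an (n_records, n_predictors) float array; row order
    matches ``records`` and column order matches ``predictors``.

    ``firewall_flags`` marks (record_id, predictor_name) cells whose value
    overlaps the training data of a machine-learning constituent predictor;
    ``firewall_substitutes`` holds the leakage-safe replacement values
    (e.g. the constituent's own cross-validated predictions).
    """

    records: list[MutationRecord]
    predictors: list[PredictorMeta]
    scores: np.ndarray
    firewall_substitutes: dict[tuple[str, str], float] = field(default_factory=dict)
    firewall_flags: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise TableValidationError("scores must be a 2-D matrix")
        if self.scores.shape != (len(self.records), len(self.predictors)):
            raise TableValidationError(
                f"scores shape {self.scores.shape} does not match "
                f"{len(self.records)} records x {len(self.predictors)} predictors"
            )
        if self.scores.size and not np.all(np.isfinite(self.scores)):
            bad = np.argwhere(~np.isfinite(self.scores))[0]
            raise TableValidationError(
                f"non-finite score at record {self.records[bad[0]].record_id!r}, "
                f"predictor {self.predictors[bad[1]].name!r}"
            )
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TableValidationError(f"duplicate record_id(s): {dupes}")
        names = [p.name for p in self.predictors]
        if len(set(names)) != len(names):
            raise TableValidationError("duplicate predictor names")
        firewall_names = {p.name for p in self.predictors if p.needs_leakage_firewall}
        known_ids = set(ids)
        for rid, pname in self.firewall_flags:
            if pname not in firewall_names:
                raise TableValidationError(
                    f"firewall flag on {pname!r}, which is not a "
                    "needs_leakage_firewall predictor"
                )
            if rid not in known_ids:
                raise TableValidationError(f"firewall flag on unknown record {rid!r}")

    # -- convenience accessors -------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_predictors(self) -> int:
        return len(self.predictors)

    @property
    def predictor_names(self) -> list[str]:
        return [p.name for p in self.predictors]

    @property
    def record_ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    @property
    def ddg_exp(self) -> np.ndarray:
        return np.array([r.ddg_exp for r in self.records], dtype=float)

    def column_index(self, name: str) -> int:
        try:
            return self.predictor_names.index(name)
        except ValueError:
            raise SchemaError(
                f"unknown predictor {name!r}; table has {self.predictor_names}"
            ) from None

    def column(self, name: str) -> np.ndarray:
        """Score column for one predictor, as a copy."""
        return self.scores[:, self.column_index(name)].copy()

    def feature_matrix(self, subset: Sequence[str] | None = None) -> np.ndarray:
        """Score columns for ``subset`` (default: all), in the given order."""
        names = list(subset) if subset is not None else self.predictor_names
        idx = [self.column_index(n) for n in names]
        return self.scores[:, idx].copy()

    def subset_records(self, indices: Sequence[int]) -> "FeatureTable":
        """New table restricted to the given record indices (order kept)."""
        indices = list(indices)
        recs = [self.records[i] for i in indices]
        kept = {r.record_id for r in recs}
        return FeatureTable(
            records=recs,
            predictors=list(self.predictors),
            scores=self.scores[indices, :].copy(),
            firewall_substitutes={
                k: v for k, v in self.firewall_substitutes.items() if k[0] in kept
            },
            firewall_flags={k for k in self.firewall_flags if k[0] in kept},
        )

    def to_dataframe(self, colmap: "ColumnMap | None" = None) -> pd.DataFrame:
        colmap = colmap or ColumnMap()
        data: dict[str, object] = {
            colmap.record_id: self.record_ids,
            colmap.complex_id: [r.complex_id for r in self.records],
            colmap.chain: [r.chain for r in self.records],
            colmap.position: [r.position for r in self.records],
            colmap.wt_residue: [r.wt_residue for r in self.records],
            colmap.mut_residue: [r.mut_residue for r in self.records],
            colmap.ddg_exp: self.ddg_exp,
        }
        mapping = colmap.predictor_columns(self.predictor_names)
        for j, name in enumerate(self.predictor_names):
            data[mapping[name]] = self.scores[:, j]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class ColumnMap:
    """Explicit column mapping between a delimited file and the data model.

    ``predictors`` maps predictor name -> file column; when ``None``, every
    column not claimed by a metadata field is taken as a predictor score
    column named after itself, in header order.  ``delimiter`` may be
    ``","``, ``"\\t"`` or ``None`` (choose by filename extension / default
    comma); nothing beyond comma-vs-tab is sniffed, parsing stays
    deterministic.
    """

    record_id: str = "record_id"
    complex_id: str = "complex_id"
    chain: str = "chain"
    position: str = "position"
    wt_residue: str = "wt_residue"
    mut_residue: str = "mut_residue"
    ddg_exp: str = "ddg_exp"
    predictors: Mapping[str, str] | None = None
    delimiter: str | None = None

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "ColumnMap":
        kwargs = {k: v for k, v in d.items() if v is not None}
        preds = kwargs.get("predictors")
        if preds is not None:
            kwargs["predictors"] = dict(preds)  # type: ignore[arg-type]
        return cls(**kwargs)  # type: ignore[arg-type]

    def meta_columns(self) -> list[str]:
        return [
            self.record_id,
            self.complex_id,
            self.chain,
            self.position,
            self.wt_residue,
            self.mut_residue,
            self.ddg_exp,
        ]

    def predictor_columns(self, names: Iterable[str]) -> dict[str, str]:
        if self.predictors is None:
            return {n: n for n in names}
        return {n: self.predictors[n] for n in names}


@dataclass(frozen=True)
class Diagnostic:
    """One validation warning about a feature table (never fatal)."""

    kind: str  # "orientation" or "zero_variance"
    predictor: str
    message: str


def _resolve_delimiter(colmap: ColumnMap, source) -> str:
    if colmap.delimiter is not None:
        if colmap.delimiter not in (",", "\t"):
            raise SchemaError(
                f"unsupported delimiter {colmap.delimiter!r}; use ',' or tab"
            )
        return colmap.delimiter
    name = getattr(source, "name", None) or (source if isinstance(source, (str, Path)) else "")
    return "\t" if str(name).endswith((".tsv", ".tab")) else ","


def read_feature_table(
    source: str | Path | TextIO,
    colmap: ColumnMap | None = None,
    registry: Sequence[PredictorMeta] | None = None,
) -> FeatureTable:
    """Read a CSV/TSV mutation feature table.

    Parameters
    ----------
    source
        Path or open text stream with a header row.
    colmap
        Column mapping; defaults map columns by their canonical names and
        treat every unclaimed column as a predictor score.
    registry
        Optional predictor metadata to attach by name; predictors absent
        from the registry get minimal molecular-mechanics metadata.

    Raises
    ------
    SchemaError
        A mapped column is missing from the header.
    TableParseError
        A score / target cell is blank or non-numeric (reports row and
        column coordinates).
    TableValidationError
        Duplicate record ids or other structural violations.
    """
    colmap = colmap or ColumnMap()
    sep = _resolve_delimiter(colmap, source)
    df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)

    for col in colmap.meta_columns():
        if col not in df.columns:
            raise SchemaError(f"missing mapped column {col!r} in table header")

    if colmap.predictors is None:
        score_cols = {c: c for c in df.columns if c not in colmap.meta_columns()}
    else:
        score_cols = dict(colmap.predictors)
        for name, col in score_cols.items():
            if col not in df.columns:
                raise SchemaError(f"missing mapped column {col!r} for predictor {name!r}")
    if not score_cols:
        raise SchemaError("no predictor score columns found")

    def parse_numeric(col: str) -> np.ndarray:
        # numpy/float() are correctly rounded; pd.to_numeric's fast path is
        # not, which would break bit-exact round-trips
        raw = df[col].str.strip()
        try:
            vals = raw.to_numpy().astype(np.float64)
        except ValueError:
            for row, cell in enumerate(raw):
                try:
                    v = float(cell)
                except ValueError:
                    v = np.nan
                if np.isnan(v) and cell.lower() not in ("nan", "-nan", "+nan"):
                    raise TableParseError(
                        f"non-numeric value {cell!r} at row {row}, column {col!r}",
                        row=row,
                        column=col,
                    ) from None
            raise  # pragma: no cover - unreachable
        bad = np.flatnonzero(np.isnan(vals))
        if len(bad):
            row = int(bad[0])
            raise TableParseError(
                f"non-finite value {raw.iloc[row]!r} at row {row}, column {col!r}",
                row=row,
                column=col,
            )
        return vals

    ddg = parse_numeric(colmap.ddg_exp)
    try:
        positions = parse_numeric(colmap.position).astype(int)
    except TableParseError as exc:
        raise TableParseError(
            f"position column: {exc}", row=exc.row, column=exc.column
        ) from exc

    by_name = {m.name: m for m in (registry or builtin_predictor_registry())}
    predictors = [
        by_name.get(
            name,
            PredictorMeta(name=name, approach="molecular_mechanics", scoring_function="unknown"),
        )
        for name in score_cols
    ]
    scores = np.column_stack([parse_numeric(col) for col in score_cols.values()])

    records = [
        MutationRecord(
            record_id=str(df[colmap.record_id].iloc[i]),
            complex_id=str(df[colmap.complex_id].iloc[i]),
            chain=str(df[colmap.chain].iloc[i]),
            position=int(positions[i]),
            wt_residue=str(df[colmap.wt_residue].iloc[i]),
            mut_residue=str(df[colmap.mut_residue].iloc[i]),
            ddg_exp=float(ddg[i]),
        )
        for i in range(len(df))
    ]
    return FeatureTable(records=records, predictors=predictors, scores=scores)


def write_feature_table(
    table: FeatureTable,
    sink: str | Path | TextIO,
    colmap: ColumnMap | None = None,
) -> None:
    """Write a feature table as CSV/TSV with lossless float precision.

    Floats are written with Python's shortest round-trip repr so that
    ``read_feature_table(write_feature_table(t))`` reproduces ``scores``
    bit-identically.
    """
    colmap = colmap or ColumnMap()
    sep = _resolve_delimiter(colmap, sink)
    df = table.to_dataframe(colmap)
    # shortest round-trip repr per float, not pandas' 16-digit default
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(repr)
    df.to_csv(sink, sep=sep, index=False)


def builtin_predictor_registry() -> tuple[PredictorMeta, ...]:
    """The twelve constituent predictors of the reference ensemble.

    Eleven molecular-mechanics protocols differing in scoring function
    (SIE, Talaris2013, Talaris-interface, CHARMm Polar H, FOLDEF),
    mutant-structure regeneration (single-site repack, interface side-chain
    repack, CDR-loop backrub, SCWRL + local minimization) and
    unbound-state regeneration (rigid separation vs. refinement), plus the
    graph-signature machine-learning predictor mCSM-AB.  Ten target the
    binding free-energy change; FoldX-S and DS-S target fold stability.
    Pure function: returns an identical, identically ordered tuple on
    every call.
    """
    mm = dict(approach="molecular_mechanics")
    return (
        PredictorMeta(
            name="DS-B", scoring_function="CHARMm Polar H",
            mutant_regeneration="mutated side-chain repack + minimization",
            unbound_regeneration="rigid separation", energy_equation="binding", **mm,
        ),
        PredictorMeta(
            name="DS-S", scoring_function="CHARMm Polar H",
            mutant_regeneration="mutated side-chain repack + minimization",
            unbound_regeneration="rigid separation", energy_equation="folding", **mm,
        ),
        PredictorMeta(
            name="FoldX-B", scoring_function="FOLDEF",
            mutant_regeneration="side-chain repack",
            unbound_regeneration="rigid separation", energy_equation="binding", **mm,
        ),
        PredictorMeta(
            name="FoldX-S", scoring_function="FOLDEF",
            mutant_regeneration="side-chain repack",
            unbound_regeneration="rigid separation", energy_equation="folding", **mm,
        ),
        PredictorMeta(
            name="SIE-Scwrl_mut", scoring_function="SIE",
            mutant_regeneration="SCWRL repack + Amber local minimization",
            unbound_regeneration="rigid separation", energy_equation="binding", **mm,
        ),
        PredictorMeta(
            name="Ros_mut", scoring_function="Talaris-interface",
            mutant_regeneration="mutated side-chain repack",
            unbound_regeneration="rigid separation", energy_equation="binding", **mm,
        ),
        PredictorMeta(
            name="Ros_iface-sc", scoring_function="Talaris2013",
            mutant_regeneration="interface side-chain repack",
            unbound_regeneration="rigid separation", energy_equation="binding", **mm,
        ),
        PredictorMeta(
            name="Ros_CDR-loop", scoring_function="Talaris2013",
            mutant_regeneration="CDR-loop backrub + repack",
            unbound_regeneration="rigid separation", energy_equation="binding", **mm,
        ),
        PredictorMeta(
            name="SIE-Ros_mut", scoring_function="SIE",
            mutant_regeneration="mutated side-chain repack (Rosetta)",
            unbound_regeneration="rigid separation", energy_equation="binding", **mm,
        ),
        PredictorMeta(
            name="SIE-Ros_iface-sc", scoring_function="SIE",
            mutant_regeneration="interface side-chain repack (Rosetta)",
            unbound_regeneration="rigid separation", energy_equation="binding", **mm,
        ),
        PredictorMeta(
            name="SIE-Ros_CDR-loop", scoring_function="SIE",
            mutant_regeneration="CDR-loop backrub + repack (Rosetta)",
            unbound_regeneration="rigid separation", energy_equation="binding", **mm,
        ),
        PredictorMeta(
            name="mCSM-AB", approach="machine_learning",
            scoring_function="graph-based signatures + supervised regression",
            energy_equation="binding", needs_leakage_firewall=True,
        ),
    )


def validate_table(table: FeatureTable) -> list[Diagnostic]:
    """Diagnostic-only sanity checks on a feature table.

    Warns (never errors) about predictor columns that correlate negatively
    with the experimental target — a likely sign-orientation problem, since
    every constituent predictor is expected to estimate the same ddG
    quantity — and about constant (zero-variance) columns.  Signs are never
    flipped automatically: silent correction would corrupt provenance.
    """
    out: list[Diagnostic] = []
    y = table.ddg_exp
    y_const = table.n_records < 2 or np.ptp(y) == 0
    for j, p in enumerate(table.predictors):
        col = table.scores[:, j]
        if table.n_records < 2 or np.ptp(col) == 0:
            out.append(
                Diagnostic(
                    kind="zero_variance",
                    predictor=p.name,
                    message=f"predictor {p.name!r} is constant across all records",
                )
            )
            continue
        if y_const:
            continue
        r = float(np.corrcoef(col, y)[0, 1])
        if r < 0:
            out.append(
                Diagnostic(
                    kind="orientation",
                    predictor=p.name,
                    message=(
                        f"predictor {p.name!r} correlates negatively with ddg_exp "
                        f"(r = {r:.3f}); check its sign convention"
                    ),
                )
            )
    return out
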