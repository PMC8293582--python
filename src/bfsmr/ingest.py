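"""Chunked ingest: streaming, outcome derivation, encoding, imputation.

The cohort file is never loaded whole. A first streaming pass accumulates
per-(age, sex) BMI distributions and the categorical level registry; a
second pass yields fixed-size encoded chunks with labels attached. The
binary outcome marks visits whose BMI is strictly above the age/sex
stratum's empirical 90th percentile (nearest-rank), the standard
"overweight" indicator for pediatric cohorts lacking an external growth
reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("bfsmr.ingest")

__all__ = [
    "ColumnSpec",
    "FeatureSchema",
    "OutcomeReference",
    "Chunk",
    "stream_chunks",
    "build_outcome_reference",
    "nearest_rank_percentile",
    "derive_labels",
    "encode_and_impute",
    "first_pass",
    "ingest_file",
    "schema_from_cohort_config",
]

MIN_STRATUM_SIZE = 10

KINDS = ("numeric", "categorical", "identifier", "outcome_source")


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str
    levels: tuple[str, ...] = ()
    impute: str = "median"  # numerics: "median" | "zero"; categoricals ignored (all-zero row)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown column kind {self.kind!r}")


@dataclass(frozen=True)
class FeatureSchema:
    """Declares every raw column's role.

    Exactly one outcome-source group (bmi + age + sex columns) must be
    present; those columns feed label derivation and are excluded from the
    feature matrix.
    """

    entries: tuple[ColumnSpec, ...]
    bmi_column: str = "bmi"
    age_column: str = "age"
    sex_column: str = "sex"

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate raw column names in schema")
        sources = {e.name for e in self.entries if e.kind == "outcome_source"}
        if sources != {self.bmi_column, self.age_column, self.sex_column}:
            raise ValueError(
                "schema must declare exactly the BMI, age and sex columns as outcome_source"
            )

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def feature_entries(self) -> list[ColumnSpec]:
        return [e for e in self.entries if e.kind in ("numeric", "categorical")]

    def encoded_columns(self, registry: dict[str, list[str]]) -> list[str]:
        """Deterministic encoded column order: schema order, categorical levels sorted."""
        cols: list[str] = []
        for e in self.feature_entries:
            if e.kind == "numeric":
                cols.append(e.name)
            else:
                for lv in registry.get(e.name, list(e.levels)):
                    cols.append(f"{e.name}_{lv}")
        return cols

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "bmi_column": self.bmi_column,
            "age_column": self.age_column,
            "sex_column": self.sex_column,
            "columns": [
                {"name": e.name, "kind": e.kind, "levels": list(e.levels), "impute": e.impute}
                for e in self.entries
            ],
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureSchema":
        payload = yaml.safe_load(Path(path).read_text())
        entries = tuple(
            ColumnSpec(
                name=c["name"],
                kind=c["kind"],
                levels=tuple(c.get("levels", ())),
                impute=c.get("impute", "median"),
            )
            for c in payload["columns"]
        )
        return cls(
            entries=entries,
            bmi_column=payload.get("bmi_column", "bmi"),
            age_column=payload.get("age_column", "age"),
            sex_column=payload.get("sex_column", "sex"),
        )


@dataclass
class OutcomeReference:
    """Per-stratum BMI thresholds defining the overweight indicator."""

    strata: dict[tuple[int, int], float]
    percentile: float = 90.0
    pooled_threshold: float = float("nan")
    small_strata: list[tuple[int, int]] = field(default_factory=list)

    def threshold(self, age: int, sex: int) -> float:
        return self.strata.get((int(age), int(sex)), self.pooled_threshold)


@dataclass
class Chunk:
    """One encoded block: complete numeric matrix, binary labels, metadata."""

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    chunk_index: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        assert self.matrix.shape[0] == self.labels.shape[0]

    @property
    def n_records(self) -> int:
        return self.matrix.shape[0]


def _dtype_map(schema: FeatureSchema) -> dict[str, object]:
    out: dict[str, object] = {}
    for e in schema.entries:
        if e.kind == "numeric" or e.name == schema.bmi_column:
            out[e.name] = float
        elif e.kind == "categorical":
            out[e.name] = object
    return out


def stream_chunks(
    path: str | Path, chunk_size: int, schema: FeatureSchema | None = None
) -> Iterator[pd.DataFrame]:
    """Yield the file's rows as blocks of ``chunk_size`` rows, in file order.

    The last block may be shorter; an empty data section yields no blocks.
    Raises on a header/schema mismatch or a malformed row (with row context
    from the parser).
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    path = Path(path)
    header = pd.read_csv(path, nrows=0).columns.tolist()
    if schema is not None:
        missing = [n for n in schema.names if n not in header]
        if missing:
            raise ValueError(f"header mismatch: file lacks schema columns {missing}")
    dtypes = _dtype_map(schema) if schema is not None else None
    try:
        with pd.read_csv(path, chunksize=chunk_size, dtype=dtypes) as reader:
            for block in reader:
                if len(block):  # a header-only file yields one empty frame
                    yield block
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed row while reading {path}: {exc}") from exc


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank empirical percentile: the ceil(p/100 * n)-th order statistic."""
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    if n == 0:
        raise ValueError("empty sample")
    rank = int(np.ceil(percentile / 100.0 * n))
    return float(values[max(rank, 1) - 1])


def build_outcome_reference(
    blocks: Iterable[pd.DataFrame], schema: FeatureSchema, percentile: float = 90.0
) -> OutcomeReference:
    """Exact per-(age, sex) nearest-rank BMI percentile from a streaming pass.

    Strata with fewer than ``MIN_STRATUM_SIZE`` records fall back to the
    pooled threshold (with a warning).
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    acc: dict[tuple[int, int], list[np.ndarray]] = {}
    for block in blocks:
        sub = block[[schema.age_column, schema.sex_column, schema.bmi_column]].dropna()
        if sub.empty:
            continue
        ages = sub[schema.age_column].astype(int).to_numpy()
        sexes = sub[schema.sex_column].astype(int).to_numpy()
        bmis = sub[schema.bmi_column].astype(float).to_numpy()
        for key in set(zip(ages.tolist(), sexes.tolist())):
            mask = (ages == key[0]) & (sexes == key[1])
            acc.setdefault(key, []).append(bmis[mask])
    if not acc:
        raise ValueError("no complete (age, sex, BMI) records found")
    pooled_values = np.concatenate([v for parts in acc.values() for v in parts])
    pooled = nearest_rank_percentile(pooled_values, percentile)
    strata: dict[tuple[int, int], float] = {}
    small: list[tuple[int, int]] = []
    for key, parts in acc.items():
        vals = np.concatenate(parts)
        if len(vals) < MIN_STRATUM_SIZE:
            small.append(key)
            strata[key] = pooled
        else:
            strata[key] = nearest_rank_percentile(vals, percentile)
    if small:
        warnings.warn(
            f"{len(small)} strata had fewer than {MIN_STRATUM_SIZE} records; "
            "pooled threshold used",
            stacklevel=2,
        )
    return OutcomeReference(
        strata=strata, percentile=percentile, pooled_threshold=pooled, small_strata=small
    )


def derive_labels(
    block: pd.DataFrame, ref: OutcomeReference, schema: FeatureSchema
) -> tuple[np.ndarray, pd.DataFrame, int]:
    """Label each complete record: 1 iff BMI strictly above its stratum threshold.

    Records missing BMI, age or sex are dropped; the dropped count is
    returned and logged.
    """
    required = [schema.bmi_column, schema.age_column, schema.sex_column]
    complete = block.dropna(subset=required)
    n_dropped = len(block) - len(complete)
    if n_dropped:
        logger.info("dropped %d records with missing BMI/age/sex", n_dropped)
    thresholds = np.array(
        [
            ref.threshold(a, s)
            for a, s in zip(
                complete[schema.age_column].astype(int),
                complete[schema.sex_column].astype(int),
            )
        ]
    )
    labels = (complete[schema.bmi_column].astype(float).to_numpy() > thresholds).astype(np.int8)
    return labels, complete, n_dropped


def _discover_levels(blocks: Iterable[pd.DataFrame], schema: FeatureSchema) -> dict[str, list[str]]:
    registry: dict[str, set[str]] = {
        e.name: set(e.levels) for e in schema.feature_entries if e.kind == "categorical"
    }
    for block in blocks:
        for name in registry:
            observed = block[name].dropna().astype(str).unique()
            registry[name].update(observed.tolist())
    return {name: sorted(levels) for name, levels in registry.items()}


def first_pass(
    path: str | Path, schema: FeatureSchema, chunk_size: int = 10_000, percentile: float = 90.0
) -> tuple[OutcomeReference, dict[str, list[str]]]:
    """Reference pass: outcome thresholds plus the frozen categorical level registry."""
    thresholds_blocks = stream_chunks(path, chunk_size, schema)
    ref = build_outcome_reference(thresholds_blocks, schema, percentile)
    registry = _discover_levels(stream_chunks(path, chunk_size, schema), schema)
    return ref, registry


def encode_and_impute(
    block: pd.DataFrame,
    schema: FeatureSchema,
    ref: OutcomeReference,
    registry: dict[str, list[str]] | None = None,
    chunk_index: int = 0,
) -> Chunk:
    """Turn one raw block into a complete numeric chunk.

    Categoricals expand to one dummy column per registry level (missing or
    unseen values encode as all-zeros, with unseen occurrences logged);
    numeric missing values are imputed with the per-chunk median (or zero,
    per the column's policy). Column order is fixed by the schema and the
    frozen registry, so it is identical across chunks.
    """
    if registry is None:
        registry = {
            e.name: sorted(e.levels) for e in schema.feature_entries if e.kind == "categorical"
        }
    labels, complete, n_dropped = derive_labels(block, ref, schema)
    columns: list[np.ndarray] = []
    names: list[str] = []
    n = len(complete)
    for entry in schema.feature_entries:
        if entry.kind == "numeric":
            values = complete[entry.name].astype(float).to_numpy(copy=True)
            missing = np.isnan(values)
            if missing.any():
                if entry.impute == "zero":
                    fill = 0.0
                else:
                    observed = values[~missing]
                    fill = float(np.median(observed)) if observed.size else 0.0
                values[missing] = fill
            columns.append(values)
            names.append(entry.name)
        else:
            levels = registry.get(entry.name, sorted(entry.levels))
            raw = complete[entry.name].astype(object).to_numpy()
            str_vals = np.array([None if pd.isna(v) else str(v) for v in raw], dtype=object)
            seen = set(levels)
            unseen = sum(1 for v in str_vals if v is not None and v not in seen)
            if unseen:
                logger.info(
                    "%d values of %s outside the frozen level registry (encoded all-zero)",
                    unseen,
                    entry.name,
                )
            for lv in levels:
                columns.append((str_vals == lv).astype(float))
                names.append(f"{entry.name}_{lv}")
    matrix = (
        np.column_stack(columns) if columns else np.empty((n, 0), dtype=float)
    )
    return Chunk(
        matrix=matrix,
        labels=labels,
        feature_names=names,
        chunk_index=chunk_index,
        n_dropped=n_dropped,
    )


def ingest_file(
    path: str | Path,
    schema: FeatureSchema,
    chunk_size: int = 10_000,
    percentile: float = 90.0,
    ref: OutcomeReference | None = None,
    registry: dict[str, list[str]] | None = None,
) -> Iterator[Chunk]:
    """Two-pass ingest driver: reference pass, then encoded labelled chunks."""
    if ref is None or registry is None:
        built_ref, built_registry = first_pass(path, schema, chunk_size, percentile)
        ref = ref if ref is not None else built_ref
        registry = registry if registry is not None else built_registry
    for idx, block in enumerate(stream_chunks(path, chunk_size, schema)):
        yield encode_and_impute(block, schema, ref, registry, chunk_index=idx)


def schema_from_cohort_config(config) -> FeatureSchema:
    """Build the matching ingest schema for a synthetic cohort config."""
    entries = [
        ColumnSpec("child_id", "identifier"),
        ColumnSpec("age", "outcome_source"),
        ColumnSpec("sex", "outcome_source"),
        ColumnSpec("bmi", "outcome_source"),
    ]
    for spec in config.feature_specs:
        if spec.kind == "numeric":
            entries.append(ColumnSpec(spec.name, "numeric"))
        else:
            entries.append(ColumnSpec(spec.name, "categorical", levels=tuple(spec.levels())))
    return FeatureSchema(entries=tuple(entries))
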