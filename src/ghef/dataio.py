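"""Dataset schema, CSV ingestion, splitting and design summary statistics.

A solubility record is one equilibrium measurement of a drug in
supercritical CO2: temperature (K), pressure (MPa), molecular weight
(g/mol), melting point (°C) and the observed solubility in the working
unit (g/L) × 10.  Solubility may be absent for prediction-only records;
every training-path operation rejects such records explicitly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

FEATURE_COLUMNS = ("temperature", "pressure", "molecular_weight", "melting_point")
TARGET_COLUMN = "solubility"
CSV_COLUMNS = ("compound",) + FEATURE_COLUMNS + (TARGET_COLUMN,)


class SchemaError(ValueError):
    """A CSV file does not carry the required solubility schema."""


@dataclass(frozen=True)
class SolubilityRecord:
    """One experimental observation (features x_i, optional target y_i)."""

    temperature: float
    pressure: float
    molecular_weight: float
    melting_point: float
    solubility: float | None = None
    compound: str = ""

    def __post_init__(self) -> None:
        for name in ("temperature", "pressure", "molecular_weight"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value!r}")
        if self.solubility is not None and self.solubility < 0:
            raise ValueError(f"solubility must be >= 0, got {self.solubility!r}")

    @property
    def features(self) -> tuple[float, float, float, float]:
        return (self.temperature, self.pressure, self.molecular_weight, self.melting_point)


@dataclass(frozen=True)
class Dataset:
    """Ordered collection of solubility records sharing one schema."""

    records: tuple[SolubilityRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if len(self.records) < 1:
            raise ValueError("a Dataset requires at least one record")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SolubilityRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SolubilityRecord:
        return self.records[i]

    @property
    def has_targets(self) -> bool:
        return all(r.solubility is not None for r in self.records)

    def feature_matrix(self) -> np.ndarray:
        """n × 4 array in the fixed order (T, P, MW, MP)."""
        return np.array([r.features for r in self.records], dtype=float)

    def targets(self) -> np.ndarray:
        if not self.has_targets:
            raise ValueError("dataset contains records without solubility values")
        return np.array([r.solubility for r in self.records], dtype=float)

    def compounds(self) -> tuple[str, ...]:
        """Distinct compound labels in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.compound, None)
        return tuple(seen)

    def subset(self, indices: Sequence[int]) -> "Dataset":
        return Dataset(tuple(self.records[i] for i in indices), provenance=self.provenance)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "compound": r.compound,
                "temperature": r.temperature,
                "pressure": r.pressure,
                "molecular_weight": r.molecular_weight,
                "melting_point": r.melting_point,
                "solubility": np.nan if r.solubility is None else r.solubility,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "") -> "Dataset":
        records = []
        for _, row in frame.iterrows():
            sol = row.get(TARGET_COLUMN, np.nan)
            records.append(
                SolubilityRecord(
                    temperature=float(row["temperature"]),
                    pressure=float(row["pressure"]),
                    molecular_weight=float(row["molecular_weight"]),
                    melting_point=float(row["melting_point"]),
                    solubility=None if pd.isna(sol) else float(sol),
                    compound="" if "compound" not in frame.columns or pd.isna(row["compound"]) else str(row["compound"]),
                )
            )
        return cls(tuple(records), provenance=provenance)


def read_dataset(path: str | Path) -> Dataset:
    """Read a solubility CSV (comma, '.' decimal, UTF-8, header required)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = [c for c in FEATURE_COLUMNS + (TARGET_COLUMN,) if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    if len(frame) == 0:
        raise SchemaError(f"{path}: no data rows")
    for col in FEATURE_COLUMNS + (TARGET_COLUMN,):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame[col].notna() & coerced.isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, counting the header line
            raise SchemaError(f"{path}: non-numeric value {frame[col][bad.idxmax()]!r} in column {col!r}, line {row}")
        frame[col] = coerced
    return Dataset.from_frame(frame, provenance=str(path))


def write_dataset(dataset: Dataset, path: str | Path) -> Path:
    """Write a dataset as CSV in canonical column order at full float precision."""
    path = Path(path)
    frame = dataset.to_frame()
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# Design summary statistics

SummaryMode = Literal["levels", "records"]


@dataclass(frozen=True)
class SummaryStats:
    """Per-compound, per-feature min/max/mean/population-std table.

    ``mode="levels"`` (default) summarizes the *distinct design levels* of
    each feature, which is how the published design table reports its
    statistics (four equally spaced temperature levels 308..338 K have
    population std sqrt(125) = 11.1803); ``mode="records"`` summarizes raw
    record values.
    """

    table: Mapping[str, Mapping[str, Mapping[str, float]]]
    mode: SummaryMode = "levels"

    def __getitem__(self, compound: str) -> Mapping[str, Mapping[str, float]]:
        return self.table[compound]

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps({c: {f: dict(s) for f, s in feats.items()} for c, feats in self.table.items()}, indent=indent)


def _stats(values: Sequence[float]) -> dict[str, float]:
    arr = np.asarray(values, dtype=float)
    return {
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
        "std": float(arr.std(ddof=0)),  # population std, matching the design table
    }


def summarize(dataset: Dataset, mode: SummaryMode = "levels") -> SummaryStats:
    """Summary statistics per compound and feature (plus solubility)."""
    frame = dataset.to_frame()
    table: dict[str, dict[str, dict[str, float]]] = {}
    for compound, group in frame.groupby("compound", sort=False):
        feats: dict[str, dict[str, float]] = {}
        for col in FEATURE_COLUMNS + (TARGET_COLUMN,):
            values = group[col].dropna().to_numpy()
            if values.size == 0:
                continue
            if mode == "levels":
                values = np.unique(values)
            feats[col] = _stats(values)
        table[str(compound)] = feats
    return SummaryStats(table=table, mode=mode)


# ---------------------------------------------------------------------------
# Train/test splitting


@dataclass(frozen=True)
class SplitResult:
    train: Dataset
    test: Dataset
    seed: int
    fraction: float


def _allocate_counts(sizes: Sequence[int], total_test: int) -> list[int]:
    """Largest-remainder allocation of `total_test` across strata."""
    n = sum(sizes)
    quotas = [s * total_test / n for s in sizes]
    counts = [math.floor(q) for q in quotas]
    remainders = sorted(range(len(sizes)), key=lambda i: (quotas[i] - counts[i], sizes[i]), reverse=True)
    k = total_test - sum(counts)
    for i in remainders[:k]:
        counts[i] += 1
    # never empty a stratum's training side if avoidable
    return counts


def split_train_test(dataset: Dataset, fraction: float, seed: int) -> SplitResult:
    """Sample round(n·fraction) test records without replacement.

    Stratified by compound label when labels exist, so every compound
    contributes proportionally to the held-out set.  Deterministic given
    ``seed``.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    n = len(dataset)
    n_test = int(round(n * fraction))
    if n_test < 1:
        raise ValueError(f"n*fraction = {n * fraction:.3g} yields an empty test set")
    rng = np.random.default_rng(seed)
    labels = [r.compound for r in dataset.records]
    strata: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        strata.setdefault(lab, []).append(i)
    if len(strata) > 1:
        counts = _allocate_counts([len(v) for v in strata.values()], n_test)
        test_idx: list[int] = []
        for (_, idx), c in zip(strata.items(), counts):
            test_idx.extend(rng.choice(idx, size=c, replace=False).tolist())
    else:
        test_idx = rng.choice(n, size=n_test, replace=False).tolist()
    test_set = sorted(test_idx)
    train_set = [i for i in range(n) if i not in set(test_set)]
    return SplitResult(
        train=dataset.subset(train_set),
        test=dataset.subset(test_set),
        seed=seed,
        fraction=fraction,
    )
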