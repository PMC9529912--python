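"""Data model for behavioral cohorts and CSV/JSON round-tripping.

A cohort is a rectangular table of animals x behavioral measures with
per-animal metadata (genotype, sex, cohort, treatment group).  Missing cells
are allowed and are represented as NaN.  The measure battery (names, units,
expected direction of impairment, bounds) is configuration, not inferred from
data, so the same machinery works for any disease model.
"""
from __future__ import annotations

import dataclasses
import json
import math
import typing
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

#: Metadata columns recognized in input CSVs, in canonical order.
METADATA_COLUMNS = ("animal_id", "genotype", "sex", "cohort", "group")

#: Cell contents treated as missing.  Anything else non-numeric is an error.
MISSING_SENTINELS = frozenset({"", "NA"})


@dataclass(frozen=True)
class MeasureSpec:
    """One behavioral measure in a battery.

    ``impairment_direction`` is the expected sign of (mutant - wildtype) for
    an impaired animal: +1 when impaired animals score higher (e.g. weight,
    forced-swim immobility), -1 when they score lower (e.g. rotarod latency,
    marbles buried).
    """

    name: str
    units: str = ""
    impairment_direction: int = 1
    bounds: Optional[tuple[float, float]] = None
    integer_valued: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("measure name must be non-empty")
        if self.impairment_direction not in (-1, 1):
            raise ValueError(
                f"impairment_direction for {self.name!r} must be +1 or -1, "
                f"got {self.impairment_direction}"
            )
        if self.bounds is not None:
            lo, hi = self.bounds
            if not lo < hi:
                raise ValueError(f"bounds for {self.name!r} require lo < hi")
            object.__setattr__(self, "bounds", (float(lo), float(hi)))


class AnimalRecord(typing.NamedTuple):
    """A single animal's metadata and measure values (NaN where missing)."""

    animal_id: str
    genotype: str
    sex: str
    cohort: Optional[str]
    group: Optional[str]
    values: dict[str, float]


@dataclass
class BehaviorDataset:
    """Animals x measures with metadata, backed by a pandas DataFrame.

    The DataFrame holds the metadata columns that are present (``animal_id``,
    ``genotype`` and ``sex`` always; ``cohort``/``group`` optionally) followed
    by one float column per battery measure, in battery order.
    """

    battery: list[MeasureSpec]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        names = [m.name for m in self.battery]
        if len(names) != len(set(names)):
            raise ValueError("duplicate measure names in battery")
        if len(self.battery) < 1:
            raise ValueError("battery needs at least one measure")
        if len(self.data) < 2:
            raise ValueError("dataset needs at least two animals")
        for col in ("animal_id", "genotype", "sex"):
            if col not in self.data.columns:
                raise ValueError(f"required column {col!r} absent")
        ids = self.data["animal_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate animal_id {dup!r}")
        for col in ("genotype", "sex"):
            vals = self.data[col]
            if vals.isna().any() or (vals.astype(str) == "").any():
                raise ValueError(f"missing {col} for some animals")
        for name in names:
            if name not in self.data.columns:
                raise ValueError(f"measure column {name!r} absent from data")
        meta = [c for c in METADATA_COLUMNS if c in self.data.columns]
        self.data = self.data.loc[:, meta + names].reset_index(drop=True)
        self.data[names] = self.data[names].astype(float)

    # -- convenience accessors -------------------------------------------

    @property
    def measures(self) -> list[str]:
        return [m.name for m in self.battery]

    @property
    def n_animals(self) -> int:
        return len(self.data)

    @property
    def animal_ids(self) -> list[str]:
        return self.data["animal_id"].tolist()

    @property
    def genotypes(self) -> np.ndarray:
        return self.data["genotype"].to_numpy()

    @property
    def sexes(self) -> np.ndarray:
        return self.data["sex"].to_numpy()

    @property
    def has_cohorts(self) -> bool:
        return "cohort" in self.data.columns

    @property
    def has_groups(self) -> bool:
        return "group" in self.data.columns

    def values_matrix(self, measures: Optional[Sequence[str]] = None) -> np.ndarray:
        """Animals x measures float matrix (NaN for missing)."""
        cols = list(measures) if measures is not None else self.measures
        return self.data[cols].to_numpy(dtype=float)

    def spec_for(self, name: str) -> MeasureSpec:
        for m in self.battery:
            if m.name == name:
                return m
        raise KeyError(name)

    def animals(self) -> Iterator[AnimalRecord]:
        for _, row in self.data.iterrows():
            yield AnimalRecord(
                animal_id=row["animal_id"],
                genotype=row["genotype"],
                sex=row["sex"],
                cohort=row.get("cohort"),
                group=row.get("group"),
                values={m: float(row[m]) for m in self.measures},
            )

    def select_rows(self, mask: np.ndarray) -> "BehaviorDataset":
        """Subset of animals by boolean mask (battery unchanged)."""
        return BehaviorDataset(list(self.battery), self.data.loc[np.asarray(mask)].copy())

    def missingness_report(self) -> pd.DataFrame:
        """Per-cohort count of missing cells per measure."""
        key = "cohort" if self.has_cohorts else "animal_id"
        return self.data.groupby(key)[self.measures].apply(lambda g: g.isna().sum())


# ---------------------------------------------------------------------------
# Battery configuration IO
# ---------------------------------------------------------------------------

def load_battery(path: str | Path) -> list[MeasureSpec]:
    """Read a battery config: a JSON list of measure-spec objects."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    specs = []
    for entry in raw:
        bounds = entry.get("bounds")
        specs.append(
            MeasureSpec(
                name=entry["name"],
                units=entry.get("units", ""),
                impairment_direction=int(entry.get("impairment_direction", 1)),
                bounds=tuple(bounds) if bounds is not None else None,
                integer_valued=bool(entry.get("integer_valued", False)),
            )
        )
    return specs


def save_battery(battery: Sequence[MeasureSpec], path: str | Path) -> None:
    out = []
    for m in battery:
        out.append(
            {
                "name": m.name,
                "units": m.units,
                "impairment_direction": m.impairment_direction,
                "bounds": list(m.bounds) if m.bounds is not None else None,
                "integer_valued": m.integer_valued,
            }
        )
    Path(path).write_text(json.dumps(out, indent=2), encoding="utf-8")


# ---------------------------------------------------------------------------
# Dataset IO
# ---------------------------------------------------------------------------

def read_dataset(path: str | Path, battery: Sequence[MeasureSpec] | str | Path) -> BehaviorDataset:
    """Parse a cohort CSV against a battery config.

    The CSV must have a header with ``animal_id``, ``genotype``, ``sex``
    (optionally ``cohort`` and ``group``) followed by one column per measure.
    Empty cells and the literal ``NA`` are missing; any other non-numeric
    measure cell raises with its row and column.
    """
    if isinstance(battery, (str, Path)):
        battery = load_battery(battery)
    battery = list(battery)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    names = [m.name for m in battery]
    for col in df.columns:
        if col not in METADATA_COLUMNS and col not in names:
            raise ValueError(f"column {col!r} is not in the battery config")
    for name in names:
        if name not in df.columns:
            raise ValueError(f"battery measure {name!r} has no column in {path}")
    parsed = {}
    for name in names:
        vals = []
        for i, cell in enumerate(df[name]):
            cell = cell.strip()
            if cell in MISSING_SENTINELS:
                vals.append(math.nan)
            else:
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"non-numeric value {cell!r} in column {name!r}, row {i + 2}"
                    ) from None
        parsed[name] = vals
    for name, vals in parsed.items():
        df[name] = vals
    return BehaviorDataset(battery, df)


def write_dataset(ds: BehaviorDataset, path: str | Path) -> None:
    """Write a cohort CSV (missing values as empty cells).

    Float formatting uses Python's shortest round-tripping repr, so
    write-then-read reproduces values bit for bit.
    """
    df = ds.data.copy()
    for name in ds.measures:
        df[name] = [("" if math.isnan(v) else repr(v)) for v in df[name]]
    df.to_csv(path, index=False)


def complete_case_subset(
    ds: BehaviorDataset, measures: Optional[Sequence[str]] = None
) -> BehaviorDataset:
    """Animals with non-missing values for every requested measure.

    The battery is restricted to the requested measures (in battery order).
    Idempotent, and monotone: requesting more measures never increases the
    animal count.
    """
    if measures is None:
        measures = ds.measures
    measures = list(measures)
    unknown = set(measures) - set(ds.measures)
    if unknown:
        raise ValueError(f"measures not in battery: {sorted(unknown)}")
    keep_specs = [m for m in ds.battery if m.name in set(measures)]
    names = [m.name for m in keep_specs]
    mask = ds.data[names].notna().all(axis=1)
    if not mask.any():
        raise ValueError("no complete cases for the requested measures")
    meta = [c for c in METADATA_COLUMNS if c in ds.data.columns]
    sub = ds.data.loc[mask, meta + names].copy()
    return BehaviorDataset(keep_specs, sub)


# ---------------------------------------------------------------------------
# Generic result serialization
# ---------------------------------------------------------------------------

def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [_to_jsonable(v) for v in seq]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def _from_jsonable(tp, obj):
    origin = typing.get_origin(tp)
    args = typing.get_args(tp)
    if obj is None:
        return None
    if origin is typing.Union:
        non_none = [a for a in args if a is not type(None)]
        return _from_jsonable(non_none[0], obj) if len(non_none) == 1 else obj
    if dataclasses.is_dataclass(tp) and isinstance(tp, type):
        hints = typing.get_type_hints(tp)
        kwargs = {f.name: _from_jsonable(hints[f.name], obj[f.name]) for f in dataclasses.fields(tp)}
        return tp(**kwargs)
    if tp is np.ndarray:
        return np.asarray(obj, dtype=float)
    if origin in (list, typing.List):
        return [_from_jsonable(args[0] if args else typing.Any, v) for v in obj]
    if origin in (tuple, typing.Tuple):
        if args and args[-1] is Ellipsis:
            return tuple(_from_jsonable(args[0], v) for v in obj)
        if args:
            return tuple(_from_jsonable(a, v) for a, v in zip(args, obj))
        return tuple(obj)
    if origin in (dict, typing.Dict):
        kt = args[0] if args else str
        vt = args[1] if args else typing.Any
        caster = int if kt is int else str
        return {caster(k): _from_jsonable(vt, v) for k, v in obj.items()}
    if origin in (set, frozenset):
        return origin(obj)
    if tp is float:
        return float(obj)
    if tp is int:
        return int(obj)
    return obj


def write_results(obj, path: str | Path) -> None:
    """Serialize a result object: DataFrames to CSV, everything else to JSON."""
    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
        return
    payload = {"type": type(obj).__name__, "payload": _to_jsonable(obj)}
    path.write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_results(path: str | Path, cls):
    """Reconstruct a dataclass result previously written by write_results."""
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    if raw.get("type") != cls.__name__:
        raise ValueError(f"expected {cls.__name__}, file holds {raw.get('type')!r}")
    return _from_jsonable(cls, raw["payload"])
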