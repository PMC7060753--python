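"""Reading, validation, filtering and merging of constant-temperature incubation records.

The unit of observation is one incubation group: a clutch (or pooled clutches)
of eggs incubated at a constant setpoint temperature, with the resulting
hatchlings sexed as male, female or intersex. Sex ratio is expressed as the
relative male frequency throughout.

The CSV dialect mirrors the column layout of the ``databaseTSD`` distribution:
comma separated, UTF-8, header row required, default column names
``Area, Country, RMU, Incubation.temperature, Incubation.temperature.Amplitude,
Males, Females, Intersexes, Reference`` (overridable through ``column_map``).
A ``Correction.factor`` column, when present, is parsed and stored but never
applied to the temperatures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "IncubationGroup",
    "TSDDataset",
    "SchemaError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "filter_dataset",
    "merge_duplicate_temperatures",
    "table1_fixture",
]

#: default CSV column names -> IncubationGroup field names
DEFAULT_COLUMNS: Mapping[str, str] = {
    "Area": "area",
    "Country": "country",
    "RMU": "rmu",
    "Incubation.temperature": "temperature",
    "Incubation.temperature.Amplitude": "amplitude",
    "Males": "males",
    "Females": "females",
    "Intersexes": "intersexes",
    "Reference": "reference",
    "Correction.factor": "correction_factor",
}

REQUIRED_FIELDS = ("temperature", "males", "females")


class SchemaError(ValueError):
    """A required column could not be resolved in the input file."""


class ValidationError(ValueError):
    """A row violates an invariant (negative/fractional count, non-finite temperature)."""


@dataclass(frozen=True)
class IncubationGroup:
    """One constant-temperature incubation group.

    Parameters
    ----------
    temperature
        Constant incubation setpoint in degrees Celsius.
    amplitude
        Maximum temperature amplitude (whole or middle-third of incubation)
        in degrees Celsius, or ``None`` when not reported. Groups with
        unreported amplitude are retained by the amplitude filter.
    males, females, intersexes
        Counts of sexed embryos/hatchlings.
    correction_factor
        Incubator-vs-egg temperature offset when reported; stored only,
        never applied.
    """

    temperature: float
    males: int
    females: int
    intersexes: int = 0
    amplitude: float | None = None
    area: str = ""
    country: str = ""
    rmu: str = ""
    reference: str = ""
    correction_factor: float | None = None

    def __post_init__(self) -> None:
        for name in ("males", "females", "intersexes"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                if isinstance(v, float) and v.is_integer() and v >= 0:
                    object.__setattr__(self, name, int(v))
                else:
                    raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative, got {v!r}")
        if not math.isfinite(self.temperature):
            raise ValidationError(f"temperature must be finite, got {self.temperature!r}")
        if self.amplitude is not None:
            if math.isnan(self.amplitude):
                object.__setattr__(self, "amplitude", None)
            elif self.amplitude < 0:
                raise ValidationError(f"amplitude must be >= 0, got {self.amplitude!r}")

    @property
    def n_sexed(self) -> int:
        """Males + females (intersexes are never part of the binomial total)."""
        return self.males + self.females

    @property
    def is_mixed(self) -> bool:
        """True when both sexes were observed at this temperature."""
        return self.males > 0 and self.females > 0


@dataclass
class TSDDataset:
    """Ordered collection of incubation groups; the unit of model fitting."""

    groups: list[IncubationGroup]
    label: str = ""
    filters_applied: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups)

    # -- aggregate views -------------------------------------------------
    @property
    def temperatures(self) -> list[float]:
        return [g.temperature for g in self.groups]

    @property
    def total_males(self) -> int:
        return sum(g.males for g in self.groups)

    @property
    def total_females(self) -> int:
        return sum(g.females for g in self.groups)

    @property
    def total_intersexes(self) -> int:
        return sum(g.intersexes for g in self.groups)

    @property
    def n_mixed(self) -> int:
        return sum(g.is_mixed for g in self.groups)

    def n_distinct_temperatures(self, tolerance: float = 0.0) -> int:
        """Number of distinct temperatures, merging values within ``tolerance``."""
        return len(merge_duplicate_temperatures(self, tolerance).groups)

    def has_sexed_embryos(self) -> bool:
        return any(g.n_sexed >= 1 for g in self.groups)

    # -- selection -------------------------------------------------------
    def subset(
        self,
        rmu: str | None = None,
        country: str | None = None,
        area: str | None = None,
        label: str | None = None,
    ) -> "TSDDataset":
        """Stable-order subset by RMU / country / area labels."""
        keep = [
            g
            for g in self.groups
            if (rmu is None or g.rmu == rmu)
            and (country is None or g.country == country)
            and (area is None or g.area == area)
        ]
        if label is None:
            parts = [p for p in (rmu, country, area) if p is not None]
            label = " / ".join(parts) if parts else self.label
        return TSDDataset(keep, label=label, filters_applied=list(self.filters_applied))

    def to_frame(self) -> pd.DataFrame:
        inv = {v: k for k, v in DEFAULT_COLUMNS.items()}
        records = []
        for g in self.groups:
            rec = {
                inv["area"]: g.area,
                inv["country"]: g.country,
                inv["rmu"]: g.rmu,
                inv["temperature"]: g.temperature,
                inv["amplitude"]: g.amplitude,
                inv["males"]: g.males,
                inv["females"]: g.females,
                inv["intersexes"]: g.intersexes,
                inv["reference"]: g.reference,
            }
            if g.correction_factor is not None:
                rec[inv["correction_factor"]] = g.correction_factor
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def filter_report_json(self) -> str:
        return json.dumps(self.filters_applied, indent=2)


def _parse_count(value, row: int, column: str) -> int:
    if pd.isna(value):
        return 0
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: non-numeric {column} value {value!r}") from None
    if not f.is_integer():
        raise ValidationError(f"row {row}: fractional {column} count {value!r}")
    if f < 0:
        raise ValidationError(f"row {row}: negative {column} count {value!r}")
    return int(f)


def read_dataset(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    label: str | None = None,
) -> TSDDataset:
    """Read incubation records from a ``databaseTSD``-style CSV file.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Optional mapping from CSV column name to field name, overriding
        entries of :data:`DEFAULT_COLUMNS`.
    label
        Dataset label; defaults to the file stem.

    Raises
    ------
    SchemaError
        When one of the required columns (temperature, males, females)
        cannot be resolved.
    ValidationError
        On negative, fractional or non-numeric counts (with the row index).
    """
    path = Path(path)
    frame = pd.read_csv(path)
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    by_field = {v: k for k, v in colmap.items() if k in frame.columns}
    for required in REQUIRED_FIELDS:
        if required not in by_field:
            wanted = [k for k, v in colmap.items() if v == required]
            raise SchemaError(f"missing required column {wanted[0]!r} (field {required})")

    groups: list[IncubationGroup] = []
    for i, row in frame.iterrows():
        tval = row[by_field["temperature"]]
        try:
            temperature = float(tval)
        except (TypeError, ValueError):
            raise ValidationError(f"row {i}: non-numeric temperature {tval!r}") from None

        def _opt_float(fieldname: str) -> float | None:
            if fieldname not in by_field:
                return None
            v = row[by_field[fieldname]]
            return None if pd.isna(v) else float(v)

        def _opt_str(fieldname: str) -> str:
            if fieldname not in by_field:
                return ""
            v = row[by_field[fieldname]]
            return "" if pd.isna(v) else str(v)

        try:
            group = IncubationGroup(
                temperature=temperature,
                amplitude=_opt_float("amplitude"),
                males=_parse_count(row[by_field["males"]], i, "males"),
                females=_parse_count(row[by_field["females"]], i, "females"),
                intersexes=(
                    _parse_count(row[by_field["intersexes"]], i, "intersexes")
                    if "intersexes" in by_field
                    else 0
                ),
                area=_opt_str("area"),
                country=_opt_str("country"),
                rmu=_opt_str("rmu"),
                reference=_opt_str("reference"),
                correction_factor=_opt_float("correction_factor"),
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        groups.append(group)
    return TSDDataset(groups, label=label if label is not None else path.stem)


def write_dataset(ds: TSDDataset, path: str | Path) -> None:
    """Serialize a dataset back to the same CSV dialect."""
    ds.to_frame().to_csv(path, index=False)


def filter_dataset(
    ds: TSDDataset,
    max_amplitude: float = 2.0,
    drop_intersex: bool = True,
) -> TSDDataset:
    """Apply the standard exclusion rules for constant-incubation analyses.

    Groups whose recorded temperature amplitude exceeds ``max_amplitude``
    (default 2 degrees C) are removed; groups with unreported amplitude are
    retained. When ``drop_intersex`` is set, intersex individuals are removed
    from the analysable totals (the group itself is kept as long as it still
    carries males or females). Both rules, with counts of removed groups and
    embryos, are appended to ``filters_applied``; filtering is idempotent.
    """
    removed_groups = [
        g for g in ds.groups if g.amplitude is not None and g.amplitude > max_amplitude
    ]
    kept = [g for g in ds.groups if g not in removed_groups]
    report = {
        "filter": "max_amplitude",
        "max_amplitude": max_amplitude,
        "groups_removed": len(removed_groups),
        "embryos_removed": sum(g.males + g.females + g.intersexes for g in removed_groups),
    }
    reports = [report]
    if drop_intersex:
        n_intersex = sum(g.intersexes for g in kept)
        kept = [replace(g, intersexes=0) for g in kept]
        reports.append(
            {
                "filter": "drop_intersex",
                "intersex_excluded": n_intersex,
            }
        )
    return TSDDataset(
        kept,
        label=ds.label,
        filters_applied=list(ds.filters_applied) + reports,
    )


def merge_duplicate_temperatures(ds: TSDDataset, tolerance: float = 0.0) -> TSDDataset:
    """Pool groups whose temperatures coincide within ``tolerance``.

    Counts are summed; the first group of each pooled run supplies the labels.
    The result has strictly distinct temperatures and preserves the order of
    first appearance. Used for the distinct-temperature sample-size convention
    of the BIC dataset comparison; never applied before likelihood evaluation.
    """
    if tolerance < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")
    merged: list[IncubationGroup] = []
    for g in ds.groups:
        for i, m in enumerate(merged):
            if abs(m.temperature - g.temperature) <= tolerance:
                merged[i] = replace(
                    m,
                    males=m.males + g.males,
                    females=m.females + g.females,
                    intersexes=m.intersexes + g.intersexes,
                )
                break
        else:
            merged.append(g)
    return TSDDataset(merged, label=ds.label, filters_applied=list(ds.filters_applied))


def table1_fixture() -> TSDDataset:
    """The 40 constant-temperature *Lepidochelys olivacea* incubation groups.

    Covers three Regional Management Units (West Atlantic, Northeast Indian,
    East Pacific) from six nesting beaches; 277 males, 168 females and
    19 intersexes. Subsets are available through :meth:`TSDDataset.subset`.
    """
    ref = resources.files("tsdfit.data").joinpath(
        "lepidochelys_olivacea_constant_incubations.csv"
    )
    with resources.as_file(ref) as path:
        return read_dataset(path, label="Lepidochelys olivacea (worldwide)")
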