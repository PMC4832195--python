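"""Validated I/O for sample tables, sample metadata and design summaries.

Tables are plain delimited text (comma or tab, auto-detected from the
header line): samples in rows, variables in columns, the first column
holding sample identifiers.  The variable category (``ion`` vs ``enzyme``)
travels either as a per-table default or in a two-column *variables
manifest* file, because bare names like ``"P"`` are ambiguous.  Missing
values are rejected, never imputed.

Ion concentrations are extract concentrations; enzyme activities are
expressed in nmol · h⁻¹ · g⁻¹ soil.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("ion", "enzyme")
TREATMENTS = ("CF", "COF")
METADATA_COLUMNS = ("sample_id", "site", "fertilization", "replicate", "pH")

#: significant digits used for all numeric text output (>= 10 required
#: so that write→read round trips are value-identical at tested precision)
FLOAT_FORMAT = "%.12g"


class ValidationError(ValueError):
    """An input object violates a documented contract."""


class TableParseError(ValueError):
    """A delimited table could not be parsed into numbers."""


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


# ---------------------------------------------------------------------------
# SampleTable
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleTable:
    """A samples × variables matrix of non-negative measurements.

    Parameters
    ----------
    sample_ids : ordered unique sample labels (rows).
    variable_ids : ordered unique variable labels (columns).
    categories : per-variable category, each one of ``{"ion", "enzyme"}``.
    values : ``(n_samples, n_variables)`` array of finite, non-negative reals.
    """

    sample_ids: tuple
    variable_ids: tuple
    categories: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "variable_ids", tuple(str(v) for v in self.variable_ids))
        object.__setattr__(self, "categories", tuple(str(c) for c in self.categories))
        values = np.asarray(self.values, dtype=float).copy()
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if len(set(self.variable_ids)) != len(self.variable_ids):
            raise ValidationError("duplicate variable ids")
        if len(self.categories) != len(self.variable_ids):
            raise ValidationError("exactly one category per variable is required")
        unknown = set(self.categories) - set(CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown variable categories: {sorted(unknown)}")
        if values.ndim != 2 or values.shape != (len(self.sample_ids), len(self.variable_ids)):
            raise ValidationError(
                f"values shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.variable_ids)} variables"
            )
        if not np.all(np.isfinite(values)):
            i, j = map(int, np.argwhere(~np.isfinite(values))[0])
            raise ValidationError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"variable {self.variable_ids[j]!r}"
            )
        if np.any(values < 0):
            i, j = map(int, np.argwhere(values < 0)[0])
            raise ValidationError(
                f"negative value at sample {self.sample_ids[i]!r}, "
                f"variable {self.variable_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variables(self) -> int:
        return len(self.variable_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.asarray(self.values),
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=list(self.variable_ids),
        )

    def column(self, variable_id: str) -> np.ndarray:
        try:
            j = self.variable_ids.index(variable_id)
        except ValueError:
            raise KeyError(f"unknown variable {variable_id!r}") from None
        return np.asarray(self.values[:, j])

    def subset_samples(self, sample_ids: Sequence[str]) -> "SampleTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in sample_ids]
        except KeyError as exc:
            raise ValidationError(f"unknown sample id {exc.args[0]!r}") from None
        return SampleTable(tuple(sample_ids), self.variable_ids, self.categories,
                           self.values[rows, :])

    def write(self, path, delimiter: str = ",") -> None:
        self.to_dataframe().to_csv(path, sep=delimiter, float_format=FLOAT_FORMAT)


def concat_tables(first: SampleTable, second: SampleTable) -> SampleTable:
    """Column-concatenate two tables sharing an identical sample order."""
    if first.sample_ids != second.sample_ids:
        raise ValidationError("tables have different sample ids or ordering")
    return SampleTable(
        first.sample_ids,
        first.variable_ids + second.variable_ids,
        first.categories + second.categories,
        np.hstack([first.values, second.values]),
    )


def read_sample_table(
    path,
    category: str = "ion",
    manifest: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> SampleTable:
    """Read a delimited samples × variables table.

    The delimiter is auto-detected from the header line unless given.
    ``category`` applies to every variable unless a ``manifest`` mapping
    (variable_id → category) is supplied.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = delimiter or _detect_delimiter(header)
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str, na_filter=False)
    sample_ids = [str(s) for s in frame.index]
    variable_ids = [str(c) for c in frame.columns]

    values = np.empty(frame.shape, dtype=float)
    raw = frame.to_numpy()
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            cell = raw[i, j]
            try:
                if not isinstance(cell, str):
                    raise ValueError
                values[i, j] = float(cell)
            except ValueError:
                raise TableParseError(
                    f"non-numeric cell {cell!r} at row {sample_ids[i]!r}, "
                    f"column {variable_ids[j]!r} of {path.name}"
                ) from None
            if not np.isfinite(values[i, j]):
                raise TableParseError(
                    f"non-finite cell {cell!r} at row {sample_ids[i]!r}, "
                    f"column {variable_ids[j]!r} of {path.name}"
                )

    if manifest is not None:
        try:
            categories = tuple(manifest[v] for v in variable_ids)
        except KeyError as exc:
            raise ValidationError(
                f"variable {exc.args[0]!r} missing from variables manifest"
            ) from None
    else:
        categories = (category,) * len(variable_ids)
    return SampleTable(tuple(sample_ids), tuple(variable_ids), categories, values)


def read_variables_manifest(path) -> dict:
    """Read a two-column (variable_id, category) manifest file."""
    with open(path) as fh:
        header = fh.readline()
    sep = _detect_delimiter(header)
    frame = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("variable_id", "category"):
        if col not in frame.columns:
            raise ValidationError(f"variables manifest is missing column {col!r}")
    out = dict(zip(frame["variable_id"], frame["category"]))
    unknown = set(out.values()) - set(CATEGORIES)
    if unknown:
        raise ValidationError(f"unknown variable categories in manifest: {sorted(unknown)}")
    return out


def write_variables_manifest(manifest: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"variable_id": list(manifest), "category": list(manifest.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metadata:
    """Validated per-sample metadata (site, fertilization, replicate, pH).

    Fertilization labels are normalized to ``CF``/``COF``; every
    (site, fertilization) cell must hold at least two replicates because
    downstream variance estimation requires it.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        frame = self.frame.copy()
        missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"metadata is missing columns {missing}")
        frame = frame.loc[:, list(METADATA_COLUMNS)].reset_index(drop=True)
        frame["sample_id"] = frame["sample_id"].astype(str)
        frame["site"] = frame["site"].astype(str)
        frame["fertilization"] = frame["fertilization"].astype(str).str.upper()

        if frame["sample_id"].duplicated().any():
            dupes = sorted(frame.loc[frame["sample_id"].duplicated(), "sample_id"])
            raise ValidationError(f"duplicate sample ids in metadata: {dupes}")
        bad_fert = sorted(set(frame["fertilization"]) - set(TREATMENTS))
        if bad_fert:
            raise ValidationError(
                f"unknown fertilization labels {bad_fert}; expected one of {TREATMENTS}"
            )
        reps = pd.to_numeric(frame["replicate"], errors="coerce")
        if reps.isna().any() or (reps <= 0).any() or (reps != reps.round()).any():
            raise ValidationError("replicate must be a positive integer")
        frame["replicate"] = reps.astype(int)
        ph = pd.to_numeric(frame["pH"], errors="coerce")
        if ph.isna().any():
            raise ValidationError("pH must be numeric")
        if ((ph < 0) | (ph > 14)).any():
            offender = frame.loc[(ph < 0) | (ph > 14), "sample_id"].iloc[0]
            raise ValidationError(f"pH outside [0, 14] for sample {offender!r}")
        frame["pH"] = ph.astype(float)

        cell_sizes = frame.groupby(["site", "fertilization"]).size()
        if (cell_sizes < 2).any():
            small = cell_sizes[cell_sizes < 2].index.tolist()
            raise ValidationError(
                f"(site, fertilization) cells with fewer than 2 replicates: {small}"
            )
        object.__setattr__(self, "frame", frame)

    @property
    def sample_ids(self) -> tuple:
        return tuple(self.frame["sample_id"])

    def samples_where(self, fertilization: str | None = None, site: str | None = None) -> tuple:
        mask = pd.Series(True, index=self.frame.index)
        if fertilization is not None:
            mask &= self.frame["fertilization"] == fertilization.upper()
        if site is not None:
            mask &= self.frame["site"] == site
        return tuple(self.frame.loc[mask, "sample_id"])

    def ph_for(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = dict(zip(self.frame["sample_id"], self.frame["pH"]))
        return np.array([lookup[s] for s in sample_ids], dtype=float)

    def row(self, sample_id: str) -> pd.Series:
        match = self.frame[self.frame["sample_id"] == sample_id]
        if match.empty:
            raise KeyError(sample_id)
        return match.iloc[0]

    def validate_against(self, table: SampleTable) -> None:
        missing = set(table.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"samples missing from metadata: {sorted(missing)}")

    def write(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_metadata(path) -> Metadata:
    with open(path) as fh:
        header = fh.readline()
    sep = _detect_delimiter(header)
    return Metadata(pd.read_csv(path, sep=sep))


# ---------------------------------------------------------------------------
# Design summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignSummary:
    n_sites: int
    n_treatments: int
    n_replicates_per_cell: int
    n_samples_total: int
    balanced: bool


def summarize_design(metadata: Metadata) -> DesignSummary:
    """Count the factorial structure of the sampling design.

    ``balanced`` is true iff every (site, fertilization) cell holds the same
    number of replicates; for unbalanced designs ``n_replicates_per_cell``
    reports the smallest cell.
    """
    frame = metadata.frame
    if frame.empty:
        raise ValidationError("empty metadata")
    cells = frame.groupby(["site", "fertilization"]).size()
    balanced = cells.nunique() == 1
    return DesignSummary(
        n_sites=int(frame["site"].nunique()),
        n_treatments=int(frame["fertilization"].nunique()),
        n_replicates_per_cell=int(cells.min()),
        n_samples_total=int(len(frame)),
        balanced=bool(balanced),
    )
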