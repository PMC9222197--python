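"""Data model and I/O for differential-centrifugation fraction profiles.

A fractionation experiment quantifies each protein across ``F`` sequential
centrifugation fractions (default ``F = 10``), in one or more biological
replicates of a single condition.  Profiles are made compositional by
normalizing each protein/replicate vector to sum to one, replicates are then
concatenated column-wise into the matrix consumed by the classifier and the
differential-localization test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateProfileError,
    EmptyResultError,
    IntegrityError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: Canonical compartment set used throughout (11 classes).
DEFAULT_CLASSES: tuple[str, ...] = (
    "cytosol",
    "ER",
    "proteasome",
    "Golgi",
    "lysosome",
    "mitochondrion",
    "nucleus",
    "nucleus-chromatin",
    "ribosome",
    "peroxisome",
    "plasma membrane",
)

#: Label used for proteins without a confident compartment assignment.
UNKNOWN_LABEL = "unknown"


@dataclass(frozen=True)
class ProfileSchema:
    """Column naming convention for profile tables.

    Wide form: one row per (protein, replicate) with columns
    ``fraction_1 .. fraction_F``.  Long form: one row per
    (protein, replicate, fraction) with an ``abundance`` column.
    """

    protein_col: str = "protein_id"
    replicate_col: str = "replicate"
    fraction_prefix: str = "fraction_"
    fraction_col: str = "fraction"
    abundance_col: str = "abundance"


DEFAULT_SCHEMA = ProfileSchema()


@dataclass
class FractionationExperiment:
    """One condition's replicate set of protein x fraction abundance tables.

    Parameters
    ----------
    condition_label : str
        Free-text condition name (e.g. ``"control"``).
    replicates : list of pandas.DataFrame
        One table per replicate, indexed by protein id, with ``F`` numeric
        fraction columns in centrifugation order (1-based naming).
    replicate_labels : list of str
        Replicate names, same order as ``replicates``.
    """

    condition_label: str
    replicates: list[pd.DataFrame]
    replicate_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise IntegrityError("experiment needs at least one replicate")
        if not self.replicate_labels:
            self.replicate_labels = [str(i + 1) for i in range(len(self.replicates))]
        if len(self.replicate_labels) != len(self.replicates):
            raise IntegrityError("replicate_labels length mismatch")
        widths = {t.shape[1] for t in self.replicates}
        if len(widths) != 1:
            raise IntegrityError(f"replicates disagree on fraction count: {sorted(widths)}")
        for label, table in zip(self.replicate_labels, self.replicates):
            values = table.to_numpy(dtype=float)
            if not np.all(np.isfinite(values)):
                raise IntegrityError(f"replicate {label!r}: non-finite abundance")
            if (values < 0).any():
                raise IntegrityError(f"replicate {label!r}: negative abundance")
            if table.index.has_duplicates:
                dup = table.index[table.index.duplicated()][0]
                raise IntegrityError(f"replicate {label!r}: duplicate protein {dup!r}")

    @property
    def n_fractions(self) -> int:
        return self.replicates[0].shape[1]

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


@dataclass
class SpatialProfileMatrix:
    """Proteins x concatenated sum-normalized fraction profiles.

    ``replicate_boundaries`` holds half-open column ranges ``(start, stop)``
    (0-based) delimiting each replicate's block of ``F`` columns.
    """

    protein_ids: list[str]
    matrix: np.ndarray
    replicate_boundaries: list[tuple[int, int]]
    n_fractions: int
    condition_label: str = ""
    replicate_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.protein_ids), self.n_fractions * len(self.replicate_boundaries)):
            raise IntegrityError("matrix shape inconsistent with ids/boundaries")
        for start, stop in self.replicate_boundaries:
            block = self.matrix[:, start:stop]
            if self.matrix.size and not np.allclose(block.sum(axis=1), 1.0, atol=1e-9):
                raise IntegrityError("replicate block rows must sum to 1 +/- 1e-9")

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_boundaries)

    def replicate_block(self, r: int) -> np.ndarray:
        start, stop = self.replicate_boundaries[r]
        return self.matrix[:, start:stop]

    def row(self, protein_id: str) -> np.ndarray:
        return self.matrix[self.protein_ids.index(protein_id)]

    def profiles_of(self, protein_id: str) -> np.ndarray:
        """Return the (R, F) array of per-replicate compositions for one protein."""
        i = self.protein_ids.index(protein_id)
        return self.matrix[i].reshape(self.n_replicates, self.n_fractions)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"rep{r + 1}_fraction_{f + 1}"
            for r in range(self.n_replicates)
            for f in range(self.n_fractions)
        ]
        return pd.DataFrame(self.matrix, index=pd.Index(self.protein_ids, name="protein_id"), columns=cols)


@dataclass
class MarkerMap:
    """Curated protein -> compartment assignments used as training labels."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise IntegrityError("marker map is empty")

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.entries.values())))

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cls in self.entries.values():
            counts[cls] = counts.get(cls, 0) + 1
        return dict(sorted(counts.items()))

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, protein_ids: Iterable[str]) -> "MarkerMap":
        keep = set(protein_ids)
        return MarkerMap({p: c for p, c in self.entries.items() if p in keep})


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a UTF-8 tabular file; delimiter chosen by extension (.csv -> comma)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def _write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame.to_csv(path, sep=sep, index=index)


def read_profiles(
    path: str | Path,
    schema: ProfileSchema = DEFAULT_SCHEMA,
    condition_label: str = "",
) -> FractionationExperiment:
    """Load a wide- or long-form profile table into an experiment.

    Wide form needs columns ``protein_id, replicate, fraction_1..fraction_F``;
    long form needs ``protein_id, replicate, fraction, abundance``.  Replicates
    are ordered by replicate label.  Negative, missing or non-numeric
    abundances are rejected.
    """
    raw = _read_table(path)
    cols = list(raw.columns)
    for required in (schema.protein_col, schema.replicate_col):
        if required not in cols:
            raise SchemaError(f"{path}: missing required column {required!r}")

    fraction_cols = [c for c in cols if c.startswith(schema.fraction_prefix)]
    if fraction_cols:
        # wide form; order fraction columns by their numeric suffix
        try:
            fraction_cols.sort(key=lambda c: int(c[len(schema.fraction_prefix):]))
        except ValueError as exc:
            raise SchemaError(f"{path}: non-integer fraction column suffix") from exc
        long = raw.melt(
            id_vars=[schema.protein_col, schema.replicate_col],
            value_vars=fraction_cols,
            var_name=schema.fraction_col,
            value_name=schema.abundance_col,
        )
        long[schema.fraction_col] = (
            long[schema.fraction_col].str[len(schema.fraction_prefix):].astype(int)
        )
    elif {schema.fraction_col, schema.abundance_col}.issubset(cols):
        long = raw[[schema.protein_col, schema.replicate_col, schema.fraction_col, schema.abundance_col]].copy()
    else:
        raise SchemaError(
            f"{path}: expected either {schema.fraction_prefix}1..F columns (wide) "
            f"or ({schema.fraction_col!r}, {schema.abundance_col!r}) columns (long)"
        )

    values = pd.to_numeric(long[schema.abundance_col], errors="coerce")
    if values.isna().any():
        bad = long.loc[values.isna(), schema.protein_col].iloc[0]
        raise IntegrityError(f"{path}: non-numeric or missing abundance (protein {bad!r})")
    if (values < 0).any():
        bad = long.loc[values < 0, schema.protein_col].iloc[0]
        raise IntegrityError(f"{path}: negative abundance (protein {bad!r})")
    long[schema.abundance_col] = values.astype(float)

    dup = long.duplicated([schema.protein_col, schema.replicate_col, schema.fraction_col])
    if dup.any():
        bad = long.loc[dup, [schema.protein_col, schema.replicate_col]].iloc[0]
        raise IntegrityError(
            f"{path}: duplicate entry for protein {bad.iloc[0]!r} replicate {bad.iloc[1]!r}"
        )

    replicate_labels = sorted(long[schema.replicate_col].astype(str).unique())
    tables = []
    for label in replicate_labels:
        sub = long[long[schema.replicate_col].astype(str) == label]
        wide = sub.pivot(index=schema.protein_col, columns=schema.fraction_col, values=schema.abundance_col)
        if wide.isna().any().any():
            bad = wide.index[wide.isna().any(axis=1)][0]
            raise IntegrityError(f"{path}: incomplete fraction series for protein {bad!r}")
        wide = wide[sorted(wide.columns)]
        wide.columns = [f"{schema.fraction_prefix}{f}" for f in wide.columns]
        wide.index.name = schema.protein_col
        tables.append(wide)
    return FractionationExperiment(condition_label or Path(path).stem, tables, replicate_labels)


def write_profiles(
    exp: FractionationExperiment,
    path: str | Path,
    schema: ProfileSchema = DEFAULT_SCHEMA,
) -> None:
    """Write an experiment in wide form (inverse of :func:`read_profiles`)."""
    rows = []
    for label, table in zip(exp.replicate_labels, exp.replicates):
        block = table.copy()
        block.insert(0, schema.replicate_col, label)
        block = block.reset_index().rename(columns={block.index.name or "index": schema.protein_col})
        rows.append(block)
    _write_table(pd.concat(rows, ignore_index=True), path)


def sum_normalize(raw: Sequence[float] | np.ndarray) -> np.ndarray:
    """Scale a non-negative abundance vector to sum to one."""
    vec = np.asarray(raw, dtype=float)
    if (vec < 0).any():
        raise IntegrityError("negative abundance in profile")
    total = vec.sum()
    if total <= 0:
        raise DegenerateProfileError("all-zero profile cannot be normalized")
    return vec / total


def normalize_experiment(exp: FractionationExperiment) -> FractionationExperiment:
    """Sum-normalize every protein/replicate profile, dropping all-zero rows.

    All-zero profiles are treated as missing values for that replicate and
    removed with a logged count, so they fall out of the replicate
    intersection downstream.
    """
    tables = []
    for label, table in zip(exp.replicate_labels, exp.replicates):
        values = table.to_numpy(dtype=float)
        totals = values.sum(axis=1)
        dead = totals <= 0
        if dead.any():
            logger.warning(
                "condition %s replicate %s: dropping %d all-zero profile(s)",
                exp.condition_label, label, int(dead.sum()),
            )
        kept = values[~dead] / totals[~dead, None]
        tables.append(pd.DataFrame(kept, index=table.index[~dead], columns=table.columns))
    return FractionationExperiment(exp.condition_label, tables, list(exp.replicate_labels))


def concatenate_replicates(exp: FractionationExperiment) -> SpatialProfileMatrix:
    """Join replicates column-wise over the proteins observed in all of them.

    Every replicate must already be sum-normalized (see
    :func:`normalize_experiment`).  Row order is sorted protein id for
    determinism.
    """
    common: set[str] | None = None
    for table in exp.replicates:
        ids = set(table.index)
        common = ids if common is None else common & ids
    assert common is not None
    if not common:
        raise EmptyResultError("no protein observed in every replicate")
    order = sorted(common)

    blocks = []
    for label, table in zip(exp.replicate_labels, exp.replicates):
        block = table.loc[order].to_numpy(dtype=float)
        if not np.allclose(block.sum(axis=1), 1.0, atol=1e-6):
            raise IntegrityError(
                f"replicate {label!r} is not sum-normalized; call normalize_experiment first"
            )
        # renormalize exactly so concatenation satisfies the 1e-9 contract
        blocks.append(block / block.sum(axis=1, keepdims=True))

    F = exp.n_fractions
    boundaries = [(r * F, (r + 1) * F) for r in range(exp.n_replicates)]
    return SpatialProfileMatrix(
        protein_ids=order,
        matrix=np.hstack(blocks),
        replicate_boundaries=boundaries,
        n_fractions=F,
        condition_label=exp.condition_label,
        replicate_labels=list(exp.replicate_labels),
    )


def intersect_conditions(a: SpatialProfileMatrix, b: SpatialProfileMatrix) -> list[str]:
    """Sorted protein ids present in both conditions' matrices."""
    if a.n_fractions != b.n_fractions:
        raise IntegrityError("matrices were built with different fraction counts")
    common = sorted(set(a.protein_ids) & set(b.protein_ids))
    if not common:
        logger.warning(
            "conditions %r and %r share no proteins", a.condition_label, b.condition_label
        )
    return common


def read_markers(path: str | Path, proteins: Iterable[str] | None = None) -> MarkerMap:
    """Load a two-column ``protein_id, compartment`` marker table.

    Markers absent from ``proteins`` (when given) are dropped with a logged
    count.  A marker listed under two different compartments is an integrity
    error.
    """
    table = _read_table(path)
    for required in ("protein_id", "compartment"):
        if required not in table.columns:
            raise SchemaError(f"{path}: missing required column {required!r}")
    if table.empty:
        raise EmptyResultError(f"{path}: marker file has no entries")

    table = table.drop_duplicates()
    conflicted = table["protein_id"][table["protein_id"].duplicated()]
    if not conflicted.empty:
        raise IntegrityError(
            f"{path}: marker {conflicted.iloc[0]!r} listed under more than one compartment"
        )

    entries = dict(zip(table["protein_id"].astype(str), table["compartment"].astype(str)))
    if proteins is not None:
        universe = set(proteins)
        dropped = [p for p in entries if p not in universe]
        if dropped:
            logger.info("dropping %d marker(s) absent from the profile matrix", len(dropped))
        entries = {p: c for p, c in entries.items() if p in universe}
        if not entries:
            raise EmptyResultError(f"{path}: no marker overlaps the profile matrix")
    markers = MarkerMap(entries)
    logger.info("marker classes: %s", markers.class_counts)
    return markers


def write_markers(markers: MarkerMap, path: str | Path) -> None:
    frame = pd.DataFrame(
        sorted(markers.entries.items()), columns=["protein_id", "compartment"]
    )
    _write_table(frame, path)
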