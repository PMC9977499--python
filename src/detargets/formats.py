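"""Readers, writers and validated in-memory containers for every on-disk
format the pipeline touches.

Conventions
-----------
* Genomic coordinates are 0-based, half-open ``[start, end)`` everywhere
  (the BED convention); no 1-based dialects are accepted.
* Floats in result tables are written in scientific notation with six
  significant digits, so identical inputs always produce byte-identical
  output files.
* Duplicate feature or sample identifiers are hard errors: silent
  aggregation of duplicated rows hides upstream data bugs.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("detargets")

#: float format for all TSV outputs — scientific, 6 significant digits
FLOAT_FORMAT = "%.5e"

VALID_STRANDS = ("+", "-", ".")

INTERVAL_COLUMNS = ("chrom", "start", "end", "name", "strand")


class ValidationError(ValueError):
    """An input file or in-memory table violates its contract."""


class PipelineError(RuntimeError):
    """A pipeline stage failed for a non-validation reason."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTable:
    """A feature x sample intensity matrix plus sample group labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature ID with one column per sample ID.
    groups
        Series mapping sample ID -> group label, in sample (column) order.
    scale
        ``"log2"`` or ``"linear"``.  Linear values must be strictly
        positive; both scales must be finite.
    """

    values: pd.DataFrame
    groups: pd.Series
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValidationError(f"unknown scale marker {self.scale!r}")
        idx = self.values.index.astype(str)
        cols = self.values.columns.astype(str)
        self.values.index = idx
        self.values.columns = cols
        for kind, labels in (("feature", idx), ("sample", cols)):
            dup = labels[labels.duplicated()]
            if len(dup):
                raise ValidationError(
                    f"duplicate {kind} ID {dup[0]!r} in expression matrix"
                )
        try:
            mat = self.values.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric expression value: {exc}") from exc
        bad = ~np.isfinite(mat)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite value at feature {idx[i]!r}, sample {cols[j]!r}"
            )
        if self.scale == "linear" and (mat <= 0).any():
            i, j = np.argwhere(mat <= 0)[0]
            raise ValidationError(
                f"non-positive linear intensity at feature {idx[i]!r}, "
                f"sample {cols[j]!r}"
            )
        groups = self.groups.astype(str)
        groups.index = groups.index.astype(str)
        missing = [s for s in cols if s not in groups.index]
        if missing:
            raise ValidationError(f"sample {missing[0]!r} has no group label")
        extra = [s for s in groups.index if s not in set(cols)]
        if extra:
            raise ValidationError(
                f"group file lists sample {extra[0]!r} absent from the matrix"
            )
        # keep groups in column order
        self.groups = groups.reindex(cols)

    # -- convenience accessors ------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_labels(self) -> list[str]:
        """Group labels in first-seen (sample column) order."""
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionTable":
        """Return a new table with the same samples/groups and new values."""
        return ExpressionTable(values, self.groups.copy(), scale or self.scale)


def read_expression(path: str | Path, groups_path: str | Path,
                    scale: str = "log2") -> ExpressionTable:
    """Read a TSV expression matrix (header = sample IDs, first column =
    feature IDs) and a two-column sample-to-group TSV."""
    path = Path(path)
    groups_path = Path(groups_path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header:
        raise ValidationError(f"{path}: empty expression file")
    samples = header.split("\t")[1:]
    if not samples:
        raise ValidationError(f"{path}: header row lists no samples")
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise ValidationError(f"{path}: duplicate sample ID {s!r}")
        seen.add(s)
    raw = pd.read_csv(
        path, sep="\t", skiprows=1, header=None,
        names=["__feature__", *samples], dtype=str,
    )
    features = raw["__feature__"]
    dup = features[features.duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate feature ID {dup.iloc[0]!r}")
    body = raw[samples]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: non-numeric value {body.iat[i, j]!r} at feature "
            f"{features.iloc[i]!r}, sample {samples[j]!r}"
        )
    values = numeric.set_axis(features.astype(str), axis=0)
    values.index.name = "feature_id"
    groups = read_groups(groups_path)
    return ExpressionTable(values, groups, scale=scale)


def read_groups(path: str | Path) -> pd.Series:
    """Read a two-column TSV of (sample_id, group).  A header line whose
    first field is ``sample_id`` is tolerated and skipped."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().lower() == "sample_id":
                continue
            if len(fields) != 2:
                raise ValidationError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            pairs.append((fields[0], fields[1]))
    if not pairs:
        raise ValidationError(f"{path}: no sample-to-group assignments")
    ids = [p[0] for p in pairs]
    dup = {s for s in ids if ids.count(s) > 1}
    if dup:
        raise ValidationError(f"{path}: duplicate sample ID {sorted(dup)[0]!r}")
    return pd.Series(dict(pairs), name="group")


def write_expression(table: ExpressionTable, path: str | Path,
                     groups_path: str | Path) -> None:
    """Write an expression matrix and its group table (inverse of
    :func:`read_expression` up to the declared float format)."""
    table.values.to_csv(Path(path), sep="\t", float_format=FLOAT_FORMAT,
                        index_label="feature_id", lineterminator="\n")
    with open(groups_path, "w") as fh:
        for sample, group in table.groups.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# Genomic intervals (gene models and ChIP-Seq peak calls)
# ---------------------------------------------------------------------------

@dataclass
class IntervalTable:
    """BED-style intervals: 0-based half-open, unique names per table."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in INTERVAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"interval table missing column {missing[0]!r}")
        df = self.df.loc[:, list(INTERVAL_COLUMNS)].reset_index(drop=True)
        df["chrom"] = df["chrom"].astype(str)
        df["name"] = df["name"].astype(str)
        df["strand"] = df["strand"].astype(str)
        try:
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-integer interval coordinate: {exc}") from exc
        if len(df):
            if (df["start"] < 0).any():
                bad = df.loc[df["start"] < 0].iloc[0]
                raise ValidationError(f"negative start for interval {bad['name']!r}")
            nonpos = df["start"] >= df["end"]
            if nonpos.any():
                bad = df.loc[nonpos].iloc[0]
                raise ValidationError(
                    f"empty interval (start >= end) for {bad['name']!r}"
                )
            if not df["strand"].isin(VALID_STRANDS).all():
                bad = df.loc[~df["strand"].isin(VALID_STRANDS)].iloc[0]
                raise ValidationError(
                    f"invalid strand {bad['strand']!r} for {bad['name']!r}"
                )
            dup = df["name"][df["name"].duplicated()]
            if len(dup):
                raise ValidationError(
                    f"duplicate interval name {dup.iloc[0]!r} within one table"
                )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def names(self) -> list[str]:
        return list(self.df["name"])

    def sorted_by_position(self) -> "IntervalTable":
        df = self.df.sort_values(["chrom", "start", "end", "name"],
                                 kind="mergesort").reset_index(drop=True)
        return IntervalTable(df)


def read_bed(path: str | Path) -> IntervalTable:
    """Parse BED3+ (columns beyond the sixth are ignored).

    Missing names are synthesised as ``rec<n>``; missing strand becomes
    ``"."``.  Malformed lines raise :class:`ValidationError` naming the
    line number.
    """
    path = Path(path)
    records: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: BED needs >= 3 fields"
                )
            chrom = fields[0]
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError:
                raise ValidationError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from None
            if start < 0:
                raise ValidationError(f"{path}: line {lineno}: negative start")
            if start >= end:
                raise ValidationError(
                    f"{path}: line {lineno}: start >= end ({start} >= {end})"
                )
            name = fields[3] if len(fields) >= 4 and fields[3] else f"rec{len(records) + 1}"
            strand = fields[5] if len(fields) >= 6 else "."
            if strand not in VALID_STRANDS:
                raise ValidationError(
                    f"{path}: line {lineno}: invalid strand {strand!r}"
                )
            records.append((chrom, start, end, name, strand))
    df = pd.DataFrame(records, columns=list(INTERVAL_COLUMNS))
    if not len(df):
        df = df.astype({"start": np.int64, "end": np.int64})
    try:
        return IntervalTable(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_bed(table: IntervalTable, path: str | Path) -> None:
    """Write BED6 (score column fixed to 0); coordinates round-trip
    unchanged through :func:`read_bed`."""
    with open(path, "w") as fh:
        for row in table.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t0\t{row.strand}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions.

    Member lists are deduplicated preserving first-seen order; set names
    are unique.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            seen: dict[str, None] = {}
            for g in members:
                seen.setdefault(g, None)
            self.sets[name] = list(seen)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse GMT: one set per line, ``name<TAB>description<TAB>member...``."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: GMT needs >= 3 tab-separated fields"
                )
            name, desc, *members = fields
            if name in sets:
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate gene-set name {name!r}"
                )
            sets[name] = [m for m in members if m]
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene ID per line; blank lines skipped; duplicates collapsed
    preserving first-seen order."""
    seen: dict[str, None] = {}
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g:
                seen.setdefault(g, None)
    return list(seen)


def read_probe_map(path: str | Path) -> pd.DataFrame:
    """Two-column TSV of (probe_id, gene_id); many-to-one and one-to-many
    allowed, exact duplicate pairs are errors."""
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().lower() == "probe_id":
                continue
            if len(fields) != 2:
                raise ValidationError(
                    f"{path}: line {lineno}: expected 2 fields, got {len(fields)}"
                )
            rows.append((fields[0], fields[1]))
    df = pd.DataFrame(rows, columns=["probe_id", "gene_id"])
    if df.duplicated().any():
        bad = df[df.duplicated()].iloc[0]
        raise ValidationError(
            f"{path}: duplicate probe-gene pair ({bad.probe_id!r}, {bad.gene_id!r})"
        )
    return df


# ---------------------------------------------------------------------------
# Result writing
# ---------------------------------------------------------------------------

def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.ndarray, tuple)):
        return list(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(obj: Mapping, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed indentation, trailing newline."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  summary: Mapping | None = None) -> dict[str, Path]:
    """Write each result table as ``<name>.tsv`` with the frozen float
    format, plus an optional ``run_summary.json``.

    Identical inputs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        frame = df.reset_index() if df.index.name is not None else df
        path = out_dir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT,
                     lineterminator="\n")
        paths[name] = path
    if summary is not None:
        path = out_dir / "run_summary.json"
        write_json(summary, path)
        paths["run_summary"] = path
    return paths
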