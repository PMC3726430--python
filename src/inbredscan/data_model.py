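"""Validated containers and TSV/JSON plumbing for the expression pipeline.

The canonical interchange formats are plain tab-separated text, in the style of
a GEO series-matrix layout: expression matrices carry probes in rows and
samples in columns, sample sheets carry one labelled row per array, and
productivity tables carry one row per replicate vial.  Lines starting with
``#`` are treated as comments so that result tables can carry provenance
headers.  Missing values are rejected rather than imputed — the normalised
matrices this pipeline consumes are complete by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ROLES = ("inbred", "control")
LEVELS = ("most_depressed", "least_depressed")
SHEET_COLUMNS = ("sample_id", "role", "line", "level", "subline_index")
PRODUCTIVITY_COLUMNS = ("line", "subline_id", "replicate_id", "pupae_per_female")

_NONE_TOKENS = {"", "none", "na", "nan", "-"}


class FormatError(ValueError):
    """An input table violates the interchange format or a type invariant."""


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A log2-scale probe-by-sample expression matrix.

    Invariants (enforced at construction): probe and sample identifiers are
    unique, every value is finite, and there are at least 3 samples — the
    minimum at which a Grubbs test is defined.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicated probe id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise FormatError(f"duplicated sample id {dup!r}")
        if df.shape[1] < 3:
            raise FormatError(
                f"expression matrix needs >= 3 samples, got {df.shape[1]}"
            )
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric values")
        bad = ~np.isfinite(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"non-finite value at probe {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        df = df.astype(float)
        df.index.name = None
        df.columns.name = None
        self.values = df

    # -- accessors ----------------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, probes: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "ExpressionMatrix":
        df = self.values
        if probes is not None:
            missing = [p for p in probes if p not in df.index]
            if missing:
                raise KeyError(f"unknown probe ids: {missing[:5]}")
            df = df.loc[list(probes)]
        if samples is not None:
            missing = [s for s in samples if s not in df.columns]
            if missing:
                raise KeyError(f"unknown sample ids: {missing[:5]}")
            df = df[list(samples)]
        return ExpressionMatrix(df)

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        try:
            raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                              keep_default_na=False, comment="#")
        except pd.errors.ParserError as exc:  # ragged rows etc.
            raise FormatError(f"malformed expression TSV {path}: {exc}") from exc
        if raw.index.has_duplicates:
            dup = raw.index[raw.index.duplicated()][0]
            raise FormatError(f"duplicated probe id {dup!r} in {path}")
        numeric = raw.apply(lambda c: pd.to_numeric(c, errors="coerce"))
        bad = numeric.isna().to_numpy()
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"non-numeric cell {raw.iat[i, j]!r} at probe {raw.index[i]!r}, "
                f"sample {raw.columns[j]!r} in {path}"
            )
        return cls(numeric)

    def to_tsv(self, path: str | Path,
               header_lines: Sequence[str] = ()) -> None:
        write_table(self.values.reset_index(names="probe_id"), path,
                    header_lines=header_lines)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a probe-by-sample TSV (first column probe id, header sample ids)."""
    return ExpressionMatrix.from_tsv(path)


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------


def _norm_token(x) -> str | None:
    s = str(x).strip().lower()
    return None if s in _NONE_TOKENS else s


@dataclass
class SampleSheet:
    """Design labels for each array: role, inbred line, depression level.

    Controls carry no line/level; every inbred sample carries both.  The
    canonical study design is 4 lines x 2 levels x 3 sublines + 3 controls.
    """

    table: pd.DataFrame
    _cells: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns {missing}")
        df = df.loc[:, list(SHEET_COLUMNS)]
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicated sample id {dup!r}")
        df["role"] = df["role"].map(lambda x: str(x).strip().lower())
        bad_role = ~df["role"].isin(ROLES)
        if bad_role.any():
            tok = df.loc[bad_role, "role"].iloc[0]
            raise FormatError(f"unknown role token {tok!r}")
        df["line"] = df["line"].map(_norm_token)
        df["level"] = df["level"].map(_norm_token)
        for _, row in df.iterrows():
            if row["role"] == "control":
                if row["line"] is not None or row["level"] is not None:
                    raise FormatError(
                        f"control sample {row['sample_id']!r} must not carry "
                        f"line/level labels"
                    )
            else:
                if row["line"] is None or row["level"] is None:
                    raise FormatError(
                        f"inbred sample {row['sample_id']!r} lacks line or level"
                    )
                if row["level"] not in LEVELS:
                    raise FormatError(
                        f"unknown level token {row['level']!r} for sample "
                        f"{row['sample_id']!r}"
                    )
        df["subline_index"] = pd.to_numeric(df["subline_index"],
                                            errors="coerce").astype("Int64")
        self.table = df.reset_index(drop=True)
        self._cells = None

    # -- accessors ----------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def inbred_ids(self) -> list[str]:
        t = self.table
        return list(t.loc[t["role"] == "inbred", "sample_id"])

    @property
    def control_ids(self) -> list[str]:
        t = self.table
        return list(t.loc[t["role"] == "control", "sample_id"])

    def cell_of(self, sample_id: str):
        """Return the (line, level) cell of an inbred sample, None for controls."""
        if self._cells is None:
            cells = {}
            for _, row in self.table.iterrows():
                cells[row["sample_id"]] = (
                    None if row["role"] == "control"
                    else (row["line"], row["level"])
                )
            self._cells = cells
        try:
            return self._cells[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in sample sheet") from None

    def is_canonical_design(self) -> bool:
        """True for the study layout: 4 lines x 2 levels x 3 sublines + 3 controls."""
        t = self.table
        inbred = t[t["role"] == "inbred"]
        if len(self.control_ids) != 3 or inbred["line"].nunique() != 4:
            return False
        counts = inbred.groupby(["line", "level"], sort=False).size()
        return len(counts) == 8 and (counts == 3).all()

    def cross_check(self, matrix: ExpressionMatrix) -> None:
        """Reject any sample present in exactly one of sheet and matrix."""
        sheet_ids = set(self.sample_ids)
        mat_ids = set(matrix.sample_ids)
        only_sheet = sorted(sheet_ids - mat_ids)
        only_mat = sorted(mat_ids - sheet_ids)
        if only_sheet or only_mat:
            raise FormatError(
                f"sample sheet / matrix mismatch: only in sheet {only_sheet}, "
                f"only in matrix {only_mat}"
            )

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        out = self.table.copy()
        out["line"] = out["line"].map(lambda v: "none" if v is None else v)
        out["level"] = out["level"].map(lambda v: "none" if v is None else v)
        write_table(out, path, header_lines=header_lines)


def read_sample_sheet(path: str | Path,
                      matrix: ExpressionMatrix | None = None,
                      cross_check: bool = False) -> SampleSheet:
    """Read and validate a sample sheet; optionally cross-check against a matrix."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     comment="#")
    sheet = SampleSheet(df)
    if cross_check:
        if matrix is None:
            raise ValueError("cross_check=True requires a matrix")
        sheet.cross_check(matrix)
    return sheet


# ---------------------------------------------------------------------------
# ProductivityTable
# ---------------------------------------------------------------------------


@dataclass
class ProductivityTable:
    """Replicate-level pupa productivity: one row per (line, subline, vial).

    Control vials use ``line == "control"``.  Counts are non-negative reals
    (pupae per female); each subline needs at least one replicate.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in PRODUCTIVITY_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"productivity table missing columns {missing}")
        df = df.loc[:, list(PRODUCTIVITY_COLUMNS)]
        df["pupae_per_female"] = pd.to_numeric(df["pupae_per_female"],
                                               errors="raise")
        if (df["pupae_per_female"] < 0).any():
            raise FormatError("negative productivity value")
        if df.empty:
            raise FormatError("empty productivity table")
        self.table = df.reset_index(drop=True)

    def subline_means(self, include_controls: bool = False) -> pd.DataFrame:
        """Mean productivity per (line, subline) across replicate vials."""
        t = self.table
        if not include_controls:
            t = t[t["line"] != "control"]
        out = (t.groupby(["line", "subline_id"], sort=True)["pupae_per_female"]
               .mean().rename("mean_productivity").reset_index())
        return out

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        write_table(self.table, path, header_lines=header_lines)


def read_productivity_table(path: str | Path) -> ProductivityTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return ProductivityTable(df)


# ---------------------------------------------------------------------------
# Generic result-table plumbing
# ---------------------------------------------------------------------------


def write_table(rows, path: str | Path, format: str = "tsv",
                header_lines: Sequence[str] = ()) -> None:
    """Write rows (DataFrame or list of dicts) as TSV or JSON records.

    TSV numeric fields use repr-round-trippable formatting so that
    ``read_table(write_table(x)) == x``.  An empty frame yields a header-only
    file.  ``header_lines`` are emitted as ``#``-prefixed comments.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.12g")
    elif format == "json":
        payload = {
            "header": list(header_lines),
            "rows": json.loads(df.to_json(orient="records")),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_table(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    if format == "tsv":
        return pd.read_csv(path, sep="\t", comment="#")
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        return pd.DataFrame(payload["rows"])
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Optional GEO series-matrix convenience loader
# ---------------------------------------------------------------------------


def read_geo_series_matrix(path: str | Path):
    """Extract an expression matrix and sample metadata from a GEO series-matrix file.

    Convenience for users holding the deposited study series (accession
    GSE47176); sample role/line/level labels must still be assigned by hand
    from the series' sample titles.  Returns ``(ExpressionMatrix, metadata)``
    where metadata is a DataFrame of the ``!Sample_*`` annotation lines.
    """
    meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line.replace('"', ""))
            elif line.startswith("!Sample_"):
                key, *vals = line.split("\t")
                meta.setdefault(key.lstrip("!"), []).extend(
                    v.strip('"') for v in vals
                )
    if not table_lines:
        raise FormatError(f"no series_matrix_table block in {path}")
    from io import StringIO

    raw = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    metadata = pd.DataFrame({k: pd.Series(v) for k, v in meta.items()})
    return ExpressionMatrix(raw), metadata
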