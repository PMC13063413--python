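"""Data model and delimited-text I/O for biodegradation rate-constant tables.

The analysis operates on three kinds of tables, all plain delimited text
(comma- or tab-separated, chosen by file extension):

* a long-format *rate table* with one row per chemical x site-experiment,
  holding the first-order rate constant ``k`` (d^-1) and optional experiment
  metadata (pH, freely dissolved fraction, TOC, replicate stddev of log10 k);
* a companion *chemicals* table with per-chemical metadata, notably the pKa
  values and acid/base site types needed for the pH-7 speciation correction;
* wide *descriptor matrices* (chemicals x MACCS bits, biotransformation-rule
  triggers, or rule probabilities) used for data-independent grouping.

The central in-memory container is :class:`RateMatrix`, a chemicals x
site-experiments grid of log10 k with NaN as the explicit missing marker.
Missing cells are written as empty fields, never as sentinel numbers, so the
missingness pattern round-trips through write/read unchanged.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AmbiguityError, DomainError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: canonical -> default file column names for the long rate table
DEFAULT_DIALECT = {
    "chemical_id": "chemical_id",
    "site_id": "site_id",
    "k": "k",
    "valid": "valid",
    "pH": "pH",
    "f_dissolved": "f_dissolved",
    "toc": "toc",
    "replicate_stddev": "replicate_stddev",
}

REQUIRED_COLUMNS = ("chemical_id", "site_id", "k")

#: expected descriptor counts for the canonical descriptor sets
EXPECTED_DESCRIPTOR_WIDTHS = {"maccs": 166, "btrules": 208, "btrules_prob": 65}

_TRUE_TOKENS = {"true", "t", "1", "yes", "y"}
_FALSE_TOKENS = {"false", "f", "0", "no", "n"}


def _sep_for(path: str | Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab", ".txt"} else ","


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateRecord:
    """One measured rate constant: a chemical in one site-experiment.

    ``valid`` marks rate constants significantly different from zero; invalid
    records are carried through parsing but excluded from every downstream
    computation. ``replicate_stddev`` is the stddev of log10 k across the
    three test-treatment replicates (measurement uncertainty, log10 units).
    """

    chemical_id: str
    site_id: str
    k_apparent: float
    valid: bool = True
    pH_exp: float | None = None
    f_dissolved: float | None = None
    toc: float | None = None
    replicate_stddev: float | None = None

    def __post_init__(self) -> None:
        if self.valid and not (self.k_apparent > 0):
            raise ValidationError(
                f"valid record ({self.chemical_id}, {self.site_id}) has "
                f"non-positive k={self.k_apparent!r}"
            )
        if self.f_dissolved is not None and not (0 < self.f_dissolved <= 1):
            raise ValidationError(
                f"record ({self.chemical_id}, {self.site_id}): f_dissolved "
                f"{self.f_dissolved!r} outside (0, 1]"
            )
        if self.replicate_stddev is not None and not (self.replicate_stddev >= 0):
            raise ValidationError(
                f"record ({self.chemical_id}, {self.site_id}): negative "
                f"replicate_stddev {self.replicate_stddev!r}"
            )


@dataclass(frozen=True)
class ChemicalMeta:
    """Per-chemical metadata; ``pka_list`` holds (pKa, 'acid'|'base') pairs.

    An empty ``pka_list`` denotes a permanently neutral chemical.
    """

    chemical_id: str
    name: str = ""
    pka_list: tuple[tuple[float, str], ...] = ()
    notes: str = ""

    def __post_init__(self) -> None:
        for pka, site_type in self.pka_list:
            if not math.isfinite(pka):
                raise ValidationError(
                    f"chemical {self.chemical_id}: non-finite pKa {pka!r}"
                )
            if site_type not in ("acid", "base"):
                raise DomainError(
                    f"chemical {self.chemical_id}: unknown speciation site type "
                    f"{site_type!r} (expected 'acid' or 'base')"
                )


@dataclass
class RateTable:
    """A parsed rate table: records plus chemical metadata."""

    records: list[RateRecord]
    meta: dict[str, ChemicalMeta] = field(default_factory=dict)

    def valid_records(self) -> list[RateRecord]:
        return [r for r in self.records if r.valid]

    def pka_for(self, chemical_id: str) -> tuple[tuple[float, str], ...]:
        m = self.meta.get(chemical_id)
        return m.pka_list if m is not None else ()

    def __len__(self) -> int:
        return len(self.records)


class RateMatrix:
    """Chemicals x site-experiments grid of log10 rate constants.

    Backed by a float DataFrame (index = chemical ids, columns = site ids)
    with NaN as the explicit missing marker. Every non-missing cell is finite.
    """

    def __init__(self, logk: pd.DataFrame):
        if logk.index.has_duplicates:
            raise ValidationError("duplicated chemical_id in rate matrix")
        if logk.columns.has_duplicates:
            raise ValidationError("duplicated site_id in rate matrix")
        values = logk.to_numpy(dtype=float)
        if np.isinf(values).any():
            raise ValidationError("rate matrix contains non-finite log10 k")
        self.logk = logk.astype(float)
        self.logk.index = self.logk.index.astype(str)
        self.logk.columns = self.logk.columns.astype(str)

    @property
    def chemicals(self) -> list[str]:
        return list(self.logk.index)

    @property
    def sites(self) -> list[str]:
        return list(self.logk.columns)

    @property
    def values(self) -> np.ndarray:
        return self.logk.to_numpy(dtype=float)

    def row(self, chemical_id: str) -> np.ndarray:
        return self.logk.loc[chemical_id].to_numpy(dtype=float)

    def n_valid(self) -> pd.Series:
        """Number of non-missing sites per chemical."""
        return self.logk.notna().sum(axis=1)

    def n_values(self) -> int:
        """Total number of non-missing cells."""
        return int(self.logk.notna().to_numpy().sum())

    def subset(self, chemicals: Sequence[str]) -> "RateMatrix":
        return RateMatrix(self.logk.loc[list(chemicals)].copy())

    def copy(self) -> "RateMatrix":
        return RateMatrix(self.logk.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"RateMatrix({len(self.chemicals)} chemicals x {len(self.sites)} "
            f"sites, {self.n_values()} values)"
        )


class DescriptorMatrix:
    """Chemicals x descriptor-features grid for data-independent grouping.

    ``kind`` is one of ``maccs``/``btrules`` (binary 0/1), ``btrules_prob``
    (probabilities in [0, 1]) or ``custom`` (unvalidated reals).
    """

    KINDS = ("maccs", "btrules", "btrules_prob", "custom")

    def __init__(self, values: pd.DataFrame, kind: str):
        if kind not in self.KINDS:
            raise DomainError(f"unknown descriptor kind {kind!r}")
        if values.index.has_duplicates:
            raise ValidationError("duplicated chemical_id in descriptor matrix")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite descriptor value at ({values.index[bad[0]]}, "
                f"{values.columns[bad[1]]})"
            )
        if kind in ("maccs", "btrules"):
            bad = np.argwhere(~np.isin(arr, (0.0, 1.0)))
            if bad.size:
                i, j = bad[0]
                raise ValidationError(
                    f"descriptor kind {kind!r} requires binary values; got "
                    f"{arr[i, j]!r} at ({values.index[i]}, {values.columns[j]})"
                )
        elif kind == "btrules_prob":
            bad = np.argwhere((arr < 0) | (arr > 1))
            if bad.size:
                i, j = bad[0]
                raise ValidationError(
                    f"descriptor kind 'btrules_prob' requires values in [0, 1]; "
                    f"got {arr[i, j]!r} at ({values.index[i]}, {values.columns[j]})"
                )
        expected = EXPECTED_DESCRIPTOR_WIDTHS.get(kind)
        if expected is not None and values.shape[1] != expected:
            logger.warning(
                "descriptor matrix of kind %r has %d columns (expected %d)",
                kind,
                values.shape[1],
                expected,
            )
        self.values = values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.kind = kind

    @property
    def chemicals(self) -> list[str]:
        return list(self.values.index)

    @property
    def descriptor_names(self) -> list[str]:
        return [str(c) for c in self.values.columns]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _parse_valid(token: object) -> bool:
    if isinstance(token, (bool, np.bool_)):
        return bool(token)
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return True  # absent validity defaults to valid
    s = str(token).strip().lower()
    if s in _TRUE_TOKENS:
        return True
    if s in _FALSE_TOKENS:
        return False
    raise ValidationError(f"unrecognized validity token {token!r}")


def _opt_float(value: object) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return float(value)


def parse_pka_list(text: object) -> tuple[tuple[float, str], ...]:
    """Parse a ``"4.5:acid;9.2:base"``-style speciation specification."""
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return ()
    s = str(text).strip()
    if not s:
        return ()
    out = []
    for part in s.split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            pka_s, site_type = part.split(":")
        except ValueError as exc:
            raise FormatError(f"malformed pKa entry {part!r}") from exc
        out.append((float(pka_s), site_type.strip().lower()))
    return tuple(out)


def read_chemical_meta(path: str | Path) -> dict[str, ChemicalMeta]:
    """Read the chemicals metadata table (chemical_id, name, pka_list, notes)."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if "chemical_id" not in df.columns:
        raise FormatError(f"chemicals file {path}: missing column 'chemical_id'")
    meta = {}
    for _, row in df.iterrows():
        cid = str(row["chemical_id"]).strip()
        meta[cid] = ChemicalMeta(
            chemical_id=cid,
            name=str(row.get("name", "") or ""),
            pka_list=parse_pka_list(row.get("pka_list")),
            notes=str(row.get("notes", "") or ""),
        )
    return meta


def read_rate_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    chemicals_path: str | Path | None = None,
) -> RateTable:
    """Read a long-format rate table.

    ``dialect`` maps canonical column names (``chemical_id``, ``site_id``,
    ``k``, ``valid``, ``pH``, ``f_dissolved``, ``toc``, ``replicate_stddev``)
    to the actual column names in the file, so external tables can be adapted
    without editing them. Rows lacking a validity column default to valid.
    Numeric parsing is locale-independent (dot decimal separator).
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, sep=_sep_for(path))
    for canon in REQUIRED_COLUMNS:
        if cols[canon] not in df.columns:
            raise FormatError(
                f"rate table {path}: missing required column {cols[canon]!r} "
                f"(canonical {canon!r})"
            )

    records = []
    errors = []
    has = {c: cols[c] in df.columns for c in cols}
    for idx, row in df.iterrows():
        try:
            valid = _parse_valid(row[cols["valid"]]) if has["valid"] else True
            records.append(
                RateRecord(
                    chemical_id=str(row[cols["chemical_id"]]).strip(),
                    site_id=str(row[cols["site_id"]]).strip(),
                    k_apparent=float(row[cols["k"]]),
                    valid=valid,
                    pH_exp=_opt_float(row[cols["pH"]]) if has["pH"] else None,
                    f_dissolved=_opt_float(row[cols["f_dissolved"]])
                    if has["f_dissolved"]
                    else None,
                    toc=_opt_float(row[cols["toc"]]) if has["toc"] else None,
                    replicate_stddev=_opt_float(row[cols["replicate_stddev"]])
                    if has["replicate_stddev"]
                    else None,
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {idx + 2}: {exc}")  # +2: header + 1-based
    if errors:
        raise ValidationError(
            f"rate table {path}: {len(errors)} invalid row(s):\n  "
            + "\n  ".join(errors)
        )
    meta = read_chemical_meta(chemicals_path) if chemicals_path else {}
    return RateTable(records=records, meta=meta)


def pivot_log_matrix(table: RateTable) -> RateMatrix:
    """Pivot valid records into the chemicals x sites grid of log10 k.

    Chemical and site orders are sorted lexicographically for determinism;
    cells with no valid record are missing. Duplicate valid records for one
    (chemical, site) pair raise :class:`AmbiguityError`.
    """
    valid = table.valid_records()
    if not valid:
        raise ValidationError("rate table contains no valid records")
    seen: dict[tuple[str, str], float] = {}
    dups = []
    for r in valid:
        key = (r.chemical_id, r.site_id)
        if key in seen:
            dups.append(key)
        seen[key] = math.log10(r.k_apparent)
    if dups:
        raise AmbiguityError(
            "duplicate valid records for (chemical, site) pairs: "
            + ", ".join(map(str, sorted(set(dups))))
        )
    chemicals = sorted({c for c, _ in seen})
    sites = sorted({s for _, s in seen})
    grid = pd.DataFrame(np.nan, index=chemicals, columns=sites, dtype=float)
    for (c, s), v in seen.items():
        grid.loc[c, s] = v
    return RateMatrix(grid)


def read_descriptor_matrix(path: str | Path, kind: str) -> DescriptorMatrix:
    """Read a chemicals x descriptors table; first column is chemical_id."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    return DescriptorMatrix(df, kind=kind)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_rate_matrix(matrix: RateMatrix, path: str | Path) -> None:
    """Write a RateMatrix; missing cells become empty fields."""
    df = matrix.logk.copy()
    df.index.name = "chemical_id"
    df.to_csv(path, sep=_sep_for(path))


def read_rate_matrix(path: str | Path) -> RateMatrix:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return RateMatrix(df)


def write_benchmark_report(
    result,
    table_path: str | Path,
    summary_path: str | Path | None = None,
) -> None:
    """Write a benchmark result as a per-chemical table plus a JSON summary.

    The table has one row per benchmarked chemical (chemical_id, group,
    benchmark_id, n_sites, n_gap_filled, stddev_before, stddev_after, rem);
    the summary holds the median REM, the fraction of chemicals with REM > 0
    and the per-group benchmark choices. Output is deterministic (sorted rows,
    fixed key order).
    """
    table_path = Path(table_path)
    if summary_path is None:
        summary_path = table_path.with_suffix(".summary.json")
    rows = []
    groups = getattr(result, "groups", None) or {}
    for cid in sorted(result.per_chemical):
        entry = result.per_chemical[cid]
        rows.append(
            {
                "chemical_id": cid,
                "group": groups.get(cid, ""),
                "benchmark_id": result.assignments.get(cid, ""),
                "n_sites": entry.n_sites,
                "n_gap_filled": entry.n_gap_filled,
                "stddev_before": entry.stddev_before,
                "stddev_after": entry.stddev_after,
                "rem": entry.rem,
            }
        )
    columns = [
        "chemical_id",
        "group",
        "benchmark_id",
        "n_sites",
        "n_gap_filled",
        "stddev_before",
        "stddev_after",
        "rem",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(
        table_path, sep=_sep_for(table_path), index=False
    )
    with open(summary_path, "w") as fh:
        json.dump({"mode": result.mode, **result.summary}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_benchmark_report(table_path: str | Path) -> pd.DataFrame:
    """Read back the per-chemical benchmark table written above."""
    return pd.read_csv(table_path, sep=_sep_for(table_path))
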