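"""Readers and writers for FAERS-style quarterly ASCII tables.

The quarterly dumps are ``$``-delimited text files with a single header row.
Three tables are understood: DEMO (one row per report version), DRUG (one row
per drug mention) and REAC (one row per reported reaction).  Parsing is
header-driven, so column order never matters.  Unparseable field values
degrade to missing and are tallied for logging; they never abort a read.

Two small auxiliary formats share the dialect: a two-column PT -> SOC mapping
table and a two-column synonym dictionary used for drug-name standardization.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DELIMITER = "$"

#: canonical column sets, by schema name
SCHEMAS: dict[str, tuple[str, ...]] = {
    "DEMO": (
        "primaryid",
        "caseid",
        "caseversion",
        "fda_dt",
        "sex",
        "age",
        "age_cod",
        "occp_cod",
        "occr_country",
    ),
    "DRUG": ("primaryid", "drugname", "role_cod"),
    "REAC": ("primaryid", "pt"),
}

#: multiply a value in this unit by the factor to obtain years
AGE_UNIT_TO_YEARS: dict[str, float] = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
}

VALID_SEX = frozenset({"F", "M"})
VALID_REPORTER = frozenset({"CN", "MD", "PH", "OT"})
VALID_ROLE = frozenset({"PS", "SS", "C", "I"})

UNMAPPED_SOC = "UNMAPPED"


class SchemaError(ValueError):
    """Header does not provide a column the schema requires."""


@dataclass(frozen=True)
class RawDemoRow:
    primaryid: str
    caseid: str
    caseversion: object  # int or None
    fda_dt: str
    sex: str
    age: str
    age_cod: str
    occp_cod: str
    occr_country: str


@dataclass(frozen=True)
class RawDrugRow:
    primaryid: str
    drugname: str
    role_cod: str


@dataclass(frozen=True)
class RawReacRow:
    primaryid: str
    pt: str


_ROW_TYPES = {"DEMO": RawDemoRow, "DRUG": RawDrugRow, "REAC": RawReacRow}


@dataclass
class ParsedTable:
    """Result of :func:`read_table`.

    ``frame`` keeps the raw schema columns verbatim (as strings) plus derived,
    analysis-ready columns for DEMO tables: ``age_years`` (float, NaN when
    missing), ``reporter`` (normalized occupation code), ``country`` (blank
    mapped to ``"Unknown"``) and ``fda_dt_valid`` (bool).
    """

    schema: str
    frame: pd.DataFrame
    n_rows: int
    missing: dict[str, int] = field(default_factory=dict)
    path: Path | None = None

    @property
    def rows(self) -> list:
        """Materialize the raw schema fields as typed row objects."""
        cls = _ROW_TYPES[self.schema]
        cols = SCHEMAS[self.schema]
        out = []
        for tup in self.frame[list(cols)].itertuples(index=False):
            kwargs = dict(zip(cols, tup))
            if self.schema == "DEMO":
                try:
                    kwargs["caseversion"] = int(kwargs["caseversion"])
                except (TypeError, ValueError):
                    kwargs["caseversion"] = None
            out.append(cls(**kwargs))
        return out


def _read_text(path: Path) -> str:
    """UTF-8 with a per-file latin-1 fallback (real dumps mix encodings)."""
    data = path.read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        logger.warning("%s: not valid UTF-8, falling back to latin-1", path)
        return data.decode("latin-1")


def _parse_lines(text: str) -> tuple[list[str], list[list[str]]]:
    lines = text.splitlines()
    if not lines:
        raise SchemaError("empty file: no header row")
    header = [h.strip().lower() for h in lines[0].split(DELIMITER)]
    records = [line.split(DELIMITER) for line in lines[1:] if line.strip()]
    return header, records


def _is_valid_fda_dt(value: str) -> bool:
    if not re.fullmatch(r"\d{8}", value or ""):
        return False
    try:
        pd.Timestamp(f"{value[:4]}-{value[4:6]}-{value[6:]}")
    except ValueError:
        return False
    return True


def read_table(path: str | Path, schema: str) -> ParsedTable:
    """Read one quarterly ASCII table.

    Parameters
    ----------
    path
        Path to a ``$``-delimited file whose first line is the header.
    schema
        One of ``"DEMO"``, ``"DRUG"``, ``"REAC"``.

    Returns
    -------
    ParsedTable
        Parsed rows plus a per-field tally of values that could not be
        interpreted (kept as missing, never fatal).

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    SchemaError
        If the header lacks a column the schema requires.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)

    header, records = _parse_lines(_read_text(path))
    required = SCHEMAS[schema]
    for col in required:
        if col not in header:
            raise SchemaError(f"{path}: header is missing required column {col!r}")

    positions = [header.index(c) for c in required]
    ncols = len(header)
    data: dict[str, list[str]] = {c: [] for c in required}
    for rec in records:
        if len(rec) < ncols:  # short row: pad, never abort
            rec = rec + [""] * (ncols - len(rec))
        for col, pos in zip(required, positions):
            data[col].append(rec[pos].strip())

    frame = pd.DataFrame(data, columns=list(required), dtype=str)
    missing: dict[str, int] = {}

    if schema == "DEMO":
        frame, missing = _normalize_demo(frame)
    elif schema == "DRUG":
        frame["drugname"] = frame["drugname"].str.strip()
        role = frame["role_cod"].str.upper()
        bad_role = ~role.isin(VALID_ROLE) & (role != "")
        if bad_role.any():
            missing["role_cod"] = int(bad_role.sum())
        frame["role_cod"] = role
    elif schema == "REAC":
        frame["pt"] = frame["pt"].str.strip()
        empty_pt = frame["pt"] == ""
        if empty_pt.any():
            missing["pt"] = int(empty_pt.sum())

    result = ParsedTable(schema, frame, n_rows=len(frame), missing=missing, path=path)
    logger.info("%s: read %d %s rows, missing tallies %s", path, len(frame), schema, missing)
    return result


def normalize_demo(frame: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Derive the analysis columns for an in-memory raw DEMO frame.

    Equivalent to the normalization applied by :func:`read_table`; useful when
    a generator hands over frames directly instead of going through files.
    """
    return _normalize_demo(frame[list(SCHEMAS["DEMO"])].copy())


def _normalize_demo(frame: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    missing: dict[str, int] = {}

    sex = frame["sex"].str.upper()
    bad_sex = ~sex.isin(VALID_SEX) & (sex != "") & (sex != "UNK")
    if bad_sex.any():
        missing["sex"] = int(bad_sex.sum())
    frame["sex"] = sex.where(sex.isin(VALID_SEX), "UNK")

    dt_ok = frame["fda_dt"].map(_is_valid_fda_dt)
    if (~dt_ok).any():
        missing["fda_dt"] = int((~dt_ok).sum())
    frame["fda_dt_valid"] = dt_ok.to_numpy()

    age_num = pd.to_numeric(frame["age"].where(frame["age"] != ""), errors="coerce")
    bad_age = age_num.isna() & (frame["age"] != "")
    if bad_age.any():
        missing["age"] = int(bad_age.sum())
    code = frame["age_cod"].str.upper()
    factor = code.map(AGE_UNIT_TO_YEARS)
    bad_code = factor.isna() & (code != "") & age_num.notna()
    if bad_code.any():
        missing["age_cod"] = int(bad_code.sum())
    frame["age_years"] = (age_num * factor).astype(float)

    rep = frame["occp_cod"].str.upper()
    frame["reporter"] = np.where(
        rep.isin(VALID_REPORTER), rep, np.where((rep == "") | (rep == "UNK"), "UNK", "OT")
    )

    country = frame["occr_country"].str.strip()
    frame["country"] = country.where(country != "", "Unknown")

    ver = pd.to_numeric(frame["caseversion"].where(frame["caseversion"] != ""), errors="coerce")
    bad_ver = ver.isna() & (frame["caseversion"] != "")
    if bad_ver.any():
        missing["caseversion"] = int(bad_ver.sum())

    return frame, missing


def write_table(frame: pd.DataFrame, path: str | Path, schema: str) -> int:
    """Write rows in the quarterly-dump dialect.

    The dialect has no quoting, so any embedded delimiter inside a value is
    replaced by a space (and counted in the return value).  Only the raw
    schema columns are written; derived columns are ignored.

    Returns the number of sanitized field values.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    cols = SCHEMAS[schema]
    for col in cols:
        if col not in frame.columns:
            raise SchemaError(f"cannot write {schema}: frame lacks column {col!r}")
    path = Path(path)

    out = frame[list(cols)].astype(object).fillna("").astype(str)
    sanitized = 0
    for col in cols:
        has_delim = out[col].str.contains(re.escape(DELIMITER), regex=True)
        n = int(has_delim.sum())
        if n:
            sanitized += n
            out[col] = out[col].str.replace(DELIMITER, " ", regex=False)
    if sanitized:
        logger.warning("%s: sanitized %d embedded delimiter(s)", path, sanitized)

    lines = [DELIMITER.join(cols)]
    for tup in out.itertuples(index=False):
        lines.append(DELIMITER.join(tup))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return sanitized


# ---------------------------------------------------------------------------
# auxiliary mapping tables


class PtSocMap:
    """Case-insensitive PT -> SOC lookup with an ``UNMAPPED`` sentinel."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self._map: dict[str, str] = {}
        self._display: dict[str, str] = {}
        conflicts: list[str] = []
        for pt, soc in pairs:
            key = pt.strip().casefold()
            soc = soc.strip()
            if not key:
                raise ValueError("empty PT in PT->SOC map")
            if key in self._map and self._map[key] != soc:
                conflicts.append(pt.strip())
            self._map[key] = self._map.get(key, soc)
            self._display.setdefault(key, pt.strip())
        if conflicts:
            raise ValueError(
                "conflicting SOC assignments for PT(s): " + ", ".join(sorted(set(conflicts)))
            )

    def soc(self, pt: str) -> str:
        return self._map.get(pt.strip().casefold(), UNMAPPED_SOC)

    def map_series(self, pts: pd.Series) -> pd.Series:
        keys = pts.str.strip().str.casefold()
        return keys.map(self._map).fillna(UNMAPPED_SOC)

    def __contains__(self, pt: str) -> bool:
        return pt.strip().casefold() in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self) -> Iterator[tuple[str, str]]:
        for key, soc in self._map.items():
            yield self._display[key], soc


def load_pt_soc_map(path: str | Path, sep: str = DELIMITER) -> PtSocMap:
    """Load a two-column (PT, SOC) table with a header row."""
    path = Path(path)
    header, records = _parse_header_records(path, sep)
    if len(header) < 2:
        raise SchemaError(f"{path}: PT->SOC map needs two columns, got {len(header)}")
    return PtSocMap((rec[0], rec[1]) for rec in records if len(rec) >= 2)


class SynonymDict:
    """Ordered (pattern, canonical ingredient) rules for drug names.

    Patterns are regular expressions searched case-insensitively, so a plain
    word behaves as a substring match and ``^``/``$`` give anchoring.  Rules
    are tried in declaration order; the first match wins.
    """

    def __init__(self, entries: Sequence[tuple[str, str]]):
        if not entries:
            raise ValueError("synonym dictionary is empty")
        self.entries: list[tuple[str, str]] = []
        self._compiled: list[tuple[re.Pattern, str]] = []
        for pattern, canonical in entries:
            if not pattern or not pattern.strip():
                raise ValueError("empty pattern in synonym dictionary")
            self.entries.append((pattern, canonical))
            self._compiled.append((re.compile(pattern, re.IGNORECASE), canonical))

    def match(self, name: str) -> str | None:
        text = (name or "").strip()
        for rx, canonical in self._compiled:
            if rx.search(text):
                return canonical
        return None

    def match_series(self, names: pd.Series, default: str = "OTHER") -> pd.Series:
        # dictionary passes are per unique name; dumps repeat names heavily
        uniq = pd.Series(names.unique())
        mapped = {n: (self.match(n) or default) for n in uniq}
        return names.map(mapped)

    def __len__(self) -> int:
        return len(self.entries)


def load_synonym_dict(path: str | Path, sep: str = DELIMITER) -> SynonymDict:
    """Load a two-column (pattern, canonical ingredient) dictionary."""
    path = Path(path)
    header, records = _parse_header_records(path, sep)
    if len(header) < 2:
        raise SchemaError(f"{path}: synonym dictionary needs two columns, got {len(header)}")
    return SynonymDict([(rec[0].strip(), rec[1].strip()) for rec in records if len(rec) >= 2])


def _parse_header_records(path: Path, sep: str) -> tuple[list[str], list[list[str]]]:
    if not path.is_file():
        raise FileNotFoundError(path)
    lines = _read_text(path).splitlines()
    if not lines:
        raise SchemaError(f"{path}: empty file")
    header = lines[0].split(sep)
    records = [line.split(sep) for line in lines[1:] if line.strip()]
    return header, records
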