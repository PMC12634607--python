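"""Reading and writing FAERS-style quarterly bundles.

A quarterly extract is a set of dollar-delimited text tables sharing the
PRIMARYID key: DEMO (one row per report version), DRUG (one row per drug
mention), REAC (one row per reported reaction, MedDRA preferred term) and
THER (therapy episodes with start/end dates).  Dates are numeric tokens in
``YYYYMMDD`` form that real-world reporters frequently truncate to
``YYYYMM`` or ``YYYY``; :func:`parse_faers_date` classifies every token by
its resolution rather than coercing it, so downstream completeness filters
can be explicit about what they exclude.

All tables are held as :class:`pandas.DataFrame` with string columns; raw
date tokens are kept verbatim until a stage needs calendar arithmetic.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("pvsignal")

__all__ = [
    "FormatError",
    "FaersDate",
    "QuarterBundle",
    "parse_faers_date",
    "normalize_drug_name",
    "read_quarter",
    "write_quarter",
    "concat_bundles",
    "read_two_column_map",
    "DEMO_COLUMNS",
    "DRUG_COLUMNS",
    "REAC_COLUMNS",
    "THER_COLUMNS",
    "ROLE_CODES",
]

DELIMITER = "$"

DEMO_COLUMNS = [
    "primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
    "sex", "wt", "wt_cod", "occp_cod", "reporter_country",
]
DRUG_COLUMNS = ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "start_dt"]
REAC_COLUMNS = ["primaryid", "caseid", "pt"]
THER_COLUMNS = ["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"]

_TABLE_COLUMNS = {
    "demo": DEMO_COLUMNS,
    "drug": DRUG_COLUMNS,
    "reac": REAC_COLUMNS,
    "ther": THER_COLUMNS,
}

ROLE_CODES = frozenset({"PS", "SS", "I", "C"})


class FormatError(ValueError):
    """A bundle file is missing a mandatory column or table."""


# ---------------------------------------------------------------------------
# Date tokens
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FaersDate:
    """A FAERS date token classified by resolution.

    ``resolution`` is ``"day"`` only when the raw token is 8 digits forming
    a valid calendar date, in which case ``value`` carries it as a
    :class:`datetime.date`.  Month (``YYYYMM``) and year (``YYYY``) tokens
    are recognised but carry no ``value``; everything else — empty strings,
    stray text, impossible dates like 20230230 — is ``"invalid"``.
    """

    raw: str
    resolution: str  # day | month | year | invalid
    value: _dt.date | None = None

    @property
    def is_complete(self) -> bool:
        return self.resolution == "day"


def parse_faers_date(token: object) -> FaersDate:
    """Classify a raw date token. Total: never raises."""
    raw = "" if token is None else str(token).strip()
    if raw.endswith(".0"):  # numeric round-trip artefact from lax readers
        raw = raw[:-2]
    if not raw.isdigit():
        return FaersDate(raw, "invalid")
    if len(raw) == 8:
        y, m, d = int(raw[:4]), int(raw[4:6]), int(raw[6:8])
        if 1 <= m <= 12 and y >= 1 and 1 <= d <= calendar.monthrange(y, m)[1]:
            return FaersDate(raw, "day", _dt.date(y, m, d))
        return FaersDate(raw, "invalid")
    if len(raw) == 6:
        m = int(raw[4:6])
        if 1 <= m <= 12:
            return FaersDate(raw, "month")
        return FaersDate(raw, "invalid")
    if len(raw) == 4:
        return FaersDate(raw, "year")
    return FaersDate(raw, "invalid")


# ---------------------------------------------------------------------------
# Drug-name normalisation
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s+")


def normalize_drug_name(raw: object, synonym_map: Mapping[str, str] | None = None) -> str:
    """Canonicalize a verbatim drug name and resolve brand synonyms.

    Canonical form is uppercase, trimmed, internal whitespace collapsed,
    with combination products joined by a backslash (``A\\B``); the synonym
    map (brand -> generic) is applied after canonicalization, so map keys
    must themselves be canonical.  Idempotent when map values are canonical.
    """
    name = _WS.sub(" ", str(raw).strip()).upper()
    name = name.replace("/", "\\")
    name = "\\".join(part.strip() for part in name.split("\\"))
    if synonym_map:
        name = synonym_map.get(name, name)
    return name


# ---------------------------------------------------------------------------
# Quarter bundles
# ---------------------------------------------------------------------------

@dataclass
class QuarterBundle:
    """Linked DEMO/DRUG/REAC/THER tables for one or more quarters.

    ``dropped`` counts malformed rows removed per table at read time (rows
    with a blank PRIMARYID, or DRUG rows with a role code outside PS/SS/I/C).
    ``truth`` is only populated by the synthetic generator: a per-case
    ground-truth table used by tests, never by the pipeline itself.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    dropped: dict[str, int] = field(default_factory=dict)
    truth: pd.DataFrame | None = None

    def n_rows(self) -> dict[str, int]:
        return {
            "demo": len(self.demo),
            "drug": len(self.drug),
            "reac": len(self.reac),
            "ther": len(self.ther),
        }

    def join_violations(self) -> dict[str, int]:
        """Count DRUG/REAC/THER rows whose PRIMARYID has no DEMO row."""
        known = set(self.demo["primaryid"])
        return {
            name: int((~getattr(self, name)["primaryid"].isin(known)).sum())
            for name in ("drug", "reac", "ther")
        }


def _table_kind(path: Path) -> str | None:
    stem = path.name.lower()
    for kind in _TABLE_COLUMNS:
        if stem.startswith(kind):
            return kind
    return None


def _read_table(path: Path, kind: str) -> tuple[pd.DataFrame, int]:
    df = pd.read_csv(path, sep=DELIMITER, dtype=str, keep_default_na=False,
                     engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = _TABLE_COLUMNS[kind]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing mandatory column '{col}'")
    df = df[required].copy()  # extra columns tolerated and ignored
    for col in required:
        df[col] = df[col].str.strip()

    bad = df["primaryid"] == ""
    if kind == "drug":
        bad |= ~df["role_cod"].isin(ROLE_CODES)
    dropped = int(bad.sum())
    if dropped:
        logger.warning("%s: dropped %d malformed row(s)", path.name, dropped)
    return df.loc[~bad].reset_index(drop=True), dropped


def read_quarter(paths: Sequence[str | Path] | str | Path) -> QuarterBundle:
    """Read one quarterly bundle from explicit file paths or a directory.

    File roles are recognised by name prefix (DEMO*/DRUG*/REAC*/THER*).
    Malformed rows are dropped and counted, never silently coerced.
    """
    if isinstance(paths, (str, Path)):
        p = Path(paths)
        paths = sorted(p.iterdir()) if p.is_dir() else [p]
    tables: dict[str, pd.DataFrame] = {}
    dropped: dict[str, int] = {}
    for path in map(Path, paths):
        kind = _table_kind(path)
        if kind is None:
            continue
        if not path.exists():
            raise FormatError(f"{path}: file not found")
        tables[kind], dropped[kind] = _read_table(path, kind)
    for kind in _TABLE_COLUMNS:
        if kind not in tables:
            raise FormatError(f"no {kind.upper()} table among inputs")
    bundle = QuarterBundle(**tables, dropped=dropped)
    logger.info("read quarter: rows=%s dropped=%s", bundle.n_rows(), dropped)
    return bundle


def write_quarter(bundle: QuarterBundle, outdir: str | Path,
                  quarter: str = "24Q1") -> dict[str, Path]:
    """Write a bundle in the dollar-delimited dialect (DEMOyyQq.txt etc.).

    When the bundle carries a synthetic truth table it is written alongside
    as ``truth.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for kind in _TABLE_COLUMNS:
        path = outdir / f"{kind.upper()}{quarter}.txt"
        getattr(bundle, kind).to_csv(path, sep=DELIMITER, index=False,
                                     lineterminator="\n")
        paths[kind] = path
    if bundle.truth is not None:
        path = outdir / "truth.tsv"
        bundle.truth.to_csv(path, sep="\t", index=False, lineterminator="\n")
        paths["truth"] = path
    return paths


def concat_bundles(bundles: Iterable[QuarterBundle]) -> QuarterBundle:
    """Concatenate several quarterly bundles into one (pre-dedup) bundle."""
    bundles = list(bundles)
    if not bundles:
        raise ValueError("no bundles to concatenate")
    merged_dropped: dict[str, int] = {}
    for b in bundles:
        for k, v in b.dropped.items():
            merged_dropped[k] = merged_dropped.get(k, 0) + v
    truths = [b.truth for b in bundles if b.truth is not None]
    return QuarterBundle(
        demo=pd.concat([b.demo for b in bundles], ignore_index=True),
        drug=pd.concat([b.drug for b in bundles], ignore_index=True),
        reac=pd.concat([b.reac for b in bundles], ignore_index=True),
        ther=pd.concat([b.ther for b in bundles], ignore_index=True),
        dropped=merged_dropped,
        truth=pd.concat(truths, ignore_index=True) if truths else None,
    )


def read_two_column_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (key, value) such as a synonym or ATC map.

    Keys are canonicalized with :func:`normalize_drug_name` so lookups match
    pipeline keys; a header row is detected and skipped if its first field
    is not a data-looking token.
    """
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.rstrip("\r")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{Path(path).name}: line {i + 1} is not two-column TSV")
        key, value = parts[0].strip(), parts[1].strip()
        if i == 0 and key.lower() in {"drug", "drugname", "brand", "name", "key"}:
            continue
        out[normalize_drug_name(key)] = value
    return out
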