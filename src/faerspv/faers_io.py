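"""Reading and writing FAERS-style quarterly ASCII bundles.

The FDA distributes quarterly report bundles as '$'-delimited ASCII
tables with a header row: DEMO (demographics/administrative), DRUG
(one row per drug per report, with a role code), REAC (MedDRA preferred
terms), THER (therapy start/end dates) and OUTC (outcome codes). This
module parses those five tables into pandas DataFrames with normalised
lower-case column names, links the non-DEMO tables to DEMO by
``primaryid``, and writes the analysis output tables.

The dialect has no quoting: an embedded '$' in a free-text field splits
the row, which then has the wrong field count and is skipped (and
counted). pandas' CSV reader pads under-length rows instead of flagging
them, so the line-level splitting here is done by hand; everything
downstream is ordinary pandas.

Legacy pre-2012Q4 "ISR"-era files (no PRIMARYID column) are rejected
outright rather than half-supported. Both header generations of the
modern format are accepted (e.g. DEMO's GNDR_COD, renamed SEX in 2014).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .disproportionality import SignalResult, results_to_records

logger = logging.getLogger(__name__)

__all__ = [
    "TABLE_NAMES",
    "RawQuarterBundle",
    "Corpus",
    "read_quarter",
    "read_corpus",
    "combine_bundles",
    "load_corpus",
    "write_signal_table",
]

TABLE_NAMES = ("demo", "drug", "reac", "ther", "outc")

# column -> accepted aliases (header generation changes)
_ALIASES = {
    "sex": ("gndr_cod",),
    "caseid": ("case",),
}

# mandatory / optional columns per table, post-normalisation
_SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "demo": (
        ("primaryid", "caseid", "fda_dt"),
        ("caseversion", "event_dt", "age", "age_cod", "sex", "occp_cod",
         "reporter_country", "occr_country"),
    ),
    "drug": (("primaryid", "drug_seq", "role_cod", "drugname"), ("caseid", "prod_ai")),
    "reac": (("primaryid", "pt"), ("caseid",)),
    "ther": (("primaryid", "dsg_drug_seq", "start_dt"), ("caseid", "end_dt")),
    "outc": (("primaryid", "outc_cod"), ("caseid",)),
}

ROLE_CODES = ("PS", "SS", "C", "I")

_QUARTER_RE = re.compile(r"(\d{2})[qQ]([1-4])")


def _infer_quarter(filename: str) -> str | None:
    m = _QUARTER_RE.search(Path(filename).stem)
    if not m:
        return None
    return f"20{m.group(1)}q{m.group(2)}"


def _normalise_header(fields: Sequence[str]) -> list[str]:
    cols = [f.strip().lower() for f in fields]
    for canonical, aliases in _ALIASES.items():
        cols = [canonical if c in aliases else c for c in cols]
    return cols


def read_table(path: str | Path, table: str) -> tuple[pd.DataFrame, int]:
    """Parse one '$'-delimited FAERS table.

    Returns the DataFrame (string dtype except integer ``primaryid``)
    and the number of skipped malformed rows. Raises ``ValueError`` for
    a missing mandatory column or a legacy ISR-era header.
    """
    if table not in _SCHEMAS:
        raise ValueError(f"unknown table {table!r}")
    mandatory, optional = _SCHEMAS[table]
    path = Path(path)
    with open(path, "r", encoding="latin-1") as fh:
        header_line = fh.readline().rstrip("\r\n")
        if not header_line:
            raise ValueError(f"{path}: empty file, no header row")
        cols = _normalise_header(header_line.split("$"))
        if "isr" in cols and "primaryid" not in cols:
            raise ValueError(
                f"{path}: legacy ISR-era file format is not supported; "
                "use the modern (2012Q4+) PRIMARYID-based files"
            )
        for col in mandatory:
            if col not in cols:
                raise ValueError(f"{path}: mandatory column {col.upper()} missing from {table.upper()} header")
        nfields = len(cols)
        rows: list[list[str]] = []
        skipped = 0
        for line in fh:
            parts = line.rstrip("\r\n").split("$")
            if len(parts) != nfields:
                if parts == [""]:
                    continue  # trailing blank line
                skipped += 1
                continue
            rows.append(parts)
    df = pd.DataFrame(rows, columns=cols)
    # keep only the columns the analysis model knows about
    keep = [c for c in (*mandatory, *optional) if c in df.columns]
    df = df[keep] if len(df) else pd.DataFrame(columns=keep)
    pid = pd.to_numeric(df["primaryid"], errors="coerce") if len(df) else pd.Series(dtype="float64")
    bad = pid.isna()
    if bad.any():
        skipped += int(bad.sum())
        df = df[~bad]
        pid = pid[~bad]
    df = df.assign(primaryid=pid.astype("int64")) if len(df) else df.assign(primaryid=pd.Series(dtype="int64"))
    if skipped:
        logger.warning("%s: skipped %d malformed row(s)", path, skipped)
    return df.reset_index(drop=True), skipped


@dataclass
class RawQuarterBundle:
    """One quarter's five tables, parsed but not yet linked or deduplicated."""

    quarter_label: str
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    skipped: dict[str, int] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @property
    def row_counts(self) -> dict[str, int]:
        return {t: len(self.table(t)) for t in TABLE_NAMES}


def read_quarter(paths: Mapping[str, str | Path], quarter_label: str | None = None) -> RawQuarterBundle:
    """Read one quarter from a table-name -> file-path mapping.

    Missing tables among the five are a hard error; the quarter label is
    inferred from the file names when not given.
    """
    missing = [t for t in TABLE_NAMES if t not in paths]
    if missing:
        raise ValueError(f"missing table file(s) for quarter: {', '.join(missing)}")
    tables: dict[str, pd.DataFrame] = {}
    skipped: dict[str, int] = {}
    labels = set()
    for t in TABLE_NAMES:
        tables[t], skipped[t] = read_table(paths[t], t)
        lbl = _infer_quarter(str(paths[t]))
        if lbl:
            labels.add(lbl)
    if quarter_label is None:
        quarter_label = labels.pop() if len(labels) == 1 else "unknown"
    return RawQuarterBundle(quarter_label=quarter_label, skipped=skipped, **tables)


def read_corpus(directory: str | Path) -> list[RawQuarterBundle]:
    """Read every quarterly bundle found in a directory.

    Files are grouped by the yyQq token in their names; each quarter
    must supply all five tables (DEMO/DRUG/REAC/THER/OUTC prefixes,
    case-insensitive).
    """
    directory = Path(directory)
    quarters: dict[str, dict[str, Path]] = {}
    for p in sorted(directory.iterdir()):
        if not p.is_file() or p.suffix.lower() != ".txt":
            continue
        name = p.stem.lower()
        for t in TABLE_NAMES:
            if name.startswith(t):
                q = _infer_quarter(p.name) or "unknown"
                quarters.setdefault(q, {})[t] = p
    if not quarters:
        raise FileNotFoundError(f"no FAERS table files (*.txt) found under {directory}")
    bundles = []
    for q in sorted(quarters):
        bundles.append(read_quarter(quarters[q], quarter_label=q))
    return bundles


@dataclass
class Corpus:
    """All quarters concatenated, with orphan rows dropped.

    An orphan is a non-DEMO row whose primaryid has no DEMO row anywhere
    in the loaded corpus; orphans are counted and removed, never fatal.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    orphans_dropped: dict[str, int] = field(default_factory=dict)
    skipped_rows: dict[str, int] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)


def combine_bundles(bundles: Iterable[RawQuarterBundle]) -> Corpus:
    """Concatenate quarterly bundles into one corpus, enforcing linkage."""
    bundles = list(bundles)
    if not bundles:
        raise ValueError("no bundles to combine")
    tables: dict[str, pd.DataFrame] = {}
    skipped: dict[str, int] = {t: 0 for t in TABLE_NAMES}
    for t in TABLE_NAMES:
        parts = [b.table(t) for b in bundles if len(b.table(t))]
        tables[t] = (
            pd.concat(parts, ignore_index=True) if parts else bundles[0].table(t).iloc[0:0].copy()
        )
        for b in bundles:
            skipped[t] += b.skipped.get(t, 0)
    known = set(tables["demo"]["primaryid"].tolist())
    orphans: dict[str, int] = {}
    for t in TABLE_NAMES[1:]:
        df = tables[t]
        if len(df):
            ok = df["primaryid"].isin(known)
            orphans[t] = int((~ok).sum())
            if orphans[t]:
                logger.warning("%s: dropped %d orphan row(s) with no DEMO record", t, orphans[t])
            tables[t] = df[ok].reset_index(drop=True)
        else:
            orphans[t] = 0
    return Corpus(orphans_dropped=orphans, skipped_rows=skipped, **tables)


def load_corpus(directory: str | Path) -> Corpus:
    """read_corpus + combine_bundles in one step."""
    return combine_bundles(read_corpus(directory))


def write_signal_table(results: Sequence[SignalResult], path: str | Path, ndigits: int = 2) -> None:
    """Write one CSV row per drug set: full-precision statistics, flags,
    and 2-decimal display columns in the printed-table style."""
    records = results_to_records(results, ndigits=ndigits)
    columns = [
        "drug", "N", "ROR", "ROR_CI_low", "ROR_CI_high", "PRR", "chi2",
        "IC", "IC025", "EBGM", "EBGM05",
        "ror_pass", "prr_pass", "bcpnn_pass", "ebgm_pass", "signal",
        "ROR_display", "PRR_display", "IC_display", "EBGM_display",
    ]
    pd.DataFrame(records, columns=columns).to_csv(path, index=False)
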