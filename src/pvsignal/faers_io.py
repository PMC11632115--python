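"""Reading and writing FAERS-style quarterly ASCII extracts.

The FDA Adverse Event Reporting System distributes each quarter as a set of
"$"-delimited ASCII tables (DEMO, DRUG, REAC, OUTC, THER) with one header
line.  The format has no quoting or escape mechanism, so a literal "$" cannot
occur inside a field; identifiers are kept as text because leading zeros are
significant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

DELIMITER = "$"

#: The five table kinds of a FAERS quarterly extract.
TABLE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "THER")

#: Minimal column sets each table kind must carry.  Extra columns are
#: preserved as opaque fields.
REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "DEMO": ("PRIMARYID", "CASEID", "CASEVERSION", "FDA_DT", "AGE", "AGE_COD",
             "SEX", "OCCP_COD", "REPORTER_COUNTRY", "EVENT_DT"),
    "DRUG": ("PRIMARYID", "CASEID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME",
             "PROD_AI"),
    "REAC": ("PRIMARYID", "CASEID", "PT"),
    "OUTC": ("PRIMARYID", "CASEID", "OUTC_COD"),
    "THER": ("PRIMARYID", "CASEID", "DSG_DRUG_SEQ", "START_DT"),
}


class FaersFormatError(ValueError):
    """Raised for malformed or missing FAERS-format files."""


@dataclass
class RawRecordSet:
    """One parsed FAERS table: a list of field-maps keyed by column name."""

    table_kind: str
    quarter_label: str
    columns: list[str] = field(default_factory=list)
    rows: list[dict[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.table_kind not in TABLE_KINDS:
            raise ValueError(f"unknown table kind {self.table_kind!r}")

    def __len__(self) -> int:
        return len(self.rows)


def quarter_file_name(table_kind: str, quarter_label: str) -> str:
    """``("DEMO", "2018Q4") -> "DEMO18Q4.txt"`` (FAERS naming convention)."""
    year, q = quarter_label.split("Q")
    return f"{table_kind}{year[-2:]}Q{q}.txt"


def _parse_lines(lines: list[str], table_kind: str, quarter_label: str,
                 on_bad_lines: str) -> RawRecordSet:
    if not lines:
        raise FaersFormatError(f"{table_kind}: file is empty (no header line)")
    header = [c.strip().upper() for c in lines[0].split(DELIMITER)]
    ncol = len(header)
    rows: list[dict[str, str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        parts = line.split(DELIMITER)
        if len(parts) == ncol + 1 and parts[-1].strip() == "":
            # trailing delimiter produced one empty extra field
            warnings.warn(
                f"{table_kind} line {lineno}: trailing '{DELIMITER}' field dropped",
                stacklevel=3,
            )
            parts = parts[:-1]
        if len(parts) != ncol:
            msg = (f"{table_kind} line {lineno}: expected {ncol} fields, "
                   f"got {len(parts)}")
            if on_bad_lines == "error":
                raise FaersFormatError(msg)
            warnings.warn(msg + " — line rejected", stacklevel=3)
            continue
        rows.append({k: v.strip() for k, v in zip(header, parts)})
    return RawRecordSet(table_kind=table_kind, quarter_label=quarter_label,
                        columns=header, rows=rows)


def read_table(path: Path | str, table_kind: str, quarter_label: str,
               on_bad_lines: str = "warn") -> RawRecordSet:
    """Parse one "$"-delimited FAERS table file.

    Field values are whitespace-trimmed and column names upper-cased.
    Parsing is insensitive to a trailing newline and to CRLF vs LF endings.
    """
    if on_bad_lines not in ("warn", "error"):
        raise ValueError("on_bad_lines must be 'warn' or 'error'")
    text = Path(path).read_text(encoding="utf-8")
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")
    while lines and lines[-1] == "":
        lines.pop()
    return _parse_lines(lines, table_kind, quarter_label, on_bad_lines)


def read_quarter(directory: Path | str, quarter_label: str,
                 on_bad_lines: str = "warn") -> dict[str, RawRecordSet]:
    """Read the five FAERS tables for one quarter from *directory*.

    Returns a map ``table_kind -> RawRecordSet`` and logs the row count per
    table.  A missing file raises :class:`FaersFormatError` naming the table.
    """
    directory = Path(directory)
    out: dict[str, RawRecordSet] = {}
    for kind in TABLE_KINDS:
        path = directory / quarter_file_name(kind, quarter_label)
        if not path.exists():
            raise FaersFormatError(
                f"missing {kind} file for {quarter_label}: {path}")
        out[kind] = read_table(path, kind, quarter_label, on_bad_lines)
        logger.info("%s %s: %d rows", quarter_label, kind, len(out[kind]))
    return out


def write_table(records: RawRecordSet, path: Path | str) -> None:
    """Write one table in FAERS ASCII format (header + "$"-delimited rows).

    The format cannot escape the delimiter, so any field containing "$"
    is rejected.
    """
    columns = records.columns or (list(records.rows[0]) if records.rows else [])
    lines = [DELIMITER.join(columns)]
    for row in records.rows:
        values = [row.get(c, "") for c in columns]
        for v in values:
            if DELIMITER in v:
                raise FaersFormatError(
                    f"field value {v!r} contains the delimiter {DELIMITER!r}")
        lines.append(DELIMITER.join(values))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_quarter(records: dict[str, RawRecordSet],
                  directory: Path | str) -> list[Path]:
    """Write a full quarter file set; inverse of :func:`read_quarter`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for kind, recs in records.items():
        path = directory / quarter_file_name(kind, recs.quarter_label)
        write_table(recs, path)
        written.append(path)
    return written


def _fmt(value: float) -> str:
    """Round to 2 decimals and drop trailing zeros: 2.5, 0.77, 8.1."""
    import math

    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return str(round(float(value), 2))


def _fmt_ci(value: float, ci: tuple[float, float]) -> str:
    return f"{_fmt(value)} ({_fmt(ci[0])}, {_fmt(ci[1])})"


def write_signal_table(results: Iterable, path: Path | str) -> None:
    """Write signal results as a comma-delimited table.

    One row per term with the columns of a standard disproportionality
    report: n, ROR (95% CI), PRR (95% CI), chi-squared, IC (IC025),
    EBGM (EBGM05) and the per-algorithm flags.  Numeric cells are rounded
    to 2 decimal places; confidence intervals render as "low, high".
    """
    header = ("term,level,n,ROR (95% CI),PRR (95% CI),Chi-squared,"
              "IC (IC025),EBGM (EBGM05),ror_signal,prr_signal,ic_signal,"
              "ebgm_signal,significant_any,significant_all")
    lines = [header]
    for r in results:
        f, b, m = r.frequentist, r.bcpnn, r.mgps
        term = f'"{r.term}"' if "," in r.term else r.term
        lines.append(",".join([
            term,
            r.level,
            str(r.n),
            f'"{_fmt_ci(f.ror, f.ror_ci)}"',
            f'"{_fmt_ci(f.prr, f.prr_ci)}"',
            _fmt(f.chi2),
            f'"{_fmt(b.ic)} ({_fmt(b.ic025)})"',
            f'"{_fmt(m.ebgm)} ({_fmt(m.ebgm05)})"',
            str(f.ror_signal),
            str(f.prr_signal),
            str(b.flag),
            str(m.flag),
            str(r.significant_any),
            str(r.significant_all),
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
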