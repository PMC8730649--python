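"""Crash-safe incremental CSV output.

Coding output is appended row by row and flushed to disk after every data
point, so a process halt at any moment loses at most the row being written
and never corrupts what came before. Final summaries are written atomically
via a temp-file rename.

Dialect: RFC 4180, UTF-8, LF line endings, mandatory header row. Numeric
formatting is fixed — durations to one decimal (the 0.2 s grid needs no
more), fractions to four — so identical runs produce byte-identical files.
"""
from __future__ import annotations

import csv
import io as _stdio
import os
import tempfile
from pathlib import Path
from typing import Iterable, Sequence

from .errors import OutputSchemaError

#: Results-CSV schema identifier, written as a comment-free header row only;
#: versioning travels in the column set itself.
CODING_SCHEMA = [
    "subject_id",
    "phase",
    "epoch_index",
    "indicator",
    "seconds_present",
    "fraction_present",
]
RESULTS_SCHEMA = [
    "subject_id",
    "phase",
    "epoch_index",
    "measure",
    "bb",
    "es",
    "nf",
    "hr",
    "spo2",
    "ga",
    "state",
    "total",
    "flags",
]


def fmt_duration(x: float) -> str:
    return f"{x:.1f}"


def fmt_fraction(x: float) -> str:
    return f"{x:.4f}"


class OutputLog:
    """Append-only CSV log, durable after every row.

    The header is written on open; each :meth:`append_data_point` validates
    the row against the schema, writes it, flushes, and fsyncs. Use as a
    context manager.
    """

    def __init__(self, destination: str | Path, schema: Sequence[str]):
        self.destination = Path(destination)
        self.schema = list(schema)
        self.rows_appended = 0
        self._fh = open(self.destination, "w", encoding="utf-8", newline="")
        self._writer = csv.writer(self._fh, lineterminator="\n")
        self._writer.writerow(self.schema)
        self._sync()

    def _sync(self) -> None:
        self._fh.flush()
        os.fsync(self._fh.fileno())

    def append_data_point(self, row: Sequence) -> "OutputLog":
        """Durably append one row; the file stays parseable throughout."""
        if len(row) != len(self.schema):
            raise OutputSchemaError(
                f"row has {len(row)} fields, schema {self.destination.name} "
                f"expects {len(self.schema)}"
            )
        self._writer.writerow(row)
        self._sync()
        self.rows_appended += 1
        return self

    def close(self) -> None:
        if not self._fh.closed:
            self._sync()
            self._fh.close()

    def __enter__(self) -> "OutputLog":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def write_atomic(destination: str | Path, text: str) -> None:
    """Write ``text`` to ``destination`` via temp file + rename."""
    destination = Path(destination)
    fd, tmp = tempfile.mkstemp(
        dir=destination.parent, prefix=destination.name, suffix=".tmp"
    )
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
            fh.flush()
            os.fsync(fh.fileno())
        os.replace(tmp, destination)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def rows_to_csv_text(schema: Sequence[str], rows: Iterable[Sequence]) -> str:
    """Render rows as RFC 4180 CSV text with LF endings."""
    buf = _stdio.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(schema)
    for row in rows:
        if len(row) != len(schema):
            raise OutputSchemaError(
                f"row has {len(row)} fields, expected {len(schema)}"
            )
        w.writerow(row)
    return buf.getvalue()
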