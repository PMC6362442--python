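"""Reading and writing encounter-history files.

Two dialects:

* CSV with columns ``id, history, count`` (``count`` optional, default 1;
  an optional ``group`` column is carried through but unused), history being
  a string of event digits 0-3, one column of digits per occasion;
* MARK-style ``.inp``: one history per line, whitespace, a frequency, and a
  terminating ``;`` (``/* ... */`` comments are stripped).
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .model_core import CRDataset, EncounterHistory

__all__ = ["read_histories", "write_histories", "HistoryFormatError"]

_DIGITS = re.compile(r"^[0-3]+$")


class HistoryFormatError(ValueError):
    """One or more rows of a history file failed validation."""


def _validate_rows(rows: list[tuple[int, str, str, int]]) -> CRDataset:
    """rows: (line_number, id, history_string, count). Collects all errors."""
    errors: list[str] = []
    histories: list[EncounterHistory] = []
    lengths = {len(h) for _, _, h, _ in rows}
    if len(lengths) > 1:
        errors.append(f"histories have unequal lengths {sorted(lengths)}")
    for line, ident, hist, count in rows:
        bad = [ch for ch in hist if ch not in "0123"]
        if bad:
            errors.append(f"line {line}: invalid event digit {bad[0]!r} in {hist!r}")
            continue
        if not hist or set(hist) == {"0"}:
            errors.append(f"line {line}: all-zero history {hist!r}")
            continue
        if count < 1:
            errors.append(f"line {line}: count {count} is not positive")
            continue
        histories.append(EncounterHistory.from_string(hist, id=ident, count=count))
    if errors:
        raise HistoryFormatError("invalid history file:\n  " + "\n  ".join(errors))
    if not histories:
        raise HistoryFormatError("history file contains no data rows")
    return CRDataset(histories)


def _read_csv(path: Path) -> CRDataset:
    df = pd.read_csv(path, dtype={"history": str})
    if "history" not in df.columns:
        raise HistoryFormatError(f"{path}: CSV must have a 'history' column")
    ids = df["id"].astype(str) if "id" in df.columns else [f"ind{i + 1}" for i in range(len(df))]
    counts = df["count"].astype(int) if "count" in df.columns else [1] * len(df)
    rows = [
        (i + 2, str(ident), str(h).strip(), int(c))  # +2: header is line 1
        for i, (ident, h, c) in enumerate(zip(ids, df["history"], counts))
    ]
    return _validate_rows(rows)


def _read_inp(path: Path) -> CRDataset:
    text = re.sub(r"/\*.*?\*/", "", path.read_text(), flags=re.S)
    rows = []
    for line_no, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if not line.endswith(";"):
            raise HistoryFormatError(f"{path}: line {line_no}: missing terminating ';'")
        parts = line[:-1].split()
        if len(parts) == 1:
            hist, count = parts[0], 1
        elif len(parts) == 2:
            hist, count = parts[0], int(float(parts[1]))
        else:
            raise HistoryFormatError(
                f"{path}: line {line_no}: expected 'history frequency;', got {line!r}"
            )
        rows.append((line_no, f"ind{len(rows) + 1}", hist, count))
    return _validate_rows(rows)


def read_histories(path, dialect: str | None = None) -> CRDataset:
    """Load a history file; dialect 'csv' or 'inp' (inferred from suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "inp" if path.suffix.lower() == ".inp" else "csv"
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "inp":
        return _read_inp(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_histories(dataset: CRDataset, path, dialect: str | None = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "inp" if path.suffix.lower() == ".inp" else "csv"
    if dialect == "csv":
        pd.DataFrame(
            dict(
                id=[h.id for h in dataset.histories],
                history=[str(h) for h in dataset.histories],
                count=[h.count for h in dataset.histories],
            )
        ).to_csv(path, index=False)
    elif dialect == "inp":
        with open(path, "w") as fh:
            for h in dataset.histories:
                fh.write(f"{h} {h.count};\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
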