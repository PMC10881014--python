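"""Reading and writing Raven-Pro-style selection tables and recording covariates.

Raven Pro exports one tab-delimited row per annotated sound element
("selection"), labelled by its start/end time in seconds and its lower/upper
frequency bound in Hz.  This module parses those exports into validated
:class:`ElementRecord` objects and round-trips them losslessly.  Recording-level
covariates (site, date, hour, water temperature, acoustic richness, vessel
densities) live in a companion CSV parsed into :class:`RecordingMeta`.

Parsing is deliberately strict: cells are read as text and converted
explicitly, so a malformed number fails loudly with its row number, and
decimal-comma exports are rejected rather than silently coerced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd

__all__ = [
    "ElementRecord",
    "RecordingMeta",
    "SelectionTableFormatError",
    "SelectionTableParseError",
    "read_selection_table",
    "write_selection_table",
    "read_covariates",
    "write_covariates",
]

#: Columns a Raven selection table must provide, with their exact header names.
REQUIRED_COLUMNS = (
    "Selection",
    "Begin Time (s)",
    "End Time (s)",
    "Low Freq (Hz)",
    "High Freq (Hz)",
)

#: Fixed column order on output (Raven's conventional layout).
OUTPUT_COLUMNS = (
    "Selection",
    "View",
    "Channel",
    "Begin Time (s)",
    "End Time (s)",
    "Low Freq (Hz)",
    "High Freq (Hz)",
)

#: Header used when an SNR column is written.
SNR_COLUMN = "SNR (dB)"


class SelectionTableFormatError(ValueError):
    """A selection table is structurally malformed (e.g. a required column is missing)."""


class SelectionTableParseError(ValueError):
    """A selection table cell could not be parsed as the expected type."""


@dataclass(frozen=True)
class ElementRecord:
    """One annotated sound element.

    Times are absolute seconds from the start of the recording; frequency
    bounds are the annotated bandwidth in Hz.  ``snr_db`` is optional: it is
    only present when the annotator exported a signal-to-noise measurement.
    """

    selection_id: int
    begin_s: float
    end_s: float
    low_hz: float
    high_hz: float
    snr_db: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.selection_id <= 0:
            raise ValueError(f"selection_id must be positive, got {self.selection_id}")
        if self.begin_s < 0:
            raise ValueError(
                f"selection {self.selection_id}: begin_s must be >= 0, got {self.begin_s}"
            )
        if not self.begin_s < self.end_s:
            raise ValueError(
                f"selection {self.selection_id}: begin_s ({self.begin_s}) must be "
                f"strictly before end_s ({self.end_s})"
            )
        if self.low_hz < 0:
            raise ValueError(
                f"selection {self.selection_id}: low_hz must be >= 0, got {self.low_hz}"
            )
        if self.low_hz > self.high_hz:
            raise ValueError(
                f"selection {self.selection_id}: low_hz ({self.low_hz}) must not "
                f"exceed high_hz ({self.high_hz})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.begin_s


@dataclass(frozen=True)
class RecordingMeta:
    """Covariates attached to one recording (one ``source_id``).

    Vessel densities are AIS traffic densities in hours per square kilometre
    per month, split by vessel category; ``acoustic_richness`` counts the fish
    sound types present in the recording.
    """

    source_id: str
    site_name: str
    year: int
    month: int
    day: int
    hour: int
    water_temp_c: float
    acoustic_richness: int
    vessel_density_total: float
    vessel_density_trade: float
    vessel_density_fishing: float
    vessel_density_recreational: float
    vessel_density_passenger: float
    vessel_density_other: float

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"{self.source_id}: month must be in 1..12, got {self.month}")
        if not 1 <= self.day <= 31:
            raise ValueError(f"{self.source_id}: day must be in 1..31, got {self.day}")
        if not 0 <= self.hour <= 23:
            raise ValueError(f"{self.source_id}: hour must be in 0..23, got {self.hour}")
        if self.acoustic_richness < 0:
            raise ValueError(
                f"{self.source_id}: acoustic_richness must be >= 0, "
                f"got {self.acoustic_richness}"
            )
        for name in (
            "vessel_density_total",
            "vessel_density_trade",
            "vessel_density_fishing",
            "vessel_density_recreational",
            "vessel_density_passenger",
            "vessel_density_other",
        ):
            if getattr(self, name) < 0:
                raise ValueError(
                    f"{self.source_id}: {name} must be >= 0, got {getattr(self, name)}"
                )


def _parse_float(cell: object, *, column: str, row: int) -> float:
    """Parse one table cell as a dot-decimal float.

    Decimal commas (``"2,78"``) are rejected on purpose: annotation exports
    produced under comma-decimal locales must be fixed upstream, not silently
    reinterpreted.
    """
    text = "" if cell is None else str(cell).strip()
    if text == "" or text.lower() == "nan":
        raise SelectionTableParseError(
            f"row {row}: empty cell in column {column!r}"
        )
    try:
        value = float(text)
    except ValueError:
        raise SelectionTableParseError(
            f"row {row}: cannot parse {text!r} in column {column!r} as a number "
            "(decimal comma inputs are rejected; use dot decimals)"
        ) from None
    if not math.isfinite(value):
        raise SelectionTableParseError(
            f"row {row}: non-finite value {text!r} in column {column!r}"
        )
    return value


def _parse_int(cell: object, *, column: str, row: int) -> int:
    value = _parse_float(cell, column=column, row=row)
    if value != int(value):
        raise SelectionTableParseError(
            f"row {row}: expected an integer in column {column!r}, got {cell!r}"
        )
    return int(value)


def _find_snr_column(columns: Iterable[str]) -> str | None:
    """Return the first column whose header looks like an SNR measurement."""
    for name in columns:
        if "snr" in name.lower():
            return name
    return None


def _infer_source_id(path_or_stream: str | Path | IO[str]) -> str:
    if isinstance(path_or_stream, (str, Path)):
        return Path(path_or_stream).stem
    return getattr(path_or_stream, "name", "") or ""


def read_selection_table(
    path_or_stream: str | Path | IO[str],
    source_id: str | None = None,
) -> list[ElementRecord]:
    """Read a Raven selection table into time-sorted :class:`ElementRecord` objects.

    Parameters
    ----------
    path_or_stream
        Path to a tab-delimited selection table with a header row, or an open
        text stream.
    source_id
        Recording identifier to stamp on every record.  Defaults to the file
        stem (or the stream's ``name``).

    Returns
    -------
    list of ElementRecord, sorted ascending by onset time.  An SNR-like column
    (any header containing "SNR") is mapped to ``snr_db``; other extra columns
    are ignored.
    """
    if source_id is None:
        source_id = _infer_source_id(path_or_stream)
    table = pd.read_csv(path_or_stream, sep="\t", dtype=str)
    for column in REQUIRED_COLUMNS:
        if column not in table.columns:
            raise SelectionTableFormatError(
                f"selection table is missing required column {column!r}"
            )
    snr_column = _find_snr_column(table.columns)

    records: list[ElementRecord] = []
    seen_ids: set[int] = set()
    for i, row in enumerate(table.itertuples(index=False), start=2):  # header = row 1
        cells = dict(zip(table.columns, row))
        sel = _parse_int(cells["Selection"], column="Selection", row=i)
        if sel in seen_ids:
            raise SelectionTableFormatError(
                f"row {i}: duplicate selection id {sel} within {source_id!r}"
            )
        seen_ids.add(sel)
        snr = None
        if snr_column is not None:
            raw = cells[snr_column]
            if raw is not None and str(raw).strip() not in ("", "nan"):
                snr = _parse_float(raw, column=snr_column, row=i)
        records.append(
            ElementRecord(
                selection_id=sel,
                begin_s=_parse_float(cells["Begin Time (s)"], column="Begin Time (s)", row=i),
                end_s=_parse_float(cells["End Time (s)"], column="End Time (s)", row=i),
                low_hz=_parse_float(cells["Low Freq (Hz)"], column="Low Freq (Hz)", row=i),
                high_hz=_parse_float(cells["High Freq (Hz)"], column="High Freq (Hz)", row=i),
                snr_db=snr,
                source_id=source_id,
            )
        )
    records.sort(key=lambda r: (r.begin_s, r.end_s, r.selection_id))
    return records


def write_selection_table(
    elements: Sequence[ElementRecord],
    path: str | Path | IO[str],
) -> None:
    """Write elements as a Raven-dialect selection table.

    Column order is fixed (Selection, View, Channel, times, frequencies, then
    the optional SNR column).  Numbers are written with six decimal places so
    a write/read round trip reproduces the records to well below annotation
    precision.
    """
    any_snr = any(e.snr_db is not None for e in elements)
    rows = []
    for e in elements:
        row = {
            "Selection": e.selection_id,
            "View": "Spectrogram 1",
            "Channel": 1,
            "Begin Time (s)": f"{e.begin_s:.6f}",
            "End Time (s)": f"{e.end_s:.6f}",
            "Low Freq (Hz)": f"{e.low_hz:.6f}",
            "High Freq (Hz)": f"{e.high_hz:.6f}",
        }
        if any_snr:
            row[SNR_COLUMN] = "" if e.snr_db is None else f"{e.snr_db:.6f}"
        rows.append(row)
    columns = list(OUTPUT_COLUMNS) + ([SNR_COLUMN] if any_snr else [])
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


_META_INT_FIELDS = {"year", "month", "day", "hour", "acoustic_richness"}
_META_STR_FIELDS = {"source_id", "site_name"}

#: Documented covariate CSV schema, in column order.
COVARIATE_COLUMNS = tuple(f.name for f in fields(RecordingMeta))


def read_covariates(path: str | Path | IO[str]) -> list[RecordingMeta]:
    """Read the per-recording covariate CSV into :class:`RecordingMeta` rows."""
    table = pd.read_csv(path, dtype=str)
    for column in COVARIATE_COLUMNS:
        if column not in table.columns:
            raise SelectionTableFormatError(
                f"covariate table is missing required column {column!r}"
            )
    metas: list[RecordingMeta] = []
    seen: set[str] = set()
    for i, row in enumerate(table.itertuples(index=False), start=2):
        cells = dict(zip(table.columns, row))
        kwargs: dict[str, object] = {}
        for name in COVARIATE_COLUMNS:
            raw = cells[name]
            if name in _META_STR_FIELDS:
                text = "" if raw is None else str(raw).strip()
                if text == "" or text == "nan":
                    raise SelectionTableParseError(f"row {i}: empty cell in column {name!r}")
                kwargs[name] = text
            elif name in _META_INT_FIELDS:
                kwargs[name] = _parse_int(raw, column=name, row=i)
            else:
                kwargs[name] = _parse_float(raw, column=name, row=i)
        meta = RecordingMeta(**kwargs)  # type: ignore[arg-type]
        if meta.source_id in seen:
            raise SelectionTableFormatError(
                f"row {i}: duplicate source_id {meta.source_id!r}"
            )
        seen.add(meta.source_id)
        metas.append(meta)
    return metas


def write_covariates(metas: Sequence[RecordingMeta], path: str | Path | IO[str]) -> None:
    """Write :class:`RecordingMeta` rows to CSV with the documented schema."""
    rows = []
    for m in metas:
        row = {}
        for name in COVARIATE_COLUMNS:
            value = getattr(m, name)
            row[name] = f"{value:.6f}" if isinstance(value, float) else value
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(COVARIATE_COLUMNS))
    frame.to_csv(path, index=False, lineterminator="\n")
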