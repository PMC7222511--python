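"""Reading and writing plate-reader time-course CSVs.

The accepted dialect is the one continuous-assay plate readers export and
the common web analysis tools consume: a header row, a first column of time
(seconds or minutes), and one further column per reaction well. Every well
header must contain a number giving the titrant concentration — ``"320"``,
``"SIRT1 40 uM"`` and ``"inhibitor_2.5e-2_mM"`` all parse. Signals may be
converted to substrate concentrations with a user-supplied arithmetic
transform in one variable ``x`` (the measured signal), evaluated by a small
restricted parser rather than general code execution.
"""

from __future__ import annotations

import ast
import io
import logging
import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np
import pandas as pd

from .endpoint_models import RateRow, RateTable

__all__ = [
    "TimeUnit",
    "KineticTrace",
    "KineticDataset",
    "TransformSpec",
    "parse_concentration",
    "read_trace_csv",
    "apply_transform",
    "subtract_blank_line",
    "write_rate_table_csv",
    "read_rate_table_csv",
]

logger = logging.getLogger(__name__)

PathOrStream = Union[str, Path, IO[str]]

# first maximal numeric token in a header; decimals and scientific notation.
# digits glued to a preceding letter are part of a name ("SIRT1"), not a number
_NUMERIC_TOKEN = re.compile(r"(?<![A-Za-z])[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")


class TimeUnit(str, Enum):
    seconds = "seconds"
    minutes = "minutes"
    unspecified = "unspecified"


@dataclass
class KineticTrace:
    """One well's progress curve with the titrant concentration parsed from its header."""

    label: str
    concentration: float
    time: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.signal.ndim != 1:
            raise ValueError(f"trace {self.label!r}: time and signal must be 1-D")
        if self.time.size != self.signal.size:
            raise ValueError(f"trace {self.label!r}: time and signal lengths differ")
        if self.time.size < 3:
            raise ValueError(f"trace {self.label!r}: need at least 3 points")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError(f"trace {self.label!r}: time must be strictly increasing")
        if self.concentration < 0:
            raise ValueError(f"trace {self.label!r}: concentration must be non-negative")

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass
class KineticDataset:
    """A set of traces sharing one time vector (one uploaded experiment)."""

    traces: list[KineticTrace]
    time_unit: TimeUnit = TimeUnit.unspecified
    blank_label: str | None = None

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValueError("dataset must contain at least one trace")
        t0 = self.traces[0].time
        for tr in self.traces[1:]:
            if tr.time.shape != t0.shape or not np.array_equal(tr.time, t0):
                raise ValueError(f"trace {tr.label!r} does not share the dataset time vector")
        labels = [tr.label for tr in self.traces]
        if len(set(labels)) != len(labels):
            raise ValueError("trace labels must be unique")
        if self.blank_label is not None and self.blank_label not in labels:
            raise KeyError(f"blank label {self.blank_label!r} not among traces")

    @property
    def time(self) -> np.ndarray:
        return self.traces[0].time

    @property
    def labels(self) -> list[str]:
        return [tr.label for tr in self.traces]

    def __len__(self) -> int:
        return len(self.traces)

    def __getitem__(self, label: str) -> KineticTrace:
        for tr in self.traces:
            if tr.label == label:
                return tr
        raise KeyError(label)


def parse_concentration(header: str) -> float:
    """Titrant concentration from a column header: the first maximal numeric token.

    Supports decimals and scientific notation; any sign is stripped so the
    result is non-negative. Deterministic and locale-independent (decimal
    point only).
    """
    m = _NUMERIC_TOKEN.search(str(header))
    if m is None:
        raise ValueError(f"no numeric token in column header {header!r}")
    return abs(float(m.group(0)))


_ALLOWED_BINOPS = {ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow}
_ALLOWED_UNARY = {ast.USub, ast.UAdd}


@dataclass(frozen=True)
class TransformSpec:
    """Arithmetic expression in the single variable ``x`` (the measured signal).

    Grammar: numbers, ``x``, ``+ - * / ^`` (``**`` also accepted), parentheses
    and unary minus. Anything else — names other than x, calls, attributes —
    is rejected at construction.
    """

    expression: str

    def __post_init__(self) -> None:
        self._tree()  # validate eagerly

    def _tree(self) -> ast.expr:
        src = self.expression.replace("^", "**")
        try:
            tree = ast.parse(src, mode="eval")
        except SyntaxError as exc:
            raise ValueError(f"invalid transform expression {self.expression!r}: {exc.msg}") from None
        for node in ast.walk(tree):
            if isinstance(node, (ast.Expression, ast.BinOp, ast.UnaryOp, ast.expr_context)):
                continue
            if isinstance(node, tuple(_ALLOWED_BINOPS) + tuple(_ALLOWED_UNARY)):
                continue
            if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
                continue
            if isinstance(node, ast.Name) and node.id == "x":
                continue
            raise ValueError(
                f"transform expression {self.expression!r} may only use numbers, "
                f"'x', + - * / ^ and parentheses (found {type(node).__name__}"
                + (f" {node.id!r}" if isinstance(node, ast.Name) else "")
                + ")"
            )
        return tree.body

    def __call__(self, x: np.ndarray | float) -> np.ndarray:
        return _eval_expr(self._tree(), np.asarray(x, dtype=float))


def _eval_expr(node: ast.expr, x: np.ndarray) -> np.ndarray:
    if isinstance(node, ast.Constant):
        return np.asarray(float(node.value))
    if isinstance(node, ast.Name):
        return x
    if isinstance(node, ast.UnaryOp):
        v = _eval_expr(node.operand, x)
        return -v if isinstance(node.op, ast.USub) else +v
    if isinstance(node, ast.BinOp):
        a = _eval_expr(node.left, x)
        b = _eval_expr(node.right, x)
        if isinstance(node.op, ast.Add):
            return a + b
        if isinstance(node.op, ast.Sub):
            return a - b
        if isinstance(node.op, ast.Mult):
            return a * b
        if isinstance(node.op, ast.Div):
            return a / b
        if isinstance(node.op, ast.Pow):
            return a**b
    raise ValueError(f"unsupported expression node {type(node).__name__}")  # pragma: no cover


def read_trace_csv(source: PathOrStream, time_unit: str | TimeUnit | None = None) -> KineticDataset:
    """Read a time-course CSV: first column time, one trace per further column.

    Concentrations are parsed from the headers via :func:`parse_concentration`
    (a header without any numeric token is a hard error naming the column).
    Rows containing any non-numeric cell are dropped for the whole dataset —
    preserving the shared time vector — with a logged warning. Duplicate
    headers are disambiguated with an ordinal suffix.
    """
    df = pd.read_csv(source, encoding="utf-8-sig", skip_blank_lines=True)
    df.columns = [str(c).lstrip("﻿").strip() for c in df.columns]
    if df.shape[1] < 2:
        raise ValueError("CSV must have a time column plus at least one trace column")

    df = df.apply(pd.to_numeric, errors="coerce")
    bad = df.isna().any(axis=1)
    if bad.any():
        logger.warning(
            "dropping %d row(s) with non-numeric cells (rows %s)",
            int(bad.sum()),
            [int(i) for i in df.index[bad][:10]],
        )
        df = df.loc[~bad]
    if df.shape[0] < 3:
        raise ValueError("fewer than 3 usable data rows")

    time = df.iloc[:, 0].to_numpy(dtype=float)
    if not np.all(np.diff(time) > 0):
        raise ValueError(f"time column {df.columns[0]!r} is not strictly increasing")

    seen: dict[str, int] = {}
    traces: list[KineticTrace] = []
    for col in df.columns[1:]:
        conc = parse_concentration(col)  # raises naming the column
        label = col
        seen[col] = seen.get(col, 0) + 1
        if seen[col] > 1:
            label = f"{col}_{seen[col]}"
        traces.append(KineticTrace(label, conc, time, df[col].to_numpy(dtype=float)))

    unit = TimeUnit(time_unit) if time_unit is not None else TimeUnit.unspecified
    return KineticDataset(traces=traces, time_unit=unit)


def apply_transform(dataset: KineticDataset, spec: TransformSpec, invert: bool = False) -> KineticDataset:
    """Apply a signal transform y -> f(y) (and optionally -f(y)) to every trace.

    ``invert`` multiplies by -1, for product-accumulation data that must be
    re-expressed as substrate loss before an integrated-rate-law fit. Time
    is untouched. Any non-finite transformed value is a hard error naming
    the trace and row.
    """
    sign = -1.0 if invert else 1.0
    new_traces = []
    for tr in dataset.traces:
        out = sign * np.broadcast_to(spec(tr.signal), tr.signal.shape).astype(float)
        if not np.all(np.isfinite(out)):
            row = int(np.flatnonzero(~np.isfinite(out))[0])
            raise ValueError(
                f"transform {spec.expression!r} produced a non-finite value in trace "
                f"{tr.label!r} at row {row} (signal {tr.signal[row]!r})"
            )
        new_traces.append(replace(tr, signal=out))
    return replace(dataset, traces=new_traces)


def subtract_blank_line(dataset: KineticDataset, blank_label: str) -> KineticDataset:
    """Subtract a straight line fitted to the blank trace from every other trace.

    The blank trace is removed from the returned dataset.
    """
    blank = dataset[blank_label]  # raises KeyError if absent
    slope, intercept = np.polyfit(blank.time, blank.signal, 1)
    line = intercept + slope * dataset.time
    traces = [
        replace(tr, signal=tr.signal - line)
        for tr in dataset.traces
        if tr.label != blank_label
    ]
    if not traces:
        raise ValueError("dataset contains only the blank trace")
    return replace(dataset, traces=traces, blank_label=None)


_RATE_COLUMNS = ["label", "concentration", "rate", "rate_stderr", "mode", "window_start", "window_end"]


def write_rate_table_csv(table: RateTable, sink: PathOrStream) -> None:
    """Write a rate table as CSV (12 significant digits; lossless round trip)."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty rate table")
    df = pd.DataFrame(
        {
            "label": [r.label for r in table.rows],
            "concentration": [r.concentration for r in table.rows],
            "rate": [r.rate for r in table.rows],
            "rate_stderr": [r.stderr for r in table.rows],
            "mode": [r.mode for r in table.rows],
            "window_start": [r.window[0] for r in table.rows],
            "window_end": [r.window[1] for r in table.rows],
        }
    )
    df.to_csv(sink, index=False, float_format="%.12g")


def read_rate_table_csv(source: PathOrStream) -> RateTable:
    """Read back a rate table written by :func:`write_rate_table_csv`."""
    df = pd.read_csv(source, encoding="utf-8-sig")
    missing = [c for c in _RATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rate table CSV missing column(s) {missing}")
    rows = [
        RateRow(
            label=str(rec.label),
            concentration=float(rec.concentration),
            rate=float(rec.rate),
            stderr=float(rec.rate_stderr),
            mode="" if pd.isna(rec.mode) else str(rec.mode),
            window=(float(rec.window_start), float(rec.window_end)),
        )
        for rec in df.itertuples()
    ]
    return RateTable(tuple(rows))
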