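"""Reading and writing time-resolved SC-ICP-MS traces and acquisition metadata.

The canonical on-disk dialect is a plain-text CSV with a comment header
carrying the acquisition metadata::

    # element=24Mg dwell_time_s=0.003 flow_mL_min=0.3
    time_s,counts
    0.000000,10
    0.003000,12

A single-column dialect (``counts`` only, dwell time taken from the header)
is also accepted.  Detector counts are integral by nature; fractional values
in an input file indicate a pre-processed trace and are rejected.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AcquisitionConfig",
    "CellSuspension",
    "TimeTrace",
    "TraceParseError",
    "read_trace",
    "write_trace",
]


class TraceParseError(ValueError):
    """Raised when a trace file cannot be parsed into a valid TimeTrace."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Instrument settings for one time-resolved acquisition.

    Parameters
    ----------
    sample_flow_rate_mL_min
        Sample uptake rate Q in mL/min.
    dwell_time_s
        Integration (dwell) time per data point, seconds.
    duration_s
        Total acquisition time, seconds.
    nebuliser_gas_L_min
        Nebuliser gas flow in L/min.  Carried as metadata only; it never
        enters any computation.
    element
        Isotope label, e.g. ``"24Mg"``.
    """

    sample_flow_rate_mL_min: float
    dwell_time_s: float
    duration_s: float
    nebuliser_gas_L_min: Optional[float] = None
    element: str = ""

    def __post_init__(self) -> None:
        if self.sample_flow_rate_mL_min <= 0:
            raise ValueError("sample_flow_rate_mL_min must be > 0")
        if self.dwell_time_s <= 0:
            raise ValueError("dwell_time_s must be > 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")

    @property
    def n_dwells(self) -> int:
        return int(round(self.duration_s / self.dwell_time_s))


@dataclass(frozen=True)
class CellSuspension:
    """Cell number concentration from hemocytometry.

    ``replicate_counts`` holds the individual chamber counts (typically a
    triplicate) whose mean is the working concentration; ``viability_fraction``
    is the live-cell fraction from Trypan-blue exclusion, applied as a
    multiplicative correction by consumers that request it.
    """

    concentration_cells_per_mL: float
    replicate_counts: Optional[tuple] = None
    viability_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.concentration_cells_per_mL <= 0:
            raise ValueError("concentration_cells_per_mL must be > 0")
        if self.viability_fraction is not None and not (
            0.0 <= self.viability_fraction <= 1.0
        ):
            raise ValueError("viability_fraction must lie in [0, 1]")
        if self.replicate_counts is not None:
            reps = tuple(float(x) for x in self.replicate_counts)
            if len(reps) < 1:
                raise ValueError("replicate_counts must have >= 1 entries")
            mean = float(np.mean(reps))
            if not math.isclose(
                mean, self.concentration_cells_per_mL, rel_tol=1e-6
            ):
                raise ValueError(
                    "mean of replicate_counts does not reproduce "
                    "concentration_cells_per_mL"
                )
            object.__setattr__(self, "replicate_counts", reps)

    @classmethod
    def from_replicates(
        cls,
        replicate_counts: Sequence[float],
        viability_fraction: Optional[float] = None,
    ) -> "CellSuspension":
        reps = tuple(float(x) for x in replicate_counts)
        return cls(
            concentration_cells_per_mL=float(np.mean(reps)),
            replicate_counts=reps,
            viability_fraction=viability_fraction,
        )

    @property
    def effective_concentration(self) -> float:
        """Concentration weighted by viability when viability is known."""
        if self.viability_fraction is None:
            return self.concentration_cells_per_mL
        return self.concentration_cells_per_mL * self.viability_fraction


@dataclass
class TimeTrace:
    """A time-resolved acquisition: one integer detector count per dwell."""

    counts: np.ndarray
    dwell_time_s: float
    element: str = ""
    acquisition: Optional[AcquisitionConfig] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.rint(arr)):
                raise ValueError("counts must be integer-valued")
            arr = arr.astype(np.int64)
        else:
            arr = arr.astype(np.int64, copy=False)
        if arr.size and arr.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.dwell_time_s <= 0:
            raise ValueError("dwell_time_s must be > 0")
        self.counts = arr

    @property
    def n_dwells(self) -> int:
        return int(self.counts.size)

    @property
    def duration_s(self) -> float:
        return self.n_dwells * self.dwell_time_s

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_dwells) * self.dwell_time_s

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeTrace):
            return NotImplemented
        return (
            np.array_equal(self.counts, other.counts)
            and math.isclose(self.dwell_time_s, other.dwell_time_s, rel_tol=1e-9)
            and self.element == other.element
        )


_HEADER_KEYS = ("element", "dwell_time_s", "flow_mL_min")


def _parse_header_line(line: str) -> dict:
    meta: dict = {}
    for token in line.lstrip("#").split():
        if "=" not in token:
            continue
        key, _, value = token.partition("=")
        meta[key] = value
    return meta


def read_trace(path, dialect: str = "auto") -> TimeTrace:
    """Read a time-resolved trace from a text file.

    Two dialects are accepted: two-column ``time_s,counts`` (dwell time
    inferred from the time spacing and cross-checked against the header when
    present) and single-column ``counts`` (dwell time required in the
    ``# dwell_time_s=...`` header).  Non-uniform time spacing beyond 1% of
    the median step is a dialect error; fractional counts are a parse error.
    """
    if dialect not in ("auto", "two_column", "single_column"):
        raise ValueError(f"unknown dialect {dialect!r}")
    meta: dict = {}
    times: list = []
    counts: list = []
    n_columns = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                meta.update(_parse_header_line(line))
                continue
            fields = [f.strip() for f in line.split(",")]
            # skip a textual column-header row
            if any(not _is_number(f) for f in fields):
                if not counts and not times:
                    continue
                raise TraceParseError(
                    f"{path}: malformed row at line {lineno}: {line!r}"
                )
            if n_columns is None:
                n_columns = len(fields)
                if n_columns not in (1, 2):
                    raise TraceParseError(
                        f"{path}: expected 1 or 2 columns, got {n_columns} "
                        f"at line {lineno}"
                    )
            elif len(fields) != n_columns:
                raise TraceParseError(
                    f"{path}: inconsistent column count at line {lineno}"
                )
            if n_columns == 2:
                times.append(float(fields[0]))
                raw_count = float(fields[1])
            else:
                raw_count = float(fields[0])
            if raw_count != int(raw_count):
                raise TraceParseError(
                    f"{path}: fractional count {raw_count} at line {lineno}; "
                    "detector counts must be integral"
                )
            counts.append(int(raw_count))
    if not counts:
        raise TraceParseError(f"{path}: no data rows")
    if dialect == "two_column" and n_columns != 2:
        raise TraceParseError(f"{path}: expected two-column dialect")
    if dialect == "single_column" and n_columns != 1:
        raise TraceParseError(f"{path}: expected single-column dialect")

    header_dwell = float(meta["dwell_time_s"]) if "dwell_time_s" in meta else None
    if n_columns == 2 and len(times) >= 2:
        steps = np.diff(np.asarray(times))
        dwell = float(np.median(steps))
        if dwell <= 0 or np.any(np.abs(steps - dwell) > 0.01 * dwell):
            raise TraceParseError(
                f"{path}: non-uniform time spacing beyond 1% tolerance"
            )
        if header_dwell is not None:
            dwell = header_dwell  # header is authoritative at full precision
    elif header_dwell is not None:
        dwell = header_dwell
    else:
        raise TraceParseError(
            f"{path}: dwell time cannot be determined (no time column, "
            "no dwell_time_s header)"
        )

    acquisition = None
    if "flow_mL_min" in meta:
        acquisition = AcquisitionConfig(
            sample_flow_rate_mL_min=float(meta["flow_mL_min"]),
            dwell_time_s=dwell,
            duration_s=len(counts) * dwell,
            element=meta.get("element", ""),
        )
    return TimeTrace(
        counts=np.asarray(counts, dtype=np.int64),
        dwell_time_s=dwell,
        element=meta.get("element", ""),
        acquisition=acquisition,
    )


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_trace(trace: TimeTrace, path) -> None:
    """Write a trace in the canonical CSV dialect; lossless round trip."""
    parts = []
    if trace.element:
        parts.append(f"element={trace.element}")
    parts.append(f"dwell_time_s={trace.dwell_time_s!r}")
    if trace.acquisition is not None:
        parts.append(f"flow_mL_min={trace.acquisition.sample_flow_rate_mL_min!r}")
    buf = io.StringIO()
    buf.write("# " + " ".join(parts) + "\n")
    buf.write("time_s,counts\n")
    dwell = trace.dwell_time_s
    for i, c in enumerate(trace.counts):
        buf.write(f"{i * dwell:.9g},{int(c)}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
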