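"""Separate single-cell ionisation events from background.

The detector follows the Poisson-statistics convention used throughout
SP/SC-ICP-MS: the background mean and standard deviation are estimated
iteratively, dwells whose counts exceed mean + k·SD (k = 3 by default) are
classified as single-cell events and removed, and the statistics are
re-estimated until no further dwell is removed.

Two deliberate conventions, both documented in the methods note:

* the comparison is *strictly* greater than the threshold, so a constant
  trace (SD = 0) yields no events rather than flagging every dwell;
* the background SD follows Poisson counting statistics, SD = sqrt(mean of
  the current background set) — shot noise is the model for detector
  counts, and it keeps the threshold meaningful when only a handful of
  background dwells remain.  ``sd_mode="sample"`` switches to the empirical
  sample standard deviation (n−1 denominator) instead; the two agree
  closely on genuinely Poisson backgrounds.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .trace_io import TimeTrace, TraceParseError

__all__ = [
    "BackgroundModel",
    "Event",
    "EventTable",
    "NoBackgroundError",
    "iterative_threshold",
    "extract_events",
    "max_intensity",
    "write_event_table",
    "read_event_table",
]

MAX_ITERATIONS = 1000


class NoBackgroundError(ValueError):
    """Raised when the iterative threshold leaves no usable background."""


@dataclass(frozen=True)
class BackgroundModel:
    """Converged background statistics for one trace.

    ``threshold_counts`` equals ``mean_counts + k_sigma * sd_counts`` by
    construction; ``background_indices`` lists the dwells classified as
    background in the final iteration.
    """

    mean_counts: float
    sd_counts: float
    threshold_counts: float
    k_sigma: float
    n_iterations: int
    background_indices: np.ndarray
    n_dwells_total: int
    sd_mode: str = "poisson"

    @property
    def n_background(self) -> int:
        return int(self.background_indices.size)


@dataclass(frozen=True)
class Event:
    """One detected single-cell ionisation event."""

    start_index: int
    n_dwells_spanned: int
    raw_counts_sum: int
    net_counts: float
    clipped: bool = False  # True when raw − span·background fell below 0


@dataclass
class EventTable:
    """Detected events plus the background model that produced them."""

    events: List[Event]
    background: BackgroundModel
    dwell_time_s: float
    element: str = ""

    @property
    def n_events(self) -> int:
        return len(self.events)

    def net_counts(self) -> np.ndarray:
        return np.array([e.net_counts for e in self.events], dtype=float)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "start_index": [e.start_index for e in self.events],
                "start_time_s": [
                    e.start_index * self.dwell_time_s for e in self.events
                ],
                "n_dwells": [e.n_dwells_spanned for e in self.events],
                "raw_counts": [e.raw_counts_sum for e in self.events],
                "net_counts": [e.net_counts for e in self.events],
            }
        )


def iterative_threshold(
    trace: TimeTrace,
    k_sigma: float = 3.0,
    sd_mode: str = "poisson",
    max_iterations: int = MAX_ITERATIONS,
) -> BackgroundModel:
    """Estimate the background by iterative mean + k·SD outlier rejection.

    Each iteration computes the mean of the current background set, takes
    SD = sqrt(mean) (``sd_mode="poisson"``, the default, treating the
    background as shot noise) or the sample SD (``sd_mode="sample"``), and
    removes every dwell strictly above mean + k·SD; it terminates when an
    iteration removes nothing.  Convergence is guaranteed because the
    background set shrinks monotonically; the iteration cap only guards
    pathological input and reaching it is an error.

    Raises
    ------
    NoBackgroundError
        If fewer than two background dwells remain.
    ValueError
        If the trace has fewer than 10 dwells or ``k_sigma <= 0``.
    """
    if trace.n_dwells < 10:
        raise ValueError("trace must have at least 10 dwells")
    if k_sigma <= 0:
        raise ValueError("k_sigma must be > 0")
    if sd_mode not in ("poisson", "sample"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    counts = trace.counts.astype(float)
    mask = np.ones(counts.size, dtype=bool)
    for iteration in range(1, max_iterations + 1):
        background = counts[mask]
        if background.size < 2:
            raise NoBackgroundError(
                "no background remains: fewer than 2 dwells below threshold"
            )
        mean = float(background.mean())
        if sd_mode == "poisson":
            sd = float(np.sqrt(mean))
        else:
            sd = float(background.std(ddof=1))
        threshold = mean + k_sigma * sd
        new_mask = mask & ~(counts > threshold)
        n_removed = int(mask.sum() - new_mask.sum())
        mask = new_mask
        if n_removed == 0:
            return BackgroundModel(
                mean_counts=mean,
                sd_counts=sd,
                threshold_counts=threshold,
                k_sigma=float(k_sigma),
                n_iterations=iteration,
                background_indices=np.nonzero(mask)[0],
                n_dwells_total=counts.size,
                sd_mode=sd_mode,
            )
    raise NoBackgroundError(
        f"iterative threshold failed to converge in {max_iterations} iterations"
    )


def extract_events(
    trace: TimeTrace,
    background: BackgroundModel,
    merge_gap: int = 0,
) -> EventTable:
    """Group above-threshold dwells into events and integrate net counts.

    A maximal run of above-threshold dwells — allowing up to ``merge_gap``
    consecutive below-threshold dwells inside the run — becomes one event.
    Net counts are the raw sum over the spanned dwells minus the expected
    background contribution (span × background mean), clipped at zero.
    """
    if background.n_dwells_total != trace.n_dwells:
        raise ValueError(
            "background model was fit on a trace of different length"
        )
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    counts = trace.counts
    above = counts > background.threshold_counts
    events: List[Event] = []
    idx = np.nonzero(above)[0]
    if idx.size:
        # split indices into runs where gaps exceed merge_gap + 1
        breaks = np.nonzero(np.diff(idx) > merge_gap + 1)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        for s, e in zip(starts, ends):
            lo, hi = int(idx[s]), int(idx[e])
            span = hi - lo + 1
            raw = int(counts[lo : hi + 1].sum())
            net = raw - span * background.mean_counts
            clipped = net < 0
            events.append(
                Event(
                    start_index=lo,
                    n_dwells_spanned=span,
                    raw_counts_sum=raw,
                    net_counts=max(net, 0.0),
                    clipped=clipped,
                )
            )
    return EventTable(
        events=events,
        background=background,
        dwell_time_s=trace.dwell_time_s,
        element=trace.element,
    )


def detect_events(
    trace: TimeTrace, k_sigma: float = 3.0, merge_gap: int = 0
) -> EventTable:
    """Convenience: iterative_threshold followed by extract_events."""
    return extract_events(trace, iterative_threshold(trace, k_sigma), merge_gap)


def max_intensity(trace: TimeTrace) -> int:
    """Maximum per-dwell count of the trace."""
    if trace.n_dwells == 0:
        raise ValueError("empty trace has no maximum intensity")
    return int(trace.counts.max())


def write_event_table(table: EventTable, path) -> None:
    """Write events as CSV with the background model embedded in the header."""
    bg = table.background
    buf = io.StringIO()
    buf.write(
        "# "
        f"background_mean={bg.mean_counts!r} background_sd={bg.sd_counts!r} "
        f"threshold={bg.threshold_counts!r} k_sigma={bg.k_sigma!r} "
        f"iterations={bg.n_iterations} dwell_time_s={table.dwell_time_s!r} "
        f"n_dwells_total={bg.n_dwells_total}"
    )
    if table.element:
        buf.write(f" element={table.element}")
    buf.write("\n")
    buf.write("start_index,start_time_s,n_dwells,raw_counts,net_counts\n")
    for e in table.events:
        buf.write(
            f"{e.start_index},{e.start_index * table.dwell_time_s:.9g},"
            f"{e.n_dwells_spanned},{e.raw_counts_sum},{e.net_counts!r}\n"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_event_table(path) -> EventTable:
    """Read an event-table CSV written by :func:`write_event_table`."""
    meta: dict = {}
    events: List[Event] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line.lstrip("#").split():
                    if "=" in token:
                        key, _, value = token.partition("=")
                        meta[key] = value
                continue
            if line.startswith("start_index"):
                continue
            fields = line.split(",")
            if len(fields) != 5:
                raise TraceParseError(
                    f"{path}: malformed event row at line {lineno}"
                )
            events.append(
                Event(
                    start_index=int(fields[0]),
                    n_dwells_spanned=int(fields[2]),
                    raw_counts_sum=int(fields[3]),
                    net_counts=float(fields[4]),
                )
            )
    required = {"background_mean", "background_sd", "threshold", "k_sigma"}
    if not required.issubset(meta):
        raise TraceParseError(f"{path}: missing background header fields")
    background = BackgroundModel(
        mean_counts=float(meta["background_mean"]),
        sd_counts=float(meta["background_sd"]),
        threshold_counts=float(meta["threshold"]),
        k_sigma=float(meta["k_sigma"]),
        n_iterations=int(meta.get("iterations", 1)),
        background_indices=np.array([], dtype=int),
        n_dwells_total=int(meta.get("n_dwells_total", 0)),
    )
    return EventTable(
        events=events,
        background=background,
        dwell_time_s=float(meta.get("dwell_time_s", 0.003)),
        element=meta.get("element", ""),
    )
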