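"""Mass quantification: calibration, per-cell masses, detection limits.

Dissolved calibration standards (ng/L vs counts per dwell, internal-standard
corrected) give the instrument sensitivity S.  A detected event's net counts
convert to element mass per cell as

    m_cell = net_counts × Q × t_dwell × TE / S

with Q in L/s, t_dwell in s and the result converted to fg; intuitively,
S/(Q·t_dwell·TE) is the detector response in counts per unit of mass that
actually reaches the plasma, and a detected cell delivers its whole mass.

Limits of detection follow the 3σ convention: 3 × SD(blank)/S for dissolved
concentrations, and the mass equivalent of k·SD(background) net counts for
single-cell events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .event_detection import BackgroundModel, EventTable
from .trace_io import AcquisitionConfig
from .transport_efficiency import TransportEfficiency
from .units import FG_PER_NG, flow_L_per_s

__all__ = [
    "CalibrationCurve",
    "CellMassSample",
    "fit_calibration",
    "read_calibration_csv",
    "mass_per_event",
    "dissolved_lod",
    "event_mass_lod",
    "quantify_events",
    "write_masses",
    "read_masses",
    "bulk_mass_per_cell",
    "bulk_vs_sc_relative_error",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Dissolved-standard response: counts per dwell vs concentration (ng/L)."""

    slope: float  # counts per (ng/L) per dwell
    intercept: float
    r_squared: float
    standards: tuple = ()
    conc_range_ng_L: Tuple[float, float] = (0.0, 0.0)
    internal_standard: Optional[str] = None
    element: str = ""

    def conc_from_counts(self, counts: float) -> float:
        """Invert the curve; extrapolation outside the standards is the
        caller's responsibility (see :meth:`in_range`)."""
        return (counts - self.intercept) / self.slope

    def in_range(self, conc_ng_L: float) -> bool:
        lo, hi = self.conc_range_ng_L
        return lo <= conc_ng_L <= hi


@dataclass
class CellMassSample:
    """Per-cell element masses (fg) for one population.

    ``masses_fg`` holds the quantifiable cells; cells whose events fell
    below the single-cell mass LOD are counted in ``n_below_lod`` but not
    imputed.  ``len(masses_fg) + n_below_lod`` equals the total number of
    detected events.
    """

    masses_fg: np.ndarray
    n_below_lod: int = 0
    element: str = ""
    te_used: Optional[TransportEfficiency] = None
    calibration_used: Optional[CalibrationCurve] = None
    acq_used: Optional[AcquisitionConfig] = None
    lod_fg: Optional[float] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.masses_fg, dtype=float)
        if arr.size and arr.min() < 0:
            raise ValueError("masses must be non-negative")
        self.masses_fg = arr

    @property
    def n_cells(self) -> int:
        return int(self.masses_fg.size)

    @property
    def n_events_total(self) -> int:
        return self.n_cells + self.n_below_lod


def fit_calibration(
    standards: Sequence[tuple],
    internal_standard: Optional[str] = None,
    element: str = "",
) -> CalibrationCurve:
    """Ordinary least squares of (IS-corrected) counts vs concentration.

    ``standards`` rows are ``(conc_ng_L, analyte_counts)`` or
    ``(conc_ng_L, analyte_counts, is_counts)``.  When internal-standard
    counts are present, analyte counts are divided by (IS / mean IS across
    the run) before fitting — a ratio drift correction that is a no-op when
    the IS channel is constant.  At least three standards (including a
    blank or low point) are required.
    """
    if len(standards) < 3:
        raise ValueError("need at least 3 calibration standards")
    conc = np.array([row[0] for row in standards], dtype=float)
    counts = np.array([row[1] for row in standards], dtype=float)
    has_is = all(len(row) >= 3 and row[2] is not None for row in standards)
    if has_is:
        is_counts = np.array([row[2] for row in standards], dtype=float)
        if np.any(is_counts <= 0):
            raise ValueError("internal-standard counts must be > 0")
        counts = counts / (is_counts / is_counts.mean())
    fit = stats.linregress(conc, counts)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        standards=tuple(tuple(row) for row in standards),
        conc_range_ng_L=(float(conc.min()), float(conc.max())),
        internal_standard=internal_standard if has_is else None,
        element=element,
    )


def read_calibration_csv(
    path, internal_standard: Optional[str] = None, element: str = ""
) -> CalibrationCurve:
    """Fit a calibration from a ``conc_ng_L,counts[,is_counts]`` CSV."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    if "conc_ng_L" not in df.columns or "counts" not in df.columns:
        raise ValueError(f"{path}: need columns conc_ng_L,counts[,is_counts]")
    if "is_counts" in df.columns and df["is_counts"].notna().all():
        rows = list(zip(df["conc_ng_L"], df["counts"], df["is_counts"]))
    else:
        rows = list(zip(df["conc_ng_L"], df["counts"]))
    return fit_calibration(rows, internal_standard=internal_standard, element=element)


def mass_per_event(
    net_counts: Union[float, np.ndarray],
    cal: CalibrationCurve,
    te: TransportEfficiency,
    acq: AcquisitionConfig,
):
    """Convert net event counts to element mass per cell, in fg."""
    if te.value <= 0:
        raise ValueError("cannot quantify without transport efficiency (TE = 0)")
    if cal.slope <= 0:
        raise ValueError("calibration slope must be > 0")
    q_l_s = flow_L_per_s(acq.sample_flow_rate_mL_min)
    mass_ng = (
        np.asarray(net_counts, dtype=float)
        * q_l_s
        * acq.dwell_time_s
        * te.value
        / cal.slope
    )
    mass_fg = mass_ng * FG_PER_NG
    if np.isscalar(net_counts):
        return float(mass_fg)
    return mass_fg


def dissolved_lod(
    blank_counts: Sequence[float], cal: CalibrationCurve
) -> float:
    """Dissolved limit of detection: 3 × SD(blank replicates) / slope, ng/L."""
    blanks = np.asarray(blank_counts, dtype=float)
    if blanks.size < 3:
        raise ValueError("need at least 3 blank replicates")
    if cal.slope <= 0:
        raise ValueError("calibration slope must be > 0")
    return 3.0 * float(blanks.std(ddof=1)) / cal.slope


def event_mass_lod(
    background: BackgroundModel,
    cal: CalibrationCurve,
    te: TransportEfficiency,
    acq: AcquisitionConfig,
) -> float:
    """Smallest detectable per-cell mass (fg) under the detection threshold.

    An event is detectable when its net counts exceed k·SD of the
    background, so that count level converted to mass is the single-cell
    mass LOD.
    """
    return float(
        mass_per_event(
            background.k_sigma * background.sd_counts, cal, te, acq
        )
    )


def quantify_events(
    events: EventTable,
    cal: CalibrationCurve,
    te: TransportEfficiency,
    acq: AcquisitionConfig,
    lod_fg: Optional[float] = None,
    element: str = "",
) -> CellMassSample:
    """Quantify every detected event; split at the single-cell mass LOD.

    When ``lod_fg`` is not given it is derived from the event table's own
    background model via :func:`event_mass_lod`.
    """
    masses = mass_per_event(events.net_counts(), cal, te, acq)
    if lod_fg is None:
        lod_fg = event_mass_lod(events.background, cal, te, acq)
    below = masses < lod_fg
    return CellMassSample(
        masses_fg=masses[~below],
        n_below_lod=int(below.sum()),
        element=element or events.element,
        te_used=te,
        calibration_used=cal,
        acq_used=acq,
        lod_fg=float(lod_fg),
    )


def write_masses(sample: CellMassSample, path) -> None:
    """Write per-cell masses as ``event_id,mass_fg,below_lod`` CSV.

    Below-LOD events have no stored mass; they are emitted as trailing rows
    with an empty mass field so the event accounting round-trips.
    """
    with open(path, "w", encoding="utf-8") as fh:
        header = f"# element={sample.element}" if sample.element else "#"
        if sample.lod_fg is not None:
            header += f" lod_fg={sample.lod_fg!r}"
        fh.write(header + "\n")
        fh.write("event_id,mass_fg,below_lod\n")
        for i, m in enumerate(sample.masses_fg):
            fh.write(f"{i},{float(m)!r},0\n")
        for j in range(sample.n_below_lod):
            fh.write(f"{sample.n_cells + j},,1\n")


def read_masses(path) -> CellMassSample:
    """Read a per-cell mass CSV written by :func:`write_masses`."""
    masses: List[float] = []
    n_below = 0
    element = ""
    lod_fg = None
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("event_id"):
                continue
            if line.startswith("#"):
                for token in line.lstrip("#").split():
                    key, _, value = token.partition("=")
                    if key == "element":
                        element = value
                    elif key == "lod_fg":
                        lod_fg = float(value)
                continue
            fields = line.split(",")
            if len(fields) != 3:
                raise ValueError(f"{path}: malformed mass row {line!r}")
            if fields[2].strip() == "1":
                n_below += 1
            else:
                masses.append(float(fields[1]))
    return CellMassSample(
        masses_fg=np.asarray(masses, dtype=float),
        n_below_lod=n_below,
        element=element,
        lod_fg=lod_fg,
    )


def bulk_mass_per_cell(
    measured_conc_ng_L: float,
    digest_volume_L: float,
    dilution_factor: float,
    n_cells: float,
) -> float:
    """Average mass per cell (fg) from a bulk acid digest of a counted pellet."""
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    if measured_conc_ng_L < 0:
        raise ValueError("measured concentration must be >= 0")
    if digest_volume_L <= 0 or dilution_factor <= 0:
        raise ValueError("digest volume and dilution factor must be > 0")
    mass_ng = measured_conc_ng_L * digest_volume_L * dilution_factor
    return mass_ng * FG_PER_NG / n_cells


def bulk_vs_sc_relative_error(bulk_fg: float, sc_mean_fg: float) -> float:
    """Relative error (%) of the single-cell mean against the bulk value.

    Positive when the bulk digest reads higher than the single-cell mean —
    the signature of extracellular debris inflating the bulk channel.
    """
    if bulk_fg <= 0:
        raise ValueError("bulk mass must be > 0")
    return 100.0 * (bulk_fg - sc_mean_fg) / bulk_fg
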