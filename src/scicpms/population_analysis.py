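"""Population heterogeneity of per-cell mass distributions.

Per-cell element masses are right-skewed and compared between populations
(e.g. infected vs uninfected macrophages) via normalised kernel-density
curves, robust summary statistics, and a seeded bootstrap on the median
difference and CV ratio.  Cells below the single-cell mass LOD are excluded
from densities but always reported as a fraction — no imputation.

Also here: the sample-preparation QC rules — percentage reduction in peak
counts between fixation conditions, cell recovery against a 70% threshold,
and the ±1 SD count-stability rule.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .quantification import CellMassSample

__all__ = [
    "DensityCurve",
    "HeterogeneitySummary",
    "probability_density",
    "heterogeneity_summary",
    "compare_populations",
    "peak_reduction_pct",
    "cell_recovery_pct",
    "count_stability",
]


@dataclass(frozen=True)
class DensityCurve:
    """A smoothed relative-probability curve over per-cell mass."""

    grid_fg: np.ndarray
    density: np.ndarray
    bandwidth_fg: float
    normalisation: str  # "area_one" or "max_one"

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid_fg))


@dataclass(frozen=True)
class HeterogeneitySummary:
    n_cells: int
    median_fg: float
    mean_fg: float
    sd_fg: float
    cv: float
    iqr_fg: float
    q05_fg: float
    q95_fg: float
    frac_below_lod: float

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "median_fg": self.median_fg,
            "mean_fg": self.mean_fg,
            "sd_fg": self.sd_fg,
            "cv": self.cv,
            "iqr_fg": self.iqr_fg,
            "q05_fg": self.q05_fg,
            "q95_fg": self.q95_fg,
            "frac_below_lod": self.frac_below_lod,
        }


def _masses(sample: Union[CellMassSample, Sequence[float]]) -> np.ndarray:
    if isinstance(sample, CellMassSample):
        return np.asarray(sample.masses_fg, dtype=float)
    return np.asarray(sample, dtype=float)


def probability_density(
    sample: Union[CellMassSample, Sequence[float]],
    bandwidth: Optional[float] = None,
    normalisation: str = "area_one",
    n_grid: int = 512,
) -> DensityCurve:
    """Gaussian-kernel density of above-LOD masses on [0, 1.1 × max mass].

    ``bandwidth`` is in fg; when omitted, Silverman's rule is applied to the
    above-LOD masses.  ``area_one`` rescales so the trapezoid integral over
    the grid is 1; ``max_one`` rescales the peak to 1.
    """
    if normalisation not in ("area_one", "max_one"):
        raise ValueError(f"unknown normalisation {normalisation!r}")
    masses = _masses(sample)
    if masses.size < 5:
        raise ValueError("insufficient cells for density (need >= 5 above LOD)")
    hi = float(masses.max()) * 1.1
    if hi <= 0:
        hi = 1.0
    grid = np.linspace(0.0, hi, n_grid)
    sd = float(masses.std(ddof=1))
    if sd == 0.0:
        # degenerate sample: all masses identical; a narrow Gaussian bump
        bw = bandwidth if bandwidth is not None else max(0.01 * masses[0], 1e-6)
        density = np.exp(-0.5 * ((grid - masses[0]) / bw) ** 2) / (
            bw * math.sqrt(2.0 * math.pi)
        )
    else:
        if bandwidth is not None:
            if bandwidth <= 0:
                raise ValueError("bandwidth must be > 0")
            kde = stats.gaussian_kde(masses, bw_method=bandwidth / sd)
            bw = bandwidth
        else:
            kde = stats.gaussian_kde(masses, bw_method="silverman")
            bw = float(kde.factor) * sd
        density = kde(grid)
    density = np.clip(density, 0.0, None)
    if normalisation == "area_one":
        area = np.trapezoid(density, grid)
        if area > 0:
            density = density / area
    else:
        peak = density.max()
        if peak > 0:
            density = density / peak
    return DensityCurve(
        grid_fg=grid, density=density, bandwidth_fg=bw, normalisation=normalisation
    )


def heterogeneity_summary(
    sample: Union[CellMassSample, Sequence[float]]
) -> HeterogeneitySummary:
    """Summary statistics of one per-cell mass sample."""
    masses = _masses(sample)
    if masses.size < 2:
        raise ValueError("need at least 2 masses for a heterogeneity summary")
    n_below = sample.n_below_lod if isinstance(sample, CellMassSample) else 0
    mean = float(masses.mean())
    sd = float(masses.std(ddof=1))
    q05, q25, med, q75, q95 = np.quantile(masses, [0.05, 0.25, 0.5, 0.75, 0.95])
    total = masses.size + n_below
    return HeterogeneitySummary(
        n_cells=int(masses.size),
        median_fg=float(med),
        mean_fg=mean,
        sd_fg=sd,
        cv=sd / mean if mean > 0 else float("nan"),
        iqr_fg=float(q75 - q25),
        q05_fg=float(q05),
        q95_fg=float(q95),
        frac_below_lod=n_below / total if total else 0.0,
    )


def compare_populations(
    a: Union[CellMassSample, Sequence[float]],
    b: Union[CellMassSample, Sequence[float]],
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Divergence report between two per-cell mass samples.

    Combines the two-sample Kolmogorov–Smirnov statistic with percentile
    bootstrap 95% CIs on the median difference (b − a) and CV ratio (b / a);
    fully deterministic under a fixed seed.
    """
    xa = _masses(a)
    xb = _masses(b)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both samples must be non-empty")
    report_warnings = []
    if n_boot < 100:
        report_warnings.append(
            f"n_boot={n_boot} < 100: bootstrap CIs will be unreliable"
        )
    ks = stats.ks_2samp(xa, xb, method="asymp")
    rng = np.random.default_rng(seed)
    med_diffs = np.empty(n_boot)
    cv_ratios = np.empty(n_boot)
    for i in range(n_boot):
        ra = rng.choice(xa, size=xa.size, replace=True)
        rb = rng.choice(xb, size=xb.size, replace=True)
        med_diffs[i] = np.median(rb) - np.median(ra)
        cv_a = ra.std(ddof=1) / ra.mean() if ra.mean() > 0 else np.nan
        cv_b = rb.std(ddof=1) / rb.mean() if rb.mean() > 0 else np.nan
        cv_ratios[i] = cv_b / cv_a if cv_a and np.isfinite(cv_a) else np.nan
    med_lo, med_hi = np.nanquantile(med_diffs, [0.025, 0.975])
    cv_lo, cv_hi = np.nanquantile(cv_ratios, [0.025, 0.975])
    summary_a = heterogeneity_summary(a) if xa.size >= 2 else None
    summary_b = heterogeneity_summary(b) if xb.size >= 2 else None
    return {
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "median_difference_fg": float(np.median(xb) - np.median(xa)),
        "median_difference_ci95": [float(med_lo), float(med_hi)],
        "cv_ratio": (
            float((xb.std(ddof=1) / xb.mean()) / (xa.std(ddof=1) / xa.mean()))
            if xa.size >= 2 and xb.size >= 2 and xa.mean() > 0 and xb.mean() > 0
            else None
        ),
        "cv_ratio_ci95": [float(cv_lo), float(cv_hi)],
        "n_boot": n_boot,
        "seed": seed,
        "summary_a": summary_a.to_dict() if summary_a else None,
        "summary_b": summary_b.to_dict() if summary_b else None,
        "warnings": report_warnings,
    }


def peak_reduction_pct(n_reference: float, n_condition: float) -> float:
    """Percentage reduction in detected peak count relative to a reference.

    Negative values indicate a gain over the reference, by convention.
    """
    if n_reference <= 0:
        raise ValueError("reference peak count must be > 0")
    return 100.0 * (n_reference - n_condition) / n_reference


def cell_recovery_pct(
    count_before: float, count_after: float, threshold_pct: float = 70.0
) -> tuple:
    """Cell recovery (%) across a preparation step, with pass/fail flag."""
    if count_before <= 0:
        raise ValueError("before-count must be > 0")
    recovery = 100.0 * count_after / count_before
    return recovery, recovery >= threshold_pct


def count_stability(
    baseline: Sequence[float], later: Sequence[float]
) -> bool:
    """Stability rule: later mean within ±1 SD (of baseline replicates)."""
    base = np.asarray(baseline, dtype=float)
    if base.size < 2:
        raise ValueError("need >= 2 baseline replicates (SD undefined)")
    lat = np.asarray(later, dtype=float)
    if lat.size < 1:
        raise ValueError("need >= 1 later replicate")
    return abs(float(lat.mean()) - float(base.mean())) <= float(base.std(ddof=1))
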