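"""Radiocarbon calibration, summed probability distributions, and the
chronological sampling protocols.

A calibration curve maps calendar age (ka BP) to a conventional radiocarbon
age with a per-point curve error.  A lab date (14C age +/- error) is
calibrated by scoring every calendar age on the curve grid with the normal
density of the measured age around the interpolated curve mean, with
variance equal to the sum of squared lab and curve errors, then normalizing
(trapezoid rule).  Per-locale dates are combined into summed probability
distributions (SPDs); point ages are SPD medians and age uncertainty is the
68.27% highest-density region of the SPD.

All ages are carried in ka BP; the climate bins (GS-2, GI-1, GS-1,
Holocene) are bounded at 14.6, 12.9 and 11.7 ka BP, each boundary belonging
to the older bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "CalCurve",
    "CalDensity",
    "DatedSample",
    "CLIMATE_BOUNDARIES",
    "CLIMATE_BINS",
    "calibrate",
    "spd",
    "median_age",
    "sigma_range",
    "scale_age",
    "assign_bin",
    "sample_one_per_locale",
    "stratified_subsample",
]

CLIMATE_BOUNDARIES = (14.6, 12.9, 11.7)
CLIMATE_BINS = ("GS-2", "GI-1", "GS-1", "Holocene")
ONE_SIGMA = 0.6827


@dataclass
class CalCurve:
    """Calibration curve on an ascending calendar-age grid (ka BP)."""

    grid: np.ndarray
    c14_mean: np.ndarray
    c14_error: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.c14_mean = np.asarray(self.c14_mean, dtype=float)
        self.c14_error = np.asarray(self.c14_error, dtype=float)
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("curve grid must be strictly increasing")
        if np.any(self.c14_error <= 0):
            raise ValueError("curve errors must be positive")

    def mean_at(self, age):
        return np.interp(age, self.grid, self.c14_mean)

    def error_at(self, age):
        return np.interp(age, self.grid, self.c14_error)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.grid[0]), float(self.grid[-1])

    # -- IntCal-layout CSV (years BP in the file, ka BP in memory) ---------
    @classmethod
    def from_csv(cls, path) -> "CalCurve":
        df = pd.read_csv(path, comment="#")
        df = df.sort_values(df.columns[0])
        return cls(df.iloc[:, 0].to_numpy() / 1000.0,
                   df.iloc[:, 1].to_numpy() / 1000.0,
                   df.iloc[:, 2].to_numpy() / 1000.0)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "calBP": np.round(self.grid * 1000.0, 3),
            "c14BP": np.round(self.c14_mean * 1000.0, 3),
            "error": np.round(self.c14_error * 1000.0, 3),
        }).to_csv(path, index=False)


@dataclass
class CalDensity:
    """A normalized density over calendar ages (trapezoid rule)."""

    grid: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.shape != self.density.shape:
            raise ValueError("grid and density must have equal shape")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        mass = np.trapezoid(self.density, self.grid)
        if not np.isclose(mass, 1.0, atol=1e-6):
            raise ValueError(f"density integrates to {mass}, not 1")


@dataclass
class DatedSample:
    """A taxon with its point age and one-sigma age interval (ka BP)."""

    taxon_id: str
    locale_id: str
    median_age: float
    age_min: float
    age_max: float
    bin: str = ""

    def __post_init__(self):
        if not self.age_min <= self.median_age <= self.age_max:
            raise ValueError("age_min <= median_age <= age_max violated")
        if not self.bin:
            self.bin = assign_bin(self.median_age)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate(c14_age: float, c14_err: float, curve: CalCurve) -> CalDensity:
    """Calibrated density of one lab date over the curve grid."""
    sd = np.sqrt(c14_err ** 2 + curve.c14_error ** 2)
    z = (c14_age - curve.c14_mean) / sd
    raw = np.exp(-0.5 * z * z) / (sd * np.sqrt(2.0 * np.pi))
    mass = np.trapezoid(raw, curve.grid)
    if mass <= 0.0 or not np.isfinite(mass):
        raise ValueError(
            f"date {c14_age} +/- {c14_err} has no mass on the curve grid")
    return CalDensity(curve.grid, raw / mass)


def spd(densities: Sequence[CalDensity]) -> CalDensity:
    """Summed probability distribution: pointwise sum, renormalized."""
    if len(densities) == 0:
        raise ValueError("cannot sum an empty list of densities")
    grid = densities[0].grid
    for d in densities[1:]:
        if d.grid.shape != grid.shape or not np.allclose(d.grid, grid):
            raise ValueError("densities must share a grid")
    total = np.sum([d.density for d in densities], axis=0)
    return CalDensity(grid, total / np.trapezoid(total, grid))


def median_age(d: CalDensity) -> float:
    """Age at which the cumulative mass first reaches one half."""
    dx = np.diff(d.grid)
    seg = 0.5 * (d.density[:-1] + d.density[1:]) * dx
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    cum /= cum[-1]
    i = int(np.searchsorted(cum, 0.5))
    if i == 0:
        return float(d.grid[0])
    frac = (0.5 - cum[i - 1]) / (cum[i] - cum[i - 1])
    return float(d.grid[i - 1] + frac * dx[i - 1])


def sigma_range(d: CalDensity, level: float = ONE_SIGMA,
                method: str = "hpd") -> tuple[float, float]:
    """Envelope (min, max) of the smallest region holding ``level`` mass.

    ``method="hpd"`` collects grid points in order of decreasing density
    (highest-density region); ``method="central"`` returns the central
    interval between the (1-level)/2 and (1+level)/2 quantiles.
    """
    if method == "central":
        lo = _quantile(d, (1.0 - level) / 2.0)
        hi = _quantile(d, (1.0 + level) / 2.0)
        return lo, hi
    if method != "hpd":
        raise ValueError(f"unknown method {method!r}")
    w = _grid_weights(d.grid)
    mass = d.density * w
    order = np.argsort(d.density)[::-1]
    cum = np.cumsum(mass[order])
    take = order[: int(np.searchsorted(cum, level * cum[-1])) + 1]
    return float(d.grid[take].min()), float(d.grid[take].max())


def _grid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.empty_like(grid)
    w[1:-1] = (grid[2:] - grid[:-2]) / 2.0
    w[0] = (grid[1] - grid[0]) / 2.0
    w[-1] = (grid[-1] - grid[-2]) / 2.0
    return w


def _quantile(d: CalDensity, q: float) -> float:
    dx = np.diff(d.grid)
    seg = 0.5 * (d.density[:-1] + d.density[1:]) * dx
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    cum /= cum[-1]
    i = int(np.searchsorted(cum, q))
    if i == 0:
        return float(d.grid[0])
    if i >= len(cum):
        return float(d.grid[-1])
    frac = (q - cum[i - 1]) / (cum[i] - cum[i - 1])
    return float(d.grid[i - 1] + frac * dx[i - 1])


# ---------------------------------------------------------------------------
# age scaling and binning
# ---------------------------------------------------------------------------

def scale_age(age_bp: float) -> float:
    """Years BP -> ka BP, rounded half-even to three decimals."""
    if age_bp < 0:
        raise ValueError("ages must be non-negative")
    return float(np.round(age_bp / 1000.0, 3))


def assign_bin(age_ka: float,
               boundaries: Sequence[float] = CLIMATE_BOUNDARIES,
               labels: Sequence[str] = CLIMATE_BINS) -> str:
    """Climate bin of an age; a boundary belongs to the older bin."""
    b = np.asarray(boundaries, dtype=float)
    if not np.all(np.diff(b) < 0):
        raise ValueError("boundaries must be strictly decreasing")
    return labels[int(np.sum(age_ka < b))]


# ---------------------------------------------------------------------------
# sampling protocols
# ---------------------------------------------------------------------------

def sample_one_per_locale(records: pd.DataFrame, seed: int) -> pd.DataFrame:
    """One uniformly chosen specimen per unique locale (deterministic).

    This mirrors the Poisson-sampling assumption of the FBD process: a
    lineage is sampled at most once at any one time point, so co-located
    specimens reduce to a single representative.
    """
    if len(records) == 0:
        raise ValueError("no records to sample from")
    if "locale_id" not in records.columns:
        raise ValueError("records need a locale_id column")
    rng = np.random.default_rng(seed)
    parts = []
    for _, group in records.groupby("locale_id", sort=True):
        parts.append(group.iloc[int(rng.integers(0, len(group)))])
    return pd.DataFrame(parts).reset_index(drop=True)


def stratified_subsample(samples: Sequence[DatedSample], per_bin: int,
                         seed: int) -> list[DatedSample]:
    """Up to ``per_bin`` samples uniformly chosen per climate bin.

    Subsets at increasing ``per_bin`` are nested for a fixed seed: each
    bin's members are shuffled once and prefixes are taken.
    """
    if per_bin < 1:
        raise ValueError("per_bin must be at least 1")
    rng = np.random.default_rng(seed)
    out: list[DatedSample] = []
    for label in CLIMATE_BINS:
        members = [s for s in samples if s.bin == label]
        if not members:
            warnings.warn(f"climate bin {label} has no samples")
            continue
        perm = rng.permutation(len(members))
        out.extend(members[i] for i in perm[:per_bin])
    return out
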