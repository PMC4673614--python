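"""Morphometric summary statistics of a tumor lattice state.

Covers phenotype counts and fractions, the angular front profile (per-bin
maximum living-cell radius about the founding grid), mean front radius and
its growth velocity, global surface roughness (population standard deviation
of the binned front radii), and per-sector radial distribution functions of
the living cells.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .world import WorldState

__all__ = [
    "MetricError",
    "FrontProfile",
    "TimeSeriesRecord",
    "phenotype_counts",
    "front_profile",
    "mean_front_radius",
    "surface_roughness",
    "fit_slope",
    "radial_distribution",
    "summarize_state",
    "records_to_frame",
    "write_timeseries",
    "write_rdf",
]


class MetricError(ValueError):
    """A statistic's precondition is not met (e.g. no living cells)."""


@dataclasses.dataclass
class FrontProfile:
    """Tumor front described in polar bins around the founding grid.

    ``front_radius[j]`` is the maximum radial distance (grids, Euclidean)
    over living-cell grids whose angle falls in bin ``j``; ``occupied[j]``
    flags bins that contain at least one living-cell grid — empty bins are
    excluded from all downstream statistics, not interpolated.
    """

    bin_angle: np.ndarray
    front_radius: np.ndarray
    occupied: np.ndarray

    def radii(self) -> np.ndarray:
        """Front radii of the occupied bins only."""
        return self.front_radius[self.occupied]


@dataclasses.dataclass
class TimeSeriesRecord:
    """One per-cycle row of the growth time series."""

    t: int
    n_prolif: int
    n_invasive: int
    n_necrotic: int
    frac_prolif: float
    frac_invasive: float
    frac_necrotic: float
    mean_front_radius: float
    roughness: float


def phenotype_counts(state: WorldState) -> tuple[dict, dict]:
    """Total counts and fractions by phenotype; fractions sum to 1."""
    counts = {
        "proliferative": int(state.n_prolif.sum()),
        "invasive": int(state.n_invasive.sum()),
        "necrotic": int(state.n_necrotic.sum()),
    }
    total = sum(counts.values())
    if total > 0:
        fractions = {k: v / total for k, v in counts.items()}
    else:
        fractions = {k: math.nan for k in counts}
    return counts, fractions


def _living_polar(state: WorldState) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(angle in [0, 2pi), radius, per-grid living count) of living-cell grids."""
    living = state.living_total()
    rows, cols = np.nonzero(living)
    if rows.size == 0:
        raise MetricError("state has no living cells")
    c = (state.shape[0] - 1) // 2
    dy = rows - c
    dx = cols - c
    angle = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    radius = np.hypot(dy, dx)
    return angle, radius, living[rows, cols]


def front_profile(state: WorldState, n_bins: int = 360) -> FrontProfile:
    """Per-angular-bin maximum living-cell radius about the central grid."""
    if n_bins < 1:
        raise MetricError("n_bins must be >= 1")
    angle, radius, _ = _living_polar(state)
    idx = np.minimum((angle * n_bins / (2.0 * np.pi)).astype(np.int64), n_bins - 1)
    front = np.zeros(n_bins)
    occupied = np.zeros(n_bins, dtype=bool)
    np.maximum.at(front, idx, radius)
    occupied[idx] = True
    centers = (np.arange(n_bins) + 0.5) * (2.0 * np.pi / n_bins)
    return FrontProfile(bin_angle=centers, front_radius=front, occupied=occupied)


def mean_front_radius(profile: FrontProfile) -> float:
    """Arithmetic mean of the occupied bins' front radii."""
    r = profile.radii()
    if r.size < 1:
        raise MetricError("front profile has no occupied bins")
    return float(r.mean())


def surface_roughness(profile: FrontProfile) -> float:
    """Population standard deviation of the occupied bins' front radii.

    ``sqrt((1/N_r) * sum (r_i - <r>)^2)`` — the global surface roughness
    R(t) of the growth front.
    """
    r = profile.radii()
    if r.size < 2:
        raise MetricError("surface roughness needs >= 2 occupied bins")
    return float(r.std())


def fit_slope(t: Sequence[float], y: Sequence[float], burn_in: float = 0.0) -> float:
    """Ordinary-least-squares slope of y(t) for ``t >= burn_in``.

    Non-finite y values are dropped.  Used for both the front growth
    velocity v (on the mean front radius) and the roughness velocity v_r
    (on R(t)); invariant to shifting t by a constant.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape:
        raise MetricError("t and y must have equal length")
    keep = (t >= burn_in) & np.isfinite(y)
    if keep.sum() < 2:
        raise MetricError("need >= 2 points after burn-in for a slope fit")
    return float(np.polyfit(t[keep], y[keep], 1)[0])


def radial_distribution(
    state: WorldState, sector: int, bin_width: float = 2.0
) -> pd.DataFrame:
    """Radial distribution function g(r) of living cells in one quadrant.

    Sector ``k`` (1..4) covers angles ``[(k-1)*pi/2, k*pi/2)``.  With
    ``n(r)`` the number of living cells at radial distance in
    ``[r, r + bin_width)`` and ``N_s`` the sector's living-cell total,
    ``g(r) = n(r) / (N_s * bin_width)`` — a probability density over the
    radial coordinate: ``sum g * bin_width = 1``.

    Returns a table with columns ``r_bin_low`` and ``g``.
    """
    if sector not in (1, 2, 3, 4):
        raise MetricError("sector must be 1, 2, 3 or 4")
    if bin_width <= 0:
        raise MetricError("bin_width must be positive")
    angle, radius, weight = _living_polar(state)
    lo = (sector - 1) * np.pi / 2.0
    hi = sector * np.pi / 2.0
    sel = (angle >= lo) & (angle < hi)
    n_s = weight[sel].sum()
    if n_s == 0:
        raise MetricError(f"sector {sector} contains no living cells")
    r = radius[sel]
    edges = np.arange(0.0, r.max() + 2.0 * bin_width, bin_width)
    hist, _ = np.histogram(r, bins=edges, weights=weight[sel].astype(float))
    g = hist / (n_s * bin_width)
    return pd.DataFrame({"r_bin_low": edges[:-1], "g": g})


def summarize_state(state: WorldState, n_bins: int = 360) -> TimeSeriesRecord:
    """One time-series row; front statistics are NaN when undefined.

    Mean front radius needs at least one living cell, roughness at least two
    occupied angular bins (the t=0 founder yields radius 0, roughness NaN).
    """
    counts, fractions = phenotype_counts(state)
    radius = math.nan
    rough = math.nan
    if counts["proliferative"] + counts["invasive"] > 0:
        profile = front_profile(state, n_bins)
        radius = mean_front_radius(profile)
        if int(profile.occupied.sum()) >= 2:
            rough = surface_roughness(profile)
    return TimeSeriesRecord(
        t=state.t,
        n_prolif=counts["proliferative"],
        n_invasive=counts["invasive"],
        n_necrotic=counts["necrotic"],
        frac_prolif=fractions["proliferative"],
        frac_invasive=fractions["invasive"],
        frac_necrotic=fractions["necrotic"],
        mean_front_radius=radius,
        roughness=rough,
    )


def records_to_frame(records: Sequence[TimeSeriesRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def write_timeseries(records: Sequence[TimeSeriesRecord], path: str | Path) -> None:
    """CSV with one row per cycle: counts, fractions, front radius, roughness."""
    records_to_frame(records).to_csv(path, index=False)


def write_rdf(state: WorldState, path: str | Path, bin_width: float = 2.0) -> None:
    """CSV of the four sector RDFs (columns sector, r_bin_low, g).

    Sectors without living cells are omitted.
    """
    tables = []
    for sector in (1, 2, 3, 4):
        try:
            df = radial_distribution(state, sector, bin_width)
        except MetricError:
            continue
        df.insert(0, "sector", sector)
        tables.append(df)
    if not tables:
        raise MetricError("no sector contains living cells")
    pd.concat(tables, ignore_index=True).to_csv(path, index=False)
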