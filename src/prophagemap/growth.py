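"""Culture kinetics and virion morphometrics.

Descriptive statistics of a spontaneous-induction time course — doubling
time, the phage-like-particle (PLP) to bacterium ratio — plus capsid
morphometrics: sphere volume from capsid diameter and a packing-density
based genome-size estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountSeries",
    "VirionMorphometrics",
    "read_counts_tsv",
    "doubling_time",
    "plp_ratio_series",
    "capsid_volume",
    "format_2sig",
    "genome_size_from_capsid",
]

#: Default DNA packing-density range inside the capsid, bp per nm^3.
#: Calibrated so a 60-nm capsid implies a 45-60 kb genome.
DEFAULT_PACKING_DENSITY = (0.40, 0.53)


@dataclass
class CountSeries:
    """One replicate's time course of cell and PLP concentrations (per mL)."""

    timepoints: np.ndarray
    cells: np.ndarray
    plps: np.ndarray
    replicate: str = "1"

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.cells = np.asarray(self.cells, dtype=float)
        self.plps = np.asarray(self.plps, dtype=float)
        if not (self.timepoints.size == self.cells.size == self.plps.size):
            raise ValueError("timepoints, cells and plps must have equal length")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.cells < 0) or np.any(self.plps < 0):
            raise ValueError("counts must be >= 0")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.timepoints,
                "cells_per_ml": self.cells,
                "plp_per_ml": self.plps,
                "replicate": self.replicate,
            }
        )


def read_counts_tsv(path) -> list[CountSeries]:
    """Read a count table (columns time_h, cells_per_ml, plp_per_ml, replicate)."""
    df = pd.read_csv(path, sep="\t")
    required = {"time_h", "cells_per_ml", "plp_per_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = "1"
    out = []
    for rep, grp in df.groupby("replicate", sort=True):
        grp = grp.sort_values("time_h")
        out.append(
            CountSeries(
                grp["time_h"].to_numpy(),
                grp["cells_per_ml"].to_numpy(),
                grp["plp_per_ml"].to_numpy(),
                str(rep),
            )
        )
    return out


def doubling_time(B: float, b: float, t: float) -> float:
    """Doubling (generation) time from counts at a time interval's endpoints.

    g = t / (3.3 * log10(b / B)), with B the count at the interval start, b
    the count at its end, and t the interval in hours; 3.3 approximates
    1 / log10(2), so one doubling over t gives g ~ t.
    """
    if not (b > B > 0):
        raise ValueError(f"require b > B > 0 (no growth in [{B}, {b}])")
    if t <= 0:
        raise ValueError("time interval must be positive")
    return t / (3.3 * math.log10(b / B))


@dataclass
class PlpRatioResult:
    table: pd.DataFrame  # columns: time_h, ratio (replicate-averaged)
    max_ratio: float
    argmax_time: float


def plp_ratio_series(series) -> PlpRatioResult:
    """Per-timepoint PLP:bacterium ratio, averaged across replicates.

    Ratios are computed per replicate first and then averaged at matching
    timepoints; timepoints missing from some replicates are averaged over
    the replicates that have them.  A zero cell count is an error.
    """
    if isinstance(series, CountSeries):
        series = [series]
    if not series:
        raise ValueError("no count series given")
    frames = []
    for s in series:
        if np.any(s.cells == 0):
            raise ValueError(f"replicate {s.replicate!r}: zero cell count")
        frames.append(pd.DataFrame({"time_h": s.timepoints, "ratio": s.plps / s.cells}))
    merged = pd.concat(frames).groupby("time_h", as_index=False)["ratio"].mean()
    imax = int(merged["ratio"].idxmax())
    return PlpRatioResult(
        table=merged,
        max_ratio=float(merged.loc[imax, "ratio"]),
        argmax_time=float(merged.loc[imax, "time_h"]),
    )


def capsid_volume(d: float) -> float:
    """Sphere volume (nm^3) from capsid diameter d (nm): (4/3) pi (d/2)^3."""
    if d <= 0:
        raise ValueError("capsid diameter must be > 0")
    return (4.0 / 3.0) * math.pi * (d / 2.0) ** 3


def format_2sig(x: float) -> str:
    """Two-significant-figure scientific notation in compact form, e.g. 1.8E5."""
    if x == 0:
        return "0.0E0"
    exp = math.floor(math.log10(abs(x)))
    mant = round(x / 10**exp, 1)
    if abs(mant) >= 10:  # rounding pushed the mantissa over
        mant /= 10
        exp += 1
    return f"{mant:.1f}E{exp}"


def genome_size_from_capsid(
    d: float, packing_density=DEFAULT_PACKING_DENSITY
) -> tuple[float, float] | float:
    """Genome size (kb) implied by capsid diameter and DNA packing density.

    ``packing_density`` is bp per nm^3, either a (low, high) range or a
    point value; the result is V(d) * rho / 1000 in kb.
    """
    v = capsid_volume(d)
    if np.isscalar(packing_density):
        rho = float(packing_density)
        if rho <= 0:
            raise ValueError("packing density must be > 0")
        return v * rho / 1000.0
    lo, hi = packing_density
    if not (0 < lo <= hi):
        raise ValueError("packing density range must be positive and ordered")
    return (v * lo / 1000.0, v * hi / 1000.0)


@dataclass(frozen=True)
class VirionMorphometrics:
    """TEM-derived virion measurements and derived quantities."""

    capsid_diameter: float  # nm
    tail_length: float | None = None  # nm
    morphology: str | None = None  # {podophage, siphophage, myophage}

    def __post_init__(self) -> None:
        if self.capsid_diameter <= 0:
            raise ValueError("capsid diameter must be > 0")
        if self.morphology is not None and self.morphology not in (
            "podophage", "siphophage", "myophage",
        ):
            raise ValueError(f"unknown morphology {self.morphology!r}")

    @property
    def capsid_volume(self) -> float:
        return capsid_volume(self.capsid_diameter)

    def summary(self) -> dict:
        lo, hi = genome_size_from_capsid(self.capsid_diameter)
        return {
            "capsid_diameter_nm": self.capsid_diameter,
            "tail_length_nm": self.tail_length,
            "morphology": self.morphology,
            "capsid_volume_nm3": self.capsid_volume,
            "capsid_volume_2sig": format_2sig(self.capsid_volume),
            "genome_size_kb_range": [lo, hi],
        }
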