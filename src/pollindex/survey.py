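"""Published summary statistics of the roadside noise-barrier survey.

These are the per-side descriptive statistics (mg/kg dry soil) and the
inter-element Spearman rank correlations of a 121-sample topsoil transect
survey flanking a ~4 m roadside noise screen along an urban ring road:
11 stations every ~150 m along the barrier, crossed with six perpendicular
distances on the left (windward/west) side and five on the right (road)
side, six field subsamples per station.

The tables serve two purposes in this package: they are the calibration
targets of the synthetic transect generator, and they are the worked-
example inputs that the index stack can be fed with directly — because PI
and Igeo are strictly monotone in concentration and the PI-linear
integrated indices commute with averaging, the survey's index summary
cells are recoverable from these concentration summaries alone.
"""

from __future__ import annotations

import pandas as pd

from .reference import ELEMENTS

__all__ = [
    "summary",
    "side_statistic",
    "rank_correlation",
    "sample_size",
    "SIDES",
]

SIDES = ("left", "right")

_ROWS = ("Min", "Max", "Mean", "SD", "Q1", "Med", "Q3", "Skewness", "Kurtosis", "CV")

_LEFT = {
    "Zn": [36.29, 1034.39, 241.25, 200.83, 111.22, 166.71, 278.25, 2.06, 4.45, 0.83],
    "Cu": [42.57, 220.04, 86.00, 36.31, 63.16, 75.23, 93.25, 1.87, 3.74, 0.42],
    "Pb": [2.22, 198.88, 58.64, 50.55, 26.55, 39.63, 83.52, 1.39, 1.29, 0.86],
    "Cr": [16.36, 137.62, 56.08, 26.23, 39.53, 51.29, 72.22, 0.94, 0.89, 0.47],
    "Ni": [20.85, 73.69, 45.05, 11.98, 37.67, 44.39, 53.59, 0.36, -0.21, 0.27],
    "Cd": [3.15, 24.14, 6.51, 2.71, 5.39, 5.96, 6.71, 4.46, 26.76, 0.42],
}

_RIGHT = {
    "Zn": [17.32, 1371.15, 302.16, 254.91, 171.70, 221.53, 335.10, 2.35, 6.34, 0.84],
    "Cu": [36.08, 318.26, 91.83, 48.85, 65.19, 81.72, 99.46, 2.64, 8.83, 0.53],
    "Pb": [2.34, 361.83, 53.73, 58.77, 12.47, 34.88, 79.67, 2.83, 12.47, 1.09],
    "Cr": [2.31, 78.06, 34.77, 17.34, 22.31, 32.62, 45.39, 0.34, -0.25, 0.50],
    "Ni": [0.03, 88.21, 27.85, 18.90, 11.06, 25.54, 40.47, 0.74, 0.53, 0.68],
    "Cd": [0.19, 7.79, 2.11, 1.68, 0.98, 1.60, 2.61, 1.83, 3.39, 0.80],
}

_N = {"left": 66, "right": 55}

# Upper-triangle Spearman rank correlations between element concentrations.
_CORR_LEFT = {
    ("Zn", "Cu"): 0.88, ("Zn", "Pb"): 0.77, ("Zn", "Cr"): 0.77, ("Zn", "Ni"): 0.68, ("Zn", "Cd"): 0.69,
    ("Cu", "Pb"): 0.70, ("Cu", "Cr"): 0.90, ("Cu", "Ni"): 0.82, ("Cu", "Cd"): 0.72,
    ("Pb", "Cr"): 0.57, ("Pb", "Ni"): 0.45, ("Pb", "Cd"): 0.54,
    ("Cr", "Ni"): 0.79, ("Cr", "Cd"): 0.62,
    ("Ni", "Cd"): 0.67,
}

_CORR_RIGHT = {
    ("Zn", "Cu"): 0.88, ("Zn", "Pb"): 0.75, ("Zn", "Cr"): 0.80, ("Zn", "Ni"): 0.72, ("Zn", "Cd"): 0.71,
    ("Cu", "Pb"): 0.70, ("Cu", "Cr"): 0.79, ("Cu", "Ni"): 0.74, ("Cu", "Cd"): 0.64,
    ("Pb", "Cr"): 0.70, ("Pb", "Ni"): 0.54, ("Pb", "Cd"): 0.69,
    ("Cr", "Ni"): 0.69, ("Cr", "Cd"): 0.41,
    ("Ni", "Cd"): 0.44,
}


def summary() -> pd.DataFrame:
    """Both sides' descriptive statistics as a (side, statistic) x element frame."""
    blocks = []
    for side, data in (("left", _LEFT), ("right", _RIGHT)):
        block = pd.DataFrame(data, index=_ROWS)
        block.loc["n"] = _N[side]
        block.index = pd.MultiIndex.from_product([[side], block.index], names=["side", "statistic"])
        blocks.append(block)
    return pd.concat(blocks)[list(ELEMENTS)]


def side_statistic(side: str, statistic: str) -> pd.Series:
    """One summary row, e.g. ``side_statistic("left", "Med")``."""
    return summary().loc[(side, statistic)]


def sample_size(side: str) -> int:
    return _N[side]


def rank_correlation(side: str) -> pd.DataFrame:
    """Symmetric Spearman target matrix for one side (unit diagonal)."""
    corr = {"left": _CORR_LEFT, "right": _CORR_RIGHT}[side]
    mat = pd.DataFrame(1.0, index=list(ELEMENTS), columns=list(ELEMENTS))
    for (a, b), r in corr.items():
        mat.at[a, b] = r
        mat.at[b, a] = r
    return mat
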