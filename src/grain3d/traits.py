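"""The 32-trait record per grain, accuracy metrics, trait correlations,
and L9 orthogonal-array range analysis.

The trait set holds 16 basic measurements (length l, width w, thickness
h, volume V, surface area S, sulcus depth D, three section perimeters
and areas, slice perimeter/area, sulcus area, l/w) and 16 derived values
(dimension ratios, box volume, surface/volume ratios, section roundness
indices and sphericity).  Accuracy metrics are MAPE (percent), RMSE and
R^2 = 1 - sum (x-y)^2 / sum (x - mean(y))^2, where x are the reference
and y the system measurements (note the nonstandard centring on the
system mean; a switch selects the textbook definition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Outline2D, roundness, sphericity
from .sulcus import SliceProfile

__all__ = [
    "TRAIT_NAMES",
    "assemble_traits",
    "metrics",
    "correlation_matrix",
    "orthogonal_analysis",
]

#: Column order of the trait table: 16 basic then 16 derived traits.
TRAIT_NAMES = [
    "l", "w", "h", "V", "S", "D",
    "C_yz", "S_yz", "C_xz", "S_xz", "C_xy", "S_xy",
    "C_c", "S_c", "S_s", "l/w",
    "l/h", "w/h", "D/h", "V_obb", "S/V", "S/l", "S/w", "S/h",
    "V/l", "V/w", "V/h", "S_s/S_c", "c_yz", "c_xz", "c_xy", "E",
]


def assemble_traits(
    l: float,
    w: float,
    h: float,
    volume: float,
    area: float,
    outlines: dict[str, Outline2D],
    slice_profile: SliceProfile,
) -> dict[str, float]:
    """Build the full 32-trait record for one grain.

    ``outlines`` maps projection axis ("X", "Y", "Z") to its
    :class:`Outline2D`: X supplies the (y, z) cross section, Y the (x, z)
    longitudinal section, Z the (x, y) horizontal section.
    ``slice_profile`` must already be measured (depth, C_c, S_c, S_s).
    """
    cross, longi, horiz = outlines["X"], outlines["Y"], outlines["Z"]
    if slice_profile.depth is None or slice_profile.area is None:
        raise ValueError("slice profile is unmeasured; run measure_profile first")
    basics = {
        "l": l, "w": w, "h": h, "V": volume, "S": area, "D": slice_profile.depth,
        "C_yz": cross.perimeter, "S_yz": cross.area,
        "C_xz": longi.perimeter, "S_xz": longi.area,
        "C_xy": horiz.perimeter, "S_xy": horiz.area,
        "C_c": slice_profile.perimeter, "S_c": slice_profile.area,
        "S_s": slice_profile.sulcus_area,
    }
    for name in ("l", "w", "h", "V", "S", "S_c"):
        if basics[name] <= 0:
            raise ZeroDivisionError(f"degenerate basic trait {name} = {basics[name]!r}")
    record = dict(basics)
    record["l/w"] = l / w
    record["l/h"] = l / h
    record["w/h"] = w / h
    record["D/h"] = basics["D"] / h
    record["V_obb"] = l * w * h
    record["S/V"] = area / volume
    record["S/l"] = area / l
    record["S/w"] = area / w
    record["S/h"] = area / h
    record["V/l"] = volume / l
    record["V/w"] = volume / w
    record["V/h"] = volume / h
    record["S_s/S_c"] = basics["S_s"] / basics["S_c"]
    record["c_yz"] = roundness(cross)
    record["c_xz"] = roundness(longi)
    record["c_xy"] = roundness(horiz)
    record["E"] = sphericity(volume, area)
    out = {name: float(record[name]) for name in TRAIT_NAMES}
    if not all(np.isfinite(v) for v in out.values()):
        bad = [k for k, v in out.items() if not np.isfinite(v)]
        raise ValueError(f"non-finite trait values: {bad}")
    return out


def metrics(
    x: np.ndarray,
    y: np.ndarray,
    r2_definition: str = "system_mean",
) -> tuple[float, float, float]:
    """(MAPE %, RMSE, R^2) of system measurements y against reference x.

    MAPE = 100/n * sum |x - y| / x (requires x != 0); RMSE is the root mean
    square difference; R^2 centres on mean(y) by default
    (``r2_definition="system_mean"``) or mean(x) (``"standard"``).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("x and y must be equal-length with n >= 2")
    if np.any(x == 0):
        raise ZeroDivisionError("MAPE undefined: reference value x_i = 0")
    mape = 100.0 * float(np.mean(np.abs(x - y) / np.abs(x)))
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    center = y.mean() if r2_definition == "system_mean" else x.mean()
    denom = float(np.sum((x - center) ** 2))
    if denom == 0:
        raise ZeroDivisionError("R^2 undefined: zero variance around the centring mean")
    r2 = 1.0 - float(np.sum((x - y) ** 2)) / denom
    return mape, rmse, r2


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix over trait (and weight) columns.

    Zero-variance columns yield NaN rows/columns and a warning naming them
    rather than silently propagating.
    """
    numeric = table.select_dtypes(include=[np.number])
    if "id" in numeric.columns:
        numeric = numeric.drop(columns=["id"])
    if numeric.shape[0] < 3:
        raise ValueError("correlation needs at least 3 rows")
    if numeric.isna().any().any():
        raise ValueError("correlation input contains missing values")
    degenerate = [c for c in numeric.columns if numeric[c].std(ddof=0) == 0]
    if degenerate:
        warnings.warn(f"zero-variance columns have undefined correlations: {degenerate}",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = numeric.corr(method="pearson")
    return corr


def orthogonal_analysis(table: pd.DataFrame) -> dict:
    """Range analysis of a balanced L9 (3-level) design.

    For each factor f, K[f][i] is the mean response over the three tests run
    at level i+1, R[f] = max K - min K (a larger range means a more
    influential factor), and the best level is the one minimising K (the
    response is an error measure).  The last column is the response.
    """
    factors = table.columns[:-1]
    response = table.iloc[:, -1].to_numpy(dtype=np.float64)
    if table.shape[0] != 9:
        raise ValueError("range analysis expects the 9 tests of an L9 design")
    K: dict[str, list[float]] = {}
    R: dict[str, float] = {}
    best: dict[str, int] = {}
    for f in factors:
        levels = table[f].to_numpy(dtype=int)
        counts = [int((levels == lv).sum()) for lv in (1, 2, 3)]
        if counts != [3, 3, 3]:
            raise ValueError(f"unbalanced design: factor {f!r} level counts {counts}")
        k = [float(response[levels == lv].mean()) for lv in (1, 2, 3)]
        K[f] = k
        R[f] = float(max(k) - min(k))
        best[f] = int(np.argmin(k)) + 1
    return {"K": K, "R": R, "best_levels": best}
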