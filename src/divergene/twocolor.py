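"""Two-colour array transforms and normalization.

A hybridization compares a Cy5-labelled sample (R) against a Cy3-labelled
one (G) on the same slide.  Analysis happens on the MA plane, with
``M = log2 R - log2 G`` (the per-spot log ratio) and
``A = (log2 R + log2 G) / 2`` (the mean log intensity).  Normalization
proceeds in a fixed order:

1. global: subtract the median M (scale factor between channels),
2. loess: subtract an intensity-dependent LOESS smooth c(A) of the
   MA-plot, fitted on a configurable fraction of the spots (default 40%),
3. subarray: subtract per-block medians, balancing print-tip /
   sub-array differences.

Oriented stacking then sign-flips arrays that carried the second line on
Cy5, so every column of the stacked matrix means log2(HAB/LAB).

M is deliberately computed as ``log2 R - log2 G`` so that swapping the
channels negates M bit-exactly; the whole pipeline is equivariant under
a simultaneous channel swap and orientation flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "TwoColorArray",
    "MASet",
    "ma_transform",
    "normalize_global",
    "normalize_loess",
    "normalize_subarray",
    "orient_and_stack",
    "normalize_array",
    "read_intensity_table",
]

_STATES = ("raw", "global", "loess", "subarray")


@dataclass
class TwoColorArray:
    """Spot-level intensities of one hybridization.

    ``spots`` columns: probe_id, block, R, G (row/col optional).
    ``orientation`` names the line on Cy5 ("HAB" or "LAB").
    """

    spots: pd.DataFrame
    orientation: str
    array_id: str = ""

    def __post_init__(self) -> None:
        required = {"probe_id", "block", "R", "G"}
        missing = required - set(self.spots.columns)
        if missing:
            raise ValueError(f"spot table missing columns {sorted(missing)}")
        rg = self.spots[["R", "G"]].to_numpy(float)
        if not np.all(np.isfinite(rg)):
            raise ValueError("R and G must be finite")
        if (rg < 0).any():
            raise ValueError("R and G must be >= 0")


@dataclass
class MASet:
    """Per-spot (M, A) values of one array with normalization state.

    Spots with a zero channel are flagged unusable (``usable`` False,
    M/A = NaN) and are excluded from every median and fit, but retained
    in outputs.  ``c_global`` stores the subtracted global constant;
    ``curve`` tabulates the fitted LOESS correction on an A-grid.
    """

    probe_id: np.ndarray
    block: np.ndarray
    R: np.ndarray
    G: np.ndarray
    M: np.ndarray
    A: np.ndarray
    usable: np.ndarray
    orientation: str
    array_id: str = ""
    state: str = "raw"
    c_global: float | None = None
    curve: pd.DataFrame | None = None

    def copy(self) -> "MASet":
        return MASet(self.probe_id, self.block, self.R, self.G,
                     self.M.copy(), self.A, self.usable, self.orientation,
                     self.array_id, self.state, self.c_global, self.curve)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "probe_id": self.probe_id, "block": self.block,
            "M": self.M, "A": self.A, "state": self.state,
        })


def _require_state(ma: MASet, expected: str, op: str) -> None:
    if ma.state != expected:
        raise ValueError(f"{op} requires state {expected!r}, got {ma.state!r}")


def ma_transform(array: TwoColorArray) -> MASet:
    """Compute per-spot M and A from raw channel intensities.

    Spots with R=0 or G=0 have no defined log ratio and are flagged
    missing.  Raises if no spot is usable.
    """
    r = array.spots["R"].to_numpy(float)
    g = array.spots["G"].to_numpy(float)
    usable = (r > 0) & (g > 0)
    if not usable.any():
        raise ValueError("no usable spots (all have a zero channel)")
    m = np.full(r.shape, np.nan)
    a = np.full(r.shape, np.nan)
    with np.errstate(divide="ignore"):
        lr, lg = np.log2(r), np.log2(g)
    m[usable] = lr[usable] - lg[usable]
    a[usable] = (lr[usable] + lg[usable]) / 2.0
    return MASet(
        probe_id=array.spots["probe_id"].to_numpy(object),
        block=array.spots["block"].to_numpy(int),
        R=r, G=g, M=m, A=a, usable=usable,
        orientation=array.orientation, array_id=array.array_id,
    )


def normalize_global(ma: MASet) -> MASet:
    """Subtract the median of usable M (channel scale factor, log2)."""
    _require_state(ma, "raw", "normalize_global")
    out = ma.copy()
    c = float(np.median(ma.M[ma.usable]))
    out.M = ma.M - c
    out.c_global = c
    out.state = "global"
    return out


def normalize_loess(ma: MASet, span: float = 0.40, grid_points: int = 256,
                    delta_frac: float = 0.005) -> MASet:
    """Subtract an intensity-dependent LOESS smooth c(A) from M.

    Local linear fit with tricube weights, neighborhood = ``span``
    fraction of the usable spots, evaluated at every spot.  For dense
    arrays, points closer than ``delta_frac`` of the A range share a
    locally interpolated fit (the smoother's standard point-collapsing
    device); the resulting curve is also tabulated on a uniform A-grid
    of ``grid_points`` points and stored on the result.
    """
    _require_state(ma, "global", "normalize_loess")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    u = ma.usable
    if int(u.sum()) < 10:
        raise ValueError("fewer than 10 usable spots: LOESS fit unidentifiable")
    a, m = ma.A[u], ma.M[u]
    delta = delta_frac * (a.max() - a.min())
    fit = lowess(m, a, frac=span, it=0, delta=delta, return_sorted=False)
    out = ma.copy()
    out.M = ma.M.copy()
    out.M[u] = m - fit
    grid = np.linspace(a.min(), a.max(), grid_points)
    order = np.argsort(a, kind="stable")
    out.curve = pd.DataFrame({
        "A": grid, "c": np.interp(grid, a[order], fit[order]),
    })
    out.state = "loess"
    return out


def normalize_subarray(ma: MASet) -> MASet:
    """Subtract the per-block median of M within each sub-array.

    Balances unequal probe distribution in array production and
    unbalanced fluorescence within one slide.  A block with no usable
    spot is left unchanged.
    """
    _require_state(ma, "loess", "normalize_subarray")
    out = ma.copy()
    out.M = ma.M.copy()
    for b in np.unique(ma.block):
        sel = (ma.block == b) & ma.usable
        if not sel.any():
            continue
        out.M[ma.block == b] -= np.median(ma.M[sel])
    out.state = "subarray"
    return out


def normalize_array(array: TwoColorArray, span: float = 0.40,
                    skip_subarray: bool = False) -> MASet:
    """Full per-array chain: MA transform, global, LOESS, sub-array."""
    ma = normalize_loess(normalize_global(ma_transform(array)), span=span)
    if not skip_subarray:
        ma = normalize_subarray(ma)
    return ma


def orient_and_stack(mas: list[MASet], require_state: str = "subarray"
                     ) -> pd.DataFrame:
    """Stack normalized arrays into a probe x array M matrix, HAB-over-LAB.

    Arrays with LAB on Cy5 are sign-flipped so every column means
    log2(HAB/LAB).  Probes are aligned by id; a probe absent from an
    array yields a missing cell.
    """
    if not mas:
        raise ValueError("no arrays to stack")
    cols = {}
    for i, ma in enumerate(mas):
        if require_state is not None:
            _require_state(ma, require_state, "orient_and_stack")
        if ma.orientation == "HAB":
            s = 1.0
        elif ma.orientation == "LAB":
            s = -1.0
        else:
            raise ValueError(f"unknown orientation {ma.orientation!r}")
        name = ma.array_id or f"array{i}"
        cols[name] = pd.Series(s * ma.M, index=ma.probe_id)
    stack = pd.DataFrame(cols)
    stack.index.name = "probe_id"
    return stack


def read_intensity_table(path, orientation: str, array_id: str = "") -> TwoColorArray:
    """Read the tab-delimited intensity dialect (probe_id, block, row, col, R, G)."""
    spots = pd.read_csv(path, sep="\t")
    return TwoColorArray(spots=spots, orientation=orientation,
                         array_id=array_id or str(path))
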