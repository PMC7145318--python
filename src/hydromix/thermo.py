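"""Density-temperature curves, glass-transition extraction from density
maxima, and Couchman-Karasz mixture comparison.

The glass transition is read from the maximum of the density-vs-temperature
curve of each composition (an unconventional but deliberate criterion here);
a smoothing-spline alternative is provided for robustness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

__all__ = [
    "DensityCurve",
    "TgEstimate",
    "CKParameters",
    "estimate_tg_from_density",
    "couchman_karasz_tg",
    "compare_tg",
]


@dataclass
class DensityCurve:
    """(T, rho) series for one composition, sorted by temperature."""

    omega: float
    temperature: np.ndarray    # K, strictly increasing
    density: np.ndarray        # g/cm^3

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, float)
        self.density = np.asarray(self.density, float)
        if len(self.temperature) < 4:
            raise ValueError("need at least 4 points")
        if len(self.temperature) != len(self.density):
            raise ValueError("temperature/density length mismatch")
        if not np.all(np.diff(self.temperature) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(self.density <= 0):
            raise ValueError("densities must be positive")


@dataclass
class TgEstimate:
    tg: float                  # K
    method: str                # density_maximum fit variant
    curvature: float           # d2rho/dT2 at the maximum (negative)
    residual: float


@dataclass(frozen=True)
class CKParameters:
    """Component glass temperatures (K) and heat-capacity increments (J/gK).

    Defaults are literature-typical placeholder values for water and
    trehalose; they are configuration, not measured claims.
    """

    tg_water: float = 136.0
    dcp_water: float = 1.94
    tg_thal: float = 388.0
    dcp_thal: float = 0.55

    def __post_init__(self) -> None:
        if min(self.tg_water, self.tg_thal) <= 0:
            raise ValueError("component Tg values must be > 0")
        if min(self.dcp_water, self.dcp_thal) <= 0:
            raise ValueError("heat-capacity increments must be > 0")


def estimate_tg_from_density(curve: DensityCurve,
                             fit: str = "quadratic_window") -> TgEstimate:
    """Tg from the interior maximum of rho(T).

    ``quadratic_window``: parabola through the 5 points bracketing the grid
    maximum; Tg is the vertex.  ``spline``: cubic smoothing-spline argmax.
    Both enforce negative curvature; a vertex escaping the bracketing window
    falls back to the grid argmax with a warning.
    """
    temps, rho = curve.temperature, curve.density
    imax = int(np.argmax(rho))
    if imax == 0 or imax == len(rho) - 1:
        raise ValueError("no density maximum in span: curve is monotone at "
                         "the grid maximum")
    if fit == "quadratic_window":
        lo = max(0, imax - 2)
        hi = min(len(rho), imax + 3)
        lo = max(0, hi - 5)
        hi = min(len(rho), lo + 5)
        tw, rw = temps[lo:hi], rho[lo:hi]
        coef = np.polyfit(tw, rw, 2)
        a, b = coef[0], coef[1]
        resid = float(np.sqrt(np.mean((np.polyval(coef, tw) - rw) ** 2)))
        if a >= 0:
            raise ValueError("no density maximum: fitted parabola opens upward")
        vertex = -b / (2.0 * a)
        if not tw[0] <= vertex <= tw[-1]:
            warnings.warn(
                "parabola vertex escaped the bracketing window; falling back "
                "to the grid argmax")
            vertex = float(temps[imax])
        return TgEstimate(tg=float(vertex), method="density_maximum/quadratic",
                          curvature=float(2 * a), residual=resid)
    if fit == "spline":
        spl = UnivariateSpline(temps, rho, k=3, s=0.0)
        grid = np.linspace(temps[0], temps[-1], 4001)
        vals = spl(grid)
        j = int(np.argmax(vals))
        if j == 0 or j == len(grid) - 1:
            raise ValueError("no interior density maximum (spline)")
        curv = float(spl.derivative(2)(grid[j]))
        if curv >= 0:
            raise ValueError("spline maximum has non-negative curvature")
        resid = float(np.sqrt(np.mean((spl(temps) - rho) ** 2)))
        return TgEstimate(tg=float(grid[j]), method="density_maximum/spline",
                          curvature=curv, residual=resid)
    raise ValueError(f"unknown fit method {fit!r}")


def couchman_karasz_tg(omega: float, params: CKParameters = CKParameters()) -> float:
    """Couchman-Karasz mixture glass temperature.

    Tg(w) = (w dCp_T Tg_T + (1-w) dCp_W Tg_W) / (w dCp_T + (1-w) dCp_W).
    """
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must lie in [0, 1]")
    num = (omega * params.dcp_thal * params.tg_thal
           + (1.0 - omega) * params.dcp_water * params.tg_water)
    den = omega * params.dcp_thal + (1.0 - omega) * params.dcp_water
    return num / den


def compare_tg(md: dict[float, float], ck: dict[float, float]) -> pd.DataFrame:
    """Per-composition MD-vs-model differences; summary stats in ``df.attrs``."""
    if sorted(md) != sorted(ck):
        raise ValueError("composition grids do not match")
    omegas = sorted(md)
    rows = [{"omega": w, "tg_md": md[w], "tg_ck": ck[w],
             "difference": md[w] - ck[w]} for w in omegas]
    df = pd.DataFrame(rows)
    df.attrs["mean_absolute_difference"] = float(df["difference"].abs().mean())
    df.attrs["max_absolute_difference"] = float(df["difference"].abs().max())
    return df
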