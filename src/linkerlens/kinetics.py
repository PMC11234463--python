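"""Michaelis–Menten kinetics: initial rates, nonlinear fits, catalytic efficiency.

Exopolyphosphatase activity is assayed by coupling released phosphate to a
chromogenic reaction and reading absorbance over time; the initial slope in
absorbance per minute, divided by the phosphate standard-curve slope
(absorbance units per µM Pi), gives the initial rate in µM Pi per second.

Rates v over a substrate grid S are fitted to

    v = kcat · E0 · S / (Km + S)

by multistart nonlinear least squares (unweighted residuals). Catalytic
efficiency is kcat/Km in µM⁻¹·s⁻¹ — the low-substrate second-order rate
constant, and the quantity that tracks α-linker length across enzyme
variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

__all__ = [
    "KineticsDataset",
    "StandardCurve",
    "MMFit",
    "initial_rate",
    "fit_mm",
    "efficiency",
]


@dataclass
class KineticsDataset:
    substrate: np.ndarray  # µM
    rates: np.ndarray      # µM·s⁻¹
    enzyme_conc: float     # µM (E0)
    label: str = ""

    def __post_init__(self) -> None:
        self.substrate = np.asarray(self.substrate, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.substrate.shape != self.rates.shape:
            raise ValueError("substrate and rates must have equal length")
        if np.any(self.substrate <= 0):
            raise ValueError("substrate concentrations must be positive")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme concentration must be positive")

    def require_fittable(self) -> None:
        if len(np.unique(self.substrate)) < 4:
            raise ValueError("need ≥4 distinct substrate concentrations to fit")


@dataclass(frozen=True)
class StandardCurve:
    slope: float       # absorbance units per µM Pi
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("standard-curve slope must be positive")


@dataclass
class MMFit:
    kcat: float          # s⁻¹
    km: float            # µM
    kcat_sd: float
    km_sd: float
    r2: float
    efficiency: float    # µM⁻¹·s⁻¹
    n: int
    vmax_identifiable: bool = True
    label: str = ""


def michaelis_menten(s: np.ndarray, kcat: float, km: float, e0: float) -> np.ndarray:
    return kcat * e0 * s / (km + s)


def initial_rate(
    times: np.ndarray,
    absorbance: np.ndarray,
    curve: StandardCurve,
    window: tuple[float, float] | None = None,
) -> float:
    """Initial rate (µM Pi·s⁻¹) from an absorbance time series.

    The least-squares slope of absorbance vs time (seconds) over the window
    is divided by the standard-curve slope. The default window is the first
    20% of the trace or the first 10 points, whichever is larger. Negative
    slopes are clamped to zero with a warning.
    """
    times = np.asarray(times, dtype=float)
    absorbance = np.asarray(absorbance, dtype=float)
    if times.shape != absorbance.shape:
        raise ValueError("times and absorbance must have equal length")
    if window is None:
        span = times[-1] - times[0]
        t_hi = times[0] + 0.2 * span
        n_min = min(10, len(times))
        t_hi = max(t_hi, times[n_min - 1])
        window = (times[0], t_hi)
    lo, hi = window
    if lo < times[0] - 1e-12 or hi > times[-1] + 1e-12:
        raise ValueError(f"window ({lo}, {hi}) outside trace span ({times[0]}, {times[-1]})")
    mask = (times >= lo - 1e-12) & (times <= hi + 1e-12)
    if mask.sum() < 3:
        raise ValueError("initial-rate window must contain ≥3 points")
    slope_au_per_s = linregress(times[mask], absorbance[mask]).slope
    rate = slope_au_per_s / curve.slope
    if rate < 0:
        warnings.warn(f"negative initial slope ({rate:.3g} µM/s) clamped to 0", stacklevel=2)
        rate = 0.0
    return float(rate)


def _fit_starts(s: np.ndarray, v: np.ndarray) -> list[tuple[float, float]]:
    """Multistart grid: Vmax ∈ {max v, 2 max v} × Km ∈ quartiles of S, plus a
    Lineweaver–Burk linearization seed."""
    vmax0 = float(v.max())
    starts = [
        (vm, km)
        for vm in (vmax0, 2.0 * vmax0)
        for km in np.percentile(s, [25, 50, 75])
    ]
    pos = v > 0
    if pos.sum() >= 2:
        # 1/v = (Km/Vmax)(1/S) + 1/Vmax
        lb = linregress(1.0 / s[pos], 1.0 / v[pos])
        if lb.intercept > 0 and lb.slope > 0:
            starts.append((1.0 / lb.intercept, lb.slope / lb.intercept))
    return starts


def fit_mm(data: KineticsDataset) -> MMFit:
    """Fit v = kcat·E0·S/(Km+S) by multistart nonlinear least squares.

    Unweighted residuals; the best sum of squared residuals wins, ties going
    to the smaller Km. Parameter SDs come from the asymptotic covariance
    (J^T J)⁻¹·s². A fit where all S ≪ Km (Vmax unidentifiable) is flagged.
    """
    data.require_fittable()
    s, v, e0 = data.substrate, data.rates, data.enzyme_conc

    def residuals(p: np.ndarray) -> np.ndarray:
        vmax, km = p
        return vmax * s / (km + s) - v

    best = None
    for vmax0, km0 in _fit_starts(s, v):
        try:
            res = least_squares(
                residuals, x0=[vmax0, km0],
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        ssr = float(2.0 * res.cost)
        if best is None or ssr < best[0] - 1e-12 or (
            abs(ssr - best[0]) <= 1e-12 and res.x[1] < best[1].x[1]
        ):
            best = (ssr, res)
    if best is None or not best[1].success and best[1].status <= 0:
        raise RuntimeError("Michaelis–Menten fit failed to converge from any start")
    ssr, res = best
    vmax, km = res.x

    sstot = float(((v - v.mean()) ** 2).sum())
    r2 = 1.0 - ssr / sstot if sstot > 0 else 1.0

    # asymptotic covariance from the final Jacobian
    dof = max(len(s) - 2, 1)
    s2 = ssr / dof
    jac = res.jac
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        vmax_sd, km_sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        vmax_sd = km_sd = float("nan")

    identifiable = bool(s.max() >= km)
    if not identifiable:
        warnings.warn(
            "all substrate concentrations below fitted Km: Vmax poorly identified",
            stacklevel=2,
        )
    kcat = vmax / e0
    return MMFit(
        kcat=float(kcat), km=float(km),
        kcat_sd=float(vmax_sd / e0), km_sd=float(km_sd),
        r2=float(r2), efficiency=efficiency(kcat, km),
        n=len(s), vmax_identifiable=identifiable, label=data.label,
    )


def efficiency(kcat: float, km: float) -> float:
    """Catalytic efficiency kcat/Km (µM⁻¹·s⁻¹)."""
    if km <= 0:
        raise ValueError("Km must be positive")
    return float(kcat / km)
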