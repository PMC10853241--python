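"""Thermal-shift (nanoDSF-style) melt-curve analysis.

The observable is the intrinsic-fluorescence ratio F350/F330 recorded over a
thermal ramp (default 35-95 degC). Two Tm estimators are provided: an
assumption-light smoothed-derivative peak, and a two-state (van 't Hoff)
fit with linear folded/unfolded baselines,

    ratio(T) = [rF + mF*T + (rU + mU*T) * K(T)] / (1 + K(T)),
    K(T) = exp[-(dH/R) * (1/T_K - 1/Tm_K)],   T_K in kelvin,

which is the default reportable. Concentration series of a chemical are
classified into stability groups by the total Tm shift across the series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

__all__ = [
    "MeltCurve",
    "TwoStateFit",
    "ChemicalSeries",
    "SeriesClassification",
    "NoTransitionError",
    "FitFailureError",
    "ratio_curve",
    "tm_derivative",
    "fit_two_state",
    "delta_tm",
    "classify_series",
    "two_state_ratio",
]

R_KJ = 8.314462618e-3  # gas constant, kJ/(mol K)
KELVIN = 273.15


class NoTransitionError(ValueError):
    """The curve shows no interior unfolding transition."""


class FitFailureError(RuntimeError):
    """Nonlinear fit did not converge after bounded restarts."""


@dataclass
class MeltCurve:
    temperature: np.ndarray  # degC, strictly increasing
    ratio: np.ndarray  # F350/F330, dimensionless
    sample: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.temperature.shape != self.ratio.shape or self.temperature.ndim != 1:
            raise ValueError("temperature and ratio must be equal-length 1-D arrays")
        if len(self.temperature) < 10:
            raise ValueError("a melt curve needs at least 10 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature must be strictly increasing")
        if not np.all(np.isfinite(self.ratio)) or np.any(self.ratio <= 0):
            raise ValueError("ratio must be finite and positive")

    @property
    def span(self) -> float:
        return float(self.temperature[-1] - self.temperature[0])


@dataclass
class TwoStateFit:
    tm: float  # degC
    dH: float  # kJ/mol, apparent van 't Hoff
    folded_intercept: float
    folded_slope: float
    unfolded_intercept: float
    unfolded_slope: float
    rss: float = 0.0
    method: str = "two_state"
    at_boundary: bool = False

    def params(self) -> np.ndarray:
        return np.array(
            [
                self.tm,
                self.dH,
                self.folded_intercept,
                self.folded_slope,
                self.unfolded_intercept,
                self.unfolded_slope,
            ]
        )


def two_state_ratio(
    temperature_c: np.ndarray,
    tm_c: float,
    dH: float,
    folded_intercept: float,
    folded_slope: float,
    unfolded_intercept: float,
    unfolded_slope: float,
) -> np.ndarray:
    """Two-state equilibrium signal with linear baselines (see module docs)."""
    t = np.asarray(temperature_c, dtype=float)
    tk = t + KELVIN
    tmk = tm_c + KELVIN
    k = np.exp(-(dH / R_KJ) * (1.0 / tk - 1.0 / tmk))
    folded = folded_intercept + folded_slope * t
    unfolded = unfolded_intercept + unfolded_slope * t
    return (folded + unfolded * k) / (1.0 + k)


def ratio_curve(
    f350: np.ndarray,
    f330: np.ndarray,
    temperature: np.ndarray,
    sample: str = "",
    condition: str = "",
) -> MeltCurve:
    """Build a 350/330 ratio curve; rows are sorted by temperature and
    duplicate temperatures averaged."""
    f350 = np.asarray(f350, dtype=float)
    f330 = np.asarray(f330, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    if not (f350.shape == f330.shape == temperature.shape):
        raise ValueError("f350, f330 and temperature must have equal lengths")
    if np.any(f330 <= 0):
        raise ValueError("f330 must be positive everywhere")
    df = pd.DataFrame({"t": temperature, "r": f350 / f330}).groupby("t", sort=True).mean()
    return MeltCurve(df.index.to_numpy(), df["r"].to_numpy(), sample=sample, condition=condition)


def read_melt_csv(path, sample: str = "", condition: str = "") -> MeltCurve:
    """Read a delimited table with columns temperature_C and either
    (f350, f330) or a precomputed ratio column."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    t = df[cols["temperature_c"]].to_numpy(dtype=float)
    if "ratio" in cols:
        order = np.argsort(t)
        return MeltCurve(t[order], df[cols["ratio"]].to_numpy(dtype=float)[order],
                         sample=sample, condition=condition)
    return ratio_curve(df[cols["f350"]].to_numpy(dtype=float),
                       df[cols["f330"]].to_numpy(dtype=float), t,
                       sample=sample, condition=condition)


def _derivative_tm(temperature: np.ndarray, signal: np.ndarray, smooth_window: int) -> float:
    n = len(temperature)
    window = min(smooth_window, n if n % 2 == 1 else n - 1)
    if window >= 5:
        smoothed = savgol_filter(signal, window_length=window, polyorder=3)
        # the same local-polynomial filter yields the derivative directly;
        # uniform grids only (enforced upstream by MeltCurve)
        step = float(np.median(np.diff(temperature)))
        deriv = savgol_filter(signal, window_length=window, polyorder=3, deriv=1, delta=step)
        # the filter extrapolates inside the first/last half-window; clamp those
        # samples to the nearest fully-supported estimate to avoid edge spikes
        k = window // 2
        deriv[:k] = deriv[k]
        deriv[-k:] = deriv[-k - 1]
    else:
        smoothed = signal
        deriv = np.gradient(signal, temperature)
    mag = np.abs(deriv)
    # flat-curve rejection: the smoothed signal must swing well beyond its own
    # high-frequency noise
    noise_est = float(np.std(signal - smoothed))
    swing = float(smoothed.max() - smoothed.min())
    if swing <= max(10.0 * noise_est, 1e-12):
        raise NoTransitionError("signal swing indistinguishable from noise (flat curve)")
    # smoothing the derivative magnitude stabilizes peak localization against
    # noise without shifting a genuine (locally symmetric) transition midpoint
    w2 = min(21, n if n % 2 == 1 else n - 1)
    if w2 >= 5:
        mag = savgol_filter(mag, window_length=w2, polyorder=2, mode="nearest")
    peak = int(np.argmax(mag))
    if mag[peak] < 2.0 * float(np.median(mag)):
        raise NoTransitionError("no significant derivative peak (flat curve)")
    guard = min(max(w2 // 2, 1), max((n - 3) // 2, 1))
    if peak < guard or peak > n - 1 - guard:
        raise NoTransitionError("derivative extremum at scan edge; no interior transition")
    # quadratic vertex over the peak and its neighbours (least squares, +/-7)
    lo, hi = max(0, peak - 7), min(n, peak + 8)
    coeffs = np.polyfit(temperature[lo:hi], mag[lo:hi], 2)
    if coeffs[0] < 0:
        vertex = -coeffs[1] / (2.0 * coeffs[0])
        if temperature[lo] <= vertex <= temperature[hi - 1]:
            return float(vertex)
    return float(temperature[peak])


def tm_derivative(curve: MeltCurve, smooth_window: int = 7) -> float:
    """Tm (degC) from the peak of the smoothed first derivative of the ratio."""
    if curve.span < 20.0:
        raise ValueError("melt curve must span at least 20 degC")
    return _derivative_tm(curve.temperature, curve.ratio, smooth_window)


def _fit_two_state_arrays(
    temperature: np.ndarray,
    signal: np.ndarray,
    init: TwoStateFit | None = None,
    boundary_margin: float = 2.0,
) -> TwoStateFit:
    t = np.asarray(temperature, dtype=float)
    y = np.asarray(signal, dtype=float)
    n = len(t)
    t_lo, t_hi = float(t[0]), float(t[-1])

    if init is None:
        try:
            tm0 = _derivative_tm(t, y, 7)
        except NoTransitionError:
            tm0 = 0.5 * (t_lo + t_hi)
        k = max(3, n // 10)
        fold = np.polyfit(t[:k], y[:k], 1)
        unf = np.polyfit(t[-k:], y[-k:], 1)
        init = TwoStateFit(
            tm=tm0, dH=300.0,
            folded_intercept=float(fold[1]), folded_slope=float(fold[0]),
            unfolded_intercept=float(unf[1]), unfolded_slope=float(unf[0]),
        )

    def resid(p):
        return two_state_ratio(t, *p) - y

    scale = float(np.std(y)) or 1.0
    lower = [t_lo, 1.0, -np.inf, -np.inf, -np.inf, -np.inf]
    upper = [t_hi, 5000.0, np.inf, np.inf, np.inf, np.inf]
    p0 = init.params()
    p0[0] = np.clip(p0[0], t_lo, t_hi)
    p0[1] = np.clip(p0[1], 1.0, 5000.0)

    best = None
    rng = np.random.default_rng(20260918)  # fixed sub-seeds for jittered restarts
    for attempt in range(4):
        if attempt == 0:
            start = p0.copy()
        else:
            start = p0.copy()
            start[0] = np.clip(p0[0] + rng.normal(0, 3.0), t_lo, t_hi)
            start[1] = np.clip(p0[1] * rng.uniform(0.5, 2.0), 1.0, 5000.0)
        try:
            sol = least_squares(resid, start, bounds=(lower, upper), method="trf")
        except Exception:
            continue
        if not sol.success:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[1]:
            best = (sol.x, rss)
        if best[1] < (1e-3 * scale) ** 2 * n or attempt == 0 and sol.success:
            break
    if best is None:
        raise FitFailureError("two-state fit failed to converge after 4 starts")
    p, rss = best
    at_boundary = bool(p[0] <= t_lo + boundary_margin or p[0] >= t_hi - boundary_margin)
    return TwoStateFit(
        tm=float(p[0]), dH=float(p[1]),
        folded_intercept=float(p[2]), folded_slope=float(p[3]),
        unfolded_intercept=float(p[4]), unfolded_slope=float(p[5]),
        rss=rss, method="two_state", at_boundary=at_boundary,
    )


def fit_two_state(curve: MeltCurve, init: TwoStateFit | None = None) -> TwoStateFit:
    """Nonlinear least-squares two-state fit of a ratio melt curve.

    The fitted Tm is flagged ``at_boundary`` when it lands within 2 degC of
    the scan edge — such a Tm is never a reliable interior estimate.
    """
    if curve.span < 20.0:
        raise ValueError("melt curve must span at least 20 degC")
    return _fit_two_state_arrays(curve.temperature, curve.ratio, init=init)


def delta_tm(sample: TwoStateFit, reference: TwoStateFit) -> float:
    """Tm shift of sample relative to reference (degC)."""
    return float(sample.tm - reference.tm)


@dataclass
class ChemicalSeries:
    chemical: str
    concentrations: np.ndarray  # % v/v, ascending after normalization
    tm_values: np.ndarray  # (n_conc, n_proteins), degC
    proteins: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        tm = np.atleast_2d(np.asarray(self.tm_values, dtype=float))
        if tm.shape[0] != len(conc):
            tm = tm.T
        if tm.shape[0] != len(conc):
            raise ValueError("tm_values and concentrations lengths differ")
        order = np.argsort(conc)
        self.concentrations = conc[order]
        self.tm_values = tm[order]
        if not self.proteins:
            self.proteins = [f"protein_{i + 1}" for i in range(tm.shape[1])]


@dataclass
class SeriesClassification:
    group: str  # "A" (flat), "B" (intermediate), "C" (drastic)
    stabilizer: bool
    total_shift: float  # degC
    gap_preserved: bool | None  # defined only for two-protein series


def classify_series(
    series: ChemicalSeries,
    flat_tol: float = 2.0,
    drastic_tol: float = 10.0,
) -> SeriesClassification:
    """Assign a chemical's concentration series to a stability group.

    total_shift = Tm(max conc) - Tm(0), averaged over proteins. Group A when
    |shift| <= flat_tol (stable even at high co-solvent), group C when
    |shift| >= drastic_tol, else B. A positive shift marks a stabilizer
    (glycerol-like). For two-protein series ``gap_preserved`` reports whether
    the inter-protein Tm gap stays within flat_tol of its zero-concentration
    value at every concentration.
    """
    conc = series.concentrations
    if len(conc) < 3:
        raise ValueError("a series needs at least 3 concentration points")
    if conc[0] != 0:
        raise ValueError("the series must include a zero-concentration reference")
    shifts = series.tm_values[-1] - series.tm_values[0]
    total_shift = float(shifts.mean())
    if abs(total_shift) <= flat_tol:
        group = "A"
    elif abs(total_shift) >= drastic_tol:
        group = "C"
    else:
        group = "B"
    gap_preserved: bool | None = None
    if series.tm_values.shape[1] == 2:
        gap = series.tm_values[:, 1] - series.tm_values[:, 0]
        gap_preserved = bool(np.max(np.abs(gap - gap[0])) <= flat_tol)
    return SeriesClassification(
        group=group,
        stabilizer=total_shift > 0,
        total_shift=total_shift,
        gap_preserved=gap_preserved,
    )
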