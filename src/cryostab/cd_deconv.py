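"""CD secondary-structure deconvolution over a thermal ramp.

Each spectrum (delta-epsilon vs wavelength, 190-250 nm) is decomposed into
fractions of four components (helix, beta, turn, other) by non-negative least
squares with a sum-to-one constraint, against a packaged synthetic basis. The
basis is a transparent stand-in built from Gaussian band shapes with the
canonical qualitative features (helix: + ~192 nm, - 208/222 nm; beta: + ~196,
- ~218; coil: strong negative ~198); it is not a measured reference set, so
absolute fractions are only meaningful against this basis. Unfolding onset is
detected as sustained divergence from a low-temperature baseline, and a
single-wavelength melt trace (default 210 nm, the helix band) yields a Tm via
the two-state machinery shared with the fluorescence module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .melt import NoTransitionError, TwoStateFit, _derivative_tm, _fit_two_state_arrays

__all__ = [
    "CDSpectrum",
    "BasisSet",
    "FractionTrajectory",
    "reference_basis",
    "deconvolve_fractions",
    "fraction_trajectory",
    "onset_temperature",
    "tm_at_wavelength",
]

COMPONENTS = ("helix", "beta", "turn", "other")
DEFAULT_GRID = np.arange(190.0, 250.0 + 0.25, 0.5)  # nm


@dataclass
class CDSpectrum:
    wavelength: np.ndarray  # nm, ascending uniform grid
    delta_epsilon: np.ndarray  # M^-1 cm^-1
    temperature: float  # degC

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.delta_epsilon = np.asarray(self.delta_epsilon, dtype=float)
        if self.wavelength.shape != self.delta_epsilon.shape:
            raise ValueError("wavelength and delta_epsilon lengths differ")
        steps = np.diff(self.wavelength)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ValueError("wavelength grid must be ascending and uniform")
        if not np.all(np.isfinite(self.delta_epsilon)):
            raise ValueError("delta_epsilon must be finite")


@dataclass
class BasisSet:
    names: tuple[str, ...]
    wavelength: np.ndarray  # nm
    spectra: np.ndarray  # (n_components, n_wavelengths)

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.shape != (len(self.names), len(self.wavelength)):
            raise ValueError("spectra shape must be (n_components, n_wavelengths)")
        if np.linalg.matrix_rank(self.spectra) < len(self.names):
            raise ValueError("basis spectra are linearly dependent on this grid")


@dataclass
class FractionTrajectory:
    temperatures: np.ndarray  # degC, ascending
    fractions: np.ndarray  # (n_temps, 4), each row on the simplex
    residuals: np.ndarray  # per-temperature fit residual norm

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fractions, columns=list(COMPONENTS))
        df.insert(0, "temperature_C", self.temperatures)
        df["residual"] = self.residuals
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def reference_basis(wavelength: np.ndarray | None = None) -> BasisSet:
    """Packaged synthetic four-component basis (delta-epsilon units).

    Band positions/amplitudes follow textbook far-UV CD phenomenology; the
    set is a synthetic stand-in, not a measured protein reference library.
    """
    wl = DEFAULT_GRID if wavelength is None else np.asarray(wavelength, dtype=float)
    helix = 22.0 * _gauss(wl, 192, 8) - 11.0 * _gauss(wl, 209, 9) - 10.5 * _gauss(wl, 222, 10)
    beta = 7.5 * _gauss(wl, 196, 8) - 4.8 * _gauss(wl, 218, 11)
    turn = -6.0 * _gauss(wl, 190, 6) + 5.5 * _gauss(wl, 205, 8) - 2.5 * _gauss(wl, 222, 12)
    other = -14.0 * _gauss(wl, 198, 9) + 1.2 * _gauss(wl, 220, 20)
    return BasisSet(COMPONENTS, wl, np.vstack([helix, beta, turn, other]))


def _common_grid(spectrum: CDSpectrum, basis: BasisSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample basis onto the spectrum grid (linear) over the overlap."""
    if spectrum.wavelength.shape == basis.wavelength.shape and np.allclose(
        spectrum.wavelength, basis.wavelength
    ):
        return spectrum.wavelength, spectrum.delta_epsilon, basis.spectra
    lo = max(spectrum.wavelength[0], basis.wavelength[0])
    hi = min(spectrum.wavelength[-1], basis.wavelength[-1])
    if hi - lo < 50.0:
        raise ValueError("spectrum and basis overlap by less than 50 nm")
    mask = (spectrum.wavelength >= lo) & (spectrum.wavelength <= hi)
    wl = spectrum.wavelength[mask]
    resampled = np.vstack(
        [np.interp(wl, basis.wavelength, b) for b in basis.spectra]
    )
    return wl, spectrum.delta_epsilon[mask], resampled


def deconvolve_fractions(
    spectrum: CDSpectrum, basis: BasisSet
) -> tuple[np.ndarray, float]:
    """Simplex-constrained decomposition of one spectrum.

    Minimizes ||y - sum f_i b_i||^2 subject to f_i >= 0 with the sum-to-one
    constraint imposed through an augmented equation weighted at 100x the mean
    basis-row norm; the solution is renormalized onto the simplex. Returns
    (fractions, residual norm on the data block).
    """
    wl, y, B = _common_grid(spectrum, basis)
    if np.linalg.matrix_rank(B) < B.shape[0]:
        raise ValueError("basis is rank-deficient on the working grid")
    w = 100.0 * float(np.mean(np.linalg.norm(B, axis=1)))
    A = np.hstack([B, np.full((B.shape[0], 1), w)])  # rows: components
    rhs = np.concatenate([y, [w]])
    f, _ = nnls(A.T, rhs)
    total = f.sum()
    if total <= 0:
        raise ValueError("degenerate spectrum: all-zero solution")
    f = f / total
    residual = float(np.linalg.norm(y - f @ B))
    return f, residual


def fraction_trajectory(
    series: list[CDSpectrum], basis: BasisSet
) -> FractionTrajectory:
    """Per-temperature deconvolution of an ascending-temperature series."""
    if len(series) < 2:
        raise ValueError("a trajectory needs at least 2 temperatures")
    temps = np.array([s.temperature for s in series], dtype=float)
    if np.any(np.diff(temps) <= 0):
        raise ValueError("series temperatures must be strictly ascending")
    fractions = np.empty((len(series), len(basis.names)))
    residuals = np.empty(len(series))
    for i, spec in enumerate(series):
        fractions[i], residuals[i] = deconvolve_fractions(spec, basis)
    return FractionTrajectory(temps, fractions, residuals)


def onset_temperature(series: list[CDSpectrum], z: float = 3.0) -> float | None:
    """Lowest temperature at which the spectrum departs from the cold baseline
    (RMS z-score > z) and stays departed at every higher temperature.

    The baseline is the mean and per-wavelength SD of the 3 lowest-temperature
    spectra; each wavelength's SD is floored at the median SD so that a
    3-spectrum variance estimate cannot blow up single-wavelength z-scores.
    Returns None when the series never departs.
    """
    if len(series) < 5:
        raise ValueError("onset detection needs at least 5 temperatures")
    temps = np.array([s.temperature for s in series])
    order = np.argsort(temps)
    series = [series[i] for i in order]
    temps = temps[order]
    base = np.vstack([s.delta_epsilon for s in series[:3]])
    mu = base.mean(axis=0)
    sd = base.std(axis=0, ddof=1)
    floor = float(np.median(sd))
    if floor <= 0:
        floor = max(float(sd.max()), 1e-12)
    sd = np.maximum(sd, floor)
    zscores = np.array(
        [float(np.sqrt(np.mean(((s.delta_epsilon - mu) / sd) ** 2))) for s in series]
    )
    exceeded = zscores > z
    # sustained exceedance: all temperatures from the onset upward
    for i in range(len(series)):
        if exceeded[i:].all() and exceeded[i]:
            return float(temps[i])
    return None


def tm_at_wavelength(
    series: list[CDSpectrum], wavelength: float = 210.0
) -> tuple[float, TwoStateFit | None]:
    """Tm (degC) from the single-wavelength melt trace at the nearest grid
    wavelength (default 210 nm, tracking the helix band).

    A two-state fit is attempted first; if it fails or pins to the scan edge,
    the smoothed-derivative estimate is returned. Returns (tm, fit-or-None).
    """
    if len(series) < 10:
        raise ValueError("need at least 10 temperatures for a melt trace")
    temps = np.array([s.temperature for s in series], dtype=float)
    order = np.argsort(temps)
    temps = temps[order]
    grid = series[order[0]].wavelength
    idx = int(np.argmin(np.abs(grid - wavelength)))
    trace = np.array([series[i].delta_epsilon[idx] for i in order])
    if temps[-1] - temps[0] < 20.0:
        raise ValueError("melt trace must span at least 20 degC")
    # reject flat traces up front so both methods fail consistently
    _ = _derivative_tm(temps, trace, 7)  # raises NoTransitionError when flat
    try:
        fit = _fit_two_state_arrays(temps, trace)
        if not fit.at_boundary:
            return fit.tm, fit
    except Exception as exc:
        if isinstance(exc, NoTransitionError):
            raise
    return _derivative_tm(temps, trace, 7), None


def read_cd_matrix(path) -> list[CDSpectrum]:
    """Read a CSV matrix: first column wavelength_nm, remaining columns named
    by temperature in degC."""
    df = pd.read_csv(path)
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    out = []
    for col in df.columns[1:]:
        out.append(CDSpectrum(wl, df[col].to_numpy(dtype=float), float(col)))
    out.sort(key=lambda s: s.temperature)
    return out


def write_cd_matrix(series: list[CDSpectrum], path) -> None:
    df = pd.DataFrame({"wavelength_nm": series[0].wavelength})
    for s in series:
        df[f"{s.temperature:g}"] = s.delta_epsilon
    df.to_csv(path, index=False)
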