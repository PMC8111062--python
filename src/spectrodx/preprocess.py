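"""Spectral preprocessing: region selection, baseline correction, smoothing,
normalisation, and the fixed-order pipeline that produces classifier features.

The pipeline order is fixed as region -> baseline -> smooth -> normalise.
Normalising last makes the features scale-free, which cancels the
multiplicative droplet-thickness variation the simulator injects per well.
Defaults follow conventional serum-FTIR chemometrics: fingerprint region
1800-900 cm^-1, rubberband (convex-hull) baseline, no smoothing, unit
vector normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import (
    DegenerateInputError,
    IncompatibleGridError,
    InvalidConfigError,
    InvalidInputError,
)
from .simulate import Spectrum

__all__ = [
    "PreprocessConfig",
    "select_region",
    "baseline_correct",
    "smooth",
    "normalise",
    "preprocess_pipeline",
]


@dataclass(frozen=True)
class PreprocessConfig:
    region_lo: float = 900.0
    region_hi: float = 1800.0
    baseline_method: str = "rubberband"  # none | polynomial | rubberband
    baseline_degree: int = 2
    smooth_window: int | None = None  # odd window length; None disables
    smooth_polyorder: int = 2
    normalise: str = "vector_unit"  # none | vector_unit | minmax

    def __post_init__(self) -> None:
        if self.region_lo >= self.region_hi:
            raise InvalidConfigError("region_lo must be < region_hi")
        if self.baseline_method not in ("none", "polynomial", "rubberband"):
            raise InvalidConfigError(f"unknown baseline_method {self.baseline_method!r}")
        if self.baseline_method == "polynomial" and self.baseline_degree < 0:
            raise InvalidConfigError("baseline_degree must be >= 0")
        if self.smooth_window is not None:
            if self.smooth_window < 3 or self.smooth_window % 2 == 0:
                raise InvalidConfigError("smooth_window must be an odd integer >= 3")
            if self.smooth_polyorder >= self.smooth_window:
                raise InvalidConfigError("smooth_polyorder must be < smooth_window")
        if self.normalise not in ("none", "vector_unit", "minmax"):
            raise InvalidConfigError(f"unknown normalise method {self.normalise!r}")


def _replace(s: Spectrum, wavenumbers: np.ndarray, absorbances: np.ndarray) -> Spectrum:
    return Spectrum(s.patient_id, s.well, s.scan, wavenumbers, absorbances)


def select_region(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Restrict a spectrum to wavenumbers in [lo, hi], preserving grid order."""
    if lo > hi:
        lo, hi = hi, lo
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if not mask.any():
        raise InvalidInputError(f"region [{lo}, {hi}] does not overlap the grid")
    return _replace(spectrum, spectrum.wavenumbers[mask], spectrum.absorbances[mask])


def _rubberband_baseline(wn: np.ndarray, ab: np.ndarray) -> np.ndarray:
    """Lower convex-hull envelope of the spectrum, linearly interpolated.

    Works on an ascending copy of the grid; the classic chemometric
    'rubberband' stretched under the spectrum.
    """
    order = np.argsort(wn)
    x, y = wn[order], ab[order]
    # Andrew's monotone chain, lower hull only.
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            cross = (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    base_sorted = np.interp(x, x[hull], y[hull])
    base = np.empty_like(base_sorted)
    base[order] = base_sorted
    return base


def baseline_correct(spectrum: Spectrum, config: PreprocessConfig) -> Spectrum:
    """Subtract an estimated baseline.

    ``polynomial`` fits a least-squares polynomial of ``baseline_degree`` to
    the whole trace and subtracts it; ``rubberband`` subtracts the lower
    convex-hull envelope (result is then >= 0 up to rounding).
    """
    n = spectrum.wavenumbers.size
    if config.baseline_method == "none":
        return spectrum
    if config.baseline_method == "polynomial":
        if n < config.baseline_degree + 2:
            raise InvalidInputError(
                f"need >= {config.baseline_degree + 2} points for degree "
                f"{config.baseline_degree} baseline, got {n}"
            )
        coeffs = np.polynomial.polynomial.polyfit(
            spectrum.wavenumbers, spectrum.absorbances, config.baseline_degree
        )
        base = np.polynomial.polynomial.polyval(spectrum.wavenumbers, coeffs)
    else:  # rubberband
        if n < 3:
            raise InvalidInputError(f"need >= 3 points for rubberband baseline, got {n}")
        base = _rubberband_baseline(spectrum.wavenumbers, spectrum.absorbances)
    return _replace(spectrum, spectrum.wavenumbers, spectrum.absorbances - base)


def smooth(spectrum: Spectrum, window: int, polyorder: int) -> Spectrum:
    """Savitzky-Golay smoothing; exactly reproduces polynomials of degree <= polyorder."""
    n = spectrum.wavenumbers.size
    if window % 2 == 0 or window < 3 or window > n:
        raise InvalidInputError(f"window must be odd, >= 3 and <= {n}, got {window}")
    if polyorder >= window:
        raise InvalidInputError("polyorder must be < window")
    ab = savgol_filter(spectrum.absorbances, window, polyorder)
    return _replace(spectrum, spectrum.wavenumbers, ab)


def normalise(spectrum: Spectrum, method: str) -> Spectrum:
    """Scale absorbances: ``vector_unit`` to Euclidean norm 1, ``minmax`` to [0, 1]."""
    ab = spectrum.absorbances
    if method == "none":
        return spectrum
    if method == "vector_unit":
        nrm = float(np.linalg.norm(ab))
        if nrm == 0.0:
            raise DegenerateInputError("cannot vector-normalise a zero spectrum")
        return _replace(spectrum, spectrum.wavenumbers, ab / nrm)
    if method == "minmax":
        lo, hi = float(ab.min()), float(ab.max())
        if hi == lo:
            raise DegenerateInputError("cannot min-max normalise a constant spectrum")
        return _replace(spectrum, spectrum.wavenumbers, (ab - lo) / (hi - lo))
    raise InvalidConfigError(f"unknown normalise method {method!r}")


def preprocess_pipeline(
    spectra: Sequence[Spectrum], config: PreprocessConfig
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Apply region -> baseline -> smooth -> normalise to every spectrum.

    All input spectra must share one wavenumber grid.  Returns the feature
    matrix (one row per spectrum), the common feature grid, and an index
    frame with columns ``patient_id``, ``well``, ``scan`` aligned to the rows.
    """
    if not spectra:
        raise InvalidInputError("no spectra to preprocess")
    grid0 = spectra[0].wavenumbers
    for s in spectra:
        if s.wavenumbers.shape != grid0.shape or not np.array_equal(s.wavenumbers, grid0):
            raise IncompatibleGridError(
                f"spectrum {s.patient_id}/w{s.well}/s{s.scan} is on a different grid"
            )
    rows = []
    for s in spectra:
        out = select_region(s, config.region_lo, config.region_hi)
        out = baseline_correct(out, config)
        if config.smooth_window is not None:
            out = smooth(out, config.smooth_window, config.smooth_polyorder)
        out = normalise(out, config.normalise)
        rows.append(out)
    feature_grid = rows[0].wavenumbers
    X = np.vstack([r.absorbances for r in rows])
    index = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in spectra],
            "well": [s.well for s in spectra],
            "scan": [s.scan for s in spectra],
        }
    )
    return X, feature_grid, index
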