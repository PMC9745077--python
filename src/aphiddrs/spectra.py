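"""Narrow-band spectra and broadband sensor resampling.

A field spectroradiometer measures canopy reflectance on a ~1 nm grid; a
multispectral satellite sensor integrates that signal through per-band
spectral response functions.  ``resample_spectrum`` performs the simulation
of the broadband measurement as the response-weighted mean of the
narrow-band reflectance,

    R_b = sum_i w_b(lambda_i) r(lambda_i) / sum_i w_b(lambda_i),

which preserves constant spectra (a flat reflectance resamples to itself in
every band).  True Sentinel-2B response curves are not bundled; Gaussian
surrogates centered on the published band centers with nominal bandwidths
are the default, and measured response tables can be loaded from CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import DEFAULT_FWHM_NM, BandSet, SENTINEL2B_WORKING

__all__ = [
    "Spectrum",
    "ResponseFunction",
    "BandVector",
    "make_gaussian_response",
    "default_responses",
    "resample_spectrum",
    "read_spectral_library",
    "write_spectral_library",
    "read_response_table",
]


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed reflectance curve.

    Parameters
    ----------
    wavelengths : array of float
        Wavelengths in nm, strictly increasing.
    reflectance : array of float
        Unitless reflectance fractions, finite and non-negative, one per
        wavelength.
    label : str, optional
        Class or severity-grade tag.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if w.ndim != 1 or r.shape != w.shape:
            raise ValueError("wavelengths and reflectance must be 1-D and equal length")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise ValueError("reflectance must be finite")
        if np.any(r < 0):
            raise ValueError("reflectance must be non-negative")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "reflectance", r)

    def value_at(self, wavelength_nm: float) -> float:
        """Linearly interpolated reflectance at a wavelength inside the grid."""
        w = self.wavelengths
        if not (w[0] <= wavelength_nm <= w[-1]):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside spectrum range "
                f"[{w[0]}, {w[-1]}] nm"
            )
        return float(np.interp(wavelength_nm, w, self.reflectance))


@dataclass(frozen=True)
class ResponseFunction:
    """Per-band spectral sensitivity used to integrate a narrow-band spectrum.

    Weights are non-negative, not all zero; the normalized weighted mean of a
    constant spectrum returns that constant.
    """

    band_name: str
    wavelengths: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        s = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or s.shape != w.shape:
            raise ValueError("wavelengths and weights must be 1-D and equal length")
        if np.any(s < 0):
            raise ValueError(f"response weights for {self.band_name} must be >= 0")
        if not np.any(s > 0):
            raise ValueError(f"response weights for {self.band_name} are all zero")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "weights", s)


@dataclass(frozen=True)
class BandVector:
    """Per-band reflectance of one pixel/sample, aligned to a BandSet."""

    values: np.ndarray
    band_set: BandSet = SENTINEL2B_WORKING

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) != len(self.band_set):
            raise ValueError(
                f"expected {len(self.band_set)} band values, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("band values must be finite")
        object.__setattr__(self, "values", v)

    def __getitem__(self, band_name: str) -> float:
        return float(self.values[self.band_set.index(band_name)])


def make_gaussian_response(
    center_nm: float, fwhm_nm: float, grid_nm: np.ndarray, band_name: str = ""
) -> ResponseFunction:
    """Gaussian surrogate response centered at ``center_nm`` with the given FWHM.

    Raises
    ------
    ValueError
        If the center lies outside the grid span (names the band).
    """
    grid = np.asarray(grid_nm, dtype=float)
    if fwhm_nm <= 0:
        raise ValueError("fwhm must be positive")
    if not (grid.min() <= center_nm <= grid.max()):
        raise ValueError(
            f"band {band_name or f'{center_nm} nm'}: center {center_nm} nm outside "
            f"grid span [{grid.min()}, {grid.max()}] nm"
        )
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    weights = np.exp(-0.5 * ((grid - center_nm) / sigma) ** 2)
    return ResponseFunction(band_name or f"{center_nm:.1f}nm", grid, weights)


def default_responses(
    grid_nm: np.ndarray, band_set: BandSet = SENTINEL2B_WORKING
) -> list[ResponseFunction]:
    """Gaussian surrogate responses for every band of ``band_set``."""
    return [
        make_gaussian_response(
            b.center_nm, DEFAULT_FWHM_NM.get(b.name, 30.0), grid_nm, b.name
        )
        for b in band_set
    ]


def resample_spectrum(
    spec: Spectrum,
    responses: list[ResponseFunction] | None = None,
    band_set: BandSet = SENTINEL2B_WORKING,
) -> BandVector:
    """Integrate a narrow-band spectrum into broadband reflectances.

    Each band value is the response-weighted mean sum(w*r)/sum(w) over the
    overlap of the response support and the spectrum grid.

    Raises
    ------
    ValueError
        If a band's response support does not intersect the spectrum range
        (the error names the band).
    """
    if responses is None:
        responses = default_responses(spec.wavelengths, band_set)
    if len(responses) != len(band_set):
        raise ValueError(
            f"got {len(responses)} responses for a {len(band_set)}-band set"
        )
    values = np.empty(len(responses))
    for i, rf in enumerate(responses):
        inside = (rf.wavelengths >= spec.wavelengths[0]) & (
            rf.wavelengths <= spec.wavelengths[-1]
        )
        w = rf.weights[inside]
        if not np.any(w > 0):
            raise ValueError(
                f"band {rf.band_name}: response support does not overlap the "
                f"spectrum range [{spec.wavelengths[0]}, {spec.wavelengths[-1]}] nm"
            )
        r = np.interp(rf.wavelengths[inside], spec.wavelengths, spec.reflectance)
        values[i] = np.sum(w * r) / np.sum(w)
    return BandVector(values, band_set)


# ---------------------------------------------------------------------------
# CSV interfaces


def read_spectral_library(path: str | Path) -> list[Spectrum]:
    """Read a spectral-library CSV: one ``wavelength_nm`` column plus one
    labeled column per spectrum."""
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise ValueError(f"{path}: missing 'wavelength_nm' column")
    w = df["wavelength_nm"].to_numpy(dtype=float)
    return [
        Spectrum(w, df[col].to_numpy(dtype=float), label=col)
        for col in df.columns
        if col != "wavelength_nm"
    ]


def write_spectral_library(spectra: list[Spectrum], path: str | Path) -> None:
    if not spectra:
        raise ValueError("no spectra to write")
    w = spectra[0].wavelengths
    data = {"wavelength_nm": w}
    for i, s in enumerate(spectra):
        if not np.array_equal(s.wavelengths, w):
            raise ValueError("all spectra must share one wavelength grid")
        data[s.label or f"spectrum_{i}"] = s.reflectance
    pd.DataFrame(data).to_csv(path, index=False)


def read_response_table(
    path: str | Path, band_set: BandSet = SENTINEL2B_WORKING
) -> list[ResponseFunction]:
    """Read measured response curves from CSV (band_name, wavelength_nm, weight),
    returned in band-set order."""
    df = pd.read_csv(path)
    needed = {"band_name", "wavelength_nm", "weight"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)}")
    out = []
    for name in band_set.names:
        sub = df[df["band_name"] == name].sort_values("wavelength_nm")
        if sub.empty:
            raise ValueError(f"{path}: no response rows for band {name}")
        out.append(
            ResponseFunction(
                name,
                sub["wavelength_nm"].to_numpy(dtype=float),
                sub["weight"].to_numpy(dtype=float),
            )
        )
    return out
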