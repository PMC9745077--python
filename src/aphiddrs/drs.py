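"""Derivative-of-ratio spectroscopy (DRS).

Under the two-endmember linear mixing model a pixel spectrum is

    gamma(lambda) = F1 * gamma1(lambda) + F2 * gamma2(lambda),

with gamma1 the stressed-canopy endmember and gamma2 the healthy background.
Dividing band-by-band by the background gives

    gamma / gamma2 = F2 + F1 * (gamma1 / gamma2),

and differentiating with respect to wavelength removes the constant F2 term:

    d/dlambda (gamma / gamma2) = F1 * d/dlambda (gamma1 / gamma2).

The derivative feature vector is therefore independent of the background
abundance F2 and exactly linear in the target abundance F1 — the property
that lets mixed satellite pixels be graded by canopy stress alone.

On a 10-band sensor subset the derivative is taken as the first-order
forward difference between adjacent band centers divided by the center
spacing in nm, yielding 9 features labeled by the left band of each pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .bands import BandSet, SENTINEL2B_WORKING
from .spectra import BandVector

__all__ = [
    "RatioSpectrum",
    "DRSpectrum",
    "ratio_spectrum",
    "derivative_spectrum",
    "drs_transform",
    "drs_segment_labels",
    "visible_segments",
    "nir_segment",
    "DRSTransformer",
    "DEFAULT_EPS",
]

#: Zero-divisor guard on background reflectance (reflectance units).
DEFAULT_EPS = 1e-6


@dataclass(frozen=True)
class RatioSpectrum:
    """Band-by-band ratio of a target to a background spectrum.

    Entries where the divisor fell inside the zero-guard are flagged invalid
    (``valid`` False, value NaN).
    """

    values: np.ndarray
    centers_nm: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        c = np.asarray(self.centers_nm, dtype=float)
        m = np.asarray(self.valid, dtype=bool)
        if not (v.shape == c.shape == m.shape) or v.ndim != 1:
            raise ValueError("values, centers and valid flags must align")
        if not np.all(np.isfinite(v[m])):
            raise ValueError("valid ratio entries must be finite")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "centers_nm", c)
        object.__setattr__(self, "valid", m)


@dataclass(frozen=True)
class DRSpectrum:
    """Derivative-of-ratio feature vector (ratio change per nm).

    One entry per adjacent pair of valid bands, labeled by the left band.
    """

    values: np.ndarray
    segment_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) != len(self.segment_labels):
            raise ValueError("one value per segment label required")
        if not np.all(np.isfinite(v)):
            raise ValueError("derivative values must be finite")
        object.__setattr__(self, "values", v)


def ratio_spectrum(
    target: BandVector, background: BandVector, eps: float = DEFAULT_EPS
) -> RatioSpectrum:
    """Elementwise target/background ratio with a zero-divisor guard.

    Raises
    ------
    ValueError
        If the two vectors are aligned to different band sets.
    """
    if target.band_set.names != background.band_set.names:
        raise ValueError(
            f"misaligned band sets: {target.band_set.names} vs "
            f"{background.band_set.names}"
        )
    valid = np.abs(background.values) > eps
    values = np.full(len(target.values), np.nan)
    values[valid] = target.values[valid] / background.values[valid]
    return RatioSpectrum(values, target.band_set.centers_nm, valid)


def derivative_spectrum(
    ratio: RatioSpectrum, band_set: BandSet = SENTINEL2B_WORKING
) -> DRSpectrum:
    """Forward difference of the ratio over adjacent valid bands.

    Invalid (zero-guarded) bands are dropped before differencing, so the
    feature count is (number of valid bands) - 1.

    Raises
    ------
    ValueError
        If fewer than two valid bands remain.
    """
    idx = np.flatnonzero(ratio.valid)
    if len(idx) < 2:
        raise ValueError("need at least two valid bands to differentiate")
    v = ratio.values[idx]
    c = ratio.centers_nm[idx]
    deriv = np.diff(v) / np.diff(c)
    labels = tuple(band_set.names[i] for i in idx[:-1])
    return DRSpectrum(deriv, labels)


def drs_transform(
    target: BandVector, background: BandVector, eps: float = DEFAULT_EPS
) -> DRSpectrum:
    """Ratio against the background endmember, then differentiate."""
    return derivative_spectrum(ratio_spectrum(target, background, eps), target.band_set)


def drs_segment_labels(band_set: BandSet = SENTINEL2B_WORKING) -> tuple[str, ...]:
    """Left-band labels of the DRS segments when all bands are valid."""
    return tuple(band_set.names[:-1])


def visible_segments(band_set: BandSet = SENTINEL2B_WORKING) -> tuple[str, ...]:
    """Segments whose left band center lies in the visible range (< 700 nm)."""
    return tuple(
        b.name for b in list(band_set)[:-1] if b.center_nm < 700.0
    )


def nir_segment(band_set: BandSet = SENTINEL2B_WORKING) -> str:
    """The segment lying fully on the NIR plateau (left band center >= 800 nm)."""
    for left, right in zip(list(band_set)[:-1], list(band_set)[1:]):
        if left.center_nm >= 800.0 and right.center_nm >= 800.0:
            return left.name
    raise ValueError("band set has no fully-NIR segment")


def _drs_array(X: np.ndarray, background: np.ndarray, centers: np.ndarray,
               eps: float) -> np.ndarray:
    """Vectorized DRS over rows of X; zero-guarded bands become NaN features."""
    bg = np.where(np.abs(background) > eps, background, np.nan)
    ratio = X / bg
    return np.diff(ratio, axis=-1) / np.diff(centers)


class DRSTransformer(TransformerMixin, BaseEstimator):
    """Derivative-of-ratio spectroscopy as a scikit-learn transformer.

    Transforms (n_samples, n_bands) reflectance rows into
    (n_samples, n_bands - 1) background-free derivative features.

    Parameters
    ----------
    background : array-like of shape (n_bands,), optional
        Background endmember band vector.  If None, it is estimated during
        ``fit`` as the mean of the rows whose label equals
        ``healthy_label`` (requires ``y``).
    healthy_label : int, default 0
        Label value marking background (healthy) training rows.
    eps : float, default 1e-6
        Zero-divisor guard on background reflectance.
    band_set : BandSet
        Band semantics; supplies the center wavelengths for differencing.

    Attributes
    ----------
    background_ : ndarray of shape (n_bands,)
        Background endmember used by ``transform``.
    feature_names_ : tuple of str
        Left-band segment labels of the output features.
    """

    def __init__(
        self,
        background=None,
        healthy_label: int = 0,
        eps: float = DEFAULT_EPS,
        band_set: BandSet = SENTINEL2B_WORKING,
    ):
        self.background = background
        self.healthy_label = healthy_label
        self.eps = eps
        self.band_set = band_set

    def fit(self, X, y=None):
        X = check_array(X)
        if X.shape[1] != len(self.band_set):
            raise ValueError(
                f"X has {X.shape[1]} bands, band set has {len(self.band_set)}"
            )
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (X.shape[1],):
                raise ValueError("background shape must match the band count")
        else:
            if y is None:
                raise ValueError(
                    "y is required to estimate the background from healthy rows"
                )
            y = np.asarray(y)
            healthy = X[y == self.healthy_label]
            if len(healthy) == 0:
                raise ValueError(
                    f"no rows with healthy label {self.healthy_label}"
                )
            bg = healthy.mean(axis=0)
        self.background_ = bg
        self.feature_names_ = drs_segment_labels(self.band_set)
        return self

    def transform(self, X):
        check_is_fitted(self, "background_")
        X = check_array(X)
        return _drs_array(
            X, self.background_, self.band_set.centers_nm, self.eps
        )

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_")
        return np.asarray(self.feature_names_, dtype=object)
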