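"""Sentinel-2B band semantics.

The working band subset for canopy-stress analysis is B1--B9 (442.3--943.2 nm),
the ten bands whose centers fall inside the 325--1075 nm range of a field
spectroradiometer.  SWIR bands (B10--B12) never enter the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Band",
    "BandSet",
    "SENTINEL2B_BANDS",
    "SENTINEL2B_WORKING",
    "DEFAULT_FWHM_NM",
]


@dataclass(frozen=True)
class Band:
    """One sensor band: name, center wavelength (nm), native resolution (m)."""

    name: str
    center_nm: float
    resolution_m: float


# Sentinel-2B MSI spectral characteristics (ESA published centers).
SENTINEL2B_BANDS: tuple[Band, ...] = (
    Band("B1", 442.3, 60),
    Band("B2", 492.1, 10),
    Band("B3", 559.0, 10),
    Band("B4", 665.0, 10),
    Band("B5", 703.8, 20),
    Band("B6", 739.1, 20),
    Band("B7", 779.7, 20),
    Band("B8", 833.0, 10),
    Band("B8A", 864.0, 20),
    Band("B9", 943.2, 60),
    Band("B10", 1376.9, 60),
    Band("B11", 1610.4, 20),
    Band("B12", 2185.7, 20),
)

# Nominal published FWHM bandwidths (nm) used for Gaussian response surrogates.
DEFAULT_FWHM_NM: dict[str, float] = {
    "B1": 20.0,
    "B2": 65.0,
    "B3": 35.0,
    "B4": 30.0,
    "B5": 15.0,
    "B6": 15.0,
    "B7": 20.0,
    "B8": 105.0,
    "B8A": 20.0,
    "B9": 20.0,
}


@dataclass(frozen=True)
class BandSet:
    """An ordered collection of bands defining the columns of a BandVector.

    Parameters
    ----------
    bands : tuple of Band
        Band descriptors in wavelength order; centers must be strictly
        increasing.
    """

    bands: tuple[Band, ...] = field(
        default_factory=lambda: SENTINEL2B_BANDS[:10]
    )

    def __post_init__(self) -> None:
        centers = np.asarray([b.center_nm for b in self.bands], dtype=float)
        if len(centers) < 2:
            raise ValueError("a BandSet needs at least two bands")
        if not np.all(np.diff(centers) > 0):
            raise ValueError("band centers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    @property
    def centers_nm(self) -> np.ndarray:
        return np.asarray([b.center_nm for b in self.bands], dtype=float)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"band {name!r} not in band set {self.names}") from None


#: The default ten-band working subset (B1..B9, 442.3-943.2 nm).
SENTINEL2B_WORKING = BandSet()
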