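"""Vegetation indices on Sentinel-2 band reflectances.

Ten indices commonly used in crop-stress work, in their standard literature
forms.  Band roles: Blue=B2, Green=B3, Red=B4, red-edge 1=B5, red-edge 2=B6,
NIR=B8.  Indices with a zero denominator are returned as NaN (flagged
invalid) rather than raising.
"""

from __future__ import annotations

import numpy as np

from .spectra import BandVector

__all__ = ["VI_NAMES", "vi_suite", "ndvi"]

VI_NAMES = (
    "NDVI",
    "GNDVI",
    "TVI",
    "SAVI",
    "ARVI",
    "RDVI",
    "EVI",
    "NDVI705",
    "mSR705",
    "mNDVI705",
)


def _safe_div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = den != 0
    np.divide(num, den, out=out, where=ok)
    return out


def vi_suite(bands: BandVector | None = None, **named) -> dict[str, float]:
    """Compute the ten-index suite from a BandVector (or keyword bands).

    Accepts either a :class:`BandVector` or explicit keywords
    ``blue, green, red, re1, re2, nir`` (arrays allowed, broadcast
    elementwise).  Returns a dict keyed by ``VI_NAMES``.
    """
    if bands is not None:
        blue, green, red = bands["B2"], bands["B3"], bands["B4"]
        re1, re2, nir = bands["B5"], bands["B6"], bands["B8"]
    else:
        try:
            blue, green, red = named["blue"], named["green"], named["red"]
            re1, re2, nir = named["re1"], named["re2"], named["nir"]
        except KeyError as e:
            raise ValueError(f"missing required band {e}") from None
    blue, green, red, re1, re2, nir = (
        np.asarray(x, dtype=float) for x in (blue, green, red, re1, re2, nir)
    )
    out = {
        "NDVI": _safe_div(nir - red, nir + red),
        "GNDVI": _safe_div(nir - green, nir + green),
        "TVI": 0.5 * (120.0 * (nir - green) - 200.0 * (red - green)),
        "SAVI": 1.5 * _safe_div(nir - red, nir + red + 0.5),
        "ARVI": _safe_div(nir - (2 * red - blue), nir + (2 * red - blue)),
        "RDVI": _safe_div(nir - red, np.sqrt(np.maximum(nir + red, 0.0))),
        "EVI": 2.5 * _safe_div(nir - red, nir + 6 * red - 7.5 * blue + 1),
        "NDVI705": _safe_div(re2 - re1, re2 + re1),
        "mSR705": _safe_div(re2 - blue, re1 - blue),
        "mNDVI705": _safe_div(re2 - re1, re2 + re1 - 2 * blue),
    }
    if bands is not None:
        out = {k: float(v) for k, v in out.items()}
    return out


def ndvi(nir, red):
    """(NIR - Red) / (NIR + Red); NaN where the denominator is zero."""
    return _safe_div(
        np.asarray(nir, dtype=float) - red, np.asarray(nir, dtype=float) + red
    )
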