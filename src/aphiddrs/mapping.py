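"""Raster-level pipeline stages: land-cover classification, pear/cotton mask
algebra, and pixelwise derivative-of-ratio processing.

The cotton planting area is extracted in two steps that mirror a two-date
field campaign: a five-class supervised classification of the July scene
(vegetation / buildings / roads / bare lands / clouds) yields the vegetation
mask, and an NDVI threshold on the June scene — when the pear orchard is
dense (NDVI > 0.45) but cotton is still sparse (NDVI < 0.45) — yields the
pear mask.  Cotton = vegetation AND NOT pear.  Pixels exactly at the
threshold fall to the cotton side (strict ``>`` for pear).

Rasters are 0-based row-major (row, col) arrays; band planes follow the
BandSet order.  Scene/mask files are plain multiband TIFF (band-major
planes); point tables are CSV with columns row, col, grade.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from sklearn.svm import SVC

from .bands import BandSet, SENTINEL2B_WORKING
from .drs import DEFAULT_EPS, _drs_array
from .indices import ndvi
from .spectra import BandVector
from .synthetic import SCENE_CLASSES, GroundPoints

__all__ = [
    "LANDCOVER_CLASSES",
    "SCENE_TO_LANDCOVER",
    "Scene",
    "Mask",
    "LandcoverSamples",
    "ndvi_raster",
    "classify_landcover",
    "pear_mask",
    "cotton_mask",
    "pixelwise_drs",
    "extract_point_features",
    "read_scene",
    "write_scene",
    "read_points",
    "write_points",
    "read_mask",
    "write_mask",
]

#: Supervised-classification classes, in label-code order.
LANDCOVER_CLASSES = ("vegetation", "building", "road", "bare", "cloud")

#: Scene truth class -> land-cover class (cotton and pear are both vegetation).
SCENE_TO_LANDCOVER = {
    "cotton": "vegetation",
    "pear": "vegetation",
    "bare": "bare",
    "building": "building",
    "road": "road",
    "cloud": "cloud",
}


@dataclass(frozen=True)
class Scene:
    """A multiband reflectance raster aligned to a BandSet.

    ``bands`` has shape (rows, cols, n_bands); NaN marks nodata.
    """

    bands: np.ndarray
    band_set: BandSet = SENTINEL2B_WORKING
    pixel_size_m: float = 10.0

    def __post_init__(self) -> None:
        b = np.asarray(self.bands, dtype=float)
        if b.ndim != 3 or b.shape[2] != len(self.band_set):
            raise ValueError(
                f"expected (rows, cols, {len(self.band_set)}) raster, got "
                f"shape {b.shape}"
            )
        object.__setattr__(self, "bands", b)

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[:2]

    def band(self, name: str) -> np.ndarray:
        return self.bands[:, :, self.band_set.index(name)]

    def pixel(self, row: int, col: int) -> BandVector:
        return BandVector(self.bands[row, col], self.band_set)


Mask = np.ndarray  # rows x cols boolean


@dataclass(frozen=True)
class LandcoverSamples:
    """Labeled training pixels for the five-class supervised classification."""

    rows: np.ndarray
    cols: np.ndarray
    labels: np.ndarray  # codes into LANDCOVER_CLASSES

    def __post_init__(self) -> None:
        r = np.asarray(self.rows, dtype=int)
        c = np.asarray(self.cols, dtype=int)
        l = np.asarray(self.labels, dtype=int)
        if not (r.shape == c.shape == l.shape) or r.ndim != 1 or r.size == 0:
            raise ValueError("rows, cols and labels must be 1-D, aligned, non-empty")
        object.__setattr__(self, "rows", r)
        object.__setattr__(self, "cols", c)
        object.__setattr__(self, "labels", l)

    @classmethod
    def from_truth(
        cls,
        class_truth: np.ndarray,
        n_per_class: int = 20,
        seed=0,
    ) -> "LandcoverSamples":
        """Draw training pixels from a scene-class truth map, pooled into the
        five land-cover classes."""
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        lc_truth = scene_to_landcover_truth(class_truth)
        rows, cols, labels = [], [], []
        for code in range(len(LANDCOVER_CLASSES)):
            rr, cc = np.nonzero(lc_truth == code)
            if rr.size == 0:
                continue
            pick = rng.choice(rr.size, size=min(n_per_class, rr.size), replace=False)
            rows.append(rr[pick])
            cols.append(cc[pick])
            labels.append(np.full(pick.size, code))
        return cls(np.concatenate(rows), np.concatenate(cols), np.concatenate(labels))


def scene_to_landcover_truth(class_truth: np.ndarray) -> np.ndarray:
    """Map scene-class codes to land-cover codes (-1 stays -1)."""
    out = np.full(class_truth.shape, -1, dtype=int)
    for code, name in enumerate(SCENE_CLASSES):
        out[class_truth == code] = LANDCOVER_CLASSES.index(SCENE_TO_LANDCOVER[name])
    return out


def ndvi_raster(scene: Scene) -> np.ndarray:
    """Per-pixel (B8 - B4) / (B8 + B4); nodata (NaN) propagates."""
    return ndvi(scene.band("B8"), scene.band("B4"))


def classify_landcover(
    scene: Scene,
    samples: LandcoverSamples | None = None,
    classifier: str | object = "svm",
    class_truth: np.ndarray | None = None,
) -> np.ndarray:
    """Five-class supervised classification of a scene.

    ``classifier`` may be ``"svm"`` (RBF support-vector machine, the
    default), ``"oracle"`` (returns the land-cover truth derived from
    ``class_truth`` — for exact tests), or any fitted-API sklearn classifier
    instance.

    Returns a (rows, cols) int raster of codes into LANDCOVER_CLASSES.
    """
    if classifier == "oracle":
        if class_truth is None:
            raise ValueError("oracle classifier requires class_truth")
        return scene_to_landcover_truth(class_truth)
    if samples is None:
        raise ValueError("supervised classification requires samples")
    if classifier == "svm":
        est = SVC(kernel="rbf", C=10.0, gamma="scale")
    elif isinstance(classifier, str):
        raise ValueError(f"unknown classifier {classifier!r}")
    else:
        est = classifier
    rows, cols, nb = scene.bands.shape
    X_train = scene.bands[samples.rows, samples.cols]
    classes = np.unique(samples.labels)
    if classes.size == 1:
        # degenerate training: the whole (valid) raster is that class
        flat_ok = np.all(np.isfinite(scene.bands.reshape(-1, nb)), axis=1)
        out = np.full(rows * cols, -1, dtype=int)
        out[flat_ok] = int(classes[0])
        return out.reshape(rows, cols)
    est.fit(X_train, samples.labels)
    flat = scene.bands.reshape(-1, nb)
    ok = np.all(np.isfinite(flat), axis=1)
    out = np.full(rows * cols, -1, dtype=int)
    if ok.any():
        out[ok] = est.predict(flat[ok])
    return out.reshape(rows, cols)


def pear_mask(june_scene: Scene, threshold: float = 0.45) -> Mask:
    """True where June NDVI strictly exceeds the threshold (pear orchard)."""
    if not -1.0 < threshold < 1.0:
        raise ValueError("NDVI threshold must lie in (-1, 1)")
    nd = ndvi_raster(june_scene)
    return np.asarray(nd > threshold)  # NaN compares False -> excluded


def cotton_mask(veg_mask: Mask, pear: Mask) -> Mask:
    """Vegetation minus pear orchard: veg AND NOT pear."""
    if veg_mask.shape != pear.shape:
        raise ValueError(
            f"mask shapes differ: {veg_mask.shape} vs {pear.shape}"
        )
    return veg_mask & ~pear


def pixelwise_drs(
    scene: Scene,
    background: BandVector,
    mask: Mask | None = None,
    eps: float = DEFAULT_EPS,
) -> np.ndarray:
    """Apply the DRS transform to every masked pixel.

    Returns a (rows, cols, n_bands - 1) feature raster; unmasked pixels are
    NaN in all planes, as are features whose divisor fell inside the
    zero-guard.
    """
    if background.band_set.names != scene.band_set.names:
        raise ValueError("background band set does not match the scene")
    if mask is None:
        mask = np.ones(scene.shape, dtype=bool)
    if mask.shape != scene.shape:
        raise ValueError(f"mask shape {mask.shape} != scene shape {scene.shape}")
    feats = _drs_array(
        scene.bands, background.values, scene.band_set.centers_nm, eps
    )
    feats[~mask] = np.nan
    return feats


def extract_point_features(raster: np.ndarray, points: GroundPoints) -> np.ndarray:
    """Per-point feature rows from a (rows, cols, k) feature raster."""
    return raster[points.rows, points.cols]


# ---------------------------------------------------------------------------
# File interfaces (plain multiband TIFF + CSV)


def write_scene(scene: Scene, path) -> None:
    """Write a scene as a band-major multiband TIFF with band names and pixel
    size in the image description."""
    meta = {
        "band_names": scene.band_set.names,
        "pixel_size_m": scene.pixel_size_m,
    }
    tifffile.imwrite(
        path,
        np.moveaxis(scene.bands, 2, 0),
        photometric="minisblack",
        description=json.dumps(meta),
    )


def read_scene(path, band_set: BandSet = SENTINEL2B_WORKING) -> Scene:
    """Read a scene written by :func:`write_scene`; band order and values
    round-trip losslessly.

    Raises
    ------
    ValueError
        If the file's band count does not match the configured band set.
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            pass
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a multiband raster, got shape {data.shape}")
    if data.shape[0] != len(band_set):
        raise ValueError(
            f"{path}: file has {data.shape[0]} bands, configured band set has "
            f"{len(band_set)}"
        )
    names = meta.get("band_names")
    if names is not None and list(names) != band_set.names:
        raise ValueError(
            f"{path}: band names {names} do not match configured {band_set.names}"
        )
    return Scene(
        np.moveaxis(data, 0, 2),
        band_set,
        pixel_size_m=float(meta.get("pixel_size_m", 10.0)),
    )


def write_mask(mask: Mask, path) -> None:
    tifffile.imwrite(path, mask.astype(np.uint8))


def read_mask(path) -> Mask:
    return tifffile.imread(path).astype(bool)


def write_points(points: GroundPoints, path) -> None:
    pd.DataFrame(
        {"row": points.rows, "col": points.cols, "grade": points.grades}
    ).to_csv(path, index=False)


def read_points(path) -> GroundPoints:
    df = pd.read_csv(path)
    needed = {"row", "col", "grade"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)}")
    return GroundPoints(
        df["row"].to_numpy(), df["col"].to_numpy(), df["grade"].to_numpy()
    )
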