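"""Synthetic canopy spectra, mixed-pixel scenes and ground survey points.

Emulates the statistical structure of a boll-stage cotton field under aphid
infestation as seen by a 10-band visible/NIR satellite sensor:

* canopy reflectance rises with aphid severity in the visible (chlorophyll
  loss and honeydew films brighten the leaf) and falls on the NIR plateau
  (cell-structure collapse in curled leaves), with a small leftward shift of
  the red edge;
* a satellite pixel is a two-endmember linear mixture of stressed canopy
  (fraction F1) and healthy background canopy (F2 = 1 - F1) plus additive
  Gaussian sensor noise;
* severity clusters near the field borders where aphids migrate in first;
* ground truthing yields 60 labeled points with grade counts 20/20/10/6/4.

The severity effect is multiplicative but wavelength-weighted: the visible
gain follows a smooth bump centered at 620 nm and the NIR loss a logistic
ramp with midpoint 760 nm, so the stressed/healthy reflectance ratio has
grade-dependent slope inside band segments — the feature that a
derivative-of-ratio transform reads out.  Magnitudes are surrogate values
chosen to match the qualitative field behavior, not measured curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .bands import BandSet, SENTINEL2B_WORKING
from .spectra import BandVector, Spectrum, resample_spectrum

__all__ = [
    "DEFAULT_GRID_NM",
    "GRADE_COUNTS",
    "SCENE_CLASSES",
    "GradeEffect",
    "SceneConfig",
    "GroundPoints",
    "SceneBundle",
    "healthy_base_spectrum",
    "apply_grade_effect",
    "simulate_canopy_sample",
    "mix_pixel",
    "endmember_spectra",
    "endmember_band_vectors",
    "simulate_scene",
    "generate_ground_points",
]

#: 1 nm field-spectroradiometer grid, 325-1075 nm.
DEFAULT_GRID_NM = np.arange(325.0, 1076.0, 1.0)

#: Ground-survey grade counts for grades 0..4 (total 60).
GRADE_COUNTS = (20, 20, 10, 6, 4)

#: Scene truth classes, in label-code order.
SCENE_CLASSES = ("cotton", "pear", "bare", "building", "road", "cloud")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Canopy spectra


def healthy_base_spectrum(grid_nm: np.ndarray = DEFAULT_GRID_NM) -> Spectrum:
    """Parametric healthy green-canopy reflectance curve.

    Low blue/red pigment troughs, a green bump near 550 nm, a sigmoid red
    edge with midpoint 718 nm, a NIR plateau near 0.5 and a shallow 970 nm
    water dip.
    """
    grid = np.asarray(grid_nm, dtype=float)
    if grid.min() < 325.0 or grid.max() > 1075.0:
        raise ValueError("grid must lie within 325-1075 nm")
    vis = 0.04 + 0.05 * np.exp(-0.5 * ((grid - 550.0) / 33.0) ** 2)
    edge = expit((grid - 718.0) / 9.0)
    nir = 0.50 - 0.03 * np.exp(-0.5 * ((grid - 970.0) / 20.0) ** 2)
    r = vis * (1.0 - edge) + nir * edge
    return Spectrum(grid, r, label="healthy")


def _visible_weight(grid: np.ndarray) -> np.ndarray:
    # Severity brightening is strongest in the red/orange, fading into NIR.
    return np.exp(-0.5 * ((grid - 620.0) / 90.0) ** 2)


def _nir_weight(grid: np.ndarray) -> np.ndarray:
    # Severity darkening ramps up across the red edge onto the NIR plateau.
    return expit((grid - 760.0) / 60.0)


@dataclass(frozen=True)
class GradeEffect:
    """Spectral consequence of one aphid severity grade (0 = healthy .. 4).

    ``visible_gain`` multiplies visible reflectance upward, ``nir_loss``
    multiplies NIR reflectance downward, ``red_edge_shift_nm`` moves the red
    edge to shorter wavelengths; all monotone in grade.
    """

    grade: int
    visible_gain: float
    nir_loss: float
    red_edge_shift_nm: float

    def __post_init__(self) -> None:
        if not 0 <= self.grade <= 4:
            raise ValueError("grade must be in 0..4")
        if self.grade == 0 and not (
            self.visible_gain == 1.0
            and self.nir_loss == 1.0
            and self.red_edge_shift_nm == 0.0
        ):
            raise ValueError("grade 0 must be the identity effect")
        if self.visible_gain < 1.0 or self.nir_loss > 1.0 or self.nir_loss <= 0:
            raise ValueError("visible_gain >= 1 and 0 < nir_loss <= 1 required")
        if self.red_edge_shift_nm < 0:
            raise ValueError("red_edge_shift_nm must be >= 0")

    @classmethod
    def for_grade(
        cls,
        grade: int,
        visible_gain_per_grade: float = 0.15,
        nir_loss_per_grade: float = 0.08,
        shift_nm_per_grade: float = 3.0,
    ) -> "GradeEffect":
        """Default linear-in-grade effect magnitudes."""
        return cls(
            grade=grade,
            visible_gain=1.0 + visible_gain_per_grade * grade,
            nir_loss=1.0 - nir_loss_per_grade * grade,
            red_edge_shift_nm=shift_nm_per_grade * grade,
        )


def apply_grade_effect(spec: Spectrum, effect: GradeEffect) -> Spectrum:
    """Apply a severity grade's spectral effect to a canopy spectrum.

    The red-edge shift resamples the curve at ``lambda + shift`` inside a
    smooth window around the red edge; the visible/NIR multipliers are then
    applied through their wavelength weights, blending smoothly at the
    region boundaries.
    """
    grid = spec.wavelengths
    r = spec.reflectance
    if effect.red_edge_shift_nm > 0:
        shifted = np.interp(grid + effect.red_edge_shift_nm, grid, r)
        w = np.exp(-0.5 * ((grid - 715.0) / 25.0) ** 2)
        r = (1.0 - w) * r + w * shifted
    gain = 1.0 + (effect.visible_gain - 1.0) * _visible_weight(grid)
    loss = 1.0 - (1.0 - effect.nir_loss) * _nir_weight(grid)
    out = np.clip(r * gain * loss, 0.0, 1.0)
    return Spectrum(grid, out, label=f"grade{effect.grade}")


def simulate_canopy_sample(
    grade: int,
    noise_sd: float = 0.0,
    seed=None,
    grid_nm: np.ndarray = DEFAULT_GRID_NM,
    effect: GradeEffect | None = None,
) -> Spectrum:
    """One field-sampled canopy spectrum: base + grade effect + Gaussian noise,
    clipped to [0, 1].  Reproducible given ``seed``."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if effect is None:
        effect = GradeEffect.for_grade(grade)
    clean = apply_grade_effect(healthy_base_spectrum(grid_nm), effect)
    if noise_sd == 0:
        return clean
    rng = _rng(seed)
    noisy = np.clip(
        clean.reflectance + rng.normal(0.0, noise_sd, clean.reflectance.shape),
        0.0,
        1.0,
    )
    return Spectrum(clean.wavelengths, noisy, label=clean.label)


# ---------------------------------------------------------------------------
# Linear mixing


def mix_pixel(
    endmembers: list[BandVector],
    fractions,
    noise_sd: float = 0.0,
    seed=None,
) -> BandVector:
    """Linear spectral mixture sum_j F_j * gamma_j + xi with per-band
    Gaussian noise xi ~ N(0, noise_sd).

    Raises
    ------
    ValueError
        If fractions are negative or do not sum to 1.
    """
    f = np.asarray(fractions, dtype=float)
    if len(f) != len(endmembers):
        raise ValueError("one fraction per endmember required")
    if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must be >= 0 and sum to 1, got {f}")
    band_set = endmembers[0].band_set
    stack = np.stack([e.values for e in endmembers])
    mixed = f @ stack
    if noise_sd > 0:
        mixed = mixed + _rng(seed).normal(0.0, noise_sd, mixed.shape)
    return BandVector(mixed, band_set)


# ---------------------------------------------------------------------------
# Scene endmembers


def endmember_spectra(grid_nm: np.ndarray = DEFAULT_GRID_NM) -> dict[str, Spectrum]:
    """Parametric endmember spectra for the non-cotton scene classes plus the
    seasonal cotton variants.

    ``cotton_june`` is a sparse early-season canopy (soil-dominated, NDVI
    below the pear/cotton threshold); ``pear`` is a dense orchard canopy with
    high NDVI in both months.
    """
    grid = np.asarray(grid_nm, dtype=float)
    healthy = healthy_base_spectrum(grid)
    soil = Spectrum(grid, 0.15 + 0.00020 * (grid - 325.0), label="bare")
    # Pear: denser canopy, deeper red trough, higher NIR plateau.
    edge = expit((grid - 712.0) / 9.0)
    pear_vis = 0.035 + 0.045 * np.exp(-0.5 * ((grid - 550.0) / 30.0) ** 2)
    pear = Spectrum(grid, pear_vis * (1 - edge) + 0.56 * edge, label="pear")
    cotton_june = Spectrum(
        grid,
        0.35 * healthy.reflectance + 0.65 * soil.reflectance,
        label="cotton_june",
    )
    return {
        "healthy": healthy,
        "pear": pear,
        "bare": soil,
        "building": Spectrum(grid, np.full(grid.shape, 0.35), label="building"),
        "road": Spectrum(grid, np.full(grid.shape, 0.10), label="road"),
        "cloud": Spectrum(grid, np.full(grid.shape, 0.85), label="cloud"),
        "cotton_june": cotton_june,
    }


def endmember_band_vectors(
    band_set: BandSet = SENTINEL2B_WORKING,
    grid_nm: np.ndarray = DEFAULT_GRID_NM,
) -> dict[str, BandVector]:
    """Endmember spectra resampled to the working band set, including the
    graded cotton canopies ``grade0``..``grade4``."""
    spectra = endmember_spectra(grid_nm)
    out = {
        name: resample_spectrum(s, band_set=band_set) for name, s in spectra.items()
    }
    base = healthy_base_spectrum(grid_nm)
    for g in range(5):
        stressed = apply_grade_effect(base, GradeEffect.for_grade(g))
        out[f"grade{g}"] = resample_spectrum(stressed, band_set=band_set)
    return out


# ---------------------------------------------------------------------------
# Scenes


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of one synthetic study area.

    ``class_proportions`` cover the six scene classes; within cotton,
    ``grade_proportions`` set the severity mix and ``f1_range`` the
    per-pixel stressed-canopy fraction F1 (healthy background fraction is
    F2 = 1 - F1).  ``edge_weighted`` places high grades preferentially near
    the scene border.
    """

    rows: int = 64
    cols: int = 64
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "cotton": 0.40,
            "pear": 0.15,
            "bare": 0.20,
            "building": 0.10,
            "road": 0.08,
            "cloud": 0.07,
        }
    )
    grade_proportions: tuple[float, ...] = (0.50, 0.20, 0.12, 0.10, 0.08)
    f1_range: tuple[float, float] = (0.75, 0.95)
    noise_sd: float = 0.002
    edge_weighted: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 4 or self.cols < 4:
            raise ValueError("scene must be at least 4x4")
        if set(self.class_proportions) - set(SCENE_CLASSES):
            raise ValueError(f"unknown scene classes in {self.class_proportions}")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValueError("class proportions must be >= 0")
        if abs(sum(self.grade_proportions) - 1.0) > 1e-9 or len(
            self.grade_proportions
        ) != 5:
            raise ValueError("grade proportions must be 5 values summing to 1")
        lo, hi = self.f1_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("f1_range must satisfy 0 <= lo <= hi <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundPoints:
    """Ground survey points: pixel coordinates and surveyed aphid grade."""

    rows: np.ndarray
    cols: np.ndarray
    grades: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rows, dtype=int)
        c = np.asarray(self.cols, dtype=int)
        g = np.asarray(self.grades, dtype=int)
        if not (r.shape == c.shape == g.shape) or r.ndim != 1:
            raise ValueError("rows, cols and grades must be 1-D and aligned")
        object.__setattr__(self, "rows", r)
        object.__setattr__(self, "cols", c)
        object.__setattr__(self, "grades", g)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class SceneBundle:
    """A simulated study area: July and June band rasters plus truth maps.

    ``class_truth`` holds scene-class codes (index into SCENE_CLASSES),
    ``grade_truth`` aphid grades on cotton pixels (-1 elsewhere), ``f1_truth``
    the stressed-canopy fraction per cotton pixel (NaN elsewhere).
    """

    july: "np.ndarray"
    june: "np.ndarray"
    class_truth: np.ndarray
    grade_truth: np.ndarray
    f1_truth: np.ndarray
    band_set: BandSet
    config: SceneConfig


def _clustered_field(rows: int, cols: int, rng: np.random.Generator) -> np.ndarray:
    """Smoothed Gaussian random field used to carve spatially clustered
    class/grade patches."""
    return gaussian_filter(rng.standard_normal((rows, cols)), sigma=3.0,
                           mode="reflect")


def _assign_by_quantile(score: np.ndarray, counts: list[int]) -> np.ndarray:
    """Assign codes 0..k-1 to the entries of ``score`` in rank order, with
    exact per-code counts."""
    order = np.argsort(score, kind="stable")
    out = np.empty(score.size, dtype=int)
    start = 0
    for code, cnt in enumerate(counts):
        out[order[start : start + cnt]] = code
        start += cnt
    return out


def simulate_scene(config: SceneConfig = SceneConfig()) -> SceneBundle:
    """Simulate the July (infested) and June (pear-separation) scenes.

    Cotton pixels are two-endmember mixtures F1 * grade-canopy +
    (1 - F1) * healthy-canopy plus noise; other classes are their endmember
    plus noise.  In the noise-free June scene every pear pixel has NDVI
    above 0.45 and every cotton pixel below it.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.rows, config.cols
    n_pix = rows * cols
    band_set = SENTINEL2B_WORKING
    ems = endmember_band_vectors(band_set)

    # --- class map: clustered patches with exact class counts
    counts = []
    acc = 0
    for name in SCENE_CLASSES:
        c = int(round(config.class_proportions.get(name, 0.0) * n_pix))
        counts.append(c)
        acc += c
    counts[0] += n_pix - acc  # rounding residue goes to cotton
    field2d = _clustered_field(rows, cols, rng)
    class_truth = _assign_by_quantile(field2d.ravel(), counts).reshape(rows, cols)

    # --- grade map on cotton: edge-weighted clustered severity
    grade_truth = np.full((rows, cols), -1, dtype=int)
    cotton = class_truth == 0
    idx = np.flatnonzero(cotton.ravel())
    if idx.size:
        rr, cc = np.unravel_index(idx, (rows, cols))
        if config.edge_weighted:
            d = np.minimum.reduce([rr, cc, rows - 1 - rr, cols - 1 - cc])
            edge_score = 1.0 - d / max(d.max(), 1)
        else:
            edge_score = np.zeros(idx.size)
        rough = _clustered_field(rows, cols, rng).ravel()[idx]
        rough = (rough - rough.mean()) / (rough.std() + 1e-12)
        severity = edge_score + 0.5 * rough
        gcounts = [int(round(p * idx.size)) for p in config.grade_proportions]
        gcounts[0] += idx.size - sum(gcounts)
        # rank ascending severity -> grade 0 first
        grade_flat = _assign_by_quantile(severity, gcounts)
        grade_truth.ravel()[idx] = grade_flat

    # --- F1 abundance per cotton pixel
    f1_truth = np.full((rows, cols), np.nan)
    lo, hi = config.f1_range
    f1_truth.ravel()[idx] = rng.uniform(lo, hi, idx.size)

    # --- band rasters
    nb = len(band_set)
    july = np.empty((rows, cols, nb))
    june = np.empty((rows, cols, nb))
    healthy = ems["healthy"].values
    grade_stack = np.stack([ems[f"grade{g}"].values for g in range(5)])
    june_by_class = {
        0: ems["cotton_june"].values,
        1: ems["pear"].values,
        2: ems["bare"].values,
        3: ems["building"].values,
        4: ems["road"].values,
        5: ems["cloud"].values,
    }
    july_by_class = dict(june_by_class)
    july_by_class[0] = healthy  # overwritten below with mixtures
    july_by_class[1] = ems["pear"].values
    for code in range(len(SCENE_CLASSES)):
        sel = class_truth == code
        july[sel] = july_by_class[code]
        june[sel] = june_by_class[code]
    if idx.size:
        f1 = f1_truth.ravel()[idx][:, None]
        stressed = grade_stack[grade_truth.ravel()[idx]]
        july.reshape(n_pix, nb)[idx] = f1 * stressed + (1.0 - f1) * healthy
    if config.noise_sd > 0:
        july += rng.normal(0.0, config.noise_sd, july.shape)
        june += rng.normal(0.0, config.noise_sd, june.shape)

    return SceneBundle(
        july=july,
        june=june,
        class_truth=class_truth,
        grade_truth=grade_truth,
        f1_truth=f1_truth,
        band_set=band_set,
        config=config,
    )


def generate_ground_points(
    bundle: SceneBundle,
    counts: tuple[int, ...] = GRADE_COUNTS,
    seed: int | np.random.Generator = 0,
) -> GroundPoints:
    """Sample ground survey points from the cotton truth, without replacement,
    with the given per-grade counts.

    Raises
    ------
    ValueError
        If the scene has too few cotton pixels of some grade (names the
        grade).
    """
    rng = _rng(seed)
    rows_out, cols_out, grades_out = [], [], []
    for g, cnt in enumerate(counts):
        if cnt == 0:
            continue
        rr, cc = np.nonzero(bundle.grade_truth == g)
        if rr.size < cnt:
            raise ValueError(
                f"grade {g}: need {cnt} cotton pixels, scene has {rr.size}"
            )
        pick = rng.choice(rr.size, size=cnt, replace=False)
        rows_out.append(rr[pick])
        cols_out.append(cc[pick])
        grades_out.append(np.full(cnt, g))
    return GroundPoints(
        np.concatenate(rows_out), np.concatenate(cols_out), np.concatenate(grades_out)
    )
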