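"""Synthetic data generators: Boolean canopy scenes, grayscale acquisitions,
and laboratory-by-replicate LAI estimate matrices.

The Boolean scene generator places black discs ("foliage") of a fixed radius
at uniformly random positions, with overlap allowed, until the vegetation
cover — counted exactly from the raster — reaches a target level. Under this
Boolean model the expected disc count for cover ``c`` is ``-A·ln(1-c)/a``
(``A`` image area, ``a`` disc area), the same exponential relation that links
gap fraction and LAI downstream.

The acquisition model renders a binary scene as an 8-bit grayscale image the
way a printed sheet photographed under uneven lighting would appear: two
class mean intensities (sky brighter than foliage), Gaussian blur creating
mixed pixels along disc boundaries, radial vignetting, and additive Gaussian
noise, clamped to [0, 255].

Estimate-matrix simulation mirrors the two-variance-component decomposition
that the ISO 5725 analysis estimates: a laboratory effect shared by all
replicates of one laboratory plus an independent within-laboratory error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SceneSpec",
    "BinaryScene",
    "AcquisitionModel",
    "VarianceComponents",
    "EstimateMatrix",
    "generate_boolean_scene",
    "render_acquisition",
    "simulate_estimate_matrix",
    "simulate_user_thresholds",
    "CoverUnreachableError",
]

#: Default working raster, standing in for an A4-class print of the scene.
DEFAULT_SIZE = 1200
#: Default disc radius in pixels (a 3 mm disc at the working resolution).
DEFAULT_RADIUS = 10


class CoverUnreachableError(RuntimeError):
    """Raised when the target cover cannot be hit within tolerance."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one Boolean random-disc canopy scene.

    Parameters
    ----------
    target_cover : float
        Vegetation cover fraction to hit, in [0, 1].
    circle_radius : int
        Disc radius in pixels (>= 1).
    width, height : int
        Raster size in pixels.
    cover_tolerance : float
        Maximum |achieved - target| cover accepted (> 0).
    max_circles : int
        Hard cap on the number of discs placed.
    seed : int
        Seed for disc placement.
    """

    target_cover: float
    circle_radius: int = DEFAULT_RADIUS
    width: int = DEFAULT_SIZE
    height: int = DEFAULT_SIZE
    cover_tolerance: float = 0.005
    max_circles: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_cover <= 1.0:
            raise ValueError("target_cover must be in [0, 1]")
        if self.circle_radius < 1:
            raise ValueError("circle_radius must be >= 1 pixel")
        if self.cover_tolerance <= 0:
            raise ValueError("cover_tolerance must be > 0")
        if self.width < 1 or self.height < 1:
            raise ValueError("scene must have positive size")


@dataclass(frozen=True)
class BinaryScene:
    """A rasterized Boolean canopy with exactly known cover.

    ``mask`` is boolean with ``True`` = vegetation. ``achieved_cover`` is the
    exact vegetation pixel fraction, counted from the mask — never estimated.
    """

    mask: np.ndarray
    achieved_cover: float
    spec: SceneSpec
    n_circles: int = 0

    def __post_init__(self) -> None:
        exact = float(np.count_nonzero(self.mask)) / self.mask.size
        if abs(exact - self.achieved_cover) > 1e-12:
            raise ValueError("achieved_cover does not match the mask")


@dataclass(frozen=True)
class AcquisitionModel:
    """Grayscale rendering model: class means, blur, vignetting, noise.

    ``mean_background_intensity`` (sky) must exceed
    ``mean_vegetation_intensity`` (foliage). ``blur_radius`` is the Gaussian
    sigma in pixels and is what creates mixed pixels at disc boundaries;
    ``vignetting_strength`` in [0, 1) darkens the frame radially from the
    centre by a factor ``1 - s·(d/d_max)²``.
    """

    mean_vegetation_intensity: float = 40.0
    mean_background_intensity: float = 220.0
    noise_sd: float = 8.0
    blur_radius: float = 1.5
    vignetting_strength: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_background_intensity > self.mean_vegetation_intensity:
            raise ValueError("background (sky) must be brighter than vegetation")
        if not 0.0 <= self.vignetting_strength < 1.0:
            raise ValueError("vignetting_strength must be in [0, 1)")
        if self.noise_sd < 0 or self.blur_radius < 0:
            raise ValueError("noise_sd and blur_radius must be >= 0")


@dataclass(frozen=True)
class VarianceComponents:
    """Generative counterparts of the repeatability / between-lab variances.

    ``sigma_within`` is the within-laboratory (repeatability-level) SD and
    ``sigma_between`` the between-laboratory SD, both in LAI units.
    """

    sigma_within: float
    sigma_between: float

    def __post_init__(self) -> None:
        if self.sigma_within < 0 or self.sigma_between < 0:
            raise ValueError("variance components must be >= 0")


@dataclass(frozen=True)
class EstimateMatrix:
    """p laboratories × n replicates of LAI estimates for one entity.

    ``values[l, k]`` is the k-th replicate of laboratory l, in one-sided leaf
    area per ground area (dimensionless). ``true_mean`` is set only for
    simulated matrices. Balanced designs only: no missing cells.
    """

    values: np.ndarray
    entity_id: str = ""
    canopy_class: str = ""
    true_mean: float | None = None
    labs: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D labs × replicates array")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("need at least 2 laboratories and 2 replicates")
        if not np.all(np.isfinite(v)):
            raise ValueError("missing cells are not allowed")
        if np.any(v < 0):
            raise ValueError("LAI estimates must be >= 0")
        object.__setattr__(self, "values", v)
        if not self.labs:
            object.__setattr__(
                self, "labs", tuple(chr(ord("A") + i) for i in range(v.shape[0]))
            )
        elif len(self.labs) != v.shape[0]:
            raise ValueError("labs must label every row")

    @property
    def n_labs(self) -> int:
        return self.values.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]


def _disc_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer offsets of the rasterized disc |dx|²+|dy|² <= r²."""
    r = int(radius)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    inside = dx * dx + dy * dy <= r * r
    return dy[inside], dx[inside]


def disc_pixel_area(radius: int) -> int:
    """Exact pixel count of the rasterized disc used by the generator."""
    return int(_disc_offsets(radius)[0].size)


def generate_boolean_scene(spec: SceneSpec) -> BinaryScene:
    """Generate a Boolean random-disc scene hitting ``target_cover``.

    Discs with centres uniform over the raster are stamped sequentially
    (overlap allowed) until the exact vegetation fraction reaches the target.
    Boundaries are periodic (discs wrap around the edges), so the Boolean
    density relation ``cover = 1 - exp(-n·a/A)`` holds without edge bias.
    Deterministic for a fixed ``spec.seed``.

    Raises
    ------
    CoverUnreachableError
        If ``max_circles`` is exhausted first, or a single disc overshoots
        the target by more than ``cover_tolerance`` (radius too coarse for
        the requested control).
    """
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=bool)
    total = h * w
    if spec.target_cover == 0.0:
        return BinaryScene(mask=mask, achieved_cover=0.0, spec=spec, n_circles=0)

    rng = np.random.default_rng(spec.seed)
    dy, dx = _disc_offsets(spec.circle_radius)
    flat_mask = mask.ravel()
    covered = 0
    n = 0
    target_px = spec.target_cover * total
    while covered < target_px:
        if n >= spec.max_circles:
            raise CoverUnreachableError(
                f"placed {n} discs but cover {covered / total:.4f} "
                f"< target {spec.target_cover:.4f}"
            )
        cy = int(rng.integers(0, h))
        cx = int(rng.integers(0, w))
        idx = np.unique(((cy + dy) % h) * w + (cx + dx) % w)
        newly = int(np.count_nonzero(~flat_mask[idx]))
        flat_mask[idx] = True
        covered += newly
        n += 1

    achieved = covered / total
    if abs(achieved - spec.target_cover) > spec.cover_tolerance:
        raise CoverUnreachableError(
            f"achieved cover {achieved:.4f} misses target "
            f"{spec.target_cover:.4f} by more than tolerance "
            f"{spec.cover_tolerance} (radius too large for fine control)"
        )
    return BinaryScene(mask=mask, achieved_cover=achieved, spec=spec, n_circles=n)


def render_acquisition(scene: BinaryScene, model: AcquisitionModel) -> np.ndarray:
    """Render a binary scene as an 8-bit grayscale acquisition.

    Vegetation / background pixels start at their class mean intensities; the
    image is then Gaussian-blurred (mixed pixels), radially vignetted,
    perturbed with Gaussian noise, and clamped to [0, 255]. Deterministic for
    a fixed ``model.seed``. Returns a ``uint8`` array shaped like the mask.
    """
    img = np.where(
        scene.mask,
        model.mean_vegetation_intensity,
        model.mean_background_intensity,
    ).astype(float)

    if model.blur_radius > 0:
        img = ndimage.gaussian_filter(img, sigma=model.blur_radius)

    if model.vignetting_strength > 0:
        h, w = img.shape
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        yy, xx = np.ogrid[:h, :w]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        img *= 1.0 - model.vignetting_strength * d2 / d2.max()

    if model.noise_sd > 0:
        rng = np.random.default_rng(model.seed)
        img = img + rng.normal(0.0, model.noise_sd, size=img.shape)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def simulate_estimate_matrix(
    true_mean: float,
    vc: VarianceComponents,
    p: int = 4,
    n: int = 4,
    seed: int = 0,
    entity_id: str = "",
    canopy_class: str = "",
) -> EstimateMatrix:
    """Simulate a p×n laboratory-by-replicate LAI estimate matrix.

    ``value[l, k] = true_mean + B_l + e_lk`` with ``B_l ~ N(0, σ_between²)``
    shared across a laboratory's replicates and ``e_lk ~ N(0, σ_within²)``
    independent; values are truncated at 0 (LAI is non-negative).
    """
    if true_mean < 0:
        raise ValueError("true_mean must be >= 0")
    if p < 2 or n < 2:
        raise ValueError("need p >= 2 laboratories and n >= 2 replicates")
    rng = np.random.default_rng(seed)
    lab_effect = rng.normal(0.0, vc.sigma_between, size=(p, 1))
    noise = rng.normal(0.0, vc.sigma_within, size=(p, n))
    values = np.maximum(true_mean + lab_effect + noise, 0.0)
    return EstimateMatrix(
        values=values,
        entity_id=entity_id,
        canopy_class=canopy_class,
        true_mean=true_mean,
    )


def simulate_user_thresholds(
    optimal: float,
    user_bias_sd: float,
    session_sd: float,
    p: int = 4,
    n: int = 4,
    seed: int = 0,
) -> np.ndarray:
    """Simulate the segmentation thresholds p users would pick in n sessions.

    ``threshold[l, k] = optimal + U_l + s_lk`` with a per-user systematic
    offset ``U_l ~ N(0, user_bias_sd²)`` (the user's sensibility and habits)
    and a per-session wobble ``s_lk ~ N(0, session_sd²)``, clamped to the
    usable grey range [1, 254]. Returns a float p×n array.
    """
    if user_bias_sd < 0 or session_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    if p < 1 or n < 1:
        raise ValueError("need at least one user and one session")
    rng = np.random.default_rng(seed)
    user = rng.normal(0.0, user_bias_sd, size=(p, 1))
    session = rng.normal(0.0, session_sd, size=(p, n))
    return np.clip(optimal + user + session, 1.0, 254.0)
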