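"""Cover and LAI estimation from grayscale canopy images.

Segmentation follows the two threshold conventions practitioners use when
they anchor the cutoff on opposite pixel categories:

* **sky** method — pixels with intensity >= T are sky (background); the
  remainder are vegetation.
* **green** method — pixels with intensity <= T are vegetation; the
  remainder are sky.

With the same integer threshold the two labelings differ only on pixels
exactly at T (sky method sends them to sky, green method to vegetation).
When thresholds are chosen per method — e.g. Otsu shifted down for sky and
up for green, emulating how users anchored on opposite categories resolve
mixed pixels — this asymmetry makes the green method report systematically
higher cover on blurred imagery.

LAI inversion uses the Poisson gap-fraction model: in a flat (nadir) view
``LAI = -ln(1 - cover)``; in a fisheye view, a weighted least-squares fit of
``ln P0(θ_i) = -G·L / cos θ_i`` over zenith annuli with extinction
coefficient ``G = 0.5`` (spherical leaf angle distribution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FlatGeometry",
    "FisheyeGeometry",
    "GrayscaleImage",
    "SegmentationConfig",
    "GapFractionProfile",
    "LAIEstimate",
    "measure_cover",
    "auto_threshold",
    "otsu_threshold",
    "segment",
    "gap_fraction_profile",
    "invert_lai",
    "cover_to_lai",
]

#: Extinction coefficient for a spherical leaf angle distribution.
DEFAULT_G = 0.5


@dataclass(frozen=True)
class FlatGeometry:
    """Whole-frame view: every pixel belongs to the scene."""

    kind: str = "flat"


@dataclass(frozen=True)
class FisheyeGeometry:
    """Equidistant fisheye projection: zenith angle ∝ radial distance.

    ``center`` is the optical centre (row, col) in pixel coordinates (pixel
    centres at integer coordinates); ``radius_px`` the image-circle radius;
    ``max_zenith_deg`` the zenith angle mapped to that radius.
    """

    center: tuple[float, float]
    radius_px: float
    max_zenith_deg: float = 60.0
    kind: str = "fisheye"

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius_px must be > 0")
        if not 0 < self.max_zenith_deg <= 90:
            raise ValueError("max_zenith_deg must be in (0, 90]")

    def zenith_map(self, shape: tuple[int, int]) -> np.ndarray:
        """Per-pixel zenith angle in degrees (inf outside the image circle)."""
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        d = np.hypot(yy - self.center[0], xx - self.center[1])
        z = self.max_zenith_deg * d / self.radius_px
        return np.where(d <= self.radius_px, z, np.inf)


Geometry = FlatGeometry | FisheyeGeometry


@dataclass(frozen=True)
class GrayscaleImage:
    """8-bit grayscale canopy image plus its viewing geometry."""

    intensities: np.ndarray
    geometry: Geometry = FlatGeometry()

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 2:
            raise ValueError("intensities must be 2-D")
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("intensities must be within [0, 255]")
        object.__setattr__(self, "intensities", arr.astype(np.uint8))
        if isinstance(self.geometry, FisheyeGeometry):
            cy, cx = self.geometry.center
            r = self.geometry.radius_px
            h, w = arr.shape
            if cy - r < -0.5 or cx - r < -0.5 or cy + r > h - 0.5 or cx + r > w - 0.5:
                raise ValueError("image circle must fit inside the frame")

    def counted(self) -> np.ndarray:
        """Boolean mask of pixels belonging to the scene under the geometry."""
        if isinstance(self.geometry, FisheyeGeometry):
            return np.isfinite(self.geometry.zenith_map(self.intensities.shape))
        return np.ones(self.intensities.shape, dtype=bool)


@dataclass(frozen=True)
class SegmentationConfig:
    """Threshold segmentation settings.

    ``threshold`` is an integer grey level or ``"auto"`` (Otsu).
    ``auto_bias`` shifts the auto threshold per method — subtracted for the
    sky method, added for the green method — modelling users who anchor the
    cutoff on opposite pixel categories; it is ignored for explicit
    thresholds.
    """

    method: str = "sky"
    threshold: int | str = "auto"
    auto_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in ("sky", "green"):
            raise ValueError("method must be 'sky' or 'green'")
        if isinstance(self.threshold, str):
            if self.threshold != "auto":
                raise ValueError("threshold must be an integer or 'auto'")
        elif not 0 <= int(self.threshold) <= 255:
            raise ValueError("threshold must be within [0, 255]")


@dataclass(frozen=True)
class GapFractionProfile:
    """Per-annulus gap fraction over zenith angle."""

    ring_bounds_deg: np.ndarray  # (rings, 2) [lo, hi) zenith intervals
    gap_fraction: np.ndarray
    pixel_count: np.ndarray

    def __post_init__(self) -> None:
        gf = np.asarray(self.gap_fraction, dtype=float)
        if np.any((gf < 0) | (gf > 1)):
            raise ValueError("gap fractions must be in [0, 1]")
        b = np.asarray(self.ring_bounds_deg, dtype=float)
        if np.any(b[:, 1] <= b[:, 0]) or np.any(b[1:, 0] < b[:-1, 1] - 1e-9):
            raise ValueError("rings must be ordered and non-overlapping")

    @property
    def ring_midpoints_deg(self) -> np.ndarray:
        return self.ring_bounds_deg.mean(axis=1)


@dataclass(frozen=True)
class LAIEstimate:
    """Effective LAI with its provenance.

    ``clamped`` flags saturated (zero-gap) inputs that were floored at one
    sky pixel per ring before taking logs; ``reliable`` is False when every
    ring was saturated.
    """

    lai: float
    cover_estimate: float
    inversion: str
    clamped: bool = False
    reliable: bool = True

    def __post_init__(self) -> None:
        if self.lai < 0:
            raise ValueError("lai must be >= 0")
        if not 0 <= self.cover_estimate <= 1:
            raise ValueError("cover_estimate must be in [0, 1]")


def measure_cover(mask: np.ndarray, geometry: Geometry = FlatGeometry()) -> float:
    """Vegetation-pixel fraction of the counted region (exact pixel count).

    ``mask`` is boolean with True = vegetation. Under fisheye geometry only
    pixels inside the image circle are counted.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("mask is empty")
    if isinstance(geometry, FisheyeGeometry):
        counted = np.isfinite(geometry.zenith_map(mask.shape))
        total = int(np.count_nonzero(counted))
        if total == 0:
            raise ValueError("no pixels inside the image circle")
        return float(np.count_nonzero(mask & counted)) / total
    return float(np.count_nonzero(mask)) / mask.size


def otsu_threshold(values: np.ndarray) -> int:
    """Otsu's threshold over 8-bit values, as an integer split point T.

    Returns the T in [1, 255] maximizing the between-class variance of the
    split {< T} vs {>= T}; ties broken toward the smallest T.
    """
    values = np.asarray(values, dtype=np.uint8).ravel()
    hist = np.bincount(values, minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise ValueError("image needs at least two distinct intensities")
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)[:-1]  # pixels < T for T = 1..255
    w1 = hist.sum() - w0
    s0 = np.cumsum(hist * levels)[:-1]
    total = (hist * levels).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / w0
        mu1 = (total - s0) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -1.0
    return int(np.argmax(between)) + 1


def auto_threshold(img: GrayscaleImage) -> int:
    """Otsu threshold over the counted pixels of an image."""
    return otsu_threshold(img.intensities[img.counted()])


def _resolve_threshold(img: GrayscaleImage, cfg: SegmentationConfig) -> int:
    if cfg.threshold == "auto":
        t = auto_threshold(img)
        t += -cfg.auto_bias if cfg.method == "sky" else cfg.auto_bias
        return int(round(min(max(t, 1), 255)))
    return int(cfg.threshold)


def segment(img: GrayscaleImage, cfg: SegmentationConfig) -> np.ndarray:
    """Threshold segmentation; returns boolean mask, True = vegetation.

    Sky method: intensity >= T → sky, else vegetation. Green method:
    intensity <= T → vegetation, else sky. Pixels exactly at T therefore go
    to sky under the sky method and to vegetation under the green method.
    Pixels outside the counted region (fisheye) are labelled sky.
    """
    t = _resolve_threshold(img, cfg)
    arr = img.intensities.astype(int)
    if cfg.method == "sky":
        veg = arr < t
    else:
        veg = arr <= t
    return veg & img.counted()


def segmentation_threshold(img: GrayscaleImage, cfg: SegmentationConfig) -> int:
    """The effective threshold `segment` would use (after auto resolution)."""
    return _resolve_threshold(img, cfg)


def gap_fraction_profile(
    mask: np.ndarray, geometry: FisheyeGeometry, rings: int = 6
) -> GapFractionProfile:
    """Per-annulus gap fraction of a vegetation mask under fisheye geometry.

    The zenith range [0, max_zenith] is split into ``rings`` equal-width
    annuli; each ring's gap fraction is its sky-pixel share.
    """
    if not isinstance(geometry, FisheyeGeometry):
        raise TypeError("gap fraction profiles require fisheye geometry")
    if rings < 1:
        raise ValueError("need at least one ring")
    mask = np.asarray(mask, dtype=bool)
    zen = geometry.zenith_map(mask.shape)
    edges = np.linspace(0.0, geometry.max_zenith_deg, rings + 1)
    bounds, gaps, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (zen >= lo) & (zen < hi) if hi < geometry.max_zenith_deg else (
            (zen >= lo) & (zen <= hi)
        )
        n = int(np.count_nonzero(sel))
        if n == 0:
            raise ValueError(f"ring [{lo:.1f}, {hi:.1f}) deg contains no pixels")
        sky = n - int(np.count_nonzero(mask & sel))
        bounds.append((lo, hi))
        gaps.append(sky / n)
        counts.append(n)
    return GapFractionProfile(
        ring_bounds_deg=np.asarray(bounds),
        gap_fraction=np.asarray(gaps),
        pixel_count=np.asarray(counts),
    )


def cover_to_lai(cover: float) -> float:
    """Nadir Poisson inversion ``LAI = -ln(1 - cover)`` (G/cosθ taken as 1)."""
    if not 0 <= cover < 1:
        raise ValueError("cover must be in [0, 1) for a finite LAI")
    return float(-np.log1p(-cover))


def invert_lai(
    profile_or_cover: GapFractionProfile | float,
    g: float = DEFAULT_G,
) -> LAIEstimate:
    """Invert gap fraction to effective LAI under the Poisson model.

    Flat mode (scalar cover): ``LAI = -ln(1 - cover)``. Fisheye mode
    (profile): weighted least squares of ``ln P0(θ_i) = -g·L/cos θ_i`` over
    ring midpoints, weights the ring pixel counts; zero gaps are clamped to
    one sky pixel per ring before the log and flagged.
    """
    if isinstance(profile_or_cover, GapFractionProfile):
        prof = profile_or_cover
        p0 = prof.gap_fraction.astype(float).copy()
        counts = prof.pixel_count.astype(float)
        saturated = p0 <= 0.0
        clamped = bool(saturated.any())
        p0[saturated] = 1.0 / counts[saturated]
        theta = np.deg2rad(prof.ring_midpoints_deg)
        x = g / np.cos(theta)
        w = counts
        # ln p0 = -x * L  (through the origin)
        lai = float(-(w * x * np.log(p0)).sum() / (w * x * x).sum())
        cover = float(1.0 - (w * p0).sum() / w.sum())
        return LAIEstimate(
            lai=max(lai, 0.0),
            cover_estimate=min(max(cover, 0.0), 1.0),
            inversion="fisheye-poisson",
            clamped=clamped,
            reliable=not bool(saturated.all()),
        )

    cover = float(profile_or_cover)
    if not 0 <= cover <= 1:
        raise ValueError("cover must be in [0, 1]")
    clamped = False
    if cover == 1.0:
        raise ValueError("cover = 1 has no finite flat-mode LAI")
    return LAIEstimate(
        lai=cover_to_lai(cover),
        cover_estimate=cover,
        inversion="flat-poisson",
        clamped=clamped,
    )
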