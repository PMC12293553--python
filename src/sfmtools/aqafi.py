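"""AQAFI: automated quality assessment of fluorescent images.

The pipeline locates fluorescent particles and scores each one with three
intensity components and two derived quality metrics:

* **bead intensity** — mean of the window pixels strictly above the
  window's 99th-percentile intensity (the particle core);
* **vicinity noise** — mean of the remaining window pixels (the
  scattering halo around the particle);
* **background noise** — mean of all image pixels outside every particle
  window (residual excitation-source light), shared per image;

and

    SDNR     = (bead intensity − vicinity noise) / background noise
    Contrast = (bead intensity − vicinity noise) / vicinity noise
    CNR      = Contrast / background noise

Particles are found with a FAST-style segment test on the radius-3
Bresenham circle (16 pixels): a pixel is a feature when at least
``fast_arc`` *contiguous* circle pixels are all darker than the center by
more than the threshold. On a dark-background fluorescence image the
bright particles are the only such structures; the darker polarity
(center dimmer than the circle) is excluded by default. Features
belonging to one particle are grouped by agglomerative clustering at a
pixel-distance cutoff, and the cluster centroid gives the particle
location. The whole pipeline is deterministic: identical image and
configuration yield an identical report.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .image import GrayImage, RgbImage

__all__ = [
    "BRESENHAM_CIRCLE",
    "FeaturePixel",
    "ParticleDetection",
    "ParticleMetrics",
    "ImageQualityReport",
    "AqafiConfig",
    "detect_features",
    "cluster_features",
    "measure_background",
    "measure_particle",
    "assess_image",
]

#: The 16 (row, col) offsets of the radius-3 Bresenham circle, clockwise
#: from straight up.
BRESENHAM_CIRCLE: tuple[tuple[int, int], ...] = (
    (-3, 0), (-3, 1), (-2, 2), (-1, 3),
    (0, 3), (1, 3), (2, 2), (3, 1),
    (3, 0), (3, -1), (2, -2), (1, -3),
    (0, -3), (-1, -3), (-2, -2), (-3, -1),
)


@dataclass(frozen=True)
class FeaturePixel:
    row: int
    col: int
    polarity: Literal["brighter", "darker"] = "brighter"


@dataclass
class ParticleDetection:
    """One located particle: the centroid of its member feature pixels."""

    center_row: float
    center_col: float
    member_features: list[FeaturePixel]
    window_half: int

    def __post_init__(self) -> None:
        if not self.member_features:
            raise ValueError("a detection must have at least one member feature")


@dataclass
class ParticleMetrics:
    bead_intensity: float
    vicinity_noise: float
    background_noise: float
    sdnr: float
    contrast: float
    cnr: float
    flags: tuple[str, ...] = ()

    @property
    def defined(self) -> bool:
        return math.isfinite(self.sdnr) and math.isfinite(self.cnr)


@dataclass
class ImageQualityReport:
    particles: list[tuple[ParticleDetection, ParticleMetrics]]
    mean_sdnr: float
    mean_cnr: float
    background_noise: float
    n_particles: int
    n_excluded: int = 0

    def centers(self) -> np.ndarray:
        """(n, 2) array of particle centroids (row, col)."""
        if not self.particles:
            return np.empty((0, 2))
        return np.array(
            [(d.center_row, d.center_col) for d, _ in self.particles]
        )


@dataclass
class AqafiConfig:
    """Tunable parameters of the assessment pipeline.

    ``fast_threshold`` is an absolute intensity delta on the 0–255 scale.
    With ``fast_threshold_mode="adaptive"`` the threshold is instead
    derived from the image itself as
    max(0.4 × P99.9(|∂x|), 5 × robust noise sd): anchored just below the
    steepest edge gradients present (particle rims) but above the halo
    skirts' gentler gradients and the noise floor. This adapts the
    segment test to images whose dynamic range was compressed by
    filtering. ``window_half_px`` is the half-side of
    the square analysis window around each particle; it should be near
    the expected particle diameter in pixels so the halo falls inside the
    window (see :func:`for_diameter`).
    """

    fast_threshold: float = 20.0
    fast_threshold_mode: Literal["absolute", "adaptive"] = "absolute"
    fast_arc: int = 11
    include_darker: bool = False
    cluster_linkage: Literal["single", "complete", "average"] = "single"
    cluster_cutoff_px: float = 6.0
    window_half_px: int = 8
    intensity_percentile: float = 99.0
    channel_for_detection: Literal["green", "gray"] = "green"

    def __post_init__(self) -> None:
        if not (0 < self.fast_arc <= 16):
            raise ValueError("fast_arc must be in 1..16")
        if self.fast_threshold < 0:
            raise ValueError("fast_threshold must be >= 0")
        if self.fast_threshold_mode not in ("absolute", "adaptive"):
            raise ValueError(f"unknown fast_threshold_mode {self.fast_threshold_mode!r}")
        if self.cluster_cutoff_px <= 0:
            raise ValueError("cluster_cutoff_px must be positive")
        if self.window_half_px < 1:
            raise ValueError("window_half_px must be >= 1")
        if not (0 < self.intensity_percentile < 100):
            raise ValueError("intensity_percentile must be in (0, 100)")
        if self.cluster_linkage not in ("single", "complete", "average"):
            raise ValueError(f"unknown linkage {self.cluster_linkage!r}")

    @classmethod
    def for_diameter(cls, diameter_px: float, **overrides) -> "AqafiConfig":
        """Defaults scaled to an expected particle diameter in pixels.

        The analysis window half-side equals the diameter (square side
        about twice the diameter, so the halo is inside the window) and
        the clustering cutoff equals the diameter (features of one
        particle lie within one diameter of each other).
        """
        params = dict(
            window_half_px=max(2, round(diameter_px)),
            cluster_cutoff_px=max(2.0, float(diameter_px)),
        )
        params.update(overrides)
        return cls(**params)


def _detection_channel(image: RgbImage | GrayImage | np.ndarray, config: AqafiConfig) -> np.ndarray:
    if isinstance(image, GrayImage):
        return image.pixels
    if isinstance(image, RgbImage):
        if config.channel_for_detection == "green":
            return image.green
        return image.pixels.mean(axis=2)
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        return arr[:, :, 1] if config.channel_for_detection == "green" else arr.mean(axis=2)
    return arr


def robust_noise_scale(channel: np.ndarray) -> float:
    """Robust pixel-noise sd from horizontal first differences.

    1.4826 × MAD of adjacent-pixel differences, divided by √2: smooth
    structure (halo skirts, illumination gradients) cancels in the
    differences, so the estimate tracks the noise floor even on images
    dominated by particle halos."""
    d = np.diff(channel, axis=1)
    return 1.4826 * float(np.median(np.abs(d))) / math.sqrt(2.0)


# adaptive-threshold anchors: fraction of the steepest gradients present,
# and a noise-floor guard in robust sd units
_ADAPTIVE_GRADIENT_FRACTION = 0.4
_ADAPTIVE_NOISE_MULT = 5.0


def effective_fast_threshold(channel: np.ndarray, config: AqafiConfig) -> float:
    """The segment-test threshold actually applied to this image."""
    if config.fast_threshold_mode == "absolute":
        return config.fast_threshold
    grad = np.abs(np.diff(channel, axis=1))
    return max(
        _ADAPTIVE_GRADIENT_FRACTION * float(np.percentile(grad, 99.9)),
        _ADAPTIVE_NOISE_MULT * robust_noise_scale(channel),
    )


def detect_features(
    image: RgbImage | GrayImage | np.ndarray, config: AqafiConfig
) -> list[FeaturePixel]:
    """FAST-style segment test on the detection channel.

    A pixel is a brighter-polarity feature when >= ``fast_arc`` contiguous
    pixels of its radius-3 Bresenham circle are all below center − t.
    Pixels within 3 of the border are never features. Images smaller than
    7×7 yield an empty list with a warning.
    """
    g = _detection_channel(image, config)
    H, W = g.shape
    if H < 7 or W < 7:
        warnings.warn("image smaller than 7x7: no room for the Bresenham circle")
        return []
    t = effective_fast_threshold(g, config)
    center = g[3 : H - 3, 3 : W - 3]
    n_circ = len(BRESENHAM_CIRCLE)
    darker = np.empty((n_circ,) + center.shape, dtype=bool)
    brighter = np.empty_like(darker) if config.include_darker else None
    for i, (dr, dc) in enumerate(BRESENHAM_CIRCLE):
        ring = g[3 + dr : H - 3 + dr, 3 + dc : W - 3 + dc]
        darker[i] = ring < center - t
        if brighter is not None:
            brighter[i] = ring > center + t

    def contiguous_hit(mask: np.ndarray) -> np.ndarray:
        wrapped = np.concatenate([mask, mask[: config.fast_arc - 1]], axis=0)
        hit = np.zeros(mask.shape[1:], dtype=bool)
        for s in range(n_circ):
            hit |= wrapped[s : s + config.fast_arc].all(axis=0)
        return hit

    feats: list[FeaturePixel] = []
    rows, cols = np.nonzero(contiguous_hit(darker))
    feats.extend(
        FeaturePixel(int(r) + 3, int(c) + 3, "brighter") for r, c in zip(rows, cols)
    )
    if brighter is not None:
        rows, cols = np.nonzero(contiguous_hit(brighter))
        feats.extend(
            FeaturePixel(int(r) + 3, int(c) + 3, "darker") for r, c in zip(rows, cols)
        )
    feats.sort(key=lambda f: (f.row, f.col, f.polarity))
    return feats


def _single_linkage_labels(coords: np.ndarray, cutoff: float) -> np.ndarray:
    # single-linkage clusters at a distance cutoff are exactly the connected
    # components of the <=cutoff neighbor graph; cKDTree makes this near-linear
    pairs = cKDTree(coords).query_pairs(r=cutoff, output_type="ndarray")
    n = len(coords)
    data = np.ones(len(pairs), dtype=np.int8)
    graph = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return labels


def cluster_features(
    features: Sequence[FeaturePixel], config: AqafiConfig
) -> list[ParticleDetection]:
    """Group feature pixels into particles by agglomerative clustering.

    Clustering runs on Euclidean pixel distance and is cut at
    ``cluster_cutoff_px``; each cluster becomes one detection whose
    centroid is the arithmetic mean of member coordinates. Clusters are
    returned ordered by their first member in lexicographic pixel order,
    which makes the pipeline deterministic.
    """
    feats = list(features)
    if not feats:
        return []
    coords = np.array([(f.row, f.col) for f in feats], dtype=np.float64)
    if len(feats) == 1:
        labels = np.zeros(1, dtype=int)
    elif config.cluster_linkage == "single":
        labels = _single_linkage_labels(coords, config.cluster_cutoff_px)
    else:
        Z = linkage(coords, method=config.cluster_linkage)
        labels = fcluster(Z, t=config.cluster_cutoff_px, criterion="distance")
    detections: list[ParticleDetection] = []
    seen: dict[int, int] = {}
    order: list[int] = []
    for lab in labels:
        if lab not in seen:
            seen[lab] = len(order)
            order.append(lab)
    for lab in order:
        idx = np.nonzero(labels == lab)[0]
        members = [feats[i] for i in idx]
        detections.append(
            ParticleDetection(
                center_row=float(coords[idx, 0].mean()),
                center_col=float(coords[idx, 1].mean()),
                member_features=members,
                window_half=config.window_half_px,
            )
        )
    return detections


def _iround(x: float) -> int:
    return int(math.floor(x + 0.5))


def _window_slices(
    detection: ParticleDetection, shape: tuple[int, int]
) -> tuple[slice, slice, bool]:
    h = detection.window_half
    r, c = _iround(detection.center_row), _iround(detection.center_col)
    r0, r1 = r - h, r + h + 1
    c0, c1 = c - h, c + h + 1
    clipped = r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]
    return (
        slice(max(r0, 0), min(r1, shape[0])),
        slice(max(c0, 0), min(c1, shape[1])),
        clipped,
    )


def measure_background(
    image: RgbImage | GrayImage | np.ndarray,
    detections: Sequence[ParticleDetection],
    config: AqafiConfig,
) -> float:
    """Mean intensity outside the union of all particle windows.

    With no detections this is the whole-image mean; if the windows cover
    the entire image the background is undefined and an error is raised.
    """
    g = _detection_channel(image, config)
    mask = np.ones(g.shape, dtype=bool)
    for det in detections:
        rs, cs, _ = _window_slices(det, g.shape)
        mask[rs, cs] = False
    if not mask.any():
        raise ValueError("particle windows cover the whole image: background undefined")
    return float(g[mask].mean())


def measure_particle(
    image: RgbImage | GrayImage | np.ndarray,
    detection: ParticleDetection,
    background_noise: float,
    config: AqafiConfig,
) -> ParticleMetrics:
    """Intensity components and quality metrics for one particle window.

    The window's pixel multiset is split at its ``intensity_percentile``
    percentile (linear interpolation; "above" is strict): pixels above it
    average into the bead intensity, the rest into the vicinity noise. A
    constant window has no pixel strictly above its percentile and scores
    zero signal (bead = vicinity = window mean, SDNR = Contrast = 0)
    rather than failing. Zero denominators yield NaN metrics carrying an
    ``undefined-*`` flag; a window clipped at the image border is kept and
    flagged ``border``.
    """
    g = _detection_channel(image, config)
    rs, cs, clipped = _window_slices(detection, g.shape)
    pix = g[rs, cs].ravel()
    if pix.size == 0:
        raise ValueError("empty particle window")
    flags: list[str] = ["border"] if clipped else []
    split = np.percentile(pix, config.intensity_percentile)
    bead_mask = pix > split
    if bead_mask.any():
        bead = float(pix[bead_mask].mean())
        vic = float(pix[~bead_mask].mean())
        degenerate = False
    else:
        bead = vic = float(pix.mean())
        degenerate = True
        flags.append("degenerate-window")
    if bead < vic:
        flags.append("inverted")

    if degenerate:
        sdnr = 0.0
        contrast = 0.0
        cnr = 0.0 if background_noise > 0 else float("nan")
        if background_noise <= 0:
            flags.append("undefined-cnr")
    else:
        if background_noise > 0:
            sdnr = (bead - vic) / background_noise
        else:
            sdnr = float("nan")
            flags.append("undefined-sdnr")
        if vic > 0:
            contrast = (bead - vic) / vic
        else:
            contrast = float("nan")
            flags.append("undefined-contrast")
        if vic > 0 and background_noise > 0:
            cnr = contrast / background_noise
        else:
            cnr = float("nan")
            flags.append("undefined-cnr")
    return ParticleMetrics(
        bead_intensity=bead,
        vicinity_noise=vic,
        background_noise=background_noise,
        sdnr=sdnr,
        contrast=contrast,
        cnr=cnr,
        flags=tuple(flags),
    )


def assess_image(
    image: RgbImage | GrayImage | np.ndarray, config: AqafiConfig
) -> ImageQualityReport:
    """Full pipeline: detect, cluster, and score every particle.

    Image-level mean SDNR/CNR are arithmetic means over particles with
    defined metrics; particles with undefined metrics are excluded from
    the means and counted in ``n_excluded``. An image with no detected
    particles yields an explicit empty report with NaN means.
    """
    features = detect_features(image, config)
    detections = cluster_features(features, config)
    particles: list[tuple[ParticleDetection, ParticleMetrics]] = []
    if detections:
        background = measure_background(image, detections, config)
        for det in detections:
            particles.append(
                (det, measure_particle(image, det, background, config))
            )
    else:
        g = _detection_channel(image, config)
        background = float(g.mean())
    defined = [m for _, m in particles if m.defined]
    mean_sdnr = float(np.mean([m.sdnr for m in defined])) if defined else float("nan")
    mean_cnr = float(np.mean([m.cnr for m in defined])) if defined else float("nan")
    return ImageQualityReport(
        particles=particles,
        mean_sdnr=mean_sdnr,
        mean_cnr=mean_cnr,
        background_noise=background,
        n_particles=len(particles),
        n_excluded=len(particles) - len(defined),
    )
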