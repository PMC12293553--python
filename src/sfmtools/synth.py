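"""Synthetic smartphone-fluorescence-microscope scenes with ground truth.

The generator emulates the imaging regime of a low-cost smartphone
fluorescence microscope observing green fluorescent beads (or stained
leukocytes) on a dark field:

* a dark background whose mean level and spread grow with the excitation
  source intensity (parameterized here by the excitation voltage);
* green-dominant bead signal: each bead renders as a flat-top disc at
  (1 − core_gain)·peak topped by a narrow central core spike reaching
  ``peak`` exactly at the center — the focal hotspot real beads show —
  surrounded by an additive Gaussian scattering halo outside the disc;
* red/blue channels nearly dark (10% of the green background) except for
  large, bright beads whose signal bleeds through at ``rb_bleed``;
* optionally a fraction of dim, near-edge beads at 30% peak, emulating
  out-of-focus particles at the border of the field of view.

Bead centers are placed uniformly at random subject to a minimum spacing
(dilute-sample regime); all randomness flows from the spec's seed, so a
fixed seed reproduces the scene bit for bit. ``two_level_scene`` builds a
noise-free analytic scene whose particles have exactly known bead,
vicinity, and background intensities, used to validate the metric
formulas end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .aqafi import AqafiConfig
from .image import RgbImage

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "generate_scene",
    "preset_scene",
    "two_level_scene",
    "default_aqafi_config",
    "PRESET_NAMES",
]


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    ``bead_diameter_um`` may be a single diameter or a (low, high) range
    sampled per bead (leukocyte-like populations). ``min_spacing_px``
    defaults to 2·d_px + 34 so that even after heavy (21-wide) filtering
    the footprints of neighboring beads stay separated, as in the dilute
    samples such instruments image.
    """

    height: int = 1024
    width: int = 1024
    um_per_px: float = 0.085
    bead_diameter_um: float | tuple[float, float] = 2.0
    n_beads: int = 50
    peak_intensity: float = 230.0
    halo_gain: float = 0.25
    halo_width_factor: float = 1.5
    core_gain: float = 0.2
    core_sigma_px: float = 1.0
    background_level: float = 19.0
    background_sd: float = 4.0
    rb_bleed: float = 0.06
    bleed_threshold: float = 800.0  # peak × diameter(µm) above which R/B bleed applies
    edge_dim_fraction: float = 0.0
    edge_dim_factor: float = 0.3
    min_spacing_px: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beads < 0:
            raise ValueError("n_beads must be >= 0")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if not (0 <= self.halo_gain < 1):
            raise ValueError("halo_gain must lie in [0, 1)")
        if not (0 <= self.core_gain < 1):
            raise ValueError("core_gain must lie in [0, 1)")
        for name in ("peak_intensity", "background_level"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name} must lie in [0, 255]")

    @property
    def diameter_range_um(self) -> tuple[float, float]:
        d = self.bead_diameter_um
        if isinstance(d, tuple):
            return d
        return (d, d)

    @property
    def mean_diameter_px(self) -> float:
        lo, hi = self.diameter_range_um
        return 0.5 * (lo + hi) / self.um_per_px

    def spacing_px(self, d_px: float) -> float:
        if self.min_spacing_px is not None:
            return max(self.min_spacing_px, 2.0 * d_px)
        return 2.0 * d_px + 34.0


@dataclass
class SceneTruth:
    """Planted ground truth: one entry per rendered bead."""

    centers: np.ndarray  # (n, 2) float (row, col)
    diameters_px: np.ndarray  # (n,)
    peaks: np.ndarray  # (n,) effective peak (dim beads already scaled)
    is_edge_dim: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        n = len(self.centers)
        if not (len(self.diameters_px) == len(self.peaks) == len(self.is_edge_dim) == n):
            raise ValueError("truth arrays must have equal length")


def _bead_patch(
    shape: tuple[int, int],
    center: tuple[float, float],
    d_px: float,
    peak: float,
    spec: SceneSpec,
) -> tuple[tuple[slice, slice], np.ndarray]:
    """Additive intensity contribution of one bead, restricted to a patch."""
    radius = d_px / 2.0
    sigma_h = spec.halo_width_factor * radius
    extent = int(math.ceil(max(radius + 2.0, 2.5 * sigma_h)))
    cr, cc = center
    r0 = max(0, int(math.floor(cr)) - extent)
    r1 = min(shape[0], int(math.ceil(cr)) + extent + 1)
    c0 = max(0, int(math.floor(cc)) - extent)
    c1 = min(shape[1], int(math.ceil(cc)) + extent + 1)
    rows = np.arange(r0, r1, dtype=np.float64)[:, None] - cr
    cols = np.arange(c0, c1, dtype=np.float64)[None, :] - cc
    rr = np.hypot(rows, cols)
    plateau = (1.0 - spec.core_gain) * peak
    spike = spec.core_gain * peak
    core = plateau + spike * np.exp(-(rr**2) / (2.0 * spec.core_sigma_px**2))
    halo = spec.halo_gain * peak * np.exp(-(rr**2) / (2.0 * sigma_h**2))
    return (slice(r0, r1), slice(c0, c1)), np.where(rr <= radius, core, halo)


def generate_scene(spec: SceneSpec) -> tuple[RgbImage, SceneTruth]:
    """Render one scene and return the image with its planted truth.

    Beads are placed uniformly at random with rejection until the minimum
    center spacing holds; if a bead cannot be placed after bounded
    retries a ValueError suggests lowering ``n_beads``.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    lo, hi = spec.diameter_range_um

    n_edge = int(round(spec.edge_dim_fraction * spec.n_beads))
    centers: list[tuple[float, float]] = []
    diameters: list[float] = []
    peaks: list[float] = []
    edge_flags: list[bool] = []

    def try_place(edge_dim: bool) -> None:
        d_um = lo if lo == hi else float(rng.uniform(lo, hi))
        d_px = d_um / spec.um_per_px
        spacing = spec.spacing_px(d_px)
        for _ in range(500):
            if edge_dim:
                # deliberately near a border, within one diameter of it
                side = int(rng.integers(4))
                off = float(rng.uniform(2.0, max(2.0 + 1e-6, d_px)))
                if side == 0:
                    cand = (off, float(rng.uniform(0, W)))
                elif side == 1:
                    cand = (H - off, float(rng.uniform(0, W)))
                elif side == 2:
                    cand = (float(rng.uniform(0, H)), off)
                else:
                    cand = (float(rng.uniform(0, H)), W - off)
            else:
                margin = d_px / 2.0 + 14.0
                if 2 * margin >= min(H, W):
                    raise ValueError("image too small for this bead diameter")
                cand = (
                    float(rng.uniform(margin, H - margin)),
                    float(rng.uniform(margin, W - margin)),
                )
            ok = all(
                math.hypot(cand[0] - r, cand[1] - c) >= spacing
                for r, c in centers
            )
            if ok:
                centers.append(cand)
                diameters.append(d_px)
                peaks.append(
                    spec.peak_intensity * (spec.edge_dim_factor if edge_dim else 1.0)
                )
                edge_flags.append(edge_dim)
                return
        raise ValueError(
            f"could not place bead {len(centers) + 1}/{spec.n_beads} without "
            f"violating spacing; lower n_beads or enlarge the scene"
        )

    for i in range(spec.n_beads):
        try_place(edge_dim=i < n_edge)

    green = np.zeros((H, W), dtype=np.float64)
    red = np.zeros_like(green)
    blue = np.zeros_like(green)
    for (cr, cc), d_px, peak in zip(centers, diameters, peaks):
        sl, patch = _bead_patch((H, W), (cr, cc), d_px, peak, spec)
        green[sl] += patch
        if peak * d_px * spec.um_per_px > spec.bleed_threshold:
            red[sl] += spec.rb_bleed * patch
            blue[sl] += spec.rb_bleed * patch

    green += spec.background_level + rng.normal(0.0, spec.background_sd, size=(H, W))
    for chan in (red, blue):
        chan += 0.1 * spec.background_level + rng.normal(
            0.0, 0.1 * spec.background_sd, size=(H, W)
        )
    pixels = np.clip(np.stack([red, green, blue], axis=-1), 0.0, 255.0)
    truth = SceneTruth(
        centers=np.array(centers, dtype=np.float64).reshape(-1, 2),
        diameters_px=np.array(diameters, dtype=np.float64),
        peaks=np.array(peaks, dtype=np.float64),
        is_edge_dim=np.array(edge_flags, dtype=bool),
    )
    return RgbImage(pixels), truth


# per-size preset defaults; bead diameters follow the sizes the instrument
# was characterized with, leukocyte diameters span the 6-15 µm range of
# human leukocyte subpopulations
_PRESETS: dict[str, dict] = {
    "beads_8.3um": dict(bead_diameter_um=8.3, height=3200, width=3200, n_beads=50),
    "beads_2um": dict(bead_diameter_um=2.0, height=1280, width=1280, n_beads=50),
    "beads_1um": dict(bead_diameter_um=1.0, height=1024, width=1024, n_beads=50),
    "beads_0.8um": dict(
        bead_diameter_um=0.8, height=1024, width=1024, n_beads=50, edge_dim_fraction=0.1
    ),
    "leukocytes": dict(
        bead_diameter_um=(6.0, 15.0), height=2560, width=2560, n_beads=10
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def voltage_to_illumination(voltage: float) -> dict[str, float]:
    """Monotone affine map from excitation voltage to brightness levels.

    Higher voltage means a brighter signal *and* more background light;
    only the ordering across the 4.3-4.5 V range carries meaning, no
    physical units are claimed.
    """
    if not (4.3 <= voltage <= 4.5):
        raise ValueError("voltage must lie in [4.3, 4.5]")
    dv = voltage - 4.3
    return dict(
        peak_intensity=200.0 + 150.0 * dv,
        background_level=13.0 + 30.0 * dv,
        background_sd=2.5 + 7.5 * dv,
    )


def preset_spec(name: str, voltage: float = 4.5, seed: int = 0, **overrides) -> SceneSpec:
    """The :class:`SceneSpec` a named preset expands to."""
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    params = dict(_PRESETS[name])
    params.update(voltage_to_illumination(voltage))
    params.update(overrides)
    return SceneSpec(seed=seed, **params)


def preset_scene(
    name: str, voltage: float = 4.5, seed: int = 0, **overrides
) -> tuple[RgbImage, SceneTruth]:
    """Generate a scene from a named preset at a given excitation voltage."""
    return generate_scene(preset_spec(name, voltage=voltage, seed=seed, **overrides))


def default_aqafi_config(spec: SceneSpec, **overrides) -> AqafiConfig:
    """Assessment defaults scaled to the scene's expected bead diameter."""
    return AqafiConfig.for_diameter(spec.mean_diameter_px, **overrides)


def two_level_scene(
    n_particles: int = 10,
    core_value: float = 200.0,
    vicinity_value: float = 50.0,
    background_value: float = 10.0,
    window_half: int = 15,
) -> tuple[RgbImage, np.ndarray, AqafiConfig]:
    """Noise-free analytic scene with exactly known metric components.

    Each particle is a 3×3 core at ``core_value`` centered in a
    (2·window_half+1)² square at ``vicinity_value`` on a uniform
    background. The core occupies under 1% of the window, so the
    99th-percentile split recovers core and vicinity exactly:
    SDNR = (core − vicinity)/background holds to machine precision.
    Returns the image, the (n, 2) particle centers, and the matching
    assessment config.
    """
    side = 2 * window_half + 1
    if 9 >= 0.01 * side * side:
        raise ValueError("window too small: the 3x3 core must stay under 1% of it")
    pitch = 3 * side
    n_cols = int(math.ceil(math.sqrt(n_particles)))
    n_rows = int(math.ceil(n_particles / n_cols))
    H = n_rows * pitch + pitch
    W = n_cols * pitch + pitch
    green = np.full((H, W), background_value, dtype=np.float64)
    centers = []
    for k in range(n_particles):
        i, j = divmod(k, n_cols)
        cr = pitch + i * pitch
        cc = pitch + j * pitch
        green[cr - window_half : cr + window_half + 1,
              cc - window_half : cc + window_half + 1] = vicinity_value
        green[cr - 1 : cr + 2, cc - 1 : cc + 2] = core_value
        centers.append((cr, cc))
    pixels = np.zeros((H, W, 3), dtype=np.float64)
    pixels[:, :, 1] = green
    # threshold above the vicinity/background step so the sharp corners of
    # the vicinity square do not register, but below the core/vicinity step
    config = AqafiConfig(
        fast_threshold=0.5 * (core_value - vicinity_value),
        fast_arc=11,
        cluster_cutoff_px=5.0,
        window_half_px=window_half,
    )
    return RgbImage(pixels), np.array(centers, dtype=np.float64), config
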