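"""3D and 2D Averaging / Gaussian filtering of RGB fluorescence micrographs.

The 3D variant treats the three color channels as a third image dimension:
the H×W×3 volume is convolved with an m×m×m kernel,

    g(x, y, z) = sum_s sum_t sum_u k(s, t, u) · f(x−s, y−t, z−u),

and one output plane (by default the one aligned with the green channel,
where the fluorescence signal lives) becomes the grayed result, which is
then false-colored green. Because the kernel is m deep while the channel
axis holds only 3 real planes, kernel mass falling outside the channels is
zero-padded by default and *not* renormalized; this strong attenuation of
all intensities is the characteristic behavior of channel-aware filtering
and is the mechanism behind its background-noise suppression. The 2D
variant convolves each channel independently with the m×m central-slice
analogue and leaves constant regions unchanged.

Averaging kernels carry uniform weights 1/m³; Gaussian kernels carry
weights ∝ exp(−(x²+y²+z²)/(2σ²)), renormalized to sum to one because the
discrete truncation makes the analytic normalization constant insufficient.
Both families are separable, and the convolution is evaluated as three 1-D
passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import convolve1d

from .image import GrayImage, RgbImage

__all__ = [
    "Kernel3D",
    "FilterConfig",
    "make_average_kernel",
    "make_gaussian_kernel",
    "convolve3d",
    "convolve2d_per_channel",
    "false_color_green",
    "apply_filter",
]

KERNEL_SIZES = (3, 7, 11, 15, 21)
GAUSSIAN_SIGMAS = (1.0, 3.0, 5.0)

_PAD_MODE = {"replicate": "edge", "reflect": "reflect", "zero": "constant"}


def _check_size(size_m: int) -> None:
    if not isinstance(size_m, (int, np.integer)):
        raise ValueError(f"kernel size must be an integer, got {size_m!r}")
    if size_m < 3 or size_m % 2 == 0:
        raise ValueError(f"kernel size must be an odd integer >= 3, got {size_m}")


@dataclass(frozen=True)
class Kernel3D:
    """An m×m×m stack of convolution weights summing to one.

    ``profile`` is the normalized 1-D factor whose triple outer product
    equals ``weights``; both the Averaging and Gaussian families are
    separable, which the convolution routines exploit.
    """

    weights: np.ndarray
    size_m: int
    family: Literal["average", "gaussian"]
    sigma: float | None = None
    profile: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.shape != (self.size_m,) * 3:
            raise ValueError(f"weights must be {self.size_m}^3, got {w.shape}")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("kernel weights must sum to 1 within 1e-9")
        object.__setattr__(self, "weights", w)
        if self.profile is not None:
            object.__setattr__(
                self, "profile", np.asarray(self.profile, dtype=np.float64)
            )


def make_average_kernel(size_m: int) -> Kernel3D:
    """Uniform m×m×m kernel with every weight 1/m³."""
    _check_size(size_m)
    profile = np.full(size_m, 1.0 / size_m)
    weights = np.full((size_m,) * 3, 1.0 / size_m**3)
    return Kernel3D(weights, int(size_m), "average", profile=profile)


def _gaussian_profile(size_m: int, sigma: float) -> np.ndarray:
    offsets = np.arange(size_m, dtype=np.float64) - size_m // 2
    p = np.exp(-(offsets**2) / (2.0 * sigma**2))
    return p / p.sum()


def make_gaussian_kernel(size_m: int, sigma: float) -> Kernel3D:
    """Isotropic Gaussian m×m×m kernel, truncated and renormalized.

    The weight at offset (x, y, z) from the center is proportional to
    exp(−(x²+y²+z²)/(2σ²)); weights are renormalized so the truncated
    kernel preserves constants.
    """
    _check_size(size_m)
    if not (sigma > 0):
        raise ValueError(f"sigma must be positive, got {sigma}")
    profile = _gaussian_profile(size_m, float(sigma))
    weights = np.einsum("i,j,k->ijk", profile, profile, profile)
    return Kernel3D(weights, int(size_m), "gaussian", float(sigma), profile=profile)


@dataclass
class FilterConfig:
    """Settings for one filtering operation.

    sigma is required for (and only valid with) the Gaussian family.
    ``spatial_border`` pads rows/columns; ``channel_border`` pads the
    3-deep channel axis, zero by default so out-of-channel kernel mass
    contributes nothing. ``output_plane`` selects how the convolved volume
    collapses to one gray plane.
    """

    family: Literal["average", "gaussian"]
    size_m: int
    sigma: float | None = None
    spatial_border: Literal["replicate", "reflect", "zero"] = "replicate"
    channel_border: Literal["zero", "replicate"] = "zero"
    output_plane: Literal["green", "mean"] = "green"
    dims: Literal["3d", "2d"] = "3d"

    def __post_init__(self) -> None:
        if self.family not in ("average", "gaussian"):
            raise ValueError(f"unknown filter family {self.family!r}")
        _check_size(self.size_m)
        if self.family == "gaussian":
            if self.sigma is None or not (self.sigma > 0):
                raise ValueError("gaussian family requires sigma > 0")
        elif self.sigma is not None:
            raise ValueError("sigma is only valid with the gaussian family")
        if self.spatial_border not in _PAD_MODE:
            raise ValueError(f"unknown spatial_border {self.spatial_border!r}")
        if self.channel_border not in ("zero", "replicate"):
            raise ValueError(f"unknown channel_border {self.channel_border!r}")
        if self.output_plane not in ("green", "mean"):
            raise ValueError(f"unknown output_plane {self.output_plane!r}")
        if self.dims not in ("3d", "2d"):
            raise ValueError(f"dims must be '3d' or '2d', got {self.dims!r}")

    def make_kernel(self) -> Kernel3D:
        if self.family == "average":
            return make_average_kernel(self.size_m)
        return make_gaussian_kernel(self.size_m, self.sigma)

    def label(self) -> str:
        tag = f"{self.family}_m{self.size_m}"
        if self.sigma is not None:
            tag += f"_s{self.sigma:g}"
        return tag + ("_2d" if self.dims == "2d" else "")


def _separable_valid(volume: np.ndarray, profile: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """True convolution with the outer-product kernel, valid region only.

    ``volume`` must already be padded by len(profile)//2 along each axis in
    ``axes``; each pass convolves one axis and crops it back.
    """
    p = len(profile) // 2
    out = volume
    for ax in axes:
        out = convolve1d(out, profile, axis=ax, mode="constant", cval=0.0)
        sl = [slice(None)] * out.ndim
        sl[ax] = slice(p, out.shape[ax] - p)
        out = out[tuple(sl)]
    return out


def _channel_coefficients(
    profile: np.ndarray, out_plane: int, channel_border: str
) -> np.ndarray:
    """Weight each real channel contributes to one output plane.

    The channel axis holds only 3 real planes inside an m-deep padded
    stack, so the valid 1-D convolution along it reduces to a fixed
    3-coefficient combination: out[z] = sum_u w[u] · x[z + m−1−u] with
    x[j] the padded stack. Zero padding drops out-of-range taps; replicate
    padding clamps them onto the edge channels.
    """
    m = len(profile)
    p = m // 2
    coeffs = np.zeros(3)
    for u in range(m):
        j = out_plane + (m - 1) - u  # index into the padded channel stack
        c = j - p
        if 0 <= c <= 2:
            coeffs[c] += profile[u]
        elif channel_border == "replicate":
            coeffs[min(max(c, 0), 2)] += profile[u]
    return coeffs


def convolve3d(image: RgbImage, kernel: Kernel3D, config: FilterConfig) -> GrayImage:
    """Convolve the H×W×3 volume with an m×m×m kernel and collapse to a plane.

    Evaluated separably: the channel axis contracts to a weighted sum of
    the three real channels (exact, for any kernel depth), then the two
    spatial axes are convolved on the resulting single plane.
    """
    if config.dims != "3d":
        raise ValueError("convolve3d requires config.dims == '3d'")
    m = kernel.size_m
    if m > image.height or m > image.width:
        raise ValueError(
            f"kernel size {m} exceeds image extent {image.height}x{image.width}"
        )
    p = m // 2
    if config.output_plane == "green":
        coeffs = _channel_coefficients(kernel.profile, 1, config.channel_border)
    else:  # mean over the three output planes
        coeffs = np.mean(
            [
                _channel_coefficients(kernel.profile, z, config.channel_border)
                for z in range(3)
            ],
            axis=0,
        )
    plane = np.tensordot(image.pixels, coeffs, axes=([2], [0]))
    padded = np.pad(plane, p, mode=_PAD_MODE[config.spatial_border])
    out = _separable_valid(padded, kernel.profile, axes=(0, 1))
    return GrayImage(np.clip(out, 0.0, 255.0))


def convolve2d_per_channel(
    image: RgbImage,
    kernel2d_size: int,
    family: Literal["average", "gaussian"],
    sigma: float | None = None,
    spatial_border: Literal["replicate", "reflect", "zero"] = "replicate",
) -> RgbImage:
    """Convolve each color channel with the m×m central-slice kernel.

    The 2D kernel is the normalized central slice of the corresponding 3D
    family (uniform 1/m², or exp(−(x²+y²)/(2σ²)) renormalized); constant
    regions are preserved, so this blurs without attenuating.
    """
    _check_size(kernel2d_size)
    if kernel2d_size > image.height or kernel2d_size > image.width:
        raise ValueError("kernel size exceeds image extent")
    if family == "average":
        profile = np.full(kernel2d_size, 1.0 / kernel2d_size)
    elif family == "gaussian":
        if sigma is None or not (sigma > 0):
            raise ValueError("gaussian family requires sigma > 0")
        profile = _gaussian_profile(kernel2d_size, float(sigma))
    else:
        raise ValueError(f"unknown filter family {family!r}")
    p = kernel2d_size // 2
    padded = np.pad(
        image.pixels, ((p, p), (p, p), (0, 0)), mode=_PAD_MODE[spatial_border]
    )
    out = _separable_valid(padded, profile, axes=(0, 1))
    return RgbImage(np.clip(out, 0.0, 255.0), bit_depth=image.bit_depth)


def false_color_green(gray: GrayImage) -> RgbImage:
    """Place a gray plane into the green channel of an otherwise black image.

    No rescaling or contrast stretch is applied, so quality metrics
    computed downstream see the filtered intensities unmodified.
    """
    out = np.zeros((gray.height, gray.width, 3), dtype=np.float64)
    out[:, :, 1] = gray.pixels
    return RgbImage(out)


def apply_filter(image: RgbImage, config: FilterConfig) -> RgbImage:
    """Run one configured filtering operation end to end.

    3D: build the kernel, convolve the volume, false-color the result
    green. 2D: per-channel convolution, output stays RGB.
    """
    if config.dims == "2d":
        return convolve2d_per_channel(
            image,
            config.size_m,
            config.family,
            config.sigma,
            config.spatial_border,
        )
    kernel = config.make_kernel()
    return false_color_green(convolve3d(image, kernel, config))
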