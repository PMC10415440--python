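"""Seeded synthetic phantoms emulating 2-D abdominal CSE-MRI slices.

Anatomy is deliberately simple: a body ellipse containing a handful of
elliptical tissue compartments, each with a constant fat fraction (spanning
the hepatic range of roughly 4-36%) and a constant R2*, on top of a smooth
low-order polynomial off-resonance field.  That is enough piecewise-smooth
structure for skip-connection networks to learn from, without pretending to
be an anatomical atlas.

The module also carries the study-style preprocessing: additive circular
complex Gaussian noise (magnitude therefore Rician), image resizing by
centred k-space cropping, and background removal by thresholding the mean
all-echo magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_model import (
    AcquisitionParams,
    EchoSeries,
    ParameterMaps,
    ValidationError,
)

__all__ = [
    "PhantomConfig",
    "generate_phantom",
    "add_noise",
    "kspace_resize",
    "threshold_mask",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic slice.

    Defaults: fat fraction 4-36% (the hepatic range the networks must
    cover), compartment R2* 10-150 1/s within the [0, 200] normalisation
    envelope, field-map amplitude 150 Hz (abdominal-realistic at 1.5 T,
    within the +/-400 Hz envelope), SNR 50.
    """

    image_size: int = 64
    n_regions: int = 5
    pdff_range: tuple[float, float] = (0.04, 0.36)
    r2star_range_per_s: tuple[float, float] = (10.0, 150.0)
    fieldmap_amplitude_hz: float = 150.0
    noise_snr: "float | None" = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 16 or self.image_size % 16 != 0:
            raise ValidationError("image_size must be >= 16 and divisible by 16")
        if not (1 <= self.n_regions <= 16):
            raise ValidationError("n_regions must be in [1, 16]")
        lo, hi = self.pdff_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("pdff_range must satisfy 0 <= low <= high <= 1")
        rlo, rhi = self.r2star_range_per_s
        if not (0.0 <= rlo <= rhi):
            raise ValidationError("r2star range must be non-negative and ordered")
        if self.fieldmap_amplitude_hz < 0:
            raise ValidationError("fieldmap_amplitude_hz must be >= 0")
        if self.noise_snr is not None and self.noise_snr <= 0:
            raise ValidationError("noise_snr must be positive or None")


def _ellipse_mask(size: int, cx: float, cy: float, ax: float, ay: float, theta: float) -> np.ndarray:
    y, x = np.mgrid[0:size, 0:size]
    xr = (x - cx) * np.cos(theta) + (y - cy) * np.sin(theta)
    yr = -(x - cx) * np.sin(theta) + (y - cy) * np.cos(theta)
    return (xr / ax) ** 2 + (yr / ay) ** 2 <= 1.0


def generate_phantom(config: PhantomConfig) -> ParameterMaps:
    """Deterministic ground-truth parameter maps for one slice.

    The body ellipse is the mask; internal ellipses are painted in order
    (later ones overwrite).  Water and fat share a common initial phase
    phi0 drawn per slice, so voxel signals are genuinely complex.
    """
    rng = np.random.default_rng(config.seed)
    n = config.image_size

    # body ellipse with mild jitter around the image centre
    cx = n / 2 + rng.uniform(-0.02, 0.02) * n
    cy = n / 2 + rng.uniform(-0.02, 0.02) * n
    body = _ellipse_mask(
        n, cx, cy,
        ax=rng.uniform(0.38, 0.44) * n,
        ay=rng.uniform(0.30, 0.38) * n,
        theta=rng.uniform(-0.2, 0.2),
    )

    pdff = np.zeros((n, n))
    r2s = np.zeros((n, n))
    mag = np.zeros((n, n))

    def draw(lo, hi):
        return lo if lo == hi else rng.uniform(lo, hi)

    # base tissue filling the body, then internal compartments
    pdff[body] = draw(*config.pdff_range)
    r2s[body] = draw(*config.r2star_range_per_s)
    mag[body] = rng.uniform(0.7, 1.0)
    for _ in range(config.n_regions):
        region = _ellipse_mask(
            n,
            cx=rng.uniform(0.25, 0.75) * n,
            cy=rng.uniform(0.25, 0.75) * n,
            ax=rng.uniform(0.06, 0.20) * n,
            ay=rng.uniform(0.06, 0.20) * n,
            theta=rng.uniform(0, np.pi),
        ) & body
        pdff[region] = draw(*config.pdff_range)
        r2s[region] = draw(*config.r2star_range_per_s)
        mag[region] = rng.uniform(0.7, 1.0)

    # smooth low-order polynomial off-resonance field, bounded in magnitude
    yy, xx = np.mgrid[0:n, 0:n]
    u = (xx - n / 2) / (n / 2)
    v = (yy - n / 2) / (n / 2)
    coeffs = rng.standard_normal(6)
    raw = (
        coeffs[0]
        + coeffs[1] * u
        + coeffs[2] * v
        + coeffs[3] * u * v
        + coeffs[4] * u**2
        + coeffs[5] * v**2
    )
    peak = np.max(np.abs(raw))
    if peak > 0 and config.fieldmap_amplitude_hz > 0:
        fmap = raw * (config.fieldmap_amplitude_hz * rng.uniform(0.6, 1.0) / peak)
    else:
        fmap = np.zeros_like(raw)
    fmap[~body] = 0.0

    phi0 = rng.uniform(-np.pi, np.pi)
    phase = np.exp(1j * phi0)
    water = mag * (1.0 - pdff) * phase
    fat = mag * pdff * phase
    water[~body] = 0.0
    fat[~body] = 0.0
    r2s[~body] = 0.0

    return ParameterMaps(water=water, fat=fat, r2star_per_s=r2s, fieldmap_hz=fmap, mask=body)


def add_noise(echoes: EchoSeries, snr: "float | None", seed: int) -> EchoSeries:
    """Add i.i.d. circular complex Gaussian noise at a given first-echo SNR.

    sigma = (mean foreground magnitude at the first echo) / snr is applied
    to the real and imaginary parts of every voxel, background included.
    ``snr=None`` is the noiseless limit and returns the input unchanged.
    """
    if snr is None:
        return echoes
    if snr <= 0:
        raise ValidationError("snr must be positive")
    mag1 = np.abs(echoes.data[0])
    fg = mag1 > 0
    if not np.any(fg):
        raise ValidationError("cannot scale noise on an all-zero first echo")
    sigma = float(mag1[fg].mean()) / snr
    rng = np.random.default_rng(seed)
    noise = rng.normal(scale=sigma, size=echoes.data.shape) + 1j * rng.normal(
        scale=sigma, size=echoes.data.shape
    )
    return EchoSeries(
        data=echoes.data + noise,
        echo_times_s=echoes.echo_times_s,
        acquisition=echoes.acquisition,
    )


def kspace_resize(image: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Resize a complex image by centred cropping of its 2-D Fourier transform.

    The inverse transform of the cropped spectrum is scaled by the pixel-count
    ratio so mean intensity (the DC level) is preserved.
    """
    image = np.asarray(image, dtype=np.complex128)
    if image.ndim != 2:
        raise ValidationError("kspace_resize expects a 2-D image")
    th, tw = int(target[0]), int(target[1])
    h, w = image.shape
    if th > h or tw > w or th < 1 or tw < 1:
        raise ValidationError(f"target {target} must be within source shape {image.shape}")
    spec = np.fft.fftshift(np.fft.fft2(image))
    r0 = (h - th) // 2
    c0 = (w - tw) // 2
    cropped = spec[r0 : r0 + th, c0 : c0 + tw]
    out = np.fft.ifft2(np.fft.ifftshift(cropped))
    return out * (th * tw) / (h * w)


def threshold_mask(echoes: EchoSeries, threshold_fraction: float = 0.05) -> np.ndarray:
    """Background mask: mean all-echo magnitude above a fraction of its max."""
    if not (0.0 < threshold_fraction < 1.0):
        raise ValidationError("threshold_fraction must be in (0, 1)")
    mean_mag = np.abs(echoes.data).mean(axis=0)
    peak = mean_mag.max()
    return mean_mag > threshold_fraction * peak
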