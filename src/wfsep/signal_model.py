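"""Physics core for chemical-shift-encoded (CSE) MRI water-fat separation.

A multi-echo gradient-echo acquisition samples, at echo times ``TE_n``, the
complex voxel signal

    I_n = exp(-R2* . TE_n) . exp(j 2 pi df . TE_n)
          . [ PW + PF . sum_p alpha_p exp(j 2 pi f_{F,p} TE_n) ]

where ``PW``/``PF`` are the complex water and fat signals, ``R2*`` the
effective transverse relaxation rate (1/s), ``df`` the off-resonance field
map (Hz) and ``(f_{F,p}, alpha_p)`` the multi-peak fat spectrum with
``sum_p alpha_p = 1``.  The proton density fat fraction follows as

    PDFF = |PF| / (|PW| + |PF|).

Everything downstream (phantom generation, voxel fitting, network training)
goes through the forward model and PDFF definition implemented here.
Units are SI throughout: seconds, Hz, 1/s.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ValidationError",
    "GYROMAGNETIC_RATIO_MHZ_PER_T",
    "FatSpectrum",
    "AcquisitionParams",
    "ParameterMaps",
    "EchoSeries",
    "PdffMap",
    "fat_modulation",
    "simulate_signal",
    "compute_pdff",
    "default_liver_spectrum",
]

#: Proton gyromagnetic ratio over 2*pi, in MHz/T (so f[Hz] = gamma_bar * B0[T] * ppm).
GYROMAGNETIC_RATIO_MHZ_PER_T = 42.577478518


class ValidationError(ValueError):
    """A domain object or argument violates its contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FatSpectrum:
    """Multi-peak fat spectrum: peak frequencies (Hz) and relative amplitudes.

    Frequencies are offsets from the water resonance; negative values lie
    upfield of water (the dominant methylene peak is near -217 Hz at 1.5 T).
    Amplitudes are dimensionless and must sum to 1.
    """

    peak_frequencies_hz: tuple[float, ...]
    relative_amplitudes: tuple[float, ...]

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.peak_frequencies_hz)
        amps = tuple(float(a) for a in self.relative_amplitudes)
        object.__setattr__(self, "peak_frequencies_hz", freqs)
        object.__setattr__(self, "relative_amplitudes", amps)
        if len(freqs) != len(amps):
            raise ValidationError(
                f"peak count mismatch: {len(freqs)} frequencies vs {len(amps)} amplitudes"
            )
        if len(freqs) < 1:
            raise ValidationError("a fat spectrum needs at least one peak")
        if any(a <= 0 for a in amps):
            raise ValidationError("all relative amplitudes must be positive")
        if abs(sum(amps) - 1.0) > 1e-9:
            raise ValidationError(
                f"relative amplitudes must sum to 1 (got {sum(amps):.12g})"
            )

    @property
    def n_peaks(self) -> int:
        return len(self.peak_frequencies_hz)

    @classmethod
    def from_ppm(
        cls,
        ppm_offsets: "list[float] | tuple[float, ...]",
        relative_amplitudes: "list[float] | tuple[float, ...]",
        field_strength_t: float,
    ) -> "FatSpectrum":
        """Convert ppm offsets (relative to water) to Hz at a given B0.

        Amplitudes are renormalised to sum exactly to 1 so that tabulated
        values rounded to three decimals remain valid.
        """
        if field_strength_t <= 0:
            raise ValidationError("field strength must be positive")
        larmor_hz_per_ppm = GYROMAGNETIC_RATIO_MHZ_PER_T * field_strength_t
        freqs = tuple(larmor_hz_per_ppm * p for p in ppm_offsets)
        total = float(np.sum(relative_amplitudes))
        amps = tuple(float(a) / total for a in relative_amplitudes)
        return cls(freqs, amps)


@dataclass(frozen=True)
class AcquisitionParams:
    """Multi-echo gradient-echo timing: TE_n = te1_s + (n-1) * delta_te_s."""

    te1_s: float
    delta_te_s: float
    n_echoes: int
    field_strength_t: float = 1.5

    def __post_init__(self) -> None:
        if self.te1_s <= 0:
            raise ValidationError("te1_s must be positive")
        if self.delta_te_s <= 0:
            raise ValidationError("delta_te_s must be positive")
        if self.n_echoes < 1:
            raise ValidationError("n_echoes must be >= 1")
        if self.field_strength_t <= 0:
            raise ValidationError("field strength must be positive")

    @property
    def echo_times_s(self) -> np.ndarray:
        return self.te1_s + np.arange(self.n_echoes) * self.delta_te_s

    @classmethod
    def from_ms(
        cls, te1_ms: float, delta_te_ms: float, n_echoes: int, field_strength_t: float = 1.5
    ) -> "AcquisitionParams":
        """Boundary convenience: echo timing given in milliseconds."""
        return cls(te1_ms * 1e-3, delta_te_ms * 1e-3, n_echoes, field_strength_t)


def _as_2d(name: str, arr, dtype) -> np.ndarray:
    out = np.asarray(arr, dtype=dtype)
    if out.ndim != 2:
        raise ValidationError(f"{name} must be a 2-D array, got ndim={out.ndim}")
    return out


@dataclass
class ParameterMaps:
    """Per-voxel water/fat signals, R2* (1/s), field map (Hz), and body mask.

    Water and fat are complex (a shared initial phase is physical); PDFF uses
    their magnitudes only.  Outside the mask every map is zero.
    """

    water: np.ndarray
    fat: np.ndarray
    r2star_per_s: np.ndarray
    fieldmap_hz: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.water = _as_2d("water", self.water, np.complex128)
        self.fat = _as_2d("fat", self.fat, np.complex128)
        self.r2star_per_s = _as_2d("r2star_per_s", self.r2star_per_s, np.float64)
        self.fieldmap_hz = _as_2d("fieldmap_hz", self.fieldmap_hz, np.float64)
        self.mask = _as_2d("mask", self.mask, bool)
        shapes = {
            a.shape
            for a in (self.water, self.fat, self.r2star_per_s, self.fieldmap_hz, self.mask)
        }
        if len(shapes) != 1:
            raise ValidationError(f"map arrays must share one shape, got {shapes}")
        if np.any(self.r2star_per_s[self.mask] < 0):
            raise ValidationError("r2star_per_s must be >= 0 inside the mask")
        outside = ~self.mask
        for name in ("water", "fat", "r2star_per_s", "fieldmap_hz"):
            if np.any(getattr(self, name)[outside] != 0):
                raise ValidationError(f"{name} must be zero outside the mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @classmethod
    def zeros(cls, shape: tuple[int, int]) -> "ParameterMaps":
        return cls(
            water=np.zeros(shape, np.complex128),
            fat=np.zeros(shape, np.complex128),
            r2star_per_s=np.zeros(shape),
            fieldmap_hz=np.zeros(shape),
            mask=np.zeros(shape, bool),
        )


@dataclass
class EchoSeries:
    """Complex multi-echo image stack, shape (n_echoes, H, W)."""

    data: np.ndarray
    echo_times_s: tuple[float, ...]
    acquisition: AcquisitionParams

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        self.echo_times_s = tuple(float(t) for t in self.echo_times_s)
        if self.data.ndim != 3:
            raise ValidationError("echo data must have shape (n_echoes, H, W)")
        if self.data.shape[0] != len(self.echo_times_s):
            raise ValidationError(
                f"leading dim {self.data.shape[0]} != number of echo times "
                f"{len(self.echo_times_s)}"
            )
        if self.data.shape[0] != self.acquisition.n_echoes:
            raise ValidationError("echo count inconsistent with acquisition parameters")
        tes = np.asarray(self.echo_times_s)
        if np.any(np.diff(tes) <= 0):
            raise ValidationError("echo times must be strictly increasing")
        if not np.allclose(tes, self.acquisition.echo_times_s, rtol=0, atol=1e-9):
            raise ValidationError("echo times inconsistent with acquisition parameters")

    @property
    def n_echoes(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class PdffMap:
    """Proton density fat fraction in [0, 1], with the validity mask."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = _as_2d("values", self.values, np.float64)
        self.mask = _as_2d("mask", self.mask, bool)
        if self.values.shape != self.mask.shape:
            raise ValidationError("values and mask must share a shape")
        inside = self.values[self.mask]
        if inside.size and (np.any(~np.isfinite(inside)) or np.any(inside < 0) or np.any(inside > 1)):
            raise ValidationError("PDFF must be finite and in [0, 1] inside the mask")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def fat_modulation(te_s, spectrum: FatSpectrum):
    """Complex fat dephasing factor ``sum_p alpha_p exp(j 2 pi f_p te)``.

    Accepts a scalar echo time or an array of echo times; the magnitude is
    bounded by 1 (triangle inequality) and equals 1 at te = 0.
    """
    te = np.asarray(te_s, dtype=np.float64)
    if np.any(te < 0):
        raise ValidationError("echo times must be non-negative")
    freqs = np.asarray(spectrum.peak_frequencies_hz)
    amps = np.asarray(spectrum.relative_amplitudes)
    phase = 2j * np.pi * np.multiply.outer(te, freqs)
    out = (amps * np.exp(phase)).sum(axis=-1)
    return complex(out) if np.isscalar(te_s) or te.ndim == 0 else out


def simulate_signal(
    maps: ParameterMaps, acq: AcquisitionParams, spectrum: FatSpectrum
) -> EchoSeries:
    """Forward-simulate the multi-echo complex signal from parameter maps.

    Voxels outside the mask are exactly zero (the maps are zero there by
    contract, and decay/off-resonance factors multiply zero).
    """
    tes = acq.echo_times_s
    cf = fat_modulation(tes, spectrum)  # (n_echoes,)
    te_col = tes[:, None, None]
    decay = np.exp(-maps.r2star_per_s[None] * te_col)
    offres = np.exp(2j * np.pi * maps.fieldmap_hz[None] * te_col)
    composition = maps.water[None] + maps.fat[None] * cf[:, None, None]
    data = decay * offres * composition
    data[:, ~maps.mask] = 0.0
    return EchoSeries(data=data, echo_times_s=tuple(tes), acquisition=acq)


def compute_pdff(maps: ParameterMaps) -> PdffMap:
    """PDFF = |PF| / (|PW| + |PF|), with zero-signal voxels defined as 0.

    Voxels where |PW| + |PF| = 0 carry no composition information; they are
    set to 0 and removed from the returned mask to avoid NaN propagation.
    """
    aw = np.abs(maps.water)
    af = np.abs(maps.fat)
    denom = aw + af
    nonzero = denom > 0
    values = np.zeros(maps.shape)
    values[nonzero] = af[nonzero] / denom[nonzero]
    return PdffMap(values=values, mask=maps.mask & nonzero)


def default_liver_spectrum(field_strength_t: float = 1.5, config_path=None) -> FatSpectrum:
    """Standard six-peak liver fat spectrum at the given field strength.

    Peak locations and amplitudes are loaded from a YAML configuration (the
    packaged triglyceride model by default; pass ``config_path`` to override)
    and converted from ppm offsets to Hz via f = gamma_bar * B0 * ppm.
    """
    if config_path is None:
        ref = importlib.resources.files("wfsep").joinpath("data/liver_spectrum_6peak.yaml")
        text = ref.read_text()
    else:
        with open(config_path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    try:
        ppm = cfg["ppm_offsets"]
        amps = cfg["relative_amplitudes"]
    except (TypeError, KeyError) as exc:
        raise ValidationError(f"fat spectrum config missing field: {exc}") from exc
    return FatSpectrum.from_ppm(ppm, amps, field_strength_t)
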