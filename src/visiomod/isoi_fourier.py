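"""Per-pixel spectral analysis of intrinsic-signal imaging stacks.

Intrinsic-signal optical imaging (ISOI) records tiny periodic reflectance
changes of cortex under red light while a periodic visual stimulus plays.
The pipeline here mirrors the standard acquisition chain: 12-bit frames at
30 Hz are binned 4× temporally and 2×2 spatially by *summation* (16 samples
of 12-bit data fit exactly in 16 bits: 16 × 4095 = 65520), and each binned
pixel's time course is reduced to the complex Fourier coefficient at the
stimulus frequency. The coefficient's argument gives the response phase
(retinotopic position under a drifting-bar stimulus) and its magnitude,
normalised per pixel, gives the fractional reflectance modulation ΔR/R.

Normalisation convention: for a pixel x[t] = m·(1 + a·cos(2πft + φ)) sampled
over an integer number of cycles, ``magnitude`` returns exactly ``a`` and
``phase`` returns ``φ`` (forward-transform coefficient, e^{-iωt} kernel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ImagingStack",
    "FourierMaps",
    "bin_stack",
    "fourier_maps",
    "delta_r_over_r_map",
]


@dataclass
class ImagingStack:
    """A T×H×W frame sequence with acquisition metadata.

    ``bit_depth`` is 12 or 16 for integer stacks, or the string ``"float"``
    for synthetic / derived real-valued stacks.
    """

    frames: np.ndarray
    frame_rate_hz: float
    bit_depth: int | str = 16
    modality: str = "isoi"  # isoi | twophoton
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T×H×W, got shape {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("stack needs at least one frame")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.bit_depth != "float":
            depth = int(self.bit_depth)
            if np.issubdtype(self.frames.dtype, np.integer):
                mx = self.frames.max(initial=0)
                if mx >= 2 ** depth:
                    raise ValueError(
                        f"pixel value {mx} exceeds declared bit depth {depth}"
                    )
            if self.frames.min(initial=0) < 0:
                raise ValueError("integer stacks must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.frame_rate_hz


@dataclass
class FourierMaps:
    """Magnitude (ΔR/R, dimensionless) and phase maps at one frequency.

    ``magnitude`` is the single-sided fractional modulation amplitude;
    ``phase`` is in [-π, π) and set to 0 wherever magnitude is undefined
    (zero-mean pixels, recorded in ``undefined_mask``).
    """

    magnitude: np.ndarray
    phase: np.ndarray
    analysis_frequency_hz: float
    frame_rate_hz: float
    binning: tuple[int, int] = (1, 1)  # (temporal, spatial)
    mean_image: np.ndarray | None = None
    undefined_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase shapes differ")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude map must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitude.shape


def bin_stack(
    stack: ImagingStack,
    temporal_factor: int = 4,
    spatial_factor: int = 2,
    *,
    method: str = "sum",
) -> ImagingStack:
    """Bin a stack temporally and spatially.

    The default is summation, which turns 12-bit input into data that
    exactly fills a 16-bit container (max 16 × 4095 = 65520). ``method=
    "mean"`` divides by the bin size instead and yields a float stack.
    Trailing frames/rows/columns that do not fill a bin are dropped (with
    a warning for the spatial dimensions).
    """
    if temporal_factor < 1 or spatial_factor < 1:
        raise ValueError("binning factors must be >= 1")
    if method not in ("sum", "mean"):
        raise ValueError("method must be 'sum' or 'mean'")
    frames = stack.frames
    T, H, W = frames.shape
    if T < temporal_factor:
        raise ValueError(f"need at least {temporal_factor} frames, got {T}")
    if H % spatial_factor or W % spatial_factor:
        warnings.warn(
            f"spatial dims ({H}, {W}) not divisible by {spatial_factor}; "
            "trailing rows/cols dropped",
            stacklevel=2,
        )
    Tb = T // temporal_factor
    Hb = H // spatial_factor
    Wb = W // spatial_factor
    cropped = frames[: Tb * temporal_factor, : Hb * spatial_factor, : Wb * spatial_factor]
    work = cropped.astype(np.int64) if np.issubdtype(cropped.dtype, np.integer) else cropped.astype(float)
    binned = work.reshape(Tb, temporal_factor, Hb, spatial_factor, Wb, spatial_factor)
    binned = binned.sum(axis=(1, 3, 5))

    n_samples = temporal_factor * spatial_factor * spatial_factor
    if method == "mean":
        out = binned / n_samples
        bit_depth: int | str = "float"
    elif np.issubdtype(cropped.dtype, np.integer):
        if binned.max(initial=0) >= 2 ** 16:
            raise OverflowError(
                f"binned sum {binned.max()} exceeds 16-bit range; "
                "input deeper than 12 bits cannot be sum-binned into uint16"
            )
        out = binned.astype(np.uint16)
        bit_depth = 16
    else:
        out = binned
        bit_depth = "float"
    return ImagingStack(
        frames=out,
        frame_rate_hz=stack.frame_rate_hz / temporal_factor,
        bit_depth=bit_depth,
        modality=stack.modality,
        meta={**stack.meta, "binning": (temporal_factor, spatial_factor), "bin_method": method},
    )


def fourier_maps(
    stack: ImagingStack,
    f_analysis_hz: float,
    *,
    detrend: str = "mean",
) -> FourierMaps:
    """Extract per-pixel magnitude and phase at the stimulus frequency.

    The discrete Fourier coefficient at the bin nearest ``f_analysis_hz`` is
    computed on each pixel's mean-subtracted (optionally linearly detrended)
    time course; magnitude is the single-sided amplitude 2|c|/T divided by
    the pixel's temporal mean, i.e. the fractional modulation ΔR/R.

    Requires at least two stimulus cycles in the record and an analysis
    frequency below Nyquist.
    """
    if detrend not in ("mean", "linear"):
        raise ValueError("detrend must be 'mean' or 'linear'")
    frames = np.asarray(stack.frames, dtype=float)
    T = frames.shape[0]
    fs = stack.frame_rate_hz
    if f_analysis_hz <= 0:
        raise ValueError("analysis frequency must be > 0")
    if f_analysis_hz >= fs / 2:
        raise ValueError(
            f"analysis frequency {f_analysis_hz} Hz is at/above Nyquist ({fs / 2} Hz)"
        )
    k = int(round(f_analysis_hz * T / fs))
    if k < 2:
        raise ValueError(
            f"record spans {f_analysis_hz * T / fs:.2f} stimulus cycles; "
            "need at least 2 to resolve the stimulus frequency"
        )

    mean_img = frames.mean(axis=0)
    if detrend == "linear":
        t = np.arange(T, dtype=float)
        t0 = t - t.mean()
        slope = np.tensordot(t0, frames, axes=(0, 0)) / np.dot(t0, t0)
        resid = frames - mean_img[None] - slope[None] * t0[:, None, None]
    else:
        resid = frames - mean_img[None]

    kernel = np.exp(-2j * np.pi * k * np.arange(T) / T)
    coeff = np.tensordot(kernel, resid, axes=(0, 0))

    with np.errstate(divide="ignore", invalid="ignore"):
        magnitude = (2.0 * np.abs(coeff) / T) / mean_img
    undefined = ~np.isfinite(magnitude) | (mean_img <= 0)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} pixel(s) have non-positive mean; "
            "their ΔR/R is undefined and set to 0",
            stacklevel=2,
        )
    magnitude = np.where(undefined, 0.0, magnitude)
    phase = np.where(undefined | (magnitude == 0), 0.0, np.angle(coeff))

    return FourierMaps(
        magnitude=magnitude,
        phase=phase,
        analysis_frequency_hz=k * fs / T,
        frame_rate_hz=fs,
        binning=tuple(stack.meta.get("binning", (1, 1))),
        mean_image=mean_img,
        undefined_mask=undefined,
    )


def delta_r_over_r_map(maps: FourierMaps) -> np.ndarray:
    """The fractional-modulation (ΔR/R) magnitude map.

    An accessor: the magnitude map is already mean-normalised per pixel.
    """
    return maps.magnitude
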