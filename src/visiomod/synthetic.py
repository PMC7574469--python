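"""Ground-truthed synthetic cortical imaging data.

Real recordings of this kind are not publicly deposited, so every stage of
the analysis is validated against simulations whose ground truth is known
exactly:

* :func:`make_cortex_scene` lays out a V1-like primary area plus mirrored
  satellite areas (LM, AL, RL) on a pixel canvas, each carrying a smooth
  linear retinotopic map whose field sign alternates along the chain —
  the structure that field-sign segmentation assumes.
* :func:`simulate_isoi` renders a 30-Hz widefield reflectance stack in
  which each area modulates at the stimulus frequency with a configurable
  fractional amplitude, after convolution with a gamma-shaped hemodynamic
  kernel, over shot noise and spatially correlated 1/f noise.
* :func:`simulate_bar_retinotopy` renders drifting-bar sweeps whose
  response phase encodes each pixel's mapped visual-field coordinate.
* :func:`simulate_calcium` renders GCaMP6s-like ΔF/F traces whose firing
  rate is locked to the speed-up / slow-down transitions of a slow-fast
  grating cycle, with genotype- and cell-class-dependent effect profiles.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .isoi_fourier import ImagingStack
from .stimulus import StimulusProtocol, transition_frames

__all__ = [
    "CortexArea",
    "CortexScene",
    "SyntheticCellParams",
    "CalciumSimulation",
    "make_cortex_scene",
    "hemodynamic_kernel",
    "calcium_kernel",
    "response_waveform",
    "simulate_isoi",
    "simulate_bar_retinotopy",
    "simulate_calcium",
    "make_population",
    "render_cells_movie",
    "DEFAULT_AMPLITUDES",
    "MODULATION_PROFILES",
]

# Fractional reflectance-modulation amplitudes per area for the default
# grating drive. HVA amplitudes are set below V1's, in line with widefield
# responses being strongest in V1.
DEFAULT_AMPLITUDES = {"V1": 0.010, "LM": 0.007, "AL": 0.008, "RL": 0.004}

#: mean resting reflectance level, 12-bit counts
DEFAULT_BASELINE_COUNTS = 2000.0

#: visual-field extent the scene maps, degrees
AZIMUTH_SPAN_DEG = (0.0, 90.0)
ELEVATION_SPAN_DEG = (0.0, 60.0)


@dataclass
class CortexArea:
    """One cortical visual area: mask, retinotopic map, mirror parity."""

    name: str
    mask: np.ndarray  # H×W bool
    azimuth_deg: np.ndarray  # H×W, NaN outside mask
    elevation_deg: np.ndarray
    parity: int  # ±1 visual field sign

    def __post_init__(self) -> None:
        if self.parity not in (-1, 1):
            raise ValueError("parity must be ±1")
        if not self.mask.any():
            raise ValueError(f"area {self.name!r} has an empty mask")


@dataclass
class CortexScene:
    """Canvas of disjoint retinotopically mapped areas plus response params."""

    shape: tuple[int, int]
    areas: list[CortexArea]
    amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    baseline_counts: float = DEFAULT_BASELINE_COUNTS
    hemo_peak_s: float = 2.0

    def __post_init__(self) -> None:
        occupancy = np.zeros(self.shape, dtype=int)
        for area in self.areas:
            if area.mask.shape != self.shape:
                raise ValueError(f"area {area.name!r} mask shape mismatch")
            occupancy += area.mask
        if (occupancy > 1).any():
            raise ValueError("area masks overlap")

    def area(self, name: str) -> CortexArea:
        for a in self.areas:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.areas]


def _ellipse_mask(shape, center, radii) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return ((yy - center[0]) / radii[0]) ** 2 + ((xx - center[1]) / radii[1]) ** 2 <= 1.0


# Default layout on a 128×128 canvas (rows: anterior at low index; columns:
# lateral at high index). V1 posterior-medial and largest; LM lateral to V1;
# AL anterior-lateral; RL anterior to AL. Radii/centres scale with the canvas.
_DEFAULT_LAYOUT = {
    "V1": {"center": (0.69, 0.31), "radii": (0.25, 0.20), "parity": +1},
    "LM": {"center": (0.67, 0.67), "radii": (0.11, 0.094), "parity": -1},
    "AL": {"center": (0.44, 0.72), "radii": (0.094, 0.086), "parity": +1},
    "RL": {"center": (0.23, 0.63), "radii": (0.086, 0.078), "parity": -1},
}


def make_cortex_scene(
    shape: tuple[int, int] = (128, 128),
    layout: dict | None = None,
    amplitudes: dict | None = None,
    seed: int | None = None,
) -> CortexScene:
    """Build the default cortical scene: V1 plus mirrored LM, AL, RL.

    Each area carries a linear retinotopic map covering the full simulated
    visual field; mirror parity flips the azimuth gradient, so adjacent
    areas along the V1→LM→AL→RL chain alternate field sign. Deterministic:
    ``seed`` is accepted for interface uniformity but the default layout is
    parameter-driven.
    """
    layout = dict(_DEFAULT_LAYOUT if layout is None else layout)
    H, W = shape
    areas = []
    for name, spec in layout.items():
        cy, cx = spec["center"]
        ry, rx = spec["radii"]
        mask = _ellipse_mask(shape, (cy * H, cx * W), (max(ry * H, 2.0), max(rx * W, 2.0)))
        if not mask.any():
            raise ValueError(f"canvas {shape} too small for area {name!r}")
        ys, xs = np.nonzero(mask)
        y0, y1 = ys.min(), ys.max()
        x0, x1 = xs.min(), xs.max()
        # local coordinates in [0, 1] across the area's bounding box
        u = np.full(shape, np.nan)
        v = np.full(shape, np.nan)
        u[mask] = (xs - x0) / max(x1 - x0, 1)
        v[mask] = (ys - y0) / max(y1 - y0, 1)
        parity = int(spec["parity"])
        if parity < 0:  # mirror image: azimuth runs the other way
            u[mask] = 1.0 - u[mask]
        az = np.full(shape, np.nan)
        el = np.full(shape, np.nan)
        az[mask] = AZIMUTH_SPAN_DEG[0] + u[mask] * (AZIMUTH_SPAN_DEG[1] - AZIMUTH_SPAN_DEG[0])
        el[mask] = ELEVATION_SPAN_DEG[0] + v[mask] * (ELEVATION_SPAN_DEG[1] - ELEVATION_SPAN_DEG[0])
        areas.append(CortexArea(name=name, mask=mask, azimuth_deg=az,
                                elevation_deg=el, parity=parity))
    return CortexScene(shape=shape, areas=areas,
                       amplitudes=dict(DEFAULT_AMPLITUDES if amplitudes is None else amplitudes))


# -- kernels ------------------------------------------------------------

def hemodynamic_kernel(frame_rate_hz: float, peak_s: float = 2.0,
                       duration_s: float = 12.0) -> np.ndarray:
    """Gamma-shaped causal impulse response, unit area, peak at ``peak_s``.

    Only the stimulus-frequency Fourier coefficient of the convolved
    waveform matters downstream, so any smooth causal kernel would do; the
    gamma shape with a ~2 s peak is a conventional stand-in for the
    intrinsic-signal hemodynamic response.
    """
    k = 3.0  # shape; peak at (k-1)*theta
    theta = peak_s / (k - 1.0)
    t = np.arange(0.0, duration_s, 1.0 / frame_rate_hz)
    h = t ** (k - 1.0) * np.exp(-t / theta)
    return h / h.sum()


def calcium_kernel(frame_rate_hz: float, rise_s: float = 0.2, decay_s: float = 1.8,
                   duration_s: float = 12.0) -> np.ndarray:
    """Difference-of-exponentials GCaMP6s-like kernel, unit area.

    ``decay_s`` must exceed ``rise_s``; defaults emulate the slow,
    high-sensitivity indicator used for the cellular recordings.
    """
    if not (decay_s > rise_s > 0):
        raise ValueError("need decay_s > rise_s > 0")
    t = np.arange(0.0, duration_s, 1.0 / frame_rate_hz)
    h = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return h / h.sum()


def _circular_convolve(cycle: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Steady-state response of a periodic drive: circular convolution,
    folding a kernel longer than one cycle back onto the cycle."""
    n = cycle.size
    k = np.zeros(n)
    for i, v in enumerate(kernel):
        k[i % n] += v
    return np.real(np.fft.ifft(np.fft.fft(cycle) * np.fft.fft(k)))


def _fundamental_amplitude(cycle: np.ndarray) -> float:
    """Single-sided amplitude of the first harmonic of one cycle."""
    n = cycle.size
    return 2.0 * np.abs(np.fft.fft(cycle)[1]) / n


def response_waveform(protocol: StimulusProtocol, *, peak_s: float = 2.0,
                      normalize_fundamental: bool = True) -> np.ndarray:
    """One cycle of the hemodynamic response to the stimulus envelope.

    The neural drive is modelled as an indicator of the "on" epoch (the
    fast epoch of a grating cycle; the moving epoch of an RDK cycle),
    convolved with the hemodynamic kernel and mean-subtracted. With
    ``normalize_fundamental`` the waveform is scaled so its first harmonic
    has single-sided amplitude 1: an area simulated with amplitude ``a``
    then yields a ΔR/R magnitude of exactly ``a`` at the stimulus
    frequency.
    """
    if protocol.kind not in ("grating_cycle", "rdk_cycle"):
        raise ValueError(f"no envelope waveform for protocol kind {protocol.kind!r}")
    env = np.zeros(protocol.cycle_frames)
    bounds = np.cumsum((0,) + protocol.epoch_frames)
    if protocol.kind == "grating_cycle":
        on = 1  # fast epoch
    else:
        on = 0  # moving epoch
    env[bounds[on]: bounds[on + 1]] = 1.0
    kernel = hemodynamic_kernel(protocol.frame_rate_hz, peak_s=peak_s)
    w = _circular_convolve(env, kernel)
    w -= w.mean()
    if normalize_fundamental:
        amp = _fundamental_amplitude(w)
        if amp <= 0:
            raise ValueError("stimulus envelope has no power at the fundamental")
        w /= amp
    return w


def _pink_noise_field(rng: np.ndarray, shape: tuple[int, int, int],
                      amplitude: float, n_components: int = 8) -> np.ndarray:
    """Spatially correlated 1/f temporal noise as a low-rank field.

    A handful of global 1/f time courses weighted by smooth random spatial
    maps — emulating the shared slow hemodynamic drifts that dominate
    widefield recordings — rather than independent pink noise per pixel.
    """
    from scipy.ndimage import gaussian_filter

    T, H, W = shape
    freqs = np.fft.rfftfreq(T, d=1.0)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    comps = np.empty((n_components, T))
    for i in range(n_components):
        spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) * scale
        x = np.fft.irfft(spec, n=T)
        sd = x.std()
        comps[i] = x / sd if sd > 0 else x
    maps = rng.standard_normal((n_components, H, W))
    for i in range(n_components):
        maps[i] = gaussian_filter(maps[i], sigma=max(H, W) / 8.0)
        maps[i] /= max(np.abs(maps[i]).max(), 1e-12)
    field = np.tensordot(comps.T, maps, axes=(1, 0))  # T×H×W
    return amplitude * field / np.sqrt(n_components)


def _finalize_stack(signal: np.ndarray, rng, shot_sd: float, pink_amplitude: float,
                    quantize: bool, frame_rate_hz: float, meta: dict) -> ImagingStack:
    if pink_amplitude > 0:
        signal = signal + _pink_noise_field(rng, signal.shape, pink_amplitude)
    if shot_sd > 0:
        signal = signal + rng.normal(0.0, shot_sd, size=signal.shape)
    if quantize:
        lo, hi = 0.0, 4095.0
        if signal.min() < lo or signal.max() > hi:
            warnings.warn("synthetic reflectance clipped to the 12-bit range", stacklevel=3)
        frames = np.clip(np.round(signal), lo, hi).astype(np.uint16)
        return ImagingStack(frames=frames, frame_rate_hz=frame_rate_hz,
                            bit_depth=12, modality="isoi", meta=meta)
    return ImagingStack(frames=signal, frame_rate_hz=frame_rate_hz,
                        bit_depth="float", modality="isoi", meta=meta)


def simulate_isoi(
    scene: CortexScene,
    protocol: StimulusProtocol,
    *,
    amplitudes: dict | None = None,
    shot_sd: float = 5.0,
    pink_amplitude: float = 2.0,
    quantize: bool = True,
    seed: int = 0,
) -> ImagingStack:
    """Render a widefield reflectance stack for a periodic grating/RDK drive.

    Each in-area pixel follows ``baseline × (1 + a · w(t))`` where ``w`` is
    the kernel-convolved stimulus waveform (fundamental amplitude 1) and
    ``a`` the area's fractional modulation amplitude; pixels outside any
    area stay at baseline. Shot noise (i.i.d. Gaussian, counts) and
    spatially correlated 1/f noise are added, and frames are rounded and
    clipped to the 12-bit range unless ``quantize=False``.
    """
    rng = np.random.default_rng(seed)
    amps = dict(scene.amplitudes)
    if amplitudes:
        amps.update(amplitudes)
    w = response_waveform(protocol, peak_s=scene.hemo_peak_s)
    T = protocol.total_frames
    wt = np.tile(w, protocol.n_cycles)
    H, W = scene.shape
    amp_map = np.zeros((H, W))
    for area in scene.areas:
        amp_map[area.mask] = amps.get(area.name, 0.0)
    signal = scene.baseline_counts * (1.0 + wt[:, None, None] * amp_map[None, :, :])
    meta = {"protocol": protocol.name, "seed": seed, "kind": protocol.kind}
    return _finalize_stack(signal, rng, shot_sd, pink_amplitude, quantize,
                           protocol.frame_rate_hz, meta)


def simulate_bar_retinotopy(
    scene: CortexScene,
    axis: str,
    *,
    n_cycles: int = 4,
    sweep_duration_s: float = 8.0,
    frame_rate_hz: float = 30.0,
    amplitude: float | None = None,
    bump_width: float = 0.08,
    shot_sd: float = 5.0,
    pink_amplitude: float = 2.0,
    quantize: bool = True,
    seed: int = 0,
) -> ImagingStack:
    """Render drifting-bar sweeps that encode retinotopy in response phase.

    ``axis="vertical"`` is the vertical bar sweeping horizontally (azimuth
    map); ``axis="horizontal"`` the horizontal bar (elevation map). Each
    in-area pixel responds with a periodic wrapped-Gaussian bump (width
    ``bump_width`` cycles) centred at the time the bar crosses its mapped
    coordinate, convolved with the hemodynamic kernel. Response phase is
    therefore proportional to the mapped coordinate, up to a global offset.
    """
    if axis not in ("horizontal", "vertical"):
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    rng = np.random.default_rng(seed)
    Tc = int(round(sweep_duration_s * frame_rate_hz))
    # one-cycle template: bump at phase 0, hemodynamically smoothed
    s = np.arange(Tc) / Tc
    d = np.minimum(s, 1.0 - s)
    bump = np.exp(-0.5 * (d / bump_width) ** 2)
    kernel = hemodynamic_kernel(frame_rate_hz, peak_s=scene.hemo_peak_s)
    wav = _circular_convolve(bump, kernel)
    wav -= wav.mean()
    wav /= _fundamental_amplitude(wav)

    H, W = scene.shape
    T = Tc * n_cycles
    signal = np.full((T, H, W), scene.baseline_counts)
    lo, hi = AZIMUTH_SPAN_DEG if axis == "vertical" else ELEVATION_SPAN_DEG
    for area in scene.areas:
        a = scene.amplitudes.get(area.name, 0.0) if amplitude is None else amplitude
        if a == 0:
            continue
        coord = area.azimuth_deg if axis == "vertical" else area.elevation_deg
        u = (coord[area.mask] - lo) / (hi - lo)
        shifts = np.round(u * Tc).astype(int) % Tc
        ys, xs = np.nonzero(area.mask)
        for sh in np.unique(shifts):
            sel = shifts == sh
            tc = np.tile(np.roll(wav, sh), n_cycles)
            signal[:, ys[sel], xs[sel]] = scene.baseline_counts * (1.0 + a * tc[:, None])
    meta = {"protocol": f"bar_{axis}", "seed": seed, "kind": "drifting_bar",
            "axis": axis, "sweep_frames": Tc}
    return _finalize_stack(signal, rng, shot_sd, pink_amplitude, quantize,
                           frame_rate_hz, meta)


# -- cellular simulation ------------------------------------------------

@dataclass
class SyntheticCellParams:
    """Rate model for one simulated cell.

    The firing-rate drive (in ΔF/F units: a sustained level r produces a
    fluorescence plateau of r once the unit-area calcium kernel settles) is
    piecewise constant over the stimulus cycle — ``baseline`` plus
    ``sd_rate_step`` during the slow epoch and ``su_rate_step`` during the
    fast epoch — plus exponential transients of peak ``su_transient`` /
    ``sd_transient`` (time constant ``transient_tau_s``) launched at the
    corresponding transitions. Transients let the slow-down response be a
    surge rather than the mirror image of the speed-up response.
    """

    cell_id: str
    cell_class: str  # excitatory | inhibitory
    genotype_profile: str  # WT-like | AS-like
    baseline: float = 0.5
    su_rate_step: float = 0.0
    sd_rate_step: float = 0.0
    su_transient: float = 0.0
    sd_transient: float = 0.0
    transient_tau_s: float = 1.0
    rise_s: float = 0.2
    decay_s: float = 1.8
    noise_sd: float = 0.1
    f_rest: float = 100.0

    def __post_init__(self) -> None:
        if not (self.decay_s > self.rise_s > 0):
            raise ValueError("need decay_s > rise_s > 0")
        if self.baseline < 0:
            raise ValueError("baseline rate must be >= 0")


@dataclass
class CalciumSimulation:
    """Observable traces plus the ground truth they were generated from."""

    fluorescence: np.ndarray  # n_cells × T raw F
    dff_clean: np.ndarray  # n_cells × T noiseless ΔF/F
    rate: np.ndarray  # n_cells × T rate drive (after truncation)
    cells: list
    protocol: StimulusProtocol

    @property
    def frame_rate_hz(self) -> float:
        return self.protocol.frame_rate_hz


def _rate_cycle(params: SyntheticCellParams, protocol: StimulusProtocol) -> np.ndarray:
    n = protocol.cycle_frames
    su_frame, _ = transition_frames(protocol)
    rate = np.full(n, params.baseline)
    rate[:su_frame] += params.sd_rate_step  # slow epoch
    rate[su_frame:] += params.su_rate_step  # fast epoch
    dt = protocol.frame_period_s
    t = np.arange(n) * dt
    if params.su_transient:
        dt_su = (t - su_frame * dt) % (n * dt)
        rate += params.su_transient * np.exp(-dt_su / params.transient_tau_s)
    if params.sd_transient:
        dt_sd = t % (n * dt)  # SD transition at the cycle wrap
        rate += params.sd_transient * np.exp(-dt_sd / params.transient_tau_s)
    return rate


def simulate_calcium(
    cells: list,
    protocol: StimulusProtocol,
    *,
    mode: str = "gaussian",
    event_amplitude: float = 0.2,
    seed: int = 0,
) -> CalciumSimulation:
    """Simulate GCaMP6s-like traces locked to a slow-fast grating cycle.

    ``mode="gaussian"`` convolves each cell's rate drive with its calcium
    kernel and adds Gaussian noise — deterministic expected ΔF/F, suited to
    calibration tests. ``mode="poisson"`` draws discrete events per frame at
    the equivalent rate (amplitude ``event_amplitude`` ΔF/F each) before the
    convolution. Negative rate drives are truncated at zero with a warning.
    Returns observable fluorescence alongside the noiseless ΔF/F and rate
    ground truth.
    """
    if protocol.kind != "grating_cycle":
        raise ValueError("calcium simulation expects a grating_cycle protocol")
    if mode not in ("gaussian", "poisson"):
        raise ValueError("mode must be 'gaussian' or 'poisson'")
    rng = np.random.default_rng(seed)
    T = protocol.total_frames
    n_cells = len(cells)
    dff_clean = np.empty((n_cells, T))
    rates = np.empty((n_cells, T))
    F = np.empty((n_cells, T))
    truncated = 0
    dt = protocol.frame_period_s
    for i, p in enumerate(cells):
        cyc = _rate_cycle(p, protocol)
        if (cyc < 0).any():
            truncated += 1
            cyc = np.maximum(cyc, 0.0)
        kernel = calcium_kernel(protocol.frame_rate_hz, p.rise_s, p.decay_s)
        clean_cycle = _circular_convolve(cyc, kernel)
        rate_t = np.tile(cyc, protocol.n_cycles)
        clean = np.tile(clean_cycle, protocol.n_cycles)
        if mode == "poisson":
            nu = rate_t / event_amplitude  # events/s equivalent to the rate drive
            events = rng.poisson(np.maximum(nu * dt, 0.0)).astype(float)
            # E[event_amplitude * events / dt] = rate, so the expected ΔF/F
            # equals the Gaussian-mode clean trace
            dff = np.convolve(event_amplitude * events / dt, kernel)[:T]
        else:
            dff = clean
        obs = dff + rng.normal(0.0, p.noise_sd, size=T)
        F[i] = p.f_rest * (1.0 + obs)
        dff_clean[i] = clean
        rates[i] = rate_t
    if truncated:
        warnings.warn(
            f"{truncated} cell(s) had negative rate drive truncated at 0", stacklevel=2
        )
    return CalciumSimulation(fluorescence=F, dff_clean=dff_clean, rate=rates,
                             cells=list(cells), protocol=protocol)


# Default modulation profiles: (sd_rate_step, su_rate_step, su_transient,
# sd_transient) per genotype × cell class, in ΔF/F-equivalent rate units.
# They encode the qualitative AL effect structure of the study system:
# WT excitatory cells step up at SU with only a slight SD dip; AS
# excitatory cells invert that pattern; WT inhibitory cells surge at SD
# and withdraw at SU; AS inhibitory cells are nearly flat. Values were
# solved (least squares against the linear rate→modulation map of the
# default kernel and timing) so the clean-trace SU/SD modulations land at
# representative published effect sizes; see docs/methods.md.
MODULATION_PROFILES: dict = {}  # filled below


def _register_profiles() -> None:
    prof = {
        ("WT-like", "excitatory"): dict(sd_rate_step=0.0, su_rate_step=0.0660,
                                        su_transient=0.0, sd_transient=0.2127),
        ("AS-like", "excitatory"): dict(sd_rate_step=0.0, su_rate_step=-0.0223,
                                        su_transient=0.0, sd_transient=0.0399),
        ("WT-like", "inhibitory"): dict(sd_rate_step=0.0, su_rate_step=-0.0586,
                                        su_transient=0.0, sd_transient=0.3058),
        ("AS-like", "inhibitory"): dict(sd_rate_step=0.0, su_rate_step=0.0105,
                                        su_transient=0.0, sd_transient=0.0),
    }
    MODULATION_PROFILES.update(prof)


_register_profiles()


def make_population(
    genotype_profile: str,
    cell_class: str,
    n_cells: int,
    *,
    step_jitter_sd: float = 0.15,
    noise_sd: float = 0.1,
    baseline: float = 0.5,
    seed: int = 0,
) -> list:
    """Draw a heterogeneous cell population around a modulation profile.

    Cell-to-cell variability is modelled as independent Gaussian jitter of
    the epoch steps (sd ``step_jitter_sd``, ΔF/F units) — a unimodal
    simplification of the bimodal single-cell response distributions seen
    in vivo, adequate for population-mean statistics.
    """
    key = (genotype_profile, cell_class)
    if key not in MODULATION_PROFILES:
        raise KeyError(f"no profile for {key}")
    base = MODULATION_PROFILES[key]
    rng = np.random.default_rng(seed)
    cells = []
    for i in range(n_cells):
        cells.append(
            SyntheticCellParams(
                cell_id=f"{genotype_profile}_{cell_class}_{i:04d}",
                cell_class=cell_class,
                genotype_profile=genotype_profile,
                baseline=baseline,
                sd_rate_step=base["sd_rate_step"] + rng.normal(0, step_jitter_sd),
                su_rate_step=base["su_rate_step"] + rng.normal(0, step_jitter_sd),
                su_transient=base["su_transient"],
                sd_transient=base["sd_transient"],
                noise_sd=noise_sd,
            )
        )
    return cells


def scene_rois(scene: CortexScene, spatial_bin: int = 2, mode: str = "strict"):
    """Ground-truth area masks at binned map geometry.

    ``mode="strict"`` keeps a binned pixel only if every contributing
    source pixel lies inside the area (so every retained pixel carries the
    full injected amplitude — the right reference for amplitude-recovery
    checks); ``mode="majority"`` keeps it when more than half do, matching
    how full-resolution manual ROIs are downsampled for quantification.
    """
    from .segmentation import AreaROISet

    if mode not in ("strict", "majority"):
        raise ValueError("mode must be 'strict' or 'majority'")
    H, W = scene.shape
    Hb, Wb = H // spatial_bin, W // spatial_bin
    masks = {}
    for area in scene.areas:
        blocks = area.mask[: Hb * spatial_bin, : Wb * spatial_bin].reshape(
            Hb, spatial_bin, Wb, spatial_bin
        )
        frac = blocks.mean(axis=(1, 3))
        masks[area.name] = frac >= 1.0 if mode == "strict" else frac > 0.5
    return AreaROISet(masks=masks, provenance="manual",
                      notes={"source": "synthetic ground truth", "mode": mode})


def render_cells_movie(
    F: np.ndarray,
    masks: list,
    shape: tuple[int, int],
    *,
    background: float = 50.0,
) -> ImagingStack:
    """Paint per-cell fluorescence traces onto disjoint pixel masks.

    A minimal forward model for testing ROI trace extraction: every pixel
    of a cell's mask carries the cell's trace; everything else sits at a
    constant background.
    """
    F = np.asarray(F, dtype=float)
    T = F.shape[1]
    frames = np.full((T, *shape), background)
    occupancy = np.zeros(shape, dtype=int)
    for trace, mask in zip(F, masks):
        occupancy += mask
        frames[:, mask] = trace[:, None]
    if (occupancy > 1).any():
        raise ValueError("cell masks overlap")
    return ImagingStack(frames=frames, frame_rate_hz=1.0 / 0.26727,
                        bit_depth="float", modality="twophoton")
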