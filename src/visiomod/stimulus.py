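"""Visual stimulus protocols and their timing structure.

The analyses in this package are all locked to a periodic stimulus: drifting
square-wave gratings that cycle between a slow and a fast drift speed
(e.g. 0→50 °/s or 10→50 °/s), a random-dot kinematogram with a moving /
stationary envelope, or a single drifting bar used for retinotopic mapping.
Every downstream stage only needs the timing skeleton of the stimulus — the
cycle period (hence the analysis frequency) and the frame indices of the
speed-up (SU, slow→fast) and slow-down (SD, fast→slow) transitions — so that
is all a :class:`StimulusProtocol` stores.

Durations may be given in seconds or in imaging frames; internally everything
is canonicalised to frames at the acquisition rate (round to nearest).
Frame indexing is 0-based and the slow epoch opens each cycle, so the SD
transition sits at the cycle wrap (frame 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "StimulusEpoch",
    "StimulusProtocol",
    "build_grating_protocol",
    "build_rdk_protocol",
    "build_bar_protocol",
    "stimulus_frequency",
    "transition_frames",
    "load_protocol",
    "save_protocol",
]

PROTOCOL_KINDS = ("grating_cycle", "rdk_cycle", "drifting_bar", "orientation_probe")

#: spatial frequency of the square-wave gratings, cycles per degree
DEFAULT_SPATIAL_FREQUENCY_CPD = 0.04


@dataclass(frozen=True)
class StimulusEpoch:
    """One constant-speed segment of a stimulus cycle.

    Exactly one of ``duration_s`` / ``duration_frames`` must be given; the
    protocol converts to frames at its own acquisition rate.
    """

    label: str
    drift_speed_dps: float
    duration_s: float | None = None
    duration_frames: int | None = None
    spatial_frequency_cpd: float | None = DEFAULT_SPATIAL_FREQUENCY_CPD

    def __post_init__(self) -> None:
        if (self.duration_s is None) == (self.duration_frames is None):
            raise ValueError(
                f"epoch {self.label!r}: give exactly one of duration_s / duration_frames"
            )
        if self.duration_s is not None and self.duration_s <= 0:
            raise ValueError(f"epoch {self.label!r}: duration_s must be > 0")
        if self.duration_frames is not None and self.duration_frames <= 0:
            raise ValueError(f"epoch {self.label!r}: duration_frames must be > 0")
        if self.drift_speed_dps < 0:
            raise ValueError(f"epoch {self.label!r}: drift_speed_dps must be >= 0")
        if self.spatial_frequency_cpd is not None and self.spatial_frequency_cpd <= 0:
            raise ValueError(f"epoch {self.label!r}: spatial_frequency_cpd must be > 0")

    def n_frames(self, frame_rate_hz: float) -> int:
        """Duration in frames at ``frame_rate_hz`` (round to nearest)."""
        if self.duration_frames is not None:
            return int(self.duration_frames)
        n = int(round(self.duration_s * frame_rate_hz))
        if n < 1:
            raise ValueError(
                f"epoch {self.label!r}: duration {self.duration_s} s is shorter "
                f"than one frame at {frame_rate_hz} Hz"
            )
        return n


@dataclass(frozen=True)
class StimulusProtocol:
    """A periodic stimulus: ordered epochs repeated for ``n_cycles``.

    For ``grating_cycle`` protocols there are exactly two epochs, slow first
    then fast; ``stimulus_frequency`` is 1 / cycle duration.
    """

    kind: str
    epochs: tuple[StimulusEpoch, ...]
    n_cycles: int
    frame_rate_hz: float
    axis: str | None = None  # drifting_bar only: horizontal | vertical
    name: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if not self.epochs:
            raise ValueError("protocol needs at least one epoch")
        if self.kind == "grating_cycle":
            if len(self.epochs) != 2:
                raise ValueError("grating_cycle protocols have exactly two epochs (slow, fast)")
            slow, fast = self.epochs
            if slow.drift_speed_dps > fast.drift_speed_dps:
                raise ValueError("grating_cycle epochs must be ordered slow then fast")
        if self.kind == "drifting_bar" and self.axis not in ("horizontal", "vertical"):
            raise ValueError("drifting_bar protocols need axis='horizontal'|'vertical'")
        object.__setattr__(self, "epochs", tuple(self.epochs))

    # -- timing ---------------------------------------------------------
    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def epoch_frames(self) -> tuple[int, ...]:
        return tuple(ep.n_frames(self.frame_rate_hz) for ep in self.epochs)

    @property
    def cycle_frames(self) -> int:
        """Frames per stimulus cycle."""
        return int(sum(self.epoch_frames))

    @property
    def cycle_duration_s(self) -> float:
        return self.cycle_frames * self.frame_period_s

    @property
    def total_frames(self) -> int:
        return self.cycle_frames * self.n_cycles


def build_grating_protocol(
    slow_speed_dps: float,
    fast_speed_dps: float,
    slow_duration,
    fast_duration,
    n_cycles: int,
    frame_rate_hz: float | None = None,
    frame_period_s: float | None = None,
    *,
    timing: str = "seconds",
    spatial_frequency_cpd: float = DEFAULT_SPATIAL_FREQUENCY_CPD,
    name: str = "",
) -> StimulusProtocol:
    """Build a slow→fast drifting-grating cycle protocol.

    Parameters
    ----------
    slow_speed_dps, fast_speed_dps
        Drift speeds of the two epochs, degrees of visual angle per second.
        The "still-fast" stimulus is (0, 50); "slow-fast" is (10, 50).
    slow_duration, fast_duration
        Epoch durations, interpreted per ``timing``: ``"seconds"`` or
        ``"frames"``.
    n_cycles
        Number of stimulus repetitions.
    frame_rate_hz, frame_period_s
        Acquisition timing; give exactly one.
    """
    if (frame_rate_hz is None) == (frame_period_s is None):
        raise ValueError("give exactly one of frame_rate_hz / frame_period_s")
    if frame_rate_hz is None:
        frame_rate_hz = 1.0 / frame_period_s
    if timing not in ("seconds", "frames"):
        raise ValueError("timing must be 'seconds' or 'frames'")
    key = "duration_s" if timing == "seconds" else "duration_frames"
    if timing == "frames":
        slow_duration = int(slow_duration)
        fast_duration = int(fast_duration)
    epochs = (
        StimulusEpoch(
            label="slow", drift_speed_dps=slow_speed_dps,
            spatial_frequency_cpd=spatial_frequency_cpd, **{key: slow_duration},
        ),
        StimulusEpoch(
            label="fast", drift_speed_dps=fast_speed_dps,
            spatial_frequency_cpd=spatial_frequency_cpd, **{key: fast_duration},
        ),
    )
    if not name:
        name = f"grating_{slow_speed_dps:g}to{fast_speed_dps:g}dps"
    return StimulusProtocol(
        kind="grating_cycle", epochs=epochs, n_cycles=n_cycles,
        frame_rate_hz=frame_rate_hz, name=name,
    )


def build_rdk_protocol(
    moving_duration_s: float = 6.0,
    stationary_duration_s: float = 2.0,
    n_cycles: int = 50,
    frame_rate_hz: float = 30.0,
) -> StimulusProtocol:
    """Random-dot kinematogram timing envelope: dots move, then hold still.

    Only the on/off envelope matters to the Fourier analysis; dot motion
    itself is never rendered.
    """
    epochs = (
        StimulusEpoch(label="moving", drift_speed_dps=0.0, duration_s=moving_duration_s,
                      spatial_frequency_cpd=None),
        StimulusEpoch(label="stationary", drift_speed_dps=0.0,
                      duration_s=stationary_duration_s, spatial_frequency_cpd=None),
    )
    return StimulusProtocol(kind="rdk_cycle", epochs=epochs, n_cycles=n_cycles,
                            frame_rate_hz=frame_rate_hz, name="rdk")


def build_bar_protocol(
    axis: str,
    sweep_duration_s: float = 8.0,
    n_cycles: int = 20,
    frame_rate_hz: float = 30.0,
) -> StimulusProtocol:
    """Single drifting bar for retinotopic mapping (one sweep per cycle)."""
    epochs = (
        StimulusEpoch(label="sweep", drift_speed_dps=0.0, duration_s=sweep_duration_s,
                      spatial_frequency_cpd=None),
    )
    return StimulusProtocol(kind="drifting_bar", epochs=epochs, n_cycles=n_cycles,
                            frame_rate_hz=frame_rate_hz, axis=axis,
                            name=f"bar_{axis}")


def stimulus_frequency(protocol: StimulusProtocol) -> float:
    """Analysis frequency in Hz: the reciprocal of the cycle duration."""
    return 1.0 / protocol.cycle_duration_s


def transition_frames(protocol: StimulusProtocol) -> tuple[int, int]:
    """0-based within-cycle frame indices of the SU and SD transitions.

    The speed-up (slow→fast) transition is the first frame of the fast
    epoch; the slow-down (fast→slow) transition is the cycle wrap, frame 0.
    Only defined for two-epoch grating cycles.
    """
    if protocol.kind != "grating_cycle":
        raise ValueError(
            f"transition frames are defined for grating_cycle protocols, not {protocol.kind!r}"
        )
    slow_frames, _fast_frames = protocol.epoch_frames
    return int(slow_frames), 0


# -- protocol files -----------------------------------------------------

def _protocol_to_dict(protocol: StimulusProtocol) -> dict:
    d = {
        "kind": protocol.kind,
        "name": protocol.name,
        "n_cycles": protocol.n_cycles,
        "frame_rate_hz": protocol.frame_rate_hz,
        "epochs": [],
    }
    if protocol.axis is not None:
        d["axis"] = protocol.axis
    for ep in protocol.epochs:
        e: dict = {"label": ep.label, "speed_dps": ep.drift_speed_dps}
        if ep.duration_s is not None:
            e["duration_s"] = ep.duration_s
        else:
            e["duration_frames"] = ep.duration_frames
        if ep.spatial_frequency_cpd is not None:
            e["sf_cpd"] = ep.spatial_frequency_cpd
        d["epochs"].append(e)
    return d


def _protocol_from_dict(d: dict) -> StimulusProtocol:
    if "frame_rate_hz" in d:
        rate = float(d["frame_rate_hz"])
    elif "frame_period_ms" in d:
        rate = 1000.0 / float(d["frame_period_ms"])
    else:
        raise ValueError("protocol file needs frame_rate_hz or frame_period_ms")
    epochs = []
    for e in d["epochs"]:
        epochs.append(
            StimulusEpoch(
                label=e.get("label", f"epoch{len(epochs)}"),
                drift_speed_dps=float(e.get("speed_dps", 0.0)),
                duration_s=float(e["duration_s"]) if "duration_s" in e else None,
                duration_frames=int(e["duration_frames"]) if "duration_frames" in e else None,
                spatial_frequency_cpd=float(e["sf_cpd"]) if "sf_cpd" in e else None,
            )
        )
    return StimulusProtocol(
        kind=d["kind"], epochs=tuple(epochs), n_cycles=int(d["n_cycles"]),
        frame_rate_hz=rate, axis=d.get("axis"), name=d.get("name", ""),
    )


def save_protocol(protocol: StimulusProtocol, path) -> None:
    """Write a protocol as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    d = _protocol_to_dict(protocol)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_protocol(path) -> StimulusProtocol:
    """Read a protocol from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _protocol_from_dict(d)
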