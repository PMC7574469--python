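"""Cellular ΔF/F analysis of speed-transition responses.

Two-photon movies (267.27 ms/frame) recorded during a slow-fast grating
cycle (50 frames at 10 °/s, then 50 frames at 50 °/s, 21 cycles) are
reduced per cell to:

* a ΔF/F trace (baseline F0 = a low percentile of the raw trace by
  default), with the first stimulus presentation discarded so 20 cycles
  remain;
* a responsiveness call: one-way ANOVA between the per-cycle mean ΔF/F of
  the slow epoch and of the fast epoch (20 pairs; with two groups the F
  statistic equals t² of the unpaired t test);
* signed modulation values at the two speed transitions, computed on the
  cycle-averaged trace in 25-frame bins — the speed-up (SU) modulation is
  the mean just after minus just before the 10→50 °/s transition, the
  slow-down (SD) modulation likewise around the 50→10 °/s transition at
  the cycle wrap.

Only cells passing the responsiveness test enter the modulation analysis;
population summaries report mean ± SEM by area, genotype, and cell class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .isoi_fourier import ImagingStack
from .stimulus import StimulusProtocol, transition_frames

__all__ = [
    "CellROI",
    "CellTrace",
    "ModulationResult",
    "PopulationSummary",
    "extract_traces",
    "delta_f_over_f",
    "responsive_cells",
    "modulation",
    "population_summary",
    "analyze_cells",
]

DEFAULT_BIN_FRAMES = 25
DEFAULT_F0_PERCENTILE = 10.0
DEFAULT_ALPHA = 0.05


@dataclass
class CellROI:
    """A cell's pixel mask on the imaging field."""

    cell_id: str
    mask: np.ndarray
    plane: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"cell {self.cell_id!r}: empty ROI mask")


@dataclass
class CellTrace:
    """ΔF/F per frame after first-cycle removal, with cycle structure."""

    cell_id: str
    dff: np.ndarray
    protocol: StimulusProtocol
    n_cycles_retained: int
    f0: float
    baseline_method: str

    def cycle_average(self) -> np.ndarray:
        """Mean ΔF/F over retained cycles, one value per cycle frame."""
        n = self.protocol.cycle_frames
        usable = (len(self.dff) // n) * n
        return self.dff[:usable].reshape(-1, n).mean(axis=0)


@dataclass
class ModulationResult:
    """Per-cell SU/SD modulation plus the responsiveness call."""

    cell_id: str
    su_mod: float
    sd_mod: float
    responsive: bool
    p_responsive: float
    cell_class: str = ""
    genotype: str = ""
    area: str = ""


@dataclass
class PopulationSummary:
    """Mean ± SEM of SU and SD modulation for one cell grouping."""

    grouping: dict
    n_cells: int
    su_mean: float
    su_sem: float
    sd_mean: float
    sd_sem: float


def extract_traces(stack: ImagingStack, rois: list) -> dict:
    """Mean pixel value over each ROI mask, per frame.

    Returns {cell_id: raw F array of length T}.
    """
    frames = np.asarray(stack.frames, dtype=float)
    out = {}
    for roi in rois:
        if roi.mask.shape != frames.shape[1:]:
            raise ValueError(f"cell {roi.cell_id!r}: mask shape does not match field")
        out[roi.cell_id] = frames[:, roi.mask].mean(axis=1)
    return out


def delta_f_over_f(
    raw_f: np.ndarray,
    protocol: StimulusProtocol,
    *,
    cell_id: str = "",
    baseline_method: str = "percentile",
    percentile: float = DEFAULT_F0_PERCENTILE,
    drop_first_cycle: bool = True,
) -> CellTrace:
    """ΔF/F = (F − F0)/F0 with the first stimulus presentation removed.

    ``baseline_method``: ``"percentile"`` (default: the given percentile of
    the raw trace), ``"slow_epoch_mean"`` (mean over slow-epoch frames), or
    ``"global_mean"``. A non-positive F0 excludes the cell (raises with the
    reason). A 21-cycle recording retains 20 cycles.
    """
    raw_f = np.asarray(raw_f, dtype=float)
    n = protocol.cycle_frames
    if len(raw_f) < 2 * n:
        raise ValueError("trace must span at least two stimulus cycles")
    if baseline_method == "percentile":
        f0 = float(np.percentile(raw_f, percentile))
    elif baseline_method == "slow_epoch_mean":
        su_frame, _ = transition_frames(protocol)
        in_slow = (np.arange(len(raw_f)) % n) < su_frame
        f0 = float(raw_f[in_slow].mean())
    elif baseline_method == "global_mean":
        f0 = float(raw_f.mean())
    else:
        raise ValueError(f"unknown baseline_method {baseline_method!r}")
    if f0 <= 0:
        raise ValueError(
            f"cell {cell_id!r} excluded: baseline F0 = {f0:g} is not positive"
        )
    dff = (raw_f - f0) / f0
    if drop_first_cycle:
        dff = dff[n:]
    n_retained = len(dff) // n
    if abs(len(dff) - n_retained * n) > 1:
        dff = dff[: n_retained * n]
    return CellTrace(cell_id=cell_id, dff=dff, protocol=protocol,
                     n_cycles_retained=n_retained, f0=f0,
                     baseline_method=baseline_method)


def responsive_cells(
    traces: list,
    alpha: float = DEFAULT_ALPHA,
) -> dict:
    """Responsiveness call per cell: ANOVA between slow- and fast-epoch means.

    For each retained cycle the mean ΔF/F of the slow epoch and of the fast
    epoch is computed; a one-way ANOVA between the two epoch groups (each
    n = cycles retained) gives the p-value, and a cell is responsive when
    p < alpha. Identical epoch means give F = 0, p = 1. Returns
    {cell_id: (flag, p)}.
    """
    out = {}
    for trace in traces:
        proto = trace.protocol
        n = proto.cycle_frames
        if trace.n_cycles_retained < 2:
            raise ValueError(f"cell {trace.cell_id!r}: need >= 2 retained cycles")
        su_frame, _ = transition_frames(proto)
        usable = trace.n_cycles_retained * n
        cyc = trace.dff[:usable].reshape(trace.n_cycles_retained, n)
        slow_means = cyc[:, :su_frame].mean(axis=1)
        fast_means = cyc[:, su_frame:].mean(axis=1)
        if np.allclose(slow_means, fast_means) and np.ptp(slow_means) == 0 and np.ptp(fast_means) == 0:
            out[trace.cell_id] = (False, 1.0)
            continue
        f, p = sps.f_oneway(slow_means, fast_means)
        if not np.isfinite(p):
            p = 1.0
        out[trace.cell_id] = (bool(p < alpha), float(p))
    return out


def modulation(
    trace: CellTrace,
    *,
    bin_frames: int = DEFAULT_BIN_FRAMES,
    responsive: bool = True,
    p_responsive: float = np.nan,
    **labels,
) -> ModulationResult:
    """SU and SD modulation of one cell in ``bin_frames``-frame bins.

    On the cycle-averaged ΔF/F trace with the slow epoch opening the cycle
    (frames 0..su-1) and circular indexing:

    * ``su_mod``: mean of the first bin of the fast epoch minus mean of the
      last bin of the slow epoch (frames su..su+b-1 minus su-b..su-1);
    * ``sd_mod``: mean of the first bin of the slow epoch minus mean of the
      last bin of the fast epoch (frames 0..b-1 minus cycle-b..cycle-1).

    By linearity this equals the per-cycle difference averaged over cycles.
    Each epoch must hold at least two bins.
    """
    proto = trace.protocol
    su_frame, _ = transition_frames(proto)
    n = proto.cycle_frames
    fast_frames = n - su_frame
    if min(su_frame, fast_frames) < 2 * bin_frames:
        raise ValueError(
            f"bin of {bin_frames} frames does not fit twice in each epoch "
            f"(slow {su_frame}, fast {fast_frames} frames)"
        )
    cyc = trace.cycle_average()
    b = bin_frames
    su_mod = cyc[su_frame: su_frame + b].mean() - cyc[su_frame - b: su_frame].mean()
    sd_mod = cyc[:b].mean() - cyc[n - b:].mean()
    return ModulationResult(
        cell_id=trace.cell_id, su_mod=float(su_mod), sd_mod=float(sd_mod),
        responsive=responsive, p_responsive=float(p_responsive),
        cell_class=labels.get("cell_class", ""), genotype=labels.get("genotype", ""),
        area=labels.get("area", ""),
    )


def analyze_cells(
    traces: list,
    *,
    alpha: float = DEFAULT_ALPHA,
    bin_frames: int = DEFAULT_BIN_FRAMES,
    labels: dict | None = None,
    include_nonresponsive: bool = False,
) -> list:
    """Responsiveness gating plus modulation for a list of cell traces.

    Cells failing the responsiveness test are excluded (not zero-filled)
    unless ``include_nonresponsive`` is set. ``labels`` maps cell_id →
    {"cell_class", "genotype", "area"}.
    """
    labels = labels or {}
    calls = responsive_cells(traces, alpha=alpha)
    results = []
    for trace in traces:
        flag, p = calls[trace.cell_id]
        if not flag and not include_nonresponsive:
            continue
        results.append(
            modulation(trace, bin_frames=bin_frames, responsive=flag,
                       p_responsive=p, **labels.get(trace.cell_id, {}))
        )
    return results


def population_summary(results: list, grouping_keys: tuple = ("genotype", "cell_class")) -> list:
    """Mean ± SEM of SU and SD modulation per cell group.

    ``grouping_keys`` picks attributes of :class:`ModulationResult` to
    group by; an empty tuple pools everything (e.g. excitatory and
    inhibitory populations together). Empty inputs yield an empty list.
    """
    if not results:
        return []
    df = pd.DataFrame(
        {
            "su_mod": [r.su_mod for r in results],
            "sd_mod": [r.sd_mod for r in results],
            **{k: [getattr(r, k) for r in results] for k in grouping_keys},
        }
    )
    groups = df.groupby(list(grouping_keys)) if grouping_keys else [((), df)]
    out = []
    for key, sub in groups:
        if not isinstance(key, tuple):
            key = (key,)
        n = len(sub)
        out.append(
            PopulationSummary(
                grouping=dict(zip(grouping_keys, key)),
                n_cells=n,
                su_mean=float(sub["su_mod"].mean()),
                su_sem=float(sub["su_mod"].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                sd_mean=float(sub["sd_mod"].mean()),
                sd_sem=float(sub["sd_mod"].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
            )
        )
    return out
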