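"""Magnitude-map quantification: masked per-area means normalised to V1.

The response amplitude of each visual area is read off the ΔR/R magnitude
map in three steps. A duplicate of the map is Gaussian-filtered (5×5-pixel
kernel) and thresholded to build a binary *responsive mask* that excludes
non-responsive cortex; the mask — not the filtered values — is then applied
to the ORIGINAL magnitude map; finally each area's mean over (area ∩ mask)
is divided by V1's, removing animal-to-animal variation in overall cortical
activation and hemodynamics. Starting-speed response curves and tidy group
tables for the statistics layer are assembled from those normalised values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .segmentation import AreaROISet

__all__ = [
    "ResponsiveMask",
    "AreaResponse",
    "SpeedResponseCurve",
    "responsive_mask",
    "area_responses",
    "build_speed_curve",
    "group_table",
]

#: truncated Gaussian of total width 5 px; sigma chosen as width/4
DEFAULT_KERNEL_SIZE = 5
DEFAULT_THRESHOLD_FRACTION = 0.25


@dataclass
class ResponsiveMask:
    """Binary mask of visually responsive cortex plus its provenance."""

    mask: np.ndarray
    threshold_value: float
    kernel_size: int = DEFAULT_KERNEL_SIZE
    threshold_rule: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class AreaResponse:
    """Mean ΔR/R of one area over the responsive mask, and its V1 ratio."""

    area: str
    stimulus: str
    raw_mean: float
    normalized: float
    n_pixels: int
    flagged_empty: bool = False

    @property
    def normalized_pct(self) -> float:
        """The V1 ratio expressed in percent (ratio 2.17 → 217%)."""
        return 100.0 * self.normalized


@dataclass
class SpeedResponseCurve:
    """Normalised response vs starting speed for one area in one animal."""

    area: str
    animal: str
    points: list  # (start_speed_dps, normalized) sorted by speed

    def __post_init__(self) -> None:
        speeds = [s for s, _ in self.points]
        if len(set(speeds)) != len(speeds):
            raise ValueError("duplicate starting speed in curve")
        self.points = sorted(self.points)

    @property
    def speeds(self) -> list:
        return [s for s, _ in self.points]

    @property
    def values(self) -> list:
        return [v for _, v in self.points]


def responsive_mask(
    magnitude: np.ndarray,
    kernel_size: int = DEFAULT_KERNEL_SIZE,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    threshold_value: float | None = None,
) -> ResponsiveMask:
    """Threshold a Gaussian-filtered magnitude map into a responsive mask.

    The filter only shapes the mask; downstream means are taken over the
    original map. The default threshold is ``threshold_fraction`` of the
    filtered map's 99th percentile (a scale-free rule robust to outlier
    pixels); an absolute ``threshold_value`` overrides it.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    if not np.isfinite(magnitude).all():
        raise ValueError("magnitude map contains non-finite values")
    sigma = kernel_size / 4.0
    truncate = (kernel_size - 1) / 2.0 / sigma  # total width = kernel_size px
    filtered = gaussian_filter(magnitude, sigma=sigma, truncate=truncate)
    if threshold_value is None:
        threshold_value = threshold_fraction * np.percentile(filtered, 99)
        rule = f"{threshold_fraction:g} x p99(filtered)"
    else:
        rule = "absolute"
    mask = filtered >= threshold_value
    if not mask.any():
        warnings.warn("responsive mask is empty at this threshold", stacklevel=2)
    return ResponsiveMask(mask=mask, threshold_value=float(threshold_value),
                          kernel_size=kernel_size, threshold_rule=rule)


def area_responses(
    magnitude: np.ndarray,
    mask: ResponsiveMask,
    rois: AreaROISet,
    *,
    stimulus: str = "",
    reference: str = "V1",
) -> list:
    """Per-area mean ΔR/R over (area ∩ responsive mask), normalised to V1.

    Areas whose intersection with the mask is empty are recorded with
    ``raw_mean`` 0, ``n_pixels`` 0 and a flag; an empty intersection for
    the reference area is an error, since the normalisation is undefined.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    if reference not in rois:
        raise ValueError(f"reference area {reference!r} not in ROI set")
    raw = {}
    counts = {}
    for name in rois.names:
        sel = rois[name] & mask.mask
        counts[name] = int(sel.sum())
        raw[name] = float(magnitude[sel].mean()) if counts[name] else 0.0
    if counts[reference] == 0 or raw[reference] <= 0:
        raise ValueError(
            f"reference area {reference!r} has no responsive pixels "
            "(normalisation undefined)"
        )
    ref_mean = raw[reference]
    out = []
    for name in rois.names:
        flagged = counts[name] == 0
        if flagged:
            warnings.warn(f"area {name!r} has no responsive pixels", stacklevel=2)
        out.append(
            AreaResponse(
                area=name, stimulus=stimulus, raw_mean=raw[name],
                normalized=raw[name] / ref_mean, n_pixels=counts[name],
                flagged_empty=flagged,
            )
        )
    return out


def build_speed_curve(
    responses: list,
    *,
    area: str,
    animal: str,
) -> SpeedResponseCurve:
    """Assemble a starting-speed response curve from (speed, response) pairs.

    ``responses`` is a list of (start_speed_dps, AreaResponse-or-float).
    At least two distinct speeds are required; missing speeds are simply
    absent from the curve.
    """
    points = []
    for speed, resp in responses:
        value = resp.normalized if isinstance(resp, AreaResponse) else float(resp)
        points.append((float(speed), value))
    speeds = [s for s, _ in points]
    if len(set(speeds)) != len(speeds):
        raise ValueError("duplicate starting speed for this area/animal")
    if len(set(speeds)) < 2:
        raise ValueError("a speed-response curve needs at least two distinct speeds")
    return SpeedResponseCurve(area=area, animal=animal, points=points)


def group_table(records: list, metadata: dict) -> pd.DataFrame:
    """Tidy long-format table of normalised responses for the stats layer.

    ``records`` is a list of (animal_id, AreaResponse); ``metadata`` maps
    animal_id → {"genotype": ..., "age": ...}. One row per (animal, area,
    stimulus); duplicates or missing metadata are errors.
    """
    missing = sorted({a for a, _ in records} - set(metadata))
    if missing:
        raise ValueError(f"missing metadata for animal(s): {', '.join(missing)}")
    rows = []
    for animal, resp in records:
        meta = metadata[animal]
        rows.append(
            {
                "animal": animal,
                "genotype": meta["genotype"],
                "age": meta.get("age"),
                "area": resp.area,
                "stimulus": resp.stimulus,
                "raw_mean": resp.raw_mean,
                "normalized": resp.normalized,
                "normalized_pct": resp.normalized_pct,
                "n_pixels": resp.n_pixels,
            }
        )
    df = pd.DataFrame(rows)
    dup = df.duplicated(subset=["animal", "area", "stimulus"])
    if dup.any():
        bad = df.loc[dup, ["animal", "area", "stimulus"]].to_records(index=False)
        raise ValueError(f"duplicated (animal, area, stimulus) rows: {list(bad)}")
    return df.sort_values(["genotype", "animal", "area", "stimulus"]).reset_index(drop=True)
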