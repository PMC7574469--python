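"""Visual-area delineation from retinotopic phase maps.

The borders between V1 and the higher visual areas appear as reversals in
the progression of retinotopy: crossing from a non-mirror-image area into a
mirror-image neighbour flips the handedness of the (azimuth, elevation)
map. The *visual field sign* — the sign of the sine of the angle between
the azimuth-phase gradient and the elevation-phase gradient — makes those
reversals explicit: it is uniform within an area and flips across area
borders. Connected components of constant sign, restricted to pixels with
adequate response magnitude, yield area masks; names (V1, LM, AL, RL) are
then assigned from the stereotyped posterior-medial → anterior-lateral
layout of mouse visual cortex. Manually drawn label images can always be
substituted and take precedence over the automatic labels.

Phase gradients are computed on the complex exponential of phase, so
wrapped maps need no explicit unwrapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import label as cc_label

from .isoi_fourier import FourierMaps

__all__ = [
    "RetinotopyPair",
    "FieldSignMap",
    "AreaROISet",
    "field_sign",
    "segment_areas",
    "load_manual_rois",
]

#: magnitude support threshold: fraction of the in-map 95th percentile
DEFAULT_SUPPORT_FRACTION = 0.30
DEFAULT_SMOOTHING_SIGMA = 2.0


@dataclass
class RetinotopyPair:
    """Matched elevation and azimuth Fourier maps from bar sweeps."""

    elevation: FourierMaps
    azimuth: FourierMaps

    def __post_init__(self) -> None:
        if self.elevation.shape != self.azimuth.shape:
            raise ValueError("elevation and azimuth map shapes differ")
        if self.elevation.binning != self.azimuth.binning:
            raise ValueError("elevation and azimuth maps have different binning")


@dataclass
class FieldSignMap:
    """Per-pixel visual field sign: ±1 inside supported cortex, 0 elsewhere."""

    sign: np.ndarray
    smoothing_sigma: float
    support: np.ndarray

    def __post_init__(self) -> None:
        vals = np.unique(self.sign)
        if not np.isin(vals, (-1, 0, 1)).all():
            raise ValueError("field sign values must be in {-1, 0, +1}")


@dataclass
class AreaROISet:
    """Named, pairwise-disjoint binary area masks."""

    masks: dict
    provenance: str = "auto"  # auto | manual
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("area masks have inconsistent shapes")
        occupancy = None
        for name, mask in self.masks.items():
            mask = np.asarray(mask, dtype=bool)
            if not mask.any():
                raise ValueError(f"area {name!r} mask is empty")
            self.masks[name] = mask
            occupancy = mask.astype(int) if occupancy is None else occupancy + mask
        if occupancy is not None and (occupancy > 1).any():
            raise ValueError("area masks overlap")

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks


def _wrapped_phase_gradient(
    phase: np.ndarray, sigma: float, weight: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed spatial gradient of a wrapped phase map.

    The phase is lifted to the unit circle (weighted by response magnitude
    when given, so unresponsive pixels contribute nothing to their
    neighbours' smoothed phase), smoothed there, and the gradient of its
    argument recovered as Im(conj(z)·dz)/|z|², which is immune to ±π
    branch cuts.
    """
    z = np.exp(1j * phase)
    if weight is not None:
        w = weight / max(weight.max(), 1e-12)
        z = w * z
    if sigma > 0:
        z = gaussian_filter(z.real, sigma) + 1j * gaussian_filter(z.imag, sigma)
    gy_r, gx_r = np.gradient(z.real)
    gy_i, gx_i = np.gradient(z.imag)
    denom = np.maximum(np.abs(z) ** 2, 1e-12)
    dphi_dy = (z.real * gy_i - z.imag * gy_r) / denom
    dphi_dx = (z.real * gx_i - z.imag * gx_r) / denom
    return dphi_dy, dphi_dx


def field_sign(
    pair: RetinotopyPair,
    smoothing_sigma: float = DEFAULT_SMOOTHING_SIGMA,
    support_fraction: float = DEFAULT_SUPPORT_FRACTION,
) -> FieldSignMap:
    """Visual field sign from an (elevation, azimuth) phase-map pair.

    Per pixel: the sign of the z-component of ∇φ_azimuth × ∇φ_elevation
    after Gaussian smoothing of both phase maps on the unit circle. Pixels
    whose magnitude falls below ``support_fraction`` of either map's 95th
    percentile are left unassigned (0).
    """
    az, el = pair.azimuth, pair.elevation
    support = np.ones(az.shape, dtype=bool)
    for maps in (az, el):
        thresh = support_fraction * np.percentile(maps.magnitude, 95)
        support &= (maps.magnitude >= thresh) & (maps.magnitude > 0)
    if not support.any():
        warnings.warn("no pixels pass the magnitude support threshold", stacklevel=2)
        return FieldSignMap(sign=np.zeros(az.shape, dtype=int),
                            smoothing_sigma=smoothing_sigma, support=support)
    az_dy, az_dx = _wrapped_phase_gradient(az.phase, smoothing_sigma, weight=az.magnitude)
    el_dy, el_dx = _wrapped_phase_gradient(el.phase, smoothing_sigma, weight=el.magnitude)
    cross = az_dx * el_dy - az_dy * el_dx
    sign = np.sign(cross).astype(int)
    sign[~support] = 0
    return FieldSignMap(sign=sign, smoothing_sigma=smoothing_sigma, support=support)


def _layout_labels(components: list[dict]) -> dict:
    """Name components by the stereotyped cortical layout.

    Largest component → V1; the remaining components are ordered by
    distance from the V1 centroid along the anterolateral direction
    (decreasing row, increasing column) and named LM, AL, RL in that
    order; any further components become AREA_k.
    """
    components = sorted(components, key=lambda c: c["size"], reverse=True)
    names: dict = {}
    v1 = components[0]
    names["V1"] = v1
    rest = components[1:]
    cy0, cx0 = v1["centroid"]
    # anterolateral progression: anterior = lower row index
    rest.sort(key=lambda c: ((cy0 - c["centroid"][0]) + (c["centroid"][1] - cx0)))
    order = ["LM", "AL", "RL"]
    for i, comp in enumerate(rest):
        names[order[i] if i < len(order) else f"AREA_{i - len(order) + 1}"] = comp
    return names


def segment_areas(
    fsm: FieldSignMap,
    min_area: int = 30,
    expected: tuple = ("V1", "LM", "AL", "RL"),
) -> AreaROISet:
    """Split a field-sign map into named area masks.

    Connected components of constant nonzero sign with at least
    ``min_area`` pixels are labeled by the layout rule of
    :func:`_layout_labels`. Fewer than two surviving components yields a
    partial (possibly empty) set with a warning.
    """
    comps = []
    for s in (-1, 1):
        lab = cc_label(fsm.sign == s, connectivity=1)
        for k in range(1, lab.max() + 1):
            mask = lab == k
            size = int(mask.sum())
            if size < min_area:
                continue
            ys, xs = np.nonzero(mask)
            comps.append({"mask": mask, "size": size, "sign": s,
                          "centroid": (ys.mean(), xs.mean())})
    if len(comps) < 2:
        warnings.warn(
            f"only {len(comps)} field-sign component(s) of >= {min_area} px survive; "
            "returning a partial area set",
            stacklevel=2,
        )
    if not comps:
        return AreaROISet(masks={}, provenance="auto", notes={"n_components": 0})
    named = _layout_labels(comps)
    masks = {name: comp["mask"] for name, comp in named.items()}
    notes = {
        "n_components": len(comps),
        "signs": {name: comp["sign"] for name, comp in named.items()},
        "expected_missing": [n for n in expected if n not in masks],
    }
    return AreaROISet(masks=masks, provenance="auto", notes=notes)


def load_manual_rois(
    label_image: np.ndarray,
    names: dict,
    geometry: tuple[int, int] | None = None,
) -> AreaROISet:
    """Build an area set from a label image plus a {label: name} map.

    Label images cannot overlap by construction; geometry is checked
    against the Fourier-map frame when given, and a requested name whose
    label is absent from the image is an error.
    """
    label_image = np.asarray(label_image)
    if label_image.ndim != 2:
        raise ValueError("label image must be 2-D")
    if geometry is not None and tuple(label_image.shape) != tuple(geometry):
        raise ValueError(
            f"label image shape {label_image.shape} does not match map geometry {geometry}"
        )
    masks = {}
    for lab, name in names.items():
        mask = label_image == int(lab)
        if not mask.any():
            raise ValueError(f"label {lab} for area {name!r} is absent from the label image")
        masks[str(name)] = mask
    return AreaROISet(masks=masks, provenance="manual")
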