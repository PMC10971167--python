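"""Nucleus segmentation, damage-stripe detection, background ring, trace extraction.

The laser cut leaves a bright linear stripe of recruited protein inside the
nucleus.  Detection is signal-based: a post-minus-pre difference image inside
each nucleus is thresholded and the largest elongated component is taken as
the stripe.  Local background is the two-pixel-wide ring around the stripe,
clipped to the nucleus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu, threshold_li, threshold_triangle
from skimage.measure import label, regionprops
from skimage.segmentation import clear_border

from .stack_io import FrameSeries

__all__ = [
    "NucleusROI",
    "DamageSiteROI",
    "IntensityTrace",
    "segment_nuclei",
    "detect_damage_site",
    "make_background_ring",
    "measure_trace",
    "classify_recruitment",
    "compute_fold_change",
]

log = logging.getLogger(__name__)

_THRESHOLDS = {"otsu": threshold_otsu, "li": threshold_li, "triangle": threshold_triangle}

# 8-connectivity throughout: one structuring element for labelling and dilation
_SELEM8 = np.ones((3, 3), dtype=bool)


@dataclass
class NucleusROI:
    label: int
    mask: np.ndarray          # boolean, full-frame
    centroid: tuple           # (y, x) pixels
    area_px: int


@dataclass
class DamageSiteROI:
    """Stripe mask plus its two-pixel background ring, both within one nucleus."""

    nucleus_label: int
    site_mask: np.ndarray
    ring_mask: np.ndarray
    stripe_axis: tuple = (0.0, 0.0)   # unit vector along the stripe

    def __post_init__(self):
        if np.logical_and(self.site_mask, self.ring_mask).any():
            raise ValueError("site and ring masks must be disjoint")


@dataclass
class IntensityTrace:
    """Per-timepoint site/ring means and the background-corrected normalized trace.

    ``corrected = site_mean - ring_mean`` removes local background;
    ``normalized`` additionally subtracts the pre-irradiation mean of
    ``corrected`` so that the pre-irradiation level is zero.
    """

    timestamps: np.ndarray
    site_mean: np.ndarray
    ring_mean: np.ndarray
    corrected: np.ndarray
    normalized: np.ndarray
    irradiation_time_s: float

    def __post_init__(self):
        n = len(self.timestamps)
        for name in ("site_mean", "ring_mean", "corrected", "normalized"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match timestamps")

    @property
    def pre_mask(self) -> np.ndarray:
        return np.asarray(self.timestamps) < self.irradiation_time_s

    @property
    def post_mask(self) -> np.ndarray:
        return ~self.pre_mask


def segment_nuclei(
    frame: np.ndarray,
    threshold: str = "otsu",
    smoothing_sigma: float = 2.0,
    min_area_px: int = 500,
    max_area_px: int = 50_000,
    exclude_border: bool = True,
) -> list[NucleusROI]:
    """Segment nuclei on a single 2-D frame by automatic global thresholding.

    The frame is Gaussian-smoothed, thresholded (Otsu by default; ``li`` and
    ``triangle`` are pluggable), labelled with 8-connectivity and filtered by
    area and (optionally) border contact.  Returns an empty list — not an
    error — when nothing qualifies.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    smoothed = gaussian(frame, sigma=smoothing_sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        log.info("segment_nuclei: flat frame, no nuclei")
        return []
    thr = _THRESHOLDS[threshold](smoothed)
    binary = smoothed > thr
    if exclude_border:
        binary = clear_border(binary)
    labels = label(binary, connectivity=2)
    rois = []
    for rp in regionprops(labels):
        if not (min_area_px <= rp.area <= max_area_px):
            continue
        rois.append(NucleusROI(
            label=int(rp.label),
            mask=labels == rp.label,
            centroid=tuple(rp.centroid),
            area_px=int(rp.area),
        ))
    if not rois:
        log.info("segment_nuclei: no component passed the filters")
    return rois


def detect_damage_site(
    series: FrameSeries,
    nucleus: NucleusROI,
    irradiation_time_s: float,
    post_window_s: float = 60.0,
    min_eccentricity: float = 0.8,
    min_area_px: int = 10,
    significance_k: float = 3.0,
    ring_width_px: int = 2,
) -> DamageSiteROI | None:
    """Detect the recruitment stripe within one nucleus, or ``None``.

    Computes a difference image (mean of frames within ``post_window_s``
    after irradiation minus mean of pre-irradiation frames), thresholds the
    in-nucleus difference values (Otsu), and keeps the largest elongated
    component (eccentricity >= ``min_eccentricity``).  A candidate must also
    be significant: its mean difference must exceed the in-nucleus median by
    ``significance_k`` robust standard deviations, which rejects the spurious
    components Otsu produces on pure noise.
    """
    t = series.timestamps
    pre = t < irradiation_time_s
    post = (t >= irradiation_time_s) & (t <= irradiation_time_s + post_window_s)
    if pre.sum() < 3 or post.sum() < 3:
        raise ValueError("need >= 3 pre- and >= 3 post-irradiation frames")
    diff = series.frames[post].mean(axis=0) - series.frames[pre].mean(axis=0)
    mask = nucleus.mask
    vals = diff[mask]
    if np.ptp(vals) == 0:
        return None
    med = float(np.median(vals))
    sigma = 1.4826 * float(np.median(np.abs(vals - med)))
    thr = threshold_otsu(vals)
    candidate = np.zeros_like(mask)
    candidate[mask] = vals > thr
    labels = label(candidate, connectivity=2)
    best = None
    for rp in regionprops(labels):
        if rp.area < min_area_px or rp.eccentricity < min_eccentricity:
            continue
        comp_mean = float(diff[labels == rp.label].mean())
        if sigma > 0 and (comp_mean - med) < significance_k * sigma:
            continue
        if best is None or rp.area > best.area:
            best = rp
    if best is None:
        return None
    site = labels == best.label
    try:
        ring = make_background_ring(site, mask, width_px=ring_width_px)
    except ValueError:
        return None
    theta = best.orientation  # angle between y-axis and major axis
    axis = (float(np.cos(theta)), float(np.sin(theta)))
    return DamageSiteROI(nucleus_label=nucleus.label, site_mask=site,
                         ring_mask=ring, stripe_axis=axis)


def make_background_ring(site: np.ndarray, nucleus_mask: np.ndarray, width_px: int = 2) -> np.ndarray:
    """Ring of ``width_px`` pixels around the site, clipped to the nucleus.

    ``(dilate(site, width) - site) ∩ nucleus`` with 8-connected dilation.
    Raises when the ring would be empty (site fills the nucleus).
    """
    site = np.asarray(site, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    if np.any(site & ~nucleus_mask):
        raise ValueError("site must lie within the nucleus mask")
    dilated = ndi.binary_dilation(site, structure=_SELEM8, iterations=width_px)
    ring = dilated & ~site & nucleus_mask
    if not ring.any():
        raise ValueError("background ring is empty (site fills the nucleus)")
    return ring


def measure_trace(series: FrameSeries, roi: DamageSiteROI, irradiation_time_s: float) -> IntensityTrace:
    """Per-frame site/ring means, background-corrected and baseline-normalized."""
    if not roi.site_mask.any() or not roi.ring_mask.any():
        raise ValueError("site and ring masks must be non-empty")
    site = series.frames[:, roi.site_mask].mean(axis=1)
    ring = series.frames[:, roi.ring_mask].mean(axis=1)
    corrected = site - ring
    pre = series.timestamps < irradiation_time_s
    if not pre.any():
        raise ValueError("no pre-irradiation frames: normalization undefined")
    normalized = corrected - corrected[pre].mean()
    return IntensityTrace(
        timestamps=series.timestamps.copy(),
        site_mean=site,
        ring_mean=ring,
        corrected=corrected,
        normalized=normalized,
        irradiation_time_s=irradiation_time_s,
    )


def compute_fold_change(trace: IntensityTrace, ring_corrected: bool = False) -> float:
    """Fold change (Intensity_C - Intensity_A) / Intensity_A at the damage site.

    Intensity_A is the mean pre-irradiation site level and Intensity_C the
    maximum site level.  By default both are raw site means; with
    ``ring_corrected=True`` the ring-subtracted series is used instead (only
    meaningful when the site is intrinsically brighter than its surround
    before irradiation).  Returns ``nan`` when Intensity_A <= 0.
    """
    series = trace.corrected if ring_corrected else trace.site_mean
    pre = trace.pre_mask
    intensity_a = float(np.mean(series[pre]))
    intensity_c = float(np.max(series))
    if intensity_a <= 0:
        return float("nan")
    return (intensity_c - intensity_a) / intensity_a


def classify_recruitment(
    trace: IntensityTrace,
    k_sigma: float = 3.0,
    min_consecutive: int = 3,
    min_fold_change: float = 0.1,
) -> bool:
    """True iff the trace shows sustained, sizeable recruitment.

    The normalized trace must exceed ``k_sigma``·σ_pre for at least
    ``min_consecutive`` consecutive post-irradiation samples, and the fold
    change must reach ``min_fold_change``.  σ_pre is the standard deviation
    of the pre-irradiation normalized samples.
    """
    pre = trace.pre_mask
    if pre.sum() < 5:
        raise ValueError("need >= 5 pre-irradiation samples to estimate noise")
    sigma_pre = float(np.std(trace.normalized[pre], ddof=1))
    threshold = k_sigma * max(sigma_pre, 1e-12)
    above = trace.normalized[trace.post_mask] > threshold
    run, longest = 0, 0
    for flag in above:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    if longest < min_consecutive:
        return False
    fold = compute_fold_change(trace)
    return bool(np.isfinite(fold) and fold >= min_fold_change)
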