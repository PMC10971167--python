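"""Lateral-drift registration and photobleaching correction.

Fixed order of operations downstream of the maximum-intensity projection:
registration first (background factors must be computed on aligned frames),
then bleaching correction, then measurement.  Registration is
translation-only — the assay compensates lateral cell movement, not rotation
or scaling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import curve_fit
from skimage.registration import phase_cross_correlation

from .stack_io import FrameSeries

__all__ = [
    "DriftModel",
    "BleachModel",
    "register_frames",
    "estimate_bleaching",
    "correct_bleaching",
]

log = logging.getLogger(__name__)


@dataclass
class DriftModel:
    """Per-frame translation (dy, dx) in pixels applied to align each frame
    with the reference frame.  The reference frame's shift is (0, 0)."""

    shifts: np.ndarray              # (T, 2) corrections applied, (dy, dx)
    reference_index: int
    flagged: np.ndarray             # (T,) True where the raw estimate exceeded the bound
    max_shift_px: float = 20.0

    def to_json(self) -> str:
        return json.dumps({
            "shifts": np.asarray(self.shifts).tolist(),
            "reference_index": int(self.reference_index),
            "flagged": np.asarray(self.flagged).astype(bool).tolist(),
            "max_shift_px": float(self.max_shift_px),
        })


@dataclass
class BleachModel:
    """Per-frame normalization factors for photobleaching.

    ``form`` is ``"exponential"`` (mono-exponential-plus-offset fit to the
    control-region mean) or ``"ratio"`` (frame-by-frame observed ratio, the
    fallback when the fit cannot converge).  ``factors[0] == 1`` and all
    factors are strictly positive.
    """

    form: str
    factors: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.factors = np.asarray(self.factors, dtype=float)
        if self.factors.size == 0 or not np.all(self.factors > 0):
            raise ValueError("bleach factors must be strictly positive")
        if abs(self.factors[0] - 1.0) > 1e-9:
            raise ValueError("bleach factor at the first frame must be 1")

    def to_json(self) -> str:
        return json.dumps({
            "form": self.form,
            "factors": self.factors.tolist(),
            "params": {k: float(v) for k, v in self.params.items()},
        })


def register_frames(
    series: FrameSeries,
    reference_index: int = 0,
    max_shift_px: float = 20.0,
    upsample_factor: int = 20,
) -> tuple[FrameSeries, DriftModel]:
    """Translation-only registration against a reference frame.

    Shifts are estimated by (phase) cross-correlation with sub-pixel
    refinement and applied by linear interpolation; pixels shifted in from
    outside the field are filled with the frame's median.  Estimates larger
    than ``max_shift_px`` are clamped and flagged.
    """
    if series.n_frames < 2:
        raise ValueError("registration needs at least 2 frames")
    ref = series.frames[reference_index]
    # Hann window suppresses the spectral leakage of non-periodic boundaries,
    # which otherwise biases the correlation peak on small fields
    win = np.outer(np.hanning(ref.shape[0]), np.hanning(ref.shape[1]))
    ref_w = ref * win
    out = np.empty_like(series.frames)
    shifts = np.zeros((series.n_frames, 2))
    flagged = np.zeros(series.n_frames, dtype=bool)
    for i, frame in enumerate(series.frames):
        if i == reference_index:
            out[i] = frame
            continue
        shift, _, _ = phase_cross_correlation(ref_w, frame * win, upsample_factor=upsample_factor)
        mag = float(np.hypot(*shift))
        if mag > max_shift_px:
            flagged[i] = True
            shift = shift * (max_shift_px / mag)
            log.warning("frame %d: estimated shift %.1f px exceeds bound %.1f px; clamped",
                        i, mag, max_shift_px)
        shifts[i] = shift
        out[i] = ndi.shift(frame, shift, order=1, mode="constant",
                           cval=float(np.median(frame)))
    model = DriftModel(shifts=shifts, reference_index=reference_index,
                       flagged=flagged, max_shift_px=max_shift_px)
    return series.with_frames(out, provenance="registered"), model


def _mono_exp(t, a, k, c):
    return a * np.exp(-k * t) + c


def estimate_bleaching(series: FrameSeries, control_mask: np.ndarray) -> BleachModel:
    """Fit the control-region mean intensity with ``a·exp(-k·t) + c``.

    The control mask should cover stable fluorescence away from the damage
    stripe (nucleus pixels excluding stripe + ring).  Normalization factors
    are ``fitted(t)/fitted(t0)``.  Falls back to per-frame ratio factors when
    the fit cannot be performed (fewer than 5 frames or non-convergence).
    """
    control_mask = np.asarray(control_mask, dtype=bool)
    if not control_mask.any():
        raise ValueError("control mask is empty")
    means = series.frames[:, control_mask].mean(axis=1)
    if means[0] <= 0 or np.any(means <= 0):
        raise ValueError("control region mean must be positive in every frame")
    t = series.timestamps - series.timestamps[0]
    if series.n_frames >= 5:
        a0 = max(means[0] - means[-1], 1e-3 * means[0])
        span = max(t[-1], 1.0)
        try:
            popt, _ = curve_fit(
                _mono_exp, t, means,
                p0=(a0, 1.0 / span, means[-1]),
                bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
            fitted = _mono_exp(t, *popt)
            if np.all(fitted > 0):
                return BleachModel(
                    form="exponential",
                    factors=fitted / fitted[0],
                    params={"amplitude": popt[0], "rate_per_s": popt[1], "offset": popt[2]},
                )
        except (RuntimeError, ValueError):
            log.warning("bleach fit did not converge; falling back to ratio mode")
    return BleachModel(form="ratio", factors=means / means[0])


def correct_bleaching(series: FrameSeries, model: BleachModel) -> FrameSeries:
    """Divide frame ``t`` by its normalization factor; the first frame is unchanged."""
    if model.factors.shape[0] != series.n_frames:
        raise ValueError("bleach model does not cover every frame")
    out = series.frames / model.factors[:, None, None]
    return series.with_frames(out, provenance="bleach-corrected")
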