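"""Four-phase recruitment kinetics: phase points A–E, robust model fit, nine parameters.

The recruitment of a repair protein at a damage stripe is segmented into
four phases delimited by five time points:

* **A** — laser irradiation,
* **B** — onset of recruitment (end of the lag phase I),
* **C** — end of recruitment (end of the association phase II),
* **D** — onset of dissociation (end of the plateau phase III),
* **E** — return to a pre-irradiation-like level (end of phase IV).

The fitted model is first-order binding kinetics: zero before B, a
mono-exponential association ``delta_max·(1 - e^(-k_on·(t-B)))`` between B
and D, and a mono-exponential dissociation from the level reached at D with
rate ``k_off`` afterwards.  Under this model the 95%-of-peak definition of C
gives ``C - B = ln(20)/k_on``, and the extrapolated E (95% of the
dissociation completed) is ``D + ln(20)/k_off``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import least_squares

from .detect import IntensityTrace, compute_fold_change

__all__ = [
    "PhasePoints",
    "TraceModel",
    "KineticParameters",
    "FitResult",
    "NotRecruitingError",
    "model_curve",
    "detect_phase_points",
    "fit_kinetics",
    "extrapolate_E",
    "compute_parameters",
]

log = logging.getLogger(__name__)

LN20 = math.log(20.0)
RATE_BOUNDS = (1e-5, 10.0)  # 1/s, admissible k_on / k_off range


class NotRecruitingError(RuntimeError):
    """Raised when no recruitment onset (point B) can be found in a trace."""


@dataclass
class PhasePoints:
    """The five phase-delimiting time points, in seconds.

    ``tE`` is ``nan`` with ``tE_extrapolated=True`` when the trace does not
    return to baseline inside the window; :func:`extrapolate_E` then supplies
    the model-based value.
    """

    tA: float
    tB: float
    tC: float
    tD: float
    tE: float
    tE_extrapolated: bool = False

    def __post_init__(self):
        seq = [self.tA, self.tB, self.tC, self.tD]
        if not all(a <= b + 1e-9 for a, b in zip(seq, seq[1:])):
            raise ValueError(f"phase points must be ordered A<=B<=C<=D, got {seq}")
        if np.isfinite(self.tE) and self.tE < self.tD - 1e-9:
            raise ValueError("tE must not precede tD")

    @property
    def plateau_present(self) -> bool:
        return (self.tD - self.tC) > 1e-9


@dataclass
class TraceModel:
    """Piecewise recruitment model: lag, exponential association, exponential dissociation."""

    delta_max: float
    k_on: float
    k_off: float
    tB: float
    tD: float
    baseline: float = 0.0
    plateau_present: bool = True

    def amplitude_at_tD(self) -> float:
        return self.delta_max * (1.0 - math.exp(-self.k_on * (self.tD - self.tB)))


@dataclass
class KineticParameters:
    """The nine per-cell kinetic parameters (durations in s, rates in 1/s)."""

    lag_time_s: float            # A -> B
    association_time_s: float    # B -> C
    plateau_time_s: float        # C -> D
    dissociation_time_s: float   # D -> E
    duration_s: float            # B -> E (phases II + III + IV)
    k_on: float
    k_off: float
    fold_change: float
    plateau_present: bool


@dataclass
class FitResult:
    model: TraceModel
    residual_scale: float
    converged: bool
    weights: np.ndarray | None = None


def model_curve(model: TraceModel, timestamps: np.ndarray) -> np.ndarray:
    """Evaluate the piecewise model; continuous at tB and tD."""
    t = np.asarray(timestamps, dtype=float)
    y = np.full(t.shape, model.baseline, dtype=float)
    rise = (t >= model.tB) & (t < model.tD)
    y[rise] += model.delta_max * (1.0 - np.exp(-model.k_on * (t[rise] - model.tB)))
    fall = t >= model.tD
    y[fall] += model.amplitude_at_tD() * np.exp(-model.k_off * (t[fall] - model.tD))
    return y


def _first_run(flags: np.ndarray, min_consecutive: int) -> int | None:
    """Index (into flags) of the first run of >= min_consecutive True values."""
    run = 0
    for i, f in enumerate(flags):
        run = run + 1 if f else 0
        if run >= min_consecutive:
            return i - min_consecutive + 1
    return None


def _refine_crossing(t, ys, level, i_raw, lo, hi, halfwidth, t_lo, t_hi):
    """Localize a threshold crossing by a local straight-line fit.

    A raw first/last-crossing index is noise-biased (first passage); fitting
    a line to the smoothed trace over ``±halfwidth`` samples around it and
    solving for the level crossing removes most of that bias.  The result is
    clipped to [t_lo, t_hi]; on a degenerate fit the raw sample time is kept.
    """
    a = max(lo, i_raw - halfwidth)
    b = min(hi, i_raw + halfwidth)
    if b - a >= 3:
        coeffs = np.polyfit(t[a:b + 1], ys[a:b + 1], 1)
        if abs(coeffs[0]) > 1e-12:
            crossing = (level - coeffs[1]) / coeffs[0]
            return float(np.clip(crossing, t_lo, t_hi))
    return float(np.clip(t[i_raw], t_lo, t_hi))


def detect_phase_points(
    trace: IntensityTrace,
    smooth_window: int = 5,
    k_sigma: float = 3.0,
    peak_fraction: float = 0.95,
    plateau_min_s: float = 10.0,
    min_consecutive: int = 3,
    refine_halfwidth: int = 10,
) -> PhasePoints:
    """Detect the empirical phase points B–E on the smoothed normalized trace.

    B: trigger at the first run of ``min_consecutive`` post-irradiation
    samples above ``k_sigma``·σ (σ from the smoothed pre-irradiation
    samples), then walked back to where the trace last sat at baseline
    (<= 1σ).  The plateau level P is the smoothed maximum minus an
    extreme-value noise correction.  C is the first and D the last crossing
    of ``peak_fraction``·P, each refined by a local linear fit; if D - C is
    shorter than ``plateau_min_s`` there is no plateau and C = D = argmax
    time.  E is the first sustained drop below ``(1 - peak_fraction)``·P
    after D, refined likewise; when the trace never drops that far, tE is
    ``nan`` and flagged for model-based extrapolation.
    """
    t = np.asarray(trace.timestamps, dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("timestamps must be strictly increasing")
    y = np.asarray(trace.normalized, dtype=float)
    tA = float(trace.irradiation_time_s)
    pre = t < tA
    if pre.sum() < 5:
        raise ValueError("need >= 5 pre-irradiation samples")

    ys = uniform_filter1d(y, size=smooth_window, mode="nearest")
    # noise scale of the smoothed trace: the raw pre-irradiation samples are
    # independent, so their sd shrinks by sqrt(window) under the moving mean;
    # estimating from the few (correlated) smoothed pre samples is unstable
    sigma_s = float(np.std(y[pre], ddof=1)) / math.sqrt(smooth_window)
    sigma_floor = max(sigma_s, 1e-12)

    post_start = int(np.searchsorted(t, tA))
    above = ys > k_sigma * sigma_floor
    # the triggering excursion must not only sustain k_sigma·σ for
    # min_consecutive samples but also climb to twice that level somewhere —
    # noise runs hover near the threshold, real rises shoot far past it
    trigger = None
    rel_offset = post_start
    while True:
        rel = _first_run(above[rel_offset:], min_consecutive)
        if rel is None:
            break
        run_start = rel_offset + rel
        run_end = run_start
        while run_end + 1 < t.size and above[run_end + 1]:
            run_end += 1
        if float(np.max(ys[run_start:run_end + 1])) >= 2.0 * k_sigma * sigma_floor:
            trigger = run_start
            break
        rel_offset = run_end + 1
    if trigger is None:
        raise NotRecruitingError("no sustained rise above baseline noise")

    # onset: local hinge (changepoint) fit on the raw trace.  The model is
    # flat zero up to t0 and a line of non-negative slope after it; the
    # candidate t0 with the smallest squared error is the onset.  Raw samples
    # are used because their noise is uncorrelated, unlike the smoothed ones.
    lo = max(post_start, trigger - 6)
    hi = min(t.size - 1, trigger + 4)
    t_win, y_win = t[lo:hi + 1], y[lo:hi + 1]
    sses = []
    for cand in range(lo, trigger + 1):
        x = np.clip(t_win - t[cand], 0.0, None)
        sxx = float(x @ x)
        slope = max(float(x @ y_win) / sxx, 0.0) if sxx > 0 else 0.0
        sses.append(float(((y_win - slope * x) ** 2).sum()))
    sses = np.asarray(sses)
    # parsimony tie-break: the latest onset whose error is within 5% of the
    # minimum — the hinge slightly underfits the curved rise, which otherwise
    # lets a spuriously early onset win on noisy traces
    near = np.where(sses <= sses.min() * 1.05 + 1e-12)[0]
    tB = max(float(t[lo + int(near[-1])]), tA)
    jB = int(np.searchsorted(t, tB))

    # plateau level, two passes: first the smoothed maximum minus its expected
    # extreme-value noise inflation, then — when a broad plateau exists — the
    # median of the later plateau half, which sits nearest the asymptote and
    # is far less noise-sensitive than the maximum
    seg = ys[jB:]
    imax = jB + int(np.argmax(seg))
    peak_raw = float(ys[imax])
    n_high = int(np.sum(seg >= peak_raw - 3.0 * sigma_s))
    n_eff = max(n_high / smooth_window, 1.0)
    plateau_level = peak_raw - sigma_s * math.sqrt(2.0 * math.log(n_eff)) if n_eff > 1 else peak_raw

    rough = np.where(ys[jB:] >= peak_fraction * plateau_level)[0] + jB
    if rough.size >= 6:
        half = rough[(rough[0] + rough[-1]) // 2 <= rough]
        if half.size >= 3:
            plateau_level = float(np.median(ys[half]))

    c_hi = peak_fraction * plateau_level
    hi_idx = np.where(ys[jB:] >= c_hi)[0] + jB
    if hi_idx.size == 0:  # only possible through the noise correction
        hi_idx = np.array([imax])
    last = t.size - 1
    tC = _refine_crossing(t, ys, c_hi, int(hi_idx[0]), jB, imax, refine_halfwidth, tB, float(t[imax]))
    tD = _refine_crossing(t, ys, c_hi, int(hi_idx[-1]), imax, last, refine_halfwidth, tC, float(t[last]))

    if (tD - tC) < plateau_min_s:
        tC = tD = float(t[imax])

    # end of dissociation: sustained drop below (1 - peak_fraction)·P
    c_lo = (1.0 - peak_fraction) * plateau_level
    after = np.where(t > tD)[0]
    tE, extrapolated = float("nan"), True
    if after.size:
        below = ys[after] < c_lo
        rel_e = _first_run(below, min(2, after.size))
        if rel_e is not None:
            i_e = int(after[rel_e])
            tE = _refine_crossing(t, ys, c_lo, i_e, int(after[0]), last, refine_halfwidth, tD, float(t[last]))
            extrapolated = False
    return PhasePoints(tA=tA, tB=tB, tC=tC, tD=tD, tE=tE, tE_extrapolated=extrapolated)


def _pack_model(theta, plateau_present: bool) -> TraceModel:
    tB, delta, k_on, span, k_off = theta
    return TraceModel(delta_max=float(delta), k_on=float(k_on), k_off=float(k_off),
                      tB=float(tB), tD=float(tB + span), plateau_present=plateau_present)


def fit_kinetics(
    trace: IntensityTrace,
    points: PhasePoints,
    max_restarts: int = 3,
    rate_bounds: tuple = RATE_BOUNDS,
) -> FitResult:
    """Robust non-linear regression of the recruitment model on a trace.

    Least squares with a soft-L1 loss scaled to the pre-irradiation noise
    (1.345 × the MAD-based robust sigma, the standard Huber tuning constant),
    so isolated outlier frames barely move the parameters.  Initial values
    come from the empirical phase points; rates are bounded to
    ``rate_bounds``.  Non-convergence is reported, not raised — downstream
    parameters then fall back to the empirical points.
    """
    t = np.asarray(trace.timestamps, dtype=float)
    y = np.asarray(trace.normalized, dtype=float)
    pre = trace.pre_mask
    mad = float(np.median(np.abs(y[pre] - np.median(y[pre]))))
    sigma = 1.4826 * mad
    lo_rate, hi_rate = rate_bounds

    assoc0 = max(points.tC - points.tB, 1.0)
    k_on0 = float(np.clip(3.0 / assoc0, lo_rate * 1.1, hi_rate * 0.9))
    span0 = max(points.tD - points.tB, 1.0)
    diss_span = (points.tE - points.tD) if np.isfinite(points.tE) else (t[-1] - points.tD)
    k_off0 = float(np.clip(3.0 / max(diss_span, 5.0), lo_rate * 1.1, hi_rate * 0.9))
    ys_peak = max(float(np.max(uniform_filter1d(y, 5, mode="nearest"))), 1e-6)

    lower = [points.tA, 1e-9, lo_rate, 0.0, lo_rate]
    upper = [float(t[-1]), 10.0 * ys_peak, hi_rate, float(t[-1] - points.tA) + 1e4, hi_rate]

    def residuals(theta):
        return model_curve(_pack_model(theta, points.plateau_present), t) - y

    kwargs = dict(bounds=(lower, upper), xtol=1e-12, ftol=1e-12, gtol=1e-12)
    if sigma > 1e-9:
        kwargs.update(loss="soft_l1", f_scale=1.345 * sigma)

    best = None
    for mult_on, mult_off in ((1.0, 1.0), (0.3, 3.0), (3.0, 0.3))[:max_restarts]:
        theta0 = np.clip(
            [points.tB, ys_peak, k_on0 * mult_on, span0, k_off0 * mult_off], lower, upper
        )
        try:
            res = least_squares(residuals, theta0, **kwargs)
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-20:
            break

    if best is None:
        model = _pack_model([points.tB, ys_peak, k_on0, span0, k_off0], points.plateau_present)
        return FitResult(model=model, residual_scale=sigma, converged=False)

    model = _pack_model(best.x, points.plateau_present)
    rates_ok = all(lo_rate * 1.001 < k < hi_rate * 0.999 for k in (model.k_on, model.k_off))
    converged = bool(best.success and rates_ok and model.delta_max > 0)
    if sigma > 1e-9:
        z = best.fun / (1.345 * sigma)
        weights = 1.0 / np.sqrt(1.0 + z ** 2)
    else:
        weights = np.ones_like(best.fun)
    return FitResult(model=model, residual_scale=sigma, converged=converged, weights=weights)


def extrapolate_E(fit: FitResult, points: PhasePoints) -> float:
    """Time point E; extrapolated as ``tD + ln(20)/k_off`` when unobserved.

    An observed E inside the window is returned as-is.  The extrapolation is
    the time at which the fitted dissociation exponential has lost 95% of
    its amplitude at D.  Returns ``nan`` when the fit did not converge or
    k_off is not positive.
    """
    if np.isfinite(points.tE) and not points.tE_extrapolated:
        return float(points.tE)
    if fit is None or not fit.converged or fit.model.k_off <= 0:
        return float("nan")
    return float(points.tD + LN20 / fit.model.k_off)


def compute_parameters(
    trace: IntensityTrace,
    points: PhasePoints,
    fit: FitResult | None = None,
    ring_corrected_fold_change: bool = False,
) -> KineticParameters:
    """Assemble the nine per-cell kinetic parameters.

    Durations come from the empirical phase points (E extrapolated from the
    fit when needed), the rates from the regression (``nan`` when it did not
    converge), and the fold change from the raw site-intensity trace.
    """
    tE = points.tE if (np.isfinite(points.tE) and not points.tE_extrapolated) else extrapolate_E(fit, points)
    lag = points.tB - points.tA
    association = points.tC - points.tB
    plateau = points.tD - points.tC
    dissociation = tE - points.tD if np.isfinite(tE) else float("nan")
    duration = tE - points.tB if np.isfinite(tE) else float("nan")
    converged = fit is not None and fit.converged
    return KineticParameters(
        lag_time_s=float(lag),
        association_time_s=float(association),
        plateau_time_s=float(plateau),
        dissociation_time_s=float(dissociation),
        duration_s=float(duration),
        k_on=float(fit.model.k_on) if converged else float("nan"),
        k_off=float(fit.model.k_off) if converged else float("nan"),
        fold_change=compute_fold_change(trace, ring_corrected=ring_corrected_fold_change),
        plateau_present=points.plateau_present,
    )
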