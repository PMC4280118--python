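"""Blood and plasma processing.

Turns a whole-blood curve (continuously sampled or image-derived) plus sparse
manual samples into a metabolite-corrected parent-plasma input function:

    Cp_parent(t) = C_wb(t) / r(t) * pf(t)

where r(t) is the bi-exponential whole-blood-to-plasma concentration ratio and
pf(t) the Hill-model parent (un-metabolized) fraction, both fitted to the
manual samples. Continuous arterial sampling lines additionally need
dispersion (single-exponential kernel, tau ~ 16 s) and delay handling;
image-derived curves do not, but need one-point calibration against a manual
sample and an occasional repair of a single inversion point near 1.5 min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit, minimize_scalar
from scipy.signal import savgol_filter

from .curves import InputFunction, InsufficientDataError, TimeActivityCurve
from .io import ManualSample

__all__ = [
    "BiExpParams", "HillParams", "fit_blood_to_plasma", "fit_parent_fraction",
    "apply_dispersion", "correct_dispersion", "estimate_delay",
    "assemble_input_function", "calibrate_idif", "correct_inversion",
]


@dataclass
class BiExpParams:
    """Bi-exponential whole-blood-to-plasma ratio r(t) = offset + a1 e^{-b1 t} + a2 e^{-b2 t}.

    Times in minutes; rates b1, b2 in 1/min. ``converged`` is False when the
    nonlinear fit failed and the constant-ratio fallback was used.
    """

    a1: float
    a2: float
    b1: float
    b2: float
    offset: float
    converged: bool = True
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        if self.b1 < 0 or self.b2 < 0:
            raise ValueError("decay rates must be non-negative")

    def predict(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        return (self.offset + self.a1 * np.exp(-self.b1 * t)
                + self.a2 * np.exp(-self.b2 * t))


@dataclass
class HillParams:
    """Hill parent-fraction model pf(t) = 1 - amplitude * t^s / (t^s + h^s).

    pf(0) = 1 by construction; pf is monotone non-increasing for amplitude,
    half_time, slope > 0. half_time (minutes) is where the metabolized
    fraction reaches half its asymptote; with amplitude = 1 this makes
    pf(half_time) = 0.5.
    """

    amplitude: float
    half_time: float
    slope: float
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        if not (0.0 <= self.amplitude <= 1.0):
            raise ValueError("amplitude must lie in [0, 1]")
        if self.half_time <= 0 or self.slope <= 0:
            raise ValueError("half_time and slope must be positive")

    def predict(self, t_min) -> np.ndarray:
        t = np.maximum(np.asarray(t_min, dtype=float), 0.0)
        ts = t ** self.slope
        return 1.0 - self.amplitude * ts / (ts + self.half_time ** self.slope)


def fit_blood_to_plasma(samples: list[ManualSample],
                        weights: np.ndarray | None = None) -> BiExpParams:
    """Weighted least-squares bi-exponential fit of the blood-to-plasma ratio.

    Requires >= 3 samples with plasma > 0. On non-convergence the result falls
    back to the constant mean ratio with ``converged=False``.
    """
    usable = [s for s in samples if s.plasma > 0]
    if len(usable) < 3:
        raise InsufficientDataError("need >= 3 samples with plasma > 0")
    t = np.array([s.time for s in usable])
    ratio = np.array([s.whole_blood / s.plasma for s in usable])
    w = np.ones_like(ratio) if weights is None else np.asarray(weights, float)

    def model(tt, a1, a2, b1, b2, offset):
        return offset + a1 * np.exp(-b1 * tt) + a2 * np.exp(-b2 * tt)

    p0 = [ratio[0] - ratio[-1], 0.0, 0.3, 0.01, ratio[-1]]
    bounds = ([-10, -10, 0, 0, -10], [10, 10, 20, 20, 10])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, t, ratio, p0=p0, sigma=1.0 / np.sqrt(w),
                                bounds=bounds, maxfev=20000)
        params = BiExpParams(popt[0], popt[1], popt[2], popt[3], popt[4])
        params.residuals = ratio - params.predict(t)
        if not np.all(np.isfinite(params.residuals)):
            raise RuntimeError
    except (RuntimeError, ValueError):
        params = BiExpParams(0.0, 0.0, 0.0, 0.0, float(np.mean(ratio)),
                             converged=False)
        params.residuals = ratio - params.predict(t)
    return params


def fit_parent_fraction(samples: list[ManualSample]) -> HillParams:
    """Least-squares Hill fit to the parent-fraction samples (pf(0)=1 enforced)."""
    if len(samples) < 3:
        raise InsufficientDataError("need >= 3 parent-fraction samples")
    t = np.array([s.time for s in samples])
    pf = np.array([s.parent_fraction for s in samples])
    if np.any((pf < 0) | (pf > 1)):
        raise ValueError("parent fractions must lie in [0, 1]")

    def model(tt, amp, half, slope):
        tt = np.maximum(tt, 0.0)
        ts = tt ** slope
        return 1.0 - amp * ts / (ts + half ** slope)

    amp0 = np.clip(1.0 - pf.min(), 1e-6, 1.0)
    p0 = [amp0, max(np.median(t), 1e-3), 2.0]
    bounds = ([0.0, 1e-6, 1e-3], [1.0, 1e4, 20.0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(model, t, pf, p0=p0, bounds=bounds, maxfev=20000)
    params = HillParams(*popt)
    params.residuals = pf - params.predict(t)
    return params


def _fine_grid(tac: TimeActivityCurve, dt: float) -> TimeActivityCurve:
    diffs = np.diff(tac.times)
    if diffs.size and np.allclose(diffs, diffs[0]) and diffs[0] <= dt * 1.0001:
        return tac
    return tac.resample(dt)


def apply_dispersion(tac: TimeActivityCurve, tau: float) -> TimeActivityCurve:
    """Disperse a curve with the single-exponential kernel (1/tau) exp(-t/tau).

    Models the smearing of blood activity in the sampling line; the kernel
    integrates to one, so total AUC is preserved. tau = 0 is the identity.
    The curve is resampled internally to a fine uniform grid and the result is
    returned at the original sample times.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if tau == 0:
        return tac.with_values(tac.values.copy())
    dt = min(0.1, tau / 100.0)
    fine = _fine_grid(tac, dt)
    h = fine.times[1] - fine.times[0]
    # midpoint-sampled kernel: first moment matches the continuum to O(h^2)
    kt = (np.arange(int(np.ceil(20 * tau / h))) + 0.5) * h
    kernel = np.exp(-kt / tau)
    kernel /= kernel.sum()
    dispersed = np.convolve(fine.values, kernel)[: fine.times.size]
    out_vals = np.interp(tac.times, fine.times, dispersed)
    return tac.with_values(out_vals)


def correct_dispersion(tac: TimeActivityCurve, tau: float) -> TimeActivityCurve:
    """Invert the exponential-kernel dispersion: C_true = C_meas + tau dC/dt.

    This is the exact continuum inverse of :func:`apply_dispersion`; the
    derivative is a Savitzky-Golay smoothed numerical derivative for noise
    stability. Grids coarser than tau trigger a warning and a resample.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if tau == 0:
        return tac.with_values(tac.values.copy())
    spacing = np.diff(tac.times)
    work = tac
    if spacing.max() > tau:
        warnings.warn("time grid coarser than tau; resampling for the derivative")
        work = tac.resample(tau / 50.0)
    elif not np.allclose(spacing, spacing[0]):
        work = tac.resample(spacing.min())
    h = work.times[1] - work.times[0]
    n = work.times.size
    window = min(7, n if n % 2 == 1 else n - 1)
    if window >= 5:
        deriv = savgol_filter(work.values, window, polyorder=3, deriv=1,
                              delta=h, mode="interp")
    else:
        deriv = np.gradient(work.values, h)
    corrected = work.values + tau * deriv
    return tac.with_values(np.interp(tac.times, work.times, corrected))


def estimate_delay(blood: TimeActivityCurve, head_curve: TimeActivityCurve,
                   fit_window: float = 50.0, max_delay: float = 30.0,
                   coarse_step: float = 0.5, fine_step: float = 0.05) -> float:
    """Delay between a blood curve and the early head (field-of-view) signal.

    The head signal over the first ``fit_window`` seconds is modelled as an
    irreversible one-compartment uptake driven by the shifted blood curve,
    head(t) ~= K * integral_0^t blood(s - delay) ds, and the delay minimizing
    the SSE is found by coarse grid search plus local refinement (K is
    profiled out in closed form). Returns the delay in seconds.
    """
    if np.allclose(blood.values, 0.0):
        raise ValueError("blood curve is identically zero; delay undefined")
    if np.std(head_curve.values[head_curve.times <= fit_window]) < 1e-12:
        raise ValueError("flat head curve; delay undefined")
    dt = 0.05
    tgrid = np.arange(0.0, fit_window + dt / 2, dt)
    head = head_curve(tgrid)
    b_times, b_vals = blood.times, blood.values

    def sse(delta: float) -> float:
        shifted = np.interp(tgrid - delta, b_times, b_vals,
                            left=b_vals[0], right=b_vals[-1])
        cum = cumulative_trapezoid(shifted, tgrid, initial=0.0)
        denom = float(cum @ cum)
        if denom <= 0:
            return float(head @ head)
        k = float(head @ cum) / denom
        resid = head - k * cum
        return float(resid @ resid)

    coarse = np.arange(-max_delay, max_delay + coarse_step / 2, coarse_step)
    best = coarse[int(np.argmin([sse(d) for d in coarse]))]
    fine = np.arange(best - coarse_step, best + coarse_step + fine_step / 2,
                     fine_step)
    return float(fine[int(np.argmin([sse(d) for d in fine]))])


def assemble_input_function(whole_blood: TimeActivityCurve, b2p: BiExpParams,
                            hill: HillParams, provenance: str = "ABSS",
                            ratio_is_plasma_to_blood: bool = False
                            ) -> InputFunction:
    """Build the metabolite-corrected parent-plasma input function.

    parent_plasma(t) = whole_blood(t) / r(t) * pf(t) on the whole-blood time
    grid, with r the fitted blood-to-plasma ratio and pf the Hill parent
    fraction. Set ``ratio_is_plasma_to_blood`` if the fitted ratio follows the
    opposite convention (the curve is then multiplied by it instead).
    """
    t_min = whole_blood.times / 60.0
    ratio = b2p.predict(t_min)
    if np.any(ratio <= 0):
        raise ValueError("blood-to-plasma ratio prediction must be positive")
    pf = hill.predict(t_min)
    plasma = (whole_blood.values * ratio if ratio_is_plasma_to_blood
              else whole_blood.values / ratio)
    out = InputFunction(whole_blood.times.copy(), plasma * pf,
                        provenance=provenance,
                        calibration=getattr(whole_blood, "calibration", {}))
    return out


def calibrate_idif(idif: TimeActivityCurve, sample: ManualSample,
                   at: float = 15.0) -> TimeActivityCurve:
    """One-point calibration of an image-derived whole-blood curve.

    Scales the whole curve so that its value at ``at`` minutes (linear
    interpolation between frame mid-times) equals the manual whole-blood
    sample. The scale factor is recorded on the returned curve.
    """
    t_s = at * 60.0
    if not (idif.times[0] <= t_s <= idif.times[-1]):
        raise ValueError(f"curve does not cover the {at}-minute calibration time")
    level = float(idif(t_s))
    if level <= 0:
        raise ValueError("curve value at the calibration time must be positive")
    if sample.whole_blood <= 0:
        raise ValueError("calibration sample activity must be positive")
    scale = sample.whole_blood / level
    out = idif.with_values(idif.values * scale)
    out.calibration = {"scale": scale, "sample_time_min": at,
                       "sample_kBq_mL": sample.whole_blood}
    return out


def correct_inversion(idif: TimeActivityCurve, sample: ManualSample | None = None,
                      near: float = 1.5, window: float = 0.5,
                      scale: float = 1.0) -> TimeActivityCurve:
    """Repair a single inversion point near ``near`` minutes post-injection.

    Extraction occasionally produces one point that breaks local monotonicity:
    a dip (below both neighbours) on the post-peak decay, or a spike (above
    both neighbours) on the pre-peak rise. Within +/- ``window`` minutes of
    ``near``, such a point is replaced by the manual sample value (times
    ``scale``, to express it in the curve's current units) when the sample
    time lands on that point, and by linear interpolation of its neighbours
    otherwise. Curves without an artifact are returned unchanged.
    """
    t_lo, t_hi = (near - window) * 60.0, (near + window) * 60.0
    if idif.times[0] > t_lo or idif.times[-1] < t_hi:
        raise ValueError("curve does not cover the inversion-search window")
    v = idif.values.copy()
    t = idif.times
    peak_idx = int(np.argmax(v))
    candidates = [i for i in range(1, t.size - 1) if t_lo <= t[i] <= t_hi]
    repaired = False
    for i in candidates:
        dip = v[i] < v[i - 1] and v[i] < v[i + 1] and i > peak_idx
        spike = v[i] > v[i - 1] and v[i] > v[i + 1] and i < peak_idx
        if not (dip or spike):
            continue
        half_gap = 0.5 * max(t[i] - t[i - 1], t[i + 1] - t[i])
        if sample is not None and abs(sample.time * 60.0 - t[i]) <= half_gap:
            v[i] = sample.whole_blood * scale
        else:
            v[i] = np.interp(t[i], [t[i - 1], t[i + 1]], [v[i - 1], v[i + 1]])
        repaired = True
        break
    out = idif.with_values(v)
    out.inversion_repaired = repaired
    if hasattr(idif, "calibration"):
        out.calibration = idif.calibration
    return out
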