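"""Two-tissue compartment (2-TCM) kinetic modelling.

The model describes reversible radioligand uptake with a free/non-specific
tissue compartment C1 and a specifically bound compartment C2:

    dC1/dt = K1 Cp - (k2 + k3) C1 + k4 C2
    dC2/dt = k3 C1 - k4 C2

driven by the metabolite-corrected parent-plasma input Cp. The measured PET
signal mixes tissue and vascular activity,

    C_PET(t) = (1 - vb) (C1 + C2) + vb C_wb(t),

with vb the fractional cerebral blood volume (default 0.05). The endpoint is
the total distribution volume V_T = K1/k2 (1 + k3/k4), the equilibrium
tissue-to-plasma concentration ratio.

The linear ODE system is solved analytically (bi-exponential impulse response
convolved with Cp on a fine grid) and frame-averaged over the acquisition
schedule. Fitting is weighted nonlinear least squares with trues-based frame
weights w_i = dt_i^2 / (T_i dc_i^2), multi-start, with standard errors from
the Jacobian at the optimum.

Rates are in 1/min and K1 in mL cm^-3 min^-1; curve times remain in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import fftconvolve

from .curves import FrameSchedule, TimeActivityCurve

F18_HALF_LIFE_MIN = 109.77
F18_LAMBDA_PER_MIN = np.log(2.0) / F18_HALF_LIFE_MIN

__all__ = [
    "TCM2Params", "FrameWeights", "tcm2_forward", "decay_factor",
    "frame_weights", "compute_vt", "TwoTissueModel", "TwoTissueResults",
    "F18_LAMBDA_PER_MIN",
]


@dataclass
class TCM2Params:
    """Rate constants of the two-tissue compartment model.

    K1 [mL cm^-3 min^-1], k2..k4 [1/min], vb dimensionless blood-volume
    fraction. V_T is derived, never stored.
    """

    K1: float
    k2: float
    k3: float
    k4: float
    vb: float = 0.05

    def __post_init__(self):
        if min(self.K1, self.k2, self.k3, self.k4) < 0:
            raise ValueError("rate constants must be non-negative")
        if not (0.0 <= self.vb < 1.0):
            raise ValueError("vb must lie in [0, 1)")

    @property
    def vt(self) -> float:
        return compute_vt(self)

    def as_dict(self) -> dict:
        d = {"K1": self.K1, "k2": self.k2, "k3": self.k3, "k4": self.k4,
             "vb": self.vb}
        try:
            d["VT"] = self.vt
        except ValueError:
            d["VT"] = float("nan")
        return d


def compute_vt(params: TCM2Params) -> float:
    """Total distribution volume V_T = K1/k2 (1 + k3/k4) [mL/cm^3]."""
    if params.k2 <= 0 or params.k4 <= 0:
        raise ValueError("V_T undefined for k2 = 0 or k4 = 0")
    return params.K1 / params.k2 * (1.0 + params.k3 / params.k4)


def decay_factor(t_mid_min, lam: float = F18_LAMBDA_PER_MIN):
    """Fraction of activity remaining at ``t_mid_min`` minutes: exp(-lam t)."""
    if lam < 0:
        raise ValueError("decay constant must be >= 0")
    return np.exp(-lam * np.asarray(t_mid_min, dtype=float))


@dataclass
class FrameWeights:
    """Trues-based fit weights w_i = dt_i^2 / (T_i dc_i^2).

    Longer frames and late (decayed) frames carry more weight because their
    reconstructed values are less noisy relative to the decaying signal.
    Frames with zero trues get zero weight.
    """

    weights: np.ndarray
    trues: np.ndarray
    decay_factors: np.ndarray

    @property
    def normalized(self) -> np.ndarray:
        s = self.weights.sum()
        return self.weights / s if s > 0 else self.weights


def frame_weights(schedule: FrameSchedule, trues,
                  lam: float = F18_LAMBDA_PER_MIN,
                  cap_ratio: float = 25.0) -> FrameWeights:
    """Trues-based weights with a numerical guard.

    Frames acquired before tracer arrival have almost no trues, which would
    give them near-infinite weight and let them dominate the fit; weights are
    therefore capped at ``cap_ratio`` times the median positive weight
    (``cap_ratio=None`` disables the cap). Zero-trues frames get zero weight.
    """
    trues = np.asarray(trues, dtype=float)
    if trues.shape != (schedule.n_frames,):
        raise ValueError("trues must have one entry per frame")
    if np.any(trues < 0):
        raise ValueError("trues must be non-negative")
    dc = decay_factor(schedule.mid_times / 60.0, lam)
    dur = schedule.durations
    with np.errstate(divide="ignore"):
        w = np.where(trues > 0, dur ** 2 / (trues * dc ** 2), 0.0)
    if cap_ratio is not None and np.any(w > 0):
        w = np.minimum(w, cap_ratio * np.median(w[w > 0]))
    return FrameWeights(w, trues, dc)


def _impulse_response(p: TCM2Params, t_min: np.ndarray) -> np.ndarray:
    """Analytic tissue impulse response h(t) with C_T = h (*) Cp."""
    s = p.k2 + p.k3 + p.k4
    disc = max(s * s - 4.0 * p.k2 * p.k4, 0.0)
    root = np.sqrt(disc)
    a1 = 0.5 * (s - root)
    a2 = 0.5 * (s + root)
    if root < 1e-12:  # repeated eigenvalue
        return p.K1 * np.exp(-a1 * t_min) * (1.0 + (p.k3 + p.k4 - a1) * t_min)
    c1 = (p.k3 + p.k4 - a1) / root
    c2 = (a2 - p.k3 - p.k4) / root
    return p.K1 * (c1 * np.exp(-a1 * t_min) + c2 * np.exp(-a2 * t_min))


def _conv_trapezoid(h: np.ndarray, cp: np.ndarray, dt: float) -> np.ndarray:
    """Discrete convolution with trapezoid end-point correction (O(dt^2))."""
    out = fftconvolve(h, cp)[: h.size] * dt
    return out - 0.5 * dt * (h[0] * cp + h * cp[0])


def tcm2_forward(params: TCM2Params, input_fn: TimeActivityCurve,
                 whole_blood: TimeActivityCurve, schedule: FrameSchedule,
                 dt_s: float = 1.0) -> TimeActivityCurve:
    """Model PET TAC: (1-vb)(C1+C2) + vb C_wb, frame-averaged over the schedule.

    C1+C2 is computed by discrete convolution of the analytic bi-exponential
    impulse response with the input function on a ``dt_s``-second grid.
    """
    tgrid_s = np.arange(0.0, schedule.total_time + dt_s / 2, dt_s)
    dt_min = dt_s / 60.0
    cp = np.interp(tgrid_s, input_fn.times, input_fn.values, left=0.0)
    h = _impulse_response(params, tgrid_s / 60.0)
    tissue = _conv_trapezoid(h, cp, dt_min)
    wb = np.interp(tgrid_s, whole_blood.times, whole_blood.values, left=0.0)
    signal = (1.0 - params.vb) * tissue + params.vb * wb
    frame_vals = schedule.frame_average(tgrid_s, signal)
    return TimeActivityCurve(schedule.mid_times, frame_vals)


class TwoTissueModel:
    """Weighted 2-TCM fit of a regional tissue TAC against an input function.

    Parameters
    ----------
    tissue : TimeActivityCurve
        Regional TAC on the frame mid-times of ``schedule``.
    input_fn : TimeActivityCurve
        Metabolite-corrected parent-plasma input function.
    whole_blood : TimeActivityCurve
        Whole-blood curve for the vascular term.
    schedule : FrameSchedule
        Acquisition frames (used for frame averaging of the model curve).
    weights : FrameWeights or None
        Trues-based weights; None means uniform.
    vb : float
        Blood-volume fraction; fixed unless ``fit_vb``.
    """

    BOUNDS = (1e-6, 10.0)

    def __init__(self, tissue: TimeActivityCurve, input_fn: TimeActivityCurve,
                 whole_blood: TimeActivityCurve, schedule: FrameSchedule,
                 weights: FrameWeights | None = None, vb: float = 0.05,
                 fit_vb: bool = False, dt_s: float = 1.0):
        if tissue.times.size != schedule.n_frames:
            raise ValueError("tissue TAC must have one value per frame")
        if not np.all(np.isfinite(tissue.values)):
            raise ValueError("tissue TAC contains non-finite values")
        if not np.all(np.isfinite(input_fn.values)):
            raise ValueError("input function contains non-finite values")
        self.tissue = tissue
        self.input_fn = input_fn
        self.whole_blood = whole_blood
        self.schedule = schedule
        self.weights = weights
        self.vb = vb
        self.fit_vb = fit_vb
        self.dt_s = dt_s
        # precompute fine-grid curves shared by every objective evaluation
        self._tgrid = np.arange(0.0, schedule.total_time + dt_s / 2, dt_s)
        self._cp = np.interp(self._tgrid, input_fn.times, input_fn.values,
                             left=0.0)
        self._wb = np.interp(self._tgrid, whole_blood.times,
                             whole_blood.values, left=0.0)
        self._avg = schedule.averaging_matrix(self._tgrid)
        self._wb_frames = self._avg @ self._wb
        w = np.ones(schedule.n_frames) if weights is None else weights.weights
        self._sqrt_w = np.sqrt(w / max(w.sum(), 1e-300) * schedule.n_frames)

    def _model_frames(self, theta: np.ndarray) -> np.ndarray:
        vb = theta[4] if self.fit_vb else self.vb
        p = TCM2Params(theta[0], theta[1], theta[2], theta[3], vb)
        h = _impulse_response(p, self._tgrid / 60.0)
        tissue = _conv_trapezoid(h, self._cp, self.dt_s / 60.0)
        frames = self._avg @ tissue
        return (1.0 - vb) * frames + vb * self._wb_frames

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        return self._sqrt_w * (self.tissue.values - self._model_frames(theta))

    def fit(self, init: TCM2Params | None = None, n_starts: int = 5,
            seed: int = 0, bounds: tuple[float, float] | None = None
            ) -> "TwoTissueResults":
        """Multi-start trust-region weighted least squares; best-SSE winner."""
        lo, hi = bounds if bounds is not None else self.BOUNDS
        init = init or TCM2Params(0.1, 0.1, 0.05, 0.05, self.vb)
        base = np.array([init.K1, init.k2, init.k3, init.k4])
        if self.fit_vb:
            base = np.append(base, init.vb if init.vb > 0 else 0.05)
        rng = np.random.default_rng(seed)
        best = None
        n_params = base.size
        lo_vec = np.full(n_params, lo)
        hi_vec = np.full(n_params, hi)
        if self.fit_vb:
            lo_vec[4], hi_vec[4] = 0.0, 0.2
        for start in range(max(n_starts, 1)):
            x0 = base if start == 0 else np.clip(
                base * np.exp(rng.normal(0.0, 0.7, n_params)), lo_vec, hi_vec)
            try:
                sol = least_squares(self._residuals, x0, bounds=(lo_vec, hi_vec),
                                    method="trf", xtol=1e-10, ftol=1e-10)
            except ValueError:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("all optimization starts failed")
        theta = best.x
        vb = theta[4] if self.fit_vb else self.vb
        params = TCM2Params(theta[0], theta[1], theta[2], theta[3], vb)
        sse = 2.0 * best.cost
        dof = max(self.schedule.n_frames - n_params, 1)
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj) * (sse / dof)
            bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            bse = np.full(n_params, np.nan)
        fitted = self._model_frames(theta)
        return TwoTissueResults(self, params, sse, bse, fitted,
                                converged=bool(best.success),
                                n_starts=n_starts)


@dataclass
class TwoTissueResults:
    """Fit result: parameter estimates, uncertainties, diagnostics."""

    model: TwoTissueModel
    params: TCM2Params
    sse: float
    bse: np.ndarray
    fittedvalues: np.ndarray
    converged: bool = True
    n_starts: int = 1

    @property
    def vt(self) -> float:
        return self.params.vt

    @property
    def residuals(self) -> np.ndarray:
        return self.model.tissue.values - self.fittedvalues

    def summary(self) -> str:
        names = ["K1", "k2", "k3", "k4"] + (["vb"] if self.model.fit_vb else [])
        vals = [self.params.K1, self.params.k2, self.params.k3, self.params.k4]
        if self.model.fit_vb:
            vals.append(self.params.vb)
        lines = ["Two-tissue compartment model fit",
                 "=" * 40,
                 f"frames: {self.model.schedule.n_frames}"
                 f"   weighted SSE: {self.sse:.6g}"
                 f"   converged: {self.converged}",
                 f"{'param':>6} {'estimate':>12} {'std err':>12}"]
        for name, v, se in zip(names, vals, self.bse):
            lines.append(f"{name:>6} {v:12.5g} {se:12.4g}")
        if not self.model.fit_vb:
            lines.append(f"{'vb':>6} {self.params.vb:12.5g} {'(fixed)':>12}")
        try:
            lines.append(f"V_T = K1/k2 (1 + k3/k4) = {self.vt:.4g} mL/cm^3")
        except ValueError:
            lines.append("V_T undefined (k2 or k4 at zero)")
        return "\n".join(lines)
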