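"""Tracer kinetic engines: 2TCM simulation/fitting and Logan graphical V_T.

The two-tissue compartment model (2TCM) with plasma-to-tissue rate K1 and
tissue rates k2, k3, k4 has the analytic impulse response

    IRF(t) = K1/(a2 - a1) * [(k3 + k4 - a1) e^{-a1 t} + (a2 - k3 - k4) e^{-a2 t}]

with a1, a2 the roots of s^2 - (k2+k3+k4) s + k2 k4.  Its integral over
[0, inf) is the total distribution volume V_T = (K1/k2)(1 + k3/k4), which is
what both the 2TCM fit and the Logan plot estimate.  Tissue curves are the
convolution of the IRF with the arterial input, computed by trapezoid on a
fine time grid and averaged within acquisition frames.

The Logan plot regresses int_0^T C_T / C_T(T) on int_0^T C_p / C_T(T); the
slope over frames after t* is V_T.  Because the plot depends on the input only
through its running integral, inflating the input AUC deflates the estimated
V_T -- the mechanism probed by the bias studies in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares
from scipy.signal import fftconvolve

from .input_function import FittedInputFunction

FINE_DT = 0.05  # min; convolution/integration grid

#: default synthetic frame schedule: 6x0.5, 3x1, 2x2, 4x5, 9x10 = 120 min
DEFAULT_FRAME_DURATIONS = [0.5] * 6 + [1.0] * 3 + [2.0] * 2 + [5.0] * 4 + [10.0] * 9


def default_frames() -> tuple[np.ndarray, np.ndarray]:
    ends = np.cumsum(DEFAULT_FRAME_DURATIONS)
    starts = ends - np.asarray(DEFAULT_FRAME_DURATIONS)
    return starts, ends


@dataclass(frozen=True)
class TwoTCMParams:
    """Rate constants for the two-tissue compartment model.

    K1 in mL cm^-3 min^-1; k2, k3, k4 in 1/min; vB the fractional blood
    volume (0 by default -- no blood-borne signal in the tissue curve).
    """

    K1: float
    k2: float
    k3: float
    k4: float
    vB: float = 0.0

    def __post_init__(self):
        if self.K1 <= 0 or self.k2 <= 0 or self.k3 < 0 or self.k4 <= 0:
            raise ValueError("rate constants must be positive (k3 may be 0)")
        if not 0 <= self.vB <= 0.1:
            raise ValueError("vB must be in [0, 0.1]")

    @property
    def vt(self) -> float:
        return (self.K1 / self.k2) * (1.0 + self.k3 / self.k4)

    def irf(self, t) -> np.ndarray:
        """Analytic impulse response at times t (min)."""
        t = np.asarray(t, float)
        s = self.k2 + self.k3 + self.k4
        disc = s * s - 4.0 * self.k2 * self.k4
        if disc > 1e-12 * s * s:
            root = np.sqrt(disc)
            a1 = 0.5 * (s - root)
            a2 = 0.5 * (s + root)
            return (self.K1 / (a2 - a1)) * (
                (self.k3 + self.k4 - a1) * np.exp(-a1 * t)
                + (a2 - self.k3 - self.k4) * np.exp(-a2 * t))
        # repeated-eigenvalue limit
        a = 0.5 * s
        return self.K1 * np.exp(-a * t) * (1.0 + (self.k3 + self.k4 - a) * t)


def input_on_grid(input_curve, tgrid: np.ndarray) -> np.ndarray:
    """Evaluate any supported input representation on a fine time grid.

    Accepts a FittedInputFunction (evaluated exactly), an object with
    ``times``/``values`` arrays (e.g. a scaled PBIF; linearly interpolated),
    or a (times, values) tuple.
    """
    if isinstance(input_curve, FittedInputFunction):
        return input_curve.value(tgrid)
    if hasattr(input_curve, "times") and hasattr(input_curve, "values"):
        return np.interp(tgrid, input_curve.times, input_curve.values)
    times, values = input_curve
    return np.interp(tgrid, np.asarray(times, float), np.asarray(values, float))


def _convolve_trapezoid(f: np.ndarray, g: np.ndarray, dt: float) -> np.ndarray:
    """Trapezoid-rule convolution of two causal signals on a uniform grid."""
    n = f.size
    full = fftconvolve(f, g)[:n] * dt
    return full - 0.5 * dt * (f[0] * g[:n] + g[0] * f[:n])


def simulate_2tcm(params: TwoTCMParams, input_curve, frame_starts, frame_ends,
                  dt: float = FINE_DT) -> np.ndarray:
    """Forward-simulate a regional TAC: IRF (x) input on a fine grid, then
    averaged within each acquisition frame.  Adds vB x input if vB > 0."""
    fs = np.asarray(frame_starts, float)
    fe = np.asarray(frame_ends, float)
    tgrid = np.arange(0.0, fe[-1] + dt / 2, dt)
    cp = input_on_grid(input_curve, tgrid)
    ct = _convolve_trapezoid(params.irf(tgrid), cp, dt)
    if params.vB > 0:
        ct = (1.0 - params.vB) * ct + params.vB * cp
    out = np.empty(fs.size)
    for i, (a, b) in enumerate(zip(fs, fe)):
        m = (tgrid >= a - 1e-9) & (tgrid <= b + 1e-9)
        out[i] = np.trapezoid(ct[m], tgrid[m]) / (b - a)
    return out


@dataclass(frozen=True)
class LoganResult:
    """Logan graphical fit: slope (V_T), intercept, and linearity diagnostics."""

    vt: float
    intercept: float
    t_star: float
    n_points: int
    r_squared: float
    max_rel_deviation: float = float("nan")

    def __post_init__(self):
        if self.n_points < 3:
            raise ValueError("Logan fit needs >= 3 points")
        if not np.isfinite(self.vt):
            raise ValueError("non-finite Logan V_T")

    def is_linear(self, tol: float = 0.10) -> bool:
        """Linearization check: no included point deviates from the fitted
        line by more than ``tol`` relative to the fitted value."""
        return bool(self.max_rel_deviation <= tol)


def logan_vt(tac_values, frame_starts, frame_ends, input_curve,
             t_star: float = 30.0, dt: float = FINE_DT) -> LoganResult:
    """Logan graphical estimate of V_T from one regional TAC.

    Tissue integrals are cumulative frame sums (exact for frame-constant
    curves); the input integral is a trapezoid on the fine grid.  Ordinary
    least squares over frames whose mid-time is >= t_star.
    """
    ct = np.asarray(tac_values, float)
    fs = np.asarray(frame_starts, float)
    fe = np.asarray(frame_ends, float)
    mids = 0.5 * (fs + fe)
    dur = fe - fs
    # cumulative tissue integral up to each frame mid-time
    cum = np.cumsum(ct * dur)
    tiss_int = cum - 0.5 * ct * dur

    tgrid = np.arange(0.0, fe[-1] + dt / 2, dt)
    cp = input_on_grid(input_curve, tgrid)
    cp_cum = np.concatenate([[0.0], np.cumsum(0.5 * (cp[1:] + cp[:-1]) * np.diff(tgrid))])
    plasma_int = np.interp(mids, tgrid, cp_cum)

    use = mids >= t_star
    if use.sum() < 3:
        raise ValueError(
            f"only {int(use.sum())} frames after t*={t_star}; need >= 3")
    if np.any(ct[use] <= 0):
        raise ValueError("non-positive tissue values after t*")
    x = plasma_int[use] / ct[use]
    y = tiss_int[use] / ct[use]
    fit = stats.linregress(x, y)
    yhat = fit.slope * x + fit.intercept
    max_dev = float(np.max(np.abs(y - yhat) / np.abs(yhat)))
    return LoganResult(vt=float(fit.slope), intercept=float(fit.intercept),
                       t_star=float(t_star), n_points=int(use.sum()),
                       r_squared=float(fit.rvalue ** 2),
                       max_rel_deviation=max_dev)


_LOG_LO, _LOG_HI = np.log(1e-4), np.log(2.0)


def fit_2tcm(tac_values, frame_starts, frame_ends, input_curve,
             multistarts: int = 8, seed: int = 0, dt: float = FINE_DT):
    """Unconstrained 2TCM fit by weighted nonlinear least squares.

    Frame residuals are weighted by sqrt(frame duration).  All four rate
    constants are searched in log-space within (1e-4, 2); ``multistarts``
    log-uniform starting points (seeded) guard against local minima.  Returns
    (TwoTCMParams, vt, diagnostics).  Raises RuntimeError if every start
    fails.
    """
    ct = np.asarray(tac_values, float)
    fs = np.asarray(frame_starts, float)
    fe = np.asarray(frame_ends, float)
    if ct.size < 10:
        raise ValueError(f"2TCM fit needs >= 10 frames, got {ct.size}")
    w = np.sqrt(fe - fs)
    scale = max(float(np.max(np.abs(ct))), 1e-12)

    tgrid = np.arange(0.0, fe[-1] + dt / 2, dt)
    cp = input_on_grid(input_curve, tgrid)
    masks = [(tgrid >= a - 1e-9) & (tgrid <= b + 1e-9) for a, b in zip(fs, fe)]

    def model(x):
        p = TwoTCMParams(*np.exp(x))
        conv = _convolve_trapezoid(p.irf(tgrid), cp, dt)
        return np.array([np.trapezoid(conv[m], tgrid[m]) for m in masks]) / (fe - fs)

    def residual(x):
        return (model(x) - ct) * w / scale

    rng = np.random.default_rng(seed)
    starts = [np.log([0.1, 0.1, 0.05, 0.05])]
    while len(starts) < multistarts:
        starts.append(rng.uniform(_LOG_LO, _LOG_HI, 4))
    best, n_ok = None, 0
    for x0 in starts:
        try:
            sol = least_squares(residual, x0, bounds=(_LOG_LO, _LOG_HI),
                                method="trf", ftol=1e-12, xtol=1e-12,
                                max_nfev=400)
        except Exception:
            continue
        n_ok += 1
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("2TCM fit failed from every start")
    params = TwoTCMParams(*np.exp(best.x))
    diagnostics = {"cost": float(best.cost), "n_starts_converged": n_ok,
                   "success": bool(best.success)}
    return params, params.vt, diagnostics
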