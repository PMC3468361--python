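"""One-tissue compartment kinetics for dynamic [15O]water PET.

The measured activity in a tumour volume of interest is modelled as

    M(t) = V0 * Ca(t - delay) + Me(t),
    dMe/dt = K1 * Ca(t - delay) - k2 * Me(t),

with arterial input Ca(t), perfusion K1 (mL/g/min), washout k2 (1/min) and
vascular volume fraction V0 (mL/g, tissue density taken as 1 g/mL).  The
analytic solution of the tissue state is the exponential convolution

    Me(t) = K1 * (Ca conv exp(-k2 t))(t),

which this module evaluates by fine-grid quadrature.  Two estimators are
provided: a nonlinear least-squares fit of (K1, k2, V0), and a spectral
(basis-of-exponentials) linearisation in which M(t) is expressed as a
non-negative combination of Ca convolved with exponentials at fixed rates
beta_i >= 0; the weights alpha_i are obtained by non-negative least squares
and perfusion is read off as the sum of the spectrum.

Conventions
-----------
* Times at the interface are seconds (frame starts, durations, delays).
* Rates (k2, beta) and perfusion (K1, alpha) are per-minute quantities.
* Convolution integrals are taken with time in minutes, so that
  alpha_i [mL/g/min] times a basis column has the units of activity.
* Frame values are means of the fine-grid model samples falling inside the
  frame interval (left-closed, right-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .errors import DegenerateInputError, DomainError, GridMismatchError, ParameterError

SEC_PER_MIN = 60.0
#: Physical half-life of 15O in seconds.
O15_HALF_LIFE_S = 122.24
#: Default fine-grid step for quadrature, seconds.
DEFAULT_DT = 0.5


# ---------------------------------------------------------------------------
# Frame schedule and time-activity curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameSchedule:
    """Dynamic acquisition timing: per-frame start times and durations (s)."""

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or dur.shape != start.shape or start.size == 0:
            raise ParameterError("frame_start and frame_duration must be equal-length 1-D arrays")
        if np.any(dur <= 0):
            raise ParameterError("frame durations must be positive")
        ends = start + dur
        if np.any(np.diff(start) <= 0) or np.any(start[1:] < ends[:-1] - 1e-9):
            raise ParameterError("frames must be ordered and non-overlapping")

    @classmethod
    def from_durations(cls, durations, t0: float = 0.0) -> "FrameSchedule":
        durations = np.asarray(durations, dtype=float)
        starts = t0 + np.concatenate(([0.0], np.cumsum(durations)[:-1]))
        return cls(starts, durations)

    @classmethod
    def water_default(cls) -> "FrameSchedule":
        """The dynamic water protocol: 4 x 5 s, 2 x 10 s, 4 x 30 s (10 frames, 160 s)."""
        return cls.from_durations([5] * 4 + [10] * 2 + [30] * 4)

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    @property
    def frame_mid(self) -> np.ndarray:
        return self.frame_start + self.frame_duration / 2.0

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def total_end(self) -> float:
        return float(self.frame_end[-1])

    def fine_grid(self, dt: float = DEFAULT_DT) -> np.ndarray:
        """Uniform quadrature grid from 0 to the end of the last frame."""
        n = int(round(self.total_end / dt))
        return np.linspace(0.0, n * dt, n + 1)

    def frame_average(self, fine_times: np.ndarray, fine_values: np.ndarray) -> np.ndarray:
        """Time-average of a fine-grid curve over each frame interval
        (trapezoidal rule on the samples spanning [start, end])."""
        out = np.empty(self.n_frames)
        for i, (s, e) in enumerate(zip(self.frame_start, self.frame_end)):
            lo = np.searchsorted(fine_times, s - 1e-9, side="left")
            hi = np.searchsorted(fine_times, e + 1e-9, side="right")
            if hi - lo < 2:
                raise ParameterError("fine grid too coarse for frame averaging")
            seg_t = fine_times[lo:hi]
            out[i] = np.trapezoid(fine_values[lo:hi], seg_t) / (seg_t[-1] - seg_t[0])
        return out


@dataclass(frozen=True)
class TimeActivityCurve:
    """Per-frame tracer concentration (kBq/mL) on an acquisition schedule."""

    schedule: FrameSchedule
    activity: np.ndarray
    decay_corrected: bool = True

    def __post_init__(self):
        act = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "activity", act)
        if act.shape != (self.schedule.n_frames,):
            raise GridMismatchError(
                f"activity length {act.size} != frame count {self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(act)):
            raise ParameterError("activity values must be finite")


# ---------------------------------------------------------------------------
# Arterial input functions
# ---------------------------------------------------------------------------

class InputFunction:
    """Continuous-time arterial concentration Ca(t), kBq/mL.

    Two representations are supported: a parametric gamma-variate bolus and a
    sampled curve with linear interpolation.  Both are zero before the
    appearance time and non-negative everywhere.
    """

    def __init__(self, fn, support_end: float, t0: float, description: str):
        self._fn = fn
        self.support_end = float(support_end)
        self.t0 = float(t0)
        self.description = description

    @classmethod
    def gamma_variate(
        cls,
        amplitude: float = 50.0,
        t0: float = 5.0,
        time_to_peak: float = 20.0,
        shape: float = 3.0,
    ) -> "InputFunction":
        """Gamma-variate bolus with its maximum equal to ``amplitude``.

        Ca(t) = A * (x ** shape) * exp(shape * (1 - x)),  x = (t - t0)/time_to_peak,

        peaking at t0 + time_to_peak.  Amplitude in kBq/mL, times in seconds.
        """
        if amplitude <= 0 or time_to_peak <= 0 or shape <= 0 or t0 < 0:
            raise ParameterError("gamma-variate parameters must be positive (t0 >= 0)")

        def fn(t):
            x = (np.asarray(t, dtype=float) - t0) / time_to_peak
            with np.errstate(invalid="ignore"):
                val = np.where(x > 0, np.power(np.clip(x, 0, None), shape)
                               * np.exp(shape * (1.0 - x)), 0.0)
            return amplitude * val

        return cls(fn, support_end=np.inf, t0=t0,
                   description=f"gamma_variate(A={amplitude}, t0={t0}, tp={time_to_peak}, shape={shape})")

    @classmethod
    def from_samples(cls, times, values) -> "InputFunction":
        """Sampled curve; linear interpolation between samples, zero before the
        first sample and constant extrapolation is *not* allowed (domain error
        past the last sample at evaluation time)."""
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.ndim != 1 or times.shape != values.shape or times.size < 2:
            raise ParameterError("need >= 2 aligned samples")
        if np.any(np.diff(times) <= 0):
            raise ParameterError("sample times must be strictly increasing")
        values = np.clip(values, 0.0, None)  # enforce non-negativity contract

        def fn(t):
            return np.interp(np.asarray(t, dtype=float), times, values, left=0.0, right=values[-1])

        first_pos = times[np.argmax(values > 0)] if np.any(values > 0) else times[0]
        return cls(fn, support_end=float(times[-1]), t0=float(first_pos),
                   description=f"sampled(n={times.size})")

    @classmethod
    def zero(cls) -> "InputFunction":
        return cls(lambda t: np.zeros_like(np.asarray(t, dtype=float)),
                   support_end=np.inf, t0=0.0, description="zero")

    @classmethod
    def constant(cls, level: float) -> "InputFunction":
        """Ca = level for t >= 0 (analytic-oracle convenience)."""
        def fn(t):
            t = np.asarray(t, dtype=float)
            return np.where(t >= 0, float(level), 0.0)
        return cls(fn, support_end=np.inf, t0=0.0, description=f"constant({level})")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t > self.support_end + 1e-9):
            raise DomainError("evaluation time outside input-function support window")
        return np.where(t < 0, 0.0, self._fn(np.clip(t, 0.0, None)))

    def shifted(self, delay: float) -> "InputFunction":
        """Input delayed by ``delay`` seconds: returns Ca(t - delay)."""
        if delay == 0:
            return self
        base = self

        def fn(t):
            return base._fn(np.clip(np.asarray(t, dtype=float) - delay, 0.0, None)) * \
                (np.asarray(t, dtype=float) - delay >= 0)

        end = base.support_end + delay if np.isfinite(base.support_end) else np.inf
        return InputFunction(fn, support_end=max(end, 0.0), t0=base.t0 + delay,
                             description=f"{base.description} shifted {delay:+g}s")


# ---------------------------------------------------------------------------
# Model parameters and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OneTissueParams:
    """Parameters of the one-tissue model with vascular term.

    K1 : perfusion, mL/g/min;  k2 : washout, 1/min;
    V0 : vascular volume fraction, mL/g;  delay : input delay, s.
    """

    K1: float
    k2: float
    V0: float = 0.0
    delay: float = 0.0

    def __post_init__(self):
        if self.K1 < 0 or self.k2 < 0:
            raise ParameterError("K1 and k2 must be non-negative")
        if not (0.0 <= self.V0 <= 1.0):
            raise ParameterError("V0 must lie in [0, 1]")
        if abs(self.delay) > 120.0:
            raise ParameterError("delay outside the supported +/-120 s window")


@dataclass(frozen=True)
class SpectralBasis:
    """Fixed exponential-rate grid for spectral analysis.

    Rates in 1/min, strictly increasing, with the first rate exactly zero so
    that irreversible trapping (and slow washout) is representable; the top of
    the grid absorbs near-instantaneous (vascular-like) components.
    """

    rates: np.ndarray
    dt: float = DEFAULT_DT

    def __post_init__(self):
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", rates)
        if rates.ndim != 1 or rates.size < 2:
            raise ParameterError("need at least two basis rates")
        if rates[0] != 0.0:
            raise ParameterError("first basis rate must be exactly 0")
        if np.any(np.diff(rates) <= 0):
            raise ParameterError("basis rates must be strictly increasing")
        if self.dt <= 0:
            raise ParameterError("fine-grid step must be positive")

    @classmethod
    def default(cls, n_rates: int = 48, beta_min: float = 1e-3,
                beta_max: float = 6.0, dt: float = DEFAULT_DT) -> "SpectralBasis":
        """48 log-spaced rates in [1e-3, beta_max]/min plus the exact zero rate."""
        if beta_max <= 0:
            raise ParameterError("beta_max must be positive")
        grid = np.concatenate(([0.0], np.geomspace(beta_min, beta_max, n_rates)))
        return cls(grid, dt=dt)


@dataclass(frozen=True)
class SpectralResult:
    """Non-negative spectrum and the perfusion estimates derived from it.

    ``v0`` is the weight of the explicit blood-volume column (Ca itself) when
    the fit includes one, 0 otherwise; the exponential spectrum ``alpha`` then
    carries tissue exchange only.
    """

    basis: SpectralBasis
    alpha: np.ndarray
    fitted_curve: TimeActivityCurve
    residual_norm: float
    vascular_cutoff: float
    v0: float = 0.0
    perfusion_sum: float = field(init=False)
    perfusion_tissue: float = field(init=False)
    vascular_weight: float = field(init=False)

    def __post_init__(self):
        alpha = np.asarray(self.alpha, dtype=float)
        object.__setattr__(self, "alpha", alpha)
        if alpha.shape != self.basis.rates.shape:
            raise GridMismatchError("alpha and basis rate grids differ")
        if np.any(alpha < 0):
            raise ParameterError("spectral weights must be non-negative")
        tissue = alpha[self.basis.rates < self.vascular_cutoff].sum()
        vasc = alpha[self.basis.rates >= self.vascular_cutoff].sum()
        object.__setattr__(self, "perfusion_tissue", float(tissue))
        object.__setattr__(self, "vascular_weight", float(vasc))
        object.__setattr__(self, "perfusion_sum", float(tissue + vasc))


@dataclass(frozen=True)
class NonlinearFitResult:
    params: OneTissueParams
    residual_norm: float
    converged: bool
    message: str
    n_evaluations: int
    fitted_curve: TimeActivityCurve


@dataclass(frozen=True)
class DelayEstimate:
    """Grid-search delay with its residual profile for QC.

    ``flatness`` is (max - min)/max of the residual profile; profiles flatter
    than ``flatness_threshold`` carry no delay information and are flagged.
    """

    delay: float
    grid: np.ndarray
    residuals: np.ndarray
    flatness: float
    low_confidence: bool


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _exp_convolve_grid(ca: np.ndarray, beta_per_min: float, dt: float) -> np.ndarray:
    """(Ca conv exp(-beta t)) on a uniform grid, integral in *minutes*.

    Recursive trapezoid: y[k] = e^{-b dt} y[k-1] + dt/2 (e^{-b dt} ca[k-1] + ca[k]),
    exact for piecewise-linear Ca up to trapezoid error, O(n).
    """
    b = beta_per_min / SEC_PER_MIN  # 1/s
    decay = np.exp(-b * dt)
    out = np.empty_like(ca)
    out[0] = 0.0
    w_prev = 0.5 * dt * decay
    w_curr = 0.5 * dt
    for k in range(1, ca.size):
        out[k] = decay * out[k - 1] + w_prev * ca[k - 1] + w_curr * ca[k]
    return out / SEC_PER_MIN


def convolve_exponential(input_fn: InputFunction, beta: float, eval_times) -> np.ndarray:
    """Evaluate (Ca conv exp(-beta t))(t) at ``eval_times`` (seconds).

    ``beta`` is per minute; the integral is taken with time in minutes, so the
    result has units kBq/mL * min.  For beta = 0 this is the running integral
    of Ca.  Fine-grid trapezoid quadrature at DEFAULT_DT resolution.
    """
    if beta < 0:
        raise ParameterError("beta must be non-negative")
    t = np.atleast_1d(np.asarray(eval_times, dtype=float))
    if np.any(t < 0) or np.any(t > input_fn.support_end + 1e-9):
        raise DomainError("eval_times outside the input-function support window")
    if t.size == 0:
        return np.zeros(0)
    t_end = float(t.max())
    n = max(int(np.ceil(t_end / DEFAULT_DT)), 1)
    grid = np.linspace(0.0, n * DEFAULT_DT, n + 1)
    conv = _exp_convolve_grid(input_fn(grid), beta, DEFAULT_DT)
    return np.interp(t, grid, conv)


def forward_model(params: OneTissueParams, input_fn: InputFunction,
                  schedule: FrameSchedule, dt: float = DEFAULT_DT) -> TimeActivityCurve:
    """Frame-averaged model curve M(t) = V0 Ca(t-delay) + K1 (Ca(.-delay) conv e^{-k2 t})."""
    if schedule.n_frames == 0:
        raise ParameterError("empty frame schedule")
    ca_fn = input_fn.shifted(params.delay)
    grid = schedule.fine_grid(dt)
    if grid[-1] > ca_fn.support_end + 1e-9:
        raise DomainError("schedule extends beyond input-function support")
    ca = ca_fn(grid)
    m = params.V0 * ca + params.K1 * _exp_convolve_grid(ca, params.k2, dt)
    return TimeActivityCurve(schedule, schedule.frame_average(grid, m))


def _design_matrix(input_fn: InputFunction, schedule: FrameSchedule,
                   basis: SpectralBasis) -> np.ndarray:
    grid = schedule.fine_grid(basis.dt)
    if grid[-1] > input_fn.support_end + 1e-9:
        raise DomainError("schedule extends beyond input-function support")
    ca = input_fn(grid)
    cols = []
    for beta in basis.rates:
        conv = _exp_convolve_grid(ca, beta, basis.dt)
        cols.append(schedule.frame_average(grid, conv))
    return np.column_stack(cols)


def spectral_fit(tac: TimeActivityCurve, input_fn: InputFunction,
                 basis: SpectralBasis | None = None,
                 vascular_cutoff: float = 2.0,
                 fit_blood_volume: bool = True) -> SpectralResult:
    """Non-negative spectral deconvolution of a tissue curve.

    Solves min ||A alpha - M||_2 with alpha >= 0, where column i of A is the
    frame-averaged convolution of the input with exp(-beta_i t).  With
    ``fit_blood_volume`` (default) the design additionally carries the input
    curve itself as an explicit blood-volume column whose weight estimates V0;
    without it the fast end of the spectrum must absorb the vascular signal.
    Weights at rates >= ``vascular_cutoff`` (1/min) are reported separately
    as the vascular-like part of the spectrum.
    """
    basis = basis or SpectralBasis.default()
    A = _design_matrix(input_fn, tac.schedule, basis)
    if fit_blood_volume:
        grid = tac.schedule.fine_grid(basis.dt)
        ca_col = tac.schedule.frame_average(grid, input_fn(grid))
        A = np.column_stack([A, ca_col])
    if not np.any(A):
        raise DegenerateInputError("design matrix is identically zero (no input signal)")
    coef, rnorm = optimize.nnls(A, tac.activity)
    alpha, v0 = (coef[:-1], float(coef[-1])) if fit_blood_volume else (coef, 0.0)
    fitted = TimeActivityCurve(tac.schedule, A @ coef, tac.decay_corrected)
    return SpectralResult(basis=basis, alpha=alpha, fitted_curve=fitted,
                          residual_norm=float(rnorm), vascular_cutoff=vascular_cutoff,
                          v0=v0)


def perfusion_from_spectrum(result: SpectralResult) -> dict:
    """Perfusion read-outs from a spectral fit (mL/g/min).

    ``perfusion`` follows the sum-of-all-weights convention (the default
    read-out); ``perfusion_tissue`` excludes the vascular-like fast rates and
    ``vascular_weight`` is their total.
    """
    return {
        "perfusion": result.perfusion_sum,
        "perfusion_tissue": result.perfusion_tissue,
        "vascular_weight": result.vascular_weight,
        "vascular_cutoff_per_min": result.vascular_cutoff,
        "blood_volume_fraction": result.v0,
    }


def nonlinear_fit(tac: TimeActivityCurve, input_fn: InputFunction,
                  init: OneTissueParams | None = None,
                  bounds: tuple = ((0.0, 0.0, 0.0), (10.0, 10.0, 1.0)),
                  dt: float = DEFAULT_DT,
                  weights="auto") -> NonlinearFitResult:
    """Weighted least-squares fit of (K1, k2, V0) to a TAC.

    Delay is taken from ``init`` and held fixed (estimate it first with
    :func:`estimate_delay`).  PET frame noise is heteroscedastic (variance ~
    activity / frame duration), so residuals are weighted by the inverse
    frame noise s.d. estimated from the measured activity, floored at 10 % of
    the peak to keep near-zero frames from dominating.  ``weights`` may be
    "auto" (default), None (unweighted), or an explicit per-frame array.
    """
    init = init or OneTissueParams(K1=0.5, k2=0.5, V0=0.05)
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    x0 = np.clip([init.K1, init.k2, init.V0], lo, hi)
    if isinstance(weights, str) and weights == "auto":
        floor = 0.1 * np.max(np.abs(tac.activity))
        w = np.sqrt(tac.schedule.frame_duration
                    / np.clip(tac.activity, floor, None)) if floor > 0 else \
            np.ones(tac.schedule.n_frames)
    elif weights is None:
        w = np.ones(tac.schedule.n_frames)
    else:
        w = np.asarray(weights, dtype=float)

    def residuals(x):
        p = OneTissueParams(K1=x[0], k2=x[1], V0=x[2], delay=init.delay)
        return (forward_model(p, input_fn, tac.schedule, dt).activity
                - tac.activity) * w

    sol = optimize.least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-12,
                                 ftol=1e-12, gtol=1e-12)
    params = OneTissueParams(K1=sol.x[0], k2=sol.x[1], V0=sol.x[2], delay=init.delay)
    fitted = forward_model(params, input_fn, tac.schedule, dt)
    return NonlinearFitResult(
        params=params,
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success),
        message=str(sol.message),
        n_evaluations=int(sol.nfev),
        fitted_curve=fitted,
    )


def estimate_delay(tac: TimeActivityCurve, input_fn: InputFunction,
                   search_grid=None, basis: SpectralBasis | None = None,
                   flatness_threshold: float = 0.1) -> DelayEstimate:
    """Grid-search the input/tissue transit delay by spectral-fit residual.

    The candidate delay is applied to the input function; the delay minimising
    the residual wins, ties going to the smallest |delay|.  A residual profile
    whose relative spread (max-min)/max falls below ``flatness_threshold``
    carries no delay information (pure noise) and is flagged low-confidence.
    """
    grid = np.arange(-10.0, 20.0 + 1e-9, 2.0) if search_grid is None else \
        np.asarray(search_grid, dtype=float)
    if grid.size == 0:
        raise ParameterError("empty delay search grid")
    basis = basis or SpectralBasis.default()
    residuals = np.empty(grid.size)
    for i, d in enumerate(grid):
        residuals[i] = spectral_fit(tac, input_fn.shifted(d), basis).residual_norm
    rmax = residuals.max()
    flatness = float((rmax - residuals.min()) / rmax) if rmax > 0 else 0.0
    order = sorted(range(grid.size),
                   key=lambda i: (residuals[i], abs(grid[i]), grid[i]))
    best = order[0]
    return DelayEstimate(delay=float(grid[best]), grid=grid, residuals=residuals,
                         flatness=flatness,
                         low_confidence=flatness < flatness_threshold)


def decay_correct(tac: TimeActivityCurve,
                  half_life: float = O15_HALF_LIFE_S) -> TimeActivityCurve:
    """Correct frame activities for physical decay to injection time.

    Each frame is scaled by exp(lambda * t_mid), lambda = ln 2 / half-life.
    """
    if tac.decay_corrected:
        raise ParameterError("curve is already decay-corrected")
    lam = np.log(2.0) / half_life
    return TimeActivityCurve(tac.schedule,
                             tac.activity * np.exp(lam * tac.schedule.frame_mid),
                             decay_corrected=True)


def decay_uncorrect(tac: TimeActivityCurve,
                    half_life: float = O15_HALF_LIFE_S) -> TimeActivityCurve:
    """Inverse of :func:`decay_correct` (re-applies physical decay)."""
    if not tac.decay_corrected:
        raise ParameterError("curve is not decay-corrected")
    lam = np.log(2.0) / half_life
    return TimeActivityCurve(tac.schedule,
                             tac.activity * np.exp(-lam * tac.schedule.frame_mid),
                             decay_corrected=False)


def percent_change(baseline: float, followup: float) -> float:
    """100 * (followup - baseline) / baseline; baseline must be positive."""
    if baseline <= 0:
        raise ParameterError("baseline must be positive")
    return 100.0 * (followup - baseline) / baseline
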