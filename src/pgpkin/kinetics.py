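"""Compartment-model forward operators and weighted least-squares fitting.

The brain kinetics of a P-gp substrate are described by standard serial
compartment models driven by the arterial parent-plasma input C_p(t), with
a fractional blood-volume term:

* one-tissue (1TC):   dC_T/dt = K1*C_p - k2*C_T
* two-tissue (2TC):   dC_1/dt = K1*C_p - (k2+k3)*C_1 + k4*C_2
                      dC_2/dt = k3*C_1 - k4*C_2,  C_T = C_1 + C_2
  (optionally with k4 fixed to 0, the irreversible-trapping variant)

and the measured concentration is C_model = (1-vB)*C_T + vB*C_wb, where
C_wb is whole-blood activity.  K1 is reported in mL/cc/min, k2..k4 in
1/min, vB is unitless in [0, 1].

The convolutions with exp(-alpha*t) are evaluated by the closed-form
solution for a piecewise-linear input (exact per segment, no quadrature
error), which makes tight oracle comparisons possible and handles the
non-uniform frame schedule without interpolation tricks.

Fitting follows the statsmodels convention: build a
:class:`CompartmentModel` from the data, call :meth:`~CompartmentModel.fit`,
and work with the returned :class:`KineticFitResults` (estimates, %COV,
AIC, residuals, ``summary()``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize, signal

from .curves import FrameSchedule, InputFunction, TimeActivityCurve, frame_average

__all__ = [
    "KineticParams",
    "FitOptions",
    "CompartmentModel",
    "KineticFitResults",
    "ModelSelection",
    "expconv",
    "model_1tc",
    "model_2tc",
    "fit_model",
    "fit_window",
    "k1k2_ratio",
    "akaike",
    "compare_models",
    "MODEL_IDS",
]

MODEL_IDS = ("1tc", "2tc", "2tc-k4=0")

_SEC_PER_MIN = 60.0


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of a compartment model, in reporting units.

    K1 in mL/cc/min; k2, k3, k4 in 1/min; vB unitless.  For a one-tissue
    model k3 and k4 are ``None``.
    """

    K1: float
    k2: float
    vB: float = 0.0
    k3: float | None = None
    k4: float | None = None

    def __post_init__(self):
        for name in ("K1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if not (0.0 <= self.vB <= 1.0):
            raise ValueError(f"vB must lie in [0, 1], got {self.vB}")

    @property
    def is_two_tissue(self) -> bool:
        return self.k3 is not None

    @property
    def k1_k2(self) -> float:
        """Equilibrium distribution ratio K1/k2 (mL/cc)."""
        if self.k2 <= 0:
            raise ZeroDivisionError("K1/k2 undefined for k2 = 0")
        return self.K1 / self.k2


def expconv(alpha_per_s: float, times_s: np.ndarray, f: np.ndarray) -> np.ndarray:
    """y(t) = ∫_0^t exp(-alpha*(t-s)) f(s) ds for piecewise-linear f.

    Exact per linear segment.  ``times_s`` may be non-uniform; the uniform
    case is dispatched to a constant-coefficient linear recurrence
    (scipy.signal.lfilter) for speed.
    """
    t = np.asarray(times_s, dtype=float)
    f = np.asarray(f, dtype=float)
    if alpha_per_s < 0:
        raise ValueError("alpha must be non-negative")
    h = np.diff(t)
    if np.any(h <= 0):
        raise ValueError("times must be strictly ascending")

    if alpha_per_s == 0.0:
        seg = 0.5 * (f[1:] + f[:-1]) * h
        return np.concatenate([[0.0], np.cumsum(seg)])

    uniform = np.allclose(h, h[0], rtol=1e-10, atol=0.0)
    a = f[:-1]
    b = (f[1:] - f[:-1]) / h

    def moments(alpha: float, step):
        """(E, I0, I1) with I0 = ∫ e^{-a(h-u)}du, I1 = ∫ u e^{-a(h-u)}du."""
        x = alpha * step
        E = np.exp(-x)
        I0 = -np.expm1(-x) / alpha
        # (h - I0)/alpha cancels badly for small x; switch to the series.
        small = x < 1e-4
        series = step * step * (0.5 - x / 6.0 + x * x / 24.0)
        I1 = np.where(small, series, (step - I0) / alpha)
        return E, I0, I1

    if uniform:
        E, I0, I1 = moments(alpha_per_s, h[0])
        c = np.concatenate([[0.0], a * I0 + b * I1])
        return signal.lfilter([1.0], [1.0, -float(E)], c)

    E, I0, I1 = moments(alpha_per_s, h)
    y = np.zeros_like(f)
    for i in range(h.size):
        y[i + 1] = y[i] * E[i] + a[i] * I0[i] + b[i] * I1[i]
    return y


def _as_grid(input_fn, wb, schedule: FrameSchedule | None):
    """Normalise (input, whole-blood) to a shared fine grid."""
    if isinstance(input_fn, InputFunction):
        t, cp = input_fn.times_s, input_fn.values
    else:
        t, cp = (np.asarray(x, dtype=float) for x in input_fn)
    if wb is None:
        cwb = np.zeros_like(cp)
    elif isinstance(wb, InputFunction):
        cwb = wb(t)
    else:
        cwb = np.asarray(wb, dtype=float)
        if cwb.shape != t.shape:
            raise ValueError("whole-blood curve must match the input-function grid")
    return t, cp, cwb


def _tissue_fine(kp: KineticParams, t: np.ndarray, cp: np.ndarray) -> np.ndarray:
    """Total tissue concentration C_T(t) on the fine grid (no blood term)."""
    K1 = kp.K1 / _SEC_PER_MIN
    k2 = kp.k2 / _SEC_PER_MIN
    if not kp.is_two_tissue or kp.k3 == 0.0:
        # with k3 = 0 the second compartment never fills: exact 1TC reduction
        return K1 * expconv(k2, t, cp)
    k3 = kp.k3 / _SEC_PER_MIN
    k4 = (kp.k4 or 0.0) / _SEC_PER_MIN
    s = k2 + k3 + k4
    disc = np.sqrt(max(s * s - 4.0 * k2 * k4, 0.0))
    a1 = 0.5 * (s - disc)
    a2 = 0.5 * (s + disc)
    if a2 - a1 < 1e-12 * max(s, 1e-30):  # repeated eigenvalue: split numerically
        a2 = a1 + max(1e-14, 1e-9 * s)
    b1 = (k3 + k4 - a1) / (a2 - a1)
    b2 = (a2 - k3 - k4) / (a2 - a1)
    return K1 * (b1 * expconv(a1, t, cp) + b2 * expconv(a2, t, cp))


def _model_fine(kp: KineticParams, t, cp, cwb) -> np.ndarray:
    return (1.0 - kp.vB) * _tissue_fine(kp, t, cp) + kp.vB * cwb


def model_1tc(
    kp: KineticParams,
    input_fn,
    wb=None,
    schedule: FrameSchedule | None = None,
) -> TimeActivityCurve | np.ndarray:
    """Forward one-tissue model.

    With a ``schedule`` the prediction is frame-averaged into a
    :class:`TimeActivityCurve`; without one the fine-grid curve is returned.
    """
    if kp.is_two_tissue:
        raise ValueError("model_1tc requires one-tissue parameters (k3/k4 absent)")
    t, cp, cwb = _as_grid(input_fn, wb, schedule)
    fine = _model_fine(kp, t, cp, cwb)
    if schedule is None:
        return fine
    return TimeActivityCurve(schedule, frame_average(t, fine, schedule), source="derived")


def model_2tc(
    kp: KineticParams,
    input_fn,
    wb=None,
    schedule: FrameSchedule | None = None,
    k4_fixed_zero: bool = False,
) -> TimeActivityCurve | np.ndarray:
    """Forward two-tissue model (serial compartments, bi-exponential kernel)."""
    if not kp.is_two_tissue:
        raise ValueError("model_2tc requires k3 (and k4 unless k4_fixed_zero)")
    if k4_fixed_zero and kp.k4 not in (None, 0.0):
        raise ValueError("k4_fixed_zero requested but k4 is nonzero")
    kp = replace(kp, k4=0.0 if k4_fixed_zero or kp.k4 is None else kp.k4)
    t, cp, cwb = _as_grid(input_fn, wb, schedule)
    fine = _model_fine(kp, t, cp, cwb)
    if schedule is None:
        return fine
    return TimeActivityCurve(schedule, frame_average(t, fine, schedule), source="derived")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_DEFAULT_INIT = {"K1": 0.1, "k2": 0.1, "k3": 0.01, "k4": 0.01, "vB": 0.05}
_RATE_BOUNDS = (0.0, 10.0)  # per minute
_VB_BOUNDS = (0.0, 1.0)


@dataclass(frozen=True)
class FitOptions:
    """Options controlling the weighted least-squares fit.

    weighting : "frame-duration" (w_i ∝ Δt_i, the default) or "uniform"
    bounds : optional per-parameter (lo, hi) overrides in reporting units
    multistart : number of optimizer starts; the first uses the nominal
        initial values, the rest perturb them by ±50% log-uniform factors
        drawn from ``seed``
    """

    weighting: str = "frame-duration"
    bounds: dict[str, tuple[float, float]] | None = None
    init: dict[str, float] | None = None
    multistart: int = 5
    seed: int = 0
    max_nfev: int = 1000
    tol: float = 1e-12

    def __post_init__(self):
        if self.weighting not in ("frame-duration", "uniform"):
            raise ValueError("weighting must be 'frame-duration' or 'uniform'")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")
        init = {**_DEFAULT_INIT, **(self.init or {})}
        for name, (lo, hi) in (self.bounds or {}).items():
            if not (lo <= init[name] <= hi):
                raise ValueError(f"bounds for {name} do not contain its initial value")


def _param_names(model_id: str) -> list[str]:
    if model_id == "1tc":
        return ["K1", "k2", "vB"]
    if model_id == "2tc":
        return ["K1", "k2", "k3", "k4", "vB"]
    if model_id == "2tc-k4=0":
        return ["K1", "k2", "k3", "vB"]
    raise ValueError(f"unknown model id {model_id!r}; expected one of {MODEL_IDS}")


def _vector_to_params(model_id: str, x: np.ndarray) -> KineticParams:
    names = _param_names(model_id)
    d = dict(zip(names, x))
    if model_id == "1tc":
        return KineticParams(K1=d["K1"], k2=d["k2"], vB=d["vB"])
    k4 = d.get("k4", 0.0)
    return KineticParams(K1=d["K1"], k2=d["k2"], k3=d["k3"], k4=k4, vB=d["vB"])


class CompartmentModel:
    """Compartment-model fit of a tissue time-activity curve.

    Parameters
    ----------
    tac : TimeActivityCurve
        Frame-averaged tissue (brain) curve to fit.
    input_function : InputFunction or (times_s, values)
        Metabolite- and plasma-corrected parent input C_p on a fine grid.
    whole_blood : InputFunction, ndarray on the input grid, or None
        Whole-blood activity for the vascular term; ``None`` means no
        vascular signal (the vB term multiplies zero).
    model : {"1tc", "2tc", "2tc-k4=0"}
    t_max_s : float, optional
        Restrict the fit to frames ending at or before this time.
    """

    def __init__(
        self,
        tac: TimeActivityCurve,
        input_function,
        whole_blood=None,
        model: str = "1tc",
        t_max_s: float | None = None,
        options: FitOptions | None = None,
    ):
        self.model_id = model
        self.param_names = _param_names(model)
        self.options = options or FitOptions()
        self.t_max_s = t_max_s
        full = tac if t_max_s is None else tac.restrict(t_max_s)
        if len(full) < 5:
            raise ValueError(f"need at least 5 frames in the fit window, have {len(full)}")
        self.tac = full
        self.times_s, self.cp, self.cwb = _as_grid(input_function, whole_blood, None)
        if self.times_s[-1] < self.tac.schedule.end_s[-1] - 1e-9:
            raise ValueError("input function does not span the fit window")
        dur = self.tac.durations_s
        if self.options.weighting == "frame-duration":
            w = dur / dur.mean()
        else:
            w = np.ones_like(dur)
        self._sqrt_w = np.sqrt(w)

    # -- forward prediction ------------------------------------------------
    def predict(self, params: KineticParams | Sequence[float]) -> np.ndarray:
        if not isinstance(params, KineticParams):
            params = _vector_to_params(self.model_id, np.asarray(params, dtype=float))
        fine = _model_fine(params, self.times_s, self.cp, self.cwb)
        return frame_average(self.times_s, fine, self.tac.schedule)

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        return self._sqrt_w * (self.predict(x) - self.tac.values)

    def _setup(self):
        opts = self.options
        init_map = {**_DEFAULT_INIT, **(opts.init or {})}
        bounds_map = dict(opts.bounds or {})
        x0, lo, hi = [], [], []
        for name in self.param_names:
            default = _VB_BOUNDS if name == "vB" else _RATE_BOUNDS
            b = bounds_map.get(name, default)
            x0.append(init_map[name])
            lo.append(b[0])
            hi.append(b[1])
        return np.array(x0), np.array(lo), np.array(hi)

    def fit(self) -> "KineticFitResults":
        """Run the multistart bounded least-squares fit."""
        opts = self.options
        x0, lo, hi = self._setup()
        rng = np.random.default_rng(opts.seed)
        starts = [x0]
        for _ in range(opts.multistart - 1):
            factors = np.exp(rng.uniform(np.log(0.5), np.log(1.5), size=x0.size))
            starts.append(np.clip(x0 * factors, lo, hi))

        best = None
        any_success = False
        for start in starts:
            try:
                sol = optimize.least_squares(
                    self._residuals,
                    np.clip(start, lo, hi),
                    bounds=(lo, hi),
                    method="trf",
                    x_scale=np.maximum(x0, 1e-3),
                    ftol=opts.tol,
                    xtol=opts.tol,
                    gtol=opts.tol,
                    max_nfev=opts.max_nfev,
                )
            except Exception:  # a pathological start must not kill the fit
                continue
            any_success = any_success or bool(sol.success)
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("all optimizer starts failed")
        if not any_success:
            warnings.warn(
                "compartment fit did not converge from any start; "
                "reporting the best attempt",
                RuntimeWarning,
                stacklevel=2,
            )
        return KineticFitResults(self, best, converged=any_success)


class KineticFitResults:
    """Estimates and diagnostics of a :class:`CompartmentModel` fit.

    Attributes
    ----------
    params : KineticParams       estimates in reporting units
    bse : dict                   standard error per parameter
    pcov_percent : dict          %COV = 100*SE/|estimate| per parameter
    rss : float                  weighted residual sum of squares
    aic : float                  n*ln(RSS/n) + 2p
    fittedvalues : TimeActivityCurve over the fit window
    """

    def __init__(self, model: CompartmentModel, solution, converged: bool):
        self.model = model
        self.model_id = model.model_id
        self.converged = converged
        self.x = np.asarray(solution.x, dtype=float)
        self.params = _vector_to_params(model.model_id, self.x)
        self.nobs = len(model.tac)
        self.n_params = self.x.size
        pred = model.predict(self.x)
        self.fittedvalues = model.tac.with_values(pred)
        self.resid = model.tac.values - pred
        wres = model._sqrt_w * self.resid
        self.rss = float(wres @ wres)
        self.aic = akaike(self.rss, self.nobs, self.n_params)
        self.window_s = (
            float(model.tac.schedule.start_s[0]),
            float(model.tac.schedule.end_s[-1]),
        )
        self._covariance(solution)

    def _covariance(self, solution) -> None:
        dof = max(self.nobs - self.n_params, 1)
        s2 = self.rss / dof
        J = solution.jac
        JTJ = J.T @ J
        try:
            cov = np.linalg.inv(JTJ) * s2
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(JTJ) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        self.cov_params = cov
        self.bse = dict(zip(self.model.param_names, se))
        self.pcov_percent = {
            name: (100.0 * s / abs(est) if est != 0 else np.inf)
            for name, s, est in zip(self.model.param_names, se, self.x)
        }

    @property
    def k1_k2(self) -> float:
        return k1k2_ratio(self)

    @property
    def max_pcov_percent(self) -> float:
        return max(self.pcov_percent.values())

    def to_dict(self) -> dict:
        return {
            "model": self.model_id,
            "params": {n: float(v) for n, v in zip(self.model.param_names, self.x)},
            "se": {n: float(v) for n, v in self.bse.items()},
            "pcov_percent": {n: float(v) for n, v in self.pcov_percent.items()},
            "rss": self.rss,
            "aic": self.aic,
            "nobs": self.nobs,
            "window_s": list(self.window_s),
            "converged": self.converged,
            "weighting": self.model.options.weighting,
            "seed": self.model.options.seed,
        }

    def plot(self, ax=None):
        """Plot the observed frames against the fitted model curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mid = self.model.tac.midpoints_s / 60.0
        ax.plot(mid, self.model.tac.values, "o", ms=4, label="observed", color="0.3")
        ax.plot(mid, self.fittedvalues.values, "-", label=f"{self.model_id} fit")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("concentration (kBq/cc)")
        ax.legend(frameon=False)
        return ax

    def summary(self) -> str:
        units = {"K1": "mL/cc/min", "k2": "1/min", "k3": "1/min", "k4": "1/min", "vB": ""}
        lines = [
            f"Compartment model fit [{self.model_id}]",
            f"  frames: {self.nobs}   window: {self.window_s[0]:.0f}-{self.window_s[1]:.0f} s"
            f"   weighting: {self.model.options.weighting}",
            f"  RSS (weighted): {self.rss:.6g}   AIC: {self.aic:.3f}"
            f"   converged: {self.converged}",
            f"  {'param':<6}{'estimate':>12}{'SE':>12}{'%COV':>10}  unit",
        ]
        for name in self.model.param_names:
            est = dict(zip(self.model.param_names, self.x))[name]
            lines.append(
                f"  {name:<6}{est:>12.5f}{self.bse[name]:>12.5f}"
                f"{self.pcov_percent[name]:>10.1f}  {units[name]}"
            )
        if self.params.k2 > 0:
            lines.append(f"  K1/k2: {self.k1_k2:.3f} mL/cc")
        return "\n".join(lines)


def fit_model(
    tac: TimeActivityCurve,
    input_fn,
    wb=None,
    model: str = "1tc",
    options: FitOptions | None = None,
) -> KineticFitResults:
    """Functional wrapper: build a :class:`CompartmentModel` and fit it."""
    return CompartmentModel(tac, input_fn, wb, model=model, options=options).fit()


def fit_window(
    tac: TimeActivityCurve,
    input_fn,
    wb=None,
    model: str = "1tc",
    options: FitOptions | None = None,
    t_max_s: float = 120.0,
) -> KineticFitResults:
    """Fit using only frames that end at or before ``t_max_s``."""
    return CompartmentModel(
        tac, input_fn, wb, model=model, t_max_s=t_max_s, options=options
    ).fit()


def k1k2_ratio(fit) -> float:
    """K1/k2 distribution ratio (mL/cc) from a fit result or parameter set."""
    params = fit.params if hasattr(fit, "params") else fit
    return params.k1_k2


def akaike(rss: float, n_obs: int, n_params: int) -> float:
    """AIC = n*ln(RSS/n) + 2p for least-squares fits.

    A numerically zero RSS is floored at the smallest positive float so a
    machine-perfect noiseless fit still yields a finite (very negative) AIC.
    """
    if rss < 0:
        raise ValueError("RSS must be non-negative")
    rss = max(rss, np.finfo(float).tiny)
    return float(n_obs * np.log(rss / n_obs) + 2 * n_params)


@dataclass(frozen=True)
class ModelSelection:
    """Outcome of AIC-plus-identifiability model comparison."""

    selected: KineticFitResults
    ranked: tuple[KineticFitResults, ...]
    flagged: tuple[str, ...]  # model ids with poor parameter identifiability
    cov_threshold_percent: float
    delta_aic: float

    def summary(self) -> str:
        lines = [f"Model comparison (selected: {self.selected.model_id})"]
        for fit in self.ranked:
            flag = "  [poorly identified]" if fit.model_id in self.flagged else ""
            lines.append(
                f"  {fit.model_id:<10} AIC={fit.aic:9.3f}  p={fit.n_params}"
                f"  max%COV={fit.max_pcov_percent:8.1f}{flag}"
            )
        return "\n".join(lines)


def compare_models(
    fits: Sequence[KineticFitResults],
    cov_threshold_percent: float = 50.0,
    delta_aic: float = 2.0,
) -> ModelSelection:
    """Rank fits by AIC, flag poorly identified ones, select the simplest.

    Among models whose AIC is within ``delta_aic`` of the best, the one
    with the fewest parameters wins (ties broken by lower AIC), mirroring
    the parsimony argument for preferring 1TC when 2TC does not fit
    significantly better.
    """
    if not fits:
        raise ValueError("compare_models needs at least one fit")
    windows = {f.window_s for f in fits}
    if len(windows) > 1:
        raise ValueError("fits must share the same data window")
    ranked = tuple(sorted(fits, key=lambda f: f.aic))
    flagged = tuple(
        f.model_id for f in ranked if f.max_pcov_percent > cov_threshold_percent
    )
    best_aic = ranked[0].aic
    contenders = [f for f in ranked if f.aic - best_aic <= delta_aic]
    selected = min(contenders, key=lambda f: (f.n_params, f.aic))
    return ModelSelection(
        selected=selected,
        ranked=ranked,
        flagged=flagged,
        cov_threshold_percent=cov_threshold_percent,
        delta_aic=delta_aic,
    )
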