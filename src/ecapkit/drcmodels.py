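"""Dose-response modelling and biomarker statistics.

Trend models for dose-response curves (DRCs) come in two flavours:

* parametric least-squares fits — sigmoid, softplus, two-exponential and
  step-sigmoid (a sigmoid below a split point plus a second sigmoid fitted
  to the residuals above it);
* Gaussian-process regression with squared-exponential or Matern kernels,
  hyperparameters estimated by maximising the marginal likelihood under
  Gamma priors (MAP-II), with the model's *effective degrees of freedom*
  taken as the trace of the smoother matrix ``K (K + σ²I)⁻¹``.

Model comparison uses the approximate F-test on residual sums of squares
with parameter counts (parametric) or effective df (GP).

Biomarker statistics: the neural threshold is the current at which the
linearly interpolated DRC reaches 15% of the maximal activation (with a
nominal 3 mA threshold when never reached), the saturation threshold the
current reaching 85%; the DRC *alignment criterion* flags a plausible
mechanistic link between a fiber and a physiological effect when their
onset and saturation currents agree within tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy import optimize, stats
from scipy.spatial.distance import cdist

from .ecaps import DoseResponseCurve
from .errors import NumericalError, ValidationError

NOMINAL_THRESHOLD_MA = 3.0
ONSET_FRACTION = 0.15
SATURATION_FRACTION = 0.85


# ---------------------------------------------------------------------------
# Parametric regression functions
# ---------------------------------------------------------------------------

def _sigmoid(x, a0, a1, b):
    return a0 / (1.0 + np.exp(-(x - a1) / b))


def _softplus(x, a0, a1, a3, b):
    return a0 + a1 * np.logaddexp(0.0, (x - a3) / b)


def _two_exponential(x, a0, a1, a2, b1, b2):
    return a0 + a1 * np.exp(-x / b1) + a2 * np.exp(-x / b2)


_MODEL_PARAMS = {
    "sigmoid": ("a0", "a1", "b"),
    "softplus": ("a0", "a1", "a3", "b"),
    "two_exponential": ("a0", "a1", "a2", "b1", "b2"),
}


@dataclass
class ParametricFit:
    """A least-squares parametric DRC fit."""

    model: str
    params: dict[str, float]
    rss: float
    n: int
    df_model: int
    predict: Callable[[np.ndarray], np.ndarray]
    degenerate: bool = False  # slope-free: no better than a constant fit

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValidationError("rss must be >= 0")
        if self.n <= self.df_model:
            raise ValidationError(
                f"n = {self.n} must exceed the {self.df_model} free "
                "parameters")


def _starts_and_bounds(model: str, x: np.ndarray, y: np.ndarray,
                       n_starts: int,
                       rng: np.random.Generator) -> tuple[list, tuple]:
    xr = np.ptp(x) or 1.0
    yr = np.ptp(y) or max(abs(float(np.mean(y))), 1.0)
    ymax = float(np.max(np.abs(y))) or 1.0
    if model == "sigmoid":
        lo = [-4 * ymax, x.min() - xr, 1e-3 * xr]
        hi = [4 * ymax, x.max() + xr, 2 * xr]
    elif model == "softplus":
        lo = [-4 * ymax, -4 * ymax, x.min() - xr, 1e-3 * xr]
        hi = [4 * ymax, 4 * ymax, x.max() + xr, 2 * xr]
    elif model == "two_exponential":
        lo = [-4 * ymax, -4 * ymax, -4 * ymax, 1e-2 * xr, 1e-2 * xr]
        hi = [4 * ymax, 4 * ymax, 4 * ymax, 10 * xr, 10 * xr]
    else:
        raise ValidationError(f"unknown model {model!r}")
    lo, hi = np.array(lo), np.array(hi)
    starts = [lo + rng.random(lo.size) * (hi - lo) for _ in range(n_starts)]
    # one deterministic, data-driven start
    if model == "sigmoid":
        starts[0] = np.array([y[-1] if y[-1] else yr, float(np.median(x)),
                              xr / 5])
    elif model == "softplus":
        starts[0] = np.array([float(y[0]), yr / max(xr, 1e-9),
                              float(np.median(x)), xr / 5])
    else:
        starts[0] = np.array([float(np.mean(y)), yr / 2, -yr / 2,
                              xr / 3, 2 * xr])
    starts[0] = np.clip(starts[0], lo + 1e-12, hi - 1e-12)
    return starts, (lo, hi)


def _fit_single_family(x: np.ndarray, y: np.ndarray, model: str,
                       n_starts: int, seed: int) -> ParametricFit:
    func = {"sigmoid": _sigmoid, "softplus": _softplus,
            "two_exponential": _two_exponential}[model]
    names = _MODEL_PARAMS[model]
    rng = np.random.default_rng(seed)
    starts, (lo, hi) = _starts_and_bounds(model, x, y, n_starts, rng)

    best = None
    for p0 in starts:
        try:
            res = optimize.least_squares(
                lambda p: func(x, *p) - y, p0, bounds=(lo, hi),
                method="trf", max_nfev=2000)
        except (ValueError, np.linalg.LinAlgError):
            continue
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        raise NumericalError(f"{model} fit failed to converge from any start")
    rss, p = best
    params = dict(zip(names, (float(v) for v in p)))
    const_rss = float(np.sum((y - np.mean(y)) ** 2))
    degenerate = rss >= const_rss * (1 - 1e-9)
    return ParametricFit(model=model, params=params, rss=rss, n=x.size,
                         df_model=len(names),
                         predict=lambda xx, _p=tuple(p): func(
                             np.asarray(xx, dtype=float), *_p),
                         degenerate=degenerate)


def fit_parametric(x: np.ndarray, y: np.ndarray, model: str,
                   n_starts: int = 16, seed: int = 0,
                   split: float | None = None) -> ParametricFit:
    """Least-squares fit of one regression family with multi-start.

    ``model`` is one of ``sigmoid``, ``softplus``, ``two_exponential`` or
    ``step_sigmoid``. Starts are drawn from data-driven ranges with a fixed
    per-call seed, so fits are reproducible. For ``step_sigmoid`` the split
    point ``c`` is scanned over interior data points unless supplied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y length mismatch")
    if model in _MODEL_PARAMS:
        if x.size < len(_MODEL_PARAMS[model]) + 1:
            raise ValidationError(
                f"{model} needs >= {len(_MODEL_PARAMS[model]) + 1} points")
        return _fit_single_family(x, y, model, n_starts, seed)
    if model != "step_sigmoid":
        raise ValidationError(f"unknown model {model!r}")
    return _fit_step_sigmoid(x, y, n_starts, seed, split)


def _fit_step_sigmoid(x: np.ndarray, y: np.ndarray, n_starts: int,
                      seed: int, split: float | None) -> ParametricFit:
    if x.size < 8:
        raise ValidationError("step_sigmoid needs >= 8 points")
    candidates = [split] if split is not None else \
        sorted(set(np.asarray(x)[2:-2]))
    best = None
    for c in candidates:
        low = x < c
        if low.sum() < 4 or (~low).sum() < 4:
            continue
        try:
            first = _fit_single_family(x[low], y[low], "sigmoid",
                                       n_starts, seed)
            resid = y - first.predict(x)
            second = _fit_single_family(x[~low], resid[~low], "sigmoid",
                                        n_starts, seed + 1)
        except (NumericalError, ValidationError):
            continue

        def predict(xx, f=first, s=second):
            return f.predict(xx) + s.predict(xx)

        rss = float(np.sum((y - predict(x)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, c, first, second, predict)
    if best is None:
        raise NumericalError("step_sigmoid found no admissible split point")
    rss, c, first, second, predict = best
    params = {f"first_{k}": v for k, v in first.params.items()}
    params.update({f"second_{k}": v for k, v in second.params.items()})
    params["c"] = float(c)
    return ParametricFit(model="step_sigmoid", params=params, rss=rss,
                         n=x.size, df_model=7, predict=predict)


# ---------------------------------------------------------------------------
# Gaussian-process regression with Gamma MAP-II hyperpriors
# ---------------------------------------------------------------------------

def _kernel_matrix(kind: str, r: np.ndarray, lengthscale: float,
                   signal_var: float) -> np.ndarray:
    z = r / lengthscale
    if kind == "squared_exponential":
        return signal_var * np.exp(-0.5 * z ** 2)
    if kind == "matern":  # Matern 5/2
        s = np.sqrt(5.0) * z
        return signal_var * (1.0 + s + s ** 2 / 3.0) * np.exp(-s)
    raise ValidationError(f"unknown kernel {kind!r}")


@dataclass
class GPFit:
    """A fitted Gaussian-process regression.

    Hyperparameters are on the standardised (zero-mean, unit-variance)
    scale used internally; ``edf`` is the trace of the smoother matrix
    ``K (K + σ²I)⁻¹`` computed from the noise-free kernel at the training
    inputs.
    """

    kernel: str
    lengthscale: float
    signal_var: float
    noise_var: float
    edf: float
    rss: float
    n: int
    _x_mean: np.ndarray = field(repr=False, default=None)
    _x_scale: np.ndarray = field(repr=False, default=None)
    _y_mean: float = field(repr=False, default=0.0)
    _y_scale: float = field(repr=False, default=1.0)
    _xs: np.ndarray = field(repr=False, default=None)
    _alpha: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.noise_var <= 0:
            raise ValidationError("noise variance must be > 0")
        if not (0 < self.edf <= self.n + 1e-9):
            raise ValidationError(f"edf {self.edf} outside (0, n]")

    @property
    def df_model(self) -> float:
        return self.edf

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self._xs.shape[1]:
            x = x.T
        xs = (x - self._x_mean) / self._x_scale
        r = cdist(xs, self._xs)
        k = _kernel_matrix(self.kernel, r, self.lengthscale, self.signal_var)
        return self._y_mean + self._y_scale * (k @ self._alpha)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.predict(x)


def _gamma_logpdf(v: float, shape: float, rate: float) -> float:
    return float(stats.gamma.logpdf(v, a=shape, scale=1.0 / rate))


def fit_gp(x: np.ndarray, y: np.ndarray,
           kernel: str = "squared_exponential",
           prior_shape: float = 2.0, prior_rate: float = 1.0,
           noise_floor: float = 1e-8) -> GPFit:
    """MAP-II Gaussian-process regression on 1-D or 2-D inputs.

    The marginal likelihood is maximised jointly over length-scale, signal
    variance and noise variance with Gamma(shape, rate) priors on the
    length-scale and signal amplitude (a weak Gamma prior keeps the noise
    positive). Inputs and outputs are standardised internally. The returned
    fit exposes the posterior mean as a callable and the effective degrees
    of freedom of the smoother.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValidationError("GP regression needs >= 3 points")
    x_mean, x_scale = x.mean(axis=0), x.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    y_mean, y_scale = float(np.mean(y)), float(np.std(y)) or 1.0
    xs = (x - x_mean) / x_scale
    ys = (y - y_mean) / y_scale
    r = cdist(xs, xs)

    def objective(theta: np.ndarray) -> float:
        ell, sf2, sn2 = np.exp(theta)
        K = _kernel_matrix(kernel, r, ell, sf2)
        Ky = K + (sn2 + noise_floor) * np.eye(n)
        try:
            L = np.linalg.cholesky(Ky)
        except np.linalg.LinAlgError:
            return 1e12
        alpha = np.linalg.solve(L.T, np.linalg.solve(L, ys))
        nlml = 0.5 * ys @ alpha + np.sum(np.log(np.diag(L))) \
            + 0.5 * n * np.log(2 * np.pi)
        logprior = _gamma_logpdf(ell, prior_shape, prior_rate) \
            + _gamma_logpdf(np.sqrt(sf2), prior_shape, prior_rate) \
            + _gamma_logpdf(np.sqrt(sn2), 1.1, 1.0)
        return float(nlml - logprior)

    best = None
    for theta0 in ([0.0, 0.0, -2.0], [-1.0, 0.0, -4.0], [1.0, 0.0, -1.0],
                   [0.5, -1.0, -8.0]):
        res = optimize.minimize(objective, np.array(theta0),
                                method="Nelder-Mead",
                                options={"maxiter": 800, "xatol": 1e-5,
                                         "fatol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    ell, sf2, sn2 = np.exp(best.x)
    sn2 = sn2 + noise_floor

    K = _kernel_matrix(kernel, r, ell, sf2)
    Ky = K + sn2 * np.eye(n)
    try:
        L = np.linalg.cholesky(Ky)
    except np.linalg.LinAlgError:
        Ky = Ky + 1e-6 * np.eye(n)
        try:
            L = np.linalg.cholesky(Ky)
        except np.linalg.LinAlgError as exc:
            raise NumericalError("kernel matrix is singular even after "
                                 "jitter") from exc
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, ys))
    eigvals = np.clip(np.linalg.eigvalsh(K), 0.0, None)
    edf = float(np.sum(eigvals / (eigvals + sn2)))
    fitted = y_mean + y_scale * (K @ alpha)
    rss = float(np.sum((y - fitted) ** 2))
    return GPFit(kernel=kernel, lengthscale=float(ell),
                 signal_var=float(sf2), noise_var=float(sn2),
                 edf=min(edf, float(n)) if edf > 0 else noise_floor,
                 rss=rss, n=n, _x_mean=x_mean, _x_scale=x_scale,
                 _y_mean=y_mean, _y_scale=y_scale, _xs=xs, _alpha=alpha)


def smoother_edf(K: np.ndarray, noise_var: float) -> float:
    """Effective degrees of freedom: trace of ``K (K + σ²I)⁻¹``."""
    n = K.shape[0]
    return float(np.trace(K @ np.linalg.inv(K + noise_var * np.eye(n))))


# ---------------------------------------------------------------------------
# Approximate F-test
# ---------------------------------------------------------------------------

def approx_f_test(fit_small, fit_large) -> tuple[float, float]:
    """Approximate F-test between a smaller and a larger (nested) fit.

    ``F = ((rss_s − rss_l) / (df_l − df_s)) / (rss_l / (n − df_l))`` with
    the p-value from the F(df_l − df_s, n − df_l) distribution. Works for
    parametric fits (df = parameter count) and GP fits (df = effective
    degrees of freedom). A larger model fitting worse than the smaller one
    yields a negative F with a warning (model mis-nesting).
    """
    rss_s, rss_l = fit_small.rss, fit_large.rss
    df_s, df_l = float(fit_small.df_model), float(fit_large.df_model)
    n = fit_large.n
    if fit_small.n != n:
        raise ValidationError("fits must be computed on the same data")
    if df_l <= df_s:
        raise ValidationError("the larger model must have more df")
    df_num = df_l - df_s
    df_den = n - df_l
    if df_den <= 0:
        raise ValidationError("no residual degrees of freedom")
    if rss_l == 0 and rss_s == 0:
        return 0.0, 1.0
    if rss_l == 0:
        return float("inf"), 0.0
    f_value = ((rss_s - rss_l) / df_num) / (rss_l / df_den)
    if f_value < 0:
        warnings.warn(
            "larger model fits worse than the smaller one (F < 0); "
            "check model nesting", stacklevel=2)
        return float(f_value), 1.0
    p = float(stats.f.sf(f_value, df_num, df_den))
    return float(f_value), p


# ---------------------------------------------------------------------------
# Thresholds, outlier filtering, alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Thresholds:
    """Onset (neural threshold) and saturation currents of one DRC."""

    onset_current: float  # mA
    saturation_current: float  # mA; nan when never reached
    nominal: bool = False  # onset never reached: nominal 3 mA assigned
    left_censored: bool = False  # DRC starts above the onset fraction

    def __post_init__(self) -> None:
        if self.nominal and self.onset_current != NOMINAL_THRESHOLD_MA:
            raise ValidationError(
                f"nominal thresholds carry the {NOMINAL_THRESHOLD_MA} mA "
                "convention")
        if not self.nominal and np.isfinite(self.saturation_current):
            if self.onset_current > self.saturation_current + 1e-12:
                raise ValidationError("onset must not exceed saturation")


def _first_crossing(currents: np.ndarray, values: np.ndarray,
                    level: float) -> float | None:
    """Smallest current where the linear interpolant crosses level upward."""
    for i in range(len(currents) - 1):
        v0, v1 = values[i], values[i + 1]
        if v0 < level <= v1:
            frac = (level - v0) / (v1 - v0)
            return float(currents[i] + frac * (currents[i + 1] - currents[i]))
    return None


def neural_threshold(drc: DoseResponseCurve | np.ndarray,
                     activations: np.ndarray | None = None,
                     norm_ref: float | None = None,
                     onset_frac: float = ONSET_FRACTION,
                     saturation_frac: float = SATURATION_FRACTION,
                     ) -> Thresholds:
    """Neural threshold and saturation current of a dose-response curve.

    The onset is the smallest current at which the piecewise-linear
    interpolant of the normalised DRC crosses ``onset_frac`` (15%) upward;
    a DRC that never reaches it over the tested range gets the nominal
    3 mA threshold. A DRC already above the onset fraction at its first
    tested current is left-censored (onset = first current). Saturation is
    the first current reaching ``saturation_frac`` (85%).
    """
    if isinstance(drc, DoseResponseCurve):
        currents = drc.currents
        values = drc.activations / drc.norm_ref
    else:
        currents = np.asarray(drc, dtype=float)
        values = np.asarray(activations, dtype=float)
        ref = norm_ref if norm_ref is not None else \
            (float(np.max(values)) or 1.0)
        values = values / ref
    if np.any(np.diff(currents) <= 0):
        raise ValidationError("currents must be sorted strictly increasing")

    saturation = _first_crossing(currents, values, saturation_frac)
    if values[0] >= saturation_frac:
        saturation = float(currents[0])
    if values[0] >= onset_frac:
        return Thresholds(onset_current=float(currents[0]),
                          saturation_current=saturation
                          if saturation is not None else float("nan"),
                          left_censored=True)
    onset = _first_crossing(currents, values, onset_frac)
    if onset is None:
        return Thresholds(onset_current=NOMINAL_THRESHOLD_MA,
                          saturation_current=float("nan"), nominal=True)
    return Thresholds(onset_current=onset,
                      saturation_current=saturation
                      if saturation is not None else float("nan"))


def interpolate_drc(currents: np.ndarray, values: np.ndarray,
                    at: float) -> float:
    """Piecewise-linear DRC interpolation (the threshold convention)."""
    return float(np.interp(at, currents, values))


def outlier_filter_post_max(currents: np.ndarray, values: np.ndarray,
                            frac: float = 0.9,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Drop post-maximum sagging points from a DRC.

    After the running maximum first attains the global maximum, points
    whose value falls below ``frac`` (0.9) of that maximum are removed;
    everything before the maximum is untouched.
    """
    currents = np.asarray(currents, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return currents, values
    vmax = float(np.max(values))
    imax = int(np.argmax(values))
    keep = np.ones(values.size, dtype=bool)
    keep[imax + 1:] = values[imax + 1:] >= frac * vmax
    return currents[keep], values[keep]


@dataclass
class AlignmentReport:
    """Result of the DRC alignment criterion for one (fiber, effect) pair.

    Alignment of onset and saturation is suggestive of a mechanistic link,
    never proof of causation.
    """

    neural: Thresholds
    physio: Thresholds
    onset_difference: float  # mA
    saturation_difference: float  # mA
    tolerance: float  # mA
    aligned: bool
    reason: str = ""


def drc_alignment(neural: Thresholds, physio: Thresholds,
                  tolerance: float) -> AlignmentReport:
    """Compare neural and physiological DRC thresholds within tolerance.

    Aligned iff both the onset difference and the saturation difference
    are within ``tolerance`` mA. Nominal thresholds (onset never reached)
    make alignment undefined: reported as not aligned with the reason.
    """
    onset_diff = abs(neural.onset_current - physio.onset_current)
    sat_diff = abs(neural.saturation_current - physio.saturation_current)
    if neural.nominal or physio.nominal:
        return AlignmentReport(neural, physio, onset_diff, float("nan"),
                               tolerance, aligned=False,
                               reason="nominal threshold: onset never "
                               "reached, alignment undefined")
    if not (np.isfinite(neural.saturation_current)
            and np.isfinite(physio.saturation_current)):
        return AlignmentReport(neural, physio, onset_diff, float("nan"),
                               tolerance, aligned=False,
                               reason="saturation never reached")
    aligned = onset_diff <= tolerance and sat_diff <= tolerance
    return AlignmentReport(neural, physio, onset_diff, sat_diff, tolerance,
                           aligned=aligned)


def default_alignment_tolerance(currents: np.ndarray,
                                frac: float = 0.1) -> float:
    """Default tolerance: 10% of the tested current range."""
    currents = np.asarray(currents, dtype=float)
    return frac * float(currents.max() - currents.min())


__all__ = [
    "AlignmentReport", "GPFit", "NOMINAL_THRESHOLD_MA", "ONSET_FRACTION",
    "ParametricFit", "SATURATION_FRACTION", "Thresholds", "approx_f_test",
    "default_alignment_tolerance", "drc_alignment", "fit_gp",
    "fit_parametric", "interpolate_drc", "neural_threshold",
    "outlier_filter_post_max", "smoother_edf",
]
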