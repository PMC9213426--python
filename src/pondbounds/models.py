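"""Candidate functional forms for ecosystem-metric-vs-gradient relationships.

Four nested-complexity shapes are fit to each (gradient, metric) pair under a
Gaussian likelihood on the transformed scale:

* null       y = a                                   (flat mean)
* linear     y = b*x + c                             (ordinary least squares)
* segmented  y = d1*x + e1 (x <= bp); d2*x + e2 (x > bp)
* logistic   y = f + (g - f) / (1 + exp((bp - x)/h)) (4-parameter sigmoid)

The segmented fit profiles the breakpoint over every interior midpoint between
consecutive distinct x values (conditional fit is exact OLS), then refines the
winning interval by bounded scalar minimisation of the RSS profile.  By default
the two segments are constrained to meet at the breakpoint (e2 is derived as
e1 + (d1 - d2)*bp), the variant the `segmented` R toolchain fits; a
discontinuous variant with a free e2 is available.

The residual SD sigma is estimated by maximum likelihood and counted in k, so
k = 2 (null), 3 (linear), 5 (segmented-continuous and logistic), 6
(segmented-discontinuous).  AICc = -2*loglik + 2k + 2k(k+1)/(n-k-1).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

logger = logging.getLogger("pondbounds")

LOG10 = "log10"
IDENTITY = "identity"

#: Default response-scale transforms per ecosystem metric.  Right-skewed
#: concentration/flux/range metrics are analysed on log10 scale; pH and the
#: (signed) metabolism metrics on the raw scale.  Overridable per run.
DEFAULT_Y_TRANSFORMS: dict[str, str] = {
    "TP": LOG10,
    "TN": LOG10,
    "chl_a": LOG10,
    "CH4_flux": LOG10,
    "k600": LOG10,
    "DTR": LOG10,
    "pH": IDENTITY,
    "GPP": IDENTITY,
    "R": IDENTITY,
    "NEP": IDENTITY,
}

#: Gradient-scale transforms: surface area and depth span orders of magnitude
#: and are log-transformed; percent vegetation cover stays on its raw scale.
DEFAULT_X_TRANSFORMS: dict[str, str] = {
    "surface_area": LOG10,
    "max_depth": LOG10,
    "emergent_veg": IDENTITY,
}

NULL, LINEAR, SEGMENTED, LOGISTIC = "null", "linear", "segmented", "logistic"
FORMS = (NULL, LINEAR, SEGMENTED, LOGISTIC)


class InsufficientDataError(ValueError):
    """Too few observations for the requested fit."""


class DegenerateGradientError(ValueError):
    """The x values cannot support the requested model (e.g. all identical)."""


def _transform(values: np.ndarray, transform: str, name: str) -> tuple[np.ndarray, int]:
    """Apply a named transform, dropping (and counting) non-positive values under log10."""
    values = np.asarray(values, dtype=float)
    if transform == IDENTITY:
        return values, 0
    if transform == LOG10:
        ok = values > 0
        n_bad = int((~ok).sum())
        if n_bad:
            logger.warning("%s: dropped %d non-positive value(s) before log10", name, n_bad)
        return np.log10(values[ok]), n_bad
    raise ValueError(f"unknown transform {transform!r}")


@dataclass
class GradientDataset:
    """Paired (x, y) observations for one gradient x one metric, transformed scale.

    ``x`` and ``y`` hold the values *after* the recorded transforms have been
    applied; fits and likelihoods operate on this scale and boundary estimates
    are back-transformed afterwards.
    """

    x: np.ndarray
    y: np.ndarray
    x_name: str = "x"
    y_name: str = "y"
    x_transform: str = IDENTITY
    y_transform: str = IDENTITY
    n_dropped: int = 0
    truth: dict | None = None  # generating parameters, when simulated

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.n < 2:
            raise InsufficientDataError(f"need at least 2 points, got {self.n}")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("x and y must be finite")

    @property
    def n(self) -> int:
        return len(self.x)

    @classmethod
    def from_raw(
        cls,
        x_raw,
        y_raw,
        x_name: str = "x",
        y_name: str = "y",
        x_transform: str = IDENTITY,
        y_transform: str = IDENTITY,
    ) -> "GradientDataset":
        """Build a dataset from raw-scale values, applying transforms jointly.

        Rows where either coordinate is missing, non-finite, or non-positive
        under a log10 transform are dropped and counted in ``n_dropped``.
        """
        x_raw = np.asarray(x_raw, dtype=float)
        y_raw = np.asarray(y_raw, dtype=float)
        keep = np.isfinite(x_raw) & np.isfinite(y_raw)
        if x_transform == LOG10:
            keep &= x_raw > 0
        if y_transform == LOG10:
            keep &= y_raw > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info(
                "%s~%s: dropped %d row(s) (missing or non-positive under log10)",
                y_name, x_name, n_dropped,
            )
        x = np.log10(x_raw[keep]) if x_transform == LOG10 else x_raw[keep]
        y = np.log10(y_raw[keep]) if y_transform == LOG10 else y_raw[keep]
        return cls(x, y, x_name, y_name, x_transform, y_transform, n_dropped)


@dataclass
class ModelFit:
    """One fitted form: parameters, likelihood, AICc, RMSE and convergence."""

    form: str
    params: dict[str, float]
    sigma: float
    loglik: float
    k: int
    n: int
    aicc: float
    rmse: float
    converged: bool = True
    bp_se: float | None = None  # SE of bp on the fitted (transformed) x scale

    def predict(self, x: np.ndarray) -> np.ndarray:
        return predict(self.form, self.params, np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# shared likelihood machinery


def rmse(residuals: np.ndarray) -> float:
    residuals = np.asarray(residuals, dtype=float)
    return float(np.sqrt(np.mean(residuals**2)))


def gaussian_loglik(residuals: np.ndarray, sigma: float) -> float:
    """Gaussian log-likelihood of residuals at the given residual SD."""
    residuals = np.asarray(residuals, dtype=float)
    n = len(residuals)
    if sigma == 0.0:
        # degenerate perfect fit: conventionally +inf; callers guard via _ml_sigma
        return math.inf
    return float(-0.5 * n * math.log(2 * math.pi * sigma**2)
                 - float(np.sum(residuals**2)) / (2 * sigma**2))


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; +inf (with a warning) when n <= k + 1."""
    aic = -2.0 * loglik + 2.0 * k
    if n <= k + 1:
        warnings.warn(
            f"AICc undefined for n={n}, k={k} (needs n > k+1); returning inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


_SIGMA_FLOOR = 1e-12  # keeps the perfect-fit likelihood finite


def _ml_sigma(residuals: np.ndarray) -> float:
    return max(float(np.sqrt(np.mean(np.asarray(residuals) ** 2))), _SIGMA_FLOOR)


def _finish(form: str, params: dict, residuals: np.ndarray, k: int, n: int,
            converged: bool = True, bp_se: float | None = None) -> ModelFit:
    sigma = _ml_sigma(residuals)
    ll = gaussian_loglik(residuals, sigma)
    return ModelFit(
        form=form,
        params={key: float(v) for key, v in params.items()},
        sigma=sigma,
        loglik=ll,
        k=k,
        n=n,
        aicc=aicc(ll, k, n),
        rmse=rmse(residuals),
        converged=converged,
        bp_se=bp_se,
    )


# ---------------------------------------------------------------------------
# model functions


def predict(form: str, params: dict[str, float], x: np.ndarray) -> np.ndarray:
    """Evaluate one of the four forms at x (transformed scale)."""
    x = np.asarray(x, dtype=float)
    if form == NULL:
        return np.full_like(x, params["a"])
    if form == LINEAR:
        return params["b"] * x + params["c"]
    if form == SEGMENTED:
        d1, d2, e1, bp = params["d1"], params["d2"], params["e1"], params["bp"]
        e2 = params.get("e2", e1 + (d1 - d2) * bp)
        return np.where(x <= bp, d1 * x + e1, d2 * x + e2)
    if form == LOGISTIC:
        f, g, bp, h = params["f"], params["g"], params["bp"], params["h"]
        return f + (g - f) / (1.0 + np.exp((bp - x) / h))
    raise ValueError(f"unknown form {form!r}")


# ---------------------------------------------------------------------------
# fitters


def fit_null(data: GradientDataset) -> ModelFit:
    """Flat-mean fit: a is the arithmetic mean of y; k = 2 (a, sigma)."""
    if data.n < 2:
        raise InsufficientDataError("null fit needs n >= 2")
    a = float(np.mean(data.y))
    return _finish(NULL, {"a": a}, data.y - a, k=2, n=data.n)


def fit_linear(data: GradientDataset) -> ModelFit:
    """Closed-form OLS line; k = 3 (b, c, sigma)."""
    if data.n < 3:
        raise InsufficientDataError("linear fit needs n >= 3")
    if np.ptp(data.x) == 0:
        raise DegenerateGradientError("x values are all identical; slope undefined")
    design = np.column_stack([data.x, np.ones(data.n)])
    coef, *_ = np.linalg.lstsq(design, data.y, rcond=None)
    b, c = float(coef[0]), float(coef[1])
    return _finish(LINEAR, {"b": b, "c": c}, data.y - (b * data.x + c), k=3, n=data.n)


def _segmented_design(x: np.ndarray, bp: float, continuous: bool) -> np.ndarray:
    if continuous:
        return np.column_stack([np.ones_like(x), x, np.where(x > bp, x - bp, 0.0)])
    left = (x <= bp).astype(float)
    right = 1.0 - left
    return np.column_stack([left, left * x, right, right * x])


def _segmented_rss(x: np.ndarray, y: np.ndarray, bp: float, continuous: bool) -> tuple[float, np.ndarray]:
    design = _segmented_design(x, bp, continuous)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), coef


def breakpoint_candidates(x: np.ndarray, min_seg_points: int = 5) -> np.ndarray:
    """Interior midpoints between consecutive distinct x with >= min_seg_points per side."""
    xs = np.sort(np.asarray(x, dtype=float))
    distinct = np.unique(xs)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    ok = [m for m in mids
          if (xs <= m).sum() >= min_seg_points and (xs > m).sum() >= min_seg_points]
    return np.asarray(ok)


def fit_segmented(
    data: GradientDataset,
    continuous: bool = True,
    min_seg_points: int = 5,
    min_n: int = 10,
    refine: bool = True,
    se_method: str = "delta",
    n_boot: int = 500,
    seed: int = 0,
) -> ModelFit:
    """One-breakpoint piecewise-linear fit by exhaustive breakpoint profiling.

    For every admissible candidate breakpoint the conditional fit is exact OLS;
    the candidate minimising RSS wins and is then refined by bounded scalar
    minimisation within its bracketing interval of distinct x values.

    Parameters
    ----------
    continuous
        Constrain the segments to meet at bp (default); the right intercept is
        then derived, e2 = e1 + (d1 - d2)*bp, and k = 5.  With ``False`` both
        intercepts are free (k = 6).
    se_method
        ``"delta"`` (Gauss-Newton curvature delta method, default) or
        ``"bootstrap"`` (nonparametric pair resampling, ``n_boot`` draws,
        seeded by ``seed``).
    """
    if data.n < min_n:
        raise InsufficientDataError(f"segmented fit needs n >= {min_n}, got {data.n}")
    cands = breakpoint_candidates(data.x, min_seg_points)
    if len(cands) == 0:
        raise DegenerateGradientError(
            f"no interior breakpoint candidate with >= {min_seg_points} points per side"
        )
    x, y = data.x, data.y
    profile = np.array([_segmented_rss(x, y, bp, continuous)[0] for bp in cands])
    i = int(np.argmin(profile))
    bp = float(cands[i])
    # refine inside the bracketing interval of distinct x values (RSS is smooth there)
    if refine:
        distinct = np.unique(x)
        j = int(np.searchsorted(distinct, bp))
        lo, hi = distinct[j - 1], distinct[j]
        eps = 1e-9 * max(1.0, hi - lo)
        res = optimize.minimize_scalar(
            lambda b: _segmented_rss(x, y, b, continuous)[0],
            bounds=(lo + eps, hi - eps),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if res.fun <= profile[i]:
            bp = float(res.x)
    rss, coef = _segmented_rss(x, y, bp, continuous)
    if continuous:
        e1, d1, delta = coef
        d2 = d1 + delta
        params = {"d1": float(d1), "d2": float(d2), "e1": float(e1),
                  "e2": float(e1 + (d1 - d2) * bp), "bp": bp}
        k = 5
    else:
        e1, d1, e2, d2 = coef
        params = {"d1": float(d1), "d2": float(d2), "e1": float(e1),
                  "e2": float(e2), "bp": bp}
        k = 6
    bp_se = _segmented_bp_se(data, params, continuous, se_method, n_boot,
                             seed, min_seg_points)
    resid = y - predict(SEGMENTED, params, x)
    return _finish(SEGMENTED, params, resid, k=k, n=data.n, bp_se=bp_se)


def _segmented_bp_se(data, params, continuous, se_method, n_boot, seed,
                     min_seg_points) -> float | None:
    if se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        bps = []
        for _ in range(n_boot):
            idx = rng.integers(0, data.n, data.n)
            xb, yb = data.x[idx], data.y[idx]
            cands = breakpoint_candidates(xb, min_seg_points)
            if len(cands) == 0:
                continue
            prof = [_segmented_rss(xb, yb, bp, continuous)[0] for bp in cands]
            bps.append(cands[int(np.argmin(prof))])
        return float(np.std(bps, ddof=1)) if len(bps) > 1 else None
    if not continuous:
        # the discontinuous model is flat in bp almost everywhere, so the
        # curvature-based SE is undefined; only the bootstrap applies
        return None
    # delta method: Gauss-Newton covariance sigma^2 (J'J)^-1 at the optimum,
    # with the analytic Jacobian of m(x) = e1 + d1*min(x, bp) + d2*(x - bp)+
    x, y = data.x, data.y
    d1, d2, bp = params["d1"], params["d2"], params["bp"]
    jac = np.column_stack([
        np.ones_like(x),                    # e1
        np.minimum(x, bp),                  # d1
        np.where(x > bp, x - bp, 0.0),      # d2
        (d1 - d2) * (x > bp),               # bp
    ])
    resid = y - predict(SEGMENTED, params, x)
    dof = max(data.n - 4, 1)
    sigma2 = float(resid @ resid) / dof
    try:
        cov = sigma2 * np.linalg.inv(jac.T @ jac)
    except np.linalg.LinAlgError:
        return None
    var_bp = cov[-1, -1]
    return float(np.sqrt(var_bp)) if var_bp > 0 else None


def _logistic_starts(x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Deterministic multi-start grid: y-percentile plateaus (both orientations),
    x-percentile inflections, three transition widths."""
    f_lo, f_hi = np.percentile(y, [10, 90])
    xr = max(float(np.ptp(x)), 1e-6)
    starts = []
    for f0, g0 in ((f_lo, f_hi), (f_hi, f_lo)):
        for bp0 in np.percentile(x, [25, 50, 75]):
            for h0 in (xr / 20, xr / 8, xr / 4):
                starts.append(np.array([f0, g0, bp0, h0]))
    return starts


def fit_logistic(data: GradientDataset, min_n: int = 10,
                 se_method: str = "delta", n_boot: int = 500, seed: int = 0) -> ModelFit:
    """4-parameter sigmoid by nonlinear least squares with a deterministic
    multi-start grid; the lowest-RSS converged start wins.

    A non-converging fit is returned with ``converged=False`` (and excluded from
    model selection downstream) rather than raising.
    """
    if data.n < min_n:
        raise InsufficientDataError(f"logistic fit needs n >= {min_n}, got {data.n}")
    x, y = data.x, data.y

    def resid_fn(t):
        f, g, bp, h = t
        return f + (g - f) / (1.0 + np.exp(np.clip((bp - x) / h, -700, 700))) - y

    best = None
    for start in _logistic_starts(x, y):
        try:
            sol = optimize.least_squares(resid_fn, start, method="lm", max_nfev=2000)
        except Exception:  # noqa: BLE001 - a failed start is simply skipped
            continue
        if not sol.success or abs(sol.x[3]) < 1e-12:
            continue
        rss = float(sol.fun @ sol.fun)
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        return ModelFit(LOGISTIC, {}, math.nan, -math.inf, 5, data.n,
                        math.inf, math.nan, converged=False)
    _, sol = best
    f, g, bp, h = (float(v) for v in sol.x)
    params = {"f": f, "g": g, "bp": bp, "h": h}
    resid = -sol.fun  # least_squares residual is model - y
    bp_se = _logistic_bp_se(data, sol, se_method, n_boot, seed, resid_fn)
    return _finish(LOGISTIC, params, resid, k=5, n=data.n, bp_se=bp_se)


def _logistic_bp_se(data, sol, se_method, n_boot, seed, resid_fn) -> float | None:
    if se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        bps = []
        for _ in range(n_boot):
            idx = rng.integers(0, data.n, data.n)
            boot = GradientDataset(data.x[idx], data.y[idx],
                                   x_transform=data.x_transform,
                                   y_transform=data.y_transform)
            fit = fit_logistic(boot, min_n=2, se_method="none")
            if fit.converged:
                bps.append(fit.params["bp"])
        return float(np.std(bps, ddof=1)) if len(bps) > 1 else None
    if se_method != "delta":
        return None
    # delta method from the Jacobian at the optimum
    jac = sol.jac
    dof = max(data.n - 4, 1)
    sigma2 = float(sol.fun @ sol.fun) / dof
    try:
        cov = sigma2 * np.linalg.inv(jac.T @ jac)
        var_bp = cov[2, 2]
        return float(np.sqrt(var_bp)) if var_bp > 0 else None
    except np.linalg.LinAlgError:
        return None


def fit_all(data: GradientDataset, seed: int = 0, **segmented_opts) -> dict[str, ModelFit]:
    """Fit all four forms; segmented/logistic are skipped (not errors) when the
    dataset is too small or degenerate for them."""
    fits: dict[str, ModelFit] = {"null": fit_null(data)}
    try:
        fits[LINEAR] = fit_linear(data)
    except (InsufficientDataError, DegenerateGradientError) as exc:
        logger.info("linear fit skipped: %s", exc)
    try:
        fits[SEGMENTED] = fit_segmented(data, seed=seed, **segmented_opts)
    except (InsufficientDataError, DegenerateGradientError) as exc:
        logger.info("segmented fit skipped: %s", exc)
    try:
        fits[LOGISTIC] = fit_logistic(data, seed=seed)
    except InsufficientDataError as exc:
        logger.info("logistic fit skipped: %s", exc)
    return fits
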