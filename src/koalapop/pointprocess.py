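"""Inhomogeneous Poisson observation model for presence-only sightings.

Citizen-science sighting records are a point pattern degraded by uneven
sampling effort. The observation model treats the recorded points as an
inhomogeneous Poisson process with intensity lambda * p(x), where lambda
is the (spatially averaged) true animal density and p(x) a detection
probability combining three documented biases:

    p(x) = p_o(x) * exp(-a * d(x, h)) * exp(-c * d_r(x))
    p_o(x) = 1 if x is inside a park else b

with d(x, h) the distance to a designated detection hotspot (km), d_r(x)
the distance to the nearest road (m), and b in (0, 1] the outside-park
detection multiplier. Maximising the Poisson likelihood debiases the mean
density; a parametric bootstrap (simulate at the fitted parameters,
refit) gives confidence intervals.

``PoissonProcessModel`` follows the scikit-learn estimator protocol: set
parameters at construction, call :meth:`fit`, read trailing-underscore
attributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .landscape import SyntheticLandscape

__all__ = ["DetectionModel", "detection_probability", "log_likelihood", "PoissonProcessModel", "fit_mle", "bootstrap_ci"]

_BOUNDS = {"a": (0.0, 100.0), "b": (1e-6, 1.0), "c": (0.0, 100.0)}


@dataclass
class DetectionModel:
    """Detection-probability parameters (a: per km, b: unitless, c: per m)."""

    a: float
    b: float
    c: float

    @classmethod
    def coerce(cls, params):
        if isinstance(params, cls):
            return params
        if isinstance(params, dict):
            return cls(**params)
        return cls(*params)

    def validate(self):
        if not np.all(np.isfinite([self.a, self.b, self.c])):
            raise ValueError("detection parameters must be finite")
        if self.a < 0 or self.c < 0 or not (0 < self.b <= 1):
            raise ValueError(f"invalid detection parameters a={self.a}, b={self.b}, c={self.c}")

    def prob_grid(self, landscape: SyntheticLandscape):
        """p(x) evaluated at every cell centre."""
        po = np.where(landscape.park_mask, 1.0, self.b)
        return po * np.exp(-self.a * landscape.hotspot_distance) * np.exp(-self.c * landscape.road_distance)

    def prob_points(self, x, y, landscape: SyntheticLandscape):
        """p(x) at arbitrary planar points (exact geometry when available)."""
        in_park, hot_km, road_m = landscape.point_fields(x, y)
        po = np.where(in_park, 1.0, self.b)
        return po * np.exp(-self.a * hot_km) * np.exp(-self.c * road_m)

    def integral(self, landscape: SyntheticLandscape):
        """Cell-midpoint quadrature of the detection field, integral of p over C."""
        return float(self.prob_grid(landscape).sum() * landscape.cell_area)


def detection_probability(location, model, landscape: SyntheticLandscape):
    """Detection probability p(x) at one location (x, y) in planar km."""
    model = DetectionModel.coerce(model)
    x, y = location
    if not np.all(landscape.contains(x, y)):
        raise ValueError(f"location {location} outside the study extent {landscape.extent}")
    return float(model.prob_points(np.atleast_1d(float(x)), np.atleast_1d(float(y)), landscape)[0])


def _xy(sightings):
    if isinstance(sightings, pd.DataFrame):
        return sightings["longitude"].to_numpy(float), sightings["latitude"].to_numpy(float)
    xy = np.asarray(sightings, dtype=float).reshape(-1, 2)
    return xy[:, 0], xy[:, 1]


def log_likelihood(sightings, model, lam, landscape: SyntheticLandscape):
    """Poisson point-process log likelihood.

    n*log(lambda) + sum_i log p(x_i) - log(n!) - lambda * integral_C p dx,
    the integral by cell-midpoint quadrature at the landscape resolution.
    """
    model = DetectionModel.coerce(model)
    if not np.all(np.isfinite([lam, model.a, model.b, model.c])) or lam < 0:
        raise ValueError("non-finite or negative parameters")
    x, y = _xy(sightings)
    n = x.size
    integral = model.integral(landscape)
    if n == 0:
        return -lam * integral
    p = model.prob_points(x, y, landscape)
    if np.any(p <= 0):
        return -np.inf
    with np.errstate(divide="ignore"):
        ll = n * np.log(lam) + np.log(p).sum() - gammaln(n + 1) - lam * integral
    return float(ll)


class PoissonProcessModel(BaseEstimator):
    """Maximum-likelihood fit of the biased-observation Poisson process.

    The mean density lambda is profiled analytically (at fixed (a, b, c)
    the score equation gives lambda = n / integral of p), so only the
    three detection parameters are optimised numerically, with bounded
    L-BFGS-B from several fixed starting points.

    Parameters
    ----------
    starts : sequence of (a, b, c) optimisation starting points.
    bounds : dict with keys 'a', 'b', 'c' of (low, high) box bounds.

    Attributes (after fit)
    ----------------------
    lambda_ : debiased mean density (animals km^-2).
    a_, b_, c_ : detection parameters.
    log_likelihood_ : maximised log likelihood.
    converged_ : bool optimiser status (best-found params kept regardless).
    n_sightings_ : number of points used.
    ci_, boot_samples_, n_boot_ : set by :meth:`bootstrap`.
    """

    def __init__(self, starts=((0.1, 0.5, 1e-4), (0.5, 0.2, 1e-3), (0.01, 0.9, 1e-5)), bounds=None):
        self.starts = starts
        self.bounds = bounds

    def _resolved_bounds(self):
        b = dict(_BOUNDS)
        if self.bounds:
            b.update(self.bounds)
        return [b["a"], b["b"], b["c"]]

    def fit(self, sightings, landscape: SyntheticLandscape):
        x, y = _xy(sightings)
        n = x.size
        if n < 10:
            warnings.warn(f"only {n} sightings; the fit may be unstable", stacklevel=2)
        rows, cols = landscape.cell_index(x, y) if n else (np.array([]), np.array([]))
        if n and np.unique(np.stack([rows, cols]), axis=1).shape[1] == 1:
            warnings.warn("all sightings fall in a single cell", stacklevel=2)

        in_park, hot_km, road_m = landscape.point_fields(x, y)
        park_mask = landscape.park_mask
        hot_grid = landscape.hotspot_distance
        road_grid = landscape.road_distance
        cell_area = landscape.cell_area
        n_out = int((~in_park).sum())

        def profile_nll(theta):
            a, b, c = theta
            # integral of p over C (cell-midpoint quadrature)
            po = np.where(park_mask, 1.0, b)
            integral = (po * np.exp(-a * hot_grid - c * road_grid)).sum() * cell_area
            if not np.isfinite(integral) or integral <= 0:
                return 1e12  # finite penalty keeps the line search quiet
            if n == 0:
                return 0.0  # likelihood independent of (a,b,c) at lam=0
            # sum log p at the points; lambda profiled as n/integral
            sum_log_p = n_out * np.log(b) - a * hot_km.sum() - c * road_m.sum()
            ll = n * np.log(n / integral) + sum_log_p - gammaln(n + 1) - n
            return -ll

        best = None
        converged = False
        for start in self.starts:
            res = minimize(profile_nll, np.asarray(start, float), method="L-BFGS-B", bounds=self._resolved_bounds())
            if best is None or res.fun < best.fun:
                best = res
                converged = bool(res.success)
        a, b, c = best.x
        model = DetectionModel(a, b, c)
        integral = model.integral(landscape)
        self.a_, self.b_, self.c_ = float(a), float(b), float(c)
        self.lambda_ = n / integral if n else 0.0
        self.log_likelihood_ = log_likelihood(sightings, model, self.lambda_, landscape) if n else 0.0
        self.converged_ = converged
        if not converged:
            warnings.warn("optimiser did not report convergence; best-found parameters kept", stacklevel=2)
        self.n_sightings_ = int(n)
        self.detection_model_ = model
        return self

    def bootstrap(self, landscape: SyntheticLandscape, n_boot=1000, seed=0, max_failure_fraction=0.1):
        """Parametric-bootstrap CIs: simulate at the fit, refit, take quantiles.

        Each replicate draws a fresh inhomogeneous Poisson pattern at the
        fitted (lambda, a, b, c) by thinning and refits it; per-parameter
        CIs are the 0.025 and 0.975 quantiles across replicates. Failed
        replicate fits are dropped (error if more than
        ``max_failure_fraction`` fail).
        """
        from .synthetic import simulate_sightings

        if not hasattr(self, "lambda_"):
            raise RuntimeError("fit before bootstrap")
        rng = np.random.default_rng(seed)
        samples = {k: [] for k in ("lambda", "a", "b", "c")}
        failures = 0
        for _ in range(n_boot):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            sim = simulate_sightings(landscape, self.lambda_, (self.a_, self.b_, self.c_), seed=rep_seed)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rep = PoissonProcessModel(starts=self.starts, bounds=self.bounds).fit(sim, landscape)
            except Exception:
                failures += 1
                continue
            samples["lambda"].append(rep.lambda_)
            samples["a"].append(rep.a_)
            samples["b"].append(rep.b_)
            samples["c"].append(rep.c_)
        if failures > max_failure_fraction * n_boot:
            raise RuntimeError(f"{failures}/{n_boot} bootstrap replicates failed to fit")
        self.boot_samples_ = {k: np.asarray(v) for k, v in samples.items()}
        self.ci_ = {k: tuple(np.quantile(v, [0.025, 0.975])) for k, v in self.boot_samples_.items()}
        self.n_boot_ = n_boot - failures
        return self

    def report(self):
        """Fit summary as a JSON-serialisable dict."""
        out = {
            "lambda_hat": self.lambda_,
            "a_hat": self.a_,
            "b_hat": self.b_,
            "c_hat": self.c_,
            "log_likelihood": self.log_likelihood_,
            "converged": self.converged_,
            "n_sightings": self.n_sightings_,
        }
        if hasattr(self, "ci_"):
            out["ci"] = {k: list(v) for k, v in self.ci_.items()}
            out["n_boot"] = self.n_boot_
        return out


def fit_mle(sightings, landscape, init=None, bounds=None):
    """Functional wrapper over :class:`PoissonProcessModel`."""
    starts = (init,) if init is not None else PoissonProcessModel().starts
    return PoissonProcessModel(starts=starts, bounds=bounds).fit(sightings, landscape)


def bootstrap_ci(fit: PoissonProcessModel, landscape, n_boot=1000, seed=0):
    """Functional wrapper over :meth:`PoissonProcessModel.bootstrap`."""
    return fit.bootstrap(landscape, n_boot=n_boot, seed=seed)
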