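"""Stochastic age-structured (Leslie) projection with density feedback.

A female-only, pre-breeding-census model with 13 age classes (ages 0-12).
Vital rates come from a multi-study table of age-specific medians and
uncertainties: per resampling iteration, a study's median and standard
deviation are drawn per age class, survival probabilities are
beta-sampled around them and smoothed with the exponential association

    s(x) = a * exp(-exp(b - c*x)),

whose (a, b, c) are fitted by least squares; the distribution of fitted
constants summarises survival uncertainty. Fertility is given in
daughters per female per year (a 1:1 sex ratio converts female-only
output to total abundance by doubling).

Projections resample fertility (Gaussian, 3% SD) and survival (beta, 5%
SD) each year, apply a compensatory density feedback that reduces
survival as total abundance N approaches the carrying capacity
K = 1.2 x initial abundance (calibrated so the modified matrix has
dominant eigenvalue exactly 1 at N = K), and draw catastrophic mortality
events at 0.14 per generation (annual probability 0.14 / generation
length) that remove 50% +/- 5% of every age class. Sterilised and
disease-infertile females stay in the population but contribute no
births; sterilisation is permanent and treated animals are never
re-treated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .synthetic import N_AGE_CLASSES, survival_curve

__all__ = [
    "SurvivalSmoother",
    "resample_and_smooth_survival",
    "mean_fertility_from_table",
    "LeslieModel",
    "build_leslie",
    "DensityFeedback",
    "survival_modifier",
    "CatastropheModel",
    "StochasticRates",
    "ProjectionResult",
    "project",
]


# ---------------------------------------------------------------------------
# survival smoothing
# ---------------------------------------------------------------------------
@dataclass
class SurvivalSmoother:
    """Fitted exponential-association survival constants and their spread."""

    a: float
    b: float
    c: float
    samples: pd.DataFrame
    summary: pd.DataFrame
    n_dropped: int = 0

    def curve(self, ages=None):
        ages = np.arange(N_AGE_CLASSES) if ages is None else np.asarray(ages)
        return survival_curve(ages, self.a, self.b, self.c)


def _study_draws(table, quantity, rng):
    """Per-age (median, sd) from a randomly drawn study; missing cells take
    the mean of the values available for that age class."""
    sub = table[table["quantity"] == quantity]
    if sub.empty:
        raise ValueError(f"rate table has no {quantity} rows")
    sd_all = (sub["upper"] - sub["lower"]) / (2 * 1.96)
    med_by_age = sub.groupby("age_class")["median"].mean()
    sd_by_age = sd_all.groupby(sub["age_class"]).mean()
    studies = sub["study_id"].unique()
    meds = np.empty(N_AGE_CLASSES)
    sds = np.empty(N_AGE_CLASSES)
    by_study_age = {(r.study_id, r.age_class): (r.median, (r.upper - r.lower) / (2 * 1.96)) for r in sub.itertuples()}
    for age in range(N_AGE_CLASSES):
        study = studies[rng.integers(len(studies))]
        if (study, age) in by_study_age:
            meds[age], sds[age] = by_study_age[(study, age)]
        elif age in med_by_age.index:
            meds[age], sds[age] = med_by_age[age], sd_by_age[age]
        else:
            # age class absent from every study: linear interpolation over ages
            meds[age] = np.interp(age, med_by_age.index, med_by_age.values)
            sds[age] = np.interp(age, sd_by_age.index, sd_by_age.values)
    return meds, sds


def _beta_sample(rng, mean, sd):
    """Beta draws with given mean/SD; SD shrunk where it exceeds feasibility."""
    mean = np.clip(mean, 1e-4, 1 - 1e-4)
    max_sd = 0.95 * np.sqrt(mean * (1 - mean))
    sd = np.minimum(np.maximum(sd, 1e-6), max_sd)
    nu = mean * (1 - mean) / sd**2 - 1.0
    return rng.beta(mean * nu, (1 - mean) * nu)


def resample_and_smooth_survival(rate_table, n_resample=10000, seed=0, max_drop_fraction=0.2):
    """Resample the survival table and fit the smoothing constants.

    Per iteration: draw a study's median/SD per age class, beta-sample the
    13 survival probabilities, and least-squares fit (a, b, c) of
    s(x) = a*exp(-exp(b - c*x)). Unfittable iterations are dropped (error
    if more than ``max_drop_fraction`` are).
    """
    rng = np.random.default_rng(seed)
    ages = np.arange(N_AGE_CLASSES, dtype=float)
    rows, dropped = [], 0
    for _ in range(n_resample):
        meds, sds = _study_draws(rate_table, "survival", rng)
        s = _beta_sample(rng, meds, sds)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    survival_curve,
                    ages,
                    s,
                    p0=(min(max(s.max(), 0.05), 1.0), 0.5, 1.0),
                    bounds=([1e-3, -10.0, 1e-3], [1.0, 10.0, 10.0]),
                    maxfev=2000,
                )
        except Exception:
            dropped += 1
            continue
        rows.append(popt)
    if dropped > max_drop_fraction * n_resample:
        raise RuntimeError(f"{dropped}/{n_resample} smoothing fits failed")
    samples = pd.DataFrame(rows, columns=["a", "b", "c"])
    summary = samples.agg(["mean", lambda v: v.quantile(0.025), lambda v: v.quantile(0.975)])
    summary.index = ["mean", "q025", "q975"]
    mean = samples.mean()
    return SurvivalSmoother(a=float(mean.a), b=float(mean.b), c=float(mean.c), samples=samples, summary=summary, n_dropped=dropped)


def mean_fertility_from_table(rate_table):
    """Across-study mean fertility schedule (daughters female^-1 year^-1)."""
    sub = rate_table[rate_table["quantity"] == "fertility"]
    if sub.empty:
        raise ValueError("rate table has no fertility rows")
    by_age = sub.groupby("age_class")["median"].mean()
    fert = np.zeros(N_AGE_CLASSES)
    fert[by_age.index.to_numpy()] = by_age.to_numpy()
    return fert


# ---------------------------------------------------------------------------
# Leslie matrix
# ---------------------------------------------------------------------------
@dataclass
class LeslieModel:
    """13x13 female-only Leslie matrix with its eigen-analysis."""

    matrix: np.ndarray
    fertility: np.ndarray
    survival: np.ndarray
    lambda_det: float
    stable_age: np.ndarray
    generation_length: float


def build_leslie(fertility, survival):
    """Assemble the Leslie matrix and derive its asymptotic quantities.

    Top row = age-specific fertility (daughters per female); subdiagonal =
    age-specific survival. Generation length is the mean age of mothers at
    the stable age distribution, sum(x * l(x) * m(x)) / sum(l(x) * m(x))
    from the implied life table.
    """
    fertility = np.asarray(fertility, dtype=float)
    survival = np.asarray(survival, dtype=float)
    k = fertility.size
    if survival.size != k:
        raise ValueError("fertility and survival must have equal length")
    if np.all(fertility <= 0):
        raise ValueError("at least one age class must reproduce")
    if np.any((survival < 0) | (survival > 1)):
        raise ValueError("survival probabilities must lie in [0, 1]")
    M = np.zeros((k, k))
    M[0, :] = fertility
    M[np.arange(1, k), np.arange(k - 1)] = survival[:-1]
    eigvals, eigvecs = np.linalg.eig(M)
    i = int(np.argmax(eigvals.real))
    lam = float(eigvals[i].real)
    v = np.abs(eigvecs[:, i].real)
    stable = v / v.sum()
    lx = np.concatenate([[1.0], np.cumprod(survival[:-1])])
    lm = lx * fertility
    gen = float((np.arange(k) * lm).sum() / lm.sum())
    return LeslieModel(matrix=M, fertility=fertility, survival=survival, lambda_det=lam, stable_age=stable, generation_length=gen)


# ---------------------------------------------------------------------------
# density feedback
# ---------------------------------------------------------------------------
@dataclass
class DensityFeedback:
    """Compensatory survival reduction approaching carrying capacity K.

    The default ``power`` form is

        S_mod(N) = 1 - (1 - m_K) * (N / K) ** theta,

    with theta large (default 8) so that S_mod(N) > 0.999 for N <= K/2,
    and m_K calibrated so the survival-modified matrix has dominant
    eigenvalue exactly 1 at N = K. Because S_mod keeps declining beyond
    K, the deterministic trajectory has a stable equilibrium at K. A
    ``logistic`` alternative
    S_mod(N) = 1 - (1 - m_K) * sigmoid(g * (N - 0.9K)) is provided (it
    stalls slightly below K, where its sigmoid saturates), as is the
    ``printed`` form S_mod = a + b * N^(-1/c) with constants
    (a, b, c) = (-107, 0.00216, 34.7), retained for reference; the
    printed constants do not produce a multiplier in (0, 1] on any
    population scale tried and are clipped if used.
    """

    K: float
    form: str = "power"
    m_K: float = 1.0
    theta: float = 8.0
    n_mid_fraction: float = 0.9
    steepness: float = None
    printed_constants: tuple = (-107.0, 0.00216, 34.7)
    calibrated_: bool = field(default=False, repr=False)

    def calibrate(self, leslie: LeslieModel):
        """Solve for the survival multiplier m_K giving lambda = 1 at N = K."""
        if leslie.lambda_det <= 1.0:
            self.m_K = 1.0
        else:
            def lam_at(m):
                return build_leslie(leslie.fertility, np.clip(leslie.survival * m, 0, 1)).lambda_det - 1.0

            self.m_K = float(brentq(lam_at, 1e-3, 1.0, xtol=1e-10))
        if self.steepness is None:
            self.steepness = 200.0 / self.K
        self.calibrated_ = True
        return self

    def modifier(self, N):
        """Survival multiplier S_mod(N) in (0, 1], non-increasing in N."""
        N = np.asarray(N, dtype=float)
        if np.any(N < 0):
            raise ValueError("population size must be nonnegative")
        if self.form == "printed":
            a, b, c = self.printed_constants
            with np.errstate(divide="ignore"):
                raw = a + b * np.power(np.maximum(N, 1e-12), -1.0 / c)
            return np.clip(raw, 1e-6, 1.0)
        if not self.calibrated_:
            raise RuntimeError("call calibrate(leslie) before evaluating the feedback")
        if self.form == "logistic":
            g = self.steepness
            z = g * (N - self.n_mid_fraction * self.K)
            sig = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
            return np.maximum(1.0 - (1.0 - self.m_K) * sig, 1e-6)
        return np.maximum(1.0 - (1.0 - self.m_K) * (N / self.K) ** self.theta, 1e-6)


def survival_modifier(N, feedback: DensityFeedback):
    """Functional wrapper over :meth:`DensityFeedback.modifier`."""
    return feedback.modifier(N)


# ---------------------------------------------------------------------------
# stochastic components
# ---------------------------------------------------------------------------
@dataclass
class CatastropheModel:
    """Rare catastrophic mortality: probability per generation and magnitude."""

    p_per_generation: float = 0.14
    generation_length: float = 6.75
    magnitude_mean: float = 0.5
    magnitude_sd: float = 0.05

    @property
    def annual_p(self):
        p = self.p_per_generation / self.generation_length
        if not (0 <= p < 1):
            raise ValueError(f"annual catastrophe probability {p} outside [0, 1)")
        return p


@dataclass
class StochasticRates:
    """Year-to-year vital-rate noise: Gaussian fertility, beta survival.

    SDs are relative to the mean by default (``relative=True``); absolute
    SDs are available behind the switch.
    """

    fertility_sd: float = 0.03
    survival_sd: float = 0.05
    relative: bool = True

    def sample_fertility(self, mean, rng, size):
        sd = self.fertility_sd * (mean if self.relative else 1.0)
        return np.maximum(rng.normal(mean, np.maximum(sd, 0), size=size), 0.0)

    def sample_survival(self, mean, rng, size):
        sd = self.survival_sd * (mean if self.relative else 1.0)
        if np.all(sd <= 0):
            return np.broadcast_to(mean, size).copy()
        flat_mean = np.broadcast_to(mean, size)
        return _beta_sample(rng, flat_mean, np.broadcast_to(np.maximum(sd, 1e-9), size))


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------
@dataclass
class ProjectionResult:
    """Iterations x years trajectories plus sterilisation and event ledgers.

    ``total`` is both-sex abundance (2x females); ``females_by_age`` has
    shape (n_iter, years+1, 13) and includes sterilised and infertile
    females. ``treated`` counts animals receiving implants per year.
    """

    total: np.ndarray
    females_by_age: np.ndarray
    sterilised: np.ndarray
    treated: np.ndarray
    catastrophes: np.ndarray
    settings: dict

    @property
    def final_total(self):
        return self.total[:, -1]

    def median_trajectory(self):
        return np.median(self.total, axis=0)

    def quantile_trajectories(self, qs=(0.025, 0.5, 0.975)):
        return pd.DataFrame(
            {f"q{q}": np.quantile(self.total, q, axis=0) for q in qs},
            index=pd.RangeIndex(self.total.shape[1], name="year"),
        )


def project(
    initial_total,
    leslie: LeslieModel,
    feedback: DensityFeedback = None,
    catastrophe: CatastropheModel = None,
    rates: StochasticRates = None,
    years=25,
    n_iter=10000,
    scenario=None,
    seed=0,
    infertile_fraction=0.0,
):
    """Project the population ``years`` ahead over ``n_iter`` stochastic runs.

    Females (half of ``initial_total``) start at the stable age
    distribution. Each year: vital rates are resampled, the sterilisation
    scenario treats its eligible females, density feedback scales
    survival, the matrix advances ages and produces births, and a
    catastrophe may remove a sampled fraction of every class. Totals are
    reported as both sexes (2x females). Extinction is absorbing.

    ``infertile_fraction`` is the share of females rendered permanently
    infertile by disease; they are book-kept separately because one
    sterilisation scenario can avoid treating them.
    """
    from .management import SterilisationScenario

    if initial_total <= 0:
        raise ValueError("initial_total must be positive")
    scenario = scenario or SterilisationScenario("none", 0.0)
    rates = rates or StochasticRates()
    rng = np.random.default_rng(seed)
    k = leslie.fertility.size
    adult_ages = np.flatnonzero(leslie.fertility > 0)
    first_adult = int(adult_ages[0]) if adult_ages.size else k

    females0 = (initial_total / 2.0) * leslie.stable_age
    B = np.tile(females0 * (1 - infertile_fraction), (n_iter, 1))  # breeders
    I = np.tile(females0 * infertile_fraction, (n_iter, 1))  # disease-infertile
    S = np.zeros((n_iter, k))  # sterilised

    females_by_age = np.empty((n_iter, years + 1, k))
    total = np.empty((n_iter, years + 1))
    sterilised = np.zeros((n_iter, years + 1))
    treated = np.zeros((n_iter, years))
    catastrophes = np.zeros((n_iter, years), dtype=bool)

    females_by_age[:, 0] = B + I + S
    total[:, 0] = 2.0 * females_by_age[:, 0].sum(axis=1)
    annual_p = catastrophe.annual_p if catastrophe else 0.0

    for t in range(years):
        fert = rates.sample_fertility(leslie.fertility, rng, (n_iter, k))
        surv = rates.sample_survival(leslie.survival, rng, (n_iter, k))

        B, I, S, n_treated = scenario.apply(B, I, S, fert, first_adult, rng)
        treated[:, t] = n_treated

        if feedback is not None:
            N = 2.0 * (B + I + S).sum(axis=1)
            surv = surv * feedback.modifier(N)[:, None]
        surv = np.clip(surv, 0.0, 1.0)

        births = (fert * B).sum(axis=1)
        B_next = np.zeros_like(B)
        I_next = np.zeros_like(I)
        S_next = np.zeros_like(S)
        B_next[:, 1:] = B[:, :-1] * surv[:, :-1]
        I_next[:, 1:] = I[:, :-1] * surv[:, :-1]
        S_next[:, 1:] = S[:, :-1] * surv[:, :-1]
        B_next[:, 0] = births * (1 - infertile_fraction)
        I_next[:, 0] = births * infertile_fraction

        if catastrophe is not None and annual_p > 0:
            hit = rng.random(n_iter) < annual_p
            mag = np.clip(rng.normal(catastrophe.magnitude_mean, catastrophe.magnitude_sd, n_iter), 0.0, 1.0)
            factor = np.where(hit, 1.0 - mag, 1.0)[:, None]
            B_next *= factor
            I_next *= factor
            S_next *= factor
            catastrophes[:, t] = hit

        B, I, S = B_next, I_next, S_next
        females_by_age[:, t + 1] = B + I + S
        total[:, t + 1] = 2.0 * females_by_age[:, t + 1].sum(axis=1)
        sterilised[:, t + 1] = S.sum(axis=1)

    settings = {
        "initial_total": float(initial_total),
        "years": years,
        "n_iter": n_iter,
        "seed": seed,
        "scenario": {"kind": scenario.kind, "annual_proportion": scenario.annual_proportion},
        "infertile_fraction": infertile_fraction,
        "K": feedback.K if feedback else None,
        "lambda_det": leslie.lambda_det,
        "generation_length": leslie.generation_length,
    }
    return ProjectionResult(
        total=total,
        females_by_age=females_by_age,
        sterilised=sterilised,
        treated=treated,
        catastrophes=catastrophes,
        settings=settings,
    )
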