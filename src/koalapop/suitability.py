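"""Ensemble habitat-suitability machinery.

Presence-only records plus randomly placed pseudo-absences are split into
repeated train/validation subsets; any number of pluggable learners (the
repo ships a regularised linear learner and a tree ensemble) are fitted
per repetition and scored by AUC and the true skill statistic (TSS =
sensitivity + specificity - 1 at the TSS-maximising threshold). Per-cell
predictions are averaged across repetitions per learner and combined into
a TSS-weighted ensemble; variable importance is measured by permutation
(1 - Spearman rho between benchmark and permuted-variable predictions),
and response curves profile one variable with the others held at their
means. A variance-inflation-factor screen guards against
multicollinearity among covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "SkillScores",
    "default_learners",
    "generate_pseudo_absences",
    "split_repetitions",
    "score",
    "tss_curve",
    "ensemble",
    "EnsembleSuitabilityModel",
    "variable_importance",
    "response_curve",
    "vif_screen",
]


@dataclass
class SkillScores:
    """AUC, TSS and the suitability threshold that maximises TSS."""

    auc: float
    tss: float
    threshold_star: float


def default_learners():
    """The two shipped learners; any {name: sklearn classifier} dict works."""
    return {
        "regularised_glm": make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000)),
        "random_forest": RandomForestClassifier(n_estimators=200, min_samples_leaf=5),
    }


def generate_pseudo_absences(landscape, presences, n=2000, seed=0):
    """Sample background points uniformly from cells with no recorded presence.

    One point is drawn per sampled cell (uniform position within it);
    cells are sampled without replacement, so if fewer than ``n``
    presence-free cells exist, all of them are used with a warning.
    """
    x, y = presences["longitude"].to_numpy(float), presences["latitude"].to_numpy(float)
    if x.size == 0:
        raise ValueError("presences must be non-empty")
    rng = np.random.default_rng(seed)
    row, col = landscape.cell_index(x, y)
    occupied = np.zeros(landscape.shape, dtype=bool)
    occupied[row, col] = True
    free = np.flatnonzero(~occupied.ravel())
    if free.size == 0:
        raise ValueError("no presence-free cells to sample pseudo-absences from")
    if free.size < n:
        warnings.warn(f"only {free.size} presence-free cells available (requested {n})", stacklevel=2)
        chosen = free
    else:
        chosen = rng.choice(free, size=n, replace=False)
    r, c = np.unravel_index(chosen, landscape.shape)
    cs = landscape.cell_size
    px = (c + rng.random(chosen.size)) * cs
    py = (r + rng.random(chosen.size)) * cs
    return pd.DataFrame({"longitude": px, "latitude": py, "label": 0})


def split_repetitions(labels, train_fraction=0.8, n_rep=20, seed=0):
    """Label-stratified train/validation index splits, repeated ``n_rep`` times."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    labels = np.asarray(labels)
    splitter = StratifiedShuffleSplit(n_splits=n_rep, train_size=train_fraction, random_state=seed)
    return [(train, test) for train, test in splitter.split(np.zeros_like(labels), labels)]


def tss_curve(predictions, labels):
    """(thresholds, tss) scanning every unique predicted value as the cut."""
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels).astype(bool)
    order = np.argsort(predictions)[::-1]
    p_sorted = predictions[order]
    tp = np.cumsum(labels[order])
    fp = np.cumsum(~labels[order])
    n_pos, n_neg = labels.sum(), (~labels).sum()
    # after including the i-th sorted point as "predicted present"
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    tss = sens + spec - 1.0
    # keep the last index of each tied threshold value
    last = np.flatnonzero(np.r_[p_sorted[1:] != p_sorted[:-1], True])
    return p_sorted[last], tss[last]


def score(predictions, labels):
    """AUC (rank statistic) and maximised TSS for one validation set."""
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels)
    if np.any((predictions < 0) | (predictions > 1)):
        raise ValueError("predictions must lie in [0, 1]")
    if np.unique(labels).size < 2:
        raise ValueError("both classes required to compute skill scores")
    auc = roc_auc_score(labels, predictions)
    thresholds, tss = tss_curve(predictions, labels)
    best = int(np.argmax(tss))
    return SkillScores(auc=float(auc), tss=float(tss[best]), threshold_star=float(thresholds[best]))


def ensemble(maps, scores):
    """TSS-weighted mean of per-learner maps; learners with TSS <= 0 excluded."""
    maps = [np.asarray(m, dtype=float) for m in maps]
    tss = np.asarray([s.tss if isinstance(s, SkillScores) else float(s) for s in scores])
    keep = tss > 0
    if not keep.any():
        raise ValueError("no learner with positive TSS to ensemble")
    weights = tss[keep] / tss[keep].sum()
    stacked = np.stack([m for m, k in zip(maps, keep) if k])
    return np.tensordot(weights, stacked, axes=1)


class EnsembleSuitabilityModel(BaseEstimator):
    """TSS-weighted ensemble of pluggable presence/pseudo-absence learners.

    Parameters
    ----------
    learners : {name: classifier} dict, or None for the two defaults.
    n_rep : number of random 80/20 train/validation repetitions.
    train_fraction : training share of each split.
    random_state : master seed (splits and stochastic learners derive from it).

    Attributes (after fit)
    ----------------------
    learner_names_ : fitted learner names (all with mean TSS > 0).
    models_ : {name: [fitted clone per repetition]}.
    scores_ : DataFrame (learner, repetition, auc, tss, threshold_star).
    weights_ : {name: ensemble weight}, nonnegative, summing to 1.
    threshold_ : TSS-maximising cut of the ensemble prediction (presence below
        it is treated as absent downstream).
    """

    def __init__(self, learners=None, n_rep=20, train_fraction=0.8, random_state=0):
        self.learners = learners
        self.n_rep = n_rep
        self.train_fraction = train_fraction
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        specs = self.learners if self.learners is not None else default_learners()
        splits = split_repetitions(y, self.train_fraction, self.n_rep, self.random_state)
        rows, models = [], {name: [] for name in specs}
        for name, proto in specs.items():
            for rep, (train, test) in enumerate(splits):
                model = clone(proto)
                if "random_state" in model.get_params():
                    model.set_params(random_state=self.random_state + rep)
                model.fit(X[train], y[train])
                pred = model.predict_proba(X[test])[:, 1]
                sk = score(pred, y[test])
                rows.append({"learner": name, "repetition": rep, "auc": sk.auc, "tss": sk.tss, "threshold_star": sk.threshold_star})
                models[name].append(model)
        scores = pd.DataFrame(rows)
        mean_tss = scores.groupby("learner")["tss"].mean()
        kept = mean_tss[mean_tss > 0]
        if kept.empty:
            raise ValueError("no learner achieved positive mean TSS")
        self.learner_names_ = list(kept.index)
        self.models_ = {name: models[name] for name in self.learner_names_}
        self.scores_ = scores
        self.weights_ = (kept / kept.sum()).to_dict()
        ens_train = self.predict(X)
        sk = score(ens_train, y)
        self.threshold_ = sk.threshold_star
        self.train_scores_ = sk
        return self

    def predict_per_learner(self, X):
        """{name: mean-over-repetitions suitability} for each learner."""
        X = np.asarray(X, dtype=float)
        return {
            name: np.mean([m.predict_proba(X)[:, 1] for m in reps], axis=0)
            for name, reps in self.models_.items()
        }

    def predict(self, X):
        """TSS-weighted ensemble suitability in [0, 1] per row of X."""
        per = self.predict_per_learner(X)
        return sum(self.weights_[name] * per[name] for name in self.learner_names_)


def variable_importance(model: EnsembleSuitabilityModel, X, names=None, n_iter=10, seed=0):
    """Permutation importance: 1 - Spearman rho against the benchmark map.

    Each variable is permuted ``n_iter`` times per learner; the drop in rank
    agreement (1 - rho) between benchmark and permuted predictions is
    averaged and then TSS-weighted across learners. Constant predictions
    make rho undefined; such permutations contribute importance 0 with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    rng = np.random.default_rng(seed)
    per_learner = model.predict_per_learner(X)
    rows = []
    for j, name in enumerate(names):
        weighted_mean = 0.0
        weighted_var = 0.0
        for lname in model.learner_names_:
            benchmark = per_learner[lname]
            vals = []
            for _ in range(n_iter):
                Xp = X.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                pred = np.mean([m.predict_proba(Xp)[:, 1] for m in model.models_[lname]], axis=0)
                if np.std(pred) == 0 or np.std(benchmark) == 0:
                    warnings.warn(f"constant predictions while permuting {name}; importance set to 0", stacklevel=2)
                    vals.append(0.0)
                    continue
                rho = spearmanr(benchmark, pred).statistic
                vals.append(1.0 - rho)
            w = model.weights_[lname]
            weighted_mean += w * np.mean(vals)
            weighted_var += w * np.var(vals)
        rows.append({"variable": name, "importance": weighted_mean, "importance_sd": np.sqrt(weighted_var)})
    out = pd.DataFrame(rows).sort_values("importance", ascending=False).reset_index(drop=True)
    return out


def response_curve(model: EnsembleSuitabilityModel, X, variable, names=None, n_points=100):
    """Ensemble suitability profile of one variable, others fixed at their means."""
    X = np.asarray(X, dtype=float)
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    if variable not in names:
        raise KeyError(f"unknown variable {variable!r}; have {names}")
    j = names.index(variable)
    grid = np.linspace(X[:, j].min(), X[:, j].max(), n_points)
    probe = np.tile(X.mean(axis=0), (n_points, 1))
    probe[:, j] = grid
    return pd.DataFrame({variable: grid, "suitability": model.predict(probe)})


def vif_screen(covariates, flag_at=10.0):
    """Variance inflation factor per covariate (VIF_j = 1 / (1 - R^2_j)).

    Accepts a DataFrame or array; returns a DataFrame with the VIF and a
    flag for values >= ``flag_at``. A perfectly collinear variable yields
    an infinite VIF and is flagged.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(float)
    else:
        X = np.asarray(covariates, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two covariates")
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vifs = [variance_inflation_factor(Xc, j + 1) for j in range(X.shape[1])]
    vifs = [np.inf if not np.isfinite(v) else float(v) for v in vifs]
    return pd.DataFrame({"variable": names, "vif": vifs, "flagged": [v >= flag_at for v in vifs]})
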