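"""Repeated elastic net stability feature selection.

An ensemble of elastic-net-regularized logistic models is fitted on random
stratified subsets of the training data. Three per-feature criteria
summarize the ensemble weight distribution:

* ``c1`` — fraction of models with a nonzero weight;
* ``c2`` — |sum of weight signs| / K (sign consistency);
* ``c3`` — one-sided one-sample t-test p-value for mean weight != 0.

A feature is selected when c1 >= tau1, c2 >= tau2 and c3 <= alpha. The
brute-force wrapper repeats the whole selection over repeated stratified
K-fold training partitions (default 5 x 20 = 100 runs) for every
hyperparameter combination and reports per-feature selection frequencies
(percent of the 100 runs), choosing the combination with the best mean
held-out MCC.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

from .tabular import apply_scaler, standardize_continuous

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RentConfig:
    n_models: int = 30              # K
    subset_fraction: float = 0.8
    l1_ratio: float = 0.5
    reg_strength: float = 1.0       # C of the logistic model (inverse regularization)
    tau1: float = 0.9
    tau2: float = 0.9
    tau3_alpha: float = 0.05
    max_iter: int = 300

    def __post_init__(self):
        if self.n_models < 2:
            raise ValueError("need at least two ensemble models")
        if not 0.0 < self.subset_fraction < 1.0:
            raise ValueError("subset_fraction must be in (0, 1)")
        if not 0.0 <= self.l1_ratio <= 1.0:
            raise ValueError("l1_ratio must be in [0, 1]")


@dataclass
class RentResult:
    feature_names: list[str]
    weights: np.ndarray                  # (K, p)
    criteria: pd.DataFrame               # columns c1, c2, c3_pvalue
    selected: list[str]
    models: list = field(default_factory=list, repr=False)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=np.float64),
                        columns=[f"x{i}" for i in range(np.asarray(X).shape[1])])


def rent_criteria(weights: np.ndarray) -> pd.DataFrame:
    """The three stability criteria recomputed from a (K, p) weight matrix."""
    k = weights.shape[0]
    c1 = (weights != 0).mean(axis=0)
    c2 = np.abs(np.sign(weights).sum(axis=0)) / k
    mean = weights.mean(axis=0)
    sd = weights.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(k)), 0.0)
    # one-sided: is the mean weight significantly different from zero in
    # the direction it points?
    pvals = np.where(sd > 0, stats.t.sf(np.abs(t), df=k - 1), 1.0)
    pvals = np.where((sd == 0) & (mean != 0), 0.0, pvals)  # perfectly stable nonzero
    return pd.DataFrame({"c1": c1, "c2": c2, "c3_pvalue": pvals})


def fit_rent(X, y, config: RentConfig = RentConfig(), seed=None) -> RentResult:
    """One RENT run: K elastic-net logistic models on distinct random subsets."""
    Xf = _as_frame(X)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    rng = np.random.default_rng(seed)
    weights = np.zeros((config.n_models, Xf.shape[1]))
    models = []
    for i in range(config.n_models):
        idx, _ = train_test_split(
            np.arange(len(y)), train_size=config.subset_fraction,
            stratify=y, random_state=int(rng.integers(0, 2 ** 31)))
        clf = LogisticRegression(
            penalty="elasticnet", solver="saga", l1_ratio=config.l1_ratio,
            C=config.reg_strength, max_iter=config.max_iter, tol=1e-3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xf.iloc[idx].to_numpy(), y[idx])
        weights[i] = clf.coef_[0]
        models.append(clf)
    criteria = rent_criteria(weights)
    criteria.index = Xf.columns
    mask = ((criteria["c1"] >= config.tau1)
            & (criteria["c2"] >= config.tau2)
            & (criteria["c3_pvalue"] <= config.tau3_alpha))
    selected = list(criteria.index[mask])
    return RentResult(list(Xf.columns), weights, criteria, selected, models)


@dataclass
class BruteForceResult:
    frequencies: pd.DataFrame      # combos x features, percent of runs (0-100)
    performance: pd.Series         # mean held-out MCC per combo
    best_params: dict
    n_runs: int

    @property
    def best_frequencies(self) -> pd.Series:
        return self.frequencies.loc[str(self.best_params)]


def _expand_grid(grid: dict) -> list[dict]:
    keys = sorted(grid)
    combos = [dict(zip(keys, values))
              for values in itertools.product(*(grid[k] for k in keys))]
    return combos


def brute_force_rent(X, y, hyperparam_grid: dict | None = None,
                     n_splits: int = 5, n_repeats: int = 20, seed=None,
                     config: RentConfig = RentConfig()) -> BruteForceResult:
    """Repeated stratified K-fold RENT over a hyperparameter grid.

    Each grid combination is evaluated on n_splits x n_repeats training
    partitions (one RENT run per partition: 100 selection sets at the
    defaults). Standardization is fitted on each training partition only.
    The best combination maximizes the mean MCC of the per-run model
    ensembles on their held-out folds.
    """
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    if hyperparam_grid is None:
        hyperparam_grid = {"l1_ratio": [config.l1_ratio],
                           "reg_strength": [config.reg_strength]}
    combos = _expand_grid(hyperparam_grid)
    if not combos:
        raise ValueError("hyperparameter grid is empty")
    Xf = _as_frame(X)
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    n_runs = 0

    freq_rows, perf = {}, {}
    for combo in combos:
        cfg = RentConfig(**{**config.__dict__, **combo})
        counts = pd.Series(0.0, index=Xf.columns)
        mccs = []
        n_runs = 0  # counted, not assumed, per combination
        cv = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats,
                                     random_state=int(rng.integers(0, 2 ** 31)))
        for train_idx, test_idx in cv.split(Xf, y):
            n_runs += 1
            X_train = Xf.iloc[train_idx]
            X_test = Xf.iloc[test_idx]
            scaled_train, params = standardize_continuous(X_train, X_train.index)
            scaled_test = apply_scaler(X_test, params)
            res = fit_rent(scaled_train, y[train_idx], cfg,
                           seed=int(rng.integers(0, 2 ** 31)))
            counts[res.selected] += 1
            probs = np.mean([m.predict_proba(scaled_test.to_numpy())[:, 1]
                             for m in res.models], axis=0)
            mccs.append(matthews_corrcoef(y[test_idx], (probs >= 0.5).astype(int)))
        freq_rows[str(combo)] = counts / n_runs * 100.0
        perf[str(combo)] = float(np.mean(mccs))

    frequencies = pd.DataFrame(freq_rows).T
    performance = pd.Series(perf)
    best_key = performance.idxmax()
    best_params = combos[[str(c) for c in combos].index(best_key)]
    return BruteForceResult(frequencies, performance, best_params, n_runs)


def frequency_subset(frequencies, cutoff_percent: float) -> list[str]:
    """Features selected in at least `cutoff_percent` of the RENT runs."""
    if not 0.0 < cutoff_percent <= 100.0:
        raise ValueError("cutoff must be in (0, 100]")
    freq = pd.Series(frequencies)
    out = list(freq.index[freq >= cutoff_percent])
    if not out:
        logger.warning("no features reach a selection frequency of %s%%", cutoff_percent)
    return out
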