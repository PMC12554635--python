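"""Hyperparameter search for the graph classifiers.

The objective is mean five-fold cross-validated AUC on the training
subgraphs (folds stratified by class; paired samples share a group and
are never split across folds).  Two strategies are provided: random
search over the space (the default) and a light Bayesian optimization —
a Gaussian-process surrogate with expected improvement over a sampled
candidate pool — for the larger GNN spaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from ..graph import SampleSubgraph
from ..metrics import evaluate
from .model import GraphNetClassifier

__all__ = ["SearchSpace", "tune_hyperparameters", "cv_score"]


@dataclass
class SearchSpace:
    """Discrete choices per parameter name, e.g. {"lr": [1e-3, 1e-2], ...}."""

    choices: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.choices or any(not v for v in self.choices.values()):
            raise ValueError("search space must offer at least one choice "
                             "per parameter")

    def sample(self, rng: np.random.Generator) -> dict:
        return {k: v[rng.integers(len(v))] for k, v in self.choices.items()}

    def encode(self, config: dict) -> np.ndarray:
        """Numeric encoding (choice index, scaled to [0,1]) for the GP."""
        out = []
        for k in sorted(self.choices):
            v = self.choices[k]
            out.append(v.index(config[k]) / max(len(v) - 1, 1))
        return np.array(out)


def cv_score(subgraphs: list[SampleSubgraph], config: dict,
             k_folds: int = 5, groups: list[str] | None = None,
             seed: int = 0) -> float:
    """Mean AUC over stratified (group-aware) k-fold cross-validation."""
    labels = [s.label for s in subgraphs]
    classes = sorted(set(labels))
    y = np.array([classes.index(lbl) for lbl in labels])
    k = min(k_folds, int(np.bincount(y).min()))
    if k < 2:
        raise ValueError("need at least 2 samples per class for CV")
    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                        random_state=seed)
        splits = splitter.split(np.zeros(len(y)), y, groups=groups)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(len(y)), y)

    aucs = []
    for fold, (tr, te) in enumerate(splits):
        train = [subgraphs[i] for i in tr]
        test = [subgraphs[i] for i in te]
        if len({s.label for s in train}) < 2 or len({s.label for s in test}) < 2:
            continue
        clf = GraphNetClassifier(**{**config, "random_state": seed + fold})
        clf.fit(train)
        probs = clf.predict_proba(test)
        pos = clf.classes_[1]
        _, auc = evaluate(probs[:, 1], [s.label for s in test],
                          positive_class=pos)
        if auc is not None:
            aucs.append(auc)
    if not aucs:
        raise ValueError("no valid CV folds")
    return float(np.mean(aucs))


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray,
                          best: float) -> np.ndarray:
    from scipy.stats import norm
    sigma = np.maximum(sigma, 1e-9)
    z = (mu - best) / sigma
    return (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)


def tune_hyperparameters(
    train: list[SampleSubgraph],
    space: SearchSpace | dict[str, list],
    strategy: str = "random",
    budget: int = 10,
    seed: int = 0,
    k_folds: int = 5,
    groups: list[str] | None = None,
) -> tuple[dict, float, list[tuple[dict, float]]]:
    """Search ``space`` for the best CV-AUC configuration.

    Returns ``(best_config, best_score, trials)`` where ``trials`` lists
    every evaluated (config, score) pair.
    """
    if budget < 1:
        raise ValueError("budget must be at least 1")
    if isinstance(space, dict):
        space = SearchSpace(space)
    if strategy not in ("random", "bayesian"):
        raise ValueError("strategy must be 'random' or 'bayesian'")
    rng = np.random.default_rng(seed)
    trials: list[tuple[dict, float]] = []
    tried: set[tuple] = set()

    def evaluate_config(config: dict) -> float:
        score = cv_score(train, config, k_folds=k_folds, groups=groups,
                         seed=seed)
        trials.append((config, score))
        tried.add(tuple(sorted(config.items())))
        return score

    n_init = budget if strategy == "random" else max(min(3, budget), budget // 3)
    for _ in range(n_init):
        evaluate_config(space.sample(rng))

    if strategy == "bayesian":
        kernel = ConstantKernel(1.0) * RBF(length_scale=0.5)
        while len(trials) < budget:
            x = np.array([space.encode(c) for c, _ in trials])
            y = np.array([s for _, s in trials])
            gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-4,
                                          normalize_y=True, random_state=seed)
            gp.fit(x, y)
            pool = [space.sample(rng) for _ in range(64)]
            enc = np.array([space.encode(c) for c in pool])
            mu, sigma = gp.predict(enc, return_std=True)
            ei = _expected_improvement(mu, sigma, y.max())
            order = np.argsort(-ei)
            pick = next(
                (pool[i] for i in order
                 if tuple(sorted(pool[i].items())) not in tried),
                pool[int(order[0])],
            )
            evaluate_config(pick)

    best_config, best_score = max(trials, key=lambda t: t[1])
    return best_config, best_score, trials
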