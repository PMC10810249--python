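"""Orchestration: the hybrid selector, baselines and held-out evaluation.

``bgwo_sa_ens`` runs binary grey-wolf optimization with a simulated-
annealing pass on the alpha wolf at the end of every iteration, the
ensemble fitness as oracle, and a six-classifier held-out evaluation of the
final mask.  Baselines: the ablation without annealing (``bgwo_ens``), a
generational genetic algorithm over the same fitness (``ga_ens``), and a
filter/incremental pipeline (``mcfs_scores`` + ``ifs_search``).  The
"superior genes" report intersects DEG sets with metaheuristic selections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from gwolfsel.bgwo import GWOConfig, SelectionRun, bgwo_run
from gwolfsel.io_prep import ExpressionMatrix
from gwolfsel.objective import (
    FitnessEvaluator,
    SplitResult,
    SplitSpec,
    metrics_from_labels,
    smote_arrays,
    stratified_split,
)
from gwolfsel.sa_refine import SAConfig, sa_refine


# ---------------------------------------------------------------------------
# held-out evaluation with the six-classifier panel
# ---------------------------------------------------------------------------

def evaluation_panel(seed: int = 0) -> dict[str, object]:
    """XGBoost-style boosted trees, DT, RF, SVM, KNN and a small MLP."""
    return {
        "GBT": GradientBoostingClassifier(
            n_estimators=100, max_depth=2, random_state=seed
        ),
        "DT": DecisionTreeClassifier(random_state=seed),
        "RF": RandomForestClassifier(n_estimators=100, random_state=seed),
        "SVM": SVC(kernel="rbf", random_state=seed),  # scores via decision_function
        "KNN": KNeighborsClassifier(n_neighbors=5),
        "NN": MLPClassifier(
            hidden_layer_sizes=(32,), max_iter=1000, random_state=seed
        ),
    }


@dataclass
class EvaluationReport:
    """Per-classifier and mean test metrics for one feature set."""

    table: pd.DataFrame            # rows: classifiers + 'mean'
    n_features: int

    @property
    def mean_row(self) -> pd.Series:
        return self.table.loc["mean"]


def _scores(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    return clf.decision_function(X)


def evaluate_feature_set(
    mask: np.ndarray,
    split: SplitResult,
    seed: int = 0,
    panel: dict[str, object] | None = None,
    smote_k: int = 5,
) -> EvaluationReport:
    """Train the six-classifier panel on train+validation (SMOTE-balanced
    train), score on the untouched test partition, restricted to the mask."""
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("cannot evaluate an empty feature set")
    panel = panel or evaluation_panel(seed)
    rng = np.random.default_rng(seed)

    cols = np.flatnonzero(mask)
    Xtr, ytr = smote_arrays(
        split.train.values.T, split.train.require_labels(), k=smote_k, rng=rng
    )
    Xva, yva = split.validation.values.T, split.validation.require_labels()
    X_fit = np.vstack([Xtr, Xva])[:, cols]
    y_fit = np.concatenate([ytr, yva])
    X_te = split.test.values.T[:, cols]
    y_te = split.test.require_labels()

    rows = {}
    for name, proto in panel.items():
        clf = clone(proto)
        clf.fit(X_fit, y_fit)
        pred = np.asarray(clf.predict(X_te)).astype(int)
        ms = metrics_from_labels(y_te, pred)
        score = _scores(clf, X_te)
        rows[name] = {
            "F1": ms.f1,
            "PR_AUC": float(average_precision_score(y_te, score)),
            "ROC_AUC": float(roc_auc_score(y_te, score)),
            "MCC": ms.mcc,
            "BAc": ms.bac,
        }
    table = pd.DataFrame(rows).T
    table.loc["mean"] = table.mean(axis=0)
    return EvaluationReport(table=table, n_features=int(mask.sum()))


# ---------------------------------------------------------------------------
# the hybrid selector and its ablation
# ---------------------------------------------------------------------------

def bgwo_sa_ens(
    data: ExpressionMatrix,
    gwo_cfg: GWOConfig | None = None,
    sa_cfg: SAConfig | None = None,
    phi: float = 0.8,
    seed: int | None = None,
    use_sa: bool = True,
    evaluate: bool = True,
    split: SplitResult | None = None,
) -> SelectionRun:
    """Run BGWO (with per-iteration SA refinement of alpha) on one dataset.

    ``use_sa=False`` gives the BGWO_Ens ablation.  The 60/20/20 split, the
    SMOTE resampling, the optimizer and the annealer all derive their
    randomness from ``seed`` (defaults to the optimizer config's seed).
    """
    gwo_cfg = gwo_cfg or GWOConfig()
    sa_cfg = sa_cfg or SAConfig()
    if seed is not None:
        gwo_cfg = GWOConfig(
            n_wolves=gwo_cfg.n_wolves,
            t_max=gwo_cfg.t_max,
            init_density=gwo_cfg.init_density,
            seed=seed,
        )
    run_seed = gwo_cfg.seed
    if split is None:
        split = stratified_split(data, SplitSpec(seed=run_seed))
    evaluator = FitnessEvaluator(split=split, phi=phi, seed=run_seed)

    sa_rng = np.random.default_rng(np.random.SeedSequence([run_seed, 7]))
    hook = None
    if use_sa:
        def hook(alpha_mask, alpha_fit):
            return sa_refine(
                alpha_mask, evaluator, sa_cfg, sa_rng, start_fitness=alpha_fit
            )

    run = bgwo_run(evaluator, data.n_genes, gwo_cfg, leader_hook=hook)
    run.algorithm = "bgwo_sa_ens" if use_sa else "bgwo_ens"
    run.config.update({"phi": phi, "use_sa": use_sa})
    if evaluate:
        run.evaluation = evaluate_feature_set(run.best_mask, split, seed=run_seed)
    return run


def run_restarts(
    data: ExpressionMatrix,
    n_restarts: int = 10,
    seeds: Sequence[int] | None = None,
    **kwargs,
) -> list[SelectionRun]:
    """Independent restarts (default ten, mirroring the ten feature sets)."""
    seeds = list(seeds) if seeds is not None else list(range(1, n_restarts + 1))
    return [bgwo_sa_ens(data, seed=s, **kwargs) for s in seeds]


def restarts_table(runs: list[SelectionRun], dataset: str = "dataset") -> pd.DataFrame:
    """Fset-per-row summary (NF, fitness, mean held-out metrics)."""
    rows = []
    for i, run in enumerate(runs, start=1):
        row = {
            "Fset": f"Fset{i}",
            "Dataset": dataset,
            "NF": run.nf,
            "FV": run.best_fitness.fit,
        }
        if run.evaluation is not None:
            mean = run.evaluation.mean_row
            row.update(
                {"F1": mean["F1"], "PR_AUC": mean["PR_AUC"], "ROC_AUC": mean["ROC_AUC"]}
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# superior genes
# ---------------------------------------------------------------------------

@dataclass
class SuperiorGeneReport:
    input_sizes: dict[str, int]
    intersection: list[str]

    @property
    def n_superior(self) -> int:
        return len(self.intersection)


def superior_genes(
    deg_sets: Sequence[Iterable[str]], selected_sets: Sequence[Iterable[str]]
) -> SuperiorGeneReport:
    """Exact intersection of all DEG sets and all selected-gene sets."""
    named: dict[str, set[str]] = {}
    for i, s in enumerate(deg_sets, start=1):
        named[f"deg_{i}"] = set(s)
    for i, s in enumerate(selected_sets, start=1):
        named[f"selected_{i}"] = set(s)
    if not named or any(len(s) == 0 for s in named.values()):
        raise ValueError("all input gene sets must be non-empty")
    common = set.intersection(*named.values())
    return SuperiorGeneReport(
        input_sizes={k: len(v) for k, v in named.items()},
        intersection=sorted(common),
    )


def hypergeom_enrichment_p(
    selected: Iterable[str], truth: Iterable[str], universe: int
) -> float:
    """P(overlap >= observed) under hypergeometric sampling from the universe."""
    selected, truth = set(selected), set(truth)
    k = len(selected & truth)
    return float(stats.hypergeom.sf(k - 1, universe, len(truth), len(selected)))


# ---------------------------------------------------------------------------
# GA baseline over the same fitness
# ---------------------------------------------------------------------------

@dataclass
class GAConfig:
    population: int = 10
    generations: int = 30
    tournament_size: int = 3
    crossover_p: float = 0.5
    mutation_rate: float | None = None      # default 1/AF
    init_density: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 4:
            raise ValueError("population must be >= 4")


def ga_run(
    fitness_fn: Callable[[np.ndarray], "FitnessValue"],
    n_features: int,
    cfg: GAConfig,
    initial_population: np.ndarray | None = None,
) -> SelectionRun:
    """Generational GA: tournament selection, uniform crossover, bit-flip
    mutation, one-elite survival; minimizes the same fitness."""
    rng = np.random.default_rng(cfg.seed)
    mut = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / n_features
    if initial_population is not None:
        pop = np.asarray(initial_population, dtype=np.int8).copy()
        if pop.shape != (cfg.population, n_features):
            raise ValueError("initial_population shape mismatch")
    else:
        pop = (rng.random((cfg.population, n_features)) < cfg.init_density).astype(
            np.int8
        )
    fits = [fitness_fn(p) for p in pop]

    def best_index() -> int:
        return min(range(len(pop)), key=lambda i: (fits[i].fit, fits[i].nf, i))

    bi = best_index()
    best_mask, best_fit = pop[bi].copy(), fits[bi]
    trace = [best_fit.fit]

    for _ in range(cfg.generations):
        children = [pop[best_index()].copy()]          # elitism
        while len(children) < cfg.population:
            parents = []
            for _ in range(2):
                contenders = rng.choice(cfg.population, cfg.tournament_size, replace=False)
                w = min(contenders, key=lambda i: (fits[i].fit, fits[i].nf, i))
                parents.append(pop[w])
            swap = rng.random(n_features) < cfg.crossover_p
            child = np.where(swap, parents[1], parents[0]).astype(np.int8)
            flip = rng.random(n_features) < mut
            child[flip] = 1 - child[flip]
            children.append(child)
        pop = np.vstack(children[: cfg.population])
        fits = [fitness_fn(p) for p in pop]
        bi = best_index()
        if (fits[bi].fit, fits[bi].nf) < (best_fit.fit, best_fit.nf):
            best_mask, best_fit = pop[bi].copy(), fits[bi]
        trace.append(min(trace[-1], best_fit.fit))

    return SelectionRun(
        algorithm="ga_ens",
        best_mask=best_mask,
        best_fitness=best_fit,
        best_trace=trace,
        seed=cfg.seed,
        config={"population": cfg.population, "generations": cfg.generations},
    )


def ga_ens(
    data: ExpressionMatrix,
    ga_cfg: GAConfig | None = None,
    phi: float = 0.8,
    seed: int | None = None,
    evaluate: bool = True,
) -> SelectionRun:
    ga_cfg = ga_cfg or GAConfig()
    if seed is not None:
        ga_cfg.seed = seed
    split = stratified_split(data, SplitSpec(seed=ga_cfg.seed))
    evaluator = FitnessEvaluator(split=split, phi=phi, seed=ga_cfg.seed)
    run = ga_run(evaluator, data.n_genes, ga_cfg)
    if evaluate:
        run.evaluation = evaluate_feature_set(run.best_mask, split, seed=ga_cfg.seed)
    return run


# ---------------------------------------------------------------------------
# MCFS ranking + incremental search
# ---------------------------------------------------------------------------

def mcfs_scores(
    X: np.ndarray,
    y: np.ndarray,
    n_iter: int = 100,
    subset_size: int = 5000,
    k_folds: int = 10,
    rng: np.random.Generator | int | None = None,
    rf_trees: int = 100,
) -> pd.DataFrame:
    """Monte-Carlo feature scoring by random-subset random forests.

    Each iteration draws a uniform random feature subset, measures its
    cross-validated F1 with a random forest, and credits every member
    feature with subset_F1 weighted by the forest's within-subset
    importance.  The final score is the mean credit over the subsets that
    contained the feature; never-drawn features score 0 and rank last
    (flagged in the ``n_draws`` column).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_features = X.shape[1]
    subset_size = min(subset_size, n_features)
    totals = np.zeros(n_features)
    draws = np.zeros(n_features, dtype=int)
    seed_pool = rng.integers(0, 2**31 - 1, size=n_iter)
    for it in range(n_iter):
        cols = rng.choice(n_features, size=subset_size, replace=False)
        rf = RandomForestClassifier(
            n_estimators=rf_trees, random_state=int(seed_pool[it])
        )
        cv = StratifiedKFold(
            n_splits=k_folds, shuffle=True, random_state=int(seed_pool[it])
        )
        f1s = []
        for tr, te in cv.split(X[:, cols], y):
            rf.fit(X[np.ix_(tr, cols)], y[tr])
            f1s.append(f1_score(y[te], rf.predict(X[np.ix_(te, cols)])))
        subset_f1 = float(np.mean(f1s))
        rf.fit(X[:, cols], y)
        importance = rf.feature_importances_
        norm = importance.sum()
        if norm > 0:
            importance = importance / norm
        totals[cols] += subset_f1 * importance * subset_size
        draws[cols] += 1
    with np.errstate(invalid="ignore"):
        score = np.where(draws > 0, totals / np.maximum(draws, 1), 0.0)
    order = np.lexsort((-draws, -score))
    return pd.DataFrame(
        {"feature": order, "score": score[order], "n_draws": draws[order]}
    )


def ifs_search(
    ranked_features: Sequence[int],
    X: np.ndarray,
    y: np.ndarray,
    step: int = 5,
    panel: dict[str, object] | None = None,
    k_folds: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Incremental prefix search over a ranking.

    Evaluates prefixes of size step, 2*step, ... by mean cross-validated F1
    over the classifier panel and returns (best prefix indices, full table);
    ties prefer the smaller prefix.
    """
    ranked = np.asarray(list(ranked_features), dtype=int)
    if ranked.size == 0:
        raise ValueError("empty ranking")
    panel = panel or evaluation_panel(seed)
    if not panel:
        raise ValueError("empty classifier panel")
    sizes = list(range(step, len(ranked) + 1, step))
    if not sizes or sizes[-1] != len(ranked):
        sizes.append(len(ranked))
    rows = []
    best_size, best_f1 = sizes[0], -1.0
    for size in sizes:
        cols = ranked[:size]
        cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        per_clf = []
        for proto in panel.values():
            f1s = []
            for tr, te in cv.split(X[:, cols], y):
                clf = clone(proto)
                clf.fit(X[np.ix_(tr, cols)], y[tr])
                f1s.append(f1_score(y[te], clf.predict(X[np.ix_(te, cols)])))
            per_clf.append(np.mean(f1s))
        mean_f1 = float(np.mean(per_clf))
        rows.append({"prefix_size": size, "mean_F1": mean_f1})
        if mean_f1 > best_f1 + 1e-12:
            best_size, best_f1 = size, mean_f1
    return ranked[:best_size], pd.DataFrame(rows)
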