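"""Balanced down-sampling, splits, covariate adjustment, and pipeline search.

One *stage* of the analysis repeats, over many independent runs: down-sample
controls to match the cases, split into train / holdout-1 / holdout-2,
optionally residualize outcome and features on covariates (fitted on the
training part only, so no holdout information leaks into any fitted
component), run a template-constrained stochastic pipeline search scored by
5-fold cross-validation, and score the winning pipeline on the stage's
holdout set. Stage 1 searches over feature sets through a Feature Set
Selector (FSS) first step; stage 2 fixes the stage-1-winning FS's SNPs as
the feature matrix and drops the FSS.

The search engine is a deliberately small evolutionary optimizer over
pipeline specifications (operator choices and hyperparameters drawn from
compact grids), not a full AutoML system: the recurrence analysis downstream
depends on which feature set wins and how consistently, not on the breadth
of the operator library.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import HistGradientBoostingClassifier, HistGradientBoostingRegressor
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.feature_selection import (
    SelectPercentile,
    VarianceThreshold,
    f_classif,
    f_regression,
)
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import accuracy_score, r2_score
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .containers import GenotypeMatrix, validate_cohort
from .featuresets import FeatureSetMap

OUTCOME_COVARIATES = ["age", "sex"] + [f"pc{i}" for i in range(1, 11)]
FEATURE_COVARIATES = ["array"] + [f"pc{i}" for i in range(1, 11)]

DEFAULT_FRACTIONS = (0.75, 0.13, 0.12)


# ---------------------------------------------------------------------------
# Down-sampling and splits


def downsample_controls(cohort: pd.DataFrame, seed: int) -> np.ndarray:
    """All case rows plus an equal-size uniform sample of control rows.

    Returns positional indices into the cohort table; reproducible per seed.
    """
    validate_cohort(cohort)
    pheno = cohort["phenotype"].to_numpy()
    cases = np.flatnonzero(pheno == 1)
    controls = np.flatnonzero(pheno == 0)
    if len(controls) < len(cases):
        raise ValueError(f"{len(controls)} controls < {len(cases)} cases")
    rng = np.random.default_rng(seed)
    picked = rng.choice(controls, size=len(cases), replace=False)
    return np.sort(np.concatenate([cases, picked]))


@dataclass
class Splits:
    """Disjoint train / holdout-1 / holdout-2 index sets over the balanced set."""

    train_idx: np.ndarray
    test1_idx: np.ndarray
    test2_idx: np.ndarray
    fractions: tuple[float, float, float]
    seed: int


def make_splits(
    balanced_idx: np.ndarray,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> Splits:
    """Random partition into train/test1/test2.

    Holdout sizes are floor(fraction * n); the remainder goes to train, so
    the three sets are disjoint and exhaust the balanced set.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions {fractions} do not sum to 1")
    balanced_idx = np.asarray(balanced_idx)
    n = len(balanced_idx)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(balanced_idx)
    n1 = int(np.floor(fractions[1] * n))
    n2 = int(np.floor(fractions[2] * n))
    return Splits(
        train_idx=np.sort(perm[n1 + n2 :]),
        test1_idx=np.sort(perm[:n1]),
        test2_idx=np.sort(perm[n1 : n1 + n2]),
        fractions=tuple(fractions),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Leakage-free covariate residual adjustment


@dataclass
class Adjuster:
    """Per-column OLS fit on covariates, estimated from training rows only.

    ``apply`` returns residuals (column minus covariate prediction) for any
    row set; applying to the training rows yields residuals orthogonal to
    the covariates.
    """

    coef: np.ndarray  # (n_covariates + 1) x n_columns, intercept first
    covariates: list[str]

    def apply(self, values: np.ndarray, covariate_matrix: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        squeeze = values.ndim == 1
        V = values.reshape(len(values), -1)
        C = np.column_stack([np.ones(len(V)), covariate_matrix])
        resid = V - C @ self.coef
        return resid[:, 0] if squeeze else resid


def fit_adjuster(
    values: np.ndarray, covariate_matrix: np.ndarray, train_idx: np.ndarray,
    covariate_names: list[str] | None = None,
) -> Adjuster:
    """OLS per column on training rows only (pseudoinverse if rank-deficient)."""
    values = np.asarray(values, dtype=float)
    V = values.reshape(len(values), -1)[train_idx]
    C = np.column_stack([np.ones(len(train_idx)), np.asarray(covariate_matrix)[train_idx]])
    coef, _, rank, _ = np.linalg.lstsq(C, V, rcond=None)
    if rank < C.shape[1]:
        import logging

        logging.getLogger(__name__).warning(
            "fit_adjuster: rank-deficient covariates (rank %d < %d); pseudoinverse fit",
            rank, C.shape[1],
        )
    names = covariate_names or [f"c{i}" for i in range(C.shape[1] - 1)]
    return Adjuster(coef=coef, covariates=list(names))


# ---------------------------------------------------------------------------
# Pipeline specifications and the operator pool


@dataclass(frozen=True)
class OperatorChoice:
    name: str
    params: tuple[tuple[str, object], ...]


@dataclass
class PipelineSpec:
    """A concrete pipeline: template slots filled with operator choices."""

    template: tuple[str, ...]
    chosen_fs: str | None
    steps: tuple[OperatorChoice, ...]

    def key(self) -> tuple:
        return (self.template, self.chosen_fs, self.steps)

    def to_dict(self) -> dict:
        return {
            "template": list(self.template),
            "chosen_fs": self.chosen_fs,
            "steps": [
                {"operator": s.name, "params": dict(s.params)} for s in self.steps
            ],
        }


TRANSFORMER_GRID = {
    "variance_threshold": {"threshold": [0.0, 0.05, 0.1]},
    "select_percentile": {"percentile": [25, 50, 75, 100]},
    "standardizer": {},
}
CLASSIFIER_GRID = {
    "logistic": {"C": [0.01, 0.1, 1.0, 10.0]},
    "random_forest": {"n_estimators": [50, 100], "max_depth": [3, 6]},
    "gradient_boosting": {"max_iter": [50, 100], "learning_rate": [0.05, 0.1]},
}
REGRESSOR_GRID = {
    "ridge": {"alpha": [0.1, 1.0, 10.0]},
    "random_forest_regressor": {"n_estimators": [50, 100], "max_depth": [3, 6]},
    "gradient_boosting_regressor": {"max_iter": [50, 100], "learning_rate": [0.05, 0.1]},
}


@dataclass
class OperatorPool:
    """Operator grids per template slot kind; restrictable for fast runs."""

    transformers: dict = field(default_factory=lambda: dict(TRANSFORMER_GRID))
    classifiers: dict = field(default_factory=lambda: dict(CLASSIFIER_GRID))
    regressors: dict = field(default_factory=lambda: dict(REGRESSOR_GRID))

    def grid_for(self, slot: str) -> dict:
        if slot == "transformer":
            return self.transformers
        if slot == "classifier":
            return self.classifiers
        if slot == "regressor":
            return self.regressors
        raise KeyError(f"no operator grid for slot kind {slot!r}")


def _make_estimator(choice: OperatorChoice, problem: str, seed: int):
    p = dict(choice.params)
    n = choice.name
    if n == "variance_threshold":
        return VarianceThreshold(**p)
    if n == "select_percentile":
        score = f_classif if problem == "classification" else f_regression
        return SelectPercentile(score_func=score, **p)
    if n == "standardizer":
        return StandardScaler()
    if n == "logistic":
        return LogisticRegression(max_iter=1000, **p)
    if n == "random_forest":
        return RandomForestClassifier(random_state=seed, **p)
    if n == "gradient_boosting":
        return HistGradientBoostingClassifier(random_state=seed, **p)
    if n == "ridge":
        return Ridge(**p)
    if n == "random_forest_regressor":
        return RandomForestRegressor(random_state=seed, **p)
    if n == "gradient_boosting_regressor":
        return HistGradientBoostingRegressor(random_state=seed, **p)
    raise KeyError(f"unknown operator {n!r}")


def build_sklearn_pipeline(spec: PipelineSpec, problem: str, seed: int = 0) -> Pipeline:
    steps = [
        (f"s{i}_{c.name}", _make_estimator(c, problem, seed))
        for i, c in enumerate(spec.steps)
    ]
    return Pipeline(steps)


# ---------------------------------------------------------------------------
# The evolutionary search


@dataclass
class SearchBudget:
    population: int = 100
    generations: int = 100
    wall_clock_limit: float | None = None

    def __post_init__(self) -> None:
        if self.population <= 0 or self.generations <= 0:
            raise ValueError("population and generations must be positive")


@dataclass
class RunResult:
    run_id: int
    seed: int
    selected_fs: str | None
    cv_score: float | None
    holdout1_score: float | None
    holdout2_score: float | None
    metric: str
    pipeline: PipelineSpec | None
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "run_id": self.run_id,
            "seed": self.seed,
            "selected_fs": self.selected_fs,
            "cv_score": self.cv_score,
            "holdout1_score": self.holdout1_score,
            "holdout2_score": self.holdout2_score,
            "metric": self.metric,
            "pipeline": self.pipeline.to_dict() if self.pipeline else None,
            "error": self.error,
        }


def _random_choice(grid: dict, rng: np.random.Generator) -> OperatorChoice:
    name = list(grid)[rng.integers(len(grid))]
    params = tuple(
        (k, vals[rng.integers(len(vals))]) for k, vals in sorted(grid[name].items())
    )
    return OperatorChoice(name, params)


def _random_spec(
    template: tuple[str, ...], fs_names: list[str], pool: OperatorPool,
    rng: np.random.Generator,
) -> PipelineSpec:
    chosen_fs = None
    steps = []
    for slot in template:
        if slot == "fss":
            chosen_fs = fs_names[rng.integers(len(fs_names))]
        else:
            steps.append(_random_choice(pool.grid_for(slot), rng))
    return PipelineSpec(template, chosen_fs, tuple(steps))


def _mutate(
    spec: PipelineSpec, fs_names: list[str], pool: OperatorPool, rng: np.random.Generator
) -> PipelineSpec:
    """Resample one template slot (the FS choice or one operator/params)."""
    slots = list(spec.template)
    pick = rng.integers(len(slots))
    if slots[pick] == "fss":
        return PipelineSpec(spec.template, fs_names[rng.integers(len(fs_names))], spec.steps)
    # steps holds only non-FSS slots; map the template position onto it
    step_i = sum(1 for s in slots[:pick] if s != "fss")
    steps = list(spec.steps)
    steps[step_i] = _random_choice(pool.grid_for(slots[pick]), rng)
    return PipelineSpec(spec.template, spec.chosen_fs, tuple(steps))


def _crossover(a: PipelineSpec, b: PipelineSpec, rng: np.random.Generator) -> PipelineSpec:
    """Swap template slots between two parents (uniform per slot)."""
    chosen_fs = a.chosen_fs if rng.random() < 0.5 else b.chosen_fs
    steps = tuple(
        sa if rng.random() < 0.5 else sb for sa, sb in zip(a.steps, b.steps)
    )
    return PipelineSpec(a.template, chosen_fs, steps)


def _fs_columns(spec: PipelineSpec, snp_ids: list[str], fs_map: FeatureSetMap | None):
    if spec.chosen_fs is None:
        return np.arange(len(snp_ids))
    idx = {s: j for j, s in enumerate(snp_ids)}
    return np.array([idx[s] for s in fs_map[spec.chosen_fs] if s in idx], dtype=int)


def _cv_score(
    spec: PipelineSpec, X: np.ndarray, y: np.ndarray, snp_ids: list[str],
    fs_map: FeatureSetMap | None, problem: str, folds, seed: int,
) -> float:
    cols = _fs_columns(spec, snp_ids, fs_map)
    if len(cols) == 0:
        return -np.inf
    Xs = X[:, cols]
    proto = build_sklearn_pipeline(spec, problem, seed)
    scores = []
    for tr, va in folds:
        est = clone(proto)
        est.fit(Xs[tr], y[tr])
        pred = est.predict(Xs[va])
        if problem == "classification":
            scores.append(accuracy_score(y[va], pred))
        else:
            scores.append(r2_score(y[va], pred))
    return float(np.mean(scores))


@dataclass
class SearchOutcome:
    spec: PipelineSpec
    cv_score: float
    fitted: Pipeline
    feature_columns: np.ndarray
    n_evaluated: int


def run_pipeline_search(
    X: np.ndarray,
    y: np.ndarray,
    snp_ids: list[str],
    template: tuple[str, ...],
    fs_map: FeatureSetMap | None,
    budget: SearchBudget,
    seed: int,
    pool: OperatorPool | None = None,
    problem: str = "classification",
) -> SearchOutcome:
    """Evolutionary search over pipeline specs, scored by 5-fold CV on train.

    Tournament selection (size 2), resample-one mutation, slot-swap
    crossover, elitism of the single best. CV fold assignment is fixed per
    run; repeated evaluations of an identical spec are memoized. The best
    individual by CV score is returned (ties broken by earliest creation).
    Deterministic per seed.
    """
    if "fss" in template and (fs_map is None or len(fs_map) == 0):
        raise ValueError("template includes FSS but fs_map is empty")
    pool = pool or OperatorPool()
    fs_names = fs_map.names() if fs_map is not None else []
    rng = np.random.default_rng(seed)
    folds = list(KFold(n_splits=5, shuffle=True, random_state=seed % 2**31).split(X))
    cache: dict[tuple, float] = {}
    t0 = time.monotonic()

    def score(spec: PipelineSpec) -> float:
        k = spec.key()
        if k not in cache:
            cache[k] = _cv_score(spec, X, y, snp_ids, fs_map, problem, folds, seed % 2**31)
        return cache[k]

    best_spec, best_score, best_birth = None, -np.inf, -1
    birth = 0

    def consider(spec: PipelineSpec, s: float, b: int) -> None:
        nonlocal best_spec, best_score, best_birth
        if s > best_score or (s == best_score and best_spec is None):
            best_spec, best_score, best_birth = spec, s, b

    population = []
    for _ in range(budget.population):
        spec = _random_spec(template, fs_names, pool, rng)
        population.append((spec, score(spec), birth))
        consider(*population[-1])
        birth += 1

    def tournament() -> PipelineSpec:
        i, j = rng.integers(len(population), size=2)
        a, b = population[i], population[j]
        # higher CV wins; earliest creation breaks ties
        return a[0] if (a[1], -a[2]) >= (b[1], -b[2]) else b[0]

    for _ in range(budget.generations - 1):
        if budget.wall_clock_limit and time.monotonic() - t0 > budget.wall_clock_limit:
            break
        offspring = []
        elite = min(population, key=lambda t: (-t[1], t[2]))
        offspring.append(elite)
        while len(offspring) < budget.population:
            if rng.random() < 0.5 and budget.population > 1:
                child = _crossover(tournament(), tournament(), rng)
            else:
                child = _mutate(tournament(), fs_names, pool, rng)
            offspring.append((child, score(child), birth))
            consider(*offspring[-1])
            birth += 1
        population = offspring

    cols = _fs_columns(best_spec, snp_ids, fs_map)
    fitted = build_sklearn_pipeline(best_spec, problem, seed % 2**31)
    fitted.fit(X[:, cols], y)
    return SearchOutcome(best_spec, best_score, fitted, cols, len(cache))


def evaluate_holdout(
    fitted: Pipeline, X_holdout: np.ndarray, y_holdout: np.ndarray, metric: str
) -> float:
    """Holdout accuracy (0.5-threshold fraction correct) or R²."""
    if metric == "accuracy":
        if hasattr(fitted, "predict_proba"):
            pred = (fitted.predict_proba(X_holdout)[:, 1] >= 0.5).astype(int)
        else:
            pred = fitted.predict(X_holdout)
        return float(accuracy_score(y_holdout, pred))
    if metric == "coefficient_of_determination":
        return float(r2_score(y_holdout, fitted.predict(X_holdout)))
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# A full stage


@dataclass
class StageConfig:
    n_runs: int = 50
    template: tuple[str, ...] = ("fss", "transformer", "classifier")
    fs_map: FeatureSetMap | None = None
    budget: SearchBudget = field(default_factory=SearchBudget)
    stage: int = 1
    resadj: bool = False
    winning_fs: str | None = None  # required for stage 2
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    pool: OperatorPool | None = None
    search_fn: Callable | None = None  # injection point for stubbed searches


def run_stage(
    G: GenotypeMatrix,
    cohort: pd.DataFrame,
    config: StageConfig,
    seeds: list[int],
) -> list[RunResult]:
    """Run one full stage: per run, fresh down-sampling + splits, optional
    residual adjustment (fitted on train rows only), search, holdout scoring.

    Stage 1 scores on holdout-1, stage 2 on holdout-2; the two holdouts are
    disjoint by construction of the splits. Stage 2 restricts the feature
    matrix to the winning FS's SNPs and drops the FSS slot.
    """
    if len(set(seeds)) != len(seeds):
        raise ValueError("per-run seeds must be distinct")
    if len(seeds) != config.n_runs:
        raise ValueError("need one seed per run")
    if config.stage == 2 and config.winning_fs is None and "fss" not in config.template:
        if config.fs_map is None:
            raise ValueError("stage 2 requires a stage-1 winning FS")
    validate_cohort(cohort)

    if config.stage == 2:
        if config.winning_fs is None:
            raise ValueError("stage 2 requires a stage-1 winning FS")
        snp_ids = list(config.fs_map[config.winning_fs])
        template = tuple(s for s in config.template if s != "fss")
        fs_map_for_search = None
    else:
        if "fss" in config.template:
            union: list[str] = []
            seen = set()
            for name in config.fs_map.names():
                for s in config.fs_map[name]:
                    if s not in seen:
                        seen.add(s)
                        union.append(s)
            snp_ids = union
        else:
            snp_ids = list(G.snp_ids)
        template = config.template
        fs_map_for_search = config.fs_map if "fss" in config.template else None

    X_all = G.columns(snp_ids)
    y_all = cohort["phenotype"].to_numpy(dtype=float)
    problem = "regression" if config.resadj else "classification"
    metric = "coefficient_of_determination" if config.resadj else "accuracy"
    search = config.search_fn or run_pipeline_search

    results = []
    for run_id, seed in enumerate(seeds):
        try:
            bal = downsample_controls(cohort, seed)
            splits = make_splits(bal, config.fractions, seed)
            pos = {g: i for i, g in enumerate(bal)}
            tr = np.array([pos[i] for i in splits.train_idx])
            hold_idx = splits.test1_idx if config.stage == 1 else splits.test2_idx
            ho = np.array([pos[i] for i in hold_idx])

            X = X_all[bal]
            y = y_all[bal]
            if config.resadj:
                cov_out = cohort.iloc[bal][OUTCOME_COVARIATES].to_numpy(float)
                cov_feat = cohort.iloc[bal][FEATURE_COVARIATES].to_numpy(float)
                adj_y = fit_adjuster(y, cov_out, tr, OUTCOME_COVARIATES)
                adj_X = fit_adjuster(X, cov_feat, tr, FEATURE_COVARIATES)
                y = adj_y.apply(y, cov_out)
                X = adj_X.apply(X, cov_feat)

            outcome = search(
                X[tr], y[tr], snp_ids, template, fs_map_for_search,
                config.budget, seed, pool=config.pool, problem=problem,
            )
            hscore = evaluate_holdout(outcome.fitted, X[ho][:, outcome.feature_columns],
                                      y[ho], metric)
            results.append(
                RunResult(
                    run_id=run_id,
                    seed=seed,
                    selected_fs=outcome.spec.chosen_fs
                    if config.stage == 1
                    else config.winning_fs,
                    cv_score=outcome.cv_score,
                    holdout1_score=hscore if config.stage == 1 else None,
                    holdout2_score=hscore if config.stage == 2 else None,
                    metric=metric,
                    pipeline=outcome.spec,
                )
            )
        except Exception as exc:  # per-run failures are recorded, not fatal
            results.append(
                RunResult(run_id, seed, None, None, None, None, metric, None, repr(exc))
            )
    return results


# ---------------------------------------------------------------------------
# Polygenic risk score baseline


def prs_baseline(
    G: GenotypeMatrix,
    effects: dict[str, float],
    cohort: pd.DataFrame,
    splits: Splits,
):
    """PRS = weighted dosage sum; logistic fit of phenotype on PRS on train;
    holdout accuracy at the 0.5 probability threshold.

    ``effects`` maps snp_id to its published per-allele effect size, with
    reference alleles already matched to dosage orientation.
    """
    snps = list(effects)
    w = np.array([effects[s] for s in snps])
    prs = G.columns(snps) @ w
    y = cohort["phenotype"].to_numpy(dtype=int)
    model = LogisticRegression(max_iter=1000)
    model.fit(prs[splits.train_idx, None], y[splits.train_idx])
    hold = splits.test1_idx if len(splits.test1_idx) else splits.test2_idx
    proba = model.predict_proba(prs[hold, None])[:, 1]
    acc = float(accuracy_score(y[hold], (proba >= 0.5).astype(int)))
    return model, acc
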