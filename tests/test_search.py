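"""Down-sampling, splits, leakage-free adjustment, pipeline search, PRS."""

import numpy as np
import pandas as pd
import pytest

from snpfs.config import derive_seed
from snpfs.containers import GenotypeMatrix
from snpfs.featuresets import FeatureSetMap
from snpfs.search import (
    OperatorPool,
    SearchBudget,
    StageConfig,
    downsample_controls,
    evaluate_holdout,
    fit_adjuster,
    make_splits,
    prs_baseline,
    run_pipeline_search,
    run_stage,
)
from snpfs.synthetic import GenerativeModel, simulate_genotypes, simulate_phenotype
from snpfs.workflow import FAST_CLASSIFICATION_POOL


def _cohort(n_cases, n_controls, seed=0):
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "phenotype": [1] * n_cases + [0] * n_controls,
            "age": rng.normal(55, 8, n),
            "sex": rng.integers(0, 2, n),
            "array": rng.integers(0, 2, n),
        }
    )
    for i in range(1, 11):
        df[f"pc{i}"] = rng.normal(size=n)
    return df


# ------------------------------------------------------------- down-sampling


def test_downsample_balances_and_keeps_all_cases():
    cohort = _cohort(120, 500)
    idx = downsample_controls(cohort, seed=0)
    pheno = cohort["phenotype"].to_numpy()[idx]
    assert len(idx) == 240
    assert pheno.sum() == 120


def test_downsample_identity_when_already_balanced():
    cohort = _cohort(10, 10)
    assert np.array_equal(downsample_controls(cohort, 0), np.arange(20))


def test_downsample_seed_changes_controls_not_cases():
    cohort = _cohort(100, 1000)
    a, b = downsample_controls(cohort, 1), downsample_controls(cohort, 2)
    cases = set(np.flatnonzero(cohort["phenotype"] == 1))
    assert cases <= set(a) and cases <= set(b)
    assert set(a) != set(b)


def test_downsample_rejects_fewer_controls_than_cases():
    with pytest.raises(ValueError):
        downsample_controls(_cohort(20, 10), 0)


# ------------------------------------------------------------- splits


def test_split_sizes_exact_fractions():
    s = make_splits(np.arange(100), (0.75, 0.13, 0.12), seed=0)
    assert (len(s.train_idx), len(s.test1_idx), len(s.test2_idx)) == (75, 13, 12)


def test_split_disjoint_and_exhaustive():
    idx = np.arange(38_268)
    s = make_splits(idx, seed=3)
    parts = [set(s.train_idx), set(s.test1_idx), set(s.test2_idx)]
    assert sum(len(p) for p in parts) == len(idx)
    assert parts[0] | parts[1] | parts[2] == set(idx)
    assert not (parts[1] & parts[2])
    # floor rounding for the holdouts, remainder to train
    assert len(s.test1_idx) == int(np.floor(0.13 * 38_268))
    assert len(s.test2_idx) == int(np.floor(0.12 * 38_268))


def test_two_way_split_mode():
    s = make_splits(np.arange(100), (0.75, 0.25, 0.0), seed=0)
    assert (len(s.train_idx), len(s.test1_idx), len(s.test2_idx)) == (75, 25, 0)


def test_bad_fractions_rejected():
    with pytest.raises(ValueError):
        make_splits(np.arange(10), (0.5, 0.3, 0.1), seed=0)


# ------------------------------------------------------------- adjuster


def test_adjuster_orthogonal_covariates_give_centered_column():
    rng = np.random.default_rng(0)
    n = 400
    cov = rng.normal(size=(n, 2))
    cov -= cov.mean(axis=0)
    y = rng.normal(size=n)
    y -= cov @ np.linalg.lstsq(cov, y, rcond=None)[0]  # orthogonalize
    adj = fit_adjuster(y, cov, np.arange(n))
    resid = adj.apply(y, cov)
    assert np.allclose(resid, y - y.mean(), atol=1e-10)


def test_adjuster_exact_linear_column_zero_residuals():
    rng = np.random.default_rng(1)
    cov = rng.normal(size=(300, 3))
    y = 2.0 + cov @ np.array([1.0, -0.5, 3.0])
    adj = fit_adjuster(y, cov, np.arange(300))
    assert np.max(np.abs(adj.apply(y, cov))) < 1e-8


def test_adjuster_leakage_free_and_residuals_orthogonal():
    rng = np.random.default_rng(2)
    n, n_train = 500, 350
    cov = rng.normal(size=(n, 4))
    X = rng.normal(size=(n, 3)) + cov @ rng.normal(size=(4, 3))
    train = np.arange(n_train)
    a = fit_adjuster(X, cov, train)
    # refit after perturbing the held-out rows: coefficients must not move
    X2 = X.copy()
    X2[n_train:] += 100.0
    b = fit_adjuster(X2, cov, train)
    assert np.array_equal(a.coef, b.coef)
    resid = a.apply(X, cov)[train]
    for j in range(cov.shape[1]):
        for c in range(X.shape[1]):
            r = np.corrcoef(resid[:, c], cov[train, j])[0, 1]
            assert abs(r) < 1e-8


def test_adjuster_rank_deficient_warns(caplog):
    import logging

    cov = np.ones((50, 2))  # duplicate constant columns
    y = np.random.default_rng(3).normal(size=50)
    with caplog.at_level(logging.WARNING, logger="snpfs.search"):
        fit_adjuster(y, cov, np.arange(50))
    assert any("rank-deficient" in r.message for r in caplog.records)


# ------------------------------------------------------------- search


def _planted(n=2000, n_fs=10, snps_per_fs=5, beta=3.0, seed=0):
    m = n_fs * snps_per_fs
    G = simulate_genotypes(n, np.full(m, 0.3), ld_rho=0.0, seed=seed)
    sets = {
        f"FS{k}": G.snp_ids[k * snps_per_fs : (k + 1) * snps_per_fs]
        for k in range(n_fs)
    }
    fs_map = FeatureSetMap(sets)
    model = GenerativeModel([1.0], [[(sets["FS0"][0], beta)]], seed=seed + 1)
    cohort, _ = simulate_phenotype(G, model)
    return G, cohort, fs_map


def test_single_configuration_pool_returns_it():
    G, cohort, fs_map = _planted(n=300, n_fs=1, seed=4)
    pool = OperatorPool(
        transformers={"standardizer": {}},
        classifiers={"logistic": {"C": [1.0]}},
    )
    y = cohort["phenotype"].to_numpy(float)
    out = run_pipeline_search(
        G.dosage, y, G.snp_ids, ("fss", "transformer", "classifier"),
        fs_map, SearchBudget(population=3, generations=2), seed=0, pool=pool,
    )
    assert out.spec.chosen_fs == "FS0"
    assert [s.name for s in out.spec.steps] == ["standardizer", "logistic"]


def test_search_finds_planted_feature_set():
    G, cohort, fs_map = _planted(seed=5)
    y = cohort["phenotype"].to_numpy(float)
    hits = 0
    for seed in range(10):
        out = run_pipeline_search(
            G.dosage, y, G.snp_ids, ("fss", "transformer", "classifier"),
            fs_map, SearchBudget(population=12, generations=10), seed=seed,
            pool=FAST_CLASSIFICATION_POOL,
        )
        hits += out.spec.chosen_fs == "FS0"
    assert hits >= 9


def test_search_deterministic_per_seed():
    G, cohort, fs_map = _planted(n=400, seed=6)
    y = cohort["phenotype"].to_numpy(float)
    kw = dict(
        template=("fss", "transformer", "classifier"), fs_map=fs_map,
        budget=SearchBudget(population=5, generations=4), seed=42,
        pool=FAST_CLASSIFICATION_POOL,
    )
    a = run_pipeline_search(G.dosage, y, G.snp_ids, **kw)
    b = run_pipeline_search(G.dosage, y, G.snp_ids, **kw)
    assert a.spec == b.spec and a.cv_score == b.cv_score


def test_search_requires_fs_map_with_fss_template():
    G, cohort, _ = _planted(n=100, n_fs=1, seed=7)
    with pytest.raises(ValueError, match="fs_map"):
        run_pipeline_search(
            G.dosage, cohort["phenotype"].to_numpy(float), G.snp_ids,
            ("fss", "transformer", "classifier"), None, SearchBudget(2, 2), 0,
        )


def test_null_data_holdout_accuracy_near_half():
    G = simulate_genotypes(600, np.full(10, 0.3), seed=8)
    # slightly negative baseline keeps controls in the majority
    model = GenerativeModel([1.0], [[]], baseline_log_odds=-0.3, seed=9)
    cohort, _ = simulate_phenotype(G, model)
    fs_map = FeatureSetMap({"A": G.snp_ids[:5], "B": G.snp_ids[5:]})
    cfg = StageConfig(
        n_runs=20, fs_map=fs_map, budget=SearchBudget(4, 3),
        pool=FAST_CLASSIFICATION_POOL,
    )
    results = run_stage(G, cohort, cfg, seeds=list(range(20)))
    accs = [r.holdout1_score for r in results if r.error is None]
    se = 0.5 / np.sqrt(sum(len(make_splits(downsample_controls(cohort, s)).test1_idx)
                           for s in range(20)))
    assert abs(np.mean(accs) - 0.5) < 3 * se + 0.02


# ------------------------------------------------------------- holdout metric


def test_evaluate_holdout_trivial_values():
    class Constant:
        def predict(self, X):
            return np.zeros(len(X))

        def predict_proba(self, X):
            return np.column_stack([np.ones(len(X)), np.zeros(len(X))])

    y = np.array([0, 1] * 10)
    assert evaluate_holdout(Constant(), np.zeros((20, 2)), y, "accuracy") == 0.5

    class Perfect:
        def predict(self, X):
            return X[:, 0]

        def predict_proba(self, X):
            p = X[:, 0]
            return np.column_stack([1 - p, p])

    X = np.column_stack([y, y])
    assert evaluate_holdout(Perfect(), X.astype(float), y, "accuracy") == 1.0

    class Mean:
        def predict(self, X):
            return np.full(len(X), 1.5)

    yr = np.array([1.0, 2.0] * 10)
    assert evaluate_holdout(Mean(), np.zeros((20, 1)), yr,
                            "coefficient_of_determination") == pytest.approx(0.0)
    with pytest.raises(ValueError):
        evaluate_holdout(Mean(), np.zeros((20, 1)), yr, "auc")


# ------------------------------------------------------------- stages


def test_stage_runs_have_distinct_downsamplings_and_are_reproducible():
    G, cohort, fs_map = _planted(n=400, n_fs=2, seed=10)
    cfg = StageConfig(n_runs=2, fs_map=fs_map, budget=SearchBudget(3, 2),
                      pool=FAST_CLASSIFICATION_POOL)
    seeds = [derive_seed(0, 1, r) for r in range(2)]
    a = run_stage(G, cohort, cfg, seeds)
    b = run_stage(G, cohort, cfg, seeds)
    assert [r.to_dict() for r in a] == [r.to_dict() for r in b]
    d0, d1 = (set(downsample_controls(cohort, s)) for s in seeds)
    assert d0 != d1


def test_stage2_uses_winning_fs_and_drops_fss():
    G, cohort, fs_map = _planted(n=400, seed=11)
    captured = {}

    def spy_search(X, y, snp_ids, template, fs_map_arg, budget, seed, pool=None,
                   problem="classification"):
        captured["snp_ids"] = snp_ids
        captured["template"] = template
        captured["fs_map"] = fs_map_arg
        return run_pipeline_search(X, y, snp_ids, template, fs_map_arg, budget,
                                   seed, pool=FAST_CLASSIFICATION_POOL, problem=problem)

    cfg = StageConfig(
        n_runs=1, template=("fss", "transformer", "classifier"), fs_map=fs_map,
        budget=SearchBudget(2, 2), stage=2, winning_fs="FS0", search_fn=spy_search,
    )
    results = run_stage(G, cohort, cfg, [0])
    assert captured["snp_ids"] == fs_map["FS0"]
    assert "fss" not in captured["template"]
    assert captured["fs_map"] is None
    assert results[0].selected_fs == "FS0"
    assert results[0].holdout2_score is not None and results[0].holdout1_score is None


def test_stage2_without_winner_rejected():
    G, cohort, fs_map = _planted(n=100, seed=12)
    cfg = StageConfig(n_runs=1, fs_map=fs_map, budget=SearchBudget(2, 2), stage=2)
    with pytest.raises(ValueError, match="winning"):
        run_stage(G, cohort, cfg, [0])


def test_resadj_stage_reports_r2_metric():
    G, cohort, fs_map = _planted(n=400, n_fs=2, seed=13)
    from snpfs.workflow import FAST_REGRESSION_POOL

    cfg = StageConfig(
        n_runs=1, template=("fss", "transformer", "regressor"), fs_map=fs_map,
        budget=SearchBudget(3, 2), resadj=True, pool=FAST_REGRESSION_POOL,
    )
    results = run_stage(G, cohort, cfg, [0])
    assert results[0].error is None
    assert results[0].metric == "coefficient_of_determination"


# ------------------------------------------------------------- PRS baseline


def test_prs_zero_weights_give_half_accuracy():
    G, cohort, _ = _planted(n=1000, n_fs=2, seed=14)
    bal = downsample_controls(cohort, 0)
    cb = cohort.iloc[bal].reset_index(drop=True)
    Gb = GenotypeMatrix([G.sample_ids[i] for i in bal], G.snp_ids, G.dosage[bal])
    splits = make_splits(np.arange(len(bal)), (0.75, 0.25, 0.0), 0)
    _, acc = prs_baseline(Gb, {s: 0.0 for s in G.snp_ids[:3]}, cb, splits)
    assert abs(acc - 0.5) < 0.12


def test_prs_sign_flip_symmetry():
    G, cohort, _ = _planted(n=1000, n_fs=2, beta=1.5, seed=15)
    bal = downsample_controls(cohort, 0)
    cb = cohort.iloc[bal].reset_index(drop=True)
    Gb = GenotypeMatrix([G.sample_ids[i] for i in bal], G.snp_ids, G.dosage[bal])
    splits = make_splits(np.arange(len(bal)), (0.75, 0.25, 0.0), 0)
    effects = {G.snp_ids[0]: 1.5}
    _, acc = prs_baseline(Gb, effects, cb, splits)
    flipped = GenotypeMatrix(Gb.sample_ids, Gb.snp_ids, 2.0 - Gb.dosage)
    _, acc_flip = prs_baseline(flipped, {k: -v for k, v in effects.items()}, cb, splits)
    assert acc == pytest.approx(acc_flip)


def test_prs_missing_snp_rejected():
    G, cohort, _ = _planted(n=100, n_fs=1, seed=16)
    splits = make_splits(np.arange(100), (0.75, 0.25, 0.0), 0)
    with pytest.raises(KeyError):
        prs_baseline(G, {"absent": 1.0}, cohort, splits)
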