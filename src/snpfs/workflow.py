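"""End-to-end workflow: synthetic study → feature sets → 2-stage search →
recurrence permutation test → SHAP dissection.

The stages chain exactly as the 2-stage design prescribes: stage 1 searches
with a Feature Set Selector over all candidate FSs and is judged on
holdout-1; the recurrence of the winning FS across runs is referred to a
target-permutation null; stage 2 fixes that FS's SNPs, searches without the
FSS, and is judged on the disjoint holdout-2; the best stage-2 model's
well-predicted cases are dissected with kernel SHAP and clustered.

Desk-scale defaults (cohorts of a few thousand samples, tens of runs,
compact operator pools) keep a full chain to a few minutes on one CPU;
every scale knob lives in :class:`snpfs.config.AnalysisConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig, RunLedger, derive_seed
from .containers import GenotypeMatrix, write_cohort
from .explain import (
    cluster_cases_by_shap,
    export_force_matrix,
    kmeans_background,
    permutation_importance,
    rank_features_per_cluster,
    select_k_by_dunn,
    select_well_predicted,
    shap_matrix,
)
from .featuresets import (
    FeatureSetMap,
    build_feature_sets,
    build_snp_gene_map,
    filter_snps_by_scores,
    filter_snps_qc,
    ld_prune,
    write_fs_file,
)
from .recurrence import (
    compare_to_null,
    config_hash,
    permutation_null,
    summarize_recurrence,
)
from .search import (
    OperatorPool,
    SearchBudget,
    StageConfig,
    downsample_controls,
    make_splits,
    run_stage,
)
from .synthetic import (
    AnnotationFixture,
    GenerativeModel,
    ScoreModel,
    simulate_annotations,
    simulate_genotypes,
    simulate_phenotype,
    bayes_accuracy,
)

# Compact pools for desk-scale runs: regularized linear estimators evaluate in
# milliseconds per fold, and FS-selection consistency — the quantity under
# study — does not hinge on tree ensembles being in the pool.
FAST_CLASSIFICATION_POOL = OperatorPool(
    transformers={"standardizer": {}, "variance_threshold": {"threshold": [0.0, 0.05]}},
    classifiers={"logistic": {"C": [0.01, 0.1, 1.0]}},
)
FAST_REGRESSION_POOL = OperatorPool(
    transformers={"standardizer": {}, "variance_threshold": {"threshold": [0.0, 0.05]}},
    regressors={"ridge": {"alpha": [0.1, 1.0, 10.0]}},
)


@dataclass
class StudyData:
    """A fully generated synthetic study ready for the 2-stage analysis."""

    annotations: AnnotationFixture
    genotypes: GenotypeMatrix
    cohort: pd.DataFrame
    subgroups: np.ndarray
    model: GenerativeModel
    fs_map: FeatureSetMap
    causal_fs: str
    causal_snps: list[str]


def build_synthetic_study(cfg: AnalysisConfig) -> StudyData:
    """Generate annotations, genotypes, feature sets, and a planted-signal
    phenotype whose causal SNPs are private to one feature set."""
    ann = simulate_annotations(
        n_druggable=cfg.n_druggable,
        connected_per_druggable=cfg.connected_per_druggable,
        snps_per_gene=cfg.snps_per_gene,
        score_distributions=ScoreModel(pass_fraction=cfg.pass_fraction),
        seed=derive_seed(cfg.base_seed, 1),
    )
    G = simulate_genotypes(
        cfg.n_samples,
        ann,
        ld_block_size=cfg.ld_block_size,
        ld_rho=cfg.ld_rho,
        n_subpops=cfg.n_subpops,
        seed=derive_seed(cfg.base_seed, 2),
    )
    retained = filter_snps_by_scores(filter_snps_qc(ann.snp_table))
    sg_map = build_snp_gene_map(retained, ann.genes, ann.enhancers)
    mapped = retained[retained["snp_id"].isin(sg_map["snp_id"])]
    pruned = ld_prune(G.subset_snps(mapped["snp_id"].tolist()))
    sg_map = sg_map[sg_map["snp_id"].isin(pruned)].reset_index(drop=True)
    fs_map = build_feature_sets(sg_map, ann.genes)

    names = fs_map.names()
    causal_fs = names[cfg.causal_fs_index % len(names)]
    druggable, _ = fs_map.genes.get(causal_fs, (None, None))
    shared = set()
    if druggable is not None:
        for other in names:
            if other != causal_fs and fs_map.genes.get(other, (None,))[0] == druggable:
                shared |= set(fs_map[other])
    private = [s for s in fs_map[causal_fs] if s not in shared]
    causal_snps = (private or list(fs_map[causal_fs]))[: cfg.n_causal_snps]

    model = GenerativeModel(
        subgroup_fractions=[1.0],
        causal_sets=[[(s, cfg.causal_beta) for s in causal_snps]],
        # cases are the minority in a case/control cohort; the analysis then
        # down-samples controls to balance, so controls must outnumber cases
        baseline_log_odds=-0.4,
        covariate_effects={"age": 0.1, "sex": 0.2, "array": 0.0},
        seed=derive_seed(cfg.base_seed, 3),
    )
    cohort, subgroups = simulate_phenotype(G, model)
    return StudyData(ann, G, cohort, subgroups, model, fs_map, causal_fs, causal_snps)


def stage_config(cfg: AnalysisConfig, stage: int, fs_map, winning_fs=None) -> StageConfig:
    problem_pool = FAST_REGRESSION_POOL if cfg.resadj else FAST_CLASSIFICATION_POOL
    if cfg.resadj:
        template = (
            ("fss", "transformer", "regressor") if stage == 1 else ("transformer", "regressor")
        )
    else:
        template = (
            ("fss", "transformer", "classifier")
            if stage == 1
            else ("transformer", "classifier")
        )
    return StageConfig(
        n_runs=cfg.n_runs,
        template=template,
        fs_map=fs_map,
        budget=SearchBudget(population=cfg.population, generations=cfg.generations),
        stage=stage,
        resadj=cfg.resadj,
        winning_fs=winning_fs,
        fractions=cfg.fractions,
        pool=problem_pool,
    )


def stage_seeds(cfg: AnalysisConfig, stage: int) -> list[int]:
    return [derive_seed(cfg.base_seed, 10 + stage, r) for r in range(cfg.n_runs)]


def run_workflow(cfg: AnalysisConfig, outdir) -> dict:
    """Execute the full chain, writing every artifact under ``outdir``.

    Returns a summary dict (also written as summary.json). Re-running with
    the same config and base seed reproduces the outputs bit-for-bit.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.save(out / "config.yaml")
    ledger = RunLedger(out / "runs.ledger.jsonl")

    study = build_synthetic_study(cfg)
    study.genotypes.write(out / "genotypes.tsv")
    write_cohort(study.cohort, out / "cohort.tsv")
    study.annotations.write_gene_bed(out / "genes.bed")
    study.annotations.write_enhancer_bed(out / "enhancers.bed")
    study.annotations.write_snp_table(out / "snp_scores.tsv")
    write_fs_file(study.fs_map, out / "feature_sets.tsv")

    summary: dict = {
        "config_hash": cfg.config_hash,
        "base_seed": cfg.base_seed,
        "n_feature_sets": len(study.fs_map),
        "planted_fs": study.causal_fs,
        "planted_fs_size": len(study.fs_map[study.causal_fs]),
        "bayes_accuracy": bayes_accuracy(study.model, study.genotypes),
    }

    # ---- stage 1
    cfg1 = stage_config(cfg, 1, study.fs_map)
    seeds1 = stage_seeds(cfg, 1)
    results1 = run_stage(study.genotypes, study.cohort, cfg1, seeds1)
    _write_results(results1, out / "stage1_results.jsonl", ledger, cfg, stage=1)
    rec = summarize_recurrence(results1)
    summary["stage1"] = {
        "fs_counts": rec.fs_counts,
        "max_count": rec.max_count,
        "argmax_fs": rec.argmax_fs,
        "best_holdout_score": rec.best_holdout_score,
    }

    # ---- permutation null
    if cfg.n_permutations > 0:
        null = permutation_null(
            study.genotypes,
            study.cohort,
            cfg1,
            n_permutations=cfg.n_permutations,
            base_seed=derive_seed(cfg.base_seed, 20),
            expected_digest=config_hash(cfg1),
        )
        for p, results in enumerate(null.per_permutation):
            _write_results(results, None, ledger, cfg, stage=1, permutation=p)
        report = compare_to_null(rec, null)
        (out / "permtest.json").write_text(json.dumps(report, indent=2))
        summary["permutation_test"] = report

    # ---- stage 2 on the recurrent FS
    winning_fs = rec.argmax_fs[0]
    cfg2 = stage_config(cfg, 2, study.fs_map, winning_fs=winning_fs)
    seeds2 = stage_seeds(cfg, 2)
    results2 = run_stage(study.genotypes, study.cohort, cfg2, seeds2)
    _write_results(results2, out / "stage2_results.jsonl", ledger, cfg, stage=2)
    ok2 = [r for r in results2 if r.error is None]
    best2 = max(ok2, key=lambda r: r.holdout2_score)
    summary["stage2"] = {
        "winning_fs": winning_fs,
        "best_holdout_score": best2.holdout2_score,
        "metric": best2.metric,
    }

    # ---- SHAP dissection of the best stage-2 run
    summary["explanation"] = explain_best_run(cfg, study, best2, winning_fs, out)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary


def explain_best_run(cfg, study: StudyData, best_run, winning_fs: str, out: Path) -> dict:
    """Refit the best stage-2 pipeline on its own split and dissect the
    well-predicted holdout-2 cases with kernel SHAP."""
    from .search import evaluate_holdout, fit_adjuster, OUTCOME_COVARIATES, FEATURE_COVARIATES
    from .search import build_sklearn_pipeline

    snp_ids = list(study.fs_map[winning_fs])
    X_all = study.genotypes.columns(snp_ids)
    y_all = study.cohort["phenotype"].to_numpy(float)
    bal = downsample_controls(study.cohort, best_run.seed)
    splits = make_splits(bal, cfg.fractions, best_run.seed)
    pos = {g: i for i, g in enumerate(bal)}
    tr = np.array([pos[i] for i in splits.train_idx])
    ho = np.array([pos[i] for i in splits.test2_idx])
    X, y = X_all[bal], y_all[bal]
    problem = "regression" if cfg.resadj else "classification"
    if cfg.resadj:
        cov_out = study.cohort.iloc[bal][OUTCOME_COVARIATES].to_numpy(float)
        cov_feat = study.cohort.iloc[bal][FEATURE_COVARIATES].to_numpy(float)
        y = fit_adjuster(y, cov_out, tr, OUTCOME_COVARIATES).apply(y, cov_out)
        X = fit_adjuster(X, cov_feat, tr, FEATURE_COVARIATES).apply(X, cov_feat)

    fitted = build_sklearn_pipeline(best_run.pipeline, problem, best_run.seed % 2**31)
    fitted.fit(X[tr], y[tr])

    if problem == "classification":
        predict_fn = lambda A: fitted.predict_proba(np.asarray(A))[:, 1]  # noqa: E731
        preds = predict_fn(X[ho])
        case_mask = None
    else:
        predict_fn = lambda A: fitted.predict(np.asarray(A))  # noqa: E731
        preds = predict_fn(X[ho])
        case_mask = y_all[bal][ho] == 1
    wp_local = select_well_predicted(preds, y[ho] if problem == "regression" else y_all[bal][ho],
                                     problem, case_mask=case_mask)
    wp_rows = ho[wp_local]

    imp = permutation_importance(
        fitted, X[ho], y[ho] if problem == "regression" else y_all[bal][ho],
        metric="accuracy" if problem == "classification" else "r2",
        n_repeats=5, seed=derive_seed(cfg.base_seed, 30),
    )
    imp.table.assign(feature=[snp_ids[j] for j in imp.table["feature"]]).to_csv(
        out / "importance.tsv", sep="\t", index=False
    )

    if cfg.k_background is not None:
        k_bg = cfg.k_background
    else:
        sub = X[tr][: min(500, len(tr))]
        k_bg, _, _ = select_k_by_dunn(
            sub, range(4, 11), seed=derive_seed(cfg.base_seed, 31)
        )
    background = kmeans_background(X[tr], k_bg, seed=derive_seed(cfg.base_seed, 32))

    m = len(snp_ids)
    n_coal = cfg.n_coalitions
    if n_coal == "auto":
        n_coal = "all" if m <= 12 else 2 * m + 256
    S = shap_matrix(
        predict_fn,
        X[wp_rows],
        background,
        seed=derive_seed(cfg.base_seed, 33),
        case_ids=[study.genotypes.sample_ids[bal[i]] for i in wp_rows],
        feature_ids=snp_ids,
        n_coalitions=n_coal,
    )
    pd.DataFrame(S.values, index=S.case_ids, columns=S.feature_ids).to_csv(
        out / "shap_matrix.tsv", sep="\t"
    )

    clusters = cluster_cases_by_shap(
        S,
        k_range=range(cfg.k_range[0], min(cfg.k_range[1], len(S.case_ids) - 1) + 1),
        seed=derive_seed(cfg.base_seed, 34),
        k_override=cfg.k_clusters,
    )
    pd.DataFrame({"case": S.case_ids, "cluster": clusters.labels}).to_csv(
        out / "clusters.tsv", sep="\t", index=False
    )
    ranking = rank_features_per_cluster(S, clusters, top_m=5)
    (out / "cluster_rankings.json").write_text(json.dumps(ranking, indent=2))
    export_force_matrix(S).to_csv(out / "force_matrix.tsv", sep="\t", index=False)

    sizes = np.bincount(clusters.labels).tolist()
    return {
        "n_well_predicted": int(len(wp_rows)),
        "k_background": int(k_bg),
        "k_clusters": int(clusters.k),
        "dunn": float(clusters.dunn),
        "cluster_sizes": sizes,
        "base_value": float(S.base_value),
        "top_union": ranking.get("top_union"),
    }


def _write_results(results, path, ledger: RunLedger, cfg, stage, permutation=None):
    if path is not None:
        with open(path, "w") as fh:
            for r in results:
                fh.write(json.dumps(r.to_dict()) + "\n")
    for r in results:
        ledger.append(
            config_hash=cfg.config_hash,
            seed=r.seed,
            stage=stage,
            permutation=permutation,
            outcome="ok" if r.error is None else "failed",
            selected_fs=r.selected_fs,
        )
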