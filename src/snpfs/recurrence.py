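"""Feature-set recurrence statistic and its target-permutation null.

With weak per-SNP signal, single-run holdout accuracy barely clears 0.5, so
the consistency with which independent search runs select the *same* feature
set becomes the inferential statistic: the maximum selection count over FSs
across runs. Its null distribution is built by permuting the phenotype
column of the full cohort (before down-sampling, so case/control totals are
preserved but assignments scramble) and repeating the entire stage per
permutation, recording each permutation's maximum count and best holdout
score. The reported p-value is the conservative add-one empirical bound
p <= (1 + #{null >= observed}) / (1 + n_permutations).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .search import RunResult, StageConfig, run_stage


@dataclass
class RecurrenceSummary:
    fs_counts: dict[str, int]
    max_count: int
    argmax_fs: list[str]  # all FSs attaining the maximum (ties reported)
    n_runs: int
    best_holdout_score: float | None


def summarize_recurrence(results: list[RunResult]) -> RecurrenceSummary:
    """Tally FS selections over successful runs; record max and best score."""
    if not results:
        raise ValueError("no run results")
    ok = [r for r in results if r.error is None and r.selected_fs is not None]
    if not ok:
        raise ValueError("all runs failed")
    counts: dict[str, int] = {}
    for r in ok:
        counts[r.selected_fs] = counts.get(r.selected_fs, 0) + 1
    mx = max(counts.values())
    scores = [
        r.holdout1_score if r.holdout1_score is not None else r.holdout2_score
        for r in ok
    ]
    scores = [s for s in scores if s is not None]
    return RecurrenceSummary(
        fs_counts=counts,
        max_count=mx,
        argmax_fs=sorted(k for k, v in counts.items() if v == mx),
        n_runs=len(results),
        best_holdout_score=max(scores) if scores else None,
    )


def permute_target(cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Uniformly permute the phenotype over all samples (pre-down-sampling).

    Covariates and genotypes are untouched; case and control totals are
    preserved. The identity permutation is redrawn, so the result always
    differs from the input ordering.
    """
    rng = np.random.default_rng(seed)
    pheno = cohort["phenotype"].to_numpy()
    n = len(pheno)
    perm = rng.permutation(n)
    while n > 1 and np.array_equal(perm, np.arange(n)):
        perm = rng.permutation(n)
    out = cohort.copy()
    out["phenotype"] = pheno[perm]
    return out


def config_hash(config: StageConfig) -> str:
    """Stable digest of the stage configuration (used to pin observed vs null)."""
    payload = {
        "n_runs": config.n_runs,
        "template": list(config.template),
        "fs_names": config.fs_map.names() if config.fs_map else None,
        "population": config.budget.population,
        "generations": config.budget.generations,
        "stage": config.stage,
        "resadj": config.resadj,
        "fractions": list(config.fractions),
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class NullDistribution:
    max_counts: list[int]
    best_scores: list[float]
    n_permutations: int
    base_seed: int
    config_digest: str = ""
    per_permutation: list[list[RunResult]] = field(default_factory=list, repr=False)


def permutation_seeds(base_seed: int, n_permutations: int, n_runs: int) -> list[list[int]]:
    """Per-permutation, per-run seeds from a documented counter scheme."""
    return [
        [
            int(np.random.SeedSequence([base_seed, p + 1, r]).generate_state(1)[0] % 2**31)
            for r in range(n_runs)
        ]
        for p in range(n_permutations)
    ]


def permutation_null(
    G: GenotypeMatrix,
    cohort: pd.DataFrame,
    stage_config: StageConfig,
    n_permutations: int = 20,
    base_seed: int = 0,
    expected_digest: str | None = None,
) -> NullDistribution:
    """Repeat the full stage on phenotype-permuted cohorts.

    The stage configuration must be identical to the observed analysis; pass
    the observed arm's ``config_hash`` as ``expected_digest`` to enforce it.
    """
    digest = config_hash(stage_config)
    if expected_digest is not None and digest != expected_digest:
        raise ValueError(
            f"null-arm config hash {digest} != observed-arm hash {expected_digest}"
        )
    seeds = permutation_seeds(base_seed, n_permutations, stage_config.n_runs)
    max_counts, best_scores, all_results = [], [], []
    for p in range(n_permutations):
        perm_seed = int(np.random.SeedSequence([base_seed, p + 1]).generate_state(1)[0] % 2**31)
        permuted = permute_target(cohort, perm_seed)
        results = run_stage(G, permuted, stage_config, seeds[p])
        summary = summarize_recurrence(results)
        max_counts.append(summary.max_count)
        best_scores.append(
            summary.best_holdout_score if summary.best_holdout_score is not None else np.nan
        )
        all_results.append(results)
    return NullDistribution(
        max_counts=max_counts,
        best_scores=best_scores,
        n_permutations=n_permutations,
        base_seed=base_seed,
        config_digest=digest,
        per_permutation=all_results,
    )


def empirical_p_upper(observed: float, null_values) -> float:
    """Conservative add-one empirical p: (1 + #{null >= obs}) / (1 + n)."""
    null_values = np.asarray(null_values, dtype=float)
    return float((1 + np.sum(null_values >= observed)) / (1 + len(null_values)))


def compare_to_null(observed: RecurrenceSummary, null: NullDistribution) -> dict:
    """Exceedance counts and add-one empirical p bounds for both statistics."""
    report = {
        "observed_max_count": observed.max_count,
        "observed_argmax_fs": observed.argmax_fs,
        "observed_best_score": observed.best_holdout_score,
        "null_max_counts": list(null.max_counts),
        "null_best_scores": [float(s) for s in null.best_scores],
        "n_permutations": null.n_permutations,
        "exceedance_max_count": int(
            np.sum(np.asarray(null.max_counts) >= observed.max_count)
        ),
        "p_upper_max_count": empirical_p_upper(observed.max_count, null.max_counts),
    }
    if observed.best_holdout_score is not None:
        finite = [s for s in null.best_scores if np.isfinite(s)]
        report["exceedance_best_score"] = int(
            np.sum(np.asarray(finite) >= observed.best_holdout_score)
        )
        report["p_upper_best_score"] = empirical_p_upper(
            observed.best_holdout_score, finite
        )
    return report
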