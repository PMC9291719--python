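"""Synthetic GWAS-like cohorts, annotations, and score tables.

Every downstream stage of the analysis (feature-set construction, pipeline
search, recurrence testing, SHAP dissection) is exercised on cohorts drawn
from an explicit generative model, since the real study population is
access-controlled. The generator emulates the statistical structure the
analysis assumes:

* biallelic dosages in [0, 2] with configurable minor-allele frequencies,
* linkage-disequilibrium blocks via a haplotype-copy chain,
* population structure (subpopulations with perturbed MAFs) that the top
  principal components of the standardized dosage matrix recover,
* a binary endpoint with small per-SNP effects and *heterogeneous* case
  subgroups — different causal SNP sets active in different latent
  subgroups — plus age/sex/PC/array covariates.

The latent subgroup labels are returned alongside the cohort for validation
purposes but are never consumed by the modelling stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import TruncatedSVD

from .containers import GenotypeMatrix

# Functionality-score thresholds used when drawing passing / failing scores.
CADD_THRESHOLD = 10.0
GWAVA_THRESHOLD = 0.5
TRAP_THRESHOLD = 0.459

SNP_TABLE_COLUMNS = ["snp_id", "chrom", "pos", "maf", "info", "cadd", "gwava", "trap"]


@dataclass
class AnnotationFixture:
    """Synthetic gene models, enhancer-gene links, and a per-SNP score table.

    ``genes``: gene_id, chrom, start, end, strand, role (druggable/connected),
    druggable_parent. ``enhancers``: gene_id, chrom, start, end, tissue.
    ``snp_table``: snp_id, chrom, pos, maf, info, cadd, gwava, trap.
    Intervals are BED-style 0-based half-open.
    """

    genes: pd.DataFrame
    enhancers: pd.DataFrame
    snp_table: pd.DataFrame

    def __post_init__(self) -> None:
        for df, what in ((self.genes, "gene"), (self.enhancers, "enhancer")):
            if len(df) and not (df["start"] < df["end"]).all():
                raise ValueError(f"{what} intervals must have start < end")
        known = set(self.genes["gene_id"])
        if len(self.enhancers) and not set(self.enhancers["gene_id"]) <= known:
            raise ValueError("every enhancer must reference a known gene")

    def write_gene_bed(self, path) -> None:
        bed = self.genes[["chrom", "start", "end", "gene_id", "role", "strand"]].copy()
        bed["druggable_parent"] = self.genes["druggable_parent"].fillna(".")
        bed.to_csv(path, sep="\t", index=False, header=False)

    def write_enhancer_bed(self, path) -> None:
        bed = self.enhancers[["chrom", "start", "end", "gene_id", "tissue"]]
        bed.to_csv(path, sep="\t", index=False, header=False)

    def write_snp_table(self, path) -> None:
        self.snp_table[SNP_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class GenerativeModel:
    """Latent-subgroup logistic model for the binary endpoint.

    Each sample belongs to one latent case subgroup; the log-odds of being a
    case add the subgroup's own causal-SNP effects (dosages centred at their
    cohort mean) to baseline and covariate terms. Disjoint causal sets across
    subgroups encode genetic heterogeneity: different SNPs drive the trait in
    different subjects.
    """

    subgroup_fractions: list[float]
    causal_sets: list[list[tuple[str, float]]]
    baseline_log_odds: float = 0.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(np.sum(self.subgroup_fractions))
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"subgroup_fractions sum to {total}, not 1")
        if len(self.causal_sets) != len(self.subgroup_fractions):
            raise ValueError("one causal set required per subgroup")

    def validate_against(self, G: GenotypeMatrix) -> None:
        known = set(G.snp_ids)
        for cs in self.causal_sets:
            missing = [s for s, _ in cs if s not in known]
            if missing:
                raise KeyError(f"causal SNPs absent from genotypes: {missing}")


def _as_snp_frame(snp_spec) -> pd.DataFrame:
    """Accept an AnnotationFixture, a snp_table-like frame, or a MAF array."""
    if isinstance(snp_spec, AnnotationFixture):
        df = snp_spec.snp_table
    elif isinstance(snp_spec, pd.DataFrame):
        df = snp_spec
    else:
        mafs = np.asarray(snp_spec, dtype=float)
        df = pd.DataFrame(
            {
                "snp_id": [f"rs{i:06d}" for i in range(len(mafs))],
                "chrom": "1",
                "pos": np.arange(len(mafs)) * 1000,
                "maf": mafs,
            }
        )
    if "chrom" in df.columns and "pos" in df.columns:
        df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return df


def simulate_genotypes(
    n_samples: int,
    snp_spec,
    ld_block_size: int = 10,
    ld_rho: float = 0.3,
    n_subpops: int = 1,
    seed: int = 0,
    subpop_maf_shift: float = 0.05,
) -> GenotypeMatrix:
    """Draw a dosage matrix with LD blocks and optional population structure.

    Each sample carries two haplotypes. Within an LD block a haplotype's
    latent uniform is copied from the previous SNP with probability
    ``ld_rho`` and redrawn otherwise; thresholding the uniform at each SNP's
    allele frequency yields alleles with exact marginal MAFs and adjacent
    correlation ~ ``ld_rho``. Blocks never span a chromosome boundary.
    Subpopulations perturb every MAF by ±``subpop_maf_shift`` (random sign
    per SNP and subpopulation), which the top principal components of the
    standardized dosages recover.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not 0 <= ld_rho < 1:
        raise ValueError("ld_rho must lie in [0, 1)")
    snps = _as_snp_frame(snp_spec)
    mafs = snps["maf"].to_numpy(dtype=float)
    if (mafs <= 0).any() or (mafs > 0.5).any():
        raise ValueError("MAFs must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    m = len(mafs)

    # Block starts: every ld_block_size SNPs, restarting at chromosome changes.
    chroms = snps["chrom"].astype(str).to_numpy() if "chrom" in snps else np.repeat("1", m)
    fresh = np.zeros(m, dtype=bool)
    fresh[0] = True
    run = 0
    for j in range(1, m):
        run += 1
        if chroms[j] != chroms[j - 1] or run >= ld_block_size:
            fresh[j] = True
            run = 0

    # Per-subpopulation allele frequencies.
    sizes = np.full(n_subpops, n_samples // n_subpops)
    sizes[: n_samples % n_subpops] += 1
    pop_mafs = np.tile(mafs, (n_subpops, 1))
    if n_subpops > 1:
        signs = rng.choice([-1.0, 1.0], size=(n_subpops, m))
        pop_mafs = np.clip(pop_mafs + subpop_maf_shift * signs, 0.005, 0.995)

    dosage = np.empty((n_samples, m))
    row = 0
    for k in range(n_subpops):
        n_hap = 2 * sizes[k]
        u = np.empty((n_hap, m))
        u[:, 0] = rng.random(n_hap)
        for j in range(1, m):
            fresh_draw = rng.random(n_hap)
            if fresh[j]:
                u[:, j] = fresh_draw
            else:
                copy = rng.random(n_hap) < ld_rho
                u[:, j] = np.where(copy, u[:, j - 1], fresh_draw)
        alleles = (u < pop_mafs[k]).astype(float)
        dosage[row : row + sizes[k]] = alleles[: sizes[k]] + alleles[sizes[k] :]
        row += sizes[k]

    sample_ids = [f"S{i:06d}" for i in range(n_samples)]
    return GenotypeMatrix(sample_ids, snps["snp_id"].tolist(), dosage)


def genotype_pcs(G: GenotypeMatrix, n_components: int = 10, seed: int = 0) -> np.ndarray:
    """Principal components of the standardized dosage matrix (truncated SVD),
    mimicking consortium-supplied genetic PCs."""
    X = G.dosage
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    k = min(n_components, min(Z.shape) - 1)
    svd = TruncatedSVD(n_components=k, random_state=seed)
    pcs = svd.fit_transform(Z)
    if k < n_components:
        pcs = np.hstack([pcs, np.zeros((Z.shape[0], n_components - k))])
    return pcs


def _linear_predictor(model: GenerativeModel, G: GenotypeMatrix, cov_terms: np.ndarray | None):
    """Per-sample, per-subgroup log-odds matrix (n_samples x n_subgroups)."""
    n = G.n_samples
    eta = np.full((n, len(model.causal_sets)), model.baseline_log_odds)
    for g, causal in enumerate(model.causal_sets):
        for snp_id, beta in causal:
            col = G.columns([snp_id])[:, 0]
            eta[:, g] += beta * (col - col.mean())
    if cov_terms is not None:
        eta += cov_terms[:, None]
    return eta


def simulate_phenotype(
    G: GenotypeMatrix, model: GenerativeModel
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assign latent subgroups and draw the binary endpoint plus covariates.

    Returns ``(cohort, subgroups)``. The cohort table carries sample_id,
    phenotype, age, sex, pc1..pc10 (computed from the genotypes), and the
    genotyping-array indicator. ``subgroups`` holds the latent labels, kept
    out of the cohort table so the modelling stages cannot see them.
    """
    model.validate_against(G)
    rng = np.random.default_rng(model.seed)
    n = G.n_samples

    age = rng.normal(57.0, 8.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    array = rng.integers(0, 2, size=n).astype(float)
    pcs = genotype_pcs(G, 10, seed=model.seed)

    std = {
        "age": (age - age.mean()) / age.std(),
        "sex": sex - sex.mean(),
        "array": array - array.mean(),
    }
    for i in range(10):
        col = pcs[:, i]
        std[f"pc{i + 1}"] = (col - col.mean()) / (col.std() or 1.0)
    cov_terms = np.zeros(n)
    for name, effect in model.covariate_effects.items():
        if name not in std:
            raise KeyError(f"unknown covariate {name!r}")
        cov_terms += effect * std[name]

    subgroups = rng.choice(len(model.subgroup_fractions), size=n, p=model.subgroup_fractions)
    eta = _linear_predictor(model, G, cov_terms)
    p_case = 1.0 / (1.0 + np.exp(-eta[np.arange(n), subgroups]))
    phenotype = (rng.random(n) < p_case).astype(int)

    cohort = pd.DataFrame({"sample_id": G.sample_ids, "phenotype": phenotype})
    cohort["age"] = age
    cohort["sex"] = sex
    for i in range(10):
        cohort[f"pc{i + 1}"] = pcs[:, i]
    cohort["array"] = array
    return cohort, subgroups


def bayes_accuracy(
    model: GenerativeModel, G: GenotypeMatrix, cohort: pd.DataFrame | None = None
) -> float:
    """Expected accuracy of the Bayes classifier under the generative model.

    The classifier observes dosages (and covariates, when a cohort is given;
    covariate terms are taken at their expectation of zero otherwise) but not
    the latent subgroup, so the case probability marginalizes over subgroups
    with the prior fractions. The value is the average of max(p, 1-p).
    """
    model.validate_against(G)
    cov_terms = None
    if cohort is not None and model.covariate_effects:
        std = {}
        age = cohort["age"].to_numpy(float)
        std["age"] = (age - age.mean()) / age.std()
        std["sex"] = cohort["sex"].to_numpy(float) - cohort["sex"].mean()
        std["array"] = cohort["array"].to_numpy(float) - cohort["array"].mean()
        for i in range(10):
            col = cohort[f"pc{i + 1}"].to_numpy(float)
            std[f"pc{i + 1}"] = (col - col.mean()) / (col.std() or 1.0)
        cov_terms = np.zeros(len(cohort))
        for name, effect in model.covariate_effects.items():
            cov_terms += effect * std[name]
    eta = _linear_predictor(model, G, cov_terms)
    p = (1.0 / (1.0 + np.exp(-eta)) * np.asarray(model.subgroup_fractions)).sum(axis=1)
    return float(np.maximum(p, 1.0 - p).mean())


def bayes_predict(model: GenerativeModel, G: GenotypeMatrix) -> np.ndarray:
    """Marginal case probability per sample (covariates at expectation)."""
    eta = _linear_predictor(model, G, None)
    return (1.0 / (1.0 + np.exp(-eta)) * np.asarray(model.subgroup_fractions)).sum(axis=1)


@dataclass
class ScoreModel:
    """Distributions for the per-SNP score table.

    ``pass_fraction`` is the probability that a SNP receives at least one
    functionality score above its threshold (CADD >= 10, GWAVA >= 0.5, or
    TraP >= 0.459); the remaining SNPs draw all three below threshold.
    MAF and imputation-info ranges control the QC-filter pass rate.
    """

    pass_fraction: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    info_range: tuple[float, float] = (0.92, 1.0)


def simulate_annotations(
    n_druggable: int = 2,
    connected_per_druggable: int = 5,
    snps_per_gene: int = 10,
    score_distributions: ScoreModel | None = None,
    seed: int = 0,
    enhancer_fraction: float = 0.25,
) -> AnnotationFixture:
    """Lay out druggable genes, connected genes, enhancers, and scored SNPs.

    Each druggable gene gets ``connected_per_druggable`` connected genes;
    every gene receives ``snps_per_gene`` SNPs, of which ~``enhancer_fraction``
    fall in a 1 kb enhancer 40 kb downstream of the gene (label E after
    mapping) and the rest in the gene body (label B). Genes are spaced 200 kb
    apart so extended intervals never collide.
    """
    if min(n_druggable, connected_per_druggable, snps_per_gene) <= 0:
        raise ValueError("all counts must be positive")
    cfg = score_distributions or ScoreModel()
    rng = np.random.default_rng(seed)

    genes, enhancers, snp_rows = [], [], []
    gene_len, spacing, enh_offset, enh_len = 20_000, 200_000, 40_000, 1_000
    snp_counter = 0
    for d in range(n_druggable):
        chrom = str(d % 22 + 1)
        dg_id = f"DG{d:02d}"
        members = [(dg_id, "druggable", None)]
        for c in range(connected_per_druggable):
            members.append((f"{dg_id}_CG{c:02d}", "connected", dg_id))
        for g, (gene_id, role, parent) in enumerate(members):
            start = 50_000 + g * spacing + d * 17  # small jitter across chroms
            end = start + gene_len
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append((gene_id, chrom, start, end, strand, role, parent))
            enh_start = end + enh_offset
            enhancers.append((gene_id, chrom, enh_start, enh_start + enh_len, "heart"))
            n_enh = int(round(enhancer_fraction * snps_per_gene))
            body_pos = rng.integers(start, end, size=snps_per_gene - n_enh)
            enh_pos = rng.integers(enh_start, enh_start + enh_len, size=n_enh)
            for pos in np.concatenate([body_pos, enh_pos]):
                passes = rng.random() < cfg.pass_fraction
                cadd = rng.uniform(0, CADD_THRESHOLD - 0.1)
                gwava = rng.uniform(0, GWAVA_THRESHOLD - 0.01)
                trap = rng.uniform(0, TRAP_THRESHOLD - 0.001)
                if passes:
                    which = rng.integers(0, 3)
                    if which == 0:
                        cadd = rng.uniform(CADD_THRESHOLD, 35.0)
                    elif which == 1:
                        gwava = rng.uniform(GWAVA_THRESHOLD, 1.0)
                    else:
                        trap = rng.uniform(TRAP_THRESHOLD, 1.0)
                snp_rows.append(
                    (
                        f"rs{snp_counter:06d}",
                        chrom,
                        int(pos),
                        rng.uniform(*cfg.maf_range),
                        rng.uniform(*cfg.info_range),
                        round(cadd, 3),
                        round(gwava, 4),
                        round(trap, 4),
                    )
                )
                snp_counter += 1

    genes_df = pd.DataFrame(
        genes, columns=["gene_id", "chrom", "start", "end", "strand", "role", "druggable_parent"]
    )
    enh_df = pd.DataFrame(enhancers, columns=["gene_id", "chrom", "start", "end", "tissue"])
    snp_df = pd.DataFrame(snp_rows, columns=SNP_TABLE_COLUMNS)
    snp_df = snp_df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return AnnotationFixture(genes_df, enh_df, snp_df)
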