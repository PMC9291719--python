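"""Biologically grouped SNP feature sets.

SNPs are mapped to genes through extended gene bodies (promoter window
included) and enhancer-gene links, filtered on QC (MAF, imputation info) and
functionality scores (CADD / GWAVA / TraP, any-of), LD-pruned on dosage r²,
and assembled into one feature set (FS) per (druggable gene, connected gene)
pair: the union of both genes' retained SNPs. By construction any two FSs of
the same druggable gene share all of that gene's SNPs.

All intervals are BED-style 0-based half-open; a SNP position is the
single-base interval [pos, pos+1), so a SNP at an interval's end coordinate
is outside it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

# Default filter thresholds.
MAF_MIN = 0.01
INFO_MIN = 0.9
CADD_MIN = 10.0
GWAVA_MIN = 0.5
TRAP_MIN = 0.459
R2_MAX = 0.8


class MissingScoreError(ValueError):
    """A SNP record lacks a field a filter needs."""


class ChromosomeStyleError(ValueError):
    """Mixed chromosome naming conventions (chr1 vs 1) in one comparison."""


def _check_chrom_style(a, b) -> None:
    a_chr = str(a).startswith("chr")
    b_chr = str(b).startswith("chr")
    if a_chr != b_chr:
        raise ChromosomeStyleError(
            f"chromosome naming mismatch: {a!r} vs {b!r}; harmonize before mapping"
        )


def extend_gene_intervals(
    genes: pd.DataFrame,
    upstream: int = 5000,
    downstream: int = 1000,
    strand_aware: bool = True,
) -> pd.DataFrame:
    """Extend each gene body by a promoter window around the TSS.

    The extended interval is the union of the gene body and
    [TSS - upstream, TSS + downstream) in strand-oriented coordinates (TSS is
    ``start`` on +, ``end`` on -; on - the upstream direction points right).
    Start positions are clipped at 0. With ``strand_aware=False`` every gene
    is treated as + strand.
    """
    out = genes.copy()
    starts, ends = [], []
    for rec in genes.itertuples(index=False):
        strand = rec.strand if strand_aware else "+"
        if strand == "+":
            s, e = rec.start - upstream, max(rec.end, rec.start + downstream)
        elif strand == "-":
            s, e = min(rec.start, rec.end - downstream), rec.end + upstream
        else:
            raise ValueError(f"unknown strand {rec.strand!r} for gene {rec.gene_id}")
        starts.append(max(0, s))
        ends.append(e)
    out["start"], out["end"] = starts, ends
    return out


def map_snps_to_gene(
    snps: pd.DataFrame, gene_interval, enhancers: pd.DataFrame
) -> pd.DataFrame:
    """Label SNPs falling in one gene's extended body (B) or enhancers (E).

    ``gene_interval`` is a row (or namedtuple) with chrom/start/end/gene_id.
    A SNP inside both body and an enhancer is labelled B; SNPs in neither are
    excluded. Half-open semantics: pos == end is outside.
    """
    g = gene_interval
    rows = []
    enh = enhancers[enhancers["gene_id"] == g.gene_id] if len(enhancers) else enhancers
    for snp in snps.itertuples(index=False):
        _check_chrom_style(snp.chrom, g.chrom)
        label = None
        if str(snp.chrom) == str(g.chrom) and g.start <= snp.pos < g.end:
            label = "B"
        else:
            for e in enh.itertuples(index=False):
                _check_chrom_style(snp.chrom, e.chrom)
                if str(snp.chrom) == str(e.chrom) and e.start <= snp.pos < e.end:
                    label = "E"
                    break
        if label:
            rows.append((g.gene_id, snp.snp_id, label, snp.pos, str(snp.chrom)))
    return pd.DataFrame(rows, columns=["gene_id", "snp_id", "region", "pos", "chrom"])


def build_snp_gene_map(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    enhancers: pd.DataFrame,
    upstream: int = 5000,
    downstream: int = 1000,
) -> pd.DataFrame:
    """Map every SNP to every gene whose extended body or enhancers contain it."""
    extended = extend_gene_intervals(genes, upstream, downstream)
    parts = [map_snps_to_gene(snps, g, enhancers) for g in extended.itertuples(index=False)]
    if not parts:
        return pd.DataFrame(columns=["gene_id", "snp_id", "region", "pos", "chrom"])
    return pd.concat(parts, ignore_index=True)


def _require(snps: pd.DataFrame, cols: list[str], allow_partial: bool = False) -> None:
    missing_cols = [c for c in cols if c not in snps.columns]
    if missing_cols:
        raise MissingScoreError(f"score table lacks columns: {missing_cols}")
    na = snps[cols].isna()
    bad = na.all(axis=1) if allow_partial else na.any(axis=1)
    if bad.any():
        which = snps.loc[bad, "snp_id"].tolist()[:5]
        raise MissingScoreError(f"SNPs with missing required scores: {which}")


def filter_snps_qc(
    snps: pd.DataFrame, maf_min: float = MAF_MIN, info_min: float = INFO_MIN
) -> pd.DataFrame:
    """Retain SNPs with MAF and imputation info strictly above threshold."""
    _require(snps, ["maf", "info"])
    keep = (snps["maf"] > maf_min) & (snps["info"] > info_min)
    return snps[keep].reset_index(drop=True)


def filter_snps_by_scores(
    snps: pd.DataFrame,
    cadd_min: float = CADD_MIN,
    gwava_min: float = GWAVA_MIN,
    trap_min: float = TRAP_MIN,
) -> pd.DataFrame:
    """Retain SNPs passing any functionality scorer (inclusive thresholds).

    An absent (NaN) score simply fails its condition; a SNP with all three
    scores missing is rejected as unscorable.
    """
    _require(snps, ["cadd", "gwava", "trap"], allow_partial=True)
    keep = (
        (snps["cadd"] >= cadd_min).fillna(False)
        | (snps["gwava"] >= gwava_min).fillna(False)
        | (snps["trap"] >= trap_min).fillna(False)
    )
    return snps[keep].reset_index(drop=True)


def ld_prune(
    G: GenotypeMatrix, snp_order: list[str] | None = None, r2_max: float = R2_MAX
) -> list[str]:
    """Greedy LD pruning on squared Pearson correlation of dosages.

    Scanning in ``snp_order`` (genomic order of the matrix by default), a SNP
    is retained iff its r² with every already-retained SNP is <= ``r2_max``.
    Zero-variance columns are uncorrelated by convention: retained, logged.
    """
    order = list(snp_order) if snp_order is not None else list(G.snp_ids)
    X = G.columns(order)
    sd = X.std(axis=0)
    mu = X.mean(axis=0)
    retained: list[int] = []
    for j in range(X.shape[1]):
        if sd[j] == 0:
            logger.warning("ld_prune: zero-variance SNP %s retained", order[j])
            retained.append(j)
            continue
        ok = True
        for i in retained:
            if sd[i] == 0:
                continue
            r = np.mean((X[:, i] - mu[i]) * (X[:, j] - mu[j])) / (sd[i] * sd[j])
            if r * r > r2_max:
                ok = False
                break
        if ok:
            retained.append(j)
    return [order[j] for j in retained]


@dataclass
class FeatureSetMap:
    """Named SNP groups: one FS per (druggable, connected) gene pair."""

    sets: dict[str, list[str]]
    genes: dict[str, tuple[str, str]] = field(default_factory=dict)  # FS -> (DG, CG)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


def build_feature_sets(snp_gene_map: pd.DataFrame, genes: pd.DataFrame) -> FeatureSetMap:
    """Assemble one FS per (druggable, connected) pair from the retained map.

    Each FS is the union of the two genes' SNPs, deduplicated and ordered by
    genomic position (snp_id breaks position ties). The filters and LD
    pruning are assumed already applied to ``snp_gene_map``.
    """
    per_gene: dict[str, pd.DataFrame] = {
        g: d for g, d in snp_gene_map.groupby("gene_id")
    }
    gene_info = genes.set_index("gene_id")
    sets: dict[str, list[str]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for rec in genes.itertuples(index=False):
        if rec.role != "connected":
            continue
        parent = rec.druggable_parent
        if parent is None or (isinstance(parent, float) and np.isnan(parent)):
            raise ValueError(f"connected gene {rec.gene_id} lacks a druggable parent")
        if parent not in gene_info.index:
            raise ValueError(f"druggable parent {parent!r} of {rec.gene_id} unknown")
        frames = [
            per_gene.get(g, pd.DataFrame(columns=snp_gene_map.columns))
            for g in (parent, rec.gene_id)
        ]
        merged = pd.concat(frames, ignore_index=True)
        merged = merged.drop_duplicates("snp_id").sort_values(
            ["chrom", "pos", "snp_id"], kind="stable"
        )
        name = f"{parent}-{rec.gene_id}"
        sets[name] = merged["snp_id"].tolist()
        meta[name] = (parent, rec.gene_id)
    return FeatureSetMap(sets, meta)


def write_fs_file(fs_map: FeatureSetMap, path) -> None:
    """Write the FS definition file: name, size, comma-separated SNP ids."""
    names = fs_map.names()
    if len(set(names)) != len(names):
        raise ValueError("duplicate FS names")
    with open(path, "w") as fh:
        fh.write("fs_name\tsize\tsnp_ids\n")
        for name in names:
            snps = fs_map[name]
            fh.write(f"{name}\t{len(snps)}\t{','.join(snps)}\n")


def read_fs_file(path) -> FeatureSetMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df["fs_name"].duplicated().any():
        raise ValueError("duplicate FS names in file")
    sets = {}
    for rec in df.itertuples(index=False):
        snps = rec.snp_ids.split(",") if isinstance(rec.snp_ids, str) and rec.snp_ids else []
        if int(rec.size) != len(snps):
            raise ValueError(f"FS {rec.fs_name}: size field {rec.size} != {len(snps)} SNPs")
        sets[rec.fs_name] = snps
    meta = {n: tuple(n.split("-", 1)) for n in sets if "-" in n}
    return FeatureSetMap(sets, meta)
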