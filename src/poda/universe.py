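"""Analysis universe: pathway-eligible SNPs/genes and per-gene SNP selection.

A SNP is *eligible* when it survives QC and maps to at least one gene that
appears in at least one pathway; a gene is eligible when it has at least one
eligible SNP.  Pathways retaining fewer than ``min_genes`` eligible genes are
dropped.  For each phenotype, every gene is represented by its single most
associated SNP, ranked by the magnitude of the Cochran-Armitage trend
statistic (scores 0/1/2), with deterministic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import GenotypeMatrix, PathwayDB, SnpGeneMap
from .phenotypes import BinaryTrait

__all__ = [
    "AnnotationUniverse",
    "GeneSnpSelection",
    "build_universe",
    "trend_test",
    "trend_test_matrix",
    "select_best_snp_per_gene",
]


@dataclass
class AnnotationUniverse:
    """Pathway-eligible SNPs and genes after QC and the >= min_genes filter."""

    eligible_snps: list[str]
    eligible_genes: list[str]
    gene_snps: dict[str, list[str]]  # gene -> sorted eligible SNP ids
    pathway_genes: dict[str, list[str]]  # retained pathway -> sorted eligible genes
    pathway_source: dict[str, str]
    dropped_pathways: set[str] = field(default_factory=set)
    min_genes: int = 5

    def summary(self) -> dict[str, int]:
        return {
            "n_eligible_snps": len(self.eligible_snps),
            "n_eligible_genes": len(self.eligible_genes),
            "n_pathways": len(self.pathway_genes),
            "n_pathways_dropped": len(self.dropped_pathways),
        }


@dataclass
class GeneSnpSelection:
    """Per-trait choice of one representative SNP per gene."""

    trait: str
    per_gene: dict[str, tuple[str, float]]  # gene -> (snp id, signed trend z)

    def snp_set_for(self, genes) -> list[str]:
        """Unique, sorted SNPs representing ``genes`` (shared SNPs dedup)."""
        return sorted({self.per_gene[g][0] for g in genes if g in self.per_gene})


def build_universe(
    g: GenotypeMatrix, m: SnpGeneMap, db: PathwayDB, min_genes: int = 5
) -> AnnotationUniverse:
    """Intersect QC-retained SNPs, the SNP->gene map, and pathway gene sets."""
    pathway_gene_universe: set[str] = set()
    for pid in db:
        pathway_gene_universe |= db[pid].genes

    snp_in_matrix = set(g.snp_ids)
    gene_snps: dict[str, set[str]] = {}
    eligible_snps: set[str] = set()
    for snp, genes in m.entries.items():
        if snp not in snp_in_matrix:
            continue
        hit = genes & pathway_gene_universe
        if not hit:
            continue
        eligible_snps.add(snp)
        for gene in hit:
            gene_snps.setdefault(gene, set()).add(snp)
    if not eligible_snps:
        raise ValueError("no QC-retained SNP maps to any pathway gene")

    eligible_genes = set(gene_snps)
    pathway_genes: dict[str, list[str]] = {}
    pathway_source: dict[str, str] = {}
    dropped: set[str] = set()
    for pid in db:
        hit = sorted(db[pid].genes & eligible_genes)
        if len(hit) >= min_genes:
            pathway_genes[pid] = hit
            pathway_source[pid] = db[pid].source
        else:
            dropped.add(pid)
    return AnnotationUniverse(
        eligible_snps=sorted(eligible_snps),
        eligible_genes=sorted(eligible_genes),
        gene_snps={g_: sorted(s) for g_, s in gene_snps.items()},
        pathway_genes=pathway_genes,
        pathway_source=pathway_source,
        dropped_pathways=dropped,
        min_genes=min_genes,
    )


def trend_test_matrix(dosage: np.ndarray, is_case: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cochran-Armitage trend test for every SNP column at once.

    Scores are the dosages themselves (0, 1, 2); missing genotypes are
    dropped per SNP.  Returns the signed normal statistic z (positive when
    the minor allele is more frequent in cases) and the two-sided p-value.
    Monomorphic columns give (0, 1).
    """
    x = np.asarray(dosage, dtype=float)
    y = np.asarray(is_case, dtype=bool)
    obs = np.isfinite(x)
    xf = np.where(obs, x, 0.0)
    n = obs.sum(axis=0).astype(float)
    r = (obs & y[:, None]).sum(axis=0).astype(float)  # cases per SNP
    t = (xf * y[:, None]).sum(axis=0)  # sum of case dosages
    sx = xf.sum(axis=0)
    sxx = (xf * xf).sum(axis=0)
    num = n * t - r * sx
    var = r * (n - r) * (n * sxx - sx * sx)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, num * np.sqrt(np.where(var > 0, n / np.maximum(var, 1e-300), 0.0)), 0.0)
    p = np.where(var > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return z, p


def trend_test(dosages: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Single-SNP Cochran-Armitage trend test; see :func:`trend_test_matrix`."""
    d = np.asarray(dosages, dtype=float).reshape(-1, 1)
    y = np.asarray(labels, dtype=bool)
    obs = np.isfinite(d[:, 0])
    if not (y[obs].any() and (~y[obs]).any()):
        raise ValueError("both classes need at least one non-missing genotype")
    z, p = trend_test_matrix(d, y)
    return float(z[0]), float(p[0])


def select_best_snp_per_gene(
    u: AnnotationUniverse, g: GenotypeMatrix, b: BinaryTrait
) -> GeneSnpSelection:
    """Pick, per eligible gene, the SNP with greatest |trend statistic|.

    Computed on the trait's case/control samples only (excluded samples do
    not influence selection).  Ties in |z| break by smaller p-value, then by
    lexicographically smaller SNP id, making selection deterministic.
    """
    included, is_case = b.mask_arrays(g.samples)
    if not (is_case[included].any() and (~is_case[included]).any()):
        raise ValueError(f"trait {b.name!r} lacks cases or controls")
    sub = g.dosage[included]
    z_all, p_all = trend_test_matrix(sub, is_case[included])
    idx = g.snp_index()
    per_gene: dict[str, tuple[str, float]] = {}
    for gene, snps in u.gene_snps.items():
        best: tuple[float, float, str] | None = None
        for snp in snps:
            j = idx.get(snp)
            if j is None:
                continue
            key = (-abs(z_all[j]), p_all[j], snp)
            if best is None or key < best:
                best = key
        if best is not None:
            snp = best[2]
            per_gene[gene] = (snp, float(z_all[idx[snp]]))
    return GeneSnpSelection(trait=b.name, per_gene=per_gene)
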