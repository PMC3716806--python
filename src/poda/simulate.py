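"""Synthetic case-control GWAS datasets with known pathway-level truth.

Genotypes are drawn in Hardy-Weinberg proportions at SNP-specific minor
allele frequencies sampled uniformly from ``maf_range``; optional
two-subpopulation structure follows the Balding-Nichols model, in which
subpopulation allele frequencies are Beta-distributed around the ancestral
frequency with variance governed by Fst.  Disease liability is additive on
the log-odds scale over the causal SNPs:

    logit P(case_i) = baseline_logodds + beta_per_snp * sum_k g_ik,

the simplest generative model under which a joint multi-SNP pathway signal
exists while each single SNP can stay individually sub-significant.  The
seven histologic columns are derived from the same liability with
independent Gaussian noise so that every trait is codeable; the
steatohepatitis diagnosis tracks the Bernoulli case draw itself (with a
small borderline fraction), NAS is the exact sum of its three component
grades, and cirrhosis is fibrosis stage 4.

Everything is reproducible from ``truth.seed``; sub-streams for genotypes,
annotation, and phenotypes are split off a single seed sequence.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    GenotypeMatrix,
    Pathway,
    PathwayDB,
    SnpGeneMap,
    write_dosage_tsv,
    write_gmt,
    write_ped_map,
    write_snp_gene_map,
)
from .phenotypes import PhenotypeTable

__all__ = [
    "PopulationStructure",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_genotypes",
    "generate_annotation",
    "generate_phenotype",
    "generate_dataset",
    "null_preset",
    "causal_preset",
    "structured_preset",
    "write_dataset",
]


@dataclass(frozen=True)
class PopulationStructure:
    """Two subpopulations under the Balding-Nichols model."""

    fst: float
    fraction_pop2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("Fst must lie in [0, 1)")
        if not (0.0 < self.fraction_pop2 < 1.0):
            raise ValueError("fraction_pop2 must lie in (0, 1)")


@dataclass
class SyntheticTruth:
    """Generating parameters carried alongside the data for recovery tests."""

    seed: int
    n_samples: int = 300
    n_snps: int = 5000
    n_genes: int = 1000
    n_pathways: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_pathway: str | None = None
    causal_snps: list[str] = field(default_factory=list)
    n_causal: int = 10
    beta_per_snp: float = 0.0
    baseline_logodds: float = 0.0
    structure: PopulationStructure | None = None
    missing_rate: float = 0.0
    pathway_size_range: tuple[int, int] = (5, 100)
    trait_noise_sd: float = 1.0
    borderline_rate: float = 0.05
    unknown_rate: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.missing_rate < 0.2):
            raise ValueError("missing_rate must lie in [0, 0.2)")
        if self.n_snps < self.n_genes:
            raise ValueError("need n_snps >= n_genes for the round-robin partition")
        if self.pathway_size_range[0] > min(self.n_genes, self.pathway_size_range[1]):
            raise ValueError("infeasible pathway_size_range for this gene count")
        if self.causal_pathway is not None and self.n_causal > self.n_genes:
            raise ValueError("more causal genes than genes")

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, default=str)


def _streams(truth: SyntheticTruth) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(int(truth.seed) & 0x7FFFFFFF)
    geno, anno, pheno = root.spawn(3)
    return {
        "genotypes": np.random.default_rng(geno),
        "annotation": np.random.default_rng(anno),
        "phenotypes": np.random.default_rng(pheno),
    }


def _snp_id(i: int) -> str:
    return f"rs{i:06d}"


def _gene_id(i: int) -> str:
    return f"GENE{i:04d}"


def population_labels(truth: SyntheticTruth) -> np.ndarray:
    """Deterministic subpopulation assignment (pop2 = trailing samples)."""
    pop = np.zeros(truth.n_samples, dtype=int)
    if truth.structure is not None:
        n2 = int(round(truth.structure.fraction_pop2 * truth.n_samples))
        if n2 > 0:
            pop[-n2:] = 1
    return pop


def generate_genotypes(truth: SyntheticTruth) -> GenotypeMatrix:
    """HWE genotypes at uniform MAFs, with optional Balding-Nichols structure
    and uniform missingness."""
    rng = _streams(truth)["genotypes"]
    n, m = truth.n_samples, truth.n_snps
    lo, hi = truth.maf_range
    maf = rng.uniform(lo, hi, size=m)
    pop = population_labels(truth)
    if truth.structure is not None and truth.structure.fst > 0:
        f = truth.structure.fst
        a, b = maf * (1 - f) / f, (1 - maf) * (1 - f) / f
        freqs = np.stack([rng.beta(a, b), rng.beta(a, b)])  # (2, m)
        p_sample = freqs[pop]  # (n, m)
    else:
        p_sample = np.broadcast_to(maf, (n, m))
    dosage = rng.binomial(2, p_sample).astype(float)
    if truth.missing_rate > 0:
        dosage[rng.random((n, m)) < truth.missing_rate] = np.nan
    samples = [f"S{i:04d}" for i in range(n)]
    return GenotypeMatrix.from_dosage(samples, [_snp_id(i) for i in range(m)], dosage)


def generate_annotation(truth: SyntheticTruth) -> tuple[SnpGeneMap, PathwayDB]:
    """Round-robin SNP->gene partition plus random gene-set pathways.

    SNP i belongs to gene (i mod n_genes), so every gene carries at least
    one SNP.  Pathway sizes are uniform over ``pathway_size_range``.  When a
    causal pathway is configured, pathway 0 is the causal one: its gene set
    is the first ``n_causal`` genes and ``truth.causal_snps`` is set to one
    SNP per causal gene (the gene's lowest-index SNP).
    """
    rng = _streams(truth)["annotation"]
    entries = {
        _snp_id(i): {_gene_id(i % truth.n_genes)} for i in range(truth.n_snps)
    }
    snp_map = SnpGeneMap(entries)

    pathways: dict[str, Pathway] = {}
    lo, hi = truth.pathway_size_range
    hi = min(hi, truth.n_genes)
    start = 0
    if truth.causal_pathway is not None:
        causal_genes = [_gene_id(i) for i in range(truth.n_causal)]
        pathways[truth.causal_pathway] = Pathway(
            name=truth.causal_pathway, source="synthetic", genes=frozenset(causal_genes)
        )
        truth.causal_snps = [_snp_id(i) for i in range(truth.n_causal)]
        start = 1
    for j in range(start, truth.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(truth.n_genes, size=size, replace=False)
        pid = f"PW{j:03d}"
        pathways[pid] = Pathway(
            name=pid, source="synthetic", genes=frozenset(_gene_id(g) for g in genes)
        )
    return snp_map, PathwayDB(pathways)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def liability(g: GenotypeMatrix, truth: SyntheticTruth) -> np.ndarray:
    """Per-sample log-odds of case status (missing causal dosages imputed at
    the SNP's mean)."""
    eta = np.full(g.n_samples, truth.baseline_logodds)
    if truth.causal_snps and truth.beta_per_snp != 0.0:
        idx = g.snp_index()
        cols = [idx[s] for s in truth.causal_snps if s in idx]
        x = g.dosage[:, cols]
        col_mean = np.nanmean(x, axis=0)
        x = np.where(np.isfinite(x), x, col_mean)
        eta = eta + truth.beta_per_snp * x.sum(axis=1)
    return eta


def generate_phenotype(g: GenotypeMatrix, truth: SyntheticTruth) -> PhenotypeTable:
    """Binary case status from the logistic liability plus six derived
    histologic columns, all codeable into the seven analysis traits."""
    rng = _streams(truth)["phenotypes"]
    n = g.n_samples
    eta = liability(g, truth)
    case = rng.random(n) < _sigmoid(eta)

    def grade(cuts: list[float]) -> np.ndarray:
        v = _sigmoid(eta + rng.normal(0.0, truth.trait_noise_sd, size=n))
        return np.digitize(v, cuts)

    steatosis = grade([0.35, 0.60, 0.85])  # 0-3
    lobular = grade([0.35, 0.60, 0.85])  # 0-3
    ballooning = grade([0.40, 0.70])  # 0-2
    # top cut chosen so ~15% of a null cohort reaches stage 4 (cirrhosis),
    # matching the prevalence seen in biopsy-proven NAFLD series
    fibrosis = grade([0.30, 0.48, 0.62, 0.75])  # 0-4
    nas = steatosis + lobular + ballooning

    dx = np.where(case, "definite", "absent").astype(object)
    dx[rng.random(n) < truth.borderline_rate] = "borderline"
    cirrhosis = np.where(fibrosis == 4, "yes", "no").astype(object)

    df = pd.DataFrame(
        {
            "steatohepatitis": dx,
            "nas": pd.array(nas, dtype="Int64"),
            "steatosis_grade": pd.array(steatosis, dtype="Int64"),
            "lobular_grade": pd.array(lobular, dtype="Int64"),
            "ballooning_grade": pd.array(ballooning, dtype="Int64"),
            "fibrosis_stage": pd.array(fibrosis, dtype="Int64"),
            "cirrhosis": cirrhosis,
        },
        index=pd.Index(g.samples, name="sample"),
    )
    if truth.unknown_rate > 0:
        for col in ("steatohepatitis", "cirrhosis", "fibrosis_stage"):
            blank = rng.random(n) < truth.unknown_rate
            df.loc[blank, col] = pd.NA
    return PhenotypeTable(df)


@dataclass
class SyntheticDataset:
    truth: SyntheticTruth
    genotypes: GenotypeMatrix
    snp_gene_map: SnpGeneMap
    pathway_db: PathwayDB
    phenotypes: PhenotypeTable


def generate_dataset(truth: SyntheticTruth) -> SyntheticDataset:
    """Draw annotation, genotypes, and phenotypes for one truth setting."""
    snp_map, db = generate_annotation(truth)  # sets truth.causal_snps
    g = generate_genotypes(truth)
    pheno = generate_phenotype(g, truth)
    return SyntheticDataset(truth, g, snp_map, db, pheno)


# ---------------------------------------------------------------------------
# Presets: the desk-scale study conditions


def null_preset(seed: int, **overrides) -> SyntheticTruth:
    """No genetic effect: 300 samples, 5,000 SNPs, 1,000 genes, 100 pathways."""
    kw = dict(seed=seed, n_samples=300, n_snps=5000, n_genes=1000, n_pathways=100)
    kw.update(overrides)
    return SyntheticTruth(**kw)


def causal_preset(
    seed: int,
    n_samples: int = 600,
    beta_per_snp: float = 0.4,
    n_causal: int = 10,
    **overrides,
) -> SyntheticTruth:
    """One causal pathway of ``n_causal`` genes, one causal SNP per gene.

    The intercept is centered at minus the expected total genetic liability
    (mean dosage per SNP is maf_lo + maf_hi under the uniform MAF draw), so
    prevalence stays near one half.
    """
    maf_range = overrides.pop("maf_range", (0.05, 0.5))
    baseline = -beta_per_snp * n_causal * (maf_range[0] + maf_range[1])
    kw = dict(
        seed=seed,
        n_samples=n_samples,
        n_snps=5000,
        n_genes=1000,
        n_pathways=100,
        maf_range=maf_range,
        causal_pathway="PW000",
        n_causal=n_causal,
        beta_per_snp=beta_per_snp,
        baseline_logodds=baseline,
    )
    kw.update(overrides)
    return SyntheticTruth(**kw)


def structured_preset(
    seed: int, fst: float = 0.2, fraction_pop2: float = 0.05, **overrides
) -> SyntheticTruth:
    """Two-subpopulation cohort for exercising the PCA screen."""
    kw = dict(
        seed=seed,
        n_samples=300,
        n_snps=5000,
        n_genes=1000,
        n_pathways=100,
        structure=PopulationStructure(fst=fst, fraction_pop2=fraction_pop2),
    )
    kw.update(overrides)
    return SyntheticTruth(**kw)


def write_dataset(ds: SyntheticDataset, outdir, genotype_format: str = "tsv") -> dict[str, Path]:
    """Write the dataset in the exact formats the readers consume."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if genotype_format == "tsv":
        paths["dosage"] = out / "dosage.tsv"
        write_dosage_tsv(ds.genotypes, paths["dosage"])
    elif genotype_format == "ped":
        paths["ped"] = out / "genotypes.ped"
        paths["map"] = out / "genotypes.map"
        write_ped_map(ds.genotypes, paths["ped"], paths["map"])
    else:
        raise ValueError("genotype_format must be 'tsv' or 'ped'")
    paths["snp_gene_map"] = out / "snp_gene_map.tsv"
    write_snp_gene_map(ds.snp_gene_map, paths["snp_gene_map"])
    paths["gmt"] = out / "pathways.gmt"
    write_gmt(ds.pathway_db, paths["gmt"])
    paths["phenotypes"] = out / "phenotypes.csv"
    from .phenotypes import write_phenotype_csv

    write_phenotype_csv(ds.phenotypes, paths["phenotypes"])
    paths["truth"] = out / "truth.json"
    ds.truth.to_json(paths["truth"])
    return paths
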