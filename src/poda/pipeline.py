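"""End-to-end orchestration: QC -> universe -> per-trait selection -> PoDA ->
statistics -> reports.

Stages run in a fixed order and every output carries the configuration hash
and seed, so identical config + inputs give identical outputs.  Per-trait
analyses share no mutable state; row order in every table is fixed by a
deterministic sort, so the results do not depend on execution order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .core import PodaEngine
from .io import (
    GenotypeMatrix,
    PathwayDB,
    SnpGeneMap,
    read_dosage_tsv,
    read_gmt,
    read_ped_map,
    read_snp_gene_map,
)
from .phenotypes import TRAITS, BinaryTrait, PhenotypeTable, code_trait, read_phenotype_csv
from .qc import QcReport, filter_snps, pca_screen, stratification_check
from .stats import PodaResult, assemble_results, cross_trait_overlap, logistic_or
from .universe import AnnotationUniverse, build_universe

__all__ = ["RunConfig", "PipelineRun", "validate_config", "run_pipeline", "analyze_trait"]


@dataclass
class RunConfig:
    """All inputs and thresholds for one pipeline run."""

    # inputs (dosage TSV or PED/MAP; exactly one genotype source)
    dosage_tsv: str | None = None
    ped: str | None = None
    map: str | None = None
    phenotypes: str | None = None
    snp_gene_map: str | None = None
    gmt: str | None = None
    outdir: str | None = None
    # analysis settings
    traits: tuple[str, ...] = TRAITS
    hwe_p: float = 1e-8
    min_maf: float = 0.02
    pca_sd: float = 6.0
    pca_components: int = 10
    remove_pca_outliers: bool = True
    min_genes: int = 5
    resamples: int = 1000
    seed: int | None = None
    alpha_ds: float = 0.05
    or_cap: float = 10.0
    fibrosis_cut: int = 2
    dummy_match: str = "genes"
    keep_null: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "traits" in data:
            data["traits"] = tuple(data["traits"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        d = self.to_dict()
        d["traits"] = list(d["traits"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def validate_config(config: RunConfig) -> list[str]:
    """Empty list iff the configuration is runnable."""
    v: list[str] = []
    has_tsv = config.dosage_tsv is not None
    has_ped = config.ped is not None and config.map is not None
    if has_tsv == has_ped:
        v.append("exactly one genotype source required: dosage_tsv OR ped+map")
    for name in ("phenotypes", "snp_gene_map", "gmt"):
        if getattr(config, name) is None:
            v.append(f"missing input path: {name}")
    if not (0 < config.hwe_p < 1):
        v.append("hwe_p must lie in (0, 1)")
    if not (0 <= config.min_maf <= 0.5):
        v.append("min_maf must lie in [0, 0.5]")
    if config.pca_sd <= 0:
        v.append("pca_sd must be positive")
    if config.pca_components < 1:
        v.append("pca_components must be >= 1")
    if config.min_genes < 1:
        v.append("min_genes must be >= 1")
    if config.resamples < 1:
        v.append("resamples must be >= 1")
    if config.resamples > 0 and config.seed is None:
        v.append("seed is mandatory for any resampling run")
    if not (0 < config.alpha_ds < 1):
        v.append("alpha_ds must lie in (0, 1)")
    if config.or_cap <= 1:
        v.append("or_cap must exceed 1")
    if not (0 <= config.fibrosis_cut <= 4):
        v.append("fibrosis_cut must lie in [0, 4]")
    if config.dummy_match not in ("genes", "snps"):
        v.append("dummy_match must be 'genes' or 'snps'")
    unknown = set(config.traits) - set(TRAITS)
    if unknown:
        v.append(f"unknown traits: {sorted(unknown)}")
    return v


@dataclass
class PipelineRun:
    config: RunConfig
    qc_report: QcReport
    universe: AnnotationUniverse
    results: dict[str, PodaResult]
    stratification: dict[str, list[float]] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def analyze_trait(
    g: GenotypeMatrix,
    universe: AnnotationUniverse,
    trait: BinaryTrait,
    B: int,
    seed: int,
    alpha_ds: float = 0.05,
    or_cap: float = 10.0,
    dummy_match: str = "genes",
    keep_null: bool = False,
) -> PodaResult:
    """PoDA over every retained pathway for one coded trait."""
    engine = PodaEngine(g, universe, trait)
    per_pathway = []
    for pid in sorted(universe.pathway_genes):
        dres = engine.resample(
            pid, B=B, seed=seed, dummy_match=dummy_match, keep_null=keep_null
        )
        _, cols, _, _ = engine.observed(pid)
        s = engine.scores_for_cols(cols)
        lres = logistic_or(s, engine.is_case, or_cap=or_cap)
        per_pathway.append((dres, lres, universe.pathway_source.get(pid, "")))
    res = assemble_results(per_pathway, alpha_ds=alpha_ds)
    res.trait = trait.name
    return res


def _load_inputs(
    config: RunConfig,
) -> tuple[GenotypeMatrix, PhenotypeTable, SnpGeneMap, PathwayDB]:
    if config.dosage_tsv is not None:
        g = read_dosage_tsv(config.dosage_tsv)
    else:
        g = read_ped_map(config.ped, config.map)
    pheno = read_phenotype_csv(config.phenotypes)
    snp_map = read_snp_gene_map(config.snp_gene_map)
    db = read_gmt(config.gmt)
    return g, pheno, snp_map, db


def run_pipeline(config: RunConfig) -> PipelineRun:
    """Execute all stages; writes result tables when ``config.outdir`` is set."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    g, pheno, snp_map, db = _load_inputs(config)

    g, qc_report = filter_snps(g, hwe_threshold=config.hwe_p, maf_threshold=config.min_maf)
    pca = pca_screen(g, n_components=config.pca_components, sd_threshold=config.pca_sd)
    qc_report.samples_removed_pca = pca.samples_removed_pca
    qc_report.pca_scores = pca.pca_scores
    qc_report.pca_component_sd = pca.pca_component_sd
    if config.remove_pca_outliers and pca.samples_removed_pca:
        keep = [s for s in g.samples if s not in pca.samples_removed_pca]
        g = g.subset_samples(keep)

    universe = build_universe(g, snp_map, db, min_genes=config.min_genes)

    results: dict[str, PodaResult] = {}
    stratification: dict[str, list[float]] = {}
    for trait_name in config.traits:
        trait = code_trait(pheno, trait_name, fibrosis_cut=config.fibrosis_cut)
        included, is_case = trait.mask_arrays(g.samples)
        if not (is_case[included].any() and (~is_case[included]).any()):
            raise ValueError(f"trait {trait_name!r}: cases or controls empty after coding")
        scores = qc_report.pca_scores.loc[[s for s, i in zip(g.samples, included) if i]]
        stratification[trait_name] = [
            float(p) for p in stratification_check(scores.to_numpy(), is_case[included])
        ]
        results[trait_name] = analyze_trait(
            g,
            universe,
            trait,
            B=config.resamples,
            seed=int(config.seed),
            alpha_ds=config.alpha_ds,
            or_cap=config.or_cap,
            dummy_match=config.dummy_match,
            keep_null=config.keep_null,
        )

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_samples_analyzed": g.n_samples,
        "n_snps_after_qc": g.n_snps,
        "universe": universe.summary(),
        "stratification_min_p": {t: min(p) for t, p in stratification.items()},
    }
    run = PipelineRun(
        config=config,
        qc_report=qc_report,
        universe=universe,
        results=results,
        stratification=stratification,
        manifest=manifest,
    )
    if config.outdir is not None:
        _write_outputs(run)
    return run


def _write_outputs(run: PipelineRun) -> None:
    out = Path(run.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    run.qc_report.to_json(out / "qc_report.json")
    run.qc_report.write_snp_stats(out / "snp_stats.tsv")
    for trait, res in run.results.items():
        res.write_tsv(out / f"results_{trait}.tsv")
        res.write_significant_tsv(out / f"significant_{trait}.tsv")
    overlap = cross_trait_overlap(run.results, alpha_ds=run.config.alpha_ds)
    overlap.to_csv(out / "cross_trait_overlap.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(run.manifest, fh, indent=2, default=str)
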