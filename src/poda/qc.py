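"""SNP-level quality control and PCA-based sample screening.

Filters follow standard GWAS practice for case-control chips: SNPs are
removed when the 1-df chi-square Hardy-Weinberg goodness-of-fit p-value falls
below ``hwe_threshold`` (default 1e-8) or the minor allele frequency falls
below ``maf_threshold`` (default 0.02); both bounds are strict, so boundary
values are retained.  Sample screening standardizes genotypes per SNP
(center by 2f, scale by sqrt(2f(1-f)), missing set to 0 after centering),
takes the top principal components, and flags any sample whose score on any
top component exceeds ``sd_threshold`` standard deviations of that component
— the de-facto EIGENSTRAT convention, applied in a single pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix

__all__ = [
    "QcReport",
    "compute_maf",
    "maf_vector",
    "genotype_counts",
    "hwe_test",
    "hwe_test_vector",
    "filter_snps",
    "pca_screen",
    "stratification_check",
]


@dataclass
class QcReport:
    """Record of what QC removed and why."""

    snps_removed_hwe: set[str] = field(default_factory=set)
    snps_removed_maf: set[str] = field(default_factory=set)
    samples_removed_pca: set[str] = field(default_factory=set)
    per_snp_stats: pd.DataFrame | None = None  # columns: snp, maf, hwe_p
    pca_scores: pd.DataFrame | None = None  # samples x components
    pca_component_sd: np.ndarray | None = None

    def to_json(self, path) -> None:
        payload = {
            "snps_removed_hwe": sorted(self.snps_removed_hwe),
            "snps_removed_maf": sorted(self.snps_removed_maf),
            "samples_removed_pca": sorted(self.samples_removed_pca),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def write_snp_stats(self, path) -> None:
        if self.per_snp_stats is not None:
            self.per_snp_stats.to_csv(path, sep="\t", index=False)


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency of one SNP: min(f, 1-f) with
    f = sum(dosage) / (2 * non-missing count)."""
    d = np.asarray(dosages, dtype=float)
    n = np.isfinite(d).sum()
    if n == 0:
        raise ValueError("MAF undefined: all genotypes missing")
    f = np.nansum(d) / (2.0 * n)
    return float(min(f, 1.0 - f))


def maf_vector(dosage: np.ndarray) -> np.ndarray:
    """Per-SNP MAF for a samples x SNPs matrix (NaN where all-missing)."""
    n = np.isfinite(dosage).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.nansum(dosage, axis=0) / (2.0 * n)
        f = np.where(n > 0, f, np.nan)
    return np.minimum(f, 1.0 - f)


def genotype_counts(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP counts of the three genotype classes (0, 1, 2 minor copies)."""
    n0 = np.nansum(dosage == 0, axis=0)
    n1 = np.nansum(dosage == 1, axis=0)
    n2 = np.nansum(dosage == 2, axis=0)
    return n0, n1, n2


def hwe_test(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """1-df chi-square goodness-of-fit p-value against Hardy-Weinberg
    proportions at the observed allele frequency.

    Monomorphic SNPs return 1.0: no departure is testable.  The test is
    symmetric in the two homozygote counts.
    """
    return float(
        hwe_test_vector(
            np.array([n_ref_hom]), np.array([n_het]), np.array([n_alt_hom])
        )[0]
    )


def hwe_test_vector(n0: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    n0 = np.asarray(n0, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if (n0 < 0).any() or (n1 < 0).any() or (n2 < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if (n < 1).any():
        raise ValueError("HWE test needs at least one genotype")
    p = (2 * n2 + n1) / (2 * n)  # frequency of the allele counted by dosage
    q = 1.0 - p
    e0, e1, e2 = n * q * q, 2 * n * p * q, n * p * p
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(e0 > 0, (n0 - e0) ** 2 / e0, 0.0)
        chi2 = chi2 + np.where(e1 > 0, (n1 - e1) ** 2 / e1, 0.0)
        chi2 = chi2 + np.where(e2 > 0, (n2 - e2) ** 2 / e2, 0.0)
    pval = stats.chi2.sf(chi2, df=1)
    mono = (p == 0.0) | (p == 1.0)
    return np.where(mono, 1.0, pval)


def filter_snps(
    g: GenotypeMatrix,
    hwe_threshold: float = 1e-8,
    maf_threshold: float = 0.02,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop SNPs with HWE p < ``hwe_threshold`` or MAF < ``maf_threshold``.

    HWE is checked first; a SNP failing both filters is recorded under HWE.
    Returns the filtered matrix and a :class:`QcReport`.
    """
    if not (0 < hwe_threshold < 1) or not (0 < maf_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    if g.n_snps == 0 or g.n_samples == 0:
        raise ValueError("cannot QC an empty genotype matrix")
    maf = maf_vector(g.dosage)
    hwe_p = hwe_test_vector(*genotype_counts(g.dosage))
    fail_hwe = hwe_p < hwe_threshold
    fail_maf = (maf < maf_threshold) | ~np.isfinite(maf)
    snp_ids = np.asarray(g.snp_ids)
    report = QcReport(
        snps_removed_hwe=set(snp_ids[fail_hwe]),
        snps_removed_maf=set(snp_ids[~fail_hwe & fail_maf]),
        per_snp_stats=pd.DataFrame({"snp": snp_ids, "maf": maf, "hwe_p": hwe_p}),
    )
    keep = ~(fail_hwe | fail_maf)
    return g.subset_snps(keep), report


def _standardize(dosage: np.ndarray) -> np.ndarray:
    """Center by 2f, scale by sqrt(2f(1-f)), missing -> 0; drop constant SNPs."""
    n = np.isfinite(dosage).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.nansum(dosage, axis=0) / (2.0 * np.maximum(n, 1.0))
    scale = np.sqrt(2.0 * f * (1.0 - f))
    with np.errstate(invalid="ignore"):
        var = np.nanvar(dosage, axis=0)
    keep = (scale > 0) & (n > 0) & (var > 0)
    if not keep.any():
        raise ValueError("degenerate genotype matrix: every SNP is constant")
    x = (dosage[:, keep] - 2.0 * f[keep]) / scale[keep]
    return np.where(np.isfinite(x), x, 0.0)


def pca_screen(
    g: GenotypeMatrix,
    n_components: int = 10,
    sd_threshold: float = 6.0,
    max_iter: int = 5,
) -> QcReport:
    """Flag samples whose score on any top principal component exceeds
    ``sd_threshold`` standard deviations of that component.

    The per-component center and spread are estimated robustly (median and
    1.4826 x MAD, the consistent Gaussian SD estimate) and refined over the
    still-unflagged samples (up to ``max_iter`` rounds).  A naive mean/SD
    rule cannot work here: a cluster holding a fraction f of the samples can
    never exceed sqrt((1-f)/f) naive SDs on the component it creates (~4.4
    for f = 0.05), because the cluster inflates that SD itself.  The robust
    scale references the bulk instead, so diverged subgroups are flagged
    while homogeneous cohorts are untouched.  Scores for all samples are
    retained in the report for the per-phenotype stratification check.
    """
    if g.n_samples < 3 or g.n_snps < 2:
        raise ValueError("PCA screen needs >=3 samples and >=2 SNPs")
    x = _standardize(g.dosage)
    # eigen-decomposition of the n x n sample covariance of standardized data
    gram = x @ x.T
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    k = min(n_components, g.n_samples - 1, x.shape[1])
    evals = np.clip(evals[order][:k], 0.0, None)
    scores = evecs[:, order][:, :k] * np.sqrt(evals)
    # deterministic sign convention: largest-|loading| coordinate positive
    for c in range(scores.shape[1]):
        j = np.argmax(np.abs(scores[:, c]))
        if scores[j, c] < 0:
            scores[:, c] = -scores[:, c]
    flagged = np.zeros(g.n_samples, dtype=bool)
    sd = scores.std(axis=0, ddof=0)
    for _ in range(max_iter):
        keep = ~flagged
        if keep.sum() < 3:
            break
        mu = np.median(scores[keep], axis=0)
        mad = np.median(np.abs(scores[keep] - mu), axis=0)
        sd = 1.4826 * mad
        # degenerate spread (>= half the bulk identical): fall back to the SD
        plain = scores[keep].std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, plain)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.abs(scores - mu) / np.where(sd > 0, sd, np.inf)
        new = flagged | (z > sd_threshold).any(axis=1)
        if (new == flagged).all():
            break
        flagged = new
    outliers = {g.samples[i] for i in np.nonzero(flagged)[0]}
    return QcReport(
        samples_removed_pca=outliers,
        pca_scores=pd.DataFrame(
            scores, index=g.samples, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        pca_component_sd=sd,
    )


def stratification_check(scores: np.ndarray | pd.DataFrame, labels: np.ndarray) -> np.ndarray:
    """Two-sample t-test p-value per component, cases vs controls.

    A small p on a top component signals population stratification aligned
    with the phenotype.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape[0] != y.shape[0]:
        raise ValueError("scores and labels are misaligned")
    if y.all() or not y.any():
        raise ValueError("both classes must be non-empty")
    res = stats.ttest_ind(s[y], s[~y], axis=0)
    return np.atleast_1d(res.pvalue)
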