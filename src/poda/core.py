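"""Distance scores, distinction scores, and the dummy-pathway resampling null.

For a pathway represented by a set of analysis SNPs, every case/control
sample i gets a distance score

    S_i = log2(D_ctrl(i) + eps) - log2(D_case(i) + eps),

where D_case(i) / D_ctrl(i) are the mean genetic distances from i to the
remaining cases / controls (leave-one-out within the sample's own class) and
the guard eps = 1 / (2 * K * N) keeps S bounded when a leave-one-out mean
distance is zero (K analysis SNPs, N case+control samples).  The genetic
distance between two samples is the mean absolute dosage difference over
their pairwise-complete SNPs, so it lies in [0, 2].  Higher S means the
sample sits closer to the cases.

The distinction score DS is the difference of class means of S; its
significance p(DS) is the fraction of "dummy" pathways — uniform random
gene sets of the same gene count, with per-gene best-SNP selection
re-applied so the selection bias of the real statistic is preserved — whose
DS is at least the observed one.  Ties count as greater-or-equal, so p(DS)
can be exactly 0 only when every dummy falls strictly below.

Computing S is antisymmetric under case/control relabeling (every S_i is
negated bitwise, because S is a difference of two log2 terms that swap);
the distinction score of a *fixed* score set is likewise negated bitwise
when its labels are swapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from zlib import crc32

import numpy as np

from .io import GenotypeMatrix
from .phenotypes import BinaryTrait
from .universe import AnnotationUniverse, GeneSnpSelection, select_best_snp_per_gene

__all__ = [
    "DistanceScoreSet",
    "DistinctionResult",
    "pairwise_distance",
    "distance_scores",
    "distinction_score",
    "resample_pds",
    "PodaEngine",
]


@dataclass
class DistanceScoreSet:
    """Per-sample distance scores S for one pathway and trait."""

    pathway: str | None
    trait: str
    samples: list[str]
    s: np.ndarray
    is_case: np.ndarray
    snp_set: list[str]


@dataclass
class DistinctionResult:
    """Observed DS with its resampling significance."""

    pathway: str
    trait: str
    ds: float
    p_ds: float
    p_ds_corrected: float  # add-one corrected (1 + count) / (1 + B)
    n_resamples: int
    n_genes: int
    n_snps: int
    dummy_ds: np.ndarray | None = None


def pairwise_distance(x_i: np.ndarray, x_j: np.ndarray) -> float:
    """Mean absolute dosage difference over pairwise-complete SNPs."""
    a = np.asarray(x_i, dtype=float)
    b = np.asarray(x_j, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    ok = np.isfinite(a) & np.isfinite(b)
    if not ok.any():
        raise ValueError("no pairwise-complete SNP between the two samples")
    return float(np.abs(a[ok] - b[ok]).mean())


def _distance_matrix(x: np.ndarray) -> np.ndarray:
    """All-pairs mean |dosage difference| over pairwise-complete SNPs.

    Dosages take three values, so |a - b| decomposes over one-hot
    indicators and the whole matrix reduces to a handful of BLAS products;
    entries with no complete SNP are NaN.
    """
    obs = np.isfinite(x)
    a0 = (x == 0) & obs
    a1 = (x == 1) & obs
    a2 = (x == 2) & obs
    f0, f1, f2, fo = (m.astype(float) for m in (a0, a1, a2, obs))
    m01 = f0 @ f1.T
    m02 = f0 @ f2.T
    m12 = f1 @ f2.T
    dsum = m01 + m01.T + 2.0 * (m02 + m02.T) + m12 + m12.T
    count = fo @ fo.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(count > 0, dsum / np.maximum(count, 1.0), np.nan)
    return d


def _loo_class_means(d: np.ndarray, is_case: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out mean distance of every sample to cases and to controls."""
    n = d.shape[0]
    defined = np.isfinite(d)
    np.fill_diagonal(defined, False)
    dz = np.where(defined, d, 0.0)
    case_cols = is_case.astype(float)
    ctrl_cols = (~is_case).astype(float)
    sum_case = dz @ case_cols
    sum_ctrl = dz @ ctrl_cols
    cnt_case = defined @ case_cols
    cnt_ctrl = defined @ ctrl_cols
    with np.errstate(invalid="ignore", divide="ignore"):
        d_case = np.where(cnt_case > 0, sum_case / np.maximum(cnt_case, 1.0), np.nan)
        d_ctrl = np.where(cnt_ctrl > 0, sum_ctrl / np.maximum(cnt_ctrl, 1.0), np.nan)
    return d_case, d_ctrl


def _scores_from_means(
    d_case: np.ndarray, d_ctrl: np.ndarray, n_snps: int, n_samples: int
) -> np.ndarray:
    eps = 1.0 / (2.0 * n_snps * n_samples)
    # difference of logs (not log of ratio): label swap negates S bitwise
    return np.log2(d_ctrl + eps) - np.log2(d_case + eps)


def distance_scores(
    g: GenotypeMatrix, snp_set: list[str], b: BinaryTrait
) -> DistanceScoreSet:
    """Compute S for every case/control sample of the trait over ``snp_set``.

    Samples with an undefined distance to an entire class are dropped with a
    warning.  Requires at least two cases and two controls.
    """
    included, is_case_all = b.mask_arrays(g.samples)
    samples = [s for s, inc in zip(g.samples, included) if inc]
    is_case = is_case_all[included]
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError("distance scores need >=2 cases and >=2 controls")
    idx = g.snp_index()
    cols = [idx[s] for s in snp_set]
    x = g.dosage[included][:, cols]
    d = _distance_matrix(x)
    d_case, d_ctrl = _loo_class_means(d, is_case)
    ok = np.isfinite(d_case) & np.isfinite(d_ctrl)
    if not ok.all():
        bad = [samples[i] for i in np.nonzero(~ok)[0]]
        warnings.warn(
            f"excluding {len(bad)} sample(s) with undefined class distance: {bad[:5]}",
            stacklevel=2,
        )
        samples = [s for s, o in zip(samples, ok) if o]
        is_case = is_case[ok]
        d_case, d_ctrl = d_case[ok], d_ctrl[ok]
    s = _scores_from_means(d_case, d_ctrl, len(snp_set), len(samples))
    return DistanceScoreSet(
        pathway=None,
        trait=b.name,
        samples=samples,
        s=s,
        is_case=is_case,
        snp_set=list(snp_set),
    )


def distinction_score(d: DistanceScoreSet) -> float:
    """DS = mean S over cases minus mean S over controls."""
    if not d.is_case.any() or d.is_case.all():
        raise ValueError("distinction score needs both classes non-empty")
    return float(d.s[d.is_case].mean() - d.s[~d.is_case].mean())


def _pathway_rng(seed: int, pathway: str, trait: str) -> np.random.Generator:
    """Per-pathway stream: results reproducible independent of run order."""
    ss = np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, crc32(pathway.encode()), crc32(trait.encode())]
    )
    return np.random.default_rng(ss)


class PodaEngine:
    """Precomputed per-trait state for fast DS evaluation of gene sets.

    The heavy object in the resampling null: for the trait's case/control
    samples it caches each gene's best-SNP dosage column and the per-class
    genotype-value counts, so the distance sums needed for a dummy pathway
    reduce to three matrix-vector products instead of an all-pairs distance
    matrix.  Columns containing missing genotypes transparently fall back to
    the exact pairwise-complete computation.
    """

    def __init__(
        self,
        g: GenotypeMatrix,
        u: AnnotationUniverse,
        b: BinaryTrait,
        selection: GeneSnpSelection | None = None,
    ) -> None:
        if selection is None:
            selection = select_best_snp_per_gene(u, g, b)
        self.universe = u
        self.trait = b.name
        self.selection = selection
        included, is_case_all = b.mask_arrays(g.samples)
        self.samples = [s for s, inc in zip(g.samples, included) if inc]
        self.is_case = is_case_all[included]
        if self.is_case.sum() < 2 or (~self.is_case).sum() < 2:
            raise ValueError("PoDA needs >=2 cases and >=2 controls")
        self.n = len(self.samples)

        self.genes = sorted(selection.per_gene)
        self._gene_pos = {gname: i for i, gname in enumerate(self.genes)}
        snp_of_gene = [selection.per_gene[gname][0] for gname in self.genes]
        self.snp_cols = sorted(set(snp_of_gene))
        col_pos = {s: j for j, s in enumerate(self.snp_cols)}
        self.gene2col = np.array([col_pos[s] for s in snp_of_gene], dtype=np.intp)

        idx = g.snp_index()
        self.x = g.dosage[included][:, [idx[s] for s in self.snp_cols]]
        self._col_has_missing = ~np.isfinite(self.x).all(axis=0)
        # |x - v| for v in {0,1,2}; exact when no missing in the used columns
        xf = np.nan_to_num(self.x, nan=0.0)
        self._absdev = [np.abs(xf - v) for v in (0.0, 1.0, 2.0)]
        self._class_counts = {}
        for cls, mask in (("case", self.is_case), ("ctrl", ~self.is_case)):
            self._class_counts[cls] = [
                ((self.x[mask] == v) & np.isfinite(self.x[mask])).sum(axis=0).astype(float)
                for v in (0.0, 1.0, 2.0)
            ]
        n_case = int(self.is_case.sum())
        self._denom_case = np.where(self.is_case, n_case - 1, n_case).astype(float)
        self._denom_ctrl = np.where(~self.is_case, self.n - n_case - 1, self.n - n_case).astype(float)

    # -- DS evaluation -----------------------------------------------------
    def cols_for_genes(self, gene_idx: np.ndarray) -> np.ndarray:
        return np.unique(self.gene2col[gene_idx])

    def scores_for_cols(self, cols: np.ndarray) -> np.ndarray:
        """S for every sample over the unique SNP columns ``cols``."""
        k = len(cols)
        if k == 0:
            raise ValueError("empty SNP set")
        if self._col_has_missing[cols].any():
            d = _distance_matrix(self.x[:, cols])
            d_case, d_ctrl = _loo_class_means(d, self.is_case)
        else:
            sum_case = np.zeros(self.n)
            sum_ctrl = np.zeros(self.n)
            for v in range(3):
                a = self._absdev[v][:, cols]
                sum_case += a @ self._class_counts["case"][v][cols]
                sum_ctrl += a @ self._class_counts["ctrl"][v][cols]
            # self-distance is zero, so only the denominator is leave-one-out
            d_case = sum_case / (k * self._denom_case)
            d_ctrl = sum_ctrl / (k * self._denom_ctrl)
        return _scores_from_means(d_case, d_ctrl, k, self.n)

    def ds_for_cols(self, cols: np.ndarray) -> float:
        s = self.scores_for_cols(cols)
        return float(s[self.is_case].mean() - s[~self.is_case].mean())

    def pathway_gene_idx(self, pathway: str) -> np.ndarray:
        genes = self.universe.pathway_genes[pathway]
        return np.array(
            [self._gene_pos[gname] for gname in genes if gname in self._gene_pos],
            dtype=np.intp,
        )

    def observed(self, pathway: str) -> tuple[float, np.ndarray, int, int]:
        """(DS, unique SNP columns, n_genes, n_snps) for a retained pathway."""
        gene_idx = self.pathway_gene_idx(pathway)
        if gene_idx.size == 0:
            raise ValueError(f"pathway {pathway!r} has no selected genes for this trait")
        cols = self.cols_for_genes(gene_idx)
        return self.ds_for_cols(cols), cols, int(gene_idx.size), int(cols.size)

    def distance_score_set(self, pathway: str) -> DistanceScoreSet:
        _, cols, _, _ = self.observed(pathway)
        return DistanceScoreSet(
            pathway=pathway,
            trait=self.trait,
            samples=list(self.samples),
            s=self.scores_for_cols(cols),
            is_case=self.is_case.copy(),
            snp_set=[self.snp_cols[j] for j in cols],
        )

    # -- resampling --------------------------------------------------------
    def resample(
        self,
        pathway: str,
        B: int = 1000,
        seed: int = 0,
        dummy_match: str = "genes",
        keep_null: bool = False,
    ) -> DistinctionResult:
        if B < 1:
            raise ValueError("B must be >= 1")
        ds_obs, cols, n_genes, n_snps = self.observed(pathway)
        rng = _pathway_rng(seed, pathway, self.trait)
        n_pool = len(self.genes)
        dummy = np.empty(B)
        if dummy_match == "genes":
            if n_genes > n_pool:
                raise ValueError(
                    f"eligible gene universe ({n_pool}) smaller than pathway "
                    f"gene count ({n_genes})"
                )
            for t in range(B):
                gene_idx = rng.choice(n_pool, size=n_genes, replace=False)
                dummy[t] = self.ds_for_cols(self.cols_for_genes(gene_idx))
        elif dummy_match == "snps":
            n_cols = len(self.snp_cols)
            if n_snps > n_cols:
                raise ValueError("selected-SNP universe smaller than pathway SNP count")
            for t in range(B):
                c = np.sort(rng.choice(n_cols, size=n_snps, replace=False))
                dummy[t] = self.ds_for_cols(c)
        else:
            raise ValueError("dummy_match must be 'genes' or 'snps'")
        count = int((dummy >= ds_obs).sum())
        return DistinctionResult(
            pathway=pathway,
            trait=self.trait,
            ds=ds_obs,
            p_ds=count / B,
            p_ds_corrected=(1 + count) / (1 + B),
            n_resamples=B,
            n_genes=n_genes,
            n_snps=n_snps,
            dummy_ds=dummy if keep_null else None,
        )


def resample_pds(
    g: GenotypeMatrix,
    u: AnnotationUniverse,
    b: BinaryTrait,
    pathway: str,
    B: int = 1000,
    seed: int = 0,
    selection: GeneSnpSelection | None = None,
    dummy_match: str = "genes",
    keep_null: bool = False,
) -> DistinctionResult:
    """Observed DS of ``pathway`` and its p(DS) from ``B`` dummy pathways.

    Dummy pathways are uniform random gene sets (without replacement) from
    the eligible genes, matched on gene count; per-gene best-SNP selection is
    re-applied to each dummy set for the same trait.  Reproducible given
    ``seed``; each pathway draws from its own seeded stream.
    """
    if pathway not in u.pathway_genes:
        raise ValueError(f"pathway {pathway!r} not retained in the universe")
    engine = PodaEngine(g, u, b, selection=selection)
    return engine.resample(
        pathway, B=B, seed=seed, dummy_match=dummy_match, keep_null=keep_null
    )
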