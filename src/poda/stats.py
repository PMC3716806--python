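"""Per-pathway logistic odds ratios, FDR control, and results tables.

For each pathway, case status is regressed on the distance score S
(intercept + slope, maximum likelihood); the odds ratio is exp(slope) per
unit S and the p-value is the two-sided Wald test on the slope.  Perfect or
quasi-perfect separation makes the MLE diverge; such fits are flagged
non-converged, their odds ratio is displayed capped (">10" by default,
following the convention of large-OR pathway tables), and the p-value falls
back to the score test, which stays well-defined at the null.  Wald p-values
are Benjamini-Hochberg adjusted across *all* pathways analyzed for the
trait; the significance table is then filtered to p(DS) < alpha for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .core import DistinctionResult

__all__ = [
    "LogisticOrResult",
    "PodaResult",
    "logistic_or",
    "bh_fdr",
    "assemble_results",
    "cross_trait_overlap",
]

# |slope| beyond this on the logit scale is treated as a diverging fit
_SLOPE_DIVERGED = 30.0


@dataclass
class LogisticOrResult:
    odds_ratio: float
    slope: float
    p_value: float
    converged: bool
    capped: bool
    display: str


def _score_test_p(s: np.ndarray, y: np.ndarray) -> float:
    """Score test of the logistic slope at beta = 0 (defined under separation)."""
    ybar = y.mean()
    u = float(((y - ybar) * s).sum())
    v = float(ybar * (1 - ybar) * ((s - s.mean()) ** 2).sum())
    if v <= 0:
        return 1.0
    z = u / np.sqrt(v)
    return float(2.0 * sps.norm.sf(abs(z)))


def logistic_or(
    S: np.ndarray, labels: np.ndarray, or_cap: float = 10.0
) -> LogisticOrResult:
    """Odds ratio of case status per unit distance score.

    Constant S carries no information: OR 1, p 1.  Separation (or an
    estimate above ``or_cap``) yields a capped display value.
    """
    s = np.asarray(S, dtype=float)
    y = np.asarray(labels, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("distance scores must be finite")
    if not (y.any() and (1 - y).any()):
        raise ValueError("both classes must be non-empty")
    if np.ptp(s) == 0:
        return LogisticOrResult(1.0, 0.0, 1.0, True, False, "1.00")

    X = sm.add_constant(s)
    slope = np.nan
    p = np.nan
    converged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        slope = float(res.params[1])
        p = float(res.pvalues[1])
        converged = bool(res.mle_retvals.get("converged", False)) and abs(slope) < _SLOPE_DIVERGED
    except (PerfectSeparationError, np.linalg.LinAlgError):
        # diverging MLE: sign of the association from the score statistic
        slope = np.inf if ((y - y.mean()) * s).sum() > 0 else -np.inf
    if not converged or not np.isfinite(p):
        p = _score_test_p(s, y)
    orr = float(np.exp(slope)) if np.isfinite(slope) else float(np.inf)
    capped = (not converged) or orr > or_cap
    display = f">{or_cap:g}" if capped and orr > 1 else (f"<{1 / or_cap:g}" if capped else f"{orr:.2f}")
    return LogisticOrResult(orr, slope, p, converged, capped, display)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PodaResult:
    """All-pathway results for one trait, sorted by p(DS) then name."""

    trait: str
    table: pd.DataFrame
    alpha_ds: float = 0.05

    def significant(self) -> pd.DataFrame:
        """Display table: pathways with p(DS) strictly below alpha."""
        return self.table[self.table["p_ds"] < self.alpha_ds].reset_index(drop=True)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def write_significant_tsv(self, path) -> None:
        cols = ["pathway", "source", "n_genes", "n_snps", "p_ds", "or_display", "q_or"]
        self.significant()[cols].to_csv(path, sep="\t", index=False)


def assemble_results(
    per_pathway: list[tuple[DistinctionResult, LogisticOrResult, str]],
    alpha_ds: float = 0.05,
) -> PodaResult:
    """Combine resampling and regression outputs into one trait table.

    ``per_pathway`` holds (distinction result, logistic fit, source label)
    per analyzed pathway.  BH-FDR runs across every analyzed pathway — the
    multiplicity family is the whole analysis, not the displayed subset.
    """
    if not per_pathway:
        return PodaResult(trait="", table=_empty_table(), alpha_ds=alpha_ds)
    trait = per_pathway[0][0].trait
    rows = []
    for dres, lres, source in per_pathway:
        if dres.n_snps > dres.n_genes:
            raise ValueError(
                f"pathway {dres.pathway!r}: n_snps {dres.n_snps} exceeds "
                f"n_genes {dres.n_genes} (one SNP per gene is violated)"
            )
        rows.append(
            {
                "pathway": dres.pathway,
                "source": source,
                "n_genes": dres.n_genes,
                "n_snps": dres.n_snps,
                "ds": dres.ds,
                "p_ds": dres.p_ds,
                "p_ds_corrected": dres.p_ds_corrected,
                "odds_ratio": lres.odds_ratio,
                "or_display": lres.display,
                "or_p": lres.p_value,
                "or_converged": lres.converged,
            }
        )
    table = pd.DataFrame(rows)
    table["q_or"] = bh_fdr(table["or_p"].to_numpy())
    table = table.sort_values(["p_ds", "pathway"], kind="mergesort").reset_index(drop=True)
    return PodaResult(trait=trait, table=table, alpha_ds=alpha_ds)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "pathway", "source", "n_genes", "n_snps", "ds", "p_ds",
            "p_ds_corrected", "odds_ratio", "or_display", "or_p",
            "or_converged", "q_or",
        ]
    )


def cross_trait_overlap(results: dict[str, PodaResult], alpha_ds: float = 0.05) -> pd.DataFrame:
    """Pathway x trait incidence of significance, for pathways significant in
    two or more traits (a join of the per-trait significant tables)."""
    hits: dict[str, dict[str, object]] = {}
    for trait, res in results.items():
        sig = res.table[res.table["p_ds"] < alpha_ds]
        for _, row in sig.iterrows():
            rec = hits.setdefault(
                row["pathway"],
                {
                    "pathway": row["pathway"],
                    "source": row["source"],
                    "n_genes": row["n_genes"],
                    "n_snps": row["n_snps"],
                },
            )
            rec[trait] = "yes"
    df = pd.DataFrame(list(hits.values()))
    if df.empty:
        return df
    trait_cols = [t for t in results if t in df.columns]
    for t in trait_cols:
        df[t] = df[t].fillna("")
    df["n_phenotypes"] = (df[trait_cols] == "yes").sum(axis=1)
    df = df[df["n_phenotypes"] >= 2]
    return df.sort_values(
        ["n_phenotypes", "pathway"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
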