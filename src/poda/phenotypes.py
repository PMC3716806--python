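"""Histologic phenotype table and its binary case/control codings.

The seven analysis traits are dichotomizations of the NASH CRN scoring
system: steatohepatitis diagnosis (definite vs absent, borderline excluded),
NAFLD activity score (NAS >= 5 vs < 5), steatosis grade (2-3 vs <2), lobular
inflammation grade (2-3 vs 0-1), hepatocyte ballooning (grade 2 vs grade 0,
grade 1 excluded), fibrosis stage (>= cut vs < cut, cut defaults to 2), and
cirrhosis (yes vs no).  Unknown values are excluded everywhere; excluded
samples never enter downstream computation for that trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TRAITS",
    "PhenotypeTable",
    "BinaryTrait",
    "read_phenotype_csv",
    "write_phenotype_csv",
    "code_trait",
    "trait_summary",
]

TRAITS = (
    "steatohepatitis",
    "nas",
    "steatosis",
    "lobular",
    "ballooning",
    "fibrosis",
    "cirrhosis",
)

_COLUMNS = {
    "steatohepatitis": ("definite", "borderline", "absent"),
    "nas": range(0, 9),
    "steatosis_grade": range(0, 4),
    "lobular_grade": range(0, 4),
    "ballooning_grade": range(0, 3),
    "fibrosis_stage": range(0, 5),
    "cirrhosis": ("yes", "no"),
}

CASE, CONTROL, EXCLUDED = "case", "control", "excluded"


@dataclass
class PhenotypeTable:
    """Per-sample histologic grades/stages; index is the sample id.

    Columns: ``steatohepatitis`` (definite/borderline/absent), ``nas`` (0-8),
    ``steatosis_grade`` (0-3), ``lobular_grade`` (0-3), ``ballooning_grade``
    (0-2), ``fibrosis_stage`` (0-4), ``cirrhosis`` (yes/no).  Unknowns are NA.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns: {missing}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids in phenotype table")
        for col, domain in _COLUMNS.items():
            vals = self.data[col].dropna()
            allowed = set(domain)
            bad = [v for v in vals.unique() if v not in allowed]
            if bad:
                raise ValueError(f"column {col!r}: values {bad!r} outside {sorted(allowed)}")
        # NAS must equal the sum of its three named components where all known
        comp = self.data[["steatosis_grade", "lobular_grade", "ballooning_grade"]]
        have_all = comp.notna().all(axis=1) & self.data["nas"].notna()
        expect = comp.loc[have_all].sum(axis=1)
        mismatch = self.data.loc[have_all, "nas"] != expect
        if mismatch.any():
            sid = mismatch[mismatch].index[0]
            raise ValueError(
                f"sample {sid!r}: NAS does not equal steatosis + lobular + "
                "ballooning grades"
            )

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.data.index]


@dataclass
class BinaryTrait:
    """A coded case/control phenotype: sample id -> case/control/excluded."""

    name: str
    labels: pd.Series  # values in {case, control, excluded}

    def mask_arrays(self, samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """(included, is_case) boolean arrays aligned with ``samples``."""
        lab = self.labels.reindex(samples).fillna(EXCLUDED)
        included = (lab != EXCLUDED).to_numpy()
        is_case = (lab == CASE).to_numpy()
        return included, is_case

    @property
    def n_cases(self) -> int:
        return int((self.labels == CASE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.labels == CONTROL).sum())


def read_phenotype_csv(path) -> PhenotypeTable:
    df = pd.read_csv(path, index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    for col in ("nas", "steatosis_grade", "lobular_grade", "ballooning_grade", "fibrosis_stage"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise").astype("Int64")
    for col in ("steatohepatitis", "cirrhosis"):
        if col in df.columns:
            df[col] = df[col].where(df[col].notna(), pd.NA)
    return PhenotypeTable(df)


def write_phenotype_csv(t: PhenotypeTable, path) -> None:
    out = t.data.copy()
    out.index.name = "sample"
    out.to_csv(path)


def _grade_code(values: pd.Series, case_pred, control_pred) -> pd.Series:
    lab = pd.Series(EXCLUDED, index=values.index, dtype=object)
    known = values.notna()
    lab[known & case_pred(values)] = CASE
    lab[known & control_pred(values)] = CONTROL
    return lab


def code_trait(t: PhenotypeTable, trait_name: str, fibrosis_cut: int = 2) -> BinaryTrait:
    """Dichotomize one of the seven traits.

    ``fibrosis_cut`` moves the fibrosis case threshold (case = stage >= cut);
    the default of 2 contrasts any significant fibrosis against none/mild.
    """
    d = t.data
    if trait_name == "steatohepatitis":
        v = d["steatohepatitis"]
        lab = pd.Series(EXCLUDED, index=d.index, dtype=object)
        lab[v == "definite"] = CASE
        lab[v == "absent"] = CONTROL
    elif trait_name == "nas":
        lab = _grade_code(d["nas"], lambda v: v >= 5, lambda v: v < 5)
    elif trait_name == "steatosis":
        lab = _grade_code(d["steatosis_grade"], lambda v: v >= 2, lambda v: v < 2)
    elif trait_name == "lobular":
        lab = _grade_code(d["lobular_grade"], lambda v: v >= 2, lambda v: v <= 1)
    elif trait_name == "ballooning":
        lab = _grade_code(d["ballooning_grade"], lambda v: v == 2, lambda v: v == 0)
    elif trait_name == "fibrosis":
        lab = _grade_code(
            d["fibrosis_stage"], lambda v: v >= fibrosis_cut, lambda v: v < fibrosis_cut
        )
    elif trait_name == "cirrhosis":
        v = d["cirrhosis"]
        lab = pd.Series(EXCLUDED, index=d.index, dtype=object)
        lab[v == "yes"] = CASE
        lab[v == "no"] = CONTROL
    else:
        raise ValueError(f"unknown trait {trait_name!r}; expected one of {TRAITS}")
    return BinaryTrait(name=trait_name, labels=lab)


def trait_summary(b: BinaryTrait) -> tuple[int, int, int]:
    """(n_cases, n_controls, n_excluded); sums to the sample count."""
    vc = b.labels.value_counts()
    return (
        int(vc.get(CASE, 0)),
        int(vc.get(CONTROL, 0)),
        int(vc.get(EXCLUDED, 0)),
    )
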