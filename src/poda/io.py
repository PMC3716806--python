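"""Readers and writers for genotype, annotation, and gene-set files.

Supported formats are deliberately plain-text: PLINK PED/MAP, a 0/1/2 dosage
TSV, two-column SNP->gene TSV, and GMT gene sets.  Dosages always count copies
of the cohort *minor* allele, determined from observed allele frequencies at
load time (ties at 0.5 broken by alphabetical allele order), so that the MAF
filter and the distance metric downstream are orientation-free.  Missing
genotypes ("0 0" in PED, "NA" in TSV) are kept as NaN and handled
pairwise-complete downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GenotypeMatrix",
    "SnpGeneMap",
    "Pathway",
    "PathwayDB",
    "read_ped_map",
    "write_ped_map",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_gmt",
    "write_gmt",
    "read_snp_gene_map",
    "write_snp_gene_map",
]


class FormatError(ValueError):
    """Malformed input file (bad column count, out-of-domain cell, ...)."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosage matrix with metadata.

    Parameters
    ----------
    samples
        Ordered sample identifiers (unique).
    snps
        DataFrame with columns ``snp``, ``chrom``, ``pos``, ``minor``,
        ``major`` — one row per SNP, in column order of ``dosage``.
    dosage
        ``(n_samples, n_snps)`` float array with values in {0, 1, 2, NaN},
        counting copies of the minor allele.
    """

    samples: list[str]
    snps: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids are not unique")
        ids = self.snps["snp"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"SNP ids are not unique (e.g. {dup!r})")
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage value {bad!r} outside {{0,1,2,NaN}}")

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return self.snps["snp"].tolist()

    def snp_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.snps["snp"])}

    @classmethod
    def from_dosage(
        cls, samples: list[str], snp_ids: list[str], dosage: np.ndarray
    ) -> "GenotypeMatrix":
        """Build a matrix with placeholder SNP metadata (chrom 0, pos 0)."""
        meta = pd.DataFrame(
            {
                "snp": list(snp_ids),
                "chrom": "0",
                "pos": 0,
                "minor": "A",
                "major": "B",
            }
        )
        return cls(list(samples), meta, dosage)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Column subset by boolean mask or integer index array."""
        meta = self.snps.iloc[keep].reset_index(drop=True)
        return GenotypeMatrix(list(self.samples), meta, self.dosage[:, keep])

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in keep]
        return GenotypeMatrix(list(keep), self.snps.copy(), self.dosage[idx])


@dataclass
class SnpGeneMap:
    """SNP id -> set of gene symbols."""

    entries: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for snp, genes in self.entries.items():
            if not genes or any(not g for g in genes):
                raise ValueError(f"SNP {snp!r} has an empty gene set or gene symbol")

    def genes_for(self, snp: str) -> set[str]:
        return self.entries.get(snp, set())


@dataclass(frozen=True)
class Pathway:
    name: str
    source: str
    genes: frozenset[str]


@dataclass
class PathwayDB:
    """Pathway id -> (name, source label, gene set)."""

    pathways: dict[str, Pathway] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, pw in self.pathways.items():
            if not pw.genes:
                raise ValueError(f"pathway {pid!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, pid: str) -> Pathway:
        return self.pathways[pid]


# ---------------------------------------------------------------------------
# PED/MAP


def _read_lines(path) -> list[str]:
    with open(path, "r", newline="") as fh:
        raw = fh.read()
    # tolerate CRLF and a trailing newline
    return [ln for ln in raw.replace("\r\n", "\n").replace("\r", "\n").split("\n") if ln.strip()]


def read_map(map_path) -> pd.DataFrame:
    """Parse a PLINK MAP file (chrom, snp id, [cM,] bp position)."""
    rows = []
    for i, line in enumerate(_read_lines(map_path), start=1):
        f = line.split()
        if len(f) == 4:
            chrom, snp, _cm, pos = f
        elif len(f) == 3:
            chrom, snp, pos = f
        else:
            raise FormatError(f"{map_path}: line {i}: expected 3 or 4 fields, got {len(f)}")
        rows.append((chrom, snp, int(pos)))
    return pd.DataFrame(rows, columns=["chrom", "snp", "pos"])


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read white-space separated PLINK PED/MAP text into minor-allele dosages.

    "0 0" allele pairs become missing.  A SNP with more than two observed
    alleles raises :class:`FormatError`.
    """
    snp_meta = read_map(map_path)
    n_snps = len(snp_meta)
    samples: list[str] = []
    allele_rows: list[list[str]] = []
    for i, line in enumerate(_read_lines(ped_path), start=1):
        f = line.split()
        if len(f) != 6 + 2 * n_snps:
            raise FormatError(
                f"{ped_path}: line {i}: expected {6 + 2 * n_snps} fields "
                f"(6 + 2x{n_snps} SNPs), got {len(f)}"
            )
        samples.append(f[1])  # IID
        allele_rows.append(f[6:])

    n = len(samples)
    dosage = np.full((n, n_snps), np.nan)
    minors: list[str] = []
    majors: list[str] = []
    alleles = np.array(allele_rows, dtype=object).reshape(n, n_snps, 2) if n else np.empty((0, n_snps, 2), object)
    for k in range(n_snps):
        a = alleles[:, k, :]
        observed = a[a != "0"]
        uniq = sorted(set(observed.tolist()))
        if len(uniq) > 2:
            raise FormatError(
                f"{ped_path}: SNP {snp_meta['snp'][k]!r} is not biallelic: alleles {uniq}"
            )
        if not uniq:
            minors.append(".")
            majors.append(".")
            continue
        if len(uniq) == 1:
            # monomorphic: every non-missing genotype carries zero minor copies
            minor, major = ".", uniq[0]
        else:
            c0 = int((observed == uniq[0]).sum())
            c1 = int((observed == uniq[1]).sum())
            # minor = rarer allele; tie at 0.5 -> alphabetically first
            minor, major = (uniq[0], uniq[1]) if c0 <= c1 else (uniq[1], uniq[0])
        minors.append(minor)
        majors.append(major)
        missing = (a[:, 0] == "0") | (a[:, 1] == "0")
        cnt = (a[:, 0] == minor).astype(float) + (a[:, 1] == minor).astype(float)
        cnt[missing] = np.nan
        dosage[:, k] = cnt

    meta = pd.DataFrame(
        {
            "snp": snp_meta["snp"],
            "chrom": snp_meta["chrom"],
            "pos": snp_meta["pos"],
            "minor": minors,
            "major": majors,
        }
    )
    return GenotypeMatrix(samples, meta, dosage)


def write_ped_map(g: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PED/MAP text; dosage d becomes d copies of the minor allele."""
    with open(map_path, "w") as fh:
        for _, r in g.snps.iterrows():
            fh.write(f"{r['chrom']}\t{r['snp']}\t0\t{r['pos']}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.samples):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for k in range(g.n_snps):
                d = g.dosage[i, k]
                minor = g.snps["minor"].iat[k]
                major = g.snps["major"].iat[k]
                if minor == ".":
                    minor = "A"  # placeholder for monomorphic columns
                if not np.isfinite(d):
                    fields += ["0", "0"]
                else:
                    d = int(d)
                    fields += [minor] * d + [major] * (2 - d)
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Dosage TSV


def read_dosage_tsv(path) -> GenotypeMatrix:
    """Read a dosage TSV: header of SNP ids, first column sample ids, cells
    in {0, 1, 2, NA}."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    snp_ids = [str(c) for c in df.columns]
    samples = [str(s) for s in df.index]
    vals = df.to_numpy(dtype=object)
    vals = np.char.strip(vals.astype(str))
    ok = np.isin(vals, ("0", "1", "2", "NA", ""))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise FormatError(
            f"{path}: row {samples[i]!r}, column {snp_ids[j]!r}: "
            f"value {vals[i, j]!r} not in {{0,1,2,NA}}"
        )
    dosage = np.full(vals.shape, np.nan)
    for key, num in (("0", 0.0), ("1", 1.0), ("2", 2.0)):
        dosage[vals == key] = num
    return GenotypeMatrix.from_dosage(samples, snp_ids, dosage)


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    cells = np.where(np.isfinite(g.dosage), g.dosage, np.nan)
    df = pd.DataFrame(cells, index=g.samples, columns=g.snp_ids)
    out = df.map(lambda v: "NA" if not np.isfinite(v) else str(int(v)))
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GMT and SNP->gene map


def read_gmt(path) -> PathwayDB:
    """Read GMT gene sets: name TAB source/description TAB gene TAB gene ...

    Duplicate genes within a line are deduplicated; empty gene fields dropped.
    """
    pathways: dict[str, Pathway] = {}
    for i, line in enumerate(_read_lines(path), start=1):
        f = line.split("\t")
        if len(f) < 3:
            raise FormatError(f"{path}: line {i}: GMT lines need >=3 tab-separated fields")
        name, source = f[0], f[1]
        genes = frozenset(g for g in f[2:] if g.strip())
        if not genes:
            raise FormatError(f"{path}: line {i}: pathway {name!r} has no genes")
        pathways[name] = Pathway(name=name, source=source, genes=genes)
    return PathwayDB(pathways)


def write_gmt(db: PathwayDB, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(db.pathways):
            pw = db[pid]
            fh.write("\t".join([pw.name, pw.source, *sorted(pw.genes)]) + "\n")


def read_snp_gene_map(path) -> SnpGeneMap:
    """Read a two-column TSV (snp_id, gene); repeat rows accumulate genes."""
    entries: dict[str, set[str]] = {}
    for i, line in enumerate(_read_lines(path), start=1):
        f = line.split("\t")
        if len(f) != 2:
            raise FormatError(f"{path}: line {i}: expected 2 tab-separated fields")
        snp, gene = f[0].strip(), f[1].strip()
        if not snp or not gene:
            raise FormatError(f"{path}: line {i}: blank SNP id or gene symbol")
        entries.setdefault(snp, set()).add(gene)
    return SnpGeneMap(entries)


def write_snp_gene_map(m: SnpGeneMap, path) -> None:
    with open(path, "w") as fh:
        for snp in sorted(m.entries):
            for gene in sorted(m.entries[snp]):
                fh.write(f"{snp}\t{gene}\n")
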