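"""Genotype dosage containers, text I/O, quality control and allele frequencies.

Genotypes are stored as allelic dosages — the (possibly fractional) count of
the minor allele per animal and SNP, in the closed interval [0, 2].  Fractional
values arise naturally from imputation.  Missing calls are held as NaN.

Two text dialects are supported:

``matrix``
    A header row of SNP ids, then one row per animal starting with the animal
    id.  Tab-delimited, ``NA`` for missing.
``plinkraw``
    PLINK ``--recode A`` style: six leading pedigree columns (FID, IID, PAT,
    MAT, SEX, PHENOTYPE) followed by per-SNP dosage columns.  Only IID and the
    dosages are used on read; placeholder pedigree columns are emitted on
    write.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QcReport",
    "read_dosage",
    "write_dosage",
    "compute_allele_freqs",
    "qc_filter",
    "mean_impute_missing",
]

_PLINKRAW_LEAD = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


@dataclass
class GenotypeMatrix:
    """Animals × SNPs allelic dosage matrix with missingness.

    Parameters
    ----------
    animal_ids, snp_ids
        Ordered, unique identifiers for rows and columns.
    chrom
        Per-SNP chromosome label (autosomes are integer-like labels;
        anything non-integer, e.g. ``"X"``, is treated as non-autosomal).
    dosage
        ``(n_animals, n_snps)`` float array in [0, 2]; NaN marks missing.
    allele_freqs
        Optional per-SNP frequency of the counted allele, in (0, 1).
    freq_animals
        Annotation of the animal set the frequencies were computed from.
    """

    animal_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    dosage: np.ndarray
    allele_freqs: np.ndarray | None = None
    freq_animals: str | None = None

    def __post_init__(self) -> None:
        self.animal_ids = [str(a) for a in self.animal_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.chrom = np.asarray(self.chrom)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise ValueError("duplicate animal ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids")
        n, m = len(self.animal_ids), len(self.snp_ids)
        if self.dosage.shape != (n, m):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != ({n}, {m})"
            )
        if self.chrom.shape != (m,):
            raise ValueError("chrom must have one label per SNP")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage out of [0, 2] at animal {self.animal_ids[i]!r}, "
                f"SNP {self.snp_ids[j]!r}: {self.dosage[i, j]}"
            )

    # -- convenience -----------------------------------------------------
    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def is_autosomal(self) -> np.ndarray:
        """Boolean per-SNP mask of integer-labelled (autosomal) chromosomes."""
        out = np.empty(self.n_snps, dtype=bool)
        for j, c in enumerate(self.chrom):
            try:
                int(str(c))
                out[j] = True
            except ValueError:
                out[j] = False
        return out

    def animal_index(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            return np.array([lookup[str(a)] for a in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown animal id {e.args[0]!r}") from None

    def subset(self, animals=None, snps=None) -> "GenotypeMatrix":
        """Row/column subset by boolean mask or index array (freqs dropped)."""
        ai = np.arange(self.n_animals) if animals is None else np.asarray(animals)
        si = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if ai.dtype == bool:
            ai = np.flatnonzero(ai)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        return GenotypeMatrix(
            [self.animal_ids[i] for i in ai],
            [self.snp_ids[j] for j in si],
            self.chrom[si],
            self.dosage[np.ix_(ai, si)],
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            animal_ids=list(self.animal_ids),
            snp_ids=list(self.snp_ids),
            chrom=self.chrom.copy(),
            dosage=self.dosage.copy(),
            allele_freqs=None if self.allele_freqs is None else self.allele_freqs.copy(),
        )


@dataclass
class QcReport:
    """Counts removed at each QC step, in order of application."""

    n_animals_in: int
    n_snps_in: int
    snps_non_autosomal: int
    animals_low_call: int
    snps_low_call: int
    snps_low_maf: int
    n_animals_out: int
    n_snps_out: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"step": ["input", "non_autosomal_snps", "low_call_animals",
                      "low_call_snps", "low_maf_snps", "output"],
             "animals": [self.n_animals_in, 0, self.animals_low_call, 0, 0,
                         self.n_animals_out],
             "snps": [self.n_snps_in, self.snps_non_autosomal, 0,
                      self.snps_low_call, self.snps_low_maf, self.n_snps_out]}
        )


def read_dosage(path, dialect: str = "matrix") -> GenotypeMatrix:
    """Read a dosage matrix from delimited text.

    Chromosome labels are not carried by either dialect; SNP ids of the form
    ``chr:rest`` (e.g. ``"3:snp17"``) have the chromosome recovered from the
    prefix, otherwise all SNPs are labelled chromosome 1.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"],
                     keep_default_na=False)
    if dialect == "plinkraw":
        if list(df.columns[:6]) != _PLINKRAW_LEAD:
            raise ValueError(
                f"{path}: plinkraw dialect expects leading columns "
                f"{_PLINKRAW_LEAD}, got {list(df.columns[:6])}"
            )
        animal_ids = df["IID"].tolist()
        body = df.iloc[:, 6:]
    elif dialect == "matrix":
        animal_ids = df.iloc[:, 0].tolist()
        body = df.iloc[:, 1:]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    dosage = body.to_numpy(dtype=float)
    snp_ids, chrom = _split_chrom_prefix(body.columns)
    return GenotypeMatrix(animal_ids, snp_ids, chrom, dosage)


def _split_chrom_prefix(columns) -> tuple[list[str], np.ndarray]:
    snp_ids, chrom = [], []
    for s in columns:
        head, _, rest = str(s).partition(":")
        if rest:
            snp_ids.append(rest)
            chrom.append(head)
        else:
            snp_ids.append(str(s))
            chrom.append("1")
    return snp_ids, np.array(chrom)


def write_dosage(g: GenotypeMatrix, path, dialect: str = "matrix") -> None:
    """Write ``g`` as delimited text; inverse of :func:`read_dosage`.

    SNP ids are prefixed ``chrom:`` when not already carrying the prefix, so
    chromosome labels survive the round trip.
    """
    path = Path(path)
    snp_cols = []
    for s, c in zip(g.snp_ids, g.chrom):
        snp_cols.append(s if str(s).startswith(f"{c}:") else f"{c}:{s}")
    body = pd.DataFrame(g.dosage, columns=snp_cols)
    body = body.round(6)
    if dialect == "plinkraw":
        lead = pd.DataFrame(
            {"FID": g.animal_ids, "IID": g.animal_ids, "PAT": "0", "MAT": "0",
             "SEX": "0", "PHENOTYPE": "-9"}
        )
        out = pd.concat([lead, body], axis=1)
    elif dialect == "matrix":
        out = pd.concat(
            [pd.DataFrame({"animal_id": g.animal_ids}), body], axis=1
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def compute_allele_freqs(g: GenotypeMatrix, animals="all") -> np.ndarray:
    """Per-SNP allele frequency p_j = mean(non-missing dosage)/2.

    Frequencies are computed over the chosen animal set; the convention in
    genomic-relationship work is to use every available animal, so ``"all"``
    is the default.
    """
    if isinstance(animals, str) and animals == "all":
        rows = np.arange(g.n_animals)
        label = "all"
    else:
        rows = g.animal_index(animals)
        label = f"subset(n={len(rows)})"
    d = g.dosage[rows]
    n_obs = np.sum(~np.isnan(d), axis=0)
    if (n_obs == 0).any():
        j = int(np.argmax(n_obs == 0))
        raise ValueError(f"SNP {g.snp_ids[j]!r} has no non-missing calls")
    p = np.nanmean(d, axis=0) / 2.0
    g.allele_freqs = p
    g.freq_animals = label
    return p


def qc_filter(
    g: GenotypeMatrix,
    min_call_animal: float = 0.9,
    min_call_snp: float = 0.9,
    min_maf: float = 0.05,
    autosomes_only: bool = True,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply marker/animal quality control in a fixed order.

    Order of application: (1) drop non-autosomal SNPs, (2) drop animals with
    call rate below ``min_call_animal``, (3) drop SNPs with call rate below
    ``min_call_snp``, (4) drop SNPs with minor-allele frequency below
    ``min_maf``, with MAF computed on the surviving animals.
    """
    for t in (min_call_animal, min_call_snp, min_maf):
        if not 0.0 <= t <= 1.0:
            raise ValueError("QC thresholds must lie in [0, 1]")
    n0, m0 = g.n_animals, g.n_snps

    cur = g
    n_nonauto = 0
    if autosomes_only:
        keep = cur.is_autosomal()
        n_nonauto = int((~keep).sum())
        cur = cur.subset(snps=keep)

    obs = ~cur.missing_mask
    if cur.n_snps == 0:
        raise ValueError("all SNPs removed by the autosome filter")
    call_animal = obs.mean(axis=1)
    keep_a = call_animal >= min_call_animal
    n_low_a = int((~keep_a).sum())
    cur = cur.subset(animals=keep_a)
    if cur.n_animals == 0:
        raise ValueError("all animals removed by the call-rate filter")

    obs = ~cur.missing_mask
    call_snp = obs.mean(axis=0)
    keep_s = call_snp >= min_call_snp
    n_low_s = int((~keep_s).sum())
    cur = cur.subset(snps=keep_s)
    if cur.n_snps == 0:
        raise ValueError("all SNPs removed by the call-rate filter")

    with np.errstate(invalid="ignore"):
        p = np.nanmean(cur.dosage, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep_m = maf >= min_maf
    n_low_m = int((~keep_m).sum())
    cur = cur.subset(snps=keep_m)
    if cur.n_snps == 0:
        raise ValueError("all SNPs removed by the MAF filter")

    report = QcReport(
        n_animals_in=n0, n_snps_in=m0,
        snps_non_autosomal=n_nonauto, animals_low_call=n_low_a,
        snps_low_call=n_low_s, snps_low_maf=n_low_m,
        n_animals_out=cur.n_animals, n_snps_out=cur.n_snps,
    )
    return cur, report


def mean_impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by their expectation 2p_j and clear the mask."""
    if g.allele_freqs is None:
        raise ValueError(
            "allele_freqs unset; call compute_allele_freqs first"
        )
    out = g.copy()
    fill = np.broadcast_to(2.0 * g.allele_freqs, out.dosage.shape)
    mask = out.missing_mask
    out.dosage[mask] = fill[mask]
    out.allele_freqs = g.allele_freqs.copy()
    out.freq_animals = g.freq_animals
    return out
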