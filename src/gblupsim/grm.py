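"""Genomic relationship matrix: construction, summaries, block partitions.

The GRM follows the allele-frequency-standardised form

    G = Z Z' / (2 Σ_j p_j(1 − p_j)),   Z = W − 2p,

where W holds allelic dosages in [0, 2] and p the per-SNP allele
frequencies.  The normaliser is the expected sum of per-locus genotype
variances, which scales G toward the pedigree numerator relationship
matrix: unrelated non-inbred animals have expected diagonal 1.

Prediction of held-out animals needs G in block form with training animals
first,

    [[G_T, G_TV'], [G_TV, G_V]],

together with the matching blocks of the Cholesky factor C (G = CC',
C = [[C_T, 0], [C_TV, C_V]]), so that C_T C_T' = G_T and C_TV C_T' = G_TV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .qc_io import GenotypeMatrix

__all__ = ["Grm", "GrmPartition", "compute_grm", "rel10", "partition_grm", "chol_psd"]

log = logging.getLogger(__name__)


@dataclass
class Grm:
    """Symmetric genomic relationship matrix with its animal index."""

    animal_ids: list[str]
    values: np.ndarray
    normalizer: float
    freq_source: str = "all"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("GRM must be square")
        if v.shape[0] != len(self.animal_ids):
            raise ValueError("GRM dimension must match animal_ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("GRM must be symmetric within 1e-10")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.animal_ids)

    def index(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            return np.array([lookup[str(a)] for a in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown animal id {e.args[0]!r}") from None


@dataclass
class GrmPartition:
    """Training/validation blocks of a GRM and of its Cholesky factor.

    ``G_TV`` is oriented validation-rows × training-columns, the orientation
    used by the validation-prediction identity â_V = G_TV G_T⁻¹ â_T.
    """

    train_ids: list[str]
    val_ids: list[str]
    G_T: np.ndarray
    G_V: np.ndarray
    G_TV: np.ndarray
    C_T: np.ndarray
    C_TV: np.ndarray
    C_V: np.ndarray
    jitter: float = 0.0


def compute_grm(g: GenotypeMatrix, freqs=None) -> Grm:
    """Allele-frequency-standardised GRM from complete dosages.

    ``freqs`` defaults to the frequencies attached to ``g`` (conventionally
    computed from all available animals).  Fractional dosages from imputation
    pass through unchanged.
    """
    if g.missing_mask.any():
        raise ValueError("GRM requires complete dosages (impute first)")
    p = np.asarray(g.allele_freqs if freqs is None else freqs, dtype=float)
    if p.shape != (g.n_snps,):
        raise ValueError("need one allele frequency per SNP")
    if (p <= 0).any() or (p >= 1).any():
        raise ValueError("allele frequencies must lie in (0, 1)")
    norm = float(2.0 * np.sum(p * (1.0 - p)))
    if norm == 0.0:
        raise ValueError("zero normaliser: all SNPs monomorphic")
    Z = g.dosage - 2.0 * p
    values = (Z @ Z.T) / norm
    values = 0.5 * (values + values.T)
    return Grm(list(g.animal_ids), values, norm,
               freq_source=g.freq_animals or "supplied")


def rel10(grm: Grm, k: int = 10) -> np.ndarray:
    """Per-animal mean of its k largest relationships (diagonal excluded).

    The usual summary of how well an animal is connected to the rest of the
    cohort; higher values predict more accurate genomic prediction.
    """
    if grm.n <= k:
        raise ValueError(f"need more than k={k} animals, have {grm.n}")
    v = grm.values.copy()
    np.fill_diagonal(v, -np.inf)
    part = np.partition(v, grm.n - k, axis=1)[:, grm.n - k:]
    return part.mean(axis=1)


def chol_psd(matrix: np.ndarray, jitter: float = 1e-8, max_tries: int = 6):
    """Lower Cholesky factor with escalating diagonal jitter.

    Genomic relationship matrices are often numerically rank-deficient
    (more animals than informative marker dimensions).  On factorisation
    failure, ``jitter × mean(diag)`` is added to the diagonal and escalated
    tenfold up to ``max_tries`` times.  Returns ``(L, applied_jitter)``.
    """
    m = np.asarray(matrix, dtype=float)
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    base = float(np.mean(np.diag(m)))
    if base <= 0:
        base = 1.0
    applied = 0.0
    for t in range(max_tries + 1):
        try:
            L = np.linalg.cholesky(m + applied * np.eye(m.shape[0]))
            if applied:
                log.info("chol_psd: applied jitter %.3g", applied)
            return L, applied
        except np.linalg.LinAlgError:
            applied = jitter * base * (10.0**t)
    raise np.linalg.LinAlgError(
        f"matrix not factorizable after jitter escalation to {applied:.3g}"
    )


def partition_grm(grm: Grm, train_ids, val_ids) -> GrmPartition:
    """Extract training/validation blocks of G and of its Cholesky factor.

    The Cholesky blocks come from factorising the full matrix permuted with
    training animals first, so the block identities C_T C_T' = G_T and
    C_TV C_T' = G_TV hold (up to the logged jitter).
    """
    train_ids = [str(a) for a in train_ids]
    val_ids = [str(a) for a in val_ids]
    if not train_ids or not val_ids:
        raise ValueError("train and validation sets must be nonempty")
    if set(train_ids) & set(val_ids):
        raise ValueError("train and validation sets overlap")
    ti = grm.index(train_ids)
    vi = grm.index(val_ids)
    t = len(ti)
    order = np.concatenate([ti, vi])
    full = grm.values[np.ix_(order, order)]
    L, applied = chol_psd(full)
    return GrmPartition(
        train_ids=train_ids,
        val_ids=val_ids,
        G_T=grm.values[np.ix_(ti, ti)],
        G_V=grm.values[np.ix_(vi, vi)],
        G_TV=grm.values[np.ix_(vi, ti)],
        C_T=L[:t, :t],
        C_TV=L[t:, :t],
        C_V=L[t:, t:],
        jitter=applied,
    )
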