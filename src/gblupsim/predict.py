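"""Prediction of validation animals and their individual reliabilities.

Validation (held-out) animals have no records; their GEBVs are obtained by
regressing on the training animals through the genomic relationships,

    â_V = G_TV G_T⁻¹ â_T = G_TV (G_T + R_T σ²_e/σ²_a)⁻¹ (y_T − 1 μ̂),

and their individual reliabilities from the same partitioned system,

    rel_i = [G_TV (G_T + R_T σ²_e/σ²_a)⁻¹ G_TV']_ii / [G_V]_ii,

the ratio of the variance of the prediction to the animal's genomic
self-relationship.  The associated accuracy is √rel.  The two quantities
are distinct and both are returned: conflating them is a common source of
optimistic reporting.

A single factorisation of (G_T + R_T λ) is shared by the prediction and the
reliability computation.  When validation genotypes were imputed toward a
small reference panel, diag(G_V) deflates, which inflates the reported
reliabilities — animals with a non-positive self-relationship are flagged
with NaN and a warning rather than aborting, since that regime is a data
artifact worth surfacing, not a programming error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .grm import GrmPartition

__all__ = ["PredictionResult", "predict_validation", "individual_reliability"]


@dataclass
class PredictionResult:
    val_ids: list[str]
    gebv_v: np.ndarray
    reliability_v: np.ndarray
    accuracy_v: np.ndarray
    variance_ratio_used: float
    diag_gv: np.ndarray


def _training_factor(part: GrmPartition, weights_T, sigma2_a, sigma2_e):
    w = np.asarray(weights_T, dtype=float)
    t = part.G_T.shape[0]
    if w.shape != (t,):
        raise ValueError("weights_T must match the training block")
    if (w <= 0).any():
        raise ValueError("training weights must be strictly positive")
    if sigma2_a <= 0 or sigma2_e <= 0:
        raise ValueError("variances must be positive")
    lam = sigma2_e / sigma2_a
    M = part.G_T + np.diag(lam / w)
    return scipy.linalg.cho_factor(M, lower=True), lam


def predict_validation(
    part: GrmPartition,
    y_T: np.ndarray,
    weights_T: np.ndarray,
    sigma2_a: float,
    sigma2_e: float,
    mu_hat: float,
) -> np.ndarray:
    """GEBVs of validation animals from training records.

    ``mu_hat`` is the training-fold mean estimate; it is never re-estimated
    here.  Computes the collapsed form
    G_TV (G_T + R_T λ)⁻¹ (y_T − 1μ̂) directly.
    """
    y = np.asarray(y_T, dtype=float)
    cho, _ = _training_factor(part, weights_T, sigma2_a, sigma2_e)
    x = scipy.linalg.cho_solve(cho, y - mu_hat)
    return part.G_TV @ x


def individual_reliability(
    part: GrmPartition,
    weights_T: np.ndarray,
    sigma2_a: float,
    sigma2_e: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-validation-animal (reliability, accuracy) from the partitioned G.

    Animals whose genomic self-relationship [G_V]_ii is non-positive get
    NaN with a warning — the regime produced by aggressive shrinkage of
    imputed genotypes, where the reliability ratio loses meaning.
    """
    cho, _ = _training_factor(part, weights_T, sigma2_a, sigma2_e)
    X = scipy.linalg.cho_solve(cho, part.G_TV.T)
    num = np.einsum("ij,ji->i", part.G_TV, X)
    diag_gv = np.diag(part.G_V).copy()
    bad = diag_gv <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} validation animal(s) have non-positive "
            "genomic self-relationship; reliability set to NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(bad, np.nan, num / diag_gv)
    acc = np.sqrt(np.clip(rel, 0.0, None))
    return rel, acc


def predict_with_reliability(
    part: GrmPartition,
    y_T: np.ndarray,
    weights_T: np.ndarray,
    sigma2_a: float,
    sigma2_e: float,
    mu_hat: float,
) -> PredictionResult:
    """Bundle GEBVs and reliabilities for the validation set."""
    gebv = predict_validation(part, y_T, weights_T, sigma2_a, sigma2_e, mu_hat)
    rel, acc = individual_reliability(part, weights_T, sigma2_a, sigma2_e)
    return PredictionResult(
        val_ids=list(part.val_ids),
        gebv_v=gebv,
        reliability_v=rel,
        accuracy_v=acc,
        variance_ratio_used=sigma2_e / sigma2_a,
        diag_gv=np.diag(part.G_V).copy(),
    )
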