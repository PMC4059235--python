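"""De-regression of EBVs with the parent average removed.

An EBV is a shrunken predictor, and part of it is parental information; used
directly as a response in genomic regression it both double-counts family
information and under-disperses.  The de-regression here back-solves the
two-effect mixed-model equations in (parent average, individual) — the
procedure standard in genomic-selection pipelines — to recover the
individual's own effective record ``y* / Z'Z_i`` and an information weight.

With λ = (1−h²)/h², α = 1/(0.5 − r²_PA) and δ = (0.5 − r²_PA)/(1 − r²_i):

    Z'Z_PA = λ(0.5α − 4) + 0.5λ√(α² + 16/δ)
    Z'Z_i  = δ·Z'Z_PA + 2λ(2δ − 1)
    y*_i   = −2λ·EBV_PA + (Z'Z_i + 2λ)·EBV_i
    dEBV   = y*_i / Z'Z_i
    r²_dEBV = 1 − λ/(Z'Z_i + λ)
    w_i    = (1 − h²) / [(c + (1 − r²_dEBV)/r²_dEBV)·h²]

``c`` is the fraction of genetic variance not captured by the markers.
Records whose own information content Z'Z_i is non-positive (young animals
whose EBV is effectively all parent average) carry no individual information
and are dropped rather than raising an error.

The module also exposes the reconstructed 2×2 mixed-model coefficient matrix
(:func:`mme_coefficient_matrix`, :func:`implied_reliabilities`) so the
algebra can be verified by direct inversion: the reliabilities implied by
the MME built from the Z'Z terms reproduce the input r²_i and r²_PA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DeregressedRecord",
    "deregress_record",
    "deregress_table",
    "mme_coefficient_matrix",
    "implied_reliabilities",
]


@dataclass
class DeregressedRecord:
    animal_id: str | None
    debv: float
    weight: float
    rel_debv: float
    kept: bool


def _information_contents(rel_i: float, rel_pa: float, h2: float):
    lam = (1.0 - h2) / h2
    alpha = 1.0 / (0.5 - rel_pa)
    delta = (0.5 - rel_pa) / (1.0 - rel_i)
    zz_pa = lam * (0.5 * alpha - 4.0) + 0.5 * lam * np.sqrt(
        alpha**2 + 16.0 / delta
    )
    zz_i = delta * zz_pa + 2.0 * lam * (2.0 * delta - 1.0)
    return lam, zz_pa, zz_i


def deregress_record(
    ebv_i: float,
    ebv_pa: float,
    rel_i: float,
    rel_pa: float,
    h2: float,
    c: float = 0.5,
) -> DeregressedRecord:
    """De-regress one animal's EBV, removing the parent-average contribution.

    Unknown parents are encoded ``rel_pa = 0, ebv_pa = 0``.  Returns a record
    with ``kept = False`` (debv/weight/rel NaN-free but meaningless) when the
    own information content is non-positive — the standard filter for young
    animals whose EBV is pure parent average.
    """
    if not 0.0 < rel_i < 1.0:
        raise ValueError("rel_i must lie in (0, 1)")
    if not 0.0 <= rel_pa < 0.5:
        raise ValueError("rel_pa must lie in [0, 0.5)")
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must lie in (0, 1)")
    if not 0.0 <= c < 1.0:
        raise ValueError("c must lie in [0, 1)")
    lam, _, zz_i = _information_contents(rel_i, rel_pa, h2)
    if zz_i <= 0.0:
        return DeregressedRecord(None, np.nan, 0.0, np.nan, False)
    y_star = -2.0 * lam * ebv_pa + (zz_i + 2.0 * lam) * ebv_i
    debv = y_star / zz_i
    rel_debv = 1.0 - lam / (zz_i + lam)
    weight = (1.0 - h2) / ((c + (1.0 - rel_debv) / rel_debv) * h2)
    return DeregressedRecord(None, debv, weight, rel_debv, weight > 0.0)


def deregress_table(
    trait_table: pd.DataFrame, h2: float, c: float = 0.5
) -> tuple[pd.DataFrame, dict]:
    """De-regress every row of a trait table.

    ``trait_table`` needs columns ``animal_id, ebv, rel_ebv, pa_ebv,
    rel_pa``.  Returns a DataFrame (animal_id, debv, weight, rel_debv, kept)
    and a summary dict with kept/dropped counts.  Records with non-positive
    weight are flagged ``kept = False`` and must be excluded from the
    response vector and weight matrix downstream.
    """
    ids = trait_table["animal_id"].astype(str)
    if ids.duplicated().any():
        raise ValueError("duplicate animal ids in trait table")
    rows = []
    for _, r in trait_table.iterrows():
        rec = deregress_record(
            float(r["ebv"]), float(r["pa_ebv"]),
            float(r["rel_ebv"]), float(r["rel_pa"]), h2, c
        )
        rows.append((str(r["animal_id"]), rec.debv, rec.weight,
                     rec.rel_debv, rec.kept))
    out = pd.DataFrame(
        rows, columns=["animal_id", "debv", "weight", "rel_debv", "kept"]
    )
    summary = {
        "n_in": len(out),
        "n_kept": int(out["kept"].sum()),
        "n_dropped": int((~out["kept"]).sum()),
    }
    return out, summary


def mme_coefficient_matrix(rel_i: float, rel_pa: float, h2: float) -> np.ndarray:
    """Reconstructed 2×2 coefficient matrix of the (PA, individual) MME.

    The relationship matrix of (parent average, animal) is
    [[0.5, 0.5], [0.5, 1.0]], whose inverse is [[4, −2], [−2, 2]]; the
    coefficient matrix is Z'Z + A⁻¹λ with the diagonal Z'Z information
    contents back-solved from the input reliabilities.
    """
    lam, zz_pa, zz_i = _information_contents(rel_i, rel_pa, h2)
    return np.array(
        [[zz_pa + 4.0 * lam, -2.0 * lam], [-2.0 * lam, zz_i + 2.0 * lam]]
    )


def implied_reliabilities(rel_i: float, rel_pa: float, h2: float):
    """Reliabilities implied by inverting the reconstructed 2×2 MME.

    With additive variance 1 and residual variance λ the prediction error
    variances are λ·diag(C⁻¹).  Reliabilities are expressed on the animal's
    breeding-value scale: the individual's is 1 − PEV_i, and the parent
    average's is 0.5 − PEV_PA (the PA effect has prior variance 0.5, which
    is why a parent average can never exceed reliability 0.5 as a predictor
    of the animal).  Round-tripping the inputs through this function is the
    independent check on the de-regression algebra.
    """
    lam = (1.0 - h2) / h2
    C = mme_coefficient_matrix(rel_i, rel_pa, h2)
    Cinv = np.linalg.inv(C)
    r2_pa = 0.5 - lam * Cinv[0, 0]
    r2_i = 1.0 - lam * Cinv[1, 1]
    return r2_i, r2_pa
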