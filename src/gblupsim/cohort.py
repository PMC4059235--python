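"""Synthetic cohorts: haplotypes, families, breeding values, EBVs, imputation.

Everything downstream of this module (QC, de-regression, GRM, GBLUP,
cross-validation) is exercised on cohorts produced here, so the generators
are deliberately simple but statistically honest:

* founder haplotypes carry tunable adjacent-locus LD via a first-order
  copying chain;
* families (sires × dams × litters) yield the half/full-sib structure that
  gives a genomic relationship matrix its spread;
* EBVs are generated so that corr(EBV, TBV) = r and the regression of TBV on
  EBV is 1, the unbiasedness property BLUP evaluations have by construction;
* imputation error is emulated parametrically as shrinkage of the true dosage
  toward twice the reference-panel allele frequency plus calibrated noise,
  reproducing both the target per-animal accuracy R² and the hallmark
  deflation of genomic-relationship diagonals under a small panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc_io import GenotypeMatrix, compute_allele_freqs

__all__ = [
    "HaplotypePanel",
    "SimTruth",
    "ImputationSpec",
    "simulate_founder_haplotypes",
    "simulate_pedigree_cohort",
    "simulate_breeding_values",
    "simulate_ebv",
    "sample_panel_freqs",
    "emulate_imputation",
]


@dataclass
class HaplotypePanel:
    """Phased founder haplotypes with per-SNP metadata.

    ``haplotypes`` is a (2·n_founders, L) 0/1 array; ``snp_meta`` has columns
    ``snp_id``, ``chrom``, ``pos`` (index-based) and ``freq`` (the marginal
    allele frequency of the generating process, in [0.05, 0.5] by
    construction); ``ld_rho`` is the copying-chain parameter.
    """

    haplotypes: np.ndarray
    snp_meta: pd.DataFrame
    ld_rho: float

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes)
        if h.ndim != 2 or h.shape[0] % 2:
            raise ValueError("haplotypes must be 2D with an even row count")
        if not np.isin(h, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")
        self.haplotypes = h.astype(np.int8)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort.

    ``tbv`` are true breeding values in trait units; ``marker_effects`` the
    per-locus additive effects; ``true_dosages`` the complete genotype
    matrix; ``pedigree`` a DataFrame (animal_id, sire_id, dam_id, generation)
    with ``None`` for unknown parents; ``sigma2_a_true`` the additive
    variance the effects were scaled to.
    """

    tbv: np.ndarray
    marker_effects: np.ndarray
    true_dosages: GenotypeMatrix
    pedigree: pd.DataFrame
    sigma2_a_true: float
    h2: float


@dataclass
class ImputationSpec:
    """Parameters of the parametric imputation-error emulator.

    ``r2_target`` is the desired per-animal squared correlation between true
    and imputed dosage; ``panel_haplotypes`` the size H of the reference
    haplotype panel whose finite sampling perturbs the frequencies imputation
    shrinks toward; ``panel_freqs`` those panel frequencies; ``maf_penalty``
    optionally lowers the per-SNP accuracy for MAF below 0.1, emulating the
    harder imputation of rare alleles.
    """

    r2_target: float
    panel_haplotypes: int
    panel_freqs: np.ndarray
    maf_penalty: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_target <= 1.0:
            raise ValueError("r2_target must lie in (0, 1]")
        if self.panel_haplotypes < 2:
            raise ValueError("panel must contain at least 2 haplotypes")
        if self.maf_penalty < 0:
            raise ValueError("maf_penalty must be >= 0")
        self.panel_freqs = np.asarray(self.panel_freqs, dtype=float)


def simulate_founder_haplotypes(
    n_founders: int,
    L: int,
    chromosomes: int = 1,
    ld_rho: float = 0.0,
    seed: int = 0,
) -> HaplotypePanel:
    """Simulate 2·``n_founders`` haplotypes of ``L`` biallelic loci.

    Per-SNP base frequencies are drawn U(0.05, 0.5) (minor-allele coding).
    Adjacent loci on the same chromosome are linked by a first-order copying
    chain: with probability ``ld_rho`` the allele is copied from the previous
    locus, otherwise drawn fresh at the locus frequency.  The marginal
    frequency of locus j is then a convex combination of upstream base
    frequencies, hence stays inside [0.05, 0.5], and the adjacent-locus
    allele correlation is ≈ ``ld_rho``.  Chromosomes are independent.
    """
    if n_founders < 2 or L < 1 or chromosomes < 1:
        raise ValueError("n_founders >= 2, L >= 1, chromosomes >= 1 required")
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError("ld_rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_founders
    base_freq = rng.uniform(0.05, 0.5, size=L)
    chrom = np.array([1 + (j * chromosomes) // L for j in range(L)])
    hap = np.empty((n_hap, L), dtype=np.int8)
    marg = np.empty(L)
    for j in range(L):
        fresh = rng.random(n_hap) < base_freq[j]
        if j > 0 and chrom[j] == chrom[j - 1] and ld_rho > 0:
            copy = rng.random(n_hap) < ld_rho
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
            marg[j] = ld_rho * marg[j - 1] + (1 - ld_rho) * base_freq[j]
        else:
            hap[:, j] = fresh
            marg[j] = base_freq[j]
    meta = pd.DataFrame(
        {"snp_id": [f"snp{j}" for j in range(L)], "chrom": chrom,
         "pos": np.arange(L), "freq": marg}
    )
    return HaplotypePanel(hap, meta, ld_rho)


def _gamete(hap_a, hap_b, chrom_bounds, recomb_per_chrom, rng):
    """One recombinant gamete from a parent's two haplotypes."""
    L = hap_a.shape[0]
    out = np.empty(L, dtype=np.int8)
    for lo, hi in chrom_bounds:
        n_x = rng.poisson(recomb_per_chrom)
        cuts = np.sort(rng.integers(lo + 1, hi, size=n_x)) if n_x and hi > lo + 1 else []
        cur = int(rng.integers(2))
        prev = lo
        for c in list(cuts) + [hi]:
            src = hap_a if cur == 0 else hap_b
            out[prev:c] = src[prev:c]
            cur = 1 - cur
            prev = c
    return out


def simulate_pedigree_cohort(
    panel: HaplotypePanel,
    n_sires: int,
    dams_per_sire: int,
    offspring_per_dam: int,
    recomb_per_chrom: float = 1.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop a two-generation pedigree through the founder panel.

    Founder sires and dams receive two haplotypes drawn (with replacement)
    from the panel; each offspring receives one recombinant gamete per
    parent, with Poisson(``recomb_per_chrom``) crossovers per chromosome at
    uniform positions.  Returns the genotype matrix of all animals (sires,
    dams, offspring; dosage = sum of the two inherited haplotypes) and the
    pedigree table.  Multiple dams per sire yield paternal half sibs;
    multiple offspring per dam yield full sibs.
    """
    if panel.n_snps == 0 or panel.n_haplotypes == 0:
        raise ValueError("empty haplotype panel")
    if min(n_sires, dams_per_sire, offspring_per_dam) < 1:
        raise ValueError("all family-size counts must be >= 1")
    rng = np.random.default_rng(seed)
    L = panel.n_snps
    chrom = panel.snp_meta["chrom"].to_numpy()
    bounds = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        bounds.append((int(idx[0]), int(idx[-1]) + 1))

    def draw_pair():
        i = rng.integers(panel.n_haplotypes, size=2)
        return panel.haplotypes[i[0]].copy(), panel.haplotypes[i[1]].copy()

    ids, sires, dams, gen, haps = [], [], [], [], {}
    for s in range(n_sires):
        sid = f"S{s:03d}"
        ids.append(sid); sires.append(None); dams.append(None); gen.append(0)
        haps[sid] = draw_pair()
    for s in range(n_sires):
        for d in range(dams_per_sire):
            did = f"D{s:03d}_{d:02d}"
            ids.append(did); sires.append(None); dams.append(None); gen.append(0)
            haps[did] = draw_pair()
    for s in range(n_sires):
        sid = f"S{s:03d}"
        for d in range(dams_per_sire):
            did = f"D{s:03d}_{d:02d}"
            for o in range(offspring_per_dam):
                oid = f"O{s:03d}_{d:02d}_{o:02d}"
                ids.append(oid); sires.append(sid); dams.append(did); gen.append(1)
                gs = _gamete(*haps[sid], bounds, recomb_per_chrom, rng)
                gd = _gamete(*haps[did], bounds, recomb_per_chrom, rng)
                haps[oid] = (gs, gd)
    dosage = np.stack([haps[a][0] + haps[a][1] for a in ids]).astype(float)
    geno = GenotypeMatrix(
        ids, panel.snp_meta["snp_id"].tolist(), chrom.astype(str), dosage
    )
    ped = pd.DataFrame(
        {"animal_id": ids, "sire_id": sires, "dam_id": dams, "generation": gen}
    )
    return geno, ped


def simulate_breeding_values(
    genotypes: GenotypeMatrix,
    h2: float = 0.5,
    sigma2_a: float = 1.0,
    n_qtl="all",
    seed: int = 0,
    pedigree: pd.DataFrame | None = None,
) -> SimTruth:
    """Assign additive marker effects and true breeding values.

    Effects are i.i.d. normal on ``n_qtl`` randomly chosen loci (zero
    elsewhere) and rescaled so the cohort's sample variance of TBV equals
    ``sigma2_a`` exactly; TBV = Z·u with Z the dosage matrix centred by twice
    the cohort allele frequency.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must lie in (0, 1)")
    if genotypes.missing_mask.any():
        raise ValueError("genotypes must be complete (no missing dosages)")
    rng = np.random.default_rng(seed)
    L = genotypes.n_snps
    if isinstance(n_qtl, str) and n_qtl == "all":
        qtl = np.arange(L)
    else:
        n_qtl = int(n_qtl)
        if not 1 <= n_qtl <= L:
            raise ValueError("n_qtl must lie in [1, L]")
        qtl = rng.choice(L, size=n_qtl, replace=False)
    p = compute_allele_freqs(genotypes)
    Z = genotypes.dosage - 2.0 * p
    u = np.zeros(L)
    u[qtl] = rng.standard_normal(qtl.size)
    tbv = Z @ u
    v = tbv.var()
    if v > 0:
        scale = np.sqrt(sigma2_a / v)
        u *= scale
        tbv *= scale
    if pedigree is None:
        pedigree = pd.DataFrame(
            {"animal_id": genotypes.animal_ids,
             "sire_id": [None] * genotypes.n_animals,
             "dam_id": [None] * genotypes.n_animals,
             "generation": 0}
        )
    return SimTruth(tbv, u, genotypes, pedigree, float(sigma2_a), float(h2))


def simulate_ebv(
    truth: SimTruth,
    rel_own,
    rel_pa=0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a trait table (EBV, reliabilities, parent averages).

    For reliability r² the EBV is built as ``EBV = r²·TBV + e`` with
    ``e ~ N(0, r²(1−r²)σ²_a)``, which gives corr(EBV, TBV) = r and unit
    regression of TBV on EBV.  The parent-average EBV is built analogously
    from (TBV_sire + TBV_dam)/2, whose own variance is σ²_a/2, giving
    ``PA = 2r²_PA·(TBV_s+TBV_d)/2 + e_PA`` with
    ``e_PA ~ N(0, r²_PA(1−2r²_PA)σ²_a)``; r²_PA must therefore stay below
    0.5.  Animals with any unknown parent get PA = 0 and r²_PA = 0.
    """
    n = truth.true_dosages.n_animals
    rel_own = np.broadcast_to(np.asarray(rel_own, dtype=float), (n,)).copy()
    rel_pa = np.broadcast_to(np.asarray(rel_pa, dtype=float), (n,)).copy()
    if (rel_own <= 0).any() or (rel_own > 1).any():
        raise ValueError("rel_own must lie in (0, 1]")
    if (rel_pa < 0).any() or (rel_pa >= 0.5).any():
        raise ValueError("rel_pa must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    s2a = truth.sigma2_a_true
    tbv = truth.tbv
    ids = truth.true_dosages.animal_ids
    tbv_of = dict(zip(truth.pedigree["animal_id"], tbv))
    sire_of = dict(zip(truth.pedigree["animal_id"], truth.pedigree["sire_id"]))
    dam_of = dict(zip(truth.pedigree["animal_id"], truth.pedigree["dam_id"]))

    ebv = rel_own * tbv + rng.normal(
        0.0, np.sqrt(rel_own * (1.0 - rel_own) * s2a)
    )
    pa_ebv = np.zeros(n)
    rel_pa_out = rel_pa.copy()
    for i, a in enumerate(ids):
        s, d = sire_of.get(a), dam_of.get(a)
        if s is None or d is None or rel_pa[i] == 0.0:
            rel_pa_out[i] = 0.0
            continue
        mid = 0.5 * (tbv_of[s] + tbv_of[d])
        sd = np.sqrt(rel_pa[i] * (1.0 - 2.0 * rel_pa[i]) * s2a)
        pa_ebv[i] = 2.0 * rel_pa[i] * mid + rng.normal(0.0, sd)
    return pd.DataFrame(
        {"animal_id": ids, "ebv": ebv, "rel_ebv": rel_own,
         "pa_ebv": pa_ebv, "rel_pa": rel_pa_out}
    )


def sample_panel_freqs(p_true, H: int, seed: int = 0) -> np.ndarray:
    """Reference-panel allele frequencies from H haplotypes.

    Each panel frequency is Binomial(H, p)/H, clamped to
    [1/(2H), 1 − 1/(2H)] so no locus is monomorphic in the panel.
    """
    if H < 2:
        raise ValueError("H must be >= 2")
    p_true = np.asarray(p_true, dtype=float)
    if (p_true <= 0).any() or (p_true >= 1).any():
        raise ValueError("p_true must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    f = rng.binomial(H, p_true) / H
    return np.clip(f, 1.0 / (2 * H), 1.0 - 1.0 / (2 * H))


def _calibrate_emulator(
    r2: float, w: np.ndarray, anchors: np.ndarray, p_true: np.ndarray
) -> tuple[float, float]:
    """Solve shrinkage s and noise scale θ for the imputation emulator.

    The emulated dosage is ŵ = a + s(w − a) + e with per-SNP noise variance
    θ·2p(1−p), where the anchor a is the information imputation recovers
    from shared haplotypes (parent-average dosage, or twice the panel
    frequency for animals without genotyped parents).  (s, θ) are solved
    from two empirical moment conditions on the animals being imputed:

    1. the across-SNP per-animal squared correlation corr²(w, ŵ) equals
       ``r2`` (the headline imputation accuracy), and
    2. the allele-frequency-centred second moment E[(ŵ − 2p)²] equals
       ``r2``·E[(w − 2p)²] (posterior-mean variance deflation, the driver
       of the shrunken genomic-relationship diagonals).

    Condition 2 determines the required mean injected-noise variance for a
    given s; condition 1 is then solved for s by bisection — it increases
    from an anchor-only correlation at s = 0 to 1 at (s, θ) = (1, 0).

    Because the noise is drawn on the bounded dosage scale, entries whose
    conditional mean sits near 0 or 2 cannot carry the full per-SNP noise
    variance (the Beta feasibility bound).  θ is therefore solved so that
    the *effective* mean noise — after capping at the feasible bound —
    matches the requirement, evaluated on a subsample of entries.
    """
    import scipy.optimize

    if r2 >= 1.0:
        return 1.0, 0.0
    p2 = 2.0 * p_true
    d = w - anchors
    ac = anchors - anchors.mean(axis=1, keepdims=True)
    dc = d - d.mean(axis=1, keepdims=True)
    L = w.shape[1]
    # across-SNP (co)variances, averaged over animals
    V_a = float(np.mean(np.sum(ac * ac, axis=1)) / L)
    V_d = float(np.mean(np.sum(dc * dc, axis=1)) / L)
    C_ad = float(np.mean(np.sum(ac * dc, axis=1)) / L)
    # allele-frequency-centred second moments
    Q_a = float(np.mean((anchors - p2) ** 2))
    Q_d = float(np.mean(d * d))
    Q_ad = float(np.mean((anchors - p2) * d))
    Q_w = float(np.mean((w - p2) ** 2))

    # subsample entries for the effective-noise accounting
    n_entries = w.size
    take = min(n_entries, 200_000)
    idx = np.linspace(0, n_entries - 1, take).astype(int)
    a_s = anchors.reshape(-1)[idx]
    d_s = d.reshape(-1)[idx]
    pq_s = (p2 * (1.0 - 0.5 * p2))[idx % L]

    def effective_noise(s, theta):
        m = a_s + s * d_s
        mu = np.clip(m / 2.0, 1e-9, 1.0 - 1e-9)
        cap = 0.999 * 4.0 * mu * (1.0 - mu)
        return float(np.mean(np.minimum(theta * pq_s, cap)))

    def solve_theta(s):
        """θ whose capped mean noise meets the deflation requirement."""
        need = r2 * Q_w - Q_a - 2.0 * s * Q_ad - s * s * Q_d
        if need <= 0:
            return 0.0, 0.0
        hi = 1.0
        while effective_noise(s, hi) < need and hi < 64:
            hi *= 2.0
        if effective_noise(s, hi) < need:
            return hi, effective_noise(s, hi)
        th = scipy.optimize.brentq(
            lambda t: effective_noise(s, t) - need, 0.0, hi, xtol=1e-6
        )
        return float(th), need

    def r2_of(s):
        _, noise = solve_theta(s)
        cov = V_a + (1.0 + s) * C_ad + s * V_d
        var_w = V_a + V_d + 2.0 * C_ad
        var_imp = V_a + s * s * V_d + 2.0 * s * C_ad + noise
        return cov * cov / (var_w * var_imp)

    if r2_of(0.0) >= r2:
        return 0.0, solve_theta(0.0)[0]
    s = float(scipy.optimize.brentq(lambda s: r2_of(s) - r2, 0.0, 1.0,
                                    xtol=1e-6))
    return s, solve_theta(s)[0]


def emulate_imputation(
    genotypes: GenotypeMatrix,
    spec: ImputationSpec,
    animals="all",
    seed: int = 0,
    pedigree: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Degrade dosages of selected animals as LD imputation would.

    LD imputation recovers the haplotypes an animal shares with the
    reference population well and loses individual-specific detail, so its
    error is not independent noise: relationships *between* animals survive
    largely intact while each animal's own dosage is shrunk — deflating the
    genomic-relationship diagonal.  The emulator reproduces this by
    shrinking each dosage toward an anchor a:

        ŵ = a + s·(w − a) + e,    Var(e) = θ·2p(1−p) per SNP,

    where a is the parent-average dosage when ``pedigree`` is given and
    both parents are genotyped (the shared-haplotype information), and
    twice the reference-panel frequency otherwise — a small panel therefore
    pulls all such animals toward the same point.  (s, θ) are calibrated so
    the realized across-SNP per-animal R² equals ``spec.r2_target`` and the
    centred dosage variance deflates by that same factor (see
    ``_calibrate_emulator``); ``spec.maf_penalty`` optionally lowers s at
    MAF below 0.1.  The dosage is drawn as 2·Beta with exactly the target
    mean and variance, which keeps it inside [0, 2] without the variance
    loss a clamped Gaussian suffers near the dosage boundaries.  Unselected
    animals are returned bit-identical; ``r2_target = 1`` is the exact
    identity.
    """
    if spec.panel_freqs.shape != (genotypes.n_snps,):
        raise ValueError("panel_freqs must have one entry per SNP")
    if genotypes.missing_mask.any():
        raise ValueError("emulate_imputation requires complete dosages")
    out = genotypes.copy()
    if spec.r2_target == 1.0 and spec.maf_penalty == 0.0:
        return out
    if isinstance(animals, str) and animals == "all":
        rows = np.arange(genotypes.n_animals)
    else:
        rows = genotypes.animal_index(animals)
    p_true = (
        genotypes.allele_freqs
        if genotypes.allele_freqs is not None
        else np.nanmean(genotypes.dosage, axis=0) / 2.0
    )
    w = genotypes.dosage[rows]

    centre = np.broadcast_to(2.0 * spec.panel_freqs, w.shape)
    anchors = np.array(centre)
    if pedigree is not None:
        idx = {a: i for i, a in enumerate(genotypes.animal_ids)}
        sire_of = dict(zip(pedigree["animal_id"], pedigree["sire_id"]))
        dam_of = dict(zip(pedigree["animal_id"], pedigree["dam_id"]))
        for k, r in enumerate(rows):
            aid = genotypes.animal_ids[r]
            s_id, d_id = sire_of.get(aid), dam_of.get(aid)
            if s_id in idx and d_id in idx:
                anchors[k] = 0.5 * (
                    genotypes.dosage[idx[s_id]] + genotypes.dosage[idx[d_id]]
                )

    s_global, theta = _calibrate_emulator(spec.r2_target, w, anchors, p_true)
    maf = np.minimum(p_true, 1.0 - p_true)
    s = s_global * (
        1.0 - spec.maf_penalty * np.clip(0.1 - maf, 0.0, None) / 0.1
    )
    s = np.clip(s, 0.0, 1.0)
    rng = np.random.default_rng(seed)
    m = anchors + s * (w - anchors)
    v = (theta * 2.0 * p_true * (1.0 - p_true))[None, :]
    v = np.broadcast_to(v, w.shape)
    # draw 2*Beta(alpha, beta) with mean m and variance v; cap v away from
    # the Beta feasibility bound mu(1-mu) and floor mu inside (0, 1)
    mu = np.clip(m / 2.0, 1e-9, 1.0 - 1e-9)
    vb = np.minimum(v / 4.0, 0.999 * mu * (1.0 - mu))
    with np.errstate(divide="ignore", invalid="ignore"):
        k = mu * (1.0 - mu) / vb - 1.0
    alpha = np.clip(mu * k, 1e-12, None)
    beta = np.clip((1.0 - mu) * k, 1e-12, None)
    zero_noise = vb <= 0
    draws = 2.0 * rng.beta(alpha, beta)
    out.dosage[rows] = np.where(zero_noise, m, draws)
    return out
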