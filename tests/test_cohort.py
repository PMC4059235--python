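import numpy as np
import pandas as pd
import pytest

from gblupsim import (
    ImputationSpec,
    compute_allele_freqs,
    compute_grm,
    emulate_imputation,
    sample_panel_freqs,
    simulate_breeding_values,
    simulate_ebv,
    simulate_founder_haplotypes,
    simulate_pedigree_cohort,
)


def adjacent_correlations(panel):
    h = panel.haplotypes.astype(float)
    chrom = panel.snp_meta["chrom"].to_numpy()
    out = []
    for j in range(1, h.shape[1]):
        if chrom[j] != chrom[j - 1]:
            continue
        c = np.corrcoef(h[:, j - 1], h[:, j])[0, 1]
        if np.isfinite(c):
            out.append(c)
    return np.array(out)


class TestFounderHaplotypes:
    def test_alleles_binary_and_count_even(self):
        p = simulate_founder_haplotypes(50, 200, 2, 0.3, seed=1)
        assert p.haplotypes.shape == (100, 200)
        assert set(np.unique(p.haplotypes)) <= {0, 1}
        assert ((p.snp_meta["freq"] >= 0.05) & (p.snp_meta["freq"] <= 0.5)).all()

    def test_ld_zero_gives_independent_loci(self):
        p = simulate_founder_haplotypes(500, 300, 1, 0.0, seed=2)
        assert np.abs(adjacent_correlations(p)).mean() < 0.05

    def test_ld_copying_chain_hits_target_correlation(self):
        p = simulate_founder_haplotypes(500, 1000, 1, 0.9, seed=3)
        assert adjacent_correlations(p).mean() == pytest.approx(0.9, abs=0.05)

    def test_chromosome_boundaries_break_ld(self):
        p = simulate_founder_haplotypes(400, 400, 4, 0.95, seed=4)
        h = p.haplotypes.astype(float)
        chrom = p.snp_meta["chrom"].to_numpy()
        cross = [np.corrcoef(h[:, j - 1], h[:, j])[0, 1]
                 for j in range(1, 400) if chrom[j] != chrom[j - 1]]
        assert np.abs(cross).max() < 0.2

    def test_deterministic_under_seed(self):
        a = simulate_founder_haplotypes(20, 50, 1, 0.5, seed=9)
        b = simulate_founder_haplotypes(20, 50, 1, 0.5, seed=9)
        c = simulate_founder_haplotypes(20, 50, 1, 0.5, seed=10)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert not np.array_equal(a.haplotypes, c.haplotypes)

    @pytest.mark.parametrize("kwargs", [
        {"n_founders": 1}, {"L": 0}, {"ld_rho": 1.0}, {"ld_rho": -0.1},
    ])
    def test_rejects_bad_arguments(self, kwargs):
        args = {"n_founders": 10, "L": 20, "chromosomes": 1, "ld_rho": 0.5}
        args.update(kwargs)
        with pytest.raises(ValueError):
            simulate_founder_haplotypes(**args, seed=0)


class TestPedigreeCohort:
    def test_offspring_mendelian_consistent_at_every_locus(self):
        panel = simulate_founder_haplotypes(20, 120, 3, 0.4, seed=5)
        geno, ped = simulate_pedigree_cohort(panel, 2, 2, 2,
                                             recomb_per_chrom=0.0, seed=6)
        idx = {a: i for i, a in enumerate(geno.animal_ids)}
        for _, r in ped[ped.sire_id.notna()].iterrows():
            child = geno.dosage[idx[r.animal_id]]
            sire = geno.dosage[idx[r.sire_id]]
            dam = geno.dosage[idx[r.dam_id]]
            # a parent with dosage 0 transmits 0, with dosage 2 transmits 1
            lo = (sire == 2).astype(float) + (dam == 2).astype(float)
            hi = 2.0 - (sire == 0) - (dam == 0)
            assert np.all(child >= lo) and np.all(child <= hi)

    def test_parent_offspring_and_sib_relationships(self):
        panel = simulate_founder_haplotypes(300, 4000, 5, 0.4, seed=7)
        geno, ped = simulate_pedigree_cohort(panel, 8, 3, 2, 1.0, seed=8)
        p = compute_allele_freqs(geno)
        G = compute_grm(geno, p)
        ids = {a: i for i, a in enumerate(G.animal_ids)}
        po, hs = [], []
        off = ped[ped.sire_id.notna()]
        for _, r in off.iterrows():
            po.append(G.values[ids[r.animal_id], ids[r.sire_id]])
        for _, grp in off.groupby("sire_id"):
            a = grp.animal_id.tolist()
            dams = grp.dam_id.tolist()
            for i in range(len(a)):
                for j in range(i + 1, len(a)):
                    if dams[i] != dams[j]:
                        hs.append(G.values[ids[a[i]], ids[a[j]]])
        assert np.mean(po) == pytest.approx(0.5, abs=0.05)
        assert np.mean(hs) == pytest.approx(0.25, abs=0.05)

    def test_rejects_empty_panel(self):
        panel = simulate_founder_haplotypes(5, 10, 1, 0.0, seed=0)
        panel.haplotypes = panel.haplotypes[:, :0]
        panel.snp_meta = panel.snp_meta.iloc[:0]
        with pytest.raises(ValueError, match="empty"):
            simulate_pedigree_cohort(panel, 1, 1, 1, 1.0, seed=0)


class TestBreedingValues:
    def test_tbv_is_centred_dosage_times_effects(self, family_cohort):
        truth = family_cohort["truth"]
        geno = family_cohort["geno"]
        Z = geno.dosage - 2 * family_cohort["freqs"]
        assert np.allclose(truth.tbv, Z @ truth.marker_effects, atol=1e-10)

    def test_variance_matches_target(self, family_cohort):
        assert family_cohort["truth"].tbv.var() == pytest.approx(1.0)

    def test_sparse_qtl_leave_other_effects_zero(self, family_cohort):
        truth = simulate_breeding_values(
            family_cohort["geno"], 0.5, 1.0, n_qtl=25, seed=3
        )
        assert (truth.marker_effects != 0).sum() == 25

    def test_deterministic_under_seed(self, family_cohort):
        g = family_cohort["geno"]
        t1 = simulate_breeding_values(g, 0.5, 1.0, "all", seed=5)
        t2 = simulate_breeding_values(g, 0.5, 1.0, "all", seed=5)
        assert np.array_equal(t1.tbv, t2.tbv)

    def test_rejects_bad_h2(self, family_cohort):
        with pytest.raises(ValueError, match="h2"):
            simulate_breeding_values(family_cohort["geno"], 1.5, 1.0)


class TestEbvSimulator:
    def test_full_reliability_returns_tbv_exactly(self, family_cohort):
        tt = simulate_ebv(family_cohort["truth"], rel_own=1.0, seed=1)
        assert np.allclose(tt["ebv"], family_cohort["truth"].tbv)

    def test_realized_correlation_matches_reliability(self):
        panel = simulate_founder_haplotypes(1100, 200, 2, 0.2, seed=21)
        geno, ped = simulate_pedigree_cohort(panel, 40, 5, 8, 1.0, seed=22)
        truth = simulate_breeding_values(geno, 0.5, 1.0, "all", seed=23,
                                         pedigree=ped)
        tt = simulate_ebv(truth, rel_own=0.74, seed=24)
        r = np.corrcoef(tt["ebv"], truth.tbv)[0, 1]
        assert r == pytest.approx(np.sqrt(0.74), abs=0.04)
        # unit regression of TBV on EBV
        slope = np.polyfit(tt["ebv"], truth.tbv, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.06)

    def test_zero_pa_reliability_gives_zero_parent_average(self, family_cohort):
        tt = simulate_ebv(family_cohort["truth"], 0.7, rel_pa=0.0, seed=2)
        assert (tt["pa_ebv"] == 0).all()

    def test_founders_get_no_parent_average(self, family_cohort):
        tt = simulate_ebv(family_cohort["truth"], 0.7, rel_pa=0.3, seed=3)
        ped = family_cohort["ped"]
        founders = ped["sire_id"].isna().to_numpy()
        assert (tt.loc[founders, "pa_ebv"] == 0).all()
        assert (tt.loc[founders, "rel_pa"] == 0).all()
        assert (tt.loc[~founders, "pa_ebv"] != 0).any()

    def test_rejects_degenerate_reliability(self, family_cohort):
        with pytest.raises(ValueError, match="rel_own"):
            simulate_ebv(family_cohort["truth"], 0.0)
        with pytest.raises(ValueError, match="rel_pa"):
            simulate_ebv(family_cohort["truth"], 0.7, rel_pa=0.5)


class TestPanelFreqs:
    def test_large_panel_recovers_truth(self):
        p = np.random.default_rng(1).uniform(0.05, 0.5, 500)
        f = sample_panel_freqs(p, 10**6, seed=2)
        assert np.abs(f - p).max() < 0.01

    def test_small_panel_unbiased(self):
        p = np.full(10_000, 0.05)
        f = sample_panel_freqs(p, 128, seed=3)
        assert f.mean() == pytest.approx(0.05, abs=0.005)

    def test_clamped_away_from_bounds(self):
        f = sample_panel_freqs(np.full(2000, 0.05), 16, seed=4)
        assert f.min() >= 1 / 32 and f.max() <= 1 - 1 / 32

    def test_deterministic_under_seed(self):
        p = np.linspace(0.06, 0.45, 50)
        assert np.array_equal(sample_panel_freqs(p, 128, seed=7),
                              sample_panel_freqs(p, 128, seed=7))

    def test_rejects_tiny_panel(self):
        with pytest.raises(ValueError, match="H"):
            sample_panel_freqs(np.array([0.2]), 1)


@pytest.fixture(scope="module")
def cohort():
    from gblupsim import qc_filter

    panel = simulate_founder_haplotypes(250, 2000, 4, 0.4, seed=31)
    geno, ped = simulate_pedigree_cohort(panel, 8, 3, 3, 1.0, seed=32)
    geno, _ = qc_filter(geno, min_maf=0.02)
    p = compute_allele_freqs(geno)
    return geno, ped, p


class TestImputationEmulator:

    def test_perfect_accuracy_is_bitwise_identity(self, cohort):
        geno, ped, p = cohort
        spec = ImputationSpec(1.0, 128, sample_panel_freqs(p, 128, seed=1))
        out = emulate_imputation(geno, spec, "all", seed=2, pedigree=ped)
        assert np.array_equal(out.dosage, geno.dosage)

    def test_unselected_animals_untouched(self, cohort):
        geno, ped, p = cohort
        spec = ImputationSpec(0.88, 128, sample_panel_freqs(p, 128, seed=1))
        sel = geno.animal_ids[:5]
        out = emulate_imputation(geno, spec, sel, seed=3, pedigree=ped)
        assert np.array_equal(out.dosage[5:], geno.dosage[5:])
        assert not np.array_equal(out.dosage[:5], geno.dosage[:5])

    def test_dosages_stay_in_range(self, cohort):
        geno, ped, p = cohort
        spec = ImputationSpec(0.8, 64, sample_panel_freqs(p, 64, seed=1))
        out = emulate_imputation(geno, spec, "all", seed=4, pedigree=ped)
        assert out.dosage.min() >= 0.0 and out.dosage.max() <= 2.0

    def test_variance_deflation_is_strict(self, cohort):
        geno, ped, p = cohort
        spec = ImputationSpec(0.88, 128, sample_panel_freqs(p, 128, seed=1))
        out = emulate_imputation(geno, spec, "all", seed=5, pedigree=ped)
        assert (np.var(out.dosage, axis=0).mean()
                < np.var(geno.dosage, axis=0).mean())

    def test_deterministic_under_seed(self, cohort):
        geno, ped, p = cohort
        spec = ImputationSpec(0.9, 128, sample_panel_freqs(p, 128, seed=1))
        a = emulate_imputation(geno, spec, "all", seed=6, pedigree=ped)
        b = emulate_imputation(geno, spec, "all", seed=6, pedigree=ped)
        c = emulate_imputation(geno, spec, "all", seed=7, pedigree=ped)
        assert np.array_equal(a.dosage, b.dosage)
        assert not np.array_equal(a.dosage, c.dosage)

    def test_maf_penalty_degrades_low_maf_snps_more(self, cohort):
        """With a MAF penalty, rare-allele SNPs are imputed with visibly
        larger error than in the unpenalized run (paired, same seed)."""
        geno, ped, p = cohort
        pf = sample_panel_freqs(p, 128, seed=1)
        plain = emulate_imputation(
            geno, ImputationSpec(0.9, 128, pf), "all", seed=8, pedigree=ped,
        )
        hard = emulate_imputation(
            geno, ImputationSpec(0.9, 128, pf, maf_penalty=0.9), "all",
            seed=8, pedigree=ped,
        )
        maf = np.minimum(p, 1 - p)
        low = maf < 0.1

        def mse(imp, mask):
            return np.mean((imp.dosage[:, mask] - geno.dosage[:, mask]) ** 2)

        assert mse(hard, low) > mse(plain, low)
        assert np.allclose(mse(hard, ~low), mse(plain, ~low), rtol=0.05)

    def test_rejects_bad_spec(self, cohort):
        geno, ped, p = cohort
        with pytest.raises(ValueError, match="r2_target"):
            ImputationSpec(0.0, 128, p)
        with pytest.raises(ValueError, match="panel"):
            ImputationSpec(0.9, 1, p)
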