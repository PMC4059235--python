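import numpy as np
import pytest

from gblupsim import (
    compute_allele_freqs,
    compute_grm,
    simulate_breeding_values,
    simulate_founder_haplotypes,
    simulate_pedigree_cohort,
)


@pytest.fixture(scope="session")
def family_cohort():
    """Small sire-family cohort reused across tests: 100 animals, 800 SNPs."""
    panel = simulate_founder_haplotypes(
        n_founders=200, L=800, chromosomes=4, ld_rho=0.4, seed=11
    )
    geno, ped = simulate_pedigree_cohort(
        panel, n_sires=10, dams_per_sire=3, offspring_per_dam=2,
        recomb_per_chrom=1.0, seed=12,
    )
    truth = simulate_breeding_values(
        geno, h2=0.5, sigma2_a=1.0, n_qtl="all", seed=13, pedigree=ped
    )
    freqs = compute_allele_freqs(geno)
    return {"panel": panel, "geno": geno, "ped": ped, "truth": truth,
            "freqs": freqs}


@pytest.fixture(scope="session")
def family_grm(family_cohort):
    return compute_grm(family_cohort["geno"], family_cohort["freqs"])
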