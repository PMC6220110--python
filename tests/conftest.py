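"""Shared fixtures: small synthetic cohorts built once per session."""

import numpy as np
import pytest

from mbherit import io_qc, relatedness, simdata


@pytest.fixture(scope="session")
def small_cohort():
    """Pedigreed cohort of 30 offspring with 200 SNPs (clean, complete)."""
    ped = simdata.simulate_pedigree(4, 3, 3, seed=11)
    G_all = simdata.simulate_genotypes(ped, 200, 0.1, 0.5, 0.0, 0, 0, seed=12)
    off = ped.offspring
    keep = [G_all.samples.index(a) for a in off.animal_id]
    G = io_qc.GenotypeMatrix(list(off.animal_id), G_all.snps.copy(), G_all.dosage[keep])
    K = relatedness.snp_kinship(G)
    return ped, G, K


@pytest.fixture(scope="session")
def family_cohort():
    """Larger pedigreed cohort (300 offspring, 800 SNPs) for estimation tests."""
    ped = simdata.simulate_pedigree(25, 25, 4, seed=21)
    G_all = simdata.simulate_genotypes(ped, 800, 0.1, 0.5, 0.0, 0, 0, seed=22)
    off = ped.offspring
    keep = [G_all.samples.index(a) for a in off.animal_id]
    G = io_qc.GenotypeMatrix(list(off.animal_id), G_all.snps.copy(), G_all.dosage[keep])
    K = relatedness.snp_kinship(G)
    return ped, G, K
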