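import numpy as np
import pytest

from pgblend import (
    SimConfig,
    ensure_pd,
    impute_missing,
    numerator_relationship_matrix,
    qc_filter,
    rescale_g,
    simulate_dataset,
    vanraden_g,
)
from pgblend.pedigree import Pedigree


@pytest.fixture
def trio_pedigree():
    """Two founders and their offspring."""
    return Pedigree([("F1", None, None), ("F2", None, None), ("O", "F1", "F2")])


@pytest.fixture(scope="session")
def small_sim():
    """One small but realistic simulated dataset shared across tests.

    12 full-sib families of 6 lines (72 lines), 300 unlinked markers, a
    little missingness.
    """
    cfg = SimConfig(
        n_founders=16,
        n_generations=3,
        n_families=12,
        sibs_per_family=6,
        n_markers=300,
        missing_rate=0.02,
        seed=42,
    )
    ped, geno_obs, geno_complete, pheno, truth = simulate_dataset(cfg)
    return {
        "cfg": cfg,
        "ped": ped,
        "geno_obs": geno_obs,
        "geno_complete": geno_complete,
        "pheno": pheno,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_matrices(small_sim):
    """A, G, Gs aligned on the line cohort of the shared simulation."""
    ped = small_sim["ped"]
    A = numerator_relationship_matrix(ped).restrict(ped.line_ids)
    geno_qc, _ = qc_filter(small_sim["geno_obs"])
    geno_imp = impute_missing(geno_qc, seed=7)
    G = vanraden_g(geno_imp)
    Gs, coef = rescale_g(G, A)
    return {
        "A": ensure_pd(A),
        "G": ensure_pd(G),
        "Gs": ensure_pd(Gs),
        "coef": coef,
        "geno_imp": geno_imp,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
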