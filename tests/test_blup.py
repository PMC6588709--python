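import numpy as np
import pytest

from pgblend import (
    SimConfig,
    blend,
    ensure_pd,
    fit_single_kernel,
    fit_two_kernel,
    heritability,
    ml_weight_from_agblup,
    numerator_relationship_matrix,
    simulate_dataset,
    snp_blup_oracle,
    vanraden_g,
)
from pgblend.blup import (
    BlupFit,
    ModelError,
    PhenotypeTable,
    VarianceComponents,
    read_phenotypes,
    write_phenotypes,
)
from pgblend.relmat import RelationshipMatrix


def identity_kinship(n):
    return RelationshipMatrix([f"L{i}" for i in range(n)], np.eye(n), "K")


@pytest.fixture
def flat_pheno(rng):
    n = 12
    return PhenotypeTable(
        [f"L{i}" for i in range(n)],
        rng.normal(0.0, 2.0, size=n),
        np.ones(n),
    )


class TestPhenotypeTable:
    def test_positive_se_required(self):
        with pytest.raises(ModelError, match="positive"):
            PhenotypeTable(["a", "b"], [1.0, 2.0], [1.0, 0.0])

    def test_duplicate_lines_rejected(self):
        with pytest.raises(ModelError, match="duplicate"):
            PhenotypeTable(["a", "a"], [1.0, 2.0], [1.0, 1.0])

    def test_tsv_round_trip(self, tmp_path, flat_pheno):
        path = tmp_path / "pheno.tsv"
        write_phenotypes(flat_pheno, str(path))
        back = read_phenotypes(str(path))
        assert back.line_ids == flat_pheno.line_ids
        np.testing.assert_allclose(back.blues, flat_pheno.blues)

    def test_trait_selection(self, tmp_path):
        path = tmp_path / "pheno.tsv"
        path.write_text(
            "line_id\ttrait\tblue\tse\n"
            + "".join(f"L{i}\tyield\t{i}.0\t1.0\n" for i in range(10))
            + "".join(f"L{i}\theight\t{2 * i}.0\t1.0\n" for i in range(10))
        )
        assert read_phenotypes(str(path), "height").blues[3] == 6.0
        with pytest.raises(ModelError, match="several traits"):
            read_phenotypes(str(path))


class TestFitSingleKernel:
    def test_uniform_shrinkage_under_identity(self, flat_pheno):
        fit = fit_single_kernel(flat_pheno, identity_kinship(flat_pheno.n))
        dev_y = flat_pheno.blues - fit.mu
        dev_g = fit.predictions(flat_pheno.line_ids)
        ratios = dev_g / dev_y
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-6)
        assert 0.0 < ratios[0] < 1.0

    def test_duplicated_covariance_row_duplicates_prediction(self, flat_pheno):
        n = flat_pheno.n
        k = np.eye(n + 1)
        k[:n, :n] += 0.3
        # new line V duplicates training line L0's covariance row and diagonal
        k[n, :n] = k[0, :n]
        k[:n, n] = k[0, :n]
        k[n, n] = k[0, 0]
        k[0, n] = k[n, 0] = k[0, 0]
        K = RelationshipMatrix(flat_pheno.line_ids + ["V"], k, "K")
        fit = fit_single_kernel(flat_pheno, K, components=(1.0, 1.0))
        assert fit.gebv["V"] == pytest.approx(fit.gebv["L0"], abs=1e-10)

    def test_too_few_lines(self):
        pheno = PhenotypeTable(["a", "b", "c"], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        with pytest.raises(ModelError, match="at least 10"):
            fit_single_kernel(pheno, RelationshipMatrix(["a", "b", "c"], np.eye(3)))

    def test_location_equivariance(self, small_sim, small_matrices):
        pheno = small_sim["pheno"]
        K = blend(small_matrices["A"], small_matrices["Gs"], 0.4)
        f1 = fit_single_kernel(pheno, K)
        shifted = PhenotypeTable(pheno.line_ids, pheno.blues + 7.5, pheno.ses)
        f2 = fit_single_kernel(shifted, K)
        assert f2.mu == pytest.approx(f1.mu + 7.5, abs=1e-6)
        assert f2.vc.sigma2_g == pytest.approx(f1.vc.sigma2_g, rel=1e-5)
        np.testing.assert_allclose(
            f2.predictions(K.ids), f1.predictions(K.ids), atol=1e-6
        )

    def test_scale_equivariance(self, small_sim, small_matrices):
        pheno = small_sim["pheno"]
        K = blend(small_matrices["A"], small_matrices["Gs"], 0.4)
        f1 = fit_single_kernel(pheno, K)
        c = 3.0
        scaled = PhenotypeTable(pheno.line_ids, c * pheno.blues, pheno.ses)
        f2 = fit_single_kernel(scaled, K)
        assert f2.vc.sigma2_g == pytest.approx(c**2 * f1.vc.sigma2_g, rel=1e-4)
        assert f2.vc.sigma2_e == pytest.approx(c**2 * f1.vc.sigma2_e, rel=1e-4)
        np.testing.assert_allclose(
            f2.predictions(K.ids), c * f1.predictions(K.ids), rtol=1e-4, atol=1e-6
        )

    def test_fixed_r_pins_residual_scale(self, small_sim, small_matrices):
        fit = fit_single_kernel(
            small_sim["pheno"], small_matrices["Gs"], fixed_r=True
        )
        assert fit.vc.sigma2_e == 1.0

    def test_conditional_prediction_crosscheck(self, small_sim, small_matrices):
        # joint-covariance predictions for held-out lines equal
        # K_VT K_TT^-1 g_hat_T when the validation lines carry no phenotype
        pheno = small_sim["pheno"]
        K = small_matrices["Gs"]
        held_out = pheno.line_ids[:10]
        train = pheno.drop(set(held_out))
        fit = fit_single_kernel(train, K, components=(1.0, 1.0))
        k_tt = K.restrict(train.line_ids).values
        k_vt = np.array(
            [[K.loc(v, t) for t in train.line_ids] for v in held_out]
        )
        g_t = fit.predictions(train.line_ids)
        expected = k_vt @ np.linalg.solve(k_tt, g_t)
        np.testing.assert_allclose(
            fit.predictions(held_out), expected, atol=1e-8
        )

    def test_h2_recovery_with_pedigree_kinship(self):
        # light parameter-recovery check; the full-scale version is in
        # the acceptance suite
        h2s = []
        for seed in range(3):
            cfg = SimConfig(
                n_founders=20,
                n_generations=3,
                n_families=30,
                sibs_per_family=8,
                n_markers=400,
                h2_true=0.5,
                w_true=1.0,  # all additive signal pedigree-borne
                missing_rate=0.0,
                seed=100 + seed,
            )
            ped, _, _, pheno, _ = simulate_dataset(cfg)
            A = ensure_pd(numerator_relationship_matrix(ped).restrict(ped.line_ids))
            fit = fit_single_kernel(pheno, A)
            h2s.append(heritability(fit.vc))
        assert np.mean(h2s) == pytest.approx(0.5, abs=0.15)


class TestSnpBlupOracle:
    def test_gblup_equivalence_at_fixed_components(self, rng):
        n, m = 50, 200
        dosages = rng.integers(0, 3, size=(n, m)).astype(float)
        from pgblend.kinship import GenotypeMatrix

        geno = GenotypeMatrix([f"L{i}" for i in range(n)], [f"M{j}" for j in range(m)], dosages)
        ses = rng.uniform(0.5, 1.5, size=n)
        y = rng.normal(0.0, 2.0, size=n)
        pheno = PhenotypeTable(geno.line_ids, y, ses)
        s2g, s2e = 1.3, 0.8
        G = vanraden_g(geno)
        kernel_fit = fit_single_kernel(pheno, G, components=(s2g, s2e))
        mu_o, preds_o = snp_blup_oracle(pheno, geno, components=(s2g, s2e))
        assert mu_o == pytest.approx(kernel_fit.mu, abs=1e-8)
        diff = max(
            abs(preds_o[i] - kernel_fit.gebv[i]) for i in geno.line_ids
        )
        assert diff < 1e-8

    def test_single_marker_two_lines_closed_form(self):
        # y = mu + w*beta + e with w = (-1, +1), Var(beta) = s2b, Var(e) = s2e:
        # beta_hat = s2b * (y2 - y1) / (2 s2b + s2e) by hand
        from pgblend.kinship import GenotypeMatrix

        geno = GenotypeMatrix(["L0", "L1"], ["M0"], np.array([[0.0], [2.0]]))
        y = np.array([1.0, 3.0])
        pheno = PhenotypeTable(["L0", "L1"], y, np.ones(2))
        s2g, s2e = 0.9, 0.7
        s2b = s2g / (2 * 0.5 * 0.5)  # p = 0.5
        beta_hat = s2b * (y[1] - y[0]) / (2 * s2b + s2e)
        mu_o, preds = snp_blup_oracle(pheno, geno, components=(s2g, s2e))
        assert mu_o == pytest.approx(2.0, abs=1e-10)
        assert preds["L1"] == pytest.approx(beta_hat, abs=1e-10)
        assert preds["L0"] == pytest.approx(-beta_hat, abs=1e-10)

    def test_zero_effect_variance(self, rng):
        from pgblend.kinship import GenotypeMatrix

        geno = GenotypeMatrix(
            ["L0", "L1", "L2"], ["M0"], np.array([[0.0], [1.0], [2.0]])
        )
        pheno = PhenotypeTable(["L0", "L1", "L2"], [1.0, 2.0, 6.0], np.ones(3))
        mu_o, preds = snp_blup_oracle(pheno, geno, components=(0.0, 1.0))
        assert mu_o == pytest.approx(3.0)
        assert all(v == 0.0 for v in preds.values())


class TestFitTwoKernel:
    def test_equivalence_with_blended_single_kernel(self, small_sim, small_matrices):
        pheno = small_sim["pheno"]
        A, Gs = small_matrices["A"], small_matrices["Gs"]
        s2m, s2a, s2e = 0.8, 0.5, 1.1
        two = fit_two_kernel(pheno, A, Gs, components=(s2m, s2a, s2e))
        w = s2a / (s2a + s2m)
        K = blend(A, Gs, w)
        one = fit_single_kernel(pheno, K, components=(s2m + s2a, s2e))
        assert two.mu == pytest.approx(one.mu, abs=1e-8)
        diff = max(abs(two.gebv[i] - one.gebv[i]) for i in Gs.ids)
        assert diff < 1e-8

    def test_loglik_comparable_across_parameterizations(
        self, small_sim, small_matrices
    ):
        pheno = small_sim["pheno"]
        A, Gs = small_matrices["A"], small_matrices["Gs"]
        s2m, s2a, s2e = 0.8, 0.5, 1.1
        two = fit_two_kernel(pheno, A, Gs, components=(s2m, s2a, s2e))
        K = blend(A, Gs, s2a / (s2a + s2m))
        one = fit_single_kernel(pheno, K, components=(s2m + s2a, s2e))
        assert two.reml_loglik == pytest.approx(one.reml_loglik, abs=1e-8)

    def test_gebv_splits_into_components(self, small_sim, small_matrices):
        fit = fit_two_kernel(
            small_sim["pheno"],
            small_matrices["A"],
            small_matrices["Gs"],
            components=(0.7, 0.3, 1.0),
        )
        for i in small_matrices["Gs"].ids:
            assert fit.gebv[i] == pytest.approx(fit.gebv_m[i] + fit.gebv_a[i])

    def test_zero_polygenic_truth_hits_boundary(self):
        cfg = SimConfig(
            n_founders=16,
            n_generations=2,
            n_families=20,
            sibs_per_family=6,
            n_markers=400,
            w_true=0.0,
            missing_rate=0.0,
            seed=7,
        )
        ped, _, geno, pheno, _ = simulate_dataset(cfg)
        A = ensure_pd(numerator_relationship_matrix(ped).restrict(ped.line_ids))
        G = ensure_pd(vanraden_g(geno))
        fit = fit_two_kernel(pheno, A, G)
        assert ml_weight_from_agblup(fit) < 0.25


class TestVarianceComponents:
    def test_heritability(self):
        assert heritability(VarianceComponents(2.0, 2.0)) == 0.5
        assert heritability(VarianceComponents(2.0, 0.0)) == 1.0
        assert heritability(VarianceComponents(0.0, 2.0)) == 0.0

    def test_heritability_undefined(self):
        with pytest.raises(ModelError, match="undefined"):
            heritability(VarianceComponents(0.0, 0.0))

    def test_ml_weight_definition(self):
        vc = VarianceComponents(1.0, 1.0, sigma2_m=0.52, sigma2_a=0.48)
        fit = BlupFit(0.0, {}, vc, 0.0, True, "AG-BLUP")
        assert ml_weight_from_agblup(fit) == pytest.approx(0.48)

    def test_ml_weight_zero_polygenic(self):
        vc = VarianceComponents(1.0, 1.0, sigma2_m=1.0, sigma2_a=0.0)
        fit = BlupFit(0.0, {}, vc, 0.0, True, "AG-BLUP")
        assert ml_weight_from_agblup(fit) == 0.0

    def test_ml_weight_requires_two_kernel_fit(self):
        fit = BlupFit(0.0, {}, VarianceComponents(1.0, 1.0), 0.0, True, "G-BLUP")
        with pytest.raises(ModelError, match="two_kernel"):
            ml_weight_from_agblup(fit)
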