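"""Design assembly, AI-REML, derived summaries and pseudo-phenotypes."""

import numpy as np
import pandas as pd
import pytest

from sociogwas.relatedness import numerator_relationship
from sociogwas.simulate import (
    SimulationConfig,
    simulate_breeding_values,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_study,
)
from sociogwas.single_locus import fit_null_lmm
from sociogwas.social_model import (
    GroupedPhenotypes,
    ModelError,
    SocialModelSpec,
    assemble_design,
    derive_summaries,
    fit_social_model,
    genetic_correlation,
    heritability,
    pseudo_phenotypes,
    reml_fit,
    total_heritable_variance,
    total_heritability,
    _restricted_loglik,
    _structure_matrices,
)


@pytest.fixture(scope="module")
def fitted_study():
    cfg = SimulationConfig(n_animals=500, n_founders=100, seed=21)
    study = simulate_study(cfg, with_genotypes=False)
    fit = fit_social_model(study.phenotypes, study.pedigree, keep_history=True)
    return study, fit


class TestAssembleDesign:
    def test_social_rows_sum_to_pen_size_minus_one(self, fitted_study):
        study, fit = fitted_study
        S = fit.bundle.S
        assert np.all(S.sum(axis=1) == study.config.pen_size - 1)
        assert np.all(np.diag(S) == 0)  # self excluded

    def test_singleton_pen_flagged(self):
        df = pd.DataFrame(
            {
                "animal_id": ["a", "b", "c"],
                "y": [1.0, 2.0, 3.0],
                "sex": ["male", "female", "male"],
                "yearmonth": ["m1"] * 3,
                "litter": ["l1", "l1", "l2"],
                "pen": ["p1", "p1", "p2"],
            }
        )
        gp = GroupedPhenotypes(df)
        bundle = assemble_design(gp, SocialModelSpec())
        assert bundle.singleton_records == ["c"]
        assert np.all(bundle.S[2] == 0)

    def test_missing_pen_is_an_error(self):
        df = pd.DataFrame(
            {
                "animal_id": ["a"], "y": [1.0], "sex": ["male"],
                "yearmonth": ["m1"], "litter": ["l1"], "pen": [np.nan],
            }
        )
        with pytest.raises(ModelError, match="pen"):
            GroupedPhenotypes(df)


class TestRemlFit:
    def test_loglik_monotone_nondecreasing(self, fitted_study):
        _, fit = fitted_study
        h = np.array(fit.loglik_history)
        assert (np.diff(h) >= 0).all()
        assert fit.components.converged

    def test_reconstruction_identity(self, fitted_study):
        """Xb + Z_D a_D + Z_S a_S + W l + V g + e reproduces y exactly."""
        _, fit = fitted_study
        recon = fit.fitted_values() + fit.residuals.to_numpy()
        assert np.allclose(recon, fit.bundle.y, atol=1e-8)

    def test_null_social_variance_recovered(self):
        cfg = SimulationConfig(
            n_animals=900, n_founders=120, var_social=0.0, cov_direct_social=0.0,
            seed=5,
        )
        study = simulate_study(cfg, with_genotypes=False)
        fit = fit_social_model(study.phenotypes, study.pedigree)
        c = fit.components
        assert c.converged
        assert abs(c.var_As) <= 3.0 * c.se["var_As"] + 1e-6

    def test_grid_search_oracle_on_toy_data(self):
        """AI-REML optimum matches a dense grid search of the closed-form
        restricted likelihood on a 6-animal toy dataset."""
        df = pd.DataFrame(
            {
                "animal_id": list("abcdef"),
                "y": [2.1, -0.6, 0.8, 1.9, -1.2, 0.4],
                "sex": ["male", "female"] * 3,
                "yearmonth": ["m1"] * 6,
                "litter": ["l1", "l1", "l2", "l2", "l3", "l3"],
                "pen": ["p1", "p1", "p1", "p2", "p2", "p2"],
            }
        )
        ped_df = pd.DataFrame(
            {
                "id": list("abcdef"),
                "sire": ["0", "0", "0", "a", "a", "0"],
                "dam": ["0", "0", "0", "b", "c", "0"],
            }
        )
        from sociogwas.relatedness import Pedigree

        A = numerator_relationship(Pedigree(ped_df))
        gp = GroupedPhenotypes(df)
        spec = SocialModelSpec(fixed_factors=("sex",), include_litter=False,
                               include_group=False)
        bundle = assemble_design(gp, spec, pedigree_ids=A.ids)
        fit = reml_fit(bundle, A)

        # independent oracle: refine a dense grid over the free components
        Ks = _structure_matrices(bundle, A.values)
        names = list(Ks)
        Ks_list = [Ks[k] for k in names]
        assert names == ["var_Ad", "cov_DS", "var_As", "var_e"]
        vy = np.var(bundle.y)
        centre = np.array([vy / 3, 0.0, vy / 3, vy / 3])
        width = np.array([vy, vy, vy, vy])
        best_ll, best = -np.inf, centre
        for _ in range(14):
            axes = [np.linspace(c - w, c + w, 9) for c, w in zip(best, width)]
            grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 4)
            for th in grid:
                if th[0] <= 1e-8 * vy or th[2] < 0 or th[3] <= 1e-8 * vy:
                    continue
                if th[1] ** 2 > th[0] * th[2]:  # genetic block must stay PSD
                    continue
                try:
                    ll = _restricted_loglik(th, Ks_list, bundle.y, bundle.X)
                except np.linalg.LinAlgError:
                    continue
                if ll > best_ll:
                    best_ll, best = ll, th
            width = width / 3.0
        assert fit.loglik == pytest.approx(best_ll, abs=1e-4)

    def test_reduced_model_matches_spectral_reml_oracle(self):
        """With the social/litter/group terms dropped, the fit equals an
        independent single-component REML implemented by eigendecomposition."""
        cfg = SimulationConfig(
            n_animals=400, n_founders=80, var_social=0.0, cov_direct_social=0.0,
            var_litter=0.0, var_group=0.0, seed=13,
        )
        study = simulate_study(cfg, with_genotypes=False)
        ph = study.phenotypes
        A = numerator_relationship(study.pedigree)
        spec = SocialModelSpec(fixed_factors=(), include_social=False,
                               include_litter=False, include_group=False)
        bundle = assemble_design(ph, spec, pedigree_ids=A.ids)
        fit = reml_fit(bundle, A, tol=1e-10)

        idx = bundle.record_to_pedigree
        Arec = A.values[np.ix_(idx, idx)]
        null = fit_null_lmm(bundle.y, Arec, sample_ids=ph.animal_ids)
        c = fit.components
        ratio_ai = c.var_e / c.var_Ad
        assert ratio_ai == pytest.approx(null.delta, rel=1e-3)
        assert c.var_Ad == pytest.approx(null.sigma_g2, rel=1e-3)

    def test_singular_fixed_design_rejected(self, fitted_study):
        study, _ = fitted_study
        df = study.phenotypes.data.copy()
        df["dup"] = df["sex"]
        gp = GroupedPhenotypes(df)
        spec = SocialModelSpec(fixed_factors=("sex", "dup"))
        A = numerator_relationship(study.pedigree)
        bundle = assemble_design(gp, spec, pedigree_ids=A.ids)
        with pytest.raises(ModelError, match="singular"):
            reml_fit(bundle, A)


class TestSummaries:
    def test_heritability_and_t2_pure_ratios(self):
        assert heritability(1173.85, 5335.67) == pytest.approx(0.22, abs=0.005)
        assert total_heritability(32734.68, 33449.05) == pytest.approx(0.98, abs=0.005)

    def test_tbv_with_zero_covariance(self):
        assert total_heritable_variance(100.0, 0.0, 2.0, 10) == pytest.approx(
            100.0 + 81 * 2.0
        )

    def test_zero_variance_correlation_convention(self):
        assert genetic_correlation(0.0, 5.0, 10.0) == 0.0
        assert genetic_correlation(4.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_summaries_from_fit(self, fitted_study):
        _, fit = fitted_study
        s = derive_summaries(fit, n=10)
        c = fit.components
        assert s["var_P"] == pytest.approx(
            c.var_Ad + c.var_litter + c.var_group + c.var_e
        )
        assert s["var_TBV"] == pytest.approx(
            total_heritable_variance(c.var_Ad, c.cov_DS, c.var_As, 10)
        )
        if c.var_Ad >= 0 and s["var_P"] >= c.var_Ad:
            assert 0.0 <= s["h2"] <= 1.0


class TestPseudoPhenotypes:
    def test_algebraic_identity(self, fitted_study):
        """The two corrections differ only in which genetic term they keep:
        dge + sge - 2e equals own direct BLUP + summed pen-mate social BLUPs."""
        _, fit = fitted_study
        dge = pseudo_phenotypes(fit, "dge")
        sge = pseudo_phenotypes(fit, "sge")
        e = fit.residuals
        b = fit.bundle
        own_d = fit.blup_direct.to_numpy()[b.record_to_pedigree]
        mate_s = b.S @ fit.blup_social.to_numpy()[b.record_to_pedigree]
        assert np.allclose(dge + sge - 2 * e, own_d + mate_s, atol=1e-9)

    def test_component_sum_reconstructs_y(self, fitted_study):
        _, fit = fitted_study
        b = fit.bundle
        xb = b.X @ fit.fixed_solutions.to_numpy()
        dge = pseudo_phenotypes(fit, "dge").to_numpy()
        sge = pseudo_phenotypes(fit, "sge").to_numpy()
        litter = fit.blup_litter.reindex(b.W_labels).to_numpy()
        group = fit.blup_group.reindex(b.V_labels).to_numpy()
        e = fit.residuals.to_numpy()
        assert np.allclose(xb + dge + sge - e + litter + group, b.y, atol=1e-8)

    def test_near_noiseless_recovery_of_true_direct_bv(self):
        cfg = SimulationConfig(
            n_animals=400, n_founders=80, var_residual=1e-4, var_litter=0.0,
            var_group=0.0, fixed_effect_sd=0.0, seed=3,
        )
        study = simulate_study(cfg, with_genotypes=False)
        fit = fit_social_model(study.phenotypes, study.pedigree)
        dge = pseudo_phenotypes(fit, "dge")
        truth = study.true_direct_bv.loc[dge.index]
        assert np.corrcoef(dge, truth)[0, 1] > 0.99

    def test_sample_alignment_and_unknown_animal(self, fitted_study):
        _, fit = fitted_study
        ids = fit.bundle.record_ids[:5][::-1]
        out = pseudo_phenotypes(fit, "dge", ids)
        assert list(out.index) == ids
        with pytest.raises(ModelError, match="without phenotype"):
            pseudo_phenotypes(fit, "dge", ["nobody"])

    def test_unknown_kind_rejected(self, fitted_study):
        _, fit = fitted_study
        with pytest.raises(ValueError, match="dge"):
            pseudo_phenotypes(fit, "both")


class TestBreedingValueSimulator:
    def test_founder_independence_when_cov_zero(self):
        cfg = SimulationConfig(
            n_animals=10_000, n_founders=10_000, cov_direct_social=0.0, seed=1
        )
        ped = simulate_pedigree(cfg)
        a_D, a_S = simulate_breeding_values(ped, cfg)
        r = np.corrcoef(a_D, a_S)[0, 1]
        assert abs(r) < 0.03

    def test_zero_social_variance_gives_zero_bvs(self):
        cfg = SimulationConfig(
            n_animals=200, n_founders=50, var_social=0.0, cov_direct_social=0.0, seed=2
        )
        ped = simulate_pedigree(cfg)
        _, a_S = simulate_breeding_values(ped, cfg)
        assert np.all(a_S.to_numpy() == 0.0)

    def test_full_sib_covariance_matches_pedigree_theory(self):
        """Across many replicate trios, Cov(direct BV of sibs) ~ A_sib * var;
        the A entry itself comes from the tabular recursion (0.5)."""
        cfg = SimulationConfig(n_animals=4, n_founders=2, litter_size_range=(2, 2),
                               n_generations=1, seed=0)
        ped = simulate_pedigree(cfg)
        A = numerator_relationship(ped).values
        assert A[2, 3] == 0.5
        rng = np.random.default_rng(123)
        sib_pairs = np.empty((10_000, 2))
        for r in range(10_000):
            a_D, _ = simulate_breeding_values(ped, cfg, rng)
            sib_pairs[r] = a_D.to_numpy()[2:]
        emp = np.cov(sib_pairs.T)[0, 1]
        expected = 0.5 * cfg.var_direct
        assert emp == pytest.approx(expected, rel=0.08)

    def test_phenotype_moment_recovery_unrelated_pen_mates(self):
        """Empirical Var(P) matches var_direct + (n-1) var_social + var_litter
        + var_group + var_residual when pen mates are unrelated founders."""
        cfg = SimulationConfig(
            n_animals=2000, n_founders=2000, fixed_effect_sd=0.0, seed=31
        )
        ped = simulate_pedigree(cfg)
        # founders are unpenned by construction; assign pens directly
        df = ped.records.copy()
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(df))
        df["pen"] = ""
        df["yearmonth"] = "m1"
        df["litter"] = [f"l{i}" for i in range(len(df))]  # one per animal
        for k in range(len(df) // cfg.pen_size):
            df.loc[df.index[perm[k * 10:(k + 1) * 10]], "pen"] = f"p{k}"
        from sociogwas.relatedness import Pedigree

        ped2 = Pedigree(df)
        bvs = simulate_breeding_values(ped2, cfg, np.random.default_rng(2))
        ph = simulate_phenotypes(ped2, bvs, cfg, np.random.default_rng(3))
        expected = (cfg.var_direct + 9 * cfg.var_social + cfg.var_litter
                    + cfg.var_group + cfg.var_residual)
        assert np.var(ph.data["y"]) == pytest.approx(expected, rel=0.05)

    def test_self_exclusion_algebraic(self):
        """On a noise-free pen the phenotype is own direct BV plus the others'
        social BVs; the focal animal's own social BV never appears."""
        cfg = SimulationConfig(
            n_animals=40, n_founders=20, pen_size=4, var_litter=0.0, var_group=0.0,
            var_residual=0.0, fixed_effect_sd=0.0, litter_size_range=(4, 4), seed=4,
        )
        study = simulate_study(cfg, with_genotypes=False)
        ph = study.phenotypes.data.set_index("animal_id")
        a_D, a_S = study.true_direct_bv, study.true_social_bv
        for pen, members in study.phenotypes.pen_members().items():
            total_s = a_S.loc[members].sum()
            for m in members:
                expected = a_D.loc[m] + (total_s - a_S.loc[m])
                assert ph.loc[m, "y"] == pytest.approx(expected, abs=1e-9)

    def test_all_zero_variances_give_zero_phenotypes(self):
        cfg = SimulationConfig(
            n_animals=60, n_founders=20, pen_size=4, litter_size_range=(4, 4),
            var_direct=0.0, var_social=0.0, cov_direct_social=0.0, var_litter=0.0,
            var_group=0.0, var_residual=0.0, fixed_effect_sd=0.0, seed=6,
        )
        study = simulate_study(cfg, with_genotypes=False)
        assert np.all(study.phenotypes.data["y"].to_numpy() == 0.0)
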