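"""Bivariate ACE likelihoods, fitting, model comparison, derived estimates."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from acelink.ace import (AceModelSpec, binary_cell_counts, binary_pair_loglik,
                         compare_models, continuous_pair_loglik,
                         derived_estimates, fit_ace, fit_model_ladder,
                         implied_pair_covariance, _prep_continuous, _unpack)
from acelink.presets import load_preset, pair_components, simulate_pairs_preset
from acelink.simulate import CovariateModel, simulate_kin_pairs
from acelink.types import ComponentMatrices, PairType

Z = np.zeros((2, 2))


def _pairs_df(vals, pair_type="MZ", sex=None, by=None):
    vals = np.atleast_2d(np.asarray(vals, dtype=float))
    n = vals.shape[0]
    return pd.DataFrame({
        "pair_id": np.arange(n), "pair_type": pair_type,
        "m1_trait1": vals[:, 0], "m1_trait2": vals[:, 1],
        "m2_trait1": vals[:, 2], "m2_trait2": vals[:, 3],
        "m1_sex": 0 if sex is None else sex[:, 0],
        "m2_sex": 0 if sex is None else sex[:, 1],
        "m1_by": 1975 if by is None else by[:, 0],
        "m2_by": 1975 if by is None else by[:, 1],
    })


@pytest.fixture(scope="module")
def pop_components(liability_preset):
    return pair_components(liability_preset)


class TestImpliedCovariance:
    def test_mz_without_shared_env_cross_block_is_va(self, pop_components):
        sigma = implied_pair_covariance(pop_components, "MZ")
        np.testing.assert_allclose(sigma[:2, 2:], pop_components.V_A, atol=1e-12)

    def test_mhs_cross_block_quarter_va(self, pop_components):
        # A-only model: half-sibling cross block is 0.25 V_A
        sigma = implied_pair_covariance(pop_components, "MHS")
        np.testing.assert_allclose(sigma[:2, 2:], 0.25 * pop_components.V_A,
                                   atol=1e-12)
        np.testing.assert_allclose(np.diag(sigma[:2, 2:]),
                                   [0.25 * 0.55, 0.25 * 0.57], atol=1e-6)

    def test_within_person_block_same_for_all_types(self, pop_components):
        blocks = [implied_pair_covariance(pop_components, t)[:2, :2]
                  for t in ("MZ", "DZ", "FS", "MHS")]
        for b in blocks[1:]:
            np.testing.assert_allclose(b, blocks[0], atol=1e-12)

    def test_symmetry(self, pop_components):
        sigma = implied_pair_covariance(pop_components, "DZ")
        np.testing.assert_allclose(sigma, sigma.T, atol=1e-12)


class TestContinuousLoglik:
    spec = AceModelSpec(included=("A", "E"), measurement="continuous",
                        covariates=False)

    def _theta(self, VA, VE):
        return np.array([VA[0, 0], VA[0, 1], VA[1, 1],
                         VE[0, 0], VE[0, 1], VE[1, 1], 0.0, 0.0])

    def test_matches_mvn_density_oracle(self, rng):
        """Log-likelihood equals the generic 4D normal density, pair by pair."""
        VA = np.array([[0.4, 0.1], [0.1, 0.5]])
        VE = np.array([[0.6, 0.05], [0.05, 0.5]])
        comps = ComponentMatrices(V_A=VA, V_C=Z, V_E=VE)
        vals = rng.normal(size=(50, 4))
        df = _pairs_df(vals, pair_type="DZ")
        groups = _prep_continuous(df, by_ref=1975.0)
        ours = continuous_pair_loglik(self._theta(VA, VE), groups, self.spec)
        sigma = implied_pair_covariance(comps, "DZ")
        oracle = multivariate_normal(mean=np.zeros(4), cov=sigma).logpdf(vals).sum()
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_zero_cross_block_factorizes(self, rng):
        """With A = 0 the pair likelihood is a product over the two members."""
        VE = np.array([[1.0, 0.3], [0.3, 1.0]])
        vals = rng.normal(size=(20, 4))
        df = _pairs_df(vals, pair_type="MZ")
        groups = _prep_continuous(df, by_ref=1975.0)
        ours = continuous_pair_loglik(self._theta(Z, VE), groups, self.spec)
        biv = multivariate_normal(mean=np.zeros(2), cov=VE)
        oracle = biv.logpdf(vals[:, :2]).sum() + biv.logpdf(vals[:, 2:]).sum()
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_fiml_marginalizes_missing_member(self, rng):
        """A pair with member 2 missing contributes member 1's marginal."""
        VA = np.array([[0.5, 0.2], [0.2, 0.5]])
        VE = np.array([[0.5, 0.1], [0.1, 0.5]])
        vals = rng.normal(size=(10, 4))
        vals[:, 2:] = np.nan
        df = _pairs_df(vals, pair_type="MZ")
        groups = _prep_continuous(df, by_ref=1975.0)
        ours = continuous_pair_loglik(self._theta(VA, VE), groups, self.spec)
        P = VA + VE
        oracle = multivariate_normal(mean=np.zeros(2), cov=P).logpdf(
            vals[:, :2]).sum()
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_member_swap_invariance(self, rng):
        VA = np.array([[0.4, 0.1], [0.1, 0.5]])
        VE = np.array([[0.6, 0.05], [0.05, 0.5]])
        vals = rng.normal(size=(30, 4))
        swapped = vals[:, [2, 3, 0, 1]]
        g1 = _prep_continuous(_pairs_df(vals, "FS"), 1975.0)
        g2 = _prep_continuous(_pairs_df(swapped, "FS"), 1975.0)
        th = self._theta(VA, VE)
        assert continuous_pair_loglik(th, g1, self.spec) == pytest.approx(
            continuous_pair_loglik(th, g2, self.spec), abs=1e-10)

    def test_non_pd_total_penalized_not_crashed(self, rng):
        vals = rng.normal(size=(5, 4))
        groups = _prep_continuous(_pairs_df(vals, "MZ"), 1975.0)
        th = self._theta(np.diag([-2.0, -2.0]), np.eye(2))
        assert continuous_pair_loglik(th, groups, self.spec) < -1e9


class TestBinaryLoglik:
    spec = AceModelSpec(included=("A", "E"), measurement="binary",
                        covariates=False)

    def _theta(self, VA, e12, t1, t2):
        return np.array([VA[0, 0], VA[0, 1], VA[1, 1], e12, t1, t2])

    def test_independence_all_cells_equal(self):
        """Identity correlation, thresholds 0: every cell has p = 1/16."""
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 2, size=(40, 4)).astype(float)
        df = _pairs_df(vals, "FS")
        strata = binary_cell_counts(df, by_ref=1975.0)
        th = self._theta(Z, 0.0, 0.0, 0.0)
        ll = binary_pair_loglik(th, strata, self.spec, n_points=4096)
        assert ll == pytest.approx(40 * np.log(1 / 16), abs=1e-4)

    def test_matches_per_pair_rectangle_oracle(self, rng):
        """Aggregated cell likelihood equals the unaggregated per-pair product."""
        from acelink.liability import RectangleSpec, mvn_rectangle
        VA = np.array([[0.5, 0.15], [0.15, 0.55]])
        e12 = 0.1
        t1, t2 = 0.8, 0.3
        comps, _ = _unpack(self._theta(VA, e12, t1, t2), self.spec)
        vals = rng.integers(0, 2, size=(50, 4)).astype(float)
        df = _pairs_df(vals, "FS")
        strata = binary_cell_counts(df, by_ref=1975.0)
        ours = binary_pair_loglik(self._theta(VA, e12, t1, t2), strata,
                                  self.spec, n_points=8192)
        sigma = implied_pair_covariance(comps, "FS")
        thr = np.array([t1, t2, t1, t2])
        oracle = 0.0
        for row in vals:
            lower = np.where(row == 1, thr, -np.inf)
            upper = np.where(row == 1, np.inf, thr)
            p = mvn_rectangle(RectangleSpec(lower, upper, sigma), accuracy=1e-8)
            oracle += np.log(p)
        assert ours == pytest.approx(oracle, abs=1e-3)

    def test_stratum_split_leaves_loglik_unchanged(self, rng):
        """Splitting a stratum with identical covariates is a no-op."""
        vals = rng.integers(0, 2, size=(60, 4)).astype(float)
        df = _pairs_df(vals, "FS")
        half = _pairs_df(vals[:30], "FS")
        other = _pairs_df(vals[30:], "FS")
        th = self._theta(np.diag([0.4, 0.4]), 0.05, 0.5, 0.5)
        s_all = binary_cell_counts(df, 1975.0)
        ll_all = binary_pair_loglik(th, s_all, self.spec)
        ll_split = (binary_pair_loglik(th, binary_cell_counts(half, 1975.0),
                                       self.spec)
                    + binary_pair_loglik(th, binary_cell_counts(other, 1975.0),
                                         self.spec))
        assert ll_all == pytest.approx(ll_split, abs=1e-10)

    def test_unit_liability_identification(self):
        comps, _ = _unpack(self._theta(np.diag([0.3, 0.7]), 0.0, 0.0, 0.0),
                           self.spec)
        np.testing.assert_allclose(np.diag(comps.total), [1.0, 1.0], atol=1e-12)


class TestFitAce:
    def test_null_recovery(self):
        """Pure-E data: fitted A and C variance shares near zero."""
        comps = ComponentMatrices(V_A=Z, V_C=Z,
                                  V_E=np.array([[1.0, 0.3], [0.3, 1.0]]))
        df = simulate_kin_pairs(comps, {"MZ": 10_000, "DZ": 10_000}, seed=21)
        fit = fit_ace(df, AceModelSpec(included=("A", "C", "E")),
                      compute_se=False)
        assert fit.converged
        assert np.all(np.abs(np.diag(fit.components.V_A)) < 0.03)
        assert np.all(np.abs(np.diag(fit.components.V_C)) < 0.03)

    def test_twin_preset_recovery(self, twin_pairs):
        """AE fit on the twin preset recovers the generating A shares."""
        fit = fit_ace(twin_pairs, AceModelSpec(included=("A", "E")),
                      compute_se=False)
        assert fit.converged
        d = derived_estimates(fit)
        assert d.shares["A"][0] == pytest.approx(0.36, abs=0.04)
        assert d.shares["A"][1] == pytest.approx(0.46, abs=0.04)

    def test_falconer_moment_consistency(self, twin_pairs):
        """Fitted a^2 tracks 2 (r_MZ - r_DZ) computed on the same sample."""
        fit = fit_ace(twin_pairs, AceModelSpec(included=("A", "E")),
                      compute_se=False)
        d = derived_estimates(fit)
        r = {}
        for lab in ("MZ", "DZ"):
            sub = twin_pairs[twin_pairs.pair_type == lab]
            r[lab] = np.corrcoef(sub.m1_trait1, sub.m2_trait1)[0, 1]
        falconer = 2 * (r["MZ"] - r["DZ"])
        assert d.shares["A"][0] == pytest.approx(falconer, abs=0.05)

    def test_trait_swap_transposes_components(self, twin_pairs):
        spec = AceModelSpec(included=("A", "E"))
        fit1 = fit_ace(twin_pairs, spec, compute_se=False)
        swapped = twin_pairs.rename(columns={
            "m1_trait1": "m1_trait2", "m1_trait2": "m1_trait1",
            "m2_trait1": "m2_trait2", "m2_trait2": "m2_trait1"})
        fit2 = fit_ace(swapped, spec, compute_se=False)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-4)
        d1, d2 = derived_estimates(fit1), derived_estimates(fit2)
        assert d1.correlations["A"] == pytest.approx(d2.correlations["A"],
                                                     abs=2e-3)
        assert d1.shares["A"][0] == pytest.approx(d2.shares["A"][1], abs=2e-3)

    def test_single_pair_type_identifiability_error(self, twin_pairs):
        mz = twin_pairs[twin_pairs.pair_type == "MZ"]
        with pytest.raises(ValueError, match="relatedness"):
            fit_ace(mz, AceModelSpec(included=("A", "E")))

    def test_parameter_recovery_replicates(self, twin_preset):
        """True components inside 3 estimated SEs in most seeded replicates."""
        from acelink.presets import pair_components
        comps = pair_components(twin_preset)
        true = {"A11": comps.V_A[0, 0], "A12": comps.V_A[0, 1],
                "A22": comps.V_A[1, 1], "E11": comps.V_E[0, 0],
                "E12": comps.V_E[0, 1], "E22": comps.V_E[1, 1]}
        hits, total = 0, 0
        for seed in range(8):
            df = simulate_pairs_preset(twin_preset, seed=100 + seed,
                                       counts={"MZ": 1200, "DZ": 1500})
            fit = fit_ace(df, AceModelSpec(included=("A", "E")), compute_se=True)
            se = np.sqrt(np.diag(fit.param_cov))
            ok = all(abs(fit.params[fit.param_names.index(k)] - v)
                     < 3 * se[fit.param_names.index(k)]
                     for k, v in true.items())
            hits += ok
            total += 1
        assert hits >= total - 1


class TestCompareModels:
    def test_identical_logliks_prefer_reduced(self, twin_pairs):
        full = fit_ace(twin_pairs, AceModelSpec(included=("A", "C", "E")),
                       compute_se=False)
        red = fit_ace(twin_pairs, AceModelSpec(included=("A", "E")),
                      compute_se=False)
        cmp_ = compare_models(full, red)
        assert cmp_.df == 3  # dropping V_C frees its 3 symmetric entries
        assert cmp_.lrt >= 0
        assert cmp_.delta_aic == pytest.approx(
            -2 * (red.loglik - full.loglik) + 2 * (red.n_free - full.n_free),
            abs=1e-10)

    def test_no_fit_loss_gives_p_one(self, twin_pairs):
        full = fit_ace(twin_pairs, AceModelSpec(included=("A", "E")),
                       compute_se=False)
        forced = fit_ace(twin_pairs, AceModelSpec(included=("E",)),
                         compute_se=False)
        forced.loglik = full.loglik  # construct an identical-likelihood case
        cmp_ = compare_models(full, forced)
        assert cmp_.lrt == 0.0 and cmp_.p_value == 1.0
        assert cmp_.preferred == forced.spec.label

    def test_non_nested_rejected(self, twin_pairs):
        ae = fit_ace(twin_pairs, AceModelSpec(included=("A", "E")),
                     compute_se=False)
        ce = fit_ace(twin_pairs, AceModelSpec(included=("C", "E")),
                     compute_se=False)
        with pytest.raises(ValueError, match="nested"):
            compare_models(ae, ce)


class TestDerivedEstimates:
    def test_population_genetic_correlation_identity(self, pop_components):
        """rg = V_A[1,2] / sqrt(V_A[1,1] V_A[2,2]) = 0.28 by construction."""
        spec = AceModelSpec(included=("A", "E"), measurement="binary",
                            covariates=False)
        from acelink.types import FitResult
        theta = np.array([0.55, pop_components.V_A[0, 1], 0.57,
                          pop_components.V_E[0, 1], 2.62, 1.57])
        comps, _ = _unpack(theta, spec)
        fit = FitResult(components=comps, mean_coefs={}, loglik=0.0,
                        n_free=6, converged=True, spec=spec,
                        param_names=spec.param_names(), params=theta)
        d = derived_estimates(fit)
        assert d.correlations["A"] == pytest.approx(0.28, abs=1e-6)
        # standardized binary fit: shares sum to one per trait
        for t in range(2):
            assert sum(d.shares[c][t] for c in d.shares) == pytest.approx(
                1.0, abs=1e-10)
        # implied phenotypic correlation from the population best-fit values
        assert d.phenotypic_correlation == pytest.approx(0.2755, abs=5e-4)

    def test_negative_diagonal_flags_undefined_correlation(self):
        spec = AceModelSpec(included=("A", "C", "E"), covariates=False)
        theta = np.array([0.5, 0.1, 0.5, -0.05, 0.0, -0.02,
                          0.6, 0.1, 0.6, 0.0, 0.0])
        comps, _ = _unpack(theta, spec)
        from acelink.types import FitResult
        fit = FitResult(components=comps, mean_coefs={}, loglik=0.0,
                        n_free=11, converged=True, spec=spec,
                        param_names=spec.param_names(), params=theta)
        d = derived_estimates(fit)
        assert d.correlations["C"] is None
        assert any("negative variance" in w for w in d.warnings)


class TestModelLadder:
    def test_ladder_on_twin_data_selects_ae(self, twin_pairs):
        sub = pd.concat([
            twin_pairs[twin_pairs.pair_type == "MZ"].head(1500),
            twin_pairs[twin_pairs.pair_type == "DZ"].head(1800)])
        ladder = fit_model_ladder(sub, "continuous", seed=0)
        assert set(ladder["fits"]) == {"ACE-ACE", "AE-AE", "CE-CE", "E-E"}
        assert ladder["comparisons"]["AE-AE"].df == 3
        assert ladder["best"] in ("AE-AE", "CE-CE")  # AE truth; CE only if odd draw
        assert ladder["comparisons"]["E-E"].p_value < 0.05
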