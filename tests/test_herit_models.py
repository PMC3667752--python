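"""Named estimators: liability conversion (numeric-integration oracle),
prevalence, single/joint/ADE model behaviour on scaled-down cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize

from heritkit.genotype_io import PhenotypeTable, ValidationError
from heritkit.grm import build_ibd, build_ibd2, build_ibs, threshold_ibs
from heritkit.herit_models import (estimate_h2, estimate_joint,
                                   estimate_prevalence, fit_ade,
                                   observed_to_liability, report_on_liability)
from heritkit.simulate import PairBlock, SimulationSpec, simulate_cohort


def _phi(x):
    return np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)


def _threshold_model_multiplier(K):
    """Observed-to-liability multiplier K(1-K)/z^2 computed by numeric
    integration alone: the threshold solves the tail-integral equation and
    z is the density there (no scipy.stats shortcuts)."""
    T = optimize.brentq(
        lambda t: integrate.quad(_phi, t, 40.0)[0] - K, -12.0, 12.0,
        xtol=1e-13)
    z = _phi(T)
    return K * (1.0 - K) / z ** 2


class TestLiabilityConversion:
    def test_zero_maps_to_zero(self):
        assert observed_to_liability(0.0, 0.1, 0.3) == 0.0

    def test_half_prevalence_half_cases(self):
        """K = P = 0.5: multiplier is 0.25/phi(0)^2 ~ pi/2."""
        out = observed_to_liability(0.2, 0.5, 0.5)
        assert out == pytest.approx(0.2 * 0.25 / _phi(0.0) ** 2, rel=1e-10)
        assert out == pytest.approx(0.31416, abs=1e-4)

    @pytest.mark.parametrize("K", [0.01, 0.1, 0.3, 0.5])
    def test_matches_numeric_integration(self, K):
        """With P = K (no ascertainment) the conversion reduces to the
        threshold-model multiplier K(1-K)/z^2; agree to 1e-6."""
        expected = _threshold_model_multiplier(K)
        assert observed_to_liability(1.0, K, K) == pytest.approx(
            expected, abs=1e-6)

    def test_ascertainment_factor(self):
        """Oversampling cases (P > K) shrinks the estimate by
        K(1-K)/(P(1-P)) relative to random sampling."""
        K, P = 0.01, 0.5
        base = observed_to_liability(0.3, K, K)
        corrected = observed_to_liability(0.3, K, P)
        assert corrected == pytest.approx(
            base * (K * (1 - K)) / (P * (1 - P)), rel=1e-12)

    def test_monotone_in_h2_and_continuous_in_K(self):
        hs = np.linspace(0.0, 1.0, 21)
        outs = [observed_to_liability(h, 0.1, 0.2) for h in hs]
        assert all(b > a for a, b in zip(outs, outs[1:]))
        Ks = np.linspace(0.05, 0.5, 200)
        vals = np.array([observed_to_liability(0.3, K, 0.2) for K in Ks])
        assert np.abs(np.diff(vals)).max() < 0.05  # no jumps on a fine grid

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            observed_to_liability(0.2, 0.0, 0.3)
        with pytest.raises(ValueError):
            observed_to_liability(0.2, 0.3, 1.0)

    def test_negative_h2_passes_with_warning(self):
        with pytest.warns(RuntimeWarning):
            out = observed_to_liability(-0.05, 0.1, 0.1)
        assert out < 0


class TestEstimatePrevalence:
    def test_cohort_counts(self):
        vals = np.r_[np.ones(419), np.zeros(10085)]
        assert estimate_prevalence(vals) == pytest.approx(0.0399, abs=5e-5)

    def test_one_case_one_control(self):
        assert estimate_prevalence([1.0, 0.0]) == 0.5

    def test_missing_excluded(self):
        assert estimate_prevalence([1.0, 0.0, np.nan, np.nan]) == 0.5

    def test_all_cases_rejected(self):
        with pytest.raises(ValueError):
            estimate_prevalence([1.0, 1.0])

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            estimate_prevalence([np.nan, np.nan])


class TestBuildDesign:
    def _table(self):
        import pandas as pd
        df = pd.DataFrame({
            "q": [1.0, 3.0, 5.0, 7.0, np.nan, 2.0],
            "cc": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
            "age": [30.0, 40.0, 50.0, 60.0, 70.0, 45.0],
            "region": ["north", "south", "north", "east", "south", "north"],
        }, index=pd.Index([f"s{i}" for i in range(6)], name="id"))
        return PhenotypeTable(df)

    def test_quantitative_trait_standardized_missing_dropped(self):
        from heritkit.herit_models import build_design
        y, X, ids = build_design(self._table(), "q", ["age", "region"],
                                 [f"s{i}" for i in range(6)])
        assert "s4" not in ids and len(ids) == 5  # missing trait dropped
        assert y.mean() == pytest.approx(0.0, abs=1e-12)
        assert y.std(ddof=1) == pytest.approx(1.0)
        # intercept + age + 2 region dummies (3 levels, first as reference)
        assert X.shape == (5, 4)
        assert (X[:, 0] == 1).all()

    def test_dichotomous_trait_left_on_observed_scale(self):
        from heritkit.herit_models import build_design
        y, X, ids = build_design(self._table(), "cc", [],
                                 [f"s{i}" for i in range(6)])
        assert set(np.unique(y)) == {0.0, 1.0}

    def test_alignment_follows_requested_order(self):
        from heritkit.herit_models import build_design
        order = ["s3", "s0", "s5"]
        y, X, ids = build_design(self._table(), "q", [], order)
        assert ids == order


class TestSingleComponent:
    def test_sib_cohort_recovers_h2(self, sib_cohort_small):
        """IBD-matrix fit on a sib-pair cohort lands near the generative
        heritability (single replicate, so only a loose sanity band)."""
        c = sib_cohort_small
        K = build_ibd(c.true_ibd, c.sample_ids)
        rep = estimate_h2(c.phenotype, [], K)
        assert rep.model == "IBD"
        assert rep.fit.converged
        assert abs(rep.h2_total - 0.5) < 4 * rep.h2_total_se

    def test_pure_noise_mean_near_zero(self):
        """Unconstrained fits on pure-noise phenotypes average to ~0."""
        rng = np.random.default_rng(42)
        spec = SimulationSpec(pair_blocks=[PairBlock(60, 0.5)],
                              m_observed=50, m_unobserved=0,
                              h2_observed=0.0, h2_unobserved=0.0, seed=0)
        ests = []
        for s in range(30):
            c = simulate_cohort(SimulationSpec(
                pair_blocks=[PairBlock(60, 0.5)], m_observed=50,
                m_unobserved=0, h2_observed=0.0, h2_unobserved=0.0, seed=s))
            K = build_ibd(c.true_ibd, c.sample_ids)
            rep = estimate_h2(c.phenotype, [], K, constraint=False)
            ests.append(rep.h2_total)
        ests = np.array(ests)
        mc_se = ests.std(ddof=1) / np.sqrt(ests.size)
        assert abs(ests.mean()) < 3 * mc_se

    def test_unsupported_kind_rejected(self, sib_cohort_small):
        c = sib_cohort_small
        K2 = build_ibd2(c.true_ibd, c.sample_ids)
        with pytest.raises(ValidationError):
            estimate_h2(c.phenotype, [], K2)


class TestJointModel:
    def test_all_signal_from_genotyped_snps(self):
        """Phenotype driven only by observed SNPs: h2_g ~ h2_total."""
        spec = SimulationSpec(pair_blocks=[PairBlock(150, 0.5)],
                              m_observed=800, m_unobserved=800,
                              h2_observed=0.5, h2_unobserved=0.0, seed=21)
        c = simulate_cohort(spec)
        Kibs = build_ibs(c.observed)
        Kthr = threshold_ibs(Kibs, 0.05)
        rep = estimate_joint(c.phenotype, [], Kthr, Kibs)
        assert rep.h2_g == pytest.approx(rep.h2_total,
                                         abs=4 * rep.h2_total_se + 0.02)
        assert rep.h2_total == pytest.approx(rep.h2_g
                                             + (rep.h2_total - rep.h2_g))

    def test_components_sum_to_total(self, sib_cohort_small):
        c = sib_cohort_small
        Kibs = build_ibs(c.observed)
        Kthr = threshold_ibs(Kibs, 0.05)
        rep = estimate_joint(c.phenotype, [], Kthr, Kibs)
        props, _ = rep.fit.sigma2[:2] / rep.fit.sigma2.sum(), None
        assert rep.h2_total == pytest.approx(float(props[0] + props[1]),
                                             abs=1e-10)

    def test_identical_components_rejected(self, sib_cohort_small):
        from heritkit.grm import Kind, KinshipMatrix
        c = sib_cohort_small
        Kthr = threshold_ibs(build_ibs(c.observed), 0.05)
        K_same = KinshipMatrix(Kind.IBS, Kthr.values, list(Kthr.sample_ids))
        with pytest.raises(ValidationError, match="collinear"):
            estimate_joint(c.phenotype, [], Kthr, K_same)

    def test_wrong_kinds_rejected(self, sib_cohort_small):
        c = sib_cohort_small
        Kibs = build_ibs(c.observed)
        with pytest.raises(ValidationError):
            estimate_joint(c.phenotype, [], Kibs, Kibs)  # close must be thr/ibd


class TestAdeModel:
    def test_no_ibd2_pairs_warns_and_pins_dominance(self):
        spec = SimulationSpec(pair_blocks=[PairBlock(80, 0.5, 0.0)],
                              m_observed=200, m_unobserved=0,
                              h2_observed=0.3, h2_unobserved=0.0, seed=3)
        c = simulate_cohort(spec)
        Ka = build_ibd(c.true_ibd, c.sample_ids)
        Kd = build_ibd2(c.true_ibd, c.sample_ids)
        with pytest.warns(RuntimeWarning, match="non-identifiable"):
            rep = fit_ade(c.phenotype, [], Ka, Kd)
        assert rep.h2_dominance_like == 0.0
        assert rep.lrt_p == 1.0

    def test_dominance_like_signal_detected(self):
        """Sib-realistic plus parent-offspring pairs with a strong
        shared-pair component: the dominance-like proportion is positive and
        the LRT significant.  Both classes are needed — on a single class
        the additive and dominance-like components are not separately
        identifiable (equal IBD/IBD2 ratio for every pair)."""
        spec = SimulationSpec(pair_blocks=[PairBlock(175, 0.5, 0.25),
                                           PairBlock(175, 0.5, 0.0)],
                              m_observed=400, m_unobserved=400,
                              h2_observed=0.15, h2_unobserved=0.15,
                              shared_pair_var=0.3, seed=9)
        c = simulate_cohort(spec)
        Ka = build_ibd(c.true_ibd, c.sample_ids)
        Kd = build_ibd2(c.true_ibd, c.sample_ids)
        rep = fit_ade(c.phenotype, [], Ka, Kd)
        assert rep.h2_dominance_like > 0.1
        assert rep.lrt_p < 0.05

    def test_proportions_bounded_under_constraint(self):
        spec = SimulationSpec(pair_blocks=[PairBlock(60, 0.5, 0.25),
                                           PairBlock(60, 0.5, 0.0)],
                              m_observed=300, m_unobserved=0,
                              h2_observed=0.3, h2_unobserved=0.0,
                              dominance_var=0.2, seed=14)
        c = simulate_cohort(spec)
        Ka = build_ibd(c.true_ibd, c.sample_ids)
        Kd = build_ibd2(c.true_ibd, c.sample_ids)
        rep = fit_ade(c.phenotype, [], Ka, Kd)
        assert 0.0 <= rep.h2_total + rep.h2_dominance_like <= 1.0


class TestLiabilityReport:
    def test_joint_report_flagged_as_upper_bound(self, sib_cohort_small):
        c = sib_cohort_small
        rng = np.random.default_rng(8)
        y = c.phenotype.data["trait"].to_numpy()
        cases = (y > np.quantile(y, 0.7)).astype(float)
        pheno = PhenotypeTable(pd.DataFrame(
            {"trait": cases}, index=pd.Index(c.sample_ids, name="id")))
        K = build_ibd(c.true_ibd, c.sample_ids)
        rep = estimate_h2(pheno, [], K)
        lia = report_on_liability(rep, prevalence=0.1,
                                  case_fraction=float(cases.mean()))
        assert lia.scale == "liability"
        assert lia.liability_flag is not None
        mult = observed_to_liability(1.0, 0.1, float(cases.mean()))
        assert lia.h2_total == pytest.approx(rep.h2_total * mult)
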