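"""Tests for design assembly, pointwise likelihood and log-posterior."""

import numpy as np
import pandas as pd
import pytest

from vaxcount.data import HierarchicalCountData
from vaxcount.families import Family, FamilyParams, log_pmf
from vaxcount.model import (
    HierarchicalCountModel,
    ModelSpec,
    ParameterVector,
    PriorConfig,
    build_design,
)


def make_data(y, covariates=None, community=None, state=None, year=2003):
    n = len(y)
    df = pd.DataFrame({"y": y})
    for name, values in (covariates or {}).items():
        df[name] = values
    df["community_id"] = community if community is not None else np.zeros(n, dtype=int)
    df["state_id"] = state if state is not None else np.zeros(n, dtype=int)
    df["year"] = year
    df["weight"] = 1.0
    return HierarchicalCountData(df)


def zero_pv(model):
    d = model.design
    pv = ParameterVector(
        beta=np.zeros(len(d.x_names)),
        u_community=np.zeros(d.n_comm), u_state=np.zeros(d.n_state),
        sigma_community=0.5, sigma_state=0.5,
    )
    if model.spec.family.has_dispersion:
        pv.k = 1.0
    if model.spec.family.has_zero_inflation:
        pv.gamma = np.zeros(len(d.z_names))
    return pv


class TestBuildDesign:
    def test_three_level_covariate_reference_coding(self):
        data = make_data([0, 1, 2], covariates={"edu": pd.Categorical(
            ["none", "primary", "higher"], categories=["none", "primary", "higher"])})
        d = build_design(data, ModelSpec(family="poisson", count_formula=("edu",)))
        assert d.x_names == ["intercept", "edu=primary", "edu=higher"]
        np.testing.assert_array_equal(d.X[:, 0], 1.0)
        np.testing.assert_array_equal(d.X[:, 1], [0, 1, 0])

    def test_year_reference_is_first_survey(self):
        data = make_data([1] * 8, year=np.repeat([2003, 2008, 2013, 2018], 2))
        d = build_design(data, ModelSpec(family="poisson", count_formula=("year",)))
        assert d.x_names == ["intercept", "year=2008", "year=2013", "year=2018"]

    def test_zinb_empty_zero_formula_gives_intercept_column(self):
        data = make_data([0, 1, 2])
        d = build_design(data, ModelSpec(family="zinb"))
        assert d.z_names == ["intercept"]
        assert d.Z.shape == (3, 1)

    def test_unknown_covariate_raises(self):
        data = make_data([1, 2])
        with pytest.raises(ValueError, match="unknown covariate 'bogus'"):
            build_design(data, ModelSpec(family="poisson", count_formula=("bogus",)))

    def test_absent_category_dropped_with_warning(self):
        data = make_data([1, 2], covariates={"edu": pd.Categorical(
            ["none", "none"], categories=["none", "primary"])})
        with pytest.warns(UserWarning, match="column dropped"):
            d = build_design(data, ModelSpec(family="poisson", count_formula=("edu",)))
        assert d.x_names == ["intercept"]

    def test_zero_part_forbidden_for_plain_families(self):
        with pytest.raises(ValueError, match="zero part"):
            ModelSpec(family="nb", zero_formula=("x",))


class TestPointwiseLikelihood:
    def test_all_zero_parameters_poisson(self):
        data = make_data([0] * 6)
        model = HierarchicalCountModel(data, ModelSpec(family="poisson"))
        ll = model.log_likelihood_pointwise(zero_pv(model))
        np.testing.assert_allclose(ll, -1.0, atol=1e-14)  # mu = e^0 = 1

    def test_translation_invariance_of_eta(self):
        data = make_data(
            [1, 3, 0, 5], community=[0, 0, 1, 1], state=[0, 0, 1, 1])
        model = HierarchicalCountModel(data, ModelSpec(family="poisson"))
        pv = zero_pv(model)
        pv.beta = np.array([0.7])
        pv.u_state = np.array([0.2, -0.4])
        base = model.log_likelihood_pointwise(pv)
        c = 0.31
        pv.beta = pv.beta + c
        pv.u_state = pv.u_state - c
        np.testing.assert_allclose(model.log_likelihood_pointwise(pv), base, atol=1e-12)

    def test_single_observation_delegates_to_family_pmf(self):
        data = make_data([4])
        model = HierarchicalCountModel(data, ModelSpec(family="nb"))
        pv = zero_pv(model)
        pv.beta = np.array([0.9])
        pv.u_community = np.array([0.2])
        pv.u_state = np.array([-0.1])
        pv.k = 2.5
        mu = float(np.exp(0.9 + 0.2 - 0.1))
        expected = log_pmf(4, FamilyParams(Family.NB, mu=mu, k=2.5))
        assert model.log_likelihood_pointwise(pv)[0] == pytest.approx(expected, abs=1e-12)

    def test_non_finite_eta_reports_row(self):
        data = make_data([1, 2, 3])
        model = HierarchicalCountModel(data, ModelSpec(family="poisson"))
        pv = zero_pv(model)
        pv.beta = np.array([np.inf])
        with pytest.raises(FloatingPointError, match="row 0"):
            model.log_likelihood_pointwise(pv)


class TestLogPosterior:
    def test_separates_into_likelihood_plus_prior(self):
        """log_posterior - sum(pointwise loglik) depends only on theta,
        never on the outcomes."""
        priors = PriorConfig()
        spec = ModelSpec(family="zinb")
        pvs = []
        for y in ([0, 2, 5, 1], [3, 3, 0, 9]):
            data = make_data(y, community=[0, 0, 1, 1], state=[0, 0, 1, 1])
            model = HierarchicalCountModel(data, spec, priors=priors)
            pv = zero_pv(model)
            pv.u_community = np.array([0.1, -0.2])
            pvs.append(model.log_posterior(pv) - model.log_likelihood_pointwise(pv).sum())
        assert pvs[0] == pytest.approx(pvs[1], abs=1e-12)

    def test_halfnormal_prior_monotone_in_scale(self):
        data = make_data([1, 2, 0])
        spec = ModelSpec(family="poisson")
        small = HierarchicalCountModel(data, spec, priors=PriorConfig(sd_scale=0.5))
        large = HierarchicalCountModel(data, spec, priors=PriorConfig(sd_scale=1.0))
        pv = zero_pv(small)
        pv.sigma_community = pv.sigma_state = 0.9
        # sigma far in the small prior's tail gains prior mass when the scale doubles
        assert large.log_prior(pv) > small.log_prior(pv)

    def test_prior_from_data_centers(self):
        data = make_data([0, 0, 0, 4, 4, 4])
        pr = PriorConfig.from_data(data)
        assert pr.intercept_center == pytest.approx(np.log(2.0))
        expected_excess = 0.5 - np.exp(-2.0)
        assert pr.pi_intercept_center == pytest.approx(
            np.log(expected_excess / (1 - expected_excess)))

    def test_spec_and_priors_json_round_trip(self):
        spec = ModelSpec(family="zinb", count_formula=("edu", "year"),
                         zero_formula=("edu",), zero_random_effects=True)
        assert ModelSpec.from_dict(spec.to_dict()) == spec
        pr = PriorConfig(beta_scale=0.5, intercept_center=1.2)
        assert PriorConfig.from_dict(pr.to_dict()) == pr

    def test_flat_spec_has_no_random_effect_terms(self):
        data = make_data([1, 2, 3])
        model = HierarchicalCountModel(
            data, ModelSpec(family="poisson", random_effects=False))
        pv = ParameterVector(beta=np.zeros(1))
        lp = model.log_posterior(pv)
        # likelihood at mu=1 plus the single beta prior term
        ll = model.log_likelihood_pointwise(pv).sum()
        pr = model.priors
        prior = -0.5 * (pr.intercept_center / pr.intercept_scale) ** 2 \
            - np.log(pr.intercept_scale) - 0.5 * np.log(2 * np.pi)
        assert lp == pytest.approx(ll + prior, abs=1e-12)
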