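"""Tests for WAIC, PSIS-LOO, deviance and the comparison table."""

import math

import numpy as np
import pytest

from vaxcount.families import Family, FamilyParams, log_pmf
from vaxcount.model import HierarchicalCountModel
from vaxcount.selection import (
    compare,
    fit_ic,
    neg2_loglik,
    pointwise_matrix,
    psis_loo,
    psis_smooth,
    waic,
)


class TestWaic:
    def test_zero_variance_hand_case(self):
        ll = np.log(np.full((2, 1), 0.5))
        res = waic(ll)
        assert res.p_waic == 0.0
        assert res.waic == pytest.approx(-2 * math.log(0.5), abs=1e-12)

    def test_two_obs_three_draw_hand_matrix(self):
        """Frozen hand computation, done term by term with scalar math."""
        ll = np.array([
            [math.log(0.2), math.log(0.5)],
            [math.log(0.3), math.log(0.4)],
            [math.log(0.25), math.log(0.45)],
        ])
        # lppd_i = log((p1+p2+p3)/3); p_i = sample variance of the logs
        lppd = [math.log((0.2 + 0.3 + 0.25) / 3), math.log((0.5 + 0.4 + 0.45) / 3)]
        logs1 = [math.log(0.2), math.log(0.3), math.log(0.25)]
        logs2 = [math.log(0.5), math.log(0.4), math.log(0.45)]

        def var(xs):
            m = sum(xs) / len(xs)
            return sum((x - m) ** 2 for x in xs) / (len(xs) - 1)

        expected = -2 * ((lppd[0] - var(logs1)) + (lppd[1] - var(logs2)))
        res = waic(ll)
        assert res.waic == pytest.approx(expected, abs=1e-12)
        assert res.p_waic == pytest.approx(var(logs1) + var(logs2), abs=1e-12)

    def test_translation_identity(self):
        rng = np.random.default_rng(0)
        ll = rng.normal(-2.0, 0.3, size=(50, 8))
        c = 0.37
        base = waic(ll)
        shifted = waic(ll + c)
        assert shifted.waic == pytest.approx(base.waic - 2 * 8 * c, abs=1e-9)
        assert shifted.p_waic == pytest.approx(base.p_waic, abs=1e-9)

    def test_single_draw_rejected(self):
        with pytest.raises(ValueError, match="2 draws"):
            waic(np.zeros((1, 3)))


class TestPsisLoo:
    def test_constant_column_equals_lppd(self):
        """With no likelihood uncertainty the importance weights are uniform
        and elpd_loo reduces to lppd exactly."""
        from scipy.special import logsumexp

        rng = np.random.default_rng(1)
        ll = rng.normal(-2, 0.5, size=(200, 4))
        ll[:, 2] = -1.7  # no uncertainty for observation 2
        res = psis_loo(ll)
        assert np.isfinite(res.looic)
        assert res.pareto_k[2] == -np.inf  # degenerate tail, nothing smoothed
        lw, _ = psis_smooth(-ll[:, 2])
        assert logsumexp(lw + ll[:, 2]) == pytest.approx(-1.7, abs=1e-12)

    def test_matches_arviz_psis_smoothing(self):
        """Independent-route check of the Pareto smoothing against arviz,
        run at the same tail fraction."""
        import arviz as az
        import xarray as xr

        rng = np.random.default_rng(2)
        S = 1000
        ll = rng.normal(-2, 0.7, size=(S, 6)) + rng.standard_t(3, size=(S, 6)) * 0.2
        mine = psis_loo(ll)
        da = xr.DataArray(
            ll[None, :, :], dims=("chain", "draw", "obs")
        ).stack(__sample__=("chain", "draw"))
        lw_az, k_az = az.psislw(-da, reff=1.0)
        from scipy.special import logsumexp

        lw_mat = lw_az.transpose("__sample__", "obs").values
        elpd_az = np.array([logsumexp(lw_mat[:, i] + ll[:, i]) for i in range(6)])
        looic_az = -2 * elpd_az.sum()
        # tail fractions differ slightly between implementations; require
        # agreement well inside the Monte-Carlo SE
        assert mine.looic == pytest.approx(looic_az, abs=0.05)
        assert np.corrcoef(mine.pareto_k, k_az.values.ravel())[0, 1] > 0.8

    def test_few_draws_warns(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="draws"):
            psis_loo(rng.normal(-1, 0.2, size=(50, 3)))


class TestPointwiseMatrix:
    def test_single_draw_equals_pointwise_loglik(self, tiny_poisson_fit):
        draws, data, spec = tiny_poisson_fit
        one = _slice_draws(draws, 1)
        mat = pointwise_matrix(one, data, spec)
        model = HierarchicalCountModel(data, spec)
        expected = model.log_likelihood_pointwise(one.parameter_vector(one.flat()[0]))
        np.testing.assert_allclose(mat[0], expected, atol=1e-12)

    def test_recompute_oracle_from_raw_families(self, tiny_poisson_fit):
        """Matrix entries recomputed directly from the family pmf with the
        draw's natural parameters, bypassing the model classes."""
        draws, data, spec = tiny_poisson_fit
        few = _slice_draws(draws, 5)
        mat = pointwise_matrix(few, data, spec)
        d = HierarchicalCountModel(data, spec).design
        for s in range(5):
            row = few.flat()[s]
            pv = few.parameter_vector(row)
            mu = np.exp(d.X @ pv.beta + pv.u_community[d.comm_idx] + pv.u_state[d.state_idx])
            oracle = np.array([
                log_pmf(int(y), FamilyParams(Family.POISSON, mu=float(m)))
                for y, m in zip(data.y, mu)
            ])
            np.testing.assert_allclose(mat[s], oracle, atol=1e-10)

    def test_duplicated_draw_duplicates_row(self, tiny_poisson_fit):
        draws, data, spec = tiny_poisson_fit
        two = _slice_draws(draws, 1, repeat=2)
        mat = pointwise_matrix(two, data, spec)
        np.testing.assert_array_equal(mat[0], mat[1])


def _slice_draws(draws, n, repeat=1):
    from dataclasses import replace as dc_replace

    sub = draws.draws[:1, :n]
    if repeat > 1:
        sub = np.repeat(sub, repeat, axis=1)
    return dc_replace(draws, draws=sub)


class TestDeviance:
    def test_single_draw_is_minus_two_row_sum(self, tiny_poisson_fit):
        draws, data, spec = tiny_poisson_fit
        one = _slice_draws(draws, 1)
        mat = pointwise_matrix(one, data, spec)
        dev = neg2_loglik(one, data, spec, loglik_matrix=mat)
        assert dev.at_posterior_mean == pytest.approx(-2 * mat[0].sum(), abs=1e-9)
        assert dev.posterior_mean_deviance == pytest.approx(-2 * mat[0].sum(), abs=1e-9)

    def test_at_mean_matches_external_average(self, tiny_poisson_fit):
        """Deviance at posterior mean recomputed with an externally averaged
        parameter vector and the raw family pmf."""
        draws, data, spec = tiny_poisson_fit
        dev = neg2_loglik(draws, data, spec, loglik_matrix=np.zeros((1, data.n)))
        mean_row = draws.flat().mean(axis=0)
        pv = draws.parameter_vector(mean_row)
        d = HierarchicalCountModel(data, spec).design
        mu = np.exp(d.X @ pv.beta + pv.u_community[d.comm_idx] + pv.u_state[d.state_idx])
        oracle = -2 * sum(
            log_pmf(int(y), FamilyParams(Family.POISSON, mu=float(m)))
            for y, m in zip(data.y, mu))
        assert dev.at_posterior_mean == pytest.approx(oracle, abs=1e-8)


class TestCompare:
    def _ic(self, family, looic, waic_val, n=60):
        from vaxcount.selection import ICResult

        return ICResult(
            family=family, n_obs=n, loglik_matrix=np.zeros((2, n)),
            neg2_loglik=looic - 2, posterior_mean_deviance=looic - 1,
            waic=waic_val, waic_se=2.0, p_waic=3.0,
            looic=looic, looic_se=2.0, p_loo=3.0, pareto_k=np.zeros(n),
        )

    def test_sorted_by_looic_with_winner(self):
        table = compare([self._ic("poisson", 210.0, 211.0),
                         self._ic("zinb", 180.0, 181.0),
                         self._ic("nb", 200.0, 201.0)])
        assert list(table.table["family"]) == ["zinb", "nb", "poisson"]
        assert table.winner == "zinb"
        assert table.waic_concordant
        assert not table.tie

    def test_identical_results_reported_as_tie(self):
        table = compare([self._ic("zip", 100.0, 101.0), self._ic("zinb", 100.0, 101.0)])
        assert table.tie

    def test_mismatched_datasets_rejected(self):
        with pytest.raises(ValueError, match="row counts"):
            compare([self._ic("poisson", 1.0, 1.0, n=10),
                     self._ic("nb", 1.0, 1.0, n=12)])

    def test_needs_two_results(self):
        with pytest.raises(ValueError, match="two"):
            compare([self._ic("poisson", 1.0, 1.0)])

    def test_text_report_layout(self):
        txt = compare([self._ic("poisson", 210.0, 211.0),
                       self._ic("zinb", 180.0, 181.0)]).to_text()
        assert "-2 Log LL" in txt and "LOOIC" in txt and "WAIC" in txt
        assert "selected: zinb" in txt


def test_criteria_invariant_to_draw_order_and_chain_relabeling():
    """WAIC and PSIS-LOO depend on the draw set, not its ordering."""
    rng = np.random.default_rng(4)
    ll = rng.normal(-2, 0.6, size=(300, 5))
    perm = rng.permutation(300)
    base_w, perm_w = waic(ll), waic(ll[perm])
    assert perm_w.waic == pytest.approx(base_w.waic, abs=1e-10)
    assert perm_w.p_waic == pytest.approx(base_w.p_waic, abs=1e-10)
    base_l, perm_l = psis_loo(ll), psis_loo(ll[perm])
    assert perm_l.looic == pytest.approx(base_l.looic, abs=1e-10)
    np.testing.assert_allclose(np.sort(perm_l.pareto_k), np.sort(base_l.pareto_k))


def test_fit_ic_end_to_end(tiny_poisson_fit):
    draws, data, spec = tiny_poisson_fit
    ic = fit_ic(draws, data, spec)
    assert ic.family == "poisson"
    assert ic.n_obs == data.n
    assert ic.p_loo >= 0
    # WAIC and PSIS-LOO should agree on a well-behaved fit
    assert abs(ic.waic - ic.looic) < 2 * (ic.waic_se + ic.looic_se)
    assert ic.posterior_mean_deviance >= ic.neg2_loglik  # Jensen-style ordering
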