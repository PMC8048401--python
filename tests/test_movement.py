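"""Continuous-time movement models: closed forms, Kalman oracle, fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from homerange import (
    SimSpec,
    Track,
    ctmm_loglik,
    empirical_variogram,
    fit_ctmm,
    position_acf,
    simulate_track,
)
from homerange.errors import DomainError
from homerange.movement import CTMMFit, _dof_area


def dense_loglik(track, model, **params):
    """Oracle: dense multivariate-normal log-density from the position ACF."""
    t = track.seconds()
    lags = np.abs(t[:, None] - t[None, :])
    uere = params.pop("uere", None)
    cov = position_acf(model, lags, **params)
    if uere:
        hdop = track.hdop if track.hdop is not None else np.ones(len(t))
        cov = cov + np.diag((uere * hdop) ** 2 / 2.0)
    mu = track.xy.mean(axis=0)
    return sum(
        multivariate_normal.logpdf(track.xy[:, i], mean=np.full(len(t), mu[i]), cov=cov)
        for i in range(2)
    )


class TestPositionAcf:
    def test_ou_zero_lag_is_variance(self):
        assert position_acf("ou", 0.0, sigma2=3.0, tau_pos=100.0) == 3.0

    def test_ou_one_timescale(self):
        got = position_acf("ou", 3600.0, sigma2=1.0, tau_pos=3600.0)
        assert got == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_iid_is_delta(self):
        assert position_acf("iid", 0.0, sigma2=2.0) == 2.0
        assert position_acf("iid", 1.0, sigma2=2.0) == 0.0

    def test_ouf_limits_to_ou_as_tau_vel_vanishes(self):
        lags = np.linspace(0.0, 10 * 3600, 200)
        ou = position_acf("ou", lags, sigma2=1.0, tau_pos=3600.0)
        ouf = position_acf("ouf", lags, sigma2=1.0, tau_pos=3600.0, tau_vel=3600e-6)
        assert np.max(np.abs(ouf - ou)) < 1e-4

    def test_ouf_equal_timescales_rejected(self):
        with pytest.raises(DomainError):
            position_acf("ouf", 1.0, sigma2=1.0, tau_pos=10.0, tau_vel=10.0)


class TestLoglik:
    def test_iid_closed_form(self, iid_track):
        sigma2 = 9e5
        z = iid_track.xy - iid_track.xy.mean(axis=0)
        expected = -0.5 * np.sum(np.log(2 * np.pi * sigma2) + z**2 / sigma2)
        got = ctmm_loglik(iid_track, "iid", sigma2=sigma2)
        assert got == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize(
        "model,params",
        [
            ("iid", dict(sigma2=1e6)),
            ("ou", dict(sigma2=1e6, tau_pos=3600.0)),
            ("ouf", dict(sigma2=1e6, tau_pos=3600.0, tau_vel=600.0)),
        ],
    )
    def test_kalman_equals_dense_oracle(self, model, params):
        spec = SimSpec(model=model, sigma2=1e6, tau_pos=3600.0,
                       tau_vel=600.0 if model == "ouf" else None,
                       dt=600.0, n=20, seed=2)
        tr = simulate_track(spec)
        assert ctmm_loglik(tr, model, **params) == pytest.approx(
            dense_loglik(tr, model, **params), abs=1e-8
        )

    def test_kalman_with_error_model_equals_dense(self):
        spec = SimSpec(model="ou", sigma2=1e6, tau_pos=3600.0, dt=600.0, n=25,
                       seed=8, uere=10.0, hdop_law=("lognormal", np.log(2.0), 0.4))
        tr = simulate_track(spec)
        got = ctmm_loglik(tr, "ou", sigma2=1e6, tau_pos=3600.0, uere=10.0)
        want = dense_loglik(tr, "ou", sigma2=1e6, tau_pos=3600.0, uere=10.0)
        assert got == pytest.approx(want, abs=1e-8)

    def test_ou_vanishing_timescale_is_iid(self, iid_track):
        ou = ctmm_loglik(iid_track, "ou", sigma2=1e6, tau_pos=1e-9 * 600.0)
        iid = ctmm_loglik(iid_track, "iid", sigma2=1e6)
        assert ou == pytest.approx(iid, abs=1e-6)

    def test_irregular_sampling_matches_dense(self):
        rng = np.random.default_rng(13)
        secs = np.sort(rng.choice(np.arange(1, 40000, 37), size=30, replace=False))
        t = pd.Timestamp("2011-01-01", tz="UTC") + pd.to_timedelta(secs, unit="s")
        xy = rng.normal(scale=1000.0, size=(30, 2))
        tr = Track(x=xy[:, 0], y=xy[:, 1], t=t, crs=5070)
        for model, params in [
            ("ou", dict(sigma2=1e6, tau_pos=5000.0)),
            ("ouf", dict(sigma2=1e6, tau_pos=5000.0, tau_vel=900.0)),
        ]:
            assert ctmm_loglik(tr, model, **params) == pytest.approx(
                dense_loglik(tr, model, **params), abs=1e-8
            )

    def test_invalid_params_are_minus_inf(self, iid_track):
        assert ctmm_loglik(iid_track, "ou", sigma2=-1.0, tau_pos=10.0) == -np.inf
        assert ctmm_loglik(iid_track, "ouf", sigma2=1.0, tau_pos=10.0, tau_vel=20.0) == -np.inf


class TestVariogram:
    def test_iid_is_flat_at_sigma2(self):
        tr = simulate_track(SimSpec(model="iid", sigma2=1e6, dt=600.0, n=2000, seed=21))
        vg = empirical_variogram(tr, n_lags=12)
        # flat: every bin near sigma2 and no meaningful trend across the range
        x, g = vg["lag"].to_numpy(), vg["gamma"].to_numpy()
        assert np.all(np.abs(g - 1e6) < 0.15e6)
        slope = np.polyfit(x, g, 1)[0]
        assert abs(slope) * (x[-1] - x[0]) < 0.1e6  # drift < 10% of the sill
        assert np.median(g) == pytest.approx(1e6, rel=0.1)

    def test_ou_shape_recovered(self):
        tr = simulate_track(SimSpec(model="ou", sigma2=1e6, tau_pos=3600.0, dt=600.0,
                                    n=2000, seed=23))
        vg = empirical_variogram(tr, n_lags=400)
        x, g = vg["lag"].to_numpy(), vg["gamma"].to_numpy()
        rising = x <= 5 * 3600.0  # the informative part of the curve
        pred = 1e6 * (1 - np.exp(-x[rising] / 3600.0))
        ss_res = np.sum((g[rising] - pred) ** 2)
        ss_tot = np.sum((g[rising] - g[rising].mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.9

    def test_two_point_track(self):
        t = pd.date_range("2011-01-01", periods=2, freq="1h", tz="UTC")
        tr = Track(x=[0.0, 2.0], y=[0.0, 0.0], t=t, crs=5070)
        vg = empirical_variogram(tr)
        assert len(vg) == 1
        assert vg["gamma"][0] == pytest.approx(1.0)  # (dx^2 + dy^2) / 4


class TestFit:
    def test_ou_parameter_recovery(self):
        tr = simulate_track(SimSpec(model="ou", sigma2=1e6, tau_pos=3600.0,
                                    dt=600.0, n=1000, seed=4))
        fit = fit_ctmm(tr, "auto")
        assert fit.model == "ou"
        assert fit.sigma2 == pytest.approx(1e6, rel=0.25)
        assert fit.tau_pos == pytest.approx(3600.0, rel=0.25)
        assert 0 < fit.dof_area < fit.n

    def test_dof_area_iid_equals_n(self, iid_track):
        fit = fit_ctmm(iid_track, "iid")
        assert fit.dof_area == len(iid_track)

    def test_dof_area_monotone_in_tau(self):
        dofs = [
            _dof_area("ou", 1e6, tau, None, n=500, dt_med=600.0)
            for tau in [600.0, 3600.0, 7200.0, 86400.0]
        ]
        assert all(a >= b for a, b in zip(dofs, dofs[1:]))

    def test_aicc_counts_parameters(self):
        tr = simulate_track(SimSpec(model="ou", sigma2=1e6, tau_pos=3600.0,
                                    dt=600.0, n=200, seed=6))
        fit = fit_ctmm(tr, "ou")
        k = 4
        expected = -2 * fit.loglik + 2 * k + 2 * k * (k + 1) / (fit.n - k - 1)
        assert fit.aicc == pytest.approx(expected, abs=1e-9)

    def test_translation_leaves_model_choice_and_aicc(self):
        tr = simulate_track(SimSpec(model="ou", sigma2=1e6, tau_pos=3600.0,
                                    dt=600.0, n=300, seed=14))
        shifted = Track(x=tr.x + 5e5, y=tr.y - 7e5, t=tr.t, crs=tr.crs)
        f1 = fit_ctmm(tr, "auto")
        f2 = fit_ctmm(shifted, "auto")
        assert f1.model == f2.model
        assert f1.aicc == pytest.approx(f2.aicc, abs=1e-3)

    def test_uere_zero_without_hdop_matches_no_error(self):
        t = pd.date_range("2011-01-01", periods=100, freq="10min", tz="UTC")
        rng = np.random.default_rng(15)
        xy = rng.normal(scale=1000.0, size=(100, 2))
        tr = Track(x=xy[:, 0], y=xy[:, 1], t=t, crs=5070)
        a = ctmm_loglik(tr, "ou", sigma2=1e6, tau_pos=3600.0, uere=0.0)
        b = ctmm_loglik(tr, "ou", sigma2=1e6, tau_pos=3600.0, uere=None)
        assert a == b

    def test_auto_needs_five_fixes(self):
        t = pd.date_range("2011-01-01", periods=4, freq="1h", tz="UTC")
        tr = Track(x=[0.0, 1, 2, 3], y=[0.0, 1, 0, 1], t=t, crs=5070)
        with pytest.raises(DomainError):
            fit_ctmm(tr, "auto")

    def test_fit_summary_json_round_trips(self):
        import json

        fit = CTMMFit(model="ou", mu=np.array([1.0, 2.0]), sigma2=3.0, tau_pos=4.0,
                      tau_vel=None, uere=None, loglik=-10.0, aicc=28.0,
                      dof_area=5.0, n=10)
        d = json.loads(fit.to_json())
        assert d["model"] == "ou" and d["mu"] == [1.0, 2.0] and d["sigma2"] == 3.0
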