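"""Utilization distributions: template rasters, KDE/aKDE, cumulative UD, isopleths."""

import numpy as np
import pytest

from homerange import (
    Kde,
    SimSpec,
    Track,
    hr_akde,
    hr_area,
    hr_cud,
    hr_kde,
    hr_ud,
    make_trast,
    simulate_track,
)
from homerange.errors import (
    DegenerateGeometryError,
    DomainError,
    UnsupportedOperationError,
)
from homerange.movement import CTMMFit, fit_ctmm
from homerange.probabilistic import ud_level_mask, ud_to_isopleths
from homerange.raster import TemplateRaster

from conftest import make_simple_track


class TestMakeTrast:
    def test_auto_buffer_is_half_larger_span(self):
        tr = make_simple_track([0, 100, 0, 100], [0, 0, 50, 50])
        t = make_trast(tr, "auto", ncol=200)
        assert (t.xmin, t.xmax, t.ymin, t.ymax) == (-50.0, 150.0, -50.0, 100.0)

    def test_square_cells_and_ncol(self):
        tr = make_simple_track([0, 1, 1, 0], [0, 0, 1, 1])
        t = make_trast(tr, 0.0, ncol=10)
        assert t.ncol == 10 and t.cell_size == pytest.approx(0.1)
        assert t.nrow == 10  # unit square: same span on both axes

    def test_single_point_with_buffer(self):
        tr = make_simple_track([5.0], [7.0])
        t = make_trast(tr, 100.0, ncol=10)
        assert (t.xmin, t.xmax) == (-95.0, 105.0)
        assert (t.ymin, t.ymax) == (-93.0, 107.0)

    def test_single_point_no_buffer_degenerate(self):
        tr = make_simple_track([5.0], [7.0])
        with pytest.raises(DegenerateGeometryError):
            make_trast(tr, 0.0)


class TestKde:
    def test_mass_sums_to_one(self, ou_track):
        est = hr_kde(ou_track, levels=[0.95])
        assert hr_ud(est).sum() == pytest.approx(1.0, abs=1e-6)
        assert (hr_ud(est) >= 0).all()

    def test_reference_bandwidth_rule(self, ou_track):
        est = hr_kde(ou_track, levels=[0.95])
        n = len(ou_track)
        expected = ou_track.xy.std(axis=0, ddof=1) * n ** (-1 / 6)
        assert np.allclose(est.h_, expected)

    def test_gaussian_closed_form(self):
        sigma = 1000.0
        tr = simulate_track(SimSpec(model="iid", sigma2=sigma**2, dt=3600.0,
                                    n=10000, seed=11))
        est = hr_kde(tr, levels=[0.95])
        target = -2 * np.pi * sigma**2 * np.log(0.05)
        assert hr_area(est)["area"][0] == pytest.approx(target, rel=0.10)

    def test_area_increases_with_bandwidth(self, ou_track):
        trast = make_trast(ou_track)
        h = ou_track.xy.std(axis=0, ddof=1) * len(ou_track) ** (-1 / 6)
        a1 = hr_area(hr_kde(ou_track, trast=trast, h=tuple(h), levels=[0.95]))["area"][0]
        a2 = hr_area(hr_kde(ou_track, trast=trast, h=tuple(2 * h), levels=[0.95]))["area"][0]
        assert a2 > a1

    def test_single_kernel_peaks_at_fix(self):
        tr = make_simple_track([10.0, 10.0, 10.0, 10.0, 10.0], [20.0, 20, 20, 20, 20])
        trast = TemplateRaster.from_extent(0, 40, 0, 40, ncol=40)
        est = Kde(h=(2.0, 2.0), trast=trast, levels=[0.95]).fit(tr)
        i, j = np.unravel_index(np.argmax(est.ud_), est.ud_.shape)
        assert trast.x_centers[j] == pytest.approx(10.0, abs=trast.cell_size)
        assert trast.y_centers[i] == pytest.approx(20.0, abs=trast.cell_size)

    def test_shift_equivariance_of_mode(self, ou_track):
        est = hr_kde(ou_track, levels=[0.95])
        dx, dy = 10 * est.trast_.cell_size, -5 * est.trast_.cell_size
        shifted_trast = TemplateRaster(
            est.trast_.xmin + dx, est.trast_.ymin + dy, est.trast_.ncol,
            est.trast_.nrow, est.trast_.cell_size, est.trast_.crs,
        )
        tr2 = Track(x=ou_track.x + dx, y=ou_track.y + dy, t=ou_track.t, crs=5070)
        est2 = hr_kde(tr2, trast=shifted_trast, levels=[0.95])
        assert np.argmax(est2.ud_) == np.argmax(est.ud_)

    def test_zero_variance_axis_advises_explicit_h(self):
        tr = make_simple_track([0, 1, 2, 3, 4, 5], [2.0] * 6)
        with pytest.raises(DomainError, match="explicit h"):
            hr_kde(tr)

    def test_needs_five_fixes_for_reference_rule(self):
        tr = make_simple_track([0, 1, 2], [0, 1, 0])
        with pytest.raises(DomainError, match="5"):
            hr_kde(tr)


class TestCud:
    def test_ranked_cumulative_properties(self):
        rng = np.random.default_rng(0)
        ud = rng.random((5, 5))
        ud /= ud.sum()
        cud = hr_cud(ud)
        assert cud.ravel()[np.argmax(ud)] == pytest.approx(ud.max())
        assert cud.max() == pytest.approx(1.0)
        assert (cud > 0).all() and (cud <= 1.0 + 1e-12).all()

    def test_level_mask_matches_brute_force_subset_scan(self):
        rng = np.random.default_rng(1)
        ud = rng.random((5, 5))
        ud /= ud.sum()
        mask = ud_level_mask(ud, 0.95)
        # brute force: smallest count of highest-mass cells reaching 0.95
        flat = np.sort(ud.ravel())[::-1]
        k = int(np.searchsorted(np.cumsum(flat), 0.95)) + 1
        assert mask.sum() == k
        assert ud[mask].sum() >= 0.95
        # no smaller set of cells can hold 0.95
        assert np.sort(ud[mask].ravel())[::-1][:k - 1].sum() < 0.95

    def test_ties_share_the_larger_cumulative_value(self):
        ud = np.array([[0.4, 0.2], [0.2, 0.2]])
        cud = hr_cud(ud)
        assert cud[0, 0] == pytest.approx(0.4)
        assert np.allclose(cud.ravel()[1:], 1.0)  # the three tied cells share 1.0

    def test_rejects_geometric_estimate(self, ou_track):
        from homerange import hr_mcp

        with pytest.raises(UnsupportedOperationError):
            hr_ud(hr_mcp(ou_track))
        with pytest.raises(UnsupportedOperationError):
            hr_cud(hr_mcp(ou_track))


class TestIsopleths:
    def test_gaussian_isopleth_near_circular(self):
        tr = simulate_track(SimSpec(model="iid", sigma2=1000.0**2, dt=3600.0,
                                    n=10000, seed=11))
        est = hr_kde(tr, levels=[0.95])
        g = est.isopleths_.iloc[0]["geometry"]
        assert 4 * np.pi * g.area / g.length**2 > 0.95

    def test_nesting_within_cell_tolerance(self, ou_track):
        est = hr_kde(ou_track, levels=[0.5, 0.95])
        inner = est.isopleths_.iloc[0]["geometry"]
        outer = est.isopleths_.iloc[1]["geometry"]
        assert outer.buffer(est.trast_.cell_size).covers(inner)

    def test_polygon_area_matches_cell_counting(self, ou_track):
        est = hr_kde(ou_track, levels=[0.95], ncol=200)
        poly_area = est.isopleths_.iloc[0]["area"]
        cells = ud_level_mask(est.ud_, 0.95).sum()
        cell_area = est.trast_.cell_size**2
        assert poly_area == pytest.approx(cells * cell_area, rel=0.05)

    def test_unreachable_level_warns_and_is_empty(self):
        ud = np.zeros((4, 4))
        ud[0, 0] = 1.0  # entire mass in one cell: min cud is 1.0
        trast = TemplateRaster(0, 0, 4, 4, 1.0)
        with pytest.warns(UserWarning, match="level"):
            iso = ud_to_isopleths(ud, [0.5], trast)
        assert iso.iloc[0]["geometry"].is_empty

    def test_holes_preserved(self):
        # ring-shaped UD: uniform mass on an annulus produces a polygon with a hole
        trast = TemplateRaster.from_extent(-10, 10, -10, 10, ncol=100)
        xx, yy = np.meshgrid(trast.x_centers, trast.y_centers)
        rr = np.hypot(xx, yy)
        ud = np.exp(-((rr - 6.0) ** 2))  # densities peak on a ring of radius 6
        ud /= ud.sum()
        iso = ud_to_isopleths(ud, [0.95], trast)
        geom = iso.iloc[0]["geometry"]
        holes = sum(len(p.interiors) for p in getattr(geom, "geoms", [geom]))
        assert holes >= 1


class TestAkde:
    def test_uncorrelated_fit_reduces_to_kde(self, iid_track):
        trast = make_trast(iid_track)
        fit = fit_ctmm(iid_track, "iid")
        a = hr_akde(iid_track, fit, trast=trast, levels=[0.95])
        k = hr_kde(iid_track, trast=trast, levels=[0.95])
        ra = hr_area(a)
        ra = ra[ra["what"] == "estimate"]["area"].iloc[0]
        rk = hr_area(k)["area"].iloc[0]
        assert ra == pytest.approx(rk, rel=1e-6)

    def test_ou_area_exceeds_kde_and_tracks_truth(self):
        tr = simulate_track(SimSpec(model="ou", sigma2=1e6, tau_pos=3600.0,
                                    dt=600.0, n=1000, seed=4))
        fit = fit_ctmm(tr, "auto")
        trast = make_trast(tr)
        a = hr_akde(tr, fit, trast=trast, levels=[0.95])
        k = hr_kde(tr, trast=trast, levels=[0.95])
        area_a = hr_area(a).query("what == 'estimate'")["area"].iloc[0]
        area_k = hr_area(k)["area"].iloc[0]
        assert area_a >= area_k
        target = -2 * np.pi * 1e6 * np.log(0.05)
        # oversmoothing bias of the effective-sample-size bandwidth is bounded
        assert area_a / target < 1 + 1.1 * fit.dof_area ** (-1 / 3)

    def test_confidence_rows_ordered(self, ou_track):
        est = hr_akde(ou_track, levels=[0.95])
        a = hr_area(est).set_index("what")["area"]
        assert a["lci"] <= a["estimate"] <= a["uci"]

    def test_error_model_widens_kernels(self):
        spec = SimSpec(model="ou", sigma2=1e6, tau_pos=3600.0, dt=600.0, n=300,
                       seed=30, uere=20.0, hdop_law=("lognormal", np.log(3.0), 0.3))
        tr = simulate_track(spec)
        trast = make_trast(tr)
        plain = hr_akde(tr, fit_ctmm(tr, "ou"), trast=trast, levels=[0.95])
        noisy = hr_akde(tr, fit_ctmm(tr, "ou", uere=20.0), trast=trast, levels=[0.95])
        assert (noisy.h_ > plain.h_ - 1e-12).all()
        assert noisy.h_.mean() > plain.h_.mean()

    def test_low_effective_sample_size_refused(self, ou_track):
        fit = CTMMFit(model="ou", mu=np.zeros(2), sigma2=1e6, tau_pos=1e9,
                      tau_vel=None, uere=None, loglik=0.0, aicc=0.0,
                      dof_area=0.8, n=len(ou_track))
        with pytest.raises(DomainError, match="effective sample size"):
            hr_akde(ou_track, fit)

    def test_mismatched_fit_rejected(self, ou_track, iid_track):
        fit = fit_ctmm(iid_track, "iid")
        with pytest.raises(DomainError, match="fitted"):
            hr_akde(ou_track, fit)


class TestNormalizationProperty:
    @pytest.mark.parametrize("seed", range(10))
    def test_many_seeded_inputs_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        model = ["iid", "ou"][seed % 2]
        tr = simulate_track(SimSpec(model=model, sigma2=float(rng.uniform(1e4, 1e7)),
                                    tau_pos=3600.0, dt=600.0,
                                    n=int(rng.integers(30, 120)), seed=seed))
        est = hr_kde(tr, levels=[0.95], ncol=100)
        assert est.ud_.sum() == pytest.approx(1.0, abs=1e-6)
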