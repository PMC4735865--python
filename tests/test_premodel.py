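"""Multi-site 1/r^6 PRE model: prediction, constrained fitting, statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from oxycav import synthdata
from oxycav.premodel import (
    SCALE,
    PREFitResult,
    PREObservation,
    binding_probability,
    broadening_screen,
    fit_pre,
    occupancy_ratio,
    predict_dr1,
    site_contributions,
)
from oxycav.structures import DistanceTable, ProtonSet, Site, SiteGeometry, distance_table

from conftest import make_proton

AMIDE = synthdata.AMIDE_COEFFS
METHYL = synthdata.METHYL_COEFFS


def table_from_distances(dist: np.ndarray) -> DistanceTable:
    """Build a DistanceTable from an (n_protons, n_sites) distance array."""
    dist = np.asarray(dist, dtype=float)
    labels = [f"P{i + 1}" for i in range(dist.shape[0])]
    site_ids = list(range(1, dist.shape[1] + 1))
    cols = [str(s) for s in site_ids]
    inv6 = pd.DataFrame(dist**-6.0, index=labels, columns=cols)
    r = pd.DataFrame(dist, index=labels, columns=cols)
    return DistanceTable(labels, site_ids, inv6, r, pd.Series(dist.min(axis=1), index=labels))


class TestPredict:
    def test_single_near_site_with_baseline(self):
        # a = 1.3 at r = 5 Å, every other site effectively at infinity, f = 1.1
        dist = np.array([[5.0, 1e6, 1e6, 1e6, 1e6]])
        tab = table_from_distances(dist)
        pred = predict_dr1(np.array(AMIDE), tab, baseline=1.1)
        assert pred.iloc[0] == pytest.approx(1.3e5 / 5**6 + 1.1, abs=1e-6)
        assert pred.iloc[0] == pytest.approx(9.42, abs=5e-3)

    def test_baseline_only(self):
        tab = table_from_distances(np.full((4, 5), 10.0))
        pred = predict_dr1(np.zeros(5), tab, baseline=1.1)
        assert np.allclose(pred, 1.1)

    def test_sixth_power_scaling(self):
        d = np.array([[4.0, 7.0, 9.0, 12.0, 20.0]])
        p1 = predict_dr1(np.array(AMIDE), table_from_distances(d), baseline=0.0)
        p2 = predict_dr1(np.array(AMIDE), table_from_distances(2 * d), baseline=0.0)
        assert p1.iloc[0] == pytest.approx(64.0 * p2.iloc[0], rel=1e-12)

    def test_site_count_mismatch(self):
        tab = table_from_distances(np.full((3, 2), 5.0))
        with pytest.raises(ValueError, match="does not match"):
            predict_dr1(np.array(AMIDE), tab, baseline=0.0)

    def test_monotone_in_each_distance(self, geometry):
        tab = geometry.table
        base = predict_dr1(np.array(AMIDE), tab, baseline=1.1)
        dist = tab.r.to_numpy().copy()
        for j in range(dist.shape[1]):
            bumped = dist.copy()
            bumped[:, j] *= 1.5
            pred = predict_dr1(np.array(AMIDE), table_from_distances(bumped), baseline=1.1)
            assert (pred.to_numpy() <= base.to_numpy() + 1e-12).all()


class TestFit:
    def test_noiseless_amide_roundtrip_exact(self, geometry):
        data = synthdata.gen_pre_field(coeffs=AMIDE, baseline=synthdata.AMIDE_BASELINE,
                                       table=geometry.table, noise_sd=0.0, seed=0)
        fit = fit_pre(data.observations, geometry.table)
        assert np.allclose(fit.coefficients, AMIDE, rtol=1e-8)
        assert fit.baseline == pytest.approx(synthdata.AMIDE_BASELINE, rel=1e-8)
        assert fit.see < 1e-8
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_methyl_zero_coefficients_recovered_exactly(self, geometry):
        data = synthdata.gen_pre_field(coeffs=METHYL, baseline=synthdata.METHYL_BASELINE,
                                       table=geometry.table, noise_sd=0.0, seed=0)
        fit = fit_pre(data.observations, geometry.table)
        assert fit.coefficients[1] == 0.0  # b
        assert fit.coefficients[3] == 0.0  # d
        assert np.allclose(fit.coefficients, METHYL, rtol=1e-8, atol=1e-12)

    def test_constant_field_with_distant_sites_is_baseline_only(self):
        tab = table_from_distances(np.full((10, 5), 1e7))
        obs = [PREObservation(f"P{i + 1}", 0.9) for i in range(10)]
        fit = fit_pre(obs, tab)
        assert np.allclose(fit.coefficients, 0.0, atol=1e-6)
        assert fit.baseline == pytest.approx(0.9, rel=1e-9)
        assert fit.r_squared == 0.0  # undefined correlation reported as zero
        assert fit.see < 1e-9

    def test_excluded_observations_ignored_in_objective(self, geometry):
        data = synthdata.gen_pre_field(coeffs=AMIDE, baseline=1.1,
                                       table=geometry.table, noise_sd=0.0, seed=0)
        # corrupt two observations but mark them excluded: fit must not move
        data.observations[0] = PREObservation(data.observations[0].proton_label,
                                              999.0, excluded=True, reason="severe broadening")
        data.observations[1] = PREObservation(data.observations[1].proton_label,
                                              np.nan, excluded=True, reason="severe broadening")
        fit = fit_pre(data.observations, geometry.table)
        assert np.allclose(fit.coefficients, AMIDE, rtol=1e-8)
        assert fit.n_used == len(geometry.table) - 2

    def test_all_excluded_is_error(self, geometry):
        obs = [PREObservation(l, 1.0, excluded=True, reason="x") for l in geometry.table.labels]
        with pytest.raises(ValueError, match="excluded"):
            fit_pre(obs, geometry.table)

    def test_underdetermined_is_error(self):
        tab = table_from_distances(np.random.default_rng(0).uniform(4, 15, (4, 5)))
        obs = [PREObservation(f"P{i + 1}", 1.0) for i in range(4)]
        with pytest.raises(ValueError, match="[Uu]nderdetermined"):
            fit_pre(obs, tab)

    def test_grid_search_oracle_agrees_with_nnls(self):
        """Coarse grid over (c1, c2, f) must not beat the constrained
        least-squares solution, and the solutions must agree to the grid
        resolution on noiseless two-site data."""
        rng = np.random.default_rng(3)
        dist = rng.uniform(4.0, 12.0, size=(12, 2))
        tab = table_from_distances(dist)
        truth = np.array([0.8, 0.4])
        y = predict_dr1(truth, tab, baseline=0.6).to_numpy()
        obs = [PREObservation(l, v) for l, v in zip(tab.labels, y)]
        fit = fit_pre(obs, tab)

        A = np.hstack([tab.matrix * SCALE, np.ones((len(y), 1))])
        step = 0.05
        grid = np.arange(0.0, 1.2 + step / 2, step)
        best_sse, best = np.inf, None
        for c1, c2, f in itertools.product(grid, grid, grid):
            sse = ((A @ np.array([c1, c2, f]) - y) ** 2).sum()
            if sse < best_sse:
                best_sse, best = sse, (c1, c2, f)
        nnls_sse = (fit.see**2) * len(y)
        assert nnls_sse <= best_sse + 1e-12
        assert np.allclose([*fit.coefficients, fit.baseline], best, atol=step)


class TestContributions:
    def test_shares_plus_baseline_reconstruct_prediction(self, geometry):
        fit = PREFitResult(np.array(AMIDE), synthdata.AMIDE_BASELINE, 1.0, 0.0,
                           n_used=len(geometry.table))
        contrib = site_contributions(fit, geometry.table)
        pred = predict_dr1(fit, geometry.table)
        assert np.allclose(contrib.predicted.to_numpy(), pred.to_numpy(), atol=1e-9)

    def test_single_active_site_takes_whole_share(self):
        tab = table_from_distances(np.array([[5.0, 8.0]]))
        fit = PREFitResult(np.array([0.7, 0.0]), 0.3, 1.0, 0.0, n_used=1)
        contrib = site_contributions(fit, tab)
        pred = predict_dr1(fit, tab).iloc[0]
        assert contrib.shares.iloc[0, 0] == pytest.approx(pred - 0.3, rel=1e-12)
        assert contrib.shares.iloc[0, 1] == 0.0

    def test_equal_terms_give_equal_shares(self):
        tab = table_from_distances(np.array([[6.0, 6.0]]))
        fit = PREFitResult(np.array([0.5, 0.5]), 0.2, 1.0, 0.0, n_used=1)
        contrib = site_contributions(fit, tab)
        assert contrib.shares.iloc[0, 0] == pytest.approx(contrib.shares.iloc[0, 1])

    def test_baseline_only_proton_has_zero_shares(self):
        tab = table_from_distances(np.array([[5.0, 8.0]]))
        fit = PREFitResult(np.zeros(2), 1.1, 0.0, 0.0, n_used=1)
        contrib = site_contributions(fit, tab)
        assert (contrib.shares.to_numpy() == 0.0).all()


class TestOccupancyAndProbability:
    def test_cavity3_vs_cavity4_about_5_percent(self, five_sites):
        fit = PREFitResult(np.array(AMIDE), 1.1, 1.0, 0.0, n_used=50)
        ratio = occupancy_ratio(fit, five_sites, cavity_a=3, cavity_b=4)
        assert ratio == pytest.approx((0.11 + 0.10) / (1.3 + 1.1 + 1.5), rel=1e-12)
        assert 100 * ratio == pytest.approx(5.0, abs=0.5)

    def test_identical_sums_give_unity(self, five_sites):
        fit = PREFitResult(np.array([1.0, 0.5, 0.0, 0.5, 1.0]), 0.0, 1.0, 0.0, n_used=50)
        assert occupancy_ratio(fit, five_sites, 3, 4) == pytest.approx(1.0)

    def test_scale_invariance(self, five_sites):
        for lam in (0.1, 3.0, 42.0):
            fit = PREFitResult(lam * np.array(AMIDE), 0.0, 1.0, 0.0, n_used=50)
            assert occupancy_ratio(fit, five_sites, 3, 4) == pytest.approx(
                0.21 / 3.9, rel=1e-12)

    def test_zero_denominator_is_error(self, five_sites):
        fit = PREFitResult(np.array([0.0, 0.0, 0.0, 1.0, 1.0]), 0.0, 1.0, 0.0, n_used=50)
        with pytest.raises(ValueError, match="zero"):
            occupancy_ratio(fit, five_sites, 3, 4)

    def test_contact_limit_binding_probability(self):
        assert binding_probability(10.0) == pytest.approx(10.0 / 6200.0)
        assert binding_probability(10.0) <= 0.002
        assert binding_probability(0.0) == 0.0
        assert binding_probability(6200.0) == 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            binding_probability(-1.0)


class TestBroadeningScreen:
    def test_below_threshold_flagged(self):
        tab = table_from_distances(np.array([[5.0, 20.0]]))
        assert broadening_screen(tab).iloc[0]

    def test_boundary_is_strict(self):
        tab = table_from_distances(np.array([[6.0, 20.0]]))
        assert not broadening_screen(tab).iloc[0]

    def test_constructed_separability(self):
        rng = np.random.default_rng(5)
        near = rng.uniform(3.0, 5.5, size=(20, 1))
        far = rng.uniform(7.0, 30.0, size=(20, 1))
        tab = table_from_distances(np.vstack([near, far]))
        flags = broadening_screen(tab).to_numpy()
        assert flags[:20].all()
        assert not flags[20:].any()
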