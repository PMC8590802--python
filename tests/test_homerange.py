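"""KDE home ranges, rank tests, availability sampling, and the
distribution-weighted exponential RSF machinery."""

import numpy as np
import pandas as pd
import pytest

from habconn import homerange as hr
from habconn import synth
from habconn.geodata import PointSet


class TestFilterIndividuals:
    def _telemetry(self, counts: dict) -> PointSet:
        parts = []
        for ind, n in counts.items():
            parts.append(
                PointSet.from_arrays(
                    np.arange(n, dtype=float),
                    np.arange(n, dtype=float),
                    "telemetry",
                    ids=[f"{ind}_{k}" for k in range(n)],
                    individual_id=ind,
                )
            )
        return PointSet.concat(parts)

    def test_boundary_at_min_fixes(self):
        tel = self._telemetry({"a": 30, "b": 31})
        kept, report = hr.filter_individuals(tel, min_fixes=30)
        assert kept.individuals() == ["b"]
        assert set(report["status"]) == {"kept", "dropped: <= 30 fixes"}

    def test_noop_when_all_pass(self):
        tel = self._telemetry({"a": 40, "b": 50})
        kept, _ = hr.filter_individuals(tel, min_fixes=30)
        assert len(kept) == len(tel)

    def test_disperser_excluded_and_counts_conserved(self):
        tel = self._telemetry({"a": 40, "b": 50, "c": 45})
        kept, report = hr.filter_individuals(tel, min_fixes=30, exclude=("c",))
        assert kept.individuals() == ["a", "b"]
        assert len(report) == 3  # kept + dropped = input individuals


class TestKDEHomeRange:
    def test_single_fix_isopleth_is_gaussian_disc(self):
        """For one fix with bandwidth h the 95% isopleth of the bivariate
        normal is a disc of radius h * sqrt(chi2_2,0.95) = 2.448 h."""
        h = 100.0
        hrange = hr.kde_home_range(
            np.array([[0.0, 0.0]]), bandwidth=h, grid_res=400, min_fixes=1
        )
        expect_km2 = np.pi * (2.4477 * h / 1000.0) ** 2
        assert hrange.area_km2 == pytest.approx(expect_km2, rel=0.03)

    def test_isopleth_mass_just_reaches_level(self):
        rng = np.random.default_rng(0)
        xy = rng.normal(0, 200, (80, 2))
        hrange = hr.kde_home_range(xy)
        g = hrange.mask_grid
        # recompute mass inside the mask from the same KDE definition
        hx, hy = hrange.bandwidth
        xs, ys = g.cell_centers()
        Gx = np.exp(-0.5 * ((xs[:, None] - xy[None, :, 0]) / hx) ** 2)
        Gy = np.exp(-0.5 * ((ys[:, None] - xy[None, :, 1]) / hy) ** 2)
        dens = (Gy @ Gx.T) / (len(xy) * 2 * np.pi * hx * hy)
        mass = dens * g.cell_size**2
        inside = mass[g.values > 0.5].sum() / mass.sum()
        assert 0.95 <= inside <= 0.95 + mass.max() / mass.sum() + 1e-12

    def test_area_scales_with_coordinate_units(self):
        rng = np.random.default_rng(1)
        xy = rng.normal(0, 300, (60, 2))
        a1 = hr.kde_home_range(xy).area_km2
        a2 = hr.kde_home_range(2 * xy).area_km2
        assert a2 == pytest.approx(4 * a1, rel=0.02)

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        xy = rng.normal(0, 300, (60, 2))
        a1 = hr.kde_home_range(xy).area_km2
        a2 = hr.kde_home_range(xy + np.array([5000.0, -3000.0])).area_km2
        assert a2 == pytest.approx(a1, rel=1e-9)

    def test_identical_fixes_rejected(self):
        xy = np.zeros((10, 2))
        with pytest.raises(ValueError, match="bandwidth"):
            hr.kde_home_range(xy)


class TestKruskalWallis:
    def test_hand_computed_rank_sums(self):
        # groups {1,2,3} vs {4,5,6}: H = 12/(6*7) * (6^2/3 + 15^2/3) - 3*7
        H, df, p = hr.kruskal_wallis([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert H == pytest.approx(3.857, abs=1e-3)
        assert df == 1

    def test_identical_groups_zero(self):
        H, _, p = hr.kruskal_wallis([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert H == pytest.approx(0.0, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=20)
        lab = ["a"] * 10 + ["b"] * 10
        H1, _, _ = hr.kruskal_wallis(v, lab)
        H2, _, _ = hr.kruskal_wallis(np.exp(3 * v), lab)
        assert H1 == pytest.approx(H2, abs=1e-12)

    def test_chi_square_p_close_to_permutation(self):
        """Chi-square reference p agrees with an exhaustive-style permutation
        oracle (vectorized rank-sum recomputation over 10^5 shuffles)."""
        from scipy.stats import rankdata

        rng = np.random.default_rng(4)
        v = rng.normal(size=20)
        v[:10] += 1.5
        lab = np.array(["a"] * 10 + ["b"] * 10)
        H, _, p = hr.kruskal_wallis(v, lab)
        ranks = rankdata(v)
        n_perm = 100_000
        order = np.argsort(rng.random((n_perm, 20)), axis=1)
        Ra = ranks[order[:, :10]].sum(axis=1)
        Rb = 210.0 - Ra
        Hp = (12.0 / (20 * 21)) * (Ra**2 / 10 + Rb**2 / 10) - 3 * 21
        assert abs(p - np.mean(Hp >= H - 1e-12)) < 0.02

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            hr.kruskal_wallis([1, 2, 3], ["a"] * 3)


class TestSampleAvailability:
    def test_points_inside_mask_and_count(self):
        rng = np.random.default_rng(5)
        xy = rng.normal(0, 250, (60, 2))
        hrange = hr.kde_home_range(xy, individual_id="b1")
        pts = hr.sample_availability(hrange, 60, seed=1)
        assert len(pts) == 60
        g = hrange.mask_grid
        i, j = g.cell_of(pts.df["x"], pts.df["y"])
        assert np.all(g.values[i, j] > 0.5)

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        hrange = hr.kde_home_range(rng.normal(0, 250, (40, 2)), individual_id="b2")
        a = hr.sample_availability(hrange, 25, seed=9)
        b = hr.sample_availability(hrange, 25, seed=9)
        np.testing.assert_allclose(a.xy, b.xy)


def _used_available(stack, beta, n_ind=4, n_fix=60, seed=0):
    truth = synth.TruthModel(beta=beta, hr_sigma_m=450.0)
    used = synth.generate_telemetry(stack, truth, n_ind, n_fix, seed=seed)
    parts = []
    for k, ind in enumerate(used.individuals()):
        fixes = used.subset(used.df["individual_id"] == ind)
        hrange = hr.kde_home_range(fixes, individual_id=str(ind))
        parts.append(hr.sample_availability(hrange, len(fixes), seed=seed + 31 * k))
    return used, PointSet.concat(parts)


class TestWeightedRSF:
    def test_null_covariate_near_zero(self, stack):
        """Used and available points drawn from the same distribution (two
        independent uniform draws within each isopleth) give beta ~ 0."""
        truth = synth.TruthModel(beta={"dist_main_roads": 0.0}, hr_sigma_m=450.0)
        tel = synth.generate_telemetry(stack, truth, 4, 60, seed=11)
        used_parts, avail_parts = [], []
        for k, ind in enumerate(tel.individuals()):
            fixes = tel.subset(tel.df["individual_id"] == ind)
            hrange = hr.kde_home_range(fixes, individual_id=str(ind))
            u = hr.sample_availability(hrange, 60, seed=1000 + k)
            u.df["id"] = u.df["id"] + "_u"
            used_parts.append(u)
            avail_parts.append(hr.sample_availability(hrange, 60, seed=2000 + k))
        used = PointSet.concat(used_parts)
        avail = PointSet.concat(avail_parts)
        fit = hr.fit_weighted_rsf(used, avail, stack, terms=["dist_main_roads"])
        assert abs(fit.coef["dist_main_roads"]) < 3 * fit.se["dist_main_roads"]

    def test_equal_weights_match_unweighted(self, stack):
        used, avail = _used_available(stack, {"forest_7km2": 1.0}, seed=12)
        terms = ["forest_7km2", "pasture_7km2"]
        w_eq = hr.fit_weighted_rsf(used, avail, stack, terms,
                                   weights=np.ones(len(used) + len(avail)))
        unw = hr.fit_weighted_rsf(used, avail, stack, terms, weighting="none")
        for t in w_eq.coef:
            assert w_eq.coef[t] == pytest.approx(unw.coef[t], abs=1e-10)

    def test_duplication_with_halved_weights_invariant(self, stack):
        used, avail = _used_available(stack, {"forest_7km2": 1.0}, n_ind=3, seed=13)
        terms = ["forest_7km2"]
        base_w = np.ones(len(used) + len(avail))
        fit1 = hr.fit_weighted_rsf(used, avail, stack, terms, weights=base_w)
        # duplicate the first individual's used rows at half weight
        first = used.df["individual_id"] == used.df["individual_id"].iloc[0]
        dup = used.df[first].copy()
        dup["id"] = dup["id"] + "_dup"
        used2 = PointSet(pd.concat([used.df, dup], ignore_index=True))
        w2 = np.concatenate([
            np.where(first, 0.5, 1.0),
            np.full(first.sum(), 0.5),
            np.ones(len(avail)),
        ])
        # order: original used rows, duplicated rows, then available
        fit2 = hr.fit_weighted_rsf(used2, avail, stack, terms, weights=w2)
        assert fit2.coef["forest_7km2"] == pytest.approx(
            fit1.coef["forest_7km2"], abs=1e-8
        )

    def test_individual_missing_availability_rejected(self, stack):
        used, avail = _used_available(stack, {"forest_7km2": 1.0}, n_ind=3, seed=14)
        short = avail.subset(avail.df["individual_id"] != used.df["individual_id"].iloc[0])
        with pytest.raises(ValueError, match="lacking availability"):
            hr.fit_weighted_rsf(used, short, stack, terms=["forest_7km2"])


class TestCAIC:
    def test_formula_and_preferences(self):
        assert hr.caic(-50.0, 3, 100) == pytest.approx(100 + 3 * (np.log(100) + 1))
        # equal LL -> smaller k wins; equal k -> larger LL wins
        a = hr.RSFFit("exponential_RSF", (), {}, {}, "none", -50.0, 2, 100,
                      hr.caic(-50.0, 2, 100))
        b = hr.RSFFit("logistic_RSPF", (), {}, {}, "none", -50.0, 3, 100,
                      hr.caic(-50.0, 3, 100))
        assert hr.compare_forms([a, b]) is a
        c = hr.RSFFit("logistic_RSPF", (), {}, {}, "none", -45.0, 2, 100,
                      hr.caic(-45.0, 2, 100))
        assert hr.compare_forms([a, c]) is c

    def test_caic_exceeds_aic_for_n_at_least_8(self):
        for n in (8, 20, 1000):
            caic = hr.caic(-30.0, 4, n)
            aic = -2 * -30.0 + 2 * 4
            assert caic > aic  # ln n + 1 > 2 for n >= 8 > e

    def test_mismatched_data_rejected(self):
        a = hr.RSFFit("exponential_RSF", (), {}, {}, "none", -50.0, 2, 100, 1.0)
        b = hr.RSFFit("logistic_RSPF", (), {}, {}, "none", -50.0, 2, 90, 1.0)
        with pytest.raises(ValueError, match="identical data"):
            hr.compare_forms([a, b])


class TestRSSCurve:
    def test_flat_when_beta_zero(self, stack):
        used, avail = _used_available(stack, {"forest_7km2": 0.5}, n_ind=3, seed=15)
        fit = hr.fit_weighted_rsf(used, avail, stack, terms=["forest_7km2"])
        fit.coef["forest_7km2"] = 0.0
        curve = hr.rss_use_curve(fit, avail, stack, "forest_7km2")
        assert curve["fitted"].std() < 1e-12
        assert curve["smooth"].std() < 1e-9

    def test_monotone_beta_gives_monotone_smooth(self, stack):
        """Single positive-coefficient model: the lowess smooth through the
        fitted scores is nondecreasing (up to numerical wiggle)."""
        rng = np.random.default_rng(16)
        used, avail = _used_available(stack, {"forest_7km2": 1.0}, n_ind=3, seed=16)
        for _ in range(10):
            beta = float(rng.uniform(0.2, 2.0))
            fit = hr.fit_weighted_rsf(used, avail, stack, terms=["forest_7km2"])
            fit.coef["forest_7km2"] = beta
            curve = hr.rss_use_curve(fit, avail, stack, "forest_7km2")
            diffs = np.diff(curve["smooth"].to_numpy())
            assert diffs.min() > -1e-6 * max(1.0, np.abs(curve["smooth"]).max())

    def test_missing_covariate_rejected(self, stack):
        used, avail = _used_available(stack, {"forest_7km2": 1.0}, n_ind=3, seed=17)
        fit = hr.fit_weighted_rsf(used, avail, stack, terms=["forest_7km2"])
        with pytest.raises(KeyError):
            hr.rss_use_curve(fit, avail, stack, "dist_main_roads")


class TestGroupContrasts:
    def test_sex_area_contrast_detected(self, stack):
        """A 2.5x male/female home-range area ratio (lognormal between-animal
        spread 0.45) is detected by the rank test in most replicates."""
        rng = np.random.default_rng(20)
        detected = 0
        n_rep = 30
        for _ in range(n_rep):
            areas, labels = [], []
            for k in range(20):
                female = k < 11
                sigma = 300.0 * np.sqrt(2.5) ** (0 if female else 1)
                sigma *= np.exp(rng.normal(0, 0.45 / 2))  # area ~ sigma^2
                xy = rng.normal(0, sigma, (40, 2))
                areas.append(hr.kde_home_range(xy, grid_res=100).area_km2)
                labels.append("F" if female else "M")
            _, _, p = hr.kruskal_wallis(areas, labels)
            detected += p < 0.05
        assert detected >= 0.9 * n_rep
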