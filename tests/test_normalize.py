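import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import snparray as sp
from snparray import (SNPArrayError, SimConfig, baf_from_theta,
                      estimate_clusters, lrr_from_r, quantile_normalize_between,
                      simulate_genotypes, simulate_intensities, theta_r, tqn,
                      tqn_within)


class TestQuantileNormalizeBetween:
    def test_identical_columns_unchanged(self):
        m = np.tile([[1.0], [5.0], [3.0]], (1, 3))
        np.testing.assert_allclose(quantile_normalize_between(m), m)

    def test_sorted_mean_oracle_by_hand(self):
        m = np.array([[1.0, 3.0], [2.0, 4.0], [3.0, 5.0]])
        out = quantile_normalize_between(m)
        np.testing.assert_allclose(out, [[2, 2], [3, 3], [4, 4]])

    def test_single_column_degenerate(self):
        m = np.array([[1.0], [2.0]])
        with pytest.warns(UserWarning):
            np.testing.assert_allclose(quantile_normalize_between(m), m)

    @settings(deadline=None)
    @given(hnp.arrays(float, (11, 4), elements=st.floats(0, 100)))
    def test_equalizes_sorted_columns(self, m):
        """After QN every column's sorted values match the target exactly
        whenever there are no cross-column ties to average."""
        out = quantile_normalize_between(m)
        target = np.sort(m, axis=0).mean(axis=1)
        for j in range(4):
            if len(np.unique(m[:, j])) == m.shape[0]:
                np.testing.assert_allclose(np.sort(out[:, j]), target)


class TestTqnWithin:
    def test_equal_channels_fixed_point(self):
        x = np.array([0.2, 0.8, 0.5])
        xn, yn = tqn_within(x, x.copy(), 1.5)
        np.testing.assert_allclose(xn, x)
        np.testing.assert_allclose(yn, x)

    def test_cap_rule_by_hand(self):
        xn, yn = tqn_within(np.array([1.0]), np.array([4.0]), 1.5)
        assert xn[0] == pytest.approx(1.5)   # raw QN target 2.5, capped
        assert yn[0] == pytest.approx(2.5)   # 2.5 <= 1.5 * 4

    def test_infinite_threshold_is_plain_qn(self):
        rng = np.random.default_rng(4)
        x, y = rng.uniform(0.01, 2, 50), rng.uniform(0.01, 2, 50)
        xn, yn = tqn_within(x, y, np.inf)
        target = 0.5 * (np.sort(x) + np.sort(y))
        np.testing.assert_allclose(np.sort(xn), target)
        np.testing.assert_allclose(np.sort(yn), target)

    def test_zeros_pass_through(self):
        xn, _ = tqn_within(np.array([0.0, 1.0]), np.array([2.0, 3.0]), 1.5)
        assert xn[0] == 0.0

    def test_negative_rejected(self):
        with pytest.raises(SNPArrayError):
            tqn_within(np.array([-1.0]), np.array([1.0]), 1.5)

    @settings(deadline=None)
    @given(hnp.arrays(float, 20, elements=st.floats(0, 10)),
           hnp.arrays(float, 20, elements=st.floats(0, 10)),
           st.floats(1.01, 5))
    def test_cap_never_exceeded(self, x, y, thr):
        xn, yn = tqn_within(x, y, thr)
        assert (xn <= thr * x + 1e-12).all()
        assert (yn <= thr * y + 1e-12).all()


class TestThetaR:
    @pytest.mark.parametrize("x,y,theta,R", [
        (1.0, 0.0, 0.0, 1.0),
        (0.0, 1.0, 1.0, 1.0),
        (0.5, 0.5, 0.5, 1.0),
    ])
    def test_canonical_points(self, x, y, theta, R):
        t, r = theta_r(x, y)
        assert t == theta and r == R

    def test_origin_is_missing(self):
        t, r = theta_r(0.0, 0.0)
        assert np.isnan(t) and r == 0.0


class TestEstimateClusters:
    def _ref(self, seed=0, **kw):
        cfg = SimConfig(seed=seed, n_pops=1, n_per_pop=50, x_fraction=0,
                        y_fraction=0, missing_rate=0, **kw)
        g, _ = simulate_genotypes(cfg)
        return simulate_intensities(g, cfg), cfg

    def test_median_centroids_recovered(self):
        """With sigma = 0.03 and 50 reference samples the estimated theta
        centroids sit within 0.02 of the generating model (median over
        markers with all three clusters observed)."""
        ref, cfg = self._ref(seed=1)
        tab = estimate_clusters(ref)
        full = tab[(tab[["n_AA", "n_AB", "n_BB"]] >= 3).all(axis=1)]
        for col, truth in zip(("theta_AA", "theta_AB", "theta_BB"),
                              cfg.cluster_theta):
            assert abs(np.median(full[col]) - truth) < 0.02

    def test_het_cluster_imputed_at_midpoint(self):
        ref, _ = self._ref(seed=2, noise_sigma=0.0)
        # erase all het calls at the first marker
        ref.calls[0, ref.calls[0] == 1] = 0
        tab = estimate_clusters(ref)
        row = tab.iloc[0]
        if row["n_AB"] < 3:
            assert row["imputed_AB"]
            assert row["theta_AB"] == pytest.approx(
                0.5 * (row["theta_AA"] + row["theta_BB"]))

    def test_missing_homozygote_mirrored(self):
        ref, _ = self._ref(seed=3, noise_sigma=0.0)
        ref.calls[0, ref.calls[0] == 2] = 1  # no BB samples at marker 0
        tab = estimate_clusters(ref)
        row = tab.iloc[0]
        assert row["imputed_BB"]
        assert row["theta_BB"] == pytest.approx(1.0 - row["theta_AA"])
        assert row["r_BB"] == pytest.approx(row["r_AA"])

    def test_all_missing_marker_excluded(self):
        ref, _ = self._ref(seed=4)
        ref.calls[0, :] = sp.MISSING
        tab = estimate_clusters(ref)
        assert tab.iloc[0][["theta_AA", "theta_AB", "theta_BB"]].isna().all()


class TestBafLrr:
    def test_baf_anchors_exact(self):
        assert baf_from_theta(0.1, 0.1, 0.5, 0.9) == 0.0
        assert baf_from_theta(0.5, 0.1, 0.5, 0.9) == 0.5
        assert baf_from_theta(0.9, 0.1, 0.5, 0.9) == 1.0

    def test_baf_interior_interpolation(self):
        assert baf_from_theta(0.3, 0.1, 0.5, 0.9) == pytest.approx(0.25)

    def test_baf_degenerate_cluster_missing(self):
        assert np.isnan(baf_from_theta(0.3, 0.2, 0.2, 0.9))

    def test_baf_monotone_in_theta(self):
        thetas = np.linspace(0, 1, 101)
        baf = baf_from_theta(thetas, 0.07, 0.46, 0.93)
        assert (np.diff(baf) >= -1e-12).all()

    def test_lrr_zero_at_reference_level(self):
        assert lrr_from_r(0.5, 1.2, 0.1, 0.5, 0.9, 1.0, 1.2, 1.0) == 0.0

    def test_lrr_doubling_is_one(self):
        assert lrr_from_r(0.5, 2.4, 0.1, 0.5, 0.9, 1.0, 1.2, 1.0) == 1.0

    def test_lrr_nonpositive_r_missing(self):
        assert np.isnan(lrr_from_r(0.5, 0.0, 0.1, 0.5, 0.9, 1.0, 1.2, 1.0))

    def test_lrr_clamps_beyond_outer_clusters(self):
        v = lrr_from_r(0.0, 1.0, 0.1, 0.5, 0.9, 1.0, 2.0, 1.0)
        assert v == 0.0  # R0 clamped to r_AA, no extrapolation


class TestTqnPipeline:
    def test_requires_intensities(self, small_gset):
        with pytest.raises(SNPArrayError, match="intensities"):
            tqn(small_gset, None)

    def test_normalized_flag_and_tracks(self):
        cfg = SimConfig(seed=6, n_pops=1, n_per_pop=8, n_markers=300,
                        x_fraction=0, y_fraction=0)
        g, _ = simulate_genotypes(cfg)
        g = simulate_intensities(g, cfg)
        norm = tqn(g, estimate_clusters(g))
        assert norm.normalized
        assert norm.baf.shape == g.shape
        finite = norm.baf[np.isfinite(norm.baf)]
        assert finite.min() >= 0 and finite.max() <= 1

    def test_contamination_displaces_homozygous_baf(self):
        """A 90:10 intensity mixture with another sample shifts homozygous-call
        BAF off the 0/1 rails by a detectable margin (median > 0.02) at the
        markers informative for contamination — those where the contaminating
        sample carries a different genotype; concordant markers cannot shift.
        """
        clean_cfg = SimConfig(seed=7, missing_rate=0.0)
        g, _ = simulate_genotypes(clean_cfg)
        sid, donor = g.sample_ids[0], g.sample_ids[-1]  # different populations
        cont_cfg = SimConfig(seed=7, missing_rate=0.0,
                             contamination=[(sid, donor, 0.1)])
        clean = simulate_intensities(g, clean_cfg)
        cont = simulate_intensities(g, cont_cfg)
        ref, _ = simulate_genotypes(clean_cfg, cohort="ref", n_per_pop=17)
        ref = simulate_intensities(ref, clean_cfg, cohort="ref")
        ctab = estimate_clusters(ref)

        j, dj = 0, g.sample_ids.get_loc(donor)
        informative = (np.isin(g.calls[:, j], (0, 2))
                       & (g.calls[:, dj] != g.calls[:, j])
                       & (g.calls[:, dj] != sp.MISSING))

        def hom_dev(norm):
            baf = norm.baf[informative, j]
            baf = baf[~np.isnan(baf)]
            return np.median(np.minimum(baf, 1 - baf))

        dev_clean = hom_dev(tqn(clean, ctab))
        dev_cont = hom_dev(tqn(cont, ctab))
        assert dev_clean < 0.01
        assert dev_cont - dev_clean > 0.02
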