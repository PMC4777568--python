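"""Bootstrap sample-size curves: enumeration oracle, scaling, determinism."""

import numpy as np
import pandas as pd
import pytest

import traitvar as tv


def lognormal_values(cv, n, seed, mean=5.0):
    rng = np.random.default_rng(seed)
    s = np.sqrt(np.log1p(cv**2))
    return mean * np.exp(s * rng.standard_normal(n) - 0.5 * s**2)


class TestBootstrapMeanSE:
    def test_constant_values_zero_se(self):
        v = np.full(30, 7.0)
        for k in (2, 5, 10):
            assert tv.bootstrap_mean_se(v, k, n_boot=200, rng=0) == 0.0

    def test_two_point_exact_enumeration(self):
        """{1,3}, k=2: the 4 equiprobable resamples have SE 0,1,1,0 -> E = 0.5."""
        est = tv.bootstrap_mean_se(np.array([1.0, 3.0]), 2, n_boot=10_000, rng=1)
        assert est == pytest.approx(0.5, abs=0.03)

    def test_inverse_sqrt_k_scaling(self):
        v = lognormal_values(0.4, 150, seed=2)
        se5 = tv.bootstrap_mean_se(v, 5, n_boot=1000, rng=3)
        se100 = tv.bootstrap_mean_se(v, 100, n_boot=1000, rng=4)
        assert se100 < se5

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            tv.bootstrap_mean_se(np.array([1.0, 2.0]), 1)


class TestMinSampleSize:
    def test_constant_trait_min_is_first_grid_size(self):
        curve = tv.min_sample_size(np.full(60, 3.0), seed=0)
        assert curve.min_adequate_n == curve.grid[0] == 3

    def test_grid_truncates_at_sample_size(self):
        curve = tv.min_sample_size(lognormal_values(0.3, 42, seed=1), seed=0)
        assert max(curve.grid) <= 42
        assert list(curve.grid) == sorted(curve.grid)

    def test_not_reached_sentinel(self):
        # CV 1.2 needs ~(1.2/0.05)^2 = 576 >> 100: threshold never reached
        curve = tv.min_sample_size(lognormal_values(1.2, 300, seed=3), seed=0)
        assert curve.min_adequate_n is None

    @pytest.mark.parametrize("cv,analytic", [(0.33, (0.33 / 0.05) ** 2), (0.10, (0.10 / 0.05) ** 2)])
    def test_analytic_cv_oracle(self, cv, analytic):
        """Median min_adequate_n over 10 datasets within one grid step of the
        smallest grid size >= (CV/0.05)^2."""
        grid = tv.default_grid()
        target = next(k for k in grid if k >= analytic)
        step = 5
        mins = []
        for seed in range(10):
            vals = lognormal_values(cv, 200, seed=1000 + seed)
            mins.append(tv.min_sample_size(vals, seed=seed).min_adequate_n)
        assert all(m is not None for m in mins)
        assert abs(np.median(mins) - target) <= step

    def test_mean_se_nonincreasing_within_mc_noise(self):
        """No grid step may raise mean_se by more than 3 Monte-Carlo SEs."""
        curve = tv.min_sample_size(lognormal_values(0.33, 200, seed=5), seed=5)
        se = np.array(curve.mean_se)
        mc = np.array(curve.mc_se)
        jumps = se[1:] - se[:-1]
        allowance = 3 * np.sqrt(mc[1:] ** 2 + mc[:-1] ** 2)
        assert (jumps <= allowance).all()

    def test_min_n_nondecreasing_in_cv(self):
        """Across synthetic species differing only in CV, higher CV never
        needs fewer individuals (on the median over seeds)."""
        medians = []
        for cv in (0.1, 0.2, 0.33):
            mins = [
                tv.min_sample_size(lognormal_values(cv, 200, seed=s), seed=s).min_adequate_n
                for s in range(8)
            ]
            medians.append(np.median(mins))
        assert medians[0] <= medians[1] <= medians[2]

    def test_bitwise_reproducibility(self):
        vals = lognormal_values(0.3, 120, seed=9)
        a = tv.min_sample_size(vals, seed=42)
        b = tv.min_sample_size(vals, seed=42)
        assert a.mean_se == b.mean_se and a.min_adequate_n == b.min_adequate_n

    def test_grid_extension_preserves_earlier_values(self):
        """Per-size substreams: adding sizes never changes existing ones."""
        vals = lognormal_values(0.3, 120, seed=9)
        short = tv.min_sample_size(vals, grid=[3, 5, 10], seed=7)
        long = tv.min_sample_size(vals, grid=[3, 5, 10, 20, 40], seed=7)
        assert long.mean_se[:3] == short.mean_se


def _site_table(values_by_site, species="spX"):
    rows = []
    i = 0
    for site, vals in values_by_site.items():
        for v in vals:
            rows.append(
                {
                    "individual_id": f"i{i}",
                    "species": species,
                    "site": site,
                    "body_mass_g": float(v),
                }
            )
            i += 1
    return pd.DataFrame(rows)


class TestSiteRestricted:
    def test_single_site_species_identical_to_pooled(self):
        vals = lognormal_values(0.3, 80, seed=4)
        tab = _site_table({"site1": vals})
        pooled = tv.min_sample_size(vals, seed=3, species="spX", trait="body_mass_g")
        restricted = tv.site_restricted_curve(tab, "spX", "body_mass_g", seed=3)
        assert restricted.mean_se == pooled.mean_se
        assert restricted.min_adequate_n == pooled.min_adequate_n
        assert restricted.site == "site1" and not restricted.site_tie

    def test_tie_broken_to_lowest_label_and_flagged(self):
        tab = _site_table({"site2": [1.0, 2.0, 3.0], "site1": [4.0, 5.0, 6.0]})
        c = tv.site_restricted_curve(tab, "spX", "body_mass_g", grid=[3], n_boot=50)
        assert c.site == "site1" and c.site_tie

    def test_no_site_effect_null(self):
        """With no site effect, single-site and pooled minima differ by <= one
        grid step on the median over 10 seeds."""
        diffs = []
        for seed in range(10):
            vals = lognormal_values(0.33, 240, seed=200 + seed)
            sites = np.where(np.arange(240) % 2 == 0, "site1", "site2")
            tab = _site_table({"site1": vals[sites == "site1"], "site2": vals[sites == "site2"]})
            pooled = tv.min_sample_size(vals, seed=seed)
            single = tv.site_restricted_curve(tab, "spX", "body_mass_g", seed=seed)
            diffs.append(abs((single.min_adequate_n or 100) - (pooled.min_adequate_n or 100)))
        assert np.median(diffs) <= 5

    def test_between_site_shift_inflates_pooled_requirement(self):
        """A strong between-site shift makes the single-site minimum no larger
        than the pooled one in most replicates."""
        wins = 0
        for seed in range(10):
            a = lognormal_values(0.2, 120, seed=400 + seed, mean=5.0)
            b = lognormal_values(0.2, 110, seed=500 + seed, mean=15.0)
            tab = _site_table({"site1": a, "site2": b})
            pooled = tv.min_sample_size(np.concatenate([a, b]), seed=seed)
            single = tv.site_restricted_curve(tab, "spX", "body_mass_g", seed=seed)
            if (single.min_adequate_n or 101) <= (pooled.min_adequate_n or 101):
                wins += 1
        assert wins >= 8
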