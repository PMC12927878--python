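"""Phylotype selection, spline smoothing, derivatives, and per-capita rates."""

import math

import numpy as np
import pandas as pd
import pytest

from lotic import asv_growth as ag
from lotic import synthetic
from lotic.errors import InvalidInputError


def random_rel_table(rng, n_asv=30, n_samp=40):
    w = rng.lognormal(0.0, 2.0, size=(n_asv, n_samp))
    mask = rng.random((n_asv, n_samp)) < 0.3
    w[mask] = 0.0
    w[0, :] = 1.0  # keep every column non-empty
    rel = w / w.sum(axis=0)
    return pd.DataFrame(rel, index=[f"a{i}" for i in range(n_asv)])


class TestSelectAsvs:
    def test_zero_minimum_counts_as_passing(self):
        bloomer = np.r_[np.zeros(5), np.full(25, 0.05)]  # zero min, 5% max, prev 25
        rel = pd.DataFrame([bloomer, 1.0 - bloomer], index=["bloomer", "rest"])
        assert "bloomer" in ag.select_asvs(rel, min_prevalence=20)
        assert "bloomer" not in ag.select_asvs(rel, min_prevalence=26)

    def test_low_maximum_excluded(self):
        rel = pd.DataFrame(
            {f"s{i}": [0.005, 0.995] for i in range(30)}, index=["dim", "rest"]
        )
        assert "dim" not in ag.select_asvs(rel)

    def test_matches_brute_force_scan(self, rng):
        rel = random_rel_table(rng)
        got = set(ag.select_asvs(rel, min_ratio=100, min_max_abund=0.01,
                                 min_prevalence=20))
        expected = set()
        for asv, row in rel.iterrows():
            v = row.to_numpy()
            ratio = math.inf if v.min() <= 0 else v.max() / v.min()
            if (
                ratio >= 100
                and v.max() >= 0.01
                and int((v > 0).sum()) >= 20
            ):
                expected.add(asv)
        assert got == expected


class TestAbsoluteAbundance:
    def test_scaling(self):
        assert ag.absolute_abundance(0.10, 1e9) == pytest.approx(1e8)
        assert ag.absolute_abundance(0.0, 5e9) == 0.0

    def test_peak_magnitude_consistency(self):
        # a 16% peak over ~1.4e9 cells/l sits at ~2.3e8 cells/l
        assert ag.absolute_abundance(0.16, 1.44e9) == pytest.approx(2.3e8, rel=0.01)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            ag.absolute_abundance(1.2, 1e9)
        with pytest.raises(InvalidInputError):
            ag.absolute_abundance(0.5, 0.0)


class TestSmoother:
    def test_linear_signal_reproduced_exactly(self):
        x = np.linspace(0.0, 1000.0, 60)
        y = 5.0 + 0.02 * x
        fit = ag.fit_smoother(x, y, basis_dim=10)
        assert np.max(np.abs(fit.fitted - (5.0 + 0.02 * fit.grid))) < 1e-6
        assert fit.effective_df == pytest.approx(2.0, abs=0.05)
        assert np.allclose(fit.derivative, 0.02, atol=1e-8)

    def test_constant_has_zero_derivative(self):
        x = np.linspace(0.0, 100.0, 30)
        fit = ag.fit_smoother(x, np.full(30, 7.0), basis_dim=8)
        assert np.max(np.abs(fit.derivative)) < 1e-6

    def test_envelope_contains_fitted_curve(self, rng):
        x = np.linspace(0.0, 300.0, 50)
        y = np.exp(x / 150.0) + rng.normal(0.0, 0.1, 50)
        fit = ag.fit_smoother(x, y, basis_dim=12)
        assert np.all(fit.band_low <= fit.fitted)
        assert np.all(fit.fitted <= fit.band_high)

    def test_replicates_averaged(self):
        x = np.r_[np.repeat(np.linspace(0, 90, 10), 2)]
        y = np.r_[[v for t in np.linspace(0, 90, 10) for v in (t - 1, t + 1)]]
        fit = ag.fit_smoother(x, y, basis_dim=6)
        assert np.max(np.abs(fit.fitted - fit.grid)) < 1e-6

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            ag.fit_smoother(np.arange(5.0), np.arange(5.0))

    def test_sine_derivative_matches_cosine(self):
        x = np.linspace(0.0, 2 * np.pi, 200)
        fit = ag.fit_smoother(x, np.sin(x), basis_dim=25)
        err = np.max(np.abs(fit.derivative - np.cos(fit.grid)))
        assert err < 0.01  # 1% of the unit cosine amplitude

    def test_noisy_logistic_coverage(self):
        """The +/-2 SE band covers the true curve at >=90% of grid points."""
        tt = np.linspace(0.0, 300.0, 80)
        truth_fn = lambda t: 1.0 / (1.0 + np.exp(-0.05 * (t - 150.0)))
        rates = []
        for seed in range(25):
            r = np.random.default_rng(seed)
            y = truth_fn(tt) + r.normal(0.0, 0.05, len(tt))
            fit = ag.fit_smoother(tt, y, basis_dim=12)
            t = truth_fn(fit.grid)
            rates.append(np.mean((t >= fit.band_low) & (t <= fit.band_high)))
        assert np.mean(rates) >= 0.90


class TestDerivative:
    def test_consistent_with_central_differences(self):
        x = np.linspace(0.0, 2 * np.pi, 150)
        fit = ag.fit_smoother(x, np.sin(x), basis_dim=20, grid_n=400)
        fd = np.gradient(fit.fitted, fit.grid)
        scale = np.max(np.abs(fit.derivative))
        interior = slice(5, -5)
        assert np.max(np.abs(fd[interior] - fit.derivative[interior])) / scale < 1e-3

    def test_integrates_to_net_change(self):
        x = np.linspace(0.0, 2 * np.pi, 150)
        fit = ag.fit_smoother(x, np.cos(x) + 2.0, basis_dim=20, grid_n=3001)
        integral = np.trapezoid(fit.derivative, fit.grid)
        net = fit.fitted[-1] - fit.fitted[0]
        assert abs(integral - net) <= 1e-3 * max(abs(net), 1e-12) + 1e-9

    def test_frame_columns(self):
        x = np.linspace(0.0, 10.0, 20)
        fit = ag.fit_smoother(x, x**2, basis_dim=8)
        frame = ag.derivative_series(fit)
        assert list(frame.columns) == ["tt", "deriv", "lo", "hi"]
        assert np.all(frame["lo"] <= frame["deriv"])


class TestMaxChange:
    def test_logistic_oracle(self):
        K, g, t0 = 1.0, 0.05, 150.0
        tt = np.linspace(0.0, 300.0, 80)
        y = K / (1.0 + np.exp(-g * (tt - t0)))
        fit = ag.fit_smoother(tt, y, basis_dim=20)
        mc = ag.max_change(fit)
        assert mc.max_increase == pytest.approx(g * K / 4.0, rel=0.02)
        step = fit.grid[1] - fit.grid[0]
        assert abs(mc.tt_at_max_increase - t0) <= 2 * step

    def test_monotone_rising_flag(self):
        tt = np.linspace(0.0, 100.0, 20)
        fit = ag.fit_smoother(tt, 2.0 * tt, basis_dim=6)
        mc = ag.max_change(fit)
        assert mc.monotone_rising
        assert mc.max_decrease >= -1e-6

    def test_constant_series(self):
        tt = np.linspace(0.0, 100.0, 20)
        fit = ag.fit_smoother(tt, np.full(20, 3.0), basis_dim=6)
        mc = ag.max_change(fit)
        assert mc.max_increase == pytest.approx(0.0, abs=1e-6)
        assert mc.max_decrease == pytest.approx(0.0, abs=1e-6)


class TestSitewiseRate:
    def test_one_doubling_per_day(self):
        assert ag.sitewise_rate(1e6, 2e6, 24.0) == pytest.approx(math.log(2.0))

    def test_no_change(self):
        assert ag.sitewise_rate(5e7, 5e7, 10.0) == 0.0

    def test_antisymmetry(self):
        fwd = ag.sitewise_rate(1e6, 3e6, 12.0)
        rev = ag.sitewise_rate(3e6, 1e6, 12.0)
        assert fwd == pytest.approx(-rev)

    def test_zero_endpoints(self):
        assert ag.sitewise_rate(1e6, 0.0, 5.0) == float("-inf")
        with pytest.raises(InvalidInputError):
            ag.sitewise_rate(0.0, 1e6, 5.0)

    def test_planted_bloomer_rate_recovered(self, jds3_truth):
        """The logistic bloomer's exponential phase runs at ~100x bulk rate."""
        rep = synthetic.truth_report(jds3_truth)
        tt = np.array(rep["expected"]["tt_cum_h"])
        tcc = np.array(rep["expected"]["expected_tcc"])
        g_truth = rep["expected"]["bloomer_growth_rate_per_h"]
        traj = np.array(rep["expected"]["bloomer_relative_trajectories"][0])
        abund = traj * tcc
        # pick a consecutive pair deep in the exponential phase
        carrying = jds3_truth.bloomer_carrying_frac
        rel_next = traj[1:] / carrying
        ok = np.nonzero((traj[:-1] > 0) & (rel_next < 0.01))[0]
        i = ok[-1]
        rate = ag.sitewise_rate(abund[i], abund[i + 1], tt[i + 1] - tt[i])
        ratio = ag.rate_ratio(rate, jds3_truth.bulk_cd_daily)
        assert abs(ratio - jds3_truth.bloomer_rate_multiplier) / \
            jds3_truth.bloomer_rate_multiplier < 0.10

    def test_sampled_bloomers_show_fast_rates(self, jds3_truth, jds3_table,
                                              jds3_transect):
        """Observed (noisy) bloomer counts still show >=10x-bulk rates."""
        from lotic.diversity import relative_abundance

        rel = relative_abundance(jds3_table)
        samples = [jds3_table.site_sample(s) for s in jds3_transect.site_ids]
        rel = rel[samples]
        tt = jds3_transect.tt_cum
        tcc = jds3_transect.values("tcc")
        best = -math.inf
        for asv in [a for a in rel.index if a.startswith("ASV_B")]:
            ab = ag.absolute_abundance(rel.loc[asv].to_numpy(), tcc)
            for i in range(len(tt) - 1):
                if ab[i] > 0 and ab[i + 1] > 0:
                    best = max(best, ag.sitewise_rate(ab[i], ab[i + 1],
                                                      tt[i + 1] - tt[i]))
        assert best >= 10 * jds3_truth.bulk_cd_daily


class TestGrowthTable:
    def test_bloomers_selected_and_summarised(self, jds3_truth, jds3_table,
                                              jds3_transect):
        from lotic.diversity import relative_abundance

        rel = relative_abundance(jds3_table)
        samples = [jds3_table.site_sample(s) for s in jds3_transect.site_ids]
        rel = rel[samples]
        tcc = pd.Series(jds3_transect.values("tcc"), index=samples)
        tt = pd.Series(jds3_transect.tt_cum, index=samples)
        # the earliest bloomer is prevalent enough to pass the default filter
        assert "ASV_B1" in ag.select_asvs(rel)
        bloomers = [a for a in rel.index if a.startswith("ASV_B")]
        out = ag.growth_table(rel, tcc, tt, bulk_cd_daily=0.12, asv_ids=bloomers)
        bloom = out[out["asv_id"].str.startswith("ASV_B")]
        assert (bloom["max_increase"] > 0).all()
        # the last bloomer peaks at the river mouth where its exponential
        # phase falls below detection, so only saturated pairs remain; the
        # earlier bloomers must all show clearly super-bulk rates
        assert (bloom["ratio_to_bulk"].iloc[:3] > 10).all()
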