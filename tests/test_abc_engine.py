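"""PLS reduction, rejection, GLM adjustment, model comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from ecotypeabc.abc_engine import (
    SimulationTable,
    compare_models,
    fit_pls,
    glm_adjust,
    hpd_interval,
    posterior_summaries,
    reject,
    retained_count,
    to_estimation_scale,
)
from ecotypeabc.demographic_models import PriorSpec


@pytest.fixture
def linear_toy(rng):
    """One log-uniform parameter mapped noiselessly into two statistics,
    plus one pure-noise statistic."""
    n = 2000
    theta = np.exp(rng.uniform(math.log(10), math.log(1000), n))
    lt = np.log(theta)
    stats = pd.DataFrame({
        "s1": 2 * lt + 1.0,
        "s2": 3.0 - lt,
        "s3": rng.normal(size=n),
    })
    params = pd.DataFrame({"T": theta})
    priors = {"T": PriorSpec("T", "log_uniform", 10.0, 1000.0)}
    return SimulationTable(params, stats, "toy", 0), priors, theta


class TestSimulationTable:
    def test_row_count_mismatch(self):
        with pytest.raises(ValueError):
            SimulationTable(pd.DataFrame({"a": [1, 2]}),
                            pd.DataFrame({"s": [1.0]}), "m")

    def test_sentinel_filtering(self):
        t = SimulationTable(pd.DataFrame({"a": [1.0, 2.0, 3.0]}),
                            pd.DataFrame({"s": [0.1, np.nan, 0.3]}), "m")
        f = t.drop_sentinels()
        assert len(f) == 2 and list(f.params["a"]) == [1.0, 3.0]

    def test_save_load_roundtrip(self, tmp_path, linear_toy):
        table, _, _ = linear_toy
        table.save(str(tmp_path / "t"))
        back = SimulationTable.load(str(tmp_path / "t"), "toy")
        pd.testing.assert_frame_equal(back.params, table.params)
        pd.testing.assert_frame_equal(back.stats, table.stats)


class TestPls:
    def test_informative_linear_system_captured(self, linear_toy, rng):
        table, priors, theta = linear_toy
        tr = fit_pls(table, priors, rng=rng)
        comp = tr.apply(table.stats)
        r = np.corrcoef(comp[:, 0], np.log(theta))[0, 1]
        assert r**2 > 0.99

    def test_uninformative_stats_explain_nothing(self, linear_toy, rng):
        table, priors, theta = linear_toy
        shuffled = table.stats.sample(frac=1.0, random_state=0).reset_index(drop=True)
        tab = SimulationTable(table.params, shuffled, "perm")
        tr = fit_pls(tab, priors, rng=rng)
        comp = tr.apply(tab.stats)
        r2 = max(np.corrcoef(comp[:, j], np.log(theta))[0, 1] ** 2
                 for j in range(comp.shape[1]))
        assert r2 < 0.05

    def test_transform_deterministic(self, linear_toy, rng):
        table, priors, _ = linear_toy
        tr = fit_pls(table, priors, rng=rng)
        once = tr.apply(table.stats)
        again = tr.apply(table.stats)
        assert np.array_equal(once, again)

    def test_constant_columns_dropped(self, linear_toy, rng):
        table, priors, _ = linear_toy
        stats = table.stats.assign(flat=1.0)
        tab = SimulationTable(table.params, stats, "const")
        tr = fit_pls(tab, priors, rng=rng)
        assert tr.dropped == ["flat"]
        assert "flat" not in tr.stat_names


class TestRejection:
    def test_observed_row_retained_at_distance_zero(self, linear_toy, rng):
        table, priors, _ = linear_toy
        tr = fit_pls(table, priors, rng=rng)
        idx, dist = reject(table.stats.iloc[17], table, tr, 5)
        assert idx[0] == 17 and dist[0] == 0.0

    def test_full_retention_is_identity(self, linear_toy, rng):
        table, priors, _ = linear_toy
        tr = fit_pls(table, priors, rng=rng)
        idx, _ = reject(table.stats.iloc[0], table, tr, len(table))
        assert sorted(idx) == list(range(len(table)))

    def test_matches_exhaustive_sort(self, linear_toy, rng):
        table, priors, _ = linear_toy
        small = SimulationTable(table.params.iloc[:100].reset_index(drop=True),
                                table.stats.iloc[:100].reset_index(drop=True), "s")
        tr = fit_pls(small, priors, rng=rng)
        obs = table.stats.iloc[500]
        idx, dist = reject(obs, small, tr, 10)
        comp = tr.apply(small.stats)
        o = tr.apply(obs)
        d_all = np.sqrt(((comp - o) ** 2).sum(axis=1))
        brute = sorted(range(100), key=lambda i: (d_all[i], i))[:10]
        assert list(idx) == brute

    def test_invalid_k(self, linear_toy, rng):
        table, priors, _ = linear_toy
        tr = fit_pls(table, priors, rng=rng)
        with pytest.raises(ValueError):
            reject(table.stats.iloc[0], table, tr, 0)
        with pytest.raises(ValueError):
            reject(table.stats.iloc[0], table, tr, len(table) + 1)

    def test_retained_count_floor_and_cap(self):
        assert retained_count(10_000, 0.01) == 200  # floored
        assert retained_count(100_000, 0.01) == 1000
        assert retained_count(150, 0.01) == 150  # capped at the table


class TestGlmAdjust:
    def test_noiseless_linear_map_recovers_preimage(self, linear_toy, rng):
        table, priors, theta = linear_toy
        tr = fit_pls(table, priors, rng=rng)
        obs = table.stats.iloc[5]
        idx, _ = reject(obs, table, tr, 200)
        res = glm_adjust(table, idx, obs, priors, transform=tr, rng=rng)
        summ = posterior_summaries(res)
        assert summ.loc[0, "mode"] == pytest.approx(theta[5], rel=0.05)
        assert summ.loc[0, "hpd_lo"] <= theta[5] <= summ.loc[0, "hpd_hi"]

    def test_centroid_has_high_gof_pvalue(self, linear_toy, rng):
        table, priors, _ = linear_toy
        tr = fit_pls(table, priors, rng=rng)
        obs = table.stats.iloc[3]
        idx, _ = reject(obs, table, tr, 300)
        centroid = table.stats.iloc[idx].mean()
        res = glm_adjust(table, idx, centroid, priors, transform=tr, rng=rng,
                         compute_grids=False)
        assert res.p_value > 0.4

    def test_null_information_limit_returns_truncated_prior(self, linear_toy, rng):
        # statistics carrying no parameter information: the adjusted
        # posterior must collapse to the prior truncated to the retained
        # range (flat on the log scale for a log-uniform prior)
        table, priors, _ = linear_toy
        noise = pd.DataFrame(rng.normal(size=(len(table), 3)),
                             columns=["s1", "s2", "s3"])
        tab = SimulationTable(table.params, noise, "noise")
        res = glm_adjust(tab, np.arange(800), noise.iloc[0], priors, rng=rng)
        g, dens = res.grids["T"], res.densities["T"]
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(g))])
        cdf /= cdf[-1]
        for frac in (0.25, 0.5, 0.75):
            x = g[0] + frac * (g[-1] - g[0])
            assert np.interp(x, g, cdf) == pytest.approx(frac, abs=0.06)

    def test_identical_tables_equal_marginals(self, linear_toy, rng):
        table, priors, _ = linear_toy
        obs = table.stats.iloc[9]
        idx, _ = reject(obs, table, fit_pls(table, priors, rng=rng), 200)
        r1 = glm_adjust(table, idx, obs, priors, rng=np.random.default_rng(1),
                        compute_grids=False)
        r2 = glm_adjust(table, idx, obs, priors, rng=np.random.default_rng(2),
                        compute_grids=False)
        assert r1.log_marginal == pytest.approx(r2.log_marginal)

    def test_empty_retained_set(self, linear_toy, rng):
        table, priors, _ = linear_toy
        with pytest.raises(ValueError):
            glm_adjust(table, np.array([], dtype=int), table.stats.iloc[0],
                       priors, rng=rng)

    def test_posterior_cdf_monotone(self, linear_toy, rng):
        table, priors, _ = linear_toy
        tr = fit_pls(table, priors, rng=rng)
        obs = table.stats.iloc[11]
        idx, _ = reject(obs, table, tr, 200)
        res = glm_adjust(table, idx, obs, priors, transform=tr, rng=rng)
        qs = [res.cdf_at("T", v) for v in (20.0, 50.0, 200.0, 900.0)]
        assert qs == sorted(qs)
        assert all(0.0 <= q <= 1.0 for q in qs)


class _Fake:
    def __init__(self, log_marginal, p_value=0.5):
        self.log_marginal = log_marginal
        self.p_value = p_value


class TestCompareModels:
    def test_equal_densities_split_evenly(self):
        out = compare_models({"a": _Fake(0.0), "b": _Fake(0.0)})
        assert out["posterior_probability"].tolist() == pytest.approx([0.5, 0.5])
        assert out.loc[0, "BF_vs_b"] == pytest.approx(1.0)

    def test_three_to_one_density_ratio(self):
        out = compare_models({"a": _Fake(math.log(3)), "b": _Fake(0.0)})
        assert out["posterior_probability"].tolist() == pytest.approx([0.75, 0.25])

    def test_three_models(self):
        out = compare_models({"a": _Fake(0.0), "b": _Fake(0.0),
                              "c": _Fake(math.log(2))})
        assert out["posterior_probability"].tolist() == pytest.approx([0.25, 0.25, 0.5])

    def test_probabilities_sum_to_one_and_bf_antisymmetry(self, rng):
        lm = rng.normal(size=4) * 10
        out = compare_models({f"m{i}": _Fake(lm[i]) for i in range(4)})
        assert out["posterior_probability"].sum() == pytest.approx(1.0)
        for i in range(4):
            for j in range(4):
                if i != j:
                    bf_ij = out.loc[i, f"BF_vs_m{j}"]
                    bf_ji = out.loc[j, f"BF_vs_m{i}"]
                    assert bf_ij == pytest.approx(1.0 / bf_ji)

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            compare_models({"a": _Fake(0.0)})


class TestHpd:
    def test_gaussian_grid_matches_normal_quantiles(self):
        g = np.linspace(-6, 6, 4001)
        (lo, hi), = hpd_interval(g, np.exp(-g**2 / 2))
        assert lo == pytest.approx(-1.96, abs=0.01)
        assert hi == pytest.approx(1.96, abs=0.01)

    def test_uniform_grid_centres_by_tie_rule(self):
        g = np.linspace(0, 1, 2001)
        (lo, hi), = hpd_interval(g, np.ones_like(g))
        assert lo == pytest.approx(0.025, abs=0.002)
        assert hi == pytest.approx(0.975, abs=0.002)

    def test_bimodal_density_returns_interval_union(self):
        g = np.linspace(-6, 6, 4001)
        dens = np.exp(-((g - 3) ** 2) / 0.1) + np.exp(-((g + 3) ** 2) / 0.1)
        ivals = hpd_interval(g, dens, level=0.9)
        assert len(ivals) == 2


def test_estimation_scale_maps_log_uniform_params():
    priors = {"N": PriorSpec("N", "log_uniform", 1.0, 100.0),
              "P": PriorSpec("P", "uniform", 0.0, 1.0)}
    df = pd.DataFrame({"N": [math.e], "P": [0.3]})
    out = to_estimation_scale(df, priors)
    assert out["N"].iloc[0] == pytest.approx(1.0)
    assert out["P"].iloc[0] == 0.3
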