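"""DIF tables and scale-level DTF quantities (OMD, DTFR, d_DTF, IMPACT, TCC)."""

import numpy as np
import pytest

import harmonirt as h
from harmonirt.gpcm import ParamSet
from harmonirt.sampler import McmcConfig, Posterior, PriorConfig


# --- elementary arithmetic on published-style table rows ---------------------


@pytest.mark.parametrize(
    "m_f,m_r,expected",
    [(8.13, 8.56, -0.43), (5.53, 6.26, -0.73), (21.7, 21.6, 0.1), (4.0, 4.0, 0.0)],
)
def test_observed_mean_difference(m_f, m_r, expected):
    assert h.compute_omd(m_f, m_r) == pytest.approx(expected)


@pytest.mark.parametrize(
    "dtfr,sd_f,expected_2dp",
    [(-0.55, 5.02, -0.11), (0.22, 2.35, 0.09), (0.0, 3.0, 0.0)],
)
def test_effect_size(dtfr, sd_f, expected_2dp):
    assert round(h.effect_size(dtfr, sd_f), 2) == expected_2dp


def test_effect_size_requires_positive_sd():
    with pytest.raises(ValueError, match="SD_F"):
        h.effect_size(0.5, 0.0)


@pytest.mark.parametrize(
    "omd,dtfr,expected",
    [(0.1, -0.55, 0.65), (-0.73, -0.04, -0.69), (1.3, 0.0, 1.3)],
)
def test_impact_decomposition(omd, dtfr, expected):
    assert h.compute_impact(omd, dtfr) == pytest.approx(expected)


# --- observed sum-score statistics -------------------------------------------


def _scored_dataset(scores_per_person):
    """One group, 2 items; sum scores set by construction (codes 0..2)."""
    rows = []
    for s in scores_per_person:
        a = min(s, 2)
        rows.append([float(a), float(s - a)])
    return h.ResponseDataset(
        responses=np.array(rows),
        group_idx=np.zeros(len(rows), dtype=int),
        admin_mask=np.ones((1, 2), dtype=bool),
        item_labels=["q1", "q2"],
        group_labels=["A"],
    )


class TestObservedSumStats:
    def test_hand_arithmetic(self):
        stats = h.observed_sum_stats(_scored_dataset([2, 3, 4]), 0, ["q1", "q2"])
        assert stats.mean == pytest.approx(3.0)
        assert stats.sd == pytest.approx(1.0)
        assert stats.n == 3

    def test_constant_scores_have_zero_sd(self):
        stats = h.observed_sum_stats(_scored_dataset([3, 3, 3]), 0, ["q1", "q2"])
        assert stats.sd == 0.0

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(10)
        scores = rng.integers(0, 5, size=10)
        stats = h.observed_sum_stats(_scored_dataset(scores), 0, ["q1", "q2"])
        # independent oracle: plain loops
        n = len(scores)
        mean = sum(int(s) for s in scores) / n
        var = sum((int(s) - mean) ** 2 for s in scores) / (n - 1)
        assert stats.mean == pytest.approx(mean, abs=1e-12)
        assert stats.sd == pytest.approx(var**0.5, abs=1e-12)

    def test_single_person_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            h.observed_sum_stats(_scored_dataset([2]), 0, ["q1", "q2"])


# --- DTFR ---------------------------------------------------------------------


def _two_group_params(seed=0, K=5, shift_group1=0.0):
    rng = np.random.default_rng(seed)
    alpha = np.tile(np.exp(rng.normal(0, 0.25, K)), (2, 1))
    b1 = rng.normal(0, 0.8, K)
    beta = np.tile(np.stack([b1, b1 + 1.0], axis=-1), (2, 1, 1))
    beta[1] += shift_group1
    return ParamSet(alpha, beta, np.ones((2, K), dtype=bool))


class TestComputeDtfr:
    def test_identical_parameters_give_exact_zero(self):
        ps = _two_group_params()
        thetas = np.linspace(-2, 2, 50)
        assert h.compute_dtfr(thetas, ps, 0, 1, range(5)) == 0.0

    def test_higher_reference_thresholds_give_positive_dtfr(self):
        # reference thresholds shifted up => reference TCC lower => DTFR > 0
        ps = _two_group_params(shift_group1=0.5)
        thetas = np.linspace(-2, 2, 50)
        assert h.compute_dtfr(thetas, ps, 0, 1, range(5)) > 0

    def test_matches_double_loop_oracle(self):
        ps = _two_group_params(seed=7, shift_group1=0.3)
        rng = np.random.default_rng(3)
        thetas = rng.normal(0, 1, 100)
        # independent oracle: explicit per-person, per-item double loop
        total = 0.0
        for t in thetas:
            tf = sum(h.expected_item_score(t, ps.get(0, k)) for k in range(5))
            tr = sum(h.expected_item_score(t, ps.get(1, k)) for k in range(5))
            total += tf - tr
        oracle = total / len(thetas)
        assert h.compute_dtfr(thetas, ps, 0, 1, range(5)) == pytest.approx(oracle, abs=1e-10)

    def test_antisymmetric_at_fixed_theta_set(self):
        ps = _two_group_params(seed=2, shift_group1=0.4)
        thetas = np.linspace(-1.5, 2.5, 40)
        forward = h.compute_dtfr(thetas, ps, 0, 1, range(5))
        backward = h.compute_dtfr(thetas, ps, 1, 0, range(5))
        assert forward == pytest.approx(-backward, abs=1e-12)

    def test_empty_focal_group_rejected(self):
        ps = _two_group_params()
        with pytest.raises(ValueError, match="no trait values"):
            h.compute_dtfr(np.array([]), ps, 0, 1, range(5))

    def test_unshared_item_rejected(self):
        admin = np.ones((2, 5), dtype=bool)
        admin[1, 0] = False
        ps = _two_group_params()
        ps = ParamSet(ps.alpha, ps.beta, admin)
        with pytest.raises(ValueError, match="not shared"):
            h.compute_dtfr(np.zeros(3), ps, 0, 1, range(5))


# --- TCC curves and plots -------------------------------------------------------


class TestTccCurve:
    def test_symmetric_scale_passes_through_midpoint(self):
        ps = ParamSet(np.ones((1, 5)), np.zeros((1, 5, 2)), np.ones((1, 5), dtype=bool))
        grid, values = h.tcc_curve(ps, 0, range(5), -3, 3, n_points=7)
        assert values[3] == pytest.approx(5.0)  # theta = 0 at the grid center

    def test_identical_groups_coincide_pointwise(self):
        ps = _two_group_params()
        g0, v0 = h.tcc_curve(ps, 0, range(5), -3, 3)
        g1, v1 = h.tcc_curve(ps, 1, range(5), -3, 3)
        assert np.array_equal(v0, v1)

    def test_values_bounded_by_score_range(self):
        ps = _two_group_params(seed=5)
        _, values = h.tcc_curve(ps, 0, range(5), -8, 8)
        assert values.min() >= 0 and values.max() <= 10

    def test_inverted_range_rejected(self):
        ps = _two_group_params()
        with pytest.raises(ValueError, match="theta_min"):
            h.tcc_curve(ps, 0, range(5), 2, -2)
        with pytest.raises(ValueError, match="n_points"):
            h.tcc_curve(ps, 0, range(5), -2, 2, n_points=1)


class TestPlotTccComparison:
    @pytest.mark.parametrize("ts", [32, 72])
    def test_y_axis_spans_full_theoretical_range(self, ts, tmp_path):
        grid = np.linspace(-3, 3, 21)
        curves = {"F": (grid, np.linspace(1, 5, 21)), "R": (grid, np.linspace(1.1, 5.2, 21))}
        out = tmp_path / f"tcc{ts}.png"
        fig, ax = h.plot_tcc_comparison(curves, TS=ts, out_path=out)
        assert ax.get_ylim() == (0.0, float(ts))
        assert out.exists() and out.stat().st_size > 0
        import matplotlib.pyplot as plt

        plt.close(fig)

    def test_coincident_curves_overlap(self, tmp_path):
        grid = np.linspace(-3, 3, 21)
        y = np.linspace(0.5, 7.5, 21)
        fig, ax = h.plot_tcc_comparison({"F": (grid, y), "R": (grid, y.copy())}, TS=10)
        lines = ax.get_lines()
        assert np.array_equal(lines[0].get_ydata(), lines[1].get_ydata())
        import matplotlib.pyplot as plt

        plt.close(fig)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="common theta grid"):
            h.plot_tcc_comparison(
                {"F": (np.linspace(-3, 3, 21), np.zeros(21)),
                 "R": (np.linspace(-2, 3, 21), np.zeros(21))},
                TS=10,
            )


# --- DIF tables -----------------------------------------------------------------


def _posterior_from_draws(alpha, beta, admin, group_labels, item_labels):
    S = alpha.shape[0]
    J, K = admin.shape
    N = 2 * J
    draws = {
        "mu": np.zeros((1, S, J)),
        "tau": np.ones((1, S, J)),
        "alpha": alpha[None],
        "beta": beta[None],
        "xi": np.zeros((1, S, K, 3)),
        "xi0": np.zeros((1, S, 3)),
        "sigma_xi": np.tile(np.eye(3), (1, S, 1, 1)),
        "theta": np.zeros((1, S, N)),
    }
    return Posterior(
        draws=draws,
        admin_mask=admin,
        group_idx=np.repeat(np.arange(J), 2),
        group_labels=group_labels,
        item_labels=item_labels,
        C=2,
        mcmc=McmcConfig(n_burn=1, n_keep=S),
        priors=PriorConfig(),
        accept_rates={},
        constraint_residuals={},
    )


class TestDifTable:
    def test_identical_draw_streams_show_no_dif(self):
        rng = np.random.default_rng(1)
        S, K = 200, 4
        a = np.exp(rng.normal(0, 0.1, (S, 1, K)))
        b = rng.normal(0, 0.5, (S, 1, K, 2))
        alpha = np.tile(a, (1, 2, 1))
        beta = np.tile(b, (1, 2, 1, 1))
        post = _posterior_from_draws(
            alpha, beta, np.ones((2, K), dtype=bool), ["F", "R"], [f"i{k}" for k in range(K)]
        )
        table = h.dif_table(post, "F", "R")
        assert (table["diff_mean"] == 0).all()
        assert not table["flagged"].any()

    def test_unshared_items_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        S, K = 100, 3
        alpha = np.exp(rng.normal(0, 0.1, (S, 2, K)))
        beta = rng.normal(0, 0.5, (S, 2, K, 2))
        admin = np.array([[True, True, True], [True, True, False]])
        alpha[:, 1, 2] = np.nan
        beta[:, 1, 2] = np.nan
        post = _posterior_from_draws(alpha, beta, admin, ["F", "R"], ["i0", "i1", "i2"])
        with pytest.warns(UserWarning, match="i2"):
            table = h.dif_table(post, "F", "R")
        assert set(table["item"]) == {"i0", "i1"}

    def test_no_shared_items_gives_empty_table(self):
        rng = np.random.default_rng(3)
        S, K = 100, 2
        alpha = np.exp(rng.normal(0, 0.1, (S, 2, K)))
        beta = rng.normal(0, 0.5, (S, 2, K, 2))
        admin = np.array([[True, False], [False, True]])
        alpha[:, 0, 1] = alpha[:, 1, 0] = np.nan
        beta[:, 0, 1] = beta[:, 1, 0] = np.nan
        post = _posterior_from_draws(alpha, beta, admin, ["F", "R"], ["i0", "i1"])
        with pytest.warns(UserWarning):
            table = h.dif_table(post, "F", "R")
        assert table.empty

    def test_planted_threshold_shift_is_flagged(self, recovery_replicates):
        """A +0.5 first-threshold shift at n=300/group is flagged by the 95%
        interval far more often than the 5% chance rate (the simulation
        oracle puts per-replicate detection power near one half; 4+/20
        detections has probability ~3e-5 under the no-DIF null)."""
        flags = [m["dif_flagged"] for m in recovery_replicates["metrics"]]
        assert sum(flags) >= 4


# --- full DTF result ------------------------------------------------------------


class TestDtfResult:
    def test_report_row_consistency(self, nodif_replicates):
        ds, _, post = nodif_replicates["first"]
        table, results = h.dtf_report(ds, post, [(0, 1), (0, 2), (1, 2)])
        assert len(table) == 3
        res = results[0]
        assert res.TS == 2 * len(res.items)
        assert res.OMD == pytest.approx(res.M_F - res.M_R, abs=1e-12)
        assert res.d_DTF == pytest.approx(res.DTFR / res.SD_F, abs=1e-12)
        # the identity is exact by construction, for every pair
        for r in results:
            assert r.IMPACT == r.OMD - r.DTFR

    def test_short_form_pair_restricted_to_shared_items(self):
        # when one group only has a subset, comparisons use that subset
        rng = np.random.default_rng(6)
        K = 6
        admin = np.ones((2, K), dtype=bool)
        admin[1, :3] = False
        alpha = np.exp(np.linspace(-0.2, 0.2, K))
        alpha /= np.exp(np.mean(np.log(alpha)))
        b1 = np.linspace(-0.5, 0.5, K)
        beta = np.column_stack([b1, b1 + 1.0])
        beta -= beta.mean()
        cfg = h.TruthConfig(
            group_sizes=(80, 80),
            group_means=(0.0, 0.4),
            group_sds=(1.0, 1.0),
            alpha=alpha,
            beta=beta,
            admin_mask=admin,
            seed=int(rng.integers(1 << 20)),
        )
        ds, _ = h.generate(cfg, seed=4)
        post = h.fit(ds, h.McmcConfig(n_burn=50, n_keep=150, seed=1))
        res = h.dtf_result(ds, post, 0, 1)
        assert res.items == (3, 4, 5)
        assert res.TS == 6

    def test_tcc_grids_cover_observed_theta_range(self, nodif_replicates):
        ds, _, post = nodif_replicates["first"]
        res = h.dtf_result(ds, post, 0, 1)
        both = post.theta_mean[(ds.group_idx == 0) | (ds.group_idx == 1)]
        assert res.theta_grid[0] == pytest.approx(both.min())
        assert res.theta_grid[-1] == pytest.approx(both.max())
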