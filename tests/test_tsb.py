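import itertools

import numpy as np
import pytest
from scipy import stats

from clustercea import (
    BootstrapConfig,
    TrialDataError,
    bca_interval,
    bootstrap_arm_means,
    jackknife_cluster_deltas,
    shrunken_means,
    standardised_residuals,
    tsb_resample,
)


class TestShrunkenMeans:
    def test_all_observations_equal_collapse_to_grand_mean(self):
        with pytest.warns(UserWarning, match="between-cluster"):
            st_ = shrunken_means([3.0] * 6, ["A"] * 3 + ["B"] * 3)
        assert st_.c == 0.0
        assert np.allclose(st_.shrunken_means, 3.0)

    def test_zero_within_variance_keeps_raw_means(self):
        # clusters {0,0} and {2,2}: SS_W = 0 -> c = 1, means resampled as-is
        st_ = shrunken_means([0.0, 0.0, 2.0, 2.0], ["A", "A", "B", "B"])
        assert st_.c == 1.0
        assert np.allclose(sorted(st_.shrunken_means), [0.0, 2.0])
        assert st_.ss_within == 0.0

    def test_override_one_is_identity(self):
        y = [1.0, 2.0, 5.0, 9.0, 4.0]
        cl = ["A", "A", "B", "B", "B"]
        st_ = shrunken_means(y, cl, c_override=1.0)
        assert np.allclose(st_.shrunken_means, st_.cluster_means)

    def test_shrunken_means_between_cluster_mean_and_grand_mean(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, 60)
        cl = np.repeat(list("ABCDEF"), 10)
        st_ = shrunken_means(y, cl)
        assert 0.0 <= st_.c <= 1.0
        lo = np.minimum(st_.cluster_means, st_.grand_mean)
        hi = np.maximum(st_.cluster_means, st_.grand_mean)
        assert np.all(st_.shrunken_means >= lo - 1e-12)
        assert np.all(st_.shrunken_means <= hi + 1e-12)

    def test_single_cluster_rejected(self):
        with pytest.raises(TrialDataError, match="2 clusters"):
            shrunken_means([1.0, 2.0], ["A", "A"])

    def test_harmonic_mean_cluster_size(self):
        st_ = shrunken_means([0.0, 1.0, 2.0, 3.0, 4.0, 5.0],
                             ["A", "A", "A", "A", "B", "B"])
        assert st_.harmonic_size == pytest.approx(2 / (1 / 4 + 1 / 2))


class TestStandardisedResiduals:
    def test_constant_cluster_has_zero_residuals(self):
        r = standardised_residuals([2.0, 2.0, 5.0, 7.0], ["A", "A", "B", "B"])
        assert np.allclose(r[:2], 0.0)

    def test_pair_cluster_hand_computed(self):
        # cluster {1, 3}: residuals (y - 2) * sqrt(2/1) = -sqrt(2), +sqrt(2)
        r = standardised_residuals([1.0, 3.0, 0.0, 0.0], ["A", "A", "B", "B"])
        assert r[0] == pytest.approx(-np.sqrt(2))
        assert r[1] == pytest.approx(np.sqrt(2))

    def test_singleton_cluster_residual_is_zero(self):
        r = standardised_residuals([9.0, 1.0, 2.0], ["A", "B", "B"])
        assert r[0] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mean_square_equals_unbiased_within_variance(self, seed):
        """The sqrt(n/(n-1)) scaling makes mean(r^2) the unbiased variance."""
        rng = np.random.default_rng(seed)
        y = rng.normal(3, 2, 17)
        r = standardised_residuals(y, ["A"] * 17)
        assert np.mean(r ** 2) == pytest.approx(np.var(y, ddof=1))


def _two_arm_toy(seed=0, n_per_cluster=(3, 4, 5, 2, 3, 4)):
    rng = np.random.default_rng(seed)
    costs, effects, clusters, arms = [], [], [], []
    for i, n in enumerate(n_per_cluster):
        arm = "intervention" if i < 3 else "usual_care"
        for _ in range(n):
            costs.append(rng.normal(100 if arm == "intervention" else 90, 10))
            effects.append(rng.normal(0, 1))
            clusters.append(f"c{i}")
            arms.append(arm)
    return (np.array(costs), np.array(effects), np.array(clusters), np.array(arms))


class TestResampling:
    def test_degenerate_data_gives_zero_deltas(self):
        n = 12
        clusters = np.repeat(["a", "b", "c", "d"], 3)
        arms = np.repeat(["intervention", "usual_care"], 6)
        with pytest.warns(UserWarning):
            reps = tsb_resample(np.ones(n), np.ones(n), clusters, arms,
                                BootstrapConfig(R=50, seed=1))
        assert np.allclose(reps, 0.0)

    def test_identical_seed_identical_stream(self):
        costs, effects, clusters, arms = _two_arm_toy()
        cfg = BootstrapConfig(R=64, seed=11)
        a = tsb_resample(costs, effects, clusters, arms, cfg)
        b = tsb_resample(costs, effects, clusters, arms, cfg)
        assert np.array_equal(a, b)

    def test_increasing_r_preserves_prefix(self):
        """Per-replicate substreams: the first replicates are invariant to R."""
        costs, effects, clusters, arms = _two_arm_toy()
        short = tsb_resample(costs, effects, clusters, arms, BootstrapConfig(R=20, seed=3))
        long = tsb_resample(costs, effects, clusters, arms, BootstrapConfig(R=60, seed=3))
        assert np.array_equal(short, long[:20])

    def test_replicate_mean_tracks_observed_delta(self):
        costs, effects, clusters, arms = _two_arm_toy(seed=4)
        reps = tsb_resample(costs, effects, clusters, arms, BootstrapConfig(R=4000, seed=5))
        observed = (costs[arms == "intervention"].mean()
                    - costs[arms == "usual_care"].mean())
        se = reps[:, 0].std() / np.sqrt(4000)
        # centre within a few Monte-Carlo SEs plus a small shrinkage offset
        assert abs(reps[:, 0].mean() - observed) < max(5 * se, 0.05 * abs(observed))

    def test_singleton_clusters_reduce_to_cluster_bootstrap(self):
        """With one woman per cluster and c forced to 1, the TSB is an ordinary
        cluster-level bootstrap of raw values (equal in law)."""
        rng = np.random.default_rng(8)
        m = 12
        y = rng.normal(50, 12, 2 * m)
        clusters = np.array([f"c{i}" for i in range(2 * m)])
        arms = np.repeat(["intervention", "usual_care"], m)
        reps = tsb_resample(y, y, clusters, arms,
                            BootstrapConfig(R=3000, seed=9), c_override=1.0)
        direct = np.empty(3000)
        r2 = np.random.default_rng(10)
        yi, yu = y[:m], y[m:]
        for r in range(3000):
            direct[r] = (yi[r2.integers(0, m, m)].mean() - yu[r2.integers(0, m, m)].mean())
        # same law: compare moments within Monte-Carlo tolerance
        assert reps[:, 0].mean() == pytest.approx(direct.mean(), abs=4 * direct.std() / 50)
        assert reps[:, 0].std() == pytest.approx(direct.std(), rel=0.12)

    def test_support_enumeration_two_by_two(self):
        """Every synthetic value lies in the finite set {shrunken mean + residual}."""
        costs = np.array([1.0, 3.0, 10.0, 14.0, 0.0, 2.0, 20.0, 26.0])
        clusters = np.array(["a", "a", "b", "b", "u1", "u1", "u2", "u2"])
        arms = np.array(["intervention"] * 4 + ["usual_care"] * 4)
        reps = tsb_resample(costs, costs, clusters, arms, BootstrapConfig(R=400, seed=2))
        support = {}
        for arm in ("intervention", "usual_care"):
            mask = arms == arm
            st_ = shrunken_means(costs[mask], clusters[mask])
            res = standardised_residuals(costs[mask], clusters[mask])
            vals = []
            for j in range(2):  # drawn cluster j with its own residuals
                mu = st_.shrunken_means[j]
                rj = res[2 * j:2 * j + 2]
                # arm mean over 2 slots of 2 draws: enumerate all slot values
                vals.append([mu + r for r in rj])
            # possible arm means: average over 2 slots x 2 residual draws each
            arm_means = set()
            for j1, j2 in itertools.product(range(2), repeat=2):
                for picks in itertools.product(range(2), repeat=4):
                    v = (vals[j1][picks[0]] + vals[j1][picks[1]]
                         + vals[j2][picks[2]] + vals[j2][picks[3]]) / 4
                    arm_means.add(round(v, 9))
            support[arm] = arm_means
        deltas = {round(i - u, 8) for i in support["intervention"] for u in support["usual_care"]}
        for dc in reps[:, 0]:
            assert round(dc, 8) in deltas

    def test_pairing_preserves_cost_effect_correlation_sign(self):
        rng = np.random.default_rng(21)
        n = 200
        clusters = np.repeat([f"c{i}" for i in range(10)], n // 10)
        arms = np.repeat(["intervention", "usual_care"], n // 2)
        base = rng.normal(0, 1, n)
        costs = 100 + 10 * base + rng.normal(0, 5, n)
        effects = 5 + 2 * base + rng.normal(0, 1, n)   # positively coupled
        reps = tsb_resample(costs, effects, clusters, arms, BootstrapConfig(R=2000, seed=22))
        r = np.corrcoef(reps[:, 0], reps[:, 1])[0, 1]
        assert r > 0.3

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(TrialDataError, match="align"):
            tsb_resample([1.0], [1.0, 2.0], ["a"], ["intervention"], BootstrapConfig(R=1))


class TestVarianceCalibration:
    def test_tsb_se_matches_analytic_and_naive_fails(self):
        """On two-level normal data the TSB SE of an arm mean matches
        sqrt(sigma_B^2/M + sigma_W^2/(M*b)); the one-stage i.i.d. bootstrap
        underestimates it badly when the ICC is large."""
        rng = np.random.default_rng(12345)
        M, n = 10, 20
        sig_b, sig_w = 2.0, 5.0
        analytic = np.sqrt(sig_b ** 2 / M + sig_w ** 2 / (M * n))
        tsb_vars, naive_vars = [], []
        for t in range(60):
            u = rng.normal(0, sig_b, M)
            y = (u[:, None] + rng.normal(0, sig_w, (M, n))).ravel()
            cl = np.repeat(np.arange(M), n)
            means = bootstrap_arm_means(y, cl, R=400, seed=t)
            tsb_vars.append(means.var(ddof=1))
            r2 = np.random.default_rng(1000 + t)
            naive = np.array([y[r2.integers(0, y.size, y.size)].mean()
                              for _ in range(200)])
            naive_vars.append(naive.var(ddof=1))
        tsb_se = np.sqrt(np.mean(tsb_vars))
        naive_se = np.sqrt(np.mean(naive_vars))
        assert abs(tsb_se / analytic - 1.0) < 0.10
        assert naive_se / analytic < 0.8


class TestBca:
    def test_symmetric_replicates_equal_percentile(self):
        obs = 10.0
        reps = obs + np.linspace(-4, 4, 801)     # exactly symmetric about obs
        jack = np.linspace(-1, 1, 14)            # symmetric jackknife -> a = 0
        lo, hi = bca_interval(reps, obs, jack, level=0.95)
        plo, phi = np.quantile(reps, [0.025, 0.975])
        assert lo == pytest.approx(plo, abs=1e-9)
        assert hi == pytest.approx(phi, abs=1e-9)

    def test_upward_shifted_replicates_move_interval_down(self):
        obs = 0.0
        rng = np.random.default_rng(3)
        sym = rng.normal(0, 1, 4001)
        shifted = sym + 0.8                      # bootstrap distribution above observed
        jack = np.linspace(-1, 1, 14)
        lo_s, hi_s = bca_interval(shifted, obs, jack)
        plo, phi = np.quantile(shifted, [0.025, 0.975])
        # z0 < 0 pulls both endpoints to lower percentiles
        assert lo_s < plo and hi_s < phi

    def test_degenerate_replicates_collapse_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = bca_interval(np.full(100, 2.0), 2.0, np.zeros(5))
        assert (lo, hi) == (2.0, 2.0)

    def test_matches_scipy_on_iid_sample(self):
        """Independent-route check: same data, scipy's BCa machinery."""
        rng = np.random.default_rng(42)
        x = rng.gamma(2.0, 3.0, 60)
        R = 4000
        reps = np.array([x[rng.integers(0, 60, 60)].mean() for _ in range(R)])
        jack = np.array([np.delete(x, i).mean() for i in range(60)])
        lo, hi = bca_interval(reps, x.mean(), jack)
        ref = stats.bootstrap((x,), np.mean, n_resamples=R, method="BCa",
                              confidence_level=0.95,
                              random_state=np.random.default_rng(1))
        width = ref.confidence_interval.high - ref.confidence_interval.low
        assert lo == pytest.approx(ref.confidence_interval.low, abs=0.05 * width)
        assert hi == pytest.approx(ref.confidence_interval.high, abs=0.05 * width)

    def test_jackknife_needs_three_clusters(self):
        with pytest.raises(TrialDataError, match="3 clusters"):
            jackknife_cluster_deltas([1.0, 2.0], ["a", "b"],
                                     ["intervention", "usual_care"])
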