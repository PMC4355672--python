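import numpy as np
import pytest

from wrda import make_weights, summarize, top_n, w2rda, wrda
from wrda.scoring import GroupSummary
from wrda.weights import explicit_weights, make_k_schemes

from conftest import make_dataset, random_dataset


def manual_summary(mu_c, mu_m, sd_c, sd_m):
    """Build a GroupSummary directly from per-(i, j) arrays (lists of lists:
    time point -> sampling time -> per-feature values)."""
    n_tp = len(mu_c)
    p = np.array([len(x) for x in mu_c])
    F = len(np.atleast_1d(mu_c[0][0]))
    mean = np.full((2, n_tp, p.max(), F), np.nan)
    sd = np.zeros((2, n_tp, p.max(), F))
    count = np.zeros((2, n_tp, p.max()), dtype=int)
    for i in range(n_tp):
        for j in range(p[i]):
            mean[0, i, j], mean[1, i, j] = mu_c[i][j], mu_m[i][j]
            sd[0, i, j], sd[1, i, j] = sd_c[i][j], sd_m[i][j]
            count[:, i, j] = 2
    return GroupSummary(
        mean=mean, sd=sd, count=count,
        feature_ids=[f"F{k}" for k in range(F)], p_per_time_point=p,
    )


def brute_force_scores(dataset, omega_values, k_values_per_tp, epsilon):
    """Independent naive-loop reference for wRDA / w2RDA."""
    scores = np.empty(dataset.n_features)
    for f in range(dataset.n_features):
        D = S = 0.0
        for i, w in enumerate(omega_values):
            for j, kj in enumerate(k_values_per_tp[i]):
                stats = {}
                for g in ("C", "M"):
                    sel = [
                        dataset.values[s, f]
                        for s in range(dataset.n_samples)
                        if dataset.group[s] == g
                        and dataset.time_point[s] == i
                        and dataset.sampling_time[s] == j
                    ]
                    mu = sum(sel) / len(sel)
                    var = (
                        sum((x - mu) ** 2 for x in sel) / (len(sel) - 1)
                        if len(sel) > 1
                        else 0.0
                    )
                    stats[g] = (mu, var**0.5)
                D += w * kj * abs(stats["C"][0] - stats["M"][0])
                S += w * kj * (stats["C"][1] + stats["M"][1])
        scores[f] = D / (S + epsilon)
    return scores


class TestSummarize:
    def test_mean_and_sample_sd(self):
        ds = make_dataset([[2], [4], [5], [5]], ["C", "C", "C", "C"] , [0, 0, 1, 1])
        # need both groups for validity of scoring, but summarize itself works per stratum
        ds = make_dataset(
            [[2], [4], [5], [5], [1], [3], [5], [5]],
            ["C", "C", "C", "C", "M", "M", "M", "M"],
            [0, 0, 1, 1, 0, 0, 1, 1],
        )
        s = summarize(ds)
        assert s.mean[0, 0, 0, 0] == 3.0
        assert s.sd[0, 0, 0, 0] == pytest.approx(np.sqrt(2.0))
        assert s.sd[0, 1, 0, 0] == 0.0  # constant stratum

    def test_singleton_stratum_sd_zero_with_diagnostic(self):
        ds = make_dataset(
            [[7], [1], [2], [3], [4]], ["C", "M", "C", "M", "M"], [0, 0, 1, 1, 1]
        )
        s = summarize(ds)
        assert s.sd[0, 0, 0, 0] == 0.0 and s.mean[0, 0, 0, 0] == 7.0
        assert any("singleton" in d for d in s.diagnostics)


class TestWrdaClosedForm:
    def test_zero_scatter_score_is_d_over_epsilon(self):
        s = manual_summary(
            mu_c=[[[0.0]], [[0.0]]], mu_m=[[[1.0]], [[1.0]]],
            sd_c=[[[0.0]], [[0.0]]], sd_m=[[[0.0]], [[0.0]]],
        )
        t = wrda(s, explicit_weights([0.5, 0.5]), epsilon=0.005)
        assert t.D[0] == 1.0 and t.S[0] == 0.0
        assert t.score[0] == pytest.approx(200.0)

    def test_identical_groups_score_zero(self):
        s = manual_summary(
            mu_c=[[[3.0]], [[4.0]]], mu_m=[[[3.0]], [[4.0]]],
            sd_c=[[[1.0]], [[1.0]]], sd_m=[[[2.0]], [[1.0]]],
        )
        assert wrda(s, make_weights("equal", length=2)).score[0] == 0.0

    def test_weighted_hand_example(self):
        # D = 0.25*2 + 0.75*1 = 1.25; S = 0.25*2 + 0.75*2 = 2 -> 0.625 at eps->0
        s = manual_summary(
            mu_c=[[[1.0]], [[2.0]]], mu_m=[[[3.0]], [[1.0]]],
            sd_c=[[[1.0]], [[1.0]]], sd_m=[[[1.0]], [[1.0]]],
        )
        t = wrda(s, explicit_weights([0.25, 0.75]), epsilon=1e-15)
        assert t.score[0] == pytest.approx(0.625)

    def test_w2rda_sampling_time_hand_example(self):
        # N=2 (second point zero-weighted), p_0=2: D=0.5*2+0.5*4=3, S=2 -> 1.5
        mean = np.full((2, 2, 2, 1), np.nan)
        sd = np.zeros((2, 2, 2, 1))
        count = np.zeros((2, 2, 2), dtype=int)
        mean[0, 0, :, 0] = [0.0, 0.0]
        mean[1, 0, :, 0] = [2.0, 4.0]
        mean[:, 1, 0, 0] = 0.0
        sd[:, 0, :, 0] = 1.0
        count[:, 0, :] = 2
        count[:, 1, 0] = 2
        s = GroupSummary(mean=mean, sd=sd, count=count,
                         feature_ids=["F0"], p_per_time_point=np.array([2, 1]))
        omega = explicit_weights([1.0, 0.0])
        k = [explicit_weights([0.5, 0.5]), explicit_weights([1.0])]
        t = w2rda(s, omega, k, epsilon=1e-15)
        assert t.D[0] == pytest.approx(3.0) and t.S[0] == pytest.approx(2.0)
        assert t.score[0] == pytest.approx(1.5)

    def test_epsilon_must_be_positive(self, small_balanced):
        with pytest.raises(ValueError):
            wrda(summarize(small_balanced), make_weights("equal", length=2), epsilon=0.0)


class TestOracleEquivalence:
    def test_w2rda_matches_naive_loops_on_random_data(self, rng):
        for _ in range(30):
            ds = random_dataset(rng)
            N = ds.n_time_points
            p = ds.sampling_times_per_point
            omega = make_weights("exponential", q=float(rng.uniform(0, 1)), length=N)
            k = make_k_schemes("linear", float(rng.uniform(0, 1)), p)
            table = w2rda(summarize(ds), omega, k, epsilon=0.005)
            expected = brute_force_scores(ds, omega.values, [s.values for s in k], 0.005)
            np.testing.assert_allclose(table.score, expected, atol=1e-12, rtol=0)

    def test_wrda_matches_naive_loops(self, rng):
        for _ in range(10):
            ds = random_dataset(rng, p_max=1)
            omega = make_weights("proportional", q=0.4, length=ds.n_time_points)
            table = wrda(summarize(ds), omega)
            expected = brute_force_scores(
                ds, omega.values, [np.ones(1)] * ds.n_time_points, 0.005
            )
            np.testing.assert_allclose(table.score, expected, atol=1e-12, rtol=0)

    def test_w2rda_reduces_to_wrda_bit_identically(self, rng):
        for _ in range(20):
            ds = random_dataset(rng, p_max=1)
            s = summarize(ds)
            omega = make_weights("exponential", q=0.7, length=ds.n_time_points)
            ones = [explicit_weights([1.0]) for _ in range(ds.n_time_points)]
            a = wrda(s, omega)
            b = w2rda(s, omega, ones)
            np.testing.assert_array_equal(a.score, b.score)
            np.testing.assert_array_equal(a.rank, b.rank)


class TestScoreProperties:
    def test_scale_covariance_of_weights(self, rng):
        ds = random_dataset(rng)
        s = summarize(ds)
        omega = make_weights("linear", q=0.5, length=ds.n_time_points, normalize=False)
        k = make_k_schemes("equal", None, ds.sampling_times_per_point, normalize=False)
        t1 = w2rda(s, omega, k, epsilon=1e-300)
        scaled = explicit_weights(omega.values * 7.0)
        t2 = w2rda(s, scaled, k, epsilon=1e-300)
        np.testing.assert_allclose(t1.score, t2.score, rtol=1e-12)

    def test_zero_weight_time_points_inert(self, rng):
        ds = random_dataset(rng, p_max=1, n_time_points=4)
        omega = explicit_weights([0.0, 0.4, 0.6, 0.0])
        before = wrda(summarize(ds), omega).score
        perturbed = ds.values.copy()
        mask = np.isin(ds.time_point, [0, 3])
        perturbed[mask] = perturbed[mask] * 3.0 + 11.0
        ds2 = make_dataset(perturbed, ds.group, ds.time_point, ds.sampling_time)
        np.testing.assert_array_equal(wrda(summarize(ds2), omega).score, before)

    def test_increasing_mean_separation_never_decreases_score(self):
        base = manual_summary(
            mu_c=[[[0.0]], [[0.0]]], mu_m=[[[1.0]], [[1.0]]],
            sd_c=[[[1.0]], [[1.0]]], sd_m=[[[1.0]], [[1.0]]],
        )
        omega = make_weights("equal", length=2)
        s0 = wrda(base, omega).score[0]
        bigger = manual_summary(
            mu_c=[[[0.0]], [[0.0]]], mu_m=[[[2.5]], [[1.0]]],
            sd_c=[[[1.0]], [[1.0]]], sd_m=[[[1.0]], [[1.0]]],
        )
        assert wrda(bigger, omega).score[0] >= s0

    def test_scores_nonnegative_zero_iff_d_zero(self, rng):
        ds = random_dataset(rng)
        t = w2rda(
            summarize(ds),
            make_weights("equal", length=ds.n_time_points),
            make_k_schemes("equal", None, ds.sampling_times_per_point),
        )
        assert (t.score >= 0).all()
        np.testing.assert_array_equal(t.score == 0, t.D == 0)


class TestTopN:
    def test_returns_ids_in_rank_order(self):
        s = manual_summary(
            mu_c=[[[0.0, 0.0, 0.0]], [[0.0, 0.0, 0.0]]],
            mu_m=[[[3.0, 1.0, 2.0]], [[3.0, 1.0, 2.0]]],
            sd_c=[[[1.0] * 3], [[1.0] * 3]], sd_m=[[[1.0] * 3], [[1.0] * 3]],
        )
        t = wrda(s, make_weights("equal", length=2))
        assert top_n(t, 2) == ["F0", "F2"]
        assert top_n(t, 3) == ["F0", "F2", "F1"]

    def test_ties_break_by_input_order(self):
        s = manual_summary(
            mu_c=[[[0.0, 0.0]]] * 2, mu_m=[[[1.0, 1.0]]] * 2,
            sd_c=[[[1.0, 1.0]]] * 2, sd_m=[[[1.0, 1.0]]] * 2,
        )
        t = wrda(s, make_weights("equal", length=2))
        assert top_n(t, 2) == ["F0", "F1"]

    def test_n_out_of_range_rejected(self, small_balanced):
        t = wrda(summarize(small_balanced), make_weights("equal", length=2))
        for bad in (0, 3):
            with pytest.raises(ValueError):
                top_n(t, bad)
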