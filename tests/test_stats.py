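from itertools import combinations

import numpy as np
import pytest

from crypsis.receptor import QuantumCatchVector
from crypsis.stats import (
    BootstrapContrast,
    JndDistanceMatrix,
    PermanovaResult,
    bootstrap_centroid_jnd,
    discriminability_decision,
    dispersion_test,
    jnd_distance_matrix,
    permanova,
)
from crypsis.receptor import rnl_distance


def catches(fish, logs, group):
    return [
        QuantumCatchVector(fish, np.exp(l), stimulus_label=f"{group}{i}", group=group)
        for i, l in enumerate(np.atleast_2d(logs))
    ]


def random_two_group_dm(fish, noise, rng, n_a=5, n_b=5, shift=0.0, scale_b=1.0):
    la = rng.normal(0, 0.1, size=(n_a, 3))
    lb = rng.normal(0, 0.1 * scale_b, size=(n_b, 3))
    lb[:, 2] += shift  # chromatic shift: boost one receptor only
    return jnd_distance_matrix(catches(fish, la, "A") + catches(fish, lb, "B"), noise)


def brute_force_permanova_p(d, n_a):
    """From-scratch exhaustive PERMANOVA on a small distance matrix."""
    n = d.shape[0]

    def pseudo_f(group_a):
        group_a = set(group_a)
        ss_t = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
        ss_w = 0.0
        for members in (group_a, set(range(n)) - group_a):
            ss = sum(
                d[i, j] ** 2
                for i in members
                for j in members
                if i < j
            )
            ss_w += ss / len(members)
        return (ss_t - ss_w) / (ss_w / (n - 2))

    f_obs = pseudo_f(range(n_a))
    fs = [pseudo_f(c) for c in combinations(range(n), n_a)]
    return f_obs, np.mean([f >= f_obs - 1e-12 for f in fs])


class TestDistanceMatrix:
    def test_identical_samples_zero_offdiagonal(self, fish, fish_noise):
        qs = catches(fish, [[0.1, 0.2, 0.3], [0.1, 0.2, 0.3]], "A")
        dm = jnd_distance_matrix(qs, fish_noise)
        assert dm.d[0, 1] == 0.0

    def test_symmetric_and_elementwise(self, fish, fish_noise):
        rng = np.random.default_rng(0)
        qs = catches(fish, rng.normal(0, 0.3, (3, 3)), "A")
        dm = jnd_distance_matrix(qs, fish_noise)
        np.testing.assert_array_equal(dm.d, dm.d.T)
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert dm.d[i, j] == pytest.approx(
                        rnl_distance(qs[i], qs[j], fish_noise), rel=1e-12
                    )


class TestPermanova:
    def test_exact_enumeration_small_n(self, fish, fish_noise):
        rng = np.random.default_rng(21)
        dm = random_two_group_dm(fish, fish_noise, rng, n_a=3, n_b=3)
        res = permanova(dm)
        assert res.method == "exhaustive"
        assert res.n_permutations == 20
        f_oracle, p_oracle = brute_force_permanova_p(dm.d, 3)
        assert res.pseudo_F == pytest.approx(f_oracle, rel=1e-10)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)

    def test_extreme_separation_minimum_p(self, fish, fish_noise):
        rng = np.random.default_rng(4)
        dm = random_two_group_dm(fish, fish_noise, rng, n_a=10, n_b=10, shift=5.0)
        res = permanova(dm, n_perm=999, seed=0, exhaustive=False)
        assert res.p == pytest.approx(0.001)
        assert res.pseudo_F > 100

    def test_group_relabelling_invariance(self, fish, fish_noise):
        rng = np.random.default_rng(8)
        dm = random_two_group_dm(fish, fish_noise, rng, n_a=4, n_b=6, shift=0.4)
        swapped = JndDistanceMatrix(
            labels=dm.labels, groups=["X" if g == "B" else "Y" for g in dm.groups], d=dm.d
        )
        a = permanova(dm, seed=1)
        b = permanova(swapped, seed=1)
        assert a.pseudo_F == pytest.approx(b.pseudo_F, rel=1e-12)
        assert a.p == pytest.approx(b.p)

    def test_matches_skbio(self, fish, fish_noise):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(17)
        dm = random_two_group_dm(fish, fish_noise, rng, n_a=8, n_b=8, shift=0.15)
        res = permanova(dm, n_perm=999, seed=0, exhaustive=False)
        sk = sk_permanova(DistanceMatrix(dm.d), grouping=dm.groups, permutations=999)
        assert res.pseudo_F == pytest.approx(sk["test statistic"], rel=1e-9)
        assert res.p == pytest.approx(sk["p-value"], abs=0.03)

    def test_single_group_rejected(self, fish, fish_noise):
        qs = catches(fish, np.random.default_rng(0).normal(0, 0.1, (4, 3)), "A")
        dm = jnd_distance_matrix(qs, fish_noise)
        with pytest.raises(ValueError, match="2 groups"):
            permanova(dm)

    def test_low_permutation_warning(self, fish, fish_noise):
        rng = np.random.default_rng(2)
        dm = random_two_group_dm(fish, fish_noise, rng, n_a=6, n_b=6)
        with pytest.warns(UserWarning, match="coarse"):
            permanova(dm, n_perm=50, seed=0, exhaustive=False)

    def test_null_p_values_roughly_uniform(self, fish, fish_noise):
        # quick sanity on super-uniformity; the full calibrated check runs in
        # the acceptance suite
        rng = np.random.default_rng(100)
        ps = []
        for _ in range(200):
            dm = random_two_group_dm(fish, fish_noise, rng, n_a=6, n_b=6)
            ps.append(permanova(dm, n_perm=199, seed=rng, exhaustive=False).p)
        ps = np.array(ps)
        assert np.mean(ps <= 0.05) < 0.11
        assert np.mean(ps <= 0.5) == pytest.approx(0.5, abs=0.12)


class TestDispersion:
    def test_null_rejection_rate_near_alpha(self, fish, fish_noise):
        rng = np.random.default_rng(55)
        rej = 0
        n_sim = 300
        for _ in range(n_sim):
            dm = random_two_group_dm(fish, fish_noise, rng, n_a=8, n_b=8)
            rej += dispersion_test(dm, n_perm=199, seed=rng).p <= 0.05
        assert 0.02 <= rej / n_sim <= 0.09

    def test_scaled_group_detected_and_flagged(self, fish, fish_noise):
        # group B is group A's distribution scaled 5x about its centroid and
        # is the smaller group: expect small p and the type-I-error flag
        rng = np.random.default_rng(6)
        dm = random_two_group_dm(fish, fish_noise, rng, n_a=15, n_b=8, scale_b=5.0)
        res = dispersion_test(dm, n_perm=499, seed=0)
        assert res.p < 0.05
        assert res.smaller_group_more_variable

    def test_degenerate_identical_points(self, fish, fish_noise):
        qs = catches(fish, np.tile([0.1, 0.2, 0.3], (4, 1)), "A") + catches(
            fish, np.tile([0.1, 0.2, 0.3], (4, 1)), "B"
        )
        dm = jnd_distance_matrix(qs, fish_noise)
        res = dispersion_test(dm, seed=0)
        assert res.statistic == 0.0
        assert res.p == 1.0


class TestBootstrap:
    def test_identical_replicated_groups(self, fish, fish_noise):
        qs = catches(fish, np.tile([0.1, 0.2, 0.3], (5, 1)), "A")
        qs2 = catches(fish, np.tile([0.1, 0.2, 0.3], (5, 1)), "B")
        b = bootstrap_centroid_jnd(qs, qs2, fish_noise, n_boot=200, seed=0)
        assert b.mean_jnd == pytest.approx(0.0, abs=1e-12)
        assert b.ci_low == pytest.approx(0.0, abs=1e-12)
        assert b.ci_high == pytest.approx(0.0, abs=1e-12)

    def test_seed_reproducibility(self, fish, fish_noise):
        rng = np.random.default_rng(12)
        ga = catches(fish, rng.normal(0, 0.2, (10, 3)), "A")
        gb = catches(fish, rng.normal(0.3, 0.2, (10, 3)), "B")
        b1 = bootstrap_centroid_jnd(ga, gb, fish_noise, n_boot=500, seed=77)
        b2 = bootstrap_centroid_jnd(ga, gb, fish_noise, n_boot=500, seed=77)
        assert (b1.mean_jnd, b1.ci_low, b1.ci_high) == (b2.mean_jnd, b2.ci_low, b2.ci_high)

    def test_point_estimate_is_full_sample_statistic(self, fish, fish_noise):
        rng = np.random.default_rng(13)
        la = rng.normal(0, 0.2, (8, 3))
        lb = rng.normal(0.5, 0.2, (8, 3))
        ga, gb = catches(fish, la, "A"), catches(fish, lb, "B")
        b = bootstrap_centroid_jnd(ga, gb, fish_noise, n_boot=100, seed=0)
        cen_a = QuantumCatchVector(fish, np.exp(la.mean(axis=0)))
        cen_b = QuantumCatchVector(fish, np.exp(lb.mean(axis=0)))
        assert b.mean_jnd == pytest.approx(rnl_distance(cen_a, cen_b, fish_noise), rel=1e-12)

    def test_small_group_rejected(self, fish, fish_noise):
        qs = catches(fish, [[0.1, 0.2, 0.3]], "A")
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap_centroid_jnd(qs, qs, fish_noise)

    def test_quick_coverage(self, fish, fish_noise):
        # small-scale coverage check; the full 500-replicate version runs in
        # the acceptance suite
        rng = np.random.default_rng(99)
        mu_b = np.log(np.array([1.0, 2.0, 3.0]))
        mu_a = mu_b + np.array([0.0, 0.0, 0.2])
        truth = rnl_distance(
            QuantumCatchVector(fish, np.exp(mu_a)),
            QuantumCatchVector(fish, np.exp(mu_b)),
            fish_noise,
        )
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            ga = catches(fish, rng.normal(mu_a, 0.1, (20, 3)), "A")
            gb = catches(fish, rng.normal(mu_b, 0.1, (20, 3)), "B")
            b = bootstrap_centroid_jnd(ga, gb, fish_noise, n_boot=500, seed=rng)
            hits += b.ci_low <= truth <= b.ci_high
        assert 0.85 <= hits / n_rep <= 1.0


class TestDecision:
    def make(self, p, ci, mean):
        perm = PermanovaResult(pseudo_F=10.0, p=p, n_permutations=999, df=(1, 18))
        boot = BootstrapContrast(mean_jnd=mean, ci_low=ci[0], ci_high=ci[1], n_boot=1000)
        return discriminability_decision(perm, boot)

    def test_not_significant_is_camouflaged(self):
        assert self.make(0.20, (0.5, 6.0), 3.5).verdict == "camouflaged"

    def test_significant_ci_above_threshold_is_discriminable(self):
        assert self.make(0.001, (1.5, 4.0), 2.5).verdict == "discriminable"

    def test_ci_crossing_one_small_mean_is_camouflaged(self):
        assert self.make(0.001, (0.8, 2.0), 1.4).verdict == "camouflaged"

    def test_ambiguous_branch(self):
        assert self.make(0.001, (0.8, 9.0), 5.0).verdict == "ambiguous"

    def test_total_on_random_inputs(self):
        rng = np.random.default_rng(14)
        for _ in range(200):
            p = float(rng.uniform(0.001, 1.0))
            lo = float(rng.uniform(0, 4))
            hi = lo + float(rng.uniform(0, 4))
            mean = float(rng.uniform(lo, hi))
            verdict = self.make(p, (lo, hi), mean).verdict
            assert verdict in {"camouflaged", "discriminable", "ambiguous"}
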