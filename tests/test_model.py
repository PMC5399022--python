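"""Unit and property tests for the dual p-values and layer classification."""

import math

import numpy as np
import pytest
from scipy import integrate, special, stats

from abtlayers import (
    LAYER_ACTIVE,
    LAYER_INACTIVE,
    LAYER_PRACTICALLY_INSIGNIFICANT,
    LAYER_UNCERTAIN,
    AlternativeSpec,
    DecisionThresholds,
    VoxelStat,
    alt_p_value,
    classify_layers,
    critical_values,
    fdr_threshold,
    null_p_value,
)
from abtlayers.model import dual_p_values


def t_upper_tail_by_quadrature(t, df):
    """Independent oracle: upper-tail t probability by numerical integration
    of the Student-t density written from its closed form."""
    const = math.exp(
        special.gammaln((df + 1) / 2) - special.gammaln(df / 2)
    ) / math.sqrt(df * math.pi)

    def density(x):
        return const * (1 + x**2 / df) ** (-(df + 1) / 2)

    value, _ = integrate.quad(density, t, np.inf)
    return value


def normal_cdf_by_erf(z):
    """Independent oracle: standard normal CDF via the error function."""
    return 0.5 * (1 + math.erf(z / math.sqrt(2)))


class TestNullPValue:
    def test_symmetry_at_zero(self):
        for df in (1, 10, 148):
            assert null_p_value(0.0, df) == pytest.approx(0.5)

    def test_tail_limit(self):
        assert null_p_value(1e3, 148) < 1e-12

    def test_matches_quadrature_oracle(self):
        p = float(null_p_value(3.0, 148))
        assert p == pytest.approx(t_upper_tail_by_quadrature(3.0, 148),
                                  abs=1e-10)

    def test_negative_activation_uses_lower_tail(self):
        t = np.array([-2.0, 0.0, 2.0])
        np.testing.assert_allclose(
            null_p_value(t, 30, sign="neg"),
            null_p_value(-t, 30, sign="pos"),
            rtol=1e-12,
        )

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            null_p_value(1.0, 0)


class TestAltPValue:
    def test_half_at_alternative_mean(self):
        for tau in (0.0, 0.5, 2.0):
            alt = AlternativeSpec(1.5, tau)
            se = 0.7
            assert alt_p_value(1.5 / se, se, alt) == pytest.approx(0.5)

    def test_unit_variance_when_tau_zero(self):
        alt = AlternativeSpec(1.5, 0.0)
        se = 0.7
        p = float(alt_p_value(1.5 / se + 1.0, se, alt))
        assert p == pytest.approx(stats.norm.cdf(1.0), abs=1e-12)

    def test_matches_erf_oracle(self):
        alt = AlternativeSpec(1.5, 0.5)
        p = float(alt_p_value(1.0, 0.49, alt))
        expected = normal_cdf_by_erf((0.49 - 1.5) / math.sqrt(0.49**2 + 0.25))
        assert p == pytest.approx(expected, abs=1e-12)

    def test_strictly_increasing_in_t(self):
        alt = AlternativeSpec(1.5, 0.5)
        t = np.linspace(-5, 8, 200)
        p = alt_p_value(t, 0.5, alt)
        assert np.all(np.diff(p) > 0)

    def test_strictly_decreasing_in_mu(self):
        p = [
            float(alt_p_value(2.0, 0.5, AlternativeSpec(mu, 0.5)))
            for mu in np.linspace(0.2, 3.0, 30)
        ]
        assert np.all(np.diff(p) < 0)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            alt_p_value(1.0, 0.0, AlternativeSpec(1.5, 0.5))

    def test_negative_activation_mirror(self):
        """Deactivation mode is the exact mirror image of activation."""
        pos = AlternativeSpec(1.5, 0.5)
        neg = AlternativeSpec(-1.5, 0.5)
        t = np.linspace(-6, 6, 51)
        np.testing.assert_allclose(
            alt_p_value(t, 0.6, neg),
            alt_p_value(-t, 0.6, pos),
            rtol=1e-12,
        )


class TestFdrThreshold:
    def test_nothing_rejectable(self):
        assert fdr_threshold(np.ones(50), 0.05) == 0.0

    def test_single_voxel_reduces_to_plain_level(self):
        assert fdr_threshold([0.03], 0.05) == pytest.approx(0.03)
        assert fdr_threshold([0.06], 0.05) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=40) ** 2
        q = 0.1
        # brute force: largest k with p_(k) <= k q / m
        ps = np.sort(p)
        m = len(ps)
        k_star = 0
        for k in range(1, m + 1):
            if ps[k - 1] <= k * q / m:
                k_star = k
        thr = fdr_threshold(p, q)
        expected_rejections = set(np.nonzero(p <= ps[k_star - 1])[0]) if k_star else set()
        assert set(np.nonzero(p <= thr)[0]) == expected_rejections

    def test_spec_example_rejection_set(self):
        p = np.array([0.001, 0.01, 0.02, 0.2])
        # step-up oracle: 0.001<=q/4, 0.01<=2q/4, 0.02<=3q/4, 0.2>q
        thr = fdr_threshold(p, 0.05)
        assert set(np.nonzero(p <= thr)[0]) == {0, 1, 2}

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_statsmodels(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(100 + seed)
        p = np.concatenate([rng.uniform(size=200),
                            rng.uniform(size=20) * 1e-3])
        thr = fdr_threshold(p, 0.05)
        rejected, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(p <= thr, rejected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fdr_threshold([], 0.05)


THR = DecisionThresholds(alpha=0.001, beta=0.2, null_mode="uncorrected")


class TestClassifyLayers:
    @pytest.mark.parametrize(
        "p0, p1, expected",
        [
            (0.0005, 0.4, LAYER_ACTIVE),
            (0.5, 0.01, LAYER_INACTIVE),
            (0.5, 0.5, LAYER_UNCERTAIN),
            (0.0005, 0.01, LAYER_PRACTICALLY_INSIGNIFICANT),
        ],
    )
    def test_quadrants(self, p0, p1, expected):
        layers = classify_layers(
            np.full((1, 1, 1), p0), np.full((1, 1, 1), p1), THR,
            np.ones((1, 1, 1), bool))
        assert layers.labels[0, 0, 0] == expected

    def test_boundary_ties_resolve_to_non_rejection(self):
        # p0 == alpha -> H0 not rejected; p1 == beta -> H1 not rejected
        layers = classify_layers(
            np.full((1, 1, 1), THR.alpha), np.full((1, 1, 1), THR.beta),
            THR, np.ones((1, 1, 1), bool))
        assert layers.labels[0, 0, 0] == LAYER_UNCERTAIN

    def test_partition_of_mask(self, rng):
        p0 = rng.uniform(size=(8, 8, 4))
        p1 = rng.uniform(size=(8, 8, 4))
        mask = rng.uniform(size=(8, 8, 4)) > 0.3
        layers = classify_layers(p0, p1, THR, mask)
        counts = layers.counts()
        assert sum(counts.values()) == int(mask.sum())
        assert np.all(layers.labels[~mask] == 0)
        assert np.all(layers.labels[mask] > 0)

    def test_fdr_mode_reproduces_bh_rejections(self, rng):
        p0 = rng.uniform(size=(10, 10, 2)) ** 3
        p1 = rng.uniform(size=(10, 10, 2))
        mask = np.ones((10, 10, 2), bool)
        thr = DecisionThresholds(beta=0.2, null_mode="fdr", q=0.05)
        layers = classify_layers(p0, p1, thr, mask)
        cut = fdr_threshold(p0[mask], 0.05)
        sig = (layers.labels == LAYER_ACTIVE) | (
            layers.labels == LAYER_PRACTICALLY_INSIGNIFICANT)
        np.testing.assert_array_equal(sig, p0 <= cut)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            classify_layers(np.ones((2, 2, 2)), np.ones((2, 2, 1)), THR,
                            np.ones((2, 2, 2), bool))

    def test_beta_monotonicity_on_fixed_maps(self, rng):
        """Raising beta can only shrink the active and grow the inactive
        layer on a fixed map."""
        p0 = rng.uniform(size=(12, 12, 4))
        p1 = rng.uniform(size=(12, 12, 4))
        mask = np.ones((12, 12, 4), bool)
        previous_active = None
        previous_inactive = None
        for beta in (0.1, 0.2, 0.3, 0.5):
            thr = DecisionThresholds(alpha=0.05, beta=beta,
                                     null_mode="uncorrected")
            c = classify_layers(p0, p1, thr, mask).counts()
            if previous_active is not None:
                assert c["active"] <= previous_active
                assert c["inactive"] >= previous_inactive
            previous_active, previous_inactive = c["active"], c["inactive"]

    def test_alpha_monotonicity_on_fixed_maps(self, rng):
        """Raising alpha can only grow the NHST-significant union
        (active + practically insignificant)."""
        p0 = rng.uniform(size=(12, 12, 4))
        p1 = rng.uniform(size=(12, 12, 4))
        mask = np.ones((12, 12, 4), bool)
        previous = None
        for alpha in (0.001, 0.01, 0.05, 0.2):
            thr = DecisionThresholds(alpha=alpha, beta=0.2,
                                     null_mode="uncorrected")
            c = classify_layers(p0, p1, thr, mask).counts()
            union = c["active"] + c["practically_insignificant"]
            if previous is not None:
                assert union >= previous
            previous = union


class TestCriticalValues:
    ALT = AlternativeSpec(1.5, 0.5)

    def test_t_beta_below_alternative_mean_for_small_beta(self):
        se = np.array([0.3, 0.5, 1.0])
        thr = DecisionThresholds(alpha=0.05, beta=0.1,
                                 null_mode="uncorrected")
        _, t_beta, _ = critical_values(se, 48, self.ALT, thr)
        assert np.all(t_beta < self.ALT.mu_delta1 / se)

    def test_t_beta_decreasing_in_se_for_large_se(self):
        thr = DecisionThresholds(alpha=0.05, beta=0.2,
                                 null_mode="uncorrected")
        se = np.linspace(0.1, 5.0, 200)
        _, t_beta, _ = critical_values(se, 148, self.ALT, thr)
        # once the mean term dominates, t_beta falls monotonically in se
        tail = t_beta[se > 0.5]
        assert np.all(np.diff(tail) < 0)

    def test_classification_equals_t_scale_double_comparison(self, rng):
        """Quadrant rule on (p0, p1) and direct thresholding of t against
        (t_alpha, t_beta) agree exactly, voxel by voxel."""
        n = 10_000
        se = rng.uniform(0.1, 2.0, size=n)
        t = rng.normal(scale=3.0, size=n)
        df = 48
        thr = DecisionThresholds(alpha=0.01, beta=0.2,
                                 null_mode="uncorrected")
        shape = (n, 1, 1)
        mask = np.ones(shape, bool)
        p0, p1 = dual_p_values(t.reshape(shape), se.reshape(shape), df,
                               mask, self.ALT)
        labels = classify_layers(p0, p1, thr, mask).labels.ravel()

        t_alpha, t_beta, _ = critical_values(se, df, self.ALT, thr)
        sig0 = t > t_alpha
        rej1 = t < t_beta
        expected = np.where(
            sig0 & ~rej1, LAYER_ACTIVE,
            np.where(~sig0 & rej1, LAYER_INACTIVE,
                     np.where(~sig0 & ~rej1, LAYER_UNCERTAIN,
                              LAYER_PRACTICALLY_INSIGNIFICANT)))
        np.testing.assert_array_equal(labels, expected)

    def test_middle_layers_mutually_exclusive_per_voxel(self, rng):
        """A voxel can only ever fall in one of the two middle layers,
        determined by the sign of t_alpha - t_beta."""
        n = 10_000
        se = rng.uniform(0.05, 3.0, size=n)
        t = rng.normal(scale=3.0, size=n)
        thr = DecisionThresholds(alpha=0.01, beta=0.2,
                                 null_mode="uncorrected")
        shape = (n, 1, 1)
        mask = np.ones(shape, bool)
        p0, p1 = dual_p_values(t.reshape(shape), se.reshape(shape), 48,
                               mask, self.ALT)
        labels = classify_layers(p0, p1, thr, mask).labels.ravel()
        t_alpha, t_beta, feasible = critical_values(se, 48, self.ALT, thr)
        assert np.all(t_alpha[labels == LAYER_UNCERTAIN]
                      > t_beta[labels == LAYER_UNCERTAIN])
        assert np.all(t_alpha[labels == LAYER_PRACTICALLY_INSIGNIFICANT]
                      < t_beta[labels == LAYER_PRACTICALLY_INSIGNIFICANT])
        middle = np.isin(labels, (LAYER_UNCERTAIN,
                                  LAYER_PRACTICALLY_INSIGNIFICANT))
        np.testing.assert_array_equal(labels[middle], feasible[middle])

    def test_requires_uncorrected_mode(self):
        thr = DecisionThresholds(beta=0.2, null_mode="fdr", q=0.05)
        with pytest.raises(ValueError):
            critical_values(np.array([0.5]), 48, self.ALT, thr)


def test_false_positive_calibration_under_null(rng):
    """Under the null, the fraction of voxels with p0 < alpha stays within
    a 99% binomial interval of alpha."""
    n, df, alpha = 20_000, 48, 0.05
    t = rng.standard_t(df, size=n)
    p0 = null_p_value(t, df)
    observed = int(np.count_nonzero(p0 < alpha))
    lo, hi = stats.binom.interval(0.99, n, alpha)
    assert lo <= observed <= hi


def test_voxelstat_validation():
    stat = VoxelStat(delta_hat=1.0, se=0.5, df=48)
    assert stat.t == pytest.approx(2.0)
    with pytest.raises(ValueError):
        VoxelStat(delta_hat=1.0, se=0.0, df=48)
    with pytest.raises(ValueError):
        VoxelStat(delta_hat=1.0, se=0.5, df=0)


def test_alternative_spec_validation():
    with pytest.raises(ValueError):
        AlternativeSpec(0.0, 0.5)
    with pytest.raises(ValueError):
        AlternativeSpec(1.5, -0.1)
    assert AlternativeSpec(-1.5, 0.5).sign == "neg"


def test_decision_thresholds_validation():
    with pytest.raises(ValueError):
        DecisionThresholds(alpha=0.05, beta=1.5, null_mode="uncorrected")
    with pytest.raises(ValueError):
        DecisionThresholds(beta=0.2, null_mode="uncorrected")  # no alpha
    with pytest.raises(ValueError):
        DecisionThresholds(beta=0.2, null_mode="fdr")  # no q
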