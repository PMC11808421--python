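import numpy as np
import pytest
from scipy import stats as sps

from colocpcc import (
    ChannelPair,
    Criterion,
    DegenerateSelectionError,
    InvalidInputError,
    SpotPairSpec,
    ThresholdPair,
    compute_pcc,
    hedges_g,
    make_spot_pair,
    one_sample_t,
    rotation_null,
    scramble_null,
    two_sample_t,
)


class TestHedgesG:
    def test_equal_means_give_zero(self):
        res = hedges_g([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.g == 0.0

    def test_hand_derived_value(self):
        # mean diff -1, pooled sd 1, J = 1 - 3/15 = 0.8
        res = hedges_g([1, 2, 3], [2, 3, 4])
        assert res.g == pytest.approx(-0.8, abs=1e-12)
        assert res.pooled_sd == pytest.approx(1.0)
        assert res.correction == pytest.approx(0.8)

    def test_antisymmetry(self):
        a, b = [0.1, 0.4, 0.3], [0.2, 0.6, 0.5]
        assert hedges_g(a, b).g == pytest.approx(-hedges_g(b, a).g, abs=1e-14)

    @pytest.mark.parametrize("seed", range(5))
    def test_magnitude_below_cohens_d(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 12)
        res = hedges_g(a, b)
        cohens_d = (a.mean() - b.mean()) / res.pooled_sd
        assert abs(res.g) < abs(cohens_d)

    def test_zero_pooled_variance_raises(self):
        with pytest.raises(DegenerateSelectionError):
            hedges_g([1.0, 1.0], [1.0, 1.0])


class TestTTests:
    def test_one_sample_null_case(self):
        res = one_sample_t([1.0, 2.0, 3.0], hypothesised_mean=2.0)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_one_sample_hand_value(self):
        res = one_sample_t([0.1, 0.2, 0.3], hypothesised_mean=0.0)
        assert res.statistic == pytest.approx(0.2 / (0.1 / np.sqrt(3)), abs=1e-10)
        assert res.df == 2

    def test_one_sample_location_invariance(self):
        a = one_sample_t([0.1, 0.5, 0.2], 0.3)
        b = one_sample_t([10.1, 10.5, 10.2], 10.3)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-9)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-9)

    def test_two_sample_identical_samples(self):
        res = two_sample_t([1.0, 2.0], [1.0, 2.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_two_sample_hand_value(self):
        res = two_sample_t([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1 / np.sqrt(2 / 3), abs=1e-12)
        assert res.df == 4

    def test_two_sample_swap_negates_statistic(self):
        a, b = [0.3, 0.5, 0.9], [0.1, 0.2, 0.6]
        r1, r2 = two_sample_t(a, b), two_sample_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-14)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-14)

    @pytest.mark.parametrize("seed", range(25))
    def test_p_values_agree_with_scipy_tests(self, seed):
        """Cross-check the hand-built statistics against scipy's test APIs."""
        rng = np.random.default_rng(seed)
        x = rng.normal(0.2, 1, rng.integers(3, 12))
        y = rng.normal(0.0, 1, rng.integers(3, 12))
        mine = one_sample_t(x, 0.0)
        ref = sps.ttest_1samp(x, 0.0)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-8)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-8)
        mine2 = two_sample_t(x, y)
        ref2 = sps.ttest_ind(x, y, equal_var=True)
        assert mine2.statistic == pytest.approx(ref2.statistic, abs=1e-8)
        assert mine2.p_value == pytest.approx(ref2.pvalue, abs=1e-8)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateSelectionError):
            one_sample_t([2.0, 2.0, 2.0], 0.0)


def _noise_pair(rng, shape=(64, 64)):
    return ChannelPair(
        green=rng.uniform(0, 1, shape), red=rng.uniform(0, 1, shape)
    )


class TestRotationNull:
    def test_rotating_both_channels_is_pure_relabelling(self):
        rng = np.random.default_rng(0)
        pairs = [_noise_pair(rng) for _ in range(3)]
        thr = ThresholdPair(0.5, 0.5)
        originals = [compute_pcc(p, thr, Criterion.OR).value for p in pairs]
        null = rotation_null(pairs, Criterion.OR, thresholding=thr, rotate_both=True)
        assert np.allclose(null.values, originals, atol=1e-14)

    def test_independent_noise_null_mean_near_zero(self):
        rng = np.random.default_rng(123)
        pairs = [_noise_pair(rng, (32, 32)) for _ in range(100)]
        null = rotation_null(pairs, Criterion.ALL)
        se = null.values.std(ddof=1) / np.sqrt(len(null.values))
        assert abs(null.values.mean()) < 3 * se + 1e-12

    def test_rotation_destroys_spot_coincidence(self):
        # coincident spot off-centre: rotation moves the green copy away
        spec = SpotPairSpec(
            n_spots_per_channel=2, n_coincident=1,
            green_centres=((300, 700), (150, 150)),
            red_centres=((300, 700), (850, 850)),
        )
        pair = make_spot_pair(spec)
        null = rotation_null([pair], Criterion.AND)
        v = null.values[0]
        assert np.isnan(v) or v < 1.0

    def test_nonsquare_images_are_cropped(self):
        rng = np.random.default_rng(1)
        pair = ChannelPair(green=rng.uniform(0, 1, (20, 30)),
                           red=rng.uniform(0, 1, (20, 30)))
        null = rotation_null([pair], Criterion.ALL)
        assert np.isfinite(null.values[0])


class TestScrambleNull:
    def test_whole_image_block_is_identity(self, random_pair_factory):
        pair = random_pair_factory(3)
        thr = ThresholdPair(0, 0)
        observed = compute_pcc(pair, thr, Criterion.ALL).value
        null = scramble_null(pair, 5, block_size=16, seed=0,
                             criterion=Criterion.ALL, thresholding=thr)
        assert np.allclose(null.values, observed, atol=1e-14)

    def test_pixel_scramble_destroys_self_correlation(self):
        rng = np.random.default_rng(7)
        img = rng.uniform(0, 1, (32, 32))
        pair = ChannelPair(green=img, red=img)
        thr = ThresholdPair(0, 0)
        null = scramble_null(pair, 200, block_size=1, seed=11,
                             criterion=Criterion.ALL, thresholding=thr)
        observed = compute_pcc(pair, thr, Criterion.ALL).value
        assert observed == pytest.approx(1.0)
        assert abs(np.nanmean(null.values)) < 0.05
        assert observed > np.nanpercentile(null.values, 99)

    def test_fixed_seed_is_deterministic(self, random_pair_factory):
        pair = random_pair_factory(4)
        kwargs = dict(n_replicates=20, block_size=4, seed=42,
                      criterion=Criterion.ALL, thresholding=ThresholdPair(0, 0))
        a = scramble_null(pair, **kwargs)
        b = scramble_null(pair, **kwargs)
        assert np.array_equal(a.values, b.values)

    def test_invalid_arguments_rejected(self, random_pair_factory):
        pair = random_pair_factory(5)
        with pytest.raises(InvalidInputError):
            scramble_null(pair, 0, block_size=1, seed=0)
        with pytest.raises(InvalidInputError):
            scramble_null(pair, 5, block_size=3, seed=0)  # 3 does not divide 16
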