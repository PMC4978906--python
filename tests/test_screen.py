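"""Plate normalization, LGR, z scores, retest selection and hit calling."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spiscreen.screen import (
    NormalizationError,
    ScreenParams,
    call_hits,
    colony_size_percent,
    combine_controls,
    compute_lgr,
    normalize_plate,
    normalize_screen,
    score_screen,
    select_retest,
    strain_mean,
    zscore,
)
from spiscreen.synthetic import ScreenSimConfig, generate_screen, lognormal_factors


class TestNormalizePlate:
    @pytest.mark.parametrize(
        "sizes,expected",
        [
            ([1, 2, 3], [0.5, 1.0, 1.5]),
            ([7, 7, 7, 7], [1, 1, 1, 1]),
            ([2, 4, 6, 8], [0.4, 0.8, 1.2, 1.6]),  # even count: median = 5
        ],
    )
    def test_examples(self, sizes, expected):
        assert np.allclose(normalize_plate(sizes), expected)

    def test_all_zero_plate_raises(self):
        with pytest.raises(NormalizationError):
            normalize_plate([0.0, 0.0, 0.0])

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(
            st.floats(min_value=1e-3, max_value=1e4, allow_nan=False),
            min_size=2,
            max_size=40,
        )
    )
    def test_median_exactly_one(self, sizes):
        assert np.median(normalize_plate(sizes)) == 1.0

    def test_power_of_two_rescaling_is_bit_exact(self):
        rng = np.random.default_rng(0)
        sizes = rng.lognormal(4.0, 0.3, 1536)
        base = normalize_plate(sizes)
        for c in (0.5, 2.0, 1024.0, 2.0**-20):
            assert (normalize_plate(sizes * c) == base).all()

    def test_arbitrary_rescaling_matches_to_float_precision(self):
        rng = np.random.default_rng(1)
        sizes = rng.lognormal(4.0, 0.3, 1536)
        base = normalize_plate(sizes)
        for c in (0.3217, 7.77, 123.456):
            assert np.allclose(normalize_plate(sizes * c), base, rtol=1e-12, atol=0)

    def test_nan_propagates_without_breaking_median(self):
        out = normalize_plate([1.0, 2.0, 3.0, np.nan])
        assert np.isnan(out[3]) and np.nanmedian(out) == 1.0


class TestStrainMeanAndControls:
    def test_examples(self):
        assert strain_mean([1, 1, 1, 1]) == 1.0
        assert strain_mean([0.5, 1.5], min_replicates=2) == 1.0

    def test_too_few_replicates_flags_missing(self):
        assert math.isnan(strain_mean([1.0, np.nan, np.nan], min_replicates=2))

    def test_null_mean_within_lognormal_three_sigma_band(self):
        # 16 draws at cv 0.2: SE of the mean is 0.05, so +-0.16 is > 3 sigma
        draws = lognormal_factors(np.random.default_rng(21), 0.2, 16)
        assert abs(draws.mean() - 1.0) <= 0.16

    @pytest.mark.parametrize(
        "means,expected", [([1.0, 1.0], 1.0), ([0.8, 1.2], 1.0), ([0.9], 0.9)]
    )
    def test_combine_controls(self, means, expected):
        assert combine_controls(means) == pytest.approx(expected)

    def test_combine_controls_requires_a_control(self):
        with pytest.raises(ValueError):
            combine_controls([float("nan")])


class TestComputeLgr:
    def test_calibration_37_percent(self):
        # an LGR of ~1 corresponds to an experimental colony 37 % of control
        _, lgr = compute_lgr(1.0, 0.37)
        assert lgr == pytest.approx(0.9943, abs=1e-4)
        assert round(colony_size_percent(1.0)) == 37

    def test_calibration_67_percent(self):
        _, lgr = compute_lgr(1.0, 0.67)
        assert lgr == pytest.approx(0.4005, abs=1e-4)
        assert round(colony_size_percent(0.4)) == 67

    @pytest.mark.parametrize("c", [0.2, 1.0, 57.3])
    def test_equal_sizes_give_zero(self, c):
        growth_ratio, lgr = compute_lgr(c, c)
        assert growth_ratio == 1.0 and lgr == 0.0

    @settings(deadline=None, max_examples=100)
    @given(
        st.floats(min_value=1e-3, max_value=1e3),
        st.floats(min_value=1e-3, max_value=1e3),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_antisymmetry_and_additivity(self, a, b, c):
        assert compute_lgr(a, b)[1] == pytest.approx(-compute_lgr(b, a)[1], abs=1e-12)
        assert compute_lgr(a, b)[1] + compute_lgr(b, c)[1] == pytest.approx(
            compute_lgr(a, c)[1], abs=1e-9
        )

    def test_nonpositive_control_raises(self):
        with pytest.raises(ValueError):
            compute_lgr(0.0, 1.0)

    def test_zero_experimental_floored_not_infinite(self):
        _, lgr = compute_lgr(1.0, 0.0, ScreenParams())
        assert lgr == pytest.approx(math.log(1 / 0.01))


class TestZscore:
    def test_hand_computed_example(self):
        # mean 0.1, sample sd 0.2
        assert np.allclose(zscore([0, 0, 0, 0.4]), [-0.5, -0.5, -0.5, 1.5])

    def test_matches_scipy_standard_scores(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        lgrs = rng.normal(0, 0.1, 200)
        assert np.allclose(zscore(lgrs), stats.zscore(lgrs, ddof=1))

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        lgrs = rng.normal(0, 0.1, 50)
        assert np.allclose(zscore(2.5 * lgrs + 0.3), zscore(lgrs))

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            zscore([0.2, 0.2, 0.2])


class TestRetestAndHits:
    def test_select_all_is_identity_ordering(self):
        import pandas as pd

        res = pd.DataFrame({"strain": list("abc"), "lgr": [0.1, 0.5, 0.3], "z": [2.0, 1.0, 0.0]})
        assert select_retest(res, ScreenParams(retest_n=3)) == ["a", "b", "c"]

    def test_top_one(self):
        import pandas as pd

        res = pd.DataFrame({"strain": list("abc"), "lgr": [0.1, 0.5, 0.3], "z": [2.0, 1.0, 0.0]})
        assert select_retest(res, ScreenParams(retest_n=1)) == ["a"]

    def test_retest_n_beyond_population_warns_and_returns_all(self):
        import pandas as pd

        res = pd.DataFrame({"strain": list("ab"), "lgr": [0.1, 0.5], "z": [1.0, -1.0]})
        with pytest.warns(UserWarning):
            assert len(select_retest(res, ScreenParams(retest_n=10))) == 2

    def test_planted_hits_all_selected(self, planted_screen):
        cfg, _, tables, truth = planted_screen
        params = ScreenParams(retest_n=50)
        results = score_screen(tables, cfg.experimental, params)
        top = set(select_retest(results, params))
        planted = {s for s, l in truth.true_lgr.items() if l > 0}
        assert planted <= top

    def test_call_hits_threshold_and_boundary(self):
        import pandas as pd

        res = pd.DataFrame({"strain": ["A", "B", "C"], "lgr": [0.5, 0.3, 0.4]})
        assert call_hits(res, ScreenParams()) == {"A"}  # 0.4 exactly is NOT a hit

    def test_noiseless_round_trip_recovers_exact_hit_set(self, small_noiseless_config):
        cfg = dataclasses.replace(
            small_noiseless_config, hit_lgr={"strain-0002": 1.0, "strain-0009": 1.0}
        )
        _, tables, truth = generate_screen(cfg)
        res = score_screen(tables, cfg.experimental, ScreenParams(), with_z=False)
        assert call_hits(res, ScreenParams()) == {"strain-0002", "strain-0009"}
        # and the recovered LGR equals the planted LGR to floating tolerance
        res = res.set_index("strain")
        for s in ("strain-0002", "strain-0009"):
            assert res.loc[s, "lgr"] == pytest.approx(1.0, abs=1e-12)


class TestScoreScreen:
    def test_plate_effects_cancel_after_normalization(self, small_noiseless_config):
        cfg = dataclasses.replace(
            small_noiseless_config, plate_effect_cv=0.5, hit_lgr={"strain-0001": 0.7}, seed=3
        )
        _, tables, _ = generate_screen(cfg)
        res = score_screen(tables, cfg.experimental, with_z=False).set_index("strain")
        assert res.loc["strain-0001", "lgr"] == pytest.approx(0.7, abs=1e-12)

    def test_recovery_within_pm_015_at_16_reps(self):
        # fixed-seed Monte-Carlo check: SE of a 16-replicate lognormal mean at
        # cv 0.2 is ~0.05, so all planted LGRs land within +-0.15 of truth
        hits = {f"strain-{i:04d}": 1.0 for i in range(1, 11)}
        cfg = ScreenSimConfig(
            n_strains=100, replicates_per_strain=16, colony_noise_cv=0.2,
            plate_effect_cv=0.0, hit_lgr=hits, seed=0,
        )
        _, tables, _ = generate_screen(cfg)
        res = score_screen(tables, cfg.experimental, with_z=False).set_index("strain")
        for s in hits:
            assert abs(res.loc[s, "lgr"] - 1.0) <= 0.15

    def test_normalized_screen_every_plate_median_one(self, planted_screen):
        cfg, _, tables, _ = planted_screen
        import pandas as pd

        normed = normalize_screen(pd.concat(tables.values(), ignore_index=True))
        for _, grp in normed.groupby(["plasmid", "plate"]):
            assert np.median(grp["size_norm"]) == 1.0
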