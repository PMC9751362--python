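"""Synthetic stream/panel generator: determinism, generative-model checks,
and stream-path vs fast-path distributional agreement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from touchdid import (
    SimulationConfig,
    build_groups,
    default_lexicon,
    generate_panel,
    generate_stream,
    read_stream,
    simulate_monthly_cells,
    write_stream,
)
from touchdid.config import validate_config
from touchdid.errors import ConfigurationError
from touchdid.filtering import dedupe_exact, drop_url_records
from touchdid.proportion import stream_monthly_samples

from conftest import calibration_config


def flat_config(seed, **kw):
    base = dict(seed=seed, trend=0.0, seasonal_factors=[1.0] * 12)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_invalid_fields_name_the_field(self):
        with pytest.raises(ConfigurationError, match="seasonal_factors"):
            validate_config({"seasonal_factors": [1.0] * 11})
        with pytest.raises(ConfigurationError, match="marker_prevalence"):
            validate_config({"marker_prevalence": 1.5})
        with pytest.raises(ConfigurationError, match="target_distribution_pre"):
            validate_config({"target_distribution_pre": {"cat": 0.5, "dog": 0.6}})

    def test_seasonal_factors_geometric_mean_one(self):
        cfg = SimulationConfig()
        assert np.isclose(np.prod(cfg.seasonal_factors), 1.0, atol=1e-12)

    def test_wave_calendar(self):
        cfg = SimulationConfig()
        assert cfg.wave_of(pd.Period("2020-02")) == 1
        assert cfg.wave_of(pd.Period("2020-06")) == 1
        assert cfg.wave_of(pd.Period("2020-07")) == 2
        assert cfg.wave_of(pd.Period("2020-11")) == 2
        assert cfg.wave_of(pd.Period("2020-12")) == 3
        assert cfg.wave_of(pd.Period("2021-01")) == 3
        assert cfg.wave_of(pd.Period("2020-01")) is None
        assert cfg.wave_of(pd.Period("2021-02")) is None


class TestStream:
    def test_zero_volume_empty_stream(self):
        st = generate_stream(flat_config(0, base_volume=0.0, n_months=3))
        assert st.empty

    def test_deterministic_given_seed(self):
        cfg = flat_config(7, base_volume=2000, n_months=2)
        a, b = generate_stream(cfg), generate_stream(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_timestamps_within_range_and_attitude_invariant(self):
        cfg = flat_config(3, base_volume=5000, n_months=4)
        st = generate_stream(cfg)
        months = pd.PeriodIndex(st["timestamp"], freq="M")
        assert months.min() >= cfg.months.min() and months.max() <= cfg.months.max()
        none_rows = st[st["attitude"] == "none"]
        assert none_rows["target_word"].isna().all()

    def test_jsonl_round_trip(self, tmp_path):
        cfg = flat_config(5, base_volume=1500, n_months=1)
        st = generate_stream(cfg)
        p = tmp_path / "stream.jsonl"
        write_stream(st, p)
        back = read_stream(p)
        pd.testing.assert_frame_equal(back, st)

    def test_monthly_counts_stationary_without_trend_or_effects(self):
        """With all effects 1 and zero trend, monthly attitude counts are
        i.i.d. Poisson: a dispersion chi-square test rejects at alpha=0.01
        at roughly its nominal rate over 50 seeds."""
        rejections = 0
        for seed in range(50):
            cfg = flat_config(seed, base_volume=10_000, n_months=12,
                              start_month="2015-01")
            st = generate_stream(cfg)
            counts = (
                st[st["attitude"] != "none"]
                .groupby(pd.PeriodIndex(st.loc[st["attitude"] != "none", "timestamp"], freq="M"))
                .size()
                .to_numpy()
            )
            stat = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
            p = stats.chi2.sf(stat, df=len(counts) - 1)
            rejections += p < 0.01
        assert rejections <= 3  # Binom(50, 0.01) above 3 has probability ~2e-3

    def test_overall_effect_scales_attitude_rate(self):
        """effect_overall=1.3: post/pre ratio of the per-record attitude
        rate recovers 1.3 within 2% averaged over 100 seeds."""
        ratios = []
        for seed in range(100):
            cfg = flat_config(seed, base_volume=10_000, n_months=18,
                              start_month="2019-08", effect_overall=1.3)
            st = generate_stream(cfg)
            is_att = st["attitude"] != "none"
            post = st["timestamp"] >= pd.Timestamp("2020-02-01")
            rate_post = is_att[post].mean()
            rate_pre = is_att[~post].mean()
            ratios.append(rate_post / rate_pre)
        assert abs(np.mean(ratios) - 1.3) < 0.02 * 1.3


class TestPanel:
    def test_shape_378_rows_per_dataset(self):
        panel = generate_panel(calibration_config(0))
        for att in ("desire", "avoidance"):
            for anim in ("animate", "inanimate"):
                sub = panel[(panel.attitude == att) & (panel.animacy == anim)]
                assert len(sub) == 378  # 7 groups x 18 months x 3 samples

    def test_byte_identical_given_seed(self):
        a = generate_panel(calibration_config(11)).to_csv(index=False)
        b = generate_panel(calibration_config(11)).to_csv(index=False)
        assert a == b

    def test_no_treatment_symmetry(self):
        """All effects 1, no trend: group mean proportions agree up to
        sampling noise (spread far below any injected-effect scale)."""
        panel = generate_panel(calibration_config(13))
        sub = panel[(panel.attitude == "desire") & (panel.animacy == "animate")]
        gm = sub.groupby("group_id")["proportion"].mean()
        assert gm.std() / gm.mean() < 0.05

    def test_negative_binomial_switch_runs(self):
        cfg = calibration_config(5, count_model="negative_binomial", nb_alpha=0.05)
        panel = generate_panel(cfg)
        assert len(panel) == 4 * 378

    def test_overlapping_months_shared_across_groups(self):
        panel = generate_panel(calibration_config(2))
        sub = panel[(panel.attitude == "desire") & (panel.animacy == "animate")
                    & (panel.sample_index == 1)]
        month = "2015-01"  # inside the 2013, 2014 windows
        rows = sub[sub.calendar_month == month]
        assert len(rows) == 2
        assert rows["proportion"].nunique() == 1  # identical shared observation


@pytest.mark.parametrize("contaminated", [False, True])
def test_stream_and_fast_path_agree_in_distribution(contaminated, lexicon):
    """Kolmogorov-Smirnov on per-month proportions: the fast path must be
    indistinguishable from stream -> filter -> proportion aggregation.

    20 seeds, alpha=0.01 per test; under agreement the rejection count is
    Binomial(n_tests, 0.01)."""
    con = (
        {"duplicate": 0.05, "url": 0.10, "noisy_target": 0.30}
        if contaminated
        else {"duplicate": 0.0, "url": 0.0, "noisy_target": 0.0}
    )
    kw = dict(base_volume=25_000, marker_prevalence=0.95,
              attitude_rate={"desire": 0.02, "avoidance": 0.02},
              target_presence=0.25, contamination=con)
    groups = build_groups()
    months = pd.PeriodIndex(sorted({m for g in groups for m in g.months}), freq="M")

    n_tests, rejections = 0, 0
    for seed in range(10):
        stream = generate_stream(SimulationConfig(seed=seed, **kw), lexicon)
        deduped, _ = dedupe_exact(stream)
        clean, _ = drop_url_records(deduped)
        sp = stream_monthly_samples(clean, lexicon, months, seed=9_000 + seed)
        fp = simulate_monthly_cells(SimulationConfig(seed=50_000 + seed, **kw),
                                    lexicon, months=months)
        for anim in ("animate", "inanimate"):
            a = sp[(sp.attitude == "desire") & (sp.animacy == anim)]["proportion"]
            b = fp[(fp.attitude == "desire") & (fp.animacy == anim)]["proportion"]
            assert len(a) == len(b) == 3 * len(months)
            rejections += stats.ks_2samp(a, b).pvalue < 0.01
            n_tests += 1
    assert rejections <= 2, f"{rejections}/{n_tests} KS rejections at alpha=0.01"
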