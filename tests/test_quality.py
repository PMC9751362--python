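"""Target-word distributions, cosine similarity, similarity DID, and the
bootstrap shift test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from touchdid import (
    DIDEstimator,
    bootstrap_delta,
    build_groups,
    cosine_similarity,
    default_target_distribution,
    generate_target_counts,
    make_distribution,
    similarity_panel,
    top_bottom,
)
from touchdid.errors import EmptyPeriodError

from conftest import calibration_config


def brute_force_cosine(p, q):
    """Plain-loop dot product over the union vocabulary."""
    vocab = sorted(set(p.vocabulary) | set(q.vocabulary))
    pa = {w: x for w, x in zip(p.vocabulary, p.probabilities)}
    qa = {w: x for w, x in zip(q.vocabulary, q.probabilities)}
    dot = na = nb = 0.0
    for w in vocab:
        a, b = pa.get(w, 0.0), qa.get(w, 0.0)
        dot += a * b
        na += a * a
        nb += b * b
    return dot / ((na ** 0.5) * (nb ** 0.5))


class TestDistribution:
    def test_normalisation(self):
        d = make_distribution({"cat": 3, "dog": 1})
        assert d.vocabulary == ("cat", "dog")
        assert np.allclose(d.probabilities, [0.75, 0.25])

    def test_single_word(self):
        d = make_distribution({"cat": 5})
        assert d.probabilities[0] == 1.0

    def test_round_trip_support_counts(self):
        counts = {"a": 2, "b": 7, "c": 1}
        d = make_distribution(counts)
        total = d.support_counts.sum()
        assert dict(zip(d.vocabulary, (d.probabilities * total).round())) == {
            k: float(v) for k, v in counts.items()
        }

    def test_empty_counts_raise(self):
        with pytest.raises(EmptyPeriodError):
            make_distribution({"a": 0})


class TestCosine:
    def test_identity_disjoint_and_half(self):
        p = make_distribution({"a": 1, "b": 1})
        assert cosine_similarity(p, p) == pytest.approx(1.0)
        q = make_distribution({"c": 1, "d": 2})
        assert cosine_similarity(p, q) == 0.0
        r = make_distribution({"b": 1, "c": 1})
        # (0.5,0.5,0).(0,0.5,0.5) / (sqrt(.5) sqrt(.5)) = 0.5
        assert cosine_similarity(p, r) == pytest.approx(0.5)

    @given(st.data())
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_matches_brute_force_and_symmetry(self, data):
        words = [f"w{i}" for i in range(8)]
        c1 = {w: data.draw(st.integers(0, 20)) for w in words[:6]}
        c2 = {w: data.draw(st.integers(0, 20)) for w in words[2:]}
        if sum(c1.values()) == 0 or sum(c2.values()) == 0:
            return
        p, q = make_distribution(c1), make_distribution(c2)
        s = cosine_similarity(p, q)
        assert s == pytest.approx(brute_force_cosine(p, q), abs=1e-12)
        assert s == pytest.approx(cosine_similarity(q, p), abs=1e-15)
        assert 0.0 <= s <= 1.0 + 1e-12


def shifted_distribution(base: dict[str, float], factor=0.2, n_shift=5):
    """Shrink the largest word and spread its mass over the next few."""
    words = sorted(base, key=base.get, reverse=True)
    post = dict(base)
    moved = base[words[0]] * (1 - factor)
    post[words[0]] = base[words[0]] * factor
    for w in words[1:1 + n_shift]:
        post[w] = base[w] + moved / n_shift
    return post


class TestSimilarityDid:
    def test_identical_distribution_gives_similarity_one(self):
        cfg = calibration_config(31)
        groups = build_groups()
        months = pd.PeriodIndex(sorted({m for g in groups for m in g.months}), freq="M")
        wc = generate_target_counts(cfg, months=months)
        panel = similarity_panel(wc, attitude="desire")
        assert len(panel) == 378
        assert (panel["y"] > 0.8).all()  # noisy but close to the template

    def test_injected_shift_detected_as_similarity_drop(self):
        pre = default_target_distribution([f"w{i:02d}" for i in range(40)])
        post = shifted_distribution(pre)
        cfg = calibration_config(32, target_distribution_pre=pre,
                                 target_distribution_post=post)
        groups = build_groups()
        months = pd.PeriodIndex(sorted({m for g in groups for m in g.months}), freq="M")
        wc = generate_target_counts(cfg, months=months)
        est = DIDEstimator(model="overall").fit(similarity_panel(wc, attitude="desire"))
        row = est.effects_.iloc[0]
        assert row["significant"]
        assert row["effect_rel"] < 0  # similarity decreased


class TestBootstrap:
    def test_identical_counts_nothing_significant(self):
        counts = {f"w{i}": 50 + i for i in range(30)}
        out = bootstrap_delta(counts, counts, B=2_000, seed=0)
        assert not out["significant"].any()
        assert out["delta"].abs().max() == 0.0

    def test_deltas_sum_to_zero(self):
        rng = np.random.default_rng(2)
        t = {f"w{i}": int(rng.integers(1, 100)) for i in range(20)}
        c = {f"w{i}": int(rng.integers(1, 100)) for i in range(5, 25)}
        out = bootstrap_delta(t, c, B=500, seed=1)
        assert abs(out["delta"].sum()) < 1e-12

    def test_large_shift_flagged(self):
        rng = np.random.default_rng(3)
        p = 1 / np.arange(1, 41)
        p /= p.sum()
        p_shift = p.copy()
        p_shift[0] += 0.06
        p_shift[1] -= 0.06
        words = [f"w{i:02d}" for i in range(40)]
        t = dict(zip(words, rng.multinomial(20_000, p_shift)))
        c = dict(zip(words, rng.multinomial(20_000, p)))
        out = bootstrap_delta(t, c, B=10_000, seed=4).set_index("word")
        assert out.loc["w00", "significant"] and out.loc["w00", "delta"] > 0
        assert out.loc["w01", "significant"] and out.loc["w01", "delta"] < 0

    def test_seed_stability_at_large_B(self):
        """Two disjoint seeds at B=10000 give bounds within 1e-3."""
        rng = np.random.default_rng(5)
        words = [f"w{i:02d}" for i in range(40)]
        p = 1 / np.arange(1, 41)
        p /= p.sum()
        t = dict(zip(words, rng.multinomial(20_000, p)))
        c = dict(zip(words, rng.multinomial(20_000, p)))
        a = bootstrap_delta(t, c, B=10_000, seed=100).set_index("word")["ci_bound"]
        b = bootstrap_delta(t, c, B=10_000, seed=200).set_index("word")["ci_bound"]
        assert (a - b).abs().max() < 1e-3

    def test_zero_totals_raise(self):
        with pytest.raises(EmptyPeriodError):
            bootstrap_delta({"a": 0}, {"a": 3}, B=10)


class TestTopBottom:
    def test_full_selection(self):
        deltas = pd.DataFrame({
            "word": [f"w{i:02d}" for i in range(40)],
            "delta": np.linspace(-0.02, 0.02, 40),
            "ci_bound": 0.0, "significant": False,
        })
        sel = top_bottom(deltas, k=15)
        assert (sel["selection"] == "top").sum() == 15
        assert (sel["selection"] == "bottom").sum() == 15
        assert sel[sel.selection == "top"]["delta"].min() > \
            sel[sel.selection == "bottom"]["delta"].max()

    def test_small_vocabulary_warns(self):
        deltas = pd.DataFrame({
            "word": [f"w{i}" for i in range(20)],
            "delta": np.linspace(-1, 1, 20), "ci_bound": 0.0, "significant": False,
        })
        with pytest.warns(UserWarning, match="smaller than"):
            sel = top_bottom(deltas, k=15)
        assert len(sel) == 20

    def test_all_equal_deltas_warns_lexicographic(self):
        deltas = pd.DataFrame({
            "word": ["b", "a", "c", "d"], "delta": 0.0,
            "ci_bound": 0.0, "significant": False,
        })
        with pytest.warns(UserWarning, match="lexicographic"):
            sel = top_bottom(deltas, k=1)
        assert sel[sel.selection == "top"]["word"].iloc[0] == "a"
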