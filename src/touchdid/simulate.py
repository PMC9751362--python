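"""Seeded synthetic tweet streams and pre-aggregated monthly panels.

Two generation paths share one generative model:

``generate_stream``
    Record-level simulation.  Monthly record counts are Poisson (optionally
    negative-binomial) around ``base_volume x trend x seasonal factor``;
    each record gets a minute-resolution timestamp, a dedup content key,
    contamination flags (exact-duplicate bot posts copy an earlier record's
    content, URL posts), an independent Bernoulli marker-token flag, and —
    with small probability — a touch attitude with a target word drawn from
    the pre- or post-outbreak distribution.

``generate_panel`` / ``simulate_monthly_cells``
    Fast path that skips record-level simulation and draws the per-month,
    per-sample target and pseudo-baseline counts directly from the exact
    count law implied by the stream path (sequential binomial thinning of
    the monthly total; window-sampled baseline counts are binomial in the
    number of covered minute ticks, itself Binomial(8 x days, 1/2)).  The
    two paths therefore agree in distribution, not merely in expectation.

Both paths are deterministic given ``config.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import ATTITUDES, SimulationConfig
from .errors import ConfigurationError, DegenerateSampleError
from .lexicon import TargetLexicon, default_lexicon

STREAM_COLUMNS = [
    "timestamp",
    "content_key",
    "has_url",
    "has_marker",
    "attitude",
    "target_word",
    "is_noisy_target",
]

SECONDS_PER_BLOCK = 3 * 3600  # 3-hour sampling blocks
WINDOW_SECONDS = 30
BLOCKS_PER_DAY = 8
TICKS_PER_DAY = 1440  # minute-resolution timestamps


@dataclass(frozen=True)
class TweetRecord:
    """One post; the stream DataFrame holds one row per record."""

    timestamp: pd.Timestamp
    content_key: str
    has_url: bool
    has_marker: bool
    attitude: str  # "desire" | "avoidance" | "none"
    target_word: Optional[str]
    is_noisy_target: bool

    def __post_init__(self) -> None:
        if self.attitude == "none" and self.target_word is not None:
            raise ValueError("attitude 'none' implies no target word")


def _draw_monthly_total(rng: np.random.Generator, lam: float, config: SimulationConfig) -> int:
    if lam <= 0:
        return 0
    if config.count_model == "negative_binomial":
        r = 1.0 / config.nb_alpha
        p = r / (r + lam)
        return int(rng.negative_binomial(r, p))
    return int(rng.poisson(lam))


def sample_days(month: pd.Period) -> dict[int, np.ndarray]:
    """Days of the month split into the three every-third-day residue
    classes: sample s holds days d with d == s (mod 3)."""
    days = np.arange(1, month.days_in_month + 1)
    return {s: days[days % 3 == s % 3] for s in (1, 2, 3)}


# --------------------------------------------------------------------------- #
# record-level path
# --------------------------------------------------------------------------- #

def generate_stream(
    config: SimulationConfig, lexicon: TargetLexicon | None = None
) -> pd.DataFrame:
    """Simulate the full tweet stream as a DataFrame (one row per record).

    Records are sorted by timestamp within each month.  Duplicate records
    copy the content key, flags, attitude and target word of a uniformly
    chosen earlier record of the same month, so deduplication keeps exactly
    the "original" posts.
    """
    lexicon = lexicon or default_lexicon()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    words = sorted(lexicon.words)
    block = sorted(lexicon.blocklist)
    con = config.contamination

    frames: list[pd.DataFrame] = []
    for month in config.months:
        n = _draw_monthly_total(rng, config.expected_volume(month), config)
        if n == 0:
            continue
        days_in_month = month.days_in_month
        day = rng.integers(1, days_in_month + 1, size=n)
        minute = rng.integers(0, TICKS_PER_DAY, size=n)
        order = np.lexsort((minute, day))
        day, minute = day[order], minute[order]

        is_dup = rng.random(n) < con.duplicate
        is_dup[0] = False
        originals = ~is_dup
        n_before = np.cumsum(originals) - originals  # originals strictly earlier
        is_dup &= n_before > 0
        originals = ~is_dup

        # original-record fields
        has_url = rng.random(n) < con.url
        has_marker = rng.random(n) < config.marker_prevalence
        u = rng.random(n)
        r_d = config.attitude_rate_at("desire", month)
        r_a = config.attitude_rate_at("avoidance", month)
        attitude = np.full(n, "none", dtype=object)
        attitude[u < r_d] = "desire"
        attitude[(u >= r_d) & (u < r_d + r_a)] = "avoidance"
        has_target = (attitude != "none") & (rng.random(n) < config.target_presence)
        noisy = has_target & (rng.random(n) < con.noisy_target)
        target = np.full(n, None, dtype=object)
        n_clean = int((has_target & ~noisy).sum())
        if n_clean:
            dist = config.target_distribution_at(month, words)
            vocab = sorted(dist)
            probs = np.array([dist[w] for w in vocab])
            target[has_target & ~noisy] = rng.choice(vocab, size=n_clean, p=probs)
        if block and noisy.any():
            target[noisy] = rng.choice(block, size=int(noisy.sum()))
        key = np.array([f"{month}#{i:07d}" for i in range(n)], dtype=object)

        # duplicates copy everything content-derived from their source
        if is_dup.any():
            orig_idx = np.flatnonzero(originals)
            src = orig_idx[(rng.random(int(is_dup.sum())) * n_before[is_dup]).astype(int)]
            for col in (key, has_url, has_marker, attitude, target, noisy):
                col[is_dup] = col[src]

        ts = (
            pd.Timestamp(month.start_time)
            + pd.to_timedelta(day - 1, unit="D")
            + pd.to_timedelta(minute, unit="min")
        )
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": ts,
                    "content_key": key,
                    "has_url": has_url,
                    "has_marker": has_marker,
                    "attitude": attitude,
                    "target_word": target,
                    "is_noisy_target": noisy,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=STREAM_COLUMNS)
    return pd.concat(frames, ignore_index=True)[STREAM_COLUMNS]


def write_stream(stream: pd.DataFrame, path: str | Path) -> None:
    """Write a stream as JSONL, one record per line."""
    out = stream.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_json(path, orient="records", lines=True)


def read_stream(path: str | Path) -> pd.DataFrame:
    df = pd.read_json(path, lines=True, convert_dates=False, dtype=False)
    if df.empty:
        return pd.DataFrame(columns=STREAM_COLUMNS)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["target_word"] = df["target_word"].where(df["target_word"].notna(), None)
    return df[STREAM_COLUMNS]


# --------------------------------------------------------------------------- #
# fast path
# --------------------------------------------------------------------------- #

def _binomial(rng: np.random.Generator, n, p) -> np.ndarray:
    return rng.binomial(np.asarray(n, dtype=np.int64), p)


def simulate_monthly_cells(
    config: SimulationConfig,
    lexicon: TargetLexicon | None = None,
    months: pd.PeriodIndex | None = None,
) -> pd.DataFrame:
    """Per-calendar-month sample cells drawn from the exact stream count law.

    Returns one row per (calendar_month, sample_index, attitude, animacy)
    with target_count, baseline_count and proportion.  The pseudo-baseline
    count of a (month, sample) pair is shared by all four attitude/animacy
    cells, exactly as when a single sampled stream is aggregated.
    """
    lexicon = lexicon or default_lexicon()
    months = config.months if months is None else months
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    con = config.contamination
    q_valid = (1.0 - con.duplicate) * (1.0 - con.url)
    words = sorted(lexicon.words)

    rows: list[dict] = []
    for month in months:
        n = _draw_monthly_total(rng, config.expected_volume(month) * q_valid, config)
        day_classes = sample_days(month)
        d_tot = month.days_in_month
        shares = np.array([len(day_classes[s]) / d_tot for s in (1, 2, 3)])
        valid_s = rng.multinomial(n, shares)

        markers = _binomial(rng, valid_s, config.marker_prevalence)
        n_windows = np.array([BLOCKS_PER_DAY * len(day_classes[s]) for s in (1, 2, 3)])
        covered_ticks = rng.binomial(n_windows, 0.5)
        tick_frac = covered_ticks / (TICKS_PER_DAY * n_windows / BLOCKS_PER_DAY)
        baseline = _binomial(rng, markers, tick_frac)
        if (baseline == 0).any():
            bad = [s + 1 for s in np.flatnonzero(baseline == 0)]
            raise DegenerateSampleError(
                f"zero pseudo-baseline for month {month}, sample(s) {bad}; "
                "increase base_volume or marker_prevalence"
            )

        dist = config.target_distribution_at(month, words)
        missing = [w for w in dist if w not in lexicon]
        if missing:
            raise ConfigurationError(
                f"target distribution words not in lexicon: {missing[:5]}"
            )
        p_animate = float(sum(p for w, p in dist.items()
                              if lexicon.animacy_of(w) == "animate"))
        for att in ATTITUDES:
            r = config.attitude_rate_at(att, month)
            att_s = _binomial(rng, valid_s, r)
            clean_s = _binomial(
                rng, att_s, config.target_presence * (1.0 - con.noisy_target)
            )
            anim_s = _binomial(rng, clean_s, p_animate)
            for s in (1, 2, 3):
                for animacy, cnt in (
                    ("animate", int(anim_s[s - 1])),
                    ("inanimate", int(clean_s[s - 1] - anim_s[s - 1])),
                ):
                    rows.append(
                        {
                            "calendar_month": str(month),
                            "sample_index": s,
                            "attitude": att,
                            "animacy": animacy,
                            "target_count": cnt,
                            "baseline_count": int(baseline[s - 1]),
                            "proportion": cnt / int(baseline[s - 1]),
                        }
                    )
    return pd.DataFrame(rows)


def generate_panel(
    config: SimulationConfig,
    lexicon: TargetLexicon | None = None,
    independent_cells: bool = False,
) -> pd.DataFrame:
    """Fast-path rolling panel: 7 groups x 18 months x 3 samples per
    attitude/animacy dataset, with design variables attached.

    By default calendar months shared by overlapping group windows appear
    once per group with identical counts, as they would when a single
    observed stream is aggregated (rows across groups are then correlated,
    exactly as in the real design).  With ``independent_cells=True`` every
    group-month is drawn independently from the same count law — the
    model-consistent regime used for estimator calibration.
    """
    from .panel import assemble_panel, build_groups

    groups = build_groups()
    if not independent_cells:
        needed = pd.PeriodIndex(
            sorted({m for g in groups for m in g.months}), freq="M"
        )
        cells = simulate_monthly_cells(config, lexicon, months=needed)
        return assemble_panel(cells, groups)

    seeds = np.random.SeedSequence(config.seed).spawn(len(groups))
    frames = []
    for g, ss in zip(groups, seeds):
        sub = config.model_copy(update={"seed": int(ss.generate_state(1)[0])})
        cells = simulate_monthly_cells(sub, lexicon, months=g.months)
        frames.append(assemble_panel(cells, [g]))
    return pd.concat(frames, ignore_index=True)


def generate_target_counts(
    config: SimulationConfig,
    lexicon: TargetLexicon | None = None,
    months: pd.PeriodIndex | None = None,
) -> pd.DataFrame:
    """Fast-path word-level counts: one row per (calendar_month,
    sample_index, attitude, word) with the count of cleanly-targeted posts.

    An independent realisation of the same count law as
    :func:`simulate_monthly_cells` (word totals are split multinomially
    over the vocabulary of the month's distribution).
    """
    lexicon = lexicon or default_lexicon()
    months = config.months if months is None else months
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    con = config.contamination
    q_valid = (1.0 - con.duplicate) * (1.0 - con.url)

    rows: list[dict] = []
    for month in months:
        n = _draw_monthly_total(rng, config.expected_volume(month) * q_valid, config)
        day_classes = sample_days(month)
        d_tot = month.days_in_month
        shares = np.array([len(day_classes[s]) / d_tot for s in (1, 2, 3)])
        valid_s = rng.multinomial(n, shares)
        dist = config.target_distribution_at(month, sorted(lexicon.words))
        words = sorted(dist)
        probs = np.array([dist[w] for w in words])
        for att in ATTITUDES:
            r = config.attitude_rate_at(att, month)
            clean_s = _binomial(
                rng,
                _binomial(rng, valid_s, r),
                config.target_presence * (1.0 - con.noisy_target),
            )
            for s in (1, 2, 3):
                counts = rng.multinomial(int(clean_s[s - 1]), probs)
                for w, c in zip(words, counts):
                    if c:
                        rows.append(
                            {
                                "calendar_month": str(month),
                                "sample_index": s,
                                "attitude": att,
                                "word": w,
                                "count": int(c),
                            }
                        )
    return pd.DataFrame(rows, columns=["calendar_month", "sample_index", "attitude", "word", "count"])
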