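"""Pseudo-baseline sampling and monthly tweet-proportion samples.

The absolute number of attitude tweets confounds behaviour with platform
growth, so counts are expressed as a *tweet proportion*: attitude tweets
divided by a pseudo-baseline that tracks total posting volume.  The
pseudo-baseline counts posts containing a ubiquitous marker token inside
one uniformly placed 30-second window per 3-hour block (8 windows per
day); its expectation is ``30/10800`` of all marker posts, and any factor
common to numerator and denominator — active-user drift, seasonal volume —
cancels from the proportion.

Each month yields three proportion samples by aggregating every third day:
sample ``s`` pools days ``d`` with ``d == s (mod 3)`` (so sample 1 is days
1, 4, 7, ...; day 31 falls in sample 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateSampleError, MonthRangeError
from .simulate import BLOCKS_PER_DAY, SECONDS_PER_BLOCK, WINDOW_SECONDS


def draw_window_starts(n_days: int, seed: int) -> np.ndarray:
    """One uniform window start (seconds into the block) per (day, block):
    an (n_days, 8) array, drawn in fixed order so results are reproducible."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, SECONDS_PER_BLOCK, size=(n_days, BLOCKS_PER_DAY))


def sample_pseudo_baseline(
    stream: pd.DataFrame, month: str | pd.Period, seed: int
) -> pd.DataFrame:
    """Per-day marker counts from window sampling of one calendar month.

    For every 3-hour block of every day one 30-second window is placed
    uniformly (with wrap-around inside the block, so each instant is covered
    with probability exactly 30/10800); marker-bearing records whose
    timestamp falls inside a sampled window are counted.  Deterministic
    given ``seed``.

    Returns one row per day: (date, count).
    """
    month = pd.Period(month, freq="M")
    if stream.empty:
        raise MonthRangeError(f"stream is empty; no data for {month}")
    t0, t1 = month.start_time, month.end_time
    span = pd.PeriodIndex(stream["timestamp"], freq="M")
    if month < span.min() or month > span.max():
        raise MonthRangeError(
            f"month {month} outside stream range {span.min()}..{span.max()}"
        )
    in_month = stream[(stream["timestamp"] >= t0) & (stream["timestamp"] <= t1)]
    markers = in_month[in_month["has_marker"].astype(bool)]

    n_days = month.days_in_month
    starts = draw_window_starts(n_days, seed)

    counts = np.zeros(n_days, dtype=np.int64)
    if not markers.empty:
        ts = markers["timestamp"]
        day_idx = ts.dt.day.to_numpy() - 1
        sec_of_day = (
            ts.dt.hour.to_numpy() * 3600 + ts.dt.minute.to_numpy() * 60
            + ts.dt.second.to_numpy()
        )
        block_idx = sec_of_day // SECONDS_PER_BLOCK
        sec_in_block = sec_of_day % SECONDS_PER_BLOCK
        start = starts[day_idx, block_idx]
        offset = (sec_in_block - start) % SECONDS_PER_BLOCK  # wrap-around window
        hit = offset < WINDOW_SECONDS
        if hit.any():
            counts = np.bincount(day_idx[hit], minlength=n_days)
    dates = pd.date_range(t0.normalize(), periods=n_days, freq="D")
    return pd.DataFrame({"date": dates, "count": counts})


def monthly_proportion_samples(
    daily_targets: pd.DataFrame,
    daily_baseline: pd.DataFrame,
    month: str | pd.Period,
) -> pd.DataFrame:
    """The three every-third-day proportion samples of one calendar month.

    ``daily_targets`` has (date, attitude, animacy, count) rows (a word
    column, if present, is summed over); ``daily_baseline`` has (date,
    count) rows from :func:`sample_pseudo_baseline`.  Cells with no target
    records get a zero count (proportion 0); a zero *baseline* sum is
    degenerate and raises.

    Returns one row per (attitude, animacy, sample_index).
    """
    month = pd.Period(month, freq="M")
    t0, t1 = month.start_time, month.end_time

    base = daily_baseline[
        (daily_baseline["date"] >= t0) & (daily_baseline["date"] <= t1)
    ].copy()
    if base.empty:
        raise MonthRangeError(f"daily_baseline has no rows for {month}")
    base["sample_index"] = _residue(base["date"])
    base_sums = base.groupby("sample_index")["count"].sum()
    base_sums = base_sums.reindex([1, 2, 3], fill_value=0)
    if (base_sums == 0).any():
        bad = base_sums[base_sums == 0].index.tolist()
        raise DegenerateSampleError(
            f"zero pseudo-baseline sum for month {month}, sample(s) {bad}"
        )

    tgt = daily_targets[
        (daily_targets["date"] >= t0) & (daily_targets["date"] <= t1)
    ].copy()
    cells = (
        daily_targets[["attitude", "animacy"]].drop_duplicates()
        if not daily_targets.empty
        else pd.DataFrame({"attitude": [], "animacy": []})
    )
    if not tgt.empty:
        tgt["sample_index"] = _residue(tgt["date"])
        tgt_sums = (
            tgt.groupby(["attitude", "animacy", "sample_index"], observed=True)["count"]
            .sum()
            .reset_index()
        )
    else:
        tgt_sums = pd.DataFrame(columns=["attitude", "animacy", "sample_index", "count"])

    full = (
        cells.merge(pd.DataFrame({"sample_index": [1, 2, 3]}), how="cross")
        if not cells.empty
        else pd.DataFrame(columns=["attitude", "animacy", "sample_index"])
    )
    out = full.merge(tgt_sums, on=["attitude", "animacy", "sample_index"], how="left")
    out["count"] = out.get("count", pd.Series(dtype=float)).fillna(0).astype(int)
    out = out.rename(columns={"count": "target_count"})
    out["baseline_count"] = out["sample_index"].map(base_sums).astype(int)
    out["proportion"] = out["target_count"] / out["baseline_count"]
    out["calendar_month"] = str(month)
    cols = [
        "calendar_month", "attitude", "animacy", "sample_index",
        "target_count", "baseline_count", "proportion",
    ]
    return out[cols].sort_values(cols[:4]).reset_index(drop=True)


def _residue(dates: pd.Series) -> pd.Series:
    """Every-third-day sample index: day d -> ((d-1) mod 3) + 1."""
    return ((dates.dt.day - 1) % 3) + 1


def stream_monthly_samples(
    filtered: pd.DataFrame,
    lexicon,
    months,
    seed: int,
) -> pd.DataFrame:
    """Aggregate a filtered stream into monthly proportion samples.

    Window sampling is redrawn per month with a child seed spawned from
    ``seed``, so any month's baseline can be reproduced independently.
    """
    from .filtering import daily_target_counts

    daily = daily_target_counts(filtered, lexicon)
    daily = daily.groupby(["date", "attitude", "animacy"], observed=True)["count"].sum().reset_index()
    child_seeds = np.random.SeedSequence(seed).spawn(len(months))
    frames = []
    for month, ss in zip(months, child_seeds):
        base = sample_pseudo_baseline(filtered, month, seed=ss.generate_state(1)[0])
        frames.append(monthly_proportion_samples(daily, base, month))
    return pd.concat(frames, ignore_index=True)
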