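"""Exclusion cascade and lexicon-based target classification.

The cascade mirrors the preprocessing of the attitude-tweet collection:
exact-duplicate posts (bot reposts) are removed keeping the earliest
occurrence per content key, URL posts (ads and spam) are dropped, records
without an extractable target word are set aside, and blocklisted "noisy"
targets are rejected.  A :class:`FilterReport` records the count surviving
each stage; stages are monotonically non-increasing by construction.

The Japanese NLP stage that extracts target words from raw text is outside
this package: records arrive with a pre-annotated ``target_word``.  A
pluggable extractor callable can be supplied to re-derive the word from a
record, so a real morphological front end can be attached later.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Callable, Optional

import pandas as pd

from .lexicon import TargetLexicon

#: optional hook: maps a record (pd.Series) to a target word or None
TargetExtractor = Callable[[pd.Series], Optional[str]]


@dataclass
class FilterReport:
    """Counts surviving each stage of the exclusion cascade."""

    collected: int = 0
    after_dedup: int = 0
    after_url_drop: int = 0
    with_target: int = 0
    after_blocklist: int = 0

    def to_dict(self) -> dict[str, int]:
        return asdict(self)

    def assert_monotone(self) -> None:
        vals = list(self.to_dict().values())
        if any(a < b for a, b in zip(vals, vals[1:])):
            raise AssertionError(f"filter stages increased: {self.to_dict()}")


@dataclass(frozen=True)
class Rejection:
    word: Optional[str]
    reason: str  # "blocklist" | "out_of_lexicon" | "no_target"


def dedupe_exact(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep at most one record per content key — the earliest by timestamp.

    Returns the surviving records and the number removed.
    """
    if records.empty:
        return records.copy(), 0
    ordered = records.sort_values("timestamp", kind="stable")
    kept = ordered.drop_duplicates(subset="content_key", keep="first")
    return kept.reset_index(drop=True), len(records) - len(kept)


def drop_url_records(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove records flagged as containing a URL."""
    if records.empty:
        return records.copy(), 0
    kept = records[~records["has_url"].astype(bool)]
    return kept.reset_index(drop=True), len(records) - len(kept)


def resolve_target(
    record: pd.Series, lexicon: TargetLexicon
) -> tuple[str, str, str] | Rejection:
    """Classify a single attitude record's target word.

    Returns ``(word, category, animacy)`` or a :class:`Rejection` with the
    reason.  Records without an attitude are a usage error: classification
    is only defined for the attitude-tweet collection.
    """
    if record["attitude"] not in ("desire", "avoidance"):
        raise ValueError("resolve_target requires a record with an attitude")
    word = record.get("target_word")
    if word is None or (isinstance(word, float) and pd.isna(word)):
        return Rejection(None, "no_target")
    if word in lexicon.blocklist:
        return Rejection(word, "blocklist")
    if word not in lexicon:
        return Rejection(word, "out_of_lexicon")
    entry = lexicon.entries[word]
    return (word, entry.category, entry.animacy)


def classify_targets(
    records: pd.DataFrame,
    lexicon: TargetLexicon,
    extractor: TargetExtractor | None = None,
) -> pd.DataFrame:
    """Vectorised classification of all attitude records.

    Adds ``category`` and ``animacy`` columns and drops records whose word
    is absent, blocklisted or out of lexicon.
    """
    att = records[records["attitude"].isin(("desire", "avoidance"))].copy()
    if extractor is not None:
        att["target_word"] = att.apply(extractor, axis=1)
    att = att[att["target_word"].notna()]
    att = att[~att["target_word"].isin(lexicon.blocklist)]
    att = att[att["target_word"].isin(lexicon.entries)]
    att["category"] = att["target_word"].map(lambda w: lexicon.entries[w].category)
    att["animacy"] = att["target_word"].map(lambda w: lexicon.entries[w].animacy)
    return att.reset_index(drop=True)


def apply_filter(
    records: pd.DataFrame,
    lexicon: TargetLexicon,
    extractor: TargetExtractor | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Run the full cascade and report per-stage survivor counts.

    ``with_target`` counts surviving attitude records that carry a target
    word; ``after_blocklist`` counts those whose word is classifiable.
    The returned frame holds only classified attitude records.
    """
    report = FilterReport(collected=len(records))
    deduped, _ = dedupe_exact(records)
    report.after_dedup = len(deduped)
    no_url, _ = drop_url_records(deduped)
    report.after_url_drop = len(no_url)
    att = no_url[no_url["attitude"].isin(("desire", "avoidance"))].copy()
    if extractor is not None:
        att["target_word"] = att.apply(extractor, axis=1)
    with_target = att[att["target_word"].notna()]
    report.with_target = int(len(with_target))
    classified = with_target[
        ~with_target["target_word"].isin(lexicon.blocklist)
        & with_target["target_word"].isin(lexicon.entries)
    ].copy()
    classified["category"] = classified["target_word"].map(
        lambda w: lexicon.entries[w].category
    )
    classified["animacy"] = classified["target_word"].map(
        lambda w: lexicon.entries[w].animacy
    )
    report.after_blocklist = len(classified)
    report.assert_monotone()
    return classified.reset_index(drop=True), report


def daily_target_counts(records: pd.DataFrame, lexicon: TargetLexicon) -> pd.DataFrame:
    """Per-day counts of classified attitude records.

    One row per (date, attitude, animacy, word); the table total equals the
    number of classified records.
    """
    classified = (
        records
        if "animacy" in records.columns
        else classify_targets(records, lexicon)
    )
    if classified.empty:
        return pd.DataFrame(columns=["date", "attitude", "animacy", "word", "count"])
    out = (
        classified.assign(date=classified["timestamp"].dt.normalize())
        .groupby(["date", "attitude", "animacy", "target_word"], observed=True)
        .size()
        .rename("count")
        .reset_index()
        .rename(columns={"target_word": "word"})
    )
    return out.sort_values(["date", "attitude", "animacy", "word"]).reset_index(drop=True)
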