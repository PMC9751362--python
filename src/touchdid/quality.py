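"""Target-word distribution shifts: similarity series and bootstrap deltas.

"Quality" here means *which* targets people mention, as opposed to how
often.  Two instruments:

* a per-group cosine-similarity series between each month's target-word
  probability distribution and the group's own pre-treatment template
  (pooled months 1-6), which feeds straight back into the panel + DID
  machinery with similarity as the response; and
* a bootstrap test for per-word probability shifts between a treatment
  period and the pooled corresponding control periods: each side's counts
  are resampled as a multinomial conditioned on its observed total,
  B bootstrap replicates of the per-word difference are formed, and a
  one-tailed Bonferroni-corrected confidence bound (level ``alpha/n_tested``
  in the direction of the observed delta) decides significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import EmptyPeriodError
from .panel import GroupSpec, PRE_MONTHS, build_groups


@dataclass(frozen=True)
class TargetDistribution:
    """Empirical target-word distribution of one period."""

    period: str
    vocabulary: tuple[str, ...]
    probabilities: np.ndarray
    support_counts: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.probabilities, index=list(self.vocabulary))


def make_distribution(counts: Mapping[str, int] | pd.Series, period: str = "") -> TargetDistribution:
    """Normalise word counts into a distribution (vocabulary sorted)."""
    if isinstance(counts, pd.Series):
        counts = counts.to_dict()
    words = sorted(w for w, c in counts.items() if c > 0)
    if not words:
        raise EmptyPeriodError(f"no positive counts in period {period!r}")
    support = np.array([int(counts[w]) for w in words])
    probs = support / support.sum()
    return TargetDistribution(period=period, vocabulary=tuple(words),
                              probabilities=probs, support_counts=support)


def cosine_similarity(p: TargetDistribution, q: TargetDistribution) -> float:
    """Cosine of the two probability vectors over the union vocabulary
    (zero-filled); 1 for identical distributions, 0 for disjoint supports."""
    vocab = sorted(set(p.vocabulary) | set(q.vocabulary))
    a = p.as_series().reindex(vocab, fill_value=0.0).to_numpy()
    b = q.as_series().reindex(vocab, fill_value=0.0).to_numpy()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom)


# --------------------------------------------------------------------------- #
# similarity series feeding the DID machinery
# --------------------------------------------------------------------------- #

def similarity_series(
    word_counts: pd.DataFrame,
    groups: list[GroupSpec] | None = None,
    attitude: str | None = None,
) -> pd.DataFrame:
    """Monthly cosine similarity of each (group, month, sample) distribution
    to the group's own pre-treatment template.

    ``word_counts`` holds (calendar_month, sample_index, word, count) rows,
    optionally with an ``attitude`` column filtered by ``attitude``.  The
    template of a group pools the counts of its months 1-6 over all
    samples.  Returns panel-cell rows (calendar-month cells repeated per
    group) with ``y`` = similarity, ready for :func:`~touchdid.panel.assemble_panel`
    — except that rows are already group-expanded, so they plug directly
    into the DID estimators after design coding via ``assemble_panel`` on a
    per-group basis.  Use :func:`similarity_panel` for the one-call version.
    """
    groups = groups or build_groups()
    wc = word_counts
    if attitude is not None and "attitude" in wc.columns:
        wc = wc[wc["attitude"] == attitude]
    wc = wc.copy()
    wc["calendar_month"] = wc["calendar_month"].astype(str)

    rows = []
    for g in groups:
        months = g.months.astype(str)
        pre = wc[wc["calendar_month"].isin(months[:PRE_MONTHS])]
        if pre.empty:
            raise EmptyPeriodError(
                f"group {g.group_id} ({g.start_year}): no counts in pre-treatment months"
            )
        template = make_distribution(pre.groupby("word")["count"].sum(),
                                     period=f"group{g.group_id}-pre")
        for mi, month in enumerate(months, start=1):
            for s in (1, 2, 3):
                cell = wc[(wc["calendar_month"] == month) & (wc["sample_index"] == s)]
                if cell.empty:
                    raise EmptyPeriodError(
                        f"group {g.group_id}: no counts for {month} sample {s}"
                    )
                dist = make_distribution(cell.groupby("word")["count"].sum(),
                                         period=f"{month}-s{s}")
                rows.append({
                    "group_id": g.group_id, "start_year": g.start_year,
                    "treat": int(g.treat), "calendar_month": month,
                    "month_index": mi, "sample_index": s,
                    "y": cosine_similarity(template, dist),
                })
    return pd.DataFrame(rows)


def similarity_panel(word_counts: pd.DataFrame, attitude: str | None = None) -> pd.DataFrame:
    """Similarity series with the DID design variables attached."""
    from .panel import code_design

    series = similarity_series(word_counts, attitude=attitude)
    codes = pd.DataFrame(
        [code_design(m)._asdict() | {"month_index": m} for m in range(1, 19)]
    )
    return series.merge(codes, on="month_index").sort_values(
        ["group_id", "month_index", "sample_index"]
    ).reset_index(drop=True)


# --------------------------------------------------------------------------- #
# bootstrap shift test
# --------------------------------------------------------------------------- #

def bootstrap_delta(
    counts_treatment: Mapping[str, int] | pd.Series,
    counts_control: Mapping[str, int] | pd.Series,
    B: int = 10_000,
    alpha: float = 0.05,
    n_tested: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-word probability differences with one-tailed Bonferroni bootstrap CIs.

    ``delta = p_treatment - p_control`` over the union vocabulary.  Each
    side is resampled B times as a multinomial with its observed total; the
    one-tailed bound at level ``alpha/n_tested`` is taken in the direction
    of the observed delta (lower bound for increases, upper bound for
    decreases) and a word is significant when that bound excludes zero.

    Returns a DataFrame sorted by descending delta with columns word,
    delta, ci_bound, significant, rank.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    t = pd.Series(dict(counts_treatment), dtype=float)
    c = pd.Series(dict(counts_control), dtype=float)
    n_t, n_c = t.sum(), c.sum()
    if n_t <= 0 or n_c <= 0:
        raise EmptyPeriodError("both periods need positive total counts")
    vocab = sorted(set(t.index) | set(c.index))
    tv = t.reindex(vocab, fill_value=0.0).to_numpy()
    cv = c.reindex(vocab, fill_value=0.0).to_numpy()
    p_t, p_c = tv / n_t, cv / n_c
    delta = p_t - p_c

    rng = np.random.default_rng(seed)
    boot_t = rng.multinomial(int(n_t), p_t, size=B) / n_t
    boot_c = rng.multinomial(int(n_c), p_c, size=B) / n_c
    boot_delta = boot_t - boot_c  # (B, n_words)

    level = alpha / n_tested
    lower = np.quantile(boot_delta, level, axis=0)
    upper = np.quantile(boot_delta, 1.0 - level, axis=0)
    bound = np.where(delta >= 0, lower, upper)
    significant = np.where(delta >= 0, lower > 0, upper < 0)

    out = pd.DataFrame({
        "word": vocab, "delta": delta, "ci_bound": bound,
        "significant": significant,
    })
    out = out.sort_values(["delta", "word"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def top_bottom(deltas: pd.DataFrame, k: int = 15) -> pd.DataFrame:
    """The k largest and k smallest deltas (ties broken lexicographically).

    Adds a ``selection`` column ("top" / "bottom").  Vocabularies smaller
    than 2k are taken whole, split as evenly as possible, with a warning.
    """
    n = len(deltas)
    ordered = deltas.sort_values(["delta", "word"], ascending=[False, True],
                                 kind="stable").reset_index(drop=True)
    if n < 2 * k:
        k_eff = n // 2
        warnings.warn(
            f"vocabulary of {n} words is smaller than 2k={2 * k}; "
            f"taking {k_eff}+{k_eff}", stacklevel=2,
        )
        k = k_eff
    if ordered["delta"].nunique() == 1 and n > 1:
        warnings.warn("all deltas equal; selection is lexicographic only",
                      stacklevel=2)
    top = ordered.head(k).assign(selection="top")
    bottom = ordered.tail(k).assign(selection="bottom")
    return pd.concat([top, bottom], ignore_index=True)
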