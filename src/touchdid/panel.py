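"""Rolling 7-group panel construction and design-variable coding.

The causal design compares the 18-month window August 2019 - January 2021
(the treatment group, spanning the outbreak) with the six analogous windows
starting each August 2013-2018 (control groups).  Every window runs August
of its first year through January of its third year; month index m = 1..18,
with months 1-6 the pre-treatment period and 7-18 the post period.  The
post period is partitioned into three infection waves: months 7-11
(February-June of year two), 12-16 (July-November) and 17-18 (December -
January of year three).  Event time k = m - 7, so k = 0 is February of
year two and the reference month is k = -1 (January of year two).

Consecutive group windows overlap; a calendar month may legitimately appear
in up to three groups — the group fixed effect absorbs level differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import pandas as pd

from .errors import CompletenessError, MonthRangeError

TREAT_START_YEAR = 2019
CONTROL_START_YEARS = (2013, 2014, 2015, 2016, 2017, 2018)
MONTHS_PER_GROUP = 18
PRE_MONTHS = 6
REFERENCE_K = -1


@dataclass(frozen=True)
class GroupSpec:
    """One 18-month panel group starting in August of ``start_year``."""

    group_id: int
    start_year: int
    treat: bool

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(f"{self.start_year}-08", periods=MONTHS_PER_GROUP, freq="M")

    def month_of(self, month_index: int) -> pd.Period:
        if not 1 <= month_index <= MONTHS_PER_GROUP:
            raise MonthRangeError(f"month_index must be 1..18, got {month_index}")
        return self.months[month_index - 1]


def build_groups() -> list[GroupSpec]:
    """The seven rolling groups; only the 2019 window is treated."""
    years = CONTROL_START_YEARS + (TREAT_START_YEAR,)
    return [
        GroupSpec(group_id=i, start_year=y, treat=(y == TREAT_START_YEAR))
        for i, y in enumerate(sorted(years))
    ]


class DesignCode(NamedTuple):
    post: int
    first: int
    second: int
    third: int
    k: int


def code_design(month_index: int) -> DesignCode:
    """Design variables of a within-window month index (1..18).

    Months 1-6 are pre-treatment; 7-11 wave one, 12-16 wave two, 17-18 wave
    three; ``post = first + second + third`` and ``k = month_index - 7``.
    """
    m = month_index
    if not 1 <= m <= MONTHS_PER_GROUP:
        raise MonthRangeError(f"month_index must be 1..{MONTHS_PER_GROUP}, got {m}")
    first = int(7 <= m <= 11)
    second = int(12 <= m <= 16)
    third = int(17 <= m <= 18)
    return DesignCode(post=first + second + third, first=first, second=second,
                      third=third, k=m - 7)


def assemble_panel(
    cells: pd.DataFrame, groups: Iterable[GroupSpec] | None = None
) -> pd.DataFrame:
    """Attach monthly sample cells to every group window they fall in.

    ``cells`` must carry ``calendar_month`` plus observation columns (at
    least ``sample_index`` and either ``proportion`` or ``y``).  Each group
    contributes one row per (month_index, cell row); calendar months shared
    by overlapping windows are intentionally repeated across groups.

    Raises :class:`CompletenessError` listing any group-months absent from
    ``cells``.
    """
    groups = list(groups) if groups is not None else build_groups()
    if cells.empty:
        raise CompletenessError("no input cells; every group-month is missing")
    cells = cells.copy()
    cells["calendar_month"] = cells["calendar_month"].astype(str)
    have = set(cells["calendar_month"])

    gaps = [
        f"group {g.group_id} ({g.start_year}): {m}"
        for g in groups
        for m in g.months.astype(str)
        if m not in have
    ]
    if gaps:
        raise CompletenessError(
            "missing months in input cells: " + "; ".join(gaps[:20])
            + ("; ..." if len(gaps) > 20 else "")
        )

    frames = []
    for g in groups:
        idx = pd.DataFrame(
            {
                "calendar_month": g.months.astype(str),
                "month_index": range(1, MONTHS_PER_GROUP + 1),
            }
        )
        sub = idx.merge(cells, on="calendar_month", how="left")
        sub.insert(0, "group_id", g.group_id)
        sub.insert(1, "start_year", g.start_year)
        sub.insert(2, "treat", int(g.treat))
        frames.append(sub)
    panel = pd.concat(frames, ignore_index=True)

    codes = pd.DataFrame(
        [code_design(m)._asdict() | {"month_index": m} for m in range(1, MONTHS_PER_GROUP + 1)]
    )
    panel = panel.merge(codes, on="month_index")
    if "y" not in panel.columns and "proportion" in panel.columns:
        panel["y"] = panel["proportion"]
    sort_cols = [
        c
        for c in ("group_id", "month_index", "attitude", "animacy", "sample_index")
        if c in panel.columns
    ]
    return panel.sort_values(sort_cols, kind="stable").reset_index(drop=True)
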