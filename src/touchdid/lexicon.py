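"""Target-word lexicon: six semantic categories grouped into animate/inanimate.

Touch-attitude posts name a *target* (what the writer wants, or refuses, to
touch).  Targets are classified into six categories — body part, animal,
object, person, geometry, temperature — and the categories are collapsed into
an animate/inanimate dichotomy: body parts, animals and people are animate;
objects and geometric features are inanimate; temperature words are ambiguous
and carry an explicit per-word animacy.  A blocklist holds "noisy" targets
whose surface form does not denote a physical touch target (the classic
example being a mahjong tile in "I want to touch mahjong", meaning playing
the game); blocklisted words are never classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigurationError

CATEGORIES = ("body_part", "animal", "object", "person", "geometry", "temperature")

#: categories with a fixed animacy; "temperature" is resolved per word
CATEGORY_ANIMACY = {
    "body_part": "animate",
    "animal": "animate",
    "person": "animate",
    "object": "inanimate",
    "geometry": "inanimate",
}


@dataclass(frozen=True)
class LexiconEntry:
    word: str
    category: str
    animacy: str


@dataclass
class TargetLexicon:
    """Word -> (category, animacy) map plus a blocklist of noisy targets."""

    entries: dict[str, LexiconEntry] = field(default_factory=dict)
    blocklist: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for e in self.entries.values():
            if e.category not in CATEGORIES:
                raise ConfigurationError(f"unknown category {e.category!r} for word {e.word!r}")
            if e.animacy not in ("animate", "inanimate"):
                raise ConfigurationError(f"unknown animacy {e.animacy!r} for word {e.word!r}")
            fixed = CATEGORY_ANIMACY.get(e.category)
            if fixed is not None and e.animacy != fixed:
                raise ConfigurationError(
                    f"word {e.word!r}: category {e.category!r} implies animacy {fixed!r}, "
                    f"got {e.animacy!r}"
                )
        self.blocklist = frozenset(self.blocklist)

    @property
    def words(self) -> list[str]:
        return sorted(self.entries)

    def animacy_of(self, word: str) -> str:
        return self.entries[word].animacy

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    @classmethod
    def from_items(
        cls,
        items: Iterable[tuple[str, str] | tuple[str, str, str]],
        blocklist: Iterable[str] = (),
    ) -> "TargetLexicon":
        """Build from (word, category[, animacy]) tuples.

        The animacy element is required for "temperature" words and must be
        omitted or consistent for the five fixed-animacy categories.
        """
        entries: dict[str, LexiconEntry] = {}
        for item in items:
            word, category = item[0], item[1]
            if category == "temperature":
                if len(item) < 3:
                    raise ConfigurationError(
                        f"temperature word {word!r} needs an explicit animacy"
                    )
                animacy = item[2]
            else:
                if category not in CATEGORY_ANIMACY:
                    raise ConfigurationError(f"unknown category {category!r}")
                animacy = item[2] if len(item) > 2 else CATEGORY_ANIMACY[category]
            entries[word] = LexiconEntry(word, category, animacy)
        return cls(entries=entries, blocklist=frozenset(blocklist))

    # -- CSV round trip (word,category,animacy,blocklisted) ------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"word": e.word, "category": e.category, "animacy": e.animacy, "blocklisted": 0}
            for e in self.entries.values()
        ]
        rows += [
            {"word": w, "category": "", "animacy": "", "blocklisted": 1}
            for w in sorted(self.blocklist)
        ]
        return pd.DataFrame(rows).sort_values(["blocklisted", "word"]).reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TargetLexicon":
        df = pd.read_csv(path, keep_default_na=False)
        blocked = df[df["blocklisted"].astype(int) == 1]["word"].tolist()
        kept = df[df["blocklisted"].astype(int) == 0]
        items = list(zip(kept["word"], kept["category"], kept["animacy"]))
        return cls.from_items(items, blocklist=blocked)


def default_lexicon() -> TargetLexicon:
    """A 40-word synthetic lexicon spanning all six categories.

    The words stand in for translated Japanese touch targets; the split is
    23 animate / 17 inanimate so that all four attitude-by-animacy datasets
    are populated under the default simulation settings.
    """
    items: list[tuple[str, str] | tuple[str, str, str]] = [
        # body parts
        ("hand", "body_part"), ("hair", "body_part"), ("buttock", "body_part"),
        ("cheek", "body_part"), ("shoulder", "body_part"), ("fingertip", "body_part"),
        ("forehead", "body_part"), ("knee", "body_part"),
        # animals
        ("cat", "animal"), ("dog", "animal"), ("rabbit", "animal"),
        ("hamster", "animal"), ("bird", "animal"), ("horse", "animal"),
        ("frog", "animal"), ("squirrel", "animal"),
        # people
        ("you", "person"), ("people", "person"), ("friend", "person"),
        ("baby", "person"), ("idol", "person"),
        # objects
        ("doorknob", "object"), ("money", "object"), ("handrail", "object"),
        ("button", "object"), ("screen", "object"), ("keyboard", "object"),
        ("coin", "object"), ("strap", "object"), ("ticket", "object"),
        # geometry
        ("line", "geometry"), ("ditch", "geometry"), ("edge", "geometry"),
        ("corner", "geometry"), ("surface", "geometry"),
        # temperature, animacy decided per word
        ("warmth", "temperature", "animate"), ("fever", "temperature", "animate"),
        ("heat", "temperature", "inanimate"), ("coldness", "temperature", "inanimate"),
        ("chill", "temperature", "inanimate"),
    ]
    blocklist = ("mahjong_tile", "lottery", "jackpot")
    return TargetLexicon.from_items(items, blocklist=blocklist)
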