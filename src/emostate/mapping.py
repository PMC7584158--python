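"""Mapping discrete emotion words to PAD space and to six emotional states.

Each emotion word carries normative pleasure/arousal/dominance (PAD) ratings
on a 1-9 scale (ANEW-style affective norms).  Ratings are centred by
subtracting 5, giving scaled values in [-4, +4]; the *dominant dimension* is
the one with the largest absolute scaled value, and its sign picks one of six
emotional states:

===========  =========  =====
dimension    direction  state
===========  =========  =====
pleasure     -          discordant
pleasure     +          pleased
arousal      -          dissuaded
arousal      +          aroused
dominance    -          submissive
dominance    +          dominant
===========  =========  =====

Ties between absolute maxima are broken by preferring the first *positive*
tied dimension in P, A, D order; if no tied dimension is positive, the first
tied dimension in P, A, D order wins with negative direction.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "STATES",
    "AffectiveRating",
    "ScaledRating",
    "NeutralRatingError",
    "UnknownEmotionError",
    "scale_rating",
    "dominant_state",
    "label_events",
    "load_rating_table",
    "load_example_ratings",
]

#: The six admissible emotional-state labels, as (dimension, sign) pairs in
#: P->A->D order: (p,-), (p,+), (a,-), (a,+), (d,-), (d,+).
STATES = ("discordant", "pleased", "dissuaded", "aroused", "submissive", "dominant")

_NEG_STATE = {"p": "discordant", "a": "dissuaded", "d": "submissive"}
_POS_STATE = {"p": "pleased", "a": "aroused", "d": "dominant"}
_DIMS = ("p", "a", "d")


class NeutralRatingError(ValueError):
    """All three scaled PAD values are exactly zero: no dominant dimension."""


class UnknownEmotionError(KeyError):
    """An emotion word is missing from the affective-rating table."""


@dataclass(frozen=True)
class AffectiveRating:
    """An emotion word with raw PAD ratings on the 1-9 normative scale."""

    emotion: str
    p: float
    a: float
    d: float

    def __post_init__(self) -> None:
        for dim in _DIMS:
            v = getattr(self, dim)
            if not (1.0 <= v <= 9.0):
                raise ValueError(
                    f"rating {dim}={v} for emotion {self.emotion!r} "
                    "outside the admissible range [1, 9]"
                )


@dataclass(frozen=True)
class ScaledRating:
    """Centred PAD ratings in [-4, +4] (raw minus 5)."""

    emotion: str
    sp: float
    sa: float
    sd: float


def scale_rating(rating: AffectiveRating) -> ScaledRating:
    """Centre a raw 1-9 PAD rating by subtracting 5 from each dimension."""
    return ScaledRating(
        emotion=rating.emotion,
        sp=rating.p - 5.0,
        sa=rating.a - 5.0,
        sd=rating.d - 5.0,
    )


def dominant_state(scaled: ScaledRating) -> str:
    """Return the emotional state of the dominant PAD dimension.

    The dominant dimension is the one with the largest absolute scaled value;
    its sign gives the direction.  Ties prefer the first positive tied
    dimension in P->A->D order, then the first tied dimension overall.

    Raises
    ------
    NeutralRatingError
        If all three scaled values are exactly zero.
    """
    values = {"p": scaled.sp, "a": scaled.sa, "d": scaled.sd}
    mx = max(abs(v) for v in values.values())
    if mx == 0.0:
        raise NeutralRatingError(
            f"emotion {scaled.emotion!r} scales to (0, 0, 0); "
            "the dominant emotional state is undefined"
        )
    tied = [dim for dim in _DIMS if abs(values[dim]) == mx]
    for dim in tied:  # first positive tied dimension in PAD order
        if values[dim] > 0:
            return _POS_STATE[dim]
    return _NEG_STATE[tied[0]]


def label_events(
    events: Iterable[tuple[object, str]],
    table: pd.DataFrame,
) -> list[tuple[object, str]]:
    """Map (timestamp, emotion word) events to (timestamp, state) labels.

    ``table`` is an affective-rating table with columns emotion, p, a, d
    (see :func:`load_rating_table`).  Order is preserved; an unknown word
    raises :class:`UnknownEmotionError`.
    """
    ratings = {
        str(row.emotion): AffectiveRating(str(row.emotion), row.p, row.a, row.d)
        for row in table.itertuples(index=False)
    }
    out: list[tuple[object, str]] = []
    for ts, word in events:
        if word not in ratings:
            raise UnknownEmotionError(
                f"emotion word {word!r} not found in the rating table"
            )
        out.append((ts, dominant_state(scale_rating(ratings[word]))))
    return out


def load_rating_table(path) -> pd.DataFrame:
    """Read an affective-rating CSV (columns: emotion, p, a, d; UTF-8).

    Validates rating ranges and uniqueness of emotion identifiers.
    """
    df = pd.read_csv(path, encoding="utf-8", comment="#")
    required = {"emotion", "p", "a", "d"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rating table missing columns: {sorted(missing)}")
    dup = df["emotion"][df["emotion"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate emotion identifiers: {sorted(set(dup))}")
    for row in df.itertuples(index=False):
        AffectiveRating(str(row.emotion), row.p, row.a, row.d)  # range check
    return df[["emotion", "p", "a", "d"]].copy()


def load_example_ratings() -> pd.DataFrame:
    """Load the rating table shipped with the package.

    Contains the two published ANEW rows reproduced in the literature
    (happy, angry) plus a synthetic vocabulary covering all six states;
    the synthetic rows are labelled as such in the CSV.
    """
    ref = importlib.resources.files("emostate.data") / "ratings.csv"
    with importlib.resources.as_file(ref) as path:
        return load_rating_table(path)


def states_of_words(words: Sequence[str], table: pd.DataFrame) -> dict[str, str]:
    """Map each word in ``words`` to its dominant emotional state."""
    labeled = label_events([(i, w) for i, w in enumerate(words)], table)
    return {w: s for (_, s), w in zip(labeled, words)}
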