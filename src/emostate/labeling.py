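"""Targets for the two detection tasks: emotional states and transitions.

States are a six-class target: each window carries the dominant-dimension
state of the self-report(s) falling inside it (the last report wins when a
window holds several).  Transitions are binary: 1 when the state differs
from the reference previous state, 0 otherwise.  Because self-reports are
sparse, the default reference is the most recent *labeled* window, with the
gap available to models through the time-difference feature; a strict mode
restricts the reference to the immediately preceding grid window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mapping
from .preprocess import WindowedDataset, GRID

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledDataset",
    "assign_window_states",
    "transition_targets",
    "prune_rare_classes",
    "delta_features",
    "build_labeled_dataset",
]


@dataclass
class LabeledDataset:
    """Feature rows aligned with state and transition targets.

    ``y_state`` and ``y_transition`` are indexed like ``windowed.X``; NaN
    marks windows where the target is undefined (no self-report, or no
    previous reference for a transition).
    """

    windowed: WindowedDataset
    y_state: pd.Series
    y_transition: pd.Series

    @property
    def person(self) -> pd.Index:
        return self.windowed.X.index.get_level_values("person")


def assign_window_states(
    w: WindowedDataset,
    events: pd.DataFrame,
    rating_table: pd.DataFrame,
) -> pd.Series:
    """Label each 5-minute window with the state of its self-report(s).

    ``events`` has columns (person, timestamp, emotion).  Reports are
    floored onto the grid; if several fall in one window the most recent
    wins.  Windows without a report get NaN.  Reports outside the grid of a
    person's windows are ignored with a log message.
    """
    y = pd.Series(np.nan, index=w.X.index, dtype=object, name="y_state")
    if not len(events):
        return y
    ev = events.copy()
    ev["timestamp"] = pd.to_datetime(ev["timestamp"])
    labeled = mapping.label_events(
        list(zip(ev["timestamp"], ev["emotion"])), rating_table
    )
    ev["state"] = [s for _, s in labeled]
    ev["window_start"] = ev["timestamp"].dt.floor("5min")
    ev = ev.sort_values("timestamp", kind="stable")
    last = ev.groupby(["person", "window_start"], sort=False).last()
    hits = last.index.intersection(y.index)
    dropped = len(last) - len(hits)
    if dropped:
        logger.info("%d self-reports fell outside the window grid", dropped)
    y.loc[hits] = last.loc[hits, "state"]
    return y


def transition_targets(
    y_state: pd.Series,
    strict_consecutive: bool = False,
) -> pd.Series:
    """Binary change-of-state target per labeled window.

    For each labeled window whose person has a reference previous state,
    the target is 1 iff the state differs from that reference.  The
    reference is the person's most recent earlier labeled window, or — with
    ``strict_consecutive=True`` — only the immediately preceding grid
    window.  Windows without a reference get NaN.
    """
    y = pd.Series(np.nan, index=y_state.index, dtype=float, name="y_transition")
    for person, sub in y_state.groupby(level="person", sort=False):
        sub = sub.dropna()
        if len(sub) < 2:
            logger.warning(
                "person %s has %d labeled windows; transition target empty",
                person, len(sub),
            )
            continue
        sub = sub.sort_index(level="window_start")
        times = sub.index.get_level_values("window_start")
        states = sub.to_numpy()
        changed = (states[1:] != states[:-1]).astype(float)
        if strict_consecutive:
            gap_ok = (times[1:] - times[:-1]) == GRID
            vals = np.where(gap_ok, changed, np.nan)
        else:
            vals = changed
        y.loc[sub.index[1:]] = vals
    return y


def prune_rare_classes(
    y_state: pd.Series,
    threshold: int = 6,
) -> tuple[pd.Series, list[str]]:
    """Remove per-person state classes with at most ``threshold`` samples.

    Returns the pruned target (rare-class windows set to NaN) and the list
    of persons left with fewer than two classes, who are excluded from
    personalized state modeling.  The operation is idempotent: dropping a
    class cannot push another class below the threshold.
    """
    y = y_state.copy()
    excluded: list[str] = []
    for person, sub in y_state.groupby(level="person", sort=False):
        counts = sub.dropna().value_counts()
        rare = counts[counts <= threshold].index
        if len(rare):
            drop = sub.index[sub.isin(rare)]
            y.loc[drop] = np.nan
        if (counts > threshold).sum() < 2:
            excluded.append(person)
            logger.warning(
                "person %s left with <2 state classes after pruning; "
                "excluded from personalized state modeling", person,
            )
    return y, excluded


def delta_features(X: pd.DataFrame, persons: pd.Index | None = None) -> pd.DataFrame:
    """First differences of each feature within each person.

    Row ``t`` of the result holds ``f_t - f_{t-1}`` for every feature,
    computed within person only (rows must be time-ordered within person);
    each person's first row is dropped, having no predecessor.  Binary and
    ordinal columns are differenced like any other, so the telescoping
    identity (the per-person column sum of deltas equals last minus first)
    holds uniformly.
    """
    if persons is None:
        persons = X.index.get_level_values("person")
    grouped = X.groupby(pd.Index(persons, name="person"), sort=False)
    delta = grouped.diff()
    first = grouped.cumcount() == 0
    return delta[~first.to_numpy()]


def build_labeled_dataset(
    w: WindowedDataset,
    events: pd.DataFrame,
    rating_table: pd.DataFrame,
    strict_consecutive: bool = False,
) -> LabeledDataset:
    """Attach state and transition targets to a windowed dataset."""
    y_state = assign_window_states(w, events, rating_table)
    y_trans = transition_targets(y_state, strict_consecutive=strict_consecutive)
    return LabeledDataset(w, y_state, y_trans)
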