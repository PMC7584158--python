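"""Descriptive outputs: class proportions, importance charts, day grids.

All rendered data is first materialized as plain tables so downstream
checks can assert on numbers; figures are optional artifacts drawn from
those same tables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .preprocess import WINDOWS_PER_DAY

logger = logging.getLogger(__name__)

__all__ = ["class_proportions", "transition_proportions", "day_grid",
           "plot_day_grid", "plot_tally"]


def class_proportions(y: pd.Series) -> pd.DataFrame:
    """Per-person percentage of each class among that person's labeled rows.

    Rows are persons, columns the classes present anywhere; each row sums
    to 100 over the person's present classes.  Persons with no labeled rows
    yield an all-NaN row with a warning.
    """
    persons = sorted(set(y.index.get_level_values("person")))
    classes = sorted(set(y.dropna()))
    out = pd.DataFrame(np.nan, index=pd.Index(persons, name="person"), columns=classes)
    for person in persons:
        sub = y.xs(person, level="person").dropna()
        if not len(sub):
            logger.warning("person %s has no labeled windows", person)
            continue
        pct = sub.value_counts(normalize=True) * 100.0
        out.loc[person, pct.index] = pct
        out.loc[person] = out.loc[person].fillna(0.0)
    return out


def transition_proportions(y_transition: pd.Series) -> pd.DataFrame:
    """Per-person percentage of no-transition (0) vs transition (1) windows."""
    return class_proportions(y_transition)


def day_grid(values: pd.Series, person: str) -> pd.DataFrame:
    """Arrange one person's per-window categorical values as days x 288.

    ``values`` is indexed by (person, window_start) on the 5-minute grid;
    the result has one row per calendar day spanned and exactly 288
    columns (window-of-day); cells without a value are NaN (missing).
    """
    sub = values.xs(person, level="person")
    if not len(sub):
        return pd.DataFrame(columns=range(WINDOWS_PER_DAY))
    ts = sub.index
    day = ts.normalize()
    days = pd.date_range(day.min(), day.max(), freq="D")
    slot = (ts - day).total_seconds().astype(int) // 300
    grid = pd.DataFrame(np.full((len(days), WINDOWS_PER_DAY), np.nan, dtype=object),
                        index=days, columns=range(WINDOWS_PER_DAY))
    for d, s, v in zip(day, slot, sub.to_numpy()):
        grid.at[d, s] = v
    return grid


def plot_day_grid(grid: pd.DataFrame, ax=None, title: str = ""):
    """Render a day grid as a categorical heatmap (missing cells white)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib import colors

    cats = sorted({v for v in grid.to_numpy().ravel() if isinstance(v, str)})
    lut = {c: i for i, c in enumerate(cats)}
    img = np.full(grid.shape, np.nan)
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            v = grid.iat[i, j]
            if isinstance(v, str):
                img[i, j] = lut[v]
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 0.5 * max(1, len(grid))))
    cmap = plt.get_cmap("tab10", max(1, len(cats)))
    cmap = colors.ListedColormap([cmap(i) for i in range(max(1, len(cats)))])
    cmap.set_bad("white")
    ax.imshow(np.ma.masked_invalid(img), aspect="auto", cmap=cmap,
              interpolation="nearest")
    ax.set_xlabel("5-min window of day")
    ax.set_ylabel("day")
    ax.set_title(title)
    handles = [plt.Rectangle((0, 0), 1, 1, color=cmap(i)) for i in range(len(cats))]
    if cats:
        ax.legend(handles, cats, loc="upper right", fontsize="x-small")
    return ax


def plot_tally(tally: pd.DataFrame, ax=None, title: str = ""):
    """Stacked bar chart of the 7x3 category-by-rank importance tally."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    bottom = np.zeros(len(tally))
    for rank in tally.columns:
        ax.bar(tally.index, tally[rank], bottom=bottom, label=f"rank {rank}")
        bottom += tally[rank].to_numpy()
    ax.set_ylabel("top-3 appearances")
    ax.tick_params(axis="x", rotation=45)
    ax.legend()
    ax.set_title(title)
    return ax
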