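"""Synthetic multi-person per-minute sensor/context streams.

The generator emulates the structure of free-living smartphone/smartwatch
collections: each person follows a daily schedule of context states
(sleeping at home, working, out with friends, ...), continuous channels
respond to the context (motion magnitude high outdoors, low asleep),
binary phone-state and context-label channels flip with context-dependent
probabilities, location is a per-context anchor plus small jitter, and
emotion words are self-reported sparsely.  Two dials shape downstream
difficulty:

``rho`` (regularity)
    Probability that a self-report is the word dictated by the current
    context (the rest are uniform over the vocabulary).  ``rho=1`` makes
    emotion a deterministic function of context — the best case for
    detection; ``rho=0`` severs the link entirely.
``missing_rate``
    Probability that a whole 5-minute window (records and reports) is
    deleted, matching the 38-89 % missing-window range typical of this
    kind of data.

Everything is a pure function of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mapping import load_example_ratings
from .preprocess import FeatureSchema, SensorTable, WINDOWS_PER_DAY

__all__ = [
    "Context",
    "PersonProfile",
    "GeneratorConfig",
    "DEFAULT_CONTEXTS",
    "DEFAULT_SCHEDULE",
    "default_profiles",
    "generate",
    "summarize",
]

#: Collection start (a Monday), shared by all synthetic persons.
START = pd.Timestamp("2016-03-07")


@dataclass(frozen=True)
class Context:
    """A daily-life context state with its sensor signature."""

    name: str
    emotion: str          # word emitted under full regularity
    anchor: tuple[float, float]   # (lat, lon); anchors sit >= 100 m apart
    motion: float         # mean motion magnitude
    audio: float          # mean audio level


# Anchors are ~200-400 m apart so precision-8 geohash cells separate them.
DEFAULT_CONTEXTS = {
    "home_sleep": Context("home_sleep", "sleepy", (32.8800, -117.2300), 0.05, 0.10),
    "home_tv": Context("home_tv", "calm", (32.8800, -117.2300), 0.20, 0.80),
    "work": Context("work", "content", (32.8820, -117.2280), 0.50, 0.50),
    "outdoors": Context("outdoors", "excited", (32.8840, -117.2350), 1.50, 0.60),
    "with_friends": Context("with_friends", "happy", (32.8780, -117.2330), 0.80, 1.20),
}

#: Hour-block schedule: (start hour, end hour, context name).
DEFAULT_SCHEDULE = (
    (0, 8, "home_sleep"),
    (8, 17, "work"),
    (17, 20, "with_friends"),
    (20, 24, "home_tv"),
)


@dataclass
class PersonProfile:
    """One synthetic person's conditions."""

    person_id: str
    n_days: int = 7
    rho: float = 0.99
    missing_rate: float = 0.6
    schedule: tuple = DEFAULT_SCHEDULE
    context_emotions: dict[str, str] | None = None  # overrides Context.emotion
    report_gap_minutes: tuple[int, int] = (10, 60)

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class GeneratorConfig:
    """Full recipe for one synthetic collection.

    The seed determines the stream completely; the vocabulary (emotion
    words and their PAD ratings) defaults to the table shipped with the
    package.
    """

    profiles: list[PersonProfile]
    schema: FeatureSchema = field(default_factory=FeatureSchema.compact)
    contexts: dict[str, Context] = field(default_factory=lambda: dict(DEFAULT_CONTEXTS))
    rating_table: pd.DataFrame = field(default_factory=load_example_ratings)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("profile list is empty")
        vocab = set(self.rating_table["emotion"])
        for ctx in self.contexts.values():
            if ctx.emotion not in vocab:
                raise ValueError(f"context word {ctx.emotion!r} missing from rating table")
        for prof in self.profiles:
            for _, _, name in prof.schedule:
                if name not in self.contexts:
                    raise ValueError(f"schedule of {prof.person_id!r} uses "
                                     f"unknown context {name!r}")
            if prof.context_emotions:
                bad = set(prof.context_emotions.values()) - vocab
                if bad:
                    raise ValueError(f"override words missing from rating table: {bad}")


def default_profiles(
    n_persons: int = 18,
    seed: int = 0,
    permute_emotions: bool = False,
) -> list[PersonProfile]:
    """Profiles emulating the study population shape.

    Collection lengths cycle over 3-9 days, missing rates span 0.38-0.88,
    and regularity is high (0.99) so state transitions stay rare.  With
    ``permute_emotions=True`` each person gets an individually shuffled
    context-to-word mapping — a heterogeneous population on which general
    (cross-person) models should struggle while personalized ones succeed.
    """
    rng = np.random.default_rng(seed)
    days_cycle = [3, 8, 7, 8, 8, 8, 8, 8, 7, 8, 8, 8, 9, 7, 8, 7, 3, 7]
    miss = np.linspace(0.38, 0.88, n_persons)
    words = [c.emotion for c in DEFAULT_CONTEXTS.values()]
    names = list(DEFAULT_CONTEXTS)
    profiles = []
    for i in range(n_persons):
        overrides = None
        if permute_emotions:
            overrides = dict(zip(names, rng.permutation(words)))
        profiles.append(PersonProfile(
            person_id=f"P{i + 1:02d}",
            n_days=days_cycle[i % len(days_cycle)],
            rho=0.99,
            missing_rate=float(miss[i]),
            context_emotions=overrides,
        ))
    return profiles


# ----------------------------------------------------------------------

def _context_index_per_minute(schedule, contexts) -> np.ndarray:
    names = list(contexts)
    idx = np.empty(24 * 60, dtype=int)
    idx[:] = -1
    for start, end, name in schedule:
        idx[start * 60:end * 60] = names.index(name)
    if (idx < 0).any():
        raise ValueError("schedule does not cover all 24 hours")
    return idx


def generate(config: GeneratorConfig) -> SensorTable:
    """Generate the per-minute long-form stream described by ``config``."""
    rng = np.random.default_rng(config.seed)
    schema = config.schema
    contexts = list(config.contexts.values())
    names = [c.name for c in contexts]
    channels = schema.names

    # structural parameters, drawn once: per-channel gains and
    # per-(context, channel) levels/probabilities
    gains = {c: rng.uniform(0.5, 1.5) for c in channels}
    env_mean = rng.uniform(0.0, 1.0, size=(len(contexts), len(channels)))
    phone_p = rng.uniform(0.05, 0.95, size=(len(contexts), len(channels)))

    ctx_channels = [c for c in channels if schema.category(c) == "contextual"]

    rec_frames = []
    ev_frames = []
    for prof in sorted(config.profiles, key=lambda p: p.person_id):
        ctx_idx_day = _context_index_per_minute(prof.schedule, config.contexts)
        n_min = prof.n_days * 24 * 60
        ts = START + pd.to_timedelta(np.arange(n_min), unit="min")
        ctx_idx = np.tile(ctx_idx_day, prof.n_days)
        motion_level = np.array([c.motion for c in contexts])[ctx_idx]
        audio_level = np.array([c.audio for c in contexts])[ctx_idx]
        anchors = np.array([c.anchor for c in contexts])

        wide = np.empty((n_min, len(channels)))
        for j, ch in enumerate(channels):
            cat = schema.category(ch)
            kind = schema.kind(ch)
            if ch == "latitude":
                wide[:, j] = anchors[ctx_idx, 0] + rng.normal(0, 5e-5, n_min)
            elif ch == "longitude":
                wide[:, j] = anchors[ctx_idx, 1] + rng.normal(0, 5e-5, n_min)
            elif cat == "motion" or (cat == "location"):
                wide[:, j] = gains[ch] * motion_level + rng.normal(0, 0.2, n_min)
            elif cat == "audio":
                wide[:, j] = gains[ch] * audio_level + rng.normal(0, 0.2, n_min)
            elif cat == "environmental":
                wide[:, j] = env_mean[ctx_idx, j] + rng.normal(0, 0.1, n_min)
            elif cat == "phone_state":
                wide[:, j] = (rng.random(n_min) < phone_p[ctx_idx, j]).astype(float)
            elif cat == "contextual":
                pos = ctx_channels.index(ch)
                if pos < len(contexts):
                    base = (ctx_idx == pos).astype(float)
                    flip = rng.random(n_min) < 0.01
                    wide[:, j] = np.where(flip, 1.0 - base, base)
                else:
                    wide[:, j] = (rng.random(n_min) < 0.3).astype(float)
            else:
                wide[:, j] = rng.normal(0, 1, n_min)

        # sparse self-reports
        word_of = {c.name: c.emotion for c in contexts}
        if prof.context_emotions:
            word_of.update(prof.context_emotions)
        vocab = list(config.rating_table["emotion"])
        lo, hi = prof.report_gap_minutes
        report_min: list[int] = []
        t = int(rng.integers(lo, hi + 1))
        while t < n_min:
            report_min.append(t)
            t += int(rng.integers(lo, hi + 1))
        report_min_arr = np.array(report_min, dtype=int)
        words = []
        for m in report_min_arr:
            if rng.random() < prof.rho:
                words.append(word_of[names[ctx_idx[m]]])
            else:
                words.append(vocab[rng.integers(len(vocab))])

        # whole-window deletion
        n_win = prof.n_days * WINDOWS_PER_DAY
        keep_win = rng.random(n_win) >= prof.missing_rate
        keep_minute = np.repeat(keep_win, 5)

        kept = np.flatnonzero(keep_minute)
        long = pd.DataFrame({
            "person": prof.person_id,
            "timestamp": np.repeat(ts[kept], len(channels)),
            "channel": np.tile(channels, len(kept)),
            "value": wide[kept].ravel(),
        })
        rec_frames.append(long)

        if len(report_min_arr):
            rep_keep = keep_minute[report_min_arr]
            ev_frames.append(pd.DataFrame({
                "person": prof.person_id,
                "timestamp": ts[report_min_arr[rep_keep]],
                "emotion": np.array(words)[rep_keep],
            }))

    records = pd.concat(rec_frames, ignore_index=True)
    events = (pd.concat(ev_frames, ignore_index=True) if ev_frames
              else pd.DataFrame(columns=["person", "timestamp", "emotion"]))
    return SensorTable(records, schema, events)


def summarize(table: SensorTable) -> pd.DataFrame:
    """Per-person data summary: days, complete 5-minute windows, % missing.

    A window counts as complete when at least one record falls in it; the
    denominator is 288 windows per calendar day spanned.  Persons present
    only in the event table get 0 windows and 100 % missing.
    """
    rows = []
    rec = table.records
    for person in table.persons():
        sub = rec[rec["person"] == person]
        if not len(sub):
            rows.append({"person": person, "days": 0,
                         "complete_windows": 0, "missing_pct": 100.0})
            continue
        ts = pd.to_datetime(sub["timestamp"])
        days = (ts.max().normalize() - ts.min().normalize()).days + 1
        n_windows = ts.dt.floor("5min").nunique()
        total = days * WINDOWS_PER_DAY
        rows.append({
            "person": person,
            "days": days,
            "complete_windows": int(n_windows),
            "missing_pct": 100.0 * (1.0 - n_windows / total),
        })
    return pd.DataFrame(rows)
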