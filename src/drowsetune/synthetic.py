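"""Synthetic EEG sessions, melodies and listening tables with planted structure.

These generators stand in for hardware and human subjects so every stage
of the pipeline can be exercised end to end:

* :func:`gen_eeg` renders a session plan (alternating drowsy/alert
  segments) as a sum of one sinusoid per clinical band plus Gaussian
  noise.  The default state profiles follow the classical amplitude
  physiology — drowsiness elevates alpha (30-50 uV) and theta (up to
  30 uV) activity while suppressing beta; alertness elevates beta —
  which makes drowsy and alert windows linearly separable in
  relative-energy space.
* :func:`gen_notes` random-walks a melody with controllable pitch range,
  interval spread and duration range.
* :func:`gen_user_table` plants a known refreshing rule (optionally
  corrupted by label noise) in a song table so tree recovery is testable.
* :func:`closed_loop_sim` replays the weekly recommend-observe-retrain
  protocol against a simulated driver.

All generators are bit-reproducible under a fixed seed.  One sinusoid per
band (rather than filtered noise) keeps the band energies analytically
predictable, at the cost of realism: real EEG has broadband structure,
artifacts and non-stationarity that these traces do not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eeg import BANDS, BAND_ORDER, RawSignal
from .midi import Note, NoteSequence
from .music import FEATURE_COLUMNS, extract_features
from .refresh import build_tree, pick_song, schedule_probs, score_music, update_user_table

__all__ = [
    "EegStateProfile",
    "DROWSY_PROFILE",
    "ALERT_PROFILE",
    "SessionPlan",
    "MusicStyleProfile",
    "gen_eeg",
    "gen_notes",
    "song_catalog",
    "gen_user_table",
    "closed_loop_sim",
]


@dataclass(frozen=True)
class EegStateProfile:
    """Per-band sinusoid amplitude ranges (uV) plus broadband noise level."""

    delta: tuple[float, float]
    theta: tuple[float, float]
    alpha: tuple[float, float]
    beta: tuple[float, float]
    noise_sd: float = 2.0

    def amplitude_range(self, band: str) -> tuple[float, float]:
        rng_ = getattr(self, band)
        if rng_[0] < 0 or rng_[1] < rng_[0]:
            raise ValueError(f"invalid amplitude range for {band}: {rng_}")
        return rng_


#: Drowsy state: strong alpha (30-50 uV), moderate theta, little beta.
DROWSY_PROFILE = EegStateProfile(
    delta=(5.0, 15.0), theta=(10.0, 30.0), alpha=(30.0, 50.0), beta=(2.0, 5.0)
)

#: Alert state: dominant beta (baseline 5-20 uV scaled up), alpha blocked.
ALERT_PROFILE = EegStateProfile(
    delta=(5.0, 15.0), theta=(2.0, 8.0), alpha=(5.0, 15.0), beta=(15.0, 60.0)
)

DEFAULT_PROFILES = {"drowsy": DROWSY_PROFILE, "alert": ALERT_PROFILE}


@dataclass
class SessionPlan:
    """Ordered (state, duration_seconds) segments of a simulated drive."""

    segments: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a session plan needs at least one segment")
        for state, duration in self.segments:
            if state not in ("drowsy", "alert"):
                raise ValueError(f"unknown state {state!r}")
            if duration <= 0:
                raise ValueError("segment durations must be positive")

    @classmethod
    def alternating(cls, n_segments: int, segment_s: float,
                    start: str = "drowsy") -> "SessionPlan":
        other = "alert" if start == "drowsy" else "drowsy"
        states = [start if i % 2 == 0 else other for i in range(n_segments)]
        return cls([(s, segment_s) for s in states])

    @property
    def total_seconds(self) -> float:
        return sum(d for _, d in self.segments)


def gen_eeg(
    plan: SessionPlan,
    fs: float = 500.0,
    seed: int = 0,
    profiles: dict[str, EegStateProfile] | None = None,
    T: int = 1000,
) -> tuple[RawSignal, np.ndarray]:
    """Render a session plan as a band-structured EEG trace.

    Each segment is the sum of one sinusoid per band — frequency uniform
    inside the band, amplitude uniform in the state profile's range,
    random phase — plus white Gaussian noise.  Per-window labels
    (1 = drowsy) are assigned by majority state over each T-sample window.

    Returns
    -------
    (RawSignal, labels)
        ``labels`` has one 0/1 entry per non-overlapping T-sample window.
    """
    profiles = profiles or DEFAULT_PROFILES
    rng = np.random.default_rng(seed)
    pieces: list[np.ndarray] = []
    states: list[np.ndarray] = []
    for state, duration in plan.segments:
        n = int(round(duration * fs))
        t = np.arange(n) / fs
        prof = profiles[state]
        seg = np.zeros(n)
        for band in BAND_ORDER:
            lo, hi = BANDS[band]
            freq = rng.uniform(lo, hi)
            a_lo, a_hi = prof.amplitude_range(band)
            amp = rng.uniform(a_lo, a_hi)
            phase = rng.uniform(0, 2 * np.pi)
            seg += amp * np.sin(2 * np.pi * freq * t + phase)
        if prof.noise_sd > 0:
            seg += rng.normal(0, prof.noise_sd, size=n)
        pieces.append(seg)
        states.append(np.full(n, 1 if state == "drowsy" else 0, dtype=int))
    samples = np.concatenate(pieces)
    state_per_sample = np.concatenate(states)
    n_windows = samples.size // T
    labels = np.array(
        [
            int(state_per_sample[i * T : (i + 1) * T].mean() >= 0.5)
            for i in range(n_windows)
        ]
    )
    return RawSignal(samples=samples, fs=fs), labels


@dataclass
class MusicStyleProfile:
    """Controls for the melody random walk."""

    pitch_range: tuple[int, int] = (48, 84)
    duration_range: tuple[float, float] = (0.2, 0.8)
    interval_spread: float = 2.0  # std dev of the pitch step, semitones
    start_pitch: int | None = None
    planted_refreshing_rule: object | None = None  # predicate over features

    def __post_init__(self) -> None:
        lo, hi = self.pitch_range
        if not (0 <= lo <= hi <= 127):
            raise ValueError("pitch range must satisfy 0 <= lo <= hi <= 127")
        dlo, dhi = self.duration_range
        if not (0 < dlo <= dhi):
            raise ValueError("duration range must satisfy 0 < lo <= hi")
        if self.interval_spread < 0:
            raise ValueError("interval spread must be non-negative")


def gen_notes(style: MusicStyleProfile, n_notes: int, seed: int = 0) -> NoteSequence:
    """Random-walk melody: consecutive notes, seeded and reproducible.

    Pitch steps are rounded Gaussian draws with the style's spread,
    reflected into the pitch range; durations are uniform in the style's
    range, quantized to 1 ms so rhythm classes are well defined.
    """
    if n_notes < 2:
        raise ValueError("a melody needs at least 2 notes")
    rng = np.random.default_rng(seed)
    lo, hi = style.pitch_range
    pitch = style.start_pitch if style.start_pitch is not None else (lo + hi) // 2
    pitch = int(np.clip(pitch, lo, hi))
    dlo, dhi = style.duration_range
    notes: list[Note] = []
    t = 0.0
    for _ in range(n_notes):
        duration = max(round(rng.uniform(dlo, dhi), 3), 1e-3)
        notes.append(Note(pitch=pitch, start=t, end=t + duration))
        t += duration
        step = int(round(rng.normal(0, style.interval_spread))) if style.interval_spread > 0 else 0
        pitch = int(np.clip(pitch + step, lo, hi))
    return NoteSequence(notes)


def song_catalog(
    n_songs: int,
    seed: int = 0,
    n_notes: int = 40,
    ad_gap: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Feature table (music_id, F1..F6) for a batch of generated songs.

    Per-song style parameters are drawn at random so features spread over
    a realistic range.  ``ad_gap`` excludes a band of average durations,
    producing a catalog separable with margin on the F4 (average-duration)
    axis — useful when a planted duration rule must have no borderline
    songs.
    """
    if n_songs < 1:
        raise ValueError("catalog needs at least one song")
    rng = np.random.default_rng(seed)
    rows = []
    for mid in range(n_songs):
        center = int(rng.integers(40, 90))
        width = int(rng.integers(6, 18))
        base = rng.uniform(0.15, 1.2)
        if ad_gap is not None:
            lo_gap, hi_gap = ad_gap
            while lo_gap < base < hi_gap:
                base = rng.uniform(0.15, 1.2)
        style = MusicStyleProfile(
            pitch_range=(max(0, center - width), min(127, center + width)),
            duration_range=(max(1e-3, base * 0.8), base * 1.2),
            interval_spread=rng.uniform(0.5, 4.0),
        )
        seq = gen_notes(style, n_notes=n_notes, seed=int(rng.integers(2**31)))
        fv = extract_features(seq)
        rows.append({"music_id": mid, **fv.as_dict()})
    return pd.DataFrame(rows, columns=["music_id", *FEATURE_COLUMNS])


def gen_user_table(
    n_songs: int,
    rule,
    noise_rate: float = 0.0,
    seed: int = 0,
    n_notes: int = 40,
    ad_gap: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Listening table whose refreshing labels follow a planted rule.

    ``rule`` is a predicate over a feature row (mapping F1..F6 to floats);
    each label is flipped with probability ``noise_rate``.
    """
    if not 0 <= noise_rate < 1:
        raise ValueError("noise_rate must lie in [0, 1)")
    catalog = song_catalog(n_songs, seed=seed, n_notes=n_notes, ad_gap=ad_gap)
    rng = np.random.default_rng(seed + 1)
    labels = []
    for _, row in catalog.iterrows():
        y = bool(rule(row))
        if noise_rate > 0 and rng.random() < noise_rate:
            y = not y
        labels.append("yes" if y else "no")
    table = catalog.copy()
    table["refreshing"] = labels
    return table


def closed_loop_sim(
    catalog: pd.DataFrame,
    driver_response,
    weeks: int = 6,
    events_per_week: int = 30,
    seed: int = 0,
    max_height: int = 25,
    tree=None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Weekly recommend-observe-retrain loop against a simulated driver.

    Each drowsy event picks a song from the current play schedule; the
    recommendation is successful when ``driver_response(features_row)`` is
    true (the music stopped the drowsy episode).  Outcomes accumulate in
    the user table (latest label per song wins) and the decision tree is
    rebuilt at the end of each week.  Week one runs with no tree — a
    uniform schedule — unless an initial ``tree`` is supplied.

    Returns
    -------
    (precision, table)
        ``precision[w]`` is successful/total recommendations in week w.
    """
    if catalog.empty:
        raise ValueError("catalog must be non-empty")
    rng = np.random.default_rng(seed)
    feature_rows = catalog.set_index("music_id")[list(FEATURE_COLUMNS)]
    table = pd.DataFrame(columns=["music_id", *FEATURE_COLUMNS, "refreshing"])
    precision = np.empty(weeks)
    for week in range(weeks):
        if tree is None:
            schedule = pd.Series(
                1.0 / len(feature_rows), index=feature_rows.index
            )
        else:
            scores = {
                mid: score_music(tree, row.to_numpy())
                for mid, row in feature_rows.iterrows()
            }
            schedule = schedule_probs(scores)
        successes = 0
        for _ in range(events_per_week):
            mid = pick_song(schedule, seed=rng)
            row = feature_rows.loc[mid]
            ok = bool(driver_response(row))
            successes += ok
            table = update_user_table(
                table, mid, "refreshed" if ok else "not_refreshed",
                features=row.to_dict(),
            )
        precision[week] = successes / events_per_week
        tree = build_tree(table, max_height=max_height)
    return precision, table
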