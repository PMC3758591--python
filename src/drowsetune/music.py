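"""Six symbolic-music features of a melody, computed from its note list.

The features summarize what a listener hears at a glance: how high the
melody sits (average pitch), how varied the pitches are (pitch entropy),
how much of the 128-pitch MIDI range it touches (pitch density), how fast
it moves (average duration), how varied its rhythm is (duration entropy),
and how varied its contour is independent of key (pitch-interval entropy).
All entropies are in bits (base-2 logarithm).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .midi import NoteSequence

__all__ = [
    "MusicFeatureVector",
    "FEATURE_COLUMNS",
    "average_pitch",
    "pitch_entropy",
    "pitch_density",
    "average_duration",
    "duration_entropy",
    "pitch_interval_entropy",
    "extract_features",
    "features_to_frame",
]

#: Table layout: feature columns F1..F6 in extraction order
FEATURE_COLUMNS: tuple[str, ...] = ("F1", "F2", "F3", "F4", "F5", "F6")

#: seconds grid used when binning note durations for the entropy count,
#: so tempo arithmetic cannot split one rhythmic value into two classes
DURATION_QUANTUM = 1e-3


@dataclass(frozen=True)
class MusicFeatureVector:
    """The (AP, PE, PD, AD, DE, PIE) feature vector of one piece."""

    AP: float   # average pitch, MIDI pitch units
    PE: float   # pitch entropy, bits
    PD: float   # pitch density, fraction of the 128 available pitches
    AD: float   # average note duration, seconds
    DE: float   # duration entropy, bits
    PIE: float  # pitch-interval entropy, bits

    def as_array(self) -> np.ndarray:
        return np.array([self.AP, self.PE, self.PD, self.AD, self.DE, self.PIE])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_COLUMNS, self.as_array()))


def _entropy_bits(counts) -> float:
    counts = np.asarray(list(counts), dtype=float)
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def average_pitch(seq: NoteSequence) -> float:
    """Mean MIDI pitch over the note sequence."""
    return float(np.mean(seq.pitches))


def pitch_entropy(seq: NoteSequence) -> float:
    """Entropy (bits) of the distribution of pitch occurrence counts."""
    return _entropy_bits(Counter(seq.pitches).values())


def pitch_density(seq: NoteSequence) -> float:
    """Number of distinct pitches over the 128 available MIDI pitches."""
    return len(set(seq.pitches)) / 128.0


def average_duration(seq: NoteSequence) -> float:
    """Mean note duration in seconds."""
    return float(np.mean(seq.durations))


def _quantize(duration: float) -> int:
    return round(duration / DURATION_QUANTUM)


def duration_entropy(seq: NoteSequence) -> float:
    """Entropy (bits) of note-duration counts, on a 1 ms grid."""
    return _entropy_bits(Counter(_quantize(d) for d in seq.durations).values())


def pitch_interval_entropy(seq: NoteSequence) -> float:
    """Entropy (bits) of successive-pitch intervals; key-invariant.

    The interval string v[i+1] - v[i] has length n - 1, so at least two
    notes are required.
    """
    if len(seq) < 2:
        raise ValueError("pitch-interval entropy needs at least 2 notes")
    pitches = seq.pitches
    intervals = [b - a for a, b in zip(pitches, pitches[1:])]
    return _entropy_bits(Counter(intervals).values())


def extract_features(seq: NoteSequence) -> MusicFeatureVector:
    """All six features of one melody (needs at least 2 notes)."""
    return MusicFeatureVector(
        AP=average_pitch(seq),
        PE=pitch_entropy(seq),
        PD=pitch_density(seq),
        AD=average_duration(seq),
        DE=duration_entropy(seq),
        PIE=pitch_interval_entropy(seq),
    )


def features_to_frame(features: dict[object, MusicFeatureVector]) -> pd.DataFrame:
    """Build a music_id, F1..F6 table from per-piece feature vectors."""
    rows = [{"music_id": mid, **fv.as_dict()} for mid, fv in features.items()]
    return pd.DataFrame(rows, columns=["music_id", *FEATURE_COLUMNS])
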