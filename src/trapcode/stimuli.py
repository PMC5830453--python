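"""Playback schedules and call annotations.

Builds the three stimulus protocols used both for activity-dependent tagging
(long pure-tone or natural-call playback) and for electrophysiological
characterization (pseudo-random frequency-response-area grids, repeated call
presentations at several attenuation levels), and implements the
syllable-wise time reversal used to construct "flipped" control calls.

Conventions
-----------
* Inter-stimulus interval (ISI) is offset-to-onset everywhere.
* A schedule only contains complete stimulus periods: a partial period at the
  end of ``total_time`` is dropped.
* Attenuation is stored in dB relative to the maximum playback level;
  absolute SPL is carried as metadata only.
* Syllable windows are half-open ``[onset, onset + duration)``; when windows
  are converted to samples the boundary sample belongs to the earlier window.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "Syllable",
    "CallStimulus",
    "ScheduleEvent",
    "StimSchedule",
    "build_tone_protocol",
    "build_fra_protocol",
    "build_call_protocol",
    "flip_syllables",
    "read_call_annotations",
    "write_call_annotations",
    "read_waveform",
    "write_waveform",
]


@dataclass(frozen=True)
class Syllable:
    """A single syllable window within a call, in seconds from call start."""

    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"syllable onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"syllable duration must be > 0, got {self.duration}")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class CallStimulus:
    """A natural call: ordered syllable annotations plus an optional waveform.

    Parameters
    ----------
    name
        Stimulus label, e.g. ``"USV"`` or ``"WC"``.
    syllables
        Non-overlapping syllables sorted by onset.
    total_duration
        Length of the playback unit in seconds (3 s in the tagging protocol).
    waveform, sample_rate
        Optional audio samples; vocalizations are typically recorded at very
        high rates (up to 500 kHz), stored as float arrays.
    """

    name: str
    syllables: list[Syllable]
    total_duration: float
    waveform: np.ndarray | None = None
    sample_rate: float | None = None

    def __post_init__(self) -> None:
        if len(self.syllables) < 1:
            raise ValueError("a call must contain at least one syllable")
        self.syllables = sorted(self.syllables, key=lambda s: s.onset)
        prev_off = 0.0
        for i, syl in enumerate(self.syllables):
            if i > 0 and syl.onset < prev_off:
                raise ValueError(
                    f"syllables overlap: syllable {i} starts at {syl.onset}s "
                    f"before previous offset {prev_off}s"
                )
            if syl.offset > self.total_duration:
                raise ValueError(
                    f"syllable [{syl.onset}, {syl.offset}) s exceeds call "
                    f"duration {self.total_duration} s"
                )
            prev_off = syl.offset
        if self.waveform is not None:
            if self.sample_rate is None or self.sample_rate <= 0:
                raise ValueError("waveform requires a positive sample_rate")
            self.waveform = np.asarray(self.waveform, dtype=float)

    @property
    def n_syllables(self) -> int:
        return len(self.syllables)


@dataclass(frozen=True)
class ScheduleEvent:
    """One stimulus presentation: onset time, stimulus id and level."""

    onset: float
    stimulus_id: str
    level: float  # dB SPL for tones, attenuation dB for calls
    duration: float
    freq: float | None = None  # Hz, tone protocols only


@dataclass
class StimSchedule:
    """An ordered presentation sequence with strictly increasing onsets."""

    events: list[ScheduleEvent]
    stimulus_kind: str  # "tone" | "call"
    isi: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        onsets = np.array([e.onset for e in self.events])
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise ValueError("schedule onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [e.onset for e in self.events],
                "stimulus_id": [e.stimulus_id for e in self.events],
                "level_db": [e.level for e in self.events],
                "duration_s": [e.duration for e in self.events],
                "freq_hz": [e.freq for e in self.events],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "stimulus_kind": self.stimulus_kind,
            "isi": self.isi,
            "metadata": self.metadata,
            "events": self.to_frame().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path, stimulus_kind: str, isi: float) -> "StimSchedule":
        df = pd.read_csv(path)
        events = [
            ScheduleEvent(
                onset=row.onset_s,
                stimulus_id=str(row.stimulus_id),
                level=row.level_db,
                duration=row.duration_s,
                freq=None if pd.isna(row.freq_hz) else row.freq_hz,
            )
            for row in df.itertuples()
        ]
        return cls(events=events, stimulus_kind=stimulus_kind, isi=isi)

    @classmethod
    def from_json(cls, path: str | Path) -> "StimSchedule":
        payload = json.loads(Path(path).read_text())
        events = [
            ScheduleEvent(
                onset=e["onset_s"],
                stimulus_id=str(e["stimulus_id"]),
                level=e["level_db"],
                duration=e["duration_s"],
                freq=e.get("freq_hz"),
            )
            for e in payload["events"]
        ]
        return cls(
            events=events,
            stimulus_kind=payload["stimulus_kind"],
            isi=payload["isi"],
            metadata=payload.get("metadata", {}),
        )


def build_tone_protocol(
    tone_duration: float,
    isi: float,
    total_time: float,
    freq: float,
    level: float,
    stimulus_id: str = "tone",
) -> StimSchedule:
    """Tile ``[0, total_time]`` with identical stimuli at a fixed period.

    The period is ``tone_duration + isi`` (ISI offset-to-onset) and the event
    count is ``floor(total_time / period)``: one hour of 100 ms tones with a
    900 ms ISI yields 3600 presentations; one hour of 3 s calls with a 1 s
    ISI yields 900.
    """
    if tone_duration <= 0 or isi <= 0 or total_time <= 0:
        raise ValueError("tone_duration, isi and total_time must all be > 0")
    period = tone_duration + isi
    n_events = int(math.floor(total_time / period + 1e-12))
    events = [
        ScheduleEvent(onset=i * period, stimulus_id=stimulus_id, level=level,
                      duration=tone_duration, freq=freq)
        for i in range(n_events)
    ]
    return StimSchedule(events=events, stimulus_kind="tone", isi=isi,
                        metadata={"total_time_s": total_time})


def build_fra_protocol(
    n_freqs: int,
    freq_range: tuple[float, float],
    n_levels: int,
    levels: Sequence[float],
    n_reps: int,
    isi: float,
    seed: int,
    tone_duration: float = 0.1,
) -> StimSchedule:
    """Pseudo-random frequency x level grid for frequency-response areas.

    ``n_freqs`` log-spaced frequencies over ``freq_range`` crossed with the
    given sound levels, each combination presented exactly ``n_reps`` times,
    in a single seeded shuffle of the full trial list (30 freqs x 4 levels x
    12 reps = 1440 trials in the characterization protocol).
    """
    if n_freqs < 1 or n_levels < 1 or n_reps < 1:
        raise ValueError("n_freqs, n_levels and n_reps must all be >= 1")
    levels = list(levels)
    if len(levels) == 0:
        raise ValueError("levels must be a non-empty list")
    if len(levels) != n_levels:
        raise ValueError(f"expected {n_levels} levels, got {len(levels)}")
    freqs = np.logspace(np.log10(freq_range[0]), np.log10(freq_range[1]), n_freqs)
    combos = [(f, lv) for f in freqs for lv in levels for _ in range(n_reps)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combos))
    period = tone_duration + isi
    events = [
        ScheduleEvent(
            onset=i * period,
            stimulus_id=f"tone_{combos[j][0]:.0f}Hz_{combos[j][1]:g}dB",
            level=combos[j][1],
            duration=tone_duration,
            freq=combos[j][0],
        )
        for i, j in enumerate(order)
    ]
    return StimSchedule(events=events, stimulus_kind="tone", isi=isi,
                        metadata={"freqs_hz": freqs.tolist(), "levels_db": levels,
                                  "n_reps": n_reps, "seed": seed})


def build_call_protocol(
    call: CallStimulus,
    n_reps_per_level: int,
    attenuations: Sequence[float],
    isi: float,
    seed: int,
) -> StimSchedule:
    """Repeated presentation of one call at several attenuation levels.

    Each attenuation appears exactly ``n_reps_per_level`` times (20 reps x 3
    levels = 60 trials in the recording protocol); presentation order is a
    seeded shuffle.
    """
    if n_reps_per_level < 1:
        raise ValueError("n_reps_per_level must be >= 1")
    attenuations = list(attenuations)
    if len(attenuations) == 0:
        raise ValueError("attenuations must be a non-empty list")
    trials = [att for att in attenuations for _ in range(n_reps_per_level)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    period = call.total_duration + isi
    events = [
        ScheduleEvent(onset=i * period, stimulus_id=call.name,
                      level=trials[j], duration=call.total_duration)
        for i, j in enumerate(order)
    ]
    return StimSchedule(events=events, stimulus_kind="call", isi=isi,
                        metadata={"attenuations_db": attenuations,
                                  "n_reps_per_level": n_reps_per_level,
                                  "seed": seed})


def flip_syllables(call: CallStimulus) -> CallStimulus:
    """Time-reverse the waveform inside each syllable window.

    Samples outside every syllable window are left untouched and the syllable
    annotations are unchanged, producing a control stimulus with identical
    envelope timing but reversed fine structure. The operation is an
    involution (applying it twice restores the original waveform).
    """
    if call.waveform is None:
        raise ValueError(f"call {call.name!r} has no waveform to flip")
    wav = call.waveform.copy()
    fs = float(call.sample_rate)
    for syl in call.syllables:
        i0 = int(round(syl.onset * fs))
        i1 = int(round(syl.offset * fs))
        i1 = min(i1, len(wav))
        wav[i0:i1] = wav[i0:i1][::-1]
    return replace(call, name=f"{call.name}-flip", waveform=wav,
                   syllables=list(call.syllables))


# ---------------------------------------------------------------------------
# I/O


def write_call_annotations(calls: Sequence[CallStimulus], path: str | Path) -> None:
    """Syllable annotations as CSV (columns: name, onset_s, duration_s)."""
    rows = [
        {"name": c.name, "onset_s": s.onset, "duration_s": s.duration}
        for c in calls
        for s in c.syllables
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_call_annotations(path: str | Path, total_duration: float = 3.0) -> list[CallStimulus]:
    df = pd.read_csv(path)
    calls = []
    for name, grp in df.groupby("name", sort=False):
        syls = [Syllable(onset=r.onset_s, duration=r.duration_s)
                for r in grp.itertuples()]
        calls.append(CallStimulus(name=str(name), syllables=syls,
                                  total_duration=total_duration))
    return calls


def write_waveform(call: CallStimulus, path: str | Path) -> None:
    if call.waveform is None:
        raise ValueError("call has no waveform")
    wavfile.write(path, int(call.sample_rate), call.waveform.astype(np.float32))


def read_waveform(path: str | Path) -> tuple[np.ndarray, float]:
    rate, data = wavfile.read(path)
    return np.asarray(data, dtype=float), float(rate)
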