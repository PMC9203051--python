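"""Session configuration for trial-structured odor/sound–outcome conditioning.

The task this package analyzes presents a small set of conditioned stimuli
(odors, optionally sound tones) whose outcomes range from aversive (airpuff)
to rewarding (water), while neurons are imaged at a slow two-photon frame
rate.  Every trial is cut into a fixed peri-trial window: 1 s of pre-stimulus
baseline, stimulus onset, an anticipation period, outcome delivery, and a
post-outcome tail.  :class:`SessionConfig` pins down that geometry plus the
stimulus → valence/salience/modality/outcome bookkeeping that the coding
scores depend on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

VALENCES = ("aversive", "neutral", "rewarded")
SALIENCES = ("high", "medium", "low")
MODALITIES = ("odor", "sound")
OUTCOMES = ("strong_airpuff", "weak_airpuff", "none", "small_water", "large_water")
WATER_OUTCOMES = frozenset({"small_water", "large_water"})


def _default_stimuli() -> tuple[str, ...]:
    return ("odor1", "odor2", "odor3", "odor4", "odor5")


@dataclass(frozen=True)
class SessionConfig:
    """Geometry and stimulus bookkeeping of one conditioning session.

    Times are seconds relative to the start of the peri-trial window
    (time 0).  The stimulus comes on at ``odor_onset_s`` and the outcome
    (water drop or airpuff) at ``odor_onset_s + outcome_delay_s``.  All
    windows in the package are half-open ``[start, end)``.
    """

    sampling_rate_hz: float = 5.0
    window_pre_s: float = 1.0
    window_post_s: float = 5.0
    odor_onset_s: float = 1.0
    outcome_delay_s: float = 1.3
    stimulus_duration_s: float = 1.5
    trials_per_type_per_day: int = 30
    n_days: int = 4
    stimulus_set: tuple[str, ...] = field(default_factory=_default_stimuli)
    valence_map: Mapping[str, str] = field(
        default_factory=lambda: {
            "odor1": "aversive",
            "odor2": "aversive",
            "odor3": "neutral",
            "odor4": "rewarded",
            "odor5": "rewarded",
        }
    )
    salience_map: Mapping[str, str] = field(
        default_factory=lambda: {
            "odor1": "high",
            "odor2": "medium",
            "odor3": "low",
            "odor4": "medium",
            "odor5": "high",
        }
    )
    modality_map: Mapping[str, str] = field(
        default_factory=lambda: {s: "odor" for s in _default_stimuli()}
    )
    outcome_map: Mapping[str, str] = field(
        default_factory=lambda: {
            "odor1": "strong_airpuff",
            "odor2": "weak_airpuff",
            "odor3": "none",
            "odor4": "small_water",
            "odor5": "large_water",
        }
    )

    # -- derived geometry ---------------------------------------------------

    @property
    def window_s(self) -> float:
        """Total peri-trial window length in seconds."""
        return self.window_pre_s + self.window_post_s

    @property
    def n_frames(self) -> int:
        return int(round(self.window_s * self.sampling_rate_hz))

    @property
    def outcome_time_s(self) -> float:
        return self.odor_onset_s + self.outcome_delay_s

    def frame_times(self) -> np.ndarray:
        """Time of each frame (seconds from window start)."""
        return np.arange(self.n_frames) / self.sampling_rate_hz

    def frames_in(self, start_s: float, end_s: float) -> np.ndarray:
        """Indices of frames whose timestamps fall in ``[start_s, end_s)``."""
        t = self.frame_times()
        return np.flatnonzero((t >= start_s) & (t < end_s))

    def baseline_frames(self) -> np.ndarray:
        return self.frames_in(0.0, self.window_pre_s)

    def response_window_frames(self, window: str = "pre_outcome") -> np.ndarray:
        """Frames of the scalar-response window.

        ``pre_outcome``
            the 1 s ending at outcome delivery (the window used for
            population displays and per-trial responses).
        ``anticipatory``
            the full stimulus-onset → outcome interval.
        """
        if window == "pre_outcome":
            return self.frames_in(self.outcome_time_s - 1.0, self.outcome_time_s)
        if window == "anticipatory":
            return self.frames_in(self.odor_onset_s, self.outcome_time_s)
        raise ValueError(f"unknown response window {window!r}")

    # -- validation / serialization ----------------------------------------

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when well-formed)."""
        bad: list[str] = []
        if not self.sampling_rate_hz > 0:
            bad.append("sampling_rate_hz: must be > 0")
        if self.window_pre_s < 0 or self.window_post_s <= 0:
            bad.append("window_pre_s/window_post_s: invalid window")
        if not self.outcome_time_s < self.window_s:
            bad.append("outcome_delay_s: outcome falls outside the peri-trial window")
        if len(self.stimulus_set) == 0:
            bad.append("stimulus_set: empty")
        if len(set(self.stimulus_set)) != len(self.stimulus_set):
            bad.append("stimulus_set: duplicate stimuli")
        for name, mapping, allowed in (
            ("valence_map", self.valence_map, VALENCES),
            ("salience_map", self.salience_map, SALIENCES),
            ("modality_map", self.modality_map, MODALITIES),
            ("outcome_map", self.outcome_map, OUTCOMES),
        ):
            for stim in self.stimulus_set:
                if stim not in mapping:
                    bad.append(f"{name}: missing stimulus {stim!r}")
                elif mapping[stim] not in allowed:
                    bad.append(f"{name}: invalid value {mapping[stim]!r} for {stim!r}")
        return bad

    def to_dict(self) -> dict:
        return {
            "sampling_rate_hz": self.sampling_rate_hz,
            "window_pre_s": self.window_pre_s,
            "window_post_s": self.window_post_s,
            "odor_onset_s": self.odor_onset_s,
            "outcome_delay_s": self.outcome_delay_s,
            "stimulus_duration_s": self.stimulus_duration_s,
            "trials_per_type_per_day": self.trials_per_type_per_day,
            "n_days": self.n_days,
            "stimulus_set": list(self.stimulus_set),
            "valence_map": dict(self.valence_map),
            "salience_map": dict(self.salience_map),
            "modality_map": dict(self.modality_map),
            "outcome_map": dict(self.outcome_map),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SessionConfig":
        d = dict(d)
        if "stimulus_set" in d:
            d["stimulus_set"] = tuple(d["stimulus_set"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "SessionConfig":
        return cls.from_dict(json.loads(s))


def five_odor_task(n_days: int = 4, trials_per_type_per_day: int = 30) -> SessionConfig:
    """The canonical five-odor graded-outcome task (airpuffs → water drops)."""
    return SessionConfig(n_days=n_days, trials_per_type_per_day=trials_per_type_per_day)


def odor_sound_task(n_days: int = 3, trials_per_type_per_day: int = 30) -> SessionConfig:
    """Two odors plus two sound tones, valence-matched across modalities."""
    stimuli = ("odor1", "odor5", "sound_av", "sound_rw")
    return SessionConfig(
        n_days=n_days,
        trials_per_type_per_day=trials_per_type_per_day,
        stimulus_set=stimuli,
        valence_map={
            "odor1": "aversive",
            "odor5": "rewarded",
            "sound_av": "aversive",
            "sound_rw": "rewarded",
        },
        salience_map={s: "high" for s in stimuli},
        modality_map={
            "odor1": "odor",
            "odor5": "odor",
            "sound_av": "sound",
            "sound_rw": "sound",
        },
        outcome_map={
            "odor1": "strong_airpuff",
            "odor5": "large_water",
            "sound_av": "strong_airpuff",
            "sound_rw": "large_water",
        },
    )


__all__ = [
    "SessionConfig",
    "five_odor_task",
    "odor_sound_task",
    "VALENCES",
    "SALIENCES",
    "MODALITIES",
    "OUTCOMES",
    "WATER_OUTCOMES",
    "replace",
]
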