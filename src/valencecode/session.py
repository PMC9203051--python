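"""Trial and session containers plus structural validation.

An :class:`ImagingSession` is the unit of analysis: one animal-day (or probe
session) of raw fluorescence traces shaped ``neurons x trials x frames``,
aligned with a trial table and per-trial lick streams.  Traces are stored
raw; ΔF/F normalization is always recomputed downstream so the raw record
stays the single source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import SessionConfig


@dataclass(frozen=True)
class Trial:
    """One trial: stimulus, schedule position, outcome flag, lick times.

    ``lick_times_s`` are seconds from the start of the peri-trial window,
    sorted ascending.  ``outcome_delivered`` is False on outcome-omission
    probe trials and on every sated Block-2 trial.
    """

    trial_id: int
    stimulus: str
    day: int
    block: int = 1
    outcome_delivered: bool = True
    lick_times_s: tuple[float, ...] = ()


@dataclass
class ImagingSession:
    """Raw traces + trial metadata for one imaged population.

    ``traces[n, t, f]`` is the raw fluorescence of neuron ``n`` at frame
    ``f`` of trial ``t``; axis 1 is aligned with ``trials``.
    """

    config: SessionConfig
    traces: np.ndarray
    trials: list[Trial]
    neuron_ids: list[str] = field(default_factory=list)
    genotype_label: str = "D1"

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=np.float64)
        if not self.neuron_ids:
            self.neuron_ids = [f"n{i:04d}" for i in range(self.traces.shape[0])]

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def n_trials(self) -> int:
        return self.traces.shape[1]

    def trial_frame(self) -> pd.DataFrame:
        """Trial metadata as a DataFrame (lick times as tuples)."""
        return pd.DataFrame(
            {
                "trial_id": [t.trial_id for t in self.trials],
                "stimulus": [t.stimulus for t in self.trials],
                "day": [t.day for t in self.trials],
                "block": [t.block for t in self.trials],
                "outcome_delivered": [t.outcome_delivered for t in self.trials],
                "lick_times_s": [t.lick_times_s for t in self.trials],
            }
        )

    def trial_indices(
        self,
        stimulus: str | None = None,
        day: int | None = None,
        block: int | None = None,
    ) -> np.ndarray:
        """Positional indices of trials matching the given filters."""
        mask = np.ones(len(self.trials), dtype=bool)
        if stimulus is not None:
            mask &= np.array([t.stimulus == stimulus for t in self.trials])
        if day is not None:
            mask &= np.array([t.day == day for t in self.trials])
        if block is not None:
            mask &= np.array([t.block == block for t in self.trials])
        return np.flatnonzero(mask)


def validate_session(session: ImagingSession) -> list[str]:
    """Check all structural invariants; violations are data, not exceptions.

    Each violation names the offending field and the first offending index.
    An empty list means the session is well-formed.
    """
    report = list(session.config.validate())
    cfg = session.config
    tr = session.traces

    if tr.ndim != 3:
        report.append(f"traces: expected 3 axes, got {tr.ndim}")
        return report
    n, t, f = tr.shape
    if t != len(session.trials):
        report.append(
            f"traces/trials: trial axis has {t} entries but trial table has "
            f"{len(session.trials)} rows"
        )
    if f != cfg.n_frames:
        report.append(
            f"traces: frame axis has {f} frames but config implies {cfg.n_frames}"
        )
    if len(session.neuron_ids) != n:
        report.append(
            f"neuron_ids: {len(session.neuron_ids)} ids for {n} neurons"
        )
    bad = np.argwhere(~np.isfinite(tr))
    if bad.size:
        i = tuple(int(x) for x in bad[0])
        report.append(f"traces: non-finite value at index {i}")

    window = cfg.window_s
    for idx, trial in enumerate(session.trials):
        licks = np.asarray(trial.lick_times_s, dtype=float)
        if licks.size and np.any(np.diff(licks) < 0):
            report.append(f"trials[{idx}].lick_times_s: not sorted ascending")
        elif licks.size and (licks[0] < 0 or licks[-1] >= window):
            report.append(
                f"trials[{idx}].lick_times_s: lick outside [0, {window}) window"
            )
        if trial.block == 2 and trial.outcome_delivered:
            report.append(f"trials[{idx}]: block 2 trial with outcome_delivered=True")
        if trial.block not in (1, 2):
            report.append(f"trials[{idx}].block: must be 1 or 2, got {trial.block}")
        if trial.stimulus not in cfg.stimulus_set:
            report.append(f"trials[{idx}].stimulus: unknown stimulus {trial.stimulus!r}")
    return report


__all__ = ["Trial", "ImagingSession", "validate_session"]
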