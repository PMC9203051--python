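"""Anticipatory-lick analysis and the sated-block trial gate.

Anticipatory licks are counted in the 1 s window ending at outcome
delivery (half-open, so a lick exactly at outcome time is consummatory).
In the sated Block 2 every trial containing at least one anticipatory lick
is excluded before any neural analysis, isolating stimulus-driven activity
from residual licking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import SessionConfig
from .session import ImagingSession, Trial


def anticipatory_window(config: SessionConfig, anchor: str = "outcome") -> tuple[float, float]:
    """The 1 s anticipatory counting window ``[start, end)``.

    ``outcome`` anchors the window to end at outcome delivery (absorbing
    the odor's valve-to-nose latency); ``onset`` starts it at stimulus
    onset instead.
    """
    if anchor == "outcome":
        return config.outcome_time_s - 1.0, config.outcome_time_s
    if anchor == "onset":
        return config.odor_onset_s, config.odor_onset_s + 1.0
    raise ValueError(f"unknown window anchor {anchor!r}")


def anticipatory_licks(trial: Trial, config: SessionConfig, anchor: str = "outcome") -> int:
    """Count licks inside the anticipatory window (half-open)."""
    lo, hi = anticipatory_window(config, anchor)
    licks = np.asarray(trial.lick_times_s, dtype=float)
    return int(np.count_nonzero((licks >= lo) & (licks < hi)))


@dataclass(frozen=True)
class Block2Gate:
    kept: tuple[Trial, ...]
    excluded: tuple[Trial, ...]
    excluded_fraction: float


def exclude_licked_block2_trials(
    trials: list[Trial], config: SessionConfig, anchor: str = "outcome"
) -> Block2Gate:
    """Drop sated-block trials with any anticipatory lick.

    All inputs must be Block-2 trials; a Block-1 trial raises.  The kept
    set therefore has zero anticipatory licks by construction.
    """
    for t in trials:
        if t.block != 2:
            raise ValueError(f"trial {t.trial_id} is not a Block-2 trial")
    kept, excluded = [], []
    for t in trials:
        (excluded if anticipatory_licks(t, config, anchor) >= 1 else kept).append(t)
    frac = len(excluded) / len(trials) if trials else 0.0
    return Block2Gate(kept=tuple(kept), excluded=tuple(excluded), excluded_fraction=frac)


def lick_table(session: ImagingSession, anchor: str = "outcome") -> pd.DataFrame:
    """Per-trial anticipatory lick counts with metadata."""
    cfg = session.config
    rows = [
        {
            "trial_id": t.trial_id,
            "stimulus": t.stimulus,
            "day": t.day,
            "block": t.block,
            "anticipatory_licks": anticipatory_licks(t, cfg, anchor),
        }
        for t in session.trials
    ]
    return pd.DataFrame(rows)


def learning_curve(
    licks: pd.DataFrame,
    comparisons: list[tuple[str, str, int]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean ± SEM anticipatory licks per (stimulus, day) + rank-sum tests.

    ``comparisons`` are (stimulus_a, stimulus_b, day) triples compared by
    two-sided rank-sum over trial-wise counts.  SEM uses the n−1
    denominator; a single-trial cell reports SEM 0.
    """
    block1 = licks[licks["block"] == 1]
    rows = []
    for (stim, day), grp in block1.groupby(["stimulus", "day"], sort=True):
        c = grp["anticipatory_licks"].to_numpy(dtype=float)
        sem = float(c.std(ddof=1) / np.sqrt(len(c))) if len(c) > 1 else 0.0
        rows.append(
            {
                "stimulus": stim,
                "day": day,
                "n_trials": len(c),
                "mean_licks": float(c.mean()),
                "sem_licks": sem,
            }
        )
    curve = pd.DataFrame(rows)
    tests = []
    for a, b, day in comparisons or []:
        ca = block1.query("stimulus == @a and day == @day")["anticipatory_licks"]
        cb = block1.query("stimulus == @b and day == @day")["anticipatory_licks"]
        if len(ca) == 0 or len(cb) == 0:
            stat, p = float("nan"), float("nan")
        else:
            res = stats.ranksums(ca, cb)
            stat, p = float(res.statistic), float(res.pvalue)
        tests.append(
            {"stimulus_a": a, "stimulus_b": b, "day": day, "statistic": stat, "p_value": p}
        )
    return curve, pd.DataFrame(
        tests, columns=["stimulus_a", "stimulus_b", "day", "statistic", "p_value"]
    )


__all__ = [
    "anticipatory_window",
    "anticipatory_licks",
    "exclude_licked_block2_trials",
    "Block2Gate",
    "lick_table",
    "learning_curve",
]
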