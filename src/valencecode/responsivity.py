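"""Per-trial stimulus responses and activated/inhibited classification.

A neuron's response on one trial is the mean ΔF/F over the 1 s window
ending at outcome delivery (configurable to the full anticipatory epoch).
A neuron is *activated* by a stimulus when its trial responses deviate
significantly from zero (two-sided Wilcoxon signed-rank, α = 0.05) with a
mean above +30% ΔF/F, *inhibited* below −30%, otherwise *none*.  Neurons
with at least one non-none class are eligible for coding scores; the
stimulus with the largest-magnitude classified response is the neuron's
preferred stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import SessionConfig
from .preprocess import NormalizedTraces
from .session import ImagingSession

MIN_TRIALS = 5


def trial_responses(
    norm: NormalizedTraces,
    config: SessionConfig,
    window: str = "pre_outcome",
) -> np.ndarray:
    """Scalar response per (neuron, trial): mean ΔF/F over the window.

    Invalid-baseline entries propagate as NaN and are excluded from all
    aggregates downstream.
    """
    frames = config.response_window_frames(window)
    vals = norm.values[:, :, frames].mean(axis=2)
    vals[~norm.valid] = np.nan
    return vals


def classify_responsivity(
    responses: np.ndarray,
    deviation_thresh: float = 0.30,
    alpha: float = 0.05,
) -> tuple[str, float]:
    """Classify one neuron-stimulus response set as activated/inhibited/none.

    Two-sided one-sample Wilcoxon signed-rank test of the valid trial
    responses against zero; the class additionally requires the mean to
    clear the ±``deviation_thresh`` ΔF/F band.  Fewer than five valid
    trials ⇒ ``("none", nan)``.
    """
    vals = np.asarray(responses, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < MIN_TRIALS:
        return "none", float("nan")
    if np.allclose(vals, 0.0):
        return "none", 1.0
    try:
        p = float(stats.wilcoxon(vals, alternative="two-sided").pvalue)
    except ValueError:  # all differences zero after zero-handling
        return "none", 1.0
    mean = float(vals.mean())
    if p < alpha and mean > deviation_thresh:
        return "activated", p
    if p < alpha and mean < -deviation_thresh:
        return "inhibited", p
    return "none", p


def build_response_table(
    session: ImagingSession,
    responses: np.ndarray,
    include_mask: np.ndarray | None = None,
    trial_indices: np.ndarray | None = None,
    day: int | None = None,
    block: int | None = None,
    deviation_thresh: float = 0.30,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-(neuron, stimulus) response table over a trial subset.

    ``trial_indices`` restricts the trials considered (e.g. the zero-lick
    Block-2 trials); otherwise trials are filtered by ``day``/``block``.
    QC-excluded neurons are dropped entirely.
    """
    cfg = session.config
    if trial_indices is None:
        trial_indices = session.trial_indices(day=day, block=block)
    trial_indices = np.asarray(trial_indices, dtype=int)
    if include_mask is None:
        include_mask = np.ones(session.n_neurons, dtype=bool)
    stim_of = np.array([session.trials[i].stimulus for i in trial_indices])
    rows = []
    for n in np.flatnonzero(include_mask):
        for stim in cfg.stimulus_set:
            idx = trial_indices[stim_of == stim]
            vals = responses[n, idx]
            vals = vals[np.isfinite(vals)]
            cls, p = classify_responsivity(vals, deviation_thresh, alpha)
            rows.append(
                {
                    "neuron_id": session.neuron_ids[n],
                    "neuron_index": n,
                    "stimulus": stim,
                    "day": day,
                    "block": block,
                    "n_trials": int(vals.size),
                    "mean_response": float(vals.mean()) if vals.size else float("nan"),
                    "response_class": cls,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def preferred_stimulus(table: pd.DataFrame, config: SessionConfig) -> pd.Series:
    """Preferred stimulus per neuron: largest |mean| among classified stimuli.

    Ties break by stimulus order in the configured stimulus set; neurons
    whose classes are all ``none`` are omitted.
    """
    order = {s: i for i, s in enumerate(config.stimulus_set)}
    out = {}
    for nid, grp in table.groupby("neuron_id", sort=False):
        sig = grp[grp["response_class"] != "none"]
        if sig.empty:
            continue
        sig = sig.assign(_mag=sig["mean_response"].abs(), _ord=sig["stimulus"].map(order))
        sig = sig.sort_values(["_mag", "_ord"], ascending=[False, True], kind="stable")
        out[nid] = sig.iloc[0]["stimulus"]
    return pd.Series(out, name="preferred_stimulus", dtype=object)


def eligible_neurons(table: pd.DataFrame) -> pd.Series:
    """True for neurons with at least one non-``none`` response class."""
    return table.groupby("neuron_id", sort=False)["response_class"].apply(
        lambda c: bool((c != "none").any())
    )


def proportions_by_stimulus(
    table: pd.DataFrame,
    fisher_pairs: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stimulus activated/inhibited fractions + pairwise Fisher tests.

    Fisher tests compare 2×2 counts (activated vs not) between the two
    stimuli of each requested pair over the same neuron universe.
    """
    if table.empty:
        raise ValueError("response table is empty")
    props = []
    counts: dict[str, tuple[int, int]] = {}
    for stim, grp in table.groupby("stimulus", sort=False):
        n = len(grp)
        n_act = int((grp["response_class"] == "activated").sum())
        n_inh = int((grp["response_class"] == "inhibited").sum())
        counts[stim] = (n_act, n - n_act)
        props.append(
            {
                "stimulus": stim,
                "n_neurons": n,
                "frac_activated": n_act / n,
                "frac_inhibited": n_inh / n,
            }
        )
    tests = []
    for a, b in fisher_pairs or []:
        tbl = [list(counts[a]), list(counts[b])]
        odds, p = stats.fisher_exact(tbl, alternative="two-sided")
        tests.append({"stimulus_a": a, "stimulus_b": b, "odds_ratio": odds, "p_value": p})
    return pd.DataFrame(props), pd.DataFrame(
        tests, columns=["stimulus_a", "stimulus_b", "odds_ratio", "p_value"]
    )


@dataclass(frozen=True)
class OverlapCounts:
    only_a: int
    only_b: int
    both: int
    percent_overlap: float  # Jaccard x 100; NaN when both sets empty


def overlap_counts(set_a: set, set_b: set) -> OverlapCounts:
    """Overlap of two activated-neuron sets (Jaccard percentage)."""
    both = len(set_a & set_b)
    union = len(set_a | set_b)
    pct = 100.0 * both / union if union else float("nan")
    return OverlapCounts(
        only_a=len(set_a - set_b),
        only_b=len(set_b - set_a),
        both=both,
        percent_overlap=pct,
    )


def activated_set(table: pd.DataFrame, stimulus: str) -> set[str]:
    """Neuron ids classified activated for ``stimulus``."""
    sel = (table["stimulus"] == stimulus) & (table["response_class"] == "activated")
    return set(table.loc[sel, "neuron_id"])


__all__ = [
    "trial_responses",
    "classify_responsivity",
    "build_response_table",
    "preferred_stimulus",
    "eligible_neurons",
    "proportions_by_stimulus",
    "overlap_counts",
    "OverlapCounts",
    "activated_set",
]
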