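"""ΔF/F normalization, smoothing, transient detection, and neuron QC.

Raw traces are normalized per trial to the mean fluorescence of the 1 s
pre-stimulus baseline, lightly smoothed with a locally weighted (tricube,
degree-1) filter, and scanned for calcium transients: maximal runs of
frames exceeding the trailing robust baseline by ``k_sd`` standard
deviations and lasting strictly more than ``min_len_frames`` frames.
Neurons with fewer than two transients over the session are excluded from
all downstream analyses.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import ImagingSession


@dataclass
class NormalizedTraces:
    """Per-trial baseline-normalized ΔF/F traces.

    ``values[n, t, f] = (raw − B) / B`` with ``B`` the mean raw
    fluorescence over the pre-stimulus baseline of trial ``t``.  Entries
    whose baseline was non-positive are flagged invalid (``valid`` False,
    values NaN) rather than silently zeroed.
    """

    values: np.ndarray
    baseline_per_trial: np.ndarray
    valid: np.ndarray

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]


def baseline_normalize(session: ImagingSession) -> NormalizedTraces:
    """Normalize each (neuron, trial) to its 1 s pre-trial baseline."""
    cfg = session.config
    base_frames = cfg.baseline_frames()
    if base_frames.size < 1:
        raise ValueError("pre-trial window shorter than one frame")
    raw = session.traces
    baseline = raw[:, :, base_frames].mean(axis=2)
    valid = baseline > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        values = (raw - baseline[:, :, None]) / baseline[:, :, None]
    values[~valid] = np.nan
    return NormalizedTraces(values=values, baseline_per_trial=baseline, valid=valid)


# -- locally weighted smoothing ---------------------------------------------


def _tricube(dist: np.ndarray, half: int) -> np.ndarray:
    # distances scaled by (half + 1) so the outermost in-window frames
    # retain nonzero weight
    u = dist / (half + 1.0)
    return (1.0 - np.abs(u) ** 3) ** 3


def _edge_fit(values: np.ndarray, pos: int, half: int) -> float:
    lo, hi = max(0, pos - half), min(len(values), pos + half + 1)
    x = np.arange(lo, hi) - pos
    w = _tricube(x.astype(float), half)
    y = values[lo:hi]
    s0, s1, s2 = w.sum(), (w * x).sum(), (w * x * x).sum()
    t0, t1 = (w * y).sum(), (w * x * y).sum()
    det = s0 * s2 - s1 * s1
    if det == 0:
        return float(t0 / s0)
    return float((s2 * t0 - s1 * t1) / det)


def smooth_trace(values: np.ndarray, span_frames: int = 5) -> np.ndarray:
    """Locally weighted linear (tricube) smoothing over a centered window.

    ``span_frames`` must be odd; 1 is the identity.  At the window center
    the symmetric weights make the degree-1 fit collapse to a weighted
    mean, so interior frames are computed by convolution; edge frames use
    truncated-window weighted linear fits, which keeps the smoother exact
    on linear ramps everywhere.
    """
    values = np.asarray(values, dtype=np.float64)
    if span_frames < 1 or span_frames % 2 == 0:
        raise ValueError("span_frames must be a positive odd integer")
    if span_frames == 1 or values.size <= 1:
        return values.copy()
    half = span_frames // 2
    w = _tricube(np.arange(-half, half + 1, dtype=float), half)
    w = w / w.sum()
    out = np.convolve(values, w, mode="same")
    n = len(values)
    for pos in range(min(half, n)):
        out[pos] = _edge_fit(values, pos, half)
    for pos in range(max(n - half, 0), n):
        out[pos] = _edge_fit(values, pos, half)
    return out


def smooth_traces(values: np.ndarray, span_frames: int = 5) -> np.ndarray:
    """Apply :func:`smooth_trace` along the last axis of a stacked array."""
    flat = values.reshape(-1, values.shape[-1])
    out = np.empty_like(flat, dtype=np.float64)
    for i in range(flat.shape[0]):
        out[i] = smooth_trace(flat[i], span_frames)
    return out.reshape(values.shape)


# -- transient detection ----------------------------------------------------


def detect_transients(
    values: np.ndarray,
    sampling_rate_hz: float,
    baseline_win_s: float = 20.0,
    k_sd: float = 3.0,
    min_len_frames: int = 5,
    min_baseline_frames: int = 5,
) -> list[tuple[int, int]]:
    """Detect supra-threshold transient intervals in one concatenated trace.

    A frame is supra-threshold when its value strictly exceeds
    ``median + k_sd * 1.4826 * MAD`` of the sub-threshold frames within
    the trailing ``baseline_win_s`` seconds.  Supra-threshold frames never
    enter the baseline estimate, so transients do not inflate their own
    threshold.  Frames seen before ``min_baseline_frames`` baseline frames
    have accumulated are never flagged.  Returns half-open ``(start, end)``
    intervals for maximal runs strictly longer than ``min_len_frames``.
    """
    values = np.asarray(values, dtype=np.float64)
    win = int(round(baseline_win_s * sampling_rate_hz))
    if win < min_baseline_frames:
        raise ValueError("baseline window shorter than min_baseline_frames")
    history: deque[tuple[int, float]] = deque()
    above = np.zeros(values.size, dtype=bool)
    for t, v in enumerate(values):
        while history and history[0][0] < t - win:
            history.popleft()
        if len(history) >= min_baseline_frames:
            h = np.fromiter((x for _, x in history), dtype=np.float64)
            mu = np.median(h)
            sigma = 1.4826 * np.median(np.abs(h - mu))
            sigma = max(sigma, 1e-12 * max(1.0, abs(mu)))
            is_above = v > mu + k_sd * sigma
        else:
            is_above = False
        above[t] = is_above
        if not is_above:
            history.append((t, float(v)))
    return _runs_longer_than(above, min_len_frames)


def _runs_longer_than(above: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    events = []
    start = None
    for t, a in enumerate(above):
        if a and start is None:
            start = t
        elif not a and start is not None:
            if t - start > min_len:
                events.append((start, t))
            start = None
    if start is not None and len(above) - start > min_len:
        events.append((start, len(above)))
    return events


@dataclass
class EventRaster:
    """Detected transient intervals per neuron on the concatenated trace.

    ``events[n]`` is an array of half-open ``(start, end)`` frame pairs in
    session-concatenated coordinates; ``frames_per_trial`` and
    ``trial_ids`` map them back onto trials.
    """

    events: list[np.ndarray]
    frames_per_trial: int
    trial_ids: list[int] = field(default_factory=list)

    @property
    def event_counts(self) -> np.ndarray:
        return np.array([len(e) for e in self.events])

    def to_frame(self, neuron_ids: list[str] | None = None) -> pd.DataFrame:
        """Long table (neuron_id, trial_id, start_frame, end_frame).

        Global intervals are attributed to the trial containing their start
        frame; frame columns are local to that trial (end may extend past
        the trial boundary).
        """
        rows = []
        f = self.frames_per_trial
        for n, evs in enumerate(self.events):
            nid = neuron_ids[n] if neuron_ids else f"n{n:04d}"
            for start, end in evs:
                ti = int(start) // f
                tid = self.trial_ids[ti] if self.trial_ids else ti
                rows.append(
                    {
                        "neuron_id": nid,
                        "trial_id": tid,
                        "start_frame": int(start) - ti * f,
                        "end_frame": int(end) - ti * f,
                    }
                )
        return pd.DataFrame(rows, columns=["neuron_id", "trial_id", "start_frame", "end_frame"])


def detect_session_events(
    session: ImagingSession,
    norm: NormalizedTraces,
    smoothing_span: int = 5,
    baseline_win_s: float = 20.0,
    k_sd: float = 3.0,
    min_len_frames: int = 5,
) -> EventRaster:
    """Run transient detection on each neuron's smoothed concatenated trace.

    Trials are concatenated in session order; invalid-baseline trials
    contribute NaN frames which are treated as sub-threshold and skipped.
    """
    cfg = session.config
    n, t, f = norm.values.shape
    events = []
    for i in range(n):
        concat = norm.values[i].reshape(-1).copy()
        nanmask = ~np.isfinite(concat)
        concat[nanmask] = 0.0
        smoothed = smooth_trace(concat, smoothing_span)
        smoothed[nanmask] = 0.0
        evs = detect_transients(
            smoothed,
            cfg.sampling_rate_hz,
            baseline_win_s=baseline_win_s,
            k_sd=k_sd,
            min_len_frames=min_len_frames,
        )
        events.append(np.array(evs, dtype=int).reshape(-1, 2))
    return EventRaster(
        events=events,
        frames_per_trial=f,
        trial_ids=[tr.trial_id for tr in session.trials],
    )


def qc_filter_neurons(raster: EventRaster, min_events: int = 2) -> np.ndarray:
    """Inclusion mask: neurons with at least ``min_events`` transients."""
    return raster.event_counts >= min_events


__all__ = [
    "NormalizedTraces",
    "EventRaster",
    "baseline_normalize",
    "smooth_trace",
    "smooth_traces",
    "detect_transients",
    "detect_session_events",
    "qc_filter_neurons",
]
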