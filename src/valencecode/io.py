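"""Reading and writing sessions as a CSV bundle or an HDF5 file.

Two layouts are supported:

``csv_bundle`` — a directory with ``trials.csv`` (trial metadata; lick times
as semicolon-joined floats), ``traces.csv`` (long form ``neuron_id,
trial_id, frame, value``), ``neurons.csv`` and ``config.json``.  Plain text,
diffable, handy for fixtures and for hand-converted external data.

``hdf5`` — a single file with the 3-axis ``/traces`` dataset, a ``/trials``
group of column datasets (ragged lick times as variable-length floats) and
the configuration as a JSON attribute.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import SessionConfig
from .session import ImagingSession, Trial, validate_session

_BUNDLE_FILES = ("trials.csv", "traces.csv", "neurons.csv", "config.json")


class SessionFormatError(ValueError):
    """Raised when on-disk data does not match the session layout."""


def _format_for(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    if path.suffix in (".h5", ".hdf5"):
        return "hdf5"
    return "csv_bundle"


def save_session(session: ImagingSession, path: str | os.PathLike, format: str | None = None) -> None:
    """Write ``session`` to ``path`` in the given layout.

    ``load_session`` inverts this bit-exactly for metadata and within float
    round-trip for traces.
    """
    path = Path(path)
    fmt = _format_for(path, format)
    if fmt == "csv_bundle":
        _save_bundle(session, path)
    elif fmt == "hdf5":
        _save_hdf5(session, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_session(path: str | os.PathLike, format: str | None = None) -> ImagingSession:
    """Load a session written by :func:`save_session` and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"session path does not exist: {path}")
    fmt = _format_for(path, format)
    if fmt == "csv_bundle":
        session = _load_bundle(path)
    elif fmt == "hdf5":
        session = _load_hdf5(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    report = validate_session(session)
    if report:
        raise SessionFormatError(
        f"loaded session fails validation: {'; '.join(report[:5])}"
        )
    return session


# -- csv bundle -------------------------------------------------------------


def _licks_to_str(licks: tuple[float, ...]) -> str:
    return ";".join(repr(float(x)) for x in licks)


def _licks_from_str(s: str) -> tuple[float, ...]:
    if not isinstance(s, str) or not s:
        return ()
    return tuple(float(x) for x in s.split(";"))


def _save_bundle(session: ImagingSession, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    tf = session.trial_frame()
    tf["lick_times"] = [_licks_to_str(l) for l in tf.pop("lick_times_s")]
    tf.to_csv(path / "trials.csv", index=False)

    n, t, f = session.traces.shape
    long = pd.DataFrame(
        {
            "neuron_id": np.repeat(session.neuron_ids, t * f),
            "trial_id": np.tile(
                np.repeat([tr.trial_id for tr in session.trials], f), n
            ),
            "frame": np.tile(np.arange(f), n * t),
            "value": session.traces.ravel(),
        }
    )
    long.to_csv(path / "traces.csv", index=False)

    pd.DataFrame(
        {
            "neuron_id": session.neuron_ids,
            "genotype_label": [session.genotype_label] * n,
        }
    ).to_csv(path / "neurons.csv", index=False)

    (path / "config.json").write_text(session.config.to_json())


def _load_bundle(path: Path) -> ImagingSession:
    for name in _BUNDLE_FILES:
        if not (path / name).exists():
            raise FileNotFoundError(f"csv_bundle is missing {path / name}")
    config = SessionConfig.from_json((path / "config.json").read_text())
    trials_df = pd.read_csv(path / "trials.csv", keep_default_na=False)
    neurons = pd.read_csv(path / "neurons.csv")
    long = pd.read_csv(path / "traces.csv")

    trials = [
        Trial(
            trial_id=int(r.trial_id),
            stimulus=str(r.stimulus),
            day=int(r.day),
            block=int(r.block),
            outcome_delivered=str(r.outcome_delivered) in ("True", "true", "1"),
            lick_times_s=_licks_from_str(r.lick_times),
        )
        for r in trials_df.itertuples()
    ]
    neuron_ids = [str(x) for x in neurons["neuron_id"]]
    n, t, f = len(neuron_ids), len(trials), config.n_frames
    if len(long) != n * t * f:
        raise SessionFormatError(
            f"traces.csv has {len(long)} rows; expected {n}*{t}*{f} = {n * t * f} "
            "(neuron x trial x frame axes inconsistent with trials.csv/config.json)"
        )
    # rows are written in (neuron, trial, frame) order; re-sort defensively
    order = {nid: i for i, nid in enumerate(neuron_ids)}
    tid_order = {tr.trial_id: i for i, tr in enumerate(trials)}
    idx = (
        long["neuron_id"].map(order).to_numpy() * (t * f)
        + long["trial_id"].map(tid_order).to_numpy() * f
        + long["frame"].to_numpy()
    )
    values = np.empty(n * t * f, dtype=np.float64)
    values[idx] = long["value"].to_numpy(dtype=np.float64)
    traces = values.reshape(n, t, f)
    genotype = str(neurons["genotype_label"].iloc[0]) if len(neurons) else "D1"
    return ImagingSession(
        config=config,
        traces=traces,
        trials=trials,
        neuron_ids=neuron_ids,
        genotype_label=genotype,
    )


# -- hdf5 -------------------------------------------------------------------


def _save_hdf5(session: ImagingSession, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    str_dt = h5py.string_dtype()
    vlen_f = h5py.vlen_dtype(np.float64)
    with h5py.File(path, "w") as h:
        h.create_dataset("traces", data=session.traces)
        h.attrs["config"] = session.config.to_json()
        h.attrs["genotype_label"] = session.genotype_label
        h.create_dataset("neuron_ids", data=session.neuron_ids, dtype=str_dt)
        g = h.create_group("trials")
        g.create_dataset("trial_id", data=[t.trial_id for t in session.trials])
        g.create_dataset(
            "stimulus", data=[t.stimulus for t in session.trials], dtype=str_dt
        )
        g.create_dataset("day", data=[t.day for t in session.trials])
        g.create_dataset("block", data=[t.block for t in session.trials])
        g.create_dataset(
            "outcome_delivered",
            data=np.array([t.outcome_delivered for t in session.trials], dtype=bool),
        )
        licks = g.create_dataset(
            "lick_times_s", shape=(len(session.trials),), dtype=vlen_f
        )
        for i, t in enumerate(session.trials):
            licks[i] = np.asarray(t.lick_times_s, dtype=np.float64)


def _load_hdf5(path: Path) -> ImagingSession:
    with h5py.File(path, "r") as h:
        config = SessionConfig.from_json(h.attrs["config"])
        traces = h["traces"][()]
        neuron_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in h["neuron_ids"][()]]
        g = h["trials"]
        stim = [x.decode() if isinstance(x, bytes) else str(x) for x in g["stimulus"][()]]
        trials = [
            Trial(
                trial_id=int(tid),
                stimulus=s,
                day=int(day),
                block=int(block),
                outcome_delivered=bool(od),
                lick_times_s=tuple(float(x) for x in licks),
            )
            for tid, s, day, block, od, licks in zip(
                g["trial_id"][()],
                stim,
                g["day"][()],
                g["block"][()],
                g["outcome_delivered"][()],
                g["lick_times_s"][()],
            )
        ]
        genotype = str(h.attrs.get("genotype_label", "D1"))
    return ImagingSession(
        config=config,
        traces=traces,
        trials=trials,
        neuron_ids=neuron_ids,
        genotype_label=genotype,
    )


__all__ = ["save_session", "load_session", "SessionFormatError"]
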