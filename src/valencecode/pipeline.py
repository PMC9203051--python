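"""End-to-end pipeline: session in, tables and reports out.

A YAML config names either an input session (``input: {path, format}``) or
synthesis parameters (``simulate: {...}``), plus the stages to run.  The
pipeline normalizes, detects transients, applies QC, classifies
responsivity, computes coding scores with shuffle nulls, measures
population geometry (Block-1 subgroups reused for Block 2), and summarizes
licking.  Outputs are plain CSV/JSON files plus a run log carrying the
seed and all parameters; identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import geometry as geo
from . import preprocess as pp
from . import responsivity as resp
from . import scores as sc
from .config import SessionConfig, five_odor_task
from .io import load_session, save_session
from .session import ImagingSession, validate_session
from .simulate import SimConfig, generate_population

log = logging.getLogger("valencecode")

STAGES = ("preprocess", "responsivity", "scores", "geometry", "behavior")


def _sim_config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    d.pop("seed", None)
    session_kw = d.pop("session", {})
    n_days = d.pop("n_days", None)
    trials_per_type = d.pop("trials_per_type_per_day", None)
    cfg = five_odor_task(
        n_days=n_days if n_days is not None else 4,
        trials_per_type_per_day=trials_per_type if trials_per_type is not None else 30,
    )
    if session_kw:
        cfg = SessionConfig.from_dict({**cfg.to_dict(), **session_kw})
    return SimConfig(session=cfg, **d)


def _obtain_session(conf: dict, seed: int) -> tuple[ImagingSession, object | None]:
    if "input" in conf:
        spec = conf["input"]
        return load_session(spec["path"], spec.get("format")), None
    sim_spec = dict(conf.get("simulate", {}))
    sim_seed = sim_spec.pop("seed", seed)
    sim = _sim_config_from_dict(sim_spec)
    session, truth = generate_population(sim, int(sim_seed))
    return session, truth


def run_pipeline(
    config_file: str | Path,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the configured stages; return a dict of result objects and paths."""
    conf = yaml.safe_load(Path(config_file).read_text()) or {}
    seed = int(conf.get("seed", 0) if seed is None else seed)
    out = Path(out_dir or conf.get("out_dir", "valencecode_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = list(conf.get("stages", STAGES))
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r} (choose from {', '.join(STAGES)})")
    n_shuffles = int(conf.get("n_shuffles", 1000))
    results: dict = {"out_dir": out, "seed": seed}

    session, truth = _timed("load", _obtain_session, conf, seed)
    report = validate_session(session)
    if report:
        raise ValueError(f"load: session failed validation: {report[0]}")
    results["session"] = session
    if truth is not None:
        truth.to_frame().to_csv(out / "ground_truth.csv", index=False)
    cfg = session.config
    last_day = max(t.day for t in session.trials)
    has_block2 = any(t.block == 2 for t in session.trials)

    norm = None
    raster = None
    include = np.ones(session.n_neurons, dtype=bool)
    if "preprocess" in stages:
        norm = _timed("preprocess", pp.baseline_normalize, session)
        raster = _timed("preprocess", pp.detect_session_events, session, norm)
        include = pp.qc_filter_neurons(raster)
        raster.to_frame(session.neuron_ids).to_csv(out / "events.csv", index=False)
        pd.DataFrame(
            {
                "neuron_id": session.neuron_ids,
                "event_count": raster.event_counts,
                "included": include,
            }
        ).to_csv(out / "qc.csv", index=False)
        results.update(norm=norm, raster=raster, include=include)

    responses = None
    tables: dict[tuple[int, int], pd.DataFrame] = {}
    if "responsivity" in stages:
        if norm is None:
            raise ValueError("responsivity: requires the preprocess stage")
        responses = resp.trial_responses(norm, cfg)
        for day in sorted({t.day for t in session.trials if t.block == 1}):
            tables[(day, 1)] = _timed(
                "responsivity",
                resp.build_response_table,
                session,
                responses,
                include,
                None,
                day,
                1,
            )
        if has_block2:
            b2 = [session.trials[i] for i in session.trial_indices(block=2)]
            gate = beh.exclude_licked_block2_trials(b2, cfg)
            kept_ids = {t.trial_id for t in gate.kept}
            kept_idx = np.array(
                [i for i in session.trial_indices(block=2)
                 if session.trials[i].trial_id in kept_ids],
                dtype=int,
            )
            tables[(last_day, 2)] = resp.build_response_table(
                session, responses, include, kept_idx, last_day, 2
            )
            results["block2_gate"] = gate
        all_tables = pd.concat(tables.values(), ignore_index=True)
        all_tables.to_csv(out / "responses.csv", index=False)
        props, fisher = resp.proportions_by_stimulus(
            tables[(last_day, 1)],
            fisher_pairs=[(cfg.stimulus_set[0], cfg.stimulus_set[-1])],
        )
        props.to_csv(out / "proportions.csv", index=False)
        fisher.to_csv(out / "fisher_tests.csv", index=False)
        results.update(response_tables=tables, responses=responses)

    if "scores" in stages:
        if not tables:
            raise ValueError("scores: requires the responsivity stage")
        score_rows = []
        null_rows = []
        rng = np.random.default_rng(seed)
        for (day, block), table in sorted(tables.items()):
            elig = resp.eligible_neurons(table)
            profiles = []
            ids = []
            for nid, grp in table.groupby("neuron_id", sort=False):
                if not elig.get(nid, False):
                    continue
                r = dict(zip(grp["stimulus"], grp["mean_response"]))
                if not all(np.isfinite(list(r.values()))):
                    continue
                profiles.append(sc.NeuronResponseProfile.from_config(r, cfg))
                ids.append(nid)
            pop = sc.score_population(profiles) if profiles else {}
            for i, nid in enumerate(ids):
                score_rows.append(
                    {
                        "neuron_id": nid,
                        "day": day,
                        "block": block,
                        "valence_score": pop["valence"][i],
                        "identity_score": pop["identity"][i],
                        "salience_score": pop["salience"][i],
                        "eligible": True,
                    }
                )
            if profiles and (day, block) in ((last_day, 1), (last_day, 2)):
                for kind in ("valence", "salience"):
                    null = sc.shuffle_null(
                        profiles, kind, n_shuffles, int(rng.integers(2**31))
                    )
                    n_prof = len(profiles)
                    for j, v in enumerate(null.null_scores):
                        null_rows.append(
                            {
                                "score_kind": kind,
                                "day": day,
                                "block": block,
                                "shuffle_index": j // n_prof,
                                "value": v,
                            }
                        )
        pd.DataFrame(score_rows).to_csv(out / "scores.csv", index=False)
        pd.DataFrame(null_rows).to_csv(out / "null_scores.csv", index=False)
        results["score_table"] = pd.DataFrame(score_rows)

    if "geometry" in stages:
        if norm is None or not tables:
            raise ValueError("geometry: requires preprocess and responsivity stages")
        epoch = cfg.response_window_frames("pre_outcome")
        table1 = tables[(last_day, 1)]
        pref = resp.preferred_stimulus(table1, cfg)
        nidx = {nid: i for i, nid in enumerate(session.neuron_ids)}
        subgroups = {
            stim: np.array([nidx[n] for n in pref.index[pref == stim]], dtype=int)
            for stim in cfg.stimulus_set
            if (pref == stim).any()
        }
        geo_out: dict = {}
        neuron_pool = np.flatnonzero(include)
        blocks = [(1, session.trial_indices(day=last_day, block=1))]
        if has_block2 and "block2_gate" in results:
            kept_ids = {t.trial_id for t in results["block2_gate"].kept}
            blocks.append(
                (
                    2,
                    np.array(
                        [i for i in session.trial_indices(block=2)
                         if session.trials[i].trial_id in kept_ids],
                        dtype=int,
                    ),
                )
            )
        traj_frames = []
        for block, tidx in blocks:
            mats = _timed(
                "geometry",
                geo.condition_matrices,
                norm,
                session,
                tidx,
                epoch,
                neuron_pool,
            )
            # subgroup indices refer to the full neuron axis; remap to pool
            pool_pos = {n: i for i, n in enumerate(neuron_pool)}
            sub_pool = {
                g: np.array([pool_pos[n] for n in m if n in pool_pos], dtype=int)
                for g, m in subgroups.items()
            }
            cosine = geo.cosine_similarity_subgroups(mats, sub_pool, cfg.valence_map)
            contrast = geo.euclidean_contrast(mats, cfg.valence_map)
            full_mats = geo.condition_matrices(
                norm, session, tidx, np.arange(cfg.n_frames), neuron_pool
            )
            traj = geo.pca_trajectories(full_mats)
            tf = traj.to_frame()
            tf.insert(0, "block", block)
            traj_frames.append(tf)
            geo_out[f"block{block}"] = {
                "percent_contrast": contrast.percent_contrast,
                "mean_norm_same": contrast.mean_norm_same,
                "mean_norm_opposite": contrast.mean_norm_opposite,
                "cosine_ranksum_p": cosine.ranksum_p,
                "cosine_samples": cosine.samples.to_dict(orient="records"),
                "pca_variance_explained": traj.variance_explained.tolist(),
            }
            results[f"geometry_block{block}"] = (mats, cosine, contrast, traj)
        (out / "geometry.json").write_text(json.dumps(geo_out, indent=2, sort_keys=True))
        pd.concat(traj_frames, ignore_index=True).to_csv(
            out / "trajectories.csv", index=False
        )

    if "behavior" in stages:
        licks = _timed("behavior", beh.lick_table, session)
        rewarded = [
            s for s in cfg.stimulus_set
            if cfg.outcome_map[s] in ("small_water", "large_water")
        ]
        comparisons = (
            [(rewarded[-1], rewarded[0], last_day)] if len(rewarded) >= 2 else []
        )
        curve, tests = beh.learning_curve(licks, comparisons)
        licks.to_csv(out / "behavior.csv", index=False)
        curve.to_csv(out / "learning_curve.csv", index=False)
        tests.to_csv(out / "lick_tests.csv", index=False)
        results.update(lick_table=licks, learning_curve=curve, lick_tests=tests)

    run_log = {
        "seed": seed,
        "stages": stages,
        "n_shuffles": n_shuffles,
        "config": conf,
        "session_config": cfg.to_dict(),
        "n_neurons": session.n_neurons,
        "n_trials": session.n_trials,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    return results


def _timed(stage: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        res = fn(*args, **kwargs)
    except Exception as e:  # prefix the failing stage per the error contract
        raise type(e)(f"{stage}: {e}").with_traceback(e.__traceback__) from None
    log.info("%s: %s took %.2f s", stage, getattr(fn, "__name__", fn), time.perf_counter() - t0)
    return res


__all__ = ["run_pipeline", "STAGES"]
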