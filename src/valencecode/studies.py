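"""Canonical simulation studies exercising the pipeline end to end.

Each function generates a synthetic population under the task's stated
conditions (five stimuli, 30 trials per type per day at 5 Hz), runs the
relevant slice of the analysis, and returns the headline quantities:
archetype score recovery, shuffle-null centering, population-geometry
contrasts, salience-pattern rarity, the sated-block behavioral gate, and
the day-4 anticipatory-lick comparison.  These are the quantities reported
by ``scripts/acceptance.py`` and asserted by the acceptance test suite.
"""

from __future__ import annotations

import numpy as np

from . import behavior as beh
from . import geometry as geo
from . import preprocess as pp
from . import responsivity as resp
from . import scores as sc
from .config import SessionConfig, five_odor_task
from .session import ImagingSession
from .simulate import GroundTruth, SimConfig, generate_population


def _analyze_day(
    session: ImagingSession,
    day: int,
    block: int = 1,
    trial_indices: np.ndarray | None = None,
):
    """Preprocess + QC + response table for one (day, block)."""
    norm = pp.baseline_normalize(session)
    raster = pp.detect_session_events(session, norm)
    include = pp.qc_filter_neurons(raster)
    responses = resp.trial_responses(norm, session.config)
    table = resp.build_response_table(
        session, responses, include, trial_indices, day, block
    )
    return norm, include, responses, table


def _profiles_by_neuron(table, config: SessionConfig):
    elig = resp.eligible_neurons(table)
    profiles, indices = [], []
    for (nid, nidx), grp in table.groupby(["neuron_id", "neuron_index"], sort=False):
        if not elig.get(nid, False):
            continue
        r = dict(zip(grp["stimulus"], grp["mean_response"]))
        if not all(np.isfinite(list(r.values()))):
            continue
        profiles.append(sc.NeuronResponseProfile.from_config(r, config))
        indices.append(int(nidx))
    return profiles, indices


def score_recovery_study(seed: int = 0) -> dict:
    """Mixed-archetype recovery: do the scores separate the archetypes?

    200 neurons (50 valence coders, 50 identity coders, 10 salience
    coders, 90 nonresponsive), one day of 30 trials x 5 stimuli, default
    noise.  Returns per-archetype score medians and the rank-sum p-values
    for valence-vs-identity separation in both directions.
    """
    sim = SimConfig(
        counts={
            "valence_coder": 50,
            "identity_coder": 50,
            "salience_coder": 10,
            "nonresponsive": 90,
        },
        session=five_odor_task(n_days=1),
    )
    session, truth = generate_population(sim, seed)
    _, include, _, table = _analyze_day(session, day=1)
    profiles, indices = _profiles_by_neuron(table, session.config)
    pop = sc.score_population(profiles)
    kinds = np.array([truth.archetypes[i].kind for i in indices])

    def _vals(kind_name: str, score_kind: str) -> np.ndarray:
        v = pop[score_kind][kinds == kind_name]
        return v[np.isfinite(v)]

    val_v = _vals("valence_coder", "valence")
    val_i = _vals("identity_coder", "valence")
    idn_v = _vals("valence_coder", "identity")
    idn_i = _vals("identity_coder", "identity")
    _, p_val = sc.compare_score_distributions(val_v, val_i)
    _, p_idn = sc.compare_score_distributions(idn_i, idn_v)
    return {
        "session": session,
        "truth": truth,
        "table": table,
        "median_valence_valence_coders": float(np.median(val_v)),
        "median_valence_identity_coders": float(np.median(val_i)),
        "median_identity_identity_coders": float(np.median(idn_i)),
        "median_identity_valence_coders": float(np.median(idn_v)),
        "ranksum_p_valence": float(p_val),
        "ranksum_p_identity": float(p_idn),
        "n_scored": len(profiles),
    }


def exchangeable_null_study(
    seed: int = 0, n_neurons: int = 200, n_shuffles: int = 1000
) -> dict:
    """Shuffle-null centering on exchangeable (i.i.d. across stimuli) profiles."""
    cfg = five_odor_task()
    rng = np.random.default_rng(seed)
    profiles = [
        sc.NeuronResponseProfile.from_config(
            {s: float(v) for s, v in zip(cfg.stimulus_set, rng.normal(size=5))}, cfg
        )
        for _ in range(n_neurons)
    ]
    true_scores = np.array([sc.valence_score(p) for p in profiles])
    null = sc.shuffle_null(
        profiles, "valence", n_shuffles, int(rng.integers(2**31))
    )
    return {
        "null_mean": null.mean,
        "true_mean": float(np.nanmean(true_scores)),
        "n": n_neurons * n_shuffles,
    }


def _pure_population(kind: str, n: int, seed: int) -> tuple[ImagingSession, GroundTruth, SimConfig]:
    counts = {k: 0 for k in ("valence_coder", "identity_coder", "salience_coder", "nonresponsive")}
    counts[kind] = n
    sim = SimConfig(counts=counts, session=five_odor_task(n_days=1))
    session, truth = generate_population(sim, seed)
    return session, truth, sim


def geometry_contrast_study(kind: str = "valence_coder", n: int = 60, seed: int = 0) -> dict:
    """Euclidean percent contrast + cosine same/opposite on a pure population."""
    session, truth, _ = _pure_population(kind, n, seed)
    cfg = session.config
    norm, include, responses, table = _analyze_day(session, day=1)
    epoch = cfg.response_window_frames("pre_outcome")
    pool = np.flatnonzero(include)
    mats = geo.condition_matrices(
        norm, session, session.trial_indices(day=1, block=1), epoch, pool
    )
    contrast = geo.euclidean_contrast(mats, cfg.valence_map)
    pref = resp.preferred_stimulus(table, cfg)
    nidx = {nid: i for i, nid in enumerate(session.neuron_ids)}
    pool_pos = {nn: i for i, nn in enumerate(pool)}
    subgroups = {}
    for stim in cfg.stimulus_set:
        members = [
            pool_pos[nidx[nid]]
            for nid in pref.index[pref == stim]
            if nidx[nid] in pool_pos
        ]
        if members:
            subgroups[stim] = np.array(members, dtype=int)
    cosine = geo.cosine_similarity_subgroups(mats, subgroups, cfg.valence_map)
    return {
        "session": session,
        "table": table,
        "percent_contrast": contrast.percent_contrast,
        "cosine_ranksum_p": cosine.ranksum_p,
        "cosine_mean_same": cosine.mean("same"),
        "cosine_mean_opposite": cosine.mean("opposite"),
        "n_neurons": int(include.sum()),
    }


def salience_pattern_count(table, config: SessionConfig) -> int:
    """Neurons activated for both high-salience stimuli but no medium/low one.

    In a population of pure valence coders this pattern (activated by the
    strongest aversive and strongest rewarded stimulus only) should not
    occur.
    """
    high = [s for s in config.stimulus_set if config.salience_map[s] == "high"]
    others = [s for s in config.stimulus_set if s not in high]
    count = 0
    for nid, grp in table.groupby("neuron_id", sort=False):
        cls = dict(zip(grp["stimulus"], grp["response_class"]))
        if all(cls.get(s) == "activated" for s in high) and not any(
            cls.get(s) == "activated" for s in others
        ):
            count += 1
    return count


def sated_block_study(seed: int = 0) -> dict:
    """Sated-block behavioral gate: exclusion fraction and kept-trial purity."""
    sim = SimConfig(
        counts={"valence_coder": 10, "identity_coder": 0, "salience_coder": 0, "nonresponsive": 0},
        session=five_odor_task(n_days=1),
        include_block2=True,
    )
    session, _ = generate_population(sim, seed)
    cfg = session.config
    b2 = [session.trials[i] for i in session.trial_indices(block=2)]
    gate = beh.exclude_licked_block2_trials(b2, cfg)
    kept_counts = [beh.anticipatory_licks(t, cfg) for t in gate.kept]
    return {
        "n_block2_trials": len(b2),
        "excluded_fraction": gate.excluded_fraction,
        "max_kept_anticipatory_licks": max(kept_counts) if kept_counts else 0,
        "sated_lick_prob": sim.lick_model.sated_lick_prob,
    }


def licking_study(seed: int = 0) -> dict:
    """Four-day learning curve; day-4 large- vs small-reward lick contrast."""
    sim = SimConfig(
        counts={"valence_coder": 1, "identity_coder": 0, "salience_coder": 0, "nonresponsive": 0},
        session=five_odor_task(n_days=4),
    )
    session, _ = generate_population(sim, seed)
    licks = beh.lick_table(session)
    curve, tests = beh.learning_curve(licks, [("odor5", "odor4", 4)])
    day4 = curve[curve["day"] == 4].set_index("stimulus")
    return {
        "curve": curve,
        "mean_licks_large_day4": float(day4.loc["odor5", "mean_licks"]),
        "mean_licks_small_day4": float(day4.loc["odor4", "mean_licks"]),
        "ranksum_p_day4": float(tests["p_value"].iloc[0]),
        "n_trials_per_odor": int(day4.loc["odor5", "n_trials"]),
    }


__all__ = [
    "score_recovery_study",
    "exchangeable_null_study",
    "geometry_contrast_study",
    "salience_pattern_count",
    "sated_block_study",
    "licking_study",
]
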