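"""Synthetic GCaMP population generator with known coding ground truth.

The generator emulates the conditioning task end to end: five trial types x
30 trials/day randomly interleaved (equal counts per half-session), 10%
outcome-omission trials, an optional sated "Block 2" with outcomes omitted
and almost no licking, GCaMP7s-like double-exponential transients on a
drifting baseline, and anticipatory/consummatory lick streams.

Each simulated neuron is one of four coding archetypes:

``valence_coder``
    equal responses to stimuli of the same valence, opposite-signed
    responses to opposite valences (rewarded +, aversive −, or mirrored).
``identity_coder``
    responds to exactly one stimulus.
``salience_coder``
    responds to the high-salience stimuli (strongest outcomes) regardless
    of valence sign.
``nonresponsive``
    no stimulus tuning; only spontaneous transients.

Ground truth (archetype, tuning, kinetics) is returned alongside the
session so downstream estimators can be tested as parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import WATER_OUTCOMES, SessionConfig, five_odor_task
from .session import ImagingSession, Trial

ARCHETYPES = ("valence_coder", "identity_coder", "salience_coder", "nonresponsive")


@dataclass(frozen=True)
class KineticParams:
    """Transient kinetics and noise for one simulated neuron.

    Taus are seconds; ``amplitude`` is the peak ΔF/F of a unit-gain
    response; ``noise_sd`` and ``drift_sd`` are per-frame, expressed as
    fractions of ``baseline_f``.
    """

    rise_tau_s: float = 0.25
    decay_tau_s: float = 1.2
    amplitude: float = 1.0
    baseline_f: float = 100.0
    noise_sd: float = 0.03
    drift_sd: float = 0.002

    def __post_init__(self) -> None:
        if min(self.rise_tau_s, self.decay_tau_s, self.amplitude, self.baseline_f) <= 0:
            raise ValueError("kinetic parameters must be positive")
        if not self.decay_tau_s > self.rise_tau_s:
            raise ValueError("decay_tau_s must exceed rise_tau_s")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Coding archetype of one simulated neuron.

    ``tuning`` maps each stimulus to a response gain in [−1, 1]; ``sign``
    records whether the preferred responses are excitatory or inhibitory.
    ``learning_schedule`` maps training day to a gain multiplier.
    """

    kind: str
    sign: str = "activated"
    tuning: Mapping[str, float] = field(default_factory=dict)
    reliability: float = 0.8
    learning_schedule: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ARCHETYPES:
            raise ValueError(f"unknown archetype kind {self.kind!r}")
        if not 0.0 < self.reliability <= 1.0:
            raise ValueError("reliability must lie in (0, 1]")

    def day_gain(self, day: int) -> float:
        if not self.learning_schedule:
            return 1.0
        if day in self.learning_schedule:
            return float(self.learning_schedule[day])
        return float(self.learning_schedule[max(self.learning_schedule)])


@dataclass
class GroundTruth:
    """Per-neuron archetypes and kinetics of a generated population."""

    archetypes: list[ArchetypeSpec]
    kinetics: list[KineticParams]
    seed: int

    def kinds(self) -> list[str]:
        return [a.kind for a in self.archetypes]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (a, k) in enumerate(zip(self.archetypes, self.kinetics)):
            rows.append(
                {
                    "neuron_index": i,
                    "kind": a.kind,
                    "sign": a.sign,
                    "reliability": a.reliability,
                    "tuning": ";".join(f"{s}:{g}" for s, g in a.tuning.items()),
                    "rise_tau_s": k.rise_tau_s,
                    "decay_tau_s": k.decay_tau_s,
                    "amplitude": k.amplitude,
                    "baseline_f": k.baseline_f,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class LickModel:
    """Poisson lick-rate parameters (Hz) by epoch and outcome.

    Anticipatory rates apply over the stimulus-onset → outcome epoch for
    rewarded stimuli; aversive and neutral stimuli get
    ``nonrewarded_rate_hz`` (≈0, mirroring the near-absence of licking to
    non-rewarded stimuli after learning).  In the sated state licking
    collapses: each trial independently contains ≥1 lick with probability
    ``sated_lick_prob``.
    """

    anticipatory_rate_hz: Mapping[str, float] = field(
        default_factory=lambda: {"large_water": 2.7, "small_water": 2.0}
    )
    nonrewarded_rate_hz: float = 0.0
    consummatory_rate_hz: float = 6.0
    consummatory_duration_s: float = 1.0
    sated_lick_prob: float = 0.05
    sated_mean_licks: float = 1.2
    learning_schedule: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.3, 2: 0.7, 3: 0.9, 4: 1.0}
    )

    def day_gain(self, day: int) -> float:
        if not self.learning_schedule or day in self.learning_schedule:
            return float(self.learning_schedule.get(day, 1.0))
        return float(self.learning_schedule[max(self.learning_schedule)])


@dataclass(frozen=True)
class SimConfig:
    """Population counts, kinetics ranges, and schedule knobs."""

    counts: Mapping[str, int] = field(
        default_factory=lambda: {
            "valence_coder": 20,
            "identity_coder": 20,
            "salience_coder": 5,
            "nonresponsive": 15,
        }
    )
    session: SessionConfig = field(default_factory=five_odor_task)
    rise_tau_range: tuple[float, float] = (0.2, 0.3)
    decay_tau_range: tuple[float, float] = (1.0, 1.5)
    amplitude_range: tuple[float, float] = (0.8, 1.2)
    baseline_f_range: tuple[float, float] = (80.0, 120.0)
    noise_sd: float = 0.03
    drift_sd: float = 0.002
    reliability: float = 0.8
    amp_jitter_sigma: float = 0.3
    inhibited_fraction: float = 0.3
    spontaneous_rate_per_frame: float = 0.002
    omission_fraction: float = 0.1
    include_block2: bool = False
    block2_trials_per_type: int = 16
    valence_schedule: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.4, 2: 0.7, 3: 0.9, 4: 1.0}
    )
    lick_model: LickModel = field(default_factory=LickModel)
    genotype_label: str = "D1"


# -- transient kernel -------------------------------------------------------


def transient_peak_time_s(kinetics: KineticParams) -> float:
    """Analytic argmax of the double-exponential kernel (seconds)."""
    r, d = kinetics.rise_tau_s, kinetics.decay_tau_s
    return (r * d / (d - r)) * math.log(d / r)


def transient_waveform(
    kinetics: KineticParams, duration_frames: int, rate_hz: float
) -> np.ndarray:
    """Sampled double-exponential transient, unit peak scaled by amplitude.

    ``w(t) = exp(−t/decay) − exp(−t/rise)``, normalized by its continuous
    peak value and multiplied by ``kinetics.amplitude``; ``w(0) = 0``.
    """
    if duration_frames < 1:
        raise ValueError("duration_frames must be >= 1")
    t = np.arange(duration_frames) / rate_hz
    r, d = kinetics.rise_tau_s, kinetics.decay_tau_s
    w = np.exp(-t / d) - np.exp(-t / r)
    tp = transient_peak_time_s(kinetics)
    peak = math.exp(-tp / d) - math.exp(-tp / r)
    return kinetics.amplitude * w / peak


# -- archetype construction -------------------------------------------------


def _valence_tuning(cfg: SessionConfig, sign: str) -> dict[str, float]:
    pol = 1.0 if sign == "activated" else -1.0
    out = {}
    for s in cfg.stimulus_set:
        v = cfg.valence_map[s]
        out[s] = pol * (1.0 if v == "rewarded" else -1.0 if v == "aversive" else 0.0)
    return out


def _identity_tuning(cfg: SessionConfig, stimulus: str, sign: str) -> dict[str, float]:
    pol = 1.0 if sign == "activated" else -1.0
    return {s: (pol if s == stimulus else 0.0) for s in cfg.stimulus_set}


def _salience_tuning(cfg: SessionConfig, sign: str) -> dict[str, float]:
    pol = 1.0 if sign == "activated" else -1.0
    return {
        s: (pol if cfg.salience_map[s] == "high" else 0.0) for s in cfg.stimulus_set
    }


def make_archetypes(sim: SimConfig, rng: np.random.Generator) -> list[ArchetypeSpec]:
    """Build the population's archetype list from the configured counts.

    Identity coders take their preferred stimulus round-robin over the
    stimulus set so every stimulus is covered; excitatory/inhibitory signs
    are drawn with probability ``inhibited_fraction``.  The valence
    learning ramp applies only to multi-day simulations; a single-day
    session represents trained animals at full gain.
    """
    cfg = sim.session
    valence_schedule = dict(sim.valence_schedule) if cfg.n_days > 1 else {}
    specs: list[ArchetypeSpec] = []
    for kind in ARCHETYPES:
        count = int(sim.counts.get(kind, 0))
        if count < 0:
            raise ValueError(f"negative count for {kind}")
        for j in range(count):
            sign = "inhibited" if rng.random() < sim.inhibited_fraction else "activated"
            if kind == "valence_coder":
                tuning = _valence_tuning(cfg, sign)
                schedule = valence_schedule
            elif kind == "identity_coder":
                stim = cfg.stimulus_set[j % len(cfg.stimulus_set)]
                tuning = _identity_tuning(cfg, stim, sign)
                schedule = {}
            elif kind == "salience_coder":
                tuning = _salience_tuning(cfg, sign)
                schedule = {}
            else:
                tuning = {s: 0.0 for s in cfg.stimulus_set}
                schedule = {}
            specs.append(
                ArchetypeSpec(
                    kind=kind,
                    sign=sign,
                    tuning=tuning,
                    reliability=sim.reliability,
                    learning_schedule=schedule,
                )
            )
    if not specs:
        raise ValueError("population has zero neurons")
    return specs


# -- trial schedule ---------------------------------------------------------


def _interleave_day(
    cfg: SessionConfig,
    day: int,
    block: int,
    trials_per_type: int,
    omission_fraction: float,
    rng: np.random.Generator,
    start_id: int,
) -> list[Trial]:
    """Random trial order with equal per-type counts in each half-session."""
    half_a, half_b = [], []
    n_omit = int(round(omission_fraction * trials_per_type)) if block == 1 else 0
    for stim in cfg.stimulus_set:
        omitted = np.zeros(trials_per_type, dtype=bool)
        if n_omit:
            omitted[rng.choice(trials_per_type, size=n_omit, replace=False)] = True
        seq = [(stim, bool(o)) for o in omitted]
        half = trials_per_type // 2
        half_a.extend(seq[:half])
        half_b.extend(seq[half:])
    rng.shuffle(half_a)
    rng.shuffle(half_b)
    trials = []
    for k, (stim, omitted) in enumerate(half_a + half_b):
        delivered = (block == 1) and not omitted
        trials.append(
            Trial(
                trial_id=start_id + k,
                stimulus=stim,
                day=day,
                block=block,
                outcome_delivered=delivered,
            )
        )
    return trials


# -- licking ----------------------------------------------------------------


def generate_licks(
    trial: Trial,
    config: SessionConfig,
    sated: bool,
    lick_model: LickModel,
    rng: np.random.Generator,
) -> tuple[float, ...]:
    """Draw a lick-time stream for one trial.

    Rewarded, non-sated trials get Poisson anticipatory licks over the
    stimulus-onset → outcome epoch (rate ramping over training days) plus
    consummatory licks after a delivered water outcome.  Sated trials
    contain ≥1 lick with probability ``sated_lick_prob``, placed in the
    1 s pre-outcome counting window so the behavioral gate sees them.
    """
    t_on, t_out = config.odor_onset_s, config.outcome_time_s
    outcome = config.outcome_map[trial.stimulus]
    times: list[float] = []
    if sated:
        if rng.random() < lick_model.sated_lick_prob:
            k = 1 + rng.poisson(max(lick_model.sated_mean_licks - 1.0, 0.0))
            times.extend(rng.uniform(t_out - 1.0, t_out, size=k))
    else:
        rate = lick_model.anticipatory_rate_hz.get(
            outcome, lick_model.nonrewarded_rate_hz
        )
        rate *= lick_model.day_gain(trial.day)
        if rate > 0:
            k = rng.poisson(rate * (t_out - t_on))
            times.extend(rng.uniform(t_on, t_out, size=k))
        if trial.outcome_delivered and outcome in WATER_OUTCOMES:
            dur = min(lick_model.consummatory_duration_s, config.window_s - t_out)
            k = rng.poisson(lick_model.consummatory_rate_hz * dur)
            times.extend(rng.uniform(t_out, t_out + dur, size=k))
    eps = 1e-9
    times = [min(max(x, 0.0), config.window_s - eps) for x in times]
    return tuple(sorted(times))


# -- trace synthesis --------------------------------------------------------


def _draw_kinetics(sim: SimConfig, rng: np.random.Generator) -> KineticParams:
    return KineticParams(
        rise_tau_s=rng.uniform(*sim.rise_tau_range),
        decay_tau_s=rng.uniform(*sim.decay_tau_range),
        amplitude=rng.uniform(*sim.amplitude_range),
        baseline_f=rng.uniform(*sim.baseline_f_range),
        noise_sd=sim.noise_sd,
        drift_sd=sim.drift_sd,
    )


def _neuron_trace(
    spec: ArchetypeSpec,
    kin: KineticParams,
    trials: Sequence[Trial],
    sim: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Raw fluorescence (trials x frames) for one neuron."""
    cfg = sim.session
    nf = cfg.n_frames
    rate = cfg.sampling_rate_hz
    onset_frame = int(round(cfg.odor_onset_s * rate))
    kernel = transient_waveform(
        replace(kin, amplitude=1.0), nf - onset_frame, rate
    )
    dff = np.zeros((len(trials), nf))
    for ti, trial in enumerate(trials):
        gain = spec.tuning.get(trial.stimulus, 0.0)
        if gain != 0.0 and rng.random() < spec.reliability:
            jitter = (
                rng.lognormal(0.0, sim.amp_jitter_sigma)
                if sim.amp_jitter_sigma > 0
                else 1.0
            )
            g = gain * spec.day_gain(trial.day) * kin.amplitude * jitter
            dff[ti, onset_frame:] += g * kernel
        # spontaneous transients, uniform in time, independent of the task
        n_spont = rng.poisson(sim.spontaneous_rate_per_frame * nf)
        for _ in range(n_spont):
            f0 = int(rng.integers(0, nf))
            amp = kin.amplitude * (
                rng.lognormal(0.0, sim.amp_jitter_sigma)
                if sim.amp_jitter_sigma > 0
                else 1.0
            )
            dff[ti, f0:] += amp * transient_waveform(
                replace(kin, amplitude=1.0), nf - f0, rate
            )
    np.clip(dff, -0.95, None, out=dff)  # ΔF/F inhibition bounded below by −1

    # slow multiplicative baseline drift (random walk across the session)
    steps = rng.normal(0.0, kin.drift_sd * kin.baseline_f, size=len(trials) * nf)
    baseline = kin.baseline_f + np.cumsum(steps)
    np.clip(baseline, 0.2 * kin.baseline_f, None, out=baseline)
    baseline = baseline.reshape(len(trials), nf)

    raw = baseline * (1.0 + dff)
    if kin.noise_sd > 0:
        raw = raw + rng.normal(
            0.0, kin.noise_sd * kin.baseline_f, size=raw.shape
        )
    return raw


def generate_population(
    sim: SimConfig, seed: int
) -> tuple[ImagingSession, GroundTruth]:
    """Generate a full synthetic session plus its ground truth.

    Same ``seed`` ⇒ bit-identical traces, trials, and ground truth.
    """
    rng = np.random.default_rng(seed)
    cfg = sim.session
    specs = make_archetypes(sim, rng)
    kinetics = [_draw_kinetics(sim, rng) for _ in specs]

    trials: list[Trial] = []
    for day in range(1, cfg.n_days + 1):
        trials.extend(
            _interleave_day(
                cfg,
                day,
                block=1,
                trials_per_type=cfg.trials_per_type_per_day,
                omission_fraction=sim.omission_fraction,
                rng=rng,
                start_id=len(trials),
            )
        )
    if sim.include_block2:
        trials.extend(
            _interleave_day(
                cfg,
                cfg.n_days,
                block=2,
                trials_per_type=sim.block2_trials_per_type,
                omission_fraction=0.0,
                rng=rng,
                start_id=len(trials),
            )
        )

    trials = [
        replace_licks(
            t,
            generate_licks(t, cfg, sated=(t.block == 2), lick_model=sim.lick_model, rng=rng),
        )
        for t in trials
    ]

    traces = np.stack(
        [
            _neuron_trace(spec, kin, trials, sim, rng)
            for spec, kin in zip(specs, kinetics)
        ]
    )
    session = ImagingSession(
        config=cfg,
        traces=traces,
        trials=trials,
        genotype_label=sim.genotype_label,
    )
    return session, GroundTruth(archetypes=specs, kinetics=kinetics, seed=seed)


def replace_licks(trial: Trial, licks: tuple[float, ...]) -> Trial:
    return Trial(
        trial_id=trial.trial_id,
        stimulus=trial.stimulus,
        day=trial.day,
        block=trial.block,
        outcome_delivered=trial.outcome_delivered,
        lick_times_s=licks,
    )


__all__ = [
    "ARCHETYPES",
    "KineticParams",
    "ArchetypeSpec",
    "GroundTruth",
    "LickModel",
    "SimConfig",
    "transient_waveform",
    "transient_peak_time_s",
    "generate_licks",
    "generate_population",
    "make_archetypes",
]
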