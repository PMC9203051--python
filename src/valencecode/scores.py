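"""Per-neuron valence, identity, and salience coding scores.

The three scores summarize how a neuron's mean responses across the
stimulus set are organized:

Valence score
    ``[mean |r_i − r_j| over opposite-valence pairs − mean |r_i − r_j|
    over same-valence pairs] / |max − min|``.  Neutral stimuli are
    excluded from the pair sets but still count toward the max/min
    denominator.  +1 ⇒ responses determined entirely by valence class;
    0 ⇒ valence-blind.

Identity score
    ``(|r(1)| − |r(2)|) / |r(1)|`` over magnitude-ranked responses: 1 for
    a neuron responding to exactly one stimulus, 0 when the two strongest
    responses tie.

Salience score
    the valence formula with salience classes (high = strongest outcomes,
    medium = weak outcomes; the neutral/low stimulus excluded from the
    numerator).

Shuffle nulls permute the stimulus → class assignment once per shuffle for
the whole population, preserving label multiplicities and cross-neuron
correlation structure.  Undefined scores (flat profiles) are dropped from
distributions, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .config import SessionConfig

NAN = float("nan")


@dataclass(frozen=True)
class NeuronResponseProfile:
    """Mean response per stimulus plus the class maps the scores need."""

    responses: Mapping[str, float]
    valence_map: Mapping[str, str]
    salience_map: Mapping[str, str]

    @property
    def max_response(self) -> float:
        return max(self.responses.values())

    @property
    def min_response(self) -> float:
        return min(self.responses.values())

    @classmethod
    def from_config(
        cls, responses: Mapping[str, float], config: SessionConfig
    ) -> "NeuronResponseProfile":
        return cls(
            responses=dict(responses),
            valence_map=dict(config.valence_map),
            salience_map=dict(config.salience_map),
        )


def _pair_contrast(
    responses: Mapping[str, float],
    class_map: Mapping[str, str],
    numerator_classes: Sequence[str],
) -> float:
    """Shared valence/salience formula over arbitrary class labels.

    Stimuli outside ``numerator_classes`` are excluded from both pair
    sets; the |max − min| denominator ranges over all stimuli.
    """
    stims = list(responses)
    r = {s: float(responses[s]) for s in stims}
    denom = abs(max(r.values()) - min(r.values()))
    if denom == 0:
        return NAN
    scored = [s for s in stims if class_map.get(s) in numerator_classes]
    same, opposite = [], []
    for a, b in combinations(scored, 2):
        d = abs(r[a] - r[b])
        (same if class_map[a] == class_map[b] else opposite).append(d)
    if not same or not opposite:
        return NAN
    return (float(np.mean(opposite)) - float(np.mean(same))) / denom


def valence_score(profile: NeuronResponseProfile) -> float:
    """Valence selectivity in [−1, 1]; NaN for flat profiles."""
    return _pair_contrast(
        profile.responses, profile.valence_map, ("aversive", "rewarded")
    )


def salience_score(profile: NeuronResponseProfile) -> float:
    """Salience selectivity in [−1, 1]; NaN for flat profiles."""
    return _pair_contrast(profile.responses, profile.salience_map, ("high", "medium"))


def identity_score(profile: NeuronResponseProfile) -> float:
    """Single-stimulus selectivity in [0, 1] from magnitude-ranked responses."""
    mags = sorted((abs(float(v)) for v in profile.responses.values()), reverse=True)
    if len(mags) < 2 or mags[0] == 0:
        return NAN
    return (mags[0] - mags[1]) / mags[0]


SCORERS = {
    "valence": valence_score,
    "identity": identity_score,
    "salience": salience_score,
}


@dataclass
class ShuffleNull:
    """Pooled null scores from permuted stimulus→class assignments."""

    score_kind: str
    n_shuffles: int
    null_scores: np.ndarray
    seed: int

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.null_scores))


def _permuted_map(
    stimuli: Sequence[str], class_map: Mapping[str, str], rng: np.random.Generator
) -> dict[str, str]:
    labels = [class_map[s] for s in stimuli]
    perm = rng.permutation(len(labels))
    return {s: labels[perm[i]] for i, s in enumerate(stimuli)}


def shuffle_null(
    profiles: Sequence[NeuronResponseProfile],
    score_kind: str,
    n_shuffles: int,
    seed: int,
) -> ShuffleNull:
    """Null score distribution under shuffled stimulus→class pairings.

    Each shuffle draws one permutation of the class labels over the
    stimulus set and applies it to every neuron before recomputing the
    score; the pooled distribution concatenates all shuffles.  Identity
    scores ignore class labels, so only valence/salience nulls exist.
    """
    if score_kind not in ("valence", "salience"):
        raise ValueError(f"no shuffle null for score kind {score_kind!r}")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if not profiles:
        raise ValueError("empty profile population")
    rng = np.random.default_rng(seed)
    stimuli = list(profiles[0].responses)
    base_map = (
        profiles[0].valence_map if score_kind == "valence" else profiles[0].salience_map
    )
    numer = ("aversive", "rewarded") if score_kind == "valence" else ("high", "medium")
    pooled = []
    for _ in range(n_shuffles):
        pm = _permuted_map(stimuli, base_map, rng)
        for prof in profiles:
            pooled.append(_pair_contrast(prof.responses, pm, numer))
    return ShuffleNull(
        score_kind=score_kind,
        n_shuffles=n_shuffles,
        null_scores=np.asarray(pooled, dtype=float),
        seed=seed,
    )


def compare_score_distributions(
    a: Sequence[float], b: Sequence[float], paired: bool = False
) -> tuple[float, float]:
    """Compare two score distributions.

    Unpaired ⇒ two-sided Wilcoxon rank-sum; paired ⇒ two-tailed paired
    t-test on per-neuron differences (requires matched lengths; pairs with
    an undefined member are dropped).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired comparison requires matched neuron sets")
        keep = np.isfinite(a) & np.isfinite(b)
        a, b = a[keep], b[keep]
        if a.size == 0:
            raise ValueError("no defined paired scores")
        res = stats.ttest_rel(a, b)
        return float(res.statistic), float(res.pvalue)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("empty score distribution after dropping undefined scores")
    res = stats.ranksums(a, b)
    return float(res.statistic), float(res.pvalue)


def score_population(
    profiles: Sequence[NeuronResponseProfile],
) -> dict[str, np.ndarray]:
    """All three scores for a population (NaN where undefined)."""
    return {
        kind: np.array([fn(p) for p in profiles]) for kind, fn in SCORERS.items()
    }


__all__ = [
    "NeuronResponseProfile",
    "valence_score",
    "identity_score",
    "salience_score",
    "SCORERS",
    "ShuffleNull",
    "shuffle_null",
    "compare_score_distributions",
    "score_population",
]
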