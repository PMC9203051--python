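"""Population-vector geometry: cosine similarity, Euclidean contrast, PCA.

Condition matrices are trial-averaged ΔF/F time courses (neurons × frames)
per stimulus, with a shared neuron ordering.  On top of them:

- cosine similarity between a preferred-stimulus subgroup's
  neuron-concatenated time courses under two stimuli, collected into
  same-valence vs opposite-valence samples and compared by rank-sum;
- the Euclidean (Frobenius) norm of condition-matrix differences,
  summarized as the percent excess of opposite-valence over same-valence
  pair distances (the population valence contrast);
- PCA trajectories of the condition-stacked population activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .config import SessionConfig
from .preprocess import NormalizedTraces
from .session import ImagingSession


def condition_matrices(
    norm: NormalizedTraces,
    session: ImagingSession,
    trial_indices: np.ndarray | None = None,
    epoch_frames: np.ndarray | None = None,
    neuron_indices: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Trial-averaged activity matrix (neurons × frames) per stimulus.

    Invalid (neuron, trial) entries are excluded from the average.  A
    stimulus with zero valid trials raises, naming the condition.
    """
    cfg = session.config
    if trial_indices is None:
        trial_indices = np.arange(session.n_trials)
    trial_indices = np.asarray(trial_indices, dtype=int)
    if epoch_frames is None:
        epoch_frames = np.arange(cfg.n_frames)
    if neuron_indices is None:
        neuron_indices = np.arange(norm.values.shape[0])
    stim_of = np.array([session.trials[i].stimulus for i in trial_indices])
    out: dict[str, np.ndarray] = {}
    for stim in cfg.stimulus_set:
        idx = trial_indices[stim_of == stim]
        if idx.size == 0:
            raise ValueError(f"condition {stim!r} has zero valid trials")
        block = norm.values[np.ix_(neuron_indices, idx, epoch_frames)]
        with np.errstate(invalid="ignore"):
            mat = np.nanmean(block, axis=1)
        if not np.all(np.isfinite(mat)):
            raise ValueError(f"condition {stim!r} has zero valid trials for some neuron")
        out[stim] = mat
    return out


def _valence_pairs(
    stimuli: Sequence[str], valence_map: Mapping[str, str]
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """(same-valence pairs, opposite-valence pairs), neutral excluded."""
    scored = [s for s in stimuli if valence_map.get(s) in ("aversive", "rewarded")]
    same, opposite = [], []
    for a, b in combinations(scored, 2):
        (same if valence_map[a] == valence_map[b] else opposite).append((a, b))
    return same, opposite


@dataclass
class CosineReport:
    """Labeled cosine samples and the same-vs-opposite rank-sum test."""

    samples: pd.DataFrame  # subgroup, stimulus_a, stimulus_b, label, cosine
    ranksum_stat: float
    ranksum_p: float

    def mean(self, label: str) -> float:
        vals = self.samples.loc[self.samples["label"] == label, "cosine"]
        return float(vals.mean())


def cosine_similarity_subgroups(
    matrices: Mapping[str, np.ndarray],
    subgroups: Mapping[str, np.ndarray],
    valence_map: Mapping[str, str],
) -> CosineReport:
    """Cosine similarity per (subgroup, stimulus pair), same vs opposite.

    For subgroup ``g`` and pair ``(i, j)`` the vectors are the subgroup's
    neuron-concatenated trial-averaged time courses under the two stimuli.
    Zero-norm vectors make that sample undefined; it is excluded.
    """
    stimuli = list(matrices)
    same, opposite = _valence_pairs(stimuli, valence_map)
    rows = []
    for gname, members in subgroups.items():
        members = np.asarray(members, dtype=int)
        if members.size == 0:
            continue
        for label, pairs in (("same", same), ("opposite", opposite)):
            for a, b in pairs:
                va = matrices[a][members].ravel()
                vb = matrices[b][members].ravel()
                na, nb = np.linalg.norm(va), np.linalg.norm(vb)
                if na == 0 or nb == 0:
                    continue
                rows.append(
                    {
                        "subgroup": gname,
                        "stimulus_a": a,
                        "stimulus_b": b,
                        "label": label,
                        "cosine": float(va @ vb / (na * nb)),
                    }
                )
    samples = pd.DataFrame(
        rows, columns=["subgroup", "stimulus_a", "stimulus_b", "label", "cosine"]
    )
    s = samples.loc[samples["label"] == "same", "cosine"]
    o = samples.loc[samples["label"] == "opposite", "cosine"]
    if len(s) and len(o):
        res = stats.ranksums(s, o)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        stat, p = float("nan"), float("nan")
    return CosineReport(samples=samples, ranksum_stat=stat, ranksum_p=p)


@dataclass
class EuclideanContrast:
    mean_norm_opposite: float
    mean_norm_same: float
    percent_contrast: float  # 100·(opp − same)/same; inf when same = 0
    pair_norms: pd.DataFrame = field(default_factory=pd.DataFrame)


def euclidean_contrast(
    matrices: Mapping[str, np.ndarray], valence_map: Mapping[str, str]
) -> EuclideanContrast:
    """Percent excess of opposite-valence over same-valence pair distances.

    ``norm(i, j)`` is the Frobenius norm of ``M_i − M_j``; the neutral
    stimulus is excluded from both pair sets.
    """
    same, opposite = _valence_pairs(list(matrices), valence_map)
    if not same or not opposite:
        raise ValueError("need at least one same- and one opposite-valence pair")
    rows = []
    for label, pairs in (("same", same), ("opposite", opposite)):
        for a, b in pairs:
            rows.append(
                {
                    "stimulus_a": a,
                    "stimulus_b": b,
                    "label": label,
                    "norm": float(np.linalg.norm(matrices[a] - matrices[b])),
                }
            )
    pair_norms = pd.DataFrame(rows)
    m_same = float(pair_norms.loc[pair_norms["label"] == "same", "norm"].mean())
    m_opp = float(pair_norms.loc[pair_norms["label"] == "opposite", "norm"].mean())
    if m_same == 0:
        pct = float("inf") if m_opp > 0 else float("nan")
    else:
        pct = 100.0 * (m_opp - m_same) / m_same
    return EuclideanContrast(
        mean_norm_opposite=m_opp,
        mean_norm_same=m_same,
        percent_contrast=pct,
        pair_norms=pair_norms,
    )


@dataclass
class PCATrajectories:
    """Per-condition trajectories in shared principal-component space."""

    trajectories: dict[str, np.ndarray]  # condition -> frames × components
    variance_explained: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond, traj in self.trajectories.items():
            for f, point in enumerate(traj):
                row = {"condition": cond, "frame": f}
                row.update({f"pc{i + 1}": float(x) for i, x in enumerate(point)})
                rows.append(row)
        return pd.DataFrame(rows)


def pca_trajectories(
    matrices: Mapping[str, np.ndarray], n_components: int = 3
) -> PCATrajectories:
    """Project each condition's time course onto shared principal axes.

    Condition matrices are stacked along frames (samples = condition·frame,
    features = neurons), features centered, components ordered by
    decreasing variance.
    """
    conds = list(matrices)
    n_neurons = matrices[conds[0]].shape[0]
    if n_components > n_neurons:
        raise ValueError("n_components exceeds neuron count")
    stacked = np.concatenate([matrices[c].T for c in conds], axis=0)
    if stacked.shape[0] < n_components:
        raise ValueError("too few frames × conditions for requested components")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(stacked)
    return PCATrajectories(
        trajectories={c: pca.transform(matrices[c].T) for c in conds},
        variance_explained=pca.explained_variance_ratio_.copy(),
    )


__all__ = [
    "condition_matrices",
    "cosine_similarity_subgroups",
    "CosineReport",
    "euclidean_contrast",
    "EuclideanContrast",
    "pca_trajectories",
    "PCATrajectories",
]
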