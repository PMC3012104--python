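"""Gaze-prediction metrics: shuffled-fixation ROC area and KL divergence.

Both protocols control for the central tendency of human gaze by drawing
control locations from *fixations on other scenes* rather than uniformly:
a map that merely reproduces the center bias then scores at chance.

* AUC — the Mann–Whitney statistic P(score_fix > score_ctrl) + 1/2
  P(equal), identical to the area under the ROC curve swept over all
  thresholds with the tie convention.
* KL — divergence between the histogram of saliency at fixated locations
  and at control locations, on shared equal-width bins spanning the pooled
  range, with additive smoothing before normalization.

Standard errors come from a seeded nonparametric bootstrap over scenes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .saliency import SaliencyMap
from .scene_io import FixationSet

__all__ = [
    "EvalReport",
    "auc_from_scores",
    "shuffled_roc",
    "kl_fix_vs_control",
    "kl_between_histograms",
]

N_BOOTSTRAP = 1000


@dataclass
class EvalReport:
    auc: float
    auc_se: float
    kl: float
    kl_se: float
    n_pos: int
    n_neg: int
    negative_strategy: str
    histogram_spec: tuple[int, str, float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")
        if self.kl < 0:
            raise ValueError("KL divergence must be nonnegative")
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise ValueError("positive and control counts must be positive")


def auc_from_scores(pos, neg, method: str = "rank") -> float:
    """ROC area for positive vs control score sets.

    ``rank`` computes the Mann–Whitney form directly from midranks;
    ``threshold_sweep`` builds the ROC curve over every threshold and
    integrates it (the classifier-style definition) — the two agree
    exactly under the half-tie convention.
    """
    pos = np.asarray(pos, dtype=float).ravel()
    neg = np.asarray(neg, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be nonempty")
    if method == "rank":
        ranks = stats.rankdata(np.concatenate([pos, neg]))
        r_pos = ranks[: pos.size].sum()
        u = r_pos - pos.size * (pos.size + 1) / 2.0
        return float(u / (pos.size * neg.size))
    if method == "threshold_sweep":
        thr = np.unique(np.concatenate([pos, neg]))
        # sweep thresholds from above the max down, classifying score >= t
        # as "fixation"; trapezoidal integration across tie segments
        # realizes the half-tie convention
        tpr = [0.0]
        fpr = [0.0]
        for t in thr[::-1]:
            tpr.append(float(np.mean(pos >= t)))
            fpr.append(float(np.mean(neg >= t)))
        return float(np.trapezoid(tpr, fpr))
    raise ValueError(f"unknown AUC method {method!r}")


def _lookup(maps: dict, scene_id: str, row: int, col: int, frame: int | None) -> float:
    entry = maps[scene_id]
    if isinstance(entry, SaliencyMap):
        return entry.score_at(row, col)
    if frame is None:
        raise ValueError(f"scene {scene_id} has per-frame maps but the fixation has no frame")
    if frame not in entry:
        # nearest scored frame (early fixations precede the first scored frame)
        frame = min(entry, key=lambda f: abs(f - frame))
    return entry[frame].score_at(row, col)


def _scene_scores(
    maps: dict, fix: FixationSet, seed: int
) -> tuple[list[str], dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Positive and shuffled-control score sets per scene.

    Positives are each scene's own fixation scores; controls are that
    scene's map sampled at fixation coordinates borrowed uniformly (with
    the given seed) from the other scenes.
    """
    scene_ids = [s for s in fix.scene_ids() if s in maps]
    if len(scene_ids) < 2:
        raise ValueError("shuffled controls need fixations on at least two scenes")
    rng = np.random.default_rng(seed)
    coords = {
        s: [(r.row, r.col, r.frame) for r in fix.for_scene(s)] for s in scene_ids
    }
    pos: dict[str, np.ndarray] = {}
    neg: dict[str, np.ndarray] = {}
    for s in scene_ids:
        own = coords[s]
        pos[s] = np.array([_lookup(maps, s, r, c, f) for (r, c, f) in own])
        pool = [rc for t in scene_ids if t != s for rc in coords[t]]
        picks = rng.integers(0, len(pool), size=len(own))
        neg[s] = np.array([_lookup(maps, s, *pool[p]) for p in picks])
    return scene_ids, pos, neg


def _bootstrap_over_scenes(scene_ids, statistic, seed: int, n_boot: int = N_BOOTSTRAP) -> float:
    rng = np.random.default_rng(seed)
    vals = []
    ids = np.asarray(scene_ids, dtype=object)
    for _ in range(n_boot):
        resampled = ids[rng.integers(0, len(ids), size=len(ids))]
        vals.append(statistic(resampled))
    return float(np.std(vals, ddof=1))


def shuffled_roc(maps: dict, fix: FixationSet, seed: int = 0) -> tuple[float, float]:
    """Shuffled-fixation ROC area with a bootstrap-over-scenes SE."""
    scene_ids, pos, neg = _scene_scores(maps, fix, seed)
    auc = auc_from_scores(
        np.concatenate([pos[s] for s in scene_ids]),
        np.concatenate([neg[s] for s in scene_ids]),
    )

    def stat(resampled):
        return auc_from_scores(
            np.concatenate([pos[s] for s in resampled]),
            np.concatenate([neg[s] for s in resampled]),
        )

    se = _bootstrap_over_scenes(scene_ids, stat, seed + 1)
    return auc, se


def kl_between_histograms(p_scores, q_scores, n_bins: int = 100, eps: float | None = None) -> float:
    """KL(P || Q) in nats between histograms on shared pooled-range bins."""
    p_scores = np.asarray(p_scores, dtype=float).ravel()
    q_scores = np.asarray(q_scores, dtype=float).ravel()
    if p_scores.size == 0 or q_scores.size == 0:
        raise ValueError("both score sets must be nonempty")
    pooled = np.concatenate([p_scores, q_scores])
    lo, hi = pooled.min(), pooled.max()
    if hi == lo:
        hi = lo + 1.0  # all scores equal: both histograms collapse to one bin, KL = 0
    edges = np.linspace(lo, hi, n_bins + 1)
    if eps is None:
        eps = 1.0 / pooled.size
    p, _ = np.histogram(p_scores, bins=edges)
    q, _ = np.histogram(q_scores, bins=edges)
    p = p.astype(float) + eps
    q = q.astype(float) + eps
    return float(stats.entropy(p, q))


def kl_fix_vs_control(
    maps: dict,
    fix: FixationSet,
    strategy: str = "same_coords_other_scene",
    n_bins: int = 100,
    eps: float | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """KL divergence between fixated and control saliency histograms.

    ``same_coords_other_scene`` scores each scene's fixation coordinates on
    a randomly selected *other* scene's map (the shuffled protocol);
    ``uniform_random`` draws control locations uniformly over each scene's
    own map.
    """
    scene_ids = [s for s in fix.scene_ids() if s in maps]
    if not scene_ids:
        raise ValueError("no fixated scene has a map")
    rng = np.random.default_rng(seed)
    pos: dict[str, np.ndarray] = {}
    neg: dict[str, np.ndarray] = {}
    for s in scene_ids:
        own = [(r.row, r.col, r.frame) for r in fix.for_scene(s)]
        pos[s] = np.array([_lookup(maps, s, r, c, f) for (r, c, f) in own])
        if strategy == "same_coords_other_scene":
            if len(scene_ids) < 2:
                raise ValueError("other-scene controls need at least two scenes")
            others = [t for t in scene_ids if t != s]
            t = others[rng.integers(0, len(others))]
            neg[s] = np.array([_lookup(maps, t, r, c, f) for (r, c, f) in own])
        elif strategy == "uniform_random":
            entry = maps[s]
            m = entry if isinstance(entry, SaliencyMap) else next(iter(entry.values()))
            h, w = m.shape
            rr = rng.integers(0, h, size=len(own))
            cc = rng.integers(0, w, size=len(own))
            neg[s] = m.scores[rr, cc]
        else:
            raise ValueError(f"unknown control strategy {strategy!r}")
        if neg[s].size == 0:
            raise ValueError(f"empty control set for scene {s}")

    kl = kl_between_histograms(
        np.concatenate([pos[s] for s in scene_ids]),
        np.concatenate([neg[s] for s in scene_ids]),
        n_bins=n_bins,
        eps=eps,
    )

    def stat(resampled):
        return kl_between_histograms(
            np.concatenate([pos[s] for s in resampled]),
            np.concatenate([neg[s] for s in resampled]),
            n_bins=n_bins,
            eps=eps,
        )

    se = _bootstrap_over_scenes(scene_ids, stat, seed + 1) if len(scene_ids) > 1 else 0.0
    return kl, se
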