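"""Scoring of ranked modulator lists against ground truth.

Provides the cumulative PPV-sensitivity and ROC curves of a ranking, the two
standard composite-curve constructions (11-point interpolated average
precision for PPV-sensitivity; vertical averaging for ROC), a permutation
test comparing a ranking's precision profile against random ordering, and a
pre-ranked weighted running-sum gene-set enrichment statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RankedEvaluation",
    "CompositeCurve",
    "ppv_sensitivity_curve",
    "interpolated_average_precision_11pt",
    "vertical_average_roc",
    "average_precision",
    "ranking_permutation_test",
    "preranked_enrichment",
]

GRID_11PT = np.round(np.arange(0.0, 1.01, 0.1), 1)


@dataclass
class RankedEvaluation:
    """Cumulative confusion counts and curve points of one ranked list."""

    ranked_labels: np.ndarray  # bool, True = real modulator
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    ppv: np.ndarray
    sensitivity: np.ndarray
    fpr: np.ndarray

    @property
    def specificity(self) -> np.ndarray:
        return 1.0 - self.fpr


@dataclass
class CompositeCurve:
    """A curve averaged across rankings at 11 fixed axis levels."""

    grid: np.ndarray
    values: np.ndarray
    per_curve: np.ndarray  # (n_curves, 11) interpolated inputs
    n_curves: int


def ppv_sensitivity_curve(
    ranking: Sequence[str], truth: set[str] | Sequence[str]
) -> RankedEvaluation:
    """Cumulative PPV, sensitivity and FPR at every depth of a ranking.

    ``truth`` is the set of real modulators; every element must belong to
    the evaluated universe (the ranking).  PPV = TP/(TP+FP),
    sensitivity = TP/(TP+FN), FPR = FP/(FP+TN).
    """
    ranking = list(ranking)
    truth = set(truth)
    if not ranking:
        raise ValueError("ranking is empty")
    if not truth:
        raise ValueError("truth set is empty: sensitivity is undefined")
    stray = truth - set(ranking)
    if stray:
        raise ValueError(f"truth genes absent from the ranking: {sorted(stray)}")
    labels = np.asarray([g in truth for g in ranking], dtype=bool)
    n = labels.size
    n_pos = int(labels.sum())
    n_neg = n - n_pos
    depth = np.arange(1, n + 1)
    tp = np.cumsum(labels)
    fp = depth - tp
    fn = n_pos - tp
    tn = n_neg - fp
    return RankedEvaluation(
        ranked_labels=labels,
        tp=tp, fp=fp, fn=fn, tn=tn,
        ppv=tp / depth,
        sensitivity=tp / n_pos,
        fpr=fp / n_neg if n_neg > 0 else np.zeros(n),
    )


def _interpolated_precision(curve: RankedEvaluation, grid: np.ndarray) -> np.ndarray:
    """max PPV over all depths whose sensitivity is >= each grid level.

    The interpolated PPV at sensitivity 0 is 1 by definition; levels beyond
    the curve's maximum sensitivity get 0.
    """
    out = np.zeros(grid.size)
    for i, r in enumerate(grid):
        if r == 0.0:
            out[i] = 1.0
            continue
        mask = curve.sensitivity >= r - 1e-12
        out[i] = curve.ppv[mask].max() if mask.any() else 0.0
    return out


def interpolated_average_precision_11pt(
    curves: Sequence[RankedEvaluation],
) -> CompositeCurve:
    """Composite PPV-sensitivity curve via 11-point interpolated precision.

    Per curve, the interpolated PPV at sensitivity level ``r`` is the highest
    PPV found at any sensitivity ``r' >= r``; the composite value at each of
    the 11 levels 0.0, 0.1, ..., 1.0 is the arithmetic mean across curves.
    """
    if not curves:
        raise ValueError("need at least one curve")
    per = np.vstack([_interpolated_precision(c, GRID_11PT) for c in curves])
    return CompositeCurve(GRID_11PT.copy(), per.mean(axis=0), per, len(curves))


def vertical_average_roc(curves: Sequence[RankedEvaluation]) -> CompositeCurve:
    """Composite ROC curve by vertical averaging.

    Each curve's sensitivity is sampled at 11 fixed horizontal-axis levels
    (linear interpolation between the preceding and following curve points,
    with the (0, 0) and (1, 1) endpoints appended) and the samples are
    averaged across curves.
    """
    if not curves:
        raise ValueError("need at least one curve")
    per = np.empty((len(curves), GRID_11PT.size))
    for i, c in enumerate(curves):
        x = np.concatenate([[0.0], c.fpr, [1.0]])
        y = np.concatenate([[0.0], c.sensitivity, [1.0]])
        per[i] = np.interp(GRID_11PT, x, y)
    return CompositeCurve(GRID_11PT.copy(), per.mean(axis=0), per, len(curves))


def average_precision(ranked_labels: Sequence[bool]) -> float:
    """Mean of the cumulative PPV taken at each true-positive position.

    Equals the area under the PPV-sensitivity curve of the ranking; the
    expected value of a random ordering is close to the prevalence.
    """
    labels = np.asarray(ranked_labels, dtype=bool)
    if not labels.any():
        raise ValueError("no positives in the ranking")
    depth = np.arange(1, labels.size + 1)
    ppv = np.cumsum(labels) / depth
    return float(ppv[labels].mean())


def ranking_permutation_test(
    ranked_labels: Sequence[bool],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Is a ranking's average precision better than random ordering?

    Returns ``(observed AP, p-value)`` where the p-value is the fraction of
    label permutations whose average precision reaches the observed one.
    """
    labels = np.asarray(ranked_labels, dtype=bool)
    obs = average_precision(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if average_precision(rng.permutation(labels)) >= obs:
            hits += 1
    return obs, hits / n_permutations


def _running_sum_es(
    hit: np.ndarray, weights: np.ndarray, exponent: float
) -> float:
    """Weighted running-sum enrichment score of one membership vector."""
    w = np.abs(weights) ** exponent
    w_hit = np.where(hit, w, 0.0)
    total_hit = w_hit.sum()
    n_miss = (~hit).sum()
    if total_hit == 0 or n_miss == 0:
        return 0.0
    running = np.cumsum(w_hit / total_hit - (~hit) / n_miss)
    return float(running[np.argmax(np.abs(running))])


def preranked_enrichment(
    scores: pd.Series,
    gene_sets: Mapping[str, Sequence[str]],
    n_permutations: int = 1000,
    weight: float = 1.0,
    min_size: int = 2,
    seed: int = 0,
    p_threshold: float | None = None,
) -> pd.DataFrame:
    """Pre-ranked gene-set enrichment on a scored modulator ranking.

    ``scores`` maps gene ids to the ranking statistic (e.g. normalized ΔI);
    genes are ordered by descending score.  Per set, the enrichment score is
    the maximum deviation of the weighted-hit minus uniform-miss cumulative
    sums (weight exponent ``weight``; 0 gives the classic Kolmogorov-Smirnov
    statistic).  Significance comes from permuting gene labels: the p-value
    is the fraction of permutations whose ES is at least as extreme in the
    observed direction.  Sets with fewer than ``min_size`` members present
    in the ranking are dropped; an optional ``p_threshold`` cuts the report.
    """
    scores = scores.sort_values(ascending=False, kind="stable")
    genes = scores.index.to_numpy()
    values = scores.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in gene_sets.items():
        idx = sorted({pos[g] for g in members if g in pos})
        k = len(idx)
        if k < min_size:
            continue
        hit = np.zeros(genes.size, dtype=bool)
        hit[idx] = True
        es = _running_sum_es(hit, values, weight)
        null = np.empty(n_permutations)
        for t in range(n_permutations):
            perm_hit = np.zeros(genes.size, dtype=bool)
            perm_hit[rng.choice(genes.size, size=k, replace=False)] = True
            null[t] = _running_sum_es(perm_hit, values, weight)
        # two-sided on |ES|: uniform under a randomly ordered ranking
        p = float(np.mean(np.abs(null) >= abs(es)))
        rows.append(dict(gene_set=name, size=k, es=es, p_value=p))

    if not rows:
        warnings.warn("no gene set passed the size filter; empty enrichment result",
                      RuntimeWarning, stacklevel=2)
        return pd.DataFrame(columns=["gene_set", "size", "es", "p_value"])
    out = pd.DataFrame(rows).sort_values(
        ["p_value", "gene_set"], kind="stable"
    ).reset_index(drop=True)
    if p_threshold is not None:
        out = out.loc[out["p_value"] < p_threshold].reset_index(drop=True)
    return out
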