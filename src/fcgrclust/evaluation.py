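"""Post-hoc, label-aware evaluation of unsupervised cluster assignments.

True taxonomic labels enter only here, never during training.  The main
statistic is the unsupervised classification accuracy: the Hungarian
algorithm finds the injective cluster -> taxon mapping f maximizing
agreement, and ACC = (1/n) * #{i : l_i = f(c_i)}.  NMI and ARI are
reported as complementary external indices, and a simplex projection of
the per-sequence probability vectors supports visual inspection of the
learning process.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence as TypingSequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score


@dataclass
class ContingencyTable:
    counts: np.ndarray  # c x t integer matrix
    row_labels: list  # predicted cluster labels
    col_labels: list  # true taxon labels


@dataclass
class ClusterMapping:
    mapping: dict  # cluster label -> taxon label (injective)
    matched_count: int


def _as_lists(pred, truth):
    pred = list(pred)
    truth = list(truth)
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(truth)} labels")
    if not pred:
        raise ValueError("empty labelings")
    return pred, truth


def contingency_table(
    pred: TypingSequence[Hashable], truth: TypingSequence[Hashable]
) -> ContingencyTable:
    """counts[i][j] = number of sequences in predicted cluster i, true taxon j."""
    pred, truth = _as_lists(pred, truth)
    row_labels = sorted(set(pred), key=str)
    col_labels = sorted(set(truth), key=str)
    ri = {lab: i for i, lab in enumerate(row_labels)}
    ci = {lab: j for j, lab in enumerate(col_labels)}
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=np.int64)
    for p, t in zip(pred, truth):
        counts[ri[p], ci[t]] += 1
    return ContingencyTable(counts=counts, row_labels=row_labels, col_labels=col_labels)


def hungarian_mapping(table: ContingencyTable) -> ClusterMapping:
    """Injective cluster -> taxon map maximizing the total matched count.

    A rectangular table is zero-padded to square first; clusters matched to
    a padding column stay unmapped and contribute no matches.
    """
    counts = table.counts
    c, t = counts.shape
    side = max(c, t)
    padded = np.zeros((side, side), dtype=np.int64)
    padded[:c, :t] = counts
    rows, cols = linear_sum_assignment(-padded)
    mapping = {
        table.row_labels[r]: table.col_labels[col]
        for r, col in zip(rows, cols)
        if r < c and col < t
    }
    matched = int(sum(padded[r, col] for r, col in zip(rows, cols)))
    return ClusterMapping(mapping=mapping, matched_count=matched)


def accuracy(pred: TypingSequence, truth: TypingSequence) -> float:
    """Unsupervised classification accuracy under the optimal mapping."""
    pred, truth = _as_lists(pred, truth)
    table = contingency_table(pred, truth)
    return hungarian_mapping(table).matched_count / len(pred)


def _entropy(labels: list) -> float:
    _, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def nmi(pred: TypingSequence, truth: TypingSequence) -> float:
    """Normalized mutual information, sqrt (geometric-mean) normalization.

    Undefined when either partition has a single block (zero entropy);
    raises ``ValueError`` in that case.
    """
    pred, truth = _as_lists(pred, truth)
    if _entropy(pred) == 0.0 or _entropy(truth) == 0.0:
        raise ValueError("NMI undefined: a partition has a single block")
    codes_p = np.unique(np.asarray(pred, dtype=object), return_inverse=True)[1]
    codes_t = np.unique(np.asarray(truth, dtype=object), return_inverse=True)[1]
    return float(normalized_mutual_info_score(codes_t, codes_p, average_method="geometric"))


def ari(pred: TypingSequence, truth: TypingSequence) -> float:
    """Adjusted Rand index under the permutation-model expectation."""
    pred, truth = _as_lists(pred, truth)
    codes_p = np.unique(np.asarray(pred, dtype=object), return_inverse=True)[1]
    codes_t = np.unique(np.asarray(truth, dtype=object), return_inverse=True)[1]
    return float(adjusted_rand_score(codes_t, codes_p))


def simplex_coordinates(probabilities: np.ndarray, c: int | None = None) -> np.ndarray:
    """Project probability vectors into the plane spanned by a regular c-gon.

    Each row maps to the convex combination of the polygon's vertices
    (inscribed in the unit circle, vertex 0 at 90 degrees, counter-clockwise)
    weighted by its cluster probabilities; the uniform row lands at the
    origin, a one-hot row exactly on its vertex.
    """
    probs = np.asarray(probabilities, dtype=np.float64)
    if probs.ndim == 1:
        probs = probs[None, :]
    if c is None:
        c = probs.shape[1]
    if c < 3:
        raise ValueError("simplex projection needs c >= 3")
    if probs.shape[1] != c:
        raise ValueError("probability rows must have length c")
    angles = np.pi / 2 + 2 * np.pi * np.arange(c) / c
    vertices = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    return probs @ vertices


def plot_simplex(probabilities: np.ndarray, path, labels=None) -> None:
    """Scatter the simplex projection (optional colour by true label)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = simplex_coordinates(probabilities)
    fig, ax = plt.subplots(figsize=(5, 5))
    if labels is None:
        ax.scatter(pts[:, 0], pts[:, 1], s=8, alpha=0.6)
    else:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            sel = labels == lab
            ax.scatter(pts[sel, 0], pts[sel, 1], s=8, alpha=0.6, label=str(lab))
        ax.legend(fontsize=8)
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
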