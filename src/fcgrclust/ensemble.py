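"""Majority voting over independently trained networks.

Each training run labels clusters arbitrarily, so voter labelings are
first aligned to the first voter by solving the assignment problem on
their pairwise contingency table (Hungarian algorithm), after which a
per-sequence majority vote yields the final assignment.  Averaging over
runs damps the high run-to-run variance of the randomized training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .iic_core import ClusterAssignment, Hyperparameters, assign_clusters, train_single


@dataclass
class EnsembleResult:
    per_voter: list[ClusterAssignment]  # label-aligned to the reference voter
    final_labels: np.ndarray
    vote_counts: np.ndarray  # n x c
    agreement: np.ndarray  # fraction of voters matching the final label
    reference_index: int = 0  # voter whose labeling anchors the alignment


def align_labelings(reference: np.ndarray, other: np.ndarray, c: int) -> np.ndarray:
    """Permutation ``perm`` such that ``perm[other]`` best matches ``reference``.

    Builds the c x c contingency table between the two hard labelings and
    maximizes the total agreement with the Hungarian algorithm.
    """
    reference = np.asarray(reference)
    other = np.asarray(other)
    if reference.shape != other.shape:
        raise ValueError("labelings must have equal length")
    table = np.zeros((c, c), dtype=np.int64)
    np.add.at(table, (other, reference), 1)
    rows, cols = linear_sum_assignment(-table)
    perm = np.empty(c, dtype=np.int64)
    perm[rows] = cols
    return perm


def majority_vote(aligned: list[np.ndarray], c: int | None = None) -> EnsembleResult:
    """Per-sequence mode of the aligned voter labels.

    Ties go to the label of the first (reference) voter when it is among the
    tied maxima, otherwise to the lowest tied label index.
    """
    if not aligned:
        raise ValueError("need at least one voter")
    labels = np.stack([np.asarray(a) for a in aligned])  # V x n
    v, n = labels.shape
    if c is None:
        c = int(labels.max()) + 1
    counts = np.zeros((n, c), dtype=np.int64)
    for row in labels:
        np.add.at(counts, (np.arange(n), row), 1)
    max_count = counts.max(axis=1)
    ref = labels[0]
    ref_is_mode = counts[np.arange(n), ref] == max_count
    final = np.where(ref_is_mode, ref, counts.argmax(axis=1))
    agreement = counts[np.arange(n), final] / v
    return EnsembleResult(
        per_voter=[], final_labels=final, vote_counts=counts, agreement=agreement
    )


def train_ensemble(
    pairs,
    original_fcgrs: np.ndarray,
    hp: Hyperparameters,
    ids: list[str] | None = None,
) -> EnsembleResult:
    """Train ``hp.voters`` networks (seeds seed+0..seed+V-1), align, vote.

    The alignment reference is the voter with the lowest final-epoch
    training loss: the loss is the method's own unsupervised measure of
    clustering quality, and anchoring on an arbitrary voter is fragile —
    a reference that merged two clusters leaves the assignment of the
    better voters' labels tie-ambiguous and can outvote them.  Aligned
    per-voter assignments are retained for diagnostics.
    """
    assignments: list[ClusterAssignment] = []
    final_losses: list[float] = []
    for v in range(hp.voters):
        params, history = train_single(pairs, hp, hp.seed + v)
        assignments.append(assign_clusters(params, original_fcgrs, ids=ids))
        final_losses.append(history[-1].loss if history else np.inf)
    ref = int(np.argmin(final_losses))

    aligned: list[ClusterAssignment] = []
    for v, assignment in enumerate(assignments):
        if v == ref:
            aligned.append(assignment)
            continue
        perm = align_labelings(assignments[ref].hard_labels, assignment.hard_labels, hp.c)
        aligned.append(
            ClusterAssignment(
                ids=assignment.ids,
                probabilities=assignment.probabilities[:, np.argsort(perm)],
                hard_labels=perm[assignment.hard_labels],
            )
        )
    # the reference leads the vote so that ties resolve to its labels
    vote_order = [aligned[ref]] + [a for v, a in enumerate(aligned) if v != ref]
    result = majority_vote([a.hard_labels for a in vote_order], c=hp.c)
    result.per_voter = aligned
    result.reference_index = ref
    return result
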