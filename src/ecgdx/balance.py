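"""Class-balancing subset construction for multi-label ECG datasets.

Under-sampling caps every class at ``n_max`` retained records; because
records carry ~1.4 labels on average, a record is retained whenever *any* of
its labels still needs instances (greedy pass in seeded-random order), so a
capped class can spill slightly above ``n_max`` through multi-label records
— the qualitative behaviour of the published learning subsets.
Over-sampling tops minority classes up to a target count by duplicating
their records with replacement.  Both operations use a seeded PCG64 stream
and are reproducible across platforms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class SubsetSelection:
    """Result of an under-sampling pass."""

    selected_ids: list
    per_class_counts: dict[str, int]
    n_max: float
    seed: int
    mask: np.ndarray = field(repr=False, default=None)


def undersample(labels: np.ndarray, ids: list, n_max: float, seed: int = 0,
                classes: list[str] | None = None) -> SubsetSelection:
    """Random per-class capped selection.

    Classes with at most ``n_max`` instances are fully retained; records of
    over-represented classes are kept only while some label of theirs is
    still under the cap.  Records with no scored label are always retained
    (they inflate no class).  ``selected_ids`` preserves the input order;
    with ``n_max = inf`` the selection is the identity.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        return SubsetSelection([], {}, n_max, seed, np.zeros(0, dtype=bool))
    if labels.ndim != 2 or labels.shape[0] != len(ids):
        raise ValueError("labels must be (n_records, n_classes) aligned with ids")
    if not n_max >= 1:
        raise ValueError("n_max must be at least 1")
    n_records, n_classes = labels.shape
    classes = classes or [f"class_{i}" for i in range(n_classes)]

    rng = np.random.Generator(np.random.PCG64(seed))
    order = rng.permutation(n_records)
    counts = np.zeros(n_classes)
    keep = np.zeros(n_records, dtype=bool)
    cap = math.inf if math.isinf(n_max) else float(n_max)
    for i in order:
        row = np.flatnonzero(labels[i])
        if row.size == 0 or np.any(counts[row] < cap):
            keep[i] = True
            counts[row] += 1

    selected = [ids[i] for i in range(n_records) if keep[i]]
    per_class = {classes[j]: int(np.sum(labels[keep][:, j])) for j in range(n_classes)}
    n_unlabeled = int(np.sum(labels.sum(axis=1) == 0))
    if n_unlabeled:
        logger.info("undersample: %d record(s) without scored labels retained", n_unlabeled)
    return SubsetSelection(selected, per_class, n_max, seed, keep)


@dataclass
class OversampleResult:
    """Expanded id multiset after minority-class duplication."""

    expanded_ids: list
    duplicates: list
    per_class_counts: dict[str, int]
    seed: int


def oversample(labels: np.ndarray, ids: list, target: int, seed: int = 0,
               classes: list[str] | None = None) -> OversampleResult:
    """Top minority classes up to ``target`` instances by duplication.

    Duplicates are drawn with replacement from each deficient class's
    records and reported separately so a training manifest can expand them;
    a class with zero records cannot be over-sampled and is skipped with a
    warning.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 2 or labels.shape[0] != len(ids):
        raise ValueError("labels must be (n_records, n_classes) aligned with ids")
    n_records, n_classes = labels.shape
    classes = classes or [f"class_{i}" for i in range(n_classes)]

    rng = np.random.Generator(np.random.PCG64(seed))
    duplicates: list = []
    counts = labels.sum(axis=0).astype(float)
    for j in range(n_classes):
        have = int(counts[j])
        if have >= target:
            continue
        if have == 0:
            logger.warning("oversample: class %s has no records, skipped", classes[j])
            continue
        members = np.flatnonzero(labels[:, j])
        picks = rng.choice(members, size=target - have, replace=True)
        duplicates.extend(ids[i] for i in picks)

    expanded = list(ids) + duplicates
    dup_idx = {id_: i for i, id_ in enumerate(ids)}
    final_counts = counts.copy()
    for d in duplicates:
        final_counts += labels[dup_idx[d]]
    per_class = {classes[j]: int(final_counts[j]) for j in range(n_classes)}
    return OversampleResult(expanded, duplicates, per_class, seed)
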