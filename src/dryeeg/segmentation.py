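"""Sliding-window segmentation, label binarization, and dataset splitting.

Channel signals are cut into 2-s windows with 1.9-s overlap (0.1-s stride),
each carrying the mean soft label of its samples. The train/test split is
subject-disjoint; cross-validation folds are stratified on the binarized
(soft >= 2/3) label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .labeling import SoftLabelSeries

logger = logging.getLogger(__name__)

#: Soft labels at or above this fraction of clean votes count as clean.
CLEAN_THRESHOLD = 2.0 / 3.0


@dataclass
class Segment:
    """A fixed-length single-channel window with its pooled soft label."""

    channel_name: str
    subject_id: str
    session_id: str
    start_s: float
    samples: np.ndarray
    soft_label: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if not 0.0 <= self.soft_label <= 1.0:
            raise ValueError("soft_label must lie in [0,1]")


@dataclass
class DatasetSplit:
    """Subject-disjoint train/test segments plus CV folds over the train set."""

    train: list[Segment]
    test: list[Segment]
    folds: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    seed: int = 0


def segment_channel(
    signal: np.ndarray,
    softs: SoftLabelSeries,
    window_s: float = 2.0,
    overlap_s: float = 1.9,
    subject_id: str = "",
    session_id: str = "",
) -> list[Segment]:
    """Slice one channel into overlapping windows.

    Window arithmetic is done in integer samples (200-sample window, 10-sample
    stride at the defaults) to avoid floating-point drift. Windows containing
    any missing (NaN) soft label are dropped and the drop count is logged.
    """
    if not window_s > overlap_s >= 0:
        raise ValueError("need window_s > overlap_s >= 0")
    signal = np.asarray(signal, dtype=np.float64)
    if signal.shape[0] != softs.values.shape[0]:
        raise ValueError("signal and soft labels are misaligned")
    rate = softs.rate
    win = int(round(window_s * rate))
    stride = int(round((window_s - overlap_s) * rate))
    if stride < 1:
        raise ValueError("overlap too close to window length for this rate")
    n = signal.shape[0]
    if n < win:
        logger.warning("signal shorter than one window; no segments")
        return []
    out: list[Segment] = []
    dropped = 0
    for start in range(0, n - win + 1, stride):
        soft = softs.values[start : start + win]
        if np.isnan(soft).any():
            dropped += 1
            continue
        out.append(
            Segment(
                channel_name=softs.channel_name,
                subject_id=subject_id,
                session_id=session_id,
                start_s=start / rate,
                samples=signal[start : start + win],
                soft_label=float(soft.mean()),
            )
        )
    if dropped:
        logger.info(
            "dropped %d/%d windows with missing annotations on %s",
            dropped, dropped + len(out), softs.channel_name,
        )
    return out


def binarize_soft_label(soft):
    """1 (clean) iff soft label >= 2/3, else 0 (artifact). Scalar or array."""
    arr = np.asarray(soft, dtype=np.float64)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("soft labels must lie in [0,1]")
    out = (arr >= CLEAN_THRESHOLD).astype(np.int64)
    return int(out) if np.isscalar(soft) or arr.ndim == 0 else out


def segments_to_arrays(
    segments: Sequence[Segment],
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Stack segments into (X, soft_labels, sidecar-metadata-table)."""
    X = np.stack([s.samples for s in segments]).astype(np.float32)
    soft = np.array([s.soft_label for s in segments], dtype=np.float64)
    meta = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in segments],
            "session_id": [s.session_id for s in segments],
            "channel": [s.channel_name for s in segments],
            "start_s": [s.start_s for s in segments],
            "soft_label": soft,
        }
    )
    return X, soft, meta


def subject_split(
    segments: Sequence[Segment], test_fraction: float = 0.2, seed: int = 0
) -> DatasetSplit:
    """Assign whole subjects to train or test, approaching ``test_fraction``.

    Subjects are visited in a seeded random order and moved to the test set
    while doing so brings the realized test fraction strictly closer to the
    target. Deterministic given the seed; at least one subject per side.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0,1)")
    subjects = sorted({s.subject_id for s in segments})
    if len(subjects) < 2:
        raise ValueError("need at least two subjects for a subject-wise split")
    counts = {
        subj: sum(1 for s in segments if s.subject_id == subj) for subj in subjects
    }
    total = len(segments)
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    test_subjects: set[str] = set()
    test_n = 0
    for subj in order:
        new_frac = (test_n + counts[subj]) / total
        if abs(new_frac - test_fraction) < abs(test_n / total - test_fraction):
            test_subjects.add(subj)
            test_n += counts[subj]
    if not test_subjects:  # every candidate overshot; take the smallest subject
        smallest = min(order, key=lambda s: counts[s])
        test_subjects.add(smallest)
    if len(test_subjects) == len(subjects):
        test_subjects.discard(order[0])
    train = [s for s in segments if s.subject_id not in test_subjects]
    test = [s for s in segments if s.subject_id in test_subjects]
    logger.info(
        "subject split: %d train / %d test segments (test subjects: %s)",
        len(train), len(test), sorted(test_subjects),
    )
    return DatasetSplit(train=train, test=test, seed=seed)


def stratified_folds(
    train: Sequence[Segment],
    k: int = 3,
    seed: int = 0,
    subject_wise: bool = False,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """k-fold CV assignment stratified on the binarized segment label.

    Folds are segment-level by default; ``subject_wise=True`` additionally
    keeps each subject within a single validation fold.
    """
    labels = binarize_soft_label(np.array([s.soft_label for s in train]))
    classes, class_counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present for stratification")
    if class_counts.min() < k:
        raise ValueError(f"a class has fewer than k={k} members")
    if subject_wise:
        groups = np.array([s.subject_id for s in train])
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        gen = splitter.split(labels[:, None], labels, groups)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        gen = splitter.split(labels[:, None], labels)
    return {i: (tr.copy(), va.copy()) for i, (tr, va) in enumerate(gen)}
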