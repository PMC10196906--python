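"""Multi-reviewer sample-wise annotations, soft labels, and rater agreement.

Reviewers annotate each bipolar channel sample-wise as *clean*, *clean with a
high-frequency component*, or *artifact*. The intermediate class is resolved
automatically by the band-limited RMS of the underlying signal, votes are
aggregated to a per-sample soft label (fraction of reviewers voting clean),
and inter-rater agreement is quantified with Fleiss' kappa, stratified by
reviewer count and combined as a sample-count-weighted average.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss


class Label(IntEnum):
    CLEAN = 0
    CLEAN_HF = 1
    ARTIFACT = 2
    UNANNOTATED = 3


LABEL_NAMES = {
    Label.CLEAN: "clean",
    Label.CLEAN_HF: "clean_hf",
    Label.ARTIFACT: "artifact",
}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}


@dataclass
class AnnotationTrack:
    """One reviewer's sample-wise labels on one bipolar channel."""

    reviewer_id: str
    channel_name: str
    labels: np.ndarray  # uint8 codes from Label
    rate: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass
class HFRule:
    """Automatic resolution rule for the *clean with HF component* class.

    A sample keeps the clean label when the RMS of the band-limited signal in
    a centered window stays below ``rms_threshold``; otherwise the HF activity
    is treated as muscle-grade and the sample becomes artifact. The defaults
    (25-35 Hz, 1 s window, 10 uV) are a declared interpretation of
    "small" versus "large" high-frequency component and are configurable.
    """

    band_low: float = 25.0
    band_high: float = 35.0
    rms_threshold: float = 10.0
    window_s: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValueError("need 0 < band_low < band_high")
        if self.rms_threshold <= 0:
            raise ValueError("rms_threshold must be positive")


@dataclass
class SoftLabelSeries:
    """Per-sample fraction of reviewers voting clean; NaN where unannotated."""

    channel_name: str
    values: np.ndarray  # float, in [0,1] or NaN
    n_reviewers: np.ndarray  # int votes per sample (0 where missing)
    rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.n_reviewers = np.asarray(self.n_reviewers, dtype=np.int64)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("soft labels must lie in [0,1]")


def band_rms(
    signal: np.ndarray, rate: float, band_low: float, band_high: float,
    window_s: float,
) -> np.ndarray:
    """Centered moving RMS of the band-limited signal."""
    sos = sps.butter(4, [band_low, band_high], btype="bandpass", fs=rate, output="sos")
    filtered = sps.sosfiltfilt(sos, signal)
    win = max(1, int(round(window_s * rate)))
    mean_sq = uniform_filter1d(filtered**2, size=win, mode="nearest")
    return np.sqrt(np.maximum(mean_sq, 0.0))


def resolve_hf_labels(
    track: AnnotationTrack, signal: np.ndarray, rule: HFRule | None = None
) -> AnnotationTrack:
    """Relabel CLEAN_HF samples as CLEAN (low band-limited RMS) or ARTIFACT.

    CLEAN and ARTIFACT samples are never touched.
    """
    rule = rule if rule is not None else HFRule()
    signal = np.asarray(signal, dtype=np.float64)
    if signal.shape[0] != track.labels.shape[0]:
        raise ValueError(
            f"signal length {signal.shape[0]} != labels length {track.labels.shape[0]}"
        )
    hf = track.labels == Label.CLEAN_HF
    if not hf.any():
        return track
    rms = band_rms(signal, track.rate, rule.band_low, rule.band_high, rule.window_s)
    out = track.labels.copy()
    out[hf & (rms < rule.rms_threshold)] = Label.CLEAN
    out[hf & (rms >= rule.rms_threshold)] = Label.ARTIFACT
    return replace(track, labels=out)


def aggregate_soft_labels(tracks: Sequence[AnnotationTrack]) -> SoftLabelSeries:
    """Per-sample soft label = #clean votes / #cast votes.

    Samples where every reviewer is unannotated become NaN (missing) and are
    excluded downstream. CLEAN_HF must already be resolved.
    """
    if not tracks:
        raise ValueError("need at least one annotation track")
    channels = {t.channel_name for t in tracks}
    lengths = {t.labels.shape[0] for t in tracks}
    if len(channels) != 1 or len(lengths) != 1:
        raise ValueError("tracks must share one channel and one length")
    stacked = np.stack([t.labels for t in tracks])
    if (stacked == Label.CLEAN_HF).any():
        raise ValueError("resolve CLEAN_HF labels before aggregation")
    votes = (stacked != Label.UNANNOTATED).sum(axis=0)
    clean = (stacked == Label.CLEAN).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(votes > 0, clean / np.maximum(votes, 1), np.nan)
    return SoftLabelSeries(
        channel_name=tracks[0].channel_name,
        values=values,
        n_reviewers=votes,
        rate=tracks[0].rate,
    )


def _vote_table(
    tracks: Sequence[AnnotationTrack], categories: Sequence[int]
) -> np.ndarray:
    """Items x categories count table over fully-annotated samples.

    Raises if the per-sample rater count varies (the Fleiss assumption);
    callers stratify into constant-rater-count blocks first.
    """
    stacked = np.stack([t.labels for t in tracks])
    cast = stacked != Label.UNANNOTATED
    counts_per_item = cast.sum(axis=0)
    annotated = counts_per_item > 0
    uniq = np.unique(counts_per_item[annotated])
    if uniq.size > 1:
        raise ValueError(
            f"rater count varies across samples ({uniq.tolist()}); stratify first"
        )
    table = np.stack(
        [((stacked == c) & cast).sum(axis=0)[annotated] for c in categories], axis=1
    )
    return table


def fleiss_kappa(
    tracks: Sequence[AnnotationTrack],
    categories: Sequence[int] | None = None,
) -> float:
    """Fleiss' kappa over samples as items, for a constant rater count.

    By default agreement is computed on the three annotation categories as
    made (before HF resolution); pass ``categories`` to restrict, e.g. to the
    binary clean/artifact labels after resolution.
    """
    if categories is None:
        categories = (Label.CLEAN, Label.CLEAN_HF, Label.ARTIFACT)
    table = _vote_table(tracks, categories)
    if table.shape[0] == 0:
        raise ValueError("no annotated samples")
    present = (table.sum(axis=0) > 0).sum()
    if present < 2:
        return float("nan")  # degenerate: a single category carries no chance model
    return float(_sm_fleiss(table, method="fleiss"))


def weighted_kappa_average(
    kappas: Sequence[float], weights: Sequence[float]
) -> float:
    """Sample-count-weighted mean of per-block kappas."""
    kappas = np.asarray(kappas, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if kappas.size == 0:
        raise ValueError("no blocks")
    if weights.sum() <= 0:
        raise ValueError("weights must sum to a positive value")
    return float(np.sum(kappas * weights) / np.sum(weights))


def weighted_fleiss_kappa(
    blocks: Sequence[Sequence[AnnotationTrack]],
    categories: Sequence[int] | None = None,
) -> float:
    """Kappa per constant-rater-count block, averaged with sample-count weights.

    Used when part of the data is annotated by 3 reviewers and part by 4.
    """
    if not blocks:
        raise ValueError("no blocks")
    kappas, weights = [], []
    for tracks in blocks:
        if categories is None:
            cats: Sequence[int] = (Label.CLEAN, Label.CLEAN_HF, Label.ARTIFACT)
        else:
            cats = categories
        table = _vote_table(tracks, cats)
        kappas.append(fleiss_kappa(tracks, categories))
        weights.append(table.shape[0])
    return weighted_kappa_average(kappas, weights)
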