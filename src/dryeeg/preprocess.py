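"""Raw-EEG preprocessing: bipolar montage, bandpass filter, downsample, clip.

The pipeline mirrors standard clinical dry-electrode practice: re-reference
the 8-electrode cap to 12 within-hemisphere bipolar derivations, bandpass
0.5-35 Hz (3rd-order Butterworth, applied forward-backward so annotations
stay time-aligned), resample to 100 Hz with polyphase anti-aliasing, and clip
non-physiological excursions at +/-800 uV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: Dry-cap electrode labels, left hemisphere then right.
DEFAULT_ELECTRODES = ("FC3", "CP3", "FT7", "TP7", "FC4", "CP4", "FT8", "TP8")


class MontageError(ValueError):
    """A montage references a channel absent from the recording."""


class ConfigError(ValueError):
    """A preprocessing configuration violates its constraints."""


def normalize_label(name: str) -> str:
    """Uppercase a channel label and strip common reference suffixes."""
    label = name.strip().upper()
    for suffix in ("-REF", "-LE", "-AVG"):
        if label.endswith(suffix):
            label = label[: -len(suffix)]
    return label.replace("EEG ", "").strip()


@dataclass
class RawRecording:
    """A multichannel EEG signal block in microvolts.

    ``stages`` records which preprocessing stages have been applied, so the
    pipeline can skip non-repeatable stages on already-processed input.
    """

    signal: np.ndarray  # (channels, samples), uV
    rate: float
    channel_names: list[str]
    subject_id: str = ""
    session_id: str = ""
    stages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=np.float64))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signal.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.signal.shape[0]} signal rows but "
                f"{len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def channel(self, name: str) -> np.ndarray:
        return self.signal[self.channel_names.index(name)]


@dataclass
class MontageSpec:
    """An ordered list of (anode, cathode) bipolar derivations."""

    derivations: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.derivations)) != len(self.derivations):
            raise MontageError("duplicate derivations in montage")

    def validate_against(self, channel_names: list[str]) -> None:
        known = {normalize_label(c) for c in channel_names}
        for anode, cathode in self.derivations:
            for name in (anode, cathode):
                if normalize_label(name) not in known:
                    raise MontageError(f"montage channel {name!r} not in recording")

    @property
    def channel_names(self) -> list[str]:
        return [f"{a}-{c}" for a, c in self.derivations]


def default_montage() -> MontageSpec:
    """All six within-hemisphere electrode pairs per hemisphere (12 total).

    The cap has four electrodes per hemisphere; six bipolar channels per
    hemisphere corresponds to every pairwise derivation, C(4,2) = 6.
    """
    left = ("FC3", "CP3", "FT7", "TP7")
    right = ("FC4", "CP4", "FT8", "TP8")
    derivs = []
    for side in (left, right):
        for i in range(4):
            for j in range(i + 1, 4):
                derivs.append((side[i], side[j]))
    return MontageSpec(derivs)


@dataclass
class PreprocessConfig:
    band_low: float = 0.5
    band_high: float = 35.0
    filter_order: int = 3
    target_rate: float = 100.0
    clip_limit: float = 800.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ConfigError("need 0 < band_low < band_high")
        if self.band_high >= self.target_rate / 2:
            raise ConfigError("band_high must be below the target Nyquist rate")
        if self.filter_order < 1:
            raise ConfigError("filter_order must be a positive integer")
        if self.clip_limit <= 0:
            raise ConfigError("clip_limit must be positive")


def apply_bipolar_montage(rec: RawRecording, montage: MontageSpec) -> RawRecording:
    """Re-reference to bipolar derivations: output = anode - cathode, samplewise."""
    montage.validate_against(rec.channel_names)
    norm = {normalize_label(c): i for i, c in enumerate(rec.channel_names)}
    rows = [
        rec.signal[norm[normalize_label(a)]] - rec.signal[norm[normalize_label(c)]]
        for a, c in montage.derivations
    ]
    return replace(
        rec,
        signal=np.vstack(rows),
        channel_names=montage.channel_names,
        stages=rec.stages + ("montage",),
    )


def _butter_sos(cfg: PreprocessConfig, rate: float) -> np.ndarray:
    return sps.butter(
        cfg.filter_order, [cfg.band_low, cfg.band_high], btype="bandpass",
        fs=rate, output="sos",
    )


def bandpass_filter(rec: RawRecording, cfg: PreprocessConfig) -> RawRecording:
    """Butterworth bandpass each channel; zero-phase by default."""
    if rec.rate <= 2 * cfg.band_high:
        raise ConfigError(
            f"rate {rec.rate} Hz too low for band_high {cfg.band_high} Hz"
        )
    sos = _butter_sos(cfg, rec.rate)
    if cfg.zero_phase:
        out = sps.sosfiltfilt(sos, rec.signal, axis=1)
    else:
        out = sps.sosfilt(sos, rec.signal, axis=1)
    return replace(rec, signal=out, stages=rec.stages + ("bandpass",))


def downsample(rec: RawRecording, target_rate: float) -> RawRecording:
    """Polyphase anti-aliased resampling to ``target_rate``."""
    if target_rate > rec.rate:
        raise ConfigError("target rate exceeds recording rate")
    if target_rate == rec.rate:
        return replace(rec, stages=rec.stages + ("downsample",))
    from fractions import Fraction

    frac = Fraction(target_rate / rec.rate).limit_denominator(1000)
    out = sps.resample_poly(
        rec.signal, frac.numerator, frac.denominator, axis=1, padtype="line"
    )
    return replace(
        rec, signal=out, rate=float(target_rate), stages=rec.stages + ("downsample",)
    )


def clip_amplitude(rec: RawRecording, limit: float) -> RawRecording:
    """Clip every sample to [-limit, +limit] uV. Idempotent."""
    if limit <= 0:
        raise ConfigError("clip limit must be positive")
    return replace(
        rec, signal=np.clip(rec.signal, -limit, limit), stages=rec.stages + ("clip",)
    )


def preprocess_pipeline(
    rec: RawRecording,
    montage: MontageSpec | None = None,
    cfg: PreprocessConfig | None = None,
) -> RawRecording:
    """Montage -> bandpass -> downsample -> clip, skipping already-applied
    non-repeatable stages (montage, downsample) on flagged input."""
    montage = montage if montage is not None else default_montage()
    cfg = cfg if cfg is not None else PreprocessConfig()

    if "montage" in rec.stages:
        logger.info("montage already applied; skipping")
    else:
        rec = apply_bipolar_montage(rec, montage)
        logger.info("montage: %d derivations", len(montage.derivations))
    rec = bandpass_filter(rec, cfg)
    logger.info(
        "bandpass: %g-%g Hz order %d", cfg.band_low, cfg.band_high, cfg.filter_order
    )
    if rec.rate == cfg.target_rate:
        logger.info("already at %g Hz; skipping downsample", cfg.target_rate)
        rec = replace(rec, stages=rec.stages + ("downsample",))
    else:
        rec = downsample(rec, cfg.target_rate)
        logger.info("downsample: -> %g Hz (%d samples)", rec.rate, rec.n_samples)
    rec = clip_amplitude(rec, cfg.clip_limit)
    logger.info("clip: +/-%g uV", cfg.clip_limit)
    return rec
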