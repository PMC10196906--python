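"""File I/O: EDF recordings, annotation tables, and pipeline configuration.

Recordings are exchanged as EDF (the clinical-EEG lingua franca). Reading
goes through MNE; writing uses a minimal standards-conforming EDF writer
(16-bit, 1-s data records) since no installed library exports EDF.
Annotations travel as long-form CSV intervals (reviewer_id, channel, start_s,
end_s, label) with half-open [start, end) semantics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .labeling import NAME_TO_LABEL, LABEL_NAMES, AnnotationTrack, HFRule, Label
from .model import ModelSpec, TrainConfig
from .preprocess import PreprocessConfig, RawRecording, normalize_label
from .synthdata import BackgroundParams, ReviewerParams, SynthConfig

# ---------------------------------------------------------------------- EDF

def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: RawRecording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF with 1-second data records.

    The subject and session identifiers are stored in the patient field.
    The last record is zero-padded when the duration is not a whole number
    of seconds.
    """
    path = Path(path)
    spr = int(round(rec.rate))  # samples per 1-s record
    if abs(spr - rec.rate) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = len(rec.channel_names)
    n_records = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, : rec.n_samples] = rec.signal

    phys_max = np.maximum(np.abs(padded).max(axis=1) * 1.0001, 1.0)
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            _field("0", 8),
            _field(f"{rec.subject_id} {rec.session_id}".strip() or "X", 80),
            _field("Startdate 01-JAN-2000", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * (1 + n_ch)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )
    sig_fields = []
    for name in rec.channel_names:
        sig_fields.append(_field(name, 16))
    for _ in rec.channel_names:
        sig_fields.append(_field("", 80))
    for _ in rec.channel_names:
        sig_fields.append(_field("uV", 8))
    for pm in phys_max:
        sig_fields.append(_field(f"{-pm:.6g}"[:8], 8))
    for pm in phys_max:
        sig_fields.append(_field(f"{pm:.6g}"[:8], 8))
    for _ in rec.channel_names:
        sig_fields.append(_field(str(dig_min), 8))
    for _ in rec.channel_names:
        sig_fields.append(_field(str(dig_max), 8))
    for _ in rec.channel_names:
        sig_fields.append(_field("", 80))
    for _ in rec.channel_names:
        sig_fields.append(_field(str(spr), 8))
    for _ in rec.channel_names:
        sig_fields.append(_field("", 32))

    # physical bounds as written (8-char ASCII) define the scaling actually
    # stored, so re-parse them for an exact round trip
    pmin_txt = [f"{-pm:.6g}"[:8] for pm in phys_max]
    pmax_txt = [f"{pm:.6g}"[:8] for pm in phys_max]
    pmin = np.array([float(t) for t in pmin_txt])
    pmax = np.array([float(t) for t in pmax_txt])
    gain = (pmax - pmin) / (dig_max - dig_min)
    digital = np.clip(
        np.round((padded - pmin[:, None]) / gain[:, None] + dig_min),
        dig_min, dig_max,
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(sig_fields))
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def read_recording(path: str | Path) -> RawRecording:
    """Read an EDF/EDF+ file into a microvolt recording.

    MNE converts stored physical units to SI volts; values are rescaled to
    microvolts regardless of the stored dimension. Channel labels are
    normalized against 10-20 names (case-insensitive, reference suffix
    stripped).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_edf_size(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # unreadable or truncated: fail closed
        raise IOError(f"could not read EDF file {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6
    names = [normalize_label(n) for n in raw.ch_names]
    with open(path, "rb") as fh:
        fh.seek(8)
        patient = fh.read(80).decode("ascii", errors="replace").strip()
    parts = patient.split()
    subject = parts[0] if parts else ""
    session = parts[1] if len(parts) > 1 else ""
    return RawRecording(
        signal=data_uv,
        rate=float(raw.info["sfreq"]),
        channel_names=names,
        subject_id=subject,
        session_id=session,
    )


def _check_edf_size(path: Path) -> None:
    """Fail closed on truncated files rather than returning partial data."""
    size = path.stat().st_size
    if size < 256:
        raise IOError(f"{path} is not a valid EDF file (truncated header)")
    with open(path, "rb") as fh:
        head = fh.read(256)
    try:
        header_bytes = int(head[184:192].decode("ascii").strip())
        n_records = int(head[236:244].decode("ascii").strip())
        n_ch = int(head[252:256].decode("ascii").strip())
    except ValueError as exc:
        raise IOError(f"{path} has a malformed EDF header") from exc
    with open(path, "rb") as fh:
        fh.seek(256 + n_ch * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80))
        spr_raw = fh.read(n_ch * 8)
    try:
        spr = [int(spr_raw[i * 8 : (i + 1) * 8].decode().strip()) for i in range(n_ch)]
    except ValueError as exc:
        raise IOError(f"{path} has a malformed EDF signal header") from exc
    expected = header_bytes + n_records * sum(spr) * 2
    if size < expected:
        raise IOError(
            f"{path} is truncated: {size} bytes, header promises {expected}"
        )


# -------------------------------------------------------------- annotations

ANNOTATION_COLUMNS = ["reviewer_id", "channel", "start_s", "end_s", "label"]


def tracks_to_intervals(tracks: Sequence[AnnotationTrack]) -> pd.DataFrame:
    """Long-form interval table from sample-wise tracks (runs of one label)."""
    rows = []
    for t in tracks:
        labels = t.labels
        change = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [labels.size]])
        for i0, i1 in zip(starts, ends):
            code = Label(labels[i0])
            if code == Label.UNANNOTATED:
                continue
            rows.append(
                {
                    "reviewer_id": t.reviewer_id,
                    "channel": t.channel_name,
                    "start_s": i0 / t.rate,
                    "end_s": i1 / t.rate,
                    "label": LABEL_NAMES[code],
                }
            )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotations(tracks: Sequence[AnnotationTrack], path: str | Path) -> None:
    tracks_to_intervals(tracks).to_csv(path, index=False)


def read_annotations(
    path: str | Path, rate: float, n_samples: int
) -> list[AnnotationTrack]:
    """Rasterize an interval CSV (or JSON) to sample-wise tracks.

    Half-open intervals [start_s, end_s); time not covered by any interval is
    UNANNOTATED. Overlapping intervals from one reviewer on one channel are
    rejected (a reviewer's annotation must be a function of time).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.read_json(path)
    else:
        df = pd.read_csv(path)
    if df.empty:
        return []
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    tracks = []
    for (reviewer, channel), grp in df.groupby(["reviewer_id", "channel"], sort=True):
        labels = np.full(n_samples, Label.UNANNOTATED, dtype=np.uint8)
        covered = np.zeros(n_samples, dtype=bool)
        for row in grp.itertuples():
            if row.label not in NAME_TO_LABEL:
                raise ValueError(
                    f"row {row.Index}: unknown label {row.label!r} "
                    f"(expected one of {sorted(NAME_TO_LABEL)})"
                )
            if not row.end_s > row.start_s:
                raise ValueError(f"row {row.Index}: end_s must exceed start_s")
            i0 = int(round(row.start_s * rate))
            i1 = min(int(round(row.end_s * rate)), n_samples)
            if covered[i0:i1].any():
                raise ValueError(
                    f"row {row.Index}: overlapping intervals for reviewer "
                    f"{reviewer!r} on channel {channel!r}"
                )
            covered[i0:i1] = True
            labels[i0:i1] = NAME_TO_LABEL[row.label]
        tracks.append(
            AnnotationTrack(
                reviewer_id=str(reviewer), channel_name=str(channel),
                labels=labels, rate=rate,
            )
        )
    return tracks


# ------------------------------------------------------------- configuration

@dataclass
class SegmentationConfig:
    window_s: float = 2.0
    overlap_s: float = 1.9
    test_fraction: float = 0.2
    k_folds: int = 3
    train_decimation: int = 5  # keep every k-th highly-overlapping train segment


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, round-trippable through YAML."""

    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    hf_rule: HFRule = field(default_factory=HFRule)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(max_epochs=30, patience=10)
    )
    pretrain_subjects: int = 4
    pretrain_max_epochs: int = 20
    precision_floor: float = 0.90


_NESTED = {
    "synth": SynthConfig,
    "preprocess": PreprocessConfig,
    "hf_rule": HFRule,
    "segmentation": SegmentationConfig,
    "model": ModelSpec,
    "train": TrainConfig,
    "background": BackgroundParams,
    "reviewer": ReviewerParams,
}


def _build_nested(cls, data: dict):
    """Strict nested-dataclass construction: unknown keys are rejected."""
    if not isinstance(data, dict):
        raise ValueError(f"expected a mapping for {cls.__name__}")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        if name in _NESTED and isinstance(value, dict):
            kwargs[name] = _build_nested(_NESTED[name], value)
        elif name in ("amplitude_ranges", "duration_ranges") and isinstance(value, dict):
            kwargs[name] = {k: tuple(v) for k, v in value.items()}
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def config_to_dict(cfg: PipelineConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_from_dict(data: dict) -> PipelineConfig:
    return _build_nested(PipelineConfig, data)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML (or JSON — YAML is a superset) pipeline configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
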