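"""Reading, preprocessing and annotating continuous multichannel iEEG.

A :class:`Recording` is a channel-major signal matrix (microvolts) with a
sampling rate, channel identifiers and seizure annotations in seconds
from the recording start (0-based, half-open intervals ``[onset, offset)``).

Two on-disk formats are supported:

* EDF/EDF+ (read through :mod:`mne`);
* a plain delimited text matrix, channels as rows, with a JSON sidecar
  header (``<file>.json``) carrying ``fs`` and ``channel_ids`` — raw
  depth-electrode exports are often headerless, so metadata is explicit
  rather than guessed.

Seizure annotations live in a sidecar text file with one
``onset offset`` pair (seconds) per line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, ValidationError

__all__ = [
    "SeizureAnnotation",
    "Recording",
    "PreprocessConfig",
    "read_recording",
    "write_matrix_recording",
    "read_annotations",
    "write_annotations",
    "notch_filter",
    "resample_to",
    "select_channels",
]


@dataclass(frozen=True)
class SeizureAnnotation:
    """Ictal interval in seconds from recording start, ``[onset, offset)``."""

    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not 0 <= self.onset < self.offset:
            raise ValidationError(
                f"invalid annotation: need 0 <= onset < offset, got [{self.onset}, {self.offset})"
            )


@dataclass
class Recording:
    """Continuous multichannel recording with seizure annotations.

    ``signal`` is channel-major, shape (n_channels, n_samples), in
    microvolts.  Annotations are kept sorted by onset and must lie
    within the record duration.
    """

    signal: np.ndarray
    fs: float
    channel_ids: List[str]
    annotations: List[SeizureAnnotation] = field(default_factory=list)
    start_time: float = 0.0
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.ndim != 2 or self.signal.shape[0] < 1 or self.signal.shape[1] < 1:
            raise ValidationError("signal must be a non-empty 2-D channel-major matrix")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_ids) != self.signal.shape[0]:
            raise ValidationError(
                f"{len(self.channel_ids)} channel ids for {self.signal.shape[0]} signal rows"
            )
        self.annotations = sorted(self.annotations, key=lambda a: a.onset)
        for a in self.annotations:
            if a.offset > self.duration + 1e-9:
                raise ValidationError(
                    f"annotation [{a.onset}, {a.offset}) outside record of {self.duration:.3f} s"
                )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs


@dataclass(frozen=True)
class PreprocessConfig:
    """Notch / resampling / channel-selection settings.

    Defaults target 50 Hz power-line interference at a 256 Hz working
    rate, with six analysis channels (the intracranial convention of
    three focal plus three extra-focal electrodes).
    """

    notch_freq: float = 50.0
    notch_bandwidth: float = 1.0
    target_fs: float = 256.0
    selected_channels: Optional[List[str]] = None

    def __post_init__(self) -> None:
        if self.notch_freq >= self.target_fs / 2:
            raise ConfigurationError(
                f"notch at {self.notch_freq} Hz not below Nyquist of target fs {self.target_fs} Hz"
            )
        if self.notch_bandwidth <= 0:
            raise ConfigurationError("notch bandwidth must be positive")


def read_annotations(path) -> List[SeizureAnnotation]:
    """Parse 'onset offset' pairs (seconds, one per line; '#' comments)."""
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#")[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ValidationError(f"annotation line {raw!r}: expected 'onset offset'")
        out.append(SeizureAnnotation(float(parts[0]), float(parts[1])))
    return out


def write_annotations(annotations: Sequence[SeizureAnnotation], path) -> None:
    Path(path).write_text(
        "# onset_s offset_s\n" + "".join(f"{a.onset:.6f} {a.offset:.6f}\n" for a in annotations)
    )


def _matrix_header_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def read_recording(
    path,
    format: str = "matrix",
    fs_hint: Optional[float] = None,
    annotation_path=None,
) -> Recording:
    """Read a recording from disk.

    Parameters
    ----------
    path : path-like
        EDF file, or delimited text matrix (channels as rows).
    format : {'edf', 'matrix'}
    fs_hint : float, optional
        Sampling rate for matrix files lacking a JSON sidecar header;
        required in that case, ignored for EDF.
    annotation_path : path-like, optional
        Sidecar seizure-annotation file.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        sig = raw.get_data() * 1e6  # mne returns volts
        rec = Recording(sig, float(raw.info["sfreq"]), list(raw.ch_names), recording_id=path.stem)
    elif format == "matrix":
        header = _matrix_header_path(path)
        if header.exists():
            meta = json.loads(header.read_text())
            fs = float(meta["fs"])
            ch = [str(c) for c in meta["channel_ids"]]
        elif fs_hint is not None:
            fs = float(fs_hint)
            ch = None
        else:
            raise ConfigurationError(
                f"matrix file {path} has no sidecar header {header.name} and no fs_hint"
            )
        sig = np.loadtxt(path, ndmin=2)
        if ch is None:
            ch = [f"ch{i + 1}" for i in range(sig.shape[0])]
        rec = Recording(sig, fs, ch, recording_id=path.stem)
    else:
        raise ConfigurationError(f"unknown format {format!r}; expected 'edf' or 'matrix'")
    if annotation_path is not None:
        rec = replace_annotations(rec, read_annotations(annotation_path))
    return rec


def replace_annotations(rec: Recording, annotations: Sequence[SeizureAnnotation]) -> Recording:
    """Copy of ``rec`` with new annotations (bounds-checked)."""
    return Recording(
        rec.signal,
        rec.fs,
        list(rec.channel_ids),
        list(annotations),
        rec.start_time,
        rec.recording_id,
    )


def write_matrix_recording(rec: Recording, path, annotation_path=None) -> None:
    """Write a recording as text matrix + JSON sidecar (+ annotations)."""
    path = Path(path)
    np.savetxt(path, rec.signal, fmt="%.6g")
    _matrix_header_path(path).write_text(
        json.dumps({"fs": rec.fs, "channel_ids": list(rec.channel_ids)})
    )
    if annotation_path is not None:
        write_annotations(rec.annotations, annotation_path)


def notch_filter(rec: Recording, cfg: PreprocessConfig) -> Recording:
    """Zero-phase second-order band-reject at the power-line frequency.

    Implemented as an IIR notch applied forward and backward
    (``filtfilt``), so the filter adds no group delay that would shift
    onset-relative timing.
    """
    if cfg.notch_freq >= rec.fs / 2:
        raise ConfigurationError(
            f"notch frequency {cfg.notch_freq} Hz >= Nyquist {rec.fs / 2} Hz"
        )
    quality = cfg.notch_freq / cfg.notch_bandwidth
    b, a = sps.iirnotch(cfg.notch_freq, quality, fs=rec.fs)
    filtered = sps.filtfilt(b, a, rec.signal, axis=1)
    return Recording(
        filtered, rec.fs, list(rec.channel_ids), list(rec.annotations), rec.start_time, rec.recording_id
    )


def resample_to(rec: Recording, target_fs: float) -> Recording:
    """Polyphase resampling with anti-alias filtering on downsampling."""
    if target_fs <= 0:
        raise ValidationError("target_fs must be positive")
    if target_fs == rec.fs:
        return _copy(rec)
    ratio = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = sps.resample_poly(rec.signal, ratio.numerator, ratio.denominator, axis=1)
    n_expected = int(rec.n_samples * target_fs // rec.fs)
    out = out[:, :n_expected] if out.shape[1] > n_expected else out
    return Recording(
        out, target_fs, list(rec.channel_ids), list(rec.annotations), rec.start_time, rec.recording_id
    )


def select_channels(rec: Recording, ids: Sequence[str]) -> Recording:
    """Subset/reorder channels by id; annotations are unchanged."""
    index = {c: i for i, c in enumerate(rec.channel_ids)}
    missing = [c for c in ids if c not in index]
    if missing:
        raise ValidationError(f"unknown channel id(s): {missing}")
    rows = [index[c] for c in ids]
    return Recording(
        rec.signal[rows],
        rec.fs,
        list(ids),
        list(rec.annotations),
        rec.start_time,
        rec.recording_id,
    )


def preprocess(rec: Recording, cfg: PreprocessConfig) -> Recording:
    """Notch -> resample -> channel selection, the standard chain."""
    out = notch_filter(rec, cfg)
    if cfg.target_fs != rec.fs:
        out = resample_to(out, cfg.target_fs)
    if cfg.selected_channels:
        out = select_channels(out, cfg.selected_channels)
    return out


def _copy(rec: Recording) -> Recording:
    return Recording(
        rec.signal.copy(),
        rec.fs,
        list(rec.channel_ids),
        list(rec.annotations),
        rec.start_time,
        rec.recording_id,
    )
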