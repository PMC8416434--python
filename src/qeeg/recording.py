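"""Recording ingestion, resampling and amplitude-threshold artifact rejection.

A :class:`Recording` holds one subject's multichannel EEG in microvolts,
channels in montage order. Artifact rejection marks contiguous 2-s epochs
whose amplitude exceeds a threshold on any channel; downstream spectral
windows are restricted to the surviving spans and never straddle a
rejected epoch.

The native on-disk format is a plain CSV dialect chosen for diff-ability:
one row per channel (first column the channel label), samples across
columns, with ``# key=value`` metadata lines (rate, subject_id) on top.
EDF/EDF+ is supported read-only through MNE when available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal

from .errors import (
    InsufficientCleanDataError,
    InsufficientDataError,
    UnsupportedOperationError,
)
from .montage import DEFAULT_MONTAGE, ChannelMontage, match_channels

#: Epoch length used for artifact bookkeeping, seconds. Matches the FFT
#: analysis epoch so rejection composes cleanly with 256-point windows.
EPOCH_S = 2.0

#: Minimum artifact-free duration eligible for spectral analysis, seconds.
MIN_ANALYSIS_S = 60.0


@dataclass(frozen=True)
class Recording:
    """One subject's multichannel EEG time series.

    Parameters
    ----------
    subject_id : str
        Opaque identifier.
    data : ndarray, shape (n_channels, n_samples)
        Samples in microvolts, channels in montage order.
    rate : float
        Sampling rate, samples per second.
    montage : ChannelMontage
    spans : tuple of (start, stop) sample indices
        Artifact-free spans. Defaults to the whole record; set by
        :func:`reject_artifact_windows`.
    """

    subject_id: str
    data: np.ndarray
    rate: float
    montage: ChannelMontage = DEFAULT_MONTAGE
    spans: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if data.shape[0] != len(self.montage):
            raise ValueError(
                f"data has {data.shape[0]} rows but montage has {len(self.montage)} channels"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("data contains non-finite samples")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        object.__setattr__(self, "data", data)
        if self.spans is None:
            object.__setattr__(self, "spans", ((0, data.shape[1]),))

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    @property
    def accepted_duration_s(self) -> float:
        return sum(b - a for a, b in self.spans) / self.rate


@dataclass(frozen=True)
class RejectionMask:
    """Per-epoch artifact decisions; exportable as a (start_s, end_s) table."""

    epoch_s: float
    rejected: tuple[bool, ...]

    def rejected_intervals_s(self) -> list[tuple[float, float]]:
        return [
            (i * self.epoch_s, (i + 1) * self.epoch_s)
            for i, bad in enumerate(self.rejected)
            if bad
        ]

    def to_table(self) -> str:
        lines = ["start_s\tend_s"]
        lines += [f"{a:g}\t{b:g}" for a, b in self.rejected_intervals_s()]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------- I/O


def save_recording_csv(rec: Recording, path: str | Path) -> None:
    """Write the CSV dialect: metadata header then one labelled row per channel."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# rate={rec.rate:g}\n")
        fh.write(f"# subject_id={rec.subject_id}\n")
        for label, row in zip(rec.montage.labels, rec.data):
            fh.write(label + "," + ",".join(repr(float(v)) for v in row) + "\n")


def load_recording(
    path: str | Path,
    format: str | None = None,
    montage: ChannelMontage = DEFAULT_MONTAGE,
) -> Recording:
    """Load a recording from CSV or EDF, reordering rows to montage order.

    Channel matching is order-insensitive, case-insensitive and accepts
    legacy T3/T4/T5/T6 labels; extra channels (64-channel files) are
    dropped by label. Units are assumed microvolts.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "csv":
        return _load_csv(path, montage)
    if format == "edf":
        return _load_edf(path, montage)
    raise ValueError(f"unknown format {format!r}")


def _load_csv(path: Path, montage: ChannelMontage) -> Recording:
    meta: dict[str, str] = {}
    labels: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            label, _, payload = line.partition(",")
            try:
                row = np.array(payload.split(","), dtype=np.float64)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric payload") from None
            labels.append(label)
            rows.append(row)
    if "rate" not in meta:
        raise ValueError(f"{path}: missing '# rate=' header")
    order = match_channels(labels, montage)
    lengths = {rows[i].size for i in order}
    if len(lengths) != 1:
        raise ValueError(f"{path}: channels have unequal sample counts")
    data = np.vstack([rows[i] for i in order])
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: non-numeric payload")
    return Recording(
        subject_id=meta.get("subject_id", path.stem),
        data=data,
        rate=float(meta["rate"]),
        montage=montage,
    )


def _load_edf(path: Path, montage: ChannelMontage) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise UnsupportedOperationError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    order = match_channels(raw.ch_names, montage)
    data = raw.get_data()[order] * 1e6  # MNE loads volts; montage wants microvolts
    return Recording(subject_id=path.stem, data=data, rate=float(raw.info["sfreq"]), montage=montage)


# ---------------------------------------------------------------- resampling


def resample_to_rate(rec: Recording, target_rate: float = 128.0) -> Recording:
    """Anti-alias filter and decimate to ``target_rate``.

    Polyphase resampling with a Kaiser-windowed low-pass; upsampling is
    refused. At the target rate the recording is returned unchanged.
    """
    if rec.rate < target_rate:
        raise UnsupportedOperationError(
            f"upsampling {rec.rate} -> {target_rate} samples/s is not supported"
        )
    if rec.rate == target_rate:
        return rec
    frac = Fraction(target_rate / rec.rate).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1, padtype="mean")
    return Recording(rec.subject_id, data, target_rate, rec.montage)


# ---------------------------------------------------------------- rejection


def reject_artifact_windows(
    rec: Recording,
    amplitude_limit: float = 100.0,
    min_clean_s: float = MIN_ANALYSIS_S,
) -> tuple[Recording, RejectionMask]:
    """Reject 2-s epochs exceeding ``amplitude_limit`` microvolts on any channel.

    This is a deliberately simple, fully parameterised stand-in for a
    clinical artifact-rejection protocol. Returns the recording with its
    accepted spans restricted to the surviving contiguous epochs, plus the
    rejection mask; raises :class:`InsufficientCleanDataError` if less
    than ``min_clean_s`` survives.
    """
    epoch_len = int(round(EPOCH_S * rec.rate))
    n_epochs = rec.n_samples // epoch_len
    if n_epochs == 0:
        raise InsufficientDataError("recording shorter than one 2-s epoch")
    rejected = []
    for i in range(n_epochs):
        block = rec.data[:, i * epoch_len : (i + 1) * epoch_len]
        rejected.append(bool(np.any(np.abs(block) > amplitude_limit)))
    mask = RejectionMask(EPOCH_S, tuple(rejected))

    spans: list[tuple[int, int]] = []
    start = None
    for i, bad in enumerate(rejected):
        if not bad and start is None:
            start = i
        elif bad and start is not None:
            spans.append((start * epoch_len, i * epoch_len))
            start = None
    if start is not None:
        spans.append((start * epoch_len, n_epochs * epoch_len))

    accepted_s = sum(b - a for a, b in spans) / rec.rate
    if accepted_s < min_clean_s:
        raise InsufficientCleanDataError(
            f"only {accepted_s:g} s of clean data after rejection (< {min_clean_s:g} s)"
        )
    return replace(rec, spans=tuple(spans)), mask
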