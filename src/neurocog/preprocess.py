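"""Preprocessing chain and epoching for resting-state EEG.

The chain applied to every recording, in order: drop configured bad
channels, excise bad segments by amplitude threshold, 50 Hz notch,
0.5-100 Hz band-pass, whole-head average reference.  Filters are
zero-phase (forward-backward second-order sections), so waveform timing
used by the microstate representation is preserved.

Each feature family consumes fixed-length 2 s epochs under one of two
averaging policies: ``average_waveform`` (pointwise mean epoch, the
default for the spatial family) or ``per_epoch`` (features computed per
epoch, then averaged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import Recording, ValidationError

__all__ = [
    "PreprocessConfig",
    "EpochSet",
    "preprocess_chain",
    "reject_bad_segments",
    "average_reference",
    "bandpass",
    "notch",
    "epoch",
]


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    bandpass_hz : (low, high) pass-band edges in Hz.
    notch_hz : mains frequency to suppress (0 disables).
    notch_q : notch quality factor (bandwidth = notch_hz / Q).
    amp_thresh_uV : peak-amplitude threshold for bad-segment rejection.
    reject_win_s : rejection window length in seconds.
    bad_channels : labels dropped before any filtering.
    ica : optional callable Recording -> Recording plugged in after
        rejection; disabled (None) by default.
    """

    bandpass_hz: tuple = (0.5, 100.0)
    notch_hz: float = 50.0
    notch_q: float = 35.0
    amp_thresh_uV: float = 100.0
    reject_win_s: float = 1.0
    bad_channels: tuple = ()
    ica: object = None


@dataclass
class EpochSet:
    """Fixed-length epochs cut from one recording.

    ``epochs`` has shape (n_epochs, n_channels, n_samples); ``policy``
    records how downstream features should aggregate over epochs.
    """

    source: Recording
    epochs: np.ndarray
    epoch_len_s: float
    policy: str = "per_epoch"

    def __post_init__(self):
        if self.policy not in ("average_waveform", "per_epoch"):
            raise ValueError(f"unknown policy {self.policy!r}")
        n = round(self.epoch_len_s * self.source.fs)
        if self.epochs.ndim != 3 or self.epochs.shape[2] != n:
            raise ValidationError(
                f"epochs must be (n_epochs, channels, {n}) for "
                f"{self.epoch_len_s} s at fs={self.source.fs}"
            )
        if self.epochs.shape[0] < 1:
            raise ValidationError("need at least one epoch")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def fs(self) -> float:
        return self.source.fs

    def mean_epoch(self) -> np.ndarray:
        """Pointwise mean waveform across epochs (channels x samples)."""
        return self.epochs.mean(axis=0)


def bandpass(rec: Recording, lo: float, hi: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass."""
    nyq = rec.fs / 2.0
    if hi >= nyq:
        raise ValidationError(
            f"band edge {hi} Hz not below Nyquist {nyq} Hz (fs={rec.fs})"
        )
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.signal, axis=1)
    return rec.copy_with(signal=out, log=rec.log + [f"bandpass {lo}-{hi} Hz"])


def notch(rec: Recording, f0: float = 50.0, q: float = 35.0) -> Recording:
    """Zero-phase IIR notch at the mains frequency."""
    b, a = sps.iirnotch(f0, q, fs=rec.fs)
    out = sps.filtfilt(b, a, rec.signal, axis=1)
    return rec.copy_with(signal=out, log=rec.log + [f"notch {f0} Hz (Q={q})"])


def average_reference(rec: Recording) -> Recording:
    """Re-reference to the instantaneous mean over channels.

    After this step the mean across channels is zero at every sample.
    """
    out = rec.signal - rec.signal.mean(axis=0, keepdims=True)
    return rec.copy_with(signal=out, log=rec.log + ["average reference"])


def reject_bad_segments(
    rec: Recording, amp_thresh_uV: float = 100.0, win_s: float = 1.0
):
    """Excise windows whose peak absolute amplitude exceeds a threshold.

    The recording is scanned in consecutive non-overlapping windows of
    ``win_s`` seconds; a window is rejected if any channel exceeds
    ``amp_thresh_uV`` in absolute value.  Retained windows are
    concatenated.  Returns ``(clean_recording, mask)`` where ``mask`` is a
    boolean array over the original samples marking retained data.
    """
    if amp_thresh_uV <= 0:
        raise ValueError("amp_thresh_uV must be positive")
    n = rec.n_samples
    w = int(round(win_s * rec.fs))
    mask = np.zeros(n, dtype=bool)
    keep_slices = []
    for start in range(0, n - w + 1, w):
        sl = slice(start, start + w)
        if np.max(np.abs(rec.signal[:, sl])) <= amp_thresh_uV:
            mask[sl] = True
            keep_slices.append(sl)
    # trailing partial window is kept iff clean
    rem = n % w
    if rem:
        sl = slice(n - rem, n)
        if np.max(np.abs(rec.signal[:, sl])) <= amp_thresh_uV:
            mask[sl] = True
            keep_slices.append(sl)
    if not keep_slices:
        raise ValidationError("no clean data: every window exceeds threshold")
    out = np.concatenate([rec.signal[:, sl] for sl in keep_slices], axis=1)
    removed = n - int(mask.sum())
    new = rec.copy_with(
        signal=out,
        log=rec.log
        + [f"reject_bad_segments thresh={amp_thresh_uV} uV win={win_s} s "
           f"removed={removed} samples"],
    )
    if removed > 0.5 * n:
        new.flags.append("more than 50% of data rejected")
    return new, mask


def preprocess_chain(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Full preprocessing chain, deterministic for a given (input, config)."""
    cfg = cfg or PreprocessConfig()
    if rec.fs < 200:
        raise ValidationError(
            f"fs={rec.fs} too low: band edge {cfg.bandpass_hz[1]} Hz needs fs >= 200"
        )
    out = rec
    if cfg.bad_channels:
        keep = [i for i, l in enumerate(out.channel_labels)
                if l not in set(cfg.bad_channels)]
        out = out.copy_with(
            signal=out.signal[keep],
            channel_labels=tuple(out.channel_labels[i] for i in keep),
            log=out.log + [f"dropped channels {list(cfg.bad_channels)}"],
        )
    out, _mask = reject_bad_segments(out, cfg.amp_thresh_uV, cfg.reject_win_s)
    if cfg.ica is not None:
        out = cfg.ica(out)
        out.log.append("ica artifact removal (pluggable stage)")
    if cfg.notch_hz:
        out = notch(out, cfg.notch_hz, cfg.notch_q)
    out = bandpass(out, *cfg.bandpass_hz)
    out = average_reference(out)
    return out


def epoch(
    rec: Recording,
    n_epochs: int,
    epoch_len_s: float = 2.0,
    policy: str = "per_epoch",
) -> EpochSet:
    """Cut the earliest ``n_epochs`` consecutive non-overlapping epochs."""
    n = round(epoch_len_s * rec.fs)
    need = n_epochs * n
    if rec.n_samples < need:
        raise ValidationError(
            f"insufficient clean data: need {need / rec.fs:.1f} s, "
            f"have {rec.duration_s:.1f} s"
        )
    arr = rec.signal[:, :need].reshape(rec.n_channels, n_epochs, n)
    return EpochSet(
        source=rec,
        epochs=np.ascontiguousarray(arr.transpose(1, 0, 2)),
        epoch_len_s=epoch_len_s,
        policy=policy,
    )
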