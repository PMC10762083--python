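"""Shared data model and EEG/metadata I/O.

A :class:`Recording` is one subject-session of multi-channel resting-state
EEG (channels x samples, microvolts) together with its clinical metadata:
the diagnostic label (healthy control / mild cognitive impairment /
dementia), the two 0-30 cognitive screening scales (MoCA-B and MMSE), and
the acquisition device.  All feature modules consume recordings in the
canonical 64-channel 10-10 order defined here.

EEG files are read through MNE-Python (BrainVision triplets, EDF(+), FIF);
metadata travels as a plain CSV.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CANONICAL_64",
    "MONTAGE_1020_19",
    "LABELS",
    "Recording",
    "Cohort",
    "load_recording",
    "save_recording",
    "load_metadata",
    "save_metadata",
    "expand_channels",
    "channel_positions",
]

#: Diagnostic classes, ordered from intact to impaired cognition.
LABELS = ("HC", "MCI", "dementia")

#: Canonical 64-channel montage (extended 10-20 / 10-10 names, the standard
#: 64-electrode research cap layout).  All feature modules index channels in
#: this order.
CANONICAL_64 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8",
    "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6",
    "PO7", "PO3", "POz", "PO4", "PO8",
)

#: Classic 19-channel clinical 10-20 montage (used by the external
#: validation data; expanded to :data:`CANONICAL_64` before scoring).
MONTAGE_1020_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
)

DEVICES = ("NeuroScan", "Neuracle", "BP", "other")


class ValidationError(ValueError):
    """Raised when a recording violates a data-model invariant."""


class FormatError(IOError):
    """Raised when an EEG file cannot be parsed under its claimed format."""


@dataclass
class Recording:
    """One subject-session of multi-channel EEG plus clinical metadata.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    session : int
        Session number, >= 1 (participants are typically recorded twice).
    device : str
        Acquisition amplifier; metadata only, never used for processing.
    channel_labels : tuple of str
        Ordered electrode names (10-20 / 10-10 nomenclature).
    fs : float
        Sampling rate in Hz.
    signal : ndarray, shape (n_channels, n_samples)
        EEG in microvolts.
    label : str or None
        Clinical class, one of ``{"HC", "MCI", "dementia"}``.
    moca_b, mmse : int or None
        Cognitive screening scores, each on a 0-30 scale.
    """

    subject_id: str
    session: int
    device: str
    channel_labels: tuple
    fs: float
    signal: np.ndarray
    label: str | None = None
    moca_b: int | None = None
    mmse: int | None = None
    flags: list = field(default_factory=list)
    log: list = field(default_factory=list)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] != len(self.channel_labels):
            raise ValidationError(
                f"signal has {self.signal.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("duplicated channel labels")
        if not self.fs > 0:
            raise ValidationError("sampling rate must be positive")
        if self.session < 1:
            raise ValidationError("session must be >= 1")
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("signal contains NaN/Inf samples")
        if self.label is not None and self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}")
        for name in ("moca_b", "mmse"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 30):
                raise ValidationError(f"{name}={v} outside [0, 30]")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "Recording":
        if "flags" not in kw:
            kw["flags"] = list(self.flags)
        if "log" not in kw:
            kw["log"] = list(self.log)
        return replace(self, **kw)

    def key(self) -> tuple:
        return (self.subject_id, self.session)


@dataclass
class Cohort:
    """A list of recordings with unique (subject, session) keys."""

    recordings: list

    def __post_init__(self):
        keys = [r.key() for r in self.recordings]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (subject_id, session) pair in cohort")

    def __len__(self):
        return len(self.recordings)

    def __iter__(self):
        return iter(self.recordings)

    def subjects(self) -> list:
        seen, out = set(), []
        for r in self.recordings:
            if r.subject_id not in seen:
                seen.add(r.subject_id)
                out.append(r.subject_id)
        return out

    def by_subject(self) -> dict:
        idx: dict = {}
        for i, r in enumerate(self.recordings):
            idx.setdefault(r.subject_id, []).append(i)
        return idx


# ---------------------------------------------------------------------------
# Electrode geometry


def _standard_positions() -> dict:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mon = mne.channels.make_standard_montage("standard_1005")
    pos = mon.get_positions()["ch_pos"]
    return {k: np.asarray(v, dtype=float) for k, v in pos.items()}


_POSITIONS_CACHE: dict = {}


def channel_positions(labels: Sequence[str]) -> np.ndarray:
    """3-D scalp coordinates (meters, head frame) for 10-20/10-10 labels.

    Raises
    ------
    KeyError
        Listing every label with no resolvable standard coordinate.
    """
    if not _POSITIONS_CACHE:
        _POSITIONS_CACHE.update(_standard_positions())
    missing = [l for l in labels if l not in _POSITIONS_CACHE]
    if missing:
        raise KeyError(f"no standard 10-20 coordinates for: {missing}")
    return np.array([_POSITIONS_CACHE[l] for l in labels])


def expand_channels(rec: Recording, target_labels: Sequence[str]) -> Recording:
    """Expand a montage by nearest-neighbor channel duplication.

    Each target channel missing from ``rec`` receives a copy of the signal
    of its nearest existing electrode in 3-D scalp coordinates (Euclidean
    distance on the standard montage, ties broken by lexicographic label
    order).  Channels already present pass through unchanged.  The output
    contains exactly ``target_labels``, in order; the operation is
    idempotent on an already-complete montage.
    """
    target_labels = tuple(target_labels)
    have = {l: i for i, l in enumerate(rec.channel_labels)}
    if all(l in have for l in target_labels):
        sel = [have[l] for l in target_labels]
        return rec.copy_with(channel_labels=target_labels, signal=rec.signal[sel])

    src_pos = channel_positions(rec.channel_labels)
    tgt_missing = [l for l in target_labels if l not in have]
    tgt_pos = channel_positions(tgt_missing)

    out = np.empty((len(target_labels), rec.n_samples))
    log = list(rec.log)
    for j, lab in enumerate(target_labels):
        if lab in have:
            out[j] = rec.signal[have[lab]]
        else:
            p = tgt_pos[tgt_missing.index(lab)]
            d = np.linalg.norm(src_pos - p, axis=1)
            best = np.min(d)
            # deterministic tie-break: lexicographically first label
            cand = sorted(
                rec.channel_labels[i] for i in np.where(np.isclose(d, best))[0]
            )
            out[j] = rec.signal[have[cand[0]]]
            log.append(f"expand_channels: {lab} <- {cand[0]} (d={best:.4f} m)")
    return rec.copy_with(channel_labels=target_labels, signal=out, log=log)


# ---------------------------------------------------------------------------
# File I/O (delegated to MNE)

_READERS = {"brainvision", "edf", "fif"}


def load_recording(
    path: str | Path,
    format: str | None = None,
    *,
    subject_id: str = "",
    session: int = 1,
    device: str = "other",
    label: str | None = None,
    moca_b: int | None = None,
    mmse: int | None = None,
) -> Recording:
    """Read an EEG file into a :class:`Recording` (microvolt units).

    ``format`` is one of ``{"brainvision", "edf", "fif"}``; when omitted it
    is inferred from the file suffix (.vhdr / .edf / .fif).  Unknown channel
    labels are kept verbatim and flagged; a file containing NaN or Inf
    samples is rejected.
    """
    import mne

    path = Path(path)
    if format is None:
        format = {".vhdr": "brainvision", ".edf": "edf", ".fif": "fif"}.get(
            path.suffix.lower()
        )
    if format not in _READERS:
        raise FormatError(f"unsupported or undetectable format for {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if format == "brainvision":
                raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
            elif format == "edf":
                raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
            else:
                raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    except ValidationError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize reader failures
        raise FormatError(f"cannot read {path} as {format}: {exc}") from exc

    data = raw.get_data() * 1e6  # MNE works in volts; the model in microvolts
    labels = tuple(raw.ch_names)
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicated channel labels in {path}")
    flags = []
    if not _POSITIONS_CACHE:
        _POSITIONS_CACHE.update(_standard_positions())
    unknown = [l for l in labels if l not in _POSITIONS_CACHE]
    if unknown:
        flags.append(f"unknown channel labels kept verbatim: {unknown}")
    sid = subject_id or path.stem
    return Recording(
        subject_id=sid,
        session=session,
        device=device,
        channel_labels=labels,
        fs=float(raw.info["sfreq"]),
        signal=data,
        label=label,
        moca_b=moca_b,
        mmse=mmse,
        flags=flags,
    )


def save_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording to FIF (the one format MNE writes natively)."""
    import mne

    path = Path(path)
    info = mne.create_info(list(rec.channel_labels), rec.fs, ch_types="eeg")
    raw = mne.io.RawArray(rec.signal * 1e-6, info, verbose="error")
    raw.save(path, overwrite=True, verbose="error")
    return path


# ---------------------------------------------------------------------------
# Metadata CSV

_META_COLS = ["subject_id", "session", "device", "label", "moca_b", "mmse", "file"]


def save_metadata(cohort: Iterable[Recording], path: str | Path,
                  files: dict | None = None) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_META_COLS)
        for r in cohort:
            w.writerow([
                r.subject_id, r.session, r.device, r.label or "",
                "" if r.moca_b is None else r.moca_b,
                "" if r.mmse is None else r.mmse,
                (files or {}).get(r.key(), ""),
            ])
    return path


def load_metadata(path: str | Path) -> list:
    """Read the per-recording metadata table as a list of dicts."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append({
                "subject_id": row["subject_id"],
                "session": int(row["session"]),
                "device": row.get("device") or "other",
                "label": row.get("label") or None,
                "moca_b": int(row["moca_b"]) if row.get("moca_b") else None,
                "mmse": int(row["mmse"]) if row.get("mmse") else None,
                "file": row.get("file") or None,
            })
    return rows
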