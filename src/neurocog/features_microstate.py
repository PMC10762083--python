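"""Microstate sequence representation and its dynamics features.

This variant of microstate analysis summarizes each non-overlapping
100 ms window of multi-channel EEG by the per-channel standard deviation
(a nonnegative vector, one entry per channel), pools the window vectors
of all recordings, and clusters them into 20 global classes with
k-means.  Each recording then becomes a label sequence (1500 states for a
150 s segment), from which run-length statistics are computed: per-state
mean duration, coverage and occurrence rate, the mean Euclidean distance
between centroids of consecutive distinct states ("transition
distance"), and the Shannon entropy of the empirical transition
distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .io import Recording, ValidationError

__all__ = [
    "MicrostateModel",
    "windows",
    "fit_microstate_model",
    "assign_sequence",
    "sequence_features",
    "run_lengths",
]

DEFAULT_K = 20
WINDOW_S = 0.1


@dataclass
class MicrostateModel:
    """Global microstate centroids in z-scored window-vector space.

    ``mean``/``std`` are the pooled per-dimension statistics used to
    normalize window vectors before clustering; distances for the
    transition feature live in the same normalized space.
    """

    centroids: np.ndarray          # k x n_channels, normalized space
    k: int
    mean: np.ndarray
    std: np.ndarray
    seed: int
    inertia: float = float("nan")

    def __post_init__(self):
        if self.centroids.shape[0] != self.k:
            raise ValidationError("centroid count != k")
        if not np.all(np.isfinite(self.centroids)):
            raise ValidationError("non-finite centroids")

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        return (vectors - self.mean) / self.std

    def predict(self, vectors: np.ndarray) -> np.ndarray:
        """Nearest-centroid labels (0-based) for raw window vectors."""
        z = self.transform(np.atleast_2d(vectors))
        d = ((z[:, None, :] - self.centroids[None]) ** 2).sum(-1)
        return d.argmin(axis=1)

    def save(self, path) -> Path:
        path = Path(path)
        payload = {
            "k": self.k,
            "seed": self.seed,
            "inertia": self.inertia,
            "centroids": self.centroids.tolist(),
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "version": 1,
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path) -> "MicrostateModel":
        d = json.loads(Path(path).read_text())
        return cls(
            centroids=np.asarray(d["centroids"], dtype=float),
            k=d["k"],
            mean=np.asarray(d["mean"], dtype=float),
            std=np.asarray(d["std"], dtype=float),
            seed=d["seed"],
            inertia=d["inertia"],
        )


def windows(rec: Recording, window_s: float = WINDOW_S,
            total_s: float | None = 150.0) -> np.ndarray:
    """Per-channel std over consecutive 100 ms windows.

    Returns an (n_windows, n_channels) array; a 150 s segment yields
    exactly 1500 windows.  ``total_s=None`` uses all full windows.
    """
    w = int(round(window_s * rec.fs))
    if total_s is None:
        n_win = rec.n_samples // w
    else:
        n_win = int(np.floor(total_s / window_s))
        if rec.n_samples < n_win * w:
            raise ValidationError(
                f"insufficient data: need {total_s} s, have {rec.duration_s:.1f} s"
            )
    seg = rec.signal[:, : n_win * w].reshape(rec.n_channels, n_win, w)
    return np.ascontiguousarray(seg.std(axis=2, ddof=0).T)


def fit_microstate_model(
    pool: np.ndarray, k: int = DEFAULT_K, seed: int = 0, n_restarts: int = 10
) -> MicrostateModel:
    """Cluster pooled window vectors from all recordings into k classes.

    Window vectors are z-scored per dimension (pooled statistics, stored
    in the model), then clustered with k-means (k-means++ init,
    ``n_restarts`` restarts, best inertia kept).
    """
    pool = np.asarray(pool, dtype=float)
    if pool.shape[0] < k:
        raise ValidationError(f"pool of {pool.shape[0]} windows < k={k}")
    if np.unique(pool, axis=0).shape[0] < k:
        raise ValidationError("fewer distinct window vectors than clusters")
    mean = pool.mean(axis=0)
    std = pool.std(axis=0, ddof=0)
    std = np.where(std > 0, std, 1.0)
    z = (pool - mean) / std
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed).fit(z)
    return MicrostateModel(
        centroids=km.cluster_centers_, k=k, mean=mean, std=std,
        seed=seed, inertia=float(km.inertia_),
    )


def assign_sequence(rec: Recording, model: MicrostateModel,
                    window_s: float = WINDOW_S,
                    total_s: float | None = 150.0) -> np.ndarray:
    """Microstate label sequence (0-based class ids) for one recording."""
    return model.predict(windows(rec, window_s, total_s))


def run_lengths(labels: np.ndarray):
    """Maximal runs of a label sequence as (state, length) pairs."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [(int(labels[s]), int(e - s)) for s, e in zip(starts, ends)]


def sequence_features(labels: np.ndarray, model: MicrostateModel,
                      window_s: float = WINDOW_S) -> dict:
    """Dynamics features of one microstate label sequence.

    Per-state mean duration (seconds), coverage (fraction of windows) and
    occurrence rate (runs per second); mean transition distance between
    centroids of consecutive distinct states; Shannon entropy (nats) of
    the empirical distribution of transitions between distinct states.
    States absent from the sequence get duration, coverage and occurrence
    0.  A single-state sequence has no transitions: the transition
    distance is reported as 0 with a ``degenerate`` flag.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValidationError("empty sequence")
    if labels.min() < 0 or labels.max() >= model.k:
        raise ValidationError("label outside model range")
    k = model.k
    n = labels.size
    total_s = n * window_s

    runs = run_lengths(labels)
    feats: dict = {}
    run_count = np.zeros(k)
    run_time = np.zeros(k)
    for state, length in runs:
        run_count[state] += 1
        run_time[state] += length * window_s
    counts = np.bincount(labels, minlength=k)
    for s in range(k):
        dur = run_time[s] / run_count[s] if run_count[s] else 0.0
        feats[f"duration_state{s + 1}"] = dur
        feats[f"coverage_state{s + 1}"] = counts[s] / n
        feats[f"occurrence_state{s + 1}"] = run_count[s] / total_s

    # transitions between distinct consecutive states
    a, b = labels[:-1], labels[1:]
    mask = a != b
    ta, tb = a[mask], b[mask]
    if ta.size == 0:
        feats["mean_transition_distance"] = 0.0
        feats["transition_entropy"] = 0.0
        feats["degenerate"] = 1.0
    else:
        d = np.linalg.norm(model.centroids[ta] - model.centroids[tb], axis=1)
        feats["mean_transition_distance"] = float(d.mean())
        pair_ids = ta * k + tb
        p = np.bincount(pair_ids).astype(float)
        p = p[p > 0] / p.sum()
        feats["transition_entropy"] = float(-(p * np.log(p)).sum())
        feats["degenerate"] = 0.0
    return feats
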