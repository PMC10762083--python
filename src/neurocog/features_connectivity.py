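"""Spatial-domain features: MVAR-based directed transfer function, phase
lag index, graph-theoretic network properties and major-connection
filtering.

The directed transfer function (DTF) derives from a multivariate
autoregressive (MVAR) model fitted across 2 s epochs by least squares.
With ``A(f) = I - sum_k A_k exp(-i 2 pi f k / fs)`` and
``H(f) = A(f)^-1``, the DTF from channel j to channel i is
``|H_ij(f)|^2 / sum_m |H_im(f)|^2`` — normalized over inflows, so every
row sums to one at each frequency.  Connectivity matrices are read
column -> row ("flow from the column channel into the row channel").

The phase lag index (PLI) between two channels is the absolute mean sign
of their instantaneous (analytic-signal) phase difference; it is
insensitive to zero-lag coupling.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import signal as sps

from .preprocess import EpochSet

__all__ = [
    "MVARModel",
    "ConnectivityMatrix",
    "fit_mvar",
    "dtf",
    "pli",
    "network_properties",
    "major_connections",
]


@dataclass
class MVARModel:
    """Stable MVAR model: ``x_t = sum_k A_k x_{t-k} + e_t``."""

    order: int
    coeffs: np.ndarray        # p x ch x ch
    noise_cov: np.ndarray
    fs: float

    def spectral_radius(self) -> float:
        p, ch, _ = self.coeffs.shape
        comp = np.zeros((p * ch, p * ch))
        comp[:ch, :] = np.concatenate(self.coeffs, axis=1)
        if p > 1:
            comp[ch:, : ch * (p - 1)] = np.eye(ch * (p - 1))
        return float(np.abs(np.linalg.eigvals(comp)).max())

    def is_stable(self) -> bool:
        return self.spectral_radius() < 1.0


@dataclass
class ConnectivityMatrix:
    """Channels x channels coupling; entry (i, j) = flow j -> i."""

    values: np.ndarray
    kind: str                 # dtf | pli | strength
    band: tuple | str = "broadband"
    labels: tuple | None = None

    def mean_information_strength(self) -> float:
        """Mean of the off-diagonal entries."""
        v = self.values
        n = v.shape[0]
        off = ~np.eye(n, dtype=bool)
        return float(v[off].mean())


def _lagged_design(data: np.ndarray, p: int):
    """Stack (Y, X) regression blocks over epochs for an MVAR fit."""
    ys, xs = [], []
    for ep in data:                       # ch x n
        n = ep.shape[1]
        Y = ep[:, p:]                     # ch x (n-p)
        X = np.concatenate([ep[:, p - k : n - k] for k in range(1, p + 1)], axis=0)
        ys.append(Y)
        xs.append(X)
    return np.concatenate(ys, axis=1), np.concatenate(xs, axis=1)


def _fit_order(data: np.ndarray, p: int, fs: float) -> tuple:
    Y, X = _lagged_design(data, p)
    ch = Y.shape[0]
    A, *_ = np.linalg.lstsq(X.T, Y.T, rcond=None)
    A = A.T                                # ch x ch*p
    resid = Y - A @ X
    neff = Y.shape[1]
    cov = resid @ resid.T / max(neff - ch * p, 1)
    coeffs = np.stack([A[:, k * ch : (k + 1) * ch] for k in range(p)])
    return coeffs, cov, neff, resid


def fit_mvar(epochs: EpochSet, order: int | str = "auto",
             order_range=(2, 15)) -> MVARModel:
    """Least-squares MVAR fit pooled over epochs.

    ``order="auto"`` selects the lag order by the Bayesian information
    criterion over ``order_range``.  Raises if the fitted model is
    unstable (companion spectral radius >= 1) or under-identified.
    Under the ``average_waveform`` policy the fit uses the pointwise-mean
    epoch (the superimposed average); otherwise the regression pools all
    epochs.
    """
    if epochs.policy == "average_waveform":
        data = epochs.mean_epoch()[None]
    else:
        data = epochs.epochs
    ch = data.shape[1]
    n = data.shape[2]

    def check_ident(p):
        if n <= p * ch:
            raise ValueError(
                f"epoch length {n} must exceed order*channels = {p * ch}"
            )

    if order == "auto":
        best = None
        for p in range(order_range[0], order_range[1] + 1):
            if n <= p * ch:
                break
            coeffs, cov, neff, _ = _fit_order(data, p, epochs.fs)
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                continue
            bic = logdet + (np.log(neff) * p * ch * ch) / neff
            if best is None or bic < best[0]:
                best = (bic, p, coeffs, cov)
        if best is None:
            raise ValueError("BIC order selection failed on every candidate")
        _, p, coeffs, cov = best
    else:
        p = int(order)
        check_ident(p)
        coeffs, cov, _, _ = _fit_order(data, p, epochs.fs)

    model = MVARModel(order=p, coeffs=coeffs, noise_cov=cov, fs=epochs.fs)
    if not model.is_stable():
        raise ValueError(
            f"unstable MVAR fit: spectral radius {model.spectral_radius():.4f}"
        )
    return model


def dtf(model: MVARModel, band: tuple = (0.5, 40.0), df: float = 0.5) -> ConnectivityMatrix:
    """Band-averaged directed transfer function of a fitted MVAR model."""
    lo, hi = band
    freqs = np.arange(lo, hi + 1e-9, df)
    ch = model.coeffs.shape[1]
    p = model.order
    acc = np.zeros((ch, ch))
    k = np.arange(1, p + 1)
    for f in freqs:
        z = np.exp(-2j * np.pi * f * k / model.fs)
        Af = np.eye(ch, dtype=complex) - np.tensordot(z, model.coeffs, axes=(0, 0))
        try:
            H = np.linalg.inv(Af)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular transfer matrix at {f} Hz") from exc
        h2 = np.abs(H) ** 2
        acc += h2 / h2.sum(axis=1, keepdims=True)
    return ConnectivityMatrix(values=acc / freqs.size, kind="dtf", band=band)


def dtf_spectrum(model: MVARModel, freqs: np.ndarray) -> np.ndarray:
    """DTF at each frequency (n_freqs x ch x ch); rows sum to 1."""
    ch = model.coeffs.shape[1]
    k = np.arange(1, model.order + 1)
    out = np.empty((len(freqs), ch, ch))
    for a, f in enumerate(freqs):
        z = np.exp(-2j * np.pi * f * k / model.fs)
        Af = np.eye(ch, dtype=complex) - np.tensordot(z, model.coeffs, axes=(0, 0))
        h2 = np.abs(np.linalg.inv(Af)) ** 2
        out[a] = h2 / h2.sum(axis=1, keepdims=True)
    return out


def pli(epochs: EpochSet, band: tuple = (8.0, 12.0), order: int = 4) -> ConnectivityMatrix:
    """Phase lag index matrix, averaged over epochs.

    Each epoch is band-passed (zero-phase Butterworth), the analytic
    phase extracted per channel, and ``PLI(a, b) = |mean_t
    sign(phi_a(t) - phi_b(t))|``.  The result is symmetric with zero
    diagonal and invariant to channel amplitude scaling.
    """
    sos = sps.butter(order, band, btype="bandpass", fs=epochs.fs, output="sos")
    ch = epochs.epochs.shape[1]
    acc = np.zeros((ch, ch))
    for ep in epochs.epochs:
        filt = sps.sosfiltfilt(sos, ep, axis=1)
        phase = np.angle(sps.hilbert(filt, axis=1))
        diff = phase[:, None, :] - phase[None, :, :]
        acc += np.abs(np.sign(np.sin(diff)).mean(axis=2))
    vals = acc / epochs.n_epochs
    np.fill_diagonal(vals, 0.0)
    return ConnectivityMatrix(values=vals, kind="pli", band=band)


def network_properties(conn: ConnectivityMatrix) -> dict:
    """Weighted-directed graph metrics of a connectivity matrix.

    Edge weight j -> i is ``conn.values[i, j]`` (diagonal excluded);
    path distances are 1/weight.  Characteristic path length averages
    finite shortest-path distances over ordered pairs (unreachable pairs
    are excluded); global efficiency is the mean of 1/distance with
    unreachable pairs contributing 0, so it stays finite on disconnected
    graphs.  Density counts directed edges whose weight strictly exceeds
    the mean off-diagonal weight.
    """
    W = conn.values.copy().astype(float)
    n = W.shape[0]
    np.fill_diagonal(W, 0.0)

    in_strength = W.sum(axis=1)    # inflow into each row node
    out_strength = W.sum(axis=0)

    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                # edge j -> i with weight W[i, j]
                G.add_edge(j, i, weight=W[i, j], distance=1.0 / W[i, j])

    dists = dict(nx.all_pairs_dijkstra_path_length(G, weight="distance"))
    finite, inv = [], []
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            d = dists.get(s, {}).get(t, np.inf)
            if np.isfinite(d):
                finite.append(d)
                inv.append(1.0 / d)
            else:
                inv.append(0.0)
    cpl = float(np.mean(finite)) if finite else float("inf")
    geff = float(np.mean(inv)) if inv else 0.0

    clust = nx.clustering(G, weight="weight")
    betw = nx.betweenness_centrality(G, weight="distance", normalized=True)

    off = W[~np.eye(n, dtype=bool)]
    thresh = off.mean()
    density = float((off > thresh).sum() / (n * (n - 1)))

    return {
        "in_strength_mean": float(in_strength.mean()),
        "out_strength_mean": float(out_strength.mean()),
        "clustering": float(np.mean(list(clust.values()))),
        "char_path_length": cpl,
        "global_efficiency": geff,
        "betweenness_mean": float(np.mean(list(betw.values()))),
        "density": density,
        "mean_information_strength": conn.mean_information_strength(),
        "in_strength": in_strength,
        "out_strength": out_strength,
    }


def major_connections(conn: ConnectivityMatrix, percentile: float = 80.0):
    """Filter the network's major undirected connections.

    The strength of a pair is the sum of the two directed flows between
    its nodes; edges strictly above the given percentile of all pairwise
    strengths are kept and rescaled to (0, 1] by the maximum.  Returns a
    list of ``(a, b, normalized_strength)`` with ``a < b`` (channel
    labels when available); an all-equal network keeps no edges.
    """
    W = conn.values
    n = W.shape[0]
    pairs, strengths = [], []
    for a in range(n):
        for b in range(a + 1, n):
            pairs.append((a, b))
            strengths.append(W[a, b] + W[b, a])
    strengths = np.asarray(strengths)
    cut = np.percentile(strengths, percentile)
    keep = strengths > cut
    if not keep.any():
        return []
    mx = strengths[keep].max()
    out = []
    for (a, b), s, k in zip(pairs, strengths, keep):
        if k:
            if conn.labels:
                out.append((conn.labels[a], conn.labels[b], float(s / mx)))
            else:
                out.append((a, b, float(s / mx)))
    return out
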