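"""Time-domain features: quantized Lempel-Ziv complexity and fractal measures.

The complexity path quantizes a single-channel trace into ``l`` amplitude
levels by equal-width bins of the signal range (thresholds
``T_k = min + k*(max-min)/l``), parses the symbol sequence with the
exhaustive-history LZ76 scheme, and normalizes the phrase count as
``C = c * log_l(n) / n``.

The fractal family comprises nine waveform descriptors: Higuchi, Katz,
Petrosian, Sevcik, box-counting and Castiglioni fractal dimensions, the
Grassberger-Procaccia correlation dimension (embedding dimension 2),
the rescaled-range Hurst exponent and the detrended-fluctuation-analysis
scaling exponent.  Each is computed per channel; recording-level values
are channel means.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "QuantizedSequence",
    "ComplexityResult",
    "quantize",
    "lz76_phrase_count",
    "lz_complexity",
    "fractal_features",
    "FRACTAL_NAMES",
    "higuchi_fd",
    "katz_fd",
    "petrosian_fd",
    "sevcik_fd",
    "box_counting_fd",
    "correlation_dimension",
    "hurst_rs",
    "dfa_exponent",
    "castiglioni_fd",
]


@dataclass
class QuantizedSequence:
    """Amplitude-quantized signal over the alphabet ``{0..l-1}``."""

    symbols: np.ndarray
    l: int
    thresholds: np.ndarray
    constant: bool = False

    def __post_init__(self):
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.size and self.symbols.max() >= self.l:
            raise ValueError("symbol outside alphabet")

    @property
    def n(self) -> int:
        return self.symbols.size


@dataclass
class ComplexityResult:
    c: int
    C: float


def quantize(x: np.ndarray, l: int = 2) -> QuantizedSequence:
    """Quantize a 1-D signal into ``l`` equal-width amplitude levels.

    Interior thresholds are ``T_k = min + k*(max-min)/l`` for
    ``k = 1..l-1``; the symbol is the number of thresholds strictly below
    the sample (so ``x <= T_1`` maps to 0 and ``x > T_{l-1}`` maps to
    ``l-1``).  A constant signal yields all-zero symbols with a flag
    rather than an error.
    """
    if l < 2:
        raise ValueError("need at least 2 quantization levels")
    x = np.asarray(x, dtype=float).ravel()
    lo, hi = x.min(), x.max()
    if hi == lo:
        return QuantizedSequence(
            symbols=np.zeros(x.size, dtype=np.int64),
            l=l,
            thresholds=np.full(l - 1, lo),
            constant=True,
        )
    thr = lo + np.arange(1, l) * (hi - lo) / l
    symbols = np.searchsorted(thr, x, side="left")
    return QuantizedSequence(symbols=symbols, l=l, thresholds=thr)


def lz76_phrase_count(symbols) -> int:
    """Exhaustive-history LZ76 phrase count of a symbol sequence.

    The sequence is parsed left to right into phrases; each phrase is the
    shortest extension of the remainder that cannot be copied from the
    history (the substring check allows the copy source to overlap the
    phrase itself, excluding its final symbol).  The unfinished final
    phrase counts.  Symbols are packed into bytes so the substring search
    runs at C speed; alphabets up to 256 symbols are supported.
    """
    s = np.asarray(symbols).ravel()
    n = s.size
    if n == 0:
        return 0
    if s.size and (s.min() < 0 or s.max() > 255):
        # remap large alphabets densely (phrase structure is label-invariant)
        _, s = np.unique(s, return_inverse=True)
        if s.max() > 255:
            raise ValueError("alphabet too large (> 256 symbols)")
    b = s.astype(np.uint8).tobytes()
    c = 0
    i = 0
    while i < n:
        k = 1
        # longest reproducible extension: b[i:i+k] occurs in b[:i+k-1]
        while i + k <= n and b.find(b[i : i + k], 0, i + k - 1) != -1:
            k += 1
        c += 1
        i += k
    return c


def lz_complexity(seq: QuantizedSequence) -> ComplexityResult:
    """Normalized LZ76 complexity ``C = c * log_l(n) / n``."""
    n = seq.n
    if n < 2:
        raise ValueError("sequence too short for complexity (n >= 2)")
    c = lz76_phrase_count(seq.symbols)
    C = c * (math.log(n) / math.log(seq.l)) / n
    return ComplexityResult(c=c, C=C)


# ---------------------------------------------------------------------------
# Fractal dimensions and scaling exponents

FRACTAL_NAMES = (
    "higuchi",
    "katz",
    "petrosian",
    "sevcik",
    "box_counting",
    "correlation_dim",
    "hurst",
    "dfa",
    "castiglioni",
)


def higuchi_fd(x: np.ndarray, kmax: int = 8) -> float:
    """Higuchi fractal dimension (curve-length scaling over lag k)."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            d = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((idx.size - 1) * k)
            lengths.append(d * norm / k)
        lk[k - 1] = np.mean(lengths)
    if np.any(lk <= 0):
        return 1.0
    k = np.arange(1, kmax + 1)
    slope = np.polyfit(np.log(1.0 / k), np.log(lk), 1)[0]
    return float(slope)


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension on the (index, amplitude) waveform graph."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    t = np.arange(n, dtype=float)
    steps = np.hypot(np.diff(t), np.diff(x))
    L = steps.sum()
    d = np.hypot(t - t[0], x - x[0]).max()
    if L == 0 or d == 0:
        return 1.0
    m = n - 1  # number of steps
    denom = math.log10(m) + math.log10(d / L)
    if denom == 0:
        return 1.0
    return float(math.log10(m) / denom)


def petrosian_fd(x: np.ndarray) -> float:
    """Petrosian fractal dimension from sign changes of the derivative."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    dx = np.diff(x)
    n_delta = int(np.sum(dx[1:] * dx[:-1] < 0))
    if n_delta == 0:
        return 1.0
    return float(
        math.log10(n) / (math.log10(n) + math.log10(n / (n + 0.4 * n_delta)))
    )


def sevcik_fd(x: np.ndarray) -> float:
    """Sevcik fractal dimension: curve length in the normalized unit square."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    rng = x.max() - x.min()
    if rng == 0:
        return 1.0
    y = (x - x.min()) / rng
    t = np.linspace(0.0, 1.0, n)
    L = np.hypot(np.diff(t), np.diff(y)).sum()
    return float(1.0 + math.log(L) / math.log(2.0 * (n - 1)))


def box_counting_fd(x: np.ndarray, n_scales: int = 6) -> float:
    """Box-counting dimension of the waveform graph in the unit square."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    rng = x.max() - x.min()
    if rng == 0:
        return 1.0
    y = (x - x.min()) / rng
    t = np.linspace(0.0, 1.0, n)
    counts, scales = [], []
    for k in range(1, n_scales + 1):
        nb = 2 ** k
        eps = 1.0 / nb
        col = np.minimum((t * nb).astype(int), nb - 1)
        rows = np.minimum((y * nb).astype(int), nb - 1)
        # per column, boxes touched = contiguous row span of the curve
        starts = np.flatnonzero(np.diff(col)) + 1
        bounds = np.concatenate([[0], starts])
        rmin = np.minimum.reduceat(rows, bounds)
        rmax = np.maximum.reduceat(rows, bounds)
        counts.append(int((rmax - rmin + 1).sum()))
        scales.append(eps)
    slope = np.polyfit(np.log(1.0 / np.asarray(scales)), np.log(counts), 1)[0]
    return float(slope)


def correlation_dimension(
    x: np.ndarray, m: int = 2, tau: int = 1, max_points: int = 400
) -> float:
    """Grassberger-Procaccia correlation dimension at embedding dimension m.

    The correlation sum C(r) is evaluated on log-spaced radii between the
    5th and 50th percentile of pairwise distances; the dimension is the
    least-squares slope of log C(r) vs log r.  Long traces are thinned to
    ``max_points`` delay vectors to bound the O(n^2) pair count.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size - (m - 1) * tau
    if n < 10:
        return float("nan")
    emb = np.column_stack([x[i * tau : i * tau + n] for i in range(m)])
    if emb.shape[0] > max_points:
        idx = np.linspace(0, emb.shape[0] - 1, max_points).astype(int)
        emb = emb[idx]
    from scipy.spatial.distance import pdist

    dist = pdist(emb)
    dist = dist[dist > 0]
    if dist.size < 10:
        return float("nan")
    dist.sort()
    radii = np.exp(
        np.linspace(np.log(np.quantile(dist, 0.05)), np.log(np.quantile(dist, 0.5)), 8)
    )
    cr = np.searchsorted(dist, radii) / dist.size
    good = cr > 0
    if good.sum() < 2:
        return float("nan")
    slope = np.polyfit(np.log(radii[good]), np.log(cr[good]), 1)[0]
    return float(slope)


def hurst_rs(x: np.ndarray) -> float:
    """Hurst exponent by classical rescaled-range (R/S) analysis."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    sizes = np.unique(
        np.floor(np.exp(np.linspace(math.log(8), math.log(n // 2), 8))).astype(int)
    )
    rs, ns = [], []
    for w in sizes:
        k = n // w
        if k < 1:
            continue
        seg = x[: k * w].reshape(k, w)
        seg = seg - seg.mean(axis=1, keepdims=True)
        z = np.cumsum(seg, axis=1)
        r = z.max(axis=1) - z.min(axis=1)
        s = seg.std(axis=1, ddof=0)
        ok = s > 0
        if not ok.any():
            continue
        rs.append(np.mean(r[ok] / s[ok]))
        ns.append(w)
    if len(ns) < 2:
        return float("nan")
    return float(np.polyfit(np.log(ns), np.log(rs), 1)[0])


def dfa_exponent(x: np.ndarray, order: int = 1) -> float:
    """Detrended fluctuation analysis scaling exponent (linear detrend)."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    y = np.cumsum(x - x.mean())
    sizes = np.unique(
        np.floor(np.exp(np.linspace(math.log(8), math.log(n // 4), 8))).astype(int)
    )
    fl, ns = [], []
    t_cache = {}
    for w in sizes:
        k = n // w
        if k < 2:
            continue
        seg = y[: k * w].reshape(k, w)
        if w not in t_cache:
            t = np.arange(w, dtype=float)
            v = np.vander(t, order + 1)
            t_cache[w] = v @ np.linalg.pinv(v)   # projection onto polynomial
        resid = seg - seg @ t_cache[w].T
        f = np.sqrt((resid**2).mean())
        if f > 0:
            fl.append(f)
            ns.append(w)
    if len(ns) < 2:
        return float("nan")
    return float(np.polyfit(np.log(ns), np.log(fl), 1)[0])


def castiglioni_fd(x: np.ndarray) -> float:
    """Castiglioni's amplitude-only variant of the Katz dimension.

    Uses ordinate distances only: L is the summed absolute first
    difference, d the maximum excursion from the first sample.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    L = np.abs(np.diff(x)).sum()
    d = np.abs(x - x[0]).max()
    if L == 0 or d == 0:
        return 1.0
    denom = math.log10(n - 1) + math.log10(d / L)
    if denom == 0:
        return 1.0
    return float(math.log10(n - 1) / denom)


def fractal_features(x: np.ndarray) -> dict:
    """All nine fractal descriptors of a single-channel trace.

    A constant signal returns the definitional limit 1.0 for the fractal
    dimensions and NaN (with a warning) for the scaling exponents, which
    are undefined without fluctuations.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 128:
        raise ValueError("need at least 128 samples for fractal features")
    if x.max() == x.min():
        warnings.warn("constant signal: scaling exponents undefined (NaN)")
        return {
            "higuchi": 1.0, "katz": 1.0, "petrosian": 1.0, "sevcik": 1.0,
            "box_counting": 1.0, "castiglioni": 1.0,
            "correlation_dim": float("nan"), "hurst": float("nan"),
            "dfa": float("nan"),
        }
    return {
        "higuchi": higuchi_fd(x),
        "katz": katz_fd(x),
        "petrosian": petrosian_fd(x),
        "sevcik": sevcik_fd(x),
        "box_counting": box_counting_fd(x),
        "correlation_dim": correlation_dimension(x),
        "hurst": hurst_rs(x),
        "dfa": dfa_exponent(x),
        "castiglioni": castiglioni_fd(x),
    }
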