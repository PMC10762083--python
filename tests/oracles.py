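"""Independent brute-force reference implementations used only by tests.

Each oracle is written from the defining construction, deliberately
avoiding the algorithms and library calls the package uses, so that
agreement is a genuine two-route check.
"""

from __future__ import annotations


import numpy as np


def lz76_oracle(seq) -> int:
    """Exhaustive-history LZ76 phrase count, pointer-comparison parser.

    Classic O(n*c) two-pointer scheme (no substring search primitives):
    for the current phrase starting at j, try every copy start i < j and
    track the longest reproducible extension; close the phrase one symbol
    past it.
    """
    s = list(seq)
    n = len(s)
    if n == 0:
        return 0
    c = 1
    j = 1
    while j < n:
        kmax = 0
        for i in range(j):
            k = 0
            while j + k < n and s[i + k] == s[j + k]:
                k += 1
            kmax = max(kmax, k)
            if j + kmax >= n:
                break
        c += 1
        j += kmax + 1
    return c


def run_length_oracle(labels, k, centroids, window_s=0.1):
    """Direct scan computing every microstate sequence feature."""
    labels = list(labels)
    n = len(labels)
    runs = []
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[i - 1]:
            runs.append((labels[start], i - start))
            start = i
    feats = {}
    for s in range(k):
        rs = [l for st, l in runs if st == s]
        feats[f"duration_state{s + 1}"] = (
            float(np.mean(rs)) * window_s if rs else 0.0
        )
        feats[f"coverage_state{s + 1}"] = labels.count(s) / n
        feats[f"occurrence_state{s + 1}"] = len(rs) / (n * window_s)
    trans = [
        (a, b) for a, b in zip(labels[:-1], labels[1:]) if a != b
    ]
    if trans:
        d = [
            float(np.linalg.norm(np.asarray(centroids[a]) - np.asarray(centroids[b])))
            for a, b in trans
        ]
        feats["mean_transition_distance"] = float(np.mean(d))
        from collections import Counter

        cnt = Counter(trans)
        tot = sum(cnt.values())
        feats["transition_entropy"] = float(
            -sum((v / tot) * np.log(v / tot) for v in cnt.values())
        )
    else:
        feats["mean_transition_distance"] = 0.0
        feats["transition_entropy"] = 0.0
    return feats


def shortest_paths_oracle(W):
    """All-pairs shortest distances and shortest-path counts.

    Edge j -> i exists when W[i, j] > 0 with length 1/W[i, j]; distances
    and counts come from explicit enumeration of simple paths (feasible
    for n <= 8).
    """
    n = W.shape[0]
    nodes = list(range(n))
    dist = np.full((n, n), np.inf)
    count = np.zeros((n, n))
    for s in nodes:
        dist[s, s] = 0.0
    adj = {
        j: [(i, 1.0 / W[i, j]) for i in nodes if i != j and W[i, j] > 0]
        for j in nodes
    }

    def dfs(start):
        # enumerate every simple path from start, recording endpoints
        all_paths = []
        frontier = [(start, 0.0, (start,))]
        while frontier:
            node, d, path = frontier.pop()
            for nxt, w in adj[node]:
                if nxt in path:
                    continue
                nd = d + w
                all_paths.append((nxt, nd))
                frontier.append((nxt, nd, path + (nxt,)))
        return all_paths

    for s in nodes:
        arr = dfs(s)
        for t, d in arr:
            if d < dist[s, t] - 1e-12:
                dist[s, t] = d
                count[s, t] = 1
            elif abs(d - dist[s, t]) <= 1e-12:
                count[s, t] += 1
    return dist, count


def betweenness_oracle(W):
    """Betweenness centrality by direct enumeration (normalized)."""
    n = W.shape[0]
    dist, count = shortest_paths_oracle(W)
    # per-node dependency: count shortest s-t paths through v
    adj = {
        j: [(i, 1.0 / W[i, j]) for i in range(n) if i != j and W[i, j] > 0]
        for j in range(n)
    }

    def paths_through(s, t, v):
        # enumerate all shortest s->t simple paths, count those through v
        target = dist[s, t]
        if not np.isfinite(target):
            return 0
        hits = 0
        frontier = [(s, 0.0, (s,))]
        while frontier:
            node, d, path = frontier.pop()
            if node == t:
                if abs(d - target) <= 1e-12 and v in path[1:-1]:
                    hits += 1
                continue
            if d > target + 1e-12:
                continue
            for nxt, w in adj[node]:
                if nxt in path:
                    continue
                frontier.append((nxt, d + w, path + (nxt,)))
        return hits

    bc = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(n):
                if len({s, t, v}) < 3:
                    continue
                if count[s, t] > 0:
                    bc[v] += paths_through(s, t, v) / count[s, t]
    norm = (n - 1) * (n - 2)
    return bc / norm


def reject_windows_oracle(signal, thresh, win):
    """Number of clean length-`win` windows by direct scan (incl. tail)."""
    n = signal.shape[1]
    clean = 0
    pos = 0
    while pos < n:
        seg = signal[:, pos : pos + win]
        if np.max(np.abs(seg)) <= thresh:
            clean += 1
        pos += win
    return clean


def fgn(rng, n, hurst):
    """Fractional Gaussian noise by circulant spectral synthesis."""
    # autocovariance of fGn
    k = np.arange(n)
    g = 0.5 * (
        np.abs(k - 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k + 1) ** (2 * hurst)
    )
    row = np.concatenate([g, g[-2:0:-1]])
    lam = np.fft.fft(row).real
    lam = np.clip(lam, 0, None)
    m = row.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.fft(np.sqrt(lam / m) * z)
    return x[:n].real
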