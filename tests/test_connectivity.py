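"""MVAR/DTF estimation, PLI, graph metrics, major-connection filtering."""

import numpy as np
import pytest

from neurocog.features_connectivity import (
    ConnectivityMatrix,
    dtf,
    dtf_spectrum,
    fit_mvar,
    major_connections,
    network_properties,
    pli,
)
from neurocog.io import Recording
from neurocog.preprocess import epoch
from oracles import betweenness_oracle, shortest_paths_oracle


def _epochs(signal, fs, n_epochs, policy="per_epoch"):
    rec = Recording(
        subject_id="s", session=1, device="other",
        channel_labels=[f"ch{i}" for i in range(signal.shape[0])],
        fs=fs, signal=signal,
    )
    return epoch(rec, n_epochs, 2.0, policy)


def simulate_mvar(coeffs, n, rng, burn=200):
    """Drive a stable MVAR with unit Gaussian innovations."""
    p, ch, _ = coeffs.shape
    x = np.zeros((ch, n + burn))
    e = rng.standard_normal((ch, n + burn))
    for t in range(p, n + burn):
        acc = e[:, t].copy()
        for k in range(p):
            acc += coeffs[k] @ x[:, t - k - 1]
        x[:, t] = acc
    return x[:, burn:]


COEFS3 = np.zeros((3, 4, 4))
COEFS3[0] = 0.4 * np.eye(4)
COEFS3[1] = -0.3 * np.eye(4)
COEFS3[2, 1, 0] = 0.35   # channel 0 drives channel 1 at lag 3
COEFS3[2, 3, 2] = 0.3


class TestMVARFit:
    def test_coefficient_rmse_shrinks_with_samples(self):
        rng = np.random.default_rng(0)
        rmses = []
        for n_ep in (5, 20, 80):
            x = simulate_mvar(COEFS3, n_ep * 500, rng)
            eps = _epochs(x, 250.0, n_ep)
            model = fit_mvar(eps, order=3)
            rmses.append(float(np.sqrt(((model.coeffs - COEFS3) ** 2).mean())))
        assert rmses[2] < rmses[1] < rmses[0]
        assert rmses[2] < 0.02

    def test_independent_channels_off_diagonal_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 20 * 500))
        model = fit_mvar(_epochs(x, 250.0, 20), order=2)
        off = ~np.eye(4, dtype=bool)
        assert np.abs(model.coeffs[:, off]).max() < 0.05

    def test_auto_order_recovers_three(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = simulate_mvar(COEFS3, 12_000, rng)
            model = fit_mvar(_epochs(x, 250.0, 24), order="auto")
            hits += model.order == 3
        assert hits >= 16   # >= 80% of seeds

    def test_identifiability_guard(self):
        rng = np.random.default_rng(2)
        eps = _epochs(rng.standard_normal((40, 500)), 250.0, 1)
        with pytest.raises(ValueError):
            fit_mvar(eps, order=20)


class TestDTF:
    def test_rows_sum_to_one_at_every_frequency(self):
        rng = np.random.default_rng(3)
        x = simulate_mvar(COEFS3, 10_000, rng)
        model = fit_mvar(_epochs(x, 250.0, 20), order=3)
        spec = dtf_spectrum(model, np.arange(0.5, 40.5, 0.5))
        assert np.abs(spec.sum(axis=2) - 1.0).max() < 1e-10
        band = dtf(model, (0.5, 40.0))
        assert np.abs(band.values.sum(axis=1) - 1.0).max() < 1e-10

    def test_planted_direction_recovered(self):
        wins = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            c = np.zeros((2, 2, 2))
            c[0] = 0.5 * np.eye(2)
            c[1, 1, 0] = 0.4          # 0 -> 1
            x = simulate_mvar(c, 8000, rng)
            model = fit_mvar(_epochs(x, 250.0, 16), order=2)
            m = dtf(model, (0.5, 40.0)).values
            wins += m[1, 0] > m[0, 1]  # inflow into 1 from 0 dominates
        assert wins >= 38              # >= 95% of 40 seeds

    def test_coupled_exceeds_independent_offdiagonal(self):
        rng = np.random.default_rng(99)
        c = np.zeros((1, 3, 3))
        c[0] = 0.4 * np.eye(3)
        x_ind = simulate_mvar(c, 8000, rng)
        c2 = c.copy()
        c2[0, 1, 0] = c2[0, 2, 1] = 0.4
        x_cpl = simulate_mvar(c2, 8000, rng)
        m_ind = dtf(fit_mvar(_epochs(x_ind, 250.0, 16), 1), (0.5, 40.0))
        m_cpl = dtf(fit_mvar(_epochs(x_cpl, 250.0, 16), 1), (0.5, 40.0))
        assert m_cpl.mean_information_strength() > 2 * m_ind.mean_information_strength()


class TestPLI:
    def test_quarter_cycle_lag_gives_one(self):
        fs = 250.0
        t = np.arange(int(fs * 20)) / fs
        sig = np.vstack([np.sin(2 * np.pi * 10 * t), np.cos(2 * np.pi * 10 * t)])
        m = pli(_epochs(sig, fs, 10), (8.0, 12.0))
        assert m.values[0, 1] == pytest.approx(1.0, abs=1e-6)
        assert m.values[1, 0] == m.values[0, 1]

    def test_self_coupling_is_zero(self):
        fs = 250.0
        t = np.arange(int(fs * 10)) / fs
        x = np.sin(2 * np.pi * 10 * t)
        m = pli(_epochs(np.vstack([x, x]), fs, 5), (8.0, 12.0))
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diag(m.values) == 0)

    def test_independent_noise_small_and_scale_invariant(self):
        rng = np.random.default_rng(5)
        fs = 250.0
        sig = rng.standard_normal((2, int(fs * 40)))
        m1 = pli(_epochs(sig, fs, 20), (8.0, 12.0))
        m2 = pli(_epochs(np.diag([5.0, 0.01]) @ sig, fs, 20), (8.0, 12.0))
        # the narrowband null has a finite-sample bias ~ sqrt(2/(pi*N_eff))
        # (N_eff ~ epoch length x bandwidth ~ 8 per 2 s epoch, so ~0.28);
        # independent noise must stay well below phase-locked signals
        assert m1.values[0, 1] < 0.45
        assert m2.values[0, 1] == pytest.approx(m1.values[0, 1], abs=1e-12)


class TestNetworkProperties:
    def test_complete_unit_graph_closed_form(self):
        n = 5
        W = np.ones((n, n)) - np.eye(n)
        props = network_properties(ConnectivityMatrix(values=W, kind="strength"))
        assert props["char_path_length"] == pytest.approx(1.0)
        assert props["global_efficiency"] == pytest.approx(1.0)
        assert props["in_strength_mean"] == pytest.approx(n - 1)

    def test_disconnected_components_finite_efficiency(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = W[2, 3] = W[3, 2] = 1.0
        props = network_properties(ConnectivityMatrix(values=W, kind="strength"))
        assert np.isfinite(props["global_efficiency"])
        assert props["char_path_length"] == pytest.approx(1.0)  # reachable pairs only
        assert props["global_efficiency"] == pytest.approx(4 / 12)

    def test_random_digraph_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        n = 8
        W = rng.uniform(0.1, 1.0, (n, n)) * (rng.random((n, n)) < 0.4)
        np.fill_diagonal(W, 0.0)
        props = network_properties(ConnectivityMatrix(values=W, kind="strength"))
        dist, _count = shortest_paths_oracle(W)
        off = ~np.eye(n, dtype=bool)
        finite = dist[off][np.isfinite(dist[off])]
        inv = np.where(np.isfinite(dist[off]), 1.0 / np.where(dist[off] == 0, 1, dist[off]), 0.0)
        assert props["char_path_length"] == pytest.approx(float(finite.mean()))
        assert props["global_efficiency"] == pytest.approx(float(inv.mean()))
        assert props["in_strength_mean"] == pytest.approx(W.sum(axis=1).mean())
        assert props["out_strength_mean"] == pytest.approx(W.sum(axis=0).mean())
        bo = betweenness_oracle(W)
        assert props["betweenness_mean"] == pytest.approx(float(bo.mean()), abs=1e-9)
        thresh = W[off].mean()
        assert props["density"] == pytest.approx((W[off] > thresh).mean())


class TestMajorConnections:
    def test_keeps_strictly_above_80th_percentile(self):
        n = 5   # 10 unordered pairs
        W = np.zeros((n, n))
        s = 1.0
        for a in range(n):
            for b in range(a + 1, n):
                W[a, b] = s  # pair strength = s (one direction only)
                s += 1.0
        kept = major_connections(ConnectivityMatrix(values=W, kind="strength"), 80.0)
        assert len(kept) == 2
        assert max(k[2] for k in kept) == 1.0
        assert all(0 < k[2] <= 1 for k in kept)

    def test_all_equal_keeps_nothing(self):
        W = np.ones((4, 4)) - np.eye(4)
        assert major_connections(ConnectivityMatrix(values=W, kind="strength")) == []
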