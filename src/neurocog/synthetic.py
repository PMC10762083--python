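"""Synthetic resting-state EEG cohorts with planted class structure.

The generator emulates the group-level effects the analysis pipeline is
built to detect, calibrated to the published group statistics:

* **Spectral slowing** — per-class band-power targets (uV^2): delta and
  theta rise while alpha, beta and gamma fall from healthy controls
  through MCI to dementia (alpha 6.94 / 5.66 / 4.37, gamma with MCI 5.13
  and dementia 3.18, delta with MCI 12.42 and dementia 14.65; values the
  statistics do not pin down are filled with smooth interpolations).
* **Directed coupling** — a fixed sparse directed graph of lagged
  cross-channel influences whose gain decreases with cognitive decline,
  so the mean DTF information strength orders HC > MCI > dementia.
* **Microstate dynamics** — a hidden semi-Markov process over 20 global
  per-channel variance profiles; mean dwell time shrinks with decline
  (HC 0.5 s, MCI 0.3 s, dementia 0.15 s), shortening state durations.
* **Scale scores** — MoCA-B and MMSE drawn from truncated normals around
  the class means (MoCA-B 24.39 / 18.01 / 10.68, MMSE 27.47 / 25.18 /
  17.86), correlated with a per-subject severity factor that also
  modulates the EEG effects, and shared across a subject's two sessions.

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` spawning, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .io import CANONICAL_64, Cohort, Recording

__all__ = ["GeneratorConfig", "generate_recording", "generate_cohort"]

#: per-class band power targets, uV^2 (published where available)
BAND_POWER = {
    "HC":       {"delta": 11.0, "theta": 7.0, "alpha": 6.94, "beta": 6.5, "gamma": 5.9},
    "MCI":      {"delta": 12.42, "theta": 8.0, "alpha": 5.66, "beta": 5.8, "gamma": 5.13},
    "dementia": {"delta": 14.65, "theta": 9.5, "alpha": 4.37, "beta": 4.8, "gamma": 3.18},
}

BAND_EDGES = {
    "delta": (0.5, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 20.0),
    "gamma": (21.0, 40.0),
}

COUPLING_GAIN = {"HC": 0.5, "MCI": 0.35, "dementia": 0.15}
DWELL_MEAN_S = {"HC": 0.5, "MCI": 0.3, "dementia": 0.15}
MOCA = {"HC": 24.39, "MCI": 18.01, "dementia": 10.68}
MMSE = {"HC": 27.47, "MCI": 25.18, "dementia": 17.86}


@dataclass
class GeneratorConfig:
    """Study-design and effect-size parameters of the synthetic cohort.

    ``effect_scale`` multiplies the separation of all planted class
    effects around their across-class mean: 1 reproduces the calibrated
    group differences, 0 removes every class effect (the leakage-null
    condition) while keeping realistic within-class variability.
    """

    n_per_class: int = 30
    n_sessions: int = 2
    n_channels: int = 64
    fs: float = 1000.0
    duration_s: float = 160.0
    seed: int = 0
    effect_scale: float = 1.0
    band_power: dict = field(default_factory=lambda: {k: dict(v) for k, v in BAND_POWER.items()})
    coupling_gain: dict = field(default_factory=lambda: dict(COUPLING_GAIN))
    dwell_mean_s: dict = field(default_factory=lambda: dict(DWELL_MEAN_S))
    moca_mean: dict = field(default_factory=lambda: dict(MOCA))
    mmse_mean: dict = field(default_factory=lambda: dict(MMSE))
    moca_sd: float = 4.0
    mmse_sd: float = 3.0
    subject_sd: float = 0.08      # lognormal sigma of subject band-power factor
    session_sd: float = 0.04      # lognormal sigma of session factor
    n_states: int = 20
    state_gain_sd: float = 0.35   # spread of per-channel state variance profiles
    severity_coupling: float = 0.5  # how strongly severity shifts EEG effects
    channels: tuple | None = None

    def __post_init__(self):
        if self.channels is None:
            self.channels = CANONICAL_64[: self.n_channels]
        else:
            self.channels = tuple(self.channels)
            self.n_channels = len(self.channels)
        for d in (self.moca_sd, self.mmse_sd, self.subject_sd, self.session_sd):
            if d <= 0:
                raise ValueError("all variances must be positive")

    def effective(self, table: dict, label: str) -> float | dict:
        """Class value with separation scaled by ``effect_scale``."""
        vals = table
        if isinstance(next(iter(vals.values())), dict):
            mean = {b: np.mean([vals[c][b] for c in vals]) for b in next(iter(vals.values()))}
            return {b: mean[b] + self.effect_scale * (vals[label][b] - mean[b])
                    for b in mean}
        mean = float(np.mean(list(vals.values())))
        return mean + self.effect_scale * (vals[label] - mean)


def _cohort_structures(cfg: GeneratorConfig):
    """Global structures shared by every recording of a cohort."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 917]))
    ch = cfg.n_channels
    # 20 per-channel variance profiles (the planted "microstates")
    gains = 1.0 + cfg.state_gain_sd * rng.standard_normal((cfg.n_states, ch))
    gains = np.clip(gains, 0.3, 2.5)
    # sparse directed coupling graph: each channel receives from <=2 sources
    n_src = min(2, ch - 1)
    sources = np.empty((ch, n_src), dtype=int)
    lags = np.empty((ch, n_src), dtype=int)
    for i in range(ch):
        cand = [j for j in range(ch) if j != i]
        sources[i] = rng.choice(cand, size=n_src, replace=False)
        lags[i] = rng.integers(2, 6, size=n_src)
    weights = rng.uniform(0.5, 1.0, size=(ch, n_src))
    return gains, sources, lags, weights


def _band_noise(rng, ch: int, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal((ch, n)), axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def _dwell_windows(rng, mean_s: float, fs: float) -> int:
    # dwell quantized to 100 ms so planted states align with the windows
    w = max(1, int(np.round(rng.exponential(mean_s) / 0.1)))
    return w * int(round(0.1 * fs))


def generate_recording(
    label: str,
    cfg: GeneratorConfig,
    seed,
    *,
    subject_id: str = "S00",
    session: int = 1,
    device: str = "other",
    severity: float = 0.0,
    subject_factor: dict | float = 1.0,
    moca_b: int | None = None,
    mmse: int | None = None,
) -> Recording:
    """One synthetic recording of the given class (deterministic in seed).

    ``subject_factor`` is a per-band multiplicative random effect shared
    by a subject's sessions (a scalar applies to every band).
    """
    rng = np.random.default_rng(seed)
    gains, sources, lags, weights = _cohort_structures(cfg)
    ch, fs = cfg.n_channels, cfg.fs
    n = int(round(cfg.duration_s * fs))

    powers = cfg.effective(cfg.band_power, label)
    sev_shift = 1.0 - cfg.severity_coupling * 0.1 * severity
    session_factor = {
        band: float(np.exp(cfg.session_sd * rng.standard_normal()))
        for band in BAND_EDGES
    }

    sig = np.zeros((ch, n))
    for band, (lo, hi) in BAND_EDGES.items():
        subj_f = subject_factor[band] if isinstance(subject_factor, dict) \
            else subject_factor
        target = powers[band] * subj_f * session_factor[band]
        if band in ("alpha", "beta", "gamma"):
            target *= sev_shift            # impaired subjects lose fast power
        else:
            target *= 2.0 - sev_shift
        sig += np.sqrt(max(target, 1e-6)) * _band_noise(rng, ch, n, fs, lo, hi)

    # directed lagged coupling
    g = cfg.effective(cfg.coupling_gain, label) * sev_shift
    if g > 0:
        base = sig.copy()
        for i in range(ch):
            for s, lag, wt in zip(sources[i], lags[i], weights[i]):
                sig[i, lag:] += g * wt * base[s, :-lag]

    # hidden semi-Markov variance modulation (the planted microstates)
    dwell_mean = cfg.effective(cfg.dwell_mean_s, label)
    pos = 0
    state = int(rng.integers(cfg.n_states))
    while pos < n:
        span = min(_dwell_windows(rng, dwell_mean, fs), n - pos)
        sig[:, pos : pos + span] *= gains[state][:, None]
        nxt = int(rng.integers(cfg.n_states - 1))
        state = nxt if nxt < state else nxt + 1   # no self-transition
        pos += span

    if moca_b is None:
        moca_b = _draw_scale(rng, cfg.effective(cfg.moca_mean, label),
                             cfg.moca_sd, severity)
    if mmse is None:
        mmse = _draw_scale(rng, cfg.effective(cfg.mmse_mean, label),
                           cfg.mmse_sd, severity)
    return Recording(
        subject_id=subject_id, session=session, device=device,
        channel_labels=cfg.channels, fs=fs, signal=sig, label=label,
        moca_b=moca_b, mmse=mmse,
    )


def _draw_scale(rng, mean: float, sd: float, severity: float) -> int:
    # severity > 0 means more impaired: push scores down
    v = mean - 0.6 * sd * severity + sd * 0.8 * rng.standard_normal()
    return int(np.clip(np.round(v), 0, 30))


def generate_cohort(cfg: GeneratorConfig) -> Cohort:
    """Balanced three-class cohort, ``n_sessions`` recordings per subject.

    Subject-level severity and band-power factors are shared across a
    subject's sessions, so within-subject feature correlation exceeds
    between-subject correlation.
    """
    ss = np.random.SeedSequence([cfg.seed, 10_007])
    devices = ("NeuroScan", "Neuracle", "BP")
    recs = []
    labels = ("HC", "MCI", "dementia")
    child_seeds = ss.spawn(3 * cfg.n_per_class * (cfg.n_sessions + 1))
    k = 0
    for li, label in enumerate(labels):
        for s in range(cfg.n_per_class):
            sid = f"{label}{s:03d}"
            subj_rng = np.random.default_rng(child_seeds[k]); k += 1
            severity = float(np.clip(subj_rng.standard_normal(), -2, 2))
            subject_factor = {
                band: float(np.exp(cfg.subject_sd * subj_rng.standard_normal()))
                for band in BAND_EDGES
            }
            device = devices[(li * cfg.n_per_class + s) % len(devices)]
            moca = _draw_scale(subj_rng, cfg.effective(cfg.moca_mean, label),
                               cfg.moca_sd, severity)
            mmse = _draw_scale(subj_rng, cfg.effective(cfg.mmse_mean, label),
                               cfg.mmse_sd, severity)
            for sess in range(1, cfg.n_sessions + 1):
                recs.append(generate_recording(
                    label, cfg, child_seeds[k],
                    subject_id=sid, session=sess, device=device,
                    severity=severity, subject_factor=subject_factor,
                    moca_b=moca, mmse=mmse,
                ))
                k += 1
    return Cohort(recordings=recs)
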