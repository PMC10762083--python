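"""Per-recording feature extraction into a tidy feature table.

Seven feature families feed the ensemble: ``fractal``, ``complexity``,
``microstate``, ``spectral``, ``bispectral``, ``network`` and ``phase``.
Feature names are namespaced ``family/name``; the table is a pandas
DataFrame with one row per recording and metadata columns prefixed
``meta_``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features_connectivity as fc
from . import features_microstate as fm
from . import features_spectral as fsp
from . import features_time as ft
from .io import Cohort, Recording
from .preprocess import PreprocessConfig, epoch, preprocess_chain

__all__ = ["FeatureConfig", "extract_features", "build_feature_table", "FAMILIES"]

FAMILIES = (
    "fractal", "complexity", "microstate", "spectral", "bispectral",
    "network", "phase",
)


@dataclass
class FeatureConfig:
    """Epoching and estimator parameters for every feature family.

    The time and frequency families use 50 x 2 s epochs and the spatial
    family 20 x 2 s epochs by default; the microstate representation
    spans 150 s in 100 ms windows.  ``time_policy`` selects between
    computing time-domain features per epoch then averaging
    (``per_epoch``, default) and computing them on the pointwise-mean
    waveform (``average_waveform``); the frequency family defaults to
    per-epoch periodogram averaging.
    """

    time_epochs: int = 50
    freq_epochs: int = 50
    spatial_epochs: int = 20
    epoch_len_s: float = 2.0
    time_policy: str = "per_epoch"
    freq_policy: str = "per_epoch"
    microstate_total_s: float = 150.0
    microstate_window_s: float = 0.1
    microstate_k: int = 20
    lz_levels: int = 2
    mvar_order: object = 6
    dtf_band: tuple = (0.5, 40.0)
    pli_bands: dict = field(default_factory=lambda: dict(fsp.BANDS))
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)


def _time_features(rec: Recording, cfg: FeatureConfig) -> dict:
    eps = epoch(rec, cfg.time_epochs, cfg.epoch_len_s, cfg.time_policy)
    out: dict = {}
    if cfg.time_policy == "average_waveform":
        data = eps.mean_epoch()[None]          # 1 x ch x n
    else:
        data = eps.epochs
    frac = np.zeros(len(ft.FRACTAL_NAMES))
    for ep_ in data:
        for chan in ep_:
            f = ft.fractal_features(chan)
            frac += np.array([f[k] for k in ft.FRACTAL_NAMES])
    frac /= data.shape[0] * data.shape[1]
    for name, v in zip(ft.FRACTAL_NAMES, frac):
        out[f"fractal/{name}"] = float(v)

    # complexity under the same epoching policy, per channel then mean
    cs, Cs = [], []
    for ep_ in data:
        for chan in ep_:
            res = ft.lz_complexity(ft.quantize(chan, cfg.lz_levels))
            cs.append(res.c)
            Cs.append(res.C)
    out["complexity/lz_c"] = float(np.mean(cs))
    out["complexity/lz_C"] = float(np.mean(Cs))
    return out


def _spectral_features(rec: Recording, cfg: FeatureConfig) -> dict:
    eps = epoch(rec, cfg.freq_epochs, cfg.epoch_len_s, cfg.freq_policy)
    spec = fsp.spectrum(eps)
    out = {f"spectral/{k}": v for k, v in fsp.spectral_features(spec).items()}
    out.update(
        {f"bispectral/{k}": v for k, v in fsp.bispectral_features(eps).items()}
    )
    return out


def _spatial_features(rec: Recording, cfg: FeatureConfig) -> dict:
    eps = epoch(rec, cfg.spatial_epochs, cfg.epoch_len_s, "average_waveform")
    model = fc.fit_mvar(eps, cfg.mvar_order)
    conn = fc.dtf(model, cfg.dtf_band)
    props = fc.network_properties(conn)
    out = {
        f"network/{k}": float(v)
        for k, v in props.items()
        if np.isscalar(v) or isinstance(v, float)
    }
    plis = []
    for name, band in cfg.pli_bands.items():
        p = fc.pli(eps, band)
        v = p.mean_information_strength()
        out[f"phase/pli_{name}"] = v
        plis.append(v)
    out["phase/pli_mean"] = float(np.mean(plis))
    return out


def extract_features(
    rec: Recording,
    cfg: FeatureConfig,
    microstate_model: fm.MicrostateModel | None = None,
) -> dict:
    """All feature families for one preprocessed recording.

    Microstate features require a fitted global :class:`MicrostateModel`
    (clustered on windows pooled over the whole cohort); when none is
    given the family is skipped.
    """
    out: dict = {}
    out.update(_time_features(rec, cfg))
    out.update(_spectral_features(rec, cfg))
    out.update(_spatial_features(rec, cfg))
    if microstate_model is not None:
        seq = fm.assign_sequence(
            rec, microstate_model, cfg.microstate_window_s, cfg.microstate_total_s
        )
        sf = fm.sequence_features(seq, microstate_model, cfg.microstate_window_s)
        sf.pop("degenerate", None)
        out.update({f"microstate/{k}": v for k, v in sf.items()})
    return out


def build_feature_table(
    cohort: Cohort,
    cfg: FeatureConfig | None = None,
    *,
    preprocessed: bool = False,
    seed: int = 0,
    microstate_model: fm.MicrostateModel | None = None,
) -> pd.DataFrame:
    """Preprocess a cohort, fit the global microstate model, and extract
    every feature family for every recording.

    A pre-fitted ``microstate_model`` (e.g. from the training cohort, for
    scoring external data in the training centroid space) bypasses the
    pooled clustering step.  Returns a DataFrame with ``meta_*`` columns
    (subject, session, device, label, scale scores) followed by the
    namespaced feature columns.
    """
    cfg = cfg or FeatureConfig()
    recs = list(cohort)
    if not preprocessed:
        recs = [preprocess_chain(r, cfg.preprocess) for r in recs]

    if microstate_model is not None:
        ms_model = microstate_model
    else:
        pool = np.concatenate(
            [fm.windows(r, cfg.microstate_window_s, cfg.microstate_total_s)
             for r in recs]
        )
        ms_model = fm.fit_microstate_model(pool, cfg.microstate_k, seed=seed)

    rows = []
    for r in recs:
        row = {
            "meta_subject_id": r.subject_id,
            "meta_session": r.session,
            "meta_device": r.device,
            "meta_label": r.label,
            "meta_moca_b": r.moca_b,
            "meta_mmse": r.mmse,
        }
        row.update(extract_features(r, cfg, ms_model))
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["microstate_model"] = ms_model
    return df


def feature_family(name: str) -> str:
    """Family tag of a namespaced feature column."""
    return name.split("/", 1)[0]


def family_columns(df: pd.DataFrame, family: str) -> list:
    return [c for c in df.columns if c.startswith(f"{family}/")]
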