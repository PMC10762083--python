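import numpy as np
import pandas as pd
import pytest

from neurocog import FeatureConfig, GeneratorConfig, generate_cohort
from neurocog.features import FAMILIES, build_feature_table

#: problem sizes used throughout the suite: recordings are scaled down
#: (12 channels, 250 Hz, 44 s) while keeping the planted effect sizes at
#: their calibrated defaults.
SCALED_GEN = dict(n_channels=12, fs=250.0, duration_s=44.0)
SCALED_FEAT = dict(time_epochs=8, freq_epochs=10, spatial_epochs=10,
                   microstate_total_s=40.0)


def scaled_generator(n_per_class, seed, **kw):
    return GeneratorConfig(n_per_class=n_per_class, seed=seed, **SCALED_GEN, **kw)


def scaled_features(**kw):
    return FeatureConfig(**{**SCALED_FEAT, **kw})


def make_fake_table(n_subj=30, n_sessions=2, sep=2.0, seed=0,
                    families=FAMILIES, n_feat=3):
    """Feature-table stand-in with planted class separation per family.

    Synthetic (no EEG behind it): each family gets ``n_feat`` Gaussian
    features whose class means are ``sep`` apart; subject effects are
    shared across sessions.
    """
    rng = np.random.default_rng(seed)
    rows = []
    moca_means = {"HC": 24.39, "MCI": 18.01, "dementia": 10.68}
    mmse_means = {"HC": 27.47, "MCI": 25.18, "dementia": 17.86}
    for ci, label in enumerate(("HC", "MCI", "dementia")):
        for s in range(n_subj):
            subj_shift = 0.3 * rng.standard_normal(len(families) * n_feat)
            moca = int(np.clip(round(moca_means[label] + 3 * rng.standard_normal()), 0, 30))
            mmse = int(np.clip(round(mmse_means[label] + 2.5 * rng.standard_normal()), 0, 30))
            for sess in range(1, n_sessions + 1):
                row = {
                    "meta_subject_id": f"{label}{s:03d}",
                    "meta_session": sess,
                    "meta_device": ("NeuroScan", "Neuracle", "BP")[s % 3],
                    "meta_label": label,
                    "meta_moca_b": moca,
                    "meta_mmse": mmse,
                }
                vals = (ci * sep + subj_shift
                        + 0.5 * rng.standard_normal(len(families) * n_feat))
                for fi, fam in enumerate(families):
                    for k in range(n_feat):
                        row[f"{fam}/f{k}"] = vals[fi * n_feat + k]
                rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_table():
    """Feature table of a small real synthetic cohort (shared)."""
    cohort = generate_cohort(scaled_generator(6, seed=7))
    return build_feature_table(cohort, scaled_features(), seed=7)
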