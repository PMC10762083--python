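"""ReliefF, weak learners, AdaBoost fusion, scale regression, scoring."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_fake_table
from neurocog.ensemble import (
    CLASS_BASE,
    adaboost_fuse,
    alpha_from_error,
    cognitive_score,
    relieff,
    train_scale_regressors,
    train_weak,
    true_cognitive_score,
)
from neurocog.pipeline import train_model


class TestReliefF:
    def test_informative_feature_beats_noise_every_seed(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1, 2], 30)
            X = np.column_stack([
                y + 0.1 * rng.standard_normal(90),   # informative
                rng.standard_normal(90),             # noise
            ])
            W, _ = relieff(X, y, k_neighbors=5)
            assert W[0] > W[1]

    def test_duplicated_column_identical_weights(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 25)
        x = y + 0.3 * rng.standard_normal(50)
        X = np.column_stack([x, x, rng.standard_normal(50)])
        W, _ = relieff(X, y, k_neighbors=5)
        assert W[0] == pytest.approx(W[1])

    def test_permuted_labels_weights_near_zero(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1, 2], 20)
        X = np.column_stack([y + 0.1 * rng.standard_normal(60)])
        ws = []
        for _ in range(20):
            yp = rng.permutation(y)
            W, _ = relieff(X, yp, k_neighbors=5)
            ws.append(W[0])
        informative = relieff(X, y, k_neighbors=5)[0][0]
        assert abs(np.mean(ws)) < 0.2 * informative

    def test_k_too_large_raises(self):
        y = np.repeat([0, 1], 5)
        with pytest.raises(ValueError):
            relieff(np.random.default_rng(0).standard_normal((10, 2)), y, 5)


class TestAlphaFormula:
    def test_printed_formula_at_quarter_error(self):
        assert alpha_from_error(0.25) == pytest.approx(0.5 * math.log(7))

    def test_half_error_still_positive(self):
        # as printed: e = 0.5 gives 0.5*ln(3), not zero
        assert alpha_from_error(0.5) == pytest.approx(0.5 * math.log(3))
        assert alpha_from_error(0.5, classic=True) == pytest.approx(0.0)

    def test_strictly_decreasing_in_error(self):
        es = np.linspace(0.01, 0.99, 50)
        alphas = [alpha_from_error(e) for e in es]
        assert all(a > b for a, b in zip(alphas, alphas[1:]))

    @pytest.mark.parametrize("e", [0.0, 1.0, -0.1])
    def test_out_of_range_rejected(self, e):
        with pytest.raises(ValueError):
            alpha_from_error(e)


class TestAdaBoost:
    def _fused(self, seed=0, sep=1.2):
        df = make_fake_table(n_subj=15, sep=sep, seed=seed)
        learners = [train_weak(df, fam, n_keep=3, k_neighbors=5)
                    for fam in ("fractal", "complexity", "microstate")]
        return adaboost_fuse(learners, df), df

    def test_sample_weight_conserved_every_iteration(self):
        fused, _ = self._fused()
        assert len(fused.history) == 3
        for step in fused.history:
            assert step["weight_sum"] == pytest.approx(1.0, abs=1e-12)

    def test_selection_order_by_ascending_error(self):
        fused, _ = self._fused()
        # each round picks the smallest current weighted error
        assert all(0 < s["error"] < 1 for s in fused.history)

    def test_separable_data_clipped_error_finite_alpha(self):
        df = make_fake_table(n_subj=10, sep=8.0, seed=3)
        learners = [train_weak(df, fam, n_keep=3, k_neighbors=4)
                    for fam in ("fractal", "complexity")]
        fused = adaboost_fuse(learners, df)
        n = len(df)
        assert fused.learners[0].error == pytest.approx(1.0 / (2 * n))
        assert np.isfinite(fused.learners[0].alpha)

    def test_chance_level_error_on_uninformative_features(self):
        errs = []
        for seed in range(10):
            train = make_fake_table(n_subj=40, n_sessions=1, sep=0.0, seed=seed,
                                    families=("fractal",))
            test = make_fake_table(n_subj=40, n_sessions=1, sep=0.0, seed=seed + 500,
                                   families=("fractal",))
            wl = train_weak(train, "fractal", n_keep=3, k_neighbors=5)
            errs.append((wl.predict(test) != test["meta_label"]).mean())
        assert np.mean(errs) == pytest.approx(2.0 / 3.0, abs=0.08)

    def test_complementary_families_fusion_beats_individuals(self):
        # each family discriminates one class PAIR and carries no signal
        # about the third class, so any single learner caps near 2/3 while
        # two of three learners always vote for the true class
        pairs = {"fractal": ("HC", "MCI"), "complexity": ("HC", "dementia"),
                 "microstate": ("MCI", "dementia")}
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            labels = np.repeat(["HC", "MCI", "dementia"], 60)
            rows = []
            fams = tuple(pairs)
            for i, lab in enumerate(labels):
                row = {"meta_subject_id": f"s{i}", "meta_session": 1,
                       "meta_device": "other", "meta_label": lab,
                       "meta_moca_b": 20, "meta_mmse": 20}
                for fam, (a, b) in pairs.items():
                    if lab == a:
                        v = 1.0
                    elif lab == b:
                        v = -1.0
                    else:
                        v = rng.choice([-1.0, 1.0])  # uninformative third class
                    row[f"{fam}/f0"] = v + 0.3 * rng.standard_normal()
                rows.append(row)
            df = pd.DataFrame(rows)
            tr = df.sample(frac=0.7, random_state=seed)
            te = df.drop(tr.index)
            learners = [train_weak(tr, f, n_keep=1, k_neighbors=5) for f in fams]
            fused = adaboost_fuse(learners, tr)
            acc_f = (fused.predict(te) == te["meta_label"]).mean()
            accs = [(wl.predict(te) == te["meta_label"]).mean() for wl in fused.learners]
            wins += acc_f > max(accs)
        assert wins >= 18   # >= 90% of 20 seeds


class TestScaleRegression:
    @staticmethod
    def _sets(df, fams=("fractal", "complexity")):
        learners = [train_weak(df, f, n_keep=3, k_neighbors=5) for f in fams]
        return {wl.family: (wl.feature_names, wl.mean, wl.std) for wl in learners}

    def test_constant_target_recovered(self):
        df = make_fake_table(n_subj=15, seed=4)
        df["meta_moca_b"] = 20
        df["meta_mmse"] = 20
        regs = train_scale_regressors(df, self._sets(df))
        assert np.allclose(regs.predict(df, "moca_b"), 20.0, atol=0.5)
        assert np.allclose(regs.predict(df, "mmse"), 20.0, atol=0.5)

    def test_noiseless_linear_target_low_mae(self):
        df = make_fake_table(n_subj=20, seed=5)
        t = df["fractal/f0"].to_numpy()
        y = np.clip(15 + 5 * (t - t.mean()) / t.std(), 0, 30)
        df["meta_moca_b"] = y
        df["meta_mmse"] = y
        regs = train_scale_regressors(df, self._sets(df))
        assert np.abs(regs.predict(df, "moca_b") - y).mean() < 1.0

    def test_predictions_clipped_to_scale(self):
        df = make_fake_table(n_subj=12, seed=6)
        regs = train_scale_regressors(df, self._sets(df))
        for scale in ("moca_b", "mmse"):
            p = regs.predict(df, scale)
            assert p.min() >= 0.0 and p.max() <= 30.0


class TestCognitiveScore:
    def test_full_scores_healthy(self):
        assert cognitive_score("HC", 30, 30).total == pytest.approx(99.9)

    def test_zero_scores_dementia(self):
        assert cognitive_score("dementia", 0, 0).total == 0.0

    def test_mci_worked_example(self):
        s = cognitive_score("MCI", 18, 18)
        assert s.total == pytest.approx(33.3 + 0.5 * 36 / 30 * 33.3)
        assert s.total == pytest.approx(53.28)

    def test_class_ranges_respected(self):
        for label, lo in (("dementia", 0.0), ("MCI", 33.3), ("HC", 66.6)):
            for m in (0, 15, 30):
                t = cognitive_score(label, m, m).total
                assert lo <= t <= lo + 33.3 + 1e-9
                assert 0.0 <= t <= 99.9 + 1e-9

    def test_out_of_range_scale_rejected(self):
        with pytest.raises(ValueError):
            cognitive_score("HC", 31, 10)

    def test_ground_truth_uses_same_formula(self):
        assert true_cognitive_score("MCI", 18, 18) == cognitive_score("MCI", 18, 18).total


def test_train_model_end_to_end_on_fake_table():
    df = make_fake_table(n_subj=15, sep=2.0, seed=7)
    fused, regs = train_model(df, n_keep=3, k_neighbors=5)
    assert set(fused.alphas) == {
        "fractal", "complexity", "microstate", "spectral", "bispectral",
        "network", "phase",
    }
    acc = (fused.predict(df) == df["meta_label"]).mean()
    assert acc > 0.9
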