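"""ANN probe ranking: screen preparation, training, MCCV, rank order."""

import numpy as np
import pandas as pd
import pytest

from circmir import (CohortSpec, SplitScheme, TrainConfig, generate_cohort,
                     mccv_score_probe, prepare_screen_matrix, rank_probes,
                     select_top_k, train_ann)
from circmir.ann import _stratified_split
from tests.conftest import make_ct_rows


def small_screen(n_probes=6, seed=0, **kw):
    spec = CohortSpec(n_cases=10, n_controls=10, n_probes=n_probes, seed=seed, **kw)
    sheet, ct = generate_cohort(spec)
    return prepare_screen_matrix(ct, sheet)


class TestPrepareScreenMatrix:
    def build(self, ct_values_by_probe, n_cases=3, n_controls=3):
        rows, samples = [], []
        for i in range(n_cases):
            samples.append((f"case_{i}", "case"))
        for i in range(n_controls):
            samples.append((f"ctrl_{i}", "control"))
        for probe, vals in ct_values_by_probe.items():
            for (sid, _), v in zip(samples, vals):
                rows += make_ct_rows(sid, probe, [v], "array")
        sheet = pd.DataFrame([
            {"sample_id": sid, "group": grp} for sid, grp in samples])
        return pd.DataFrame(rows), sheet

    def test_all_undetermined_probe_excluded(self):
        ct, sheet = self.build({"dead": ["Undetermined"] * 6,
                                "alive": [25, 26, 24, 25, 26, 24]})
        m = prepare_screen_matrix(ct, sheet)
        assert m.probe_ids == ["alive"]

    def test_one_group_detection_retained(self):
        # numeric in all cases, Undetermined in all controls: kept
        ct, sheet = self.build({"half": [25, 25, 25, "Undetermined",
                                         "Undetermined", "Undetermined"],
                                "alive": [25, 26, 24, 25, 26, 24]})
        m = prepare_screen_matrix(ct, sheet)
        assert "half" in m.probe_ids

    def test_under_50pct_both_groups_excluded(self):
        ct, sheet = self.build({"rare": ["Undetermined", "Undetermined", 25,
                                         "Undetermined", "Undetermined", 25],
                                "alive": [25, 26, 24, 25, 26, 24]})
        m = prepare_screen_matrix(ct, sheet)
        assert "rare" not in m.probe_ids  # detected in 1/3 of each group

    def test_constant_probe_scales_to_zero(self):
        ct, sheet = self.build({"flat": [25.0] * 6, "alive": [25, 26, 24, 25, 26, 24]})
        m = prepare_screen_matrix(ct, sheet)
        assert np.all(m.column("flat") == 0.0)

    def test_values_in_unit_interval_and_orientation(self):
        m = small_screen()
        assert m.values.min() >= 0.0 and m.values.max() <= 1.0
        # expression scale: low C_T (high expression) maps to high value
        ct, sheet = self.build({"p": [20, 30, 25, 20, 30, 25]})
        mm = prepare_screen_matrix(ct, sheet)
        col = mm.column("p")
        assert col[0] == 1.0 and col[1] == 0.0

    def test_affine_ct_shift_absorbed(self):
        vals = [24.1, 26.3, 25.2, 24.8, 26.9, 25.5]
        ct1, sheet = self.build({"p": vals})
        ct2, _ = self.build({"p": [1.2 * v + 1.0 for v in vals]})  # stays below C_T 40
        m1 = prepare_screen_matrix(ct1, sheet)
        m2 = prepare_screen_matrix(ct2, sheet)
        # positive affine maps of C_T leave the min-max scaled column unchanged
        # (orientation flips sign of the scale factor handled by same ordering)
        assert np.allclose(m1.column("p"), m2.column("p"))

    def test_single_group_rejected(self):
        ct, sheet = self.build({"p": [25, 26, 24]}, n_cases=3, n_controls=0)
        with pytest.raises(ValueError):
            prepare_screen_matrix(ct, sheet.iloc[:3], )


class TestTrainAnn:
    def test_separable_feature_perfect_blind_accuracy(self, separable_labels):
        x, y = separable_labels
        score = mccv_score_probe(x, y, TrainConfig(seed=1),
                                 SplitScheme(n_repeats=10, seed=1), "sep")
        assert score.mean_test_accuracy == 1.0

    def test_constant_feature_majority_prediction(self):
        x = np.full(20, 0.5)
        y = np.array([1] * 12 + [0] * 8)
        rng = np.random.default_rng(0)
        tr, va, te = _stratified_split(y, SplitScheme(), rng)
        net = train_ann(x, y, TrainConfig(seed=0), tr, va, rng)
        p = net.predict_proba(x[te])
        # constant input -> constant output; accuracy equals majority fraction
        assert len(np.unique(np.round(p, 9))) == 1
        acc = np.mean((p >= 0.5).astype(int) == y[te])
        majority = max(np.mean(y[te]), 1 - np.mean(y[te]))
        assert acc in (majority, 1 - majority)

    def test_interval_rule_representable(self):
        # cases iff 0.4 < x < 0.6 with clean margins
        rng = np.random.default_rng(3)
        x_case = rng.uniform(0.45, 0.55, 10)
        x_ctrl = np.concatenate([rng.uniform(0.0, 0.3, 5), rng.uniform(0.7, 1.0, 5)])
        x = np.concatenate([x_case, x_ctrl])
        y = np.array([1] * 10 + [0] * 10)
        # representable by a difference of two steep sigmoids
        from circmir.ann import TrainedNetwork
        net = TrainedNetwork(np.array([40.0, 40.0]), np.array([-16.0, -24.0]),
                             np.array([20.0, -20.0]), -10.0, 0.0, 0, [])
        assert np.mean((net.predict_proba(x) >= 0.5).astype(int) == y) == 1.0
        # and learnable: a non-monotone rule needs wider init and more patience
        cfg = TrainConfig(seed=5, learning_rate=1.0, weight_init_range=2.0,
                          patience=500, max_epochs=8000)
        score = mccv_score_probe(x, y, cfg, SplitScheme(n_repeats=10, seed=5),
                                 "interval")
        assert score.mean_test_accuracy >= 0.9

    def test_degenerate_partition_errors(self):
        x = np.linspace(0, 1, 8)
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="re-split"):
            train_ann(x, y, TrainConfig(), np.array([0, 1, 2]), np.array([4, 5]), rng)

    def test_early_stopping_returns_best_epoch(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, 20)
        y = np.array([1] * 10 + [0] * 10)
        tr, va, _ = _stratified_split(y, SplitScheme(), rng)
        net = train_ann(x, y, TrainConfig(seed=7, max_epochs=500, patience=50),
                        tr, va, rng)
        assert net.best_val_mse == pytest.approx(min(net.val_trace), abs=1e-12)
        assert net.val_trace[net.best_epoch] == pytest.approx(net.best_val_mse)

    def test_blind_accuracy_matches_threshold_oracle_when_separable(self):
        # optimal single-threshold classifier achieves 1.0 on separated data;
        # the ANN must match it within 0.05 on blind data
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(0.8, 0.03, 10), rng.normal(0.2, 0.03, 10)])
        y = np.array([1] * 10 + [0] * 10)
        score = mccv_score_probe(x, y, TrainConfig(seed=11),
                                 SplitScheme(n_repeats=20, seed=11), "p")
        assert score.mean_test_accuracy >= 0.95


class TestMccv:
    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(0, 1, 20)
        y = rng.permutation([1] * 10 + [0] * 10)
        score = mccv_score_probe(x, y, TrainConfig(seed=13),
                                 SplitScheme(n_repeats=50, seed=13), "null")
        assert 0.35 <= score.mean_test_accuracy <= 0.65

    def test_label_copy_probe_perfect(self):
        y = np.array([1, 0] * 10)
        score = mccv_score_probe(y.astype(float), y, TrainConfig(seed=2),
                                 SplitScheme(n_repeats=10, seed=2), "copy")
        assert score.mean_test_accuracy == 1.0

    def test_split_partitions_disjoint_and_stratified(self):
        y = np.array([1] * 10 + [0] * 10)
        rng = np.random.default_rng(0)
        for _ in range(20):
            tr, va, te = _stratified_split(y, SplitScheme(), rng)
            all_idx = np.concatenate([tr, va, te])
            assert sorted(all_idx) == list(range(20))
            for part in (tr, va, te):
                assert len(np.unique(y[part])) == 2


class TestRankProbes:
    def test_column_order_invariance_and_determinism(self):
        m = small_screen(n_probes=5, seed=21,
                         planted_probe_ids={"miR-p001"}, delta_ct_shift=2.0)
        cfg = TrainConfig(seed=3)
        scheme = SplitScheme(n_repeats=5, seed=3)
        r1 = rank_probes(m, cfg, scheme)
        # permute probe columns
        perm = [2, 0, 4, 1, 3]
        m2 = small_screen(n_probes=5, seed=21,
                          planted_probe_ids={"miR-p001"}, delta_ct_shift=2.0)
        m2.values = m2.values[:, perm]
        m2.probe_ids = [m.probe_ids[i] for i in perm]
        r2 = rank_probes(m2, cfg, scheme)
        assert [s.probe_id for s in r1] == [s.probe_id for s in r2]
        assert r1 == rank_probes(m, cfg, scheme)  # byte-for-byte reproducible

    def test_planted_probe_ranks_first(self):
        m = small_screen(n_probes=8, seed=22,
                         planted_probe_ids={"miR-p002"}, delta_ct_shift=4.0,
                         biological_sd=0.3, sample_offset_sd=0.1, replicate_sd=0.1)
        ranked = rank_probes(m, TrainConfig(seed=4), SplitScheme(n_repeats=10, seed=4))
        assert ranked[0].probe_id == "miR-p002"

    def test_select_top_k(self):
        m = small_screen(n_probes=4, seed=23)
        ranked = rank_probes(m, TrainConfig(seed=5), SplitScheme(n_repeats=3, seed=5))
        assert select_top_k(ranked, 0) == []
        assert len(select_top_k(ranked, 4)) == 4
        assert select_top_k(ranked, 2) == [s.probe_id for s in ranked[:2]]
        with pytest.raises(ValueError):
            select_top_k(ranked, 5)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(hidden_nodes=0), dict(learning_rate=0.0),
        dict(patience=3000), dict(loss="hinge"),
    ])
    def test_bad_train_config(self, kw):
        with pytest.raises(ValueError):
            TrainConfig(**kw)

    def test_bad_split_scheme(self):
        with pytest.raises(ValueError):
            SplitScheme(train_frac=0.5, val_frac=0.2, test_frac=0.2)
        with pytest.raises(ValueError):
            SplitScheme(n_repeats=0)
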