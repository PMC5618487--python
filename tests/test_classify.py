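"""SVM grid search, jackknife evaluation, metrics, and the hierarchical flow."""

import numpy as np
import pandas as pd
import pytest

import ionclass as ic
from ionclass.classify import default_grid, metrics_from_confusion, reduced_grid
from ionclass.selection import LabeledDataset


def brute_metrics(cm):
    """Independent per-formula recomputation of Sn/OA/AA."""
    k = cm.shape[0]
    sn = [cm[i, i] / cm[i].sum() for i in range(k)]
    oa = sum(cm[i, i] for i in range(k)) / cm.sum()
    return sn, oa, sum(sn) / k


def separable_dataset(n=10):
    """Two well-separated Gaussian blobs in 3 features."""
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 0.05, size=(n, 3))
    b = rng.normal(3.0, 0.05, size=(n, 3))
    frame = pd.DataFrame(np.vstack([a, b]), columns=["f1", "f2", "f3"])
    return LabeledDataset(frame, np.array(["a"] * n + ["b"] * n))


class TestGrids:
    def test_default_grid_231_pairs(self):
        grid = default_grid()
        assert len(grid) == 231
        assert len(set(grid)) == 231
        cs = sorted({c for c, _ in grid})
        gs = sorted({g for _, g in grid})
        assert cs[0] == 2.0**-5 and cs[-1] == 2.0**15 and len(cs) == 11
        assert gs[0] == 2.0**-15 and gs[-1] == 2.0**5 and len(gs) == 21

    def test_reduced_grid_subset_of_default(self):
        assert set(reduced_grid()) <= set(default_grid())


class TestGridSearch:
    def test_single_pair_returned_regardless_of_score(self):
        ds = separable_dataset(4)
        config, _ = ic.grid_search(
            ds, grid=[(0.125, 4.0)], scorer=lambda d, c: 0.0
        )
        assert (config.C, config.gamma) == (0.125, 4.0)

    def test_separable_data_reaches_perfect_jackknife(self):
        ds = separable_dataset(6)
        config, score = ic.grid_search(ds, grid=reduced_grid())
        assert score == 1.0
        assert ic.jackknife_oa(ds, config) == 1.0

    def test_tie_break_smaller_c_then_gamma_order_invariant(self):
        ds = separable_dataset(4)
        grid = [(4.0, 2.0), (1.0, 8.0), (1.0, 2.0)]
        for permuted in (grid, grid[::-1], [grid[1], grid[2], grid[0]]):
            config, _ = ic.grid_search(ds, grid=permuted, scorer=lambda d, c: 0.5)
            assert (config.C, config.gamma) == (1.0, 2.0)

    def test_scorer_failure_names_pair(self):
        ds = separable_dataset(4)

        def bad_scorer(dataset, config):
            raise ValueError("nope")

        with pytest.raises(RuntimeError, match=r"C=1.0, gamma=2.0"):
            ic.grid_search(ds, grid=[(1.0, 2.0)], scorer=bad_scorer)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ic.grid_search(separable_dataset(4), grid=[])


class TestMetricsFromConfusion:
    def test_hand_applied_formulas(self):
        report = metrics_from_confusion(np.array([[3, 1], [0, 4]]))
        assert report.sensitivity == {"0": 0.75, "1": 1.0}
        assert report.overall_accuracy == pytest.approx(7 / 8)
        assert report.average_accuracy == pytest.approx(0.875)

    def test_identity_matrix_perfect(self):
        report = metrics_from_confusion(np.eye(4, dtype=int) * 5)
        assert report.overall_accuracy == 1.0
        assert report.average_accuracy == 1.0

    def test_random_matrices_match_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            cm = rng.integers(0, 20, size=(k, k))
            cm[np.arange(k), np.arange(k)] += 1  # no empty rows
            report = metrics_from_confusion(cm)
            sn, oa, aa = brute_metrics(cm)
            assert report.overall_accuracy == oa
            assert report.average_accuracy == pytest.approx(aa)
            assert list(report.sensitivity.values()) == pytest.approx(sn)
            assert 0 <= report.overall_accuracy <= 1
            assert 0 <= report.average_accuracy <= 1

    def test_oa_equals_aa_for_balanced_classes(self):
        cm = np.array([[7, 3], [2, 8]])  # both rows sum to 10
        report = metrics_from_confusion(cm)
        assert report.overall_accuracy == pytest.approx(report.average_accuracy)

    def test_empty_class_row_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics_from_confusion(np.array([[0, 0], [1, 1]]))


class TestJackknife:
    def test_perfect_classifier_perfect_report(self):
        ds = separable_dataset(5)
        report = ic.jackknife_evaluate(ds, ic.svm_train_predict(ic.SvmConfig(1, 1)))
        assert report.overall_accuracy == 1.0
        assert report.average_accuracy == 1.0
        assert all(v == 1.0 for v in report.sensitivity.values())

    def test_exactly_n_rounds_with_n_minus_1_training(self):
        ds = separable_dataset(4)
        sizes = []

        def spy(x_train, y_train, x_test):
            sizes.append((len(x_train), len(x_test)))
            return np.array([y_train[0]])

        ic.jackknife_evaluate(ds, spy)
        assert sizes == [(7, 1)] * 8

    def test_majority_dummy_matches_majority_share(self):
        frame = pd.DataFrame({"f": np.arange(7, dtype=float)})
        ds = LabeledDataset(frame, np.array(["a"] * 5 + ["b"] * 2))

        def majority(x_train, y_train, x_test):
            values, counts = np.unique(y_train, return_counts=True)
            return np.array([values[counts.argmax()]])

        report = ic.jackknife_evaluate(ds, majority)
        # each held-out "a" sees a 4-2 majority for "a"; each "b" sees 5-1
        assert report.overall_accuracy == pytest.approx(5 / 7)

    def test_deterministic_byte_identical_reports(self, planted_dataset):
        ds, _ = planted_dataset
        sub = ds.select(ic.rank_features(ds).ranked_names()[:10])
        config = ic.SvmConfig(C=8.0, gamma=8.0)
        first = ic.jackknife_evaluate(sub, ic.svm_train_predict(config, seed=3))
        second = ic.jackknife_evaluate(sub, ic.svm_train_predict(config, seed=3))
        assert first.to_tsv() == second.to_tsv()


class TestTrain:
    def test_train_predict_separable(self, default_table):
        ds = separable_dataset(6)
        params = ic.EncoderParams(lam=2, omega=0.1, table=default_table)
        bundle = ic.train(ds, params, svm_config=ic.SvmConfig(8, 1))
        predictions = bundle.predict_matrix(ds.matrix)
        assert (predictions == ds.labels).mean() == 1.0

    def test_multiclass_ovo_supported(self, default_table):
        rng = np.random.default_rng(1)
        centers = {"a": 0.0, "b": 3.0, "c": 6.0, "d": 9.0}
        rows, labels = [], []
        for label, center in centers.items():
            rows.append(rng.normal(center, 0.05, size=(5, 2)))
            labels += [label] * 5
        ds = LabeledDataset(
            pd.DataFrame(np.vstack(rows), columns=["x", "y"]), np.array(labels)
        )
        params = ic.EncoderParams(lam=2, omega=0.1, table=default_table)
        bundle = ic.train(ds, params, svm_config=ic.SvmConfig(8, 1))
        assert (bundle.predict_matrix(ds.matrix) == ds.labels).all()

    def test_retraining_identical(self, default_table):
        ds = separable_dataset(5)
        params = ic.EncoderParams(lam=2, omega=0.1, table=default_table)
        b1 = ic.train(ds, params, seed=11)
        b2 = ic.train(ds, params, seed=11)
        assert (b1.predict_matrix(ds.matrix) == b2.predict_matrix(ds.matrix)).all()

    def test_feature_name_mismatch(self, default_table):
        ds = separable_dataset(4)
        params = ic.EncoderParams(lam=2, omega=0.1, table=default_table)
        with pytest.raises(ValueError, match="lacks selected features"):
            ic.train(ds, params, selected_features=["missing"])

    def test_bundle_save_load_round_trip(self, default_table, tmp_path):
        spec = ic.two_class_spec(n_per_class=5, length=60, seed=4)
        records, labels = ic.generate(spec)
        params = ic.EncoderParams(lam=2, omega=0.1, table=default_table)
        matrix = ic.encode_matrix(records, params)
        ds = LabeledDataset(matrix, np.array(labels))
        bundle = ic.train(ds, params, svm_config=ic.SvmConfig(8, 8))
        bundle.save(tmp_path / "bundle")
        reloaded = ic.ModelBundle.load(tmp_path / "bundle")
        assert reloaded.selected_features == bundle.selected_features
        assert (
            reloaded.predict_matrix(matrix) == bundle.predict_matrix(matrix)
        ).all()
        assert reloaded.predict_record(records[0]) == bundle.predict_record(records[0])


@pytest.fixture(scope="module")
def bundles(default_table):
    """Three stage models trained on nested planted signals."""
    spec = ic.hierarchy_spec(scale=0.15, enrichment=8.0, seed=21)
    records, labels = ic.generate(spec)
    labels = np.array(labels)
    params = ic.EncoderParams(lam=3, omega=0.15, table=default_table)
    matrix = ic.encode_matrix(records, params)
    config = ic.SvmConfig(C=8.0, gamma=32.0)

    def stage(indices, stage_labels):
        ds = LabeledDataset(matrix.iloc[indices], stage_labels)
        ranked = ic.rank_features(ds).ranked_names()[:40]
        return ic.train(
            ds.select(ranked), params, selected_features=ranked, svm_config=config
        )

    is_ic = labels != "NIC"
    stage1 = stage(np.arange(len(labels)), np.where(is_ic, "IC", "NIC"))
    idx2 = np.flatnonzero(is_ic)
    stage2 = stage(
        idx2,
        np.where(
            np.char.startswith(labels[idx2].astype(str), "VGIC"), "VGIC", "LGIC"
        ),
    )
    idx3 = np.flatnonzero(np.char.startswith(labels.astype(str), "VGIC"))
    stage3 = stage(idx3, np.array([l.split("-", 1)[1] for l in labels[idx3]]))
    return stage1, stage2, stage3


class TestHierarchy:
    def test_planted_records_traverse_to_leaf(self, bundles):
        spec = ic.hierarchy_spec(scale=0.03, enrichment=8.0, seed=77)
        records, labels = ic.generate(spec)
        verdicts = ic.predict_hierarchy(records, *bundles)
        accuracy = np.mean([v.verdict == t for v, t in zip(verdicts, labels)])
        assert accuracy >= 0.8

    def test_nic_short_circuits(self, bundles):
        spec = ic.SyntheticSpec(
            classes=(ic.ClassSpec("NIC", 3),), length_range=(300, 300), seed=5
        )
        records, _ = ic.generate(spec)
        verdicts = ic.predict_hierarchy(records, *bundles)
        for v in verdicts:
            if v.verdict == "NIC":
                assert v.path == ("NIC",)

    def test_short_record_unencodable(self, bundles):
        short = ic.ProteinRecord("tiny", "ACD")
        (verdict,) = ic.predict_hierarchy([short], *bundles)
        assert verdict.verdict == "unencodable"
        assert "L <= lambda" in verdict.reason

    def test_verdicts_tsv(self, bundles, tmp_path):
        from ionclass.classify import write_verdicts

        records, _ = ic.generate(
            ic.SyntheticSpec(classes=(ic.ClassSpec("NIC", 2),), seed=6)
        )
        verdicts = ic.predict_hierarchy(records, *bundles)
        path = tmp_path / "verdicts.tsv"
        write_verdicts(verdicts, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "id\tverdict\tpath\treason"
        assert len(lines) == 3
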