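"""Holdout splitting, cross-validation and the three grid searches."""

import numpy as np
import pytest

from mdtwpose import (
    SplitPlan,
    Template,
    TemplateLibrary,
    WeightVector,
    five_fold_cv_accuracy,
    stratified_holdout,
    tune_band,
    tune_k,
    tune_weights,
)
from mdtwpose.classify import channel_distance_matrix
from mdtwpose.model_selection import (
    GridSizeError,
    log_spaced_k_grid,
    weight_delta_values,
)
from mdtwpose.sequences import CHANNELS, SequenceError


def pattern_template(label, tid, seed, shift=0.0, scale=1.0):
    """Normalized-flag template with a label-specific waveform family."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, 101)
    centers = {"DK": 0.3, "STP": 0.7, "SS": 0.5}
    c = centers[label] + shift + rng.normal(0, 0.01)
    rows = [
        scale * np.exp(-(((t - c) / 0.12) ** 2)) + 0.02 * rng.normal(size=101)
        for _ in CHANNELS
    ]
    return Template(
        angles=np.vstack(rows),
        label=label,
        subject_id=f"P{seed % 7}",
        time_normalized=True,
        scale_normalized=True,
        template_id=tid,
    )


@pytest.fixture(scope="module")
def toy_library():
    tpls = [
        pattern_template(label, f"{label}{i}", seed=i + off)
        for label, off in (("DK", 0), ("STP", 100), ("SS", 200))
        for i in range(10)
    ]
    return TemplateLibrary(templates=tpls)


class TestHoldout:
    def test_eighty_twenty(self, toy_library):
        plan = stratified_holdout(toy_library, seed=0)
        assert len(plan.test_ids) == 6  # 2 per class of 10
        assert len(plan.train_ids) == 24
        assert set(plan.train_ids) | set(plan.test_ids) == set(toy_library.ids)
        assert not set(plan.train_ids) & set(plan.test_ids)

    def test_deterministic_and_serializable(self, toy_library):
        a = stratified_holdout(toy_library, seed=3)
        b = stratified_holdout(toy_library, seed=3)
        assert a == b
        assert SplitPlan.from_json(a.to_json()) == a
        assert a != stratified_holdout(toy_library, seed=4)

    def test_rounding_rule_eleven_templates(self):
        tpls = [pattern_template("DK", f"t{i}", i) for i in range(11)]
        plan = stratified_holdout(TemplateLibrary(templates=tpls), seed=0)
        assert len(plan.test_ids) == 2  # round(0.2 * 11) = 2

    def test_fold_sizes_balanced_within_class(self, toy_library):
        plan = stratified_holdout(toy_library, seed=1)
        for label in ("DK", "STP", "SS"):
            ids = {t.template_id for t in toy_library if t.label == label}
            sizes = [len(ids & set(f)) for f in plan.folds]
            assert max(sizes) - min(sizes) <= 1
        assert sorted(i for f in plan.folds for i in f) == sorted(plan.train_ids)

    def test_small_class_rejected(self):
        tpls = [pattern_template("DK", f"t{i}", i) for i in range(4)]
        with pytest.raises(SequenceError, match="DK"):
            stratified_holdout(TemplateLibrary(templates=tpls), seed=0)


class TestCrossValidation:
    def test_separable_classes_perfect(self, toy_library):
        plan = stratified_holdout(toy_library, seed=0)
        acc = five_fold_cv_accuracy(toy_library, plan, WeightVector.initial())
        assert acc == 1.0

    def test_duplicate_template_always_correct(self, toy_library):
        # a fold item identical to a training item has distance zero to it
        plan = stratified_holdout(toy_library, seed=0)
        assert five_fold_cv_accuracy(toy_library, plan, k=1) == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(42)
        tpls = []
        for label, off in (("DK", 0), ("STP", 100), ("SS", 200)):
            for i in range(24):
                tpls.append(pattern_template(label, f"{label}{i}", seed=i + off))
        labels = [t.label for t in tpls]
        rng.shuffle(labels)
        shuffled = [
            Template(
                angles=t.angles, label=lab, subject_id=t.subject_id,
                time_normalized=True, scale_normalized=True, template_id=t.template_id,
            )
            for t, lab in zip(tpls, labels)
        ]
        lib = TemplateLibrary(templates=shuffled)
        plan = stratified_holdout(lib, seed=0)
        acc = five_fold_cv_accuracy(lib, plan)
        # chance is 1/3; allow ~4 sigma of binomial error around it
        n = len(plan.train_ids)
        assert abs(acc - 1 / 3) < 4 * np.sqrt((1 / 3) * (2 / 3) / n)


class TestTuneBand:
    def test_grid_has_eleven_entries(self, toy_library):
        plan = stratified_holdout(toy_library, seed=0)
        report = tune_band(toy_library, plan)
        assert len(report.entries) == 11
        assert report.selected_accuracy == max(a for _, a in report.entries)

    def test_band_at_length_equals_unbounded(self, toy_library):
        plan = stratified_holdout(toy_library, seed=0)
        cap = five_fold_cv_accuracy(toy_library, plan, band=101)
        unb = five_fold_cv_accuracy(toy_library, plan, band=None)
        assert cap == unb

    def test_temporal_shift_needs_wide_band(self):
        # class difference is a large shift: tiny bands cannot align within
        # class across jitter... construct two classes identical in shape but
        # offset in time; a 0-band DTW is a plain L1 distance and fails
        tpls = []
        for i in range(8):
            tpls.append(pattern_template("DK", f"a{i}", i, shift=(i % 4) * 0.12))
            tpls.append(pattern_template("STP", f"b{i}", 50 + i, shift=(i % 4) * 0.12))
        lib = TemplateLibrary(templates=tpls)
        plan = stratified_holdout(lib, seed=2)
        narrow = five_fold_cv_accuracy(lib, plan, band=0)
        wide = five_fold_cv_accuracy(lib, plan, band=50)
        assert wide >= narrow


class TestTuneK:
    def test_grid_endpoints(self):
        grid = log_spaced_k_grid(1911, 20)
        assert grid[0] == 1 and grid[-1] == 1911

    def test_k_equal_library_size_votes_majority(self):
        # with every template voting, the globally most frequent class wins
        # regardless of the distances
        from mdtwpose.classify import vote

        rng = np.random.default_rng(0)
        labels = ["DK"] * 9 + ["STP"] * 5 + ["SS"] * 4
        dists = rng.uniform(1, 10, size=len(labels))
        dists[np.array(labels) == "DK"] += 50  # majority class is farthest
        pred, _ = vote(dists, labels, k=len(labels))
        assert pred == "DK"

    def test_selects_k1_on_separable_data(self, toy_library):
        plan = stratified_holdout(toy_library, seed=0)
        report = tune_k(toy_library, plan, k_grid=[1, 3, 9, len(plan.train_ids)])
        assert report.selected == 1
        assert report.selected_accuracy == 1.0

    def test_out_of_range_k_rejected(self, toy_library):
        plan = stratified_holdout(toy_library, seed=0)
        with pytest.raises(SequenceError):
            tune_k(toy_library, plan, k_grid=[0])


class TestTuneWeights:
    def test_delta_values_seven_per_channel(self):
        vals = weight_delta_values(0.25)
        assert len(vals) == 7
        assert vals[0] == pytest.approx(0.205)
        assert vals[-1] == pytest.approx(0.295)

    def test_degenerate_grid_equals_cv_accuracy(self, toy_library):
        plan = stratified_holdout(toy_library, seed=0)
        base = WeightVector.initial()
        report = tune_weights(
            toy_library, plan, base=base, half_range=0.0, step=0.015,
            rknee_values=[1.0],
        )
        assert len(report.entries) == 1
        assert report.selected_accuracy == pytest.approx(
            five_fold_cv_accuracy(toy_library, plan, base)
        )

    def test_oversized_grid_refused_with_size(self, toy_library):
        plan = stratified_holdout(toy_library, seed=0)
        with pytest.raises(GridSizeError, match="117649"):
            tune_weights(toy_library, plan, max_grid=1000)

    def test_informative_channels_get_weight(self):
        # only knee channels carry the class signal; ankles are pure noise
        rng = np.random.default_rng(9)
        tpls = []
        t = np.linspace(0, 1, 101)
        for label, c in (("DK", 0.3), ("STP", 0.7)):
            for i in range(8):
                knee = np.exp(-(((t - c - rng.normal(0, 0.02)) / 0.1) ** 2))
                rows = []
                for ch in CHANNELS:
                    if ch.endswith("knee"):
                        rows.append(knee + 0.02 * rng.normal(size=101))
                    else:
                        rows.append(0.3 * rng.normal(size=101))
                tpls.append(
                    Template(
                        angles=np.vstack(rows), label=label, subject_id=f"P{i}",
                        time_normalized=True, scale_normalized=True,
                        template_id=f"{label}{i}",
                    )
                )
        lib = TemplateLibrary(templates=tpls)
        plan = stratified_holdout(lib, seed=0)
        report = tune_weights(
            lib, plan, half_range=0.045, step=0.045, rknee_values=[0.7, 1.0]
        )
        w = report.selected.as_mapping()
        assert w["l_knee"] >= w["l_ankle"]
        assert w["r_knee"] >= w["r_ankle"]

    def test_cached_equals_naive_on_toy_library(self, toy_library):
        # the cached fold evaluation must agree with direct classification
        plan = stratified_holdout(toy_library, seed=0)
        w = WeightVector.tuned()
        id_to_tpl = {t.template_id: t for t in toy_library}
        accs = []
        folds = plan.folds
        for f in range(5):
            lib_f = TemplateLibrary(
                templates=[
                    id_to_tpl[i] for g, fold in enumerate(folds) if g != f for i in fold
                ]
            )
            fold_q = [id_to_tpl[i] for i in folds[f]]
            per = channel_distance_matrix(lib_f, fold_q, 50)
            comb = per @ w.as_array()
            preds = [lib_f.labels[int(np.argmin(r))] for r in comb]
            accs.append(np.mean([p == q.label for p, q in zip(preds, fold_q)]))
        naive = float(np.mean(accs))
        assert five_fold_cv_accuracy(toy_library, plan, w) == pytest.approx(
            naive, abs=1e-9
        )
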