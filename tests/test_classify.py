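"""Weighted distance fusion and nearest-neighbour classification."""

import numpy as np
import pytest

from mdtwpose import (
    CHANNELS,
    Template,
    TemplateLibrary,
    WeightVector,
    combine_distances,
    knn_classify,
    mdtw_distance,
)
from mdtwpose.classify import vote
from mdtwpose.sequences import SequenceError


def make_template(angles, label, tid, subject="S0"):
    return Template(
        angles=angles,
        label=label,
        subject_id=subject,
        time_normalized=True,
        scale_normalized=True,
        template_id=tid,
    )


def wavy(seed, amp=1.0):
    """A normalized-looking 6 x 101 pattern, distinct per seed."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, 101)
    rows = []
    for _ in range(6):
        f = rng.uniform(0.5, 2.5)
        p = rng.uniform(0, np.pi)
        rows.append(amp * np.sin(2 * np.pi * f * t + p))
    a = np.vstack(rows)
    return 2 * (a - a.min()) / (a.max() - a.min()) - 1  # global [-1, 1]


class TestWeights:
    def test_named_vectors(self):
        ini = WeightVector.initial().as_mapping()
        tun = WeightVector.tuned().as_mapping()
        assert ini["r_knee"] == 1.00 and tun["r_knee"] == 1.00
        assert sum(ini.values()) == pytest.approx(3.75)
        assert sum(tun.values()) == pytest.approx(3.61)

    def test_missing_channel_named(self):
        with pytest.raises(SequenceError, match="l_hip"):
            WeightVector.from_mapping({c: 1.0 for c in CHANNELS if c != "l_hip"})

    def test_all_zero_rejected(self):
        with pytest.raises(SequenceError):
            WeightVector(values=(0.0,) * 6)


class TestCombine:
    def test_zero_distances(self):
        assert combine_distances({c: 0.0 for c in CHANNELS}, WeightVector.tuned()) == 0.0

    def test_tuned_weight_sum(self):
        # equal per-channel distances expose the total weight mass
        d = {c: 2.0 for c in CHANNELS}
        assert combine_distances(d, WeightVector.tuned()) == pytest.approx(7.22)

    def test_initial_weight_sum(self):
        d = {c: 1.0 for c in CHANNELS}
        assert combine_distances(d, WeightVector.initial()) == pytest.approx(3.75)

    def test_missing_distance_named(self):
        with pytest.raises(SequenceError, match="r_ankle"):
            combine_distances(
                {c: 1.0 for c in CHANNELS if c != "r_ankle"}, WeightVector.tuned()
            )


class TestMdtwDistance:
    def test_self_distance_zero(self):
        tpl = make_template(wavy(0), "DK", "t0")
        br = mdtw_distance(tpl, tpl)
        assert br.combined == 0.0

    def test_single_channel_offset(self):
        # differing only on the right knee by a constant 1: the diagonal path
        # accumulates 101 unit costs, weighted by the unit r_knee coefficient
        base = wavy(1) * 0.5
        tpl = make_template(base, "DK", "t0")
        shifted = base.copy()
        shifted[CHANNELS.index("r_knee")] += 1.0
        q = make_template(shifted, "DK", "q0")
        br = mdtw_distance(q, tpl, WeightVector.tuned())
        assert br.combined == pytest.approx(101.0)

    def test_amplitude_scaling_scales_combined(self):
        a, b = wavy(2) * 0.5, wavy(3) * 0.5
        t1 = make_template(a, "DK", "a")
        q1 = make_template(b, "DK", "b")
        t2 = make_template(2 * a, "DK", "a2")
        q2 = make_template(2 * b, "DK", "b2")
        d1 = mdtw_distance(q1, t1).combined
        d2 = mdtw_distance(q2, t2).combined
        assert d2 == pytest.approx(2 * d1, rel=1e-9)

    def test_combined_is_weighted_sum(self):
        tpl = make_template(wavy(4), "DK", "t")
        q = make_template(wavy(5), "DK", "q")
        br = mdtw_distance(q, tpl, WeightVector.tuned())
        assert br.combined == pytest.approx(
            combine_distances(br.per_channel, WeightVector.tuned()), abs=1e-9
        )

    def test_unnormalized_rejected_with_reason(self):
        from mdtwpose import MovementSequence

        tpl = make_template(wavy(0), "DK", "t")
        raw = MovementSequence(
            angles=wavy(0), label="DK", time_normalized=True, scale_normalized=False
        )
        with pytest.raises(SequenceError, match="scale"):
            mdtw_distance(raw, tpl)


class TestKnn:
    def build_library(self):
        tpls = [
            make_template(wavy(s), label, f"{label}{s}")
            for label, seeds in (("DK", (0, 1, 2)), ("STP", (10, 11, 12)))
            for s in seeds
        ]
        return TemplateLibrary(templates=tpls)

    def test_leave_in_identity(self):
        lib = self.build_library()
        for tpl in lib:
            pred, ranked = knn_classify(tpl, lib, k=1)
            assert pred == tpl.label
            assert ranked[0].combined == 0.0
            assert ranked[0].template_id == tpl.template_id

    def test_ranking_ascending_and_stable(self):
        lib = self.build_library()
        _, ranked = knn_classify(make_template(wavy(20), "DK", "q"), lib)
        ds = [r.combined for r in ranked]
        assert ds == sorted(ds)

    def test_weight_scale_invariance(self):
        lib = self.build_library()
        q = make_template(wavy(21), "DK", "q")
        w = WeightVector.tuned()
        w10 = WeightVector(values=tuple(10 * v for v in w.values))
        assert knn_classify(q, lib, w)[0] == knn_classify(q, lib, w10)[0]

    def test_empty_library_rejected(self):
        with pytest.raises(SequenceError):
            knn_classify(
                make_template(wavy(0), "DK", "q"), TemplateLibrary(templates=[])
            )

    def test_determinism(self):
        lib = self.build_library()
        q = make_template(wavy(22), "DK", "q")
        a = knn_classify(q, lib)
        b = knn_classify(q, lib)
        assert a[0] == b[0]
        assert [r.template_id for r in a[1]] == [r.template_id for r in b[1]]


class TestVote:
    def test_argmin_for_k1(self):
        pred, order = vote(np.array([3.0, 5.0]), ["A", "B"], 1)
        assert pred == "A" and list(order) == [0, 1]

    def test_majority_for_k3(self):
        pred, _ = vote(np.array([1.0, 2.0, 3.0, 9.0]), ["DK", "PK", "DK", "PK"], 3)
        assert pred == "DK"

    def test_tie_broken_by_mean_distance(self):
        # 2 votes each; PK neighbours are nearer on average
        pred, _ = vote(
            np.array([1.0, 1.5, 4.0, 5.0]), ["PK", "PK", "DK", "DK"], 4
        )
        assert pred == "PK"

    def test_k_bounds(self):
        with pytest.raises(SequenceError):
            vote(np.array([1.0]), ["DK"], 2)

    def test_exact_tie_at_k1_prefers_library_order(self):
        pred, _ = vote(np.array([2.0, 2.0]), ["STP", "DK"], 1)
        assert pred == "STP"
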