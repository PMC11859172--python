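"""Holdout splitting, five-fold cross-validation and grid searches.

The model-building protocol: per class, 80% of templates are randomly
allocated to training and 20% withheld for testing; the training set is
partitioned into five stratified folds; candidate settings for the band
half-width (0..100 in steps of 10), the neighbour count k (log-spaced
between 1 and the training-set size) and the six fusion weights (a local
grid of +/-0.045 in steps of 0.015 around the initial vector, the
right-knee weight spanning 0.7..1.0) are scored by mean fold accuracy.

Weight grids are evaluated through cached per-channel distances: the
weights enter only the final linear fusion, so the expensive DTW
distances are computed once per fold and reused across every candidate
weight vector.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .classify import TemplateLibrary, WeightVector, channel_distance_matrix, vote
from .dtw import DEFAULT_BAND
from .sequences import CHANNELS, SequenceError

__all__ = [
    "SplitPlan",
    "TuningReport",
    "stratified_holdout",
    "five_fold_cv_accuracy",
    "tune_band",
    "tune_k",
    "tune_weights",
    "log_spaced_k_grid",
    "GridSizeError",
]

N_FOLDS = 5


class GridSizeError(ValueError):
    """Weight grid larger than the configured cap."""


@dataclass(frozen=True)
class SplitPlan:
    """Deterministic stratified holdout split plus CV folds.

    ``train_ids`` / ``test_ids`` partition the library's template ids;
    ``folds`` partitions ``train_ids`` into five parts whose per-class
    sizes differ by at most one.
    """

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    folds: tuple[tuple[str, ...], ...]
    seed: int
    test_fraction: float = 0.2

    def to_json(self) -> str:
        return json.dumps(
            {
                "train_ids": list(self.train_ids),
                "test_ids": list(self.test_ids),
                "folds": [list(f) for f in self.folds],
                "seed": self.seed,
                "test_fraction": self.test_fraction,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        d = json.loads(text)
        return cls(
            train_ids=tuple(d["train_ids"]),
            test_ids=tuple(d["test_ids"]),
            folds=tuple(tuple(f) for f in d["folds"]),
            seed=int(d["seed"]),
            test_fraction=float(d["test_fraction"]),
        )


@dataclass(frozen=True)
class TuningReport:
    """Grid-search record: every evaluated setting and the selected one."""

    axis: str
    entries: tuple[tuple[object, float], ...]  # (setting, mean CV accuracy)
    selected: object
    selected_accuracy: float
    seed: Optional[int] = None
    notes: dict = field(default_factory=dict)


def _round_half_up_int(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_holdout(
    lib: TemplateLibrary,
    test_fraction: float = 0.2,
    seed: int = 0,
    n_folds: int = N_FOLDS,
    min_per_class: int = 5,
) -> SplitPlan:
    """Per-class random 80/20 split plus stratified CV folds.

    The number withheld per class is ``round(test_fraction * n)`` (half
    up), at least 1. Classes with fewer than ``min_per_class`` templates
    are rejected so that folds stay non-degenerate. Deterministic given
    the seed.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for t in lib:
        by_class.setdefault(t.label, []).append(t.template_id)
    for cls, ids in by_class.items():
        if len(ids) < min_per_class:
            raise SequenceError(
                f"class {cls} has only {len(ids)} templates; need >= {min_per_class}"
            )
    train, test = [], []
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for cls in sorted(by_class):
        ids = sorted(by_class[cls])
        perm = rng.permutation(len(ids))
        n_test = max(1, _round_half_up_int(test_fraction * len(ids)))
        shuffled = [ids[i] for i in perm]
        test.extend(shuffled[:n_test])
        cls_train = shuffled[n_test:]
        train.extend(cls_train)
        for j, tid in enumerate(cls_train):  # round-robin deal keeps folds stratified
            folds[j % n_folds].append(tid)
    return SplitPlan(
        train_ids=tuple(train),
        test_ids=tuple(test),
        folds=tuple(tuple(f) for f in folds),
        seed=seed,
        test_fraction=test_fraction,
    )


class _TrainDistanceCache:
    """Per-band cache of train x train per-channel DTW distances."""

    def __init__(self, lib: TemplateLibrary, plan: SplitPlan):
        self.lib = lib
        self.plan = plan
        id_to_idx = {t.template_id: i for i, t in enumerate(lib)}
        self.train_idx = [id_to_idx[i] for i in plan.train_ids]
        self.train_lib = lib.subset(self.train_idx)
        self.labels = self.train_lib.labels
        self.pos = {tid: i for i, tid in enumerate(plan.train_ids)}
        self._per_band: dict[object, np.ndarray] = {}

    def distances(self, band) -> np.ndarray:
        key = "unbounded" if band is None else int(band)
        if key not in self._per_band:
            self._per_band[key] = channel_distance_matrix(
                self.train_lib, list(self.train_lib), band
            )  # (n, n, 6)
        return self._per_band[key]


def _fold_accuracies(
    cache: _TrainDistanceCache, w: WeightVector, k: int, band
) -> list[float]:
    per = cache.distances(band)  # (n, n, 6)
    combined = per @ w.as_array()  # (n, n)
    labels = cache.labels
    accs = []
    for f, fold in enumerate(cache.plan.folds):
        if not fold:
            raise SequenceError(f"fold {f} is empty")
        fold_pos = [cache.pos[tid] for tid in fold]
        lib_pos = [
            cache.pos[tid]
            for other in cache.plan.folds
            if other is not cache.plan.folds[f]
            for tid in other
        ]
        lib_labels = [labels[i] for i in lib_pos]
        kk = min(k, len(lib_pos))
        correct = 0
        for q in fold_pos:
            pred, _ = vote(combined[q, lib_pos], lib_labels, kk)
            correct += pred == labels[q]
        accs.append(correct / len(fold_pos))
    return accs


def five_fold_cv_accuracy(
    lib: TemplateLibrary,
    plan: SplitPlan,
    w: Optional[WeightVector] = None,
    k: int = 1,
    band: Optional[int] = DEFAULT_BAND,
    cache: Optional[_TrainDistanceCache] = None,
) -> float:
    """Mean accuracy over the five fold permutations.

    For each permutation, four folds populate the template library and
    the held-out fold is classified; the returned value is the
    unweighted mean of the five per-fold accuracies.
    """
    w = w or WeightVector.initial()
    cache = cache or _TrainDistanceCache(lib, plan)
    return float(np.mean(_fold_accuracies(cache, w, k, band)))


def tune_band(
    lib: TemplateLibrary,
    plan: SplitPlan,
    w: Optional[WeightVector] = None,
    k: int = 1,
    grid: Sequence[int] = tuple(range(0, 101, 10)),
) -> TuningReport:
    """Score each band half-width by cross-validated accuracy.

    Ties select the smallest band (the least-warped model).
    """
    if not grid:
        raise SequenceError("band grid must be non-empty")
    w = w or WeightVector.initial()
    cache = _TrainDistanceCache(lib, plan)
    entries = [
        (b, five_fold_cv_accuracy(lib, plan, w, k, b, cache=cache)) for b in grid
    ]
    best = max(entries, key=lambda e: (e[1], -e[0]))
    return TuningReport(
        axis="band_halfwidth",
        entries=tuple(entries),
        selected=best[0],
        selected_accuracy=best[1],
        seed=plan.seed,
    )


def log_spaced_k_grid(n_train: int, n_points: int = 20) -> list[int]:
    """Integer k grid log-spaced between 1 and n_train, deduplicated."""
    ks = np.unique(
        np.round(np.logspace(0.0, math.log10(n_train), n_points)).astype(int)
    )
    ks = ks[(ks >= 1) & (ks <= n_train)]
    return [int(v) for v in ks]


def tune_k(
    lib: TemplateLibrary,
    plan: SplitPlan,
    w: Optional[WeightVector] = None,
    band: Optional[int] = DEFAULT_BAND,
    k_grid: Optional[Sequence[int]] = None,
    n_points: int = 20,
) -> TuningReport:
    """Score neighbour counts by cross-validated accuracy (ties: smallest k)."""
    w = w or WeightVector.initial()
    n_train = len(plan.train_ids)
    grid = list(k_grid) if k_grid is not None else log_spaced_k_grid(n_train, n_points)
    if any(k < 1 or k > n_train for k in grid):
        raise SequenceError(f"k grid must lie within [1, {n_train}]")
    cache = _TrainDistanceCache(lib, plan)
    entries = [
        (k, five_fold_cv_accuracy(lib, plan, w, k, band, cache=cache)) for k in grid
    ]
    best = max(entries, key=lambda e: (e[1], -e[0]))
    return TuningReport(
        axis="k",
        entries=tuple(entries),
        selected=best[0],
        selected_accuracy=best[1],
        seed=plan.seed,
    )


def weight_delta_values(base: float, half_range: float = 0.045, step: float = 0.015):
    """The candidate values for one non-anchored channel weight."""
    n = int(round(half_range / step))
    return [round(base + i * step, 10) for i in range(-n, n + 1)]


def tune_weights(
    lib: TemplateLibrary,
    plan: SplitPlan,
    k: int = 1,
    band: Optional[int] = DEFAULT_BAND,
    base: Optional[WeightVector] = None,
    half_range: float = 0.045,
    step: float = 0.015,
    rknee_values: Optional[Sequence[float]] = None,
    max_grid: int = 20_000,
    allow_large: bool = False,
) -> TuningReport:
    """Joint grid search over the six fusion weights.

    Every non-right-knee channel takes values within ``+/- half_range``
    of its base weight in steps of ``step`` (7 values at the defaults);
    the right-knee weight spans ``rknee_values`` (default 0.7..1.0 in
    steps of 0.05). The full joint grid is evaluated through cached
    per-channel distances. Grids larger than ``max_grid`` are refused
    unless ``allow_large`` is set; ties select the vector closest (L1)
    to the base.
    """
    base = base or WeightVector.initial()
    base_map = base.as_mapping()
    rknee = [round(v, 10) for v in (rknee_values if rknee_values is not None
                                    else np.arange(0.7, 1.0 + 1e-9, 0.05))]
    axes = []
    for c in CHANNELS:
        if c == "r_knee":
            axes.append(rknee)
        else:
            axes.append(weight_delta_values(base_map[c], half_range, step))
    size = int(np.prod([len(a) for a in axes]))
    if size > max_grid and not allow_large:
        raise GridSizeError(
            f"weight grid has {size} combinations, above the cap of {max_grid}; "
            "pass allow_large=True to run it anyway"
        )
    cache = _TrainDistanceCache(lib, plan)
    per = cache.distances(band)
    base_arr = base.as_array()

    entries = []
    for combo in itertools.product(*axes):
        wv = WeightVector(values=tuple(max(0.0, v) for v in combo))
        acc = float(np.mean(_fold_accuracies(cache, wv, k, band)))
        entries.append((wv.values, acc))
    del per

    def tie_key(e):
        vals = np.asarray(e[0])
        return (-e[1], float(np.abs(vals - base_arr).sum()), e[0])

    best = min(entries, key=tie_key)
    return TuningReport(
        axis="weights",
        entries=tuple(entries),
        selected=WeightVector(values=best[0]),
        selected_accuracy=best[1],
        seed=plan.seed,
        notes={"grid_size": size},
    )
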