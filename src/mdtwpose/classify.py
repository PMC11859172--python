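"""Weighted multi-channel DTW fusion and nearest-neighbour classification.

Per-channel DTW distances between a query trial and a template are fused
into one scalar by a weighted sum

    D_mDTW = w_LAnkle * D_LAnkle + w_RAnkle * D_RAnkle
           + w_LKnee  * D_LKnee  + w_RKnee  * D_RKnee
           + w_LHip   * D_LHip   + w_RHip   * D_RHip,

with the right-knee weight anchored at 1.00. Two named weight vectors
ship with the package: the hand-iterated ``initial`` vector
(0.25/0.25/0.75/1.00/0.75/0.75 for L-ankle/R-ankle/L-knee/R-knee/
L-hip/R-hip) and the grid-``tuned`` vector
(0.26/0.20/0.72/1.00/0.67/0.76). Classification is k-nearest-neighbour
over a template library under this metric, k = 1 by default.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .dtw import DEFAULT_BAND, batch_dtw_distance, dtw_distance
from .sequences import CHANNELS, CLASS_ORDER, MovementSequence, SequenceError, Template

__all__ = [
    "WeightVector",
    "DistanceBreakdown",
    "TemplateLibrary",
    "combine_distances",
    "mdtw_distance",
    "knn_classify",
    "channel_distance_matrix",
]


@dataclass(frozen=True)
class WeightVector:
    """Non-negative fusion weights, one per joint-angle channel."""

    values: tuple[float, ...]  # aligned with sequences.CHANNELS

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(CHANNELS),):
            raise SequenceError(
                f"need {len(CHANNELS)} weights (order {CHANNELS}), got {v.shape}"
            )
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise SequenceError("weights must be finite and >= 0")
        if not np.any(v > 0):
            raise SequenceError("at least one weight must be > 0")

    @classmethod
    def from_mapping(cls, weights: Mapping[str, float]) -> "WeightVector":
        missing = [c for c in CHANNELS if c not in weights]
        if missing:
            raise SequenceError(f"missing channel weight(s): {missing}")
        return cls(values=tuple(float(weights[c]) for c in CHANNELS))

    @classmethod
    def initial(cls) -> "WeightVector":
        """Hand-iterated starting weights (R-knee anchored at 1.00)."""
        return cls.from_mapping(
            {"l_ankle": 0.25, "r_ankle": 0.25, "l_knee": 0.75,
             "r_knee": 1.00, "l_hip": 0.75, "r_hip": 0.75}
        )

    @classmethod
    def tuned(cls) -> "WeightVector":
        """Grid-tuned weights selected by cross-validation."""
        return cls.from_mapping(
            {"l_ankle": 0.26, "r_ankle": 0.20, "l_knee": 0.72,
             "r_knee": 1.00, "l_hip": 0.67, "r_hip": 0.76}
        )

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(CHANNELS, self.values))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __getitem__(self, channel: str) -> float:
        return self.as_mapping()[channel]


@dataclass(frozen=True)
class DistanceBreakdown:
    """Per-channel DTW distances and their weighted combination."""

    per_channel: dict[str, float]
    combined: float
    template_id: str = ""
    template_label: Optional[str] = None


@dataclass
class TemplateLibrary:
    """Ordered collection of normalized templates.

    Ordering is part of the library's identity: the classifier breaks
    exact distance ties by library position, so a round-tripped library
    must classify identically.
    """

    templates: list[Template]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not all(t.label in CLASS_ORDER for t in self.templates):
            bad = sorted({t.label for t in self.templates} - set(CLASS_ORDER))
            raise SequenceError(f"library contains non-canonical labels: {bad}")
        self._stack: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.templates]

    @property
    def ids(self) -> list[str]:
        return [t.template_id for t in self.templates]

    @property
    def class_counts(self) -> dict[str, int]:
        counts = Counter(self.labels)
        return {c: counts.get(c, 0) for c in CLASS_ORDER if counts.get(c, 0)}

    def stacked(self) -> np.ndarray:
        """(K, 6, 101) template angle stack, cached."""
        if self._stack is None or self._stack.shape[0] != len(self.templates):
            self._stack = np.stack([t.angles for t in self.templates])
        return self._stack

    def subset(self, indices: Sequence[int]) -> "TemplateLibrary":
        return TemplateLibrary(
            templates=[self.templates[i] for i in indices],
            provenance=dict(self.provenance, subset_of=len(self)),
        )


def combine_distances(per_channel: Mapping[str, float], w: WeightVector) -> float:
    """Weighted sum of the six per-channel DTW distances."""
    missing = [c for c in CHANNELS if c not in per_channel]
    if missing:
        raise SequenceError(f"missing per-channel distance(s): {missing}")
    total = 0.0
    for c, wc in zip(CHANNELS, w.values):
        d = float(per_channel[c])
        if not np.isfinite(d) or d < 0:
            raise SequenceError(f"distance for channel {c} must be finite and >= 0")
        total += wc * d
    return total


def _require_normalized(seq: MovementSequence, what: str) -> None:
    missing = []
    if not seq.time_normalized:
        missing.append("time")
    if not seq.scale_normalized:
        missing.append("scale")
    if missing:
        raise SequenceError(f"{what} is missing {' and '.join(missing)} normalization")


def mdtw_distance(
    seq: MovementSequence,
    tpl: Template,
    w: Optional[WeightVector] = None,
    band_halfwidth: Optional[int] = DEFAULT_BAND,
    mode: str = "optimal",
) -> DistanceBreakdown:
    """Fused multi-channel DTW distance between a query and one template.

    Channels are paired like-to-like (left ankle to left ankle, and so
    on); fusion is the weighted sum of the six scalar DTW distances.
    """
    w = w or WeightVector.tuned()
    _require_normalized(seq, "query sequence")
    _require_normalized(tpl, "template")
    per = {
        c: dtw_distance(
            tpl.channel(c), seq.channel(c), band_halfwidth=band_halfwidth, mode=mode
        ).distance
        for c in CHANNELS
    }
    return DistanceBreakdown(
        per_channel=per,
        combined=combine_distances(per, w),
        template_id=tpl.template_id,
        template_label=tpl.label,
    )


def channel_distance_matrix(
    lib: TemplateLibrary,
    queries: Sequence[MovementSequence],
    band_halfwidth: Optional[int] = DEFAULT_BAND,
) -> np.ndarray:
    """(n_queries, n_templates, 6) optimal per-channel DTW distances.

    The heavy part of classification and of every grid search; weights
    enter only in the subsequent linear fusion, so this array can be
    reused across weight vectors.
    """
    if len(lib) == 0:
        raise SequenceError("template library is empty")
    stack = lib.stacked()  # (K, 6, L)
    out = np.empty((len(queries), stack.shape[0], len(CHANNELS)))
    for qi, q in enumerate(queries):
        _require_normalized(q, f"query {qi}")
        for ci in range(len(CHANNELS)):
            out[qi, :, ci] = batch_dtw_distance(
                stack[:, ci, :], q.angles[ci], band_halfwidth=band_halfwidth
            )
    return out


def vote(
    combined: np.ndarray, labels: Sequence[str], k: int
) -> tuple[str, np.ndarray]:
    """k-NN decision from combined distances to every template.

    Returns the predicted label and the stable ascending ranking of
    template indices. For k = 1 the nearest template's label wins (exact
    ties resolved by library position). For k > 1 the majority label
    among the k nearest wins; tied classes are resolved by the smaller
    mean combined distance among the tied neighbours, then by canonical
    class order.
    """
    if k < 1 or k > len(labels):
        raise SequenceError(f"k must be in [1, {len(labels)}], got {k}")
    order = np.argsort(combined, kind="stable")
    if k == 1:
        return labels[order[0]], order
    top = order[:k]
    votes = Counter(labels[i] for i in top)
    best_count = max(votes.values())
    tied = [c for c, n in votes.items() if n == best_count]
    if len(tied) == 1:
        return tied[0], order
    means = {
        c: float(np.mean([combined[i] for i in top if labels[i] == c])) for c in tied
    }
    tied.sort(key=lambda c: (means[c], CLASS_ORDER.index(c)))
    return tied[0], order


def knn_classify(
    seq: MovementSequence,
    lib: TemplateLibrary,
    w: Optional[WeightVector] = None,
    k: int = 1,
    band_halfwidth: Optional[int] = DEFAULT_BAND,
) -> tuple[str, list[DistanceBreakdown]]:
    """Classify one query against a template library.

    Returns the predicted class and the full ranked list of
    :class:`DistanceBreakdown` (ascending combined distance, stable).
    """
    w = w or WeightVector.tuned()
    if len(lib) == 0:
        raise SequenceError("template library is empty")
    per = channel_distance_matrix(lib, [seq], band_halfwidth)[0]  # (K, 6)
    combined = per @ w.as_array()
    labels = lib.labels
    predicted, order = vote(combined, labels, k)
    ranked = [
        DistanceBreakdown(
            per_channel=dict(zip(CHANNELS, per[i])),
            combined=float(combined[i]),
            template_id=lib.templates[i].template_id,
            template_label=labels[i],
        )
        for i in order
    ]
    return predicted, ranked
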