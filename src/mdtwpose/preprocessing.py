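"""Trial normalization, class relabelling and gait-cycle segmentation.

Raw trials are (a) relabelled onto the canonical 12-class vocabulary
(the two supported-kneeling variants collapse to SK, side leaning joins
side sitting), (b) linearly resampled to 101 samples, (c) min-max scaled
to [-1, 1], and -- for walking trials -- (d) split into single gait
cycles bounded by instants of maximum knee extension.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np
from scipy.signal import find_peaks

from .sequences import (
    CHANNELS,
    CLASS_ORDER,
    RAW_CLASS_CODES,
    TEMPLATE_LENGTH,
    MovementSequence,
    SequenceError,
    Template,
)

#: Collapsing of the 15 raw recording codes onto the 12 canonical classes.
RELABEL_MAP: dict[str, str] = {code: code for code in CLASS_ORDER}
RELABEL_MAP.update({"SAK": "SK", "DAK": "SK", "SL": "SS"})


def relabel_class(raw_label: str) -> str:
    """Map a raw recording code to its canonical motion class.

    Both arm-supported kneeling variants become SK and side leaning
    becomes side sitting; canonical codes map to themselves.
    """
    try:
        return RELABEL_MAP[raw_label]
    except KeyError:
        raise SequenceError(
            f"unknown motion code {raw_label!r}; expected one of {sorted(RAW_CLASS_CODES)}"
        ) from None


def resample_to_length(
    seq: MovementSequence, target_len: int = TEMPLATE_LENGTH
) -> MovementSequence:
    """Linearly interpolate every channel onto a uniform grid.

    The grid is uniform in normalized time [0, 1] with ``target_len``
    points, endpoints inclusive, so the first and last samples of each
    channel are preserved exactly.
    """
    if target_len < 2:
        raise SequenceError(f"target_len must be >= 2, got {target_len}")
    n = seq.n_samples
    if n < 2:
        raise SequenceError("cannot interpolate a trial with fewer than 2 samples")
    old_t = np.linspace(0.0, 1.0, n)
    new_t = np.linspace(0.0, 1.0, target_len)
    out = np.vstack([np.interp(new_t, old_t, row) for row in seq.angles])
    # endpoints exactly, regardless of interpolation round-off
    out[:, 0] = seq.angles[:, 0]
    out[:, -1] = seq.angles[:, -1]
    res = seq.copy()
    res.angles = out
    res.time_normalized = target_len == TEMPLATE_LENGTH
    # resampling changes the effective rate; keep duration bookkeeping honest
    res.sample_rate = (target_len - 1) / max(seq.duration_s, 1e-12)
    res.validate()
    return res


def scale_normalize(
    seq: MovementSequence, scope: Literal["per_channel", "per_trial"] = "per_trial"
) -> MovementSequence:
    """Affinely map angles onto [-1, 1] by min-max scaling.

    ``scope="per_trial"`` (default) uses one min/max across all six
    channels, preserving the between-joint amplitude ratios on which the
    classifier discriminates; ``"per_channel"`` scales each channel by
    its own extrema, keeping only per-channel shape. A constant channel
    (or trial) maps to zero, the midpoint of the target range, since a
    flat signal carries no shape information.
    """
    a = seq.angles
    out = np.empty_like(a, dtype=float)
    if scope == "per_trial":
        lo, hi = float(a.min()), float(a.max())
        if hi - lo <= 0:
            out[:] = 0.0
        else:
            out[:] = 2.0 * (a - lo) / (hi - lo) - 1.0
    elif scope == "per_channel":
        for i, row in enumerate(a):
            lo, hi = float(row.min()), float(row.max())
            if hi - lo <= 0:
                out[i] = 0.0
            else:
                out[i] = 2.0 * (row - lo) / (hi - lo) - 1.0
    else:
        raise SequenceError(f"unknown normalization scope {scope!r}")
    res = seq.copy()
    res.angles = out
    res.scale_normalized = True
    res.meta = dict(res.meta, scale_scope=scope)
    res.validate()
    return res


def make_template(
    seq: MovementSequence,
    template_id: str,
    scope: Literal["per_channel", "per_trial"] = "per_trial",
) -> Template:
    """Normalize a segmented, labelled trial into a 6 x 101 template."""
    label = relabel_class(seq.label) if seq.label is not None else None
    norm = scale_normalize(resample_to_length(seq), scope=scope)
    return Template(
        angles=norm.angles,
        label=label,
        subject_id=seq.subject_id,
        sample_rate=norm.sample_rate,
        time_normalized=True,
        scale_normalized=True,
        meta=norm.meta,
        template_id=template_id,
    )


def segment_gait_cycles(
    seq: MovementSequence,
    knee_channel: str = "r_knee",
    min_prominence: float = 5.0,
    min_separation_s: float = 0.4,
) -> tuple[list[MovementSequence], list[int]]:
    """Split a walking trial into gait cycles at maximum knee extension.

    Cycle boundaries are troughs of the knee flexion channel (instants of
    maximum knee extension, i.e. heel strike). Troughs are detected with
    a minimum prominence (degrees) and minimum separation (seconds); the
    trial's first and last samples additionally count as boundaries when
    they sit within the prominence threshold of the global minimum, so a
    trial that starts and ends mid-stance yields its full stride count.
    Candidate cycles that contain no prominent flexion peak (e.g. stretches
    of quiet standing) are dropped.

    Returns ``(cycles, boundaries)`` where boundaries are sample indices
    into the input; cycles are the half-open spans between consecutive
    boundaries, hence contiguous and non-overlapping.
    """
    if knee_channel not in CHANNELS:
        raise SequenceError(f"unknown knee channel {knee_channel!r}")
    x = seq.channel(knee_channel)
    min_dist = max(1, int(round(min_separation_s * seq.sample_rate)))

    flex_peaks, _ = find_peaks(x, prominence=min_prominence, distance=min_dist)
    if flex_peaks.size == 0:
        warnings.warn("no prominent knee flexion peak found; no gait cycles detected")
        return [], []

    troughs, _ = find_peaks(-x, prominence=min_prominence, distance=min_dist)
    boundaries = set(int(t) for t in troughs)
    gmin = float(x.min())
    # trial start/end count as boundaries when the knee is near maximum
    # extension there (placed at the most extended sample of the edge window)
    w = min(min_dist, x.size)
    i0 = int(np.argmin(x[:w]))
    if x[i0] <= gmin + min_prominence:
        boundaries.add(i0)
    i1 = x.size - w + int(np.argmin(x[-w:]))
    if x[i1] <= gmin + min_prominence:
        boundaries.add(i1)
    bounds = sorted(boundaries)

    if len(bounds) < 2:
        warnings.warn(
            f"fewer than 2 gait-cycle boundaries detected ({len(bounds)}); "
            "returning no cycles"
        )
        return [], []

    cycles: list[MovementSequence] = []
    kept_bounds: list[int] = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        if not np.any((flex_peaks > b0) & (flex_peaks < b1)):
            continue  # no stride inside this span
        if b1 - b0 < 2:
            continue
        cyc = seq.copy()
        cyc.angles = seq.angles[:, b0:b1]
        cyc.time_normalized = False
        cyc.meta = dict(seq.meta, cycle_bounds=(b0, b1))
        cycles.append(cyc)
        kept_bounds.extend([b0, b1])
    return cycles, sorted(set(kept_bounds))
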