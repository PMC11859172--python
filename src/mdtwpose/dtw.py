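"""Banded dynamic time warping between single joint-angle channels.

The local cost between template sample ``t_m`` and sequence sample
``s_n`` is the Euclidean norm ``|t_m - s_n|`` (scalar channels). The DTW
distance is the minimum, over monotone warping paths built from the
moves (+1,0), (0,+1), (+1,+1), of the accumulated local cost from the
first cell to the last, optionally restricted to a Sakoe-Chiba band of
half-width ``r`` around the diagonal (``|m - n| <= r`` for equal-length
inputs; around the proportional diagonal otherwise). A band of 50 on
101-sample channels -- the operating point used throughout this package
-- permits a maximum warp of 49.5% of the signal length.

Two path modes are provided. ``optimal`` solves the full dynamic
programme. ``greedy`` advances from each cell to whichever admissible
neighbour has the smallest *local* cost; it is a strictly local rule,
kept as a documented alternative for fidelity experiments, and its
distance can never undercut the optimal one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

__all__ = [
    "CostMatrix",
    "WarpResult",
    "local_cost_matrix",
    "dtw_distance",
    "brute_force_dtw",
    "max_warp_fraction",
    "batch_dtw_distance",
    "DTWBandError",
]

DEFAULT_BAND = 50


class DTWBandError(ValueError):
    """Band too narrow to connect the matrix corners."""


@dataclass(frozen=True)
class CostMatrix:
    """Local-cost matrix: ``values[m, n] = |t_m - s_n|``."""

    values: np.ndarray  # (M, N), non-negative finite

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class WarpResult:
    """Accumulated distance plus the warp path for one channel pair.

    ``path`` holds 0-based ``(m, n)`` index pairs from ``(0, 0)`` to
    ``(M-1, N-1)``; ``distance`` is the unnormalized sum of local costs
    over the path cells.
    """

    distance: float
    path: tuple[tuple[int, int], ...]
    M: int
    N: int
    band_halfwidth: Optional[int]  # None = unbounded
    mode: str = "optimal"

    @property
    def ix(self) -> np.ndarray:
        """Template-side warped index sequence."""
        return np.array([m for m, _ in self.path])

    @property
    def iy(self) -> np.ndarray:
        """Sequence-side warped index sequence."""
        return np.array([n for _, n in self.path])

    def normalized(self, how: Literal["none", "mn", "path_len"] = "none") -> float:
        """Distance under an optional normalization convention."""
        if how == "none":
            return self.distance
        if how == "mn":
            return self.distance / (self.M * self.N)
        if how == "path_len":
            return self.distance / len(self.path)
        raise ValueError(f"unknown normalization {how!r}")

    def to_text(self) -> str:
        """Plain-text record of the warp, for debugging and plotting."""
        band = "unbounded" if self.band_halfwidth is None else self.band_halfwidth
        pairs = ";".join(f"{m},{n}" for m, n in self.path)
        return (
            f"distance={self.distance!r}\nband={band}\nmode={self.mode}\n"
            f"shape={self.M}x{self.N}\npath={pairs}\n"
        )


def _check_vector(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def local_cost_matrix(template_channel, sequence_channel) -> CostMatrix:
    """Absolute-difference cost between every template/sequence sample pair."""
    t = _check_vector(template_channel, "template_channel")
    s = _check_vector(sequence_channel, "sequence_channel")
    return CostMatrix(values=np.abs(t[:, None] - s[None, :]))


def _band_limits(M: int, N: int, band: Optional[int]) -> tuple[np.ndarray, np.ndarray]:
    """Per-column admissible row range [lo, hi] inclusive.

    The band is taken around the proportional diagonal mapping column n
    to row n*(M-1)/(N-1), which is the exact diagonal for equal lengths.
    """
    n = np.arange(N)
    if band is None:
        return np.zeros(N, dtype=int), np.full(N, M - 1, dtype=int)
    center = n * (M - 1) / max(N - 1, 1)
    lo = np.maximum(0, np.ceil(center - band - 1e-9).astype(int))
    hi = np.minimum(M - 1, np.floor(center + band + 1e-9).astype(int))
    return lo, hi


def _validate_band(M: int, N: int, band: Optional[int]) -> None:
    if band is None:
        return
    if band < 0:
        raise DTWBandError(f"band_halfwidth must be >= 0, got {band}")
    required = abs(M - N)
    if band < required:
        raise DTWBandError(
            f"band_halfwidth {band} infeasible for lengths {M} x {N}; "
            f"minimum required band is {required}"
        )


def dtw_distance(
    template_channel,
    sequence_channel,
    band_halfwidth: Optional[int] = DEFAULT_BAND,
    mode: Literal["optimal", "greedy"] = "optimal",
) -> WarpResult:
    """Banded DTW distance and warp path between two scalar channels.

    ``mode="optimal"`` solves ``C(m,n) = d(m,n) + min(C(m-1,n), C(m,n-1),
    C(m-1,n-1))`` within the band and backtracks the minimizing path
    (ties prefer the diagonal move, then the vertical, then the
    horizontal, so paths are deterministic). ``mode="greedy"`` applies
    the local-move rule: from each cell step to the admissible neighbour
    with the smallest local cost.
    """
    t = _check_vector(template_channel, "template_channel")
    s = _check_vector(sequence_channel, "sequence_channel")
    M, N = t.size, s.size
    _validate_band(M, N, band_halfwidth)
    d = np.abs(t[:, None] - s[None, :])
    lo, hi = _band_limits(M, N, band_halfwidth)

    if mode == "greedy":
        return _greedy_walk(d, lo, hi, band_halfwidth)
    if mode != "optimal":
        raise ValueError(f"unknown mode {mode!r}")

    C = np.full((M, N), np.inf)
    for n in range(N):
        a, b = lo[n], hi[n]
        col = d[a : b + 1, n]
        if n == 0:
            acc = np.cumsum(col) if a == 0 else np.full(col.shape, np.inf)
            C[a : b + 1, 0] = acc
            continue
        pa, pb = lo[n - 1], hi[n - 1]
        for m in range(a, b + 1):
            best = np.inf
            if pa <= m <= pb:  # horizontal (m, n-1)
                best = C[m, n - 1]
            if pa <= m - 1 <= pb:  # diagonal (m-1, n-1)
                best = min(best, C[m - 1, n - 1])
            if m - 1 >= a:  # vertical (m-1, n)
                best = min(best, C[m - 1, n])
            C[m, n] = d[m, n] + best
    if not np.isfinite(C[M - 1, N - 1]):
        raise DTWBandError(
            f"band_halfwidth {band_halfwidth} disconnects the {M} x {N} matrix"
        )

    # backtrack; tie preference: diagonal, vertical, horizontal
    path = [(M - 1, N - 1)]
    m, n = M - 1, N - 1
    while (m, n) != (0, 0):
        cands = []  # (cost, tie rank, cell); rank: diagonal < vertical < horizontal
        if m > 0 and n > 0 and np.isfinite(C[m - 1, n - 1]):
            cands.append((C[m - 1, n - 1], 0, (m - 1, n - 1)))
        if m > 0 and np.isfinite(C[m - 1, n]):
            cands.append((C[m - 1, n], 1, (m - 1, n)))
        if n > 0 and np.isfinite(C[m, n - 1]):
            cands.append((C[m, n - 1], 2, (m, n - 1)))
        _, _, (m, n) = min(cands, key=lambda c: (c[0], c[1]))
        path.append((m, n))
    path.reverse()
    return WarpResult(
        distance=float(C[M - 1, N - 1]),
        path=tuple(path),
        M=M,
        N=N,
        band_halfwidth=band_halfwidth,
        mode="optimal",
    )


def _greedy_walk(d: np.ndarray, lo, hi, band) -> WarpResult:
    M, N = d.shape
    m, n = 0, 0
    acc = d[0, 0]
    path = [(0, 0)]
    while (m, n) != (M - 1, N - 1):
        cands = []  # (local cost, tie rank, cell); rank: diagonal < vertical < horizontal
        if m + 1 <= M - 1 and n + 1 <= N - 1 and lo[n + 1] <= m + 1 <= hi[n + 1]:
            cands.append((d[m + 1, n + 1], 0, (m + 1, n + 1)))
        if m + 1 <= M - 1 and lo[n] <= m + 1 <= hi[n]:
            cands.append((d[m + 1, n], 1, (m + 1, n)))
        if n + 1 <= N - 1 and lo[n + 1] <= m <= hi[n + 1]:
            cands.append((d[m, n + 1], 2, (m, n + 1)))
        if not cands:
            raise DTWBandError(f"greedy walk stuck at ({m}, {n}) under band {band}")
        _, _, (m, n) = min(cands, key=lambda c: (c[0], c[1]))
        acc += d[m, n]
        path.append((m, n))
    return WarpResult(
        distance=float(acc), path=tuple(path), M=M, N=N,
        band_halfwidth=band, mode="greedy",
    )


def batch_dtw_distance(
    templates: np.ndarray,
    sequence_channel,
    band_halfwidth: Optional[int] = DEFAULT_BAND,
) -> np.ndarray:
    """Optimal banded DTW distances from one channel to a stack of templates.

    ``templates`` is ``(K, L)``; the sequence channel must have the same
    length ``L`` (the classifier always compares normalized 101-sample
    signals). Runs the dynamic programme along anti-diagonals, vectorized
    over the K templates, and returns the ``(K,)`` distances. Agrees with
    :func:`dtw_distance` (mode ``optimal``) to machine precision.
    """
    T = np.asarray(templates, dtype=float)
    s = _check_vector(sequence_channel, "sequence_channel")
    if T.ndim != 2 or T.shape[1] != s.size:
        raise ValueError(
            f"templates must be (K, {s.size}); got {T.shape}"
        )
    L = s.size
    _validate_band(L, L, band_halfwidth)
    band = L if band_halfwidth is None else band_halfwidth
    K = T.shape[0]
    INF = np.inf
    # value for row m of a diagonal is stored at column m+1 (column 0 = sentinel)
    prev2 = np.full((K, L + 1), INF)
    prev1 = np.full((K, L + 1), INF)
    cur = np.full((K, L + 1), INF)
    for k in range(2 * L - 1):
        m_lo = max(0, k - L + 1, -((band - k) // 2))  # ceil((k-band)/2)
        m_hi = min(L - 1, k, (k + band) // 2)
        cur[:] = INF
        if m_lo <= m_hi:
            ms = np.arange(m_lo, m_hi + 1)
            ns = k - ms
            d = np.abs(T[:, ms] - s[ns][None, :])
            if k == 0:
                cur[:, 1] = d[:, 0]
            else:
                best = np.minimum(prev1[:, ms], prev1[:, ms + 1])  # (m-1,n), (m,n-1)
                np.minimum(best, prev2[:, ms], out=best)  # (m-1,n-1)
                cur[:, ms + 1] = d + best
        prev2, prev1, cur = prev1, cur, prev2
    out = prev1[:, L]
    if not np.all(np.isfinite(out)):
        raise DTWBandError(f"band_halfwidth {band_halfwidth} disconnects the DP")
    return out.copy()


def brute_force_dtw(template_channel, sequence_channel) -> WarpResult:
    """Exhaustive-enumeration DTW oracle for tiny inputs.

    Enumerates every monotone path from the first to the last cell using
    the moves (+1,0), (0,+1), (+1,+1) and returns the minimum accumulated
    cost. Exponential in the input lengths, hence restricted to
    channels of length <= 8; used as an independent check of the dynamic
    programme.
    """
    t = _check_vector(template_channel, "template_channel")
    s = _check_vector(sequence_channel, "sequence_channel")
    if t.size > 8 or s.size > 8:
        raise ValueError("brute_force_dtw accepts channels of length <= 8 only")
    d = np.abs(t[:, None] - s[None, :])
    M, N = d.shape
    best = {"cost": np.inf, "path": None}

    def walk(m: int, n: int, acc: float, path: list) -> None:
        if (m, n) == (M - 1, N - 1):
            if acc < best["cost"]:
                best["cost"] = acc
                best["path"] = tuple(path)
            return
        for dm, dn in ((1, 1), (1, 0), (0, 1)):
            mm, nn = m + dm, n + dn
            if mm < M and nn < N:
                path.append((mm, nn))
                walk(mm, nn, acc + d[mm, nn], path)
                path.pop()

    walk(0, 0, float(d[0, 0]), [(0, 0)])
    return WarpResult(
        distance=float(best["cost"]), path=best["path"], M=M, N=N,
        band_halfwidth=None, mode="brute_force",
    )


def max_warp_fraction(band_halfwidth: int, seq_len: int) -> float:
    """Maximum warp, as a percentage of the signal length, a band permits.

    For the operating point used here (band 50, 101-sample signals) this
    is 49.5%.
    """
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    if band_halfwidth < 0:
        raise ValueError("band_halfwidth must be >= 0")
    return 100.0 * band_halfwidth / seq_len
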