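"""Agreement between nasalance trajectories from non-synchronous recordings.

Two devices recording the same utterance at different moments (and
possibly different speaking rates) produce trajectories that cannot be
compared sample-by-sample.  Two statistics quantify their
correspondence:

* ``r_raw`` — the maximum mean-centered normalized cross-correlation
  over integer-hop lags within a +/-500 ms window (a rigid shift can be
  absorbed, speaking-rate differences cannot);
* ``r_dtw`` — the Pearson correlation after dynamic time warping aligns
  the candidate onto the reference time axis, compensating non-linear
  temporal misalignment.

Invalid (gated) frames are dropped and the remaining frames compacted
before either statistic; gated frames carry no nasalance value, so
interpolating across them would fabricate data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .nasalance import NasalanceTrajectory

__all__ = [
    "TrajectoryPair",
    "AgreementResult",
    "raw_cross_correlation",
    "dtw_align",
    "dtw_correlation",
    "compare",
]

MIN_OVERLAP_FRAMES = 10


@dataclass(frozen=True)
class TrajectoryPair:
    """Reference (x) and candidate (y) trajectories on a common hop."""

    reference: NasalanceTrajectory
    candidate: NasalanceTrajectory

    def __post_init__(self) -> None:
        if not np.isclose(self.reference.hop_s, self.candidate.hop_s, rtol=1e-3):
            raise ValueError(
                f"hop mismatch: {self.reference.hop_s} vs {self.candidate.hop_s} s; "
                "recompute both trajectories with a common frame config"
            )

    @property
    def common_hop_s(self) -> float:
        return self.reference.hop_s


@dataclass(frozen=True)
class AgreementResult:
    r_raw: float
    best_lag_s: float
    r_dtw: float
    warp_path: np.ndarray = field(repr=False)
    aligned_candidate: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {"r_raw": self.r_raw, "best_lag_s": self.best_lag_s,
                "r_dtw": self.r_dtw, "n_path_steps": int(len(self.warp_path))}


def _compact_valid(traj: NasalanceTrajectory) -> np.ndarray:
    return traj.valid_values.astype(np.float64)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance segment: correlation undefined")
    return float(stats.pearsonr(a, b)[0])


def raw_cross_correlation(pair: TrajectoryPair,
                          max_lag_s: float = 0.5) -> tuple[float, float]:
    """Maximum normalized cross-correlation over lags within +/-max_lag_s.

    For each integer-hop lag the overlapping segments of the two
    compacted valid-frame sequences are mean-centered over the overlap
    and correlated; lags leaving fewer than 10 overlapping frames are
    skipped.  Ties in the maximum break toward smaller absolute lag.

    Returns ``(r_raw, best_lag_s)``; the lag is negative when the
    candidate is delayed relative to the reference.
    """
    x = _compact_valid(pair.reference)
    y = _compact_valid(pair.candidate)
    hop = pair.common_hop_s
    max_lag = int(np.floor(max_lag_s / hop + 1e-9))
    best_r, best_lag = -np.inf, 0
    # scan lags nearest zero first so ties keep the smaller |lag|
    for lag in sorted(range(-max_lag, max_lag + 1), key=abs):
        if lag >= 0:
            xs, ys = x[lag:], y[: y.size - lag if lag else y.size]
        else:
            xs, ys = x[: x.size + lag], y[-lag:]
        n = min(xs.size, ys.size)
        if n < MIN_OVERLAP_FRAMES:
            continue
        xs, ys = xs[:n], ys[:n]
        if np.std(xs) == 0 or np.std(ys) == 0:
            continue
        r = _pearson(xs, ys)
        if r > best_r + 1e-12:
            best_r, best_lag = r, lag
    if not np.isfinite(best_r):
        raise ValueError("too few overlapping valid frames at every lag")
    return best_r, best_lag * hop


def _dtw_path(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Classic DTW: absolute-difference cost, steps {(1,0),(0,1),(1,1)},
    full boundary conditions.  Returns the optimal path and its cost."""
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("empty trajectory after validity masking")
    cost = np.abs(x[:, None] - y[None, :])
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        row = cost[i - 1]
        prev, cur = acc[i - 1], acc[i]
        cur[1:] = row  # local cost; cumulative filled below
        for j in range(1, m + 1):
            cur[j] += min(prev[j], cur[j - 1], prev[j - 1])
    path = []
    i, j = n, m
    while i > 0 or j > 0:
        path.append((i - 1, j - 1))
        if i == 1 and j == 1:
            break
        moves = []
        if i > 1 and j > 1:
            moves.append((acc[i - 1, j - 1], i - 1, j - 1))
        if i > 1:
            moves.append((acc[i - 1, j], i - 1, j))
        if j > 1:
            moves.append((acc[i, j - 1], i, j - 1))
        _, i, j = min(moves)
    path.reverse()
    return np.asarray(path, dtype=np.intp), float(acc[n, m])


def dtw_align(pair: TrajectoryPair) -> tuple[np.ndarray, np.ndarray]:
    """Warp the candidate onto the reference axis by dynamic time warping.

    Candidate frames matched to the same reference frame are averaged,
    yielding one aligned value per valid reference frame.  Returns
    ``(warp_path, aligned_candidate)``; the path is a monotone sequence
    of (reference_index, candidate_index) pairs from (0, 0) to the ends.
    """
    x = _compact_valid(pair.reference)
    y = _compact_valid(pair.candidate)
    if x.size < 2 or y.size < 2:
        raise ValueError("degenerate trajectory: need at least two valid frames")
    path, _ = _dtw_path(x, y)
    aligned = np.zeros(x.size)
    counts = np.zeros(x.size)
    np.add.at(aligned, path[:, 0], y[path[:, 1]])
    np.add.at(counts, path[:, 0], 1)
    aligned /= counts  # full boundary DTW touches every reference index
    return path, aligned


def dtw_correlation(pair: TrajectoryPair) -> float:
    """Pearson correlation between the reference and the DTW-aligned candidate."""
    x = _compact_valid(pair.reference)
    _, aligned = dtw_align(pair)
    return _pearson(x, aligned)


def compare(reference: NasalanceTrajectory, candidate: NasalanceTrajectory,
            max_lag_s: float = 0.5) -> AgreementResult:
    """Full agreement analysis: raw lagged correlation plus DTW-aligned."""
    pair = TrajectoryPair(reference=reference, candidate=candidate)
    r_raw, best_lag = raw_cross_correlation(pair, max_lag_s=max_lag_s)
    path, aligned = dtw_align(pair)
    r_dtw = _pearson(_compact_valid(pair.reference), aligned)
    return AgreementResult(r_raw=r_raw, best_lag_s=best_lag, r_dtw=r_dtw,
                           warp_path=path, aligned_candidate=aligned)
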