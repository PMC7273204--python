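"""The four alignment engines: DTW, derivative DTW, shape DTW, and EventDTW.

All engines share one dynamic program over a pointwise cost matrix with the
symmetric step set {(1,1), (1,0), (0,1)}, boundary and monotonicity
constraints, and a fixed tie-break (diagonal first, then the
reference-advancing step).  They differ only in the cost matrix:

* DTW        — absolute amplitude difference |v_R - v_Q|;
* dDTW       — the same on estimated first derivatives (Keogh estimator);
* sDTW       — Euclidean distance between local-subsequence descriptors;
* EventDTW   — Euclidean distance between 3-vectors (v, I_up, I_down),
  where the I channels carry *event information*: a quantity propagated
  exponentially along selected high-elevation monotone slopes ("events"),
  equal to 1 at the event start point, 0.1 at its end point, and 0 off
  all events.

EventDTW's event machinery: maximal strictly-monotone runs are detected as
up/down slopes; the top fraction (default 20%) by elevation — observation
count times amplitude range — become the reference's key slopes; each
companion slope is matched to the nearest same-direction key slope by start
timestamp (unmatched slopes are dropped, each key slope accepts at most one
companion slope); matched slopes become events whose start point is the
observation of maximum amplitude and whose end point is the observation of
minimum amplitude, so an upslope propagates information backward in time
from its peak.  When no events survive, the 3-vector distance collapses to
|v_R - v_Q| and EventDTW returns exactly the DTW path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .signal_core import ParameterError, Signal, SignalError

__all__ = [
    "WarpPath",
    "Slope",
    "Event",
    "InfoVector",
    "dtw_align",
    "derivative_dtw_align",
    "shape_dtw_align",
    "detect_slopes",
    "select_key_slopes",
    "match_events",
    "propagate_event_info",
    "event_dtw_align",
    "keogh_derivative",
    "info_matrix",
]

LN_TENTH = math.log(0.1)


@dataclass(frozen=True)
class WarpPath:
    """A warping path: ordered (r_index, q_index) links between two signals.

    Satisfies boundary ((0,0) to (n_r-1, n_q-1)), monotonicity, and
    continuity (each step advances one index in at least one signal).
    """

    links: np.ndarray
    n_r: int
    n_q: int
    cost: float = float("nan")

    def __post_init__(self) -> None:
        links = np.asarray(self.links, dtype=int)
        object.__setattr__(self, "links", links)
        if links.ndim != 2 or links.shape[1] != 2 or len(links) == 0:
            raise SignalError("links must be a non-empty (W, 2) array")

    def validate(self) -> None:
        """Raise if boundary/monotonicity/continuity constraints are broken."""
        links = self.links
        if tuple(links[0]) != (0, 0):
            raise SignalError("path must start at (0, 0)")
        if tuple(links[-1]) != (self.n_r - 1, self.n_q - 1):
            raise SignalError("path must end at (n_r-1, n_q-1)")
        steps = np.diff(links, axis=0)
        if not np.isin(steps, (0, 1)).all() or not (steps.sum(axis=1) >= 1).all():
            raise SignalError("path steps must be (1,1), (1,0) or (0,1)")

    def __len__(self) -> int:
        return len(self.links)

    def per_q_counts(self) -> np.ndarray:
        """m_j: number of reference observations linked to each Q_j."""
        return np.bincount(self.links[:, 1], minlength=self.n_q)

    def per_r_counts(self) -> np.ndarray:
        """Number of companion observations linked to each R_i."""
        return np.bincount(self.links[:, 0], minlength=self.n_r)


class Slope(NamedTuple):
    """A maximal strictly monotone run of observations."""

    start_index: int
    end_index: int  # inclusive
    direction: str  # "up" or "down"
    start_time: float
    end_time: float
    start_value: float
    end_value: float

    @property
    def n_obs(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def elevation(self) -> float:
        """Importance score: observation count times amplitude range."""
        return self.n_obs * abs(self.end_value - self.start_value)

    @property
    def span(self) -> float:
        """Temporal extent of the slope."""
        return self.end_time - self.start_time


class Event(NamedTuple):
    """An information-propagation anchor derived from a matched slope.

    The start point (t_s, v_s) is the slope observation of maximum
    amplitude and the end point (t_e, v_e) the observation of minimum
    amplitude, so for an upslope t_s > t_e: information flows backward in
    time from the peak.  Never assume t_s < t_e.
    """

    t_s: float
    t_e: float
    v_s: float
    v_e: float
    direction: str

    @classmethod
    def from_slope(cls, slope: Slope) -> "Event":
        if slope.direction == "up":
            return cls(slope.end_time, slope.start_time,
                       slope.end_value, slope.start_value, "up")
        return cls(slope.start_time, slope.end_time,
                   slope.start_value, slope.end_value, "down")


class InfoVector(NamedTuple):
    """Per-observation (amplitude, upslope info, downslope info) triple."""

    v: float
    i_up: float
    i_down: float


# ---------------------------------------------------------------------------
# shared dynamic program
# ---------------------------------------------------------------------------

def _dtw_core(cost: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal-path dynamic program over a pointwise cost matrix.

    Returns the traceback links and the total path cost.  Ties are broken
    preferring the diagonal step, then the reference-advancing step.
    """
    n, m = cost.shape
    acc = np.empty((n, m))
    acc[0, 0] = cost[0, 0]
    acc[0, 1:] = cost[0, 1:].cumsum() + cost[0, 0]
    acc[1:, 0] = cost[1:, 0].cumsum() + cost[0, 0]
    for i in range(1, n):
        row, prev = acc[i], acc[i - 1]
        ci = cost[i]
        for j in range(1, m):
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if row[j - 1] < best:
                best = row[j - 1]
            row[j] = ci[j] + best
    # traceback
    i, j = n - 1, m - 1
    rev = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, up, left = acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]
            if diag <= up and diag <= left:
                i, j = i - 1, j - 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
        rev.append((i, j))
    links = np.array(rev[::-1], dtype=int)
    return links, float(acc[n - 1, m - 1])


def _align(cost: np.ndarray) -> WarpPath:
    links, total = _dtw_core(cost)
    path = WarpPath(links, n_r=cost.shape[0], n_q=cost.shape[1], cost=total)
    path.validate()
    return path


# ---------------------------------------------------------------------------
# baseline engines
# ---------------------------------------------------------------------------

def dtw_align(R: Signal, Q: Signal) -> WarpPath:
    """Classic DTW on amplitudes with |v_R - v_Q| pointwise cost."""
    cost = np.abs(R.values[:, None] - Q.values[None, :])
    return _align(cost)


def keogh_derivative(values: np.ndarray) -> np.ndarray:
    """First-derivative estimate d_i = ((v_i - v_{i-1}) + (v_{i+1} - v_{i-1})/2) / 2.

    Interior points only; endpoints copy their neighbors.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise SignalError("derivative estimation needs at least 3 observations")
    d = np.empty_like(v)
    d[1:-1] = ((v[1:-1] - v[:-2]) + (v[2:] - v[:-2]) / 2.0) / 2.0
    d[0], d[-1] = d[1], d[-2]
    return d


def derivative_dtw_align(R: Signal, Q: Signal) -> WarpPath:
    """Derivative DTW: classic DTW on estimated first derivatives."""
    cost = np.abs(keogh_derivative(R.values)[:, None] - keogh_derivative(Q.values)[None, :])
    return _align(cost)


def _shape_descriptors(values: np.ndarray, window_len: int) -> np.ndarray:
    half = window_len // 2
    padded = np.pad(values, half, mode="edge")
    return np.lib.stride_tricks.sliding_window_view(padded, window_len)


def shape_dtw_align(R: Signal, Q: Signal, window_len: int = 5) -> WarpPath:
    """Shape DTW: DTW over raw-subsequence descriptors of each observation.

    The descriptor of observation i is the length-``window_len`` amplitude
    subsequence centered on i (edge-padded); pointwise cost is the
    Euclidean distance between descriptors.
    """
    if window_len < 1 or window_len % 2 == 0:
        raise ParameterError(f"window_len must be odd and >= 1, got {window_len}")
    dr = _shape_descriptors(R.values, window_len)
    dq = _shape_descriptors(Q.values, window_len)
    return _align(cdist(dr, dq, metric="euclidean"))


# ---------------------------------------------------------------------------
# EventDTW machinery
# ---------------------------------------------------------------------------

def detect_slopes(signal: Signal) -> list[Slope]:
    """Maximal strictly monotone runs, labeled up/down.

    Plateaus (equal consecutive values) terminate runs and belong to no
    slope; a run needs at least 2 observations.  Adjacent up/down runs
    share their turning point.  A constant signal yields no slopes.
    """
    v, t = signal.values, signal.timestamps
    sign = np.sign(np.diff(v))
    slopes: list[Slope] = []
    start = 0
    for k in range(1, len(sign) + 1):
        if k == len(sign) or sign[k] != sign[start]:
            if sign[start] != 0:
                direction = "up" if sign[start] > 0 else "down"
                slopes.append(Slope(start, k, direction,
                                    t[start], t[k], v[start], v[k]))
            start = k
    return slopes


def select_key_slopes(slopes: Sequence[Slope], frac: float = 0.2) -> list[Slope]:
    """The ceil(frac * N) slopes of highest elevation (both directions pooled).

    Ties broken toward the earlier start index.  frac defaults to the 20%
    event-frequency setting; limiting events to prominent slopes keeps
    noise from being promoted to alignment anchors.
    """
    if not 0.0 < frac <= 1.0:
        raise ParameterError(f"frac must lie in (0, 1], got {frac}")
    if not slopes:
        return []
    n_keep = math.ceil(frac * len(slopes))
    ranked = sorted(slopes, key=lambda s: (-s.elevation, s.start_index))
    return sorted(ranked[:n_keep], key=lambda s: s.start_index)


def match_events(
    key_slopes_r: Sequence[Slope],
    slopes_q: Sequence[Slope],
    proximity_threshold: float | None = None,
) -> list[tuple[Slope, Slope]]:
    """Pair companion slopes with reference key slopes by timestamp proximity.

    Each Q slope seeks the same-direction key slope with the nearest start
    timestamp; pairs farther apart than the threshold (default: half the
    median key-slope span) are excluded, and each key slope accepts at most
    one Q slope (nearest wins, losers are excluded).  Returned pairs are
    ordered by the reference slope's start index.
    """
    if not key_slopes_r or not slopes_q:
        return []
    if proximity_threshold is None:
        spans = np.array([abs(s.span) for s in key_slopes_r])
        proximity_threshold = 0.5 * float(np.median(spans))
    candidates: list[tuple[float, int, int]] = []  # (distance, q_idx, r_idx)
    for qi, sq in enumerate(slopes_q):
        best_r, best_dist = -1, np.inf
        for ri, sr in enumerate(key_slopes_r):
            if sr.direction != sq.direction:
                continue
            dist = abs(sr.start_time - sq.start_time)
            if dist < best_dist:
                best_r, best_dist = ri, dist
        if best_r >= 0 and best_dist <= proximity_threshold:
            candidates.append((best_dist, qi, best_r))
    # one-to-one: nearest claimant per key slope wins, ties to earlier Q slope
    taken_r: set[int] = set()
    taken_q: set[int] = set()
    pairs: list[tuple[Slope, Slope]] = []
    for dist, qi, ri in sorted(candidates, key=lambda c: (c[0], c[1])):
        if ri in taken_r or qi in taken_q:
            continue
        taken_r.add(ri)
        taken_q.add(qi)
        pairs.append((key_slopes_r[ri], slopes_q[qi]))
    pairs.sort(key=lambda p: p[0].start_index)
    return pairs


def propagate_event_info(signal: Signal, events: Sequence[Event]) -> list[InfoVector]:
    """Spread event information exponentially along each event's slope.

    An observation at time t on an event's slope (between t_s and t_e in
    either time order, inclusive) carries

        I = exp(ln(0.1) * |t - t_s| / |t_e - t_s|),

    i.e. 1 at the start point decaying to 0.1 at the end point; 0 off all
    events.  The value lands in the up or down channel according to the
    event's direction; where same-direction events overlap, the larger
    information value wins, keeping I <= 1.
    """
    t = signal.timestamps
    info = np.zeros((len(t), 2))  # columns: up, down
    for ev in events:
        if ev.t_s == ev.t_e:
            raise ParameterError("degenerate event: t_s == t_e")
        lo, hi = min(ev.t_s, ev.t_e), max(ev.t_s, ev.t_e)
        on = (t >= lo) & (t <= hi)
        decay = np.exp(LN_TENTH * np.abs(t[on] - ev.t_s) / abs(ev.t_e - ev.t_s))
        col = 0 if ev.direction == "up" else 1
        info[on, col] = np.maximum(info[on, col], decay)
    return [InfoVector(v, iu, idn) for v, (iu, idn) in zip(signal.values, info)]


def info_matrix(signal: Signal, events: Sequence[Event]) -> np.ndarray:
    """(L, 3) array of (v, I_up, I_down) vectors."""
    return np.array(propagate_event_info(signal, events), dtype=float)


def event_dtw_align(
    R: Signal,
    Q: Signal,
    frac: float = 0.2,
    proximity_threshold: float | None = None,
    channel_weights: Sequence[float] | None = None,
) -> WarpPath:
    """EventDTW: DTW over (amplitude, event-information) 3-vectors.

    Detects slopes in both signals, keeps the top ``frac`` of the
    reference's slopes by elevation as key slopes, matches companion slopes
    to them by timestamp proximity, propagates event information along each
    matched slope, and aligns the resulting 3-vector sequences under the
    Euclidean distance.  With no surviving events the path is identical to
    plain DTW on amplitudes.

    ``channel_weights`` optionally scales the (v, I_up, I_down) channels;
    the default is unweighted, assuming amplitudes were standardized.
    """
    pairs = match_events(
        select_key_slopes(detect_slopes(R), frac),
        detect_slopes(Q),
        proximity_threshold,
    )
    if not pairs and channel_weights is None:
        # all info channels are zero: the 3-D distance reduces to |dv|
        return dtw_align(R, Q)
    events_r = [Event.from_slope(sr) for sr, _ in pairs]
    events_q = [Event.from_slope(sq) for _, sq in pairs]
    vr = info_matrix(R, events_r)
    vq = info_matrix(Q, events_q)
    if channel_weights is not None:
        w = np.asarray(channel_weights, dtype=float)
        if w.shape != (3,) or (w < 0).any():
            raise ParameterError("channel_weights must be 3 non-negative numbers")
        vr, vq = vr * w, vq * w
    return _align(cdist(vr, vq, metric="euclidean"))
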