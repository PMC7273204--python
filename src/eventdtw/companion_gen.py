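"""Synthetic warped companion signals with known ground-truth alignment.

To benchmark alignment algorithms one needs a pair of signals whose optimal
alignment is known.  Starting from a uniform reference signal R this module
builds:

* an intermediate signal R' by warping R's time axis with a localized,
  sigmoid-derivative-shaped horizontal shift and distorting its amplitude
  with a Gaussian bump around an anchor point, and
* a companion signal Q by down-sampling: Q takes every d-th reference
  timestamp and linearly interpolates R' (as a function of its warped
  timestamps) at those times.

Because Q was constructed from R, each companion observation Q_j is
optimally aligned with a group G_j of d consecutive reference observations.
The grouping is recovered by minimizing the summed Euclidean distance in
the (t, v) plane between Q_j and windows of d consecutive R' observations,
subject to the groups being ordered and non-overlapping; R' indices map
one-to-one onto R indices.

The horizontal shift uses the derivative of the logistic sigmoid,

    s(t) = exp(-|t - t_A| / w) / (1 + exp(-|t - t_A| / w))^2,

which peaks at 0.25 at the anchor t_A and decays smoothly in both
directions; ``shift_scale`` multiplies it.  The vertical distortion inside
the window |t - t_A| < w is, in the default ``as-printed`` variant,
``exp(-((t - t_A)/w)^2) - 1`` (a downward dip, discontinuous at the window
edge); the opt-in ``positive-gaussian`` variant adds the bump without the
-1 offset, which is continuous at the edge.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .signal_core import ParameterError, Signal, SignalError

__all__ = [
    "WarpSpec",
    "OptimalAlignment",
    "sigmoid_shift",
    "amplitude_bump",
    "generate_warped",
    "downsample_to_companion",
    "optimal_alignment",
    "generate_companion_pair",
]

BUMP_VARIANTS = ("as-printed", "positive-gaussian", "none")


@dataclass(frozen=True)
class WarpSpec:
    """Parameters of the synthetic warp.

    Attributes
    ----------
    anchor_time : float or None
        Warp center t_A in timestamp units; default (None) means L/2.
    window : float or None
        Warp window width w in timestamp units; default (None) means 0.1*L.
        Must satisfy 0 < w < 0.5*L so the warp stays inside the signal.
    shift_scale : float
        Multiplier on the sigmoid-derivative shift (whose raw maximum is
        0.25 time units).  1.0 reproduces the formula verbatim; the
        benchmark preset uses a larger value so the warp is clearly
        visible at typical signal lengths.
    bump_variant : str
        "as-printed" (downward dip, default), "positive-gaussian", or
        "none" (no amplitude distortion; useful for identity pipelines).
    """

    anchor_time: float | None = None
    window: float | None = None
    shift_scale: float = 1.0
    bump_variant: str = "as-printed"

    def resolve(self, L: int) -> tuple[float, float]:
        """Return concrete (t_A, w) for a signal of length L, validated."""
        t_a = L / 2.0 if self.anchor_time is None else float(self.anchor_time)
        w = 0.1 * L if self.window is None else float(self.window)
        if not 0.0 < w < 0.5 * L:
            raise ParameterError(f"window must lie in (0, {0.5 * L}), got {w}")
        if not 0.0 < t_a < L:
            raise ParameterError(f"anchor_time must lie in (0, {L}), got {t_a}")
        if self.bump_variant not in BUMP_VARIANTS:
            raise ParameterError(
                f"unknown bump_variant {self.bump_variant!r}; choose from {BUMP_VARIANTS}"
            )
        return t_a, w


@dataclass(frozen=True)
class OptimalAlignment:
    """Ground-truth grouping of reference observations per companion point.

    ``group_start[j]`` is the first R index of group G_j; each G_j consists
    of exactly ``d`` consecutive R indices.  Groups are ordered and
    disjoint.
    """

    group_start: np.ndarray
    d: int
    n_r: int

    def __post_init__(self) -> None:
        gs = np.asarray(self.group_start, dtype=int)
        object.__setattr__(self, "group_start", gs)
        if self.d < 1:
            raise ParameterError("d must be >= 1")
        if len(gs) == 0:
            raise SignalError("alignment needs at least one group")
        if (np.diff(gs) < self.d).any():
            raise SignalError("groups must be ordered and non-overlapping")
        if gs[0] < 0 or gs[-1] + self.d > self.n_r:
            raise SignalError("groups fall outside the reference signal")

    @property
    def n_q(self) -> int:
        return len(self.group_start)

    @property
    def groups(self) -> list[np.ndarray]:
        """G_j as explicit index arrays."""
        return [np.arange(s, s + self.d) for s in self.group_start]

    def r_to_group(self) -> np.ndarray:
        """Map each R index to its optimal group index j.

        R observations not claimed by any group (possible when
        ``n_r > n_q * d``) are assigned to the nearest group.
        """
        j_of_i = np.full(self.n_r, -1, dtype=int)
        for j, s in enumerate(self.group_start):
            j_of_i[s : s + self.d] = j
        unassigned = np.flatnonzero(j_of_i < 0)
        if len(unassigned):
            assigned = np.flatnonzero(j_of_i >= 0)
            nearest = assigned[
                np.argmin(np.abs(unassigned[:, None] - assigned[None, :]), axis=1)
            ]
            j_of_i[unassigned] = j_of_i[nearest]
        return j_of_i


def sigmoid_shift(t, t_a: float, w: float):
    """Horizontal shift magnitude s(t): the derivative of the sigmoid.

    Peaks at 0.25 when t == t_a, decays symmetrically, and is essentially
    zero a few window widths away.  Vectorized over ``t``.
    """
    if w <= 0:
        raise ParameterError(f"window w must be positive, got {w}")
    u = np.exp(-np.abs(np.asarray(t, dtype=float) - t_a) / w)
    return u / (1.0 + u) ** 2


def amplitude_bump(v, t, t_a: float, w: float, variant: str = "as-printed"):
    """Vertical amplitude distortion applied inside |t - t_a| < w.

    Vectorized over ``v`` and ``t`` (broadcast together).
    """
    if w <= 0:
        raise ParameterError(f"window w must be positive, got {w}")
    if variant not in BUMP_VARIANTS:
        raise ParameterError(f"unknown bump variant {variant!r}")
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if variant == "none":
        return v + np.zeros_like(t)
    x = (t - t_a) / w
    bump = np.exp(-(x**2))
    if variant == "as-printed":
        bump = bump - 1.0
    inside = np.abs(t - t_a) < w
    return np.where(inside, v + bump, v)


def generate_warped(R: Signal, spec: WarpSpec = WarpSpec()) -> Signal:
    """Warp a uniform reference signal R into the intermediate signal R'.

    Timestamps become ``i - shift_scale * s_i`` and amplitudes receive the
    Gaussian bump.  The warped timestamps must remain strictly increasing;
    a shift_scale strong enough to fold time over raises an error naming
    the first violating index.
    """
    if not R.uniform:
        raise SignalError("generate_warped requires a uniform reference signal")
    L = len(R)
    t_a, w = spec.resolve(L)
    s = sigmoid_shift(R.timestamps, t_a, w)
    t_warp = R.timestamps - spec.shift_scale * s
    dt = np.diff(t_warp)
    if (dt <= 0).any():
        bad = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise ParameterError(
            f"shift_scale {spec.shift_scale} destroys timestamp monotonicity "
            f"at index {bad}; reduce it or widen the window"
        )
    v_warp = amplitude_bump(R.values, R.timestamps, t_a, w, spec.bump_variant)
    return Signal(t_warp, v_warp, uniform=False)


def downsample_to_companion(R: Signal, R_warp: Signal, d: int) -> Signal:
    """Down-sample the warped signal onto every d-th reference timestamp.

    The companion keeps the time base of R: its j-th timestamp is that of
    the (j*d)-th reference observation in 1-based counting (0-based index
    ``j*d - 1``), giving ``L_Q = floor(L_R / d)`` observations.  Amplitudes
    are linear interpolations of R' as a function of its warped timestamps,
    clamped to the nearest R' value outside R's warped time range.
    """
    L = len(R)
    if not R.uniform:
        raise SignalError("downsample_to_companion requires a uniform reference")
    if d < 1 or d >= L:
        raise ParameterError(f"down-sampling ratio d must be in [1, {L - 1}], got {d}")
    n_q = L // d
    idx = np.arange(1, n_q + 1) * d - 1
    t_q = R.timestamps[idx]
    v_q = np.interp(t_q, R_warp.timestamps, R_warp.values)
    if n_q < 2:
        raise ParameterError(f"d={d} leaves fewer than 2 companion observations")
    return Signal(t_q, v_q, uniform=(d == 1))


def _window_costs(R_warp: Signal, t_q: float, v_q: float, d: int) -> np.ndarray:
    """Summed (t, v)-plane Euclidean distance from Q_j to every d-window of R'."""
    dist = np.hypot(R_warp.timestamps - t_q, R_warp.values - v_q)
    csum = np.concatenate([[0.0], np.cumsum(dist)])
    return csum[d:] - csum[:-d]


def optimal_alignment(R: Signal, R_warp: Signal, Q: Signal, d: int) -> OptimalAlignment:
    """Recover the ground-truth grouping G_j for a generated companion pair.

    For each Q_j the group is the window of d consecutive R' observations
    minimizing the summed Euclidean distance in the (t, v) plane, under the
    constraint that groups are ordered and non-overlapping.  The joint
    minimizer over all groups is found exactly by dynamic programming, with
    ties broken toward the smaller start index; windows in R' index the
    same positions in R.

    Raises
    ------
    SignalError
        If no ordered non-overlapping grouping fits (``n_q * d > L_R``).
    """
    L, n_q = len(R), len(Q)
    if n_q * d > L:
        raise SignalError(
            f"alignment infeasible: {n_q} groups of {d} exceed reference length {L}"
        )
    n_starts = L - d + 1
    costs = np.empty((n_q, n_starts))
    for j in range(n_q):
        costs[j] = _window_costs(R_warp, Q.timestamps[j], Q.values[j], d)

    # best[j, s]: minimal total cost of groups 0..j with group j starting at s.
    INF = np.inf
    best = np.full((n_q, n_starts), INF)
    best[0] = costs[0]
    for j in range(1, n_q):
        # prefix running-minimum of the previous row, shifted by d
        prev = best[j - 1]
        run = np.minimum.accumulate(prev)
        best[j, d:] = costs[j, d:] + run[:-d]

    starts = np.empty(n_q, dtype=int)
    # smallest final start achieving the optimum, then walk back greedily
    # to the earliest feasible optimal predecessor (ties -> smaller index).
    starts[-1] = int(np.argmin(best[-1]))
    for j in range(n_q - 2, -1, -1):
        limit = starts[j + 1] - d
        prev = best[j, : limit + 1]
        starts[j] = int(np.argmin(prev))
    return OptimalAlignment(starts, d=d, n_r=L)


def generate_companion_pair(
    R: Signal, d: int, spec: WarpSpec = WarpSpec()
) -> tuple[Signal, Signal, OptimalAlignment]:
    """Full pipeline: warp R, down-sample to Q, recover the optimal alignment."""
    R_warp = generate_warped(R, spec)
    Q = downsample_to_companion(R, R_warp, d)
    opt = optimal_alignment(R, R_warp, Q, d)
    return R_warp, Q, opt
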