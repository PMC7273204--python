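"""Alignment-quality metrics: error rate, singularity score, path length.

Error rate (ER) measures how far an observed alignment is from the known
optimal one.  Each path link (i, k) is charged |k - j| index units, where j
is the optimal group of reference observation i; the total is normalized by
the misalignment of the worst admissible path — the one linking every
companion observation to the first reference observation and every
reference observation to the last companion observation — whose total is

    (1/2) * L_Q * (L_Q - 1) * (1 + d)  -  (L_Q - 1).

ER is 0 exactly at the optimal alignment and 1 exactly at that worst case.

Singularity score (SS) measures the severity of the singularity problem —
uneven dispersion of per-companion link counts m_j around the ideal d:

    SS = sum_j (m_j - d)^2 / L_Q.

The problem is directional: M > 1 companion (low-frequency) observations
collapsing onto a single reference observation is worse than the reverse,
so each such companion observation contributes with m_j replaced by 1/M.

The warping-path length W (link count) is kept as the classical comparator
metric; two paths of equal W can have very different SS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .companion_gen import OptimalAlignment
from .dtw_engines import WarpPath
from .signal_core import ParameterError, SignalError

__all__ = [
    "MetricReport",
    "error_rate",
    "singularity_score",
    "warping_path_length",
    "worst_case_path",
    "path_from_alignment",
    "score_alignment",
]


@dataclass(frozen=True)
class MetricReport:
    """Scores of one observed alignment against one companion pair."""

    algorithm: str
    d: int
    error_rate: float
    singularity_score: float
    path_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError(f"error_rate out of [0, 1]: {self.error_rate}")
        if self.singularity_score < 0.0:
            raise ValueError(f"negative singularity_score: {self.singularity_score}")


def _er_denominator(n_q: int, d: int) -> float:
    return 0.5 * n_q * (n_q - 1) * (1 + d) - (n_q - 1)


def error_rate(
    observed: WarpPath,
    optimal: OptimalAlignment,
    d: int | None = None,
    n_q: int | None = None,
) -> float:
    """Normalized total index misalignment of an observed path.

    Sums |k - j| over every path link, where k is the link's companion
    index and j the optimal group of its reference index, and divides by
    the worst-case total.  ``d`` and ``n_q``, if given, are checked against
    the optimal alignment.

    Raises if the path's index ranges disagree with the optimal alignment,
    or if the result leaves [0, 1] by more than numerical noise.
    """
    if d is not None and d != optimal.d:
        raise ParameterError(f"d={d} inconsistent with optimal alignment (d={optimal.d})")
    if n_q is not None and n_q != optimal.n_q:
        raise ParameterError(
            f"n_q={n_q} inconsistent with optimal alignment (n_q={optimal.n_q})"
        )
    if observed.n_r != optimal.n_r or observed.n_q != optimal.n_q:
        raise SignalError(
            f"path covers ({observed.n_r}, {observed.n_q}) but optimal alignment "
            f"covers ({optimal.n_r}, {optimal.n_q})"
        )
    if optimal.n_q < 2:
        raise SignalError("error rate needs at least 2 companion observations")
    observed.validate()
    j_of_i = optimal.r_to_group()
    numer = float(np.abs(observed.links[:, 1] - j_of_i[observed.links[:, 0]]).sum())
    er = numer / _er_denominator(optimal.n_q, optimal.d)
    if er > 1.0:
        if er > 1.0 + 1e-9:
            raise ValueError(f"error rate {er} exceeds 1: path/alignment mismatch")
        er = 1.0
    return er


def singularity_score(observed: WarpPath, d: int) -> float:
    """Variance-like dispersion of per-companion link counts around d.

    m_j is the number of reference observations linked to Q_j.  When M > 1
    companion observations are linked to one reference observation, each of
    them whose own link count is 1 contributes with m_j replaced by 1/M
    (the directional penalty: d >= 1, so m_j < 1 inflates the squared
    term).  Returns sum_j (m_j - d)^2 / L_Q.
    """
    if d < 1:
        raise ParameterError(f"d must be >= 1, got {d}")
    if observed.n_q < 1:
        raise SignalError("empty companion signal")
    m = observed.per_q_counts().astype(float)
    big_m = observed.per_r_counts()  # M per reference observation
    r_of_q = {}
    for i, k in observed.links:
        r_of_q.setdefault(int(k), []).append(int(i))
    adjusted = m.copy()
    for j in range(observed.n_q):
        partners = r_of_q.get(j, [])
        if len(partners) == 1 and big_m[partners[0]] > 1:
            adjusted[j] = 1.0 / big_m[partners[0]]
    return float(((adjusted - d) ** 2).sum() / observed.n_q)


def warping_path_length(observed: WarpPath) -> int:
    """W: the number of links in the path."""
    return len(observed)


def worst_case_path(n_r: int, n_q: int) -> WarpPath:
    """The degenerate admissible path with the most severe singularity.

    All companion observations link to the first reference observation,
    then all reference observations link to the last companion observation.
    Its error rate against any generated companion pair is exactly 1.
    """
    if n_r < 2 or n_q < 2:
        raise ParameterError("worst_case_path needs n_r, n_q >= 2")
    first_leg = [(0, j) for j in range(n_q)]
    second_leg = [(i, n_q - 1) for i in range(1, n_r)]
    path = WarpPath(np.array(first_leg + second_leg), n_r=n_r, n_q=n_q)
    path.validate()
    return path


def path_from_alignment(optimal: OptimalAlignment) -> WarpPath:
    """The observed path equivalent to the ground-truth alignment.

    Links every reference observation to its optimal group's companion
    observation; by construction its error rate is 0.
    """
    j_of_i = optimal.r_to_group()
    # enforce valid steps: group index may not jump by more than 1 per i
    links = [(i, int(j_of_i[i])) for i in range(optimal.n_r)]
    fixed: list[tuple[int, int]] = []
    for i, j in links:
        if fixed and j > fixed[-1][1] + 1:
            for jj in range(fixed[-1][1] + 1, j):
                fixed.append((i, jj))
        fixed.append((i, j))
    path = WarpPath(np.array(fixed), n_r=optimal.n_r, n_q=optimal.n_q)
    path.validate()
    return path


def score_alignment(
    observed: WarpPath, optimal: OptimalAlignment, algorithm: str = ""
) -> MetricReport:
    """Convenience: full metric report for one observed path."""
    return MetricReport(
        algorithm=algorithm,
        d=optimal.d,
        error_rate=error_rate(observed, optimal),
        singularity_score=singularity_score(observed, optimal.d),
        path_length=warping_path_length(observed),
    )
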