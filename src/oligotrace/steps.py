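"""Photobleaching step counting by piecewise-constant change-point fitting.

A bleaching trace is modeled as a staircase: constant plateaus separated by
abrupt downward steps, one per photobleaching event, ending at background
once every fluorophore has bleached.  Steps are found by greedy binary
segmentation: the trace is recursively split at the residual-sum-of-squares
minimizing point, and a split is kept only while it lowers a BIC-type cost
(N·log(RSS/N) penalized by the parameter count times log N).  A merge pass
then removes steps much smaller than the typical step, and an optional
monotone mode removes upward steps (bleaching is irreversible; upward
excursions are artifacts).

The number of accepted steps per spot feeds the step-count frequency table
from which oligomeric stoichiometry is inferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .traces import BleachTrace

__all__ = [
    "StepFitParams",
    "AcceptanceParams",
    "StepFit",
    "StepCountTable",
    "fit_steps",
    "accept_trace",
    "count_distribution",
]

MIN_TRACE_LENGTH = 10


@dataclass(frozen=True)
class StepFitParams:
    """Tunables of the change-point fit.

    ``penalty_scale`` multiplies the BIC parameter penalty; larger values
    make splitting more conservative.  ``merge_fraction`` is the fraction of
    the median absolute step below which a fitted step is merged away.
    ``monotone`` drops upward steps after fitting.
    """

    penalty_scale: float = 2.0
    merge_fraction: float = 0.5
    monotone: bool = False
    min_segment_length: int = 1


@dataclass(frozen=True)
class AcceptanceParams:
    """Quality gate for counted spots.

    ``k_max`` is the largest countable step number (4, the largest oligomer
    considered); ``max_step_ratio`` flags suspiciously large steps
    (coincident double bleaches) relative to the median step; a trace must
    end within ``end_tol_sd`` residual standard deviations of
    ``background`` (complete bleaching reached).
    """

    k_max: int = 4
    max_step_ratio: float = 2.5
    background: float = 0.0
    end_tol_sd: float = 2.0


@dataclass(frozen=True)
class StepFit:
    """Piecewise-constant fit of one bleaching trace.

    ``change_points`` are 0-based frame indices: a step occurs between frame
    ``cp - 1`` and frame ``cp``.  ``levels`` holds one plateau mean per
    segment (``n_steps + 1`` entries).
    """

    spot_id: int | str
    change_points: tuple[int, ...]
    levels: tuple[float, ...]
    n_steps: int
    residual_sd: float
    accepted: bool = False
    rejection_reason: str | None = None

    def __post_init__(self) -> None:
        if len(self.levels) != self.n_steps + 1:
            raise ValueError("levels must have n_steps + 1 entries")
        if len(self.change_points) != self.n_steps:
            raise ValueError("change_points must have n_steps entries")


@dataclass(frozen=True)
class StepCountTable:
    """Observed frequency of 1..k_max bleaching steps across accepted spots."""

    counts: dict[int, int]
    total_spots: int
    k_max: int = 4

    def __post_init__(self) -> None:
        if any(k < 1 or k > self.k_max for k in self.counts):
            raise ValueError("step counts must lie in 1..k_max")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if sum(self.counts.values()) != self.total_spots:
            raise ValueError("counts must sum to total_spots")

    def frequency(self, k: int) -> float:
        """Relative frequency of spots showing exactly ``k`` steps."""
        return self.counts.get(k, 0) / self.total_spots

    def as_array(self) -> np.ndarray:
        return np.array([self.counts.get(k, 0) for k in range(1, self.k_max + 1)])

    @classmethod
    def from_counts(cls, counts: dict[int, int], k_max: int = 4) -> "StepCountTable":
        counts = {int(k): int(v) for k, v in counts.items() if v}
        return cls(counts=counts, total_spots=sum(counts.values()),
                   k_max=max([k_max, *counts.keys()]))


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def _segment_rss(cs: np.ndarray, cs2: np.ndarray, a: int, b: int) -> float:
    n = b - a
    s = cs[b] - cs[a]
    return float(cs2[b] - cs2[a] - s * s / n)


def _best_split(cs: np.ndarray, cs2: np.ndarray, a: int, b: int, min_len: int):
    """Best single split of segment [a, b); returns (j, rss_after) or None."""
    if b - a < 2 * min_len:
        return None
    j = np.arange(a + min_len, b - min_len + 1)
    nl = j - a
    nr = b - j
    sl = cs[j] - cs[a]
    sr = cs[b] - cs[j]
    rss = (cs2[j] - cs2[a] - sl * sl / nl) + (cs2[b] - cs2[j] - sr * sr / nr)
    i = int(np.argmin(rss))
    return int(j[i]), float(rss[i])


def _binary_segmentation(values: np.ndarray, params: StepFitParams) -> list[int]:
    """Greedy best-first binary segmentation with a BIC stopping rule."""
    n = len(values)
    cs = np.concatenate([[0.0], np.cumsum(values)])
    cs2 = np.concatenate([[0.0], np.cumsum(values**2)])
    scale = float(np.ptp(values))
    var_floor = max((1e-9 * max(scale, 1.0)) ** 2, 1e-300)
    log_n = math.log(n)

    segments: list[tuple[int, int]] = [(0, n)]
    seg_rss = {(0, n): _segment_rss(cs, cs2, 0, n)}
    seg_split = {(0, n): _best_split(cs, cs2, 0, n, params.min_segment_length)}
    change_points: list[int] = []

    def cost(total_rss: float, n_cp: int) -> float:
        n_params = 2 * n_cp + 1  # one mean per segment plus the breakpoints
        return n * math.log(max(total_rss, n * var_floor) / n) + params.penalty_scale * n_params * log_n

    total_rss = seg_rss[(0, n)]
    current_cost = cost(total_rss, 0)
    while True:
        best = None
        for seg in segments:
            sp = seg_split[seg]
            if sp is None:
                continue
            gain = seg_rss[seg] - sp[1]
            if best is None or gain > best[0]:
                best = (gain, seg, sp[0])
        if best is None:
            break
        gain, seg, j = best
        new_cost = cost(total_rss - gain, len(change_points) + 1)
        if new_cost >= current_cost - 1e-12:
            break
        a, b = seg
        segments.remove(seg)
        for sub in ((a, j), (j, b)):
            segments.append(sub)
            seg_rss[sub] = _segment_rss(cs, cs2, sub[0], sub[1])
            seg_split[sub] = _best_split(cs, cs2, sub[0], sub[1], params.min_segment_length)
        change_points.append(j)
        total_rss -= gain
        current_cost = new_cost
    return sorted(change_points)


def _levels(values: np.ndarray, change_points: list[int]) -> list[float]:
    bounds = [0, *change_points, len(values)]
    return [float(values[a:b].mean()) for a, b in zip(bounds[:-1], bounds[1:])]


def _merge_small_steps(values: np.ndarray, cps: list[int], params: StepFitParams) -> list[int]:
    """Iteratively remove the smallest step while it falls below the merge
    threshold (a fraction of the median absolute step), and optionally any
    upward step in monotone mode."""
    cps = list(cps)
    while cps:
        lv = _levels(values, cps)
        diffs = np.diff(lv)
        absd = np.abs(diffs)
        median_step = float(np.median(absd))
        idx_small = int(np.argmin(absd))
        if median_step > 0 and absd[idx_small] < params.merge_fraction * median_step:
            del cps[idx_small]
            continue
        if params.monotone:
            up = np.nonzero(diffs > 0)[0]
            if up.size:
                del cps[int(up[0])]
                continue
        break
    return cps


def fit_steps(trace: BleachTrace, params: StepFitParams | None = None) -> StepFit:
    """Fit a piecewise-constant staircase to one bleaching trace.

    Deterministic for a given trace and parameters.  Traces shorter than
    ``MIN_TRACE_LENGTH`` frames are rejected as not-evaluable (ValueError),
    which is distinct from a valid fit with zero steps.
    """
    params = params or StepFitParams()
    values = np.asarray(trace.values, dtype=float)
    if len(values) < MIN_TRACE_LENGTH:
        raise ValueError(
            f"trace {trace.spot_id!r} has {len(values)} frames; "
            f"at least {MIN_TRACE_LENGTH} are required for step fitting"
        )
    cps = _binary_segmentation(values, params)
    cps = _merge_small_steps(values, cps, params)
    levels = _levels(values, cps)
    bounds = [0, *cps, len(values)]
    rss = sum(
        float(((values[a:b] - lv) ** 2).sum())
        for (a, b), lv in zip(zip(bounds[:-1], bounds[1:]), levels)
    )
    dof = max(len(values) - len(levels), 1)
    return StepFit(
        spot_id=trace.spot_id,
        change_points=tuple(cps),
        levels=tuple(levels),
        n_steps=len(cps),
        residual_sd=math.sqrt(rss / dof),
    )


# ---------------------------------------------------------------------------
# acceptance and counting
# ---------------------------------------------------------------------------


def accept_trace(fit: StepFit, params: AcceptanceParams | None = None) -> StepFit:
    """Apply the quality gate and return the fit with its accepted flag set.

    Rejected are: flat traces (nothing to count), spots with more steps than
    the largest considered oligomer, traces that never return to background
    (incomplete bleaching), and fits containing a step much larger than the
    median step (suspected coincident double bleach).
    """
    params = params or AcceptanceParams()
    reason = None
    if fit.n_steps == 0:
        reason = "no steps"
    elif fit.n_steps > params.k_max:
        reason = f"exceeds K_max ({fit.n_steps} > {params.k_max})"
    else:
        steps = np.abs(np.diff(fit.levels))
        end_tol = max(params.end_tol_sd * fit.residual_sd, 1e-6 * float(np.median(steps)), 1e-9)
        if abs(fit.levels[-1] - params.background) > end_tol:
            reason = "non-terminal (does not return to background)"
        elif fit.n_steps >= 2:
            median_step = float(np.median(steps))
            if median_step > 0 and float(steps.max()) > params.max_step_ratio * median_step:
                reason = "step ratio (suspected coincident bleach)"
    return replace(fit, accepted=reason is None, rejection_reason=reason)


def count_distribution(fits, k_max: int = 4) -> StepCountTable:
    """Tabulate accepted fits into the observed step-count frequency table."""
    counts: dict[int, int] = {}
    total = 0
    for fit in fits:
        if not fit.accepted:
            continue
        counts[fit.n_steps] = counts.get(fit.n_steps, 0) + 1
        total += 1
    if total == 0:
        raise ValueError("no accepted fits to tabulate")
    return StepCountTable(counts=counts, total_spots=total, k_max=max(k_max, max(counts)))
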