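"""Contraction–expansion beam search for extending a seed across a gap.

Candidate extensions are scored by f = g + h, A*-style. The actual cost
g accumulates |ln p| of each chosen base, so confident predictions are
cheap and uncertain ones expensive. The heuristic h combines three
normalized structural terms:

  h = -alpha * entropy(S)/maxEntropy          (reward complex, informative paths)
      + beta  * ln(remaining)/ln(total)       (penalty shrinking toward the goal)
      + gamma * |GC(next) - GC(current)|      (compositional-plausibility penalty)

The beam width follows a relax-then-shrink schedule: it widens linearly
from ``w_init`` to ``w_max`` over the first ``contract_at`` fraction of
the target length (keeping more hypotheses alive early, when evidence is
thin), then narrows linearly to ``w_final``. The lowest-f full-length
candidate wins; ties break by channel order of the last base, then by
lexicographic sequence, which makes the search fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .encode import CHANNEL_ORDER, reverse_complement
from .gaps import GapRecord

Oracle = Callable[[Sequence[str]], np.ndarray]
"""Batched next-base oracle: contexts -> (n, 4) probability rows."""

_CHANNEL_INDEX = {b: i for i, b in enumerate(CHANNEL_ORDER)}


class OracleContractError(ValueError):
    """The oracle returned something other than probability simplex rows."""


# ---------------------------------------------------------------------------
# cost-function components
# ---------------------------------------------------------------------------

def path_cost_g(current_g: float, probabilities: Sequence[float],
                p_min: float = 1e-9) -> float:
    """Accumulate |ln p| over newly chosen bases onto the running cost.

    Probabilities are floored at ``p_min`` before the log so a hard zero
    from the oracle cannot produce an infinite cost.
    """
    if current_g < 0:
        raise ValueError("current_g must be non-negative")
    total = current_g
    for p in probabilities:
        p = max(p, p_min)
        if p > 1.0:
            raise ValueError(f"probability {p} > 1")
        total += abs(math.log(p))
    return total


def entropy_term(prob_trace: Sequence[np.ndarray], log_base: float = math.e) -> float:
    """Normalized Shannon entropy of the per-step distributions, in [0, 1].

    H(S) = sum over steps of -sum_b p log_b p, divided by the maximum
    n * log_b(4). An empty trace contributes 0 by convention.
    """
    if not len(prob_trace):
        return 0.0
    log = lambda v: math.log(v) / math.log(log_base)
    h = 0.0
    for dist in prob_trace:
        for p in np.asarray(dist, dtype=float):
            if p > 0:
                h -= p * log(p)
    return h / (len(prob_trace) * log(4.0))


def norm_rem_len(total_length: int, seed_length: int) -> float:
    """ln(remaining)/ln(total): 1 with everything left, 0 at one base left.

    ``seed_length`` counts bases already predicted. At or past the target
    the term is 0 (the search is terminating).
    """
    if total_length < 2:
        raise ValueError("total_length must be >= 2")
    remaining = total_length - seed_length
    if remaining <= 0:
        return 0.0
    return math.log(remaining) / math.log(total_length)


def gc_ratio_impact(current_seq: str, next_seq: str) -> float:
    """Absolute GC-fraction difference between the two sequences, in [0, 1]."""
    if not current_seq or not next_seq:
        raise ValueError("sequences must be non-empty")
    gc = lambda s: (s.count("G") + s.count("C")) / len(s)
    return abs(gc(next_seq) - gc(current_seq))


# ---------------------------------------------------------------------------
# search machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeuristicWeights:
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    log_base: float = math.e

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("heuristic weights must be >= 0")


@dataclass(frozen=True)
class BeamSchedule:
    """Relax-then-shrink beam width profile."""

    w_init: int = 8
    w_max: int = 16
    w_final: int = 8
    contract_at: float = 0.75

    def __post_init__(self) -> None:
        if not (1 <= self.w_init <= self.w_max and 1 <= self.w_final <= self.w_max):
            raise ValueError("require 1 <= w_init, w_final <= w_max")
        if not 0.0 < self.contract_at <= 1.0:
            raise ValueError("contract_at must be in (0, 1]")

    @classmethod
    def constant(cls, width: int) -> "BeamSchedule":
        return cls(w_init=width, w_max=width, w_final=width, contract_at=0.5)

    @classmethod
    def from_peak(cls, width: int, contract_at: float = 0.75) -> "BeamSchedule":
        """Default profile around a peak width w: w/2 -> w -> w/2."""
        half = max(1, width // 2)
        return cls(w_init=half, w_max=width, w_final=half, contract_at=contract_at)


def beam_width_at(step: int, target_length: int, schedule: BeamSchedule) -> int:
    """Width at a 0-based step: linear w_init->w_max, then linear w_max->w_final."""
    if not 0 <= step < target_length:
        raise ValueError(f"step {step} outside [0, {target_length})")
    pivot = schedule.contract_at * target_length
    if step < pivot:
        w = schedule.w_init + (schedule.w_max - schedule.w_init) * step / pivot
    else:
        last = target_length - 1
        span = last - pivot
        if span <= 0:
            w = schedule.w_final
        else:
            w = schedule.w_max + (schedule.w_final - schedule.w_max) * (step - pivot) / span
    return max(1, round(w))


@dataclass
class BeamNode:
    """A partial hypothesis: seed + predicted bases with its cost bookkeeping."""

    sequence: str
    g: float = 0.0
    h: float = 0.0
    chosen_probs: list[float] = field(default_factory=list)
    prob_trace: list[np.ndarray] = field(default_factory=list)

    @property
    def f(self) -> float:
        return self.g + self.h

    def recompute_g(self, p_min: float = 1e-9) -> float:
        """Re-derive g from the trace; used to audit cost bookkeeping."""
        return path_cost_g(0.0, self.chosen_probs, p_min=p_min)


@dataclass
class SearchResult:
    best: BeamNode
    candidates: list[BeamNode]
    direction: str
    n_seed: int
    nodes_expanded: int = 0
    peak_beam: int = 0

    @property
    def predicted(self) -> str:
        """The newly predicted bases (seed stripped)."""
        return self.best.sequence[self.n_seed :]


def heuristic_cost(
    node: BeamNode,
    candidate_base: str,
    candidate_probs: np.ndarray,
    target_length: int,
    weights: HeuristicWeights,
) -> float:
    """h for extending ``node`` by one base drawn from ``candidate_probs``."""
    trace = node.prob_trace + [candidate_probs]
    n_new = len(trace)  # predicted bases after this extension
    ent = entropy_term(trace, weights.log_base)
    rem = norm_rem_len(target_length, n_new) if target_length >= 2 else 0.0
    gc = gc_ratio_impact(node.sequence, node.sequence + candidate_base)
    return -weights.alpha * ent + weights.beta * rem + weights.gamma * gc


def _tie_key(node: BeamNode) -> tuple:
    return (node.f, _CHANNEL_INDEX[node.sequence[-1]], node.sequence)


def bscea_search(
    oracle: Oracle,
    seed: str,
    target_length: int,
    weights: HeuristicWeights | None = None,
    schedule: BeamSchedule | None = None,
    p_min: float = 1e-9,
    direction: str = "left-to-right",
) -> SearchResult:
    """Extend ``seed`` by ``target_length`` bases under f = g + h.

    At each step every surviving node is expanded by all four bases using
    one oracle call per node (the four children share the distribution);
    the ``beam_width_at(step)`` lowest-f children survive. After the last
    step the minimum-f candidate is returned.
    """
    if not seed or "N" in seed:
        raise ValueError("seed must be non-empty and N-free")
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    weights = weights or HeuristicWeights()
    schedule = schedule or BeamSchedule()
    beam = [BeamNode(sequence=seed)]
    n_expanded = 0
    peak = 1
    for step in range(target_length):
        dists = np.asarray(oracle([n.sequence for n in beam]), dtype=float)
        if dists.shape != (len(beam), 4) or np.any(dists < 0) or np.any(
            np.abs(dists.sum(axis=1) - 1.0) > 1e-6
        ):
            raise OracleContractError(
                f"oracle must return ({len(beam)}, 4) probability rows"
            )
        children = []
        for node, dist in zip(beam, dists):
            n_expanded += 1
            for j, base in enumerate(CHANNEL_ORDER):
                g = path_cost_g(node.g, [dist[j]], p_min=p_min)
                h = heuristic_cost(node, base, dist, target_length, weights)
                children.append(
                    BeamNode(
                        sequence=node.sequence + base,
                        g=g,
                        h=h,
                        chosen_probs=node.chosen_probs + [float(dist[j])],
                        prob_trace=node.prob_trace + [dist],
                    )
                )
        children.sort(key=_tie_key)
        beam = children[: beam_width_at(step, target_length, schedule)]
        peak = max(peak, len(beam))
    best = min(beam, key=_tie_key)
    return SearchResult(
        best=best,
        candidates=beam,
        direction=direction,
        n_seed=len(seed),
        nodes_expanded=n_expanded,
        peak_beam=peak,
    )


# ---------------------------------------------------------------------------
# gap-level driver
# ---------------------------------------------------------------------------

@dataclass
class GapFill:
    """A proposed fill for one gap with its search provenance."""

    gap: GapRecord
    sequence: str
    direction: str
    f: float
    g: float
    mean_step_prob: float

    @property
    def gap_id(self) -> str:
        return self.gap.gap_id


def _result_to_fill(gap: GapRecord, result: SearchResult, direction: str,
                    sequence: str) -> GapFill:
    probs = result.best.chosen_probs
    return GapFill(
        gap=gap,
        sequence=sequence,
        direction=direction,
        f=result.best.f,
        g=result.best.g,
        mean_step_prob=float(np.mean(probs)) if probs else 0.0,
    )


def _merge_candidates(left: str, right: str, min_overlap: int,
                      min_identity: float) -> str | None:
    """Splice two same-length candidates at the midpoint of their longest
    agreeing run; None when no run reaches ``min_overlap`` bases.

    Runs are exact base-for-base agreements, so their identity is 1 and
    ``min_identity`` (<= 1) is satisfied whenever the length bound is.
    """
    n = len(left)
    if n < min_overlap:
        return left if left == right else None
    best_len, best_start = 0, -1
    run_start = None
    for i in range(n + 1):
        agree = i < n and left[i] == right[i]
        if agree and run_start is None:
            run_start = i
        elif not agree and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if best_len < min_overlap or min_identity > 1.0:
        return None
    mid = best_start + best_len // 2
    return left[:mid] + right[mid:]


def fill_gap(
    model,
    gap: GapRecord,
    weights: HeuristicWeights | None = None,
    schedule: BeamSchedule | None = None,
    mode: str = "bidirectional",
    target_length: int | None = None,
    min_flank: int = 50,
    min_overlap: int = 10,
    min_identity: float = 0.9,
    p_min: float = 1e-9,
) -> GapFill | None:
    """Predict a fill for one gap; None when no usable flank exists.

    Left mode seeds from the left flank. Right mode seeds from the
    reverse complement of the right flank and reverse-complements the
    prediction back, so one model serves both strands. Bidirectional
    runs both and reconciles: candidates that locally agree are spliced
    at their longest agreeing run, otherwise the lower-f one wins.
    """
    import logging

    log = logging.getLogger(__name__)
    if mode not in ("left", "right", "bidirectional"):
        raise ValueError(f"unknown mode {mode!r}")
    target = target_length if target_length is not None else gap.length
    oracle = model.as_oracle() if hasattr(model, "as_oracle") else model

    left_ok = len(gap.left_flank) >= min_flank
    right_ok = len(gap.right_flank) >= min_flank
    want_left = mode in ("left", "bidirectional") and left_ok
    want_right = mode in ("right", "bidirectional") and right_ok
    if not want_left and not want_right:
        log.warning("gap %s: no usable flank (min %d bases); skipped", gap.gap_id, min_flank)
        return None

    left_fill = right_fill = None
    if want_left:
        res = bscea_search(oracle, gap.left_flank, target, weights, schedule,
                           p_min=p_min, direction="left-to-right")
        left_fill = _result_to_fill(gap, res, "left", res.predicted)
    if want_right:
        res = bscea_search(oracle, reverse_complement(gap.right_flank), target,
                           weights, schedule, p_min=p_min, direction="right-to-left")
        right_fill = _result_to_fill(gap, res, "right", reverse_complement(res.predicted))

    if left_fill is None:
        return right_fill
    if right_fill is None:
        return left_fill
    merged = _merge_candidates(left_fill.sequence, right_fill.sequence,
                               min_overlap, min_identity)
    if merged is not None:
        lower = min(left_fill, right_fill, key=lambda c: c.f)
        return GapFill(
            gap=gap, sequence=merged, direction="bidirectional",
            f=lower.f, g=lower.g,
            mean_step_prob=(left_fill.mean_step_prob + right_fill.mean_step_prob) / 2,
        )
    return min(left_fill, right_fill, key=lambda c: c.f)
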