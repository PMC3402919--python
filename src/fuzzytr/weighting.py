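"""Anti-smear and multiplicity weighting of candidate periods.

Indels between two matching probes shift the detected distance away
from the true period, smearing the period histogram.  The anti-smear
scheme counters this: each newly detected period ``k_g`` gains weight

    w0(k_g) += sum over k in Q of 2^-|k_g - k|

where ``Q`` holds the last ``H`` detected distances in scan order, so
near-agreeing periods from nearby probes reinforce each other with
exponentially decaying tolerance.  Multiplicity weighting then folds
harmonics back onto the fundamental:

    w1(k) = sum over m >= 1 of w0(m k)

because a repeat with many copies also produces matches at integer
multiples of its period.  Periods are ranked by ``w1``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .seeds import HitList


@dataclass
class PeriodWeightState:
    """Running period weights for one block.

    ``h`` is the per-probe hit bound, ``H`` the queue capacity, ``L``
    how many top periods to keep.  While the queue has fewer than ``H``
    entries, dequeues are suppressed so it fills to capacity.
    """

    h: int = 5
    H: int = 20
    L: int = 50
    w0: dict[int, float] = field(default_factory=dict)
    w1: dict[int, float] = field(default_factory=dict)
    Q: deque = field(default_factory=deque)


def anti_smear_update(state: PeriodWeightState, k_list: list[int]) -> PeriodWeightState:
    """Apply one probe's detected periods to the anti-smear weights.

    All increments are evaluated against the queue as it stood before
    this probe (so the result does not depend on the order of ``k_list``),
    then the periods are enqueued and an equal number dequeued — except
    that the queue is allowed to fill to capacity ``H`` first.
    """
    snapshot = list(state.Q)
    for kg in k_list:
        inc = 0.0
        for k in snapshot:
            inc += 2.0 ** (-abs(kg - k))
        if inc:
            state.w0[kg] = state.w0.get(kg, 0.0) + inc
        elif kg not in state.w0:
            state.w0[kg] = 0.0
    for kg in k_list:
        state.Q.append(kg)
    while len(state.Q) > state.H:
        state.Q.popleft()
    return state


def accumulate_hits(state: PeriodWeightState, hits: HitList) -> PeriodWeightState:
    """Replay a block's hit stream probe by probe, in scan order."""
    for _pos, _shape, k_list in hits.probes():
        anti_smear_update(state, k_list)
    return state


def multiplicity_weight(state: PeriodWeightState) -> PeriodWeightState:
    """Compute ``w1(k) = sum_m w0(m k)`` over the observed (finite) support."""
    if not state.w0:
        state.w1 = {}
        return state
    max_k = max(state.w0)
    w1 = {}
    for k in state.w0:
        total = 0.0
        mk = k
        while mk <= max_k:
            total += state.w0.get(mk, 0.0)
            mk += k
        w1[k] = total
    state.w1 = w1
    return state


def get_top_periods(state: PeriodWeightState) -> list[int]:
    """Periods ranked by ``w1`` descending, ties to the smaller period, top L."""
    ranked = sorted(state.w1, key=lambda k: (-state.w1[k], k))
    return ranked[: state.L]
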