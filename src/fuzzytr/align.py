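"""Weighted edit distance and global alignment over encoded residues.

The dynamic programs here are the workhorse of repeat validation: unit
vs unit and unit vs consensus distances, prefix-cost rows for the
wraparound-style unit extension, and a full matrix with traceback for
the center-star consensus construction.  All kernels run on ``int8``
residue codes against the model's ``(21, 21)`` cost table.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .matrices import DistanceModel, encode_sequence


@njit(cache=True)
def _dp_dist(a, b, costs, indel):
    """Minimum-cost edit distance between code arrays ``a`` and ``b``."""
    la, lb = len(a), len(b)
    prev = np.empty(lb + 1, dtype=np.float64)
    cur = np.empty(lb + 1, dtype=np.float64)
    for j in range(lb + 1):
        prev[j] = j * indel
    for i in range(la):
        cur[0] = (i + 1) * indel
        ai = a[i]
        for j in range(lb):
            best = prev[j] + costs[ai, b[j]]
            up = prev[j + 1] + indel
            if up < best:
                best = up
            left = cur[j] + indel
            if left < best:
                best = left
            cur[j + 1] = best
        prev, cur = cur, prev
    return prev[lb]


@njit(cache=True)
def _dp_last_row(a, b, costs, indel):
    """Final DP row: cost of aligning all of ``a`` to each prefix of ``b``."""
    la, lb = len(a), len(b)
    prev = np.empty(lb + 1, dtype=np.float64)
    cur = np.empty(lb + 1, dtype=np.float64)
    for j in range(lb + 1):
        prev[j] = j * indel
    for i in range(la):
        cur[0] = (i + 1) * indel
        ai = a[i]
        for j in range(lb):
            best = prev[j] + costs[ai, b[j]]
            up = prev[j + 1] + indel
            if up < best:
                best = up
            left = cur[j] + indel
            if left < best:
                best = left
            cur[j + 1] = best
        prev, cur = cur, prev
    return prev


@njit(cache=True)
def _dp_matrix(a, b, costs, indel):
    """Full (|a|+1, |b|+1) DP matrix, for traceback."""
    la, lb = len(a), len(b)
    m = np.empty((la + 1, lb + 1), dtype=np.float64)
    for j in range(lb + 1):
        m[0, j] = j * indel
    for i in range(la):
        m[i + 1, 0] = (i + 1) * indel
        ai = a[i]
        for j in range(lb):
            best = m[i, j] + costs[ai, b[j]]
            up = m[i, j + 1] + indel
            if up < best:
                best = up
            left = m[i + 1, j] + indel
            if left < best:
                best = left
            m[i + 1, j + 1] = best
    return m


def _as_codes(x) -> np.ndarray:
    if isinstance(x, str):
        return encode_sequence(x, warn=False)
    return np.asarray(x, dtype=np.int8)


def weighted_edit_distance(a, b, model: DistanceModel) -> float:
    """Weighted edit distance between two sequences (strings or code arrays).

    Substituting residues ``i -> j`` costs ``model.costs[i, j]``; every
    insertion or deletion costs ``model.indel_cost``.  Symmetric, zero on
    identical inputs, and bounded by ``indel_cost * (|a| + |b|)``.
    """
    return float(_dp_dist(_as_codes(a), _as_codes(b), model.costs, model.indel_cost))


def prefix_costs(a, b, model: DistanceModel) -> np.ndarray:
    """Cost of aligning all of ``a`` against every prefix of ``b``.

    ``prefix_costs(a, b, m)[l] == weighted_edit_distance(a, b[:l], m)``.
    Used to let a repeat unit's right boundary float during extension.
    """
    return _dp_last_row(_as_codes(a), _as_codes(b), model.costs, model.indel_cost)


def global_alignment(a, b, model: DistanceModel) -> list[tuple[int, int]]:
    """Globally align ``a`` and ``b``; return aligned index pairs.

    Each element is ``(i, j)`` with ``-1`` marking a gap on that side.
    Traceback ties prefer substitution/match, then deletion from ``a``,
    then insertion — deterministic across runs.
    """
    ca, cb = _as_codes(a), _as_codes(b)
    m = _dp_matrix(ca, cb, model.costs, model.indel_cost)
    indel = model.indel_cost
    ops: list[tuple[int, int]] = []
    i, j = len(ca), len(cb)
    eps = 1e-12
    while i > 0 or j > 0:
        if i > 0 and j > 0 and abs(
            m[i, j] - (m[i - 1, j - 1] + model.costs[ca[i - 1], cb[j - 1]])
        ) <= eps:
            i, j = i - 1, j - 1
            ops.append((i, j))
        elif i > 0 and abs(m[i, j] - (m[i - 1, j] + indel)) <= eps:
            i -= 1
            ops.append((i, -1))
        else:
            j -= 1
            ops.append((-1, j))
    ops.reverse()
    return ops
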