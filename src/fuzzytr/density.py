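"""Positional k-density: localizing where a candidate period is supported.

A true tandem repeat of period k produces matching probes clustered in
one region of the sequence.  For each top-ranked period the scan
positions that supported it (directly or through an integer multiple)
are marked, the indicator is smoothed with a k-wide sliding window, and
windows whose density reaches a threshold proportional to the mean
density become candidate (period, position) pairs for validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .seeds import HitList


class CandidatePair(NamedTuple):
    """A (period, start position) hypothesis handed to validation."""

    period: int
    pos: int


@dataclass
class DensityProfile:
    """The k-window density profile backing a period's candidate positions."""

    period: int
    contributors: set[int]
    f: np.ndarray  # 0/1 membership over [0, n)
    F: np.ndarray  # k-window sums over [0, n - k]
    threshold: float
    alpha: float


def collect_contributors(hits: HitList, k: int) -> set[int]:
    """First-probe positions of hits whose period reinforces ``k``.

    A hit at period ``m k`` (integer ``m >= 1``) contributes to ``k``
    through multiplicity weighting; each position counts once however
    many hits share it.
    """
    if k < 1:
        raise ValueError("period must be positive")
    periods = np.asarray(hits.period)
    mask = periods % k == 0
    return set(int(p) for p in np.asarray(hits.pos)[mask])


def density_profile(
    seq_len: int, k: int, contributors: Iterable[int], alpha: float = 1.0
) -> DensityProfile | None:
    """Build the k-window density profile; ``None`` when no window fits."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if seq_len <= k:
        return None
    f = np.zeros(seq_len, dtype=np.float64)
    contributors = set(contributors)
    for p in contributors:
        if 0 <= p < seq_len:
            f[p] = 1.0
    cs = np.concatenate(([0.0], np.cumsum(f)))
    F = cs[k:] - cs[: seq_len - k + 1]  # F(i) for i in [0, seq_len - k]
    threshold = alpha * float(F.mean())
    return DensityProfile(
        period=k, contributors=contributors, f=f, F=F, threshold=threshold, alpha=alpha
    )


def positional_density(
    seq_len: int, k: int, contributors: Iterable[int], alpha: float = 1.0
) -> list[CandidatePair]:
    """Candidate pairs ``(k, i)`` with window density ``F(i) >= alpha * mean(F)``.

    An empty contributor set yields no candidates.  Positions are
    returned in increasing order.
    """
    profile = density_profile(seq_len, k, contributors, alpha)
    if profile is None or not profile.contributors:
        return []
    idx = np.nonzero(profile.F >= profile.threshold - 1e-12)[0]
    return [CandidatePair(k, int(i)) for i in idx]


def coalesce_runs(pairs: list[CandidatePair]) -> list[CandidatePair]:
    """Keep only the first position of each maximal run of consecutive positions.

    Validation re-derives exact repeat boundaries, so re-validating a
    repeat at every in-run offset is redundant.
    """
    out: list[CandidatePair] = []
    prev: CandidatePair | None = None
    for p in pairs:
        if prev is None or p.period != prev.period or p.pos != prev.pos + 1:
            out.append(p)
        prev = p
    return out


def thin_candidates(pairs: list[CandidatePair], stride: int | None = None) -> list[CandidatePair]:
    """Coalesce runs but keep one seed position per period-length of run.

    Like :func:`coalesce_runs`, with additional in-run positions every
    ``stride`` residues (default: the period), so a long dense run — one
    repeat array — offers several growth anchors rather than a single
    one at its left edge.
    """
    out: list[CandidatePair] = []
    run_anchor: CandidatePair | None = None
    prev: CandidatePair | None = None
    for p in pairs:
        step = stride or p.period
        if prev is None or p.period != prev.period or p.pos != prev.pos + 1:
            out.append(p)
            run_anchor = p
        elif run_anchor is not None and (p.pos - run_anchor.pos) % step == 0:
            out.append(p)
        prev = p
    return out
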