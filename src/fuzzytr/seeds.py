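"""Gapped q-gram seeds and the homologous-pair scan.

Candidate repeat periods are discovered by sliding a small family of
spaced seeds (shapes) along the sequence and recording the distances
between *homologous* q-grams: grams agreeing exactly in at least two
sampled positions, with the one remaining position allowed to differ as
long as the two residues are mutually within the top ``z`` of each
other's similarity rankings.  ``z = 1`` demands exact identity.

The default family is complete for q = 3 and span s in {2, 3, 4}:
``###``, ``#-##``, ``##-#``, ``##--#``, ``#-#-#``, ``#--##`` — six
seeds.  The 2-gram seed ``##`` exists behind a flag (off by default);
for it, homology means both positions identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np
from numba import njit

from .matrices import DistanceModel, X_CODE


@dataclass(frozen=True)
class Shape:
    """A seed template: strictly increasing offsets starting at 0."""

    offsets: tuple[int, ...]

    def __post_init__(self):
        if not self.offsets or self.offsets[0] != 0:
            raise ValueError("a shape must contain offset 0")
        if any(b <= a for a, b in zip(self.offsets, self.offsets[1:])):
            raise ValueError("offsets must be strictly increasing")

    @property
    def q(self) -> int:
        return len(self.offsets)

    @property
    def span(self) -> int:
        return self.offsets[-1]

    def __str__(self) -> str:
        marks = ["-"] * (self.span + 1)
        for o in self.offsets:
            marks[o] = "#"
        return "".join(marks)


def enumerate_shapes(include_2gram: bool = False) -> list[Shape]:
    """The complete (3, s)-shape family for s in {2, 3, 4}: six seeds.

    Every 3-position shape samples offsets ``{0, m, s}``; the first and
    last position are always sampled.  With ``include_2gram`` the
    (2, 1)-shape ``##`` is appended.
    """
    shapes = [
        Shape(offsets=(0, m, s)) for s in (2, 3, 4) for m in range(1, s)
    ]
    if include_2gram:
        shapes.append(Shape(offsets=(0, 1)))
    return shapes


def extract_gram(seq, shape: Shape, i: int) -> tuple:
    """The residues sampled by ``shape`` anchored at position ``i``."""
    n = len(seq)
    if i < 0 or i + shape.span >= n:
        raise IndexError("gram at %d with span %d exceeds sequence" % (i, shape.span))
    return tuple(seq[i + o] for o in shape.offsets)


def homologous(g1, g2, z: int, model: DistanceModel) -> bool:
    """Mutual rank-z homology between two equal-size grams.

    True iff at most one sampled position differs, and at any differing
    position the two residues each rank within the other's top ``z``
    most-similar residues.  Residues are letters or integer codes; the
    unknown code never matches anything.
    """
    if z < 1:
        raise ValueError("rank slack z must be >= 1")
    if len(g1) != len(g2):
        raise ValueError("grams must have equal size")
    codes1 = _gram_codes(g1)
    codes2 = _gram_codes(g2)
    diff = [(a, b) for a, b in zip(codes1, codes2) if a != b]
    if len(codes1) - len(diff) < len(codes1) - 1:
        return False  # more than one differing position
    for a, b in diff:
        if a == X_CODE or b == X_CODE:
            return False
        if len(codes1) == 2:
            return False  # 2-gram homology demands full identity
        if model.rank_index[a, b] >= z or model.rank_index[b, a] >= z:
            return False
    return True


def _gram_codes(g) -> tuple[int, ...]:
    from .matrices import _AA_INDEX, AMBIGUITY_MAP

    out = []
    for x in g:
        if isinstance(x, str):
            out.append(_AA_INDEX.get(AMBIGUITY_MAP.get(x, x), X_CODE))
        else:
            out.append(int(x))
    return tuple(out)


class QGramHit(NamedTuple):
    """One homologous q-gram pair: seed index, first-probe position, period."""

    shape: int
    pos: int
    period: int


class HitList:
    """Hits from one block, in scan order (by position, then seed, then period)."""

    __slots__ = ("shape_idx", "pos", "period")

    def __init__(self, shape_idx: np.ndarray, pos: np.ndarray, period: np.ndarray):
        self.shape_idx = shape_idx
        self.pos = pos
        self.period = period

    def __len__(self) -> int:
        return len(self.pos)

    def __iter__(self) -> Iterator[QGramHit]:
        for s, i, k in zip(self.shape_idx, self.pos, self.period):
            yield QGramHit(int(s), int(i), int(k))

    def probes(self) -> Iterator[tuple[int, int, list[int]]]:
        """Group hits into per-probe period lists, preserving scan order."""
        i = 0
        n = len(self.pos)
        while i < n:
            j = i
            while (
                j < n
                and self.pos[j] == self.pos[i]
                and self.shape_idx[j] == self.shape_idx[i]
            ):
                j += 1
            yield int(self.pos[i]), int(self.shape_idx[i]), [
                int(k) for k in self.period[i:j]
            ]
            i = j


@njit(cache=True)
def _scan_shape(enc, o1, o2, z, rank, h_next, out_pos, out_per):
    """Direct next-h homologous-occurrence scan for one 3-position shape.

    For each anchor position ``i`` the scan walks forward until ``h_next``
    homologous grams are found or the block ends.  Output order is by
    ``i`` then ascending period, exactly the brute-force definition.
    """
    n = len(enc)
    span = o2
    count = 0
    last = n - span - 1
    for i in range(last + 1):
        a0 = enc[i]
        a1 = enc[i + o1]
        a2 = enc[i + o2]
        if a0 == X_CODE or a1 == X_CODE or a2 == X_CODE:
            continue
        found = 0
        for j in range(i + 1, last + 1):
            b0 = enc[j]
            b1 = enc[j + o1]
            b2 = enc[j + o2]
            if b0 == X_CODE or b1 == X_CODE or b2 == X_CODE:
                continue
            ndiff = 0
            da = 0
            db = 0
            if a0 != b0:
                ndiff += 1
                da = a0
                db = b0
            if a1 != b1:
                ndiff += 1
                da = a1
                db = b1
            if a2 != b2:
                ndiff += 1
                da = a2
                db = b2
            if ndiff > 1:
                continue
            if ndiff == 1 and (rank[da, db] >= z or rank[db, da] >= z):
                continue
            out_pos[count] = i
            out_per[count] = j - i
            count += 1
            found += 1
            if found >= h_next:
                break
    return count


@njit(cache=True)
def _scan_2gram(enc, h_next, out_pos, out_per):
    """Exact-identity scan for the (2, 1)-shape ``##``."""
    n = len(enc)
    count = 0
    last = n - 2
    for i in range(last + 1):
        a0 = enc[i]
        a1 = enc[i + 1]
        if a0 == X_CODE or a1 == X_CODE:
            continue
        found = 0
        for j in range(i + 1, last + 1):
            if enc[j] == a0 and enc[j + 1] == a1:
                out_pos[count] = i
                out_per[count] = j - i
                count += 1
                found += 1
                if found >= h_next:
                    break
    return count


def find_gapped_qgrams(
    block,
    shapes: list[Shape],
    z: int,
    model: DistanceModel,
    h_next: int = 5,
) -> HitList:
    """Scan a block for homologous q-gram pairs under every seed.

    For every seed and every position, the next ``h_next`` homologous
    occurrences are recorded as (position, period) hits.  Hits are
    returned in global scan order — position first, then seed — which is
    the order the anti-smear queue consumes them in.
    """
    if z < 1:
        raise ValueError("rank slack z must be >= 1")
    if h_next < 1:
        raise ValueError("h_next must be >= 1")
    from .matrices import encode_sequence

    enc = block if isinstance(block, np.ndarray) else encode_sequence(block, warn=False)
    enc = np.ascontiguousarray(enc, dtype=np.int8)
    n = len(enc)
    per_shape: list[tuple[np.ndarray, np.ndarray]] = []
    cap = max(1, n * min(h_next, n))
    for shape in shapes:
        out_pos = np.empty(cap, dtype=np.int32)
        out_per = np.empty(cap, dtype=np.int32)
        if shape.q == 3:
            cnt = _scan_shape(
                enc,
                shape.offsets[1],
                shape.offsets[2],
                z,
                model.rank_index,
                h_next,
                out_pos,
                out_per,
            )
        elif shape.q == 2:
            cnt = _scan_2gram(enc, h_next, out_pos, out_per)
        else:
            raise ValueError("unsupported gram size q=%d" % shape.q)
        per_shape.append((out_pos[:cnt].copy(), out_per[:cnt].copy()))

    total = sum(len(p) for p, _ in per_shape)
    shape_idx = np.empty(total, dtype=np.int32)
    pos = np.empty(total, dtype=np.int32)
    period = np.empty(total, dtype=np.int32)
    # merge per-shape streams into global scan order: position, then seed
    cursors = [0] * len(per_shape)
    w = 0
    for i in range(n):
        for s, (p_arr, k_arr) in enumerate(per_shape):
            c = cursors[s]
            while c < len(p_arr) and p_arr[c] == i:
                shape_idx[w] = s
                pos[w] = i
                period[w] = k_arr[c]
                w += 1
                c += 1
            cursors[s] = c
    return HitList(shape_idx, pos, period)
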