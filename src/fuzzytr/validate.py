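"""Tandem-repeat validation against the weighted Steiner-repeat definition.

A span of sequence decomposed into units ``x_1 .. x_t`` is accepted as a
fuzzy tandem repeat when, for a divergence budget ``mu`` in [0, 1] and a
pair-regularity constant ``c`` in [1, 2]:

  (a) consecutive units stay close:   D(x_i, x_{i+1}) <= c mu |x_i| E(C)
  (b) a consensus (Steiner) string exists with
                                      D(xbar, x_i)    <= mu |x_i| E(C)

where D is the weighted edit distance and E(C) the expected substitution
cost, so the budget reads "at most a fraction mu of the mutations random
strings of that length would show".  Condition (b) is existential; we
certify it with an explicit consensus built by center-star progressive
alignment and column-wise minimum-cost voting.  The certificate can only
be conservative: if the approximate consensus satisfies (b), a Steiner
string exists.

Candidate extraction (:func:`get_tr`) grows a seed window outward one
unit at a time, letting each unit's boundary float via prefix-cost
alignment against the running consensus (a wraparound-style scheme),
with a small slack during growth; final acceptance re-checks the strict
budgets and trims units that violate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import _dp_dist, _dp_matrix, global_alignment, prefix_costs
from .matrices import DistanceModel, decode_sequence, encode_sequence

_EPS = 1e-9


@dataclass
class TandemRepeat:
    """A validated fuzzy tandem repeat.

    ``start``/``end`` are 0-based inclusive coordinates in the parent
    sequence; ``units`` are the full repeat units in order, ``leading``
    and ``trailing`` optional fractional first/last copies.
    ``copy_number`` is the fractional span / period ratio and
    ``divergence`` the mean unit-to-consensus distance normalized by the
    per-unit budget scale ``|x_i| E(C)``.
    """

    seq_id: str | None
    start: int
    end: int
    period: int
    units: list[str]
    consensus: str
    copy_number: float
    divergence: float
    mu: float
    c: float
    trailing: str = ""
    leading: str = ""

    @property
    def total_length(self) -> int:
        return self.end - self.start + 1

    def span_text(self) -> str:
        return "%d-x-%.1f [%d-%d]" % (
            self.period,
            self.copy_number,
            self.start,
            self.end,
        )


def _as_enc(x) -> np.ndarray:
    if isinstance(x, str):
        return encode_sequence(x, warn=False)
    return np.ascontiguousarray(x, dtype=np.int8)


def _dist(a: np.ndarray, b: np.ndarray, model: DistanceModel) -> float:
    return float(_dp_dist(a, b, model.costs, model.indel_cost))


def _center_star_rows(units: list[np.ndarray], model: DistanceModel):
    """Progressive MSA rows (gap = -1), seeded by the center unit.

    The center is the unit with minimum total distance to the others
    (ties to the earliest), and every other unit is pairwise-aligned to
    it; insertion columns are spliced into the master as they appear.
    """
    t = len(units)
    d = np.zeros((t, t))
    for a in range(t):
        for b in range(a + 1, t):
            d[a, b] = d[b, a] = _dist(units[a], units[b], model)
    center = int(np.argmin(d.sum(axis=1)))
    cu = units[center]
    rows: list[list[int]] = [[int(r) for r in cu]]
    master: list[int] = list(range(len(cu)))  # column -> center index, -1 = insertion
    order = [center]
    for idx in range(t):
        if idx == center:
            continue
        ops = global_alignment(cu, units[idx], model)
        new_rows: list[list[int]] = [[] for _ in rows]
        new_row: list[int] = []
        new_master: list[int] = []
        col = 0
        for ci, uj in ops:
            if ci == -1:
                # insertion relative to center: fresh column
                for r, nr in zip(rows, new_rows):
                    nr.append(-1)
                new_row.append(int(units[idx][uj]))
                new_master.append(-1)
                continue
            # copy earlier-insertion columns preceding this center position
            while master[col] != ci:
                for r, nr in zip(rows, new_rows):
                    nr.append(r[col])
                new_row.append(-1)
                new_master.append(master[col])
                col += 1
            for r, nr in zip(rows, new_rows):
                nr.append(r[col])
            new_row.append(int(units[idx][uj]) if uj != -1 else -1)
            new_master.append(master[col])
            col += 1
        while col < len(master):
            for r, nr in zip(rows, new_rows):
                nr.append(r[col])
            new_row.append(-1)
            new_master.append(master[col])
            col += 1
        rows = new_rows + [new_row]
        master = new_master
        order.append(idx)
    return rows


def steiner_consensus(units, model: DistanceModel) -> np.ndarray:
    """Column-wise minimum-total-cost consensus over a center-star MSA.

    Per column the cheapest option is chosen between every residue
    (substitution costs to the column's residues plus one indel per gap
    row) and dropping the column (one indel per residue row); ties
    prefer keeping a residue, then the alphabetically first one.
    """
    units = [_as_enc(u) for u in units]
    units = [u for u in units if len(u)]
    if not units:
        return np.empty(0, dtype=np.int8)
    if len(units) == 1:
        return units[0].copy()
    first = units[0]
    if all(len(u) == len(first) and np.array_equal(u, first) for u in units[1:]):
        return first.copy()
    rows = _center_star_rows(units, model)
    ncol = len(rows[0])
    sub = model.costs[:20, :20]
    indel = model.indel_cost
    out: list[int] = []
    for j in range(ncol):
        col = [row[j] for row in rows]
        residues = [r for r in col if r != -1]
        gaps = len(col) - len(residues)
        if not residues:
            continue
        res_costs = sub[:, residues].sum(axis=1) + gaps * indel
        best = int(np.argmin(res_costs))  # argmin ties to lowest index = alphabet order
        drop_cost = len(residues) * indel
        if drop_cost < res_costs[best] - _EPS:
            continue
        out.append(best)
    return np.asarray(out, dtype=np.int8)


def _best_unit_right(seq, end, cons, model, budget_rate):
    """Best-scoring next unit starting at ``end``; returns (length, cost) or None."""
    n = len(seq)
    p = len(cons)
    if end >= n or p == 0:
        return None
    delta = max(2, int(budget_rate * p) + 1)
    lo = max(1, p - delta)
    window = seq[end : min(n, end + p + delta)]
    if len(window) < lo:
        return None
    row = prefix_costs(cons, window, model)
    best = None
    for ell in range(lo, len(window) + 1):
        cost = row[ell]
        key = (cost, abs(ell - p), ell)
        if best is None or key < best[0]:
            best = (key, ell, cost)
    return (best[1], float(best[2]))


def _best_unit_left(seq, start, cons, model, budget_rate):
    if start <= 0 or len(cons) == 0:
        return None
    p = len(cons)
    delta = max(2, int(budget_rate * p) + 1)
    lo = max(1, p - delta)
    wstart = max(0, start - (p + delta))
    window = seq[wstart:start][::-1].copy()
    if len(window) < lo:
        return None
    row = prefix_costs(cons[::-1].copy(), window, model)
    best = None
    for ell in range(lo, len(window) + 1):
        cost = row[ell]
        key = (cost, abs(ell - p), ell)
        if best is None or key < best[0]:
            best = (key, ell, cost)
    return (best[1], float(best[2]))


def _fractional_trailing(seq, end, cons, model, mu):
    """Longest partial last copy at ``end`` matching a consensus prefix pro-rata."""
    n = len(seq)
    p = len(cons)
    if p < 2 or end >= n:
        return 0
    ec = model.expected_cost
    window = seq[end : min(n, end + p - 1)]
    if len(window) == 0:
        return 0
    m = _dp_matrix(cons, window, model.costs, model.indel_cost)
    best = 0
    for ell in range(1, len(window) + 1):
        if m[1 : p + 1, ell].min() <= mu * ell * ec + _EPS:
            best = ell
    return best


def _fractional_leading(seq, start, cons, model, mu):
    """Longest partial first copy ending at ``start``, vs consensus suffixes."""
    p = len(cons)
    if p < 2 or start <= 0:
        return 0
    ec = model.expected_cost
    wstart = max(0, start - (p - 1))
    window = seq[wstart:start][::-1].copy()
    if len(window) == 0:
        return 0
    rcons = cons[::-1].copy()
    m = _dp_matrix(rcons, window, model.costs, model.indel_cost)
    best = 0
    for ell in range(1, len(window) + 1):
        if m[1 : p + 1, ell].min() <= mu * ell * ec + _EPS:
            best = ell
    return best


def _check_units(units, cons, model, mu, c):
    """Return (first_violation_index or None) for strict (a)/(b) budgets."""
    ec = model.expected_cost
    for i, u in enumerate(units):
        if _dist(cons, u, model) > mu * len(u) * ec + _EPS:
            return ("b", i)
    for i in range(len(units) - 1):
        if _dist(units[i], units[i + 1], model) > c * mu * len(units[i]) * ec + _EPS:
            return ("a", i)
    return None


def get_tr(
    seq,
    k: int,
    i: int,
    model: DistanceModel,
    mu: float = 0.3,
    c: float = 1.5,
    seq_id: str | None = None,
    slack: float = 1.2,
    min_total_len: int = 6,
) -> TandemRepeat | None:
    """Grow and strictly validate a candidate repeat of period ``k`` at ``i``.

    The seed window ``seq[i : i+k]`` is extended rightward then leftward
    one unit at a time; a unit is accepted while its distance to the
    running consensus stays within ``slack`` times the per-unit budget
    ``mu |unit| E(C)``, and the consensus is re-derived after every
    acceptance.  A fractional trailing copy is then attached, the strict
    budgets are re-checked with end-trimming, and the repeat is returned
    only if at least two full units and ``min_total_len`` residues
    survive.
    """
    seq = _as_enc(seq)
    n = len(seq)
    if k < 1 or i < 0 or i + k > n:
        return None
    ec = model.expected_cost
    budget_rate = mu * ec * slack
    units = [seq[i : i + k].copy()]
    start, end = i, i + k  # half-open span of full units
    cons = units[0].copy()

    # Growth acceptance mirrors the two budgets of the repeat definition:
    # a unit extends the array if it sits within condition (b)'s budget of
    # the running consensus, or failing that within condition (a)'s
    # c-scaled budget of its neighboring unit (a single divergent unit may
    # still be covered once the final consensus includes it).  While only
    # one unit has been seen the "consensus" is that unit, so only the
    # pair budget applies.  Final acceptance re-checks the strict budgets.
    # A unit extends the array if it sits within condition (b)'s budget of
    # the running consensus.  A unit over that budget may still be accepted
    # through condition (a)'s c-scaled pair budget against its neighbor —
    # the first extension necessarily is (the "consensus" is one observed
    # unit), and an isolated divergent unit may be covered once the final
    # consensus includes it — but two consecutive pair-budget acceptances
    # would let growth coast through non-repetitive sequence whenever
    # c*mu*E(C) approaches the maximal per-residue cost, so they are not
    # allowed.  Final acceptance re-checks the strict budgets either way.
    prev_fallback = False
    while True:
        got = _best_unit_right(seq, end, cons, model, budget_rate * c)
        if got is None:
            break
        ell, cost = got
        first = len(units) == 1
        if cost > mu * ell * ec * slack + _EPS or first:
            if prev_fallback and not first:
                break
            prev = units[-1]
            got_p = _best_unit_right(seq, end, prev, model, budget_rate * c)
            if got_p is None:
                break
            ell_p, cost_p = got_p
            if cost_p > c * mu * ell_p * ec * slack + _EPS:
                break
            if cost_p * ell <= cost * ell_p or first:
                ell = ell_p
            prev_fallback = not first
        else:
            prev_fallback = False
        units.append(seq[end : end + ell].copy())
        end += ell
        cons = steiner_consensus(units, model)
        if len(cons) == 0:
            return None
    prev_fallback = False
    while True:
        got = _best_unit_left(seq, start, cons, model, budget_rate * c)
        if got is None:
            break
        ell, cost = got
        first = len(units) == 1
        if cost > mu * ell * ec * slack + _EPS or first:
            if prev_fallback and not first:
                break
            prev = units[0]
            got_p = _best_unit_left(seq, start, prev, model, budget_rate * c)
            if got_p is None:
                break
            ell_p, cost_p = got_p
            if cost_p > c * mu * ell_p * ec * slack + _EPS:
                break
            if cost_p * ell <= cost * ell_p or first:
                ell = ell_p
            prev_fallback = not first
        else:
            prev_fallback = False
        units.insert(0, seq[start - ell : start].copy())
        start -= ell
        cons = steiner_consensus(units, model)
        if len(cons) == 0:
            return None

    # strict re-check with end-trimming, then one re-extension attempt per
    # round: growth decisions were made against an immature running
    # consensus, so a unit it rejected may fit the strict budget of the
    # final one.  Each round trims every violating unit and then strictly
    # (no slack) re-extends both ends; bounded to a few rounds.
    for _round in range(3):
        while len(units) >= 2:
            viol = _check_units(units, cons, model, mu, c)
            if viol is None:
                break
            kind, idx = viol
            # drop from whichever end is nearer the violation
            if idx < len(units) / 2:
                dropped = units.pop(0)
                start += len(dropped)
            else:
                dropped = units.pop(-1)
                end -= len(dropped)
            cons = steiner_consensus(units, model)
            if len(cons) == 0:
                return None
        if len(units) < 2:
            return None
        extended = False
        while True:
            got = _best_unit_right(seq, end, cons, model, mu * ec * c)
            if got is None:
                break
            ell, cost = got
            if cost > mu * ell * ec + _EPS:
                break
            units.append(seq[end : end + ell].copy())
            end += ell
            cons = steiner_consensus(units, model)
            extended = True
        while True:
            got = _best_unit_left(seq, start, cons, model, mu * ec * c)
            if got is None:
                break
            ell, cost = got
            if cost > mu * ell * ec + _EPS:
                break
            units.insert(0, seq[start - ell : start].copy())
            start -= ell
            cons = steiner_consensus(units, model)
            extended = True
        if not extended and _check_units(units, cons, model, mu, c) is None:
            break
    # final strict trim in case the last round's extension introduced a violation
    while len(units) >= 2:
        viol = _check_units(units, cons, model, mu, c)
        if viol is None:
            break
        _kind, idx = viol
        if idx < len(units) / 2:
            dropped = units.pop(0)
            start += len(dropped)
        else:
            dropped = units.pop(-1)
            end -= len(dropped)
        cons = steiner_consensus(units, model)
        if len(cons) == 0:
            return None
    if len(units) < 2:
        return None

    frac_len = _fractional_trailing(seq, end, cons, model, mu)
    trailing = seq[end : end + frac_len]
    lead_len = _fractional_leading(seq, start, cons, model, mu)
    leading = seq[start - lead_len : start]
    span = (end + frac_len) - (start - lead_len)
    p = len(cons)
    if p == 0 or span < min_total_len:
        return None
    copy_number = span / p
    if copy_number < 2.0:
        return None
    div = float(
        np.mean([_dist(cons, u, model) / (len(u) * ec) for u in units])
    )
    return TandemRepeat(
        seq_id=seq_id,
        start=int(start - lead_len),
        end=int(end + frac_len - 1),
        period=p,
        units=[decode_sequence(u) for u in units],
        consensus=decode_sequence(cons),
        copy_number=copy_number,
        divergence=div,
        mu=mu,
        c=c,
        trailing=decode_sequence(trailing),
        leading=decode_sequence(leading),
    )


def verify_tr(tr: TandemRepeat, model: DistanceModel, mu: float, c: float) -> bool:
    """Strictly re-check conditions (a) and (b) for a candidate repeat.

    The stored consensus serves as the existence certificate for the
    Steiner condition; the fractional trailing unit is checked pro-rata
    against consensus prefixes.
    """
    if len(tr.units) < 2:
        return False
    units = [_as_enc(u) for u in tr.units]
    cons = _as_enc(tr.consensus)
    ec = model.expected_cost
    for u in units:
        if _dist(cons, u, model) > mu * len(u) * ec + _EPS:
            return False
    for a, b in zip(units, units[1:]):
        if _dist(a, b, model) > c * mu * len(a) * ec + _EPS:
            return False
    if tr.trailing:
        frac = _as_enc(tr.trailing)
        m = _dp_matrix(cons, frac, model.costs, model.indel_cost)
        if m[1:, len(frac)].min() > mu * len(frac) * ec + _EPS:
            return False
    if tr.leading:
        frac = _as_enc(tr.leading)[::-1].copy()
        m = _dp_matrix(cons[::-1].copy(), frac, model.costs, model.indel_cost)
        if m[1:, len(frac)].min() > mu * len(frac) * ec + _EPS:
            return False
    return True


def filter_maximal(trs: list[TandemRepeat]) -> list[TandemRepeat]:
    """Drop repeats whose span is strictly enclosed by another's."""
    out = []
    for t in trs:
        enclosed = any(
            (o.start <= t.start and t.end <= o.end)
            and (o.start, o.end) != (t.start, t.end)
            for o in trs
            if o is not t
        )
        if not enclosed:
            out.append(t)
    return out


def filter_minp(trs: list[TandemRepeat]) -> list[TandemRepeat]:
    """Among identical spans keep the repeat with the shortest period."""
    best: dict[tuple[int, int], TandemRepeat] = {}
    for t in trs:
        key = (t.start, t.end)
        cur = best.get(key)
        if cur is None or t.period < cur.period:
            best[key] = t
    return sorted(best.values(), key=lambda t: (t.seq_id or "", t.start, t.period))
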