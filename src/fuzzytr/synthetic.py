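"""Synthetic sequences, shuffles, and the shuffle-based significance test.

The statistical question: are the repeats found in biological sequences
distinguishable from what the detector reports on composition-matched
random sequences?  Each sequence is paired with one uniform shuffle of
itself (identical residue multiset), the detector runs on both, and the
per-pair longest fuzzy-repeat lengths — floored at the 6-residue
reporting limit — feed a one-tailed Wilcoxon signed-rank test
(alternative: original longer than shuffled).  Pairs where neither run
reports anything are ties and are excluded; zero differences after
flooring are dropped by the standard signed-rank procedure.

The planted-repeat generator emulates the repeat-implant experiment:
a random unit copied into a random background with independent
per-position substitutions and indels at controlled rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrices import AMINO_ACIDS
from .pipeline import Config, longest_tr_length, detect_repeats

#: Robinson–Robinson average amino-acid frequencies: a standard protein
#: background composition, used when no composition is supplied.
DEFAULT_COMPOSITION = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}

#: Reporting floor for the longest-repeat observable (residues).
LENGTH_FLOOR = 6


def _composition_vector(composition) -> np.ndarray:
    if composition is None:
        composition = DEFAULT_COMPOSITION
    p = np.array([composition.get(a, 0.0) for a in AMINO_ACIDS], dtype=float)
    if p.sum() <= 0:
        raise ValueError("composition has no mass")
    return p / p.sum()


def random_sequence(length: int, composition=None, rng=None) -> str:
    """A random protein sequence with the given residue composition."""
    rng = np.random.default_rng(rng)
    p = _composition_vector(composition)
    idx = rng.choice(20, size=length, p=p)
    return "".join(AMINO_ACIDS[i] for i in idx)


def shuffle_sequence(seq: str, seed) -> str:
    """Uniform random permutation of the residues; composition is preserved."""
    rng = np.random.default_rng(seed)
    chars = np.array(list(seq))
    rng.shuffle(chars)
    return "".join(chars)


@dataclass
class SyntheticSpec:
    """Recipe for a background sequence with an implanted tandem array."""

    length: int
    unit_length: int
    copies: int
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    seed: int = 0
    composition: Mapping[str, float] | None = None
    unit: str | None = None
    start: int | None = None

    def __post_init__(self):
        for r in (self.substitution_rate, self.indel_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("mutation rates must lie in [0, 1]")


def _mutate_unit(unit_idx: np.ndarray, sub_rate, indel_rate, p, rng) -> np.ndarray:
    out = []
    for code in unit_idx:
        r = rng.random()
        if r < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(int(rng.choice(20, p=p)))  # insertion before the residue
            out.append(int(code))
        elif r < indel_rate + sub_rate:
            new = int(rng.choice(20, p=p))
            while new == code:
                new = int(rng.choice(20, p=p))
            out.append(new)
        else:
            out.append(int(code))
    return np.array(out, dtype=int)


def generate_planted_tr(spec: SyntheticSpec) -> tuple[str, tuple[int, int]]:
    """Background sequence with an implanted mutated tandem array.

    Each copy of the unit is independently mutated: per position, a
    substitution with probability ``substitution_rate`` (the replacement
    drawn from the background composition, forced to differ) and an
    indel with probability ``indel_rate`` (insertion or deletion,
    equally likely; inserted residues drawn from the composition).
    Returns the sequence and the 0-based inclusive span of the planted
    array.
    """
    rng = np.random.default_rng(spec.seed)
    p = _composition_vector(spec.composition)
    if spec.unit is not None:
        unit_idx = np.array([AMINO_ACIDS.index(a) for a in spec.unit], dtype=int)
    else:
        unit_idx = rng.choice(20, size=spec.unit_length, p=p)
    copies = [
        _mutate_unit(unit_idx, spec.substitution_rate, spec.indel_rate, p, rng)
        for _ in range(spec.copies)
    ]
    array = np.concatenate(copies) if copies else np.empty(0, dtype=int)
    if len(array) > spec.length:
        raise ValueError("planted array (%d aa) exceeds sequence length" % len(array))
    n_bg = spec.length - len(array)
    bg = rng.choice(20, size=n_bg, p=p)
    start = (
        spec.start
        if spec.start is not None
        else int(rng.integers(0, n_bg + 1))
    )
    if start > n_bg:
        raise ValueError("requested start leaves no room for the planted array")
    full = np.concatenate([bg[:start], array, bg[start:]])
    seq = "".join(AMINO_ACIDS[i] for i in full)
    return seq, (start, start + len(array) - 1)


@dataclass
class PairedObservation:
    """Longest-repeat lengths for an original/shuffle pair, floored at 6."""

    original: int
    shuffled: int
    both_empty: bool

    @classmethod
    def from_lengths(cls, orig: int, shuf: int) -> "PairedObservation":
        both_empty = orig == 0 and shuf == 0
        return cls(
            original=max(orig, LENGTH_FLOOR),
            shuffled=max(shuf, LENGTH_FLOOR),
            both_empty=both_empty,
        )


def signed_rank_p(diffs: Sequence[float]) -> float | None:
    """One-tailed Wilcoxon signed-rank p-value for positive location shift.

    Zero differences are dropped; ``None`` when no informative pairs
    remain.  Exact null enumeration for small samples without rank ties,
    normal approximation otherwise (scipy's standard policy).
    """
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    if len(d) == 0:
        return None
    res = stats.wilcoxon(d, alternative="greater", zero_method="wilcox")
    return float(res.pvalue)


def wilcoxon_shuffle_test(
    groups: Mapping[object, Sequence[str]],
    config: Config | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Shuffle-control significance of detected repeats, per length class.

    For every sequence the detector runs on the original and on one
    seeded shuffle; the longest reported repeat lengths (floored at 6)
    form the matched pair.  Returns one row per class with the number of
    pairs, excluded ties, the signed-rank statistic and the one-tailed
    p-value (``NaN`` when all pairs are ties).
    """
    config = config or Config()
    model = config.build_model()
    rows = []
    pair_counter = 0
    for label, seqs in groups.items():
        obs = []
        for s in seqs:
            shuf = shuffle_sequence(s, seed=(seed, pair_counter))
            pair_counter += 1
            lo = longest_tr_length(detect_repeats(s, config, model=model))
            ls = longest_tr_length(detect_repeats(shuf, config, model=model))
            obs.append(PairedObservation.from_lengths(lo, ls))
        kept = [o for o in obs if not o.both_empty]
        diffs = [o.original - o.shuffled for o in kept]
        nz = [d for d in diffs if d != 0]
        p = signed_rank_p(diffs)
        w = float(sum(r for r, d in _signed_ranks(nz) if d > 0)) if nz else np.nan
        rows.append(
            {
                "class": label,
                "n_pairs": len(obs),
                "ties_excluded": len(obs) - len(nz),
                "W": w,
                "p_value": np.nan if p is None else p,
            }
        )
    return pd.DataFrame(rows)


def _signed_ranks(diffs: Sequence[float]) -> list[tuple[float, float]]:
    """(rank, difference) pairs with midranks for tied magnitudes."""
    d = np.asarray(diffs, dtype=float)
    order = np.argsort(np.abs(d), kind="stable")
    ranks = np.empty(len(d))
    ranks[order] = np.arange(1, len(d) + 1)
    # midranks for ties in |d|
    absd = np.abs(d)
    for v in np.unique(absd):
        mask = absd == v
        ranks[mask] = ranks[mask].mean()
    return [(float(r), float(x)) for r, x in zip(ranks, d)]


def parameter_sweep(
    lengths: Sequence[int],
    mu_values: Sequence[float],
    c_values: Sequence[float],
    z_values: Sequence[int],
    matrix: str = "unit",
    n: int = 100,
    seed: int = 0,
    config_base: Config | None = None,
) -> pd.DataFrame:
    """Mean longest-repeat length on shuffled sequences over a parameter grid.

    For each length class, ``n`` random composition-matched sequences
    are generated once and reused across every (mu, c, z) cell, so cells
    differ only in detector parameters.  The mean counts sequences with
    no reported repeat as 0.
    """
    base = config_base or Config()
    rng = np.random.default_rng(seed)
    corpora = {
        length: [random_sequence(length, rng=rng) for _ in range(n)]
        for length in lengths
    }
    rows = []
    for mu in mu_values:
        for c in c_values:
            for z in z_values:
                config = Config(
                    matrix=matrix,
                    z=z,
                    mu=mu,
                    c=c,
                    L=base.L,
                    block_len=base.block_len,
                    h=base.h,
                    H=base.H,
                    alpha=base.alpha,
                )
                model = config.build_model()
                for length, seqs in corpora.items():
                    longest = [
                        longest_tr_length(detect_repeats(s, config, model=model))
                        for s in seqs
                    ]
                    rows.append(
                        {
                            "length": length,
                            "mu": mu,
                            "c": c,
                            "z": z,
                            "metric": matrix,
                            "mean_longest": float(np.mean(longest)),
                        }
                    )
    return pd.DataFrame(rows)


def group_by_length(seqs: Sequence[str], class_width: int = 100) -> dict[int, list[str]]:
    """Bucket sequences into length classes of the given width."""
    out: dict[int, list[str]] = {}
    for s in seqs:
        label = (len(s) // class_width) * class_width
        out.setdefault(label, []).append(s)
    return out
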