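"""End-to-end detector: blocks, scan, weighting, density, validation, report.

The detector processes each sequence in overlapping blocks so q-gram
pairs are only counted when close enough to belong to the same local
repeat; candidate extraction is allowed to extend past block boundaries
into the full parent sequence, so repeats longer than a block are still
recovered and cross-block duplicates collapse in the maximality filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .density import collect_contributors, positional_density, thin_candidates
from .matrices import DistanceModel, build_model, encode_sequence
from .seeds import enumerate_shapes, find_gapped_qgrams
from .validate import TandemRepeat, filter_maximal, filter_minp, get_tr, verify_tr
from .weighting import (
    PeriodWeightState,
    accumulate_hits,
    get_top_periods,
    multiplicity_weight,
)

logger = logging.getLogger("fuzzytr")

#: Columns of the tab-separated repeat table.
REPORT_COLUMNS = [
    "seq_id",
    "start",
    "end",
    "period",
    "copy_number",
    "total_length",
    "consensus",
    "divergence",
]


@dataclass
class Config:
    """Detector configuration.

    Defaults follow the reference parameterization: divergence budget
    ``mu = 0.3`` with pair constant ``c = 1.5`` (use ``c = 2`` for a
    low-divergence mode), 50 candidate periods, 2000-residue blocks with
    half-block overlap, per-probe hit bound ``h = 5`` and anti-smear
    queue capacity ``H = 20``, density threshold at ``alpha`` times the
    mean window density.
    """

    matrix: str = "BLOSUM50"
    z: int = 3
    mu: float = 0.3
    c: float = 1.5
    L: int = 50
    block_len: int = 2000
    block_overlap: int | None = None  # default: block_len // 2
    h: int = 5
    H: int = 20
    alpha: float = 1.0
    include_2gram: bool = False
    min_total_len: int = 6
    indel_cost: float = 1.0
    background: Mapping[str, float] | None = None
    slack: float = 1.2

    def __post_init__(self):
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must lie in [0, 1]")
        if not (1.0 <= self.c <= 2.0):
            raise ValueError("c must lie in [1, 2]")
        for name in ("z", "L", "block_len", "h", "H", "min_total_len"):
            if getattr(self, name) < 1:
                raise ValueError("%s must be positive" % name)
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def overlap(self) -> int:
        return self.block_len // 2 if self.block_overlap is None else self.block_overlap

    def build_model(self) -> DistanceModel:
        return build_model(
            self.matrix, indel_cost=self.indel_cost, background=self.background
        )


def _blocks(n: int, block_len: int, overlap: int) -> list[int]:
    """Block start offsets covering [0, n) with the requested overlap."""
    if n <= block_len:
        return [0]
    step = max(1, block_len - overlap)
    starts = list(range(0, n - overlap, step))
    return starts


def _covered(candidate_k: int, candidate_i: int, accepted: list[TandemRepeat]) -> bool:
    """Skip a candidate lying wholly inside an accepted repeat of a
    compatible (equal or divisor) period — the filters would drop its
    repeat anyway."""
    j = candidate_i + candidate_k - 1
    for t in accepted:
        if t.start <= candidate_i and j <= t.end and candidate_k == t.period:
            return True
    return False


def detect_repeats(
    seq: str,
    config: Config | None = None,
    seq_id: str | None = None,
    model: DistanceModel | None = None,
) -> list[TandemRepeat]:
    """Detect fuzzy tandem repeats in one protein sequence.

    Returns validated repeats in parent-sequence coordinates, sorted by
    start position, already de-duplicated, maximality- and
    shortest-period-filtered.  Deterministic: identical input and
    configuration give identical output.
    """
    config = config or Config()
    if model is None:
        model = config.build_model()
    shapes = enumerate_shapes(include_2gram=config.include_2gram)
    enc = encode_sequence(seq)
    n = len(enc)
    if n <= min(s.span for s in shapes) + 1:
        logger.warning("sequence %s shorter than the smallest seed; skipped", seq_id)
        return []

    accepted: list[TandemRepeat] = []
    seen_spans: set[tuple[int, int, int]] = set()
    for offset in _blocks(n, config.block_len, config.overlap):
        block = enc[offset : offset + config.block_len]
        hits = find_gapped_qgrams(block, shapes, config.z, model, h_next=config.h)
        if not len(hits):
            continue
        state = PeriodWeightState(h=config.h, H=config.H, L=config.L)
        accumulate_hits(state, hits)
        multiplicity_weight(state)
        for k in get_top_periods(state):
            contributors = collect_contributors(hits, k)
            pairs = thin_candidates(
                positional_density(len(block), k, contributors, config.alpha)
            )
            for _, i_local in pairs:
                i_global = offset + i_local
                if _covered(k, i_global, accepted):
                    continue
                tr = get_tr(
                    enc,
                    k,
                    i_global,
                    model,
                    mu=config.mu,
                    c=config.c,
                    seq_id=seq_id,
                    slack=config.slack,
                    min_total_len=config.min_total_len,
                )
                if tr is None:
                    continue
                if not verify_tr(tr, model, config.mu, config.c):
                    continue
                key = (tr.start, tr.end, tr.period)
                if key in seen_spans:
                    continue
                seen_spans.add(key)
                accepted.append(tr)
    out = filter_minp(filter_maximal(accepted))
    out.sort(key=lambda t: (t.start, t.period))
    return out


def detect_fasta(
    path,
    config: Config | None = None,
    one_based: bool = False,
) -> pd.DataFrame:
    """Run the detector over a FASTA file; one table row per repeat."""
    config = config or Config()
    model = config.build_model()
    rows = []
    results: dict[str, list[TandemRepeat]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        trs = detect_repeats(str(rec.seq), config, seq_id=rec.id, model=model)
        results[rec.id] = trs
        for t in trs:
            rows.append(_tr_row(t, one_based))
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.attrs["n_sequences"] = len(results)
    return df


def _tr_row(t: TandemRepeat, one_based: bool = False) -> dict:
    off = 1 if one_based else 0
    return {
        "seq_id": t.seq_id,
        "start": t.start + off,
        "end": t.end + off,
        "period": t.period,
        "copy_number": round(t.copy_number, 1),
        "total_length": t.total_length,
        "consensus": t.consensus,
        "divergence": round(t.divergence, 4),
    }


def trs_to_table(trs: Iterable[TandemRepeat], one_based: bool = False) -> pd.DataFrame:
    return pd.DataFrame([_tr_row(t, one_based) for t in trs], columns=REPORT_COLUMNS)


def scan_summary(
    results: Mapping[str, list[TandemRepeat]] | pd.DataFrame,
    min_len: int = 14,
    n_sequences: int | None = None,
) -> float:
    """Percentage of sequences containing a repeat of total length >= ``min_len``.

    ``results`` is either a mapping sequence id -> repeats (the
    denominator is its size) or a repeat table (then ``n_sequences``
    supplies the denominator; defaults to the distinct ids present).
    """
    if isinstance(results, pd.DataFrame):
        if results.empty:
            hit_ids: set = set()
            total = n_sequences or results.attrs.get("n_sequences", 0)
        else:
            hit_ids = set(results.loc[results["total_length"] >= min_len, "seq_id"])
            total = (
                n_sequences
                or results.attrs.get("n_sequences")
                or results["seq_id"].nunique()
            )
    else:
        hit_ids = {
            sid
            for sid, trs in results.items()
            if any(t.total_length >= min_len for t in trs)
        }
        total = n_sequences or len(results)
    if not total:
        raise ValueError("empty corpus: no sequences to summarize")
    return 100.0 * len(hit_ids) / total


def longest_tr_length(trs: list[TandemRepeat]) -> int:
    """Total length of the longest reported repeat, 0 when none."""
    return max((t.total_length for t in trs), default=0)


def with_params(config: Config, **kwargs) -> Config:
    """A copy of ``config`` with fields replaced."""
    return replace(config, **kwargs)
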