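"""Target-decoy competition filtering of PrSMs.

Identifications are filtered at the PrSM level: matches against a decoy
proteome (reversed sequences, ``DECOY_``-prefixed accessions) estimate the
false-match rate among targets at any score threshold, and the filter keeps
the largest accepted set whose estimated FDR stays at or below q (1% by
default).  Scores are larger-is-better; the conventional choice for search
engine output is -log10 of the E-value.
"""

from __future__ import annotations

import math
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .prsm_io import DECOY_PREFIX, PrSMRecord


class ScoredMatch(NamedTuple):
    prsm_id: int
    score: float
    is_decoy: bool


def score_from_evalue(e_value: float) -> float:
    return -math.log10(e_value)


def scored_matches(records: Iterable[PrSMRecord]) -> list[ScoredMatch]:
    return [
        ScoredMatch(r.prsm_id, score_from_evalue(r.e_value), r.is_decoy)
        for r in records
    ]


def generate_decoy(
    proteome: dict[str, str],
    method: str = "reverse",
    seed: int | None = None,
) -> dict[str, str]:
    """One decoy per target protein, composition preserved.

    ``reverse`` (default, deterministic) reverses each sequence; ``shuffle``
    permutes it with a seeded generator.
    """
    if method == "reverse":
        return {DECOY_PREFIX + acc: seq[::-1] for acc, seq in proteome.items()}
    if method == "shuffle":
        rng = np.random.default_rng(seed)
        out = {}
        for acc, seq in proteome.items():
            letters = list(seq)
            rng.shuffle(letters)
            out[DECOY_PREFIX + acc] = "".join(letters)
        return out
    raise ValueError(f"unknown decoy method {method!r}")


def fdr_filter(matches: Sequence[ScoredMatch], q: float = 0.01) -> list[int]:
    """PrSM ids accepted at estimated FDR <= q.

    Matches are ranked by descending score; at each candidate threshold the
    FDR estimate is (#decoys >= threshold) / max(1, #targets >= threshold)
    (plain count ratio, no +1 correction).  The threshold retaining the most
    targets while keeping the estimate at or below q wins; decoys are never
    returned.  Accepted ids come back in descending-score order.
    """
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    ranked = sorted(matches, key=lambda m: m.score, reverse=True)
    best_n_targets = 0
    n_targets = n_decoys = 0
    idx = 0
    while idx < len(ranked):
        threshold = ranked[idx].score
        # consume the whole tie group so a threshold never splits equal scores
        while idx < len(ranked) and ranked[idx].score == threshold:
            if ranked[idx].is_decoy:
                n_decoys += 1
            else:
                n_targets += 1
            idx += 1
        if n_decoys / max(1, n_targets) <= q:
            best_n_targets = max(best_n_targets, n_targets)
    return [m.prsm_id for m in ranked if not m.is_decoy][:best_n_targets]


def filter_records(records: Sequence[PrSMRecord], q: float = 0.01) -> list[PrSMRecord]:
    """Apply the PrSM-level FDR filter; row order of the input is preserved."""
    accepted = set(fdr_filter(scored_matches(records), q))
    return [r for r in records if r.prsm_id in accepted]
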