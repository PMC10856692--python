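"""Strand-aware PWM scanning and motif-pair enumeration.

A sequence is reduced, for a given PWM pair, to the set of candidate module
occurrences: triples ``(s1, s2, gap)`` where ``s1``/``s2`` are the normalized
scores of a PWM1 and a PWM2 occurrence and ``gap`` is the nearest-edge
distance in nucleotides between them (0 = adjacent; overlapping occurrences
are never paired).  Pairs are unordered in sequence position — either motif
may lie upstream — and every strand combination is allowed.

Coordinates are 0-based half-open internally; reverse-strand hits are
reported by the forward-strand start of the occupied interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import PWM, SequenceRecord

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N


@dataclass(frozen=True)
class Hit:
    """A scored PWM occurrence on one strand of one sequence."""

    seq_index: int
    start: int  # 0-based, forward-strand coordinate of the occupied interval
    strand: str  # "+" or "-"
    score: float  # normalized, in [0, 1]


@dataclass(frozen=True)
class PairTriple:
    """A candidate module occurrence reduced to its searchable coordinates."""

    s1: float
    s2: float
    gap: int


def encode(seq: str) -> np.ndarray:
    """Sequence -> int8 codes (A=0, C=1, G=2, T=3, anything else=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Raw additive score of every window; NaN where the window contains N.

    Accumulates one position at a time so that the summation order matches
    the scalar scorer in :func:`crmscan.io.normalized_score` bit for bit.
    """
    width = weights.shape[0]
    n_win = len(codes) - width + 1
    if n_win <= 0:
        return np.empty(0)
    # pad weights with an N column that poisons the sum
    w = np.hstack([weights, np.full((width, 1), np.nan)])
    raw = np.zeros(n_win)
    for p in range(width):
        raw += w[p, codes[p : p + n_win]]
    return raw


def scan_pwm(pwm: PWM, record: SequenceRecord, floor: float,
             seq_index: int = 0) -> list[Hit]:
    """All occurrences of ``pwm`` on both strands with normalized score >= floor.

    A reverse-strand occurrence is the forward matrix matching the
    reverse-complemented sequence; it is reported by the forward-strand start
    of the occupied interval ``[start, start + width)`` and scored by applying
    the matrix to the reverse-complemented window in forward matrix order.
    This makes reverse-complementing a whole sequence swap the two strands'
    scores bit for bit.  Windows containing N are skipped.  A sequence
    shorter than the matrix yields an empty list.
    """
    if not 0.0 <= floor <= 1.0:
        raise ValueError(f"floor must be in [0, 1], got {floor}")
    codes = encode(record.residues)
    rc_codes = _COMP[codes][::-1]
    span = pwm.raw_max - pwm.raw_min
    width = pwm.width
    last = len(codes) - width  # forward start of the last window
    hits: list[Hit] = []
    for strand, strand_codes in (("+", codes), ("-", rc_codes)):
        raw = _window_scores(strand_codes, pwm.weights)
        if raw.size == 0:
            continue
        norm = (raw - pwm.raw_min) / span
        with np.errstate(invalid="ignore"):
            keep = norm >= floor  # NaN (N windows) compares False
        for q in np.flatnonzero(keep):
            start = int(q) if strand == "+" else last - int(q)
            hits.append(Hit(seq_index, start, strand, float(norm[q])))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def pair_triples(hits1: Sequence[Hit], hits2: Sequence[Hit], w1: int, w2: int,
                 d_max: int, homotypic: bool = False) -> list[PairTriple]:
    """Enumerate co-occurrences of a PWM1 and a PWM2 hit with gap <= d_max.

    ``gap`` is the nearest-edge distance: start of the downstream occurrence
    minus end (exclusive) of the upstream one.  Overlapping occurrences (gap
    would be negative) are excluded.  With ``homotypic=True`` the two hit
    lists describe the same PWM and an occurrence is never paired with
    itself; both orderings of two distinct occurrences are emitted, which
    keeps the (s1, s2) threshold test symmetric.
    """
    if d_max < 0:
        raise ValueError("d_max must be >= 0")
    out: list[PairTriple] = []
    for h1 in hits1:
        e1 = h1.start + w1
        for h2 in hits2:
            if homotypic and h1.start == h2.start and h1.strand == h2.strand:
                continue
            gap = max(h2.start - e1, h1.start - (h2.start + w2))
            if 0 <= gap <= d_max:
                out.append(PairTriple(h1.score, h2.score, gap))
    return out


def pair_triples_arrays(hits1: Sequence[Hit], hits2: Sequence[Hit], w1: int,
                        w2: int, d_max: int, homotypic: bool = False,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`pair_triples`: column arrays (s1, s2, gap).

    Same pairing rules; the triples come out in (hits1-major) row order,
    which downstream grid construction does not depend on.
    """
    if d_max < 0:
        raise ValueError("d_max must be >= 0")
    if not hits1 or not hits2:
        return np.empty(0), np.empty(0), np.empty(0, dtype=int)
    st1 = np.array([h.start for h in hits1])[:, None]
    st2 = np.array([h.start for h in hits2])[None, :]
    gap = np.maximum(st2 - (st1 + w1), st1 - (st2 + w2))
    mask = (gap >= 0) & (gap <= d_max)
    if homotypic:
        sd1 = np.array([h.strand == "+" for h in hits1])[:, None]
        sd2 = np.array([h.strand == "+" for h in hits2])[None, :]
        mask &= ~((st1 == st2) & (sd1 == sd2))
    sc1 = np.array([h.score for h in hits1])[:, None]
    sc2 = np.array([h.score for h in hits2])[None, :]
    rows, cols = np.nonzero(mask)
    return sc1[rows, 0], sc2[0, cols], gap[rows, cols]


def triples_arrays(triples: Sequence[PairTriple]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column arrays (s1, s2, gap) for vectorized grid construction."""
    if not triples:
        return np.empty(0), np.empty(0), np.empty(0, dtype=int)
    s1 = np.array([t.s1 for t in triples])
    s2 = np.array([t.s2 for t in triples])
    gap = np.array([t.gap for t in triples], dtype=int)
    return s1, s2, gap


def write_bed6(hits: Iterable[Hit], pwm: PWM, seq_ids: Sequence[str],
               path: str | Path) -> None:
    """Export hits as BED6 (0-based half-open; score scaled to 0-1000)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{seq_ids[h.seq_index]}\t{h.start}\t{h.start + pwm.width}\t"
                f"{pwm.name}\t{round(h.score * 1000)}\t{h.strand}\n"
            )
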