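"""Promoter-set and PWM-library input/output.

Sequences are plain FASTA over {A, C, G, T, N}.  PWM libraries are read in
JASPAR four-row format or TRANSFAC-style blocks; both go through Biopython's
``Bio.motifs`` parsers and are converted to a single internal representation:
an additive per-position weight matrix with precomputed raw score extrema, so
that every downstream score can be min-max normalized to [0, 1] (1.0 = best
possible word, 0.0 = worst possible word).

Matrices whose entries are all non-negative are interpreted as nucleotide
counts and converted to log-odds against a uniform background with a
pseudocount of 0.25 per cell: ``w = log2((c + 0.25) / (total + 1) / 0.25)``.
Matrices containing negative entries are taken to be additive weights already
and are used verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO, motifs as bio_motifs

ALPHABET = "ACGT"
#: Column order of every weight matrix; N is accepted in sequences but never scored.
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UNSCORABLE = None  # sentinel for windows containing N


class FormatError(ValueError):
    """Raised for malformed FASTA or matrix input."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A single promoter sequence (uppercase, {A,C,G,T,N})."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set("ACGTN")
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains non-nucleotide character(s) "
                f"{sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PromoterSet:
    """An ordered, labelled collection of promoter sequences."""

    label: str  # "positive" or "negative"
    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be 'positive' or 'negative', got {self.label!r}")
        if not self.records:
            raise FormatError(f"empty set: {self.label} promoter set has no sequences")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise FormatError(f"duplicate sequence id {rec.id!r} in {self.label} set")
            seen.add(rec.id)

    @property
    def n(self) -> int:
        return len(self.records)

    def reverse_complemented(self) -> "PromoterSet":
        """Same set with every sequence reverse-complemented (used in tests)."""
        return PromoterSet(
            self.label,
            tuple(SequenceRecord(r.id, reverse_complement(r.residues)) for r in self.records),
        )


def read_fasta(path: str | Path, label: str = "positive") -> PromoterSet:
    """Read a promoter set from a FASTA file.

    Residues are uppercased; N is allowed.  Raises :class:`FormatError` on an
    empty file, duplicate ids, or non-nucleotide characters.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"empty set: no FASTA records in {path}")
    return PromoterSet(label, tuple(records))


def write_fasta(pset: PromoterSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in pset.records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# position weight matrices
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class PWM:
    """An additive position weight matrix with min-max score normalization.

    ``weights`` has shape (width, 4), columns ordered A, C, G, T.  ``raw_min``
    / ``raw_max`` are the sums of per-position minima / maxima, so the
    normalized score ``(raw - raw_min) / (raw_max - raw_min)`` maps the best
    possible word to 1.0 and the worst to 0.0.
    """

    name: str
    weights: np.ndarray
    raw_min: float = field(init=False)
    raw_max: float = field(init=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4:
            raise FormatError(f"matrix {self.name!r}: need 4 values per position")
        if w.shape[0] < 1:
            raise FormatError(f"matrix {self.name!r}: zero width")
        self.weights = w
        self.raw_min = float(w.min(axis=1).sum())
        self.raw_max = float(w.max(axis=1).sum())
        if not self.raw_max > self.raw_min:
            raise FormatError(f"matrix {self.name!r}: degenerate score range")

    @property
    def width(self) -> int:
        return self.weights.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.weights.argmax(axis=1))

    def reverse_complement(self, name: str | None = None) -> "PWM":
        """The matrix scoring the reverse-complement motif on the forward strand."""
        rc = PWM(name or f"{self.name}_rc", self.weights[::-1, ::-1].copy())
        # the extrema are the same per-position values summed in reverse order;
        # pin them to the source's so both strands normalize identically
        rc.raw_min = self.raw_min
        rc.raw_max = self.raw_max
        return rc


def normalized_score(pwm: PWM, window: str) -> float | None:
    """Min-max normalized additive score of ``window`` under ``pwm``.

    Returns :data:`UNSCORABLE` (None) if the window contains N; raises on a
    length mismatch.  The sum is accumulated position by position so that the
    vectorized scanner, which adds per-position columns in the same order,
    produces bit-identical scores.
    """
    if len(window) != pwm.width:
        raise ValueError(
            f"window length {len(window)} != width {pwm.width} of {pwm.name!r}"
        )
    raw = 0.0
    w = pwm.weights
    for p, base in enumerate(window):
        idx = BASE_INDEX.get(base)
        if idx is None or idx == 4:
            return UNSCORABLE
        raw += w[p, idx]
    return (raw - pwm.raw_min) / (pwm.raw_max - pwm.raw_min)


def _counts_to_weights(mat: np.ndarray) -> np.ndarray:
    """Counts -> log2 odds vs uniform background, pseudocount 0.25 per cell."""
    totals = mat.sum(axis=1, keepdims=True)
    freq = (mat + 0.25) / (totals + 1.0)
    return np.log2(freq / 0.25)


def _from_parsed_matrix(name: str, mat: np.ndarray) -> PWM:
    if np.min(mat) >= 0:
        mat = _counts_to_weights(mat)
    return PWM(name, mat)


def read_pwm_library(path: str | Path, dialect: str = "jaspar") -> list[PWM]:
    """Read a PWM library in ``jaspar`` or ``transfac`` dialect.

    Count matrices are converted to log-odds weights (see module docstring);
    matrices already containing negative entries are kept as weights.  Names
    come from the JASPAR header (matrix id, plus name if present) or the
    TRANSFAC ID/AC lines.
    """
    if dialect not in ("jaspar", "transfac"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        with open(path) as fh:
            parsed = list(bio_motifs.parse(fh, dialect))
    except FormatError:
        raise
    except Exception as exc:  # biopython raises bare Exception for ragged input
        raise FormatError(f"cannot parse {path} as {dialect}: {exc}") from exc
    if not parsed:
        raise FormatError(f"no matrices found in {path}")
    pwms = []
    for m in parsed:
        if dialect == "jaspar":
            name = m.matrix_id or m.name or f"matrix_{len(pwms) + 1}"
            if m.matrix_id and m.name and m.name != m.matrix_id:
                name = f"{m.matrix_id} {m.name}"
        else:
            name = m.get("ID") or m.get("AC") or f"matrix_{len(pwms) + 1}"
        try:
            mat = np.array([list(m.counts[b]) for b in ALPHABET], dtype=float).T
        except Exception as exc:
            raise FormatError(f"matrix {name!r}: inconsistent columns ({exc})") from exc
        if mat.shape[0] == 0:
            raise FormatError(f"matrix {name!r}: zero width")
        pwms.append(_from_parsed_matrix(name, mat))
    names = [p.name for p in pwms]
    if len(set(names)) != len(names):
        raise FormatError(f"duplicate matrix names in {path}")
    return pwms


def write_pwm_library(pwms: Iterable[PWM], path: str | Path) -> None:
    """Serialize weight matrices in JASPAR four-row layout (full precision).

    Weights are written as-is (typically containing negatives), so re-reading
    the file reproduces the same matrices without a second count conversion.
    """
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for bi, base in enumerate(ALPHABET):
                row = " ".join(repr(float(v)) for v in pwm.weights[:, bi])
                fh.write(f"{base} [ {row} ]\n")


def library_summary_tsv(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\twidth\traw_min\traw_max\n")
        for p in pwms:
            fh.write(f"{p.name}\t{p.width}\t{p.raw_min:.6g}\t{p.raw_max:.6g}\n")


def pwm_from_consensus(name: str, consensus: str, dominance: float = 0.85,
                       total: int = 100) -> PWM:
    """Build a count-derived PWM whose consensus is ``consensus``.

    At each position the consensus base receives ``dominance`` of ``total``
    pseudo-observations; the rest is split evenly over the other three bases.
    Useful for simulations and demonstrations.
    """
    consensus = consensus.upper()
    if not consensus or set(consensus) - set(ALPHABET):
        raise ValueError(f"consensus must be a non-empty string over {ALPHABET}")
    if not 0.25 < dominance <= 1.0:
        raise ValueError("dominance must be in (0.25, 1]")
    counts = np.full((len(consensus), 4), total * (1 - dominance) / 3.0)
    for p, base in enumerate(consensus):
        counts[p, BASE_INDEX[base]] = total * dominance
    return _from_parsed_matrix(name, counts)
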