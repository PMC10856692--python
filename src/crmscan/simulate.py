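"""Synthetic promoter sets with implanted motif pairs and ground truth.

The generator emulates the structure of a promoter discrimination
experiment: i.i.d. background sequences of fixed length, with a controlled
fraction of each set carrying exactly one implanted pair of motif words —
sampled from the PWMs' position distributions, rejection-sampled to a
minimum normalized score, placed in random order and orientation with a
uniformly drawn gap.  Implants overwrite the background (sequence length is
preserved) and every implant is recorded with its coordinates, so search
output can be checked against truth down to the nucleotide.

One seeded generator drives all sampling: a spec run twice produces
byte-identical FASTA and truth output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (ALPHABET, PWM, PromoterSet, SequenceRecord, normalized_score,
                 reverse_complement, write_fasta)


@dataclass(frozen=True)
class ImplantRecord:
    """Ground truth for one implanted motif word (0-based half-open)."""

    seq_id: str
    pwm_name: str
    start: int
    end: int
    strand: str
    score: float
    gap: int  # nearest-edge distance to the partner implant


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic positive/negative experiment.

    Defaults describe the standard recovery scenario: 30 + 30 promoters of
    500 nt on a uniform background, the pair implanted in 90% of positives
    and no negatives, words at normalized score >= 0.95, gaps uniform in
    [0, 50].
    """

    pwm_pair: tuple[str, str]
    n_pos: int = 30
    n_neg: int = 30
    seq_len: int = 500
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    implant_fraction_pos: float = 0.9
    implant_fraction_neg: float = 0.0
    gap_range: tuple[int, int] = (0, 50)
    strength: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("set sizes must be >= 1")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) < 0:
            raise ValueError("background must be non-negative and sum to 1")
        for f in (self.implant_fraction_pos, self.implant_fraction_neg):
            if not 0.0 <= f <= 1.0:
                raise ValueError("implant fractions must be in [0, 1]")
        lo, hi = self.gap_range
        if not 0 <= lo <= hi:
            raise ValueError("gap_range must satisfy 0 <= min <= max")
        if not 0.0 < self.strength <= 1.0:
            raise ValueError("strength must be in (0, 1]")


def sample_motif_word(pwm: PWM, strength: float, rng: np.random.Generator,
                      max_tries: int = 10_000) -> tuple[str, float]:
    """A word drawn from the PWM's per-position base distribution with
    normalized score >= strength (rejection sampling)."""
    freqs = 0.25 * np.power(2.0, pwm.weights)
    freqs /= freqs.sum(axis=1, keepdims=True)
    for _ in range(max_tries):
        idx = [rng.choice(4, p=freqs[p]) for p in range(pwm.width)]
        word = "".join(ALPHABET[i] for i in idx)
        score = normalized_score(pwm, word)
        if score >= strength:
            return word, float(score)
    raise RuntimeError(
        f"could not sample a word of {pwm.name!r} at strength {strength} "
        f"in {max_tries} tries; lower strength or sharpen the matrix")


def _implant_pair(seq: list[str], pwm_a: PWM, pwm_b: PWM, spec: SyntheticSpec,
                  rng: np.random.Generator, seq_id: str) -> list[ImplantRecord]:
    gap = int(rng.integers(spec.gap_range[0], spec.gap_range[1] + 1))
    order = [(pwm_a, *sample_motif_word(pwm_a, spec.strength, rng)),
             (pwm_b, *sample_motif_word(pwm_b, spec.strength, rng))]
    if rng.random() < 0.5:
        order.reverse()
    span = order[0][0].width + gap + order[1][0].width
    if span > spec.seq_len:
        raise ValueError(
            f"seq_len {spec.seq_len} too small for both motifs plus gap {gap}")
    start = int(rng.integers(0, spec.seq_len - span + 1))
    records = []
    pos = start
    for pwm, word, score in order:
        strand = "+" if rng.random() < 0.5 else "-"
        placed = word if strand == "+" else reverse_complement(word)
        seq[pos : pos + pwm.width] = placed
        records.append(ImplantRecord(seq_id, pwm.name, pos, pos + pwm.width,
                                     strand, score, gap))
        pos += pwm.width + gap
    return records


def _random_background(n: int, spec: SyntheticSpec,
                       rng: np.random.Generator) -> list[list[str]]:
    bases = np.array(list(ALPHABET))
    return [list(bases[rng.choice(4, size=spec.seq_len, p=list(spec.background))])
            for _ in range(n)]


def generate_sets(spec: SyntheticSpec, library: Sequence[PWM],
                  ) -> tuple[PromoterSet, PromoterSet, list[ImplantRecord]]:
    """Positive and negative sets per ``spec``, with truth annotations.

    Each sequence independently carries an implant pair with probability
    equal to its set's implant fraction.  Fully reproducible from
    ``spec.seed``.
    """
    by_name = {p.name: p for p in library}
    try:
        pwm_a, pwm_b = (by_name[n] for n in spec.pwm_pair)
    except KeyError as exc:
        raise ValueError(f"unknown PWM name {exc.args[0]!r}") from None
    min_span = pwm_a.width + pwm_b.width + spec.gap_range[1]
    if spec.seq_len < min_span:
        raise ValueError(
            f"seq_len {spec.seq_len} too small: need >= {min_span} for both "
            "motifs plus max_gap")
    rng = np.random.default_rng(spec.seed)
    truth: list[ImplantRecord] = []
    sets = []
    for label, n, frac, prefix in (
            ("positive", spec.n_pos, spec.implant_fraction_pos, "pos"),
            ("negative", spec.n_neg, spec.implant_fraction_neg, "neg")):
        seqs = _random_background(n, spec, rng)
        records = []
        for i, seq in enumerate(seqs):
            sid = f"{prefix}_{i + 1:03d}"
            if rng.random() < frac:
                truth.extend(_implant_pair(seq, pwm_a, pwm_b, spec, rng, sid))
            records.append(SequenceRecord(sid, "".join(seq)))
        sets.append(PromoterSet(label, tuple(records)))
    return sets[0], sets[1], truth


def self_correlated_fixture(spec: SyntheticSpec, library: Sequence[PWM],
                            ) -> tuple[PromoterSet, PromoterSet,
                                       list[ImplantRecord], list[PWM]]:
    """Sets where a motif is paired with its own exact reverse complement.

    The first PWM named in ``spec.pwm_pair`` is duplicated as its
    reverse-complement matrix (suffix ``_rc``) and the pair (motif, motif_rc)
    is implanted at ``implant_fraction_pos`` in the positive set and
    ``implant_fraction_neg`` in the negative set.  With equal fractions in
    both sets this reproduces the correlated-PWM situation in which the
    negative-set constraint must suppress the pair; returns the augmented
    library alongside the sets.
    """
    if not library:
        raise ValueError("empty PWM library")
    by_name = {p.name: p for p in library}
    base_name = spec.pwm_pair[0]
    if base_name not in by_name:
        raise ValueError(f"unknown PWM name {base_name!r}")
    base = by_name[base_name]
    rc = base.reverse_complement()
    augmented = list(library) + [rc]
    spec_rc = dataclasses.replace(spec, pwm_pair=(base.name, rc.name))
    pos, neg, truth = generate_sets(spec_rc, augmented)
    return pos, neg, truth, augmented


# ---------------------------------------------------------------------------
# randomized micro-instances (for oracle-equivalence checks)
# ---------------------------------------------------------------------------

def random_micro_instance(rng: np.random.Generator, n_pwms: int = 2,
                          n_pos: int = 5, n_neg: int = 5, seq_len: int = 160,
                          width_range: tuple[int, int] = (4, 6),
                          ) -> tuple[PromoterSet, PromoterSet, list[PWM]]:
    """A small random search instance: random count-derived PWMs and random
    uniform-background sequences (no implants), suitable for comparing the
    accelerated search against the brute-force reference."""
    pwms = []
    for m in range(n_pwms):
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        counts = rng.dirichlet(np.full(4, 0.8), size=width) * 100
        pwms.append(PWM(f"pwm_{m + 1}", np.log2(((counts + 0.25) /
                                                 (counts.sum(1, keepdims=True) + 1)) / 0.25)))
    bases = np.array(list(ALPHABET))
    def mkset(label, prefix, n):
        recs = tuple(
            SequenceRecord(f"{prefix}_{i + 1}",
                           "".join(bases[rng.integers(0, 4, size=seq_len)]))
            for i in range(n))
        return PromoterSet(label, recs)
    return mkset("positive", "p", n_pos), mkset("negative", "n", n_neg), pwms


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_truth_tsv(truth: Sequence[ImplantRecord], path: str | Path) -> None:
    """BED-like truth table (0-based half-open coordinates)."""
    with open(path, "w") as fh:
        fh.write("seq_id\tpwm\tstart\tend\tstrand\tscore\tgap_to_partner\n")
        for r in truth:
            fh.write(f"{r.seq_id}\t{r.pwm_name}\t{r.start}\t{r.end}\t"
                     f"{r.strand}\t{r.score:.4f}\t{r.gap}\n")


def write_manifest(spec: SyntheticSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(spec), indent=2) + "\n")


def write_fixture(spec: SyntheticSpec, library: Sequence[PWM],
                  out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the full fixture: two FASTAs, truth TSV, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pos, neg, truth = generate_sets(spec, library)
    paths = {
        "pos": out / "positive.fasta",
        "neg": out / "negative.fasta",
        "truth": out / "truth.tsv",
        "manifest": out / "manifest.json",
    }
    write_fasta(pos, paths["pos"])
    write_fasta(neg, paths["neg"])
    write_truth_tsv(truth, paths["truth"])
    write_manifest(spec, paths["manifest"])
    return paths
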