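"""Reference brute-force search and nucleotide-level prediction metrics.

:func:`brute_force_search` re-derives, for every PWM pair and every grid
cell, the presence values by direct per-sequence evaluation — no cumulative
grids, no pruning — and optimizes with explicit per-cell comparisons.  It is
deliberately written against the plain definitions so it can serve as an
independent correctness oracle for the accelerated search; a cell-count
ceiling guards against accidentally enumerating a full-size instance.

:func:`evaluate_predictions` scores predicted module intervals against
ground truth per nucleotide: every position of every sequence is classified
TP/FP/TN/FN by membership in the truth and prediction unions, and the usual
derived measures are reported — sensitivity Sn = TP/(TP+FN), specificity
Sp = TN/(TN+FP), positive predictive value PPV = TP/(TP+FP), performance
coefficient PC = TP/(TP+FN+FP), average site performance ASP = (Sn+PPV)/2,
and the nucleotide-level (Matthews) correlation coefficient
nCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)).
A metric whose denominator is zero is reported as None (undefined), never
coerced to 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import PWM, PromoterSet, normalized_score
from .search import CRMConfig, SearchParams, SearchResult

Interval = tuple[int, int]  # 0-based half-open


# ---------------------------------------------------------------------------
# brute-force search oracle
# ---------------------------------------------------------------------------

def _naive_hits(pwm: PWM, residues: str, floor: float) -> list[tuple[int, str, float]]:
    """(start, strand, score) of every window scoring >= floor, both strands.

    The reverse strand scores the reverse-complemented window with the
    forward matrix, matching the scanner's convention.
    """
    from .io import reverse_complement
    out = []
    for start in range(len(residues) - pwm.width + 1):
        window = residues[start : start + pwm.width]
        for strand, oriented in (("+", window), ("-", reverse_complement(window))):
            s = normalized_score(pwm, oriented)
            if s is not None and s >= floor:
                out.append((start, strand, s))
    return out


def _naive_triples(h1: list, h2: list, w1: int, w2: int, d_max: int,
                   homotypic: bool) -> list[tuple[float, float, int]]:
    trips = []
    for a_start, a_strand, a_score in h1:
        for b_start, b_strand, b_score in h2:
            if homotypic and a_start == b_start and a_strand == b_strand:
                continue
            gap = max(b_start - (a_start + w1), a_start - (b_start + w2))
            if 0 <= gap <= d_max:
                trips.append((a_score, b_score, gap))
    return trips


def _better(cand: tuple, best: tuple) -> bool:
    """Is candidate (ratio, c_pos, d, thr1, thr2) preferable?  Explicit
    restatement of the documented tie-break chain for one fixed pair."""
    r_c, cp_c, d_c, t1_c, t2_c = cand
    r_b, cp_b, d_b, t1_b, t2_b = best
    if r_c != r_b:
        return r_c > r_b
    if cp_c != cp_b:
        return cp_c > cp_b
    if t1_c + t2_c != t1_b + t2_b:
        return t1_c + t2_c > t1_b + t2_b
    if d_c != d_b:
        return d_c < d_b
    return t1_c < t1_b


def brute_force_search(pos: PromoterSet, neg: PromoterSet,
                       library: Sequence[PWM], params: SearchParams,
                       cell_ceiling: int = 20_000_000) -> list[SearchResult]:
    """Exhaustive reference search: every pair, every cell, direct re-scan.

    Contract-identical to :func:`crmscan.search.search_all_pairs`.  Refuses
    instances where pairs x cells x sequences exceeds ``cell_ceiling``.
    """
    if not library:
        raise ValueError("empty PWM library")
    grids = params.grids
    thr = grids.thr_values
    dist = grids.dist_values
    n_pairs = len(library) * (len(library) + 1) // 2
    work = n_pairs * len(thr) * len(thr) * len(dist) * (pos.n + neg.n)
    if work > cell_ceiling:
        raise ValueError(
            f"instance too large for brute force ({work} > {cell_ceiling} "
            "cell-sequence evaluations); raise cell_ceiling explicitly to override")
    floor = thr[0]
    d_max = dist[-1]

    hit_cache: dict[tuple[int, str], list] = {}

    def hits_for(pwm: PWM, which: str, pset: PromoterSet) -> list[list]:
        key = (id(pwm), which)
        if key not in hit_cache:
            hit_cache[key] = [_naive_hits(pwm, rec.residues, floor)
                              for rec in pset.records]
        return hit_cache[key]

    pwms = sorted(library, key=lambda p: p.name)
    results: list[SearchResult] = []
    for ai in range(len(pwms)):
        for bi in range(ai, len(pwms)):
            pwm1, pwm2 = pwms[ai], pwms[bi]
            homotypic = ai == bi
            pres = {}
            for which, pset in (("pos", pos), ("neg", neg)):
                h1 = hits_for(pwm1, which, pset)
                h2 = h1 if homotypic else hits_for(pwm2, which, pset)
                seq_trips = [
                    _naive_triples(h1[s], h2[s], pwm1.width, pwm2.width,
                                   d_max, homotypic)
                    for s in range(pset.n)
                ]
                arrays = [(np.array([t[0] for t in ts]),
                           np.array([t[1] for t in ts]),
                           np.array([t[2] for t in ts])) for ts in seq_trips]
                grid = np.zeros(grids.shape, dtype=np.int64)
                for i, t1 in enumerate(thr):
                    for j, t2 in enumerate(thr):
                        for k, d in enumerate(dist):
                            c = 0
                            for s1, s2, gp in arrays:
                                if s1.size and bool(
                                        np.any((s1 >= t1) & (s2 >= t2) & (gp <= d))):
                                    c += 1
                            grid[i, j, k] = c
                pres[which] = grid / pset.n
            eps = params.epsilon_for(neg.n)
            best = None
            best_cell = None
            for i, t1 in enumerate(thr):
                for j, t2 in enumerate(thr):
                    for k, d in enumerate(dist):
                        cp = pres["pos"][i, j, k]
                        cn = pres["neg"][i, j, k]
                        if cp < params.c_min_pos or cn > params.c_max_neg:
                            continue
                        cand = (cp / max(cn, eps), cp, d, t1, t2)
                        if best is None or _better(cand, best):
                            best = cand
                            best_cell = (i, j, k, cp, cn)
                    # cells scanned in a fixed order; _better is strict, so the
                    # first of several exactly-tied cells is kept, matching the
                    # accelerated path's stable selection
            if best is not None:
                i, j, k, cp, cn = best_cell
                cfg = CRMConfig(pwm1.name, pwm2.name, thr[i], thr[j], dist[k])
                results.append(SearchResult(cfg, float(cp), float(cn),
                                            float(best[0]), pos.n, neg.n))
    results.sort(key=lambda r: (-r.ratio, -r.c_pos,
                                -(r.config.thr1 + r.config.thr2), r.config.d,
                                r.config.pwm1_name, r.config.pwm2_name,
                                r.config.thr1))
    return results


# ---------------------------------------------------------------------------
# nucleotide-level metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvaluationMetrics:
    """Per-nucleotide confusion counts and derived scores (None = undefined)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @staticmethod
    def _div(num: float, den: float) -> float | None:
        return num / den if den > 0 else None

    @property
    def sn(self) -> float | None:
        return self._div(self.tp, self.tp + self.fn)

    @property
    def sp(self) -> float | None:
        return self._div(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._div(self.tp, self.tp + self.fp)

    @property
    def pc(self) -> float | None:
        return self._div(self.tp, self.tp + self.fn + self.fp)

    @property
    def asp(self) -> float | None:
        if self.sn is None or self.ppv is None:
            return None
        return (self.sn + self.ppv) / 2

    @property
    def ncc(self) -> float | None:
        den = math.sqrt(float(self.tp + self.fn) * (self.tn + self.fp)
                        * (self.tp + self.fp) * (self.tn + self.fn))
        if den == 0:
            return None
        return (self.tp * self.tn - self.fn * self.fp) / den

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "sn": self.sn, "sp": self.sp, "ppv": self.ppv,
                "pc": self.pc, "asp": self.asp, "ncc": self.ncc}


def evaluate_predictions(truth: Mapping[str, Sequence[Interval]],
                         predicted: Mapping[str, Sequence[Interval]],
                         lengths: Mapping[str, int]) -> EvaluationMetrics:
    """Nucleotide-level confusion between truth and predicted interval sets.

    ``truth`` and ``predicted`` map sequence id -> intervals (0-based
    half-open); every id they mention must appear in ``lengths``.  Positions
    are classified by membership in the union of each interval set.
    """
    for label, ivmap in (("truth", truth), ("predicted", predicted)):
        for sid, ivs in ivmap.items():
            if sid not in lengths:
                raise ValueError(f"{label} mentions unknown sequence {sid!r}")
            for s, e in ivs:
                if not (0 <= s < e <= lengths[sid]):
                    raise ValueError(
                        f"{label} interval [{s}, {e}) out of bounds on "
                        f"sequence {sid!r} (length {lengths[sid]})")
    tp = fp = tn = fn = 0
    for sid, length in lengths.items():
        t = np.zeros(length, dtype=bool)
        p = np.zeros(length, dtype=bool)
        for s, e in truth.get(sid, ()):  # unions: overlapping intervals merge
            t[s:e] = True
        for s, e in predicted.get(sid, ()):
            p[s:e] = True
        tp += int(np.sum(t & p))
        fp += int(np.sum(~t & p))
        fn += int(np.sum(t & ~p))
        tn += int(np.sum(~t & ~p))
    return EvaluationMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def read_bed3(path: str | Path) -> dict[str, list[Interval]]:
    """BED3 (sequence id, 0-based start, end-exclusive) -> interval map."""
    out: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            sid, s, e = line.split("\t")[:3]
            out.setdefault(sid, []).append((int(s), int(e)))
    return out


def write_bed3(intervals: Mapping[str, Sequence[Interval]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in intervals:
            for s, e in intervals[sid]:
                fh.write(f"{sid}\t{s}\t{e}\n")


def metrics_report(m: EvaluationMetrics, path: str | Path,
                   fmt: str = "json") -> None:
    d = m.as_dict()
    if fmt == "json":
        Path(path).write_text(json.dumps(
            {k: ("undefined" if v is None else v) for k, v in d.items()},
            indent=2) + "\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(d) + "\n")
            fh.write("\t".join("undefined" if v is None else f"{v:.6g}"
                               if isinstance(v, float) else str(v)
                               for v in d.values()) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
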