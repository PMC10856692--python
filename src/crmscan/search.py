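"""Exhaustive module search over (Thr1, Thr2, D), accelerated by a monotone
3-D count grid.

For one PWM pair and one promoter set, the grid cell (i, j, k) counts the
sequences containing at least one motif-pair occurrence with normalized
scores >= (thr_values[i], thr_values[j]) and gap <= dist_values[k].  The
count is monotone: it never decreases when either threshold is lowered or
the distance bound is raised, because every module found at a stricter
setting is also found at a weaker one.  This makes each per-sequence
indicator the union of axis-aligned "boxes" anchored at the per-occurrence
triples, so the whole grid is built from one cumulative-maximum pass per
axis instead of a per-cell rescan.

The optimizer then intersects the two feasible regions — presence at least
Cmin+ on the positive set, at most Cmax- on the negative set — and returns
the cell maximizing the presence ratio C+/C-, with deterministic
tie-breaking.  The positive region is computed first; when it is empty the
negative set is never scanned (a pure acceleration: the result is identical
to full evaluation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .io import PWM, PromoterSet
from .scan import (PairTriple, pair_triples, pair_triples_arrays, scan_pwm,
                   triples_arrays)


# ---------------------------------------------------------------------------
# parameter grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchGrids:
    """Discretization of the three search axes.

    ``thr_values`` (shared by both threshold axes) is strictly ascending and
    must end at 1.0, the perfect-match score; ``dist_values`` is a strictly
    ascending list of candidate maximum distances in nucleotides.
    """

    thr_values: tuple[float, ...]
    dist_values: tuple[int, ...]

    def __post_init__(self) -> None:
        thr = np.asarray(self.thr_values, dtype=float)
        dist = np.asarray(self.dist_values, dtype=int)
        if thr.size == 0 or np.any(np.diff(thr) <= 0):
            raise ValueError("thr_values must be non-empty and strictly ascending")
        if not np.isclose(thr[-1], 1.0):
            raise ValueError("thr_values must end at 1.0")
        if thr[0] < 0 or thr[-1] > 1.0 + 1e-12:
            raise ValueError("thr_values must lie in [0, 1]")
        if dist.size == 0 or np.any(np.diff(dist) <= 0) or dist[0] < 0:
            raise ValueError("dist_values must be non-empty, non-negative, strictly ascending")
        object.__setattr__(self, "thr_values", tuple(float(v) for v in thr))
        object.__setattr__(self, "dist_values", tuple(int(v) for v in dist))

    @classmethod
    def from_steps(cls, thr_min: float = 0.5, thr_step: float = 0.01,
                   dist_max: int = 200, dist_step: int = 5) -> "SearchGrids":
        n = int(round((1.0 - thr_min) / thr_step))
        thr = [round(thr_min + i * thr_step, 10) for i in range(n)] + [1.0]
        dist = list(range(0, dist_max + 1, dist_step))
        return cls(tuple(thr), tuple(dist))

    @classmethod
    def default(cls) -> "SearchGrids":
        """Thresholds 0.50..1.00 step 0.01; distances 0..200 step 5."""
        return cls.from_steps()

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.thr_values), len(self.thr_values), len(self.dist_values))

    def thr_index(self, value: float) -> int:
        thr = np.asarray(self.thr_values)
        i = int(np.argmin(np.abs(thr - value)))
        if abs(thr[i] - value) > 1e-9:
            raise ValueError(f"{value} is not on the threshold grid")
        return i

    def dist_index(self, value: int) -> int:
        try:
            return self.dist_values.index(int(value))
        except ValueError:
            raise ValueError(f"{value} is not on the distance grid") from None


@dataclass(frozen=True)
class SearchParams:
    """Boundary conditions and grids for one search run.

    ``c_min_pos`` / ``c_max_neg`` are the required minimum presence on the
    positive set and tolerated maximum presence on the negative set (defaults
    0.75 / 0.5).  ``ratio_epsilon`` guards the ratio against a zero negative
    presence; when None it defaults to 1/(2 n-) at optimization time, which
    ranks zero-negative modules above any module seen in even one negative
    sequence, ordered among themselves by positive presence.
    """

    c_min_pos: float = 0.75
    c_max_neg: float = 0.5
    grids: SearchGrids = field(default_factory=SearchGrids.default)
    ratio_epsilon: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.c_min_pos <= 1.0:
            raise ValueError("c_min_pos must be in (0, 1]")
        if not 0.0 <= self.c_max_neg < 1.0:
            raise ValueError("c_max_neg must be in [0, 1)")
        if self.ratio_epsilon is not None and self.ratio_epsilon <= 0:
            raise ValueError("ratio_epsilon must be > 0")

    def epsilon_for(self, n_neg: int) -> float:
        return self.ratio_epsilon if self.ratio_epsilon is not None else 1.0 / (2 * n_neg)


#: The specificity-group sweep used for multi-setting runs: from modules
#: common to nearly all promoters down to modules of a small subgroup.
DEFAULT_SWEEP: tuple[tuple[float, float], ...] = (
    (0.90, 0.50), (0.75, 0.50), (0.66, 0.50), (0.50, 0.25), (0.33, 0.15),
)


# ---------------------------------------------------------------------------
# grid construction
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class HashGrid:
    """Per-cell count of sequences containing >= 1 module, over one set."""

    counts: np.ndarray  # int, shape (n_thr, n_thr, n_dist)
    n: int
    grids: SearchGrids

    @property
    def presence(self) -> np.ndarray:
        return self.counts / self.n

    def is_monotone(self) -> bool:
        """Counts never decrease when a threshold drops or the distance grows."""
        c = self.counts
        return (
            bool(np.all(np.diff(c, axis=0) <= 0))
            and bool(np.all(np.diff(c, axis=1) <= 0))
            and bool(np.all(np.diff(c, axis=2) >= 0))
        )


def _close_boxes(marked: np.ndarray) -> np.ndarray:
    """Union-of-boxes closure: cell (a,b,c) true iff a marked (i,j,k) exists
    with i >= a, j >= b, k <= c."""
    g = np.flip(np.maximum.accumulate(np.flip(marked, 0), axis=0), 0)
    g = np.flip(np.maximum.accumulate(np.flip(g, 1), axis=1), 1)
    return np.maximum.accumulate(g, axis=2)


def sequence_indicator(triples: Sequence[PairTriple] | tuple[np.ndarray, ...],
                       grids: SearchGrids) -> np.ndarray:
    """Boolean grid: does this sequence contain a module at each (i, j, k)?

    Cell (i, j, k) is set iff some triple has s1 >= thr_values[i],
    s2 >= thr_values[j] and gap <= dist_values[k].  Built by marking, for
    each triple, the strictest cell it satisfies and closing under the
    monotone order.
    """
    if isinstance(triples, tuple) and len(triples) == 3:
        s1, s2, gap = triples
    else:
        s1, s2, gap = triples_arrays(list(triples))
    thr = np.asarray(grids.thr_values)
    dist = np.asarray(grids.dist_values)
    marked = np.zeros(grids.shape, dtype=bool)
    if s1.size:
        i = np.searchsorted(thr, s1, side="right") - 1  # largest i with thr[i] <= s1
        j = np.searchsorted(thr, s2, side="right") - 1
        k = np.searchsorted(dist, gap, side="left")  # smallest k with dist[k] >= gap
        ok = (i >= 0) & (j >= 0) & (k < dist.size)
        marked[i[ok], j[ok], k[ok]] = True
    return _close_boxes(marked)


def build_hash(pset: PromoterSet, pwm1: PWM, pwm2: PWM,
               grids: SearchGrids) -> HashGrid:
    """Count, per grid cell, the sequences of ``pset`` containing a module.

    Scans both PWMs over every sequence with the grid's lowest threshold as
    score floor and its largest distance as gap bound — occurrences below
    either can never contribute to any cell.
    """
    if pset.n == 0:
        raise ValueError("empty set")
    floor = grids.thr_values[0]
    d_max = grids.dist_values[-1]
    homotypic = pwm1.name == pwm2.name
    counts = np.zeros(grids.shape, dtype=np.int64)
    for idx, rec in enumerate(pset.records):
        hits1 = scan_pwm(pwm1, rec, floor, idx)
        hits2 = hits1 if homotypic else scan_pwm(pwm2, rec, floor, idx)
        trips = pair_triples_arrays(hits1, hits2, pwm1.width, pwm2.width,
                                    d_max, homotypic=homotypic)
        counts += sequence_indicator(trips, grids)
    return HashGrid(counts, pset.n, grids)


def feasible_region(h: HashGrid, bound: float, direction: str) -> np.ndarray:
    """Cells where presence >= bound (``at_least``) or <= bound (``at_most``)."""
    if not 0.0 <= bound <= 1.0:
        raise ValueError("bound must be in [0, 1]")
    pres = h.presence
    if direction == "at_least":
        return pres >= bound
    if direction == "at_most":
        return pres <= bound
    raise ValueError(f"direction must be 'at_least' or 'at_most', got {direction!r}")


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CRMConfig:
    """One module hypothesis: a PWM pair with thresholds and max distance."""

    pwm1_name: str
    pwm2_name: str
    thr1: float
    thr2: float
    d: int


@dataclass(frozen=True)
class SearchResult:
    """A pair's optimal configuration with its measured presences."""

    config: CRMConfig
    c_pos: float
    c_neg: float
    ratio: float
    n_pos: int
    n_neg: int


def _rank_key(r: SearchResult) -> tuple:
    """Descending ratio, then the deterministic tie-break chain: larger C+,
    larger Thr1+Thr2 (the most specific thresholds), smaller D (the tightest
    spacing), lexicographic names, smaller Thr1."""
    c = r.config
    return (-r.ratio, -r.c_pos, -(c.thr1 + c.thr2), c.d,
            c.pwm1_name, c.pwm2_name, c.thr1)


def optimize_pair(h_pos: HashGrid, h_neg: HashGrid, params: SearchParams,
                  pwm1: PWM, pwm2: PWM) -> SearchResult | None:
    """Globally optimal configuration for one PWM pair, or None.

    Over the intersection of the positive-feasible and negative-feasible
    regions, maximizes C+/max(C-, epsilon); ties resolved by
    :func:`_rank_key`.  Returns None when the intersection is empty.
    """
    if h_pos.counts.shape != h_neg.counts.shape:
        raise ValueError("positive and negative grids have different shapes")
    if h_pos.grids.thr_values != h_neg.grids.thr_values or \
       h_pos.grids.dist_values != h_neg.grids.dist_values:
        raise ValueError("positive and negative grids built on different axes")
    grids = h_pos.grids
    mask = feasible_region(h_pos, params.c_min_pos, "at_least") & \
        feasible_region(h_neg, params.c_max_neg, "at_most")
    if not mask.any():
        return None
    eps = params.epsilon_for(h_neg.n)
    cpos = h_pos.presence[mask]
    cneg = h_neg.presence[mask]
    ratio = cpos / np.maximum(cneg, eps)
    ii, jj, kk = np.nonzero(mask)
    thr = np.asarray(grids.thr_values)
    dist = np.asarray(grids.dist_values)
    # lexsort keys, last key most significant; mirrors _rank_key
    order = np.lexsort((thr[ii], dist[kk], -(thr[ii] + thr[jj]),
                        -cpos, -ratio))
    best = order[0]
    i, j, k = int(ii[best]), int(jj[best]), int(kk[best])
    cfg = CRMConfig(pwm1.name, pwm2.name, float(thr[i]), float(thr[j]),
                    int(dist[k]))
    return SearchResult(cfg, float(cpos[best]), float(cneg[best]),
                        float(ratio[best]), h_pos.n, h_neg.n)


def _canonical_pair(pwm1: PWM, pwm2: PWM) -> tuple[PWM, PWM]:
    return (pwm1, pwm2) if pwm1.name <= pwm2.name else (pwm2, pwm1)


def search_all_pairs(pos: PromoterSet, neg: PromoterSet, library: Sequence[PWM],
                     params: SearchParams,
                     grid_sink: Callable[[str, str, HashGrid, HashGrid], None] | None = None,
                     ) -> list[SearchResult]:
    """Optimal module per unordered PWM pair (homotypic included), ranked.

    Pairs with an empty feasible intersection are omitted.  For each pair the
    positive grid and its feasible region are computed first; the negative
    set is only scanned when that region is non-empty (the result is
    identical to unconditional full evaluation, since an empty positive
    region already implies no feasible cell).  ``grid_sink``, if given,
    receives every (pwm1_name, pwm2_name, h_pos, h_neg) actually built.
    """
    if not library:
        raise ValueError("empty PWM library")
    names = [p.name for p in library]
    if len(set(names)) != len(names):
        raise ValueError("duplicate PWM names in library")
    results: list[SearchResult] = []
    for a, b in itertools.combinations_with_replacement(
            sorted(library, key=lambda p: p.name), 2):
        pwm1, pwm2 = _canonical_pair(a, b)
        h_pos = build_hash(pos, pwm1, pwm2, params.grids)
        if not feasible_region(h_pos, params.c_min_pos, "at_least").any():
            continue  # pruning: no cell can be feasible regardless of the negatives
        h_neg = build_hash(neg, pwm1, pwm2, params.grids)
        if grid_sink is not None:
            grid_sink(pwm1.name, pwm2.name, h_pos, h_neg)
        res = optimize_pair(h_pos, h_neg, params, pwm1, pwm2)
        if res is not None:
            results.append(res)
    results.sort(key=_rank_key)
    return results


def compute_presence(pset: PromoterSet, config: CRMConfig,
                     library: Sequence[PWM]) -> float:
    """Fraction of sequences containing >= 1 module at exactly this config.

    Re-scans the set directly (no grid); equals the corresponding normalized
    grid cell by construction.
    """
    by_name = {p.name: p for p in library}
    try:
        pwm1 = by_name[config.pwm1_name]
        pwm2 = by_name[config.pwm2_name]
    except KeyError as exc:
        raise ValueError(f"unknown PWM name {exc.args[0]!r}") from None
    homotypic = config.pwm1_name == config.pwm2_name
    n_with = 0
    for idx, rec in enumerate(pset.records):
        hits1 = scan_pwm(pwm1, rec, config.thr1, idx)
        hits2 = hits1 if homotypic else scan_pwm(pwm2, rec, config.thr2, idx)
        for t in pair_triples(hits1, hits2, pwm1.width, pwm2.width, config.d,
                              homotypic=homotypic):
            if t.s1 >= config.thr1 and t.s2 >= config.thr2:
                n_with += 1
                break
    return n_with / pset.n


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def results_to_tsv(results: Sequence[SearchResult], path: str | Path) -> None:
    """One row per pair optimum: configuration, presences, ratio, set sizes."""
    with open(path, "w") as fh:
        fh.write("pwm1\tpwm2\tthr1\tthr2\tmax_dist\tc_pos\tc_neg\tratio\t"
                 "n_pos\tn_neg\n")
        for r in results:
            c = r.config
            fh.write(f"{c.pwm1_name}\t{c.pwm2_name}\t{c.thr1:.4f}\t{c.thr2:.4f}\t"
                     f"{c.d}\t{r.c_pos:.6g}\t{r.c_neg:.6g}\t{r.ratio:.6g}\t"
                     f"{r.n_pos}\t{r.n_neg}\n")


def module_instances(pset: PromoterSet, config: CRMConfig,
                     library: Sequence[PWM]) -> list[dict]:
    """Every module instance at this configuration, with 1-based inclusive
    coordinates (user-facing convention), strands, scores and gap."""
    by_name = {p.name: p for p in library}
    pwm1, pwm2 = by_name[config.pwm1_name], by_name[config.pwm2_name]
    homotypic = config.pwm1_name == config.pwm2_name
    rows = []
    for idx, rec in enumerate(pset.records):
        hits1 = scan_pwm(pwm1, rec, config.thr1, idx)
        hits2 = hits1 if homotypic else scan_pwm(pwm2, rec, config.thr2, idx)
        for h1 in hits1:
            e1 = h1.start + pwm1.width
            for h2 in hits2:
                if homotypic and h1.start == h2.start and h1.strand == h2.strand:
                    continue
                gap = max(h2.start - e1, h1.start - (h2.start + pwm2.width))
                if 0 <= gap <= config.d and h1.score >= config.thr1 \
                        and h2.score >= config.thr2:
                    rows.append({
                        "sequence": rec.id,
                        "pwm1": pwm1.name, "start1": h1.start + 1, "end1": e1,
                        "strand1": h1.strand, "score1": h1.score,
                        "pwm2": pwm2.name, "start2": h2.start + 1,
                        "end2": h2.start + pwm2.width, "strand2": h2.strand,
                        "score2": h2.score, "gap": gap,
                    })
    return rows


def instances_to_tsv(rows: Sequence[dict], path: str | Path) -> None:
    cols = ["sequence", "pwm1", "start1", "end1", "strand1", "score1",
            "pwm2", "start2", "end2", "strand2", "score2", "gap"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(
                f"{row[c]:.4f}" if c in ("score1", "score2") else str(row[c])
                for c in cols) + "\n")


def instances_to_bed12(rows: Sequence[dict], path: str | Path,
                       name: str = "module") -> None:
    """Each module instance as one BED12 record with two blocks (0-based)."""
    with open(path, "w") as fh:
        for row in rows:
            a = (row["start1"] - 1, row["end1"])
            b = (row["start2"] - 1, row["end2"])
            first, second = sorted((a, b))
            chrom_start, chrom_end = first[0], second[1]
            sizes = f"{first[1] - first[0]},{second[1] - second[0]}"
            starts = f"0,{second[0] - chrom_start}"
            score = round(min(row["score1"], row["score2"]) * 1000)
            fh.write(f"{row['sequence']}\t{chrom_start}\t{chrom_end}\t{name}\t"
                     f"{score}\t.\t{chrom_start}\t{chrom_end}\t0\t2\t"
                     f"{sizes},\t{starts},\n")
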