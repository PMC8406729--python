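"""Sliding-window identification of unique ROH genotypes.

The scan enumerates, for each window size from ``initial_window`` down to
``min_window`` in steps of ``window_decrement`` and every start position
(slide one SNP at a time, windows never crossing a chromosome end), the
partition of animals into *unique ROH genotype* classes: groups of animals
that are fully homozygous across the window with an identical allele string,
each at population frequency above ``min_class_frequency``.  All remaining
animals (heterozygous somewhere in the window, missing calls, or members of
strings below the frequency floor) form the non-ROH class.

Candidate windows are those containing at least one class whose raw carrier
phenotype mean lies strictly on the unfavorable side of the trait's
empirical cut-off.  Within each window size, runs of consecutive start
positions whose class partitions are identical are aggregated into a single
record; across sizes, windows whose carrier partition is nested inside a
larger candidate are discarded.

A missing call breaks a run, i.e. it is treated like a heterozygote: ROH
carry no heterozygous calls by definition, and an uncalled SNP cannot vouch
for homozygosity.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from .data import MISSING, GenotypeMatrix, ScanParams

logger = logging.getLogger("rohscan")


def class_id_of(string: bytes) -> str:
    """Stable short identifier for a homozygote allele string."""
    return hashlib.sha1(string).hexdigest()[:10]


# ---------------------------------------------------------------------------
# Run index
# ---------------------------------------------------------------------------

@dataclass
class RunIndex:
    """Maximal homozygous runs (length >= min_run) per animal per chromosome.

    Runs are stored as half-open global column intervals [start, end), sorted
    and disjoint within an animal.  A window is fully homozygous for an
    animal iff it lies inside one stored run, which reduces per-window
    carrier queries to interval containment.
    """

    min_run: int
    # chrom -> (animal_idx array, start array, end array), sorted by animal
    runs: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]
    n_animals: int
    chrom_bounds: dict[int, tuple[int, int]]
    _cov_cache: dict = field(default_factory=dict, repr=False)

    def coverage(self, chrom: int, size: int) -> np.ndarray:
        """Boolean (animals x starts) matrix: window [t, t+size) inside a run.

        Start positions are chromosome-local.  Cached per (chrom, size).
        """
        key = (chrom, size)
        if key in self._cov_cache:
            return self._cov_cache[key]
        lo, hi = self.chrom_bounds[chrom]
        n_starts = hi - lo - size + 1
        cov = np.zeros((self.n_animals, max(n_starts, 0)), dtype=bool)
        if n_starts <= 0:
            self._cov_cache[key] = cov
            return cov
        anim, start, end = self.runs.get(chrom, (np.array([], int),) * 3)
        for a, s, e in zip(anim, start, end):
            if e - s >= size:
                cov[a, s - lo:e - size - lo + 1] = True
        self._cov_cache[key] = cov
        return cov

    def covers(self, animal: int, start: int, end: int, chrom: int) -> bool:
        anim, s, e = self.runs.get(chrom, (np.array([], int),) * 3)
        mask = anim == animal
        return bool(np.any((s[mask] <= start) & (e[mask] >= end)))


def build_run_index(gm: GenotypeMatrix, min_run: int = 15) -> RunIndex:
    """Run-length encode homozygous stretches per animal and chromosome."""
    hom = (gm.values == 0) | (gm.values == 2)
    bounds = gm.snp_map.chrom_bounds()
    runs: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, (lo, hi) in bounds.items():
        x = hom[:, lo:hi]
        padded = np.zeros((x.shape[0], x.shape[1] + 2), dtype=np.int8)
        padded[:, 1:-1] = x
        d = np.diff(padded, axis=1)
        ai_s, starts = np.nonzero(d == 1)
        ai_e, ends = np.nonzero(d == -1)
        # starts/ends pair up in order within each animal row
        length = ends - starts
        keep = length >= min_run
        runs[chrom] = (ai_s[keep].astype(np.int32),
                       (starts[keep] + lo).astype(np.int32),
                       (ends[keep] + lo).astype(np.int32))
    return RunIndex(min_run, runs, gm.n_animals, bounds)


# ---------------------------------------------------------------------------
# Window classing and screening
# ---------------------------------------------------------------------------

@dataclass
class WindowClassing:
    """Partition of animals at one window into ROH classes and non-ROH."""

    chrom: int
    start: int  # global column index, half-open interval [start, end)
    end: int
    classes: dict[bytes, np.ndarray]  # homozygote string -> carrier indices
    non_roh: np.ndarray

    @property
    def size(self) -> int:
        return self.end - self.start


def class_window(gm: GenotypeMatrix, run_index: RunIndex, chrom: int,
                 start: int, end: int,
                 min_class_frequency: float) -> WindowClassing:
    """Partition animals at window [start, end) into unique ROH classes.

    Carriers are animals whose homozygous run covers the whole window (hence
    no heterozygous or missing call inside); they are grouped by the exact
    allele string.  Groups at frequency <= min_class_frequency fold into the
    non-ROH class.
    """
    if end <= start:
        raise ValueError("window size must be positive")
    lo, hi = run_index.chrom_bounds[chrom]
    if start < lo or end > hi:
        raise ValueError("window crosses chromosome bounds")
    size = end - start
    cov = run_index.coverage(chrom, size)
    t = start - lo
    carriers = np.flatnonzero(cov[:, t]) if cov.shape[1] > t else np.array([], int)
    return _group_carriers(gm, chrom, start, end, carriers,
                           min_class_frequency)


def _group_carriers(gm: GenotypeMatrix, chrom: int, start: int, end: int,
                    carriers: np.ndarray,
                    min_class_frequency: float) -> WindowClassing:
    n = gm.n_animals
    groups: dict[bytes, list[int]] = {}
    block = gm.values[carriers, start:end]
    for row, a in zip(block, carriers):
        groups.setdefault(row.tobytes(), []).append(int(a))
    min_count = min_class_frequency * n
    classes = {s: np.array(m, dtype=np.int64) for s, m in groups.items()
               if len(m) > min_count}
    in_class = (np.concatenate(list(classes.values()))
                if classes else np.array([], dtype=np.int64))
    mask = np.ones(n, dtype=bool)
    mask[in_class] = False
    return WindowClassing(chrom, start, end, classes, np.flatnonzero(mask))


@dataclass
class CandidateWindow:
    """A window retaining at least one class past the phenotype screen.

    After aggregation, ``start``/``end`` span the union of the merged
    windows while ``classes`` holds the representative (first) window's
    partition; ``orig_size`` is the scan window size that produced it.
    """

    chrom: int
    start: int
    end: int
    orig_size: int
    classes: dict[bytes, np.ndarray]
    carrier_means: dict[bytes, float]
    non_roh: np.ndarray

    @property
    def size(self) -> int:
        return self.end - self.start

    def partition_key(self) -> frozenset[frozenset[int]]:
        return frozenset(frozenset(v.tolist()) for v in self.classes.values())

    def interval(self) -> tuple[int, int, int]:
        return (self.chrom, self.start, self.end)


def screen_classes(classing: WindowClassing, phenotype: np.ndarray,
                   cutoff: float, direction: str) -> CandidateWindow | None:
    """Keep classes whose raw carrier mean is strictly past the cut-off.

    ``phenotype`` is aligned with genotype rows, NaN for missing records.
    Classes whose carriers are all missing the phenotype are skipped.
    Returns None when no class survives.
    """
    kept: dict[bytes, np.ndarray] = {}
    means: dict[bytes, float] = {}
    for s, members in classing.classes.items():
        vals = phenotype[members]
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            logger.info("class %s at %d:[%d,%d) has no phenotyped carriers",
                        class_id_of(s), classing.chrom, classing.start,
                        classing.end)
            continue
        mu = float(vals.mean())
        unfavorable = mu < cutoff if direction == "lower" else mu > cutoff
        if unfavorable:
            kept[s] = members
            means[s] = mu
    if not kept:
        return None
    return CandidateWindow(classing.chrom, classing.start, classing.end,
                           classing.size, kept, means, classing.non_roh)


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------

def scan_genome(gm: GenotypeMatrix, run_index: RunIndex,
                phenotype: np.ndarray, cutoff: float, direction: str,
                params: ScanParams) -> list[CandidateWindow]:
    """Full sliding-window scan over all window sizes and chromosomes.

    Windows are screened as they are formed; per window size, equivalent
    adjacent candidates are aggregated before the sizes are pooled.  Nested
    windows are *not* discarded here (see :func:`drop_nested`).
    """
    n = gm.n_animals
    min_count = params.min_class_frequency * n
    out: list[CandidateWindow] = []
    for size in params.window_sizes:
        size_cands: list[CandidateWindow] = []
        for chrom, (lo, hi) in run_index.chrom_bounds.items():
            if hi - lo < params.min_window:
                logger.warning("chromosome %d shorter than min window; "
                               "skipped", chrom)
                continue
            if hi - lo < size:
                continue
            cov = run_index.coverage(chrom, size)
            counts = cov.sum(axis=0)
            for t in range(0, cov.shape[1], params.slide_step):
                if counts[t] <= min_count:
                    continue
                start = lo + t
                carriers = np.flatnonzero(cov[:, t])
                classing = _group_carriers(gm, chrom, start, start + size,
                                           carriers,
                                           params.min_class_frequency)
                if not classing.classes:
                    continue
                cand = screen_classes(classing, phenotype, cutoff, direction)
                if cand is not None:
                    size_cands.append(cand)
        out.extend(aggregate_windows(size_cands))
    return out


def aggregate_windows(candidates: list[CandidateWindow]
                      ) -> list[CandidateWindow]:
    """Merge chains of adjacent-start candidates with identical partitions.

    Candidates must share one scan window size.  A maximal chain of
    consecutive start positions on one chromosome whose per-class carrier
    sets coincide becomes a single record spanning the union of the merged
    intervals, with the first window's classing as representative.
    """
    if not candidates:
        return []
    sizes = {c.orig_size for c in candidates}
    if len(sizes) > 1:
        raise ValueError("aggregation applies within one window size")
    candidates = sorted(candidates, key=lambda c: (c.chrom, c.start))
    merged: list[CandidateWindow] = []
    chain = [candidates[0]]
    for cand in candidates[1:]:
        prev = chain[-1]
        if (cand.chrom == prev.chrom and cand.start == prev.start + 1
                and cand.partition_key() == prev.partition_key()):
            chain.append(cand)
        else:
            merged.append(_merge_chain(chain))
            chain = [cand]
    merged.append(_merge_chain(chain))
    return merged


def _merge_chain(chain: list[CandidateWindow]) -> CandidateWindow:
    first, last = chain[0], chain[-1]
    if len(chain) == 1:
        return first
    return CandidateWindow(first.chrom, first.start, last.end,
                           first.orig_size, first.classes,
                           first.carrier_means, first.non_roh)


def drop_nested(candidates: list[CandidateWindow]) -> list[CandidateWindow]:
    """Discard candidates nested inside another with identical carrier sets.

    A candidate goes when some other candidate's interval contains its own
    (same chromosome) and the per-class carrier sets coincide.  For
    identical intervals the record from the larger scan window size wins.
    """
    keys = [c.partition_key() for c in candidates]
    keep = np.ones(len(candidates), dtype=bool)
    for i, ci in enumerate(candidates):
        for j, cj in enumerate(candidates):
            if i == j or keys[i] != keys[j] or ci.chrom != cj.chrom:
                continue
            contains = cj.start <= ci.start and ci.end <= cj.end
            if not contains:
                continue
            if (ci.start, ci.end) == (cj.start, cj.end):
                # tie: keep the larger-window record; break further ties by
                # list position to keep exactly one
                if (cj.orig_size, -j) > (ci.orig_size, -i):
                    keep[i] = False
            else:
                keep[i] = False
    return [c for c, k in zip(candidates, keep) if k]
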