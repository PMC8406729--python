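"""Cut-off calibration, trait-wise discovery, FDR control and reporting.

Per trait the pipeline is: calibrate the empirical phenotype cut-off from
randomly sampled windows -> sliding-window scan with screening and
aggregation -> nested-window discard -> mixed-model contrast of every
retained ROH class against the non-ROH class -> Benjamini-Hochberg step-up
over the trait's genome-wise family of one-tailed p values.  Pleiotropic
classes are groups of significant records from different traits whose
intervals overlap with identical carrier sets; gene annotation intersects
record intervals with a user-supplied BED or GFF3 gene table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .animal_model import (MixedModelContext, ModelError, factor_design,
                           a_inverse, fit_window_model)
from .data import (AnalysisConfig, GenotypeMatrix, Pedigree, ScanParams,
                   TraitConfig)
from .scan import (CandidateWindow, RunIndex, build_run_index, class_id_of,
                   class_window, drop_nested, scan_genome)

logger = logging.getLogger("rohscan")

#: minimum number of sampled classes required inside the significance band
#: before the cut-off is computed; the band widens by 0.01 steps until met
MIN_BAND_CLASSES = 20


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_fdr(pvalues, q: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: rejection flags and adjusted p values.

    Largest k with p_(k) <= k*q/m is found; ranks <= k are rejected.
    Adjusted p is min over j >= rank of m*p_(j)/j, capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")[:4]
    return reject, p_adj


# ---------------------------------------------------------------------------
# Model context assembly
# ---------------------------------------------------------------------------

@dataclass
class TraitContext:
    """Everything needed to fit windows for one trait."""

    trait: TraitConfig
    ctx: MixedModelContext
    record_rows: np.ndarray   # genotype-matrix row of each model record
    row_to_record: dict[int, int]
    phenotype: np.ndarray     # aligned with genotype rows; NaN = missing


def build_trait_context(trait: TraitConfig, gm: GenotypeMatrix,
                        ped: Pedigree, phenotypes: pd.DataFrame,
                        config: AnalysisConfig,
                        ainv=None) -> TraitContext:
    """Assemble the per-trait mixed-model context (records with phenotype)."""
    vc = config.variance_components[trait.name]
    pheno = phenotypes.set_index("animal_id").reindex(gm.animal_ids)
    y_full = pheno[trait.name].to_numpy(dtype=float)
    has = ~np.isnan(y_full)
    rows = np.flatnonzero(has)
    y = y_full[rows]
    sub = pheno.iloc[rows]

    blocks = [np.ones((len(rows), 1))]
    for fac in config.fixed_factors:
        blocks.append(factor_design(sub[fac]))
    X0 = np.hstack(blocks)

    iid = []
    for fac in config.random_factors:
        codes, _ = pd.factorize(sub[fac], sort=True)
        iid.append(codes)

    index_of = ped.index_of
    animal_index = np.array([index_of[a] for a in gm.animal_ids[rows]])
    if ainv is None and vc.sigma2_a > 0:
        ainv = a_inverse(ped)
    ctx = MixedModelContext(y, X0, animal_index, ainv, iid, vc)
    ctx.attach_genotypes(gm.values[rows].astype(float))
    return TraitContext(trait, ctx,
                        rows, {int(r): i for i, r in enumerate(rows)},
                        y_full)


def _record_mask(tc: TraitContext, members: np.ndarray) -> np.ndarray:
    """Map genotype-row carrier indices to model-record indices."""
    return np.array([tc.row_to_record[int(r)] for r in members
                     if int(r) in tc.row_to_record], dtype=int)


# ---------------------------------------------------------------------------
# Empirical cut-off
# ---------------------------------------------------------------------------

def empirical_cutoff(gm: GenotypeMatrix, run_index: RunIndex,
                     tc: TraitContext, params: ScanParams,
                     seed: int = 0) -> float:
    """Calibrate the unfavorable-phenotype cut-off from random windows.

    ``threshold_samples`` windows of the initial size are sampled uniformly
    over (chromosome, start); each is classed and fitted with the mixed
    model, collecting (raw carrier mean, one-tailed p) for every ROH class.
    The cut-off is the mean of carrier means whose p lies in the
    significance band (default [0.05, 0.10]); if fewer than
    ``MIN_BAND_CLASSES`` classes land in the band it widens symmetrically in
    0.01 steps (logged) until enough are collected or the band spans [0, 1],
    in which case all sampled class means are used.
    """
    rng = np.random.default_rng(seed)
    size = params.initial_window
    starts: list[tuple[int, int]] = []
    for chrom, (lo, hi) in run_index.chrom_bounds.items():
        if hi - lo >= size:
            starts.extend((chrom, s) for s in range(lo, hi - size + 1))
    if not starts:
        raise ValueError("genome too small to sample cut-off windows")
    picks = rng.integers(0, len(starts), size=params.threshold_samples)

    means: list[float] = []
    pvals: list[float] = []
    direction = tc.trait.unfavorable_direction
    for k in picks:
        chrom, start = starts[int(k)]
        classing = class_window(gm, run_index, chrom, start, start + size,
                                params.min_class_frequency)
        if not classing.classes:
            continue
        pairs = []
        for s, members in classing.classes.items():
            vals = tc.phenotype[members]
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                continue
            pairs.append((s, members, float(vals.mean())))
        if not pairs:
            continue
        carriers = [(class_id_of(s), _record_mask(tc, m)) for s, m, _ in pairs]
        try:
            fit = fit_window_model(tc.ctx, carriers,
                                   np.arange(start, start + size), direction)
        except ModelError as exc:
            logger.info("cut-off window %d:[%d,%d) skipped: %s", chrom,
                        start, start + size, exc)
            continue
        by_id = {e.class_id: e for e in fit.effects}
        for s, _, mu in pairs:
            eff = by_id.get(class_id_of(s))
            if eff is not None:
                means.append(mu)
                pvals.append(eff.p)
    if not means:
        raise ValueError("no ROH classes found in sampled windows; cannot "
                         "calibrate a cut-off")
    means_arr = np.array(means)
    p_arr = np.array(pvals)
    lo, hi = params.threshold_sig_range
    while True:
        sel = (p_arr >= lo) & (p_arr <= hi)
        if sel.sum() >= MIN_BAND_CLASSES:
            break
        if lo <= 0.0 and hi >= 1.0:
            sel = np.ones_like(sel)
            logger.warning("cut-off band widened to [0,1]; using all %d "
                           "sampled classes", len(means_arr))
            break
        lo, hi = max(lo - 0.01, 0.0), min(hi + 0.01, 1.0)
        logger.info("cut-off band widened to [%.2f, %.2f]", lo, hi)
    return float(means_arr[sel].mean())


# ---------------------------------------------------------------------------
# Discovery records
# ---------------------------------------------------------------------------

@dataclass
class DiscoveryRecord:
    """One tested ROH class with its contrast against non-ROH."""

    trait: str
    chrom: int
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    n_snps: int
    class_id: str
    n_carriers: int
    carrier_freq_pct: float
    effect: float
    se: float
    t: float
    p: float
    minus_log10_p: float
    significant: bool = False
    p_adjusted: float = 1.0
    carrier_rows: np.ndarray = field(default=None, repr=False)

    def overlaps(self, chrom: int, start: int, end: int) -> bool:
        return (self.chrom == chrom and self.start_idx < end
                and start < self.end_idx)


def records_frame(records: list[DiscoveryRecord]) -> pd.DataFrame:
    """Tabular (report-style) view of discovery records."""
    rows = []
    for r in records:
        rows.append({
            "trait": r.trait, "chrom": r.chrom,
            "start_bp": r.start_bp, "end_bp": r.end_bp,
            "start_mb": round(r.start_bp / 1e6, 2),
            "end_mb": round(r.end_bp / 1e6, 2),
            "n_snps": r.n_snps, "class_id": r.class_id,
            "n_carriers": r.n_carriers,
            "carrier_freq_pct": round(r.carrier_freq_pct, 2),
            "effect": round(r.effect, 2), "se": round(r.se, 2),
            "p": r.p, "minus_log10_p": round(r.minus_log10_p, 2),
            "significant": r.significant,
        })
    return pd.DataFrame(rows)


def discover_trait(gm: GenotypeMatrix, run_index: RunIndex,
                   tc: TraitContext, params: ScanParams,
                   seed: int = 0, cutoff: float | None = None,
                   ) -> tuple[list[DiscoveryRecord], float]:
    """Run cut-off -> scan -> aggregate -> nest-discard -> fit -> BH for one
    trait.  Returns (records, cutoff used)."""
    direction = tc.trait.unfavorable_direction
    if cutoff is None:
        cutoff = empirical_cutoff(gm, run_index, tc, params, seed=seed)
    logger.info("trait %s: cut-off %.4g (%s unfavorable)", tc.trait.name,
                cutoff, direction)
    candidates = scan_genome(gm, run_index, tc.phenotype, cutoff, direction,
                             params)
    candidates = drop_nested(candidates)
    logger.info("trait %s: %d candidate windows after nesting", tc.trait.name,
                len(candidates))

    smap = gm.snp_map
    records: list[DiscoveryRecord] = []
    for cand in candidates:
        pairs = list(cand.classes.items())
        carriers = [(class_id_of(s), _record_mask(tc, m)) for s, m in pairs]
        snp_idx = np.arange(cand.start, cand.end)
        try:
            fit = fit_window_model(tc.ctx, carriers, snp_idx, direction)
        except ModelError as exc:
            logger.warning("trait %s window %d:[%d,%d): %s", tc.trait.name,
                           cand.chrom, cand.start, cand.end, exc)
            continue
        by_id = {e.class_id: e for e in fit.effects}
        for s, members in pairs:
            eff = by_id.get(class_id_of(s))
            if eff is None:
                continue
            records.append(DiscoveryRecord(
                trait=tc.trait.name, chrom=cand.chrom,
                start_idx=cand.start, end_idx=cand.end,
                start_bp=int(smap.position_bp[cand.start]),
                end_bp=int(smap.position_bp[cand.end - 1]),
                n_snps=cand.size, class_id=eff.class_id,
                n_carriers=len(members),
                carrier_freq_pct=100.0 * len(members) / gm.n_animals,
                effect=eff.effect, se=eff.se, t=eff.t, p=eff.p,
                minus_log10_p=float(-np.log10(max(eff.p, 1e-300))),
                carrier_rows=members))
    if records:
        reject, p_adj = bh_fdr([r.p for r in records], params.fdr_q)
        for r, flag, pa in zip(records, reject, p_adj):
            r.significant = bool(flag)
            r.p_adjusted = float(pa)
    return records, cutoff


def discover(gm: GenotypeMatrix, ped: Pedigree, phenotypes: pd.DataFrame,
             config: AnalysisConfig, seed: int = 0,
             ) -> tuple[list[DiscoveryRecord], dict[str, float]]:
    """Full multi-trait discovery on QC'd genotypes.

    Returns all tested records (flagged by trait-wise genome-wise BH FDR at
    ``config.scan.fdr_q``) and the per-trait cut-offs.  Deterministic for a
    fixed seed.
    """
    run_index = build_run_index(gm, config.scan.min_run)
    ainv = a_inverse(ped)
    all_records: list[DiscoveryRecord] = []
    cutoffs: dict[str, float] = {}
    for i, (name, trait) in enumerate(sorted(config.traits.items())):
        tc = build_trait_context(trait, gm, ped, phenotypes, config,
                                 ainv=ainv)
        recs, cutoff = discover_trait(gm, run_index, tc, config.scan,
                                      seed=seed + i)
        cutoffs[name] = cutoff
        all_records.extend(recs)
    return all_records, cutoffs


# ---------------------------------------------------------------------------
# Pleiotropy and annotation
# ---------------------------------------------------------------------------

@dataclass
class PleiotropyGroup:
    """Significant records from >= 2 traits sharing interval and carriers."""

    chrom: int
    records: list[DiscoveryRecord]

    @property
    def traits(self) -> list[str]:
        return sorted({r.trait for r in self.records})


def pleiotropy_overlap(records: list[DiscoveryRecord], gm: GenotypeMatrix,
                       ) -> list[PleiotropyGroup]:
    """Group significant records across traits with overlapping intervals
    and identical carrier sets (recomputed from the genotypes)."""
    sig = [r for r in records if r.significant]
    used: set[int] = set()
    groups: list[PleiotropyGroup] = []
    for i, ri in enumerate(sig):
        if i in used:
            continue
        group = [ri]
        set_i = _verified_carriers(ri, gm)
        for j in range(i + 1, len(sig)):
            rj = sig[j]
            if j in used or rj.trait == ri.trait:
                continue
            if not rj.overlaps(ri.chrom, ri.start_idx, ri.end_idx):
                continue
            if _verified_carriers(rj, gm) == set_i:
                group.append(rj)
                used.add(j)
        if len({r.trait for r in group}) >= 2:
            groups.append(PleiotropyGroup(ri.chrom, group))
            used.add(i)
    return groups


def _verified_carriers(rec: DiscoveryRecord, gm: GenotypeMatrix
                       ) -> frozenset[int]:
    block = gm.values[rec.carrier_rows, rec.start_idx:rec.end_idx]
    hom = np.all((block == 0) | (block == 2), axis=1)
    if not hom.all():
        logger.warning("record %s has carriers no longer homozygous",
                       rec.class_id)
    return frozenset(np.asarray(rec.carrier_rows)[hom].tolist())


# -- gene annotation ---------------------------------------------------------

def _read_gene_table(path) -> pd.DataFrame:
    """Read a BED (0-based half-open) or GFF3 (1-based inclusive) gene table
    into half-open bp intervals.  Malformed lines are skipped with a
    warning."""
    rows = []
    is_gff = str(path).endswith((".gff", ".gff3"))
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if is_gff:
                    if len(f) < 9:
                        raise ValueError("fewer than 9 GFF3 fields")
                    if f[2] != "gene":
                        continue
                    chrom = int(f[0])
                    start = int(f[3]) - 1  # to 0-based half-open
                    end = int(f[4])
                    name = f"gene_l{ln}"
                    for key in ("Name", "gene_id", "ID"):
                        m = re.search(rf"(?:^|;){key}=([^;]+)", f[8])
                        if m:
                            name = m.group(1)
                            break
                else:
                    if len(f) < 3:
                        raise ValueError("fewer than 3 BED fields")
                    chrom = int(f[0].removeprefix("chr"))
                    start, end = int(f[1]), int(f[2])
                    name = f[3] if len(f) > 3 else f"gene_l{ln}"
                if end <= start:
                    raise ValueError("empty interval")
            except ValueError as exc:
                logger.warning("skipping malformed annotation line %d: %s",
                               ln, exc)
                continue
            rows.append((chrom, start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def annotate_genes(records: list[DiscoveryRecord], annotation_path,
                   ) -> dict[str, list[str]]:
    """Genes whose span intersects each record's bp interval (half-open).

    Record intervals are taken as [start_bp, end_bp + 1) so the last SNP's
    base is included; zero-length (abutting) overlaps do not count.
    Returns a mapping class_id -> sorted gene names.
    """
    genes = _read_gene_table(annotation_path)
    out: dict[str, list[str]] = {}
    for rec in records:
        lo, hi = rec.start_bp - 1, rec.end_bp  # record span, 0-based half-open
        hits = genes[(genes["chrom"] == rec.chrom)
                     & (genes["start"] < hi) & (lo < genes["end"])]
        out[rec.class_id] = sorted(set(hits["name"]))
    return out


# ---------------------------------------------------------------------------
# Truth evaluation (simulation studies)
# ---------------------------------------------------------------------------

def _is_true_discovery(rec: DiscoveryRecord,
                       planted_intervals: list[tuple[int, int, int]],
                       planted_carriers: list[set[int]] | None) -> bool:
    if any(rec.overlaps(c, s, e) for c, s, e in planted_intervals):
        return True
    if planted_carriers and rec.carrier_rows is not None:
        own = set(np.asarray(rec.carrier_rows).tolist())
        return any(own & ps for ps in planted_carriers)
    return False


def false_discovery_proportion(records: list[DiscoveryRecord],
                               planted_intervals: list[tuple[int, int, int]],
                               planted_carriers: list[set[int]] | None = None,
                               ) -> tuple[float, int, int]:
    """V/max(R,1) for one replicate against the planted truth.

    Planted effects attach to animals, so the one-tailed null hypothesis of
    a tested class (contrast >= 0 in the unfavorable-is-lower case) is false
    for *any* class containing at least one planted carrier: its true
    contrast is effect * (shared/n) on the unfavorable side.  A significant
    record is therefore a true discovery when its SNP-index interval
    overlaps a planted (chrom, start, end) interval or when its carrier set
    shares at least one animal with a planted carrier set; significant
    records of genuinely null classes count as false.
    """
    sig = [r for r in records if r.significant]
    false = sum(1 for r in sig
                if not _is_true_discovery(r, planted_intervals,
                                          planted_carriers))
    return false / max(len(sig), 1), false, len(sig)


def evaluate_truth(records: list[DiscoveryRecord], truth,
                   trait: str | None = None,
                   ) -> dict:
    """Score one replicate's records against a SimTruth.

    Returns the false-discovery proportion plus, per planted class, a
    detection flag (a significant record overlapping the planted interval)
    and the effect estimate of the best-matching significant record (highest
    carrier-set Jaccard similarity).
    """
    recs = [r for r in records if trait is None or r.trait == trait]
    intervals = [(p.chrom, p.start, p.end) for p in truth.planted]
    carrier_sets = [set(p.carrier_rows.tolist()) for p in truth.planted]
    fdp, n_false, n_sig = false_discovery_proportion(recs, intervals,
                                                     carrier_sets)
    detected: list[bool] = []
    estimates: list[float | None] = []
    for (c, s, e), ps in zip(intervals, carrier_sets):
        hits = [r for r in recs if r.significant and r.overlaps(c, s, e)]
        detected.append(bool(hits))
        if hits:
            def jaccard(r):
                own = set(np.asarray(r.carrier_rows).tolist())
                return len(own & ps) / len(own | ps)
            estimates.append(max(hits, key=jaccard).effect)
        else:
            estimates.append(None)
    return {"fdp": fdp, "n_false": n_false, "n_significant": n_sig,
            "detected": detected, "effect_estimates": estimates}
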