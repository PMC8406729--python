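"""Synthetic pedigree, genotype and phenotype generation with planted truth.

The generator emulates an intensely selected dairy population at desk scale:
a multi-generation overlapping pedigree with few sires (so inbreeding and
hence ROH accumulate mechanistically), genotypes by gene dropping founder
haplotypes through the pedigree with Haldane recombination, phenotypes from
the same animal mixed model the pipeline fits, and *planted* unfavorable
ROH-class effects whose carrier sets are recorded exactly, giving every
downstream stage a known ground truth.

Gene dropping (rather than a coalescent) is used deliberately: shared
homozygote strings then arise from recent identity-by-descent, which is the
inbreeding mechanism the discovery procedure targets.

Default desk-scale shape: 5 chromosomes x 600 SNPs at 50 kb spacing and
roughly 2,000 animals, about 20x smaller than a national 50K-array cow
dataset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .animal_model import inbreeding
from .data import (GenotypeMatrix, Pedigree, SNPMap, VarianceComponents)

logger = logging.getLogger("rohscan")


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(n_founders: int = 200, n_generations: int = 8,
                      offspring_per_dam: int = 2, sire_fraction: float = 0.05,
                      seed: int = 0) -> Pedigree:
    """Overlapping-generation pedigree under intense sire selection.

    Each generation, every dam of the previous generation produces
    ``offspring_per_dam`` offspring by a sire drawn from a small pool
    (``sire_fraction`` of available males, minimum one), mimicking heavy AI
    sire use; a small sire pool drives up inbreeding.  Founders have unknown
    parents.  Deterministic for a fixed seed.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = np.random.default_rng(seed)
    sire_idx: list[int] = [-1] * n_founders
    dam_idx: list[int] = [-1] * n_founders
    gen: list[int] = [0] * n_founders
    sex = list(rng.integers(0, 2, size=n_founders))  # 0 = male, 1 = female

    cur = list(range(n_founders))
    for g in range(1, n_generations + 1):
        males = [i for i in cur if sex[i] == 0]
        dams = [i for i in cur if sex[i] == 1]
        if not males or not dams:
            raise ValueError("no matings possible: a sex is missing in "
                             f"generation {g - 1}")
        n_sires = max(1, int(round(sire_fraction * len(males))))
        pool = rng.choice(males, size=n_sires, replace=False)
        nxt: list[int] = []
        for dam in dams:
            sires = rng.choice(pool, size=offspring_per_dam)
            for s in sires:
                i = len(sire_idx)
                sire_idx.append(int(s))
                dam_idx.append(int(dam))
                sex.append(int(rng.integers(0, 2)))
                gen.append(g)
                nxt.append(i)
        cur = nxt

    ids = np.array([f"A{i:06d}" for i in range(len(sire_idx))], dtype=object)
    return Pedigree(ids, np.array(sire_idx, dtype=np.int32),
                    np.array(dam_idx, dtype=np.int32),
                    generation=np.array(gen))


# ---------------------------------------------------------------------------
# Genotype simulation (gene dropping)
# ---------------------------------------------------------------------------

def default_snp_map(n_chromosomes: int = 5, snps_per_chrom: int = 600,
                    spacing_bp: int = 50_000) -> SNPMap:
    """Evenly spaced desk-scale SNP map (1 SNP per 50 kb by default)."""
    ids, chrom, pos = [], [], []
    for c in range(1, n_chromosomes + 1):
        for j in range(snps_per_chrom):
            ids.append(f"snp{c}_{j}")
            chrom.append(c)
            pos.append((j + 1) * spacing_bp)
    return SNPMap(np.array(ids, dtype=object), np.array(chrom),
                  np.array(pos))


def simulate_genotypes(ped: Pedigree, snp_map: SNPMap,
                       founder_maf_low: float = 0.1,
                       founder_maf_high: float = 0.5,
                       cM_per_Mb: float = 1.0,
                       seed: int = 0,
                       return_haplotypes: bool = False):
    """Gene-drop genotypes through the pedigree with Haldane recombination.

    Founder haplotypes are drawn in linkage equilibrium with per-SNP
    alternate-allele frequencies uniform in [founder_maf_low,
    founder_maf_high].  Each meiosis samples a Poisson number of crossovers
    on the genetic map (constant cM/Mb, no interference) with a random start
    phase.  Unknown parents contribute a fresh founder-like gamete.  ROH
    thus arise only through identity-by-descent.
    """
    if len(snp_map) == 0:
        raise ValueError("empty SNP map")
    rng = np.random.default_rng(seed)
    n = len(ped)
    m = len(snp_map)
    freqs = rng.uniform(founder_maf_low, founder_maf_high, size=m)
    bounds = snp_map.chrom_bounds()
    chrom_info = []
    for c, (lo, hi) in bounds.items():
        pos = snp_map.position_bp[lo:hi].astype(float)
        span_bp = pos[-1] - pos[0]
        morgans = span_bp * cM_per_Mb / 1e8  # cM/Mb * bp -> Morgans
        chrom_info.append((lo, hi, pos, morgans))

    H = np.empty((n, 2, m), dtype=np.int8)

    def founder_gamete() -> np.ndarray:
        return (rng.random(m) < freqs).astype(np.int8)

    def meiosis(parent: int) -> np.ndarray:
        gam = np.empty(m, dtype=np.int8)
        for lo, hi, pos, morgans in chrom_info:
            k = rng.poisson(morgans) if morgans > 0 else 0
            phase = rng.integers(0, 2)
            if k == 0:
                gam[lo:hi] = H[parent, phase, lo:hi]
                continue
            cx = np.sort(rng.uniform(pos[0], pos[-1], size=k))
            src = (phase + np.searchsorted(cx, pos, side="right")) % 2
            seg = np.where(src == 0, H[parent, 0, lo:hi], H[parent, 1, lo:hi])
            gam[lo:hi] = seg
        return gam

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        H[i, 0] = meiosis(s) if s >= 0 else founder_gamete()
        H[i, 1] = meiosis(d) if d >= 0 else founder_gamete()

    gm = GenotypeMatrix(H.sum(axis=1, dtype=np.int8), ped.animal_ids, snp_map)
    return (gm, H) if return_haplotypes else gm


# ---------------------------------------------------------------------------
# Planted ROH effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantRequest:
    """One ROH class to plant: where, how common, and its trait effects."""

    chrom: int
    length: int                      # SNPs
    carrier_fraction: float
    effects: dict[str, float] = field(default_factory=dict)  # trait -> units
    start: int | None = None         # global column index; random if None


@dataclass
class PlantedClass:
    chrom: int
    start: int  # global column index, half-open
    end: int
    string: bytes  # homozygote code string (values 0/2)
    effects: dict[str, float]
    carrier_rows: np.ndarray  # row indices into the genotype matrix

    def as_dict(self) -> dict:
        return {"chrom": int(self.chrom), "start": int(self.start),
                "end": int(self.end),
                "string": np.frombuffer(self.string, dtype=np.int8).tolist(),
                "effects": {k: float(v) for k, v in self.effects.items()},
                "carrier_rows": [int(r) for r in self.carrier_rows]}


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset: planted classes and settings."""

    planted: list[PlantedClass]
    variance_components: dict[str, VarianceComponents]
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "note": "synthetic ground truth; all distributions are "
                    "simulator choices, not estimates from real data",
            "seed": self.seed,
            "planted": [p.as_dict() for p in self.planted],
            "variance_components": {k: asdict(v) for k, v in
                                    self.variance_components.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def plant_roh_effects(gm: GenotypeMatrix, requests: list[PlantRequest],
                      seed: int = 0, force: bool = False) -> SimTruth:
    """Select or construct planted ROH classes and record exact carriers.

    By default (non-force) an *existing* homozygote string with frequency
    within +/-50% of the target is selected -- carriers are genuinely
    identical by descent and no genotype is edited; an error names the
    request when no such string exists.  In force mode, ceil(fraction * N)
    randomly chosen animals are overwritten over the interval with a
    homozygote string derived from a randomly chosen animal's genotypes;
    this guarantees the carrier count but breaks Mendelian transmission for
    the carriers.  Requested intervals must not overlap.
    """
    rng = np.random.default_rng(seed)
    bounds = gm.snp_map.chrom_bounds()
    n = gm.n_animals
    placed: list[tuple[int, int, int]] = []
    planted: list[PlantedClass] = []

    def check_overlap(chrom: int, start: int, end: int) -> None:
        lo, hi = bounds[chrom]
        if end > hi or start < lo:
            raise ValueError("planted interval crosses chromosome bounds")
        for (c, s, e) in placed:
            if c == chrom and s < end and start < e:
                raise ValueError("planted intervals overlap at "
                                 f"{chrom}:[{start},{end})")

    for req in requests:
        lo, hi = bounds[req.chrom]
        if force:
            start = (req.start if req.start is not None
                     else int(rng.integers(lo, hi - req.length + 1)))
            end = start + req.length
            check_overlap(req.chrom, start, end)
            n_car = int(np.ceil(req.carrier_fraction * n))
            carriers = rng.choice(n, size=n_car, replace=False)
            donor = int(rng.integers(0, n))
            string = (2 * (gm.values[donor, start:end] >= 1)).astype(np.int8)
            gm.values[np.ix_(carriers, np.arange(start, end))] = string
            planted.append(PlantedClass(req.chrom, start, end,
                                        string.tobytes(), dict(req.effects),
                                        np.sort(carriers)))
        else:
            found = _find_existing_class(gm, req, lo, hi, placed)
            if found is None:
                raise ValueError(
                    f"no homozygote string with frequency within 50% of "
                    f"{req.carrier_fraction} on chromosome {req.chrom} "
                    f"(length {req.length})")
            check_overlap(found.chrom, found.start, found.end)
            planted.append(found)
        placed.append((planted[-1].chrom, planted[-1].start, planted[-1].end))
    return SimTruth(planted, {}, seed)


def _find_existing_class(gm: GenotypeMatrix, req: PlantRequest, lo: int,
                         hi: int, placed: list[tuple[int, int, int]]
                         ) -> PlantedClass | None:
    """Best existing homozygote class near the target frequency.

    Scans every admissible start on the chromosome, grouping animals whose
    genotypes are fully homozygous over the interval, and returns the class
    whose carrier count is closest to the target (within the +/-50%
    tolerance).  Deterministic.
    """
    n = gm.n_animals
    target = req.carrier_fraction * n
    min_count = 0.5 * target
    v = gm.values[:, lo:hi]
    hom = (v == 0) | (v == 2)
    # per-start carrier counts via run-length containment
    csum = np.zeros((n, hi - lo + 1), dtype=np.int32)
    np.cumsum(hom, axis=1, out=csum[:, 1:])
    best: tuple[float, PlantedClass] | None = None
    starts = ([req.start] if req.start is not None
              else range(lo, hi - req.length + 1))
    for start in starts:
        t = start - lo
        end = start + req.length
        if any(c == req.chrom and s < end and start < e
               for c, s, e in placed):
            continue
        full = csum[:, t + req.length] - csum[:, t] == req.length
        rows = np.flatnonzero(full)
        if len(rows) < min_count:
            continue
        block = gm.values[np.ix_(rows, np.arange(start, end))]
        groups: dict[bytes, list[int]] = {}
        for row, r in zip(block, rows):
            groups.setdefault(row.tobytes(), []).append(int(r))
        for s, members in groups.items():
            gap = abs(len(members) - target)
            if gap <= 0.5 * target and (best is None or gap < best[0]):
                best = (gap, PlantedClass(req.chrom, start, end, s,
                                          dict(req.effects),
                                          np.array(sorted(members))))
    return best[1] if best else None


def recount_carriers(gm: GenotypeMatrix, planted: PlantedClass) -> np.ndarray:
    """Recompute the carrier set of a planted class from the genotypes."""
    block = gm.values[:, planted.start:planted.end]
    string = np.frombuffer(planted.string, dtype=np.int8)
    return np.flatnonzero(np.all(block == string, axis=1))


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitScale:
    """Observed-scale summary a simulated trait should match."""

    name: str
    mean: float
    sd: float
    kind: str = "continuous"   # continuous | count | binary
    unit: str = ""


def holstein_trait_scales() -> dict[str, TraitScale]:
    """Desk-scale targets mirroring first-lactation Holstein descriptives:
    305-d milk/fat/protein yield, age at first service, number of services
    (1..10), 56-day non-return rate and first service to conception."""
    scales = [
        TraitScale("MY", 9074.0, 1732.2, "continuous", "kg"),
        TraitScale("FY", 362.0, 73.85, "continuous", "kg"),
        TraitScale("PY", 295.50, 54.58, "continuous", "kg"),
        TraitScale("AFS", 449.20, 49.16, "continuous", "day"),
        TraitScale("NS", 1.59, 0.93, "count", "services"),
        TraitScale("NRR", 0.69, 0.46, "binary", ""),
        TraitScale("FSTC", 19.32, 33.37, "continuous", "day"),
    ]
    return {t.name: t for t in scales}


def simulate_phenotypes(ped: Pedigree, gm: GenotypeMatrix, truth: SimTruth,
                        vc: dict[str, VarianceComponents],
                        n_fixed_levels: dict[str, int] | None = None,
                        n_random_levels: dict[str, int] | None = None,
                        traits: dict[str, TraitScale] | None = None,
                        fixed_effect_sd_fraction: float = 0.25,
                        seed: int = 0) -> pd.DataFrame:
    """Phenotypes from the animal mixed model, with planted class effects.

    Per trait: additive values are sampled pedigree-recursively with
    covariance A*sigma2_a (founders N(0, sigma2_a); offspring = parent mean
    + Mendelian-sampling deviation of variance sigma2_a(1-(F_s+F_d)/2)/2);
    the four i.i.d. random factors and categorical fixed-effect level means
    are Gaussian; planted effects are added to their carriers; residuals are
    i.i.d.  Binary traits threshold the latent Gaussian at the configured
    incidence and count traits round and cap the latent value (1..10 for
    number of services), so the observed scale is only approximately the
    latent one.

    Returns a DataFrame with animal_id, one column per trait and the factor
    columns, with factor level assignments shared across traits.
    """
    rng = np.random.default_rng(seed)
    if traits is None:
        traits = {name: holstein_trait_scales()[name] for name in vc}
    missing = set(vc) - set(traits)
    if missing:
        raise ValueError(f"no trait scale for {sorted(missing)}")
    row_of = {a: i for i, a in enumerate(gm.animal_ids)}
    for a in gm.animal_ids:
        if a not in ped.index_of:
            raise ValueError(f"genotyped animal {a} missing from pedigree")
    ped_row = np.array([ped.index_of[a] for a in gm.animal_ids])
    n = gm.n_animals
    F = inbreeding(ped)

    n_fixed_levels = n_fixed_levels or {}
    n_random_levels = n_random_levels or {}
    df = pd.DataFrame({"animal_id": gm.animal_ids})
    fixed_assign = {}
    for fac, k in n_fixed_levels.items():
        codes = rng.integers(0, k, size=n)
        fixed_assign[fac] = codes
        df[fac] = [f"{fac}_{c}" for c in codes]
    random_assign = {}
    for fac, k in n_random_levels.items():
        codes = rng.integers(0, k, size=n)
        random_assign[fac] = codes
        df[fac] = [f"{fac}_{c}" for c in codes]

    for trait, comp in vc.items():
        scale = traits[trait]
        a_ped = _sample_breeding_values(ped, F, comp.sigma2_a, rng)
        latent = np.full(n, scale.mean, dtype=float)
        latent += a_ped[ped_row]
        for fac, codes in fixed_assign.items():
            level_means = rng.normal(0.0, fixed_effect_sd_fraction * scale.sd,
                                     size=codes.max() + 1)
            latent += level_means[codes]
        for (fac, codes), s2 in zip(random_assign.items(),
                                    comp.iid_components):
            if s2 > 0:
                level_eff = rng.normal(0.0, np.sqrt(s2), size=codes.max() + 1)
                latent += level_eff[codes]
        latent += rng.normal(0.0, np.sqrt(comp.sigma2_e), size=n)
        for planted in truth.planted:
            eff = planted.effects.get(trait, 0.0)
            if eff:
                rows = np.array([row_of[gm.animal_ids[r]]
                                 for r in planted.carrier_rows])
                latent[rows] += eff
        if scale.kind == "binary":
            # threshold the latent Gaussian so P(y=1) equals the incidence
            thr = scale.mean - np.sqrt(comp.total) * norm.ppf(scale.mean)
            df[trait] = (latent > thr).astype(int)
        elif scale.kind == "count":
            df[trait] = np.clip(np.round(latent), 1, 10).astype(int)
        else:
            df[trait] = latent
    return df


def standard_variance_components(sd: float, h2: float = 0.3,
                                 iid_fraction: float = 0.05,
                                 ) -> VarianceComponents:
    """Partition a phenotypic variance sd^2 into model components.

    h2 goes to the additive component, ``iid_fraction`` to each of the four
    i.i.d. factors, the remainder to the residual.
    """
    tot = sd * sd
    resid = 1.0 - h2 - 4 * iid_fraction
    if resid <= 0:
        raise ValueError("h2 and iid fractions exceed the total variance")
    return VarianceComponents(sigma2_a=h2 * tot,
                              sigma2_HY=iid_fraction * tot,
                              sigma2_HRYS=iid_fraction * tot,
                              sigma2_SS=iid_fraction * tot,
                              sigma2_AIT=iid_fraction * tot,
                              sigma2_e=resid * tot)


@dataclass
class SimulatedStudy:
    """One complete synthetic dataset plus its ground truth and config."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: SimTruth
    config: "object"  # AnalysisConfig; typed loosely to avoid an import cycle


def simulate_study(seed: int, traits: tuple[str, ...] = ("MY",),
                   n_founders: int = 200, n_generations: int = 8,
                   n_chromosomes: int = 5, snps_per_chrom: int = 600,
                   h2: float = 0.3, n_planted: int = 3,
                   planted_effect_sd: float = -1.0,
                   planted_fraction: float = 0.03,
                   planted_length: int = 60,
                   n_fixed_levels: dict[str, int] | None = None,
                   n_random_levels: dict[str, int] | None = None,
                   ) -> SimulatedStudy:
    """Desk-scale study: pedigree, gene-dropped genotypes, planted classes
    and phenotypes, plus a matching analysis configuration.

    ``planted_effect_sd`` is the planted class effect in phenotypic standard
    deviations (negative = depresses the trait); planted classes are placed
    on distinct chromosomes.  The analysis config carries the
    simulation-true variance components.
    """
    from .data import AnalysisConfig, default_trait_config

    scales = holstein_trait_scales()
    if n_fixed_levels is None:
        n_fixed_levels = {"f1": 8, "f2": 5}
    if n_random_levels is None:
        n_random_levels = {"r1": 25, "r2": 25, "r3": 20, "r4": 20}
    ped = simulate_pedigree(n_founders=n_founders,
                            n_generations=n_generations, seed=seed)
    smap = default_snp_map(n_chromosomes, snps_per_chrom)
    gm = simulate_genotypes(ped, smap, seed=seed + 1)

    effects = {}
    for t in traits:
        sc = scales[t]
        sign = 1.0 if default_trait_config(t).unfavorable_direction == \
            "higher" else -1.0
        effects[t] = abs(planted_effect_sd) * sc.sd * sign \
            if planted_effect_sd != 0 else 0.0
    # one planted class per chromosome where an eligible IBD class exists;
    # chromosomes lacking one are skipped, then revisited for extra classes
    truth = SimTruth([], {}, seed)
    if n_planted > 0:
        chrom_order = ([1 + k % n_chromosomes
                        for k in range(n_planted)]
                       + [1 + k % n_chromosomes
                          for k in range(n_planted, 3 * n_chromosomes)])
        bounds = smap.chrom_bounds()
        placed: list[tuple[int, int, int]] = []
        for chrom in chrom_order:
            if len(truth.planted) == n_planted:
                break
            req = PlantRequest(chrom, planted_length, planted_fraction,
                               effects)
            lo, hi = bounds[chrom]
            found = _find_existing_class(gm, req, lo, hi, placed)
            if found is None:
                continue
            truth.planted.append(found)
            placed.append((found.chrom, found.start, found.end))
        if len(truth.planted) < n_planted:
            raise ValueError("could not place all planted classes; genome "
                             "has too few eligible IBD classes")

    vc = {t: standard_variance_components(scales[t].sd, h2=h2)
          for t in traits}
    truth.variance_components = vc
    pheno = simulate_phenotypes(ped, gm, truth, vc,
                                n_fixed_levels=n_fixed_levels,
                                n_random_levels=n_random_levels,
                                seed=seed + 3)
    config = AnalysisConfig(
        traits={t: default_trait_config(t) for t in traits},
        fixed_factors=list(n_fixed_levels),
        random_factors=list(n_random_levels),
        variance_components=vc)
    return SimulatedStudy(ped, gm, pheno, truth, config)


def _sample_breeding_values(ped: Pedigree, F: np.ndarray, sigma2_a: float,
                            rng: np.random.Generator) -> np.ndarray:
    n = len(ped)
    a = np.zeros(n)
    if sigma2_a <= 0:
        return a
    sd_f = np.sqrt(sigma2_a)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            a[i] = rng.normal(0.0, sd_f)
        elif s >= 0 and d >= 0:
            ms_var = sigma2_a * (1 - (F[s] + F[d]) / 2) / 2
            a[i] = 0.5 * (a[s] + a[d]) + rng.normal(0.0, np.sqrt(ms_var))
        else:
            p = max(s, d)
            ms_var = sigma2_a * (0.75 - F[p] / 4)
            a[i] = 0.5 * a[p] + rng.normal(0.0, np.sqrt(ms_var))
    return a
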