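"""Shared data model, file I/O and configuration.

Containers used throughout the pipeline: a SNP map plus genotype matrix in
alternate-allele-count coding, a topologically sorted pedigree, a phenotype
table, and the configuration objects (scan parameters, per-trait direction of
the unfavorable effect, variance components of the animal model).

Coordinate conventions
----------------------
SNP windows are half-open 0-based column-index intervals ``[start, end)``.
Genomic spans are reported as the 1-based bp positions of the first and last
SNP, and in Mb rounded to 2 decimals.

Allele coding
-------------
PLINK text genotypes are recoded per SNP to counts of the *alternate* allele,
defined as the lexicographically later of the two alleles observed at that
SNP.  This convention is arbitrary but harmless: ROH classing groups animals
by homozygote strings, which is invariant to allele polarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("rohscan")

#: sentinel for a missing genotype call in the int8 code matrix
MISSING: int = -1

#: chromosomes labelled 1..29 are cattle autosomes; anything else is dropped by QC
MAX_AUTOSOME: int = 29

#: traits for which a *lower* value is unfavorable; all other known traits are
#: higher-unfavorable (more services, longer intervals are worse)
LOWER_UNFAVORABLE = ("MY", "FY", "PY", "NRR")
HIGHER_UNFAVORABLE = ("NS", "FSTC", "AFS")


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


class ConfigError(ValueError):
    """Raised for unknown or inconsistent configuration keys."""


# ---------------------------------------------------------------------------
# SNP map and genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class SNPMap:
    """Ordered SNP metadata: ids, chromosome labels and bp positions.

    Rows are ordered by (chromosome, position) and row ``i`` describes column
    ``i`` of the genotype matrix.  Positions must be strictly increasing
    within a chromosome.
    """

    snp_id: np.ndarray      # str array, length M
    chromosome: np.ndarray  # int array, length M
    position_bp: np.ndarray  # int array, length M

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=np.int64)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        if not (len(self.snp_id) == len(self.chromosome) == len(self.position_bp)):
            raise FormatError("SNPMap fields must have equal length")
        if np.any(self.position_bp < 0):
            raise FormatError("SNP positions must be non-negative")
        order = np.lexsort((self.position_bp, self.chromosome))
        if not np.array_equal(order, np.arange(len(order))):
            raise FormatError("SNPMap must be sorted by (chromosome, position)")
        for c in np.unique(self.chromosome):
            pos = self.position_bp[self.chromosome == c]
            if np.any(np.diff(pos) <= 0):
                raise FormatError(
                    f"positions not strictly increasing on chromosome {c}"
                )

    def __len__(self) -> int:
        return len(self.snp_id)

    def chrom_bounds(self) -> dict[int, tuple[int, int]]:
        """Half-open column-index range ``[lo, hi)`` of each chromosome."""
        out: dict[int, tuple[int, int]] = {}
        for c in np.unique(self.chromosome):
            idx = np.flatnonzero(self.chromosome == c)
            out[int(c)] = (int(idx[0]), int(idx[-1]) + 1)
        return out

    def subset(self, keep: np.ndarray) -> "SNPMap":
        return SNPMap(self.snp_id[keep], self.chromosome[keep], self.position_bp[keep])


@dataclass
class GenotypeMatrix:
    """Animals x SNPs matrix of alternate-allele counts {0,1,2} or MISSING."""

    values: np.ndarray       # int8, shape (N, M)
    animal_ids: np.ndarray   # str array, length N
    snp_map: SNPMap

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        if self.values.ndim != 2:
            raise FormatError("genotype matrix must be 2-D")
        n, m = self.values.shape
        if n != len(self.animal_ids):
            raise FormatError("one row per animal id required")
        if m != len(self.snp_map):
            raise FormatError("one column per SNP required")
        if len(set(self.animal_ids)) != n:
            raise FormatError("duplicate animal ids in genotype matrix")
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            raise FormatError("genotype codes must be in {0,1,2} or MISSING")

    @property
    def n_animals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.values[:, keep], self.animal_ids,
                              self.snp_map.subset(keep))


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

class PedigreeCycleError(ValueError):
    """A pedigree contains an animal that is its own ancestor."""


@dataclass
class Pedigree:
    """Animal/sire/dam triples in topological order (parents precede offspring).

    ``sire`` / ``dam`` hold 0-based row indices into ``animal_ids`` or -1 for
    an unknown parent.  Construction via :meth:`from_records` performs cycle
    detection and the topological sort; founders are animals with both
    parents unknown.
    """

    animal_ids: np.ndarray  # str array, length n
    sire: np.ndarray        # int32 indices, -1 = unknown
    dam: np.ndarray
    generation: np.ndarray | None = None  # optional simulator metadata

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.sire = np.asarray(self.sire, dtype=np.int32)
        self.dam = np.asarray(self.dam, dtype=np.int32)
        n = len(self.animal_ids)
        for par in (self.sire, self.dam):
            if np.any(par >= np.arange(n)):
                raise PedigreeCycleError("pedigree is not topologically sorted")

    def __len__(self) -> int:
        return len(self.animal_ids)

    @property
    def index_of(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.animal_ids)}

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire < 0) & (self.dam < 0)))

    @classmethod
    def from_records(cls, records: list[tuple[str, str | None, str | None]],
                     ) -> "Pedigree":
        """Build a pedigree from (animal, sire, dam) string triples.

        Parents that never appear as animals are silently added as founders
        (with a log message); a cycle raises :class:`PedigreeCycleError`
        naming one offending cycle.
        """
        null = {None, "", "0", "NA", "nan"}
        parents: dict[str, tuple[str | None, str | None]] = {}
        order: list[str] = []
        for animal, sire, dam in records:
            animal = str(animal)
            s = None if sire is None or str(sire) in null else str(sire)
            d = None if dam is None or str(dam) in null else str(dam)
            if animal in parents:
                raise FormatError(f"duplicate pedigree record for {animal}")
            parents[animal] = (s, d)
            order.append(animal)
        extra = []
        for s, d in list(parents.values()):
            for p in (s, d):
                if p is not None and p not in parents:
                    parents[p] = (None, None)
                    extra.append(p)
        if extra:
            logger.info("added %d parent-only animals as founders", len(extra))
        order = extra + order

        # Kahn topological sort over the parent->offspring DAG
        state: dict[str, int] = {}
        sorted_ids: list[str] = []

        def visit(a: str) -> None:
            stack = [(a, False)]
            path: list[str] = []
            while stack:
                node, done = stack.pop()
                if done:
                    state[node] = 2
                    path.pop()
                    sorted_ids.append(node)
                    continue
                st = state.get(node, 0)
                if st == 2:
                    continue
                if st == 1:
                    cyc = path[path.index(node):] + [node]
                    raise PedigreeCycleError(
                        "pedigree cycle: " + " -> ".join(cyc))
                state[node] = 1
                path.append(node)
                stack.append((node, True))
                for p in parents[node]:
                    if p is not None and state.get(p, 0) != 2:
                        if state.get(p, 0) == 1:
                            cyc = path[path.index(p):] + [p]
                            raise PedigreeCycleError(
                                "pedigree cycle: " + " -> ".join(cyc))
                        stack.append((p, False))

        for a in order:
            if state.get(a, 0) != 2:
                visit(a)

        idx = {a: i for i, a in enumerate(sorted_ids)}
        sire_idx = np.full(len(sorted_ids), -1, dtype=np.int32)
        dam_idx = np.full(len(sorted_ids), -1, dtype=np.int32)
        for a, (s, d) in parents.items():
            if s is not None:
                sire_idx[idx[a]] = idx[s]
            if d is not None:
                dam_idx[idx[a]] = idx[d]
        return cls(np.array(sorted_ids, dtype=object), sire_idx, dam_idx)


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV with header ``animal,sire,dam`` (0/empty = unknown)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    need = {"animal", "sire", "dam"}
    if not need.issubset(df.columns):
        raise FormatError(f"pedigree file must have columns {sorted(need)}")
    return Pedigree.from_records(
        list(df[["animal", "sire", "dam"]].itertuples(index=False, name=None)))


def write_pedigree(ped: Pedigree, path) -> None:
    sire = [ped.animal_ids[s] if s >= 0 else "0" for s in ped.sire]
    dam = [ped.animal_ids[d] if d >= 0 else "0" for d in ped.dam]
    pd.DataFrame({"animal": ped.animal_ids, "sire": sire, "dam": dam}
                 ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PLINK text and TSV genotype I/O
# ---------------------------------------------------------------------------

def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK text .ped/.map files into alternate-allele-count coding.

    The alternate allele at each SNP is the lexicographically later of the
    two observed alleles; '0 0' pairs become MISSING.  SNPs are sorted by
    (chromosome, position) and matrix columns reordered to match.
    """
    mp = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str)
    if mp.shape[1] != 4:
        raise FormatError(".map file must have 4 columns")
    chrom = mp[0].astype(int).to_numpy()
    snp_id = mp[1].to_numpy(dtype=object)
    pos = mp[3].astype(int).to_numpy()
    m = len(mp)

    animal_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise FormatError(
                    f".ped row for {tok[1] if len(tok) > 1 else '?'} has "
                    f"{len(tok) - 6} allele fields, expected {2 * m}")
            animal_ids.append(tok[1])
            allele_rows.append(np.array(tok[6:], dtype="U1"))
    alleles = np.array(allele_rows)  # (N, 2M)
    a1, a2 = alleles[:, 0::2], alleles[:, 1::2]

    codes = np.full((len(animal_ids), m), MISSING, dtype=np.int8)
    for j in range(m):
        pair = np.stack([a1[:, j], a2[:, j]], axis=1)
        miss = (pair == "0").any(axis=1)
        obs = np.unique(pair[~miss])
        if len(obs) > 2:
            raise FormatError(f"SNP {snp_id[j]} has >2 alleles: {sorted(obs)}")
        if len(obs) == 0:
            continue  # all missing
        alt = sorted(obs)[-1]
        codes[~miss, j] = (pair[~miss] == alt).sum(axis=1)

    order = np.lexsort((pos, chrom))
    gm = GenotypeMatrix(codes[:, order], np.array(animal_ids, dtype=object),
                        SNPMap(snp_id[order], chrom[order], pos[order]))
    return gm


def write_plink_text(gm: GenotypeMatrix, ped_path, map_path,
                     ref: str = "A", alt: str = "G") -> None:
    """Write .ped/.map text using fixed ref/alt allele letters (alt > ref)."""
    if not ref < alt:
        raise ValueError("ref allele letter must sort before alt")
    smap = gm.snp_map
    with open(map_path, "w") as fh:
        for j in range(len(smap)):
            fh.write(f"{smap.chromosome[j]}\t{smap.snp_id[j]}\t0\t"
                     f"{smap.position_bp[j]}\n")
    pair = {0: f"{ref} {ref}", 1: f"{ref} {alt}", 2: f"{alt} {alt}",
            MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, aid in enumerate(gm.animal_ids):
            geno = " ".join(pair[int(c)] for c in gm.values[i])
            fh.write(f"FAM {aid} 0 0 0 -9 {geno}\n")


def read_genotype_tsv(path) -> GenotypeMatrix:
    """Read a genotype TSV: animal_id + one 0/1/2/NA column per SNP.

    Column headers are ``snpid:chrom:pos``.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    snp_cols = df.columns[1:]
    ids, chrom, pos = [], [], []
    for c in snp_cols:
        parts = c.rsplit(":", 2)
        if len(parts) != 3:
            raise FormatError(f"bad SNP column header {c!r}")
        ids.append(parts[0]); chrom.append(int(parts[1])); pos.append(int(parts[2]))
    vals = df[snp_cols].to_numpy(dtype=float)
    codes = np.where(np.isnan(vals), MISSING, vals).astype(np.int8)
    return GenotypeMatrix(codes, df.iloc[:, 0].to_numpy(dtype=object),
                          SNPMap(np.array(ids, dtype=object), chrom, pos))


def write_genotype_tsv(gm: GenotypeMatrix, path) -> None:
    smap = gm.snp_map
    cols = [f"{smap.snp_id[j]}:{smap.chromosome[j]}:{smap.position_bp[j]}"
            for j in range(len(smap))]
    df = pd.DataFrame(gm.values, columns=cols)
    df = df.mask(df == MISSING)
    df.insert(0, "animal_id", gm.animal_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA",
              float_format="%.0f")


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype/covariate CSV; first column must be ``animal_id``."""
    df = pd.read_csv(path, dtype={"animal_id": str})
    if df.columns[0] != "animal_id":
        raise FormatError("phenotype file must start with an animal_id column")
    return df


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitConfig:
    """Name, unfavorable direction and unit of one analyzed trait."""

    name: str
    unfavorable_direction: str  # "lower" or "higher"
    unit: str = ""

    def __post_init__(self) -> None:
        if self.unfavorable_direction not in ("lower", "higher"):
            raise ConfigError(
                f"direction for {self.name} must be 'lower' or 'higher'")


def default_trait_config(name: str) -> TraitConfig:
    if name in LOWER_UNFAVORABLE:
        return TraitConfig(name, "lower")
    if name in HIGHER_UNFAVORABLE:
        return TraitConfig(name, "higher")
    raise ConfigError(f"no default unfavorable direction for trait {name!r}; "
                      "declare one in the config")


@dataclass(frozen=True)
class ScanParams:
    """Tuning knobs of the sliding-window ROH-genotype scan.

    Defaults follow the published procedure: 60-SNP windows slid by one SNP,
    shrunk by 5 SNPs down to 50; runs of at least 15 homozygous SNPs; class
    frequency above 0.75%; genome-wise FDR at 1%; the empirical phenotype
    cut-off from 1000 randomly sampled windows using classes whose one-tailed
    significance falls in [0.05, 0.10].
    """

    initial_window: int = 60
    window_decrement: int = 5
    min_window: int = 50
    slide_step: int = 1
    min_run: int = 15
    min_class_frequency: float = 0.0075
    fdr_q: float = 0.01
    threshold_samples: int = 1000
    threshold_sig_range: tuple[float, float] = (0.05, 0.10)

    def __post_init__(self) -> None:
        if not self.min_window <= self.initial_window:
            raise ConfigError("min_window must be <= initial_window")
        if not 0 < self.min_class_frequency < 1:
            raise ConfigError("min_class_frequency must be in (0,1)")
        if not 0 < self.fdr_q < 1:
            raise ConfigError("fdr_q must be in (0,1)")
        lo, hi = self.threshold_sig_range
        if not 0 <= lo < hi <= 1:
            raise ConfigError("threshold_sig_range must be an increasing pair")

    @property
    def window_sizes(self) -> list[int]:
        return list(range(self.initial_window, self.min_window - 1,
                          -self.window_decrement))


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components of the animal model, in squared trait units.

    The additive variance sigma2_a goes with the pedigree relationship
    matrix; the four i.i.d. components (herd-year, herd within
    region-year-season, service sire, insemination technician in the dairy
    application) go with identity covariance; sigma2_e is residual.
    """

    sigma2_a: float
    sigma2_HY: float = 0.0
    sigma2_HRYS: float = 0.0
    sigma2_SS: float = 0.0
    sigma2_AIT: float = 0.0
    sigma2_e: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ConfigError(f"{f.name} must be non-negative")
        if self.sigma2_e <= 0:
            raise ConfigError("sigma2_e must be positive")

    @property
    def iid_components(self) -> tuple[float, float, float, float]:
        return (self.sigma2_HY, self.sigma2_HRYS, self.sigma2_SS,
                self.sigma2_AIT)

    @property
    def total(self) -> float:
        return (self.sigma2_a + sum(self.iid_components) + self.sigma2_e)

    def scaled(self, factor: float) -> "VarianceComponents":
        return VarianceComponents(*(getattr(self, f.name) * factor
                                    for f in fields(self)))


#: the four i.i.d. random factors of the animal model, in the order their
#: variance components appear in VarianceComponents
RANDOM_FACTOR_COMPONENTS = ("sigma2_HY", "sigma2_HRYS", "sigma2_SS",
                            "sigma2_AIT")


@dataclass
class AnalysisConfig:
    """Full configuration: scan parameters, traits, model factors, variances."""

    scan: ScanParams = field(default_factory=ScanParams)
    traits: dict[str, TraitConfig] = field(default_factory=dict)
    fixed_factors: list[str] = field(default_factory=list)
    random_factors: list[str] = field(default_factory=list)
    variance_components: dict[str, VarianceComponents] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        if self.random_factors and len(self.random_factors) != 4:
            raise ConfigError("the animal model uses exactly 4 i.i.d. random "
                              f"factors, got {len(self.random_factors)}")


_SCAN_KEYS = {f.name for f in fields(ScanParams)}
_VC_KEYS = {f.name for f in fields(VarianceComponents)}


def load_config(path) -> AnalysisConfig:
    """Load a YAML analysis config; unknown keys are an error.

    Unspecified scan keys take ScanParams defaults; traits from the standard
    set get their default unfavorable direction.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {"scan", "traits", "fixed_factors", "random_factors",
             "variance_components"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")

    scan_raw = raw.get("scan") or {}
    bad = set(scan_raw) - _SCAN_KEYS
    if bad:
        raise ConfigError(f"unknown scan key(s): {sorted(bad)}")
    if "threshold_sig_range" in scan_raw:
        scan_raw["threshold_sig_range"] = tuple(scan_raw["threshold_sig_range"])
    scan = ScanParams(**scan_raw)

    traits: dict[str, TraitConfig] = {}
    for name, entry in (raw.get("traits") or {}).items():
        entry = entry or {}
        bad = set(entry) - {"direction", "unit"}
        if bad:
            raise ConfigError(f"unknown trait key(s) for {name}: {sorted(bad)}")
        if "direction" in entry:
            traits[name] = TraitConfig(name, entry["direction"],
                                       entry.get("unit", ""))
        else:
            tc = default_trait_config(name)
            traits[name] = replace(tc, unit=entry.get("unit", tc.unit))

    vcs: dict[str, VarianceComponents] = {}
    for name, entry in (raw.get("variance_components") or {}).items():
        bad = set(entry) - _VC_KEYS
        if bad:
            raise ConfigError(f"unknown variance key(s) for {name}: {sorted(bad)}")
        vcs[name] = VarianceComponents(**entry)

    return AnalysisConfig(scan=scan, traits=traits,
                          fixed_factors=list(raw.get("fixed_factors") or []),
                          random_factors=list(raw.get("random_factors") or []),
                          variance_components=vcs)
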