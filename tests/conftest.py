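"""Shared fixtures and test oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from rohscan import sim, discovery, qc
from rohscan.scan import build_run_index

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


def tabular_a(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Independent tabular-method numerator relationship matrix."""
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            aij = 0.0
            if sire[i] >= 0:
                aij += 0.5 * A[sire[i], j]
            if dam[i] >= 0:
                aij += 0.5 * A[dam[i], j]
            A[i, j] = A[j, i] = aij
        A[i, i] = 1.0
        if sire[i] >= 0 and dam[i] >= 0:
            A[i, i] += 0.5 * A[sire[i], dam[i]]
    return A


def random_pedigree_arrays(n: int, rng: np.random.Generator,
                           founder_fraction: float = 0.2):
    """Random topologically sorted pedigree as (sire, dam) index arrays."""
    sire = np.full(n, -1, dtype=np.int32)
    dam = np.full(n, -1, dtype=np.int32)
    n_f = max(2, int(founder_fraction * n))
    for i in range(n_f, n):
        sire[i] = rng.integers(0, i)
        dam[i] = rng.integers(0, i)
    return sire, dam


@pytest.fixture(scope="session")
def small_study():
    """One desk-scale simulated dataset with three planted classes."""
    return sim.simulate_study(seed=20011)


@pytest.fixture(scope="session")
def planted_replicates():
    """Full-pipeline runs on replicate simulated datasets with planted
    unfavorable classes; shared by the FDR-control and power checks.

    Study conditions: ~2,000 animals over 8 generations, 5 chromosomes x
    600 SNPs, three planted classes (about 3% carriers, -1 phenotypic SD),
    h2 = 0.3, full scan -> mixed model -> BH at q = 0.01.
    """
    results = []
    queue = list(range(1, 21)) + list(range(100, 110))
    while len(results) < 20 and queue:
        seed = queue.pop(0)
        try:
            study = sim.simulate_study(seed=seed * 1000)
        except ValueError:
            # genome without three eligible IBD classes; use a spare seed
            continue
        gm = study.genotypes
        stats = qc.compute_snp_stats(gm)
        gm, _ = qc.apply_snp_filters(stats, gm)
        ri = build_run_index(gm, study.config.scan.min_run)
        tc = discovery.build_trait_context(
            study.config.traits["MY"], gm, study.pedigree,
            study.phenotypes, study.config)
        recs, _ = discovery.discover_trait(gm, ri, tc, study.config.scan,
                                           seed=seed * 1000)
        ev = discovery.evaluate_truth(recs, study.truth, "MY")
        ev["truth_effect"] = study.truth.planted[0].effects["MY"]
        results.append(ev)
    return results
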