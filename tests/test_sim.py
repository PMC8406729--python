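"""Synthetic data generator: pedigree, gene dropping, planting, phenotypes."""

import numpy as np
import pytest

from conftest import tabular_a
from rohscan import sim
from rohscan.animal_model import inbreeding
from rohscan.data import Pedigree, VarianceComponents
from rohscan.scan import build_run_index


def full_sib_line(n_generations):
    """Two founders, then one full-sib pair per generation."""
    sire = [-1, -1]
    dam = [-1, -1]
    prev = (0, 1)
    for g in range(n_generations):
        i = len(sire)
        sire += [prev[0], prev[0]]
        dam += [prev[1], prev[1]]
        prev = (i, i + 1)
    ids = np.array([f"a{i}" for i in range(len(sire))], dtype=object)
    return Pedigree(ids, np.array(sire, dtype=np.int32),
                    np.array(dam, dtype=np.int32))


class TestPedigreeSim:
    def test_zero_generations_founders_only(self):
        ped = sim.simulate_pedigree(n_founders=30, n_generations=0, seed=1)
        assert len(ped) == 30 and ped.n_founders == 30

    def test_deterministic(self):
        p1 = sim.simulate_pedigree(n_founders=50, n_generations=3, seed=5)
        p2 = sim.simulate_pedigree(n_founders=50, n_generations=3, seed=5)
        assert np.array_equal(p1.sire, p2.sire)
        assert np.array_equal(p1.dam, p2.dam)
        assert list(p1.animal_ids) == list(p2.animal_ids)

    def test_intense_selection_builds_inbreeding(self):
        """Few sires over 8 generations drive mean F of the last
        generation above zero (checked against the tabular-A oracle)."""
        ped = sim.simulate_pedigree(n_founders=60, n_generations=8,
                                    sire_fraction=0.02, seed=2)
        A = tabular_a(ped.sire, ped.dam)
        F = np.diag(A) - 1.0
        last = ped.generation == ped.generation.max()
        assert F[last].mean() > 0.05
        assert np.allclose(inbreeding(ped), F, atol=1e-9)


class TestGeneDropping:
    def test_mendelian_consistency(self):
        ped = sim.simulate_pedigree(n_founders=40, n_generations=3, seed=3)
        gm = sim.simulate_genotypes(ped, sim.default_snp_map(2, 100), seed=4)
        g = gm.values
        for i in range(len(ped)):
            s, d = ped.sire[i], ped.dam[i]
            if s < 0 or d < 0:
                continue
            lo = (g[s] > 1).astype(int) + (g[d] > 1).astype(int)
            hi = 2 - (g[s] < 1).astype(int) - (g[d] < 1).astype(int)
            assert np.all(g[i] >= lo) and np.all(g[i] <= hi)

    def test_zero_recombination_transmits_whole_haplotypes(self):
        ped = sim.simulate_pedigree(n_founders=10, n_generations=2, seed=6)
        gm, H = sim.simulate_genotypes(ped, sim.default_snp_map(1, 80),
                                       cM_per_Mb=0.0, seed=7,
                                       return_haplotypes=True)
        for i in range(len(ped)):
            for which, par in ((0, ped.sire[i]), (1, ped.dam[i])):
                if par < 0:
                    continue
                gam = H[i, which]
                assert (np.array_equal(gam, H[par, 0])
                        or np.array_equal(gam, H[par, 1]))

    def test_deterministic(self):
        ped = sim.simulate_pedigree(n_founders=20, n_generations=2, seed=8)
        g1 = sim.simulate_genotypes(ped, sim.default_snp_map(1, 60), seed=9)
        g2 = sim.simulate_genotypes(ped, sim.default_snp_map(1, 60), seed=9)
        assert np.array_equal(g1.values, g2.values)

    def test_empty_snp_map_rejected(self):
        ped = sim.simulate_pedigree(n_founders=4, n_generations=0, seed=1)
        smap = sim.default_snp_map(1, 1)
        smap.snp_id = smap.snp_id[:0]
        smap.chromosome = smap.chromosome[:0]
        smap.position_bp = smap.position_bp[:0]
        with pytest.raises(ValueError):
            sim.simulate_genotypes(ped, smap, seed=1)

    def test_full_sib_line_autozygosity(self):
        """Six generations of full-sib mating: at least half the genome
        lies in homozygous runs, matching pedigree expectations (F ~ 0.73)."""
        ped = full_sib_line(6)
        fracs = []
        for seed in range(5):
            gm = sim.simulate_genotypes(ped, sim.default_snp_map(2, 300),
                                        seed=seed)
            ri = build_run_index(gm, 15)
            last_two = [len(ped) - 2, len(ped) - 1]
            for a in last_two:
                in_run = 0
                for chrom, (anim, st, en) in ri.runs.items():
                    mask = anim == a
                    in_run += (en[mask] - st[mask]).sum()
                fracs.append(in_run / gm.n_snps)
        assert np.mean(fracs) >= 0.5

    def test_roh_burden_tracks_pedigree_inbreeding(self):
        ped = sim.simulate_pedigree(n_founders=120, n_generations=6,
                                    sire_fraction=0.04, seed=10)
        gm = sim.simulate_genotypes(ped, sim.default_snp_map(3, 400),
                                    seed=11)
        F = inbreeding(ped)
        ri = build_run_index(gm, 15)
        burden = np.zeros(len(ped))
        for chrom, (anim, st, en) in ri.runs.items():
            np.add.at(burden, anim, en - st)
        burden /= gm.n_snps
        r = np.corrcoef(F, burden)[0, 1]
        assert r >= 0.5


class TestPlanting:
    def test_force_mode_exact_carrier_count(self):
        ped = sim.simulate_pedigree(n_founders=60, n_generations=2, seed=12)
        gm = sim.simulate_genotypes(ped, sim.default_snp_map(2, 200),
                                    seed=13)
        n = gm.n_animals
        req = sim.PlantRequest(1, 60, 0.03, {"MY": -100.0})
        truth = sim.plant_roh_effects(gm, [req], seed=14, force=True)
        p = truth.planted[0]
        assert len(p.carrier_rows) == int(np.ceil(0.03 * n))
        block = gm.values[p.carrier_rows, p.start:p.end]
        assert np.all((block == 0) | (block == 2))
        assert np.all(block == np.frombuffer(p.string, dtype=np.int8))

    def test_overlapping_requests_rejected(self):
        ped = sim.simulate_pedigree(n_founders=60, n_generations=2, seed=12)
        gm = sim.simulate_genotypes(ped, sim.default_snp_map(1, 200),
                                    seed=13)
        reqs = [sim.PlantRequest(1, 80, 0.05, {}, start=10),
                sim.PlantRequest(1, 80, 0.05, {}, start=50)]
        with pytest.raises(ValueError, match="overlap"):
            sim.plant_roh_effects(gm, reqs, seed=1, force=True)

    def test_nonforce_recount_matches_recorded(self):
        ped = sim.simulate_pedigree(n_founders=100, n_generations=6,
                                    sire_fraction=0.04, seed=15)
        gm = sim.simulate_genotypes(ped, sim.default_snp_map(2, 300),
                                    seed=15)
        req = sim.PlantRequest(1, 60, 0.05, {})
        truth = sim.plant_roh_effects(gm, [req], seed=16, force=False)
        p = truth.planted[0]
        recount = sim.recount_carriers(gm, p)
        assert np.array_equal(recount, p.carrier_rows)
        target = 0.05 * gm.n_animals
        assert abs(len(p.carrier_rows) - target) <= 0.5 * target


class TestPhenotypes:
    def test_residual_only_variance(self):
        ped = sim.simulate_pedigree(n_founders=5000, n_generations=0, seed=17)
        gm = sim.simulate_genotypes(ped, sim.default_snp_map(1, 30), seed=18)
        vc = {"MY": VarianceComponents(sigma2_a=0.0, sigma2_e=1500.0 ** 2)}
        truth = sim.SimTruth([], vc, 0)
        df = sim.simulate_phenotypes(ped, gm, truth, vc, seed=19)
        assert df["MY"].std() == pytest.approx(1500.0, rel=0.10)
        assert df["MY"].mean() == pytest.approx(9074.0, rel=0.02)

    def test_planted_effect_recovered_in_raw_means(self):
        rng = np.random.default_rng(20)
        ped = sim.simulate_pedigree(n_founders=5000, n_generations=0, seed=20)
        gm = sim.simulate_genotypes(ped, sim.default_snp_map(1, 80), seed=21)
        carriers = rng.choice(5000, size=250, replace=False)
        planted = sim.PlantedClass(1, 0, 60, b"", {"MY": -500.0},
                                   np.sort(carriers))
        vc = {"MY": VarianceComponents(sigma2_a=0.0, sigma2_e=1000.0 ** 2)}
        truth = sim.SimTruth([planted], vc, 0)
        df = sim.simulate_phenotypes(ped, gm, truth, vc, seed=22)
        y = df["MY"].to_numpy()
        mask = np.zeros(5000, dtype=bool)
        mask[carriers] = True
        diff = y[mask].mean() - y[~mask].mean()
        se = np.sqrt(1000.0 ** 2 / mask.sum() + 1000.0 ** 2 / (~mask).sum())
        assert abs(diff - (-500.0)) < 3 * se

    def test_founder_additive_variance(self):
        ped = sim.simulate_pedigree(n_founders=2000, n_generations=0,
                                    seed=23)
        F = inbreeding(ped)
        rng = np.random.default_rng(24)
        a = sim._sample_breeding_values(ped, F, 4.0, rng)
        assert np.var(a) == pytest.approx(4.0, rel=0.15)

    def test_binary_and_count_traits(self):
        ped = sim.simulate_pedigree(n_founders=4000, n_generations=0, seed=25)
        gm = sim.simulate_genotypes(ped, sim.default_snp_map(1, 30), seed=26)
        scales = sim.holstein_trait_scales()
        vc = {"NRR": sim.standard_variance_components(scales["NRR"].sd),
              "NS": sim.standard_variance_components(scales["NS"].sd)}
        truth = sim.SimTruth([], vc, 0)
        df = sim.simulate_phenotypes(ped, gm, truth, vc,
                                     n_random_levels={"r1": 20, "r2": 20,
                                                      "r3": 20, "r4": 20},
                                     seed=27)
        assert set(df["NRR"].unique()) <= {0, 1}
        assert df["NRR"].mean() == pytest.approx(0.69, abs=0.05)
        assert df["NS"].between(1, 10).all()

    def test_dataset_reproducible(self):
        s1 = sim.simulate_study(seed=404, n_founders=80, n_generations=4,
                                n_chromosomes=2, snps_per_chrom=300,
                                n_planted=1)
        s2 = sim.simulate_study(seed=404, n_founders=80, n_generations=4,
                                n_chromosomes=2, snps_per_chrom=300,
                                n_planted=1)
        assert np.array_equal(s1.genotypes.values, s2.genotypes.values)
        assert s1.phenotypes.equals(s2.phenotypes)
        assert np.array_equal(s1.truth.planted[0].carrier_rows,
                              s2.truth.planted[0].carrier_rows)

    def test_truth_json(self, tmp_path):
        s = sim.simulate_study(seed=405, n_founders=80, n_generations=4,
                               n_chromosomes=2, snps_per_chrom=300,
                               n_planted=1)
        s.truth.to_json(tmp_path / "truth.json")
        import json
        payload = json.loads((tmp_path / "truth.json").read_text())
        assert payload["planted"][0]["carrier_rows"] == \
            s.truth.planted[0].carrier_rows.tolist()
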