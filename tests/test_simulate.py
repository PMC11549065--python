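"""Pedigree simulator: structural invariants, design targets, genotype truth."""

import numpy as np
import pandas as pd
import pytest

from sealkin.demography import LifeHistorySchedules
from sealkin.genotypes import CLASS_FAIL
from sealkin.simulate import (
    GenotypeDesign,
    HarvestDesign,
    SimConfig,
    expected_kin_counts_analytic,
    sample_harvest,
    simulate_genotypes,
    simulate_pedigree,
    study_harvest_design,
)


@pytest.fixture(scope="module")
def small_run():
    sched = LifeHistorySchedules.from_raw()
    years = np.arange(2004, 2014)
    design = HarvestDesign(years=years, n_per_year=np.full(years.size, 25))
    cfg = SimConfig(n_initial=4000, schedules=sched, pi=0.4, harvest=design, burn_in=42)
    ped = simulate_pedigree(cfg, seed=11)
    recs, kin = sample_harvest(ped)
    return cfg, ped, recs, kin


class TestPedigreeStructure:
    def test_structural_invariants(self, small_run):
        cfg, ped, _, _ = small_run
        kids = np.flatnonzero(ped.mother >= 0)
        mothers = ped.mother[kids]
        fathers = ped.father[kids]
        # mothers female, alive at the birth, born before it
        assert np.all(ped.sex[mothers] == 0)
        alive_m = (ped.death[mothers] == -1) | (ped.death[mothers] >= ped.birth[kids])
        assert np.all(alive_m)
        assert np.all(ped.birth[mothers] < ped.birth[kids])
        # fathers male breeders, alive in the birth year
        assert np.all(ped.sex[fathers] == 1)
        assert np.all(ped.breeder[fathers])
        alive_f = (ped.death[fathers] == -1) | (ped.death[fathers] >= ped.birth[kids])
        assert np.all(alive_f)
        # mtDNA strictly maternal
        assert np.all(ped.hap[kids] == ped.hap[mothers])
        # lifespan cap respected
        died = ped.death >= 0
        assert np.all(ped.death[died] - ped.birth[died] <= 39)

    def test_one_pup_per_female_per_year(self, small_run):
        _, ped, _, _ = small_run
        kids = np.flatnonzero(ped.mother >= 0)
        pairs = set(zip(ped.mother[kids].tolist(), ped.birth[kids].tolist()))
        assert len(pairs) == kids.size

    def test_identical_seeds_identical_pedigrees(self, small_run):
        cfg, ped, _, _ = small_run
        ped2 = simulate_pedigree(cfg, seed=11)
        assert np.array_equal(ped.birth, ped2.birth)
        assert np.array_equal(ped.death, ped2.death)
        assert np.array_equal(ped.father, ped2.father)
        assert np.array_equal(ped.hap, ped2.hap)

    def test_no_fecundity_stops_births(self):
        sched = LifeHistorySchedules.from_raw()
        zero_f = LifeHistorySchedules(
            phi=sched.phi, fecundity=np.zeros_like(sched.fecundity), maturity=sched.maturity
        )
        years = np.arange(2000, 2002)
        cfg = SimConfig(
            n_initial=500,
            schedules=zero_f,
            harvest=HarvestDesign(years=years, n_per_year=np.array([5, 5])),
            burn_in=5,
        )
        ped = simulate_pedigree(cfg, seed=0)
        assert np.all(ped.mother == -1)  # founders only


class TestHarvest:
    def test_realized_pup_fraction_matches_design(self):
        sched = LifeHistorySchedules.from_raw()
        design = study_harvest_design(total=1000, start_year=2005, end_year=2015)
        cfg = SimConfig(n_initial=30_000, schedules=sched, pi=0.5, harvest=design, burn_in=41)
        ped = simulate_pedigree(cfg, seed=1)
        recs, _ = sample_harvest(ped, include_third_order=False)
        ages = np.array([r.age for r in recs])
        assert len(recs) == 1000
        assert abs((ages == 0).mean() - 0.46) < 0.02

    def test_shortfall_logged_when_demand_exceeds_supply(self):
        sched = LifeHistorySchedules.from_raw()
        years = np.arange(2000, 2001)
        cfg = SimConfig(
            n_initial=60,
            schedules=sched,
            harvest=HarvestDesign(years=years, n_per_year=np.array([120])),
            burn_in=3,
        )
        ped = simulate_pedigree(cfg, seed=2)
        assert ped.shortfalls

    def test_mother_pup_same_year_pair_is_pop(self, small_run):
        # a mother and her pup harvested in the whelping year are labeled
        # POP with matching sampling years (the same-year exclusion case)
        _, ped, recs, kin = small_run
        rd = {r.id: r for r in recs}
        pops = kin[kin["kin_class"] == "POP"]
        same_year = [
            row
            for row in pops.itertuples(index=False)
            if rd[row.id1].death_year == rd[row.id2].death_year
        ]
        # existence is stochastic; structure must hold whenever present
        for row in same_year:
            assert rd[row.id2].birth_year == rd[row.id2].death_year

    def test_kin_labels_match_pedigree_truth(self, small_run):
        _, ped, recs, kin = small_run
        for row in kin.itertuples(index=False):
            i1, i2 = int(row.id1[1:]), int(row.id2[1:])
            if row.kin_class == "POP":
                assert i1 in (ped.mother[i2], ped.father[i2])
            elif row.kin_class == "MHSP":
                assert ped.mother[i1] == ped.mother[i2] >= 0
                assert not (0 <= ped.father[i1] == ped.father[i2])
            elif row.kin_class == "PHSP":
                assert ped.father[i1] == ped.father[i2] >= 0
            elif row.kin_class == "GGP":
                gps = [
                    ped.mother[p] for p in (ped.mother[i2], ped.father[i2]) if p >= 0
                ] + [ped.father[p] for p in (ped.mother[i2], ped.father[i2]) if p >= 0]
                assert i1 in gps

    def test_same_cohort_paternal_sibs_occur_with_skew(self):
        # strong polygyny: some half-sib pairs share a birth year, and the
        # count agrees with the pedigree truth labels
        sched = LifeHistorySchedules.from_raw()
        years = np.arange(2008, 2013)
        cfg = SimConfig(
            n_initial=2500,
            schedules=sched,
            pi=0.1,
            harvest=HarvestDesign(years=years, n_per_year=np.full(years.size, 60)),
            burn_in=41,
        )
        total = 0
        for seed in range(4):
            ped = simulate_pedigree(cfg, seed=seed)
            recs, kin = sample_harvest(ped, include_third_order=False)
            rd = {r.id: r for r in recs}
            for row in kin[kin["kin_class"] == "PHSP"].itertuples(index=False):
                if rd[row.id1].birth_year == rd[row.id2].birth_year:
                    total += 1
        assert total > 0


class TestGenotypeSimulation:
    def test_founder_class_frequencies_match_model(self):
        # founders drawn straight from (p, q, nu): observed class frequencies
        # match (p^2+2pnu, 2pq, q^2+2qnu, nu^2) within 3 binomial SEs
        sched = LifeHistorySchedules.from_raw()
        years = np.arange(2000, 2001)
        cfg = SimConfig(
            n_initial=10_000,
            schedules=sched,
            harvest=HarvestDesign(years=years, n_per_year=np.array([0])),
            burn_in=0,
            genotypes=GenotypeDesign(n_loci=30, fail_rate=0.0, n_sex_linked=0),
        )
        ped = simulate_pedigree(cfg, seed=3)
        founders = np.flatnonzero(ped.mother == -1)
        panel = simulate_genotypes(ped, cfg.genotypes, seed=4, samples=founders)
        p, q, nu = panel.true_freqs.T
        n = founders.size
        for l in range(30):
            expected = np.array(
                [
                    p[l] ** 2 + 2 * p[l] * nu[l],
                    2 * p[l] * q[l],
                    q[l] ** 2 + 2 * q[l] * nu[l],
                    nu[l] ** 2,
                ]
            )
            counts = np.array([(panel.classes[l] == c).sum() for c in (0, 1, 2, 9)])
            se = np.sqrt(expected * (1 - expected) * n)
            assert np.all(np.abs(counts - expected * n) <= 3 * np.maximum(se, 2.0))

    def test_no_nulls_no_heritable_fails(self):
        sched = LifeHistorySchedules.from_raw()
        years = np.arange(2000, 2001)
        cfg = SimConfig(
            n_initial=500,
            schedules=sched,
            harvest=HarvestDesign(years=years, n_per_year=np.array([100])),
            burn_in=10,
            genotypes=GenotypeDesign(n_loci=40, nu_max=0.0, fail_rate=0.0, n_sex_linked=0),
        )
        ped = simulate_pedigree(cfg, seed=5)
        panel = simulate_genotypes(ped, cfg.genotypes, seed=6)
        assert not (panel.classes == CLASS_FAIL).any()

    def test_seed_reproducibility(self, small_run):
        cfg, ped, _, _ = small_run
        g1 = simulate_genotypes(ped, GenotypeDesign(n_loci=25), seed=9)
        g2 = simulate_genotypes(ped, GenotypeDesign(n_loci=25), seed=9)
        assert np.array_equal(g1.classes, g2.classes)


class TestAnalyticExpectations:
    def test_doubling_abundance_halves_counts(self, knife_edge_schedules):
        design = study_harvest_design(total=400, start_year=2010, end_year=2018)
        e1 = expected_kin_counts_analytic(knife_edge_schedules, 100_000, design)
        e2 = expected_kin_counts_analytic(knife_edge_schedules, 200_000, design)
        assert e2["HSP"] == pytest.approx(e1["HSP"] / 2, rel=1e-6)
        assert e2["POP"] == pytest.approx(e1["POP"] / 2, rel=1e-6)

    def test_kin_scale_with_sample_product_not_n_squared_only(self, knife_edge_schedules):
        # POP expectation scales with (offspring x adult) sample product;
        # doubling total samples multiplies POPs by ~4 only if both factors
        # double, which the ramped design does approximately
        d1 = study_harvest_design(total=400, start_year=2010, end_year=2018)
        d2 = study_harvest_design(total=800, start_year=2010, end_year=2018)
        e1 = expected_kin_counts_analytic(knife_edge_schedules, 100_000, d1)
        e2 = expected_kin_counts_analytic(knife_edge_schedules, 100_000, d2)
        assert e2["HSP"] == pytest.approx(4 * e1["HSP"], rel=0.1)

    def test_halving_pi_doubles_paternal_expectation(self, knife_edge_schedules):
        design = study_harvest_design(total=400, start_year=2010, end_year=2018)
        e1 = expected_kin_counts_analytic(knife_edge_schedules, 100_000, design, pi=0.8)
        e2 = expected_kin_counts_analytic(knife_edge_schedules, 100_000, design, pi=0.4)
        assert e2["PHSP"] == pytest.approx(2 * e1["PHSP"], rel=1e-6)
        assert e2["MHSP"] == pytest.approx(e1["MHSP"], rel=1e-6)
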