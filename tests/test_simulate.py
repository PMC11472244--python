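import numpy as np
import pytest

from hzmhc.data_model import ZoneCategory
from hzmhc.simulate import (
    SimParams,
    SimState,
    allele_fitness,
    binarize,
    build_transect,
    fixed_ends_cline,
    generate_parametric_zone,
    run_split_simulation,
    transect_positions,
    wf_generation,
)


class TestAlleleFitness:
    @pytest.mark.parametrize(
        "f,s,expected",
        [
            (0.5, 0.5, 1.0),  # midpoint: rare-allele advantage cancels
            (0.5, 0.1, 1.0),
            (0.0, 0.5, 1.25),  # brand-new allele gets the maximum
            (1.0, 0.5, 0.75),  # fixed allele pays the maximum cost
        ],
    )
    def test_values(self, f, s, expected):
        assert allele_fitness(f, s) == pytest.approx(expected)

    def test_bounds_hold_for_any_frequency(self):
        f = np.linspace(0, 1, 101)
        w = allele_fitness(f, 0.5)
        assert np.all(w >= 0.75 - 1e-12) and np.all(w <= 1.25 + 1e-12)

    def test_frequency_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            allele_fitness(1.2, 0.5)


def _mono_state(n_hap, n_loci=2, allele=0):
    return SimState(0, np.full((n_hap, n_loci), allele, dtype=np.int64), allele + 1)


class TestWrightFisher:
    def test_pool_size_conserved(self):
        params = SimParams(N=20, n_loci=2, theta=(0.6, 0.6), s=0.5)
        state = _mono_state(40)
        rng = np.random.default_rng(0)
        for _ in range(5):
            state = wf_generation(state, params, rng)
            assert state.n_haplotypes == 40

    def test_fixed_locus_stays_fixed_without_mutation(self):
        params = SimParams(N=20, n_loci=2, theta=(0.0, 0.0), s=0.5)
        state = _mono_state(40)
        rng = np.random.default_rng(1)
        for _ in range(20):
            state = wf_generation(state, params, rng)
        assert np.all(state.haplotypes == 0)

    def test_neutral_drift_is_a_martingale(self):
        # s=0, theta=0: expected frequency of an allele is unchanged by one
        # generation; average over many replicates of binomial sampling
        params = SimParams(N=25, n_loci=1, theta=(0.0,), s=0.0)
        base = np.zeros((50, 1), dtype=np.int64)
        base[:15, 0] = 1  # allele 1 at frequency 0.3
        freqs = []
        rng = np.random.default_rng(2)
        for _ in range(2000):
            state = SimState(0, base.copy(), 2)
            state = wf_generation(state, params, rng)
            freqs.append(np.mean(state.haplotypes == 1))
        mean = np.mean(freqs)
        sem = np.sqrt(0.3 * 0.7 / 50) / np.sqrt(2000)
        assert abs(mean - 0.3) < 4 * sem

    def test_mutation_introduces_new_identifiers_only(self):
        params = SimParams(N=30, n_loci=1, theta=(2.0,), s=0.0)
        state = _mono_state(60, n_loci=1)
        rng = np.random.default_rng(3)
        new = wf_generation(state, params, rng)
        created = set(np.unique(new.haplotypes)) - {0}
        assert all(a >= state.next_allele_id for a in created)
        assert new.next_allele_id >= state.next_allele_id


class TestSplitSimulation:
    def test_burn_in_is_twenty_n_generations(self):
        params = SimParams(N=500)
        assert params.burn_in_gens == 10_000

    def test_same_seed_reproduces_allele_histories(self):
        params = SimParams(N=30, seed=5, split_gens=(0.5,), burn_in_gens=100)
        s1 = run_split_simulation(params)[0.5]
        s2 = run_split_simulation(params)[0.5]
        np.testing.assert_array_equal(s1[0].haplotypes, s2[0].haplotypes)
        np.testing.assert_array_equal(s1[1].haplotypes, s2[1].haplotypes)

    def test_species_evolve_independently_after_split(self, small_split_states):
        a, b = small_split_states
        assert not np.array_equal(a.haplotypes, b.haplotypes)

    def test_nfds_maintains_more_alleles_than_neutral(self):
        # paired small-scale comparison at equal theta
        def mean_alleles(s, seed):
            params = SimParams(
                N=40, n_loci=2, theta=(0.6, 0.6), s=s, burn_in_gens=400,
                split_gens=(0.25,), seed=seed,
            )
            st = run_split_simulation(params)[0.25][0]
            return np.mean([len(np.unique(st.haplotypes[:, l])) for l in range(2)])

        seeds = range(12)
        sel = np.mean([mean_alleles(0.5, s) for s in seeds])
        neu = np.mean([mean_alleles(0.0, 100 + s) for s in seeds])
        assert sel > neu


class TestTransect:
    def test_population_layout(self):
        pos = transect_positions()
        assert len(pos) == 35
        core = pos[(pos >= 97) & (pos <= 103)]
        assert len(core) == 15  # fifteen equally spaced core populations
        assert len(pos[pos < 97]) == 10 and len(pos[pos > 103]) == 10
        assert pos.min() >= 0 and pos.max() <= 200

    def test_center_population_expected_admixture_half(self):
        assert fixed_ends_cline(100.0, 100.0, 6.0) == pytest.approx(0.5)

    def test_transect_structure(self, small_transect):
        assert len(small_transect.populations) == 35
        assert all(p.n_individuals == 10 for p in small_transect.populations)
        assert small_transect.reference_a.shape[0] == 60  # 30 diploid refs

    def test_mean_known_ancestry_tracks_expected_admixture(self, small_split_states):
        a, b = small_split_states
        rng = np.random.default_rng(11)
        # accumulate many draws of the center population's ancestry
        draws = []
        for _ in range(200):
            tr = build_transect(a, b, rng, n_per_population=10)
            center = min(tr.populations, key=lambda p: abs(p.position_km - 100))
            draws.append(center.known_ancestry().mean())
        se = np.sqrt(0.25 / 20) / np.sqrt(200)
        assert abs(np.mean(draws) - 0.5) < 4 * se


class TestBinarize:
    def test_homozygote_collapses_to_single_presence(self):
        pres, ids = binarize(np.array([[7], [7]]))
        assert pres.shape == (1, 1) and pres[0, 0] == 1

    def test_fully_heterozygous_individual_row_sum(self):
        haps = np.array([[1, 2, 3, 4, 5], [6, 7, 8, 9, 10]])
        pres, _ = binarize(haps)
        assert pres.sum() == 10

    def test_row_sums_bounded_by_locus_count(self, small_transect):
        n_loci = small_transect.n_loci
        for pop in small_transect.populations[:5]:
            pres, _ = binarize(pop.haplotypes)
            sums = pres.sum(axis=1)
            assert np.all(sums >= n_loci) and np.all(sums <= 2 * n_loci)


class TestParametricZone:
    def test_zero_alleles_is_an_error(self):
        with pytest.raises(ValueError):
            generate_parametric_zone(n_alleles=0)

    def test_metadata_layout(self):
        m, recs = generate_parametric_zone(n_near=5, n_far=7, seed=0)
        assert m.n_individuals == 24
        near = [r for r in recs if r.zone_category == ZoneCategory.NEAR]
        assert len(near) == 10
        assert {r.species for r in recs} == {"sp1", "sp2"}

    def test_extreme_sharing_contrast_separates_pools(self):
        m, recs = generate_parametric_zone(sharing_near=1.0, sharing_far=0.0, seed=2)
        by = {(r.species, r.zone_category.value): set() for r in recs}
        for r, row in zip(recs, m.presence):
            by[(r.species, r.zone_category.value)] |= {
                a for a, v in zip(m.allele_ids, row) if v
            }
        assert by[("sp1", "near")] & by[("sp2", "near")]  # full sharing near
        assert not (by[("sp1", "far")] & by[("sp2", "far")])  # none far

    def test_seed_reproducibility(self):
        m1, _ = generate_parametric_zone(seed=9)
        m2, _ = generate_parametric_zone(seed=9)
        np.testing.assert_array_equal(m1.presence, m2.presence)
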