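import numpy as np
import pytest

from mswsim.abm import (
    EMPTY,
    PdeConfig,
    SimParams,
    TreatmentSchedule,
    counts_from_lattice,
    init_population,
    resistant_fraction,
    run,
    seed_kernel,
    step,
)
from mswsim.diffusion import PkParams, VesselLayout
from mswsim.msw import predicted_counts, selection_map
from mswsim.seascape import FitnessSeascape, LogisticCurve, generate_tradeoff_seascape


def const_seascape(g: float) -> FitnessSeascape:
    """Two-allele seascape where every genotype grows at rate g, any conc."""
    curve = LogisticCurve(g_drugless=g, ic50=1e9, nu=-1e8) if g > 0 else LogisticCurve(0.0, 1e9, -1e8)
    return FitnessSeascape({f"{i:02b}": curve for i in range(4)})


class TestInit:
    def test_all_wild_type_when_mutant_prob_zero(self, tradeoff):
        p = SimParams(init_mutant_prob=0.0, rng_seed=1)
        st = init_population(p, tradeoff, (100, 100))
        occ = st.lattice[st.lattice >= 0]
        assert len(occ) > 0 and np.all(occ == 0)

    def test_circle_radius_10_site_count(self, tradeoff):
        # full density: occupied sites = lattice points with x^2 + y^2 <= 100
        p = SimParams(init_density=1.0, init_radius=10.0, rng_seed=0)
        st = init_population(p, tradeoff, (100, 100))
        assert st.cell_count == 317

    def test_mutant_fraction_matches_probability(self, tradeoff):
        prob = 0.2
        fracs = []
        for seed in range(30):
            p = SimParams(init_mutant_prob=prob, rng_seed=seed)
            st = init_population(p, tradeoff, (100, 100))
            counts = counts_from_lattice(st.lattice, 2)
            fracs.append(resistant_fraction(counts))
        n = 317 * 30
        se = np.sqrt(prob * (1 - prob) / n)
        assert abs(np.mean(fracs) - prob) < 4 * se

    def test_square_init_and_density(self, tradeoff):
        p = SimParams(init_shape="square", init_side=100, init_density=0.1, rng_seed=0)
        st = init_population(p, tradeoff, (100, 100))
        assert 800 < st.cell_count < 1200

    def test_geometry_must_fit(self, tradeoff):
        p = SimParams(init_radius=30.0)
        with pytest.raises(ValueError):
            init_population(p, tradeoff, (40, 40))


class TestStep:
    def test_no_death_no_growth_leaves_state_unchanged(self):
        ss = const_seascape(0.0)
        p = SimParams(death_rate=0.0, rng_seed=3)
        st = init_population(p, ss, (30, 30))
        before = st.lattice.copy()
        seed_kernel(0)
        step(st, ss, np.zeros((30, 30)), p)
        assert np.array_equal(st.lattice, before)
        assert st.time == 1.0

    def test_certain_death_extinguishes_population(self, tradeoff):
        p = SimParams(death_rate=1.0, rng_seed=3)
        st = init_population(p, tradeoff, (30, 30))
        seed_kernel(0)
        step(st, tradeoff, np.zeros((30, 30)), p)
        assert st.cell_count == 0

    def test_sparse_growth_expectation(self):
        # sparse cells with division prob p and no death multiply by ~(1+p)
        g = 0.25
        ss = const_seascape(g)
        finals = []
        for seed in range(40):
            p = SimParams(
                death_rate=0.0, mutation_rate=0.0, init_mutant_prob=0.0,
                init_density=0.02, init_shape="square", init_side=60, rng_seed=seed, n_steps=1,
            )
            ts, st = run(p, ss, field=np.zeros((60, 60)), grid_shape=(60, 60))
            n0 = ts[ts.time == 0]["count"].sum()
            finals.append(st.cell_count / n0)
        growth = np.mean(finals)
        gp = g / (1.0 + np.exp(-10.0))  # flat logistic curve sits just below g
        assert growth == pytest.approx(1.0 + gp, abs=0.02)

    def test_empirical_net_loss_blocks_division(self, pc9):
        p = SimParams(
            death_rate=0.0, net_loss_threshold=0.8, rng_seed=0, init_mutant_prob=0.5
        )
        st = init_population(p, pc9, (30, 30))
        before = st.cell_count
        seed_kernel(1)
        for _ in range(20):
            step(st, pc9, np.full((30, 30), 5.0), p)  # conc above threshold
        assert st.cell_count == before  # no divisions, no deaths


class TestRun:
    def test_zero_steps_returns_initial_counts(self, tradeoff):
        p = SimParams(n_steps=0, rng_seed=5)
        ts, st = run(p, tradeoff, field=np.zeros((50, 50)), grid_shape=(50, 50))
        assert set(ts.time) == {0.0}
        assert ts["count"].sum() == st.cell_count

    def test_same_seed_identical_trajectories(self, tradeoff):
        p = SimParams(n_steps=40, rng_seed=11)
        ts1, st1 = run(p, tradeoff, field=np.zeros((40, 40)), grid_shape=(40, 40))
        ts2, st2 = run(p, tradeoff, field=np.zeros((40, 40)), grid_shape=(40, 40))
        assert ts1.equals(ts2)
        assert np.array_equal(st1.lattice, st2.lattice)

    def test_event_audit_conservation(self, tradeoff):
        p = SimParams(n_steps=60, rng_seed=7)
        ts, st = run(p, tradeoff, field=np.zeros((50, 50)), grid_shape=(50, 50))
        n0 = ts[ts.time == 0]["count"].sum()
        assert st.cell_count == n0 + st.births - st.deaths

    def test_occupancy_is_single_valued(self, tradeoff):
        # lattice values are genotype indices or EMPTY; counts sum to occupancy
        p = SimParams(n_steps=30, rng_seed=2)
        _, st = run(p, tradeoff, field=np.zeros((40, 40)), grid_shape=(40, 40))
        assert set(np.unique(st.lattice)) <= {EMPTY, 0, 1, 2, 3}
        assert counts_from_lattice(st.lattice, 2).sum() == st.cell_count

    def test_neutral_drift_is_unbiased(self):
        # identical curves, no mutation: mean genotype frequency stays put
        ss = const_seascape(0.2)
        fracs = []
        for seed in range(40):
            p = SimParams(
                death_rate=0.05, mutation_rate=0.0, init_mutant_prob=0.5,
                rng_seed=seed, n_steps=60,
            )
            _, st = run(p, ss, field=np.zeros((60, 60)), grid_shape=(60, 60))
            counts = counts_from_lattice(st.lattice, 2)
            if counts.sum():
                fracs.append(resistant_fraction(counts))
        assert abs(np.mean(fracs) - 0.5) < 0.05

    def test_selection_increases_favored_genotype(self, tradeoff):
        # uniform conc inside genotype 10's selection window
        field = np.full((50, 50), 1.0)
        deltas = []
        for seed in range(10):
            p = SimParams(
                death_rate=0.1, mutation_rate=0.0, init_mutant_prob=0.5,
                rng_seed=seed, n_steps=50,
            )
            ts, st = run(p, tradeoff, field=field, grid_shape=(50, 50))
            first = ts[ts.time == 0].set_index("genotype")["count"]
            last = counts_from_lattice(st.lattice, 2)
            f0 = first[2] / first.sum()
            f1 = last[2] / last.sum()
            deltas.append(f1 - f0)
        assert np.mean(deltas) > 0.2

    def test_long_run_approaches_msw_predicted_counts(self, tradeoff):
        # constant field entirely inside one selection window: the selected
        # genotype fills most of its predicted area, others stay marginal
        field = np.full((50, 50), 1.0)
        swmap = selection_map(tradeoff, field, death_rate=0.1)
        pred = predicted_counts(swmap)
        assert pred[2] == 2500  # whole grid selects genotype 10
        for seed in range(3):
            p = SimParams(
                death_rate=0.1, init_mutant_prob=0.75, init_radius=10.0,
                rng_seed=seed, n_steps=600,
            )
            _, st = run(p, tradeoff, field=field, grid_shape=(50, 50))
            counts = counts_from_lattice(st.lattice, 2)
            assert counts[2] > 0.6 * pred[2]
            # near-neutral competitors are excluded slowly; allow a remnant
            assert counts[0] + counts[1] + counts[3] < 0.05 * pred[2]

    def test_elimination_rate_sets_selection_regime(self):
        # fast drug clearance leaves a wild-type tumor; slow clearance selects
        # resistant genotypes (directional check over 5 seeds)
        from mswsim.experiments import synthetic_sim_params

        layout = VesselLayout(positions=[(50, 25), (50, 75)], strengths=[1000.0] * 2)
        res_frac = {1e-4: [], 0.5: []}
        wt_majority = []
        for seed in range(5):
            ss = generate_tradeoff_seascape(2, rng_seed=seed + 1)
            for gamma in res_frac:
                p = synthetic_sim_params(seed=seed + 200)
                pk = PkParams(D=0.1, gamma=gamma, k=1000.0)
                _, st = run(
                    p, ss, pde=PdeConfig(layout=layout, params=pk),
                    grid_shape=(100, 100), record_every=1000,
                )
                counts = counts_from_lattice(st.lattice, 2)
                res_frac[gamma].append(resistant_fraction(counts))
                if gamma == 0.5:
                    wt_majority.append(counts[0] > counts.sum() / 2)
        assert all(wt_majority)
        assert all(f > 0.5 for f in res_frac[1e-4])
        assert np.mean(res_frac[1e-4]) > np.mean(res_frac[0.5]) + 0.3

    def test_pde_co_integration_runs_and_is_deterministic(self, tradeoff):
        layout = VesselLayout(positions=[(25, 12), (25, 38)], strengths=[100.0, 100.0])
        pk = PkParams(D=0.1, gamma=0.01, k=100.0)
        p = SimParams(n_steps=30, rng_seed=9, vessel_conc=100.0)
        ts1, st1 = run(p, tradeoff, pde=PdeConfig(layout=layout, params=pk), grid_shape=(50, 50))
        ts2, st2 = run(p, tradeoff, pde=PdeConfig(layout=layout, params=pk), grid_shape=(50, 50))
        assert np.array_equal(st1.lattice, st2.lattice)
        assert np.allclose(st1.drug, st2.drug)
        assert st1.drug.max() == 100.0


class TestResistantFraction:
    def test_examples(self):
        assert resistant_fraction([100, 0, 0, 0]) == 0.0
        assert resistant_fraction([70, 10, 10, 10]) == pytest.approx(0.30)
        assert resistant_fraction([0, 0, 0, 0]) == 0.0


class TestSchedule:
    def test_cyclic_structure(self):
        s = TreatmentSchedule.cyclic()
        assert s.duration == 2016.0
        assert s.is_on(0.0) and s.is_on(167.0)
        assert not s.is_on(168.0)
        assert s.is_on(336.0) and s.is_on(1008.0)
        assert not s.is_on(1176.0) and not s.is_on(2015.0)

    def test_overlap_and_gap_rejected(self):
        with pytest.raises(ValueError):
            TreatmentSchedule([(0.0, 10.0, True), (5.0, 20.0, False)])
        with pytest.raises(ValueError):
            TreatmentSchedule([(0.0, 10.0, True), (15.0, 20.0, False)])

    def test_off_schedule_means_no_drug(self, tradeoff):
        # lethal field, but schedule OFF: population survives
        field = np.full((40, 40), 1e6)
        p = SimParams(death_rate=0.0, rng_seed=4, n_steps=20)
        sched = TreatmentSchedule.always_off(100.0)
        ts, st = run(p, tradeoff, field=field, schedule=sched, grid_shape=(40, 40))
        assert st.cell_count > ts[ts.time == 0]["count"].sum()  # grew drug-free


def test_sim_params_validation():
    with pytest.raises(ValueError):
        SimParams(mutation_rate=1.5)
    with pytest.raises(ValueError):
        SimParams(death_rate=-0.1)
    with pytest.raises(ValueError):
        SimParams(neighborhood="hex")
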