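"""Life-cycle operators: selection, meiosis, mating, coupled iteration."""

import itertools

import numpy as np
import pytest

from redqueen import (
    Dominance,
    ExtinctionError,
    PopulationState,
    Regime,
    Strategy,
    initial_state,
    inject_modifier,
    run,
    step,
)
from redqueen.lifecycle import (
    host_gamete_pool,
    host_gamete_tables,
    parasite_gamete_table,
    random_mating,
    select,
    two_locus_gametes,
    trace_frame,
)

from conftest import random_state


def meiosis_oracle(hap_i: int, hap_j: int, r: float) -> np.ndarray:
    """Exhaustive three-locus meiosis for one host adult.

    Gene order M--A--B with r_MA = 0.5 (unlinked modifier), r_AB = r and
    no crossover interference: enumerate the starting parent and the two
    independent switch events.
    """
    out = np.zeros(8)
    haps = [divmod(hap_i, 4), divmod(hap_j, 4)]  # (modifier, ab)
    parents = [(m, ab >> 1, ab & 1) for m, ab in haps]
    for s in (0, 1):                       # parent providing the M allele
        for x in (0, 1):                   # switch between M and A
            for y in (0, 1):               # switch between A and B
                prob = 0.5 * 0.5 * (r if y else 1.0 - r)
                m = parents[s][0]
                a = parents[s ^ x][1]
                b = parents[(s ^ x) ^ y][2]
                out[4 * m + 2 * a + b] += prob
    return out


class TestSelect:
    def test_uniform_fitness_is_identity(self, rng):
        st = random_state(rng)
        a, wbar = select(st.host_z, np.full((8, 8), 0.7))
        np.testing.assert_allclose(a, st.host_z, atol=1e-15)
        assert wbar == pytest.approx(0.7)

    def test_two_class_example(self):
        z = np.array([0.5, 0.5])
        a, wbar = select(z, np.array([1.0, 0.5]))
        np.testing.assert_allclose(a, [2 / 3, 1 / 3])
        assert wbar == pytest.approx(0.75)

    def test_mean_fitness_between_extremes(self, rng):
        st = random_state(rng)
        w = rng.random((8, 8))
        _, wbar = select(st.host_z, w)
        assert w.min() <= wbar <= w.max()

    def test_all_lethal_raises(self):
        with pytest.raises(ExtinctionError):
            select(np.array([0.5, 0.5]), np.zeros(2))


class TestTwoLocusGametes:
    def test_double_heterozygote_at_r02(self):
        dist = two_locus_gametes((1, 1), (2, 2), 0.2)
        np.testing.assert_allclose(dist, [0.4, 0.1, 0.1, 0.4])

    def test_free_recombination(self):
        dist = two_locus_gametes((1, 1), (2, 2), 0.5)
        np.testing.assert_allclose(dist, [0.25] * 4)

    def test_homozygote_degenerate(self):
        for r in (0.0, 0.17, 0.5):
            dist = two_locus_gametes((1, 1), (1, 1), r)
            np.testing.assert_allclose(dist, [1, 0, 0, 0])

    def test_matches_chromatid_enumeration(self, rng):
        """Oracle: enumerate the parent choice and the A--B switch event."""
        for _ in range(25):
            h1 = tuple(rng.integers(1, 3, 2))
            h2 = tuple(rng.integers(1, 3, 2))
            r = float(rng.uniform(0, 0.5))
            oracle = np.zeros(4)
            for s, y in itertools.product((0, 1), repeat=2):
                prob = 0.5 * (r if y else 1.0 - r)
                a = (h1, h2)[s][0]
                b = (h1, h2)[s ^ y][1]
                oracle[2 * (a - 1) + (b - 1)] += prob
            np.testing.assert_allclose(two_locus_gametes(h1, h2, r), oracle,
                                       atol=1e-15)

    def test_rate_out_of_range(self):
        with pytest.raises(ValueError):
            two_locus_gametes((1, 1), (2, 2), 0.6)


class TestGametePools:
    def test_host_tables_match_meiosis_oracle(self, rng):
        """P(r) = G0 + r*G1 equals exhaustive three-locus meiosis for all
        64 genotypes at 100 random rates."""
        g0, g1 = host_gamete_tables()
        for r in rng.uniform(0, 0.5, 100):
            table = g0 + r * g1
            for i in range(8):
                for j in range(8):
                    np.testing.assert_allclose(
                        table[8 * i + j], meiosis_oracle(i, j, r), atol=1e-12)

    def test_table_rows_are_distributions(self):
        for r in (0.0, 0.23, 0.5):
            g0, g1 = host_gamete_tables()
            table = g0 + r * g1
            assert (table >= -1e-15).all()
            np.testing.assert_allclose(table.sum(axis=1), 1.0, atol=1e-12)
            np.testing.assert_allclose(
                parasite_gamete_table(r).sum(axis=1), 1.0, atol=1e-12)

    def test_no_recombination_keeps_parental_haplotypes(self):
        g0, _ = host_gamete_tables()
        # A1B1,M1 / A2B2,M2 at r=0: only parental AB types appear
        row = g0[8 * 0 + 7]  # hap 0 = (M1, A1B1), hap 7 = (M2, A2B2)
        present = {k for k, v in enumerate(row) if v > 0}
        assert present == {0, 3, 4, 7}  # A1B1/A2B2 with either modifier

    def test_full_independence_at_half(self):
        """Free recombination, modifier heterozygote, double heterozygote:
        all 8 gametes equiprobable."""
        g0, g1 = host_gamete_tables()
        row = (g0 + 0.5 * g1)[8 * 0 + 7]
        np.testing.assert_allclose(row, np.full(8, 1 / 8), atol=1e-15)

    def test_pool_on_random_states(self, rng):
        """Pool = frequency-weighted mixture of per-genotype meiosis."""
        for _ in range(100):
            st = random_state(rng)
            rates = rng.uniform(0, 0.5, 64)
            pool = host_gamete_pool(st.host_z, rates)
            oracle = np.zeros(8)
            flat = st.host_z.reshape(-1)
            for t in range(64):
                oracle += flat[t] * meiosis_oracle(t // 8, t % 8, rates[t])
            np.testing.assert_allclose(pool, oracle, atol=1e-12)

    def test_fixed_population_gives_point_mass(self):
        z = np.zeros((8, 8))
        z[2, 2] = 1.0
        pool = host_gamete_pool(z, np.full(64, 0.3))
        np.testing.assert_allclose(pool, np.eye(8)[2], atol=1e-15)


class TestRandomMating:
    def test_point_mass(self):
        g = np.eye(4)[1]
        z = random_mating(g)
        assert z[1, 1] == 1.0 and z.sum() == 1.0

    def test_hardy_weinberg_two_haplotypes(self):
        z = random_mating(np.array([0.5, 0.5]))
        np.testing.assert_allclose(z, np.full((2, 2), 0.25))

    def test_symmetry_and_marginal_conservation(self, rng):
        g = rng.random(8)
        g /= g.sum()
        z = random_mating(g)
        np.testing.assert_allclose(z, z.T, atol=1e-15)
        np.testing.assert_allclose(z.sum(axis=1), g, atol=1e-14)


class TestCoupledStep:
    def test_kernel_matches_reference_step(self, mild_regime):
        """The compiled path and the numpy reference path agree to 1e-12
        over many generations, including plastic strategy mixtures."""
        pairs = [
            (Strategy.constant(0.2), None),
            (Strategy.prevention(0.1, 0.3), None),
            (Strategy.remediation(0.05, 0.25), None),
            (Strategy.constant(0.1), Strategy.remediation(0.0, 0.3)),
            (Strategy.prevention(0.0, 0.5), Strategy.remediation(0.1, 0.2)),
        ]
        for resident, invader in pairs:
            state = initial_state()
            if invader is not None:
                state = inject_modifier(state, 0.2)
            fast, _ = run(state, mild_regime, resident, invader, 30)
            slow = state
            for _ in range(30):
                slow = step(slow, mild_regime,
                            (resident, invader if invader else resident))
            np.testing.assert_allclose(fast.host_z, slow.host_z, atol=1e-12)
            np.testing.assert_allclose(fast.parasite_z, slow.parasite_z,
                                       atol=1e-12)

    def test_normalization_over_ten_thousand_generations(self, mild_regime):
        final, _ = run(initial_state(), mild_regime, Strategy.constant(0.2),
                       None, 10_000)
        assert abs(final.host_z.sum() - 1.0) < 1e-9
        assert abs(final.parasite_z.sum() - 1.0) < 1e-9
        np.testing.assert_allclose(final.host_z, final.host_z.T, atol=1e-15)

    def test_modifier_neutral_when_host_selection_off(self):
        """With s_h = 0 the modifier allele frequency is conserved to
        machine precision across 10,000 generations."""
        regime = Regime(0.0, 0.8, 0.2, Dominance.IN_PHASE)
        state = inject_modifier(
            run(initial_state(), regime, Strategy.constant(0.1), None, 50,
                record=False)[0], 0.05)
        _, trace = run(state, regime, Strategy.constant(0.1),
                       Strategy.prevention(0.0, 0.5), 10_000)
        assert np.abs(trace[:, 2] - 0.05).max() < 1e-12

    def test_neutral_dynamics_conserve_allele_frequencies(self):
        regime = Regime(0.0, 0.0, 0.3, Dominance.IN_PHASE)
        _, trace = run(initial_state(), regime, Strategy.constant(0.2),
                       None, 500)
        for col in (0, 1, 3, 4):
            assert np.ptp(trace[:, col]) < 1e-12

    def test_mean_fitnesses_share_infection_probability(self, mild_regime):
        """Every generation satisfies wbar_h = 1 - s_h*Q and
        wbar_p = 1 - s_p*(1-Q) for a common Q."""
        _, trace = run(initial_state(), mild_regime, Strategy.constant(0.2),
                       None, 2_000)
        q_host = (1.0 - trace[:, 5]) / mild_regime.s_h
        q_par = 1.0 - (1.0 - trace[:, 6]) / mild_regime.s_p
        np.testing.assert_allclose(q_host, q_par, atol=1e-12)
        assert (q_host > -1e-12).all() and (q_host < 1 + 1e-12).all()

    def test_locus_swap_symmetry(self, rng):
        """Relabeling the two selected loci (A<->B) in both species
        commutes with the dynamics (dominance is identical at both loci)."""
        regime = Regime(0.6, 0.7, 0.25, Dominance.ANTI_PHASE)
        perm_ab = np.array([0, 2, 1, 3])         # swap the two locus bits
        perm_h = np.concatenate([perm_ab, perm_ab + 4])
        st = random_state(rng)
        swapped = PopulationState(st.host_z[np.ix_(perm_h, perm_h)],
                                  st.parasite_z[np.ix_(perm_ab, perm_ab)])
        a, _ = run(st, regime, Strategy.constant(0.2), None, 200,
                   record=False)
        b, _ = run(swapped, regime, Strategy.constant(0.2), None, 200,
                   record=False)
        np.testing.assert_allclose(b.host_z,
                                   a.host_z[np.ix_(perm_h, perm_h)],
                                   atol=1e-12)
        np.testing.assert_allclose(b.parasite_z,
                                   a.parasite_z[np.ix_(perm_ab, perm_ab)],
                                   atol=1e-12)

    def test_sustained_oscillations_under_strong_selection(self, extreme_regime):
        """Strong-selection dynamics keep oscillating after 10,000
        generations with period above 25 generations."""
        from redqueen.experiments import estimate_period

        _, trace = run(initial_state(), extreme_regime,
                       Strategy.constant(0.32), None, 10_000)
        tail = trace[-2_000:, 0]
        assert np.ptp(tail) > 0.5          # large-amplitude oscillation
        assert estimate_period(tail) > 25


class TestInjection:
    def test_injection_invariants(self, mild_regime):
        """Frequency exactly 0.05, Hardy-Weinberg at the modifier, zero
        linkage disequilibrium with both selected loci, untouched AB
        genotype distribution."""
        base, _ = run(initial_state(), mild_regime, Strategy.constant(0.2),
                      None, 3_000)
        inj = inject_modifier(base, 0.05)
        assert inj.invader_modifier_freq() == pytest.approx(0.05, abs=1e-14)
        f = inj.host_hap_freqs()
        ab_marg = f[:4] + f[4:]
        # within-haplotype LD between modifier and each selected locus
        for locus_mask in ((0, 1), (0, 2)):   # haplotypes carrying A1 / B1
            allele = f[list(locus_mask)].sum() + f[[m + 4 for m in locus_mask]].sum()
            d = f[[m + 4 for m in locus_mask]].sum() - 0.05 * allele
            assert abs(d) < 1e-12
        # modifier genotype frequencies are Hardy-Weinberg
        mm = inj.host_z[4:, 4:].sum()
        assert mm == pytest.approx(0.05 ** 2, abs=1e-14)
        # marginal AB zygote distribution unchanged
        z_ab = (inj.host_z[:4, :4] + inj.host_z[:4, 4:]
                + inj.host_z[4:, :4] + inj.host_z[4:, 4:])
        base_ab = (base.host_z[:4, :4] + base.host_z[:4, 4:]
                   + base.host_z[4:, :4] + base.host_z[4:, 4:])
        np.testing.assert_allclose(z_ab, base_ab, atol=1e-14)

    def test_injection_requires_fixed_resident(self, mild_regime):
        st = inject_modifier(initial_state(), 0.05)
        with pytest.raises(ValueError):
            inject_modifier(st, 0.05)


class TestTraceFrame:
    def test_long_format_columns(self):
        _, trace = run(initial_state(), Regime(0.3, 0.4, 0.1,
                                               Dominance.IN_PHASE),
                       Strategy.constant(0.1), None, 5)
        long = trace_frame(trace, start_generation=100)
        assert set(long.columns) == {"generation", "species", "variable",
                                     "value"}
        assert long["generation"].min() == 100
        assert len(long) == 5 * 7
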