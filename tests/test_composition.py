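import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmcnano.composition import (
    CM,
    CM8,
    DEFAULT_AMIDE_FRACTION,
    OH,
    PATTERNS8,
    Chain,
    PatternDistribution,
    build_monomer_library,
    chain_statistics,
    count_negative_sites,
    fit_pattern_distribution,
    generate_chain,
)
from cmcnano.constants import (
    CM8_INCREMENT,
    CM_INCREMENT_FREE_ACID,
    CM_INCREMENT_SODIUM_SALT,
    M_ANHYDROGLUCOSE,
)
from cmcnano.errors import ConfigurationError, FitError


class TestMonomerLibrary:
    def test_exactly_27_states(self):
        lib = build_monomer_library()
        assert len(lib) == 27

    def test_both_conventions_have_27_states(self):
        for conv in ("sodium_salt", "free_acid"):
            assert len(build_monomer_library(conv)) == 27

    def test_unsubstituted_state(self):
        state = build_monomer_library()[("OH", "OH", "OH")]
        assert state.charge == 0
        assert state.n_alkyl == 0
        assert state.n_cm_total == 0
        assert state.mass == pytest.approx(M_ANHYDROGLUCOSE)

    def test_tri_cm_state_has_charge_minus_3(self):
        state = build_monomer_library()[("CM", "CM", "CM")]
        assert state.charge == -3
        assert state.n_cm_total == 3

    def test_charge_equals_minus_cm_count_everywhere(self):
        for names, state in build_monomer_library().items():
            assert state.charge == -sum(1 for n in names if n == "CM")
            assert -3 <= state.charge <= 0

    def test_masses_are_base_plus_increments(self):
        lib = build_monomer_library("sodium_salt")
        state = lib[("CM", "OH", "CM8")]
        assert state.mass == pytest.approx(
            M_ANHYDROGLUCOSE + CM_INCREMENT_SODIUM_SALT + CM8_INCREMENT
        )
        lib_fa = build_monomer_library("free_acid")
        assert lib_fa[("CM", "OH", "OH")].mass == pytest.approx(
            M_ANHYDROGLUCOSE + CM_INCREMENT_FREE_ACID
        )

    def test_unknown_convention_raises(self):
        with pytest.raises(ConfigurationError):
            build_monomer_library("hydrate")


class TestFitPatternDistribution:
    def test_zero_targets_put_all_mass_on_unsubstituted(self):
        dist = fit_pattern_distribution(
            positional_targets={2: (0.0, 0.0), 3: (0.0, 0.0), 6: (0.0, 0.0)},
            class_targets=[(1.0, 1.0), (0.0, 0.0), (0.0, 0.0), (0.0, 0.0)],
            total_cm=0.0,
        )
        assert dist.probs[PATTERNS8.index((0, 0, 0))] == pytest.approx(1.0)

    def test_default_tri_fraction_in_printed_range(self, default_dist):
        assert 0.020 - 1e-6 <= default_dist.f3 <= 0.030 + 1e-6

    def test_default_marginals_in_printed_ranges(self, default_dist):
        assert 0.360 - 1e-6 <= default_dist.p2 <= 0.370 + 1e-6
        assert 0.160 - 1e-6 <= default_dist.p3 <= 0.170 + 1e-6
        assert 0.350 - 1e-6 <= default_dist.p6 <= 0.360 + 1e-6

    def test_default_total_cm_pinned(self, default_dist):
        assert default_dist.mean_cm_per_monomer == pytest.approx(0.9, abs=1e-6)

    def test_independent_product_marginals_exact(self):
        # Oracle: direct summation over the 8 patterns.
        p = np.array([0.37, 0.17, 0.36])
        dist = PatternDistribution.from_independent(p)
        oracle = np.zeros(3)
        for pat, prob in zip(PATTERNS8, dist.probs):
            oracle += np.array(pat) * prob
        np.testing.assert_allclose(dist.positional_marginals, p, atol=1e-14)
        np.testing.assert_allclose(oracle, p, atol=1e-14)

    def test_infeasible_ranges_raise_fit_error(self):
        with pytest.raises(FitError):
            fit_pattern_distribution(
                positional_targets={2: (0.9, 0.9), 3: (0.9, 0.9), 6: (0.9, 0.9)},
                class_targets=[(1.0, 1.0), (0.0, 0.0), (0.0, 0.0), (0.0, 0.0)],
                total_cm=2.7,
            )

    def test_provenance_records_targets(self, default_dist):
        assert "positional_targets" in default_dist.provenance
        assert "note" in default_dist.provenance

    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=10.0), min_size=8, max_size=8
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_marginal_identity_for_any_distribution(self, raw):
        # p2 + p3 + p6 == f1 + 2 f2 + 3 f3 (both count mean CM per monomer)
        probs = np.array(raw) / np.sum(raw)
        dist = PatternDistribution(probs)
        lhs = dist.positional_marginals.sum()
        f = dist.class_fractions
        rhs = f[1] + 2 * f[2] + 3 * f[3]
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_json_round_trip(self, default_dist, tmp_path):
        path = tmp_path / "dist.json"
        default_dist.to_json(path)
        loaded = PatternDistribution.from_json(path)
        np.testing.assert_allclose(loaded.probs, default_dist.probs)


class TestGenerateChain:
    def test_exact_counts_1000mer(self, default_dist):
        chain = generate_chain(
            default_dist, 1000, amide_fraction=DEFAULT_AMIDE_FRACTION, seed=0
        )
        assert chain.n_cm_total == 900
        assert chain.n_cm8 == 200

    def test_100mer_cmc_charge(self, cmc_chain_100):
        assert cmc_chain_100.total_charge == -90

    def test_100mer_cmc8_charge(self, cmc8_chain_100):
        assert cmc8_chain_100.total_charge == -70

    def test_same_seed_identical(self, default_dist):
        a = generate_chain(default_dist, 500, amide_fraction=0.2, seed=99)
        b = generate_chain(default_dist, 500, amide_fraction=0.2, seed=99)
        assert np.array_equal(a.codes, b.codes)

    def test_different_seeds_differ(self, default_dist):
        a = generate_chain(default_dist, 500, seed=1)
        b = generate_chain(default_dist, 500, seed=2)
        assert not np.array_equal(a.codes, b.codes)

    def test_charge_bookkeeping_conserved(self, default_dist):
        # charge = -(round(ds*N) - round(a * round(ds*N))) under exact counts
        for n, a in ((1000, DEFAULT_AMIDE_FRACTION), (100, 0.5), (250, 0.0)):
            chain = generate_chain(default_dist, n, amide_fraction=a, seed=3)
            n_cm = round(0.9 * n)
            expected = -(n_cm - round(a * n_cm))
            assert chain.total_charge == expected

    def test_iid_mode_skips_repair(self, default_dist):
        chain = generate_chain(
            default_dist, 1000, enforce_exact_counts=False, seed=5
        )
        # i.i.d. totals fluctuate; just check the chain is valid and near 900
        assert 800 < chain.n_cm_total < 1000

    def test_bad_args(self, default_dist):
        with pytest.raises(ValueError):
            generate_chain(default_dist, 0, seed=1)
        with pytest.raises(ValueError):
            generate_chain(default_dist, 10, amide_fraction=1.5, seed=1)


class TestChainStatistics:
    def test_unsubstituted_chain_all_zero(self):
        chain = Chain(codes=np.zeros((50, 3), dtype=np.int8), ds_cm=0.0)
        s = chain_statistics(chain)
        assert s.total_charge == 0
        assert s.n_cm_total == 0
        assert s.n_alkyl == 0
        assert s.class_counts == (50, 0, 0, 0)
        assert s.mean_monomer_mass == pytest.approx(M_ANHYDROGLUCOSE)

    def test_cmc8_100mer_charge(self, cmc8_chain_100):
        assert chain_statistics(cmc8_chain_100).total_charge == -70

    def test_mc_mean_position2_matches_binomial_oracle(self, default_dist):
        # Oracle: binomial expectation 1000 * p2 with 3-SE tolerance.
        n_chains, n = 500, 1000
        counts = np.empty(n_chains)
        for i in range(n_chains):
            chain = generate_chain(default_dist, n, seed=10_000 + i)
            counts[i] = chain_statistics(chain).cm_by_position[2]
        p2 = default_dist.p2
        se = math.sqrt(n * p2 * (1 - p2) / n_chains)
        assert abs(counts.mean() - n * p2) < 3 * se


class TestCountNegativeSites:
    def test_unsubstituted_chain_zero_sites(self):
        chain = Chain(codes=np.zeros((100, 3), dtype=np.int8), ds_cm=0.0)
        for rule in ("tri_full", "tri_ge2"):
            assert count_negative_sites(chain, rule).count == 0

    def test_unknown_rule(self, cmc_chain_100):
        with pytest.raises(ConfigurationError):
            count_negative_sites(cmc_chain_100, "penta")

    def test_site_count_bounded_by_length(self, cmc8_chain_100):
        rep = count_negative_sites(cmc8_chain_100, "tri_full")
        assert 0 <= rep.count <= len(cmc8_chain_100)

    def test_tri_full_mean_matches_f3_oracle(self, default_dist):
        # Oracle: expectation 1000 * f3 from the fitted class fraction.
        n_chains, n = 500, 1000
        counts = np.array(
            [
                count_negative_sites(
                    generate_chain(default_dist, n, seed=20_000 + i), "tri_full"
                ).count
                for i in range(n_chains)
            ]
        )
        f3 = default_dist.f3
        se = math.sqrt(n * f3 * (1 - f3) / n_chains)
        assert abs(counts.mean() - n * f3) < 3 * se

    def test_tri_ge2_mean_matches_retention_oracle(self, default_dist):
        # Oracle: closed-form binomial retention. A tri-CM monomer keeps each
        # CM with prob q = 1 - a; it qualifies with >= 2 retained:
        # P = 3 q^2 (1-q) + q^3.
        n_chains, n = 500, 1000
        a = DEFAULT_AMIDE_FRACTION
        q = 1.0 - a
        p_keep = 3 * q**2 * (1 - q) + q**3
        counts = np.array(
            [
                count_negative_sites(
                    generate_chain(
                        default_dist, n, amide_fraction=a, seed=30_000 + i
                    ),
                    "tri_ge2",
                ).count
                for i in range(n_chains)
            ]
        )
        mean_expect = n * default_dist.f3 * p_keep
        # Conservative SE: treat qualification as Bernoulli per monomer.
        p = default_dist.f3 * p_keep
        se = math.sqrt(n * p * (1 - p) / n_chains)
        assert abs(counts.mean() - mean_expect) < 3 * se
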