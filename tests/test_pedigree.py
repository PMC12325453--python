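"""Pedigree simulator and the closed-form generation-size calculus."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtped.pedigree import (
    FEMALE,
    MALE,
    GenerationShortfallError,
    PedigreeConfig,
    PedigreeError,
    assemble_sample,
    expected_generation_sizes,
    expected_pedigree_size,
    simulate_pedigree,
)


class TestExpectedSizes:
    def test_generation_sizes_closed_form(self):
        # k=3, G=5, r=1: all integer generation sizes summing to 161
        assert expected_generation_sizes(3, 5, 1.0).tolist() == [2, 6, 18, 54, 81]
        # second generation of a k=4, r=.7 design: 4 * 1.7 = 6.8
        assert expected_generation_sizes(4, 3, 0.7)[1] == pytest.approx(6.8)
        # single generation: just the founder couple
        assert expected_generation_sizes(3, 1, 0.7).tolist() == [2.0]

    @pytest.mark.parametrize(
        "k,G,r,total",
        [(3, 4, 0.7, 33), (4, 4, 0.7, 61), (8, 4, 0.7, 344), (3, 8, 0.7, 657), (3, 5, 1.0, 161)],
    )
    def test_pedigree_size_matches_study_designs(self, k, G, r, total):
        assert expected_pedigree_size(k, G, r) == total

    def test_bias_design_total_sample(self):
        assert expected_pedigree_size(3, 5, 1.0) * 124 == 19964

    def test_invalid_parameters_raise(self):
        with pytest.raises(PedigreeError):
            expected_generation_sizes(0, 4, 0.7)
        with pytest.raises(PedigreeError):
            expected_generation_sizes(3, 0, 0.7)
        with pytest.raises(PedigreeError):
            expected_pedigree_size(3, 4, 1.5)


def _structural_checks(ped, config):
    ped.validate()
    gens = np.unique(ped.generation)
    assert gens.tolist() == list(range(1, config.G + 1))
    # final generation never has children
    has_child = ped.has_children()
    assert not has_child[ped.generation == config.G].any()
    # parents sit exactly one generation above their children
    kids = np.flatnonzero(ped.father >= 0)
    assert (ped.generation[ped.father[kids]] == ped.generation[kids] - 1).all()
    assert (ped.generation[ped.mother[kids]] == ped.generation[kids] - 1).all()
    # monogamy: each parent appears with exactly one partner
    couples = {}
    for i in kids:
        f, m = int(ped.father[i]), int(ped.mother[i])
        assert couples.setdefault(f, m) == m
        assert couples.setdefault(m, f) == f
    # every child has one bloodline and one married-in parent, except
    # generation-2 children whose parents are both founders
    gen2plus = kids[ped.generation[kids] > 2]
    assert (
        ped.married_in[ped.father[gen2plus]] ^ ped.married_in[ped.mother[gen2plus]]
    ).all()


class TestSimulator:
    def test_single_generation_is_one_couple(self):
        ped = simulate_pedigree(PedigreeConfig(k=3, G=1, p=0.5, r=0.7, seed=5))
        assert ped.n == 2
        assert sorted(ped.sex.tolist()) == [FEMALE, MALE]
        assert (ped.father == -1).all()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_expected_mode_reproduces_design_size(self, seed):
        config = PedigreeConfig(
            k=3, G=4, p=0.5, r=0.7, size_mode="expected", seed=seed
        )
        ped = simulate_pedigree(config)
        assert ped.n == 33
        # per-generation totals equal the per-generation ceilings
        sizes = np.ceil(expected_generation_sizes(3, 4, 0.7) - 1e-9).astype(int)
        counts = np.bincount(ped.generation)[1:]
        assert counts.tolist() == sizes.tolist()
        _structural_checks(ped, config)

    def test_poisson_mode_mean_size_near_closed_form(self):
        # conditioning on reaching all G generations biases the mean a few
        # per cent above the closed-form ceiling total; 10% brackets it
        sizes = [
            simulate_pedigree(PedigreeConfig(k=3, G=4, r=0.7, seed=s)).n
            for s in range(500)
        ]
        assert np.mean(sizes) == pytest.approx(33, rel=0.10)

    def test_newborn_sex_ratio_within_binomial_bounds(self):
        peds = assemble_sample(PedigreeConfig(k=3, G=4, r=0.7, seed=11), 12_000)
        sexes = np.concatenate(
            [p.sex[(p.father >= 0)] for p in peds]
        )
        n = len(sexes)
        assert n > 8_000
        frac_male = (sexes == MALE).mean()
        half_width = 2.576 * np.sqrt(0.25 / n)
        assert abs(frac_male - 0.5) < half_width + 0.005

    def test_generation_shortfall_raises(self):
        # k so small that deep generations cannot be populated
        with pytest.raises(GenerationShortfallError):
            simulate_pedigree(PedigreeConfig(k=0.01, G=6, r=0.7, seed=0))

    def test_determinism(self):
        a = simulate_pedigree(PedigreeConfig(k=3, G=4, r=0.7, seed=9))
        b = simulate_pedigree(PedigreeConfig(k=3, G=4, r=0.7, seed=9))
        assert np.array_equal(a.father, b.father)
        assert np.array_equal(a.sex, b.sex)

    @settings(max_examples=12, deadline=None, derandomize=True)
    @given(
        k=st.floats(min_value=1.0, max_value=5.0),
        G=st.integers(min_value=1, max_value=5),
        p=st.floats(min_value=0.1, max_value=0.9),
        r=st.floats(min_value=0.4, max_value=1.0),
        mode=st.sampled_from(["poisson", "expected"]),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_structural_invariants_hold_for_random_configs(self, k, G, p, r, mode, seed):
        config = PedigreeConfig(k=k, G=G, p=p, r=r, size_mode=mode, seed=seed)
        try:
            ped = simulate_pedigree(config)
        except GenerationShortfallError:
            return  # legitimately impossible configuration
        _structural_checks(ped, config)


class TestAssembleSample:
    def test_bias_protocol_pool(self):
        config = PedigreeConfig(k=3, G=5, r=1.0, size_mode="expected", seed=1)
        peds = assemble_sample(config, 124 * 161)
        assert len(peds) == 124
        assert sum(p.n for p in peds) == 19964

    def test_single_couple_target(self):
        peds = assemble_sample(PedigreeConfig(k=3, G=1, r=0.7, seed=1), 2)
        assert len(peds) == 1 and peds[0].n == 2

    def test_expected_mode_pool_arithmetic(self):
        config = PedigreeConfig(k=3, G=4, p=0.5, r=0.7, size_mode="expected", seed=2)
        peds = assemble_sample(config, 10_000)
        assert len(peds) == int(np.ceil(10_000 / 33)) == 304
        assert sum(p.n for p in peds) == 10_032

    def test_distinct_pedigree_ids_and_determinism(self):
        config = PedigreeConfig(k=3, G=3, r=0.7, seed=4)
        a = assemble_sample(config, 200)
        b = assemble_sample(config, 200)
        assert [p.pedigree_id for p in a] == [p.pedigree_id for p in b]
        assert len({p.pedigree_id for p in a}) == len(a)
        assert all(np.array_equal(x.sex, y.sex) for x, y in zip(a, b))
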