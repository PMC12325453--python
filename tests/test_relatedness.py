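"""Relatedness-matrix construction against closed forms and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import gene_drop_additive, matriline_oracle_matrix
from mtped.pedigree import PedigreeConfig, simulate_pedigree
from mtped.relatedness import (
    additive_matrix,
    build_all,
    ce_matrix,
    cf_matrix,
    epistasis_matrix,
    joint_matrix,
    mito_matrix,
)


def _pos(ped, member_id):
    return int(np.flatnonzero(ped.member_id == member_id)[0])


class TestAdditive:
    def test_classic_coefficients(self, cousin_pedigree):
        A = additive_matrix(cousin_pedigree)
        p = lambda m: _pos(cousin_pedigree, m)
        assert A[p(1), p(3)] == 0.5  # parent-offspring
        assert A[p(3), p(4)] == 0.5  # full siblings
        assert A[p(11), p(12)] == 0.125  # first cousins
        assert A[p(13), p(14)] == 0.125  # first cousins (maternal)
        assert A[p(7), p(8)] == 0.0  # married-in founders unrelated
        assert np.allclose(np.diag(A), 1.0)

    def test_matches_gene_dropping_oracle(self):
        ped = simulate_pedigree(PedigreeConfig(k=2, G=4, p=0.5, r=0.9, seed=17))
        assert ped.n <= 30
        A = additive_matrix(ped)
        A_hat, se = gene_drop_additive(ped, reps=100_000, seed=3)
        # 4.5 SE per entry guards the simultaneous check over all entries
        tol = 4.5 * se + 1e-9
        assert (np.abs(A - A_hat) <= tol).all()

    def test_positive_semidefinite(self):
        for seed in range(5):
            ped = simulate_pedigree(PedigreeConfig(k=3, G=4, r=0.7, seed=seed))
            A = additive_matrix(ped)
            assert np.linalg.eigvalsh(A).min() > -1e-10


class TestMito:
    def test_transmission_rules(self, cousin_pedigree):
        M = mito_matrix(cousin_pedigree)
        p = lambda m: _pos(cousin_pedigree, m)
        assert M[p(2), p(3)] == 1.0  # mother-offspring share
        assert M[p(1), p(3)] == 0.0  # father does not transmit
        assert M[p(13), p(14)] == 1.0  # children of two sisters
        assert M[p(11), p(12)] == 0.0  # children of two brothers
        assert M[p(11), p(13)] == 0.0  # wives found new matrilines

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_matches_label_propagation_oracle(self, seed):
        ped = simulate_pedigree(PedigreeConfig(k=3, G=4, r=0.7, seed=seed))
        assert np.array_equal(mito_matrix(ped), matriline_oracle_matrix(ped))

    def test_shared_matriline_chains_meet_at_common_female(self):
        ped = simulate_pedigree(PedigreeConfig(k=3, G=5, r=0.8, seed=21))
        M = mito_matrix(ped)

        def chain(i):
            out = [i]
            while ped.mother[out[-1]] >= 0:
                out.append(int(ped.mother[out[-1]]))
            return out

        for i in range(ped.n):
            for j in range(i + 1, ped.n):
                ci, cj = chain(i), chain(j)
                meets = len(set(ci) & set(cj)) > 0
                assert (M[i, j] == 1.0) == meets


class TestElementwise:
    def test_epistasis_is_square(self, cousin_pedigree):
        A = additive_matrix(cousin_pedigree)
        I_AA = epistasis_matrix(A)
        assert I_AA[_pos(cousin_pedigree, 3), _pos(cousin_pedigree, 4)] == 0.25
        assert np.allclose(I_AA, A * A)

    def test_joint_is_product_and_separates_matrilineal_kinship(self, cousin_pedigree):
        A = additive_matrix(cousin_pedigree)
        M = mito_matrix(cousin_pedigree)
        J = joint_matrix(A, M)
        p = lambda m: _pos(cousin_pedigree, m)
        assert J[p(3), p(5)] == 0.5  # maternal full siblings: A=.5, M=1
        assert J[p(11), p(12)] == 0.0  # M=0 zeroes the interaction
        # same M=1 but different A gives different J (identification)
        assert J[p(13), p(14)] == 0.125
        assert J[p(5), p(13)] == 0.5
        with pytest.raises(ValueError):
            joint_matrix(A, M[:3, :3])


class TestHousehold:
    def test_cf_full_siblings_only(self, cousin_pedigree):
        C = cf_matrix(cousin_pedigree)
        p = lambda m: _pos(cousin_pedigree, m)
        assert C[p(3), p(4)] == 1.0  # full siblings
        assert C[p(1), p(3)] == 0.0  # parent-offspring excluded
        assert C[p(11), p(12)] == 0.0
        assert np.allclose(np.diag(C), 1.0)

    def test_cf_half_siblings_excluded(self):
        # half sibs share the mother but have different fathers
        import mtped.pedigree as pg

        half = pg.PedigreeTable(
            member_id=np.arange(1, 6, dtype=np.int64),
            father=np.array([-1, -1, -1, 0, 2]),
            mother=np.array([-1, -1, -1, 1, 1]),
            sex=np.array([pg.MALE, pg.FEMALE, pg.MALE, pg.MALE, pg.FEMALE], dtype=np.int8),
            generation=np.array([1, 1, 1, 2, 2], dtype=np.int16),
            married_in=np.zeros(5, dtype=bool),
            pedigree_id="half",
        )
        C = cf_matrix(half)
        assert C[3, 4] == 0.0  # shared mother only

    def test_cf_include_parents_option(self, cousin_pedigree):
        C = cf_matrix(cousin_pedigree, include_parents=True)
        p = lambda m: _pos(cousin_pedigree, m)
        assert C[p(1), p(3)] == 1.0
        assert C[p(1), p(2)] == 1.0

    def test_ce_connected_component_block(self, cousin_pedigree):
        C = ce_matrix(cousin_pedigree)
        assert (C == 1.0).all()  # one connected pedigree

    def test_ce_zero_across_components_after_link_deletion(self, cousin_pedigree):
        from mtped.bias import drop_parent_links

        broken = drop_parent_links(cousin_pedigree, 5)  # daughter 5 disconnected
        C = ce_matrix(broken)
        p = lambda m: _pos(broken, m)
        # her new family unit: herself, husband 9, child 13
        for m in (9, 13):
            assert C[p(5), p(m)] == 1.0
        for m in (1, 2, 3, 6, 14):
            assert C[p(5), p(m)] == 0.0


class TestBuildAll:
    def test_founder_couple_matrices(self):
        ped = simulate_pedigree(PedigreeConfig(k=3, G=1, r=0.7, seed=2))
        mats = build_all(ped)
        assert np.allclose(mats.A, np.eye(2))
        assert np.allclose(mats.M, np.eye(2))
        assert np.allclose(mats.C_F, np.eye(2))
        assert np.allclose(mats.C_E, np.ones((2, 2)))

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        k=st.floats(min_value=1.5, max_value=4.0),
        G=st.integers(min_value=2, max_value=5),
        r=st.floats(min_value=0.5, max_value=1.0),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_structural_invariants(self, k, G, r, seed):
        from mtped.pedigree import GenerationShortfallError

        try:
            ped = simulate_pedigree(PedigreeConfig(k=k, G=G, p=0.5, r=r, seed=seed))
        except GenerationShortfallError:
            return
        mats = build_all(ped)
        for name, mat in mats.as_dict().items():
            assert np.allclose(mat, mat.T), name
            assert np.allclose(np.diag(mat), 1.0), name
        for mat in (mats.M, mats.C_F, mats.C_E):
            assert set(np.unique(mat)) <= {0.0, 1.0}
        # the most distant pairs are generation-G members whose only common
        # ancestors are the two founders: A = 2^(3 - 2G)
        offdiag = mats.A[~np.eye(ped.n, dtype=bool)]
        nonzero = offdiag[offdiag > 0]
        assert ((nonzero >= 2.0 ** (3 - 2 * G) - 1e-12) & (nonzero <= 1.0)).all()
        assert (mats.J <= mats.A + 1e-15).all()
        assert (mats.I_AA <= mats.A + 1e-15).all()
        assert np.allclose(mats.I_AA, mats.A**2)
        assert np.allclose(mats.J, mats.A * mats.M)
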