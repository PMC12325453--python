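"""The six relatedness matrices of the extended-pedigree covariance model.

For a pedigree with members 1..n the model distinguishes seven patterns of
similarity, six of which are encoded as symmetric n x n matrices (the
seventh, unique environment E, is the identity):

* ``A``    — additive nuclear relatedness, twice the kinship coefficient
  computed by the classic recursion over the pedigree (founders unrelated
  and non-inbred, so diag(A) = 1).
* ``I_AA`` — additive-by-additive epistasis, the elementwise square of A.
* ``M``    — mtDNA sharing indicator: 1 for pairs on the same matriline
  (an unbroken chain of mother links back to a common founding female),
  0 otherwise.  Males carry but do not transmit their mother's matriline.
* ``J``    — nuclear-by-mitochondrial interaction, elementwise A * M.
* ``C_F``  — shared nuclear-family environment: 1 for full siblings
  (identical recorded mother and father) and on the diagonal.
* ``C_E``  — shared extended-family environment: 1 within each connected
  component of the family graph (parent-child, co-parent and mate edges).

All matrices are dense per pedigree block; cross-pedigree entries are zero
by construction and never materialised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import PedigreeTable

__all__ = [
    "ComponentMatrices",
    "MATRIX_NAMES",
    "additive_matrix",
    "epistasis_matrix",
    "mito_matrix",
    "joint_matrix",
    "cf_matrix",
    "ce_matrix",
    "build_all",
    "build_sample_matrices",
]

#: order of the matrix stack; matches the component order of VarianceComponents
MATRIX_NAMES = ("A", "I_AA", "M", "J", "C_F", "C_E", "E")


@dataclass
class ComponentMatrices:
    """The six relatedness matrices of one pedigree block, index-aligned."""

    A: np.ndarray
    I_AA: np.ndarray
    M: np.ndarray
    J: np.ndarray
    C_F: np.ndarray
    C_E: np.ndarray
    index: np.ndarray  # member identifiers, aligned with all matrices
    pedigree_id: str = "ped"

    @property
    def n(self) -> int:
        return int(self.A.shape[0])

    def stack(self) -> np.ndarray:
        """(7, n, n) array ordered as MATRIX_NAMES (E = identity last)."""
        return np.stack(
            [self.A, self.I_AA, self.M, self.J, self.C_F, self.C_E, np.eye(self.n)]
        )

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "A": self.A,
            "I_AA": self.I_AA,
            "M": self.M,
            "J": self.J,
            "C_F": self.C_F,
            "C_E": self.C_E,
        }


def additive_matrix(ped: PedigreeTable) -> np.ndarray:
    """Additive relatedness A = 2 * kinship, by the tabular recursion.

    phi(i, i) = (1 + phi(father_i, mother_i)) / 2 and, for j already
    processed, phi(i, j) = (phi(father_i, j) + phi(mother_i, j)) / 2;
    founders are mutually unrelated and non-inbred.  Raises on cyclic
    parent links.
    """
    n = ped.n
    order = ped.topological_order()
    phi = np.zeros((n, n))
    if np.array_equal(order, np.arange(n)):
        # simulator tables are already parents-before-children: slice views
        for i in range(n):
            f, m = int(ped.father[i]), int(ped.mother[i])
            if f < 0:
                phi[i, i] = 0.5
            else:
                row = 0.5 * (phi[f, :i] + phi[m, :i])
                phi[i, :i] = row
                phi[:i, i] = row
                phi[i, i] = 0.5 * (1.0 + phi[f, m])
        return 2.0 * phi
    done = np.zeros(n, dtype=bool)
    for i in order:
        f, m = int(ped.father[i]), int(ped.mother[i])
        if f < 0:
            phi[i, i] = 0.5
        else:
            row = 0.5 * (phi[f, done] + phi[m, done])
            phi[i, done] = row
            phi[done, i] = row
            phi[i, i] = 0.5 * (1.0 + phi[f, m])
        done[i] = True
    return 2.0 * phi


def epistasis_matrix(A: np.ndarray) -> np.ndarray:
    """Additive-by-additive epistasis: elementwise square of A."""
    return A * A


def matriline_labels(ped: PedigreeTable) -> np.ndarray:
    """Matriline label per member: own index for members without a recorded
    mother (matriline founders), otherwise the mother's label."""
    labels = np.arange(ped.n, dtype=np.int64)
    for i in ped.topological_order():
        m = int(ped.mother[i])
        if m >= 0:
            labels[i] = labels[m]
    return labels


def mito_matrix(ped: PedigreeTable) -> np.ndarray:
    """mtDNA sharing indicator: 1 iff two members share a matriline."""
    labels = matriline_labels(ped)
    return (labels[:, None] == labels[None, :]).astype(float)


def joint_matrix(A: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Nuclear-mitochondrial interaction: elementwise product A * M."""
    if A.shape != M.shape:
        raise ValueError(f"shape mismatch: A {A.shape} vs M {M.shape}")
    return A * M


def cf_matrix(ped: PedigreeTable, include_parents: bool = False) -> np.ndarray:
    """Nuclear-family indicator: 1 for full siblings and on the diagonal.

    With ``include_parents=True`` the nuclear-family household is extended
    to each sibship's two parents (off by default: the model codes shared
    nuclear-family environment for members who share both parents).
    """
    n = ped.n
    # encode the parental couple; members without parents get a unique key
    key = np.where(
        ped.father >= 0,
        ped.father.astype(np.int64) * (n + 1) + ped.mother.astype(np.int64),
        -np.arange(1, n + 1, dtype=np.int64),
    )
    C = (key[:, None] == key[None, :]).astype(float)
    if include_parents:
        for i in range(n):
            f, m = int(ped.father[i]), int(ped.mother[i])
            if f >= 0:
                for par in (f, m):
                    C[i, par] = C[par, i] = 1.0
                C[f, m] = C[m, f] = 1.0
    np.fill_diagonal(C, 1.0)
    return C


def ce_matrix(ped: PedigreeTable) -> np.ndarray:
    """Extended-family indicator: 1 within each connected family component.

    The family graph joins each member to its recorded parents, each
    co-parenting couple to each other, and recorded mates (so a childless
    couple still belongs to the family).  Deleting a member's parent links
    splits her branch — spouse and descendants included — into a separate
    component with zeros to the rest.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    n = ped.n
    rows, cols = [], []
    for i in range(n):
        f, m = int(ped.father[i]), int(ped.mother[i])
        if f >= 0:
            rows += [i, i, f]
            cols += [f, m, m]
        if ped.spouse is not None and ped.spouse[i] >= 0:
            rows.append(i)
            cols.append(int(ped.spouse[i]))
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return (labels[:, None] == labels[None, :]).astype(float)


def build_all(ped: PedigreeTable) -> ComponentMatrices:
    """Build all six relatedness matrices for one pedigree block."""
    A = additive_matrix(ped)
    M = mito_matrix(ped)
    return ComponentMatrices(
        A=A,
        I_AA=epistasis_matrix(A),
        M=M,
        J=joint_matrix(A, M),
        C_F=cf_matrix(ped),
        C_E=ce_matrix(ped),
        index=ped.member_id.copy(),
        pedigree_id=ped.pedigree_id,
    )


def build_sample_matrices(peds: list[PedigreeTable]) -> list[ComponentMatrices]:
    """Build the per-pedigree matrix blocks for a pooled sample."""
    return [build_all(p) for p in peds]
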