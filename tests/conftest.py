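"""Shared fixtures and independent oracles for the mtped test suite.

The expensive Monte-Carlo experiments (power conditions, bias scenarios,
null-model false positives, LRT calibration) are session-scoped fixtures so
that every consumer test shares one computation.  All seeds are fixed
module constants; problem sizes are desk-scale versions of the study
protocols (documented in docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pytest

from mtped.bias import MAIN_TRUTH, run_bias_experiment, run_null_experiment
from mtped.pedigree import FEMALE, MALE, PedigreeConfig, PedigreeTable
from mtped.power import unit_statistic

# fixed seeds for the shared experiment fixtures
SEED_POWER_T7 = 101
SEED_POWER_T8 = 102
SEED_MUTATION = 103
SEED_MISSING = 104
SEED_NULL = 105

# desk-scale replicate counts (study protocols use 100/500/200)
REPS_POWER_T7 = 30
REPS_POWER_T8 = 20
REPS_MUTATION = 25
REPS_MISSING = 15
REPS_NULL = 32


# ---------------------------------------------------------------------------
# hand-built reference pedigree
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def cousin_pedigree() -> PedigreeTable:
    """Three-generation pedigree with maternal and paternal cousin pairs.

    Members (1-based ids):
      1 (M) x 2 (F) founders
      gen 2: sons 3, 4; daughters 5, 6; married-in wives 7, 8; husbands 9, 10
      gen 3: 11 = child of 3+7, 12 = child of 4+8  (children of brothers)
             13 = child of 9+5, 14 = child of 10+6 (children of sisters)
    """
    father = np.array([-1, -1, 0, 0, 0, 0, -1, -1, -1, -1, 2, 3, 8, 9])
    mother = np.array([-1, -1, 1, 1, 1, 1, -1, -1, -1, -1, 6, 7, 4, 5])
    sex = np.array([MALE, FEMALE, MALE, MALE, FEMALE, FEMALE, FEMALE, FEMALE,
                    MALE, MALE, MALE, FEMALE, MALE, FEMALE], dtype=np.int8)
    generation = np.array([1, 1, 2, 2, 2, 2, 2, 2, 2, 2, 3, 3, 3, 3], dtype=np.int16)
    married_in = np.array([False, False, False, False, False, False, True, True,
                           True, True, False, False, False, False])
    ped = PedigreeTable(
        member_id=np.arange(1, 15, dtype=np.int64),
        father=father,
        mother=mother,
        sex=sex,
        generation=generation,
        married_in=married_in,
        pedigree_id="cousins",
    )
    ped.validate()
    return ped


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def gene_drop_additive(
    ped: PedigreeTable, reps: int = 100_000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo gene-dropping estimate of the additive matrix.

    Drops two uniquely labelled alleles per founder through the pedigree
    (each child inherits one random allele from each parent) and estimates
    relatedness from identity-by-descent allele sharing:
    off-diagonal A_ij = 2 * P(random allele of i IBD to random allele of j),
    diagonal A_ii = 1 + P(i's two alleles IBD).

    Returns (A_hat, standard_error) per entry.
    """
    rng = np.random.default_rng(seed)
    n = ped.n
    order = ped.topological_order()
    alleles = np.empty((n, 2, reps), dtype=np.int32)
    cols = np.arange(reps)
    for i in order:
        f, m = int(ped.father[i]), int(ped.mother[i])
        if f < 0:
            alleles[i, 0] = 2 * i
            alleles[i, 1] = 2 * i + 1
        else:
            alleles[i, 0] = alleles[f, rng.integers(0, 2, reps), cols]
            alleles[i, 1] = alleles[m, rng.integers(0, 2, reps), cols]
    A_hat = np.empty((n, n))
    se = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                q = (alleles[i, 0] == alleles[i, 1]).astype(float)
                est = 1.0 + q.mean()
            else:
                q = np.zeros(reps)
                for a in range(2):
                    for b in range(2):
                        q += alleles[i, a] == alleles[j, b]
                q /= 2.0  # 2 * (sum of 4 indicators) / 4
                est = q.mean()
            A_hat[i, j] = A_hat[j, i] = est
            s = q.std(ddof=1) / np.sqrt(reps)
            se[i, j] = se[j, i] = s
    return A_hat, se


def matriline_oracle_matrix(ped: PedigreeTable) -> np.ndarray:
    """Label-propagation oracle for the mtDNA matrix: each member without a
    recorded mother founds a matriline; every child copies its mother's
    label.  Implemented by identifier with plain dict recursion."""
    members = {m.member_id: m for m in ped.members()}
    labels: dict[int, int] = {}

    def label_of(mid: int) -> int:
        if mid not in labels:
            mom = members[mid].mother_id
            labels[mid] = mid if mom is None else label_of(mom)
        return labels[mid]

    ids = [m.member_id for m in ped.members()]
    lab = np.array([label_of(i) for i in ids])
    return (lab[:, None] == lab[None, :]).astype(float)


def dense_neg2ll(vc, endog: np.ndarray, mats) -> float:
    """Naive full-matrix Gaussian -2 log-likelihood over pooled blocks."""
    from scipy.linalg import block_diag
    from scipy.stats import multivariate_normal

    from mtped.phenotypes import compose_covariance

    sigma = block_diag(*[compose_covariance(vc, m) for m in mats])
    return float(-2.0 * multivariate_normal(mean=np.zeros(len(endog)), cov=sigma).logpdf(endog))


# ---------------------------------------------------------------------------
# shared Monte-Carlo experiment fixtures (heavy; run at most once)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def power_condition_t7():
    """Unit statistic for the small-pedigree condition (k=3, G=4, r=.7)."""
    return unit_statistic(
        PedigreeConfig(k=3, G=4, p=0.5, r=0.7, size_mode="poisson"),
        MAIN_TRUTH,
        reps=REPS_POWER_T7,
        n_per_rep=10_000,
        seed=SEED_POWER_T7,
        n_starts=1,
    )


@pytest.fixture(scope="session")
def power_condition_t8():
    """Unit statistic for the wide-pedigree condition (k=8, G=4, r=.7)."""
    return unit_statistic(
        PedigreeConfig(k=8, G=4, p=0.5, r=0.7, size_mode="poisson"),
        MAIN_TRUTH,
        reps=REPS_POWER_T8,
        n_per_rep=10_000,
        seed=SEED_POWER_T8,
        n_starts=1,
    )


@pytest.fixture(scope="session")
def mutation_bias_summary():
    """Mutation-scenario bias experiment, correct + misspecified fits."""
    return run_bias_experiment(
        "mutation", reps=REPS_MUTATION, seed=SEED_MUTATION, n_starts=1
    )


@pytest.fixture(scope="session")
def missing_link_bias_summary():
    """Missing-link bias experiment, correct + misspecified fits."""
    return run_bias_experiment(
        "missing_link", reps=REPS_MISSING, seed=SEED_MISSING, n_starts=1
    )


@pytest.fixture(scope="session")
def null_experiment_summary():
    """Full-model fits to data generated without mtDNA effects."""
    return run_null_experiment(reps=REPS_NULL, seed=SEED_NULL, n_starts=1)
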