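"""Misspecification experiments: missing maternal links, undetected mtDNA
mutation, and false positives under the null.

All three experiments follow the same template.  Each replicate pools 124
pedigrees of the fixed design k=3, G=5, r=1 (n=161 per pedigree, N=19964
per replicate), generates phenotypes from the data-generating ("truth")
matrices under a fixed variance configuration, and fits the full
seven-component model:

* ``missing_link`` — one random second-generation female's links to both
  parents are deleted, so her branch truly forms a separate family: the
  data-generating matrices are all rebuilt from the broken pedigree, while
  the misspecified fit uses the intact-pedigree matrices (the analyst's
  kinship records wrongly connect the branch).  The correct-matrices fit
  uses the broken (data-generating) matrices.
* ``mutation`` — one random second-generation female carries an mtDNA
  mutation: she and her matrilineal descendants form their own haplotype
  class.  The data-generating truth uses the mutation-aware M (and
  J = A o M) with all other matrices intact; the misspecified fit uses the
  intact-pedigree M and J.
* ``null_model`` — data generated with mt2 = j2 = 0; the full model is fit
  and the distribution of the spurious mt2/j2 estimates is summarized.

In both perturbation scenarios the misspecification enters the data
generation and the misspecified analyst assumes an intact, mutation-free
pedigree.  (Fitting the reverse direction — data from the intact pedigree,
model matrices from the broken one — leaves the estimates unbiased: the
broken model is block-separable, so maximum likelihood simply ignores the
unmodelled cross-branch covariance.)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelSpec, MtdnaVarianceModel
from .pedigree import FEMALE, PedigreeConfig, PedigreeTable, simulate_pedigree
from .phenotypes import COMPONENT_NAMES, VarianceComponents, simulate_phenotypes
from .relatedness import ComponentMatrices, build_all, joint_matrix, matriline_labels

__all__ = [
    "BiasSummary",
    "MAIN_TRUTH",
    "NULL_TRUTH",
    "BIAS_PEDIGREE_CONFIG",
    "drop_parent_links",
    "inject_mito_mutation",
    "run_bias_experiment",
    "run_null_experiment",
]

logger = logging.getLogger(__name__)

#: variance configuration of the bias experiments (e2 = .34)
MAIN_TRUTH = VarianceComponents.truth(a2=0.40, i2=0.0, mt2=0.05, j2=0.01, cF2=0.10, cE2=0.10)
#: null-model truth: no mtDNA effects (e2 = .40)
NULL_TRUTH = VarianceComponents.truth(a2=0.40, i2=0.0, mt2=0.0, j2=0.0, cF2=0.10, cE2=0.10)
#: fixed pedigree design of the bias experiments: n = 161 per pedigree
BIAS_PEDIGREE_CONFIG = PedigreeConfig(k=3, G=5, p=0.5, r=1.0, size_mode="expected")
BIAS_N_PEDIGREES = 124


@dataclass
class BiasSummary:
    """Distribution summary of variance-component estimates per fit kind.

    ``estimates`` maps a fit kind ("correct" / "misspec" / "full") to a
    (reps x 7) DataFrame of per-replicate estimates from converged fits.
    """

    scenario: str
    reps: int
    estimates: dict[str, pd.DataFrame]
    truth: VarianceComponents
    n_dropped: int = 0

    def mean(self, kind: str) -> pd.Series:
        return self.estimates[kind].mean()

    def sd(self, kind: str) -> pd.Series:
        return self.estimates[kind].std(ddof=1)

    def prop_within(self, kind: str, component: str, tol: float) -> float:
        """Fraction of estimates within ``tol`` of the truth value."""
        truth = getattr(self.truth, component)
        vals = self.estimates[kind][component]
        return float((np.abs(vals - truth) <= tol).mean())

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "reps": self.reps,
            "n_dropped": self.n_dropped,
            "truth": self.truth.as_dict(),
            "mean": {k: v.mean().to_dict() for k, v in self.estimates.items()},
            "sd": {k: v.std(ddof=1).to_dict() for k, v in self.estimates.items()},
        }


# ---------------------------------------------------------------------------
# perturbation operators
# ---------------------------------------------------------------------------

def drop_parent_links(ped: PedigreeTable, member_id: int) -> PedigreeTable:
    """Copy of ``ped`` with one member's father and mother links cleared.

    Clearing both links makes the member a founder of her own branch;
    matrix construction then treats the branch as a separate connected
    component.  Dropping links of a member who is already a founder is a
    no-op with a warning.  The input pedigree is never modified.
    """
    pos = np.flatnonzero(ped.member_id == member_id)
    if pos.size != 1:
        raise ValueError(f"member {member_id} not found in pedigree {ped.pedigree_id!r}")
    i = int(pos[0])
    out = ped.copy()
    if ped.father[i] < 0:
        warnings.warn(
            f"member {member_id} is a founder; no parent links to drop", stacklevel=2
        )
        return out
    out.father[i] = -1
    out.mother[i] = -1
    return out


def inject_mito_mutation(ped: PedigreeTable, carrier_id: int) -> np.ndarray:
    """mtDNA matrix with a de-novo haplotype founded at ``carrier_id``.

    The carrier and her matrilineal descendants form their own haplotype
    class (1 among themselves), with zeros to everybody else including the
    carrier's own mother and siblings.  All other matriline classes are
    unchanged.  The carrier must be female (the mutation is modelled at
    gamete formation in a female).
    """
    pos = np.flatnonzero(ped.member_id == carrier_id)
    if pos.size != 1:
        raise ValueError(f"member {carrier_id} not found in pedigree {ped.pedigree_id!r}")
    i = int(pos[0])
    if ped.sex[i] != FEMALE:
        raise ValueError(f"mutation carrier {carrier_id} must be female")
    labels = matriline_labels(ped).copy()
    new_label = ped.n  # outside the existing label range
    labels[i] = new_label
    for j in ped.topological_order():
        m = int(ped.mother[j])
        if m >= 0 and labels[m] == new_label:
            labels[j] = new_label
    return (labels[:, None] == labels[None, :]).astype(float)


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

def _eligible_gen2_females(ped: PedigreeTable) -> np.ndarray:
    """Positions of second-generation bloodline females with children."""
    has_child = ped.has_children()
    mask = (
        (ped.generation == 2)
        & (ped.sex == FEMALE)
        & (ped.father >= 0)
        & has_child
    )
    return np.flatnonzero(mask)


def _simulate_bias_pedigree(
    config: PedigreeConfig, ss: np.random.SeedSequence, pid: str
) -> tuple[PedigreeTable, int]:
    """One pedigree guaranteed to contain an eligible second-generation
    female, plus her member id (chosen uniformly)."""
    for _ in range(100):
        child = ss.spawn(1)[0]
        rng = np.random.default_rng(child)
        ped = simulate_pedigree(config, rng=rng)
        ped.pedigree_id = pid
        eligible = _eligible_gen2_females(ped)
        if eligible.size:
            target = int(rng.choice(eligible))
            return ped, int(ped.member_id[target])
    raise RuntimeError("no pedigree with an eligible second-generation female found")


def _with_mito(mats: ComponentMatrices, M: np.ndarray) -> ComponentMatrices:
    return ComponentMatrices(
        A=mats.A,
        I_AA=mats.I_AA,
        M=M,
        J=joint_matrix(mats.A, M),
        C_F=mats.C_F,
        C_E=mats.C_E,
        index=mats.index,
        pedigree_id=mats.pedigree_id,
    )


def run_bias_experiment(
    scenario: str,
    reps: int = 500,
    seed: int | None = None,
    n_pedigrees: int = BIAS_N_PEDIGREES,
    config: PedigreeConfig = BIAS_PEDIGREE_CONFIG,
    truth: VarianceComponents = MAIN_TRUTH,
    fits: tuple[str, ...] = ("correct", "misspec"),
    n_starts: int = 1,
) -> BiasSummary:
    """Monte-Carlo bias experiment for ``scenario`` in {missing_link, mutation}.

    Per replicate: pool ``n_pedigrees`` fixed-size pedigrees, perturb one
    random eligible second-generation female per pedigree, generate
    phenotypes from the perturbed (data-generating) matrices and fit the
    full model with the requested matrix sets: "correct" uses the
    data-generating matrices, "misspec" the intact-pedigree matrices.
    """
    if scenario not in ("missing_link", "mutation"):
        raise ValueError(f"unknown scenario {scenario!r}")
    ss = np.random.SeedSequence(seed)
    rows: dict[str, list[np.ndarray]] = {kind: [] for kind in fits}
    dropped = 0
    for rep in range(reps):
        rep_ss, pheno_ss = ss.spawn(2)
        truth_mats = []
        misspec_mats = []
        for ip in range(n_pedigrees):
            ped, target_id = _simulate_bias_pedigree(config, rep_ss, f"P{ip + 1}")
            intact = build_all(ped)
            if scenario == "missing_link":
                broken = drop_parent_links(ped, target_id)
                truth_mats.append(build_all(broken))
            else:  # mutation
                M_mut = inject_mito_mutation(ped, target_id)
                truth_mats.append(_with_mito(intact, M_mut))
            if "misspec" in fits:
                misspec_mats.append(intact)
        y = simulate_phenotypes(truth_mats, truth, seed=pheno_ss)
        fit_sets = {"correct": truth_mats, "misspec": misspec_mats}
        ok = True
        rep_rows = {}
        for kind in fits:
            model = MtdnaVarianceModel(y, fit_sets[kind])
            res = model.fit(ModelSpec.full(), n_starts=n_starts)
            if not res.converged:
                ok = False
                logger.warning("rep %d: %s fit did not converge", rep, kind)
                break
            rep_rows[kind] = res.estimates.as_array()
        if not ok:
            dropped += 1
            continue
        for kind, arr in rep_rows.items():
            rows[kind].append(arr)
    estimates = {
        kind: pd.DataFrame(np.vstack(vals), columns=COMPONENT_NAMES)
        for kind, vals in rows.items()
        if vals
    }
    return BiasSummary(
        scenario=scenario,
        reps=reps - dropped,
        estimates=estimates,
        truth=truth,
        n_dropped=dropped,
    )


def run_null_experiment(
    reps: int = 200,
    seed: int | None = None,
    n_pedigrees: int = BIAS_N_PEDIGREES,
    config: PedigreeConfig = BIAS_PEDIGREE_CONFIG,
    truth: VarianceComponents = NULL_TRUTH,
    n_starts: int = 1,
) -> BiasSummary:
    """False-positive experiment: full model fit to mtDNA-free data.

    Returns the distribution of the seven estimates over replicates; the
    mt2 and j2 columns summarize how often spurious mtDNA variance is
    estimated (use :meth:`BiasSummary.prop_within` for tolerance bands).
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    dropped = 0
    for rep in range(reps):
        rep_ss, pheno_ss = ss.spawn(2)
        mats = []
        for ip in range(n_pedigrees):
            child = rep_ss.spawn(1)[0]
            ped = simulate_pedigree(config, rng=np.random.default_rng(child))
            ped.pedigree_id = f"P{ip + 1}"
            mats.append(build_all(ped))
        y = simulate_phenotypes(mats, truth, seed=pheno_ss)
        res = MtdnaVarianceModel(y, mats).fit(ModelSpec.full(), n_starts=n_starts)
        if not res.converged:
            dropped += 1
            logger.warning("rep %d: null-experiment fit did not converge", rep)
            continue
        rows.append(res.estimates.as_array())
    estimates = {"full": pd.DataFrame(np.vstack(rows), columns=COMPONENT_NAMES)}
    return BiasSummary(
        scenario="null_model",
        reps=reps - dropped,
        estimates=estimates,
        truth=truth,
        n_dropped=dropped,
    )
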