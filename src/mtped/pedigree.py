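"""Random extended-pedigree generation and the closed-form size calculus.

A pedigree is parameterised by its depth ``G`` (number of generations), its
width ``k`` (mean number of offspring per mated couple), the male newborn
proportion ``p`` and the reproductive rate ``r`` (the fraction of each
non-final generation's bloodline members who mate).  Every pedigree starts
from a single mated founder couple and ends with a generation in which
nobody has mated.  Mates are always "married-in" founders, unrelated to
everybody already in the pedigree (no consanguinity, no remarriage, no
twins).

The expected generation sizes follow

    m_1 = 2
    m_g = k^(g-1) r^(g-2) (1 + r)   for 2 <= g <= G-1
    m_G = k^(G-1) r^(G-2)

and the expected pedigree size is the sum of the per-generation ceilings,
which reproduces the canonical study designs (m = 33, 61, 344, 657, 161).

Two size modes are supported: ``"expected"`` builds a pedigree whose
per-generation counts equal the ceilings of the expected sizes exactly
(used when a fixed per-pedigree n is required), while ``"poisson"`` draws
each couple's offspring count from Poisson(k) (the data-generating
mechanism used for the power analyses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "FEMALE",
    "MALE",
    "PedigreeError",
    "GenerationShortfallError",
    "PedigreeConfig",
    "PedigreeMember",
    "PedigreeTable",
    "expected_generation_sizes",
    "expected_pedigree_size",
    "simulate_pedigree",
    "assemble_sample",
]

FEMALE = 0
MALE = 1
SEX_LABELS = {FEMALE: "F", MALE: "M"}

_MAX_ATTEMPTS = 100


class PedigreeError(ValueError):
    """A pedigree table or configuration is structurally invalid."""


class GenerationShortfallError(PedigreeError):
    """Repeated simulation attempts failed to populate all G generations."""


@dataclass(frozen=True)
class PedigreeConfig:
    """Shape parameters of a simulated extended pedigree.

    Parameters
    ----------
    k : float
        Mean number of offspring per mated couple (> 0).
    G : int
        Number of generations (>= 1).
    p : float
        Proportion of male newborns, in [0, 1].
    r : float
        Reproductive rate: proportion of each non-final generation's
        bloodline members that mates, in (0, 1].
    size_mode : {"poisson", "expected"}
        Offspring-count mechanism (see module docstring).
    seed : int, optional
        Seed for the random number generator.
    """

    k: float
    G: int
    p: float = 0.5
    r: float = 0.7
    size_mode: str = "poisson"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise PedigreeError(f"k must be > 0, got {self.k}")
        if int(self.G) != self.G or self.G < 1:
            raise PedigreeError(f"G must be an integer >= 1, got {self.G}")
        if not 0.0 <= self.p <= 1.0:
            raise PedigreeError(f"p must be in [0, 1], got {self.p}")
        if not 0.0 < self.r <= 1.0:
            raise PedigreeError(f"r must be in (0, 1], got {self.r}")
        if self.size_mode not in ("poisson", "expected"):
            raise PedigreeError(f"unknown size_mode {self.size_mode!r}")


@dataclass(frozen=True)
class PedigreeMember:
    """One row of a pedigree table, with identifier-based parent links."""

    member_id: int
    father_id: int | None
    mother_id: int | None
    sex: int  # FEMALE or MALE
    generation: int
    married_in: bool


@dataclass
class PedigreeTable:
    """A single connected pedigree stored in flat positional arrays.

    ``father`` and ``mother`` hold positional indices into the table's own
    arrays (-1 when missing), which keeps all matrix builders O(n^2) with
    pure array operations.  ``member_id`` carries the external identifiers
    used by the file formats.
    """

    member_id: np.ndarray
    father: np.ndarray
    mother: np.ndarray
    sex: np.ndarray
    generation: np.ndarray
    married_in: np.ndarray
    pedigree_id: str = "ped"
    phenotype: np.ndarray | None = None
    #: positional index of the recorded mate (-1 = unmated); the simulator
    #: fills this in, file readers leave it None (couples are then inferred
    #: from co-parenthood, so childless file-read couples stay unlinked)
    spouse: np.ndarray | None = None

    @property
    def n(self) -> int:
        return int(self.member_id.shape[0])

    def copy(self) -> "PedigreeTable":
        return PedigreeTable(
            member_id=self.member_id.copy(),
            father=self.father.copy(),
            mother=self.mother.copy(),
            sex=self.sex.copy(),
            generation=self.generation.copy(),
            married_in=self.married_in.copy(),
            pedigree_id=self.pedigree_id,
            phenotype=None if self.phenotype is None else self.phenotype.copy(),
            spouse=None if self.spouse is None else self.spouse.copy(),
        )

    def members(self) -> Iterator[PedigreeMember]:
        for i in range(self.n):
            f, m = int(self.father[i]), int(self.mother[i])
            yield PedigreeMember(
                member_id=int(self.member_id[i]),
                father_id=None if f < 0 else int(self.member_id[f]),
                mother_id=None if m < 0 else int(self.member_id[m]),
                sex=int(self.sex[i]),
                generation=int(self.generation[i]),
                married_in=bool(self.married_in[i]),
            )

    def has_children(self) -> np.ndarray:
        """Boolean mask: does member i appear as a parent of anyone?"""
        out = np.zeros(self.n, dtype=bool)
        out[self.father[self.father >= 0]] = True
        out[self.mother[self.mother >= 0]] = True
        return out

    def topological_order(self) -> np.ndarray:
        """Positional indices ordered parents-before-children (cached).

        Raises
        ------
        PedigreeError
            If the parent links contain a cycle.
        """
        cached = getattr(self, "_topo_cache", None)
        if cached is not None:
            return cached
        n = self.n
        indeg = np.where(self.father >= 0, 2, 0)
        order = np.empty(n, dtype=np.int64)
        stack = list(np.flatnonzero(indeg == 0))
        # children adjacency
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            for par in (int(self.father[i]), int(self.mother[i])):
                if par >= 0:
                    children[par].append(i)
        k = 0
        while stack:
            i = stack.pop()
            order[k] = i
            k += 1
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    stack.append(c)
        if k != n:
            raise PedigreeError(
                f"pedigree {self.pedigree_id!r}: parent links contain a cycle"
            )
        object.__setattr__(self, "_topo_cache", order)
        return order

    def validate(self) -> None:
        """Check the structural invariants of a pedigree table."""
        n = self.n
        ids = self.member_id
        if len(np.unique(ids)) != n:
            raise PedigreeError(f"pedigree {self.pedigree_id!r}: duplicate member ids")
        both = (self.father >= 0) == (self.mother >= 0)
        if not both.all():
            bad = ids[~both].tolist()
            raise PedigreeError(
                f"pedigree {self.pedigree_id!r}: members {bad} have exactly one "
                "recorded parent (need both or neither)"
            )
        for name, arr in (("father", self.father), ("mother", self.mother)):
            if ((arr < -1) | (arr >= n)).any():
                raise PedigreeError(
                    f"pedigree {self.pedigree_id!r}: {name} index out of range"
                )
        has_f = self.father >= 0
        if has_f.any():
            if (self.sex[self.father[has_f]] != MALE).any():
                raise PedigreeError(
                    f"pedigree {self.pedigree_id!r}: a referenced father is not male"
                )
            if (self.sex[self.mother[has_f]] != FEMALE).any():
                raise PedigreeError(
                    f"pedigree {self.pedigree_id!r}: a referenced mother is not female"
                )
        self.topological_order()  # raises on cycles

    def to_dataframe(self) -> pd.DataFrame:
        f, m = self.father, self.mother
        df = pd.DataFrame(
            {
                "fid": self.pedigree_id,
                "id": self.member_id,
                "father": np.where(f >= 0, self.member_id[np.clip(f, 0, None)], 0),
                "mother": np.where(m >= 0, self.member_id[np.clip(m, 0, None)], 0),
                "sex": [SEX_LABELS[int(s)] for s in self.sex],
                "generation": self.generation,
                "married_in": self.married_in.astype(bool),
            }
        )
        if self.phenotype is not None:
            df["phenotype"] = self.phenotype
        return df


def expected_generation_sizes(k: float, G: int, r: float) -> np.ndarray:
    """Expected (real-valued) per-generation sizes [m_1 .. m_G].

    m_1 = 2; m_g = k^(g-1) r^(g-2) (1+r) for the middle generations;
    m_G = k^(G-1) r^(G-2).  No rounding is applied.
    """
    _validate_kGr(k, G, r)
    sizes = np.empty(G, dtype=float)
    sizes[0] = 2.0
    for g in range(2, G + 1):
        raw = k ** (g - 1) * r ** (g - 2)
        sizes[g - 1] = raw if g == G else raw * (1.0 + r)
    return sizes


def expected_pedigree_size(k: float, G: int, r: float) -> int:
    """Expected total pedigree size: sum of per-generation ceilings."""
    sizes = expected_generation_sizes(k, G, r)
    return int(np.ceil(sizes - 1e-9).sum())


def _validate_kGr(k: float, G: int, r: float) -> None:
    if not k > 0:
        raise PedigreeError(f"k must be > 0, got {k}")
    if int(G) != G or G < 1:
        raise PedigreeError(f"G must be an integer >= 1, got {G}")
    if not 0.0 < r <= 1.0:
        raise PedigreeError(f"r must be in (0, 1], got {r}")


def _expected_children_counts(k: float, G: int, r: float) -> list[int]:
    """Integer bloodline-children count per generation (gen 1 = founders)."""
    counts = [2]
    for g in range(2, G + 1):
        counts.append(int(math.ceil(k ** (g - 1) * r ** (g - 2) - 1e-9)))
    return counts


def simulate_pedigree(
    config: PedigreeConfig, rng: np.random.Generator | None = None
) -> PedigreeTable:
    """Simulate one extended pedigree under ``config``.

    Offspring counts follow the configured size mode; a fraction ``r`` of
    each non-final generation's bloodline mates with a newly created
    married-in spouse of the opposite sex; newborn sex is Bernoulli(p);
    the final generation never mates.  Configurations that repeatedly fail
    to populate all G generations (e.g. all Poisson draws zero) raise
    :class:`GenerationShortfallError` after bounded resampling.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for _ in range(_MAX_ATTEMPTS):
        table = _try_build(config, rng)
        if table is not None:
            return table
    raise GenerationShortfallError(
        f"could not populate {config.G} generations in {_MAX_ATTEMPTS} attempts "
        f"(k={config.k}, r={config.r}, size_mode={config.size_mode})"
    )


def _try_build(config: PedigreeConfig, rng: np.random.Generator) -> PedigreeTable | None:
    k, G, p, r = config.k, config.G, config.p, config.r
    sex: list[int] = [MALE, FEMALE]
    father: list[int] = [-1, -1]
    mother: list[int] = [-1, -1]
    generation: list[int] = [1, 1]
    married_in: list[bool] = [False, False]
    spouse: list[int] = [1, 0]  # founders are a mated couple

    if config.size_mode == "expected":
        child_counts = _expected_children_counts(k, G, r)
        totals = [int(math.ceil(s - 1e-9)) for s in expected_generation_sizes(k, G, r)]

    couples: list[tuple[int, int]] = [(0, 1)]  # (father_idx, mother_idx)
    for g in range(2, G + 1):
        if not couples:
            return None
        # --- bloodline children of generation g ---
        if config.size_mode == "poisson":
            draws = rng.poisson(k, size=len(couples))
        else:
            total_children = child_counts[g - 1]
            base, rem = divmod(total_children, len(couples))
            draws = np.full(len(couples), base, dtype=np.int64)
            if rem:
                extra = rng.choice(len(couples), size=rem, replace=False)
                draws[extra] += 1
        n_children = int(draws.sum())
        if n_children == 0:
            return None
        child_idx: list[int] = []
        for (f_idx, m_idx), c in zip(couples, draws):
            for _ in range(int(c)):
                i = len(sex)
                sex.append(MALE if rng.random() < p else FEMALE)
                father.append(f_idx)
                mother.append(m_idx)
                generation.append(g)
                married_in.append(False)
                spouse.append(-1)
                child_idx.append(i)
        if g == G:
            break
        # --- maters and their married-in spouses ---
        if config.size_mode == "poisson":
            n_mater = int(round(r * n_children))
        else:
            n_mater = totals[g - 1] - n_children
            n_mater = min(max(n_mater, 0), n_children)
        if n_mater == 0:
            if config.size_mode == "poisson":
                return None  # cannot reach generation G; resample
            n_mater = 1  # forced mater keeps deeper generations reachable
        maters = rng.choice(np.asarray(child_idx), size=n_mater, replace=False)
        couples = []
        for mtr in maters:
            mtr = int(mtr)
            j = len(sex)
            sex.append(FEMALE if sex[mtr] == MALE else MALE)
            father.append(-1)
            mother.append(-1)
            generation.append(g)
            married_in.append(True)
            spouse.append(mtr)
            spouse[mtr] = j
            if sex[mtr] == MALE:
                couples.append((mtr, j))
            else:
                couples.append((j, mtr))

    n = len(sex)
    return PedigreeTable(
        member_id=np.arange(1, n + 1, dtype=np.int64),
        father=np.asarray(father, dtype=np.int64),
        mother=np.asarray(mother, dtype=np.int64),
        sex=np.asarray(sex, dtype=np.int8),
        generation=np.asarray(generation, dtype=np.int16),
        married_in=np.asarray(married_in, dtype=bool),
        spouse=np.asarray(spouse, dtype=np.int64),
    )


def assemble_sample(config: PedigreeConfig, n_target: int) -> list[PedigreeTable]:
    """Simulate independent pedigrees until the pooled size reaches ``n_target``.

    Pedigrees are drawn from deterministic substreams of ``config.seed``, so
    the returned sample is reproducible.  The cumulative size first reaching
    or exceeding ``n_target`` stops the loop.
    """
    if n_target < 1:
        raise PedigreeError(f"n_target must be >= 1, got {n_target}")
    ss = np.random.SeedSequence(config.seed)
    peds: list[PedigreeTable] = []
    total = 0
    i = 0
    while total < n_target:
        child = ss.spawn(1)[0]
        ped = simulate_pedigree(config, rng=np.random.default_rng(child))
        i += 1
        ped.pedigree_id = f"P{i}"
        peds.append(ped)
        total += ped.n
    return peds


def sample_size(peds: list[PedigreeTable]) -> int:
    """Total number of individuals pooled across pedigrees."""
    return int(sum(p.n for p in peds))
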