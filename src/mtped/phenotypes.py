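"""Model covariance composition and multivariate-normal phenotype simulation.

The phenotypic covariance of one pedigree block is the linear combination

    Sigma = a2*A + i2*I_AA + mt2*M + j2*J + cF2*C_F + cE2*C_E + e2*I

with the seven standardized variance components as weights.  Phenotypes are
zero-mean multivariate-normal draws per pedigree block, independent across
blocks, with deterministic per-block substreams of a master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .relatedness import ComponentMatrices

__all__ = [
    "COMPONENT_NAMES",
    "VarianceComponents",
    "compose_covariance",
    "simulate_phenotypes",
]

#: component order, aligned with the ComponentMatrices.stack() matrix order
COMPONENT_NAMES = ("a2", "i2", "mt2", "j2", "cF2", "cE2", "e2")


@dataclass(frozen=True)
class VarianceComponents:
    """The seven standardized variance components of the model.

    Truth configurations (for simulation) must be non-negative and sum to 1
    (standardized trait); estimates are unbounded and may go negative.
    """

    a2: float = 0.0
    i2: float = 0.0
    mt2: float = 0.0
    j2: float = 0.0
    cF2: float = 0.0
    cE2: float = 0.0
    e2: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in COMPONENT_NAMES])

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in COMPONENT_NAMES}

    @classmethod
    def from_array(cls, values: np.ndarray) -> "VarianceComponents":
        return cls(**dict(zip(COMPONENT_NAMES, map(float, values))))

    @classmethod
    def truth(cls, **components: float) -> "VarianceComponents":
        """Build a truth configuration; ``e2`` is the remainder to 1 if omitted."""
        unknown = set(components) - set(COMPONENT_NAMES)
        if unknown:
            raise ValueError(f"unknown variance components: {sorted(unknown)}")
        if "e2" not in components:
            components["e2"] = 1.0 - sum(components.values())
        vc = cls(**components)
        vc.validate_truth()
        return vc

    def validate_truth(self) -> None:
        arr = self.as_array()
        if (arr < -1e-12).any():
            raise ValueError(f"truth components must be non-negative: {self.as_dict()}")
        total = float(arr.sum())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"truth components must sum to 1, got {total}")


def compose_covariance(vc: VarianceComponents, mats: ComponentMatrices) -> np.ndarray:
    """Model covariance of one pedigree block under variance components ``vc``."""
    sigma = vc.a2 * mats.A
    sigma += vc.i2 * mats.I_AA
    sigma += vc.mt2 * mats.M
    sigma += vc.j2 * mats.J
    sigma += vc.cF2 * mats.C_F
    sigma += vc.cE2 * mats.C_E
    sigma[np.diag_indices_from(sigma)] += vc.e2
    return sigma


def simulate_phenotypes(
    mats: list[ComponentMatrices],
    vc: VarianceComponents,
    seed: int | np.random.SeedSequence | None = None,
) -> np.ndarray:
    """Zero-mean multivariate-normal phenotypes, one draw per pedigree block.

    Returns the concatenated phenotype vector in block order (block-internal
    order follows each block's member index).  Each block uses its own
    deterministic substream of ``seed``, so results are reproducible and
    independent of any parallel scheduling.

    Raises
    ------
    numpy.linalg.LinAlgError
        If a block covariance is not positive definite (reported with the
        offending pedigree id).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(len(mats))
    out = []
    for block, sub in zip(mats, streams):
        sigma = compose_covariance(vc, block)
        try:
            L = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"covariance of pedigree {block.pedigree_id!r} is not positive "
                f"definite under {vc.as_dict()}"
            ) from err
        z = np.random.default_rng(sub).standard_normal(block.n)
        out.append(L @ z)
    return np.concatenate(out) if out else np.empty(0)
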