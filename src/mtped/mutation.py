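"""Closed-form expectations for mtDNA mutation incidence.

With a per-site per-generation mutation rate u and an mtDNA length of L
base pairs, the expected number of germline mutations per parent-offspring
transmission is u * L, and one mutation is expected roughly every
1 / (u * L) transmissions.  The default length of 17,000 bp together with
u = 2.7e-7 gives 4.59e-3 expected mutations per transmission, i.e. one
mutation about every 218 transmissions.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MutationParams",
    "expected_mutations_per_transmission",
    "transmissions_per_mutation",
]


@dataclass(frozen=True)
class MutationParams:
    """Mutation rate per site per generation and mtDNA length in base pairs."""

    rate_per_site: float = 2.7e-7
    n_sites: int = 17_000

    def __post_init__(self) -> None:
        if self.rate_per_site < 0:
            raise ValueError(f"rate_per_site must be >= 0, got {self.rate_per_site}")
        if self.n_sites <= 0:
            raise ValueError(f"n_sites must be > 0, got {self.n_sites}")


def expected_mutations_per_transmission(params: MutationParams) -> float:
    """Expected germline mtDNA mutations per parent-offspring transmission."""
    return params.rate_per_site * params.n_sites


def transmissions_per_mutation(params: MutationParams) -> int:
    """Expected number of transmissions between successive mutations (rounded)."""
    expectation = expected_mutations_per_transmission(params)
    if expectation <= 0:
        raise ValueError("transmissions_per_mutation undefined for zero mutation rate")
    return round(1.0 / expectation)
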