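"""YAML experiment configuration with a flat, documented key set.

Keys (all optional unless noted): ``kind`` (power | bias | null | fit,
required), pedigree shape ``k``, ``G``, ``p``, ``r``, ``size_mode``,
truth components ``a2 i2 mt2 j2 cF2 cE2`` (``e2`` inferred as the
remainder to 1), ``reps``, ``n_per_rep``, ``alpha``, ``powers``,
``seed`` and ``out``.  CLI flags override config values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .pedigree import PedigreeConfig
from .phenotypes import COMPONENT_NAMES, VarianceComponents

__all__ = ["ExperimentConfig", "load_config"]

_KINDS = ("power", "bias", "null", "fit")


@dataclass
class ExperimentConfig:
    kind: str
    pedigree: PedigreeConfig
    truth: VarianceComponents
    reps: int = 20
    n_per_rep: int = 5_000
    alpha: float = 0.05
    powers: tuple[float, ...] = (0.4, 0.6, 0.8)
    seed: int | None = None
    out: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"experiment kind must be one of {_KINDS}, got {self.kind!r}")


def load_config(path: str | Path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    pedigree = PedigreeConfig(
        k=float(raw.get("k", 3.0)),
        G=int(raw.get("G", 4)),
        p=float(raw.get("p", 0.5)),
        r=float(raw.get("r", 0.7)),
        size_mode=str(raw.get("size_mode", "poisson")),
        seed=raw.get("seed"),
    )
    comps = {c: float(raw[c]) for c in COMPONENT_NAMES if c in raw}
    truth = VarianceComponents.truth(**comps) if comps else VarianceComponents(e2=1.0)
    return ExperimentConfig(
        kind=str(raw.get("kind", "fit")),
        pedigree=pedigree,
        truth=truth,
        reps=int(raw.get("reps", 20)),
        n_per_rep=int(raw.get("n_per_rep", 5_000)),
        alpha=float(raw.get("alpha", 0.05)),
        powers=tuple(raw.get("powers", (0.4, 0.6, 0.8))),
        seed=raw.get("seed"),
        out=raw.get("out"),
    )
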