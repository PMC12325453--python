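"""Noncentrality-based power analysis for the joint mt2 + j2 test.

The likelihood-ratio test comparing the full model against the null with
mt2 = j2 = 0 has 2 degrees of freedom.  Its per-individual noncentrality
contribution, the unit statistic

    T = ( [-2 log L(H0)] - [-2 log L(H1)] ) / N

is estimated by Monte-Carlo simulation (fit both models to replicate
samples, average T over replicates).  For any target sample size N' the
noncentrality parameter is lambda = (N' - 1) T, and

    power = P( chi2_df(lambda) > chi2_{df, 1-alpha}(0) ).

Required sample sizes invert this relation for a target power.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import ModelSpec, MtdnaVarianceModel, likelihood_ratio
from .pedigree import PedigreeConfig, assemble_sample
from .phenotypes import VarianceComponents, simulate_phenotypes
from .relatedness import build_sample_matrices

__all__ = ["PowerResult", "unit_statistic", "power_at_n", "required_n", "power_table"]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_DF = 2


@dataclass
class PowerResult:
    """Unit statistic and derived power quantities for one condition."""

    T: float
    reps: int
    N_per_rep: int
    alpha: float = DEFAULT_ALPHA
    df: int = DEFAULT_DF
    per_rep_T: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_dropped: int = 0

    def power_curve(self, n_values: np.ndarray) -> pd.Series:
        vals = [power_at_n(self.T, int(n), self.alpha, self.df) for n in n_values]
        return pd.Series(vals, index=np.asarray(n_values, dtype=int), name="power")

    def required_n(self, target_power: float) -> int:
        return required_n(self.T, target_power, self.alpha, self.df)


def unit_statistic(
    config: PedigreeConfig,
    vc: VarianceComponents,
    reps: int = 100,
    n_per_rep: int = 10_000,
    seed: int | None = None,
    n_starts: int = 1,
) -> PowerResult:
    """Monte-Carlo estimate of the unit statistic T for one condition.

    For each replicate: pool pedigrees to ~``n_per_rep`` individuals,
    simulate phenotypes under the truth ``vc``, fit the full and the
    mt2/j2-restricted model by ML, and record the likelihood-ratio
    statistic divided by the replicate's exact N.  T is the mean over
    replicates.  Replicates where either fit fails to converge are dropped;
    more than 20% dropped raises RuntimeError.
    """
    ss = np.random.SeedSequence(seed)
    values = []
    dropped = 0
    total_n = 0
    for rep in range(reps):
        ped_ss, pheno_ss = ss.spawn(2)
        rep_config = PedigreeConfig(
            k=config.k, G=config.G, p=config.p, r=config.r,
            size_mode=config.size_mode,
            seed=int(ped_ss.generate_state(1)[0] % (2**31)),
        )
        peds = assemble_sample(rep_config, n_per_rep)
        mats = build_sample_matrices(peds)
        y = simulate_phenotypes(mats, vc, seed=pheno_ss)
        model = MtdnaVarianceModel(y, mats)
        null_spec = ModelSpec.null_mtdna()
        fit_alt = model.fit(ModelSpec.full(), n_starts=n_starts)
        # warm-start the nested fit from the restricted full-model estimates
        warm = fit_alt.estimates.as_array()[null_spec.free_indices]
        fit_null = model.fit(null_spec, n_starts=n_starts, start_values=warm)
        if not (fit_alt.converged and fit_null.converged):
            dropped += 1
            logger.warning("replicate %d dropped (non-convergence)", rep)
            continue
        lrt = likelihood_ratio(fit_alt, fit_null)
        values.append(lrt.statistic / model.nobs)
        total_n += model.nobs
    if dropped > 0.2 * reps:
        raise RuntimeError(f"{dropped}/{reps} replicates failed to converge")
    per_rep = np.asarray(values)
    return PowerResult(
        T=float(per_rep.mean()),
        reps=len(values),
        N_per_rep=int(round(total_n / max(len(values), 1))),
        per_rep_T=per_rep,
        n_dropped=dropped,
    )


def power_at_n(
    T: float, n_prime: int, alpha: float = DEFAULT_ALPHA, df: int = DEFAULT_DF
) -> float:
    """Power of the df-degree LRT at sample size ``n_prime`` given unit T."""
    if T < 0:
        raise ValueError(f"T must be >= 0, got {T}")
    if n_prime < 2:
        raise ValueError(f"N' must be >= 2, got {n_prime}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    crit = stats.chi2.ppf(1.0 - alpha, df)
    lam = (n_prime - 1) * T
    if lam == 0.0:
        return float(stats.chi2.sf(crit, df))
    return float(stats.ncx2.sf(crit, df, lam))


def required_n(
    T: float,
    target_power: float,
    alpha: float = DEFAULT_ALPHA,
    df: int = DEFAULT_DF,
) -> int:
    """Smallest integer N' whose LRT power reaches ``target_power``."""
    if T <= 0:
        raise ValueError(f"required_n needs T > 0, got {T}")
    if not alpha < target_power < 1.0:
        raise ValueError(
            f"target power must lie in (alpha, 1), got {target_power} (alpha={alpha})"
        )
    crit = stats.chi2.ppf(1.0 - alpha, df)

    def gap(lam: float) -> float:
        return stats.ncx2.sf(crit, df, lam) - target_power

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
    lam_star = optimize.brentq(gap, 0.0, hi, xtol=1e-10)
    n = max(2, int(math.ceil(lam_star / T)) + 1)
    while n > 2 and power_at_n(T, n - 1, alpha, df) >= target_power:
        n -= 1
    while power_at_n(T, n, alpha, df) < target_power:
        n += 1
    return n


def power_table(
    conditions: dict[str, tuple[PedigreeConfig, VarianceComponents]],
    powers: tuple[float, ...] = (0.4, 0.6, 0.8),
    reps: int = 20,
    n_per_rep: int = 5_000,
    seed: int | None = None,
    alpha: float = DEFAULT_ALPHA,
    n_starts: int = 1,
) -> pd.DataFrame:
    """Required-N table across named conditions and target power levels.

    Each row is one condition (a pedigree configuration plus a truth
    variance configuration); columns report the estimated unit statistic T
    and the required N per target power.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for name, (config, vc) in conditions.items():
        sub = ss.spawn(1)[0]
        res = unit_statistic(
            config, vc, reps=reps, n_per_rep=n_per_rep,
            seed=int(sub.generate_state(1)[0] % (2**31)), n_starts=n_starts,
        )
        row: dict[str, object] = {
            "condition": name,
            "k": config.k,
            "G": config.G,
            "r": config.r,
            "mt2": vc.mt2,
            "T": res.T,
            "reps": res.reps,
        }
        for p in powers:
            row[f"n_power_{p:g}"] = res.required_n(p)
        rows.append(row)
    return pd.DataFrame(rows)
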