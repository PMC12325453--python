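"""Maximum-likelihood estimation of the extended-pedigree variance components.

The central objects follow the statsmodels convention: a model object built
from data (:class:`MtdnaVarianceModel`) whose :meth:`~MtdnaVarianceModel.fit`
returns a results object (:class:`VarianceComponentResults`) carrying the
estimates, fit diagnostics and a ``summary()`` table.  The phenotype vector
is modelled as zero-mean multivariate normal, block-diagonal over pedigrees,
with covariance linear in the seven variance components.

Estimates are intentionally unbounded: negative variance-component estimates
are admissible so that the likelihood-ratio statistic for the joint
mt2 + j2 test keeps its central/noncentral chi-square(2) reference
distribution without boundary corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._likelihood import BlockedGaussian
from .pedigree import PedigreeTable
from .phenotypes import COMPONENT_NAMES, VarianceComponents
from .relatedness import ComponentMatrices, build_sample_matrices

__all__ = [
    "ModelSpec",
    "MtdnaVarianceModel",
    "VarianceComponentResults",
    "LikelihoodRatio",
    "neg2_loglik",
    "fit_model",
    "likelihood_ratio",
]


@dataclass(frozen=True)
class ModelSpec:
    """Which variance components are free; the rest are fixed (default 0).

    ``e2`` is always free: a residual variance is required for the block
    covariances to stay positive definite at the optimum.
    """

    free: tuple[str, ...] = COMPONENT_NAMES
    fixed: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        unknown = set(self.free) - set(COMPONENT_NAMES)
        if unknown:
            raise ValueError(f"unknown components in free set: {sorted(unknown)}")
        if "e2" not in self.free:
            raise ValueError("e2 (residual variance) must always be free")
        fixed_names = {name for name, _ in self.fixed}
        overlap = fixed_names & set(self.free)
        if overlap:
            raise ValueError(f"components both free and fixed: {sorted(overlap)}")

    @classmethod
    def full(cls) -> "ModelSpec":
        """All seven components free (the full mtDNA model)."""
        return cls(free=COMPONENT_NAMES)

    @classmethod
    def null_mtdna(cls) -> "ModelSpec":
        """The mtDNA null: mt2 and j2 fixed at 0 (df difference 2)."""
        free = tuple(c for c in COMPONENT_NAMES if c not in ("mt2", "j2"))
        return cls(free=free, fixed=(("mt2", 0.0), ("j2", 0.0)))

    @classmethod
    def with_free(cls, components: Iterable[str]) -> "ModelSpec":
        comps = set(components) | {"e2"}
        free = tuple(c for c in COMPONENT_NAMES if c in comps)
        return cls(free=free)

    @property
    def free_indices(self) -> np.ndarray:
        return np.array([COMPONENT_NAMES.index(c) for c in self.free])

    def fixed_values(self) -> np.ndarray:
        """Length-7 vector with fixed components filled in, free ones at 0."""
        out = np.zeros(7)
        fixed = dict(self.fixed)
        for i, name in enumerate(COMPONENT_NAMES):
            if name not in self.free:
                out[i] = fixed.get(name, 0.0)
        return out

    def full_vector(self, free_values: np.ndarray) -> np.ndarray:
        out = self.fixed_values()
        out[self.free_indices] = free_values
        return out

    def is_nested_in(self, other: "ModelSpec") -> bool:
        """True if this spec is a restriction of ``other``."""
        if not set(self.free) <= set(other.free):
            return False
        mine, theirs = dict(self.fixed), dict(other.fixed)
        for name in COMPONENT_NAMES:
            if name not in self.free and name not in other.free:
                if mine.get(name, 0.0) != theirs.get(name, 0.0):
                    return False
        return True


class LikelihoodRatio(NamedTuple):
    statistic: float
    df: int
    pvalue: float


class VarianceComponentResults:
    """ML estimates and diagnostics for one fitted component set.

    Attributes
    ----------
    estimates : VarianceComponents
        Point estimates; fixed components echo their fixed values.
    params : pandas.Series
        The same estimates as a named series.
    neg2ll : float
        -2 log-likelihood at the optimum.
    converged : bool
    n_function_evals : int
    n_individuals : int
    """

    def __init__(
        self,
        model: "MtdnaVarianceModel",
        spec: ModelSpec,
        estimates: VarianceComponents,
        neg2ll: float,
        converged: bool,
        n_function_evals: int,
        message: str = "",
        start_used: str = "",
    ):
        self.model = model
        self.spec = spec
        self.estimates = estimates
        self.neg2ll = float(neg2ll)
        self.converged = bool(converged)
        self.n_function_evals = int(n_function_evals)
        self.n_individuals = model.nobs
        self.message = message
        self.start_used = start_used

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.estimates.as_dict(), name="estimate")

    @property
    def nobs(self) -> int:
        return self.n_individuals

    def lrt(self, null_result: "VarianceComponentResults") -> LikelihoodRatio:
        return likelihood_ratio(self, null_result)

    def summary(self) -> str:
        lines = [
            "Extended-pedigree variance component model",
            "=" * 46,
            f"N individuals: {self.n_individuals:>8d}    blocks: {len(self.model.matrices):d}",
            f"-2 log L:      {self.neg2ll:14.4f}",
            f"converged:     {self.converged}    function evals: {self.n_function_evals}",
            "-" * 46,
            f"{'component':<10}{'estimate':>12}  status",
        ]
        for name in COMPONENT_NAMES:
            status = "free" if name in self.spec.free else "fixed"
            lines.append(f"{name:<10}{getattr(self.estimates, name):>12.4f}  {status}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<VarianceComponentResults neg2ll={self.neg2ll:.3f} "
            f"converged={self.converged} free={self.spec.free}>"
        )


class MtdnaVarianceModel:
    """Zero-mean Gaussian variance-component model over pedigree blocks.

    Parameters
    ----------
    endog : array-like
        Concatenated phenotype vector, aligned with the blocks of
        ``matrices`` in order.
    matrices : sequence of ComponentMatrices
        One relatedness-matrix block per pedigree.
    demean : bool
        If True, subtract the pooled sample mean before fitting (a single
        profiled-out intercept for external data; it cancels in the LRT).
        Simulated data are zero-mean, so the default is False.
    """

    def __init__(
        self,
        endog: np.ndarray | Sequence[float],
        matrices: Sequence[ComponentMatrices],
        demean: bool = False,
    ):
        y = np.asarray(endog, dtype=float).ravel()
        sizes = [m.n for m in matrices]
        if y.shape[0] != sum(sizes):
            raise ValueError(
                f"phenotype length {y.shape[0]} does not match total block size {sum(sizes)}"
            )
        if demean:
            y = y - y.mean()
        self.matrices = list(matrices)
        self.endog = y
        splits = np.cumsum(sizes)[:-1]
        ys = np.split(y, splits)
        self._engine = BlockedGaussian.from_components(self.matrices, ys)
        self.nobs = self._engine.n_total

    @classmethod
    def from_pedigrees(
        cls,
        peds: Sequence[PedigreeTable],
        endog: np.ndarray | None = None,
        demean: bool = False,
    ) -> "MtdnaVarianceModel":
        """Build the model from pedigree tables; phenotypes default to the
        tables' own ``phenotype`` columns."""
        mats = build_sample_matrices(list(peds))
        if endog is None:
            phenos = []
            for p in peds:
                if p.phenotype is None:
                    raise ValueError(
                        f"pedigree {p.pedigree_id!r} carries no phenotype column"
                    )
                phenos.append(p.phenotype)
            endog = np.concatenate(phenos)
        return cls(endog, mats, demean=demean)

    # ------------------------------------------------------------------
    def neg2_loglik(self, vc: VarianceComponents) -> float:
        """-2 log-likelihood at the given variance components."""
        return self._engine.neg2ll(vc.as_array())

    def _starts(self, spec: ModelSpec) -> list[tuple[str, np.ndarray]]:
        """Deterministic optimizer starts over the free components."""
        free_idx = spec.free_indices
        fixed = spec.fixed_values()
        vtot = self._engine.total_variance()
        he = self._engine.he_estimate(free_idx, fixed)
        # keep the start strictly inside the PD region: clip e2 up
        e2_pos = list(spec.free).index("e2")
        he_start = he.copy()
        he_start[e2_pos] = max(he_start[e2_pos], 0.05 * vtot)
        equal = np.full(len(free_idx), vtot / len(free_idx))
        blend = 0.5 * np.clip(he_start, 0.0, None) + 0.5 * equal
        return [("he", he_start), ("equal", equal), ("blend", blend)]

    def fit(
        self,
        spec: ModelSpec | None = None,
        n_starts: int = 3,
        maxiter: int = 500,
        ftol: float = 1e-9,
        gtol: float = 1e-4,
        start_values: np.ndarray | None = None,
    ) -> VarianceComponentResults:
        """Minimize -2 log L over the free components (unbounded quasi-Newton).

        Up to three deterministic starts are tried (a Haseman-Elston
        moment start, an equal split of the phenotypic variance, and a
        blend); the best local optimum is returned.  ``start_values``
        (ordered over the free components) prepends a caller-supplied warm
        start, e.g. a nested model's estimates.
        """
        spec = spec or ModelSpec.full()
        free_idx = spec.free_indices
        engine = self._engine

        def fun_grad(x: np.ndarray):
            w = spec.full_vector(x)
            f, g = engine.neg2ll_grad(w)
            return f, g[free_idx]

        best = None
        total_evals = 0
        starts = self._starts(spec)[: max(1, n_starts)]
        if start_values is not None:
            warm = np.asarray(start_values, dtype=float)
            if warm.shape != (len(free_idx),):
                raise ValueError(
                    f"start_values must cover the {len(free_idx)} free components"
                )
            starts = [("warm", warm)] + starts[: max(0, n_starts - 1)]
        for label, x0 in starts:
            res = optimize.minimize(
                fun_grad,
                x0,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol},
            )
            total_evals += res.nfev
            if best is None or res.fun < best[1].fun:
                best = (label, res)
        label, res = best
        estimates = VarianceComponents.from_array(spec.full_vector(res.x))
        converged = bool(res.success) and np.isfinite(res.fun)
        return VarianceComponentResults(
            model=self,
            spec=spec,
            estimates=estimates,
            neg2ll=res.fun,
            converged=converged,
            n_function_evals=total_evals,
            message=str(res.message),
            start_used=label,
        )


def neg2_loglik(
    vc: VarianceComponents,
    endog: np.ndarray,
    matrices: Sequence[ComponentMatrices],
) -> float:
    """Functional form of the pooled block-diagonal -2 log-likelihood."""
    return MtdnaVarianceModel(endog, matrices).neg2_loglik(vc)


def fit_model(
    endog: np.ndarray,
    matrices: Sequence[ComponentMatrices],
    spec: ModelSpec | None = None,
    **options,
) -> VarianceComponentResults:
    """Fit the variance-component model; see :meth:`MtdnaVarianceModel.fit`."""
    return MtdnaVarianceModel(endog, matrices).fit(spec=spec, **options)


def likelihood_ratio(
    fit_alt: VarianceComponentResults, fit_null: VarianceComponentResults
) -> LikelihoodRatio:
    """Likelihood-ratio statistic of nested fits on the same data.

    The statistic is [-2 log L(null)] - [-2 log L(alt)], clipped at zero
    against optimizer noise; df is the difference in free-component counts.
    """
    if not fit_null.spec.is_nested_in(fit_alt.spec):
        raise ValueError(
            f"null spec {fit_null.spec.free} is not nested in {fit_alt.spec.free}"
        )
    if fit_alt.n_individuals != fit_null.n_individuals:
        raise ValueError("likelihood-ratio test requires fits on the same data")
    df = len(fit_alt.spec.free) - len(fit_null.spec.free)
    stat = max(0.0, fit_null.neg2ll - fit_alt.neg2ll)
    pvalue = float(stats.chi2.sf(stat, df)) if df > 0 else float("nan")
    return LikelihoodRatio(statistic=stat, df=df, pvalue=pvalue)
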