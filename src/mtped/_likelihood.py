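"""Batched block-diagonal Gaussian likelihood for variance-component fitting.

The pooled sample is a block-diagonal multivariate normal: independent
pedigree blocks, each with covariance linear in the seven variance
components.  This module stores the per-block matrix stacks grouped by
block size so that composition, Cholesky factorisation and inversion run
as batched array operations, and evaluates

    -2 log L = sum_f [ n_f log(2 pi) + log det Sigma_f + y_f' Sigma_f^-1 y_f ]

together with its analytic gradient

    d(-2 log L)/d c_k = sum_f [ tr(Sigma_f^-1 K_fk) - a_f' K_fk a_f ],
    a_f = Sigma_f^-1 y_f

with respect to the component weights c.  Blocks of size >= _LOOP_MIN use
per-block LAPACK Cholesky inversion (dpotrf/dpotri, ~n^3 flops); smaller
blocks use numpy's batched cholesky/inv to avoid Python-loop overhead.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import lapack

_LOG_2PI = float(np.log(2.0 * np.pi))
_PENALTY = 1e10
_LOOP_MIN = 128


class _Group:
    """All pedigree blocks of one common size n, batched.

    ``KB`` holds the matrix stacks in block-major layout (B, 7, n*n) so
    that covariance composition and gradient contraction are contiguous
    batched matmuls.
    """

    def __init__(self, stacks: list[np.ndarray], ys: list[np.ndarray]):
        self.B = len(ys)
        self.n = ys[0].shape[0]
        m = self.n * self.n
        self.KB = np.empty((self.B, 7, m))
        for b, st in enumerate(stacks):
            self.KB[b] = st.reshape(7, m)
        self.y = np.ascontiguousarray(np.stack(ys))  # (B, n)


class BlockedGaussian:
    """Pooled likelihood over pedigree blocks with analytic gradients."""

    def __init__(self, stacks: list[np.ndarray], ys: list[np.ndarray]):
        if len(stacks) != len(ys):
            raise ValueError("one phenotype vector per matrix block required")
        by_size: dict[int, tuple[list[np.ndarray], list[np.ndarray]]] = {}
        self.n_total = 0
        for st, y in zip(stacks, ys):
            n = y.shape[0]
            if st.shape != (7, n, n):
                raise ValueError(
                    f"matrix stack shape {st.shape} does not match phenotype length {n}"
                )
            by_size.setdefault(n, ([], []))[0].append(st)
            by_size[n][1].append(np.asarray(y, dtype=float))
            self.n_total += n
        self.groups = [_Group(s, y) for s, y in by_size.values()]
        self._he_cache: tuple[np.ndarray, np.ndarray] | None = None

    @classmethod
    def from_components(cls, mats, ys: list[np.ndarray]) -> "BlockedGaussian":
        """Build directly from ComponentMatrices blocks without intermediate
        per-block stacks (avoids one full copy of the matrix data)."""
        self = cls.__new__(cls)
        self.n_total = 0
        self._he_cache = None
        by_size: dict[int, tuple[list, list[np.ndarray]]] = {}
        for block, y in zip(mats, ys):
            n = y.shape[0]
            if block.n != n:
                raise ValueError(
                    f"block {block.pedigree_id!r} size {block.n} does not match "
                    f"phenotype length {n}"
                )
            by_size.setdefault(n, ([], []))[0].append(block)
            by_size[n][1].append(np.asarray(y, dtype=float))
            self.n_total += n
        self.groups = []
        for n, (blocks, ys_n) in by_size.items():
            g = _Group.__new__(_Group)
            g.B = len(blocks)
            g.n = n
            m = n * n
            g.KB = np.empty((g.B, 7, m))
            for b, block in enumerate(blocks):
                for i, mat in enumerate(
                    (block.A, block.I_AA, block.M, block.J, block.C_F, block.C_E)
                ):
                    g.KB[b, i] = mat.reshape(-1)
                eye = g.KB[b, 6].reshape(n, n)
                eye[:] = 0.0
                np.fill_diagonal(eye, 1.0)
            g.y = np.ascontiguousarray(np.stack(ys_n))
            self.groups.append(g)
        return self

    # -- moment (Haseman-Elston) start ------------------------------------
    def he_crossproducts(self) -> tuple[np.ndarray, np.ndarray]:
        """Gram matrix G_kl = sum_f <K_k, K_l> and b_k = sum_f y'K_k y (cached)."""
        if self._he_cache is not None:
            return self._he_cache
        G = np.zeros((7, 7))
        b = np.zeros(7)
        for g in self.groups:
            G += np.matmul(g.KB, g.KB.transpose(0, 2, 1)).sum(axis=0)
            outer = (g.y[:, :, None] * g.y[:, None, :]).reshape(g.B, -1, 1)
            b += np.matmul(g.KB, outer)[:, :, 0].sum(axis=0)
        self._he_cache = (G, b)
        return G, b

    def he_estimate(self, free_idx: np.ndarray, fixed: np.ndarray) -> np.ndarray:
        """Least-squares regression of y y' on the component matrices.

        Solves min_c || sum_f (y_f y_f' - Sigma_f(c)) ||_F^2 over the free
        components with the fixed components held at their given values.
        A consistent estimator; used as the deterministic optimizer start.
        """
        G, b = self.he_crossproducts()
        b = b - G @ fixed
        Gff = G[np.ix_(free_idx, free_idx)]
        bf = b[free_idx]
        try:
            sol = np.linalg.solve(Gff, bf)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(Gff, bf, rcond=None)[0]
        return sol

    # -- likelihood --------------------------------------------------------
    def neg2ll(self, weights: np.ndarray) -> float:
        return self.neg2ll_grad(weights)[0]

    def neg2ll_grad(self, weights: np.ndarray) -> tuple[float, np.ndarray]:
        """-2 log-likelihood and its gradient w.r.t. the 7 component weights.

        Returns a large finite penalty (with a descent direction built from
        the most negative eigenvalue) when any block covariance is not
        positive definite, keeping line searches inside the PD region.
        """
        f = 0.0
        grad = np.zeros(7)
        for g in self.groups:
            sigma = np.matmul(weights, g.KB).reshape(g.B, g.n, g.n)
            if g.n >= _LOOP_MIN:
                res = self._eval_group_loop(g, sigma)
            else:
                res = self._eval_group_batch(g, sigma)
            if res is None:
                return self._penalty(weights, g)
            logdet, quad, W = res
            f += g.B * g.n * _LOG_2PI + logdet + quad
            grad += np.matmul(g.KB, W.reshape(g.B, -1, 1))[:, :, 0].sum(axis=0)
        return f, grad

    @staticmethod
    def _eval_group_batch(g: _Group, sigma: np.ndarray):
        try:
            L = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return None
        logdet = 2.0 * float(np.log(np.diagonal(L, axis1=1, axis2=2)).sum())
        S = np.linalg.inv(sigma)
        alpha = np.einsum("bij,bj->bi", S, g.y)
        quad = float(np.einsum("bi,bi->", alpha, g.y))
        W = S
        W -= alpha[:, :, None] * alpha[:, None, :]
        return logdet, quad, W

    @staticmethod
    def _eval_group_loop(g: _Group, sigma: np.ndarray):
        logdet = 0.0
        quad = 0.0
        W = sigma  # reuse the buffer; overwritten block by block
        for b in range(g.B):
            c, info = lapack.dpotrf(sigma[b], lower=1, overwrite_a=0)
            if info != 0:
                return None
            logdet += 2.0 * float(np.log(np.diag(c)).sum())
            inv, info = lapack.dpotri(c, lower=1, overwrite_c=1)
            if info != 0:
                return None
            S = np.tril(inv) + np.tril(inv, -1).T
            alpha = S @ g.y[b]
            quad += float(alpha @ g.y[b])
            S -= np.outer(alpha, alpha)
            W[b] = S
        return logdet, quad, W

    def _penalty(self, weights, g: _Group) -> tuple[float, np.ndarray]:
        """Finite barrier outside the PD region, sloped along the most
        negative eigenvalue across the group's blocks."""
        sigma = np.matmul(weights, g.KB).reshape(g.B, g.n, g.n)
        worst = 0.0
        worst_vec = None
        worst_b = 0
        for b in range(g.B):
            lam, vec = np.linalg.eigh(sigma[b])
            if lam[0] < worst:
                worst = float(lam[0])
                worst_vec = vec[:, 0]
                worst_b = b
        f = _PENALTY * (1.0 - worst)
        grad = np.zeros(7)
        if worst_vec is not None:
            K = g.KB[worst_b].reshape(7, g.n, g.n)
            grad = -_PENALTY * np.einsum("i,kij,j->k", worst_vec, K, worst_vec)
        return f, grad

    def total_variance(self) -> float:
        """Pooled phenotypic second moment (zero-mean convention)."""
        return float(
            sum(np.sum(g.y**2) for g in self.groups) / max(self.n_total, 1)
        )
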