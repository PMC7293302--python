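"""Dimensionality reduction: truncated SVD, a hierarchical block variant,
and a centered-PCA baseline.

For a data matrix A with singular value decomposition A = U S V*, the
rank-k truncation A_k = sum_{i<=k} s_i u_i v_i* is the optimal rank-k
approximation (Eckart-Young), with spectral error equal to s_{k+1}.
Truncated SVD here operates on the *uncentered* matrix (the standard
truncated-SVD convention, suited to sparse nonnegative-ish codings);
the PCA baseline mean-centers first.  Both are contrasted as distinct
baselines in the benchmark.

The hierarchical reducer (t-SVDh) treats the chemical-fingerprint and
expression blocks of a fused matrix as separate sub-domains: each block
gets its own truncated SVD retaining a target fraction (default 95%) of
its squared-singular-value mass, and the reduced blocks are concatenated,
chemical components first.  On the real 166 + 964 resource this yields a
57-dimensional space (17 chemical + 40 expression components).

Determinism: singular vectors are sign-fixed (the largest-magnitude entry
of each right-singular vector is made positive; ties broken by the lowest
index) so repeated fits are bit-stable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .datatypes import FusedMatrix
from .exceptions import ValidationError


@dataclass
class SVDFactorization:
    """Truncated SVD factors of one matrix (or block)."""

    U: np.ndarray                 # (N, k)
    singular_values: np.ndarray   # (k,), nonincreasing
    V: np.ndarray                 # (d, k), orthonormal columns
    k: int
    rank: int                     # numerical rank of the input
    variance_retained: float      # share of squared singular mass kept
    centered: bool = False
    full_spectrum: np.ndarray = None  # all singular values of the input

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.V

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) @ self.V.T


def components_for_variance(singular_values: np.ndarray, threshold: float = 0.95) -> int:
    """Smallest k whose leading squared singular values reach ``threshold``
    of the total squared mass."""
    if not 0.0 < threshold <= 1.0:
        raise ValidationError("variance threshold must lie in (0, 1]")
    s = np.asarray(singular_values, dtype=float)
    if s.size == 0:
        raise ValidationError("empty spectrum")
    if np.any(np.diff(s) > 1e-12 * max(s[0], 1.0)):
        raise ValidationError("spectrum must be nonincreasing")
    energy = np.cumsum(s**2) / np.sum(s**2)
    if threshold >= 1.0:
        # full numerical rank
        tol = s[0] * max(s.size, 1) * np.finfo(float).eps
        return int(np.sum(s > tol))
    return int(np.searchsorted(energy, threshold - 1e-12) + 1)


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make the largest-|entry| of each V column positive (first index wins
    ties) and flip the matching U column to preserve the product."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, V * signs


class TruncatedSVDReducer(TransformerMixin, BaseEstimator):
    """Truncated SVD of an uncentered matrix.

    Exactly one of ``k`` and ``variance_target`` selects the number of
    retained components; ``k`` exceeding the numerical rank is clamped
    with a warning.  The full spectrum is computed (matrix sizes here make
    that affordable) so variance retention is exact rather than estimated.
    """

    def __init__(self, k: int | None = None, variance_target: float | None = None):
        self.k = k
        self.variance_target = variance_target

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.size == 0:
            raise ValidationError("X must be a nonempty 2-D matrix")
        if not np.any(X):
            raise ValidationError("X is identically zero")
        if (self.k is None) == (self.variance_target is None):
            raise ValidationError("specify exactly one of k and variance_target")
        U, s, Vt = scipy.linalg.svd(X, full_matrices=False)
        tol = s[0] * max(X.shape) * np.finfo(float).eps
        rank = int(np.sum(s > tol))
        if self.k is not None:
            k = int(self.k)
            if k > min(X.shape):
                raise ValidationError(f"k={k} exceeds min(N, d)={min(X.shape)}")
            if k > rank:
                warnings.warn(
                    f"k={k} exceeds numerical rank {rank}; clamping", stacklevel=2
                )
                k = rank
        else:
            k = components_for_variance(s, self.variance_target)
        U, V = _fix_signs(U[:, :k], Vt[:k].T)
        self.factorization_ = SVDFactorization(
            U=U,
            singular_values=s[:k].copy(),
            V=V,
            k=k,
            rank=rank,
            variance_retained=float(np.sum(s[:k] ** 2) / np.sum(s**2)),
            centered=False,
            full_spectrum=s.copy(),
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        self._check_width(X)
        return self.factorization_.transform(X)

    def inverse_transform(self, Z):
        Z = np.asarray(Z, dtype=float)
        if Z.shape[-1] != self.factorization_.k:
            raise ValidationError(
                f"expected {self.factorization_.k} reduced columns, got {Z.shape[-1]}"
            )
        return self.factorization_.inverse_transform(Z)

    def _check_width(self, X):
        X = np.asarray(X)
        if X.shape[-1] != self.n_features_in_:
            raise ValidationError(
                f"expected {self.n_features_in_} columns, got {X.shape[-1]}"
            )


def fit_tsvd(
    X: np.ndarray, k: int | None = None, variance_target: float | None = None
) -> SVDFactorization:
    """Functional wrapper over :class:`TruncatedSVDReducer`."""
    return TruncatedSVDReducer(k=k, variance_target=variance_target).fit(X).factorization_


class HierarchicalTSVD(TransformerMixin, BaseEstimator):
    """Per-block truncated SVD with variance retention (t-SVDh).

    Parameters
    ----------
    variance_threshold : float, default 0.95
        Squared-singular-mass fraction retained in *each* block.
    n_chemical : int
        Width of the leading (chemical fingerprint) block; the remaining
        columns form the expression block.
    """

    block_names = ("chemical", "expression")

    def __init__(self, variance_threshold: float = 0.95, n_chemical: int = 0):
        self.variance_threshold = variance_threshold
        self.n_chemical = n_chemical

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        b = int(self.n_chemical)
        if not 0 < b < X.shape[1]:
            raise ValidationError(
                "both blocks must be nonempty: 0 < n_chemical < n_features"
            )
        self.block_boundaries_ = {"chemical": (0, b), "expression": (b, X.shape[1])}
        self.block_factorizations_ = []
        for name in self.block_names:
            lo, hi = self.block_boundaries_[name]
            block = X[:, lo:hi]
            if not np.any(block):
                raise ValidationError(f"{name} block is all zeros")
            self.block_factorizations_.append(
                fit_tsvd(block, variance_target=self.variance_threshold)
            )
        ks = [f.k for f in self.block_factorizations_]
        edges = np.concatenate([[0], np.cumsum(ks)])
        self.reduced_boundaries_ = {
            name: (int(edges[i]), int(edges[i + 1]))
            for i, name in enumerate(self.block_names)
        }
        self.total_k_ = int(edges[-1])
        self.n_features_in_ = X.shape[1]
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_features_in_:
            raise ValidationError(
                f"expected {self.n_features_in_} columns, got {X.shape[-1]}"
            )
        parts = []
        for name, fac in zip(self.block_names, self.block_factorizations_):
            lo, hi = self.block_boundaries_[name]
            parts.append(fac.transform(X[:, lo:hi]))
        return np.hstack(parts)

    def inverse_transform(self, Z):
        Z = np.asarray(Z, dtype=float)
        if Z.shape[-1] != self.total_k_:
            raise ValidationError(
                f"expected {self.total_k_} reduced columns, got {Z.shape[-1]}"
            )
        parts = []
        for name, fac in zip(self.block_names, self.block_factorizations_):
            lo, hi = self.reduced_boundaries_[name]
            parts.append(fac.inverse_transform(Z[..., lo:hi]))
        return np.hstack(parts)

    def block_of_dimension(self, dim: int) -> str:
        """Which original block a reduced dimension belongs to."""
        for name, (lo, hi) in self.reduced_boundaries_.items():
            if lo <= dim < hi:
                return name
        raise ValidationError(f"reduced dimension {dim} out of range")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": "tsvdh",
            "variance_threshold": self.variance_threshold,
            "n_chemical": self.n_chemical,
            "blocks": [
                {
                    "name": name,
                    "V": fac.V.tolist(),
                    "singular_values": fac.singular_values.tolist(),
                    "k": fac.k,
                    "rank": fac.rank,
                    "variance_retained": fac.variance_retained,
                }
                for name, fac in zip(self.block_names, self.block_factorizations_)
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, payload: dict) -> "HierarchicalTSVD":
        self = cls(
            variance_threshold=payload["variance_threshold"],
            n_chemical=payload["n_chemical"],
        )
        self.block_factorizations_ = []
        widths = []
        for blk in payload["blocks"]:
            V = np.asarray(blk["V"], dtype=float)
            widths.append(V.shape[0])
            self.block_factorizations_.append(
                SVDFactorization(
                    U=None,
                    singular_values=np.asarray(blk["singular_values"]),
                    V=V,
                    k=blk["k"],
                    rank=blk["rank"],
                    variance_retained=blk["variance_retained"],
                )
            )
        b = int(payload["n_chemical"])
        total = sum(widths)
        self.block_boundaries_ = {"chemical": (0, b), "expression": (b, total)}
        ks = [f.k for f in self.block_factorizations_]
        edges = np.concatenate([[0], np.cumsum(ks)])
        self.reduced_boundaries_ = {
            name: (int(edges[i]), int(edges[i + 1]))
            for i, name in enumerate(cls.block_names)
        }
        self.total_k_ = int(edges[-1])
        self.n_features_in_ = total
        return self

    @classmethod
    def load(cls, path) -> "HierarchicalTSVD":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_hierarchical(fused: FusedMatrix, threshold: float = 0.95) -> HierarchicalTSVD:
    """Fit t-SVDh on a fused matrix, taking the block split from it."""
    return HierarchicalTSVD(
        variance_threshold=threshold, n_chemical=fused.n_chemical
    ).fit(fused.X)


class PCAReducer(TransformerMixin, BaseEstimator):
    """Mean-centered principal-component baseline with the same
    transform/inverse contract as the SVD reducers (delegates to
    :class:`sklearn.decomposition.PCA`)."""

    def __init__(self, k: int = 2):
        self.k = k

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.pca_ = PCA(n_components=self.k, svd_solver="full").fit(X)
        self.singular_values_ = self.pca_.singular_values_.copy()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return self.pca_.transform(np.asarray(X, dtype=float))

    def inverse_transform(self, Z):
        return self.pca_.inverse_transform(np.asarray(Z, dtype=float))


def fit_pca(X: np.ndarray, k: int) -> PCAReducer:
    return PCAReducer(k=k).fit(X)
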