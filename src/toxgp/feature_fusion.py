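"""Fusing the fingerprint and expression blocks and splitting train/test.

The design matrix concatenates the chemical fingerprint block first and
the ternary expression block second (166 + 964 = 1,130 columns for the
real resource).  The held-out test set can be chosen uniformly at random
or as *divergent* compounds: an iterative farthest-point selection in
Tanimoto distance on the fingerprint block, so the test compounds are the
chemically most dissimilar from everything else — the stricter, more
realistic evaluation regime for a toxicity model.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .datatypes import FusedMatrix, MatchedDataset, SplitIndices
from .exceptions import ValidationError


def fuse_features(dataset: MatchedDataset) -> FusedMatrix:
    """Concatenate ``[fingerprints | expression]`` into one real matrix."""
    fp = dataset.fingerprints.to_numpy(dtype=float)
    expr = dataset.expression.to_numpy(dtype=float)
    if fp.shape[0] != expr.shape[0]:
        raise ValidationError(
            f"misaligned blocks: {fp.shape[0]} fingerprint vs "
            f"{expr.shape[0]} expression rows"
        )
    X = np.hstack([fp, expr])
    names = [str(c) for c in dataset.fingerprints.columns] + [
        str(c) for c in dataset.expression.columns
    ]
    return FusedMatrix(
        X=X,
        n_chemical=fp.shape[1],
        n_expression=expr.shape[1],
        feature_names=names,
        compounds=list(dataset.compounds),
    )


def tanimoto_distance_matrix(bits: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto (Jaccard) distances between binary rows."""
    bits = np.asarray(bits, dtype=bool)
    if bits.shape[0] < 2:
        return np.zeros((bits.shape[0], bits.shape[0]))
    return squareform(pdist(bits, metric="jaccard"))


def divergent_split(
    fused: FusedMatrix,
    test_fraction: float = 0.2,
    strategy: str = "divergent",
    seed: int = 0,
) -> SplitIndices:
    """Hold out ``round(test_fraction * N)`` rows for testing.

    strategy="divergent"
        Farthest-point sampling in Tanimoto distance on the fingerprint
        block: start from the compound with maximal mean distance to all
        others, then repeatedly add the compound maximizing its minimum
        distance to the already-chosen set.  Falls back to Euclidean
        distance (with a warning) when any fingerprint row is all zeros,
        where Tanimoto is undefined.
    strategy="random"
        Uniform sampling without replacement, seeded.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError("test_fraction must lie in (0, 1)")
    n = fused.N
    n_test = int(round(test_fraction * n))
    if not 0 < n_test < n:
        raise ValidationError(f"test size {n_test} infeasible for N={n}")

    if strategy == "random":
        rng = np.random.default_rng(seed)
        test = np.sort(rng.choice(n, size=n_test, replace=False))
    elif strategy == "divergent":
        bits = fused.block("chemical")
        if bits.shape[1] == 0 or (bits.sum(axis=1) == 0).any():
            warnings.warn(
                "all-zero fingerprint rows: Tanimoto distance undefined, "
                "falling back to Euclidean distance on the fingerprint block",
                stacklevel=2,
            )
            dist = cdist(bits, bits, metric="euclidean")
        else:
            dist = tanimoto_distance_matrix(bits)
        chosen = [int(np.argmax(dist.mean(axis=1)))]
        remaining = set(range(n)) - set(chosen)
        while len(chosen) < n_test:
            rem = np.array(sorted(remaining))
            min_to_chosen = dist[np.ix_(rem, chosen)].min(axis=1)
            nxt = int(rem[np.argmax(min_to_chosen)])
            chosen.append(nxt)
            remaining.discard(nxt)
        test = np.sort(np.array(chosen))
    else:
        raise ValidationError(f"unknown split strategy {strategy!r}")

    train = np.setdiff1d(np.arange(n), test)
    return SplitIndices(train=train, test=test, strategy=strategy, seed=seed)


def nearest_neighbor_distance(
    fused: FusedMatrix, split: SplitIndices
) -> float:
    """Mean over test compounds of the Tanimoto distance to their nearest
    training compound — a measure of how divergent the held-out set is."""
    bits = fused.block("chemical").astype(bool)
    d = cdist(bits[split.test], bits[split.train], metric="jaccard")
    return float(d.min(axis=1).mean())
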