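"""Shared container types for the toxicity-prediction pipeline.

Tables of perturbation signatures, fingerprints and toxicity records are
plain :class:`pandas.DataFrame` objects (see :mod:`toxgp.io_ingest` for the
column conventions); the dataclasses here carry the row-aligned, matched
dataset and the fused design matrix with its block bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MatchedDataset:
    """One row per compound, aligned across modalities.

    Attributes
    ----------
    compounds : list of str
        Compound identifiers, defining row order for every component.
    expression : pandas.DataFrame, shape (N, G)
        Ternary (-1/0/+1) expression signatures, indexed by compound.
    fingerprints : pandas.DataFrame, shape (N, B)
        Binary structural fingerprints, indexed by compound.
    targets : pandas.Series, length N
        Blood-urea-nitrogen level in mg/dl per compound.
    ood_labels : numpy.ndarray of bool, optional
        True where a compound was generated out-of-distribution.
    """

    compounds: list[str]
    expression: pd.DataFrame
    fingerprints: pd.DataFrame
    targets: pd.Series
    ood_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.compounds)
        if len(set(self.compounds)) != n:
            raise ValueError("duplicate compound ids in MatchedDataset")
        for name, comp in (
            ("expression", self.expression),
            ("fingerprints", self.fingerprints),
            ("targets", self.targets),
        ):
            if len(comp) != n:
                raise ValueError(
                    f"{name} has {len(comp)} rows, expected {n} (one per compound)"
                )

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def n_bits(self) -> int:
        return self.fingerprints.shape[1]

    def subset(self, indices) -> "MatchedDataset":
        """Row-subset the dataset (positional indices)."""
        idx = np.asarray(indices)
        return MatchedDataset(
            compounds=[self.compounds[i] for i in idx],
            expression=self.expression.iloc[idx],
            fingerprints=self.fingerprints.iloc[idx],
            targets=self.targets.iloc[idx],
            ood_labels=None if self.ood_labels is None else self.ood_labels[idx],
        )


@dataclass
class MatchReport:
    """Bookkeeping from cross-source compound matching."""

    n_signatures: int
    n_fingerprints: int
    n_toxicity: int
    n_matched: int
    dropped_signature_ids: list[str] = field(default_factory=list)
    dropped_fingerprint_ids: list[str] = field(default_factory=list)
    dropped_toxicity_ids: list[str] = field(default_factory=list)


@dataclass
class FusedMatrix:
    """Design matrix of concatenated fingerprint and expression blocks.

    Chemical (fingerprint) columns come first, then expression columns,
    matching the reduced-space convention in which the leading dimensions
    represent chemical features.
    """

    X: np.ndarray
    n_chemical: int
    n_expression: int
    feature_names: list[str]
    compounds: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[1] != self.n_chemical + self.n_expression:
            raise ValueError(
                f"X has {self.X.shape[1]} columns, expected "
                f"{self.n_chemical} + {self.n_expression}"
            )
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def block_boundaries(self) -> dict[str, tuple[int, int]]:
        """Half-open column ranges of the two blocks."""
        b = self.n_chemical
        return {"chemical": (0, b), "expression": (b, b + self.n_expression)}

    def block(self, name: str) -> np.ndarray:
        lo, hi = self.block_boundaries[name]
        return self.X[:, lo:hi]


@dataclass
class SplitIndices:
    """Train/test row partition of a fused matrix."""

    train: np.ndarray
    test: np.ndarray
    strategy: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=int)
        self.test = np.asarray(self.test, dtype=int)
        if np.intersect1d(self.train, self.test).size:
            raise ValueError("train and test indices overlap")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# strategy={self.strategy} seed={self.seed}\n")
            fh.write("train\t" + ",".join(map(str, self.train)) + "\n")
            fh.write("test\t" + ",".join(map(str, self.test)) + "\n")

    @classmethod
    def load(cls, path) -> "SplitIndices":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ")
            meta = dict(tok.split("=") for tok in header.split())
            rows = dict(line.strip().split("\t") for line in fh if line.strip())
        seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
        return cls(
            train=np.array([int(i) for i in rows["train"].split(",") if i != ""]),
            test=np.array([int(i) for i in rows["test"].split(",") if i != ""]),
            strategy=meta.get("strategy", "unknown"),
            seed=seed,
        )
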