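"""Feature-importance analysis.

Two complementary routes from a fitted pipeline back to interpretable
features:

* an extremely-randomized-trees ensemble fitted on the raw fused matrix
  gives impurity-decrease importances per original feature, from which
  per-modality shares (chemical vs expression) and the count of
  significantly contributing features are derived;
* the ARD length scales of the GP rank *reduced* dimensions by influence
  (shortest scale = largest influence); an inverse projection — switching
  on a single reduced dimension and mapping the unit vector back through
  the block's right-singular vectors — expresses that dimension as
  contributions over the original features of its block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor

from .datatypes import FusedMatrix
from .dimred import HierarchicalTSVD
from .exceptions import ValidationError
from .gp_model import GaussianProcessRegressorARD

SIGNIFICANCE_THRESHOLD = 4e-9


@dataclass
class ImportanceReport:
    """Normalized per-feature importances over the fused feature space."""

    importances: np.ndarray          # length d, >= 0, sums to 1
    feature_names: list[str]
    n_chemical: int
    cumulative: np.ndarray           # sorted descending, cumulative sums
    modality_shares: tuple[float, float]  # (chemical, expression)
    n_significant: int
    significance_threshold: float

    def to_frame(self) -> pd.DataFrame:
        block = ["chemical"] * self.n_chemical + ["expression"] * (
            len(self.feature_names) - self.n_chemical
        )
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "block": block,
                "importance": self.importances,
            }
        )


@dataclass
class DimensionAttribution:
    """One reduced dimension expressed over its block's original features."""

    dimension: int
    block: str
    length_scale: float
    contributions: np.ndarray        # length d (zero outside the block)
    feature_names: list[str]
    selected: list[tuple[str, float]]  # |contribution| > threshold
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.feature_names, "contribution": self.contributions}
        )


def tree_importance(
    fused: FusedMatrix,
    y,
    n_trees: int = 500,
    seed: int = 0,
    significance_threshold: float = SIGNIFICANCE_THRESHOLD,
) -> ImportanceReport:
    """Impurity-decrease importances from an extremely randomized forest
    on the raw fused features (model-agnostic: does not involve the GP)."""
    y = np.asarray(y, dtype=float).ravel()
    if fused.N < 10:
        raise ValidationError("need at least 10 datapoints for importances")
    if np.std(y) == 0:
        raise ValidationError("target is constant; importances undefined")
    forest = ExtraTreesRegressor(n_estimators=n_trees, random_state=seed)
    forest.fit(fused.X, y)
    imp = forest.feature_importances_.astype(float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    shares = modality_share(imp, fused.n_chemical)
    return ImportanceReport(
        importances=imp,
        feature_names=list(fused.feature_names),
        n_chemical=fused.n_chemical,
        cumulative=np.cumsum(np.sort(imp)[::-1]),
        modality_shares=shares,
        n_significant=int(np.sum(imp > significance_threshold)),
        significance_threshold=significance_threshold,
    )


def modality_share(importances: np.ndarray, n_chemical: int) -> tuple[float, float]:
    """Block-wise sums of normalized importances: (chemical, expression)."""
    imp = np.asarray(importances, dtype=float)
    total = imp.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValidationError("importances must be normalized to sum to 1")
    chem = float(imp[:n_chemical].sum())
    return chem, float(total - chem)


def attribute_dimension(
    reducer: HierarchicalTSVD,
    model: GaussianProcessRegressorARD,
    which: str = "shortest_overall",
    block: str | None = None,
    threshold: float = 0.5,
    feature_names: list[str] | None = None,
) -> DimensionAttribution:
    """Inverse-project the most influential reduced dimension.

    The target dimension is the one with the shortest ARD length scale,
    either over the whole reduced space (``which="shortest_overall"``) or
    restricted to one block (``which="shortest_in_block"`` with ``block``
    in {"chemical", "expression"}).  Its reduced-space unit vector is
    mapped back to the full feature space; contributions are confined to
    the owning block by construction, and features with
    |contribution| > ``threshold`` are flagged.
    """
    ranking = model.length_scale_ranking()
    if model.n_features_in_ != reducer.total_k_:
        raise ValidationError(
            "GP was not fitted on this reducer's output space "
            f"({model.n_features_in_} vs {reducer.total_k_} dimensions)"
        )
    if which == "shortest_overall":
        dim, scale = ranking[0]
    elif which == "shortest_in_block":
        if block not in reducer.reduced_boundaries_:
            raise ValidationError(f"unknown block {block!r}")
        lo, hi = reducer.reduced_boundaries_[block]
        if hi == lo:
            raise ValidationError(f"block {block!r} has zero reduced dimensions")
        in_block = [(d, s) for d, s in ranking if lo <= d < hi]
        dim, scale = in_block[0]
    else:
        raise ValidationError(f"unknown selection rule {which!r}")

    unit = np.zeros(reducer.total_k_)
    unit[dim] = 1.0
    contributions = reducer.inverse_transform(unit[None, :])[0]
    owning = reducer.block_of_dimension(dim)
    if feature_names is None:
        names = [f"f{i}" for i in range(contributions.size)]
    else:
        if len(feature_names) != contributions.size:
            raise ValidationError("feature_names length mismatch")
        names = list(feature_names)
    selected = [
        (names[i], float(contributions[i]))
        for i in np.argsort(-np.abs(contributions))
        if abs(contributions[i]) > threshold
    ]
    return DimensionAttribution(
        dimension=int(dim),
        block=owning,
        length_scale=float(scale),
        contributions=contributions,
        feature_names=names,
        selected=selected,
        threshold=threshold,
    )
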