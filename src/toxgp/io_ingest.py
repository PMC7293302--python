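"""Reading, validating and matching the three input tables.

The pipeline consumes three CSV sources (gzip transparently supported):

* a signature matrix — one row per perturbation (compound x cell line x
  dose x duration) with G ternary gene columns coded -1/0/+1 for
  down-regulation / no change / up-regulation;
* a fingerprint matrix — one row per compound with B binary substructure
  bits (166 for MACCS keys);
* a toxicity table — compound id and rat blood-urea-nitrogen level (mg/dl),
  optionally with administered dose and duration.

Column names are adapted to arbitrary exports through a ``column_map``
dictionary, so real L1000 / DrugMatrix files can be read without code
changes.  Compound identifiers are normalized (whitespace-trimmed,
case-folded) only at the matching step; no fuzzy or synonym matching is
attempted — unmatched ids are reported as dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import MatchedDataset, MatchReport
from .exceptions import FormatError, MatchError, ValidationError

# canonical annotation column names
SIG_META = ("compound_id", "cell_line", "dose", "duration")
TERNARY = frozenset((-1.0, 0.0, 1.0))

DEFAULT_COLUMN_MAP: dict[str, str] = {
    "compound_id": "compound_id",
    "cell_line": "cell_line",
    "dose": "dose",
    "duration": "duration",
    "bun_level": "bun_level",
}


def _rename(df: pd.DataFrame, column_map: dict[str, str] | None) -> pd.DataFrame:
    if not column_map:
        return df
    inverse = {v: k for k, v in column_map.items()}
    return df.rename(columns=inverse)


def _check_coded(df: pd.DataFrame, columns, allowed: frozenset, what: str) -> None:
    """Validate that every cell of ``columns`` lies in ``allowed``; name the
    offending row/column in the error."""
    values = df[list(columns)].to_numpy(dtype=float, copy=False)
    ok = np.isin(values, list(allowed))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValidationError(
            f"non-{what} value {values[i, j]!r} at row {df.index[i]}, "
            f"column {list(columns)[j]!r}"
        )


def read_signature_matrix(
    path, column_map: dict[str, str] | None = None, delimiter: str = ","
) -> pd.DataFrame:
    """Read a perturbation-signature table.

    Returns a DataFrame with the four annotation columns (``compound_id``,
    ``cell_line``, ``dose``, ``duration``) followed by the G gene columns in
    file order; gene values are validated to be exactly -1, 0 or +1.
    A header-only file yields an empty table with G inferred from the header.
    """
    df = _rename(pd.read_csv(path, sep=delimiter), column_map)
    missing = [c for c in SIG_META if c not in df.columns]
    if missing:
        raise FormatError(f"signature file {path} lacks annotation columns {missing}")
    gene_cols = [c for c in df.columns if c not in SIG_META]
    df = df[list(SIG_META) + gene_cols]
    if len(df):
        _check_coded(df, gene_cols, TERNARY, "ternary")
        df[gene_cols] = df[gene_cols].astype(np.int8)
    return df


def write_signature_matrix(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    df.to_csv(path, sep=delimiter, index=False)


def read_fingerprint_matrix(
    path, column_map: dict[str, str] | None = None, delimiter: str = ","
) -> pd.DataFrame:
    """Read a fingerprint bit matrix: ``compound_id`` plus B binary columns.

    All-zero rows are legal (a sparse fingerprint), as are all-zero bits.
    """
    df = _rename(pd.read_csv(path, sep=delimiter), column_map)
    if "compound_id" not in df.columns:
        raise FormatError(f"fingerprint file {path} lacks a compound_id column")
    bit_cols = [c for c in df.columns if c != "compound_id"]
    df = df[["compound_id"] + bit_cols]
    if len(df):
        _check_coded(df, bit_cols, frozenset((0.0, 1.0)), "binary")
        df[bit_cols] = df[bit_cols].astype(np.int8)
    return df


def write_fingerprint_matrix(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    df.to_csv(path, sep=delimiter, index=False)


def read_toxicity_table(
    path, column_map: dict[str, str] | None = None, delimiter: str = ","
) -> pd.DataFrame:
    """Read compound BUN measurements (mg/dl); duplicates per compound are
    kept here — the deduplication policy lives in :func:`match_compounds`."""
    df = _rename(pd.read_csv(path, sep=delimiter), column_map)
    for col in ("compound_id", "bun_level"):
        if col not in df.columns:
            raise FormatError(f"toxicity file {path} lacks a {col} column")
    bun = pd.to_numeric(df["bun_level"], errors="coerce")
    if bun.isna().any():
        row = df.index[bun.isna()][0]
        raise ValidationError(f"non-numeric BUN level at row {row}")
    if (bun <= 0).any():
        row = df.index[bun <= 0][0]
        raise ValidationError(f"non-positive BUN level at row {row}")
    df = df.copy()
    df["bun_level"] = bun.astype(float)
    return df


def write_toxicity_table(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    df.to_csv(path, sep=delimiter, index=False)


def select_representative(
    signatures: pd.DataFrame, per_cell_line: bool = False
) -> pd.DataFrame:
    """Keep one perturbation per compound: highest dose, then longest
    duration, then first in file order.

    Dose and duration are compared ordinally in whatever units the file
    uses.  With ``per_cell_line`` the rule is applied per
    compound x cell-line pair instead (sensitivity analysis).
    """
    if not len(signatures):
        raise ValidationError("cannot select representatives from an empty table")
    keys = ["compound_id", "cell_line"] if per_cell_line else ["compound_id"]
    df = signatures.reset_index(drop=True).copy()
    df["_ord"] = np.arange(len(df))
    ranked = df.sort_values(
        keys + ["dose", "duration", "_ord"],
        ascending=[True] * len(keys) + [False, False, True],
        kind="mergesort",
    )
    picked = ranked.drop_duplicates(keys, keep="first").sort_values("_ord")
    return picked.drop(columns="_ord").reset_index(drop=True)[signatures.columns]


def normalize_compound_id(cid: str) -> str:
    """Exact-string normalization: trim whitespace and case-fold."""
    return str(cid).strip().casefold()


def match_compounds(
    signatures: pd.DataFrame,
    fingerprints: pd.DataFrame,
    toxicity: pd.DataFrame,
) -> tuple[MatchedDataset, MatchReport]:
    """Intersect compound ids across the three sources and row-align them.

    ``signatures`` must already hold one record per compound (run
    :func:`select_representative` first).  Several BUN records for one
    compound are averaged.  Rows are ordered by normalized compound id, so
    the result is invariant to the row order of every input.
    """
    sig = signatures.copy()
    sig["_cid"] = sig["compound_id"].map(normalize_compound_id)
    if sig["_cid"].duplicated().any():
        raise MatchError(
            "signature table has several records per compound; "
            "apply select_representative first"
        )
    fp = fingerprints.copy()
    fp["_cid"] = fp["compound_id"].map(normalize_compound_id)
    tox = toxicity.copy()
    tox["_cid"] = tox["compound_id"].map(normalize_compound_id)

    ids = [set(t["_cid"]) for t in (sig, fp, tox)]
    common = sorted(ids[0] & ids[1] & ids[2])
    report = MatchReport(
        n_signatures=len(ids[0]),
        n_fingerprints=len(ids[1]),
        n_toxicity=len(ids[2]),
        n_matched=len(common),
        dropped_signature_ids=sorted(ids[0] - set(common)),
        dropped_fingerprint_ids=sorted(ids[1] - set(common)),
        dropped_toxicity_ids=sorted(ids[2] - set(common)),
    )
    if not common:
        raise MatchError(
            "no compound appears in all three sources "
            f"({report.n_signatures} signature, {report.n_fingerprints} "
            f"fingerprint, {report.n_toxicity} toxicity ids)"
        )

    gene_cols = [c for c in sig.columns if c not in SIG_META + ("_cid",)]
    expr = (
        sig.set_index("_cid").loc[common, gene_cols].astype(np.int8)
    )
    bit_cols = [c for c in fp.columns if c not in ("compound_id", "_cid")]
    fps = fp.drop_duplicates("_cid").set_index("_cid").loc[common, bit_cols]
    targets = tox.groupby("_cid")["bun_level"].mean().loc[common]
    targets.name = "bun_level"
    dataset = MatchedDataset(
        compounds=list(common),
        expression=expr,
        fingerprints=fps.astype(np.int8),
        targets=targets,
    )
    return dataset, report


def dose_redundancy_stats(signatures: pd.DataFrame) -> tuple[float, float]:
    """Quantify how similar a compound's ternary profile is across doses.

    For every (compound, gene) pair with at least two dose records, the
    population standard deviation of the ternary value across those records
    is computed.  Returns ``(fraction_zero_sd, mean_sd)``: the share of
    pairs whose SD is exactly zero, and the mean SD over all pairs.
    """
    gene_cols = [c for c in signatures.columns if c not in SIG_META]
    counts = signatures.groupby("compound_id", sort=False).size()
    multi = counts.index[counts >= 2]
    if not len(multi):
        raise ValidationError("no compound has two or more dose records")
    sub = signatures[signatures["compound_id"].isin(multi)]
    sds = (
        sub.groupby("compound_id", sort=False)[gene_cols]
        .std(ddof=0)
        .to_numpy()
        .ravel()
    )
    return float(np.mean(sds == 0.0)), float(sds.mean())
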