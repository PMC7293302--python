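"""Synthetic datasets with the statistical structure the pipeline assumes.

A shared low-rank latent space drives three observation channels per
compound:

* a ternary expression profile — a linear map of the latent vector plus
  private Gaussian noise, ternarized by symmetric per-gene quantile
  thresholds so a configurable fraction of entries is exactly zero;
* a binary fingerprint — Bernoulli draws with logits given by a second
  linear map of the same latent vector;
* a continuous target (blood-urea-nitrogen level, mg/dl) — an affine map of
  a latent projection into a configured range, plus Gaussian noise scaled
  by a signal-to-noise ratio.

Because both feature blocks share the latent factors while carrying
private noise, neither block alone identifies the target as well as their
combination — the structure required for a combination experiment to be
meaningful.  Ground truth (latent factors, loadings, noise levels) is
returned alongside and is never consumed by the pipeline under test.

The generator makes no attempt to mimic real L1000 gene-gene correlation
or MACCS bit semantics; see the methods note for what passing tests on
this data do and do not show.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MatchedDataset
from .exceptions import ValidationError


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study.

    Defaults emulate the real resource: 964 landmark genes, 166 fingerprint
    bits, ~70% zeros in the ternary profiles, targets spanning
    7.75-39.60 mg/dl, and a dose-flip probability giving ~90% dose-invariant
    (compound, gene) pairs at two doses.
    """

    n_compounds: int = 200
    n_genes: int = 964
    n_bits: int = 166
    latent_rank: int = 10
    expression_sparsity: float = 0.7
    signal_to_noise: float = 5.0
    target_range: tuple[float, float] = (7.75, 39.60)
    dose_flip_prob: float = 0.05
    seed: int = 0
    expression_noise_sd: float = 0.5
    fingerprint_logit_scale: float = 1.5
    # each modality observes only this fraction of the latent dimensions
    # (expression the leading ones, chemistry the trailing ones, with
    # overlap), so neither block alone carries the full target signal
    block_latent_fraction: float = 0.7
    # fraction of genes / bits with nonzero latent loadings; the rest are
    # pure noise channels, as most landmark genes do not respond to a
    # given compound
    informative_genes_fraction: float = 0.3
    informative_bits_fraction: float = 0.6

    def __post_init__(self) -> None:
        low, high = self.target_range
        if not low < high:
            raise ValidationError("target_range must satisfy low < high")
        if not 0.0 < self.expression_sparsity < 1.0:
            raise ValidationError("expression_sparsity must lie in (0, 1)")
        if self.latent_rank >= min(self.n_genes, self.n_bits, self.n_compounds):
            raise ValidationError(
                "latent_rank must be smaller than every observed dimension"
            )
        if self.signal_to_noise <= 0:
            raise ValidationError("signal_to_noise must be positive")
        if not 0.0 <= self.dose_flip_prob <= 1.0:
            raise ValidationError("dose_flip_prob must lie in [0, 1]")
        for name in ("block_latent_fraction", "informative_genes_fraction",
                     "informative_bits_fraction"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in (0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth stored beside a generated dataset (sidecar only)."""

    latent_factors: np.ndarray            # (n_compounds, latent_rank)
    target_weights: np.ndarray            # (latent_rank,)
    noise_sd_per_compound: np.ndarray     # (n_compounds,)
    expression_loadings: np.ndarray = None  # (latent_rank, n_genes)
    expression_thresholds: np.ndarray = None  # (n_genes,)
    fingerprint_loadings: np.ndarray = None   # (latent_rank, n_bits)
    fingerprint_intercepts: np.ndarray = None  # (n_bits,)
    target_scale: float = 1.0
    target_offset: float = 0.0
    config: GeneratorConfig = None

    def save(self, path) -> None:
        np.savez(
            path,
            latent_factors=self.latent_factors,
            target_weights=self.target_weights,
            noise_sd_per_compound=self.noise_sd_per_compound,
            expression_loadings=self.expression_loadings,
            expression_thresholds=self.expression_thresholds,
            fingerprint_loadings=self.fingerprint_loadings,
            fingerprint_intercepts=self.fingerprint_intercepts,
            target_scale=self.target_scale,
            target_offset=self.target_offset,
        )


def _ternarize(continuous: np.ndarray, sparsity: float) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric per-column quantile thresholding: the ``sparsity`` fraction
    of smallest |values| in each column becomes 0, the rest keeps its sign."""
    absval = np.abs(continuous)
    thresholds = np.quantile(absval, sparsity, axis=0)
    ternary = np.where(absval > thresholds, np.sign(continuous), 0.0)
    return ternary.astype(np.int8), thresholds


def _observe(
    Z: np.ndarray, truth: SyntheticTruth, rng: np.random.Generator, cfg: GeneratorConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Push latent vectors through the frozen observation model."""
    expr_cont = Z @ truth.expression_loadings + cfg.expression_noise_sd * rng.standard_normal(
        (Z.shape[0], cfg.n_genes)
    )
    expression = np.where(
        np.abs(expr_cont) > truth.expression_thresholds, np.sign(expr_cont), 0.0
    ).astype(np.int8)
    logits = cfg.fingerprint_logit_scale * (Z @ truth.fingerprint_loadings) + truth.fingerprint_intercepts
    bits = (rng.random((Z.shape[0], cfg.n_bits)) < 1.0 / (1.0 + np.exp(-logits))).astype(
        np.int8
    )
    clean = truth.target_offset + truth.target_scale * (Z @ truth.target_weights)
    noise_sd = np.std(clean) / cfg.signal_to_noise
    targets = clean + noise_sd * rng.standard_normal(Z.shape[0])
    targets = np.clip(targets, *cfg.target_range)
    return expression, bits, targets


def generate_dataset(config: GeneratorConfig) -> tuple[MatchedDataset, SyntheticTruth]:
    """Draw a matched dataset and its ground truth, reproducible from the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    Z = rng.standard_normal((cfg.n_compounds, cfg.latent_rank))

    # block-specific latent visibility: expression loads on the leading
    # latent dims, chemistry on the trailing ones (overlapping in the
    # middle), so the blocks share structure without either being complete
    r = cfg.latent_rank
    n_vis = max(1, int(np.ceil(cfg.block_latent_fraction * r)))
    expr_dims = np.arange(n_vis)
    fp_dims = np.arange(r - n_vis, r)

    W_expr = rng.standard_normal((r, cfg.n_genes))
    W_expr[np.setdiff1d(np.arange(r), expr_dims), :] = 0.0
    n_info_genes = max(1, int(round(cfg.informative_genes_fraction * cfg.n_genes)))
    noise_genes = rng.permutation(cfg.n_genes)[n_info_genes:]
    W_expr[:, noise_genes] = 0.0

    W_fp = rng.standard_normal((r, cfg.n_bits))
    W_fp[np.setdiff1d(np.arange(r), fp_dims), :] = 0.0
    n_info_bits = max(1, int(round(cfg.informative_bits_fraction * cfg.n_bits)))
    noise_bits = rng.permutation(cfg.n_bits)[n_info_bits:]
    W_fp[:, noise_bits] = 0.0

    b_fp = rng.standard_normal(cfg.n_bits)
    w_y = rng.standard_normal(r)

    # calibrate ternarization thresholds on this draw's continuous values
    expr_cont = Z @ W_expr + cfg.expression_noise_sd * rng.standard_normal(
        (cfg.n_compounds, cfg.n_genes)
    )
    expression, thresholds = _ternarize(expr_cont, cfg.expression_sparsity)

    logits = cfg.fingerprint_logit_scale * (Z @ W_fp) + b_fp
    bits = (rng.random((cfg.n_compounds, cfg.n_bits)) < 1.0 / (1.0 + np.exp(-logits))).astype(
        np.int8
    )

    score = Z @ w_y
    low, high = cfg.target_range
    span = score.max() - score.min()
    if span == 0:
        raise ValidationError("degenerate latent draw: constant target score")
    scale = (high - low) / span
    offset = low - scale * score.min()
    clean = offset + scale * score
    noise_sd = np.std(clean) / cfg.signal_to_noise
    targets = np.clip(clean + noise_sd * rng.standard_normal(cfg.n_compounds), low, high)

    compounds = [f"cmpd_{i:04d}" for i in range(cfg.n_compounds)]
    gene_names = [f"gene_{j:04d}" for j in range(cfg.n_genes)]
    bit_names = [f"bit_{j:03d}" for j in range(cfg.n_bits)]
    dataset = MatchedDataset(
        compounds=compounds,
        expression=pd.DataFrame(expression, index=compounds, columns=gene_names),
        fingerprints=pd.DataFrame(bits, index=compounds, columns=bit_names),
        targets=pd.Series(targets, index=compounds, name="bun_level"),
        ood_labels=np.zeros(cfg.n_compounds, dtype=bool),
    )
    truth = SyntheticTruth(
        latent_factors=Z,
        target_weights=w_y,
        noise_sd_per_compound=np.full(cfg.n_compounds, noise_sd),
        expression_loadings=W_expr,
        expression_thresholds=thresholds,
        fingerprint_loadings=W_fp,
        fingerprint_intercepts=b_fp,
        target_scale=scale,
        target_offset=offset,
        config=cfg,
    )
    return dataset, truth


def flip_prob_for_zero_fraction(zero_fraction: float, n_doses: int) -> float:
    """Invert the dose-series model: with the highest dose fixed to the base
    profile and each of the other ``n_doses - 1`` records flipping
    independently with probability p, a (compound, gene) pair has zero SD
    across doses iff no record flipped, so
    ``zero_fraction = (1 - p) ** (n_doses - 1)``."""
    if n_doses < 2:
        raise ValidationError("need at least two doses")
    if not 0.0 < zero_fraction <= 1.0:
        raise ValidationError("zero_fraction must lie in (0, 1]")
    return 1.0 - zero_fraction ** (1.0 / (n_doses - 1))


def generate_dose_series(
    dataset: MatchedDataset,
    truth: SyntheticTruth,
    n_doses: int = 2,
    flip_prob: float | None = None,
) -> pd.DataFrame:
    """Expand each compound's base profile into a dose series.

    Dose d = n_doses (the highest) reproduces the base profile exactly, so
    representative selection by highest dose recovers the base; every other
    (gene, dose) value flips to one of the two other ternary values with
    probability ``flip_prob`` (default: the generator config's
    ``dose_flip_prob``).
    """
    if n_doses < 2:
        raise ValidationError("a dose series needs n_doses >= 2")
    cfg = truth.config
    if flip_prob is None:
        flip_prob = cfg.dose_flip_prob if cfg is not None else 0.05
    seed = cfg.seed if cfg is not None else 0
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    base = dataset.expression.to_numpy()
    n, g = base.shape
    records = []
    for dose in range(1, n_doses + 1):
        values = base.copy()
        if dose < n_doses:
            flips = rng.random((n, g)) < flip_prob
            # move to one of the two other ternary values, uniformly
            offsets = rng.integers(1, 3, size=(n, g))
            shifted = ((values + 1 + offsets) % 3 - 1).astype(np.int8)
            values = np.where(flips, shifted, values)
        rec = pd.DataFrame(values, columns=dataset.expression.columns)
        rec.insert(0, "duration", 1.0)
        rec.insert(0, "dose", float(dose))
        rec.insert(0, "cell_line", "SYN1")
        rec.insert(0, "compound_id", dataset.compounds)
        records.append(rec)
    return pd.concat(records, ignore_index=True)


def make_outliers(
    dataset: MatchedDataset,
    truth: SyntheticTruth,
    n: int,
    shift: float,
    seed: int = 0,
) -> MatchedDataset:
    """Create ``n`` out-of-distribution compounds.

    Each new latent vector is a fresh standard-normal draw displaced by
    ``shift`` latent standard deviations along a random unit direction, then
    pushed through the same frozen observation model as the in-set
    compounds.  ``shift = 0`` therefore reproduces the in-set distribution.
    """
    if dataset.n_compounds == 0:
        raise ValidationError("dataset is empty")
    cfg = truth.config
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    r = truth.latent_factors.shape[1]
    Z = rng.standard_normal((n, r))
    if shift != 0.0:
        directions = rng.standard_normal((n, r))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        Z = Z + shift * directions
    expression, bits, targets = _observe(Z, truth, rng, cfg)
    compounds = [f"ood_{i:04d}" for i in range(n)]
    return MatchedDataset(
        compounds=compounds,
        expression=pd.DataFrame(
            expression, index=compounds, columns=dataset.expression.columns
        ),
        fingerprints=pd.DataFrame(
            bits, index=compounds, columns=dataset.fingerprints.columns
        ),
        targets=pd.Series(targets, index=compounds, name="bun_level"),
        ood_labels=np.ones(n, dtype=bool),
    )


def write_dataset_csvs(dataset: MatchedDataset, truth: SyntheticTruth, outdir) -> dict:
    """Write the dataset in the CSV dialects the ingest readers consume,
    plus the truth sidecar (which the pipeline never reads)."""
    from pathlib import Path

    from . import io_ingest

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sig = generate_dose_series(dataset, truth, n_doses=2)
    paths = {
        "signatures": outdir / "signatures.csv",
        "fingerprints": outdir / "fingerprints.csv",
        "toxicity": outdir / "toxicity.csv",
        "truth": outdir / "truth.npz",
    }
    io_ingest.write_signature_matrix(sig, paths["signatures"])
    fp = dataset.fingerprints.reset_index(names="compound_id")
    io_ingest.write_fingerprint_matrix(fp, paths["fingerprints"])
    tox = dataset.targets.rename_axis("compound_id").reset_index()
    io_ingest.write_toxicity_table(tox, paths["toxicity"])
    truth.save(paths["truth"])
    return paths
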