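"""Synthetic two-channel microarray data with known ground truth.

The generator emulates the structure of two-dye cervical-tumor microarray
experiments: a genes x samples log2-ratio matrix with balanced
tumor/normal labels, a configurable set of informative genes whose class
means differ by a planted effect, block-correlated gene modules built
from one shared latent factor per block (value = sqrt(rho)*factor +
sqrt(1-rho)*noise, giving within-block correlation rho in expectation),
and missing cells planted uniformly at random.  ``to_two_channel``
inverts log-ratio normalisation to produce a spot table with the
54-feature column layout typical of scanner exports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, REQUIRED_CHANNEL_COLUMNS, TwoChannelTable

__all__ = ["GroundTruth", "generate_dataset", "to_two_channel"]

#: Total feature columns emitted by :func:`to_two_channel`.
N_FEATURE_COLUMNS = 54


@dataclass
class GroundTruth:
    """What was planted: informative genes, module blocks, rates, seed."""

    informative: dict[str, float]     # gene_id -> effect size (log2 shift)
    blocks: list[list[str]]           # disjoint correlated gene groups
    rho: float
    noise_sd: float
    missing_rate: float
    seed: int
    effect_size: float = 0.0

    def to_json(self, path) -> None:
        payload = {
            "informative": self.informative,
            "blocks": self.blocks,
            "rho": self.rho,
            "noise_sd": self.noise_sd,
            "missing_rate": self.missing_rate,
            "effect_size": self.effect_size,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def generate_dataset(
    n_genes: int = 200,
    n_samples: int = 60,
    n_informative: int = 10,
    blocks: tuple[int, ...] = (),
    rho: float = 0.9,
    effect_size: float = 1.5,
    noise_sd: float = 1.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, np.ndarray, GroundTruth]:
    """Simulate a labelled log2-ratio expression matrix.

    ``blocks`` lists the sizes of correlated gene blocks (within-block
    correlation ``rho``); remaining genes are independent.  The first
    ``n_informative`` non-block genes get a class-mean shift of
    ``effect_size`` log2 units on tumor samples (with the default
    ``noise_sd`` of 1.0 this is an effect in SD units).  Labels are
    balanced: the first half of samples normal (0), the second tumor (1).
    """
    if n_informative > n_genes:
        raise ValueError(
            f"n_informative={n_informative} exceeds n_genes={n_genes}"
        )
    if sum(blocks) > n_genes:
        raise ValueError("block sizes exceed n_genes")
    if not 0 <= rho < 1:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if not 0 <= missing_rate < 1:
        raise ValueError(f"missing_rate must be in [0, 1), got {missing_rate}")

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    sample_ids = [f"S{j:03d}" for j in range(n_samples)]
    labels = np.zeros(n_samples, dtype=int)
    labels[n_samples // 2:] = 1

    values = noise_sd * rng.standard_normal((n_genes, n_samples))

    # correlated blocks occupy the tail of the gene list so informative
    # genes (taken from the head) stay independent of the modules
    block_ids: list[list[str]] = []
    g = n_genes
    for size in reversed(blocks):
        g -= size
        factor = rng.standard_normal(n_samples)
        values[g:g + size] = noise_sd * (
            np.sqrt(rho) * factor
            + np.sqrt(1.0 - rho) * rng.standard_normal((size, n_samples))
        )
        block_ids.insert(0, gene_ids[g:g + size])
    if n_informative > g:
        raise ValueError("not enough non-block genes for n_informative")

    informative = {}
    for i in range(n_informative):
        values[i, labels == 1] += effect_size
        informative[gene_ids[i]] = effect_size

    if missing_rate > 0:
        miss = rng.random((n_genes, n_samples)) < missing_rate
        # keep every gene observable at least once
        all_gone = miss.all(axis=1)
        miss[all_gone, 0] = False
        values = values.copy()
        values[miss] = np.nan

    x = ExpressionMatrix(values, gene_ids, sample_ids, labels)
    truth = GroundTruth(
        informative=informative, blocks=block_ids, rho=rho,
        noise_sd=noise_sd, missing_rate=missing_rate, seed=seed,
        effect_size=effect_size,
    )
    return x, labels, truth


def _filler_features(base: pd.DataFrame, n_extra: int) -> pd.DataFrame:
    """Deterministic transforms of the intensity columns as filler features."""
    c1m, c1d = base["CH1_MEAN"], base["CH1_MEDIAN"]
    c2m, c2d = base["CH2_MEAN"], base["CH2_MEDIAN"]
    recipes = [
        ("SUM_MEAN", c1m + c2m),
        ("SUM_MEDIAN", c1d + c2d),
        ("RAT_MEAN", c1m / c2m),
        ("RAT_MEDIAN", c1d / c2d),
        ("LOG_CH1_MEAN", np.log2(c1m)),
        ("LOG_CH2_MEAN", np.log2(c2m)),
        ("DIFF_MEAN", c1m - c2m),
        ("DIFF_MEDIAN", c1d - c2d),
    ]
    cols = {}
    for i in range(n_extra):
        name, series = recipes[i % len(recipes)]
        scale = 1 + i // len(recipes)
        cols[f"F{i + 7:02d}_{name}"] = series * scale
    return pd.DataFrame(cols)


def to_two_channel(
    x: ExpressionMatrix,
    baseline_intensity: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TwoChannelTable:
    """Invert log-ratio normalisation into a two-channel spot table.

    CH2 intensities are drawn log-normally around ``baseline_intensity``;
    CH1 = CH2 * 2^value with multiplicative log2-noise of SD ``noise_sd``.
    The table has the full 54-feature-column layout (six channel
    intensity/background columns plus deterministic filler transforms).
    Missing expression cells become NA intensities.  At zero noise the
    table round-trips through log-ratio normalisation up to per-array
    median centring.
    """
    if baseline_intensity <= 0:
        raise ValueError(
            f"baseline_intensity must be positive, got {baseline_intensity}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for j, sid in enumerate(x.sample_ids):
        for i, gid in enumerate(x.gene_ids):
            value = x.values[i, j]
            ch2 = baseline_intensity * 2.0 ** rng.normal(0.0, 0.25)
            if np.isnan(value):
                ch1 = ch2 = np.nan
            else:
                ch1 = ch2 * 2.0 ** (value + rng.normal(0.0, noise_sd))
            row = {
                "spot_id": f"{sid}_spot{i:04d}",
                "gene_id": gid,
                "sample_id": sid,
                "CH1_MEAN": ch1,
                "CH1_MEDIAN": ch1,
                "CH2_MEAN": ch2,
                "CH2_MEDIAN": ch2,
                "CH1_BG": 0.02 * baseline_intensity,
                "CH2_BG": 0.02 * baseline_intensity,
            }
            rows.append(row)
    base = pd.DataFrame(rows)
    n_extra = N_FEATURE_COLUMNS - len(REQUIRED_CHANNEL_COLUMNS)
    table = pd.concat([base, _filler_features(base, n_extra)], axis=1)
    if x.labels is not None:
        label_of = {sid: ("tumor" if lab else "normal")
                    for sid, lab in zip(x.sample_ids, x.labels)}
        table["label"] = table["sample_id"].map(label_of)
    return TwoChannelTable(table)
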