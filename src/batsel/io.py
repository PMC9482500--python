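"""Reading, writing and normalising two-channel microarray expression data.

Two on-disk formats are supported, both plain tab-delimited text:

``matrix_tsv``
    A genes x samples expression matrix.  First column ``gene_id``, header
    row holds sample identifiers, and an optional second header row (first
    field ``label``) carries per-sample class labels (0 = normal,
    1 = tumor).  Missing values are empty fields or ``NA``.

``two_channel_tsv``
    A long-format spot table for two-dye arrays (Cy5 = CH1, Cy3 = CH2):
    one row per (sample, spot) with named intensity columns ``CH1_MEAN``,
    ``CH1_MEDIAN``, ``CH2_MEAN``, ``CH2_MEDIAN``, background columns
    ``CH1_BG``/``CH2_BG`` and any number of extra per-spot feature columns.

Expression values are log2 ratios of the two channel intensities,
median-centred per array so each sample's median log-ratio is zero.
Missing cells are imputed with the mean of the gene's observed values
among samples of the same class (all samples when no labels are present).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "TwoChannelTable",
    "FormatError",
    "read_expression_table",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_two_channel_tsv",
    "write_two_channel_tsv",
    "log_ratio_normalize",
    "impute_missing",
]

#: Intensity columns that must be present in a two-channel spot table.
REQUIRED_CHANNEL_COLUMNS = (
    "CH1_MEAN",
    "CH1_MEDIAN",
    "CH2_MEAN",
    "CH2_MEDIAN",
    "CH1_BG",
    "CH2_BG",
)

_ID_COLUMNS = ("spot_id", "gene_id", "sample_id", "label")


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix with identifiers and optional labels.

    ``values`` holds log-ratio expression with genes in rows and samples in
    columns; missing entries are NaN and mirrored in ``missing_mask``.
    ``labels``, when present, is a 0/1 vector per sample (1 = tumor).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray | None = None
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} rows"
            )
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samples} columns"
            )
        _check_unique(self.gene_ids, "gene_id")
        _check_unique(self.sample_ids, "sample_id")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n_samples,):
                raise ValueError("labels must have one entry per sample")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be 0 (normal) or 1 (tumor)")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape mismatch")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            list(self.gene_ids),
            list(self.sample_ids),
            None if self.labels is None else self.labels.copy(),
            self.missing_mask.copy(),
        )

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene_id {gene_id!r}") from None


@dataclass
class TwoChannelTable:
    """Long-format spot table for a set of two-dye arrays.

    Wraps a DataFrame with one row per (sample, spot).  Feature columns are
    every column other than the identifier/label columns; the six channel
    intensity/background columns of :data:`REQUIRED_CHANNEL_COLUMNS` must
    be among them.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("spot_id", "gene_id", "sample_id"):
            if col not in self.data.columns:
                raise FormatError(f"missing required column {col!r}")
        for col in REQUIRED_CHANNEL_COLUMNS:
            if col not in self.data.columns:
                raise FormatError(f"missing required column {col!r}")
        dup = self.data.duplicated(subset=["sample_id", "gene_id"])
        if dup.any():
            row = self.data.loc[dup.idxmax()]
            raise FormatError(
                "duplicate spot for gene "
                f"{row['gene_id']!r} in sample {row['sample_id']!r}"
            )

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in _ID_COLUMNS]

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample_id"].astype(str)))

    @property
    def gene_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["gene_id"].astype(str)))

    def sample_labels(self) -> np.ndarray | None:
        """0/1 label per sample (order of :attr:`sample_ids`) or None."""
        if "label" not in self.data.columns:
            return None
        mapping = {"normal": 0, "tumor": 1, "0": 0, "1": 1}
        labels = []
        for sid in self.sample_ids:
            raw = self.data.loc[self.data["sample_id"] == sid, "label"]
            values = {str(v) for v in raw.dropna()}
            if len(values) != 1:
                raise FormatError(f"inconsistent labels for sample {sid!r}")
            value = values.pop()
            if value not in mapping:
                raise FormatError(f"unknown label {value!r} (sample {sid!r})")
            labels.append(mapping[value])
        return np.asarray(labels, dtype=int)


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} {x!r}")
        seen.add(x)


def _fmt(v: float) -> str:
    return "NA" if not math.isfinite(v) else repr(float(v))


# ---------------------------------------------------------------------------
# matrix_tsv


def write_matrix_tsv(x: ExpressionMatrix, path) -> None:
    """Write an :class:`ExpressionMatrix` as matrix_tsv (lossless round-trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(x.sample_ids) + "\n")
        if x.labels is not None:
            fh.write("label\t" + "\t".join(str(v) for v in x.labels) + "\n")
        for i, gid in enumerate(x.gene_ids):
            row = "\t".join(_fmt(v) for v in x.values[i])
            fh.write(f"{gid}\t{row}\n")


def read_matrix_tsv(path) -> ExpressionMatrix:
    """Read a matrix_tsv file into an :class:`ExpressionMatrix`."""
    raw = pd.read_csv(path, sep="\t", dtype=str, header=0, keep_default_na=False)
    if raw.columns[0] != "gene_id":
        raise FormatError("missing required column 'gene_id'")
    sample_ids = [str(c) for c in raw.columns[1:]]
    labels = None
    if len(raw) and str(raw.iloc[0, 0]) == "label":
        try:
            labels = raw.iloc[0, 1:].astype(int).to_numpy()
        except ValueError as exc:
            raise FormatError(f"non-integer label row: {exc}") from None
        raw = raw.iloc[1:].reset_index(drop=True)
    gene_ids = [str(g) for g in raw["gene_id"]]
    values = np.empty((len(gene_ids), len(sample_ids)))
    for j, col in enumerate(raw.columns[1:]):
        # exact strtod parsing keeps write->read round-trips bit-identical
        for i, cell in enumerate(raw[col]):
            try:
                values[i, j] = _parse_cell(cell)
            except ValueError:
                raise FormatError(
                    f"non-numeric value {cell!r} at gene "
                    f"{gene_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from None
    return ExpressionMatrix(values, gene_ids, sample_ids, labels)


def _parse_cell(cell: str) -> float:
    if cell in ("", "NA"):
        return math.nan
    return float(cell)


# ---------------------------------------------------------------------------
# two_channel_tsv


def write_two_channel_tsv(t: TwoChannelTable, path) -> None:
    df = t.data.copy()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_two_channel_tsv(path) -> TwoChannelTable:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("spot_id", "gene_id", "sample_id"):
        if col not in raw.columns:
            raise FormatError(f"missing required column {col!r}")
    for col in REQUIRED_CHANNEL_COLUMNS:
        if col not in raw.columns:
            raise FormatError(f"missing required column {col!r}")
    out = raw.copy()
    for col in raw.columns:
        if col in _ID_COLUMNS:
            continue
        parsed = np.empty(len(raw))
        for i, cell in enumerate(raw[col]):
            try:
                parsed[i] = _parse_cell(cell)
            except ValueError:
                raise FormatError(
                    f"non-numeric value {cell!r} in column {col!r}, row {i}"
                ) from None
        out[col] = parsed
    return TwoChannelTable(out)


def read_expression_table(path, format: str):
    """Dispatch reader: ``matrix_tsv`` or ``two_channel_tsv``."""
    if format == "matrix_tsv":
        return read_matrix_tsv(path)
    if format == "two_channel_tsv":
        return read_two_channel_tsv(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# normalisation / imputation


def log_ratio_normalize(
    t: TwoChannelTable,
    summary: str = "median",
    subtract_background: bool = False,
    background_floor: float = 1e-3,
) -> ExpressionMatrix:
    """Per-spot log2(CH1/CH2) with per-array median centring.

    ``summary`` chooses the per-spot intensity summary (``mean`` or
    ``median``).  Background subtraction is off by default; when enabled,
    each channel summary has its background subtracted and is floored at
    ``background_floor`` to keep ratios defined.
    """
    if summary not in ("mean", "median"):
        raise ValueError(f"summary must be 'mean' or 'median', got {summary!r}")
    ch1_col = f"CH1_{summary.upper()}"
    ch2_col = f"CH2_{summary.upper()}"
    gene_ids = t.gene_ids
    sample_ids = t.sample_ids
    gidx = {g: i for i, g in enumerate(gene_ids)}
    sidx = {s: j for j, s in enumerate(sample_ids)}

    values = np.full((len(gene_ids), len(sample_ids)), np.nan)
    for row in t.data.itertuples(index=False):
        ch1 = getattr(row, ch1_col)
        ch2 = getattr(row, ch2_col)
        if subtract_background:
            ch1 = max(ch1 - getattr(row, "CH1_BG"), background_floor)
            ch2 = max(ch2 - getattr(row, "CH2_BG"), background_floor)
        i = gidx[str(row.gene_id)]
        j = sidx[str(row.sample_id)]
        if np.isnan(ch1) or np.isnan(ch2):
            continue  # stays a missing cell
        if ch1 <= 0 or ch2 <= 0:
            raise ValueError(
                f"non-positive intensity for spot {row.spot_id!r} "
                f"(sample {row.sample_id!r})"
            )
        values[i, j] = np.log2(ch1 / ch2)

    for j, sid in enumerate(sample_ids):
        col = values[:, j]
        if np.isnan(col).all():
            raise ValueError(f"sample {sid!r} has no observed spots")
        values[:, j] = col - np.nanmedian(col)

    return ExpressionMatrix(values, gene_ids, sample_ids, t.sample_labels())


def impute_missing(x: ExpressionMatrix) -> ExpressionMatrix:
    """Fill missing cells with the gene's mean over comparable samples.

    Comparable means same class label when labels are present, otherwise
    all samples.  Observed cells are untouched; the result has no missing
    values.  Idempotent.
    """
    out = x.copy()
    groups: list[np.ndarray]
    if x.labels is None:
        groups = [np.arange(x.n_samples)]
    else:
        groups = [np.flatnonzero(x.labels == g) for g in (0, 1)]
    for i, gid in enumerate(x.gene_ids):
        row = out.values[i]
        if not np.isnan(row).any():
            continue
        if np.isnan(row).all():
            raise ValueError(f"gene {gid!r} has no observed values")
        for idx in groups:
            sub = row[idx]
            miss = np.isnan(sub)
            if not miss.any():
                continue
            obs = sub[~miss]
            # fall back to the overall gene mean when the group is all-missing
            fill = obs.mean() if obs.size else row[~np.isnan(row)].mean()
            sub[miss] = fill
            row[idx] = sub
    out.missing_mask = np.zeros_like(out.missing_mask)
    return out
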