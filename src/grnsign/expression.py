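"""Expression compendium container and cross-study normalization.

The compendium is a gene × sample matrix pooled from several datasets
(microarray and RNA-seq studies).  Two normalization stages are provided:
quantile normalization within each dataset (all samples of a dataset are
forced onto a common value distribution) and per-gene, per-dataset z-scoring
(each gene's values within a dataset are centered and scaled), which puts
heterogeneous platforms on one comparable scale before contrasts are taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

PLATFORMS = ("microarray", "rnaseq")


@dataclass
class ExpressionCompendium:
    """Gene × sample expression values plus per-sample dataset metadata.

    ``values``: DataFrame indexed by gene id, columns are sample ids.
    ``sample_meta``: DataFrame indexed by sample id with columns
    ``dataset`` and ``platform``; every sample belongs to exactly one dataset.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        self.sample_meta = self.sample_meta.loc[list(self.values.columns)]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def datasets(self) -> list[str]:
        return list(dict.fromkeys(self.sample_meta["dataset"]))

    def dataset_samples(self, dataset: str) -> list[str]:
        mask = self.sample_meta["dataset"] == dataset
        return list(self.sample_meta.index[mask])

    def copy_with(self, values: pd.DataFrame) -> "ExpressionCompendium":
        return ExpressionCompendium(values, self.sample_meta.copy())


# -- IO --------------------------------------------------------------------


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression TSV: first column ``gene``, remaining columns sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV: ``sample<TAB>dataset<TAB>platform``."""
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    bad = sorted(set(meta["platform"]) - set(PLATFORMS))
    if bad:
        raise ValueError(f"unknown platform(s) {bad}; expected one of {PLATFORMS}")
    return meta


def read_compendium(expression_path: str | Path, meta_path: str | Path) -> ExpressionCompendium:
    return ExpressionCompendium(read_expression(expression_path), read_sample_meta(meta_path))


def write_compendium(comp: ExpressionCompendium, expression_path: str | Path, meta_path: str | Path) -> None:
    comp.values.to_csv(expression_path, sep="\t", index_label="gene")
    comp.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


# -- quantile normalization ------------------------------------------------


def _quantile_normalize_matrix(mat: np.ndarray) -> np.ndarray:
    """Classic quantile normalization of a genes × samples matrix.

    The reference distribution is the row-wise mean of the column-sorted
    matrix; each entry is replaced by the reference value at its within-column
    rank, ties receiving the mean of the reference values at the rank
    positions the tied block occupies.
    """
    n, m = mat.shape
    reference = np.sort(mat, axis=0).mean(axis=1)
    ref_cumsum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(mat, dtype=float)
    for j in range(m):
        col = mat[:, j]
        lo = rankdata(col, method="min").astype(int)      # first rank of tie block
        hi = rankdata(col, method="max").astype(int)      # last rank of tie block
        out[:, j] = (ref_cumsum[hi] - ref_cumsum[lo - 1]) / (hi - lo + 1)
    return out


def quantile_normalize(comp: ExpressionCompendium, per_dataset: bool = True) -> ExpressionCompendium:
    """Quantile-normalize the compendium (by default within each dataset).

    Requires at least 2 samples per normalized group and no missing values
    (impute first, see :func:`impute_missing`).
    """
    if comp.values.isna().any().any():
        raise ValueError("missing values present; impute or drop before quantile normalization")
    values = comp.values.copy()
    groups = comp.datasets() if per_dataset else ["__all__"]
    for ds in groups:
        cols = comp.dataset_samples(ds) if per_dataset else list(values.columns)
        if len(cols) < 2:
            raise ValueError(
                f"quantile normalization undefined for a single sample (dataset {ds!r})"
            )
        values.loc[:, cols] = _quantile_normalize_matrix(values[cols].to_numpy(dtype=float))
    return comp.copy_with(values)


# -- z-scoring -------------------------------------------------------------


def zscore_by_dataset(comp: ExpressionCompendium) -> ExpressionCompendium:
    """Per-gene, per-dataset standardization: (x - mean) / sd, sample sd (n-1).

    Constant rows within a dataset map to 0.  Each dataset needs >= 2 samples.
    """
    if comp.values.isna().any().any():
        raise ValueError("missing values present; impute or drop before z-scoring")
    values = comp.values.copy().astype(float)
    for ds in comp.datasets():
        cols = comp.dataset_samples(ds)
        if len(cols) < 2:
            raise ValueError(f"dataset {ds!r} has a single sample; z-score undefined")
        sub = values[cols]
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        z = sub.sub(mu, axis=0).div(sd, axis=0)
        z[sd == 0] = 0.0
        values.loc[:, cols] = z
    return comp.copy_with(values)


def impute_missing(comp: ExpressionCompendium) -> ExpressionCompendium:
    """Fill missing values with the per-gene, per-dataset mean."""
    values = comp.values.copy()
    for ds in comp.datasets():
        cols = comp.dataset_samples(ds)
        sub = values[cols]
        values.loc[:, cols] = sub.apply(lambda row: row.fillna(row.mean()), axis=1)
    if values.isna().any().any():
        raise ValueError("genes with no observed value in some dataset cannot be imputed")
    return comp.copy_with(values)
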