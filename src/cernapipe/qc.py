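"""Expression summarization and sample-level QC.

FPKM, median-of-ratios library size factors, PCA sample coordinates and the
all-pairs Pearson sample correlation matrix. Only the size-factor
normalization of the DESeq2 framework is reproduced here (the exact test in
:mod:`cernapipe.diffexpr` consumes the factors); its GLM machinery is not.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .models import ValidationError


def fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    value = count * 1e9 / (length_bp * library_size). When ``library_sizes``
    is not given, per-sample column sums are used.
    """
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValidationError(f"missing lengths for features: {missing[:5].tolist()}")
    if (lengths.loc[counts.index] <= 0).any():
        raise ValidationError("non-positive transcript lengths")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0).astype(float)
    if (library_sizes <= 0).any():
        raise ValidationError("non-positive library sizes")
    L = lengths.loc[counts.index].to_numpy(dtype=float)[:, None]
    M = library_sizes.loc[counts.columns].to_numpy(dtype=float)[None, :]
    return pd.DataFrame(
        counts.to_numpy(dtype=float) * 1e9 / (L * M),
        index=counts.index,
        columns=counts.columns,
    )


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-feature geometric mean across samples, computed
    over features with no zero count (standard behavior). With
    ``pseudo_reference=True`` the geometric mean is taken over the nonzero
    entries of each feature instead, a fallback for sparse matrices.
    """
    x = counts.to_numpy(dtype=float)
    if x.size == 0:
        raise ValidationError("empty count matrix has no size factors")
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    if pseudo_reference:
        usable = (x > 0).sum(axis=1) > 0
        ref = np.full(x.shape[0], -np.inf)
        nz = (x > 0)
        ref[usable] = np.where(nz, logx, 0.0)[usable].sum(axis=1) / nz[usable].sum(axis=1)
    else:
        usable = (x > 0).all(axis=1)
        ref = np.where(usable, logx.mean(axis=1), -np.inf)
    if not usable.any():
        raise ValidationError(
            "no feature is nonzero in every sample; "
            "retry with pseudo_reference=True"
        )
    factors = []
    for j in range(x.shape[1]):
        ratios = logx[usable, j] - ref[usable]
        ratios = ratios[np.isfinite(ratios)]
        if ratios.size == 0:
            raise ValidationError(
                f"sample {counts.columns[j]!r} shares no nonzero feature "
                "with the reference"
            )
        factors.append(np.exp(np.median(ratios)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def pca_coordinates(
    matrix: pd.DataFrame, n_components: int = 2, log_transform: bool = True
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample PCA coordinates from (optionally log2(x+1)) centered features.

    Returns (coordinates: samples x PCs, variance fractions).
    """
    if n_components > min(matrix.shape):
        raise ValidationError(
            f"n_components={n_components} exceeds min(matrix dims)={min(matrix.shape)}"
        )
    x = matrix.to_numpy(dtype=float).T  # samples x features
    if log_transform:
        x = np.log2(x + 1.0)
    x = x - x.mean(axis=0, keepdims=True)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    out = pd.DataFrame(
        coords,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return out, pca.explained_variance_ratio_


def sample_correlation(matrix: pd.DataFrame, log_transform: bool = True) -> pd.DataFrame:
    """Symmetric all-pairs Pearson correlation of samples.

    Zero-variance samples get NaN rows/columns (flagged undefined rather than
    silently 0); valid diagonal entries are exactly 1.
    """
    x = matrix.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    ns = x.shape[1]
    dev = x - x.mean(axis=0, keepdims=True)
    sd = np.sqrt((dev**2).sum(axis=0))
    out = np.full((ns, ns), np.nan)
    valid = sd > 0
    denom = np.outer(sd, sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = dev.T @ dev / denom
    out[np.ix_(valid, valid)] = np.clip(corr[np.ix_(valid, valid)], -1.0, 1.0)
    np.fill_diagonal(out, np.where(valid, 1.0, np.nan))
    return pd.DataFrame(out, index=matrix.columns, columns=matrix.columns)
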