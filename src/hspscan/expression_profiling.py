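"""Expression-based pseudogene calling, heatmap scaling and PCA.

A gene counts as a potential pseudogene when its TPM sum across all
surveyed experiments is strictly below 1 (silence across the whole
expression atlas). Heatmap rows are centred and scaled to unit variance
(sample standard deviation, n-1); PCA is a column-centred SVD of the
samples x genes matrix with a deterministic sign convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import logger


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM table with optional sample group labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    sample_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match labels")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite expression values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.sample_ids)

    def subset(self, genes: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), self.sample_ids,
                                self.values[rows], dict(self.sample_groups))


@dataclass
class PseudogeneCall:
    gene_id: str
    tpm_sum: float
    is_pseudogene: bool


def call_pseudogenes(matrix: ExpressionMatrix, genes: Iterable[str],
                     threshold: float = 1.0) -> list[PseudogeneCall]:
    """Flag genes whose TPM sum over all samples is strictly < threshold."""
    sub = matrix.subset(list(genes))
    sums = sub.values.sum(axis=1)
    return [PseudogeneCall(g, float(s), bool(s < threshold))
            for g, s in zip(sub.gene_ids, sums)]


def scale_unit_variance(matrix: ExpressionMatrix
                        ) -> tuple[ExpressionMatrix, list[str]]:
    """Row-wise centre and scale to unit variance (sample sd, n-1).

    Constant rows become all zeros and are returned as the flagged list.
    A single-column matrix has no defined sample variance and is an error.
    """
    if len(matrix.sample_ids) < 2:
        raise ValueError("unit-variance scaling needs at least two samples")
    v = matrix.values
    means = v.mean(axis=1, keepdims=True)
    sds = v.std(axis=1, ddof=1, keepdims=True)
    constant = sds[:, 0] == 0
    safe = np.where(constant[:, None], 1.0, sds)
    scaled = (v - means) / safe
    scaled[constant] = 0.0
    flagged = [g for g, c in zip(matrix.gene_ids, constant) if c]
    if flagged:
        logger.info("%d constant expression rows scaled to zero", len(flagged))
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids),
                            scaled, dict(matrix.sample_groups)), flagged


@dataclass
class PCAResult:
    scores: np.ndarray            # samples x components
    loadings: np.ndarray          # components x features
    variance_explained: np.ndarray  # percent, sums to 100
    row_ids: list[str]


def pca(matrix: np.ndarray, row_ids: Sequence[str] | None = None) -> PCAResult:
    """Column-centred SVD PCA of a samples x features matrix.

    ``variance_explained`` is in percent of total variance and sums to
    100. Component signs are fixed by making each component's
    largest-magnitude loading positive, so results are reproducible
    across runs and sample orderings (up to that fixed sign).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with >= 2 rows")
    if not x.any():
        raise ValueError("PCA of an all-zero matrix is undefined")
    centred = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s
    total = (s ** 2).sum()
    var = (100.0 * s ** 2 / total) if total > 0 else np.zeros_like(s)
    ids = list(row_ids) if row_ids is not None else [str(i) for i in range(x.shape[0])]
    return PCAResult(scores=scores, loadings=vt, variance_explained=var,
                     row_ids=ids)


def pca_samples(matrix: ExpressionMatrix, scale_genes: bool = True) -> PCAResult:
    """Sample-space PCA of an expression matrix (samples as observations).

    With ``scale_genes`` each gene row is unit-variance scaled first,
    the ClustVis-style preprocessing behind both the heatmaps and the
    sample-grouping plots.
    """
    if scale_genes:
        matrix, _ = scale_unit_variance(matrix)
    return pca(matrix.values.T, row_ids=matrix.sample_ids)


def induction_summary(matrix: ExpressionMatrix,
                      gene_subfamilies: Mapping[str, str],
                      groups: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Mean scaled expression per sub-family x sample group.

    Rows for sub-families with no gene in the matrix are omitted with a
    log notice. ``groups`` defaults to the matrix's own sample groups and
    must cover every sample.
    """
    groups = dict(groups) if groups is not None else dict(matrix.sample_groups)
    missing = [s for s in matrix.sample_ids if s not in groups]
    if missing:
        raise ValueError(f"samples without group annotation: {missing}")
    scaled, _ = scale_unit_variance(matrix)
    df = scaled.to_frame()
    rows = {}
    for subfamily in sorted(set(gene_subfamilies.values())):
        genes = [g for g, sf in gene_subfamilies.items()
                 if sf == subfamily and g in df.index]
        if not genes:
            logger.info("sub-family %s has no genes in the expression "
                        "matrix; row omitted", subfamily)
            continue
        block = df.loc[genes]
        rows[subfamily] = {grp: float(block[cols].to_numpy().mean())
                           for grp in sorted(set(groups.values()))
                           if (cols := [s for s in df.columns
                                        if groups[s] == grp])}
    out = pd.DataFrame(rows).T
    out.index.name = "subfamily"
    return out
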