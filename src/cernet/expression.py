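"""Expression matrix container and probe-level preprocessing.

The whole pipeline operates on log2-scale feature-by-sample matrices with a
sample metadata table carrying a ``group`` label (case/control) or a
``timepoint`` label. :class:`ExpressionMatrix` is a thin, validated wrapper
around two :class:`pandas.DataFrame` objects rather than a heavyweight
container: every downstream statistic is a plain matrix operation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix", "collapse_probes", "ensure_log2"]


@dataclass
class ExpressionMatrix:
    """Features x samples log2 expression values plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, one column per sample id.
    samples
        DataFrame indexed by sample id. Must cover every column of
        ``values``; carries a ``group`` column (e.g. ``CAD`` / ``control``)
        and, for time-course data, a ``timepoint`` column.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> "ExpressionMatrix":
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dups[:5])!r}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if len(self.samples):
            missing = self.values.columns.difference(self.samples.index)
            if len(missing):
                raise ValueError(
                    f"samples absent from metadata: {list(missing[:5])!r}"
                )
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        return self

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def group_samples(self, label: str) -> list[str]:
        """Sample ids whose metadata ``group`` equals *label*."""
        grp = self.samples.loc[self.values.columns, "group"]
        return list(grp.index[grp == label])


def collapse_probes(
    matrix: ExpressionMatrix, annotation: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probe-level rows to gene level by averaging.

    Each gene's expression in every sample is the arithmetic mean of the
    values of all probes annotated to that gene. Probes absent from the
    annotation are dropped. Output genes are sorted lexicographically.

    Raises
    ------
    ValueError
        If no probe in the matrix has an annotation entry — an empty
        result would silently kill the downstream screen.
    """
    ann = pd.Series(dict(annotation), dtype=object)
    mapped = matrix.values.index.intersection(ann.index)
    if len(mapped) == 0:
        raise ValueError("no probe in the matrix is covered by the annotation")
    n_drop = len(matrix.values.index) - len(mapped)
    if n_drop:
        logger.info("collapse_probes: dropping %d unannotated probes", n_drop)
    vals = matrix.values.loc[mapped]
    genes = ann.loc[mapped]
    collapsed = vals.groupby(genes.to_numpy()).mean().sort_index()
    collapsed.index.name = matrix.values.index.name
    return ExpressionMatrix(collapsed, matrix.samples)


def ensure_log2(
    matrix: ExpressionMatrix, linear_threshold: float = 50.0
) -> ExpressionMatrix:
    """Apply ``log2(x + 1)`` if the matrix looks linear-scale.

    Microarray series matrices are sometimes deposited on the linear scale.
    The heuristic: a matrix whose maximum exceeds ``linear_threshold``
    (default 50, far above any plausible log2 intensity) is judged linear
    and transformed; otherwise it is returned unchanged. The decision is
    logged either way.
    """
    arr = matrix.values.to_numpy()
    if arr.size == 0 or np.nanmax(arr) <= linear_threshold:
        logger.info("ensure_log2: matrix judged log2-scale, left unchanged")
        return matrix
    if (arr < 0).any():
        raise ValueError("matrix judged linear-scale but contains negatives")
    logger.info(
        "ensure_log2: max=%.3g > %.3g, applying log2(x+1)",
        float(np.nanmax(arr)),
        linear_threshold,
    )
    return ExpressionMatrix(np.log2(matrix.values + 1.0), matrix.samples)
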