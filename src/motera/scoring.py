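"""Single-sample signature scoring by mean within-sample percentile rank.

Every gene is percentile-ranked within each sample (fractional average rank,
ascending: higher expression => higher percentile), and a sample's score is
the mean percentile of the signature genes. Because the statistic depends
only on within-sample ranks it is invariant under any strictly increasing
per-sample transform — in particular log2(x + c) for any pseudocount c.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix
from .signature import SignatureDefinition

MIN_COVERAGE = 0.5  # hard floor on the fraction of signature genes that must be present


@dataclass
class ScoreTable:
    """Per-sample signature scores.

    ``table`` columns: sample_id, score, n_genes_used; ``missing_genes`` are
    signature genes absent from the matrix (shared by all samples, dropped —
    never imputed).
    """

    table: pd.DataFrame
    missing_genes: list[str] = field(default_factory=list)
    signature_name: str = ""

    @property
    def scores(self) -> pd.Series:
        return self.table.set_index("sample_id")["score"]

    def write(self, path) -> None:
        out = self.table.copy()
        out["missing_genes"] = ";".join(self.missing_genes)
        out.to_csv(path, index=False)


def percentile_ranks(sample_values) -> np.ndarray:
    """Fractional average-rank percentiles of one sample's expression vector.

    percentile_g = avg_rank(value_g, ascending) / N, so output lies in
    (0, 1]; ties receive the mean of their rank positions. With all values
    equal every percentile is (N + 1) / (2N).
    """
    values = np.asarray(sample_values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-D vector of >= 2 gene values")
    if np.isnan(values).any():
        raise ValueError("missing values are not allowed")
    if np.all(values == values[0]):
        warnings.warn("all gene values equal; percentiles are degenerate", stacklevel=2)
    return rankdata(values, method="average") / values.size


def signature_score(matrix: ExpressionMatrix, signature: SignatureDefinition) -> ScoreTable:
    """Mean within-sample percentile rank of the signature genes.

    Percentiles are computed over *all* genes in the matrix; signature genes
    missing from the matrix are dropped (recorded, never imputed), with a
    hard error when fewer than half the signature genes are present. The
    matrix may be on a linear or log2 scale — scores are identical.
    """
    if matrix.n_genes < 2 or matrix.n_samples < 1:
        raise ValueError("matrix must have >= 2 genes and >= 1 sample")
    index = set(matrix.gene_ids)
    present = [g for g in signature.genes if g in index]
    missing = [g for g in signature.genes if g not in index]
    if len(present) < MIN_COVERAGE * len(signature.genes):
        raise ValueError(
            f"only {len(present)}/{len(signature.genes)} signature genes present; "
            f"missing: {missing}"
        )
    if missing:
        warnings.warn(
            f"{len(missing)} signature gene(s) absent from the matrix and dropped: {missing}",
            stacklevel=2,
        )

    ranks = rankdata(matrix.values.to_numpy(), method="average", axis=0) / matrix.n_genes
    percentiles = pd.DataFrame(ranks, index=matrix.gene_ids, columns=matrix.sample_ids)
    scores = percentiles.loc[present].mean(axis=0)
    table = pd.DataFrame({
        "sample_id": matrix.sample_ids,
        "score": scores.to_numpy(),
        "n_genes_used": len(present),
    })
    return ScoreTable(table, missing_genes=missing, signature_name=signature.name)
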