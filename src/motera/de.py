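"""Differential expression and candidate-gene filtering.

Candidate genes for the active-fusion signature are those upregulated in the
active group versus a comparator with linear fold change > 4 and BH-adjusted
FDR < 0.05 (both strict). The location test is a two-sided Welch t-test on
log2(x + 1) values; fold changes are ratios of linear group means with a
small stabilizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleTable

DEFAULT_FC_THRESHOLD = 4.0
DEFAULT_FDR_THRESHOLD = 0.05
FOLD_CHANGE_EPS = 0.01


@dataclass
class DEResult:
    """Per-gene differential-expression statistics for one group comparison.

    ``table`` is indexed by gene with columns mean_a, mean_b, fold_change,
    log2_fc, p_value, q_value. Means are on the linear scale; fold_change is
    (mean_a + eps) / (mean_b + eps).
    """

    table: pd.DataFrame
    group_a: str
    group_b: str

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


@dataclass
class CandidateSet:
    """Ordered candidate gene list plus the thresholds that produced it."""

    genes: list[str]
    comparison_name: str
    fc_threshold: float = DEFAULT_FC_THRESHOLD
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("candidate genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _resolve_group(samples: SampleTable, spec, e2: str | None = None) -> list[str]:
    """Map a group spec (group_class value, group label, or explicit sample IDs)
    to a list of sample IDs, optionally restricted to one E2 arm."""
    if isinstance(spec, str):
        ids = samples.select(group_class=spec, e2=e2)
        if not ids:
            ids = samples.select(group=spec, e2=e2)
        if not ids:
            raise ValueError(f"group {spec!r} matches no samples")
        return ids
    ids = list(spec)
    known = set(samples.sample_ids)
    missing = [s for s in ids if s not in known]
    if missing:
        raise ValueError(f"sample IDs not in sample table: {missing}")
    return ids


def de_test(matrix: ExpressionMatrix, samples: SampleTable, group_a, group_b,
            *, e2: str | None = None, pseudocount: float = 1.0,
            min_mean: float = 1.0, eps: float = FOLD_CHANGE_EPS) -> DEResult:
    """Welch t-test (two-sided, on log2(x + pseudocount)) of group A vs group B.

    Parameters
    ----------
    group_a, group_b
        Either a ``group_class`` value / group label resolved against the
        sample table, or an explicit list of sample IDs. Groups must be
        disjoint with >= 2 samples each.
    e2
        Optional E2 arm restriction applied when resolving labels.
    min_mean
        Low-expression prefilter: genes with linear mean below this in *both*
        groups are excluded before testing (set to 0 to disable).
    """
    if not matrix.is_linear:
        raise ValueError("de_test expects a linear-scale matrix")
    ids_a = _resolve_group(samples, group_a, e2)
    ids_b = _resolve_group(samples, group_b, e2)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    overlap = set(ids_a) & set(ids_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")

    a = matrix.values[ids_a].to_numpy()
    b = matrix.values[ids_b].to_numpy()
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)

    keep = (mean_a >= min_mean) | (mean_b >= min_mean)
    genes = matrix.values.index[keep]
    a, b = a[keep], b[keep]
    mean_a, mean_b = mean_a[keep], mean_b[keep]

    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        # zero variance in both groups: identical means -> no evidence, else certain
        same = np.isclose(la.mean(axis=1), lb.mean(axis=1))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
        warnings.warn(f"{int(degenerate.sum())} gene(s) had zero within-group variance", stacklevel=2)

    fold_change = (mean_a + eps) / (mean_b + eps)
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fold_change,
            "log2_fc": np.log2(fold_change),
            "p_value": p,
            "q_value": benjamini_hochberg(p),
        },
        index=genes,
    )
    name_a = group_a if isinstance(group_a, str) else "groupA"
    name_b = group_b if isinstance(group_b, str) else "groupB"
    return DEResult(table, name_a, name_b)


def select_candidates(de: DEResult, fc_threshold: float = DEFAULT_FC_THRESHOLD,
                      fdr_threshold: float = DEFAULT_FDR_THRESHOLD) -> CandidateSet:
    """Upregulated genes passing strict FC > threshold and q < threshold filters."""
    t = de.table
    mask = (t["fold_change"] > fc_threshold) & (t["q_value"] < fdr_threshold) & (t["mean_a"] > t["mean_b"])
    return CandidateSet(
        genes=list(t.index[mask]),
        comparison_name=f"{de.group_a}_vs_{de.group_b}",
        fc_threshold=fc_threshold,
        fdr_threshold=fdr_threshold,
    )


def intersect_candidates(a: CandidateSet, b: CandidateSet) -> CandidateSet:
    """Genes present in both candidate sets, in ``a``'s order."""
    in_b = set(b.genes)
    return CandidateSet(
        genes=[g for g in a.genes if g in in_b],
        comparison_name=f"({a.comparison_name})&({b.comparison_name})",
        fc_threshold=a.fc_threshold,
        fdr_threshold=a.fdr_threshold,
    )
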