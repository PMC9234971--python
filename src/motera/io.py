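"""Expression-matrix, sample-table and gene-set containers and file formats.

The package works at the abundance-matrix level: a genes-by-samples table of
TPM/FPKM values (or their log2 transform), a companion per-sample annotation
table, and GMT gene-set collections. All readers validate on entry so that
downstream stages can assume clean inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LINEAR_SCALES = ("linear_TPM", "linear_FPKM")
SCALE_TAGS = LINEAR_SCALES + ("log2",)

GROUP_CLASSES = ("active", "inactive", "control", "wt_tumor", "mutant_tumor", "unknown")
E2_CONDITIONS = ("minus_E2", "plus_E2", "unknown")


class ExpressionIOError(ValueError):
    """Malformed expression/annotation input."""


@dataclass
class ExpressionMatrix:
    """Genes-by-samples abundance matrix with an explicit scale tag.

    Parameters
    ----------
    values
        DataFrame with gene IDs as index and sample IDs as columns. No
        missing entries are allowed; linear-scale values must be >= 0.
    scale
        One of ``linear_TPM``, ``linear_FPKM`` (natural units) or ``log2``.
    """

    values: pd.DataFrame
    scale: str = "linear_TPM"

    def __post_init__(self) -> None:
        if self.scale not in SCALE_TAGS:
            raise ExpressionIOError(f"unknown scale tag {self.scale!r}; expected one of {SCALE_TAGS}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate gene IDs: {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate sample IDs: {dup}")
        if self.values.isna().any().any():
            raise ExpressionIOError("expression matrix contains missing values")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ExpressionIOError("expression matrix contains non-numeric values")
        if self.is_linear and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ExpressionIOError(
                f"negative value at gene {idx[g]!r}, sample {cols[s]!r} on linear scale {self.scale}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def is_linear(self) -> bool:
        return self.scale in LINEAR_SCALES

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.scale)


@dataclass
class SampleTable:
    """Per-sample annotations: group label, group class, E2 arm, truth label.

    ``truth_active`` is the ground-truth "driven by an active ESR1 protein"
    label; it lives here explicitly and is never inferred from sample names.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "group", "group_class", "e2")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ExpressionIOError(f"sample table missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].tolist()
            raise ExpressionIOError(f"duplicate sample IDs in sample table: {dup}")
        bad_class = set(self.table["group_class"]) - set(GROUP_CLASSES)
        if bad_class:
            raise ExpressionIOError(f"unknown group_class values: {sorted(bad_class)}")
        bad_e2 = set(self.table["e2"]) - set(E2_CONDITIONS)
        if bad_e2:
            raise ExpressionIOError(f"unknown e2 values: {sorted(bad_e2)}")
        if "truth_active" not in self.table.columns:
            self.table = self.table.assign(truth_active=pd.NA)
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def select(self, group_class: str | None = None, e2: str | None = None,
               group: str | None = None) -> list[str]:
        """Sample IDs matching the given annotation values (None = any)."""
        mask = pd.Series(True, index=self.table.index)
        if group_class is not None:
            mask &= self.table["group_class"] == group_class
        if e2 is not None:
            mask &= self.table["e2"] == e2
        if group is not None:
            mask &= self.table["group"] == group
        return list(self.table.loc[mask, "sample_id"])

    def subset(self, sample_ids: list[str]) -> "SampleTable":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        order = {s: i for i, s in enumerate(sample_ids)}
        keep = keep.sort_values("sample_id", key=lambda s: s.map(order), kind="stable")
        return SampleTable(keep.reset_index(drop=True))

    def truth_labels(self, sample_ids: list[str] | None = None) -> np.ndarray:
        """Boolean truth vector aligned to ``sample_ids`` (default: table order)."""
        t = self.table.set_index("sample_id")["truth_active"]
        if sample_ids is not None:
            t = t.loc[list(sample_ids)]
        if t.isna().any():
            raise ExpressionIOError("truth_active is undefined for some samples")
        return t.astype(bool).to_numpy()


@dataclass
class GeneSetCollection:
    """Named gene sets over an explicit gene universe."""

    sets: dict[str, list[str]]
    universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.universe:
            seen: dict[str, None] = {}
            for members in self.sets.values():
                for g in members:
                    seen.setdefault(g)
            self.universe = list(seen)
        uni = set(self.universe)
        for name, members in self.sets.items():
            if not members:
                raise ExpressionIOError(f"gene set {name!r} is empty")
            stray = set(members) - uni
            if stray:
                raise ExpressionIOError(f"gene set {name!r} has members outside the universe: {sorted(stray)[:5]}")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# matrix I/O


def read_matrix(path, scale: str = "linear_TPM") -> ExpressionMatrix:
    """Read a genes-by-samples TSV (first column = gene ID, header = sample IDs)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        raise ExpressionIOError(f"duplicate gene ID(s) in {path}: {dup}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.any().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ExpressionIOError(
            f"non-numeric cell in {path} at gene {raw.index[g]!r}, sample {raw.columns[s]!r}: {raw.iloc[g, s]!r}"
        )
    if numeric.isna().any().any():
        g, s = np.argwhere(numeric.isna().to_numpy())[0]
        raise ExpressionIOError(f"missing cell in {path} at gene {raw.index[g]!r}, sample {raw.columns[s]!r}")
    numeric = numeric.astype(float)
    numeric.index.name = None  # write_matrix labels the column; identity on roundtrip
    return ExpressionMatrix(numeric, scale)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def read_samples(path) -> SampleTable:
    table = pd.read_csv(path, dtype={"sample_id": str})
    if "truth_active" in table.columns:
        table["truth_active"] = table["truth_active"].map(
            {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
        )
    return SampleTable(table)


def write_samples(samples: SampleTable, path) -> None:
    samples.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# transforms and filters


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount) transform of a linear-scale matrix.

    The downstream signature score is rank-based, so the pseudocount cannot
    change scores; it only guards against log2(0).
    """
    if not matrix.is_linear:
        raise ExpressionIOError("matrix is already log2-scaled; refusing to double-transform")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return ExpressionMatrix(np.log2(matrix.values + pseudocount), "log2")


def filter_er_positive(matrix: ExpressionMatrix, samples: SampleTable,
                       esr1_gene_id: str = "ESR1", threshold: float = 1.0
                       ) -> tuple[ExpressionMatrix, SampleTable]:
    """Keep samples with ESR1 abundance strictly above ``threshold`` (ER+ filter)."""
    if not matrix.is_linear:
        raise ExpressionIOError("ER+ filter is defined on linear-scale abundance")
    if esr1_gene_id not in matrix.values.index:
        raise ExpressionIOError(f"ESR1 gene {esr1_gene_id!r} not present in the matrix")
    esr1 = matrix.values.loc[esr1_gene_id]
    keep = [s for s in matrix.sample_ids if esr1[s] > threshold]
    return matrix.subset_samples(keep), samples.subset(keep)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path, universe: list[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ExpressionIOError(f"{path}:{lineno}: gene set line has no members")
            name, _desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ExpressionIOError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ExpressionIOError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = members
    return GeneSetCollection(sets, universe or [])


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")
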