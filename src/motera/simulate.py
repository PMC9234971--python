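"""Synthetic expression cohorts with planted transcriptional programs.

Emulates the two study designs the analysis assumes, without any external
data:

* a T47D-like *training* cohort — groups of cell lines expressing active
  fusions, inactive fusions, or controls, profiled with and without
  estradiol (E2), where active samples upregulate estrogen-response and
  EMT program genes hormone-independently; and
* a PDX-like *validation* cohort — wild-type tumors whose program genes are
  E2-inducible versus mutant tumors with constitutively high program
  expression.

Expression is generated on a linear TPM-like scale: per-gene baselines are
2**Normal(baseline_log2_mean, baseline_log2_sd), planted effects are
multiplicative fold changes, and per-sample noise is multiplicative
log2-normal. Identical (config, seed) pairs produce bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection, SampleTable, write_gmt, write_matrix, write_samples

ACTIVE_CLASSES = ("active", "mutant_tumor")       # constitutive program expression
E2_INDUCIBLE_CLASSES = ("control", "wt_tumor")    # program expression only under +E2
GROUP_CLASSES = ACTIVE_CLASSES + E2_INDUCIBLE_CLASSES + ("inactive",)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_groups() -> list[tuple[str, str, int]]:
    # training design: 4 active-fusion, 3 inactive-fusion, 3 control lines, 3 replicates
    groups: list[tuple[str, str, int]] = []
    groups += [(f"active_{i}", "active", 3) for i in range(1, 5)]
    groups += [(f"inactive_{i}", "inactive", 3) for i in range(1, 4)]
    groups += [(f"control_{i}", "control", 3) for i in range(1, 4)]
    return groups


def _default_programs() -> dict[str, int]:
    return {"estrogen_early": 30, "estrogen_late": 30, "emt": 20}


@dataclass
class SimulationConfig:
    """Stated world for a synthetic cohort.

    Attributes
    ----------
    n_genes
        Total genes in the matrix (program genes are a subset).
    program_sizes
        Genes per planted program (estrogen_early / estrogen_late / emt).
    groups
        ``(group_name, group_class, n_replicates)`` triples; classes are
        ``active``, ``inactive``, ``control``, ``wt_tumor``, ``mutant_tumor``.
    e2_conditions
        E2 arms generated for every group.
    planted_fc
        Linear fold change of program genes in constitutively active samples
        (active fusions / mutant tumors), both E2 arms.
    e2_fc
        Fold change of program genes in control / WT samples under +E2 only.
    noise_sd
        SD (log2 units) of per-sample multiplicative noise.
    baseline_log2_mean, baseline_log2_sd
        Background expression distribution: baseline_g = 2**N(mean, sd).
    """

    n_genes: int = 2000
    program_sizes: dict[str, int] = field(default_factory=_default_programs)
    groups: list[tuple[str, str, int]] = field(default_factory=_default_groups)
    e2_conditions: tuple[str, ...] = ("minus_E2", "plus_E2")
    planted_fc: float = 6.0
    e2_fc: float = 6.0
    noise_sd: float = 0.25
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 2.0
    seed: int = 0
    sample_seed: int | None = None  # separate noise stream: same `seed` + new
    # `sample_seed` yields held-out samples from the same world (same planted
    # genes and baselines)

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ConfigError("n_genes must be >= 2")
        if not self.program_sizes:
            raise ConfigError("at least one program is required")
        if any(k < 1 for k in self.program_sizes.values()):
            raise ConfigError("every program needs >= 1 gene")
        if sum(self.program_sizes.values()) > self.n_genes:
            raise ConfigError("program genes exceed n_genes")
        if self.planted_fc <= 0 or self.e2_fc <= 0:
            raise ConfigError("fold changes must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not self.groups:
            raise ConfigError("at least one sample group is required")
        for name, cls, reps in self.groups:
            if cls not in GROUP_CLASSES:
                raise ConfigError(f"unknown group_class {cls!r} for group {name!r}")
            if reps < 1:
                raise ConfigError(f"group {name!r} needs >= 1 replicate")
        bad = set(self.e2_conditions) - {"minus_E2", "plus_E2"}
        if bad:
            raise ConfigError(f"unknown E2 conditions: {sorted(bad)}")


def pdx_like_config(n_mutant: int = 11, n_wt: int = 9, n_replicates: int = 3,
                    **overrides) -> SimulationConfig:
    """Validation-cohort design: mutant/fusion tumor lines vs WT lines, both E2 arms."""
    groups = [(f"mutant_{i}", "mutant_tumor", n_replicates) for i in range(1, n_mutant + 1)]
    groups += [(f"wt_{i}", "wt_tumor", n_replicates) for i in range(1, n_wt + 1)]
    return SimulationConfig(groups=groups, **overrides)


@dataclass
class SyntheticCohort:
    """A generated cohort: matrix + annotations + planted ground truth."""

    matrix: ExpressionMatrix
    samples: SampleTable
    planted_genes: dict[str, list[str]]
    config: SimulationConfig

    @property
    def program_genes(self) -> list[str]:
        out: list[str] = []
        for genes in self.planted_genes.values():
            out.extend(genes)
        return out

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_matrix(self.matrix, outdir / "matrix.tsv")
        write_samples(self.samples, outdir / "samples.csv")
        sets = GeneSetCollection(dict(self.planted_genes), universe=self.matrix.gene_ids)
        write_gmt(sets, outdir / "planted_programs.gmt")


def _gene_pool(config: SimulationConfig) -> list[str]:
    width = len(str(config.n_genes))
    return [f"GENE{i + 1:0{width}d}" for i in range(config.n_genes)]


def _draw_baseline_and_programs(config: SimulationConfig, rng: np.random.Generator
                                ) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Shared draw order: per-gene baselines, then disjoint program assignment."""
    baseline = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    n_prog = sum(config.program_sizes.values())
    chosen = rng.choice(config.n_genes, size=n_prog, replace=False)
    planted_idx: dict[str, np.ndarray] = {}
    offset = 0
    for program, size in config.program_sizes.items():
        planted_idx[program] = chosen[offset:offset + size]
        offset += size
    return baseline, chosen, planted_idx


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a cohort from the configured generative model.

    Baseline per gene is shared by all samples; program genes are multiplied
    by ``planted_fc`` in constitutively active classes (both E2 arms) and by
    ``e2_fc`` in control/WT samples under +E2; every entry then receives
    independent 2**N(0, noise_sd) multiplicative noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_ids = _gene_pool(config)
    baseline, all_prog_idx, planted_idx = _draw_baseline_and_programs(config, rng)
    planted = {prog: [gene_ids[i] for i in idx] for prog, idx in planted_idx.items()}
    if config.sample_seed is not None:
        rng = np.random.default_rng(config.sample_seed)

    columns: dict[str, np.ndarray] = {}
    rows: list[dict] = []
    for group_name, group_class, n_reps in config.groups:
        for e2 in config.e2_conditions:
            for rep in range(1, n_reps + 1):
                sample_id = f"{group_name}.{e2}.r{rep}"
                mean = baseline.copy()
                if group_class in ACTIVE_CLASSES:
                    mean[all_prog_idx] *= config.planted_fc
                elif group_class in E2_INDUCIBLE_CLASSES and e2 == "plus_E2":
                    mean[all_prog_idx] *= config.e2_fc
                noise = 2.0 ** rng.normal(0.0, config.noise_sd, config.n_genes)
                columns[sample_id] = mean * noise
                rows.append({
                    "sample_id": sample_id,
                    "group": group_name,
                    "group_class": group_class,
                    "e2": e2,
                    "truth_active": group_class in ACTIVE_CLASSES,
                })

    values = pd.DataFrame(columns, index=gene_ids)
    matrix = ExpressionMatrix(values, "linear_TPM")
    samples = SampleTable(pd.DataFrame(rows))
    return SyntheticCohort(matrix, samples, planted, config)


def generate_gene_sets(config: SimulationConfig, extra_random_sets: int = 0,
                       seed: int | None = None, n_decoys_per_set: int = 50,
                       random_set_size: int = 50) -> GeneSetCollection:
    """Hallmark-style gene-set collection matching the planted programs.

    The three named sets contain the planted program genes plus random decoy
    members (mimicking the breadth of curated pathway sets); additional
    all-decoy sets can be appended. The universe is the full gene pool.
    """
    config.validate()
    if extra_random_sets < 0:
        raise ValueError("extra_random_sets must be >= 0")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    hallmark_names = {
        "estrogen_early": "HALLMARK_ESTROGEN_RESPONSE_EARLY",
        "estrogen_late": "HALLMARK_ESTROGEN_RESPONSE_LATE",
        "emt": "HALLMARK_EPITHELIAL_MESENCHYMAL_TRANSITION",
    }
    gene_ids = _gene_pool(config)

    # reproduce the planted assignment of generate_cohort (same seed, same draw order)
    rng_cohort = np.random.default_rng(config.seed)
    _, chosen, planted_idx = _draw_baseline_and_programs(config, rng_cohort)
    non_program = np.setdiff1d(np.arange(config.n_genes), chosen)

    sets: dict[str, list[str]] = {}
    for program, idx in planted_idx.items():
        decoys = rng.choice(non_program, size=min(n_decoys_per_set, non_program.size), replace=False)
        members = [gene_ids[i] for i in idx] + [gene_ids[i] for i in decoys]
        sets[hallmark_names.get(program, f"PROGRAM_{program.upper()}")] = members
    for k in range(1, extra_random_sets + 1):
        idx = rng.choice(config.n_genes, size=min(random_set_size, config.n_genes), replace=False)
        sets[f"RANDOM_SET_{k:02d}"] = [gene_ids[i] for i in idx]
    return GeneSetCollection(sets, universe=gene_ids)
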