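"""End-to-end orchestration: simulate → derive → score → evaluate.

Each stage reads/writes the package's standard artifacts (matrix TSV, sample
CSV, GMT, signature JSON, score CSV, report JSON) under one output directory
and logs every parameter and seed so a run log suffices to reproduce any
output file byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import de, evaluation, io, scoring, signature as sig
from .simulate import SimulationConfig, SyntheticCohort, generate_cohort, generate_gene_sets

logger = logging.getLogger("motera")

MODES = ("simulate", "derive", "score", "evaluate", "full")


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    mode: str = "full"
    outdir: str = "motera_run"
    seed: int = 0
    # input paths (unused in simulate/full modes, which generate their inputs)
    matrix_path: str | None = None
    samples_path: str | None = None
    gene_sets_path: str | None = None
    signature_path: str | None = None
    # stage parameters
    fc_threshold: float = 4.0
    fdr_threshold: float = 0.05
    pseudocount: float = 1.0
    cutoff: float | str = "derive"
    scale: str = "linear_TPM"
    derive_e2: str | None = "minus_E2"    # E2 arm used for the DE comparisons
    evaluate_e2: str | None = "minus_E2"  # E2 arm used for ROC/classification
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def simulation_config(self) -> SimulationConfig:
        params = dict(self.simulation)
        params.setdefault("seed", self.seed)
        if "groups" in params:
            params["groups"] = [tuple(g) for g in params["groups"]]
        return SimulationConfig(**params)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(config: PipelineConfig) -> list[str]:
    """Human-readable diagnostics; an empty list means the config is runnable."""
    diags: list[str] = []
    if config.mode not in MODES:
        diags.append(f"mode: unknown mode {config.mode!r}; expected one of {MODES}")
    if config.fc_threshold <= 0:
        diags.append("fc_threshold: must be positive")
    if not 0 < config.fdr_threshold <= 1:
        diags.append("fdr_threshold: must lie in (0, 1]")
    if config.pseudocount <= 0:
        diags.append("pseudocount: must be positive")
    if isinstance(config.cutoff, str) and config.cutoff != "derive":
        diags.append('cutoff: must be a number or the string "derive"')
    needs_inputs = config.mode in ("derive", "score", "evaluate")
    if needs_inputs and not config.matrix_path:
        diags.append(f"matrix_path: required for mode {config.mode!r}")
    if needs_inputs and not config.samples_path:
        diags.append(f"samples_path: required for mode {config.mode!r}")
    if config.mode == "derive" and not config.gene_sets_path:
        diags.append("gene_sets_path: required for mode 'derive'")
    if config.mode == "simulate" or config.mode == "full":
        try:
            config.simulation_config().validate()
        except (TypeError, ValueError) as exc:
            diags.append(f"simulation: {exc}")
    return diags


def _setup_run(config: PipelineConfig) -> Path:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    with open(outdir / "resolved_config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    logger.info("resolved config written; mode=%s seed=%d", config.mode, config.seed)
    return outdir


def derive_signature(matrix: io.ExpressionMatrix, samples: io.SampleTable,
                     gene_sets: io.GeneSetCollection, *,
                     fc_threshold: float = 4.0, fdr_threshold: float = 0.05,
                     pseudocount: float = 1.0, e2: str | None = "minus_E2",
                     ) -> tuple[de.DEResult, de.DEResult, de.CandidateSet, sig.ORAResult, sig.SignatureDefinition]:
    """Active-vs-inactive and active-vs-control DE, candidate intersection,
    overrepresentation, and signature assembly (the derivation workflow)."""
    de_inactive = de.de_test(matrix, samples, "active", "inactive", e2=e2, pseudocount=pseudocount)
    de_control = de.de_test(matrix, samples, "active", "control", e2=e2, pseudocount=pseudocount)
    cand_inactive = de.select_candidates(de_inactive, fc_threshold, fdr_threshold)
    cand_control = de.select_candidates(de_control, fc_threshold, fdr_threshold)
    candidates = de.intersect_candidates(cand_inactive, cand_control)
    logger.info("candidates: %d vs inactive, %d vs control, %d overlapping",
                len(cand_inactive), len(cand_control), len(candidates))
    ora = sig.overrepresentation(candidates, gene_sets)
    signature = sig.assemble_signature(candidates, ora)
    logger.info("assembled signature with %d genes from sets %s", len(signature), signature.source_sets)
    return de_inactive, de_control, candidates, ora, signature


@dataclass
class PipelineResult:
    outdir: Path
    cohort: SyntheticCohort | None = None
    signature: sig.SignatureDefinition | None = None
    scores: scoring.ScoreTable | None = None
    roc: evaluation.ROCCurve | None = None
    report: evaluation.ClassificationReport | None = None


def run_full(config: PipelineConfig) -> PipelineResult:
    """Execute the configured stages; artifacts land under ``config.outdir``."""
    diags = validate_config(config)
    if diags:
        raise ValueError("invalid configuration:\n" + "\n".join(f"  - {d}" for d in diags))
    outdir = _setup_run(config)
    result = PipelineResult(outdir=outdir)
    try:
        matrix = samples = gene_sets = None

        if config.mode in ("simulate", "full"):
            sim = config.simulation_config()
            cohort = generate_cohort(sim)
            cohort.write(outdir)
            gene_sets = generate_gene_sets(sim)
            io.write_gmt(gene_sets, outdir / "gene_sets.gmt")
            matrix, samples = cohort.matrix, cohort.samples
            result.cohort = cohort
            logger.info("simulated cohort: %d genes x %d samples", matrix.n_genes, matrix.n_samples)
            if config.mode == "simulate":
                return result
        else:
            matrix = io.read_matrix(config.matrix_path, config.scale)
            samples = io.read_samples(config.samples_path)
            if config.gene_sets_path:
                gene_sets = io.read_gmt(config.gene_sets_path, universe=matrix.gene_ids)

        if config.mode in ("derive", "full"):
            de_a, de_b, candidates, ora, signature = derive_signature(
                matrix, samples, gene_sets,
                fc_threshold=config.fc_threshold, fdr_threshold=config.fdr_threshold,
                pseudocount=config.pseudocount, e2=config.derive_e2)
            de_a.write(outdir / "de_active_vs_inactive.tsv")
            de_b.write(outdir / "de_active_vs_control.tsv")
            ora.table.to_csv(outdir / "overrepresentation.tsv", sep="\t", index=False)
            signature.write(outdir / "signature.json")
        elif config.signature_path:
            signature = sig.read_signature(config.signature_path)
        else:
            signature = sig.load_motera()
        result.signature = signature
        if config.mode == "derive":
            return result

        scores = scoring.signature_score(matrix, signature)
        scores.write(outdir / "scores.csv")
        result.scores = scores
        logger.info("scored %d samples with %d/%d signature genes",
                    len(scores.table), scores.table["n_genes_used"].iloc[0], len(signature))
        if config.mode == "score":
            return result

        # evaluate under estrogen deprivation by default: +E2 samples of
        # E2-responsive classes legitimately express the program and would
        # contaminate the negative class
        eval_ids = matrix.sample_ids
        if config.evaluate_e2 is not None:
            arm = samples.select(e2=config.evaluate_e2)
            eval_ids = [s for s in matrix.sample_ids if s in set(arm)] or eval_ids
        truth = samples.truth_labels(eval_ids)
        eval_scores = scores.scores.loc[eval_ids].to_numpy()
        roc = evaluation.roc_curve(eval_scores, truth)
        evaluation.roc_points_frame(roc).to_csv(outdir / "roc_points.csv", index=False)
        cutoff = evaluation.choose_cutoff(roc) if config.cutoff == "derive" else float(config.cutoff)
        pred = evaluation.classify(eval_scores, cutoff)
        report = evaluation.confusion_metrics(pred, truth, cutoff=cutoff)
        report.predictions.index = pd.Index(eval_ids)
        payload = report.to_dict()
        payload["auc"] = roc.auc
        payload["auc_ci"] = [roc.auc_ci_low, roc.auc_ci_high]
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
        result.roc, result.report = roc, report
        logger.info("evaluation: AUC=%.4f cutoff=%.4f accuracy=%.4f", roc.auc, cutoff, report.accuracy)
        return result
    except Exception:
        logger.exception("pipeline stage failed; partial outputs retained in %s", outdir)
        raise
    finally:
        for h in list(logger.handlers):
            if isinstance(h, logging.FileHandler):
                logger.removeHandler(h)
                h.close()
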